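"""ChIP quantification: efficiency-corrected qPCR enrichment, spike-in
calibrated sequencing occupancy ratios, and centromere-anchored
composite profiles.

qPCR enrichment uses the primer-efficiency-corrected delta-CT:

    dCT        = CT_ChIP - (CT_Input - log_E(dilution))
    enrichment = E ** (-dCT)

where ``E`` is the primer efficiency (fold amplification per cycle, in
(1, 2]), the dilution correction ``log_E(dilution)`` accounts for the
input being a diluted aliquot, and the CT entering the formula is the
geometric mean of technical replicates.  "log_E" is the logarithm with
base E: with dilution 1 the correction vanishes, which is the only
dimensionally consistent reading.

Spike-in calibration: reads from a calibration genome (e.g. S. pombe
chromatin mixed into every sample) give the occupancy ratio

    OR = (Wc * IPx) / (Wx * IPc)

with W = input reads, IP = ChIP reads, c = calibration genome, x =
experimental genome.  Per-position coverage is multiplied by OR so
signal is comparable across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QpcrMeasurement:
    """CT readings for one (sample, primer, role) with primer metadata."""

    sample: str
    primer: str
    role: str  # "ChIP" or "Input"
    ct_values: np.ndarray  # technical replicates, cycles
    efficiency: float  # fold/cycle, in (1, 2]
    dilution: float = 1.0  # input dilution factor, >= 1
    replicate: str | None = None  # biological replicate id

    def __post_init__(self) -> None:
        self.ct_values = np.atleast_1d(np.asarray(self.ct_values, dtype=float))
        if self.ct_values.size < 1:
            raise ValueError("need at least one technical replicate CT")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError(f"primer efficiency must be in (1, 2]; got {self.efficiency}")
        if self.dilution < 1:
            raise ValueError("input dilution factor must be >= 1")

    @property
    def ct(self) -> float:
        """Geometric mean of technical-replicate CTs."""
        return float(stats.gmean(self.ct_values))


def qpcr_enrichment(m_chip: QpcrMeasurement, m_input: QpcrMeasurement) -> float:
    """Efficiency-corrected ChIP/input enrichment fraction."""
    if m_chip.primer != m_input.primer:
        raise ValueError(
            f"primer mismatch: {m_chip.primer!r} vs {m_input.primer!r}"
        )
    if m_chip.efficiency != m_input.efficiency:
        raise ValueError("ChIP and Input must share one primer efficiency")
    e = m_chip.efficiency
    dct = m_chip.ct - (m_input.ct - np.log(m_input.dilution) / np.log(e))
    return float(e ** (-dct))


@dataclass
class AggregateResult:
    """Across-biological-replicate summary of two paired conditions."""

    mean_a: float
    sem_a: float | None
    mean_b: float
    sem_b: float | None
    t: float | None
    p: float | None
    n: int
    degenerate: bool  # zero-variance paired differences


def aggregate_replicates(values_a, values_b) -> AggregateResult:
    """Mean, SEM and two-tailed paired t-test across biological replicates.

    ``values_a``/``values_b`` are enrichments for two conditions, paired
    by biological replicate.  SEM needs >= 2 replicates; the paired test
    needs >= 3.  Identical pairs (zero variance of differences) make the
    t statistic undefined: the result carries ``degenerate=True`` with
    ``p=None`` instead of a fabricated p-value.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("conditions must have paired (equal-length) replicates")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing replicate value in paired data")
    n = a.size
    sem_a = float(stats.sem(a, ddof=1)) if n > 1 else None
    sem_b = float(stats.sem(b, ddof=1)) if n > 1 else None
    t = p = None
    degenerate = False
    if n >= 3:
        diffs = a - b
        if np.allclose(diffs, diffs[0]):
            degenerate = True
        else:
            res = stats.ttest_rel(a, b)
            t, p = float(res.statistic), float(res.pvalue)
    return AggregateResult(
        mean_a=float(a.mean()),
        sem_a=sem_a,
        mean_b=float(b.mean()),
        sem_b=sem_b,
        t=t,
        p=p,
        n=n,
        degenerate=degenerate,
    )


@dataclass
class ChipSeqCounts:
    """Read counts for spike-in calibration (all strictly positive)."""

    wx: float  # input reads, experimental genome
    ipx: float  # ChIP reads, experimental genome
    wc: float  # input reads, calibration genome
    ipc: float  # ChIP reads, calibration genome

    def __post_init__(self) -> None:
        for name in ("wx", "ipx", "wc", "ipc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"count {name} must be strictly positive")


def occupancy_ratio(c: ChipSeqCounts) -> float:
    """Spike-in occupancy ratio OR = (Wc * IPx) / (Wx * IPc)."""
    return float((c.wc * c.ipx) / (c.wx * c.ipc))


@dataclass
class CoverageTrack:
    """Per-basepair signal along one chromosome (dense, 1 value/bp)."""

    chrom: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")

    @property
    def length(self) -> int:
        return len(self.values)


def calibrate_track(track: CoverageTrack, occupancy: float) -> CoverageTrack:
    """Scale every per-position value by the occupancy ratio."""
    if occupancy <= 0:
        raise ValueError("occupancy ratio must be positive")
    return CoverageTrack(chrom=track.chrom, values=track.values * occupancy)


@dataclass
class CompositeProfile:
    """Centromere-anchored median signal over a symmetric window.

    ``offsets`` run from -half_window to +half_window bp relative to the
    centromere midpoint; ``median`` holds the across-centromere median
    at each offset (NaN where no centromere contributes) and
    ``n_contributing`` the number of centromeres with data there.
    """

    offsets: np.ndarray
    median: np.ndarray
    n_contributing: np.ndarray


def composite_median_profile(
    tracks: dict[str, CoverageTrack],
    centromere_midpoints: dict[str, int] | list[tuple[str, int]],
    half_window: int = 3000,
) -> CompositeProfile:
    """Median signal across centromeres, per offset in a 6 kb window.

    For each offset in ``[-half_window, +half_window]`` the median over
    centromeres of the signal at ``midpoint + offset`` is taken; offsets
    falling off a chromosome end are excluded for that centromere and
    ``n_contributing`` records how many remain.
    """
    if isinstance(centromere_midpoints, dict):
        cens = list(centromere_midpoints.items())
    else:
        cens = list(centromere_midpoints)
    if not cens:
        raise ValueError("no centromeres given")
    offsets = np.arange(-half_window, half_window + 1)
    width = len(offsets)
    mat = np.full((len(cens), width), np.nan)
    for k, (chrom, mid) in enumerate(cens):
        track = tracks[chrom]
        if not 0 <= mid < track.length:
            raise ValueError(f"centromere midpoint {mid} outside {chrom}")
        pos = mid + offsets
        valid = (pos >= 0) & (pos < track.length)
        mat[k, valid] = track.values[pos[valid]]
    n_contrib = (~np.isnan(mat)).sum(axis=0)
    with np.errstate(all="ignore"):
        median = np.nanmedian(mat, axis=0)
    median[n_contrib == 0] = np.nan
    return CompositeProfile(offsets=offsets, median=median, n_contributing=n_contrib)


def profile_difference(a: CompositeProfile, b: CompositeProfile) -> CompositeProfile:
    """Elementwise ``a - b``; offsets must match, missing data stays NaN."""
    if not np.array_equal(a.offsets, b.offsets):
        raise ValueError("profiles have mismatched offsets")
    diff = a.median - b.median  # NaN propagates where either side lacks data
    n = np.minimum(a.n_contributing, b.n_contributing)
    return CompositeProfile(offsets=a.offsets.copy(), median=diff, n_contributing=n)


# ---------------------------------------------------------------------------
# plain-text genome-track I/O (bedGraph: 4 columns, 0-based half-open; BED)

def write_bedgraph(tracks: dict[str, CoverageTrack], path) -> None:
    """Write dense tracks as 4-column bedGraph, collapsing equal runs."""
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            v = tracks[chrom].values
            if len(v) == 0:
                continue
            change = np.nonzero(np.diff(v))[0]
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [len(v)]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:.10g}\n")


def read_bedgraph(path, chrom_lengths: dict[str, int] | None = None) -> dict[str, CoverageTrack]:
    """Read a 4-column bedGraph into dense per-bp tracks."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["chrom", "start", "end", "value"],
        comment="#",
    )
    tracks: dict[str, CoverageTrack] = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        length = (
            chrom_lengths[chrom] if chrom_lengths is not None else int(grp["end"].max())
        )
        values = np.zeros(length)
        for start, end, value in zip(grp["start"], grp["end"], grp["value"]):
            values[int(start) : int(end)] = value
        tracks[str(chrom)] = CoverageTrack(chrom=str(chrom), values=values)
    return tracks


def write_bed(intervals: list[tuple[str, int, int, str]], path) -> None:
    """Write BED intervals (chrom, start, end, name); 0-based half-open."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed_midpoints(path) -> dict[str, int]:
    """Centromere anchors: interval midpoint of each BED record."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
    )
    return {
        str(r.chrom): int((int(r.start) + int(r.end)) // 2)
        for r in df.itertuples()
    }
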