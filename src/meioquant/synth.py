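"""Synthetic data with recorded ground truth for every pipeline stage.

Every input the quantification pipeline consumes can be generated here
— two-channel time-lapse movies of centromere foci, cell trajectories
with an anaphase-marker channel, qPCR CT tables, spike-in coverage
tracks, and peptide intensity tables — together with the ground truth
each observable was generated from, so that all downstream stages are
testable without any external download.

Defaults mirror the acquisition conditions of the emulated assays:
0.107 um/px, images every 15 min, 7 z-slices at 0.85 um spacing; split
probability 0.3 with proximal inter-focus distances ~ N(1.0, 0.2) um
(cohesion intact) and distal ~ N(3.5, 0.5) um (cohesion lost).  Camera
noise is Poisson (scaled signal) plus additive Gaussian, applied last.
Identical parameters (including the seed) give identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .classify import CellTrajectory, Focus
from .chip import CoverageTrack
from .stack import ImageStack

CATEGORY_CO = "co_segregated"
CATEGORY_PROXIMAL = "split_proximal"
CATEGORY_DISTAL = "split_distal"

HOM_SEGREGATING = "segregating"
HOM_CO_SEGREGATING = "co_segregating"
HOM_FAILING = "failing_to_segregate"


@dataclass
class NoiseModel:
    """Fluorescence camera model: Poisson(scaled signal)/scale + Gaussian."""

    poisson_scale: float = 1.0  # photons per AU; 0 disables shot noise
    gaussian_sd: float = 5.0  # read-noise sd, AU; 0 disables

    def __post_init__(self) -> None:
        if self.poisson_scale < 0 or self.gaussian_sd < 0:
            raise ValueError("noise amplitudes must be non-negative")


@dataclass
class SimParams:
    """Population-simulation parameters (defaults = study conditions)."""

    seed: int = 0
    n_cells: int = 50
    p_split: float = 0.3  # probability a cell's CEN5 focus is split at anaphase
    p_distal_given_split: float = 0.5  # split cells drawing a distal distance
    dist_proximal: tuple[float, float] = (1.0, 0.2)  # N(mean, sd), um
    dist_distal: tuple[float, float] = (3.5, 0.5)  # N(mean, sd), um
    spot_amplitude: float = 2000.0  # peak intensity at a focus, AU
    secondary_amplitude: float = 300.0  # readout-channel peak intensity, AU
    spot_sigma: float = 1.5  # px
    background_level: float = 100.0  # AU
    noise: NoiseModel = field(default_factory=NoiseModel)
    pixel_size: float = 0.107  # um/px
    z_slices: int = 7
    z_spacing: float = 0.85  # um
    frame_interval: float = 15.0  # min
    n_frames: int = 10
    onset_frame_range: tuple[int, int] = (3, 7)  # half-open [lo, hi)
    image_shape: tuple[int, int] = (52, 52)  # px

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_split <= 1.0:
            raise ValueError("p_split must be a probability")
        if not 0.0 <= self.p_distal_given_split <= 1.0:
            raise ValueError("p_distal_given_split must be a probability")
        for name in ("spot_amplitude", "secondary_amplitude", "spot_sigma",
                     "background_level", "pixel_size", "z_spacing",
                     "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spot_amplitude <= self.background_level:
            raise ValueError("spot_amplitude must exceed background_level")
        lo, hi = self.onset_frame_range
        if not 0 <= lo < hi:
            raise ValueError("onset_frame_range must satisfy 0 <= lo < hi")
        # the 2-frame scoring window after the latest onset (hi - 1)
        # must fit inside the movie
        if self.n_frames < hi + 2:
            raise ValueError(
                "n_frames too small: classification window would overrun "
                f"(need >= {hi + 2}, got {self.n_frames})"
            )


@dataclass
class CellTruth:
    """Ground truth for one simulated cell."""

    cell_id: str
    category: str
    onset_frame: int
    split_distance_um: float | None
    positions_um: list  # per frame: list of (y, x)
    spot_amplitude: float
    secondary_amplitude: float


@dataclass
class GroundTruth:
    """Ground truth for a generated dataset (one entry per observable)."""

    cells: list[CellTruth] = field(default_factory=list)
    qpcr_enrichments: list[float] = field(default_factory=list)
    noiseless_tracks: dict = field(default_factory=dict)
    per_residue_log2fc: list | None = None

    def to_json(self, path) -> None:
        payload = {
            "cells": [asdict(c) for c in self.cells],
            "qpcr_enrichments": self.qpcr_enrichments,
            "noiseless_tracks": {
                k: list(v.values) for k, v in self.noiseless_tracks.items()
            },
            "per_residue_log2fc": self.per_residue_log2fc,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# movie / trajectory simulation


def _render_frame(
    shape: tuple[int, int],
    foci_px: list[tuple[float, float, float, float]],  # (y, x, z_slice, peak)
    params: SimParams,
) -> np.ndarray:
    """Render one channel of one frame: z-stack of Gaussian spots.

    Spots are symmetric 2-D Gaussians on each slice, attenuated in z by
    a 1-D Gaussian around the focus' z position (sigma = 0.5 slices),
    on a flat background.  Peak total intensity at the focus equals the
    configured amplitude.
    """
    h, w = shape
    z = params.z_slices
    img = np.full((z, h, w), params.background_level, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    sig2 = 2.0 * params.spot_sigma**2
    z_sig2 = 2.0 * 0.5**2  # z attenuation sigma in slice units
    for y0, x0, z0, peak in foci_px:
        lateral = np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2) / sig2)
        for zi in range(z):
            atten = np.exp(-((zi - z0) ** 2) / z_sig2)
            img[zi] += (peak - params.background_level) * atten * lateral
    return img


def _apply_noise(img: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    out = img
    if noise.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * noise.poisson_scale) / noise.poisson_scale
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def make_population(
    params: SimParams, render_images: bool = True
) -> tuple[list[ImageStack], list[CellTrajectory], GroundTruth]:
    """Simulate a population of heterozygously marked cells.

    Each cell shows one focus per frame before its anaphase onset;
    after onset it keeps one focus (co-segregation, probability
    ``1 - p_split``) or shows two foci at a distance drawn from the
    proximal or distal distribution.  The marker channel flips at the
    onset frame; camera noise is applied last.  With
    ``render_images=False`` only trajectories and ground truth are
    produced (the movie list is empty), which keeps large
    parameter-recovery simulations cheap.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0]) * params.pixel_size  # um
    margin_um = 3.0 * params.pixel_size  # keep spots off the image border
    stacks: list[ImageStack] = []
    trajectories: list[CellTrajectory] = []
    truth = GroundTruth()
    lo, hi = params.onset_frame_range
    for i in range(params.n_cells):
        cell_id = f"cell_{i:04d}"
        split = rng.random() < params.p_split
        if split:
            distal = rng.random() < params.p_distal_given_split
            mean, sd = params.dist_distal if distal else params.dist_proximal
            d = float(abs(rng.normal(mean, sd)))
            category = CATEGORY_DISTAL if distal else CATEGORY_PROXIMAL
        else:
            d = None
            category = CATEGORY_CO
        onset = int(rng.integers(lo, hi))
        theta = float(rng.uniform(0, 2 * np.pi))
        axis = np.array([np.sin(theta), np.cos(theta)])
        if d is not None:
            # clamp the half-extent so both foci stay inside the field
            half_max = _max_half_extent(center, axis, (h, w), params.pixel_size, margin_um)
            d = min(d, 2.0 * half_max)
        pole_dir = axis  # co-segregating focus moves along the same axis
        positions: list[list[tuple[float, float]]] = []
        marker: list[bool] = []
        foci_frames: list[list[Focus]] = []
        for f in range(params.n_frames):
            marker.append(f >= onset)
            if f <= onset:
                pts = [center + rng.normal(0.0, 0.02, size=2)]
            elif category == CATEGORY_CO:
                step = min(1.0 * (f - onset), 1.5)
                step = min(step, _max_half_extent(center, pole_dir, (h, w),
                                                  params.pixel_size, margin_um))
                pts = [center + step * pole_dir]
            else:
                pts = [center - (d / 2.0) * axis, center + (d / 2.0) * axis]
            positions.append([(float(p[0]), float(p[1])) for p in pts])
            foci_frames.append(
                [
                    Focus(
                        y_um=float(p[0]),
                        x_um=float(p[1]),
                        intensity=params.spot_amplitude,
                        secondary_intensity=params.secondary_amplitude,
                    )
                    for p in pts
                ]
            )
        traj = CellTrajectory(
            cell_id=cell_id,
            foci=foci_frames,
            marker_state=marker,
            frame_interval=params.frame_interval,
        )
        trajectories.append(traj)
        truth.cells.append(
            CellTruth(
                cell_id=cell_id,
                category=category,
                onset_frame=onset,
                split_distance_um=d,
                positions_um=positions,
                spot_amplitude=params.spot_amplitude,
                secondary_amplitude=params.secondary_amplitude,
            )
        )
        if render_images:
            voxels = np.empty((params.n_frames, params.z_slices, 2, h, w))
            z_center = (params.z_slices - 1) / 2.0
            for f in range(params.n_frames):
                foci_px = [
                    (
                        p[0] / params.pixel_size,
                        p[1] / params.pixel_size,
                        z_center,
                        params.spot_amplitude,
                    )
                    for p in positions[f]
                ]
                voxels[f, :, 0] = _render_frame((h, w), foci_px, params)
                foci_px2 = [
                    (y, x, z, params.secondary_amplitude) for y, x, z, _ in foci_px
                ]
                voxels[f, :, 1] = _render_frame((h, w), foci_px2, params)
            voxels = _apply_noise(voxels, params.noise, rng)
            stacks.append(
                ImageStack(
                    voxels=voxels,
                    pixel_size=params.pixel_size,
                    frame_interval=params.frame_interval,
                    channel_names=("tdTomato", "GFP"),
                )
            )
    return stacks, trajectories, truth


def _max_half_extent(center, axis, shape, pixel_size, margin_um) -> float:
    """Largest s such that center +/- s*axis stays inside the field."""
    h, w = shape
    limits = []
    for k in range(2):
        hi_um = ((h - 1) if k == 0 else (w - 1)) * pixel_size - margin_um
        lo_um = margin_um
        a = axis[k]
        if abs(a) > 1e-12:
            limits.append((hi_um - center[k]) / a if a > 0 else (lo_um - center[k]) / a)
            limits.append((lo_um - center[k]) / a if a > 0 else (hi_um - center[k]) / a)
    pos = [l for l in limits if l > 0]
    return float(min(pos)) if pos else 0.0


def make_homozygous_trajectories(
    n_cells: int,
    probs: tuple[float, float, float] = (0.6, 0.2, 0.2),
    params: SimParams | None = None,
    seed: int | None = None,
) -> tuple[list[CellTrajectory], list[str]]:
    """Simulate homozygously marked cells with pole-labelled foci.

    ``probs`` are the (segregating, co_segregating, failing) category
    probabilities.  Segregating cells place their two foci at opposite
    poles after onset; co-segregating cells place both at one pole;
    failing cells never separate their foci beyond the split threshold.
    Pole labels are attached to each focus, as the classifier expects.
    """
    params = params or SimParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    p = np.asarray(probs, dtype=float)
    if p.min() < 0 or not np.isclose(p.sum(), 1.0):
        raise ValueError("probs must be non-negative and sum to 1")
    h, w = params.image_shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0]) * params.pixel_size
    axis = np.array([0.0, 1.0])
    pole_a = center - 2.0 * axis
    pole_b = center + 2.0 * axis
    lo, hi = params.onset_frame_range
    categories = [HOM_SEGREGATING, HOM_CO_SEGREGATING, HOM_FAILING]
    trajectories, truths = [], []
    for i in range(n_cells):
        cat = categories[int(rng.choice(3, p=p))]
        onset = int(rng.integers(lo, hi))
        foci_frames: list[list[Focus]] = []
        marker: list[bool] = []
        for f in range(params.n_frames):
            marker.append(f >= onset)
            amp = params.spot_amplitude
            if f <= onset:
                foci = [
                    Focus(center[0], center[1] - 0.1, amp, pole=None),
                    Focus(center[0], center[1] + 0.1, amp, pole=None),
                ]
            elif cat == HOM_SEGREGATING:
                foci = [
                    Focus(pole_a[0], pole_a[1], amp, pole=0),
                    Focus(pole_b[0], pole_b[1], amp, pole=1),
                ]
            elif cat == HOM_CO_SEGREGATING:
                foci = [
                    Focus(pole_a[0], pole_a[1] - 0.1, amp, pole=0),
                    Focus(pole_a[0], pole_a[1] + 0.1, amp, pole=0),
                ]
            else:  # failing: no poleward movement
                foci = [
                    Focus(center[0], center[1] - 0.1, amp, pole=None),
                    Focus(center[0], center[1] + 0.1, amp, pole=None),
                ]
            foci_frames.append(foci)
        trajectories.append(
            CellTrajectory(
                cell_id=f"hom_{i:04d}",
                foci=foci_frames,
                marker_state=marker,
                frame_interval=params.frame_interval,
            )
        )
        truths.append(cat)
    return trajectories, truths


# ---------------------------------------------------------------------------
# qPCR table generation (inverse of the enrichment formula)


def make_qpcr_table(
    rows: list[tuple[float, float, float]],
    seed: int = 0,
    ct_input: float = 20.0,
    jitter_sd: float = 0.0,
    n_technical: int = 3,
):
    """Generate CT tables whose forward computation returns known
    enrichments.

    ``rows`` holds ``(efficiency E, input dilution factor,
    true_enrichment)`` triples.  CTs are constructed so that
    ``E**(-dCT)`` equals the planted enrichment; with ``jitter_sd=0``
    the round trip through :func:`meioquant.chip.qpcr_enrichment` is
    exact to floating precision.

    Returns ``(measurements, truth)`` where measurements is a list of
    ``(chip, input)`` :class:`~meioquant.chip.QpcrMeasurement` pairs.
    """
    from .chip import QpcrMeasurement

    rng = np.random.default_rng(seed)
    measurements = []
    truth: list[float] = []
    for k, (eff, dilution, enrichment) in enumerate(rows):
        if enrichment <= 0:
            raise ValueError("true enrichment must be positive")
        if not 1.0 < eff <= 2.0:
            raise ValueError("efficiency must be in (1, 2]")
        log_e = np.log(eff)
        ct_chip = ct_input - np.log(dilution) / log_e - np.log(enrichment) / log_e
        jitter_c = rng.normal(0.0, jitter_sd, n_technical) if jitter_sd > 0 else np.zeros(n_technical)
        jitter_i = rng.normal(0.0, jitter_sd, n_technical) if jitter_sd > 0 else np.zeros(n_technical)
        m_chip = QpcrMeasurement(
            sample=f"sample_{k}", primer=f"primer_{k}", role="ChIP",
            ct_values=ct_chip + jitter_c, efficiency=eff, dilution=dilution,
        )
        m_input = QpcrMeasurement(
            sample=f"sample_{k}", primer=f"primer_{k}", role="Input",
            ct_values=ct_input + jitter_i, efficiency=eff, dilution=dilution,
        )
        measurements.append((m_chip, m_input))
        truth.append(float(enrichment))
    return measurements, truth


def qpcr_to_dataframe(measurements) -> pd.DataFrame:
    """Tidy CSV-ready table: one row per technical-replicate CT."""
    rows = []
    for m_chip, m_input in measurements:
        for m in (m_chip, m_input):
            for r, ct in enumerate(m.ct_values):
                rows.append(
                    {
                        "sample": m.sample, "primer": m.primer, "role": m.role,
                        "technical_rep": r, "ct": ct,
                        "efficiency": m.efficiency, "dilution": m.dilution,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coverage-track generation


def triangular_peak(half_width: int = 2000, height: float = 10.0) -> np.ndarray:
    """A symmetric triangular peak of odd length ``2*half_width + 1``."""
    return np.bartlett(2 * half_width + 1) * height


def make_coverage_tracks(
    chrom_lengths: dict[str, int],
    centromere_midpoints: dict[str, int],
    peak_shape: np.ndarray | None = None,
    background: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    end_margin: int = 3000,
):
    """Per-bp coverage tracks with a planted peak at each centromere.

    Signal = background + peak_shape centered at the midpoint + Gaussian
    noise; the noiseless track is recorded as ground truth.  A midpoint
    within ``end_margin`` bp of a chromosome end truncates the planted
    window and is carried as a warning flag in the output.

    Returns ``(tracks, bed_intervals, truth, warnings)``.
    """
    rng = np.random.default_rng(seed)
    tracks: dict[str, CoverageTrack] = {}
    truth: dict[str, CoverageTrack] = {}
    warnings: list[str] = []
    bed: list[tuple[str, int, int, str]] = []
    for chrom, length in chrom_lengths.items():
        mid = centromere_midpoints.get(chrom)
        clean = np.full(length, float(background))
        if mid is not None:
            if not 0 <= mid < length:
                raise ValueError(f"centromere midpoint {mid} outside {chrom}")
            if mid < end_margin or mid > length - 1 - end_margin:
                warnings.append(chrom)
            if peak_shape is not None and len(peak_shape) > 0:
                half = (len(peak_shape) - 1) // 2
                lo = mid - half
                src_lo = max(0, -lo)
                dst_lo = max(0, lo)
                dst_hi = min(length, lo + len(peak_shape))
                clean[dst_lo:dst_hi] += peak_shape[src_lo : src_lo + (dst_hi - dst_lo)]
            bed.append((chrom, max(0, mid - 60), min(length, mid + 60), f"CEN_{chrom}"))
        noisy = clean.copy()
        if noise_sd > 0:
            noisy = np.clip(noisy + rng.normal(0.0, noise_sd, size=length), 0.0, None)
        tracks[chrom] = CoverageTrack(chrom=chrom, values=noisy)
        truth[chrom] = CoverageTrack(chrom=chrom, values=clean)
    return tracks, bed, truth, warnings


# ---------------------------------------------------------------------------
# peptide-table generation


def make_peptide_table(
    protein_length: int,
    peptides: list[tuple[int, int, str]],
    per_residue_log2fc: np.ndarray,
    smc3_factors: dict | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    jitter_sd: float = 0.0,
    conditions: tuple[str, str] = ("WT", "mutant"),
    base_intensity: float = 1.0e6,
):
    """Generate target + reference peptide tables with planted fold
    changes.

    ``peptides`` holds ``(start, end, phospho_state)`` spans (1-based
    inclusive).  A peptide's mutant/WT fold change is ``2**mean(fc over
    its span)``; on residues covered by exactly one peptide whose span
    has a constant planted fc, the per-residue pipeline recovers the
    planted value exactly at ``jitter_sd=0``.  ``smc3_factors`` maps a
    condition (or ``(condition, replicate)``) to the IP-efficiency
    scale applied to *all* of that sample's intensities, including the
    reference-protein peptides, so normalization can cancel it.

    Returns ``(target_table, reference_table, truth_log2fc)``.
    """
    if not peptides:
        raise ValueError("peptide list must not be empty")
    fc = np.asarray(per_residue_log2fc, dtype=float)
    if fc.shape != (protein_length,):
        raise ValueError("per_residue_log2fc must have one value per residue")
    for start, end, _state in peptides:
        if not (1 <= start <= end <= protein_length):
            raise ValueError(f"span {start}..{end} outside protein of length {protein_length}")
    baseline, mutant = conditions
    rng = np.random.default_rng(seed)

    def factor(cond: str, rep: str) -> float:
        if smc3_factors is None:
            return 1.0
        if (cond, rep) in smc3_factors:
            return float(smc3_factors[(cond, rep)])
        return float(smc3_factors.get(cond, 1.0))

    rows = []
    for pid, (start, end, state) in enumerate(peptides):
        pep_fc = float(fc[start - 1 : end].mean())
        for r in range(n_replicates):
            rep = f"rep{r + 1}"
            wt_val = base_intensity * float(rng.uniform(0.5, 1.5))
            mut_val = wt_val * 2.0**pep_fc
            if jitter_sd > 0:
                mut_val *= 2.0 ** float(rng.normal(0.0, jitter_sd))
            for cond, val in ((baseline, wt_val), (mutant, mut_val)):
                rows.append(
                    {
                        "peptide_id": f"pep_{pid:03d}",
                        "start": start, "end": end, "phospho_state": state,
                        "condition": cond, "replicate": rep,
                        "intensity": val * factor(cond, rep),
                    }
                )
    target = pd.DataFrame(rows)
    ref_rows = []
    for pid, ref_val in enumerate((2.0e6, 3.0e6)):  # two reference peptides
        for r in range(n_replicates):
            rep = f"rep{r + 1}"
            for cond in conditions:
                ref_rows.append(
                    {
                        "peptide_id": f"smc3_{pid}",
                        "start": 1, "end": 10, "phospho_state": "nonphosphopeptide",
                        "condition": cond, "replicate": rep,
                        "intensity": ref_val * factor(cond, rep),
                    }
                )
    reference = pd.DataFrame(ref_rows)
    return target, reference, fc.copy()


# ---------------------------------------------------------------------------
# trajectory serialization


def trajectories_to_dataframe(trajectories: list[CellTrajectory]) -> pd.DataFrame:
    """One row per focus per frame, plus the marker state."""
    rows = []
    for traj in trajectories:
        for f, (foci, marker) in enumerate(zip(traj.foci, traj.marker_state)):
            if not foci:
                rows.append(
                    {
                        "cell_id": traj.cell_id, "frame": f, "focus": -1,
                        "y_um": np.nan, "x_um": np.nan,
                        "intensity": np.nan, "secondary_intensity": np.nan,
                        "marker": marker,
                    }
                )
            for k, focus in enumerate(foci):
                rows.append(
                    {
                        "cell_id": traj.cell_id, "frame": f, "focus": k,
                        "y_um": focus.y_um, "x_um": focus.x_um,
                        "intensity": focus.intensity,
                        "secondary_intensity": focus.secondary_intensity,
                        "marker": marker,
                    }
                )
    return pd.DataFrame(rows)


def trajectories_from_dataframe(
    df: pd.DataFrame, frame_interval: float = 15.0
) -> list[CellTrajectory]:
    """Inverse of :func:`trajectories_to_dataframe`."""
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        n_frames = int(grp["frame"].max()) + 1
        foci: list[list[Focus]] = [[] for _ in range(n_frames)]
        marker = [False] * n_frames
        for r in grp.itertuples():
            marker[int(r.frame)] = bool(r.marker)
            if int(r.focus) >= 0 and not np.isnan(r.y_um):
                foci[int(r.frame)].append(
                    Focus(
                        y_um=float(r.y_um), x_um=float(r.x_um),
                        intensity=float(r.intensity),
                        secondary_intensity=(
                            None if pd.isna(r.secondary_intensity)
                            else float(r.secondary_intensity)
                        ),
                    )
                )
        out.append(
            CellTrajectory(
                cell_id=str(cell_id), foci=foci, marker_state=marker,
                frame_interval=frame_interval,
            )
        )
    return out
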