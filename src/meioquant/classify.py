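"""Live-cell chromosome-segregation phenotype scoring.

Scoring follows the anaphase-anchored conventions of the assay: the
anaphase-I onset of each cell is the first frame where its marker
(Cdc14 release from the nucleolus, or securin/Pds1 disappearance) turns
on; distances between centromere foci are then measured within the two
frames strictly after onset (the onset frame itself can optionally be
included).  Heterozygously marked centromeres yield three categories:

* ``co_segregated``   — a single focus (or foci closer than
  ``split_min``): sister centromeres travelled together.
* ``split_proximal``  — two distinct foci < 2 um apart: monoorientation
  lost, but protected pericentromeric cohesin still holds sisters.
* ``split_distal``    — foci >= 2 um apart: both monoorientation and
  cohesion lost.

The 2 um boundary itself is assigned to ``split_distal`` (proximal is
defined as strictly "< 2 um").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CO_SEGREGATED = "co_segregated"
SPLIT_PROXIMAL = "split_proximal"
SPLIT_DISTAL = "split_distal"
UNCLASSIFIABLE = "unclassifiable"

SEGREGATING = "segregating"
CO_SEGREGATING = "co_segregating"
FAILING = "failing_to_segregate"

#: minimum inter-focus distance (um) to call two foci "distinct";
#: roughly 3-4 px at the stated magnification.
DEFAULT_SPLIT_MIN = 0.4
#: proximal/distal category boundary (um).
DEFAULT_BOUNDARY = 2.0
#: default presence call: focus brighter than this factor over background.
DEFAULT_PRESENCE_FACTOR = 2.0
#: maximum nearest-neighbor step (um/frame) when linking foci over time.
MAX_LINK_STEP_UM = 1.5


@dataclass
class Focus:
    """One focus in one frame: position in um, per-channel intensity."""

    y_um: float
    x_um: float
    intensity: float
    secondary_intensity: float | None = None
    pole: int | None = None  # 0/1 spindle-pole assignment, if known

    @property
    def position(self) -> np.ndarray:
        return np.array([self.y_um, self.x_um])


@dataclass
class CellTrajectory:
    """Per-frame foci and anaphase-marker state for one cell."""

    cell_id: str
    foci: list[list[Focus]]  # one list per frame
    marker_state: list[bool]
    frame_interval: float = 15.0  # min

    def __post_init__(self) -> None:
        if len(self.foci) != len(self.marker_state):
            raise ValueError("foci and marker_state must cover the same frames")

    @property
    def n_frames(self) -> int:
        return len(self.foci)


@dataclass
class SegregationCall:
    category: str
    max_distance: float | None
    onset_frame: int | None


@dataclass
class HomozygousCall:
    category: str
    onset_frame: int | None


@dataclass
class PresenceTimecourse:
    frames: list[int]
    present: list[bool]
    truncated: bool


def anaphase_onset(traj: CellTrajectory) -> int | None:
    """First frame where the anaphase marker is on; ``None`` if never."""
    for f, state in enumerate(traj.marker_state):
        if state:
            return f
    return None


def _window_frames(
    onset: int, n_frames: int, include_onset: bool = False
) -> tuple[list[int], bool]:
    """The two scoring frames after onset; flags window overrun."""
    start = onset if include_onset else onset + 1
    frames = [start, start + 1]
    if frames[-1] > n_frames - 1:
        return [f for f in frames if f < n_frames], True
    return frames, False


def _two_brightest(foci: list[Focus]) -> list[Focus]:
    return sorted(foci, key=lambda s: -s.intensity)[:2]


def max_split_distance(
    traj: CellTrajectory, onset: int, include_onset: bool = False
) -> tuple[float | None, bool]:
    """Maximum distance (um) between the two brightest foci in the window.

    Scans the two frames strictly after ``onset`` (optionally including
    the onset frame).  Returns ``(distance, overrun)``: distance is
    ``None`` when two foci are never simultaneously present; ``overrun``
    flags a window that runs past the end of the movie.
    """
    frames, overrun = _window_frames(onset, traj.n_frames, include_onset)
    best: float | None = None
    for f in frames:
        foci = traj.foci[f]
        if len(foci) >= 2:
            a, b = _two_brightest(foci)
            d = float(np.linalg.norm(a.position - b.position))
            if best is None or d > best:
                best = d
    return best, overrun


def classify_heterozygous(
    traj: CellTrajectory,
    boundary_um: float = DEFAULT_BOUNDARY,
    split_min: float = DEFAULT_SPLIT_MIN,
    include_onset: bool = False,
) -> SegregationCall:
    """Categorize a heterozygously marked cell by its anaphase-I split.

    ``None`` or sub-``split_min`` distance -> co_segregated;
    ``split_min <= d < boundary_um`` -> split_proximal;
    ``d >= boundary_um`` -> split_distal.  Cells without a marker
    transition, or whose scoring window overruns the movie, are
    unclassifiable.
    """
    onset = anaphase_onset(traj)
    if onset is None:
        return SegregationCall(UNCLASSIFIABLE, None, None)
    d, overrun = max_split_distance(traj, onset, include_onset)
    if overrun:
        return SegregationCall(UNCLASSIFIABLE, d, onset)
    if d is None or d < split_min:
        return SegregationCall(CO_SEGREGATED, d, onset)
    if d < boundary_um:
        return SegregationCall(SPLIT_PROXIMAL, d, onset)
    return SegregationCall(SPLIT_DISTAL, d, onset)


def assign_poles(
    foci: list[Focus],
    pole_a,
    pole_b,
    capture_radius_um: float = 1.0,
) -> None:
    """Nearest-pole heuristic: label each focus with its closest pole.

    A focus farther than ``capture_radius_um`` from both poles keeps
    ``pole=None`` (no poleward movement).
    """
    pa = np.asarray(pole_a, dtype=float)
    pb = np.asarray(pole_b, dtype=float)
    for focus in foci:
        da = float(np.linalg.norm(focus.position - pa))
        db = float(np.linalg.norm(focus.position - pb))
        if min(da, db) > capture_radius_um:
            focus.pole = None
        else:
            focus.pole = 0 if da <= db else 1


def classify_homozygous(
    traj: CellTrajectory,
    split_min: float = DEFAULT_SPLIT_MIN,
    include_onset: bool = False,
) -> HomozygousCall:
    """Score a homozygously marked cell within two frames after onset.

    Foci moving to opposite poles -> segregating; all foci at one pole
    -> co_segregating; no poleward separation (no focus acquires a pole
    label and foci never separate beyond ``split_min``) ->
    failing_to_segregate.  Requires pole labels from the simulator or
    from :func:`assign_poles`.
    """
    onset = anaphase_onset(traj)
    if onset is None:
        return HomozygousCall(UNCLASSIFIABLE, None)
    frames, overrun = _window_frames(onset, traj.n_frames, include_onset)
    if overrun and not frames:
        return HomozygousCall(UNCLASSIFIABLE, onset)
    poles: set[int] = set()
    moved = False
    for f in frames:
        for focus in _two_brightest(traj.foci[f]):
            if focus.pole is not None:
                poles.add(focus.pole)
                moved = True
    if not moved:
        return HomozygousCall(FAILING, onset)
    if len(poles) == 2:
        return HomozygousCall(SEGREGATING, onset)
    return HomozygousCall(CO_SEGREGATING, onset)


def score_presence(
    traj: CellTrajectory,
    onset: int,
    background: float,
    channel: str = "primary",
    presence_factor: float = DEFAULT_PRESENCE_FACTOR,
    window_hours: float = 4.0,
) -> PresenceTimecourse:
    """Per-frame marker-presence booleans for 4 h after onset.

    A frame is "present" when at least one focus in the chosen channel
    has mean intensity above ``presence_factor * background``.  The
    window covers frames strictly after onset up to ``window_hours``
    (16 frames at 15-min intervals); truncation by the movie end is
    flagged.
    """
    if background <= 0:
        raise ValueError("background must be positive")
    n_window = int(round(window_hours * 60.0 / traj.frame_interval))
    frames = list(range(onset + 1, onset + n_window + 1))
    truncated = frames[-1] > traj.n_frames - 1 if frames else False
    frames = [f for f in frames if f < traj.n_frames]
    present = []
    for f in frames:
        vals = [
            (s.intensity if channel == "primary" else (s.secondary_intensity or 0.0))
            for s in traj.foci[f]
        ]
        present.append(any(v > presence_factor * background for v in vals))
    return PresenceTimecourse(frames=frames, present=present, truncated=truncated)


def normalize_intensity(values, background_cells) -> np.ndarray:
    """Divide intensities by the mean background signal of control cells.

    Mirrors the convention of normalizing GFP intensity to the average
    background signal measured in 50 wild-type meiosis-II cells.
    """
    background_cells = np.asarray(background_cells, dtype=float)
    if background_cells.size == 0:
        raise ValueError("background list is empty")
    mean_bg = background_cells.mean()
    if mean_bg <= 0:
        raise ValueError("background mean must be positive")
    return np.asarray(values, dtype=float) / mean_bg


def anaphase_intensity_window(
    traj: CellTrajectory,
    onset: int,
    background_cells,
    include_onset: bool = False,
) -> tuple[float | None, bool]:
    """Background-normalized readout-channel intensity just after onset.

    Averages the secondary-channel intensity of the brightest focus
    (the kinetochore footprint) over the first two frames after onset
    and normalizes via :func:`normalize_intensity`.  Returns
    ``(value, flag)`` with ``value=None`` and the flag set when no foci
    fall inside the window or the window overruns the movie.
    """
    frames, overrun = _window_frames(onset, traj.n_frames, include_onset)
    vals = []
    for f in frames:
        foci = [s for s in traj.foci[f] if s.secondary_intensity is not None]
        if foci:
            brightest = max(foci, key=lambda s: s.intensity)
            vals.append(brightest.secondary_intensity)
    if not vals:
        return None, True
    value = float(normalize_intensity(np.mean(vals), background_cells))
    return value, overrun


def population_summary(calls_by_replicate: list[list[str]]) -> pd.DataFrame:
    """Per-category fractions with across-replicate mean and SEM.

    ``calls_by_replicate`` holds one list of category labels per
    experimental replicate.  SEM (sd/sqrt(n), ddof=1) is null for a
    single replicate.
    """
    if not calls_by_replicate or any(len(r) == 0 for r in calls_by_replicate):
        raise ValueError("every replicate must contain at least one call")
    categories = sorted({c for rep in calls_by_replicate for c in rep})
    rows = []
    for cat in categories:
        fracs = np.array(
            [sum(c == cat for c in rep) / len(rep) for rep in calls_by_replicate]
        )
        n = len(fracs)
        sem = float(fracs.std(ddof=1) / np.sqrt(n)) if n > 1 else None
        rows.append(
            {
                "category": cat,
                "fractions": list(fracs),
                "mean": float(fracs.mean()),
                "sem": sem,
                "n_replicates": n,
            }
        )
    return pd.DataFrame(rows)


def link_foci(
    frames_of_spots: list[list[Focus]],
    max_step_um: float = MAX_LINK_STEP_UM,
) -> list[list[Focus]]:
    """Greedy nearest-neighbor linking of foci between consecutive frames.

    The two-focus problem needs only trivial tracking: each focus in a
    frame is matched to the nearest focus of the previous frame if
    within ``max_step_um``; ordering within a frame is made stable by
    the match.  Returns the (re-ordered) per-frame lists.
    """
    linked: list[list[Focus]] = []
    prev: list[Focus] = []
    for foci in frames_of_spots:
        if not prev or not foci:
            ordered = list(foci)
        else:
            ordered = []
            remaining = list(foci)
            for p in prev:
                if not remaining:
                    break
                dists = [np.linalg.norm(p.position - s.position) for s in remaining]
                k = int(np.argmin(dists))
                if dists[k] <= max_step_um:
                    ordered.append(remaining.pop(k))
            ordered.extend(remaining)
        linked.append(ordered)
        prev = ordered or prev
    return linked
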