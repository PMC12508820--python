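"""RR-interval preprocessing: artifact filtering, 4 Hz resampling, segmentation.

Irregular beat-by-beat series are converted into the fixed-length vectors the
classifier consumes: a median-based artifact filter, natural cubic-spline
resampling onto an equidistant 4 Hz grid, 5-min phase segments of 1200 points
and 1-min epoch segments of 240 points, shorter sequences tail-padded with
zeros. Epochs follow the protocol windows: B4 and B5 are the last two baseline
minutes, S1 and S2 the first two stress minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from .synthetic import BeatSeries, PHASE_DURATION_S

__all__ = [
    "FS_HZ",
    "SEGMENT_LEN_5MIN",
    "SEGMENT_LEN_1MIN",
    "EPOCH_WINDOWS",
    "ResampledSeries",
    "Segment",
    "ArtifactRejectionError",
    "InsufficientDataError",
    "FilterResult",
    "artifact_filter",
    "resample_4hz",
    "segment_phase",
    "extract_epochs",
    "make_phase_dataset",
    "make_epoch_dataset",
]

logger = logging.getLogger(__name__)

FS_HZ: int = 4
SEGMENT_LEN_5MIN: int = 1200  # 300 s * 4 Hz
SEGMENT_LEN_1MIN: int = 240  # 60 s * 4 Hz

# Half-open [start, stop) windows in seconds from the parent phase onset.
EPOCH_WINDOWS: Dict[str, Tuple[str, float, float]] = {
    "B4": ("baseline", 180.0, 240.0),
    "B5": ("baseline", 240.0, 300.0),
    "S1": ("stress", 0.0, 60.0),
    "S2": ("stress", 60.0, 120.0),
}

# Artifact-filter thresholds: physiological RRI range, relative deviation from
# the local median, and the flagged fraction above which a series is rejected.
RRI_MIN_MS: float = 300.0
RRI_MAX_MS: float = 2000.0
MEDIAN_DEVIATION_FRAC: float = 0.25
N_MEDIAN_NEIGHBORS: int = 5
REJECT_FRACTION: float = 0.20


class ArtifactRejectionError(ValueError):
    """Raised when too large a fraction of beats is flagged as artifactual."""


class InsufficientDataError(ValueError):
    """Raised when a series has too few beats to support spline resampling."""


@dataclass(frozen=True)
class ResampledSeries:
    """Equidistant 4 Hz RRI values on the grid t0 + k / fs."""

    participant_id: str
    visit: int
    phase: str
    values: np.ndarray  # RRI (ms) at grid points
    t0: float = 0.0
    fs: int = FS_HZ
    group: str = ""

    def __post_init__(self) -> None:
        if self.fs != FS_HZ:
            raise ValueError(f"sampling rate fixed at {FS_HZ} Hz")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("resampled values must be finite")


@dataclass(frozen=True)
class Segment:
    """Fixed-length labeled input vector (1200 or 240 points).

    Positions at index >= ``n_valid`` are zero padding.
    """

    values: np.ndarray
    n_valid: int
    label: str  # "baseline"/"stress" or epoch "B4"/"B5"/"S1"/"S2"
    participant_id: str
    group: str
    visit: int

    def __post_init__(self) -> None:
        if len(self.values) not in (SEGMENT_LEN_5MIN, SEGMENT_LEN_1MIN):
            raise ValueError("segment length must be 1200 or 240")
        if not 1 <= self.n_valid <= len(self.values):
            raise ValueError("n_valid out of range")
        if self.n_valid < len(self.values) and np.any(self.values[self.n_valid:] != 0):
            raise ValueError("padded positions must be exactly zero")


class FilterResult(NamedTuple):
    series: BeatSeries
    n_corrections: int


def _local_medians(rri: np.ndarray) -> np.ndarray:
    """Median of the 5 nearest other intervals, per beat.

    Nearest-by-index with ties broken toward earlier beats, so interior
    beats use the fixed offsets {-3, -2, -1, +1, +2}; the few edge beats
    fall back to an explicit neighbor search.
    """
    n = len(rri)
    med = np.empty(n)
    if n > 6:
        interior = np.arange(3, n - 2)
        offsets = np.array([-3, -2, -1, 1, 2])
        med[3 : n - 2] = np.median(rri[interior[:, None] + offsets], axis=1)
    for i in (*range(min(3, n)), *range(max(3, n - 2), n)):
        order = sorted((j for j in range(n) if j != i),
                       key=lambda j: (abs(j - i), j))
        neighbors = order[:N_MEDIAN_NEIGHBORS]
        med[i] = np.median(rri[neighbors]) if neighbors else rri[i]
    return med


def artifact_filter(series: BeatSeries) -> FilterResult:
    """Flag and repair artifactual beats.

    A beat is flagged when its interval falls outside the physiological range
    [300, 2000] ms or deviates from the median of its 5 nearest neighboring
    intervals by more than 25%. Flagged intervals are replaced by cubic-spline
    interpolation over beat index through the unflagged beats, and beat times
    are recomputed by cumulative summation.

    Raises
    ------
    ArtifactRejectionError
        If more than 20% of beats are flagged.
    """
    rri = series.rri
    n = len(rri)
    med = _local_medians(rri)
    flagged = (
        (rri < RRI_MIN_MS)
        | (rri > RRI_MAX_MS)
        | (np.abs(rri - med) > MEDIAN_DEVIATION_FRAC * med)
    )
    n_flagged = int(flagged.sum())
    if n_flagged == 0:
        return FilterResult(series, 0)
    if n_flagged > REJECT_FRACTION * n:
        raise ArtifactRejectionError(
            f"{series.participant_id} v{series.visit} {series.phase}: "
            f"{n_flagged}/{n} beats flagged (> {REJECT_FRACTION:.0%})"
        )
    good = ~flagged
    if good.sum() >= 4:
        spline = CubicSpline(np.flatnonzero(good), rri[good], bc_type="natural")
        repaired = rri.copy()
        repaired[flagged] = spline(np.flatnonzero(flagged))
    else:  # too few clean beats for a cubic fit; fall back to the local median
        repaired = rri.copy()
        repaired[flagged] = med[flagged]
    repaired = np.clip(repaired, RRI_MIN_MS, RRI_MAX_MS)
    times = np.cumsum(repaired) / 1000.0
    logger.info(
        "%s v%d %s: corrected %d/%d beats",
        series.participant_id,
        series.visit,
        series.phase,
        n_flagged,
        n,
    )
    out = BeatSeries(
        series.participant_id, series.visit, series.phase, times, repaired,
        group=series.group,
    )
    return FilterResult(out, n_flagged)


#: How far (s) past the last observed beat the spline may be evaluated. The
#: heart keeps beating across the phase boundary, so the RR-interval function
#: is physiologically defined up to roughly one beat beyond the last R peak;
#: without this allowance the final grid samples of nearly every recording
#: would become zero padding, branding the last epoch of each phase with a
#: positional artifact that a classifier can exploit.
EXTRAPOLATION_LIMIT_S: float = 2.0


def resample_4hz(series: BeatSeries, duration: float) -> ResampledSeries:
    """Natural cubic-spline resampling of (beat time, RRI) onto a 4 Hz grid.

    The grid is k / 4 s for k = 0 .. ceil(duration * 4) - 1. Grid points more
    than ``EXTRAPOLATION_LIMIT_S`` beyond the last observed beat are dropped
    (the shortfall is handled by zero padding during segmentation); points
    within that margin use the spline's boundary extrapolation.
    """
    if len(series.rri) < 4:
        raise InsufficientDataError(
            f"cubic spline needs >= 4 beats, got {len(series.rri)}"
        )
    spline = CubicSpline(series.beat_times, series.rri, bc_type="natural")
    n_grid = int(np.ceil(duration * FS_HZ))
    grid = np.arange(n_grid) / FS_HZ
    grid = grid[grid <= series.beat_times[-1] + EXTRAPOLATION_LIMIT_S + 1e-12]
    return ResampledSeries(
        participant_id=series.participant_id,
        visit=series.visit,
        phase=series.phase,
        values=spline(grid),
        group=series.group,
    )


def _pad_to(values: np.ndarray, length: int) -> Tuple[np.ndarray, int]:
    n_valid = min(len(values), length)
    out = np.zeros(length)
    out[:n_valid] = values[:n_valid]
    return out, n_valid


def _zscore_valid(values: np.ndarray, n_valid: int) -> np.ndarray:
    """Standardize the valid prefix in place; padding stays exactly zero."""
    out = np.zeros_like(values)
    v = values[:n_valid]
    sd = v.std()
    out[:n_valid] = (v - v.mean()) / sd if sd > 0 else 0.0
    return out


def segment_phase(rs: ResampledSeries, zscore: bool = False) -> Segment:
    """Pack a 5-min resampled phase into a 1200-point tail-padded segment."""
    values, n_valid = _pad_to(rs.values, SEGMENT_LEN_5MIN)
    if zscore:
        values = _zscore_valid(values, n_valid)
    return Segment(
        values=values,
        n_valid=n_valid,
        label=rs.phase,
        participant_id=rs.participant_id,
        group=rs.group,
        visit=rs.visit,
    )


def extract_epochs(
    baseline: ResampledSeries,
    stress: ResampledSeries,
    zscore: bool = False,
) -> Dict[str, Segment]:
    """Cut the four protocol epochs (B4, B5, S1, S2) as 240-point segments.

    An epoch whose source window contains no samples (e.g. a baseline
    recording shorter than 240 s leaves B4 empty) is excluded with a log
    entry rather than emitted as an all-padding segment.
    """
    sources = {"baseline": baseline, "stress": stress}
    epochs: Dict[str, Segment] = {}
    for name, (phase, start, stop) in EPOCH_WINDOWS.items():
        rs = sources[phase]
        i0, i1 = int(start * FS_HZ), int(stop * FS_HZ)
        window = rs.values[i0:i1]
        if len(window) == 0:
            logger.warning(
                "%s v%d: epoch %s invalid (%s phase has %d samples, window "
                "starts at %d); excluded",
                rs.participant_id, rs.visit, name, phase, len(rs.values), i0,
            )
            continue
        values, n_valid = _pad_to(window, SEGMENT_LEN_1MIN)
        if zscore:
            values = _zscore_valid(values, n_valid)
        epochs[name] = Segment(
            values=values,
            n_valid=n_valid,
            label=name,
            participant_id=rs.participant_id,
            group=rs.group,
            visit=rs.visit,
        )
    return epochs


def _paired_sessions(
    recordings: Sequence[BeatSeries],
) -> List[Tuple[BeatSeries, BeatSeries]]:
    by_key: Dict[Tuple[str, int], Dict[str, BeatSeries]] = {}
    for s in recordings:
        by_key.setdefault((s.participant_id, s.visit), {})[s.phase] = s
    pairs = []
    for key in sorted(by_key):
        phases = by_key[key]
        if "baseline" in phases and "stress" in phases:
            pairs.append((phases["baseline"], phases["stress"]))
        else:
            logger.warning("session %s missing a phase; skipped", key)
    return pairs


def make_phase_dataset(
    recordings: Sequence[BeatSeries],
    zscore: bool = False,
    filter_artifacts: bool = True,
) -> List[Segment]:
    """Full 5-min baseline/stress segments for every complete session."""
    segments: List[Segment] = []
    for baseline, stress in _paired_sessions(recordings):
        for series in (baseline, stress):
            if filter_artifacts:
                series = artifact_filter(series).series
            rs = resample_4hz(series, PHASE_DURATION_S)
            segments.append(segment_phase(rs, zscore=zscore))
    return segments


def make_epoch_dataset(
    recordings: Sequence[BeatSeries],
    zscore: bool = False,
    filter_artifacts: bool = True,
) -> List[Segment]:
    """B4/B5/S1/S2 1-min epoch segments for every complete session."""
    segments: List[Segment] = []
    for baseline, stress in _paired_sessions(recordings):
        if filter_artifacts:
            baseline = artifact_filter(baseline).series
            stress = artifact_filter(stress).series
        rs_b = resample_4hz(baseline, PHASE_DURATION_S)
        rs_s = resample_4hz(stress, PHASE_DURATION_S)
        segments.extend(extract_epochs(rs_b, rs_s, zscore=zscore).values())
    return segments
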