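"""Synthetic longitudinal RR-interval cohort generator.

Emulates a three-group clinical cohort (major depressive disorder, panic
disorder, healthy controls) measured over up to five lab visits, each visit
contributing a 5-min resting baseline and a 5-min mental-arithmetic stress
phase of beat-by-beat RR intervals (RRI, ms).

The generative model encodes the autonomic structure that downstream stages
must detect and estimate:

* stress shortens RRI in every group (sympathetic activation with vagal
  withdrawal), by a group-specific amount ``delta_g`` that is largest in
  magnitude for healthy controls;
* within the stress phase, the first minute (S1) is the RRI nadir and RRI
  rebounds from the second minute onward in HC and PD but not in MDD
  (``rebound_g``);
* beat-to-beat variability is a sum of a low-frequency (~0.1 Hz) and a
  high-frequency (~0.25 Hz respiratory) oscillation plus white noise, with
  the high-frequency amplitude damped under stress (vagal withdrawal).

The numeric defaults are tunable simulation choices calibrated to the
qualitative group ordering and rebound pattern above; they are not measured
clinical values.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "GROUPS",
    "PHASE_DURATION_S",
    "SimConfig",
    "Participant",
    "BeatSeries",
    "ConfigError",
    "simulate_cohort",
    "rri_process",
    "simulate_session",
    "simulate_recordings",
]

logger = logging.getLogger(__name__)

GROUPS: Tuple[str, ...] = ("MDD", "PD", "HC")

#: Duration of each protocol phase (resting baseline, mental-arithmetic stress).
PHASE_DURATION_S: float = 300.0

#: Onset (s) of the post-nadir rebound within the stress phase: minute one
#: (S1) sits at the group's full stress drop, minutes two onward recover by
#: ``rebound_g``.
REBOUND_ONSET_S: float = 60.0

#: Hard physiological floor applied to every generated interval (ms).
RRI_FLOOR_MS: float = 300.0


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Attributes
    ----------
    n_per_group:
        Participants per diagnostic group.
    visit_attendance:
        Mapping ``number of visits attended -> participant count`` in the
        reference cohort; rescaled to probabilities for cohorts of any size.
        The default mirrors a 147-participant cohort in which 110 completed
        five visits, 16 four, 4 three, 7 two and 10 one.
    mu_rri, sigma_subject:
        Population mean resting RRI (ms) and between-subject SD (ms).
    delta_g:
        Mean baseline-to-stress RRI change per group (ms, negative = the
        expected stress-induced shortening).
    rebound_g:
        Mean S1-to-S2 RRI recovery per group (ms, >= 0). Zero for MDD by
        default: depressed participants show no within-stress rebound.
    sigma_delta:
        Between-session SD (ms) of the individual stress response around
        ``delta_g``.
    lf_amp, hf_amp_base, hf_amp_stress:
        Amplitudes (ms) of the low-frequency oscillation and of the
        high-frequency (respiratory) oscillation during baseline and stress.
    lf_freq, hf_freq:
        Oscillation frequencies (Hz).
    sigma_noise:
        Per-beat white-noise SD (ms).
    visit_shift:
        Optional additive RRI drift per visit index (ms/visit); 0 by default
        (visit enters the statistical models only as a nuisance covariate).
    seed:
        Master seed; the cohort and every beat series derive from it.
    """

    n_per_group: Dict[str, int] = field(
        default_factory=lambda: {"MDD": 41, "PD": 47, "HC": 59}
    )
    visit_attendance: Dict[int, int] = field(
        default_factory=lambda: {5: 110, 4: 16, 3: 4, 2: 7, 1: 10}
    )
    mu_rri: float = 850.0
    sigma_subject: float = 70.0
    delta_g: Dict[str, float] = field(
        default_factory=lambda: {"HC": -60.0, "MDD": -35.0, "PD": -30.0}
    )
    rebound_g: Dict[str, float] = field(
        default_factory=lambda: {"HC": 15.0, "PD": 12.0, "MDD": 0.0}
    )
    sigma_delta: float = 10.0
    lf_amp: float = 25.0
    hf_amp_base: float = 40.0
    hf_amp_stress: float = 20.0
    lf_freq: float = 0.1
    hf_freq: float = 0.25
    sigma_noise: float = 10.0
    visit_shift: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if set(self.n_per_group) != set(GROUPS):
            raise ConfigError(f"n_per_group must have keys {GROUPS}")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ConfigError("group sizes must be non-negative")
        if sum(self.n_per_group.values()) == 0:
            raise ConfigError("cohort is empty")
        if not self.visit_attendance:
            raise ConfigError("visit_attendance is empty")
        if any(k < 1 or k > 5 for k in self.visit_attendance):
            raise ConfigError("visit counts must lie in 1..5")
        if any(v < 0 for v in self.visit_attendance.values()):
            raise ConfigError("attendance counts must be non-negative")
        if sum(self.visit_attendance.values()) <= 0:
            raise ConfigError("attendance distribution has zero mass")
        for name in ("sigma_subject", "sigma_delta", "lf_amp", "hf_amp_base",
                     "hf_amp_stress", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for g in GROUPS:
            if self.mu_rri + self.delta_g[g] <= RRI_FLOOR_MS:
                raise ConfigError(
                    f"mu_rri + delta_g[{g}] must exceed the {RRI_FLOOR_MS} ms floor"
                )

    def with_overrides(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Participant:
    id: str
    group: str
    baseline_mu: float  # subject-level mean resting RRI (ms)
    visits: Tuple[int, ...]  # attended visit indices, subset of 1..5

    def __post_init__(self) -> None:
        if not self.visits:
            raise ValueError("participant must attend at least one visit")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass(frozen=True)
class BeatSeries:
    """Beat-by-beat RR intervals for one participant-visit-phase.

    ``beat_times`` are seconds from phase onset, strictly increasing, with
    ``rri[i] == (beat_times[i] - beat_times[i-1]) * 1000`` (the first
    interval is measured from t = 0).
    """

    participant_id: str
    visit: int
    phase: str  # "baseline" | "stress"
    beat_times: np.ndarray
    rri: np.ndarray
    group: str = ""

    def validate(self) -> None:
        t, r = self.beat_times, self.rri
        if len(t) != len(r) or len(t) == 0:
            raise ValueError("beat_times and rri must be equal-length, non-empty")
        if np.any(np.diff(t) <= 0) or t[0] <= 0:
            raise ValueError("beat times must be strictly increasing and > 0")
        if np.any(r <= 0):
            raise ValueError("rri must be positive")
        if t[-1] > PHASE_DURATION_S + 1e-9 and self.phase in ("baseline", "stress"):
            raise ValueError("last beat time exceeds phase duration")
        implied = np.diff(np.concatenate([[0.0], t])) * 1000.0
        if np.max(np.abs(implied - r)) > 1e-9 * 1000.0:
            raise ValueError("rri inconsistent with successive beat times")

    @property
    def duration(self) -> float:
        return float(self.beat_times[-1])


# ---------------------------------------------------------------------------
# Beat-level generator
# ---------------------------------------------------------------------------

def _beat_loop(
    mean_before: float,
    mean_after: float,
    t_switch: float,
    lf_amp: float,
    hf_amp: float,
    noise: np.ndarray,
    duration: float,
    lf_freq: float,
    hf_freq: float,
) -> Tuple[np.ndarray, np.ndarray, int, int]:
    two_pi = 2.0 * math.pi
    max_beats = len(noise)
    times = np.empty(max_beats)
    rris = np.empty(max_beats)
    t = 0.0
    n = 0
    n_nonpos = 0
    while True:
        mean = mean_before if t < t_switch else mean_after
        rri = (
            mean
            + lf_amp * math.sin(two_pi * lf_freq * t)
            + hf_amp * math.sin(two_pi * hf_freq * t)
            + noise[n]
        )
        if rri <= 0:
            n_nonpos += 1
        if rri < RRI_FLOOR_MS:
            rri = RRI_FLOOR_MS
        t_next = t + rri / 1000.0
        if t_next > duration + 1e-12:
            break
        times[n] = t_next
        rris[n] = rri
        t = t_next
        n += 1
    return times, rris, n, n_nonpos


try:  # the sequential beat recurrence is the simulation hot spot
    from numba import njit

    _beat_loop = njit(cache=False)(_beat_loop)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    pass


def _generate_beats(
    mean_before: float,
    mean_after: float,
    t_switch: float,
    lf_amp: float,
    hf_amp: float,
    sigma_noise: float,
    duration: float,
    rng: np.random.Generator,
    lf_freq: float,
    hf_freq: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Iteratively lay down beats until ``duration`` is reached.

    rri_n = mean(t_n) + lf_amp*sin(2*pi*lf_freq*t_n) + hf_amp*sin(2*pi*hf_freq*t_n) + eps_n
    with the next beat at t_{n+1} = t_n + rri_n / 1000 and a piecewise-
    constant mean switching from ``mean_before`` to ``mean_after`` at
    ``t_switch``; intervals are clipped below at the physiological floor.
    """
    # Pre-draw noise for the worst case (all intervals at the floor).
    max_beats = int(duration * 1000.0 / RRI_FLOOR_MS) + 2
    noise = (
        rng.normal(0.0, sigma_noise, size=max_beats)
        if sigma_noise > 0
        else np.zeros(max_beats)
    )
    times, rris, n, n_nonpos = _beat_loop(
        mean_before, mean_after, t_switch, lf_amp, hf_amp, noise, duration,
        lf_freq, hf_freq,
    )
    if n and n_nonpos > 0.01 * n:
        logger.warning(
            "generator produced %d/%d non-positive intervals before clipping",
            n_nonpos,
            n,
        )
    return times[:n].copy(), rris[:n].copy()


def rri_process(
    mean_rri: float,
    lf_amp: float,
    hf_amp: float,
    sigma_noise: float,
    duration: float,
    seed: int = 0,
    lf_freq: float = 0.1,
    hf_freq: float = 0.25,
    participant_id: str = "sim",
    visit: int = 1,
    phase: str = "baseline",
) -> BeatSeries:
    """Generate a single constant-mean beat series (see :func:`_generate_beats`)."""
    if mean_rri <= 0:
        raise ValueError("mean_rri must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    times, rris = _generate_beats(
        mean_rri, mean_rri, math.inf, lf_amp, hf_amp, sigma_noise, duration,
        rng, lf_freq, hf_freq,
    )
    series = BeatSeries(participant_id, visit, phase, times, rris)
    series.validate()
    return series


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _session_rng(config_seed: int, participant_id: str, visit: int, stream: int) -> np.random.Generator:
    """Deterministic per-session generator, stable across cohort composition."""
    pid_hash = zlib.crc32(participant_id.encode("utf-8"))
    return np.random.default_rng([config_seed, pid_hash, visit, stream])


def simulate_cohort(config: SimConfig) -> List[Participant]:
    """Draw the participant roster: group sizes, resting means, attendance.

    Deterministic given ``config.seed``. The number of visits each
    participant attends is drawn from ``visit_attendance`` (rescaled to a
    probability distribution); the attended visit indices are a uniformly
    chosen subset of 1..5 of that size.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0xC04057])
    counts = sorted(config.visit_attendance.items())
    n_visits_support = np.array([k for k, _ in counts])
    probs = np.array([v for _, v in counts], dtype=float)
    probs /= probs.sum()

    cohort: List[Participant] = []
    for group in GROUPS:
        n = config.n_per_group[group]
        baseline_mu = config.mu_rri + rng.normal(0.0, config.sigma_subject, size=n)
        n_attend = rng.choice(n_visits_support, size=n, p=probs)
        for j in range(n):
            visits = tuple(
                sorted(rng.choice(np.arange(1, 6), size=int(n_attend[j]), replace=False))
            )
            cohort.append(
                Participant(
                    id=f"{group}{j + 1:03d}",
                    group=group,
                    baseline_mu=float(baseline_mu[j]),
                    visits=tuple(int(v) for v in visits),
                )
            )
    return cohort


def simulate_session(
    p: Participant, visit: int, config: SimConfig
) -> Tuple[BeatSeries, BeatSeries]:
    """Generate the (baseline, stress) beat series for one attended visit.

    The baseline phase has constant mean ``p.baseline_mu`` (plus any
    configured per-visit drift) and the full high-frequency amplitude. The
    stress phase drops the mean by the group's ``delta_g`` (plus a
    session-specific reactivity deviation) during minute one and recovers by
    ``rebound_g`` from minute two onward, with the high-frequency amplitude
    damped to ``hf_amp_stress``.
    """
    if visit not in p.visits:
        raise LookupError(f"participant {p.id} did not attend visit {visit}")
    base_mu = p.baseline_mu + config.visit_shift * (visit - 1)

    rng_b = _session_rng(config.seed, p.id, visit, 1)
    times_b, rri_b = _generate_beats(
        base_mu,
        base_mu,
        math.inf,
        config.lf_amp,
        config.hf_amp_base,
        config.sigma_noise,
        PHASE_DURATION_S,
        rng_b,
        config.lf_freq,
        config.hf_freq,
    )
    baseline = BeatSeries(p.id, visit, "baseline", times_b, rri_b, group=p.group)

    rng_s = _session_rng(config.seed, p.id, visit, 2)
    delta = config.delta_g[p.group] + (
        rng_s.normal(0.0, config.sigma_delta) if config.sigma_delta > 0 else 0.0
    )
    rebound = config.rebound_g[p.group]
    # minute one (S1) sits at the full stress drop; later minutes recover
    times_s, rri_s = _generate_beats(
        base_mu + delta,
        base_mu + delta + rebound,
        REBOUND_ONSET_S,
        config.lf_amp,
        config.hf_amp_stress,
        config.sigma_noise,
        PHASE_DURATION_S,
        rng_s,
        config.lf_freq,
        config.hf_freq,
    )
    stress = BeatSeries(p.id, visit, "stress", times_s, rri_s, group=p.group)
    baseline.validate()
    stress.validate()
    return baseline, stress


def simulate_recordings(
    cohort: Sequence[Participant], config: SimConfig
) -> List[BeatSeries]:
    """All beat series of the cohort, ordered by participant, visit, phase."""
    recordings: List[BeatSeries] = []
    for p in cohort:
        for visit in p.visits:
            baseline, stress = simulate_session(p, visit, config)
            recordings.append(baseline)
            recordings.append(stress)
    return recordings
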