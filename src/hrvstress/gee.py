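"""Population-average GEE analysis of stress reactivity in RR intervals.

Two marginal models, fitted by generalized estimating equations (Gaussian
family, identity link) with participants as clusters and robust Liang-Zeger
sandwich covariances:

* **phase5min** — response: per-recording mean RRI (ms) of each 5-min phase;
  fixed effects: phase (baseline = reference), group (HC = reference),
  phase x group, and visit (1-5, categorical).
* **epoch1min** — response: per-epoch mean RRI of the four 1-min epochs
  (B4, B5, S1, S2; S1 = reference); fixed effects: epoch, group,
  epoch x group, visit.

The working correlation is exchangeable by default (an AR(1) option exists
but is not the default: AR(1) is fragile when some clusters hold only two
observations). Scientific questions are answered by Wald z contrasts on the
coefficients: a group's baseline-to-stress change is the phase main effect
plus that group's interaction term; differences in reactivity between groups
are the interaction terms alone.

Fitting is delegated to statsmodels' GEE implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .preprocess import (
    EPOCH_WINDOWS,
    FS_HZ,
    artifact_filter,
    resample_4hz,
)
from .synthetic import BeatSeries, PHASE_DURATION_S

__all__ = [
    "LongTable",
    "GEEFit",
    "Contrast",
    "build_long_table",
    "fit_gee",
    "phase_contrasts",
    "epoch_contrasts",
]

logger = logging.getLogger(__name__)

ModelName = Literal["phase5min", "epoch1min"]

#: column layout of the tidy long table
LONG_COLUMNS = ("participant_id", "group", "visit", "rri")


@dataclass
class GEEFit:
    """Fitted marginal model: coefficients, sandwich covariance, diagnostics."""

    model: str
    params: pd.Series
    cov_robust: pd.DataFrame
    alpha: float  # exchangeable working-correlation parameter
    scale: float
    n_clusters: int
    n_obs: int
    converged: bool
    result: object  # underlying statsmodels GEEResults

    def coefficient_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_robust.values))
        z = self.params.values / se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"term": self.params.index, "estimate": self.params.values,
             "robust_se": se, "z": z, "p": p}
        )


@dataclass(frozen=True)
class Contrast:
    """A linear combination c'beta with its robust Wald z test."""

    name: str
    estimate: float
    se: float

    @property
    def z(self) -> float:
        return self.estimate / self.se

    @property
    def p(self) -> float:
        return float(2 * stats.norm.sf(abs(self.z)))

    def ci(self, level: float = 0.95) -> tuple:
        zq = stats.norm.ppf(0.5 + level / 2)
        return (self.estimate - zq * self.se, self.estimate + zq * self.se)


def _mean_rri_resampled(series: BeatSeries, filter_artifacts: bool) -> np.ndarray:
    if filter_artifacts:
        series = artifact_filter(series).series
    return resample_4hz(series, PHASE_DURATION_S).values


def build_long_table(
    recordings: Sequence[BeatSeries],
    model: ModelName,
    filter_artifacts: bool = True,
) -> pd.DataFrame:
    """One response row per participant-visit-phase (or -epoch).

    The response is the mean of the 4 Hz-resampled RRI over the 5-min phase
    (phase5min) or over each 1-min epoch window (epoch1min). Rows are ordered
    by participant, visit, then phase/epoch.
    """
    rows: List[dict] = []
    if model == "phase5min":
        for s in recordings:
            values = _mean_rri_resampled(s, filter_artifacts)
            rows.append(
                {"participant_id": s.participant_id, "group": s.group,
                 "visit": s.visit, "phase": s.phase, "rri": float(values.mean())}
            )
        df = pd.DataFrame(rows)
        phase_order = {"baseline": 0, "stress": 1}
        df = df.sort_values(
            ["participant_id", "visit", "phase"],
            key=lambda c: c.map(phase_order) if c.name == "phase" else c,
        ).reset_index(drop=True)
    elif model == "epoch1min":
        by_session: Dict[tuple, Dict[str, BeatSeries]] = {}
        for s in recordings:
            by_session.setdefault((s.participant_id, s.visit), {})[s.phase] = s
        epoch_order = ["B4", "B5", "S1", "S2"]
        for (pid, visit), phases in sorted(by_session.items()):
            if set(phases) != {"baseline", "stress"}:
                logger.warning("session (%s, %s) incomplete; skipped", pid, visit)
                continue
            resampled = {
                ph: _mean_rri_resampled(series, filter_artifacts)
                for ph, series in phases.items()
            }
            group = phases["baseline"].group
            for epoch in epoch_order:
                phase, start, stop = EPOCH_WINDOWS[epoch]
                window = resampled[phase][int(start * FS_HZ): int(stop * FS_HZ)]
                if len(window) == 0:
                    logger.warning("session (%s, %s): epoch %s empty; skipped",
                                   pid, visit, epoch)
                    continue
                rows.append(
                    {"participant_id": pid, "group": group, "visit": visit,
                     "epoch": epoch, "rri": float(window.mean())}
                )
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown model {model!r}")
    return df


def _formula(model: ModelName) -> str:
    if model == "phase5min":
        return ("rri ~ C(phase, Treatment('baseline')) "
                "* C(group, Treatment('HC')) + C(visit)")
    return ("rri ~ C(epoch, Treatment('S1')) "
            "* C(group, Treatment('HC')) + C(visit)")


def fit_gee(
    table: pd.DataFrame,
    model: ModelName,
    cov_struct: str = "exchangeable",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> GEEFit:
    """Fit the marginal model by GEE.

    ``cov_struct`` is "exchangeable" (default), "independence", or "ar1".
    Raises on a rank-deficient design; non-convergence is flagged on the
    returned fit rather than raised.
    """
    factor = "phase" if model == "phase5min" else "epoch"
    required = {"participant_id", "group", "visit", factor, "rri"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"long table missing columns: {sorted(missing)}")
    if table["participant_id"].nunique() < 2:
        raise ValueError("GEE requires at least 2 clusters")

    structs = {
        "exchangeable": sm.cov_struct.Exchangeable,
        "independence": sm.cov_struct.Independence,
        "ar1": sm.cov_struct.Autoregressive,
    }
    if isinstance(cov_struct, str):
        if cov_struct not in structs:
            raise ValueError(f"unknown working correlation {cov_struct!r}")
        cs = structs[cov_struct]()
    else:  # a ready statsmodels CovStruct instance (e.g. a frozen variant)
        cs = cov_struct
        cov_struct = type(cs).__name__.lower()

    gee = sm.GEE.from_formula(
        _formula(model),
        groups="participant_id",
        data=table,
        family=sm.families.Gaussian(),
        cov_struct=cs,
    )
    if np.linalg.matrix_rank(gee.exog) < gee.exog.shape[1]:
        raise ValueError("design matrix is rank deficient")
    import warnings

    from statsmodels.tools.sm_exceptions import IterationLimitWarning

    with warnings.catch_warnings():
        # non-convergence is surfaced through the `converged` flag instead
        warnings.simplefilter("ignore", IterationLimitWarning)
        result = gee.fit(maxiter=maxiter, ctol=tol)
    converged = bool(getattr(result, "converged", True))
    if not converged:
        logger.warning("GEE (%s, %s) did not converge", model, cov_struct)
    alpha = float(np.atleast_1d(cs.dep_params)[0]) if cov_struct != "independence" else 0.0
    cov = pd.DataFrame(result.cov_params(), index=result.params.index,
                       columns=result.params.index)
    return GEEFit(
        model=model,
        params=result.params,
        cov_robust=cov,
        alpha=alpha,
        scale=float(result.scale),
        n_clusters=int(table["participant_id"].nunique()),
        n_obs=int(len(table)),
        converged=converged,
        result=result,
    )


def _contrast(fit: GEEFit, name: str, terms: Dict[str, float]) -> Contrast:
    c = pd.Series(0.0, index=fit.params.index)
    for term, weight in terms.items():
        if term not in c.index:
            raise KeyError(
                f"term {term!r} not in coefficient space {list(c.index)}"
            )
        c[term] = weight
    est = float(c @ fit.params)
    se = float(np.sqrt(c.values @ fit.cov_robust.values @ c.values))
    return Contrast(name=name, estimate=est, se=se)


def _interaction_term(factor_term: str, group: str) -> str:
    return f"{factor_term}:C(group, Treatment('HC'))[T.{group}]"


def phase_contrasts(fit: GEEFit) -> Dict[str, Contrast]:
    """Baseline-to-stress RRI change per group, and group differences therein.

    HC's change is the phase main effect; MDD's and PD's add their
    interaction terms; "MDD-HC" and "PD-HC" are the interaction terms alone
    (how much each patient group's reactivity differs from controls).
    """
    if fit.model != "phase5min":
        raise ValueError("phase_contrasts requires a phase5min fit")
    phase = "C(phase, Treatment('baseline'))[T.stress]"
    out = {
        "HC": _contrast(fit, "HC", {phase: 1.0}),
        "MDD": _contrast(fit, "MDD", {phase: 1.0,
                                      _interaction_term(phase, "MDD"): 1.0}),
        "PD": _contrast(fit, "PD", {phase: 1.0,
                                    _interaction_term(phase, "PD"): 1.0}),
        "MDD-HC": _contrast(fit, "MDD-HC", {_interaction_term(phase, "MDD"): 1.0}),
        "PD-HC": _contrast(fit, "PD-HC", {_interaction_term(phase, "PD"): 1.0}),
    }
    return out


def epoch_contrasts(fit: GEEFit) -> Dict[str, Contrast]:
    """Within-group contrasts of B4, B5 and S2 against the S1 nadir.

    Keys are "<group>:<epoch>-S1". A positive estimate means the epoch's RRI
    exceeds S1's (e.g. the S2 rebound).
    """
    if fit.model != "epoch1min":
        raise ValueError("epoch_contrasts requires an epoch1min fit")
    out: Dict[str, Contrast] = {}
    for epoch in ("B4", "B5", "S2"):
        main = f"C(epoch, Treatment('S1'))[T.{epoch}]"
        for group in ("HC", "MDD", "PD"):
            terms = {main: 1.0}
            if group != "HC":
                terms[_interaction_term(main, group)] = 1.0
            out[f"{group}:{epoch}-S1"] = _contrast(
                fit, f"{group}:{epoch}-S1", terms
            )
    return out


def contrasts_frame(contrasts: Dict[str, Contrast]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"contrast": c.name, "estimate": c.estimate, "robust_se": c.se,
          "z": c.z, "p": c.p} for c in contrasts.values()]
    )
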