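"""GEE fits: oracle equivalences, contrast arithmetic, robustness properties."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from hrvstress import (
    SimConfig,
    build_long_table,
    epoch_contrasts,
    fit_gee,
    phase_contrasts,
    simulate_cohort,
    simulate_recordings,
)
from hrvstress.gee import Contrast, GEEFit
from hrvstress.synthetic import GROUPS


def _singleton_table(seed=0, n=60):
    """One observation per cluster: GEE must reduce to ordinary least squares."""
    rng = np.random.default_rng(seed)
    groups = rng.choice(list(GROUPS), size=n)
    phases = rng.choice(["baseline", "stress"], size=n)
    visits = rng.integers(1, 6, size=n)
    rri = (
        850
        + np.where(phases == "stress", -50, 0)
        + np.where(groups == "MDD", 20, 0)
        + rng.normal(0, 30, size=n)
    )
    return pd.DataFrame(
        {"participant_id": [f"P{i}" for i in range(n)], "group": groups,
         "visit": visits, "phase": phases, "rri": rri}
    )


def _paired_table(seed=0, n=80):
    """Balanced 2-observation clusters (baseline + stress per participant)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        g = rng.choice(list(GROUPS))
        subj = rng.normal(0, 40)
        for phase, eff in (("baseline", 0.0), ("stress", -50.0)):
            rows.append(
                {"participant_id": f"P{i}", "group": g, "visit": 1,
                 "phase": phase,
                 "rri": 850 + subj + eff + rng.normal(0, 25)}
            )
    return pd.DataFrame(rows)


def _sim_table(n_per_group, seed, model="phase5min", **overrides):
    cfg = SimConfig(
        n_per_group={g: n_per_group for g in GROUPS}, seed=seed, **overrides
    )
    recs = simulate_recordings(simulate_cohort(cfg), cfg)
    return build_long_table(recs, model, filter_artifacts=False), cfg


class TestOracles:
    def test_singleton_clusters_reduce_to_ols(self):
        table = _singleton_table()
        fit = fit_gee(table, "phase5min")
        ols = sm.OLS.from_formula(
            "rri ~ C(phase, Treatment('baseline')) * C(group, Treatment('HC'))"
            " + C(visit)",
            data=table,
        ).fit()
        assert np.max(np.abs(fit.params.values - ols.params.values)) <= 1e-8

    def test_exchangeable_alpha_matches_residual_product_loop(self):
        table = _paired_table()
        fit = fit_gee(table, "phase5min")
        fitted = np.asarray(fit.result.fittedvalues)
        resid = table["rri"].to_numpy() - fitted
        n_params = len(fit.params)
        n_obs = len(table)
        # brute-force moment estimator with the same ddof convention:
        # scale from squared residuals, alpha from within-cluster products
        scale = 0.0
        residsq_sum = 0.0
        n_pairs = 0.0
        for pid, idx in table.groupby("participant_id").groups.items():
            r = resid[np.asarray(idx)]
            scale += np.sum(r * r)
            residsq_sum += (r.sum() ** 2 - np.sum(r * r)) / 2
            n_pairs += len(r) * (len(r) - 1) / 2
        scale /= n_obs - n_params
        alpha_oracle = (residsq_sum / scale) / (n_pairs - n_params)
        assert fit.alpha == pytest.approx(alpha_oracle, rel=1e-10)
        # paired clusters with a real shared subject effect: alpha must be
        # positive and below 1
        assert 0.0 < fit.alpha < 1.0

    def test_frozen_alpha_zero_equals_independence_fit(self):
        class FrozenExchangeable(sm.cov_struct.Exchangeable):
            def update(self, params):
                self.dep_params = 0.0

        table = _paired_table(seed=3)
        frozen = fit_gee(table, "phase5min", cov_struct=FrozenExchangeable())
        indep = fit_gee(table, "phase5min", cov_struct="independence")
        assert np.max(np.abs(frozen.params.values - indep.params.values)) <= 1e-10


class TestContrastArithmetic:
    def _manual_fit(self):
        phase = "C(phase, Treatment('baseline'))[T.stress]"
        inter = phase + ":C(group, Treatment('HC'))[T.MDD]"
        inter_pd = phase + ":C(group, Treatment('HC'))[T.PD]"
        idx = ["Intercept", phase, inter, inter_pd]
        params = pd.Series([850.0, -60.0, 25.0, 30.0], index=idx)
        cov = pd.DataFrame(4.0 * np.eye(4), index=idx, columns=idx)
        return GEEFit(model="phase5min", params=params, cov_robust=cov,
                      alpha=0.3, scale=1.0, n_clusters=50, n_obs=100,
                      converged=True, result=None)

    def test_group_contrast_sums_main_and_interaction(self):
        contrasts = phase_contrasts(self._manual_fit())
        assert contrasts["HC"].estimate == -60.0
        assert contrasts["MDD"].estimate == -35.0  # -60 + 25
        assert contrasts["MDD-HC"].estimate == 25.0
        # SE of a sum of two independent coefficients with var 4 each
        assert contrasts["MDD"].se == pytest.approx(np.sqrt(8.0))

    def test_z_equals_estimate_over_se(self):
        c = Contrast("x", estimate=-35.0, se=2.5)
        assert c.z == -35.0 / 2.5
        assert 0.0 <= c.p <= 1.0


class TestFittedModels:
    def test_phase_contrasts_recover_generator_truth(self):
        table, cfg = _sim_table(15, seed=41)
        fit = fit_gee(table, "phase5min")
        contrasts = phase_contrasts(fit)
        for g in GROUPS:
            truth = cfg.delta_g[g] + 0.8 * cfg.rebound_g[g]
            assert abs(contrasts[g].estimate - truth) <= 4 * contrasts[g].se + 1.0
            assert contrasts[g].estimate < 0
        assert contrasts["MDD-HC"].estimate > 0  # attenuated MDD reactivity
        assert contrasts["PD-HC"].estimate > 0

    def test_epoch_contrasts_show_rebound_in_hc_and_pd_only(self):
        table, cfg = _sim_table(15, seed=42, model="epoch1min")
        fit = fit_gee(table, "epoch1min")
        ec = epoch_contrasts(fit)
        assert ec["HC:S2-S1"].estimate > 5
        assert ec["PD:S2-S1"].estimate > 5
        assert abs(ec["MDD:S2-S1"].estimate) < 5
        for g in GROUPS:  # S1 is the nadir: both baseline epochs sit above it
            assert ec[f"{g}:B4-S1"].estimate > 0
            assert ec[f"{g}:B5-S1"].estimate > 0

    def test_no_epoch_effect_gives_null_contrasts(self):
        table, _ = _sim_table(
            10, seed=43, model="epoch1min",
            delta_g={g: 0.0 for g in GROUPS},
            rebound_g={g: 0.0 for g in GROUPS},
            hf_amp_stress=40.0,
        )
        fit = fit_gee(table, "epoch1min")
        for c in epoch_contrasts(fit).values():
            assert abs(c.estimate) <= 4 * c.se + 0.5

    def test_estimates_invariant_to_row_order(self):
        table, _ = _sim_table(8, seed=44)
        fit1 = fit_gee(table, "phase5min")
        shuffled = table.sample(frac=1.0, random_state=0)
        fit2 = fit_gee(shuffled, "phase5min")
        assert np.max(np.abs(
            fit1.params.values - fit2.params[fit1.params.index].values
        )) <= 1e-8

    def test_sandwich_variance_shrinks_with_clusters(self):
        table_small, _ = _sim_table(12, seed=45)
        table_big, _ = _sim_table(24, seed=45)
        tr_small = np.trace(fit_gee(table_small, "phase5min").cov_robust.values)
        tr_big = np.trace(fit_gee(table_big, "phase5min").cov_robust.values)
        ratio = tr_small / tr_big
        assert 1.5 <= ratio <= 2.5  # ~1/n_clusters scaling within 25%

    def test_rank_deficient_design_rejected(self):
        # alias the visit factor with phase: visit 1 iff baseline, so the
        # C(visit) dummy duplicates the phase dummy
        table = _paired_table()
        table["visit"] = np.where(table["phase"] == "baseline", 1, 2)
        with pytest.raises(ValueError):
            fit_gee(table, "phase5min")

    def test_type_i_error_calibrated_under_null(self):
        # no stress effect anywhere: within-group phase contrasts should
        # reject at roughly the nominal 5% rate
        null_overrides = dict(
            delta_g={g: 0.0 for g in GROUPS},
            rebound_g={g: 0.0 for g in GROUPS},
            hf_amp_stress=40.0,
            sigma_delta=0.0,
        )
        # sandwich z-tests are asymptotic in cluster count, so calibration
        # is checked at 90 clusters (single-visit cohorts keep this cheap)
        null_overrides["visit_attendance"] = {1: 1}
        n_cohorts = 100
        rejections = 0
        n_tests = 0
        for i in range(n_cohorts):
            table, _ = _sim_table(30, seed=1000 + i, **null_overrides)
            fit = fit_gee(table, "phase5min")
            if not fit.converged:
                continue
            contrasts = phase_contrasts(fit)
            for g in GROUPS:
                n_tests += 1
                if abs(contrasts[g].z) > 1.96:
                    rejections += 1
        rate = rejections / n_tests
        assert n_tests >= 270  # nearly all fits converge
        # binomial tolerance around the nominal 0.05
        assert 0.025 <= rate <= 0.085
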