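"""Survival / mixed-model fits: oracle equivalence, recovery, bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from camoseek.game import GameConfig, HazardParams, generate_sessions, simulate_observer
from camoseek.models import (
    BASE_COX_TERMS,
    FitError,
    ModelSpec,
    build_design,
    build_diff_records,
    fit_cox,
    fit_encounters_interaction,
    fit_morph_switch,
    fit_timediff_lmm,
    orthogonal_poly,
    rank_metrics,
)


# ---------------------------------------------------------------------------
# independent oracle: brute-force Cox partial likelihood (no ties)
# ---------------------------------------------------------------------------


def cox_partial_loglik(beta, times, events, x):
    """Breslow/Efron partial log-likelihood for one covariate, distinct times."""
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def grid_cox_mle(times, events, x, lo=-5, hi=5, iters=4):
    lo, hi = float(lo), float(hi)
    for _ in range(iters):
        grid = np.linspace(lo, hi, 201)
        ll = [cox_partial_loglik(b, times, events, x) for b in grid]
        best = grid[int(np.argmax(ll))]
        step = (hi - lo) / 200
        lo, hi = best - step, best + step
    return best


# interleaved event times across the two groups keep the MLE finite
TOY = pd.DataFrame(
    {
        "capture_ms": [800.0, 1200.0, 2100.0, 3400.0, 5000.0, 15000.0],
        "timed_out": [False, False, False, False, False, True],
        "treat": [1.0, 0.0, 0.0, 1.0, 1.0, 0.0],
        "session_id": [1, 1, 2, 2, 3, 3],
    }
)


class TestCoxOracle:
    def test_toy_coefficient_matches_grid_maximisation(self):
        fit = fit_cox(TOY, ModelSpec(terms=("treat",)))
        oracle = grid_cox_mle(
            TOY["capture_ms"].to_numpy(), (~TOY["timed_out"]).to_numpy(), TOY["treat"].to_numpy()
        )
        assert fit.coef("treat") == pytest.approx(oracle, abs=1e-4)

    def test_removing_censored_row_shifts_risk_set_as_oracle_dictates(self):
        sub = TOY.iloc[:-1]
        fit = fit_cox(sub, ModelSpec(terms=("treat",)))
        oracle = grid_cox_mle(
            sub["capture_ms"].to_numpy(), (~sub["timed_out"]).to_numpy(), sub["treat"].to_numpy()
        )
        assert fit.coef("treat") == pytest.approx(oracle, abs=1e-4)

    def test_all_censored_rejected(self):
        df = TOY.assign(timed_out=True, capture_ms=15000.0)
        with pytest.raises(FitError):
            fit_cox(df, ModelSpec(terms=("treat",)))

    def test_time_scaling_invariance(self):
        fit1 = fit_cox(TOY, ModelSpec(terms=("treat",)))
        scaled = TOY.assign(capture_ms=TOY["capture_ms"] * 3.0)
        fit2 = fit_cox(scaled, ModelSpec(terms=("treat",)))
        assert fit2.coef("treat") == pytest.approx(fit1.coef("treat"), abs=1e-8)

    def test_event_bookkeeping(self):
        fit = fit_cox(TOY, ModelSpec(terms=("treat",)))
        assert fit.n_events == 5 and fit.n_censored == 1
        assert fit.n_events + fit.n_censored == fit.n_obs
        assert fit.z("treat") == pytest.approx(fit.coef("treat") / fit.table.loc["treat", "se"])


class TestDesign:
    def test_orthogonal_poly_properties(self, rng):
        x = rng.uniform(0, 800, 500)
        basis = orthogonal_poly(x, 2)
        assert basis.shape == (500, 2)
        gram = basis.T @ basis
        assert np.allclose(gram, np.eye(2), atol=1e-10)
        assert np.allclose(basis.sum(axis=0), 0.0, atol=1e-8)

    def test_zero_variance_covariate_rejected(self, rng):
        df = pd.DataFrame({"a": np.ones(10), "b": rng.normal(size=10)})
        with pytest.raises(FitError):
            build_design(df, ModelSpec(terms=("a", "b")))

    def test_missing_covariate_named(self):
        with pytest.raises(FitError, match="missing"):
            build_design(pd.DataFrame({"a": [1.0, 2.0]}), ModelSpec(terms=("zz",)))


@pytest.fixture(scope="module")
def recovery_log(small_catalog):
    """Log generated with a single active metric (gabrat_l) for ranking tests."""
    params = HazardParams(
        baseline=-8.0,
        metric_coefs={"gabrat_l": -3.0},
        encounters_coef=0.05,
        session_sd=0.2,
    )
    sessions = generate_sessions(small_catalog, 250, GameConfig(), np.random.default_rng(77))
    return simulate_observer(
        sessions, small_catalog.crabs.drop(columns=["morph"]), params, np.random.default_rng(78)
    )


class TestRanking:
    def test_active_metric_ranked_first(self, recovery_log):
        ranking, fits = rank_metrics(
            recovery_log, ["gabrat_l", "colour_dist_surround", "pattern_diff_surround"]
        )
        assert ranking.iloc[0]["metric"] == "gabrat_l"
        assert fits["gabrat_l"].coef("gabrat_l") < 0

    def test_duplicate_metric_column_deterministic(self, recovery_log):
        log = recovery_log.assign(gabrat_l_copy=recovery_log["gabrat_l"])
        ranking, fits = rank_metrics(log, ["gabrat_l", "gabrat_l_copy"])
        assert fits["gabrat_l"].z("gabrat_l") == pytest.approx(
            fits["gabrat_l_copy"].z("gabrat_l_copy"), abs=1e-8
        )

    def test_zero_variance_metric_raises(self, recovery_log):
        log = recovery_log.assign(flat=1.0)
        with pytest.raises(FitError):
            rank_metrics(log, ["flat"])

    def test_encounters_direction_recovered(self, recovery_log):
        fit = fit_encounters_interaction(recovery_log, "gabrat_l")
        # generator: hazard rises with encounters -> shorter times
        assert fit.coef("encounters") > 0
        assert fit.coef("gabrat_l") < 0


class TestDiffRecords:
    def test_full_session_yields_n_minus_one_records(self, gameplay):
        log, _ = gameplay
        one = log[log["session_id"] == log["session_id"].iloc[0]]
        diffs = build_diff_records(one)
        assert len(diffs) == 23

    def test_time_ratios_map_to_log_differences(self):
        log = pd.DataFrame(
            {
                "session_id": 1,
                "slide": [1, 2, 3],
                "capture_ms": [1000.0, 1000.0, 2000.0],
                "novel_crab": [True, True, False],
                "morph_switch": [np.nan, 1.0, 1.0],
                "morph": ["Green", "Pale", "Pale"],
                "crab_area": 1.0,
                "x": 0.5,
                "y": 0.5,
                "played_before": False,
                "encounters": 0,
            }
        )
        diffs = build_diff_records(log, metric_cols=[])
        assert diffs["time_diff"].iloc[0] == pytest.approx(0.0)
        assert diffs["time_diff"].iloc[1] == pytest.approx(np.log(2.0))

    def test_single_slide_session_warns_and_skips(self):
        log = pd.DataFrame(
            {
                "session_id": [1, 2, 2],
                "slide": [1, 1, 2],
                "capture_ms": [1000.0, 900.0, 1100.0],
                "novel_crab": True,
                "morph_switch": np.nan,
                "morph": "Green",
                "crab_area": 1.0,
                "x": 0.5,
                "y": 0.5,
                "played_before": False,
                "encounters": 0,
            }
        )
        with pytest.warns(UserWarning, match="single slide"):
            diffs = build_diff_records(log, metric_cols=[])
        assert len(diffs) == 1


class TestTimediffLmm:
    def test_ols_fallback_matches_plain_ols(self, gameplay):
        import statsmodels.api as sm

        log, _ = gameplay
        diffs = build_diff_records(log)
        fit = fit_timediff_lmm(diffs, "gabrat_a_diff")
        # session effects cancel in within-session differences, so the
        # intercept variance degenerates and the fallback engages
        assert fit.method == "ols_fallback"
        spec = ModelSpec(
            terms=tuple(
                t for t in (
                    "crab_area", "p_area", "played_before", "slide",
                    ("x", 2), ("y", 2), ("p_x", 2), ("p_y", 2),
                )
            )
            + ("gabrat_a_diff", "novel_crab"),
            interactions=(("gabrat_a_diff", "novel_crab"),),
        )
        d = diffs.copy()
        d["novel_crab"] = d["novel_crab"].astype(float)
        X = sm.add_constant(build_design(d, spec))
        ols = sm.OLS(d["time_diff"].to_numpy(), X).fit()
        assert fit.coef("gabrat_a_diff:novel_crab") == pytest.approx(
            ols.params["gabrat_a_diff:novel_crab"], abs=1e-6
        )

    def test_novelty_interaction_sign_recovered(self, gameplay):
        # generator: gabrat_a protects more strongly on novel slides
        log, truth = gameplay
        diffs = build_diff_records(log)
        fit = fit_timediff_lmm(diffs, "gabrat_a_diff")
        assert truth["hazard_params"]["novelty_coefs"]["gabrat_a"] < 0
        assert fit.coef("gabrat_a_diff:novel_crab") > 0

    def test_novel_slides_take_longer(self, gameplay):
        log, _ = gameplay
        diffs = build_diff_records(log)
        fit = fit_timediff_lmm(diffs, "gabrat_a_diff")
        assert fit.coef("novel_crab") > 0
        assert fit.z("novel_crab") > 2


class TestMorphSwitch:
    def test_matrix_partition(self, gameplay):
        from camoseek.report import morph_switch_heatmap

        log, _ = gameplay
        diffs = build_diff_records(log)
        _, matrix = fit_morph_switch(diffs)
        assert matrix.shape == (6, 6)
        # diagonal cells aggregate same-morph switches only
        switches = diffs[diffs["novel_crab"]]
        same = switches[switches["morph"] == switches["p_morph"]]
        for m in matrix.index:
            cell = same[same["morph"] == m]["time_diff"].mean()
            if np.isfinite(matrix.loc[m, m]):
                assert matrix.loc[m, m] == pytest.approx(cell)
        hm = morph_switch_heatmap(diffs, include_same_morph=False)
        assert hm.size == 36 and hm.values[np.eye(6, dtype=bool)].tolist() == [
            pytest.approx(np.nan, nan_ok=True)
        ] * 6

    def test_cross_morph_penalty_sign_recovered(self, gameplay):
        log, truth = gameplay
        diffs = build_diff_records(log)
        fit, _ = fit_morph_switch(diffs)
        assert truth["hazard_params"]["morph_switch_penalty"] < 0
        assert fit.coef("morph_switch:novel_crab") > 0
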