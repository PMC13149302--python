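"""Bulk scoring, Cox association, KM stratification, permutation null,
drug correlation — checked against brute-force likelihood oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from perturbcircuit import (
    CoxNewton1D,
    SimulationConfig,
    cox_association,
    drug_correlation,
    generate_truth,
    km_stratify,
    permutation_specificity,
    score_bulk,
    simulate_cohort,
)
from perturbcircuit.programs import ProgramSignature
from perturbcircuit.synthetic import SurvivalCohort


@pytest.fixture(scope="module")
def truth():
    return generate_truth(
        SimulationConfig(n_genes=400, n_targets=6, n_programs=4,
                         background_fraction=0.2), seed=20)


@pytest.fixture(scope="module")
def cohort(truth):
    sig = truth.program_genes(0)[:20]
    return simulate_cohort(truth, sig, n_samples=500, hr_per_unit=0.5,
                           censor_rate=0.3, seed=20), sig


def _expr(matrix, genes):
    return pd.DataFrame(matrix, columns=genes,
                        index=[f"s{i}" for i in range(len(matrix))])


class TestScoreBulk:
    def test_identical_samples_score_zero(self):
        expr = _expr(np.ones((6, 10)), [f"g{i}" for i in range(10)])
        scores = score_bulk(expr, [f"g{i}" for i in range(5)])
        np.testing.assert_allclose(scores, 0.0)

    def test_two_sd_outlier_scores_two(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        m = rng.normal(0, 1, size=(200, 30))
        m[0, :] = m[1:, :].mean(axis=0) + 2 * m[1:, :].std(axis=0)
        scores = score_bulk(_expr(m, genes), genes[:20])
        assert scores.iloc[0] == pytest.approx(2.0, abs=0.15)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(12)]
        expr = _expr(rng.normal(size=(40, 12)), genes)
        a = score_bulk(expr, genes[:6])
        b = score_bulk(expr, genes[:6][::-1])
        np.testing.assert_allclose(a, b)


def _brute_force_cox_coef(x, time, event):
    """Grid maximization of the (tie-free) Cox partial likelihood."""
    order = np.argsort(time)
    x, event = x[order], event[order]

    def negpl(beta):
        eta = beta * x
        # risk set for the i-th smallest time is samples i..n-1
        log_denoms = np.logaddexp.accumulate(eta[::-1])[::-1]
        return -np.sum(event * (eta - log_denoms))

    grid = np.arange(-3.0, 3.0, 1e-3)
    vals = np.array([negpl(b) for b in grid])
    best = grid[vals.argmin()]
    fine = np.arange(best - 2e-3, best + 2e-3, 1e-5)
    vals = np.array([negpl(b) for b in fine])
    return fine[vals.argmin()]


class TestCoxNewton1D:
    def test_matches_brute_force_grid_no_ties(self):
        rng = np.random.default_rng(4)
        n = 20
        x = rng.normal(size=n)
        time = rng.exponential(1.0 / np.exp(0.7 * x))
        event = np.ones(n)
        solver = CoxNewton1D(time, event)
        coef, se, ok = solver.fit(x)
        assert ok
        oracle = _brute_force_cox_coef(x, time, event)
        assert coef == pytest.approx(oracle, abs=1e-4)

    def test_matches_lifelines_with_censoring_and_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        n = 150
        x = rng.normal(size=n)
        time = np.round(rng.exponential(1.0 / np.exp(0.5 * x)), 1) + 0.1
        event = (rng.uniform(size=n) < 0.7).astype(float)
        coef, se, ok = CoxNewton1D(time, event).fit(x)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"time": time, "event": event, "x": x}),
            "time", "event")
        assert coef == pytest.approx(float(cph.params_["x"]), abs=1e-6)
        assert se == pytest.approx(float(cph.standard_errors_["x"]), rel=1e-4)

    def test_logrank_equals_cox_score_test(self):
        """Two-group log-rank chi-square equals the score test U(0)^2/I(0)
        of the single-covariate Cox model (no ties)."""
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(6)
        n = 80
        group = (np.arange(n) % 2).astype(float)
        time = rng.exponential(1.0 / np.exp(0.8 * group))
        event = np.ones(n)
        res = logrank_test(time[group == 1], time[group == 0],
                           event_observed_A=event[group == 1],
                           event_observed_B=event[group == 0])
        solver = CoxNewton1D(time, event)
        # score statistic at beta = 0
        x = group[solver.order]
        U = float(np.sum(solver.d * x))
        I = 0.0
        w = np.ones(n)
        SRw = solver._suffix_at_starts(w)
        SRwx = solver._suffix_at_starts(w * x)
        SRwx2 = solver._suffix_at_starts(w * x * x)
        SDw = np.add.reduceat(w * solver.d, solver.starts)
        SDwx = np.add.reduceat(w * x * solver.d, solver.starts)
        SDwx2 = np.add.reduceat(w * x * x * solver.d, solver.starts)
        for k in np.flatnonzero(solver.m > 0):
            m = int(solver.m[k])
            for ell in range(m):
                f = ell / m
                denom = SRw[k] - f * SDw[k]
                num1 = SRwx[k] - f * SDwx[k]
                U -= num1 / denom
                I += (SRwx2[k] - f * SDwx2[k]) / denom - (num1 / denom) ** 2
        assert U * U / I == pytest.approx(res.test_statistic, rel=1e-6)


class TestCoxAssociation:
    def test_planted_hr_recovered(self, cohort):
        coh, sig = cohort
        scores = score_bulk(coh.expr, sig)
        res = cox_association(scores, coh, adjust=False)
        assert abs(res.coefficient - np.log(0.5)) < 3 * res.se

    def test_adjusted_fit_keeps_signal(self, cohort):
        coh, sig = cohort
        scores = score_bulk(coh.expr, sig)
        res = cox_association(scores, coh, adjust=True)
        assert res.adjusted
        assert res.hazard_ratio < 1.0
        assert res.p < 0.05

    def test_duplicating_samples_keeps_point_estimate(self, cohort):
        coh, sig = cohort
        scores = score_bulk(coh.expr, sig)
        dup = SurvivalCohort(
            expr=pd.concat([coh.expr, coh.expr.set_axis(
                [f"d_{i}" for i in coh.expr.index])]),
            time=pd.concat([coh.time, coh.time.set_axis(
                [f"d_{i}" for i in coh.time.index])]),
            event=pd.concat([coh.event, coh.event.set_axis(
                [f"d_{i}" for i in coh.event.index])]),
            covariates=pd.concat([coh.covariates, coh.covariates.set_axis(
                [f"d_{i}" for i in coh.covariates.index])]),
        )
        dup_scores = score_bulk(dup.expr, sig)
        a = cox_association(scores, coh, adjust=False)
        b = cox_association(dup_scores, dup, adjust=False)
        # duplication leaves the partial likelihood shape unchanged up to
        # Efron's tie correction (duplicates create ties), so the point
        # estimate agrees closely while the SE shrinks
        assert b.hazard_ratio == pytest.approx(a.hazard_ratio, rel=1e-2)
        assert b.se < a.se

    def test_too_few_events_rejected(self, truth):
        sig = truth.program_genes(0)[:10]
        coh = simulate_cohort(truth, sig, n_samples=20, hr_per_unit=1.0,
                              censor_rate=0.95, seed=1)
        if coh.event.sum() < 10:
            with pytest.raises(ValueError):
                cox_association(pd.Series(0.0, index=coh.time.index), coh)


class TestKMStratify:
    def test_median_cut_group_sizes(self, cohort):
        coh, sig = cohort
        scores = score_bulk(coh.expr, sig)
        out = km_stratify(scores, coh)
        # low group includes the median sample
        assert out["n_low"] >= out["n_high"]
        assert out["n_low"] + out["n_high"] == len(scores)

    def test_complete_separation_tiny_p(self):
        n = 200
        time = np.concatenate([np.full(100, 0.5) + np.arange(100) * 1e-3,
                               np.full(100, 50.0) + np.arange(100) * 1e-3])
        coh = SurvivalCohort(
            expr=pd.DataFrame(index=[f"s{i}" for i in range(n)]),
            time=pd.Series(time, index=[f"s{i}" for i in range(n)]),
            event=pd.Series(1, index=[f"s{i}" for i in range(n)]),
            covariates=pd.DataFrame(index=[f"s{i}" for i in range(n)]),
        )
        scores = pd.Series(np.concatenate([np.zeros(100), np.ones(100)]),
                           index=coh.time.index)
        out = km_stratify(scores, coh)
        assert out["p"] < 1e-6

    def test_constant_scores_rejected(self, cohort):
        coh, _ = cohort
        with pytest.raises(ValueError):
            km_stratify(pd.Series(1.0, index=coh.time.index), coh)


class TestPermutationSpecificity:
    def test_planted_signature_is_extreme(self, cohort):
        coh, sig = cohort
        null_hrs, p, info = permutation_specificity(coh, sig, n_perm=500,
                                                    seed=0)
        assert p < 0.05
        assert info["n_used"] > 450

    def test_zero_perms_rejected(self, cohort):
        coh, sig = cohort
        with pytest.raises(ValueError):
            permutation_specificity(coh, sig, n_perm=0, seed=0)

    def test_small_pool_rejected(self, cohort):
        coh, sig = cohort
        with pytest.raises(ValueError):
            permutation_specificity(coh, sig, n_perm=10, seed=0,
                                    candidate_pool=list(sig) * 2)


class TestDrugCorrelation:
    def test_perfect_anticorrelation(self):
        scores = pd.Series(np.arange(30.0), index=[f"s{i}" for i in range(30)])
        auc = pd.DataFrame({"D": -scores})
        out = drug_correlation(scores, auc)
        assert out["pearson_r"].iloc[0] == pytest.approx(-1.0)
        assert bool(out["sensitizing"].iloc[0])

    def test_constant_auc_flagged(self):
        scores = pd.Series(np.arange(30.0), index=[f"s{i}" for i in range(30)])
        auc = pd.DataFrame({"D": np.ones(30)}, index=scores.index)
        out = drug_correlation(scores, auc)
        assert np.isnan(out["pearson_r"].iloc[0])
        assert out["flag"].iloc[0] == "constant"

    def test_pairwise_complete_missing_values(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=60),
                           index=[f"s{i}" for i in range(60)])
        auc = pd.DataFrame({"D": -scores + rng.normal(0, 0.1, 60)})
        auc.iloc[:10, 0] = np.nan
        out = drug_correlation(scores, auc)
        assert out["n"].iloc[0] == 50
        assert out["pearson_r"].iloc[0] < -0.9
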