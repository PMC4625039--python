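"""GRM construction, REML variance components, liability transform, meta."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

import polyherit as ph
from polyherit.heritability import (
    GRM,
    residual_only_fit,
    LiabilityScaleParams,
    compute_grm,
    deviation_test,
    enrichment_of_variance,
    ivw_meta,
    lrt_component,
    prune_related,
    reml_fit,
    to_liability,
)
from tests.conftest import make_cohort


class TestGRM:
    def test_hand_computed_single_snp(self):
        # M=1, p=0.5: individual with x=2 has diagonal (2-1)^2/0.5 = 2
        x = np.array([[2.0], [0.0]])
        grm = compute_grm(make_cohort(x))
        assert grm.matrix[0, 0] == pytest.approx(2.0)
        assert grm.matrix[0, 1] == pytest.approx(-2.0)
        assert grm.n_snps == 1

    def test_identical_individuals(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.3, (10, 100)).astype(float)
        x[3] = x[7]
        grm = compute_grm(make_cohort(x))
        assert grm.matrix[3, 7] == pytest.approx(grm.matrix[3, 3])

    def test_oracle_brute_force(self):
        rng = np.random.default_rng(1)
        x = rng.binomial(2, rng.uniform(0.1, 0.5, 200), (50, 200)).astype(float)
        grm = compute_grm(make_cohort(x))
        p = x.mean(axis=0) / 2
        n, m = x.shape
        expected = np.zeros((n, n))
        for j in range(n):
            for k in range(n):
                expected[j, k] = np.mean(
                    (x[j] - 2 * p) * (x[k] - 2 * p) / (2 * p * (1 - p))
                )
        assert np.abs(grm.matrix - expected).max() < 1e-10

    def test_trace_near_one_per_individual(self):
        rng = np.random.default_rng(2)
        x = rng.binomial(2, rng.uniform(0.05, 0.5, 1500), (80, 1500)).astype(float)
        grm = compute_grm(make_cohort(x))
        assert np.trace(grm.matrix) / 80 == pytest.approx(1.0, abs=0.1)

    def test_monomorphic_dropped(self):
        x = np.column_stack([np.full(20, 2.0), np.random.default_rng(3).binomial(2, 0.4, 20)]).astype(float)
        with pytest.warns(UserWarning, match="monomorphic"):
            grm = compute_grm(make_cohort(x))
        assert grm.n_snps == 1


class TestPruneRelated:
    def test_unrelated_all_kept(self):
        a = np.eye(30) + np.random.default_rng(4).normal(0, 0.005, (30, 30))
        a = (a + a.T) / 2
        grm = GRM(matrix=a, n_snps=100, ids=np.arange(30))
        assert len(prune_related(grm, 0.05)) == 30

    def test_duplicate_pair_one_removed(self):
        a = np.eye(10) * 1.0
        a[2, 5] = a[5, 2] = 1.98
        grm = GRM(matrix=a, n_snps=100, ids=np.arange(10))
        kept = prune_related(grm, 0.05)
        assert len(kept) == 9
        assert (2 in kept) != (5 in kept)

    def test_postcondition_no_pair_above_cutoff(self):
        rng = np.random.default_rng(5)
        n = 40
        a = rng.normal(0, 0.02, (n, n))
        a = (a + a.T) / 2
        for i, j in [(0, 1), (1, 2), (10, 30), (15, 16)]:
            a[i, j] = a[j, i] = rng.uniform(0.06, 0.5)
        np.fill_diagonal(a, 1.0)
        grm = GRM(matrix=a, n_snps=100, ids=np.arange(n))
        kept = prune_related(grm, 0.05)
        idx = np.flatnonzero(np.isin(np.arange(n), kept))
        sub = a[np.ix_(idx, idx)]
        np.fill_diagonal(sub, 0.0)
        assert sub.max() <= 0.05


def _simulated_gaussian_trait(n, m, h2, seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.5, m)
    x = rng.binomial(2, p, (n, m)).astype(float)
    z = (x - x.mean(0)) / x.std(0)
    b = rng.normal(0, np.sqrt(1.0 / m), m)
    g = z @ b
    if h2 > 0:
        g *= np.sqrt(h2) / g.std()
    else:
        g = np.zeros(n)
    y = g + rng.normal(0, np.sqrt(1 - h2), n)
    return make_cohort(x), y


def _grid_search_oracle(y, grm, X=None):
    """Independent REML oracle: eigendecompose the GRM and scan the
    heritability ratio on a dense grid, profiling total variance."""
    n = len(y)
    X = np.ones((n, 1)) if X is None else X
    lam, U = np.linalg.eigh(grm.matrix)
    yt = U.T @ y
    Xt = U.T @ X

    def restricted_ll(h, vp):
        d = vp * (h * lam + (1 - h))
        if (d <= 0).any():
            return -np.inf
        vinv_y = yt / d
        xtvx = (Xt.T / d) @ Xt
        beta = np.linalg.solve(xtvx, Xt.T @ vinv_y)
        resid = yt - Xt @ beta
        ypy = float(resid @ (resid / d))
        _, ld_x = np.linalg.slogdet(xtvx)
        return -0.5 * (np.log(d).sum() + ld_x + ypy)

    best = (-np.inf, None)
    from scipy.optimize import minimize_scalar

    for h in np.linspace(0.0, 0.99, 199):
        res = minimize_scalar(
            lambda vp: -restricted_ll(h, vp), bounds=(1e-3, 10.0), method="bounded"
        )
        if -res.fun > best[0]:
            best = (-res.fun, h)
    return best[1]


class TestReml:
    def test_null_recovery(self):
        hits = 0
        for seed in range(6):
            cohort, y = _simulated_gaussian_trait(800, 500, 0.0, 10 + seed)
            fit = reml_fit(y, None, [compute_grm(cohort)])
            hits += fit.ratios[0] <= 2 * fit.se_ratios[0] + 1e-9
        assert hits >= 5

    def test_h2_half_recovery(self):
        hits = 0
        for seed in range(6):
            cohort, y = _simulated_gaussian_trait(1200, 800, 0.5, 20 + seed)
            fit = reml_fit(y, None, [compute_grm(cohort)])
            assert fit.converged
            hits += abs(fit.ratios[0] - 0.5) <= 2 * fit.se_ratios[0]
        assert hits >= 5

    def test_agrees_with_grid_search_oracle(self):
        for seed in (1, 2):
            cohort, y = _simulated_gaussian_trait(500, 400, 0.4, seed)
            grm = compute_grm(cohort)
            fit = reml_fit(y, None, [grm])
            h_oracle = _grid_search_oracle(y, grm)
            assert fit.ratios[0] == pytest.approx(h_oracle, abs=5e-3)

    def test_ratios_sum_to_one_with_residual(self):
        cohort, y = _simulated_gaussian_trait(400, 300, 0.3, 3)
        fit = reml_fit(y, None, [compute_grm(cohort)])
        total = fit.variances.sum() + fit.residual_variance
        assert fit.ratios.sum() + fit.residual_variance / total == pytest.approx(1.0, abs=1e-9)

    def test_identical_grms_degenerate_but_sum_recovers(self):
        import warnings as _w

        cohort, y = _simulated_gaussian_trait(600, 400, 0.4, 4)
        grm = compute_grm(cohort)
        single = reml_fit(y, None, [grm])
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            double = reml_fit(y, None, [grm, GRM(grm.matrix.copy(), grm.n_snps, grm.ids)])
        assert double.ai_singular  # unidentifiable split is flagged
        assert double.ratios.sum() == pytest.approx(single.ratios[0], abs=4 * single.se_ratios[0])

    def test_three_component_recovery_continuous_liability(self):
        # jointly fitted compartment components recover the simulated
        # liability h2 vector on the continuous scale (no ascertainment)
        from polyherit import synthetic as syn
        from polyherit.pipelines import proportional_assignment

        h2 = {"genic_coding": 0.10, "genic_noncoding": 0.25, "intergenic": 0.07}
        split = {"genic_coding": 0.05, "genic_noncoding": 0.45, "intergenic": 0.50}
        hits = pd.Series(0, index=list(h2))
        seeds = range(6)
        for seed in seeds:
            cfg = ph.SimulationConfig(
                n_individuals=1500, n_snps=1200, h2_by_compartment=h2, seed=900 + seed
            )
            rng = np.random.default_rng(cfg.seed)
            snp_table = syn.draw_snp_table(cfg, rng)
            assignment = proportional_assignment(snp_table, split, rng)
            effects = syn.draw_effects(snp_table, assignment, cfg, rng)
            labels = assignment.labels.to_numpy()
            effects = syn._calibrate_scales(effects, labels, snp_table, cfg, rng)
            dos = syn.dosage_matrix(snp_table["freq"].to_numpy(), cfg, 1500, rng)
            liab = syn._standardize(dos, snp_table["freq"].to_numpy()) @ effects
            liab = liab + rng.standard_normal(1500) * np.sqrt(1 - cfg.h2_total)
            cohort = ph.CohortData(dosages=dos, snp_table=snp_table)
            grms = [compute_grm(cohort, np.flatnonzero(labels == c)) for c in h2]
            fit = reml_fit(liab, None, grms)
            for c, ratio, se in zip(h2, fit.ratios, fit.se_ratios):
                hits[c] += abs(ratio - h2[c]) <= 2 * se
        for c in h2:
            assert hits[c] >= len(seeds) - 1, f"{c}: {hits[c]}/{len(seeds)}"

    def test_covariates_accepted(self):
        rng = np.random.default_rng(6)
        cohort, y = _simulated_gaussian_trait(400, 300, 0.3, 5)
        covs = rng.standard_normal((400, 2))
        y = y + covs @ np.array([0.5, -0.3])
        fit = reml_fit(y, covs, [compute_grm(cohort)])
        assert fit.converged
        assert 0 <= fit.ratios[0] <= 1


class TestLrt:
    def test_boundary_mixture_at_zero(self):
        full = _dummy_fit(loglik=-100.0, k=2)
        reduced = _dummy_fit(loglik=-100.0, k=1)
        assert lrt_component(full, reduced) == pytest.approx(0.5)

    def test_chi2_tail_halved(self):
        full = _dummy_fit(loglik=-100.0 + 3.84 / 2, k=2)
        reduced = _dummy_fit(loglik=-100.0, k=1)
        p = lrt_component(full, reduced)
        assert p == pytest.approx(0.5 * stats.chi2.sf(3.84, 1), rel=1e-10)
        assert p == pytest.approx(0.025, abs=2e-4)

    def test_optimizer_failure_detected(self):
        full = _dummy_fit(loglik=-101.0, k=2)
        reduced = _dummy_fit(loglik=-100.0, k=1)
        with pytest.raises(RuntimeError):
            lrt_component(full, reduced)

    def test_null_calibration(self):
        # component truly absent: rejection at nominal 0.05 stays nominal
        rejections = 0
        n_rep = 120
        for seed in range(n_rep):
            cohort, y = _simulated_gaussian_trait(150, 120, 0.0, 1000 + seed)
            grm = compute_grm(cohort)
            full = reml_fit(y, None, [grm])
            reduced = residual_only_fit(y)
            try:
                p = lrt_component(full, reduced)
            except RuntimeError:
                continue
            rejections += p < 0.05
        rate = rejections / n_rep
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


def _dummy_fit(loglik, k):
    from polyherit.heritability import VarianceComponentsFit

    return VarianceComponentsFit(
        variances=np.full(k, 0.1),
        residual_variance=0.8,
        se_variances=np.full(k, 0.05),
        ratios=np.full(k, 0.1),
        se_ratios=np.full(k, 0.05),
        loglik=loglik,
        n_iterations=5,
        converged=True,
        covariance=np.eye(k + 1),
    )


class TestLiability:
    def test_zero_maps_to_zero(self):
        assert to_liability(0.0, LiabilityScaleParams(0.06, 0.5)) == 0.0

    def test_half_half_multiplier_pi_over_two(self):
        params = LiabilityScaleParams(0.5, 0.5)
        assert params.multiplier == pytest.approx(np.pi / 2, rel=1e-12)

    def test_linearity(self):
        params = LiabilityScaleParams(0.06, 0.5)
        m = params.multiplier
        for h in (0.01, 0.2, 0.42):
            assert to_liability(h, params) == pytest.approx(h * m, rel=1e-12)

    def test_prevalence_sensitivity_direction(self):
        # halving assumed prevalence from 6% to 3% shrinks liability h2 by
        # the multiplier ratio ~0.815 (0.42 -> ~0.34)
        m6 = LiabilityScaleParams(0.06, 0.5).multiplier
        m3 = LiabilityScaleParams(0.03, 0.5).multiplier
        assert m3 / m6 == pytest.approx(0.815, abs=0.005)
        assert to_liability(0.42 / m6, LiabilityScaleParams(0.03, 0.5)) < 0.42

    @pytest.mark.parametrize("bad", [(0.0, 0.5), (1.0, 0.5), (0.06, 0.0), (0.06, 1.0)])
    def test_degenerate_params_rejected(self, bad):
        with pytest.raises(ValueError):
            LiabilityScaleParams(*bad)


class TestTableArithmetic:
    def test_enrichment_of_variance(self):
        assert enrichment_of_variance(0.042, 0.42, 37_142, 7_095_944) == pytest.approx(19.1, abs=0.05)
        assert enrichment_of_variance(0.13, 0.42, 3_703_319, 7_095_944) == pytest.approx(0.6, abs=0.05)
        assert enrichment_of_variance(0.1, 0.4, 10, 40) == pytest.approx(1.0)

    def test_enrichment_errors(self):
        with pytest.raises(ValueError):
            enrichment_of_variance(0.1, 0.4, 0, 40)

    def test_deviation_expected_and_p(self):
        v_exp, p = deviation_test(0.13, 0.034, 0.42, 0.52)
        assert v_exp == pytest.approx(0.22, abs=0.005)
        v_exp2, p2 = deviation_test(0.042, 0.023, 0.42, 0.005234)
        assert p2 == pytest.approx(0.084, abs=0.02)  # printed 0.088 given rounding
        _, p_eq = deviation_test(0.3, 0.1, 0.6, 0.5)
        assert p_eq == pytest.approx(1.0)

    def test_deviation_sign_symmetric(self):
        _, p_hi = deviation_test(0.30, 0.05, 0.4, 0.5)
        _, p_lo = deviation_test(0.10, 0.05, 0.4, 0.5)
        assert p_hi == pytest.approx(p_lo, rel=1e-12)


class TestIvwMeta:
    def test_equal_weights(self):
        est, se = ivw_meta([0.2, 0.4], [0.1, 0.1])
        assert est == pytest.approx(0.3)
        assert se == pytest.approx(0.1 / np.sqrt(2))

    def test_tiny_se_dominates(self):
        est, _ = ivw_meta([0.9, 0.1], [1e-6, 10.0])
        assert est == pytest.approx(0.9, abs=1e-6)

    def test_closed_form_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 5)
        s = rng.uniform(0.05, 0.5, 5)
        est, se = ivw_meta(x, s)
        w = 1 / s**2
        assert est == pytest.approx(np.sum(w * x) / np.sum(w), rel=1e-12)
        assert se == pytest.approx(1 / np.sqrt(np.sum(w)), rel=1e-12)

    def test_single_study_passthrough(self):
        assert ivw_meta([0.3], [0.2]) == (0.3, 0.2)
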