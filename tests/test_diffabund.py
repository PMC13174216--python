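import numpy as np
import pandas as pd
import pytest

from prisge import diffabund as da
from prisge.errors import InsufficientDataError, ValidationError
from prisge.simulate import simulate_null_counts


def _two_group_design(n_per=6):
    n = 2 * n_per
    group = np.repeat([0.0, 1.0], n_per)
    return da.DesignSpec(
        sample_ids=[f"s{i}" for i in range(n)],
        full=np.column_stack([np.ones(n), group]),
        reduced=np.ones((n, 1)),
        full_names=["intercept", "group"],
        reduced_names=["intercept"],
        t_final=1.0,
    )


class TestSizeFactors:
    def test_identical_columns_give_ones(self):
        m = np.tile(np.array([[4.0], [9.0], [25.0]]), 4)
        assert np.allclose(da.size_factors(m), 1.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        m = rng.poisson(100, (50, 4)).astype(float) + 1
        sf = da.size_factors(m)
        m2 = m.copy()
        m2[:, 2] *= 3
        sf2 = da.size_factors(m2)
        # up to the global geometric-mean renormalization
        assert sf2[2] / sf[2] == pytest.approx(3 * (sf2[0] / sf[0]), rel=1e-9)

    def test_hand_computed_3x3(self):
        m = np.array([[2.0, 4.0, 8.0],
                      [3.0, 6.0, 12.0],
                      [5.0, 10.0, 20.0]])
        # every row is proportional to (1, 2, 4): the median ratio per
        # column is (1, 2, 4) / geomean(row), and after geometric-mean
        # normalization the factors must be (1, 2, 4) / 2
        sf = da.size_factors(m)
        assert np.allclose(sf, np.array([1.0, 2.0, 4.0]) / 2.0)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(1)
        m = rng.poisson(50, (30, 6)).astype(float) + 1
        sf = da.size_factors(m)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)


class TestDispersions:
    def test_poisson_counts_give_small_alpha(self):
        rng = np.random.default_rng(2)
        design = _two_group_design()
        counts = rng.poisson(200, (2000, 12)).astype(float)
        disp = da.estimate_dispersions(counts, np.ones(12), design)
        assert np.nanmedian(disp.alpha_final) < 0.02

    def test_nb_alpha_recovered(self):
        rng = np.random.default_rng(3)
        n = 30
        design = da.DesignSpec(
            sample_ids=[f"s{i}" for i in range(n)],
            full=np.column_stack([np.ones(n), np.repeat([0.0, 1.0], 15)]),
            reduced=np.ones((n, 1)),
            full_names=["intercept", "group"], reduced_names=["intercept"],
            t_final=1.0,
        )
        r = 1 / 0.1
        counts = rng.poisson(rng.gamma(r, 100 / r, size=(2000, n)))
        disp = da.estimate_dispersions(counts.astype(float), np.ones(n), design)
        assert 0.05 < np.nanmedian(disp.alpha_final) < 0.2

    def test_constant_counts_zero_raw(self):
        design = _two_group_design()
        counts = np.full((5, 12), 50.0)
        disp = da.estimate_dispersions(counts, np.ones(12), design)
        assert np.all(disp.alpha_raw == 0.0)


class TestNBFit:
    def test_intercept_only_closed_form(self):
        y = np.full(8, 13.0)
        fit = da.fit_nb_glm(y, np.ones((8, 1)), np.ones(8), alpha=0.1)
        assert fit.beta[0] == pytest.approx(np.log(13.0), abs=1e-8)
        assert np.allclose(fit.mu, 13.0)

    def test_saturated_two_group_closed_form(self):
        y = np.array([10.0] * 4 + [40.0] * 4)
        X = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
        fit = da.fit_nb_glm(y, X, np.ones(8), alpha=0.0)
        assert fit.beta[1] == pytest.approx(np.log(4.0), abs=1e-8)

    def test_linearly_dependent_design_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValidationError):
            da.fit_nb_glm(np.ones(6), X, np.ones(6), alpha=0.0)

    def test_irls_matches_optimizer_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(6, 13))
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            sf = np.exp(rng.normal(0, 0.2, n))
            beta = np.array([3.0, 0.5])
            mu = sf * np.exp(X @ beta)
            y = rng.poisson(rng.gamma(10, mu / 10))
            fit = da.fit_nb_glm(y, X, sf, alpha=0.1)
            oracle = da.nb_loglik_optimum_oracle(y, X, sf, alpha=0.1)
            assert fit.loglik == pytest.approx(oracle, abs=1e-4)

    def test_deviance_monotone_in_debug_mode(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = 10
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = rng.poisson(20, n).astype(float)
            da.fit_nb_glm(y, X, np.ones(n), alpha=0.05, debug_monotone=True)


class TestLRT:
    def test_identical_designs(self):
        y = np.arange(1.0, 13.0)
        X = np.ones((12, 1))
        f = da.fit_nb_glm(y, X, np.ones(12), 0.1)
        stat, df, p = da.lrt(f, f)
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_mismatched_alpha_rejected(self):
        y = np.arange(1.0, 13.0)
        f1 = da.fit_nb_glm(y, np.ones((12, 1)), np.ones(12), 0.1)
        f2 = da.fit_nb_glm(y, np.ones((12, 1)), np.ones(12), 0.2)
        with pytest.raises(ValidationError):
            da.lrt(f1, f2)

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(6)
        design = _two_group_design()
        y = np.concatenate([rng.poisson(100, 6), rng.poisson(400, 6)]).astype(float)
        full = da.fit_nb_glm(y, design.full, np.ones(12), 0.01)
        red = da.fit_nb_glm(y, design.reduced, np.ones(12), 0.01)
        stat, df, p = da.lrt(full, red)
        assert p < 1e-10 and stat > 0

    def test_stat_nonnegative_under_null(self):
        rng = np.random.default_rng(7)
        design = _two_group_design()
        for _ in range(20):
            y = rng.poisson(50, 12).astype(float)
            full = da.fit_nb_glm(y, design.full, np.ones(12), 0.05)
            red = da.fit_nb_glm(y, design.reduced, np.ones(12), 0.05)
            stat, _, p = da.lrt(full, red)
            assert stat >= 0.0 and 0.0 <= p <= 1.0


class TestWald:
    def test_contrast_negation_symmetry(self):
        rng = np.random.default_rng(8)
        design = _two_group_design()
        y = np.concatenate([rng.poisson(100, 6), rng.poisson(150, 6)]).astype(float)
        fit = da.fit_nb_glm(y, design.full, np.ones(12), 0.05)
        c = np.array([0.0, 1.0])
        s1, p1 = da.wald_one_sided(fit, c)
        s2, p2 = da.wald_one_sided(fit, -c)
        assert s2 == pytest.approx(-s1)
        assert p2 == pytest.approx(1.0 - p1, abs=1e-12)

    def test_null_p_centred(self):
        rng = np.random.default_rng(9)
        design = _two_group_design()
        ps = []
        for _ in range(200):
            y = rng.poisson(100, 12).astype(float)
            fit = da.fit_nb_glm(y, design.full, np.ones(12), 0.01)
            ps.append(da.wald_one_sided(fit, np.array([0.0, 1.0]))[1])
        assert abs(np.median(ps) - 0.5) < 0.1


class TestBH:
    def test_all_equal(self):
        p = np.array([0.3, 0.3, 0.3])
        assert np.allclose(da.adjust_bh(p), p)

    def test_hand_step_up(self):
        q = da.adjust_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_nan_propagation_and_single(self):
        q = da.adjust_bh(np.array([0.05, np.nan]))
        assert q[0] == pytest.approx(0.05)
        assert np.isnan(q[1])


class TestEmpiricalFDR:
    def test_all_controls_is_bh_like(self):
        p = np.linspace(0.01, 1.0, 50)
        efdr = da.empirical_fdr(p, np.ones(50, bool))
        n = 50
        expected = np.minimum(1.0, (np.arange(1, 51) / n) * n / np.arange(1, 51))
        # with every unit a control, efdr_i = (rank/n) * n / rank = 1
        assert np.allclose(efdr, expected)

    def test_unit_below_all_controls(self):
        p = np.array([1e-6] + list(np.linspace(0.2, 0.9, 20)))
        is_ctrl = np.array([False] + [True] * 20)
        efdr = da.empirical_fdr(p, is_ctrl)
        assert efdr[0] == 0.0

    def test_monotone_in_p(self):
        rng = np.random.default_rng(10)
        p = rng.random(100)
        is_ctrl = rng.random(100) < 0.3
        efdr = da.empirical_fdr(p, is_ctrl)
        order = np.argsort(p)
        assert (np.diff(efdr[order]) >= -1e-12).all()

    def test_too_few_controls(self):
        with pytest.raises(InsufficientDataError):
            da.empirical_fdr(np.linspace(0, 1, 20), np.zeros(20, bool))


class TestCallHits:
    def test_empty_results(self):
        out = da.call_hits(pd.DataFrame(columns=["efdr", "log2fc_model"]))
        assert "hit" in out.columns and len(out) == 0

    def test_depletion_not_a_hit(self):
        res = pd.DataFrame({"efdr": [0.005, 0.005], "log2fc_model": [-1.0, 1.0]})
        out = da.call_hits(res)
        assert list(out["hit"]) == [False, True]

    def test_nan_never_hit(self):
        res = pd.DataFrame({"efdr": [np.nan], "log2fc_model": [2.0]})
        assert not da.call_hits(res)["hit"].iloc[0]


class TestDesign:
    def test_continuous_time_shapes(self, simple_sheet):
        spec = da.build_design(simple_sheet.frame, "osimertinib", "vehicle")
        assert spec.full.shape[1] == 4 and spec.reduced.shape[1] == 2
        assert spec.df_test == 2
        c = spec.drug_contrast()
        assert c[2] == 1.0 and c[3] == spec.t_final

    def test_factor_time_nested(self, simple_sheet):
        spec = da.build_design(simple_sheet.frame, "osimertinib", "vehicle",
                               time_as_factor=True)
        assert spec.reduced.shape[1] < spec.full.shape[1]
        assert np.linalg.matrix_rank(spec.full) == spec.full.shape[1]
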