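import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from prisge.errors import InsufficientDataError, PairingError, ValidationError
from prisge.library import LibraryDesign
from prisge.quantify import CountMatrix
from prisge.scores import (
    aggregate_variants,
    false_negative_rate,
    hit_rate,
    log2fc,
    moi_from_positive_fraction,
    normalize_log2,
    replicate_correlation,
    ssmd,
    ttest_vs_reference,
    z_scores,
)
from conftest import make_construct


def _cm(data, sheet):
    df = pd.DataFrame(data, columns=sheet.sample_ids)
    return CountMatrix(df, sheet)


class TestNormalize:
    def test_identical_samples_identical_columns(self, simple_sheet):
        rng = np.random.default_rng(0)
        col = rng.poisson(100, 50)
        cm = _cm(np.tile(col[:, None], len(simple_sheet.sample_ids)),
                 simple_sheet)
        nm = normalize_log2(cm)
        assert np.allclose(nm.to_numpy(), nm.to_numpy()[:, :1])

    def test_depth_invariance_at_high_counts(self, simple_sheet):
        rng = np.random.default_rng(1)
        col = rng.integers(1000, 5000, 50)
        data = np.tile(col[:, None], len(simple_sheet.sample_ids))
        data[:, 1] = 10 * col
        nm = normalize_log2(_cm(data, simple_sheet))
        assert np.max(np.abs(nm.iloc[:, 1] - nm.iloc[:, 0])) < 0.02

    def test_pseudocount_hand_value(self, simple_sheet):
        n = len(simple_sheet.sample_ids)
        nm = normalize_log2(_cm(np.full((1, n), 999_999), simple_sheet))
        # (999999 + 1) / 10^6 * 10^6 = 10^6
        assert nm.iloc[0, 0] == pytest.approx(np.log2(1e6))

    def test_all_zero_sample_warns_but_defined(self, simple_sheet):
        data = np.ones((5, len(simple_sheet.sample_ids)), dtype=int)
        data[:, 0] = 0
        with pytest.warns(UserWarning):
            nm = normalize_log2(_cm(data, simple_sheet))
        assert np.isfinite(nm.to_numpy()).all()


class TestLog2FC:
    def test_treatment_equals_vehicle_is_zero(self, simple_sheet):
        rng = np.random.default_rng(2)
        col = rng.poisson(500, 30)
        cm = _cm(np.tile(col[:, None], len(simple_sheet.sample_ids)),
                 simple_sheet)
        fc = log2fc(normalize_log2(cm), simple_sheet, "osimertinib", 3.0, 1)
        assert np.allclose(fc, 0.0)

    def test_doubled_construct(self, simple_sheet):
        # many constructs so doubling one barely moves the column total
        rng = np.random.default_rng(3)
        col = rng.integers(2000, 4000, 1000)
        data = np.tile(col[:, None], len(simple_sheet.sample_ids))
        sids = simple_sheet.sample_ids
        treat_idx = sids.index("osimertinib_d3_r1")
        data[0, treat_idx] = 2 * data[0, treat_idx]
        fc = log2fc(normalize_log2(_cm(data, simple_sheet)), simple_sheet,
                    "osimertinib", 3.0, 1)
        assert fc.iloc[0] == pytest.approx(1.0, abs=0.02)

    def test_antisymmetry_swapping_arms(self, simple_sheet):
        rng = np.random.default_rng(4)
        data = rng.poisson(300, (30, len(simple_sheet.sample_ids)))
        nm = normalize_log2(_cm(data, simple_sheet))
        fc = log2fc(nm, simple_sheet, "osimertinib", 19.0, 2)
        treat = nm["osimertinib_d19_r2"]
        veh = nm["vehicle_d19_r2"]
        assert np.allclose(fc, -(veh - treat))

    def test_missing_vehicle_named_in_error(self, simple_sheet):
        nm = normalize_log2(_cm(np.ones((3, len(simple_sheet.sample_ids)),
                                        dtype=int), simple_sheet))
        with pytest.raises(PairingError, match="day=11"):
            log2fc(nm, simple_sheet, "osimertinib", 11.0, 1)


class TestZScores:
    def test_unit_sd_controls(self):
        vals = pd.Series({"a": 2.0, "c1": -1.0, "c2": 0.0, "c3": 1.0})
        z = z_scores(vals, ["c1", "c2", "c3"])
        assert z["a"] == pytest.approx(2.0)

    def test_degenerate_controls_raise(self):
        vals = pd.Series({"a": 1.0, "c1": 0.0, "c2": 0.0})
        with pytest.raises(InsufficientDataError):
            z_scores(vals, ["c1", "c2"])
        with pytest.raises(InsufficientDataError):
            z_scores(vals, ["c1"])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=40, unique=True))
    def test_standardization_identity(self, ctrl_vals):
        vals = pd.Series(ctrl_vals, index=[f"c{i}" for i in range(len(ctrl_vals))])
        if vals.std(ddof=1) == 0:
            return
        z = z_scores(vals, list(vals.index))
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-10)


class TestAggregate:
    def lib(self):
        return LibraryDesign([
            make_construct("a1", "A" * 20, "C" * 20, variant="V1"),
            make_construct("a2", "G" * 20, "T" * 20, variant="V1"),
            make_construct("b1", "C" * 20, "A" * 20, variant="V2",
                           mclass="synonymous"),
        ])

    def test_mean_and_singleton(self):
        vals = pd.Series({"a1": 1.0, "a2": 3.0, "b1": 5.0})
        agg = aggregate_variants(vals, self.lib())
        assert agg["V1"] == 2.0 and agg["V2"] == 5.0

    def test_permutation_invariance(self):
        vals = pd.Series({"a1": 1.0, "a2": 3.0, "b1": 5.0})
        agg1 = aggregate_variants(vals, self.lib())
        agg2 = aggregate_variants(vals[::-1], self.lib())
        assert agg1.equals(agg2)

    def test_unknown_construct_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_variants(pd.Series({"zz": 1.0}), self.lib())


class TestTTest:
    def test_identical_groups(self):
        r = ttest_vs_reference([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_degenerate_variance_flag(self):
        r = ttest_vs_reference([0, 0, 0, 0], [1, 1, 1, 1])
        assert r.degenerate_variance
        assert r.p == 0.0

    def test_hand_computed_t(self):
        # pooled sp^2 = 0.01, t = 1 / sqrt(0.01 * 2/3) = 12.247
        r = ttest_vs_reference([1.1, 0.9, 1.0], [0.1, -0.1, 0.0], n_tests=5)
        assert r.t == pytest.approx(12.247, abs=1e-3)
        assert r.p_bonferroni == pytest.approx(min(1.0, r.p * 5))

    def test_too_small_group(self):
        with pytest.raises(InsufficientDataError):
            ttest_vs_reference([1.0], [0.0, 1.0])


class TestSSMD:
    def test_equal_means_zero(self):
        assert ssmd([1, 2, 3], [3, 2, 1]).ssmd == pytest.approx(0.0)

    def test_hand_value(self):
        # each group variance 2: 10 / sqrt(4) = 5
        assert ssmd([10, 12], [0, 2]).ssmd == pytest.approx(5.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=10),
           st.lists(st.floats(-10, 10), min_size=2, max_size=10),
           st.floats(-5, 5))
    def test_antisymmetry_and_shift_invariance(self, a, b, shift):
        r1 = ssmd(a, b)
        r2 = ssmd(b, a)
        if not r1.infinite:
            assert r1.ssmd == pytest.approx(-r2.ssmd, abs=1e-9)
            r3 = ssmd(np.array(a) + shift, np.array(b) + shift)
            assert r3.ssmd == pytest.approx(r1.ssmd, abs=1e-6)

    def test_both_zero_variance_flagged(self):
        assert ssmd([1, 1], [0, 0]).infinite


class TestMOI:
    def test_thirty_percent_positivity(self):
        moi = moi_from_positive_fraction(0.30)
        assert moi == pytest.approx(0.357, abs=1e-3)

    def test_boundaries(self):
        assert moi_from_positive_fraction(0.0) == 0.0
        assert moi_from_positive_fraction(1 - np.exp(-2)) == pytest.approx(2.0)
        with pytest.raises(ValidationError):
            moi_from_positive_fraction(1.0)

    def test_inverse_identity(self):
        for m in np.linspace(0.01, 5, 25):
            f = 1 - np.exp(-m)
            assert moi_from_positive_fraction(f) == pytest.approx(m, rel=1e-9)


class TestFNRAndHitRate:
    def test_all_recovered(self):
        assert false_negative_rate({"a", "b"}, {"a"}) == 0.0

    def test_forty_percent(self):
        known = {f"k{i}" for i in range(10)}
        hits = {f"k{i}" for i in range(6)}
        assert false_negative_rate(hits, known) == pytest.approx(0.4)

    def test_empty_known_raises(self):
        with pytest.raises(ValidationError):
            false_negative_rate({"a"}, set())

    def test_hit_rate_percent(self):
        assert hit_rate(85, 3660) == pytest.approx(2.3, abs=0.05)
        assert hit_rate(87, 498) == pytest.approx(17.5, abs=0.05)


class TestReplicateCorrelation:
    def test_identical_replicates_r1(self, simple_sheet):
        rng = np.random.default_rng(5)
        col = rng.poisson(200, 60)
        data = np.tile(col[:, None], len(simple_sheet.sample_ids))
        nm = normalize_log2(_cm(data, simple_sheet))
        # duplicated columns are constant across constructs? no: same per
        # replicate, so r between replicates is exactly 1
        rc = replicate_correlation(nm, simple_sheet)
        assert np.allclose(rc["r"], 1.0)

    def test_independent_noise_near_zero(self, simple_sheet):
        rng = np.random.default_rng(6)
        n = 4000
        data = rng.poisson(300, (n, len(simple_sheet.sample_ids)))
        nm = normalize_log2(_cm(data, simple_sheet))
        rc = replicate_correlation(nm, simple_sheet)
        # null sd of r is 1/sqrt(n); 4-sigma bound over the 4 pairs tested
        assert (rc["r"].abs() < 4 / np.sqrt(n)).all()
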