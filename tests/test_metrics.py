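"""Overlap metrics, error metrics, and agreement statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ivcmquant.metrics import (
    agreement_report,
    bland_altman,
    confusion,
    dice,
    icc,
    mae,
    mape,
    pearson,
    precision,
    recall,
    specificity,
)

binary_mask = hnp.arrays(np.uint8, (8, 8), elements=st.integers(0, 1))


class TestOverlapMetrics:
    def test_identity(self):
        rng = np.random.default_rng(0)
        m = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        for metric in (dice, recall, precision, specificity):
            assert metric(m, m) == 1.0

    def test_complement_dice_zero(self):
        rng = np.random.default_rng(1)
        m = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        assert dice(1 - m, m) == 0.0

    def test_hand_counted_grid(self):
        """tp=3, fp=1, fn=1, tn=95 on a 10x10 grid."""
        truth = np.zeros((10, 10), dtype=np.uint8)
        truth[0, :4] = 1
        pred = np.zeros((10, 10), dtype=np.uint8)
        pred[0, 1:4] = 1  # 3 tp, 1 fn (0,0)
        pred[5, 5] = 1    # 1 fp
        c = confusion(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 1, 1, 95)
        assert dice(pred, truth) == pytest.approx(0.75)
        assert recall(pred, truth) == pytest.approx(0.75)
        assert precision(pred, truth) == pytest.approx(0.75)
        assert specificity(pred, truth) == pytest.approx(95 / 96)

    def test_empty_vs_empty_is_perfect(self):
        z = np.zeros((4, 4), dtype=np.uint8)
        assert dice(z, z) == recall(z, z) == precision(z, z) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((4, 4)), np.zeros((5, 5)))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(binary_mask, binary_mask)
    def test_symmetry_and_duality(self, a, b):
        assert dice(a, b) == pytest.approx(dice(b, a))
        assert recall(a, b) == pytest.approx(precision(b, a))
        for metric in (dice, recall, precision, specificity):
            assert 0.0 <= metric(a, b) <= 1.0


class TestErrorMetrics:
    def test_identical_vectors(self):
        assert mape([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert mae([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_computation(self):
        assert mape([11.0, 18.0], [10.0, 20.0]) == pytest.approx(10.0)
        assert mae([11.0, 18.0], [10.0, 20.0]) == pytest.approx(1.5)

    def test_single_pair(self):
        assert mape([1.0], [2.0]) == pytest.approx(50.0)
        assert mape([2.0], [1.0]) == pytest.approx(100.0)
        assert mae([1.0], [2.0]) == 1.0

    def test_zero_truth_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero reference"):
            value = mape([1.0, 5.0], [0.0, 4.0])
        assert value == pytest.approx(25.0)

    def test_all_zero_truth_rejected(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                mape([1.0], [0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae([1.0], [1.0, 2.0])


class TestBlandAltman:
    def test_printed_per_image_limits(self):
        """Differences with bias -0.01 mm and SD 0.13 mm give a lower limit
        of -0.2648, printed as -0.26."""
        bias, sd = -0.01, 0.13
        loa_low = bias - 1.96 * sd
        loa_high = bias + 1.96 * sd
        assert round(loa_low, 2) == -0.26
        assert loa_low == pytest.approx(-0.2648)
        assert loa_high == pytest.approx(0.2448)

    def test_computed_from_vectors(self):
        rng = np.random.default_rng(0)
        b = rng.normal(2.0, 0.5, 500)
        a = b + rng.normal(-0.01, 0.13, 500)
        bias, sd, lo, hi = bland_altman(a, b)
        d = a - b
        assert bias == pytest.approx(np.mean(d))
        assert sd == pytest.approx(np.std(d, ddof=1))
        assert hi - lo == pytest.approx(2 * 1.96 * sd)
        assert lo <= bias <= hi

    def test_identical_vectors(self):
        assert bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 0.0, 0.0, 0.0)

    def test_normal_coverage(self):
        """~95% of N(0,1) differences fall inside the limits."""
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 10000)
        b = np.zeros(10000)
        _, _, lo, hi = bland_altman(a, b)
        inside = np.mean((a >= lo) & (a <= hi))
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestIcc:
    def test_perfect_agreement(self):
        a = np.arange(10.0)
        val, ci = icc(a, a)
        assert val == 1.0 and ci == (1.0, 1.0)

    def test_large_noise_drives_icc_to_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 500)
        b = a + rng.normal(0, 20, 500)
        val, _ = icc(a, b)
        assert abs(val) < 0.1

    def test_constant_offset_penalized(self):
        a = np.arange(30.0)
        prev = 1.0
        for c in (8.0, 4.0, 1.0, 0.1):
            val, _ = icc(a, a + c)
            assert val < 1.0
            assert val > prev - 1.0  # increases toward 1 as the offset shrinks
            prev = val
        assert icc(a, a + 0.1)[0] > icc(a, a + 8.0)[0]
        assert icc(a, a + 0.001)[0] == pytest.approx(1.0, abs=1e-4)

    def test_matches_pingouin_two_way_absolute(self):
        """Cross-check ICC(A,1)/ICC(A,k) and CIs against pingouin."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        a = rng.normal(10, 3, 40)
        b = a + rng.normal(0.5, 1.0, 40)
        n = a.size
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(n), 2),
            "raters": np.tile(["m", "auto"], n),
            "scores": np.column_stack([a, b]).ravel(),
        })
        table = pg.intraclass_corr(df, targets="targets", raters="raters",
                                   ratings="scores").set_index("Type")
        for form, pg_type in (("single", "ICC(A,1)"), ("average", "ICC(A,k)")):
            ours, ours_ci = icc(a, b, form=form)
            row = table.loc[pg_type]
            assert ours == pytest.approx(row["ICC"], abs=1e-9)
            # pingouin rounds its reported interval to 2 decimals
            assert ours_ci[0] == pytest.approx(row["CI95"][0], abs=0.005)
            assert ours_ci[1] == pytest.approx(row["CI95"][1], abs=0.005)

    def test_zero_variance_identical_columns(self):
        val, ci = icc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert val == 1.0

    def test_zero_variance_unequal_columns_rejected(self):
        with pytest.raises(ValueError):
            icc([2.0, 2.0, 2.0], [3.0, 3.0, 3.0])


class TestPearson:
    def test_linear_transform_gives_unity(self):
        a = np.arange(10.0)
        r, _ = pearson(a, 2 * a + 1)
        assert r == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        a = np.arange(10.0)
        r, _ = pearson(a, -a)
        assert r == pytest.approx(-1.0)

    def test_ci_formula_self_consistency_at_n_128(self):
        """The reported interval equals tanh(atanh(r) +/- 1.96/sqrt(n-3))."""
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 128)
        b = 0.9 * a + rng.normal(0, 0.2, 128)
        r, (lo, hi) = pearson(a, b)
        z = np.arctanh(r)
        half = 1.959963984540054 / np.sqrt(128 - 3)
        assert lo == pytest.approx(np.tanh(z - half), abs=1e-9)
        assert hi == pytest.approx(np.tanh(z + half), abs=1e-9)
        assert lo < r < hi

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAgreementReport:
    def test_report_fields_consistent(self):
        rng = np.random.default_rng(7)
        manual = rng.uniform(10, 25, 60)
        auto = manual + rng.normal(-0.05, 0.4, 60)
        rep = agreement_report(auto, manual)
        assert rep.loa_low <= rep.bias <= rep.loa_high
        assert rep.loa_high - rep.bias == pytest.approx(rep.bias - rep.loa_low)
        assert -1 <= rep.icc <= 1 and -1 <= rep.pearson_r <= 1
        assert rep.mape >= 0 and rep.mae >= 0
        assert rep.n == 60

    def test_icc_and_pearson_agree_for_equal_moments(self):
        """With equal means and variances the two coefficients coincide in
        the large-n limit."""
        rng = np.random.default_rng(11)
        z = rng.normal(0, 1, (2, 5000))
        corr = 0.8
        a = z[0]
        b = corr * z[0] + np.sqrt(1 - corr**2) * z[1]
        icc_val, _ = icc(a, b)
        r, _ = pearson(a, b)
        assert icc_val == pytest.approx(r, abs=0.02)
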