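import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assrkit.errors import (DataIntegrityError, DegenerateDataError,
                            ParameterError)
from assrkit.reliability import classify_icc, icc_a1, icc_table


class TestICCA1:
    def test_pure_subject_effect_is_unity(self):
        m = np.array([[1.0, 1.0, 1.0], [5.0, 5.0, 5.0], [9.0, 9.0, 9.0]])
        res = icc_a1(m)
        assert res.icc == pytest.approx(1.0)

    def test_hand_computed_four_by_two(self):
        """Two-way ANOVA by hand: SS_rows=10, SS_cols=2, SS_err=0."""
        m = np.array([[1, 2], [2, 3], [3, 4], [4, 5]], dtype=float)
        res = icc_a1(m)
        assert res.icc == pytest.approx(10.0 / 13.0, abs=1e-10)
        assert res.f_value == np.inf
        assert res.df == (3.0, 3.0)

    def test_variance_ratio_recovery_monte_carlo(self):
        """y = b_i + c_j + e_ij with (9, 0.5, 0.5) variances: ICC -> 0.9."""
        rng = np.random.default_rng(17)
        n, k = 200, 5
        estimates = []
        for _ in range(100):
            y = (3.0 * rng.standard_normal((n, 1))
                 + np.sqrt(0.5) * rng.standard_normal((1, k))
                 + np.sqrt(0.5) * rng.standard_normal((n, k)))
            estimates.append(icc_a1(y).icc)
        assert np.mean(estimates) == pytest.approx(0.9, abs=0.03)

    def test_agrees_with_pingouin_on_random_matrices(self):
        """Independent reference: pingouin's two-way absolute-agreement
        single-measure ICC on 50 random tables."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(23)
        for _ in range(50):
            n = rng.integers(4, 12)
            k = rng.integers(2, 7)
            m = rng.normal(0, 1, size=(n, k)) \
                + rng.normal(0, 1.5, size=(n, 1))
            ours = icc_a1(m)
            long = pd.DataFrame({
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": m.ravel(),
            })
            ref = pingouin.intraclass_corr(
                long, targets="subject", raters="rater", ratings="score")
            ref2 = ref.set_index("Type").loc["ICC(A,1)"]
            assert ours.icc == pytest.approx(ref2["ICC"], abs=1e-6)
            assert ours.f_value == pytest.approx(ref2["F"], rel=1e-6)
            lo, hi = ref2["CI95"]  # pingouin rounds the CI to 2 decimals
            assert ours.ci95[0] == pytest.approx(lo, abs=6e-3)
            assert ours.ci95[1] == pytest.approx(hi, abs=6e-3)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(29)
        m = rng.normal(0, 1, (10, 4)) + rng.normal(0, 2, (10, 1))
        res = icc_a1(m)
        assert res.ci95[0] <= res.icc <= res.ci95[1]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_affine_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(0, 1, (6, 4)) + rng.normal(0, 1, (6, 1))
        base = icc_a1(m).icc
        assert icc_a1(3.5 * m + 11.0).icc == pytest.approx(base, abs=1e-10)
        assert icc_a1(m[rng.permutation(6)]).icc == \
            pytest.approx(base, abs=1e-10)
        assert icc_a1(m[:, rng.permutation(4)]).icc == \
            pytest.approx(base, abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            icc_a1(np.full((4, 3), 7.0))
        with pytest.raises(ParameterError):
            icc_a1(np.array([[1.0, np.nan], [2.0, 3.0]]))
        with pytest.raises(ParameterError):
            icc_a1(np.array([[1.0, 2.0]]))


class TestClassify:
    @pytest.mark.parametrize("value,category", [
        (0.85, "good"),
        (0.90, "excellent"),
        (0.95, "excellent"),
        (0.75, "good"),
        (0.5, "moderate"),
        (0.49, "poor"),
        (-0.2, "poor"),
    ])
    def test_interpretation_bands(self, value, category):
        assert classify_icc(value) == category

    def test_nonfinite_rejected(self):
        with pytest.raises(ParameterError):
            classify_icc(float("nan"))


class TestICCTable:
    def _long(self, with_gap=False):
        rows = []
        rng = np.random.default_rng(31)
        for sex, animals in (("M", ["M01", "M02", "M03", "M04"]),
                             ("F", ["F01", "F02", "F03", "F04"])):
            for aid in animals:
                subject = rng.normal(0, 2)
                for day in (1, 2, 3):
                    if with_gap and aid == "M02" and day == 3:
                        continue
                    rows.append({"animal_id": aid, "sex": sex, "day": day,
                                 "plf": subject + rng.normal(0, 0.3)})
        return pd.DataFrame(rows)

    def test_one_row_per_group(self):
        tab = icc_table(self._long(), "plf")
        assert list(tab["group"]) == ["F", "M"]
        assert set(tab["category"]) <= {"poor", "moderate", "good",
                                        "excellent"}

    def test_incomplete_series_named_in_strict_mode(self):
        with pytest.raises(DataIntegrityError, match="M02"):
            icc_table(self._long(with_gap=True), "plf", strict=True)

    def test_incomplete_series_dropped_when_lenient(self):
        tab = icc_table(self._long(with_gap=True), "plf", strict=False)
        assert tab.loc[tab.group == "M", "n_dropped"].iloc[0] == 1
        assert tab.loc[tab.group == "M", "n_subjects"].iloc[0] == 3
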