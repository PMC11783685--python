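import math

import numpy as np
import pytest

from poserom import (
    AngleMeasurement,
    Method,
    Movement,
    StudyTable,
    analyze_reliability,
    analyze_validity,
    bland_altman,
    classify_icc,
    classify_r,
    icc_two_way_random,
    mdc,
    pearson_r,
    sem,
)
from poserom.errors import (
    InsufficientDataError,
    UndefinedStatisticError,
    ValidationError,
)


def icc_a1_oracle(s1, s2):
    """Independent brute-force ANOVA evaluation of the single-measure
    absolute-agreement two-way random ICC, written with explicit loops."""
    n, k = len(s1), 2
    data = [[s1[i], s2[i]] for i in range(n)]
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((m - grand) ** 2 for m in row_means) / (n - 1)
    msc = n * sum((m - grand) ** 2 for m in col_means) / (k - 1)
    sse = sum(
        (data[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + mse + 2 * (msc - mse) / n)


class TestICC:
    def test_toy_table_matches_anova_oracle(self):
        s1, s2 = [10, 20, 30, 40], [12, 18, 32, 38]
        icc, _, _ = icc_two_way_random(s1, s2)
        assert icc == pytest.approx(icc_a1_oracle(s1, s2), abs=1e-12)
        # frozen value computed by the oracle: exact rational 230/233
        assert icc == pytest.approx(230 / 233, abs=1e-12)

    def test_random_tables_match_oracle(self, rng):
        for _ in range(50):
            a = rng.normal(50, 10, 12)
            b = a + rng.normal(0, 4, 12)
            icc, _, _ = icc_two_way_random(a, b)
            assert icc == pytest.approx(icc_a1_oracle(list(a), list(b)), abs=1e-12)

    def test_matches_pingouin_icc2(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        a = rng.normal(50, 10, 30)
        b = a + rng.normal(0, 4, 30)
        icc, lo, hi = icc_two_way_random(a, b)
        df = pd.DataFrame(
            {
                "subject": list(range(30)) * 2,
                "session": ["s1"] * 30 + ["s2"] * 30,
                "score": np.concatenate([a, b]),
            }
        )
        tab = pg.intraclass_corr(df, "subject", "session", "score")
        row = tab[tab.Type == "ICC(A,1)"].iloc[0] if (tab.Type == "ICC(A,1)").any() else tab[tab.Type == "ICC2"].iloc[0]
        assert icc == pytest.approx(float(row["ICC"]), abs=1e-10)
        ci = np.asarray(row["CI95"] if "CI95" in row else row["CI95%"], dtype=float)
        assert lo == pytest.approx(ci[0], abs=0.005)  # pingouin rounds to 2 dp
        assert hi == pytest.approx(ci[1], abs=0.005)

    def test_identical_sessions_give_one(self):
        icc, lo, hi = icc_two_way_random([10, 20, 30], [10, 20, 30])
        assert (icc, lo, hi) == (1.0, 1.0, 1.0)

    def test_constant_offset_penalized(self):
        s1 = [10.0, 20.0, 30.0, 40.0]
        icc, _, _ = icc_two_way_random(s1, [x + 5 for x in s1])
        assert icc < 1.0

    def test_absolute_agreement_monotone_in_offset(self):
        s1 = [10.0, 20.0, 30.0, 40.0, 50.0]
        iccs = [icc_two_way_random(s1, [x + off for x in s1])[0] for off in (0, 2, 5, 10, 20)]
        assert all(a > b for a, b in zip(iccs, iccs[1:]))

    def test_consistency_form_ignores_offset(self):
        s1 = [10.0, 20.0, 30.0, 40.0]
        icc_c, _, _ = icc_two_way_random(s1, [x + 5 for x in s1], form="consistency")
        assert icc_c == pytest.approx(1.0, abs=1e-12)

    def test_invariance_under_shift_and_scale(self, rng):
        a = rng.normal(50, 10, 20)
        b = a + rng.normal(0, 5, 20)
        base, _, _ = icc_two_way_random(a, b)
        shifted, _, _ = icc_two_way_random(a + 17.3, b + 17.3)
        scaled, _, _ = icc_two_way_random(a * 2.5, b * 2.5)
        assert shifted == pytest.approx(base, abs=1e-10)
        assert scaled == pytest.approx(base, abs=1e-10)

    def test_ci_brackets_estimate(self, rng):
        a = rng.normal(50, 10, 30)
        b = a + rng.normal(0, 4, 30)
        icc, lo, hi = icc_two_way_random(a, b)
        assert lo <= icc <= hi <= 1.0

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            icc_two_way_random([1, 2], [1, 2])
        with pytest.raises(UndefinedStatisticError):
            icc_two_way_random([5, 5, 5], [5, 5, 5])
        with pytest.raises(ValidationError):
            icc_two_way_random([1, 2, 3], [1, 2])


class TestSemMdc:
    def test_sem_zero_at_perfect_reliability(self):
        assert sem([1, 2, 3, 4], 1.0) == 0.0

    def test_sem_closed_form(self):
        # pooled SD 10, ICC 0.75 -> SEM = 10 * sqrt(0.25) = 5
        scores = [40.0, 50.0, 60.0, 40.0, 50.0, 60.0]
        s = np.std(scores, ddof=1)
        assert sem(scores, 0.75) == pytest.approx(s * 0.5, abs=1e-12)
        assert sem(np.array(scores) / s * 10, 0.75) == pytest.approx(5.0, abs=1e-12)

    def test_sem_domain(self):
        with pytest.raises(ValidationError):
            sem([1, 2, 3], 1.5)
        with pytest.raises(ValidationError):
            sem([1, 2, 3], -0.1)

    @pytest.mark.parametrize("s,expected", [(0.0, 0.0), (1.0, 2.771859), (5.0, 13.859293)])
    def test_mdc_closed_form(self, s, expected):
        assert mdc(s) == pytest.approx(expected, abs=5e-6)

    def test_mdc_ratio_constant(self):
        for s in (0.3, 1.7, 9.9):
            assert mdc(s) / s == pytest.approx(math.sqrt(2) * 1.96, abs=1e-12)
        with pytest.raises(ValidationError):
            mdc(-1.0)

    def test_sem_recovers_error_sd(self, rng):
        """With true score variance vb and error variance vw, SEM estimates
        sqrt(vw): SEM = S sqrt(1-ICC), S^2 ~ vb + vw, ICC ~ vb/(vb+vw)."""
        vb, vw = 81.0, 9.0
        sems = []
        for _ in range(100):
            t = rng.normal(100, math.sqrt(vb), 30)
            s1 = t + rng.normal(0, math.sqrt(vw), 30)
            s2 = t + rng.normal(0, math.sqrt(vw), 30)
            icc, _, _ = icc_two_way_random(s1, s2)
            sems.append(sem(np.concatenate([s1, s2]), icc))
        assert np.mean(sems) == pytest.approx(math.sqrt(vw), rel=0.1)


class TestClassifications:
    @pytest.mark.parametrize(
        "icc,label",
        [
            (0.93, "almost perfect"),
            (0.82, "almost perfect"),
            (0.83, "almost perfect"),
            (0.81, "almost perfect"),
            (0.74, "substantial"),
            (0.61, "substantial"),
            (0.60, "moderate"),
            (0.41, "moderate"),
            (0.30, "fair"),
            (0.10, "slight"),
            (0.0, "slight"),
        ],
    )
    def test_landis_koch_bands(self, icc, label):
        assert classify_icc(icc) == label

    def test_negative_icc_warns_slight(self):
        with pytest.warns(UserWarning):
            assert classify_icc(-0.2) == "slight"

    @pytest.mark.parametrize(
        "r,label",
        [
            (0.99, "very strong"),
            (0.98, "very strong"),
            (0.90, "very strong"),
            (0.87, "strong"),
            (0.85, "strong"),
            (0.70, "strong"),
            (0.69, "moderate"),
            (0.50, "moderate"),
            (0.30, "weak"),
            (0.10, "very weak"),
            (-0.95, "very strong"),  # magnitude only
        ],
    )
    def test_correlation_bands(self, r, label):
        assert classify_r(r) == label


class TestPearson:
    def test_linear_relations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, [2 * v + 3 for v in x]) == pytest.approx(1.0, abs=1e-12)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0, abs=1e-12)

    def test_toy_table_frozen_value(self):
        # covariance-definition oracle by hand: cov=3/3, sd_x*sd_y=5/3 -> r=0.6
        assert pearson_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6, abs=1e-12)

    def test_errors(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(InsufficientDataError):
            pearson_r([1, 2], [1, 2])


class TestBlandAltman:
    def test_identical_methods(self):
        ba = bland_altman([10, 20, 30], [10, 20, 30])
        assert ba.bias == 0.0
        assert (ba.loa_low, ba.loa_high) == (0.0, 0.0)
        assert ba.n_outside_loa == 0

    def test_hand_computed_differences(self):
        # differences {-1, 0, 1}: bias 0, SD 1, LoA +/- 1.96
        ba = bland_altman([9, 20, 31], [10, 20, 30])
        assert ba.bias == pytest.approx(0.0, abs=1e-12)
        assert ba.sd_diff == pytest.approx(1.0, abs=1e-12)
        assert ba.loa_low == pytest.approx(-1.96, abs=1e-12)
        assert ba.loa_high == pytest.approx(1.96, abs=1e-12)
        assert ba.n_outside_loa == 0

    def test_bias_is_difference_of_means_and_loa_width(self, rng):
        a = rng.normal(50, 10, 40)
        b = rng.normal(48, 10, 40)
        ba = bland_altman(a, b)
        assert ba.bias == pytest.approx(a.mean() - b.mean(), abs=1e-10)
        assert ba.loa_high - ba.loa_low == pytest.approx(3.92 * ba.sd_diff, abs=1e-10)

    def test_normal_coverage(self, rng):
        d = rng.normal(0, 2.5, 100_000)
        ba = bland_altman(d, np.zeros_like(d))
        inside = np.mean((d >= ba.loa_low) & (d <= ba.loa_high))
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            bland_altman([1, 2, 3], [1, 2])


def _table_from_arrays(movement, s1, s2, ref=None):
    table = StudyTable()
    for i, (a, b) in enumerate(zip(s1, s2)):
        pid = f"P{i:02d}"
        table.add(AngleMeasurement(pid, 1, movement, Method.APP, float(a)))
        table.add(AngleMeasurement(pid, 2, movement, Method.APP, float(b)))
        if ref is not None:
            table.add(AngleMeasurement(pid, 1, movement, Method.REFERENCE, float(ref[i])))
    return table


class TestStudyAnalyses:
    def test_reliability_equals_direct_calls(self):
        s1 = [100.0, 105, 110, 95, 120, 90]
        s2 = [101.0, 103, 112, 96, 118, 92]
        table = _table_from_arrays(Movement.HIP_FLEXION, s1, s2)
        (res,) = analyze_reliability(table)
        icc, lo, hi = icc_two_way_random(s1, s2)
        assert res.icc == icc and res.ci_low == lo and res.ci_high == hi
        assert res.sem == pytest.approx(sem(s1 + s2, icc), abs=1e-12)
        assert res.mdc == pytest.approx(mdc(res.sem), abs=1e-12)
        assert res.icc_class == classify_icc(icc)

    def test_missing_session_lists_participants(self):
        table = _table_from_arrays(Movement.HIP_FLEXION, [100.0, 105, 110], [101.0, 103, 112])
        table.add(AngleMeasurement("P99", 1, Movement.HIP_FLEXION, Method.APP, 100.0))
        with pytest.raises(ValidationError, match="P99"):
            analyze_reliability(table)

    def test_validity_equals_direct_calls(self):
        app = [100.0, 105, 110, 95, 120, 90]
        ref = [101.0, 104, 112, 95, 119, 93]
        table = _table_from_arrays(Movement.KNEE_FLEXION, app, app, ref)
        (res,) = analyze_validity(table)
        assert res.r == pytest.approx(pearson_r(app, ref), abs=1e-12)
        ba = bland_altman(app, ref)
        assert res.bias == ba.bias and res.n_outside_loa == ba.n_outside_loa

    def test_unpaired_methods_rejected(self):
        table = _table_from_arrays(Movement.KNEE_FLEXION, [1.0, 2, 3], [1.0, 2, 3], [1.0, 2, 3])
        table.add(AngleMeasurement("P50", 1, Movement.KNEE_FLEXION, Method.APP, 10.0))
        with pytest.raises(ValidationError, match="P50"):
            analyze_validity(table)
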