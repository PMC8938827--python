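"""Two-way random-effects ICC, interpretation bands, planner, Welch tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hp13c.repeatability import (
    DegenerateMatrixError,
    RepeatabilityMatrix,
    UnbalancedDesignError,
    build_matrix,
    icc_absolute,
    icc_band,
    icc_sample_size,
    icc_table,
    icc_wald_ci,
    welch_ttest,
)


from conftest import icc_a1_oracle


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["subject_id", "site_id", "exam_id", "metric_name", "roi_label", "value"],
    )


class TestBuildMatrix:
    def test_one_exam_per_cell_is_raw_values(self):
        rows = [
            (s, site, f"{s}{site}", "k_pl", "cortex", v)
            for (s, site, v) in [("a", "s1", 1.0), ("a", "s2", 2.0), ("b", "s1", 3.0), ("b", "s2", 4.0)]
        ]
        m = build_matrix(_records(rows), "k_pl", roi_rule="cortex", rater_kind="site")
        assert np.allclose(m.values, [[1, 2], [3, 4]])

    def test_site_mean_aggregation(self):
        rows = [
            ("a", "s1", "e1", "k_pl", "cortex", 0.02),
            ("a", "s1", "e2", "k_pl", "cortex", 0.03),
            ("a", "s2", "e3", "k_pl", "cortex", 0.04),
            ("b", "s1", "e4", "k_pl", "cortex", 0.05),
            ("b", "s2", "e5", "k_pl", "cortex", 0.06),
        ]
        m = build_matrix(_records(rows), "k_pl", roi_rule="cortex", rater_kind="site")
        assert m.values[0, 0] == pytest.approx(0.025)

    def test_cortex_dwm_mean_rule(self):
        rows = [
            ("a", "s1", "e1", "k_pl", "cortex", 0.02),
            ("a", "s1", "e1", "k_pl", "deep_white_matter", 0.04),
            ("a", "s2", "e2", "k_pl", "cortex", 0.02),
            ("a", "s2", "e2", "k_pl", "deep_white_matter", 0.02),
            ("b", "s1", "e3", "k_pl", "cortex", 0.05),
            ("b", "s1", "e3", "k_pl", "deep_white_matter", 0.05),
            ("b", "s2", "e4", "k_pl", "cortex", 0.06),
            ("b", "s2", "e4", "k_pl", "deep_white_matter", 0.06),
        ]
        m = build_matrix(_records(rows), "k_pl", roi_rule="cortex_dwm_mean", rater_kind="site")
        assert m.values[0, 0] == pytest.approx(0.03)

    def test_examination_mode_truncates_to_common_minimum(self):
        # 3, 3 and 2 exams per subject -> 3 x 2 matrix
        rows = []
        counts = {"a": 3, "b": 3, "c": 2}
        v = 0.0
        for s, cnt in counts.items():
            for e in range(cnt):
                v += 1.0
                rows.append((s, "s1", f"{s}e{e}", "k_pl", "cortex", v))
        m = build_matrix(_records(rows), "k_pl", roi_rule="cortex", rater_kind="examination")
        assert m.values.shape == (3, 2)
        assert m.raters == ["exam1", "exam2"]
        # chronological order preserved within each subject
        assert np.allclose(m.values[0], [1.0, 2.0])

    def test_missing_site_raises(self):
        rows = [
            ("a", "s1", "e1", "k_pl", "cortex", 1.0),
            ("a", "s2", "e2", "k_pl", "cortex", 2.0),
            ("b", "s1", "e3", "k_pl", "cortex", 3.0),
        ]
        with pytest.raises(UnbalancedDesignError):
            build_matrix(_records(rows), "k_pl", roi_rule="cortex", rater_kind="site")


class TestIccAbsolute:
    def test_perfect_agreement(self):
        m = RepeatabilityMatrix(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]), ["a", "b", "c"], ["s1", "s2"], "site")
        r = icc_absolute(m)
        assert r.icc == pytest.approx(1.0)
        assert r.band == "excellent"
        assert r.p_value < 0.05

    def test_constant_rater_offset_penalized(self):
        x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        m = RepeatabilityMatrix(x, ["a", "b", "c"], ["s1", "s2"], "site")
        r = icc_absolute(m)
        assert r.icc < 1.0
        assert r.icc == pytest.approx(icc_a1_oracle(x), abs=1e-12)

    def test_matches_raw_ss_oracle_on_random_matrices(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(3, 21))
            k = int(rng.integers(2, 6))
            x = rng.normal(10, 3, size=(n, k)) + rng.normal(0, 2, size=(n, 1))
            m = RepeatabilityMatrix(x, [f"s{i}" for i in range(n)], [f"r{j}" for j in range(k)], "site")
            assert icc_absolute(m).icc == pytest.approx(icc_a1_oracle(x), abs=1e-10)

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        for _ in range(5):
            n, k = 8, 3
            x = rng.normal(0, 1, size=(n, k)) + rng.normal(0, 1, size=(n, 1))
            df = pd.DataFrame(
                [
                    {"targets": i, "raters": j, "ratings": x[i, j]}
                    for i in range(n)
                    for j in range(k)
                ]
            )
            ref = pingouin.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
            icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
            m = RepeatabilityMatrix(x, list("abcdefgh"), ["r1", "r2", "r3"], "site")
            assert icc_absolute(m).icc == pytest.approx(icc2, abs=1e-6)

    def test_shift_invariance_and_column_offset(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, size=(10, 3)) + rng.normal(0, 2, size=(10, 1))
        m = RepeatabilityMatrix(x, [f"s{i}" for i in range(10)], ["a", "b", "c"], "site")
        base = icc_absolute(m).icc
        shifted = RepeatabilityMatrix(x + 5.0, m.subjects, m.raters, "site")
        assert icc_absolute(shifted).icc == pytest.approx(base, abs=1e-12)
        skew = x.copy()
        skew[:, 0] += 5.0  # systematic offset of one rater
        m2 = RepeatabilityMatrix(skew, m.subjects, m.raters, "site")
        assert icc_absolute(m2).icc < base

    def test_zero_variance_degenerate(self):
        m = RepeatabilityMatrix(np.ones((3, 2)), ["a", "b", "c"], ["s1", "s2"], "site")
        with pytest.raises(DegenerateMatrixError):
            icc_absolute(m)

    def test_large_n_consistency(self):
        # generating components implying ICC = 0.8 recovered within +/-0.03
        rng = np.random.default_rng(2024)
        n, k = 1000, 2
        sd_b = 1.0
        sd_e = math.sqrt(1 / 0.8 - 1)
        x = rng.normal(0, sd_b, (n, 1)) + rng.normal(0, sd_e, (n, k))
        m = RepeatabilityMatrix(x, [f"s{i}" for i in range(n)], ["r1", "r2"], "site")
        assert icc_absolute(m).icc == pytest.approx(0.8, abs=0.03)


class TestIccBand:
    @pytest.mark.parametrize(
        "icc,band",
        [
            (0.83, "good"),
            (0.49999, "poor"),
            (0.5, "moderate"),
            (0.75, "good"),
            (0.9, "excellent"),
            (-0.2, "poor"),
        ],
    )
    def test_boundaries(self, icc, band):
        assert icc_band(icc) == band

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            icc_band(1.2)


class TestSampleSize:
    def test_published_planning_points(self):
        assert icc_sample_size(0.8, 0.2, 0.05, k=2).n_required == 14
        assert icc_sample_size(0.8, 0.2, 0.05, k=3).n_required == 10

    def test_floor_at_two(self):
        assert icc_sample_size(0.8, 50.0, 0.05, k=2).n_required == 2

    @given(
        rho=st.floats(0.05, 0.95),
        w=st.floats(0.05, 0.5),
        k=st.integers(2, 6),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_k_and_w(self, rho, w, k):
        n = icc_sample_size(rho, w, k=k).n_required
        assert icc_sample_size(rho, w, k=k + 1).n_required <= n
        assert icc_sample_size(rho, w * 1.5, k=k).n_required <= n

    def test_variance_term_gradient_sign(self):
        # d/drho of (1-rho)^2 (1+(k-1) rho)^2 changes sign at rho = (k-2)/(2(k-1));
        # check the implemented n(rho) follows the numeric derivative's sign
        k = 4
        g = lambda rho: (1 - rho) ** 2 * (1 + (k - 1) * rho) ** 2
        rhos = np.linspace(0.05, 0.95, 19)
        num_grad = np.gradient([g(r) for r in rhos], rhos)
        ns = [icc_sample_size(r, 0.05, k=k).n_required for r in rhos]
        for i in range(1, len(rhos) - 1):
            if num_grad[i] > 1e-3:
                assert ns[i + 1] >= ns[i - 1]
            elif num_grad[i] < -1e-3:
                assert ns[i + 1] <= ns[i - 1]

    def test_invalid_domains(self):
        for bad in (dict(rho=0.0), dict(rho=1.0), dict(w=0.0), dict(k=1), dict(alpha=0.0)):
            kwargs = dict(rho=0.8, w=0.2, alpha=0.05, k=2) | bad
            with pytest.raises(ValueError):
                icc_sample_size(**kwargs)


class TestPlannerEstimatorConsistency:
    def test_coverage_at_planned_n(self):
        # at the planner's n = 14, k = 2 for rho = 0.8, w = 0.2: the mean
        # estimate is nearly unbiased and the Wald CI covers the truth
        rng = np.random.default_rng(7)
        n, k, rho = 14, 2, 0.8
        sd_e = math.sqrt(1 / rho - 1)
        est, covered, narrow_covered = [], 0, 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(0, 1.0, (n, 1)) + rng.normal(0, sd_e, (n, k))
            m = RepeatabilityMatrix(x, [f"s{i}" for i in range(n)], ["a", "b"], "site")
            icc = icc_absolute(m).icc
            est.append(icc)
            lo, hi = icc_wald_ci(icc, n, k)
            if lo <= rho <= hi:
                covered += 1
        assert abs(np.mean(est) - rho) < 0.05
        assert covered / reps >= 0.93


class TestWelch:
    def test_identical_groups(self):
        r = welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_separated_groups(self):
        r = welch_ttest([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert r.p < 1e-3

    def test_hand_computed_statistic(self):
        a, b = np.array([10.0, 12.0, 14.0]), np.array([11.0, 13.0, 15.0, 17.0])
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = math.sqrt(va / 3 + vb / 4)
        t_hand = (a.mean() - b.mean()) / se
        df_hand = (va / 3 + vb / 4) ** 2 / ((va / 3) ** 2 / 2 + (vb / 4) ** 2 / 3)
        r = welch_ttest(a, b)
        assert r.t == pytest.approx(t_hand, rel=1e-12)
        assert r.df == pytest.approx(df_hand, rel=1e-12)

    def test_degenerate_variances(self):
        with pytest.raises(ValueError):
            welch_ttest([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            welch_ttest([1.0], [2.0, 3.0])


class TestIccTable:
    def test_degenerate_reported_as_perfect_with_warning(self, caplog):
        rows = []
        for s in ("a", "b"):
            for site in ("s1", "s2"):
                for roi in ("cortex", "deep_white_matter"):
                    rows.append((s, site, f"{s}{site}", "k_pl", roi, 0.02))
        import logging

        with caplog.at_level(logging.WARNING, logger="hp13c"):
            table = icc_table(_records(rows), metrics=("k_pl",), rater_kinds=("site",))
        assert table["icc"].iloc[0] == 1.0
        assert table["band"].iloc[0] == "excellent"
        assert "zero total variance" in caplog.text
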