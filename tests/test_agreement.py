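"""Two-way ANOVA decomposition, ICC(2,1), and Fleiss–Shrout intervals.

The brute-force oracle recomputes every sum of squares from its definition
(explicit Python loops over cells) so the vectorized decomposition is
checked against an independent path; pingouin's ICC(A,1) provides an
external cross-check of both the estimate and the interval.
"""

import numpy as np
import pytest

from tilring.agreement import (
    AgreementError,
    DegenerateVarianceError,
    IncompleteDataError,
    VarianceComponents,
    anova_decompose,
    icc_2_1,
    icc_confidence_interval,
    icc_report,
)
from tilring.core_io import ScoreMatrix

from conftest import random_matrix


def brute_force_components(y):
    """Direct-definition sums of squares, independent of the implementation."""
    n, k = y.shape
    grand = sum(y[i][j] for i in range(n) for j in range(k)) / (n * k)
    mi = [sum(y[i]) / k for i in range(n)]
    mj = [sum(y[i][j] for i in range(n)) / n for j in range(k)]
    bms = k * sum((m - grand) ** 2 for m in mi) / (n - 1)
    jms = n * sum((m - grand) ** 2 for m in mj) / (k - 1)
    ems = sum(
        (y[i][j] - mi[i] - mj[j] + grand) ** 2
        for i in range(n) for j in range(k)
    ) / ((n - 1) * (k - 1))
    return bms, jms, ems


class TestAnovaDecompose:
    def test_constant_matrix_all_zero(self):
        m = ScoreMatrix(("a", "b"), ("x", "y"), np.full((2, 2), 42.0))
        c = anova_decompose(m)
        assert c.ms_cases == c.ms_readers == c.ms_error == 0

    def test_identical_readers_only_case_variance(self, identical_readers):
        c = anova_decompose(identical_readers)
        assert c.ms_readers == 0 and c.ms_error == 0 and c.ms_cases > 0

    def test_worked_matrix_matches_brute_force(self, worked_4x3):
        c = anova_decompose(worked_4x3)
        bms, jms, ems = brute_force_components(worked_4x3.scores)
        assert c.ms_cases == pytest.approx(bms, rel=1e-10)
        assert c.ms_readers == pytest.approx(jms, rel=1e-10)
        assert c.ms_error == pytest.approx(ems, rel=1e-10)

    def test_sum_of_squares_partition_identity(self, worked_4x3):
        c = anova_decompose(worked_4x3)
        total = ((worked_4x3.scores - worked_4x3.scores.mean()) ** 2).sum()
        parts = (c.df_cases * c.ms_cases + c.df_readers * c.ms_readers
                 + c.df_error * c.ms_error)
        assert parts == pytest.approx(total, rel=1e-9)

    def test_missing_cells_rejected(self):
        m = ScoreMatrix(("a", "b"), ("x", "y"),
                        np.array([[1.0, np.nan], [2.0, 3.0]]))
        with pytest.raises(IncompleteDataError):
            anova_decompose(m)

    @pytest.mark.parametrize("shape", [(1, 3), (3, 1)])
    def test_dimension_errors(self, shape):
        m = ScoreMatrix(tuple(f"s{i}" for i in range(shape[0])),
                        tuple(f"r{j}" for j in range(shape[1])),
                        np.zeros(shape))
        with pytest.raises(AgreementError):
            anova_decompose(m)


class TestIcc21:
    def test_perfect_agreement_is_one(self, identical_readers):
        assert icc_2_1(anova_decompose(identical_readers)).estimate == 1.0

    def test_constant_matrix_degenerate(self):
        m = ScoreMatrix(("a", "b"), ("x", "y"), np.full((2, 2), 10.0))
        with pytest.raises(DegenerateVarianceError):
            icc_2_1(anova_decompose(m))

    def test_mean_square_and_variance_component_forms_agree(self, worked_4x3):
        c = anova_decompose(worked_4x3)
        est = icc_2_1(c).estimate
        alt = c.var_cases / (c.var_cases + c.var_readers + c.var_error)
        assert est == pytest.approx(alt, rel=1e-12)

    def test_negative_estimate_flagged_not_clamped(self):
        m = ScoreMatrix(("a", "b", "c"), ("r1", "r2"),
                        np.array([[0, 100], [100, 0], [0, 100]], float))
        r = icc_2_1(anova_decompose(m))
        assert r.estimate < 0 and r.negative_flag

    def test_location_and_scale_invariance(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            m = random_matrix(rng)
            base = icc_2_1(anova_decompose(m)).estimate
            shifted = ScoreMatrix(m.slide_ids, m.reader_ids, m.scores + 7.3)
            scaled = ScoreMatrix(m.slide_ids, m.reader_ids, m.scores * 0.4)
            assert icc_2_1(anova_decompose(shifted)).estimate == pytest.approx(
                base, abs=1e-10)
            assert icc_2_1(anova_decompose(scaled)).estimate == pytest.approx(
                base, abs=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        m = random_matrix(rng, n=10, k=5)
        base = icc_report(m)
        perm_s = rng.permutation(10)
        perm_r = rng.permutation(5)
        shuffled = ScoreMatrix(
            tuple(m.slide_ids[i] for i in perm_s),
            tuple(m.reader_ids[j] for j in perm_r),
            m.scores[np.ix_(perm_s, perm_r)],
        )
        out = icc_report(shuffled)
        assert out.estimate == pytest.approx(base.estimate, abs=1e-12)
        assert out.ci_low == pytest.approx(base.ci_low, abs=1e-12)
        assert out.ci_high == pytest.approx(base.ci_high, abs=1e-12)

    def test_more_reader_variance_lowers_icc(self):
        # 1 - ICC is the reader-attributable share: inflate reader bias
        from tilring.simulate import NormalCases, SimulationConfig, simulate_study

        means = []
        for var_reader in (4, 100, 400):
            ests = []
            for seed in range(40):
                cfg = SimulationConfig(
                    n_slides=40, n_readers=6,
                    case_distribution=NormalCases(mean=50, sd=np.sqrt(300)),
                    sigma_reader=np.sqrt(var_reader), sigma_region=0,
                    sigma_error=np.sqrt(75), clip=False, seed=seed,
                )
                ests.append(icc_report(simulate_study(cfg)[0]).estimate)
            means.append(np.mean(ests))
        assert means[0] > means[1] > means[2]


class TestConfidenceInterval:
    def test_brackets_estimate_on_random_matrices(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            m = random_matrix(rng)
            r = icc_report(m)
            assert r.ci_low - 1e-9 <= r.estimate <= r.ci_high + 1e-9

    def test_perfect_agreement_interval_degenerate(self, identical_readers):
        r = icc_report(identical_readers)
        assert (r.ci_low, r.ci_high) == (1.0, 1.0)
        assert r.degenerate_ci
        assert r.format() == "1.00 (degenerate)"

    def test_matches_pingouin_external_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(0)
        y = (rng.normal(30, 10, (12, 5)) + rng.normal(0, 4, 5)[None, :]
             + rng.normal(0, 15, 12)[:, None])
        m = ScoreMatrix(tuple(f"s{i}" for i in range(12)),
                        tuple(f"r{j}" for j in range(5)), y)
        r = icc_report(m)
        df = pd.DataFrame({
            "t": np.repeat(np.arange(12), 5),
            "r": np.tile(np.arange(5), 12),
            "y": y.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="t", raters="r", ratings="y")
        # absolute-agreement single-rater row; label varies across versions
        row = ref[ref.Type.isin(["ICC2", "ICC(A,1)"])].iloc[0]
        assert r.estimate == pytest.approx(row.ICC, abs=1e-10)
        lo, hi = row["CI95"]
        assert r.ci_low == pytest.approx(lo, abs=0.005)  # pingouin rounds to 2dp
        assert r.ci_high == pytest.approx(hi, abs=0.005)

    def test_width_shrinks_with_sample_size(self):
        from tilring.simulate import NormalCases, SimulationConfig, simulate_study

        widths = []
        for n in (20, 60, 200):
            w = []
            for seed in range(60):
                cfg = SimulationConfig(
                    n_slides=n, n_readers=6,
                    case_distribution=NormalCases(mean=50, sd=np.sqrt(300)),
                    sigma_reader=5, sigma_region=0, sigma_error=np.sqrt(75),
                    clip=False, seed=seed,
                )
                r = icc_report(simulate_study(cfg)[0])
                w.append(r.ci_high - r.ci_low)
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]

    def test_invalid_level_rejected(self, worked_4x3):
        c = anova_decompose(worked_4x3)
        with pytest.raises(AgreementError):
            icc_confidence_interval(c, 0.5, level=1.5)

    def test_report_composes_the_stages(self, worked_4x3):
        c = anova_decompose(worked_4x3)
        point = icc_2_1(c)
        ci = icc_confidence_interval(c, point.estimate, 0.95)
        r = icc_report(worked_4x3, 0.95)
        assert (r.estimate, r.ci_low, r.ci_high) == (point.estimate, ci.low, ci.high)


def test_variance_components_dof():
    c = VarianceComponents(1.0, 1.0, 1.0, n=60, k=32)
    assert (c.df_cases, c.df_readers, c.df_error) == (59, 31, 59 * 31)
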