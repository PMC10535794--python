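"""Nonparametric battery: Kruskal-Wallis, Wilcoxon vs limit, Spearman matrix."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from troutrisk.errors import DegenerateDataError, PairingError, ValidationError
from troutrisk.stats import (
    bh_adjust,
    kruskal_wallis,
    spearman_matrix,
    wilcoxon_vs_limit,
)


class TestKruskalWallis:
    def test_worked_three_group_example(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2, rel=1e-12)
        assert res.n == (3, 3, 3)

    def test_identical_groups_give_zero_statistic(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_rank_invariance_under_within_group_permutation(self):
        rng = np.random.default_rng(0)
        groups = [rng.uniform(size=8) for _ in range(3)]
        shuffled = [rng.permutation(g) for g in groups]
        assert kruskal_wallis(groups).statistic == pytest.approx(
            kruskal_wallis(shuffled).statistic, rel=1e-12
        )

    def test_monotone_transform_invariance(self):
        groups = [[1.0, 2.0, 3.0], [1.5, 2.5, 9.0], [0.1, 4.0, 5.0]]
        transformed = [list(np.exp(g)) for g in groups]
        assert kruskal_wallis(groups).statistic == pytest.approx(
            kruskal_wallis(transformed).statistic, rel=1e-12
        )

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1, 2, 3]])


class TestWilcoxonVsLimit:
    def test_symmetric_example_after_zero_drop(self):
        # (1,2,3) vs 2: the zero difference is dropped, remaining ranks tie
        res = wilcoxon_vs_limit([1, 2, 3], 2, alternative="two_sided")
        assert res.statistic == 1.5
        assert res.p_value == 1.0
        assert res.n == (2,)

    def test_extreme_one_sided_case_exact_tail(self):
        values = np.arange(1, 13) + 100.0
        res = wilcoxon_vs_limit(values, 100.0, alternative="greater")
        assert res.p_value == pytest.approx(2**-12, rel=1e-12)
        assert res.significant

    def test_all_values_at_limit_degenerate(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_vs_limit([2.0, 2.0, 2.0], 2.0)

    def test_exact_matches_scipy_on_tie_free_data(self):
        # independent oracle: scipy's exact signed-rank on tie-free differences
        rng = np.random.default_rng(4)
        for _ in range(20):
            values = rng.normal(0.5, 1.0, 12)
            ours = wilcoxon_vs_limit(values, 0.0, alternative="two_sided")
            ref = sps.wilcoxon(values, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    def test_one_sided_exact_tails_match_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            values = rng.normal(0.5, 1.0, 10)
            for ours_alt, scipy_alt in [("greater", "greater"), ("less", "less")]:
                ours = wilcoxon_vs_limit(values, 0.0, alternative=ours_alt).p_value
                ref = sps.wilcoxon(values, alternative=scipy_alt, method="exact").pvalue
                assert ours == pytest.approx(ref, rel=1e-12)
        # the two discrete tails overlap exactly at the observed atom
        g = wilcoxon_vs_limit(values, 0.0, alternative="greater").p_value
        l = wilcoxon_vs_limit(values, 0.0, alternative="less").p_value
        assert g + l >= 1.0

    def test_large_n_uses_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(5)
        values = np.round(rng.normal(10.2, 1.0, 60), 1)  # rounding creates ties
        res = wilcoxon_vs_limit(values, 10.0, alternative="greater")
        assert res.method.startswith("normal approximation")
        ref = sps.wilcoxon(values - 10.0, alternative="greater", method="approx",
                           correction=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_monotone_transform_invariance_of_flag(self):
        values = [1.2, 1.5, 1.9, 2.4, 3.0]
        a = wilcoxon_vs_limit(values, 1.0, "greater").p_value
        b = wilcoxon_vs_limit(np.exp(values), np.exp(1.0), "greater").p_value
        assert a == b


class TestSpearmanMatrix:
    def test_worked_n4_example(self):
        rho = sps.spearmanr([1, 2, 3, 4], [2, 1, 4, 3]).statistic
        assert rho == pytest.approx(0.6, rel=1e-12)

    def test_matrix_properties_on_survey_dataset(self, survey_dataset):
        cm = spearman_matrix(survey_dataset)
        assert len(cm.labels) == 12  # 3 matrices x 4 elements
        assert cm.n == 36  # sectors pooled
        r = cm.rho.to_numpy()
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0)
        assert np.abs(r).max() <= 1 + 1e-12
        long = cm.to_long()
        assert len(long) == 12 * 11 // 2

    def test_perfect_monotone_pairs(self):
        rows = []
        for i, (x, y) in enumerate(zip([1, 2, 3, 4], [10, 20, 30, 40]), start=1):
            rows.append(("lower", "muscle", "As", i, x))
            rows.append(("lower", "water", "As", i, y))
        frame = pd.DataFrame(
            rows, columns=["sector", "matrix", "element", "replicate_id", "concentration"]
        )
        cm = spearman_matrix(frame)
        assert cm.rho.loc["As-m", "As-w"] == pytest.approx(1.0)
        frame.loc[frame["matrix"] == "water", "concentration"] = [40, 30, 20, 10]
        cm2 = spearman_matrix(frame)
        assert cm2.rho.loc["As-m", "As-w"] == pytest.approx(-1.0)

    def test_brute_force_definition_on_tie_free_vectors(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) without ties
        rng = np.random.default_rng(11)
        for _ in range(20):
            x, y = rng.normal(size=(2, 15))
            rx, ry = sps.rankdata(x), sps.rankdata(y)
            d2 = np.sum((rx - ry) ** 2)
            brute = 1 - 6 * d2 / (15 * (15**2 - 1))
            assert sps.spearmanr(x, y).statistic == pytest.approx(brute, rel=1e-12)

    def test_misaligned_replicates_raise(self, survey_dataset):
        broken = survey_dataset.drop(index=survey_dataset.index[0])
        with pytest.raises(PairingError):
            spearman_matrix(broken)

    def test_per_sector_matrices(self, survey_dataset):
        per = spearman_matrix(survey_dataset, per_sector=True)
        assert set(per) == {"upper", "middle", "lower"}
        assert all(cm.n == 12 for cm in per.values())


class TestBhAdjust:
    def test_step_up_hand_example(self):
        adj = bh_adjust([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(adj, [0.02, 0.04, 0.04, 0.02])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1)
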