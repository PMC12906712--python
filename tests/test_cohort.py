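import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diadetect.cohort import (
    compare_id_counts,
    correlate_with_behavior,
    pca_replicates,
    summarize_bal,
)

BAL_MALE = [91.8, 171.7, 144.2, 132.4, 165.7, 235.1]
BAL_FEMALE = [145.5, 152.8, 134.2, 177.8, 158.5, 199.3]


class TestCompareIdCounts:
    def test_identical_groups(self):
        out = compare_id_counts([1, 2, 3], [1, 2, 3])
        assert out["t_statistic"] == 0.0
        assert out["p_value"] == pytest.approx(1.0)

    def test_degenerate_zero_variance(self):
        out = compare_id_counts([5, 5], [5, 5])
        assert out["t_statistic"] == 0.0 and out["p_value"] == 1.0

    def test_pooled_variance_closed_form(self):
        a, b = [10.0, 11.0, 12.0], [20.0, 21.0, 22.0]
        out = compare_id_counts(a, b)
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        t_manual = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert out["t_statistic"] == pytest.approx(t_manual, abs=1e-9)
        assert out["shapiro_p_per_group"][0] > 0.05

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(99)
        reps, hits = 1000, 0
        for _ in range(reps):
            a = rng.normal(300, 30, size=4)
            b = rng.normal(300, 30, size=5)
            hits += compare_id_counts(a, b)["p_value"] < 0.05
        rate = hits / reps
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se


class TestPcaReplicates:
    def _matrix(self, values, runs):
        return pd.DataFrame(values, columns=runs)

    def test_duplicated_samples_collapse(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(100, 1000, size=(20, 2))
        mat = self._matrix(np.hstack([base[:, [0]]] * 3 + [base[:, [1]]] * 3),
                           [f"S{i}" for i in range(6)])
        scores = pca_replicates(mat)["scores"]
        within_a = np.linalg.norm(scores.iloc[0] - scores.iloc[1])
        within_b = np.linalg.norm(scores.iloc[3] - scores.iloc[4])
        assert within_a == pytest.approx(0.0, abs=1e-9)
        assert within_b == pytest.approx(0.0, abs=1e-9)

    def test_rank_one_matrix_pc1_explains_all(self):
        rng = np.random.default_rng(1)
        u = rng.uniform(1, 2, size=20)
        v = rng.uniform(1, 3, size=5)
        mat = self._matrix(2.0 ** np.outer(u, v), [f"S{i}" for i in range(5)])
        fractions = pca_replicates(mat)["variance_fractions"]
        assert fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_fractions_nonincreasing_sum_below_one(self, bundle):
        from diadetect.quant import quantify_all
        from diadetect.diann_io import apply_filters

        quant = quantify_all(apply_filters(bundle.report), bundle.metadata)
        out = pca_replicates(quant)
        fr = out["variance_fractions"]
        assert all(b <= a + 1e-12 for a, b in zip(fr, fr[1:]))
        assert sum(fr) <= 1 + 1e-9

    def test_sample_reorder_invariance_up_to_sign(self):
        rng = np.random.default_rng(3)
        mat = self._matrix(2.0 ** rng.normal(15, 2, size=(30, 6)), [f"S{i}" for i in range(6)])
        scores = pca_replicates(mat)["scores"]
        perm = ["S3", "S0", "S5", "S1", "S4", "S2"]
        scores_perm = pca_replicates(mat[perm])["scores"].loc[scores.index]
        for pc in scores.columns:
            match = np.allclose(scores[pc], scores_perm[pc], atol=1e-8)
            flipped = np.allclose(scores[pc], -scores_perm[pc], atol=1e-8)
            assert match or flipped

    def test_planted_separation_detected(self):
        rng = np.random.default_rng(4)
        n_prot = 40
        base = rng.normal(15, 0.5, size=(n_prot, 1))
        dep = base + 2.0 + rng.normal(0, 0.2, size=(n_prot, 4))
        nondep = base + rng.normal(0, 0.2, size=(n_prot, 5))
        mat = self._matrix(2.0 ** np.hstack([dep, nondep]),
                           [f"D{i}" for i in range(4)] + [f"N{i}" for i in range(5)])
        scores = pca_replicates(mat)["scores"]
        from sklearn.metrics import silhouette_score

        labels = [0] * 4 + [1] * 5
        assert silhouette_score(scores[["PC1"]], labels) > 0

    def test_too_few_complete_proteins_errors(self):
        mat = self._matrix([[1.0, np.nan, 2.0], [np.nan, 1.0, 2.0]], ["A", "B", "C"])
        with pytest.raises(ValueError, match="complete-case"):
            pca_replicates(mat)


class TestSummarizeBal:
    def test_reference_table_reproduced(self):
        table = summarize_bal({"Male": BAL_MALE, "Female": BAL_FEMALE})
        assert table.loc["Male Mean", "Overall"] == 156.8
        assert table.loc["Female Mean", "Overall"] == 161.4
        assert table.loc["Combined Mean", "Overall"] == 159.1
        assert list(table.loc["Combined Mean"][:-1]) == [118.7, 162.3, 139.2, 155.1, 162.1, 217.2]

    def test_half_away_from_zero_rounding(self):
        # 91.8 and 145.5 average to 118.65, which must round up to 118.7
        table = summarize_bal({"Male": [91.8] * 6, "Female": [145.5] * 6})
        assert table.loc["Combined Mean", "CIE 1"] == 118.7

    def test_identical_rows_combined_equals_them(self):
        table = summarize_bal({"Male": BAL_MALE, "Female": BAL_MALE})
        assert list(table.loc["Combined Mean"]) == list(table.loc["Male Mean"])

    def test_missing_cycle_named(self):
        with pytest.raises(ValueError, match="CIE 6"):
            summarize_bal({"Male": BAL_MALE[:5], "Female": BAL_FEMALE})

    def test_missing_sex_row(self):
        with pytest.raises(ValueError, match="Female"):
            summarize_bal({"Male": BAL_MALE})


class TestCorrelateWithBehavior:
    def test_monotone_pair_exact_permutation_p(self):
        out = correlate_with_behavior([1, 2, 3, 4], [10, 20, 30, 40], method="spearman")
        assert out["coefficient"] == pytest.approx(1.0)
        assert out["p_value"] == pytest.approx(1 / 24)

    def test_anticorrelated_pair(self):
        out = correlate_with_behavior([1, 2, 3, 4], [8, 6, 4, 2], method="pearson")
        assert out["coefficient"] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        out = correlate_with_behavior([1, 1, 1, 1], [1, 2, 3, 4])
        assert out["defined"] is False and out["coefficient"] is None

    def test_permutation_p_matches_full_enumeration(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        out = correlate_with_behavior(x, y, method="pearson")
        obs = stats.pearsonr(x, y).statistic
        count = 0
        for perm in itertools.permutations(y):
            s = stats.pearsonr(x, np.array(perm)).statistic
            count += (s >= obs - 1e-12) if obs >= 0 else (s <= obs + 1e-12)
        assert out["p_value"] == pytest.approx(count / math.factorial(5))

    def test_planted_correlation_recovered_on_average(self):
        rng = np.random.default_rng(8)
        reps, estimates = 1000, []
        for _ in range(reps):
            x = rng.normal(size=4)
            y = 0.9 * x + math.sqrt(1 - 0.81) * rng.normal(size=4)
            estimates.append(correlate_with_behavior(x, y, method="pearson")["coefficient"])
        assert abs(np.mean(estimates) - 0.9) < 0.1

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            correlate_with_behavior([1, 2], [3, 4])
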