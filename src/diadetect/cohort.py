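"""Supporting cohort statistics.

Normality-gated comparison of per-run identification counts, PCA of
replicates on the complete-case log2 protein matrix, blood-alcohol-level
(BAL) table summarisation, and behaviour–protein correlations with exact
permutation p-values at very small n.
"""

from __future__ import annotations

import itertools
import math
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

BAL_CYCLES = ("CIE 1", "CIE 2", "CIE 3", "CIE 4", "CIE 5", "CIE 6")


def compare_id_counts(counts_a, counts_b) -> dict:
    """Shapiro–Wilk normality per group plus a pooled-variance t-test.

    The normality check is advisory (reported, not used to switch
    tests); the t-test is two-sided Student's t for equal variance.
    Degenerate input (zero variance in both groups with equal means)
    returns t = 0, p = 1 by convention.
    """
    a = np.asarray(list(counts_a), dtype=float)
    b = np.asarray(list(counts_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group for the t-test")
    out: dict = {"shapiro_w_per_group": [], "shapiro_p_per_group": []}
    for vals in (a, b):
        if len(vals) >= 3 and np.ptp(vals) > 0:
            w, p = stats.shapiro(vals)
        else:
            w, p = float("nan"), float("nan")
        out["shapiro_w_per_group"].append(float(w))
        out["shapiro_p_per_group"].append(float(p))
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = stats.ttest_ind(a, b, equal_var=True)
    out["t_statistic"] = float(t_stat)
    out["p_value"] = float(p_val)
    return out


def pca_replicates(quant: pd.DataFrame, n_components: int = 2, impute_half_min: bool = False) -> dict:
    """PCA of samples on the log2 protein matrix.

    By default only complete-case proteins (quantified in every sample)
    enter, so no values are fabricated; ``impute_half_min=True`` instead
    replaces missing values by half the protein's minimum observed
    abundance.  Columns (proteins) are mean-centred; scores come from an
    SVD of the samples × proteins matrix.

    Returns ``{"scores": DataFrame (samples × PCs), "variance_fractions": list}``.
    """
    if quant.shape[1] < 3:
        raise ValueError("need >= 3 samples for PCA")
    mat = quant.copy()
    if impute_half_min:
        fill = mat.min(axis=1) / 2.0
        mat = mat.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    else:
        mat = mat.dropna(axis=0, how="any")
    if mat.shape[0] < 3:
        raise ValueError(
            "fewer than 3 proteins are quantified in every sample; "
            "complete-case PCA is impossible (imputation is out of scope by default)"
        )
    x = np.log2(mat.to_numpy(dtype=float)).T  # samples × proteins
    n_components = min(n_components, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x - x.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return {
        "scores": pd.DataFrame(scores, index=mat.columns, columns=cols),
        "variance_fractions": [float(v) for v in pca.explained_variance_ratio_],
    }


def _round_half_away(value: Decimal, decimals: int = 1) -> Decimal:
    exp = Decimal(1).scaleb(-decimals)
    return value.quantize(exp, rounding=ROUND_HALF_UP)


def summarize_bal(per_sex_cycle_means: dict[str, list[float]]) -> pd.DataFrame:
    """Derive combined and overall blood-alcohol means from per-sex rows.

    Input maps ``"Male"``/``"Female"`` to six per-cycle mean BALs
    (mg/dL).  The combined per-cycle mean is the unweighted mean of the
    two sex means; each overall value is the mean of the six per-cycle
    values of its row.  All derived cells are rounded to one decimal,
    half away from zero, using exact decimal arithmetic (118.65 → 118.7).
    """
    for sex in ("Male", "Female"):
        if sex not in per_sex_cycle_means:
            raise ValueError(f"missing {sex} row")
        if len(per_sex_cycle_means[sex]) != len(BAL_CYCLES):
            got = len(per_sex_cycle_means[sex])
            missing = BAL_CYCLES[got] if got < len(BAL_CYCLES) else None
            raise ValueError(f"{sex} row has {got} cycles, expected {len(BAL_CYCLES)}"
                             + (f" (missing {missing})" if missing else ""))
    male = [Decimal(str(v)) for v in per_sex_cycle_means["Male"]]
    female = [Decimal(str(v)) for v in per_sex_cycle_means["Female"]]
    combined = [_round_half_away((m + f) / 2) for m, f in zip(male, female)]
    rows = {}
    for name, vals in (("Male Mean", male), ("Female Mean", female), ("Combined Mean", combined)):
        overall = _round_half_away(sum(vals) / len(vals))
        rows[name] = [float(v) for v in vals] + [float(overall)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(BAL_CYCLES) + ["Overall"])


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, statistic, observed: float) -> float:
    """One-sided exact permutation p in the direction of the observed statistic."""
    n = len(y)
    count = 0
    total = math.factorial(n)
    for perm in itertools.permutations(range(n)):
        s = statistic(x, y[list(perm)])
        if observed >= 0:
            count += s >= observed - 1e-12
        else:
            count += s <= observed + 1e-12
    return count / total


def correlate_with_behavior(
    protein_values, behavior_values, method: str = "spearman"
) -> dict:
    """Correlate per-animal protein log2 values with a behaviour metric.

    Pairwise-complete observations; ``method`` is ``"spearman"``
    (default; robust at n = 4) or ``"pearson"``.  The p-value is an
    exact one-sided permutation p (all n! orderings, in the direction of
    the observed coefficient) when n ≤ 8, otherwise the asymptotic
    p-value.  Zero variance in either vector yields an explicit
    undefined result rather than NaN propagation.
    """
    x = np.asarray(list(protein_values), dtype=float)
    y = np.asarray(list(behavior_values), dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 paired complete observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"coefficient": None, "n": n, "p_value": None, "defined": False}
    if method == "spearman":
        def statistic(a, b):
            return stats.spearmanr(a, b).statistic
    elif method == "pearson":
        def statistic(a, b):
            return stats.pearsonr(a, b).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    observed = float(statistic(x, y))
    if n <= 8:
        p = _exact_permutation_p(x, y, statistic, observed)
    else:
        res = stats.spearmanr(x, y) if method == "spearman" else stats.pearsonr(x, y)
        p = float(res.pvalue)
    return {"coefficient": observed, "n": n, "p_value": float(p), "defined": True}
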