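"""Detection matrices and rule-based evidence classification.

Presence/absence analysis of a two-group design (alcohol-dependent
``Dep`` vs non-dependent ``NonDep`` mice in the reference study): a
protein is "detected" in a run when it carries a quantified value after
filtering, and group-level detection patterns are classified into
evidence tiers:

* **Strong**  — detected in ≥75 % of Dep (3/4) with ≤1 NonDep, or
  ≥80 % of NonDep (4/5) with ≤1 Dep;
* **Moderate** — ≥50 % of Dep (2/4) with ≤1 NonDep, or ≥60 % of NonDep
  (3/5) with ≤1 Dep;
* **Weak** — detected in <50/60 % of the preferred group, or in ≥2
  animals of both groups;
* **None** — no preferred group can be assigned.

Fractional thresholds generalise to other group sizes as
``ceil(fraction * n)``, which reproduces the study's integer cut-offs at
n = 4/5.  The group-preference sets used for the headline counts use the
looser ≥2-in-group / ≤1-in-other rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from diadetect.diann_io import ReportError

DEP, NONDEP, NONE = "Dep", "NonDep", "None"
STRONG, MODERATE, WEAK = "Strong", "Moderate", "Weak"


@dataclass(frozen=True)
class RuleSet:
    """Thresholds for evidence tiers and group-preference sets.

    Minimum detection fractions are resolved against actual group sizes
    with a ceiling; the "other group" tolerance and the preference-set
    minimum are absolute counts, as in the reference rule
    (≥2 in one group, ≤1 in the other).
    """

    strong_min_frac_dep: float = 0.75
    strong_min_frac_nondep: float = 0.80
    moderate_min_frac_dep: float = 0.50
    moderate_min_frac_nondep: float = 0.60
    other_max_count: int = 1
    preferred_min_count: int = 2

    def __post_init__(self) -> None:
        if self.strong_min_frac_dep < self.moderate_min_frac_dep:
            raise ValueError("strong threshold below moderate threshold (Dep)")
        if self.strong_min_frac_nondep < self.moderate_min_frac_nondep:
            raise ValueError("strong threshold below moderate threshold (NonDep)")

    @staticmethod
    def resolve(frac: float, n: int) -> int:
        """Minimum count for a fractional threshold at group size n."""
        return math.ceil(frac * n)


def build_detection_matrix(quant: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Boolean protein × sample detection matrix from a quant matrix.

    A protein is detected in a sample iff its quantified value is
    present (non-NaN).  Columns are ordered as in the metadata.
    """
    for group in (DEP, NONDEP):
        if (meta["group"] == group).sum() == 0:
            raise ReportError(f"group {group!r} has no samples")
    unknown = set(quant.columns) - set(meta["run_id"])
    if unknown:
        raise ReportError(f"quant matrix column(s) without metadata: {sorted(unknown)}")
    return quant.reindex(columns=list(meta["run_id"])).notna()


def detection_summary(detected: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-protein detection counts in each group.

    Returns a DataFrame indexed by protein with columns
    ``k_dep, n_dep, k_nondep, n_nondep``.
    """
    dep_runs = meta.loc[meta["group"] == DEP, "run_id"]
    nondep_runs = meta.loc[meta["group"] == NONDEP, "run_id"]
    out = pd.DataFrame(index=detected.index)
    out["k_dep"] = detected[list(dep_runs)].sum(axis=1).astype(int)
    out["n_dep"] = len(dep_runs)
    out["k_nondep"] = detected[list(nondep_runs)].sum(axis=1).astype(int)
    out["n_nondep"] = len(nondep_runs)
    return out


def classify_protein(
    k_dep: int, n_dep: int, k_nondep: int, n_nondep: int, rules: RuleSet | None = None
) -> tuple[str, str]:
    """Classify one detection pattern into (preferred_group, evidence).

    Deterministic: Strong is checked before Moderate in each direction;
    a pattern meeting neither directional rule but detected in ≥2
    animals of some group is Weak toward the group with the higher
    detection fraction (≥2 in both groups demotes to Weak); otherwise
    (None, None).
    """
    rules = rules or RuleSet()
    if not (0 <= k_dep <= n_dep and 0 <= k_nondep <= n_nondep):
        raise ValueError("detection counts outside group sizes")
    strong_dep = rules.resolve(rules.strong_min_frac_dep, n_dep)
    strong_nondep = rules.resolve(rules.strong_min_frac_nondep, n_nondep)
    moderate_dep = rules.resolve(rules.moderate_min_frac_dep, n_dep)
    moderate_nondep = rules.resolve(rules.moderate_min_frac_nondep, n_nondep)
    other = rules.other_max_count

    if k_dep >= strong_dep and k_nondep <= other:
        return DEP, STRONG
    if k_nondep >= strong_nondep and k_dep <= other:
        return NONDEP, STRONG
    if k_dep >= moderate_dep and k_nondep <= other:
        return DEP, MODERATE
    if k_nondep >= moderate_nondep and k_dep <= other:
        return NONDEP, MODERATE

    frac_dep = k_dep / n_dep
    frac_nondep = k_nondep / n_nondep
    if max(k_dep, k_nondep) >= rules.preferred_min_count and frac_dep != frac_nondep:
        return (DEP, WEAK) if frac_dep > frac_nondep else (NONDEP, WEAK)
    return NONE, NONE


def classify_all(summary: pd.DataFrame, rules: RuleSet | None = None) -> pd.DataFrame:
    """Vector version of :func:`classify_protein` over a detection summary."""
    rules = rules or RuleSet()
    assigned = [
        classify_protein(row.k_dep, row.n_dep, row.k_nondep, row.n_nondep, rules)
        for row in summary.itertuples()
    ]
    out = summary.copy()
    out["preferred_group"] = [a[0] for a in assigned]
    out["evidence"] = [a[1] for a in assigned]
    return out


def preferred_sets(
    summary: pd.DataFrame,
    rules: RuleSet | None = None,
) -> dict[str, set[str]]:
    """Partition detected proteins into Dep-preferred / NonDep-preferred / shared.

    ``dep_preferred`` = detected in ≥ ``preferred_min_count`` Dep and
    ≤ ``other_max_count`` NonDep animals; symmetrically for
    ``nondep_preferred``.  The universe is every protein detected (per
    the ≥2-replicates rule) in at least one group; ``shared`` is the
    remainder of that universe, so the three sets partition it.
    """
    rules = rules or RuleSet()
    k1, k2 = summary["k_dep"], summary["k_nondep"]
    in_universe = (k1 >= rules.preferred_min_count) | (k2 >= rules.preferred_min_count)
    dep_pref = (k1 >= rules.preferred_min_count) & (k2 <= rules.other_max_count)
    nondep_pref = (k2 >= rules.preferred_min_count) & (k1 <= rules.other_max_count)
    return {
        "dep_preferred": set(summary.index[dep_pref]),
        "nondep_preferred": set(summary.index[nondep_pref]),
        "shared": set(summary.index[in_universe & ~dep_pref & ~nondep_pref]),
    }


def top_k_specific(summary: pd.DataFrame, rules: RuleSet | None = None, k: int = 10) -> list[str]:
    """Top-k strictly group-specific proteins.

    Candidates are detected in ≥ ``preferred_min_count`` replicates of
    one group and **zero** of the other; ranked by detection count in
    the preferred group (descending), ties broken lexicographically by
    protein id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rules = rules or RuleSet()
    cand = summary.loc[
        ((summary["k_dep"] >= rules.preferred_min_count) & (summary["k_nondep"] == 0))
        | ((summary["k_nondep"] >= rules.preferred_min_count) & (summary["k_dep"] == 0))
    ]
    k_pref = cand[["k_dep", "k_nondep"]].max(axis=1)
    order = sorted(cand.index, key=lambda p: (-int(k_pref[p]), str(p)))
    return order[:k]


def sensitivity_scan(
    summary: pd.DataFrame,
    grid: list[tuple[int, int]],
) -> pd.DataFrame:
    """Preference-set sizes across a (min_preferred, max_other) threshold grid."""
    if not grid:
        raise ValueError("threshold grid is empty")
    rows = []
    for min_pref, max_other in grid:
        rules = RuleSet(preferred_min_count=min_pref, other_max_count=max_other)
        sets = preferred_sets(summary, rules)
        rows.append(
            {
                "min_preferred_count": min_pref,
                "max_other_count": max_other,
                "n_dep_preferred": len(sets["dep_preferred"]),
                "n_nondep_preferred": len(sets["nondep_preferred"]),
            }
        )
    return pd.DataFrame(rows)
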