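"""Exact power and sample size for two-group binomial detection designs.

Small presence/absence studies compare detection *rates* between two
groups of n₁ and n₂ animals.  With n ≤ 50 per group the joint outcome
space (k₁, k₂) can be enumerated completely, so power is computed
exactly: the rejection region is the set of outcomes whose test
statistic passes, and power is the summed product of the two binomial
pmfs over that region.  Three decision rules are supported:

* ``fisher_one_sided`` — one-sided Fisher exact test (group 1 enriched),
  p ≤ α rejects;
* ``fisher_mid_p`` — mid-p variant (half weight on the observed table);
* ``rule_based`` — the deterministic classification rule
  (k₁ ≥ min_preferred AND k₂ ≤ max_other), whose power factorises over
  groups.

No asymptotic approximation is used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats

ENUMERATION_BOUND = 50

TESTS = ("fisher_one_sided", "fisher_mid_p", "rule_based")


@dataclass(frozen=True)
class PowerSpec:
    """A two-binomial detection design.

    n1/n2 are group sizes, p1/p2 the true per-animal detection
    probabilities, ``test`` the decision rule.  For ``rule_based`` the
    rule is (k1 ≥ rule_min_preferred AND k2 ≤ rule_max_other).
    """

    n1: int
    n2: int
    p1: float
    p2: float
    alpha: float = 0.05
    test: str = "fisher_one_sided"
    rule_min_preferred: int = 2
    rule_max_other: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.n1 <= ENUMERATION_BOUND and 1 <= self.n2 <= ENUMERATION_BOUND):
            raise ValueError(
                f"group sizes must be in [1, {ENUMERATION_BOUND}] for complete enumeration; "
                "approximate power is out of scope"
            )
        if not (0.0 <= self.p1 <= 1.0 and 0.0 <= self.p2 <= 1.0):
            raise ValueError("detection probabilities must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.test not in TESTS:
            raise ValueError(f"unknown test {self.test!r}; expected one of {TESTS}")


@dataclass(frozen=True)
class PowerResult:
    """Exact power with its rejection region and attained size."""

    power: float
    rejection_region: tuple[tuple[int, int], ...]
    attained_size: float
    spec: PowerSpec = field(repr=False)


def _hypergeom_tail(k1: int, n1: int, k2: int, n2: int, strict: bool) -> Fraction:
    """Exact P(X > k1) (strict) or P(X ≥ k1) at margins fixed to the table.

    X = group-1 successes under Hypergeom(population n1+n2, successes
    k1+k2, draws n1).  Rational arithmetic so boundary cases such as
    p = 1/20 at α = 0.05 are decided exactly, not by float rounding.
    """
    total = k1 + k2
    denom = comb(n1 + n2, total)
    start = k1 + 1 if strict else k1
    num = sum(comb(n1, j) * comb(n2, total - j) for j in range(start, min(n1, total) + 1))
    return Fraction(num, denom)


def fisher_p_one_sided(k1: int, n1: int, k2: int, n2: int) -> float:
    """One-sided Fisher exact p (direction: group 1 enriched).

    Hypergeometric tail probability, at margins fixed to the observed
    table, of tables with group-1 successes ≥ k1.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts outside group sizes")
    return float(_hypergeom_tail(k1, n1, k2, n2, strict=False))


def fisher_p_mid(k1: int, n1: int, k2: int, n2: int) -> float:
    """Mid-p one-sided Fisher: P(X > k1) + 0.5 P(X = k1) at fixed margins."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts outside group sizes")
    tail = _hypergeom_tail(k1, n1, k2, n2, strict=True)
    point = _hypergeom_tail(k1, n1, k2, n2, strict=False) - tail
    return float(tail + point / 2)


def _alpha_fraction(alpha: float) -> Fraction:
    """alpha as an exact rational (via its decimal string, so 0.05 -> 1/20)."""
    return Fraction(str(alpha))


def _rejection_region(spec: PowerSpec) -> list[tuple[int, int]]:
    alpha = _alpha_fraction(spec.alpha)
    region = []
    for k1 in range(spec.n1 + 1):
        for k2 in range(spec.n2 + 1):
            if spec.test == "fisher_one_sided":
                reject = _hypergeom_tail(k1, spec.n1, k2, spec.n2, strict=False) <= alpha
            elif spec.test == "fisher_mid_p":
                tail = _hypergeom_tail(k1, spec.n1, k2, spec.n2, strict=True)
                point = _hypergeom_tail(k1, spec.n1, k2, spec.n2, strict=False) - tail
                reject = tail + point / 2 <= alpha
            else:  # rule_based
                reject = k1 >= spec.rule_min_preferred and k2 <= spec.rule_max_other
            if reject:
                region.append((k1, k2))
    return region


def _region_probability(region: list[tuple[int, int]], n1: int, n2: int, p1: float, p2: float) -> float:
    if not region:
        return 0.0
    # binomial pmf in log space; guard the p∈{0,1} edges where log pmf is -inf/0
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pmf1 = stats.binom.logpmf(np.arange(n1 + 1), n1, p1)
        log_pmf2 = stats.binom.logpmf(np.arange(n2 + 1), n2, p2)
    total = 0.0
    for k1, k2 in region:
        log_p = log_pmf1[k1] + log_pmf2[k2]
        if np.isfinite(log_p):
            total += float(np.exp(log_p))
    return min(total, 1.0)


def exact_power(spec: PowerSpec, null_grid: np.ndarray | None = None) -> PowerResult:
    """Exact power of the design by complete enumeration.

    All (n1+1)×(n2+1) joint outcomes are enumerated; the rejection
    region collects outcomes where the chosen test rejects at
    ``spec.alpha``; power is the total probability of the region under
    Binomial(n1, p1) × Binomial(n2, p2).  The attained size is the
    maximum rejection probability over the null line p1 = p2 = p for p
    on a grid (default 0.05 … 0.95 in steps of 0.05).
    """
    region = _rejection_region(spec)
    power = _region_probability(region, spec.n1, spec.n2, spec.p1, spec.p2)
    if null_grid is None:
        null_grid = np.arange(0.05, 0.951, 0.05)
    size = max(
        (_region_probability(region, spec.n1, spec.n2, p, p) for p in null_grid),
        default=0.0,
    )
    return PowerResult(power=power, rejection_region=tuple(region), attained_size=size, spec=spec)


def rule_based_power_closed_form(spec: PowerSpec) -> float:
    """Rule-based power via the group factorisation.

    P(reject) = P(K1 ≥ min_preferred) · P(K2 ≤ max_other); used as an
    independent cross-check of the enumeration.
    """
    p_k1 = float(stats.binom.sf(spec.rule_min_preferred - 1, spec.n1, spec.p1))
    p_k2 = float(stats.binom.cdf(spec.rule_max_other, spec.n2, spec.p2))
    return p_k1 * p_k2


class PowerNotAchievableError(ValueError):
    """No group size within the enumeration bound reaches the target power."""


def sample_size_for_power(
    p1: float,
    p2: float,
    target_power: float,
    alpha: float = 0.05,
    test: str = "fisher_one_sided",
    rule_min_preferred: int = 2,
    rule_max_other: int = 1,
) -> int:
    """Smallest equal per-group n with exact power ≥ target.

    Scans n = 2 … 50 upward; exact-test power need not be monotone in
    n, so the scan (rather than bisection) guarantees the minimum.
    """
    if p1 == p2:
        raise ValueError("p1 must differ from p2")
    if not 0.0 <= target_power < 1.0:
        raise ValueError("target_power must be in [0, 1)")
    for n in range(2, ENUMERATION_BOUND + 1):
        spec = PowerSpec(
            n1=n, n2=n, p1=p1, p2=p2, alpha=alpha, test=test,
            rule_min_preferred=rule_min_preferred, rule_max_other=rule_max_other,
        )
        if exact_power(spec).power >= target_power:
            return n
    raise PowerNotAchievableError(
        f"no n ≤ {ENUMERATION_BOUND} per group reaches power {target_power} "
        f"for p1={p1}, p2={p2} ({test}, alpha={alpha})"
    )
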