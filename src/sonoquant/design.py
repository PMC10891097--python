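"""Exact single-arm binomial trial design and dosing arithmetic.

The phase-2 efficacy question is whether the proportion of successful
BBB-opening sessions exceeds a fixed objective performance criterion
(OPC).  With n subjects each contributing one success/failure, the design
rejects the OPC when the lower limit of the exact (Clopper-Pearson) 95%
confidence interval for the success proportion exceeds p0 -- equivalently,
when the observed success count reaches the smallest k whose upper-tail
probability under Binomial(n, p0) is at most the one-sided level.  Power
at a postulated true proportion p1 is the exact upper-tail probability of
that critical count under Binomial(n, p1); no normal approximation is
used anywhere.

The carboplatin dose calculation (Calvert formula: dose in mg = target
AUC x (GFR + 25)) is included because sonications are paired with
carboplatin cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BinomialDesign",
    "DesignEvaluation",
    "clopper_pearson",
    "exact_power",
    "success_proportion_evaluation",
    "carboplatin_dose",
]


@dataclass(frozen=True)
class BinomialDesign:
    """Single-arm exact binomial design against an OPC.

    Defaults follow the trial protocol: OPC p0 = 0.30, design true
    success proportion p1 = 0.70, one-sided alpha = 2.5%, n = 15.
    """

    n: int = 15
    p0: float = 0.30
    p1: float = 0.70
    alpha: float = 0.025

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 < self.p0 < self.p1 < 1:
            raise ValueError("require 0 < p0 < p1 < 1")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")


@dataclass(frozen=True)
class DesignEvaluation:
    """Critical success count, achieved size, and power of a design.

    ``critical_k`` is None when no rejection region exists (n too small),
    in which case power is 0.
    """

    critical_k: int | None
    exact_alpha: float
    power: float


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided Clopper-Pearson interval for a binomial proportion.

    Computed from Beta quantiles; the lower limit is 0 at k = 0 and the
    upper limit 1 at k = n.
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    a = (1.0 - level) / 2.0
    lower = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - a, k + 1, n - k))
    return lower, upper


def exact_power(design: BinomialDesign) -> DesignEvaluation:
    """Exact size and power of the CI-lower-bound rejection rule.

    The critical count is the smallest k whose Clopper-Pearson lower
    bound (at confidence 1 - 2*alpha) exceeds p0; by the Beta/binomial
    tail duality this coincides with the smallest k with
    P(X >= k | n, p0) <= alpha.  All tail probabilities are exact
    binomial sums.
    """
    n, p0, p1, alpha = design.n, design.p0, design.p1, design.alpha
    level = 1.0 - 2.0 * alpha
    critical_k: int | None = None
    for k in range(n + 1):
        if clopper_pearson(k, n, level=level)[0] > p0:
            critical_k = k
            break
    if critical_k is None:
        warnings.warn(
            f"design n={n} has no achievable rejection region", stacklevel=2
        )
        return DesignEvaluation(critical_k=None, exact_alpha=0.0, power=0.0)
    exact_alpha = float(stats.binom.sf(critical_k - 1, n, p0))
    power = float(stats.binom.sf(critical_k - 1, n, p1))
    return DesignEvaluation(critical_k=critical_k, exact_alpha=exact_alpha, power=power)


def success_proportion_evaluation(
    successes: np.ndarray, level: float = 0.95, opc: float = 0.30
) -> dict[str, float | bool]:
    """Observed success proportion with exact CI and effectiveness flag.

    Effectiveness is demonstrated when the exact lower confidence limit
    exceeds the OPC.
    """
    flags = np.asarray(successes, dtype=bool)
    if flags.size == 0:
        raise ValueError("need at least one observation")
    k, n = int(flags.sum()), int(flags.size)
    lower, upper = clopper_pearson(k, n, level=level)
    return {
        "n": n,
        "successes": k,
        "proportion": k / n,
        "ci_lower": lower,
        "ci_upper": upper,
        "effective": bool(lower > opc),
    }


def carboplatin_dose(target_auc: float, gfr: float) -> float:
    """Carboplatin dose (mg) by the Calvert formula: AUC x (GFR + 25).

    ``target_auc`` is in mg*min/mL, ``gfr`` in mL/min.  Targets outside
    the protocol's 4-6 range are allowed with a warning.
    """
    if target_auc <= 0 or gfr <= 0:
        raise ValueError("target AUC and GFR must be positive")
    if not 4.0 <= target_auc <= 6.0:
        warnings.warn(
            f"target AUC {target_auc} outside the protocol range 4-6", stacklevel=2
        )
    return float(target_auc * (gfr + 25.0))
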