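"""Shared result container for the five treatment-effect estimators."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

from scipy import stats

#: Canonical method names, in the order they are reported.
METHODS = ("unadjusted", "random_intercept", "mantel_haenszel", "gee", "gee_fg")

#: Methods whose estimate targets the within-center (conditional) odds ratio.
CONDITIONAL_METHODS = frozenset({"random_intercept", "mantel_haenszel"})


def estimand_for(method: str) -> str:
    """Return ``"conditional"`` or ``"marginal"`` for a method name."""
    return "conditional" if method in CONDITIONAL_METHODS else "marginal"


@dataclass
class FitResult:
    """One method's treatment-effect estimate for one trial dataset.

    The estimate and its 95% confidence limits are on the log odds ratio
    scale; ``odds_ratio`` exponentiates. ``converged`` reflects only the
    fitter's own status — the additional magnitude-based failure rule is
    applied by :func:`rarecenter.evaluate.classify_convergence`.
    """

    method: str
    log_or: float
    se: float
    p_value: float
    ci_low: float
    ci_high: float
    converged: bool
    estimand: str
    n_analyzed: int
    extras: dict[str, Any] = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)

    def to_row(self) -> dict[str, Any]:
        """Flatten to a dict suitable for one CSV row."""
        row = {
            "method": self.method,
            "log_or": self.log_or,
            "se": self.se,
            "p_value": self.p_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "converged": self.converged,
            "estimand": self.estimand,
            "n_analyzed": self.n_analyzed,
        }
        row.update({f"extra_{k}": v for k, v in self.extras.items()})
        return row


def wald_result(
    method: str,
    log_or: float,
    se: float,
    n_analyzed: int,
    converged: bool = True,
    df: float | None = None,
    extras: dict[str, Any] | None = None,
) -> FitResult:
    """Build a FitResult with a two-sided Wald test and matching 95% CI.

    With ``df=None`` the reference distribution is standard normal (z);
    otherwise a t distribution with ``df`` degrees of freedom, so that the
    test and the interval always reject/exclude together.
    """
    if not (math.isfinite(log_or) and math.isfinite(se) and se > 0):
        return FitResult(
            method, log_or, se, math.nan, math.nan, math.nan,
            False, estimand_for(method), n_analyzed, extras or {},
        )
    z = log_or / se
    if df is None:
        p = 2.0 * stats.norm.sf(abs(z))
        crit = stats.norm.ppf(0.975)
    else:
        p = 2.0 * stats.t.sf(abs(z), df)
        crit = stats.t.ppf(0.975, df)
    return FitResult(
        method, log_or, se, p, log_or - crit * se, log_or + crit * se,
        converged, estimand_for(method), n_analyzed, extras or {},
    )


def failed_fit(method: str, n_analyzed: int = 0,
               extras: dict[str, Any] | None = None) -> FitResult:
    """A placeholder result for a fit that could not be completed."""
    nan = math.nan
    return FitResult(method, nan, nan, nan, nan, nan, False,
                     estimand_for(method), n_analyzed, extras or {})
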