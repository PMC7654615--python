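"""Per-scenario performance measures with Monte Carlo standard errors, and
the convergence classification applied to every fit.

A fit counts as a convergence failure when the fitter itself reported one,
or when the estimated odds ratio or its standard error exceeds 1000 — a
magnitude rule that catches estimates drifting to the boundary under
separation. Performance measures (rejection rate, mean OR, CI coverage) are
computed over converged fits only, alongside the convergence rate itself;
each measure carries a Monte Carlo SE (binomial form for proportions,
delta-method on the log scale for the mean OR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .results import CONDITIONAL_METHODS, FitResult

__all__ = ["classify_convergence", "summarize", "PerformanceSummary"]

#: Magnitude bound above which an OR or SE marks a convergence failure.
DIVERGENCE_BOUND = 1000.0


def classify_convergence(fit: FitResult,
                         bound: float = DIVERGENCE_BOUND) -> bool:
    """True when the fit converged and stayed within the magnitude bound."""
    if not fit.converged:
        return False
    if not (math.isfinite(fit.log_or) and math.isfinite(fit.se)):
        return False
    return math.exp(fit.log_or) <= bound and fit.se <= bound


@dataclass
class PerformanceSummary:
    """One scenario x method cell of a simulation-study results table."""

    scenario: str
    method: str
    n_generated: int
    n_prescreen_excluded: int
    n_converged: int
    rejection_rate: float
    mean_or: float
    coverage: float
    convergence_rate: float          # percentage of analyzable replicates
    mcse_rejection: float
    mcse_mean: float
    mcse_coverage: float
    truth_used: float
    extras: dict = field(default_factory=dict)

    @property
    def n_analyzable(self) -> int:
        return self.n_generated - self.n_prescreen_excluded

    def to_row(self) -> dict:
        return {
            "scenario": self.scenario,
            "method": self.method,
            "n_generated": self.n_generated,
            "n_prescreen_excluded": self.n_prescreen_excluded,
            "n_converged": self.n_converged,
            "rejection_rate": self.rejection_rate,
            "mean_or": self.mean_or,
            "coverage": self.coverage,
            "convergence_rate": self.convergence_rate,
            "mcse_rejection": self.mcse_rejection,
            "mcse_mean": self.mcse_mean,
            "mcse_coverage": self.mcse_coverage,
            "truth_used": self.truth_used,
        }


def _proportion_mcse(p: float, m: int) -> float:
    return math.sqrt(p * (1 - p) / m) if m > 0 else math.nan


def summarize(
    fits: Iterable[FitResult],
    truth_conditional: float,
    truth_marginal: float,
    n_generated: int | None = None,
    n_prescreen_excluded: int = 0,
    scenario: str = "",
    alpha_level: float = 0.05,
    min_converged: int = 50,
) -> PerformanceSummary:
    """Aggregate one method's fits from one scenario into summary measures.

    ``truth_conditional``/``truth_marginal`` are the true odds ratios on the
    two estimand scales; coverage scores each fit's CI against the scale its
    method targets (conditional for the random-intercept and Mantel–Haenszel
    estimators, marginal otherwise). Rejection is ``p < alpha_level`` among
    converged fits, and the mean OR exponentiates the mean log OR. When
    fewer than ``min_converged`` fits survive, the estimate-based measures
    are reported as NaN — a handful of surviving fits says more about the
    failure mechanism than about the estimator.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("summarize needs at least one fit")
    method = fits[0].method
    if any(f.method != method for f in fits):
        raise ValueError("all fits must come from the same method")
    if n_generated is None:
        n_generated = len(fits) + n_prescreen_excluded
    n_analyzable = n_generated - n_prescreen_excluded

    truth = (truth_conditional if method in CONDITIONAL_METHODS
             else truth_marginal)
    log_truth = math.log(truth)

    converged = [f for f in fits if classify_convergence(f)]
    m = len(converged)
    convergence_rate = 100.0 * m / n_analyzable if n_analyzable else math.nan

    if m >= max(min_converged, 1):
        p_rej = float(np.mean(
            [f.p_value < alpha_level for f in converged]))
        p_cov = float(np.mean(
            [f.ci_low <= log_truth <= f.ci_high for f in converged]))
        log_ors = np.array([f.log_or for f in converged])
        mean_log = float(log_ors.mean())
        mean_or = math.exp(mean_log)
        sd_log = float(log_ors.std(ddof=1)) if m > 1 else math.nan
        mcse_mean = mean_or * sd_log / math.sqrt(m) if m > 1 else math.nan
        mcse_rej = _proportion_mcse(p_rej, m)
        mcse_cov = _proportion_mcse(p_cov, m)
    else:
        p_rej = p_cov = mean_or = math.nan
        mcse_rej = mcse_cov = mcse_mean = math.nan

    return PerformanceSummary(
        scenario=scenario, method=method,
        n_generated=n_generated,
        n_prescreen_excluded=n_prescreen_excluded,
        n_converged=m,
        rejection_rate=p_rej, mean_or=mean_or, coverage=p_cov,
        convergence_rate=convergence_rate,
        mcse_rejection=mcse_rej, mcse_mean=mcse_mean,
        mcse_coverage=mcse_cov, truth_used=truth)


def summaries_to_frame(summaries: Iterable[PerformanceSummary]) -> pd.DataFrame:
    """Stack summaries into the table layout used by the CLI outputs."""
    return pd.DataFrame([s.to_row() for s in summaries])
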