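"""Mantel–Haenszel common odds ratio across center strata.

The estimator pools per-center 2x2 tables,

    OR_MH = sum_j (a_j d_j / n_j) / sum_j (b_j c_j / n_j),

where ``a_j``/``b_j`` count treated subjects with/without an event and
``c_j``/``d_j`` the controls. Strata with ``a_j d_j = b_j c_j = 0`` (no
events, or a single arm represented) contribute nothing to either sum:
those subjects are effectively excluded from the analysis, which is the
estimator's Achilles heel with rare events. The log-OR standard error is
the Robins–Breslow–Greenland estimator, and the p-value comes from the
Mantel–Haenszel chi-square test (continuity-corrected by default, matching
standard software).

Following the behavior of the standard stratified-test routine, the fit is
flagged non-converged when any stratum has fewer than two subjects or when
either pooled sum is zero (common odds ratio undefined); with many tiny
centers this rule, not the estimator itself, dominates the failure rate.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .results import FitResult, failed_fit
from .simulate import TrialData

__all__ = ["tabulate_strata", "mh_common_or"]


def tabulate_strata(data: TrialData) -> pd.DataFrame:
    """Per-center 2x2 counts, one row per center ordered by center id.

    Columns: ``a`` treated with event, ``b`` treated without, ``c`` control
    with event, ``d`` control without, ``n`` stratum total.
    """
    if data.n_subjects == 0:
        raise ValueError("cannot tabulate an empty trial")
    centers, idx = np.unique(data.center_id, return_inverse=True)
    J = centers.size
    a = np.bincount(idx, weights=data.arm * data.outcome, minlength=J)
    b = np.bincount(idx, weights=data.arm * (1 - data.outcome), minlength=J)
    c = np.bincount(idx, weights=(1 - data.arm) * data.outcome, minlength=J)
    d = np.bincount(idx, weights=(1 - data.arm) * (1 - data.outcome),
                    minlength=J)
    table = pd.DataFrame(
        {"a": a, "b": b, "c": c, "d": d, "n": a + b + c + d},
        index=pd.Index(centers, name="center_id"),
    ).astype(np.int64)
    return table


def mh_common_or(strata: pd.DataFrame, continuity: bool = True,
                 min_stratum_size: int = 2) -> FitResult:
    """Mantel–Haenszel common OR with RBG interval and MH chi-square test.

    Parameters
    ----------
    strata : output of :func:`tabulate_strata`.
    continuity : apply the 0.5 continuity correction to the chi-square
        statistic (the default of standard software).
    min_stratum_size : strata smaller than this mark the fit non-converged,
        mirroring the stratum-size requirement of the standard routine; set
        to 0 to disable.

    No continuity constant is added to cells for estimation — the MH
    estimator tolerates zero cells natively, and adding one would bias the
    pooled OR. ``n_analyzed`` counts subjects in informative strata only.
    """
    if len(strata) == 0:
        raise ValueError("need at least one stratum")
    a = strata["a"].to_numpy(float)
    b = strata["b"].to_numpy(float)
    c = strata["c"].to_numpy(float)
    d = strata["d"].to_numpy(float)
    n = strata["n"].to_numpy(float)

    informative = (a * d > 0) | (b * c > 0)
    n_informative = int(n[informative].sum())
    extras = {
        "n_strata": int(len(strata)),
        "n_informative_strata": int(informative.sum()),
    }

    R = float(np.sum(a * d / n))
    S = float(np.sum(b * c / n))
    size_ok = (min_stratum_size <= 1
               or bool((n >= min_stratum_size).all()))

    if R <= 0 or S <= 0:
        return failed_fit("mantel_haenszel", n_informative, extras)
    log_or = math.log(R / S)

    # Robins–Breslow–Greenland variance of log OR_MH
    P = (a + d) / n
    Q = (b + c) / n
    var = (float(np.sum(P * a * d / n)) / (2 * R * R)
           + float(np.sum(P * b * c / n + Q * a * d / n)) / (2 * R * S)
           + float(np.sum(Q * b * c / n)) / (2 * S * S))
    se = math.sqrt(var) if var > 0 else math.nan

    # Mantel–Haenszel chi-square test of common OR = 1
    usable = n >= 2
    t = float(a[usable].sum())
    expected = float(np.sum((a + b)[usable] * (a + c)[usable] / n[usable]))
    hyper_var = float(np.sum(
        (a + b)[usable] * (c + d)[usable] * (a + c)[usable]
        * (b + d)[usable] / (n[usable] ** 2 * (n[usable] - 1.0))))
    if hyper_var > 0:
        dev = abs(t - expected) - (0.5 if continuity else 0.0)
        chi2 = max(dev, 0.0) ** 2 / hyper_var
        p_value = float(stats.chi2.sf(chi2, df=1))
        extras["chi2"] = chi2
    else:
        p_value = math.nan

    converged = size_ok and math.isfinite(se) and math.isfinite(p_value)
    crit = stats.norm.ppf(0.975)
    ci_low = log_or - crit * se if math.isfinite(se) else math.nan
    ci_high = log_or + crit * se if math.isfinite(se) else math.nan
    return FitResult("mantel_haenszel", log_or, se, p_value, ci_low, ci_high,
                     converged, "conditional", n_informative, extras)
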