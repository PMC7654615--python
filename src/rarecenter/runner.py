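"""Scenario-grid orchestration and the applied-analysis entry point.

``run_scenario`` generates replicate trials from one design cell, applies
prescreening, fits the requested methods (sharing one GEE solve between the
uncorrected and Fay–Graubard results), classifies convergence, and
summarizes. ``run_grid`` iterates a cartesian design grid with
deterministic per-scenario seeding, and ``analyze_dataset`` applies the
same estimators to a user-supplied subject-level trial table, pairwise
against a named reference arm when more than two arms are present.

Replicate seeds are pre-spawned from the scenario seed, so results are
identical whatever the worker count or execution order.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibrate import conditional_to_marginal
from .evaluate import PerformanceSummary, classify_convergence, summarize
from .gee import fay_graubard_correct, fit_gee_exchangeable
from .likelihood import fit_random_intercept, fit_unadjusted
from .mantel_haenszel import mh_common_or, tabulate_strata
from .results import METHODS, FitResult, failed_fit
from .simulate import ScenarioConfig, TrialData, generate_trial, prescreen_trial

__all__ = ["GridSpec", "ScenarioResult", "fit_methods", "run_scenario",
           "run_grid", "analyze_dataset"]

logger = logging.getLogger("rarecenter")


def fit_methods(data: TrialData,
                methods: Sequence[str] = METHODS) -> dict[str, FitResult]:
    """Fit each requested method to one trial, never raising.

    Exceptions from individual fitters are logged at DEBUG and recorded as
    non-converged results. A GEE solve is shared between ``gee`` and
    ``gee_fg`` when both are requested.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s) {sorted(unknown)}; "
                         f"choose from {METHODS}")
    results: dict[str, FitResult] = {}
    need_gee = "gee" in methods or "gee_fg" in methods
    if need_gee:
        try:
            gee_result, gee_state = fit_gee_exchangeable(
                data, return_state=True)
        except Exception as exc:  # noqa: BLE001 - any fitter failure
            logger.debug("gee fit failed: %s", exc)
            gee_result, gee_state = failed_fit("gee", data.n_subjects), None
        if "gee" in methods:
            results["gee"] = gee_result
        if "gee_fg" in methods:
            try:
                results["gee_fg"] = fay_graubard_correct(gee_state)
            except Exception as exc:  # noqa: BLE001
                logger.debug("gee_fg correction failed: %s", exc)
                results["gee_fg"] = failed_fit("gee_fg", data.n_subjects)
    simple = {
        "unadjusted": fit_unadjusted,
        "random_intercept": fit_random_intercept,
        "mantel_haenszel": lambda d: mh_common_or(tabulate_strata(d)),
    }
    for name, fitter in simple.items():
        if name in methods:
            try:
                results[name] = fitter(data)
            except Exception as exc:  # noqa: BLE001
                logger.debug("%s fit failed: %s", name, exc)
                results[name] = failed_fit(name, data.n_subjects)
    return {m: results[m] for m in methods}


@dataclass
class ScenarioResult:
    """Replicate-level records plus per-method summaries for one scenario."""

    scenario: str
    config: ScenarioConfig
    summaries: dict[str, PerformanceSummary]
    long: pd.DataFrame
    n_generated: int
    n_prescreen_excluded: int
    exclusion_counts: dict[str, int]


def _replicate_task(config, child_seed, methods):
    rng = np.random.default_rng(child_seed)
    trial = generate_trial(config, rng)
    status = prescreen_trial(trial)
    if status != "retain":
        return status, None
    return status, fit_methods(trial, methods)


def scenario_label(config: ScenarioConfig) -> str:
    return (f"n{config.n_total}_J{config.n_centers_target}"
            f"_icc{config.icc}_p{config.p0}"
            f"_or{config.true_conditional_or}_{config.size_distribution}")


def run_scenario(
    config: ScenarioConfig,
    replicates: int,
    seed: int | np.random.SeedSequence,
    methods: Sequence[str] = METHODS,
    n_jobs: int = 1,
    min_converged: int = 50,
) -> ScenarioResult:
    """Simulate and analyze one scenario.

    ``seed`` feeds a SeedSequence from which one child stream per replicate
    is spawned up front, making the run reproducible and independent of
    ``n_jobs``. Prescreen-excluded replicates are dropped (not replaced);
    both the generated and analyzable counts appear in the summaries.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(replicates)
    if n_jobs != 1:
        from joblib import Parallel, delayed

        outcomes = Parallel(n_jobs=n_jobs)(
            delayed(_replicate_task)(config, child, methods)
            for child in children)
    else:
        outcomes = [_replicate_task(config, child, methods)
                    for child in children]

    label = scenario_label(config)
    exclusion_counts = {"exclude_no_events": 0, "exclude_one_arm_only": 0}
    rows = []
    fits_by_method: dict[str, list[FitResult]] = {m: [] for m in methods}
    for rep, (status, fits) in enumerate(outcomes):
        if status != "retain":
            exclusion_counts[status] += 1
            continue
        for m in methods:
            fit = fits[m]
            fits_by_method[m].append(fit)
            row = {"scenario": label, "replicate": rep}
            row.update(fit.to_row())
            row["converged"] = classify_convergence(fit)
            rows.append(row)

    n_excluded = sum(exclusion_counts.values())
    sigma2 = config.sigma2
    truth_cond = config.true_conditional_or
    truth_marg = math.exp(
        conditional_to_marginal(math.log(truth_cond), sigma2))
    summaries = {
        m: summarize(
            fits_by_method[m], truth_cond, truth_marg,
            n_generated=replicates, n_prescreen_excluded=n_excluded,
            scenario=label, min_converged=min_converged)
        for m in methods if fits_by_method[m]
    }
    logger.info(
        "%s: %d generated, %d prescreen-excluded; convergence %s",
        label, replicates, n_excluded,
        {m: f"{s.convergence_rate:.1f}%" for m, s in summaries.items()})
    long = pd.DataFrame(rows)
    return ScenarioResult(label, config, summaries, long,
                          replicates, n_excluded, exclusion_counts)


@dataclass
class GridSpec:
    """A cartesian scenario grid plus execution settings."""

    n_total: Sequence[int] = (200, 500, 1000, 5000)
    n_centers: Sequence[int] = (5, 50, 100)
    icc: Sequence[float] = (0.025, 0.075)
    p0: Sequence[float] = (0.02, 0.05, 0.10)
    size_distribution: Sequence[str] = ("balanced", "skewed")
    true_or: Sequence[float] = (1.0,)
    replicates: int = 5000
    seed: int = 0
    methods: Sequence[str] = METHODS
    n_jobs: int = 1
    min_converged: int = 50

    def configs(self) -> list[ScenarioConfig]:
        return [
            ScenarioConfig(n_total=n, n_centers_target=j, icc=icc, p0=p0,
                           true_conditional_or=or_, size_distribution=dist)
            for n, j, icc, p0, dist, or_ in itertools.product(
                self.n_total, self.n_centers, self.icc, self.p0,
                self.size_distribution, self.true_or)
        ]

    @classmethod
    def from_file(cls, path: str | Path) -> "GridSpec":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def run_grid(spec: GridSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every scenario in the grid.

    Returns ``(long, summary)`` data frames: one row per replicate x method,
    and one row per scenario x method mirroring the usual simulation-study
    table columns.
    """
    configs = spec.configs()
    scenario_seeds = np.random.SeedSequence(spec.seed).spawn(len(configs))
    longs, summary_rows = [], []
    for config, sseed in zip(configs, scenario_seeds):
        result = run_scenario(
            config, spec.replicates, sseed, spec.methods,
            n_jobs=spec.n_jobs, min_converged=spec.min_converged)
        longs.append(result.long)
        for s in result.summaries.values():
            summary_rows.append(s.to_row())
    long = pd.concat(longs, ignore_index=True) if longs else pd.DataFrame()
    return long, pd.DataFrame(summary_rows)


def analyze_dataset(
    source: str | Path | pd.DataFrame,
    methods: Sequence[str] = METHODS,
    reference_arm=None,
) -> pd.DataFrame:
    """Apply the estimator suite to a subject-level trial table.

    The table needs columns ``center_id``, ``arm`` and ``outcome``
    (delimited text or a data frame). With a 0/1-coded two-arm table the
    reference defaults to arm 0; with named or multiple arms,
    ``reference_arm`` selects the comparator and each other arm is analyzed
    pairwise against it. The returned frame has one row per comparison x
    method, including the analyzed-subject count (which exposes the
    Mantel–Haenszel exclusions).
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source)
    else:
        df = source.copy()
    missing = [c for c in ("center_id", "arm", "outcome")
               if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing}; "
                         f"found {list(df.columns)}")
    bad = ~df["outcome"].isin([0, 1])
    if bad.any():
        idx = int(df.index[bad][0])
        raise ValueError(
            f"outcome must be coded 0/1; row {idx} has "
            f"value {df.loc[idx, 'outcome']!r}")
    arms = sorted(df["arm"].unique().tolist(), key=str)
    if len(arms) < 2:
        raise ValueError("need at least two arms")
    if reference_arm is None:
        if set(arms) == {0, 1}:
            reference_arm = 0
        else:
            raise ValueError(
                f"reference_arm is required for arms {arms}")
    if reference_arm not in arms:
        raise ValueError(
            f"reference arm {reference_arm!r} not present; arms are {arms}")
    rows = []
    for arm in arms:
        if arm == reference_arm:
            continue
        sub = df[df["arm"].isin([reference_arm, arm])]
        trial = TrialData(
            sub["center_id"].to_numpy(),
            (sub["arm"] == arm).astype(int).to_numpy(),
            sub["outcome"].to_numpy())
        for m, fit in fit_methods(trial, methods).items():
            row = {"comparison": f"{arm} vs {reference_arm}",
                   "n_total": trial.n_subjects}
            row.update(fit.to_row())
            row["converged"] = classify_convergence(fit)
            row["odds_ratio"] = (math.exp(fit.log_or)
                                 if math.isfinite(fit.log_or) else math.nan)
            rows.append(row)
    return pd.DataFrame(rows)
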