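"""Trial simulator: latent-variable outcome model with stratified permuted-block
randomization across centers.

The data-generating mechanism is a threshold model on the logit scale,

    Y*_ij = alpha + beta_trt * X_ij + u_j + eps_ij,      Y_ij = 1{Y*_ij > 0},

where ``u_j ~ N(0, sigma^2)`` is a center effect and ``eps_ij`` is standard
logistic noise (variance pi^2/3). The intra-class correlation on the latent
scale is therefore ``ICC = sigma^2 / (sigma^2 + pi^2/3)``. Treatment is
allocated 1:1 within each center via permuted blocks, and center sizes are
either equal (balanced) or one multinomial draw over equal-probability cells
(skewed); multinomial cells drawn as zero disappear, so a skewed trial may
realize fewer centers than targeted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "LOGISTIC_VARIANCE",
    "ScenarioConfig",
    "TrialData",
    "icc_to_sigma2",
    "sigma2_to_icc",
    "calibrate_intercept",
    "assign_center_sizes",
    "permuted_block_randomize",
    "generate_trial",
    "prescreen_trial",
]

#: Variance of the standard logistic distribution, pi^2 / 3.
LOGISTIC_VARIANCE = math.pi**2 / 3

_COLUMNS = ("center_id", "arm", "outcome")


def icc_to_sigma2(icc: float) -> float:
    """Between-center variance on the logit scale implied by an ICC.

    Inverts ``ICC = sigma^2 / (sigma^2 + pi^2/3)``:
    ``sigma^2 = icc / (1 - icc) * pi^2 / 3``.
    """
    if not 0.0 <= icc < 1.0:
        raise ValueError(f"icc must lie in [0, 1), got {icc!r}")
    return icc / (1.0 - icc) * LOGISTIC_VARIANCE


def sigma2_to_icc(sigma2: float) -> float:
    """Latent-scale ICC implied by a between-center variance."""
    if sigma2 < 0:
        raise ValueError(f"sigma2 must be nonnegative, got {sigma2!r}")
    return sigma2 / (sigma2 + LOGISTIC_VARIANCE)


def calibrate_intercept(p0: float, sigma2: float,
                        mode: str = "conditional") -> float:
    """Intercept alpha such that the control arm hits event probability p0.

    ``conditional`` (default) sets ``alpha = logit(p0)``, i.e. p0 holds at the
    median center (u = 0). ``marginal`` solves
    ``E_u[expit(alpha + u)] = p0`` by 1-D root finding, the expectation taken
    by Gauss–Hermite quadrature over u ~ N(0, sigma2).
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0!r}")
    if mode == "conditional" or sigma2 == 0.0:
        return float(logit(p0))
    if mode != "marginal":
        raise ValueError(f"unknown calibration mode {mode!r}")
    nodes, weights = np.polynomial.hermite.hermgauss(40)
    sd = math.sqrt(sigma2)

    def marginal_minus_target(alpha: float) -> float:
        vals = expit(alpha + math.sqrt(2.0) * sd * nodes)
        return float(weights @ vals) / math.sqrt(math.pi) - p0

    lo, hi = logit(p0) - 6 * sd - 1, logit(p0) + 6 * sd + 1
    return float(brentq(marginal_minus_target, lo, hi, xtol=1e-12))


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation design grid.

    Parameters
    ----------
    n_total : total number of randomized participants.
    n_centers_target : number of centers the design aims for; skewed size
        draws may realize fewer.
    icc : latent-scale intra-class correlation in [0, 1).
    p0 : control-arm event probability in (0, 1).
    true_conditional_or : conditional (within-center) odds ratio for
        treatment; 1.0 gives a null scenario.
    size_distribution : ``"balanced"`` or ``"skewed"``.
    block_size : permuted block length (even; default 4 for 1:1 allocation).
    calibration : whether ``p0`` is the conditional (median-center) or the
        marginal control-arm event probability.
    seed : optional root seed recorded alongside the scenario.
    """

    n_total: int
    n_centers_target: int
    icc: float
    p0: float
    true_conditional_or: float = 1.0
    size_distribution: str = "balanced"
    block_size: int = 4
    calibration: str = "conditional"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_total < 1 or self.n_centers_target < 1:
            raise ValueError("n_total and n_centers_target must be >= 1")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError(f"icc must lie in [0, 1), got {self.icc!r}")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError(f"p0 must lie in (0, 1), got {self.p0!r}")
        if self.true_conditional_or <= 0:
            raise ValueError("true_conditional_or must be positive")
        if self.size_distribution not in ("balanced", "skewed"):
            raise ValueError(
                f"size_distribution must be 'balanced' or 'skewed', "
                f"got {self.size_distribution!r}")
        if self.block_size % 2 != 0 or self.block_size < 2:
            raise ValueError("block_size must be a positive even integer")

    @property
    def sigma2(self) -> float:
        return icc_to_sigma2(self.icc)

    @property
    def beta_trt(self) -> float:
        return math.log(self.true_conditional_or)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_file(self, path: str | Path) -> None:
        """Write as a flat ``key: value`` YAML mapping."""
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class TrialData:
    """Subject-level data for one (simulated or real) two-arm trial."""

    center_id: np.ndarray
    arm: np.ndarray
    outcome: np.ndarray

    def __post_init__(self) -> None:
        self.center_id = np.asarray(self.center_id, dtype=np.int64)
        self.arm = np.asarray(self.arm, dtype=np.int64)
        self.outcome = np.asarray(self.outcome, dtype=np.int64)
        n = self.center_id.shape[0]
        if self.arm.shape[0] != n or self.outcome.shape[0] != n:
            raise ValueError("center_id, arm and outcome must share a length")
        for name, arr in (("arm", self.arm), ("outcome", self.outcome)):
            bad = ~np.isin(arr, (0, 1))
            if bad.any():
                idx = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"{name} must be coded 0/1; first offending row "
                    f"{idx} has value {arr[idx]!r}")

    @property
    def n_subjects(self) -> int:
        return int(self.center_id.shape[0])

    @property
    def n_centers(self) -> int:
        """Realized number of (non-empty) centers."""
        return int(np.unique(self.center_id).size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "center_id": self.center_id,
            "arm": self.arm,
            "outcome": self.outcome,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialData":
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(
                f"missing required column(s) {missing}; "
                f"found {list(df.columns)}")
        return cls(df["center_id"].to_numpy(), df["arm"].to_numpy(),
                   df["outcome"].to_numpy())

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialData":
        return cls.from_frame(pd.read_csv(path))


def assign_center_sizes(n_total: int, n_centers_target: int, mode: str,
                        rng: np.random.Generator) -> np.ndarray:
    """Per-center enrollment counts summing to ``n_total``.

    Balanced mode splits as evenly as possible, assigning the remainder one
    subject each to the lowest-indexed centers. Skewed mode takes a single
    multinomial draw with equal cell probabilities 1/J and drops empty cells,
    so the returned length — the realized center count — may be below the
    target.
    """
    if n_total < 1 or n_centers_target < 1:
        raise ValueError("n_total and n_centers_target must be >= 1")
    if mode == "balanced":
        base, rem = divmod(n_total, n_centers_target)
        sizes = np.full(n_centers_target, base, dtype=np.int64)
        sizes[:rem] += 1
        return sizes[sizes > 0]
    if mode == "skewed":
        probs = np.full(n_centers_target, 1.0 / n_centers_target)
        sizes = rng.multinomial(n_total, probs)
        return sizes[sizes > 0].astype(np.int64)
    raise ValueError(f"mode must be 'balanced' or 'skewed', got {mode!r}")


def permuted_block_randomize(center_sizes: np.ndarray, block_size: int,
                             rng: np.random.Generator) -> np.ndarray:
    """1:1 treatment assignments, permuted blocks stratified by center.

    Within each center the assignment sequence is a concatenation of
    independently permuted blocks containing ``block_size/2`` of each arm; a
    final incomplete block is a fresh permuted block truncated to the
    remaining count. Returns one concatenated 0/1 array in enrollment order,
    centers in the order given.
    """
    if block_size % 2 != 0 or block_size < 2:
        raise ValueError("block_size must be a positive even integer")
    sizes = np.asarray(center_sizes, dtype=np.int64)
    half = block_size // 2
    blocks_per_center = -(-sizes // block_size)  # ceil division
    total_blocks = int(blocks_per_center.sum())
    base = np.concatenate([np.zeros(half, np.int64), np.ones(half, np.int64)])
    all_blocks = rng.permuted(
        np.tile(base, (total_blocks, 1)), axis=1)
    out = np.empty(int(sizes.sum()), dtype=np.int64)
    pos = 0
    blk = 0
    for size, nblk in zip(sizes, blocks_per_center):
        seq = all_blocks[blk:blk + nblk].ravel()[:size]
        out[pos:pos + size] = seq
        pos += size
        blk += nblk
    return out


def generate_trial(config: ScenarioConfig,
                   rng: np.random.Generator) -> TrialData:
    """Draw one trial dataset from the latent-variable mechanism.

    Draw order is fixed (center sizes, treatment blocks, center effects,
    subject noise) so that identical ``(config, seed)`` pairs reproduce the
    trial bit for bit.
    """
    sizes = assign_center_sizes(config.n_total, config.n_centers_target,
                                config.size_distribution, rng)
    arm = permuted_block_randomize(sizes, config.block_size, rng)
    sigma2 = config.sigma2
    u = rng.normal(0.0, math.sqrt(sigma2), size=sizes.size)
    eps = rng.logistic(size=config.n_total)
    alpha = calibrate_intercept(config.p0, sigma2, config.calibration)
    center_index = np.repeat(np.arange(sizes.size), sizes)
    latent = alpha + config.beta_trt * arm + u[center_index] + eps
    outcome = (latent > 0).astype(np.int64)
    return TrialData(center_index + 1, arm, outcome)


def prescreen_trial(data: TrialData) -> str:
    """Classify a simulated trial before analysis.

    Returns ``"retain"``, ``"exclude_no_events"`` (no events at all), or
    ``"exclude_one_arm_only"`` (all events in a single arm). Trials in the
    two exclusion classes are unanalyzable by every method compared here and
    are dropped from performance summaries, with the drop count reported.
    """
    events_trt = int(data.outcome[data.arm == 1].sum())
    events_ctl = int(data.outcome[data.arm == 0].sum())
    if events_trt + events_ctl == 0:
        return "exclude_no_events"
    if events_trt == 0 or events_ctl == 0:
        return "exclude_one_arm_only"
    return "retain"
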