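"""Cohort simulator: ITH ground truth, read counts, covariates, survival.

The generator mirrors a benchmark design for ITH-survival association
studies.  Per subject it draws a subclone tree uniformly (count uniform on
1..s_max, then uniform among trees of that size), subclone fractions from a
logit-uniform construction ``eta_s = exp(U_s) / (1 + sum exp(U_s'))`` with
``U_s ~ Uniform(-3, 1)`` — which simultaneously yields tumor purity
``phi = sum eta_s`` — rejecting draws until every subclone holds more than 5%
of cancer cells and all cellular prevalences are separated by more than 0.05.
Read depths are negative-binomial (mean ``mu``, dispersion ``delta``, variance
``mu + mu^2/delta``), each mutation's allocation x multiplicity combination is
uniform over those valid for its copy state, and alternate reads are binomial.
Survival times follow a proportional-hazards model with constant baseline
hazard ``exp(-7.0)`` and uniform censoring on ``(0, tau)``, with ``tau`` tuned
to a target censoring fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .likelihood import SampleData, SpmRecord, shannon_entropy, success_prob
from .selection import high_ith_indicator
from .trees import CopyState, TreeConfig, build_combos, enumerate_trees

__all__ = [
    "SimConfig",
    "SimTruth",
    "draw_ith",
    "draw_reads",
    "draw_covariates",
    "draw_survival",
    "tune_tau",
    "simulate_cohort",
    "truth_to_sample",
]

DEFAULT_STATES = (CopyState(1, 1), CopyState(0, 1), CopyState(1, 2))
MAX_REJECTIONS = 100_000


@dataclass(frozen=True)
class SimConfig:
    """Knobs of one simulation scenario.

    Defaults follow the benchmark's baseline grid point: cohorts of 400
    subjects, 100 mutations per sample, mean depth 500 with dispersion 2,
    20% censoring, trees up to five subclones, high-ITH threshold kappa=3,
    ITH effect 0.5 on the log-hazard scale, baseline hazard exp(-7), and
    covariate effects (0.55, 0.15, 0.8, 1.7, 2.7).
    """

    n_subjects: int = 400
    n_spms: int = 100
    depth_mean: float = 500.0
    depth_disp: float = 2.0
    censor_rate: float = 0.2
    s_max: int = 5
    kappa: int = 3
    beta_e: float = 0.5
    beta_h: float = 0.5
    log_lambda0: float = -7.0
    gamma_z: tuple[float, ...] = (0.55, 0.15, 0.8, 1.7, 2.7)
    min_prop: float = 0.05
    min_prev_gap: float = 0.05
    states: tuple[CopyState, ...] = DEFAULT_STATES
    state_probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.censor_rate < 1:
            raise ValueError("censor_rate must lie in (0, 1)")
        if self.depth_mean <= 0 or self.depth_disp <= 0:
            raise ValueError("depth parameters must be positive")


@dataclass
class SimTruth:
    """Ground truth for one simulated tumor sample."""

    tree: TreeConfig
    eta: np.ndarray  # per-subclone fraction of all cells
    purity: float
    theta: np.ndarray  # per-subclone fraction of cancer cells
    entropy: float
    high_ith: int
    # per-SPM draws (filled by draw_reads)
    states: list[CopyState] = field(default_factory=list)
    origins: np.ndarray | None = None
    multiplicities: np.ndarray | None = None
    depths: np.ndarray | None = None
    alt_counts: np.ndarray | None = None

    @property
    def n_subclones(self) -> int:
        return self.tree.n_subclones


def _trees_by_size(s_max: int) -> dict[int, list[TreeConfig]]:
    out: dict[int, list[TreeConfig]] = {}
    for tree in enumerate_trees(s_max):
        out.setdefault(tree.n_subclones, []).append(tree)
    return out


def draw_ith(
    config: SimConfig,
    rng: np.random.Generator,
    _trees: dict[int, list[TreeConfig]] | None = None,
) -> SimTruth:
    """Rejection-sample one subject's subclone structure.

    The subclone count is uniform on 1..s_max and the tree uniform among
    trees of that size.  Draws are rejected until the smallest subclone
    proportion exceeds ``min_prop`` and all pairwise cellular-prevalence
    differences exceed ``min_prev_gap``.
    """
    trees = _trees if _trees is not None else _trees_by_size(config.s_max)
    for _ in range(MAX_REJECTIONS):
        s = int(rng.integers(1, config.s_max + 1))
        tree = trees[s][int(rng.integers(len(trees[s])))]
        u = rng.uniform(-3.0, 1.0, size=s)
        exp_u = np.exp(u)
        eta = exp_u / (1.0 + exp_u.sum())
        phi = float(eta.sum())
        theta = eta / phi
        if theta.min() <= config.min_prop:
            continue
        prevalences = tree.allocation_matrix() @ theta
        if s > 1:
            gaps = np.abs(prevalences[:, None] - prevalences[None, :])
            if gaps[np.triu_indices(s, 1)].min() <= config.min_prev_gap:
                continue
        return SimTruth(
            tree=tree,
            eta=eta,
            purity=phi,
            theta=theta,
            entropy=shannon_entropy(theta),
            high_ith=high_ith_indicator(s, config.kappa, "simulation"),
        )
    raise RuntimeError(
        "rejection sampling exceeded the iteration cap; the separation "
        "constraints are too strict for the configured scenario"
    )


def draw_reads(
    truth: SimTruth, config: SimConfig, rng: np.random.Generator
) -> SimTruth:
    """Simulate per-mutation depths and alternate read counts into ``truth``.

    Depth is NegBin(mean mu, dispersion delta) truncated below at 1; the copy
    state comes from ``config.states``/``state_probs``; the allocation x
    multiplicity combination is uniform over the state's valid combinations;
    alternate reads are Binomial(depth, p) with the combination's success
    probability.
    """
    n = config.n_spms
    mu, disp = config.depth_mean, config.depth_disp
    depths = rng.negative_binomial(disp, disp / (disp + mu), size=n)
    depths = np.maximum(depths, 1)
    probs = config.state_probs
    state_idx = rng.choice(len(config.states), size=n, p=probs)
    combos = build_combos(truth.tree, config.states)
    origins = np.empty(n, dtype=int)
    mults = np.empty(n, dtype=int)
    alts = np.empty(n, dtype=int)
    states: list[CopyState] = []
    for l in range(n):
        state = config.states[state_idx[l]]
        states.append(state)
        rows = combos.combos[state]
        combo = rows[int(rng.integers(len(rows)))]
        prevalence = float(np.dot(combo.allocation, truth.theta))
        p = success_prob(combo.multiplicity, truth.purity, prevalence, state)
        origins[l] = combo.origin
        mults[l] = combo.multiplicity
        alts[l] = rng.binomial(int(depths[l]), p)
    truth.states = states
    truth.origins = origins
    truth.multiplicities = mults
    truth.depths = depths.astype(int)
    truth.alt_counts = alts
    return truth


def truth_to_sample(truth: SimTruth) -> SampleData:
    """Package a simulated sample's reads as estimator input."""
    if truth.alt_counts is None:
        raise ValueError("reads have not been simulated for this truth")
    spms = tuple(
        SpmRecord(
            alt_count=int(a),
            ref_count=int(t - a),
            state=s,
        )
        for a, t, s in zip(truth.alt_counts, truth.depths, truth.states)
    )
    return SampleData(spms=spms, purity=truth.purity)


def draw_covariates(n: int, rng: np.random.Generator) -> np.ndarray:
    """Baseline covariates resembling sex, age, and tumor stage.

    Z1 ~ Bernoulli(0.5), Z2 ~ N(0, 1), Z3-Z5 one-hot indicators of a
    four-category equal-probability stage variable (reference level dropped).
    """
    z = np.empty((n, 5))
    z[:, 0] = rng.integers(0, 2, size=n)
    z[:, 1] = rng.standard_normal(n)
    stage = rng.integers(0, 4, size=n)
    for j in range(3):
        z[:, 2 + j] = stage == j + 1
    return z


def _hazard_rates(
    ith: np.ndarray, z: np.ndarray, config: SimConfig, metric: Literal["E", "H"]
) -> np.ndarray:
    beta = config.beta_e if metric == "E" else config.beta_h
    lin = beta * ith + z @ np.asarray(config.gamma_z)
    return np.exp(config.log_lambda0 + lin)


def draw_survival(
    ith: np.ndarray,
    z: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    metric: Literal["E", "H"] = "E",
    tau: float | None = None,
) -> pd.DataFrame:
    """Event and censoring times under the proportional-hazards model.

    With a constant baseline hazard the event time is exponential with rate
    ``lambda_0 exp(beta * ith + gamma . Z)``; censoring is Uniform(0, tau).
    Returns a frame with follow-up ``time`` = min(T, C) and ``event`` =
    I(T <= C).
    """
    if tau is None:
        raise ValueError("tau must be supplied (see tune_tau)")
    if tau <= 0:
        raise ValueError("tau must be positive")
    rates = _hazard_rates(np.asarray(ith, float), z, config, metric)
    t_event = rng.exponential(1.0 / rates)
    t_censor = rng.uniform(0.0, tau, size=len(rates))
    return pd.DataFrame(
        {
            "time": np.minimum(t_event, t_censor),
            "event": (t_event <= t_censor).astype(int),
        }
    )


def _censor_prob(rates: np.ndarray, tau: float) -> np.ndarray:
    """P(censored) = P(U(0,tau) < Exp(rate)) = (1 - exp(-rate tau))/(rate tau)."""
    x = rates * tau
    return (1.0 - np.exp(-x)) / x


def tune_tau(
    config: SimConfig,
    metric: Literal["E", "H"] = "E",
    n_pilot: int = 100_000,
    rng: np.random.Generator | None = None,
    tol: float = 0.005,
) -> float:
    """Bisect the censoring bound tau to hit the target censoring fraction.

    A pilot population of subjects (ITH truth plus covariates) is drawn once;
    for a candidate tau the expected censoring fraction is the pilot average
    of the exact per-subject censoring probability, so the bisection target is
    smooth and monotone decreasing in tau.
    """
    target = config.censor_rate
    if not 0.01 <= target <= 0.9:
        raise ValueError("censor_rate target must lie in [0.01, 0.9]")
    rng = np.random.default_rng(rng)
    trees = _trees_by_size(config.s_max)
    if metric == "E":
        ith = np.array(
            [draw_ith(config, rng, trees).entropy for _ in range(n_pilot)]
        )
    else:
        ith = np.array(
            [draw_ith(config, rng, trees).high_ith for _ in range(n_pilot)]
        )
    z = draw_covariates(n_pilot, rng)
    rates = _hazard_rates(ith, z, config, metric)

    def f(tau: float) -> float:
        return float(_censor_prob(rates, tau).mean()) - target

    lo, hi = 1e-3, 10.0
    while f(hi) > 0:
        hi *= 4.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket tau; hazards degenerate")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        val = f(mid)
        if abs(val) < tol:
            return mid
        if val > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    metric: Literal["E", "H"] = "E",
    tau: float | None = None,
    with_reads: bool = False,
) -> tuple[list[SimTruth], pd.DataFrame]:
    """Simulate one cohort: ITH truths, covariates, and survival outcomes.

    Returns the per-subject truths and a survival frame with columns ``time``,
    ``event``, ``Z1..Z5``, ``E_true``, ``H_true``, ``S_true``.  With
    ``with_reads=True`` each truth also carries simulated read counts.
    """
    rng = np.random.default_rng(rng)
    if tau is None:
        tau = tune_tau(config, metric, rng=np.random.default_rng(rng.integers(2**31)))
    trees = _trees_by_size(config.s_max)
    truths = [draw_ith(config, rng, trees) for _ in range(config.n_subjects)]
    if with_reads:
        for truth in truths:
            draw_reads(truth, config, rng)
    z = draw_covariates(config.n_subjects, rng)
    ith = np.array(
        [t.entropy for t in truths]
        if metric == "E"
        else [t.high_ith for t in truths],
        dtype=float,
    )
    surv = draw_survival(ith, z, config, rng, metric, tau)
    for j in range(5):
        surv[f"Z{j + 1}"] = z[:, j]
    surv["E_true"] = [t.entropy for t in truths]
    surv["H_true"] = [t.high_ith for t in truths]
    surv["S_true"] = [t.n_subclones for t in truths]
    return truths, surv
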