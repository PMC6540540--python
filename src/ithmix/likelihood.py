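"""Binomial-mixture likelihood of somatic read counts and its EM maximizer.

For a fixed subclone tree, the alternate read count ``A_l`` of a mutation with
total depth ``T_l`` and copy state ``(C_l1, C_l2)`` follows a mixture over the
state's allocation x multiplicity combinations ``d``:

    P(A_l) = eps / T_l + (1 - eps) * sum_d pi_wd Binom(A_l; T_l, p_wd),

    p_wd = m_wd * phi * (theta . q_d) / ((C_l1 + C_l2) phi + 2 (1 - phi)),

where ``phi`` is tumor purity, ``theta`` the subclone proportions among cancer
cells, ``theta . q_d`` the combination's cellular prevalence, and the
``eps``-weighted discrete-uniform term absorbs read counts unexplained by any
combination.  The likelihood is maximized per tree by EM: the noise weight and
the per-state mixture weights ``pi_w`` have closed-form updates, while
``theta`` is updated on the expected complete-data log-likelihood with BFGS in
an unconstrained softmax parameterization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, softmax

from .trees import Combo, ComboTable, CopyState, TreeConfig, build_combos

__all__ = [
    "SpmRecord",
    "SampleData",
    "ModelParams",
    "FitResult",
    "ModelInconsistencyError",
    "success_prob",
    "spm_loglik",
    "sample_loglik",
    "e_step",
    "m_step_pi_eps",
    "m_step_theta",
    "fit_configuration",
    "model_size",
    "shannon_entropy",
]

P_FLOOR = 1e-9
EPS_BOUNDS = (1e-6, 0.25)
EPS_INIT = 1e-3


class ModelInconsistencyError(ValueError):
    """A combination implies a binomial success probability above one."""


@dataclass(frozen=True)
class SpmRecord:
    """One somatic point mutation: read counts plus clonal copy state."""

    alt_count: int
    ref_count: int
    state: CopyState

    def __post_init__(self) -> None:
        if self.alt_count < 0 or self.ref_count < 0:
            raise ValueError("read counts must be non-negative")
        if self.depth < 1:
            raise ValueError("total depth must be at least 1")

    @property
    def depth(self) -> int:
        return self.alt_count + self.ref_count


@dataclass(frozen=True)
class SampleData:
    """All retained mutations of one tumor sample plus its purity."""

    spms: tuple[SpmRecord, ...]
    purity: float

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        if len(self.spms) == 0:
            raise ValueError("sample must contain at least one mutation")

    @property
    def n_spms(self) -> int:
        return len(self.spms)

    def unique_states(self) -> list[CopyState]:
        return list(dict.fromkeys(spm.state for spm in self.spms))


@dataclass
class ModelParams:
    """Mixture parameters (eps, theta, {pi_w}) for one tree configuration."""

    epsilon: float
    theta: np.ndarray
    pi: dict[CopyState, np.ndarray]

    def validate(self) -> None:
        if not 0 <= self.epsilon <= 1:
            raise ValueError("epsilon must lie in [0, 1]")
        if np.any(self.theta <= 0) or abs(self.theta.sum() - 1) > 1e-8:
            raise ValueError("theta must be positive and sum to 1")
        for state, pw in self.pi.items():
            if np.any(pw < 0) or abs(pw.sum() - 1) > 1e-8:
                raise ValueError(f"pi for state {state} must be a simplex vector")


@dataclass
class FitResult:
    """Maximized fit of one tree configuration, plus model-selection fields."""

    config: TreeConfig
    loglik: float
    model_size: int
    bic: float
    entropy: float
    params: ModelParams
    map_combo: np.ndarray  # per-SPM MAP combination index within its state
    map_origin: np.ndarray  # per-SPM origin subclone of the MAP combination
    map_prevalence: np.ndarray  # per-SPM cellular prevalence of MAP allocation
    converged: bool = True
    n_iter: int = 0
    posterior_weight: float = field(default=np.nan)
    loglik_path: np.ndarray | None = None  # per-iteration observed log-likelihood

    @property
    def n_subclones(self) -> int:
        return self.config.n_subclones


def shannon_entropy(theta: np.ndarray | Sequence[float]) -> float:
    """Shannon entropy -sum theta_s log theta_s (natural log, 0 log 0 := 0)."""
    t = np.asarray(theta, dtype=float)
    if np.any(t < 0):
        raise ValueError("proportions must be non-negative")
    if abs(t.sum() - 1.0) > 1e-6:
        raise ValueError("proportions must sum to 1")
    nz = t[t > 0]
    return float(-(nz * np.log(nz)).sum())


def success_prob(
    m: int,
    phi: float,
    prevalence: float,
    state: CopyState,
    p_floor: float = P_FLOOR,
) -> float:
    """Binomial success probability of a combination.

    ``m * phi * prevalence / ((C1 + C2) phi + 2 (1 - phi))`` clipped to
    ``[p_floor, 1 - p_floor]``.  Raises :class:`ModelInconsistencyError` when
    the unclipped value exceeds one, which signals a multiplicity inconsistent
    with the copy state.
    """
    if m < 1:
        raise ValueError("multiplicity must be at least 1")
    if not 0 < prevalence <= 1 + 1e-9:
        raise ValueError("prevalence must lie in (0, 1]")
    prevalence = min(prevalence, 1.0)
    denom = state.total * phi + 2.0 * (1.0 - phi)
    p = m * phi * prevalence / denom
    if p > 1.0 + 1e-12:
        raise ModelInconsistencyError(
            f"success probability {p:.4f} > 1 for m={m}, state={state}"
        )
    return float(np.clip(p, p_floor, 1.0 - p_floor))


# ---------------------------------------------------------------------------
# Vectorized per-state blocks
# ---------------------------------------------------------------------------


@dataclass
class _StateBlock:
    state: CopyState
    spm_idx: np.ndarray  # positions in the sample's SPM list
    alt: np.ndarray
    depth: np.ndarray
    log_binom_coef: np.ndarray
    mult: np.ndarray  # (D,)
    alloc: np.ndarray  # (D, S)
    origin: np.ndarray  # (D,)
    coef: np.ndarray  # (D,)  m * phi / denominator

    @property
    def n_combos(self) -> int:
        return len(self.mult)


def _build_blocks(data: SampleData, combos: ComboTable) -> list[_StateBlock]:
    phi = data.purity
    blocks = []
    states = [spm.state for spm in data.spms]
    for state in dict.fromkeys(states):
        if state not in combos.combos:
            raise KeyError(f"copy state {state} missing from combination table")
        idx = np.array([i for i, s in enumerate(states) if s == state])
        alt = np.array([data.spms[i].alt_count for i in idx], dtype=float)
        depth = np.array([data.spms[i].depth for i in idx], dtype=float)
        rows = combos.combos[state]
        mult = np.array([c.multiplicity for c in rows], dtype=float)
        alloc = np.array([c.allocation for c in rows], dtype=float)
        origin = np.array([c.origin for c in rows], dtype=int)
        denom = state.total * phi + 2.0 * (1.0 - phi)
        blocks.append(
            _StateBlock(
                state=state,
                spm_idx=idx,
                alt=alt,
                depth=depth,
                log_binom_coef=gammaln(depth + 1)
                - gammaln(alt + 1)
                - gammaln(depth - alt + 1),
                mult=mult,
                alloc=alloc,
                origin=origin,
                coef=mult * phi / denom,
            )
        )
    return blocks


def _combo_logpmf(block: _StateBlock, theta: np.ndarray) -> np.ndarray:
    """(n, D) binomial log-pmf matrix; combos with p >= 1 are masked to -inf."""
    prev = block.alloc @ theta
    raw = block.coef * prev
    invalid = raw >= 1.0
    if invalid.any():
        warnings.warn(
            f"dropping {int(invalid.sum())} combination(s) with success "
            f"probability >= 1 for state {block.state}",
            RuntimeWarning,
            stacklevel=3,
        )
    p = np.clip(raw, P_FLOOR, 1.0 - P_FLOOR)
    ll = (
        block.log_binom_coef[:, None]
        + block.alt[:, None] * np.log(p)[None, :]
        + (block.depth - block.alt)[:, None] * np.log1p(-p)[None, :]
    )
    ll[:, invalid] = -np.inf
    return ll


def _rows_logsumexp_and_resp(joint: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise log-sum-exp of a joint log matrix and the softmax rows."""
    m = joint.max(axis=1)
    shifted = np.exp(joint - m[:, None])
    ssum = shifted.sum(axis=1)
    return m + np.log(ssum), shifted / ssum[:, None]


def _block_loglik(
    block: _StateBlock, epsilon: float, pi_w: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """Per-SPM mixture log density for one state block."""
    ll = _combo_logpmf(block, theta)
    with np.errstate(divide="ignore"):
        log_comp = np.log1p(-epsilon) + np.log(pi_w)[None, :] + ll
        log_noise = np.log(epsilon) - np.log(block.depth)
    norm, _ = _rows_logsumexp_and_resp(np.column_stack([log_noise, log_comp]))
    return norm


def spm_loglik(
    spm: SpmRecord, params: ModelParams, phi: float, combos: ComboTable
) -> float:
    """Log density of one mutation's alternate read count under the mixture."""
    data = SampleData(spms=(spm,), purity=phi)
    (block,) = _build_blocks(data, combos)
    return float(
        _block_loglik(block, params.epsilon, params.pi[spm.state], params.theta)[0]
    )


def sample_loglik(
    data: SampleData, params: ModelParams, combos: ComboTable
) -> float:
    """Observed-data log-likelihood: sum of per-mutation mixture log densities."""
    blocks = _build_blocks(data, combos)
    total = 0.0
    for block in blocks:
        total += float(
            _block_loglik(
                block, params.epsilon, params.pi[block.state], params.theta
            ).sum()
        )
    return total


@dataclass
class Responsibilities:
    """E-step posteriors: per state block, noise column plus combo columns."""

    blocks: list[_StateBlock]
    noise: list[np.ndarray]  # each (n_w,)
    combo: list[np.ndarray]  # each (n_w, D_w)
    loglik: float


def e_step(
    data: SampleData, params: ModelParams, combos: ComboTable
) -> Responsibilities:
    """Posterior membership of each mutation in the noise term and each combo."""
    blocks = _build_blocks(data, combos)
    return _e_step_blocks(blocks, params)


def _e_step_blocks(
    blocks: list[_StateBlock], params: ModelParams
) -> Responsibilities:
    noise_out, combo_out = [], []
    total_ll = 0.0
    for block in blocks:
        ll = _combo_logpmf(block, params.theta)
        pi_w = params.pi[block.state]
        with np.errstate(divide="ignore"):
            log_comp = np.log1p(-params.epsilon) + np.log(pi_w)[None, :] + ll
            log_noise = np.log(params.epsilon) - np.log(block.depth)
        joint = np.column_stack([log_noise, log_comp])
        norm, resp = _rows_logsumexp_and_resp(joint)
        noise_out.append(resp[:, 0])
        combo_out.append(resp[:, 1:])
        total_ll += float(norm.sum())
    return Responsibilities(blocks, noise_out, combo_out, total_ll)


def m_step_pi_eps(
    resp: Responsibilities, eps_bounds: tuple[float, float] = EPS_BOUNDS
) -> tuple[float, dict[CopyState, np.ndarray]]:
    """Closed-form updates: eps = mean noise weight; pi_w = normalized tallies."""
    n_total = sum(len(r) for r in resp.noise)
    eps = sum(float(r.sum()) for r in resp.noise) / n_total
    eps = float(np.clip(eps, *eps_bounds))
    pi: dict[CopyState, np.ndarray] = {}
    for block, r in zip(resp.blocks, resp.combo):
        col = r.sum(axis=0)
        tot = col.sum()
        if tot <= 0:
            warnings.warn(
                f"state {block.state} has no non-noise responsibility; "
                "resetting pi to uniform",
                RuntimeWarning,
                stacklevel=2,
            )
            pi[block.state] = np.full(block.n_combos, 1.0 / block.n_combos)
        else:
            pi[block.state] = col / tot
    return eps, pi


def _theta_objective(
    z: np.ndarray, alloc: np.ndarray, coef: np.ndarray, ra: np.ndarray, rt: np.ndarray
) -> tuple[float, np.ndarray]:
    """Negative expected complete-data log-likelihood in theta and its gradient.

    ``z`` are the free softmax coordinates (last pinned at 0); ``ra``/``rt``
    are responsibility-weighted alt and ref counts per combination, stacked
    across copy states alongside the allocation and coefficient rows.
    """
    theta = softmax(np.append(z, 0.0))
    raw = coef * (alloc @ theta)
    p = np.clip(raw, P_FLOOR, 1.0 - P_FLOOR)
    val = float(ra @ np.log(p) + rt @ np.log1p(-p))
    interior = (raw > P_FLOOR) & (raw < 1.0 - P_FLOOR)
    gp = np.where(interior, (ra / p - rt / (1.0 - p)) * coef, 0.0)
    grad_theta = alloc.T @ gp
    # softmax Jacobian with the last coordinate pinned
    gz = theta[:-1] * (grad_theta[:-1] - grad_theta @ theta)
    return -val, -gz


def m_step_theta(
    data: SampleData,
    resp: Responsibilities,
    theta_init: np.ndarray,
    combos: ComboTable,
    max_bfgs_iter: int = 8,
    grad_skip_tol: float = 1e-6,
) -> np.ndarray:
    """Update subclone proportions by BFGS on the expected complete-data
    log-likelihood, in a softmax parameterization with the last coordinate
    pinned.  Never returns a theta with a lower objective than ``theta_init``.
    When the gradient at ``theta_init`` is already negligible the update is
    skipped (late EM iterations mostly refine eps and pi).
    """
    s = len(theta_init)
    if s == 1:
        return np.ones(1)
    alloc = np.vstack([b.alloc for b in resp.blocks])
    coef = np.concatenate([b.coef for b in resp.blocks])
    ra = np.concatenate([r.T @ b.alt for b, r in zip(resp.blocks, resp.combo)])
    rt = np.concatenate(
        [r.T @ (b.depth - b.alt) for b, r in zip(resp.blocks, resp.combo)]
    )
    theta0 = np.clip(theta_init, 1e-10, None)
    theta0 = theta0 / theta0.sum()
    z0 = np.log(theta0[:-1]) - np.log(theta0[-1])
    f0, g0 = _theta_objective(z0, alloc, coef, ra, rt)
    if np.max(np.abs(g0)) < grad_skip_tol * (abs(f0) + 1.0):
        return theta_init
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = minimize(
            _theta_objective,
            z0,
            args=(alloc, coef, ra, rt),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_bfgs_iter, "gtol": 1e-7},
        )
    if res.fun <= f0:
        return softmax(np.append(res.x, 0.0))
    return theta_init  # keep the ascent guarantee when BFGS fails to improve


def model_size(tree: TreeConfig, combos: ComboTable) -> int:
    """Free-parameter count: eps, the theta simplex, and each pi_w simplex."""
    s = tree.n_subclones
    return 1 + (s - 1) + sum(len(rows) - 1 for rows in combos.combos.values())


def fit_configuration(
    data: SampleData,
    tree: TreeConfig,
    n_inits: int = 5,
    random_state: int | np.random.Generator | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    eps_init: float = EPS_INIT,
    eps_bounds: tuple[float, float] = EPS_BOUNDS,
    burn_in: int = 12,
) -> FitResult:
    """Fit one tree configuration by EM, keeping the best of ``n_inits`` starts.

    Each start draws theta from a flat Dirichlet (uniform on the simplex),
    initializes every pi_w uniform and eps at ``eps_init``, then alternates the
    E-step with the closed-form eps/pi updates and the BFGS theta update.  To
    avoid spending full convergence runs on dominated starts, the restarts are
    staged: every start runs a few iterations, the two best continue through
    ``burn_in`` iterations, and only the best-scoring start then continues
    until the relative change in the observed-data log-likelihood drops below
    ``tol`` or ``max_iter`` total iterations are reached.
    """
    if n_inits < 1:
        raise ValueError("n_inits must be at least 1")
    rng = np.random.default_rng(random_state)
    combos = build_combos(tree, data.unique_states())
    blocks = _build_blocks(data, combos)
    s = tree.n_subclones
    n_starts = 1 if s == 1 else n_inits

    def em_iterate(params, resp, n_iters, path):
        converged = False
        done = 0
        for _ in range(n_iters):
            prev_ll = resp.loglik
            eps, pi = m_step_pi_eps(resp, eps_bounds)
            theta_new = m_step_theta(
                data, resp, params.theta, combos
            )
            params = ModelParams(epsilon=eps, theta=theta_new, pi=pi)
            resp = _e_step_blocks(blocks, params)
            path.append(resp.loglik)
            done += 1
            if abs(resp.loglik - prev_ll) < tol * (abs(prev_ll) + 1.0):
                converged = True
                break
        return params, resp, converged, done

    screen_iters = min(3, burn_in, max_iter)
    candidates = []
    for _ in range(n_starts):
        theta = np.ones(1) if s == 1 else rng.dirichlet(np.ones(s))
        params = ModelParams(
            epsilon=eps_init,
            theta=theta,
            pi={b.state: np.full(b.n_combos, 1.0 / b.n_combos) for b in blocks},
        )
        resp = _e_step_blocks(blocks, params)
        path = [resp.loglik]
        params, resp, converged, done = em_iterate(params, resp, screen_iters, path)
        candidates.append([resp.loglik, params, resp, converged, done, path])

    candidates.sort(key=lambda c: c[0], reverse=True)
    for cand in candidates[:2]:
        if not cand[3]:  # not yet converged
            params, resp, converged, done = em_iterate(
                cand[1], cand[2], min(burn_in, max_iter) - cand[4], cand[5]
            )
            cand[:5] = [resp.loglik, params, resp, converged, cand[4] + done]

    _, params, resp, converged, n_iter, path = max(candidates, key=lambda c: c[0])
    if not converged:
        params, resp, converged, done = em_iterate(
            params, resp, max_iter - n_iter, path
        )
        n_iter += done
    ll = resp.loglik
    n_spms = data.n_spms
    m_b = model_size(tree, combos)
    bic = 2.0 * ll - m_b * np.log(n_spms)

    map_combo = np.empty(n_spms, dtype=int)
    map_origin = np.empty(n_spms, dtype=int)
    map_prev = np.empty(n_spms, dtype=float)
    for block, r in zip(resp.blocks, resp.combo):
        d_star = np.argmax(r, axis=1)
        map_combo[block.spm_idx] = d_star
        map_origin[block.spm_idx] = block.origin[d_star]
        map_prev[block.spm_idx] = block.alloc[d_star] @ params.theta

    return FitResult(
        config=tree,
        loglik=ll,
        model_size=m_b,
        bic=float(bic),
        entropy=shannon_entropy(params.theta),
        params=params,
        map_combo=map_combo,
        map_origin=map_origin,
        map_prevalence=map_prev,
        converged=converged,
        n_iter=n_iter,
        loglik_path=np.array(path),
    )
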