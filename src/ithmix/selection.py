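"""BIC model averaging over tree configurations and entropy-based ITH metrics.

Fitted configurations are scored by ``BIC_b = 2 L_b - m_b log(L)`` (larger is
better) and weighted by a softmax of ``0.5 * BIC``, a large-sample
approximation to posterior model probability.  ITH is summarized by Shannon
entropy of the subclone proportions, reported two ways: the *optimal* entropy
averages configurations tied at the best BIC, while the *weighted* entropy
averages all retained configurations by their posterior weights.  A support
filter drops configurations in which some subclone is backed by too few
mutations before the metrics are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .likelihood import FitResult, shannon_entropy

__all__ = [
    "IthSummary",
    "entropy",
    "posterior_weights",
    "optimal_entropy",
    "weighted_entropy",
    "high_ith_indicator",
    "support_filter",
    "spm_prevalence",
    "summarize",
]

BIC_TIE_TOL = 1e-6


def entropy(theta: Sequence[float] | np.ndarray) -> float:
    """Shannon entropy of a subclone proportion vector (natural log)."""
    return shannon_entropy(theta)


def posterior_weights(fits: Sequence[FitResult]) -> np.ndarray:
    """Posterior configuration probabilities: softmax of 0.5 * BIC.

    Computed via log-sum-exp; invariant to adding a constant to every BIC.
    """
    if len(fits) == 0:
        raise ValueError("no fitted configurations to weight")
    half_bic = 0.5 * np.array([f.bic for f in fits])
    return np.exp(half_bic - logsumexp(half_bic))


def _tied_best(fits: Sequence[FitResult], tol: float = BIC_TIE_TOL) -> np.ndarray:
    bics = np.array([f.bic for f in fits])
    return np.abs(bics - bics.max()) < tol


def optimal_entropy(fits: Sequence[FitResult], tol: float = BIC_TIE_TOL) -> float:
    """Entropy averaged over configurations tied at the best BIC.

    With a unique best-BIC configuration this is simply its entropy; ties
    (within ``tol`` on the BIC scale) are averaged with their (equal) weights.
    """
    if len(fits) == 0:
        raise ValueError("no fitted configurations")
    tied = _tied_best(fits, tol)
    entropies = np.array([f.entropy for f in fits])
    w = posterior_weights(fits)[tied]
    return float(w @ entropies[tied] / w.sum())


def weighted_entropy(fits: Sequence[FitResult]) -> float:
    """Entropy averaged over all retained configurations by posterior weight."""
    if len(fits) == 0:
        raise ValueError("no fitted configurations")
    w = posterior_weights(fits)
    return float(w @ np.array([f.entropy for f in fits]))


def high_ith_indicator(
    s_opt: int, kappa: int = 3, mode: str = "simulation"
) -> int:
    """Binary high-ITH call from the selected subclone count.

    ``mode="simulation"`` uses the strict rule I(S > kappa); ``mode=
    "application"`` uses I(S >= kappa), i.e. "kappa or more subclones".
    """
    if s_opt < 1:
        raise ValueError("subclone count must be at least 1")
    if mode == "simulation":
        return int(s_opt > kappa)
    if mode == "application":
        return int(s_opt >= kappa)
    raise ValueError(f"unknown mode {mode!r}")


def support_filter(
    fits: Sequence[FitResult], min_support: int = 2
) -> list[FitResult]:
    """Drop configurations with an under-supported subclone.

    A configuration is removed when any non-root subclone's origin allocation
    is the MAP assignment of fewer than ``min_support`` mutations — each
    subclone must be anchored by at least that many mutations not shared with
    its parent.  The single-clone configuration is always retained, and if
    every multi-clone configuration is removed the single-clone fit(s) remain
    as the fallback.
    """
    retained = []
    for fit in fits:
        s = fit.config.n_subclones
        if s == 1:
            retained.append(fit)
            continue
        counts = np.bincount(fit.map_origin, minlength=s)
        if np.all(counts[1:] >= min_support):
            retained.append(fit)
    if not retained:
        warnings.warn(
            "support filter removed every configuration; no single-clone "
            "fallback was available",
            RuntimeWarning,
            stacklevel=2,
        )
        return list(fits)
    return retained


def spm_prevalence(fits: Sequence[FitResult]) -> np.ndarray:
    """Model-averaged cellular prevalence per mutation.

    For each mutation, the prevalence of its MAP allocation in every retained
    configuration is averaged with the posterior configuration weights.  A
    clonal allocation contributes prevalence 1 in any configuration.
    """
    if len(fits) == 0:
        raise ValueError("no fitted configurations")
    w = posterior_weights(fits)
    prev = np.stack([f.map_prevalence for f in fits])
    return w @ prev


@dataclass
class IthSummary:
    """Per-sample ITH summary from the retained configuration fits."""

    n_subclones: int
    entropy_optimal: float
    entropy_weighted: float
    high_ith: int
    prevalence: np.ndarray
    fits: list[FitResult]

    def to_row(self) -> dict:
        return {
            "n_subclones": self.n_subclones,
            "entropy_optimal": round(self.entropy_optimal, 10),
            "entropy_weighted": round(self.entropy_weighted, 10),
            "high_ith": self.high_ith,
        }


def summarize(
    fits: Sequence[FitResult],
    min_support: int = 2,
    kappa: int = 3,
    indicator_mode: str = "simulation",
    apply_filter: bool = True,
) -> IthSummary:
    """Filter, weight, and summarize a set of configuration fits.

    The support filter runs first (unless disabled), weights are renormalized
    over the retained set, and the entropy metrics, selected subclone count,
    and high-ITH indicator are computed on that set.
    """
    retained = support_filter(fits, min_support) if apply_filter else list(fits)
    weights = posterior_weights(retained)
    for fit, w in zip(retained, weights):
        fit.posterior_weight = float(w)
    best = int(np.argmax([f.bic for f in retained]))
    s_opt = retained[best].config.n_subclones
    return IthSummary(
        n_subclones=s_opt,
        entropy_optimal=optimal_entropy(retained),
        entropy_weighted=weighted_entropy(retained),
        high_ith=high_ith_indicator(s_opt, kappa, indicator_mode),
        prevalence=spm_prevalence(retained),
        fits=list(retained),
    )
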