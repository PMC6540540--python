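"""Scikit-learn style estimator for intra-tumor heterogeneity inference.

``SubcloneEntropy.fit`` consumes one tumor sample's somatic point mutations
(alt/ref read counts plus clonal allele-specific copy numbers) together with
the sample's purity, enumerates all subclone phylogenies with up to ``s_max``
subclones, maximizes each tree's binomial-mixture likelihood by EM, and
summarizes intra-tumor heterogeneity by BIC-model-averaged Shannon entropy of
the subclone proportions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .likelihood import SampleData, SpmRecord, fit_configuration
from .selection import IthSummary, summarize
from .trees import CopyState, enumerate_trees

__all__ = ["SubcloneEntropy", "infer_ith", "sample_from_frame"]

REQUIRED_COLUMNS = ("alt_count", "ref_count", "cn_minor", "cn_major")


def sample_from_frame(table: pd.DataFrame, purity: float) -> SampleData:
    """Build a :class:`SampleData` from a mutation table.

    The table needs columns ``alt_count``, ``ref_count``, ``cn_minor``,
    ``cn_major``; one row per somatic point mutation of a single sample.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"mutation table is missing columns: {missing}")
    spms = tuple(
        SpmRecord(
            alt_count=int(row.alt_count),
            ref_count=int(row.ref_count),
            state=CopyState(int(row.cn_minor), int(row.cn_major)),
        )
        for row in table.itertuples(index=False)
    )
    return SampleData(spms=spms, purity=float(purity))


class SubcloneEntropy(BaseEstimator):
    """Infer subclone structure and entropy-based ITH from read counts.

    Parameters
    ----------
    s_max : int, default 5
        Largest subclone count considered when enumerating phylogenies.
    n_inits : int, default 5
        Random restarts of the EM per tree configuration.
    min_support : int, default 2
        Minimum mutations anchoring each non-root subclone (MAP assignment);
        configurations violating it are dropped before model averaging.
    kappa : int, default 3
        Subclone-count threshold of the high-ITH indicator.
    indicator_mode : {"simulation", "application"}, default "simulation"
        Strict I(S > kappa) vs inclusive I(S >= kappa) indicator rule.
    apply_support_filter : bool, default True
        Whether the support filter runs before entropy averaging.
    max_iter, tol : EM stopping rule (iteration cap, relative log-likelihood
        change).
    random_state : int, Generator or None
        Seeds the EM restarts.

    Attributes
    ----------
    fits_ : list of FitResult
        Retained per-configuration fits with posterior weights.
    n_subclones_ : int
        Subclone count of the best-BIC retained configuration.
    entropy_optimal_, entropy_weighted_ : float
        Best-BIC (tie-averaged) and model-averaged Shannon entropy.
    high_ith_ : int
        Binary high-ITH call.
    theta_ : ndarray
        Subclone proportions of the best-BIC configuration.
    prevalence_ : ndarray of shape (n_spms,)
        Model-averaged cellular prevalence per mutation.
    summary_ : IthSummary
    """

    def __init__(
        self,
        s_max: int = 5,
        n_inits: int = 5,
        min_support: int = 2,
        kappa: int = 3,
        indicator_mode: str = "simulation",
        apply_support_filter: bool = True,
        max_iter: int = 500,
        tol: float = 1e-6,
        random_state: int | np.random.Generator | None = None,
    ):
        self.s_max = s_max
        self.n_inits = n_inits
        self.min_support = min_support
        self.kappa = kappa
        self.indicator_mode = indicator_mode
        self.apply_support_filter = apply_support_filter
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None, *, purity: float | None = None):
        """Fit all enumerated tree configurations to one sample.

        ``X`` is either a :class:`SampleData` or a DataFrame with columns
        ``alt_count``, ``ref_count``, ``cn_minor``, ``cn_major`` (in which
        case ``purity`` is required).
        """
        if isinstance(X, SampleData):
            data = X
        else:
            if purity is None:
                raise ValueError("purity is required with a mutation table")
            data = sample_from_frame(pd.DataFrame(X), purity)
        rng = np.random.default_rng(self.random_state)
        all_fits = [
            fit_configuration(
                data,
                tree,
                n_inits=self.n_inits,
                random_state=rng,
                max_iter=self.max_iter,
                tol=self.tol,
            )
            for tree in enumerate_trees(self.s_max)
        ]
        summary = summarize(
            all_fits,
            min_support=self.min_support,
            kappa=self.kappa,
            indicator_mode=self.indicator_mode,
            apply_filter=self.apply_support_filter,
        )
        self.all_fits_ = all_fits
        self.summary_ = summary
        self.fits_ = summary.fits
        self.n_subclones_ = summary.n_subclones
        self.entropy_optimal_ = summary.entropy_optimal
        self.entropy_weighted_ = summary.entropy_weighted
        self.high_ith_ = summary.high_ith
        self.prevalence_ = summary.prevalence
        best = max(summary.fits, key=lambda f: f.bic)
        self.theta_ = best.params.theta
        self.n_spms_ = data.n_spms
        return self

    def transform(self, X=None) -> np.ndarray:
        """Return the fitted per-mutation model-averaged cellular prevalence."""
        if not hasattr(self, "prevalence_"):
            raise AttributeError("estimator is not fitted")
        return self.prevalence_


def infer_ith(
    table: pd.DataFrame | SampleData,
    purity: float | None = None,
    **params,
) -> IthSummary:
    """One-call ITH inference: fit a :class:`SubcloneEntropy` and return its
    per-sample summary."""
    est = SubcloneEntropy(**params)
    est.fit(table, purity=purity)
    return est.summary_
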