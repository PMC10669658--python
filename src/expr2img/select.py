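"""Differentially expressed gene selection via L1-penalized regression.

The binary task label is regressed on all gene values with a LASSO
objective; genes with nonzero coefficients form the selected set.  Penalty
convention (pinned because the sparsity parameter is meaningless without
it):

    minimize  (1/n_samples) * ||y - X b - b0||^2  +  lambda * sum_j |b_j|

Predictors are used as-is (the merged cohort is already on the [0, 1]
scale) and an intercept is fitted.  This maps onto
``sklearn.linear_model.Lasso`` — which minimizes ``(1/2n)||r||^2 +
alpha*||b||_1`` — with ``alpha = lambda / 2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .containers import ExpressionMatrix
from .errors import EmptySelectionError

#: default sparsity parameter
DEFAULT_LAMBDA = 1e-6
#: |coefficient| above this counts as selected (absorbs solver noise)
NONZERO_TOL = 1e-12


@dataclass
class SelectionResult:
    """Outcome of a LASSO gene-selection fit."""

    selected_indices: np.ndarray  # ascending positions into the probe list
    lam: float
    coefficients: np.ndarray  # one per input gene

    @property
    def n_selected(self) -> int:
        return int(len(self.selected_indices))


class LassoGeneSelector(BaseEstimator):
    """Select genes by the nonzero coefficients of a LASSO fit.

    Parameters
    ----------
    lam : float
        Sparsity penalty lambda under the convention in the module docstring.
    tol, max_iter : coordinate-descent convergence controls (sklearn
        semantics); the fit is deterministic for fixed input.

    Attributes
    ----------
    coef_ : (n_genes,) fitted coefficients
    selected_indices_ : ascending indices of genes with |coef| > 1e-12
    n_selected_ : size of the selected set
    """

    def __init__(self, lam: float = DEFAULT_LAMBDA, tol: float = 1e-4, max_iter: int = 20000):
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LassoGeneSelector":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be samples x genes aligned with y")
        if len(np.unique(y)) < 2:
            raise ValueError("labels contain a single class; need both classes")
        model = Lasso(
            alpha=self.lam / 2.0,
            fit_intercept=True,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        with warnings.catch_warnings():
            # at very small lambda with p > n the duality gap shrinks slowly;
            # the max_iter cap is part of the documented convergence contract
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X, y)
        self.coef_ = np.asarray(model.coef_, dtype=float)
        self.intercept_ = float(model.intercept_)
        self.selected_indices_ = np.flatnonzero(np.abs(self.coef_) > NONZERO_TOL)
        if self.selected_indices_.size == 0:
            raise EmptySelectionError(
                f"LASSO with lambda={self.lam:g} selected no genes; use a smaller lambda"
            )
        self.n_selected_ = int(self.selected_indices_.size)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.selected_indices_]

    def fit_transform(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.fit(X, y).transform(X)


def lasso_select(matrix: ExpressionMatrix, lam: float = DEFAULT_LAMBDA) -> SelectionResult:
    """Run LASSO selection on a pairwise-task subset (binary labels attached)."""
    if matrix.binary_labels is None:
        raise ValueError("matrix has no binary labels; run make_pair_subset first")
    sel = LassoGeneSelector(lam=lam).fit(matrix.X, matrix.binary_labels)
    return SelectionResult(
        selected_indices=sel.selected_indices_, lam=lam, coefficients=sel.coef_
    )


def lambda_upper_bound(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda at which every coefficient is exactly zero.

    With the module's penalty convention this is ``2 * max_j
    |<x_j - mean(x_j), y - mean(y)>| / n``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return 2.0 * float(np.max(np.abs(Xc.T @ yc))) / len(y)
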