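"""Log-transformed principal component analysis of colour and environment.

Variables are log-transformed before the PCA: x → log(1 + x) for columns
that are non-negative (areas, distances, depths, precipitation, lightness;
zeros are legal for mainland rows) and a signed log, sign(x)·log(1 + |x|),
for columns that take negative values (the CIELAB a and b opponent axes).
Columns are then centred and scaled, so the decomposition is of the
correlation matrix and the variance fractions sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import NotFittedError

__all__ = ["LogPCA", "OrdinationResult", "log_pca"]


def signed_log1p(x):
    """sign(x)·log(1 + |x|); the identity-preserving log for signed variables."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.log1p(np.abs(x))


class LogPCA(BaseEstimator, TransformerMixin):
    """PCA of the correlation matrix after per-column log transforms.

    Parameters
    ----------
    scale : bool
        Scale columns to unit variance (correlation PCA) after centring.

    Attributes (after :meth:`fit`)
    ------------------------------
    feature_names_in_ : columns used (constant columns are dropped with a warning)
    dropped_ : names of dropped constant columns
    signed_ : per-column flag, True where the signed log was applied
    loadings_ : (n_components, n_features) eigenvector rows
    explained_variance_ : eigenvalues
    explained_variance_ratio_ : non-negative, non-increasing, sums to 1
    """

    def __init__(self, scale: bool = True):
        self.scale = scale

    def _transform_columns(self, df: pd.DataFrame):
        out = {}
        for c in df.columns:
            x = df[c].to_numpy(dtype=float)
            if self.signed_[c]:
                out[c] = signed_log1p(x)
            else:
                out[c] = np.log1p(x)
        return pd.DataFrame(out, index=df.index)

    def fit(self, X: pd.DataFrame, y=None):
        df = pd.DataFrame(X).select_dtypes(include=[np.number])
        self.signed_ = {c: bool((df[c] < 0).any()) for c in df.columns}
        T = self._transform_columns(df)
        keep, dropped = [], []
        for c in T.columns:
            (keep if T[c].std(ddof=1) > 0 else dropped).append(c)
        if dropped:
            warnings.warn(f"dropping constant column(s): {dropped}")
        self.dropped_ = dropped
        self.feature_names_in_ = list(keep)
        T = T[keep]
        self.mean_ = T.mean().to_numpy()
        self.scale_ = T.std(ddof=1).to_numpy() if self.scale else np.ones(len(keep))
        Z = (T.to_numpy() - self.mean_) / self.scale_
        n = Z.shape[0]
        # SVD of the standardized matrix == eigendecomposition of the correlation matrix
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        eig = s**2 / (n - 1)
        self.loadings_ = Vt
        self.explained_variance_ = eig
        self.explained_variance_ratio_ = eig / eig.sum()
        self._U_s = (U, s)
        return self

    def transform(self, X: pd.DataFrame):
        if not hasattr(self, "loadings_"):
            raise NotFittedError("LogPCA must be fitted before transform")
        df = pd.DataFrame(X)[self.feature_names_in_]
        T = self._transform_columns(df)
        Z = (T.to_numpy() - self.mean_) / self.scale_
        return Z @ self.loadings_.T

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


@dataclass
class OrdinationResult:
    """Loadings, scores and explained-variance fractions of one ordination."""

    loadings: pd.DataFrame
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    cumulative_explained: np.ndarray


def log_pca(df: pd.DataFrame) -> OrdinationResult:
    """Run the log-PCA and package the result."""
    est = LogPCA()
    scores = est.fit_transform(df)
    loadings = pd.DataFrame(
        est.loadings_,
        columns=est.feature_names_in_,
        index=[f"PC{i + 1}" for i in range(est.loadings_.shape[0])],
    )
    ratio = est.explained_variance_ratio_
    return OrdinationResult(
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=ratio,
        cumulative_explained=np.cumsum(ratio),
    )
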