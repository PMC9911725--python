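"""Principal component analysis of the bioclimatic variables.

The 19 bioclim-style variables mix incommensurate units (°C, mm,
dimensionless indices), so the PCA is computed on the correlation matrix:
each variable is z-scored before the decomposition.  Plots are projected
onto the first ``n_components`` axes (default 4) and those scores serve as
the climatic gradients in all downstream models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = ["ClimatePCA", "fit_climate_pca", "project_climate"]


class ClimatePCA(TransformerMixin, BaseEstimator):
    """Correlation-matrix PCA of per-plot climate variables.

    Parameters
    ----------
    n_components : int, default 4
        Number of axes plots are projected onto.  All eigenvalues are kept
        internally so explained-variance fractions sum to 1 over the full
        spectrum.

    Attributes
    ----------
    mean_, scale_ : per-variable standardization parameters (scale uses the
        sample standard deviation, ddof=1).
    loadings_ : (n_variables, n_components) orthonormal loading matrix.
        Column signs are fixed so each column's largest-magnitude entry is
        positive, making orientations stable across runs.
    explained_variance_ : eigenvalues of all components.
    explained_variance_ratio_ : fractions for all components (sum to 1).
    feature_names_in_ : variable names seen at fit time, when a DataFrame
        was supplied.
    """

    def __init__(self, n_components: int = 4):
        self.n_components = n_components

    def fit(self, X, y=None):
        X, names = _as_matrix(X)
        n, p = X.shape
        if self.n_components < 1 or self.n_components > p:
            raise ValueError(f"n_components must be in 1..{p}")
        if n < self.n_components + 1:
            raise ValueError("need at least n_components + 1 complete-case plots")
        if not np.isfinite(X).all():
            raise ValueError("climate matrix contains missing or non-finite values; "
                             "filter incomplete plots upstream")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        zero = self.scale_ <= 0
        if zero.any():
            bad = [names[i] if names else str(i) for i in np.flatnonzero(zero)]
            raise ValueError(f"zero-variance climate variable(s): {', '.join(bad)}")
        Z = (X - self.mean_) / self.scale_
        k_full = min(n, p)
        pca = PCA(n_components=k_full, svd_solver="full")
        pca.fit(Z)
        load = pca.components_.T  # p x k_full, orthonormal columns
        # deterministic orientation: largest |entry| of each column positive
        flip = np.sign(load[np.abs(load).argmax(axis=0), np.arange(k_full)])
        flip[flip == 0] = 1.0
        load = load * flip
        self.loadings_ = load[:, : self.n_components]
        self._loadings_full = load
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.feature_names_in_ = list(names) if names else None
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        X, names = _as_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("variable-set mismatch with the fitted model")
        if names and self.feature_names_in_ and list(names) != self.feature_names_in_:
            if sorted(names) != sorted(self.feature_names_in_):
                raise ValueError("variable-set mismatch with the fitted model")
            order = [names.index(v) for v in self.feature_names_in_]
            X = X[:, order]
        Z = (X - self.mean_) / self.scale_
        return Z @ self.loadings_

    def inverse_transform_full(self, X):
        """Reconstruct standardized variables from *all* component scores."""
        check_is_fitted(self, "loadings_")
        X, _ = _as_matrix(X)
        Z = (X - self.mean_) / self.scale_
        scores = Z @ self._loadings_full
        return scores @ self._loadings_full.T * self.scale_ + self.mean_


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        cols = [c for c in X.columns if c not in ("plot_id", "climate_missing")]
        return X[cols].to_numpy(dtype=float), cols
    return np.asarray(X, dtype=float), None


def fit_climate_pca(climate: pd.DataFrame, n_components: int = 4) -> ClimatePCA:
    """Fit the correlation PCA on a validated climate table."""
    return ClimatePCA(n_components=n_components).fit(climate)


def project_climate(climate: pd.DataFrame, model: ClimatePCA) -> pd.DataFrame:
    """Plot scores on the retained PCs, keyed by plot_id."""
    scores = model.transform(climate)
    out = pd.DataFrame(
        scores, columns=[f"pc{i + 1}" for i in range(scores.shape[1])]
    )
    if isinstance(climate, pd.DataFrame) and "plot_id" in climate.columns:
        out.insert(0, "plot_id", climate["plot_id"].to_numpy())
    return out
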