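"""Eigenvalue-weighted PCA ranking of internal coordinates.

Given a frames x features matrix of one internal-coordinate kind, the
analysis (i) centers the columns — dihedral columns are first re-wrapped
about their circular mean so the +/-180 degree branch cut cannot inject
spurious variance — (ii) eigendecomposes the sample covariance,
(iii) keeps the smallest leading subset J of principal components whose
cumulative explained variance reaches a threshold (default 90%), and
(iv) scores every feature as

    S_i = sum_{j in J} lambda_j |c_ij|

where lambda_j is the eigenvalue of PC j and c_ij the loading of
feature i on it. Features in the top fraction (default 10%, ceil count)
of S_i are the ones carrying the thermodynamically dominant fluctuations.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InputError, NumericalError
from .internal_coords import FeatureMatrix, FeatureSet

__all__ = [
    "InternalCoordinatePCA",
    "PCARanking",
    "OverlapReport",
    "preprocess",
    "pca",
    "select_pcs",
    "score_and_rank",
    "compare",
]

#: circular variance (1 - mean resultant length) above which a dihedral
#: column is close to the uniform limit and its linearized variance is
#: unreliable
CIRCULAR_VARIANCE_WARN = 0.9


# ---------------------------------------------------------------------------
# functional core
# ---------------------------------------------------------------------------

def _circular_mean_deg(col: np.ndarray) -> float:
    return float(stats.circmean(col, high=180.0, low=-180.0))


def _circular_variance_deg(col: np.ndarray) -> float:
    return float(stats.circvar(col, high=180.0, low=-180.0))


def _rewrap(col: np.ndarray, mu: float) -> np.ndarray:
    """Wrap angles (degrees) into the interval (mu - 180, mu + 180]."""
    out = np.mod(col - mu + 180.0, 360.0) + mu - 180.0
    # mod maps the upper boundary to the lower one; put it back
    return np.where(np.isclose(out, mu - 180.0), mu + 180.0, out)


def preprocess(matrix: FeatureMatrix) -> tuple[np.ndarray, dict]:
    """Center a feature matrix for covariance PCA.

    Bond/angle columns are mean-centered. Dihedral columns are re-wrapped
    about their circular mean before centering, and masked degenerate
    cells are imputed with the column circular mean. Returns the centered
    matrix and a diagnostics dict (imputed cell count, unreliable
    near-uniform circular columns).
    """
    if matrix.n_frames < 2:
        raise InputError("need at least 2 frames")
    values = matrix.values.copy()
    info: dict = {"imputed_cells": 0, "unreliable_features": []}
    if matrix.kind == "dihedral":
        mask = matrix.mask
        for c in range(values.shape[1]):
            col = values[:, c]
            bad = mask[:, c] | ~np.isfinite(col)
            good = col[~bad]
            if good.size == 0:
                raise NumericalError(
                    f"feature {matrix.features.labels()[c]} is degenerate in every frame"
                )
            mu = _circular_mean_deg(good)
            if bad.any():
                col = col.copy()
                col[bad] = mu
                info["imputed_cells"] += int(bad.sum())
            if _circular_variance_deg(good) > CIRCULAR_VARIANCE_WARN:
                info["unreliable_features"].append(c)
            values[:, c] = _rewrap(col, mu)
    elif not np.isfinite(values).all():
        raise InputError("non-finite values in a bond/angle matrix")
    centered = values - values.mean(axis=0)
    return centered, info


def pca(centered: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the sample covariance (n-1 denominator).

    Returns (eigenvalues descending, loadings with features on rows and
    PCs on columns). Sign convention: the largest-magnitude entry of
    each loading column is positive, so results are deterministic.
    """
    n = centered.shape[0]
    if n < 2:
        raise InputError("PCA needs at least 2 frames")
    cov = centered.T @ centered / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: flip each PC so its dominant loading is positive
    dominant = np.argmax(np.abs(evecs), axis=0)
    signs = np.sign(evecs[dominant, np.arange(evecs.shape[1])])
    signs[signs == 0] = 1.0
    return evals, evecs * signs


def select_pcs(eigenvalues: np.ndarray, threshold: float = 0.90) -> np.ndarray:
    """Smallest leading PC subset with cumulative variance >= threshold."""
    if not 0.0 < threshold <= 1.0:
        raise InputError("variance threshold must be in (0, 1]")
    total = float(np.sum(eigenvalues))
    if total <= 0.0:
        raise NumericalError("all eigenvalues are zero: the matrix has no variance")
    frac = np.cumsum(eigenvalues) / total
    k = int(np.searchsorted(frac, threshold - 1e-12) + 1)
    return np.arange(k)


@dataclasses.dataclass
class PCARanking:
    """Full result of the eigenvalue-weighted ranking of one matrix."""

    eigenvalues: np.ndarray         # descending, variance units of the input
    loadings: np.ndarray            # (n_features, n_pcs), orthonormal columns
    explained_variance_ratio: np.ndarray
    selected_pcs: np.ndarray        # indices into eigenvalues (the >=90% set)
    scores: np.ndarray              # S_i per feature
    order: np.ndarray               # feature indices, score-descending
    top_features: np.ndarray        # head of `order`, ceil(fraction * n)
    feature_set: FeatureSet | None = None
    name: str = ""
    diagnostics: dict = dataclasses.field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.scores.shape[0]

    @property
    def top_set(self) -> set[int]:
        return set(int(i) for i in self.top_features)

    def to_frame(self) -> pd.DataFrame:
        labels = (self.feature_set.labels() if self.feature_set is not None
                  else [str(i + 1) for i in range(self.n_features)])
        rank = np.empty(self.n_features, dtype=int)
        rank[self.order] = np.arange(1, self.n_features + 1)
        return pd.DataFrame({
            "feature": labels,
            "score": self.scores,
            "rank": rank,
            "in_top_set": np.isin(np.arange(self.n_features), self.top_features),
        })

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def score_and_rank(eigenvalues: np.ndarray, loadings: np.ndarray,
                   selected: np.ndarray, fraction: float = 0.10,
                   feature_set: FeatureSet | None = None,
                   name: str = "",
                   diagnostics: dict | None = None) -> PCARanking:
    """Compute S_i over the selected PCs and isolate the top fraction.

    Ties in S_i break by ascending feature index (stable sort), so the
    ranking is deterministic across platforms.
    """
    if not 0.0 < fraction <= 1.0:
        raise InputError("top fraction must be in (0, 1]")
    lam = eigenvalues[selected]
    scores = np.abs(loadings[:, selected]) @ lam
    order = np.argsort(-scores, kind="stable")
    n_top = math.ceil(fraction * scores.shape[0])
    total = float(eigenvalues.sum())
    return PCARanking(
        eigenvalues=eigenvalues,
        loadings=loadings,
        explained_variance_ratio=eigenvalues / total if total > 0 else eigenvalues,
        selected_pcs=np.asarray(selected),
        scores=scores,
        order=order,
        top_features=order[:n_top],
        feature_set=feature_set,
        name=name,
        diagnostics=diagnostics or {},
    )


def rank_matrix(matrix: FeatureMatrix, variance_threshold: float = 0.90,
                top_fraction: float = 0.10, name: str = "") -> PCARanking:
    """Convenience one-shot: preprocess -> pca -> select -> score."""
    centered, info = preprocess(matrix)
    evals, evecs = pca(centered)
    selected = select_pcs(evals, variance_threshold)
    return score_and_rank(evals, evecs, selected, top_fraction,
                          feature_set=matrix.features, name=name,
                          diagnostics=info)


# ---------------------------------------------------------------------------
# cross-ensemble comparison
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class OverlapReport:
    """Which ensembles placed each feature in their top set."""

    membership: pd.DataFrame   # features x ensembles, bool, plus multiplicity
    multiplicity_counts: dict[int, int]

    def to_tsv(self, path: str | Path) -> None:
        self.membership.to_csv(path, sep="\t")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ensembles": [c for c in self.membership.columns if c != "multiplicity"],
            "multiplicity_counts": {str(k): v for k, v in
                                    sorted(self.multiplicity_counts.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def compare(rankings: Sequence[PCARanking]) -> OverlapReport:
    """Overlap of top-feature sets across named ensembles.

    All rankings must be over the same feature set (same kind, same
    tuples, same order).
    """
    if not rankings:
        raise InputError("no rankings to compare")
    first = rankings[0]
    for r in rankings[1:]:
        same = (r.n_features == first.n_features)
        if same and r.feature_set is not None and first.feature_set is not None:
            same = (r.feature_set.kind == first.feature_set.kind
                    and r.feature_set.tuples == first.feature_set.tuples)
        if not same:
            raise InputError("rankings are over different feature sets")
    labels = (first.feature_set.labels() if first.feature_set is not None
              else [str(i + 1) for i in range(first.n_features)])
    names = [r.name or f"ensemble_{k}" for k, r in enumerate(rankings)]
    data = {}
    for name, r in zip(names, rankings):
        flags = np.zeros(first.n_features, dtype=bool)
        flags[r.top_features] = True
        data[name] = flags
    df = pd.DataFrame(data, index=pd.Index(labels, name="feature"))
    df["multiplicity"] = df.sum(axis=1).astype(int)
    counts = df["multiplicity"].value_counts().to_dict()
    counts = {int(k): int(v) for k, v in counts.items() if k > 0}
    return OverlapReport(df, counts)


# ---------------------------------------------------------------------------
# estimator interface
# ---------------------------------------------------------------------------

class InternalCoordinatePCA(TransformerMixin, BaseEstimator):
    """Covariance PCA with eigenvalue-weighted feature ranking.

    A scikit-learn transformer: ``fit`` takes a frames x features array
    (or a :class:`FeatureMatrix`), ``transform`` projects centered data
    onto the selected principal components.

    Parameters
    ----------
    variance_threshold : float, default=0.90
        Cumulative explained-variance fraction the selected leading PC
        subset must reach.
    top_fraction : float, default=0.10
        Fraction of features isolated as the top set (ceil count).
    kind : {"bond", "angle", "dihedral", None}, default=None
        Interpretation of the columns; dihedral columns get circular
        re-wrapping. Inferred from a FeatureMatrix input when None.
    scale : bool, default=False
        If True, standardize columns (correlation PCA). Off by default:
        ranking by fluctuation magnitude requires covariances, and each
        matrix holds a single feature kind so units are homogeneous.

    Attributes
    ----------
    eigenvalues_ : ndarray, descending covariance eigenvalues
    loadings_ : ndarray (n_features, n_pcs), orthonormal columns
    explained_variance_ratio_ : ndarray
    selected_pcs_ : ndarray, indices of the >=threshold leading subset
    scores_ : ndarray, S_i per feature
    ranking_ : :class:`PCARanking`
    top_features_ : ndarray of feature indices (score-descending head)
    mean_ : ndarray of column means used for centering
    """

    def __init__(self, variance_threshold: float = 0.90,
                 top_fraction: float = 0.10,
                 kind: str | None = None,
                 scale: bool = False):
        self.variance_threshold = variance_threshold
        self.top_fraction = top_fraction
        self.kind = kind
        self.scale = scale

    def _as_feature_matrix(self, X) -> FeatureMatrix:
        if isinstance(X, FeatureMatrix):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InputError("expected a 2-D frames x features array")
        kind = self.kind or "bond"
        fs = FeatureSet(kind, [self._dummy_tuple(kind, i) for i in range(X.shape[1])])
        return FeatureMatrix(X, fs)

    @staticmethod
    def _dummy_tuple(kind: str, i: int) -> tuple[int, ...]:
        width = {"bond": 2, "angle": 3, "dihedral": 4}[kind]
        base = i * width
        return tuple(range(base, base + width))

    def fit(self, X, y=None):
        matrix = self._as_feature_matrix(X)
        centered, info = preprocess(matrix)
        if self.scale:
            sd = centered.std(axis=0, ddof=1)
            if np.any(sd == 0):
                raise NumericalError("constant column cannot be standardized")
            centered = centered / sd
        self.mean_ = matrix.values.mean(axis=0)
        evals, evecs = pca(centered)
        selected = select_pcs(evals, self.variance_threshold)
        self.ranking_ = score_and_rank(
            evals, evecs, selected, self.top_fraction,
            feature_set=matrix.features, diagnostics=info)
        self.eigenvalues_ = evals
        self.loadings_ = evecs
        self.explained_variance_ratio_ = self.ranking_.explained_variance_ratio
        self.selected_pcs_ = selected
        self.scores_ = self.ranking_.scores
        self.top_features_ = self.ranking_.top_features
        self.n_features_in_ = matrix.n_features
        self._centered_fit_ = centered
        return self

    def transform(self, X):
        if not hasattr(self, "loadings_"):
            raise InputError("estimator is not fitted")
        matrix = self._as_feature_matrix(X)
        centered, _ = preprocess(matrix)
        if self.scale:
            centered = centered / self._centered_fit_.std(axis=0, ddof=1)
        return centered @ self.loadings_[:, self.selected_pcs_]

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X)
        return self._centered_fit_ @ self.loadings_[:, self.selected_pcs_]
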