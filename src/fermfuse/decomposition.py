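"""Linear feature extraction and feature-level fusion.

Per-modality dimensionality reduction uses PCA; the concatenated PC
scores of the two modalities are then unmixed with a fixed-point ICA
(logcosh contrast, symmetric decorrelation) to strip residual
between-modality redundancy before classification.  The ICA model
assumes the square/undercomplete case: the number of independent
components never exceeds the number of concatenated features.

Sign and order conventions are pinned down so that refitting on
identical data reproduces identical models: PCs are ordered by
explained variance, ICs by descending negentropy score, and each
component's sign is chosen so its largest-magnitude loading is
positive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureMatrix

__all__ = [
    "PCAModel",
    "ICAModel",
    "fit_pca",
    "project_pca",
    "concat_features",
    "fit_ica",
    "transform_ica",
    "amari_index",
]


class SampleMismatchError(ValueError):
    """Raised when two feature blocks do not share the same samples in order."""


class NonGaussianityWarning(UserWarning):
    """Emitted when ICA is asked to unmix data that looks Gaussian."""


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Flip each component (row) so its largest-|.| element is positive."""
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(components.shape[0]), idx])
    signs[signs == 0] = 1.0
    return components * signs[:, None]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Fitted principal-component transform.

    Attributes
    ----------
    mean_ : ndarray, shape (p,)
        Column means of the training block; projection is mean-centred.
    components_ : ndarray, shape (k, p)
        Orthonormal loading vectors, one per row, ordered by variance.
    explained_variance_ : ndarray, shape (k,)
        Score variance along each component (eigenvalues, ddof=1).
    explained_variance_ratio_ : ndarray, shape (k,)
        Fractions of total training variance, non-increasing.
    """

    mean_: np.ndarray
    components_: np.ndarray
    explained_variance_: np.ndarray
    explained_variance_ratio_: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.components_.shape[0]


def _as_array(features) -> tuple[np.ndarray, list[str], list | None]:
    if isinstance(features, FeatureMatrix):
        return (
            features.to_numpy(),
            [str(c) for c in features.feature_names],
            list(features.sample_ids),
        )
    arr = np.asarray(features, dtype=float)
    return arr, [f"f{i}" for i in range(arr.shape[1])], None


def fit_pca(features, k: int) -> PCAModel:
    """Fit a k-component PCA on the given rows via SVD of the centred matrix.

    ``k`` must satisfy ``k <= min(rows - 1, columns)`` so every retained
    component has a well-defined variance.
    """
    X, names, _ = _as_array(features)
    n, p = X.shape
    k_max = min(n - 1, p)
    if not 1 <= k <= k_max:
        raise ValueError(f"k={k} out of range [1, {k_max}] for a {n}x{p} matrix")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    ev_all = s**2 / (n - 1)
    total = ev_all.sum()
    components = _fix_signs(vt[:k])
    ratios = ev_all[:k] / total if total > 0 else np.zeros(k)
    return PCAModel(
        mean_=mean,
        components_=components,
        explained_variance_=ev_all[:k],
        explained_variance_ratio_=ratios,
        feature_names=names,
    )


def project_pca(model: PCAModel, features) -> FeatureMatrix | np.ndarray:
    """Project (held-out or training) rows onto the fitted components."""
    X, _, ids = _as_array(features)
    if X.shape[1] != model.components_.shape[1]:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model "
            f"({model.components_.shape[1]})"
        )
    scores = (X - model.mean_) @ model.components_.T
    if ids is None:
        return scores
    df = pd.DataFrame(
        scores, index=ids, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
    )
    df.index.name = "sample_id"
    return FeatureMatrix(df)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

def concat_features(enose_scores: FeatureMatrix, nirs_scores: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation of per-modality scores, e-nose first.

    Both blocks must cover the same samples in the same order; a
    mismatch (including a shuffled row order) raises
    :class:`SampleMismatchError`.
    """
    if not enose_scores.sample_ids.equals(nirs_scores.sample_ids):
        raise SampleMismatchError(
            "e-nose and NIRS score blocks do not share the same samples in order"
        )
    left = enose_scores.values.add_prefix("enose_")
    right = nirs_scores.values.add_prefix("nirs_")
    fused = pd.concat([left, right], axis=1)
    return FeatureMatrix(
        fused,
        provenance={
            "enose_columns": list(left.columns),
            "nirs_columns": list(right.columns),
        },
    )


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

@dataclass
class ICAModel:
    """Fitted independent-component unmixing.

    The generative model is ``x = A s`` with statistically independent,
    non-Gaussian sources ``s``; the fit produces an unmixing matrix so
    that ``y = W x_centred`` recovers the sources up to permutation,
    sign and scale.

    Attributes
    ----------
    mean_ : ndarray, shape (p,)
    unmixing_ : ndarray, shape (n_ics, p)
        Full unmixing (whitening folded in); rows ordered by descending
        explained input variance, signs fixed.
    mixing_ : ndarray, shape (p, n_ics)
        Pseudo-inverse of the unmixing matrix.
    whitening_ : ndarray, shape (n_ics, p)
    negentropy_ : ndarray, shape (n_ics,)
        Squared deviation of E[log cosh y] from its Gaussian value, used
        to order components.
    converged : bool
    """

    mean_: np.ndarray
    unmixing_: np.ndarray
    mixing_: np.ndarray
    whitening_: np.ndarray
    negentropy_: np.ndarray
    converged: bool
    n_iter: int

    @property
    def n_components(self) -> int:
        return self.unmixing_.shape[0]


_LOGCOSH_GAUSS = 0.3745232061467533  # E[log cosh Z], Z ~ N(0,1)


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    # W <- (W W^T)^(-1/2) W
    s, u = np.linalg.eigh(W @ W.T)
    s = np.clip(s, 1e-12, None)
    return (u / np.sqrt(s)) @ u.T @ W


def fit_ica(
    features,
    n_ics: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> ICAModel:
    """Fixed-point ICA with logcosh contrast and symmetric decorrelation.

    The data are whitened to ``n_ics`` dimensions by PCA first; the
    rotation is then estimated by the fixed-point iteration.  The fit is
    deterministic for a fixed ``seed``.  Non-convergence emits a warning
    and returns the best iterate; data whose every recovered component
    has near-zero negentropy (i.e. looks Gaussian) also draws a warning,
    because the unmixing is then not identifiable.
    """
    X, _, _ = _as_array(features)
    n, p = X.shape
    if not 1 <= n_ics <= p:
        raise ValueError(f"n_ics={n_ics} out of range [1, {p}]")
    if n < p:
        raise ValueError(f"need at least as many rows ({n}) as columns ({p})")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if s[min(n_ics, len(s)) - 1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("data rank is below n_ics; cannot whiten")
    # rows of K map data to unit-variance whitened coordinates
    K = (vt[:n_ics] / s[:n_ics, None]) * np.sqrt(n - 1)
    Z = Xc @ K.T  # n x n_ics, identity covariance (ddof=1)

    rng = np.random.default_rng(seed)
    W = _sym_decorrelate(rng.standard_normal((n_ics, n_ics)))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Y = Z @ W.T  # n x n_ics
        g = np.tanh(Y)
        g_prime = 1.0 - g**2
        W_new = (g.T @ Z) / n - g_prime.mean(axis=0)[:, None] * W
        W_new = _sym_decorrelate(W_new)
        # convergence: rows of W_new align with rows of W up to sign
        delta = np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0))
        W = W_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"ICA did not converge in {max_iter} iterations "
            f"(last delta {delta:.2e}); returning best iterate",
            RuntimeWarning,
        )

    # order by descending explained input variance (squared norm of the
    # mixing column): with unit-variance independent components, IC j
    # accounts for ||A_j||^2 of the input variance, so this ranking
    # plays the role PCA's eigenvalue order plays and keeps "the first
    # n components" meaningful for sequential count selection.  The
    # negentropy score of each component is kept as a diagnostic.
    Y = Z @ W.T
    negentropy = (np.mean(np.log(np.cosh(Y)), axis=0) - _LOGCOSH_GAUSS) ** 2
    mixing = np.linalg.pinv(W @ K)
    order = np.argsort(-np.linalg.norm(mixing, axis=0) ** 2, kind="stable")
    W = W[order]
    negentropy = negentropy[order]
    unmixing = _fix_signs(W @ K)
    if np.all(negentropy < 1e-6):
        warnings.warn(
            "all recovered components have near-zero negentropy; the data "
            "look Gaussian and the unmixing is not identifiable",
            NonGaussianityWarning,
        )
    return ICAModel(
        mean_=mean,
        unmixing_=unmixing,
        mixing_=np.linalg.pinv(unmixing),
        whitening_=K,
        negentropy_=negentropy,
        converged=converged,
        n_iter=it,
    )


def transform_ica(model: ICAModel, features) -> FeatureMatrix | np.ndarray:
    """Apply the fitted unmixing to (training or held-out) rows."""
    X, _, ids = _as_array(features)
    if X.shape[1] != model.unmixing_.shape[1]:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model "
            f"({model.unmixing_.shape[1]})"
        )
    scores = (X - model.mean_) @ model.unmixing_.T
    if ids is None:
        return scores
    df = pd.DataFrame(
        scores, index=ids, columns=[f"IC{i + 1}" for i in range(scores.shape[1])]
    )
    df.index.name = "sample_id"
    out = FeatureMatrix(df)
    if isinstance(features, FeatureMatrix):
        out.provenance = dict(features.provenance)
    return out


def amari_index(P: np.ndarray) -> float:
    """Amari separation index of a matrix ``P = W @ A``.

    Zero iff ``P`` is a scaled permutation matrix (perfect source
    recovery up to order/sign/scale); normalized to [0, 1].
    """
    P = np.abs(np.asarray(P, dtype=float))
    n = P.shape[0]
    if P.shape != (n, n):
        raise ValueError("amari_index needs a square matrix")
    row = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    col = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((row.sum() + col.sum()) / (2.0 * n * (n - 1)))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: PCAModel | ICAModel, path: str | Path) -> None:
    """Serialize a fitted transform as JSON (header + matrices)."""
    path = Path(path)
    if isinstance(model, PCAModel):
        payload = {
            "kind": "pca",
            "mean": model.mean_.tolist(),
            "components": model.components_.tolist(),
            "explained_variance": model.explained_variance_.tolist(),
            "explained_variance_ratio": model.explained_variance_ratio_.tolist(),
            "feature_names": model.feature_names,
        }
    else:
        payload = {
            "kind": "ica",
            "mean": model.mean_.tolist(),
            "unmixing": model.unmixing_.tolist(),
            "mixing": model.mixing_.tolist(),
            "whitening": model.whitening_.tolist(),
            "negentropy": model.negentropy_.tolist(),
            "converged": model.converged,
            "n_iter": model.n_iter,
        }
    path.write_text(json.dumps(payload))


def load_model(path: str | Path) -> PCAModel | ICAModel:
    payload = json.loads(Path(path).read_text())
    if payload["kind"] == "pca":
        return PCAModel(
            mean_=np.array(payload["mean"]),
            components_=np.array(payload["components"]),
            explained_variance_=np.array(payload["explained_variance"]),
            explained_variance_ratio_=np.array(payload["explained_variance_ratio"]),
            feature_names=payload["feature_names"],
        )
    return ICAModel(
        mean_=np.array(payload["mean"]),
        unmixing_=np.array(payload["unmixing"]),
        mixing_=np.array(payload["mixing"]),
        whitening_=np.array(payload["whitening"]),
        negentropy_=np.array(payload["negentropy"]),
        converged=payload["converged"],
        n_iter=payload["n_iter"],
    )
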