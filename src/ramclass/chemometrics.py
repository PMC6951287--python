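"""PCA and discriminant analysis of principal components (DAPC).

Spectra are mean-centered and decomposed by SVD; a linear discriminant
classifier is then built in the space of the first k principal-component
scores: per-class score means, a pooled within-class covariance (inverted by
a tolerance-based pseudo-inverse so that rank-deficient covariances at large
k degrade gracefully instead of erroring), and uniform class priors. The
discriminant score of class c for a score vector s is

    delta_c = s' W^+ mu_c - 1/2 mu_c' W^+ mu_c + ln(prior_c)

and the predicted class is the argmax, ties broken by class order
(alphabetical). Canonical (linear-discriminant) coordinates for cluster
plots come from the eigenvectors of W^+ B, with B the between-class scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SpectralDataset


@dataclass
class PCAModel:
    """Mean spectrum, orthonormal loadings, and explained-variance fractions.

    ``loadings`` is n_components x n_points with orthonormal rows, the sign
    of each row fixed so its largest-magnitude entry is positive (runs are
    bit-reproducible). ``explained_var_frac`` is relative to the total
    variance of the training data, so the cumulative sum is <= 1.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray
    explained_var_frac: np.ndarray
    n_fit: int
    training_scores: np.ndarray = field(repr=False, default=None)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def fit_pca(d: SpectralDataset, n_components: int) -> PCAModel:
    """Mean-centered SVD of the spectra matrix.

    ``n_components`` must not exceed min(n_rows - 1, n_points). A dataset
    with zero total variance (all rows identical) is an error.
    """
    X = d.matrix
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 spectra")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} out of range [1, {min(n - 1, p)}] for a {n}x{p} matrix"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float((Xc**2).sum()) / (n - 1)
    if total_var == 0.0:
        raise ValueError("dataset has zero variance (all spectra identical)")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-magnitude entry of each loading positive
    for i in range(n_components):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    loadings = Vt[:n_components].copy()
    scores = U[:, :n_components] * S[:n_components]
    evf = (S[:n_components] ** 2 / (n - 1)) / total_var
    return PCAModel(mean, loadings, evf, n, scores)


def project(m: PCAModel, x: np.ndarray, k: int | None = None) -> np.ndarray:
    """Score vector of a spectrum-shaped vector on the first k components."""
    x = np.asarray(x, dtype=float)
    if x.shape != m.mean_spectrum.shape:
        raise ValueError(f"vector of length {x.size} does not match model grid ({m.mean_spectrum.size})")
    k = m.n_components if k is None else k
    if not 1 <= k <= m.n_components:
        raise ValueError(f"k={k} out of range [1, {m.n_components}]")
    return m.loadings[:k] @ (x - m.mean_spectrum)


@dataclass
class DAPCModel:
    """Linear discriminant classifier in retained-PC score space."""

    pca: PCAModel
    k: int
    classes: list[str]
    class_means: np.ndarray  # n_classes x k
    pooled_cov_inv: np.ndarray  # k x k, pseudo-inverse of pooled within-class cov
    priors: np.ndarray
    class_counts: np.ndarray


def _discriminant_stats(scores: np.ndarray, labels: np.ndarray, classes: list[str]):
    """Per-class means and pseudo-inverted pooled within-class covariance."""
    k = scores.shape[1]
    means = np.vstack([scores[labels == c].mean(axis=0) for c in classes])
    counts = np.array([(labels == c).sum() for c in classes])
    W = np.zeros((k, k))
    for c, mu in zip(classes, means):
        R = scores[labels == c] - mu
        W += R.T @ R
    W /= max(len(scores) - len(classes), 1)
    Winv = np.linalg.pinv(W, hermitian=True)
    Winv = (Winv + Winv.T) / 2.0
    return means, counts, Winv


def fit_dapc(d: SpectralDataset, k: int) -> DAPCModel:
    """Fit PCA with k retained components, then the discriminant statistics.

    Requires >= 2 classes with >= 2 spectra each. Priors are uniform over
    classes (class-size-agnostic, matching the 50% two-class chance level).
    """
    labels = d.labels()
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("DAPC needs at least 2 classes")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 spectra")
    pca = fit_pca(d, k)
    means, counts, Winv = _discriminant_stats(pca.training_scores, labels, classes)
    priors = np.full(len(classes), 1.0 / len(classes))
    return DAPCModel(pca, k, classes, means, Winv, priors, counts)


def _delta(m: DAPCModel, s: np.ndarray) -> np.ndarray:
    Wm = m.pooled_cov_inv @ m.class_means.T  # k x n_classes
    return s @ Wm - 0.5 * np.einsum("ck,kc->c", m.class_means, Wm) + np.log(m.priors)


def classify(m: DAPCModel, x: np.ndarray):
    """Predict the class of one spectrum-shaped vector.

    Returns ``(label, scores)`` with one discriminant score per class in
    ``m.classes`` order; ties go to the first class in that order.
    """
    s = project(m.pca, x, m.k)
    scores = _delta(m, s)
    return m.classes[int(np.argmax(scores))], scores


def classify_matrix(m: DAPCModel, X: np.ndarray) -> list[str]:
    """Vectorized classify over the rows of a matrix on the model grid."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    S = (X - m.pca.mean_spectrum) @ m.pca.loadings[: m.k].T
    D = S @ (m.pooled_cov_inv @ m.class_means.T)
    D = D - 0.5 * np.einsum(
        "ck,kc->c", m.class_means, m.pooled_cov_inv @ m.class_means.T
    ) + np.log(m.priors)
    return [m.classes[i] for i in np.argmax(D, axis=1)]


def canonical_axes(m: DAPCModel) -> np.ndarray:
    """Canonical discriminant axes: leading eigenvectors of W^+ B.

    B is the between-class scatter of the training class means (weighted by
    class counts). At most min(2, n_classes - 1) axes are returned, each unit
    norm with its largest-magnitude entry positive.
    """
    grand = (m.class_counts[:, None] * m.class_means).sum(axis=0) / m.class_counts.sum()
    Mc = m.class_means - grand
    B = (m.class_counts[:, None] * Mc).T @ Mc
    evals, evecs = np.linalg.eig(m.pooled_cov_inv @ B)
    order = np.argsort(-evals.real)
    n_axes = min(2, len(m.classes) - 1)
    axes = evecs[:, order[:n_axes]].real.T
    for i in range(axes.shape[0]):
        axes[i] /= np.linalg.norm(axes[i]) or 1.0
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    return axes


def canonical_scores(m: DAPCModel, d: SpectralDataset) -> pd.DataFrame:
    """Per-spectrum table of predictions and the first two canonical coordinates.

    Columns: specimen_id, true_label, predicted_label, correct, ld1, ld2.
    With two classes there is a single canonical axis and ld2 is zero.
    """
    axes = canonical_axes(m)
    S = (d.matrix - m.pca.mean_spectrum) @ m.pca.loadings[: m.k].T
    coords = S @ axes.T
    if coords.shape[1] < 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
    preds = classify_matrix(m, d.matrix)
    true = d.labels()
    return pd.DataFrame(
        {
            "specimen_id": d.meta["specimen_id"].astype(str),
            "true_label": true,
            "predicted_label": preds,
            "correct": [p == t for p, t in zip(preds, true)],
            "ld1": coords[:, 0],
            "ld2": coords[:, 1],
        }
    )
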