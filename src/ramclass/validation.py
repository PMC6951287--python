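"""Grouped leave-one-out validation, metrics, PC sweeps, and chance baselines.

Validation is grouped: the unit held out in each fold is a specimen (its
averaged spectrum) or an individual (all of that individual's spectra at
once). PCA and the discriminant statistics are refit in every fold, so the
held-out unit never leaks into centering, loadings, or covariance. The
metrics follow the clinical-screening convention: accuracy is the percentage
of spectra classified correctly; sensitivity is the true-positive rate for a
user-designated positive class (disease present); specificity is the
true-negative rate.

Two chance baselines put those numbers in context: a uniform-guess model
(labels assigned uniformly at random over the class set, giving accuracy
100/k_classes regardless of class representation — 50% for two classes) and
a permutation model (predicted labels drawn as a random permutation of the
true labels, estimated by Monte Carlo with a standard error).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemometrics import _discriminant_stats, fit_pca
from .io import SpectralDataset


class UndefinedMetricWarning(UserWarning):
    """A ratio with zero denominator was requested; reported as NaN."""


@dataclass
class ConfusionCounts:
    """Counts per ordered (true, predicted) class pair."""

    classes: list[str]
    counts: np.ndarray  # n_classes x n_classes int, rows = true, cols = predicted

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.classes), len(self.classes)):
            raise ValueError("counts must be square over the class list")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_records(cls, true, predicted, classes=None) -> "ConfusionCounts":
        true = list(map(str, true))
        predicted = list(map(str, predicted))
        classes = sorted(set(true) | set(predicted)) if classes is None else list(classes)
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(true, predicted):
            counts[idx[t], idx[p]] += 1
        return cls(classes, counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ValidationReport:
    """Machine twin of a PC-count sweep table plus per-fold predictions."""

    table: pd.DataFrame  # n_pcs, variance_explained_pct, accuracy_pct, sensitivity_pct, specificity_pct
    folds: pd.DataFrame  # n_pcs, unit_id, true_label, predicted_label
    positive_class: str


@dataclass
class ChanceReport:
    """Expected metrics of a label-agnostic random classifier."""

    model: str  # 'uniform-guess' | 'permutation'
    classes: list[str]
    accuracy_pct: float
    sensitivity_pct: dict[str, float]
    specificity_pct: dict[str, float]
    accuracy_se_pct: float | None = None
    n_mc: int | None = None


def metrics(c: ConfusionCounts, positive_class: str):
    """Accuracy, sensitivity, and specificity (percent) from confusion counts.

    Accuracy is 100 * diagonal / total. Sensitivity and specificity reduce
    multi-class counts one-vs-rest against ``positive_class``. A ratio with
    an empty denominator is returned as NaN with an UndefinedMetricWarning,
    never silently coerced to 0 or 100.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    if positive_class not in c.classes:
        raise ValueError(f"positive class {positive_class!r} not among {c.classes}")
    i = c.classes.index(positive_class)
    tp = int(c.counts[i, i])
    fn = int(c.counts[i].sum()) - tp
    fp = int(c.counts[:, i].sum()) - tp
    tn = c.total - tp - fn - fp
    accuracy = 100.0 * int(np.trace(c.counts)) / c.total

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined: zero denominator", UndefinedMetricWarning)
            return float("nan")
        return 100.0 * num / den

    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    return accuracy, sensitivity, specificity


def _unit_groups(d: SpectralDataset, unit: str):
    if unit not in ("specimen", "individual"):
        raise ValueError("unit must be 'specimen' or 'individual'")
    key = d.meta[f"{unit}_id"].astype(str)
    groups: dict[str, np.ndarray] = {}
    for uid in key.unique():
        idx = np.flatnonzero((key == uid).to_numpy())
        labels = set(d.meta["class_label"].iloc[idx].astype(str))
        if len(labels) > 1:
            raise ValueError(f"validation unit {uid!r} has conflicting class labels")
        groups[uid] = idx
    return groups


def _loo_predictions(d: SpectralDataset, k_list, unit: str) -> pd.DataFrame:
    """Grouped LOO predictions for every k in ``k_list`` (shared per-fold PCA).

    Within a fold the PCA loadings are nested across k, so one decomposition
    at max(k_list) serves every retained-PC count; the discriminant
    statistics are rebuilt per k. Identical to refitting per k, only faster.
    """
    ks = sorted(set(int(k) for k in k_list))
    if ks[0] < 1:
        raise ValueError("retained-PC counts must be >= 1")
    groups = _unit_groups(d, unit)
    labels_all = d.labels()
    records = []
    for uid, idx in groups.items():
        mask = np.ones(d.n_scans, dtype=bool)
        mask[idx] = False
        train_idx = np.flatnonzero(mask)
        train_labels = labels_all[train_idx]
        classes = sorted(set(train_labels))
        if len(classes) < 2:
            raise ValueError(
                f"training fold for unit {uid!r} has fewer than 2 classes; "
                "is it the only unit of its class?"
            )
        for c in classes:
            if (train_labels == c).sum() < 2:
                raise ValueError(
                    f"training fold for unit {uid!r} leaves class {c!r} with < 2 spectra"
                )
        kmax = ks[-1]
        limit = min(len(train_idx) - 1, d.n_points)
        if kmax > limit:
            raise ValueError(
                f"k={kmax} exceeds the {limit} components available in the "
                f"training fold for unit {uid!r}"
            )
        train = d.subset(train_idx)
        pca = fit_pca(train, kmax)
        held = (d.matrix[idx] - pca.mean_spectrum) @ pca.loadings.T  # n_held x kmax
        for k in ks:
            means, _, Winv = _discriminant_stats(
                pca.training_scores[:, :k], train_labels, classes
            )
            priors = np.full(len(classes), 1.0 / len(classes))
            D = held[:, :k] @ (Winv @ means.T)
            D = D - 0.5 * np.einsum("ck,kc->c", means, Winv @ means.T) + np.log(priors)
            preds = [classes[j] for j in np.argmax(D, axis=1)]
            for row_i, p in zip(idx, preds):
                records.append(
                    {
                        "n_pcs": k,
                        "unit_id": uid,
                        "true_label": labels_all[row_i],
                        "predicted_label": p,
                    }
                )
    return pd.DataFrame(records)


def loo_validate(d: SpectralDataset, k: int, unit: str = "specimen"):
    """Grouped leave-one-out validation at a single retained-PC count.

    Every unit is held out once; the DAPC model (PCA included) is refit on
    the remainder and the unit's spectra are classified by the fold model.
    Returns ``(ConfusionCounts, fold_records)``.
    """
    folds = _loo_predictions(d, [k], unit)
    counts = ConfusionCounts.from_records(
        folds["true_label"], folds["predicted_label"], classes=d.classes
    )
    return counts, folds


def pc_sweep(
    d: SpectralDataset,
    k_list,
    positive_class: str,
    unit: str = "specimen",
) -> ValidationReport:
    """LOO metrics versus retained-PC count, one report row per k.

    The variance-explained column is the cumulative explained variance of a
    full-data PCA (one value per k, as a sweep table prints it); accuracy,
    sensitivity, and specificity come from the grouped LOO folds. Duplicate
    k values are deduplicated; rows are sorted ascending by k.
    """
    ks = sorted(set(int(k) for k in k_list))
    full_pca = fit_pca(d, min(max(ks), d.n_scans - 1, d.n_points))
    cum_var = 100.0 * np.cumsum(full_pca.explained_var_frac)
    folds = _loo_predictions(d, ks, unit)
    rows = []
    for k in ks:
        sub = folds[folds["n_pcs"] == k]
        counts = ConfusionCounts.from_records(
            sub["true_label"], sub["predicted_label"], classes=d.classes
        )
        acc, sens, spec = metrics(counts, positive_class)
        rows.append(
            {
                "n_pcs": k,
                "variance_explained_pct": float(cum_var[min(k, len(cum_var)) - 1]),
                "accuracy_pct": acc,
                "sensitivity_pct": sens,
                "specificity_pct": spec,
            }
        )
    return ValidationReport(pd.DataFrame(rows), folds, positive_class)


def random_chance(
    labels,
    model: str = "uniform-guess",
    n_mc: int = 10_000,
    seed: int = 0,
) -> ChanceReport:
    """Chance-level accuracy, sensitivity, and specificity for a label list.

    ``uniform-guess``: closed form for a classifier drawing labels uniformly
    over the class set — accuracy and every sensitivity are 100/k_classes and
    every specificity is 100*(k_classes-1)/k_classes, independent of class
    representation. ``permutation``: predictions are a random permutation of
    the true labels; metrics are Monte-Carlo means over ``n_mc`` replicates
    with a standard error. Deterministic for fixed seed.
    """
    labels = np.array([str(x) for x in labels])
    classes = sorted(set(labels))
    kc = len(classes)
    if kc < 2:
        raise ValueError("chance baselines need at least 2 classes")
    if model == "uniform-guess":
        return ChanceReport(
            model="uniform-guess",
            classes=classes,
            accuracy_pct=100.0 / kc,
            sensitivity_pct={c: 100.0 / kc for c in classes},
            specificity_pct={c: 100.0 * (kc - 1) / kc for c in classes},
        )
    if model != "permutation":
        raise ValueError("model must be 'uniform-guess' or 'permutation'")
    rng = np.random.default_rng(seed)
    acc = np.empty(n_mc)
    sens = {c: np.empty(n_mc) for c in classes}
    spec = {c: np.empty(n_mc) for c in classes}
    for r in range(n_mc):
        perm = rng.permutation(labels)
        hit = perm == labels
        acc[r] = hit.mean()
        for c in classes:
            pos = labels == c
            sens[c][r] = hit[pos].mean()
            spec[c][r] = (perm[~pos] != c).mean()
    return ChanceReport(
        model="permutation",
        classes=classes,
        accuracy_pct=100.0 * float(acc.mean()),
        sensitivity_pct={c: 100.0 * float(v.mean()) for c, v in sens.items()},
        specificity_pct={c: 100.0 * float(v.mean()) for c, v in spec.items()},
        accuracy_se_pct=100.0 * float(acc.std(ddof=1)) / np.sqrt(n_mc),
        n_mc=n_mc,
    )
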