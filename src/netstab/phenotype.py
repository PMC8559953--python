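"""Variability of a brain-phenotype classification under perturbation.

Connectome vectors are reduced with PCA and classified with a
ridge-penalized logistic regression under stratified k-fold
cross-validation.  The number of components is the smallest count whose
cumulative explained-variance fraction, averaged over the training folds,
exceeds a threshold (default 0.90).  The whole analysis is repeated over
resamplings that draw one perturbed connectome per subject, yielding a
distribution of model performances around the reference run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ModelRun",
    "PerformanceSummary",
    "select_components",
    "classify_cohort",
    "resampled_performance",
]

#: fixed ridge-penalty strength of the logistic classifier
LOGISTIC_C = 1.0


@dataclass
class ModelRun:
    """Metrics of one cross-validated classification run."""

    sampling_index: int
    k: int
    n_components: int
    explained_variance: float   # cumulative fraction at the selected count
    accuracy: float             # pooled over held-out predictions
    f1: float                   # binary positive-class F1 (flag: macro optional)
    fold_accuracies: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0 and 0.0 <= self.f1 <= 1.0):
            raise ValueError("accuracy and F1 must lie in [0, 1]")
        if self.n_components < 1:
            raise ValueError("component count must be >= 1")


def _fold_indices(y: np.ndarray, k: int, seed: int):
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def select_components(
    x: np.ndarray,
    y: np.ndarray | None = None,
    k: int = 5,
    threshold: float = 0.90,
    seed: int = 0,
) -> int:
    """Smallest component count explaining more than ``threshold`` variance.

    PCA is fit on the training portion of each fold; the cumulative
    explained-variance fractions are averaged across folds and the
    smallest count exceeding the threshold is returned.  With ``y`` None
    (or k=1) a single fit on all rows is used.  Degenerate rank-deficient
    input falls back to the available rank with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 training samples")
    curves = []
    if y is not None and k > 1:
        splits = _fold_indices(np.asarray(y), k, seed)
        train_sets = [tr for tr, _ in splits]
    else:
        train_sets = [np.arange(x.shape[0])]
    max_comp = min(x.shape[1], min(len(tr) for tr in train_sets))
    for tr in train_sets:
        pca = PCA(n_components=min(max_comp, len(tr), x.shape[1]))
        pca.fit(x[tr])
        ratios = np.zeros(max_comp)
        r = pca.explained_variance_ratio_
        ratios[: len(r)] = r[:max_comp]
        curves.append(np.cumsum(ratios))
    mean_curve = np.mean(curves, axis=0)
    above = np.flatnonzero(mean_curve > threshold)
    if above.size == 0:
        warnings.warn(
            "explained variance never exceeds the threshold; "
            "falling back to full rank",
            RuntimeWarning,
        )
        return int(len(mean_curve))
    return int(above[0] + 1)


def classify_cohort(
    x: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    threshold: float = 0.90,
    seed: int = 0,
    sampling_index: int = -1,
    f1_average: str = "binary",
) -> ModelRun:
    """Stratified k-fold PCA + logistic-regression classification.

    Component selection and all fitting use training folds only;
    accuracy and F1 are pooled over the held-out predictions.  ``k`` may
    be the number of subjects, which is equivalent to leave-one-out.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) != 2:
        raise ValueError("binary labels required")
    n = x.shape[0]
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, n_subjects], got {k}")
    counts = np.bincount(y)
    if k > counts.min() and k < n:
        raise ValueError(
            f"stratification error: k={k} exceeds minority class size {counts.min()}"
        )

    if k == n:  # leave-one-out: stratification degenerates to single-row folds
        splits = [
            (np.delete(np.arange(n), i), np.array([i])) for i in range(n)
        ]
    else:
        splits = _fold_indices(y, k, seed)

    n_components = select_components(x, y if k < n else None,
                                     k=min(k, 5), threshold=threshold, seed=seed)
    preds = np.empty(n, dtype=int)
    fold_accs = []
    explained = []
    for tr, te in splits:
        n_comp = min(n_components, len(tr), x.shape[1])
        scaler = StandardScaler().fit(x[tr])
        pca = PCA(n_components=n_comp).fit(scaler.transform(x[tr]))
        explained.append(float(np.sum(pca.explained_variance_ratio_)))
        clf = LogisticRegression(C=LOGISTIC_C, max_iter=2000)
        if len(np.unique(y[tr])) < 2:
            raise ValueError("single-class training fold")
        clf.fit(pca.transform(scaler.transform(x[tr])), y[tr])
        preds[te] = clf.predict(pca.transform(scaler.transform(x[te])))
        fold_accs.append(float(accuracy_score(y[te], preds[te])))

    return ModelRun(
        sampling_index=sampling_index,
        k=k,
        n_components=n_components,
        explained_variance=float(np.mean(explained)),
        accuracy=float(accuracy_score(y, preds)),
        f1=float(f1_score(y, preds, average=f1_average, zero_division=0)),
        fold_accuracies=fold_accs,
    )


@dataclass
class PerformanceSummary:
    """Reference run plus the distribution over perturbed resamplings."""

    reference: ModelRun
    runs: list[ModelRun]

    @property
    def accuracy_range(self) -> tuple[float, float]:
        accs = [r.accuracy for r in self.runs]
        return (min(accs), max(accs))

    @property
    def f1_range(self) -> tuple[float, float]:
        f1s = [r.f1 for r in self.runs]
        return (min(f1s), max(f1s))

    @property
    def explained_variance_range(self) -> tuple[float, float]:
        evs = [r.explained_variance for r in self.runs]
        return (min(evs), max(evs))

    def to_json_summary(self) -> dict:
        accs = [r.accuracy for r in self.runs]
        return {
            "n_repeats": len(self.runs),
            "reference_accuracy": self.reference.accuracy,
            "reference_f1": self.reference.f1,
            "accuracy_min": min(accs),
            "accuracy_max": max(accs),
            "accuracy_mean": float(np.mean(accs)),
            "f1_min": self.f1_range[0],
            "f1_max": self.f1_range[1],
            "explained_variance_min": self.explained_variance_range[0],
            "explained_variance_max": self.explained_variance_range[1],
        }


def resampled_performance(
    reference_per_subject: Sequence[np.ndarray] | Mapping[int, np.ndarray],
    sims_per_subject: Sequence[Sequence[np.ndarray]] | Mapping[int, Sequence[np.ndarray]],
    labels: Sequence[int],
    k: int = 5,
    n_repeats: int = 20,
    threshold: float = 0.90,
    seed: int = 0,
) -> PerformanceSummary:
    """Repeat the classification over random samplings of perturbed runs.

    Each repeat draws one perturbed connectome vector per subject
    uniformly at random (seeded) and refits the model; the reference
    vectors give the comparison run.  Inputs are per-subject vectorized
    connectomes (or matrices, which are vectorized by upper triangle).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    def vec(a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=np.float64)
        if a.ndim == 2 and a.shape[0] == a.shape[1]:
            iu = np.triu_indices(a.shape[0], k=1)
            return a[iu]
        return a.ravel()

    if isinstance(reference_per_subject, Mapping):
        order = sorted(reference_per_subject)
        refs = [vec(reference_per_subject[s]) for s in order]
        sims = [[vec(v) for v in sims_per_subject[s]] for s in order]
    else:
        refs = [vec(v) for v in reference_per_subject]
        sims = [[vec(v) for v in subj] for subj in sims_per_subject]
    y = np.asarray(labels, dtype=int)
    if not all(len(s) >= 2 for s in sims):
        raise ValueError("need >= 2 perturbed simulations per subject")

    reference = classify_cohort(
        np.stack(refs), y, k=k, threshold=threshold, seed=seed, sampling_index=-1
    )
    rng = np.random.default_rng(seed)
    runs = []
    for rep in range(n_repeats):
        x = np.stack([subj[rng.integers(len(subj))] for subj in sims])
        runs.append(
            classify_cohort(
                x, y, k=k, threshold=threshold,
                seed=seed + 1 + rep, sampling_index=rep,
            )
        )
    return PerformanceSummary(reference=reference, runs=runs)
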