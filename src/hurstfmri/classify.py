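"""RBF-SVM classification under leave-one-out CV with nested feature selection.

The procedure mirrors the flowchart of the underlying study: for every pair
(gamma, C) on a 33 x 33 dyadic grid, each LOOCV fold re-runs the t-test /
Fisher-score selection on its training rows only, z-scores the retained
features with training statistics, trains a soft-margin SVM, and predicts
the held-out subject.  The best grid accuracy is reported as the headline
number — an optimistic selection rule, reported as such; the full per-point
accuracy table is kept so unbiased summaries can be derived from it.

MCI is the positive class throughout: sensitivity is the correct rate among
patients, specificity among controls, and ROC/AUC use the signed SVM
decision values pooled over folds at the best point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skmetrics
from sklearn.svm import SVC

from .exceptions import EmptySelectionWarning, InvalidInputError, InvalidParameterError
from .features import FeatureMatrix
from .selection import SelectionResult, select_features

__all__ = [
    "GridPoint",
    "FoldOutcome",
    "CVResult",
    "HoldoutResult",
    "grid_values",
    "default_grid",
    "train_predict",
    "loocv_at_point",
    "grid_search",
    "confusion_metrics",
    "roc_auc",
    "retention_analysis",
    "holdout_validation",
]

POSITIVE = "MCI"


@dataclass(frozen=True)
class GridPoint:
    gamma: float
    C: float


@dataclass
class FoldOutcome:
    held_out_id: str
    true_label: str
    predicted_label: str
    decision_value: float
    retained_features: list[int]


@dataclass
class CVResult:
    best_point: GridPoint
    accuracy: float
    sensitivity: float
    specificity: float
    gammas: np.ndarray
    Cs: np.ndarray
    per_point_accuracy: np.ndarray  # (len(gammas), len(Cs))
    fold_outcomes: list[FoldOutcome]
    retention_counts: np.ndarray  # per feature, over folds
    stability_threshold: int
    stable_features: list[int]
    stable_mean_fisher: np.ndarray
    auc: float
    roc: tuple[np.ndarray, np.ndarray]  # (fpr, tpr)
    fold_selections: list[SelectionResult] = field(repr=False, default_factory=list)


@dataclass
class HoldoutResult:
    accuracy: float
    best_point: GridPoint
    inner_accuracy: float
    train_ids: list[str]
    test_ids: list[str]
    outcomes: list[FoldOutcome]


def grid_values(lo_exp: float = -8, hi_exp: float = 8, step: float = 0.5) -> np.ndarray:
    """Powers of two over an inclusive exponent range: 2^lo, 2^(lo+step), ..., 2^hi."""
    if step <= 0:
        raise InvalidParameterError("grid step must be positive")
    n = int(round((hi_exp - lo_exp) / step))
    exps = lo_exp + step * np.arange(n + 1)
    exps = exps[exps <= hi_exp + 1e-12]
    return 2.0 ** exps


def default_grid() -> tuple[np.ndarray, np.ndarray]:
    """The 33 x 33 (gamma, C) grid: exponents -8 .. 8 in steps of 0.5."""
    return grid_values(), grid_values()


def _encode(groups) -> np.ndarray:
    return np.where(np.asarray(groups) == POSITIVE, 1, -1)


def _zscore_train(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def _fit_svm(
    xtr: np.ndarray, ytr: np.ndarray, point: GridPoint, kernel: str
) -> SVC:
    if len(np.unique(ytr)) < 2:
        raise InvalidInputError("training set contains a single class")
    clf = SVC(C=point.C, gamma=point.gamma, kernel=kernel)
    clf.fit(xtr, ytr)
    return clf


def train_predict(
    train: FeatureMatrix,
    test: FeatureMatrix,
    point: GridPoint,
    features: list[int] | None = None,
    kernel: str = "rbf",
) -> list[FoldOutcome]:
    """Train on one fold view and predict another; returns one outcome per test row.

    Features are restricted to ``features`` (default: all columns) and
    z-scored with training-fold statistics only.
    """
    cols = np.arange(train.values.shape[1]) if features is None else np.asarray(features)
    xtr = train.values[:, cols]
    mu, sd = _zscore_train(xtr)
    clf = _fit_svm((xtr - mu) / sd, _encode(train.groups), point, kernel)
    xte = (test.values[:, cols] - mu) / sd
    dec = clf.decision_function(xte)
    pred = np.where(dec > 0, POSITIVE, "HC")
    return [
        FoldOutcome(
            held_out_id=sid,
            true_label=grp,
            predicted_label=str(p),
            decision_value=float(d),
            retained_features=[int(c) for c in cols],
        )
        for sid, grp, p, d in zip(test.subject_ids, test.groups, pred, dec)
    ]


def _effective_retained(sel: SelectionResult, fold: str = "") -> list[int]:
    if not sel.empty_selection:
        return sel.retained
    best = int(np.nanargmax(sel.fisher_scores))
    warnings.warn(
        f"no feature passed p < {sel.alpha} in fold {fold}; "
        f"falling back to the single best Fisher-score feature {best}",
        EmptySelectionWarning,
        stacklevel=3,
    )
    return [best]


def _prepare_loocv_folds(matrix: FeatureMatrix, alpha: float):
    """Per-fold selection and standardized design matrices (grid-independent)."""
    n = matrix.n_subjects
    if n < 2:
        raise InvalidInputError("LOOCV needs at least 2 subjects")
    if len(set(matrix.groups)) < 2:
        raise InvalidInputError("both classes must be present")
    folds = []
    y_all = _encode(matrix.groups)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        sel = select_features(matrix.values[tr], np.asarray(matrix.groups)[tr], alpha)
        cols = np.asarray(_effective_retained(sel, matrix.subject_ids[i]))
        xtr = matrix.values[np.ix_(tr, cols)]
        mu, sd = _zscore_train(xtr)
        folds.append(
            {
                "held_out": i,
                "selection": sel,
                "cols": cols,
                "xtr": (xtr - mu) / sd,
                "ytr": y_all[tr],
                "xte": ((matrix.values[i, cols] - mu) / sd)[None, :],
            }
        )
    return folds


def _run_point(folds, matrix: FeatureMatrix, point: GridPoint, kernel: str):
    outcomes = []
    correct = 0
    for f in folds:
        clf = _fit_svm(f["xtr"], f["ytr"], point, kernel)
        dec = float(clf.decision_function(f["xte"])[0])
        pred = POSITIVE if dec > 0 else "HC"
        i = f["held_out"]
        true = matrix.groups[i]
        correct += pred == true
        outcomes.append(
            FoldOutcome(
                held_out_id=matrix.subject_ids[i],
                true_label=true,
                predicted_label=pred,
                decision_value=dec,
                retained_features=[int(c) for c in f["cols"]],
            )
        )
    return correct / len(folds), outcomes


def loocv_at_point(
    matrix: FeatureMatrix,
    point: GridPoint,
    alpha: float = 0.05,
    kernel: str = "rbf",
) -> tuple[float, list[FoldOutcome]]:
    """Leave-one-out CV at a single (gamma, C): N folds, selection per fold."""
    folds = _prepare_loocv_folds(matrix, alpha)
    return _run_point(folds, matrix, point, kernel)


def confusion_metrics(outcomes: list[FoldOutcome]) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) with MCI as the positive class."""
    if not outcomes:
        raise InvalidInputError("no fold outcomes")
    tp = sum(o.true_label == POSITIVE and o.predicted_label == POSITIVE for o in outcomes)
    tn = sum(o.true_label != POSITIVE and o.predicted_label != POSITIVE for o in outcomes)
    n_pos = sum(o.true_label == POSITIVE for o in outcomes)
    n_neg = len(outcomes) - n_pos
    acc = (tp + tn) / len(outcomes)
    sens = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")
    return acc, sens, spec


def roc_auc(outcomes: list[FoldOutcome]) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical ROC over pooled decision values; AUC is the Mann-Whitney
    probability that a random patient outscores a random control (ties 1/2)."""
    y = np.asarray([1 if o.true_label == POSITIVE else 0 for o in outcomes])
    s = np.asarray([o.decision_value for o in outcomes])
    if len(np.unique(y)) < 2:
        raise InvalidInputError("both classes needed for a ROC curve")
    if not np.isfinite(s).all():
        raise InvalidInputError("non-finite decision values")
    fpr, tpr, _ = skmetrics.roc_curve(y, s)
    auc = float(skmetrics.roc_auc_score(y, s))
    return fpr, tpr, auc


def retention_analysis(
    fold_selections: list[SelectionResult],
    n_features: int,
    stability_fraction: float = 0.95,
) -> tuple[np.ndarray, int, list[int], np.ndarray]:
    """Retention counts over folds and the stable feature set.

    The stability threshold is ceil(stability_fraction x n_folds); a feature
    retained in at least that many folds is stable and reported with its
    mean Fisher score across folds.
    """
    n_folds = len(fold_selections)
    counts = np.zeros(n_features, dtype=int)
    fs = np.zeros((n_folds, n_features))
    for k, sel in enumerate(fold_selections):
        counts[sel.retained] += 1
        fs[k] = sel.fisher_scores
    threshold = math.ceil(stability_fraction * n_folds)
    stable = np.nonzero(counts >= threshold)[0].tolist()
    return counts, threshold, stable, fs.mean(axis=0)[stable]


def grid_search(
    matrix: FeatureMatrix,
    gammas: np.ndarray | None = None,
    Cs: np.ndarray | None = None,
    alpha: float = 0.05,
    kernel: str = "rbf",
    stability_fraction: float = 0.95,
) -> CVResult:
    """Full LOOCV grid search; the best grid accuracy is the reported one.

    Ties on the grid break toward the smallest C, then the smallest gamma
    (least complex model), independent of grid ordering.
    """
    if gammas is None or Cs is None:
        g_def, c_def = default_grid()
        gammas = g_def if gammas is None else np.asarray(gammas, float)
        Cs = c_def if Cs is None else np.asarray(Cs, float)
    gammas = np.asarray(gammas, float)
    Cs = np.asarray(Cs, float)
    if gammas.size == 0 or Cs.size == 0:
        raise InvalidParameterError("grid must be non-empty")

    folds = _prepare_loocv_folds(matrix, alpha)
    acc = np.empty((gammas.size, Cs.size))
    for gi, g in enumerate(gammas):
        for ci, c in enumerate(Cs):
            acc[gi, ci], _ = _run_point(folds, matrix, GridPoint(g, c), kernel)

    best = acc.max()
    cand = np.argwhere(np.isclose(acc, best))
    order = sorted(cand.tolist(), key=lambda rc: (Cs[rc[1]], gammas[rc[0]]))
    gi, ci = order[0]
    best_point = GridPoint(float(gammas[gi]), float(Cs[ci]))
    _, outcomes = _run_point(folds, matrix, best_point, kernel)

    accuracy, sensitivity, specificity = confusion_metrics(outcomes)
    fpr, tpr, auc = roc_auc(outcomes)
    sels = [f["selection"] for f in folds]
    counts, threshold, stable, stable_fs = retention_analysis(
        sels, matrix.values.shape[1], stability_fraction
    )
    return CVResult(
        best_point=best_point,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        gammas=gammas,
        Cs=Cs,
        per_point_accuracy=acc,
        fold_outcomes=outcomes,
        retention_counts=counts,
        stability_threshold=threshold,
        stable_features=stable,
        stable_mean_fisher=stable_fs,
        auc=auc,
        roc=(fpr, tpr),
        fold_selections=sels,
    )


def holdout_validation(
    matrix: FeatureMatrix,
    n_train_mci: int = 42,
    n_train_hc: int = 40,
    n_test_mci: int = 22,
    n_test_hc: int = 20,
    gammas: np.ndarray | None = None,
    Cs: np.ndarray | None = None,
    alpha: float = 0.05,
    kernel: str = "rbf",
    seed: int = 0,
) -> HoldoutResult:
    """Single random train/test split with internal two-fold CV for (gamma, C).

    The training subset is halved (stratified); each half is used to select
    features and train while the other is predicted, and the mean of the two
    accuracies scores the grid point.  The final model re-selects features
    and trains on the full training subset and is evaluated once on the
    held-out test subset.
    """
    if gammas is None or Cs is None:
        g_def, c_def = default_grid()
        gammas = g_def if gammas is None else np.asarray(gammas, float)
        Cs = c_def if Cs is None else np.asarray(Cs, float)
    groups = np.asarray(matrix.groups)
    mci_idx = np.nonzero(groups == POSITIVE)[0]
    hc_idx = np.nonzero(groups != POSITIVE)[0]
    if len(mci_idx) < n_train_mci + n_test_mci or len(hc_idx) < n_train_hc + n_test_hc:
        raise InvalidParameterError(
            f"split infeasible: have {len(mci_idx)} MCI / {len(hc_idx)} HC, "
            f"need {n_train_mci + n_test_mci} / {n_train_hc + n_test_hc}"
        )
    rng = np.random.default_rng(seed)
    mci_perm = rng.permutation(mci_idx)
    hc_perm = rng.permutation(hc_idx)
    train_rows = np.sort(
        np.concatenate([mci_perm[:n_train_mci], hc_perm[:n_train_hc]])
    )
    test_rows = np.sort(
        np.concatenate(
            [
                mci_perm[n_train_mci : n_train_mci + n_test_mci],
                hc_perm[n_train_hc : n_train_hc + n_test_hc],
            ]
        )
    )
    train = matrix.subset(train_rows)
    test = matrix.subset(test_rows)

    # stratified internal two-fold split of the training subset
    tgroups = np.asarray(train.groups)
    halves = np.zeros(train.n_subjects, dtype=int)
    for cls in (POSITIVE, "HC"):
        rows = rng.permutation(np.nonzero(tgroups == cls)[0])
        halves[rows[: len(rows) // 2]] = 1
    fold_a = train.subset(halves == 0)
    fold_b = train.subset(halves == 1)

    prepared = []
    for tr, te in ((fold_a, fold_b), (fold_b, fold_a)):
        sel = select_features(tr.values, tr.groups, alpha)
        cols = np.asarray(_effective_retained(sel, "holdout-inner"))
        mu, sd = _zscore_train(tr.values[:, cols])
        prepared.append(
            (
                (tr.values[:, cols] - mu) / sd,
                _encode(tr.groups),
                (te.values[:, cols] - mu) / sd,
                _encode(te.groups),
            )
        )

    inner = np.empty((len(gammas), len(Cs)))
    for gi, g in enumerate(gammas):
        for ci, c in enumerate(Cs):
            accs = []
            for xtr, ytr, xte, yte in prepared:
                clf = _fit_svm(xtr, ytr, GridPoint(g, c), kernel)
                accs.append((clf.predict(xte) == yte).mean())
            inner[gi, ci] = np.mean(accs)
    best = inner.max()
    cand = np.argwhere(np.isclose(inner, best))
    gi, ci = sorted(cand.tolist(), key=lambda rc: (Cs[rc[1]], gammas[rc[0]]))[0]
    best_point = GridPoint(float(gammas[gi]), float(Cs[ci]))

    sel = select_features(train.values, train.groups, alpha)
    cols = _effective_retained(sel, "holdout-final")
    outcomes = train_predict(train, test, best_point, features=cols, kernel=kernel)
    accuracy, _, _ = confusion_metrics(outcomes)
    return HoldoutResult(
        accuracy=accuracy,
        best_point=best_point,
        inner_accuracy=float(best),
        train_ids=train.subject_ids,
        test_ids=test.subject_ids,
        outcomes=outcomes,
    )
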