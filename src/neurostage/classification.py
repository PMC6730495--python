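"""Nested cross-validated multiclass SVM with balanced subsampling.

The evaluation protocol: per diagnostic group, 80% of subjects form the
train/cross-validation set and 20% an untouched test set (5 outer
folds); the train set is split 80/20 again into 5 inner folds for the
wrapper stage of feature selection.  Per-group counts use
round-half-up, which on group sizes 34/25/69/49 gives the canonical
141 / 36 train/test and 113 / 26 inner-train/validation totals.

Group imbalance is neutralized by balanced subsampling: every group
contributes exactly as many training subjects as the smallest group,
redrawn independently for each of ``n_reps`` repetitions (1,000 in the
full protocol), and performance is averaged over folds x repetitions.

The metric panel reports the k x k confusion matrix, per-class
sensitivity / specificity / PPV / AUC (one-vs-rest on decision scores)
and per-class accuracy (the class's recall), plus overall accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from ._rng import child_rng
from .feature_selection import default_svm, mrmr_rank, sfc_select
from .morphometry import FeatureMatrix

N_FOLDS = 5
TRAIN_FRACTION = 0.8


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class SplitPlan:
    """Outer and inner fold memberships, per group."""

    outer_folds: list[dict[str, np.ndarray]]   # per fold: group -> test indices
    inner_folds: list[list[dict[str, np.ndarray]]]
    group_indices: dict[str, np.ndarray]
    seed: int

    def outer_test(self, fold: int) -> np.ndarray:
        return np.concatenate(list(self.outer_folds[fold].values()))

    def outer_train(self, fold: int) -> np.ndarray:
        test = set(self.outer_test(fold).tolist())
        return np.concatenate(
            [idx[~np.isin(idx, list(test))] for idx in self.group_indices.values()]
        )

    def outer_train_by_group(self, fold: int) -> dict[str, np.ndarray]:
        test = set(self.outer_test(fold).tolist())
        return {
            g: idx[~np.isin(idx, list(test))]
            for g, idx in self.group_indices.items()
        }


def _fold_sizes(n: int, n_folds: int = N_FOLDS) -> list[int]:
    """Near-equal fold sizes with fold 0 holding round-half-up(n/5).

    The n % 5 oversized folds are placed first when the remainder rounds
    up (>= 3) and last otherwise, so the first fold always holds exactly
    the per-group 20% count obtained by round-half-up — the allocation
    that reproduces the canonical partition sizes for groups 34/25/69/49.
    """
    base, extra = divmod(n, n_folds)
    if extra >= (n_folds + 1) // 2:
        return [base + (1 if f < extra else 0) for f in range(n_folds)]
    return [base + (1 if f >= n_folds - extra else 0) for f in range(n_folds)]


def holdout_counts(group_sizes: dict[str, int], fraction: float = 0.2) -> dict[str, int]:
    """Per-group held-out counts at ``fraction``, round-half-up."""
    return {g: round_half_up(fraction * n) for g, n in group_sizes.items()}


def make_split_plan(
    groups: pd.Series | dict[str, str] | np.ndarray,
    seed: int = 0,
    n_folds: int = N_FOLDS,
) -> SplitPlan:
    """Randomized per-group 5-fold partition with nested inner folds.

    ``groups`` maps subject position (or id) to group label; indices in
    the plan refer to positions in the label array's order.
    """
    labels = np.asarray(list(groups.values()) if isinstance(groups, dict) else groups)
    group_names, counts = np.unique(labels, return_counts=True)
    for g, n in zip(group_names, counts):
        if n < n_folds:
            raise ValueError(f"group {g!r} has {n} < {n_folds} subjects")

    rng = child_rng(seed, "split_plan")
    group_indices = {
        g: rng.permutation(np.flatnonzero(labels == g)) for g in group_names
    }

    outer_folds: list[dict[str, np.ndarray]] = []
    cursor = {g: 0 for g in group_names}
    for f in range(n_folds):
        fold: dict[str, np.ndarray] = {}
        for g in group_names:
            size = _fold_sizes(len(group_indices[g]), n_folds)[f]
            start = cursor[g]
            fold[g] = group_indices[g][start : start + size]
            cursor[g] = start + size
        outer_folds.append(fold)

    inner_folds: list[list[dict[str, np.ndarray]]] = []
    for f in range(n_folds):
        test = set(np.concatenate(list(outer_folds[f].values())).tolist())
        inner_per_group = {
            g: rng.permutation(idx[~np.isin(idx, list(test))])
            for g, idx in group_indices.items()
        }
        folds_f: list[dict[str, np.ndarray]] = []
        cur = {g: 0 for g in group_names}
        for i in range(n_folds):
            fold_i: dict[str, np.ndarray] = {}
            for g in group_names:
                size = _fold_sizes(len(inner_per_group[g]), n_folds)[i]
                start = cur[g]
                fold_i[g] = inner_per_group[g][start : start + size]
                cur[g] = start + size
            folds_f.append(fold_i)
        inner_folds.append(folds_f)

    return SplitPlan(
        outer_folds=outer_folds,
        inner_folds=inner_folds,
        group_indices=group_indices,
        seed=seed,
    )


def balanced_subsample(
    train_by_group: dict[str, np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    """Every group contributes n_min subjects, sampled without replacement."""
    n_min = min(len(idx) for idx in train_by_group.values())
    if n_min < 2:
        raise ValueError("smallest group must have at least 2 training subjects")
    picks = [
        rng.choice(idx, size=n_min, replace=False)
        for idx in train_by_group.values()
    ]
    return np.concatenate(picks)


# ---------------------------------------------------------------------------
# metric panel


@dataclass
class ClassificationReport:
    classes: list[str]
    confusion_counts: np.ndarray           # row = true, col = predicted
    per_class: pd.DataFrame                # sens/spec/ppv/auc/accuracy (%)
    overall_accuracy: float                # percent
    n_selected: dict[str, float] = field(default_factory=dict)
    n_reps: int = 1
    selection_log: list = field(default_factory=list)

    @property
    def confusion_percent(self) -> np.ndarray:
        row_sums = self.confusion_counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.confusion_counts / row_sums


def confusion_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    classes: list[str],
    scores: np.ndarray | None = None,
) -> ClassificationReport:
    """Per-class sensitivity / specificity / PPV / AUC / accuracy panel.

    ``scores`` is an optional (n_samples, n_classes) array of one-vs-rest
    decision values for the AUC; without it AUC is NaN.  Per-class
    accuracy is the class's recall; overall accuracy is trace / total.
    A class never predicted has undefined PPV, reported as NaN with a
    warning.
    """
    import warnings

    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k), dtype=float)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1

    rows = {}
    total = cm.sum()
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens = 100.0 * tp / (tp + fn) if tp + fn else np.nan
        spec = 100.0 * tn / (tn + fp) if tn + fp else np.nan
        if tp + fp == 0:
            warnings.warn(f"class {c!r} never predicted; PPV undefined")
            ppv = np.nan
        else:
            ppv = 100.0 * tp / (tp + fp)
        if scores is not None and 0 < (y_true == c).sum() < len(y_true):
            auc = roc_auc_score((y_true == c).astype(int), scores[:, i])
        else:
            auc = np.nan
        rows[c] = {
            "sensitivity": sens,
            "specificity": spec,
            "ppv": ppv,
            "auc": auc,
            "accuracy": sens,              # per-class accuracy = recall
        }
    overall = 100.0 * np.trace(cm) / total if total else np.nan
    return ClassificationReport(
        classes=list(classes),
        confusion_counts=cm,
        per_class=pd.DataFrame(rows).T,
        overall_accuracy=float(overall),
    )


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class NestedCvConfig:
    k_max: int = 50
    n_reps: int = 1000
    selector: str = "sfc"                  # sfc | dca | none
    classifier_factory: object = default_svm


def _ovr_scores(clf, x: np.ndarray, classes_enc: np.ndarray) -> np.ndarray:
    """One-vs-rest decision values; falls back to vote margins for OvO."""
    df = clf.decision_function(x)
    if df.ndim == 1:
        df = df[:, None]
    n_classes = len(classes_enc)
    if df.shape[1] == n_classes:
        return df
    # one-vs-one: aggregate pairwise margins per class
    scores = np.zeros((x.shape[0], n_classes))
    col = 0
    for i in range(n_classes):
        for j in range(i + 1, n_classes):
            scores[:, i] += df[:, col]
            scores[:, j] -= df[:, col]
            col += 1
    return scores


def nested_cv_classify(
    features: FeatureMatrix | pd.DataFrame,
    labels: pd.Series | None = None,
    config: NestedCvConfig | None = None,
    seed: int = 0,
    groups_to_use: list[str] | None = None,
) -> ClassificationReport:
    """Run the full nested protocol and return the averaged metric panel.

    Per outer fold: MRMR+SFC feature selection on the outer-train
    subjects only (wrapper accuracies from the inner folds), then for
    each repetition a balanced subsample of outer-train subjects trains
    the SVM, which is evaluated on the untouched outer-test subjects.
    Selection runs once per fold and is shared across repetitions.
    """
    modality = None
    if isinstance(features, FeatureMatrix):
        data = features.data
        modality = features.modality
        labels = features.groups.reindex(data.index)
    else:
        data = features
        if labels is None:
            raise ValueError("labels required when features is a plain DataFrame")
        labels = labels.reindex(data.index)
    if groups_to_use is not None:
        keep = labels.isin(groups_to_use)
        data, labels = data[keep], labels[keep]

    config = config or NestedCvConfig()
    x = data.to_numpy(dtype=float)
    y = labels.to_numpy()
    classes = sorted(np.unique(y).tolist())
    plan = make_split_plan(y, seed=seed)

    all_true: list = []
    all_pred: list = []
    all_scores: list = []
    selection_log = []
    n_selected: list[int] = []

    for f in range(N_FOLDS):
        train_by_group = plan.outer_train_by_group(f)
        train_idx = np.concatenate(list(train_by_group.values()))
        test_idx = plan.outer_test(f)

        if config.selector == "sfc":
            rank_state = mrmr_rank(x[train_idx], y[train_idx], k_max=config.k_max)
            # plan's inner folds, re-indexed to positions within outer-train
            pos = {int(g): p for p, g in enumerate(train_idx)}
            inner = []
            for fold_i in plan.inner_folds[f]:
                val = np.array(
                    [pos[int(i)] for i in np.concatenate(list(fold_i.values()))],
                    dtype=int,
                )
                tr = np.setdiff1d(np.arange(len(train_idx)), val)
                inner.append((tr, val))
            sfc = sfc_select(
                x[train_idx],
                y[train_idx],
                k_max=config.k_max,
                seed=plan.seed + f,
                ranking=rank_state.selected,
                classifier_factory=config.classifier_factory,
                feature_names=list(data.columns),
                folds=inner,
            )
            x_fold = x[:, np.array(sfc.chosen)]
            selection_log.append(
                {"fold": f, "chosen": sfc.chosen_names, "size": sfc.chosen_size}
            )
            n_selected.append(sfc.chosen_size)
        elif config.selector == "dca":
            if modality is None:
                raise ValueError("DCA selection needs a FeatureMatrix with modality tags")
            from .feature_selection import dca_fit, dca_fuse

            tags = modality.to_numpy()
            cols_x = np.flatnonzero(tags == tags[0])
            cols_z = np.flatnonzero(tags != tags[0])
            model = dca_fit(
                x[np.ix_(train_idx, cols_x)], x[np.ix_(train_idx, cols_z)],
                y[train_idx],
            )
            # the train-fitted projection is applied row-wise; test rows
            # never influence the fit
            x_fold = dca_fuse(model, x[:, cols_x], x[:, cols_z])
            selection_log.append({"fold": f, "chosen": None, "size": model.r})
            n_selected.append(model.r)
        else:
            x_fold = x
            n_selected.append(x.shape[1])

        for rep in range(config.n_reps):
            rng = child_rng(seed, "subsample", f, rep)
            sub = balanced_subsample(train_by_group, rng)
            clf = config.classifier_factory(x_fold.shape[1])
            try:
                clf.fit(x_fold[sub], y[sub])
            except Exception as exc:
                raise RuntimeError(f"classifier failed at fold {f}, rep {rep}") from exc
            pred = clf.predict(x_fold[test_idx])
            scores = _ovr_scores(clf, x_fold[test_idx], clf.classes_)
            # clf.classes_ is sorted, matching `classes`
            all_true.extend(y[test_idx])
            all_pred.extend(pred)
            all_scores.append(scores)

    report = confusion_metrics(
        np.array(all_true),
        np.array(all_pred),
        classes,
        scores=np.vstack(all_scores),
    )
    report.n_reps = config.n_reps
    report.selection_log = selection_log
    report.n_selected = {"mean": float(np.mean(n_selected))}
    return report


# ---------------------------------------------------------------------------
# ANOVA on selected features


def group_anova(
    features: pd.DataFrame, labels: pd.Series, columns: list[str] | None = None
) -> pd.DataFrame:
    """One-way ANOVA per feature across groups; raw (unadjusted) p-values."""
    labels = labels.reindex(features.index)
    groups = labels.unique()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    cols = columns if columns is not None else list(features.columns)
    rows = {}
    for c in cols:
        samples = [features.loc[labels == g, c].to_numpy() for g in groups]
        if all(np.ptp(s) == 0 for s in samples):
            raise ValueError(f"feature {c!r} has zero within-group variance")
        f_stat, p = stats.f_oneway(*samples)
        rows[c] = {"F": float(f_stat), "p": float(p)}
    return pd.DataFrame(rows).T
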