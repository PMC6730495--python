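"""Feature selection: MRMR ranking, SFC subset search, DCA fusion.

MRMR (minimum redundancy, maximum relevance) scores a feature set S
against class labels c as

    score(S) = (1/|S|)   * sum_{f_i in S} I(f_i; c)
             - (1/|S|^2) * sum_{f_i, f_j in S} I(f_i; f_j)

with plug-in mutual information (bits) on 3-bin discretized features;
the redundancy sum runs over all ordered pairs of S including i = j, as
the criterion is printed.  Ranking is greedy forward selection: the
first feature maximizes relevance, each next feature maximizes the set
score, ties broken by column index.

SFC (sequential feature collection) is the filter+wrapper combination:
rank all features by MRMR, then pick the prefix size whose inner-CV
classification accuracy is best (smallest size on ties).

DCA (discriminant correlation analysis) is the fusion alternative: each
modality block is projected onto the <= (c-1)-dimensional signal
subspace of its between-class scatter (whitened), the two projected
blocks are aligned by an SVD of their cross-covariance, and fused by
elementwise summation (or concatenation).

Discretization statistics (mean, SD) always come from training data
only — test values are binned with the train statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


# ---------------------------------------------------------------------------
# discretization and mutual information


def discretize(values: np.ndarray, train_mean: float, train_sd: float) -> np.ndarray:
    """3-bin coding: (-inf, mu-sd] -> 0, (mu-sd, mu+sd] -> 1, (mu+sd, inf) -> 2."""
    if train_sd <= 0:
        raise ValueError("training SD must be positive to discretize")
    v = np.asarray(values, dtype=float)
    bins = np.ones(v.shape, dtype=np.int64)
    bins[v <= train_mean - train_sd] = 0
    bins[v > train_mean + train_sd] = 2
    return bins


def discretize_matrix(
    x: np.ndarray, train_mean: np.ndarray, train_sd: np.ndarray
) -> np.ndarray:
    """Column-wise 3-bin coding with per-feature train statistics."""
    if np.any(train_sd <= 0):
        bad = np.flatnonzero(train_sd <= 0).tolist()
        raise ValueError(f"zero-variance feature(s) in training data: {bad[:5]}")
    x = np.asarray(x, dtype=float)
    bins = np.ones(x.shape, dtype=np.int64)
    bins[x <= train_mean - train_sd] = 0
    bins[x > train_mean + train_sd] = 2
    return bins


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information of two discrete vectors, in bits."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have equal length")
    if x.shape[0] == 0:
        raise ValueError("need at least one sample")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx_, ny_ = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny_ + yi, minlength=nx_ * ny_).reshape(nx_, ny_)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nzero = p > 0
    return float(np.sum(p[nzero] * np.log2(p[nzero] / (px @ py)[nzero])))


# ---------------------------------------------------------------------------
# MRMR


@dataclass
class MrmrState:
    """Bookkeeping of a greedy MRMR run."""

    selected: list[int]
    relevance: np.ndarray                  # I(f_i; c) per feature
    redundancy_sums: np.ndarray            # sum over selected s of I(f_i; f_s)
    scores: list[float] = field(default_factory=list)


def _encode_labels(labels: np.ndarray) -> np.ndarray:
    _, enc = np.unique(np.asarray(labels), return_inverse=True)
    return enc


def mrmr_rank(
    x: np.ndarray,
    labels: np.ndarray,
    k_max: int | None = None,
    discretized: bool = False,
) -> MrmrState:
    """Greedy MRMR forward ranking of the columns of ``x``.

    ``x`` is samples x features; unless ``discretized``, each column is
    3-bin coded with its own (training) mean and SD first.  Returns the
    state whose ``selected`` attribute is the ranked index list.
    """
    x = np.asarray(x)
    n, p = x.shape
    if p < 2:
        raise ValueError("need at least 2 features")
    y = _encode_labels(labels)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    if k_max is None:
        k_max = p
    if k_max > p:
        import warnings

        warnings.warn(f"k_max {k_max} exceeds feature count {p}; truncating")
        k_max = p

    if discretized:
        d = x.astype(np.int64)
    else:
        d = discretize_matrix(x, x.mean(axis=0), x.std(axis=0))

    relevance = np.array([mutual_information(d[:, j], y) for j in range(p)])
    self_info = np.array([mutual_information(d[:, j], d[:, j]) for j in range(p)])

    selected: list[int] = []
    scores: list[float] = []
    red_sums = np.zeros(p)                 # sum_{s in S} I(f_j; f_s) per candidate
    available = np.ones(p, dtype=bool)

    # first pick: maximal relevance (the |S|=1 score is relevance - self-info,
    # whose argmax can differ; the criterion's intent and every MRMR
    # implementation start from the most relevant feature)
    first = int(np.argmax(relevance))
    selected.append(first)
    available[first] = False
    scores.append(relevance[first] - self_info[first])

    while len(selected) < k_max and available.any():
        last = selected[-1]
        cand = np.flatnonzero(available)
        red_sums[cand] += np.array(
            [mutual_information(d[:, j], d[:, last]) for j in cand]
        )
        s = len(selected)
        rel_sum = relevance[selected].sum()
        red_sel = sum(
            mutual_information(d[:, a], d[:, b])
            for a in selected
            for b in selected
        )
        # score of S u {j}: ordered-pair redundancy gains 2*sum_s I(j;s) + I(j;j)
        new_scores = (rel_sum + relevance[cand]) / (s + 1) - (
            red_sel + 2.0 * red_sums[cand] + self_info[cand]
        ) / (s + 1) ** 2
        best = cand[int(np.argmax(new_scores))]  # argmax takes first = lowest index
        selected.append(int(best))
        available[best] = False
        scores.append(float(np.max(new_scores)))

    return MrmrState(
        selected=selected,
        relevance=relevance,
        redundancy_sums=red_sums,
        scores=scores,
    )


def mrmr_set_score(d: np.ndarray, y: np.ndarray, subset: list[int]) -> float:
    """Direct evaluation of the MRMR criterion for an explicit subset."""
    s = len(subset)
    rel = sum(mutual_information(d[:, j], y) for j in subset) / s
    red = (
        sum(
            mutual_information(d[:, a], d[:, b]) for a in subset for b in subset
        )
        / s**2
    )
    return rel - red


# ---------------------------------------------------------------------------
# SFC


@dataclass
class SfcResult:
    ranking: list[int]
    accuracy_curve: np.ndarray             # inner-CV accuracy for k = 1..k_max
    chosen_size: int
    chosen: list[int]
    feature_names: list[str] | None = None

    @property
    def chosen_names(self) -> list[str] | None:
        if self.feature_names is None:
            return None
        return [self.feature_names[j] for j in self.chosen]


def default_svm(n_features: int | None = None) -> SVC:
    """The study classifier: one-vs-one RBF SVM, C=1, gamma=1/n_features."""
    return SVC(kernel="rbf", C=1.0, gamma="auto", decision_function_shape="ovo")


def sfc_select(
    x: np.ndarray,
    labels: np.ndarray,
    k_max: int = 50,
    n_inner_folds: int = 5,
    seed: int = 0,
    classifier_factory=default_svm,
    ranking: list[int] | None = None,
    feature_names: list[str] | None = None,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> SfcResult:
    """Filter + wrapper search over nested MRMR-ranked prefixes.

    For k = 1..k_max the inner-CV mean accuracy of the classifier on the
    top-k prefix is evaluated; the chosen size is the argmax, smallest k
    on ties.  All statistics (discretization, ranking, classifier fits)
    use training folds only.  ``folds`` may supply explicit
    (train, validation) index pairs (e.g. a nested split plan's inner
    folds); otherwise a seeded stratified k-fold is used.
    """
    x = np.asarray(x, dtype=float)
    y = _encode_labels(labels)
    k_max = min(k_max, x.shape[1])
    if ranking is None:
        ranking = mrmr_rank(x, y, k_max=k_max).selected
    if not ranking:
        raise ValueError("empty feature ranking")

    if folds is None:
        n_splits = min(n_inner_folds, int(np.bincount(y).min()))
        if n_splits < 2:
            raise ValueError("smallest class too small for inner cross-validation")
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        folds = list(skf.split(x, y))
    curve = np.zeros(k_max)
    for k in range(1, k_max + 1):
        cols = ranking[:k]
        accs = []
        for f, (tr, va) in enumerate(folds):
            if len(tr) == 0 or len(va) == 0:   # tiny groups can empty a fold
                continue
            clf = classifier_factory(len(cols))
            try:
                clf.fit(x[np.ix_(tr, cols)], y[tr])
                accs.append(float(np.mean(clf.predict(x[np.ix_(va, cols)]) == y[va])))
            except Exception as exc:        # pragma: no cover - defensive
                raise RuntimeError(f"classifier failed on inner fold {f}") from exc
        if not accs:
            raise ValueError("no usable inner fold (all empty)")
        curve[k - 1] = float(np.mean(accs))

    chosen_size = int(np.argmax(curve)) + 1  # argmax returns first max: smallest k
    return SfcResult(
        ranking=list(ranking),
        accuracy_curve=curve,
        chosen_size=chosen_size,
        chosen=list(ranking[:chosen_size]),
        feature_names=feature_names,
    )


# ---------------------------------------------------------------------------
# DCA


@dataclass
class DcaModel:
    class_means: dict
    between_scatter: tuple[np.ndarray, np.ndarray]
    within_scatter: tuple[np.ndarray, np.ndarray]
    projections: tuple[np.ndarray, np.ndarray]   # per-block p x r bases
    alignment: tuple[np.ndarray, np.ndarray]     # r x r rotations from the SVD
    means: tuple[np.ndarray, np.ndarray]
    r: int


def _scatters(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
    mu = x.mean(axis=0)
    s_b = np.zeros((x.shape[1], x.shape[1]))
    s_w = np.zeros_like(s_b)
    class_means = {}
    for c in np.unique(y):
        xc = x[y == c]
        mc = xc.mean(axis=0)
        class_means[int(c)] = mc
        diff = (mc - mu)[:, None]
        s_b += xc.shape[0] * (diff @ diff.T)
        centered = xc - mc
        s_w += centered.T @ centered
    return s_b, s_w, class_means


def _signal_projection(s_b: np.ndarray, r: int) -> np.ndarray:
    """Whitened basis of the r-dimensional signal subspace of S_b."""
    vals, vecs = np.linalg.eigh(s_b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = min(r, int(np.sum(vals > 1e-10 * max(vals[0], 1e-300))))
    if keep < r:
        import warnings

        warnings.warn(f"between-class scatter rank {keep} < requested {r}; reducing")
    return vecs[:, :keep] / np.sqrt(vals[:keep])


def dca_fit(
    block_x: np.ndarray, block_y: np.ndarray, labels: np.ndarray, r: int | None = None
) -> DcaModel:
    """Fit the two-block discriminant correlation analysis.

    Each block is projected onto the whitened signal subspace of its
    between-class scatter (dimension <= n_classes - 1); the projected
    blocks are then rotated onto each other via the SVD of their
    cross-covariance so that corresponding components are maximally
    correlated across modalities.
    """
    y = _encode_labels(labels)
    n_classes = np.unique(y).size
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    r_max = n_classes - 1
    r = r_max if r is None else min(r, r_max)

    x = np.asarray(block_x, dtype=float)
    z = np.asarray(block_y, dtype=float)
    mx, mz = x.mean(axis=0), z.mean(axis=0)
    sbx, swx, cmx = _scatters(x, y)
    sbz, swz, cmz = _scatters(z, y)
    wx = _signal_projection(sbx, r)
    wz = _signal_projection(sbz, r)
    r_eff = min(wx.shape[1], wz.shape[1])
    wx, wz = wx[:, :r_eff], wz[:, :r_eff]

    px = (x - mx) @ wx
    pz = (z - mz) @ wz
    cross = px.T @ pz / x.shape[0]
    u, _, vt = np.linalg.svd(cross)
    return DcaModel(
        class_means={"x": cmx, "y": cmz},
        between_scatter=(sbx, sbz),
        within_scatter=(swx, swz),
        projections=(wx, wz),
        alignment=(u, vt.T),
        means=(mx, mz),
        r=r_eff,
    )


def dca_transform(
    model: DcaModel, block_x: np.ndarray, block_y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Project and align both blocks into the common discriminant space."""
    wx, wz = model.projections
    u, v = model.alignment
    mx, mz = model.means
    tx = (np.asarray(block_x, dtype=float) - mx) @ wx @ u
    tz = (np.asarray(block_y, dtype=float) - mz) @ wz @ v
    return tx, tz


def dca_fuse(
    model: DcaModel,
    block_x: np.ndarray,
    block_y: np.ndarray,
    mode: str = "sum",
) -> np.ndarray:
    """Fuse the aligned blocks by summation (default) or concatenation."""
    tx, tz = dca_transform(model, block_x, block_y)
    if mode == "sum":
        return tx + tz
    if mode == "concat":
        return np.hstack([tx, tz])
    raise ValueError(f"unknown fusion mode {mode!r}")
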