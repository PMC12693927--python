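"""From-scratch classification and regression trees (CART) with
cost-complexity pruning, rolling-origin cross-validation, 1-SE model
selection, temporal holdout and the usual classification metrics.

The classifier grows greedy binary trees on the Gini criterion with
deterministic tie-breaking (lowest feature index, then lowest
threshold; candidate thresholds are midpoints between consecutive
distinct sorted feature values).  Weakest-link pruning yields the
nested subtree sequence and its complexity-penalty (alpha) path; the
complexity parameter cp is reported on the relative-error scale
(alpha divided by the root's resubstitution risk, so the root-only
tree has relative error 1).

Model selection is time-aware: cross-validation folds use an expanding
training origin — train on everything before a cut point, validate on
the next contiguous block — and the 1-SE rule picks the largest cp
whose mean CV error is within one standard error of the minimum.
Final evaluation uses a temporal holdout (last 30% of rows by
default).

The same splitting machinery provides regression trees (squared-error
criterion, optional per-node feature subsampling) for the bagged
ensembles of the gap-imputation module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats  # noqa: F401  (parity with sibling modules)

__all__ = [
    "gini", "TreeNode", "grow", "grow_regression", "predict",
    "predict_regression", "PrunePath", "prune_path", "cv_plan",
    "rolling_origin_cv", "one_se_select", "temporal_holdout",
    "EvalReport", "evaluate", "CartResult", "fit_cart",
]

_EPS = 1e-12


def gini(class_counts) -> float:
    """Gini impurity 1 - sum(p_c^2) of a nonnegative count vector."""
    c = np.asarray(class_counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    n = c.sum()
    if n <= 0:
        raise ValueError("at least one count must be positive")
    p = c / n
    return float(1.0 - np.sum(p * p))


@dataclass
class TreeNode:
    """One node of a binary tree; a leaf iff ``feature`` is None.

    Left child takes values <= threshold, right child values > threshold.
    ``counts`` holds the class distribution (classification) and
    ``value`` the mean response (regression).
    """

    n: int
    impurity: float
    counts: np.ndarray | None = None
    value: float | None = None
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    node_id: int = -1

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.leaves() + self.right.leaves()

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def to_lists(self, class_order=None):
        """Nested-list text form: leaf -> [prediction, n]; internal ->
        [feature, threshold, left, right]."""
        if self.is_leaf:
            if self.counts is not None and class_order is not None:
                pred = class_order[int(np.argmax(self.counts))]
            elif self.value is not None:
                pred = float(self.value)
            else:
                pred = None
            return [pred, int(self.n)]
        return [int(self.feature), float(self.threshold),
                self.left.to_lists(class_order),
                self.right.to_lists(class_order)]


# ---------------------------------------------------------------------------
# splitting

def _best_split_classification(X, codes, n_classes, min_leaf, feat_idx):
    """Best (feature, threshold) minimizing weighted child Gini.

    Deterministic: features scanned in ascending index order, strict
    improvement required, first (= lowest) threshold wins within a
    feature.  Returns None when no admissible split exists.
    """
    n = X.shape[0]
    best = None
    best_score = np.inf
    eye = np.eye(n_classes)
    for j in feat_idx:
        x = X[:, j]
        order = np.argsort(x, kind="mergesort")
        xs = x[order]
        if xs[0] == xs[-1]:
            continue  # zero-variance feature
        onehot = eye[codes[order]]
        left_counts = np.cumsum(onehot, axis=0)
        total = left_counts[-1]
        cut = np.nonzero(xs[1:] != xs[:-1])[0]  # split between i and i+1
        nl = cut + 1.0
        nr = n - nl
        ok = (nl >= min_leaf) & (nr >= min_leaf)
        cut, nl, nr = cut[ok], nl[ok], nr[ok]
        if cut.size == 0:
            continue
        lc = left_counts[cut]
        rc = total - lc
        gl = 1.0 - np.sum((lc / nl[:, None]) ** 2, axis=1)
        gr = 1.0 - np.sum((rc / nr[:, None]) ** 2, axis=1)
        score = (nl * gl + nr * gr) / n
        k = int(np.argmin(score))
        if score[k] < best_score - _EPS:
            best_score = score[k]
            thr = _midpoint(xs[cut[k]], xs[cut[k] + 1])
            best = (j, thr, float(best_score))
    return best


def _midpoint(lo: float, hi: float) -> float:
    # midpoint of consecutive distinct values; falls back to the left
    # value when rounding would collapse onto the right one
    thr = 0.5 * (lo + hi)
    return float(lo) if thr >= hi else float(thr)


def _best_split_regression(X, y, min_leaf, feat_idx):
    """Best (feature, threshold) minimizing total child SSE."""
    n = X.shape[0]
    best = None
    best_score = np.inf
    for j in feat_idx:
        x = X[:, j]
        order = np.argsort(x, kind="mergesort")
        xs = x[order]
        if xs[0] == xs[-1]:
            continue
        ys = y[order]
        cs = np.cumsum(ys)
        cs2 = np.cumsum(ys * ys)
        cut = np.nonzero(xs[1:] != xs[:-1])[0]
        nl = cut + 1.0
        nr = n - nl
        ok = (nl >= min_leaf) & (nr >= min_leaf)
        cut, nl, nr = cut[ok], nl[ok], nr[ok]
        if cut.size == 0:
            continue
        sl, sl2 = cs[cut], cs2[cut]
        sr, sr2 = cs[-1] - sl, cs2[-1] - sl2
        sse = (sl2 - sl * sl / nl) + (sr2 - sr * sr / nr)
        k = int(np.argmin(sse))
        if sse[k] < best_score - _EPS:
            best_score = float(sse[k])
            best = (j, _midpoint(xs[cut[k]], xs[cut[k] + 1]), best_score)
    return best


# ---------------------------------------------------------------------------
# growth

def grow(X, y, class_order=None, min_split: int = 20, min_leaf: int = 7,
         max_depth: int = 30) -> tuple[TreeNode, list]:
    """Grow a Gini classification tree.

    Returns ``(root, class_order)``; ``y`` may be any labels, mapped to
    codes in ``class_order`` (first-appearance order if not given —
    leaf ties break toward the earlier class in this order).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite (impute upstream)")
    if class_order is None:
        class_order = list(pd.unique(y))
    else:
        class_order = list(class_order)
    lut = {c: i for i, c in enumerate(class_order)}
    try:
        codes = np.array([lut[v] for v in y], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"label {exc} not in class_order") from None
    K = len(class_order)
    counter = iter(range(10 ** 9))
    feat_idx = np.arange(X.shape[1])

    def build(idx, depth):
        counts = np.bincount(codes[idx], minlength=K).astype(float)
        node = TreeNode(n=len(idx), impurity=gini(counts), counts=counts,
                        node_id=next(counter))
        if (len(idx) < min_split or depth >= max_depth
                or node.impurity <= _EPS):
            return node
        split = _best_split_classification(X[idx], codes[idx], K,
                                           min_leaf, feat_idx)
        if split is None or split[2] >= node.impurity - _EPS:
            return node
        j, thr, _ = split
        mask = X[idx, j] <= thr
        node.feature, node.threshold = j, thr
        node.left = build(idx[mask], depth + 1)
        node.right = build(idx[~mask], depth + 1)
        return node

    root = build(np.arange(len(y)), 0)
    return root, class_order


def grow_regression(X, y, min_split: int = 5, min_leaf: int = 2,
                    max_depth: int = 12, mtry: int | None = None,
                    rng: np.random.Generator | None = None) -> TreeNode:
    """Grow a squared-error regression tree.

    ``mtry`` features are drawn uniformly without replacement at each
    node when given (random-forest style); all features otherwise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if mtry is not None and rng is None:
        rng = np.random.default_rng()
    counter = iter(range(10 ** 9))

    def build(idx, depth):
        ys = y[idx]
        mean = float(ys.mean())
        sse = float(np.sum((ys - mean) ** 2))
        node = TreeNode(n=len(idx), impurity=sse / len(idx), value=mean,
                        node_id=next(counter))
        if len(idx) < min_split or depth >= max_depth or sse <= _EPS:
            return node
        if mtry is not None and mtry < p:
            feats = np.sort(rng.choice(p, size=mtry, replace=False))
        else:
            feats = np.arange(p)
        split = _best_split_regression(X[idx], ys, min_leaf, feats)
        if split is None or split[2] >= sse - _EPS:
            return node
        j, thr, _ = split
        mask = X[idx, j] <= thr
        node.feature, node.threshold = j, thr
        node.left = build(idx[mask], depth + 1)
        node.right = build(idx[~mask], depth + 1)
        return node

    return build(np.arange(len(y)), 0)


def _descend(node: TreeNode, row, collapsed=frozenset()):
    while not node.is_leaf and node.node_id not in collapsed:
        node = node.left if row[node.feature] <= node.threshold else node.right
    return node


def predict(root: TreeNode, X, class_order, collapsed=frozenset()):
    """Majority-class predictions; ``collapsed`` treats the listed node
    ids as leaves (used by pruning)."""
    X = np.asarray(X, dtype=float)
    out = np.empty(X.shape[0], dtype=object)
    for i in range(X.shape[0]):
        leaf = _descend(root, X[i], collapsed)
        out[i] = class_order[int(np.argmax(leaf.counts))]
    return out


def predict_regression(root: TreeNode, X):
    X = np.asarray(X, dtype=float)
    return np.array([_descend(root, X[i]).value for i in range(X.shape[0])])


# ---------------------------------------------------------------------------
# cost-complexity pruning

@dataclass
class PrunePath:
    """Weakest-link pruning sequence of a grown tree.

    ``alphas`` are strictly increasing penalties (first 0 = full tree);
    ``collapsed`` gives, per step, the cumulative set of internal node
    ids treated as leaves; ``n_leaves`` the matching subtree sizes.
    ``root_risk`` is the root's resubstitution misclassification rate,
    the normalizer of the relative-error cp scale.
    """

    alphas: list[float]
    collapsed: list[frozenset]
    n_leaves: list[int]
    root_risk: float

    def subtree_for_alpha(self, alpha: float) -> frozenset:
        """Collapse set of the optimal subtree at penalty ``alpha``."""
        k = 0
        for i, a in enumerate(self.alphas):
            if a <= alpha + _EPS:
                k = i
        return self.collapsed[k]

    def subtree_for_cp(self, cp: float) -> frozenset:
        return self.subtree_for_alpha(cp * self.root_risk)

    @property
    def cp_values(self) -> list[float]:
        if self.root_risk <= 0:
            return [0.0 for _ in self.alphas]
        return [a / self.root_risk for a in self.alphas]


def _node_risk(node: TreeNode, n_total: int) -> float:
    # resubstitution misclassification contribution of this node as a leaf
    return (node.n - float(np.max(node.counts))) / n_total


def prune_path(root: TreeNode) -> PrunePath:
    """Minimal cost-complexity (weakest-link) pruning sequence.

    At each step every internal node's link strength
    g(t) = (R(t) - R(T_t)) / (|leaves(T_t)| - 1) is computed on the
    current subtree and all nodes attaining the minimum are collapsed;
    the sequence ends at the root-only tree.  Alphas are strictly
    increasing and subtrees nested by construction.
    """
    n_total = root.n
    root_risk = _node_risk(root, n_total)
    alphas = [0.0]
    collapsed_steps = [frozenset()]
    n_leaves = [root.leaves()]
    collapsed: set[int] = set()

    def subtree_stats(node):
        # (risk of current subtree below node, current leaf count)
        if node.is_leaf or node.node_id in collapsed:
            return _node_risk(node, n_total), 1
        rl, ll = subtree_stats(node.left)
        rr, lr = subtree_stats(node.right)
        return rl + rr, ll + lr

    def internal_nodes(node, acc):
        if node.is_leaf or node.node_id in collapsed:
            return
        acc.append(node)
        internal_nodes(node.left, acc)
        internal_nodes(node.right, acc)

    while True:
        acc: list[TreeNode] = []
        internal_nodes(root, acc)
        if not acc:
            break
        links = []
        for node in acc:
            r_sub, leaves = subtree_stats(node)
            g = (_node_risk(node, n_total) - r_sub) / (leaves - 1)
            links.append((g, node))
        gmin = min(g for g, _ in links)
        for g, node in links:
            if g <= gmin + _EPS:
                collapsed.add(node.node_id)
        alphas.append(max(gmin, 0.0))
        collapsed_steps.append(frozenset(collapsed))
        _, leaves = subtree_stats(root)
        n_leaves.append(leaves)

    # enforce strict monotonicity in degenerate equal-g cascades
    for i in range(1, len(alphas)):
        if alphas[i] <= alphas[i - 1]:
            alphas[i] = alphas[i - 1] + _EPS
    return PrunePath(alphas=alphas, collapsed=collapsed_steps,
                     n_leaves=n_leaves, root_risk=root_risk)


# ---------------------------------------------------------------------------
# time-ordered model selection

def cv_plan(n: int, k: int = 5, initial_fraction: float = 0.5
            ) -> list[tuple[int, int, int]]:
    """Expanding-origin fold plan over ``n`` time-ordered rows.

    Returns k triples (train_end, val_start, val_end): train on
    [0, train_end), validate on [val_start, val_end).  Validation
    blocks are contiguous, disjoint and partition the tail after the
    initial window (the last block absorbs the remainder).
    """
    if not 0 < initial_fraction < 1:
        raise ValueError("initial_fraction must be in (0, 1)")
    initial = int(round(initial_fraction * n))
    tail = n - initial
    if k < 1 or tail < k:
        raise ValueError(f"n={n} too small for k={k} folds "
                         f"after an initial window of {initial}")
    block = tail // k
    plan = []
    for i in range(k):
        start = initial + i * block
        end = n if i == k - 1 else start + block
        plan.append((start, start, end))
    return plan


def rolling_origin_cv(X, y, k: int = 5, cp_grid=None,
                      initial_fraction: float = 0.5, class_order=None,
                      timestamps=None, **grow_kwargs) -> pd.DataFrame:
    """Per-cp misclassification error (mean and SE over folds) under
    expanding-origin cross-validation.

    Rows must be time-sorted; if ``timestamps`` are supplied they are
    checked for monotonicity and a warning is raised otherwise.  The cp
    grid defaults to geometric midpoints of the full-data pruning path
    (relative-error scale).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if timestamps is not None:
        ts = pd.to_datetime(pd.Series(list(timestamps)))
        if not ts.is_monotonic_increasing:
            warnings.warn("rows are not in timestamp order; rolling-origin "
                          "folds assume a time-sorted series", UserWarning)
    if class_order is None:
        class_order = list(pd.unique(y))
    if cp_grid is None:
        full, _ = grow(X, y, class_order=class_order, **grow_kwargs)
        cp_grid = cp_grid_from_path(prune_path(full))
    plan = cv_plan(len(y), k=k, initial_fraction=initial_fraction)
    errors = np.empty((len(cp_grid), len(plan)))
    for f, (train_end, v0, v1) in enumerate(plan):
        tr = slice(0, train_end)
        tree_f, _ = grow(X[tr], y[tr], class_order=class_order,
                         **grow_kwargs)
        path_f = prune_path(tree_f)
        for c, cp in enumerate(cp_grid):
            collapsed = path_f.subtree_for_cp(cp)
            pred = predict(tree_f, X[v0:v1], class_order, collapsed)
            errors[c, f] = np.mean(pred != y[v0:v1])
    mean = errors.mean(axis=1)
    se = errors.std(axis=1, ddof=1) / np.sqrt(len(plan))
    return pd.DataFrame({"cp": list(cp_grid), "mean_error": mean,
                         "se": se})


def cp_grid_from_path(path: PrunePath) -> list[float]:
    """Candidate cp values: geometric midpoints between consecutive
    path cps, bracketed by the endpoints."""
    cps = path.cp_values
    if len(cps) == 1:
        return [0.0]
    grid = [0.0]
    for a, b in zip(cps[:-1], cps[1:]):
        lo = max(a, _EPS)
        grid.append(float(np.sqrt(lo * max(b, _EPS))))
    grid.append(cps[-1] * 1.001 + _EPS)
    return grid


def one_se_select(cv_results: pd.DataFrame) -> float:
    """Largest cp whose mean CV error is within one standard error of
    the minimum mean CV error."""
    if len(cv_results) == 0:
        raise ValueError("empty CV results")
    i_min = int(cv_results["mean_error"].idxmin())
    bound = (cv_results.loc[i_min, "mean_error"]
             + cv_results.loc[i_min, "se"])
    ok = cv_results[cv_results["mean_error"] <= bound + _EPS]
    return float(ok["cp"].max())


def temporal_holdout(n_or_rows, fraction: float = 0.30):
    """Split time-sorted rows into (train, test) with the last
    ceil(fraction*n) rows as the test set; no shuffling."""
    if np.isscalar(n_or_rows):
        n = int(n_or_rows)
        items = None
    else:
        items = n_or_rows
        n = len(items)
    if n < 4:
        raise ValueError("need at least 4 rows for a temporal holdout")
    n_test = int(np.ceil(fraction * n))
    n_train = n - n_test
    if items is None:
        return np.arange(n_train), np.arange(n_train, n)
    if isinstance(items, pd.DataFrame):
        return items.iloc[:n_train], items.iloc[n_train:]
    return items[:n_train], items[n_train:]


# ---------------------------------------------------------------------------
# evaluation metrics

@dataclass
class EvalReport:
    """Confusion matrix (rows = truth, cols = prediction, in the fixed
    class order) and the scalar agreement metrics."""

    class_order: list
    confusion: np.ndarray
    accuracy: float
    balanced_accuracy: float
    macro_f1: float
    kappa: float

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "macro_f1": self.macro_f1,
            "kappa": None if np.isnan(self.kappa) else self.kappa,
        }


def evaluate(truth, predictions, class_order) -> EvalReport:
    """Confusion matrix, overall/balanced accuracy, macro F1, Cohen's κ.

    Balanced accuracy averages recall over classes present in the
    truth; per-class F1 with an empty denominator counts as 0 toward
    the macro mean; κ is NaN (with a warning) when chance agreement is
    1 (single-class marginals).
    """
    truth = np.asarray(truth)
    predictions = np.asarray(predictions)
    if len(truth) != len(predictions):
        raise ValueError("truth and predictions differ in length")
    order = list(class_order)
    lut = {c: i for i, c in enumerate(order)}
    K = len(order)
    cm = np.zeros((K, K), dtype=int)
    for t, p in zip(truth, predictions):
        cm[lut[t], lut[p]] += 1
    n = cm.sum()
    acc = float(np.trace(cm)) / n

    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    recalls = [cm[i, i] / row[i] for i in range(K) if row[i] > 0]
    bal_acc = float(np.mean(recalls))

    f1s = []
    for i in range(K):
        if row[i] == 0 and col[i] == 0:
            continue  # class absent everywhere: excluded from the mean
        denom = 2 * cm[i, i] + (row[i] - cm[i, i]) + (col[i] - cm[i, i])
        f1s.append(2 * cm[i, i] / denom if denom > 0 else 0.0)
    macro_f1 = float(np.mean(f1s)) if f1s else 0.0

    p_o = acc
    p_e = float(np.sum(row * col)) / (n * n)
    if abs(1.0 - p_e) < _EPS:
        warnings.warn("Cohen's kappa undefined: chance agreement is 1",
                      UserWarning)
        kappa = np.nan
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return EvalReport(class_order=order, confusion=cm, accuracy=acc,
                      balanced_accuracy=bal_acc, macro_f1=macro_f1,
                      kappa=float(kappa))


# ---------------------------------------------------------------------------
# end-to-end fit

@dataclass
class CartResult:
    tree: TreeNode
    class_order: list
    path: PrunePath
    collapsed: frozenset
    cv_results: pd.DataFrame
    selected_cp: float
    holdout_report: EvalReport
    n_train: int
    n_test: int

    def predict(self, X):
        return predict(self.tree, X, self.class_order, self.collapsed)


def fit_cart(X, y, class_order=None, holdout_fraction: float = 0.30,
             k: int = 5, initial_fraction: float = 0.5, timestamps=None,
             min_split: int = 20, min_leaf: int = 7, max_depth: int = 30
             ) -> CartResult:
    """Full time-aware CART pipeline.

    Last ``holdout_fraction`` of rows held out; cp tuned on the
    training block by expanding-origin CV with the 1-SE rule; the tree
    grown on the training block is pruned at the selected cp and
    evaluated on the holdout.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if class_order is None:
        class_order = list(pd.unique(y))
    tr_idx, te_idx = temporal_holdout(len(y), holdout_fraction)
    if timestamps is not None:
        timestamps = np.asarray(timestamps)
        ts_tr = timestamps[tr_idx]
    else:
        ts_tr = None
    grow_kwargs = dict(min_split=min_split, min_leaf=min_leaf,
                       max_depth=max_depth)
    tree_tr, _ = grow(X[tr_idx], y[tr_idx], class_order=class_order,
                      **grow_kwargs)
    path = prune_path(tree_tr)
    cp_grid = cp_grid_from_path(path)
    cv_results = rolling_origin_cv(
        X[tr_idx], y[tr_idx], k=k, cp_grid=cp_grid,
        initial_fraction=initial_fraction, class_order=class_order,
        timestamps=ts_tr, **grow_kwargs)
    cp = one_se_select(cv_results)
    collapsed = path.subtree_for_cp(cp)
    pred = predict(tree_tr, X[te_idx], class_order, collapsed)
    report = evaluate(y[te_idx], pred, class_order)
    return CartResult(tree=tree_tr, class_order=class_order, path=path,
                      collapsed=collapsed, cv_results=cv_results,
                      selected_cp=cp, holdout_report=report,
                      n_train=len(tr_idx), n_test=len(te_idx))
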