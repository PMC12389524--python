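"""Regression trees, gradient boosting, random forest, and split-gain selection.

The trees here are deliberately the package's own: each split records its
squared-error improvement tau_i^2 (the drop in total SSE achieved by the
split), because the descriptor-selection statistic is the per-feature sum of
tau_i^2 over that feature's split nodes, averaged over the trees of an
ensemble.  Candidate thresholds are midpoints between consecutive sorted
unique values; ties in gain are broken by (feature index, threshold)
lexicographic order so fits are fully deterministic.

``select_descriptors`` reproduces the two-stage selection used for the
nonlinear QSAR models: rank all descriptors by boosted-tree split gain, then
walk the ranking keeping a descriptor only if its absolute Pearson
correlation with every already-kept descriptor is below the 0.8 threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mixqsar.datasets import DescriptorTable
from mixqsar.errors import ConfigurationError, DataError

# minimum relative SSE improvement for a split to be accepted; guards against
# splits that only exist through floating-point cancellation
_GAIN_EPS = 1e-12


@dataclass(frozen=True)
class TreeConfig:
    max_depth: int = 6
    min_samples_split: int = 2
    min_samples_leaf: int = 1

    def __post_init__(self) -> None:
        if self.max_depth < 0:
            raise ConfigurationError("max_depth must be >= 0")
        if self.min_samples_split < 2:
            raise ConfigurationError("min_samples_split must be >= 2")
        if self.min_samples_leaf < 1:
            raise ConfigurationError("min_samples_leaf must be >= 1")


@dataclass
class TreeNode:
    value: float
    n_samples: int
    feature: int | None = None
    threshold: float | None = None
    gain: float = 0.0  # tau_i^2 of this split (parent SSE - child SSEs)
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class RegressionTree:
    root: TreeNode
    n_features: int
    config: TreeConfig
    feature_map: np.ndarray | None = None  # local -> global column indices

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.feature_map is not None:
            X = X[:, self.feature_map]
        out = np.empty(len(X))
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.value
        return out

    def splits(self):
        """Yield (global feature index, tau^2) over all internal nodes."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                feat = node.feature
                if self.feature_map is not None:
                    feat = int(self.feature_map[feat])
                yield feat, node.gain
                stack.append(node.left)
                stack.append(node.right)


def _node_sse(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2))


def _best_split(X: np.ndarray, y: np.ndarray, cfg: TreeConfig):
    """Exhaustive search for the (gain, feature, threshold) maximizing the
    SSE improvement; returns None if no admissible split improves."""
    n, p = X.shape
    total = _node_sse(y)
    best_gain, best_feat, best_thr = 0.0, None, None
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        csum = np.cumsum(ys)
        csq = np.cumsum(ys * ys)
        idx = np.arange(1, n)  # left size
        valid = (xs[1:] > xs[:-1]) & (idx >= cfg.min_samples_leaf) & (n - idx >= cfg.min_samples_leaf)
        if not valid.any():
            continue
        nl = idx[valid].astype(float)
        nr = n - nl
        sl, ql = csum[:-1][valid], csq[:-1][valid]
        sr, qr = csum[-1] - sl, csq[-1] - ql
        sse = (ql - sl * sl / nl) + (qr - sr * sr / nr)
        gains = total - sse
        i = int(np.argmax(gains))  # first max -> smallest threshold on ties
        if gains[i] > best_gain + _GAIN_EPS * max(1.0, total):
            pos = np.flatnonzero(valid)[i]
            best_gain = float(gains[i])
            best_feat = j
            best_thr = 0.5 * (xs[pos] + xs[pos + 1])
    if best_feat is None:
        return None
    return best_gain, best_feat, best_thr


def _grow(X: np.ndarray, y: np.ndarray, cfg: TreeConfig, depth: int) -> TreeNode:
    node = TreeNode(value=float(y.mean()), n_samples=len(y))
    if depth >= cfg.max_depth or len(y) < cfg.min_samples_split:
        return node
    found = _best_split(X, y, cfg)
    if found is None:
        return node
    gain, feat, thr = found
    mask = X[:, feat] <= thr
    node.feature, node.threshold, node.gain = feat, float(thr), gain
    node.left = _grow(X[mask], y[mask], cfg, depth + 1)
    node.right = _grow(X[~mask], y[~mask], cfg, depth + 1)
    return node


def fit_regression_tree(
    X: np.ndarray, y: np.ndarray, config: TreeConfig | None = None
) -> RegressionTree:
    """Greedy binary CART with the squared-error criterion."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(y) == 0 or X.shape[0] == 0:
        raise DataError("cannot fit a tree on empty data")
    if X.shape[0] != len(y):
        raise DataError(f"X has {X.shape[0]} rows but y has {len(y)}")
    config = config or TreeConfig()
    return RegressionTree(_grow(X, y, config, 0), X.shape[1], config)


@dataclass
class GBDTModel:
    """Gradient-boosted regression trees under squared-error loss.

    Stage m fits the residuals of the running prediction f_{m-1} and the
    model advances as f_m = f_{m-1} + learning_rate * T_m(x), starting from
    the training mean.
    """

    stages: list[RegressionTree]
    learning_rate: float
    initial_prediction: float
    n_features: int

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.full(len(X), self.initial_prediction)
        for tree in self.stages:
            out += self.learning_rate * tree.predict(X)
        return out

    def staged_predict(self, X: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.full(len(X), self.initial_prediction)
        for tree in self.stages:
            out = out + self.learning_rate * tree.predict(X)
            yield out.copy()


def fit_gbdt(
    X: np.ndarray,
    y: np.ndarray,
    n_stages: int = 100,
    learning_rate: float = 0.1,
    tree_config: TreeConfig | None = None,
) -> GBDTModel:
    if n_stages < 1:
        raise ConfigurationError("n_stages must be >= 1")
    if learning_rate <= 0:
        raise ConfigurationError("learning_rate must be > 0")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    tree_config = tree_config or TreeConfig(max_depth=3)
    f = np.full(len(y), y.mean())
    stages = []
    for _ in range(n_stages):
        tree = fit_regression_tree(X, y - f, tree_config)
        f = f + learning_rate * tree.predict(X)
        stages.append(tree)
    return GBDTModel(stages, learning_rate, float(y.mean()), X.shape[1])


@dataclass
class RFModel:
    """Bootstrap-aggregated regression trees; prediction is the tree mean."""

    trees: list[RegressionTree]
    tree_config: TreeConfig
    bootstrap_seed: int
    n_features: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.mean([tree.predict(X) for tree in self.trees], axis=0)

    def tree_predictions(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.stack([tree.predict(X) for tree in self.trees])


def fit_rf(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    tree_config: TreeConfig | None = None,
    seed: int = 0,
    feature_subsample: float = 1.0,
    bootstrap: bool = True,
) -> RFModel:
    """Random forest with seeded bootstrap resampling.

    ``feature_subsample`` < 1 restricts each tree to a random descriptor
    subset (all descriptors by default).
    """
    if n_trees < 1:
        raise ConfigurationError("n_trees must be >= 1")
    if not 0.0 < feature_subsample <= 1.0:
        raise ConfigurationError("feature_subsample must lie in (0, 1]")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    tree_config = tree_config or TreeConfig()
    rng = np.random.default_rng(seed)
    n, p = X.shape
    n_feat = max(1, int(round(feature_subsample * p)))
    trees = []
    for _ in range(n_trees):
        rows = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        if n_feat < p:
            feats = np.sort(rng.choice(p, size=n_feat, replace=False))
        else:
            feats = None
        Xb = X[rows] if feats is None else X[np.ix_(rows, feats)]
        tree = fit_regression_tree(Xb, y[rows], tree_config)
        if feats is not None:
            tree.feature_map = feats
            tree.n_features = p
        trees.append(tree)
    return RFModel(trees, tree_config, seed, p)


@dataclass
class ImportanceReport:
    """Per-feature split-gain importance for a tree or ensemble."""

    importance: np.ndarray  # mean over trees of per-feature sum of tau^2
    share: np.ndarray  # importance normalized to sum 1 (zeros if no split)
    ranking: np.ndarray  # feature indices, non-increasing importance
    feature_names: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or [f"x{j}" for j in range(len(self.importance))]
        frame = pd.DataFrame(
            {
                "feature": names,
                "importance": self.importance,
                "share": self.share,
            }
        )
        rank = np.empty(len(self.ranking), dtype=int)
        rank[self.ranking] = np.arange(1, len(self.ranking) + 1)
        frame["rank"] = rank
        return frame.sort_values("rank").reset_index(drop=True)

    def successive_ratios(self) -> np.ndarray:
        """importance[rank k+1] / importance[rank k]; helps spot the gap
        after which additional descriptors stop mattering."""
        ordered = self.importance[self.ranking]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(ordered[:-1] > 0, ordered[1:] / ordered[:-1], np.nan)


def split_gain_importance(model, feature_names: list[str] | None = None) -> ImportanceReport:
    """Split-gain importance: per-feature tau^2 sums averaged over trees."""
    if isinstance(model, RegressionTree):
        trees = [model]
        p = model.n_features
    elif isinstance(model, (GBDTModel, RFModel)):
        trees = model.stages if isinstance(model, GBDTModel) else model.trees
        p = model.n_features
    else:
        raise ConfigurationError(f"cannot compute importance for {type(model).__name__}")
    if not trees:
        raise ConfigurationError("model has no fitted trees")
    total = np.zeros(p)
    for tree in trees:
        for feat, gain in tree.splits():
            total[feat] += gain
    importance = total / len(trees)
    s = importance.sum()
    share = importance / s if s > 0 else np.zeros(p)
    # stable ranking: non-increasing importance, ties by column index
    ranking = np.lexsort((np.arange(p), -importance))
    return ImportanceReport(importance, share, ranking, feature_names)


def select_descriptors(
    table: DescriptorTable,
    k: int,
    corr_threshold: float = 0.8,
    n_stages: int = 60,
    learning_rate: float = 0.1,
    tree_config: TreeConfig | None = None,
) -> tuple[list[str], ImportanceReport]:
    """Split-gain descriptor selection with the pairwise correlation rule.

    Fits a gradient-boosted ensemble on all descriptors, ranks them by
    split-gain importance, then walks the ranking keeping a descriptor only
    if |Pearson r| with every already-kept descriptor is < ``corr_threshold``,
    stopping once ``k`` are kept.  Warns (and returns the shorter list) if
    the ranking is exhausted first.
    """
    p = len(table.descriptor_names)
    if k < 1 or k > p:
        raise ConfigurationError(f"k must lie in [1, {p}], got {k}")
    tree_config = tree_config or TreeConfig(max_depth=3)
    model = fit_gbdt(table.X, table.response, n_stages, learning_rate, tree_config)
    report = split_gain_importance(model, feature_names=table.descriptor_names)
    corr = np.corrcoef(table.X, rowvar=False)
    kept: list[int] = []
    for j in report.ranking:
        if report.importance[j] <= 0:
            break
        if all(abs(corr[j, i]) < corr_threshold for i in kept):
            kept.append(int(j))
        if len(kept) == k:
            break
    names = [table.descriptor_names[j] for j in kept]
    if len(names) < k:
        warnings.warn(
            f"only {len(names)} descriptors satisfy the correlation rule "
            f"(requested {k})",
            stacklevel=2,
        )
    return names, report
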