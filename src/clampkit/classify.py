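"""Cell-typing machinery: Ward clustering, Thorndike cut, tree/forest models.

Neurons are z-scored on the 15 membrane properties, clustered by Ward's
agglomerative method (squared-Euclidean ESS criterion), and the cluster
count is chosen at the largest jump in merge height (Thorndike).  The
cluster labels then supervise a cost-complexity-pruned decision tree
(bootstrap-validated over 500 80/20 splits without replacement) and a
10,000-tree random forest with OOB error, Gini importances, a leaf
co-occupancy proximity matrix and its 2-D PCA embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier


@dataclass
class FeatureTable:
    """Neurons × properties table with optional labels / response status."""

    data: pd.DataFrame
    labels: np.ndarray | None = None
    response_status: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.data):
                raise ValueError("labels length must match rows")
        if self.response_status is not None:
            self.response_status = np.asarray(self.response_status)
            if len(self.response_status) != len(self.data):
                raise ValueError("response_status length must match rows")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


def zscore_table(table: FeatureTable) -> FeatureTable:
    """Column-wise z-scoring: each column to mean 0, sample SD 1."""
    x = table.data
    sd = x.std(ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    z = (x - x.mean()) / sd
    return FeatureTable(z, labels=table.labels, response_status=table.response_status)


@dataclass
class ClusterResult:
    """Ward merge sequence with heights; labels at any k on demand."""

    linkage_matrix: np.ndarray
    n: int
    chosen_k: int | None = None
    labels: np.ndarray | None = None

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def ess_increments(self) -> np.ndarray:
        """Within-cluster ESS increase at each merge (height² / 2)."""
        return self.heights**2 / 2.0

    @property
    def gap_profile(self) -> np.ndarray:
        return np.diff(self.heights)

    def labels_at(self, k: int) -> np.ndarray:
        return fcluster(self.linkage_matrix, t=k, criterion="maxclust")

    def merge_sequence(self) -> list[tuple[frozenset, float]]:
        members: dict[int, frozenset] = {i: frozenset([i]) for i in range(self.n)}
        out = []
        for m, (a, b, h, _) in enumerate(self.linkage_matrix):
            merged = members[int(a)] | members[int(b)]
            members[self.n + m] = merged
            out.append((merged, float(h)))
        return out


def ward_cluster(ztable: FeatureTable) -> ClusterResult:
    """Agglomerate by Ward's minimum-ESS-increase criterion."""
    x = ztable.values
    if len(x) < 2:
        raise ValueError("need at least 2 rows")
    if np.isnan(x).any():
        raise ValueError("missing values in clustering input")
    return ClusterResult(linkage_matrix=linkage(x, method="ward"), n=len(x))


def thorndike_cut(result: ClusterResult) -> tuple[int, np.ndarray]:
    """Choose k at the stage preceding the largest merge-height jump.

    With merges indexed 0..n−2, a gap between merge j and j+1 cuts the
    dendrogram there, leaving k = n − j − 1 clusters (so k ≥ 2 always).
    """
    if result.n < 3:
        raise ValueError("Thorndike cut needs at least 3 rows")
    gaps = result.gap_profile
    j = int(np.argmax(gaps))
    k = result.n - j - 1
    labels = result.labels_at(k)
    result.chosen_k, result.labels = k, labels
    return k, labels


# ---------------------------------------------------------------------------
# Decision tree (rpart-style cost-complexity pruning)
# ---------------------------------------------------------------------------


@dataclass
class TreeModel:
    model: DecisionTreeClassifier
    ccp_alpha: float
    cp_table: pd.DataFrame  # alpha vs cross-validated misclassification error
    full_depth: int
    pruned_depth: int
    bootstrap_accuracy: float | None = None  # mean %, filled by bootstrap_validate

    @property
    def root_feature(self) -> str | int | None:
        t = self.model.tree_
        if t.node_count == 0 or t.children_left[0] == -1:
            return None
        i = int(t.feature[0])
        names = getattr(self.model, "feature_names_in_", None)
        return names[i] if names is not None else i


def _pruned_tree(
    x: np.ndarray,
    y: np.ndarray,
    seed: int,
    min_samples_split: int,
    cv: int,
) -> tuple[DecisionTreeClassifier, float, pd.DataFrame]:
    rng = np.random.RandomState(seed)
    full = DecisionTreeClassifier(
        min_samples_split=min_samples_split, random_state=rng.randint(2**31)
    ).fit(x, y)
    alphas = np.unique(full.cost_complexity_pruning_path(x, y).ccp_alphas)
    alphas = alphas[alphas >= 0]
    n_splits = min(cv, int(np.min(np.unique(y, return_counts=True)[1])), len(y))
    if n_splits < 2 or len(alphas) == 1:
        return full, 0.0, pd.DataFrame({"alpha": [0.0], "cv_error": [np.nan]})
    folds = list(
        StratifiedKFold(
            n_splits=n_splits, shuffle=True, random_state=rng.randint(2**31)
        ).split(x, y)
    )
    errors = []
    for alpha in alphas:
        wrong = 0
        for tr, te in folds:
            clf = DecisionTreeClassifier(
                min_samples_split=min_samples_split,
                ccp_alpha=alpha,
                random_state=0,
            ).fit(x[tr], y[tr])
            wrong += int((clf.predict(x[te]) != y[te]).sum())
        errors.append(wrong / len(y))
    best = int(np.argmin(errors))  # ties -> smallest alpha (least pruning)
    pruned = DecisionTreeClassifier(
        min_samples_split=min_samples_split,
        ccp_alpha=alphas[best],
        random_state=0,
    ).fit(x, y)
    return pruned, float(alphas[best]), pd.DataFrame(
        {"alpha": alphas, "cv_error": errors}
    )


def fit_tree(
    table: FeatureTable,
    labels: Sequence | None = None,
    min_samples_split: int = 5,
    cv: int = 10,
    seed: int = 0,
) -> TreeModel:
    """Grow a classification tree and prune at the min-CV-error complexity.

    The cost-complexity path of the fully grown tree supplies the candidate
    subtree sequence; internal (stratified, 10-fold by default) cross-
    validation picks the alpha with the least misclassification error.
    """
    y = np.asarray(labels if labels is not None else table.labels)
    if y is None or len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    x = table.values
    full = DecisionTreeClassifier(min_samples_split=min_samples_split, random_state=0)
    full.fit(table.data, y)
    pruned, alpha, cp_table = _pruned_tree(x, y, seed, min_samples_split, cv)
    # refit pruned tree with feature names for interpretability
    named = DecisionTreeClassifier(
        min_samples_split=min_samples_split, ccp_alpha=alpha, random_state=0
    ).fit(table.data, y)
    return TreeModel(
        model=named,
        ccp_alpha=alpha,
        cp_table=cp_table,
        full_depth=int(full.get_depth()),
        pruned_depth=int(named.get_depth()),
    )


# ---------------------------------------------------------------------------
# Random forest
# ---------------------------------------------------------------------------


@dataclass
class ForestModel:
    model: RandomForestClassifier
    n_trees: int
    oob_error: float  # fraction
    gini_importance: pd.Series  # mean decrease in Gini impurity
    proximity: np.ndarray  # fraction of trees sharing a terminal node
    cv_accuracy: float | None = None  # mean %, filled by bootstrap_validate


def fit_forest(
    table: FeatureTable,
    labels: Sequence | None = None,
    n_trees: int = 10_000,
    seed: int = 0,
    max_features: str | int = "sqrt",
    compute_proximity: bool = True,
) -> ForestModel:
    """Random forest with OOB error, Gini importances and proximity matrix.

    Each tree sees a bootstrap (with replacement) of the rows and a random
    feature subset of size √p per split.  The proximity of two samples is
    the fraction of trees in which they land in the same terminal node.
    """
    y = np.asarray(labels if labels is not None else table.labels)
    if y is None or len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    ).fit(table.data, y)
    proximity = (
        _proximity_matrix(rf, table.data)
        if compute_proximity
        else np.eye(len(table))
    )
    return ForestModel(
        model=rf,
        n_trees=n_trees,
        oob_error=float(1.0 - rf.oob_score_),
        gini_importance=pd.Series(rf.feature_importances_, index=table.data.columns),
        proximity=proximity,
    )


def _proximity_matrix(rf: RandomForestClassifier, x: np.ndarray) -> np.ndarray:
    leaves = rf.apply(x)  # (n_samples, n_trees)
    n = leaves.shape[0]
    prox = np.zeros((n, n))
    # chunk over trees to bound memory at n*n per chunk
    for t0 in range(0, leaves.shape[1], 256):
        block = leaves[:, t0 : t0 + 256]
        prox += (block[:, None, :] == block[None, :, :]).sum(axis=2)
    return prox / leaves.shape[1]


def proximity_pca(forest: ForestModel, n_components: int = 2) -> np.ndarray:
    """Per-sample coordinates on the first two PCs of the proximity matrix."""
    prox = forest.proximity
    if np.allclose(prox, prox.flat[0]):
        raise ValueError("degenerate proximity matrix (all entries equal)")
    return PCA(n_components=n_components).fit_transform(prox)


# ---------------------------------------------------------------------------
# Validation and concordance
# ---------------------------------------------------------------------------


def bootstrap_validate(
    model_kind: str,
    table: FeatureTable,
    labels: Sequence | None = None,
    n_draws: int | None = None,
    seed: int = 0,
    test_fraction: float = 0.2,
    stratified: bool = True,
    n_trees: int = 1000,
    min_samples_split: int = 5,
    cv: int = 10,
) -> float:
    """Mean held-out accuracy (%) over seeded resampling draws.

    ``model_kind="tree"``: 500 draws by default; each is an 80/20
    train/test split drawn without replacement, the tree grown and pruned
    on the training portion and scored on the held-out 20%.
    ``model_kind="forest"``: 20 runs; the 20% test set is drawn without
    replacement and the forest trains on a bootstrap (with replacement)
    of the remaining 80%.
    """
    y = np.asarray(labels if labels is not None else table.labels)
    x = table.values
    n = len(y)
    if n_draws is None:
        n_draws = 500 if model_kind == "tree" else 20
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_draws):
        test_idx = _draw_test(y, test_fraction, stratified, rng)
        if test_idx.size == 0:
            raise ValueError("empty test split")
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if model_kind == "tree":
            model, _, _ = _pruned_tree(
                x[train_idx], y[train_idx],
                int(rng.integers(2**31)), min_samples_split, cv,
            )
        elif model_kind == "forest":
            boot = rng.choice(train_idx, size=train_idx.size, replace=True)
            model = RandomForestClassifier(
                n_estimators=n_trees,
                max_features="sqrt",
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            ).fit(x[boot], y[boot])
        else:
            raise ValueError(f"unknown model_kind {model_kind!r}")
        accs.append(float(np.mean(model.predict(x[test_idx]) == y[test_idx])))
    return 100.0 * float(np.mean(accs))


def _draw_test(
    y: np.ndarray, fraction: float, stratified: bool, rng: np.random.Generator
) -> np.ndarray:
    n = len(y)
    if not stratified:
        return rng.choice(n, size=max(1, int(round(fraction * n))), replace=False)
    picks = []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        k = max(1, int(round(fraction * idx.size)))
        picks.append(rng.choice(idx, size=k, replace=False))
    return np.concatenate(picks)


def responder_concordance(
    labels: Sequence,
    response_status: Sequence,
    fs_label=None,
    feature_table: FeatureTable | None = None,
) -> tuple[pd.DataFrame, float]:
    """Cluster × response contingency and % of responders in the FS cluster.

    ``fs_label`` names the fast-spiking cluster; if omitted it is inferred
    as the cluster with the higher mean ``max_firing_rate`` in
    ``feature_table`` (one of the two must be provided).
    """
    labels = np.asarray(labels)
    resp = np.asarray(response_status, dtype=bool)
    if len(labels) != len(resp):
        raise ValueError("labels and response_status must align")
    if fs_label is None:
        if feature_table is None or "max_firing_rate" not in feature_table.data:
            raise ValueError(
                "provide fs_label or a feature_table with max_firing_rate"
            )
        rates = feature_table.data["max_firing_rate"].to_numpy()
        means = {c: rates[labels == c].mean() for c in np.unique(labels)}
        fs_label = max(means, key=means.get)
    table = pd.crosstab(
        pd.Series(labels, name="cluster"), pd.Series(resp, name="responder")
    )
    n_resp = int(resp.sum())
    if n_resp == 0:
        raise ValueError("no responders")
    pct = 100.0 * int(resp[labels == fs_label].sum()) / n_resp
    return table, pct
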