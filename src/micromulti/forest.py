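"""Bagged regression-tree forest with OOB error and %IncMSE importance.

Used to ask how much of a profile matrix (GCF content or metabolome) a
grouping criterion explains: the encoded group label is regressed on the
profile features, variance explained is R^2 = 1 - MSE_oob / Var(y), and
feature importance is the percent increase of each tree's out-of-bag MSE
when that feature's OOB values are permuted.

Individual trees are sklearn ``DecisionTreeRegressor``s; the bagging loop,
out-of-bag bookkeeping and per-tree permutation importance are implemented
here so every tree's in-bag/OOB index sets are available — the quantities the
importance definition needs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ForestConfig",
    "ForestResult",
    "fit_forest",
    "permutation_importance",
    "compare_groupings",
    "encode_response",
]


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters.

    ``n_trees`` defaults to 5,000 (the pipeline setting); ``mtry`` is the
    number of features tried per split (regression convention ceil(p/3) when
    unset); nodes with fewer than ``min_node_size`` samples are not split.
    """

    n_trees: int = 5000
    mtry: int | None = None
    min_node_size: int = 5
    seed: int = 0
    response_encoding: str = "auto"  # auto | binary | integer_codes | one_vs_rest

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass
class ForestResult:
    r_squared: float
    oob_mse: float
    importance: pd.Series | None  # feature -> %IncMSE
    top_k: list[str] | None
    n_trees: int
    _trees: list = field(default_factory=list, repr=False)
    _oob_sets: list = field(default_factory=list, repr=False)
    _oob_mses: list = field(default_factory=list, repr=False)
    _importance_seed: int | None = field(default=None, repr=False)
    _feature_names: list[str] = field(default_factory=list, repr=False)


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def fit_forest(X, y, config: ForestConfig, compute_importance: bool = True, top_k: int = 10) -> ForestResult:
    """Grow a bagged regression forest and score it out of bag.

    Each tree is grown on a bootstrap sample of n draws with replacement; the
    OOB prediction for a sample averages the trees that did not see it; R^2 =
    1 - MSE_oob / Var(y) with the population variance, so it can be negative
    for uninformative predictors.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n < 10:
        raise ValueError("need at least 10 samples")
    var_y = float(np.var(y))
    if var_y == 0:
        raise ValueError("constant response: variance of y is zero")
    mtry = config.mtry if config.mtry is not None else max(1, math.ceil(p / 3))
    if mtry > p:
        raise ValueError(f"mtry={mtry} exceeds number of features p={p}")

    rng = np.random.default_rng(config.seed)
    oob_sum = np.zeros(n)
    oob_count = np.zeros(n, dtype=int)
    trees, oob_sets, oob_mses = [], [], []
    for _ in range(config.n_trees):
        boot = rng.integers(0, n, size=n)
        in_bag = np.zeros(n, dtype=bool)
        in_bag[boot] = True
        oob = np.flatnonzero(~in_bag)
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_split=config.min_node_size,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(Xm[boot], y[boot])
        trees.append(tree)
        oob_sets.append(oob)
        if len(oob):
            pred = tree.predict(Xm[oob])
            oob_sum[oob] += pred
            oob_count[oob] += 1
            oob_mses.append(float(np.mean((pred - y[oob]) ** 2)))
        else:
            oob_mses.append(np.nan)

    covered = oob_count > 0
    if not covered.all():
        warnings.warn(
            f"{int((~covered).sum())} sample(s) had no OOB tree and were "
            "excluded from the OOB MSE; increase n_trees",
            stacklevel=2,
        )
    oob_pred = oob_sum[covered] / oob_count[covered]
    oob_mse = float(np.mean((oob_pred - y[covered]) ** 2))
    result = ForestResult(
        r_squared=1.0 - oob_mse / var_y,
        oob_mse=oob_mse,
        importance=None,
        top_k=None,
        n_trees=config.n_trees,
        _trees=trees,
        _oob_sets=oob_sets,
        _oob_mses=oob_mses,
        _importance_seed=int(rng.integers(2**31 - 1)),
        _feature_names=names,
    )
    if compute_importance:
        result.importance = permutation_importance(result, Xm, y)
        result.top_k = list(result.importance.sort_values(ascending=False).head(top_k).index)
    return result


def permutation_importance(forest: ForestResult, X, y) -> pd.Series:
    """%IncMSE: per-feature OOB permutation importance.

    For each tree and each feature used by that tree, the feature's column is
    permuted within the tree's OOB set and the tree's OOB MSE recomputed;
    %IncMSE_j = 100 x mean over trees of (MSE_perm - MSE_tree) / MSE_tree.
    Features a tree never splits on contribute exactly 0 for that tree
    (permutation cannot change its predictions), so a constant column scores
    0 exactly.
    """
    if not forest._trees:
        raise ValueError("forest carries no fitted trees")
    Xm, names = _as_matrix(X)
    if len(names) != len(forest._feature_names):
        raise ValueError("feature matrix does not match the fitted forest")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(forest._importance_seed)
    p = Xm.shape[1]
    total = np.zeros(p)
    n_used = 0
    for tree, oob, mse_tree in zip(forest._trees, forest._oob_sets, forest._oob_mses):
        if len(oob) == 0 or not np.isfinite(mse_tree):
            continue
        n_used += 1
        if mse_tree == 0:
            continue  # ratio undefined; tree contributes 0 for every feature
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        X_oob = Xm[oob]
        y_oob = y[oob]
        for j in used:
            if j >= p:
                raise ValueError(f"feature index {j} absent from the model matrix")
            saved = X_oob[:, j].copy()
            X_oob[:, j] = saved[rng.permutation(len(saved))]
            mse_perm = float(np.mean((tree.predict(X_oob) - y_oob) ** 2))
            X_oob[:, j] = saved
            total[j] += (mse_perm - mse_tree) / mse_tree
    if n_used == 0:
        raise ValueError("no tree has OOB samples; cannot compute importance")
    return pd.Series(100.0 * total / n_used, index=forest._feature_names, name="pct_inc_mse")


def encode_response(labels: pd.Series, encoding: str = "auto") -> np.ndarray:
    """Numeric encoding of a categorical grouping for regression forests.

    Two-level criteria become 0/1; multi-level criteria become integer codes
    of the sorted levels (``auto``). The encoding is the analysis's largest
    free choice and is therefore explicit and logged by the pipeline.
    """
    levels = sorted(pd.Series(labels).unique())
    if len(levels) < 2:
        raise ValueError("grouping must have at least 2 levels")
    if encoding == "binary":
        if len(levels) != 2:
            raise ValueError("binary encoding needs exactly 2 levels")
    elif encoding not in ("auto", "integer_codes"):
        raise ValueError(f"unknown encoding {encoding!r}")
    return np.array([levels.index(v) for v in labels], dtype=float)


def compare_groupings(
    profile_table: pd.DataFrame,
    metadata: pd.DataFrame,
    groupings: list[str],
    config: ForestConfig,
    compute_importance: bool = True,
    top_k: int = 10,
) -> tuple[pd.DataFrame, dict[str, ForestResult]]:
    """One forest per grouping criterion; results ranked by R^2.

    ``profile_table`` holds samples x features, ``metadata`` one row per
    sample with the grouping columns. For ``one_vs_rest`` encoding a forest
    is fitted per level and the per-level R^2 averaged.
    """
    missing = [g for g in groupings if g not in metadata.columns]
    if missing:
        raise ValueError(f"groupings absent from metadata: {missing}")
    results: dict[str, ForestResult] = {}
    rows = []
    for grouping in groupings:
        labels = metadata.loc[profile_table.index, grouping]
        if config.response_encoding == "one_vs_rest" and labels.nunique() > 2:
            levels = sorted(labels.unique())
            subs = []
            for lev in levels:
                y = (labels == lev).astype(float).to_numpy()
                subs.append(fit_forest(profile_table, y, config, compute_importance=False))
            r2 = float(np.mean([s.r_squared for s in subs]))
            res = subs[int(np.argmax([s.r_squared for s in subs]))]
            res.r_squared = r2
        else:
            enc = "auto" if config.response_encoding == "one_vs_rest" else config.response_encoding
            y = encode_response(labels, enc)
            res = fit_forest(
                profile_table, y, config, compute_importance=compute_importance, top_k=top_k
            )
        results[grouping] = res
        rows.append(
            {
                "grouping": grouping,
                "r_squared": res.r_squared,
                "oob_mse": res.oob_mse,
                "n_trees": res.n_trees,
            }
        )
    summary = (
        pd.DataFrame(rows).sort_values("r_squared", ascending=False).set_index("grouping")
    )
    return summary, results
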