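"""Comparison learners under a common fit/predict contract.

Alongside PLS, the benchmark runs a CART regression tree with
cost-complexity pruning, elastic net / Lasso, and a single-feature
"maximum correlation" baseline. All learners fit on training lines only,
select their hyperparameters by nested cross-validation inside the
training fold, and expose a pure ``predict``.

The penalized fits and tree growing are delegated to scikit-learn
(coordinate descent and CART respectively); the elastic-net objective
used here, (1/2n)·RSS + λ[(1−α)‖β‖² + α‖β‖₁], is mapped exactly onto
scikit-learn's (alpha, l1_ratio) parameterization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.tree import DecisionTreeRegressor

from .pls import PLSModel, pls_fit, pls_predict

__all__ = [
    "fold_indices",
    "complement_indices",
    "TreeModel",
    "ElasticNetModel",
    "MaxCorrModel",
    "tree_fit",
    "elastic_net_fit",
    "select_alpha_lambda",
    "lasso_sparsity_sweep",
    "max_corr_fit",
    "PLSLearner",
    "TreeLearner",
    "ElasticNetLearner",
    "LassoLearner",
    "MaxCorrLearner",
    "make_learner",
]


def fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random unstratified partition of ``range(n)`` into ``n_folds`` folds.

    Fold sizes differ by at most one (e.g. 49 lines in 10 folds gives nine
    fives and one four).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n_folds = min(n_folds, n)
    perm = rng.permutation(n)
    return [np.asarray(f) for f in np.array_split(perm, n_folds)]


def complement_indices(n: int, idx: np.ndarray) -> np.ndarray:
    """Indices of range(n) not in ``idx`` (fast fold complement)."""
    mask = np.ones(n, dtype=bool)
    mask[idx] = False
    return np.nonzero(mask)[0]


# ---------------------------------------------------------------------------
# regression tree
# ---------------------------------------------------------------------------


@dataclass
class TreeModel:
    """CART regression tree with a nested-CV–selected pruning level."""

    estimator: DecisionTreeRegressor
    ccp_alpha: float
    min_bucket: int
    cv_rms: float = float("nan")  # nested-CV RMS at the selected pruning level

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    @property
    def root_feature(self) -> Optional[int]:
        """Index of the feature split at the root, or None for a stump."""
        f = self.estimator.tree_.feature[0]
        return None if f < 0 else int(f)


def _collapse_alphas(tree) -> np.ndarray:
    """Weakest-link pruning levels per node of a fitted sklearn tree.

    Returns, for every node, the cost-complexity parameter at which the
    node's subtree collapses into a leaf (np.inf for nodes that are leaves
    already). Matches sklearn's ccp pruning: a node is pruned at
    ``ccp_alpha`` iff its collapse level is <= ccp_alpha.
    """
    t = tree.tree_
    left, right = t.children_left, t.children_right
    n_nodes = t.node_count
    total_w = t.weighted_n_node_samples[0]
    r_node = t.impurity * t.weighted_n_node_samples / total_w

    parent = np.full(n_nodes, -1)
    for i in range(n_nodes):
        if left[i] >= 0:
            parent[left[i]] = i
            parent[right[i]] = i

    # sklearn stores nodes in preorder, so children have larger indices
    r_sub = r_node.copy()
    n_leaves = np.ones(n_nodes)
    for i in range(n_nodes - 1, -1, -1):
        if left[i] >= 0:
            r_sub[i] = r_sub[left[i]] + r_sub[right[i]]
            n_leaves[i] = n_leaves[left[i]] + n_leaves[right[i]]

    collapse = np.full(n_nodes, np.inf)
    active = left >= 0  # internal nodes still standing
    alpha = 0.0
    while active.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(active, (r_node - r_sub) / np.maximum(n_leaves - 1, 1), np.inf)
        weakest = int(np.argmin(g))
        alpha = max(alpha, float(g[weakest]))
        # the whole subtree of the weakest link vanishes at this level
        stack = [weakest]
        removed_r, removed_leaves = r_sub[weakest], n_leaves[weakest]
        while stack:
            node = stack.pop()
            if active[node]:
                collapse[node] = alpha
                active[node] = False
                stack.extend((left[node], right[node]))
        # the collapsed node now counts as one leaf with risk r_node
        delta_r = r_node[weakest] - removed_r
        delta_l = 1 - removed_leaves
        a = parent[weakest]
        while a >= 0:
            r_sub[a] += delta_r
            n_leaves[a] += delta_l
            a = parent[a]
    return collapse


def _pruned_predictions(tree, collapse: np.ndarray, X: np.ndarray,
                        alphas: np.ndarray) -> np.ndarray:
    """Predictions of every pruned subtree at once: (n_samples, n_alphas)."""
    t = tree.tree_
    left, right = t.children_left, t.children_right
    feature, threshold = t.feature, t.threshold
    value = t.value[:, 0, 0]
    out = np.empty((len(X), len(alphas)))
    for i, x in enumerate(X):
        path_nodes = []
        node = 0
        while True:
            path_nodes.append(node)
            if left[node] < 0:
                break
            node = left[node] if x[feature[node]] <= threshold[node] else right[node]
        path_nodes = np.asarray(path_nodes)
        stops = collapse[path_nodes]
        for j, alpha in enumerate(alphas):
            # tolerance absorbs last-ulp differences from sklearn's own
            # pruning-path arithmetic
            hit = np.nonzero(stops <= alpha * (1 + 1e-9) + 1e-15)[0]
            stop = path_nodes[hit[0]] if hit.size else path_nodes[-1]
            out[i, j] = value[stop]
    return out


def _grow_tree(X32, y, min_bucket, ccp_alpha=0.0):
    est = DecisionTreeRegressor(
        min_samples_leaf=min_bucket, ccp_alpha=ccp_alpha, random_state=0
    )
    est.fit(X32, y, check_input=False)
    return est


def tree_fit(
    X: np.ndarray,
    y: np.ndarray,
    min_bucket: int = 5,
    n_inner_folds: int = 10,
    rng: Optional[np.random.Generator] = None,
    max_alphas: int = 8,
) -> TreeModel:
    """Grow a variance-reduction tree and prune by nested 10-fold CV.

    The complexity-parameter grid is the full tree's own cost-complexity
    pruning sequence (subsampled to at most ``max_alphas`` values); the
    winner minimises nested-CV RMS, with ties resolved toward the smaller
    tree (larger alpha). Within the inner CV each fold grows a single full
    tree and evaluates all pruning levels by weakest-link collapsing, which
    is equivalent to refitting at each ccp_alpha. Constant responses yield
    a stump predicting the mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    X32 = np.asfortranarray(X, dtype=np.float32)
    rng = np.random.default_rng(0) if rng is None else rng

    full = _grow_tree(X32, y, min_bucket)
    collapse_full = _collapse_alphas(full)
    finite = collapse_full[np.isfinite(collapse_full)]
    alphas = np.unique(np.concatenate(([0.0], finite)))
    if alphas.size > max_alphas:
        pick = np.unique(np.linspace(0, alphas.size - 1, max_alphas).round().astype(int))
        alphas = alphas[pick]

    if alphas.size == 1 or y.std() == 0:
        return TreeModel(estimator=full, ccp_alpha=0.0, min_bucket=min_bucket,
                         cv_rms=float(np.sqrt(np.mean((y - y.mean()) ** 2))))

    folds = fold_indices(len(y), n_inner_folds, rng)
    sse = np.zeros(alphas.size)
    for te in folds:
        tr = complement_indices(len(y), te)
        sub = _grow_tree(np.asfortranarray(X[tr], dtype=np.float32), y[tr], min_bucket)
        preds = _pruned_predictions(sub, _collapse_alphas(sub), X[te], alphas)
        sse += ((preds - y[te][:, None]) ** 2).sum(axis=0)
    rms = np.sqrt(sse / len(y))
    best = rms.min()
    # ties -> largest alpha (smallest tree)
    j_star = int(np.max(np.nonzero(rms <= best + 1e-12)[0]))
    # nudge the refit level so boundary nodes prune exactly as evaluated
    est = _grow_tree(X32, y, min_bucket, float(alphas[j_star]) * (1 + 1e-9) + 1e-15)
    return TreeModel(
        estimator=est,
        ccp_alpha=float(alphas[j_star]),
        min_bucket=min_bucket,
        cv_rms=float(rms[j_star]),
    )


# ---------------------------------------------------------------------------
# elastic net / Lasso
# ---------------------------------------------------------------------------


@dataclass
class ElasticNetModel:
    """Penalized linear model minimising (1/2n)RSS + λ[(1−α)‖β‖² + α‖β‖₁]."""

    coefficients: np.ndarray
    intercept: float
    lam: float
    alpha: float  # mixing parameter in [0, 1]; 1 = Lasso, 0 = ridge
    cv_rms: float = float("nan")

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients + self.intercept

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.coefficients != 0))


def _sklearn_params(alpha: float, lam: float) -> tuple[float, float]:
    # (1/2n)RSS + λα‖β‖₁ + λ(1−α)‖β‖² == sklearn with
    # a·l1 = λα and a(1−l1)/2 = λ(1−α)  =>  a = λ(2−α), l1 = α/(2−α)
    sk_alpha = lam * (2.0 - alpha)
    l1_ratio = alpha / (2.0 - alpha)
    return sk_alpha, l1_ratio


def elastic_net_fit(
    X: np.ndarray, y: np.ndarray, alpha: float, lam: float
) -> ElasticNetModel:
    """Fit the elastic net at a fixed (α, λ); the intercept is unpenalized."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam == 0:
        ols = LinearRegression().fit(X, y)
        return ElasticNetModel(
            coefficients=ols.coef_.copy(), intercept=float(ols.intercept_),
            lam=0.0, alpha=alpha,
        )
    sk_alpha, l1_ratio = _sklearn_params(alpha, lam)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        est = ElasticNet(
            alpha=sk_alpha, l1_ratio=l1_ratio, max_iter=50_000, tol=1e-8
        ).fit(X, y)
    return ElasticNetModel(
        coefficients=est.coef_.copy(), intercept=float(est.intercept_),
        lam=float(lam), alpha=float(alpha),
    )


def _lambda_grid(X, y, alpha: float, n_lambda: int, min_ratio: float) -> np.ndarray:
    yc = y - y.mean()
    lam_max = np.max(np.abs(X.T @ yc)) / len(y)
    if lam_max <= 0:  # degenerate response: any penalty gives the null model
        lam_max = 1.0
    lam_max = lam_max / max(alpha, 0.05)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def select_alpha_lambda(
    X: np.ndarray,
    y: np.ndarray,
    alphas: Sequence[float] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1)),
    n_lambda: int = 20,
    lambda_min_ratio: float = 1e-3,
    n_inner_folds: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float, float]:
    """Grid-search (α, λ) by nested 10-fold CV RMS.

    Returns (α, λ, cv_rms) of the winner. Ties favour the smallest α, then
    the largest λ (the sparser, more regularized model).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(0) if rng is None else rng
    folds = fold_indices(len(y), n_inner_folds, rng)
    splits = [(complement_indices(len(y), te), te) for te in folds]

    best = (None, None, np.inf)
    for alpha in alphas:
        lams = _lambda_grid(X, y, alpha, n_lambda, lambda_min_ratio)
        sse = np.zeros(lams.size)
        for tr, te in splits:
            for j, lam in enumerate(lams):
                m = elastic_net_fit(X[tr], y[tr], alpha, lam)
                sse[j] += np.sum((m.predict(X[te]) - y[te]) ** 2)
        rms = np.sqrt(sse / len(y))
        for j in range(lams.size):  # λ descending within α
            if rms[j] < best[2] - 1e-12:
                best = (float(alpha), float(lams[j]), float(rms[j]))
    return best


def lasso_sparsity_sweep(
    X: np.ndarray,
    y: np.ndarray,
    n_lambda: int = 30,
    lambda_min_ratio: float = 1e-3,
    n_folds: int = 10,
    rng: Optional[np.random.Generator] = None,
):
    """Cross-validated performance as a function of Lasso support size.

    For each λ on a log-spaced path (α = 1), records the number of nonzero
    coefficients of the full-data fit and the 10-fold CV RMS / Spearman ρ
    of held-out predictions. At full shrinkage the model reduces to the
    training-mean predictor.
    """
    import pandas as pd

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(0) if rng is None else rng
    lams = _lambda_grid(X, y, 1.0, n_lambda, lambda_min_ratio)
    # prepend a penalty heavy enough that every fold-wise fit is empty
    lams = np.concatenate(([lams[0] * 10.0], lams))
    folds = fold_indices(len(y), n_folds, rng)
    rows = []
    for lam in lams:
        pred = np.empty_like(y)
        for te in folds:
            tr = complement_indices(len(y), te)
            m = elastic_net_fit(X[tr], y[tr], 1.0, lam)
            pred[te] = m.predict(X[te])
        full = elastic_net_fit(X, y, 1.0, lam)
        rho = stats.spearmanr(y, pred).statistic if np.std(pred) > 0 else np.nan
        rows.append(
            {
                "lam": float(lam),
                "n_nonzero": full.n_nonzero,
                "cv_rms": float(np.sqrt(np.mean((pred - y) ** 2))),
                "cv_rho": float(rho) if rho == rho else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# maximum-correlation baseline
# ---------------------------------------------------------------------------


@dataclass
class MaxCorrModel:
    """Simple regression on the single most-correlated feature."""

    feature_index: int
    slope: float
    intercept: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.feature_index] * self.slope + self.intercept


def max_corr_fit(X: np.ndarray, y: np.ndarray) -> MaxCorrModel:
    """Pick the feature with largest |Pearson r| to y; ties → lowest index."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("max_corr_fit requires at least 3 training lines")
    sd = X.std(axis=0, ddof=0)
    if not (sd > 0).any():
        raise ValueError("all features are constant; no correlation defined")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    ysd = y.std(ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (len(y) * sd * ysd)
    r[sd == 0] = 0.0
    if ysd == 0:
        r[:] = 0.0
    j = int(np.argmax(np.abs(r)))
    xj = X[:, j]
    var = np.var(xj)
    slope = float(np.cov(xj, y, ddof=0)[0, 1] / var) if var > 0 else 0.0
    intercept = float(y.mean() - slope * xj.mean())
    return MaxCorrModel(feature_index=j, slope=slope, intercept=intercept)


# ---------------------------------------------------------------------------
# common fit/predict contract used by the CV orchestrator
# ---------------------------------------------------------------------------


@dataclass
class FittedPLS:
    model: PLSModel
    n_components: int
    cv_rms: float = float("nan")

    def predict(self, X: np.ndarray) -> np.ndarray:
        return pls_predict(self.model, X, self.n_components)


class PLSLearner:
    """PLS with the number of components chosen by nested CV.

    The selection rule is the first-local-minimum rule: the smallest PC
    where adding one more component increases the nested-CV RMS.
    """

    name = "pls"

    def __init__(self, pc_min: int = 1, pc_max: int = 10):
        self.pc_min = pc_min
        self.pc_max = pc_max

    def fit_nested(self, X, y, n_inner_folds: int, rng: np.random.Generator) -> FittedPLS:
        from .evaluation import select_ncomp  # local import to avoid a cycle
        from .pls import coef_path_1d

        n = len(y)
        folds = fold_indices(n, n_inner_folds, rng)
        sse = np.zeros(self.pc_max)
        for te in folds:
            tr = complement_indices(n, te)
            B, xm, ym, _ = coef_path_1d(X[tr], y[tr], self.pc_max)
            preds = (X[te] - xm) @ B + ym  # (n_te, A); rank-exhausted columns
            sse += ((preds - y[te][:, None]) ** 2).sum(axis=0)  # repeat the deepest model
        rms = np.sqrt(sse / n)
        a_star = select_ncomp(rms[self.pc_min - 1 :]) + (self.pc_min - 1)
        final = pls_fit(X, y, self.pc_max, warn=False)
        a_star = min(a_star, final.n_components)
        return FittedPLS(model=final, n_components=a_star, cv_rms=float(rms[a_star - 1]))


class TreeLearner:
    name = "tree"

    def __init__(self, min_bucket: int = 5, max_alphas: int = 8):
        self.min_bucket = min_bucket
        self.max_alphas = max_alphas

    def fit_nested(self, X, y, n_inner_folds: int, rng: np.random.Generator) -> TreeModel:
        return tree_fit(
            X, y, min_bucket=self.min_bucket, n_inner_folds=n_inner_folds,
            rng=rng, max_alphas=self.max_alphas,
        )


class ElasticNetLearner:
    name = "enet"

    def __init__(self, alphas: Optional[Sequence[float]] = None, n_lambda: int = 20):
        self.alphas = alphas
        self.n_lambda = n_lambda

    def fit_nested(self, X, y, n_inner_folds: int, rng: np.random.Generator) -> ElasticNetModel:
        kwargs = {} if self.alphas is None else {"alphas": self.alphas}
        alpha, lam, cv_rms = select_alpha_lambda(
            X, y, n_lambda=self.n_lambda, n_inner_folds=n_inner_folds, rng=rng, **kwargs
        )
        model = elastic_net_fit(X, y, alpha, lam)
        model.cv_rms = cv_rms
        return model


class LassoLearner(ElasticNetLearner):
    name = "lasso"

    def __init__(self, n_lambda: int = 20):
        super().__init__(alphas=(1.0,), n_lambda=n_lambda)


class MaxCorrLearner:
    name = "maxcorr"

    def fit_nested(self, X, y, n_inner_folds: int, rng: np.random.Generator) -> MaxCorrModel:
        return max_corr_fit(X, y)


_LEARNERS = {
    "pls": PLSLearner,
    "tree": TreeLearner,
    "enet": ElasticNetLearner,
    "lasso": LassoLearner,
    "maxcorr": MaxCorrLearner,
}


def make_learner(spec, **kwargs):
    """Learner factory: accepts a name ('pls', 'tree', 'enet', 'lasso',
    'maxcorr') or passes an existing learner object through."""
    if isinstance(spec, str):
        if spec not in _LEARNERS:
            raise ValueError(f"unknown learner {spec!r}; choose from {sorted(_LEARNERS)}")
        return _LEARNERS[spec](**kwargs)
    return spec
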