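"""Cross-validation orchestration, metrics, and permutation nulls.

The central routine, :func:`repeated_nested_cv`, implements the per-drug
modelling protocol: discard lines without sensitivity data; repeatedly
partition lines into 10 folds; within each training fold transform,
filter and standardize the features, select hyperparameters by nested
10-fold CV, fit, and predict the held-out fold with the training fold's
transform parameters; average Spearman rank correlations (and R², RMS)
over repeats. Statistical significance comes from a permutation null:
shuffle the response across lines, rerun the whole pipeline, and compare.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .feature_prep import (
    FeatureMatrix,
    PROTEIN_SD_MIN,
    TRANSCRIPT_MEAN_MIN,
    TRANSCRIPT_SD_MIN,
    transform_expression,
)
from .learners import complement_indices, fold_indices, make_learner
from .pls import pls2_fit, pls_predict_path

__all__ = [
    "CVConfig",
    "PredictionResult",
    "PermutationNull",
    "repeated_nested_cv",
    "repeated_nested_cv_multi",
    "select_ncomp",
    "r2_explained",
    "spearman_rho",
    "permutation_background",
    "bh_adjust",
    "welch_group_test",
]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings (defaults match the benchmark protocol)."""

    n_folds: int = 10
    n_repeats: int = 100
    nested_n_folds: int = 10
    pc_min: int = 1
    pc_max: int = 10
    seed: int = 0
    metric: str = "spearman"  # 'spearman' or 'r2'

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.pc_min > self.pc_max:
            raise ValueError("pc_min must not exceed pc_max")
        if self.metric not in ("spearman", "r2"):
            raise ValueError("metric must be 'spearman' or 'r2'")


@dataclass
class PredictionResult:
    """Cross-validated predictions and per-repeat summary metrics."""

    measured: pd.Series  # a_i
    predicted: pd.Series  # â_i, averaged over repeats
    per_repeat_rho: np.ndarray
    per_repeat_r2: np.ndarray
    per_repeat_rms: np.ndarray
    n_features_used: float = float("nan")  # mean over folds

    @property
    def rho(self) -> float:
        """Mean Spearman ρ over repeats (ρ_s)."""
        return float(np.nanmean(self.per_repeat_rho))

    @property
    def r2(self) -> float:
        """Mean fraction of variance explained over repeats."""
        return float(np.nanmean(self.per_repeat_r2))

    @property
    def rms(self) -> float:
        return float(np.nanmean(self.per_repeat_rms))

    @property
    def n_lines(self) -> int:
        return len(self.measured)

    def metric_value(self, metric: str) -> float:
        return self.rho if metric == "spearman" else self.r2


@dataclass
class PermutationNull:
    """Empirical null distribution of a performance metric."""

    null_values: np.ndarray
    observed: float
    metric: str

    @property
    def n_shuffles(self) -> int:
        return len(self.null_values)

    @property
    def p_value(self) -> float:
        """One-sided add-one empirical p: (1 + #{null ≥ observed}) / (1 + N)."""
        k = int(np.sum(self.null_values >= self.observed))
        return (1 + k) / (1 + self.n_shuffles)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def r2_explained(a: np.ndarray, a_hat: np.ndarray) -> float:
    """Fraction of variance explained: R² = 1 − ⟨(â−a)²⟩ / ⟨(a−ā)²⟩.

    May be negative (worse than predicting the panel mean); 1 iff perfect.
    """
    a = np.asarray(a, dtype=float)
    a_hat = np.asarray(a_hat, dtype=float)
    if a.shape != a_hat.shape or a.size < 2:
        raise ValueError("a and a_hat must have equal length >= 2")
    denom = np.mean((a - a.mean()) ** 2)
    if denom == 0:
        raise ValueError("measured vector is constant; R² undefined")
    return float(1.0 - np.mean((a_hat - a) ** 2) / denom)


def spearman_rho(a: np.ndarray, a_hat: np.ndarray) -> float:
    """Spearman rank correlation (ties get average ranks).

    Returns NaN (flagged with a warning) when either vector is constant.
    """
    a = np.asarray(a, dtype=float)
    a_hat = np.asarray(a_hat, dtype=float)
    if a.size < 3:
        raise ValueError("spearman_rho requires length >= 3")
    if np.std(a) == 0 or np.std(a_hat) == 0:
        warnings.warn("constant vector: Spearman correlation undefined", stacklevel=2)
        return float("nan")
    return float(stats.spearmanr(a, a_hat).statistic)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_group_test(values: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """Welch's t test between the two groups; returns (t, df, two-sided p).

    ``t`` is signed as group0 − group1 where group0 is the first label in
    sorted order (False before True for boolean labels).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels.size}")
    g0 = values[groups == labels[0]]
    g1 = values[groups == labels[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each group needs at least 2 members")
    if np.var(g0) == 0 and np.var(g1) == 0:
        if g0.mean() == g1.mean():
            return 0.0, float(len(values) - 2), 1.0
    res = stats.ttest_ind(g0, g1, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def select_ncomp(nested_rms: Sequence[float]) -> int:
    """First-local-minimum rule for the number of PLS components.

    Returns the smallest PC (1-based) where RMS(PC+1) > RMS(PC); if the
    RMS never increases, returns the largest PC available.
    """
    rms = np.asarray(list(nested_rms), dtype=float)
    if rms.size == 0:
        raise ValueError("nested_rms must not be empty")
    for i in range(rms.size - 1):
        if rms[i + 1] > rms[i]:
            return i + 1
    return int(rms.size)


# ---------------------------------------------------------------------------
# fold-wise feature preparation (fast path over numpy arrays)
# ---------------------------------------------------------------------------


def _prep_fold(
    arrays: Sequence[np.ndarray], data_types: Sequence[str], train_idx: np.ndarray
) -> np.ndarray:
    """Filter + standardize each block with training-row statistics only,
    then concatenate. Mirrors feature_prep.filter_features/fit_standardizer."""
    mats = []
    for X, dt in zip(arrays, data_types):
        Xtr = X[train_idx]
        if dt == "transcript":
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=1)
            keep = (mu >= TRANSCRIPT_MEAN_MIN) & (sd >= TRANSCRIPT_SD_MIN)
        elif dt == "protein":
            keep = Xtr.std(axis=0, ddof=1) >= PROTEIN_SD_MIN
        else:
            keep = np.ones(X.shape[1], dtype=bool)
        X2 = X[:, keep]
        m = X2[train_idx].mean(axis=0)
        s = X2[train_idx].std(axis=0, ddof=0)
        pos = s > 0
        mats.append((X2[:, pos] - m[pos]) / s[pos])
    Z = np.hstack(mats) if len(mats) > 1 else mats[0]
    if Z.shape[1] == 0:
        raise ValueError("no features survive fold-wise filtering")
    return Z


def _align_blocks(
    blocks: Union[FeatureMatrix, Sequence[FeatureMatrix]], y: pd.Series
) -> tuple[list[np.ndarray], list[str], pd.Series]:
    if isinstance(blocks, FeatureMatrix):
        blocks = [blocks]
    blocks = [transform_expression(b) for b in blocks]
    lines = y.dropna().index
    for b in blocks:
        lines = lines[lines.isin(b.values.index)]
    if len(lines) < 4:
        raise ValueError(f"too few cell lines with complete data ({len(lines)})")
    arrays = [b.values.loc[lines].to_numpy(dtype=float) for b in blocks]
    dtypes = [b.data_type for b in blocks]
    return arrays, dtypes, y.loc[lines].astype(float)


def _repeat_rng(seed: int, rng_key: int, repeat: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(rng_key), int(repeat)))
    )


def repeated_nested_cv(
    blocks: Union[FeatureMatrix, Sequence[FeatureMatrix]],
    y: pd.Series,
    learner,
    cv: CVConfig,
    rng_key: int = 0,
) -> PredictionResult:
    """Repeated 10-fold CV with fold-wise preparation and nested
    hyperparameter selection.

    Multiple feature blocks are prepared independently per fold and
    concatenated (early integration); a single block is the plain per-drug
    protocol. ``rng_key`` isolates the random stream (e.g. one key per
    drug) so results are independently reproducible.
    """
    learner = make_learner(learner)
    arrays, dtypes, yv = _align_blocks(blocks, y)
    n = len(yv)
    n_folds = cv.n_folds
    if n < n_folds:
        warnings.warn(f"only {n} lines; reducing folds from {n_folds} to {n}", stacklevel=2)
        n_folds = n
    y_arr = yv.to_numpy()

    preds = np.empty((cv.n_repeats, n))
    rho = np.empty(cv.n_repeats)
    r2 = np.empty(cv.n_repeats)
    rms = np.empty(cv.n_repeats)
    nfeat = []
    for rep in range(cv.n_repeats):
        rng = _repeat_rng(cv.seed, rng_key, rep)
        folds = fold_indices(n, n_folds, rng)
        yhat = np.empty(n)
        for te in folds:
            tr = complement_indices(n, te)
            Z = _prep_fold(arrays, dtypes, tr)
            model = learner.fit_nested(Z[tr], y_arr[tr], cv.nested_n_folds, rng)
            yhat[te] = model.predict(Z[te])
            nfeat.append(Z.shape[1])
        preds[rep] = yhat
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho[rep] = spearman_rho(y_arr, yhat) if n >= 3 else np.nan
        r2[rep] = r2_explained(y_arr, yhat)
        rms[rep] = float(np.sqrt(np.mean((yhat - y_arr) ** 2)))

    return PredictionResult(
        measured=yv,
        predicted=pd.Series(preds.mean(axis=0), index=yv.index),
        per_repeat_rho=rho,
        per_repeat_r2=r2,
        per_repeat_rms=rms,
        n_features_used=float(np.mean(nfeat)),
    )


def repeated_nested_cv_multi(
    blocks: Union[FeatureMatrix, Sequence[FeatureMatrix]],
    Y: pd.DataFrame,
    cv: CVConfig,
    rng_key: int = 0,
) -> dict[str, PredictionResult]:
    """PLS2 protocol: predict all drugs at once with one shared component set.

    Restricted to cell lines with complete sensitivity data for all modeled
    drugs. The number of components minimises the *summed* nested-CV RMS
    over drugs (first-local-minimum rule on the summed curve).
    """
    complete = Y.dropna(axis=0)
    pseudo_y = pd.Series(0.0, index=complete.index)
    arrays, dtypes, _ = _align_blocks(blocks, pseudo_y)
    lines = [ln for ln in complete.index if ln in pseudo_y.index]
    Yv = complete.loc[lines].to_numpy(dtype=float)
    n, m = Yv.shape
    n_folds = min(cv.n_folds, n)

    preds = np.empty((cv.n_repeats, n, m))
    for rep in range(cv.n_repeats):
        rng = _repeat_rng(cv.seed, rng_key, rep)
        folds = fold_indices(n, n_folds, rng)
        for te in folds:
            tr = complement_indices(n, te)
            Z = _prep_fold(arrays, dtypes, tr)
            # nested selection of the shared component count (summed RMS)
            inner = fold_indices(len(tr), cv.nested_n_folds, rng)
            sse = np.zeros(cv.pc_max)
            for ite in inner:
                itr = complement_indices(len(tr), ite)
                mdl = pls2_fit(Z[tr][itr], Yv[tr][itr], cv.pc_max, warn=False)
                pp = pls_predict_path(mdl, Z[tr][ite])  # (n_val, m, A)
                a_fit = pp.shape[2]
                err = ((pp - Yv[tr][ite][:, :, None]) ** 2).sum(axis=(0, 1))
                sse[:a_fit] += err
                if a_fit < cv.pc_max:
                    sse[a_fit:] += err[-1]
            rms_curve = np.sqrt(sse / (len(tr) * m))
            a_star = select_ncomp(rms_curve[cv.pc_min - 1 :]) + (cv.pc_min - 1)
            final = pls2_fit(Z[tr], Yv[tr], cv.pc_max, warn=False)
            a_star = min(a_star, final.n_components)
            preds[rep][te] = pls_predict_path(final, Z[te])[:, :, a_star - 1]

    results = {}
    for j, drug in enumerate(complete.columns):
        yj = Yv[:, j]
        rho = np.empty(cv.n_repeats)
        r2 = np.empty(cv.n_repeats)
        rmsv = np.empty(cv.n_repeats)
        for rep in range(cv.n_repeats):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho[rep] = spearman_rho(yj, preds[rep, :, j])
            r2[rep] = r2_explained(yj, preds[rep, :, j])
            rmsv[rep] = float(np.sqrt(np.mean((preds[rep, :, j] - yj) ** 2)))
        results[drug] = PredictionResult(
            measured=pd.Series(yj, index=lines),
            predicted=pd.Series(preds[:, :, j].mean(axis=0), index=lines),
            per_repeat_rho=rho,
            per_repeat_r2=r2,
            per_repeat_rms=rmsv,
        )
    return results


def permutation_background(
    blocks: Union[FeatureMatrix, Sequence[FeatureMatrix]],
    y: pd.Series,
    learner,
    cv: CVConfig,
    n_shuffles: int,
    rng_key: int = 0,
    observed: Optional[float] = None,
) -> PermutationNull:
    """Null distribution of the CV metric under response shuffling.

    Each shuffle permutes the response across cell lines and reruns the
    complete pipeline — fold-wise filtering, standardization, and nested
    hyperparameter selection included — with a single CV run per shuffle.
    The observed value (computed with the full ``cv.n_repeats`` if not
    supplied) is compared one-sided: higher metric = better.
    """
    learner = make_learner(learner)
    if observed is None:
        observed = repeated_nested_cv(blocks, y, learner, cv, rng_key=rng_key).metric_value(
            cv.metric
        )
    single = replace(cv, n_repeats=1)
    null = np.empty(n_shuffles)
    y_clean = y.dropna()
    for s in range(n_shuffles):
        rng = _repeat_rng(cv.seed, rng_key, 100_000 + s)
        y_perm = pd.Series(rng.permutation(y_clean.to_numpy()), index=y_clean.index)
        shuffled_cv = replace(single, seed=cv.seed + 1)  # partitions independent of observed
        res = repeated_nested_cv(
            blocks, y_perm, learner, shuffled_cv, rng_key=rng_key * 131 + s + 1
        )
        null[s] = res.metric_value(cv.metric)
    return PermutationNull(null_values=null, observed=float(observed), metric=cv.metric)
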