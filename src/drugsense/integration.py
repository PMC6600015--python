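"""Multi-omic integration and cross-tumor-type transfer benchmarking.

Early integration concatenates fold-wise–prepared feature blocks before a
single model fit; late integration combines per-block predictions with
inverse-RMS weights. Transfer benchmarking trains on all lines outside a
target tissue and evaluates on the target, optionally resampling the
training set down to the target's size ("cross fair") to remove the
sample-size advantage of pooling tissues. A leave-one-out tissue-mean
predictor serves as the tissue-only baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dose_response import mean_viability_auc
from .evaluation import (
    CVConfig,
    PredictionResult,
    _align_blocks,
    _prep_fold,
    _repeat_rng,
    r2_explained,
    spearman_rho,
)
from .feature_prep import FeatureMatrix
from .learners import complement_indices, fold_indices, make_learner

__all__ = [
    "TissuePanel",
    "early_integration_fit",
    "late_integration_predict",
    "late_integration_cv",
    "tissue_mean_predictor",
    "cross_tissue_transfer",
    "cross_fair_benchmark",
    "exclude_duplicate_patients",
]

logger = logging.getLogger(__name__)


@dataclass
class TissuePanel:
    """Feature blocks, sensitivity matrix and annotations for one panel."""

    features: dict[str, FeatureMatrix]  # keyed by data type
    auc: pd.DataFrame  # cell line × drug
    tissues: pd.Series
    patients: pd.Series

    def __post_init__(self):
        lines = set(self.auc.index)
        for name, fm in self.features.items():
            if set(fm.values.index) != lines:
                raise ValueError(f"feature block {name!r} has a different cell-line set")
        if not self.tissues.index.equals(self.auc.index):
            self.tissues = self.tissues.reindex(self.auc.index)
        if self.tissues.isna().any():
            raise ValueError("every cell line needs a tissue label")

    @classmethod
    def from_synthetic(cls, panel) -> "TissuePanel":
        """Assemble a TissuePanel from a SyntheticPanel (AUC recomputed
        from the emitted dose-response table)."""
        auc = mean_viability_auc(panel.dose_response, check_grid=False)
        return cls(
            features={
                "mutation": FeatureMatrix(panel.mutation_matrix.loc[auc.index], "mutation"),
                "transcript": FeatureMatrix(
                    panel.transcript_matrix.loc[auc.index], "transcript"
                ),
                "protein": FeatureMatrix(panel.protein_matrix.loc[auc.index], "protein"),
            },
            auc=auc,
            tissues=panel.tissues.loc[auc.index],
            patients=panel.ground_truth.patient_ids.loc[auc.index],
        )


def early_integration_fit(
    blocks: Sequence[FeatureMatrix],
    y: pd.Series,
    learner,
    cv: CVConfig,
    rng_key: int = 0,
) -> PredictionResult:
    """Early integration: per-fold block-wise prep, then one model on the
    concatenated matrix. A single block reduces to the plain protocol."""
    from .evaluation import repeated_nested_cv

    lines = None
    for b in blocks:
        s = set(b.values.index)
        if lines is None:
            lines = s
        elif s != lines:
            raise ValueError("early integration requires blocks over the same cell lines")
    return repeated_nested_cv(list(blocks), y, learner, cv, rng_key=rng_key)


def late_integration_predict(
    predictions: Sequence[np.ndarray], block_rms: Sequence[float]
) -> np.ndarray:
    """Combine per-block predictions with inverse-RMS weights.

    â_combined = Σ_m (1/RMS_m)·â_m / Σ_m (1/RMS_m). A zero RMS gives that
    block (or blocks, split equally) all the weight.
    """
    preds = [np.asarray(p, dtype=float) for p in predictions]
    rms = np.asarray(list(block_rms), dtype=float)
    if len(preds) != rms.size:
        raise ValueError("predictions and block_rms must have matching lengths")
    if (rms < 0).any():
        raise ValueError("RMS values must be non-negative")
    if (rms == 0).any():
        logger.info("zero RMS block(s) take all the late-integration weight")
        w = (rms == 0).astype(float)
    else:
        w = 1.0 / rms
    w = w / w.sum()
    return sum(wi * pi for wi, pi in zip(w, preds))


def late_integration_cv(
    blocks: Sequence[FeatureMatrix],
    y: pd.Series,
    learner,
    cv: CVConfig,
    rng_key: int = 0,
) -> PredictionResult:
    """Late integration under the repeated-CV protocol.

    All blocks share each repeat's fold partition; within a fold each block
    is prepared and fitted separately, and the per-block test predictions
    are combined with weights 1/RMS where RMS is the block's nested-CV RMS
    on the training fold (so no test information enters the weights).
    """
    learner = make_learner(learner)
    arrays, dtypes, yv = _align_blocks(list(blocks), y)
    n = len(yv)
    y_arr = yv.to_numpy()
    n_folds = min(cv.n_folds, n)

    preds = np.empty((cv.n_repeats, n))
    rho = np.empty(cv.n_repeats)
    r2 = np.empty(cv.n_repeats)
    rms_arr = np.empty(cv.n_repeats)
    for rep in range(cv.n_repeats):
        rng = _repeat_rng(cv.seed, rng_key, rep)
        folds = fold_indices(n, n_folds, rng)
        yhat = np.empty(n)
        for te in folds:
            tr = complement_indices(n, te)
            block_preds = []
            block_rms = []
            for X, dt in zip(arrays, dtypes):
                Z = _prep_fold([X], [dt], tr)
                model = learner.fit_nested(Z[tr], y_arr[tr], cv.nested_n_folds, rng)
                block_preds.append(model.predict(Z[te]))
                nested = getattr(model, "cv_rms", float("nan"))
                if not np.isfinite(nested):  # learners without a nested criterion
                    nested = float(np.sqrt(np.mean((model.predict(Z[tr]) - y_arr[tr]) ** 2)))
                block_rms.append(nested)
            yhat[te] = late_integration_predict(block_preds, block_rms)
        preds[rep] = yhat
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho[rep] = spearman_rho(y_arr, yhat)
        r2[rep] = r2_explained(y_arr, yhat)
        rms_arr[rep] = float(np.sqrt(np.mean((yhat - y_arr) ** 2)))
    return PredictionResult(
        measured=yv,
        predicted=pd.Series(preds.mean(axis=0), index=yv.index),
        per_repeat_rho=rho,
        per_repeat_r2=r2,
        per_repeat_rms=rms_arr,
    )


def tissue_mean_predictor(auc: pd.Series, tissues: pd.Series) -> pd.Series:
    """Leave-one-out tissue-mean prediction.

    â_i is the mean sensitivity of the other cell lines of i's tissue;
    lines whose tissue has no other measured line get NaN.
    """
    auc = auc.astype(float)
    tissues = tissues.reindex(auc.index)
    out = pd.Series(np.nan, index=auc.index)
    for tissue, members in auc.groupby(tissues):
        vals = members.dropna()
        for line in members.index:
            others = vals.drop(line, errors="ignore")
            if len(others) >= 1 and not np.isnan(auc[line]):
                out[line] = others.mean()
    return out


@dataclass
class TransferResult:
    """Per-drug outcome of a single tissue-held-out evaluation."""

    per_drug: pd.DataFrame  # drug, rho, r2, rms, n_train, n_test
    predictions: dict[str, pd.Series]


def _fit_predict_split(
    arrays, dtypes, y_arr, train_idx, test_idx, learner, cv, rng
) -> np.ndarray:
    Z = _prep_fold(arrays, dtypes, train_idx)
    model = learner.fit_nested(Z[train_idx], y_arr[train_idx], cv.nested_n_folds, rng)
    return model.predict(Z[test_idx])


def cross_tissue_transfer(
    panel: TissuePanel,
    target_tissue: str,
    learner,
    cv: CVConfig,
    data_type: str = "protein",
    cv_filter_threshold: Optional[float] = 0.2,
    drugs: Optional[Sequence[str]] = None,
) -> TransferResult:
    """Train on all lines outside ``target_tissue``; evaluate on the target.

    Hyperparameters are selected by nested CV within the training set; the
    target tissue is predicted once (no outer repeats). Drugs whose AUC
    coefficient of variation falls below ``cv_filter_threshold`` in either
    the target tissue or the remaining lines are filtered out.
    """
    learner = make_learner(learner)
    target_lines = panel.tissues.index[panel.tissues == target_tissue]
    train_lines = panel.tissues.index[panel.tissues != target_tissue]
    if len(target_lines) < 3:
        raise ValueError(f"target tissue {target_tissue!r} has fewer than 3 lines")
    if len(train_lines) == 0:
        raise ValueError("no training lines left outside the target tissue")

    drug_list = list(drugs) if drugs is not None else list(panel.auc.columns)
    if cv_filter_threshold is not None:
        kept = []
        for d in drug_list:
            a_t = panel.auc.loc[target_lines, d].dropna()
            a_c = panel.auc.loc[train_lines, d].dropna()
            if len(a_t) < 3 or len(a_c) < 3:
                continue
            cv_t = a_t.std(ddof=1) / a_t.mean()
            cv_c = a_c.std(ddof=1) / a_c.mean()
            if cv_t >= cv_filter_threshold and cv_c >= cv_filter_threshold:
                kept.append(d)
        drug_list = kept

    fm = panel.features[data_type]
    rows = []
    predictions = {}
    for key, drug in enumerate(drug_list):
        y = panel.auc[drug]
        arrays, dtypes, yv = _align_blocks(fm, y)
        is_test = yv.index.isin(target_lines)
        test_idx = np.nonzero(is_test)[0]
        train_idx = np.nonzero(~is_test)[0]
        if len(test_idx) < 3 or len(train_idx) < cv.nested_n_folds:
            continue
        rng = _repeat_rng(cv.seed, key, 0)
        yhat = _fit_predict_split(
            arrays, dtypes, yv.to_numpy(), train_idx, test_idx, learner, cv, rng
        )
        y_test = yv.to_numpy()[test_idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = spearman_rho(y_test, yhat)
        rows.append(
            {
                "drug": drug,
                "rho": rho,
                "r2": r2_explained(y_test, yhat),
                "rms": float(np.sqrt(np.mean((yhat - y_test) ** 2))),
                "n_train": len(train_idx),
                "n_test": len(test_idx),
            }
        )
        predictions[drug] = pd.Series(yhat, index=yv.index[test_idx])
    return TransferResult(per_drug=pd.DataFrame(rows), predictions=predictions)


def cross_fair_benchmark(
    panel: TissuePanel,
    target_tissue: str,
    learner,
    cv: CVConfig,
    n_resamples: int = 1024,
    data_type: str = "protein",
    cv_filter_threshold: Optional[float] = 0.2,
    drugs: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """"Cross fair" transfer: equal-n resampled training sets.

    For each resample, as many non-target lines as the target tissue has
    are drawn without replacement, a model is trained on them and
    evaluated once on the target tissue. Returns per-drug mean and SD of
    Spearman ρ over resamples plus the resample count.
    """
    learner = make_learner(learner)
    target_lines = panel.tissues.index[panel.tissues == target_tissue]
    complement = panel.tissues.index[panel.tissues != target_tissue]
    if len(complement) < len(target_lines):
        raise ValueError("complement smaller than the target tissue; cannot equalize n")

    drug_list = list(drugs) if drugs is not None else list(panel.auc.columns)
    if cv_filter_threshold is not None:
        base = cross_tissue_transfer(
            panel, target_tissue, learner, cv, data_type=data_type,
            cv_filter_threshold=cv_filter_threshold, drugs=drug_list,
        )
        drug_list = list(base.per_drug["drug"])

    fm = panel.features[data_type]
    records: dict[str, list[float]] = {d: [] for d in drug_list}
    for key, drug in enumerate(drug_list):
        y = panel.auc[drug]
        arrays, dtypes, yv = _align_blocks(fm, y)
        is_test = yv.index.isin(target_lines)
        test_idx = np.nonzero(is_test)[0]
        pool = np.nonzero(~is_test)[0]
        n_draw = len(test_idx)
        if len(pool) < n_draw:
            raise ValueError("complement too small after dropping missing AUCs")
        y_arr = yv.to_numpy()
        for s in range(n_resamples):
            draw_rng = _repeat_rng(cv.seed, 7_000_000 + key, s)
            train_idx = np.sort(draw_rng.choice(pool, size=n_draw, replace=False))
            # model-fitting stream matches cross_tissue_transfer, so a resample
            # equal to the full complement reproduces the plain transfer run
            fit_rng = _repeat_rng(cv.seed, key, 0)
            yhat = _fit_predict_split(
                arrays, dtypes, y_arr, train_idx, test_idx, learner, cv, fit_rng
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                records[drug].append(spearman_rho(y_arr[test_idx], yhat))
    rows = []
    for drug, vals in records.items():
        v = np.asarray(vals, dtype=float)
        rows.append(
            {
                "drug": drug,
                "mean_rho": float(np.nanmean(v)),
                "sd_rho": float(np.nanstd(v, ddof=1)) if len(v) > 1 else float("nan"),
                "n_resamples": len(v),
            }
        )
    return pd.DataFrame(rows)


def exclude_duplicate_patients(panel: TissuePanel) -> TissuePanel:
    """Retain one cell line per patient (first by stable panel order)."""
    keep_mask = ~panel.patients.duplicated(keep="first")
    keep = panel.auc.index[keep_mask.reindex(panel.auc.index).fillna(True)]
    return TissuePanel(
        features={
            k: FeatureMatrix(fm.values.loc[keep], fm.data_type, fm.transform_state,
                             fm.log_transformed)
            for k, fm in panel.features.items()
        },
        auc=panel.auc.loc[keep],
        tissues=panel.tissues.loc[keep],
        patients=panel.patients.loc[keep],
    )
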