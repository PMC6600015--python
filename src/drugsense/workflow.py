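"""End-to-end benchmark: which data type best predicts drug sensitivity?

For every drug × data type × learner combination the workflow runs the
repeated nested-CV protocol plus a shuffled-response background, adjusts
permutation p-values per (data type, learner) family across drugs, and
summarises which data type predicts the most drugs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dose_response import select_variable_drugs
from .evaluation import CVConfig, bh_adjust, permutation_background, repeated_nested_cv
from .feature_prep import filter_mutations_by_frequency
from .integration import TissuePanel
from .synthetic import SyntheticPanel, read_panel

__all__ = ["BenchmarkConfig", "BenchmarkResult", "run_full_benchmark", "rank_data_types"]

logger = logging.getLogger(__name__)

#: which learners run on which data type by default (trees on the binary
#: mutation matrix, PLS on the continuous blocks)
DEFAULT_LEARNERS = {
    "mutation": ("tree",),
    "transcript": ("pls",),
    "protein": ("pls",),
}

#: metric used for the permutation comparison per learner: fraction of
#: variance explained for trees, Spearman ρ for the linear models
METRIC_BY_LEARNER = {"tree": "r2"}


@dataclass
class BenchmarkConfig:
    learners_by_datatype: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_LEARNERS.items()}
    )
    cv: CVConfig = field(default_factory=lambda: CVConfig(n_repeats=10))
    n_permutations: int = 200
    drugs: Optional[Sequence[str]] = None
    #: ('top_k', k) or ('cv_threshold', t) or None to keep all drugs
    drug_selection: Optional[tuple[str, float]] = None
    mutation_min_count: int = 3
    exclude_duplicates: bool = False
    significance_level: float = 0.05

    def hash(self) -> str:
        payload = json.dumps(
            {**{k: v for k, v in asdict(self).items() if k != "cv"}, "cv": asdict(self.cv)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class BenchmarkResult:
    """Tidy result table plus provenance.

    One row per (drug, data_type, learner) with cross-validated ρ_s, R²,
    RMS, the permutation p-value and its BH adjustment within the
    (data_type, learner) family.
    """

    table: pd.DataFrame
    coefficients: dict  # (data_type, learner, drug) -> feature importance Series
    config_hash: str
    seed: int
    timestamp: str


def _stable_key(*parts: str) -> int:
    """Process-independent integer key for per-(drug, model) RNG streams."""
    digest = hashlib.sha256("|".join(parts).encode()).digest()
    return int.from_bytes(digest[:3], "big")


def _resolve_panel(panel: Union[SyntheticPanel, TissuePanel, str]) -> TissuePanel:
    if isinstance(panel, TissuePanel):
        return panel
    if isinstance(panel, str):
        panel = read_panel(panel)
    return TissuePanel.from_synthetic(panel)


def run_full_benchmark(
    panel: Union[SyntheticPanel, TissuePanel, str], config: BenchmarkConfig
) -> BenchmarkResult:
    """Run the complete comparative experiment on a panel.

    ``panel`` may be a SyntheticPanel, a TissuePanel, or a panel directory
    written by the simulator. Mutation features are prevalence-filtered to
    [min_count, n − min_count] before modelling; drug selection (top-k CV
    or threshold) applies across all data types.
    """
    from .integration import exclude_duplicate_patients

    tp = _resolve_panel(panel)
    if config.exclude_duplicates:
        tp = exclude_duplicate_patients(tp)
    auc = tp.auc

    drugs = list(config.drugs) if config.drugs is not None else list(auc.columns)
    if config.drug_selection is not None:
        mode, value = config.drug_selection
        drugs = [d for d in select_variable_drugs(auc[drugs], mode, value)]

    features = dict(tp.features)
    if "mutation" in features:
        features["mutation"] = filter_mutations_by_frequency(
            features["mutation"], min_count=config.mutation_min_count
        )

    rows = []
    coefficients = {}
    t0 = time.time()
    for data_type, learners in config.learners_by_datatype.items():
        if data_type not in features:
            raise ValueError(f"panel has no {data_type!r} feature block")
        fm = features[data_type]
        for learner_name in learners:
            metric = METRIC_BY_LEARNER.get(learner_name, "spearman")
            cv = CVConfig(**{**asdict(config.cv), "metric": metric})
            for j, drug in enumerate(drugs):
                key = _stable_key(data_type, learner_name, drug)
                res = repeated_nested_cv(fm, auc[drug], learner_name, cv, rng_key=key)
                null = permutation_background(
                    fm, auc[drug], learner_name, cv, config.n_permutations,
                    rng_key=key, observed=res.metric_value(metric),
                )
                rows.append(
                    {
                        "drug": drug,
                        "data_type": data_type,
                        "learner": learner_name,
                        "rho": res.rho,
                        "r2": res.r2,
                        "rms": res.rms,
                        "p_perm": null.p_value,
                        "n_cell_lines": res.n_lines,
                        "n_features_used": res.n_features_used,
                    }
                )
                coefficients[(data_type, learner_name, drug)] = _importance(
                    fm, auc[drug], learner_name, cv
                )
            logger.info(
                "%s/%s done (%d drugs, %.1fs elapsed)",
                data_type, learner_name, len(drugs), time.time() - t0,
            )

    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    for (dt, ln), idx in table.groupby(["data_type", "learner"]).groups.items():
        table.loc[idx, "p_adj"] = bh_adjust(table.loc[idx, "p_perm"].to_numpy())
    return BenchmarkResult(
        table=table,
        coefficients=coefficients,
        config_hash=config.hash(),
        seed=config.cv.seed,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )


def _importance(fm, y, learner_name, cv) -> Optional[pd.Series]:
    """Feature importances from a full-data fit (normalized-input linear
    coefficients for PLS-family models; impurity importances for trees)."""
    from .evaluation import _align_blocks, _prep_fold, _repeat_rng
    from .learners import make_learner

    try:
        arrays, dtypes, yv = _align_blocks(fm, y)
    except ValueError:
        return None
    all_idx = np.arange(len(yv))
    Z = _prep_fold(arrays, dtypes, all_idx)
    # reconstruct surviving column names for reporting
    fm_t = fm
    learner = make_learner(learner_name)
    rng = _repeat_rng(cv.seed, 999, 0)
    model = learner.fit_nested(Z, yv.to_numpy(), cv.nested_n_folds, rng)
    if hasattr(model, "model"):  # FittedPLS
        coef = model.model.coef_path[:, 0, model.n_components - 1]
    elif hasattr(model, "coefficients"):
        coef = np.asarray(model.coefficients)
    elif hasattr(model, "estimator"):
        coef = model.estimator.feature_importances_
    else:
        return None
    names = _surviving_columns(fm, yv.index)
    if names is not None and len(names) == len(coef):
        return pd.Series(coef, index=names)
    return pd.Series(coef)


def _surviving_columns(fm, lines):
    from .feature_prep import filter_features, transform_expression

    try:
        t = transform_expression(fm)
        t = filter_features(t, list(lines)) if t.data_type != "mutation" else t
        cols = t.values.columns
        # drop zero-variance columns exactly as the fold prep does
        sub = t.values.loc[list(lines)]
        sd = sub.std(axis=0, ddof=0)
        return list(cols[(sd > 0).to_numpy()])
    except ValueError:
        return None


def rank_data_types(result: BenchmarkResult, significance_level: float = 0.05) -> pd.DataFrame:
    """Order data types by how many drugs they predict significantly.

    Per data type (pooled over its learners): count of drugs with adjusted
    p < the significance level, and the mean Spearman ρ across drugs.
    Descending by count, ties broken by mean ρ, then by name.
    """
    t = result.table
    rows = []
    for data_type, sub in t.groupby("data_type"):
        rows.append(
            {
                "data_type": data_type,
                "n_significant": int((sub["p_adj"] < significance_level).sum()),
                "mean_rho": float(sub["rho"].mean()),
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        by=["n_significant", "mean_rho", "data_type"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out
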