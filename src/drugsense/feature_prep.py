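"""Data-type–specific transforms, filters and mutation-matrix construction.

All statistics used for filtering or standardization are computed on the
training cell lines of the current cross-validation fold only, and the
fitted state is what transforms held-out lines — the test set never
contributes to its own normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "StandardizerState",
    "transform_expression",
    "filter_features",
    "build_mutation_matrix",
    "filter_mutations_by_frequency",
    "subset_genes",
    "fit_standardizer",
    "apply_standardizer",
    "TRANSCRIPT_MEAN_MIN",
    "TRANSCRIPT_SD_MIN",
    "PROTEIN_SD_MIN",
]

logger = logging.getLogger(__name__)

DATA_TYPES = ("mutation", "transcript", "protein")

# Expression filter thresholds, applied on the log2 scale.
TRANSCRIPT_MEAN_MIN = 2.0
TRANSCRIPT_SD_MIN = 0.5
PROTEIN_SD_MIN = 0.1

# Ordinal variant impact scale; unknown categories fail the filter.
IMPACT_ORDER = {"LOW": 0, "MODERATE": 1, "HIGH": 2}


@dataclass
class StandardizerState:
    """Per-feature centering/scaling parameters fitted on training lines."""

    means: pd.Series
    sds: pd.Series

    @property
    def columns(self) -> pd.Index:
        return self.means.index


@dataclass
class FeatureMatrix:
    """Cell line × feature matrix tagged with its data type.

    ``data_type`` controls which transform and filter apply; mutation
    matrices are binary and pass through the expression transform
    unchanged. ``transform_state``, once fitted, fully determines the
    test-data standardization.
    """

    values: pd.DataFrame
    data_type: str
    transform_state: Optional[StandardizerState] = None
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if self.data_type not in DATA_TYPES:
            raise ValueError(f"data_type must be one of {DATA_TYPES}, got {self.data_type!r}")
        if self.data_type == "mutation":
            vals = self.values.to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mutation matrices must be binary (0/1)")


def transform_expression(matrix: FeatureMatrix) -> FeatureMatrix:
    """log2(1+x) for transcripts, log2(x) for proteins, identity for mutations."""
    if matrix.log_transformed:
        return matrix
    if matrix.data_type == "mutation":
        return matrix
    vals = matrix.values
    if matrix.data_type == "transcript":
        if (vals.to_numpy() < 0).any():
            raise ValueError("transcript values must be non-negative")
        out = np.log2(1.0 + vals)
    else:
        if (vals.to_numpy() <= 0).any():
            raise ValueError("protein values must be strictly positive for log2 transform")
        out = np.log2(vals)
    return replace(matrix, values=out, log_transformed=True)


def filter_features(
    matrix: FeatureMatrix,
    fold_training_lines: Sequence[str],
    mean_min: Optional[float] = None,
    sd_min: Optional[float] = None,
) -> FeatureMatrix:
    """Drop low-signal expression features, judged on training lines only.

    Transcripts require mean ≥ 2.0 and sample SD ≥ 0.5 on the log2(1+x)
    scale; proteins require sample SD ≥ 0.1 on the log2 scale; mutation
    matrices pass through. ``mean_min``/``sd_min`` override the defaults.
    The surviving column set is applied to the full matrix (train and test
    alike).
    """
    if matrix.data_type == "mutation":
        return matrix
    if not matrix.log_transformed:
        raise ValueError("filter_features expects an already log-transformed matrix")
    train = matrix.values.loc[list(fold_training_lines)]
    sd = train.std(axis=0, ddof=1)
    if matrix.data_type == "transcript":
        mean_thr = TRANSCRIPT_MEAN_MIN if mean_min is None else mean_min
        sd_thr = TRANSCRIPT_SD_MIN if sd_min is None else sd_min
        keep = (train.mean(axis=0) >= mean_thr) & (sd >= sd_thr)
    else:
        keep = sd >= (PROTEIN_SD_MIN if sd_min is None else sd_min)
    kept = matrix.values.columns[keep.to_numpy()]
    if len(kept) == 0:
        raise ValueError(f"no {matrix.data_type} features survive the filter")
    return replace(matrix, values=matrix.values[kept])


def build_mutation_matrix(
    variants: pd.DataFrame,
    min_depth: int = 30,
    min_fraction: float = 0.2,
    min_impact: str = "MODERATE",
    excluded_gene_prefixes: Sequence[str] = ("HLA-", "MUC-"),
    cell_lines: Optional[Sequence[str]] = None,
    granularity: str = "gene",
) -> FeatureMatrix:
    """Binary mutation matrix from a variant table.

    A variant qualifies when it is covered by at least ``min_depth`` reads,
    at least ``min_fraction`` of the reads support it, its impact is at
    least ``min_impact`` (LOW < MODERATE < HIGH; unknown impact fails), and
    its gene does not carry one of the excluded prefixes (known
    false-positive cancer genes). ``granularity='gene'`` sets an entry to 1
    iff the cell line carries ≥ 1 qualifying variant in the gene;
    ``granularity='position'`` keeps one column per (gene, position).
    """
    required = {"cell_line", "gene", "position", "read_depth", "supporting_reads"}
    missing = required - set(variants.columns)
    if missing:
        raise ValueError(f"variant table lacks columns: {sorted(missing)}")
    if (variants["supporting_reads"] > variants["read_depth"]).any():
        raise ValueError("supporting_reads cannot exceed read_depth")
    min_rank = IMPACT_ORDER[min_impact]

    v = variants
    depth_ok = v["read_depth"] >= min_depth
    with np.errstate(invalid="ignore"):
        frac_ok = v["supporting_reads"] >= min_fraction * v["read_depth"]
    impact_rank = v["impact"].map(IMPACT_ORDER)
    impact_ok = impact_rank.notna() & (impact_rank >= min_rank)
    gene_ok = ~v["gene"].astype(str).str.startswith(tuple(excluded_gene_prefixes))
    passing = v[depth_ok & frac_ok & impact_ok & gene_ok]

    if cell_lines is None:
        cell_lines = sorted(v["cell_line"].unique())
    if granularity == "gene":
        feats = sorted(passing["gene"].unique())
        key = passing["gene"]
    elif granularity == "position":
        key = passing["gene"].astype(str) + ":" + passing["position"].astype(str)
        feats = sorted(key.unique())
    else:
        raise ValueError("granularity must be 'gene' or 'position'")
    mat = pd.DataFrame(0, index=list(cell_lines), columns=feats, dtype=int)
    for cl, f in zip(passing["cell_line"], key):
        if cl in mat.index:
            mat.loc[cl, f] = 1
    if mat.shape[1] == 0:
        logger.warning("no variants pass the filters; mutation matrix is empty")
    return FeatureMatrix(values=mat, data_type="mutation")


def filter_mutations_by_frequency(
    matrix: FeatureMatrix, min_count: int = 3, max_count: Optional[int] = None
) -> FeatureMatrix:
    """Keep mutations observed in between ``min_count`` and ``max_count`` lines.

    ``max_count`` defaults to n_cell_lines − min_count, mirroring the
    "at least three but not more than n − 3" prevalence window.
    """
    if matrix.data_type != "mutation":
        raise ValueError("frequency filter applies to mutation matrices only")
    n = matrix.values.shape[0]
    if max_count is None:
        max_count = n - min_count
    if min_count > max_count:
        raise ValueError(f"min_count ({min_count}) exceeds max_count ({max_count})")
    sums = matrix.values.sum(axis=0)
    keep = matrix.values.columns[(sums >= min_count) & (sums <= max_count)]
    return replace(matrix, values=matrix.values[keep])


def subset_genes(
    matrix: FeatureMatrix,
    gene_list: Optional[Sequence[str]] = None,
    random_k: Optional[int] = None,
    seed: Optional[int] = None,
) -> FeatureMatrix:
    """Column subset by explicit gene list or seeded random selection."""
    if (gene_list is None) == (random_k is None):
        raise ValueError("provide exactly one of gene_list or random_k")
    if gene_list is not None:
        present = [g for g in gene_list if g in matrix.values.columns]
        if not present:
            raise ValueError("gene_list has empty intersection with the feature set")
        return replace(matrix, values=matrix.values[present])
    if random_k > matrix.values.shape[1]:
        raise ValueError(
            f"random_k={random_k} exceeds feature count ({matrix.values.shape[1]})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(matrix.values.columns, size=random_k, replace=False)
    return replace(matrix, values=matrix.values[list(chosen)])


def fit_standardizer(
    matrix: FeatureMatrix, fold_training_lines: Sequence[str]
) -> FeatureMatrix:
    """Standardize all lines with training-line parameters; attach the state.

    Training columns end up with mean 0 and SD 1 (population SD, so the
    identity is exact); zero-variance training columns cannot be
    standardized and are dropped with a warning. The fitted state is
    recorded in ``transform_state`` for later application to fresh data.
    """
    train = matrix.values.loc[list(fold_training_lines)]
    means = train.mean(axis=0)
    sds = train.std(axis=0, ddof=0)
    nonzero = sds > 0
    if not nonzero.all():
        dropped = list(sds.index[~nonzero])
        warnings.warn(
            f"dropping {len(dropped)} zero-variance training column(s): {dropped[:5]}...",
            stacklevel=2,
        )
    state = StandardizerState(means=means[nonzero], sds=sds[nonzero])
    values = (matrix.values[state.columns] - state.means) / state.sds
    return replace(matrix, values=values, transform_state=state)


def apply_standardizer(matrix: FeatureMatrix, state: StandardizerState) -> FeatureMatrix:
    """Transform data with a previously fitted standardizer state."""
    missing = [c for c in state.columns if c not in matrix.values.columns]
    if missing:
        raise ValueError(f"matrix lacks columns required by the standardizer: {missing[:5]}")
    values = (matrix.values[state.columns] - state.means) / state.sds
    return replace(matrix, values=values, transform_state=state)
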