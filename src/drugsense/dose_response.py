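"""Drug-sensitivity summaries from dose–response measurements.

The primary sensitivity summary is the mean viability across evenly
log-spaced drug concentrations — equivalently the (normalised) area under
the dose–response curve on that grid. Lower AUC means a more sensitive
cell line. IC50 and maximum inhibition are computed as optional extras but
are not used by any downstream model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DoseGridError",
    "mean_viability_auc",
    "curve_summaries",
    "select_variable_drugs",
    "normalize_auc_per_drug",
]

_REQUIRED_COLUMNS = ("cell_line", "drug", "dose", "viability")


class DoseGridError(ValueError):
    """Raised when a (cell line, drug) dose series is not a geometric grid."""


def _validate_table(curves: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLUMNS if c not in curves.columns]
    if missing:
        raise ValueError(f"dose-response table lacks required columns: {missing}")
    if (curves["dose"] <= 0).any():
        raise ValueError("doses must be strictly positive")
    if (curves["viability"] < 0).any():
        raise ValueError("viability must be non-negative")
    return curves


def _check_geometric(group: pd.DataFrame, rtol: float = 1e-6) -> None:
    doses = np.sort(group["dose"].to_numpy(dtype=float))
    if doses.size < 2:
        raise DoseGridError(
            f"series ({group.name[0]}, {group.name[1]}) has fewer than 2 doses"
        )
    ratios = doses[1:] / doses[:-1]
    if not np.allclose(ratios, ratios[0], rtol=rtol):
        raise DoseGridError(
            f"series ({group.name[0]}, {group.name[1]}) doses are not a geometric grid: "
            f"{doses.tolist()}"
        )


def mean_viability_auc(curves: pd.DataFrame, check_grid: bool = True) -> pd.DataFrame:
    """AUC matrix (cell line × drug) as the arithmetic mean of viabilities.

    Because the dose grid is evenly spaced in log-concentration, the mean
    viability over the grid equals the trapezoid AUC up to endpoint
    weighting. (Cell line, drug) pairs absent from the input are NaN in the
    output; they are flagged missing, never imputed.

    Parameters
    ----------
    curves:
        Long table with columns ``cell_line, drug, dose, viability``.
    check_grid:
        Verify that each series forms a geometric dose grid
        (raises :class:`DoseGridError` naming the offending series).
    """
    _validate_table(curves)
    grouped = curves.groupby(["cell_line", "drug"], sort=True)
    if check_grid:
        grouped.apply(lambda g: _check_geometric(g), include_groups=False)
    auc = grouped["viability"].mean().unstack("drug")
    auc.index.name = None
    auc.columns.name = None
    return auc


def curve_summaries(curves: pd.DataFrame) -> pd.DataFrame:
    """Per (cell line, drug) extras: AUC, IC50 and maximum inhibition.

    IC50 is the log-interpolated dose where viability crosses 0.5 (NaN if
    the curve never reaches 0.5); maximum inhibition is 1 − min viability.
    These summaries are provided for exploratory use only.
    """
    _validate_table(curves)
    rows = []
    for (cl, drug), g in curves.groupby(["cell_line", "drug"], sort=True):
        g = g.sort_values("dose")
        v = g["viability"].to_numpy(dtype=float)
        d = g["dose"].to_numpy(dtype=float)
        ic50 = np.nan
        below = np.nonzero(v <= 0.5)[0]
        if below.size:
            i = below[0]
            if i == 0:
                ic50 = d[0]
            else:
                # interpolate in log-dose between the bracketing points
                x0, x1 = np.log(d[i - 1]), np.log(d[i])
                f = (0.5 - v[i - 1]) / (v[i] - v[i - 1])
                ic50 = float(np.exp(x0 + f * (x1 - x0)))
        rows.append(
            {
                "cell_line": cl,
                "drug": drug,
                "auc": float(v.mean()),
                "ic50": ic50,
                "max_inhibition": float(1.0 - v.min()),
            }
        )
    return pd.DataFrame(rows)


def select_variable_drugs(
    auc: pd.DataFrame, mode: str, k_or_threshold: float
) -> list[str]:
    """Select drugs by coefficient of variation σ/μ of AUC across lines.

    σ is the sample SD over non-missing entries. ``mode='top_k'`` returns
    the k drugs with largest CV (descending, ties by drug name);
    ``mode='cv_threshold'`` returns all drugs with CV ≥ threshold.
    """
    counts = auc.notna().sum(axis=0)
    if (counts < 3).any():
        bad = list(counts.index[counts < 3])
        raise ValueError(f"drugs with fewer than 3 non-missing AUCs: {bad}")
    mu = auc.mean(axis=0, skipna=True)
    if (mu <= 0).any():
        raise ValueError("AUC means must be positive to form a coefficient of variation")
    cv = auc.std(axis=0, ddof=1, skipna=True) / mu
    if mode == "top_k":
        k = int(k_or_threshold)
        if k > auc.shape[1]:
            raise ValueError(f"k={k} exceeds the number of drugs ({auc.shape[1]})")
        order = sorted(cv.index, key=lambda d: (-cv[d], d))
        return order[:k]
    if mode == "cv_threshold":
        return [d for d in auc.columns if cv[d] >= k_or_threshold]
    raise ValueError(f"unknown mode {mode!r}; expected 'top_k' or 'cv_threshold'")


def normalize_auc_per_drug(auc: pd.DataFrame) -> pd.DataFrame:
    """Per-drug z-scores over non-missing entries; missing stays missing."""
    counts = auc.notna().sum(axis=0)
    if (counts < 2).any():
        bad = list(counts.index[counts < 2])
        raise ValueError(f"drugs with fewer than 2 non-missing AUCs: {bad}")
    sd = auc.std(axis=0, ddof=1, skipna=True)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"cannot normalize zero-variance drugs: {bad}")
    return (auc - auc.mean(axis=0, skipna=True)) / sd
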