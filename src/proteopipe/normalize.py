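"""Per-sample scaling normalizations and the diagnostic used to compare them.

Four candidate schemes are provided — mean-based, down-scaling,
total-count and housekeeping — all expressed as per-sample multipliers.
Down-scaling (the pipeline default) divides the lowest sample total in
a stratum by each sample's total, so every sample is scaled *down* to
the stratum minimum; strata are the sex groups when sex is annotated,
so male and female samples are normalized independently.

Missing values (e.g. cells blanked by outlier QC) are excluded from all
totals and means so that removed outliers do not deflate the factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix_io import group_samples

__all__ = [
    "NormalizationResult",
    "down_scaling_factors",
    "mean_based_factors",
    "total_count_factors",
    "housekeeping_factors",
    "normalize_matrix",
    "apply_factors",
    "evaluate_normalizations",
    "sample_strata",
]

METHODS = ("mean", "down_scaling", "total_count", "housekeeping")


@dataclass
class NormalizationResult:
    method: str
    factors: pd.Series          # per-sample multipliers, > 0
    strata: pd.Series           # sample -> stratum label used for the factors
    normalized: pd.DataFrame


def sample_strata(ann: pd.DataFrame | None, samples, by_sex: bool = True) -> pd.Series:
    """Stratum label per sample: sex when annotated and requested, else one stratum."""
    samples = list(samples)
    if ann is not None and by_sex and (ann.loc[samples, "sex"] != "NA").any():
        return ann.loc[samples, "sex"].rename("stratum")
    return pd.Series("all", index=pd.Index(samples), name="stratum")


def _totals(matrix: pd.DataFrame) -> pd.Series:
    totals = matrix.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero-total sample(s): {bad}")
    return totals


def down_scaling_factors(matrix: pd.DataFrame, strata: pd.Series | None = None) -> pd.Series:
    """factor_s = (lowest sample total in the stratum) / (total of sample s).

    Factors lie in (0, 1] with at least one exact 1 per stratum;
    applying them makes every sample total equal its stratum minimum.
    """
    totals = _totals(matrix)
    if strata is None:
        strata = pd.Series("all", index=matrix.columns)
    mins = totals.groupby(strata).transform("min")
    return (mins / totals).rename("factor")


def mean_based_factors(matrix: pd.DataFrame) -> pd.Series:
    """factor_s = grand mean of per-sample means / per-sample mean."""
    means = matrix.mean(axis=0, skipna=True)
    if (means <= 0).any() or means.isna().any():
        raise ValueError("every sample needs a positive mean abundance")
    return (means.mean() / means).rename("factor")


def total_count_factors(matrix: pd.DataFrame) -> pd.Series:
    """factor_s = grand mean of sample totals / sample total (equalizes totals)."""
    totals = _totals(matrix)
    return (totals.mean() / totals).rename("factor")


def housekeeping_factors(matrix: pd.DataFrame, reference_ids) -> pd.Series:
    """Scale on the mean abundance of reference (housekeeping) proteins.

    All reference proteins must be present and non-missing in every
    sample; factor_s = grand mean of per-sample reference means /
    per-sample reference mean.
    """
    reference_ids = list(reference_ids)
    missing = [r for r in reference_ids if r not in matrix.index]
    if missing:
        raise KeyError(f"reference protein(s) not in matrix: {missing}")
    ref = matrix.loc[reference_ids]
    if ref.isna().any().any():
        bad = list(ref.columns[ref.isna().any(axis=0)])
        raise ValueError(f"reference proteins missing values in sample(s): {bad}")
    ref_means = ref.mean(axis=0)
    if (ref_means <= 0).any():
        raise ValueError("reference means must be positive")
    return (ref_means.mean() / ref_means).rename("factor")


def apply_factors(matrix: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    return matrix.mul(factors.reindex(matrix.columns), axis=1)


def normalize_matrix(matrix: pd.DataFrame, ann: pd.DataFrame | None = None,
                     method: str = "down_scaling", reference_ids=None,
                     by_sex: bool = True) -> NormalizationResult:
    """Compute factors for one method and return the normalized matrix."""
    strata = sample_strata(ann, matrix.columns, by_sex=by_sex)
    if method == "down_scaling":
        factors = down_scaling_factors(matrix, strata)
    elif method == "mean":
        factors = mean_based_factors(matrix)
    elif method == "total_count":
        factors = total_count_factors(matrix)
    elif method == "housekeeping":
        if reference_ids is None:
            raise ValueError("housekeeping normalization needs reference_ids")
        factors = housekeeping_factors(matrix, reference_ids)
    else:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return NormalizationResult(method=method, factors=factors, strata=strata,
                               normalized=apply_factors(matrix, factors))


def _cv(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    if x.size < 2 or x.mean() == 0:
        return np.nan
    return float(x.std(ddof=1) / x.mean())


def _within_cell_cvs(matrix: pd.DataFrame, ann: pd.DataFrame) -> np.ndarray:
    cvs = []
    for _, samples in group_samples(ann, by_sex=True).items():
        block = matrix[samples].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            m = np.nanmean(block, axis=1)
            s = np.nanstd(block, axis=1, ddof=1)
        ok = np.isfinite(m) & np.isfinite(s) & (m > 0)
        cvs.append(s[ok] / m[ok])
    return np.concatenate(cvs) if cvs else np.array([])


def evaluate_normalizations(matrix: pd.DataFrame, ann: pd.DataFrame,
                            reference_ids=None, by_sex: bool = True) -> pd.DataFrame:
    """Diagnostic table comparing raw data and each normalization.

    Columns (lower is better for each):

    - ``total_cv``: CV of post-normalization sample totals, averaged
      over strata (within a stratum all totals should coincide for any
      total-equalizing scheme);
    - ``median_within_cell_cv``: median CV across proteins within each
      genotype x treatment (x sex) cell;
    - ``low_abundance_log2_distortion``: mean |log2 change| of relative
      expression (value / protein mean) versus raw, over the
      lowest-abundance quartile of proteins — how much the scheme
      perturbs the signal of weakly expressed proteins.

    The pipeline default remains down-scaling regardless of this table;
    the table documents the comparison. Housekeeping is included only
    when ``reference_ids`` is given.
    """
    strata = sample_strata(ann, matrix.columns, by_sex=by_sex)
    raw_mean = matrix.mean(axis=1, skipna=True)
    low_quart = matrix.index[raw_mean <= raw_mean.quantile(0.25)]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_raw = np.log2(matrix.div(raw_mean, axis=0)).to_numpy()

    def diagnostics(normed: pd.DataFrame) -> dict:
        totals = normed.sum(axis=0, skipna=True)
        total_cv = float(np.nanmean([
            _cv(totals[strata == s].to_numpy(dtype=float)) for s in strata.unique()
        ]))
        cvs = _within_cell_cvs(normed, ann)
        med_cv = float(np.nanmedian(cvs)) if cvs.size else np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.log2(normed.div(normed.mean(axis=1, skipna=True), axis=0)).to_numpy()
        delta = np.abs(rel - rel_raw)[matrix.index.get_indexer(low_quart)]
        distortion = float(np.nanmean(delta)) if delta.size else np.nan
        return {"total_cv": total_cv, "median_within_cell_cv": med_cv,
                "low_abundance_log2_distortion": distortion}

    rows = {"raw": diagnostics(matrix)}
    for method in METHODS:
        if method == "housekeeping" and reference_ids is None:
            continue
        result = normalize_matrix(matrix, ann, method=method,
                                  reference_ids=reference_ids, by_sex=by_sex)
        rows[method] = diagnostics(result.normalized)
    table = pd.DataFrame(rows).T
    table.index.name = "method"
    return table
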