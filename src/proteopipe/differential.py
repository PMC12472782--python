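"""Fold changes, normality-routed two-group tests, and volcano classification.

Per protein, the case/control fold change is the ratio of group mean
abundances, log2-transformed for symmetric thresholding. Each protein
is routed to a test by Shapiro–Wilk normality of both groups: normal
data go to the classical (equal-variance) Student's t test, anything
else to the two-sided Mann–Whitney U test, exact when both groups have
at most 8 observations and no ties (the asymptotic approximation is
poor at the study's group sizes of 4–6).

Volcano classification is the joint rule: p below the cutoff AND log2
fold change beyond the asymmetric cuts (+0.32 up, -0.41 down, i.e.
roughly +/-25% on the ratio scale) AND an arithmetic change of at
least 25%. No multiplicity adjustment is applied at this stage; FDR
control enters later, during candidate selection.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .matrix_io import samples_for

__all__ = ["fold_change", "route_and_test", "classify_volcano", "differential_table",
           "DEFAULT_P_CUT", "DEFAULT_UP_CUT", "DEFAULT_DOWN_CUT", "DEFAULT_MIN_CHANGE"]

DEFAULT_P_CUT = 0.05
DEFAULT_UP_CUT = 0.32
DEFAULT_DOWN_CUT = -0.41
DEFAULT_MIN_CHANGE = 0.25
#: largest per-group size at which the exact Mann-Whitney null is used
_EXACT_MAX_N = 8


def _finite(values) -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    return v[np.isfinite(v)]


def fold_change(case_values, control_values) -> tuple[float, float]:
    """(fc, log2fc) with fc = mean(case) / mean(control).

    Returns (nan, nan) when either side has no non-missing value or a
    non-positive mean; such records are left untested downstream.
    """
    case, control = _finite(case_values), _finite(control_values)
    if case.size == 0 or control.size == 0:
        return math.nan, math.nan
    mc, mk = case.mean(), control.mean()
    if mc <= 0 or mk <= 0:
        return math.nan, math.nan
    fc = mc / mk
    return fc, math.log2(fc)


def _passes_shapiro(values: np.ndarray, alpha: float) -> bool:
    """True when Shapiro–Wilk does not reject normality.

    Constant vectors (undefined W) count as non-normal, which routes
    the protein to the rank test.
    """
    if np.ptp(values) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bool(stats.shapiro(values).pvalue > alpha)


def route_and_test(case_values, control_values,
                   alpha_normality: float = 0.05) -> tuple[str, float]:
    """Choose and run the two-group test; returns (test_used, p_value).

    ``test_used`` is one of ``student_t``, ``mann_whitney``,
    ``degenerate`` (both groups constant and equal: p = 1) or
    ``untested`` (fewer than 3 values on either side: p = nan).
    """
    case, control = _finite(case_values), _finite(control_values)
    if case.size < 3 or control.size < 3:
        return "untested", math.nan
    if np.ptp(case) == 0 and np.ptp(control) == 0 and case[0] == control[0]:
        return "degenerate", 1.0
    if _passes_shapiro(case, alpha_normality) and _passes_shapiro(control, alpha_normality):
        res = stats.ttest_ind(case, control, equal_var=True)
        return "student_t", float(res.pvalue)
    combined = np.concatenate([case, control])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (max(case.size, control.size) <= _EXACT_MAX_N
                         and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(case, control, alternative="two-sided",
                             method=method, use_continuity=True)
    return "mann_whitney", float(min(res.pvalue, 1.0))


def classify_volcano(log2fc: float, p_value: float, pct_change: float,
                     p_cut: float = DEFAULT_P_CUT, up_cut: float = DEFAULT_UP_CUT,
                     down_cut: float = DEFAULT_DOWN_CUT,
                     min_change: float = DEFAULT_MIN_CHANGE) -> str:
    """'up' / 'down' / 'ns' under the joint p, log2FC and %-change rule.

    Inequalities on p and log2FC are strict; the minimum arithmetic
    change is inclusive. Untested records (nan p) are 'ns'.
    """
    if not (np.isfinite(log2fc) and np.isfinite(p_value)):
        return "ns"
    if p_value >= p_cut or pct_change < min_change:
        return "ns"
    if log2fc > up_cut:
        return "up"
    if log2fc < down_cut:
        return "down"
    return "ns"


def differential_table(matrix: pd.DataFrame, ann: pd.DataFrame,
                       contrast: str = "genotype", within: str | None = "VEH",
                       alpha_normality: float = 0.05,
                       p_cut: float = DEFAULT_P_CUT, up_cut: float = DEFAULT_UP_CUT,
                       down_cut: float = DEFAULT_DOWN_CUT,
                       min_change: float = DEFAULT_MIN_CHANGE) -> pd.DataFrame:
    """Per-protein differential record for a two-group contrast.

    ``contrast='genotype'`` compares TG (case) vs WT (control), within
    one treatment arm (``within``, default the vehicle arm; ``None``
    pools both). ``contrast='treatment'`` compares DCI vs VEH within
    one genotype (default TG when ``within`` names no genotype).

    Returns one row per protein with means, fc, log2fc, pct_change,
    test_used, p_value, neg_log10_p and volcano_class.
    """
    if contrast == "genotype":
        fix = {} if within is None else {"treatment": within}
        case_samples = samples_for(ann, genotype="TG", **fix)
        control_samples = samples_for(ann, genotype="WT", **fix)
    elif contrast == "treatment":
        fix = {"genotype": within if within in ("WT", "TG") else "TG"}
        case_samples = samples_for(ann, treatment="DCI", **fix)
        control_samples = samples_for(ann, treatment="VEH", **fix)
    else:
        raise ValueError("contrast must be 'genotype' or 'treatment'")
    if not case_samples or not control_samples:
        raise ValueError("empty case or control group for the requested contrast")

    case_block = matrix[case_samples].to_numpy(dtype=float)
    ctrl_block = matrix[control_samples].to_numpy(dtype=float)
    rows = []
    for i, pid in enumerate(matrix.index):
        case, control = case_block[i], ctrl_block[i]
        fc, log2fc = fold_change(case, control)
        if math.isnan(fc):
            test_used, p = "untested", math.nan
        else:
            test_used, p = route_and_test(case, control, alpha_normality)
        pct = abs(fc - 1.0) if np.isfinite(fc) else math.nan
        neg_log10_p = -math.log10(p) if (np.isfinite(p) and p > 0) else (
            math.inf if p == 0 else math.nan)
        rows.append({
            "protein_id": pid,
            "mean_control": float(np.nanmean(ctrl_block[i])) if np.isfinite(ctrl_block[i]).any() else math.nan,
            "mean_case": float(np.nanmean(case_block[i])) if np.isfinite(case_block[i]).any() else math.nan,
            "fc": fc,
            "log2fc": log2fc,
            "pct_change": pct,
            "test_used": test_used,
            "p_value": p,
            "neg_log10_p": neg_log10_p,
            "volcano_class": classify_volcano(log2fc, p, pct, p_cut, up_cut,
                                              down_cut, min_change),
        })
    return pd.DataFrame(rows).set_index("protein_id")
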