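"""Relative-variance candidate selection with BH FDR control.

Proteins are ranked by relative variance — the sample variance of the
group means (between-group, denominator G-1) divided by the pooled
within-group sample variance — computed over the genotype x treatment
cells. The top 5% are retained (boundary ties included), and
Benjamini–Hochberg FDR adjustment is applied to the selected
candidates' test p-values; earlier stages deliberately carry raw
p-values.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .matrix_io import group_samples

__all__ = ["relative_variance", "select_top_fraction", "bh_adjust", "candidate_table"]

#: guard and cap for the zero-within-variance degenerate case
RV_EPS = 1e-12
RV_CAP = 1e12


def relative_variance(values_by_group, eps: float = RV_EPS, cap: float = RV_CAP) -> float:
    """Between-group variance of group means over pooled within-group variance.

    Groups with fewer than 2 non-missing values are dropped; at least
    two usable groups are required (otherwise nan). A zero pooled
    within-group variance is guarded by ``eps`` and the ratio capped at
    ``cap``.
    """
    groups = []
    for g in values_by_group:
        v = np.asarray(g, dtype=float).ravel()
        v = v[np.isfinite(v)]
        if v.size >= 2:
            groups.append(v)
    if len(groups) < 2:
        return math.nan
    means = np.array([g.mean() for g in groups])
    between = means.var(ddof=1)
    dof = sum(g.size - 1 for g in groups)
    within = sum((g.size - 1) * g.var(ddof=1) for g in groups) / dof
    if between == 0.0:
        return 0.0
    return float(min(between / max(within, eps), cap))


def select_top_fraction(scores: pd.Series, fraction: float = 0.05) -> pd.Series:
    """Boolean mask of the top ``ceil(fraction * m)`` scores, ties included.

    ``m`` counts the non-missing scores. Ties at the selection boundary
    are all retained, so the selected count can exceed the ceiling.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    valid = scores.dropna()
    if valid.empty:
        return pd.Series(False, index=scores.index)
    n_sel = math.ceil(fraction * len(valid))
    threshold = valid.sort_values(ascending=False).iloc[n_sel - 1]
    return (scores >= threshold).fillna(False)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def candidate_table(matrix: pd.DataFrame, ann: pd.DataFrame,
                    diff_table: pd.DataFrame | None = None,
                    fraction: float = 0.05) -> pd.DataFrame:
    """Score, rank and select candidate proteins.

    Relative variance is computed over the genotype x treatment cells
    of (typically normalized) ``matrix``. When a differential table is
    supplied, BH q-values are computed over the selected candidates'
    p-values; non-selected proteins carry no q-value.

    Returns columns relative_variance, rank (dense, descending),
    selected, p_value, q_value.
    """
    cells = group_samples(ann, by_sex=False)
    blocks = {key: matrix[samples].to_numpy(dtype=float) for key, samples in cells.items()}
    rv = pd.Series(
        [relative_variance([blk[i] for blk in blocks.values()])
         for i in range(len(matrix.index))],
        index=matrix.index, name="relative_variance")
    rank = rv.rank(method="dense", ascending=False).astype("Int64")
    selected = select_top_fraction(rv, fraction)

    table = pd.DataFrame({"relative_variance": rv, "rank": rank, "selected": selected})
    table["p_value"] = np.nan
    table["q_value"] = np.nan
    if diff_table is not None:
        table["p_value"] = diff_table["p_value"].reindex(table.index)
        cand = table.index[table["selected"] & table["p_value"].notna()]
        if len(cand):
            table.loc[cand, "q_value"] = bh_adjust(table.loc[cand, "p_value"].to_numpy())
    return table
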