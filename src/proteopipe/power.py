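"""A-priori power analysis for the 2x2 genotype-by-treatment interaction.

The design assumes the transgenic vehicle cell departs from the control
mean by a fixed fraction (35% in the study design) while treatment
normalizes it back, with a common within-cell SD equal to a fraction of
the control mean (20%). The interaction is the 1-df
difference-in-differences contrast; its test statistic under the
alternative follows a noncentral F(1, 4(n-1)) with noncentrality
``lambda = n * sum(gamma_ij^2) / sigma^2`` where ``gamma`` are the
two-way interaction effects of the cell-mean pattern. ``solve_n``
returns the smallest balanced per-cell n reaching the target power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PowerDesign", "EffectDecomposition", "decompose_effects",
           "interaction_power", "solve_n", "study_design",
           "monte_carlo_interaction_power"]


@dataclass(frozen=True)
class PowerDesign:
    """Cell-mean pattern and error model of a balanced 2x2 design.

    ``cell_means`` is a 2x2 array-like with rows = genotype (WT, TG)
    and columns = treatment (VEH, DCI); ``sigma`` is the common
    within-cell SD in the same units as the means.
    """

    cell_means: tuple[tuple[float, float], tuple[float, float]]
    sigma: float
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self):
        means = np.asarray(self.cell_means, dtype=float)
        if means.shape != (2, 2) or not np.all(np.isfinite(means)):
            raise ValueError("cell_means must be a finite 2x2 pattern")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must lie in (0, 1)")

    @property
    def means(self) -> np.ndarray:
        return np.asarray(self.cell_means, dtype=float)


@dataclass(frozen=True)
class EffectDecomposition:
    grand_mean: float
    main_genotype: tuple[float, float]
    main_treatment: tuple[float, float]
    interaction_effects: tuple[tuple[float, float], tuple[float, float]]
    cohen_f: float
    noncentrality_per_n: float


def study_design(control_mean: float = 1.0, effect_fraction: float = 0.35,
                 cv: float = 0.20, alpha: float = 0.05,
                 target_power: float = 0.80) -> PowerDesign:
    """The normalizing-treatment scenario: TG-VEH departs, all else at control.

    WT-VEH, WT-DCI and TG-DCI sit at the control mean (treatment
    restores the transgenic cell and is assumed neutral in wild types);
    TG-VEH = control * (1 - effect_fraction); sigma = cv * control.
    """
    m = control_mean
    return PowerDesign(
        cell_means=((m, m), (m * (1.0 - effect_fraction), m)),
        sigma=cv * m, alpha=alpha, target_power=target_power)


def decompose_effects(cell_means, sigma: float) -> EffectDecomposition:
    """Standard two-way decomposition of a 2x2 cell-mean pattern.

    Interaction effect of cell (i, j) is
    ``mu_ij - grand - row_i - col_j``; Cohen's f is the RMS interaction
    effect over sigma, and the per-subject noncentrality is
    ``sum(gamma^2) / sigma^2``.
    """
    means = np.asarray(cell_means, dtype=float)
    if means.shape != (2, 2):
        raise ValueError("cell_means must be 2x2")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    grand = means.mean()
    row = means.mean(axis=1) - grand
    col = means.mean(axis=0) - grand
    gamma = means - grand - row[:, None] - col[None, :]
    cohen_f = float(np.sqrt((gamma ** 2).mean()) / sigma)
    ncp_per_n = float((gamma ** 2).sum() / sigma ** 2)
    return EffectDecomposition(
        grand_mean=float(grand),
        main_genotype=tuple(row),
        main_treatment=tuple(col),
        interaction_effects=tuple(map(tuple, gamma)),
        cohen_f=cohen_f,
        noncentrality_per_n=ncp_per_n,
    )


def interaction_power(design: PowerDesign, n_per_cell: int) -> float:
    """Power of the interaction F test at a balanced per-cell size.

    Upper-tail probability of noncentral F(1, 4(n-1), lambda) beyond
    the central-F critical value at ``design.alpha``, with
    ``lambda = n * sum(gamma^2) / sigma^2``. A zero-interaction pattern
    gives exactly alpha.
    """
    if n_per_cell < 2:
        raise ValueError("n_per_cell must be >= 2")
    dec = decompose_effects(design.means, design.sigma)
    lam = n_per_cell * dec.noncentrality_per_n
    dfd = 4 * (n_per_cell - 1)
    fcrit = stats.f.isf(design.alpha, 1, dfd)
    if lam == 0:
        return design.alpha
    return float(stats.ncf.sf(fcrit, 1, dfd, lam))


def solve_n(design: PowerDesign, max_n: int = 10 ** 6) -> int:
    """Smallest integer n >= 2 per cell with interaction power >= target.

    Raises when the pattern has no interaction (no finite n exists).
    """
    dec = decompose_effects(design.means, design.sigma)
    if dec.noncentrality_per_n == 0:
        raise ValueError("cell-mean pattern has zero interaction: no finite "
                         "sample size reaches the target power")
    n = 2
    while n <= max_n:
        if interaction_power(design, n) >= design.target_power:
            return n
        n += 1
    raise RuntimeError(f"no n <= {max_n} reaches the target power")


def monte_carlo_interaction_power(design: PowerDesign, n_per_cell: int,
                                  n_reps: int = 10_000, seed: int = 0) -> float:
    """Simulated rejection rate of the interaction F test (oracle cross-check).

    Draws balanced normal samples from the design's cell means and runs
    the classical two-way ANOVA interaction test on each replicate;
    fully vectorized over replicates.
    """
    if n_per_cell < 2:
        raise ValueError("n_per_cell must be >= 2")
    rng = np.random.default_rng(seed)
    means = design.means
    # data: reps x 2 x 2 x n
    data = rng.normal(means[None, :, :, None], design.sigma,
                      (n_reps, 2, 2, n_per_cell))
    cell_means = data.mean(axis=3)
    grand = cell_means.mean(axis=(1, 2), keepdims=True)
    row = cell_means.mean(axis=2, keepdims=True) - grand
    col = cell_means.mean(axis=1, keepdims=True) - grand
    gamma_hat = cell_means - grand - row - col
    ss_int = n_per_cell * (gamma_hat ** 2).sum(axis=(1, 2))
    sse = ((data - cell_means[..., None]) ** 2).sum(axis=(1, 2, 3))
    dfd = 4 * (n_per_cell - 1)
    f_stat = ss_int / (sse / dfd)
    fcrit = stats.f.isf(design.alpha, 1, dfd)
    return float((f_stat > fcrit).mean())
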