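"""Synthetic spike-in generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes for
a balanced 2x2 genotype (WT vs TG) by treatment (VEH vs DCI) design:

- protein baselines spread over orders of magnitude (log-uniform);
- a genotype effect of a configurable fraction of the control mean,
  present only in the TG-VEH cell (treatment normalizes TG back to
  control levels, and WT is unaffected by treatment);
- multiplicative Gaussian within-cell noise with a fixed coefficient
  of variation, truncated to keep abundances positive;
- per-sample depth multipliers (log-normal) applied uniformly to all
  proteins of a sample;
- optional sex strata and optional gross outlier cells.

Every stochastic operation is keyed by an explicit integer seed and is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import GENOTYPES, SEXES, TREATMENTS
from .matrix_io import write_annotation, write_matrix, write_provenance

__all__ = ["SimulationConfig", "SyntheticTruth", "generate_matrix",
           "inject_outliers", "write_truth"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated experiment.

    Defaults mirror the study design this generator emulates: a 35%
    genotype effect in the vehicle-treated transgenic cell, within-cell
    noise equal to 20% of the cell mean, 6 animals per
    genotype x treatment x sex cell (12 per 2x2 cell, 48 samples), and
    5% of proteins carrying the effect.
    """

    n_proteins: int = 2000
    n_per_cell: int = 6
    cv: float = 0.2
    effect_fraction: float = 0.35
    spike_fraction: float = 0.05
    baseline_log10_range: tuple[float, float] = (4.0, 9.0)
    depth_sigma: float = 0.1
    outlier_rate: float = 0.0
    outlier_factor: float = 10.0
    sexes: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1 or self.n_per_cell < 1:
            raise ValueError("n_proteins and n_per_cell must be >= 1")
        if not 0.0 < self.cv < 1.0:
            raise ValueError("cv must lie in (0, 1): multiplicative normal noise "
                             "with cv >= 1 would cross zero too often")
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise ValueError("spike_fraction must lie in [0, 1]")
        if not 0.0 <= self.effect_fraction < 1.0:
            raise ValueError("effect_fraction must lie in [0, 1)")
        if self.outlier_rate and self.outlier_factor <= 1.0:
            raise ValueError("outlier_factor must be > 1")
        lo, hi = self.baseline_log10_range
        if not lo <= hi:
            raise ValueError("baseline_log10_range must be (lo, hi) with lo <= hi")
        if self.depth_sigma < 0:
            raise ValueError("depth_sigma must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated matrix.

    ``table`` has one row per protein (index ``protein_id``) with
    ``is_spiked`` and ``true_ratio`` (TG-VEH cell mean over baseline;
    1 for non-spiked proteins). ``outlier_cells`` lists the
    (protein_id, sample_id) cells multiplied by a gross factor.
    """

    table: pd.DataFrame
    outlier_cells: list[tuple[str, str]] = field(default_factory=list)


def _sample_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    sexes: Sequence[str] = SEXES if config.sexes else ("NA",)
    for g in GENOTYPES:
        for t in TREATMENTS:
            for sx in sexes:
                for i in range(config.n_per_cell):
                    tag = f"{g}-{t}" + (f"-{sx}" if sx != "NA" else "")
                    rows.append({"sample_id": f"{tag}-{i + 1:02d}",
                                 "genotype": g, "treatment": t, "sex": sx})
    return pd.DataFrame(rows).set_index("sample_id")


def _truncated_noise(rng: np.random.Generator, cv: float, shape: tuple[int, int]) -> np.ndarray:
    """N(0, cv^2) draws, redrawn wherever <= -1 so abundances stay positive."""
    eps = rng.normal(0.0, cv, shape)
    bad = eps <= -1.0
    while bad.any():
        eps[bad] = rng.normal(0.0, cv, int(bad.sum()))
        bad = eps <= -1.0
    return eps


def generate_matrix(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate an abundance matrix, its annotation and the spiked truth.

    Spiked proteins carry the genotype effect only in the TG-VEH cell:
    its mean is ``baseline * (1 +/- effect_fraction)`` (direction split
    evenly up/down), while TG-DCI, WT-VEH and WT-DCI stay at baseline.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ann = _sample_frame(config)
    n, m = config.n_proteins, len(ann)

    lo, hi = config.baseline_log10_range
    baselines = 10.0 ** rng.uniform(lo, hi, n)

    n_spiked = int(round(config.spike_fraction * n))
    spiked_idx = np.sort(rng.choice(n, size=n_spiked, replace=False))
    true_ratio = np.ones(n)
    if n_spiked:
        direction = np.ones(n_spiked)
        direction[: n_spiked // 2] = -1.0  # half down, half (plus remainder) up
        rng.shuffle(direction)
        true_ratio[spiked_idx] = 1.0 + direction * config.effect_fraction

    # cell means: baseline everywhere except the TG-VEH column of spiked proteins
    means = np.tile(baselines[:, None], (1, m))
    tg_veh = ((ann["genotype"] == "TG") & (ann["treatment"] == "VEH")).to_numpy()
    means[:, tg_veh] *= true_ratio[:, None]

    eps = _truncated_noise(rng, config.cv, (n, m))
    depth = np.exp(rng.normal(0.0, config.depth_sigma, m)) if config.depth_sigma > 0 else np.ones(m)
    values = means * (1.0 + eps) * depth[None, :]

    protein_ids = pd.Index([f"P{i + 1:05d}" for i in range(n)], name="protein_id")
    matrix = pd.DataFrame(values, index=protein_ids, columns=ann.index)

    truth_table = pd.DataFrame(
        {"is_spiked": np.isin(np.arange(n), spiked_idx), "true_ratio": true_ratio},
        index=protein_ids,
    )
    truth = SyntheticTruth(table=truth_table)

    if config.outlier_rate > 0:
        matrix, cells = inject_outliers(matrix, config.outlier_rate,
                                        config.outlier_factor, config.seed + 1)
        truth.outlier_cells = cells
    return matrix, ann, truth


def inject_outliers(matrix: pd.DataFrame, rate: float, factor: float,
                    seed: int) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Multiply ``floor(rate * n_cells)`` randomly chosen cells by ``factor``.

    Returns the modified copy and the list of (protein_id, sample_id)
    cells touched. ``rate`` is capped below 0.1 so the fixture stays a
    sparse contamination rather than a shifted distribution.
    """
    if not 0.0 <= rate < 0.1:
        raise ValueError("outlier rate must lie in [0, 0.1)")
    if factor <= 1.0:
        raise ValueError("outlier factor must be > 1")
    out = matrix.copy()
    n_cells = out.size
    n_out = int(np.floor(rate * n_cells))
    if n_out == 0:
        return out, []
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_out, replace=False)
    rows, cols = np.unravel_index(flat, out.shape)
    vals = out.to_numpy()
    vals[rows, cols] *= factor
    out = pd.DataFrame(vals, index=out.index, columns=out.columns)
    cells = [(str(out.index[r]), str(out.columns[c])) for r, c in zip(rows, cols)]
    return out, cells


def write_truth(truth: SyntheticTruth, path: str | Path,
                provenance: dict | None = None) -> None:
    """Write the truth table as TSV; outlier cells go into the provenance sidecar."""
    path = Path(path)
    truth.table.to_csv(path, sep="\t", index_label="protein_id")
    record = dict(provenance or {})
    record["outlier_cells"] = [list(c) for c in truth.outlier_cells]
    write_provenance(path, record)


def simulate_to_dir(config: SimulationConfig, out_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate and write matrix.tsv, annotation.tsv and truth.tsv to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, ann, truth = generate_matrix(config)
    prov = {"stage": "simulate", "config": vars(config) | {
        "baseline_log10_range": list(config.baseline_log10_range)}}
    write_matrix(matrix, out / "matrix.tsv", prov)
    write_annotation(ann, out / "annotation.tsv", prov)
    write_truth(truth, out / "truth.tsv", prov)
    return matrix, ann, truth


def null_config(config: SimulationConfig) -> SimulationConfig:
    """The same design with the genotype effect switched off."""
    return replace(config, spike_fraction=0.0)
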