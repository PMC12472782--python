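"""End-to-end orchestration: simulate/load -> QC -> normalize -> test -> select -> report.

A run is described by a :class:`RunConfig` (YAML-serializable, unknown
keys rejected); all randomness flows from its single seed, and re-runs
with the same config produce byte-identical TSV outputs. Each written
file carries a JSON provenance sidecar; stage counts are gathered into
a :class:`RunReport`.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, differential, matrix_io, network, normalize, qc, selection, synthetic

__all__ = ["RunConfig", "RunReport", "run_pipeline", "score_against_truth"]


def _from_dict(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class QCParams:
    enabled: bool = True
    k: int | None = None
    z_threshold: float = 3.5
    by_sex: bool = True


@dataclass(frozen=True)
class NormalizationParams:
    method: str = "down_scaling"
    by_sex: bool = True
    reference_ids: tuple[str, ...] | None = None
    evaluate: bool = True


@dataclass(frozen=True)
class DifferentialParams:
    contrast: str = "genotype"
    within: str | None = "VEH"
    alpha_normality: float = 0.05
    p_cut: float = differential.DEFAULT_P_CUT
    up_cut: float = differential.DEFAULT_UP_CUT
    down_cut: float = differential.DEFAULT_DOWN_CUT
    min_change: float = differential.DEFAULT_MIN_CHANGE


@dataclass(frozen=True)
class SelectionParams:
    fraction: float = 0.05


@dataclass(frozen=True)
class NetworkParams:
    edges_path: str | None = None
    min_score: int = 400
    min_component: int = 3
    gmt_path: str | None = None


@dataclass(frozen=True)
class RunConfig:
    """Full parameterization of one pipeline run.

    Either ``simulate`` holds generator parameters, or ``matrix_path``
    and ``annotation_path`` point at input files.
    """

    seed: int = 0
    out_dir: str = "proteopipe_run"
    simulate: synthetic.SimulationConfig | None = None
    matrix_path: str | None = None
    annotation_path: str | None = None
    qc: QCParams = field(default_factory=QCParams)
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    differential: DifferentialParams = field(default_factory=DifferentialParams)
    selection: SelectionParams = field(default_factory=SelectionParams)
    network: NetworkParams = field(default_factory=NetworkParams)

    def to_dict(self) -> dict[str, Any]:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                obj = dataclasses.asdict(obj)
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            return obj
        return conv(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sub = {
            "simulate": lambda d: _from_dict(synthetic.SimulationConfig, _tupled(d)),
            "qc": lambda d: _from_dict(QCParams, d),
            "normalization": lambda d: _from_dict(NormalizationParams, _tupled(d)),
            "differential": lambda d: _from_dict(DifferentialParams, d),
            "selection": lambda d: _from_dict(SelectionParams, d),
            "network": lambda d: _from_dict(NetworkParams, d),
        }
        for key, builder in sub.items():
            if data.get(key) is not None and isinstance(data[key], dict):
                data[key] = builder(data[key])
        return _from_dict(cls, data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


@dataclass
class RunReport:
    """Stage-by-stage record counts plus the parameter echo."""

    counts: dict[str, int]
    seed: int
    config: dict[str, Any]
    elapsed_seconds: float

    def to_json(self, path: str | Path) -> None:
        payload = {"counts": self.counts, "seed": self.seed,
                   "config": self.config, "elapsed_seconds": self.elapsed_seconds,
                   "version": __version__}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                         default=str) + "\n")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all configured stages, writing outputs under ``config.out_dir``."""
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov_base = {"seed": config.seed, "config": config.to_dict()}
    counts: dict[str, int] = {}

    # --- input ---------------------------------------------------------
    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        matrix, ann, truth = _stage("simulate")(synthetic.generate_matrix)(sim_cfg)
        matrix_io.write_matrix(matrix, out / "matrix_raw.tsv", prov_base | {"stage": "simulate"})
        matrix_io.write_annotation(ann, out / "annotation.tsv", prov_base | {"stage": "simulate"})
        synthetic.write_truth(truth, out / "truth.tsv", prov_base | {"stage": "simulate"})
    elif config.matrix_path and config.annotation_path:
        matrix = _stage("read")(matrix_io.read_matrix)(config.matrix_path)
        ann = _stage("read")(matrix_io.read_annotation)(config.annotation_path, matrix)
    else:
        raise PipelineError("stage 'input' failed: provide either simulate "
                            "parameters or matrix_path + annotation_path")
    matrix_io.require_nonempty_cells(ann)
    counts["proteins_in"] = int(matrix.shape[0])
    counts["samples"] = int(matrix.shape[1])

    # --- outlier QC ----------------------------------------------------
    if config.qc.enabled:
        matrix, report = _stage("qc")(qc.remove_outliers)(
            matrix, ann, k=config.qc.k, z_threshold=config.qc.z_threshold,
            by_sex=config.qc.by_sex)
        report.flagged.to_csv(out / "outliers.tsv", sep="\t", index=False)
        matrix_io.write_provenance(out / "outliers.tsv",
                                   prov_base | {"stage": "qc"} | report.summary())
        counts["flagged_outliers"] = int(len(report.flagged))

    # --- normalization -------------------------------------------------
    result = _stage("normalize")(normalize.normalize_matrix)(
        matrix, ann, method=config.normalization.method,
        reference_ids=config.normalization.reference_ids,
        by_sex=config.normalization.by_sex)
    matrix = result.normalized
    factors = pd.DataFrame({"factor": result.factors, "stratum": result.strata})
    factors.to_csv(out / "normalization_factors.tsv", sep="\t", index_label="sample_id")
    matrix_io.write_provenance(out / "normalization_factors.tsv",
                               prov_base | {"stage": "normalize",
                                            "method": result.method})
    matrix_io.write_matrix(matrix, out / "matrix_normalized.tsv",
                           prov_base | {"stage": "normalize"})
    if config.normalization.evaluate:
        diag = _stage("normalize")(normalize.evaluate_normalizations)(
            matrix, ann, reference_ids=config.normalization.reference_ids,
            by_sex=config.normalization.by_sex)
        diag.to_csv(out / "normalization_diagnostics.tsv", sep="\t")

    # --- differential testing ------------------------------------------
    d = config.differential
    diff = _stage("diffexp")(differential.differential_table)(
        matrix, ann, contrast=d.contrast, within=d.within,
        alpha_normality=d.alpha_normality, p_cut=d.p_cut, up_cut=d.up_cut,
        down_cut=d.down_cut, min_change=d.min_change)
    diff.to_csv(out / "differential.tsv", sep="\t")
    matrix_io.write_provenance(out / "differential.tsv", prov_base | {"stage": "diffexp"})
    counts["tested"] = int((diff["test_used"].isin(["student_t", "mann_whitney"])).sum())
    counts["up"] = int((diff["volcano_class"] == "up").sum())
    counts["down"] = int((diff["volcano_class"] == "down").sum())

    # --- candidate selection -------------------------------------------
    cand = _stage("select")(selection.candidate_table)(
        matrix, ann, diff_table=diff, fraction=config.selection.fraction)
    cand.to_csv(out / "candidates.tsv", sep="\t")
    matrix_io.write_provenance(out / "candidates.tsv", prov_base | {"stage": "select"})
    counts["candidates"] = int(cand["selected"].sum())

    # --- network / enrichment (optional, offline inputs) ---------------
    significant = list(diff.index[diff["volcano_class"].isin(["up", "down"])])
    if config.network.edges_path:
        graph = _stage("network")(network.read_string_edges)(
            config.network.edges_path, min_score=config.network.min_score)
        comps = network.induced_subgraph(graph, significant,
                                         min_component=config.network.min_component)
        comp_rows = [{"component": i + 1, "size": len(c),
                      "members": ";".join(sorted(c))}
                     for i, c in enumerate(comps)]
        pd.DataFrame(comp_rows, columns=["component", "size", "members"]).to_csv(
            out / "components.tsv", sep="\t", index=False)
        counts["components"] = len(comps)
    if config.network.gmt_path:
        terms = _stage("enrich")(network.read_gmt)(config.network.gmt_path)
        enr = network.hypergeometric_enrichment(significant, terms,
                                                universe=diff.index)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        counts["enriched_terms"] = int((enr["q_value"] < 0.05).sum())

    report = RunReport(counts=counts, seed=config.seed, config=config.to_dict(),
                       elapsed_seconds=time.monotonic() - t0)
    report.to_json(out / "run_report.json")
    return report


def score_against_truth(truth: synthetic.SyntheticTruth | pd.DataFrame,
                        diff_table: pd.DataFrame) -> dict[str, float]:
    """Sensitivity and empirical false-discovery proportion of volcano calls.

    A call is any protein classified up or down; a true positive is a
    call on a spiked protein. FDP is 0 when nothing is called.
    """
    table = truth.table if isinstance(truth, synthetic.SyntheticTruth) else truth
    spiked = table["is_spiked"].astype(bool).reindex(diff_table.index, fill_value=False)
    called = diff_table["volcano_class"].isin(["up", "down"])
    tp = int((called & spiked).sum())
    n_called = int(called.sum())
    n_spiked = int(spiked.sum())
    return {
        "sensitivity": tp / n_spiked if n_spiked else float("nan"),
        "fdp": (n_called - tp) / n_called if n_called else 0.0,
        "n_called": n_called,
        "n_spiked": n_spiked,
    }
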