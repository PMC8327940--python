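"""End-to-end driver: simulate/load -> filter -> normalize -> model -> classify.

One :class:`PipelineConfig` fully determines a run; identical configs (and
inputs) produce byte-identical deterministic outputs, recorded in a
:class:`RunManifest` with per-stage row counts, timings and output
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .classify import (
    classify_genes,
    concordance_test,
    plasticity_amplification,
    timepoint_concordance,
)
from .data import ValidationError
from .dge import run_standard_contrasts
from .io import (
    read_counts,
    read_samples,
    write_calls,
    write_counts,
    write_dge_result,
    write_json_atomic,
    write_norm_factors,
    write_samples,
)
from .normalize import filter_by_expression, tmm_factors
from .simulate import SimConfig, simulate_experiment, write_truth

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "summary_from_results"]


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    output_dir: str = "plastevo_run"
    counts_path: str | None = None
    samples_path: str | None = None
    annotation_path: str | None = None
    cpm_min: float = 10.0
    min_prop: float | None = None
    trim_m: float = 0.30
    trim_a: float = 0.05
    span: float = 0.5
    fdr_alpha: float = 0.1
    classify_alpha: float = 0.1
    simulation: SimConfig | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValidationError("fdr_alpha must lie in (0, 1)")
        if not 0.0 < self.classify_alpha < 1.0:
            raise ValidationError("classify_alpha must lie in (0, 1)")
        has_inputs = self.counts_path is not None and self.samples_path is not None
        if not has_inputs and self.simulation is None:
            raise ValidationError(
                "config needs either counts_path + samples_path or a simulation block"
            )
        if has_inputs:
            for p in (self.counts_path, self.samples_path):
                if not Path(p).exists():
                    raise ValidationError(f"input path does not exist: {p}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
            if d["simulation"].get("cell_sizes") is not None:
                d["simulation"]["cell_sizes"] = dict(d["simulation"]["cell_sizes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.get("simulation")
        if sim is not None:
            d["simulation"] = SimConfig(**sim)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    """Snapshot of what ran: config, versions, sizes, checksums, timings."""

    config: dict
    version: str
    input_checksums: dict = field(default_factory=dict)
    output_checksums: dict = field(default_factory=dict)
    stage_rows: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def summary_from_results(results: dict, alpha: float = 0.1) -> dict:
    """Headline numbers from the standard contrast tables."""
    calls = classify_genes(
        results["plastic_control_pooled"], results["evolved_unsprayed"], alpha=alpha
    )
    conc = concordance_test(calls)
    r_tp, n_changed = timepoint_concordance(
        results["plastic_control_8h"], results["plastic_control_32h"], alpha=alpha
    )
    amp = plasticity_amplification(
        results["plastic_control_pooled"], results["plastic_resistant_pooled"], alpha=alpha
    )
    counts = calls["call"].value_counts()
    return {
        "n_both": conc.n_both,
        "n_adaptive": int(counts.get("adaptive", 0)),
        "n_maladaptive": int(counts.get("maladaptive", 0)),
        "p_binomial": conc.p_two_sided,
        "fraction_greater": amp.fraction_greater,
        "n_sig_control": amp.n_sig_control,
        "n_sig_resistant": amp.n_sig_resistant,
        "r_timepoints": r_tp,
        "n_direction_changed": n_changed,
    }, calls


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage and write all artifacts into ``config.output_dir``."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=__version__)

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest.stage_seconds[name] = time.perf_counter() - self.t0
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                return False

        return _Timer()

    with stage("input"):
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            counts, design, truth = simulate_experiment(sim)
            write_counts(counts, outdir / "counts.tsv")
            write_samples(design, outdir / "samples.tsv")
            write_truth(truth, outdir / "truth.tsv")
        else:
            counts = read_counts(config.counts_path)
            design = read_samples(config.samples_path)
            manifest.input_checksums = {
                "counts": _sha256(Path(config.counts_path)),
                "samples": _sha256(Path(config.samples_path)),
            }
        if not design.sample_ids.equals(counts.sample_ids):
            raise ValidationError("sample sheet does not match count matrix columns")
        manifest.stage_rows["input"] = counts.n_genes

    with stage("filter"):
        filtered = filter_by_expression(
            counts, design, cpm_min=config.cpm_min, min_prop=config.min_prop
        )
        write_counts(filtered, outdir / "filtered_counts.tsv")
        manifest.stage_rows["filter"] = filtered.n_genes

    with stage("normalize"):
        factors = tmm_factors(filtered, trim_m=config.trim_m, trim_a=config.trim_a)
        write_norm_factors(factors, outdir / "norm_factors.tsv")
        manifest.stage_rows["normalize"] = len(factors.factors)

    with stage("dge"):
        results = run_standard_contrasts(filtered, design, factors, span=config.span)
        for name, table in results.items():
            write_dge_result(table, outdir / f"dge_{name}.tsv")
        manifest.stage_rows["dge"] = len(next(iter(results.values())))

    with stage("classify"):
        summary, calls = summary_from_results(results, alpha=config.classify_alpha)
        write_calls(calls, outdir / "calls.tsv")
        write_json_atomic(summary, outdir / "summary.json")
        manifest.stage_rows["classify"] = len(calls)

    for p in sorted(outdir.iterdir()):
        if p.suffix in {".tsv", ".json"} and p.name != "manifest.json":
            manifest.output_checksums[p.name] = _sha256(p)
    write_json_atomic(dataclasses.asdict(manifest), outdir / "manifest.json")
    return manifest
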