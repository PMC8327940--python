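"""Synthetic RNA-seq count experiments with planted plasticity structure.

The generator emulates the experiment the pipeline is built for: two line
types (control lines vs. lines artificially selected for herbicide
resistance), two treatments (unsprayed vs. sprayed) and two sampling
timepoints (8 h and 32 h after spray).  Counts are negative binomial with
``Var = mu + phi * mu^2`` and a dispersion trend ``phi_g = a1 + a0 / mu_g``
decaying with mean expression — the mean-variance shape the downstream
precision weights assume.

Effects are planted on the log2 scale: a *plastic* effect shifts sprayed
samples (multiplied by ``amplification`` in resistant lines) and an
*evolved* effect shifts resistant samples.  Genes carrying both effects are
sign-concordant (adaptive) with probability ``prob_concordant``, otherwise
discordant (maladaptive).  Plastic effects are identical at both
timepoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data import LINE_TYPES, TIMEPOINTS, TREATMENTS, CountMatrix, SampleDesign, ValidationError

__all__ = ["SimConfig", "SimTruth", "simulate_experiment", "write_truth", "read_truth"]

CLASS_LABELS = ("adaptive", "maladaptive", "plastic_only", "evolved_only", "null")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic experiment.

    Defaults mirror the real study's scale where it states one: eight
    replicates per factorial cell (the study had 15-16 plants per
    line x treatment group split over two timepoints) and library sizes
    log-normal around 28 million reads.  Effect sizes and fractions are
    free knobs of the generator.
    """

    n_genes: int = 5000
    samples_per_cell: int = 8
    baseline_log2cpm_mean: float = 5.0
    baseline_log2cpm_sd: float = 2.0
    libsize_log_mean: float = math.log(28e6)
    libsize_log_sd: float = 0.25
    dispersion_a0: float = 2.0  # phi_g = a1 + a0 / mu_g
    dispersion_a1: float = 0.04
    frac_plastic: float = 0.15
    frac_evolved: float = 0.05
    frac_both: float = 0.05
    prob_concordant: float = 0.72
    effect_lfc_mean: float = 2.0
    effect_lfc_sd: float = 0.5
    amplification: float = 1.0
    seed: int = 0
    cell_sizes: Mapping[str, int] | None = None  # optional per-cell override

    def validate(self) -> None:
        if not isinstance(self.n_genes, (int, np.integer)) or isinstance(self.n_genes, bool):
            raise ValidationError("n_genes must be an integer")
        if not isinstance(self.samples_per_cell, (int, np.integer)):
            raise ValidationError("samples_per_cell must be an integer")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.samples_per_cell < 2:
            raise ValidationError("samples_per_cell must be >= 2")
        for name in ("frac_plastic", "frac_evolved", "frac_both", "prob_concordant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.frac_plastic + self.frac_evolved + self.frac_both > 1.0 + 1e-12:
            raise ValidationError("effect fractions must sum to <= 1")
        if self.dispersion_a0 < 0 or self.dispersion_a1 <= 0:
            raise ValidationError("dispersion trend requires a0 >= 0 and a1 > 0")
        if self.amplification < 0:
            raise ValidationError("amplification must be >= 0")


@dataclass
class SimTruth:
    """Planted per-gene effects and the class label they imply."""

    table: pd.DataFrame  # class_label, true_plastic_lfc, true_evolved_lfc, amplified

    def __post_init__(self) -> None:
        t = self.table
        p = t["true_plastic_lfc"].to_numpy()
        e = t["true_evolved_lfc"].to_numpy()
        expected = _labels_from_effects(p, e)
        if not (t["class_label"].to_numpy() == expected).all():
            raise ValidationError("class_label inconsistent with planted effect signs")

    def class_counts(self) -> pd.Series:
        return self.table["class_label"].value_counts().reindex(CLASS_LABELS, fill_value=0)


def _labels_from_effects(plastic: np.ndarray, evolved: np.ndarray) -> np.ndarray:
    labels = np.full(len(plastic), "null", dtype=object)
    both = (plastic != 0) & (evolved != 0)
    labels[(plastic != 0) & (evolved == 0)] = "plastic_only"
    labels[(plastic == 0) & (evolved != 0)] = "evolved_only"
    labels[both & (np.sign(plastic) == np.sign(evolved))] = "adaptive"
    labels[both & (np.sign(plastic) != np.sign(evolved))] = "maladaptive"
    return labels


def _sample_sheet(config: SimConfig) -> SampleDesign:
    rows = []
    abbrev = {"control": "ctl", "resistant": "res", "unsprayed": "uns", "sprayed": "spr"}
    for line in LINE_TYPES:
        for treat in TREATMENTS:
            for tp in TIMEPOINTS:
                cell = f"{line}.{treat}.{tp}"
                n = config.samples_per_cell
                if config.cell_sizes and cell in config.cell_sizes:
                    n = int(config.cell_sizes[cell])
                for rep in range(1, n + 1):
                    sid = f"{abbrev[line]}_{abbrev[treat]}_{tp}h_r{rep}"
                    rows.append((sid, line, treat, tp, rep))
    table = pd.DataFrame(
        rows, columns=["sample", "line_type", "treatment", "timepoint", "replicate"]
    ).set_index("sample")
    return SampleDesign(table)


def simulate_experiment(
    config: SimConfig,
) -> tuple[CountMatrix, SampleDesign, SimTruth]:
    """Draw one complete experiment; the same seed reproduces it exactly."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = _sample_sheet(config)
    n_genes, n_samples = config.n_genes, design.n_samples
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene")

    baseline = rng.normal(config.baseline_log2cpm_mean, config.baseline_log2cpm_sd, n_genes)
    # renormalize so the planted abundances are a proper CPM composition
    # (sum to 1e6); the realized per-gene baseline is recorded in the truth
    baseline += np.log2(1e6) - np.log2(np.sum(2.0 ** baseline))
    lib = np.exp(rng.normal(config.libsize_log_mean, config.libsize_log_sd, n_samples))

    probs = [
        config.frac_plastic,
        config.frac_evolved,
        config.frac_both,
        1.0 - config.frac_plastic - config.frac_evolved - config.frac_both,
    ]
    kind = rng.choice(4, size=n_genes, p=np.clip(probs, 0, None) / np.sum(np.clip(probs, 0, None)))

    def magnitudes() -> np.ndarray:
        return np.abs(rng.normal(config.effect_lfc_mean, config.effect_lfc_sd, n_genes))

    plastic_sign = rng.choice([-1.0, 1.0], size=n_genes)
    concordant = rng.random(n_genes) < config.prob_concordant
    plastic_lfc = np.where(np.isin(kind, [0, 2]), plastic_sign * magnitudes(), 0.0)
    evolved_sign = np.where(
        kind == 2, np.where(concordant, plastic_sign, -plastic_sign),
        rng.choice([-1.0, 1.0], size=n_genes),
    )
    evolved_lfc = np.where(np.isin(kind, [1, 2]), evolved_sign * magnitudes(), 0.0)

    sprayed = (design.table["treatment"] == "sprayed").to_numpy()
    resistant = (design.table["line_type"] == "resistant").to_numpy()
    plastic_scale = np.where(sprayed, np.where(resistant, config.amplification, 1.0), 0.0)
    log2cpm = (
        baseline[:, None]
        + plastic_lfc[:, None] * plastic_scale[None, :]
        + evolved_lfc[:, None] * resistant[None, :].astype(float)
    )
    mu = 2.0 ** log2cpm * lib[None, :] / 1e6
    phi = config.dispersion_a1 + config.dispersion_a0 / mu.mean(axis=1)

    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    tiny = phi < 1e-8
    if tiny.any():
        counts[tiny] = rng.poisson(mu[tiny])
    if (~tiny).any():
        size = 1.0 / phi[~tiny]
        p = size[:, None] / (size[:, None] + mu[~tiny])
        counts[~tiny] = rng.negative_binomial(size[:, None], p)

    matrix = CountMatrix(pd.DataFrame(counts, index=genes, columns=design.sample_ids))
    truth = SimTruth(
        pd.DataFrame(
            {
                "class_label": _labels_from_effects(plastic_lfc, evolved_lfc),
                "true_plastic_lfc": plastic_lfc,
                "true_evolved_lfc": evolved_lfc,
                "amplified": (plastic_lfc != 0) & (config.amplification != 1.0),
                "baseline_log2cpm": baseline,
            },
            index=genes,
        )
    )
    return matrix, design, truth


def write_truth(truth: SimTruth, path) -> None:
    """TSV with one row per gene; round-trips losslessly via read_truth."""
    truth.table.to_csv(path, sep="\t", index_label="gene")


def read_truth(path) -> SimTruth:
    # "null" is a class label, not a missing value
    table = pd.read_csv(path, sep="\t", index_col="gene", keep_default_na=False)
    table = table.astype(
        {"true_plastic_lfc": float, "true_evolved_lfc": float, "amplified": bool}
    )
    table["class_label"] = table["class_label"].astype(object)
    return SimTruth(table)
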