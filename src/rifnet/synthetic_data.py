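"""Synthetic two-condition expression studies with planted structure.

The generator emulates the data shape of a two-condition microarray study:
normalized log-scale intensities with Gaussian noise, two groups of samples
(treated S, control C), a subset of genes shifted in mean between
conditions (planted DE targets), and one or more planted *regulators* that
are not differentially expressed themselves but whose correlation to a
block of DE targets differs between conditions — the differential
connectivity signature the RIF statistics are designed to detect.

Construction, deterministic given the seed:

* every gene gets a baseline mean drawn uniformly from
  ``baseline_mean_range`` and i.i.d. Gaussian noise of SD ``noise_sd``;
* planted DE targets get ``de_effect * noise_sd`` added to every treated
  sample;
* each planted regulator keeps equal means in both conditions; each target
  in its block is rebuilt, condition by condition, as
  ``coupling * z_R + sqrt(1 - coupling^2) * eps`` on standardized residuals
  (``z_R`` is the regulator standardized within the condition) and then
  rescaled back to the target's mean and SD, using ``coupling_S`` in S and
  ``coupling_C`` in C;
* all remaining genes are independent noise.

A latent shared variable induces the couplings, so two targets of the same
block are themselves correlated at about ``coupling**2`` within a
condition — block-level tests should expect that.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import CONTROL, TREATED, ExpressionStudy, ValidationError

__all__ = ["SimConfig", "SimTruth", "simulate_study", "desk_config", "paper_scale_config"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Defaults are desk-scale: 2000 genes, one planted regulator coupled at
    0.8 (S) / 0.0 (C) to a 60-gene block inside 200 planted DE targets,
    20 + 20 samples, DE effect of two noise SDs, and a 500-gene regulator
    universe that contains the planted regulator, the DE genes and
    background fill.  ``paper_scale_config`` returns the larger preset
    matching the study dimensions (7350 genes, 1279 DE, 23 + 23 samples).
    """

    n_genes: int = 2000
    n_regulators_planted: int = 1
    n_de_planted: int = 200
    block_size: int = 60
    n_samples_S: int = 20
    n_samples_C: int = 20
    de_effect: float = 2.0
    coupling_S: float = 0.8
    coupling_C: float = 0.0
    noise_sd: float = 1.0
    baseline_mean_range: tuple[float, float] = (6.0, 12.0)
    n_regulator_universe: int | None = None  # default: min(500, n_genes)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regulator_universe is None:
            object.__setattr__(self, "n_regulator_universe", min(500, self.n_genes))
        if not (-1.0 <= self.coupling_S <= 1.0 and -1.0 <= self.coupling_C <= 1.0):
            raise ValidationError("couplings must lie in [-1, 1]")
        if self.n_samples_S < 3 or self.n_samples_C < 3:
            raise ValidationError("need >= 3 samples per condition")
        if self.n_de_planted + self.n_regulators_planted > self.n_genes:
            raise ValidationError("planted DE genes + regulators exceed gene count")
        if self.n_regulators_planted > 0 and self.block_size * self.n_regulators_planted > max(
            self.n_de_planted, 0
        ):
            raise ValidationError(
                "target blocks exceed the planted DE set: "
                f"{self.n_regulators_planted} x {self.block_size} > {self.n_de_planted}"
            )
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not 2 <= self.n_regulator_universe <= self.n_genes:
            raise ValidationError("n_regulator_universe must lie in [2, n_genes]")


@dataclass
class SimTruth:
    """Ground-truth labels emitted next to each simulated study."""

    de_gene_ids: list[str]
    dc_regulator_ids: list[str]
    target_blocks: dict[str, list[str]]
    regulator_universe: list[str]
    coupling_S: float
    coupling_C: float

    def to_dict(self) -> dict:
        return asdict(self)


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def simulate_study(config: SimConfig) -> tuple[ExpressionStudy, SimTruth]:
    """Generate a study plus its ground truth; bit-identical for a given config."""
    rng = np.random.default_rng(config.seed)
    n_s, n_c = config.n_samples_S, config.n_samples_C
    n_total = n_s + n_c
    genes = _gene_ids(config.n_genes)

    # layout: planted regulators first, then planted DE targets, then background
    reg_ids = genes[: config.n_regulators_planted]
    de_ids = genes[config.n_regulators_planted : config.n_regulators_planted + config.n_de_planted]
    universe = genes[: config.n_regulator_universe]

    mu = rng.uniform(*config.baseline_mean_range, size=config.n_genes)
    values = mu[:, None] + config.noise_sd * rng.standard_normal((config.n_genes, n_total))

    s_cols = slice(0, n_s)
    c_cols = slice(n_s, n_total)
    de_index = np.arange(
        config.n_regulators_planted, config.n_regulators_planted + config.n_de_planted
    )
    values[de_index, s_cols] += config.de_effect * config.noise_sd

    blocks: dict[str, list[str]] = {}
    gene_pos = {g: i for i, g in enumerate(genes)}
    for k, reg in enumerate(reg_ids):
        block = de_ids[k * config.block_size : (k + 1) * config.block_size]
        blocks[reg] = list(block)
        reg_row = values[gene_pos[reg]]
        for cols, coupling in ((s_cols, config.coupling_S), (c_cols, config.coupling_C)):
            seg = reg_row[cols]
            z_reg = (seg - seg.mean()) / seg.std()
            n_cond = seg.size
            for tgt in block:
                i = gene_pos[tgt]
                # block targets are DE by construction: keep the S-side shift
                target_mean = mu[i] + (
                    config.de_effect * config.noise_sd if cols is s_cols else 0.0
                )
                eps = rng.standard_normal(n_cond)
                std_target = coupling * z_reg + np.sqrt(1.0 - coupling**2) * eps
                values[i, cols] = target_mean + config.noise_sd * std_target

    sample_ids = [f"S{i:02d}" for i in range(1, n_s + 1)] + [
        f"C{i:02d}" for i in range(1, n_c + 1)
    ]
    condition_of = {s: (TREATED if s.startswith("S") else CONTROL) for s in sample_ids}
    study = ExpressionStudy(
        pd.DataFrame(values, index=genes, columns=sample_ids), condition_of
    )
    truth = SimTruth(
        de_gene_ids=list(de_ids),
        dc_regulator_ids=list(reg_ids),
        target_blocks=blocks,
        regulator_universe=list(universe),
        coupling_S=config.coupling_S,
        coupling_C=config.coupling_C,
    )
    return study, truth


def desk_config(seed: int = 0, **overrides) -> SimConfig:
    """The default desk-scale configuration (see :class:`SimConfig`)."""
    return SimConfig(seed=seed, **overrides)


def paper_scale_config(seed: int = 0) -> SimConfig:
    """Preset matching the study's dimensions: 7350 genes, 1279 DE, 23+23 samples."""
    return SimConfig(
        n_genes=7350,
        n_de_planted=1279,
        n_samples_S=23,
        n_samples_C=23,
        n_regulator_universe=7350,
        seed=seed,
    )


def null_config(seed: int = 0, n_genes: int = 2000, n_samples: int = 20) -> SimConfig:
    """No planted structure at all: pure i.i.d. Gaussian noise on log scale."""
    return SimConfig(
        n_genes=n_genes,
        n_regulators_planted=0,
        n_de_planted=0,
        block_size=0,
        de_effect=0.0,
        n_samples_S=n_samples,
        n_samples_C=n_samples,
        seed=seed,
    )
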