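"""Reciprocal-cross expression simulator with per-gene ground truth.

Generates TPM matrices for two parental breeds (Cor, WL) and their reciprocal
F1 females (CL = Cor dam, LC = WL dam) across tissues and replicates. Each
gene carries a generating regulatory class that fixes the F1 mean rule:

* ``cis_dominant``        F1 mean equals the maternal population's mean
                          (CL tracks Cor, LC tracks WL);
* ``trans_dominant``      F1 mean equals the paternal population's mean;
* ``trans_additive``      F1 mean is the mean of the parental means
                          (arithmetic by default, geometric by config);
* ``trans_overdominant``  F1 mean = max(parental means) x excess factor;
* ``trans_underdominant`` F1 mean = min(parental means) / excess factor;
* ``conserved``           parents sit just above the fold-change threshold
                          (1.3-fold apart) with the F1 at their midpoint;
* ``null``                no divergence anywhere.

Replicate values are the population mean times multiplicative lognormal noise
of unit mean with the configured coefficient of variation. The default design
is unbalanced like the source study: 3 female replicates for Cor, WL and CL,
2 for LC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from wregdiv.expression_io import ExpressionMatrix, SampleSheet

__all__ = [
    "SIMULATED_CLASSES",
    "SimulationConfig",
    "generate_dataset",
    "generate_null_dataset",
]

SIMULATED_CLASSES = (
    "cis_dominant",
    "trans_dominant",
    "trans_additive",
    "trans_overdominant",
    "trans_underdominant",
    "conserved",
    "null",
)

_DEFAULT_REPLICATES = {"Cor": 3, "WL": 3, "CL": 3, "LC": 2}
_CONSERVED_FOLD = 1.3  # just above the 1.25 significance window


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated reciprocal-cross dataset.

    ``class_counts`` maps generating class names to gene counts. ``seed`` is
    mandatory — every dataset must be exactly reproducible.
    """

    class_counts: Mapping[str, int]
    seed: int
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 0.5
    log2_effect: float = 3.0
    random_effect_sign: bool = True
    dominance_excess: float = 3.0
    noise_cv: float = 0.15
    replicates: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_REPLICATES)
    )
    tissues: tuple[str, ...] = ("brain", "liver", "muscle")
    additive_mode: str = "arithmetic"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        unknown = set(self.class_counts) - set(SIMULATED_CLASSES)
        if unknown:
            raise ValueError(
                f"unknown gene class(es) {sorted(unknown)}; "
                f"allowed: {list(SIMULATED_CLASSES)}"
            )
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if sum(self.class_counts.values()) == 0:
            raise ValueError("no genes configured")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.dominance_excess <= 1.0:
            raise ValueError("dominance_excess must be > 1")
        missing = set(_DEFAULT_REPLICATES) - set(self.replicates)
        if missing:
            raise ValueError(f"replicates missing population(s): {sorted(missing)}")
        if any(v < 1 for v in self.replicates.values()):
            raise ValueError("each population needs >= 1 replicate")
        if self.additive_mode not in ("arithmetic", "geometric"):
            raise ValueError("additive_mode must be 'arithmetic' or 'geometric'")
        if not self.tissues:
            raise ValueError("at least one tissue required")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data = dict(data)
        if "tissues" in data:
            data["tissues"] = tuple(data["tissues"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "class_counts": dict(self.class_counts),
            "seed": self.seed,
            "baseline_log2_mean": self.baseline_log2_mean,
            "baseline_log2_sd": self.baseline_log2_sd,
            "log2_effect": self.log2_effect,
            "random_effect_sign": self.random_effect_sign,
            "dominance_excess": self.dominance_excess,
            "noise_cv": self.noise_cv,
            "replicates": dict(self.replicates),
            "tissues": list(self.tissues),
            "additive_mode": self.additive_mode,
        }


def _f1_mean(
    gene_class: str,
    maternal: float,
    paternal: float,
    excess: float,
    additive_mode: str,
) -> float:
    if gene_class == "cis_dominant":
        return maternal
    if gene_class == "trans_dominant":
        return paternal
    if gene_class == "trans_additive":
        if additive_mode == "geometric":
            return math.sqrt(maternal * paternal)
        return 0.5 * (maternal + paternal)
    if gene_class == "trans_overdominant":
        return max(maternal, paternal) * excess
    if gene_class == "trans_underdominant":
        return min(maternal, paternal) / excess
    # conserved: midpoint of the narrowly separated parents; null: no divergence
    if gene_class == "conserved":
        return 0.5 * (maternal + paternal)
    return maternal  # null: maternal == paternal == baseline


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleSheet, pd.DataFrame]:
    """Simulate one dataset; returns (matrix, sample sheet, truth table).

    The truth table has one row per gene: generating class, signed log2
    parental effect (Cor relative to WL) and the per-tissue baseline TPM.
    All genes are implicitly W-linked; samples are all female.
    """
    rng = np.random.default_rng(config.seed)

    gene_classes: list[str] = []
    for cls_name in SIMULATED_CLASSES:  # fixed order -> reproducible ids
        gene_classes.extend([cls_name] * int(config.class_counts.get(cls_name, 0)))
    n_genes = len(gene_classes)
    width = max(4, len(str(n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]

    # signed parental effect per gene (Cor = baseline * 2^effect, WL = baseline)
    effects = np.zeros(n_genes)
    for i, cls_name in enumerate(gene_classes):
        if cls_name == "null":
            continue
        magnitude = (
            math.log2(_CONSERVED_FOLD) if cls_name == "conserved" else config.log2_effect
        )
        sign = rng.choice([-1.0, 1.0]) if config.random_effect_sign else 1.0
        effects[i] = sign * magnitude

    baselines = 2.0 ** rng.normal(
        config.baseline_log2_mean,
        config.baseline_log2_sd,
        size=(n_genes, len(config.tissues)),
    )

    populations = ("Cor", "WL", "CL", "LC")
    columns: list[tuple[str, str, int]] = []  # (population, tissue, replicate)
    for tissue in config.tissues:
        for pop in populations:
            for rep in range(1, int(config.replicates[pop]) + 1):
                columns.append((pop, tissue, rep))
    sample_ids = [f"{pop}_{tissue}_F{rep}" for pop, tissue, rep in columns]

    # population means per gene x tissue
    means: dict[tuple[str, int], np.ndarray] = {}
    for t_idx in range(len(config.tissues)):
        base = baselines[:, t_idx]
        mean_wl = base
        mean_cor = base * 2.0**effects
        mean_cl = np.empty(n_genes)
        mean_lc = np.empty(n_genes)
        for i, cls_name in enumerate(gene_classes):
            mean_cl[i] = _f1_mean(
                cls_name, mean_cor[i], mean_wl[i],
                config.dominance_excess, config.additive_mode,
            )
            mean_lc[i] = _f1_mean(
                cls_name, mean_wl[i], mean_cor[i],
                config.dominance_excess, config.additive_mode,
            )
        means[("Cor", t_idx)] = mean_cor
        means[("WL", t_idx)] = mean_wl
        means[("CL", t_idx)] = mean_cl
        means[("LC", t_idx)] = mean_lc

    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
        mu = -(sigma**2) / 2.0  # unit-mean lognormal multiplier
    values = np.empty((n_genes, len(columns)))
    tissue_index = {t: i for i, t in enumerate(config.tissues)}
    for j, (pop, tissue, _rep) in enumerate(columns):
        mean = means[(pop, tissue_index[tissue])]
        if config.noise_cv > 0:
            noise = rng.lognormal(mu, sigma, size=n_genes)
            values[:, j] = mean * noise
        else:
            values[:, j] = mean

    matrix = ExpressionMatrix(tuple(gene_ids), tuple(sample_ids), values)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "population": [c[0] for c in columns],
                "sex": "F",
                "tissue": [c[1] for c in columns],
                "replicate": [c[2] for c in columns],
            }
        )
    )
    truth = pd.DataFrame({"gene_id": gene_ids, "gene_class": gene_classes,
                          "log2_effect": effects})
    for t_idx, tissue in enumerate(config.tissues):
        truth[f"baseline_{tissue}"] = baselines[:, t_idx]
    return matrix, sheet, truth


def generate_null_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleSheet, pd.DataFrame]:
    """Same design as :func:`generate_dataset` but every gene is class null."""
    total = sum(config.class_counts.values())
    null_config = SimulationConfig(
        class_counts={"null": total},
        seed=config.seed,
        baseline_log2_mean=config.baseline_log2_mean,
        baseline_log2_sd=config.baseline_log2_sd,
        log2_effect=config.log2_effect,
        random_effect_sign=config.random_effect_sign,
        dominance_excess=config.dominance_excess,
        noise_cv=config.noise_cv,
        replicates=dict(config.replicates),
        tissues=config.tissues,
        additive_mode=config.additive_mode,
    )
    return generate_dataset(null_config)


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.6g")
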