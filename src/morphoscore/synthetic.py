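"""Synthetic screens with planted statistical structure.

Generates single-cell profile tables that emulate the distributional layout
a morphology hit-calling analysis consumes: a reference and a target control
population that differ on a known "planted" feature subset, perturbation
groups whose means interpolate (or extrapolate) between the two states at a
graded efficacy lambda, optional planted off-target shifts, phenotype/gene
labeling for leave-one-gene-out evaluation, and multi-plate replicate
layouts with plate-level batch offsets.

The generative family is Gaussian with unit marginal variance and an
optional shared-factor correlation: with correlation rho, every cell draws
one latent factor g and each feature is sqrt(rho)*g + sqrt(1-rho)*noise.
Effect sizes are therefore in SD units.  All draws flow from a single root
seed, so any output is reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import ProfileTable

__all__ = ["ScreenConfig", "ScreenTruth", "generate_screen", "make_multiplate", "generate_logo_dataset"]


@dataclass
class ScreenConfig:
    """Parameters of a planted synthetic screen.

    Defaults mirror the canonical two-state setting used throughout the
    test-bed: 20 features of which 5 are shifted by 3 SD between the
    reference and target states, 500 cells per group.
    """

    n_features: int = 20
    n_on_features: int = 5
    effect_size: float = 3.0
    n_cells_per_group: int = 500
    correlation: float = 0.0
    efficacy_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    n_off_shift_features: int = 0
    off_shift_magnitude: float = 0.0
    n_plates: int = 1
    n_wells: int = 1
    n_treatments: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_features < 1 or self.n_cells_per_group < 1:
            raise ValueError("counts must be positive")
        if not (0 <= self.n_on_features <= self.n_features):
            raise ValueError("n_on_features must lie in [0, n_features]")
        if not (0.0 <= self.correlation < 1.0):
            raise ValueError("correlation must lie in [0, 1)")
        if self.n_plates < 1 or self.n_wells < 1:
            raise ValueError("layout counts must be positive")
        if self.n_off_shift_features > self.n_features - self.n_on_features:
            raise ValueError("n_off_shift_features exceeds the off-feature pool")
        if self.n_treatments is not None and self.n_treatments < 1:
            raise ValueError("n_treatments must be positive")


@dataclass
class ScreenTruth:
    """Ground truth planted into a generated screen."""

    on_features: list[str]
    efficacies: dict[str, float]
    off_shifted: dict[str, list[str]]
    seed: int

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _feature_names(n: int) -> list[str]:
    return [f"feature_{i:03d}" for i in range(n)]


def _draw(rng: np.random.Generator, n: int, mean: np.ndarray, rho: float) -> np.ndarray:
    p = mean.size
    eps = rng.standard_normal((n, p))
    if rho > 0:
        g = rng.standard_normal((n, 1))
        eps = np.sqrt(rho) * g + np.sqrt(1.0 - rho) * eps
    return eps + mean


def _wells(n_cells: int, n_wells: int) -> np.ndarray:
    # contiguous blocks so each well is itself an i.i.d. sample
    return np.array([f"w{1 + (i * n_wells) // n_cells:02d}" for i in range(n_cells)])


def generate_screen(config: ScreenConfig) -> tuple[ProfileTable, ScreenTruth]:
    """Generate a single-plate screen with planted efficacy structure.

    The reference population has mean 0; the target population is identical
    except the planted on-subset (the first ``n_on_features`` features) is
    shifted by ``effect_size`` SD.  Each treatment t is assigned an efficacy
    lambda from ``efficacy_grid`` (cycled over ``n_treatments``) and its
    cells are drawn around the interpolated mean
    ``(1 - lambda) * ref + lambda * target`` — values outside [0, 1]
    extrapolate past either state.  Planted off-target effects add
    ``off_shift_magnitude`` to a random off-feature subset per treatment.

    Returns the table plus a :class:`ScreenTruth` recording the planted
    on-subset, each treatment's lambda, and each off-shifted subset.
    """
    rng = np.random.default_rng(config.seed)
    names = _feature_names(config.n_features)
    on_idx = np.arange(config.n_on_features)
    mu_target = np.zeros(config.n_features)
    mu_target[on_idx] = config.effect_size

    n_trt = config.n_treatments if config.n_treatments is not None else len(config.efficacy_grid)
    lambdas = [config.efficacy_grid[i % len(config.efficacy_grid)] for i in range(n_trt)]

    blocks, meta_rows = [], []
    truth_eff: dict[str, float] = {}
    truth_off: dict[str, list[str]] = {}

    def add_group(name: str, mean: np.ndarray, phenotype: str, gene: str):
        X = _draw(rng, config.n_cells_per_group, mean, config.correlation)
        blocks.append(X)
        meta_rows.append(
            pd.DataFrame(
                {
                    "Metadata_treatment": name,
                    "Metadata_well": _wells(config.n_cells_per_group, config.n_wells),
                    "Metadata_plate": "plate_01",
                    "Metadata_phenotype": phenotype,
                    "Metadata_gene": gene,
                }
            )
        )

    add_group("reference", np.zeros(config.n_features), "reference_state", "none")
    add_group("target", mu_target, "target_state", "none")
    off_pool = np.arange(config.n_on_features, config.n_features)
    for t, lam in enumerate(lambdas):
        name = f"trt_{t + 1:02d}"
        mean = lam * mu_target
        shifted: list[str] = []
        if config.n_off_shift_features > 0:
            chosen = rng.choice(off_pool, size=config.n_off_shift_features, replace=False)
            mean = mean.copy()
            mean[chosen] += config.off_shift_magnitude
            shifted = [names[i] for i in sorted(chosen)]
        truth_eff[name] = float(lam)
        truth_off[name] = shifted
        add_group(name, mean, "perturbed", name)

    features = pd.DataFrame(np.vstack(blocks), columns=names)
    meta = pd.concat(meta_rows, ignore_index=True)
    table = ProfileTable(pd.concat([meta, features], axis=1))
    truth = ScreenTruth(
        on_features=[names[i] for i in on_idx],
        efficacies=truth_eff,
        off_shifted=truth_off,
        seed=config.seed,
    )
    return table, truth


def make_multiplate(config: ScreenConfig, plate_effect_sd: float = 0.0) -> tuple[ProfileTable, ScreenTruth]:
    """Generate a multi-plate replicate screen.

    Each treatment has one effect vector shared across all plates: a random
    subset of ``n_on_features`` features shifted by ``effect_size`` with
    random signs.  Every plate also receives an additive plate-level offset
    drawn with scale ``plate_effect_sd`` and applied to all its cells —
    the batch effect that cross-plate replicate analysis must tolerate.
    Control cells (treatment ``"control"``, mean equal to the plate offset)
    are present on every plate.  Each (plate, treatment, well) cell block
    has ``n_cells_per_group`` cells.
    """
    if config.n_plates < 2:
        raise ValueError("multi-plate layout needs n_plates >= 2")
    if plate_effect_sd < 0:
        raise ValueError("plate_effect_sd must be nonnegative")
    rng = np.random.default_rng(config.seed)
    names = _feature_names(config.n_features)
    n_trt = config.n_treatments if config.n_treatments is not None else len(config.efficacy_grid)

    effects: dict[str, np.ndarray] = {}
    for t in range(n_trt):
        vec = np.zeros(config.n_features)
        idx = rng.choice(config.n_features, size=config.n_on_features, replace=False)
        vec[idx] = config.effect_size * rng.choice([-1.0, 1.0], size=config.n_on_features)
        effects[f"trt_{t + 1:02d}"] = vec
    effects["control"] = np.zeros(config.n_features)

    plate_offsets = rng.normal(0.0, plate_effect_sd, size=(config.n_plates, config.n_features))

    blocks, meta_rows = [], []
    for p in range(config.n_plates):
        plate = f"plate_{p + 1:02d}"
        for trt in sorted(effects):
            mean = effects[trt] + plate_offsets[p]
            for w in range(config.n_wells):
                X = _draw(rng, config.n_cells_per_group, mean, config.correlation)
                blocks.append(X)
                meta_rows.append(
                    pd.DataFrame(
                        {
                            "Metadata_treatment": trt,
                            "Metadata_well": f"w{w + 1:02d}",
                            "Metadata_plate": plate,
                            "Metadata_phenotype": "control" if trt == "control" else "perturbed",
                            "Metadata_gene": "none" if trt == "control" else trt,
                        },
                        index=range(config.n_cells_per_group),
                    )
                )
    features = pd.DataFrame(np.vstack(blocks), columns=names)
    meta = pd.concat(meta_rows, ignore_index=True)
    table = ProfileTable(pd.concat([meta, features], axis=1))
    truth = ScreenTruth(
        on_features=[],
        efficacies={t: 1.0 for t in effects if t != "control"},
        off_shifted={t: [names[i] for i in np.flatnonzero(effects[t])] for t in effects if t != "control"},
        seed=config.seed,
    )
    return table, truth


def generate_logo_dataset(
    n_genes: int = 6,
    n_phenotypes: int = 2,
    n_features: int = 20,
    n_shifted_per_phenotype: int = 5,
    effect_size: float = 3.0,
    cells_per_gene: int = 200,
    reference_cells: int = 500,
    proportions: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[ProfileTable, pd.DataFrame]:
    """Generate a labeled-phenotype screen for leave-one-gene-out evaluation.

    Emulates a genome-scale knockdown screen with per-cell phenotype
    annotations: a reference population of unperturbed ("interphase") cells
    at mean 0, and per-gene perturbation groups whose cells are a mixture —
    a gene-specific proportion of cells drawn from a phenotype-shifted
    distribution (and labeled with that phenotype), the remainder drawn from
    the reference distribution (labeled interphase).  Each phenotype shifts
    its own disjoint feature subset by ``effect_size`` SD, so genes with a
    higher labeled proportion sit distributionally closer to the phenotype
    target — the planted monotone structure the evaluation must recover.

    ``proportions`` is an (n_genes, n_phenotypes) matrix of labeled-cell
    fractions (row sums at most 1; the remainder of each gene's cells stay
    interphase-like).  The default grades genes evenly so each gene's total
    labeled fraction runs from 0.15 to 0.9, split equally across phenotypes,
    with the same gene order in every phenotype.  Returns the table and the
    proportion matrix as a DataFrame (genes x phenotypes).
    """
    if n_shifted_per_phenotype * n_phenotypes > n_features:
        raise ValueError("phenotype feature subsets must fit disjointly in n_features")
    rng = np.random.default_rng(seed)
    names = _feature_names(n_features)
    genes = [f"gene_{g + 1:02d}" for g in range(n_genes)]
    phenotypes = [f"pheno_{p + 1:02d}" for p in range(n_phenotypes)]
    if proportions is None:
        grades = np.linspace(0.15, 0.9, n_genes) / n_phenotypes
        proportions = np.tile(grades[:, None], (1, n_phenotypes))
    proportions = np.asarray(proportions, dtype=float)
    if proportions.shape != (n_genes, n_phenotypes):
        raise ValueError(f"proportions must have shape ({n_genes}, {n_phenotypes})")
    if np.any(proportions < 0) or np.any(proportions.sum(axis=1) > 1 + 1e-9):
        raise ValueError("proportions must be nonnegative with row sums at most 1")

    pheno_means = {}
    for p, pheno in enumerate(phenotypes):
        mu = np.zeros(n_features)
        mu[p * n_shifted_per_phenotype : (p + 1) * n_shifted_per_phenotype] = effect_size
        pheno_means[pheno] = mu

    blocks, meta_rows = [], []

    X_ref = rng.standard_normal((reference_cells, n_features))
    blocks.append(X_ref)
    meta_rows.append(
        pd.DataFrame(
            {
                "Metadata_treatment": "scramble",
                "Metadata_well": "w01",
                "Metadata_plate": "plate_01",
                "Metadata_phenotype": "interphase",
                "Metadata_gene": "scramble",
            },
            index=range(reference_cells),
        )
    )

    for g, gene in enumerate(genes):
        labels = np.full(cells_per_gene, "interphase", dtype=object)
        X = rng.standard_normal((cells_per_gene, n_features))
        # partition the gene's cells across phenotype components by its proportions
        counts = np.floor(proportions[g] * cells_per_gene).astype(int)
        start = 0
        for p, pheno in enumerate(phenotypes):
            k = counts[p]
            X[start : start + k] += pheno_means[pheno]
            labels[start : start + k] = pheno
            start += k
        perm = rng.permutation(cells_per_gene)
        blocks.append(X[perm])
        meta_rows.append(
            pd.DataFrame(
                {
                    "Metadata_treatment": gene,
                    "Metadata_well": "w01",
                    "Metadata_plate": "plate_01",
                    "Metadata_phenotype": labels[perm],
                    "Metadata_gene": gene,
                }
            )
        )

    features = pd.DataFrame(np.vstack(blocks), columns=names)
    meta = pd.concat(meta_rows, ignore_index=True)
    table = ProfileTable(pd.concat([meta, features], axis=1))
    prop_df = pd.DataFrame(proportions, index=genes, columns=phenotypes)
    return table, prop_df
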