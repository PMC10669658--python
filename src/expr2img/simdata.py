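"""Synthetic multi-dataset expression cohorts with planted class signal.

The generator emulates the structure of a multi-cohort case/control
transcriptomics study: several datasets measured on a shared probe set, a
subset of informative genes whose class-conditional means are separated, and
per-dataset affine batch effects (a multiplicative scale followed by an
additive offset applied to the whole dataset) that the per-dataset
standardization step downstream must remove.

Signal model
------------
Every gene is Gaussian with per-gene noise standard deviation ``noise_sd``.
Background genes have mean 0 in every class.  Each informative gene is
"designated" to one of the two extreme diagnosis classes (alternating AD,
NC, AD, NC, ...): the designated class's mean is shifted by ``effect_size``
latent units, the other extreme class stays at 0, and MCI — the intermediate
clinical stage — sits midway at ``effect_size / 2`` on every informative
gene, so pairwise tasks have graded difficulty (AD vs NC easiest).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import VALID_CLASSES, ExpressionMatrix
from .errors import ConfigError


@dataclass(frozen=True)
class SimConfig:
    """Conditions for one simulated cohort.

    Defaults give three datasets of 50 samples per class — a 2-class cohort
    of 300 samples (150 per class) — with 1000 genes of which 60 carry a
    1-latent-unit class shift at unit noise, and mild per-dataset batch
    distortion.
    """

    n_datasets: int = 3
    samples_per_class_per_dataset: int = 50
    n_genes: int = 1000
    n_informative: int = 60
    effect_size: float = 1.0
    noise_sd: float = 1.0
    batch_scale_range: tuple[float, float] = (0.8, 1.2)
    batch_offset_range: tuple[float, float] = (-0.5, 0.5)
    classes: tuple[str, ...] = ("AD", "NC")
    seed: int = 0

    def validate(self) -> None:
        if self.n_datasets < 1 or self.samples_per_class_per_dataset < 1:
            raise ConfigError("dataset and per-class sample counts must be >= 1")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ConfigError("need 0 <= n_informative <= n_genes")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        for lo, hi in (self.batch_scale_range, self.batch_offset_range):
            if lo > hi:
                raise ConfigError("batch ranges must satisfy lo <= hi")
        if len(self.classes) == 0:
            raise ConfigError("class set must be nonempty")
        if len(set(self.classes)) != len(self.classes):
            raise ConfigError("duplicate class labels")
        for c in self.classes:
            if c not in VALID_CLASSES:
                raise ConfigError(f"unknown class {c!r}; allowed: {VALID_CLASSES}")


def informative_structure(config: SimConfig) -> tuple[np.ndarray, list[str]]:
    """Ground truth of the planted signal.

    Returns the informative gene indices (the first ``n_informative`` genes)
    and the designated extreme class of each, alternating AD / NC.
    """
    idx = np.arange(config.n_informative)
    designated = ["AD" if i % 2 == 0 else "NC" for i in idx]
    return idx, designated


def _class_means(config: SimConfig) -> np.ndarray:
    """(n_genes, n_classes) latent class means before batch distortion."""
    mu = np.zeros((config.n_genes, len(config.classes)))
    idx, designated = informative_structure(config)
    for g, dcls in zip(idx, designated):
        for j, c in enumerate(config.classes):
            if c == "MCI":
                mu[g, j] = config.effect_size / 2.0
            elif c == dcls:
                mu[g, j] = config.effect_size
    return mu


def simulate_cohort(config: SimConfig) -> list[ExpressionMatrix]:
    """Draw one cohort: one labeled ExpressionMatrix per simulated dataset.

    Identical configs (including seed) reproduce identical matrices.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mu = _class_means(config)
    n_per = config.samples_per_class_per_dataset
    matrices: list[ExpressionMatrix] = []
    probe_ids = [f"G{i:06d}" for i in range(config.n_genes)]
    for d in range(config.n_datasets):
        dataset_id = f"SIM{d}"
        labels: list[str] = []
        blocks: list[np.ndarray] = []
        for j, c in enumerate(config.classes):
            noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_per))
            blocks.append(mu[:, [j]] + noise)
            labels.extend([c] * n_per)
        values = np.concatenate(blocks, axis=1)
        scale = rng.uniform(*config.batch_scale_range)
        offset = rng.uniform(*config.batch_offset_range)
        values = scale * values + offset
        sample_ids = [f"{dataset_id}_S{i:04d}" for i in range(values.shape[1])]
        matrices.append(
            ExpressionMatrix(
                values=values,
                probe_ids=probe_ids,
                sample_ids=sample_ids,
                labels=labels,
                dataset_ids=[dataset_id] * len(sample_ids),
            )
        )
    return matrices


def write_cohort(matrices: list[ExpressionMatrix], outdir: str | Path) -> list[tuple[Path, Path]]:
    """Write each dataset as TSV + labels CSV; returns the path pairs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in matrices:
        stem = m.dataset_id or "dataset"
        tsv = outdir / f"{stem}.tsv"
        csv = outdir / f"{stem}_labels.csv"
        m.write_tsv(tsv, csv)
        paths.append((tsv, csv))
    return paths
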