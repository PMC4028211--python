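"""Microarray-like synthetic data with known ground truth.

The generator plants three gene populations: informative genes whose mean is
shifted in one class, redundant genes that are noisy copies of an informative
source (emulating co-regulated probes that cluster together), and pure-noise
genes. This is the structure the clustering/filtering stages exploit, so every
downstream stage can be tested against a known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core_data import ExpressionDataset


@dataclass
class SyntheticSpec:
    """Generator configuration.

    effect_size is the class-mean shift of an informative gene in units of the
    baseline noise standard deviation. Each informative gene is "up" in one
    class, assigned round-robin, and flat elsewhere. Per-class sample counts
    may be unbalanced, mirroring real cohorts.
    """

    n_samples_per_class: tuple[int, ...] = (30, 30)
    n_informative: int = 5
    redundancy: int = 5  # noisy copies per informative gene
    copy_noise_sd: float = 0.3
    n_noise: int = 250
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples_per_class) < 2:
            raise ValueError("each class needs >=2 samples")
        if self.n_informative < 0 or self.redundancy < 0 or self.n_noise < 0:
            raise ValueError("counts must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")


@dataclass
class GroundTruth:
    """Which planted population each gene belongs to."""

    informative: list[str]
    redundant_source: dict[str, str]  # redundant gene id -> informative source id
    noise: list[str]

    def group_members(self, informative_id: str) -> list[str]:
        """An informative gene together with all its redundant copies."""
        copies = [g for g, src in self.redundant_source.items() if src == informative_id]
        return [informative_id] + copies

    def to_json(self) -> str:
        return json.dumps(
            {
                "informative": self.informative,
                "redundant_source": self.redundant_source,
                "noise": self.noise,
            },
            indent=2,
        )


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one dataset; bit-identical for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    n_classes = len(spec.n_samples_per_class)
    y = np.concatenate([np.full(n, k) for k, n in enumerate(spec.n_samples_per_class)])
    n_samples = y.size

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    informative_ids: list[str] = []
    redundant_source: dict[str, str] = {}
    noise_ids: list[str] = []

    shift = spec.effect_size * spec.noise_sd
    for i in range(spec.n_informative):
        up_class = i % n_classes  # round-robin assignment of the "up" class
        base = rng.normal(0.0, spec.noise_sd, n_samples) + shift * (y == up_class)
        gid = f"INF{i}"
        gene_ids.append(gid)
        rows.append(base)
        informative_ids.append(gid)
        for j in range(spec.redundancy):
            rid = f"RED{i}_{j}"
            gene_ids.append(rid)
            rows.append(base + rng.normal(0.0, spec.copy_noise_sd, n_samples))
            redundant_source[rid] = gid
    for i in range(spec.n_noise):
        gid = f"NOISE{i}"
        gene_ids.append(gid)
        rows.append(rng.normal(0.0, spec.noise_sd, n_samples))
        noise_ids.append(gid)

    sample_ids = [f"S{j}" for j in range(n_samples)]
    ds = ExpressionDataset(
        gene_ids,
        sample_ids,
        np.vstack(rows) if rows else np.empty((0, n_samples)),
        y,
        [f"class{k}" for k in range(n_classes)],
    )
    return ds, GroundTruth(informative_ids, redundant_source, noise_ids)
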