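"""Negative-binomial count simulation with known DE ground truth.

Counts are drawn gene-by-sample from a negative binomial with mean
``depth * lambda_g * fc`` (the fold change applied only in the gene's
up-regulated group) and variance ``mu + dispersion * mu**2``. Baseline means
``lambda_g`` are log-normal. DE membership is deterministic -- the first
``floor(g * pdeg)`` genes -- so truth counts are exact; per-group
up-allocation follows largest-remainder rounding of the ``p_up`` proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from atmm.core import CountMatrix

__all__ = ["SimConfig", "SimulatedDataset", "simulate_counts", "truth_vector"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    ``groups`` lists replicate counts per group (e.g. ``(3, 3)``); ``p_up``
    gives, per group, the proportion of DE genes up-regulated in that group
    and must sum to 1. ``mean_log_mean``/``mean_log_sd`` parameterize the
    log-normal baseline means on the natural-log scale.
    """

    n_genes: int = 10_000
    groups: tuple[int, ...] = (3, 3)
    pdeg: float = 0.25
    p_up: tuple[float, ...] = (0.9, 0.1)
    fc: float = 4.0
    mean_log_mean: float = 4.0
    mean_log_sd: float = 1.0
    dispersion: float = 0.1
    depth_factors: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.groups) < 1 or any(r < 1 for r in self.groups):
            raise ValueError("each group needs at least one replicate")
        if not (0.0 <= self.pdeg < 1.0):
            raise ValueError(f"pdeg must be in [0, 1), got {self.pdeg}")
        if len(self.p_up) != len(self.groups):
            raise ValueError(
                f"p_up has {len(self.p_up)} entries for {len(self.groups)} groups"
            )
        if abs(sum(self.p_up) - 1.0) > 1e-12:
            raise ValueError(f"p_up must sum to 1, got {sum(self.p_up)}")
        if any(p < 0 for p in self.p_up):
            raise ValueError("p_up entries must be non-negative")
        if self.fc < 1.0:
            raise ValueError(f"fc must be >= 1, got {self.fc}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.mean_log_sd < 0:
            raise ValueError("mean_log_sd must be non-negative")
        if self.depth_factors is not None:
            if len(self.depth_factors) != sum(self.groups):
                raise ValueError(
                    f"depth_factors has {len(self.depth_factors)} entries for "
                    f"{sum(self.groups)} samples"
                )
            if any(d <= 0 for d in self.depth_factors):
                raise ValueError("depth_factors must be positive")

    @property
    def n_samples(self) -> int:
        return sum(self.groups)


@dataclass(frozen=True)
class SimulatedDataset:
    """Simulated counts plus ground truth.

    ``up_group[g]`` is the group index receiving the fold change for DE gene
    ``g`` and -1 for non-DE genes.
    """

    counts: CountMatrix
    group_of_sample: np.ndarray
    is_de: np.ndarray
    up_group: np.ndarray


def largest_remainder(total: int, proportions) -> np.ndarray:
    """Integer allocation of ``total`` across categories by largest remainder.

    Floors the real targets ``total * proportions`` and hands the remaining
    units to the categories with the largest fractional parts (ties broken
    toward the lower index). The result sums to ``total`` exactly.
    """
    props = np.asarray(proportions, dtype=np.float64)
    targets = props * total
    base = np.floor(targets).astype(np.int64)
    remainder = total - int(base.sum())
    if remainder > 0:
        frac = targets - base
        order = np.argsort(-frac, kind="stable")
        base[order[:remainder]] += 1
    return base


def simulate_counts(config: SimConfig) -> SimulatedDataset:
    """Draw a reproducible NB count matrix per the configuration."""
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    n_groups = len(config.groups)
    n_samples = config.n_samples

    lam = rng.lognormal(config.mean_log_mean, config.mean_log_sd, size=g)

    n_de = int(np.floor(g * config.pdeg))
    is_de = np.zeros(g, dtype=bool)
    is_de[:n_de] = True
    up_group = np.full(g, -1, dtype=np.int64)
    alloc = largest_remainder(n_de, config.p_up)
    up_group[:n_de] = np.repeat(np.arange(n_groups), alloc)

    group_of_sample = np.repeat(np.arange(n_groups), config.groups)
    depth = (np.ones(n_samples) if config.depth_factors is None
             else np.asarray(config.depth_factors, dtype=np.float64))

    phi = config.dispersion
    size = 1.0 / phi  # NB shape parameter: variance mu + phi * mu^2
    counts = np.empty((g, n_samples), dtype=np.int64)
    for s in range(n_samples):
        mu = depth[s] * lam * np.where(up_group == group_of_sample[s], config.fc, 1.0)
        p = size / (size + mu)
        counts[:, s] = rng.negative_binomial(size, p)

    gene_ids = [f"gene_{i + 1}" for i in range(g)]
    sample_ids = [
        f"grp{group_of_sample[s] + 1}_rep{s - int(np.sum(config.groups[:group_of_sample[s]])) + 1}"
        for s in range(n_samples)
    ]
    cm = CountMatrix(counts, gene_ids, sample_ids)
    return SimulatedDataset(
        counts=cm,
        group_of_sample=group_of_sample,
        is_de=is_de,
        up_group=up_group,
    )


def truth_vector(dataset: SimulatedDataset) -> np.ndarray:
    """Binary DE labels in gene order (1 = truly differentially expressed)."""
    return dataset.is_de.astype(np.int64)
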