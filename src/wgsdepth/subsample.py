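"""Seeded fractional subsampling and the replicate plan/aggregation policy.

Datasets below the replicate threshold (default 45x) are simulated ten
times with distinct derived seeds and analysis metrics are averaged over
the replicates; at or above the threshold a single dataset is used.
Subsampling follows samtools ``view -s`` semantics: independent Bernoulli
retention per item, order preserved.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TypeVar

import numpy as np

from .config import SimulationConfig

__all__ = [
    "ReplicatePlan",
    "plan_replicates",
    "subsample_fraction",
    "aggregate_replicates",
    "replicate_dispersion",
]

T = TypeVar("T")


@dataclass(frozen=True)
class ReplicatePlan:
    """How many seeded datasets to simulate at one target depth."""

    target_depth: float
    n_replicates: int
    seeds: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seeds) != self.n_replicates:
            raise ValueError("seed count must equal n_replicates")


def plan_replicates(
    target_depth: float,
    config: SimulationConfig,
    depth_index: int | None = None,
) -> ReplicatePlan:
    """Replicate plan for one depth: ``n_replicates`` seeded datasets
    strictly below the threshold, one at or above it.

    ``depth_index`` defaults to the depth's position in the configured
    schedule (0 if absent) and feeds the derived per-dataset seeds.
    """
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    if depth_index is None:
        try:
            depth_index = config.depth_schedule.index(target_depth)
        except ValueError:
            depth_index = 0
    n = config.n_replicates if target_depth < config.replicate_threshold else 1
    seeds = tuple(config.dataset_seed(depth_index, r) for r in range(n))
    return ReplicatePlan(target_depth=target_depth, n_replicates=n, seeds=seeds)


def subsample_fraction(items: Sequence[T], fraction: float, seed: int) -> list[T]:
    """Retain each item independently with probability ``fraction``.

    Input order is preserved and the draw is deterministic for a fixed
    seed (Bernoulli thinning, not exact-count sampling).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random(len(items)) < fraction
    return [item for item, keep in zip(items, mask) if keep]


def aggregate_replicates(values: Sequence[float]) -> float:
    """Unweighted mean over replicate metric values (single values pass
    through)."""
    if len(values) == 0:
        raise ValueError("no replicate values to aggregate")
    return float(np.mean(values))


def replicate_dispersion(values: Sequence[float]) -> tuple[float, float]:
    """(mean, sample SD) across replicates; SD is 0 for a single value."""
    mean = aggregate_replicates(values)
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return mean, sd
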