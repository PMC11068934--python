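"""Permutation null for the overlap between two networks' key-driver sets.

To ask whether two independently constructed networks (e.g. the same
sex/depot group in two cohorts) agree on more key drivers than chance, a
random set of genes of the same size as each network's key-driver list is
drawn from each network's gene universe, and the intersection size is
recorded; repeating this (default 10,000 times) forms the null
distribution.  The empirical p-value uses the add-one rule
``(1 + #{null >= observed}) / (1 + replicates)`` so it is never exactly
zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import GeneSet

__all__ = ["OverlapTest", "overlap_null"]


@dataclass(frozen=True)
class OverlapTest:
    """Observed overlap, its permutation null, and the empirical p-value."""

    observed_overlap: int
    null_distribution: np.ndarray
    empirical_p: float
    universe_sizes: tuple[int, int]
    draw_sizes: tuple[int, int]
    seed: int

    @property
    def null_mean(self) -> float:
        return float(self.null_distribution.mean())

    def histogram(self) -> dict[int, int]:
        """Integer counts of the null distribution (plot-ready)."""
        values, counts = np.unique(self.null_distribution, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}


def overlap_null(
    universe_a: GeneSet | frozenset[str],
    universe_b: GeneSet | frozenset[str],
    n_a: int,
    n_b: int,
    observed: int,
    replicates: int = 10_000,
    seed: int = 0,
) -> OverlapTest:
    """Permutation test for the shared-gene count between two sampled sets.

    Per replicate, ``n_a`` genes are drawn without replacement from
    ``universe_a`` and ``n_b`` from ``universe_b`` (independent draws), and
    the intersection size recorded.  Deterministic under ``seed``.
    """
    members_a = np.array(
        sorted(universe_a.members if isinstance(universe_a, GeneSet) else universe_a)
    )
    members_b = np.array(
        sorted(universe_b.members if isinstance(universe_b, GeneSet) else universe_b)
    )
    if n_a > members_a.size:
        raise ValueError(f"draw size {n_a} exceeds universe of {members_a.size}")
    if n_b > members_b.size:
        raise ValueError(f"draw size {n_b} exceeds universe of {members_b.size}")
    if observed < 0:
        raise ValueError("observed overlap must be non-negative")
    rng = np.random.default_rng(seed)
    null = np.empty(replicates, dtype=np.int64)
    shared = np.intersect1d(members_a, members_b)
    shared_set = set(shared.tolist())
    for i in range(replicates):
        draw_a = rng.choice(members_a, size=n_a, replace=False)
        draw_b = rng.choice(members_b, size=n_b, replace=False)
        if shared_set:
            null[i] = len(
                (set(draw_a.tolist()) & shared_set) & set(draw_b.tolist())
            )
        else:
            null[i] = 0
    p = (1 + int((null >= observed).sum())) / (1 + replicates)
    return OverlapTest(
        observed_overlap=observed,
        null_distribution=null,
        empirical_p=p,
        universe_sizes=(members_a.size, members_b.size),
        draw_sizes=(n_a, n_b),
        seed=seed,
    )
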