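"""Permutation enrichment of interacting fragments over ChIP-seq peaks.

The null model resamples fragments from the universe of candidate
fragments (e.g. all restriction fragments in the region of interest)
rather than shuffling peak positions: Capture-C signal lives on a fixed
fragment grid, and resampling within it preserves that structure.  With
per-fragment overlap reduced to a binary flag, this null is exactly the
hypergeometric distribution, which serves as a closed-form cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import GenomicInterval, ValidationError
from .permutation import PermutationResult


@dataclass
class OverlapUniverse:
    """The candidate fragments a query set is drawn from."""

    fragments: list[GenomicInterval]

    def __post_init__(self):
        if not self.fragments:
            raise ValidationError("overlap universe is empty")
        self.fragments = sorted(set(self.fragments))

    def __len__(self) -> int:
        return len(self.fragments)


def _merge(peaks: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    """Per-chromosome merged peak boundaries as (starts, ends) arrays."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in sorted(peaks):
        spans = by_chrom.setdefault(p.chrom, [])
        if spans and p.start <= spans[-1][1]:
            spans[-1] = (spans[-1][0], max(spans[-1][1], p.end))
        else:
            spans.append((p.start, p.end))
    return {
        c: (np.array([s for s, _ in v]), np.array([e for _, e in v]))
        for c, v in by_chrom.items()
    }


def overlap_flags(
    fragments: Sequence[GenomicInterval], peaks: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean flag per fragment: intersects >=1 peak by >=1 bp (half-open)."""
    merged = _merge(peaks)
    flags = np.zeros(len(fragments), dtype=bool)
    for i, f in enumerate(fragments):
        if f.chrom not in merged:
            continue
        starts, ends = merged[f.chrom]
        j = np.searchsorted(starts, f.end)  # peaks with start < f.end
        flags[i] = j > 0 and ends[j - 1] > f.start
    return flags


def overlap_count(
    query: Iterable[GenomicInterval], peaks: Sequence[GenomicInterval]
) -> int:
    """Number of query intervals overlapping at least one peak."""
    q = sorted(set(query))
    return int(overlap_flags(q, peaks).sum())


def overlap_permutation_test(
    query: Iterable[GenomicInterval],
    peaks: Sequence[GenomicInterval],
    universe: OverlapUniverse,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermutationResult:
    """Is the query's peak overlap larger than random fragment draws?

    Each permutation draws ``|query|`` fragments uniformly without
    replacement from the universe and recounts overlapping fragments;
    p is the fraction of draws with a count >= the observed one (ties
    count as exceedances).
    """
    if n_perm < 1:
        raise ValidationError(f"n_perm must be >= 1, got {n_perm}")
    if seed is None:
        raise ValidationError("a seed is required for reproducibility")
    q = sorted(set(query))
    missing = [f for f in q if f not in set(universe.fragments)]
    if missing:
        raise ValidationError(
            f"{len(missing)} query fragment(s) absent from the universe, "
            f"e.g. {missing[0]}"
        )
    k = len(q)
    if k > len(universe):
        raise ValidationError("query larger than universe")
    flags = overlap_flags(universe.fragments, peaks)
    observed = overlap_count(q, peaks)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n_univ = len(universe)
    for i in range(n_perm):
        draw = rng.choice(n_univ, size=k, replace=False)
        null[i] = flags[draw].sum()
    exceedances = int(np.sum(null >= observed))
    return PermutationResult(
        observed=float(observed),
        null_values=null,
        exceedances=exceedances,
        p_value=exceedances / n_perm,
        n_perm=n_perm,
        seed=seed,
    )
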