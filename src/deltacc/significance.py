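"""Replicate q-value merging, replicated-interaction selection, curation
of locally most-significant fragments, and shared/specific set algebra.

Per-fragment p/q values are produced upstream by a distance-normalising
interaction caller and consumed here; this module never computes them
from counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .core import GenomicInterval, SignificanceTable, ValidationError

DEFAULT_Q_REPLICATION = 0.1
DEFAULT_Q_CURATION = 0.05


def merge_q(q_values: Sequence[float] | float, *more: float) -> float:
    """Geometric-mean merge of replicate q values.

    For two replicates this is ``sqrt(q1 * q2)`` — equivalently the mean
    of ``-log10 q`` on the log scale; for n replicates it generalises to
    ``(prod q)**(1/n)``.
    """
    qs = np.atleast_1d(
        np.asarray([q_values, *more] if more else q_values, dtype=float)
    )
    if qs.size < 1:
        raise ValidationError("merge_q needs at least one q value")
    if np.any((qs < 0) | (qs > 1)) or not np.all(np.isfinite(qs)):
        raise ValidationError(f"q values must lie in [0,1], got {qs.tolist()}")
    return float(np.prod(qs) ** (1.0 / qs.size))


def add_merged_q(table: SignificanceTable) -> SignificanceTable:
    """Return a copy of the table with a ``merged_q`` column appended."""
    q = table.q_matrix()
    data = table.data.copy()
    data["merged_q"] = np.prod(q, axis=1) ** (1.0 / q.shape[1])
    return SignificanceTable(
        data=data,
        q_threshold_replication=table.q_threshold_replication,
        q_threshold_curation=table.q_threshold_curation,
    )


@dataclass
class InteractionSets:
    """Labelled sets of interacting fragments (labels = cell types or viewpoints)."""

    sets: dict[str, set[GenomicInterval]] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return list(self.sets)

    @property
    def union(self) -> set[GenomicInterval]:
        out: set[GenomicInterval] = set()
        for s in self.sets.values():
            out |= s
        return out

    def __getitem__(self, label: str) -> set[GenomicInterval]:
        return self.sets[label]


def replicated_significant(
    tracks: Mapping[str, SignificanceTable],
    q_threshold: float = DEFAULT_Q_REPLICATION,
) -> InteractionSets:
    """Fragments significant in *both* (all) replicates of each cell type.

    ``tracks`` maps cell type -> per-replicate significance table; a
    fragment enters a cell type's set iff q < threshold in every
    replicate of that cell type.  The union over cell types is the
    global replicated set.
    """
    if not 0 < q_threshold < 1:
        raise ValidationError(f"q threshold {q_threshold} outside (0,1)")
    out: dict[str, set[GenomicInterval]] = {}
    for cell_type, table in tracks.items():
        if len(table.replicates) < 2:
            raise ValidationError(
                f"cell type {cell_type!r} has {len(table.replicates)} replicate(s); "
                "replication requires at least 2"
            )
        q = table.q_matrix()
        passing = np.all(q < q_threshold, axis=1)
        frags = table.fragments
        out[cell_type] = {frags[i] for i in np.nonzero(passing)[0]}
    return InteractionSets(sets=out)


def curate_local_peaks(
    table: SignificanceTable,
    window: int = 2,
    q_threshold: float | None = None,
) -> list[GenomicInterval]:
    """Fragments with the highest local merged significance.

    A fragment is curated when its ``-log10 merged_q`` (a) exceeds the
    curation threshold and (b) beats every neighbour within ``window``
    fragments on each side — strictly, with coordinate-order ties
    resolved toward the leftmost fragment.  Consequently no two curated
    fragments lie within ``window`` of each other.
    """
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    if "merged_q" not in table.data.columns:
        raise ValidationError("table lacks merged_q; call add_merged_q first")
    thr = q_threshold if q_threshold is not None else table.q_threshold_curation
    if not 0 < thr < 1:
        raise ValidationError(f"q threshold {thr} outside (0,1)")
    merged = table.data["merged_q"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        score = -np.log10(merged)
    cutoff = -np.log10(thr)
    frags = table.fragments
    curated = []
    n = len(score)
    for i in range(n):
        if not score[i] > cutoff:
            continue
        ok = True
        for j in range(max(0, i - window), min(n, i + window + 1)):
            if j == i:
                continue
            if score[j] > score[i] or (score[j] == score[i] and j < i):
                ok = False
                break
        if ok:
            curated.append(frags[i])
    return curated


def classify_sets(sets: InteractionSets) -> dict[frozenset, int]:
    """Counts for every region of the Venn partition of the labelled sets.

    Keys are frozensets of labels; the value is the number of fragments
    found in exactly those sets.  Counts over all keys sum to the size
    of the union.
    """
    if len(sets.sets) < 2:
        raise ValidationError("set classification needs at least 2 labelled sets")
    labels = sets.labels
    partition: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            partition[frozenset(combo)] = 0
    for frag in sets.union:
        membership = frozenset(l for l in labels if frag in sets.sets[l])
        partition[membership] += 1
    return partition
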