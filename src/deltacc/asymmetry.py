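"""Near-viewpoint asymmetry test with distance-preserving permutations.

Raw viewpoint-anchored counts close to the viewpoint are dominated by
genomic distance, so arbitrary shuffling is not a valid null there.
Swapping a fine bin with its mirror image at the same distance on the
opposite flank, however, preserves the distance-decay structure exactly.
Under the null hypothesis that remodelling flanking the viewpoint is
symmetric, each mirror-pair difference x_i = up_i - down_i is symmetric
about zero, so the statistic T = sum(up) - sum(down) = sum(x_i) can be
referred to the distribution of sum(+/- x_i) over independent sign
flips.  With n pairs there are 2^n such permutations; they are fully
enumerated when n is small and Monte-Carlo sampled otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import BinnedDeltaTrack
from .core import ValidationError, Viewpoint
from .permutation import PermutationResult

#: Number of fine bins per flank entering the test.
DEFAULT_N_PAIRS = 50
#: Largest pair count for which all 2^n sign assignments are enumerated.
DEFAULT_EXACT_THRESHOLD = 20


@dataclass
class MirrorPairs:
    """Fine-bin values at matching distances on either side of the viewpoint.

    ``up[i]`` and ``down[i]`` are the bins whose near edges are ``i+1``
    bins from the viewpoint bin on the upstream (lower-coordinate) and
    downstream flank; the viewpoint's own bin belongs to neither flank.
    """

    up: np.ndarray
    down: np.ndarray

    def __post_init__(self):
        self.up = np.asarray(self.up, dtype=float)
        self.down = np.asarray(self.down, dtype=float)
        if self.up.shape != self.down.shape or self.up.ndim != 1:
            raise ValidationError("up/down flanks must be 1-D and equally long")

    @property
    def n_pairs(self) -> int:
        return len(self.up)

    @property
    def diffs(self) -> np.ndarray:
        return self.up - self.down


def build_mirror_pairs(
    fine: BinnedDeltaTrack, vp: Viewpoint, n_pairs: int = DEFAULT_N_PAIRS
) -> MirrorPairs:
    """Extract ``n_pairs`` mirror pairs of fine bins around the viewpoint bin."""
    if n_pairs < 1:
        raise ValidationError(f"n_pairs must be >= 1, got {n_pairs}")
    if vp.chrom != fine.chrom:
        raise ValidationError("viewpoint and track are on different chromosomes")
    v = fine.viewpoint_bin_index
    if v is None:
        if not fine.origin <= vp.midpoint < fine.origin + len(fine) * fine.bin_size:
            raise ValidationError("viewpoint midpoint outside the track")
        v = (vp.midpoint - fine.origin) // fine.bin_size
    if v - n_pairs < 0 or v + n_pairs >= len(fine):
        raise ValidationError(
            f"track covers bins [0, {len(fine)}) but {n_pairs} pairs around "
            f"bin {v} need [{v - n_pairs}, {v + n_pairs}]"
        )
    offsets = np.arange(1, n_pairs + 1)
    return MirrorPairs(up=fine.values[v - offsets], down=fine.values[v + offsets])


def updown_statistic(pairs: MirrorPairs) -> float:
    """T = sum(upstream flank) - sum(downstream flank)."""
    return float(pairs.up.sum() - pairs.down.sum())


def count_permutations(n_pairs: int) -> int:
    """Number of distance-preserving permutations: exactly 2**n_pairs."""
    if n_pairs < 0:
        raise ValidationError(f"n_pairs must be >= 0, got {n_pairs}")
    return 1 << n_pairs


def _enumerate_sums(diffs: np.ndarray) -> np.ndarray:
    """All 2^n values of sum(+/- x_i), by doubling."""
    sums = np.zeros(1)
    for x in diffs:
        sums = np.concatenate([sums + x, sums - x])
    return sums


def asymmetry_test(
    pairs: MirrorPairs,
    n_perm: int = 10_000,
    seed: int | None = None,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
    alternative: str = "two-sided",
) -> PermutationResult:
    """Sign-flip permutation test of up/down symmetry around the viewpoint.

    Each permutation independently swaps or keeps every mirror pair,
    i.e. flips the sign of each difference x_i.  Two-sided by default:
    p is the fraction of sign assignments with |sum(+/- x_i)| >= |T|
    (ties count).  For ``n_pairs <= exact_threshold`` all 2^n
    assignments are enumerated and p is exact; otherwise ``n_perm``
    assignments are drawn with ``seed``.
    """
    if alternative not in ("two-sided", "greater"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    if pairs.n_pairs < 1:
        raise ValidationError("need at least one mirror pair")
    diffs = pairs.diffs
    observed = float(diffs.sum())

    def extreme(null: np.ndarray) -> np.ndarray:
        if alternative == "two-sided":
            return np.abs(null) >= abs(observed)
        return null >= observed

    if pairs.n_pairs <= exact_threshold:
        null = _enumerate_sums(diffs)
        exceedances = int(extreme(null).sum())
        n_total = len(null)
        return PermutationResult(
            observed=observed,
            null_values=null,
            exceedances=exceedances,
            p_value=exceedances / n_total,
            n_perm=n_total,
            seed=seed,
            exact=True,
        )

    if n_perm < 1:
        raise ValidationError(f"n_perm must be >= 1, got {n_perm}")
    if seed is None:
        raise ValidationError("a seed is required for Monte-Carlo sampling")
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, pairs.n_pairs)) * 2 - 1
    null = signs @ diffs
    exceedances = int(extreme(null).sum())
    return PermutationResult(
        observed=observed,
        null_values=null,
        exceedances=exceedances,
        p_value=exceedances / n_perm,
        n_perm=n_perm,
        seed=seed,
    )
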