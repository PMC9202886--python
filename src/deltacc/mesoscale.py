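"""Meso-scale test: constant-sign runs in a coarse-binned difference track.

A change in chromatin conformation spanning tens of kilobases shows up
in a binned two-condition difference track as a stretch of consecutive
coarse bins that all share the same sign.  The test statistic is the
largest total absolute value over all such maximal constant-sign runs.
Its null distribution is built by uniformly permuting the fine (1 kb)
bins outside a viewpoint exclusion zone, re-binning to the coarse width
and recomputing the statistic: genuine co-localised differences of like
sign are destroyed by the shuffle while the multiset of per-bin values
is preserved.

Near-viewpoint bins are excluded (default +/-50 kb) because their raw
counts are dominated by distance from the viewpoint, and they are frozen
in place rather than removed so coarse-bin geometry is identical in the
observed and permuted computations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .binning import DEFAULT_REBIN_FACTOR, BinnedDeltaTrack, rebin
from .core import ValidationError, Viewpoint
from .permutation import PermutationResult

#: Half-width of the near-viewpoint zone excluded from the statistic (bp).
DEFAULT_EXCLUSION_RADIUS = 50_000


@dataclass(frozen=True)
class SignRun:
    """A maximal run of consecutive same-sign coarse bins.

    Zero-valued bins carry no sign and terminate runs, so every member
    bin is strictly positive (sign=+1) or strictly negative (sign=-1).
    """

    start_bin: int
    end_bin: int  # inclusive
    sign: int
    total_abs: float


def sign_runs(
    track: BinnedDeltaTrack | np.ndarray,
    exclude: Iterable[int] = (),
) -> list[SignRun]:
    """Enumerate maximal constant-sign runs; excluded bins break runs."""
    values = track.values if isinstance(track, BinnedDeltaTrack) else np.asarray(track)
    excluded = set(exclude)
    runs: list[SignRun] = []
    cur_sign, cur_start, cur_total = 0, -1, 0.0
    for i, v in enumerate(values):
        s = 0 if (i in excluded or v == 0) else (1 if v > 0 else -1)
        if s == cur_sign and s != 0:
            cur_total += abs(v)
        else:
            if cur_sign != 0:
                runs.append(SignRun(cur_start, i - 1, cur_sign, cur_total))
            cur_sign, cur_start, cur_total = s, i, abs(v) if s else 0.0
    if cur_sign != 0:
        runs.append(SignRun(cur_start, len(values) - 1, cur_sign, cur_total))
    return runs


def max_run_statistic(
    track: BinnedDeltaTrack | np.ndarray,
    exclude: Iterable[int] = (),
) -> float:
    """Largest run total absolute value; 0.0 when no run exists."""
    runs = sign_runs(track, exclude)
    return max((r.total_abs for r in runs), default=0.0)


def _max_run_array(values: np.ndarray, excluded_mask: np.ndarray) -> float:
    """Fast path of :func:`max_run_statistic` for the permutation loop."""
    best = cur = 0.0
    cur_sign = 0
    for v, ex in zip(values, excluded_mask):
        s = 0 if (ex or v == 0) else (1 if v > 0 else -1)
        if s == cur_sign and s != 0:
            cur += abs(v)
        else:
            if cur > best:
                best = cur
            cur = abs(v) if s else 0.0
            cur_sign = s
    return max(best, cur)


def exclusion_fine_bins(
    fine: BinnedDeltaTrack, vp: Viewpoint, exclusion_radius: int
) -> np.ndarray:
    """Indices of fine bins overlapping ``[midpoint - r, midpoint + r)``."""
    lo = vp.midpoint - exclusion_radius
    hi = vp.midpoint + exclusion_radius
    starts = fine.origin + np.arange(len(fine)) * fine.bin_size
    return np.nonzero((starts < hi) & (starts + fine.bin_size > lo))[0]


def mesoscale_permutation_test(
    fine: BinnedDeltaTrack,
    vp: Viewpoint,
    exclusion_radius: int = DEFAULT_EXCLUSION_RADIUS,
    rebin_factor: int = DEFAULT_REBIN_FACTOR,
    n_perm: int = 1000,
    seed: int | None = None,
    bias_corrected: bool = False,
) -> PermutationResult:
    """Permutation test for the largest constant-sign region.

    Parameters
    ----------
    fine
        Fine-binned (default 1 kb) difference track spanning the region
        of interest around the viewpoint.
    vp
        The viewpoint; fine bins within ``exclusion_radius`` of its
        midpoint are frozen in place and the coarse bins overlapping
        that zone are excluded from the statistic in both the observed
        and every permuted computation.
    n_perm, seed
        Monte-Carlo sample size and mandatory random seed.
    bias_corrected
        Report ``(exceedances + 1) / (n_perm + 1)`` instead of the plain
        ``exceedances / n_perm``.

    Ties count as exceedances: a null draw equal to the observed
    statistic makes the region less surprising.
    """
    if n_perm < 1:
        raise ValidationError(f"n_perm must be >= 1, got {n_perm}")
    if seed is None:
        raise ValidationError("a seed is required for reproducibility")
    if vp.chrom != fine.chrom:
        raise ValidationError("viewpoint and track are on different chromosomes")
    if rebin_factor < 1:
        raise ValidationError(f"rebin factor must be >= 1, got {rebin_factor}")

    excluded_fine = exclusion_fine_bins(fine, vp, exclusion_radius)
    free = np.setdiff1d(np.arange(len(fine)), excluded_fine)
    if len(free) == 0:
        raise ValidationError("exclusion zone covers the entire region of interest")

    n_coarse = -(-len(fine) // rebin_factor)
    excluded_coarse_mask = np.zeros(n_coarse, dtype=bool)
    excluded_coarse_mask[np.unique(excluded_fine // rebin_factor)] = True

    coarse = rebin(fine, rebin_factor)
    observed = _max_run_array(coarse.values, excluded_coarse_mask)

    rng = np.random.default_rng(seed)
    values = fine.values
    free_values = values[free]
    padded = np.zeros(n_coarse * rebin_factor)
    null = np.empty(n_perm)
    for k in range(n_perm):
        permuted = values.copy()
        permuted[free] = free_values[rng.permutation(len(free))]
        padded[: len(values)] = permuted
        coarse_vals = padded.reshape(n_coarse, rebin_factor).sum(axis=1)
        null[k] = _max_run_array(coarse_vals, excluded_coarse_mask)

    exceedances = int(np.sum(null >= observed))
    p = (
        (exceedances + 1) / (n_perm + 1)
        if bias_corrected
        else exceedances / n_perm
    )
    return PermutationResult(
        observed=observed,
        null_values=null,
        exceedances=exceedances,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )


def largest_run(
    fine: BinnedDeltaTrack,
    vp: Viewpoint,
    exclusion_radius: int = DEFAULT_EXCLUSION_RADIUS,
    rebin_factor: int = DEFAULT_REBIN_FACTOR,
) -> SignRun | None:
    """The maximal constant-sign run of the coarse track, with coordinates."""
    excluded_fine = exclusion_fine_bins(fine, vp, exclusion_radius)
    excluded_coarse = set(np.unique(excluded_fine // rebin_factor).tolist())
    coarse = rebin(fine, rebin_factor)
    runs = sign_runs(coarse, excluded_coarse)
    return max(runs, key=lambda r: r.total_abs, default=None)
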