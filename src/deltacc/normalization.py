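"""Median-of-ratios size-factor normalization and condition-difference tracks.

The size-factor estimator is the classic median-of-ratios rule used for
sequencing count matrices: each sample's factor is the median, over
fragments with strictly positive counts in every sample, of the ratio of
that sample's count to the row geometric mean.  Rows containing a zero
are excluded from the median (the geometric mean is undefined there) but
are still rescaled during normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountMatrix, GenomicInterval, ValidationError


@dataclass
class DeltaTrack:
    """Per-fragment difference of mean normalized counts between conditions.

    ``delta[i] > 0`` means fragment ``i`` interacts more in ``condition_pair[0]``;
    negative values mean more interaction in ``condition_pair[1]``.
    """

    fragments: list[GenomicInterval]
    delta: np.ndarray
    condition_pair: tuple[str, str]

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        if len(self.fragments) != len(self.delta):
            raise ValidationError("fragment/delta length mismatch")
        if len(self.delta) and not np.all(np.isfinite(self.delta)):
            raise ValidationError("delta values must be finite")

    def __len__(self) -> int:
        return len(self.fragments)


def size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios size factor per sample.

    Raises if no fragment has strictly positive counts in every sample;
    pre-filter or add a pseudo-row in that case.
    """
    counts = matrix.matrix.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    log_geomeans = log_counts.mean(axis=1)  # -inf for any row with a zero
    finite = np.isfinite(log_geomeans)
    if not finite.any():
        raise ValidationError(
            "no fragment has positive counts in all samples; size factors are "
            "undefined — pre-filter fragments or add a pseudo-row"
        )
    log_ratios = log_counts[finite] - log_geomeans[finite, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=matrix.matrix.columns, name="size_factor")


def normalize(matrix: CountMatrix, factors: pd.Series) -> CountMatrix:
    """Divide each sample column by its size factor; metadata is preserved."""
    missing = [s for s in matrix.sample_ids if s not in factors.index]
    if missing:
        raise ValidationError(f"no size factor for samples: {missing}")
    vals = factors.loc[matrix.sample_ids].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValidationError("size factors must be positive and finite")
    return CountMatrix(
        fragments=matrix.fragments,
        matrix=matrix.matrix / vals,
        samples=matrix.samples.copy(),
    )


def delta_track(matrix: CountMatrix, cond_a: str, cond_b: str) -> DeltaTrack:
    """Mean count in ``cond_a`` replicates minus mean in ``cond_b``, per fragment."""
    conds = set(matrix.samples["condition"])
    for c in (cond_a, cond_b):
        if c not in conds:
            raise ValidationError(
                f"condition {c!r} not among sample conditions {sorted(conds)}"
            )
    a_cols = matrix.samples.index[matrix.samples["condition"] == cond_a]
    b_cols = matrix.samples.index[matrix.samples["condition"] == cond_b]
    mean_a = matrix.matrix[list(a_cols)].mean(axis=1).to_numpy()
    mean_b = matrix.matrix[list(b_cols)].mean(axis=1).to_numpy()
    return DeltaTrack(
        fragments=matrix.fragments,
        delta=mean_a - mean_b,
        condition_pair=(cond_a, cond_b),
    )
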