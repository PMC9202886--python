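"""Shared container for permutation-test results."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidationError


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null sample, and the empirical p.

    ``p_value = exceedances / n_perm`` where ``exceedances`` counts null
    draws at least as extreme as the observed value (ties count as
    exceedances).  When ``exact`` is True the null sample is the complete
    enumeration of the permutation space rather than a Monte-Carlo draw.
    """

    observed: float
    null_values: np.ndarray
    exceedances: int
    p_value: float
    n_perm: int
    seed: int | None
    exact: bool = False

    def __post_init__(self):
        self.null_values = np.asarray(self.null_values, dtype=float)
        if len(self.null_values) != self.n_perm:
            raise ValidationError("null sample length does not equal n_perm")
        if not 0 <= self.exceedances <= self.n_perm:
            raise ValidationError("exceedances outside [0, n_perm]")

    def summary(self) -> dict:
        return {
            "observed": self.observed,
            "exceedances": self.exceedances,
            "n_perm": self.n_perm,
            "p_value": self.p_value,
            "seed": self.seed,
            "exact": self.exact,
        }
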