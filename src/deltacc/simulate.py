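"""Synthetic Capture-C-like data with known ground truth.

The generator emulates what a viewpoint-anchored capture experiment
produces after fragment-level processing: per-restriction-fragment
interaction counts that decay with genomic distance from the viewpoint,
are overdispersed (negative-binomial), differ in sequencing depth
between libraries, and optionally carry injected differential domains
or near-viewpoint asymmetry between conditions.  It also emulates the
per-fragment p/q significance tables an upstream interaction caller
would emit, so replicate merging and curation are testable without any
external data.

Every entry point takes a mandatory seed; identical seeds give
identical output.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CountMatrix,
    FragmentTrack,
    GenomicInterval,
    SignificanceTable,
    ValidationError,
    Viewpoint,
)
from .digestion import DPNII, digest_sequence

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class DecayModel:
    """Expected interaction count as a function of distance from the viewpoint.

    mu(d) = amplitude * (1 + d / half_distance) ** (-exponent)

    ``amplitude`` is the expected count of a fragment touching the
    viewpoint midpoint; ``half_distance`` (bp) sets how fast contacts
    fall off; counts are drawn negative-binomially with the given
    ``dispersion`` (size) parameter, var = mu + mu^2 / dispersion.
    """

    amplitude: float = 1000.0
    half_distance: float = 5000.0
    exponent: float = 1.0
    dispersion: float = 5.0

    def __post_init__(self):
        for name in ("amplitude", "half_distance", "exponent", "dispersion"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def mean_at(self, distance) -> np.ndarray:
        d = np.asarray(distance, dtype=float)
        return self.amplitude * (1.0 + d / self.half_distance) ** (-self.exponent)


@dataclass(frozen=True)
class InjectedEffect:
    """A multiplicative change in expected counts over a region.

    ``fold`` scales the mean of every fragment overlapping ``region``;
    ``flank`` restricts the effect to one side of the viewpoint
    ("upstream" = lower coordinates), which is how near-viewpoint
    asymmetry is injected (one flank's decay amplitude scaled).
    """

    region: GenomicInterval
    fold: float = 1.0
    flank: str = "both"

    def __post_init__(self):
        if self.fold <= 0:
            raise ValidationError("fold must be positive")
        if self.flank not in ("both", "upstream", "downstream"):
            raise ValidationError(f"unknown flank {self.flank!r}")


def fragment_distances(
    fragments: Sequence[GenomicInterval], vp: Viewpoint
) -> np.ndarray:
    """Near-edge distance (bp) of each fragment to the viewpoint midpoint."""
    mid = vp.midpoint
    out = np.empty(len(fragments))
    for i, f in enumerate(fragments):
        if f.start <= mid < f.end:
            out[i] = 0
        elif f.end <= mid:
            out[i] = mid - f.end
        else:
            out[i] = f.start - mid
    return out


def _effect_multiplier(
    fragments: Sequence[GenomicInterval],
    vp: Viewpoint,
    effects: Sequence[InjectedEffect],
) -> np.ndarray:
    mult = np.ones(len(fragments))
    mid = vp.midpoint
    for eff in effects:
        for i, f in enumerate(fragments):
            if not f.overlaps(eff.region):
                continue
            center = (f.start + f.end) / 2
            if eff.flank == "upstream" and center >= mid:
                continue
            if eff.flank == "downstream" and center < mid:
                continue
            mult[i] *= eff.fold
    return mult


def simulate_track(
    fragments: Sequence[GenomicInterval],
    vp: Viewpoint,
    model: DecayModel,
    effects: Sequence[InjectedEffect] = (),
    depth_factor: float = 1.0,
    seed: int | None = None,
    sample_id: str = "",
    condition: str = "",
    replicate: str = "",
) -> FragmentTrack:
    """Draw one sample's per-fragment counts from the decay model."""
    if seed is None:
        raise ValidationError("a seed is required for reproducibility")
    if depth_factor <= 0:
        raise ValidationError("depth_factor must be positive")
    rng = np.random.default_rng(seed)
    mu = (
        depth_factor
        * model.mean_at(fragment_distances(fragments, vp))
        * _effect_multiplier(fragments, vp, effects)
    )
    r = model.dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(float)
    return FragmentTrack(
        fragments=list(fragments),
        counts=counts,
        sample_id=sample_id,
        condition=condition,
        replicate=replicate,
    )


def simulate_experiment(
    fragments: Sequence[GenomicInterval],
    vp: Viewpoint,
    models: Mapping[str, DecayModel],
    effects: Mapping[str, Sequence[InjectedEffect]] | None = None,
    n_replicates: int = 2,
    depth_range: tuple[float, float] = (0.5, 2.0),
    seed: int | None = None,
    sample_seeds: Sequence[int] | None = None,
) -> CountMatrix:
    """Simulate a replicated multi-condition experiment into a CountMatrix.

    One column per condition x replicate; each sample gets its own
    depth factor drawn uniformly from ``depth_range`` (exercising
    size-factor normalization) and its own count seed.  Per-sample
    seeds are derived from ``seed`` unless given explicitly.
    """
    if seed is None and sample_seeds is None:
        raise ValidationError("a seed (or explicit sample_seeds) is required")
    effects = effects or {}
    conditions = list(models)
    if len(conditions) < 2:
        raise ValidationError("need at least 2 conditions for differential work")
    n_samples = len(conditions) * n_replicates
    rng = np.random.default_rng(seed)
    if sample_seeds is None:
        sample_seeds = rng.integers(0, _MAX_SEED, size=n_samples).tolist()
    if len(sample_seeds) != n_samples:
        raise ValidationError(
            f"{n_samples} samples but {len(sample_seeds)} sample seeds"
        )
    if len(set(sample_seeds)) != len(sample_seeds):
        warnings.warn("duplicate sample seeds: replicate counts will be identical")
    depths = rng.uniform(*depth_range, size=n_samples)
    tracks = []
    k = 0
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            tracks.append(
                simulate_track(
                    fragments,
                    vp,
                    models[cond],
                    effects=effects.get(cond, ()),
                    depth_factor=float(depths[k]),
                    seed=int(sample_seeds[k]),
                    sample_id=f"{cond}_rep{rep}",
                    condition=cond,
                    replicate=f"rep{rep}",
                )
            )
            k += 1
    return CountMatrix.from_tracks(tracks)


def simulate_significance(
    fragments: Sequence[GenomicInterval],
    true_regions: Sequence[GenomicInterval] = (),
    n_replicates: int = 2,
    seed: int | None = None,
    q_true_max: float = 0.05,
    q_background_min: float = 0.2,
) -> SignificanceTable:
    """Emulate an interaction caller's per-fragment p/q table.

    Fragments overlapping a designated true-interaction region draw
    q ~ U(0, 0.05); background fragments draw q ~ U(0.2, 1), so no
    background fragment can pass a q < 0.1 replication filter.  p is
    drawn uniformly below q.  Replicates are independent.
    """
    if seed is None:
        raise ValidationError("a seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    is_true = np.array(
        [any(f.overlaps(r) for r in true_regions) for f in fragments], dtype=bool
    )
    data = {
        "chrom": [f.chrom for f in fragments],
        "start": [f.start for f in fragments],
        "end": [f.end for f in fragments],
    }
    for rep in range(1, n_replicates + 1):
        q = np.where(
            is_true,
            rng.uniform(0.0, q_true_max, size=len(fragments)),
            rng.uniform(q_background_min, 1.0, size=len(fragments)),
        )
        p = q * rng.uniform(0.0, 1.0, size=len(fragments))
        data[f"p_rep{rep}"] = p
        data[f"q_rep{rep}"] = q
    return SignificanceTable(data=pd.DataFrame(data))


def random_sequence(length: int, at_fraction: float, seed: int) -> str:
    """A random DNA sequence with the given A+T fraction.

    The AT fraction tunes the density of GATC sites and hence the mean
    restriction-fragment length of the synthetic genome; the default
    0.58 mirrors mammalian composition and gives ~270 bp fragments.
    """
    if not 0 < at_fraction < 1:
        raise ValidationError("at_fraction must lie in (0,1)")
    rng = np.random.default_rng(seed)
    p_at, p_gc = at_fraction / 2, (1 - at_fraction) / 2
    bases = rng.choice(
        np.array(["A", "C", "G", "T"]), size=length, p=[p_at, p_gc, p_gc, p_at]
    )
    return "".join(bases)


# ---------------------------------------------------------------------------
# Scenario: a self-contained description of one simulated study.
# ---------------------------------------------------------------------------

_SCENARIO_DEFAULTS: dict[str, object] = {
    "chrom": "chrS",
    "chrom_length": 1_100_000,
    "at_fraction": 0.58,
    "viewpoint_name": "VP",
    "viewpoint_position": 550_000,
    "roi_radius": 500_000,
    "fine_bin": 1_000,
    "rebin_factor": 10,
    "exclusion_radius": 50_000,
    "n_pairs": 50,
    "amplitude": 1000.0,
    "half_distance": 5000.0,
    "exponent": 1.0,
    "dispersion": 5.0,
    "n_replicates": 2,
    "condition_a": "esc",
    "condition_b": "neuron",
    "depth_min": 0.5,
    "depth_max": 2.0,
    "effect_condition": "neuron",
    "effect_offset": 350_000,
    "effect_width": 100_000,
    "effect_fold": 5.0,
    "flank_fold": 1.0,
    "flank_side": "none",
}

_INT_KEYS = {
    "chrom_length",
    "viewpoint_position",
    "roi_radius",
    "fine_bin",
    "rebin_factor",
    "exclusion_radius",
    "n_pairs",
    "n_replicates",
    "effect_offset",
    "effect_width",
}
_FLOAT_KEYS = {
    "at_fraction",
    "amplitude",
    "half_distance",
    "exponent",
    "dispersion",
    "depth_min",
    "depth_max",
    "effect_fold",
    "flank_fold",
}


@dataclass
class Scenario:
    """Parameters of one simulated viewpoint study (see the shipped cfg)."""

    params: dict = field(default_factory=lambda: dict(_SCENARIO_DEFAULTS))

    def __getitem__(self, key):
        return self.params[key]

    def model(self) -> DecayModel:
        return DecayModel(
            amplitude=self["amplitude"],
            half_distance=self["half_distance"],
            exponent=self["exponent"],
            dispersion=self["dispersion"],
        )

    def build_fragments(self, seed: int) -> tuple[list[GenomicInterval], Viewpoint]:
        """Digest a seeded random chromosome and locate the viewpoint fragment."""
        seq = random_sequence(self["chrom_length"], self["at_fraction"], seed)
        fragments = digest_sequence(seq, self["chrom"], DPNII)
        pos = self["viewpoint_position"]
        vp_frag = next(f for f in fragments if f.start <= pos < f.end)
        return fragments, Viewpoint(name=self["viewpoint_name"], interval=vp_frag)

    def effects(self, vp: Viewpoint) -> dict[str, list[InjectedEffect]]:
        out: dict[str, list[InjectedEffect]] = {}
        cond = str(self["effect_condition"])
        if self["effect_fold"] != 1.0 and self["effect_width"] > 0 and cond != "none":
            start = vp.midpoint + self["effect_offset"]
            region = GenomicInterval(
                self["chrom"], start, start + self["effect_width"]
            )
            out.setdefault(cond, []).append(
                InjectedEffect(region=region, fold=self["effect_fold"])
            )
        if self["flank_fold"] != 1.0 and self["flank_side"] in (
            "upstream",
            "downstream",
        ):
            width = self["n_pairs"] * self["fine_bin"]
            if self["flank_side"] == "upstream":
                region = GenomicInterval(
                    self["chrom"], vp.midpoint - width, vp.midpoint
                )
            else:
                region = GenomicInterval(
                    self["chrom"], vp.midpoint, vp.midpoint + width
                )
            out.setdefault(cond, []).append(
                InjectedEffect(
                    region=region,
                    fold=self["flank_fold"],
                    flank=str(self["flank_side"]),
                )
            )
        return out

    def simulate(self, seed: int):
        """Run the full generator: fragments, viewpoint, counts, ground truth.

        Returns ``(count_matrix, viewpoint, fragments, truth)`` where
        ``truth`` records the injected effects per condition.
        """
        rng = np.random.default_rng(seed)
        frag_seed = int(rng.integers(0, _MAX_SEED))
        exp_seed = int(rng.integers(0, _MAX_SEED))
        fragments, vp = self.build_fragments(frag_seed)
        model = self.model()
        conds = [str(self["condition_a"]), str(self["condition_b"])]
        effects = self.effects(vp)
        cm = simulate_experiment(
            fragments,
            vp,
            models={c: model for c in conds},
            effects=effects,
            n_replicates=self["n_replicates"],
            depth_range=(self["depth_min"], self["depth_max"]),
            seed=exp_seed,
        )
        return cm, vp, fragments, {c: list(v) for c, v in effects.items()}


def load_scenario(path) -> Scenario:
    """Load a flat ``key = value`` scenario file over the defaults."""
    params = dict(_SCENARIO_DEFAULTS)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in params:
                raise ValidationError(
                    f"{path}:{lineno}: unknown key {key!r}; valid keys: "
                    f"{sorted(params)}"
                )
            if key in _INT_KEYS:
                params[key] = int(value)
            elif key in _FLOAT_KEYS:
                params[key] = float(value)
            else:
                params[key] = value
    return Scenario(params=params)


def default_scenario() -> Scenario:
    """The shipped default scenario (fold-5 domain 350 kb downstream)."""
    ref = importlib.resources.files("deltacc").joinpath("data/default_scenario.cfg")
    with importlib.resources.as_file(ref) as path:
        return load_scenario(path)


def null_scenario() -> Scenario:
    """The default scenario with every injected effect removed."""
    sc = default_scenario()
    sc.params["effect_fold"] = 1.0
    sc.params["flank_fold"] = 1.0
    sc.params["flank_side"] = "none"
    return sc
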