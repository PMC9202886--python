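"""End-to-end pipeline: simulate -> normalize -> delta -> bin -> tests.

The run configuration collects every tunable with its conventional
default (±500 kb region of interest, 1 kb fine bins re-binned by 10,
±50 kb viewpoint exclusion, 1000/10000 permutations, 50 mirror pairs,
q < 0.1 replication and q < 0.05 curation thresholds).  A seed is
mandatory; identical configuration + seed produces a byte-identical
summary file.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .asymmetry import asymmetry_test, build_mirror_pairs
from .binning import bin_around_viewpoint
from .core import ValidationError, write_bed, write_bedgraph, write_count_matrix
from .mesoscale import largest_run, mesoscale_permutation_test
from .normalization import delta_track, normalize, size_factors
from .simulate import Scenario, default_scenario


@dataclass
class RunConfig:
    """All pipeline tunables, with their conventional defaults."""

    seed: int
    roi_radius: int = 500_000
    fine_bin: int = 1_000
    rebin_factor: int = 10
    exclusion_radius: int = 50_000
    n_perm_meso: int = 1_000
    n_perm_asym: int = 10_000
    n_pairs: int = 50
    q_replication: float = 0.1
    q_curation: float = 0.05

    _INT_KEYS = {
        "seed",
        "roi_radius",
        "fine_bin",
        "rebin_factor",
        "exclusion_radius",
        "n_perm_meso",
        "n_perm_asym",
        "n_pairs",
    }

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is required")
        if self.seed < 0:
            raise ValidationError("seed must be a non-negative integer")
        for name in (
            "roi_radius",
            "fine_bin",
            "rebin_factor",
            "n_perm_meso",
            "n_perm_asym",
            "n_pairs",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.exclusion_radius < 0:
            raise ValidationError("exclusion_radius must be >= 0")
        if self.exclusion_radius >= self.roi_radius:
            raise ValidationError(
                "exclusion_radius must be smaller than roi_radius"
            )
        if self.n_pairs * self.fine_bin > self.roi_radius:
            raise ValidationError(
                "n_pairs fine bins per flank do not fit inside the ROI"
            )
        for name in ("q_replication", "q_curation"):
            if not 0 < getattr(self, name) < 1:
                raise ValidationError(f"{name} must lie in (0,1)")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Read a flat ``key = value`` config file; ``overrides`` win."""
        params: dict = {}
        valid = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValidationError(
                        f"{path}:{lineno}: expected 'key = value'"
                    )
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in valid:
                    raise ValidationError(
                        f"{path}:{lineno}: unknown key {key!r}; "
                        f"valid keys: {sorted(valid)}"
                    )
                params[key] = (
                    int(value) if key in cls._INT_KEYS else float(value)
                )
        params.update({k: v for k, v in overrides.items() if v is not None})
        if "seed" not in params:
            raise ValidationError("config must supply a seed")
        return cls(**params)


def run_pipeline(
    config: RunConfig,
    scenario: Scenario | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Simulate the scenario and run the full differential analysis.

    Returns (and optionally writes) a machine-readable summary holding
    the resolved configuration, the two permutation-test results and
    the coordinates of the maximal constant-sign region.
    """
    scenario = scenario or default_scenario()
    cm, vp, fragments, truth = scenario.simulate(seed=config.seed)
    factors = size_factors(cm)
    norm = normalize(cm, factors)
    cond_a = str(scenario["condition_a"])
    cond_b = str(scenario["condition_b"])
    delta = delta_track(norm, cond_a, cond_b)
    fine = bin_around_viewpoint(
        delta, vp, radius=config.roi_radius, bin_size=config.fine_bin
    )
    meso = mesoscale_permutation_test(
        fine,
        vp,
        exclusion_radius=config.exclusion_radius,
        rebin_factor=config.rebin_factor,
        n_perm=config.n_perm_meso,
        seed=config.seed + 1,
    )
    run = largest_run(
        fine,
        vp,
        exclusion_radius=config.exclusion_radius,
        rebin_factor=config.rebin_factor,
    )
    pairs = build_mirror_pairs(fine, vp, n_pairs=config.n_pairs)
    asym = asymmetry_test(pairs, n_perm=config.n_perm_asym, seed=config.seed + 2)

    summary = {
        "config": {
            k: v for k, v in asdict(config).items() if not k.startswith("_")
        },
        "scenario": {k: scenario.params[k] for k in sorted(scenario.params)},
        "viewpoint": {
            "name": vp.name,
            "chrom": vp.chrom,
            "start": vp.interval.start,
            "end": vp.interval.end,
            "midpoint": vp.midpoint,
        },
        "n_fragments": len(fragments),
        "size_factors": {k: float(v) for k, v in factors.items()},
        "condition_pair": [cond_a, cond_b],
        "mesoscale": meso.summary(),
        "largest_run": (
            None
            if run is None
            else {
                "start_bin": run.start_bin,
                "end_bin": run.end_bin,
                "sign": run.sign,
                "total_abs": run.total_abs,
                "start_bp": fine.origin + run.start_bin
                * config.fine_bin * config.rebin_factor,
                "end_bp": fine.origin + (run.end_bin + 1)
                * config.fine_bin * config.rebin_factor,
            }
        ),
        "asymmetry": asym.summary(),
        "injected_effects": {
            cond: [
                {"region": str(e.region), "fold": e.fold, "flank": e.flank}
                for e in effs
            ]
            for cond, effs in truth.items()
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_bed(fragments, outdir / "fragments.bed")
        write_count_matrix(
            cm, outdir / "counts.tsv", outdir / "samples.tsv"
        )
        write_bedgraph(delta.delta, outdir / "delta.bedgraph", delta.fragments)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")
    return summary
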