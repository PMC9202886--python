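"""Trim a delta track to the viewpoint's region of interest and bin it.

Fragments are allocated to fixed-width bins proportionally to overlap,
so the total signal over the covered span is conserved exactly; binning
at 1 kb and re-binning by 10 therefore sums to the same total as direct
10 kb binning.  The bin origin is anchored at ``midpoint - radius`` so
the viewpoint midpoint always falls on a fine-bin boundary and the two
flanks contain the same number of bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GenomicInterval, ValidationError, Viewpoint
from .normalization import DeltaTrack

#: Half-width of the analysis window around the viewpoint midpoint (bp).
DEFAULT_ROI_RADIUS = 500_000
#: Fine bin width (bp).
DEFAULT_FINE_BIN = 1_000
#: Number of fine bins per coarse bin.
DEFAULT_REBIN_FACTOR = 10


@dataclass
class BinnedDeltaTrack:
    """A fixed-width binned difference track around a viewpoint.

    Bin ``i`` spans ``[origin + i*bin_size, origin + (i+1)*bin_size)``.
    ``viewpoint_bin_index`` marks the fine bin containing the viewpoint
    midpoint when the track was built around a viewpoint.
    ``trailing_partial`` flags a last bin that covers fewer than
    ``bin_size`` bp after re-binning.
    """

    chrom: str
    origin: int
    bin_size: int
    values: np.ndarray
    viewpoint_bin_index: int | None = None
    trailing_partial: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_size <= 0:
            raise ValidationError(f"bin_size must be positive, got {self.bin_size}")
        if self.viewpoint_bin_index is not None and not (
            0 <= self.viewpoint_bin_index < len(self.values)
        ):
            raise ValidationError("viewpoint_bin_index outside the track")

    def __len__(self) -> int:
        return len(self.values)

    def bin_interval(self, i: int) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            self.origin + i * self.bin_size,
            self.origin + (i + 1) * self.bin_size,
        )


def trim_to_roi(
    track: DeltaTrack, vp: Viewpoint, radius: int = DEFAULT_ROI_RADIUS
) -> DeltaTrack:
    """Keep fragments intersecting ``[midpoint - radius, midpoint + radius)``.

    Fragments straddling the window boundary are retained whole.
    """
    if radius <= 0:
        raise ValidationError(f"radius must be positive, got {radius}")
    chroms = {f.chrom for f in track.fragments}
    if chroms and chroms != {vp.chrom}:
        raise ValidationError(
            f"track chromosomes {sorted(chroms)} do not match viewpoint on {vp.chrom}"
        )
    lo = max(0, vp.midpoint - radius)
    hi = vp.midpoint + radius
    keep = [
        i
        for i, f in enumerate(track.fragments)
        if f.start < hi and f.end > lo
    ]
    return DeltaTrack(
        fragments=[track.fragments[i] for i in keep],
        delta=track.delta[keep] if keep else np.empty(0),
        condition_pair=track.condition_pair,
    )


def bin_track(
    track: DeltaTrack,
    bin_size: int = DEFAULT_FINE_BIN,
    origin: int | None = None,
    span: tuple[int, int] | None = None,
    viewpoint: Viewpoint | None = None,
) -> BinnedDeltaTrack:
    """Bin a fragment-keyed delta track to fixed-width bins.

    Each fragment's value is split across the bins it overlaps in
    proportion to overlap width, conserving the total.  ``origin``
    defaults to the start of the first fragment; ``span`` fixes the
    covered region ``[origin, origin + n_bins*bin_size)`` explicitly.
    """
    if bin_size <= 0:
        raise ValidationError(f"bin_size must be positive, got {bin_size}")
    if not track.fragments:
        raise ValidationError("cannot bin an empty track")
    chroms = {f.chrom for f in track.fragments}
    if len(chroms) != 1:
        raise ValidationError(f"track spans multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()

    if span is not None:
        lo, hi = span
    else:
        lo = origin if origin is not None else track.fragments[0].start
        hi = max(f.end for f in track.fragments)
    if origin is not None:
        lo = origin
    if hi <= lo:
        raise ValidationError("empty binning span")
    n_bins = -(-(hi - lo) // bin_size)  # ceil
    values = np.zeros(n_bins)
    for frag, v in zip(track.fragments, track.delta):
        if v == 0:
            continue
        a, b = max(frag.start, lo), min(frag.end, lo + n_bins * bin_size)
        if b <= a:
            continue
        first = (a - lo) // bin_size
        last = (b - 1 - lo) // bin_size
        for i in range(first, last + 1):
            bin_lo = lo + i * bin_size
            ov = min(b, bin_lo + bin_size) - max(a, bin_lo)
            values[i] += v * ov / frag.width
    vp_idx = None
    if viewpoint is not None:
        if not lo <= viewpoint.midpoint < lo + n_bins * bin_size:
            raise ValidationError("viewpoint midpoint outside the binned span")
        vp_idx = (viewpoint.midpoint - lo) // bin_size
    return BinnedDeltaTrack(
        chrom=chrom,
        origin=lo,
        bin_size=bin_size,
        values=values,
        viewpoint_bin_index=vp_idx,
    )


def bin_around_viewpoint(
    track: DeltaTrack,
    vp: Viewpoint,
    radius: int = DEFAULT_ROI_RADIUS,
    bin_size: int = DEFAULT_FINE_BIN,
) -> BinnedDeltaTrack:
    """Trim to the viewpoint ROI and bin with the origin at ``midpoint - radius``.

    This anchoring puts the viewpoint midpoint on a fine-bin boundary so
    the upstream and downstream flanks hold equally many whole bins.
    """
    trimmed = trim_to_roi(track, vp, radius)
    if not trimmed.fragments:
        raise ValidationError("no fragments inside the region of interest")
    lo = vp.midpoint - radius
    if lo < 0:
        raise ValidationError(
            "region of interest extends before position 0; reduce the radius"
        )
    return bin_track(
        trimmed,
        bin_size=bin_size,
        span=(lo, vp.midpoint + radius),
        viewpoint=vp,
    )


def write_binned_bedgraph(track: BinnedDeltaTrack, path) -> None:
    """Write a binned track as a bedGraph of uniform fixed-width bins."""
    from .core import write_bedgraph

    intervals = [track.bin_interval(i) for i in range(len(track))]
    write_bedgraph(track.values, path, intervals)


def binned_track_from_bedgraph(path, viewpoint: Viewpoint | None = None) -> BinnedDeltaTrack:
    """Reconstruct a :class:`BinnedDeltaTrack` from a uniform-bin bedGraph."""
    from .core import read_bedgraph

    t = read_bedgraph(path, signed=True)
    if not t.fragments:
        raise ValidationError(f"{path}: empty binned track")
    widths = {f.width for f in t.fragments}
    if len(widths) != 1:
        raise ValidationError(
            f"{path}: bins are not uniform width (saw widths {sorted(widths)})"
        )
    bin_size = widths.pop()
    origin = t.fragments[0].start
    starts = [f.start for f in t.fragments]
    if starts != [origin + i * bin_size for i in range(len(starts))]:
        raise ValidationError(f"{path}: bins do not tile contiguously")
    vp_idx = None
    if viewpoint is not None:
        if not origin <= viewpoint.midpoint < origin + len(starts) * bin_size:
            raise ValidationError("viewpoint midpoint outside the binned track")
        vp_idx = (viewpoint.midpoint - origin) // bin_size
    return BinnedDeltaTrack(
        chrom=t.fragments[0].chrom,
        origin=origin,
        bin_size=bin_size,
        values=t.counts,
        viewpoint_bin_index=vp_idx,
    )


def rebin(track: BinnedDeltaTrack, factor: int = DEFAULT_REBIN_FACTOR) -> BinnedDeltaTrack:
    """Sum consecutive groups of ``factor`` bins into coarser bins.

    A trailing group with fewer than ``factor`` fine bins is summed as-is
    and flagged via ``trailing_partial``.  The origin is preserved, so
    totals are conserved exactly.
    """
    if factor < 1:
        raise ValidationError(f"rebin factor must be >= 1, got {factor}")
    if factor == 1:
        return BinnedDeltaTrack(
            chrom=track.chrom,
            origin=track.origin,
            bin_size=track.bin_size,
            values=track.values.copy(),
            viewpoint_bin_index=track.viewpoint_bin_index,
            trailing_partial=track.trailing_partial,
        )
    n_fine = len(track.values)
    n_coarse = -(-n_fine // factor)
    padded = np.zeros(n_coarse * factor)
    padded[:n_fine] = track.values
    coarse = padded.reshape(n_coarse, factor).sum(axis=1)
    vp_idx = (
        track.viewpoint_bin_index // factor
        if track.viewpoint_bin_index is not None
        else None
    )
    return BinnedDeltaTrack(
        chrom=track.chrom,
        origin=track.origin,
        bin_size=track.bin_size * factor,
        values=coarse,
        viewpoint_bin_index=vp_idx,
        trailing_partial=(n_fine % factor != 0),
    )
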