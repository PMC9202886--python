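"""In-silico restriction digestion.

Produces the fragment grid that Capture-C count tracks are keyed on.
DpnII is a blunt cutter at ``^GATC`` (cut_offset 0), so every fragment
after the first begins with the recognition motif.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .core import GenomicInterval, ValidationError

_VALID_SEQ = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class RecognitionMotif:
    """A restriction enzyme recognition site and its cut position.

    ``cut_offset`` is the distance in bp from the motif start at which the
    enzyme cuts (0 for DpnII's blunt ^GATC).
    """

    sequence: str = "GATC"
    cut_offset: int = 0

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError("empty recognition motif")
        if not re.fullmatch(r"[ACGT]+", self.sequence):
            raise ValidationError(
                f"motif {self.sequence!r} must be uppercase ACGT only"
            )
        if not 0 <= self.cut_offset <= len(self.sequence):
            raise ValidationError(
                f"cut_offset {self.cut_offset} outside [0, {len(self.sequence)}]"
            )


DPNII = RecognitionMotif("GATC", 0)


def _motif_occurrences(seq: str, motif: str) -> list[int]:
    """Start positions of all (possibly overlapping) motif occurrences."""
    hits = []
    pos = seq.find(motif)
    while pos != -1:
        hits.append(pos)
        pos = seq.find(motif, pos + 1)  # step 1 so overlapping hits all cut
    return hits


def digest_sequence(
    seq: str, chrom: str, motif: RecognitionMotif = DPNII
) -> list[GenomicInterval]:
    """Cut ``seq`` at every motif occurrence, returning fragments tiling it.

    Matching is case-insensitive (soft-masked lowercase matches); ``N``
    never matches.  Cuts at position 0 or at the sequence end produce no
    zero-width fragments.
    """
    if not seq:
        raise ValidationError("empty sequence")
    upper = seq.upper()
    if not _VALID_SEQ.fullmatch(upper):
        bad = sorted(set(upper) - set("ACGTN"))
        raise ValidationError(f"sequence contains non-ACGTN characters: {bad}")
    cuts = sorted(
        {
            p + motif.cut_offset
            for p in _motif_occurrences(upper, motif.sequence)
            if 0 < p + motif.cut_offset < len(seq)
        }
    )
    bounds = [0, *cuts, len(seq)]
    return [
        GenomicInterval(chrom, a, b) for a, b in zip(bounds, bounds[1:])
    ]


def digest_genome(
    seqs: dict[str, str], motif: RecognitionMotif = DPNII
) -> list[GenomicInterval]:
    """Digest every chromosome of a name -> sequence mapping."""
    fragments: list[GenomicInterval] = []
    for chrom in sorted(seqs):
        fragments.extend(digest_sequence(seqs[chrom], chrom, motif))
    return fragments
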