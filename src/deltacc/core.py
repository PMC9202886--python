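"""Genomic interval types and plain-text readers/writers.

All coordinates are 0-based half-open (BED/bedGraph native convention);
any 1-based source must be converted at the boundary.  Counts are stored
as floats because normalized counts are fractional downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input violated a structural invariant (exit code 2 in the CLI)."""


class ParseError(ValidationError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} in {self.chrom}")
        if self.end <= self.start:
            raise ValidationError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_width(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Viewpoint:
    """The captured restriction fragment whose contacts are profiled.

    Distances elsewhere in the package are measured from ``midpoint``,
    the integer midpoint of the capture fragment.
    """

    name: str
    interval: GenomicInterval

    @property
    def midpoint(self) -> int:
        return (self.interval.start + self.interval.end) // 2

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def _check_sorted_nonoverlapping(fragments: Sequence[GenomicInterval]) -> None:
    for prev, cur in zip(fragments, fragments[1:]):
        if (cur.chrom, cur.start) < (prev.chrom, prev.start):
            raise ValidationError(f"fragments not sorted: {prev} precedes {cur}")
        if prev.chrom == cur.chrom and cur.start < prev.end:
            raise ValidationError(f"overlapping fragments: {prev} and {cur}")


@dataclass
class FragmentTrack:
    """Per-fragment values for one sample (one viewpoint library).

    Raw and normalized counts are non-negative; set ``signed`` for
    difference tracks read back from disk.
    """

    fragments: list[GenomicInterval]
    counts: np.ndarray
    sample_id: str = ""
    condition: str = ""
    replicate: str = ""
    signed: bool = field(default=False, compare=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.fragments) != len(self.counts):
            raise ValidationError(
                f"{len(self.fragments)} fragments but {len(self.counts)} counts"
            )
        if len(self.counts) and not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts must be finite")
        if not self.signed and len(self.counts) and np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        _check_sorted_nonoverlapping(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass
class CountMatrix:
    """Fragment x sample count matrix with per-sample condition/replicate labels.

    ``matrix`` columns are sample ids; ``samples`` is indexed by sample id
    with ``condition`` and ``replicate`` columns.
    """

    fragments: list[GenomicInterval]
    matrix: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if len(self.fragments) != len(self.matrix):
            raise ValidationError("fragment count does not match matrix rows")
        if list(self.matrix.columns) != list(self.samples.index):
            raise ValidationError("matrix columns do not match sample table index")
        vals = self.matrix.to_numpy(dtype=float)
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals < 0)):
            raise ValidationError("matrix values must be finite and non-negative")
        for col in ("condition", "replicate"):
            if col not in self.samples.columns:
                raise ValidationError(f"sample table lacks a '{col}' column")
        _check_sorted_nonoverlapping(self.fragments)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["condition"]))

    def column(self, sample_id: str) -> FragmentTrack:
        meta = self.samples.loc[sample_id]
        return FragmentTrack(
            fragments=self.fragments,
            counts=self.matrix[sample_id].to_numpy(dtype=float),
            sample_id=sample_id,
            condition=str(meta["condition"]),
            replicate=str(meta["replicate"]),
        )

    @classmethod
    def from_tracks(cls, tracks: Sequence[FragmentTrack]) -> "CountMatrix":
        if not tracks:
            raise ValidationError("no tracks supplied")
        frags = tracks[0].fragments
        for t in tracks[1:]:
            if t.fragments != frags:
                raise ValidationError("tracks are keyed on different fragment grids")
        ids = [t.sample_id for t in tracks]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate sample ids: {ids}")
        matrix = pd.DataFrame({t.sample_id: t.counts for t in tracks})
        samples = pd.DataFrame(
            {
                "condition": [t.condition for t in tracks],
                "replicate": [t.replicate for t in tracks],
            },
            index=pd.Index(ids, name="sample_id"),
        )
        return cls(fragments=list(frags), matrix=matrix, samples=samples)


@dataclass
class SignificanceTable:
    """Per-fragment p/q values across replicates for one viewpoint x cell type.

    Backed by a DataFrame with ``chrom``, ``start``, ``end`` plus paired
    ``p_<rep>`` / ``q_<rep>`` columns and optionally ``merged_q``.
    """

    data: pd.DataFrame
    q_threshold_replication: float = 0.1
    q_threshold_curation: float = 0.05

    def __post_init__(self):
        for col in ("chrom", "start", "end"):
            if col not in self.data.columns:
                raise ValidationError(f"significance table lacks '{col}'")
        if not self.replicates:
            raise ValidationError("significance table has no q_* columns")
        for thr in (self.q_threshold_replication, self.q_threshold_curation):
            if not 0 < thr < 1:
                raise ValidationError(f"q threshold {thr} outside (0,1)")
        for rep in self.replicates:
            q = self.data[f"q_{rep}"].to_numpy(dtype=float)
            if np.any((q < 0) | (q > 1)):
                raise ValidationError(f"q_{rep} outside [0,1]")
        coords = list(
            zip(self.data["chrom"], self.data["start"], self.data["end"])
        )
        if coords != sorted(coords):
            self.data = (
                self.data.sort_values(["chrom", "start", "end"])
                .reset_index(drop=True)
            )

    @property
    def replicates(self) -> list[str]:
        return [c[2:] for c in self.data.columns if c.startswith("q_") and c != "q_"]

    @property
    def fragments(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(c, int(s), int(e))
            for c, s, e in zip(self.data["chrom"], self.data["start"], self.data["end"])
        ]

    def q_matrix(self) -> np.ndarray:
        """Fragments x replicates matrix of q values."""
        return self.data[[f"q_{r}" for r in self.replicates]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Readers / writers.  All formats here are plain text; bedGraph values are
# rendered with repr-level precision so a read/write cycle is bitwise stable.
# ---------------------------------------------------------------------------

def _fmt(value: float) -> str:
    if float(value).is_integer() and abs(value) < 1e15:
        return str(int(value))
    return format(float(value), ".17g")


def read_bedgraph(
    path,
    sample_id: str = "",
    condition: str = "",
    replicate: str = "",
    signed: bool = False,
) -> FragmentTrack:
    """Read a 4-column bedGraph into a :class:`FragmentTrack`.

    Lines starting with ``track``, ``browser`` or ``#`` are skipped.
    Intervals are sorted and must be non-overlapping.
    """
    fragments, counts = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(
                    f"expected 4 tab-separated fields, got {len(parts)}",
                    path,
                    lineno,
                )
            try:
                iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
                value = float(parts[3])
            except (ValueError, ValidationError) as exc:
                raise ParseError(str(exc), path, lineno) from exc
            fragments.append(iv)
            counts.append(value)
    order = sorted(range(len(fragments)), key=lambda i: fragments[i])
    name = sample_id or Path(path).stem
    return FragmentTrack(
        fragments=[fragments[i] for i in order],
        counts=np.array([counts[i] for i in order], dtype=float),
        sample_id=name,
        condition=condition,
        replicate=replicate,
        signed=signed,
    )


def write_bedgraph(track_or_values, path, fragments=None) -> None:
    """Write a :class:`FragmentTrack` (or parallel fragments/values) to bedGraph."""
    if fragments is None:
        fragments, values = track_or_values.fragments, track_or_values.counts
    else:
        values = track_or_values
    with open(path, "w") as fh:
        for iv, v in zip(fragments, values):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{_fmt(v)}\n")


def read_peaks_bed(path) -> list[GenomicInterval]:
    """Read a >=3-column BED file; extra columns (name, score, strand) ignored."""
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"expected >=3 tab-separated fields, got {len(parts)}",
                    path,
                    lineno,
                )
            try:
                peaks.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except (ValueError, ValidationError) as exc:
                raise ParseError(str(exc), path, lineno) from exc
    return sorted(peaks)


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_count_matrix(counts_path, samples_path) -> CountMatrix:
    """Read a TSV count matrix plus a sidecar sample-metadata TSV.

    The counts TSV has columns ``chrom``, ``start``, ``end`` and one column
    per sample; the sidecar has ``sample_id``, ``condition``, ``replicate``.
    Sample metadata is never inferred from filenames.
    """
    df = pd.read_csv(counts_path, sep="\t")
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ParseError(f"count matrix lacks '{col}' column", counts_path)
    meta = pd.read_csv(samples_path, sep="\t")
    for col in ("sample_id", "condition", "replicate"):
        if col not in meta.columns:
            raise ParseError(f"sample table lacks '{col}' column", samples_path)
    meta = meta.astype(str).set_index("sample_id")
    sample_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
    missing = set(sample_cols) ^ set(meta.index)
    if missing:
        raise ValidationError(
            f"sample columns and sample table disagree on: {sorted(missing)}"
        )
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    fragments = [
        GenomicInterval(c, int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]
    matrix = df[list(meta.index)].astype(float)
    return CountMatrix(fragments=fragments, matrix=matrix, samples=meta)


def write_count_matrix(cm: CountMatrix, counts_path, samples_path) -> None:
    coords = pd.DataFrame(
        {
            "chrom": [f.chrom for f in cm.fragments],
            "start": [f.start for f in cm.fragments],
            "end": [f.end for f in cm.fragments],
        }
    )
    pd.concat([coords, cm.matrix.reset_index(drop=True)], axis=1).to_csv(
        counts_path, sep="\t", index=False
    )
    cm.samples.reset_index().to_csv(samples_path, sep="\t", index=False)


def read_significance_table(path, **thresholds) -> SignificanceTable:
    """Read a TSV of per-fragment p/q values (columns p_<rep>, q_<rep>)."""
    df = pd.read_csv(path, sep="\t")
    return SignificanceTable(data=df, **thresholds)


def write_significance_table(table: SignificanceTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a name -> sequence mapping (via Biopython)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
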