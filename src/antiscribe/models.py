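"""Core domain types.

Coordinates are 0-based half-open everywhere inside the package; GFF
(1-based inclusive) and wiggle (1-based) conversions happen only at the
I/O boundary in :mod:`antiscribe.annotation`.

Bulk read sets are carried as pandas DataFrames (see ``READ_COLUMNS``)
because libraries hold millions of alignments; :class:`ReadAlignment` is
the record-level view used for construction and round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

#: Column contract for bulk read DataFrames.
READ_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "is_junction",
    "intron_start",
    "intron_end",
    "library_id",
]


@dataclass(frozen=True)
class GeneModel:
    """A stranded annotated locus: gene body plus CDS, optional introns.

    ``introns`` are gaps between annotated exons, sorted, non-overlapping,
    inside the gene body. ``biotype`` distinguishes protein-coding genes
    (subject to CDS-based filters) from ncRNAs.
    """

    gene_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    cds_start: int
    cds_end: int
    introns: tuple[tuple[int, int], ...] = ()
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (self.gene_start < self.gene_end):
            raise ValueError(f"{self.gene_id}: gene_start must be < gene_end")
        if not (self.gene_start <= self.cds_start < self.cds_end <= self.gene_end):
            raise ValueError(f"{self.gene_id}: CDS must lie within the gene body")
        prev_end = self.gene_start
        for s, e in self.introns:
            if not (self.gene_start <= s < e <= self.gene_end):
                raise ValueError(f"{self.gene_id}: intron ({s},{e}) outside gene body")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: introns overlap or are unsorted")
            prev_end = e

    @property
    def length(self) -> int:
        return self.gene_end - self.gene_start

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def intron_length(self) -> int:
        return sum(e - s for s, e in self.introns)

    @property
    def exonic_length(self) -> int:
        """Gene-body length minus introns (the sense expressed length)."""
        return self.length - self.intron_length

    @property
    def tss(self) -> int:
        """Transcription start position (5' end of the sense transcript)."""
        return self.gene_start if self.strand == "+" else self.gene_end - 1

    @property
    def tes(self) -> int:
        """Transcription end position (3' end of the sense transcript)."""
        return self.gene_end - 1 if self.strand == "+" else self.gene_start

    def exons(self) -> list[tuple[int, int]]:
        """Exon intervals (gene body minus introns), 0-based half-open."""
        out = []
        pos = self.gene_start
        for s, e in self.introns:
            if s > pos:
                out.append((pos, s))
            pos = e
        if pos < self.gene_end:
            out.append((pos, self.gene_end))
        return out


@dataclass(frozen=True)
class ReadAlignment:
    """One uniquely mapped stranded read.

    Junction reads span one intron; their genomic footprint is
    ``[start, intron_start) + [intron_end, end)`` and their length obeys
    ``end - start == read_length + intron_length``.
    """

    chrom: str
    start: int
    end: int
    strand: str
    is_junction: bool = False
    intron_span: Optional[tuple[int, int]] = None
    library_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("read start must be < end")
        if self.is_junction and self.intron_span is None:
            raise ValueError("junction read requires an intron span")


def reads_to_frame(reads: list[ReadAlignment]) -> pd.DataFrame:
    """Pack record-level reads into the bulk DataFrame representation."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in reads],
            "start": [r.start for r in reads],
            "end": [r.end for r in reads],
            "strand": [r.strand for r in reads],
            "is_junction": [r.is_junction for r in reads],
            "intron_start": [r.intron_span[0] if r.intron_span else -1 for r in reads],
            "intron_end": [r.intron_span[1] if r.intron_span else -1 for r in reads],
            "library_id": [r.library_id for r in reads],
        }
    )


def frame_to_reads(df: pd.DataFrame) -> list[ReadAlignment]:
    out = []
    for row in df.itertuples(index=False):
        span = (
            (int(row.intron_start), int(row.intron_end))
            if bool(row.is_junction)
            else None
        )
        out.append(
            ReadAlignment(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                is_junction=bool(row.is_junction),
                intron_span=span,
                library_id=str(row.library_id),
            )
        )
    return out


@dataclass(frozen=True)
class GenePair:
    """Two adjacent genes on one chromosome, named left/right by coordinate.

    Orientation is a pure function of the two strands: (+,+) or (-,-) is
    tandem, (+,-) convergent (3' ends facing), (-,+) divergent (5' ends
    facing). ``intergenic_distance`` is negative for annotated overlaps.
    """

    left_gene_id: str
    right_gene_id: str
    orientation: str
    intergenic_distance: int
    overlapping: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in ("tandem", "convergent", "divergent"):
            raise ValueError(f"bad orientation {self.orientation!r}")


def pair_orientation(left_strand: str, right_strand: str) -> str:
    if left_strand == right_strand:
        return "tandem"
    return "convergent" if left_strand == "+" else "divergent"


@dataclass
class StrandSpecificity:
    """Library-level strand-assignment error estimated from junction reads."""

    library_id: str
    n_junction_reads: int
    n_wrong_orientation: int
    p_bg: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_bg <= 1.0):
            raise ValueError("p_bg must be a probability")
        if not (self.ci_low <= self.p_bg <= self.ci_high):
            raise ValueError("CI must contain the point estimate")


@dataclass
class MetaProfile:
    """Smoothed mean/SD occupancy in a gene-anchored frame for a gene group.

    ``positions`` run 5'->3' of the sense transcript. In the composite ORF
    frame, flanks are in bp (-1000..0 and beyond the end) and the gene body
    is length-scaled to ``body_bins`` bin units (see occupancy module).
    """

    group_id: str
    anchor: str
    positions: "pd.Series | list[float]"
    mean: "pd.Series | list[float]"
    sd: "pd.Series | list[float]"
    n_genes: int
    body_bins: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_id": self.group_id,
                "anchor": self.anchor,
                "rel_pos": list(self.positions),
                "mean": list(self.mean),
                "sd": list(self.sd),
                "n_genes": self.n_genes,
            }
        )


@dataclass
class GeneGroup:
    """A named gene set with the rule that defined it."""

    group_id: str
    gene_ids: tuple[str, ...]
    rule: str = ""
    matched: bool = False
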