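"""Annotation parsing, gene-pair classification, mappability, browser tracks.

GFF is read and written 1-based inclusive (the annotation convention of
GeneDB-style files); everything internal is 0-based half-open. Wiggle
output is 1-based. Those conversions live here and nowhere else.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import gffutils
import numpy as np
import pandas as pd

from .models import GeneModel, GenePair, pair_orientation

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# GFF
# ---------------------------------------------------------------------------

def _prevalidate_gff(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}: malformed GFF line {lineno}: expected >=8 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(f"{path}: malformed GFF line {lineno}: non-integer coordinates") from None
            if start < 1 or end < start:
                raise ValueError(f"{path}: malformed GFF line {lineno}: bad coordinate range {start}..{end}")


def read_gff(path: str) -> list[GeneModel]:
    """Parse gene/exon/CDS features into :class:`GeneModel` records.

    Coordinates are converted from 1-based inclusive to 0-based half-open;
    introns are derived as gaps between a gene's exons; genes come back
    sorted by (chrom, start). A CDS outside its gene body is a validation
    error.
    """
    _prevalidate_gff(path)
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        gstart, gend = feat.start - 1, feat.end  # to 0-based half-open
        exons = sorted(
            (e.start - 1, e.end) for e in db.children(feat, featuretype="exon")
        )
        cds = [(c.start - 1, c.end) for c in db.children(feat, featuretype="CDS")]
        if cds:
            cstart = min(c[0] for c in cds)
            cend = max(c[1] for c in cds)
        else:
            cstart, cend = gstart, gend
        if not (gstart <= cstart < cend <= gend):
            raise ValueError(f"gene {feat.id}: CDS [{cstart},{cend}) outside gene body [{gstart},{gend})")
        introns: list[tuple[int, int]] = []
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 > e1:
                introns.append((e1, s2))
        biotype = feat.attributes.get("biotype", ["protein_coding"])[0]
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                strand=feat.strand,
                gene_start=gstart,
                gene_end=gend,
                cds_start=cstart,
                cds_end=cend,
                introns=tuple(introns),
                biotype=biotype,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.gene_start, g.gene_id))
    return genes


def write_gff(genes: Sequence[GeneModel], path: str, source: str = "antiscribe") -> None:
    """Write genes with exon and CDS children as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.gene_start, g.gene_id)):
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.gene_start + 1}\t{g.gene_end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};biotype={g.biotype}\n"
            )
            for s, e in g.exons():
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}\n"
                )
            fh.write(
                f"{g.chrom}\t{source}\tCDS\t{g.cds_start + 1}\t{g.cds_end}\t.\t"
                f"{g.strand}\t0\tParent={g.gene_id}\n"
            )


def genes_to_frame(genes: Sequence[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "gene_start": [g.gene_start for g in genes],
            "gene_end": [g.gene_end for g in genes],
            "cds_start": [g.cds_start for g in genes],
            "cds_end": [g.cds_end for g in genes],
            "exonic_length": [g.exonic_length for g in genes],
            "biotype": [g.biotype for g in genes],
        }
    )


# ---------------------------------------------------------------------------
# reads BED
# ---------------------------------------------------------------------------

_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "is_junction", "intron_start", "intron_end"]


def write_reads_bed(reads: pd.DataFrame, path: str) -> None:
    """BED6+3: standard six columns plus junction flag and intron span."""
    df = reads.copy()
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df["library_id"],
            "score": 0,
            "strand": df["strand"],
            "is_junction": df["is_junction"].astype(int),
            "intron_start": df["intron_start"],
            "intron_end": df["intron_end"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=_BED_COLUMNS)
    return pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "strand": df["strand"].astype(str),
            "is_junction": df["is_junction"].astype(bool),
            "intron_start": df["intron_start"].astype(int),
            "intron_end": df["intron_end"].astype(int),
            "library_id": df["name"].astype(str),
        }
    )


# ---------------------------------------------------------------------------
# gene pairs
# ---------------------------------------------------------------------------

def classify_gene_pairs(genes: Sequence[GeneModel], max_intergenic: int = 1000) -> list[GenePair]:
    """Classify adjacent same-chromosome gene pairs within ``max_intergenic``.

    Orientation is determined solely by the two strands (left/right by
    coordinate): same strands tandem, (+,-) convergent, (-,+) divergent.
    Annotated overlapping pairs (negative intergenic distance) are kept
    and flagged.
    """
    if max_intergenic < 0:
        raise ValueError("max_intergenic must be >= 0")
    ordered = sorted(genes, key=lambda g: (g.chrom, g.gene_start, g.gene_id))
    pairs: list[GenePair] = []
    for a, b in zip(ordered, ordered[1:]):
        if a.chrom != b.chrom:
            continue
        dist = b.gene_start - a.gene_end
        if dist > max_intergenic:
            continue
        pairs.append(
            GenePair(
                left_gene_id=a.gene_id,
                right_gene_id=b.gene_id,
                orientation=pair_orientation(a.strand, b.strand),
                intergenic_distance=dist,
                overlapping=dist < 0,
            )
        )
    return pairs


def pairs_to_frame(pairs: Iterable[GenePair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "left_gene_id": [p.left_gene_id for p in pairs],
            "right_gene_id": [p.right_gene_id for p in pairs],
            "orientation": [p.orientation for p in pairs],
            "intergenic_distance": [p.intergenic_distance for p in pairs],
            "overlapping": [p.overlapping for p in pairs],
        }
    )


# ---------------------------------------------------------------------------
# mappability
# ---------------------------------------------------------------------------

@dataclass
class MappabilityTrack:
    """Per-base mappability masks plus per-gene fraction lookup.

    ``masks[chrom][p]`` is True iff the ``read_length``-mer starting at p
    occurs exactly once across both strands of the whole genome.
    Reverse-complement-palindromic k-mers count their two strand
    occurrences separately and are therefore never unique.
    """

    read_length: int
    masks: Mapping[str, np.ndarray]

    def fraction_for(self, gene: GeneModel) -> float:
        mask = self.masks.get(gene.chrom)
        if mask is None:
            raise KeyError(f"no mappability for chromosome {gene.chrom}")
        lo = gene.gene_start
        hi = min(gene.gene_end, mask.size)
        n_mappable = int(mask[lo:hi].sum()) if hi > lo else 0
        return n_mappable / gene.length

    def fractions(self, genes: Sequence[GeneModel]) -> pd.Series:
        return pd.Series({g.gene_id: self.fraction_for(g) for g in genes}, name="mappability")


def compute_mappability(genome: Union[str, Mapping[str, str]], read_length: int) -> MappabilityTrack:
    """Exact k-mer-census mappability of a (small) genome.

    A start position is mappable iff its k-mer occurs exactly once over
    both strands. Intended for compact genomes (the census is a plain
    hash count over all k-mers).
    """
    if isinstance(genome, str):
        genome = {"chr1": genome}
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    seqs = {c: s.upper() for c, s in genome.items()}
    for c, s in seqs.items():
        if read_length > len(s):
            raise ValueError(f"read_length {read_length} exceeds length of {c} ({len(s)})")
    counts: Counter = Counter()
    for s in seqs.values():
        for p in range(len(s) - read_length + 1):
            counts[s[p : p + read_length]] += 1
    masks = {}
    for c, s in seqs.items():
        n = len(s) - read_length + 1
        mask = np.zeros(max(n, 0), dtype=bool)
        for p in range(n):
            w = s[p : p + read_length]
            if counts[w] + counts[revcomp(w)] == 1:
                mask[p] = True
        masks[c] = mask
    return MappabilityTrack(read_length=read_length, masks=masks)


def load_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# wiggle
# ---------------------------------------------------------------------------

def _read_segments(reads: pd.DataFrame) -> pd.DataFrame:
    """Explode junction reads into their exonic segments.

    Returns columns (rid, chrom, start, end, strand); non-junction reads
    contribute one segment, junction reads two (their genomic footprint
    minus the spanned intron).
    """
    df = reads.reset_index(drop=True)
    rid = np.arange(len(df))
    body = df.loc[~df["is_junction"].astype(bool)]
    seg_frames = [
        pd.DataFrame(
            {
                "rid": rid[~df["is_junction"].astype(bool)],
                "chrom": body["chrom"].to_numpy(),
                "start": body["start"].to_numpy(),
                "end": body["end"].to_numpy(),
                "strand": body["strand"].to_numpy(),
            }
        )
    ]
    junc = df.loc[df["is_junction"].astype(bool)]
    if len(junc):
        jr = rid[df["is_junction"].astype(bool)]
        seg_frames.append(
            pd.DataFrame(
                {
                    "rid": jr,
                    "chrom": junc["chrom"].to_numpy(),
                    "start": junc["start"].to_numpy(),
                    "end": junc["intron_start"].to_numpy(),
                    "strand": junc["strand"].to_numpy(),
                }
            )
        )
        seg_frames.append(
            pd.DataFrame(
                {
                    "rid": jr,
                    "chrom": junc["chrom"].to_numpy(),
                    "start": junc["intron_end"].to_numpy(),
                    "end": junc["end"].to_numpy(),
                    "strand": junc["strand"].to_numpy(),
                }
            )
        )
    segs = pd.concat(seg_frames, ignore_index=True)
    return segs[segs["end"] > segs["start"]]


def coverage_per_base(reads: pd.DataFrame, strand: Optional[str] = None) -> dict[str, np.ndarray]:
    """Raw per-base read coverage per chromosome (junction-aware)."""
    segs = _read_segments(reads)
    if strand in ("+", "-"):
        segs = segs[segs["strand"] == strand]
    out: dict[str, np.ndarray] = {}
    for chrom, grp in segs.groupby("chrom", sort=True):
        hi = int(grp["end"].max())
        diff = np.zeros(hi + 1, dtype=np.int64)
        np.add.at(diff, grp["start"].to_numpy(), 1)
        np.add.at(diff, grp["end"].to_numpy(), -1)
        out[str(chrom)] = np.cumsum(diff)[:-1]
    return out


def write_wiggle(
    reads: pd.DataFrame,
    strand: str,
    normalization_total: int,
    path: str,
    track_name: Optional[str] = None,
) -> None:
    """Per-base coverage on one strand, in reads-per-million units.

    variableStep wiggle, 1-based positions; only nonzero positions are
    emitted, so an empty read set yields a valid empty track.
    """
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    if normalization_total <= 0:
        raise ValueError("normalization_total must be > 0")
    cov = coverage_per_base(reads, strand=strand)
    scale = normalization_total / 1e6
    name = track_name or f"coverage_{'fwd' if strand == '+' else 'rev'}"
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom in sorted(cov):
            arr = cov[chrom]
            nz = np.flatnonzero(arr)
            if nz.size == 0:
                continue
            fh.write(f"variableStep chrom={chrom}\n")
            vals = arr[nz] / scale
            for p, v in zip(nz + 1, vals):  # 1-based
                fh.write(f"{p}\t{v:.6g}\n")


def wiggle_mass(path: str) -> float:
    """Sum of wiggle values (for conservation checks)."""
    total = 0.0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "variableStep", "fixedStep", "#")):
                continue
            parts = line.split()
            if len(parts) == 2:
                total += float(parts[1])
    return total
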