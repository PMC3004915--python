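"""Stranded read counting, expression normalization, strand-specificity QC.

Counting rules
--------------
* A read overlapping a gene (>= 1 bp intersection of its exonic
  footprint with the gene body) is *sense* if its observed strand equals
  the gene strand, else *antisense*.
* Sense counting requires >= 1 bp overlap with the gene's exons — the
  annotated introns of the gene are not sense-expressed region. The
  antisense expressed region is the full gene span including introns
  (the antisense transcript has its own, unknown, intron structure).
* Reads hitting both genes of an annotated 5'-5' or 3'-3' overlapping
  coding-gene pair are ambiguous and discarded (counted for neither).
* A read overlapping two non-overlapping genes (possible for junction
  reads) is assigned to the gene containing its 5' end.

Every input read lands in exactly one of {sense, antisense, discarded
ambiguous, unassigned}; the per-library accounting is exact.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats

from .annotation import _read_segments, classify_gene_pairs
from .models import GeneModel, StrandSpecificity

logger = logging.getLogger(__name__)

CATEGORY_SENSE = "sense"
CATEGORY_ANTISENSE = "antisense"
CATEGORY_AMBIGUOUS = "ambiguous"
CATEGORY_UNASSIGNED = "unassigned"


def _overlap_pair_set(genes: Sequence[GeneModel]) -> set[frozenset[str]]:
    """Coding-coding pairs annotated with 5'-5' or 3'-3' overlaps."""
    out: set[frozenset[str]] = set()
    for p in classify_gene_pairs(genes, max_intergenic=0):
        if not p.overlapping or p.orientation == "tandem":
            continue
        by_id = {g.gene_id: g for g in genes}
        a, b = by_id[p.left_gene_id], by_id[p.right_gene_id]
        if a.biotype == "protein_coding" and b.biotype == "protein_coding":
            out.add(frozenset((p.left_gene_id, p.right_gene_id)))
    return out


def count_stranded_reads(
    reads: pd.DataFrame, genes: Sequence[GeneModel]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count sense/antisense reads per gene per library.

    Returns ``(expression, accounting)``: expression has one row per
    (gene, library) with raw ``sense_count``/``antisense_count``;
    accounting has one row per library with the exact partition of its
    reads into the four categories (plus unknown-chromosome reads, which
    are logged, skipped, and counted inside ``unassigned``).
    """
    df = reads.reset_index(drop=True)
    n_reads = len(df)
    libraries = sorted(df["library_id"].unique()) if n_reads else []
    gene_ids = [g.gene_id for g in genes]

    category = np.full(n_reads, CATEGORY_UNASSIGNED, dtype=object)
    assigned_gene = np.full(n_reads, -1, dtype=np.int64)

    known_chroms = {g.chrom for g in genes}
    unknown = ~df["chrom"].isin(known_chroms).to_numpy() if n_reads else np.zeros(0, bool)
    n_unknown = int(unknown.sum())
    if n_unknown:
        logger.warning("%d reads on unknown chromosomes skipped", n_unknown)

    if n_reads:
        segs = _read_segments(df)
        segs = segs[segs["chrom"].isin(known_chroms)]
        gene_pr = pr.PyRanges(
            pd.DataFrame(
                {
                    "Chromosome": [g.chrom for g in genes],
                    "Start": [g.gene_start for g in genes],
                    "End": [g.gene_end for g in genes],
                    "gidx": np.arange(len(genes)),
                }
            )
        )
        seg_pr = pr.PyRanges(
            segs.rename(columns={"chrom": "Chromosome", "start": "Start", "end": "End"})[
                ["Chromosome", "Start", "End", "rid"]
            ]
        )
        joined = seg_pr.join(gene_pr).df
        if len(joined):
            hits = joined[["rid", "gidx"]].drop_duplicates()
        else:
            hits = pd.DataFrame(columns=["rid", "gidx"])

        counts = hits.groupby("rid").size()
        single = counts[counts == 1].index
        multi = counts[counts >= 2].index

        one = hits[hits["rid"].isin(single)]
        assigned_gene[one["rid"].to_numpy()] = one["gidx"].to_numpy()

        if len(multi):
            overlap_pairs = _overlap_pair_set(genes)
            strand_arr = df["strand"].to_numpy()
            start_arr = df["start"].to_numpy()
            end_arr = df["end"].to_numpy()
            multi_hits = hits[hits["rid"].isin(multi)].groupby("rid")["gidx"].apply(list)
            for rid, gidxs in multi_hits.items():
                ids = [gene_ids[i] for i in gidxs]
                ambiguous = any(
                    frozenset((ids[i], ids[j])) in overlap_pairs
                    for i in range(len(ids))
                    for j in range(i + 1, len(ids))
                )
                if ambiguous:
                    category[rid] = CATEGORY_AMBIGUOUS
                    continue
                five_prime = start_arr[rid] if strand_arr[rid] == "+" else end_arr[rid] - 1
                best, best_dist = None, None
                for gi in sorted(gidxs, key=lambda i: gene_ids[i]):
                    g = genes[gi]
                    if g.gene_start <= five_prime < g.gene_end:
                        d = -1
                    else:
                        d = min(abs(five_prime - g.gene_start), abs(five_prime - (g.gene_end - 1)))
                    if best_dist is None or d < best_dist:
                        best, best_dist = gi, d
                assigned_gene[rid] = best

        # sense requires exonic overlap; compute intron overlap for assigned reads
        sel = assigned_gene >= 0
        if sel.any():
            rids = np.flatnonzero(sel)
            gidxs = assigned_gene[rids]
            gene_strand = np.array([genes[i].strand for i in gidxs])
            read_strand = df["strand"].to_numpy()[rids]
            is_sense = read_strand == gene_strand

            exonic_overlap = np.zeros(n_reads)
            intron_map = {i: genes[i].introns for i in set(gidxs) if genes[i].introns}
            # overlap of each assigned read's segments with its gene's exons
            gs = np.array([genes[i].gene_start for i in gidxs])
            ge = np.array([genes[i].gene_end for i in gidxs])
            seg_sub = segs[segs["rid"].isin(rids)]
            pos = pd.Series(np.arange(rids.size), index=rids)
            k = pos[seg_sub["rid"].to_numpy()].to_numpy()
            ov = np.maximum(
                0,
                np.minimum(seg_sub["end"].to_numpy(), ge[k]) - np.maximum(seg_sub["start"].to_numpy(), gs[k]),
            ).astype(float)
            # subtract the intronic part of each clipped segment
            gidx_of_seg = gidxs[k]
            for ii, introns in intron_map.items():
                m = gidx_of_seg == ii
                if not m.any():
                    continue
                s = np.maximum(seg_sub["start"].to_numpy()[m], gs[k][m])
                e = np.minimum(seg_sub["end"].to_numpy()[m], ge[k][m])
                for istart, iend in introns:
                    ov_part = np.maximum(0, np.minimum(e, iend) - np.maximum(s, istart))
                    ov[m] = ov[m] - ov_part
            np.add.at(exonic_overlap, seg_sub["rid"].to_numpy(), ov)

            cat = np.where(
                is_sense,
                np.where(exonic_overlap[rids] > 0, CATEGORY_SENSE, CATEGORY_UNASSIGNED),
                CATEGORY_ANTISENSE,
            )
            category[rids] = cat
            assigned_gene[rids[cat == CATEGORY_UNASSIGNED]] = -1

    # ---- aggregate ---------------------------------------------------------
    lib_arr = df["library_id"].to_numpy() if n_reads else np.empty(0, dtype=object)
    rows = []
    counted = (category == CATEGORY_SENSE) | (category == CATEGORY_ANTISENSE)
    if counted.any():
        agg = pd.DataFrame(
            {
                "gene_id": [gene_ids[i] for i in assigned_gene[counted]],
                "library_id": lib_arr[counted],
                "cat": category[counted],
            }
        )
        tab = agg.groupby(["gene_id", "library_id", "cat"]).size().unstack("cat", fill_value=0)
    else:
        tab = pd.DataFrame()
    for lib in libraries:
        for gid in gene_ids:
            s = a = 0
            if len(tab) and (gid, lib) in tab.index:
                row = tab.loc[(gid, lib)]
                s = int(row.get(CATEGORY_SENSE, 0))
                a = int(row.get(CATEGORY_ANTISENSE, 0))
            rows.append({"gene_id": gid, "library_id": lib, "sense_count": s, "antisense_count": a})
    expr = pd.DataFrame(rows, columns=["gene_id", "library_id", "sense_count", "antisense_count"])

    acc_rows = []
    for lib in libraries:
        m = lib_arr == lib
        acc_rows.append(
            {
                "library_id": lib,
                "total_reads": int(m.sum()),
                "sense": int((category[m] == CATEGORY_SENSE).sum()),
                "antisense": int((category[m] == CATEGORY_ANTISENSE).sum()),
                "ambiguous_discarded": int((category[m] == CATEGORY_AMBIGUOUS).sum()),
                "unassigned": int((category[m] == CATEGORY_UNASSIGNED).sum()),
                "unknown_chrom": int(unknown[m].sum()),
            }
        )
    accounting = pd.DataFrame(
        acc_rows,
        columns=["library_id", "total_reads", "sense", "antisense", "ambiguous_discarded", "unassigned", "unknown_chrom"],
    )
    return expr, accounting


def normalize_expression(
    expr: pd.DataFrame,
    genes: Sequence[GeneModel],
    library_totals: Mapping[str, int],
    mappability: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Add normalized levels: count per kb of effective length per million
    uniquely mapped library reads.

    The sense effective length is the exonic length, the antisense
    effective length the full gene span (strand-appropriate expressed
    regions), both scaled by the gene's mappable fraction. Genes whose
    effective length is 0 get level NaN and ``level_undefined=True``
    rather than 0; a zero effective length with a nonzero count is
    additionally flagged inconsistent.
    """
    by_id = {g.gene_id: g for g in genes}
    out = expr.copy()
    mapf = np.array([(mappability or {}).get(gid, 1.0) for gid in out["gene_id"]])
    exonic = np.array([by_id[gid].exonic_length for gid in out["gene_id"]], dtype=float)
    span = np.array([by_id[gid].length for gid in out["gene_id"]], dtype=float)
    totals = np.array([library_totals[lib] for lib in out["library_id"]], dtype=float)
    if (totals <= 0).any():
        raise ValueError("library totals must be > 0")

    eff_s = exonic * mapf
    eff_a = span * mapf
    with np.errstate(divide="ignore", invalid="ignore"):
        out["sense_level"] = np.where(eff_s > 0, out["sense_count"] / (eff_s / 1e3) / (totals / 1e6), np.nan)
        out["antisense_level"] = np.where(
            eff_a > 0, out["antisense_count"] / (eff_a / 1e3) / (totals / 1e6), np.nan
        )
    out["level_undefined"] = (eff_s <= 0) | (eff_a <= 0)
    inconsistent = ((eff_s <= 0) & (out["sense_count"] > 0)) | ((eff_a <= 0) & (out["antisense_count"] > 0))
    out["inconsistent_effective_length"] = inconsistent
    if inconsistent.any():
        logger.warning("%d records with zero effective length but nonzero count", int(inconsistent.sum()))
    return out


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) confidence interval."""
    if n <= 0:
        raise ValueError("n must be > 0")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def estimate_strand_specificity(
    reads: pd.DataFrame,
    genes: Sequence[GeneModel],
    library_id: str,
    alpha: float = 0.05,
) -> StrandSpecificity:
    """Estimate the library's strand-assignment error from junction reads.

    Junction reads whose intron span matches an annotated intron have a
    known true orientation (introns are strand-specific); the fraction
    observed on the wrong strand is the background rate p_bg, with an
    exact Clopper-Pearson CI. Junction reads matching no annotated
    intron are excluded.
    """
    intron_strand: dict[tuple[str, int, int], str] = {}
    for g in genes:
        for s, e in g.introns:
            intron_strand[(g.chrom, s, e)] = g.strand
    junc = reads[(reads["library_id"] == library_id) & reads["is_junction"].astype(bool)]
    n = 0
    wrong = 0
    keys = list(zip(junc["chrom"], junc["intron_start"], junc["intron_end"]))
    observed = junc["strand"].to_numpy()
    for key, obs in zip(keys, observed):
        true = intron_strand.get(key)
        if true is None:
            continue
        n += 1
        if obs != true:
            wrong += 1
    if n == 0:
        raise ValueError(
            f"library {library_id}: no junction reads matching annotated introns; "
            "supply p_bg manually"
        )
    p = wrong / n
    lo, hi = clopper_pearson(wrong, n, alpha=alpha)
    return StrandSpecificity(
        library_id=library_id,
        n_junction_reads=n,
        n_wrong_orientation=wrong,
        p_bg=p,
        ci_low=lo,
        ci_high=hi,
    )
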