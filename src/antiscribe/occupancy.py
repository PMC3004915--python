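"""Strand-oriented metagene occupancy profiles and group comparisons.

Probe intensities (IP and whole-cell-extract channels) are normalized
to log2(IP/WCE), mapped into a gene-anchored coordinate frame oriented
5'->3' of the sense transcript, smoothed with a Gaussian kernel
(Nadaraya-Watson, sd 40 bp by default), and averaged across the genes
of a group: the profile's height is the per-position mean and its band
the per-position SD across genes. Genes with CDS shorter than 200 bp
are excluded.

The composite ORF frame keeps the two 1 kb flanks in bp while scaling
the gene body to a fixed number of bins (default 100), so groups of
different gene lengths are comparable; single-anchor frames
(``ORF_start`` / ``ORF_end``) stay entirely in bp.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneModel, GeneGroup, MetaProfile

logger = logging.getLogger(__name__)

CDS_MIN = 200
FLANK = 1000


def normalize_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Add ``log2_ratio`` = log2(IP / WCE). WCE must be positive."""
    if (probes["wce"] <= 0).any():
        raise ValueError("whole-cell-extract intensity must be > 0 for normalization")
    out = probes.copy()
    out["log2_ratio"] = np.log2(out["ip"] / out["wce"])
    return out


def assign_probes_to_frame(
    probes: pd.DataFrame,
    gene: GeneModel,
    anchor: str = "ORF",
    flank: int = FLANK,
    cds_min: int = CDS_MIN,
    value_col: str = "log2_ratio",
) -> pd.DataFrame:
    """Map probe midpoints into the gene's anchored bp frame.

    Positions are strand-mirrored so negative is always upstream (5' of
    the sense transcript). For ``anchor='ORF'`` the frame origin is the
    ORF start and positions inside the ORF run 0..cds_length; for
    ``ORF_start``/``ORF_end`` the origin is that boundary and only
    probes within ``flank`` bp are kept. Probes outside the ORF +/-
    ``flank`` window are excluded.
    """
    if gene.cds_length < cds_min:
        raise ValueError(f"gene {gene.gene_id}: CDS {gene.cds_length} bp < {cds_min} bp filter")
    sub = probes[probes["chrom"] == gene.chrom]
    pos = sub["position"].to_numpy(dtype=float)
    if gene.strand == "+":
        rel_start = pos - gene.cds_start
    else:
        rel_start = (gene.cds_end - 1) - pos
    if anchor == "ORF":
        keep = (rel_start >= -flank) & (rel_start < gene.cds_length + flank)
        rel = rel_start
    elif anchor == "ORF_start":
        keep = np.abs(rel_start) <= flank
        rel = rel_start
    elif anchor == "ORF_end":
        rel = rel_start - gene.cds_length
        keep = np.abs(rel) <= flank
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return pd.DataFrame({"rel_pos": rel[keep], "value": sub[value_col].to_numpy()[keep]})


def gaussian_smooth(positions, values, sd: float, eval_grid) -> np.ndarray:
    """Gaussian-kernel weighted mean (Nadaraya-Watson) at ``eval_grid``.

    smoothed(x) = sum_i w_i v_i / sum_i w_i, w_i = exp(-(x - p_i)^2 / (2 sd^2)).
    A convex combination: output is bounded by [min(values), max(values)].
    Grid points whose total weight underflows to 0 come back NaN.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    grid = np.asarray(eval_grid, dtype=float)
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if positions.size == 0:
        raise ValueError("cannot smooth an empty point set")
    w = np.exp(-((grid[:, None] - positions[None, :]) ** 2) / (2 * sd * sd))
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (w @ values) / wsum
    out[wsum == 0] = np.nan
    return out


def _gene_eval_grid(cds_length: int, flank: int, body_bins: int, step: int):
    """Per-gene bp evaluation grid and its shared composite coordinates."""
    up = np.arange(-flank, 0, step, dtype=float)
    body = (np.arange(body_bins) + 0.5) / body_bins * cds_length
    down = np.arange(step, flank + 1, step, dtype=float) + cds_length
    grid_bp = np.concatenate([up, body, down])
    comp = np.concatenate(
        [up, (np.arange(body_bins) + 0.5) / body_bins * 100.0, 100.0 + (down - cds_length)]
    )
    return grid_bp, comp


def build_metaprofile(
    probes: pd.DataFrame,
    genes: Sequence[GeneModel],
    group_id: str = "group",
    anchor: str = "ORF",
    sd: float = 40.0,
    flank: int = FLANK,
    cds_min: int = CDS_MIN,
    body_bins: int = 100,
    step: int = 25,
    value_col: str = "log2_ratio",
) -> MetaProfile:
    """Mean/SD occupancy profile of a gene group in the anchored frame.

    Each gene's probes are smoothed (Gaussian sd in bp) on its own bp
    grid, mapped to the shared composite coordinates, and the profile is
    the per-position mean and SD across genes.
    """
    usable = [g for g in genes if g.cds_length >= cds_min]
    for g in genes:
        if g.cds_length < cds_min:
            logger.info("gene %s excluded from metaprofile: CDS %d bp", g.gene_id, g.cds_length)
    if not usable:
        raise ValueError(f"group {group_id!r} empty after CDS >= {cds_min} bp filter")

    comp_ref: Optional[np.ndarray] = None
    curves = []
    for g in usable:
        pts = assign_probes_to_frame(probes, g, anchor=anchor, flank=flank, cds_min=cds_min, value_col=value_col)
        if anchor == "ORF":
            grid_bp, comp = _gene_eval_grid(g.cds_length, flank, body_bins, step)
        else:
            grid_bp = np.arange(-flank, flank + 1, step, dtype=float)
            comp = grid_bp
        if comp_ref is None:
            comp_ref = comp
        if len(pts) == 0:
            curves.append(np.full(grid_bp.size, np.nan))
            continue
        curves.append(gaussian_smooth(pts["rel_pos"], pts["value"], sd, grid_bp))
    mat = np.vstack(curves)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=0)
        sd_arr = np.nanstd(mat, axis=0, ddof=0)
    return MetaProfile(
        group_id=group_id,
        anchor=anchor,
        positions=list(comp_ref),
        mean=list(mean),
        sd=list(sd_arr),
        n_genes=len(usable),
        body_bins=body_bins if anchor == "ORF" else 0,
    )


def gene_region_summary(
    probes: pd.DataFrame,
    genes: Sequence[GeneModel],
    region: str = "body",
    flank: int = FLANK,
    cds_min: int = CDS_MIN,
    value_col: str = "log2_ratio",
) -> pd.Series:
    """Per-gene mean normalized ratio over a stated region.

    ``region``: 'body' (ORF), 'upstream' or 'downstream' (1 kb flank,
    strand-aware).
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in probes.groupby("chrom"):
        srt = grp.sort_values("position")
        by_chrom[str(chrom)] = (srt["position"].to_numpy(), srt[value_col].to_numpy())
    out = {}
    for g in genes:
        if g.cds_length < cds_min or g.chrom not in by_chrom:
            continue
        if region == "body":
            lo, hi = g.cds_start, g.cds_end
        elif region == "upstream":
            lo, hi = (g.cds_start - flank, g.cds_start) if g.strand == "+" else (g.cds_end, g.cds_end + flank)
        elif region == "downstream":
            lo, hi = (g.cds_end, g.cds_end + flank) if g.strand == "+" else (g.cds_start - flank, g.cds_start)
        else:
            raise ValueError(f"unknown region {region!r}")
        pos, vals = by_chrom[g.chrom]
        i, j = np.searchsorted(pos, [lo, hi])
        if j > i:
            out[g.gene_id] = float(vals[i:j].mean())
    return pd.Series(out, name=f"mean_{value_col}_{region}")


def compare_group_occupancy(
    group_a: Sequence[str],
    group_b: Sequence[str],
    summaries: pd.Series,
    alternative: str = "greater",
) -> float:
    """One-sided Wilcoxon rank-sum on per-gene occupancy summaries.

    Tests whether group A occupancy exceeds group B (``alternative``
    configurable). The groups must not overlap.
    """
    a_ids = [g for g in group_a if g in summaries.index]
    b_ids = [g for g in group_b if g in summaries.index]
    if set(a_ids) & set(b_ids):
        raise ValueError("gene groups overlap; comparison would be circular")
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise ValueError("each group needs >= 3 genes with occupancy summaries")
    res = stats.mannwhitneyu(summaries[a_ids], summaries[b_ids], alternative=alternative)
    return float(res.pvalue)


def stratify_genes(
    gene_summary: pd.DataFrame,
    n_bins: int = 20,
    seed: int = 0,
    match_p_threshold: float = 0.1,
) -> dict[str, GeneGroup]:
    """Build the standard gene groups for occupancy analysis.

    Input: per-gene ``sense_level``, ``as_s_ratio`` and boolean
    ``called``. Emits (a) sense-level tertiles (ties broken by gene_id),
    (b) the low tertile split at its median AS/S ratio, and (c)
    expression-matched antisense-called vs uncalled groups built by
    stratified subsampling over ``n_bins`` rank bins of sense level;
    the matched groups must pass a two-sided rank test of sense-level
    distribution equality (p > ``match_p_threshold``).
    """
    df = gene_summary.copy()
    for col in ("sense_level", "as_s_ratio", "called"):
        if col not in df.columns:
            raise ValueError(f"gene_summary needs column {col!r}")
    df = df.sort_values(["sense_level", "gene_id"], kind="stable").reset_index(drop=True)
    n = len(df)
    thirds = np.array_split(np.arange(n), 3)
    low = df.loc[thirds[0], "gene_id"].tolist()
    med = df.loc[thirds[1], "gene_id"].tolist()
    high = df.loc[thirds[2], "gene_id"].tolist()
    groups = {
        "low": GeneGroup("low", tuple(low), rule="bottom third of sense level"),
        "medium": GeneGroup("medium", tuple(med), rule="middle third of sense level"),
        "high": GeneGroup("high", tuple(high), rule="top third of sense level"),
    }

    low_df = df[df["gene_id"].isin(low)].sort_values(["as_s_ratio", "gene_id"], kind="stable")
    half = len(low_df) // 2
    groups["low_low_asr"] = GeneGroup(
        "low_low_asr", tuple(low_df["gene_id"].iloc[:half]), rule="low tertile, AS/S below median"
    )
    groups["low_high_asr"] = GeneGroup(
        "low_high_asr", tuple(low_df["gene_id"].iloc[half:]), rule="low tertile, AS/S at or above median"
    )

    # expression-matched called vs uncalled
    rng = np.random.default_rng(seed)
    ranked = df.reset_index(drop=True)
    bins = np.array_split(np.arange(len(ranked)), n_bins)
    sel_called: list[str] = []
    sel_uncalled: list[str] = []
    for b in bins:
        sub = ranked.loc[b]
        c = sub[sub["called"]]["gene_id"].tolist()
        u = sub[~sub["called"]]["gene_id"].tolist()
        k = min(len(c), len(u))
        if k == 0:
            continue
        sel_called += list(rng.choice(c, size=k, replace=False))
        sel_uncalled += list(rng.choice(u, size=k, replace=False))
    if len(sel_called) < 10:
        raise ValueError(
            "expression matching infeasible: called and uncalled sense-level supports barely overlap"
        )
    lv = df.set_index("gene_id")["sense_level"]
    p_match = float(stats.mannwhitneyu(lv[sel_called], lv[sel_uncalled], alternative="two-sided").pvalue)
    if p_match <= match_p_threshold:
        raise ValueError(
            f"matched groups fail the sense-level equality check (p={p_match:.3g} <= {match_p_threshold}); "
            "increase n_bins or inspect the expression distributions"
        )
    groups["as_called_matched"] = GeneGroup(
        "as_called_matched", tuple(sel_called), rule="antisense-called, expression-matched", matched=True
    )
    groups["as_uncalled_matched"] = GeneGroup(
        "as_uncalled_matched", tuple(sel_uncalled), rule="no antisense call, expression-matched", matched=True
    )
    return groups
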