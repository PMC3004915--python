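"""Synthetic stranded-transcriptome generator with a known truth table.

Emulates the study design the analysis modules expect: two conditions
(normal growth ``NM`` and heat shock ``HS``) with replicate libraries of
stranded 36-nt read alignments over a compact gene annotation, plus
splice-junction reads whose true orientation is fixed by annotated
introns, and tiling-array style occupancy probes with an IP and a
whole-cell-extract (WCE) channel.

Model summary
-------------
* Genes are laid out left-to-right in two-gene blocks. The orientation of
  each block (tandem / convergent / divergent) is drawn i.i.d. from
  ``orientation_fractions``; between-block gaps exceed the pairing cutoff
  so the blocks are exactly the adjacent pairs downstream analysis sees.
  (A single chain of abutting genes cannot realize arbitrary
  convergent/divergent fractions, because strand flips alternate between
  the two orientations.)
* Per-gene sense rates are log-normal. A configurable fraction of genes
  is differentially expressed between conditions.
* A fraction ``frac_antisense_loci`` of genes carries true antisense
  transcription, by one of three mechanisms: ``own_promoter``
  (independent antisense rate), ``bidirectional_promoter`` (tandem pairs
  only: the focal gene's antisense is driven by the shared promoter of
  its downstream neighbour and tracks that neighbour's sense rate), and
  ``read_through`` (convergent pairs only: the focal gene's antisense is
  the partner's read-through and tracks the partner's sense rate).
  All other genes have antisense rate exactly 0.
* Replicate counts are Poisson-lognormal: the per-library log-rate
  deviation has variance ``log(1 + nb_dispersion)`` so count mean and
  variance match a negative binomial with that dispersion. For coupled
  pairs the focal antisense deviation shares the partner's deviation with
  weight ``pair_coupling_rho`` (shared log-normal latent factor), so the
  across-library log-level correlation targets rho.
* Every emitted read is placed uniformly in its gene body on the true
  strand, then the *observed* strand is flipped independently with
  probability ``strand_error_rate`` — the strand-assignment error that
  the junction-read QC downstream is designed to estimate.

All randomness derives from ``config.seed`` through per-operation,
per-library ``np.random.default_rng`` streams, so any output is a pure
function of (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .models import GeneModel, pair_orientation

logger = logging.getLogger(__name__)

CONDITIONS = ("NM", "HS")

# rng stream codes, one per operation family
_OP_ANNOTATION = 0
_OP_COUNTS = 1
_OP_BODY_READS = 2
_OP_JUNCTION_READS = 3
_OP_OCCUPANCY = 4
_OP_COUNT_FLIPS = 5


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``chrom_length`` may be left ``None`` to size the chromosome
    automatically; if given and too small for ``n_genes``,
    :func:`simulate_annotation` raises naming the required minimum.
    """

    n_genes: int = 2000
    chrom: str = "chrI"
    chrom_length: Optional[int] = None
    orientation_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"tandem": 1 / 3, "convergent": 1 / 3, "divergent": 1 / 3}
    )
    frac_antisense_loci: float = 0.4
    strand_error_rate: float = 0.005
    sense_rate_log_mean: float = 0.0
    sense_rate_log_sd: float = 1.0
    antisense_multiplier_range: tuple[float, float] = (5.0, 50.0)
    nb_dispersion: float = 0.1
    pair_coupling_rho: float = 0.8
    n_conditions: int = 2
    n_replicates_per_condition: int = 2
    library_depth: int = 250_000
    junction_fraction: float = 0.05
    read_length: int = 36
    intron_length: int = 100
    frac_differential_sense: float = 0.15
    frac_differential_antisense: float = 0.15
    de_fold: float = 4.0
    dominant_fraction_of_antisense: float = 0.15
    dominant_ratio_range: tuple[float, float] = (1.0, 5.0)
    overlap_pair_fraction: float = 0.0
    frac_short_cds: float = 0.0
    probe_spacing: int = 50
    occupancy_noise_sd: float = 0.5
    occupancy_baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        total = sum(self.orientation_fractions.get(k, 0.0) for k in ("tandem", "convergent", "divergent"))
        if abs(total - 1.0) > 1e-9:
            raise ValueError("orientation_fractions must sum to 1")
        if any(v < 0 for v in self.orientation_fractions.values()):
            raise ValueError("orientation_fractions must be non-negative")
        if not (0.0 <= self.strand_error_rate < 0.5):
            raise ValueError("strand_error_rate must be in [0, 0.5)")
        if self.n_conditions != 2:
            raise ValueError("the design is two conditions (NM, HS)")
        if self.n_replicates_per_condition < 2:
            raise ValueError("need >= 2 replicates per condition")
        for name in ("n_genes", "library_depth", "read_length", "nb_dispersion", "de_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.frac_antisense_loci <= 1.0):
            raise ValueError("frac_antisense_loci must be a proportion")
        lo, hi = self.antisense_multiplier_range
        if not (0 < lo <= hi):
            raise ValueError("antisense_multiplier_range must be 0 < lo <= hi")
        if not (0.0 <= self.junction_fraction < 1.0):
            raise ValueError("junction_fraction must be in [0, 1)")

    def library_ids(self) -> list[str]:
        """Deterministic library ordering: NM1..NMk, HS1..HSk."""
        return [f"{c}{r}" for c in CONDITIONS for r in range(1, self.n_replicates_per_condition + 1)]

    def condition_of(self, library_id: str) -> str:
        for c in CONDITIONS:
            if library_id.startswith(c):
                return c
        raise KeyError(f"unknown library {library_id!r}")

    def _library_index(self, library_id: str) -> int:
        try:
            return self.library_ids().index(library_id)
        except ValueError:
            raise KeyError(f"unknown library {library_id!r}") from None

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["orientation_fractions"] = dict(self.orientation_fractions)
        d["antisense_multiplier_range"] = list(self.antisense_multiplier_range)
        d["dominant_ratio_range"] = list(self.dominant_ratio_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("antisense_multiplier_range", "dominant_ratio_range"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthTable:
    """Ground truth of one simulation.

    ``genes``: one row per gene with geometry, mechanism label
    (none / own_promoter / bidirectional_promoter / read_through),
    coupled partner and rho, and the true sense/antisense rates per
    condition (rates are relative weights; expected read count is
    ``depth * rate / sum(all rates of the condition)``).

    ``pairs``: one row per adjacent two-gene block with orientation,
    focal gene (the antisense-carrying gene of a coupled mechanism,
    empty if none) and coupling rho.
    """

    genes: pd.DataFrame
    pairs: pd.DataFrame

    def write(self, genes_path, pairs_path) -> None:
        self.genes.to_csv(genes_path, sep="\t", index=False)
        self.pairs.to_csv(pairs_path, sep="\t", index=False)


def _rng(config: SimulationConfig, op: int, sub: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), op, sub])


def simulate_annotation(config: SimulationConfig) -> tuple[list[GeneModel], TruthTable]:
    """Generate the gene annotation and the simulation truth table."""
    rng = _rng(config, _OP_ANNOTATION)
    n = config.n_genes
    orient_names = ["tandem", "convergent", "divergent"]
    probs = np.array([config.orientation_fractions.get(k, 0.0) for k in orient_names])
    probs = probs / probs.sum()

    n_blocks, odd = divmod(n, 2)
    block_orients = rng.choice(orient_names, size=n_blocks, p=probs)

    # per-gene geometry
    short = rng.random(n) < config.frac_short_cds
    cds_len = np.clip(np.exp(rng.normal(np.log(1200), 0.4, size=n)), 250, 6000).astype(int)
    cds_len = np.where(short, rng.integers(120, 200, size=n), cds_len)
    utr5 = rng.integers(50, 301, size=n)
    utr3 = rng.integers(50, 301, size=n)

    within_gap = rng.integers(150, 801, size=n_blocks)
    overlap_block = rng.random(n_blocks) < config.overlap_pair_fraction
    overlap_amount = rng.integers(20, 81, size=n_blocks)
    between_gap = rng.integers(1500, 3001, size=n_blocks + 1)

    strands: list[str] = []
    for b, o in enumerate(block_orients):
        if o == "tandem":
            s = "+" if rng.random() < 0.5 else "-"
            strands += [s, s]
        elif o == "convergent":
            strands += ["+", "-"]
        else:
            strands += ["-", "+"]
    if odd:
        strands.append("+" if rng.random() < 0.5 else "-")

    # mechanism focal choice for convergent pairs, drawn now for determinism
    conv_focal_left = rng.random(n_blocks) < 0.5

    genes: list[GeneModel] = []
    rows = []
    cursor = 1000
    for i in range(n):
        block = i // 2
        in_block_right = i % 2 == 1 and block < n_blocks
        if i == 0:
            gap = 0
        elif in_block_right:
            if block_orients[block] != "tandem" and overlap_block[block]:
                gap = -int(overlap_amount[block])
            else:
                gap = int(within_gap[block])
        else:
            gap = int(between_gap[block])
        gstart = cursor + gap
        intron = config.intron_length
        glen = int(utr5[i] + cds_len[i] + intron + utr3[i])
        gend = gstart + glen
        strand = strands[i]
        # CDS placed inside the body respecting strand-oriented UTRs
        if strand == "+":
            cstart = gstart + int(utr5[i])
        else:
            cstart = gstart + int(utr3[i])
        cend = cstart + int(cds_len[i]) + intron
        mid = cstart + (int(cds_len[i]) + intron) // 2 - intron // 2
        intron_iv = (mid, mid + intron) if intron > 0 else None
        gid = f"SPSYN{i + 1:05d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=config.chrom,
                strand=strand,
                gene_start=gstart,
                gene_end=gend,
                cds_start=cstart,
                cds_end=cend,
                introns=(intron_iv,) if intron_iv else (),
            )
        )
        rows.append(
            {
                "gene_id": gid,
                "chrom": config.chrom,
                "strand": strand,
                "gene_start": gstart,
                "gene_end": gend,
                "cds_start": cstart,
                "cds_end": cend,
                "intron_start": intron_iv[0] if intron_iv else -1,
                "intron_end": intron_iv[1] if intron_iv else -1,
                "pair_id": f"pair{block + 1:05d}" if (i % 2 == 0 and i + 1 < n) or in_block_right else "",
            }
        )
        cursor = gend

    required = cursor + 1000
    if config.chrom_length is not None and config.chrom_length < required:
        raise ValueError(
            f"chrom_length={config.chrom_length} too small for n_genes={n}; "
            f"requires at least {required} bp"
        )

    gdf = pd.DataFrame(rows)
    gdf["exonic_length"] = (
        gdf["gene_end"] - gdf["gene_start"] - np.where(gdf["intron_start"] >= 0, config.intron_length, 0)
    )

    # ---- truth: mechanisms, couplings, rates -------------------------------
    orientation = np.array([""] * n, dtype=object)
    partner = np.array([""] * n, dtype=object)
    focal_of_pair = np.array([""] * n_blocks, dtype=object)
    for b in range(n_blocks):
        li, ri = 2 * b, 2 * b + 1
        o = block_orients[b]
        orientation[li] = orientation[ri] = o
        if o == "tandem":
            # the shared promoter sits 5' of the downstream gene; its
            # divergent arm runs antisense over the upstream neighbour
            focal_idx = li if strands[li] == "+" else ri
        elif o == "convergent":
            focal_idx = li if conv_focal_left[b] else ri
        else:
            focal_idx = -1
        if focal_idx >= 0:
            focal_of_pair[b] = gdf.loc[focal_idx, "gene_id"]
            other = ri if focal_idx == li else li
            partner[focal_idx] = gdf.loc[other, "gene_id"]

    has_as = rng.random(n) < config.frac_antisense_loci
    mechanism = np.array(["none"] * n, dtype=object)
    coupling_rho = np.zeros(n)
    for i in range(n):
        if not has_as[i]:
            continue
        if partner[i] and orientation[i] == "tandem":
            mechanism[i] = "bidirectional_promoter"
            coupling_rho[i] = config.pair_coupling_rho
        elif partner[i] and orientation[i] == "convergent":
            mechanism[i] = "read_through"
            coupling_rho[i] = config.pair_coupling_rho
        else:
            mechanism[i] = "own_promoter"
    partner = np.where(mechanism == "none", "", np.where(np.isin(mechanism, ["own_promoter"]), "", partner))

    s_base = np.exp(rng.normal(config.sense_rate_log_mean, config.sense_rate_log_sd, size=n))
    de_s = rng.random(n) < config.frac_differential_sense
    de_s_dir = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    s_nm = s_base
    s_hs = s_base * np.where(de_s, config.de_fold ** de_s_dir, 1.0)

    lo, hi = config.antisense_multiplier_range
    mult = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    e_ref = max(config.strand_error_rate, 1e-3)  # background-equivalent unit
    gid_to_idx = {g: i for i, g in enumerate(gdf["gene_id"])}
    a_nm = np.zeros(n)
    a_hs = np.zeros(n)
    de_a = rng.random(n) < config.frac_differential_antisense
    de_a_dir = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    # a slice of own-promoter loci are antisense-dominant: antisense rate
    # drawn as a >=1x multiple of the sense rate instead of a multiple of
    # the strand-error background
    dom = rng.random(n) < config.dominant_fraction_of_antisense
    dlo, dhi = config.dominant_ratio_range
    dom_ratio = np.exp(rng.uniform(np.log(dlo), np.log(dhi), size=n))
    for i in range(n):
        if mechanism[i] == "none":
            continue
        if mechanism[i] == "own_promoter":
            if dom[i]:
                a_nm[i] = dom_ratio[i] * s_base[i]
            else:
                a_nm[i] = mult[i] * e_ref * s_base[i]
            a_hs[i] = a_nm[i] * (config.de_fold ** de_a_dir[i] if de_a[i] else 1.0)
        else:
            j = gid_to_idx[partner[i]]
            a_nm[i] = mult[i] * e_ref * s_nm[j]
            a_hs[i] = mult[i] * e_ref * s_hs[j]

    gdf["orientation"] = orientation
    gdf["mechanism"] = mechanism
    gdf["partner"] = partner
    gdf["coupling_rho"] = coupling_rho
    gdf["sense_rate_NM"] = s_nm
    gdf["sense_rate_HS"] = s_hs
    gdf["as_rate_NM"] = a_nm
    gdf["as_rate_HS"] = a_hs
    gdf["de_sense"] = np.where(de_s, de_s_dir, 0.0)
    gdf["de_antisense"] = np.where((mechanism == "own_promoter") & de_a, de_a_dir, 0.0)

    prows = []
    for b in range(n_blocks):
        li, ri = 2 * b, 2 * b + 1
        gap = int(gdf.loc[ri, "gene_start"] - gdf.loc[li, "gene_end"])
        focal = focal_of_pair[b]
        focal_mech = mechanism[gid_to_idx[focal]] if focal else "none"
        coupled = focal_mech in ("bidirectional_promoter", "read_through")
        prows.append(
            {
                "pair_id": f"pair{b + 1:05d}",
                "left_gene_id": gdf.loc[li, "gene_id"],
                "right_gene_id": gdf.loc[ri, "gene_id"],
                "orientation": block_orients[b],
                "intergenic_distance": gap,
                "overlapping": gap < 0,
                "focal_gene": focal if coupled else "",
                "coupling_rho": config.pair_coupling_rho if coupled else 0.0,
            }
        )
    truth = TruthTable(genes=gdf, pairs=pd.DataFrame(prows))
    return genes, truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _log_sigma(config: SimulationConfig) -> float:
    return float(np.sqrt(np.log1p(config.nb_dispersion)))


def draw_library_counts(truth: TruthTable, config: SimulationConfig, library_id: str) -> pd.DataFrame:
    """True per-gene read counts of one library, before strand error.

    Deterministic in (config.seed, library). Both read-level simulators
    and the count-level fast path draw from this same table, so junction
    and body reads of a library always share one underlying sense count.
    """
    lib_idx = config._library_index(library_id)
    cond = config.condition_of(library_id)
    rng = _rng(config, _OP_COUNTS, lib_idx)
    g = truth.genes
    n = len(g)
    sigma = _log_sigma(config)

    z_s = rng.normal(0.0, sigma, size=n)
    eps = rng.normal(0.0, sigma, size=n)
    gid_to_idx = {gid: i for i, gid in enumerate(g["gene_id"])}
    z_a = eps.copy()
    coupled = (g["coupling_rho"].to_numpy() > 0) & (g["partner"].to_numpy() != "")
    for i in np.flatnonzero(coupled):
        rho = g["coupling_rho"].iat[i]
        j = gid_to_idx[g["partner"].iat[i]]
        z_a[i] = rho * z_s[j] + np.sqrt(1 - rho**2) * eps[i]

    s_rate = g[f"sense_rate_{cond}"].to_numpy() * np.exp(z_s - sigma**2 / 2)
    a_rate = g[f"as_rate_{cond}"].to_numpy() * np.exp(z_a - sigma**2 / 2)
    total = g[f"sense_rate_{cond}"].sum() + g[f"as_rate_{cond}"].sum()

    n_sense = rng.poisson(config.library_depth * s_rate / total)
    n_as = rng.poisson(config.library_depth * a_rate / total)
    n_junction = rng.binomial(n_sense, config.junction_fraction)
    return pd.DataFrame(
        {
            "gene_id": g["gene_id"],
            "library_id": library_id,
            "condition": cond,
            "n_sense": n_sense,
            "n_junction": n_junction,
            "n_antisense": n_as,
        }
    )


def simulate_stranded_counts(truth: TruthTable, config: SimulationConfig) -> pd.DataFrame:
    """Observed per-gene sense/antisense counts for all libraries.

    Count-level fast path: strand-assignment error is applied as binomial
    flips of whole counts rather than per placed read. Expected antisense
    count of a no-antisense gene is exactly Binomial(n_sense, error).
    Adds normalized levels (per kb of strand-appropriate expressed length
    per million library reads).
    """
    e = config.strand_error_rate
    frames = []
    for lib in config.library_ids():
        cnt = draw_library_counts(truth, config, lib)
        rng = _rng(config, _OP_COUNT_FLIPS, config._library_index(lib))
        f_s = rng.binomial(cnt["n_sense"].to_numpy(), e)
        f_a = rng.binomial(cnt["n_antisense"].to_numpy(), e)
        cnt["sense_count"] = cnt["n_sense"] - f_s + f_a
        cnt["antisense_count"] = cnt["n_antisense"] - f_a + f_s
        frames.append(cnt)
    out = pd.concat(frames, ignore_index=True)
    g = truth.genes.set_index("gene_id")
    span = (g["gene_end"] - g["gene_start"]).reindex(out["gene_id"]).to_numpy()
    exonic = g["exonic_length"].reindex(out["gene_id"]).to_numpy()
    totals = out.groupby("library_id")[["sense_count", "antisense_count"]].transform("sum").sum(axis=1).to_numpy()
    out["sense_level"] = out["sense_count"] / (exonic / 1e3) / (totals / 1e6)
    out["antisense_level"] = out["antisense_count"] / (span / 1e3) / (totals / 1e6)
    return out.drop(columns=["n_sense", "n_junction", "n_antisense"])


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _flip_strands(strands: np.ndarray, rng: np.random.Generator, e: float) -> np.ndarray:
    flip = rng.random(strands.size) < e
    flipped = np.where(strands == "+", "-", "+")
    return np.where(flip, flipped, strands)


def simulate_read_alignments(truth: TruthTable, config: SimulationConfig, library_id: str) -> pd.DataFrame:
    """Non-junction stranded reads of one library (bulk DataFrame form)."""
    cnt = draw_library_counts(truth, config, library_id)
    rng = _rng(config, _OP_BODY_READS, config._library_index(library_id))
    g = truth.genes
    rl = config.read_length

    starts_all: list[np.ndarray] = []
    strands_all: list[np.ndarray] = []
    for i in range(len(g)):
        n_body = int(cnt["n_sense"].iat[i] - cnt["n_junction"].iat[i])
        n_as = int(cnt["n_antisense"].iat[i])
        lo = int(g["gene_start"].iat[i])
        hi = int(g["gene_end"].iat[i]) - rl
        hi = max(hi, lo + 1)
        if n_body:
            starts_all.append(rng.integers(lo, hi, size=n_body))
            strands_all.append(np.full(n_body, g["strand"].iat[i]))
        if n_as:
            starts_all.append(rng.integers(lo, hi, size=n_as))
            strands_all.append(np.full(n_as, "-" if g["strand"].iat[i] == "+" else "+"))
    if starts_all:
        starts = np.concatenate(starts_all)
        true_strand = np.concatenate(strands_all)
    else:
        starts = np.empty(0, dtype=int)
        true_strand = np.empty(0, dtype=object)

    observed = _flip_strands(true_strand, rng, config.strand_error_rate)
    return pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": starts,
            "end": starts + rl,
            "strand": observed,
            "is_junction": False,
            "intron_start": -1,
            "intron_end": -1,
            "library_id": library_id,
        }
    )


def simulate_junction_reads(truth: TruthTable, config: SimulationConfig, library_id: str) -> pd.DataFrame:
    """Splice-junction reads of one library.

    Each read spans a gene's annotated intron, so its true orientation is
    the gene strand; the observed strand is flipped with probability
    ``strand_error_rate``. Genes without an intron are skipped with a log
    entry.
    """
    cnt = draw_library_counts(truth, config, library_id)
    rng = _rng(config, _OP_JUNCTION_READS, config._library_index(library_id))
    g = truth.genes
    rl = config.read_length

    rows_start, rows_end, rows_is, rows_ie, strands = [], [], [], [], []
    for i in range(len(g)):
        n_j = int(cnt["n_junction"].iat[i])
        if n_j == 0:
            continue
        istart, iend = int(g["intron_start"].iat[i]), int(g["intron_end"].iat[i])
        if istart < 0:
            logger.warning(
                "gene %s has no intron; %d junction reads skipped", g["gene_id"].iat[i], n_j
            )
            continue
        k = rng.integers(1, rl, size=n_j)  # bases on the upstream-exon side
        rows_start.append(istart - k)
        rows_end.append(iend + (rl - k))
        rows_is.append(np.full(n_j, istart))
        rows_ie.append(np.full(n_j, iend))
        strands.append(np.full(n_j, g["strand"].iat[i]))
    if rows_start:
        start = np.concatenate(rows_start)
        end = np.concatenate(rows_end)
        ispan_s = np.concatenate(rows_is)
        ispan_e = np.concatenate(rows_ie)
        true_strand = np.concatenate(strands)
    else:
        start = end = ispan_s = ispan_e = np.empty(0, dtype=int)
        true_strand = np.empty(0, dtype=object)

    observed = _flip_strands(true_strand, rng, config.strand_error_rate)
    return pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": start,
            "end": end,
            "strand": observed,
            "is_junction": True,
            "intron_start": ispan_s,
            "intron_end": ispan_e,
            "library_id": library_id,
        }
    )


def simulate_library(truth: TruthTable, config: SimulationConfig, library_id: str) -> pd.DataFrame:
    """Body plus junction reads of one library, in deterministic order."""
    body = simulate_read_alignments(truth, config, library_id)
    junc = simulate_junction_reads(truth, config, library_id)
    return pd.concat([body, junc], ignore_index=True)


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

def simulate_occupancy_track(
    genes: Sequence[GeneModel],
    group_assignment: Optional[Mapping[str, str]],
    config: SimulationConfig,
    group_effects: Optional[Mapping[str, float]] = None,
    track: int = 0,
) -> pd.DataFrame:
    """Tiling probes with IP and WCE channels over the gene set.

    The true log2(IP/WCE) of a probe is ``occupancy_baseline`` plus the
    group effect of the gene whose body contains the probe midpoint, plus
    Gaussian noise of sd ``occupancy_noise_sd``. The WCE channel carries
    independent log-normal intensity so that IP/WCE normalization is a
    real operation downstream, not a pass-through.
    """
    rng = _rng(config, _OP_OCCUPANCY, track)
    group_effects = dict(group_effects or {})
    frames = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for gm in genes:
        by_chrom.setdefault(gm.chrom, []).append(gm)
    for chrom in sorted(by_chrom):
        gs = sorted(by_chrom[chrom], key=lambda g: g.gene_start)
        lo = max(0, gs[0].gene_start - 1000)
        hi = gs[-1].gene_end + 1000
        pos = np.arange(lo + config.probe_spacing // 2, hi, config.probe_spacing)
        signal = np.full(pos.size, float(config.occupancy_baseline))
        if group_assignment:
            for gm in gs:
                grp = group_assignment.get(gm.gene_id)
                eff = group_effects.get(grp, 0.0) if grp is not None else 0.0
                if eff:
                    m = (pos >= gm.gene_start) & (pos < gm.gene_end)
                    signal[m] += eff
        if config.occupancy_noise_sd > 0:
            signal = signal + rng.normal(0.0, config.occupancy_noise_sd, size=pos.size)
        wce = np.exp(rng.normal(np.log(1000.0), 0.15, size=pos.size))
        ip = wce * np.exp2(signal)
        frames.append(pd.DataFrame({"chrom": chrom, "position": pos, "ip": ip, "wce": wce}))
    return pd.concat(frames, ignore_index=True)


def expected_antisense_count(truth: TruthTable, config: SimulationConfig, condition: str) -> pd.Series:
    """Expected true antisense read count per gene, summed over the
    replicate libraries of one condition (the scale on which the caller
    tests)."""
    g = truth.genes
    total = g[f"sense_rate_{condition}"].sum() + g[f"as_rate_{condition}"].sum()
    per_lib = config.library_depth * g[f"as_rate_{condition}"] / total
    return pd.Series(
        per_lib.to_numpy() * config.n_replicates_per_condition, index=g["gene_id"], name="expected_antisense"
    )
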