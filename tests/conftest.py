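import mpmath as mp
import numpy as np
import pandas as pd
import pytest

from antiscribe import SimulationConfig, simulate_annotation, simulate_library
from antiscribe.models import GeneModel


@pytest.fixture(scope="session")
def small_sim():
    """A compact dataset exercising all orientations and mechanisms."""
    cfg = SimulationConfig(
        n_genes=60,
        library_depth=30_000,
        n_replicates_per_condition=2,
        overlap_pair_fraction=0.1,
        seed=7,
    )
    genes, truth = simulate_annotation(cfg)
    return cfg, genes, truth


@pytest.fixture(scope="session")
def small_reads(small_sim):
    cfg, genes, truth = small_sim
    frames = [simulate_library(truth, cfg, lib) for lib in cfg.library_ids()]
    return pd.concat(frames, ignore_index=True)


def binom_tail_oracle(a: int, n: int, p_num: int, p_den: int) -> float:
    """Independent oracle: direct cumulative summation of the binomial
    upper tail at 50 significant digits (exact rational p)."""
    if a <= 0:
        return 1.0
    with mp.workdps(50):
        p = mp.mpf(p_num) / p_den
        q = 1 - p
        if a <= n * p:
            s = mp.mpf(0)
            t = q**n  # pmf(0); sum the short lower tail, subtract from 1
            for k in range(0, a):
                s += t
                t = t * (n - k) / (k + 1) * p / q
            return float(1 - s)
        t = mp.binomial(n, a) * p**a * q ** (n - a)
        s = mp.mpf(0)
        k = a
        while k <= n:
            s += t
            if t < s * mp.mpf(10) ** -45:
                break
            t = t * (n - k) / (k + 1) * p / q
            k += 1
        return float(s)


def make_gene(
    gene_id="g1",
    chrom="chr1",
    strand="+",
    start=0,
    end=1000,
    cds=None,
    introns=(),
    biotype="protein_coding",
):
    cds_start, cds_end = cds if cds else (start, end)
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        gene_start=start,
        gene_end=end,
        cds_start=cds_start,
        cds_end=cds_end,
        introns=tuple(introns),
        biotype=biotype,
    )


def make_reads(rows, library_id="L1"):
    """rows: (chrom, start, end, strand[, intron_span])"""
    if not rows:
        return pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "start": pd.Series(dtype=int),
                "end": pd.Series(dtype=int),
                "strand": pd.Series(dtype=str),
                "is_junction": pd.Series(dtype=bool),
                "intron_start": pd.Series(dtype=int),
                "intron_end": pd.Series(dtype=int),
                "library_id": pd.Series(dtype=str),
            }
        )
    recs = []
    for row in rows:
        chrom, start, end, strand = row[:4]
        span = row[4] if len(row) > 4 else None
        recs.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "is_junction": span is not None,
                "intron_start": span[0] if span else -1,
                "intron_end": span[1] if span else -1,
                "library_id": library_id,
            }
        )
    return pd.DataFrame(recs)
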