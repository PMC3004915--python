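"""Background-corrected antisense calling, FDR control, dominance classes.

The null hypothesis for a locus is that every antisense-strand read is a
strand-assignment artifact: given ``n_total = sense + antisense`` reads
over the locus and a library background rate ``p_bg`` (estimated from
splice-junction reads), the antisense count is Binomial(n_total, p_bg).
The reported p-value is the upper tail P(X >= a). An optional negative
binomial null with the same mean and a given dispersion absorbs extra
overdispersion; as dispersion -> 0 it converges to the binomial/Poisson
tail. Multiple testing is Benjamini-Hochberg ("q value"), run within
each condition over all genes; a gene has antisense expression if called
in either condition at q < 0.01.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: pseudocount (raw-count equivalent) used in log2(S/AS)
LOG_RATIO_PSEUDOCOUNT = 0.5


def antisense_tail_test(
    a: int, n_total: int, p_bg: float, dispersion: Optional[float] = None
) -> float:
    """Upper-tail probability of the antisense count under the background null.

    Binomial(n_total, p_bg) when ``dispersion`` is None; otherwise a
    negative binomial with mean ``n_total * p_bg`` and variance
    ``mean + dispersion * mean**2``. ``a = 0`` returns exactly 1.
    """
    if not (0 <= a <= n_total):
        raise ValueError("need 0 <= a <= n_total")
    if not (0.0 < p_bg < 1.0):
        raise ValueError("p_bg must be in (0, 1)")
    if a == 0:
        return 1.0
    if dispersion is None or dispersion == 0:
        return float(stats.binom.sf(a - 1, n_total, p_bg))
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    mean = n_total * p_bg
    size = 1.0 / dispersion  # NB shape; p = size / (size + mean)
    return float(stats.nbinom.sf(a - 1, size, size / (size + mean)))


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, permutation-stable)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def estimate_background_dispersion(
    expr: pd.DataFrame, p_bg: float, quantile: float = 0.1
) -> Optional[float]:
    """Method-of-moments NB dispersion from low-expression genes.

    Uses genes in the bottom ``quantile`` of total read count, whose
    antisense reads should be almost purely background, and matches the
    variance of their antisense counts around the binomial expectation.
    Returns None when the data show no overdispersion (estimate <= 0).
    """
    tot = expr.groupby("gene_id")[["sense_count", "antisense_count"]].sum()
    n = tot.sum(axis=1)
    cut = n.quantile(quantile)
    low = tot[n <= cut]
    if len(low) < 20:
        return None
    ntot = (low["sense_count"] + low["antisense_count"]).to_numpy(dtype=float)
    a = low["antisense_count"].to_numpy(dtype=float)
    mu = ntot * p_bg
    keep = mu > 0
    if keep.sum() < 20:
        return None
    excess = (a[keep] - mu[keep]) ** 2 - mu[keep]
    phi = float(np.sum(excess) / np.sum(mu[keep] ** 2))
    return phi if phi > 0 else None


def _pooled_p_bg(p_bg: Union[float, Mapping[str, float]], libs, weights) -> float:
    if np.isscalar(p_bg):
        return float(p_bg)
    missing = [l for l in libs if l not in p_bg]
    if missing:
        raise ValueError(f"missing p_bg for libraries {missing}; supply a global override")
    w = np.asarray(weights, dtype=float)
    vals = np.array([p_bg[l] for l in libs])
    if w.sum() == 0:
        return float(vals.mean())
    return float(np.sum(w * vals) / w.sum())


def call_antisense_loci(
    expr: pd.DataFrame,
    p_bg: Union[float, Mapping[str, float]],
    q_threshold: float = 0.01,
    dispersion: Optional[float] = None,
    estimate_dispersion: bool = False,
) -> pd.DataFrame:
    """Call high-confidence antisense loci per gene per condition.

    Replicate counts are summed within condition, the background tail
    test applied to the pooled counts (with the read-count-weighted mean
    p_bg when per-library rates are given), and BH run over all genes
    within each condition. Output columns: gene_id, condition, a, n,
    p_value, q_value, called, log2_s_as.
    """
    required = {"gene_id", "library_id", "condition", "sense_count", "antisense_count"}
    if not required.issubset(expr.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")

    if estimate_dispersion and dispersion is None:
        p_for_est = (
            float(np.mean(list(p_bg.values()))) if isinstance(p_bg, Mapping) else float(p_bg)
        )
        dispersion = estimate_background_dispersion(expr, p_for_est)
        if dispersion is not None:
            logger.info("using NB null with estimated dispersion %.4g", dispersion)

    out_frames = []
    for cond, sub in expr.groupby("condition", sort=True):
        libs = sorted(sub["library_id"].unique())
        lib_tot = sub.groupby("library_id")[["sense_count", "antisense_count"]].sum().sum(axis=1)
        pbg_c = _pooled_p_bg(p_bg, libs, [lib_tot.get(l, 0) for l in libs])
        agg = (
            sub.groupby("gene_id")[["sense_count", "antisense_count"]]
            .sum()
            .sort_index()
        )
        a = agg["antisense_count"].to_numpy()
        n = (agg["sense_count"] + agg["antisense_count"]).to_numpy()
        pvals = np.array(
            [antisense_tail_test(int(ai), int(ni), pbg_c, dispersion) if ni > 0 else 1.0 for ai, ni in zip(a, n)]
        )
        qvals = adjust_fdr(pvals)
        log2_s_as = np.log2(
            (agg["sense_count"] + LOG_RATIO_PSEUDOCOUNT)
            / (agg["antisense_count"] + LOG_RATIO_PSEUDOCOUNT)
        )
        out_frames.append(
            pd.DataFrame(
                {
                    "gene_id": agg.index,
                    "condition": cond,
                    "a": a,
                    "n": n,
                    "p_value": pvals,
                    "q_value": qvals,
                    "called": qvals < q_threshold,
                    "log2_s_as": log2_s_as.to_numpy(),
                }
            )
        )
    return pd.concat(out_frames, ignore_index=True)


def antisense_gene_set(calls: pd.DataFrame) -> set[str]:
    """Genes called in either condition ("has antisense expression")."""
    return set(calls.loc[calls["called"], "gene_id"])


def summarize_calls(calls: pd.DataFrame) -> dict:
    genes = calls["gene_id"].unique()
    called = antisense_gene_set(calls)
    per_cond = calls.groupby("condition")["called"].sum().to_dict()
    return {
        "n_genes": int(len(genes)),
        "n_called_either_condition": int(len(called)),
        "fraction_called": float(len(called) / len(genes)) if len(genes) else float("nan"),
        "called_per_condition": {k: int(v) for k, v in per_cond.items()},
    }


def classify_dominance(expr_levels: pd.DataFrame) -> pd.DataFrame:
    """Dominance flags and PP/PN/NP/NN condition categories per gene.

    Input: per (gene, condition) normalized ``sense_level`` and
    ``antisense_level`` (replicate-averaged). Antisense is dominant in a
    condition iff antisense_level >= sense_level (ties count as
    dominant). The category letter of a condition is 'P' when
    sense >= antisense and 'N' when sense < antisense, so at an exact tie
    a gene is both dominant and lettered 'P'. Genes with both levels
    zero in a condition are flagged undefined.
    """
    required = {"gene_id", "condition", "sense_level", "antisense_level"}
    if not required.issubset(expr_levels.columns):
        raise ValueError(f"need columns {sorted(required)}")
    wide_s = expr_levels.pivot_table(index="gene_id", columns="condition", values="sense_level", aggfunc="mean")
    wide_a = expr_levels.pivot_table(index="gene_id", columns="condition", values="antisense_level", aggfunc="mean")
    for c in ("NM", "HS"):
        if c not in wide_s.columns:
            raise ValueError(f"missing condition {c}")
    rows = []
    for gid in wide_s.index:
        s_nm, s_hs = wide_s.loc[gid, "NM"], wide_s.loc[gid, "HS"]
        a_nm, a_hs = wide_a.loc[gid, "NM"], wide_a.loc[gid, "HS"]
        undef = (s_nm == 0 and a_nm == 0) or (s_hs == 0 and a_hs == 0) or any(
            np.isnan(x) for x in (s_nm, s_hs, a_nm, a_hs)
        )
        dom_nm = bool(a_nm >= s_nm)
        dom_hs = bool(a_hs >= s_hs)
        letter = lambda s, a: "P" if s >= a else "N"
        cat = (letter(s_nm, a_nm) + letter(s_hs, a_hs)) if not undef else "undefined"
        rows.append(
            {
                "gene_id": gid,
                "dominant_nm": dom_nm,
                "dominant_hs": dom_hs,
                "category": cat,
                "undefined": undef,
            }
        )
    return pd.DataFrame(rows)
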