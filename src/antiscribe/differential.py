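"""Differential expression (SAM-style permutation test), coordination
classes, rank-sum group comparisons, and Fisher enrichment.

The differential test is a moderated-d permutation test in the style of
significance analysis of microarrays: per gene,
``d = (mean_HS - mean_NM) / (pooled SE + s0)`` on log2 levels, with the
null distribution built from condition-label permutations (exhaustive
when there are <= ``max_exhaustive`` distinct assignments, sampled with
a seed otherwise) and the q-value estimated as the median permutation
count of |d*| above each gene's |d| over the observed count. A
transcript is significant when q < 0.05 and its fold change exceeds 2
(either direction).
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

COORDINATION_CLASSES = ("correlated", "anti-correlated", "independent_AS", "independent_S", "unchanged")


def _label_assignments(
    n_libs: int, n_cond2: int, max_exhaustive: int, n_permutations: int, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    from math import comb

    total = comb(n_libs, n_cond2)
    if total <= max_exhaustive:
        return list(combinations(range(n_libs), n_cond2))
    seen = []
    for _ in range(n_permutations):
        seen.append(tuple(sorted(rng.choice(n_libs, size=n_cond2, replace=False))))
    return seen


def permutation_diff_test(
    levels: pd.DataFrame,
    design: Mapping[str, str],
    n_permutations: int = 300,
    s0: Optional[float] = None,
    q_threshold: float = 0.05,
    fold_threshold: float = 2.0,
    pseudocount: float = 0.5,
    max_exhaustive: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """SAM-style differential test between the two conditions.

    ``levels``: genes x libraries matrix of normalized expression levels
    (linear scale; log2 with pseudocount is taken internally).
    ``design``: library -> condition ("NM"/"HS"). Requires >= 2
    libraries per condition. Returns per gene: d, fold_change (HS/NM on
    linear levels), permutation p, q_value, significant.
    """
    libs = [c for c in levels.columns if c in design]
    if len(libs) != levels.shape[1]:
        missing = [c for c in levels.columns if c not in design]
        raise ValueError(f"libraries missing from design: {missing}")
    cond = np.array([design[l] for l in libs])
    idx_nm = np.flatnonzero(cond == "NM")
    idx_hs = np.flatnonzero(cond == "HS")
    if len(idx_nm) < 2 or len(idx_hs) < 2:
        raise ValueError("need >= 2 libraries per condition")

    x = levels[libs].to_numpy(dtype=float)
    lx = np.log2(x + pseudocount)

    def d_stat(group_hs: np.ndarray, s0_val: float) -> tuple[np.ndarray, np.ndarray]:
        in_hs = np.zeros(len(libs), dtype=bool)
        in_hs[list(group_hs)] = True
        a, b = lx[:, in_hs], lx[:, ~in_hs]
        n1, n2 = a.shape[1], b.shape[1]
        diff = a.mean(axis=1) - b.mean(axis=1)
        pooled_var = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)) / (n1 + n2 - 2)
        se = np.sqrt(pooled_var * (1 / n1 + 1 / n2))
        return diff / (se + s0_val), se

    # s0: median pooled SE over genes for the observed labelling
    _, se_obs = d_stat(idx_hs, 1.0)
    s0_val = float(np.median(se_obs)) if s0 is None else float(s0)
    if s0_val == 0:
        s0_val = 1e-8

    d_obs, _ = d_stat(idx_hs, s0_val)

    rng = np.random.default_rng(seed)
    assignments = _label_assignments(len(libs), len(idx_hs), max_exhaustive, n_permutations, rng)
    d_null = np.stack([d_stat(g, s0_val)[0] for g in assignments])  # (B, genes)

    abs_obs = np.abs(d_obs)
    abs_null = np.abs(d_null)
    # permutation p per gene: one-sided in the fixed HS > NM direction,
    # the fraction of assignments (incl. identity when exhaustive) with
    # d* >= d. Exactly uniform on {1/B..1} under label exchangeability and
    # attains 1/B (1/6 for a 2v2 design). A doubled two-sided companion is
    # also reported; significance itself is decided by the |d|-based q.
    p_up = (d_null >= d_obs[None, :]).mean(axis=0)
    p_down = (d_null <= d_obs[None, :]).mean(axis=0)
    p_perm = p_up
    p_two = np.minimum(1.0, 2.0 * np.minimum(p_up, p_down))

    # q: median over permutations of the genome-wide count of |d*| above
    # each gene's threshold, over the observed count above it
    B = abs_null.shape[0]
    per_perm_counts = np.stack(
        [abs_null[b].size - np.searchsorted(np.sort(abs_null[b]), abs_obs, side="left") for b in range(B)]
    )
    v_med = np.median(per_perm_counts, axis=0)
    sorted_obs = np.sort(abs_obs)
    r_obs = abs_obs.size - np.searchsorted(sorted_obs, abs_obs, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(r_obs > 0, v_med / r_obs, 1.0)
    q = np.minimum(q, 1.0)
    # enforce monotone non-increasing q in |d|
    order = np.argsort(-abs_obs, kind="stable")
    q_sorted = np.minimum.accumulate(q[order])
    q_mono = np.empty_like(q)
    q_mono[order] = q_sorted

    mean_nm = x[:, idx_nm].mean(axis=1)
    mean_hs = x[:, idx_hs].mean(axis=1)
    fold = (mean_hs + pseudocount) / (mean_nm + pseudocount)
    significant = (q_mono < q_threshold) & ((fold > fold_threshold) | (fold < 1 / fold_threshold))

    return pd.DataFrame(
        {
            "gene_id": levels.index,
            "d": d_obs,
            "fold_change": fold,
            "p_permutation": p_perm,
            "p_two_sided": p_two,
            "q_value": q_mono,
            "significant": significant,
        }
    ).set_index("gene_id")


def classify_coordination(diff_sense: pd.DataFrame, diff_antisense: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene one of five sense/antisense coordination classes.

    Both significant and same direction -> correlated; both significant,
    opposite directions -> anti-correlated; only antisense significant ->
    independent_AS; only sense -> independent_S; neither -> unchanged.
    The five classes partition all genes present in both inputs.
    """
    common = diff_sense.index.intersection(diff_antisense.index)
    rows = []
    for gid in common:
        s = diff_sense.loc[gid]
        a = diff_antisense.loc[gid]
        s_sig, a_sig = bool(s["significant"]), bool(a["significant"])
        if s_sig and a_sig:
            same = (s["fold_change"] > 1) == (a["fold_change"] > 1)
            cls = "correlated" if same else "anti-correlated"
        elif a_sig:
            cls = "independent_AS"
        elif s_sig:
            cls = "independent_S"
        else:
            cls = "unchanged"
        rows.append({"gene_id": gid, "coordination": cls})
    return pd.DataFrame(rows).set_index("gene_id")


def compare_as_ratio_distributions(
    values_a: Sequence[float], values_b: Sequence[float], exact_max_n: int = 10
) -> tuple[float, bool]:
    """One-sided Wilcoxon rank-sum p that group A stochastically exceeds B.

    Exact enumeration when both groups have <= ``exact_max_n`` values,
    normal approximation with tie correction otherwise. Returns
    ``(p, degenerate)``; when every value is tied the test is degenerate
    and p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 values")
    if np.unique(np.concatenate([a, b])).size == 1:
        return 1.0, True
    method = "exact" if (len(a) <= exact_max_n and len(b) <= exact_max_n) else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    except ValueError:
        res = stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
    return float(res.pvalue), False


def enrichment_fisher(
    study_set: set,
    population_set: set,
    term_to_genes: Mapping[str, set],
    adjust: bool = True,
) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric upper tail) per functional term.

    2x2 per term: in-study/not x in-term/not over the population. Genes
    not covered by the term map simply count as unannotated. Adds a BH
    column when ``adjust``.
    """
    study = set(study_set)
    population = set(population_set)
    if not study:
        raise ValueError("empty study set")
    if not study.issubset(population):
        raise ValueError("study set must be a subset of the population")
    N = len(population)
    n = len(study)
    rows = []
    for term in sorted(term_to_genes):
        term_genes = set(term_to_genes[term]) & population
        K = len(term_genes)
        k = len(term_genes & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"term": term, "n_term": K, "n_study": n, "n_overlap": k, "p_value": p})
    df = pd.DataFrame(rows)
    if adjust and len(df):
        from .calling import adjust_fdr

        df["q_value"] = adjust_fdr(df["p_value"].to_numpy())
    return df
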