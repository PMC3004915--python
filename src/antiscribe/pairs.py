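"""Gene-pair mechanism analysis: bidirectional promoters and read-through.

For a focal gene with antisense expression, the across-library
correlation of its antisense level with a neighbour's sense level tests
a shared-production mechanism:

* tandem pairs — the promoter of the downstream gene can fire in both
  directions, producing the downstream sense mRNA and an antisense RNA
  over the upstream neighbour; the focal (antisense-carrying) gene is
  the upstream one and the predicted correlate is the downstream
  neighbour's sense level;
* convergent (tail-to-tail) pairs — transcription that fails to
  terminate at one gene's 3' end runs into the other gene as its
  antisense; the predicted correlate is the read-through donor's
  ("upstream") sense level.

Correlations are computed across libraries (conditions x replicates)
per pair on log2 levels with a pseudocount, then pooled across pairs on
the Fisher z scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.5


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-distribution p (n-2 df).

    Zero variance in either vector leaves r undefined: returns
    (nan, nan) rather than 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -0.999999, 0.999999))


def _log_levels(expr: pd.DataFrame, gene_id: str, column: str, libraries: list[str]) -> Optional[np.ndarray]:
    sub = expr[expr["gene_id"] == gene_id].set_index("library_id")[column]
    try:
        vals = sub.loc[libraries].to_numpy(dtype=float)
    except KeyError:
        return None
    if np.isnan(vals).any():
        return None
    return np.log2(vals + PSEUDOCOUNT)


@dataclass
class PooledPairResult:
    """Per-pair correlations plus the pooled across-pairs test."""

    per_pair: pd.DataFrame
    pooled_mean_r_partner: float
    pooled_mean_r_own: float
    pooled_p: float
    n_pairs: int
    fraction_partner_gt_own: float


def _correlate_pairs(
    records: list[dict], expr: pd.DataFrame, libraries: list[str]
) -> pd.DataFrame:
    rows = []
    for rec in records:
        focal, partner, pid, orient = rec["focal"], rec["partner"], rec["pair_id"], rec["orientation"]
        as_focal = _log_levels(expr, focal, "antisense_level", libraries)
        s_focal = _log_levels(expr, focal, "sense_level", libraries)
        s_partner = _log_levels(expr, partner, "sense_level", libraries)
        if as_focal is None or s_partner is None or len(libraries) < 3:
            logger.info("pair %s skipped: missing levels in some libraries", pid)
            continue
        r_partner, p_partner = pearson_with_p(as_focal, s_partner)
        if s_focal is not None:
            r_own, p_own = pearson_with_p(as_focal, s_focal)
        else:
            r_own, p_own = float("nan"), float("nan")
        if np.isnan(r_partner):
            logger.info("pair %s skipped: constant partner or antisense levels", pid)
            continue
        rows.append(
            {
                "pair_id": pid,
                "orientation": orient,
                "focal_gene": focal,
                "partner_gene": partner,
                "r_own": r_own,
                "p_own": p_own,
                "r_partner": r_partner,
                "p_partner": p_partner,
                "n_points": len(libraries),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "orientation",
            "focal_gene",
            "partner_gene",
            "r_own",
            "p_own",
            "r_partner",
            "p_partner",
            "n_points",
        ],
    )


def _pool(per_pair: pd.DataFrame, paired_own_test: bool) -> PooledPairResult:
    if len(per_pair) == 0:
        return PooledPairResult(per_pair, float("nan"), float("nan"), float("nan"), 0, float("nan"))
    z_partner = fisher_z(per_pair["r_partner"].to_numpy())
    r_own = per_pair["r_own"].to_numpy()
    have_own = ~np.isnan(r_own)
    z_own = fisher_z(r_own[have_own])
    mean_r_partner = float(np.tanh(np.mean(z_partner)))
    mean_r_own = float(np.tanh(np.mean(z_own))) if have_own.any() else float("nan")
    if paired_own_test and have_own.sum() >= 6:
        diffs = fisher_z(per_pair.loc[have_own, "r_partner"].to_numpy()) - z_own
        if np.allclose(diffs, 0):
            pooled_p = 1.0
        else:
            pooled_p = float(stats.wilcoxon(diffs, alternative="greater").pvalue)
    elif not paired_own_test and len(z_partner) >= 6:
        if np.allclose(z_partner, 0):
            pooled_p = 1.0
        else:
            pooled_p = float(stats.wilcoxon(z_partner, alternative="greater").pvalue)
    else:
        pooled_p = float("nan")
    frac = float(np.mean(per_pair.loc[have_own, "r_partner"] > per_pair.loc[have_own, "r_own"])) if have_own.any() else float("nan")
    return PooledPairResult(
        per_pair=per_pair,
        pooled_mean_r_partner=mean_r_partner,
        pooled_mean_r_own=mean_r_own,
        pooled_p=pooled_p,
        n_pairs=len(per_pair),
        fraction_partner_gt_own=frac,
    )


def _strand_of(expr_or_map, gene_id):
    return expr_or_map[gene_id]


def tandem_promoter_correlation(
    pairs: pd.DataFrame,
    expr: pd.DataFrame,
    strands: Mapping[str, str],
    libraries: Optional[list[str]] = None,
) -> PooledPairResult:
    """Bidirectional-promoter test over tandem pairs.

    For each tandem pair the focal gene is the upstream one (the gene
    whose 3' end faces the downstream neighbour's promoter): the left
    gene when both are '+', the right gene when both are '-'.
    ``r_partner`` correlates the focal antisense level with the
    downstream neighbour's sense level, ``r_own`` with the focal gene's
    own sense level; pooled by a paired Wilcoxon signed-rank of
    Fisher-z(r_partner) vs Fisher-z(r_own).
    """
    libraries = libraries or sorted(expr["library_id"].unique())
    records = []
    for row in pairs.itertuples(index=False):
        if row.orientation != "tandem":
            continue
        left, right = row.left_gene_id, row.right_gene_id
        if strands[left] == "+":
            focal, partner = left, right
        else:
            focal, partner = right, left
        records.append(
            {
                "pair_id": getattr(row, "pair_id", f"{left}|{right}"),
                "orientation": "tandem",
                "focal": focal,
                "partner": partner,
            }
        )
    per_pair = _correlate_pairs(records, expr, libraries)
    return _pool(per_pair, paired_own_test=True)


def convergent_readthrough_correlation(
    pairs: pd.DataFrame,
    expr: pd.DataFrame,
    libraries: Optional[list[str]] = None,
    focal_genes: Optional[set] = None,
) -> PooledPairResult:
    """Read-through test over convergent pairs.

    Either gene of a convergent pair can be the read-through recipient;
    by default both directions are analyzed (focal = recipient, partner
    = the upstream donor whose sense transcription runs toward the
    focal gene's body). Restrict to ``focal_genes`` — e.g. genes with
    called antisense expression — to test only loci where antisense is
    actually observed. Pooled one-sided Wilcoxon signed-rank that the
    Fisher-z r_partner distribution is centered above 0.
    """
    libraries = libraries or sorted(expr["library_id"].unique())
    records = []
    for row in pairs.itertuples(index=False):
        if row.orientation != "convergent":
            continue
        left, right = row.left_gene_id, row.right_gene_id
        for focal, partner in ((left, right), (right, left)):
            if focal_genes is not None and focal not in focal_genes:
                continue
            records.append(
                {
                    "pair_id": getattr(row, "pair_id", f"{left}|{right}"),
                    "orientation": "convergent",
                    "focal": focal,
                    "partner": partner,
                }
            )
    per_pair = _correlate_pairs(records, expr, libraries)
    return _pool(per_pair, paired_own_test=False)
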