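"""End-to-end orchestration: quantify -> call -> differential -> pairs ->
occupancy, with a run manifest.

Stages communicate through on-disk TSVs in the output directory so any
intermediate is inspectable; the manifest records package and library
versions, the full parameter set, input checksums and per-stage record
counts. A run is a pure function of (inputs, config, seed): re-running
with identical inputs reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    classify_gene_pairs,
    genes_to_frame,
    pairs_to_frame,
    read_gff,
    read_reads_bed,
    write_gff,
    write_reads_bed,
)
from .calling import antisense_gene_set, call_antisense_loci, classify_dominance, summarize_calls
from .differential import classify_coordination, enrichment_fisher, permutation_diff_test
from .occupancy import (
    build_metaprofile,
    compare_group_occupancy,
    gene_region_summary,
    normalize_probes,
    stratify_genes,
)
from .pairs import convergent_readthrough_correlation, tandem_promoter_correlation
from .quantify import count_stranded_reads, estimate_strand_specificity, normalize_expression
from .simulate import SimulationConfig, simulate_annotation, simulate_library, simulate_occupancy_track

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}/{code}] {message}")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    gff: str
    reads: Mapping[str, str]  # library_id -> BED path
    design: Mapping[str, str]  # library_id -> condition
    out_dir: str
    probes: Optional[str] = None
    term_map: Optional[str] = None
    q_call: float = 0.01
    q_diff: float = 0.05
    fold: float = 2.0
    sd_smooth: float = 40.0
    max_intergenic: int = 1000
    cds_min: int = 200
    seed: int = 0

    def validate(self) -> None:
        missing = [lib for lib in self.design if lib not in self.reads]
        if missing:
            raise ValueError(f"libraries without a reads path: {missing}")
        for name in ("q_call", "q_diff", "fold", "sd_smooth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_intergenic < 0 or self.cds_min < 0:
            raise ValueError("max_intergenic and cds_min must be >= 0")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["reads"] = dict(self.reads)
        d["design"] = dict(self.design)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "antiscribe",
        "version": __version__,
        "lib_versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("reads", "design")
        },
        "design": dict(config.design),
        "inputs": {},
        "stages": {},
    }
    manifest["inputs"]["gff"] = _sha256(config.gff)
    for lib, path in sorted(config.reads.items()):
        manifest["inputs"][f"reads:{lib}"] = _sha256(path)
    if config.probes:
        manifest["inputs"]["probes"] = _sha256(config.probes)

    def stage(name, code, fn):
        try:
            return fn()
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, code, str(exc)) from exc

    # ---- annotation --------------------------------------------------------
    genes = stage("annotation", "gff_parse_error", lambda: read_gff(config.gff))
    pairs = classify_gene_pairs(genes, max_intergenic=config.max_intergenic)
    genes_to_frame(genes).to_csv(out / "genes.tsv", sep="\t", index=False)
    pdf = pairs_to_frame(pairs)
    pdf.insert(0, "pair_id", [f"{p.left_gene_id}|{p.right_gene_id}" for p in pairs])
    pdf.to_csv(out / "gene_pairs.tsv", sep="\t", index=False)
    manifest["stages"]["annotation"] = {"n_genes": len(genes), "n_pairs": len(pairs)}

    # ---- quantify ----------------------------------------------------------
    def _quantify():
        frames = [read_reads_bed(config.reads[lib]) for lib in sorted(config.design)]
        reads = pd.concat(frames, ignore_index=True)
        expr, accounting = count_stranded_reads(reads, genes)
        totals = accounting.set_index("library_id")["total_reads"].to_dict()
        expr = normalize_expression(expr, genes, totals)
        qc = []
        for lib in sorted(config.design):
            spec = estimate_strand_specificity(reads, genes, lib)
            qc.append(
                {
                    "library_id": lib,
                    "n_junction_reads": spec.n_junction_reads,
                    "n_wrong_orientation": spec.n_wrong_orientation,
                    "p_bg": spec.p_bg,
                    "ci_low": spec.ci_low,
                    "ci_high": spec.ci_high,
                }
            )
        return expr, accounting, pd.DataFrame(qc)

    expr, accounting, qc = stage("quantify", "counting_error", _quantify)
    expr["condition"] = expr["library_id"].map(config.design)
    expr.to_csv(out / "expression.tsv", sep="\t", index=False)
    accounting.to_csv(out / "accounting.tsv", sep="\t", index=False)
    qc.to_csv(out / "qc_strand_specificity.tsv", sep="\t", index=False)
    manifest["stages"]["quantify"] = {
        "n_records": len(expr),
        "accounting": accounting.to_dict(orient="records"),
    }

    # ---- caller ------------------------------------------------------------
    def _call():
        # guard against a zero junction-error estimate: use the CI upper
        # bound as a conservative background when no wrong reads were seen
        p_bg = {
            r.library_id: (r.p_bg if r.p_bg > 0 else max(r.ci_high / 2, 1e-6))
            for r in qc.itertuples(index=False)
        }
        calls = call_antisense_loci(expr, p_bg, q_threshold=config.q_call)
        level_means = (
            expr.groupby(["gene_id", "condition"])[["sense_level", "antisense_level"]]
            .mean()
            .reset_index()
        )
        dominance = classify_dominance(level_means)
        return calls, dominance

    calls, dominance = stage("caller", "calling_error", _call)
    calls.to_csv(out / "antisense_calls.tsv", sep="\t", index=False)
    dominance.to_csv(out / "dominance.tsv", sep="\t", index=False)
    called_set = antisense_gene_set(calls)
    call_summary = summarize_calls(calls)
    n_dom = int((dominance["dominant_nm"] | dominance["dominant_hs"]).sum())
    manifest["stages"]["caller"] = {
        **call_summary,
        "n_dominant_either_condition": n_dom,
        "fraction_dominant": n_dom / max(len(dominance), 1),
        "category_counts": dominance["category"].value_counts().to_dict(),
    }

    # ---- differential ------------------------------------------------------
    def _diff():
        sense_levels = expr.pivot_table(index="gene_id", columns="library_id", values="sense_level")
        as_levels = expr.pivot_table(index="gene_id", columns="library_id", values="antisense_level")
        diff_s = permutation_diff_test(
            sense_levels, config.design, q_threshold=config.q_diff, fold_threshold=config.fold, seed=config.seed
        )
        as_input = as_levels.loc[sorted(set(as_levels.index) & called_set)]
        if len(as_input) >= 2:
            diff_a = permutation_diff_test(
                as_input, config.design, q_threshold=config.q_diff, fold_threshold=config.fold, seed=config.seed
            )
        else:
            diff_a = diff_s.iloc[0:0]
        coord = classify_coordination(diff_s, diff_a) if len(diff_a) else pd.DataFrame(columns=["coordination"])
        return diff_s, diff_a, coord

    diff_s, diff_a, coord = stage("differential", "diff_test_error", _diff)
    diff_s.assign(strand_class="sense").to_csv(out / "differential_sense.tsv", sep="\t")
    diff_a.assign(strand_class="antisense").to_csv(out / "differential_antisense.tsv", sep="\t")
    coord.to_csv(out / "coordination.tsv", sep="\t")
    manifest["stages"]["differential"] = {
        "n_sense_significant": int(diff_s["significant"].sum()),
        "n_antisense_significant": int(diff_a["significant"].sum()) if len(diff_a) else 0,
        "coordination_counts": coord["coordination"].value_counts().to_dict() if len(coord) else {},
    }

    # ---- enrichment (optional) --------------------------------------------
    if config.term_map:
        def _enrich():
            tm = pd.read_csv(config.term_map, sep="\t", header=None, names=["term", "gene_id"])
            term_to_genes = {t: set(g["gene_id"]) for t, g in tm.groupby("term")}
            population = {g.gene_id for g in genes}
            study = called_set & population
            return enrichment_fisher(study, population, term_to_genes)

        enr = stage("enrichment", "fisher_error", _enrich)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"]["enrichment"] = {"n_terms": len(enr)}

    # ---- pairs -------------------------------------------------------------
    def _pairs():
        strands = {g.gene_id: g.strand for g in genes}
        tandem = tandem_promoter_correlation(pdf, expr, strands)
        convergent = convergent_readthrough_correlation(pdf, expr, focal_genes=called_set)
        return tandem, convergent

    tandem_res, conv_res = stage("pairs", "pair_correlation_error", _pairs)
    tandem_res.per_pair.to_csv(out / "pairs_tandem.tsv", sep="\t", index=False)
    conv_res.per_pair.to_csv(out / "pairs_convergent.tsv", sep="\t", index=False)
    manifest["stages"]["pairs"] = {
        "tandem": {
            "n_pairs": tandem_res.n_pairs,
            "mean_r_partner": tandem_res.pooled_mean_r_partner,
            "mean_r_own": tandem_res.pooled_mean_r_own,
            "pooled_p": tandem_res.pooled_p,
            "fraction_partner_gt_own": tandem_res.fraction_partner_gt_own,
        },
        "convergent": {
            "n_pairs": conv_res.n_pairs,
            "mean_r_partner": conv_res.pooled_mean_r_partner,
            "pooled_p": conv_res.pooled_p,
        },
    }

    # ---- occupancy (optional) ---------------------------------------------
    if config.probes:
        def _occupancy():
            probes = normalize_probes(pd.read_csv(config.probes, sep="\t"))
            eps = 1e-3
            lv = expr.groupby("gene_id")[["sense_level", "antisense_level"]].mean()
            summary = pd.DataFrame(
                {
                    "gene_id": lv.index,
                    "sense_level": lv["sense_level"].to_numpy(),
                    "as_s_ratio": (lv["antisense_level"] + eps).to_numpy() / (lv["sense_level"] + eps).to_numpy(),
                    "called": [g in called_set for g in lv.index],
                }
            )
            groups = stratify_genes(summary, seed=config.seed)
            by_id = {g.gene_id: g for g in genes}
            profiles = []
            for gid, grp in groups.items():
                members = [by_id[x] for x in grp.gene_ids if by_id[x].cds_length >= config.cds_min]
                if not members:
                    continue
                mp = build_metaprofile(
                    probes, members, group_id=gid, sd=config.sd_smooth, cds_min=config.cds_min
                )
                profiles.append(mp.to_frame())
            body = gene_region_summary(probes, genes, region="body", cds_min=config.cds_min)
            tests = {}
            tests["called_vs_uncalled_body_p"] = compare_group_occupancy(
                groups["as_called_matched"].gene_ids, groups["as_uncalled_matched"].gene_ids, body
            )
            tests["low_highASR_vs_lowASR_body_p"] = compare_group_occupancy(
                groups["low_high_asr"].gene_ids, groups["low_low_asr"].gene_ids, body
            )
            return pd.concat(profiles, ignore_index=True), tests

        profiles, occ_tests = stage("occupancy", "occupancy_error", _occupancy)
        profiles.to_csv(out / "occupancy_profiles.tsv", sep="\t", index=False)
        manifest["stages"]["occupancy"] = {"n_profile_rows": len(profiles), "tests": occ_tests}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


# ---------------------------------------------------------------------------
# demo dataset
# ---------------------------------------------------------------------------

def make_demo(
    seed: int = 0,
    out_dir: str = "demo_data",
    n_genes: int = 2000,
    library_depth: int = 250_000,
    n_replicates_per_condition: int = 4,
    h2az_effect: float = 1.0,
) -> tuple[RunConfig, SimulationConfig]:
    """Write a complete desk-scale synthetic dataset plus its RunConfig.

    Defaults emulate the study design: ~2000 genes, 8 libraries (two
    conditions x 4 replicate libraries), ~2 million reads in total, plus
    an H2A.Z-style occupancy track elevated over antisense-positive
    gene bodies.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = SimulationConfig(
        n_genes=n_genes,
        library_depth=library_depth,
        n_replicates_per_condition=n_replicates_per_condition,
        overlap_pair_fraction=0.02,
        frac_short_cds=0.01,
        seed=seed,
    )
    genes, truth = simulate_annotation(sim)
    write_gff(genes, str(out / "annotation.gff3"))
    truth.write(out / "truth_genes.tsv", out / "truth_pairs.tsv")

    reads_paths = {}
    for lib in sim.library_ids():
        reads = simulate_library(truth, sim, lib)
        path = out / f"reads_{lib}.bed"
        write_reads_bed(reads, str(path))
        reads_paths[lib] = str(path)

    group_assignment = {
        row.gene_id: ("antisense" if row.mechanism != "none" else "background")
        for row in truth.genes.itertuples(index=False)
    }
    probes = simulate_occupancy_track(
        genes, group_assignment, sim, group_effects={"antisense": h2az_effect}
    )
    probes.to_csv(out / "probes_h2az.tsv", sep="\t", index=False)

    design = {lib: sim.condition_of(lib) for lib in sim.library_ids()}
    run = RunConfig(
        gff=str(out / "annotation.gff3"),
        reads=reads_paths,
        design=design,
        probes=str(out / "probes_h2az.tsv"),
        out_dir=str(out / "results"),
        seed=seed,
    )
    run.to_yaml(out / "run_config.yaml")
    sim.to_yaml(out / "sim_config.yaml")
    return run, sim
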