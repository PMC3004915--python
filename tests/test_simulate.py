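"""Generator: geometry, determinism, count model, strand error, coupling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from antiscribe import (
    SimulationConfig,
    simulate_annotation,
    simulate_junction_reads,
    simulate_library,
    simulate_occupancy_track,
    simulate_read_alignments,
    simulate_stranded_counts,
)
from antiscribe.pairs import fisher_z


def _cfg(**kw):
    base = dict(n_genes=40, library_depth=20_000, seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestAnnotation:
    def test_two_convergent_genes_face_tail_to_tail(self):
        cfg = _cfg(n_genes=2, orientation_fractions={"tandem": 0, "convergent": 1, "divergent": 0})
        genes, truth = simulate_annotation(cfg)
        assert [g.strand for g in genes] == ["+", "-"]
        assert genes[0].gene_end <= genes[1].gene_start + 100  # 3' ends facing
        assert list(truth.pairs["orientation"]) == ["convergent"]

    def test_same_seed_identical_annotation(self):
        g1, t1 = simulate_annotation(_cfg(seed=5))
        g2, t2 = simulate_annotation(_cfg(seed=5))
        assert g1 == g2
        pd.testing.assert_frame_equal(t1.genes, t2.genes)
        g3, _ = simulate_annotation(_cfg(seed=6))
        assert g1 != g3

    def test_orientation_fractions_multinomial(self):
        # chi-square GOF of realized orientation counts over 20 seeds
        n_pass = 0
        for seed in range(20):
            cfg = _cfg(n_genes=300, seed=seed)
            _, truth = simulate_annotation(cfg)
            counts = truth.pairs["orientation"].value_counts()
            obs = [counts.get(k, 0) for k in ("tandem", "convergent", "divergent")]
            p = stats.chisquare(obs).pvalue
            n_pass += p > 0.01
        assert n_pass >= 18

    def test_chrom_too_small_names_required_minimum(self):
        with pytest.raises(ValueError, match="requires at least"):
            simulate_annotation(_cfg(n_genes=50, chrom_length=10_000))

    def test_truth_table_invariants(self, small_sim):
        _, genes, truth = small_sim
        g = truth.genes
        none = g[g.mechanism == "none"]
        assert (none[["as_rate_NM", "as_rate_HS"]] == 0).all().all()
        assert set(g.loc[g.mechanism == "bidirectional_promoter", "orientation"]) <= {"tandem"}
        assert set(g.loc[g.mechanism == "read_through", "orientation"]) <= {"convergent"}
        # genes are placed left to right without unannotated overlaps
        # except the configured overlapping pairs
        overlap_pairs = truth.pairs[truth.pairs["overlapping"]]
        assert (overlap_pairs["orientation"] != "tandem").all()

    def test_config_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            _cfg(orientation_fractions={"tandem": 0.9, "convergent": 0.3, "divergent": 0.0})
        with pytest.raises(ValueError, match="strand_error_rate"):
            _cfg(strand_error_rate=0.7)


class TestReads:
    def test_no_error_no_antisense_reads_on_silent_loci(self):
        cfg = _cfg(strand_error_rate=0.0, frac_antisense_loci=0.0)
        _, truth = simulate_annotation(cfg)
        expr = simulate_stranded_counts(truth, cfg)
        assert (expr["antisense_count"] == 0).all()
        reads = simulate_read_alignments(truth, cfg, "NM1")
        strand_of = dict(zip(truth.genes.gene_id, truth.genes.strand))
        # every read lies in some gene body on the gene's strand
        for row in reads.sample(min(len(reads), 200), random_state=0).itertuples():
            hit = truth.genes[(truth.genes.gene_start <= row.start) & (truth.genes.gene_end >= row.end)]
            assert len(hit) == 1
            assert row.strand == strand_of[hit.iloc[0].gene_id]

    def test_antisense_counts_follow_strand_error_binomial(self):
        # with no true antisense, the antisense count given n_total reads
        # is exactly Binomial(n_total, e); check 99% central coverage
        e = 0.005
        hits = 0
        n_trials = 100
        for seed in range(n_trials):
            cfg = SimulationConfig(
                n_genes=4,
                library_depth=40_000,
                frac_antisense_loci=0.0,
                strand_error_rate=e,
                sense_rate_log_sd=0.05,
                seed=seed,
            )
            _, truth = simulate_annotation(cfg)
            expr = simulate_stranded_counts(truth, cfg)
            row = expr.iloc[0]
            n_total = int(row.sense_count + row.antisense_count)
            lo, hi = stats.binom.interval(0.99, n_total, e)
            hits += lo <= row.antisense_count <= hi
        assert hits >= 95

    def test_depth_scaling_doubles_totals(self):
        cfg1 = _cfg(n_genes=100, library_depth=100_000, seed=3)
        cfg2 = _cfg(n_genes=100, library_depth=200_000, seed=3)
        _, t1 = simulate_annotation(cfg1)
        _, t2 = simulate_annotation(cfg2)
        n1 = len(simulate_library(t1, cfg1, "NM1"))
        n2 = len(simulate_library(t2, cfg2, "NM1"))
        assert 1.9 <= n2 / n1 <= 2.1

    def test_reads_deterministic_and_in_bounds(self, small_sim, small_reads):
        cfg, genes, truth = small_sim
        again = simulate_library(truth, cfg, "NM1")
        pd.testing.assert_frame_equal(again, simulate_library(truth, cfg, "NM1"))
        assert (small_reads["start"] < small_reads["end"]).all()
        assert small_reads["start"].min() >= 0


class TestJunctions:
    def test_no_error_all_junctions_correct(self):
        cfg = _cfg(strand_error_rate=0.0, junction_fraction=0.2)
        _, truth = simulate_annotation(cfg)
        junc = simulate_junction_reads(truth, cfg, "NM1")
        strand_of = truth.genes.set_index("intron_start")["strand"]
        assert len(junc) > 100
        assert (junc["strand"].to_numpy() == strand_of[junc["intron_start"]].to_numpy()).all()
        # footprint includes the intron span
        assert ((junc["end"] - junc["start"]) == cfg.read_length + cfg.intron_length).all()

    def test_wrong_orientation_fraction_matches_binomial(self):
        e = 0.005
        cfg = SimulationConfig(
            n_genes=10, library_depth=25_000, junction_fraction=0.5, strand_error_rate=e, seed=2
        )
        _, truth = simulate_annotation(cfg)
        junc = simulate_junction_reads(truth, cfg, "NM1")
        strand_of = truth.genes.set_index("intron_start")["strand"]
        wrong = (junc["strand"].to_numpy() != strand_of[junc["intron_start"]].to_numpy()).sum()
        n = len(junc)
        lo, hi = stats.binom.interval(0.99, n, e)
        assert lo <= wrong <= hi

    def test_concordance_in_observed_regime(self):
        # strand error at the center of the observed 0.4-0.6% band gives
        # 99.4-99.6% correctly oriented junction reads
        cfg = SimulationConfig(
            n_genes=20, library_depth=100_000, junction_fraction=0.5, strand_error_rate=0.005, seed=4
        )
        _, truth = simulate_annotation(cfg)
        junc = simulate_junction_reads(truth, cfg, "NM1")
        strand_of = truth.genes.set_index("intron_start")["strand"]
        correct = (junc["strand"].to_numpy() == strand_of[junc["intron_start"]].to_numpy()).mean()
        assert len(junc) > 20_000
        assert 0.994 <= correct <= 0.996


class TestCoupling:
    def test_coupled_pairs_recover_rho_at_many_replicates(self):
        # across >= 50 library points the log-level correlation of focal
        # antisense vs partner sense approaches the target rho
        cfg = SimulationConfig(
            n_genes=60,
            orientation_fractions={"tandem": 1.0, "convergent": 0.0, "divergent": 0.0},
            frac_antisense_loci=1.0,
            frac_differential_sense=0.0,
            frac_differential_antisense=0.0,
            dominant_fraction_of_antisense=0.0,
            antisense_multiplier_range=(60.0, 60.0),
            sense_rate_log_sd=0.3,
            n_replicates_per_condition=25,
            library_depth=150_000,
            pair_coupling_rho=0.8,
            seed=9,
        )
        _, truth = simulate_annotation(cfg)
        expr = simulate_stranded_counts(truth, cfg)
        piv_s = expr.pivot_table(index="gene_id", columns="library_id", values="sense_level")
        piv_a = expr.pivot_table(index="gene_id", columns="library_id", values="antisense_level")
        zs = []
        focal_pairs = truth.pairs[truth.pairs["focal_gene"] != ""]
        assert len(focal_pairs) >= 25
        for row in focal_pairs.itertuples():
            partner = (
                row.right_gene_id if row.focal_gene == row.left_gene_id else row.left_gene_id
            )
            x = np.log2(piv_a.loc[row.focal_gene].to_numpy() + 0.5)
            y = np.log2(piv_s.loc[partner].to_numpy() + 0.5)
            zs.append(fisher_z(np.corrcoef(x, y)[0, 1]))
        mean_r = np.tanh(np.mean(zs))
        assert abs(mean_r - 0.8) <= 0.1


class TestOccupancySim:
    def test_flat_profile_without_noise_or_effect(self, small_sim):
        cfg, genes, _ = small_sim
        flat_cfg = SimulationConfig(
            n_genes=cfg.n_genes, occupancy_noise_sd=0.0, occupancy_baseline=0.7, seed=cfg.seed
        )
        probes = simulate_occupancy_track(genes, None, flat_cfg)
        ratio = np.log2(probes["ip"] / probes["wce"])
        assert np.allclose(ratio, 0.7)

    def test_same_seed_identical_probe_table(self, small_sim):
        cfg, genes, truth = small_sim
        grp = {g: "a" for g in truth.genes.gene_id}
        p1 = simulate_occupancy_track(genes, grp, cfg, group_effects={"a": 1.0})
        p2 = simulate_occupancy_track(genes, grp, cfg, group_effects={"a": 1.0})
        pd.testing.assert_frame_equal(p1, p2)
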