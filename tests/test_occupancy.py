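"""Gene-frame mapping, Gaussian smoothing, metaprofiles, stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from antiscribe import (
    SimulationConfig,
    assign_probes_to_frame,
    build_metaprofile,
    compare_group_occupancy,
    gaussian_smooth,
    simulate_annotation,
    simulate_occupancy_track,
    stratify_genes,
)
from antiscribe.occupancy import gene_region_summary, normalize_probes

from conftest import make_gene


def _probes(positions, values, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "position": positions, "log2_ratio": values})


class TestFrame:
    def test_upstream_probe_negative_position(self):
        g = make_gene("g", strand="+", start=0, end=2000, cds=(500, 1500))
        out = assign_probes_to_frame(_probes([400], [1.0]), g)
        assert out.iloc[0]["rel_pos"] == -100

    def test_minus_strand_mirrored(self):
        # same physical offsets map to the same frame coordinates on
        # either strand after mirroring
        plus = make_gene("p", strand="+", start=0, end=2000, cds=(500, 1500))
        minus = make_gene("m", strand="-", start=0, end=2000, cds=(500, 1500))
        # 100 bp upstream of the ORF start
        up_plus = assign_probes_to_frame(_probes([400], [1.0]), plus).iloc[0]["rel_pos"]
        up_minus = assign_probes_to_frame(_probes([1599], [1.0]), minus).iloc[0]["rel_pos"]
        assert up_plus == up_minus == -100
        # 100 bp downstream (3') of the ORF end; positions are measured
        # from the first transcribed ORF base, so 100 bp past the last
        # ORF base is +99 relative to the ORF-end anchor on both strands
        dn_plus = assign_probes_to_frame(_probes([1599], [1.0]), plus, anchor="ORF_end").iloc[0]["rel_pos"]
        dn_minus = assign_probes_to_frame(_probes([400], [1.0]), minus, anchor="ORF_end").iloc[0]["rel_pos"]
        assert dn_plus == dn_minus == 99

    def test_probes_beyond_flank_excluded(self):
        g = make_gene("g", strand="+", start=0, end=10_000, cds=(4000, 6000))
        out = assign_probes_to_frame(_probes([100, 3500, 5000], [1.0, 1.0, 1.0]), g)
        assert list(out["rel_pos"]) == [-500, 1000]

    def test_short_cds_excluded(self):
        g = make_gene("g", strand="+", start=0, end=1000, cds=(400, 550))
        with pytest.raises(ValueError, match="CDS 150"):
            assign_probes_to_frame(_probes([450], [1.0]), g)

    def test_wce_normalization_requires_positive(self):
        with pytest.raises(ValueError, match="whole-cell-extract"):
            normalize_probes(pd.DataFrame({"chrom": ["c"], "position": [1], "ip": [2.0], "wce": [0.0]}))


class TestSmoother:
    def test_single_point_constant(self):
        out = gaussian_smooth([0.0], [3.5], 40.0, np.linspace(-500, 500, 11))
        assert np.allclose(out, 3.5)

    def test_two_point_kernel_ratio_closed_form(self):
        out = gaussian_smooth([-40.0, 40.0], [0.0, 1.0], 40.0, [-40.0])
        expect = np.exp(-2.0) / (1 + np.exp(-2.0))  # 0.11920292...
        assert out[0] == pytest.approx(expect, abs=1e-9)
        assert out[0] == pytest.approx(0.1192, abs=5e-5)

    def test_all_equal_values_flat(self):
        out = gaussian_smooth(np.arange(0, 1000, 50), np.full(20, 2.0), 40.0, np.arange(0, 1000, 10))
        assert np.allclose(out, 2.0)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 1000, 50)
        val = rng.normal(size=50)
        out = gaussian_smooth(pos, val, 40.0, np.linspace(0, 1000, 200))
        ok = ~np.isnan(out)
        assert (out[ok] >= val.min() - 1e-12).all() and (out[ok] <= val.max() + 1e-12).all()

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            gaussian_smooth([], [], 40.0, [0.0])


class TestMetaprofile:
    def _flat_setup(self, baseline=1.0, noise=0.0, effect=0.0, n_genes=30, seed=5):
        cfg = SimulationConfig(
            n_genes=n_genes,
            occupancy_baseline=baseline,
            occupancy_noise_sd=noise,
            seed=seed,
        )
        genes, truth = simulate_annotation(cfg)
        groups = {g.gene_id: "g" for g in genes}
        probes = simulate_occupancy_track(genes, groups, cfg, group_effects={"g": effect})
        return genes, normalize_probes(probes)

    def test_flat_track_flat_profile(self):
        genes, probes = self._flat_setup(baseline=1.0)
        mp = build_metaprofile(probes, genes)
        assert np.allclose(mp.mean, 1.0)
        assert np.allclose(mp.sd, 0.0)
        assert mp.n_genes == len([g for g in genes if g.cds_length >= 200])

    def test_body_effect_recovered_in_body_only(self):
        # elevate alternating genes only, so the flanks of elevated genes
        # face unelevated neighbours and stay at baseline
        cfg = SimulationConfig(n_genes=60, occupancy_noise_sd=0.2, seed=5)
        genes, _ = simulate_annotation(cfg)
        assign = {g.gene_id: ("A" if i % 2 == 0 else "B") for i, g in enumerate(genes)}
        probes = normalize_probes(
            simulate_occupancy_track(genes, assign, cfg, group_effects={"A": 1.5})
        )
        group_a = [g for i, g in enumerate(genes) if i % 2 == 0]
        mp = build_metaprofile(probes, group_a)
        pos = np.array(mp.positions)
        mean = np.array(mp.mean)
        body = (pos >= 20) & (pos <= 80)  # inner gene body bins
        far_flank = pos <= -500
        assert mean[body].mean() == pytest.approx(1.5, abs=0.2)
        assert abs(mean[far_flank].mean()) < 0.3

    def test_deterministic(self):
        genes, probes = self._flat_setup(noise=0.3)
        a = build_metaprofile(probes, genes)
        b = build_metaprofile(probes, genes)
        assert a.mean == b.mean and a.sd == b.sd

    def test_empty_group_after_filter_errors(self):
        g = make_gene("g", strand="+", start=0, end=1000, cds=(400, 550))
        with pytest.raises(ValueError, match="CDS"):
            build_metaprofile(_probes([450], [1.0]), [g], group_id="tiny")


class TestStratify:
    def _summary(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        level = rng.lognormal(2, 1, n)
        called = rng.random(n) < 0.4
        ratio = np.where(rng.random(n) < 0.5, rng.uniform(0.5, 2.0, n), rng.uniform(0.0, 0.05, n))
        return pd.DataFrame(
            {"gene_id": [f"g{i:04d}" for i in range(n)], "sense_level": level, "as_s_ratio": ratio, "called": called}
        )

    def test_tertiles_of_equal_size(self):
        groups = stratify_genes(self._summary(300))
        assert len(groups["low"].gene_ids) == len(groups["medium"].gene_ids) == len(groups["high"].gene_ids) == 100

    def test_as_ratio_split_recovers_planted_labels(self):
        df = self._summary(300, seed=1)
        groups = stratify_genes(df)
        high = set(groups["low_high_asr"].gene_ids)
        truth_high = set(df[df["as_s_ratio"] > 0.2]["gene_id"]) & set(groups["low"].gene_ids)
        inter = len(high & truth_high) / max(len(truth_high), 1)
        assert inter >= 0.95

    def test_matched_groups_pass_equality_by_construction(self):
        groups = stratify_genes(self._summary(400, seed=2))
        a, b = groups["as_called_matched"], groups["as_uncalled_matched"]
        assert len(a.gene_ids) == len(b.gene_ids)
        assert a.matched and b.matched
        assert not (set(a.gene_ids) & set(b.gene_ids))


class TestGroupComparison:
    def _two_group_setup(self, effect, n_per_group=200, seed=3, noise=0.5):
        cfg = SimulationConfig(
            n_genes=2 * n_per_group, occupancy_noise_sd=noise, seed=seed
        )
        genes, _ = simulate_annotation(cfg)
        assign = {g.gene_id: ("A" if i % 2 == 0 else "B") for i, g in enumerate(genes)}
        probes = normalize_probes(
            simulate_occupancy_track(genes, assign, cfg, group_effects={"A": effect})
        )
        summary = gene_region_summary(probes, genes, region="body")
        a = [g for g, v in assign.items() if v == "A"]
        b = [g for g, v in assign.items() if v == "B"]
        return a, b, summary

    def test_power_at_unit_effect(self):
        a, b, summary = self._two_group_setup(effect=1.0)
        p = compare_group_occupancy(a, b, summary)
        assert p < 1e-10

    def test_identical_groups_error(self):
        a, b, summary = self._two_group_setup(effect=0.0, n_per_group=20)
        with pytest.raises(ValueError, match="overlap"):
            compare_group_occupancy(a, a, summary)

    def test_sign_recovery_at_moderate_effect(self):
        a, b, summary = self._two_group_setup(effect=0.25, n_per_group=100, seed=8)
        assert compare_group_occupancy(a, b, summary) < 0.05
        assert compare_group_occupancy(b, a, summary) > 0.5
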