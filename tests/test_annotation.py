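"""GFF round-trips, pair classification, mappability, wiggle tracks."""

import numpy as np
import pytest

from antiscribe import (
    classify_gene_pairs,
    compute_mappability,
    read_gff,
    simulate_annotation,
    simulate_library,
    write_gff,
    write_wiggle,
)
from antiscribe.annotation import (
    coverage_per_base,
    read_reads_bed,
    revcomp,
    wiggle_mass,
    write_reads_bed,
)
from antiscribe.models import GeneModel, pair_orientation

from conftest import make_gene, make_reads


class TestGff:
    def test_one_based_inclusive_to_half_open(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "chr1\tx\texon\t1\t100\t.\t+\t.\tParent=g1\n"
            "chr1\tx\tCDS\t1\t100\t.\t+\t0\tParent=g1\n"
        )
        (g,) = read_gff(str(p))
        assert (g.gene_start, g.gene_end) == (0, 100)
        assert g.introns == ()

    def test_intron_from_exon_gap(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "chr1\tx\texon\t1\t50\t.\t+\t.\tParent=g1\n"
            "chr1\tx\texon\t61\t100\t.\t+\t.\tParent=g1\n"
            "chr1\tx\tCDS\t11\t90\t.\t+\t0\tParent=g1\n"
        )
        (g,) = read_gff(str(p))
        assert g.introns == ((50, 60),)
        assert g.exonic_length == 90

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("chr1\tx\tgene\t1\t100\t.\t+\t.\tID=g1\nchr1\tgene\toops\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gff(str(p))

    def test_cds_outside_gene_rejected(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(
            "chr1\tx\tgene\t10\t100\t.\t+\t.\tID=g1\n"
            "chr1\tx\texon\t10\t100\t.\t+\t.\tParent=g1\n"
            "chr1\tx\tCDS\t5\t100\t.\t+\t0\tParent=g1\n"
        )
        with pytest.raises(ValueError, match="CDS"):
            read_gff(str(p))

    def test_round_trip_identity(self, tmp_path, small_sim):
        _, genes, _ = small_sim
        p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
        write_gff(genes, str(p1))
        back = read_gff(str(p1))
        assert back == sorted(genes, key=lambda g: (g.chrom, g.gene_start, g.gene_id))
        write_gff(back, str(p2))
        assert p1.read_text() == p2.read_text()

    def test_reads_bed_round_trip(self, tmp_path, small_reads):
        p = tmp_path / "r.bed"
        sub = small_reads.head(500)
        write_reads_bed(sub, str(p))
        back = read_reads_bed(str(p))
        assert (back["start"] == sub["start"].to_numpy()).all()
        assert (back["is_junction"] == sub["is_junction"].to_numpy()).all()


class TestGenePairs:
    def test_orientation_rules(self):
        a = make_gene("a", strand="+", start=0, end=1000)
        assert pair_orientation("+", "-") == "convergent"
        b = make_gene("b", strand="-", start=1200, end=2200)
        (p,) = classify_gene_pairs([a, b])
        assert p.orientation == "convergent"
        assert p.intergenic_distance == 200
        c = make_gene("c", strand="+", start=1200, end=2200)
        a2 = make_gene("a2", strand="-", start=0, end=1000)
        (p2,) = classify_gene_pairs([a2, c])
        assert p2.orientation == "divergent"

    def test_distance_cutoff_excludes(self):
        a = make_gene("a", strand="+", start=0, end=1000)
        b = make_gene("b", strand="+", start=6000, end=7000)
        assert classify_gene_pairs([a, b], max_intergenic=1000) == []

    def test_strand_flip_and_mirror_symmetry(self, small_sim):
        # coordinate mirroring alone swaps convergent <-> divergent (a 3'-3'
        # pair becomes 5'-5'); adding a global strand flip restores each
        # gene's pointing direction, so the combined transform preserves
        # every orientation
        _, genes, _ = small_sim
        pairs = classify_gene_pairs(genes)
        hi = max(g.gene_end for g in genes) + 100

        def transform(flip_strand: bool):
            return [
                GeneModel(
                    gene_id=g.gene_id,
                    chrom=g.chrom,
                    strand=("-" if g.strand == "+" else "+") if flip_strand else g.strand,
                    gene_start=hi - g.gene_end,
                    gene_end=hi - g.gene_start,
                    cds_start=hi - g.cds_end,
                    cds_end=hi - g.cds_start,
                    introns=tuple(sorted((hi - e, hi - s) for s, e in g.introns)),
                )
                for g in genes
            ]

        count = lambda ps, o: sum(p.orientation == o for p in ps)
        both = classify_gene_pairs(transform(flip_strand=True))
        for o in ("tandem", "convergent", "divergent"):
            assert count(pairs, o) == count(both, o)
        mirror_only = classify_gene_pairs(transform(flip_strand=False))
        assert count(pairs, "tandem") == count(mirror_only, "tandem")
        assert count(pairs, "convergent") == count(mirror_only, "divergent")
        assert count(pairs, "divergent") == count(mirror_only, "convergent")


class TestMappability:
    def test_repeat_genome_fully_unmappable(self):
        track = compute_mappability("AAAAAAAA", 4)
        g = make_gene("g", chrom="chr1", start=0, end=8)
        assert track.fraction_for(g) == 0.0

    def test_unique_kmers_fully_mappable(self):
        # all 4-mers distinct, no reverse-complement collisions
        seq = "AACCACAC"
        track = compute_mappability(seq, 4)
        assert track.masks["chr1"].all()

    def test_matches_brute_force_census(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        seq = seq[:20] + seq[5:15] + seq[20:]  # plant a duplicated 10-mer
        k = 10
        track = compute_mappability(seq, k)
        # independent brute-force oracle
        occ = {}
        for s in (seq, revcomp(seq)):
            for p in range(len(s) - k + 1):
                w = s[p : p + k]
                occ[w] = occ.get(w, 0) + 1
        expect = np.array([occ[seq[p : p + k]] == 1 for p in range(len(seq) - k + 1)])
        assert (track.masks["chr1"] == expect).all()

    def test_read_length_longer_than_chrom(self):
        with pytest.raises(ValueError, match="read_length"):
            compute_mappability("ACGTACGT", 20)


class TestWiggle:
    def test_single_read_per_million_units(self, tmp_path):
        reads = make_reads([("chr1", 10, 46, "+")])
        p = tmp_path / "t.wig"
        write_wiggle(reads, "+", 1_000_000, str(p))
        lines = [l for l in p.read_text().splitlines() if "\t" in l]
        assert len(lines) == 36
        assert all(float(l.split("\t")[1]) == 1.0 for l in lines)

    def test_stacked_reads_additive(self, tmp_path):
        reads = make_reads([("chr1", 10, 46, "+"), ("chr1", 10, 46, "+")])
        cov = coverage_per_base(reads, "+")
        assert cov["chr1"][10:46].tolist() == [2] * 36

    def test_mass_conservation_with_junctions(self, tmp_path, small_reads):
        sub = small_reads[small_reads["library_id"] == "NM1"]
        total = len(sub)
        fwd, rev = tmp_path / "f.wig", tmp_path / "r.wig"
        write_wiggle(sub, "+", total, str(fwd))
        write_wiggle(sub, "-", total, str(rev))
        mass = (wiggle_mass(str(fwd)) + wiggle_mass(str(rev))) * total / 1e6
        aligned_bases = int(
            (sub["end"] - sub["start"]).sum()
            - np.where(sub["is_junction"], sub["intron_end"] - sub["intron_start"], 0).sum()
        )
        assert abs(mass - aligned_bases) < 1e-4 * aligned_bases

    def test_empty_track_valid(self, tmp_path):
        reads = make_reads([])
        p = tmp_path / "e.wig"
        write_wiggle(reads, "+", 100, str(p))
        assert p.read_text().startswith("track")
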