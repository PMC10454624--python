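"""Read/pair stratification against 16S annotations, and gene coverage."""

import numpy as np
import pytest

from mockbench.io_formats import AlignmentRecord, GenomeAnnotation, SsuGene
from mockbench.read_stratify import (
    classify_pair,
    classify_single,
    gene_coverage,
    identical_copy_groups,
    overlaps_ssu,
    reverse_complement,
    stratify,
)
from mockbench.synthetic_data import SimConfig, simulate_mock, simulate_reads


def rec(read_id="r", mate="fwd", genome="g1", start=0, end=10,
        mapped=True, primary=True, blocks=None):
    if not mapped:
        return AlignmentRecord(read_id, mate, mapped=False, primary=primary)
    blocks = blocks or [(start, end)]
    return AlignmentRecord(read_id, mate, mapped=True, primary=primary,
                           genome_id=genome, ref_span=(blocks[0][0], blocks[-1][1]),
                           aligned_blocks=blocks)


@pytest.fixture()
def two_copy_genome():
    """Genome with identical copies A1/A2, a one-base-off copy B, and space."""
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    gene = "".join(rng.choice(bases, 200))
    gene_b = ("T" if gene[0] != "T" else "A") + gene[1:]
    spacer = "".join(rng.choice(bases, 300))
    seq = spacer + gene + spacer + gene + spacer + gene_b + spacer
    genes = [
        SsuGene("A1", 300, 500, "+"),
        SsuGene("A2", 800, 1000, "+"),
        SsuGene("B", 1300, 1500, "+"),
    ]
    ann = GenomeAnnotation("g1", len(seq), genes)
    return seq, ann


class TestIdenticalCopyGroups:
    def test_two_identical_copies_one_group(self, two_copy_genome):
        seq, ann = two_copy_genome
        groups = identical_copy_groups(seq, ann.ssu_genes)
        assert groups["A1"] == groups["A2"] == "A1|A2"
        assert groups["B"] == "B"

    def test_minus_strand_copy_groups_with_plus(self):
        gene = "ACGTACGTTTGGCA" * 5
        seq = "T" * 50 + gene + "G" * 50 + reverse_complement(gene) + "C" * 50
        genes = [SsuGene("p", 50, 120, "+"), SsuGene("m", 170, 240, "-")]
        groups = identical_copy_groups(seq, genes)
        assert groups["p"] == groups["m"]

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(ValueError):
            identical_copy_groups("ACGT" * 10, [SsuGene("x", 30, 60)])

    def test_planted_identical_and_mutated_copies(self):
        """Simulator-planted copy structure is recovered exactly."""
        cfg = SimConfig(n_species=3, genome_length_range=(25_000, 30_000),
                        ssu_copies_range=(4, 4), identical_copy_fraction=0.5,
                        seed=3)
        bundle = simulate_mock(cfg)
        for gid, ann in bundle.annotations.items():
            groups = identical_copy_groups(bundle.genomes[gid], ann.ssu_genes)
            sizes = sorted(
                list(groups.values()).count(g) for g in set(groups.values()))
            assert sizes == [1, 1, 2]  # 2 identical + 2 mutated singletons

    @pytest.mark.parametrize("fraction, expected_groups", [(1.0, 1), (0.0, 3)])
    def test_fraction_extremes(self, fraction, expected_groups):
        cfg = SimConfig(n_species=2, genome_length_range=(22_000, 26_000),
                        ssu_copies_range=(3, 3),
                        identical_copy_fraction=fraction, seed=4)
        bundle = simulate_mock(cfg)
        for gid, ann in bundle.annotations.items():
            groups = identical_copy_groups(bundle.genomes[gid], ann.ssu_genes)
            assert len(set(groups.values())) == expected_groups


class TestOverlap:
    ann = GenomeAnnotation("g1", 1000, [SsuGene("ssuA", 100, 300)])

    def test_fully_inside(self):
        assert overlaps_ssu(rec(start=150, end=250), self.ann) == "ssuA"

    def test_fully_outside(self):
        assert overlaps_ssu(rec(start=400, end=500), self.ann) is None

    @pytest.mark.parametrize("min_overlap", [1, 5, 37])
    def test_threshold_boundary(self, min_overlap):
        # read ends inside the gene by exactly (min_overlap - 1) or min_overlap
        just_under = rec(start=0, end=100 + min_overlap - 1)
        at_threshold = rec(start=0, end=100 + min_overlap)
        assert overlaps_ssu(just_under, self.ann, min_overlap) is None
        assert overlaps_ssu(at_threshold, self.ann, min_overlap) == "ssuA"

    def test_deletion_block_counts_toward_overlap(self):
        # two blocks bridged outside; only the second touches the gene
        r = rec(blocks=[(0, 50), (95, 105)])
        assert overlaps_ssu(r, self.ann, min_overlap_bp=5) == "ssuA"
        assert overlaps_ssu(r, self.ann, min_overlap_bp=6) is None

    def test_requires_primary_mapped(self):
        with pytest.raises(ValueError):
            overlaps_ssu(rec(mapped=False), self.ann)
        with pytest.raises(ValueError):
            overlaps_ssu(rec(primary=False), self.ann)


class TestClassifyPair:
    @pytest.fixture(autouse=True)
    def _setup(self, two_copy_genome):
        seq, ann = two_copy_genome
        self.ann = {"g1": ann}
        self.groups = {"g1": identical_copy_groups(seq, ann.ssu_genes)}

    def classify(self, fwd, rev):
        return classify_pair(fwd, rev, self.ann, self.groups)

    def test_both_mates_same_gene(self):
        c = self.classify(rec(mate="fwd", start=310, end=360),
                          rec(mate="rev", start=420, end=470))
        assert c.category == "on_target"
        assert c.assigned_gene == "A1|A2"

    def test_mates_on_identical_copies(self):
        c = self.classify(rec(mate="fwd", start=310, end=360),
                          rec(mate="rev", start=820, end=870))
        assert c.category == "on_target" and c.assigned_gene == "A1|A2"

    def test_mates_on_nonidentical_copies_ambiguous(self):
        c = self.classify(rec(mate="fwd", start=310, end=360),
                          rec(mate="rev", start=1320, end=1370))
        assert c.category == "ambiguous" and c.assigned_gene is None

    def test_one_mate_off_target_is_ambiguous(self):
        c = self.classify(rec(mate="fwd", start=310, end=360),
                          rec(mate="rev", start=0, end=50))
        assert c.category == "ambiguous"

    def test_one_mate_unmapped_on_gene_is_ambiguous(self):
        c = self.classify(rec(mate="fwd", start=310, end=360),
                          rec(mate="rev", mapped=False))
        assert c.category == "ambiguous"

    def test_both_off_target(self):
        c = self.classify(rec(mate="fwd", start=0, end=50),
                          rec(mate="rev", start=550, end=600))
        assert c.category == "off_target"

    def test_off_target_with_unmapped_mate(self):
        c = self.classify(rec(mate="fwd", start=0, end=50),
                          rec(mate="rev", mapped=False))
        assert c.category == "off_target"

    def test_both_unmapped(self):
        c = self.classify(rec(mate="fwd", mapped=False),
                          rec(mate="rev", mapped=False))
        assert c.category == "unmapped"

    def test_cross_genome_identical_sequences_stay_ambiguous(self,
                                                             two_copy_genome):
        seq, ann = two_copy_genome
        ann2 = GenomeAnnotation("g2", ann.length_bp, ann.ssu_genes)
        anns = {"g1": ann, "g2": ann2}
        groups = {gid: identical_copy_groups(seq, a.ssu_genes)
                  for gid, a in anns.items()}
        c = classify_pair(rec(mate="fwd", genome="g1", start=310, end=360),
                          rec(mate="rev", genome="g2", start=310, end=360),
                          anns, groups)
        assert c.category == "ambiguous"

    def test_mismatched_read_ids_rejected(self):
        with pytest.raises(ValueError, match="read ids differ"):
            self.classify(rec(read_id="a", mate="fwd", start=310, end=360),
                          rec(read_id="b", mate="rev", start=310, end=360))


class TestClassifySingle:
    ann = {"g1": GenomeAnnotation("g1", 1000, [SsuGene("ssuA", 100, 300)])}

    def test_spanning_read_on_target(self):
        c = classify_single(rec(mate="single", start=50, end=350), self.ann)
        assert c.category == "on_target" and c.assigned_gene == "ssuA"

    def test_intergenic_read_off_target(self):
        assert classify_single(rec(mate="single", start=400, end=600),
                               self.ann).category == "off_target"

    def test_unmapped_and_missing(self):
        assert classify_single(rec(mapped=False), self.ann).category == "unmapped"
        assert classify_single(None, self.ann).category == "unmapped"


class TestStratify:
    def test_all_unmapped(self):
        recs = [rec(read_id=f"r{i}", mate=m, mapped=False)
                for i in range(5) for m in ("fwd", "rev")]
        report = stratify(recs, {}, paired=True)
        assert report.counts["unmapped"] == report.total == 5
        assert report.percentages["unmapped"] == 100.0

    def test_secondary_alignments_never_influence(self, two_copy_genome):
        seq, ann = two_copy_genome
        anns = {"g1": ann}
        groups = {"g1": identical_copy_groups(seq, ann.ssu_genes)}
        primaries = [rec(read_id="r1", mate="fwd", start=310, end=360),
                     rec(read_id="r1", mate="rev", start=420, end=470)]
        # decoy secondaries landing off-target and on the non-identical copy
        decoys = [rec(read_id="r1", mate="fwd", start=0, end=50, primary=False),
                  rec(read_id="r1", mate="rev", start=1320, end=1370,
                      primary=False)]
        with_decoys = stratify(primaries + decoys, anns, groups, paired=True)
        without = stratify(primaries, anns, groups, paired=True)
        assert with_decoys.counts == without.counts
        assert with_decoys.counts["on_target"] == 1

    def test_conservation_on_simulated_pairs(self, small_bundle):
        reads = simulate_reads(small_bundle)
        report = stratify(reads.alignment_records(), small_bundle.annotations,
                          small_bundle.copy_groups, paired=True,
                          species_of=small_bundle.genome_to_species)
        assert sum(report.counts.values()) == report.total
        assert report.total == len(reads.truth())
        assert sum(report.percentages.values()) == pytest.approx(100.0,
                                                                 abs=1e-6)

    def test_error_free_gene_reads_all_on_target(self, small_bundle):
        cfg = small_bundle.config.with_(off_target_fraction=0.0,
                                        read_error=0.0, n_reads=300)
        reads = simulate_reads(small_bundle, config=cfg)
        report = stratify(reads.alignment_records(), small_bundle.annotations,
                          small_bundle.copy_groups, paired=True)
        assert report.counts["on_target"] == report.total

    def test_on_off_mix_recovers_fractions(self, small_bundle):
        cfg = small_bundle.config.with_(off_target_fraction=0.2,
                                        n_reads=2000, seed=9)
        reads = simulate_reads(small_bundle, mode="long", config=cfg)
        report = stratify(reads.alignment_records(), small_bundle.annotations,
                          paired=False)
        frac_on = report.counts["on_target"] / report.total
        # 3 binomial SEs around 0.8 at n=2000
        assert abs(frac_on - 0.8) < 3 * np.sqrt(0.8 * 0.2 / 2000)

    def test_unannotated_genome_rejected(self):
        with pytest.raises(ValueError, match="unannotated"):
            stratify([rec(genome="gX")], {}, paired=False)


class TestCoverage:
    gene = SsuGene("ssuA", 100, 300)

    def test_single_spanning_read_constant_depth(self):
        profile = gene_coverage([rec(start=100, end=300)], "g1", self.gene)
        assert (profile.depth == 1).all()
        assert profile.total_bases == 200

    def test_no_reads_all_zero(self):
        profile = gene_coverage([], "g1", self.gene)
        assert profile.depth.shape == (200,)
        assert (profile.depth == 0).all()

    def test_matches_bruteforce_recount(self, rng):
        reads = []
        for i in range(300):
            start = int(rng.integers(0, 400))
            length = int(rng.integers(20, 120))
            reads.append(rec(read_id=f"r{i}", start=start, end=start + length))
        profile = gene_coverage(reads, "g1", self.gene)
        brute = np.zeros(200, dtype=int)
        for p in range(200):
            pos = self.gene.start + p
            brute[p] = sum(1 for r in reads
                           for s, e in r.aligned_blocks if s <= pos < e)
        assert (profile.depth == brute).all()

    def test_secondary_and_other_genome_ignored(self):
        reads = [rec(start=100, end=300),
                 rec(start=100, end=300, primary=False),
                 rec(start=100, end=300, genome="g2")]
        profile = gene_coverage(reads, "g1", self.gene)
        assert (profile.depth == 1).all()
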