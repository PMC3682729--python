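"""Coordinate model: TSS distances, locus construction, clustering, composition."""

import numpy as np
import pytest

from enhevo.intervals import (
    Enhancer,
    Gene,
    GenomicInterval,
    assign_enhancers_to_loci,
    bin_counts,
    build_locus,
    clustering_simulation,
    cpg_overlap_fraction,
    find_singletons,
    gc_content,
    nearest_tss_distance,
)

from conftest import make_enhancer, random_genes


class TestGenomicInterval:
    def test_rejects_inverted_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)

    def test_tss_follows_strand(self):
        assert Gene("chr1", 100, 200, "+", "g").tss == 100
        assert Gene("chr1", 100, 200, "-", "g").tss == 199


class TestNearestTss:
    def test_tss_at_midpoint_gives_zero(self):
        genes = [Gene("chr1", 150, 400, "+", "g1")]
        assert nearest_tss_distance(make_enhancer("chr1", 100, 200), genes) == 0

    def test_picks_closest_of_two(self):
        genes = [Gene("chr1", 100, 300, "+", "a"), Gene("chr1", 500, 700, "+", "b")]
        assert nearest_tss_distance(make_enhancer("chr1", 100, 200), genes) == 50

    def test_no_gene_on_chromosome_is_missing(self):
        genes = [Gene("chr2", 100, 300, "+", "a")]
        assert nearest_tss_distance(make_enhancer("chr1", 100, 200), genes) is None

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(42)
        genes = random_genes(rng, "chr1", 20, 100_000)
        for _ in range(50):
            s = int(rng.integers(0, 99_000))
            enh = make_enhancer("chr1", s, s + 500)
            expected = min(abs(enh.midpoint - g.tss) for g in genes)
            assert nearest_tss_distance(enh, genes) == expected


class TestBuildLocus:
    GENES = [
        Gene("chr1", 100, 200, "+", "gA"),
        Gene("chr1", 500, 600, "+", "gB"),
        Gene("chr1", 900, 1200, "+", "gC"),
    ]

    def test_intergenic_locus_spans_flanking_genes(self):
        locus = build_locus(make_enhancer("chr1", 300, 400), self.GENES, 10_000)
        assert (locus.boundary.start, locus.boundary.end) == (100, 600)
        assert locus.length == 500
        assert locus.context == "intergenic"
        assert [g.gene_id for g in locus.genes] == ["gA", "gB"]

    def test_intronic_locus_spans_flanking_intergenic_intervals(self):
        genes = [
            Gene("chr1", 100, 200, "+", "prev"),
            Gene("chr1", 300, 700, "+", "host"),
            Gene("chr1", 900, 1000, "+", "next"),
        ]
        locus = build_locus(make_enhancer("chr1", 400, 500), genes, 10_000)
        assert (locus.boundary.start, locus.boundary.end) == (200, 900)
        assert locus.length == 700
        assert locus.context == "intronic"

    def test_chromosome_start_clips_boundary(self):
        genes = [Gene("chr1", 500, 600, "+", "gB")]
        locus = build_locus(make_enhancer("chr1", 50, 150), genes, 10_000)
        assert (locus.boundary.start, locus.boundary.end) == (0, 600)

    def test_gene_free_chromosome_flagged(self):
        locus = build_locus(make_enhancer("chr1", 50, 150), [], 10_000)
        assert locus.context == "chromosome"
        assert (locus.boundary.start, locus.boundary.end) == (0, 10_000)

    def test_length_invariant_to_position_within_gap(self):
        for start in (210, 300, 450):
            locus = build_locus(make_enhancer("chr1", start, start + 40), self.GENES, 10_000)
            assert locus.length == 500


class TestLocusAssignment:
    def test_same_gap_same_locus(self):
        genes = TestBuildLocus.GENES
        e1, e2 = make_enhancer("chr1", 250, 300, "e1"), make_enhancer("chr1", 350, 400, "e2")
        lmap = assign_enhancers_to_loci([e1, e2], genes, {"chr1": 10_000})
        assert lmap.locus_of["e1"] == lmap.locus_of["e2"]

    def test_gene_separates_loci(self):
        genes = TestBuildLocus.GENES
        e1, e2 = make_enhancer("chr1", 250, 300, "e1"), make_enhancer("chr1", 700, 750, "e2")
        lmap = assign_enhancers_to_loci([e1, e2], genes, {"chr1": 10_000})
        assert lmap.locus_of["e1"] != lmap.locus_of["e2"]

    def test_partition_matches_boundary_equality_oracle(self):
        rng = np.random.default_rng(3)
        genes = random_genes(rng, "chr1", 15, 100_000)
        enhancers = []
        for i in range(60):
            s = int(rng.integers(0, 99_000))
            enhancers.append(make_enhancer("chr1", s, s + 300, f"e{i}"))
        sizes = {"chr1": 100_000}
        lmap = assign_enhancers_to_loci(enhancers, genes, sizes)
        # partition property
        assert sum(len(m) for m in lmap.members.values()) == len(enhancers)
        # oracle: co-locus iff identical boundaries and context
        for a in enhancers:
            for b in enhancers:
                la = build_locus(a, genes, 100_000)
                lb = build_locus(b, genes, 100_000)
                same = (
                    la.context == lb.context
                    and la.boundary.start == lb.boundary.start
                    and la.boundary.end == lb.boundary.end
                )
                assert (lmap.locus_of[a.id] == lmap.locus_of[b.id]) == same

    def test_singletons_are_complement_of_clustered(self):
        rng = np.random.default_rng(4)
        genes = random_genes(rng, "chr1", 15, 100_000)
        enhancers = [
            make_enhancer("chr1", int(s), int(s) + 300, f"e{i}")
            for i, s in enumerate(rng.integers(0, 99_000, size=40))
        ]
        lmap = assign_enhancers_to_loci(enhancers, genes, {"chr1": 100_000})
        singles = {e.id for e in find_singletons(lmap)}
        clustered = {
            e.id
            for ms in lmap.members.values()
            if len(ms) > 1
            for e in ms
        }
        assert singles | clustered == {e.id for e in enhancers}
        assert singles & clustered == set()


class TestClusteringSimulation:
    def _two_class_map(self, n_shared, n_lineage, loci_shared, loci_lineage):
        """Build enhancers assigned to synthetic loci (one gap per locus id)."""
        genes = [
            Gene("chr1", 1000 * (i + 1), 1000 * (i + 1) + 500, "+", f"g{i}")
            for i in range(max(loci_shared + loci_lineage) + 2)
        ]
        shared, lineage = [], []
        for i in range(n_shared):
            lid = loci_shared[i % len(loci_shared)]
            s = 1000 * (lid + 1) + 600 + (i * 7) % 300
            shared.append(make_enhancer("chr1", s, s + 20, f"s{i}"))
        for i in range(n_lineage):
            lid = loci_lineage[i % len(loci_lineage)]
            s = 1000 * (lid + 1) + 600 + 300 + (i * 7) % 90
            lineage.append(make_enhancer("chr1", s, s + 5, f"l{i}"))
        lmap = assign_enhancers_to_loci(shared + lineage, genes, {"chr1": 10_000_000})
        return shared, lineage, lmap

    def test_all_singletons_gives_zero(self):
        shared, lineage, lmap = self._two_class_map(5, 5, [0, 2, 4, 6, 8], [1, 3, 5, 7, 9])
        res = clustering_simulation(shared, lineage, lmap, draws_per_class=5, replicates=50, seed=0)
        for r in res.values():
            assert r.pct_clustered_with_shared == 0.0
            assert r.pct_clustered_with_lineage == 0.0

    def test_single_locus_gives_hundred(self):
        shared, lineage, lmap = self._two_class_map(6, 6, [0], [0])
        res = clustering_simulation(shared, lineage, lmap, draws_per_class=6, replicates=20, seed=0)
        for r in res.values():
            assert r.pct_clustered_with_shared == 100.0
            assert r.pct_clustered_with_lineage == 100.0

    def test_empty_class_raises(self):
        shared, lineage, lmap = self._two_class_map(4, 4, [0], [1])
        with pytest.raises(ValueError):
            clustering_simulation([], lineage, lmap)

    def test_draws_reduced_with_warning_when_class_small(self):
        shared, lineage, lmap = self._two_class_map(4, 4, [0], [1])
        with pytest.warns(UserWarning):
            res = clustering_simulation(
                shared, lineage, lmap, draws_per_class=500, replicates=10, seed=0
            )
        assert res["shared"].draws_per_class == 4

    def test_adding_colocated_enhancer_raises_percentages(self):
        # in expectation, growing a locus never lowers clustering
        shared1, lineage, lmap1 = self._two_class_map(6, 6, [0, 1, 2], [3, 4, 5])
        r1 = clustering_simulation(
            shared1, lineage, lmap1, draws_per_class=4, replicates=5000, seed=1
        )
        shared2 = shared1 + [make_enhancer("chr1", 1000 + 650, 1000 + 660, "extra")]
        genes = [
            Gene("chr1", 1000 * (i + 1), 1000 * (i + 1) + 500, "+", f"g{i}")
            for i in range(8)
        ]
        lmap2 = assign_enhancers_to_loci(shared2 + lineage, genes, {"chr1": 10_000_000})
        r2 = clustering_simulation(
            shared2, lineage, lmap2, draws_per_class=4, replicates=5000, seed=1
        )
        assert (
            r2["shared"].pct_clustered_with_shared
            >= r1["shared"].pct_clustered_with_shared
        )


class TestSequenceComposition:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCC", 1.0), ("ATAT", 0.0), ("ANGC", 2 / 3)],
    )
    def test_gc_content(self, tmp_path, seq, expected):
        fa = tmp_path / f"g_{seq}.fa"
        fa.write_text(f">chr1\n{seq}\n")
        import pyfaidx

        genome = pyfaidx.Fasta(str(fa))
        iv = GenomicInterval("chr1", 0, len(seq))
        assert gc_content(iv, genome) == pytest.approx(expected)

    def test_gc_interval_beyond_sequence_errors(self, tmp_path):
        fa = tmp_path / "short.fa"
        fa.write_text(">chr1\nACGT\n")
        import pyfaidx

        genome = pyfaidx.Fasta(str(fa))
        with pytest.raises(ValueError):
            gc_content(GenomicInterval("chr1", 0, 10), genome)

    def test_cpg_overlap_trivial_cases(self):
        enh = [make_enhancer("chr1", 100, 200, "e1"), make_enhancer("chr1", 500, 600, "e2")]
        assert cpg_overlap_fraction(enh, []) == 0.0
        whole = [GenomicInterval("chr1", 0, 10_000, "isl")]
        assert cpg_overlap_fraction(enh, whole) == 1.0

    def test_cpg_overlap_matches_pairwise_oracle(self):
        rng = np.random.default_rng(9)
        enh = [
            make_enhancer("chr1", int(s), int(s) + 200, f"e{i}")
            for i, s in enumerate(rng.integers(0, 50_000, size=30))
        ]
        islands = [
            GenomicInterval("chr1", int(s), int(s) + int(l), f"i{i}")
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 50_000, size=20), rng.integers(50, 5000, size=20))
            )
        ]
        expected = sum(
            any(e.interval.overlap_bp(i) >= 1 for i in islands) for e in enh
        ) / len(enh)
        assert cpg_overlap_fraction(enh, islands) == pytest.approx(expected)


def test_bin_counts_uses_report_edges():
    # bins are lower-inclusive half-open: [10k, 50k) is the middle bin
    counts = bin_counts([5_000, 20_000, 60_000, 9_999, 10_000], (10_000, 50_000))
    assert counts == {"<10000": 2, "10000-50000": 2, ">50000": 1}
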