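"""Conservation classification: cross-mapping, class partition, compensation."""

import numpy as np
import pandas as pd
import pytest

from enhevo.classify import (
    ClassificationConfig,
    ReadDensityTable,
    classification_summary,
    classify_enhancers,
    classify_lineage_specific,
    cross_map_enhancer_sets,
    orthologous_locus_compensation,
    outgroup_presence,
)
from enhevo.intervals import Gene, GenomicInterval
from enhevo.liftover import Chain, ChainSet

from conftest import make_enhancer

IDENTITY_CHAIN = Chain(
    score=1000, t_name="rchr1", t_size=100_000, t_strand="+",
    t_start=0, t_end=100_000, q_name="chr1", q_size=100_000, q_strand="+",
    q_start=0, q_end=100_000, blocks=[(100_000, 0, 0)],
)


def _ref_enh(chrom, start, end, eid):
    e = make_enhancer(chrom, start, end, eid)
    e.species = "reference"
    return e


class TestCrossMap:
    def test_planted_pair_under_identity_is_shared(self):
        q = [make_enhancer("chr1", 1000, 1600, "q0")]
        r = [_ref_enh("rchr1", 1200, 1800, "r0")]
        res = cross_map_enhancer_sets(q, r, ChainSet([IDENTITY_CHAIN]))
        assert res.labels["q0"] == "shared"
        assert res.reference_labels["r0"] == "shared"

    def test_reference_enhancer_in_gene_desert_is_reference_specific(self):
        q = [make_enhancer("chr1", 1000, 1600, "q0")]
        r = [_ref_enh("rchr1", 50_000, 50_600, "r0")]
        res = cross_map_enhancer_sets(q, r, ChainSet([IDENTITY_CHAIN]))
        assert res.labels["q0"] == "lineage_specific"
        assert res.reference_labels["r0"] == "reference_specific"

    def test_overlap_rule_threshold(self):
        q = [make_enhancer("chr1", 1000, 1600, "q0")]
        r = [_ref_enh("rchr1", 1590, 2100, "r0")]  # 10 bp overlap
        cfg_loose = ClassificationConfig(overlap_rule=1)
        cfg_strict = ClassificationConfig(overlap_rule=50)
        cs = ChainSet([IDENTITY_CHAIN])
        assert cross_map_enhancer_sets(q, r, cs, cfg_loose).labels["q0"] == "shared"
        assert cross_map_enhancer_sets(q, r, cs, cfg_strict).labels["q0"] == "lineage_specific"


class TestClassPartition:
    def _density(self, rows):
        return ReadDensityTable(pd.DataFrame(rows, columns=["chrom", "start", "end", "reads"]))

    def test_density_lookup_is_reads_per_base(self):
        table = self._density([("rchr1", 100, 200, 300.0)])
        assert table.density_over(GenomicInterval("rchr1", 100, 200)) == pytest.approx(3.0)
        # half-overlapping row contributes proportionally
        assert table.density_over(GenomicInterval("rchr1", 150, 250)) == pytest.approx(1.5)
        assert table.density_over(GenomicInterval("rchr1", 500, 600)) is None

    def test_class_rules(self):
        q2r = ChainSet([Chain(
            score=1000, t_name="chr1", t_size=100_000, t_strand="+",
            t_start=0, t_end=100_000, q_name="rchr1", q_size=99_000, q_strand="+",
            q_start=0, q_end=99_000,
            blocks=[(50_000, 1_000, 0), (49_000, 0, 0)],  # deletion at [50k, 51k)
        )])
        enh = [
            make_enhancer("chr1", 50_200, 50_800, "in_deletion"),
            make_enhancer("chr1", 1_000, 1_600, "hot"),
            make_enhancer("chr1", 2_000, 2_600, "cold"),
        ]
        density = self._density([
            ("rchr1", 1_000, 1_600, 1_200.0),  # 2 reads/bp
            ("rchr1", 2_000, 2_600, 120.0),  # 0.2 reads/bp
        ])
        cfg = ClassificationConfig(background_density=1.0)
        labels, _ = classify_lineage_specific(enh, q2r, density, cfg)
        assert labels == {"in_deletion": "class3", "hot": "class1", "cold": "class2"}

    def test_missing_density_warns_and_is_class2(self):
        q2r = ChainSet([Chain(
            score=10, t_name="chr1", t_size=100_000, t_strand="+",
            t_start=0, t_end=100_000, q_name="rchr1", q_size=100_000, q_strand="+",
            q_start=0, q_end=100_000, blocks=[(100_000, 0, 0)],
        )])
        enh = [make_enhancer("chr1", 1_000, 1_600, "nodata")]
        density = self._density([("rchr1", 90_000, 90_100, 5.0)])
        with pytest.warns(UserWarning, match="nodata"):
            labels, _ = classify_lineage_specific(
                enh, q2r, density, ClassificationConfig(background_density=1.0)
            )
        assert labels["nodata"] == "class2"


class TestBundleRecovery:
    def test_labels_match_planted_truth(self, bundle_data, classified):
        truth = bundle_data["ground_truth"]["labels"]
        labels = classified.labels
        agreement = sum(labels[k] == truth[k] for k in labels) / len(labels)
        assert agreement >= 0.99

    def test_classification_is_a_partition(self, bundle_data, classified):
        labels = classified.labels
        assert set(labels) == {e.id for e in bundle_data["query_enhancers"]}
        assert set(labels.values()) <= {"shared", "class1", "class2", "class3"}

    def test_reference_specific_matches_truth(self, bundle_data, classified):
        truth = bundle_data["ground_truth"]["labels"]
        for rid, lab in classified.reference_labels.items():
            expected = "shared" if truth[rid] == "shared_counterpart" else "reference_specific"
            assert lab == expected

    def test_summary_headline_percentage(self):
        labels = {f"q{i}": ("shared" if i < 1066 else "lineage_specific") for i in range(5042)}
        summary = classification_summary(labels)
        assert summary["pct_lineage_specific"] == 79
        assert summary["n_shared"] == 1066


class TestOutgroupPresence:
    def test_no_outgroups_warns_and_returns_zero(self):
        enh = [make_enhancer("chr1", 0, 100, "e")]
        with pytest.warns(UserWarning):
            flags, frac = outgroup_presence(enh, {})
        assert frac == 0.0 and flags == {"e": False}

    def test_identity_outgroup_gives_one(self):
        chains = {"dog": ChainSet([Chain(
            score=10, t_name="chr1", t_size=100_000, t_strand="+",
            t_start=0, t_end=100_000, q_name="dog_chr1", q_size=100_000, q_strand="+",
            q_start=0, q_end=100_000, blocks=[(100_000, 0, 0)],
        )])}
        enh = [make_enhancer("chr1", i * 1000, i * 1000 + 500, f"e{i}") for i in range(5)]
        flags, frac = outgroup_presence(enh, chains)
        assert frac == 1.0

    def test_bundle_presence_matches_planted_absences(self, bundle_data, classified):
        truth = bundle_data["ground_truth"]
        class3 = [
            e for e in bundle_data["query_enhancers"]
            if classified.labels[e.id] == "class3"
        ]
        flags, frac = outgroup_presence(class3, bundle_data["outgroup_chains"])
        absent = set(truth["outgroup_absent"])
        for e in class3:
            assert flags[e.id] == (e.id not in absent)


class TestCompensation:
    def _setup(self):
        q_genes = [Gene("chr1", 1000, 2000, "+", "gA"), Gene("chr1", 9000, 10_000, "+", "gB")]
        r_genes = [Gene("rchr1", 1000, 2000, "+", "r_gA"), Gene("rchr1", 9000, 10_000, "+", "r_gB")]
        hmap = {"gA": "r_gA", "gB": "r_gB"}
        chains = ChainSet([Chain(
            score=10, t_name="chr1", t_size=100_000, t_strand="+",
            t_start=0, t_end=100_000, q_name="rchr1", q_size=100_000, q_strand="+",
            q_start=0, q_end=100_000, blocks=[(100_000, 0, 0)],
        )])
        singleton = make_enhancer("chr1", 4000, 4600, "s0")
        sizes = {"chr1": 100_000}
        r_sizes = {"rchr1": 100_000}
        return q_genes, r_genes, hmap, chains, singleton, sizes, r_sizes

    def test_no_reference_specific_gives_zero(self):
        q_genes, r_genes, hmap, chains, s, sizes, r_sizes = self._setup()
        res = orthologous_locus_compensation(
            {"shared": [s]}, chains, q_genes, r_genes, hmap, [], sizes, r_sizes
        )
        assert res["shared"].fraction == 0.0

    def test_compensator_in_every_locus_gives_one(self):
        q_genes, r_genes, hmap, chains, s, sizes, r_sizes = self._setup()
        comp = _ref_enh("rchr1", 6000, 6600, "rs0")
        res = orthologous_locus_compensation(
            {"shared": [s]}, chains, q_genes, r_genes, hmap, [comp], sizes, r_sizes
        )
        assert res["shared"].fraction == 1.0
        # distance between lifted position (identity) and compensator midpoints
        assert res["shared"].mean_distance == pytest.approx(abs(6300 - 4300))

    def test_class3_goes_through_homologous_flanking_genes(self):
        q_genes, r_genes, hmap, chains, s, sizes, r_sizes = self._setup()
        # no chain covers chrU, so the enhancer itself is unmappable
        s3 = make_enhancer("chr1", 4000, 4600, "c3")
        empty_chains = ChainSet([])
        comp = _ref_enh("rchr1", 6000, 6600, "rs0")
        res = orthologous_locus_compensation(
            {"class3": [s3]}, empty_chains, q_genes, r_genes, hmap, [comp], sizes, r_sizes
        )
        assert res["class3"].n_with_locus == 1
        assert res["class3"].fraction == 1.0

    def test_unprojectable_locus_excluded(self):
        q_genes, r_genes, hmap, chains, s, sizes, r_sizes = self._setup()
        s3 = make_enhancer("chr1", 4000, 4600, "c3")
        res = orthologous_locus_compensation(
            {"class3": [s3]}, ChainSet([]), q_genes, r_genes, {}, [], sizes, r_sizes
        )
        assert res["class3"].n_excluded == 1
        assert res["class3"].n_with_locus == 0

    def test_bundle_rates_match_planted_truth(self, bundle_data, classified):
        from enhevo.intervals import assign_enhancers_to_loci, find_singletons

        data = bundle_data
        truth = data["ground_truth"]
        lmap = assign_enhancers_to_loci(
            data["query_enhancers"], data["genes"], data["chrom_sizes"]
        )
        singles = find_singletons(lmap)
        by_class = {}
        for e in singles:
            cls = classified.labels[e.id]
            if cls in ("shared", "class2", "class3"):
                by_class.setdefault(cls, []).append(e)
        ref_specific = [
            r for r in data["reference_enhancers"]
            if classified.reference_labels[r.id] == "reference_specific"
        ]
        res = orthologous_locus_compensation(
            by_class,
            data["chains_q2r"],
            data["genes"],
            data["ref_genes"],
            data["homolog_map"],
            ref_specific,
            data["chrom_sizes"],
            data["ref_chrom_sizes"],
        )
        planted = truth["compensated_loci"]
        for cls, enhancers in by_class.items():
            expected = sum(planted.get(e.id, False) for e in enhancers)
            got = res[cls].n_compensated
            # locus projection is exact on the synthetic genome
            assert abs(got - expected) <= max(1, 0.1 * len(enhancers))
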