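"""Variant polarization, DAF spectra, MK test and the exact 2x2 test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhevo.intervals import GenomicInterval
from enhevo.selection import (
    DAFSpectrumResult,
    PolarizationStats,
    VariantRecord,
    compare_spectra,
    compute_D,
    daf_spectrum,
    daf_spectrum_from_counts,
    mk_test,
    polarize_variant,
    region_mk_counts,
)
from enhevo.stats import fisher_exact_2x2


def exact_fisher_oracle(a, b, c, d):
    """Exhaustive enumeration with exact integer arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    num_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = tail = 0
    for k in range(lo, hi + 1):
        nk = math.comb(r1, k) * math.comb(r2, c1 - k)
        total += nk
        if nk <= num_obs:
            tail += nk
    return tail / total if total else 1.0


class TestPolarize:
    def test_ancestral_ref_keeps_af(self):
        rec = VariantRecord("chr1", 10, "A", "G", 0.02, "A")
        assert polarize_variant(rec) == pytest.approx(0.02)

    def test_ancestral_alt_flips_af(self):
        rec = VariantRecord("chr1", 10, "A", "G", 0.02, "G")
        assert polarize_variant(rec) == pytest.approx(0.98)

    def test_missing_ancestral_skipped_and_counted(self):
        stats = PolarizationStats()
        rec = VariantRecord("chr1", 10, "A", "G", 0.02, None)
        assert polarize_variant(rec, stats) is None
        assert stats.n_skipped == 1

    def test_third_allele_ancestral_skipped(self):
        stats = PolarizationStats()
        rec = VariantRecord("chr1", 10, "A", "G", 0.02, "T")
        assert polarize_variant(rec, stats) is None
        assert stats.n_skipped_mismatch == 1

    @given(
        af=st.floats(0, 1, allow_nan=False),
        anc_is_ref=st.booleans(),
    )
    @settings(deadline=None, max_examples=100)
    def test_allele_swap_symmetry(self, af, anc_is_ref):
        """Swapping ref/alt (with AF -> 1-AF) leaves the DAF unchanged."""
        anc = "A" if anc_is_ref else "G"
        rec = VariantRecord("chr1", 10, "A", "G", af, anc)
        swapped = VariantRecord("chr1", 10, "G", "A", 1 - af, anc)
        assert polarize_variant(rec) == pytest.approx(polarize_variant(swapped))


class TestDafSpectrum:
    @pytest.mark.parametrize(
        "label,low,total,pct",
        [
            ("shared", 10_640, 14_311, 74.3),
            ("class2", 4_793, 6_213, 77.1),
            ("class3", 5_006, 6_701, 74.7),
            ("pseudogenes", 192_359, 281_111, 68.4),
        ],
    )
    def test_low_frequency_fractions_from_counts(self, label, low, total, pct):
        res = daf_spectrum_from_counts(label, low, total)
        assert round(100 * res.fraction, 1) == pct

    def test_counts_must_be_consistent(self):
        with pytest.raises(ValueError):
            daf_spectrum_from_counts("x", 10, 5)

    def test_uniform_daf_matches_cutoff_probability(self):
        rng = np.random.default_rng(12)
        region = GenomicInterval("chr1", 0, 10_000_000, "r0")
        n = 10_000
        pos = np.sort(rng.choice(10_000_000, size=n, replace=False)) + 1
        variants = [
            VariantRecord("chr1", int(p), "A", "G", float(rng.uniform()), "A")
            for p in pos
        ]
        res = daf_spectrum([region], variants, cutoff=0.05)
        # binomial(10^4, 0.05): ~4.4 sigma band
        assert abs(res.fraction - 0.05) < 4.4 * np.sqrt(0.05 * 0.95 / n)

    def test_variants_outside_regions_ignored_and_skips_counted(self):
        region = GenomicInterval("chr1", 100, 200, "r0")
        variants = [
            VariantRecord("chr1", 150, "A", "G", 0.01, "A"),
            VariantRecord("chr1", 150, "A", "G", 0.01, None),  # skip
            VariantRecord("chr1", 500, "A", "G", 0.01, "A"),  # outside
            VariantRecord("chr2", 150, "A", "G", 0.01, "A"),  # other chrom
        ]
        res = daf_spectrum([region], variants)
        assert res.total_count == 1 and res.skipped == 1

    def test_identical_spectra_not_significant(self):
        a = daf_spectrum_from_counts("a", 500, 1000)
        b = daf_spectrum_from_counts("b", 500, 1000)
        assert compare_spectra(a, b) == pytest.approx(1.0)


class TestComputeD:
    def test_simple_difference(self):
        assert compute_D(10, 3) == 7

    def test_zero_inputs(self):
        assert compute_D(0, 0) == 0

    def test_floor_with_warning(self):
        with pytest.warns(UserWarning):
            assert compute_D(2, 5) == 0


class TestMKTest:
    PN, DN = 349_789, 442_395  # pseudogene neutral reference

    @pytest.mark.parametrize(
        "pe,de,ni",
        [
            (12_893, 10_148, 1.61),
            (5_736, 4_312, 1.68),
            (6_283, 5_400, 1.47),
        ],
    )
    def test_neutrality_indices_from_printed_counts(self, pe, de, ni):
        res = mk_test(pe, de, self.PN, self.DN)
        assert round(res.neutrality_index, 2) == ni
        assert res.regime == "negative"

    def test_reference_against_itself_is_neutral(self):
        res = mk_test(self.PN, self.DN, self.PN, self.DN)
        assert res.neutrality_index == pytest.approx(1.0)
        assert res.regime == "neutral"
        assert res.p_value == pytest.approx(1.0)

    def test_equal_ratios_give_unit_index_and_p_one(self):
        res = mk_test(10, 10, 100, 100)
        assert res.neutrality_index == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_denominator_reported(self):
        res = mk_test(10, 0, 100, 100)
        assert res.neutrality_index is None
        assert res.reason == "zero denominator"

    def test_region_counts_aggregate_divergence_table(self):
        regions = [GenomicInterval("chr1", 0, 100, "a"), GenomicInterval("chr1", 200, 300, "b")]
        variants = [
            VariantRecord("chr1", 50, "A", "G", 0.5, "A"),
            VariantRecord("chr1", 250, "A", "G", 0.5, None),  # unpolarized still counts as P
            VariantRecord("chr1", 150, "A", "G", 0.5, "A"),  # outside
        ]
        counts = region_mk_counts(regions, variants, {"a": (10, 2), "b": (5, 1)})
        assert counts.P == 2
        assert counts.d == 15 and counts.pi == 3
        assert counts.D == 12


class TestFisherExact:
    def test_worked_example(self):
        odds, p = fisher_exact_2x2([[1, 9], [11, 3]])
        assert p == pytest.approx(0.002759456, rel=1e-6)
        assert odds == pytest.approx((1 * 3) / (9 * 11))

    def test_symmetric_table_is_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]])[1] == pytest.approx(1.0)

    def test_large_balanced_table_is_one(self):
        assert fisher_exact_2x2([[1000, 1000], [1000, 1000]])[1] == pytest.approx(1.0)

    def test_rejects_negative_or_fractional(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 1], [0, 2]])

    def test_matches_exact_enumeration_small_margins(self):
        for r1 in range(0, 13):
            for a in range(r1 + 1):
                for r2 in range(0, 13):
                    for c in range(r2 + 1):
                        p = fisher_exact_2x2([[a, r1 - a], [c, r2 - c]])[1]
                        assert p == pytest.approx(
                            exact_fisher_oracle(a, r1 - a, c, r2 - c), abs=1e-10
                        )

    def test_matches_scipy_on_random_tables(self):
        from scipy.stats import fisher_exact as scipy_fisher

        rng = np.random.default_rng(23)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 400, size=4)
            table = [[int(a), int(b)], [int(c), int(d)]]
            p_mine = fisher_exact_2x2(table)[1]
            p_scipy = scipy_fisher(table)[1]
            assert p_mine == pytest.approx(p_scipy, rel=1e-7, abs=1e-12)


class TestPlantedSelectionRecovery:
    def _simulate_counts(self, seed, factor, n_regions=600):
        """MK inputs from the generator's variant model at moderate size."""
        from enhevo.simulate import SimConfig, generate_variants

        cfg = SimConfig(seed=seed, selection_divergence_factor=factor)
        rng = np.random.default_rng(seed)
        sizes = {"chr1": 10_000_000}
        regions = []
        for i in range(n_regions):
            s = i * 3000
            regime = "constrained" if i % 2 == 0 else "neutral"
            regions.append((GenomicInterval("chr1", s, s + 1500, f"r{i}"), regime))
        records, div = generate_variants(cfg, regions, sizes, rng)
        variants = [VariantRecord(c, p, r, a, af, aa) for c, p, r, a, af, aa in records]
        div_map = dict(zip(div["region_id"], zip(div["d"], div["pi"])))
        cons = [iv for iv, reg in regions if reg == "constrained"]
        neut = [iv for iv, reg in regions if reg == "neutral"]
        ce = region_mk_counts(cons, variants, div_map)
        ne = region_mk_counts(neut, variants, div_map)
        return ce, ne, cons, neut, variants

    def test_neutral_vs_neutral_gives_unit_index(self):
        """With no divergence reduction, constrained-vs-neutral labels are a
        relabeling of identical processes, so NI ~ 1."""
        cfg_factor = 1.0
        ce, ne, *_ = self._simulate_counts(31, cfg_factor)
        res = mk_test(ce.P, ce.D, ne.P, ne.D)
        assert abs(res.neutrality_index - 1.0) < 0.1

    def test_planted_constraint_raises_index_and_shifts_spectrum(self):
        ce, ne, cons, neut, variants = self._simulate_counts(32, 0.675)
        res = mk_test(ce.P, ce.D, ne.P, ne.D)
        assert res.neutrality_index > 1.2
        assert res.regime == "negative"
        # constrained regions draw DAF from the selection-shifted Beta
        sc = daf_spectrum(cons, variants, label="constrained")
        sn = daf_spectrum(neut, variants, label="neutral")
        assert sc.fraction > sn.fraction
        assert compare_spectra(sc, sn) < 1e-6
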