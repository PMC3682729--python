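"""Selection-pressure estimation: DAF spectra and the McDonald-Kreitman test.

Variants are polarized against an inferred ancestral allele: the derived
allele frequency (DAF) equals the alternate allele frequency when the
ancestral allele is the reference, and its complement when the ancestral
allele is the alternate. Variants whose ancestral state is missing or
matches neither allele are skipped (and counted) rather than folded, since
folding would inflate the low-frequency class.

Negative selection leaves an excess of low-frequency derived variants
(DAF <= 5%) relative to a neutral reference (pseudogenes), and a
McDonald-Kreitman neutrality index NI = (Pe/De)/(Pn/Dn) above 1, where P is
the polymorphic site count and D = d - pi the fixed-difference count
(interspecies differences d minus heterozygous sites pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval
from .stats import fisher_exact_2x2

__all__ = [
    "VariantRecord",
    "PolarizationStats",
    "DAFSpectrumResult",
    "MKCounts",
    "MKResult",
    "polarize_variant",
    "polarize_all",
    "daf_spectrum",
    "daf_spectrum_from_counts",
    "compare_spectra",
    "compute_D",
    "mk_test",
    "region_mk_counts",
]

DEFAULT_DAF_CUTOFF = 0.05


@dataclass(frozen=True)
class VariantRecord:
    """A bi-allelic SNP with alternate allele frequency and ancestral state."""

    chrom: str
    pos: int  # 1-based position, as in VCF
    ref: str
    alt: str
    allele_frequency: float
    ancestral: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.allele_frequency <= 1:
            raise ValueError("allele_frequency must be in [0, 1]")


@dataclass
class PolarizationStats:
    n_polarized: int = 0
    n_skipped_missing: int = 0
    n_skipped_mismatch: int = 0

    @property
    def n_skipped(self) -> int:
        return self.n_skipped_missing + self.n_skipped_mismatch


def polarize_variant(
    record: VariantRecord, stats: PolarizationStats | None = None
) -> float | None:
    """Derived allele frequency, or None when the variant cannot be polarized."""
    if record.ancestral is None:
        if stats:
            stats.n_skipped_missing += 1
        return None
    if record.ancestral == record.ref:
        daf = record.allele_frequency
    elif record.ancestral == record.alt:
        daf = 1.0 - record.allele_frequency
    else:
        if stats:
            stats.n_skipped_mismatch += 1
        return None
    if stats:
        stats.n_polarized += 1
    return daf


def polarize_all(
    records: list[VariantRecord],
) -> tuple[list[tuple[VariantRecord, float]], PolarizationStats]:
    stats = PolarizationStats()
    out = []
    for rec in records:
        daf = polarize_variant(rec, stats)
        if daf is not None:
            out.append((rec, daf))
    return out, stats


@dataclass
class DAFSpectrumResult:
    label: str
    low_freq_count: int
    total_count: int
    cutoff: float = DEFAULT_DAF_CUTOFF
    p_value: float | None = None
    skipped: int = 0

    @property
    def fraction(self) -> float:
        return self.low_freq_count / self.total_count if self.total_count else float("nan")


def daf_spectrum_from_counts(
    label: str, low: int, total: int, cutoff: float = DEFAULT_DAF_CUTOFF
) -> DAFSpectrumResult:
    """Build a spectrum row directly from (low-frequency, total) counts."""
    if not 0 <= low <= total:
        raise ValueError("need 0 <= low <= total")
    return DAFSpectrumResult(label, low, total, cutoff)


class _RegionIndex:
    def __init__(self, regions: list[GenomicInterval]) -> None:
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        tmp: dict[str, list[tuple[int, int]]] = {}
        for r in regions:
            tmp.setdefault(r.chrom, []).append((r.start, r.end))
        for chrom, ivs in tmp.items():
            ivs.sort()
            self._by_chrom[chrom] = (
                np.array([s for s, _ in ivs]),
                np.maximum.accumulate(np.array([e for _, e in ivs])),
            )

    def contains(self, chrom: str, pos0: int) -> bool:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, max_ends = entry
        i = int(np.searchsorted(starts, pos0, side="right"))
        return i > 0 and max_ends[i - 1] > pos0


def daf_spectrum(
    regions: list[GenomicInterval],
    variants: list[VariantRecord],
    cutoff: float = DEFAULT_DAF_CUTOFF,
    label: str = "",
) -> DAFSpectrumResult:
    """Low-frequency DAF fraction over polarizable variants inside regions."""
    index = _RegionIndex(regions)
    stats = PolarizationStats()
    low = total = 0
    for rec in variants:
        if not index.contains(rec.chrom, rec.pos - 1):
            continue
        daf = polarize_variant(rec, stats)
        if daf is None:
            continue
        total += 1
        if daf <= cutoff:
            low += 1
    return DAFSpectrumResult(label, low, total, cutoff, skipped=stats.n_skipped)


def compare_spectra(test: DAFSpectrumResult, reference: DAFSpectrumResult) -> float:
    """Two-sided Fisher p for the low/high frequency contrast vs a reference."""
    table = [
        [test.low_freq_count, test.total_count - test.low_freq_count],
        [reference.low_freq_count, reference.total_count - reference.low_freq_count],
    ]
    _, p = fisher_exact_2x2(table)
    test.p_value = p
    return p


@dataclass
class MKCounts:
    """Raw counts for one region class: polymorphism and fixed differences."""

    P: int  # polymorphic sites
    d: int  # interspecies nucleotide differences
    pi: int  # heterozygous sites

    @property
    def D(self) -> int:
        return compute_D(self.d, self.pi)


def compute_D(d: int, pi: int) -> int:
    """Fixed differences D = d - pi, floored at 0 (with warning) on noisy input."""
    if d < 0 or pi < 0:
        raise ValueError("d and pi must be non-negative")
    if pi > d:
        warnings.warn(
            f"heterozygous sites ({pi}) exceed interspecies differences ({d}); "
            "flooring D at 0",
            stacklevel=2,
        )
        return 0
    return d - pi


@dataclass
class MKResult:
    Pe: int
    De: int
    Pn: int
    Dn: int
    neutrality_index: float | None
    p_value: float
    regime: str  # "negative" | "neutral" | "positive" | "undefined"
    reason: str = ""


def mk_test(Pe: int, De: int, Pn: int, Dn: int) -> MKResult:
    """McDonald-Kreitman test of a region class against the neutral reference.

    NI = (Pe/De)/(Pn/Dn); NI > 1 indicates negative selection on the test
    class, NI < 1 positive selection. p is the two-sided Fisher's exact
    probability of the [[Pe, De], [Pn, Dn]] table.
    """
    if min(Pe, De, Pn, Dn) < 0:
        raise ValueError("MK counts must be non-negative")
    _, p = fisher_exact_2x2([[Pe, De], [Pn, Dn]])
    if De == 0 or Dn == 0 or Pn == 0:
        return MKResult(Pe, De, Pn, Dn, None, p, "undefined", reason="zero denominator")
    ni = (Pe / De) / (Pn / Dn)
    if np.isclose(ni, 1.0, rtol=0, atol=1e-12):
        regime = "neutral"
    elif ni > 1:
        regime = "negative"
    else:
        regime = "positive"
    return MKResult(Pe, De, Pn, Dn, ni, p, regime)


def region_mk_counts(
    regions: list[GenomicInterval],
    variants: list[VariantRecord],
    divergence: dict[str, tuple[int, int]],
) -> MKCounts:
    """Aggregate MK counts over a region set.

    ``divergence`` maps region id -> (d, pi) precomputed interspecies
    difference and heterozygous-site counts. P is the number of SNPs falling
    in the regions (polarizable or not: polymorphism needs no polarization).
    """
    index = _RegionIndex(regions)
    P = sum(1 for rec in variants if index.contains(rec.chrom, rec.pos - 1))
    d = pi = 0
    for r in regions:
        if r.id in divergence:
            dd, pp = divergence[r.id]
            d += int(dd)
            pi += int(pp)
    return MKCounts(P=P, d=d, pi=pi)
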