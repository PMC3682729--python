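"""Conservation classification of enhancers between two species.

A query enhancer is *shared* when the lifted orthologous position of at
least one reference enhancer overlaps it; otherwise it is lineage-specific.
Lineage-specific enhancers split into three classes by the fate of their
orthologous sequence in the reference genome:

* class1 — orthologue exists and its ChIP read density exceeds the
  background level over evolutionarily conserved regions (equivocal: may be
  a weak reference enhancer missed by peak calling);
* class2 — orthologue exists, density at or below background (functional
  loss with sequence conservation);
* class3 — no orthologous sequence at all (lift-over fails).

Reference enhancers whose lifted position overlaps no query enhancer are
*reference-specific* — functional non-conservation, irrespective of
sequence conservation.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import Enhancer, Gene, GenomicInterval, build_locus, _GeneIndex
from .liftover import ChainSet, MappingResult, map_interval

__all__ = [
    "ClassificationConfig",
    "ClassificationResult",
    "CompensationResult",
    "ReadDensityTable",
    "cross_map_enhancer_sets",
    "classify_lineage_specific",
    "classify_enhancers",
    "outgroup_presence",
    "orthologous_locus_compensation",
    "classification_summary",
]


@dataclass
class ClassificationConfig:
    """Thresholds for shared/lineage-specific and class I/II/III calls."""

    min_match: float = 0.95  # liftOver default aligned-fraction threshold
    overlap_rule: int = 1  # minimum overlapping bases for "shared"
    background_density: float | None = None  # reads/bp; None -> from ECRs

    def __post_init__(self) -> None:
        if not 0 < self.min_match <= 1:
            raise ValueError("min_match must be in (0, 1]")
        if self.overlap_rule < 1:
            raise ValueError("overlap_rule must be >= 1")
        if self.background_density is not None and self.background_density < 0:
            raise ValueError("background_density must be >= 0")


class ReadDensityTable:
    """ChIP read counts per genomic interval, queried as reads per base."""

    def __init__(self, table: pd.DataFrame) -> None:
        self._rows: dict[str, tuple[list[int], np.ndarray, np.ndarray]] = {}
        for chrom, grp in table.groupby("chrom", sort=True):
            grp = grp.sort_values("start")
            self._rows[str(chrom)] = (
                grp["start"].tolist(),
                grp["end"].to_numpy(),
                grp["reads"].to_numpy(float),
            )

    def density_over(self, interval: GenomicInterval) -> float | None:
        """Reads overlapping the interval / interval length.

        Reads of a partially overlapping row contribute proportionally to
        the overlapped fraction of the row. None when no row overlaps.
        """
        rows = self._rows.get(interval.chrom)
        if rows is None:
            return None
        starts, ends, reads = rows
        # rows are non-overlapping and sorted by start
        j = max(0, bisect.bisect_right(starts, interval.start) - 1)
        total = 0.0
        hit = False
        while j < len(starts) and starts[j] < interval.end:
            ov = min(ends[j], interval.end) - max(starts[j], interval.start)
            if ov > 0:
                hit = True
                total += reads[j] * ov / (ends[j] - starts[j])
            j += 1
        return total / len(interval) if hit else None

    def mean_density(self) -> float:
        """Mean reads-per-base over all rows (ECR background level)."""
        num, den = 0.0, 0.0
        for starts, ends, reads in self._rows.values():
            num += float(reads.sum())
            den += float((ends - np.array(starts)).sum())
        if den == 0:
            raise ValueError("empty density table")
        return num / den


@dataclass
class ClassificationResult:
    labels: dict[str, str]  # query enhancer id -> class label
    reference_labels: dict[str, str]  # reference enhancer id -> label
    mappings: dict[str, MappingResult] = field(default_factory=dict)

    def by_class(self, enhancers: list[Enhancer]) -> dict[str, list[Enhancer]]:
        out: dict[str, list[Enhancer]] = {}
        for e in enhancers:
            out.setdefault(self.labels[e.id], []).append(e)
        return out


def _overlap_hits(
    targets: list[GenomicInterval], queries: list[Enhancer], min_bp: int
) -> tuple[set[str], set[str]]:
    """(query ids hit, target ids hit) for >= min_bp overlaps."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in targets:
        by_chrom.setdefault(t.chrom, []).append(t)
    for lst in by_chrom.values():
        lst.sort(key=lambda iv: iv.start)
    q_hit: set[str] = set()
    t_hit: set[str] = set()
    for q in queries:
        iv = q.interval
        for t in by_chrom.get(iv.chrom, []):
            if t.start >= iv.end:
                break
            if min(t.end, iv.end) - max(t.start, iv.start) >= min_bp:
                q_hit.add(q.id)
                t_hit.add(t.id)
    return q_hit, t_hit


def cross_map_enhancer_sets(
    query_enhancers: list[Enhancer],
    reference_enhancers: list[Enhancer],
    chains_ref_to_query: ChainSet,
    config: ClassificationConfig | None = None,
) -> ClassificationResult:
    """Label query enhancers shared vs lineage-specific by functional overlap.

    Reference enhancers are lifted into query coordinates; query enhancers
    overlapping a lifted reference enhancer by at least ``overlap_rule``
    bases are shared, the rest lineage-specific. Reference enhancers hitting
    no query enhancer are reference-specific.
    """
    config = config or ClassificationConfig()
    lifted: list[GenomicInterval] = []
    ref_mapped_ids: set[str] = set()
    mappings: dict[str, MappingResult] = {}
    for ref in reference_enhancers:
        res = map_interval(ref.interval, chains_ref_to_query, config.min_match)
        mappings[ref.id] = res
        if res.status == "mapped":
            lifted.append(res.target)
            ref_mapped_ids.add(ref.id)
    shared_q, shared_ref = _overlap_hits(lifted, query_enhancers, config.overlap_rule)
    labels = {
        e.id: ("shared" if e.id in shared_q else "lineage_specific")
        for e in query_enhancers
    }
    ref_labels = {
        r.id: ("shared" if r.id in shared_ref else "reference_specific")
        for r in reference_enhancers
    }
    return ClassificationResult(labels, ref_labels, mappings)


def classify_lineage_specific(
    lineage_enhancers: list[Enhancer],
    chains_query_to_ref: ChainSet,
    density: ReadDensityTable,
    config: ClassificationConfig | None = None,
    ecr_density: ReadDensityTable | None = None,
) -> tuple[dict[str, str], dict[str, MappingResult]]:
    """Partition lineage-specific enhancers into class1/class2/class3.

    The background read density is ``config.background_density`` when set,
    else the mean reads-per-base over the supplied ECR table.
    """
    config = config or ClassificationConfig()
    background = config.background_density
    if background is None:
        if ecr_density is None:
            raise ValueError("need background_density or an ECR density table")
        background = ecr_density.mean_density()
    labels: dict[str, str] = {}
    mappings: dict[str, MappingResult] = {}
    for enh in lineage_enhancers:
        res = map_interval(enh.interval, chains_query_to_ref, config.min_match)
        mappings[enh.id] = res
        if res.status != "mapped":
            labels[enh.id] = "class3"
            continue
        d = density.density_over(res.target)
        if d is None:
            warnings.warn(
                f"no read density for orthologue of {enh.id}; treating as 0",
                stacklevel=2,
            )
            d = 0.0
        labels[enh.id] = "class1" if d > background else "class2"
    return labels, mappings


def classify_enhancers(
    query_enhancers: list[Enhancer],
    reference_enhancers: list[Enhancer],
    chains_ref_to_query: ChainSet,
    chains_query_to_ref: ChainSet,
    density: ReadDensityTable,
    config: ClassificationConfig | None = None,
    ecr_density: ReadDensityTable | None = None,
) -> ClassificationResult:
    """Full classification: shared, then class1/2/3 for the remainder.

    Every query enhancer receives exactly one of
    {shared, class1, class2, class3}; the label is also written onto
    ``Enhancer.class_label``.
    """
    result = cross_map_enhancer_sets(
        query_enhancers, reference_enhancers, chains_ref_to_query, config
    )
    lineage = [e for e in query_enhancers if result.labels[e.id] == "lineage_specific"]
    sub_labels, sub_maps = classify_lineage_specific(
        lineage, chains_query_to_ref, density, config, ecr_density
    )
    result.labels.update(sub_labels)
    result.mappings.update(sub_maps)
    for e in query_enhancers:
        e.class_label = result.labels[e.id]
    for r in reference_enhancers:
        if result.reference_labels[r.id] == "reference_specific":
            r.class_label = "species_specific"
    return result


def classification_summary(labels: dict[str, str]) -> dict:
    """Class counts plus the headline lineage-specific percentage."""
    counts: dict[str, int] = {}
    for lab in labels.values():
        counts[lab] = counts.get(lab, 0) + 1
    total = len(labels)
    n_shared = counts.get("shared", 0)
    pct_ls = round(100.0 * (total - n_shared) / total) if total else 0
    return {
        "counts": dict(sorted(counts.items())),
        "n_total": total,
        "n_shared": n_shared,
        "n_lineage_specific": total - n_shared,
        "pct_lineage_specific": pct_ls,
    }


def outgroup_presence(
    class3_enhancers: list[Enhancer],
    outgroup_chains: dict[str, ChainSet],
    min_match: float = 0.95,
) -> tuple[dict[str, bool], float]:
    """Presence of class-III sequences in at least one out-group genome.

    Presence in any out-group implies the sequence is ancestral, i.e. it was
    deleted in the reference lineage rather than inserted in the query
    lineage. Returns per-enhancer flags and the summary fraction.
    """
    if not outgroup_chains:
        warnings.warn("no out-group chains supplied; presence fraction is 0", stacklevel=2)
        return {e.id: False for e in class3_enhancers}, 0.0
    flags: dict[str, bool] = {}
    for enh in class3_enhancers:
        flags[enh.id] = any(
            map_interval(enh.interval, cs, min_match).status == "mapped"
            for cs in outgroup_chains.values()
        )
    total = len(flags)
    fraction = sum(flags.values()) / total if total else 0.0
    return flags, fraction


@dataclass
class CompensationResult:
    enhancer_class: str
    n_singletons: int
    n_with_locus: int  # singletons whose orthologous locus could be built
    n_compensated: int  # locus holds >= 1 reference-specific enhancer
    fraction: float
    mean_distance: float | None  # lifted position to nearest compensator
    n_excluded: int


def _ref_specific_index(ref_specific: list[Enhancer]) -> dict[str, np.ndarray]:
    mids: dict[str, list[int]] = {}
    for e in ref_specific:
        mids.setdefault(e.interval.chrom, []).append(e.midpoint)
    return {c: np.array(sorted(v)) for c, v in mids.items()}


def orthologous_locus_compensation(
    singletons_by_class: dict[str, list[Enhancer]],
    chains_query_to_ref: ChainSet,
    query_genes: list[Gene],
    ref_genes: list[Gene],
    homolog_map: dict[str, str],
    ref_specific_enhancers: list[Enhancer],
    query_chrom_sizes: dict[str, int],
    ref_chrom_sizes: dict[str, int],
    min_match: float = 0.95,
) -> dict[str, CompensationResult]:
    """Redundancy analysis: does the orthologous locus of a singleton query
    enhancer hold a reference-specific enhancer that could compensate its
    absence in the reference genome?

    Mappable singletons are lifted and their reference-side locus is built
    from the reference annotation. Class-III singletons have no orthologous
    sequence, so their locus is projected through the homologous flanking
    genes instead and the locus midpoint serves as the distance reference
    point. Singletons whose locus cannot be projected are excluded from the
    denominator and counted.
    """
    q_index = _GeneIndex(list(query_genes))
    r_index = _GeneIndex(list(ref_genes))
    ref_gene_by_id = {g.gene_id: g for g in ref_genes}
    rs_mids = _ref_specific_index(ref_specific_enhancers)

    out: dict[str, CompensationResult] = {}
    for cls, singles in singletons_by_class.items():
        n_comp = 0
        n_locus = 0
        n_excl = 0
        distances: list[float] = []
        for enh in singles:
            anchor: tuple[str, int] | None = None
            boundary: GenomicInterval | None = None
            if cls != "class3":
                res = map_interval(enh.interval, chains_query_to_ref, min_match)
                if res.status == "mapped":
                    lifted = Enhancer(res.target, species="reference")
                    locus = build_locus(
                        lifted, r_index, ref_chrom_sizes[res.target.chrom]
                    )
                    boundary = locus.boundary
                    anchor = (res.target.chrom, res.target.midpoint)
            if boundary is None:
                # project the query locus through homologous flanking genes
                q_locus = build_locus(
                    enh, q_index, query_chrom_sizes[enh.interval.chrom]
                )
                homs = [
                    ref_gene_by_id[homolog_map[g.gene_id]]
                    for g in q_locus.genes
                    if g.gene_id in homolog_map
                    and homolog_map[g.gene_id] in ref_gene_by_id
                ]
                if homs and len({g.chrom for g in homs}) == 1:
                    lo = min(g.start for g in homs)
                    hi = max(g.end for g in homs)
                    if hi > lo:
                        boundary = GenomicInterval(homs[0].chrom, lo, hi)
                        anchor = (boundary.chrom, boundary.midpoint)
            if boundary is None:
                n_excl += 1
                continue
            n_locus += 1
            mids = rs_mids.get(boundary.chrom)
            if mids is not None:
                inside = mids[(mids >= boundary.start) & (mids < boundary.end)]
                if inside.size:
                    n_comp += 1
                    distances.append(float(np.abs(inside - anchor[1]).min()))
        out[cls] = CompensationResult(
            enhancer_class=cls,
            n_singletons=len(singles),
            n_with_locus=n_locus,
            n_compensated=n_comp,
            fraction=n_comp / n_locus if n_locus else 0.0,
            mean_distance=float(np.mean(distances)) if distances else None,
            n_excluded=n_excl,
        )
    return out
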