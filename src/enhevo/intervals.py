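"""Core genomic coordinate model.

Intervals are 0-based, half-open (BED convention) throughout. The central
construct is the *regulatory locus* of an enhancer: for an intergenic
enhancer the locus spans the two flanking genes plus the intergenic region
between them; for an intronic enhancer it spans the host gene plus both
flanking intergenic intervals (i.e. from the end of the previous gene to the
start of the next gene). Two enhancers belong to the same locus iff their
loci are defined by the same flanking-gene pair or the same host gene.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicInterval",
    "Gene",
    "Enhancer",
    "Locus",
    "LocusMap",
    "ClusteringResult",
    "nearest_tss_distance",
    "build_locus",
    "assign_enhancers_to_loci",
    "find_singletons",
    "clustering_simulation",
    "gc_content",
    "cpg_overlap_fraction",
    "bin_counts",
    "TSS_DISTANCE_BINS",
    "LOCUS_LENGTH_BINS",
]

# Reporting bins: distance to nearest TSS (<10 kb, 10-50 kb, >50 kb) and
# locus length (<200 kb, 200-500 kb, >500 kb).
TSS_DISTANCE_BINS = (10_000, 50_000)
LOCUS_LENGTH_BINS = (200_000, 500_000)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    id: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Gene:
    """A gene body with a single TSS at its strand-appropriate end."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.gene_id, self.strand)


@dataclass
class Enhancer:
    interval: GenomicInterval
    species: str = ""
    read_density: float | None = None
    class_label: str = "unclassified"

    @property
    def id(self) -> str:
        return self.interval.id

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass
class Locus:
    boundary: GenomicInterval
    genes: list[Gene]
    context: str  # "intergenic" | "intronic" | "chromosome"
    key: tuple = field(default=())

    @property
    def length(self) -> int:
        return len(self.boundary)


@dataclass
class ClusteringResult:
    focal_class: str
    pct_clustered_with_shared: float
    pct_clustered_with_lineage: float
    sd_with_shared: float
    sd_with_lineage: float
    replicates: int
    draws_per_class: int


class LocusMap:
    """Partition of enhancers into regulatory loci.

    ``loci`` maps locus key -> Locus; ``members`` maps locus key -> member
    enhancers; ``locus_of`` maps enhancer id -> locus key.
    """

    def __init__(self) -> None:
        self.loci: dict[tuple, Locus] = {}
        self.members: dict[tuple, list[Enhancer]] = {}
        self.locus_of: dict[str, tuple] = {}

    def add(self, enhancer: Enhancer, locus: Locus) -> None:
        key = locus.key
        if key not in self.loci:
            self.loci[key] = locus
            self.members[key] = []
        self.members[key].append(enhancer)
        self.locus_of[enhancer.id] = key

    def locus_size(self, enhancer_id: str) -> int:
        return len(self.members[self.locus_of[enhancer_id]])

    def __len__(self) -> int:
        return len(self.loci)


class _GeneIndex:
    """Per-chromosome sorted gene lookup."""

    def __init__(self, genes: list[Gene]) -> None:
        self.by_chrom: dict[str, list[Gene]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)
        self.starts: dict[str, list[int]] = {}
        for chrom, gs in self.by_chrom.items():
            gs.sort(key=lambda g: g.start)
            self.starts[chrom] = [g.start for g in gs]

    def on(self, chrom: str) -> list[Gene]:
        return self.by_chrom.get(chrom, [])


def nearest_tss_distance(enhancer: Enhancer, genes: list[Gene] | _GeneIndex) -> int | None:
    """Distance from the enhancer midpoint to the closest TSS on its chromosome.

    Returns None when the chromosome carries no gene (distance undefined).
    """
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(list(genes))
    chrom_genes = index.on(enhancer.interval.chrom)
    if not chrom_genes:
        return None
    mid = enhancer.midpoint
    return min(abs(mid - g.tss) for g in chrom_genes)


def _flanking(chrom_genes: list[Gene], starts: list[int], iv: GenomicInterval):
    """(host, previous, next) genes relative to an interval.

    host: gene overlapping the interval body (genes assumed non-overlapping,
    any overlap counts as intronic). previous/next: nearest genes strictly
    left/right of the interval (or of the host gene when intronic).
    """
    i = bisect.bisect_right(starts, iv.start) - 1
    host = None
    if i >= 0 and chrom_genes[i].end > iv.start:
        host = chrom_genes[i]
    elif i + 1 < len(chrom_genes) and chrom_genes[i + 1].start < iv.end:
        host = chrom_genes[i + 1]
    if host is not None:
        hi = chrom_genes.index(host)
        prev_g = chrom_genes[hi - 1] if hi > 0 else None
        next_g = chrom_genes[hi + 1] if hi + 1 < len(chrom_genes) else None
        return host, prev_g, next_g
    prev_g = chrom_genes[i] if i >= 0 else None
    next_g = chrom_genes[i + 1] if i + 1 < len(chrom_genes) else None
    return None, prev_g, next_g


def build_locus(enhancer: Enhancer, genes: list[Gene] | _GeneIndex, chrom_size: int) -> Locus:
    """Construct the regulatory locus of an enhancer.

    Intergenic: boundary from the start of the upstream flanking gene to the
    end of the downstream flanking gene. Intronic (enhancer overlaps a gene
    body): boundary from the end of the previous gene to the start of the
    next gene. Boundaries are clipped to [0, chrom_size]; an enhancer on a
    gene-free chromosome gets the whole chromosome, flagged via context.
    """
    iv = enhancer.interval
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(list(genes))
    chrom_genes = index.on(iv.chrom)
    if not chrom_genes:
        boundary = GenomicInterval(iv.chrom, 0, chrom_size)
        return Locus(boundary, [], "chromosome", key=("chromosome", iv.chrom))
    starts = index.starts[iv.chrom]
    host, prev_g, next_g = _flanking(chrom_genes, starts, iv)
    if host is not None:
        start = prev_g.end if prev_g is not None else 0
        end = next_g.start if next_g is not None else chrom_size
        members = [g for g in (prev_g, host, next_g) if g is not None]
        # host gene identifies the locus
        key = ("intronic", iv.chrom, host.gene_id)
        context = "intronic"
    else:
        start = prev_g.start if prev_g is not None else 0
        end = next_g.end if next_g is not None else chrom_size
        members = [g for g in (prev_g, next_g) if g is not None]
        key = (
            "intergenic",
            iv.chrom,
            prev_g.gene_id if prev_g else None,
            next_g.gene_id if next_g else None,
        )
        context = "intergenic"
    boundary = GenomicInterval(iv.chrom, max(0, start), min(chrom_size, end))
    return Locus(boundary, members, context, key=key)


def assign_enhancers_to_loci(
    enhancers: list[Enhancer],
    genes: list[Gene],
    chrom_sizes: dict[str, int],
) -> LocusMap:
    """Assign every enhancer to exactly one locus; co-locus iff same key."""
    index = _GeneIndex(list(genes))
    lmap = LocusMap()
    for enh in enhancers:
        size = chrom_sizes[enh.interval.chrom]
        lmap.add(enh, build_locus(enh, index, size))
    return lmap


def find_singletons(lmap: LocusMap) -> list[Enhancer]:
    """Enhancers that are the only member of their locus."""
    return [ms[0] for ms in lmap.members.values() if len(ms) == 1]


def _locus_codes(enhancers: list[Enhancer], lmap: LocusMap) -> np.ndarray:
    keys = {k: i for i, k in enumerate(lmap.loci)}
    return np.array([keys[lmap.locus_of[e.id]] for e in enhancers], dtype=np.int64)


def clustering_simulation(
    shared: list[Enhancer],
    lineage: list[Enhancer],
    lmap: LocusMap,
    draws_per_class: int = 500,
    replicates: int = 1000,
    seed: int | np.random.Generator = 0,
    min_cluster_size: int = 2,
) -> dict[str, ClusteringResult]:
    """Resampling estimate of co-locus clustering between enhancer classes.

    Per replicate, ``draws_per_class`` enhancers are sampled without
    replacement from each class; a focal enhancer counts as clustered with
    class X when its locus holds enough sampled class-X enhancers to reach
    ``min_cluster_size`` members including itself. Returns one result per
    focal class with mean percentages over replicates and their dispersion.
    """
    if not shared or not lineage:
        raise ValueError("both enhancer classes must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loci = {"shared": _locus_codes(shared, lmap), "lineage": _locus_codes(lineage, lmap)}
    sizes = {k: len(v) for k, v in loci.items()}
    draws = {k: min(draws_per_class, sizes[k]) for k in sizes}
    if any(draws[k] < draws_per_class for k in draws):
        import warnings

        warnings.warn("class smaller than draws_per_class; draws reduced", stacklevel=2)
    need_other = min_cluster_size - 1  # sampled others of class X in the locus
    n_codes = int(max(v.max(initial=0) for v in loci.values())) + 1
    pcts: dict[tuple[str, str], list[float]] = {
        (f, o): [] for f in loci for o in loci
    }
    for _ in range(replicates):
        sample = {
            k: loci[k][rng.choice(sizes[k], size=draws[k], replace=False)]
            for k in loci
        }
        counts = {k: np.bincount(sample[k], minlength=n_codes) for k in loci}
        for focal in loci:
            for other in loci:
                c = counts[other][sample[focal]]
                if focal == other:
                    clustered = c >= need_other + 1  # focal itself is counted
                else:
                    clustered = c >= need_other
                pcts[(focal, other)].append(100.0 * clustered.mean())
    out = {}
    for focal in loci:
        ws = np.array(pcts[(focal, "shared")])
        wl = np.array(pcts[(focal, "lineage")])
        out[focal] = ClusteringResult(
            focal_class=focal,
            pct_clustered_with_shared=float(ws.mean()),
            pct_clustered_with_lineage=float(wl.mean()),
            sd_with_shared=float(ws.std(ddof=1)) if replicates > 1 else 0.0,
            sd_with_lineage=float(wl.std(ddof=1)) if replicates > 1 else 0.0,
            replicates=replicates,
            draws_per_class=draws[focal],
        )
    return out


def gc_content(interval: GenomicInterval, genome) -> float:
    """(G+C) / (A+C+G+T) over the interval; ambiguous bases excluded.

    ``genome`` is any mapping of chromosome name to sliceable sequence
    (e.g. a ``pyfaidx.Fasta``).
    """
    record = genome[interval.chrom]
    if interval.end > len(record):
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} "
            "extends beyond sequence end"
        )
    seq = str(record[interval.start : interval.end]).upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("interval contains no unambiguous bases")
    return gc / (gc + at)


def cpg_overlap_fraction(
    enhancers: list[Enhancer], islands: list[GenomicInterval]
) -> float:
    """Fraction of enhancers overlapping (>= 1 bp) at least one island."""
    if not enhancers:
        return 0.0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for isl in islands:
        by_chrom.setdefault(isl.chrom, []).append((isl.start, isl.end))
    index: dict[str, tuple[list[int], np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = [s for s, _ in ivs]
        # running max of island ends: a hit exists iff some island starting
        # before the enhancer end reaches past the enhancer start
        max_ends = np.maximum.accumulate(np.array([e for _, e in ivs]))
        index[chrom] = (starts, max_ends)
    n_hit = 0
    for enh in enhancers:
        iv = enh.interval
        if iv.chrom not in index:
            continue
        starts, max_ends = index[iv.chrom]
        i = bisect.bisect_right(starts, iv.end - 1)
        if i > 0 and max_ends[i - 1] > iv.start:
            n_hit += 1
    return n_hit / len(enhancers)


def bin_counts(values: list[float], edges: tuple[float, ...]) -> dict[str, int]:
    """Count values into <edge0, edge0-edge1, ..., >edgeN report bins."""
    labels = (
        [f"<{edges[0]}"]
        + [f"{a}-{b}" for a, b in zip(edges, edges[1:])]
        + [f">{edges[-1]}"]
    )
    counts = dict.fromkeys(labels, 0)
    for v in values:
        idx = bisect.bisect_right(list(edges), v)
        counts[labels[idx]] += 1
    return counts
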