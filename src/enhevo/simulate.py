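"""Seeded synthetic fixture bundles with planted ground truth.

The generator emulates the data model of a two-species comparative enhancer
study: a query genome with annotated genes and tissue enhancers, a
reference genome related to it by a chain-file alignment with planted
deletions, SNPs with neutral vs selection-shifted derived-allele-frequency
spectra, expression tables with planted tissue-high genes, a flat GO map
with cardiac-named terms, CpG islands, pseudogene (neutral reference)
regions and a histone-signal track.

Planted structure and what recovers it downstream:

* a ``frac_shared`` fraction of query enhancers has an aligned counterpart
  in the reference enhancer set (recovered by cross-mapping);
* lineage-specific enhancers split into class1 (orthologue with
  above-background read density), class2 (at/below background) and class3
  (inside a planted chain deletion, hence unmappable);
* ``clustering_bias`` co-places enhancers of the same conservation group in
  already-occupied loci (recovered by the clustering simulation);
* planted heart genes are boosted ``heart_effect``-fold in heart samples
  (recovered by the top-N ranking) and sit preferentially in loci of shared
  enhancers;
* constrained regions draw DAF from a distribution with excess
  low-frequency mass and reduced divergence (recovered by the DAF spectrum
  contrast and the MK neutrality index);
* reference-specific enhancers are planted into the orthologous loci of
  singleton query enhancers at class-specific compensation rates.

All randomness flows from one ``numpy`` generator seeded by
``SimConfig.seed``: identical configs produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .intervals import Enhancer, Gene, GenomicInterval, assign_enhancers_to_loci
from .liftover import Chain, write_chain

__all__ = [
    "SimConfig",
    "GroundTruth",
    "Bundle",
    "generate_annotation",
    "generate_enhancer_sets",
    "generate_chain_file",
    "generate_variants",
    "generate_expression_tables",
    "generate_go_annotations",
    "generate_signal_track",
    "write_fixture_bundle",
    "load_bundle",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of one synthetic study; defaults emulate the study design.

    Fractions mirror the observed composition of the real enhancer sets
    (21% shared; 78.3/10.5/11.2% class I/II/III among lineage-specific);
    expression uses 5 heart and 10 non-heart samples with an 8-fold boost
    for planted heart genes; DAF distributions are Beta-shaped with the
    constrained class shifted toward low frequencies; constrained regions
    have their divergence reduced by ``selection_divergence_factor``.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 2_000_000
    n_genes: int = 240
    n_enhancers_query: int = 600
    n_enhancers_reference: int = 660
    frac_shared: float = 0.21
    frac_class1: float = 0.783
    frac_class2: float = 0.105
    frac_class3: float = 0.112
    clustering_bias: float = 0.3
    daf_neutral_params: tuple[float, float] = (0.3, 1.2)
    daf_selected_params: tuple[float, float] = (0.22, 1.6)
    snp_rate: float = 0.02  # SNPs per base
    divergence_rate: float = 0.03  # interspecies differences per base (neutral)
    het_rate: float = 0.004  # heterozygous sites per base
    selection_divergence_factor: float = 0.675
    ancestral_missing_frac: float = 0.05
    n_heart_samples: int = 5
    n_nonheart_samples: int = 10
    heart_effect: float = 8.0
    n_heart_genes: int = 60
    n_go_terms: int = 200
    frac_cardiac_terms: float = 0.15
    genes_per_term: tuple[int, int] = (5, 25)
    enhancer_length: int = 600
    frac_intronic: float = 0.2
    deletion_margin: int = 400
    background_density: float = 1.0
    n_ecr: int = 200
    ecr_length: int = 1_000
    n_pseudogenes: int = 120
    pseudogene_length: int = 1_000
    n_cpg_islands: int = 120
    cpg_island_length: int = 800
    cpg_shared_bias: float = 0.6
    n_outgroups: int = 2
    outgroup_absent_frac: float = 0.02
    comp_rate_shared: float = 0.60
    comp_rate_class2: float = 0.15
    comp_rate_class3: float = 0.26
    signal_bump_height: float = 5.0
    signal_bump_sigma: float = 500.0
    signal_background: float = 0.2
    signal_bin: int = 50
    include_fasta: bool = True
    include_signal: bool = True
    gc_background: float = 0.40
    gc_shared: float = 0.60

    def validate(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length": self.chrom_length,
            "n_enhancers_query": self.n_enhancers_query,
            "n_enhancers_reference": self.n_enhancers_reference,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not 0 <= self.frac_shared <= 1:
            raise ValueError("frac_shared must be in [0, 1]")
        s = self.frac_class1 + self.frac_class2 + self.frac_class3
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {s}")
        if not 0 <= self.clustering_bias <= 1:
            raise ValueError("clustering_bias must be in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["daf_neutral_params"] = list(self.daf_neutral_params)
        d["daf_selected_params"] = list(self.daf_selected_params)
        d["genes_per_term"] = list(self.genes_per_term)
        return d


@dataclass
class GroundTruth:
    """Planted truth for every generated object."""

    labels: dict[str, str] = field(default_factory=dict)  # enhancer id -> class
    regimes: dict[str, str] = field(default_factory=dict)  # region id -> regime
    heart_genes: list[str] = field(default_factory=list)
    compensated_loci: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "regimes": self.regimes,
            "heart_genes": self.heart_genes,
            "compensated_loci": self.compensated_loci,
        }


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


def generate_annotation(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[Gene], dict[str, int]]:
    """Non-overlapping genes with strand and a single TSS per gene."""
    config.validate()
    sizes = {_chrom_name(i): config.chrom_length for i in range(config.n_chromosomes)}
    chroms = list(sizes)
    per_chrom = [
        config.n_genes // len(chroms) + (1 if i < config.n_genes % len(chroms) else 0)
        for i in range(len(chroms))
    ]
    genes: list[Gene] = []
    gi = 0
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        lengths = rng.integers(2_000, 10_000, size=k)
        min_gap = 1_000
        free = config.chrom_length - int(lengths.sum()) - (k + 1) * min_gap
        if free < 0:
            raise ValueError(
                f"chromosome {chrom} too short ({config.chrom_length} bp) to place "
                f"{k} genes without overlap"
            )
        gaps = np.floor(rng.dirichlet(np.ones(k + 1)) * free).astype(int) + min_gap
        pos = 0
        for j in range(k):
            pos += int(gaps[j])
            start = pos
            end = start + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(chrom, start, end, strand, f"g{gi:05d}"))
            pos = end
            gi += 1
    return genes, sizes


@dataclass
class _Layout:
    """Internal placement bookkeeping shared across generation steps."""

    genes: list[Gene]
    chrom_sizes: dict[str, int]
    query_enhancers: list[Enhancer] = field(default_factory=list)
    reference_enhancers: list[Enhancer] = field(default_factory=list)
    deletions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    truth: GroundTruth = field(default_factory=GroundTruth)
    # query-coordinate positions of reference-only enhancers (pre-lift)
    ref_only_query_coords: list[GenomicInterval] = field(default_factory=list)
    chain_split_points: dict[str, int] = field(default_factory=dict)


def _intergenic_gaps(genes: list[Gene], sizes: dict[str, int], margin: int = 1_500):
    """(chrom, lo, hi, locus_key) usable intergenic windows between genes.

    The slot key equals the locus key an enhancer placed in the window will
    receive from ``build_locus``, so placement bias and locus bookkeeping
    agree downstream.
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    gaps = []
    for chrom in sizes:
        gs = sorted(by_chrom.get(chrom, []), key=lambda g: g.start)
        bounds = [0] + [x for g in gs for x in (g.start, g.end)] + [sizes[chrom]]
        for i in range(0, len(bounds), 2):
            j = i // 2
            lo, hi = bounds[i] + margin, bounds[i + 1] - margin
            if hi - lo >= 2_000:
                prev_id = gs[j - 1].gene_id if j > 0 else None
                next_id = gs[j].gene_id if j < len(gs) else None
                gaps.append((chrom, lo, hi, ("intergenic", chrom, prev_id, next_id)))
    return gaps


def _place_in_window(
    rng: np.random.Generator,
    lo: int,
    hi: int,
    length: int,
    occupied: list[tuple[int, int]],
    tries: int = 40,
    sep: int = 200,
) -> tuple[int, int] | None:
    if hi - lo < length:
        return None
    for _ in range(tries):
        start = int(rng.integers(lo, hi - length + 1))
        end = start + length
        if all(end + sep <= s or e + sep <= start for s, e in occupied):
            return start, end
    return None


def generate_enhancer_sets(
    config: SimConfig, genes: list[Gene], chrom_sizes: dict[str, int], rng: np.random.Generator
) -> _Layout:
    """Place query and reference enhancer sets with planted class structure."""
    config.validate()
    layout = _Layout(genes=genes, chrom_sizes=chrom_sizes)
    n_q = config.n_enhancers_query
    n_shared = int(round(config.frac_shared * n_q))
    n_ls = n_q - n_shared
    n_c3 = int(round(config.frac_class3 * n_ls))
    n_c2 = int(round(config.frac_class2 * n_ls))
    n_c1 = n_ls - n_c2 - n_c3
    if min(n_c1, 0) < 0:
        raise ValueError("infeasible class fractions")
    labels = (
        ["shared"] * n_shared + ["class1"] * n_c1 + ["class2"] * n_c2 + ["class3"] * n_c3
    )
    rng.shuffle(labels)

    gaps = _intergenic_gaps(genes, chrom_sizes)
    if not gaps:
        raise ValueError("no intergenic space to place enhancers")
    genes_list = [g for g in genes if g.end - g.start > 3_000]
    occupied: dict[tuple, list[tuple[int, int]]] = {}
    # same-locus placement bias is conservation-group-assortative
    group_slots: dict[str, list[tuple]] = {"shared": [], "lineage": []}
    slot_window = {g[3]: (g[0], g[1], g[2]) for g in gaps}
    for g in genes_list:
        key = ("intronic", g.chrom, g.gene_id)
        slot_window[key] = (g.chrom, g.start + 500, g.end - 500)

    intron_keys = [("intronic", g.chrom, g.gene_id) for g in genes_list]
    gap_keys = [g[3] for g in gaps]
    # deletions extend deletion_margin beyond class3 enhancers; keep every
    # pair of enhancers separated further than that so no deletion clips a
    # non-class3 enhancer
    sep = config.deletion_margin + 100

    def _pick_slot(label: str) -> tuple:
        group = "shared" if label == "shared" else "lineage"
        pool = group_slots[group]
        if pool and rng.random() < config.clustering_bias:
            return pool[int(rng.integers(len(pool)))]
        # class3 must sit in an intergenic gap (its deletion may not touch genes)
        if label != "class3" and intron_keys and rng.random() < config.frac_intronic:
            return intron_keys[int(rng.integers(len(intron_keys)))]
        return gap_keys[int(rng.integers(len(gap_keys)))]

    length = config.enhancer_length
    for i, label in enumerate(labels):
        placed = None
        for _ in range(200):
            slot = _pick_slot(label)
            if label == "class3" and slot[0] == "intronic":
                continue
            chrom, lo, hi = slot_window[slot]
            if label == "class3":
                # leave room for the deletion margin inside the window
                lo2, hi2 = lo + config.deletion_margin, hi - config.deletion_margin
            else:
                lo2, hi2 = lo, hi
            placed = _place_in_window(
                rng, lo2, hi2, length, occupied.setdefault(slot, []), sep=sep
            )
            if placed is not None:
                break
        if placed is None:
            raise ValueError("could not place all enhancers; genome too crowded")
        occupied[slot].append(placed)
        group_slots["shared" if label == "shared" else "lineage"].append(slot)
        iv = GenomicInterval(chrom, placed[0], placed[1], f"qe{i:05d}")
        layout.query_enhancers.append(Enhancer(iv, species="query"))
        layout.truth.labels[iv.id] = label

    # planted deletions around class3 enhancers (merged if adjacent)
    dels: dict[str, list[tuple[int, int]]] = {}
    for enh in layout.query_enhancers:
        if layout.truth.labels[enh.id] != "class3":
            continue
        iv = enh.interval
        dels.setdefault(iv.chrom, []).append(
            (iv.start - config.deletion_margin, iv.end + config.deletion_margin)
        )
    for chrom, lst in dels.items():
        lst.sort()
        merged = [list(lst[0])]
        for s, e in lst[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        dels[chrom] = [(s, e) for s, e in merged]
    layout.deletions = dels

    # one split point per chromosome (inside a gene body, away from enhancers)
    for chrom in chrom_sizes:
        host = next((g for g in genes if g.chrom == chrom), None)
        if host is not None:
            layout.chain_split_points[chrom] = (host.start + host.end) // 2

    _plant_reference_set(config, layout, rng)
    return layout


def _q_to_ref(layout: _Layout, chrom: str, pos: int) -> int:
    """Project a query coordinate to reference coordinates (identity - deletions)."""
    shift = 0
    for s, e in layout.deletions.get(chrom, []):
        if e <= pos:
            shift += e - s
        elif s <= pos:
            raise ValueError("position inside a planted deletion")
    return pos - shift


def _ref_chrom_sizes(layout: _Layout) -> dict[str, int]:
    return {
        chrom: size - sum(e - s for s, e in layout.deletions.get(chrom, []))
        for chrom, size in layout.chrom_sizes.items()
    }


def _plant_reference_set(config: SimConfig, layout: _Layout, rng: np.random.Generator) -> None:
    """Reference enhancers: shared counterparts + reference-specific extras.

    Reference-specific enhancers are first planted into the loci of
    singleton query enhancers at the class compensation rates, then the
    remainder go to unoccupied loci.
    """
    truth = layout.truth
    ref_enh: list[Enhancer] = []
    ri = 0
    for enh in layout.query_enhancers:
        if truth.labels[enh.id] != "shared":
            continue
        iv = enh.interval
        start = _q_to_ref(layout, iv.chrom, iv.start)
        ref_iv = GenomicInterval(f"r_{iv.chrom}", start, start + len(iv), f"re{ri:05d}")
        ref_enh.append(Enhancer(ref_iv, species="reference"))
        truth.labels[ref_iv.id] = "shared_counterpart"
        ri += 1

    lmap = assign_enhancers_to_loci(
        layout.query_enhancers, layout.genes, layout.chrom_sizes
    )
    comp_rates = {
        "shared": config.comp_rate_shared,
        "class2": config.comp_rate_class2,
        "class3": config.comp_rate_class3,
    }
    occupied: dict[str, list[tuple[int, int]]] = {
        c: [] for c in layout.chrom_sizes
    }
    for e in layout.query_enhancers:
        occupied[e.interval.chrom].append((e.interval.start, e.interval.end))

    def _free_in(chrom, lo, hi):
        win = _place_in_window(
            rng, lo, hi, config.enhancer_length, occupied[chrom], tries=60
        )
        if win is None:
            return None
        # keep clear of planted deletions
        for s, e in layout.deletions.get(chrom, []):
            if win[0] < e and s < win[1]:
                return None
        return win

    n_extra = config.n_enhancers_reference - sum(
        1 for lab in truth.labels.values() if lab == "shared_counterpart"
    )
    if n_extra < 0:
        raise ValueError("n_enhancers_reference smaller than planted shared count")

    def _add_ref_specific(chrom: str, win: tuple[int, int]) -> None:
        nonlocal ri
        occupied[chrom].append(win)
        start = _q_to_ref(layout, chrom, win[0])
        ref_iv = GenomicInterval(
            f"r_{chrom}", start, start + config.enhancer_length, f"re{ri:05d}"
        )
        ref_enh.append(Enhancer(ref_iv, species="reference"))
        truth.labels[ref_iv.id] = "reference_specific"
        layout.ref_only_query_coords.append(
            GenomicInterval(chrom, win[0], win[1], ref_iv.id)
        )
        ri += 1

    # gaps whose window lies inside a singleton locus boundary are reserved
    # for the planted compensation draws below
    singleton_items: list[tuple[tuple, Enhancer]] = [
        (key, ms[0]) for key, ms in lmap.members.items() if len(ms) == 1
    ]
    singleton_bounds: dict[str, list[tuple[int, int]]] = {}
    for key, enh in singleton_items:
        b = lmap.loci[key].boundary
        singleton_bounds.setdefault(b.chrom, []).append((b.start, b.end))

    planted = 0
    for key, enh in singleton_items:
        cls = truth.labels[enh.id]
        rate = comp_rates.get(cls)
        if rate is None:
            continue
        do_comp = bool(rng.random() < rate) and planted < n_extra
        if not do_comp:
            continue
        b = lmap.loci[key].boundary
        win = _free_in(b.chrom, b.start + 200, b.end - 200)
        if win is None:
            continue
        _add_ref_specific(b.chrom, win)
        planted += 1

    # remaining reference-specific enhancers avoid all singleton loci
    gaps = _intergenic_gaps(layout.genes, layout.chrom_sizes)
    guard = 0
    while planted < n_extra and guard < 50 * n_extra + 1000:
        guard += 1
        chrom, lo, hi, _ = gaps[int(rng.integers(len(gaps)))]
        win = _free_in(chrom, lo, hi)
        if win is None:
            continue
        if any(win[0] < e and s < win[1] for s, e in singleton_bounds.get(chrom, [])):
            continue
        _add_ref_specific(chrom, win)
        planted += 1
    if planted < n_extra:
        raise ValueError("could not place all reference-specific enhancers")
    layout.reference_enhancers = ref_enh

    # exact planted truth: a singleton locus is compensated iff a
    # reference-specific enhancer midpoint landed inside its boundary
    rs_mids: dict[str, list[int]] = {}
    for iv in layout.ref_only_query_coords:
        rs_mids.setdefault(iv.chrom, []).append(iv.midpoint)
    for key, enh in singleton_items:
        if truth.labels[enh.id] not in comp_rates:
            continue
        b = lmap.loci[key].boundary
        truth.compensated_loci[enh.id] = any(
            b.start <= m < b.end for m in rs_mids.get(b.chrom, [])
        )


def generate_chain_file(config: SimConfig, layout: _Layout, rng: np.random.Generator):
    """Chains in both directions plus out-group chain sets.

    The query->reference chain per chromosome is identity with dt gaps at
    planted deletions; one chromosome's chain is split in two at a point
    inside a gene to exercise split handling, and a low-score off-diagonal
    decoy chain tests chain-selection order. Out-group chains are identity
    chains that omit a small fraction of class3 regions (sequences absent
    from every out-group).
    """
    ref_sizes = _ref_chrom_sizes(layout)
    q2r: list[Chain] = []
    r2q: list[Chain] = []
    cid = 1
    split_chrom = list(layout.chrom_sizes)[0] if layout.chrom_sizes else None

    for chrom, size in layout.chrom_sizes.items():
        dels = layout.deletions.get(chrom, [])
        rsize = ref_sizes[chrom]
        pieces: list[tuple[int, int]] = [(0, size)]
        if chrom == split_chrom and chrom in layout.chain_split_points:
            sp = layout.chain_split_points[chrom]
            if any(s < sp < e for s, e in dels):
                sp = None
            if sp and 0 < sp < size:
                pieces = [(0, sp), (sp, size)]
        for p_lo, p_hi in pieces:
            # blocks between deletions restricted to this piece
            blocks: list[tuple[int, int, int]] = []
            cur = p_lo
            piece_dels = [(max(s, p_lo), min(e, p_hi)) for s, e in dels if s < p_hi and e > p_lo]
            for s, e in piece_dels:
                if s > cur:
                    blocks.append((s - cur, e - s, 0))
                cur = e
            if p_hi > cur:
                blocks.append((p_hi - cur, 0, 0))
            elif blocks:
                size_, dt, dq = blocks[-1]
                blocks[-1] = (size_, 0, 0)
            if not blocks:
                continue
            t_start = p_lo
            t_end = p_hi
            q_start = _q_to_ref(layout, chrom, _first_alignable(p_lo, piece_dels))
            q_span = sum(b[0] for b in blocks)
            # trailing deletion gap shortens the source span of the chain
            t_span = sum(b[0] + b[1] for b in blocks)
            t_end = t_start + t_span
            ch = Chain(
                score=1_000_000 + (p_hi - p_lo),
                t_name=chrom,
                t_size=size,
                t_strand="+",
                t_start=t_start,
                t_end=t_end,
                q_name=f"r_{chrom}",
                q_size=rsize,
                q_strand="+",
                q_start=q_start,
                q_end=q_start + q_span,
                chain_id=str(cid),
                blocks=blocks,
            )
            ch.validate()
            q2r.append(ch)
            r2q.append(_invert_chain(ch, str(cid + 500)))
            cid += 1

    # low-score off-diagonal decoy: maps the start of chr1 onto a shifted
    # location; never selected while a high-score chain overlaps
    if layout.chrom_sizes:
        chrom = list(layout.chrom_sizes)[0]
        size = layout.chrom_sizes[chrom]
        rsize = ref_sizes[chrom]
        span = min(50_000, size // 4, rsize // 4)
        if span >= 1000:
            decoy = Chain(
                score=100,
                t_name=chrom,
                t_size=size,
                t_strand="+",
                t_start=0,
                t_end=span,
                q_name=f"r_{chrom}",
                q_size=rsize,
                q_strand="+",
                q_start=rsize - span,
                q_end=rsize,
                chain_id="9999",
                blocks=[(span, 0, 0)],
            )
            q2r.append(decoy)

    outgroups: dict[str, list[Chain]] = {}
    class3 = [
        e for e in layout.query_enhancers
        if layout.truth.labels[e.id] == "class3"
    ]
    absent_ids = {
        e.id
        for e in class3
        if rng.random() < config.outgroup_absent_frac
    }
    for og in range(config.n_outgroups):
        name = f"outgroup{og + 1}"
        chains: list[Chain] = []
        for chrom, size in layout.chrom_sizes.items():
            # absent class3 regions are gaps in every out-group chain
            holes = sorted(
                (e.interval.start, e.interval.end)
                for e in class3
                if e.interval.chrom == chrom and e.id in absent_ids
            )
            blocks = []
            cur = 0
            for s, e in holes:
                if s > cur:
                    blocks.append((s - cur, e - s, e - s))
                cur = e
            if size > cur:
                blocks.append((size - cur, 0, 0))
            elif blocks:
                b = blocks[-1]
                blocks[-1] = (b[0], 0, 0)
            ch = Chain(
                score=500_000,
                t_name=chrom,
                t_size=size,
                t_strand="+",
                t_start=0,
                t_end=sum(b[0] + b[1] for b in blocks),
                q_name=f"{name}_{chrom}",
                q_size=size,
                q_strand="+",
                q_start=0,
                q_end=sum(b[0] + b[2] for b in blocks),
                chain_id=str(og + 1),
                blocks=blocks,
            )
            ch.validate()
            chains.append(ch)
        outgroups[name] = chains
    return q2r, r2q, outgroups, absent_ids


def _first_alignable(pos: int, dels: list[tuple[int, int]]) -> int:
    for s, e in dels:
        if s <= pos < e:
            return e
    return pos


def _invert_chain(ch: Chain, cid: str) -> Chain:
    blocks = [(size, dq, dt) for size, dt, dq in ch.blocks]
    # drop trailing source-side gap so the last block is gapless
    size_, dt, dq = blocks[-1]
    assert dt == 0 and dq == 0
    return Chain(
        score=ch.score,
        t_name=ch.q_name,
        t_size=ch.q_size,
        t_strand="+",
        t_start=ch.q_start,
        t_end=ch.q_end,
        q_name=ch.t_name,
        q_size=ch.t_size,
        q_strand="+",
        q_start=ch.t_start,
        q_end=ch.t_end,
        chain_id=cid,
        blocks=blocks,
    )


def generate_variants(
    config: SimConfig,
    regions: list[tuple[GenomicInterval, str]],
    chrom_sizes: dict[str, int],
    rng: np.random.Generator,
):
    """SNPs with regime-dependent DAF spectra plus a divergence table.

    ``regions``: (interval, regime) pairs, regime in {neutral, constrained}.
    Returns (variant tuples for the VCF writer, divergence DataFrame).
    Constrained regions draw DAF from the selection-shifted Beta and have
    their interspecies divergence reduced by the selection factor.
    """
    params = {
        "neutral": config.daf_neutral_params,
        "constrained": config.daf_selected_params,
    }
    records = []
    div_rows = []
    for iv, regime in regions:
        if iv.chrom not in chrom_sizes or iv.end > chrom_sizes[iv.chrom]:
            raise ValueError(f"region {iv.id} outside chromosome")
        a, b = params[regime]
        L = len(iv)
        n = int(rng.poisson(L * config.snp_rate))
        n = min(n, L)
        if n:
            offsets = rng.choice(L, size=n, replace=False)
            offsets.sort()
            dafs = rng.beta(a, b, size=n)
            for off, daf in zip(offsets, dafs):
                ref_i, alt_i = rng.choice(4, size=2, replace=False)
                ref, alt = _BASES[ref_i], _BASES[alt_i]
                anc_is_ref = rng.random() < 0.5
                af = float(daf if anc_is_ref else 1.0 - daf)
                aa = (ref if anc_is_ref else alt)
                if rng.random() < config.ancestral_missing_frac:
                    aa = None
                records.append((iv.chrom, iv.start + int(off) + 1, str(ref), str(alt), af, aa))
        d_rate = config.divergence_rate * (
            config.selection_divergence_factor if regime == "constrained" else 1.0
        )
        d = int(rng.poisson(L * d_rate))
        pi = int(rng.poisson(L * config.het_rate))
        div_rows.append(
            {"region_id": iv.id, "chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "regime": regime, "d": d, "pi": pi}
        )
    records.sort(key=lambda r: (r[0], r[1]))
    return records, pd.DataFrame(div_rows)


def generate_expression_tables(
    config: SimConfig,
    genes: list[Gene],
    heart_genes: list[str],
    rng: np.random.Generator,
):
    """Query + reference expression matrices and the homolog map.

    Base per-gene expression is log-normal; planted heart genes are boosted
    ``heart_effect``-fold in heart samples. Reference homologs reuse the
    base profile with mild noise, so matched profiles correlate strongly.
    """
    gene_ids = [g.gene_id for g in genes]
    heart_set = set(heart_genes)
    base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=len(gene_ids))

    def _samples(n, boost_mask=None):
        cols = {}
        for s in range(n):
            noise = rng.lognormal(mean=0.0, sigma=0.3, size=len(gene_ids))
            vals = base * noise
            if boost_mask is not None:
                vals = np.where(boost_mask, vals * config.heart_effect, vals)
            cols[f"s{s + 1}"] = vals
        return cols

    boost = np.array([g in heart_set for g in gene_ids])
    heart = pd.DataFrame(_samples(config.n_heart_samples, boost), index=gene_ids)
    nonheart = pd.DataFrame(_samples(config.n_nonheart_samples), index=gene_ids)
    heart.index.name = nonheart.index.name = "gene_id"

    homolog_map = {g: f"r_{g}" for g in gene_ids}
    ref_ids = [homolog_map[g] for g in gene_ids]
    ref_noise = rng.lognormal(mean=0.0, sigma=0.2, size=len(gene_ids))
    ref_base = base * ref_noise
    ref_heart = pd.DataFrame(
        {
            f"s{s + 1}": ref_base
            * np.where(boost, config.heart_effect, 1.0)
            * rng.lognormal(0.0, 0.3, len(gene_ids))
            for s in range(config.n_heart_samples)
        },
        index=ref_ids,
    )
    ref_nonheart = pd.DataFrame(
        {
            f"s{s + 1}": ref_base * rng.lognormal(0.0, 0.3, len(gene_ids))
            for s in range(config.n_nonheart_samples)
        },
        index=ref_ids,
    )
    ref_heart.index.name = ref_nonheart.index.name = "gene_id"
    return heart, nonheart, ref_heart, ref_nonheart, homolog_map


def generate_go_annotations(
    config: SimConfig,
    genes: list[Gene],
    favored_genes: set[str],
    rng: np.random.Generator,
) -> dict[str, tuple[str, frozenset]]:
    """Flat GO map; cardiac-named terms preferentially annotate favored genes."""
    cardiac_stems = (
        "heart morphogenesis",
        "cardiac muscle contraction",
        "cardioblast differentiation",
        "heart looping",
        "cardiac septum development",
        "cardiovascular system development",
    )
    other_stems = (
        "neuron differentiation",
        "kidney development",
        "immune response",
        "lipid metabolic process",
        "axon guidance",
        "cell cycle checkpoint",
    )
    gene_ids = np.array([g.gene_id for g in genes])
    if gene_ids.size == 0:
        return {}
    favored = np.array([g in favored_genes for g in gene_ids], dtype=float)
    n_cardiac = int(round(config.frac_cardiac_terms * config.n_go_terms))
    terms: dict[str, tuple[str, frozenset]] = {}
    lo, hi = config.genes_per_term
    for i in range(config.n_go_terms):
        cardiac = i < n_cardiac
        stems = cardiac_stems if cardiac else other_stems
        name = f"{stems[i % len(stems)]} {i:03d}"
        k = int(rng.integers(lo, hi + 1))
        k = min(k, gene_ids.size)
        if cardiac and favored.sum() > 0:
            w = 1.0 + 9.0 * favored
            p = w / w.sum()
            members = rng.choice(gene_ids, size=k, replace=False, p=p)
        else:
            members = rng.choice(gene_ids, size=k, replace=False)
        terms[f"T{i:04d}"] = (name, frozenset(str(m) for m in members))
    return terms


def generate_signal_track(
    config: SimConfig,
    chrom_sizes: dict[str, int],
    bump_centers: list[tuple[str, int]],
    rng: np.random.Generator,
):
    """Binned bedGraph: uniform noisy background + Gaussian bumps."""
    rows = []
    binsize = config.signal_bin
    centers_by_chrom: dict[str, list[int]] = {}
    for chrom, mid in bump_centers:
        centers_by_chrom.setdefault(chrom, []).append(mid)
    for chrom, size in chrom_sizes.items():
        n_bins = size // binsize
        starts = np.arange(n_bins) * binsize
        vals = config.signal_background * (1.0 + 0.2 * rng.standard_normal(n_bins))
        vals = np.clip(vals, 0, None)
        mids = starts + binsize / 2
        for c in centers_by_chrom.get(chrom, []):
            sigma = max(config.signal_bump_sigma, 1e-9)
            vals = vals + config.signal_bump_height * np.exp(
                -0.5 * ((mids - c) / sigma) ** 2
            )
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": starts + binsize, "value": vals}
            )
        )
    return pd.concat(rows, ignore_index=True)


def _random_regions(
    rng: np.random.Generator,
    chrom_sizes: dict[str, int],
    n: int,
    length: int,
    avoid: list[GenomicInterval],
    prefix: str,
) -> list[GenomicInterval]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in avoid:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = []
    chroms = list(chrom_sizes)
    guard = 0
    while len(out) < n and guard < 100 * n + 1000:
        guard += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = chrom_sizes[chrom]
        if size <= length:
            continue
        start = int(rng.integers(0, size - length))
        end = start + length
        if any(start < e and s < end for s, e in by_chrom.get(chrom, [])):
            continue
        iv = GenomicInterval(chrom, start, end, f"{prefix}{len(out):05d}")
        out.append(iv)
        by_chrom.setdefault(chrom, []).append((start, end))
    if len(out) < n:
        raise ValueError(f"could not place {n} {prefix} regions")
    return out


def _write_fasta(config: SimConfig, layout: _Layout, rng: np.random.Generator, path) -> None:
    shared_ivs: dict[str, list[tuple[int, int]]] = {}
    for e in layout.query_enhancers:
        if layout.truth.labels[e.id] == "shared":
            shared_ivs.setdefault(e.interval.chrom, []).append(
                (e.interval.start, e.interval.end)
            )
    with open(path, "w") as fh:
        for chrom, size in layout.chrom_sizes.items():
            gc = config.gc_background
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            codes = rng.choice(4, size=size, p=p)
            gcs = config.gc_shared
            ps = np.array([(1 - gcs) / 2, gcs / 2, gcs / 2, (1 - gcs) / 2])
            for s, e in shared_ivs.get(chrom, []):
                codes[s:e] = rng.choice(4, size=e - s, p=ps)
            seq = "".join(_BASES[codes])
            fh.write(f">{chrom}\n")
            for i in range(0, size, 80):
                fh.write(seq[i : i + 80] + "\n")


FILES = {
    "chrom_sizes": "chrom.sizes",
    "ref_chrom_sizes": "ref_chrom.sizes",
    "genes": "genes.tsv",
    "ref_genes": "ref_genes.tsv",
    "query_enhancers": "enhancers_query.bed",
    "reference_enhancers": "enhancers_reference.bed",
    "chain_q2r": "query_to_ref.chain",
    "chain_r2q": "ref_to_query.chain",
    "variants": "variants.vcf",
    "divergence": "divergence.tsv",
    "pseudogenes": "pseudogenes.bed",
    "cpg_islands": "cpg_islands.bed",
    "density": "ref_read_density.tsv",
    "ecr": "ecr_read_density.tsv",
    "expression_heart": "expression_heart.tsv",
    "expression_nonheart": "expression_nonheart.tsv",
    "expression_ref_heart": "expression_ref_heart.tsv",
    "expression_ref_nonheart": "expression_ref_nonheart.tsv",
    "homolog_map": "homolog_map.tsv",
    "go": "go_annotations.tsv",
    "ground_truth": "ground_truth.json",
    "manifest": "manifest.json",
}
OPTIONAL_FILES = {"genome": "genome.fa", "signal": "signal.bedgraph"}


@dataclass
class Bundle:
    """Paths and key objects of one generated fixture bundle."""

    root: Path
    config: SimConfig
    truth: GroundTruth

    def path(self, key: str) -> Path:
        name = FILES.get(key) or OPTIONAL_FILES.get(key)
        if name is None:
            raise KeyError(key)
        return self.root / name


def write_fixture_bundle(config: SimConfig, outdir) -> Bundle:
    """Generate and write a complete, self-describing fixture bundle."""
    config.validate()
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    genes, chrom_sizes = generate_annotation(config, rng)
    layout = generate_enhancer_sets(config, genes, chrom_sizes, rng)
    truth = layout.truth
    q2r, r2q, outgroups, absent_ids = generate_chain_file(config, layout, rng)
    ref_sizes = _ref_chrom_sizes(layout)

    # reference annotation: genes projected through the deletion map
    ref_genes = [
        Gene(
            f"r_{g.chrom}",
            _q_to_ref(layout, g.chrom, g.start),
            _q_to_ref(layout, g.chrom, g.end),
            g.strand,
            f"r_{g.gene_id}",
        )
        for g in genes
    ]

    # regions for the selection analysis: enhancers constrained, pseudogenes neutral
    avoid = [e.interval for e in layout.query_enhancers] + [g.interval for g in genes]
    pseudogenes = _random_regions(
        rng, chrom_sizes, config.n_pseudogenes, config.pseudogene_length, avoid, "pg"
    )
    regions = [(e.interval, "constrained") for e in layout.query_enhancers]
    regions += [(iv, "neutral") for iv in pseudogenes]
    for iv, regime in regions:
        truth.regimes[iv.id] = regime
    variant_records, divergence = generate_variants(config, regions, chrom_sizes, rng)

    # read densities over reference orthologue intervals + ECR background
    density_rows = []
    for e in layout.query_enhancers:
        lab = truth.labels[e.id]
        if lab not in ("class1", "class2"):
            continue
        iv = e.interval
        start = _q_to_ref(layout, iv.chrom, iv.start)
        L = len(iv)
        if lab == "class1":
            dens = config.background_density * float(rng.uniform(2.0, 4.0))
        else:
            dens = config.background_density * float(rng.uniform(0.0, 0.8))
        density_rows.append(
            {"chrom": f"r_{iv.chrom}", "start": start, "end": start + L,
             "reads": round(dens * L, 3)}
        )
    density_df = pd.DataFrame(
        density_rows, columns=["chrom", "start", "end", "reads"]
    ).sort_values(["chrom", "start"])
    ref_sizes = {f"r_{c}": s for c, s in ref_sizes.items()}
    ecr_ivs = _random_regions(
        rng, ref_sizes, config.n_ecr, config.ecr_length, [], "ecr",
    )
    ecr_df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in ecr_ivs],
            "start": [iv.start for iv in ecr_ivs],
            "end": [iv.end for iv in ecr_ivs],
            "reads": [
                float(rng.poisson(config.background_density * len(iv))) for iv in ecr_ivs
            ],
        }
    ).sort_values(["chrom", "start"])

    # planted heart genes: prefer genes flanking shared enhancers
    from .annotation import nearest_gene as _nearest

    shared_enh = [e for e in layout.query_enhancers if truth.labels[e.id] == "shared"]
    near_shared: list[str] = []
    seen = set()
    for e in shared_enh:
        g = _nearest(e, genes)
        if g and g.gene_id not in seen:
            seen.add(g.gene_id)
            near_shared.append(g.gene_id)
    pool = near_shared + [g.gene_id for g in genes if g.gene_id not in seen]
    heart_genes = pool[: min(config.n_heart_genes, len(pool))]
    truth.heart_genes = list(heart_genes)

    heart, nonheart, ref_heart, ref_nonheart, homolog_map = generate_expression_tables(
        config, genes, heart_genes, rng
    )
    go_terms = generate_go_annotations(config, genes, set(near_shared), rng)

    # CpG islands overlap shared enhancers preferentially
    cpg: list[GenomicInterval] = []
    k_biased = int(round(config.cpg_shared_bias * config.n_cpg_islands))
    order = rng.permutation(len(shared_enh)) if shared_enh else []
    for idx in list(order)[:k_biased]:
        e = shared_enh[int(idx)]
        mid = e.midpoint
        half = config.cpg_island_length // 2
        start = max(0, mid - half)
        cpg.append(
            GenomicInterval(
                e.interval.chrom, start, start + config.cpg_island_length,
                f"cpg{len(cpg):05d}",
            )
        )
    cpg += _random_regions(
        rng, chrom_sizes, config.n_cpg_islands - len(cpg), config.cpg_island_length,
        [e.interval for e in layout.query_enhancers], "cpgr",
    )

    # write everything
    paths = {k: root / v for k, v in FILES.items()}
    io.write_chrom_sizes(chrom_sizes, paths["chrom_sizes"])
    io.write_chrom_sizes(ref_sizes, paths["ref_chrom_sizes"])
    io.write_genes(genes, paths["genes"])
    io.write_genes(ref_genes, paths["ref_genes"])
    io.write_enhancer_bed(layout.query_enhancers, paths["query_enhancers"])
    io.write_enhancer_bed(layout.reference_enhancers, paths["reference_enhancers"])
    write_chain(q2r, paths["chain_q2r"])
    write_chain(r2q, paths["chain_r2q"])
    for name, chains in outgroups.items():
        write_chain(chains, root / f"{name}.chain")
    io.write_vcf(variant_records, chrom_sizes, paths["variants"])
    divergence.to_csv(paths["divergence"], sep="\t", index=False)
    io.write_bed(pseudogenes, paths["pseudogenes"])
    io.write_bed(cpg, paths["cpg_islands"])
    io.write_density_table(density_df, paths["density"])
    io.write_density_table(ecr_df, paths["ecr"])
    io.write_expression(heart, paths["expression_heart"])
    io.write_expression(nonheart, paths["expression_nonheart"])
    io.write_expression(ref_heart, paths["expression_ref_heart"])
    io.write_expression(ref_nonheart, paths["expression_ref_nonheart"])
    io.write_homolog_map(homolog_map, paths["homolog_map"])
    io.write_go_annotations(go_terms, paths["go"])

    optional = {}
    if config.include_fasta:
        _write_fasta(config, layout, rng, root / OPTIONAL_FILES["genome"])
        optional["genome"] = OPTIONAL_FILES["genome"]
    if config.include_signal:
        bumps = [(e.interval.chrom, e.midpoint) for e in shared_enh]
        track = generate_signal_track(config, chrom_sizes, bumps, rng)
        io.write_bedgraph(track, root / OPTIONAL_FILES["signal"])
        optional["signal"] = OPTIONAL_FILES["signal"]

    truth_dict = truth.to_dict()
    truth_dict["outgroup_absent"] = sorted(absent_ids)
    io.write_json(truth_dict, paths["ground_truth"])
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "files": {**{k: v for k, v in FILES.items() if k != "manifest"}, **optional,
                  **{f"outgroup_{n}": f"{n}.chain" for n in outgroups}},
        "outgroups": sorted(outgroups),
    }
    io.write_json(manifest, paths["manifest"])
    return Bundle(root=root, config=config, truth=truth)


class MissingInputError(FileNotFoundError):
    pass


def load_bundle(root) -> dict:
    """Load a bundle directory into in-memory objects for the pipeline.

    Raises MissingInputError naming the first missing input file.
    """
    from .liftover import ChainSet, parse_chain

    root = Path(root)
    manifest_path = root / FILES["manifest"]
    if not manifest_path.exists():
        raise MissingInputError(f"missing input: {manifest_path}")
    manifest = io.read_json(manifest_path)
    for key, name in manifest["files"].items():
        if not (root / name).exists():
            raise MissingInputError(f"missing input '{key}': {root / name}")
    files = manifest["files"]
    data = {
        "manifest": manifest,
        "chrom_sizes": io.read_chrom_sizes(root / files["chrom_sizes"]),
        "ref_chrom_sizes": io.read_chrom_sizes(root / files["ref_chrom_sizes"]),
        "genes": io.read_genes(root / files["genes"]),
        "ref_genes": io.read_genes(root / files["ref_genes"]),
        "query_enhancers": io.read_enhancer_bed(root / files["query_enhancers"], "query"),
        "reference_enhancers": io.read_enhancer_bed(
            root / files["reference_enhancers"], "reference"
        ),
        "chains_q2r": ChainSet(parse_chain(root / files["chain_q2r"])),
        "chains_r2q": ChainSet(parse_chain(root / files["chain_r2q"])),
        "outgroup_chains": {
            name: ChainSet(parse_chain(root / f"{name}.chain"))
            for name in manifest.get("outgroups", [])
        },
        "variants_path": root / files["variants"],
        "divergence": pd.read_csv(root / files["divergence"], sep="\t"),
        "pseudogenes": io.read_bed(root / files["pseudogenes"]),
        "cpg_islands": io.read_bed(root / files["cpg_islands"]),
        "density": io.read_density_table(root / files["density"]),
        "ecr": io.read_density_table(root / files["ecr"]),
        "expression_heart": io.read_expression(root / files["expression_heart"]),
        "expression_nonheart": io.read_expression(root / files["expression_nonheart"]),
        "expression_ref_heart": io.read_expression(root / files["expression_ref_heart"]),
        "expression_ref_nonheart": io.read_expression(
            root / files["expression_ref_nonheart"]
        ),
        "homolog_map": io.read_homolog_map(root / files["homolog_map"]),
        "go": io.read_go_annotations(root / files["go"]),
        "ground_truth": io.read_json(root / FILES["ground_truth"]),
    }
    if "genome" in files:
        data["genome_path"] = root / files["genome"]
    if "signal" in files:
        data["signal"] = io.read_bedgraph(root / files["signal"])
    return data
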