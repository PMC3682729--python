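"""Nearest-gene assignment, cardiac GO enrichment and signal metaprofiles.

GO annotations are consumed as a flat term -> gene-set map (no DAG
propagation). Cardiac terms are those whose name contains "heart",
"cardiac" or "cardio" (case-insensitive substring match). Enrichment of a
test gene set T against a background B is Fisher's exact test per term with
Bonferroni correction over the terms actually tested (those with at least
one annotated gene in B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import Enhancer, Gene, _GeneIndex
from .stats import fisher_exact_2x2

__all__ = [
    "MetaProfile",
    "SignalTrack",
    "nearest_gene",
    "cardiac_term_filter",
    "go_enrichment",
    "cardiac_fold_enrichment",
    "signal_metaprofile",
    "mark_overlap_test",
]

CARDIAC_SUBSTRINGS = ("heart", "cardiac", "cardio")


def nearest_gene(enhancer: Enhancer, genes: list[Gene] | _GeneIndex) -> Gene | None:
    """Gene whose TSS is closest to the enhancer midpoint; ties by gene id."""
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(list(genes))
    chrom_genes = index.on(enhancer.interval.chrom)
    if not chrom_genes:
        return None
    mid = enhancer.midpoint
    return min(chrom_genes, key=lambda g: (abs(mid - g.tss), g.gene_id))


def cardiac_term_filter(annotations: dict[str, tuple[str, frozenset]]) -> set[str]:
    """Term ids whose name contains a cardiac substring (case-insensitive)."""
    out = set()
    for term_id, (name, _) in annotations.items():
        low = name.lower()
        if any(s in low for s in CARDIAC_SUBSTRINGS):
            out.add(term_id)
    return out


def go_enrichment(
    test_genes: set[str],
    background_genes: set[str],
    annotations: dict[str, tuple[str, frozenset]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term Fisher enrichment of T within B with Bonferroni correction.

    The test contrasts membership in the term between T and the rest of the
    background (B - T), i.e. the hypergeometric model of drawing |T| genes
    from B. Returns a frame with the 2x2 counts against the full background
    (a = |T & term|, b = |T - term|, c = |B & term|, d = |B - term|), odds
    ratio, raw and Bonferroni p, and fold enrichment (a/|T|)/(c/|B|). Only
    terms with >= 1 annotated gene in B are tested and counted toward the
    correction.
    """
    if not test_genes:
        raise ValueError("test gene set is empty")
    if not test_genes <= background_genes:
        raise ValueError("test genes must be a subset of the background")
    nT, nB = len(test_genes), len(background_genes)
    rows = []
    for term_id in sorted(annotations):
        name, genes = annotations[term_id]
        c = len(genes & background_genes)
        if c == 0:
            continue
        a = len(genes & test_genes)
        odds, p = fisher_exact_2x2([[a, nT - a], [c - a, (nB - nT) - (c - a)]])
        rows.append(
            {
                "term_id": term_id,
                "term_name": name,
                "a": a,
                "b": nT - a,
                "c": c,
                "d": nB - c,
                "odds_ratio": odds,
                "p_value": p,
                "fold_enrichment": (a / nT) / (c / nB),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_bonferroni"] = np.minimum(1.0, df["p_value"] * len(df))
        df["significant"] = df["p_bonferroni"] <= alpha
        df = df.sort_values(["p_value", "term_id"]).reset_index(drop=True)
    return df


def cardiac_fold_enrichment(
    class_gene_sets: dict[str, set[str]],
    control_genes: set[str],
    annotations: dict[str, tuple[str, frozenset]],
) -> pd.DataFrame:
    """Cardiac-annotation rate per enhancer class relative to a control set.

    For each class, the fraction of its (deduplicated) nearest genes
    annotated to >= 1 cardiac term, divided by the same fraction in the
    control gene set; the binomial p tests the class count against the
    control rate.
    """
    cardiac_terms = cardiac_term_filter(annotations)
    cardiac_genes: set[str] = set()
    for t in cardiac_terms:
        cardiac_genes |= set(annotations[t][1])
    n_ctrl = len(control_genes)
    k_ctrl = len(control_genes & cardiac_genes)
    ctrl_rate = k_ctrl / n_ctrl if n_ctrl else 0.0
    rows = []
    for cls in sorted(class_gene_sets):
        genes = class_gene_sets[cls]
        k = len(genes & cardiac_genes)
        n = len(genes)
        frac = k / n if n else 0.0
        if n and 0 < ctrl_rate < 1:
            p = sps.binomtest(k, n, ctrl_rate).pvalue
        else:
            p = None
        rows.append(
            {
                "class": cls,
                "n_genes": n,
                "n_cardiac": k,
                "fraction_cardiac": frac,
                "fold_enrichment": (frac / ctrl_rate) if ctrl_rate else 0.0,
                "p_vs_control": p,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MetaProfile:
    bin_centers: np.ndarray  # offsets from enhancer midpoint, bases
    mean_signal: np.ndarray
    n_regions: int
    window: int
    n_bins: int


class SignalTrack:
    """Dense per-chromosome signal materialized from a bedGraph frame."""

    def __init__(self, bedgraph: pd.DataFrame, chrom_sizes: dict[str, int]) -> None:
        self.chrom_sizes = dict(chrom_sizes)
        self._arrays: dict[str, np.ndarray] = {
            c: np.zeros(size, dtype=np.float32) for c, size in chrom_sizes.items()
        }
        for r in bedgraph.itertuples():
            arr = self._arrays.get(str(r.chrom))
            if arr is None:
                continue
            arr[max(0, int(r.start)) : min(len(arr), int(r.end))] = r.value

    def window_values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Signal over [start, end); positions outside the chromosome read 0."""
        size = self.chrom_sizes.get(chrom)
        out = np.zeros(end - start, dtype=np.float32)
        if size is None:
            return out
        lo, hi = max(0, start), min(size, end)
        if lo < hi:
            out[lo - start : hi - start] = self._arrays[chrom][lo:hi]
        return out


def signal_metaprofile(
    enhancers: list[Enhancer],
    track: SignalTrack,
    window: int = 5000,
    n_bins: int = 50,
) -> MetaProfile:
    """Mean signal in bins over [midpoint - window, midpoint + window).

    Each enhancer contributes its per-bin average; the profile is the mean
    over enhancers. Bins are symmetric about the midpoint.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    if not enhancers:
        raise ValueError("no enhancers supplied")
    width = 2 * window
    edges = np.linspace(0, width, n_bins + 1).astype(int)
    acc = np.zeros(n_bins)
    for e in enhancers:
        mid = e.midpoint
        vals = track.window_values(e.interval.chrom, mid - window, mid + window)
        for i in range(n_bins):
            acc[i] += vals[edges[i] : edges[i + 1]].mean()
    centers = (edges[:-1] + edges[1:]) / 2 - window
    return MetaProfile(
        bin_centers=centers,
        mean_signal=acc / len(enhancers),
        n_regions=len(enhancers),
        window=window,
        n_bins=n_bins,
    )


def mark_overlap_test(
    class_a: list[Enhancer],
    class_b: list[Enhancer],
    peaks: list,
) -> dict:
    """Fisher contrast of peak-overlap rates between two enhancer classes."""
    from .intervals import cpg_overlap_fraction  # same >=1 bp overlap semantics

    def _count(enhancers):
        frac = cpg_overlap_fraction(enhancers, peaks)
        k = round(frac * len(enhancers))
        return k, len(enhancers) - k

    a_in, a_out = _count(class_a)
    b_in, b_out = _count(class_b)
    odds, p = fisher_exact_2x2([[a_in, a_out], [b_in, b_out]])
    return {
        "fraction_a": a_in / len(class_a) if class_a else 0.0,
        "fraction_b": b_in / len(class_b) if class_b else 0.0,
        "odds_ratio": odds,
        "p_value": p,
    }
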