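"""Heart-specificity ranking and expression impact of enhancer classes.

The heart-specificity score of a gene is the log2 ratio of its mean heart
expression to its mean non-heart expression after adding a small offset
(default 16) to both means, which stabilises ratios at low expression. The
top-ranked genes define the highly expressed heart gene set; enhancer
classes are then compared by the fraction of their members whose regulatory
locus contains such a gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import Enhancer, LocusMap
from .stats import fisher_exact_2x2

__all__ = [
    "ProfileComparison",
    "heart_specificity_score",
    "top_heart_genes",
    "fraction_in_high_expression_loci",
    "high_expression_contrast",
    "profile_r2",
]

DEFAULT_OFFSET = 16.0


@dataclass
class ProfileComparison:
    label: str
    r_squared: float | None
    n_genes: int


def heart_specificity_score(
    heart: pd.DataFrame,
    nonheart: pd.DataFrame,
    offset: float = DEFAULT_OFFSET,
) -> pd.DataFrame:
    """Per-gene heart-specificity scores.

    Parameters
    ----------
    heart, nonheart : expression matrices indexed by gene_id (one column per
        sample). Gene universes are intersected.
    offset : pseudo-expression added to both means before the log ratio.

    Returns a frame indexed by gene_id with columns heart_mean,
    nonheart_mean and score = log2(heart_mean+offset) - log2(nonheart_mean+offset).
    """
    if heart.shape[1] < 1 or nonheart.shape[1] < 1:
        raise ValueError("need at least one sample per condition")
    if (heart.to_numpy() < 0).any() or (nonheart.to_numpy() < 0).any():
        raise ValueError("negative expression values")
    genes = heart.index.intersection(nonheart.index)
    hm = heart.loc[genes].mean(axis=1)
    nm = nonheart.loc[genes].mean(axis=1)
    if offset <= 0 and ((hm == 0).any() or (nm == 0).any()):
        raise ValueError("offset must be > 0 when zero expression values are present")
    score = np.log2(hm + offset) - np.log2(nm + offset)
    return pd.DataFrame(
        {"heart_mean": hm, "nonheart_mean": nm, "score": score}, index=genes
    )


def top_heart_genes(records: pd.DataFrame, n: int = 1000) -> list[str]:
    """The n highest-scoring genes; boundary ties broken by gene id."""
    order = sorted(records["score"].items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [gene for gene, _ in order[:n]]


def fraction_in_high_expression_loci(
    enhancers: list[Enhancer],
    lmap: LocusMap,
    top_genes: set[str] | list[str],
) -> float:
    """Fraction of enhancers whose locus holds >= 1 top heart gene."""
    if not enhancers:
        return 0.0
    top = set(top_genes)
    hits = 0
    for e in enhancers:
        locus = lmap.loci[lmap.locus_of[e.id]]
        if any(g.gene_id in top for g in locus.genes):
            hits += 1
    return hits / len(enhancers)


def high_expression_contrast(
    class_a: list[Enhancer],
    class_b: list[Enhancer],
    lmap: LocusMap,
    top_genes: set[str] | list[str],
) -> dict:
    """Fisher's exact contrast of two classes' high-expression-locus rates."""
    top = set(top_genes)

    def _count(enhancers):
        k = sum(
            any(g.gene_id in top for g in lmap.loci[lmap.locus_of[e.id]].genes)
            for e in enhancers
        )
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


def profile_r2(
    query_profile: pd.Series,
    reference_profile: pd.Series,
    homolog_map: dict[str, str],
    offset: float = DEFAULT_OFFSET,
    log_scale: bool = True,
    label: str = "",
) -> ProfileComparison:
    """Squared Pearson correlation between homolog-matched expression profiles.

    Profiles are matched through the query->reference homolog map and
    log2-transformed after adding ``offset`` (set ``log_scale=False`` for
    raw-scale correlation). Undefined (r_squared None) below 3 pairs.
    """
    pairs = [
        (q, r)
        for q, r in homolog_map.items()
        if q in query_profile.index and r in reference_profile.index
    ]
    if len(pairs) < 3:
        return ProfileComparison(label, None, len(pairs))
    x = np.array([query_profile[q] for q, _ in pairs], dtype=float)
    y = np.array([reference_profile[r] for _, r in pairs], dtype=float)
    if log_scale:
        x = np.log2(x + offset)
        y = np.log2(y + offset)
    if np.std(x) == 0 or np.std(y) == 0:
        return ProfileComparison(label, None, len(pairs))
    r = sps.pearsonr(x, y).statistic
    return ProfileComparison(label, float(r * r), len(pairs))
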