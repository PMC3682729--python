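"""Shared fixtures: synthetic bundles generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from enhevo.classify import ReadDensityTable, classify_enhancers
from enhevo.intervals import Enhancer, Gene, GenomicInterval, assign_enhancers_to_loci
from enhevo.simulate import SimConfig, load_bundle, write_fixture_bundle


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Small default-condition bundle with genome FASTA and signal track."""
    cfg = SimConfig(seed=7)
    root = tmp_path_factory.mktemp("bundle_small")
    return write_fixture_bundle(cfg, root)


@pytest.fixture(scope="session")
def bundle_data(bundle):
    return load_bundle(bundle.root)


@pytest.fixture(scope="session")
def classified(bundle_data):
    """Classification result over the small bundle."""
    return classify_enhancers(
        bundle_data["query_enhancers"],
        bundle_data["reference_enhancers"],
        bundle_data["chains_r2q"],
        bundle_data["chains_q2r"],
        ReadDensityTable(bundle_data["density"]),
        ecr_density=ReadDensityTable(bundle_data["ecr"]),
    )


@pytest.fixture(scope="session")
def locus_map(bundle_data):
    return assign_enhancers_to_loci(
        bundle_data["query_enhancers"],
        bundle_data["genes"],
        bundle_data["chrom_sizes"],
    )


def random_genes(rng: np.random.Generator, chrom: str, n: int, size: int) -> list[Gene]:
    """Non-overlapping random genes for small constructed fixtures."""
    starts = np.sort(rng.choice(size // 1000 - 10, size=n, replace=False)) * 1000
    genes = []
    for i, s in enumerate(starts):
        length = int(rng.integers(200, 900))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(chrom, int(s), int(s) + length, strand, f"g{i:03d}"))
    return genes


def make_enhancer(chrom: str, start: int, end: int, eid: str = "e") -> Enhancer:
    return Enhancer(GenomicInterval(chrom, start, end, eid), species="query")
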