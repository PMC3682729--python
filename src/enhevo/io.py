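"""Readers and writers for the plain-text formats the pipeline consumes.

BED is 0-based half-open; the BED score column carries ChIP read density for
enhancer sets. Expression tables are TSV with a ``gene_id`` column followed
by one column per sample. VCF is read through pysam.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .intervals import Enhancer, Gene, GenomicInterval

__all__ = [
    "read_bed",
    "write_bed",
    "read_enhancer_bed",
    "write_enhancer_bed",
    "read_genes",
    "write_genes",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_density_table",
    "write_density_table",
    "read_homolog_map",
    "write_homolog_map",
    "read_go_annotations",
    "write_go_annotations",
    "read_expression",
    "write_expression",
    "read_bedgraph",
    "write_bedgraph",
    "read_vcf_variants",
    "write_vcf",
    "write_json",
    "read_json",
]

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> list[GenomicInterval]:
    ivs = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else f"{Path(path).stem}_{i}"
            strand = f[5] if len(f) > 5 else "."
            ivs.append(GenomicInterval(f[0], int(f[1]), int(f[2]), name, strand))
    return ivs


def write_bed(intervals: list[GenomicInterval], path, scores=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            score = 0 if scores is None else scores[i]
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t{score:g}\t{iv.strand}\n")


def read_enhancer_bed(path, species: str = "") -> list[Enhancer]:
    enhancers = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[3], f[5] if len(f) > 5 else ".")
            density = float(f[4]) if len(f) > 4 else None
            enhancers.append(Enhancer(iv, species=species, read_density=density))
    return enhancers


def write_enhancer_bed(enhancers: list[Enhancer], path) -> None:
    with open(path, "w") as fh:
        for e in enhancers:
            iv = e.interval
            dens = e.read_density if e.read_density is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t{dens:g}\t{iv.strand}\n")


def read_genes(path) -> list[Gene]:
    df = pd.read_csv(path, sep="\t")
    genes = [
        Gene(r.chrom, int(r.start), int(r.end), r.strand, r.gene_id)
        for r in df.itertuples()
    ]
    for g, tss in zip(genes, df["tss"]):
        if g.tss != int(tss):
            raise ValueError(f"gene {g.gene_id}: tss column {tss} inconsistent with strand")
    return genes


def write_genes(genes: list[Gene], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tgene_id\ttss\n")
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{g.gene_id}\t{g.tss}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_density_table(path) -> pd.DataFrame:
    """TSV of (chrom, start, end, reads): ChIP reads per interval."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_density_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_homolog_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["query_gene_id"], df["reference_gene_id"]))


def write_homolog_map(mapping: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_gene_id\treference_gene_id\n")
        for q, r in mapping.items():
            fh.write(f"{q}\t{r}\n")


def read_go_annotations(path) -> dict[str, tuple[str, frozenset]]:
    """Flat GO map: term_id -> (term_name, annotated gene set)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, tuple[str, frozenset]] = {}
    for term_id, grp in df.groupby("term_id", sort=True):
        genes = frozenset(grp["gene_id"])
        if not genes:
            continue
        out[str(term_id)] = (str(grp["term_name"].iloc[0]), genes)
    return out


def write_go_annotations(terms: dict[str, tuple[str, frozenset]], path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tterm_name\tgene_id\n")
        for term_id in sorted(terms):
            name, genes = terms[term_id]
            for g in sorted(genes):
                fh.write(f"{term_id}\t{name}\t{g}\n")


def read_expression(path) -> pd.DataFrame:
    """Expression matrix indexed by gene_id, one column per sample."""
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.4f")


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "value"],
        comment="t",  # skips optional "track" header lines
        dtype={"chrom": str},
    )


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.4f")


def read_vcf_variants(path):
    """Yield (chrom, pos1, ref, alt, af, ancestral) from a VCF.

    Multi-allelic records are split into bi-allelic ones; the AF INFO field
    must be per-alt. Missing AA comes through as None.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            aa = rec.info.get("AA")
            if isinstance(aa, (tuple, list)):
                aa = aa[0]
            if aa is not None:
                aa = str(aa).upper()
                if aa in (".", "", "N", "-"):
                    aa = None
            afs = rec.info.get("AF")
            if afs is None:
                continue
            if not isinstance(afs, (tuple, list)):
                afs = (afs,)
            for alt, af in zip(rec.alts or (), afs):
                yield rec.chrom, rec.pos, rec.ref.upper(), str(alt).upper(), float(af), aa


def write_vcf(records, contigs: dict[str, int], path) -> None:
    """Write bi-allelic SNP records as VCF 4.2.

    ``records``: iterable of (chrom, pos1, ref, alt, af, ancestral-or-None).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">\n')
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        for chrom, size in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, af, aa in records:
            aa_str = aa if aa is not None else "."
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tAF={af:.6f};AA={aa_str}\n"
            )


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
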