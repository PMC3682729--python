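"""Configuration-driven orchestration of the full comparative analysis.

Stages run in dependency order: classify (cross-mapping + class I/II/III +
out-group presence) -> loci (locus construction, genomic features,
clustering simulation) -> expression (heart-specificity ranking, locus
enrichment, profile R^2) -> selection (DAF spectra, MK test) -> enrich
(cardiac GO, metaprofiles) -> compensate (singleton redundancy). A stage
subset can be selected; the report is a plain dict serialized to JSON plus
per-table TSVs, deterministic under a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .annotation import (
    SignalTrack,
    cardiac_fold_enrichment,
    cardiac_term_filter,
    go_enrichment,
    nearest_gene,
    signal_metaprofile,
)
from .classify import (
    ClassificationConfig,
    ReadDensityTable,
    classification_summary,
    classify_enhancers,
    orthologous_locus_compensation,
    outgroup_presence,
)
from .expression import (
    fraction_in_high_expression_loci,
    heart_specificity_score,
    high_expression_contrast,
    profile_r2,
    top_heart_genes,
)
from .intervals import (
    LOCUS_LENGTH_BINS,
    TSS_DISTANCE_BINS,
    GenomicInterval,
    assign_enhancers_to_loci,
    bin_counts,
    clustering_simulation,
    cpg_overlap_fraction,
    find_singletons,
    gc_content,
    nearest_tss_distance,
)
from .selection import (
    DAFSpectrumResult,
    VariantRecord,
    compare_spectra,
    daf_spectrum,
    mk_test,
    region_mk_counts,
)
from .simulate import load_bundle

logger = logging.getLogger("enhevo")

ALL_STAGES = ("classify", "loci", "expression", "selection", "enrich", "compensate")
CLASS_ORDER = ("shared", "class1", "class2", "class3")


@dataclass
class PipelineConfig:
    """Paths plus the analysis parameters, all defaulting to the study values."""

    bundle_dir: str = "."
    seed: int = 0
    min_match: float = 0.95
    overlap_rule: int = 1
    background_density: float | None = None
    draws_per_class: int = 500
    replicates: int = 1000
    expression_offset: float = 16.0
    top_n: int = 1000
    daf_cutoff: float = 0.05
    metaprofile_window: int = 5000
    metaprofile_bins: int = 50
    stages: tuple[str, ...] = ALL_STAGES

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _read_variants(path) -> list[VariantRecord]:
    return [
        VariantRecord(chrom, pos, ref, alt, af, aa)
        for chrom, pos, ref, alt, af, aa in io.read_vcf_variants(path)
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the selected stages over a fixture-bundle directory."""
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    data = load_bundle(config.bundle_dir)
    report: dict = {
        "provenance": {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "bundle_seed": data["manifest"].get("seed"),
        }
    }
    cls_cfg = ClassificationConfig(
        min_match=config.min_match,
        overlap_rule=config.overlap_rule,
        background_density=config.background_density,
    )
    query = data["query_enhancers"]
    reference = data["reference_enhancers"]
    genes = data["genes"]
    chrom_sizes = data["chrom_sizes"]

    # classification is a prerequisite of every later stage
    result = classify_enhancers(
        query,
        reference,
        data["chains_r2q"],
        data["chains_q2r"],
        ReadDensityTable(data["density"]),
        cls_cfg,
        ecr_density=ReadDensityTable(data["ecr"]),
    )
    by_class = result.by_class(query)
    ref_specific = [
        r for r in reference
        if result.reference_labels[r.id] == "reference_specific"
    ]
    if "classify" in config.stages:
        summary = classification_summary(result.labels)
        class3 = by_class.get("class3", [])
        flags, frac = outgroup_presence(
            class3, data["outgroup_chains"], config.min_match
        )
        summary["outgroup"] = {
            "n_class3": len(class3),
            "n_present": int(sum(flags.values())),
            "pct_present": round(100.0 * frac) if class3 else 0,
        }
        n_unmapped = sum(
            1 for m in result.mappings.values() if m.status != "mapped"
        )
        logger.info("classify: %d intervals unmapped", n_unmapped)
        report["classification"] = summary

    lmap = assign_enhancers_to_loci(query, genes, chrom_sizes)

    if "loci" in config.stages:
        genome = None
        if "genome_path" in data:
            import pyfaidx

            genome = pyfaidx.Fasta(str(data["genome_path"]))
        features: dict = {}
        lineage = [e for e in query if result.labels[e.id] != "shared"]
        for label, subset in (("shared", by_class.get("shared", [])), ("lineage_specific", lineage)):
            dists = [
                d for e in subset
                if (d := nearest_tss_distance(e, genes)) is not None
            ]
            lengths = [lmap.loci[lmap.locus_of[e.id]].length for e in subset]
            entry = {
                "n": len(subset),
                "tss_distance_bins": bin_counts(dists, TSS_DISTANCE_BINS),
                "median_tss_distance": float(np.median(dists)) if dists else None,
                "locus_length_bins": bin_counts(lengths, LOCUS_LENGTH_BINS),
                "median_locus_length": float(np.median(lengths)) if lengths else None,
                "cpg_overlap_fraction": cpg_overlap_fraction(subset, data["cpg_islands"]),
            }
            if genome is not None and subset:
                entry["mean_gc"] = float(
                    np.mean([gc_content(e.interval, genome) for e in subset])
                )
            features[label] = entry
        sims = clustering_simulation(
            by_class.get("shared", []),
            lineage,
            lmap,
            draws_per_class=config.draws_per_class,
            replicates=config.replicates,
            seed=np.random.default_rng(config.seed),
        )
        features["clustering"] = {
            focal: {
                "pct_clustered_with_shared": r.pct_clustered_with_shared,
                "pct_clustered_with_lineage": r.pct_clustered_with_lineage,
                "sd_with_shared": r.sd_with_shared,
                "sd_with_lineage": r.sd_with_lineage,
                "replicates": r.replicates,
                "draws_per_class": r.draws_per_class,
            }
            for focal, r in sims.items()
        }
        features["n_loci"] = len(lmap)
        features["n_singletons"] = len(find_singletons(lmap))
        report["loci"] = features

    scores = heart_specificity_score(
        data["expression_heart"], data["expression_nonheart"], config.expression_offset
    )
    top = top_heart_genes(scores, config.top_n)
    if "expression" in config.stages:
        fractions = {
            cls: fraction_in_high_expression_loci(by_class.get(cls, []), lmap, top)
            for cls in CLASS_ORDER
        }
        contrasts = {}
        for other in ("class2", "class3"):
            if by_class.get("shared") and by_class.get(other):
                contrasts[f"shared_vs_{other}"] = high_expression_contrast(
                    by_class["shared"], by_class[other], lmap, top
                )
        ref_scores = heart_specificity_score(
            data["expression_ref_heart"],
            data["expression_ref_nonheart"],
            config.expression_offset,
        )
        r2 = profile_r2(
            scores["heart_mean"],
            ref_scores["heart_mean"],
            data["homolog_map"],
            offset=config.expression_offset,
            label="reference_heart",
        )
        report["expression"] = {
            "top_n": config.top_n,
            "fraction_in_high_expression_loci": fractions,
            "contrasts": contrasts,
            "profile_r2": {
                "label": r2.label,
                "r_squared": r2.r_squared,
                "n_genes": r2.n_genes,
            },
        }

    if "selection" in config.stages:
        variants = _read_variants(data["variants_path"])
        pg = data["pseudogenes"]
        div = data["divergence"]
        div_map = dict(zip(div["region_id"], zip(div["d"], div["pi"])))
        spectra: dict[str, DAFSpectrumResult] = {}
        mk_rows = {}
        pg_spec = daf_spectrum(pg, variants, config.daf_cutoff, label="pseudogenes")
        pg_counts = region_mk_counts(pg, variants, div_map)
        for cls in CLASS_ORDER:
            subset = by_class.get(cls, [])
            if not subset:
                continue
            regions = [e.interval for e in subset]
            spec = daf_spectrum(regions, variants, config.daf_cutoff, label=cls)
            compare_spectra(spec, pg_spec)
            spectra[cls] = spec
            counts = region_mk_counts(regions, variants, div_map)
            mk = mk_test(counts.P, counts.D, pg_counts.P, pg_counts.D)
            mk_rows[cls] = mk
        mk_self = mk_test(pg_counts.P, pg_counts.D, pg_counts.P, pg_counts.D)
        report["selection"] = {
            "daf_table": {
                name: {
                    "low_freq_count": s.low_freq_count,
                    "total_count": s.total_count,
                    "fraction": s.fraction,
                    "pct_low_freq": round(100 * s.fraction, 1),
                    "p_value": s.p_value,
                    "skipped": s.skipped,
                }
                for name, s in {**spectra, "pseudogenes": pg_spec}.items()
            },
            "mk_table": {
                name: {
                    "P": m.Pe,
                    "D": m.De,
                    "neutrality_index": m.neutrality_index,
                    "neutrality_index_2dp": (
                        round(m.neutrality_index, 2)
                        if m.neutrality_index is not None
                        else None
                    ),
                    "p_value": m.p_value,
                    "regime": m.regime,
                }
                for name, m in {**mk_rows, "pseudogenes": mk_self}.items()
            },
        }

    if "enrich" in config.stages:
        annotations = data["go"]
        near: dict[str, set[str]] = {}
        for cls in CLASS_ORDER:
            near[cls] = {
                g.gene_id
                for e in by_class.get(cls, [])
                if (g := nearest_gene(e, genes)) is not None
            }
        background = set().union(*near.values()) if near else set()
        cardiac = cardiac_term_filter(annotations)
        enr = {}
        for cls in CLASS_ORDER:
            if not near.get(cls) or not background or near[cls] == background:
                continue
            cardiac_ann = {t: annotations[t] for t in cardiac}
            df = go_enrichment(near[cls], background, cardiac_ann)
            enr[cls] = {
                "n_terms_tested": int(len(df)),
                "n_significant": int(df["significant"].sum()) if len(df) else 0,
                "top_terms": df.head(5)[
                    ["term_id", "p_value", "p_bonferroni", "fold_enrichment"]
                ].to_dict("records")
                if len(df)
                else [],
            }
        rng = np.random.default_rng(config.seed + 1)
        all_gene_ids = [g.gene_id for g in genes]
        n_ctrl = min(len(all_gene_ids), max(100, config.top_n))
        control = set(
            rng.choice(all_gene_ids, size=n_ctrl, replace=False).tolist()
        )
        fold = cardiac_fold_enrichment(
            {c: s for c, s in near.items() if s}, control, annotations
        )
        entry = {
            "n_cardiac_terms": len(cardiac),
            "per_class": enr,
            "cardiac_fold_enrichment": fold.to_dict("records"),
        }
        if "signal" in data:
            track = SignalTrack(data["signal"], chrom_sizes)
            profiles = {}
            for cls, subset in by_class.items():
                if not subset:
                    continue
                mp = signal_metaprofile(
                    subset, track, config.metaprofile_window, config.metaprofile_bins
                )
                profiles[cls] = {
                    "bin_centers": mp.bin_centers.tolist(),
                    "mean_signal": mp.mean_signal.tolist(),
                }
            entry["metaprofiles"] = profiles
        report["enrichment"] = entry

    if "compensate" in config.stages:
        singles = find_singletons(lmap)
        singles_by_class: dict[str, list] = {}
        for e in singles:
            cls = result.labels[e.id]
            if cls in ("shared", "class2", "class3"):
                singles_by_class.setdefault(cls, []).append(e)
        comp = orthologous_locus_compensation(
            singles_by_class,
            data["chains_q2r"],
            genes,
            data["ref_genes"],
            data["homolog_map"],
            ref_specific,
            chrom_sizes,
            data["ref_chrom_sizes"],
            min_match=config.min_match,
        )
        report["compensation"] = {
            cls: {
                "n_singletons": r.n_singletons,
                "n_with_locus": r.n_with_locus,
                "n_compensated": r.n_compensated,
                "fraction": r.fraction,
                "pct": round(100 * r.fraction, 1),
                "mean_distance": r.mean_distance,
                "n_excluded": r.n_excluded,
            }
            for cls, r in comp.items()
        }
    return report


def format_pct(x: float) -> str:
    """Percentages rendered to 1 decimal place for report tables."""
    return f"{x:.1f}%"


def format_ni(x: float) -> str:
    """Neutrality index rendered to 2 decimal places."""
    return f"{x:.2f}"


def write_report(report: dict, outdir, formats: tuple[str, ...] = ("json", "tsv")) -> list[Path]:
    """Serialize the report: JSON always, one TSV per tabular section."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "json" in formats or True:  # JSON is mandatory
        path = out / "report.json"
        io.write_json(report, path)
        written.append(path)
    if "tsv" not in formats:
        return written
    if "selection" in report:
        daf = report["selection"]["daf_table"]
        rows = [
            {
                "class": name,
                "low_freq": r["low_freq_count"],
                "total": r["total_count"],
                "pct_low_freq": format_pct(100 * r["fraction"]),
                "p_value": r["p_value"],
            }
            for name, r in daf.items()
        ]
        p = out / "daf_table.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        written.append(p)
        mk = report["selection"]["mk_table"]
        rows = [
            {
                "class": name,
                "P": r["P"],
                "D": r["D"],
                "neutrality_index": (
                    format_ni(r["neutrality_index"])
                    if r["neutrality_index"] is not None
                    else "NA"
                ),
                "p_value": r["p_value"],
            }
            for name, r in mk.items()
        ]
        p = out / "mk_table.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        written.append(p)
    if "classification" in report:
        rows = [
            {"class": k, "count": v}
            for k, v in report["classification"]["counts"].items()
        ]
        p = out / "classification.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        written.append(p)
    if "compensation" in report:
        rows = [
            {"class": cls, **{k: v for k, v in r.items() if k != "pct"},
             "pct": format_pct(100 * r["fraction"])}
            for cls, r in report["compensation"].items()
        ]
        p = out / "compensation.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        written.append(p)
    empty = [k for k in ("classification", "loci", "expression", "selection") if k not in report]
    if empty:
        logger.info("report sections omitted (stage not run): %s", ", ".join(empty))
    return written
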