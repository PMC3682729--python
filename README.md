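# enhevo

Comparative analysis of functionally conserved versus lineage-specific
tissue enhancers between two species.

Most regulatory DNA is not conserved across mammals: when P300-bound heart
enhancers of human and mouse are compared, only about a fifth of them have a
functional orthologue in the other species. `enhevo` implements the full
analysis pipeline behind that kind of study for any pair of "query" and
"reference" species:

* **Cross-mapping** — reference enhancers are lifted into query coordinates
  through UCSC chain files (an internal single-best-chain liftOver with a
  configurable minimum aligned fraction, default 0.95). Query enhancers
  overlapping a lifted reference enhancer are *shared*; the rest are
  *lineage-specific*.
* **Class I/II/III partition** — lineage-specific enhancers are split by the
  fate of their orthologous sequence: class I (orthologue present, ChIP
  read density above the evolutionarily-conserved-region background —
  equivocal calls), class II (orthologue present, no signal), class III (no
  orthologous sequence at all). Class III regions are tested for presence
  in out-group genomes to distinguish deletion in the reference lineage
  from insertion in the query lineage.
* **Regulatory loci** — each enhancer's locus spans its two flanking genes
  (intergenic case) or its host gene plus both flanking intergenic
  intervals (intronic case). Locus clustering between enhancer classes is
  quantified by a resampling simulation (500 draws per class, 1000
  replicates by default).
* **Expression impact** — genes are ranked by heart specificity,
  `log2(mean_heart + 16) − log2(mean_nonheart + 16)`; the top 1000 define
  highly expressed heart genes, and enhancer classes are compared by the
  fraction of members whose locus contains one (Fisher's exact test).
  Cross-species expression-profile similarity is reported as squared
  Pearson correlation over homolog pairs.
* **Selection pressure** — variants are polarized by ancestral allele to
  derived allele frequencies (DAF); the fraction of low-frequency variants
  (DAF ≤ 5%) per class is contrasted against a pseudogene neutral
  reference, and a McDonald–Kreitman test computes the neutrality index
  NI = (Pe/De)/(Pn/Dn) with D = d − π (interspecies differences minus
  heterozygous sites). NI > 1 indicates negative selection.
* **Functional annotation** — cardiac GO terms (names containing "heart",
  "cardiac" or "cardio") are tested for enrichment among each class's
  nearest genes with Bonferroni correction; histone-signal metaprofiles are
  aggregated around enhancer midpoints.
* **Singleton compensation** — for query enhancers that are alone in their
  locus, the orthologous reference locus is checked for reference-specific
  enhancers that could compensate the loss of activity.

A first-class synthetic-data module (`enhevo.simulate`) generates complete,
seeded fixture bundles — annotation, enhancer BEDs, chain files with planted
deletions, VCF with neutral vs selection-shifted DAF spectra, expression
tables with planted heart-high genes, GO maps, CpG islands, pseudogenes and
signal tracks — with a JSON ground truth, so every stage is testable without
downloading anything.

## Worked example

```sh
enhevo simulate --seed 7 --outdir bundle/
enhevo run --bundle bundle/ --seed 7 --outdir report/
```

This generates a 3-chromosome synthetic genome (600 query enhancers, 21%
planted shared) and runs all stages. From `report/report.json`:

```
classification counts:  class1 371  class2 50  class3 53  shared 126
lineage-specific:       79%
out-group presence:     53/53 class-III regions (100%)
```

i.e. the classifier recovered exactly the planted 126/371/50/53 composition.
The selection tables (also written as `daf_table.tsv`, `mk_table.tsv`):

```
class        P      D     neutrality_index   p_value
shared       1538   1265  1.51               5.2e-19
class2       612    458   1.66               3.2e-14
class3       587    532   1.37               1.3e-06
pseudogenes  2445   3046  1.00               1.0

class        low_freq/total   pct_low_freq
shared       862/1475         58.4%
class3       319/561          56.9%
pseudogenes  1024/2330        43.9%
```

All enhancer classes show the planted excess of low-frequency derived
variants over the pseudogene reference and neutrality indices above 1 —
the signature of negative selection the pipeline is designed to detect.
Genomic features behave accordingly: planted shared enhancers have mean GC
0.60 vs 0.40 for lineage-specific ones, and homolog-matched heart
expression profiles give R² = 0.97.

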