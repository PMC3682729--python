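# Methods

This note documents the models, parameters and design choices behind
`enhevo`, and what the synthetic fixtures do and do not establish about
real data.

## Coordinate model and loci

All intervals are 0-based, half-open (BED convention). A gene has a single
TSS at its strand-appropriate end (start on `+`, end−1 on `−`); no
exon/intron substructure is modelled, so "intronic" means overlapping a
gene body at all. Distances to the TSS are measured from the enhancer
midpoint — the reporting bins are <10 kb / 10–50 kb / >50 kb
for TSS distance and <200 kb / 200–500 kb / >500 kb for locus length, with
lower-inclusive half-open bins.

The regulatory locus of an intergenic enhancer spans from the start of the
upstream flanking gene to the end of the downstream flanking gene; for an
intronic enhancer it spans from the end of the previous gene to the start
of the next gene (host gene plus both flanking intergenic intervals).
Boundaries are clipped to the chromosome; an enhancer on a gene-free
chromosome receives the whole chromosome as a flagged degenerate locus.
Two enhancers are co-locus iff their loci are defined by the same
flanking-gene pair or host gene — identical-boundary equality, not interval
overlap, which keeps locus membership an equivalence relation.

## Clustering simulation

Per replicate, `draws_per_class` (default 500) enhancers are sampled
without replacement from each class; a focal enhancer is "clustered with
class X" when its locus holds at least `min_cluster_size` (default 2)
members counting itself and the sampled class-X enhancers. Reported values
are mean percentages over replicates (default 1000) with their standard
deviation. The ≥2 reading of "clustered" (focal plus at least one other)
is a deliberate choice; the threshold is an argument, so a ≥3 reading is
one keyword away. When a class is smaller than `draws_per_class`, draws are
reduced to the class size with a warning — note that comparisons between
"with shared" and "with lineage-specific" percentages are only fair when
both classes are sampled at the same depth.

## Lift-over

Chains follow the UCSC format; block arithmetic is validated on parse
(sizes ≥ 1, block sums equal to header spans, no trailing gaps). Mapping
uses single-best-chain semantics: the highest-scoring chain overlapping the
interval is selected, the aligned fraction of interval bases must reach
`min_match` (default 0.95, matching the external liftOver tool's
documented default), and the lifted interval spans first to last mapped
base in target coordinates, normalized to the plus strand. An interval
touched by several chains none of which reaches `min_match` is reported as
`split`. Raising `min_match` can only unmap intervals, never the reverse.

## Classification

Shared calls need ≥ `overlap_rule` bases of overlap (default 1 bp, since
the criterion is functional co-occurrence, not sequence identity) between a
query enhancer and a lifted reference enhancer. Reference enhancers whose
lifted position hits no query enhancer are reference-specific — functional
non-conservation regardless of sequence conservation.

Read density is reads overlapping an interval divided by its length; rows
of the density table contribute proportionally to their overlapped
fraction. The class-I/II background is either given explicitly or computed
as total reads over total bases of the supplied ECR intervals. A mapped
orthologue with no density row is treated as density 0 with a warning
(class II), since absence from a read table is evidence of no signal.

For singleton-compensation analysis, class-III enhancers cannot be lifted;
their reference locus is projected through the homologous flanking genes
(span from the leftmost homolog start to the rightmost homolog end), and
the locus midpoint serves as the reference point for distances to the
nearest compensating enhancer. Singletons whose locus cannot be projected
(missing homologs, homologs on different chromosomes) are excluded from
the denominator and counted.

## Expression

Heart specificity is `log2(mean_heart + offset) − log2(mean_nonheart +
offset)` with offset 16; means are arithmetic across samples before the
offset. Log base 2 is a display choice — any base rescales all scores by a
constant and leaves the ranking unchanged. Ties at the top-N boundary break
lexicographically by gene identifier, making the top set deterministic.
Profile similarity is squared Pearson correlation over homolog-matched,
log-transformed values (raw scale available via `log_scale=False`);
undefined below 3 pairs or for constant profiles.

## Selection

Polarization: DAF = AF when the ancestral allele equals the reference
allele, 1 − AF when it equals the alternate; variants with missing or
third-allele ancestral states are skipped and counted rather than folded —
folding would artificially inflate the low-frequency class the analysis
keys on. Multi-allelic VCF records are split into bi-allelic ones on read.
The low-frequency cutoff is DAF ≤ 0.05.

The MK test consumes polymorphic-site counts (P; polarizability not
required) and a per-region divergence table of interspecies differences d
and heterozygous sites π, with fixed differences D = d − π floored at 0
(with a warning) since noisy inputs can drive it negative. The neutrality
index (Pe/De)/(Pn/Dn) is reported at full precision and rendered to two
decimals in tables; low-frequency percentages render to one decimal.

`fisher_exact_2x2` computes the two-sided p by summing hypergeometric
point probabilities not exceeding the observed one (relative tie slack
1e−9), in log space over the full support, which keeps it stable and fast
for count tables up to ~10⁶ per cell. Test sidedness is fixed at
two-sided throughout.

## GO enrichment

Annotations are a flat term → gene-set map (no DAG propagation). Cardiac
terms match "heart", "cardiac" or "cardio" as case-insensitive substrings —
"pericardium" deliberately does not match. Enrichment of a test set T
against a background B is the hypergeometric model of drawing |T| genes
from B (the Fisher table contrasts T with B − T); reported counts are
against the full background for readability, and fold enrichment is
(a/|T|)/(c/|B|). Bonferroni multiplies by the number of terms actually
tested — terms with at least one annotated gene in B — not the global
term count. The enrichment unit is the gene: nearest genes (midpoint-to-TSS
distance, ties by gene id) are deduplicated within each test set.

## Signal metaprofiles

Profiles average the track per bin over `[midpoint − window, midpoint +
window)` (defaults 5 kb, 50 bins) per enhancer, then over enhancers, so a
union of region sets yields the count-weighted mean of the member
profiles. Positions absent from the track read as 0.

## Synthetic data

The generator emulates the study design rather than genome realism:

* Genome: 3 chromosomes × 2 Mb by default; genes of 2–10 kb placed without
  overlap with Dirichlet-distributed gaps.
* Enhancers: 600 query / 660 reference, length 600 bp, 21% planted shared;
  the lineage-specific remainder splits 78.3/10.5/11.2% into classes
  I/II/III, mirroring the composition of the real enhancer sets. A
  `clustering_bias` of 0.3 sends an enhancer into a locus already occupied
  by its conservation group. Class III enhancers are placed intergenic
  only, because their planted deletions (±400 bp margins) must not remove
  gene sequence.
* Chains: identity minus planted deletions, written in both directions;
  one chromosome's chain is split in two inside a gene body and a
  low-score off-diagonal decoy chain exercises chain-selection order.
  Out-group chains omit a 2% fraction of class III regions (sequences
  absent from every out-group).
* Variants: SNP rate 0.02/bp; neutral DAF ~ Beta(0.3, 1.2), constrained
  DAF ~ Beta(0.22, 1.6) (low-frequency mass 0.44 vs 0.59 at the 5%
  cutoff); 5% of records carry a missing ancestral allele. Divergence is
  Poisson at 0.03/bp with heterozygous sites at 0.004/bp; constrained
  regions have divergence scaled by 0.675, which sets the expected
  neutrality index near 1.6 — the magnitude the analysis should recover.
* Expression: log-normal base expression, 5 heart / 10 non-heart samples,
  planted heart genes (preferentially the nearest genes of shared
  enhancers) boosted 8-fold in heart samples; reference homologs reuse the
  base profile with mild noise.
* GO: 200 flat terms, 15% cardiac-named, cardiac terms annotating
  near-shared genes with 10× weight. CpG islands overlap shared enhancers
  with probability 0.6; FASTA sequence is GC 0.60 inside shared enhancers
  vs 0.40 elsewhere.
* Compensation: reference-specific enhancers are planted into singleton
  query loci at rates 0.60/0.15/0.26 for shared/class II/class III; the
  ground truth records the compensation state actually constructed, not
  the intended draw, so recovery tests are exact.

All randomness flows from a single seeded numpy generator; identical
configs produce byte-identical bundles.

What passing tests show — and do not show. The fixtures have exact
coordinate arithmetic (identity-minus-deletions chains), independent
variants (no linkage disequilibrium), flat GO structure and well-separated
density classes. Recovery of planted structure therefore validates the
*implementation* of each statistic, not its power on real data, where
alignment ambiguity, LD, annotation bias and overlapping signals all blur
the contrasts. The published genome-scale counts themselves depend on raw
data (ChIP-Seq sets, variant panels, microarrays) that this package does
not download; its summary builders reproduce the published percentages and
neutrality indices exactly when fed the published count tables, which is
how `scripts/acceptance.py` checks them.

Problem sizes used by the acceptance script: 5000-enhancer bundles on a
40 Mb genome for classifier recovery and top-gene ranking, 10⁴ random
intervals for the lift-over oracle, ~2×10⁵ simulated variant sites per MK
contrast, and 100 replicate null runs for the family-wise error of the GO
enrichment — sizes chosen so every stochastic check sits far inside its
tolerance while the whole script stays around half a minute.

## Known limitations

* Single best chain only: no chain stitching, net/axt support or
  paralogy resolution.
* One nearest gene per enhancer (configurable designs could use both
  flanking genes); no promoter/UTR classes.
* Divergence counts (d, π) are consumed precomputed; the package does not
  call differences from alignments.
* The GO model has no term hierarchy; annotations are taken as given.
* `D = d − π` flooring biases D upward for very noisy regions; such
  regions also trigger a warning.
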