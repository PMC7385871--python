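# Methods

This note documents the models behind `augref`, the defaults and why
they were chosen, what the synthetic data does and does not emulate,
and the numerical conventions a user relying on the outputs should
know.

## Synthetic genomes

`generate_reference` draws i.i.d. bases at a configurable GC content
(default 0.42, a mammalian autosome value). A uniformly random sequence
is almost perfectly mappable — every 21-mer is unique — so on such a
genome the reference structure would be irrelevant. Real genomes are
not like that: mapping errors concentrate in repeat families whose
copies are similar but not identical. The optional `RepeatSpec`
therefore implants dispersed repeat families (default for a 200-kb
genome: 6 families × 10 copies × 600 bp ≈ 18% repeat content, copies
mutated at 1% divergence) and records them as `repeat` BED features.
With these defaults the baseline linear mapping-error rate of the
pipeline lands at a few reads per thousand, the same order as
chromosome-scale short-read studies, and the error mass sits in
repeats — which is the regime in which reference structure matters.
The defaults were fixed from this reasoning before the evaluation
experiments were frozen.

What the repeat model does *not* emulate: nested/hierarchical repeat
structure, tandem arrays, satellite DNA, segmental duplications longer
than the fragment length, and GC-biased mutation.

## Population model

`simulate_population` places non-overlapping biallelic variants
(SNPs and anchored indels < 50 bp; default 10% indels, lengths drawn
from a geometric body with mean ≈ 2 bp plus a uniform tail so long-indel
length bins are populated) and assigns each variant a site-frequency
class: singleton, (0, 0.05], (0.05, 0.1], (0.1, 0.25], (0.25, 0.5],
(0.5, 1). Default class weights give 14% singletons (a cattle-like
spectrum; a human-like spectrum uses ≈ 23%). Singletons get exactly one
carrier haplotype; other variants draw a per-population carrier count
from Binomial(2N, f) with f uniform in the class, carriers chosen
without replacement, and degenerate draws (0 or 1 copies panel-wide)
promoted to two copies so every variant is polymorphic and the realized
singleton fraction tracks the singleton weight.

Populations are frequency-differentiated: `shared_fraction` (default
0.7) of non-singleton variants segregate in every population, the rest
are private to one. A shared variant keeps its frequency class in all
populations with probability `class_correlation` (default 0.5) and
draws an independent class per population otherwise. The default makes
a variant that is common in one population frequently rare or absent in
another, which is what separates targeted, pan-genome and across-
population graphs; fully correlated classes would make all three nearly
identical at desk scale.

Not emulated: linkage disequilibrium and haplotype blocks (carriers are
drawn independently per site), mutation/recombination processes,
selection, and relatedness structure within populations. Consequences:
haplotype walks are less "blocky" than real phased data, so
haplotype-restricted graph indexes are slightly *less* constraining
here than a GBWT on real data, and measures that depend on LD decay are
out of reach.

## Graphs

`build_graph` splits the reference backbone at allele boundaries into
nodes of at most `max_node_len` (default 32 bp, the chunk size implied
by node counts of chromosome-scale graph tools; the division remainder
merges into the final chunk of each segment). SNPs become parallel
single-base nodes, insertions extra nodes between backbone nodes,
deletions bypass edges; the graph is a DAG, and the backbone path
spells the reference exactly. Haplotype walks substitute bubble paths
for carried alleles; variants absent from the graph are traversed via
the reference allele. k-mer path counts (`graph_stats`) enumerate
distinct k-length sequence paths — all paths, or only windows of the
embedded walks when a haplotype index is supplied — with a cap for
large graphs.

Variant selection implements strict-inequality AF thresholds
(AF > t in a population), count matching across populations (each
population's passing set subsampled to the minimum count so graph
density is comparable), pooled-frequency (pan) selection, uniform
random pools, personalized sets, and the empty graph. Alleles observed
only in the excluded (read-simulation) samples are dropped from every
non-personalized mode.

## Read simulation

Defaults follow common short-read simulator settings: 2 × 150 bp pairs,
fragment length Normal(500, 50) truncated at the read length, fragments
uniform per haplotype with equal counts per haplotype, substitution
errors at 0.01/base (uniform among the three alternatives) and indel
errors at 0.002/base (1-bp, insertion/deletion equiprobable, the read
re-trimmed or refilled to 150 bp from the true downstream sequence).
Truth coordinates are the error-free fragment ends lifted from
haplotype to reference coordinates through the haplotype's coordinate
chain; positions inside haplotype-only insertions resolve to the
nearest mapped base. Injected error events are also recorded per read,
which is how the realized indel-error rate is measured without
alignment.

## Mapping

The mapper is a deterministic seed-and-extend aligner designed to
reproduce the *behaviours* that the evaluation statistics measure, not
any particular production tool:

* exact-k-mer seeding (k = 21, every reference position indexed; for
  graphs, each bubble additionally contributes its alternate-allele
  context k-mers), diagonal clustering, up to 8 candidate loci;
* extension with edlib's edit-distance-optimal path, re-scored with
  affine constants match +1, mismatch −4, gap open −6, gap extend −1.
  At the simulated error rates the unit-cost optimal path is in
  practice the affine-optimal one, and the C implementation keeps
  20k-pair cells in seconds;
* free end-clipping: the maximal-scoring contiguous sub-path (Kadane
  over the alignment path) replaces the full-length alignment when it
  scores higher. This is the mechanism that soft-clips reads spanning
  long insertions against a linear reference — the cause of reference
  allele bias downstream;
* graph-aware extension: a candidate window is evaluated under local
  allele combinations — those observed among the embedded haplotype
  walks, plus all-reference and all-alternate — and the best combination
  wins; its alignment start is surjected to linear coordinates
  (alignments starting inside alternate nodes take the preceding
  backbone base);
* MQ = min(60, 6 × (best − second best)) with MQ 0 on ties; paired ends
  are scored jointly with a fragment-length bonus decaying linearly to
  zero at six standard deviations; ties break toward the lowest
  reference position, so mapping is fully deterministic;
* reads with no seed hit or best score below 40 are unmapped.

Known limitations: no base-quality awareness, no rescue alignment of an
unseeded mate, and the clipping search is restricted to the
edit-distance-optimal path rather than all affine paths, so in rare
near-tie cases the reported clip differs from a full affine DP.

## Genotyping

`pileup_and_call` is a deliberately transparent single-sample caller.
A mapped read (MQ ≥ 10) contributes depth at a site when its aligned
span covers the allele's reference interval with one base of margin; it
supports the reference or alternate allele when its sequence contains
that allele embedded in 10 bp of flanking context, with contexts
enumerated over allele combinations of neighbouring candidate sites so
nearby variants cannot mask support. Genotypes are maximum-likelihood
under a binomial read model (alternate-allele probability 0.01 / 0.5 /
0.99 for the three diploid genotypes), QUAL is the phred-scaled
genotype posterior and QD = QUAL/DP. Because a clipped read's aligned
span ends at the clip, reads soft-clipped at an insertion simply drop
out of that site's pileup — no local realignment or soft-clip rescue is
attempted — which is exactly how reference allele bias at indels arises
from linear alignments and why graph alignments avoid it.

Site filters default to QD > 10, MQ > 40, DP > 25. Note the QUAL model
here is a simple binomial posterior, so QD is on a different numerical
scale than the annotations of production callers; the filter thresholds
preserve their semantics (deep, confidently mapped sites) rather than
their exact operating points, and the concordance and bias analyses do
not depend on the QD filter.

## Evaluation

A read is counted correctly mapped when its reported start is within
k = 150 bp (one read length, allowing for clipping at indels) of its
truth start; unmapped reads are incorrect. The headline error rate
counts unmapped reads in the numerator and all reads in the
denominator; the pseudo-ROC, per its definition, is computed over
mapped reads only, with MQ buckets [i, next threshold) for
i ∈ {60, 50, 40, 30, 20, 10, 0} and MQ 60 its own bucket, cumulated
from 60 downward. "Perfect" means mapped full-length with edit distance
0 and no clipping; "unique" means a single primary alignment or MQ 60
despite secondaries. Allelic-ratio profiles average AD_alt/(AD_ref+AD_alt)
at truly heterozygous sites per signed variant length (negative =
deletion, 0 = SNP, positive = insertion), split by graph membership,
reporting mean ± s.e.m. Concordance metrics come from the 3×3
truth-by-call matrix: concordance = trace/total; non-reference
sensitivity = genotype-matching variant calls / truth variants;
precision = genotype-matching non-reference calls / all non-reference
calls; non-reference discrepancy = discordant cells / (total −
concordant homozygous-reference cell).

A note on expectation at long insertions even with perfect mapping: a
read must span the entire inserted sequence plus flanking context to
register alternate support, but only the anchor base to register
reference support, so the geometric expectation of the allelic ratio
falls below 0.5 as insertion length grows. Graph alignment removes the
clipping-driven part of the bias, not this geometric part — matching
what pileup-based callers report on real graph alignments.

## Experiment orchestration and problem sizes

`run_experiment` generates the genome and panel once per configuration,
then per replicate re-draws read simulation and any random subsampling
(replicate seed = base seed + replicate index) and maps the *same*
reads to every configured reference structure, so mode comparisons are
paired. The simulated individual's private alleles are excluded from
all non-personalized graphs. The random-graph mode draws from a catalog
of panel variants plus three times as many novel synthetic variants,
emulating an external variant collection in which most entries do not
segregate in the study populations and none carry phase.

Desk-scale experiment sizes are chosen so the full design runs on one
CPU in minutes: 100–200-kb genomes, panels of 1 variant per 80–100 bp
(the density of a densely genotyped livestock chromosome), two
populations of 20 diploids, 2.5k–20k read pairs per replicate, ten
replicates. At a panel of 2 × 40 haplotypes an AF threshold of 0.03
barely filters (any two copies pass), so the reference-structure
comparison uses AF > 0.2 as its "common variant" threshold — the
desk-scale analog of 0.03 on a 100+-sample panel; the threshold-sweep
experiment exposes the full grid (steps of 0.01 below 0.1, 0.1 above).

## Degenerate inputs and tie-breaks

Variants at AF exactly 0.5 are not replaced in consensus building
("major" means strictly > 0.5). Selection thresholds are strict
inequalities. Mapping ties yield MQ 0 and resolve to the lowest
reference position. Pileup sites with zero informative reads are
skipped in bias profiles. Chains with no length-changing alleles map
identically in both directions. Empty inputs raise errors rather than
returning empty statistics wherever a denominator would vanish.
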