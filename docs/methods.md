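# Methods

`dartmap` characterizes a DArT (Diversity Arrays Technology) genotyping
array against a reference genome. DArT markers are dominant
presence/absence calls produced by hybridizing complexity-reduced
genomic representations to an array of cloned probes (~300-500 bp).
The package covers the full analysis chain: marker quality control and
segregation testing, two-point linkage mapping in an outbred full-sib
(CP) family, probe-sequence redundancy clustering, post-processing of
probe-to-genome alignments, integration of the genetic and physical
maps, and gene-space coverage statistics. A synthetic-data module
generates genomes, probe sets and mapping populations with known truth
so every stage is testable end to end.

## Synthetic data model

**Genome.** Chromosome-scale sequences (default eleven, uniform base
composition at a configurable GC fraction) plus a tail of small
unanchored scaffolds. Gene models are non-overlapping intervals placed
per chromosome with Poisson counts at a configurable density (genes per
Mbp). All internal coordinates are 0-based half-open; GFF3 output is
1-based inclusive.

**Probes.** `plant_probes` extracts fragments (default 300-500 bp, the
typical DArT insert size) at non-overlapping source coordinates — a
deliberate constraint: distinct "unique" loci must not overlap, or the
planted truth clustering would disagree with genuine sequence
redundancy. A configurable fraction of probes are mutated copies of
earlier probes (per-base substitution rate), in random orientation;
truth clusters and source coordinates are recorded. Optionally each
probe can be planted fully inside a gene model with probability
`p_genic` (and strictly outside otherwise), which calibrates the
gene-space statistics, and a CTGCAG (PstI) site can be stamped at
fragment boundaries to mirror a PstI representation.

**Cross.** A two-parent outbred F1 family (default 177 progeny, the
reference pedigree size). Marker positions are uniform per chromosome;
truth cM positions derive from a planted kbp/cM ratio (default 500,
inside the 357-736 range reported for *Eucalyptus* pseudochromosomes).
Meioses follow a no-interference (Poisson) crossover process, sampled
exactly at the marker loci as a two-state Markov chain whose switch
probability between adjacent loci is the Haldane recombination fraction
of their distance. Marker types: dominant 1:1 pseudo-testcross markers
(heterozygous in one parent), dominant 3:1 intercross markers
(heterozygous in both), and fully informative codominant markers coded
`ac/ad/bc/bd` with parents `ab` x `cd`. Phases are random per marker
and parent. Missing data and score flips are injected at configurable
rates at the observation level (a dominant call flips as a whole; a
codominant genotype flips each transmitted-allele call independently).
All noise is drawn unconditionally so that a given seed yields identical
meioses across noise settings; the noise-free transmissions are
returned for calibration tests.

What the generator does **not** emulate: realistic sequence composition
(repeats, methylation-sensitive representation), microarray
fluorescence, crossover interference, segregation distortion, or
genotyping errors correlated across markers. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to these additional features of real data.

## Marker QC and segregation

Markers pass QC when three inclusive thresholds hold simultaneously:
reproducibility >= 0.95, cluster-separation quality Q >= 65 (percent of
signal variance between clusters) and call rate >= 0.75. Segregation
classes are determined from the parental scores, never by best fit
among ratios (which would bias the test): one dominant parent -> 1:1,
two -> 3:1, codominant `ab` x `cd` -> 1:1:1:1, `ab` x `ab` -> 1:2:1.
Adherence is a Pearson chi-square without continuity correction on the
non-missing progeny calls, df = classes - 1, rejecting when p < 0.01.
Null x null parents with segregating progeny raise an inconsistency
error; undeterminable parental data are excluded with a distinct code.

## Two-point linkage analysis

For a marker pair, joint progeny class probabilities are assembled from
the per-parent transmission model: each parent heterozygous for both
markers transmits the two marked alleles together with probability
(1-r) under coupling (r under repulsion); every other transmission is
an independent fair coin. Observation maps project transmissions onto
scored classes (dominant presence is an OR over parents). A known
per-score error rate (`MappingParams.assay_error_rate`, default 0) is
folded in as a symmetric misclassification channel per marker — without
it, dense-map distances are inflated by roughly twice the error rate
per interval, because raw discordance overestimates recombination.
The likelihood is maximized over r in [0, 0.5) per admissible phase
combination (golden-section search, tolerance 1e-6, in the scalar API;
a vectorized r grid at ~1e-3 resolution for all-pairs tables), ties
broken toward coupling; LOD = log10 L(r_hat)/L(0.5). Pairs with no
commonly heterozygous parent (e.g. dominant testcross markers from
different parents) are structurally uninformative and return LOD 0.

Grouping is single-linkage transitive closure over pairs with
LOD > 15 and r_hat <= 0.4 (the conventional CP settings). Note that at
LOD > 15 with ~177 progeny, 3:1 markers whose phases are repulsion with
all nearby informative markers can legitimately fail to join any group;
the expected per-pair LOD of a repulsion-phase 3:1 x 3:1 pair at r = 0
is only ~6 at this sample size.

## Ordering and map distances

A sum-of-adjacent-r seriation is degenerate at high marker density:
weakly informative pairs yield spurious r_hat = 0 estimates, and chains
of such pairs give wrong orders a *lower* criterion value than the true
order. Ordering therefore maximizes the **two-point composite
log-likelihood** of the configuration: each informative pair
contributes its profile (over phase) log-likelihood evaluated at the
recombination fraction implied by the two markers' map positions.
Numerical choices:

* The internal additive scale is **Haldane**, consistent with the
  no-interference gamete model (under which Haldane distances are the
  additive ones). Reported positions are cumulative **Kosambi**
  distances over the adjacent fitted recombination fractions — the
  conventional mapping function for this assay; at dense spacing the
  two scales coincide to well under 1%.
* Pair likelihoods are censored beyond r = 0.4: distant pairs
  distinguish "far" from "close" but their noisy distance estimates
  explode on the map scale near r = 0.5, and their accumulated pull
  otherwise stretches the configuration.
* Optimization: three complementary seriation initializations
  (principal classical-MDS axis; horseshoe unroll of the first two MDS
  coordinates; Fiedler vector of a local affinity graph), each refined
  by coordinate ascent (every marker relocated to its conditional
  optimum — a generalized ripple that includes window-1 swaps),
  block-reversal moves (which repair large-scale folds) and a global
  scale line search (which fixes the collective expansion/compression
  mode that single-marker moves cannot). The refinement with the best
  composite likelihood wins.

**Framework vs full maps.** The full map places every grouped marker.
The framework map defers poorly supported placements after the full
fit: (a) markers whose flanked-pair goodness-of-fit chi-square exceeds
the jump threshold (default 5) — the observed recombinant count of the
flanking pair against the count expected from the Kosambi-additive
distance through the marker; and (b) markers whose local order is
unresolved — swapping the marker with its neighbor costs less than
LOD 1 in the composite likelihood. The order-support sweep is
self-limiting (spacing grows as markers drop); the misfit screen is
applied once, on the original adjacencies, because the statistic is
meaningless for the widening triples that removals create. Retained
markers keep their fitted positions: deferral judges placements, it
does not re-estimate the configuration.

**Accuracy, calibrated on synthetic data.** At the reference settings
(11 chromosomes, 177 progeny, 100 markers/chromosome, 10% missing, 1%
score errors, assay error rate declared to the estimator) the full map
recovers within-group order at |Spearman| >= 0.99 and tracks the
*realized* map length of each chromosome to within a few percent. The
realized map itself fluctuates around its expectation with a sd of
5-7% per chromosome at this progeny number — an irreducible
meiosis-sampling effect that dominates the error of any per-chromosome
kbp/cM estimate.

## Probe redundancy

Candidate pairs share an exact word (k-mer index at the preset's index
word length, both orientations); verification aligns the shorter probe
as an infix of the longer (edit-distance alignment) and accepts a merge
when overlap >= 50 bp, overlap identity >= 98%, and the preset's
mismatch/gap-count/gap-size allowances hold (ambiguity codes count as
matches up to the allowance, then as mismatches). Clusters are the
transitive closure of merges; consensus sequences are not built because
only membership feeds the accounting. The four stringency presets
(A1-A4) are strictly nested, so relaxing the preset can only coarsen
the clustering and never increases the unique-locus count. The
accounting identities are: singletons + redundant members = total;
unique loci = singletons + clusters; redundancy rate =
100 x (total - unique)/total, truncated to 2 decimals (the convention
of the reference tabulation). Scaling unique loci to a full array of
size N uses floor(N x unique/total). Staggered dovetail overlaps are
not modelled (planted duplicates are full-length copies).

## Physical placement

The retention band T is ceil(2 x median(5.5 ln L)) over the probe
lengths L — natural log, which reproduces the reference fixed threshold
T = 70 at the median probe length of 534 bp (log10 would give ~30).
Per probe, the best-scoring hit plus any hit within T of it are
retained; more than two retained hits is an unsuccessful (ambiguous)
mapping, and the mapping error rate is their fraction among all
evaluated (non-unmapped) probes. Two retained hits classify by the gap
between nearest interval ends: overlap -> one locus; < 1 kb -> proximal
tandem duplication; > 10 kb -> far; otherwise distal; different
scaffolds -> multi-chromosome (or multi-with-unanchored). Boundaries
are strict inequalities.

The built-in aligner (for synthetic scale) seeds exact 15-mers through
a sorted-array genome index, clusters seeds by scaffold and diagonal,
and extends candidate windows with affine-gap local alignment
(match +1, mismatch -3, gap open 5, gap extend 2, i.e. a gap of length
g costs 5 + 2g). SAM input is supported as the external-aligner path
(primary plus secondary alignments with AS scores; 1-based coordinates
converted internally).

## Integration and gene space

Per linkage group, the majority chromosome is the plurality vote of its
placed markers; collinearity is the orientation-corrected |Spearman|
between cM and bp, with discordant markers listed when their removal
improves rank agreement by more than 0.01. The kbp/cM ratio divides the
min-max physical span of the placed framework markers by their cM span;
the genome-wide figure is the unweighted mean of per-chromosome ratios
(which reproduces the reference genome-wide average), with an n-1 sd.
Coverage is the summed physical spans over the assembled total,
reported at full precision and as a rounded headline percent.
Unanchored scaffolds are assigned the linkage group of their mapped
markers; multi-group support flags a conflict and blocks assignment.
Full and framework maps are compared by a two-sample asymptotic KS test
on adjacent-gap distributions plus the fraction of gaps under 1 cM.

Gene-space statistics tile chromosomes into half-open bins (5 Mbp
default, last bin truncated), count probes, mapped markers and gene
models by start coordinate (conserving totals exactly), correlate
per-bin counts with a mid-rank Spearman rho (t-approximation p), and
measure each probe's bp distance to the closest gene model on its
chromosome (0 on any overlap; strand ignored), summarized over
configurable distance-class edges (default 0 / 1 / 5 / 10 kbp).

## Problem sizes

Synthetic linkage runs use 11 chromosomes x 100 markers at 177 progeny
(~1,100 markers, ~600k pairs, about a minute end to end); sequence-level
runs (probe planting, clustering, alignment, gene space) use genomes of
a few hundred kbp per chromosome with 100-200 probes, which exercise
every code path in seconds. These sizes were chosen so the full
characterization remains interactive while keeping every statistical
property measurable.

## Known limitations

* Two-point composite likelihood only; no multipoint HMM. Local order
  of markers closer than ~1/(2N) Morgans is unresolvable by design and
  is handled by framework deferral rather than by multipoint smoothing.
* The error-channel rate is a declared constant, not estimated from
  replicate concordance.
* Kosambi reporting over a Haldane-consistent fit is a convention
  compromise; on real data with crossover interference the roles
  reverse (Kosambi approximately additive), and the small mid-range
  discrepancy changes sign.
* The clustering engine targets near-full-length redundancy (cloned
  inserts of the same locus), not contig assembly of partial overlaps.
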