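# Methods

This note records the models, conventions and numerical choices behind
`ypanel`, and what the synthetic-data generator does and does not
emulate.

## Haplogroup name grammar and tree

A haplogroup name is one uppercase major-clade letter followed by
alternating digit runs and lowercase letter runs. Parsing splits the
name into components; joining components reproduces the name exactly
(round-trip invariant). Digit runs are compared as strings, never as
integers, so a hypothetical multi-digit component survives verbatim. A
single trailing `~` (provisional branch in ISOGG usage) is accepted,
stripped, and recorded on the label.

The tree is induced from the panel's labels alone: each label's parent
is its longest proper component-prefix present in the panel, else the
virtual root `Y` (which carries no markers). Bridging over missing
intermediate labels is deliberate — a panel need not carry a marker for
every level of the phylogeny. Markers sharing a label share a node, so
the node count equals the distinct-label count and the marker multiset
is conserved.

## Calling model

Two depth cutoffs, defaulting to the validated 18-read detection and
54-read analysis thresholds:

* depth < detection → genotype filtered out (`NO_CALL`/`FILTERED`);
* detection ≤ depth < analysis → called from the majority allele,
  status `REVIEW`. The bench workflow reviews this window manually; a
  library needs a deterministic rule, so the majority call is accepted
  while the `REVIEW` status is preserved for downstream consumers to
  exclude if they wish;
* depth ≥ analysis → `PASS`.

Loci are hemizygous: exactly two legitimate alleles. The majority
fraction is computed over ancestral + derived reads only; off-target
reads count toward depth but never toward a call. A majority fraction
below `allele_fraction_min` (default 0.9 — the upstream caller's exact
rule is unpublished, so this is exposed as configuration) or an
off-target fraction above 0.1 sets `MIXED_FLAG`. Ties resolve to
ancestral, which is conservative: it never pushes a sample deeper into
the tree. Y-Indel alleles are compared by sequence equality of the
spanning allele, not by length, so same-length substitutions cannot
masquerade as the derived state.

Profiles whose called-locus count is below 5% of the panel are labelled
"no reliable male DNA", mirroring the sporadic low-depth calls female
controls produce.

VCF-derived genotypes resolve orientation against the panel's
ancestral/derived alleles rather than REF/ALT order, accept `Y` as an
alias of `chrY`, take depth from FORMAT/DP when present and otherwise
leave it unmeasured (no fabricated read counts), and exclude loci whose
VCF alleles match neither panel allele (flagged on the profile).

## Inference rules

Terminal = deepest node with ≥ 1 derived marker whose root path is
fully supported. A path node is passable if it has a derived call, or —
under the default imputation policy — if all its markers dropped out (a
deeper derived marker rescues the path; cross-platform concordance data
justify this default, and it can be switched off). An ancestral call is
a hard veto on the node and its subtree. Mixed-flagged calls are
treated as no-calls; review-zone calls count as their state by default.

Candidates surviving in disjoint clades produce `CONFLICTED`; the
winner maximises (derived markers on its root path, depth), with a
lexicographic tie-break recorded on the assignment. Off-path derived
singletons (genotyping error or recurrent mutation — the panel design
excludes markers with reported back-mutations, so they should be rare)
are reported and downgrade confidence to `IMPUTED`, nothing more.

Reduced-panel inference rebuilds the tree from the marker subset before
inferring, which is exactly how a lower-resolution panel behaves; with
error-free calls its result is always an ancestor-or-equal of the
full-panel terminal.

## Population statistics

* Diversity: H = N(1 − Σ xᵢ²)/(N − 1) with xᵢ = nᵢ/N. This equals the
  probability that two individuals drawn without replacement differ in
  haplogroup (tested as an exact identity against pair enumeration).
  Rendered to 4 decimals alongside full precision; percentages to one
  decimal — the field's conventional rendering.
* HFS at level L truncates each terminal to its first L name components
  and tallies; level-(L−1) frequencies are exactly the sums of their
  level-L children.
* Fst: the study this package models names no estimator, so the
  documented default is unweighted two-population Nei G_ST on haploid
  haplogroup frequencies: H_S = mean(1 − Σp²), H_T from the unweighted
  mean frequency vector, Fst = (H_T − H_S)/H_T, defined as 0 when both
  populations are fixed for the same haplogroup. Merging published
  cohorts is row concatenation on the frequency matrix.
* PCA: column-centred frequency matrix, full SVD (no scaling), signs
  fixed so each component's largest-magnitude loading is positive.
  Level-4 HFS is the default input, configurable.
* Pedigree degrees: parent-offspring and full siblings are 1st-degree,
  with siblings censused in their own bucket (matching the pair
  taxonomy of pedigree validation studies); otherwise degree = meioses
  for lineal pairs and meioses − 1 for collateral pairs. Mutation
  events are discordant co-called loci summed over parent-offspring
  pairs, i.e. one meiosis each.

## Synthetic-data generator

What it emulates: panel tables with connected prefix families per clade
and amplicon lengths ~N(200, 12²) clipped to [120, 273] bp;
tree-consistent truth genotypes (derived exactly on the root path);
patrilineal inheritance with per-meiosis, per-locus flip probability;
and per-locus read counts that are negative-binomial
(variance μ + 0.3 μ², dispersion exposed in `DepthModel`) around
mean = baseline × mass × locus efficiency × scenario survival.

Calibration choices, made once:

* baseline mean depth 3,741× at 1 ng — the cohort-scale mean DOC of the
  instrument runs this models;
* locus efficiency is lognormal with unit mean and σ = 0.5, fixed per
  locus (amplification efficiency is locus-intrinsic); across ~639 loci
  this spans roughly 0.1×–4× of baseline, matching the printed
  442×–13,750× locus range;
* degradation survival exp(−len·ln(DI)/L): the bench data give only
  (DI, loci-called) anchors, no mechanism, so the form is chosen for
  monotonicity in amplicon length and degradation index, and L is
  calibrated by bisection on the exact negative-binomial detection
  probabilities so the expected called-locus count reproduces the
  published anchor (529 of 639 loci at DI 11.76). This is a calibration
  anchor, not a validated fragmentation mechanism, and the model is not
  expected to reproduce other DI points;
* inhibition is a retention-fraction lookup per (inhibitor, dose)
  shaped like the published dose-response curves; no chemistry;
* female stray reads are off-target (never the male truth's derived
  allele), with per-locus lognormal rates (median 0.17 reads/locus/unit
  mass, σ = 2.0) chosen so a female-only library yields a handful of
  sporadic calls (~6–12) and a few hundred total stray reads, the
  pattern female specificity controls show.

What it does not emulate: read-level data and alignment, sequencer run
metrics, PCR chemistry, genotyping error beyond symmetric per-meiosis
flips, recurrent/back mutation, and population structure beyond the
supplied sampling weights. Passing closed-loop tests therefore shows
the informatics is self-consistent under these study conditions, not
that the scenario models are mechanistically true of real libraries.

The 11 reference pedigree structures are synthetic stand-ins (the
study's diagrams are not redistributable) constructed so the sampled
relationship census reproduces the published one exactly: 41 males, 79
related pairs — 23 parent-offspring, 12 full siblings, 24 2nd-, 13
3rd-, 4 4th-, 2 5th- and one 6th-degree.

## Problem sizes and numerics

The test suite exercises the scales the package is designed for:
639-marker panels, a 500-node tree with 5,000 simulated samples for
recovery properties, 1,000 random spectra (N ≤ 30) for the diversity
identity at 1e-12, PCA against an independent eigendecomposition at
1e-8, and frequency-sum validation at 1e-9. All generators take
explicit seeds and are reproducible byte-for-byte; hypothesis runs
derandomised.

Degenerate inputs: diversity is an error below N = 2; Fst requires
frequency vectors summing to 1 (1e-9); PCA requires ≥ 3 populations;
an empty marker subset infers the virtual root; a depth-0 scenario
yields all no-calls.

## Known limitations

* The tree is purely nominal: it trusts the name grammar, so a panel
  whose labels disagree with the phylogeny they came from will build a
  nominally consistent but phylogenetically wrong tree.
* Assignment is rule-based, not probabilistic; there is no posterior
  over terminals and no error model for miscalls beyond veto/flag
  handling.
* The two-population G_ST estimator ignores sample sizes; for very
  small cohorts a variance-corrected estimator would differ.
* Real supplementary tables (full published panel and cohort) cannot
  ship with the package; the two tests that need them fail with
  instructions until the files are placed under `data/`.
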