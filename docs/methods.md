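# Methods

This note documents the models, procedures, defaults and numerical choices
behind familyscope, and what the synthetic-data generator does and does not
emulate.

## Domain scanning and subfamily classification

Family membership is decided with position-specific scoring matrices
(PSSMs) rather than full profile HMMs.  The discriminative content needed
here is the presence, count and completeness of AP2/B3 domain instances
plus two diagnostic residues; that does not require insert/delete states,
and results of a real profile-HMM search (HMMER3 `domtblout`) can be
imported for full fidelity on real data (a hit is "complete" when its
envelope covers ≥ 90 % of the model width).

The bundled AP2 (width 58) and B3 (width 100) models are **synthetic
consensus constructs**: each position places probability 0.95 on the
consensus residue and spreads the rest uniformly; scores are log-odds
against a uniform 1/20 background.  Positions 14 and 19 of the AP2 model
are scored neutrally (uniform frequencies) because they legitimately differ
between the ERF subfamily (Ala-14/Asp-19) and the DREB subfamily
(Val-14/Glu-19): a single-consensus model would otherwise penalize one
subfamily's genuine domains.  A window is a complete hit when its score
reaches 60 % of the model's maximum attainable score (default threshold,
tunable); hits are selected greedily best-first without overlap, ties by
the lower start coordinate.  Matches cut by a sequence boundary (a model
prefix flush at the C-terminus, or suffix at the N-terminus, minimum 10
positions) are reported with `complete=False` if they clear the same
fractional threshold on their covered positions.  Unknown residues
(including `X`) score as background, i.e. contribute zero.

Classification follows the domain-count rules; mixed diagnostic residues
fall back to position 14 alone with an ambiguity flag, and a non-A/V
residue at position 14 defaults to ERF, flagged.  Diagnostic positions are
counted 1-based from the reported hit start.  All coordinates in the
package are 1-based inclusive.

Protein properties: molecular weight uses average isotopic residue masses
plus one water; the isoelectric point is found by charge bisection with the
Bjellqvist pKa set (termini plus D, E, C, Y, H, K, R), both via Biopython's
ProtParam, which implements exactly that procedure.

## Homolog pairs and NG86 Ka/Ks

Candidate pairs must be ≥ 300 bp and exceed 40 % global-alignment identity
(identity = matches / alignment length); cross-species pairs additionally
must be reciprocal best matches.  The nucleotide aligner scores match +1,
mismatch −1 with **affine** gaps, open −16 / extend −4 (all exposed).  The
affine form is essential: with a linear gap cost the |ΔL| gap symbols
forced by any length difference cost the same wherever they sit, so the
optimizer scatters them to harvest spurious matches and unrelated
codon-structured sequences reach ~0.5 identity, defeating the 40 % floor.
With the defaults, unrelated CDS measure ~0.25–0.35 and genuine homologs
> 0.85.

Ka/Ks uses Nei–Gojobori (1986) counting under the standard genetic code:

* per sense codon, each position contributes (number of the 3 single-
  nucleotide changes that are synonymous and do not create a stop)/3
  synonymous sites; changes to stop codons count as nonsynonymous;
* differences are averaged over all k! mutational orderings between two
  codons, excluding orderings that pass through a stop codon (if every
  ordering is blocked the unrestricted average is used and flagged);
* codon alignment threads a BLOSUM62 protein alignment back as triplets;
  columns with a gap or an ambiguous base are dropped; ≥ 30 compared
  codons are required;
* site counts are averaged over the two sequences; pN = Nd/N, pS = Sd/S
  are Jukes–Cantor corrected (undefined at p ≥ 3/4, reported as an error;
  the pipeline records such saturated pairs as NA).

Ratio conventions: Ka = 0 gives ratio 0 (the convention of published
paralog tables); Ks = 0 with Ka > 0 leaves the ratio undefined.
Classification compares the ratio with 1 exactly.  No transition/
transversion correction is applied (this is NG86, not LWL or YN00).

## Phylogeny

The progressive aligner builds a guide tree from 3-mer set distances
(1 − shared/min) with UPGMA, then merges profiles by global
Needleman–Wunsch with BLOSUM62, gap open −10 / extend −0.5, scoring
profile columns by frequency-weighted average substitution score.
Tie-breaking is deterministic (diagonal preferred, then the vertical gap
state).  The dynamic program is vectorized row-wise; the horizontal gap
state is a running maximum with linear extension decay computed by
`np.maximum.accumulate`.

Distances use pairwise deletion; the Poisson correction d = −ln(1 − p) is
the protein default, with plain p-distance selectable.  Neighbor joining
is the Saitou–Nei algorithm with the standard Q-criterion; ties break to
the lowest index pair; negative branch lengths are clamped to zero with
the deficit transferred to the sister branch so the pair's summed length
is preserved.  On additive matrices the implementation reproduces the
generating topology and branch lengths to 1e-9 (tested against ten random
8-taxon trees and cross-checked against dendropy's NJ).

Bootstrap supports resample alignment columns with replacement and count
the percentage of replicates containing each internal bipartition of the
full-data tree.  Within replicates a saturated pair (p = 1) is clamped
just below 1 before the Poisson correction — `compute_distances` itself
still raises on saturated input — so degenerate resamples do not abort a
run.

Clans are assigned by the nearest labelled reference (Poisson distance in
a joint alignment) rather than by full co-clustering: nearest-reference is
the deterministic, testable reduction of "adjacent to an *Arabidopsis*
member in the tree".  Ties go to the lexicographically smaller clan label
with margin 0; AP2/RAV subfamily calls override the distance-based clan.

## Expression analysis

DEGs between two groups are called by a Welch t test on log2(FPKM + 1)
with a fold-change filter on raw group means (pseudocount 1).  The
fold-change threshold defaults to 2; a literal "any increase" criterion
(threshold 1) is degenerate but available.  p-values are raw by default
(mirroring fold-change + raw-p DEG definitions in the transcriptome
literature), with Benjamini–Hochberg available by flag.  Genes with zero
variance in both groups get p = 1 when means agree.  "Expressed" means a
maximum group-mean FPKM above 1.  Heatmap matrices are per-gene z-scores
of log2(FPKM + 1) group means; constant genes become zero rows.

Co-expression edges are Pearson correlations over the six stage means
(configurable to replicate columns), with the two-sided p from
t = r√((n−2)/(1−r²)) at n−2 df; pairs with p ≥ 0.05 are deleted and each
gene keeps its top-10 edges by |r| (union over endpoints), so negative
regulators survive.  Edges are canonical (sorted gene pair) and
deduplicated.

## qRT-PCR statistics

ΔCt is computed per replicate (Ct_target − Ct_reference), ΔΔCt subtracts
the mean calibrator ΔCt (0 h by default), and rq = 2^−ΔΔCt with the
amplification efficiency fixed at 2.  The per-condition summary rq is
2^−(mean ΔΔCt) — the geometric mean of replicate rqs — which makes the
calibrator's summary exactly 1 by construction; per-replicate rqs are also
returned.

Timepoint effects use one-way ANOVA followed by Duncan's multiple range
test at α = 0.05.  The critical range for a span of p ordered means is
q(α_p, p, df_error)·√(MSE/n) with Duncan's protection level
α_p = 1 − 0.95^(p−1); quantiles come from
`scipy.stats.studentized_range.ppf` (cached) rather than a bundled table —
scipy's implementation is exact and pinned in the environment, which beats
maintaining an interpolated table.  Letters follow the standard stepwise
procedure (a non-significant range protects all its sub-ranges), and the
whole letter split is **gated on a significant omnibus F test**: without
the gate the probability of any letter split under the null is the span-6
protection level (~0.23), not the nominal 5 %; the gated procedure holds
~5 % (verified by simulation) and matches the usual reading of "one-way
ANOVA, Duncan's multiple range test".

qPCR co-regulatory networks keep gene pairs with |PCC| > 0.5 and p < 0.05
over the six timepoint means, computed per treatment (published figures
show negative-correlation edges, so the magnitude is thresholded and the
sign retained).  Constant profiles are excluded with a warning.

## Synthetic-data generator

The generator emulates the statistical structure each stage assumes, with
truth tables covering every generated entity, and is byte-deterministic
under a fixed seed.

* **Transcriptome** — ERF/DREB genes descend from one of six clan
  ancestors each (B1–B6, A1–A6): flanks diverge by point mutation (3 % per
  residue by default) while the domain itself is inherited verbatim
  (domains are under strong purifying selection), with the diagnostic
  residues forced per subfamily.  AP2-subfamily genes carry two sampled
  AP2 instances, RAV genes AP2 + B3, decoys a 50 %-width terminal AP2
  fragment, negatives none.  CDS use uniform synonymous codon choice (no
  codon bias — keeps NG86 site counts unbiased); same-clan members inherit
  the ancestor's codons with sparse synonymous substitutions, so
  within-clan paralog pairs have realistic low dS.  The clan ancestors are
  emitted as the labelled reference set for clan assignment.
* **Divergent pairs** — `evolve_pair` proposes uniform single-nucleotide
  changes, rejects stop-creating proposals, accepts synonymous proposals
  with probability 1 and nonsynonymous ones with probability ω, and stops
  when the accepted synonymous events reach round(dS·S) for the ancestor's
  NG86 synonymous site count S — dS is controlled directly in accepted
  events, not proposals.  Because the Jukes–Cantor correction recovers
  event counts, the expected NG86 ratio equals ω; simulation at ω = 0.2
  and ω = 1 recovers means within [0.15, 0.25] and [0.85, 1.15].
* **Expression** — log2 FPKM is Normal(μ_g, σ) within replicates
  (log-normal FPKM noise; σ = 0.1 default), DE genes shift their group
  mean by log2(fold), and module members share a per-group latent factor:
  x = μ + s·(λ·z_group + √(1−λ²)·ε), so the pairwise correlation across
  group means approaches λ².  The default loading λ = 0.998 was derived
  analytically from the operating point the module-recovery property
  needs: with six stage means, a p < 0.05 Pearson filter corresponds to
  |r| > 0.8114, and keeping all ten within-module edges in ≥ 95 % of runs
  requires pairwise ρ ≈ 0.995 = λ² (Fisher-z calculation).  Weaker
  loadings (e.g. 0.95, ρ ≈ 0.90) produce modules whose edges are lost by
  the filter in most runs.  Non-module, non-DE genes are flat across
  groups, which is what makes the null DEG and null network simulations
  clean.
* **Ct tables** — reference Ct ~ Normal(20, 0.1) regardless of condition;
  target Ct = per-gene baseline − log2(planted fold) + Normal(0, 0.15);
  three biological replicates per cell; the 0 h calibrator is mandatory.

What the generator does **not** emulate: read-level RNA-seq (FPKM is
drawn, not quantified), codon-usage bias, indels (substitutions only),
expression mean–variance trends, amplification-efficiency deviations from
2, and between-replicate batch structure.  Passing tests therefore
demonstrate correctness of the statistical machinery under its stated
assumptions, not robustness to real-data artifacts such as misassembly or
incomplete ORFs — for real data the external HMMER import path and the
config-exposed thresholds are the intended entry points.

## Pipeline

`run_all` executes simulate → identify → tree/clans → pairs/Ka-Ks →
DEG/networks → qPCR from one flat YAML config (schema-checked; unknown
keys are rejected listing the valid ones; `seed` is mandatory).  Stage
outputs are cached by a parameter hash, reruns skip clean stages, and the
manifest hash over counts and parameters is invariant across reruns.
Expression and qPCR blocks can be disabled; the manifest marks them
skipped.  Default problem sizes (tens of genes, 100 bootstrap replicates,
300-codon pairs) keep a full run in the tens of seconds while every filter
still has work to do; all sizes are config keys.

## Known limitations

* The PSSM scan reports at most one incomplete terminal hit per end and
  does not model internal deletions inside a domain instance.
* NG86 with Jukes–Cantor correction saturates near p = 3/4; deeply
  diverged pairs (common among cross-clan candidates) are reported as NA
  rather than extrapolated.
* The progressive aligner has no iterative refinement; for hard real-data
  alignments an external MSA can be passed in as a `Msa` directly.
* Duncan letters assume equal group sizes (the three-replicate design).
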