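# Methods

## Substitution model

Unpaired (and, in analysis, all) sites evolve under GTR+Γ.  The generator is
`Q_ij = s_ij π_j` for `i ≠ j` with six symmetric exchangeabilities
(order AC, AG, AU, CG, CU, GU) and stationary frequencies `π`, normalised to
one expected substitution per site at equilibrium so that branch lengths are
expected substitutions/site.  Among-site rate variation uses Yang's discrete
gamma: `K` equal-probability bins represented by their means (default
`K = 4`), bin means computed from the regularised incomplete gamma function
and rescaled to mean 1.  `P(t) = exp(Qt·r)` is computed by symmetric
eigendecomposition of `diag(√π)·Q·diag(1/√π)`, which is numerically stable
and exact for reversible `Q`; rows are clipped/renormalised against rounding.

**Defaults** (no fitted values are published for the system this package
emulates; these are the package's fixed choices): exchangeabilities
`(1, 1.5, 1, 1, 1.5, 1)` — mild transition bias — frequencies
`(0.26, 0.24, 0.27, 0.23)`, `α = 1.0`.  The mildness matters: the neutral
one-third rule (below) presumes near-equal replacement probabilities.  Under
equal exchangeabilities the restoring fraction of double changes is exactly
1/3 at any branch length (the child state is uniform over the three
alternatives); a short-branch closed-form calculation puts it at ≈ 0.335 for
transition/transversion ratios near 1.2–1.5 but ≈ 0.49 for strongly
transition-biased models.  A user analysing data with a heavily
transition-biased model should interpret the one-third baseline accordingly.
Parameters can be supplied in a YAML block or fitted by direct Nelder–Mead
maximisation of the pruning likelihood (frequencies fixed at empirical
counts, AU exchangeability as the unit).

Gaps and `N` are missing data (all-ones partial likelihoods).  Per-site
scaling with logged scale factors prevents underflow on large trees.

## Ancestral reconstruction

Marginal (empirical-Bayes) posteriors combine inside ("down", pruning) and
outside ("up") partial likelihoods at every internal node, per gamma
category; categories are then averaged with weights proportional to each
site's per-category likelihood (the per-site category posterior under a
uniform prior).  MAP states break ties in fixed alphabet order A<C<G<U —
relevant only in symmetric toy cases.  An all-gap column yields the
stationary distribution and is flagged.  Substitution mapping is the simple
endpoint-difference indicator per edge (leaf states from the alignment, a
leaf gap masks its edge).  Probabilistic (expected-count) mapping was
deliberately not implemented: reconstruction posteriors on the intended data
scale are high (the test suite requires a mean MAP posterior ≥ 0.9 at the
benchmark depth), where the indicator and expected-count mappings nearly
coincide.

## Watson–Crick switches and the TIR

For each structural pair and each pair of extant species whose
dinucleotides are distinct Watson–Crick pairs, the number of substitutions
at the two sites along the connecting tree path is read off the MAP/observed
states; a count of exactly two defines a clean switch.  With exactly two
changes the LCA state is necessarily an endpoint (terminal — both changes on
one side of the LCA) or the one-step intermediate (changes on opposite
sides).  The TIR is the ratio of terminal to intermediate counts.

Counting is **per qualifying species pair**, not per collapsed event: the
TIR's neutral calibration (≈ 1) relies on terminal configurations being
weighted by the many lineage pairs that flank them.  Collapsing to unique
substitution-edge pairs inverts the weighting (sibling-subtree geometries
vastly outnumber nested ones) and drives the neutral ratio far below 1; an
event-level view is still available via `collapse_events=True`.  Switches
whose connecting path carries three or four substitutions between
Watson–Crick endpoints are tallied at event level (deduplicated by their
flanking change edges, and suppressed when those edges already belong to a
clean switch) as the residual "multiple substitutions" category; they are
excluded from TIR counts.  Wobble (GU/UG) is never a Watson–Crick endpoint —
it is an intermediate of the AU↔GC type — but counts as paired in the
stem-integrity trajectory when `wobble_ok` is set (two distinct notions,
separately configurable).

Internal-node endpoints can be admitted (`endpoints="all"`); the default is
species pairs, which matches the LCA framing of the statistic and is less
dominated by single deep events.

Records any of whose path nodes have a MAP posterior below 0.7 (configurable)
at either site are flagged low-confidence and excluded from headline counts.

Switch types are AU↔GC, AU↔UA, GC↔CG and AU↔CG; orientation-swapped
endpoint pairs (e.g. UA↔CG) map onto the same type.  Intermediates are
computed in site order — an AU→CG switch at sites (i, j) passes through CU
or AG; the conventional table labels ("AG or UC") mix the two orientations.

## The one-third rule

Among tree edges where both members of a pair change **and the parental
state is Watson–Crick**, neutrality predicts one third of child states to be
canonical again.  The test is χ² with 1 df against the (1/3, 2/3) split,
without continuity correction, on exact expected fractions (displayed
rounded to integers).  Conditioning on a paired parent is essential: without
it even Jukes–Cantor gives ≈ 1/4.  The published per-taxon observed counts
shipped in `rnacoevo/data/` reproduce printed expected pairs
((8, 17), (18, 35), (5, 11), (9, 18)) and a χ² of exactly 24.5 for the
(20, 5) data set; the corresponding printed p-values are not reproducible by
a standard 1-df χ² (the exact value for 24.5 is 7.4×10⁻⁷), which this
package documents rather than chases.

## Coevolution detection

*MIp*: mutual information in nats from plug-in counts (pairwise gap
deletion, no pseudocounts), APC `= MI(i,·)·MI(·,j)/MI̅` over the scored site
set, MIp = MI − APC.  Significance (`p_mip`) is the one-sided normal tail of
MIp standardised against the mean and SD of MIp across all scored pairs;
because background pairs share the alignment's phylogenetic structure this
is robust to tree-induced correlation.  A within-column permutation p
(`p_perm`) is also reported; it is exact for exchangeable taxa and
anticonservative otherwise — on tree-structured data it flags most pairs.

*Vector correlation*: Pearson correlation of per-branch substitution
indicator vectors.  The null is a parametric bootstrap: independent-site
alignments simulated on the analysis tree and model, passed through the same
reconstruction and mapping, all pairwise correlations recorded jointly with
each pair's minimum per-site substitution total.  A pair's p-value is
computed against the null pairs closest in minimum variability, with the
matching window grown until it holds 50,000 entries (or the whole null) —
locally matched, yet fine-grained enough for multiple-testing control.
Equality-only strata calibrate well but cannot resolve p-values below
1/stratum; unstratified pools mix the discrete correlations of
barely-variable pairs into the tail.  Default replicates: 10,000 for
production runs, a few hundred in tests.

*Consensus*: pairs significant under **both** detectors, with α applied to
Benjamini–Hochberg-adjusted p-values by default (thousands of candidate
pairs are scored; raw per-pair thresholds at α = 0.05 would admit ~α of all
pairs through the better-calibrated detector alone).  Raw thresholds remain
available.  Multi-site groups are formed post hoc by transitive closure of
significant pairs rather than by full cluster testing.

## Synthetic benchmarks

The generator emulates a 5S-like molecule: a fixed 120-nt template with five
helices (I: 10 bp, II: 9, III: 9, IV: 8, V: 8) and five loops (A: the
three-part hinge, B internal, C and D hairpins, E internal), 44 base pairs
in total; Yule (pure-birth) trees scaled to a tip depth of 0.5 expected
substitutions/site; 30–160 taxa (default 100).  Loop sites follow GTR+Γ.
Stem pairs evolve jointly on the 7-state alphabet {AU, GC, GU, UA, CG, UG,
MM}, MM pooling the ten non-canonical dinucleotides.  Default pair
frequencies (AU = UA = 0.17, GC = CG = 0.24, GU = UG = 0.07, MM = 0.04) echo
canonical-pair dominance; default exchangeabilities weight concerted
double substitutions between complementary pairs (AU↔GC, UA↔CG) highest,
wobble-mediated single steps moderately, and mismatch paths lowest — the
qualitative structure of fitted paired-site rRNA models.  All are
configurable.  `selection_strength` rescales the stationary mass of MM
(σ → 0 forbids mismatches; σ = 1 recovers the base model), which under the
GTR parameterisation scales every rate *into* the mismatch class.  The pair
process is normalised to one expected nucleotide substitution per stem site.

States are sampled edge-wise from `P(t)` (endpoint sampling), not by
event-by-event simulation; recorded "events" are therefore endpoint
differences and collapse multiple hits within an edge.  A pair entering MM
draws a concrete mismatched dinucleotide uniformly and keeps it until the
pair state next changes, so the neutral-limit equivalence with independent
sites holds at the 7-class resolution, not per mismatch dinucleotide.  A
single seed fixes everything: tree, categories, states, and file artefacts
are bit-identical across reruns.

What the generator does **not** emulate: indels and alignment error (no
gaps are simulated), heterotachy, base-pair stacking or loop–helix
thermodynamic coupling, pseudoknots, and real 5S sequence composition.
Passing benchmarks therefore demonstrate correctness and calibration of the
statistics under the stated model, not robustness to alignment artefacts.

## Problem sizes and tolerances

Test and acceptance runs use 20 replicates of 100-taxon, 120-site
benchmarks for the neutral and selective TIR checks, 50-taxon benchmarks
for reconstruction accuracy, 200-replicate bootstrap nulls and
300-permutation calibrations — sizes chosen so the whole suite runs in
about a minute while leaving the statistics' sampling error well inside the
asserted bands.  Exact oracles (enumeration over all ancestral assignments
on 4-leaf trees, closed-form Jukes–Cantor, hand-computed MI tables) are
held to 10⁻⁸ or tighter; stochastic properties assert the bands stated in
their docstrings.

## Known limitations

* Analysis reconstructs ancestors under an independent-sites model even for
  stem positions; the paired simulation violates that model deliberately
  (it is the signal being detected), so stem-site posteriors are slightly
  miscalibrated under strong selection.
* The TIR's per-species-pair counts are not independent observations; the
  package reports counts and ratios, not a parametric test on them.
* Compensation-mechanism labels (direct-WC, multi-site-same-helix,
  new-pair-created, stem-loop-boundary-change) come from a breadth-first
  scan over the fixed template structure, not from re-predicted ancestral
  structures; thermodynamic evaluation of ancestral structures is out of
  scope (an external folding tool can be applied to the exported ancestral
  FASTA).
* Trees are inputs; no topology inference or model selection is performed.
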