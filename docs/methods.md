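# Methods

## The scoring model

The pipeline treats the heavy/light isotope abundance ratio as the primary
datum and never lets downstream steps overrule it — network support and
disease-specificity penalties act as multiplicative modifiers only.

**Selection.** A protein is a candidate iff its heavy/light ratio strictly
exceeds the fold threshold (default 1.2; a ratio of exactly 1.2 fails) in
at least one database search (`any_db` mode; `primary_db` restricts to the
swissprot-tagged records). Exclusion gene sets then remove known GVHD or
common proteins. These two steps fully determine membership; everything
after re-ranks.

**Connectivity.** On the candidate subnetwork (edges at confidence ≥
`min_confidence`, default 0.7 — the conventional high-confidence STRING
cutoff; the score range is 0–1 with the 0–1000 file dialect handled at
load), raw support of core gene *g* is the sum of confidences of its
retained edges to any retained node, including outer genes when the
one-hop extension is enabled. Weights are normalized by the maximum over
core genes, so ĉ ∈ [0, 1] and at least one gene has ĉ = 1 whenever any
edge exists. Candidates missing from the PPI graph get ĉ = 0 but are
retained (absence of curated interactions is not evidence against a
candidate).

**Relevance and penalty.** relevance = ratio · (1 + α·ĉ) and
final = relevance / (1 + β·k), where k counts the other-disease penalty
sets containing the gene. Both forms were chosen for three properties:
they preserve the ratio as the leading factor; each collapses to the
identity at parameter 0 (α = 0 gives the pure fold-change ranking, β = 0
reproduces a no-penalty run); and a gene hit by two penalty sets at the
default β = 0.5 has its score halved, so penalties can change a score
more than two-fold while never altering which genes are present. The
functional forms are a design choice of this package and are isolated
behind the `scoring` module surface so an alternative strategy can be
swapped in without touching the rest of the pipeline.

**Combination.** The signature is the union of the two experiments'
scored candidates. Genes scored in both receive the geometric mean of
their final scores — symmetric and scale-respecting for ratio-like
quantities (the arithmetic mean is available by config); singletons carry
their own final score, with provenance recorded. No score cutoff is
applied for membership: sub-1 combined scores stay in the signature,
only stratified in the report. Ties are broken alphabetically everywhere
(ordering, report rows) for reproducibility.

## GeneTerrain

The layout is networkx's Fruchterman–Reingold force-directed embedding
with edge attraction weighted by confidence, deterministic under a fixed
seed, rescaled into [0.05, 0.95]² so peaks stay off the raster border. A
single node sits at (0.5, 0.5). The surface is the sum of isotropic
Gaussian kernels, one per gene, evaluated at cell centers
((i + 0.5)/G): surface(p) = Σ z·exp(−‖p − p_gene‖²/(2σ²)). Defaults
G = 256, σ = 0.05 resolve a few dozen genes into distinct peaks; heights
default to the combined final score, with log2(ratio) selectable.
Kernels are accumulated in sorted gene order so the surface is exactly
independent of input order. Consequences used by the tests: a single
kernel's grid maximum is within 1% of its height (the nearest cell center
is at most half a cell diagonal away); the surface is linear in the
heights; and total mass ≈ 2πσ²·Σz when genes sit well inside the border
and σ spans ≥ 2 cells.

## Single-cell classification

The classifier is a detection-fraction threshold rule: a gene is
"expressed" in a condition when the fraction of cells with a nonzero
count is ≥ θ (default 0.1). Expression in the two antigen-positive
conditions determines the category (both → general activation, PRAME only
→ PRAME-specific, CMV only → CMV-specific, neither → not expressed).
Genes detected only in antigen-negative or nonreactive cells are
classified not-expressed-in-activated-cells and flagged. A fold-change or
test-based rule could be substituted behind the same interface; the
threshold rule was chosen because it reproduces the intended category
semantics with one interpretable parameter. The CMV-specific category is
kept as a legal output even when empty, so partitions on other data are
not silently distorted. `overlap_summary` reports the category partition
of a signature, the expressed-in-T-cells total, and its percentage
rounded to the nearest integer.

## The synthetic generator

`generate_experiments` emulates the paired pooled design: two experiments
over one gene universe of 60 signature, 80 GVHD-confounder, 700
background and 50 contaminant genes (defaults).

* Ratios are LogNormal — positive and multiplicative. Signature and GVHD
  genes draw from LogNormal(ln 1.6, 0.25) left-truncated at the 1.2
  threshold (inverse-CDF truncation), so every planted gene passes the
  filter and recovery measures specificity rather than luck; background
  and contaminant genes draw from LogNormal(0, 0.15). No public data
  constrain these spreads; they are calibrated for test power only and
  make no biological claim.
* Each protein is independently dropped from each experiment with
  probability 0.15, emulating incomplete identification.
* GVHD confounders look like signal in both tables but every one belongs
  to at least one of two overlapping exclusion sets, so the exclusion
  step should remove them all.
* The network is Barabási–Albert preferential attachment (m = 2) over the
  whole universe — approximating the scale-free degree structure of real
  PPI networks — with base confidences Uniform(0.2, 0.95) and 120 extra
  planted edges among signature genes at Uniform(0.7, 0.99), giving the
  planted module the dense high-confidence structure the connectivity
  weight rewards.
* Each of 20 penalty sets contains a random 5% of background genes plus
  each contaminant with probability 0.5, and never a signature gene (a
  switch allows contaminated penalty sets for robustness tests).

`generate_singlecell` assigns each provided gene a truth category with
default mix 11:32:0:18 (PRAME-specific : general : CMV-specific :
silent, the partition scale of a 61-gene signature) by largest-remainder
apportionment, then draws negative-binomial counts (dispersion r = 2)
with mean 2.0 in conditions where the category says expressed and 0.02
elsewhere, for 200 cells in each of five conditions. At these defaults
an expressed gene's detection fraction is ≈ 0.75 and a silent gene's
≈ 0.02, on either side of θ = 0.1, so classification recovers ≥ 90% of
truth labels. 200 cells per condition (not the thousands of a real
droplet run) keeps the default suite fast; the count is configurable
upward.

What the generator does **not** emulate: peptide-level quantification and
pooling of individual patients (each experiment is one collapsed ratio
table), correlated dual-database searches, batch effects, ambient RNA or
doublets in the single-cell matrix, and any biological correlation
between a gene's proteomic ratio and its transcript detection. Passing
tests therefore demonstrate algorithmic correctness and planted-truth
recovery under the stated model, not clinical validity on real plasma.

## Recovery metric

Planted-signature recovery is reported as precision/recall of the top-k
genes ranked by combined final score, with k equal to the number of
planted signature genes — the standard planted-module convention, which
makes precision and recall coincide and avoids an arbitrary score
cutoff. Membership-level precision (all filter survivors vs truth) is
deliberately not the headline metric: with an 11% upper tail of the null
ratio distribution above the 1.2 threshold, the filter alone admits many
background genes by construction, and it is the scoring stage's ranking
that separates them. Zero surviving GVHD confounders is asserted
separately. On default bundles, seeds 1–10, mean precision = recall
≈ 0.97.

## Numerical and interface choices

* Duplicate quantification rows for a gene keep the larger peptide count,
  then the larger ratio (better-supported quantification wins).
* Report files serialize floats with full `repr` precision and are parsed
  back with exact string-to-double conversion, so write → read is an
  identity on all score chains (pandas' fast csv float path is bypassed
  for values; it is only used to mask unparsable cells).
* The STRING score dialect (unit vs 0–1000) is explicit configuration and
  never guessed from magnitudes.
* One integer seed drives a `numpy` Generator for the proteomics bundle;
  the single-cell stream is spawned from (seed, 1) so the two generators
  are independent but jointly reproducible. Fixed seed ⇒ byte-identical
  outputs, verified by tests.
* Default problem sizes (890-gene universe, 200 cells × 5 conditions,
  256² raster) were chosen so a full pipeline run completes in about two
  seconds; all are configurable upward.

## Known limitations

* The relevance/penalty functional forms and the detection-threshold
  classifier are this package's choices; results on real data will
  depend on them even though all qualitative behaviors (retention of
  sub-1 scores, >2× penalty modification, penalties never changing
  membership) are invariant to the parameters.
* Connectivity normalization by the core maximum makes ĉ relative within
  an experiment; scores are not comparable across networks of very
  different density.
* The one-hop extension adds outer genes to connectivity support only;
  outer–outer edges are excluded by default (available behind a flag for
  sensitivity analysis).
* GeneTerrain output is qualitative: no pixel-level correspondence to any
  particular published rendering is attempted.
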