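# Methods

This note documents the models, conventions and numerical choices
behind `metaprot`, in the order data flows through the pipeline.

## Synthetic data: what is emulated, and what is not

The generator produces the statistical structure an integrated
metagenomics–metaproteomics quantification consumes, not mass spectra.
A sample's PSMs are a multinomial draw over database proteins, with the
weight of protein *p* in taxon *T* equal to

    w_p = fraction(T) · expr_p · length_p / Σ_{p'∈T} expr_{p'} · length_{p'} .

Normalizing expression×length *within* the taxon makes a taxon's
expected PSM share exactly its configured fraction, which is the
ground-truth contract the biomass profiler is validated against; with
unnormalized weights the species share would also depend on the random
total catalog weight per species, confounding recovery tests.

Defaults (chosen once as realistic study conditions; none are fit to
data): Dirichlet α = 0.5 for species biomass (a few dominant species,
many rare ones); host fraction 0.20 and dietary-protein fraction 0.04
of PSMs; 3% and 8% of microbial signal routed to the low-quality-bin
and unbinned partitions; protein lengths log-normal with median 300 aa
(σ = 0.35); within-taxon expression log-normal (σ = 1); per-sample
depth 20,000 target PSMs for calibration-style runs and 3,000 for the
demo pipeline.  Proteins are concatenations of unique random tryptic
peptides (7–30 aa, ending K/R, no interior K/R, no missed cleavages),
so an in-silico digest of the database reproduces the generating
peptides exactly.  A configurable fraction of species peptides is
copied into a second species' protein to create shared-peptide
ambiguity; host and diet proteins never share peptides with microbial
ones, which keeps the microbe:host contract independent of the
ambiguity contract.

Scores follow the standard target-decoy generative model: a fraction
(default 0.1) of target PSMs are incorrect matches scoring from the
null Normal(0, 1) and assigned to uniformly random proteins; correct
targets score Normal(4, 1); the decoy count is drawn with the same
expectation as the false-target count, the regime in which decoy counts
estimate false-target counts and target-decoy FDR is calibrated.

Not emulated: spectrum physics (m/z, retention time, charge),
post-translational modifications, peptide detectability differences,
protein-inference ambiguity beyond shared tryptic peptides, and
compositional covariance between taxa.  Passing tests therefore
demonstrate correctness of the *quantification arithmetic and
statistics* under the stated sampling model, not robustness to
instrument- or search-engine-specific artifacts in real data.

The feeding-study simulator layers log-linear effects on species
abundance — per-(protein-source, species) effects (σ = 0.9),
per-(mouse-group, species) effects (σ = 0.7) and per-sample noise
(σ = 0.25) — over a 12-mouse, two-group, eight-diet repeated-measures
design, giving PERMANOVA and the mixed models genuine between-sample
variance sources.

## Database assembly

Bins pass one of two quality tiers (strict inequalities): species-grade
at completeness > 50% and contamination < 10%, or a relaxed tier at
> 30% and < 5% whose proteins carry the `LOWQ` code.  A sequence found
in species-grade bins of two or more species groups is `AMBIGUOUS`; a
sequence in both a species-grade and a low-quality bin follows the
species code (precedence logged).  Unbinned gene calls are added only
when no binned sequence matches at ≥ 90% identity; host and dietary
reference proteomes are each collapsed at ≥ 95% identity before being
coded `HOST`/`DIET`; database sequences matching a named reference
proteome at ≥ 95% are recoded to that species.

Identity is matched columns divided by the shorter sequence length
(CD-HIT `-c` semantics) under a global alignment with match +2,
mismatch −1, gap open −2.5, gap extend −0.5.  Pure max-matches scoring
with free gaps computes a longest common subsequence and overstates
identity, hence the small gap penalties.  A shared 4-mer prefilter
skips hopeless pairs before the exact dynamic program.  Greedy
clustering visits sequences longest-first with first-seen tie-break, so
output is deterministic.

## PSM filtering and counting

FDR is estimated at the PSM level by target-decoy competition:
FDR(s) = #decoys(≥ s) / max(1, #targets(≥ s)) at each score threshold,
with q-values the monotone non-increasing envelope over score (no +1
correction).  Tied scores share one threshold; row order never affects
the result.  Filtering retains target PSMs with q ≤ 0.05 by default.

Peptides resolve to proteins by in-silico tryptic digest of the
database (peptide equality on the plain amino-acid string; I/L kept
distinct).  A protein is reported only with ≥ 1 protein-unique peptide
observed.  Under the default `unique-only` counting policy a PSM counts
only toward the protein for which its peptide is unique — shared
peptides are never double-counted — and Σ protein counts ≤ retained
PSMs with equality when nothing is shared.  A `count-to-all` switch
increments every matching protein instead.

## Biomass profiles

Only proteins with ≥ 2 protein-unique peptides contribute to biomass.
The evidence is pooled across the study by default (a protein observed
with one unique peptide in each of two samples qualifies); a
`per_sample` switch applies the rule within each sample.  "Unique"
means unique to the protein accession; this is deliberately weaker than
species-unique, and `AMBIGUOUS`-coded proteins are excluded from
species sums but kept as a partition.  Species percentages divide by
species-assigned counts only; the microbe:host ratio adds the
ambiguous, low-quality and unbinned partitions to the numerator and
excludes diet everywhere.  Samples without host spectra yield a missing
ratio with a warning rather than an error.

## Diversity and PERMANOVA

Shannon index uses natural logarithms over within-sample proportions.
Bray–Curtis is 1 − 2Σmin/(ΣA+ΣB) (scipy's implementation); a pair of
all-zero samples is undefined and flagged.

PERMANOVA partitions the Gower-centered squared-distance matrix
G = −½ J D² J sequentially: nested design matrices X₀=[1] ⊂ X₁ ⊂ …
(categorical factors as dummy blocks, numeric factors as single
covariates), hat matrices H_k via pseudoinverse, SS_k = tr((H_k −
H_{k−1}) G), residual SS = tr((I − H_m) G), pseudo-F = (SS_k/df_k) /
(SS_res/df_res).  Factor order follows the input (the convention of a
single ordered-factor table: protein source, amount, mouse group,
age).  Significance comes from free permutation of sample labels
(rows/columns of G), p = (b+1)/(m+1), default m = 999 with a mandatory
seed.  Collinear factors get df = 0 and a flagged NaN F.  Pairwise
PERMANOVA runs one two-group test per pair, skips singleton groups with
a warning, and BH-adjusts p across pairs.

CLR-PCA uses ln(x + pseudocount) centered within sample, then SVD of
the sample-centered matrix; the pseudocount defaults to half the
smallest nonzero value (the zero-handling convention adopted here), and
component signs are fixed so each component's largest-magnitude loading
is positive.  Hierarchical clustering is ward.D2 on Euclidean distances
(scipy `linkage(method="ward")`), optionally after the same log
transform, with Newick output carrying branch lengths derived from
merge heights.

## Functional profiles

NSAF% divides length-normalized counts by the summed microbial total —
host and diet proteins enter neither side; the default microbial scope
includes the ambiguous/low-quality/unbinned codes since they are
microbial material.  NSAF uses all proteins passing the ≥ 1-unique-
peptide identification filter (the ≥ 2 rule applies to biomass only).
`orgNSAF` restricts both sides to one organism, so it is invariant to
every other species' counts.

Annotation labels resolve by precedence: curated label > curated label
extrapolated to proteins sharing the exact per-tool label signature of
a curated protein > consensus when all tools that produced a label
agree > unannotated.  Curated proteins with identical signatures but
different labels block extrapolation for that signature (warned).
Rollups sum member NSAF% per broad/detailed category, enzyme name,
GH family or PUL, with an explicit `unannotated` feature so columns
conserve the protein-level total; PUL membership must partition.
Amino-acid pathway rollups classify enzymes by (amino acid, direction ∈
degradation/synthesis/interconversion/reversible); the
ammonia-producing panel sums degrading or reversible enzymes with
ammonia among their products.  The enzyme and pathway vocabularies ship
as editable TSVs under `metaprot/data/`.

## Per-feature statistics

The mixed model is `value ~ C(group, Sum) * C(diet, Sum)` with a random
intercept per mouse, fit by REML.  The diet test is a Wald F on the
diet main-effect coefficients (sum-to-zero contrasts make it a
marginal, Type-III-style test) with denominator df = n − rank(X); a
Satterthwaite approximation is not used because the underlying mixed
model implementation does not expose one — with the balanced designs
this pipeline targets the residual-df F is close.  Marginal means
average fixed-effect predictions over groups with equal weight (the
averaging convention adopted here) and carry Wald 95% intervals.
Degenerate inputs are flagged rather than fatal: a zero-variance
feature returns p = 1 with collapsed intervals; a design where some
diet appears in only one group (or any fit failure) degrades to
per-diet cell means with a `singular` flag.

Welch tests use the unequal-variance t statistic with
Welch–Satterthwaite df; zero-variance limits resolve to t = 0, p = 1
(equal constants) or |t| = ∞, p = 0.  Log₂ fold-changes clip both means
at a floor defaulting to half the smallest nonzero value across the
two matrices.  BH adjustment is the standard step-up (delegated to
statsmodels; validated against a brute-force implementation in tests).

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: biomass recovery
on 50-species communities at 10⁵ PSMs/sample over 10 seeds (mean RMSE
vs truth, threshold 0.01); FDR calibration pooled over 20 simulations
at 20,000 PSMs each; PERMANOVA equivalence on ≤ 8-sample toys against
an independent eigen-embedding partition (10⁻⁹ tolerance) plus 500
null simulations at 99 permutations for p-value uniformity (KS at
α = 0.01); ward.D2 agreement on 6-point instances; and mixed-model
power on 100 simulated 12-mouse × 10-diet studies with a 2σ diet
effect.  These sizes give stable statistics while keeping a full
validation run under a minute of compute.

## Known limitations

- FDR is estimated at PSM level only; peptide- and protein-level
  error control of a full search pipeline is approximated, not
  reproduced.
- The identity threshold operations use exact pairwise alignment with a
  k-mer prefilter; they are meant for the database sizes a desk
  analysis handles, not for clustering millions of sequences.
- PERMANOVA assumes exchangeable samples under the null; the repeated-
  measures structure of a feeding study is not reflected in the
  permutation scheme (as is conventional for these factor tables).
- The synthetic generator's independence assumptions (no taxon
  covariance, no detectability bias) mean calibration results bound
  what the arithmetic can do, not what any instrument will deliver.
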