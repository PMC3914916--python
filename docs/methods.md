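# Methods

This note documents the models, parameter choices and numerical conventions
behind `nifhnet`, and what the synthetic-study tests do and do not
demonstrate about real data.

## Synthetic study generator

The generator emulates a dead-wood survey: 45 logs split between two tree
species (*Fagus*, *Picea*) and three forest-management types
(age-class, selection, unmanaged), each log carrying covariates and two
occurrence tables (sporocarp presence, *nifH* MOTU clone counts).

**Covariates.** Remaining mass (%) is drawn uniformly within one of four
decay strata — (75, 95], (55, 75], (35, 55], (15, 35] — cycled over logs so
all decay stages are represented. Nitrogen per density unit starts at
8·10⁻⁴ g·cm⁻³ and rises in expectation by a factor of up to 3.5 as mass
falls, with multiplicative lognormal noise (σ = 0.15); the
`covariate_coupling` knob scales the trend and at 0 decouples N from mass
exactly. Carbon per density unit declines mildly (≤ 10 %) from a base of
0.25 g·cm⁻³. Water content is unimodal in remaining mass, peaking at
54.9 % water near 55 % remaining mass with additive Gaussian noise
(σ = 2 percentage points). These are qualitative trend emulations, not
fitted field models.

**Occurrences.** Cell probabilities follow a logit-additive model
`logit p = α_taxon + species_effect · pref_taxon · s_log + c_log`, with
taxon baselines α ~ N(0, 0.8²), per-taxon tree-species preferences
pref ~ U(−1, 1), and a per-log offset `c_log` solved by bisection so the
expected per-log richness hits species-specific targets (nifH: 9.5 on
*Fagus*, 7.5 on *Picea*; fungi: 9.1 / 6.0, matching the reported mean
richness contrast between the two wood species). This parameterisation was
chosen because with `species_effect = 0` the occurrence *odds* factor into
a row term times a column term, and conditioning such a product-form
distribution on its margins yields the *uniform* distribution over matrices
with those margins — exactly the fixed–fixed null. Calibration runs are
therefore exact by construction, not approximately so. The magnitude of the
tree-species composition effect is left as a free parameter
(`species_effect`, default 1.0 on the logit scale) since no quantitative
effect size is available to pin it.

Per-log nifH richness is kept inside [3, 14] (fungi: [2, 20]) by a
deterministic adjustment that adds the most probable absent taxa or removes
the least probable present ones. With the default taxon counts (40 MOTUs,
30 fungi) the unclipped richness already falls in range for > 99 % of logs,
so the adjustment is a rare boundary correction and leaves pairwise
independence effectively intact.

**Planted associations.** A planted pair is coupled through a mixture
copula on a shared uniform: with probability `strength` the two taxa use
the same (positive, comonotone) or complementary (negative,
countermonotone) uniform, otherwise independent draws. Pair members share
marginal parameters, so at strength 1 a positive pair co-occurs exactly
wherever either member occurs and a negative pair never co-occurs. Planted
taxa get their baseline floored at α ≥ 0 so the ground truth is prevalent
enough to pass the ≥ 3-occurrence filter and remains evaluable downstream.
Present MOTU cells receive clone counts 1 + Poisson(2), giving library
sizes near the ~1,000-clone scale of a full survey; sporocarp cells are
presence only, since fruiting-body surveys carry no abundance.

**Amplicons.** Each MOTU's insert encodes a 106-codon window of a bundled
reference NifH-like profile (a *synthetic* constructed stand-in, not a
database sequence) with a private 10 % amino-acid substitution load —
sparing the two conserved cysteines — reverse-translated with random
synonymous codons; two trailing untranslated bases pad the insert to 320 nt
so the full amplicon (primers included) is 360 bp. Within-MOTU variation is
confined to a MOTU-specific pool of polymorphic sites of size
`divergence_within × 320` with one fixed alternative base each, never
creating an in-frame stop and never touching the cysteine codons. This
bounds *pairwise* within-MOTU divergence by `divergence_within` (reads
differ only where their mutation subsets differ), which is what makes exact
MOTU-count recovery at the 97 % threshold a well-posed expectation; free
per-read mutation would let read pairs drift past the threshold. Reads are
flanked by random IUPAC expansions of the PolF/PolR primers, substitutions
only (no indels, no chimeras, no quality errors).

## Sequence processing

Primer matching is positional and IUPAC-aware over the full primer length,
with 0 mismatches allowed by default (configurable); unmatched reads are
flagged and left untrimmed. Identity is the number of matched bases in the
optimal global alignment (match 1, mismatch and gap 0 — i.e. the longest
common subsequence) divided by the shorter sequence length; this denominator
follows the CD-HIT convention. Greedy clustering processes reads
longest-first (ties keep input order) and joins the first cluster whose
*representative* matches at ≥ 97 %; on ≤ 30-sequence inputs the resulting
clusters provably refine the connected components of the brute-force
identity graph, which the tests assert. Reading frames are forward-strand
only (the forward primer fixes orientation): among frames without a
premature stop codon, the translation most similar to the bundled reference
profile wins, ties to the lowest frame. Consensus proteins are per-column
majorities over the equal-length member translations, column ties resolved
to the representative's residue.

## Community statistics

Decay classes use the exact 1-D k-means optimum: in one dimension the
optimal clusters are contiguous intervals of the sorted values, so dynamic
programming over interval partitions finds the global minimum
deterministically — equivalent in objective to k-means with unlimited
restarts, without seed sensitivity. Classes are numbered 1–4 by descending
remaining-mass center.

perMANOVA uses the Gower-centered inner-product matrix G = J(−D²/2)J; the
sum of squares explained by a nested design is tr(HG). Terms enter
sequentially (Type I) in the order: tree species, decay class, management,
and their interactions — decay class as a centered numeric single-df
covariate, factors treatment-coded, interaction columns as products.
Permutations shuffle rows freely (no strata) and p = (count of permuted
F ≥ observed + 1)/(n_perm + 1), so 999 permutations give a p floor of
0.001. The implementation is cross-checked in the tests against two
independent oracles: scikit-bio's `permanova` (single factor) and vegan's
`adonis2(..., by = "terms")` (multi-term sequential SS), both of which it
matches to numerical precision.

The multivariate regression tree greedily splits nodes to minimise the
summed within-child sum of squared Euclidean distances; ordered predictors
(decay class) use threshold splits, categorical predictors all level
bipartitions. Stop rules: node size < 5, depth 4, or best improvement
< 1 % of the root SS (no cross-validated pruning — fixed rules keep the
tree deterministic). The PCA stage decomposes the unweighted covariance of
the MRT group means and projects samples onto those axes; the per-axis
"intersect correlation" is defined here as the Pearson correlation between
sample scores and their group-mean scores (the source analysis names but
does not define it), and axes above 0.8 are flagged.

Richness models regress sporocarp richness on tree species, log N and log C
per density unit, decay class and nifH richness (each one df; log of a
non-positive value is an error), report the sequential ANOVA of the full
model, and then backward-eliminate the largest-p predictor until all
retained p < 0.05.

## Null models

The C-score, checkerboard pair count and summed checkerboard units are
linked by the identity ΣCU = units and mean CU = C-score, asserted as an
internal-consistency property. The fixed–fixed sampler attempts sequential
swaps: draw a random 2×2 submatrix, flip it iff it is a checkerboard. The
proposal is symmetric, so the chain's stationary distribution is uniform
over the margin-preserving state space (verified by chi-square against full
enumeration on a 4×4 matrix). Defaults: burn-in 10× and spacing 5× the
number of occupied cells, 100 sampled matrices; the swap acceptance rate is
logged to expose degenerate (e.g. nested) matrices, which additionally
raise a warning. Because the "checkerboard index" could mean either the
never-co-occur pair count or the summed units, both are computed; the pair
count is the default. Pairwise Z uses the population-sd of the 100 null CU
samples; a zero null sd yields Z = 0 when the observed value equals the
null mean and is flagged indeterminate otherwise. Matrix-level tests use
the full unfiltered species set, pairwise tests the ≥ 3-occurrence subset.

Calibration runs use the exchangeable configuration (`species_effect = 0`,
no planted pairs), where the fixed–fixed null is exact for the generator
(see above); under it the |Z| > 1.96 flag rate and the perMANOVA rejection
rate at α = 0.05 sit within 3 binomial standard errors of 5 % across 500
replicates of a 20-log × 20-taxon study with 100-matrix ensembles — sizes
chosen to make the Monte-Carlo check sharp while the whole suite stays
fast. Recovery runs likewise use the exchangeable configuration so the
planted signal is the only structure present.

## Network

Edges are significant pairs with at least one *nifH* endpoint
(fungus–fungus associations are out of scope by design). Affiliation is
inclusive at the 75 % boundary (exactly 75 % counts as affiliated) — the
rule's strictness is not specified anywhere, so the inclusive reading is
documented and configurable. The hub rule is strict (> 10). Edge display
widths map the two-sided empirical pair p linearly and decreasingly from
0.049 (width 1) to 0.0017 (width 5), clipped outside that range. Mean
degree 2E/N is computed on the filtered simple graph.

## Problem sizes and determinism

Default analysis sizes are the study's own (45 logs, 999 permutations,
100 null matrices). Tests and the acceptance script run reduced designs
(12–24 logs, 12–20 taxa, 199 permutations) where the quantity being checked
does not depend on scale; the calibration experiment uses 500 replicates at
20×20. One global seed is fanned out to per-stage substreams via
`SeedSequence`, and rerunning any configuration reproduces byte-identical
numeric outputs.

## Limitations

The generator omits chimeras, sequencing error, indels, spatial plot
structure and phylogenetic signal; passing recovery tests therefore shows
the statistical machinery is correct, not that real amplicon noise is
handled. Greedy clustering is representative-based and order-dependent,
as in CD-HIT; identity is global (LCS-based), which can differ from local
or banded identities on real, indel-containing data. Published headline
values from any particular field dataset (observed C-scores, ANOVA tables,
figure R² values) depend on the raw occurrence matrices and are not
reproducible from synthetic data; the package instead reproduces every
structural quantity (degrees of freedom, p floors, filter counts, rule
boundaries) and validates the statistics against brute-force oracles.
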