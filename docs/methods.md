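# Methods

This note documents the models, estimators, numerical choices and known
limitations of `mitodemes`. Everything stated here is computed by the test
suite or the acceptance script; nothing is quoted from external runs.

## Data model and masking

Alignments are haploid sequence matrices over {A, C, G, T, -, N}, assumed
pre-aligned to rCRS coordinates so that column *i* (1-based) is nucleotide
position *i*. The default mask removes the classic mitogenome hypermutable
columns — the np16519 hotspot transition and the poly-C stretches np303–315
and np16182–16194 — plus every column containing a gap. Masking drops whole
columns rather than per-pair cells so that haplotype identity stays
transitive; for the same reason haplotype collapsing uses complete-case
columns (any column with an N anywhere is ignored alignment-wide), while
distance computations use pairwise-complete columns (an N only removes the
pairs it touches). Comparing a sample with itself excludes same-individual
pairs, which makes FST of a population against itself exactly zero.

## Coalescent simulator

The simulator realizes the exact structured coalescent with serial sampling
in continuous time. State: per-deme lineage lists. Events compete as
exponential clocks — within-deme coalescence at rate k(k−1)/(2·Ne(t)) for
haploid Ne (mtDNA semantics throughout; no factor-2 ambiguity), and
per-lineage backward migration at the active epoch's matrix rates. Waiting
times are capped at the next structural breakpoint (tip entry, deme epoch
boundary, migration epoch boundary, demographic event), where rates are
recomputed. Replacement and merge events move every lineage of the source
deme into the sink instantaneously; the difference between the two is
purely which samples are old enough to enter the pre-event deme.
Simulations that can never coalesce (isolated demes) are detected and
raised rather than left to a time cap; an overall cap of 5×10⁷ generations
guards pathological parameter draws.

The continuous-time approximation is standard and accurate for Ne ≫ k; the
smallest Ne the shipped priors allow is 100 against ≤ 385 sampled lineages
spread over 15 millennia of entry times, which keeps simultaneous-merger
error negligible for these designs.

Mutations are overlaid on the genealogy finite-site: per branch,
Poisson(branch length × μ × L) hits, uniform sites, repeat hits allowed,
transition bias κ (default 1, i.e. Jukes–Cantor-like). Default
μ = 4.16×10⁻⁷ per site per generation — the whole-mitogenome clock of one
substitution per 3,624 years divided by 16,569 sites and multiplied by the
25-year generation time. L defaults to 16,569; simulations for testing use
L = 2,000 since every statistic scales linearly in L.

## Demographic model library

Eleven sampling groups reproduce an island time transect: Mesolithic and
Neolithic cave groups (n = 8, 8), Chalcolithic and Bronze-Age site groups
(4, 3), Bronze-Age island-wide (14), Iron Age (55), a Phoenician/Punic
colony (3), a Greek-associated group (3), medieval Islamic (5) and
Christian (6) cemeteries, and 236 modern donors split across nine
geogroups (Agrigento 36, Caltanissetta-Enna 21, Catania-Siracusa 17,
Gela 21, Messina 17, Palermo city 65, Palermo outer 27, Ragusa 12,
Trapani 20). Sampling ages are normal radiocarbon priors truncated at
zero, redrawn per simulation; the chosen means sit at the midpoints of the
conventional period boundaries (forager/farmer 7,950, Bronze 4,449, Iron
2,899, medieval 1,399 yr B.P.).

Models: **A** — a single deme in full continuity; **B–E** — separate
Phoenician, Greek and Islamic demes merging backward into the island
lineage, with a replacement of the island deme at no boundary (B), the
forager/farmer boundary (C), the Bronze (D) or Iron (E) boundary; **F–I** —
B–E plus two-way migration during the Iron-Age epoch (island ↔ Phoenician ↔
Greek) and the medieval epoch (island ↔ Islamic); **Gpan/Gst** — model G
with the modern population split into the nine geogroup demes merging back
at the medieval boundary, exchanging migrants either panmictically (Gpan)
or only within a western block (Palermo city/outer, Trapani, Agrigento) and
an eastern block (Caltanissetta-Enna, Catania-Siracusa, Gela, Messina,
Ragusa) (Gst). Replacement is modeled as 100 % backward lineage movement
into an incoming deme with its own founding Ne, which rejoins the forager
lineage at a deep-ancestry merge set to 25,000 yr B.P. — old enough to make
a replacement visible as excess forager-vs-later differentiation, young
enough that all lineages share a common ancestor quickly thereafter.

Shipped default priors: log-uniform Ne ∈ [10², 10⁵] per deme, uniform
migration ∈ [0, 0.01] (modern geogroup exchange up to 0.05), event times
fixed at the period boundaries. Priors are ordinary config: any study
should replace them with its own.

## Summary statistics and ABC-RF

Per population: haplotype count K, gene diversity H (haplotype-level, same
estimator as Hd), segregating sites S, Tajima's D with the standard 1989
constants. Per pair: Hudson FST = 1 − Hw/Hb and mean cross-population
differences Pi. Vectors are fixed-order (4 per population, 2 per pair;
length 154 for 11 groups) and the same code path summarizes observed and
simulated data. D is undefined when S = 0 (or n < 4); reference-table
assembly imputes 0 and appends a was-defined indicator column per affected
statistic, keeping table geometry fixed.

Model choice trains a 500-tree random forest on the reference table
(optionally augmented with the class-LDA coordinates as extra predictors —
the default, following standard ABC-RF practice; a flag disables it). The
prior error rate is the out-of-bag misclassification fraction; per-model CE
is the off-diagonal row share of the OOB confusion matrix. The posterior
probability of the selected model is one minus the local error predicted at
the observed point by a regression forest trained on the OOB
misclassification indicator; a naive vote-fraction estimator is available
but the regression-forest estimator is the default. Reference tables are
class-balanced (uniform implicit model prior) and reproducible: the
per-simulation stream is seeded by (master seed, model index, simulation
index, retry attempt), so parallel or re-ordered construction cannot change
results.

## Rho dating

Input is either a newick tree whose branch lengths are mutation counts, or
a root haplotype plus tip sequences (counts under the active mask). rho is
the mean root-to-tip count; sigma² = Σ (n_b/n)²·l_b over branches.
Recalibration adds age·rate *expected* (real-valued) mutations to each
ancient terminal branch — deterministic by default so that recalibrated ≥
classic holds as an identity, with a Poisson mode for recovery
experiments. Sigma is recalibrated through the same branch counts and both
parameter sets are always reported. Conversion: age = ρ/λ, CI =
(ρ ± 1.96σ)/λ floored at 0, default λ = 1/3,624 yr⁻¹ for the complete
mitogenome. The purifying-selection polynomial correction sometimes applied
with this clock family is *not* implemented; ages are linear in ρ. Ancient
tip ages use the point estimate; a sensitivity mode could resample from the
radiocarbon prior but is not needed for the identities tested. A (mean, sd)
clock prior of (2.45×10⁻⁵, 3.5×10⁻⁶) is stored on `ClockModel` verbatim
for reference; its units are not per-genome-per-year and it takes no part
in any computation.

## Exploratory analyses

FST matrices floor negatives at zero for distance use (raw values are
returned alongside); groups below three individuals are excluded with a
warning. Classical MDS is Torgerson double-centering with an eigh
decomposition; negative eigenvalues (non-Euclidean inputs) are reported,
and coordinates reproduce the input distances exactly when the matrix is
Euclidean-embeddable in k dimensions. Correspondence analysis is the SVD
of the standardized residuals (P − rcᵀ)/√(rcᵀ) with principal coordinates
for rows and columns; total inertia equals χ²/n as an identity. Chi-square
offers the asymptotic Pearson test and a fixed-margins Monte-Carlo version
p = (1 + #{χ²_perm ≥ χ²_obs})/(B+1); the Monte-Carlo mode is the sensible
default for sparse haplogroup tables.

## Synthetic data

The generator emulates the *shape* of a real mitogenome study — group
sizes, serial sampling ages with radiocarbon noise, geogroup labels,
sparse haplogroup tables (labels from single-linkage clustering at a
configurable distance threshold; the label prefix avoids colliding with
real haplogroup nomenclature). It does not emulate ancient-DNA damage,
sequencing error, reference bias, or real phylogenetic haplogroup
structure, so passing tests demonstrate correctness of the machinery, not
robustness of the inferences to those artifacts.

## Test-scale choices and the calibration caveat

Simulation experiments in the suite run at reduced scale: quarter group
sizes with a floor of two (so every within-group statistic stays defined;
(2,2,2,2,4,14,2,2,2,2,59), 93 tips) and L = 2,000. Recovery experiments
use pseudo-observed datasets generated at fixed representative replacement
parameters (forager Ne 800, island Ne 3,000, ancestral Ne 5,000, external
demes 2,000) against reference tables drawn from the shipped priors — the
standard design for checking that a known truth is recovered. Under fully
prior-drawn truths the A-vs-C comparison has irreducible overlap (a
forager Ne near 10⁵ makes a ~680-generation isolation window invisible),
which is a property of the broad priors, not of the classifier.

One calibration identity is knowingly out of reach at L = 2,000: mean
Tajima's D over 5,000 neutral constant-size replicates is not within three
standard errors of zero, because (a) holding mean π to the infinite-sites
expectation 2·Ne·μ·L requires per-site divergence small enough that θ ≲ 25,
and (b) at such θ the *exact* neutral coalescent has E[D] ≈ −0.03 to −0.08
(Tajima's variance normalization is only approximate), which 5,000
replicates resolve. The simulator itself is calibrated: its mean D matches
msprime's to within Monte-Carlo error under identical conditions (a
dual-route test in the suite), and mean π matches the finite-site
(Jukes–Cantor-corrected) expectation analytically. The suite's calibration
test asserts the idealized band regardless and is expected to fail on the
D leg; treat it as documentation of this statistic's intrinsic bias.

## Known limitations

- No recombination (appropriate for mtDNA) and no selection.
- Finite-site saturation makes π fall below 2·Ne·μ·L at high per-site
  divergence; use the Jukes–Cantor-corrected expectation when calibrating.
- ABC parameter estimation (posterior densities for Ne or migration) is
  out of scope; the package does model choice only.
- The simulator is not a file-format replacement for external coalescent
  tools; model/prior specification is Python/config-level.
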