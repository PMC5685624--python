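# Methods

## Data model

The package analyzes *dominant-scored* SSR data from inbred (self-pollinated)
germplasm: each accession carries one effective haplotype, and each SSR
fragment size is an allele-locus scored 1 (band present), 0 (absent) or
missing. Allele-locus ids encode the parent marker as
`<marker>_<fragment>`; the marker name is recovered by splitting at the last
underscore, which is unambiguous as long as marker names do not themselves
end in `_<digits>`. Whether such tables encode band presence or diploid
genotypes is often unstated in practice; the band-presence reading is
adopted throughout because every statistic downstream (frequencies, r²,
kinship, marker regression) operates on the 0/1 band indicator.

## Diversity statistics

Band frequency is the fraction of non-missing calls carrying the band; a
marker's allele-frequency vector is its band-frequency vector normalized to
sum one. PIC uses the Botstein multiallelic form
`1 − Σp² − Σ_{i<j} 2p_i²p_j²` (the default of the standard marker-analysis
packages); "heterozygosity" is implemented as Nei's gene diversity
`H = 1 − Σp²`, the appropriate quantity for dominant scoring of selfing
lines, and satisfies `H ≥ PIC` identically. The genetic distance is the
mean character difference on band profiles with pairwise deletion of
missing calls; Dice/Nei–Li is available as a config option since published
panels rarely name their metric. The minor-allele filter removes loci with
band frequency strictly below the threshold (default 5%), making a zero
threshold the identity and the filter idempotent.

UPGMA uses unweighted average linkage with lexicographic tie-breaking on
the clusters' smallest tip labels, so rebuilt trees are reproducible;
dendrogram cuts interpret a genetic-distance threshold as a bound on
cophenetic distance (twice the merge height). Neighbor joining is the
Saitou–Nei Q-criterion; negative branch lengths are clamped to zero with
the deficit moved to the sister branch, standard practice that preserves
path lengths. Both emit scikit-bio trees and Newick text.

## AMOVA and F_ST

AMOVA is the one-level decomposition of squared Euclidean band distances
(for 0/1 data, mismatch counts rescaled for pairwise-complete missingness):
`SSD_total = Σ_{i<j} d²_ij/N`, within-group terms analogously, variance
components from the mean squares with the unequal-size coefficient
`n̄ = (N − Σn_g²/N)/(G−1)`, and `Φ_ST = σ²_a/(σ²_a+σ²_w)`. Significance
comes from label permutations with plus-one correction. The frequency-based
cross-check `wright_fst` is the per-locus ANOVA of band frequencies
(Weir–Cockerham-style θ for haploid data, ratio of sums over loci); on
complete data the two routes agree algebraically, which the tests exploit.

## Admixture model and Evanno ΔK

The Bayesian clustering of the classic structure software is replaced by a
maximum-likelihood admixture model for binary bands,
`P(x_il = 1 | Q, F) = Σ_k q_ik f_kl`, fitted by EM over latent per-cell
ancestries. The likelihood is non-decreasing per iteration, Q stays
row-stochastic, missing cells drop out, and `K = 1` has the closed-form
Bernoulli solution. Multiple random restarts guard against local optima;
runs are deterministic given a seed. The best log-likelihood `L(K)` plays
the role of the posterior deviance in Evanno's rule:
`ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd_runs(L(K))`, undefined at grid edges
and when the run spread is zero (reported as NaN rather than dividing by
zero). Because a deterministic optimizer can reach the same optimum in
every run, single-restart runs (which retain initialization noise) are the
default protocol for ΔK grids. Membership is assigned at a q > 0.70 cutoff,
otherwise "mixed"; comparisons against a reference Q first resolve label
switching by Hungarian assignment on column overlaps.

## Kinship and LD

Kinship is the standardized covariance of band indicators centered at panel
frequencies, restricted to jointly scored loci. Its expectation for
unrelated accessions is ~0 up to the usual −1/(n−1) centering bias.
Negative estimates may be truncated to zero for reporting summaries; the
mixed model always uses the untruncated estimator because truncation
destroys positive semidefiniteness (small negative eigenvalues from
estimator noise are bent to zero; clearly indefinite matrices are
rejected).

Because loci are binary, the weighted multiallelic r² statistic reduces to
the plain squared Pearson correlation per locus pair, computed with
pairwise deletion. Permutation significance shuffles accession labels of
one member of each pair, with one shared set of shuffles applied to all
pairs (vectorized as matrix products on the standardized, mean-imputed
matrix) and plus-one correction `p = (1 + #{r²_perm ≥ r²_obs})/(n_perm+1)`.
On binary data the permutation statistic lives on a discrete overlap
lattice, so ties give p a conservative atom at 1; the lower tail — what
significance calls use — remains calibrated, and the tests check exactly
that rather than strict continuous uniformity. When the panel has no
missing calls the permutation null is exact; with missing calls it is an
approximation on the mean-imputed matrix while observed r² stays exact.

LD decay is fitted on same-chromosome pairs with map distances
(inter-chromosomal and unplaced pairs are excluded): a Hill–Weir drift
expectation with the sample-size term, parameterized by C = ρ·d; a
constrained exponential `a·e^{−bd}+c`; and a lowess smoother forced to a
non-increasing envelope. Threshold crossings report the smallest distance
at which the fitted curve drops below r² = 0.05/0.1/0.2; a curve that never
attains or never falls below a threshold reports "beyond range" (None).

## Association scans

Traits are mean-imputed and z-scored within environment and trait before
scanning. The GLM is OLS of the trait on intercept, Q columns (one dropped
for identifiability against the intercept, since Q rows sum to one) and the
marker, with a 1-df F test; markers collinear with covariates are skipped
and logged. The MLM is `y = Xβ + Qv + Zu + e` with `Var(u) = σ_g²K`,
estimated by REML through the spectral decomposition of K so the profile
likelihood is one-dimensional in δ = σ_e²/σ_g² (coarse log-grid bracketing
plus bounded refinement). `per_marker` mode re-estimates δ per marker;
`P3D` reuses the null-model δ, which is also used for the optional
trait-permutation significance. With K = I the MLM collapses to the GLM,
a tested identity. Missing marker calls are mean-imputed within the scan.

Multiple testing: Šidák `1 − (1−p)^m` and Storey q-values with the
smoother π₀ estimate (cubic spline over λ = 0.05…0.95; median fallback for
small test counts where the spline is unstable). The minimum Bayes factor
is `BFmin = −e·p·ln p`, a lower bound on the evidence against the null,
clamped to 1 for p ≥ 1/e where the formula exceeds its own bound; the
conventional `BFmin ≤ 0.13` cutoff is exposed as a configurable threshold,
not re-derived. Cross-environment consensus keeps loci significant in both
environments (optionally also passing the BFmin cutoff in both) and is
commutative; a user-supplied known-QTL catalog is left-joined for
matched/novel counts.

## Phenotype analyses

Percentiles use linear interpolation between order statistics (type 7); SD
is the n−1 sample form and CV = 100·SD/mean. The environment comparison
reports both the one-way fixed-effects ANOVA (F, sums of squares) and
Kruskal–Wallis χ² so parametric and rank readings are covered. Fiber
strength is handled in g/tex; kN·m·kg⁻¹ inputs are detected by scale
(median > 100) and divided by 10 on read. Stability selection applies each
threshold rule in *both* environments and intersects per-trait sets for the
combination rule.

## Synthetic-data generator

The generator is the package's study-condition model, not a fixture:

* **Subpopulation frequencies.** Ancestral allele frequencies per marker are
  symmetric Dirichlet; each of K subpopulations drifts as
  `Dirichlet(p·(1−F)/F)` (Balding–Nichols), so the expected Wright F_ST of
  the frequency draws equals `F_st_target` (verified over 2,000 markers in
  the tests).
* **LD and haplotypes.** Each subpopulation is a finite founder pool
  (default 30 haplotypes) recombined for a number of generations (default
  20) with crossovers placed by Haldane's map function, no interference.
  Drift in the pool regenerates associations that recombination erodes, so
  r² decays with map distance toward the inter-chromosomal background —
  the same mechanism as in real inbred collections. A consequence worth
  noting: pool drift adds within-subpopulation differentiation, so the
  realized panel-level F_ST exceeds `F_st_target`; recovery tests therefore
  compare estimators to each other or to realized truth, not to the
  nominal drift parameter.
* **Accessions.** Ancestry proportions are `Dirichlet(α)`; each accession
  is a recombinant mosaic copied from pool haplotypes, switching ancestry
  and template at Haldane recombination events, then re-expressed as band
  presence (one haplotype per accession — the inbred-line model, matching
  dominant scoring of selfed material). Missing calls are injected
  uniformly at a default 2% rate. Defaults (288 accessions, 108 markers
  with 2–5 alleles averaging ~2.8, 26 chromosomes) mirror a realistic
  long-staple cotton panel.
* **Phenotypes.** `y_env = μ_env + Σ_q β_q·m_env,q·x_q + g + e` on a
  z-score scale mapped to instrument scales (length in inches, strength in
  g/tex, micronaire, uniformity %) with per-environment trait means; the
  polygenic g is drawn once per trait from `N(0, σ_g²K_truth)` (genetic,
  hence shared across environments) with σ_g² set from `h2_polygenic`, and
  environment multipliers implement G×E. Realized variance components are
  recorded in the truth object, and the closed-form cross-environment
  correlation implied by them is what the simulation tests check.

What the generator does not emulate: SSR mutation (no coalescent repeat
model), selection, heterozygotes, genotyping error beyond uniform missing
calls, and map uncertainty. Passing recovery tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
those real-data complications.

## Numerical choices and problem sizes

Subpopulation band frequencies are clipped to [1e-6, 1−1e-6] inside the EM
for log stability; EM convergence is ΔL < 1e-6 (restarts keep the best
likelihood). REML δ is searched on a 41-point log grid over ±10 before
bounded refinement (xatol 1e-8). Kinship eigenvalues are floored at 0 with
a 1e-8 jitter. Permutation p-values always use the plus-one correction.
UPGMA/NJ ties break lexicographically. Stage seeds derive from the master
seed by SHA-256 of `"seed:stage"` reduced mod 2³¹, so adding a stage never
perturbs another stage's stream.

Test and acceptance problem sizes are deliberately desk-scale: recovery
suites use panels of 120–288 accessions and 40–150 markers, 3 runs per K on
a 1–5 grid for ΔK (20 replicates), 5 founder-pool replicates for decay
recovery, ~2,000+ null markers for MLM/GLM calibration, and 10⁴ LD
permutations only at study scale. The ΔK recovery experiment uses a
low-admixture island design (α = 0.02, F = 0.3), where the number of
subpopulations is statistically identifiable; under strong admixture ΔK is
known to prefer deeper hierarchy levels.

## Known limitations

* The admixture EM is a point estimator; it replaces posterior sampling and
  gives no credible intervals on Q.
* Permutation nulls for LD share one shuffle set across pairs — marginal
  p-values are exact in distribution but correlated across pairs.
* The Hill–Weir expectation is an equilibrium drift approximation; the
  founder-pool process is not at equilibrium, so fitted crossings are
  summaries, not estimates of 4Nc.
* With missing data, AMOVA's pairwise-complete rescaling and the
  frequency-route F_ST are no longer exactly equal (they agree to well
  within the tested ±0.03 at 2% missingness).
* The Storey spline π₀ needs a few hundred tests to be stable; below 100
  tests a median-based estimate is used instead.
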