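# Methods

`phylosym` implements the statistical machinery needed to decouple the
effects of host evolutionary history and host diet on vertebrate gut
microbiome diversity, together with a synthetic-data generator that
produces datasets with the statistical structure these analyses assume.
This note documents the models, the parameters that matter, the numerical
choices, and what the synthetic validation does and does not show.

## Data model and preprocessing

The community matrix is a samples × OTUs table of non-negative integer
counts (OTUs are exact 16S sequence variants). Because raw library sizes
vary over orders of magnitude, counts are rarefied to a fixed depth
(default 5000 reads) by multivariate-hypergeometric sampling without
replacement; samples below the depth are dropped. Rarefaction without
replacement is exact subsampling of the observed reads — it never inflates
a zero — and is idempotent at the target depth.

OTU-specific tests (LIPA, per-OTU PGLS, co-occurrence) are restricted to
OTUs present in strictly more than 5% of samples; aggregate diversity
metrics use the full rarefied table. The strict inequality matters at the
boundary: an OTU in exactly 5% of samples is excluded.

The host phylogeny is a dated species-level tree. Sample-level analyses
need one tip per sample, so each species tip with k samples becomes a
polytomy of k sample tips on branches of length ε (default 10⁻⁶ of the
median root-to-tip depth — negligible against a multi-hundred-Myr time
scale but nonzero, so the tree stays bifurcating-with-polytomies and
distance matrices stay valid). Cross-species patristic distances are
preserved up to 2ε.

## Diversity

Alpha diversity: Shannon entropy (natural log) and Faith's phylogenetic
diversity, root-inclusive (the branch path from the root to every present
tip is counted; a single-tip community has PD equal to its root-to-tip
distance). Beta diversity: unweighted UniFrac and normalized weighted
UniFrac, computed with scikit-bio.

Principal coordinates analysis double-centers −D∘D/2 and eigendecomposes.
UniFrac matrices are usually non-Euclidean, so the Cailliez correction is
available: the smallest constant c added to all off-diagonal
dissimilarities making the matrix Euclidean, found as the largest real
eigenvalue of the standard 2n × 2n companion matrix. "Negative" eigenvalue
means below −10⁻¹⁰; axes with eigenvalue ≤ 10⁻¹⁰ are dropped from
coordinates. On an already-Euclidean input c = 0 and all pairwise
distances are reproduced to 10⁻⁹.

Beta-dispersion (within-group community variance) follows the standard
multivariate-dispersion convention for non-Euclidean dissimilarities:
distances to the group centroid are computed in the full uncorrected PCoA
space, with squared contributions from negative-eigenvalue ("imaginary")
axes subtracted from the real-axis contributions and clamped at zero.
Singleton groups get dispersion 0 with a warning.

## MRM — multiple regression on distance matrices

Response and predictor matrices are unfolded to strict lower-triangle
vectors, rank-transformed (average ties; all vectors, response and
predictors), and fit by OLS. Significance is Mantel-style: the response
matrix's row/column labels are permuted jointly, the model refit, and

    p(coef)  = (#{|b_perm| ≥ |b_obs|} + 1) / (n_perm + 1)
    p(model) = (#{R²_perm ≥ R²_obs} + 1) / (n_perm + 1)

so p is never zero and the test is exact up to Monte-Carlo error. The
coefficient test is two-sided. Predictors are never permuted. The
implementation exploits the fact that ranking commutes with label
permutation of the response (the off-diagonal multiset is invariant), so
the ranked response matrix is built once and each permutation is a fancy
index plus one matrix–vector product.

The standard predictor set: host phylogeny (patristic distance on the
grafted tree), detailed diet (Gower over binary diet components), habitat
(Gower), geography (haversine on a 6371-km sphere), technical covariates
(Gower over sample type and captivity status). Gower treats binary and
categorical variables as mismatch indicators and continuous ones as
range-normalized absolute differences, averaging over variables
non-missing in both rows; zero-range continuous variables are excluded
with a warning, constant categorical variables are retained (zero
contribution).

## PGLS and local phylogenetic signal

PGLS assumes residual covariance proportional to shared branch length
under Brownian motion: C[i,j] = depth of the MRCA of tips i and j. The fit
whitens by the Cholesky factor of C and solves OLS on the whitened scale;
R² and the model F-test (all non-intercept terms vs intercept) are defined
there. On a star tree C ∝ I and PGLS reduces to OLS exactly. Screens over
response families (alpha metrics; the first k = 5 PCoA eigenvectors;
per-OTU presence) are Benjamini–Hochberg adjusted within each family.

To test host-history effects on individual OTUs while controlling for
diet, per-species OTU prevalence (fraction of the species' samples
containing the OTU) is residualized by a binomial GLM on diet (deviance
residuals; the species' sample count enters as a variance weight; on
perfect separation the fit falls back to response residuals and is
flagged). The residuals feed LIPA — local Moran's I with phylogenetic
proximity weights:

    W_ij = (1 / d_ij) / Σ_k (1 / d_ik),  W_ii = 0
    I_i  = (z_i / m2) · Σ_j W_ij z_j,    m2 = Σ z² / n

tested one-sided (positive local autocorrelation = clustering) by
permuting trait values across tips, 9999 permutations by default. The mean
of the local values equals the global Moran's I under the same weights;
this identity is exploited for the OTU-level call: `LipaResult.otu_p` is
the permutation p of the global (mean-local) statistic, which accumulates
diffuse signal across tips and controls the per-OTU error rate exactly.
The per-cell values and the raw p < 0.05 mask localize significant signal
to particular host tips. Zero-variance residual columns are excluded.

## Cophylogeny: PACo and Parafit

Both tests start from Cailliez-corrected principal coordinates of the host
and microbe patristic distance matrices and the hosts × OTUs binary
association matrix (OTU observed in any sample of the species).

PACo builds paired coordinate rows, one per association link, and
least-squares-superimposes the symbiont configuration onto the host
configuration (translation, optimal rotation/reflection via SVD, optimal
scaling). The global statistic m² is the residual sum of squares; each
link's squared residual is its contribution (they sum to m² exactly).
Small m² = congruence, so p counts null m² values ≤ observed. The null is
quasiswap: binary matrices with exactly the observed row and column sums,
generated by checkerboard 2×2 swaps — a symmetric null that assumes
neither partner tracks the other. Chain settings: burn-in 10×(number of
links) attempted swaps from the observed matrix, thinning 2×(links)
between draws. Sequential draws are therefore autocorrelated (fine for a
permutation null; for distribution-level checks use independent chains).

Parafit's global statistic is the sum of squared entries of C'A'B (B, C
the host and symbiont coordinates); the null permutes each symbiont's
association column across hosts independently. The per-link statistic is
the global statistic minus the statistic with that link removed, computed
in O(1) per link from the rank-one update, with the link tracked through
each permutation for its own p-value.

Per-link Procrustes residuals are compared across host class and diet by
two-factor ANOVA (type-II sums of squares).

## Community assembly

MPD (mean pairwise patristic distance among present OTUs) and MNTD (mean
nearest-taxon distance) are compared per sample to a taxa-label-shuffle
null (OTU labels permuted on the distance matrix, richness preserved), 999
permutations by default. SES = (obs − null mean)/null sd; negative =
clustering, positive = evenness; p is the two-sided null-rank quantile.
Samples with fewer than two present OTUs are skipped; zero-variance nulls
(e.g. the full pool present) are flagged. SES is invariant to global
branch-length scaling.

Pairwise co-occurrence is the analytic hypergeometric model: with OTUs in
n₁ and n₂ of N samples, the shared-sample count is hypergeometric, giving
exact lower/upper tail probabilities with no permutation; pairs with
expected co-occurrence n₁n₂/N < 1 are excluded. Significant pairs (either
tail below α) form a network; sub-networks are connected components of the
positive-edge graph refined by walktrap community detection (random walks
of length 4); node centrality is unnormalized shortest-path betweenness;
sub-network density is within-edges / possible edges. Sub-network
prevalence per host species (fraction of the species' samples containing
any member OTU) is compared across diets or host orders by Kruskal–Wallis
plus pairwise rank-sum tests with BH adjustment.

IndVal: specificity A (group mean abundance / sum of group means) ×
fidelity B (fraction of the group's samples where present), reported for
the argmax group, tested by permuting group labels, BH-adjusted across
taxa. A sums to 1 across groups for any taxon with nonzero abundance.

## Intra-species sensitivity framework

Species contribute 1–11 samples each while the host tree has no
within-species resolution, so every hypothesis-level analysis is repeated
on 100 random subsets, each holding exactly one uniformly chosen sample
per species (or per family). Within a subset, the test's returned p-value
family (e.g. the five MRM predictors of one model) is BH-adjusted; a
hypothesis is significant overall only if ≥95% of subsets are
individually significant at α = 0.05. Failed subsets count in the
denominator. The 95% rule is sharp: 95/100 passes, 94/100 does not. The
flag is monotone in α and antitone in the fraction threshold.

## Synthetic data generator

The generator emulates the statistical structure of a broad multi-host
gut survey; its defaults are the study conditions:

* **Host tree**: pure-birth (Yule), rescaled to a fixed depth of 400 Myr
  (vertebrate-class scale); nested class/order/family/genus labels are cut
  from the tree at fixed depth fractions (0.15/0.45/0.7/0.85).
* **Sampling design**: 128 species; samples per species = 1 + truncated
  geometric with mean ≈ 0.7 extra (overall mean ≈ 1.7, maximum 11).
* **Diet**: a symmetric 3-state Markov process (herbivore / omnivore /
  carnivore) down the tree with ≈1.5 expected state changes per
  root-to-tip lineage — phylogenetically conserved yet convergent, which
  is what lets downstream analyses separate diet from phylogeny. Binary
  detailed-diet components are drawn conditional on the general diet with
  5% per-sample flip noise; habitat fields are clade-correlated;
  coordinates are clade-clustered Gaussians.
* **OTU classes** (with ground-truth labels): *heritable* — Brownian
  liability on the host tree, presence probability logistic(intercept +
  slope·liability) with defaults −2 and 2; *diet-guild* — presence
  logit-shifted (default +3) by one binary diet component; *cospeciating*
  — confined to one host clade (4–10 tips), within-clade presence 0.8
  (0.95 in the anchored species), zero outside, with the microbe tree
  containing a scaled copy of the host clade topology for each group;
  *consortium* — blocks sharing a latent per-sample factor
  (logistic(−1.5 + 2.5u), u ~ N(0,1)), producing positive co-occurrence
  blocks; *noise* — i.i.d. with per-OTU baseline probability log-uniform
  on [0.001, 0.03]. Default class counts (15/10/30/16/2000) put ≈97–98%
  of OTUs in ≤5% of samples, reproducing the extreme sparsity of such
  surveys.
* **Counts**: present OTUs receive one guaranteed read plus a
  lognormal-weight multinomial allocation to the fixed depth.

Everything is a pure function of the config (bit-identical across
re-runs); all sub-seeds derive from the master seed.

### Validation conditions (what the tests show)

Correctness is established by exact oracles (hand-evaluated formulas,
exhaustive permutation enumeration, combinatorial enumeration,
conservation laws), null calibration (each permutation wrapper rejects at
≈5% under its null over ≥200 simulations), and recovery of planted
structure at desk scale. The recovery experiments use 40 host species and
deliberately strong, dominant planted fractions, stated here once:

* MRM diet: 30 guild OTUs at log-odds 4 against 25 prevalent noise OTUs.
* MRM phylogeny: 40 heritable OTUs (slope 3, intercept −1) against 20
  noise OTUs.
* LIPA: 12 heritable OTUs (slope 3, intercept 0 — prevalence centered at
  1/2, the most informative regime for a presence trait) with 11 samples
  per species and 9999 permutations, against 48 prevalent noise OTUs.
* PACo/Parafit: 18 cospeciating vs 42 noise OTUs (≈30% cospeciating among
  planted+noise); null calibration at 0%.
* SES: 24 cospeciating OTUs — samples of clade-hosting species show
  strongly negative SES.
* Networks: two consortium blocks of 8 recovered as distinct
  sub-networks.

Recovery datasets raise the diet switch rate to ≈3 changes per lineage so
diet decouples from phylogeny — matching the premise that hosts with
similar diets occur across distant clades. Passing these tests shows the
estimators detect their target signals at realistic-but-favorable effect
sizes and stay calibrated under the null. It does **not** show the
generator reproduces real gut communities: there is no compositionality
beyond multinomial sampling, no overdispersion across biological
replicates, no taxonomy-correlated abundance structure, no contamination
or batch effects, and the host tree is a featureless Yule tree rather
than the highly imbalanced vertebrate timetree.

## Numerical choices and degenerate inputs

* All permutation p-values use the (+1)/(n_perm+1) estimator; p = 0 is
  impossible.
* Ties in rank transforms take average ranks.
* Cholesky failure of the Brownian covariance (duplicate tips, zero
  branch lengths) raises; rank-deficient designs raise.
* Binomial-GLM separation falls back to response residuals with a flag;
  all-present/all-absent OTUs are skipped and reported.
* SES with null sd below 10⁻¹⁰ (relative) is flagged undefined rather
  than reported as ±∞.
* Quasiswap margins are asserted conserved for every draw in tests; the
  3×3 forced-margin class reproduces the input exactly.
* Pipeline stages derive independent seeds from the master seed; report
  TSVs are written with a fixed float format so re-runs are
  byte-identical.

## Known limitations

* MRM permutes the response only; heteroscedastic predictors with strong
  autocorrelation can still distort partial coefficients (a known
  limitation of MRM generally).
* Quasiswap mixes slowly on very sparse association matrices
  (checkerboard acceptance falls with fill); for distribution-level use,
  prefer independent chains.
* PGLS assumes strict Brownian covariance; no Pagel's λ or OU
  transformations are provided.
* The LIPA proximity kernel is fixed at row-normalized 1/patristic;
  other kernels (e.g. 1/d², nearest-neighbor) would change per-tip power.
* Walktrap sub-network labels depend on the positive-edge graph only;
  negative edges are annotations.
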