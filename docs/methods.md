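# Methods note

This package implements a genotype-likelihood population-genomics pipeline
for reduced-representation (ddRAD-style) data with low and uneven coverage:
simulation, SNP filtering, model-based ancestry inference, structure
summaries, diversity estimation from the site frequency spectrum, and
landscape-genetic regression on distance matrices. All inference operates on
genotype likelihoods rather than called genotypes, which propagates
genotyping uncertainty at the shallow depths typical of ddRAD data.

## Data model

The core container holds, for N individuals at L biallelic sites, a
likelihood array `P(reads | g)` for genotypes g in {0, 1, 2} (count of the
alternate allele) plus per-cell read depths. Likelihoods are stored
max-normalised per individual-site cell; all downstream quantities depend
only on likelihood ratios. A cell with zero depth carries a flat likelihood
(1, 1, 1): no data, no information. VCF input uses phred-scaled PL fields
(`10^(-PL/10)`), with GL fields as a fallback; multiallelic records are
counted and skipped.

## Synthetic data generator

`simulate_metapopulation` draws from a Balding–Nichols island model:

- Ancestral frequencies `pi_l ~ Beta(a, b)` truncated to (0.02, 0.98),
  defaults a = b = 0.8 (U-shaped, as empirical SNP panels are).
- Population frequencies `p_kl ~ Beta(pi(1-F)/F, (1-pi)(1-F)/F)`, one
  divergence parameter F per population.
- Ancestry vectors `q_i` are unit vectors (no admixture) or Dirichlet(alpha).
- Genotypes `g ~ Binomial(2, q_i . p_l)`; depths Poisson; alternate-allele
  read counts `Binomial(depth, [eps, 1/2, 1-eps][g])` with sequencing error
  eps; likelihoods are the exact binomial read-model likelihoods.
- A configurable fraction of sites (default 0.9) is invariant, fixed for the
  reference allele, mimicking the monomorphic loci a RAD assembly retains.

Scope: the generator makes independent sites (no linkage), no inbreeding,
no allele-dropout or PCR-duplicate artefacts, and a single error rate for
all reads. It is intended for parameter-recovery and calibration tests, not
for mimicking any particular empirical dataset.

`simulate_sfs_sites` places an exact, user-chosen number of alternate
alleles on 2N chromosomes by hypergeometric sampling, so the realised
spectrum equals the requested spectrum — used to test SFS estimators under
a controlled truth. `simulate_climate_geography` produces 19 bioclim-style
variables where the temperature block is affine in elevation and the
precipitation block follows a planar spatial gradient.

## SNP filtering

Applied in order, each stage reporting telescoping site counts:

1. **Biallelic**: multiallelic records dropped at parse time.
2. **Completeness**: a site is kept iff at least `ceil(t * N)` individuals
   have nonzero depth (default t = 0.92).
3. **Minor-allele frequency**: frequencies estimated by an EM algorithm on
   genotype likelihoods under Hardy–Weinberg (maximising
   `prod_i sum_g GL_ig HWE_g(f)`; update `f' = sum_i E[g_i|f]/2N`; tolerance
   1e-8). Sites with minor-allele frequency below the threshold are removed;
   the boundary value is kept. Sites where all likelihoods are flat return
   f = 0.5 flagged uninformative.
4. **Thinning**: one site retained uniformly at random per fixed 1000-bp
   block (`block = (pos-1) // 1000`), seeded for reproducibility, to reduce
   intra-locus linkage.

## Ancestry (Gibbs admixture)

A collapsed-data Gibbs sampler for the admixture model with k source
clusters: individual ancestry proportions q (Dirichlet(1) prior) and cluster
allele frequencies p (Beta(1,1) prior). Each sweep samples genotypes from
`GL * Binomial(2, q_i . p)`, assigns each allele copy a cluster of origin,
and draws conjugate updates. No sequencing-error or inbreeding parameters
are estimated — the likelihoods already carry read-level uncertainty.
Chains are initialised from a PCA + k-means + LDA soft assignment of naive
dosages. Multiple chains are aligned by greedy matching of posterior-mean
allele frequencies and averaged.

Model choice uses DIC: `DIC = D_bar + p_D` with
`p_D = D_bar - D(theta_bar)`, where the deviance is
`D = -2 sum_il log sum_g GL_ilg HWE_g(q_i . p_l)`. The selected k minimises
DIC; ties go to the smaller k. DIC on mixture-like models is a heuristic:
p_D can be noisy with short chains, so the default settings are 40,000
sweeps, 10,000 burn-in, thinning 10, five chains.

## Structure summaries

PCA of posterior-mean dosages (centred, unscaled, via SVD; deterministic
sign convention). Population allele frequencies are mean dosages / 2. Nei's
standard distance between populations x, y:
`D = -ln( J_xy / sqrt(J_x J_y) )` with `J = mean(f^2 + (1-f)^2)` over loci;
opposite fixation at every locus gives infinite D.

## Diversity from the SFS

Per-site sample-allele-frequency (SAF) likelihoods come from the standard
dynamic program over individuals:
`Q_m(j) = sum_g GL_m(g) C(2,g) Q_{m-1}(j-g)`, normalised by the Vandermonde
factor `C(2n, j)`, with per-individual max-rescaling against underflow. The
folded spectrum is fit by EM (`phi' = mean posterior over sites`). Per-site
expected pairwise diversity uses `E[pi] = sum_j post(j) j(n-j)/C(n,2)` and
Watterson's contribution `(1 - post(0))/a1`. Tajima's D per
50-kb window uses the standard constants (a1, a2, b, c, e1, e2); windows
with no segregating signal or non-positive variance are skipped. The
estimators assume independent sites and a panmictic sample within each
population.

## Landscape genetics

Pairwise predictors between population midpoints (mean member coordinates):
great-circle distance (haversine, sphere radius 6371 km), absolute
elevation difference, and absolute differences on the first two PCs of the
19 scaled climate variables. Multiple regression on distance matrices (MRM)
unfolds strict lower triangles, fits OLS with intercept, and tests R^2 by
jointly permuting rows and columns of the response matrix;
`p = (1 + #{perm R^2 >= observed}) / (1 + n_perm)`. Per-coefficient
p-values use |t| under the same permutations. `model_scan` fits all
non-empty predictor subsets (15 models for 4 predictors).

## Numerical choices and limitations

- All randomness flows through `numpy.random.Generator` with explicit seeds;
  chain seeds are spawned from a `SeedSequence` and reduced below 2^31.
- The SAF recursion is exact up to float rounding (validated against
  exhaustive enumeration for small samples); max-rescaling bounds underflow.
- EM frequency estimation and SFS EM are maximum-likelihood under
  Hardy–Weinberg / independence; misspecification (inbreeding, structure
  within a population) biases them.
- DIC-based choice of k, like all such criteria for admixture models, should
  be read as a guide rather than a significance test.
- MRM permutation p-values are exact only under exchangeability of
  populations; with few populations the permutation distribution is coarse.
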