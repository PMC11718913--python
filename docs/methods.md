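# Methods

`ssgblup` implements a single-step genomic evaluation of the days-open
(DO) fertility trait in dairy cattle — the interval in days between
calving and the next successful conception, edited in practice to 35-150
days, with lower values genetically favourable — together with the
window-based GWAS that back-solves SNP effects from the resulting
genomic breeding values. Everything runs on synthetic data from the
built-in generator, which emulates a tropical crossbred (Holstein-base)
population at desk scale.

## The repeatability animal model

Records are modelled as

    y = Xb + Qh + Zu + Wp + e

* `b` — fixed effects of breed group (3 Holstein-fraction classes),
  parity (1-5) and year-month of calving;
* `h ~ N(0, I sigma_h2)` — random herd-year of calving;
* `u ~ N(0, K sigma_u2)` — additive genetic effects, with `K = A`
  (pedigree numerator relationship matrix) for a conventional
  evaluation or `K = H` (single-step) when genotypes are present;
* `p ~ N(0, I sigma_p2)` — permanent environment of the cow, shared by
  her repeated records;
* `e ~ N(0, I sigma_e2)` — residual.

Heritability is defined against the full record variance including the
herd-year component, `h2 = sigma_u2 / (sigma_h2 + sigma_u2 + sigma_p2 +
sigma_e2)`; repeatability is `(sigma_u2 + sigma_p2)` over the same
denominator.

Identifiability of the fixed effects uses reference-level contrasts
plus an intercept; the breed-group reference defaults to the middle
class (group 2), so group effects read directly as deviations from it.

## Relationship matrices

* `A` by the tabular method; inbreeding coefficients by a
  Meuwissen-Luo-style traversal of the gene-flow decomposition
  `A = T D T'` (exact, linear memory).
* `A^-1` by Henderson's rules with inbreeding,
  `alpha_i = 1 / (0.5 - (F_s + F_d)/4)` with `F = -1` for the phantom
  unknown parent.
* `G` by VanRaden method 1, `G = W W' / (2 sum p_j q_j)` with `W` the
  allele counts centred by twice the observed frequency. Genotype QC
  first drops markers with call rate < 0.90 or minor allele frequency
  not above 0.05, then animals with call rate < 0.90; surviving missing
  calls are mean-imputed (`2 p_j`).
* `G*`: `G` is rescaled so its mean diagonal and mean off-diagonal
  match `A22` (the pedigree relationships of the genotyped animals) and
  then blended, `G* = 0.95 G + 0.05 A22`. Blending guarantees positive
  definiteness when markers are fewer than animals; the scale matching
  puts `G` on the pedigree base. No further scaling of the correction
  block is applied.
* `H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1]`, which degenerates exactly to
  `A^-1` when the genotyped set is empty or `G* = A22`.

## Solving and accuracy

Mixed-model equations are assembled in variance-ratio form and solved
directly (sparse or dense Cholesky) at desk scale; a Jacobi-
preconditioned conjugate-gradient solver is available for larger
systems (without prediction error variances, which need the inverse).
Per-animal accuracy is `sqrt(1 - PEV_i / (d_i sigma_u2))` where `d_i`
is the diagonal of the relationship matrix actually used — `1 + F_i`
under `A`, and `G*_ii` for genotyped animals under `H`. Using the
pedigree diagonal in single-step mode would be inconsistent: PEV may
legitimately exceed `(1 + F) sigma_u2` whenever `G*_ii < 1 + F`.

## AI-REML

Variance components are estimated by average-information REML on the
mixed-model equations. Per iteration the coefficient matrix is
factorized once; first derivatives use the standard trace identities
(via selected elements of the inverse) and the average-information
matrix comes from the working variates `f_i = Z_i u_i / sigma_i2`,
`f_e = e / sigma_e2`. Implementation choices:

* **Starting values** — the phenotypic variance split equally over the
  four components; robust and requires no pilot run.
* **Step control** — the AI step is step-halved (up to 8 times) while
  it proposes a non-positive component; only if that fails is a full EM
  round taken. EM is monotone and positivity-preserving but crawls; in
  practice damped AI converges in ~10-20 iterations where an
  EM-fallback-only rule needed 50+.
* **Zero boundary** — a component that falls below 0.1% of the
  phenotypic variance is treated as a boundary solution and frozen
  there (warning logged, SE reported as NaN). Without this, EM
  approaches the boundary geometrically and the component-change
  convergence test never fires.
* **Convergence** — maximum relative component change < 1e-8 (active
  components only). Standard errors are `sqrt(diag(AI^-1))` at
  convergence.
* **Absorption** — identity-covariance terms whose incidence matrix has
  one entry per row (herd-year, permanent environment) have diagonal
  LHS blocks and are absorbed before the dense factorization, roughly a
  6x flop saving at the default problem sizes; terms are only absorbed
  jointly when their cross-products vanish, and the permanent-
  environment block (the largest) wins otherwise. Traces over absorbed
  blocks are recovered through the Schur-complement identities, so the
  result is exact, not approximate.

## Back-solved SNP effects and window variance

For genotyped animals the GEBV decomposes as `u = M a`; effects are
recovered as `a = k D M' G_D^-1 u` with `k = 1/(2 sum p_j q_j)` and
`G_D = k M D M'`. With equal weights `D = I` this is the minimum-norm
solution and `M a` reconstructs `u` exactly. Optional reweighting sets
`d_j` proportional to `a_j^2 2 p_j q_j`, renormalized so the total
marker variance `sum d_j 2 p_j q_j` is conserved; one pass (no
reweighting) is the default, and two passes noticeably sharpen large
effects because the minimum-norm first pass spreads signal over all
markers when markers outnumber animals.

Window variance uses sliding (step 1) windows of five adjacent SNPs
within a chromosome: `100 * Var(M_w a_w) / Var(M a)` across genotyped
animals, a covariance-aware "variance explained" rather than a sum of
squared effects. Windows at or above 0.25% are flagged. Per-SNP
p-values come from the two-sided normal test `a_j / sd(a_j)` with the
sampling variance propagated from the prediction-error covariance of
the genotyped GEBVs through the back-solve transform; the genome-wide
threshold is `-log10(5e-8) = 7.30`. Because the PEV-based variance
is conservative at low accuracy, the null calibration errs towards no
false positives.

Gene annotation takes a BED table (converted to 1-based inclusive on
read), reports genes overlapping a SNP as on-target (distance 0) and
otherwise a signed distance — positive when the SNP lies right of the
gene end, negative when left of the gene start — classifying genes
within 37 kb (inclusive) as near; farther genes up to 500 kb are kept
with a beyond-37kb flag.

## The synthetic population

The generator mirrors the structure the model assumes, at roughly
10-50x below the study scale (which had 36k recorded cows, a 79k-animal
pedigree and 882 genotyped animals on a 50k chip):

* generation-discrete pedigree under random mating; each generation has
  few males (default 10%, mimicking AI breeding) and enough females to
  supply the requested record cows; founders are unrelated;
* defaults: 100 founders, 2 generations, 1,500 record cows, 50
  herd-year and 24 year-month levels, 3 breed groups inherited through
  the dam line;
* true variance components default to the published DO estimates
  (herd-year 30.41, additive 18.23, permanent environment 51.19,
  residual 707.87 days^2; phenotypic SD ~28.4 days around a 97-day
  mean, matching the descriptive statistics of the source population);
* breed-group effects default to (+0.372, 0, -1.508) days and parity
  effects to a second-parity-high / fifth-parity-low pattern; year-month
  effects are drawn once per level with a 6-day SD (both patterns are
  qualitative emulations, not fitted values);
* breeding values are drawn by recursive Mendelian sampling,
  `u_i = (u_s + u_d)/2 + phi_i` with `Var(phi_i) = sigma_u2 (0.5 -
  (F_s + F_d)/4)`, so `Cov(u) = A sigma_u2` without forming `A`;
* genotypes are gene-dropped: founder alleles Bernoulli with per-marker
  frequency uniform on the MAF range, one allele transmitted per parent,
  markers independent (no linkage). The genotyped subset is drawn from
  all non-founders by default, spanning sires, dams and the final
  generation like a real genotyping campaign; restricting genotyping to
  the final generation (`genotyped_scope="final"`) starves the
  single-step evaluation of cross-generation genomic ties and the
  accuracy gain over pedigree BLUP largely disappears at desk scale;
* optional QTL add a centred allele-count effect to the breeding value
  of every pedigree animal;
* records are edited by *dropping* values outside 35-150 days (the
  editing convention of the source data), never truncating; recovery
  simulations run unbounded to avoid selection bias.

What the generator does **not** emulate: linkage and LD (markers are
independent, so window variance has no LD leakage between QTL and
flanking markers), selection and culling, heterosis/dominance,
heat-stress covariates, genotyping error and real missingness patterns.
Passing tests therefore validate the estimation machinery under the
model's own assumptions, not robustness to the ways real data violate
them.

## Problem sizes and stochastic checks

Desk-scale suites use 120-1,500 cows. The heritability-recovery study
(many replicates of 1,500 cows with 1-3 parities under the published
AIREML truth) has a per-replicate sampling SD of the heritability
estimate of about 0.013-0.015 — consistent with the average-information
SE at the truth, and irreducible by pedigree-structure choices at this
record count — so the recovered mean is reported over many replicates.
Directional properties (single-step accuracy gain, QTL window capture,
null GWAS calibration) use 20 replicates each. The accuracy-gain check
is measured on the genotyped subset, where the genomic information
concentrates at these sizes; the QTL-capture check runs at a moderately
heritable configuration (additive 120 days^2) because with h2 = 0.02
and desk-scale data GEBVs are too inaccurate for any method to localize
QTL — back-solving the *true* breeding values succeeds, the estimated
ones do not.

## Known limitations

* Dense factorizations bound the practical size to a few times 10^4
  equations; no APY or iteration-on-data path.
* PEV (hence accuracy and GWAS p-values) requires the direct solver.
* Unknown-parent groups, metafounders and multi-trait models are out of
  scope.
* The GWAS p-value machinery is the standard normal companion test;
  with few markers and strong family structure it is conservative.
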