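# Methods

## Model

Each of N independent subjects contributes an r x c matrix X_i whose rows
are genes and whose columns are tissues (or any other pair of entity sets
with two-way dependence).  The X_i are assumed i.i.d. with mean matrix M
and a Kronecker-product (separable) covariance

    Cov(X_ij, X_lm) = (Sigma_R)_il (Sigma_C)_jm,

i.e. Cov(vec X) = Sigma_C (x) Sigma_R for a column-stacked vec.  Sigma_R
captures gene–gene covariance, Sigma_C tissue–tissue covariance.  The
regime of interest is r >> N with c small (thousands of genes, a handful
of tissues, ~10 subjects), where the row-side sample covariance is
singular and naive per-gene tests ignore the tissue dependence.

**Identifiability.** (a Sigma_C, Sigma_R / a) gives the same model for any
a > 0, so the pair is fixed by the convention tr(Sigma_C) = c: tissues have
average unit scale and Sigma_C reads like a correlation-strength matrix.
All estimators, tests, and the simulator operate under this convention;
column-side covariance output is renormalized to trace c, and row-side
quantities are absolutely identified.

## Trace functionals

Four moments drive everything else: t1 = tr(Sigma), t2 = tr(Sigma^2),
t3 = tr^2(Sigma), t4 = sum_j Sigma_jj^2, per side.  They are estimated
from scaled pair differences D_ij = (X_i - X_j)/sqrt(2) — mean-free with
the same Kronecker covariance, so no mean model is needed — by averaging
kernels over *distinct subject quadruples*, which makes the two pair
differences in each product independent:

* rows: t1 = avg_{i<j} tr(D D')/c; t2, t3, t4 are quadruple averages of
  tr(O_p O_q), tr(O_p) tr(O_q), and diag(O_p).diag(O_q) with O_p = D_p D_p',
  each divided by c^2.  All four are exactly unbiased under the trace
  convention (requires N >= 4).
* columns: only ratios are identified relative to the row scale, so
  t1 = c and t3 = c^2 exactly, while t2 = c^2 Q2/Q3 and t4 = c^2 Q4/Q3 with
  Q2, Q3, Q4 the analogous quadruple averages of the column Grams
  W_p = D_p' D_p.  Ratios of unbiased estimators are consistent but not
  exactly unbiased; the bias is O(1/N) and irrelevant at the sample sizes
  where the column side is used.

**Computation.** Every quadruple kernel above is an inner product of
per-pair features (O_p, tr O_p, diag O_p; W_p, ...).  The sum over ordered
disjoint pair-pairs therefore collapses to subject totals,

    sum_disjoint <F_p, F_q> = ||sum_p F_p||^2 - sum_s ||T_s||^2 + sum_p ||F_p||^2,

with T_s the feature total over pairs containing subject s — O(P) per
feature set (P = N(N-1)/2 pairs) instead of O(P^2).  When the stacked r x r
row features would exceed ~200 MB the implementation falls back to
explicit (P, P) kernel matrices built from c x c subject cross-Grams in
chunks.  Both paths, and a literal O(N^4) four-loop enumeration oracle,
agree to 1e-10 relative in the test suite; correctness is pinned by the
oracle, not by the algebra.

## Shrinkage estimation

The sample covariances are S_R = sum_i (X_i - Xbar)(X_i - Xbar)'/((N-1) c)
(unbiased for Sigma_R under the convention) and the analogous column
matrix rescaled to trace c.  The shrinkage estimator mixes S with a target
T: spherical (tr S/p) I, identity I, or diagonal diag(S), with intensity

    spherical: lambda = (t3 + t2) / (N t2 + ((p - N + 1)/p) t3)
    identity:  lambda = (t3 + t2) / (N (t2 - 2 t1 + p) + t2 + t3)
    diagonal:  lambda = (t3 + t2 - 2 t4) / (N (t2 - t4) + t2 + t3 - 2 t4)

obtained by minimizing expected Frobenius loss and plugging in the
U-statistic functionals; t3 uses the dedicated unbiased quadruple
estimator rather than t1^2 to avoid its O(tr(Sigma^2)/N) upward bias.
lambda is truncated to [0, 1]; a nonpositive denominator (data already
inside the target family, or degenerate) maps to lambda = 1 with a
warning.  Plugging population values of an on-target Sigma into any of the
three formulas gives lambda = 1 identically, and lambda decays like O(1/N)
off target.  For lambda > 0 and a positive-definite target the output is
positive definite — hence invertible at any dimension.  Column output is
renormalized to trace c after mixing.

## Mean-conservation test

A column grouping G induces the block-diagonal centering projection P
(I_k - J_k/k per group); "mean profile constant within each group" is
M P = 0.  The statistic

    T = (1/(N(N-1))) sum_{i != j} tr(X_i P X_j')

is exactly unbiased for tr(M P M') >= 0 and exactly mean-zero under H0
(independent subjects in each summand; no squared-noise bias).  Its null
variance 2 tr((P Sigma_C)^2) tr(Sigma_R^2) / (N(N-1)) is estimated
unbiasedly by the distinct-quadruple average of [tr(D_ij P D_kl')]^2, and
z = T/sqrt(var) is referred to N(0, 1), one-sided (the alternative is a
nonnegative squared norm).  Standardizing under H0 only is the
conservative choice; it affects power, not size.  Normality of z rests on
r >> N (many genes act as the averaging dimension), not on Gaussian data.
The statistic and its variance term are exactly invariant to adding any
fixed matrix whose rows are constant within groups, so subject-shared
baseline expression never leaks into the test.

Pairwise workflows (a tissue-specific gene list tested between a reference
tissue and each other tissue, c-1 p-values) and grouped multi-tissue
hypotheses are thin wrappers; families are adjusted by Benjamini-Hochberg
step-up (via statsmodels).

## Covariance-structure tests

With (t1, t2) of the tested side, the sphericity distance is
U = p t2/t1^2 - 1 (zero iff Sigma proportional to I, scale-free) and the
identity distance V = (t2 - 2 t1 + p)/p = ||Sigma - I||_F^2/p under the
trace convention.  On the column side the convention fixes the scale, so
V and U coincide there; the identity test is chiefly a row-side tool.

**Null reference.**  A Hoeffding-projection calculation (Gaussian
sampling, the non-tested dimension large) shows the quadruple U-statistic
dominates and

    N p U / (2 rho_o) -> chi2_nu - nu,    nu = (p - 1)(p + 2)/2,

where rho_o = tr(Sigma_o^2)/tr^2(Sigma_o) is the scale-free ratio of the
*other* side's covariance — the matrix-variate analogue of the classical
John sphericity limit, with the many genes supplying the CLT and rho_o/N
setting the effective noise scale.  The chi-square rather than its normal
limit is used because the tested dimension is small (a tissue pair has
nu = 2) and the null is visibly right-skewed; the reported z is the
normal quantile equivalent of the p-value.  The variance constant was
checked against the directly simulated null spread of U before being
frozen, and the size-calibration suite (r=200, N=50, all 36 pairs of 9
columns) verifies the resulting 5%-level size empirically.

rho_o is estimated from the same data: testing rows it is the column
ratio t2_C/c^2; testing columns it is the vectorized-data ratio
tr(Omega^2)/tr^2(Omega) (Omega = Sigma_C (x) Sigma_R), estimated from the
centered N x N subject Gram with the Gaussian-unbiased numerator
correction, divided by the column ratio.  This avoids any O(P^2 r)
row-side computation inside the per-pair screen.  The Gaussian fourth
moments behind both the chi-square constant and the Gram correction are
the main distributional assumption; the Monte-Carlo p-value mode
(simulate the fitted null with the other side set to its spherical-target
shrinkage estimate, p = (1 + #{U* >= U})/(R + 1)) is the fallback when
heavy tails are suspected.

The all-pairs screen computes, for every unordered column pair, exactly
the statistic the single-pair test would produce, but shares the pair
differences, the per-column Grams, and the quadruple subject-totals across
the C(c, 2) tests; equality with the per-pair route is asserted in tests.
A rejected "sphericity" hypothesis on a pair means *proportionality to the
identity* fails — unequal variances reject it just as correlation does, so
reports carry the precise hypothesis wording.

## Simulator

X_i = M + L_R Z_i L_C' with symmetric eigendecomposition square roots
(label permutations then commute with generation) and iid standardized
innovations: Gaussian, or centered scaled Gamma with shape a (skewness
2/sqrt(a)) to probe non-normality.  Sigma_C is renormalized to trace c at
configuration.  Subject i draws from substream (seed, i), so growing N
extends a sample instead of reshuffling it.  Structured factories cover
identity, AR1(rho), compound symmetry(rho) and unequal diagonals.

The "GTEx-like" configuration emulates the motivating shape class — many
genes, 9 tissues, 11 subjects — with a silent-gene fraction (mean ~1e-3)
that the standard 0.1 expression-sum filter removes, log-uniform expressed
levels in [0.5, 50), per-gene SD at 30% of level, AR1(0.5) gene
correlation and compound-symmetric tissue correlation 0.2.  It reproduces
the *shape and dependence class* of multi-tissue RNAseq, not its marginal
count distributions: values are real-valued and can dip below zero for
weakly expressed genes, there is no mean–variance count relation, no
batch or library-size artefacts, and gene correlation has banded AR1 form
rather than co-expression-module structure.  Passing the calibration
suites therefore demonstrates correctness of the estimators and the
stated error control under separable dependence — not robustness to
count noise or to non-separable covariance.

## Simulation sizes and numerical choices

Calibration runs use sizes that make Monte-Carlo error small relative to
the bands being checked while keeping the suite quick on one core: mean
test size at r=100, c=5, N=15 with 5000 replicates (binomial 3-sigma
~0.009 at the 0.05 level); pair-sphericity size at r=200, c=9, N=50 with
2000 replicates per pair; unbiasedness at r=6, c=3, N=40 with 2000
replicates; shrinkage risk at r=100, N=10 with 200 replicates; power
curves at deliberately small designs (r=20, N=8 for sphericity) so the
rejection rate traverses (0.05, 1) and monotonicity is informative.

Ties and degenerate inputs: quadruple statistics refuse N < 4; exact
duplicate subjects yield zero pair differences and estimates that collapse
toward zero without error; zero total variance raises on the column side
(the trace normalization would divide by zero); nuisance ratios are
floored at 1e-12; p-values are clamped away from 0/1 only for the z
(probit) report.  File round trips write floats at 17 significant digits
and parse with correctly-rounded ("round_trip") conversion, so
write-then-load is bit-exact.

## Known limitations

* Column-side t2/t4 are ratio-consistent, not unbiased; their bias enters
  the sphericity statistic at O(1/N).
* The analytic covariance-test reference assumes Gaussian fourth moments
  and a large non-tested dimension; for heavy-tailed data use the
  Monte-Carlo mode (itself conditional on a plug-in null).
* The identity test's t1-fluctuation is neglected in the standardization;
  this is justified when r/(Nc) is large, the regime the test targets.
* The mean test standardizes under H0 only, which can cost power very far
  from the null; size is unaffected.
* No missing-data handling: cubes must be complete, by design.
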