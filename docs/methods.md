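# Methods

## The model

All estimators assume continuous traits evolving by Brownian motion (BM) on
a rooted, branch-length-bearing phylogeny.  For taxa *i*, *j* the implied
trait covariance is `σ² V_ij`, where `V_ij` is the shared root-to-MRCA path
length; the diagonal holds root-to-leaf depths.  Pagel's λ relaxes this:
`V(λ)` multiplies off-diagonal entries by λ ∈ [0, 1] while keeping the
diagonal, interpolating between full Brownian structure (λ = 1) and
phylogenetic independence (λ = 0).  λ > 1 and other transforms (κ, δ, OU)
are out of scope.

**PGLS.**  For response `y` and design `X` (intercept always included) the
fit solves the generalized normal equations through Cholesky whitening of
`V(λ)`.  Standard errors use `σ̂² = RSS_w / df` with the whitened residual
sum of squares; two-tailed p-values come from Student's t via the
regularized incomplete beta function `p = I_{df/(df+t²)}(df/2, 1/2)`.  The
reported log-likelihood is the ML profile value (σ² profiled out), the
reported R² is the squared Pearson correlation between fitted and observed
responses (a descriptive quantity, always in [0, 1]).

**λ estimation.**  `profile_lambda` maximizes the ML (not REML)
log-likelihood over λ ∈ [0, 1]: a 41-point grid bracket followed by bounded
scalar minimization to an absolute tolerance of 1e-6.  Boundary maxima are
reported exactly as 0 or 1.  On a star tree the likelihood does not depend
on λ; the profile is flagged flat and λ̂ is NaN (fitting with `lam="ml"`
raises).  ML was chosen over REML for transparency and because the
reproduction-scale analyses (n = 14) are reported with fixed df anyway;
REML would shift Table-2-style t-values only in the second decimal.

**Independent contrasts.**  The pruning recursion computes one standardized
contrast per internal node; daughter branch lengths are extended by
`v₁v₂/(v₁+v₂)` when an ancestral value is reconstructed as the
inverse-variance-weighted daughter average.  Polytomies are first resolved
deterministically (children sorted by smallest descendant label) with
zero-length branches, which leaves `V` unchanged.  Expected variances are
floored at 1e-12 before standardization so zero-length sister branches
cannot divide by zero.  Contrast pairs are positivized on the predictor
variable; exact-zero predictor contrasts keep their orientation.  The
regression is through the origin; under BM its slope equals the
PGLS(λ = 1) slope, an identity the test suite enforces to 1e-8 against an
explicit-inverse GLS oracle.

## Degrees of freedom

The study this package reproduces fixed df = 11 for its n = 14 analyses
(three subtracted from n: one for computing contrasts, two for slope and
intercept), for both PGLS and contrast regression.  `df_convention="paper"`
reproduces that rule (df = n − 3 in every estimator, including the
Pearson t-test); `"standard"` uses n − (k+1) for PGLS, n_contrasts − 1 for
contrast regression and n − 2 for Pearson.  Because the original software's
internal SE denominator is not documented, the chosen df is used both as
the residual-variance denominator and as the t reference df — the only
self-consistent reading.  "paper" is the pipeline default (reproduction
mode); "standard" is the library default for new analyses.

## Trees

Newick parsing and writing delegate to dendropy behind a validating
wrapper: balanced parentheses, terminal semicolon and non-negative branch
lengths are checked with character positions before parsing; unique
non-empty leaf labels after.  Output writes branch lengths with 17
significant digits so parse∘write round-trips exactly.

Pruning suppresses unary nodes (branch lengths summed).  The residual stem
between the original root and the retained taxa's MRCA is kept as a root
edge by default, so every retained leaf keeps its original depth and the
VCV of a pruned tree is exactly the corresponding submatrix of the original
VCV — the property that makes pruned-tree analyses consistent with
subsetting the covariance, and the scientifically correct choice whenever
λ < 1 (a constant added to all entries of `V` is *not* absorbed by the
intercept once off-diagonals are rescaled).  `drop_root_edge=True` gives
the alternative normalization (depths measured from the new root) for users
who want it.

Ultrametricity is checked with a relative tolerance of 1e-6 of tree depth.

## The synthetic-data generator

`simulate_yule_tree` draws pure-birth trees (exponential waiting times at
rate k·b for k lineages, uniform lineage choice, all lineages extended to
the present), so trees are exactly ultrametric and deterministic given a
seed.  `simulate_bm_traits` draws tip values from the matrix-normal law
with across-taxa covariance `V(λ)` (via a PSD-safe square-root factor) and
across-trait covariance given by the evolutionary rate matrix.  λ is
honored exactly by construction — branch-wise simulation cannot represent
λ < 1, which is why the covariance route was chosen.  Count-like traits are
rounded to integers and floored at zero after simulation; the inferential
model remains Gaussian, as in the study design, and a dedicated test checks
that rounding at gene-count scale moves Pearson r² by < 0.05 on average.

Defaults mirror the study scale: n = 14 taxa, unit birth rate (tree depth
of order one), unit rates (tip SD of order one, comparable to the
cross-species spread of log₁₀ lifespan), λ = 1.

`simulate_null_battery` measures realized type-I error of naive Pearson
correlation, contrast regression and PGLS(λ = 1) (both with standard df)
under independent-trait BM.  The naive test is included deliberately: on
trees with deep structure it rejects a true null far above nominal level
(≈ 0.35 at n = 14 on Yule trees in the acceptance run), which is the
methodological premise for applying a phylogenetic correction at all.

## The packaged dataset is synthetic

The original study's species table and the two time trees exist only as
figure images; their numbers are not machine-readable.  The packaged
dataset (`data/synthetic_traits.csv`, `data/synthetic_tree_I.nwk`,
`data/synthetic_tree_II.nwk`) is therefore a labelled synthetic stand-in:
the 14 species names and two anchor counts (human 10, mouse 5 CD33rSiglecs)
are documented facts; lifespans, weights, remaining counts and all branch
lengths are plausible values chosen once by the package authors to emulate
the study's qualitative design — a focal family tracking log lifespan
strongly, a near-invariant KLK-like control, a weak TLR-like control, and
an IgG-Fc-receptor-like control whose apparent signal is driven by the
human outlier (and collapses when the human row is excluded).  The two
trees share one topology and differ in divergence-time calibration, both
ultrametric, branch lengths in Myr.

Consequently, tests and the acceptance script assert the *pattern* of
results (which family dominates, what survives correction, how the outlier
control behaves) and the *correctness* of every estimator against
independent oracles and parameter-recovery simulations — not the original
publication's printed statistics, which cannot be checked without the
original data.

## Problem sizes and numerical choices

* λ recovery battery: 200-leaf Yule tree, 500 replicates in the test suite
  (300 in the acceptance script), evolutionary correlation 0.8; mean λ̂
  within 0.05 of the simulated λ = 1, and mean λ̂ < 0.1 under pure tip
  noise.
* Type-I calibration: 2,000 replicates at n = 14.
* Slope-identity check: 100 simulated datasets, 4–20 taxa, tolerance 1e-8.
* t-kernel accuracy: checked against adaptive quadrature of the t density
  to 1e-10 and against the df = 1 Cauchy closed form.
* Whitening uses `numpy.linalg.cholesky` plus triangular solves; rank
  deficiency of the whitened design (detected via QR) raises a named
  error rather than silently pseudo-inverting.
* Contrasts of an exactly constant trait are exactly zero (equal daughter
  values short-circuit the weighted average).

## Known limitations

* Gene counts are modelled as continuous Gaussian traits (as in the study
  design); no phylogenetic Poisson/logistic alternative is offered.
* No measurement-error model; lifespan estimates from small samples enter
  as point values (the pipeline's lifespan-override directive exists partly
  to probe this).
* λ is the only covariance transform; no OU, κ, δ, or multi-rate models.
* The synthetic dataset demonstrates the pipeline; conclusions about real
  mammalian gene families require the original (or re-curated) data, which
  the pipeline accepts via its config interface without code changes.
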