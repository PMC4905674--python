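# Methods

## Observation model

The unit observation is a site pattern: one orthologous ERV locus coded in
six primates (human, chimp, gorilla, orangutan, macaque, marmoset) as
`0` (absent), `1` (full-length or partial provirus) or `x` (solo-LTR).
Marmoset is the outgroup and is constrained to `0`; loci present in
marmoset are outside the model's scope. Because the only permitted state
history is `0 → 1 → x` (integration happens once; solo-LTR formation is
irreversible; re-insertion at the same site is ignored), a pattern is
*coherent* exactly when its non-0 positions form the descendant tip set of
one branch of the chronogram, and that branch — the insertion branch — is
then unique. Coherent patterns number 70 in total: for an insertion branch
with k descendant tips, each tip is independently `1` or `x`, giving 2^k
outcomes (32 for the root branch). Incoherent supports (e.g. human and
macaque present but gorilla absent) are the signature of incomplete
lineage sorting or annotation error and are rejected with a diagnostic;
the extraction pipeline counts and drops them.

Patterns that are `x` at every supported tip are retained as ordinary
insertions. This assumes every locus endogenised in full-length form,
which may overstate the deletion rate if some elements integrate already
truncated.

## The chronogram

The tree is hard-wired: branches `h c g o m hc hcg hcgo hcgom`, with
marmoset carrying no branch. Branch durations are in Myr. The shipped
defaults are reconstructed from the reference per-family insertion counts
and rates by least squares (`T = Σ N·r / Σ r²` over families per branch),
because each published (count, rate) pair is an observation `N = r·T`.
The resulting tree (h 6.62, c 6.56, g 8.57, o 18.33, m 30.51, hc 2.00,
hcg 9.70, hcgo 12.19, hcgom 12.41) reproduces 53 of the 54 reference rates
exactly at 2 dp (the root-branch HERV-K rate is internally inconsistent
with the other five families by one rounding ulp) and is ultrametric over
the five ingroup tips to 0.065 Myr. Any tree can be supplied via a
YAML/JSON mapping or Newick, but it must map onto the fixed 9-branch
shape: the pruning recursion and the pattern semantics assume it.

## Deletion models

Deletion is the conversion of a full-length provirus into a solo-LTR.

* exponential: survival `S(a) = exp(−ψ_e a)`, constant hazard `ψ_e` per
  Myr; mean lifetime `1/ψ_e`.
* Weibull: survival `S(a) = exp(−(a/ψ_w)^ω)` with scale `ψ_w` (Myr) and
  dimensionless shape `ω`; hazard `(ω/ψ_w)(a/ψ_w)^{ω−1}` is strictly
  decreasing for `ω < 1` and increasing for `ω > 1`; mean lifetime
  `ψ_w Γ(1 + 1/ω)`. `ω = 1` recovers the exponential model exactly, which
  the tests assert operation by operation.

Internally the Weibull scale is stored; reports expose the inverse scale
`1/ψ_w`, the convention used for published fits. All free parameters are
box-constrained to `[1e-6, 1e2]`: datasets with no full-length survivors
on a branch carry no upper information about the deletion rate, and the
box makes such boundary solutions explicit (estimates within 1e-3 of a
bound in log10 space are flagged and should be read as inequalities).

Two branch-level transition probabilities are needed.

*Insertion branch* (length `t`): the insertion time `t_i` is uniform on
the branch (a consequence of the Poisson insertion process), so
`Pr(0→x) = (1/t)∫₀ᵗ [1 − S(t − t_i)] dt_i`. For the exponential model this
is `1 + (e^{−ψt} − 1)/(ψt)`, evaluated via `expm1` for small `ψt`. For the
Weibull model the branch-averaged survival is
`(ψ/(ωt)) γ(1/ω, (t/ψ)^ω)` with `γ` the lower incomplete gamma function,
evaluated through `gammaln` + the regularised `gammainc`; where that
underflows (shape far below ~0.01) the defining integral is evaluated by
adaptive quadrature instead.

*Post-insertion branch* from `t1` to `t2` after the insertion-branch
origin: retention is `(1/t)∫₀ᵗ S(t2 − t_i)/S(t1 − t_i) dt_i`. Under the
exponential model this is `exp(−ψ(t2 − t1))` — independent of `t1` and of
`t_i` (memorylessness). Under the Weibull model it is age dependent and is
integrated numerically. The survival *ratio* is the only reading of the
post-branch integrand that is a probability and reduces correctly at
`ω = 1`; the `t_i` average is taken independently per branch factor, i.e.
the likelihood deliberately factorises over branches and does not
propagate cross-branch correlation in the unknown insertion time. A
joint-integral helper sharing one `t_i` across a transition chain exists
for sensitivity analysis.

Numerics: 64-point Gauss–Legendre, cross-checked against a 128-point rule
at 1e-10 relative tolerance; on disagreement (the integrand has an
endpoint derivative singularity when `ω < 1` and the post branch abuts the
insertion branch) the integral falls back to double-exponential (tanh-sinh)
quadrature, and finally to adaptive Gauss–Kronrod. Closed forms agree with
adaptive quadrature of the defining integrals to ≤ 1e-8 across the tested
parameter grid.

## Likelihood and inference

The joint log likelihood is the Poisson insertion term (closed-form MLE
`Φ̂_i = N_i/T_i`) plus per-pattern deletion terms conditional on the
insertion branch; the two components are independent and are reported
separately (the insertion term cancels in model comparison). Each pattern
term sums over all internal-node assignments consistent with `0 → 1 → x`
via a pruning-style recursion seeded at the insertion branch with the
`0→{1,x}` integral; `x` is absorbing, and `x → 1` has probability zero.
Cumulative times from the insertion-branch origin are precomputed per
branch, which is what the age-dependent Weibull factors require. The
recursion is verified against exhaustive enumeration of internal states
for all 70 coherent patterns at 1e-12, and the 2^k outcome probabilities
of each insertion branch sum to 1 at 1e-12.

Deletion parameters are estimated in log10 space under the box constraint
using a deterministic start grid plus seeded uniform multi-starts
(default 16) refined by L-BFGS-B; identical patterns are collapsed with
multiplicities so the cost is independent of dataset size. Evaluations
where the likelihood underflows to zero return a large finite penalty so
finite-difference gradients remain defined. Model comparison uses
`2Δℓ = 2(ℓ_w − ℓ_e)` with 1 df against the χ² 0.001 quantile (10.83); the
null calibration test confirms essentially no false rejections at this
cutoff (the truth lying on the `ω = 1` interior line makes the statistic a
χ²₁-mixture, conservative at the nominal level). Uncertainty is from a
case-resampling bootstrap over patterns (default 1000 replicates,
percentile intervals, per-replicate seeds derived from the master seed);
replicate counts and CI construction are package choices, as is the
multi-start budget.

## Forward simulation and goodness of fit

`simulate_patterns` has two modes.

* `factorized` (default): every branch transition is a Bernoulli draw from
  the same per-branch probabilities the likelihood uses. Simulated pattern
  frequencies therefore converge to `exp(pattern_log_likelihood)` exactly;
  the test suite checks every coherent pattern at 10⁵ insertions against
  3-SE/exact-binomial bounds for both models. This mode is the correct
  null for testing the fitted model's adequacy.
* `mechanistic`: one uniform insertion time per locus, survival ratios
  applied per lineage conditional on that time (daughters independent
  given `t_i`). For the exponential model the two modes coincide by
  memorylessness, which is asserted distributionally.

The goodness-of-fit test builds the r×2 table of distinct patterns ×
(observed, simulated) counts and computes a seeded Monte-Carlo exact test:
conditional on both margins, tables are drawn by vectorised multivariate
hypergeometric sampling (default 10⁵) and the p-value is the fraction with
log-probability at most the observed table's. Raw counts are compared, not
normalised frequencies.

`generate_synthetic_study` is the drop-in replacement for a genome-scale
survey: for each of the six reference families it draws per-branch Poisson
counts at the reference insertion rates and simulates deletion at the
reference Weibull parameters. For the five families whose published
estimates sit on the parameter box boundary, the boundary values
(inverse scale 100, the quoted shape) are used as point values — the
generator's conditions are fixed, not tuned. What passing tests on this
generator do *not* show: robustness to annotation noise, alignment error,
lineage sorting, rate heterogeneity across loci, or non-uniform insertion
times within branches — none of which the generator emulates.

## Wright–Fisher LTR-divergence simulation

A new insertion starts at one copy in a diploid population of N = 10,000
(2N = 20,000 allele slots; haploid mode available), resampled binomially
each generation. Each carrier copy mutates across its paired LTRs
(2 × 1,000 bp target) at 1e-8 per site per generation, infinite-sites, no
back mutation; any mutation creates an LTR–LTR difference in that copy.
Generation time 10 years converts generations to years.

Reported statistics and their conditioning:

* *First difference while segregating*: the generation of the first
  mutation event among carriers, averaged over replicates in which the
  allele is segregating (0 < k < 2N) at that event; the allele frequency
  at the event is reported alongside. Computed by a vectorised batch
  engine over unconditioned trajectories; at the default parameters the
  acceptance script obtains a mean near 220 generations with mean
  frequency ≈ 0.8%. The waiting time scales as `(μL)^{−1/2}`, not
  `(μL)^{−1}`, because the hazard `μ_c k_t` grows with the conditionally
  surviving copy number.
* *Mutation load at fixation*: the mutation count of a copy sampled
  uniformly at the generation fixation is first reached — our definition
  of "the state of the fixed locus". Explicit runs also record the count
  shared by all copies at that moment. The efficient sampler uses two
  exact identities: the copy-number chain conditioned on eventual fixation
  is Markov with `k' ~ 1 + Binomial(2N−1, k/2N)` (size-biasing of the
  neutral transition by the fixation probability `k/2N`), and the sampled
  copy's ancestry spans exactly T_fix single-copy generations, so its
  count is `Binomial(T_fix, μ_c)` given T_fix. Both identities are
  cross-validated against explicit per-copy tracking at small N. A note on
  magnitude: with E[T_fix | fix] = 4N = 40,000 generations and
  `μ_c = 2e-5`, the zero-mutation fraction satisfies
  `E[(1−μ_c)^{T_fix}] ≥ e^{−0.8} ≈ 0.45` by Jensen's inequality for any
  distribution of T_fix with that mean; the acceptance script computes
  ≈ 0.49 at the 10× scale-down. Substantially smaller values are not
  reachable under these parameters and this (or any lineage-based)
  conditioning.
* Fixation-spectrum runs use the N·μ·L-preserving scale-down N = 1,000,
  μ = 1e-7 by default; the scaling of the spectrum under joint rescaling
  is what justifies this, and the conditioned-chain fixation-time mean is
  checked against the 4N expectation.

## Pattern extraction

Coordinates are 0-based half-open; annotation strand is ignored (the
pattern state of a locus does not depend on strand). Cells of the 6×m
classification matrix are `d` (unannotated nucleotide), `g` (gap),
`s-family-k` / `c-family-k` (solo-LTR / provirus instance, numbered per
species and family). Overlapping annotations on one species are rejected —
nested insertions must be resolved to the outer element upstream.

Maximal runs of identical columns are collapsed into pre-patterns and runs
under 50 columns discarded (sub-50 bp features are below the pipeline's
resolution); consecutive equal pre-patterns that appear after filtering
are not re-merged. Candidate windows are ≥ 3 pre-patterns anchored by
all-`d` pre-patterns whose interior carries one common s/c instance in
some row and an all-gap row, with the marmoset row required to be gapped
(insertions must postdate the outgroup split). Since a valid interior can
contain no all-`d` pre-pattern, anchors are consecutive in the all-`d`
subsequence and the scan is linear; it is tested against a quadratic
all-windows oracle.

Coding per row over the interior: any `s` ⇒ `x`, any `c` ⇒ `1` (checked in
that order, so a row showing both codes resolves to `1`), all-`d` ⇒ inherit
`1` if the pattern already has a `1` else `x` (unannotated sequence fully
aligned to an annotated element inherits its state), all-`g` ⇒ `0`. A row
mixing `d` and `g` without annotation is coded `0` (no confident call);
this case is undefined in the four rules and the conservative choice
avoids fabricating presence.

Post-filters: both flanking anchors must be ≥ 100 nt (so pre-integration
sites are genuinely aligned and gaps mean absence), and the best-backed row
of the inter-flank region must carry ≥ 250 nt (boundaries inclusive).
The 85% relabelling rule corrects solo-LTR calls contradicted by homology:
an `x` becomes `1` when the identically matched called columns cover at
least 85% of an aligned full-length row's called inter-flank sequence.
The denominator is deliberately the *full-length* row's backing — scoring
the `x` row against its own extent would relabel every true solo-LTR,
since a solo-LTR is near-identical to its partner LTR over its own length.
A pure called-length-ratio variant is available via `relabel_mode`.
Mixed patterns (both `1` and `x`) are flagged in the extraction report for
review rather than handled interactively. The fixture generator plants
elements with known states and identical orthologous flanks; on such
noise-free input extraction recovers exactly the coherent plants
(recall = precision = 1), which bounds correctness of the bookkeeping, not
performance on real alignments.

## Problem sizes used by the default test and acceptance runs

Simulator–likelihood agreement uses 10⁵ insertions per model;
goodness-of-fit calibration uses 25 datasets of 13 loci against 10⁴
simulated; bootstrap-coverage checks use 30 outer replications × 60
bootstrap replicates of 150-locus datasets under the exponential model;
Wright–Fisher statistics use ≥ 10⁴ qualifying replicates (first
difference, full N = 10,000) and 10⁴ conditioned fixations (spectrum,
scaled-down N = 1,000). These sizes are the package's defaults for
routine verification; all are configurable upward.

## Known limitations

* The likelihood factorises per-branch insertion-time integrals; the exact
  joint treatment is available only as a sensitivity helper.
* Deletion parameters are shared across branches; branch-specific deletion
  and gene conversion are not modelled.
* Polymorphic (unfixed) loci, allele frequencies, rate heterogeneity
  across loci, and selection are out of scope.
* The macaque terminal branch averages 30 Myr of activity; insertions
  concentrated early on it will bias deletion-rate estimates upward, a
  property of the data resolution rather than the implementation.
* Boundary Weibull fits (inverse scale at 100/Myr) mean the data bound the
  deletion process only from one side; reported inequalities should be
  taken at face value.
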