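# Methods

## Model

The allometric diet breadth model maps a community of S body masses and a
parameter point θ = (a, ai, aj, b) to exactly one binary S×S predation
matrix. Each consumer's diet is the solution of the contingency foraging
model: prey are ranked by profitability P_ij = E_i/H_ij and added in rank
order while the next item's profitability strictly exceeds the intake rate

    R(D) = Σ λ_ij E_i / (1 + Σ λ_ij H_ij),   λ_ij = A_ij N_i,

stopping at the first exclusion. Because the items are ranked by P, this
prefix is the global maximizer of R over all 2^S prey subsets (zero-one
rule); the test suite verifies the equivalence against exhaustive
enumeration on hundreds of random instances with S ≤ 8. Strict inequality
(P > R) means zero-profitability prey are never eaten; profitability ties
are broken toward smaller prey mass and then label order, so the output is
deterministic. Cannibalism is treated like any other link: the self-ratio
M_i/M_i = 1 is feasible iff b > 1.

Model assumptions worth keeping in mind: body mass is the only trait, so
predicted diets are always contiguous in prey size — a real web with gaps
in a consumer's size-ordered diet can never be matched exactly, which is
the structural reason the fitted connectance tends to exceed an observed
(under-sampled) connectance.

### Parameters and constants

| parameter | meaning | default / prior |
|---|---|---|
| a (m²·s⁻¹ or m³·s⁻¹ scale constant) | space-clearance constant | log10 a uniform; upper bound 10, lower bound web-specific (see below) |
| ai | prey-mass exponent of attack rate | uniform on (−1.5, 1.5) |
| aj | consumer-mass exponent of attack rate | uniform on (0, 3) |
| b | prey/consumer mass-ratio threshold for finite handling | log10 b uniform on (−15, 15) |
| e, n, h | energy, density, handling constants | fixed at 1 |
| ni | density-mass exponent | fixed at −3/4 |

e is arbitrary (rescaling it multiplies both sides of the inclusion test
P > R and cannot change any diet), and structure depends on n, a, h only
through the product n·a·h; both facts are asserted as exact
web-equality tests. The exponent priors follow published compilations of
allometric foraging rates; the b prior spans the mass-ratio range implied
by communities whose body masses span up to ~14 orders of magnitude.

The lower prior bound of log10 a is elicited per web
(`elicit_a_lower_bound`): best-attainable TSS (maximized over a common
probe set of (ai, aj, b) values) is scanned over a log10 a grid; as a
decreases the intake rate falls and diets saturate at "all feasible,
profitable prey", so TSS rises and then plateaus. The proposed bound is
the largest grid value at which the running maximum (scanning downward
from large a) is within `plateau_tol` (default 0.02) of the overall
maximum — the prior then spans the full TSS variation while staying as
narrow as possible. If the running maximum is still rising at the grid
minimum, a warning is emitted and the minimum returned.

## Distance and fitting

The fit criterion is d = 1 − TSS computed over all S² cells, diagonal
included (the potential-link count is S² throughout, matching connectance
L/S²). TSS is undefined when the observed web has no links or no absences;
this raises an error rather than returning a sentinel, since every
meaningful observed web has 0 < C < 1. The numerator TP·TN − FP·FN is
integer arithmetic; one floating division follows.

Rejection ABC draws θ from the prior, runs the model, and accepts with
probability K(d)/K(0) = 1 − (d/tol)² (Epanechnikov kernel; zero at and
beyond tol, so an accepted distance is strictly below tol). One seeded
`numpy` Generator supplies, per proposal, four parameter uniforms followed
by one acceptance uniform, in that fixed order — runs are bitwise
reproducible per seed, and every accepted sample's stored distance
regenerates exactly from its parameters because the model is
deterministic. If `max_attempts` (default 10⁶) proposals are exhausted the
failure carries the minimum distance seen, which diagnoses a tolerance set
below the model's attainable distance for that web.

Threshold selection re-uses one reference sample of (θ, d, C) proposals
(default 5000) and re-filters it per grid tolerance, reusing one uniform
per proposal so the accepted sets are nested along the grid; this is
statistically equivalent to independent re-simulation for independent
proposals and orders of magnitude cheaper. The selected tol is the
smallest grid value whose central predicted-connectance interval (95% by
default; a min–max option exists) contains the observed connectance.
Parameter summaries are credible intervals; TSS and connectance summaries
are posterior-predictive intervals; both are empirical quantiles of the
accepted sample.

## Structural properties

Eleven per-web metrics support posterior-predictive evaluation. Reference
food web packages differ in detail, so the definitions are fixed here:
classification (basal/intermediate/top, and herbivory) ignores self-links;
generality/vulnerability count all links and are normalized by L/S before
taking a sample standard deviation; diet similarity is mean pairwise
Jaccard of resource sets with two empty diets counting as identical;
trophic levels are shortest-path based (basal = 1) and omnivory is the
population standard deviation of a consumer's resource levels; clustering
is the mean local coefficient of the undirected projection; mean path
length averages directed shortest paths over reachable ordered pairs; and
nestedness is NODF on the 0–100 scale (cross-checked in the tests against
the vegan reference implementation). Undefined values (omnivory without
basal species, path length with no reachable pair) are `None` markers, and
standardized errors exclude them pairwise: the raw error |observed −
predicted| is divided by the maximum raw error for that property across
the predicted stack (zero when all raw errors are zero), and the per-web
mean is taken over defined properties only. Numeric parity with any
particular R package is a non-goal.

## Synthetic benchmarks

The generator emulates three features of real data: communities with
log-uniform body masses over a configurable log10 range (real community
tables span roughly 4–16 orders of magnitude); ground-truth webs produced
by the ADBM itself under known parameters, so recovery can be checked
against a known answer; and under-sampling as i.i.d. deletion of each link
with probability q. The packaged default scenario is S = 20, masses over
10⁻⁶–10² g, log10 a = −3, ai = aj = 0.5, b = 0.1, q = 0.2, giving
ground-truth connectance ≈ 0.17.

What passing the synthetic tests does *not* show: real webs are not
generated by the ADBM, their diets are not contiguous in size, their
masses are not log-uniform, and real under-sampling is not independent per
link — so parameter recovery and coverage rates here quantify internal
consistency of the estimation machinery, not field accuracy.

## Problem sizes and numerical choices

Benchmarks use S = 20 communities, n_accept = 200 (coverage runs, 20
replicates) or 100 (under-sampling runs, 10 replicates), and reference
samples of 1500–2000 proposals for threshold selection; these sizes give
stable intervals while keeping each replicate to a few seconds. Powers are
evaluated in log10 space and an unrepresentable magnitude (|log10| > 300)
raises an error naming the species and exponent; infinite handling times
are stored as IEEE +inf, never a sentinel. Communities are canonically
sorted by (mass, label) so matrices always display smallest-to-largest and
tied masses order deterministically.

## Known limitations

MCMC and sequential ABC variants are out of scope (pure rejection is used
throughout). Only body mass enters the model; discontiguous diets are
unrepresentable. Mean and maximum trophic level are not among the reported
properties. The observed-web readers support empirical data files, but no
empirical webs ship with the package.
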