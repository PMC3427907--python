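# Methods

## Model and procedure

`mcpgraph` implements closed multiple test procedures whose intersection
weights are generated by a graphical weighting strategy. A strategy on m
hypotheses is a pair (w, G): initial weights w_i ≥ 0 with Σw_i ≤ 1, and a
transition matrix G = (g_ij) with g_ij ∈ [0, 1], zero diagonal and row sums
≤ 1. Removing hypothesis j propagates its weight along its outgoing edges,

    w_l ← w_l + w_j·g_jl   (l ≠ j surviving),

and rewires the remaining edges through the removed node,

    g_kl ← (g_kl + g_kj·g_jl) / (1 − g_kj·g_jk),

with the quotient defined as 0 when g_kj·g_jk ≥ 1 (a two-node loop of total
weight one keeps its level inside the pair; this is the γ = 1 limit of the
truncated-Holm constructor, where the secondary family is never fed).
Removing the complement of J in any order yields w_j(J); order invariance
is a structural property of the update and is tested on random graphs.
Because each removal only ever adds weight, graph-generated tables always
satisfy the monotonicity condition w_j(J′) ≥ w_j(J) for J′ ⊆ J — the basis
for the sequential Bonferroni shortcut. `check_monotonicity` exists for
hand-built tables, where the condition can fail.

Three local tests are applied to each intersection H_J:

- **Weighted Bonferroni** — reject if some p_j ≤ w_j(J)·α. The closure is
  never enumerated in the sequential procedure: rejecting any eligible
  hypothesis on the current graph and updating reproduces the closed test's
  decisions exactly; adjusted p-values come from continuing the rejection
  sequence past α and taking the running maximum of the minimal ratios
  p_j/w_j. Equality with the explicit-closure values (max over J ∋ i of
  min_j p_j/w_j(J), with x/0 := +∞, capped at 1) is a tested property.
- **Weighted parametric (min-p)** — reject if some p_j ≤ c_J·w_j(J)·α. The
  test statistics are one-sided z-statistics; their correlation matrix may
  contain unknown entries, in which case the known/unknown pattern must be
  exactly block-diagonal (anything else is rejected, not approximated, since
  the blockwise level condition is only defined for a partition). c_J is
  the largest constant with Σ_h P(∪_{j∈J∩I_h} {P_j ≤ c·w_j(J)·α}) = α, a
  Bonferroni bound across blocks that is exact when a single block covers
  J. Zero-weight hypotheses impose threshold 0 and drop out, so degenerate
  joint distributions never arise. Weight-t support is out of scope.
- **Weighted Simes** — reject if some p_j ≤ α·Σ_{k∈J: p_k ≤ p_j} w_k(J)
  (ties included via ≤; with equal weights this is the classical Simes
  test, and the closure reduces to Hommel's procedure). Validity requires
  positive regression dependence of the statistics, which is the user's
  assertion — the package documents it and cannot verify it. When PRD holds
  only within blocks of a partition, the test is applied per block and the
  blocks are joined by the Bonferroni inequality.

The Simes closure admits a partially sequential procedure: retain all if
every p > α; reject all if every p ≤ α (valid because exhaustive closure
weights always put full cumulative weight behind the largest p — skipped
when the weights are not exhaustive); otherwise run the sequential
Bonferroni procedure and stop if at most two hypotheses survive (one
survivor must have p > α; two survivors cannot both be below α, and a
single small one would already have been rejected by the Bonferroni step).
Only then is the closure of the survivor graph enumerated. Equivalence with
the direct closure is tested on 500 random exhaustive instances.

Adjusted p-values are, throughout, the smallest overall level at which a
hypothesis is rejected: the maximum over containing intersections of the
intersection's local p-value. For the parametric test the local p-value is
computed by the direct union-probability formula (the blockwise probability
evaluated at the observed weighted min-p threshold) rather than nested root
finding; agreement with the smallest-rejecting-level definition
(c(q)·q = min-ratio at q = local p) is a tested property. The Simes local
p-value uses the minimal ratio of p_j to its cumulative weight; the
reference material does not define Simes adjusted p-values, so this is
documented as the package's extension, consistent with the rejection rule
at every α (tested on a level grid).

## Consonance and its enforcement

A closed procedure is consonant when rejecting an intersection always
allows rejecting an elementary hypothesis, which is what licenses
sequential shortcuts. For the parametric test this amounts to monotone
local levels: c_{J′}·w_j(J′) ≥ c_J·w_j(J) for J′ ⊂ J. Both this check and
the weight-monotonicity check inspect only immediate pairs J, J \ {k};
the general nested condition follows by chaining. The default comparison
tolerance is 1e-9 absolute — appropriate because every quantity involved is
computed to ~1e-10 or better (see below).

The two-dose hierarchical strategy with within-pair correlation 0.5 is the
canonical non-consonant example: the full intersection tests each primary
at c·α/2 (c = 1.07829) but the intersection without the other primary
reverts to a cross-block Bonferroni level α/2. Adding δ-weight edges
between the primaries (and reducing the primary→secondary edges to 1 − δ)
raises the primaries' downstream weights to (1+δ)/2; consonance requires
(1+δ)/2·α ≥ c·α/2, i.e. δ ≥ c − 1 ≈ 0.07829. `min_consonance_delta`
finds the bound by bisection (tolerance 1e-6) on the full consonance check
rather than this one binding constraint, so it remains correct for other
correlation strengths; it grows with the within-primary correlation and
reaches 1 (a degenerate graph) as the correlation reaches 1.

## Numerical choices

- Bivariate normal rectangle probabilities use the exact Owen's-T
  representation (`scipy.special.owens_t`), vectorised, with the ρ = ±1
  limits (min / boundary form) special-cased; verified against scipy's
  quadrature to 2e-16. Dimension ≥ 3 uses
  `scipy.stats.multivariate_normal.cdf`, which is deterministic across
  calls for fixed input in this configuration.
- Critical constants are found with `brentq` on [1, (1−1e-12)/(α·max w_j)],
  xtol 1e-10. At c = 1 the blockwise probability is at most α (Bonferroni),
  so the bracket always contains the root; a residual ≥ −1e-12 at c = 1
  short-circuits to the pure Bonferroni constant.
- All weight and probability comparisons use a 1e-9 absolute tolerance;
  these are pure arithmetic quantities with no statistical noise. Rounding
  happens only at presentation (CLI and reports), never internally.
- Subsets are encoded as bitmasks internally, 0-based; all user-facing
  output uses the 1-based H1…Hm labels. Closure enumeration is guarded at
  m ≤ 20 (2^20 − 1 intersections is the practical desk-scale ceiling) and
  shares intermediate graphs along a depth-first removal tree, costing
  O(2^m·m²) rather than O(2^m·m³).
- Undefined weights (hypotheses outside J) are represented as absent
  entries, never 0 — a 0 weight is a meaningful local level.

## Synthetic data and what the simulations show

`simulation` draws z-statistics from a multivariate normal with a
user-specified correlation matrix and noncentrality vector (0 = true null)
— exactly the known-variance one-way layout the parametric test assumes —
and converts them to one-sided p-values. A single `default_rng(seed)`
stream generates one replicate matrix shared by all compared procedures, so
power comparisons are paired and the parametric ≥ Bonferroni dominance
holds replicate-by-replicate. The generator emulates the distributional
assumptions of the tests, not real trial data: no t-statistics (finite-df
variance estimation), no binary/survival endpoints, no staggered
information times. Passing FWER checks therefore validate the procedures
under their stated model; robustness to model departures is a separate
question the package does not address.

Monte-Carlo runs in the test suite use 10^5 replicates for error-rate
checks (binomial SE ≈ 5e-4 at α = 0.025, so α + 3·SE is a tight bound) and
2·10^4 for paired power comparisons; the m = 2 independent Holm case is
checked against its closed form 1 − (1 − α/2)². The per-replicate closed
tests are vectorised across the replicate matrix (blocks of size ≤ 2 use
the closed-form bivariate CDF); blocks of size ≥ 3 fall back to a
per-replicate loop.

## Known limitations

- No simultaneous confidence intervals, ε-edges (infinitesimal weights),
  resampling-based null distributions, or t-distributed statistics.
- Unknown-entry correlation patterns that are not block-diagonal are
  rejected outright.
- Consonance enforcement is implemented for the two-dose hierarchical
  δ-graph family; arbitrary graphs must be checked (and, if non-consonant,
  tested through the full closure).
- The closure is enumerated explicitly for the closed tests, so runtime
  grows as 2^m; the sequential Bonferroni shortcut is the only m-step path.
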