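# Methods

## The statistical model

Each cell cluster (or condition) supplies one p-value of differential
expression per gene. These are modelled as draws from the beta-uniform
mixture (BUM)

    f(x) = λ + (1 − λ) α x^(α−1),   x ∈ (0, 1],  λ, α ∈ (0, 1),

i.e. a fraction λ of genes are null (uniform p-values) and the rest carry
signal concentrated near zero (Beta(α, 1), with smaller α meaning stronger
signal). The density at x = 1, π̂ = λ + (1 − λ)α, is a conservative upper
bound on the null proportion.

**Fitting.** (λ, α) are estimated by maximum likelihood with bounded
L-BFGS-B from a fixed 5×5 grid of starts over [0.05, 0.95]², keeping the
best optimum; the box is [10⁻⁵, 1 − 10⁻⁵]². The multi-start matters because
the likelihood surface develops a flat, unidentifiable ridge
(λ + (1−λ)α ≈ 1) when the sample is nearly uniform; single starts can end
anywhere along it. The fit is deterministic given the data. A fit whose
log-likelihood gain over the pure-uniform model (log-likelihood exactly 0)
is below 7 — a likelihood-ratio cut at roughly p ≈ 10⁻³ for a
two-parameter alternative, conservative here because the null lies on the
boundary of the mixture family — is flagged *no-signal*, and detection
refuses to run on it unless forced: on the ridge the fitted parameters, and
hence the threshold below, are meaningless. At least 50 p-values are
required (configurable); zeros must be clamped upstream (the readers clamp
to the smallest positive normal double, ≈ 2.2×10⁻³⁰⁸, so that values far
below any rank-test output — single-cell marker tests can report 10⁻⁶³ —
survive the logarithm).

**FDR → τ.** For a target FDR q, the significance threshold τ solves the
model-based identity

    q = π̂ τ / F(τ),     F(τ) = λ τ + (1 − λ) τ^α,

(expected null fraction among genes called at τ over the expected called
fraction), which inverts in closed form:

    τ = ((π̂ − λ q) / (q (1 − λ)))^(1/(α−1)).

τ is strictly increasing in q and reaches 1 exactly at q = π̂; larger
targets are infeasible and are rejected with the attainable range. The
implementation is tested against an independent bisection of the identity,
so any algebraically equivalent form would pass. When α is so close to 1
that τ underflows, the threshold is reported as degenerate rather than
returning 0.

**Scoring.** Each measured gene receives the signed weight

    W(x) = (α − 1) (log x − log τ),

positive iff x < τ and zero at x = τ. One published description states the
opposite sign convention in prose; with α < 1 the prefactor is negative, so
small p-values score positive, which is the convention implemented here and
required for the optimisation below to make sense. Two useful consequences,
both exploited by tests and by the sweep: (i) for a fixed fit, changing the
FDR shifts *every* gene's weight by the same constant (α−1)(log τ − log τ′),
which makes the optimal module size non-decreasing in the FDR (a larger FDR
can only make bigger subgraphs more attractive, never smaller ones); (ii)
the detected node set depends on the fit only through τ — weights are an
increasing affine function of −log x — so sweeping the FDR explores every
operating point the scoring can produce.

## Module detection

Weights are attached to the PPIN restricted to measured genes
(`missing_policy="drop"`, the default). The alternative `"penalty"` policy
retains unmeasured proteins at the minimum observed score, letting them act
as connectors while never improving the objective on their own; it is a
deliberately simple stand-in for incorporating missing data and is flagged
as such in run metadata.

The *active module* is the maximum-weight connected subgraph (MWCS): the
connected node set S maximising Σ_{v∈S} W(v), with negative weights
allowed. The instance is first shifted into a prize-collecting Steiner tree
(PCST): with w_floor = min(0, min_v W(v)), prizes p_v = W(v) − w_floor ≥ 0
and uniform edge cost −w_floor. For any tree T,

    Σ_T p_v − (|T|−1)(−w_floor) = Σ_T W(v) − w_floor,

so PCST and MWCS optima coincide up to the constant offset; the min(0, ·)
clamp keeps edge costs at zero when all weights are positive, in which case
the whole component is trivially optimal.

**Exact solver.** The default backend certifies optimality:

1. *Reductions* (optimality-preserving): connected components are solved
   independently; degree-1 nodes with non-positive weight are removed
   iteratively (such a leaf never helps a solution of size ≥ 2, and
   single-node optima are tracked separately); adjacent positive-weight
   nodes are contracted into supernodes (an optimal solution touching a
   positive component can always absorb all of it at no cost).
2. *Cutting-plane MILP* on the reduced graph: one binary y_v per node,
   objective max Σ W(v) y_v, with connectivity enforced lazily. If the
   optimum of the current relaxation induces a connected subgraph it is a
   certified global optimum (the relaxation value is an upper bound).
   Otherwise, for each connected component C of the selection, any
   connected set containing a node of C and a selected node outside
   C ∪ N(C) must intersect the separator N(C), giving valid cuts
   y_u + y_v ≤ 1 + Σ_{s∈N(C)} y_s that the current selection violates;
   they are added and the MILP re-solved (HiGHS through
   `scipy.optimize.milp`). Components of each iterate double as feasible
   incumbents, allowing an early stop when the bound meets the incumbent.
   This formulation replaced an initial single-commodity-flow MILP whose
   big-M relaxation was too weak beyond ~100 nodes.

The exact backend accepts components up to a configured size bound (default
2,000 nodes after reduction) and raises an error beyond it rather than
silently approximating; a greedy backend (grow-from-best, then prune
negative leaves) is available for larger instances and marks its output
inexact. A brute-force enumerator over all connected induced subgraphs
(≤ 15 nodes) serves as the independent oracle in tests; the exact backend
matches it on 200 random instances.

**Determinism and ties.** All randomness is injected through seeds; the
solver itself is deterministic (fixed node ordering, deterministic HiGHS).
Among exactly tied optima the brute-force oracle returns the
lexicographically smallest node set, and cross-component ties are broken
lexicographically; within one MILP solve the tie falls to HiGHS's
deterministic choice (exact ties have measure zero for continuous scores).
The reported spanning tree is the BFS tree of the module from its smallest
node with sorted neighbour order. Objectives are recomputable from member
weights to 10⁻⁹.

**Sweep.** `fdr_sweep` fits the mixture once, re-derives τ per grid point,
and re-solves. Module size along the sweep is non-decreasing (see the
uniform-shift argument above); module *membership* is not nested, and tests
deliberately do not assume it.

## Enrichment

Detected modules are tested for over-represented annotation terms with the
one-sided hypergeometric (Fisher's exact) test and Benjamini–Hochberg
adjustment across terms, against a user-supplied gene→term mapping (GMT or
two-column TSV). The universe defaults to all genes that carried a p-value
in the run — the set that could have entered a module at all. This is a
flat test: no ontology topology or parent–child weighting is used, which is
a difference from GO-graph-aware tools; supplying a slim or pathway
collection keeps terms comparable. Terms with no universe genes are
skipped. The adjusted values are monotone after sorting by raw p and capped
at 1; a permutation test in the suite checks the raw p-values are calibrated
(empirical type-I proportion at 0.05 within [0.03, 0.07] over 1,000 random
modules, with set sizes chosen so the discrete null's attainable level is
~0.037 — hypergeometric discreteness makes very small configurations
conservative).

## Synthetic instances

The generator starts at the layer the method consumes: a random graph plus
one p-value per node. Defaults: 300 nodes, Barabási–Albert attachment with
m = 2 (the heavy-tailed degree distribution mimics interactome hub
structure; Erdős–Rényi is available), a 15-node planted set grown by
seeded randomised BFS (hence connected by construction), planted p-values
from Beta(0.1, 1) — median ≈ 10⁻³ — and Uniform(0, 1) elsewhere. One
`numpy` Generator per instance, seeded explicitly; identical parameters and
seed reproduce instances bit-exactly. The simulation does **not** model
read counts, dropout, normalisation, clustering, or the upstream rank test,
so passing recovery tests demonstrates the scoring-plus-optimisation
machinery, not robustness to single-cell noise; it also ignores degree bias
of annotation and interaction coverage present in real PPINs.

**Recovery benchmark.** `recovery_benchmark` generates seeded replicates
and scores each by the F1 between detected and planted nodes at the *best*
point of a fixed FDR ladder (0.05–0.5 in half-decade steps) — i.e.
recoverability at a well-chosen operating point of the M(FDR) curve, the
method's one free parameter. The oracle choice of grid point measures what
the curve contains, not what a blind FDR choice would find; with a single
global FDR the mean F1 is a few points lower, because about a third of
Beta(0.1, 1) draws exceed any reasonable τ (P(p > 0.03) ≈ 0.3) and those
planted nodes are recoverable only as connectors. Typical values with the
default generator: mean best-F1 ≈ 0.80–0.85 over 20 replicates.

## Problem sizes and numerics

The test suite and the acceptance script run instances of 150–300 nodes
(sweeps, recovery), 20,000-point mixture fits, and 200 oracle comparisons
at ≤ 12 nodes; these sizes characterise the method's behaviour well while a
full human interactome (~17k nodes, ~300k edges) remains within the exact
backend's reach after reduction for the sparse weighted subgraphs that
p-value tables induce. Tolerances: optimality comparisons at 10⁻⁹;
FDR-identity round trips at 10⁻⁹ (measured ~10⁻¹⁶); the score at τ is
exactly 0 in floating point because log x − log τ cancels exactly at
x = τ. Mixture-parameter recovery at n = 20,000 is within ±0.05 of truth.

## Known limitations

- The BUM fit is poorly identified when signal is weak or scarce; the
  no-signal guard refuses clearly degenerate fits, but moderately biased
  (λ̂, α̂) still shift τ relative to the ideal. Only τ affects the detected
  set, so an FDR sweep is the recommended usage.
- The penalty missing-data policy is a simple surrogate, not a calibrated
  treatment of unmeasured proteins.
- Enrichment ignores ontology structure and annotation bias.
- The greedy backend carries no optimality guarantee and is intended only
  for instances beyond the exact-size bound.
- Identifier handling assumes a gene↔protein bijection; no identifier
  mapping service is consulted, and mixed identifier schemes within one run
  are not supported.
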