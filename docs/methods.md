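# Methods

## Pathway model

A pathway is a signed directed graph. Nodes carry one of three kinds:
`single` (one protein), `alternatives` (redundant proteins, any one
suffices) and `complex` (all members required simultaneously). Edges are
`activation` or `inhibition`.

KGML mapping: relation subtypes *phosphorylation, dephosphorylation,
indirect, expression, compound* (and plain *activation*) are activations;
*inhibition, repression, ubiquitination* are inhibitions, and an inhibition
label wins over any co-occurring activation label (a phosphorylation that
inhibits its target is an inhibition). Unknown subtypes default to
activation with a warning. Compound-mediated relations are collapsed to a
direct activation edge between the flanking gene nodes. `group` entries and
endpoints of binding/association relations merge into one complex node;
edges re-point to the merged node and self-edges produced by merging are
dropped. Entries referencing other pathway maps (`map`/`maplink`) are
dropped with a warning — pathways are modeled independently, and
cross-pathway links have no defined semantics in this model. Node
identifiers are namespaced by pathway id so multi-pathway runs cannot
collide. Parallel edges with conflicting signs are resolved to inhibition,
consistent with the label-conflict rule.

## Circuits

Inputs are nodes with in-degree 0, outputs nodes with out-degree 0;
isolated nodes are neither. One circuit per connected (input, output) pair
carries **all** loop-free simple paths between them, enumerated by
iterative depth-first search (`networkx.all_simple_paths`) with a cap
(default 10,000 paths per circuit; beyond it the circuit is flagged
truncated). Shortest-path algorithms cannot produce this "all possible
sub-pathways" semantics, which is why plain all-simple-paths enumeration is
used. Circuits any of whose path nodes lie on a directed cycle (non-trivial
strongly connected component) are removed rather than broken: feedback
cannot be represented by a static transmission probability.

## Node activation probabilities

Each feature of a reference compendium is fitted with a two-component
mixture by EM. Candidate family pairs are normal–normal and gamma–normal
(the low-expression state is often heavy-tailed; the gamma pair is skipped
when values are not strictly positive). Initialization takes the two
highest peaks of a Gaussian KDE of the values (falling back to the 25th/75th
percentiles when unimodal); proportions start at ½. The normal M-step is
the standard weighted update; the gamma M-step matches weighted moments
(shape = m²/v, scale = v/m), since no closed-form shape update exists.
Convergence: relative log-likelihood change ≤ 1e−8, at most 500 iterations;
if no candidate converges the feature falls back to a single normal, flagged
and effectively non-informative (posterior ½ everywhere). The best
candidate by log-likelihood wins (equal parameter counts make BIC
equivalent here). The lower-mean component is labeled inactive.

A fit is flagged *degenerate* when one proportion is below 1% or the
component means are separated by less than one sample standard deviation —
both patterns mean the data behave as a single population and the
"active/inactive" split is not identified.

Posteriors are computed in log-space; where both component densities
underflow, the posterior is resolved by which side of the active mean the
value lies on. Probe → gene aggregation uses the 90th percentile (linear
interpolation): the strongest credible hybridization evidence without being
driven by a single outlier probe. Node probabilities: single → the gene's
value; alternatives → 90th percentile over all member genes' probes pooled;
complex → minimum over member genes (the scarcest member limits complex
integrity). Probes mapping to more than one gene are discarded before any
aggregation. A node none of whose genes are measured is *non-informative*:
it contributes no factor to path products, and circuits are annotated with
a completeness fraction instead of having states forced by imputing 0 or 1.

## Transmission probability

For a linear path, every on-path node is required active until an in-path
inhibition edge flips the required state of everything downstream; a second
in-path inhibition restores activating parity. The source of an inhibition
edge must itself be present to transmit its repressive signal. For every
on-path node required active, sources of inhibition edges into it from
outside the path are required inactive; a node required both active and
inactive makes the event impossible (probability 0). A path delivers an
*activating* signal to the effector only when its net parity is activating;
only such paths count toward circuit activation. The exact repression
convention is a documented modeling choice and is isolated in
`propagation.path_requirements` so it can be swapped.

Node activations are independent Bernoulli events shared across paths, so
overlapping paths are correlated exactly through their shared nodes. The
union over path events is computed by inclusion–exclusion, each
intersection being the product over the merged requirement set. This is
exponential in the number of paths; up to 20 paths (≈10⁶ terms) it is exact,
beyond that a seeded Monte-Carlo estimate over 10⁵ Bernoulli node-state
draws is used and flagged. Accumulated alternating sums are clipped to
[0, 1].

## Differential testing

Circuit-level comparison uses the two-sample Wilcoxon rank-sum test: exact
p-values when both groups have ≤ 25 samples and the data are tie-free,
otherwise the tie-corrected normal approximation with continuity correction
(the convention of the reference R implementation). Identical constant
groups return p = 1. The location estimate is the Hodges–Lehmann shift
(median of pairwise condition2 − condition1 differences); its sign gives
the activated condition, ties give no direction. Benjamini–Hochberg
adjustment is applied within each pathway's circuit set by default — each
pathway is interpreted as one family of hypotheses — with a global mode for
multi-pathway experiments where a single family is preferred. Significance
is adjusted p < α (default 0.05).

## Synthetic data

The fixture set contains: the bifurcating toy topology (3 receptors, 3
effectors, 5 circuits, A→H running through A,B,D,F,H and A,B,D,G,H — the
printed paths; the remaining edges are a synthetic completion consistent
with the input/output/circuit counts), a chain exercising complex and
alternatives nodes, a chain with an external inhibitor, a pathway whose
only route crosses a 2-cycle (to exercise loop removal), and seeded random
DAGs with inhibitions. Probe maps assign 3 probes per gene.

**Null simulation.** Every probe of every node gets one base activation
probability (grid 0.1–0.9) plus per-sample Normal(0, 0.05) noise, clipped
to [0, 1]; each dataset (n ∈ {10, 20, 50, 100}) is split into two halves
and compared. Because both halves share one generator, every significant
circuit is a false positive. This mode operates directly on probabilities,
bypassing mixture fitting, so it isolates the aggregation + propagation +
testing chain. The default replication is 100 datasets per cell (the
package's standard desk-scale setting; larger replications are a
parameter). The raw rank-test rejection rate on this continuous null sits
at the test's nominal level by construction — measured levels are 3–5% per
cell — while circuits *declared significant* by the full methodology
(within-pathway FDR < 0.05) are far rarer (≈1–3% per cell), since BH under
a complete null bounds the probability of any rejection per pathway by α.

**Study generator.** Reference samples draw each probe from the assumed
hard two-state mixture (Normal(4,1) / Normal(9,1), π₁ = ½ — a
well-separated, realistic log-intensity scale). Study samples instead carry
a continuous latent activity per gene, Normal(mean, 0.1) clipped to [0, 1],
mapped linearly between the component means with Normal(0, 0.5) probe
noise: transcriptional activity in real samples is graded, not binary, and
this keeps circuit activities continuous. Genes on designated circuits get
latent mean 0.5 + effect in condition 2 (default effect +0.4, clipped with
a warning if outside [0, 1]). Ground truth is the set of circuits
containing any shifted gene. What this generator does **not** emulate:
probe-specific affinities and cross-hybridization, correlated biological
pathways outside the shifted circuit, batch effects, and platform
normalization artifacts — passing tests therefore demonstrate correctness
of the statistical machinery under the model's own assumptions, not
robustness to those real-data phenomena.

## Numerical and design choices

- Percentiles use linear interpolation (`numpy.percentile`).
- All randomness flows from explicit `numpy.random.default_rng` seeds; CLI
  runs record the seed in `manifest.json` and format TSV floats to 6
  significant digits for stable file-level comparisons.
- The output-node definition (out-degree 0) treats effectors as terminal,
  matching the worked example's topology; defining outputs as "any node
  with outgoing interactions" would make nearly every node an output and
  dissolve the circuit concept.
- Known limitations: no feedback/kinetic modeling, no cross-pathway signal
  propagation, two conditions only, no paired designs or covariates, and
  RNA-seq counts are not modeled (inputs are assumed pre-normalized,
  approximately continuous intensities).
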