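# Methods

This note documents the model, the algorithmic choices and the numerical
conventions implemented in `mvphi`, and what the synthetic generators do
and do not emulate.

## System model

A network is an ordered list of elements with state counts
`(S_1, …, S_n)` and an `S × S` row-stochastic TPM over joint states,
`S = ∏ S_i`. Joint states are indexed little-endian (element 0 varies
fastest); the same convention applies to file formats and repertoires.
TPM rows must sum to 1 within `1e-6` (they are then renormalized
exactly); larger deviations are rejected rather than silently fixed.

The analysis requires conditional independence of the elements given the
previous joint state (the Markov factorization). `validate_network`
checks it by reassembling the TPM from the per-element conditionals
(absolute tolerance `1e-10`, configurable); deterministic truth-table
TPMs always pass, since point masses factorize trivially. Element `j` is
a *parent* of `i` when two prior states differing only in `j` give `i`
different conditionals; the adjacency matrix is inferred this way and, if
supplied by the user, cross-checked.

Networks with a single element are allowed: their CES has at most one
distinction, no system cut exists, and Φ is defined as 0.

## Repertoires

All marginalization of unconstrained elements uses the uniform
("maximum-entropy perturbation") distribution, in both temporal
directions. The effect repertoire over a purview is the **product of
single-element effect repertoires** (virtual elements); correlations in
next states induced by shared marginalized inputs are intentionally not
tracked, which matches the interventional reading of the TPM. The cause
repertoire factorizes over *mechanism* elements: each mechanism element
contributes the likelihood of every prior purview state (non-purview
priors summed out per factor), the factors are multiplied and the product
normalized. For multi-element mechanisms this differs from a joint
Bayesian inversion of the whole mechanism state; the factored form is the
convention adopted here. A mechanism state that cannot be produced by any
prior purview state yields a *null* cause repertoire; the mechanism then
specifies no cause and its φ is 0 (not an error).

## Mechanism-level integration

Partitions of a (mechanism, purview) pair are **tripartitions**: each
mechanism element and each purview element is assigned to one of three
part slots; parts with both sides empty are dropped; partitions are
deduplicated under slot permutation; the identity assignment (everything
in one part) is excluded. A part with an empty mechanism contributes the
unconstrained repertoire over its purview; a part with an empty purview
contributes the scalar 1. With one mechanism and one purview element the
only partition is the full cut — so φ is always bounded by the AID
between the constrained and the unconstrained repertoire, which also
guarantees φ is finite (the unconstrained repertoire is strictly positive
wherever the intact one is).

The repertoire measure is the absolute intrinsic difference,
`AID(p, q) = max_s p(s)·|log2(p(s)/q(s))|`, in bits. Terms with
`p(s) = 0` contribute 0; `q(s) = 0 < p(s)` contributes +∞ (full
determination destroyed), optionally capped via `RunConfig.phi_cap`
(default: uncapped). The measure sits behind a single function so that a
different repertoire distance can be swapped in; no alternative is
currently implemented (notably, no earth-mover's distance — it is not
defined here for mixed-radix purviews). The state attaining the maximum
at the minimizing partition is recorded as the specified cause/effect
state; ties take the first state in index order.

φ of a pair is the minimum AID over tripartitions (ties: first partition
in the deterministic enumeration order). The MICE maximizes φ over all
non-empty purviews; ties prefer the larger purview, then the
lexicographically first. φ values below `1e-10` are clamped to exactly 0
(float round-off from repertoire products); distinction φ is
`min(cause φ, effect φ)`, and no normalization by partition or part size
is applied anywhere.

Two shortcuts accelerate the search without changing results: (i) on the
effect side, if some purview element's single-element repertoire equals
its unconstrained repertoire, detaching it reproduces the intact
repertoire exactly and φ = 0; (ii) partitions that sever the same
mechanism–purview dependencies (differing only in how mechanism elements
with empty purviews are grouped) are evaluated once.

## System-level integration

System cuts are the `2^n − 2` ordered bipartitions: connections from one
part into the other are severed by uniformly averaging the affected
conditionals over the severed inputs (independent noise); connections
within parts and in the reverse direction stay intact. Cuts are
idempotent and never create parents. Φ is the minimum over cuts of the
total |φ lost| from the intact CES, with each intact mechanism's purviews
re-searched on the cut network and destroyed distinctions contributing
their full φ; new mechanisms are not searched under a cut (cuts are
assumed not to create distinctions). Cut ties resolve to the first cut in
(from-part size, lexicographic) order.

`sia` requires the analyzed state to be *reachable* (a nonzero TPM
column) and otherwise raises with advice to pick a state from the TPM;
drivers that must evaluate possibly unreachable mapped states (see the
binarization correlation below) disable the check explicitly.
`major_complex` evaluates every non-empty subset with external elements
frozen in their current state (inputs conditioned, outputs dropped),
skipping subsystems whose conditioned TPM cannot reach their state, and
breaks Φ ties toward the larger, then lexicographically first subset.

Effective information is `I(X_t; X_{t+1})` under a uniform input
distribution — a property of the TPM alone, invariant under regrouping
elements, unlike Φ.

## Binarizations and coarse-graining

*Van Ham*: an `m`-state component becomes `m − 1` ordered Boolean
constituents; value `k` is encoded as `k` ones followed by zeros. The
mapping is a bijection onto the *admissible* binary states, and the
binarized function is partial — non-admissible states get no successor.

*Fauré–Kaji* (requires an asymptotic function, i.e. every component's
target is 0, its current value, or its maximum): any binary state is read
through the bit-sum of each constituent group; the target is written as
all zeros (target 0), all ones (target max) or bits-unchanged (maintain).
The "maintain" branch keeps raw constituent bits even on non-admissible
states — the only reading that is total and coarse-grains back exactly;
on the p53 model this branch never fires (targets are always 0 or max).
Coarse-graining the result by bit sums reproduces the original function
exactly (property-tested on random asymptotic functions).

*Tonello*: each component's coarse (bit-sum) value moves one step toward
its target per update and is re-encoded in threshold form. This matches
the published worked example bit for bit (golden-file test) and is
well-defined for any deterministic function, but the defining reference
is external; beyond p53-like systems the implementation is best-effort.

*Probabilistic binarization* (experimental, conjectural): a target value
`v` is mapped onto all constituent bit patterns with `v` ones with equal
probability. The result coarse-grains back exactly for arbitrary
deterministic functions but generally violates per-element conditional
independence, so it is suitable for coarse-graining demonstrations, not
for causal analysis.

`coarse_grain` aggregates a TPM under a grouping of elements and a total
micro→macro state map: rows are averaged uniformly within each macro
state, columns summed. Macro elements must keep at least two states.

## Generators and study conditions

Random deterministic networks of a class (digits = per-element state
counts) draw one uniform successor per row — the minimal reading of
"randomly generated" — so all `S^S` deterministic TPMs are equally
likely. Shared-TPM classes (e.g. `44(2222)`) reuse the source class's
draw and reinterpret the radices. Random asymptotic evolution functions
draw each component's target uniformly from the *set* {0, current, max}
(duplicates collapse, e.g. two options when current = 0). All generators
are reproducible from a seed.

Survey state choice: "one state chosen at random from the TPM" is
implemented by drawing a row uniformly and sampling its successor, which
is reachable by construction; for deterministic TPMs this weights a state
by its number of predecessors. The binarization-correlation driver
evaluates the successor of the all-zero state (the first state stored in
the TPM) for the same reason; its threshold-mapped image is reachable in
the Fauré–Kaji binarization by construction but may be unreachable under
Tonello, where it is evaluated with the reachability check disabled and
flagged in the records.

The three-neuron circuit: a neuron fires iff it is currently silent
(otherwise refractory) and at least one other neuron is active; a firing
neuron bursts (two spikes) with probability `p_burst` (default 0.2, the
condition under study). Refractoriness does not distinguish one- from
two-spike activity. The binary reading merges firing levels and is
deterministic; it equals the coarse-grained ternary TPM exactly. States
with all three neurons active are structurally unreachable in both
readings; state averages are taken over reachable states.

What the generators do *not* emulate: structured topologies (modular,
spatial), correlated or biased transition sampling, measurement noise,
and asynchronous update schemes of regulatory-network practice (the
causal analysis always reads the synchronous evolution function). Passing
tests therefore certify the analysis pipeline under idealized uniform
random dynamics and the two hand-built biological fixtures, not
performance on empirically estimated TPMs.

## Problem sizes and defaults

The analysis is exponential in the element count (mechanisms × purviews ×
partitions × cuts); up to ~5–6 elements is comfortable, and the state
count per element matters far less than the element count. Default
survey sizes are desk-scale — 200 networks for 2–3-element classes in the
summary drivers and the acceptance script (60 for the 27-state class
333, 100 functions for the binarization correlation) — chosen so the
reported means and correlations are stable to well within their sampling
bands; all drivers take `n` and a seed for larger runs. Bootstrap CIs use
1000 percentile resamples at level 0.95.

## Known limitations

- The tripartition family and the AID tie-break conventions are one
  defensible reading of a formalism whose exact partition set is defined
  in external and partly forthcoming work; small systematic differences
  (a few percent in mean CES size on random classes) against other
  implementations' variants are expected.
- Cause-side factorization over mechanism elements (rather than joint
  inversion) is a convention, documented above.
- No relations between distinctions, no asynchronous dynamics, no
  continuous or non-Markovian systems, no performance parity with
  binary-specialized implementations.
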