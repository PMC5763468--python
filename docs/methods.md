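# Methods

## Problem setting

A generic signaling map is a signed directed graph: protein and
transcription-factor (TF) nodes, activation (+1) and inhibition (−1)
edges, plus a small set of *output* nodes representing cell functions.
Edges into output nodes are fixed arithmetic definitions (the output
state is the signed sum of its TF states) and are never pruning
candidates; all other edges are candidate reactions that a given cell
line may or may not use.  Perturbation data are log2(treatment/control)
phosphoprotein ratios for a subset of nodes (the *observed* nodes) under
several compound treatments; literature priors pin the direction of known
compound targets.

## Discretization

Ratios are discretized at a fold-change threshold t > 1 (default 1.2):
+1 when ρ ≥ log2 t, −1 when ρ ≤ −log2 t, 0 in between; boundary values
are classified as regulated (inclusive ≥/≤).  Missing measurements stay
missing and contribute neither mismatch terms nor constraints.  When a
condition is measured in replicate columns, replicates are averaged on
the log2 scale before thresholding — a deliberate choice; thresholding
each replicate and voting would be the main alternative, but averaging
uses the quantitative information and is the convention for log-scale
ratios.

## The integer program

Variables, per condition k:

* x_{j,k} ∈ {−1,0,1} for every protein/TF node (integer domain), split
  into sign binaries x = x⁺ − x⁻ with x⁺ + x⁻ ≤ 1; output-node states
  are integers bounded by the sum of absolute coefficients of their
  definition.
* z_{i,k} ∈ {0,1} per candidate edge: 0 means reaction i takes place
  under k (the inverted convention is kept as in the discrete-modeling
  literature).
* a_{j,k} ∈ {0,1} per observed, non-missing pair: mismatch indicator,
  enforced by m − x ≤ 2a and x − m ≤ 2a.  The binary indicator replaces
  the squared error (m − x)², which would penalize a 2-unit miss four
  times as much as a 1-unit miss and bias the fit.
* y_i ∈ {0,1} per candidate edge (training only): edge removed.
* Auxiliary binaries: four AND products w per (edge, condition)
  linearizing p = x_u·x_d from the endpoint sign splits
  (w ≤ b₁, w ≤ b₂, w ≥ b₁+b₂−1; p = w⁺⁺ + w⁻⁻ − w⁺⁻ − w⁻⁺), and
  delivered-signal indicators pos/neg per (edge, condition).

Constraints:

* **Removal/occurrence coupling.**  z_{i,k} ≥ y_i (a removed edge occurs
  nowhere) and Σ_k z_{i,k} ≤ L − 1 + y_i (a kept edge occurs under at
  least one of the L conditions).
* **No missing edges.**  −1 ≤ p + z ≤ 1 for activations and
  −1 ≤ p − z ≤ 1 for inhibitions: when the endpoints co-change
  consistently with the edge sign (p·sign = 1) the reaction is forced to
  occur, so an edge that explains data cannot be pruned merely to shrink
  the network.
* **Parent activity.**  1 − z ≤ x⁺_u + x⁻_u: a reaction cannot occur
  from an unchanged parent.
* **Linking-pattern support.**  For each node d with incoming candidate
  edges, x⁺_d ≤ Σ pos_{i,k} and x⁻_d ≤ Σ neg_{i,k} over its incoming
  edges, where pos_{i,k} ≤ (delivered-positive indicator: u⁺ for an
  activation, u⁻ for an inhibition) and pos_{i,k} ≤ 1 − z_{i,k} (neg
  mirrored).  A node can change only if some occurring reaction delivers
  a matching signal; conflicting parents are arbitrated by the data-fit
  objective.  Root nodes (no incoming candidate edges) are exempt — they
  model receptor-level entry points — and so is a node pinned by prior
  knowledge in that condition, since the compound acts on it directly
  (the exemption can be disabled via ``exempt_prior_targets=False``).
* **Priors.**  A literature target fixes x_{j,k} to the stated direction
  (with the ternary domain, "down" ⇔ x ≤ −1 ⇔ x = −1).  A prior that
  contradicts an observation wins, and the conflict is logged; priors on
  output nodes are rejected.
* **Outputs.**  x_out = Σ coeff·x_TF as equalities.

Objective: min Σ a + γ Σ y with γ ∈ (−1/|E_candidate|, 0), default the
interval midpoint −0.5/|E_candidate|.  Because |γ|·|E_candidate| < 1,
removing every edge gains less than one mismatch unit: the optimal fit
term always equals the best achievable fit, and γ only selects the
sparsest network among equally fitting ones (verified against the
enumeration oracle on 100 random instances in the test suite).

Prediction mode drops the y variables and the coupling constraints and
minimizes Σ a alone on the pruned topology; occurrences remain free per
condition subject to the support/parent/missing-edge constraints.

## Decoding and readouts

Solver values are rounded (integrality tolerance 1e−6 in the backend;
decoding asserts integrality within 1e−4) and the removal/occurrence
logic is re-checked on every solution.  Edge labels for response
networks: an occurring edge is "up" or "down" by the sign of its
delivered signal sign(edge)·x_parent (an occurring edge never has an
unchanged parent); a non-occurring edge between two unchanged endpoints
is "no-change"; any other non-occurring edge is "not-occurring".
Fixed TF→output links are labelled by their delivered signal alone.

Fitting precision is the exact-match fraction over observed, non-missing
(protein, condition) pairs — the unique definition consistent with ratio
arithmetic such as 125/150 = 83.33% and 14/15 = 93.33%.  The similarity
score between compounds is the Pearson correlation of their 4-component
outcome vectors; it is undefined (raises) for a zero-variance vector
rather than silently returning 0.  Topology similarity between an
inferred network and a reference is |shared edges| / |reference edges|.

## Multiple optima and determinism

The program can have several optimal solutions (the data rarely pin every
hidden node).  No tie-break is imposed; the backend's first proven
optimum is reported.  HiGHS is deterministic for a fixed model, so runs
with identical inputs reproduce bit-for-bit; the run manifests record
seed and a config hash.  The enumeration oracle reports the number of
optimal assignments, which tests use to know when a uniqueness assertion
is meaningful.

## Synthetic data

The generator emulates the study conditions the method targets: a layered
acyclic signed map whose terminal TFs feed output nodes, a hidden subset
of candidate edges that is truly absent, and per-condition perturbations
propagated by sign over the true subnetwork (node state = sign of the
summed delivered signals, 0 on a tie; outputs carry the signed sum).
Defaults mirror the packaged map's shape: 35 nodes, 50 edges (11 fixed
TF→output links), 4 outputs, 11 TFs, 30% inhibitions, 10 conditions,
25% of candidate edges truly absent, 50% observation coverage, no noise.
Perturbations hit two root (receptor-level) entry points per condition —
compounds typically engage more than one entry point, and a single root
perturbation rarely propagates past the hidden removals to the output
layer.  Noise flips an observed entry to one of the two other ternary
values uniformly at the given rate, the simplest exchangeable corruption
for precision/recall curves.  Only full-map roots are perturbed, so
noise-free profiles are exactly feasible for the inference program and
its fit term is provably 0 — asserted for every generated instance in
the tests.

What the generator does not emulate: measurement correlation across
proteins, compound-specific off-pathway activity, dose dependence, or
feedback loops (the propagation model requires acyclicity; the MILP
itself does not).  Passing recovery tests therefore show correctness of
the optimization and decoding machinery under the model's own
assumptions, not performance on real phosphoproteomic data.

## The enumeration oracle

For instances with ≤ 8 signaling nodes, ≤ 8 candidate edges and ≤ 2
conditions, `validation.brute_force_solve` enumerates all ternary
assignments per condition, filters by priors and support, and derives the
optimal occurrences and removals analytically: an edge is forced to occur
under k iff sign·x_u·x_d = 1, and can be removed iff it is forced in no
condition (removal is then always rewarded).  Per-condition results are
reduced to (forced-edge bitmask → minimal mismatch) tables and combined
across conditions, shrinking the search from 3^(nL)·2^(|E|(L+1)) to
3^(nL) plus a 2^|E|-sized merge.  The oracle shares no code with the MILP
path.

## Problem sizes and runtime choices

The packaged 35-node map with 10 conditions yields 350 integer variables,
~3.5k binaries and ~8.9k constraints, solving in about 2 s.  Oracle
cross-checks use 100 random instances with 3–6 nodes, density 0.3–0.6
(max 7 edges), 30% inhibitions, 1–2 conditions, 60–100% observation
coverage and ~15% missingness (seeds 1–100).  Recovery and
cross-validation studies default to 12–14-node maps with 4–8 conditions,
sized so the full suite runs in seconds while still exercising multi-
parent linking patterns.

## Known limitations

* The constraint system treats parents of a node as independent (OR-type
  linking); AND-gated regulation (complex formation) is not expressible.
* Fitting precision on hidden nodes is unknowable; precision is computed
  on the final optimal states of observed nodes only.
* The pruned network is one optimal topology; alternate-optima
  enumeration is out of scope.
* GCT input follows the 1.3 layout (one version line, one dimension
  line, leading metadata rows/columns); GCTX/HDF5 is not supported.
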