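# Methods

## The model

`dyadnet` implements a generative dyadic model for binary networks
that separates two scales of structure. Every actor *i* carries an
*activity* a_i ∈ [0, 1] and every event *j* a *popularity*
b_j ∈ [0, 1] (the microscopic, node-specific scale). Every node also
carries a latent class label — c_i ∈ {0..q−1} for actors,
d_j ∈ {0..l−1} for events — and a q×l *preference* (block) matrix π
with entries in [0, 1] holds the linking tendency between classes (the
mesoscopic scale). Dyads are conditionally independent given the
parameters, with Bernoulli link probability

    p_ij = a_i · b_j · π_{c_i d_j}.

Because every factor lives on [0, 1], p_ij is automatically a valid
probability; up to a bounded reparametrisation the model is an
exponential random graph with additive log-odds fields. Clamping
a ≡ b ≡ 1 (`node_effects=False`) removes the microscopic scale and
leaves a plain stochastic block model, which the package treats as a
first-class configuration for comparison experiments.

Unipartite variants: undirected networks use a single per-node
activity entering both ends of an edge (p_ij = a_i a_j π_{c_i c_j},
π symmetric). Directed networks give each node an activity (out) and
popularity (in) parameter and one class label; each unordered node
pair is a 4-state dyad (x_ij, x_ji) whose state weights are the two
independent Bernoulli directions with the mutual state reweighted by a
symmetric class-pair reciprocity ρ_{rs} ≥ 0 and renormalised per dyad.
ρ = 1 recovers independent directions; ρ > 1 enriches reciprocated
pairs.

Known identifiability caveat: (a, b, π) share a joint scale freedom
(a → s·a, π → π/s). The bounded supports and priors break it only
softly, so individual parameter values are comparable only up to this
scale; identifiable quantities are the dyad probabilities p_ij,
expected degrees and the class partition. All recovery checks use
those.

## Inference

The posterior over all parameters is approximated by belief
propagation on the factor graph of the dyad-factorised likelihood.
Each dyad is one factor; actor variables attach to all factors in
their row, event variables to their column, and the block-level
variables (π, ρ) to every factor. Two message families circulate:
R-messages (factor → variable) carry the expected likelihood of one
dyad as a function of the target variable with all other adjacent
variables integrated out under their incoming messages; Q-messages
(variable → factor) are cavity posteriors — prior × all incoming
R-messages except the destination factor's. At a fixed point the
marginal posterior of a variable is its prior times all incoming
R-messages, normalised.

Numerical representation: continuous parameters are carried as
weights on B equally spaced grid points (default B = 25 on [0, 1];
ρ on [0, ρ_max], default ρ_max = 10). For binary dyads the Bernoulli
likelihood is linear in each continuous parameter separately, so the
R-message expectations depend on incoming messages only through their
means and the grid quadrature is exact given the messages. For the
4-state directed dyad the per-dyad renormaliser makes the likelihood
nonlinear in the non-target parameters; there the engine sums exactly
over class pairs and over the target's own grid while evaluating the
other continuous parameters at their incoming-message means. This is
the package's own numerical choice for the directed variant; it keeps
the cost per sweep proportional to (dyads)·q²·B.

Schedule: synchronous sweeps (all R, then all Q) with damping
λ = 0.5 by default; convergence when the largest absolute weight
change falls below 1e−6, capped at 500 sweeps (non-convergence is
flagged on the summary, not raised). All cavity products are
accumulated in log space with explicit −inf bookkeeping so that grid
points vetoed by a single factor are handled exactly.

### Fixed-point multiplicity and restarts

The joint posterior over labels and block parameters supports a
label-symmetric message-passing fixed point. Empirically this fixed
point is *locally stable* even on strongly structured data: the block
parameters are global variables whose posteriors lock tightly onto the
average density before small class tilts can grow, so perturbative
symmetry breaking (initialisation noise of any realistic amplitude)
decays. Truth-initialised messages, by contrast, stay at an
informative fixed point and recover planted structure exactly — the
update equations are not the issue; the basin structure is.

The engine therefore explores fixed points by restarting: the first
restart uses the perturbed-prior initialisation (per-variable
multiplicative noise, ε = 0.01, seeded); each further restart seeds
the π messages with a high/low block pattern (assortative and
disassortative orientations first, then random non-constant patterns,
high 0.85 / low 0.10, Gaussian-shaped on the grid with width 0.15) and
holds them fixed for `burn_in` sweeps (default 20) while the class
messages condense, then releases everything. Pattern restarts that
fall back to the symmetric point are abandoned early (they duplicate
the plain restart). The returned fixed point is the one with the
highest **Bethe evidence**,

    log Z ≈ Σ_a log Z_a + Σ_i log Z_i − Σ_(i,a) log Z_ia,

with Z_a the expected dyad likelihood under incoming messages, Z_i
the variable-posterior normaliser and Z_ia the per-edge message
overlap. On weakly informative data (tiny networks) the symmetric
fixed point wins and the marginals match exhaustive enumeration; on
planted block structure a broken fixed point wins and recovers the
classes. Defaults: `n_restarts = 5`, `burn_in = 20`.

Class labels are identified only up to permutation at any broken
fixed point; all partition comparisons in the package use normalized
mutual information, which is permutation-invariant.

Priors default to Beta(1,1) (uniform, renormalised on the grid) for
a, b, π; uniform on [0, ρ_max] for ρ; uniform categorical for labels.
Other Beta shapes can be supplied per parameter family.

## Null ensembles and motif statistics

Two nulls are provided. The *model-based* ensemble draws networks
from fitted parameters (independent dyads; 4-state draws for the
directed variant), preserving node-specific and group-specific
structure in expectation. The *link-randomized* ensemble applies
double-edge swaps to the observed directed network within two
categories — single arcs and reciprocated pairs — rejecting any move
that would create self-loops, duplicate arcs, or convert a single arc
into a reciprocated pair (or vice versa). This conserves every node's
in-, out- and reciprocated-degree exactly; the default randomization
depth is 10 attempted swaps per arc. Exact uniform sampling of the
constrained graph space and mixing diagnostics are out of scope.

The triad census classifies all C(n,3) node triples into the 16
standard MAN-coded classes (003 … 300). Significance per class is the
Z-score against the ensemble sample mean and standard deviation, with
two conventions: zero-variance classes score Z = 0 when the
observation equals the ensemble constant and an infinite sentinel
otherwise, and counts are additionally normalised by the ensemble
mean. Box-plot quartiles and 1.5×IQR whiskers are exported so that
whisker-based flagging can be compared with the default |Z| > 2
operationalisation of "strongly over/under-represented" (the
threshold is a package choice; the underlying notion is qualitative).

## Evaluation and prediction

Partition overlap uses NMI = 2 I(X;Y)/(H(X)+H(Y)) from the empirical
contingency table, with the conventions NMI = 1 when both partitions
are trivial and 0 when exactly one is. Link prediction ranks dyads by
p_ij at posterior-mean point estimates (means, not MAP grid points:
smoother probabilities and a deterministic tie structure), descending,
ties broken row-major; the scope is either the dyads absent from
training (new links) or present (repeat observations). Recovery
curves report the fraction of held-out positives within each top
fraction of the list; under random ranking the curve follows the
diagonal, which is the chance reference.

## Synthetic data

All tests run on planted-model draws with known ground truth. The
generic generators (`plant_bipartite`, `plant_directed`) assign class
labels in blocks by proportion, draw activities/popularities uniformly
on configurable intervals, and sample the network from the model. The
default planted condition used by the recovery checks is a 60×40
bipartite network, two equally sized classes per side, preference
contrast 0.9/0.05, activities and popularities uniform on [0.3, 1].

`davis_shape_fixture` emulates the shape and difficulty profile of
the classic 18-women × 14-events attendance record with two social
classes of 9 women each: each class has its own 7-event class
(preference 0.95 within, 0.04 across), activities spread on
[0.45, 1], and event popularities strongly bimodal (sparsely attended
gatherings at 0.15–0.3 vs. popular events at 0.9–1). The bimodal
attendance profile is what misleads the plain block model into
splitting events by attendance count — the qualitative failure the
node-effects model corrects. The design was chosen once against the
Bayes-optimal classifier under the true parameters (median NMI 1.0
over seeds; a one-sided design with "universal" events turned out to
be information-theoretically too noisy for any method at this size).

What the generators do *not* emulate: degree-degree correlations
beyond the model, transitivity/clustering, temporal structure, and
the long-tailed degree distributions of real gene–disease data.
Passing tests therefore demonstrate correctness of the inference and
analysis machinery under the model's own assumptions, not robustness
to model misspecification.

## Problem sizes and numerical choices

The shipped checks use: tiny networks (≤ 3×3, B = 5, q = l = 2) for
exact-enumeration comparisons (total-variation tolerance 0.05);
60×40 / B = 15 for planted recovery; 18×14 for the attendance
contrast; 40-node directed networks with 200-replicate ensembles and
10–20 repetitions for motif calibration; 30×20 with 10–20 seeds for
prediction lift. These sizes keep every stage well resolved while the
whole suite runs in minutes on one core; all generators and the
engine are deterministic given seeds.

Degenerate inputs: dyads whose four state weights are all zero raise
a degeneracy error; messages that collapse to zero weight raise a
normalisation error naming the offending factor; empty networks are
valid inputs (log-likelihood 0 when consistent); networks with fewer
than three nodes yield an empty triad census.

## Known limitations

- The number of classes q (and l) is a user-set resolution parameter;
  no model selection over q is provided.
- Directed-variant messages use the mean-field evaluation described
  above rather than full quadrature over non-target parameters.
- The Bethe evidence is itself an approximation; on near-threshold
  data the selection between symmetric and broken fixed points can be
  conservative.
- Reciprocity estimates for class pairs with few dyads stay close to
  their prior (uniform on [0, ρ_max]), i.e. they are reported with
  appropriately wide posteriors rather than shrunk to a point.
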