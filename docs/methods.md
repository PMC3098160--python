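# Methods

This note documents the models, estimators and numerical choices behind
`grninfer`, in the order data flows through the pipeline.

## 1. Benchmark data generator

### Topology

`generate_source_topology` produces a weakly connected signed digraph with
heavy-tailed out-degrees by preferential attachment on the regulator side,
emulating the hub-dominated structure of transcriptional networks (defaults:
150 genes, mean degree 2, 60% activating edges).  Benchmark instances are
grown out of the source network from a random seed node by repeatedly
absorbing a uniformly chosen neighbour until the requested size is reached;
the induced signed subgraph is the ground truth.  Growth by neighbour
absorption preserves local modules and hubs, unlike uniform node sampling.

### Kinetics

Each topology is dressed with gene-level ODE kinetics in one of two modes.

**Hill mode (default).**

    dx_i/dt = m_i * prod_{j in act(i)} (1 + a_ij h_ij(x_j)) / (1 + a_ij)
                  * prod_{j in rep(i)} 1 / (1 + a_ij h_ij(x_j))
              - delta_i x_i,        h_ij(x) = x^n_ij / (K_ij^n_ij + x^n_ij)

Production is multiplicative over regulators and bounded in `(0, m_i]`, so a
finite positive wild-type steady state always exists.  Parameter ranges
(units: expression/time for `m`, 1/time for `delta`, dimensionless
otherwise):

| parameter | default range | rationale |
|---|---|---|
| basal rate `m` | U(0.5, 1.5) | sets the expression scale ~ m/delta |
| decay `delta` | U(0.05, 0.2) | relaxation times 5–20 time units: resolvable by the 8-unit sampling interval of the standard design (26 points over [0, 200]); faster decay makes the sampled time course carry no recoverable dynamics, slower decay leaves knockout steady states impractically far away |
| strength `a` | U(1, 5) | 2–6-fold maximal modulation per edge |
| Hill `n` | {1, 2, 3} | graded to switch-like responses |
| half-saturation `K` | U(0.1, 1.0) × m_j/delta_j | drawn over the regulator's attainable range, as in-silico benchmark suites do; edges whose regulator operates far from K are intrinsically hard to detect, giving realistic heterogeneity in edge detectability |

**Linear mode.** `dx/dt = m + S x - delta x` with the signed strength matrix
halved until the spectral abscissa of `S - diag(delta)` is below half the
smallest decay rate and the steady state is non-negative.  Linear mode is
exactly the estimation model, so it anchors closed-form and
parameter-recovery tests.

### Experiments

*Wild-type perturbation time course.* The system starts at the wild-type
steady state; at t=0 the basal rates of a random third of the genes are
multiplied by log-uniform factors in [1/3, 3] (multifactorial perturbation),
and the trajectory is sampled at 26 equally spaced points over [0, 200].
Perturbing a subset — rather than every gene — leaves the other genes as
passive reporters whose movement is purely regulatory propagation, which is
the signal that delayed correlation and derivative matching read.  Each of
the 3 replicates receives independent multiplicative Gaussian noise (sd = 5%
of the signal, truncated at zero).

*Knockout compendium.* Each gene in turn is hard-deleted (state clamped at
zero, production removed).  `mode="steady"` records the post-deletion steady
state (integration to a 2000-unit horizon plus a Newton polish; residual
must fall below 1e-6 relative); `mode="timecourse"` records the relaxation
from the wild-type state on the standard grid.  `coverage < 1` keeps a
seeded random subset of mutants.  Noise is applied as above; the deleted
gene's own row stays exactly zero.

## 2. Preprocessing

Replicates are averaged pointwise.  Each gene is then fitted with one global
least-squares polynomial — degree chosen per gene by leave-one-out error
over degrees 2–6, time axis rescaled to [0, 1] for conditioning — and
evaluated, with its analytic derivative, on a 200-point equally spaced grid.
Constant profiles short-circuit to a degree-0 fit with zero derivative.

A consequence worth stating plainly: polynomial values of degree ≤ 6 span at
most a 7-dimensional function space, so the derivative-matching design
matrix has rank ≤ 7 regardless of N.  The squared-error criterion then pins
only a low-dimensional projection of (w, b); the remaining directions are
decided by the objectives (in MOO) or by the minimum-norm/initialisation
convention (in SOO).  This mirrors what any polynomial-interpolated pipeline
does implicitly.

## 3. Estimators

### SOO

Per gene, `least_squares(method="trf")` from a seeded random start (entries
uniform on [-0.1, 0.1]), tolerances 1e-6; the problem is linear so the fit
attains the least-squares optimum (verified against the normal-equation
solution in the test suite).  `solver="exact"` returns the minimum-norm
closed form.

### MOO (goal attainment)

The program is: minimise gamma over (w, b, gamma) subject to

    E_SQE(w, b) <= E_SQE_min * (1 + slack)          (hard; slack = 0.05)
    ||w - O_k||_mask - theta_k * gamma <= J_k        (per objective)

The literal hard goal "E_SQE <= 0" is infeasible for noisy data; the relaxed
bound keeps its intent.  An absolute floor of `1e-9 * sum(dx/dt^2)` is added
because polynomial-interpolated derivatives often lie exactly in the design
span (E_SQE_min at machine zero), where a purely relative slack is an
unattainable numerical target.

All constraint functions are convex, so the optimum is computed exactly
rather than by a local NLP solver (`solver="dual"`, the default):

1. scalarise: minimise `sum_k alpha_k ||w - O_k||^2 + lambda E_SQE`, which
   decomposes into one (N+1)-dimensional linear solve per gene;
2. bisect `lambda` until the E_SQE bound is tight (or, when no finite
   `lambda` reaches the bound because the data are exactly fittable, switch
   to the lambda→infinity limit: pin the SQE-minimising component via SVD
   and minimise the objective distance over the design null space);
3. for several soft objectives, rebalance the weights `alpha_k`
   multiplicatively until the normalised attainments `(F_k - J_k)/theta_k`
   coincide (the defining property of a goal-attainment optimum on the
   Pareto surface); hard non-SQE goals get their weight escalated until met,
   or an infeasibility error lists the violating terms.

A direct SLSQP transcription of the program from a seeded random initial
matrix is available (`solver="slsqp"`) and agrees with the dual solver on
small instances in the test suite.  Because the default solver is exact and
deterministic, repeated fits from different seeds give identical results;
the 50-run reproducibility study therefore reports a spread of 0 percentage
points (the convexity of the program is the substantive reason the
optimisation is reproducible at all).

Degenerate inputs: objective entries excluded by the mask are biased to zero
by a 1e-9 ridge rather than left undetermined; an empty term list makes
`fit(method="moo")` fall back to SOO; an all-zero objective is used as-is.

### Objectives

*DSp.* For every ordered pair (i, j) and delay d = 0..20 grid steps, the
Spearman correlation of gene i shifted forward by d against gene j on the
overlapping window; the coefficient of largest magnitude wins, smallest
delay on ties, constant profiles give 0.  Pairs whose best delay is below
`t_o = 1` are zeroed: instantaneous co-variation carries no directional
information (and removes co-regulated siblings, which respond with zero
relative lag).  Diagonal zero.

*Ratios (Tr/Sr).* `O_ij = log2(x_i(mutant j)/x_i(wild type))` at the
selected time (`t_p`) or steady state; wild-type values floored at 1e-6.
The plain log ratio (not its negation) is the default: its magnitude ranks
interactions while its entry signs are systematically *opposite* to the
regulatory sign (an activator's loss lowers the target), which is exactly
why the ensemble takes signs from the correlation fit instead.
`negated_log` and `raw` conventions are selectable.  Columns without a
knockout, and each deleted gene's own row, are masked.

*Correlations (Tc/Sc).* Pearson (default) or Spearman correlation of each
gene pair across the knockout conditions, at `t_p` or steady state,
excluding for each pair the conditions that delete either member — an
engineered zero is not an observation of a gene's transcriptional response,
and including it leaks direct-effect information that inflates accuracy.

*t_p heuristic.* Per gene, the time of largest mean |dx/dt| across the
knockout trajectories (central differences; the deletion instant is
excluded since expression has not yet responded there); `t_p` is the modal
index over genes, earliest on ties; all-constant panels fall back to the
midpoint with a warning.

*Scaling.* Before entering the fit each objective is rescaled
(`unit_max` default: masked entries divided by their maximum magnitude) so
distances to **w** are commensurate across objectives; z-scoring and no-op
are available.

### Ensemble

`|w_a| = |w_r|`, `sign(w_a) = sign(w_c)`; a zero sign-donor entry keeps a
positive sign (with zero magnitude the choice is irrelevant; the rule is
fixed for determinism).

## 4. Evaluation

*Undirected AUC:* unordered pairs scored by `max(|w_ij|, |w_ji|)` (max
rather than mean preserves single-direction detections), positive class =
pair linked either way, area by the Mann-Whitney rank formula with tie
averaging.  *Directed-signed AUC:* thresholds sweep the sorted `|w|` values
over ordered pairs; at each threshold the prediction set is compared with
the signed truth, counting as true positives only sign-and-direction-exact
edges; TPR is plotted against the true-negative rate over true non-edges
and integrated by trapezoid from (TNR=1, TPR=0) to full inclusion.  Sign
mismatches are false positives, so systematically sign-flipped predictors
score near 0 — which is why sub-0.5 values are informative here.
Self-loops are excluded from both metrics; the generator emits none.
Distribution comparisons use the Wilcoxon rank-sum test (exact null for
group sizes ≤ 10).  `threshold_network` sparsifies a fit to a target edge
count or connected-gene count by magnitude ranking.

## 5. Benchmark protocol and problem sizes

`run_benchmark` orchestrates the full pipeline for ten procedures (SOO, the
raw DSp matrix as a predictor, MOO with each single objective, MOO-(Tr+Sr),
and the two ensembles) over independent networks, each seeded from the run
seed via `SeedSequence` spawning.  The standard study uses ten networks at
sizes 20 and 35 and five at size 50, with the partial-coverage study (50%
of genes with knockouts) at size 50 — sizes chosen so the complete suite
runs in minutes on one CPU while keeping per-condition sampling error near
the spread of the published distributions.

## 6. What the synthetic benchmark does and does not show

The generator reproduces the qualitative structure of the published
experiments: knockout-ratio objectives dominate undirected recovery while
their signs are uninformative; cross-mutant correlation objectives dominate
directed-signed recovery; the ensemble combines both strengths; halving
knockout coverage degrades accuracy.  Quantitatively, the knockout-based
procedures land close to the published table values, and the
partial-coverage correlation fit runs somewhat above them.

Time-course-only procedures (SOO, DSp, MOO-dSp) sit much closer to chance
here than in the published study.  The reason is information, not the
estimator: a single 26-point time course of a one-layer ODE relaxation
identifies only a low-dimensional projection of **w** (an exact-derivative
oracle caps single-trajectory SOO near AUC 0.68 even noiselessly, and
interpolation from 26 samples loses most of that margin).  Benchmark suites
with two-layer mRNA/protein kinetics produce richer, delayed dynamics that
single-layer kinetics cannot imitate; modelling that layer is outside this
package's scope.  Conclusions drawn from this benchmark about time-course-
only inference on real data should be correspondingly conservative.

Other aspects of real data the generator does not emulate: measurement-
platform normalisation artefacts, correlated (batch) noise, unmeasured
regulators and post-transcriptional control, and compensatory rewiring in
knockout strains.

## 7. Known limitations

- `E_SQE` uses derivative matching; the trajectory-matching variant of the
  criterion is not implemented (the interpolation pipeline exists precisely
  to license derivative matching, which keeps the problem convex).
- The multi-term weight-balancing loop is quasi-exact for two soft
  objectives (the benchmark's maximum); with many mutually conflicting soft
  terms convergence of the multiplicative rebalancing is not guaranteed.
- Knockout semantics are hard deletion only; knockdowns (partial
  inactivation) are not modelled.
- The directed-signed AUC follows the operational reconstruction described
  above; other conventions for handling sign mismatches exist in the
  literature.
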