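# Methods

## The model family

All eleven network variants share one kinetic grammar.  Each species
(dimensionless expression level) is produced at a saturating rational rate
and degraded linearly:

    dx_i/dt = N_i(x, T) / D_i(x, T) - mu_i x_i

`N_i` is a basal rate (`a0, b0, ..., j0`) plus a sum of activation terms,
each either linear in one regulator or a product of two (heterodimeric
binding); `D_i` contains 1, every numerator term except the basal rate, and
additional repression products.  Only pairwise (heterodimeric) interactions
are admitted: with free choice of Hill exponents almost any two-node motif
can be made bistable, so restricting cooperativity to products of two
factors is what gives the structural questions (which feedback loop can
switch?) empirical content.  Because `D_i >= 1 + (N_i - basal)`, every
production is bounded by `max(1, basal + input gain)`, which yields the
forward-invariant box `[0, bound_i / mu_i]` used throughout for equilibrium
search and trajectory sanity checks, and non-negativity is forward
invariant (at `x_i = 0` production is non-negative and degradation
vanishes).

The two environmental inputs `T_EBF1` and `T_ZNF521` enter the EBF1 and
ZNF521 equations as additional activation terms and serve as bifurcation
parameters.

Three printed-form subtleties are implemented deliberately
(see the module docstring of `bswitch.model_core`):

- the full network represses EBF1 through `a4 * x_ZNF521` and ZNF521
  through `b3 * x_ZNF521 * x_EBF1`, while the isolated sub-modules use
  `a4 * x_EBF1 * x_ZNF521` and `b3 * x_EBF1`; each variant keeps its own
  published form, and the sub-module-consistency tests cover only the
  equations whose forms coincide;
- the two-node module's ZNF521 equation degrades its own state
  (`-mu7 * x_ZNF521`); the source prints `-mu7 * x_EBF1`, which cannot be a
  degradation term for the ZNF521 balance;
- two five-species modules print a production of the form
  `(numerator) x (1 + ...)`; this is implemented as division by the
  saturating factor, consistent with every other equation.

The alternative hypotheses replace the PAX5 repression product
`b4 * x_EBF1 * x_PAX5` in the ZNF521 denominator with `b4 * x_EBF1 * x_E2A`
(variant B) or `b4 * x_EBF1 * x_IKAROS` (variant C) — reconstructions built
on the same structural pattern, since the originals are not printed — and
the ablation variant simply sets `b4 = 0`.

Equations are written once, symbolically (sympy), and compiled to numpy
callables together with exact state Jacobians and input derivatives; the
finite-difference agreement of the Jacobian is a test, not the
implementation.

## Nominal parameters

The originally reported kinetic constants are not available in
machine-readable form, so the packaged nominal set
(`src/bswitch/data/nominal_params.txt`) is the package's own calibration,
found with the same kind of seeded evolutionary/local search the package
exposes (`search_bistable_parameters`) under these constraints, all of
which are regression-tested:

- two admissible attractors at rest with the observed expression program
  (FLT3, ZNF521 high / EBF1, PAX5, CD19 low in the multipotent state, and
  the mirror image in the committed state);
- irreversible bistability versus `T_EBF1` at `T_ZNF521 = 0` (left fold at
  negative activation), reversible bistability at `T_ZNF521 = 0.12`, and a
  right-shifted, near-cusp diagram at `T_ZNF521 = 0.3`;
- the module ladder: the bare EBF1/ZNF521 loop monostable with a single
  inaccessible limit point, every intermediate module monostable, the
  EBF1/PAX5/ZNF521 loop irreversibly bistable;
- variants B and C and the `b4 = 0` ablation monostable;
- a finite, two-sided bistability interval in `b4` inside the x1/64..x64
  sensitivity scan.

All degradation rates are 1, so time is measured in units of the common
protein lifetime and all expression levels live in [0, ~1].  Quantities
that depend on the *specific* published constants — exact fold
coordinates, the printed numeric log2 bounds of the `b4` range, and the
full sensitivity-table group structure — are not reproduced by this
calibration; the package reports its own computed values for them.  The
qualitative claims above are the calibration targets and are what the test
suite asserts.

## Dynamics

Integration uses LSODA (stiff-capable; the rational kinetics stiffen near
saturation) at `rtol 1e-8 / atol 1e-10`.  Equilibria come from damped
Newton iterations (with a `scipy.optimize.root` fallback) started from a
seeded Latin-hypercube over the invariant box plus its corners and center,
deduplicated at `1e-5` in the max-norm and polished to residual `1e-9`.
Roots with a negative coordinate are returned but flagged inadmissible.
Stability is eigenvalue-based; real parts within `1e-7` of the axis flag
the point *marginal* and it is bookkept as unstable (this band only
matters in fold neighbourhoods).  Nullclines of two-state models are
traced by per-grid-line bracketing and Brent refinement in both scan
directions, so near-vertical arcs are captured.

## Continuation and classification

Branches of `F(x, lambda) = 0` are traced in the extended space by a
tangent predictor / bordered-Newton corrector (Moore-Penrose style) with
adaptive arclength steps (initial 1e-2, range [1e-6, 5e-2]); each accepted
point is corrected to residual `1e-10` and carries its eigenvalues.  Folds
are detected by a sign change of the tangent's parameter component and
refined by bisection along the predictor arclength until the parameter is
resolved to about `1e-8`; refined folds sit on a numerically singular state
Jacobian (smallest singular value `< 1e-6`, asserted in tests).  Diagrams
launch bidirectional continuations from every admissible equilibrium found
at five probe values of the free parameter, discard legs and branches that
re-trace an already-covered curve (point-to-polyline distance), and abandon
branches that leave a generous multiple of the invariant box.

Classification works on *stable, physically admissible* arcs: a parameter
value is bistable when two such arcs cover it.  Arc endpoints are snapped
to refined fold parameters, and when an arc is cut by a state coordinate
crossing zero (rather than by a fold) the crossing is located by
interpolation.  The switch is `monostable` if no admissible parameter value
is bistable, `reversible_bistable` if the bistable interval is bounded by
accessible folds, and `irreversible_bistable` if its continuation extends
below the admissible parameter minimum (default 0): the inaccessible fold
disconnects the two stable branches over the physical domain.  Toy systems
whose states legitimately go negative set `state_min=None`.

A Hopf scan along stored branch eigenvalues flags complex-pair axis
crossings by interpolation; for this fold-organized network the expected
(and tested) result is none.

## Sensitivity and search

`bistability_interval` scans a parameter over 33 log-spaced points spanning
x1/64..x64 of nominal (wide enough to bracket a several-fold bistable
range), evaluates the predicate "at least two admissible stable equilibria
at the reference inputs", and bisects the boundaries of the contiguous
bistable block containing nominal in log space to relative tolerance 1e-3.
Boundaries that run off the scan edge are reported censored rather than
invented; a parameter with no bistable scan point is `unimodal`.  A zero
nominal value yields linear bounds with an undefined log2 ratio.

The GA (`search_bistable_parameters`) evolves log-parameter genomes with
3-way tournament selection, BLX-0.5 blend crossover and log-normal
mutation; fitness is a graded distance-to-bistability score (stable-state
counts at probe input levels, attractor separation, and a fold-margin term
from the smallest Jacobian singular value when seeking folds).  Every
candidate above threshold is re-verified with a full diagram and switch
classification before being reported, and identical seeds give identical
results.  The screen's negative control runs this search on the ablated
network and asserts that it finds nothing.

## Reprogramming

Schedules are piecewise-constant input programs.  The start state is the
named attractor under resting conditions; each segment is integrated long
enough (default segments of 150 time units, i.e. 150 protein lifetimes) to
reach quasi-steady state.  The final state is labelled by the nearest
attractor (max-norm) of the final condition's equilibrium set; if the two
nearest attractors are within a factor 2 in distance the result is
`undecided` instead of a guess.  Attractor identity follows the expression
program (FLT3/ZNF521 versus EBF1/PAX5/CD19 relative to the cross-attractor
midpoint), not absolute thresholds.

## Synthetic data

The expression fixture emulates only the *direction structure* of the
two-condition (multipotent versus pro-B) profiling comparison: programmed
means with multiplicative log-normal noise (sd 0.05 on the log scale;
intensities are positive and right-skewed), markers separated four- to
six-fold, non-markers flat.  It deliberately omits probe-level artifacts,
replicate correlation and normalization effects, so concordance against it
validates the comparison pipeline and the model's attractor program, not
microarray preprocessing.  The differential-filter fixture plants true
positives that pass the |fold| >= 2, p < 0.05 rule with margin and nulls
that fail both margins, so exact recovery is the correct expectation.
Per-factor max-normalization (each factor divided by its maximum across the
two conditions) is one of two readings of "normalized with respect to the
maximum value"; it is adopted because it renders each factor with value 1
in exactly one condition, matching the paired-bar comparison it feeds.
Factors whose normalized difference is below 0.1 are called flat and leave
the concordance denominator.

## Problem sizes and known limitations

Default test and acceptance runs use multi-start budgets of 50-200 starts,
17-33-point sensitivity scans, and GA populations of 8-32 over <= 25
generations; these sizes make every reported quantity stable under seed
changes while keeping a full run in the minutes range on one CPU.

Known limitations: the calibrated constants are not the published ones, so
coordinate-level numbers (fold positions, sensitivity bounds) are
package-specific; classification trusts the branch inventory, so a stable
branch disconnected from every probe equilibrium would be missed (the
dense-count cross-check guards the nominal configurations); the
deterministic ODE treatment has no stochastic gene expression; and the GA's
negative results are evidence under its budget, not proofs of
impossibility.
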