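# Methods

## Model and assumptions

`arborgeom` models an axonal arbor, recorded as an SWC tree of trace
points in micrometres, as a collection of differentiable space curves.
The representation rests on three assumptions:

* the trace points sample smooth underlying neurites densely enough that
  an interpolating curve through them is meaningful (for typical
  light-microscopy traces, point spacing of order 1 μm);
* cumulative chord length is an adequate stand-in for arclength as the
  curve parameter — exact in the limit of dense sampling (see the
  `speed-invariant` variant below for when it is not);
* the topological segment classes (primary / collateral / terminal,
  defined purely from the longest-path decomposition) are a useful proxy
  for the qualitative anatomical vocabulary. They are unambiguous and
  rigid-motion invariant, but deliberately ignore branch angles and radii.

### Decomposition

The longest root-to-leaf path by cumulative Euclidean length is extracted
as one segment; every sub-tree hanging off it is processed recursively,
rooted at the shared branch point (so each segment has a defined start
point and at least two points). The first segment is primary; later
segments are collateral if sub-trees hang off them, terminal otherwise.
Edges are partitioned exactly once and the segment count equals the leaf
count. Exact ties between path lengths are broken toward the smaller leaf
id, purely for determinism; real coordinates essentially never tie.

### Spline representation

Each segment is fitted by an interpolating B-spline (smoothing `s = 0`)
with parameter values equal to the points' cumulative chord lengths, via
`scipy.interpolate.splprep`; interior/boundary knot construction beyond
the interpolation contract is FITPACK's standard clamped construction —
the contract the analyses rely on is only "passes through every point,
parameterized by chord length". Degree follows the point count: 5 for
n > 5 (minimal degree with a continuous third derivative), 3 for
3 < n ≤ 5, 2 for n = 3, 1 for n = 2. Even degree 4 is skipped: high even
degree interpolation is poorly conditioned in this setting. Basis
functions, their derivatives and curve evaluation are implemented from
the Cox–de Boor recursion and its closed-form derivative recurrence
(orders 1–3); tests cross-check them against FITPACK's independent
evaluator and against central finite differences.

### Curvature and torsion

κ = ‖x′ × x″‖ and τ = ⟨x′ × x″, x‴⟩/‖x′ × x″‖², with τ := 0 wherever
‖x′ × x″‖ < 1e−12 (the quotient is undefined at zero curvature; the
threshold only guards floating-point division). Both are in (μm)⁻¹, both
sampled at t = 0, 1, …, ⌊L⌋ μm by default (a grid from 0 is the simplest
deterministic reading of "every 1 μm"; the endpoint enters only when L is
integral). Analyses use |τ|: the sign encodes handedness, which is not of
interest here.

Two formula variants exist. The default `chord` variant applies the
arclength formulas directly to chord-parameter derivatives — faithful to
the processing pipeline the representation comes from. Since the spline's
speed ‖x′‖ is slightly above 1 (the curve between knots is longer than
the chord), `chord` curvature is biased upward by ≈ ‖x′‖³. For a helix
with r = c = 1 μm this is ≈ 3% at 1 μm point spacing and ≈ 0.8% at
0.5 μm; validation fixtures therefore sample the generator at 0.5 μm
where 2%-level recovery is asserted. The `speed-invariant` variant
(κ = ‖x′ × x″‖/‖x′‖³; the τ quotient is already parameterization
invariant) removes the bias entirely and is recommended for sparsely
sampled traces.

### Statistics

*Autocorrelation.* Per segment, the normalized autocorrelation of the
sampled κ (or |τ|) series, with the series mean and variance; lag k needs
at least k + 2 samples. Constant series (e.g. perfectly straight
segments) have no defined autocorrelation and are excluded from
averaging — the exclusion count is reported. Per lag, a one-sample
one-sided t-test of mean r(k) > 0.3 (the conventional floor for a
"moderate" correlation) at α = 0.05; no correction across lags, each lag
is its own question. The maximum lag is a free parameter (default 10 μm).

*Class comparisons.* Neurons are paired samples; a neuron's class value
is the unweighted mean of its segments' mean κ (or |τ|) for that class —
the most literal reading of "the average of one segment class"
(length-weighted pooling across samples is available as an option).
Neurons lacking a class drop out of pairs involving it. The six tests
(two parameters × three class pairs) use the exact sign test: ties
discarded, k of n informative pairs positive, one-sided
p = P(Bin(n, ½) ≥ k) computed exactly. Because the tested direction is
taken from the data (the empirical majority), the reported one-sided tail
is doubled before comparison with the Bonferroni threshold α/6 — this is
precisely the exact two-sided sign test of H0: Pr[X>Y] = ½ vs
H1: Pr[X>Y] ≠ ½, and it is what makes the family-wise guarantee true:
simulations with per-neuron label shuffling put the family-wise rejection
rate at ≈ 0.03 (≤ 0.05), whereas judging the selected one-sided tail
against α/6 would double it to ≈ 0.09. Both p-values are reported
(`p_value`, `p_adjusted`).

*Ordering table.* Per neuron with all three classes and strict
inequalities, the (curvature, torsion) pair of class orderings indexes
one of 6 × 6 cells; neurons with a missing class or an exact tie are
excluded and counted.

*Perturbation.* Replicate r of the dropout experiment seeds a generator
with `base_seed + r`, draws one sub-seed per tree, removes every non-root
node with probability 0.1 (children re-attach to the nearest surviving
ancestor; the root is kept so the arbor's origin — and hence the
primary-segment definition — is stable), and reruns the full comparison.
20 replicates by default; bitwise reproducible for a fixed base seed.

## Synthetic data

The generator produces constant-speed samplings of lines, circular arcs
and helices — the curves whose curvature and torsion are known in closed
form — assembled into rooted trees. The default cohort plants the
ordering curvature C > T > P and torsion C > P > T using three helix
families: primary r = c = 5 μm (κ = |τ| = 0.10 μm⁻¹, trunk length
250 μm), collateral r = c = 1 μm (κ = |τ| = 0.50, length 60 μm, two per
neuron), terminal r = 3, c = 0.45 μm (κ ≈ 0.33, |τ| ≈ 0.049, length
25 μm, one per collateral). Per neuron, each class's (r, c) is scaled by
an independent ±5% uniform factor and the curves are randomly oriented,
so class values vary across the cohort while the planted strict ordering
holds for every neuron, with margins wide enough (≥ ~1.5×) to survive the
10% dropout perturbation. Trunk and attachment lengths guarantee the
decomposition is the intended one with ≥ 5 μm of path-length margin.

What the generator does *not* emulate: imaging noise and annotator
disagreement (coordinates are exact unless `jitter_sd > 0`), variable
point spacing along a neurite, curvature that varies along a segment,
soma geometry, and the scale and branching complexity of real cortical
projection neurons (hundreds of branches vs. five segments here). Passing
the planted-ordering tests therefore demonstrates that the pipeline
recovers known geometric signal through decomposition, fitting, sampling
and testing — not that real axon classes differ, which only real cohorts
can show.

## Problem sizes and numerical choices

Validation runs use: helix fixtures of length 40–100 μm at 0.5 μm
spacing; a 30-neuron planted cohort (~450 points per neuron, five
segments) for the statistical analyses; 20 perturbation replicates; 200
label-shuffling simulations for the type-I rate. These sizes give
unanimous sign tests (p = 2⁻³⁰) and type-I estimates with ±0.015
binomial error while keeping the whole suite under a minute.

* Interpolation residual asserted at ≤ 1e−6 μm (observed ~1e−13).
* Closed-form derivatives vs. central differences: ≤ 1e−5 relative.
* Duplicate consecutive trace points are merged with a warning before
  fitting (chord parameters must be strictly increasing); a segment
  collapsing to one distinct point is an error.
* Evaluation outside `[0, L]` raises rather than extrapolating; the right
  endpoint is attached to the last non-empty knot span so the closed
  interval is covered.
* All randomness (generator, dropout, shuffling) flows from explicit
  integer seeds through `numpy.random.default_rng`.

## Limitations

Chord-parameter curvature carries the sampling-dependent upward bias
quantified above; use `speed-invariant` when point spacing is coarse
relative to the radius of curvature. The segment classes are topological
conventions, not anatomical ground truth. Autocorrelation lags live on
the chord-parameter grid, i.e. straight-line distance between trace
points, not true arclength. The sign tests say nothing about effect
size — only about the direction's consistency across neurons.
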