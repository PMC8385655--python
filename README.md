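# arborgeom

Differential geometry of neuron traces.

Most neuromorphology pipelines treat a traced neuron as a piecewise-linear
tree and summarize it with macroscopic features (branch counts, total
length, tortuosity). That representation has no usable higher derivatives:
curvature and torsion are zero along the line segments and undefined at the
joints. `arborgeom` instead treats the trace points of an axonal arbor as a
sampling of differentiable space curves: it splits the arbor into segments,
fits each segment with an interpolating B-spline, and computes the
Frenet–Serret parameters — curvature κ and torsion τ — in closed form at
any point along the arbor. It is aimed at neuroanatomists and
morphometricians working with SWC reconstructions (MouseLight,
NeuroMorpho.Org, …) who want *pointwise, endpoint-free* geometry rather
than ratio summaries.

## Method

1. **Decomposition.** The arbor is split by recursively extracting the
   longest root-to-leaf path (in cumulative Euclidean length, so the split
   is rigid-motion invariant). The first path is the **primary** segment;
   sub-trees hanging off a path are decomposed the same way from the shared
   branch point; segments that still carry sub-trees are **collateral**,
   the rest **terminal**. Segments partition the edges; one segment per
   leaf.

2. **Spline fit.** Each segment's points are interpolated (smoothing s = 0,
   via `scipy.interpolate.splprep`) with parameter values equal to
   cumulative chord length, so the knot span is `[0, L]` in μm. Degree is
   chosen from the point count n: `n > 5 → 5` (the minimal degree giving a
   thrice continuously differentiable curve), `3 < n ≤ 5 → 3`, `n = 3 → 2`,
   `n = 2 → 1`; degree 4 is never used.

3. **Geometry.** With x′, x″, x‴ the closed-form spline derivatives,

       κ = ‖x′ × x″‖,   τ = ⟨x′ × x″, x‴⟩ / ‖x′ × x″‖²

   (τ := 0 where κ vanishes), sampled every 1 μm; analyses use |τ|. A
   `speed-invariant` variant (κ = ‖x′ × x″‖/‖x′‖³) is available for curves
   whose chord-length parameter is far from arclength.

4. **Statistics.** Per neuron, a class value is the unweighted mean of its
   segments' mean κ (or |τ|) for that class. Six exact paired sign tests
   (κ and |τ| × {primary–collateral, collateral–terminal,
   primary–terminal}) are judged at the Bonferroni threshold α/6 = 0.0083;
   a 6×6 table counts the strict class orderings per neuron; per-lag
   autocorrelation of the κ/|τ| series is tested one-sidedly against a 0.3
   floor; and a perturbation experiment reruns everything on seeded copies
   with 10% of trace points removed.

Synthetic ground truth is built in: lines, arcs and helices have known
κ = r/(r² + c²) and |τ| = |c|/(r² + c²), and `arborgeom.synth` assembles
them into branching arbors and whole cohorts with planted class orderings.

## Worked example

```python
from arborgeom import stats, synth

trees = synth.make_cohort(10, rng_seed=7)        # synthetic SWC-ready arbors
geometry = stats.cohort_geometry(trees)          # decompose -> fit -> sample
table = stats.class_value_table(geometry)        # per-neuron class means
results = stats.run_class_comparisons(table, alpha=0.05)
print(stats.comparisons_to_frame(results).to_string(index=False))
print(stats.ordering_counts(table).modal_cell())
```

prints

```
parameter    class_a    class_b  n_pos  n_neg  n_tie           direction  p_value  p_adjusted  significant  alpha_corrected
curvature    primary collateral      0     10      0  collateral>primary 0.000977    0.001953         True         0.008333
curvature collateral   terminal     10      0      0 collateral>terminal 0.000977    0.001953         True         0.008333
curvature    primary   terminal      0     10      0    terminal>primary 0.000977    0.001953         True         0.008333
  torsion    primary collateral      0     10      0  collateral>primary 0.000977    0.001953         True         0.008333
  torsion collateral   terminal     10      0      0 collateral>terminal 0.000977    0.001953         True         0.008333
  torsion    primary   terminal     10      0      0    primary>terminal 0.000977    0.001953         True         0.008333

('C>T>P', 'C>P>T', 10)
```

All ten neurons order curvature collateral > terminal > primary and torsion
collateral > primary > terminal — the ordering planted by the generator —
so every sign test is unanimous (one-sided p = 2⁻¹⁰ ≈ 0.000977, doubled for
the data-driven direction, well below 0.0083) and all ten neurons fall in
the single modal cell of the 6×6 ordering table.

The same pipeline is available from the shell:

```sh
arborgeom synth -n 30 --seed 1 -o cohort/
arborgeom decompose cohort/*.swc -o segments.csv
arborgeom geometry  cohort/*.swc -o geometry.csv
arborgeom compare   cohort/*.swc -o results/ --perturb --seed 1
```

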