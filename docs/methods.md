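# Methods

## The model

An organoid is a closed monolayer of `N` cells around a lumen of volume `V`
containing an amount `n` of osmotically active substance. Each cell `i` is a
point agent with position `x_i` (µm) and radius `ρ` (µm), moving in
overdamped dynamics

    γ dx_i = F_i dt + γ σ √dt ξ_i,

integrated with the explicit Euler–Maruyama scheme (`ξ_i` standard normal
3-vectors). The force on a cell has three parts:

1. **Springs** along neighbour edges: `F = −k_spring (‖x_i−x_j‖ − ℓ0) û_ij`.
   Neighbourhood is convex-hull adjacency of the cell positions (equivalent
   to a spherical Delaunay triangulation while the shell is convex),
   rebuilt after every division and every `rebuild_every` steps.
2. **Lumen pressure** `P = κ·n/V` (van 't Hoff / ideal gas, with the factor
   i·R·T lumped into κ), acting outward along the radial unit vector on an
   equal area share `a_i = 4πR_fit²/N`, where `R_fit` is the mean
   cell–centre distance. Equal shares reflect the homogeneous-cell
   assumption.
3. **Bending**: a harmonic restoring force `−k_bend (‖x_i−c‖ − R_fit) r̂_i`
   toward the instantaneous best-fit sphere. Because `R_fit` moves with the
   cells, this penalises deviations from sphericity without resisting
   uniform inflation — the mildest form consistent with a polarised
   epithelium that maintains a spherical shape.

Cells secrete substance at constant rate `J_in` per cell. When the mean
distance over all neighbour edges exceeds `ℓ_rupture` the shell tears and
substance leaks at constant rate `J_out` (a pressure-proportional leak is
available as `pressure_coupled_outflux`); when the mean edge relaxes below
`ℓ_seal` the shell closes. `n` is floored at zero. The lumen volume is
refit as `(4/3)πR_fit³` each step. Division follows a schedule —
exponential (per-cell rate), linear (cells/hour), piecewise
exponential-linear, or an interpolated target-count table tracked exactly —
realised as Poisson draws per step (or deterministically by expectation
tracking). Daughters appear at a tangential offset of `0.2ρ` with the
parent's radius; cell growth is neglected.

## Parameter defaults and their calibration

The experimental literature reports no mechanical parameter values for this
system, so the defaults are calibrated, not measured. Units are µm and
hours; forces are in units of `k_spring·µm`.

| parameter | default | meaning |
|---|---|---|
| `k_spring` | 1 | cell–cell spring constant |
| `ell0` | 10 µm | rest length ≈ cell diameter |
| `k_bend` | 1 | sphericity restoring stiffness |
| `kappa` | 1 | pressure per substance concentration |
| `j_in` | 2 /cell/h | secretion rate |
| `j_out` | 1000 /h | leak rate while ruptured |
| `ell_rupture` | 13 µm (1.3 ℓ0) | rupture threshold on the mean edge |
| `ell_seal` | 11 µm (1.1 ℓ0) | reseal threshold |
| `gamma` | 1 | drag |
| `sigma` | 0.05 µm/√h | positional noise (uncharacterised; kept small) |
| `dt` | 0.01 h | timestep (stability bound `γ/4k` is enforced) |

A force balance on an inflated shell gives the substance needed for rupture
as `n_rupt ≈ (k ℓ0²/κ) s(s−1) N` with stretch `s = ℓ_rupture/ℓ0`, and hence
two derived scales that guided the calibration, done once:

- **rupture time** of a sealed shell ≈ `0.35 k ℓ0²/(κ J_in)` ≈ 18 h — a
  64-cell organoid under slow linear growth ruptures on the tens-of-hours
  scale observed experimentally;
- **critical relative growth rate** `r* ≈ J_in κ/(0.39 k ℓ0²)` ≈ 0.05/h —
  shells whose relative surface growth exceeds `r*` never reach the rupture
  stretch. This reproduces the scaling-law prediction in the discrete
  model: for linear cell-number growth the relative rate `m/N(t)` decays
  like 1/t, so oscillations start only once growth has slowed, matching the
  observation that cultures show no events during early fast growth.

Initial states place `N0` cells on a Fibonacci lattice (recentred so every
cell is exactly `R0` from the centroid) with `R0` chosen so the mean edge is
`ℓ0`, and set `n` so the starting pressure is 10% of the rupture-scale
pressure — low enough to avoid immediate rupture, high enough to skip a long
dead transient.

For the size-effect experiment (ruptures per 100 h across
`N0 ∈ {16, 64, 256}`) the common schedule is deliberately slow (0.05
cells/h): a large *absolute* slope shared across sizes would relieve small
organoids relatively more (relief scales with `m/N`) and mask the
surface-to-volume effect under study. The exponential-vs-linear contrast
uses `N0 = 8`, rate 0.08/h (> r*) until `t* = 40 h`, then 0.65 cells/h —
the average division rate observed for a small organoid. Tests and the
examples run at `dt = 0.02 h` with ≤ ~300 cells, sizes chosen so a run
takes seconds; the dynamics are insensitive to this halving of the default
step (first-order convergence is verified in the suite).

## The scaling law

With `V ∝ A^{3/2}` (sphere), `ṅ ∝ N ∝ A` (homogeneous secretion by surface
cells) and `Π ∝ n/V`, the pressure is `Π(t) ∝ (∫₀ᵗ A)/A^{3/2}`. For
`A = t^p` the log-log slope of Π is `1 − p/2`, so Π is constant exactly at
`p = 2`. `constant_pressure_exponent` recovers this numerically by
bracketing the sign change of the fitted log-log slope over a log-spaced
grid and refining with Brent's method; the first 5% of the grid is excluded
because Π is singular at t → 0 for power laws. The cumulative trapezoid
misses the `∫₀^{t0} A` head when a grid starts at `t0 > 0`;
`pressure_from_surface` therefore adds a local power-law extrapolation of
the first two samples (exact for power laws, and what makes the `A = t²`
constancy hold on finite grids).

`classify_growth` decides whether oscillations are expected from the tail
(last 50%, the asymptotic regime) of a cell-count curve. Rather than
thresholding a single log-log slope, it selects the best of three growth
families fitted on log N — exponential, power law, affine-linear — because
affine-linear data with a large intercept can locally resemble an
exponential on the log scale. Exponential growth → no oscillations; a
power law → no oscillations iff its exponent ≥ 2 (the stated boundary is
inclusive); linear → oscillations.

`fit_piecewise_exp_linear` fits `N(t) = N0 e^{rt}` up to a transition `t*`
with a continuous linear continuation, selecting `t*` over the observed
time points (the 30-min sampling makes finer resolution unidentifiable) by
least squares; residual ties resolve to the latest transition so purely
exponential data report `t*` at the final time point.

## Trace features

Traces are normalised per well by the median area at the fifth time point;
the first four frames cover organoid formation, where segmentation is
unreliable, and are excluded from phase detection. A decline phase starts
at the first frame below 95% of the running maximum since the previous
phase end — the running-maximum reference keeps the rule scale-free — and
ends at the first frame where the area rises again. Expansion candidates
span from a decline's end (the trace start acts as a virtual decline end)
to the frame before the next decline; they are accepted with ≥ 5 frames and
Pearson r > 0.9 of a straight-line fit, whose slope per hour on the
normalised area is the expansion factor. An oscillation event is a decline
immediately followed by an accepted expansion. Organoids without any
accepted expansion are excluded from culture medians rather than counted as
zero, which would bias the medians downward. Quartiles use linear
interpolation so outlier masks are reproducible. Circularity uses the raw
(unnormalised) area and perimeter; any frame below 0.6 flags the organoid
as deficiently segmented.

## Morphometry

Neighbour graphs come from scipy's Delaunay tetrahedralisation (DCG) and a
strict `< cutoff` proximity rule (PCG, default 50 voxels). Volume and
surface are convex-hull proxies of the centroid cloud — a stand-in for
surface-reconstruction pipelines, not an equivalent. Segmentation
evaluation matches segmented to ground-truth centroids one-to-one within a
10-voxel radius; when one segmented centroid is nearest to several
ground-truth centroids the per-point "closest wins" rule is ambiguous, so
pairs are assigned globally in ascending distance order, which is
deterministic and coincides with the per-point rule whenever there is no
conflict. Distances are in voxel units by default (anisotropy ignored, as
in the 10-voxel convention); a µm-space mode uses the voxel-size metadata.

## Synthetic data

Generators emulate the *shapes* of segmentation outputs, not images. Traces
are piecewise-linear excursions around a linear growth trend: each planted
event drops the area by a fixed fraction in one frame and recovers linearly
back to the trend, so every recovery is an exactly linear expansion
(r = 1) and the final area is event-independent — which is what makes exact
round-trip tests possible, and also what real traces are not: real declines
spread over frames, recoveries curve, and noise can split or merge phases.
Passing round trips therefore validate the bookkeeping of the rules, not
their robustness on noisy data (the oracle-equivalence tests on random
walks cover the rule boundaries instead). Initial areas are lognormal
(positivity); planted event counts scale inversely with initial area,
emulating the observed size dependence. Centroid clouds are jittered
spherical shells with Binomial deletions/additions; spurious detections are
placed deep inside the lumen so they cannot shadow shell points within the
matching radius. All generators are bit-reproducible for a fixed seed and
attach their ground truth as a sidecar, never inferred from the output.

## Numerical choices and edge cases

- Floats are written with `repr` (shortest round-trip form), so
  `read(write(x))` is bit-exact; writers fix column order and newlines,
  making outputs byte-deterministic per seed.
- Degenerate cell pairs (< 1 nm apart) get a capped repulsion and a logged
  warning instead of a force singularity; non-finite forces abort the run
  naming the offending cell and step.
- Empty-vs-empty centroid sets define all metrics as 1.0 (with a warning);
  one-sided emptiness gives F = 0. Coincident points in the proximity graph
  count as mutual neighbours.
- A Kruskal–Wallis comparison across wells with zero rank variation
  reports H = 0, p = 1; a single well skips the comparison with a message.
- The convergence test freezes hull adjacency: edge flips are discrete
  events that would otherwise mask the integrator's O(Δt) order.

## Known limitations

- All cells in an organoid share one radius and secretion rate; cell-size
  heterogeneity, fusion, rotation, migration and budding are out of scope.
- The bending force maintains global sphericity only; it does not model
  local curvature energetics, so strongly non-spherical shells are outside
  the model's regime.
- Hull-based lumen volume and equal area shares degrade if the shell
  becomes strongly non-convex (not reached under the default parameters).
- The simulator's parameters are calibrated to reproduce qualitative
  behaviour (oscillation presence, size ordering, time scales), not fitted
  to measured forces or pressures.
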