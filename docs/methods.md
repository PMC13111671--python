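# Methods

This note documents the models, parameters and numerical choices behind
`ciliaflow`, and what the synthetic benchmarks do and do not establish
about real recordings.

## Input model and time accounting

A track is one bead's time-ordered 2-D positions in µm.  Recordings are
made at a native frame rate `fps` (default 24 frames/s) and thinned before
export by an integer `subsample_factor` (default 2, i.e. every second frame
retained).  The `frame` column of the CSV dialect indexes *retained*
frames, so the elapsed time per unit frame difference is
`subsample_factor / fps` seconds (0.0833 s at the defaults).  All speeds
use this conversion; getting it wrong scales every speed statistic by the
thinning factor.  Spatial calibration (`um_per_px`) is a required user
input for real tracker exports — it cannot be inferred from the data — and
is applied by `rescale_tracks`.

I/O keeps any track with ≥ 2 points; the feature stage applies its own
policies.  This separation means ingestion never silently imposes analysis
decisions.

## Per-track statistics

Eight statistics per track: number of turns, sinuosity, mean / maximum /
sample-variance of speed, number of self-intersections, path length, and
net displacement length.

*Sinuosity* is path length over start-to-end distance.  Closed tracks
(zero displacement) would be infinite; instead the displacement is floored
at `displacement_epsilon` (1e-9 µm) and the track flagged, keeping the
feature matrix finite for clustering.

*Windowed sinuosity* slides a 20-**point** window one point at a time and
assigns each point the maximum over all complete windows containing it.
The window is defined in points, not µm, so its physical scale varies with
frame rate and specimen size; that scale is reported, not adapted.  Tracks
shorter than 20 points use a single whole-track window — they stay in the
dataset rather than being dropped, which matters for small specimens with
short tracks.  A *turn* is a maximal run of points with windowed sinuosity
strictly above 1.2; a run of length one counts.

*Self-intersections* are counted over all non-adjacent segment pairs with
orientation predicates on doubles and a relative collinearity tolerance of
1e-12; touching counts, and a collinear overlap counts once per pair.  The
test suite checks this against shapely pair-by-pair.

*Speed variance* uses the n−1 denominator and carries (µm/s)² units.

Normalizations: z-score ((x−mean)/sample s.d.) feeds clustering; min–max
(to [0, 1]) feeds visualization.  Constant columns become zeros and are
flagged rather than producing NaNs — noiseless synthetic data hits this
constantly (e.g. all-zero turn counts).

The clustered "sinuosity" column is the global ratio (the quantity defined
by formula); the per-track maximum of the windowed values is available as
an optional extra column (`include_windowed_max`).

## Clustering and composition statistics

Tracks are clustered on the z-scored 8-feature vectors: a k-nearest-
neighbour graph (k = 15, a conventional neighbour-graph default; only the
metric, resolution and min_dist are method-level commitments) under
correlation distance d = 1 − Pearson r, symmetrized by union; Leiden
community detection on the unweighted graph with the resolution-
parameterized modularity objective at resolution 0.05; a 2-D UMAP
embedding with min_dist 0.2.  Constant feature rows (correlation
undefined) are flagged and pushed to the metric's maximum distance 2.
UMAP's embedding metric is set to correlation for coherence with the
graph; the embedding is seeded and deterministic.  Labels are 1..K with no
gaps; permuting input rows permutes labels identically.

Cluster compositions are per-species percentages over clusters (rows sum
to 100) compared by Euclidean distance.  Feature differences between a
cluster and the rest use Welch's unequal-variance t-test — robust to the
very unequal cluster sizes Leiden produces at low resolution.  No
multiple-testing correction is applied by default; a Benjamini–Hochberg
adjustment can be applied downstream by the user on the returned p-values.

The permutation proportion test takes a focal group mask, computes per
cluster the absolute difference of within-group proportions (the absolute
value makes the test two-sided; no sign convention is otherwise defined),
and builds the null from 1000 random splits preserving group sizes.  The
p-value is the strict-exceedance count over the number of permutations,
which can be exactly 0; an add-one-corrected variant
((count+1)/(n+1)) is available for users needing positive p-values.

**Discreteness caveat.** Permutation p-values are discrete: with few
tracks the proportion-difference statistic lives on a coarse lattice, ties
between observed and null values are common, and the strict-exceedance
p-value is mildly anti-conservative (ties shrink p).  The calibration
benchmark therefore uses 960 tracks (focal group 320, eight clusters with
uneven occupancy), where the lattice is fine enough that the test's
continuum behaviour is measurable: empirical type-I error ≈ 0.055 at
α = 0.05 and KS distance to Uniform(0, 1) ≈ 0.06 over 500 replicates.  At
much smaller sample sizes users should prefer the add-one-corrected
variant.

## Grid vector field

One steady field per recording summarizes all track steps.  Each step
contributes an observation: velocity = chord / elapsed time, located at
the step midpoint (trapezoid-consistent with the bilinear basis).  The
field minimizes

    (1/N) Σ_steps ‖v_obs − A w‖²  +  (w_s/M) ‖L w‖²

with A the bilinear design matrix, L the 4-neighbour lattice graph
Laplacian, and smoothing weight w_s = 0.5 on this normalized two-term
objective (the normalization is this package's definition; recovery
properties, not bit-compatibility with any external tool, validate it).
The Laplacian's nullspace is the constant field, so uniform flows are
recovered exactly and empty cells are filled smoothly.  With w_s = 0 and
unsupported nodes the system is singular and the fit raises instead of
returning silent zeros; with no in-domain steps it raises as well.  The
default domain is the tracks' bounding box padded 5 %.  The sparse normal
equations (900 unknowns per component at 30 × 30) are solved by one LU
factorization shared by u and v.

Chord velocities underestimate curved motion; with the default 0.083 s
step this bias is negligible for the µm/s-scale flows simulated here.

## Flow maps and FTLE

Flow maps are integrated with classical 4th-order Runge–Kutta (the
dt-halving benchmark confirms convergence: < 0.1 % change on the saddle
benchmark) on the bilinearly interpolated field.  The step is specified in
retained frames (default Δt = 5 frames) and converted to seconds via the
TrackSet metadata; the default horizon n_steps = 20 000 deliberately
exceeds the recording length — the field is steady, and long horizons let
trajectories sweep the whole domain.  The closed-form benchmarks use far
fewer steps because their horizons (T = 4 s and 2 s) are reached sooner at
an accurate dt.

Outside the domain the velocity is zero by default (trajectories halt at
the boundary); a `freeze_position` mode stops a trajectory at its exit
point instead.  The FTLE at each grid node is

    ln √λ_max((∇Φ)ᵀ ∇Φ) / |T|

with ∇Φ by central differences over the seed grid (second-order one-sided
stencils at edges).  Boundary halting compresses the numerical flow map,
so each FTLE field carries a `valid_mask`: nodes whose own and stencil-
neighbour trajectories never left the domain.  Inside the mask the values
are quantitative (the saddle and shear benchmarks hold to < 2 % there);
outside they are qualitative ridge indicators only — which is how FTLE
ridges near domain boundaries should always be read.  Only forward-time
FTLE is computed by default; `backward=True` negates the field.

## Principal trees

SimplePPT-style alternating optimization: Gaussian soft assignment of
points to nodes (bandwidth σ, a squared-length scale in data units),
minimum-spanning-tree topology over squared node distances, and a
λ-regularized linear solve for node positions.  Each step minimizes the
joint objective (distortion + entropy + λ·edge lengths) over its block, so
the objective trace is non-increasing — asserted on every test instance.
Defaults λ = 10, σ = 10 assume data rescaled to the µm ranges typical
here; both are exposed because their effect scales with the data.  Nodes
default to one per tracked point of the frame and are initialized as a
seeded random subset of the points.

## Synthetic generator

The generator emulates what the analysis assumes about bead motion:
advection by a stereotyped, time-independent surface flow plus bead
diffusion, frame thinning, and tracking jitter.  Paths follow explicit
Euler–Maruyama at the native frame rate (first-order accuracy suffices for
generation and keeps the generator independent of the analysis-side RK4 —
no shared bugs), are truncated at the last in-domain point (so short
tracks occur naturally), thinned, and then perturbed by i.i.d. Gaussian
measurement noise on retained frames only.  Defaults: 24 fps, thinning 2,
D = 0.5 µm²/s, noise s.d. 0.2 µm, no sedimentation drift (the bead
preparation targets near-neutral buoyancy; a constant −y drift in µm/s is
available).  Seeding is uniform in the domain, or on an annulus for
stellar patterns.  Bead density per area is not a calibrated quantity;
`n_tracks` is free.

The stereotyped patterns: stellar in/out (±v0 radial unit vector within an
optional disk; exact antisymmetry between the two), longitudinal (constant
v0 along an axis within a band), filament (flow along a polyline, with
beads beyond the branch-spacing scale drawn toward it), uniform, saddle
(v = (ax, −ay); the rate a fixes velocities, v0 unused), vortex
(v = ω(−y, x)), and none (pure Brownian null).

What the generator does **not** emulate: unsteady or 3-D flow, spatially
varying diffusivity, bead–surface adhesion events, tracking dropouts and
identity switches, and pixelation artifacts.  Passing benchmarks therefore
demonstrate that the computations are correct on data satisfying the
model's assumptions — not that a real recording satisfies them.

## Presence heuristic

The per-recording verdict "directional currents detected" is a
convenience summary, not a statistical test: a track qualifies when its
straightness (displacement/length) ≥ r_min (0.6) and mean speed ≥ v_min
(2 µm/s), and the verdict fires when the qualifying fraction reaches f_min
(0.5).  All thresholds are explicit configuration and the output is
labelled heuristic.  On synthetic recordings (advection ≥ 5 µm/s vs pure
diffusion ≤ 10 µm²/s) it discriminates essentially perfectly; real
recordings with mixed regimes on one surface will be harder.

## Problem sizes of the benchmarks

The repository's benchmarks use sizes chosen to make each property
measurable while staying desk-scale: 100 random-walk tracks for the oracle
suite; 30 × 30 grids for all field work; 400–600 simulated tracks for
field-recovery checks; 500 replicates × 1000 permutations (960 tracks
each) for calibration; 10 seeds × 200 rows for clustering recovery; 100
synthetic recordings of 30 tracks for discrimination.  Full-scale studies
(10⁴–10⁵ tracks) run the same code paths; the O(n²) self-intersection
count dominates for very long tracks.
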