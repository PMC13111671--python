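# ciliaflow

Many cnidarians — corals, sea anemones, jellyfish polyps — move the water
layer hugging their epithelium with coordinated ciliary beating, producing
stereotyped surface currents: inward or outward "stellar" flows converging
on or radiating from the mouth, longitudinal foot-to-mouth flows, and flows
running along filament-shaped colonies.  These currents are measured by
seeding the surface layer with fluorescent microbeads, video-tracking the
beads, and analysing the resulting 2-D trajectories.

`ciliaflow` is the trajectory-analysis side of that experiment: it takes
particle-track tables (tracker-export CSV; µm positions, thinned frames)
and produces

1. **per-track movement statistics** — number of turns, sinuosity, mean /
   maximum / variance of speed, self-intersections, track length and net
   displacement length;
2. **track-regime clustering** — a k-nearest-neighbour graph on the
   z-scored feature vectors under correlation distance, Leiden community
   detection (resolution 0.05) and a UMAP embedding (min_dist 0.2);
3. **composition statistics** — per-species cluster-composition percentages,
   their Euclidean distance matrix, per-cluster Welch t-tests, and a
   permutation test (1000 random splits) on per-cluster proportion
   differences between a focal group and the rest;
4. **Lagrangian flow structure** — a smoothed 30 × 30 grid vector field
   fitted to all track steps of a recording, flow maps integrated with
   bilinear interpolation + 4th-order Runge–Kutta, the finite-time Lyapunov
   exponent (FTLE) field whose ridges mark transport barriers, and
   SimplePPT-style principal trees fitted to the tracked points of a frame;
5. **a synthetic-track generator** — beads advected by the stereotyped flow
   patterns (stellar in/out, longitudinal, filament, uniform, saddle,
   vortex, or pure Brownian) with tunable diffusion, measurement noise,
   sedimentation drift, frame rate and frame thinning, so the whole
   pipeline is verifiable without any recording.

## The statistics in brief

For a track with points $x_0, \dots, x_{n-1}$ sampled every
$\Delta t = k/f$ seconds ($f$ = camera fps, $k$ = frame-thinning factor):

- path length $L = \sum_i \lVert x_{i+1} - x_i \rVert$, displacement
  $d = \lVert x_{n-1} - x_0 \rVert$, **sinuosity** $S = L/d \ge 1$;
- **windowed sinuosity**: $S$ of each 20-point sliding window, each point
  keeping the maximum over the windows containing it; a **turn** is a
  maximal run of points with windowed sinuosity $> 1.2$;
- per-step speeds $\lVert x_{i+1}-x_i \rVert / \Delta t$ give mean, max and
  sample variance; self-intersections are counted over all non-adjacent
  segment pairs.

The grid vector field $v$ minimises
$\frac1N\sum_s \lVert v_\text{obs}(s) - v(m_s)\rVert^2 +
\frac{w}{M}\lVert L v \rVert^2$ over the $M$ grid nodes (bilinear
interpolation at step midpoints $m_s$, lattice Laplacian $L$, smoothing
weight $w = 0.5$).  The FTLE at a grid point is
$\frac{1}{|T|}\ln\sqrt{\lambda_\mathrm{max}\big((\nabla\Phi)^\top\nabla\Phi\big)}$
for the flow map $\Phi$ integrated over horizon $T$.

## Worked example

```python
import numpy as np
import ciliaflow as cf

# a synthetic "stellar inward" recording: beads spiralling toward a mouth
field = cf.make_flow_field("stellar_in", domain=(-50, 50, -50, 50), v0=8.0, radius=45)
params = cf.SimulationParams(n_tracks=150, duration_s=5, fps=24, subsample_factor=2,
                             diffusion=0.5, measurement_noise_sd=0.2, seed=1)
tracks = cf.simulate_tracks(field, params, seeding="annulus", annulus=(15, 42))
print(f"{len(tracks)} tracks, frame_dt = {tracks.frame_dt:.4f} s")

table = cf.feature_table(tracks)
print(table.df[["sinuosity", "mean_speed", "track_length", "displacement_length"]]
      .describe().loc[["mean", "50%"]].round(2))

from ciliaflow.pipeline import summarize_flow_presence
res = summarize_flow_presence(table)
print("verdict:", res["verdict"])

F = cf.fit_grid_vector_field(tracks, domain=(-50, 50, -50, 50))
XX, YY = np.meshgrid(F.x_nodes_, F.y_nodes_)
r = np.hypot(XX, YY)
radial = (F.u_ * XX + F.v_ * YY) / np.maximum(r, 1e-9)
disk = (r > 5) & (r < 42)
print(f"inward nodes in disk: {(radial[disk] < 0).mean():.1%}")
```

prints

```
150 tracks, frame_dt = 0.0833 s
      sinuosity  mean_speed  track_length  displacement_length
mean       1.62        8.73         43.67                28.52
50%        1.51        8.76         43.82                28.71
verdict: directional currents detected
inward nodes in disk: 100.0%
```

Each bead moves ~8.7 µm/s (the imposed 8 µm/s advection plus diffusion and
tracking jitter), paths are mildly curved (median sinuosity 1.5 — jitter on
sub-µm steps), the presence heuristic flags the recording as directional,
and the fitted vector field points toward the centre at every grid node
inside the seeded disk — the "stellar inward" signature.

The same steps run from a shell:

```bash
ciliaflow simulate --pattern stellar_in --v0 8 --seed 1 --out tracks.csv
ciliaflow features tracks.csv --out features.csv
ciliaflow field tracks.csv --out field.txt
ciliaflow run --config config.yaml     # full pipeline with persisted outputs
```

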