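# Methods

## The model

`pgcsim` simulates N motile progenitor cells as adhesive self-propelled
point particles in a two-dimensional rectangular chamber that abstracts
the gonad-forming region of a zebrafish embryo at ~1 day post
fertilisation. Working units are cell diameters (d = 11 μm) and
minutes. Each particle i obeys the overdamped Langevin equation

    γ dx_i/dt = F0 n̂_i + Σ_j F_ij + F_iw ,      n̂_i = (cos θ_i, sin θ_i)
    dθ_i      = sqrt(2 D_r) dW_i

integrated with the Euler–Maruyama scheme. The motility force F0 = γ v0
propels a free particle at exactly v0 = 0.05 d/min (0.6 μm/min to the
printed precision of the measured value), and the propulsion direction
diffuses with D_r = 1/60 min⁻¹, giving a persistent random walk with
persistence time 1/D_r = 60 min. Cell–cell adhesion is a truncated 12-6
Lennard-Jones pair force with well depth ε (the adhesion parameter,
swept 0–0.3) and σ = 2^(−1/6) d, so the potential minimum sits at 1 d —
touching cells. The cutoff is 2.5 σ, plain truncation.

The chamber is 5 × 36 d: periodic along the long (y) axis (minimal-image
convention for pair displacements; cell number is conserved by
construction) and walled across the short (x) axis. Walls are
short-ranged purely repulsive WCA potentials (12-6 truncated at its
minimum) acting on the distance to each wall. Two boundary rules are
compared:

* **non-reflective** — the wall only pushes; persistent self-propelled
  particles therefore accumulate against it, the generic wall-trapping
  of active matter;
* **reflective** — in addition, any particle within a small threshold of
  wall contact has its propulsion instantly set perpendicular to the
  wall, pointing into the interior. This mimics contact inhibition of
  locomotion at a tissue barrier: the cell repolarises away on touch.
  Reorientation re-fires on every step spent within the threshold;
  the event log records zone entries.

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `n_particles` | 14 | measured cell count at the site |
| `cell_diameter_um` | 11 | unit length in μm |
| `speed_v0` | 0.05 d/min | measured arrival-stage speed |
| `rotational_diffusion_dr` | 1/60 min⁻¹ | measured directional persistence |
| `adhesion_epsilon` | 0.2 | the adhesion level that best matches the observed cluster-size mixture |
| `drag_gamma` | 12 | sets the adhesion-to-propulsion force ratio; see below |
| `channel_width`, `channel_length` | 5, 36 d | measured region |
| `lj_sigma`, `lj_cutoff` | 2^(−1/6), 2.5 σ d | pair minimum at contact; standard truncation |
| `wall_sigma`, `wall_epsilon`, `wall_force_cap` | 0.15 d, 0.02, 6 | thin, effectively hard wall; see numerics |
| `reflect_threshold` | 0.1 d | "small threshold" from the wall-contact position (wall_range + 0.1 ≈ 0.27 d from the wall) |
| `dt` | 0.02 min | integrator stability; see numerics |
| `t_total`, steady window | 5000, [4000, 5000] min | protocol used for all steady-state statistics |
| `save_interval` | 5 min | ~10³ analysis frames per run |

### The drag coefficient γ

The equation of motion fixes two independent observable ratios: F0/γ (=
v0, measured) and ε/γ (adhesion force scale). Because the model has no
translational noise, a bound pair separates only if the peak relative
motility speed 2 v0 exceeds the peak relative closing speed from the
bond, 2·max|F_LJ|/γ = 2·2.686 ε/γ, which gives a *sharp* binding
threshold

    ε_c = v0 γ / 2.686 .

The observed regime map — wall accumulation and transient small
clusters at ε ≤ 0.2, a stable compact cluster only at ε = 0.3 —
therefore requires ε_c to lie between 0.2 and 0.3. The default γ = 12
puts ε_c ≈ 0.22. With γ near 1 the whole swept range is deep in the
irreversible-aggregation regime and the ε-dependence of the steady
state disappears, which contradicts the phenomenology the model is
built to capture; a coarse scan over γ confirmed that the window
8 ≲ γ ≲ 13 is where all the qualitative contrasts coexist.

### Numerical choices

* **Time step.** Overdamped Euler is stable when dt < 2γ/k for the
  stiffest active contact, k = U''(r). At the pair minimum this allows
  dt ≈ 0.5 min at ε = 0.3, γ = 12, but compressed contacts inside a
  dense 14-cell cluster sit on the much stiffer core (r ≈ 0.9 d).
  dt = 0.02 min runs the full sweep grid cleanly; a runtime guard
  aborts with a diagnostic if any single-step displacement exceeds
  0.1 d or turns non-finite.
* **Walls.** σ_w = 0.15 d keeps the excluded zone (wall_range =
  2^(1/6) σ_w ≈ 0.17 d) narrower than one density bin (0.25 d), so wall
  accumulation is resolvable in the histogram; ε_w = 0.02 keeps the
  wall stiffness inside the stability bound. The wall force is clamped
  at 6 force units very close to the wall so that an overshooting
  particle is pushed back in finite steps; the clamp region is ~0.005 d
  wide and unreachable in normal dynamics. Force–potential consistency
  is tested by central differences away from clamp and cutoff.
* **Noise streams.** One master seed spawns one substream per particle
  (`numpy` SeedSequence children), so an N-particle run at ε = 0 far
  from walls factorises *exactly* into N single-particle runs — used as
  a correctness test of the integrator.
* **Initial condition.** Uniform random positions with pairwise
  (minimal-image) separation ≥ 0.9 d, uniform headings. At ε = 0.3 and
  dt = 0.02 the first-step displacement at 0.9 d separation stays under
  the guard.
* **Tie-breaks.** Cluster labels are renumbered in order of first
  occurrence; the periodic wrap maps exact-length values to 0 so y
  always lies in [0, L).

## Observables

Clusters are single-linkage connected components at linking distance
1.2 d — just beyond the adhesive minimum, so touching cells link and
second-shell cells do not (±0.1 d changes absolute sizes slightly but
none of the qualitative contrasts). "Large cluster" means ≥ 3 cells,
separating pairs from aggregates at N = 14; both thresholds are
parameters. The density profile uses 20 bins across the 5-d width.
Steady-state statistics pool frames in [4000, 5000] min over ≥ 10
independent seeds; seeds are the independent unit for standard errors,
and the fraction-in-large-clusters uncertainty is a bootstrap over
frames.

Track statistics operate on tidy tables (track_id, time_min, x_um,
y_um), from the simulator (unwrapped across the periodic seam) or the
synthetic generator. Speeds are displacement per time gap with
time-gap-weighted means; persistence is an exp(−t/τ) fit to the pooled
step-direction autocorrelation. Contact episodes are maximal runs of ≥ 2
consecutive common-grid frames with separation ≤ 12 μm (cell–cell,
centre-to-centre: one diameter plus margin) or point-to-polyline
distance ≤ 6 μm (cell–barrier); mixed frame intervals are first linearly
interpolated onto one global grid at the coarsest per-track median
interval. Episode duration is last-minus-first marked time, so k frames
at interval Δ last (k−1)Δ — stated explicitly because the convention
used for the in vivo numbers is not recoverable. Cross-sectional
positions are normalised affinely onto [0, 1] between the region
borders.

The persistence fit (both for simulator ensembles and tracks) uses lags
up to ~1.5 τ, where the autocorrelation is well above its sampling
noise floor; including the noise-dominated tail roughly triples the
estimator spread.

## The synthetic-data generator

`synthetic.generate_prw_tracks` emulates the measured tracks: constant
speed 0.6 μm/min, persistence 60 min, 0.5–3 min frame intervals
(default 1 min), Gaussian marking jitter of 0.5 μm, billiard reflection
at the arena edge. Contact episodes are *planted* by steering the
designated partner along a smooth cosine approach/hold/retreat ramp to
a hold distance inside the contact threshold, so speeds stay physical
and the truth episode list is exact; overlapping steering windows that
share a track are rejected as infeasible. `generate_position_table`
draws cross-sectional positions from a centre-truncated normal, a
uniform, or a two-sided wall-peaked mixture — the three phenotypes the
channel model produces.

What the generator does **not** emulate: cell shape and subcellular
polarity (no actin readout, so the rapid-vs-prolonged repolarisation
split is out of scope), density-dependent motility changes, uneven
manual-marking cadence, and segmentation errors. Passing the recovery
tests therefore shows the estimator chain is unbiased for ideal
persistent random walks, not that it is robust to every artefact of
microscopy tracking. In particular, finite-difference speeds computed
from jittered positions are biased upward by ~sd·sqrt(π/2)/Δ per frame;
parameter-recovery tests run on jitter-free tracks and the jitter
default is exercised separately.

## Known limitations

* **Coarsening is slow at strong adhesion.** Above ε_c aggregation is
  irreversible, and the final merger of the last two clusters is a
  quasi-1D diffusive search along the periodic axis with cluster
  diffusivity ≈ v0²τ/(2n) — a ~10⁴-min timescale that the 5000-min
  protocol truncates. In the [4000, 5000] window at ε = 0.3 all 14
  cells form one cluster in only ~30% of frames (any γ, both boundary
  modes); on longer horizons (~15 000 min) reflective-wall runs do
  converge to a single centrally positioned cluster (a dedicated test
  demonstrates this), while non-reflective runs can take longer still.
  Statements about the ε = 0.3 steady state in the standard window
  should be read as mid-coarsening snapshots.
* Two dimensions only; the thin third dimension of the real region is
  dropped.
* No chemokine fields, no LPP repulsion gradients, no cell polarity
  mechanics: boundaries and ε absorb all of these.
* Fixed N: no division, death, or exchange with the surroundings.
* The binding threshold is sharp because translational noise is absent;
  real cells jostle, so the in vivo transition is necessarily smoother.
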