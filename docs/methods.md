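# Methods

## Model and assumptions

Each target is an orientation-free particle with state
`s = (x, y, z, ẋ, ẏ, ż)` (metres, metres per second, world frame
right-handed with z up). Dynamics are a discrete constant-velocity model
`s_{t+1} = A s_t + w` with `A = [[I, dt·I], [0, I]]`; everything a real
animal does beyond straight flight (saccades, accelerations) is absorbed
into the process noise `w ~ N(0, Q)`. The observation is the
concatenation of the target position's projections through the
contributing cameras, linearized analytically for the EKF; its noise is
isotropic Gaussian on the image plane. These are strong assumptions —
the posterior is only approximately Gaussian through the projective
nonlinearity — but at 60–200 frames per second the per-frame motion and
innovation are small and the linearization is accurate.

Targets are assumed nearly independent: the filter and association run
per target. The only inter-target coupling is the merge-prevention pass
(below). Identity is deliberately not preserved across track loss: a
target that disappears and reappears gets a new id.

## Parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `dt` | 0.01 | s | 100 fps small-arena rig |
| `q_pos` | 1e-4 (100 mm²) | m² | manoeuvre noise, fruit-fly scale |
| `q_vel` | 0.25 | m² s⁻² | manoeuvre noise on velocity |
| `r_px` | 1.0 | px² | one pixel of detection variance |
| `init_pos_var` / `init_vel_var` | 0.01 / 1.0 | m², m² s⁻² | deliberately high birth uncertainty |
| `max_pixel_dist` | 20 | px | association gate radius |
| `min_area` | 1 | px² | area gate (strict inequality) |
| `max_reproj_error_birth` | 3 | px | birth-hypothesis acceptance |
| `max_covariance_trace_death` | 0.1 | m² | positional-trace death threshold |
| `max_frames_unobserved` | 20 | frames | secondary death criterion |
| `update_interval` / `learning_rate` | 500 / 0.25 | frames, – | background refresh |
| `clear_fraction` | 0.3 | – | moment-arm suppression in blobs |

The noise covariances are the values that work well for fruit-fly-sized
targets at ~100 fps; the gates are "arbitrary threshold" knobs exposed in
`TrackerConfig` and on the CLI. Positional process noise is stored in m²
(100 mm² = 1e-4 m²) so all geometry is metric.

## Numerical choices

* **Projection / triangulation / calibration.** Pixel (0,0) is the
  centre of the top-left pixel. Triangulation solves the stacked
  cross-product constraints by SVD (no iterative refinement); it raises
  on <2 views or a solution at infinity (parallel rays). DLT calibration
  uses Hartley-style similarity normalization of both point sets,
  requires ≥6 non-coplanar points (coplanarity detected on the 3D
  scatter matrix), returns `‖P‖_F = 1` with sign fixed by positive
  median depth. Distortion is two-term radial about an explicit centre;
  undistortion is a fixed-point iteration (tol 1e-8 px, ≤20 iterations)
  — adequate for mild machine-vision distortion, not fisheye.
* **EKF update.** One stacked update over the contributing cameras
  (block-diagonal R), Joseph-form covariance update plus explicit
  symmetrization to keep P positive-semidefinite. With no gated
  observations the posterior is set to the prior, so P grows by Q until
  either more data arrive or the death threshold is crossed.
* **Likelihood.** The ray term of the association likelihood is
  `exp(−d²_mahal/2)` of the closest point on the feature's
  back-projected ray to the prior mean under the prior's 3×3 positional
  covariance — the closest point is closed-form because the squared
  Mahalanobis distance is quadratic in the ray parameter. Any monotone
  decreasing function of the distance yields the same argmax; the
  Gaussian kernel was chosen for interpretability. The two cheap gates
  short-circuit it.
* **Tie-breaks.** Pixel gate inclusive at the boundary; area gate strict
  (`α > min_area`); birth hypotheses ranked by (camera count, −error);
  shared-assignment conflicts resolved by summed image distance with
  ties to the lower target id.
* **Birth search.** Exhaustive enumeration over camera combinations is
  exponential in clutter; a per-frame budget (default 10,000 hypotheses)
  bounds the cost and defers overflow to the next frame. Two-view
  hypotheses always triangulate exactly, so chance alignments of clutter
  can create short-lived tracks; they die quickly and are the expected
  cost of biasing toward few missed detections.
* **Eccentricity.** ε = sqrt(1 − λ₂/λ₁) from the eigenvalues of the
  central second-moment matrix; a single-pixel blob returns ε = 0.
  Orientation θ = ½·atan2(2μ11, μ20 − μ02) in [0, π).

## The synthetic generator

`flight3d.synthetic` emulates the study conditions the tracker is meant
for: a ring of 2–11 cameras (common focal length chosen so the whole
arena is visible in every view), flight paths made of constant-speed
segments (speed ~ N(0.15, 0.03) m/s) joined by saccades — 90–150°
direction changes over 2–5 frames at Poisson times (default 0.5 s⁻¹) —
confined to the arena by reflective turning; detections with isotropic
Gaussian pixel noise, Bernoulli misses, and Poisson clutter whose
area/peak statistics match true detections so that area gating is a
meaningful test. The default arena is 0.3 × 0.3 × 1.5 m at 100 fps; an
11-camera, 2 m × 0.8 m, 60 fps preset is provided. Rendered frames place
Gaussian blobs (optionally elongated along the projected velocity) on a
smooth random texture.

What it does **not** emulate: occlusion by other targets or apparatus,
motion blur, illumination flicker, wing/body articulation, target–target
interaction (pursuit), and non-Gaussian heavy-tailed detection errors.
Passing tests therefore demonstrate correctness of the algorithms under
the stated noise model, not robustness to every artefact of real
footage.

## Problem sizes in tests and the acceptance script

The shipped checks use desk-scale runs chosen to make their statistics
stable: 1000 tracked frames for reprojection precision, 200 calibration
replicates, 1000 random association instances, 100 seeded two-target
crossings, 100-frame state-recovery runs, and 10–20 rendered frames for
blob recovery. Each reported number is recomputed from scratch at run
time from the seed supplied on the command line.

## Known limitations

* NNSF keeps a single association hypothesis; during close passes the
  wrong assignment can briefly win and identities may swap even though
  merging is prevented. Offline multi-hypothesis re-association is out
  of scope.
* Track birth requires simultaneous consistent detections in ≥2 cameras;
  a target visible in one camera only is never born (though an existing
  track survives on one camera).
* Distortion parameters are accepted as input, never estimated;
  multi-camera self-calibration and bundle adjustment are out of scope.
* The death criterion uses the positional covariance trace only; a track
  with confident position but wild velocity is kept.
* Real-time transport (camera buses, clock sync) is replaced by an
  in-process frame iterator; the algorithmic order of operations per
  frame is preserved exactly.
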