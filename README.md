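# flight3d

Multi-camera 3D tracking of multiple flying animals — flies, hummingbirds
and similar small, fast targets viewed by a rig of 2–11 calibrated
cameras. The package re-implements, at desk scale, the classic real-time
tracking pipeline used in flight-behaviour laboratories:

1. **2D feature extraction** — running-Gaussian background subtraction
   turns each camera frame into a short list of blob detections
   `z = (u, v, α, β, θ, ε)`: sub-pixel centre, area, peak difference,
   orientation and eccentricity from image moments.
2. **State estimation** — each target is an extended Kalman filter over
   the state `s = (x, y, z, ẋ, ẏ, ż)` with constant-velocity dynamics
   `s_{t+1} = A s_t + w`, `w ~ N(0, Q)`, and the nonlinear observation
   `y = h(s) + v`, where `h` concatenates the projections of the target's
   position through every contributing camera (3×4 matrices `P_i`) and
   `v ~ N(0, R)` is pixel noise. Manoeuvring is absorbed by `Q`
   (defaults: 100 mm² position, 0.25 m² s⁻² velocity; `R` = 1 px²).
3. **Data association** — the nearest-neighbour standard filter: per
   target and per camera, the feature maximizing a gated likelihood
   (pixel-distance gate × area gate × `exp(−d²_mahal/2)` of the
   feature's back-projected ray against the positional prior). A
   merge-prevention pass guarantees no two targets keep an identical
   non-empty feature set. Tracks are *born* by exhaustive triangulation
   hypothesis testing over all 2…n-camera combinations of unclaimed
   features, and *die* when the positional covariance trace crosses a
   threshold.
4. **Geometry** — pinhole projection, two-term radial distortion, ray
   back-projection, SVD triangulation and DLT calibration from 2D–3D
   correspondences.
5. **Simulation & analysis** — a synthetic generator (camera rigs,
   saccade-punctuated flight paths, noisy/cluttered detections, rendered
   blob images) with full ground truth, plus trajectory statistics:
   horizontal speed, angular velocity, approach angle to a landmark, and
   wall-filtered speed histograms.

## Worked example

```python
import numpy as np
from flight3d.pipeline import Tracker, TrackerConfig
from flight3d.synthetic import SimulationConfig, make_rig, make_trajectory, observe

cfg = SimulationConfig(n_frames=300, pixel_noise_sigma=0.5,
                       miss_rate=0.05, clutter_rate=0.5, seed=0)
rng = np.random.default_rng(cfg.seed)
rig = make_rig(cfg)                      # 5 cameras, 0.3 x 0.3 x 1.5 m arena
truth = make_trajectory(cfg, rng)        # saccading flight at ~0.15 m/s
bundles, _ = observe(truth, rig, cfg, rng)
tracker = Tracker(rig, TrackerConfig(dt=cfg.dt))
trajectories = tracker.run(bundles)
```

Running `python examples/track_synthetic_flight.py` (this scenario)
prints:

```
frames: 300, features seen: 2167
births: 15, deaths: 12
longest trajectory: 300/300 frames (100.0% coverage)
position RMSE: 1.89 mm
```

The fly's track covers every frame despite 5% missed detections and
Poisson clutter (the extra short-lived births are clutter hypotheses
that die within a few frames), and the 3D position error is ~2 mm —
the precision 0.5 px detection noise supports in this rig. The other
scripts in `examples/` demonstrate DLT calibration + triangulation,
blob extraction from rendered images, and flight statistics.

A thin CLI mirrors the library: `flight3d simulate | extract | track |
analyze` (see `flight3d --help`).

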