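# motionews

Early-warning-signal analysis of intentional motion onset.

Before a person starts a deliberate movement, the body's resting
fluctuations change character: their lag-1 autocorrelation AR(1) and
autocorrelation decay time τ rise, and their variance grows.  These
are the classic early warning signals (EWS) of a system approaching a
critical transition — here, a saddle-node (fold) bifurcation in which
a slowly drifting "decision momentum" *y* destabilizes the static pose
of the fast variable *x* (the body velocity):

    ẋ = y + a x² − x³ + γ ξ(t),    ẏ = ε.

Near the transition time *t\** the fluctuation variance of a fold
diverges as σ² ∝ (t\* − t)^(−1/2) — against (t\* − t)^(−1) for
pitchfork or Hopf transitions — so the fitted exponent identifies the
bifurcation type.

`motionews` packages this analysis end to end, for researchers in
motor neuroscience and critical-transition detection:

* **foldsim** — fold-transition dot trajectories and matched
  step-plus-noise controls (the stimulus ensembles of a
  motion-detection psychophysics task);
* **synthetic_motion** — synthetic 240 Hz seven-sensor motion-capture
  trials of an attacker/defender reaching game, with a latent fold
  fluctuation field and exact ground-truth event times;
* **ews** — sliding-window AR(1), τ and variance with the
  threshold-based rise detectors (AR(1) > 0.1, τ jump > 20%, variance
  threshold);
* **kinematics** — first-PC / center-of-mass extraction and the
  0.05 cm/s motion-onset rule;
* **scaling** — variance-divergence curve extraction (±100 ms around
  the divergence, 30-trial block averaging) and the power-law fit
  log σ² = −log b + n·log(t\* − t) on 48 ms sub-windows;
* **stats** — kernel-density outlier filtering, the Δt intercept
  regression of onset times on EWS times, and reaction-time
  comparisons (Mann–Whitney, Kolmogorov–Smirnov, Harrell–Davis shift
  function);
* **pipeline / cli** — one-config orchestration and the `motion-ews`
  command-line entry point.

See `docs/methods.md` for the models, numerical choices, and what the
synthetic generators do and do not emulate.

## Worked example

Simulate matched fold/control dot ensembles and compare the arms:

```python
import json
from motionews import RunConfig, run_experiment3

report = run_experiment3(RunConfig(exp3_n_per_arm=100, seed=7))
print(json.dumps(report["pre_transition_detection_rates"], indent=1))
```

prints

```json
{
 "fold": {"ar1": 1.0, "tau": 1.0},
 "control": {"ar1": 0.64, "tau": 0.12}
}
```

Every fold trajectory shows an AR(1) and decay-time rise from windows
lying wholly before its transition time, while the matched
uncorrelated controls rarely do (the residual control rate is the
false-positive rate of the threshold detectors on white noise).  The
report also carries a motion-threshold observer readout; see the
methods note for why that readout favors the control arm even though
the fold arm warns earlier.

On the synthetic motion-capture side:

```python
import numpy as np
from motionews import MotionConfig, generate_attacker_trial, first_pc, velocity
from motionews import WindowSpec, compute_ews, detect_tau_rise

trial = generate_attacker_trial(MotionConfig(seed=5))
pc = first_pc(trial)                       # six body sensors, finger excluded
v = velocity(pc.projection / np.sqrt(len(pc.sensors)), trial.rate)
s = compute_ews(v, WindowSpec(length_ms=60, rate=trial.rate), t0=trial.t[1])
print(f"tau rise {detect_tau_rise(s):.3f} s, "
      f"finger onset {trial.truth['finger_onset_true']:.3f} s")
```

prints `tau rise 1.256 s, finger onset 1.379 s` — the decay-time rise
leads finger motion by ~120 ms here; across an ensemble the
density-filtered regression recovers the 131 ms lead the generator
encodes.

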