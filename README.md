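# imugait

Seven-node wearable-IMU gait analysis: orientation estimation with a
parameter-adaptive nonlinear complementary filter, adaptive heel-strike /
toe-off detection, ZUPT-corrected foot trajectories and spatiotemporal
parameters, clinical joint and pelvic angles, and method-comparison
statistics — together with a synthetic gait simulator so that every stage of
the pipeline can be exercised and verified without any hardware.

## Who this is for

Researchers and engineers working on wearable inertial gait analysis: a
sensor network of nine-axis IMUs on the pelvis, both thighs, shanks, and
feet (seven nodes, 200 Hz) measures the full pelvis–lower-limb kinematic
chain during walking. The package turns those raw streams into the outputs a
gait lab reports — heel-strike/toe-off events, stride length, step width,
cadence, walking velocity, sagittal hip/knee/ankle angles, pelvic tilt and
rotation — and quantifies agreement against a reference system (RMSE,
relative RMSE, Pearson r, Bland–Altman bias and limits of agreement,
ICC(2,1)).

## The model

Per-node orientation is a quaternion q (sensor→global) driven by the
strapdown equation q̇ = ½ q ⊗ (0, ω) and corrected by a PI feedback on the
composite cross-product error

    e = â × v̂_g + m̂ × v̂_b,       ω̂ = ω_gyro − b + Kp·e + Ki·∫e dτ,

where v̂_g and v̂_b are the global gravity and magnetic references projected
into the sensor frame by the current estimate. Two gait-aware adaptations
distinguish the filter from a fixed-gain complementary filter:

* **magnitude gating** — Kp = Kp0 · exp(−α (‖a‖ − g)²), so the
  accelerometer correction is strongest under quasi-static load and nearly
  vanishes during impact and swing transients (Kp0 = 1.8, α = 0.5);
* **phase scheduling** — Ki switches between 0.05 during stance (reliable
  gravity reference) and 0.005 during swing.

Heel strikes and toe offs are detected on the foot nodes by a dual-feature
conjunction: local extrema of global-frame vertical acceleration against
individualized thresholds (0.6 × the mean extremum amplitude of the first
three stable cycles) confirmed by sagittal angular-velocity zero crossings
within ±50 ms. Foot trajectories are double-integrated with zero-velocity
updates anchored at detected foot-flat midpoints; joint angles are Z–Y–X
Euler decompositions of q_prox⁻¹ ⊗ q_dist after neutral-standing
sensor-to-segment alignment.

## Worked example

Simulate a 14-cycle walk (cadence 114 steps/min, stride 1.36 m, with sensor
noise and a synthetic 100 Hz reference), run the full pipeline, and compare:

```
imugait simulate --seed 7 --out demo
imugait run demo/trial.csv --reference demo/reference.csv --out demo/report
```

`demo/report/summary.md` then contains (abridged):

```
## Spatiotemporal parameters

- stride length: 1.375 m
- step width: 0.090 m
- cadence: 114.0 steps/min
- walking velocity: 1.261 m/s
- gait cycle: 1.053 s

## Mean range of motion (stable cycles)

- hip_l: 45.41°
- knee_l: 64.02°
- ankle_l: 25.73°
- pelvic_tilt: 3.04°
- pelvic_rotation: 8.00°

## Agreement vs reference

- hip_l: RMSE 4.48, r 0.957, ICC 0.954
- pelvic_rotation: RMSE 0.36, r 0.989, ICC 0.989
```

The simulated subject walks at 1.053 s per gait cycle with 1.36 m strides,
so the recovered stride length (1.375 m, ~1% high) and cadence
(114 steps/min, exact) indicate that event detection and the ZUPT
integration are working; the ROM values match the simulator's canonical
normal-gait waveforms (hip ≈ 43°, knee ≈ 63°, ankle ≈ 26°). The agreement
block compares the pipeline output against the noisy, time-lagged reference
stream after automatic cross-correlation alignment.

The same objects are available from Python:

```python
from imugait import (GaitProfile, NoiseModel, TrialRecording,
                     generate_gait_truth, synthesize_imu, run_pipeline)

truth = generate_gait_truth(GaitProfile())
streams = synthesize_imu(truth, NoiseModel(seed=7))
report = run_pipeline(TrialRecording(streams))
print(report.spatiotemporal.stride_length_m)
```

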