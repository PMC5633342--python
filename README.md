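# axontrack

Tracking single action potentials (APs) across axonal arbors recorded on
CMOS-based high-density microelectrode arrays (HD-MEAs).

Axonal extracellular spikes are tiny — typically 1–20 σ_noise, versus up
to ~180 σ_noise near the axon initial segment (AIS) — so a simple
amplitude threshold either misses them or drowns in false positives.
`axontrack` implements the multi-electrode **matched-filter (template
matching)** approach for detecting individual axonal APs on local groups
of 1–6 neighboring electrodes, plus everything around it: spike-
triggered-average electrical footprints, sub-sample arrival-time
estimation, and the downstream conduction statistics (activation
latency/jitter decomposition, conduction velocity, propagation-jitter
accumulation, high-frequency train effects).  A seeded synthetic HD-MEA
recording simulator with full ground truth drives all benchmarks and
tests.

## The method in brief

With the stacked multi-electrode template `s` (k electrodes × L samples)
and spike-free noise covariance `C`, the optimal linear detector is the
whitened matched filter `w = C⁻¹s`.  Convolving the recording with `w`
per electrode and summing over the group gives an output that peaks at
`E = sᵀC⁻¹s` for a perfectly aligned AP and is `N(0, E)` on noise, so
the analytic (equal-prior Bayes) detection threshold is `E/2`.  The
filter-output peak, sinc-interpolated at 10× (effective 200 kHz),
estimates the AP arrival time at sub-sample precision.

Arrival times referenced to a proximal alignment electrode then yield:

* **velocity** `v = 1/slope` of mean arrival time vs. axial distance
  (arc length along the branch, in mm);
* **propagation jitter**: arrival-time variance grows linearly with
  axial distance (a white-noise/Brownian accumulation model); the
  through-origin regression slope gives the jitter rate as
  `√slope` in µs per mm;
* **activation latency/jitter** per stimulation voltage via
  `T_arrival = T_propagation + T_activation`,
  `J_arrival = J_activation + J_propagation`, with voltages normalized
  as `Vnorm = (V − V_inter)/(V_thr − V_inter)`.

See `docs/methods.md` for the full model, defaults and limitations.

## Worked example

```python
from axontrack.benchmarks import mixed_trial_evaluation, kinetics_recovery

# 40 AP trials mixed with 20 noise trials (2:1) per electrode group on a
# simulated branched axon (axonal amplitudes 3-10 sigma); 3-electrode
# whitened matched filters with the analytic threshold:
res = mixed_trial_evaluation(seed=0, ks=(3,))[3]
print(f"TP {res.tp_percent:.1f}%  FP {res.fp_percent:.1f}%  "
      f"({res.n_spike_trials} spike trials, {res.n_detections} detections)")

# full pipeline on a straight 1.5 mm axon, 15 electrodes, 100 trials:
kin = kinetics_recovery(seed=0)
print(f"velocity {kin['velocity_m_per_s']:.3f} m/s (true {kin['true_velocity_m_per_s']}), "
      f"jitter {kin['jitter_rate_us_per_mm']:.1f} us/mm (true {kin['true_jitter_rate_us_per_mm']})")
```

prints

```
TP 100.0%  FP 0.0%  (1760 spike trials, 1760 detections)
velocity 0.725 m/s (true 0.71), jitter 88.1 us/mm (true 100.0)
```

i.e. every one of the 40 AP trials is detected in each of the 44
electrode groups with no false positives at axonal signal-to-noise
ratios, and the detection-based arrival times recover the simulated
conduction velocity within ~2% and the propagation-jitter accumulation
rate within ~12%.

## Command line

```bash
axontrack simulate --preset propagation --seed 7 --out rec.h5 --ground-truth gt.csv
axontrack footprint --in rec.h5 --out fp.h5
axontrack detect    --in rec.h5 --footprint fp.h5 --k 3 --out events.csv
axontrack analyze   --events events.csv --path branch.csv --mode jitter --out stats.csv
axontrack benchmark --seed 1 --out metrics.json
```

`benchmark` runs the full mixed-trial detection evaluation and the
kinetics recovery and emits a metrics JSON (`tp_percent`, `fp_percent`,
`velocity_mps`, `jitter_rate_us_per_mm`); identical seeds give
byte-identical output.

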