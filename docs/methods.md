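# Methods

`axontrack` detects single action potentials (APs) of one neuron's axonal
arbor in multichannel extracellular recordings from high-density
microelectrode arrays (HD-MEAs), and turns the per-trial arrival times
into conduction statistics.  Because axonal extracellular spikes are tiny
(1–20 σ_noise) compared to the axon-initial-segment (AIS) signal
(up to ~180 σ_noise), single-electrode amplitude thresholding fails on
axons; the package's core is a multi-electrode, noise-whitened matched
filter that pools neighboring electrodes.

## Detection model

For an electrode group with stacked spatio-temporal template
`s` (k electrodes × L samples, from the spike-triggered-average
footprint) and spike-free noise with spatio-temporal covariance `C`, the
matched filter solves `C w = s`.  The recording is correlated with `w`
per electrode and summed over the group; a perfectly aligned template
produces the output peak `E = sᵀC⁻¹s`, and on Gaussian noise the output
is zero-mean with variance `E`.  Detection thresholds the output; the
likelihood-ratio threshold for two equal-variance Gaussians is analytic,

    θ = E/2 + (σ²_out / E) · ln(prior_ratio)  =  E/2   at equal priors,

and requires no manual tuning.  The output peak is a robust estimator of
the AP's temporal position; sub-sample times come from windowed-sinc
(Hann-tapered, Whittaker–Shannon) interpolation of the output around the
peak at 10× resolution (an effective 200 kHz grid for 20 kHz data).
Whole-trace band-limited upsampling uses Fourier resampling.

The covariance is estimated from spike-free periods as cross-covariance
functions `c_ij(h)` up to `max_lag = L − 1` (3 ms at 20 kHz), assembled
into the block-Toeplitz `C`, symmetrized and diagonally loaded with
`ε·σ_i²` (ε = 1e-3) for positive definiteness.  A `spatial` whitening
mode keeps only the lag-0 covariance for speed.  With white noise the
filter reduces exactly to plain template correlation scaled by `1/σ²`.

Filter templates are cut from the footprint where any group electrode
exceeds 0.5 σ, clipped to 1–3 ms around the seed electrode's negative
peak.  The seed's sub-sample peak position within the template (parabolic
interpolation) is carried as a timing correction so detected event times
estimate the arrival at the seed electrode.

## Footprint and AIS

Trials are 10 ms windows (3 ms pre-trigger, 7 ms post — axonal arrivals
trail the AIS) triggered on −5 σ crossings of the AIS electrode, aligned
to the negative peak within 0.5 ms of the crossing, with a 2 ms trigger
dead time.  Forty trials per electrode are averaged by default.
Templates from overlapping electrode configurations are merged by
integer-sample alignment on the largest shared electrode and averaging
weighted by trial counts.  The AIS is the electrode with the maximal
negative-phase template amplitude (ties: earliest peak, then lowest id).

## Kinetics

Arrival times decompose as `T_arrival = T_propagation + T_activation` and
`J_arrival = J_activation + J_propagation`.  `T_propagation` is taken as
the mean arrival at the largest stimulation voltage (immediate activation
there), and `J_propagation` as the minimum arrival-time jitter over
voltages.  The default subtracts jitters on the standard-deviation scale;
a variance-scale alternative (`sqrt(J_arrival² − J_prop²)`), appropriate
for independent noise sources, sits behind `jitter_mode="variance"`.
The standard-deviation convention is the package default because it is
the conventional field summary for this decomposition; both are exposed.

Excitability regimes follow the printed definitions: sub-threshold (no
responses), intermediate (some), supra-threshold (100%); `v_thr` is the
lowest 100% voltage and voltages normalize as
`Vnorm = (V − V_inter) / (V_thr − V_inter)`.

Along a branch, axial distance is the arc length of the branch polyline
at each electrode's nearest-point projection (electrodes farther than one
pitch are excluded; distances are rebased to the first retained
electrode, the alignment site).  Velocity is the reciprocal slope of the
ordinary regression of mean arrival time on axial distance.  Arrival
times referenced to the alignment electrode cancel all shared per-trial
offsets; their variance grows linearly with axial distance under the
white-noise (Brownian) jitter model, so the through-origin regression of
per-electrode variance (unbiased, ddof = 1) on distance yields the jitter
rate as `sqrt(slope)` in µs at 1 mm.  A negative fitted slope reports
rate 0 with a warning.  The through-origin fit is unweighted by default;
the χ²-based variance-of-variance weights (2σ⁴/(n−1)) are a config
option.  High-frequency trains are analyzed per stimulation-pulse index
across episodes with the same two regressions.

## Synthetic recordings

The simulator generates what the analysis assumes, with full ground
truth:

* **Waveform** — negative-first biphasic shape (one sine period under a
  Hann window), 2 ms default, zero-mean, negative peak at one third of
  the period; amplitudes are expressed in σ_noise multiples and inserted
  at continuous (sub-sample) arrival times.
* **Geometry** — electrodes on a 17.8 µm-pitch grid (or arbitrary
  positions); the arbor is a tree of polylines; an electrode within one
  pitch of a branch records the nearest path point's waveform scaled by
  its per-electrode amplitude (no volume-conductor physics — amplitudes
  are prescribed, not modeled).  Off-path electrodes carry noise only.
* **Amplitudes** — axonal electrodes uniform in 3–10 σ by default; the
  AIS-adjacent electrode at 10× the median axonal amplitude.
* **Arrival times** — `t₀ + d/v + ε(d)` with `ε` a Brownian process in
  axial distance: independent Gaussian increments of variance
  `rate²·Δd`, shared by electrodes at the same path position and carried
  across branch points.  `rate` (µs at 1 mm) defaults to 100.  Each
  increment is lower-truncated just below the segment's propagation time
  so that ground-truth arrivals are strictly increasing along every
  branch (no overtaking).  At the electrode spacings and rates used here
  the truncation probability is ≤ a few percent per segment on a dense
  grid and ~10⁻⁶ on the sparse kinetics line, so the process is Brownian
  to within the quoted recovery tolerances; configurations with very
  dense sampling and extreme rates would bias the variance low.
* **Stimulation** — response probability 0 below `v_inter` (30 mV),
  1 at/above `v_thr` (60 mV), rising linearly from 0.25 in between.
  Activation latency and jitter decay exponentially in `Vnorm`:
  `172.6·exp(−Vnorm/0.715)` µs and `51.6·exp(−Vnorm)` µs, anchored so the
  latency drops ~130 µs across the intermediate regime (a further ~40 µs
  by `Vnorm = 3`) and the jitter ~12 µs between `Vnorm` 1 and 2.  The
  exponential form is this package's choice; only the anchor drops and
  monotonicity are constrained by the phenomenology.
* **Trains** — 100 episodes × 100 pulses at 100 Hz, no failures;
  per-pulse velocity interpolates 0.71/0.65/0.62/0.57 m/s at pulses
  1/25/50/100 and the jitter rate 111/115/121/124 µs/mm.  The implied
  velocity decrease is 19.7%; the 60 s inter-episode gaps are not
  rendered.
* **Noise** — zero-mean Gaussian, optionally spatially correlated as an
  AR(1) process across the channel index (neighbor correlation exactly
  `c`).  One master seed; per-trial streams are keyed by trial (or
  episode and pulse), so any subset of trials reproduces bit-for-bit.

What the simulator does **not** emulate: stimulation artifacts, drift
and non-stationary noise, multi-neuron background activity and spike
overlap, electrode-interface variability, conduction failures, 8-bit
quantization.  Passing tests therefore demonstrate correctness of the
algorithms under the stated statistical model, not performance on real
recordings with those additional nuisances.

## Benchmark protocols and problem sizes

* **Mixed-trial detection** — branched arbor on an 8×16 grid, 40 training
  trials, noise statistics from a separate 20 000-sample inactive-state
  recording, then 40 fresh AP trials + 20 noise trials (2:1) scored per
  electrode group at the analytic threshold with a 1 ms matching
  tolerance; TP% over spike trials, FP% over all detections, pooled over
  groups, medians over 20 seeded replicates for group sizes 3 and 6.
* **Kinetics recovery** — straight 1.5 mm axon over 15 line electrodes
  (8 σ axonal amplitude, 80 σ at the proximal alignment electrode),
  100 trials at 0.71 m/s and 100 µs/mm.  Estimator-level recovery uses
  the simulator's arrival tables; the full detection pipeline is run in
  `axontrack benchmark`.  Detection-derived arrival times carry a
  per-electrode systematic offset of roughly ±20 µs stemming from noise
  in the 40-trial average template (the timing reference inherits the
  template's peak-position error); this leaves the jitter regressions
  essentially untouched but adds ~1% scatter to pipeline-level velocity
  estimates.

These sizes keep the full test suite under a few minutes on one CPU
while leaving every statistical criterion comfortably powered.

## Known limitations

* Whitening assumes stationary Gaussian noise; gross artifacts must be
  excluded via the spike-free mask.
* Events are single-neuron: overlapping spikes from other units are out
  of scope (no subtraction or multi-unit resolution).
* The std-scale jitter subtraction can report small negative activation
  jitters under sampling noise; the variance-scale mode clips at 0.
* `assemble_footprint` aligns configurations at integer samples only.
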