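"""End-to-end evaluation protocols on seeded synthetic recordings.

``mixed_trial_evaluation`` reproduces the standard detection benchmark:
per electrode group, a whitened matched filter is built from 40 training
trials and scored on a fresh mix of 40 AP trials and 20 noise trials (2:1)
with the analytic threshold; true positives are detections matched to
ground truth within 1 ms, false positives are unmatched detections as a
percentage of all detections.  ``kinetics_recovery`` runs the detection
pipeline on a straight-axon preparation and recovers conduction velocity
and the propagation-jitter rate from the detected arrival times.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import kinetics, matched_filter as mf
from .footprint import Footprint, detect_ais_spikes, spike_triggered_average
from .presets import detection_preset, kinetics_preset
from .synthetic import TRIAL_T0_S, TRIAL_WINDOW_S, _spawn, simulate_propagation_trials, synth_noise
from .recording import Recording

logger = logging.getLogger(__name__)


def _noise_model(arbor, array, sigma_uv, seed, n_samples=20_000, max_lag=mf.DEFAULT_MAX_LAG):
    """Noise statistics from a separate inactive-state recording."""
    rng = np.random.default_rng(_spawn(seed, (9, 0)))
    traces = synth_noise(array.n_electrodes, n_samples, sigma_uv, rng=rng)
    rec = Recording(traces=traces, fs=20_000.0, positions=array.positions)
    return mf.estimate_noise(rec, max_lag=max_lag)


def _training_footprint(arbor, array, sigma_uv, seed, n_train=40):
    """Footprint from spike-triggered averaging of the training trials,
    triggered by simple 5-sigma thresholding at the AIS electrode."""
    rec, gt = simulate_propagation_trials(arbor, array, n_train, sigma_uv, _spawn(seed, (10,)))
    ais_electrode = int(np.argmax(arbor.amplitude_profile))
    triggers = detect_ais_spikes(rec, ais_electrode, sigma_uv)
    templates = spike_triggered_average(rec, triggers)
    fp = Footprint.from_templates(templates)
    return fp, len(triggers)


def detect_on_recording(
    recording: Recording,
    gfilter: mf.GroupFilter,
    prior_ratio: float = 1.0,
    refine: bool = True,
    window_s: float = TRIAL_WINDOW_S,
) -> pd.DataFrame:
    """Convolve, threshold, refine: detection events for one group."""
    out = mf.convolve_and_sum(recording, gfilter)
    thr = mf.optimal_threshold(gfilter, prior_ratio=prior_ratio)
    events = mf.detect_events(out, thr, recording.fs)
    if refine:
        events = [mf.refine_time(out, ev, recording.fs) for ev in events]
    table = mf.events_to_table(events, window_s=window_s)
    table["time_s"] += gfilter.time_correction_s
    return table


def mixed_trial_evaluation(
    seed: int | np.random.SeedSequence = 0,
    ks=(1, 3, 6),
    n_train: int = 40,
    n_spike: int = 40,
    n_noise: int = 20,
    sigma_uv: float = 1.0,
    tolerance_s: float = 0.001,
    whitening: str = "full",
) -> dict[int, mf.DetectionMetrics]:
    """One seed of the 40:20 mixed-trial detection benchmark.

    Returns pooled metrics (across all electrode groups) for each group
    size in ``ks``.  The simulation, noise model and footprint are shared
    across group sizes so that the comparison isolates the group size.
    """
    arbor, array = detection_preset(_spawn(seed, (11,)))
    noise = _noise_model(arbor, array, sigma_uv, seed)
    footprint, n_triggers = _training_footprint(arbor, array, sigma_uv, seed, n_train)
    if n_triggers < n_train:
        logger.warning("training produced %d/%d triggers", n_triggers, n_train)

    flags = [True] * n_spike + [False] * n_noise
    eval_rec, gt = simulate_propagation_trials(
        arbor, array, n_spike + n_noise, sigma_uv, _spawn(seed, (12,)), spike_present=flags
    )

    results: dict[int, mf.DetectionMetrics] = {}
    for k in ks:
        groups = mf.group_electrodes(footprint, array, k, noise_sigma=noise.sigma)
        matched = spikes = dets = noise_trials = 0
        for gi, group in enumerate(groups):
            tpl = mf.extract_group_template(footprint, group, noise_sigma=noise.sigma)
            gfilter = mf.build_matched_filter(tpl, noise, mode=whitening)
            events = detect_on_recording(eval_rec, gfilter, refine=False)
            truth = gt[gt["electrode"] == group[0]]
            m = mf.evaluate_detection(events, truth, tolerance_s)
            matched += m.n_matched
            spikes += m.n_spike_trials
            dets += m.n_detections
            noise_trials += m.n_noise_trials
        tp = 100.0 * matched / spikes if spikes else 0.0
        fp = 100.0 * (dets - matched) / dets if dets else 0.0
        results[k] = mf.DetectionMetrics(
            tp_percent=tp,
            fn_percent=100.0 - tp,
            fp_percent=fp,
            n_spike_trials=spikes,
            n_noise_trials=noise_trials,
            n_detections=dets,
            n_matched=matched,
        )
    return results


def detection_benchmark(
    seed: int = 0,
    n_seeds: int = 20,
    ks=(1, 3, 6),
    **kwargs,
) -> pd.DataFrame:
    """Repeat the mixed-trial evaluation over ``n_seeds`` seeded
    replicates; one row per (replicate, group size)."""
    rows = []
    for rep in range(n_seeds):
        res = mixed_trial_evaluation(_spawn(seed, (20, rep)), ks=ks, **kwargs)
        for k, m in res.items():
            rows.append(
                {
                    "replicate": rep,
                    "k": k,
                    "tp_percent": m.tp_percent,
                    "fp_percent": m.fp_percent,
                    "fn_percent": m.fn_percent,
                    "n_detections": m.n_detections,
                    "n_spike_trials": m.n_spike_trials,
                }
            )
    return pd.DataFrame(rows)


def arrival_table(
    recording: Recording,
    footprint: Footprint,
    noise: mf.NoiseModel,
    electrodes,
    window_s: float = TRIAL_WINDOW_S,
    whitening: str = "full",
) -> pd.DataFrame:
    """Per-trial, per-electrode arrival times from single-electrode
    matched filters (at most one event per trial and electrode: the
    largest-score detection in each window)."""
    tables = []
    for e in electrodes:
        tpl = mf.extract_group_template(footprint, (e,), noise_sigma=noise.sigma)
        gfilter = mf.build_matched_filter(tpl, noise, mode=whitening)
        tab = detect_on_recording(recording, gfilter, window_s=window_s)
        tab = tab.sort_values("score").drop_duplicates("trial", keep="last")
        tab["electrode"] = e
        tables.append(tab[["trial", "electrode", "time_s", "score"]])
    return pd.concat(tables, ignore_index=True)


def kinetics_recovery(
    seed: int | np.random.SeedSequence = 0,
    n_trials: int = 100,
    n_train: int = 40,
    sigma_uv: float = 1.0,
) -> dict:
    """Velocity and jitter-rate recovery through the full pipeline.

    Simulates the straight-axon preparation (0.71 m/s, 100 us/mm), detects
    per-electrode arrival times with matched filters, references them to
    the proximal alignment electrode and runs the velocity and variance
    regressions.
    """
    arbor, array = kinetics_preset()
    noise = _noise_model(arbor, array, sigma_uv, seed)
    footprint, _ = _training_footprint(arbor, array, sigma_uv, seed, n_train)
    rec, gt = simulate_propagation_trials(arbor, array, n_trials, sigma_uv, _spawn(seed, (13,)))

    path = kinetics.axial_distance(
        arbor.branches[0].points, array.positions, max_offset_um=array.pitch
    )
    arrivals = arrival_table(rec, footprint, noise, path.electrodes)
    # subtract the within-window pulse offset so times are relative to the AP start
    aligned = kinetics.align_arrivals(arrivals, int(path.electrodes[0]))
    vfit = kinetics.velocity_fit(aligned, path)
    jfit = kinetics.jitter_fit(aligned, path)
    return {
        "velocity_m_per_s": vfit.velocity_m_per_s,
        "velocity_se_m_per_s": vfit.velocity_se_m_per_s,
        "jitter_rate_us_per_mm": jfit.jitter_rate_us_per_mm,
        "true_velocity_m_per_s": arbor.velocity_m_per_s,
        "true_jitter_rate_us_per_mm": arbor.jitter_rate_us_per_mm,
        "n_trials": int(aligned["trial"].nunique()),
        "n_electrodes": len(path.electrodes),
    }


def run_benchmark(seed: int = 0, n_seeds: int = 20) -> dict:
    """Full benchmark: mixed-trial detection medians plus kinetics
    recovery, as a JSON-ready dictionary."""
    det = detection_benchmark(seed, n_seeds=n_seeds)
    med = det.groupby("k")[["tp_percent", "fp_percent"]].median()
    kin = kinetics_recovery(_spawn(seed, (30,)))
    return {
        "tp_percent": float(med.loc[3, "tp_percent"]),
        "fp_percent": float(med.loc[3, "fp_percent"]),
        "velocity_mps": kin["velocity_m_per_s"],
        "jitter_rate_us_per_mm": kin["jitter_rate_us_per_mm"],
        "per_group_size": {
            int(k): {
                "tp_percent": float(med.loc[k, "tp_percent"]),
                "fp_percent": float(med.loc[k, "fp_percent"]),
            }
            for k in med.index
        },
        "n_seeds": n_seeds,
    }
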