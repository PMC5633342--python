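"""Excitability classification, latency/jitter decomposition, axial
distances, and the velocity / propagation-jitter regressions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from axontrack import kinetics
from axontrack.presets import kinetics_preset, stimulation_preset, train_preset
from axontrack.synthetic import (
    simulate_propagation_trials,
    simulate_stimulation_series,
    simulate_train,
    _spawn,
)


def unit_std_vector(n: int) -> np.ndarray:
    """Deterministic zero-mean vector with sample std (ddof=1) exactly 1."""
    v = np.arange(n, dtype=float)
    v -= v.mean()
    return v / v.std(ddof=1)


def arrivals_from_gt(gt: pd.DataFrame) -> pd.DataFrame:
    out = gt.rename(columns={"true_time_s": "time_s"})
    return out[[c for c in ("trial", "electrode", "time_s", "pulse_index", "voltage_mv")
                if c in out.columns]]


class TestClassifyRegimes:
    def test_printed_definition(self):
        prof = kinetics.classify_regimes(
            [10, 20, 30, 40, 50, 60], [0.0, 0.0, 0.4, 0.9, 1.0, 1.0]
        )
        assert prof.v_inter_mv == 30 and prof.v_thr_mv == 50
        regimes = prof.table.set_index("voltage_mv")["regime"]
        assert regimes.loc[20] == "sub"
        assert regimes.loc[40] == "intermediate"
        assert regimes.loc[50] == "supra"

    def test_degenerate_all_full(self):
        prof = kinetics.classify_regimes([10, 20, 30], [1.0, 1.0, 1.0])
        assert prof.v_inter_mv == prof.v_thr_mv == 10
        assert (prof.table["regime"] != "intermediate").all()

    def test_no_full_response_errors(self):
        with pytest.raises(ValueError, match="v_thr"):
            kinetics.classify_regimes([10, 20], [0.2, 0.8])

    def test_monte_carlo_threshold_recovery(self):
        """Over 100 seeded sweeps (60 trials/voltage), the recovered
        stimulation threshold lies within one 10 mV step of the model's
        v_thr in at least 95 of them."""
        stim, arbor, array = stimulation_preset()
        voltages = np.arange(10.0, 101.0, 10.0)
        hits = 0
        for seed in range(100):
            _, gt = simulate_stimulation_series(
                stim, arbor, array, voltages, 60, seed=seed, render=False
            )
            frac = gt.drop_duplicates("trial").groupby("voltage_mv")["spike_present"].mean()
            prof = kinetics.classify_regimes(frac.index.to_numpy(), frac.to_numpy())
            if abs(prof.v_thr_mv - stim.v_thr_mv) <= 10.0:
                hits += 1
        assert hits >= 95


class TestNormalizeVoltage:
    def test_fixed_points_and_scale(self):
        assert kinetics.normalize_voltage(50, 30, 50) == 1.0
        assert kinetics.normalize_voltage(30, 30, 50) == 0.0
        assert kinetics.normalize_voltage(90, 30, 50) == 3.0

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            kinetics.normalize_voltage(40, 50, 50)

    @given(
        st.floats(-300, 300),
        st.floats(-100, 100),
        st.floats(1, 200),
        st.floats(-50, 50),
    )
    def test_affine_invariance(self, v, v_inter, width, shift):
        """Shifting all voltages by a constant leaves Vnorm unchanged."""
        a = kinetics.normalize_voltage(v, v_inter, v_inter + width)
        b = kinetics.normalize_voltage(v + shift, v_inter + shift, v_inter + width + shift)
        assert a == pytest.approx(b, abs=1e-9)


class TestDecomposeLatencyJitter:
    def make_arrivals(self, stats_by_voltage):
        """stats_by_voltage: voltage -> (mean_us, std_us, n)."""
        rows = []
        for v, (mean_us, std_us, n) in stats_by_voltage.items():
            times = mean_us * 1e-6 + std_us * 1e-6 * unit_std_vector(n)
            for t in times:
                rows.append({"voltage_mv": v, "time_s": t})
        return pd.DataFrame(rows)

    def test_activation_latency_subtraction(self):
        """Mean arrival 1.63 ms at threshold vs 1.50 ms at the largest
        voltage gives a 130 us activation latency."""
        arr = self.make_arrivals({50: (1630.0, 10.0, 20), 90: (1500.0, 10.0, 20)})
        res = kinetics.decompose_latency_jitter(arr)
        per = res.per_voltage.set_index("voltage_mv")
        assert res.t_propagation_us == pytest.approx(1500.0)
        assert per.loc[50, "t_activation_us"] == pytest.approx(130.0)
        assert per.loc[90, "t_activation_us"] == pytest.approx(0.0, abs=1e-9)

    def test_jitter_subtraction_modes(self):
        arr = self.make_arrivals({40: (1700, 60.0, 30), 60: (1600, 55.0, 30),
                                  90: (1500, 50.0, 30)})
        res = kinetics.decompose_latency_jitter(arr)
        per = res.per_voltage.set_index("voltage_mv")
        assert res.j_propagation_us == pytest.approx(50.0)
        np.testing.assert_allclose(per["j_activation_us"], [10.0, 5.0, 0.0], atol=1e-9)
        res_var = kinetics.decompose_latency_jitter(arr, jitter_mode="variance")
        per_var = res_var.per_voltage.set_index("voltage_mv")
        np.testing.assert_allclose(
            per_var["j_activation_us"],
            [np.sqrt(60**2 - 50**2), np.sqrt(55**2 - 50**2), 0.0],
            atol=1e-9,
        )

    def test_requires_two_populated_voltages(self):
        arr = self.make_arrivals({50: (1600, 10.0, 20), 60: (1590, 10.0, 3)})
        with pytest.raises(ValueError, match="voltages"):
            kinetics.decompose_latency_jitter(arr)

    def test_simulated_latency_recovery_within_2se(self):
        """Activation latencies recovered from a simulated sweep agree
        with the model's latency curve within 2 standard errors at 60
        trials per voltage."""
        stim, arbor, array = stimulation_preset()
        voltages = np.array([40.0, 50.0, 60.0, 80.0, 120.0])
        _, gt = simulate_stimulation_series(stim, arbor, array, voltages, 60,
                                            seed=3, render=False)
        sub = gt[(gt.electrode == 0) & gt.spike_present.astype(bool)].copy()
        pulse_time = sub.trial * 0.01 + 0.003
        sub["time_s"] = sub.true_time_s - pulse_time
        res = kinetics.decompose_latency_jitter(sub[["voltage_mv", "time_s"]])
        per = res.per_voltage.set_index("voltage_mv")
        v_max = per.index.max()
        z_scores = []
        for v in voltages[:-1]:
            truth = stim.latency_us(v) - stim.latency_us(v_max)
            est = per.loc[v, "t_activation_us"]
            se = np.sqrt(
                per.loc[v, "j_arrival_us"] ** 2 / per.loc[v, "n"]
                + per.loc[v_max, "j_arrival_us"] ** 2 / per.loc[v_max, "n"]
            )
            z_scores.append((est - truth) / se)
        # joint criterion: each deviation is ~N(0,1), so the squared sum
        # follows chi-square with 4 dof (99th percentile 13.28)
        assert float(np.square(z_scores).sum()) < 13.28
        assert np.abs(z_scores).max() < 3.5


class TestAxialDistance:
    def test_straight_segment(self):
        path = kinetics.axial_distance(
            np.array([[0.0, 0.0], [1000.0, 0.0]]),
            np.array([[0.0, 0.0], [1000.0, 0.0]]),
        )
        np.testing.assert_allclose(path.distance_mm, [0.0, 1.0])

    def test_right_angle_arc_vs_chord(self):
        """A 500 + 500 um right-angle path has 1.0 mm axial distance but
        only ~0.707 mm Euclidean distance."""
        polyline = np.array([[0.0, 0.0], [500.0, 0.0], [500.0, 500.0]])
        positions = np.array([[0.0, 0.0], [500.0, 500.0]])
        path = kinetics.axial_distance(polyline, positions)
        np.testing.assert_allclose(path.distance_mm, [0.0, 1.0])
        chord = np.linalg.norm(positions[1] - positions[0]) * 1e-3
        assert chord == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_far_electrode_excluded(self):
        polyline = np.array([[0.0, 0.0], [1000.0, 0.0]])
        positions = np.array([[0.0, 0.0], [500.0, 200.0], [1000.0, 0.0]])
        path = kinetics.axial_distance(polyline, positions, max_offset_um=17.8)
        assert list(path.electrodes) == [0, 2]

    def test_matches_simulator_parameterization(self, straight_axon):
        from axontrack.synthetic import map_electrodes

        arbor, array = straight_axon
        emap = map_electrodes(arbor, array).set_index("electrode")
        path = kinetics.axial_distance(arbor.branches[0].points, array.positions,
                                       max_offset_um=array.pitch)
        for e, d in zip(path.electrodes, path.distance_mm):
            assert d == pytest.approx(emap.loc[e, "arc_mm"], abs=array.pitch * 1e-3)


class TestVelocityFit:
    def path3(self):
        return kinetics.BranchPath(electrodes=[0, 1, 2], distance_mm=[0.0, 0.5, 1.0])

    def arrivals(self, times_by_electrode, n=12):
        rows = []
        for e, t in times_by_electrode.items():
            for trial in range(n):
                rows.append({"trial": trial, "electrode": e, "time_s": t})
        return pd.DataFrame(rows)

    def test_exact_arithmetic(self):
        """1.4286 ms over 1 mm is 0.7 m/s."""
        arr = self.arrivals({0: 0.0, 1: 0.71430e-3, 2: 1.42857e-3})
        fit = kinetics.velocity_fit(arr, self.path3())
        assert fit.velocity_m_per_s == pytest.approx(0.7, rel=1e-3)

    def test_rejects_flat_times(self):
        arr = self.arrivals({0: 1e-3, 1: 1e-3, 2: 1e-3})
        with pytest.raises(ValueError, match="slope"):
            kinetics.velocity_fit(arr, self.path3())

    def test_simulator_recovery_within_2pct(self, straight_axon):
        """0.71 m/s recovered within 2% from 100 trials on 15 electrodes
        over 1.5 mm."""
        arbor, array = straight_axon
        _, gt = simulate_propagation_trials(arbor, array, 100, seed=_spawn(0, (13,)))
        path = kinetics.axial_distance(arbor.branches[0].points, array.positions,
                                       max_offset_um=array.pitch)
        aligned = kinetics.align_arrivals(arrivals_from_gt(gt), int(path.electrodes[0]))
        fit = kinetics.velocity_fit(aligned, path)
        assert fit.velocity_m_per_s == pytest.approx(0.71, rel=0.02)

    def test_permutation_invariant(self, straight_axon, rng):
        arbor, array = straight_axon
        _, gt = simulate_propagation_trials(arbor, array, 30, seed=1)
        path = kinetics.axial_distance(arbor.branches[0].points, array.positions,
                                       max_offset_um=array.pitch)
        arr = kinetics.align_arrivals(arrivals_from_gt(gt), int(path.electrodes[0]))
        ref_v = kinetics.velocity_fit(arr, path).velocity_m_per_s
        ref_j = kinetics.jitter_fit(arr, path).jitter_rate_us_per_mm
        shuffled = arr.sample(frac=1.0, random_state=rng.integers(1 << 31))
        assert kinetics.velocity_fit(shuffled, path).velocity_m_per_s == pytest.approx(ref_v)
        assert kinetics.jitter_fit(shuffled, path).jitter_rate_us_per_mm == pytest.approx(ref_j)


class TestJitterFit:
    def test_exact_through_origin(self):
        """Variances (0.01, 0.02, 0.03) ms^2 at (1, 2, 3) mm give a slope
        of 0.01 ms^2/mm, i.e. a jitter rate of exactly 100 us at 1 mm."""
        rows = []
        for e, (d, var_ms2) in enumerate(zip([1.0, 2.0, 3.0], [0.01, 0.02, 0.03])):
            std_s = np.sqrt(var_ms2) * 1e-3
            for i, z in enumerate(unit_std_vector(20)):
                rows.append({"trial": i, "electrode": e, "time_s": std_s * z})
        arr = pd.DataFrame(rows)
        path = kinetics.BranchPath(electrodes=[0, 1, 2], distance_mm=[1.0, 2.0, 3.0])
        fit = kinetics.jitter_fit(arr, path)
        assert fit.variance_slope_us2_per_mm == pytest.approx(1e4, rel=1e-9)
        assert fit.jitter_rate_us_per_mm == pytest.approx(100.0, rel=1e-9)

    def test_zero_jitter_limit(self, straight_axon):
        arbor, array = straight_axon
        arbor.jitter_rate_us_per_mm = 0.0
        _, gt = simulate_propagation_trials(arbor, array, 20, seed=0)
        path = kinetics.axial_distance(arbor.branches[0].points, array.positions,
                                       max_offset_um=array.pitch)
        aligned = kinetics.align_arrivals(arrivals_from_gt(gt), int(path.electrodes[0]))
        fit = kinetics.jitter_fit(aligned, path)
        assert fit.jitter_rate_us_per_mm == pytest.approx(0.0, abs=1e-6)

    def test_negative_slope_reports_zero(self):
        rows = []
        for e, d in enumerate([1.0, 2.0, 3.0]):
            std_s = 50e-6 * (3 - e)  # variance decreasing with distance
            for i, z in enumerate(unit_std_vector(15)):
                rows.append({"trial": i, "electrode": e, "time_s": std_s * z})
        path = kinetics.BranchPath(electrodes=[0, 1, 2], distance_mm=[1.0, 2.0, 3.0])
        fit = kinetics.jitter_fit(pd.DataFrame(rows), path)
        assert fit.jitter_rate_us_per_mm >= 0.0

    def test_recovery_within_15pct_over_seeds(self, straight_axon):
        """The 100 us/mm rate is recovered within 15% in at least 90% of
        50 seeded replicates (100 trials, 15 electrodes over 1.5 mm)."""
        arbor, array = straight_axon
        path = kinetics.axial_distance(arbor.branches[0].points, array.positions,
                                       max_offset_um=array.pitch)
        hits = 0
        for seed in range(50):
            _, gt = simulate_propagation_trials(arbor, array, 100, seed=seed)
            aligned = kinetics.align_arrivals(arrivals_from_gt(gt), int(path.electrodes[0]))
            fit = kinetics.jitter_fit(aligned, path)
            if abs(fit.jitter_rate_us_per_mm - 100.0) <= 15.0:
                hits += 1
        assert hits >= 45

    def test_alignment_cancels_common_offsets(self, straight_axon, rng):
        """Adding a common per-trial offset to all electrodes (activation
        jitter) changes neither the velocity nor the jitter fit, because
        arrivals are referenced to the alignment electrode."""
        arbor, array = straight_axon
        _, gt = simulate_propagation_trials(arbor, array, 50, seed=2)
        path = kinetics.axial_distance(arbor.branches[0].points, array.positions,
                                       max_offset_um=array.pitch)
        arr = arrivals_from_gt(gt)
        offsets = pd.Series(rng.normal(0, 200e-6, 50), index=range(50))
        shifted = arr.copy()
        shifted["time_s"] = shifted["time_s"] + shifted["trial"].map(offsets)
        align = int(path.electrodes[0])
        a0 = kinetics.align_arrivals(arr, align)
        a1 = kinetics.align_arrivals(shifted, align)
        assert kinetics.velocity_fit(a1, path).velocity_m_per_s == pytest.approx(
            kinetics.velocity_fit(a0, path).velocity_m_per_s)
        assert kinetics.jitter_fit(a1, path).jitter_rate_us_per_mm == pytest.approx(
            kinetics.jitter_fit(a0, path).jitter_rate_us_per_mm)


class TestTrainAnalysis:
    def test_constant_model_is_stationary(self):
        from axontrack.synthetic import TrainModel

        train = TrainModel(
            n_episodes=60,
            velocity_anchors=((1, 0.7), (100, 0.7)),
            jitter_anchors=((1, 100.0), (100, 100.0)),
        )
        _, arbor, array = train_preset()
        _, gt = simulate_train(train, arbor, array, seed=0,
                               pulse_subset=(1, 50, 100), render=False)
        path = kinetics.axial_distance(arbor.branches[0].points, array.positions,
                                       max_offset_um=array.pitch)
        res = kinetics.train_analysis(arrivals_from_gt(gt), path, (1, 50, 100))
        v = res.per_pulse["velocity_m_per_s"]
        assert (v.max() - v.min()) / v.mean() < 0.03

    def test_default_velocity_decrease_band(self):
        """The default anchors (0.71 -> 0.57 m/s) produce a ~19.7%
        velocity decrease between the 1st and 100th pulse."""
        train, arbor, array = train_preset()
        _, gt = simulate_train(train, arbor, array, seed=0, render=False,
                               pulse_subset=(1, 25, 50, 100))
        path = kinetics.axial_distance(arbor.branches[0].points, array.positions,
                                       max_offset_um=array.pitch)
        res = kinetics.train_analysis(arrivals_from_gt(gt), path)
        assert res.velocity_change_percent == pytest.approx(19.7, abs=2.0)
        v = res.per_pulse.set_index("pulse_index")["velocity_m_per_s"]
        assert (np.diff(v.loc[[1, 25, 50, 100]]) < 0).all()

    def test_jitter_increase_across_seeds(self):
        """The fitted jitter rate at pulse 100 exceeds pulse 1 in at
        least 90% of 50 seeded replicates (111 vs 124 us/mm truth)."""
        train, arbor, array = train_preset()
        path = kinetics.axial_distance(arbor.branches[0].points, array.positions,
                                       max_offset_um=array.pitch)
        wins = 0
        for seed in range(50):
            _, gt = simulate_train(train, arbor, array, seed=seed,
                                   pulse_subset=(1, 100), render=False)
            res = kinetics.train_analysis(arrivals_from_gt(gt), path, (1, 100))
            j = res.per_pulse.set_index("pulse_index")["jitter_rate_us_per_mm"]
            if j.loc[100] > j.loc[1]:
                wins += 1
        assert wins >= 45
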