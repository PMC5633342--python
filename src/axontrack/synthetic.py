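"""Seeded simulator for HD-MEA recordings of single-neuron axonal activity.

The generator produces multichannel recordings with full ground truth
(per-trial, per-electrode arrival times and spike labels) that match the
statistical structure the detection and kinetics modules assume:

* biphasic extracellular spikes propagating along a branching arbor at a
  constant conduction velocity (default 0.7 m/s);
* an axon-initial-segment (AIS) signal roughly 10x larger than the median
  axonal amplitude, with axonal amplitudes in the 1-20 sigma_noise range;
* arrival-time jitter accumulating as a white Gaussian process along the
  axial path, i.e. variance growing linearly with axial distance
  (``jitter_rate_us_per_mm`` is the standard deviation, in microseconds,
  accumulated after exactly 1 mm of path);
* voltage-dependent activation latency/jitter and probabilistic responses
  between the first effective voltage and the 100%-response threshold;
* activity-dependent conduction slowing and jitter growth over 100-pulse
  100 Hz stimulation trains.

All randomness is driven by a single master seed; per-trial streams are
derived deterministically with :class:`numpy.random.SeedSequence` so that
any subset of trials is reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .recording import DEFAULT_FS, Recording

logger = logging.getLogger(__name__)

DEFAULT_PITCH_UM = 17.8  # electrode center-to-center pitch
TRIAL_WINDOW_S = 0.010  # one trial = 10 ms of data on all electrodes
TRIAL_T0_S = 0.003  # trigger/stimulus position inside the trial window

_PEAK_PHASE = 1.0 / 3.0  # fraction of the waveform period at the negative peak
_PEAK_VALUE = 3.0 * np.sqrt(3.0) / 8.0  # |min| of sin(theta)*hann(theta)


# --------------------------------------------------------------------------
# electrode geometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ElectrodeArray:
    """Planar electrode layout.

    ``positions`` is an ``(n, 2)`` array of (x, y) coordinates in
    micrometers; ``pitch`` is the nominal center-to-center spacing used as
    the default pickup radius and path-assignment cutoff.
    """

    positions: np.ndarray
    pitch: float = DEFAULT_PITCH_UM

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array of coordinates")
        if self.pitch <= 0:
            raise ValueError(f"electrode pitch must be positive, got {self.pitch}")
        if len(np.unique(pos, axis=0)) != len(pos):
            raise ValueError("electrode positions must be unique")
        object.__setattr__(self, "positions", pos)

    @property
    def n_electrodes(self) -> int:
        return len(self.positions)


def build_array(n_rows: int, n_cols: int, pitch: float = DEFAULT_PITCH_UM) -> ElectrodeArray:
    """Regular rectangular grid with row-major electrode indexing.

    Electrode ``r * n_cols + c`` sits at ``(c * pitch, r * pitch)``.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if pitch <= 0:
        raise ValueError(f"electrode pitch must be positive, got {pitch}")
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    pos = np.column_stack([cols.ravel() * pitch, rows.ravel() * pitch])
    return ElectrodeArray(positions=pos, pitch=pitch)


def line_array(n_electrodes: int, spacing_um: float, pitch: float = DEFAULT_PITCH_UM) -> ElectrodeArray:
    """Electrodes placed on a straight line along x; convenient for
    kinetics benchmarks where the path geometry should be unambiguous."""
    x = np.arange(n_electrodes) * spacing_um
    return ElectrodeArray(positions=np.column_stack([x, np.zeros_like(x)]), pitch=pitch)


# --------------------------------------------------------------------------
# spike waveform
# --------------------------------------------------------------------------


def _biphasic_unit(u_s: np.ndarray, duration_s: float) -> np.ndarray:
    """Continuous negative-first biphasic spike with unit negative peak.

    The shape is one period of a sine under a Hann window; the negative
    peak sits at ``u = 0`` (one third of the period into the waveform) and
    the support is ``[-T/3, 2T/3]``.  The waveform integrates to zero.
    """
    t = np.asarray(u_s, dtype=float) + duration_s * _PEAK_PHASE
    theta = 2.0 * np.pi * t / duration_s
    val = -np.sin(theta) * 0.5 * (1.0 - np.cos(theta))
    inside = (t >= 0.0) & (t <= duration_s)
    return np.where(inside, val, 0.0) / _PEAK_VALUE


def synth_waveform(peak_amp: float, duration_ms: float = 2.0, fs: float = DEFAULT_FS) -> np.ndarray:
    """Sampled biphasic spike whose discrete negative peak equals ``-peak_amp``.

    ``peak_amp`` is expressed in whatever unit the caller works in
    (typically multiples of sigma_noise).  The waveform is zero-mean and
    strictly linear in ``peak_amp``.
    """
    if peak_amp <= 0:
        raise ValueError(f"peak amplitude must be positive, got {peak_amp}")
    if duration_ms > 10.0:
        raise ValueError("waveform duration must be <= 10 ms (one trial window)")
    n = int(round(duration_ms * 1e-3 * fs))
    t = np.arange(n) / fs
    shape = _biphasic_unit(t - duration_ms * 1e-3 * _PEAK_PHASE, duration_ms * 1e-3)
    shape = shape - shape.mean()  # exact zero mean (the shape is antisymmetric)
    return shape * (peak_amp / -shape.min())


# --------------------------------------------------------------------------
# noise
# --------------------------------------------------------------------------


def synth_noise(
    n_electrodes: int,
    n_samples: int,
    sigma: float = 1.0,
    spatial_corr: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Zero-mean Gaussian noise traces, optionally spatially correlated.

    With ``spatial_corr = c`` the correlation between channels ``i`` and
    ``j`` is ``c ** |i - j|`` (an AR(1) process across the channel index),
    so neighboring channels correlate at exactly ``c`` while each channel
    keeps standard deviation ``sigma``.
    """
    if sigma <= 0:
        raise ValueError(f"noise sigma must be positive, got {sigma}")
    if not (0.0 <= spatial_corr < 1.0):
        raise ValueError("spatial_corr must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_electrodes, n_samples))
    if spatial_corr > 0.0 and n_electrodes > 1:
        out = np.empty_like(white)
        out[0] = white[0]
        c = spatial_corr
        scale = np.sqrt(1.0 - c * c)
        for i in range(1, n_electrodes):
            out[i] = c * out[i - 1] + scale * white[i]
        white = out
    return white * sigma


# --------------------------------------------------------------------------
# arbor geometry
# --------------------------------------------------------------------------


@dataclass
class Branch:
    """One polyline of the axonal arbor, in micrometers.

    Root branches (``parent is None``) start at the AIS; a child branch
    must start on its parent's polyline.
    """

    points: np.ndarray
    parent: int | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise ValueError("branch polyline needs >= 2 (x, y) points")
        self.points = pts


def _polyline_arcs(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _project_point(points: np.ndarray, q: np.ndarray) -> tuple[float, float]:
    """Nearest point of a polyline to ``q``: returns (distance, arc length)."""
    arcs = _polyline_arcs(points)
    best = (np.inf, 0.0)
    for i in range(len(points) - 1):
        a, b = points[i], points[i + 1]
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0.0 else float(np.clip((q - a) @ ab / denom, 0.0, 1.0))
        proj = a + t * ab
        d = float(np.linalg.norm(q - proj))
        if d < best[0]:
            best = (d, float(arcs[i] + t * np.linalg.norm(ab)))
    return best


@dataclass
class ArborModel:
    """Geometry and physiology of a simulated axonal arbor.

    ``amplitude_profile`` holds the inserted negative-peak amplitude of the
    spike at each electrode, in multiples of sigma_noise; ``None`` means a
    default profile is drawn at simulation time (axonal amplitudes uniform
    in ``(3, 10)`` sigma, the AIS-adjacent electrode at 10x the median
    axonal amplitude).
    """

    ais_position: tuple[float, float]
    branches: list[Branch]
    velocity_m_per_s: float = 0.7
    jitter_rate_us_per_mm: float = 100.0
    amplitude_profile: np.ndarray | None = None

    _ATTACH_TOL_UM = 1.0

    def __post_init__(self) -> None:
        if self.velocity_m_per_s <= 0:
            raise ValueError("conduction velocity must be positive")
        if self.jitter_rate_us_per_mm < 0:
            raise ValueError("jitter rate must be non-negative")
        ais = np.asarray(self.ais_position, dtype=float)
        for i, br in enumerate(self.branches):
            if br.parent is None:
                if np.linalg.norm(br.points[0] - ais) > self._ATTACH_TOL_UM:
                    raise ValueError(f"root branch {i} does not start at the AIS")
            else:
                if not (0 <= br.parent < i):
                    raise ValueError(
                        f"branch {i} must attach to an earlier branch, got parent={br.parent}"
                    )
                d, _ = _project_point(self.branches[br.parent].points, br.points[0])
                if d > self._ATTACH_TOL_UM:
                    raise ValueError(f"branch {i} does not start on its parent polyline")

    def branch_base_arcs_mm(self) -> np.ndarray:
        """Axial distance (mm, from the AIS) of each branch's starting point."""
        base = np.zeros(len(self.branches))
        for i, br in enumerate(self.branches):
            if br.parent is not None:
                _, arc = _project_point(self.branches[br.parent].points, br.points[0])
                base[i] = base[br.parent] + arc * 1e-3
        return base


def map_electrodes(
    arbor: ArborModel,
    array: ElectrodeArray,
    pickup_radius_um: float | None = None,
) -> pd.DataFrame:
    """Assign electrodes to the arbor path.

    Each electrode within ``pickup_radius_um`` (default: one pitch) of a
    branch polyline records the waveform of the nearest path point; the
    returned table has columns ``electrode``, ``branch``, ``local_arc_mm``
    (arc length along that branch) and ``arc_mm`` (axial distance from the
    AIS), plus the perpendicular ``offset_um``.  Electrodes farther than
    the pickup radius carry noise only and are absent from the table.
    """
    radius = array.pitch if pickup_radius_um is None else pickup_radius_um
    base = arbor.branch_base_arcs_mm()
    rows = []
    for e, q in enumerate(array.positions):
        best = None
        for b, br in enumerate(arbor.branches):
            d, arc = _project_point(br.points, q)
            if d <= radius and (best is None or d < best[0]):
                best = (d, b, arc)
        if best is not None:
            d, b, arc = best
            rows.append((e, b, arc * 1e-3, base[b] + arc * 1e-3, d))
    return pd.DataFrame(rows, columns=["electrode", "branch", "local_arc_mm", "arc_mm", "offset_um"])


def default_amplitude_profile(
    arbor: ArborModel,
    array: ElectrodeArray,
    seed: int | np.random.SeedSequence = 0,
    amp_range: tuple[float, float] = (3.0, 10.0),
    ais_factor: float = 10.0,
    pickup_radius_um: float | None = None,
) -> np.ndarray:
    """Per-electrode peak amplitudes in sigma_noise multiples.

    Axonal electrodes draw uniformly from ``amp_range``; the electrode
    closest to the AIS is set to ``ais_factor`` times the median axonal
    amplitude, mirroring the ~10:1 AIS-to-axon amplitude ratio of
    extracellular footprints.
    """
    rng = np.random.default_rng(_spawn(seed, (2, 0)))
    emap = map_electrodes(arbor, array, pickup_radius_um)
    profile = np.zeros(array.n_electrodes)
    if emap.empty:
        raise ValueError("no electrode lies within pickup range of the arbor")
    idx = emap["electrode"].to_numpy()
    profile[idx] = rng.uniform(*amp_range, size=len(idx))
    ais = np.asarray(arbor.ais_position, dtype=float)
    d_ais = np.linalg.norm(array.positions[idx] - ais, axis=1)
    ais_electrode = int(idx[np.argmin(d_ais)])
    axonal = profile[idx[idx != ais_electrode]]
    median = float(np.median(axonal)) if len(axonal) else profile[ais_electrode]
    profile[ais_electrode] = ais_factor * median
    return profile


# --------------------------------------------------------------------------
# stimulation / train models
# --------------------------------------------------------------------------


@dataclass
class StimulationModel:
    """Voltage-dependent excitability of extracellular AIS stimulation.

    The neuron never fires below ``v_inter_mv``, always fires at or above
    ``v_thr_mv``, and fires with probability rising linearly from
    ``p_inter`` in between.  Activation latency and activation jitter both
    decay exponentially with the normalized voltage
    ``(V - v_inter) / (v_thr - v_inter)``; the default constants place a
    ~130 us latency drop across the intermediate regime (a further ~40 us
    by three normalized-voltage units) and a ~12 us jitter drop between
    one and two normalized-voltage units.
    """

    v_inter_mv: float = 30.0
    v_thr_mv: float = 60.0
    p_inter: float = 0.25
    latency_scale_us: float = 172.6
    latency_tau: float = 0.7146
    jitter_scale_us: float = 51.6
    jitter_tau: float = 1.0
    latency_curve: Callable[[float], float] | None = None
    jitter_curve: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if not self.v_inter_mv < self.v_thr_mv:
            raise ValueError("v_inter must be strictly below v_thr")
        if not (0.0 < self.p_inter < 1.0):
            raise ValueError("p_inter must lie strictly in (0, 1)")

    def _vnorm(self, voltage_mv: float) -> float:
        return (voltage_mv - self.v_inter_mv) / (self.v_thr_mv - self.v_inter_mv)

    def response_prob(self, voltage_mv: float) -> float:
        """Probability that one pulse elicits a spike.  Voltages outside
        the modeled range extrapolate to 0 below and 1 above."""
        if voltage_mv < self.v_inter_mv:
            return 0.0
        if voltage_mv >= self.v_thr_mv:
            return 1.0
        return self.p_inter + (1.0 - self.p_inter) * self._vnorm(voltage_mv)

    def latency_us(self, voltage_mv: float) -> float:
        if self.latency_curve is not None:
            return float(self.latency_curve(voltage_mv))
        v = max(self._vnorm(voltage_mv), 0.0)
        return self.latency_scale_us * np.exp(-v / self.latency_tau)

    def jitter_us(self, voltage_mv: float) -> float:
        if self.jitter_curve is not None:
            return float(self.jitter_curve(voltage_mv))
        v = max(self._vnorm(voltage_mv), 0.0)
        return self.jitter_scale_us * np.exp(-v / self.jitter_tau)


@dataclass
class TrainModel:
    """High-frequency stimulation protocol with activity-dependent slowing.

    Defaults follow the standard protocol of 100 episodes of 100 pulses at
    100 Hz, with per-pulse conduction velocity interpolated linearly
    through 0.71 / 0.65 / 0.62 / 0.57 m/s at pulses 1 / 25 / 50 / 100 and
    the propagation-jitter rate through 111 / 115 / 121 / 124 us per mm.
    Every pulse elicits a spike (threshold stimulation without failures).
    """

    n_episodes: int = 100
    n_pulses: int = 100
    rate_hz: float = 100.0
    velocity_anchors: tuple[tuple[int, float], ...] = (
        (1, 0.71),
        (25, 0.65),
        (50, 0.62),
        (100, 0.57),
    )
    jitter_anchors: tuple[tuple[int, float], ...] = (
        (1, 111.0),
        (25, 115.0),
        (50, 121.0),
        (100, 124.0),
    )
    activation_latency_us: float = 200.0
    activation_jitter_us: float = 20.0

    def __post_init__(self) -> None:
        v = self.velocity_by_pulse()
        j = self.jitter_by_pulse()
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("velocity_by_pulse must be non-increasing")
        if np.any(np.diff(j) < -1e-12):
            raise ValueError("jitter_by_pulse must be non-decreasing")

    def _interp(self, anchors: tuple[tuple[int, float], ...]) -> np.ndarray:
        k = np.array([a[0] for a in anchors], dtype=float)
        v = np.array([a[1] for a in anchors], dtype=float)
        return np.interp(np.arange(1, self.n_pulses + 1), k, v)

    def velocity_by_pulse(self) -> np.ndarray:
        """Conduction velocity (m/s) for pulses 1..n_pulses."""
        return self._interp(self.velocity_anchors)

    def jitter_by_pulse(self) -> np.ndarray:
        """Propagation-jitter rate (us at 1 mm) for pulses 1..n_pulses."""
        return self._interp(self.jitter_anchors)


# --------------------------------------------------------------------------
# jitter process along the path
# --------------------------------------------------------------------------


class _JitterTree:
    """Brownian arrival-time noise sampled at the electrode path positions.

    The accumulated noise is a white Gaussian process in axial distance:
    independent increments with variance ``rate**2 * delta_d``.  Increments
    are lower-truncated at (just under) the negative of the propagation
    time of the segment so that ground-truth arrival times are strictly
    increasing along every branch path ("no overtaking"); at the electrode
    spacings and jitter rates used here the truncation probability is
    negligible and the process is Brownian to numerical accuracy.
    """

    def __init__(self, arbor: ArborModel, emap: pd.DataFrame):
        self.arbor = arbor
        base = arbor.branch_base_arcs_mm()
        arcs: dict[int, set[float]] = {b: set() for b in range(len(arbor.branches))}
        for _, row in emap.iterrows():
            arcs[int(row["branch"])].add(float(row["local_arc_mm"]))
        attach: dict[int, float] = {}
        for i, br in enumerate(arbor.branches):
            if br.parent is not None:
                _, arc = _project_point(arbor.branches[br.parent].points, br.points[0])
                attach[i] = arc * 1e-3
                arcs[br.parent].add(arc * 1e-3)
            else:
                arcs.setdefault(i, set()).add(0.0)
                attach[i] = 0.0
        # per-branch sorted node arcs; flat node index for lookup
        self.branch_arcs = {b: np.array(sorted(a)) for b, a in arcs.items()}
        self.node_index: dict[tuple[int, float], int] = {}
        n = 0
        for b in range(len(arbor.branches)):
            for a in self.branch_arcs[b]:
                self.node_index[(b, float(a))] = n
                n += 1
        self.n_nodes = n
        self.attach = attach
        # electrode -> node index
        self.electrode_node = {
            int(r["electrode"]): self.node_index[(int(r["branch"]), float(r["local_arc_mm"]))]
            for _, r in emap.iterrows()
        }

    def sample_us(self, rng: np.random.Generator, rate_us_per_mm: float,
                  velocity_m_per_s: float) -> np.ndarray:
        """One trial's noise value (us) at every path node."""
        values = np.zeros(self.n_nodes)
        if rate_us_per_mm == 0.0:
            return values
        for b in range(len(self.arbor.branches)):
            arcs = self.branch_arcs[b]
            parent = self.arbor.branches[b].parent
            if parent is None:
                prev_val, prev_arc = 0.0, 0.0
            else:
                prev_arc = self.attach[b]
                prev_val = values[self.node_index[(parent, float(prev_arc))]]
                prev_arc = 0.0  # child arcs are local; attachment is local arc 0
            for a in arcs:
                delta = float(a) - prev_arc
                if delta <= 0.0:
                    inc = 0.0
                else:
                    scale = rate_us_per_mm * np.sqrt(delta)
                    # propagation time of the segment, in us
                    lower = -0.999 * delta / velocity_m_per_s * 1e3
                    inc = rng.normal(0.0, scale)
                    for _ in range(100):
                        if inc > lower:
                            break
                        inc = rng.normal(0.0, scale)
                    else:  # pragma: no cover - pathological configurations
                        inc = lower * 0.5
                prev_val = prev_val + inc
                prev_arc = float(a)
                values[self.node_index[(b, float(a))]] = prev_val
        return values


def _spawn(seed: int | np.random.SeedSequence, key: tuple[int, ...]) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        entropy = seed.entropy
        base_key = tuple(seed.spawn_key)
    else:
        entropy = int(seed)
        base_key = ()
    return np.random.SeedSequence(entropy=entropy, spawn_key=base_key + key)


def _insert_spike(
    row: np.ndarray,
    fs: float,
    arrival_s: float,
    amp: float,
    duration_s: float,
) -> None:
    """Add one continuous-time biphasic spike (negative peak at
    ``arrival_s``) to a single-electrode trace, in place."""
    t_lo = arrival_s - duration_s * _PEAK_PHASE
    n0 = max(int(np.ceil(t_lo * fs)), 0)
    n1 = min(int(np.floor((t_lo + duration_s) * fs)), len(row) - 1)
    if n1 < n0:
        return
    u = np.arange(n0, n1 + 1) / fs - arrival_s
    row[n0 : n1 + 1] += amp * _biphasic_unit(u, duration_s)


_GT_COLUMNS = ["trial", "electrode", "true_time_s", "spike_present", "pulse_index", "voltage_mv"]


def _resolve_profile(arbor, array, seed, pickup_radius_um):
    if arbor.amplitude_profile is not None:
        profile = np.asarray(arbor.amplitude_profile, dtype=float)
        if len(profile) != array.n_electrodes:
            raise ValueError("amplitude_profile length must match the electrode count")
        return profile
    return default_amplitude_profile(arbor, array, seed, pickup_radius_um=pickup_radius_um)


# --------------------------------------------------------------------------
# simulators
# --------------------------------------------------------------------------


def simulate_propagation_trials(
    arbor: ArborModel,
    array: ElectrodeArray,
    n_trials: int,
    sigma_uv: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    *,
    fs: float = DEFAULT_FS,
    window_s: float = TRIAL_WINDOW_S,
    t0_s: float = TRIAL_T0_S,
    waveform_ms: float = 2.0,
    pickup_radius_um: float | None = None,
    spatial_corr: float = 0.0,
    spike_present: Sequence[bool] | None = None,
    dtype=np.float32,
) -> tuple[Recording, pd.DataFrame]:
    """Simulate spontaneous single-AP trials propagating along the arbor.

    Each trial is a 10 ms window; in spike trials the AP leaves the AIS at
    ``t0_s`` into the window and arrives at axial distance ``d`` (mm) at
    ``t0 + d / velocity + eps(d)`` with ``eps`` the accumulated Brownian
    jitter.  Noise trials carry noise only.  Returns the recording and a
    ground-truth table (one row per trial and path electrode).
    """
    emap = map_electrodes(arbor, array, pickup_radius_um)
    if emap.empty:
        raise ValueError("no electrode lies within pickup range of the arbor")
    profile = _resolve_profile(arbor, array, seed, pickup_radius_um)
    tree = _JitterTree(arbor, emap)
    if spike_present is None:
        spike_present = [True] * n_trials
    if len(spike_present) != n_trials:
        raise ValueError("spike_present must have one flag per trial")

    w = int(round(window_s * fs))
    traces = np.zeros((array.n_electrodes, n_trials * w))
    electrodes = emap["electrode"].to_numpy(dtype=int)
    arcs = emap["arc_mm"].to_numpy()
    rows = []
    for trial in range(n_trials):
        rng = np.random.default_rng(_spawn(seed, (0, trial)))
        noise_rng = np.random.default_rng(_spawn(seed, (1, trial)))
        sl = slice(trial * w, (trial + 1) * w)
        traces[:, sl] = synth_noise(
            array.n_electrodes, w, sigma_uv, spatial_corr, rng=noise_rng
        )
        if spike_present[trial]:
            eps = tree.sample_us(rng, arbor.jitter_rate_us_per_mm, arbor.velocity_m_per_s)
            t_start = trial * window_s + t0_s
            for e, arc in zip(electrodes, arcs):
                arrival = t_start + arc / arbor.velocity_m_per_s * 1e-3 + eps[tree.electrode_node[e]] * 1e-6
                _insert_spike(traces[e], fs, arrival, profile[e] * sigma_uv, waveform_ms * 1e-3)
                rows.append((trial, e, arrival, True, np.nan, np.nan))
        else:
            for e in electrodes:
                rows.append((trial, e, np.nan, False, np.nan, np.nan))

    rec = Recording(
        traces=traces.astype(dtype),
        fs=fs,
        positions=array.positions,
        metadata={"generator": "axontrack.synthetic.propagation", "sigma_uv": sigma_uv,
                  "window_s": window_s, "t0_s": t0_s},
    )
    return rec, pd.DataFrame(rows, columns=_GT_COLUMNS)


def simulate_stimulation_series(
    stim: StimulationModel,
    arbor: ArborModel,
    array: ElectrodeArray,
    voltages_mv: Sequence[float],
    n_trials_per_voltage: int,
    seed: int | np.random.SeedSequence = 0,
    sigma_uv: float = 1.0,
    *,
    fs: float = DEFAULT_FS,
    window_s: float = TRIAL_WINDOW_S,
    t0_s: float = TRIAL_T0_S,
    waveform_ms: float = 2.0,
    pickup_radius_um: float | None = None,
    render: bool = True,
    dtype=np.float32,
) -> tuple[Recording | None, pd.DataFrame]:
    """Simulate a randomized voltage sweep of AIS stimulation.

    Each pulse elicits a spike with probability ``stim.response_prob(V)``;
    elicited spikes leave the AIS after the voltage-dependent activation
    latency plus Gaussian activation jitter and then propagate as in
    :func:`simulate_propagation_trials`.  Trials of different voltages are
    interleaved in random order.  With ``render=False`` only the
    ground-truth table is produced (no traces), which keeps large
    Monte-Carlo sweeps cheap.
    """
    if n_trials_per_voltage < 1:
        raise ValueError("need at least one trial per voltage")
    emap = map_electrodes(arbor, array, pickup_radius_um)
    if emap.empty:
        raise ValueError("no electrode lies within pickup range of the arbor")
    profile = _resolve_profile(arbor, array, seed, pickup_radius_um)
    tree = _JitterTree(arbor, emap)

    order_rng = np.random.default_rng(_spawn(seed, (3, 0)))
    voltage_per_trial = np.repeat(np.asarray(voltages_mv, dtype=float), n_trials_per_voltage)
    order_rng.shuffle(voltage_per_trial)
    n_trials = len(voltage_per_trial)

    w = int(round(window_s * fs))
    traces = np.zeros((array.n_electrodes, n_trials * w)) if render else None
    electrodes = emap["electrode"].to_numpy(dtype=int)
    arcs = emap["arc_mm"].to_numpy()
    rows, stim_rows = [], []
    for trial, voltage in enumerate(voltage_per_trial):
        rng = np.random.default_rng(_spawn(seed, (0, trial)))
        pulse_time = trial * window_s + t0_s
        stim_rows.append((trial, pulse_time, voltage, np.nan, np.nan))
        if render:
            noise_rng = np.random.default_rng(_spawn(seed, (1, trial)))
            sl = slice(trial * w, (trial + 1) * w)
            traces[:, sl] = synth_noise(array.n_electrodes, w, sigma_uv, rng=noise_rng)
        fired = rng.random() < stim.response_prob(voltage)
        if fired:
            latency_us = stim.latency_us(voltage) + rng.normal(0.0, stim.jitter_us(voltage))
            eps = tree.sample_us(rng, arbor.jitter_rate_us_per_mm, arbor.velocity_m_per_s)
            t_start = pulse_time + latency_us * 1e-6
            for e, arc in zip(electrodes, arcs):
                arrival = t_start + arc / arbor.velocity_m_per_s * 1e-3 + eps[tree.electrode_node[e]] * 1e-6
                if render:
                    _insert_spike(traces[e], fs, arrival, profile[e] * sigma_uv, waveform_ms * 1e-3)
                rows.append((trial, e, arrival, True, np.nan, voltage))
        else:
            for e in electrodes:
                rows.append((trial, e, np.nan, False, np.nan, voltage))

    gt = pd.DataFrame(rows, columns=_GT_COLUMNS)
    stim_table = pd.DataFrame(stim_rows, columns=["trial", "time_s", "voltage_mv", "episode", "pulse_index"])
    if not render:
        return None, gt
    rec = Recording(
        traces=traces.astype(dtype),
        fs=fs,
        positions=array.positions,
        stim=stim_table,
        metadata={"generator": "axontrack.synthetic.stimulation", "sigma_uv": sigma_uv,
                  "window_s": window_s, "t0_s": t0_s},
    )
    return rec, gt


def simulate_train(
    train: TrainModel,
    arbor: ArborModel,
    array: ElectrodeArray,
    sigma_uv: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    *,
    fs: float = DEFAULT_FS,
    t0_s: float = TRIAL_T0_S,
    waveform_ms: float = 2.0,
    pickup_radius_um: float | None = None,
    pulse_subset: Sequence[int] | None = None,
    render: bool = True,
    dtype=np.float32,
) -> tuple[Recording | None, pd.DataFrame]:
    """Simulate high-frequency stimulation trains.

    Pulse ``k`` (1-based) of every episode conducts at
    ``train.velocity_by_pulse()[k-1]`` with jitter rate
    ``train.jitter_by_pulse()[k-1]``; every pulse elicits a spike.  The
    inter-pulse interval ``1/rate`` must fit the 10 ms trial window, and
    the 60 s gaps between episodes are not rendered.  ``pulse_subset``
    restricts generation to the given 1-based pulse indices (the per-pulse
    random streams are keyed by episode and pulse, so a subset reproduces
    exactly the corresponding trials of the full protocol).
    """
    window_s = 1.0 / train.rate_hz
    if window_s < waveform_ms * 1e-3 + t0_s:
        raise ValueError("stimulation rate too high for the trial window")
    emap = map_electrodes(arbor, array, pickup_radius_um)
    if emap.empty:
        raise ValueError("no electrode lies within pickup range of the arbor")
    profile = _resolve_profile(arbor, array, seed, pickup_radius_um)
    tree = _JitterTree(arbor, emap)
    v_by_pulse = train.velocity_by_pulse()
    j_by_pulse = train.jitter_by_pulse()

    pulses = list(range(1, train.n_pulses + 1)) if pulse_subset is None else sorted(pulse_subset)
    if any(k < 1 or k > train.n_pulses for k in pulses):
        raise ValueError("pulse_subset indices must lie in [1, n_pulses]")
    w = int(round(window_s * fs))
    n_windows = train.n_episodes * len(pulses)
    traces = np.zeros((array.n_electrodes, n_windows * w)) if render else None
    electrodes = emap["electrode"].to_numpy(dtype=int)
    arcs = emap["arc_mm"].to_numpy()
    rows, stim_rows = [], []
    window = 0
    for episode in range(train.n_episodes):
        for k in pulses:
            rng = np.random.default_rng(_spawn(seed, (0, episode, k)))
            pulse_time = window * window_s + t0_s
            trial = episode * train.n_pulses + (k - 1)
            stim_rows.append((trial, pulse_time, np.nan, episode, k))
            if render:
                noise_rng = np.random.default_rng(_spawn(seed, (1, episode, k)))
                sl = slice(window * w, (window + 1) * w)
                traces[:, sl] = synth_noise(array.n_electrodes, w, sigma_uv, rng=noise_rng)
            velocity = v_by_pulse[k - 1]
            latency_us = train.activation_latency_us + rng.normal(0.0, train.activation_jitter_us)
            eps = tree.sample_us(rng, j_by_pulse[k - 1], velocity)
            t_start = pulse_time + latency_us * 1e-6
            for e, arc in zip(electrodes, arcs):
                arrival = t_start + arc / velocity * 1e-3 + eps[tree.electrode_node[e]] * 1e-6
                if render:
                    _insert_spike(traces[e], fs, arrival, profile[e] * sigma_uv, waveform_ms * 1e-3)
                rows.append((trial, e, arrival, True, k, np.nan))
            window += 1

    gt = pd.DataFrame(rows, columns=_GT_COLUMNS)
    gt["episode"] = gt["trial"] // train.n_pulses
    stim_table = pd.DataFrame(stim_rows, columns=["trial", "time_s", "voltage_mv", "episode", "pulse_index"])
    if not render:
        return None, gt
    rec = Recording(
        traces=traces.astype(dtype),
        fs=fs,
        positions=array.positions,
        stim=stim_table,
        metadata={"generator": "axontrack.synthetic.train", "sigma_uv": sigma_uv,
                  "window_s": window_s, "t0_s": t0_s},
    )
    return rec, gt
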