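"""Arrival-time statistics: excitability, activation latency/jitter,
conduction velocity, and propagation-jitter accumulation.

All operations consume tidy arrival tables (one row per trial and
electrode, times in seconds).  The central decompositions are

    T_arrival = T_propagation + T_activation
    J_arrival = J_activation + J_propagation

where the propagation time is estimated as the mean arrival at the largest
stimulation voltage (immediate activation at strong supra-threshold
pulses), and the propagation jitter as the lowest arrival-time jitter over
voltages.  Along an axonal branch, arrival-time variance referenced to a
proximal alignment electrode grows linearly with axial distance; the
through-origin regression slope yields the propagation-jitter rate (its
square root, in microseconds at 1 mm) and the ordinary regression of mean
arrival time on axial distance yields the conduction velocity (reciprocal
slope).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import DEFAULT_PITCH_UM, _polyline_arcs, _project_point

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# excitability
# --------------------------------------------------------------------------


@dataclass
class ExcitabilityProfile:
    """Response fractions per stimulation voltage with regime labels.

    ``v_inter`` is the lowest voltage that elicited at least one response,
    ``v_thr`` the lowest voltage with a 100% response rate (the
    stimulation threshold).  Regimes: sub-threshold below ``v_inter``,
    intermediate in ``[v_inter, v_thr)``, supra-threshold at and above
    ``v_thr``.
    """

    table: pd.DataFrame  # voltage_mv, response_fraction, regime
    v_inter_mv: float
    v_thr_mv: float
    monotone: bool


def classify_regimes(voltages_mv, response_fraction) -> ExcitabilityProfile:
    """Assign excitability regimes from per-voltage response fractions.

    Requires at least one voltage with a 100% response (otherwise the
    stimulation threshold is undefined and an error names it).  Non-
    monotone response fractions are retained but flagged.
    """
    v = np.asarray(voltages_mv, dtype=float)
    f = np.asarray(response_fraction, dtype=float)
    if v.shape != f.shape or v.ndim != 1:
        raise ValueError("voltages and response fractions must be 1-D and aligned")
    order = np.argsort(v)
    v, f = v[order], f[order]
    if np.any((f < 0) | (f > 1)):
        raise ValueError("response fractions must lie in [0, 1]")
    full = v[f >= 1.0]
    if len(full) == 0:
        raise ValueError(
            "no stimulation voltage elicited a response in 100% of trials; "
            "the stimulation threshold v_thr is undefined"
        )
    responding = v[f > 0.0]
    v_thr = float(full[0])
    v_inter = float(responding[0])
    regime = np.where(v < v_inter, "sub", np.where(v < v_thr, "intermediate", "supra"))
    monotone = bool(np.all(np.diff(f) >= 0))
    if not monotone:
        logger.warning("classify_regimes: response fractions are not monotone in voltage")
    table = pd.DataFrame({"voltage_mv": v, "response_fraction": f, "regime": regime})
    return ExcitabilityProfile(table=table, v_inter_mv=v_inter, v_thr_mv=v_thr, monotone=monotone)


def normalize_voltage(voltage_mv, v_inter_mv: float, v_thr_mv: float):
    """``(V - V_inter) / (V_thr - V_inter)``: 0 at the onset of the
    intermediate regime, 1 at the stimulation threshold; supra-threshold
    voltages may exceed 1."""
    if v_thr_mv <= v_inter_mv:
        raise ValueError("voltage normalization undefined: v_thr must exceed v_inter")
    return (np.asarray(voltage_mv, dtype=float) - v_inter_mv) / (v_thr_mv - v_inter_mv)


# --------------------------------------------------------------------------
# activation latency / jitter decomposition
# --------------------------------------------------------------------------


@dataclass
class DecompositionResult:
    """Per-voltage activation latency and jitter.

    ``per_voltage`` has columns ``voltage_mv``, ``n``, ``t_arrival_us``
    (mean arrival), ``t_activation_us``, ``j_arrival_us`` and
    ``j_activation_us``.  ``t_propagation_us`` is the mean arrival at the
    largest voltage (immediate activation assumed there) and
    ``j_propagation_us`` the minimum arrival jitter over voltages.
    """

    per_voltage: pd.DataFrame
    t_propagation_us: float
    j_propagation_us: float
    jitter_mode: str


def decompose_latency_jitter(
    arrivals: pd.DataFrame,
    jitter_mode: str = "std",
    min_trials: int = 10,
) -> DecompositionResult:
    """Split arrival times into activation and propagation components.

    ``arrivals`` needs columns ``voltage_mv`` and ``time_s`` (arrival
    relative to the stimulation pulse, at one recording electrode).
    ``jitter_mode='std'`` subtracts jitters on the standard-deviation
    scale (``J_activation = J_arrival - J_propagation``);
    ``'variance'`` subtracts on the variance scale
    (``sqrt(J_arrival**2 - J_propagation**2)``), appropriate when the two
    sources are independent.  Voltages with fewer than 2 trials are
    excluded; at least two voltages with ``min_trials`` trials each are
    required.
    """
    if jitter_mode not in ("std", "variance"):
        raise ValueError(f"unknown jitter_mode {jitter_mode!r}")
    df = arrivals.dropna(subset=["time_s"])
    g = df.groupby("voltage_mv")["time_s"]
    n = g.size()
    small = n[n < 2]
    if len(small):
        logger.info("decompose_latency_jitter: excluding voltages with <2 trials: %s",
                    small.index.tolist())
    keep = n[n >= 2].index
    if (n >= min_trials).sum() < 2:
        raise ValueError(
            f"need >= 2 voltages with >= {min_trials} trials each for the decomposition"
        )
    mean_us = g.mean().loc[keep] * 1e6
    std_us = g.std(ddof=1).loc[keep] * 1e6
    v_max = keep.max()
    t_prop = float(mean_us.loc[v_max])  # immediate activation at the largest voltage
    j_prop = float(std_us.min())
    if jitter_mode == "std":
        j_act = std_us - j_prop
    else:
        j_act = np.sqrt(np.maximum(std_us**2 - j_prop**2, 0.0))
    per_voltage = pd.DataFrame(
        {
            "voltage_mv": keep.to_numpy(),
            "n": n.loc[keep].to_numpy(),
            "t_arrival_us": mean_us.to_numpy(),
            "t_activation_us": (mean_us - t_prop).to_numpy(),
            "j_arrival_us": std_us.to_numpy(),
            "j_activation_us": np.asarray(j_act),
        }
    ).reset_index(drop=True)
    return DecompositionResult(
        per_voltage=per_voltage,
        t_propagation_us=t_prop,
        j_propagation_us=j_prop,
        jitter_mode=jitter_mode,
    )


# --------------------------------------------------------------------------
# branch paths
# --------------------------------------------------------------------------


@dataclass
class BranchPath:
    """Ordered electrodes along one axonal branch with cumulative axial
    distance (arc length along the branch polyline, in mm)."""

    electrodes: np.ndarray
    distance_mm: np.ndarray

    def __post_init__(self) -> None:
        self.electrodes = np.asarray(self.electrodes, dtype=int)
        self.distance_mm = np.asarray(self.distance_mm, dtype=float)
        if len(self.electrodes) != len(self.distance_mm):
            raise ValueError("electrodes and distances must align")
        if np.any(np.diff(self.distance_mm) <= 0):
            raise ValueError("axial distances must be strictly increasing along the path")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"electrode": self.electrodes, "distance_mm": self.distance_mm})


def axial_distance(
    polyline_um: np.ndarray,
    positions_um: np.ndarray,
    electrodes=None,
    max_offset_um: float = DEFAULT_PITCH_UM,
    rebase: bool = True,
) -> BranchPath:
    """Axial (along-the-branch) distance of electrodes projected onto a
    branch polyline.

    Each electrode is assigned the cumulative arc length at its nearest
    point on the polyline; electrodes farther than ``max_offset_um`` from
    the path are excluded with a log message.  With ``rebase=True``
    (default) distances are measured from the first retained electrode,
    the convention used when that electrode serves as the alignment site.
    """
    polyline = np.asarray(polyline_um, dtype=float)
    if len(polyline) < 2:
        raise ValueError("branch polyline needs at least 2 points")
    positions = np.asarray(positions_um, dtype=float)
    if electrodes is None:
        electrodes = np.arange(len(positions))
    electrodes = np.asarray(electrodes, dtype=int)
    kept, arcs, excluded = [], [], []
    for e, q in zip(electrodes, positions):
        d, arc = _project_point(polyline, q)
        if d > max_offset_um:
            excluded.append(int(e))
        else:
            kept.append(int(e))
            arcs.append(arc * 1e-3)
    if excluded:
        logger.info("axial_distance: excluded electrode(s) %s farther than %.1f um "
                    "from the path", excluded, max_offset_um)
    if not kept:
        raise ValueError("no electrode lies within reach of the branch polyline")
    order = np.argsort(arcs)
    kept = np.asarray(kept)[order]
    arcs = np.asarray(arcs)[order]
    if rebase:
        arcs = arcs - arcs[0]
    return BranchPath(electrodes=kept, distance_mm=arcs)


# --------------------------------------------------------------------------
# velocity and jitter regressions
# --------------------------------------------------------------------------


@dataclass
class PropagationFit:
    """Propagation statistics along one branch path.

    Velocity comes from the ordinary regression of mean arrival time on
    axial distance (``velocity = 1 / slope``); the jitter rate from the
    origin-forced regression of arrival-time variance on axial distance
    (``jitter_rate = sqrt(slope)``, in microseconds at 1 mm).  Fields not
    produced by a given fit are ``None``.
    """

    velocity_m_per_s: float | None = None
    velocity_se_m_per_s: float | None = None
    jitter_rate_us_per_mm: float | None = None
    variance_slope_us2_per_mm: float | None = None
    n_points: int = 0


def align_arrivals(arrivals: pd.DataFrame, alignment_electrode: int) -> pd.DataFrame:
    """Reference arrival times to the alignment electrode, per trial.

    Subtracting the alignment electrode's arrival cancels every per-trial
    offset shared across electrodes (activation latency and jitter, and
    the propagation jitter accumulated up to the alignment site).  Trials
    in which the alignment electrode has no arrival are dropped.
    """
    ref = (
        arrivals[arrivals["electrode"] == alignment_electrode]
        .dropna(subset=["time_s"])
        .set_index("trial")["time_s"]
    )
    out = arrivals[arrivals["trial"].isin(ref.index)].copy()
    out["time_s"] = out["time_s"] - out["trial"].map(ref)
    return out


def _per_electrode_stats(arrivals: pd.DataFrame, path: BranchPath) -> pd.DataFrame:
    df = arrivals.dropna(subset=["time_s"])
    df = df[df["electrode"].isin(path.electrodes)]
    g = df.groupby("electrode")["time_s"]
    stats_df = pd.DataFrame({"n": g.size(), "mean_s": g.mean(), "var_s2": g.var(ddof=1)})
    dist = pd.Series(path.distance_mm, index=path.electrodes, name="distance_mm")
    return stats_df.join(dist, how="inner")


def velocity_fit(arrivals: pd.DataFrame, path: BranchPath, min_trials: int = 2) -> PropagationFit:
    """Conduction velocity from mean arrival time versus axial distance.

    Ordinary least squares; the velocity is the reciprocal slope with its
    standard error propagated from the slope standard error.  A
    non-positive slope signals a mis-ordered path and raises.
    """
    st = _per_electrode_stats(arrivals, path)
    st = st[st["n"] >= min_trials]
    if len(st) < 3:
        raise ValueError("velocity_fit needs >= 3 electrodes on the path")
    res = stats.linregress(st["distance_mm"], st["mean_s"])
    if res.slope <= 0:
        raise ValueError(
            f"non-positive arrival-time slope ({res.slope:.3g} s/mm): "
            "arrival order contradicts the path direction"
        )
    velocity = 1e-3 / res.slope  # s/mm -> m/s
    return PropagationFit(
        velocity_m_per_s=float(velocity),
        velocity_se_m_per_s=float(1e-3 * res.stderr / res.slope**2),
        n_points=len(st),
    )


def jitter_fit(arrivals: pd.DataFrame, path: BranchPath, min_trials: int = 10) -> PropagationFit:
    """Propagation-jitter rate from the origin-forced variance regression.

    Arrival times must be referenced to the alignment electrode (see
    :func:`align_arrivals`), whose variance is 0 by construction; the
    regression of per-electrode arrival-time variance on axial distance is
    forced through the origin and the square root of its slope is the
    jitter accumulated per unit length (us at 1 mm).  A negative fitted
    slope is reported as rate 0 with a warning.
    """
    st = _per_electrode_stats(arrivals, path)
    st = st[st["n"] >= 2]
    low = st[st["n"] < min_trials]
    if len(low):
        logger.warning("jitter_fit: %d electrode(s) have fewer than %d trials",
                       len(low), min_trials)
    if len(st) < 3:
        raise ValueError("jitter_fit needs >= 3 electrodes on the path")
    d = st["distance_mm"].to_numpy()
    v_us2 = st["var_s2"].to_numpy() * 1e12
    nz = d > 0
    slope = float(d[nz] @ v_us2[nz] / (d[nz] @ d[nz]))
    if slope < 0:
        logger.warning("jitter_fit: negative variance slope (%.3g us^2/mm); rate set to 0", slope)
        rate = 0.0
        slope = float(slope)
    else:
        rate = float(np.sqrt(slope))
    return PropagationFit(
        jitter_rate_us_per_mm=rate,
        variance_slope_us2_per_mm=slope,
        n_points=int(nz.sum()),
    )


# --------------------------------------------------------------------------
# high-frequency trains
# --------------------------------------------------------------------------


@dataclass
class TrainAnalysis:
    """Per-pulse-index propagation statistics across stimulation episodes."""

    per_pulse: pd.DataFrame
    velocity_change_percent: float
    jitter_change_percent: float


def train_analysis(
    arrivals: pd.DataFrame,
    path: BranchPath,
    pulse_indices=(1, 25, 50, 100),
    alignment_electrode: int | None = None,
) -> TrainAnalysis:
    """Velocity and jitter fits per stimulation-pulse index.

    ``arrivals`` needs columns ``trial``, ``electrode``, ``time_s`` and
    ``pulse_index``; trials of each requested pulse index are pooled
    across episodes.  Times are referenced to the alignment electrode
    (default: the first electrode of the path).  The summary reports the
    percentage velocity decrease and jitter-rate increase between the
    first and last requested index.
    """
    if alignment_electrode is None:
        alignment_electrode = int(path.electrodes[0])
    rows = []
    for k in pulse_indices:
        sub = arrivals[arrivals["pulse_index"] == k]
        if sub.empty:
            logger.warning("train_analysis: no trials for pulse index %d; skipped", k)
            continue
        aligned = align_arrivals(sub, alignment_electrode)
        vfit = velocity_fit(aligned, path)
        jfit = jitter_fit(aligned, path)
        rows.append(
            {
                "pulse_index": k,
                "n_trials": aligned["trial"].nunique(),
                "velocity_m_per_s": vfit.velocity_m_per_s,
                "velocity_se_m_per_s": vfit.velocity_se_m_per_s,
                "jitter_rate_us_per_mm": jfit.jitter_rate_us_per_mm,
                "variance_slope_us2_per_mm": jfit.variance_slope_us2_per_mm,
            }
        )
    if len(rows) < 1:
        raise ValueError("train_analysis found no usable pulse index")
    per_pulse = pd.DataFrame(rows)
    v0, v1 = per_pulse["velocity_m_per_s"].iloc[[0, -1]]
    j0, j1 = per_pulse["jitter_rate_us_per_mm"].iloc[[0, -1]]
    dv = 100.0 * (v0 - v1) / v0
    dj = 100.0 * (j1 - j0) / j0 if j0 > 0 else float("nan")
    return TrainAnalysis(per_pulse=per_pulse, velocity_change_percent=float(dv),
                         jitter_change_percent=float(dj))
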