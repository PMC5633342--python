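"""Spike-triggered-average electrical footprints.

The footprint (or "electrical image") of a neuron is the array-wide map of
its average extracellular AP waveform: one template per electrode, obtained
by averaging trials triggered on the large AIS signal.  The AIS is located
as the electrode with the largest (negative-phase) template amplitude, and
the amplitude-versus-distance profile summarizes how the extracellular
signal falls off across the arbor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import Recording
from .synthetic import ElectrodeArray

logger = logging.getLogger(__name__)

DEFAULT_STA_WINDOW_S = 0.010
DEFAULT_STA_PRE_S = 0.003  # 3 ms pre-trigger, 7 ms post: axonal arrivals trail the AIS
DEFAULT_TRIGGER_DEAD_TIME_S = 0.002


@dataclass
class Template:
    """Per-electrode average AP waveform.

    ``t0_offset_s`` is the time of the first waveform sample relative to
    the trigger (negative for pre-trigger context).  Peak amplitude is
    defined on the negative phase only, since extracellular somatic and
    axonal spikes in this preparation are negative-dominant.
    """

    waveform: np.ndarray
    fs: float
    n_trials: int
    t0_offset_s: float = -DEFAULT_STA_PRE_S

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.n_trials < 1:
            raise ValueError("a template requires at least one trial")

    @property
    def peak_index(self) -> int:
        return int(np.argmin(self.waveform))

    @property
    def peak_amplitude(self) -> float:
        """|negative peak| in microvolts (0 for non-negative waveforms)."""
        return float(max(0.0, -self.waveform.min()))

    @property
    def peak_latency_s(self) -> float:
        """Time of the negative peak relative to the trigger."""
        return self.peak_index / self.fs + self.t0_offset_s


@dataclass
class Footprint:
    """Electrode -> template map with the located AIS electrode."""

    templates: dict[int, Template]
    ais_electrode: int | None = None

    @classmethod
    def from_templates(cls, templates: dict[int, Template]) -> "Footprint":
        fp = cls(templates=dict(templates))
        fp.ais_electrode = locate_ais(fp)
        return fp

    def __len__(self) -> int:
        return len(self.templates)


def detect_ais_spikes(
    recording: Recording,
    electrode: int,
    noise_sigma: float,
    *,
    threshold_sigmas: float = 5.0,
    dead_time_s: float = DEFAULT_TRIGGER_DEAD_TIME_S,
    align: str = "peak",
    peak_search_s: float = 0.0005,
) -> np.ndarray:
    """Detect large AIS spikes by simple negative-threshold crossing.

    The threshold is ``-threshold_sigmas * noise_sigma`` (default 5 sigma,
    adequate only for the large AIS signal).  With ``align='peak'`` each
    trigger is placed on the negative peak within ``peak_search_s`` after
    the crossing, which reduces alignment jitter relative to the crossing
    time itself (``align='crossing'``).  Triggers closer than
    ``dead_time_s`` are deduplicated (first one kept).  Returns trigger
    times in seconds, sorted ascending; an empty result is valid.
    """
    if noise_sigma <= 0:
        raise ValueError("noise_sigma must be positive")
    if align not in ("peak", "crossing"):
        raise ValueError(f"unknown alignment mode {align!r}")
    x = np.asarray(recording.traces[electrode], dtype=float)
    below = x < -threshold_sigmas * noise_sigma
    crossings = np.flatnonzero(below & ~np.concatenate([[False], below[:-1]]))
    if len(crossings) == 0:
        return np.array([])
    if align == "peak":
        span = max(int(round(peak_search_s * recording.fs)), 1)
        idx = np.array([c + int(np.argmin(x[c : c + span])) for c in crossings])
    else:
        idx = crossings
    dead = dead_time_s * recording.fs
    kept = [idx[0]]
    for i in idx[1:]:
        if i - kept[-1] >= dead:
            kept.append(i)
    return np.asarray(kept) / recording.fs


def spike_triggered_average(
    recording: Recording,
    trigger_times: np.ndarray,
    window_s: float = DEFAULT_STA_WINDOW_S,
    pre_s: float = DEFAULT_STA_PRE_S,
) -> dict[int, Template]:
    """Average trigger-aligned trials on every electrode.

    Each trigger contributes the window ``[t - pre_s, t - pre_s + window_s)``;
    triggers whose window falls outside the recording are dropped with a
    logged count.  Raises if no usable trigger remains.
    """
    trigger_times = np.sort(np.asarray(trigger_times, dtype=float))
    if len(trigger_times) == 0:
        raise ValueError("spike-triggered averaging requires at least one trigger")
    w = int(round(window_s * recording.fs))
    starts = np.round((trigger_times - pre_s) * recording.fs).astype(int)
    ok = (starts >= 0) & (starts + w <= recording.n_samples)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("spike_triggered_average: dropped %d trigger(s) at recording edges", dropped)
    starts = starts[ok]
    if len(starts) == 0:
        raise ValueError("no trigger window fits inside the recording")
    idx = starts[:, None] + np.arange(w)[None, :]
    stack = recording.traces[:, idx]  # (electrodes, trials, window)
    mean = stack.mean(axis=1, dtype=float)
    return {
        e: Template(waveform=mean[e], fs=recording.fs, n_trials=len(starts), t0_offset_s=-pre_s)
        for e in range(recording.n_electrodes)
    }


def _shift_waveform(w: np.ndarray, shift: int) -> np.ndarray:
    """Integer-sample shift with zero fill (positive shifts delay)."""
    out = np.zeros_like(w)
    if shift >= 0:
        out[shift:] = w[: len(w) - shift] if shift < len(w) else 0.0
    else:
        out[:shift] = w[-shift:]
    return out


def assemble_footprint(config_templates: list[dict[int, Template]]) -> Footprint:
    """Merge templates from several electrode configurations.

    All configurations must share at least one electrode; the largest-
    amplitude shared electrode serves as the alignment reference, and each
    configuration is shifted (integer samples) so that the reference
    electrode's peak latency matches the first configuration.  Electrodes
    appearing in several configurations are averaged weighted by the
    number of trials behind each template.
    """
    if not config_templates:
        raise ValueError("assemble_footprint requires at least one configuration")
    if len(config_templates) == 1:
        return Footprint.from_templates(config_templates[0])
    common = set(config_templates[0])
    for cfg in config_templates[1:]:
        common &= set(cfg)
    if not common:
        raise ValueError("configurations share no common (AIS) electrode")
    ref = max(common, key=lambda e: config_templates[0][e].peak_amplitude)
    fs = config_templates[0][ref].fs
    ref_latency = config_templates[0][ref].peak_latency_s

    sums: dict[int, np.ndarray] = {}
    weights: dict[int, int] = {}
    t0 = config_templates[0][ref].t0_offset_s
    for cfg in config_templates:
        shift = int(round((ref_latency - cfg[ref].peak_latency_s) * fs))
        for e, tpl in cfg.items():
            w = _shift_waveform(tpl.waveform, shift)
            if e in sums:
                sums[e] = sums[e] + w * tpl.n_trials
                weights[e] += tpl.n_trials
            else:
                sums[e] = w * tpl.n_trials
                weights[e] = tpl.n_trials
    merged = {
        e: Template(waveform=sums[e] / weights[e], fs=fs, n_trials=weights[e], t0_offset_s=t0)
        for e in sums
    }
    return Footprint.from_templates(merged)


def locate_ais(footprint: Footprint | dict[int, Template]) -> int:
    """Electrode with the maximal negative-peak amplitude.

    Ties are broken by the earliest peak latency, then the lowest
    electrode id; the result is invariant to electrode ordering.
    """
    templates = footprint.templates if isinstance(footprint, Footprint) else footprint
    if not templates:
        raise ValueError("footprint is empty")
    return min(
        templates,
        key=lambda e: (-templates[e].peak_amplitude, templates[e].peak_latency_s, e),
    )


def amplitude_vs_distance(footprint: Footprint, array: ElectrodeArray) -> pd.DataFrame:
    """Peak amplitude versus Euclidean distance from the AIS electrode."""
    ais = footprint.ais_electrode
    if ais is None:
        ais = locate_ais(footprint)
    ais_pos = array.positions[ais]
    rows = [
        (
            e,
            float(np.linalg.norm(array.positions[e] - ais_pos)),
            footprint.templates[e].peak_amplitude,
        )
        for e in sorted(footprint.templates)
    ]
    return pd.DataFrame(rows, columns=["electrode", "distance_um", "peak_amplitude_uv"])
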