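"""Multi-electrode matched-filter detection of single axonal APs.

A matched filter for a known transient in Gaussian noise is the noise-
whitened, time-reversed template: with the stacked spatio-temporal template
``s`` (group electrodes x filter length) and noise covariance ``C``, the
filter coefficients solve ``C w = s``.  The filter output on a recording is
the per-electrode correlation with ``w`` summed across the electrode group;
on a perfectly aligned template it peaks at ``s' C^-1 s`` (the
``expected_peak``), and on pure noise it is zero-mean Gaussian with the
same variance, so the likelihood-ratio detection threshold between two
equal-variance Gaussians is analytic:

    threshold = expected_peak / 2 + (variance / expected_peak) * ln(prior_ratio)

which reduces to the midpoint ``expected_peak / 2`` at equal priors.  The
peak of the filter output is a robust estimate of the AP's temporal
position; sub-sample timing is recovered by windowed-sinc interpolation of
the output around the peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .footprint import Footprint, Template
from .recording import Recording
from .synthetic import ElectrodeArray

logger = logging.getLogger(__name__)

DEFAULT_MAX_LAG = 60  # samples (3 ms at 20 kHz), the maximal filter length
DEFAULT_RIDGE = 1e-3
DEFAULT_DEAD_TIME_S = 0.001
DEFAULT_UPSAMPLE = 10


class NoiseEstimationError(ValueError):
    """Raised when spike-free data are insufficient or degenerate."""


class SingularCovarianceError(np.linalg.LinAlgError):
    """Raised when the regularized noise covariance cannot be solved."""


# --------------------------------------------------------------------------
# noise statistics
# --------------------------------------------------------------------------


@dataclass
class NoiseModel:
    """Per-electrode noise sigma and spatio-temporal covariance.

    Cross-covariance functions ``c_ij(h) = E[x_i(t) x_j(t+h)]`` are
    computed lazily (and cached) from the stored spike-free samples, for
    lags up to ``max_lag``; the block covariance over a group of
    electrodes and a filter length is assembled on demand.
    """

    sigma: np.ndarray
    n_samples_used: int
    max_lag: int = DEFAULT_MAX_LAG
    _samples: np.ndarray | None = None  # (C, N) spike-free, mean-subtracted
    _xcov: dict = field(default_factory=dict)  # (i, j) -> lags -max..max

    @classmethod
    def white(cls, sigma, n_electrodes: int, max_lag: int = DEFAULT_MAX_LAG) -> "NoiseModel":
        """Analytic white-noise model (independent channels); handy as the
        un-whitened reference filter and in closed-form tests."""
        sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (n_electrodes,)).copy()
        return cls(sigma=sigma, n_samples_used=0, max_lag=max_lag, _samples=None)

    def cross_covariance(self, i: int, j: int) -> np.ndarray:
        """``c_ij(h)`` for ``h = -max_lag .. max_lag``."""
        key = (i, j)
        if key in self._xcov:
            return self._xcov[key]
        if (j, i) in self._xcov:
            out = self._xcov[(j, i)][::-1].copy()
        elif self._samples is None:
            out = np.zeros(2 * self.max_lag + 1)
            if i == j:
                out[self.max_lag] = self.sigma[i] ** 2
        else:
            xi, xj = self._samples[i], self._samples[j]
            n = len(xi)
            full = signal.correlate(xj, xi, mode="full", method="fft")
            mid = n - 1
            out = full[mid - self.max_lag : mid + self.max_lag + 1] / n
        self._xcov[key] = out
        return out

    def cov_block(
        self,
        electrodes,
        length: int,
        mode: str = "full",
        ridge: float = DEFAULT_RIDGE,
    ) -> np.ndarray:
        """Spatio-temporal covariance over ``(electrode, lag)`` pairs.

        ``mode='full'`` uses lags up to ``length - 1``; ``mode='spatial'``
        keeps only the lag-0 (spatial) covariance, a cheaper whitening.
        The result is symmetrized and diagonally loaded with
        ``ridge * sigma_i**2`` for positive definiteness.
        """
        if length - 1 > self.max_lag:
            raise ValueError(
                f"filter length {length} exceeds the estimated lag range ({self.max_lag + 1})"
            )
        electrodes = list(electrodes)
        k = len(electrodes)
        lag = np.subtract.outer(np.arange(length), np.arange(length))  # tau' - tau... see below
        C = np.zeros((k * length, k * length))
        for a, ea in enumerate(electrodes):
            for b, eb in enumerate(electrodes):
                c_ab = self.cross_covariance(ea, eb)
                if mode == "spatial":
                    block = np.eye(length) * c_ab[self.max_lag]
                elif mode == "full":
                    # entry (tau, upsilon) = c_ab(upsilon - tau)
                    block = c_ab[self.max_lag - lag]
                else:
                    raise ValueError(f"unknown whitening mode {mode!r}")
                C[a * length : (a + 1) * length, b * length : (b + 1) * length] = block
        C = 0.5 * (C + C.T)
        load = np.repeat(np.asarray(self.sigma)[electrodes] ** 2, length) * ridge
        C[np.diag_indices_from(C)] += load
        return C


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    m = np.asarray(mask, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], m.view(np.int8), [0]])))
    return list(zip(edges[::2], edges[1::2]))


def estimate_noise(
    recording: Recording,
    spike_free_mask: np.ndarray | None = None,
    max_lag: int = DEFAULT_MAX_LAG,
) -> NoiseModel:
    """Estimate noise statistics from spike-free periods of a recording.

    ``spike_free_mask`` flags the samples to use (default: all).  Requires
    at least ``10 * max_lag`` masked-in samples; covariances are computed
    over contiguous masked runs (runs shorter than the lag range are
    ignored for the lagged statistics).
    """
    if spike_free_mask is None:
        samples = np.asarray(recording.traces, dtype=float)
    else:
        spike_free_mask = np.asarray(spike_free_mask, dtype=bool)
        if spike_free_mask.shape != (recording.n_samples,):
            raise ValueError("spike_free_mask must have one flag per sample")
        runs = [r for r in _mask_runs(spike_free_mask) if r[1] - r[0] > max_lag]
        if not runs:
            raise NoiseEstimationError("no spike-free run longer than the lag range")
        samples = np.concatenate(
            [recording.traces[:, a:b] for a, b in runs], axis=1
        ).astype(float)
        # NB: concatenating runs introduces a handful of spurious cross-run
        # lag products; with runs >> max_lag the bias is negligible.
    n = samples.shape[1]
    if n < 10 * max_lag:
        raise NoiseEstimationError(
            f"insufficient spike-free data: {n} samples, need >= {10 * max_lag}"
        )
    samples = samples - samples.mean(axis=1, keepdims=True)
    sigma = samples.std(axis=1)
    if np.any(sigma == 0.0):
        dead = np.flatnonzero(sigma == 0.0)
        raise NoiseEstimationError(f"zero noise variance on electrode(s) {dead.tolist()}")
    return NoiseModel(sigma=sigma, n_samples_used=n, max_lag=max_lag, _samples=samples)


def spike_free_mask(
    recording: Recording,
    noise_sigma: np.ndarray | float,
    threshold_sigmas: float = 4.5,
    pad_s: float = 0.002,
) -> np.ndarray:
    """Conservative spike-free mask: excludes a padded window around every
    sample where any electrode exceeds ``threshold_sigmas`` times its
    noise sigma (in absolute value)."""
    sigma = np.broadcast_to(np.asarray(noise_sigma, dtype=float), (recording.n_electrodes,))
    hot = np.any(np.abs(recording.traces) > threshold_sigmas * sigma[:, None], axis=0)
    pad = int(round(pad_s * recording.fs))
    if pad > 0 and hot.any():
        kernel = np.ones(2 * pad + 1)
        hot = np.convolve(hot.astype(float), kernel, mode="same") > 0
    return ~hot


def mad_sigma(x: np.ndarray) -> float:
    """Robust noise sigma from the median absolute deviation (per trace)."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))) / 0.6744897501960817)


# --------------------------------------------------------------------------
# electrode groups and group templates
# --------------------------------------------------------------------------


def group_electrodes(
    footprint: Footprint,
    array: ElectrodeArray,
    k: int,
    noise_sigma: np.ndarray | float = 1.0,
    floor_sigmas: float = 2.0,
) -> list[tuple[int, ...]]:
    """Local electrode clusters for multi-electrode filters.

    Every electrode whose template amplitude exceeds ``floor_sigmas`` times
    its noise sigma seeds one group consisting of itself plus its ``k - 1``
    nearest neighbors (Euclidean distance, ties broken by electrode id);
    groups may overlap, and the seed is always listed first.
    """
    if k < 1:
        raise ValueError("group size must be >= 1")
    sigma = np.broadcast_to(np.asarray(noise_sigma, dtype=float), (array.n_electrodes,))
    groups = []
    for e in sorted(footprint.templates):
        if footprint.templates[e].peak_amplitude < floor_sigmas * sigma[e]:
            continue
        if k == 1:
            groups.append((e,))
            continue
        d = np.linalg.norm(array.positions - array.positions[e], axis=1)
        order = np.lexsort((np.arange(array.n_electrodes), d))
        neighbors = [int(i) for i in order if i != e][: k - 1]
        groups.append((e, *neighbors))
    return groups


@dataclass
class GroupTemplate:
    """Multichannel template snippet for one electrode group.

    ``data`` is ``(k, L)`` with the seed electrode first; ``ref_offset``
    is the integer sample of the seed electrode's negative peak within the
    snippet and ``time_correction_s`` the sub-sample residual of that peak
    (added to detected event times so that they estimate the arrival at
    the seed electrode).
    """

    electrodes: tuple[int, ...]
    data: np.ndarray
    ref_offset: int
    time_correction_s: float
    fs: float


def extract_group_template(
    footprint: Footprint,
    electrodes,
    noise_sigma: np.ndarray | float = 1.0,
    *,
    min_ms: float = 1.0,
    max_ms: float = 3.0,
    support_sigmas: float = 0.5,
) -> GroupTemplate:
    """Cut the filter template for a group out of the footprint.

    The window brackets the samples where any group electrode's template
    exceeds ``support_sigmas`` times its noise sigma, clipped to
    ``[min_ms, max_ms]`` around the seed electrode's negative peak so the
    filter stays short without losing waveform energy.
    """
    electrodes = tuple(int(e) for e in electrodes)
    seed = electrodes[0]
    tpl = footprint.templates[seed]
    fs = tpl.fs
    sigma = np.asarray(noise_sigma, dtype=float)
    if sigma.ndim == 0:
        sigma = np.full(max(electrodes) + 1, float(sigma))
    n = len(tpl.waveform)
    peak = tpl.peak_index
    above = np.zeros(n, dtype=bool)
    for e in electrodes:
        above |= np.abs(footprint.templates[e].waveform) > support_sigmas * sigma[e]
    if above.any():
        lo, hi = int(np.flatnonzero(above)[0]), int(np.flatnonzero(above)[-1]) + 1
    else:
        lo, hi = peak, peak + 1
    lo, hi = min(lo, peak), max(hi, peak + 1)
    min_n, max_n = int(round(min_ms * 1e-3 * fs)), int(round(max_ms * 1e-3 * fs))
    if hi - lo > max_n:  # shrink around the seed peak
        half = max_n // 2
        lo = max(peak - half, lo)
        hi = lo + max_n
        if hi > n:
            hi = n
            lo = hi - max_n
    while hi - lo < min_n:  # pad symmetrically
        if lo > 0:
            lo -= 1
        if hi - lo < min_n and hi < n:
            hi += 1
        if lo == 0 and hi == n:
            break
    data = np.stack([footprint.templates[e].waveform[lo:hi] for e in electrodes])
    ref = peak - lo
    frac = _refine_peak_fraction(footprint.templates[seed].waveform, peak)
    return GroupTemplate(
        electrodes=electrodes,
        data=data,
        ref_offset=ref,
        time_correction_s=frac / fs,
        fs=fs,
    )


def _refine_peak_fraction(w: np.ndarray, peak: int) -> float:
    """Sub-sample offset of a (negative) peak by parabolic interpolation."""
    if peak <= 0 or peak >= len(w) - 1:
        return 0.0
    y0, y1, y2 = w[peak - 1], w[peak], w[peak + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))


# --------------------------------------------------------------------------
# the matched filter
# --------------------------------------------------------------------------


@dataclass
class GroupFilter:
    """Whitened matched filter for one electrode group.

    ``coefficients`` is ``(k, L)``; ``expected_peak`` equals
    ``s' C^-1 s`` and is also the filter-output noise variance under the
    whitening convention, and ``threshold`` defaults to the equal-prior
    midpoint ``expected_peak / 2``.
    """

    electrodes: tuple[int, ...]
    coefficients: np.ndarray
    ref_offset: int
    time_correction_s: float
    fs: float
    expected_peak: float
    output_noise_variance: float
    threshold: float

    def __post_init__(self) -> None:
        if not 1 <= len(self.electrodes) <= 6:
            raise ValueError("electrode groups must contain 1-6 electrodes")
        if self.expected_peak <= 0:
            raise ValueError("expected_peak must be positive")
        if not 0 < self.threshold < self.expected_peak:
            raise ValueError("threshold must lie strictly between 0 and expected_peak")

    @property
    def length(self) -> int:
        return self.coefficients.shape[1]


def build_matched_filter(
    template: GroupTemplate,
    noise: NoiseModel,
    mode: str = "full",
    ridge: float = DEFAULT_RIDGE,
) -> GroupFilter:
    """Solve ``C w = s`` for the whitened matched filter of a group.

    With identity (white) covariance the filter reduces to the plain
    time-reversed template correlation scaled by ``1 / sigma**2``.
    """
    k, L = template.data.shape
    s = template.data.reshape(k * L)
    C = noise.cov_block(template.electrodes, L, mode=mode, ridge=ridge)
    try:
        w = np.linalg.solve(C, s)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - ridge prevents this
        raise SingularCovarianceError(
            f"noise covariance for group {template.electrodes} is singular"
        ) from exc
    expected_peak = float(s @ w)
    if expected_peak <= 0:
        raise SingularCovarianceError(
            f"non-positive expected peak for group {template.electrodes}; "
            "covariance is not positive definite"
        )
    return GroupFilter(
        electrodes=template.electrodes,
        coefficients=w.reshape(k, L),
        ref_offset=template.ref_offset,
        time_correction_s=template.time_correction_s,
        fs=template.fs,
        expected_peak=expected_peak,
        output_noise_variance=expected_peak,
        threshold=expected_peak / 2.0,
    )


def optimal_threshold(
    gfilter: GroupFilter,
    noise: NoiseModel | None = None,
    prior_ratio: float = 1.0,
) -> float:
    """Analytic detection threshold (Bayes rule for two equal-variance
    Gaussians).  ``prior_ratio`` is P(noise) / P(spike); 1 gives the
    midpoint ``expected_peak / 2``."""
    if prior_ratio <= 0:
        raise ValueError("prior_ratio must be positive")
    E = gfilter.expected_peak
    return E / 2.0 + gfilter.output_noise_variance / E * np.log(prior_ratio)


def convolve_and_sum(recording: Recording, gfilter: GroupFilter) -> np.ndarray:
    """Filter output trace: per-electrode correlation with the filter
    coefficients, summed over the group.

    The output time axis is aligned so that a template inserted with its
    reference (seed-electrode peak) at sample ``n`` produces the output
    maximum ``expected_peak`` at sample ``n``.
    """
    k, L = gfilter.coefficients.shape
    n = recording.n_samples
    out_full = np.zeros(n + L - 1)
    for row, e in enumerate(gfilter.electrodes):
        x = np.asarray(recording.traces[e], dtype=float)
        out_full += signal.fftconvolve(x, gfilter.coefficients[row][::-1], mode="full")
    start = L - 1 - gfilter.ref_offset
    return out_full[start : start + n]


@dataclass
class DetectionEvent:
    time_s: float
    score: float
    sample: int
    refined: bool = False
    group: int | None = None


def detect_events(
    filter_output: np.ndarray,
    threshold: float,
    fs: float,
    dead_time_s: float = DEFAULT_DEAD_TIME_S,
    group: int | None = None,
) -> list[DetectionEvent]:
    """One event per supra-threshold excursion of the filter output.

    Each excursion contributes its local maximum; events closer than
    ``dead_time_s`` are merged keeping the larger peak.
    """
    if threshold <= 0:
        raise ValueError("detection threshold must be positive")
    x = np.asarray(filter_output, dtype=float)
    above = x >= threshold
    events: list[DetectionEvent] = []
    dead = dead_time_s * fs
    for a, b in _mask_runs(above):
        peak = a + int(np.argmax(x[a:b]))
        ev = DetectionEvent(time_s=peak / fs, score=float(x[peak]), sample=peak, group=group)
        if events and peak - events[-1].sample < dead:
            if ev.score > events[-1].score:
                events[-1] = ev
        else:
            events.append(ev)
    return events


# --------------------------------------------------------------------------
# sub-sample timing
# --------------------------------------------------------------------------


def sinc_upsample(x: np.ndarray, factor: int = DEFAULT_UPSAMPLE) -> np.ndarray:
    """Whittaker-Shannon (band-limited) upsampling of a whole trace.

    Uses Fourier resampling, i.e. the periodic sinc interpolant; exact for
    band-limited periodic signals and the standard way to raise a 20 kHz
    recording to an effective 200 kHz timing grid.
    """
    x = np.asarray(x, dtype=float)
    return signal.resample(x, len(x) * factor)


def _windowed_sinc_value(x: np.ndarray, t: np.ndarray, center: int, half_width: int) -> np.ndarray:
    """Local Whittaker-Shannon interpolation with a Hann-tapered sinc
    kernel over ``center +- half_width`` samples (controls edge ringing)."""
    n = np.arange(center - half_width, center + half_width + 1)
    u = t[:, None] - n[None, :]
    taper = 0.5 * (1.0 + np.cos(np.pi * (n - center) / (half_width + 1)))
    return (np.sinc(u) * taper[None, :]) @ x[n]


def refine_time(
    filter_output: np.ndarray,
    event: DetectionEvent | int,
    fs: float,
    upsample_factor: int = DEFAULT_UPSAMPLE,
    half_window_s: float = 0.0005,
) -> DetectionEvent:
    """Sub-sample event time from the interpolated filter-output peak.

    Interpolates a ``+- half_window_s`` neighborhood of the peak on a
    ``upsample_factor`` times finer grid (windowed-sinc kernel) and
    returns the interpolated argmax.  Events too close to the trace edges
    fall back to the sample-resolution time and are flagged unrefined.
    """
    if isinstance(event, DetectionEvent):
        sample, score, group = event.sample, event.score, event.group
    else:
        sample = int(event)
        score, group = float(filter_output[sample]), None
    x = np.asarray(filter_output, dtype=float)
    half = max(int(round(half_window_s * fs)), 2)
    if sample - half < 0 or sample + half >= len(x):
        logger.warning("refine_time: event at sample %d too close to the trace edge", sample)
        return DetectionEvent(time_s=sample / fs, score=score, sample=sample,
                              refined=False, group=group)
    t = sample + np.arange(-upsample_factor, upsample_factor + 1) / upsample_factor
    y = _windowed_sinc_value(x, t, sample, half)
    best = int(np.argmax(y))
    return DetectionEvent(time_s=t[best] / fs, score=float(y[best]), sample=sample,
                          refined=True, group=group)


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------


@dataclass
class DetectionMetrics:
    """Mixed-trial detection scores (percentages)."""

    tp_percent: float
    fn_percent: float
    fp_percent: float
    n_spike_trials: int
    n_noise_trials: int
    n_detections: int
    n_matched: int


def evaluate_detection(
    events: pd.DataFrame,
    ground_truth: pd.DataFrame,
    tolerance_s: float = 0.001,
) -> DetectionMetrics:
    """Score detections against ground truth on a trial-by-trial basis.

    ``events`` needs columns ``trial`` and ``time_s``; ``ground_truth``
    needs ``trial``, ``spike_present`` and ``true_time_s``.  A spike trial
    counts as a true positive when some detection falls within
    ``tolerance_s`` of the true arrival (one detection consumed per
    spike); every other detection is a false positive.  The false-positive
    percentage is taken over all detections (0 when there is none); the
    true-positive percentage is over spike trials.
    """
    truth = ground_truth.drop_duplicates(subset="trial").set_index("trial")
    spike_trials = truth.index[truth["spike_present"].astype(bool)]
    n_matched = 0
    n_detections = len(events)
    unmatched = 0
    for trial, ev in events.groupby("trial"):
        times = ev["time_s"].to_numpy()
        used = np.zeros(len(times), dtype=bool)
        if trial in spike_trials:
            err = np.abs(times - truth.loc[trial, "true_time_s"])
            hit = int(np.argmin(err))
            if err[hit] <= tolerance_s:
                used[hit] = True
                n_matched += 1
        unmatched += int((~used).sum())
    if n_detections == 0:
        logger.info("evaluate_detection: no detections at all; FP%% defined as 0")
        fp = 0.0
    else:
        fp = 100.0 * unmatched / n_detections
    n_spike = len(spike_trials)
    tp = 100.0 * n_matched / n_spike if n_spike else 0.0
    return DetectionMetrics(
        tp_percent=tp,
        fn_percent=100.0 - tp if n_spike else 0.0,
        fp_percent=fp,
        n_spike_trials=n_spike,
        n_noise_trials=int(len(truth) - n_spike),
        n_detections=n_detections,
        n_matched=n_matched,
    )


def events_to_table(
    events: list[DetectionEvent],
    window_s: float | None = None,
    group: int | None = None,
) -> pd.DataFrame:
    """Detection events as a tidy table; with ``window_s`` given, each
    event is assigned the trial index of its 10 ms window."""
    rows = [
        {
            "trial": int(ev.time_s // window_s) if window_s else -1,
            "time_s": ev.time_s,
            "score": ev.score,
            "group": ev.group if ev.group is not None else group,
            "refined": ev.refined,
        }
        for ev in events
    ]
    return pd.DataFrame(rows, columns=["trial", "time_s", "score", "group", "refined"])
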