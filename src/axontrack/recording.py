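"""In-memory container for multichannel extracellular recordings.

A :class:`Recording` bundles the voltage traces (electrodes x samples, in
microvolts), the sampling rate, the electrode layout and, for stimulation
experiments, the pulse table.  All analysis modules consume this container;
:mod:`axontrack.io` serializes it to HDF5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_FS = 20_000.0  # Hz


@dataclass
class Recording:
    """Multichannel extracellular voltage recording.

    Parameters
    ----------
    traces:
        Array of shape ``(n_electrodes, n_samples)`` in microvolts.
    fs:
        Sampling rate in Hz.
    positions:
        ``(n_electrodes, 2)`` electrode coordinates in micrometers.
    stim:
        Optional stimulation table with columns ``trial``, ``time_s``,
        ``voltage_mv``, ``episode`` and ``pulse_index``.
    metadata:
        Free-form provenance (seed, generator version, preset name, ...).
    """

    traces: np.ndarray
    fs: float = DEFAULT_FS
    positions: np.ndarray | None = None
    stim: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D (electrodes x samples) array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if len(self.positions) != self.n_electrodes:
                raise ValueError(
                    f"electrode table has {len(self.positions)} rows but traces "
                    f"have {self.n_electrodes} channels"
                )

    @property
    def n_electrodes(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def trial_slice(self, trial: int, window_s: float = 0.010) -> np.ndarray:
        """Return the traces of one trial for recordings built from
        contiguous fixed-length trial windows."""
        w = int(round(window_s * self.fs))
        return self.traces[:, trial * w : (trial + 1) * w]
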