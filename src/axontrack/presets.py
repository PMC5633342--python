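"""Standard simulated preparations used by the benchmarks, tests and CLI.

Each preset fixes a geometry and physiology once; the only free input is
the seed.  ``detection_preset`` is a branched arbor on a regular
17.8-um-pitch grid with axonal amplitudes uniform in 3-10 sigma_noise (the
regime in which single-electrode thresholding fails but group template
matching succeeds); ``kinetics_preset`` is a straight 1.5 mm axon sampled
by a sparse line of electrodes, sized for velocity and jitter-rate
recovery; ``stimulation_preset`` places a short proximal axon 150-350 um
from the stimulation site.
"""

from __future__ import annotations

import numpy as np

from .synthetic import (
    ArborModel,
    Branch,
    ElectrodeArray,
    StimulationModel,
    TrainModel,
    build_array,
    default_amplitude_profile,
    line_array,
)

PITCH = 17.8


def detection_preset(seed: int | np.random.SeedSequence = 0):
    """Branched arbor on an 8 x 16 grid; returns ``(arbor, array)``.

    The AIS sits near the left edge; the main axon runs horizontally with
    one oblique collateral.  Axonal peak amplitudes are drawn uniformly in
    3-10 sigma_noise (seeded), the AIS-adjacent electrode at 10x their
    median.
    """
    array = build_array(8, 16, PITCH)
    ais = (PITCH, 3 * PITCH)
    main = Branch(points=np.array([[PITCH, 3 * PITCH], [15 * PITCH, 3 * PITCH]]))
    collateral = Branch(
        points=np.array([[7 * PITCH, 3 * PITCH], [15 * PITCH, 7 * PITCH]]),
        parent=0,
    )
    arbor = ArborModel(
        ais_position=ais,
        branches=[main, collateral],
        velocity_m_per_s=0.7,
        jitter_rate_us_per_mm=100.0,
    )
    arbor.amplitude_profile = default_amplitude_profile(arbor, array, seed)
    return arbor, array


def kinetics_preset(n_electrodes: int = 15, length_mm: float = 1.5):
    """Straight axon along a sparse electrode line; returns
    ``(arbor, array)``.

    The proximal electrode doubles as the alignment site and carries the
    large AIS-like signal; the rest of the line records axonal signals at
    8 sigma_noise.  Electrode spacing is ``length_mm / (n - 1)``, wide
    enough that the Brownian jitter increments never approach the
    propagation time of a segment.
    """
    spacing_um = length_mm * 1e3 / (n_electrodes - 1)
    array = line_array(n_electrodes, spacing_um)
    branch = Branch(points=np.array([[0.0, 0.0], [length_mm * 1e3 + 1.0, 0.0]]))
    profile = np.full(n_electrodes, 8.0)
    profile[0] = 80.0
    arbor = ArborModel(
        ais_position=(0.0, 0.0),
        branches=[branch],
        velocity_m_per_s=0.71,
        jitter_rate_us_per_mm=100.0,
        amplitude_profile=profile,
    )
    return arbor, array


def stimulation_preset():
    """Short proximal axon with three recording electrodes at 150-350 um
    from the stimulation site; returns ``(stim_model, arbor, array)``."""
    array = ElectrodeArray(positions=np.array([[150.0, 0.0], [250.0, 0.0], [350.0, 0.0]]),
                           pitch=PITCH)
    branch = Branch(points=np.array([[0.0, 0.0], [400.0, 0.0]]))
    arbor = ArborModel(
        ais_position=(0.0, 0.0),
        branches=[branch],
        velocity_m_per_s=0.7,
        jitter_rate_us_per_mm=100.0,
        amplitude_profile=np.full(3, 10.0),
        )
    return StimulationModel(), arbor, array


def train_preset(n_electrodes: int = 15, length_mm: float = 1.5):
    """Kinetics geometry driven by the 100 x 100-pulse 100 Hz protocol;
    returns ``(train_model, arbor, array)``."""
    arbor, array = kinetics_preset(n_electrodes, length_mm)
    return TrainModel(), arbor, array
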