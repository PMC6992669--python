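"""Pulsed plane-wave excitation definitions and stability helpers.

The excitation is a carrier sinusoid under a Gaussian envelope.  The
"duration" of a pulse is the total source-on window: the envelope is
centred at half the window and its standard deviation is chosen so the
envelope amplitude at the window edges is 1 % of the peak.  A 100 ps
window therefore passes 3, 6 and 9 carrier cycles at 30, 60 and
90 GHz; windows shorter than 1.5 carrier cycles are rejected as
physically meaningless excitations (a 20 ps window is only valid at
90 GHz).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import c as C0

from ..errors import InvalidInputError, InvalidSourceError

# envelope edge amplitude relative to peak: exp(-edge^2/2) = 0.01
_EDGE_SIGMAS = math.sqrt(2.0 * math.log(100.0))  # ~3.035

MIN_CYCLES = 1.5


class Incidence(enum.Enum):
    """Supported incidence directions relative to the canal axis (+x).

    ``ORTHOGONAL`` propagates straight down the canal; ``ANTERIOR_30``
    is rotated 30 deg toward anterior (+y) in the axial plane;
    ``SUPERIOR_45`` is rotated 45 deg toward superior (+z).
    """

    ORTHOGONAL = "orthogonal"
    ANTERIOR_30 = "anterior_30"
    SUPERIOR_45 = "superior_45"

    @property
    def angle_deg(self) -> float:
        return {"orthogonal": 0.0, "anterior_30": 30.0, "superior_45": 45.0}[self.value]

    @property
    def wave_vector(self) -> tuple[float, float, float]:
        th = math.radians(self.angle_deg)
        if self is Incidence.SUPERIOR_45:
            return (math.cos(th), 0.0, math.sin(th))
        return (math.cos(th), math.sin(th), 0.0)

    @property
    def polarization(self) -> tuple[float, float, float]:
        # E perpendicular to k: z-polarised except for the superior tilt,
        # which rotates k in the x-z plane and therefore uses y-polarisation.
        if self is Incidence.SUPERIOR_45:
            return (0.0, 1.0, 0.0)
        return (0.0, 0.0, 1.0)


@dataclass(frozen=True)
class PulseSource:
    """Gaussian-enveloped sinusoidal plane-wave excitation.

    Parameters
    ----------
    carrier : float
        Carrier frequency in Hz.
    envelope_duration : float
        Total source-on window in s (default 100 ps).
    amplitude : float
        Peak electric field in V/m (default 1.0; dosimetry rescales
        post hoc by linearity).
    incidence : Incidence
        Propagation direction (default orthogonal).
    """

    carrier: float
    envelope_duration: float = 100e-12
    amplitude: float = 1.0
    incidence: Incidence = Incidence.ORTHOGONAL

    def __post_init__(self):
        if self.carrier <= 0:
            raise InvalidSourceError(f"carrier must be > 0, got {self.carrier}")
        if self.envelope_duration <= 0:
            raise InvalidSourceError("envelope_duration must be > 0")
        cycles = self.carrier * self.envelope_duration
        if cycles < MIN_CYCLES:
            raise InvalidSourceError(
                f"envelope passes only {cycles:.2f} carrier cycles (< {MIN_CYCLES}); "
                "such a window is shorter than a wavelength period and not a valid excitation"
            )

    @property
    def center_time(self) -> float:
        return self.envelope_duration / 2.0

    @property
    def envelope_sigma(self) -> float:
        return self.envelope_duration / (2.0 * _EDGE_SIGMAS)


def gaussian_pulse(t, source: PulseSource):
    """Excitation waveform E(t) in V/m (scalar or ndarray argument).

    A cosine carrier under a Gaussian envelope centred at half the
    window, so the peak value equals ``source.amplitude`` exactly at
    the envelope centre.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("pulse time must be >= 0")
    t0 = source.center_time
    sg = source.envelope_sigma
    env = np.exp(-((t - t0) ** 2) / (2.0 * sg**2))
    wave = source.amplitude * env * np.cos(2.0 * math.pi * source.carrier * (t - t0))
    return wave if wave.ndim else float(wave)


def courant_timestep(spacings, fraction: float = 1.0) -> float:
    """Stable FDTD timestep dt = fraction / (c * sqrt(sum 1/dx_i^2)), s.

    ``spacings`` is a scalar (cubic cells, 3-D) or a per-axis sequence;
    a length-1 sequence gives the 1-D bound dt = fraction * dx / c.
    """
    if not (0.0 < fraction <= 1.0):
        raise InvalidInputError(f"fraction must be in (0, 1], got {fraction}")
    arr = np.asarray(spacings, dtype=float)
    if arr.ndim == 0:
        arr = np.full(3, float(arr))  # scalar means cubic 3-D cells
    if arr.ndim != 1 or np.any(arr <= 0):
        raise InvalidInputError("spacings must be positive scalars")
    return fraction / (C0 * math.sqrt(float(np.sum(1.0 / arr**2))))
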