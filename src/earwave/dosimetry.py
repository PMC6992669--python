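"""Power density, SAR and array statistics from sensor records.

All field quantities come out of the solver at unit incident amplitude
and are rescaled post hoc (valid by linearity, non-linear tissue
response excluded): E and H scale by the ratio of the target incident
field to the recorded source amplitude, PD and SAR by its square.

Conventions
-----------
* PD at a tissue sensor is the product of the *separately taken* peak
  |E| and peak |H| of that sensor (the paired-peaks convention);
  the instantaneous-product peak is available by flag.
* SAR uses the peak sensor field: sigma*E^2/(2*rho) in the ``peak``
  convention; the ``rms`` convention drops the /2 (equivalent to
  treating the stated E as an RMS value).  Reports record which
  convention produced each number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidInputError
from .fdtd.sensors import SensorRecord

FREE_SPACE_IMPEDANCE_NOMINAL = 377.0  # ohm, as used in PD = E^2/377


@dataclass(frozen=True)
class ExposureLevel:
    """A reference incident exposure: PD in W/m^2 and field in V/m."""

    name: str
    incident_pd: float
    incident_e: float

    def __post_init__(self):
        if self.name != "unit":
            expected = math.sqrt(self.incident_pd * FREE_SPACE_IMPEDANCE_NOMINAL)
            if abs(self.incident_e - expected) / expected > 0.005:
                raise InvalidInputError(
                    f"incident_e {self.incident_e} inconsistent with PD {self.incident_pd}"
                )


GENERAL_PUBLIC = ExposureLevel("general_public", incident_pd=10.0, incident_e=61.4)
OCCUPATIONAL = ExposureLevel("occupational", incident_pd=50.0, incident_e=137.0)
UNIT = ExposureLevel("unit", incident_pd=1.0 / FREE_SPACE_IMPEDANCE_NOMINAL, incident_e=1.0)


def pd_from_fields(e: float, h: float) -> float:
    """Power flux density PD = E*H in W/m^2 from paired peak magnitudes."""
    if e < 0 or h < 0:
        raise InvalidInputError("field magnitudes must be >= 0")
    return e * h


def pd_air(e: float) -> float:
    """Plane-wave PD in air, PD = E^2/377, W/m^2."""
    if e < 0:
        raise InvalidInputError("field magnitude must be >= 0")
    return e * e / FREE_SPACE_IMPEDANCE_NOMINAL


def sar(e_peak: float, sigma: float, rho: float, field_convention: str = "peak") -> float:
    """Specific absorption rate in W/kg.

    ``peak`` convention: sigma*E^2/(2*rho) for a peak sinusoidal field;
    ``rms``: sigma*E^2/rho (E interpreted as an RMS value).
    """
    if rho <= 0:
        raise InvalidInputError(f"density must be > 0, got {rho}")
    if e_peak < 0 or sigma < 0:
        raise InvalidInputError("e_peak and sigma must be >= 0")
    if field_convention == "peak":
        return sigma * e_peak**2 / (2.0 * rho)
    if field_convention == "rms":
        return sigma * e_peak**2 / rho
    raise InvalidInputError(f"unknown field convention {field_convention!r}")


def normalize_to_exposure(
    records: Sequence[SensorRecord], level: ExposureLevel
) -> list[SensorRecord]:
    """Rescale records to a reference incident exposure level.

    Linear and invertible: every E and H series is multiplied by
    ``level.incident_e / record.source_amplitude``.  Normalising an
    already-normalised record raises (the scaling would silently
    compound).
    """
    out = []
    for rec in records:
        if rec.source_amplitude is None:
            raise InvalidInputError(f"record {rec.name!r} has unknown source amplitude")
        if rec.normalized_level is not None:
            raise InvalidInputError(
                f"record {rec.name!r} already normalised to {rec.normalized_level!r}"
            )
        k = level.incident_e / rec.source_amplitude
        out.append(
            SensorRecord(
                name=rec.name,
                kind=rec.kind,
                timestep=rec.timestep,
                e_series=rec.e_series * k,
                h_series=None if rec.h_series is None else rec.h_series * k,
                e_components=None if rec.e_components is None else rec.e_components * k,
                h_components=None if rec.h_components is None else rec.h_components * k,
                peak_map=None if rec.peak_map is None else rec.peak_map * k,
                location=rec.location,
                source_amplitude=level.incident_e,
                normalized_level=level.name,
            )
        )
    return out


@dataclass(frozen=True)
class DosimetryResult:
    """Array statistics over a sensor set at one exposure level."""

    e_mean: float
    e_sd: float
    e_max: float
    h_mean: float | None
    h_sd: float | None
    pd_mean: float
    pd_sd: float
    pd_max: float
    per_sensor_pd: tuple[float, ...]
    level_name: str


def array_statistics(
    records: Sequence[SensorRecord], pd_convention: str = "paired_peaks"
) -> DosimetryResult:
    """Mean, sample SD (n-1) and max over a point-sensor array.

    PD is computed per sensor from that sensor's paired E and H before
    averaging; ``pd_convention='instantaneous'`` instead takes the peak
    of the per-step E*H product.
    """
    if len(records) < 2:
        raise InvalidInputError("array statistics need at least 2 sensors")
    peaks_e = np.array([r.peak_e for r in records])
    has_h = all(r.h_series is not None for r in records)
    if not has_h:
        raise InvalidInputError("array statistics need H records for PD")
    peaks_h = np.array([r.peak_h for r in records])
    if pd_convention == "paired_peaks":
        pds = peaks_e * peaks_h
    elif pd_convention == "instantaneous":
        pds = np.array([float(np.max(r.e_series * r.h_series)) for r in records])
    else:
        raise InvalidInputError(f"unknown pd convention {pd_convention!r}")
    levels = {r.normalized_level for r in records}
    level_name = levels.pop() if len(levels) == 1 and None not in levels else "unit"
    return DosimetryResult(
        e_mean=float(np.mean(peaks_e)),
        e_sd=float(np.std(peaks_e, ddof=1)),
        e_max=float(np.max(peaks_e)),
        h_mean=float(np.mean(peaks_h)),
        h_sd=float(np.std(peaks_h, ddof=1)),
        pd_mean=float(np.mean(pds)),
        pd_sd=float(np.std(pds, ddof=1)),
        pd_max=float(np.max(pds)),
        per_sensor_pd=tuple(float(p) for p in pds),
        level_name=level_name,
    )


def transmission_fraction(pd_inner: float, pd_outer: float) -> float:
    """Percentage of PD transmitted past an interface: 100*inner/outer."""
    if pd_outer <= 0:
        raise InvalidInputError("outer PD must be > 0")
    if pd_inner < 0:
        raise InvalidInputError("inner PD must be >= 0")
    return 100.0 * pd_inner / pd_outer
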