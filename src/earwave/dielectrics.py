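"""Tissue and water dielectric properties in the 30-90 GHz band.

Complex permittivity is stored as the pair (eps_real, eps_imag) with the
loss part non-negative.  The package-wide sign convention is the
engineering one, ``eps = eps' - i*eps''`` under an ``exp(+i*omega*t)``
time dependence; wherever optics-style arithmetic is more natural
(complex refractive index, transfer matrices) the conjugate physics
convention ``eps' + i*eps''`` under ``exp(-i*omega*t)`` is used
internally and only real, convention-independent quantities (R, T, A,
sigma, n, kappa, delta) cross the module boundary.

The tissue table covers six tissues at the three band anchor
frequencies (30, 60, 90 GHz) at 37 degC: bone/cartilage, dermis,
epidermis, stratum corneum (SC, the cornified outermost skin layer),
the fibrous lamina of the tympanic membrane, and mucous membrane.
Between anchors the permittivity is interpolated log-linearly in
frequency; outside the band it is an error.

Temperature correction of measured permittivities follows the
water-ratio method: tissue water dominates mm-wave dispersion, so
``eps'`` and ``eps''`` are scaled by the ratio of the single-Debye
water model evaluated at the target and measurement temperatures.
"""

from __future__ import annotations

import csv
import hashlib
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy.constants import c as C0
from scipy.constants import epsilon_0 as EPS0
from scipy.constants import mu_0 as MU0

from .errors import DataIntegrityError, InvalidInputError, NonAbsorbingMediumError

ETA0 = math.sqrt(MU0 / EPS0)  # free-space impedance, ~376.73 ohm

BAND_FREQUENCIES_HZ = (30e9, 60e9, 90e9)

TISSUES = (
    "bone_cartilage",
    "dermis",
    "epidermis",
    "stratum_corneum",
    "fibrous_tissue",
    "mucous_membrane",
)

_DATA_CHECKSUMS = {
    "tissue_permittivity_37c.csv": "30cf3a3d210267ec27f1f48cb9e3828393146ea04e806b19f2e3aa917b2fc477",
    "water_debye_coefficients.csv": "13ee9b84a8afd97c86b508608ba18feb8d06739ecee113d56e267854ede028d6",
}


def _read_data_file(name: str) -> str:
    raw = resources.files("earwave.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = _DATA_CHECKSUMS[name]
    if digest != expected:
        raise DataIntegrityError(f"{name}: checksum {digest} != expected {expected}")
    return raw.decode()


@dataclass(frozen=True)
class ComplexPermittivity:
    """Relative complex permittivity at one frequency and temperature.

    Parameters
    ----------
    eps_real : float
        Real part eps' (dimensionless, >= 1 for physical tissues in band).
    eps_imag : float
        Loss part eps'' (dimensionless, >= 0 by convention).
    frequency : float
        Frequency in Hz (> 0).
    temperature : float
        Temperature in degC the values refer to (default 37).
    """

    eps_real: float
    eps_imag: float
    frequency: float
    temperature: float = 37.0

    def __post_init__(self):
        if self.frequency <= 0:
            raise InvalidInputError(f"frequency must be > 0, got {self.frequency}")
        if self.eps_imag < 0:
            raise InvalidInputError(f"eps_imag must be >= 0, got {self.eps_imag}")

    @property
    def physics_complex(self) -> complex:
        """eps' + i*eps'' (exp(-i*omega*t) convention)."""
        return complex(self.eps_real, self.eps_imag)

    @property
    def engineering_complex(self) -> complex:
        """eps' - i*eps'' (exp(+i*omega*t) convention)."""
        return complex(self.eps_real, -self.eps_imag)


@dataclass(frozen=True)
class DerivedEMProperties:
    """EM material quantities derived from a complex permittivity.

    conductivity
        sigma = eps0 * eps'' * 2*pi*f, in S/m.
    n_real, kappa
        Real refractive index and extinction index.
    delta_field
        1/e *field* penetration depth c/(omega*kappa), in m.
    alpha_power
        Power absorption coefficient 2*omega*kappa/c = 2/delta_field, in 1/m.
    impedance
        Complex intrinsic impedance eta0/sqrt(eps) in ohm
        (physics convention).
    """

    conductivity: float
    n_real: float
    kappa: float
    delta_field: float
    alpha_power: float
    impedance: complex


def conductivity_from_permittivity(eps_imag: float, frequency: float) -> float:
    """Equivalent conductivity sigma = eps0 * eps'' * 2*pi*f in S/m."""
    if frequency <= 0:
        raise InvalidInputError(f"frequency must be > 0, got {frequency}")
    if eps_imag < 0:
        raise InvalidInputError(f"eps_imag must be >= 0, got {eps_imag}")
    return EPS0 * eps_imag * 2.0 * math.pi * frequency


def refractive_index(eps: ComplexPermittivity) -> tuple[float, float]:
    """Real index n and extinction index kappa of a lossy dielectric.

    n = sqrt((|eps| + eps')/2), kappa = sqrt((|eps| - eps')/2); this is
    the principal square root of the complex permittivity, so kappa = 0
    iff eps'' = 0.
    """
    mag = math.hypot(eps.eps_real, eps.eps_imag)
    n = math.sqrt((mag + eps.eps_real) / 2.0)
    kappa = math.sqrt(max(mag - eps.eps_real, 0.0) / 2.0)
    return n, kappa


def penetration_depth(eps: ComplexPermittivity) -> float:
    """1/e field-amplitude penetration depth delta = c/(omega*kappa) in m.

    Power decays as exp(-2 z / delta).  Raises
    :class:`NonAbsorbingMediumError` for a lossless medium.
    """
    _, kappa = refractive_index(eps)
    if kappa == 0.0:
        raise NonAbsorbingMediumError("penetration depth undefined for kappa = 0")
    omega = 2.0 * math.pi * eps.frequency
    return C0 / (omega * kappa)


def power_absorption_coefficient(eps: ComplexPermittivity) -> float:
    """Power absorption coefficient alpha = 2*omega*kappa/c in 1/m."""
    _, kappa = refractive_index(eps)
    omega = 2.0 * math.pi * eps.frequency
    return 2.0 * omega * kappa / C0


def intrinsic_impedance(eps: ComplexPermittivity) -> complex:
    """Complex intrinsic impedance eta = eta0 / sqrt(eps) in ohm.

    Physics convention (eps' + i*eps''); the principal root keeps
    Re(eta) > 0 for passive media.
    """
    return ETA0 / np.sqrt(eps.physics_complex)


def derived_properties(eps: ComplexPermittivity) -> DerivedEMProperties:
    """Bundle all derived EM material quantities for one permittivity."""
    n, kappa = refractive_index(eps)
    omega = 2.0 * math.pi * eps.frequency
    delta = C0 / (omega * kappa) if kappa > 0 else math.inf
    return DerivedEMProperties(
        conductivity=conductivity_from_permittivity(eps.eps_imag, eps.frequency),
        n_real=n,
        kappa=kappa,
        delta_field=delta,
        alpha_power=2.0 * omega * kappa / C0,
        impedance=intrinsic_impedance(eps),
    )


class TissueDielectricTable:
    """Six-tissue permittivity table at the three band anchor frequencies.

    At the anchor frequencies the values are returned exactly as
    tabulated (37 degC).  At intermediate frequencies eps' and eps'' are
    interpolated linearly in log(f) between the neighbouring anchors.
    """

    def __init__(self, entries: dict[tuple[str, float], ComplexPermittivity]):
        self._entries = dict(entries)
        for tissue in TISSUES:
            for f in BAND_FREQUENCIES_HZ:
                if (tissue, f) not in self._entries:
                    raise InvalidInputError(f"missing table entry: {tissue} @ {f} Hz")

    @property
    def tissues(self) -> tuple[str, ...]:
        return TISSUES

    @property
    def frequencies(self) -> tuple[float, ...]:
        return BAND_FREQUENCIES_HZ

    def get(self, tissue: str, frequency: float) -> ComplexPermittivity:
        if tissue not in TISSUES:
            raise InvalidInputError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
        for f in BAND_FREQUENCIES_HZ:
            if math.isclose(frequency, f, rel_tol=1e-9):
                return self._entries[(tissue, f)]
        fmin, fmax = BAND_FREQUENCIES_HZ[0], BAND_FREQUENCIES_HZ[-1]
        if not (fmin < frequency < fmax):
            raise InvalidInputError(
                f"frequency {frequency:.3g} Hz outside the tabulated band "
                f"[{fmin:.3g}, {fmax:.3g}] Hz"
            )
        anchors = list(BAND_FREQUENCIES_HZ)
        hi = next(i for i, f in enumerate(anchors) if f > frequency)
        f0, f1 = anchors[hi - 1], anchors[hi]
        w = (math.log(frequency) - math.log(f0)) / (math.log(f1) - math.log(f0))
        e0 = self._entries[(tissue, f0)]
        e1 = self._entries[(tissue, f1)]
        return ComplexPermittivity(
            eps_real=(1 - w) * e0.eps_real + w * e1.eps_real,
            eps_imag=(1 - w) * e0.eps_imag + w * e1.eps_imag,
            frequency=frequency,
            temperature=e0.temperature,
        )

    def conductivity(self, tissue: str, frequency: float) -> float:
        """sigma in S/m for a tissue at a frequency, via eps''."""
        eps = self.get(tissue, frequency)
        return conductivity_from_permittivity(eps.eps_imag, eps.frequency)


def load_tissue_table() -> TissueDielectricTable:
    """Load the bundled 37 degC tissue table (checksum-validated)."""
    text = _read_data_file("tissue_permittivity_37c.csv")
    entries: dict[tuple[str, float], ComplexPermittivity] = {}
    for row in csv.DictReader(text.splitlines()):
        f = float(row["frequency_ghz"]) * 1e9
        entries[(row["tissue"], f)] = ComplexPermittivity(
            eps_real=float(row["eps_real"]),
            eps_imag=float(row["eps_imag"]),
            frequency=f,
            temperature=37.0,
        )
    return TissueDielectricTable(entries)


# ---------------------------------------------------------------------------
# Water model and temperature adjustment
# ---------------------------------------------------------------------------

def _water_coefficients() -> dict[str, float]:
    text = _read_data_file("water_debye_coefficients.csv")
    return {row["parameter"]: float(row["value"]) for row in csv.DictReader(text.splitlines())}


_WATER = None


def _water() -> dict[str, float]:
    global _WATER
    if _WATER is None:
        _WATER = _water_coefficients()
    return _WATER


def water_static_permittivity(temperature: float) -> float:
    """Static permittivity of liquid water (Malmberg & Maryott 1956 fit)."""
    w = _water()
    t = temperature
    return (
        w["eps_static_a0"]
        + w["eps_static_a1"] * t
        + w["eps_static_a2"] * t**2
        + w["eps_static_a3"] * t**3
    )


def water_relaxation_time(temperature: float) -> float:
    """Debye relaxation time of water in s (Arrhenius fit, Kaatze 1989)."""
    w = _water()
    return w["tau_prefactor_s"] * math.exp(w["tau_activation_k"] / (temperature + 273.15))


def water_permittivity(temperature: float, frequency: float) -> ComplexPermittivity:
    """Single-Debye complex permittivity of liquid water.

    Valid for 0 <= temperature <= 60 degC and 1 GHz <= frequency <=
    100 GHz.  eps(omega) = eps_inf + (eps_s - eps_inf)/(1 + i*omega*tau)
    with temperature-dependent eps_s, eps_inf and tau.
    """
    if not (0.0 <= temperature <= 60.0):
        raise InvalidInputError(f"temperature {temperature} degC outside [0, 60]")
    if not (1e9 <= frequency <= 100e9):
        raise InvalidInputError(f"frequency {frequency:.3g} Hz outside [1, 100] GHz")
    w = _water()
    eps_s = water_static_permittivity(temperature)
    eps_inf = w["eps_inf_b0"] + w["eps_inf_b1"] * temperature
    tau = water_relaxation_time(temperature)
    x = 2.0 * math.pi * frequency * tau
    delta = eps_s - eps_inf
    eps_real = eps_inf + delta / (1.0 + x * x)
    eps_imag = delta * x / (1.0 + x * x)
    return ComplexPermittivity(eps_real, eps_imag, frequency, temperature)


def adjust_to_temperature(
    eps_measured: ComplexPermittivity, t_measured: float, t_target: float
) -> ComplexPermittivity:
    """Rescale a measured permittivity to a different temperature.

    Applies the water-ratio correction: eps'_out = eps'_in *
    eps'_water(t_target)/eps'_water(t_measured) and likewise for eps''.
    The adjustment is the identity when the two temperatures coincide
    and is exactly invertible (multiplicative).
    """
    if t_measured == t_target:
        return eps_measured
    w_target = water_permittivity(t_target, eps_measured.frequency)
    w_meas = water_permittivity(t_measured, eps_measured.frequency)
    return ComplexPermittivity(
        eps_real=eps_measured.eps_real * (w_target.eps_real / w_meas.eps_real),
        eps_imag=eps_measured.eps_imag * (w_target.eps_imag / w_meas.eps_imag),
        frequency=eps_measured.frequency,
        temperature=t_target,
    )


# ---------------------------------------------------------------------------
# Closed-form reflectance oracles
# ---------------------------------------------------------------------------

AIR = ComplexPermittivity(1.0, 0.0, 1e9)  # frequency is irrelevant for eps = 1


def _complex_index(eps: ComplexPermittivity) -> complex:
    """N = n + i*kappa, principal root (physics convention)."""
    return np.sqrt(eps.physics_complex)


def fresnel_normal_incidence(
    eps1: ComplexPermittivity, eps2: ComplexPermittivity
) -> complex:
    """Amplitude reflection coefficient at normal incidence, medium 1 -> 2.

    r = (eta2 - eta1)/(eta2 + eta1) with eta = eta0/sqrt(eps);
    |r| <= 1 for passive media.  Returned in the physics convention.
    """
    eta1 = ETA0 / _complex_index(eps1)
    eta2 = ETA0 / _complex_index(eps2)
    return (eta2 - eta1) / (eta2 + eta1)


def transfer_matrix_stack(
    layers: Sequence[tuple[ComplexPermittivity, float]],
    frequency: float,
    eps_exit: ComplexPermittivity | None = None,
) -> tuple[float, float, float]:
    """Power reflectance, transmittance and absorptance of a planar stack.

    The stack is illuminated from semi-infinite air at normal incidence;
    the exit half-space is air unless ``eps_exit`` is given (a
    zero-layer stack with an ``eps_exit`` is a single Fresnel
    interface).  Uses the standard characteristic-matrix method with
    complex indices; R + T + A = 1 to numerical precision and A = 0
    when every layer is lossless.

    Parameters
    ----------
    layers : sequence of (ComplexPermittivity, thickness_m)
    frequency : float
        Frequency in Hz at which the stack is evaluated.
    """
    if frequency <= 0:
        raise InvalidInputError(f"frequency must be > 0, got {frequency}")
    k0 = 2.0 * math.pi * frequency / C0
    y_in = 1.0 + 0.0j  # admittances in units of 1/eta0
    n_exit = _complex_index(eps_exit) if eps_exit is not None else 1.0 + 0.0j

    m = np.eye(2, dtype=complex)
    for eps, d in layers:
        if d <= 0:
            raise InvalidInputError(f"layer thickness must be > 0, got {d}")
        nj = _complex_index(eps)
        phi = k0 * nj * d
        cj, sj = np.cos(phi), np.sin(phi)
        # characteristic matrix for N = n + i*kappa under exp(-i*omega*t);
        # the -i sign pairs with the decaying exp(+i*k0*N*z) wave
        m = m @ np.array([[cj, -1j * sj / nj], [-1j * nj * sj, cj]])

    b, cc = m @ np.array([1.0 + 0.0j, n_exit])
    r = (y_in * b - cc) / (y_in * b + cc)
    t = 2.0 * y_in / (y_in * b + cc)
    reflectance = float(abs(r) ** 2)
    transmittance = float(np.real(n_exit) * abs(t) ** 2 / np.real(y_in))
    absorptance = 1.0 - reflectance - transmittance
    return reflectance, transmittance, absorptance
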