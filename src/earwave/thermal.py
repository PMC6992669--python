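"""Temperature-rise estimation for the tympanic membrane.

Three routes are provided, all operating on a lumped (0-D) membrane
node:

* method #1 - initial heating rate SAR/c_t (conduction and perfusion
  neglected);
* method #2 - initial heating rate PD*exp(-2z/delta)/(delta*rho*c)
  from the local power density and field penetration depth;
* bioheat integration - explicit-Euler integration of the Pennes-type
  balance dT/dt = (k_lump*(T_env - T) + rho_t*SAR
  - rho_b*c_b*BP*rho_t*(T - T_b)) / (rho_t*c_t) over a short exposure
  (default 0.1 s steps for 5 s).  The conduction term is not spatially
  resolved; it enters only through an optional user-supplied lumped
  loss coefficient (default 0, since for sub-degree rises over seconds
  it is negligible, as is easy to confirm with the hook).

The blood-perfusion rate BP is stored in SI volume-flow units
(m^3 kg^-1 s^-1) and multiplied by the tissue density to give
consistent units in the heat balance.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dielectrics import TissueDielectricTable, penetration_depth
from .errors import InvalidInputError

_THERMAL_CHECKSUM = "a2b3ca7a41ff3018d233c3cc82daf02e94c827ee77ad998b88c7d0e1439ad0ff"


@dataclass(frozen=True)
class TissueThermal:
    """Per-tissue thermal parameters (SI units)."""

    density: float  # kg/m^3
    heat_capacity: float  # J/(kg K)
    thermal_conductivity: float  # W/(m degC)
    blood_flow: float  # m^3/(kg s), 0 for unperfused tissues

    def __post_init__(self):
        if self.density <= 0 or self.heat_capacity <= 0 or self.thermal_conductivity <= 0:
            raise InvalidInputError("density, heat capacity and conductivity must be > 0")
        if self.blood_flow < 0:
            raise InvalidInputError("blood flow must be >= 0")


@dataclass(frozen=True)
class ThermalParams:
    """Thermal parameter set: per-tissue values plus blood properties."""

    tissues: dict[str, TissueThermal]
    blood_density: float = 1057.0
    blood_heat_capacity: float = 3600.0

    def get(self, tissue: str) -> TissueThermal:
        if tissue not in self.tissues:
            raise InvalidInputError(f"no thermal parameters for tissue {tissue!r}")
        return self.tissues[tissue]


def load_thermal_params() -> ThermalParams:
    """Load the bundled 37 degC thermal table (checksum-validated)."""
    import hashlib
    from importlib import resources

    raw = resources.files("earwave.data").joinpath("thermal_params_37c.csv").read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _THERMAL_CHECKSUM:
        from .errors import DataIntegrityError

        raise DataIntegrityError(f"thermal_params_37c.csv checksum mismatch: {digest}")
    tissues = {}
    for row in csv.DictReader(raw.decode().splitlines()):
        tissues[row["tissue"]] = TissueThermal(
            density=float(row["density_kg_m3"]),
            heat_capacity=float(row["heat_capacity_j_kg_k"]),
            thermal_conductivity=float(row["thermal_conductivity_w_m_c"]),
            blood_flow=float(row["blood_flow_m3_kg_s"]),
        )
    blood = tissues["blood"]
    return ThermalParams(
        tissues=tissues,
        blood_density=blood.density,
        blood_heat_capacity=blood.heat_capacity,
    )


@dataclass
class ThermalState:
    """Lumped tissue temperature state."""

    tissue_temperature: float = 37.0
    blood_temperature: float = 37.0
    elapsed: float = 0.0


def init_rate_method1(sar_value: float, heat_capacity: float) -> float:
    """Initial heating rate SAR/c_t in degC/s (losses neglected)."""
    if heat_capacity <= 0:
        raise InvalidInputError("heat capacity must be > 0")
    return sar_value / heat_capacity


def init_rate_method2(pd_value: float, delta: float, z: float, rho: float,
                      heat_capacity: float) -> float:
    """Initial heating rate PD*exp(-2z/delta)/(delta*rho*c) in degC/s.

    ``delta`` is the 1/e *field* penetration depth, so the exp(-2z/delta)
    factor decays as power does.
    """
    if delta <= 0 or rho <= 0 or heat_capacity <= 0:
        raise InvalidInputError("delta, rho and heat capacity must be > 0")
    if z < 0:
        raise InvalidInputError("depth must be >= 0")
    return pd_value * math.exp(-2.0 * z / delta) / (delta * rho * heat_capacity)


@dataclass(frozen=True)
class BioheatTrajectory:
    """Euler trajectory of the lumped bioheat balance."""

    times: np.ndarray  # s, starting at 0
    temperatures: np.ndarray  # degC, same length

    @property
    def final_rise(self) -> float:
        return float(self.temperatures[-1] - self.temperatures[0])


def integrate_bioheat(
    heating_rate: float | Callable[[float], float],
    tissue: TissueThermal,
    params: ThermalParams,
    state0: ThermalState | None = None,
    dt: float = 0.1,
    duration: float = 5.0,
    conduction_loss: float = 0.0,
    environment_temperature: float | None = None,
) -> BioheatTrajectory:
    """Integrate the lumped bioheat balance with explicit Euler steps.

    ``heating_rate`` is the loss-free volumetric heating expressed as a
    temperature rate, rho_t*SAR/(rho_t*c_t) = SAR/c_t in degC/s (a
    constant or a function of time).  Perfusion removes heat at
    rho_b*c_b*BP*rho_t*(T - T_b) per unit volume; ``conduction_loss``
    is an optional lumped coefficient (W m^-3 K^-1) standing in for the
    unresolved conduction term.

    Raises on dt > duration and on a diverging trajectory.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be > 0")
    if duration < dt:
        raise InvalidInputError("duration must be >= dt")
    state0 = state0 or ThermalState()
    t_env = environment_temperature if environment_temperature is not None else state0.blood_temperature

    rate_fn = heating_rate if callable(heating_rate) else (lambda _t: heating_rate)
    vol_heat_cap = tissue.density * tissue.heat_capacity  # J/(m^3 K)
    perf = params.blood_density * params.blood_heat_capacity * tissue.blood_flow * tissue.density

    n = int(round(duration / dt))
    times = np.arange(n + 1) * dt
    temps = np.empty(n + 1)
    temps[0] = state0.tissue_temperature
    tb = state0.blood_temperature
    for i in range(n):
        t = times[i]
        dT = (
            rate_fn(t)
            - perf * (temps[i] - tb) / vol_heat_cap
            - conduction_loss * (temps[i] - t_env) / vol_heat_cap
        )
        temps[i + 1] = temps[i] + dt * dT
        if not math.isfinite(temps[i + 1]) or abs(temps[i + 1] - tb) > 100.0:
            raise InvalidInputError(f"bioheat integration diverged at t = {times[i + 1]:.3g} s")
    return BioheatTrajectory(times=times, temperatures=temps)


@dataclass(frozen=True)
class ScenarioDose:
    """Dose inputs for one exposure scenario at the general-public level."""

    frequency: float  # Hz
    angle: str  # 'orthogonal' | 'anterior_30' | 'superior_45'
    sar_peak: float  # W/kg, peak-field convention, public level
    pd: float | None = None  # W/m^2 at the membrane array, public level
    tissue: str = "fibrous_tissue"


def exposure_report(
    doses: Sequence[ScenarioDose],
    params: ThermalParams,
    dielectrics: TissueDielectricTable,
    sensor_depth: float = 3e-5,
    convention: str = "rms",
    dt: float = 0.1,
    duration: float = 5.0,
) -> pd.DataFrame:
    """Method #1 / method #2 / 5-s temperature table for a scenario set.

    One row per (frequency, angle): SAR, both initial heating rates and
    the integrated 5 s rise at the general-public level, plus the
    occupational columns (exactly 5x the public values, the incident-PD
    ratio).  ``convention='rms'`` doubles the peak-convention SAR before
    dividing by c_t, which is the chain the published tabulations of
    this kind follow; the flag used is recorded in ``df.attrs``.
    """
    if convention not in ("rms", "peak"):
        raise InvalidInputError(f"unknown SAR convention {convention!r}")
    rows = []
    for dose in doses:
        if dose.frequency <= 0 or dose.angle not in ("orthogonal", "anterior_30", "superior_45"):
            raise InvalidInputError(f"bad scenario metadata: {dose}")
        tissue = params.get(dose.tissue)
        sar_eff = dose.sar_peak * (2.0 if convention == "rms" else 1.0)
        rate1 = init_rate_method1(sar_eff, tissue.heat_capacity)
        if dose.pd is not None:
            eps = dielectrics.get(dose.tissue, dose.frequency)
            delta = penetration_depth(eps)
            rate2 = init_rate_method2(dose.pd, delta, sensor_depth,
                                      tissue.density, tissue.heat_capacity)
        else:
            rate2 = math.nan
        traj = integrate_bioheat(rate1, tissue, params, dt=dt, duration=duration)
        occupational_factor = 5.0  # incident-PD ratio 50/10
        rows.append(
            {
                "frequency_ghz": dose.frequency / 1e9,
                "angle": dose.angle,
                "sar_public_w_kg": dose.sar_peak,
                "rate1_public_c_per_s": rate1,
                "rate2_public_c_per_s": rate2,
                "rise_5s_public_c": traj.final_rise,
                "sar_occupational_w_kg": dose.sar_peak * occupational_factor,
                "rate1_occupational_c_per_s": rate1 * occupational_factor,
                "rise_5s_occupational_c": traj.final_rise * occupational_factor,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["sar_convention"] = convention
    df.attrs["sensor_depth_m"] = sensor_depth
    return df
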