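"""Synthetic test inputs: analytic sensor records, layered stacks and
reduced-scale 3-D ear scenarios.

Everything here is generated programmatically — no downloads, no
stored arrays — and is bit-for-bit reproducible from its spec and
seed.  The plane-wave records exercise the dosimetry and thermal
chains without a solver run; the layered stacks pair a 1-D phantom
with its transfer-matrix answer for oracle tests; the mini ear is a
shortened (8 mm default) canal with the full membrane layering that a
single CPU runs in well under a minute per frequency, standing in for
the full-size model whose grid (~5e8 cells) is cluster-scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.constants import c as C0

from .dielectrics import (
    ComplexPermittivity,
    TissueDielectricTable,
    intrinsic_impedance,
    load_tissue_table,
    transfer_matrix_stack,
)
from .errors import InvalidInputError
from .fdtd.sensors import SensorRecord, SensorSpec
from .fdtd.sources import Incidence, PulseSource, gaussian_pulse
from .phantom import (
    MEMBRANE_LAYER_ORDER,
    EarGeometrySpec,
    VoxelPhantom,
    build_ear_phantom_with_pinna,
)

FREE_SPACE_IMPEDANCE_NOMINAL = 377.0


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of a synthetic plane-wave sensor record."""

    carrier: float = 60e9
    amplitude: float = 1.0
    duration: float = 100e-12
    medium: str | None = None  # None = air (H = E/377)
    noise_sd: float = 0.0
    seed: int = 0
    n_steps: int = 2048

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")


def make_plane_wave_record(
    spec: FixtureSpec, name: str = "plane_wave", table: TissueDielectricTable | None = None
) -> SensorRecord:
    """Analytic Gaussian-pulsed plane-wave record.

    E(t) is the pulse waveform; H(t) = E(t)/377 in air or E(t)/|eta|
    for a named tissue.  Optional multiplicative Gaussian noise is
    drawn from the fixture seed, so the record is reproducible.
    """
    src = PulseSource(carrier=spec.carrier, envelope_duration=spec.duration,
                      amplitude=spec.amplitude)
    dt = 1.0 / (spec.carrier * 40.0)
    n = spec.n_steps
    t = np.arange(n) * dt
    e = np.abs(gaussian_pulse(t, src))
    if spec.medium is None:
        eta = FREE_SPACE_IMPEDANCE_NOMINAL
    else:
        table = table or load_tissue_table()
        eta = abs(intrinsic_impedance(table.get(spec.medium, spec.carrier)))
    h = e / eta
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        factor = np.abs(1.0 + spec.noise_sd * rng.standard_normal(n))
        e = e * factor
        h = h * factor
    return SensorRecord(
        name=name, kind="point", timestep=dt, e_series=e, h_series=h,
        source_amplitude=spec.amplitude,
    )


def make_enhanced_array_records(
    central_boost: float = 0.45,
    spec: FixtureSpec | None = None,
    n_central: int = 2,
    n_total: int = 6,
) -> list[SensorRecord]:
    """Six-sensor array fixture with a stated central field enhancement.

    The central sensors carry (1 + central_boost) times the peripheral
    amplitude, emulating the preferential exposure of the membrane
    centre; used to exercise array statistics, not to prove physics.
    """
    spec = spec or FixtureSpec()
    out = []
    for i in range(n_total):
        amp = spec.amplitude * (1.0 + central_boost if i < n_central else 1.0)
        rec = make_plane_wave_record(replace(spec, amplitude=amp), name=f"array_{i}")
        out.append(rec)
    return out


def make_layered_stack(
    n_layers: int,
    seed: int,
    frequency: float = 90e9,
    table: TissueDielectricTable | None = None,
    spacing: float = 2.5e-6,
) -> tuple[list[tuple[ComplexPermittivity, float]], tuple[float, float, float]]:
    """Random tissue stack plus its transfer-matrix (R, T, A) answer.

    Materials are drawn from the tissue table at the given band
    frequency; thicknesses are whole multiples of ``spacing`` between
    20 and 120 um so the 1-D solver voxelises them exactly.  A fixed
    seed reproduces the identical stack.
    """
    if n_layers < 0 or n_layers > 5:
        raise InvalidInputError("n_layers must be between 0 and 5")
    table = table or load_tissue_table()
    rng = np.random.default_rng(seed)
    layers: list[tuple[ComplexPermittivity, float]] = []
    tissues = list(table.tissues)
    for _ in range(n_layers):
        tissue = tissues[int(rng.integers(len(tissues)))]
        cells = int(rng.integers(8, 48))
        layers.append((table.get(tissue, frequency), cells * spacing))
    answer = transfer_matrix_stack(layers, frequency)
    return layers, answer


def tympanic_stack(
    frequency: float = 90e9,
    table: TissueDielectricTable | None = None,
    geometry: EarGeometrySpec | None = None,
) -> list[tuple[ComplexPermittivity, float]]:
    """The four-layer membrane as a 1-D stack (SC, epidermis, fibrous, mucosa).

    Layer order and thicknesses come from the same geometry spec the
    voxel phantom is built from, so the two stay consistent.
    """
    table = table or load_tissue_table()
    geometry = geometry or EarGeometrySpec()
    return [
        (table.get(name, frequency), geometry.layer_thicknesses[name])
        for name in MEMBRANE_LAYER_ORDER
    ]


def stack_field_scenario(
    frequency: float = 90e9,
    table: TissueDielectricTable | None = None,
    sensor_depth: float | None = None,
):
    """Desk-scale 1-D perturbation scenario over the membrane stack.

    Returns a callable ``scenario(scale_real, scale_imag)`` that reruns
    the 1-D solver with every layer's eps' and eps'' multiplied by the
    given factors and reports the peak |E| at the epidermis/fibrous
    junction (0.03 mm inside the membrane by default) — the shape the
    permittivity-perturbation harness expects.
    """
    from .fdtd.solver1d import stack_internal_peak_1d

    table = table or load_tissue_table()
    base = tympanic_stack(frequency, table)
    geometry = EarGeometrySpec()
    if sensor_depth is None:
        sensor_depth = (
            geometry.layer_thicknesses["stratum_corneum"]
            + geometry.layer_thicknesses["epidermis"]
        )

    def scenario(scale_real: float, scale_imag: float) -> float:
        layers = [
            (ComplexPermittivity(e.eps_real * scale_real, e.eps_imag * scale_imag,
                                 e.frequency, e.temperature), d)
            for e, d in base
        ]
        return stack_internal_peak_1d(layers, frequency, sensor_depth)

    return scenario


# ---------------------------------------------------------------------------
# Reduced-scale 3-D scenario
# ---------------------------------------------------------------------------

MAX_MINI_EAR_CELLS = 10_000_000


@dataclass(frozen=True)
class MiniEarScenario:
    """Configuration of a reduced-scale ear exposure run."""

    frequency: float = 90e9
    incidence: Incidence = Incidence.ORTHOGONAL
    pulse_duration: float = 100e-12
    spacing: float = 1.5e-4
    canal_depth: float = 8e-3
    courant_fraction: float = 0.95


def make_mini_ear(
    scale_fraction: float = 8.0 / 25.0,
    spacing: float = 1.5e-4,
    pinna: bool = False,
) -> tuple[VoxelPhantom, EarGeometrySpec]:
    """Shortened-canal voxel ear phantom for desk-scale runs.

    The canal keeps its full cross-section and complete membrane
    layering but is shortened (8 mm at the default scale fraction):
    long enough for an internal reflection round trip inside a 100 ps
    window at 90 GHz, small enough to stay well under the 1e7-cell
    budget.  Raises if the requested build would exceed that budget.

    The pinna blocks are off by default: their dimensions are not
    anatomically constrained, and at reduced scale their edge
    diffraction would swamp the canal/membrane physics the scenario is
    meant to isolate (the entrance aperture in the bone face still
    diffracts).  Pass ``pinna=True`` for the full entrance geometry.
    """
    if not (0 < scale_fraction <= 1.0):
        raise InvalidInputError("scale_fraction must be in (0, 1]")
    # front_air leaves room for the source plane ahead of the pinna blocks
    # (which reach ~0.4*pinna_scale in front of the canal mouth)
    spec = EarGeometrySpec(
        canal_depth=25e-3 * scale_fraction,
        front_air=4.0e-3,
        middle_ear_depth=1.5e-3,
        baffle_depth=1.5e-3,
        lateral_padding=2.0e-3,
        pinna_scale=6e-3,
        pinna_enabled=pinna,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # thin layers are expected to inflate
        phantom = build_ear_phantom_with_pinna(spec, spacing)
    n_cells = int(np.prod(phantom.labels.shape))
    if n_cells > MAX_MINI_EAR_CELLS:
        raise InvalidInputError(
            f"mini-ear build has {n_cells} cells, over the {MAX_MINI_EAR_CELLS} budget"
        )
    return phantom, spec


def run_mini_ear(
    scenario: MiniEarScenario,
    table: TissueDielectricTable | None = None,
    phantom: VoxelPhantom | None = None,
    extra_sensors: list[SensorSpec] | None = None,
    reference: bool = False,
):
    """Run a mini-ear exposure (or its free-space reference) and return
    a dict of sensor records keyed by name.

    The sensor set is the membrane six-point array, the canal-mouth
    centre point and, for reference runs, the same mouth point on an
    all-air grid of identical shape (used to measure the incident field
    the normalisation divides by).
    """
    from .fdtd.sensors import membrane_array_sensors
    from .fdtd.solver3d import SolverConfig, run_fdtd

    table = table or load_tissue_table()
    if phantom is None:
        phantom, _ = make_mini_ear(
            scale_fraction=scenario.canal_depth / 25e-3, spacing=scenario.spacing
        )
    meta = phantom.meta
    yc, zc = meta["canal_center_yz"]
    mouth = SensorSpec("canal_mouth", "point",
                       position=(meta["x_mouth"] + 5e-4, yc, zc), snap_to_tissue="air")
    sensors = [mouth]
    if not reference:
        sensors += membrane_array_sensors(phantom)
    if extra_sensors:
        sensors += extra_sensors

    source = PulseSource(
        carrier=scenario.frequency,
        envelope_duration=scenario.pulse_duration,
        incidence=scenario.incidence,
    )
    if reference:
        empty = VoxelPhantom(
            labels=np.zeros_like(phantom.labels),
            spacing=phantom.spacing,
            origin=phantom.origin,
            meta=dict(phantom.meta),
        )
        records = run_fdtd(empty, None, source, sensors,
                           SolverConfig(courant_fraction=scenario.courant_fraction))
    else:
        records = run_fdtd(phantom, table, source, sensors,
                           SolverConfig(courant_fraction=scenario.courant_fraction))
    return {rec.name: rec for rec in records}
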