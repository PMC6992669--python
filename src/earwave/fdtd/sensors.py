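"""Field sensors: specifications, records and the default ear sensor set.

Point sensors record per-step |E| (V/m) and |H| (A/m) together with the
vector components sampled at a voxel; planar sensors record a
peak-over-time |E| map across a grid plane plus the time series at the
plane centre (so the instantaneous and peak-hold views are both
available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidInputError, SensorPlacementError
from ..phantom import TISSUE_IDS, EarGeometrySpec, VoxelPhantom

# (y, z) offsets of the six membrane-array sensors, as fractions of the
# membrane semi-axes; the first two are the central pair, the remaining
# four the peripheral ring.
ARRAY_OFFSETS = (
    (0.0, 0.0),
    (0.0, 0.25),
    (0.65, 0.0),
    (-0.65, 0.0),
    (0.0, 0.65),
    (0.0, -0.65),
)
N_CENTRAL = 2


@dataclass(frozen=True)
class SensorSpec:
    """Requested sensor: a point position (m) or an axis-aligned plane.

    For ``kind='point'`` provide ``position``; for ``kind='planar'``
    provide ``plane_axis`` (0=x, 1=y, 2=z) and ``plane_offset`` (m).
    ``snap_to_tissue`` optionally names the tissue (or 'air') the
    resolved voxel must carry; the resolver searches a few voxels along
    +/-x to land inside it (used for thin-membrane placements).
    """

    name: str
    kind: str = "point"
    position: tuple[float, float, float] | None = None
    plane_axis: int | None = None
    plane_offset: float | None = None
    snap_to_tissue: str | None = None

    def __post_init__(self):
        if self.kind not in ("point", "planar"):
            raise InvalidInputError(f"unknown sensor kind {self.kind!r}")
        if self.kind == "point" and self.position is None:
            raise InvalidInputError(f"sensor {self.name}: point sensors need a position")
        if self.kind == "planar" and (self.plane_axis is None or self.plane_offset is None):
            raise InvalidInputError(f"sensor {self.name}: planar sensors need axis and offset")


@dataclass
class SensorRecord:
    """Recorded output of one sensor.

    ``e_series``/``h_series`` are per-step magnitudes; point records
    also carry the vector components, planar records a peak-over-time
    |E| map.  ``source_amplitude`` is the incident-field amplitude the
    run was excited with, which dosimetry uses for post-hoc rescaling;
    ``normalized_level`` is set once a record has been rescaled.
    """

    name: str
    kind: str
    timestep: float
    e_series: np.ndarray
    h_series: np.ndarray | None = None
    e_components: np.ndarray | None = None
    h_components: np.ndarray | None = None
    peak_map: np.ndarray | None = None
    location: tuple | None = None
    source_amplitude: float | None = 1.0
    normalized_level: str | None = None

    def __post_init__(self):
        if np.any(self.e_series < 0):
            raise InvalidInputError("magnitude series must be non-negative")

    @property
    def n_steps(self) -> int:
        return int(self.e_series.shape[0])

    @property
    def peak_e(self) -> float:
        return float(np.max(self.e_series))

    @property
    def peak_h(self) -> float:
        if self.h_series is None:
            raise InvalidInputError(f"sensor {self.name} has no H record")
        return float(np.max(self.h_series))


def resolve_point(spec: SensorSpec, phantom: VoxelPhantom) -> tuple[int, int, int]:
    """Voxel index of a point sensor, snapping into a named tissue if asked."""
    try:
        idx = phantom.index_of(spec.position)
    except InvalidInputError as exc:
        raise SensorPlacementError(f"sensor {spec.name!r}: {exc}") from exc
    if spec.snap_to_tissue is None:
        return idx
    wanted = 0 if spec.snap_to_tissue == "air" else TISSUE_IDS[spec.snap_to_tissue]
    i, j, k = idx
    nx = phantom.labels.shape[0]
    for di in (0, 1, -1, 2, -2, 3, -3):
        ii = i + di
        if 0 <= ii < nx and phantom.labels[ii, j, k] == wanted:
            return (ii, j, k)
    raise SensorPlacementError(
        f"sensor {spec.name!r}: no {spec.snap_to_tissue} voxel near index {idx}"
    )


def resolve_plane(spec: SensorSpec, phantom: VoxelPhantom) -> tuple[int, int]:
    axis = spec.plane_axis
    idx = int(math.floor((spec.plane_offset - phantom.origin[axis]) / phantom.spacing))
    if not (0 <= idx < phantom.labels.shape[axis]):
        raise SensorPlacementError(
            f"sensor {spec.name!r}: plane offset {spec.plane_offset} outside the grid"
        )
    return axis, idx


def default_ear_sensors(spec: EarGeometrySpec) -> list[SensorSpec]:
    """The default ear sensor inventory (18 sensor objects).

    Two canal point sensors (entrance and 20 mm), four planar sensors
    (transverse at 20 mm, longitudinal bisection, membrane surface,
    0.03 mm inside the membrane), a six-point array just inside the
    membrane at the epidermis/fibrous junction and a matching six-point
    array 0.02 mm beyond the membrane in the middle ear.  Positions are
    derived from the geometry spec alone (canal axis +x).
    """
    a = spec.canal_radius_horizontal
    b = spec.canal_radius_vertical
    b_wide = b * (1.0 + spec.inferior_widening)
    yc = a + spec.lateral_padding
    zc = b_wide + spec.lateral_padding
    x_mouth = spec.front_air
    x_membrane = x_mouth + spec.canal_depth
    tilt = math.radians(spec.tm_tilt_deg)
    depth_20mm = min(20e-3, 0.8 * spec.canal_depth)
    in_depth = sum(
        spec.layer_thicknesses[k] for k in ("stratum_corneum", "epidermis")
    )  # nominal 0.03 mm: the epidermis/fibrous junction
    total = sum(spec.layer_thicknesses.values())

    sensors: list[SensorSpec] = [
        SensorSpec("canal_entrance", "point", position=(x_mouth + 5e-4, yc, zc)),
        SensorSpec("canal_20mm", "point", position=(x_mouth + depth_20mm, yc, zc)),
        SensorSpec("plane_20mm", "planar", plane_axis=0, plane_offset=x_mouth + depth_20mm),
        SensorSpec("plane_longitudinal", "planar", plane_axis=1, plane_offset=yc),
        SensorSpec("plane_membrane_surface", "planar", plane_axis=0,
                   plane_offset=x_membrane - 1e-6),
        SensorSpec("plane_in_membrane", "planar", plane_axis=0,
                   plane_offset=x_membrane + in_depth),
    ]
    for n, (fy, fz) in enumerate(ARRAY_OFFSETS):
        y0, z0 = fy * a, fz * b
        s = in_depth + 0.5 * spec.layer_thicknesses["fibrous_tissue"]
        pos = (
            x_membrane - z0 * math.tan(tilt) + s * math.cos(tilt),
            yc + y0,
            zc + z0 + s * math.sin(tilt),
        )
        sensors.append(
            SensorSpec(f"tm_array_{n}", "point", position=pos,
                       snap_to_tissue="fibrous_tissue")
        )
    for n, (fy, fz) in enumerate(ARRAY_OFFSETS):
        y0, z0 = fy * a, fz * b
        s = total + 2e-5
        pos = (
            x_membrane - z0 * math.tan(tilt) + s * math.cos(tilt),
            yc + y0,
            zc + z0 + s * math.sin(tilt),
        )
        sensors.append(
            SensorSpec(f"me_array_{n}", "point", position=pos, snap_to_tissue="air")
        )
    return sensors


def membrane_array_sensors(phantom: VoxelPhantom) -> list[SensorSpec]:
    """Six-point in-membrane array for an already-built phantom.

    Uses the phantom's effective (possibly voxel-inflated) layer bins
    so the sensors land in the fibrous layer at any build resolution.
    """
    meta = phantom.meta
    spec: EarGeometrySpec = meta["spec"]
    yc, zc = meta["canal_center_yz"]
    x_membrane = meta["x_membrane"]
    tilt = meta["tilt_rad"]
    bins = dict((name, (lo, hi)) for name, lo, hi in meta["membrane_layer_bins"])
    lo, hi = bins["fibrous_tissue"]
    # epidermis/fibrous junction: first fibrous voxel below the epidermis
    s = lo + 0.5 * phantom.spacing
    a = spec.canal_radius_horizontal
    b = spec.canal_radius_vertical
    out = []
    for n, (fy, fz) in enumerate(ARRAY_OFFSETS):
        y0, z0 = fy * a, fz * b
        pos = (
            x_membrane - z0 * math.tan(tilt) + s * math.cos(tilt),
            yc + y0,
            zc + z0 + s * math.sin(tilt),
        )
        out.append(SensorSpec(f"tm_array_{n}", "point", position=pos,
                              snap_to_tissue="fibrous_tissue"))
    return out


def middle_ear_array_sensors(phantom: VoxelPhantom, gap: float = 2e-5) -> list[SensorSpec]:
    """Matching six-point array just past the membrane in the middle ear."""
    meta = phantom.meta
    spec: EarGeometrySpec = meta["spec"]
    yc, zc = meta["canal_center_yz"]
    x_membrane = meta["x_membrane"]
    tilt = meta["tilt_rad"]
    s = meta["membrane_total_thickness"] + gap + phantom.spacing
    a = spec.canal_radius_horizontal
    b = spec.canal_radius_vertical
    out = []
    for n, (fy, fz) in enumerate(ARRAY_OFFSETS):
        y0, z0 = fy * a, fz * b
        pos = (
            x_membrane - z0 * math.tan(tilt) + s * math.cos(tilt),
            yc + y0,
            zc + z0 + s * math.sin(tilt),
        )
        out.append(SensorSpec(f"me_array_{n}", "point", position=pos, snap_to_tissue="air"))
    return out
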