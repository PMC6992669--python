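"""Simplified voxel phantom of the outer ear and canal analytics.

The phantom is a labelled 3-D grid: an elliptical air-filled canal
(narrow horizontally, wider vertically, with a configurable inferior
widening near its deep end) carved through a bone/cartilage block,
lined with stratum corneum over epidermis, and closed at its deep end
by a tilted four-layer tympanic membrane (stratum corneum, epidermis,
fibrous lamina, mucosa).  Behind the membrane lies a small air-filled
middle-ear cavity and then an absorptive bone/cartilage baffle.
Rounded bone/cartilage blocks in front of the entrance stand in for
the tragus, antitragus and antihelix of the pinna; their true
dimensions are not anatomically constrained here, so they are
configurable parameters.

Coordinate convention: 0-based voxel indices; voxel (i, j, k) spans
the half-open box [origin + i*spacing, origin + (i+1)*spacing) per
axis; the canal axis is +x (into the head), anterior is +y and
superior is +z.  Tissue label 0 is air.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.constants import c as C0

from .errors import InvalidGeometryError, InvalidInputError

AIR_ID = 0

TISSUE_IDS = {
    "bone_cartilage": 1,
    "dermis": 2,
    "epidermis": 3,
    "stratum_corneum": 4,
    "fibrous_tissue": 5,
    "mucous_membrane": 6,
}
ID_TO_TISSUE = {v: k for k, v in TISSUE_IDS.items()}

MEMBRANE_LAYER_ORDER = ("stratum_corneum", "epidermis", "fibrous_tissue", "mucous_membrane")


# ---------------------------------------------------------------------------
# Closed-form canal analytics
# ---------------------------------------------------------------------------

def waveguide_cutoff(radius: float, wave_speed: float = C0) -> float:
    """TE11 cutoff frequency of a cylindrical guide: 1.841*C/(2*pi*a), Hz."""
    if radius <= 0:
        raise InvalidInputError(f"radius must be > 0, got {radius}")
    return 1.841 * wave_speed / (2.0 * math.pi * radius)


def diffraction_first_minimum(wavelength: float, distance: float, aperture_radius: float) -> float:
    """Width of the first-order diffraction minimum, Y = lambda*D/(2*R), m."""
    if wavelength <= 0 or distance <= 0 or aperture_radius <= 0:
        raise InvalidInputError("wavelength, distance and aperture_radius must all be > 0")
    return wavelength * distance / (2.0 * aperture_radius)


# ---------------------------------------------------------------------------
# Geometry specification
# ---------------------------------------------------------------------------

def _default_layers() -> dict[str, float]:
    return {
        "stratum_corneum": 1e-5,
        "epidermis": 2e-5,
        "fibrous_tissue": 8e-5,
        "mucous_membrane": 4e-5,
    }


@dataclass
class PinnaBlock:
    """Rounded (ellipsoidal) bone/cartilage block in front of the entrance.

    ``center`` is (x, y, z) in metres relative to the canal-mouth
    centre; ``semi_axes`` are the ellipsoid semi-axes in metres.
    """

    name: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]


def _default_pinna(scale: float = 10e-3) -> list[PinnaBlock]:
    s = scale
    return [
        PinnaBlock("tragus", (-0.15 * s, -0.55 * s, 0.0), (0.25 * s, 0.35 * s, 0.5 * s)),
        PinnaBlock("antitragus", (-0.15 * s, 0.55 * s, -0.35 * s), (0.25 * s, 0.35 * s, 0.4 * s)),
        PinnaBlock("antihelix", (-0.15 * s, 0.35 * s, 0.6 * s), (0.25 * s, 0.5 * s, 0.35 * s)),
    ]


@dataclass
class EarGeometrySpec:
    """Parametric description of the simplified ear model.

    Defaults are the adult-ear dimensions the phantom is built around:
    a 3.5 mm (horizontal) by 4.5 mm (vertical) elliptical canal, 25 mm
    deep, closed by a four-layer membrane tilted 25 deg from its
    superior margin, with a 10 % inferior widening of the canal at the
    membrane.  The mucosal layer is deliberately thicker than anatomy
    (0.04 mm) to stand in for the wet mucous film on the inner surface.
    """

    canal_radius_horizontal: float = 3.5e-3
    canal_radius_vertical: float = 4.5e-3
    canal_depth: float = 25e-3
    tm_tilt_deg: float = 25.0
    layer_thicknesses: dict[str, float] = field(default_factory=_default_layers)
    lining_sc_thickness: float = 1.0e-4
    lining_epidermis_thickness: float = 2.0e-5
    inferior_widening: float = 0.10
    pinna_scale: float = 10e-3
    pinna_enabled: bool = True
    baffle: bool = True
    front_air: float = 4e-3
    middle_ear_depth: float = 3e-3
    baffle_depth: float = 3e-3
    lateral_padding: float = 3e-3

    def __post_init__(self):
        for name, val in (
            ("canal_radius_horizontal", self.canal_radius_horizontal),
            ("canal_radius_vertical", self.canal_radius_vertical),
            ("canal_depth", self.canal_depth),
        ):
            if val <= 0:
                raise InvalidInputError(f"{name} must be > 0, got {val}")
        if not (0.0 <= self.tm_tilt_deg <= 45.0):
            raise InvalidInputError(f"tm_tilt_deg must be in [0, 45], got {self.tm_tilt_deg}")
        if any(t <= 0 for t in self.layer_thicknesses.values()):
            raise InvalidInputError("membrane layer thicknesses must all be > 0")
        if sum(self.layer_thicknesses.values()) >= self.canal_depth:
            raise InvalidInputError("membrane layer sum must be smaller than the canal depth")

    def pinna_blocks(self) -> list[PinnaBlock]:
        return _default_pinna(self.pinna_scale) if self.pinna_enabled else []


# ---------------------------------------------------------------------------
# Voxel phantom container
# ---------------------------------------------------------------------------

@dataclass
class VoxelPhantom:
    """Labelled voxel grid with explicit spacing and origin.

    ``labels`` is a uint8 array indexed (x, y, z); ``palette`` maps
    label id -> tissue name (0 = air).  ``meta`` carries the geometry
    bookkeeping downstream consumers need to place sensors (canal mouth
    position, membrane plane, effective layer bins).
    """

    labels: np.ndarray
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    palette: dict[int, str] = field(default_factory=lambda: {AIR_ID: "air", **ID_TO_TISSUE})
    meta: dict = field(default_factory=dict)

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)

    def voxel_center(self, index: tuple[int, int, int]) -> tuple[float, float, float]:
        return tuple(self.origin[a] + (index[a] + 0.5) * self.spacing for a in range(3))

    def index_of(self, position: tuple[float, float, float]) -> tuple[int, int, int]:
        idx = tuple(int(math.floor((position[a] - self.origin[a]) / self.spacing)) for a in range(3))
        for a in range(3):
            if not (0 <= idx[a] < self.labels.shape[a]):
                raise InvalidInputError(f"position {position} outside the phantom grid")
        return idx

    def tissue_volume(self, tissue: str) -> float:
        """Total volume of a tissue (or 'air') in m^3."""
        wanted = AIR_ID if tissue == "air" else TISSUE_IDS[tissue]
        return float(np.count_nonzero(self.labels == wanted)) * self.spacing**3

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("labels", data=self.labels, compression="gzip")
            f.attrs["spacing"] = self.spacing
            f.attrs["origin"] = self.origin
            pal = f.create_group("palette")
            for k, v in self.palette.items():
                pal.attrs[str(k)] = v

    @classmethod
    def load_hdf5(cls, path) -> "VoxelPhantom":
        import h5py

        with h5py.File(path, "r") as f:
            labels = f["labels"][...]
            spacing = float(f.attrs["spacing"])
            origin = tuple(float(v) for v in f.attrs["origin"])
            palette = {int(k): str(v) for k, v in f["palette"].attrs.items()}
        return cls(labels=labels, spacing=spacing, origin=origin, palette=palette)

    def save_png_slices(self, directory, axis: int = 1, stride: int = 1) -> list[str]:
        """Write greyscale PNG slices of the label grid for inspection."""
        from pathlib import Path

        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        n = self.labels.shape[axis]
        for i in range(0, n, stride):
            sl = np.take(self.labels, i, axis=axis)
            out = directory / f"slice_axis{axis}_{i:04d}.png"
            plt.imsave(out, sl.T, cmap="viridis", vmin=0, vmax=max(TISSUE_IDS.values()))
            written.append(str(out))
        return written


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def build_ear_phantom(spec: EarGeometrySpec, spacing: float) -> VoxelPhantom:
    """Voxelise the ear geometry at a uniform spacing.

    Layers thinner than one voxel are inflated to one voxel (with a
    warning); the effective layer extents actually built are recorded
    in ``phantom.meta['membrane_layer_bins']``.
    """
    if spacing <= 0:
        raise InvalidGeometryError(f"spacing must be > 0, got {spacing}")

    a = spec.canal_radius_horizontal
    b = spec.canal_radius_vertical
    tilt = math.radians(spec.tm_tilt_deg)

    # effective (>= 1 voxel) membrane layer extents along the membrane normal
    bins: list[tuple[str, float, float]] = []
    s0 = 0.0
    for name in MEMBRANE_LAYER_ORDER:
        t_nominal = spec.layer_thicknesses[name]
        t_eff = max(t_nominal, spacing)
        if t_eff > t_nominal:
            warnings.warn(
                f"membrane layer {name} ({t_nominal * 1e3:.3g} mm) thinner than one voxel; "
                f"inflated to {t_eff * 1e3:.3g} mm",
                stacklevel=2,
            )
        bins.append((name, s0, s0 + t_eff))
        s0 += t_eff
    membrane_total = s0

    x_mouth = spec.front_air
    x_membrane = x_mouth + spec.canal_depth
    membrane_x_extent = membrane_total / math.cos(tilt) + 1.2 * b * math.tan(tilt)
    x_end_carve = x_membrane + membrane_x_extent + spec.middle_ear_depth
    len_x = x_end_carve + spec.baffle_depth
    b_wide = b * (1.0 + spec.inferior_widening)
    len_y = 2.0 * (a + spec.lateral_padding)
    len_z = 2.0 * (b_wide + spec.lateral_padding)

    nx = int(math.ceil(len_x / spacing))
    ny = int(math.ceil(len_y / spacing))
    nz = int(math.ceil(len_z / spacing))
    if min(nx, ny, nz) < 4:
        raise InvalidGeometryError("requested geometry does not fit the voxel grid")

    yc = ny * spacing / 2.0
    zc = nz * spacing / 2.0

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)

    xs = (np.arange(nx) + 0.5) * spacing
    ys = (np.arange(ny) + 0.5) * spacing - yc
    zs = (np.arange(nz) + 0.5) * spacing - zc

    # solid bone/cartilage block from the entrance plane inward
    i_mouth = int(round(x_mouth / spacing))
    labels[i_mouth:, :, :] = TISSUE_IDS["bone_cartilage"]

    # carve the canal lumen (with inferior widening ramp near the membrane)
    ramp_start = x_mouth + 0.75 * spec.canal_depth
    ramp_len = 0.25 * spec.canal_depth
    y2 = (ys[None, :, None] / a) ** 2
    for i in range(i_mouth, nx):
        x = xs[i]
        if x >= x_end_carve:
            break
        ramp = min(max((x - ramp_start) / ramp_len, 0.0), 1.0)
        b_inf = b * (1.0 + spec.inferior_widening * ramp)
        bz = np.where(zs < 0.0, b_inf, b)
        inside = (y2[0] + (zs[None, :] / bz[None, :]) ** 2) <= 1.0
        labels[i][inside] = AIR_ID

    # canal-wall lining: stratum corneum facing the lumen, epidermis beneath
    n_sc = max(1, int(round(spec.lining_sc_thickness / spacing)))
    n_epi = max(1, int(round(spec.lining_epidermis_thickness / spacing)))
    i_memb = int(round(x_membrane / spacing))
    canal_range = slice(i_mouth, i_memb)
    air_mask = labels[canal_range] == AIR_ID
    bone_mask = labels[canal_range] == TISSUE_IDS["bone_cartilage"]
    sc_shell = ndimage.binary_dilation(air_mask, iterations=n_sc) & bone_mask
    labels[canal_range][sc_shell] = TISSUE_IDS["stratum_corneum"]
    epi_shell = (
        ndimage.binary_dilation(air_mask | sc_shell, iterations=n_epi)
        & (labels[canal_range] == TISSUE_IDS["bone_cartilage"])
    )
    labels[canal_range][epi_shell] = TISSUE_IDS["epidermis"]

    # tilted four-layer membrane closing the canal: signed distance along the
    # membrane normal, s = (x - x_m) cos(tilt) + (z - z_c) sin(tilt);
    # superior margin (+z) sits closer to the entrance, i.e. it reaches s = 0
    # at smaller x, sloping inward below.
    b_memb = b * (1.0 + spec.inferior_widening)
    i0 = int(math.floor((x_membrane - 1.2 * b * math.tan(tilt)) / spacing))
    i1 = int(math.ceil((x_membrane + membrane_x_extent) / spacing))
    for i in range(max(i0, i_mouth), min(i1 + 1, nx)):
        x = xs[i]
        s = (x - x_membrane) * math.cos(tilt) + zs[None, :] * math.sin(tilt)
        ellipse = (y2[0] + (zs[None, :] / np.where(zs[None, :] < 0, b_memb, b)) ** 2) <= 1.0
        sl = labels[i]
        lumen_like = ellipse & ((sl == AIR_ID) | (sl == TISSUE_IDS["stratum_corneum"]))
        for name, lo, hi in bins:
            sel = lumen_like & (s >= lo) & (s < hi)
            sl[sel] = TISSUE_IDS[name]

    meta = {
        "spec": spec,
        "x_mouth": x_mouth,
        "x_membrane": x_membrane,
        "canal_center_yz": (yc, zc),
        "membrane_layer_bins": bins,
        "membrane_total_thickness": membrane_total,
        "tilt_rad": tilt,
        "middle_ear_x_range": (x_membrane + membrane_x_extent, x_end_carve),
    }
    return VoxelPhantom(labels=labels, spacing=spacing, meta=meta)


def _add_pinna(labels: np.ndarray, spec: EarGeometrySpec, spacing: float,
               mouth_center: tuple[float, float, float]) -> None:
    nx, ny, nz = labels.shape
    xs = (np.arange(nx) + 0.5) * spacing
    ys = (np.arange(ny) + 0.5) * spacing
    zs = (np.arange(nz) + 0.5) * spacing
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij", sparse=True)
    for blk in spec.pinna_blocks():
        cx = mouth_center[0] + blk.center[0]
        cy = mouth_center[1] + blk.center[1]
        cz = mouth_center[2] + blk.center[2]
        r2 = (
            ((X - cx) / blk.semi_axes[0]) ** 2
            + ((Y - cy) / blk.semi_axes[1]) ** 2
            + ((Z - cz) / blk.semi_axes[2]) ** 2
        )
        labels[(r2 <= 1.0) & (labels == AIR_ID)] = TISSUE_IDS["bone_cartilage"]


def build_ear_phantom_with_pinna(spec: EarGeometrySpec, spacing: float) -> VoxelPhantom:
    """Phantom including the parametric pinna blocks at the entrance."""
    ph = build_ear_phantom(spec, spacing)
    if spec.pinna_enabled:
        yc, zc = ph.meta["canal_center_yz"]
        _add_pinna(ph.labels, spec, spacing, (ph.meta["x_mouth"], yc, zc))
    return ph


def source_connected_air(phantom: VoxelPhantom) -> np.ndarray:
    """Mask of air voxels connected to the source (x = 0) face.

    The canal lumen up to the membrane belongs to this component; the
    middle-ear cavity behind the membrane does not (the membrane seals
    the canal), which is the intended topology.
    """
    air = phantom.labels == AIR_ID
    labelled, _ = ndimage.label(air)
    front_labels = np.unique(labelled[0][air[0]])
    mask = np.isin(labelled, front_labels[front_labels > 0])
    return mask
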