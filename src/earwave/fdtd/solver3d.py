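"""Three-dimensional Yee solver with CPML boundaries and plane-wave injection.

The solver runs a narrowband material model: each run evaluates every
tissue's relative permittivity eps' and equivalent conductivity
sigma = eps0*eps''*omega at the run's carrier frequency (separate runs
per frequency, matching how multi-frequency exposure studies are set
up), so no dispersive update equations are needed.

Boundaries are convolutional PML (8 cells by default, cubic-graded
conductivity, kappa = 1) backed by PEC walls.  The incident pulse is
injected as a soft electric-field source on a full transverse plane;
oblique incidence is produced by a per-cell arrival-time gradient
across that plane (the wave-vector is rotated, never the phantom, so
sensor coordinates are angle-invariant).  The solver always runs at
the source's stated amplitude (1 V/m by default) and dosimetry
rescales post hoc by linearity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.constants import c as C0
from scipy.constants import epsilon_0 as EPS0
from scipy.constants import mu_0 as MU0

from ..dielectrics import TissueDielectricTable, conductivity_from_permittivity
from ..errors import InvalidInputError, SensorPlacementError, SolverInstabilityError
from ..phantom import VoxelPhantom
from .sensors import SensorRecord, SensorSpec, resolve_plane, resolve_point
from .sources import Incidence, PulseSource, courant_timestep


@dataclass
class SolverConfig:
    """Run configuration for the 3-D solver.

    ``total_steps=None`` lets the solver size the run to the pulse
    duration plus three grid transits.  The solver is deterministic:
    identical inputs give bit-identical outputs.
    """

    courant_fraction: float = 0.95
    total_steps: int | None = None
    pml_cells: int = 8
    boundary: str = "cpml"  # 'cpml' or 'pec'
    nan_check_interval: int = 100

    def __post_init__(self):
        if not (0 < self.courant_fraction <= 1.0):
            raise InvalidInputError("courant_fraction must be in (0, 1]")
        if self.boundary == "cpml" and self.pml_cells < 6:
            raise InvalidInputError("CPML needs at least 6 cells")


# ---------------------------------------------------------------------------
# CPML profiles
# ---------------------------------------------------------------------------

def _cpml_profiles(n: int, npml: int, dt: float, spacing: float, staggered: bool):
    """(b, c) recursive-convolution coefficients along one axis.

    Cubic-graded sigma, sigma_max = 0.8*(m+1)/(eta0*spacing), kappa=1.
    ``staggered`` selects the half-cell (H) positions.
    """
    m = 3.0
    eta0 = math.sqrt(MU0 / EPS0)
    sigma_max = 0.8 * (m + 1.0) / (eta0 * spacing)
    b = np.ones(n)
    c = np.zeros(n)
    for i in range(n):
        pos = i + (0.5 if staggered else 0.0)
        d_lo = npml - pos
        d_hi = pos - (n - 1 - npml)
        d = max(d_lo, d_hi)
        if d > 0:
            u = min(d / npml, 1.0)
            sg = sigma_max * u**m
            b[i] = math.exp(-sg * dt / EPS0)
            c[i] = b[i] - 1.0
    return b, c


# ---------------------------------------------------------------------------
# Update kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _update_h(ex, ey, ez, hx, hy, hz,
              phxy, phxz, phyz, phyx, phzx, phzy,
              bhx, chx, bhy, chy, bhz, chz, dhu):
    nx, ny, nz = ex.shape
    for i in range(nx - 1):
        for j in range(ny - 1):
            for k in range(nz - 1):
                dyez = ez[i, j + 1, k] - ez[i, j, k]
                dzey = ey[i, j, k + 1] - ey[i, j, k]
                phxy[i, j, k] = bhy[j] * phxy[i, j, k] + chy[j] * dyez
                phxz[i, j, k] = bhz[k] * phxz[i, j, k] + chz[k] * dzey
                hx[i, j, k] -= dhu * (dyez + phxy[i, j, k] - dzey - phxz[i, j, k])

                dzex = ex[i, j, k + 1] - ex[i, j, k]
                dxez = ez[i + 1, j, k] - ez[i, j, k]
                phyz[i, j, k] = bhz[k] * phyz[i, j, k] + chz[k] * dzex
                phyx[i, j, k] = bhx[i] * phyx[i, j, k] + chx[i] * dxez
                hy[i, j, k] -= dhu * (dzex + phyz[i, j, k] - dxez - phyx[i, j, k])

                dxey = ey[i + 1, j, k] - ey[i, j, k]
                dyex = ex[i, j + 1, k] - ex[i, j, k]
                phzx[i, j, k] = bhx[i] * phzx[i, j, k] + chx[i] * dxey
                phzy[i, j, k] = bhy[j] * phzy[i, j, k] + chy[j] * dyex
                hz[i, j, k] -= dhu * (dxey + phzx[i, j, k] - dyex - phzy[i, j, k])


@njit(cache=True)
def _update_e(ex, ey, ez, hx, hy, hz, ca, cb,
              pexy, pexz, peyz, peyx, pezx, pezy,
              bex, cex, bey, cey, bez, cez, inv_d):
    nx, ny, nz = ex.shape
    for i in range(nx - 1):
        for j in range(1, ny - 1):
            for k in range(1, nz - 1):
                dyhz = hz[i, j, k] - hz[i, j - 1, k]
                dzhy = hy[i, j, k] - hy[i, j, k - 1]
                pexy[i, j, k] = bey[j] * pexy[i, j, k] + cey[j] * dyhz
                pexz[i, j, k] = bez[k] * pexz[i, j, k] + cez[k] * dzhy
                ex[i, j, k] = ca[i, j, k] * ex[i, j, k] + cb[i, j, k] * inv_d * (
                    dyhz + pexy[i, j, k] - dzhy - pexz[i, j, k]
                )
    for i in range(1, nx - 1):
        for j in range(ny - 1):
            for k in range(1, nz - 1):
                dzhx = hx[i, j, k] - hx[i, j, k - 1]
                dxhz = hz[i, j, k] - hz[i - 1, j, k]
                peyz[i, j, k] = bez[k] * peyz[i, j, k] + cez[k] * dzhx
                peyx[i, j, k] = bex[i] * peyx[i, j, k] + cex[i] * dxhz
                ey[i, j, k] = ca[i, j, k] * ey[i, j, k] + cb[i, j, k] * inv_d * (
                    dzhx + peyz[i, j, k] - dxhz - peyx[i, j, k]
                )
    for i in range(1, nx - 1):
        for j in range(1, ny - 1):
            for k in range(nz - 1):
                dxhy = hy[i, j, k] - hy[i - 1, j, k]
                dyhx = hx[i, j, k] - hx[i, j - 1, k]
                pezx[i, j, k] = bex[i] * pezx[i, j, k] + cex[i] * dxhy
                pezy[i, j, k] = bey[j] * pezy[i, j, k] + cey[j] * dyhx
                ez[i, j, k] = ca[i, j, k] * ez[i, j, k] + cb[i, j, k] * inv_d * (
                    dxhy + pezx[i, j, k] - dyhx - pezy[i, j, k]
                )


# ---------------------------------------------------------------------------
# Plane-wave injection
# ---------------------------------------------------------------------------

def plane_wave_delays(incidence: Incidence, ys: np.ndarray, zs: np.ndarray) -> np.ndarray:
    """Arrival-time offsets (s) across the source aperture.

    ``ys``/``zs`` are coordinates (m) relative to the aperture centre;
    the returned (ny, nz) array is shifted so its minimum is zero.
    """
    _, ky, kz = incidence.wave_vector
    delays = (ky * ys[:, None] + kz * zs[None, :]) / C0
    return delays - delays.min()


def _material_arrays(phantom: VoxelPhantom, materials: TissueDielectricTable,
                     frequency: float):
    labels = phantom.labels
    n_ids = int(labels.max()) + 1
    eps_lut = np.ones(n_ids)
    sig_lut = np.zeros(n_ids)
    for tid in np.unique(labels):
        name = phantom.palette[int(tid)]
        if name == "air":
            continue
        eps = materials.get(name, frequency)
        eps_lut[tid] = eps.eps_real
        sig_lut[tid] = conductivity_from_permittivity(eps.eps_imag, frequency)
    return eps_lut[labels], sig_lut[labels]


def run_fdtd(
    phantom: VoxelPhantom,
    materials: TissueDielectricTable | None,
    source: PulseSource,
    sensors: list[SensorSpec],
    config: SolverConfig | None = None,
) -> list[SensorRecord]:
    """Run a pulsed plane-wave exposure on a voxel phantom.

    Parameters
    ----------
    phantom : VoxelPhantom
        Labelled grid (label 0 = air).  ``materials`` may be None for
        an all-air phantom (free-space reference runs).
    source : PulseSource
        Carrier, envelope and incidence angle; injected as a soft
        plane source just inside the -x boundary.
    sensors : list of SensorSpec
        Resolved against the phantom; a sensor outside the grid raises
        :class:`SensorPlacementError` naming the sensor.

    Returns
    -------
    list of SensorRecord, in the order of ``sensors``.
    """
    config = config or SolverConfig()
    spacing = phantom.spacing
    nx, ny, nz = phantom.labels.shape
    dt = courant_timestep(spacing, config.courant_fraction)

    if materials is None:
        if phantom.labels.any():
            raise InvalidInputError("materials required for a non-air phantom")
        eps_r = np.ones((nx, ny, nz))
        sigma = np.zeros((nx, ny, nz))
    else:
        eps_r, sigma = _material_arrays(phantom, materials, source.carrier)

    eps = eps_r * EPS0
    loss = sigma * dt / (2.0 * eps)
    ca = ((1.0 - loss) / (1.0 + loss)).astype(np.float64)
    cb = ((dt / eps) / (1.0 + loss)).astype(np.float64)
    inv_d = 1.0 / spacing
    dhu = dt / (MU0 * spacing)

    npml = config.pml_cells if config.boundary == "cpml" else 0
    if config.boundary == "cpml":
        bex, cex = _cpml_profiles(nx, npml, dt, spacing, staggered=False)
        bey, cey = _cpml_profiles(ny, npml, dt, spacing, staggered=False)
        bez, cez = _cpml_profiles(nz, npml, dt, spacing, staggered=False)
        bhx, chx = _cpml_profiles(nx, npml, dt, spacing, staggered=True)
        bhy, chy = _cpml_profiles(ny, npml, dt, spacing, staggered=True)
        bhz, chz = _cpml_profiles(nz, npml, dt, spacing, staggered=True)
    else:
        bex = bey = bez = bhx = bhy = bhz = np.ones(max(nx, ny, nz))
        cex = cey = cez = chx = chy = chz = np.zeros(max(nx, ny, nz))
        bex, cex = np.ones(nx), np.zeros(nx)
        bey, cey = np.ones(ny), np.zeros(ny)
        bez, cez = np.ones(nz), np.zeros(nz)
        bhx, chx = np.ones(nx), np.zeros(nx)
        bhy, chy = np.ones(ny), np.zeros(ny)
        bhz, chz = np.ones(nz), np.zeros(nz)

    shape = (nx, ny, nz)
    ex, ey, ez = (np.zeros(shape) for _ in range(3))
    hx, hy, hz = (np.zeros(shape) for _ in range(3))
    psi_e = [np.zeros(shape) for _ in range(6)]
    psi_h = [np.zeros(shape) for _ in range(6)]

    # source plane just inside the -x PML
    i_src = npml + 3
    if i_src >= nx - npml - 2:
        raise InvalidInputError("grid too small along x for the source plane")
    ys = (np.arange(ny) + 0.5) * spacing
    zs = (np.arange(nz) + 0.5) * spacing
    yc, zc = phantom.meta.get("canal_center_yz", (ny * spacing / 2, nz * spacing / 2))
    delays = plane_wave_delays(source.incidence, ys - yc, zs - zc)
    pol = source.incidence.polarization
    e_plane = ez if pol[2] else ey

    if config.total_steps is None:
        transit = nx * spacing * 3.0 / C0
        n_steps = int((source.envelope_duration + transit) / dt)
    else:
        n_steps = int(config.total_steps)

    # resolve sensors up front so placement errors surface before the run
    point_specs = [s for s in sensors if s.kind == "point"]
    plane_specs = [s for s in sensors if s.kind == "planar"]
    point_idx = [resolve_point(s, phantom) for s in point_specs]
    plane_loc = [resolve_plane(s, phantom) for s in plane_specs]
    pt_e = np.zeros((len(point_specs), n_steps, 3))
    pt_h = np.zeros((len(point_specs), n_steps, 3))
    peak_maps = []
    plane_center_series = []
    plane_center_idx = []
    for (axis, idx), spec in zip(plane_loc, plane_specs):
        shp = tuple(s for a, s in enumerate(shape) if a != axis)
        peak_maps.append(np.zeros(shp))
        plane_center_series.append(np.zeros(n_steps))
        center = [s // 2 for s in shape]
        center[axis] = idx
        plane_center_idx.append(tuple(center))

    t0 = source.center_time
    sg = source.envelope_sigma
    w = 2.0 * math.pi * source.carrier
    amp = source.amplitude

    for step in range(n_steps):
        _update_h(ex, ey, ez, hx, hy, hz, *psi_h, bhx, chx, bhy, chy, bhz, chz, dhu)
        _update_e(ex, ey, ez, hx, hy, hz, ca, cb, *psi_e,
                  bex, cex, bey, cey, bez, cez, inv_d)
        t = (step + 1) * dt
        targ = t - delays - t0
        e_plane[i_src, :, :] += amp * np.exp(-(targ**2) / (2.0 * sg**2)) * np.cos(w * targ)

        for n_p, (i, j, k) in enumerate(point_idx):
            pt_e[n_p, step, 0] = ex[i, j, k]
            pt_e[n_p, step, 1] = ey[i, j, k]
            pt_e[n_p, step, 2] = ez[i, j, k]
            pt_h[n_p, step, 0] = hx[i, j, k]
            pt_h[n_p, step, 1] = hy[i, j, k]
            pt_h[n_p, step, 2] = hz[i, j, k]
        for n_pl, (axis, idx) in enumerate(plane_loc):
            exs = np.take(ex, idx, axis=axis)
            eys = np.take(ey, idx, axis=axis)
            ezs = np.take(ez, idx, axis=axis)
            emag = np.sqrt(exs**2 + eys**2 + ezs**2)
            np.maximum(peak_maps[n_pl], emag, out=peak_maps[n_pl])
            ci, cj, ck = plane_center_idx[n_pl]
            plane_center_series[n_pl][step] = math.sqrt(
                ex[ci, cj, ck] ** 2 + ey[ci, cj, ck] ** 2 + ez[ci, cj, ck] ** 2
            )

        if (step + 1) % config.nan_check_interval == 0:
            if not np.isfinite(ez[nx // 2, ny // 2, nz // 2]) or not np.all(
                np.isfinite(ez[::8, ::8, ::8])
            ):
                raise SolverInstabilityError(step)

    records: list[SensorRecord] = []
    for spec in sensors:
        if spec.kind == "point":
            n_p = point_specs.index(spec)
            e_mag = np.sqrt(np.sum(pt_e[n_p] ** 2, axis=1))
            h_mag = np.sqrt(np.sum(pt_h[n_p] ** 2, axis=1))
            records.append(
                SensorRecord(
                    name=spec.name, kind="point", timestep=dt,
                    e_series=e_mag, h_series=h_mag,
                    e_components=pt_e[n_p], h_components=pt_h[n_p],
                    location=point_idx[n_p], source_amplitude=amp,
                )
            )
        else:
            n_pl = plane_specs.index(spec)
            records.append(
                SensorRecord(
                    name=spec.name, kind="planar", timestep=dt,
                    e_series=plane_center_series[n_pl],
                    peak_map=peak_maps[n_pl],
                    location=plane_loc[n_pl], source_amplitude=amp,
                )
            )
    if not all(np.all(np.isfinite(r.e_series)) for r in records):
        raise SolverInstabilityError(n_steps - 1)
    return records


def save_records_hdf5(records: list[SensorRecord], path) -> None:
    """Write sensor records to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        for rec in records:
            g = f.create_group(rec.name)
            g.attrs["kind"] = rec.kind
            g.attrs["timestep"] = rec.timestep
            g.attrs["source_amplitude"] = rec.source_amplitude or np.nan
            g.create_dataset("e_series", data=rec.e_series)
            if rec.h_series is not None:
                g.create_dataset("h_series", data=rec.h_series)
            if rec.peak_map is not None:
                g.create_dataset("peak_map", data=rec.peak_map)
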