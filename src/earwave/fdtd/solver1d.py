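"""One-dimensional Yee solver for lossy layered media.

Used for the analytic cross-checks that anchor the 3-D solver: carrier
reflectance/transmittance of layered stacks against the
transfer-matrix oracle, exponential decay in a lossy half-space
against the penetration depth, free-space pulse speed and lossless
cavity energy conservation.

Fields are Ez at integer nodes and Hy at half nodes; materials
(relative permittivity and conductivity) are sampled at the Ez nodes.
Reflected waves are separated from the incident by linearity: the same
soft source is run on the empty (all-air) grid and subtracted, so no
total-field/scattered-field bookkeeping is needed in 1-D.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numba import njit
from scipy.constants import c as C0
from scipy.constants import epsilon_0 as EPS0
from scipy.constants import mu_0 as MU0

from ..dielectrics import ComplexPermittivity, refractive_index, transfer_matrix_stack
from ..errors import InvalidInputError, SolverInstabilityError


@njit(cache=True)
def _run_1d(ez, hy, ca, cb, dh, src, src_idx, sensor_idx, out, mur_coeff, pec):
    n = ez.shape[0]
    n_steps = src.shape[0]
    for step in range(n_steps):
        # H update (half nodes 0..n-2)
        for i in range(n - 1):
            hy[i] += dh * (ez[i + 1] - ez[i])
        # E update (interior nodes)
        ez_left = ez[1]
        ez_right = ez[n - 2]
        for i in range(1, n - 1):
            ez[i] = ca[i] * ez[i] + cb[i] * (hy[i] - hy[i - 1])
        if pec:
            ez[0] = 0.0
            ez[n - 1] = 0.0
        else:
            # first-order Mur absorbing ends
            ez[0] = ez_left + mur_coeff * (ez[1] - ez[0])
            ez[n - 1] = ez_right + mur_coeff * (ez[n - 2] - ez[n - 1])
        ez[src_idx] += src[step]
        for s in range(sensor_idx.shape[0]):
            out[s, step] = ez[sensor_idx[s]]


def run_fdtd_1d(
    eps_r: np.ndarray,
    sigma: np.ndarray,
    spacing: float,
    dt: float,
    source_values: np.ndarray,
    source_index: int,
    sensor_indices: Sequence[int],
    boundary: str = "mur",
) -> np.ndarray:
    """Run the 1-D solver and return Ez time series at the sensors.

    Parameters
    ----------
    eps_r, sigma : arrays of length n
        Relative permittivity and conductivity (S/m) at the Ez nodes.
    spacing, dt : float
        Cell size (m) and timestep (s); dt must satisfy dt <= dx/c.
    source_values : array of length n_steps
        Additive (soft) source applied to Ez at ``source_index``.
    boundary : 'mur' or 'pec'

    Returns
    -------
    (n_sensors, n_steps) array of Ez in V/m.  Deterministic;
    raises :class:`SolverInstabilityError` on non-finite fields.
    """
    eps_r = np.asarray(eps_r, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    n = eps_r.shape[0]
    if sigma.shape[0] != n:
        raise InvalidInputError("eps_r and sigma must have equal length")
    if dt > spacing / C0 * (1.0 + 1e-12):
        raise InvalidInputError("dt violates the 1-D Courant bound dx/c")
    eps = eps_r * EPS0
    loss = sigma * dt / (2.0 * eps)
    ca = (1.0 - loss) / (1.0 + loss)
    cb = (dt / (eps * spacing)) / (1.0 + loss)
    dh = dt / (MU0 * spacing)
    mur_coeff = (C0 * dt - spacing) / (C0 * dt + spacing)

    ez = np.zeros(n)
    hy = np.zeros(n - 1)
    src = np.asarray(source_values, dtype=np.float64)
    sensors = np.asarray(sensor_indices, dtype=np.int64)
    out = np.empty((sensors.shape[0], src.shape[0]))
    _run_1d(ez, hy, ca, cb, dh, src, int(source_index), sensors, out,
            mur_coeff, boundary == "pec")
    if not np.all(np.isfinite(out)):
        bad = np.argwhere(~np.isfinite(out))
        raise SolverInstabilityError(int(bad[0, 1]))
    return out


def _dft_at(series: np.ndarray, dt: float, frequency: float) -> complex:
    t = np.arange(series.shape[0]) * dt
    return complex(np.sum(series * np.exp(-2j * math.pi * frequency * t)) * dt)


def _stack_grid(
    layers: Sequence[tuple[ComplexPermittivity, float]],
    frequency: float,
    spacing: float,
    pad_cells: int,
):
    """Node-based material arrays for [air | stack | air] with the stack
    voxelised to whole cells; returns (eps_r, sigma, i_front, i_back, cells)."""
    cells = []
    for eps, d in layers:
        n_cells = max(1, int(round(d / spacing)))
        omega = 2.0 * math.pi * frequency
        cells.append((eps.eps_real, EPS0 * eps.eps_imag * omega, n_cells))
    total_cells = sum(c[2] for c in cells)
    n = 2 * pad_cells + total_cells
    eps_r = np.ones(n)
    sigma = np.zeros(n)
    i = pad_cells
    for er, sg, m in cells:
        eps_r[i : i + m] = er
        sigma[i : i + m] = sg
        i += m
    return eps_r, sigma, pad_cells, pad_cells + total_cells, cells


def reflectance_transmittance_1d(
    layers: Sequence[tuple[ComplexPermittivity, float]],
    frequency: float,
    spacing: float | None = None,
    cycles: float = 8.0,
    courant: float = 0.999,
) -> tuple[float, float, float]:
    """Carrier-frequency power reflectance/transmittance of a stack by FDTD.

    Runs the stack and an empty grid with the same soft source; the
    reflected wave is the difference at a sensor in front of the stack
    and the transmitted wave is measured behind it.  Layer thicknesses
    are voxelised to whole cells, and the matching transfer-matrix
    value should be computed for the voxelised thicknesses
    (:func:`stack_oracle` does both consistently).

    Returns (R, T, A) with A = 1 - R - T.
    """
    if not layers:
        return 0.0, 1.0, 0.0
    if spacing is None:
        n_max = max(refractive_index(eps)[0] for eps, _ in layers)
        lam0 = C0 / frequency
        spacing = min(lam0 / (120.0 * n_max), min(d for _, d in layers) / 4.0)

    pad = 60
    eps_r, sigma, i_front, i_back, _ = _stack_grid(layers, frequency, spacing, pad)
    n = eps_r.shape[0]
    dt = courant * spacing / C0

    duration = cycles / frequency
    from .sources import PulseSource, gaussian_pulse

    src = PulseSource(carrier=frequency, envelope_duration=duration)
    # run long enough for the pulse plus several grid transits to decay
    n_steps = int((duration + 8.0 * n * spacing / C0) / dt)
    t = np.arange(n_steps) * dt
    s = gaussian_pulse(t, src)

    src_idx = 8
    sensors = [i_front - 20, i_back + 20]
    rec = run_fdtd_1d(eps_r, sigma, spacing, dt, s, src_idx, sensors)
    rec0 = run_fdtd_1d(np.ones(n), np.zeros(n), spacing, dt, s, src_idx, sensors)

    inc_front = _dft_at(rec0[0], dt, frequency)
    refl = _dft_at(rec[0] - rec0[0], dt, frequency)
    inc_back = _dft_at(rec0[1], dt, frequency)
    trans = _dft_at(rec[1], dt, frequency)
    r_pow = abs(refl / inc_front) ** 2
    t_pow = abs(trans / inc_back) ** 2
    return float(r_pow), float(t_pow), float(1.0 - r_pow - t_pow)


def stack_oracle(
    layers: Sequence[tuple[ComplexPermittivity, float]],
    frequency: float,
    spacing: float,
) -> tuple[float, float, float]:
    """Transfer-matrix (R, T, A) for the grid-voxelised layer thicknesses."""
    vox = []
    for eps, d in layers:
        n_cells = max(1, int(round(d / spacing)))
        vox.append((eps, n_cells * spacing))
    return transfer_matrix_stack(vox, frequency)


def stack_internal_peak_1d(
    layers: Sequence[tuple[ComplexPermittivity, float]],
    frequency: float,
    sensor_depth: float,
    spacing: float | None = None,
    cycles: float = 8.0,
    courant: float = 0.999,
) -> float:
    """Peak |Ez| at a given depth inside a layered stack (V/m per unit
    incident amplitude).

    The observation node sits ``sensor_depth`` metres past the stack's
    front face, e.g. at a layer junction; used by the permittivity
    perturbation harness.
    """
    if not layers:
        raise InvalidInputError("stack must have at least one layer")
    if spacing is None:
        n_max = max(refractive_index(eps)[0] for eps, _ in layers)
        lam0 = C0 / frequency
        spacing = min(lam0 / (120.0 * n_max), min(d for _, d in layers) / 4.0)
    pad = 60
    eps_r, sigma, i_front, _, _ = _stack_grid(layers, frequency, spacing, pad)
    dt = courant * spacing / C0
    duration = cycles / frequency
    from .sources import PulseSource, gaussian_pulse

    src = PulseSource(carrier=frequency, envelope_duration=duration)
    n = eps_r.shape[0]
    n_steps = int((duration + 8.0 * n * spacing / C0) / dt)
    t = np.arange(n_steps) * dt
    s = gaussian_pulse(t, src)
    sensor = i_front + int(round(sensor_depth / spacing))
    rec = run_fdtd_1d(eps_r, sigma, spacing, dt, s, 8, [sensor])
    return float(np.max(np.abs(rec[0])))


def decay_profile_1d(
    eps: ComplexPermittivity,
    depths: np.ndarray,
    cycles: float = 10.0,
    spacing: float | None = None,
    courant: float = 0.999,
) -> np.ndarray:
    """Peak |Ez| versus depth inside a lossy half-space (normalised).

    An air region abuts a half-space of the given material; the pulse
    enters at normal incidence and the peak field over time is recorded
    at each requested depth.  Values are normalised to the shallowest
    depth, for comparison with exp(-(z - z0)/delta).
    """
    frequency = eps.frequency
    n_med, kappa = refractive_index(eps)
    lam0 = C0 / frequency
    if spacing is None:
        spacing = lam0 / (150.0 * n_med)
    depth_max = float(np.max(depths))
    delta = C0 / (2.0 * math.pi * frequency * kappa) if kappa > 0 else depth_max
    med_cells = int((depth_max + 8.0 * delta) / spacing)
    pad = 80
    n = pad + med_cells
    eps_r = np.ones(n)
    sigma = np.zeros(n)
    omega = 2.0 * math.pi * frequency
    eps_r[pad:] = eps.eps_real
    sigma[pad:] = EPS0 * eps.eps_imag * omega

    dt = courant * spacing / C0
    duration = cycles / frequency
    from .sources import PulseSource, gaussian_pulse

    src = PulseSource(carrier=frequency, envelope_duration=duration)
    n_steps = int((duration + 4.0 * n * spacing / C0 * n_med) / dt)
    t = np.arange(n_steps) * dt
    s = gaussian_pulse(t, src)

    sensor_idx = [pad + int(round(z / spacing)) for z in np.asarray(depths)]
    rec = run_fdtd_1d(eps_r, sigma, spacing, dt, s, 8, sensor_idx)
    peaks = np.max(np.abs(rec), axis=1)
    return peaks / peaks[0]


@njit(cache=True)
def _cavity_energy(ez, hy, dh, ce, n_steps, dx, energies):
    n = ez.shape[0]
    for step in range(n_steps):
        hy_old = hy.copy()
        for i in range(n - 1):
            hy[i] += dh * (ez[i + 1] - ez[i])
        # mixed discrete energy: E at integer time n, H product across it
        ue = 0.0
        for i in range(n):
            ue += ez[i] * ez[i]
        uh = 0.0
        for i in range(n - 1):
            uh += hy[i] * hy_old[i]
        energies[step] = 0.5 * dx * (EPS0 * ue + MU0 * uh)
        for i in range(1, n - 1):
            ez[i] = ez[i] + ce * (hy[i] - hy[i - 1])
        ez[0] = 0.0
        ez[n - 1] = 0.0


def cavity_energy_series(
    n_cells: int = 400, n_steps: int = 10_000, courant: float = 0.9
) -> np.ndarray:
    """Total EM energy per step in a lossless PEC cavity (J/m^2).

    The cavity starts from a Gaussian Ez profile and rings freely; the
    staggered-time energy (with the H product taken across the E
    update) is the discrete invariant of the lossless Yee scheme, so
    the returned series should be constant to numerical precision.
    """
    spacing = 1e-3
    dt = courant * spacing / C0
    x = np.arange(n_cells) * spacing
    x0 = n_cells * spacing / 2.0
    w = n_cells * spacing / 12.0
    ez = np.exp(-((x - x0) ** 2) / (2.0 * w**2))
    ez[0] = ez[-1] = 0.0
    hy = np.zeros(n_cells - 1)
    dh = dt / (MU0 * spacing)
    ce = dt / (EPS0 * spacing)
    energies = np.empty(n_steps)
    _cavity_energy(ez, hy, dh, ce, n_steps, spacing, energies)
    return energies
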