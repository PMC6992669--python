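"""Yee solver behaviour: 1-D oracle checks and 3-D plane-wave properties."""

import numpy as np
import pytest
from scipy.constants import c as C0

from earwave.dielectrics import AIR, ComplexPermittivity, fresnel_normal_incidence
from earwave.errors import SensorPlacementError
from earwave.fdtd import (
    Incidence,
    PulseSource,
    SensorSpec,
    SolverConfig,
    run_fdtd,
)
from earwave.fdtd.solver1d import (
    reflectance_transmittance_1d,
    run_fdtd_1d,
    stack_oracle,
)
from earwave.phantom import VoxelPhantom


def _env_peak_time(series, dt):
    i = int(np.argmax(series))
    if 0 < i < len(series) - 1:
        y0, y1, y2 = series[i - 1], series[i], series[i + 1]
        i = i + 0.5 * (y0 - y2) / (y0 - 2 * y1 + y2)
    return i * dt


def _xcorr_delay(sig_a, sig_b, dt):
    xc = np.correlate(sig_b, sig_a, "full")
    i = int(np.argmax(xc))
    y0, y1, y2 = xc[i - 1], xc[i], xc[i + 1]
    di = 0.5 * (y0 - y2) / (y0 - 2 * y1 + y2)
    return (i + di - (len(sig_a) - 1)) * dt


class Test1D:
    def test_half_space_reflectance_matches_fresnel(self, tissue_table):
        """A thick lossy slab reflects like the bare interface."""
        eps = tissue_table.get("fibrous_tissue", 90e9)
        reflectance, _, _ = reflectance_transmittance_1d([(eps, 2e-3)], 90e9)
        expected = abs(fresnel_normal_incidence(AIR, eps)) ** 2
        assert reflectance == pytest.approx(expected, abs=0.005)

    def test_lossless_slab_agrees_with_transfer_matrix(self):
        slab = ComplexPermittivity(4.0, 0.0, 60e9)
        layers = [(slab, 3.2e-4)]
        spacing = 4e-6
        got = reflectance_transmittance_1d(layers, 60e9, spacing=spacing)
        want = stack_oracle(layers, 60e9, spacing)
        assert got[0] == pytest.approx(want[0], abs=0.005)
        assert got[1] == pytest.approx(want[1], abs=0.005)

    def test_unstable_timestep_rejected(self):
        n = 100
        with pytest.raises(Exception):
            run_fdtd_1d(
                np.ones(n), np.zeros(n), 1e-5, 2e-5 / C0,
                np.zeros(10), 5, [50],
            )


def _air_phantom(n=60, spacing=2e-4):
    return VoxelPhantom(labels=np.zeros((n, n, n), dtype=np.uint8), spacing=spacing)


@pytest.fixture(scope="module")
def free_space_run():
    ph = _air_phantom(70)
    sp = ph.spacing
    c = 70 * sp / 2
    sensors = [
        SensorSpec("p1", "point", position=(30 * sp, c, c)),
        SensorSpec("p2", "point", position=(55 * sp, c, c)),
        SensorSpec("plane", "planar", plane_axis=0, plane_offset=30 * sp),
    ]
    src = PulseSource(carrier=60e9, envelope_duration=60e-12)
    recs = run_fdtd(ph, None, src, sensors, SolverConfig())
    return ph, {r.name: r for r in recs}


class Test3D:
    def test_free_space_pulse_speed(self, free_space_run):
        ph, r = free_space_run
        dt = r["p1"].timestep
        delay = _env_peak_time(r["p2"].e_series, dt) - _env_peak_time(r["p1"].e_series, dt)
        v = 25 * ph.spacing / delay
        assert v == pytest.approx(C0, rel=0.01)

    def test_plane_wave_uniform_across_aperture(self, free_space_run):
        """Peak |E| equal within 2 % over a canal-mouth-sized region."""
        ph, r = free_space_run
        pm = r["plane"].peak_map
        n = pm.shape[0]
        ctr = pm[n // 2 - 18 : n // 2 + 18, n // 2 - 18 : n // 2 + 18]
        assert (ctr.max() - ctr.min()) / ctr.mean() < 0.02

    def test_point_sensor_matches_plane_centre(self, free_space_run):
        ph, r = free_space_run
        # the plane centre series is |E| at the same voxel as p1
        assert np.allclose(r["plane"].e_series, r["p1"].e_series)

    def test_amplitude_linearity(self):
        ph = _air_phantom(40)
        c = 40 * ph.spacing / 2
        sensors = [SensorSpec("p", "point", position=(30 * ph.spacing, c, c))]
        base = run_fdtd(ph, None, PulseSource(60e9, 60e-12, amplitude=1.0),
                        sensors, SolverConfig())[0]
        double = run_fdtd(ph, None, PulseSource(60e9, 60e-12, amplitude=2.0),
                          sensors, SolverConfig())[0]
        assert np.allclose(double.e_series, 2.0 * base.e_series, rtol=1e-12, atol=1e-15)

    def test_deterministic_bit_identical(self):
        ph = _air_phantom(36)
        c = 36 * ph.spacing / 2
        sensors = [SensorSpec("p", "point", position=(28 * ph.spacing, c, c))]
        src = PulseSource(60e9, 50e-12)
        a = run_fdtd(ph, None, src, sensors, SolverConfig())[0]
        b = run_fdtd(ph, None, src, sensors, SolverConfig())[0]
        assert np.array_equal(a.e_series, b.e_series)
        assert np.array_equal(a.h_series, b.h_series)

    def test_oblique_arrival_time_gradient(self):
        """30 deg anterior incidence delays arrival across y by sin(30)/c."""
        ph = _air_phantom(80)
        sp = ph.spacing
        c = 80 * sp / 2
        sensors = [
            SensorSpec("a", "point", position=(34 * sp, c - 12 * sp, c)),
            SensorSpec("b", "point", position=(34 * sp, c + 12 * sp, c)),
        ]
        src = PulseSource(60e9, 60e-12, incidence=Incidence.ANTERIOR_30)
        recs = run_fdtd(ph, None, src, sensors, SolverConfig())
        r = {x.name: x for x in recs}
        lag = _xcorr_delay(r["a"].e_components[:, 2], r["b"].e_components[:, 2],
                           r["a"].timestep)
        gradient = lag / (24 * sp)
        assert gradient == pytest.approx(0.5 / C0, rel=0.05)

    def test_sensor_outside_grid_names_the_sensor(self):
        ph = _air_phantom(30)
        bad = SensorSpec("wayout", "point", position=(1.0, 0.0, 0.0))
        with pytest.raises(SensorPlacementError, match="wayout"):
            run_fdtd(ph, None, PulseSource(60e9, 50e-12), [bad], SolverConfig())


class TestRefinement:
    def test_membrane_field_converges_under_refinement(self, tissue_table):
        """Halving the spacing moves the near-membrane peak |E| < 5 %.

        All layers are set to 0.4 mm so both grids voxelise the same
        physical geometry; the metric is the maximum of the peak-|E|
        map over the 2 mm of canal in front of the membrane (robust to
        sub-voxel sampling offsets)."""
        import warnings

        from earwave.phantom import EarGeometrySpec, build_ear_phantom

        vals = {}
        for sp in (2e-4, 1e-4):
            spec = EarGeometrySpec(
                canal_depth=4e-3, front_air=2.5e-3, middle_ear_depth=1.2e-3,
                baffle_depth=1.2e-3, lateral_padding=1.8e-3, pinna_enabled=False,
                layer_thicknesses={
                    "stratum_corneum": 4e-4, "epidermis": 4e-4,
                    "fibrous_tissue": 4e-4, "mucous_membrane": 4e-4,
                },
                lining_sc_thickness=4e-4, lining_epidermis_thickness=4e-4,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ph = build_ear_phantom(spec, sp)
            yc, _ = ph.meta["canal_center_yz"]
            xm = ph.meta["x_membrane"]
            sensors = [SensorSpec("long", "planar", plane_axis=1, plane_offset=yc)]
            recs = run_fdtd(ph, tissue_table, PulseSource(60e9, 60e-12),
                            sensors, SolverConfig())
            pm = recs[0].peak_map
            vals[sp] = pm[int((xm - 2e-3) / sp) : int(xm / sp), :].max()
        assert abs(vals[1e-4] - vals[2e-4]) / vals[1e-4] < 0.05
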