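"""Closed-form 2D binding kinetics: printed-constant reproduction, scaling
laws, and the forward/off-rate round-trip identity."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import trailkin as tk
from trailkin.binding import (
    InvalidGeometryError,
    MIN_SHEARED_PECLET,
    RegimeValidityError,
)
from trailkin.constants import CTC_AREA, CTC_VOLUME, TRAIL_MOLAR_MASS


def rel(a, b):
    return abs(a - b) / abs(b)


class TestSlipVelocity:
    def test_physiological_value(self):
        # S = 1000 1/s across d = 10 um gives V = 1 cm/s
        assert tk.slip_velocity(1000.0, 10e-4) == pytest.approx(1.0)

    def test_linearity_and_zero_shear(self):
        assert tk.slip_velocity(0.0, 10e-4) == 0.0
        assert tk.slip_velocity(500.0, 10e-4) == pytest.approx(0.5)

    def test_invalid_geometry(self):
        with pytest.raises(InvalidGeometryError):
            tk.slip_velocity(1000.0, 0.0)
        with pytest.raises(InvalidGeometryError):
            tk.slip_velocity(-1.0, 10e-4)


class TestShearedRegime:
    def test_printed_constants_within_5pct(self, geometry):
        r = tk.derive_sheared_regime(geometry)
        assert r.slip_velocity == pytest.approx(1.0)
        assert r.peclet == pytest.approx(5000.0)
        assert rel(r.nusselt, 3183.0) < 0.05
        assert rel(r.k_o, 1.0e-5) < 0.05
        assert rel(r.encounter_duration, 4.2e-6) < 0.05
        assert rel(r.duration_dimless, 1.7e-4) < 0.05
        assert rel(r.damkohler, 2.5e7) < 0.05
        assert rel(r.binding_probability, 0.9998) < 0.05
        assert rel(r.k_f, 9.998e-6) < 0.05
        assert rel(r.k_off, 2.4e5) < 0.05

    def test_full_precision_hand_evaluation(self, geometry):
        # independent sequential evaluation of each closed form
        r = tk.derive_sheared_regime(geometry)
        lam_delta = r.duration_dimless * r.damkohler
        assert lam_delta == pytest.approx(8e9 * 5e-6 / (3 * math.pi), rel=1e-12)
        assert lam_delta == pytest.approx(4244.13, rel=1e-5)
        assert r.k_off == pytest.approx(1e9 * (1.0 / r.binding_probability - 1.0),
                                        rel=1e-12)
        assert r.k_off == pytest.approx(2.356e5, rel=1e-3)

    def test_infinitely_fast_intrinsic_reaction(self, geometry):
        import dataclasses
        fast = dataclasses.replace(geometry, intrinsic_rate=1e30)
        r = tk.derive_sheared_regime(fast)
        assert r.binding_probability == pytest.approx(1.0)
        assert r.k_f == pytest.approx(r.k_o)
        assert r.k_off == pytest.approx(0.0, abs=1e-12 * 1e30)

    def test_low_peclet_rejected(self, geometry):
        import dataclasses
        slow = dataclasses.replace(geometry, shear_rate=1.0)
        with pytest.raises(RegimeValidityError):
            tk.derive_sheared_regime(slow)
        assert MIN_SHEARED_PECLET == 100.0  # documented validity floor


class TestUnshearedRegime:
    def test_printed_constants_within_5pct(self, geometry):
        r = tk.derive_unsheared_regime(geometry)
        assert rel(r.nusselt, 2.9) < 0.05          # 2 / ln 2 = 2.885
        assert rel(r.k_o, 9.1e-9) < 0.05
        assert rel(r.encounter_duration, 3.1e-3) < 0.05
        assert r.duration_dimless == pytest.approx(0.125)
        assert r.binding_probability == pytest.approx(1.0, abs=1e-5)
        assert rel(r.k_off, 320.0) < 0.05

    def test_unit_log_geometry(self):
        g = tk.EncounterGeometry(diffusivity=1e-9, reactive_radius=5e-6,
                                 half_spacing=5e-6 * math.e, intrinsic_rate=1e9)
        assert tk.derive_unsheared_regime(g).nusselt == pytest.approx(2.0)

    def test_hand_evaluation(self, geometry):
        r = tk.derive_unsheared_regime(geometry)
        assert r.duration_dimless * r.damkohler == pytest.approx(3.125e6)
        assert r.k_off == pytest.approx(320.0)     # k_in / (Lambda delta), exactly

    def test_b_not_exceeding_a_rejected(self):
        with pytest.raises(InvalidGeometryError):
            tk.derive_unsheared_regime(tk.EncounterGeometry(
                diffusivity=1e-9, reactive_radius=5e-6, half_spacing=5e-6,
                intrinsic_rate=1e9))


class TestBellRegime:
    def test_printed_constants(self, geometry):
        r = tk.derive_bell_regime(geometry)
        assert rel(r.k_o, 6.3e-9) < 0.05           # 2 pi D
        assert r.k_off == pytest.approx(80.0)      # 2 D / a^2

    def test_linear_in_diffusivity(self, geometry):
        import dataclasses
        r1 = tk.derive_bell_regime(geometry)
        r2 = tk.derive_bell_regime(dataclasses.replace(geometry, diffusivity=2e-9))
        assert r2.k_o == pytest.approx(2 * r1.k_o)
        assert r2.k_off == pytest.approx(2 * r1.k_off)

    def test_same_order_as_unsheared(self, geometry):
        # the two diffusion-limited constructions agree within one order
        bell = tk.derive_bell_regime(geometry)
        ch = tk.derive_unsheared_regime(geometry)
        assert bell.k_o / ch.k_o == pytest.approx(math.log(2), rel=1e-9)  # ~0.69
        assert 0.1 < bell.k_o / ch.k_o < 10
        assert 0.1 < bell.k_off / ch.k_off < 10


class TestSurfaceDensities:
    def test_liposomal_trail_density(self):
        # ~65 TRAIL molecules on a 100 nm liposome -> ~2e11 /cm^2
        spec = tk.liposome_surface_density(65, 100e-7)
        assert rel(spec.density, 2e11) < 0.05
        assert spec.density == pytest.approx(65 / (math.pi * 1e-10), rel=1e-12)

    def test_zero_copies_rejected(self):
        with pytest.raises(InvalidGeometryError):
            tk.liposome_surface_density(0, 100e-7)

    def test_receptor_density_and_cell_area(self):
        # 1e4 receptors on a 1e-9 cm^3 sphere-equivalent cell
        spec = tk.cell_surface_density(1e4, CTC_VOLUME)
        assert rel(spec.density, 2e9) < 0.05
        assert rel(spec.area, 4.8e-6) < 0.05

    def test_sphere_scaling_law(self):
        s1 = tk.cell_surface_density(1e4, 1e-9)
        s8 = tk.cell_surface_density(1e4, 8e-9)
        assert s8.area == pytest.approx(4 * s1.area)
        assert s8.density == pytest.approx(s1.density / 4)

    def test_plasma_trail_conversion(self):
        # 1 ug/mL of soluble TRAIL -> ~1.85e4 per cell, ~3.8e9 /cm^2
        spec = tk.plasma_to_surface_density(1e-6, TRAIL_MOLAR_MASS, CTC_VOLUME)
        assert rel(spec.per_cell, 1.85e4) < 0.05
        assert rel(spec.density, 3.8e9) < 0.05

    def test_plasma_zero_concentration_is_control(self):
        spec = tk.plasma_to_surface_density(0.0, TRAIL_MOLAR_MASS, CTC_VOLUME)
        assert spec.per_cell == 0.0 and spec.density == 0.0

    def test_implied_molar_mass_back_solves(self):
        # the default molar-mass constant is fixed by the two printed numbers
        implied = 1e-6 * tk.binding.AVOGADRO / 1.85e13
        assert rel(TRAIL_MOLAR_MASS, implied) < 0.01


class TestVolumetricToArealRate:
    def test_printed_conversion(self):
        k2d = tk.volumetric_to_areal_rate(2.4e5, CTC_AREA, CTC_VOLUME)
        assert rel(k2d, 1.94e-12) < 0.02
        # exact arithmetic gives 1.91e-12; the printed value rounds higher
        assert k2d == pytest.approx(2.4e5 * 1e3 / tk.binding.AVOGADRO * 4800.0,
                                    rel=1e-12)

    def test_zero_and_invalid(self):
        assert tk.volumetric_to_areal_rate(0.0, CTC_AREA, CTC_VOLUME) == 0.0
        with pytest.raises(InvalidGeometryError):
            tk.volumetric_to_areal_rate(2.4e5, -1.0, CTC_VOLUME)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

geoms = st.builds(
    tk.EncounterGeometry,
    diffusivity=st.floats(1e-11, 1e-7),
    reactive_radius=st.floats(1e-7, 1e-4),
    half_spacing=st.just(None),
    shear_rate=st.floats(100.0, 1e5),
    center_distance=st.floats(1e-4, 1e-2),
    intrinsic_rate=st.floats(1e3, 1e12),
)


@settings(max_examples=200, derandomize=True)
@given(geom=geoms, factor=st.floats(1.5, 1e3))
def test_binding_probability_increases_with_intrinsic_rate(geom, factor):
    import dataclasses
    try:
        r1 = tk.derive_sheared_regime(geom)
    except RegimeValidityError:
        return
    r2 = tk.derive_sheared_regime(
        dataclasses.replace(geom, intrinsic_rate=geom.intrinsic_rate * factor))
    assert r2.binding_probability > r1.binding_probability
    assert r1.k_f <= r1.k_o


@settings(max_examples=200, derandomize=True)
@given(geom=geoms)
def test_off_rate_round_trip_identity(geom):
    """Inverting k_off from k_f and recomputing k_f returns the original."""
    try:
        r = tk.derive_sheared_regime(geom)
    except RegimeValidityError:
        return
    k_in = geom.intrinsic_rate
    k_f_back = r.k_o * k_in / (k_in + r.k_off)
    assert abs(k_f_back - r.k_f) <= 1e-10 * r.k_f


@settings(max_examples=100, derandomize=True)
@given(geom=geoms, scale=st.floats(1.1, 10.0))
def test_sheared_on_rate_scales_with_velocity_and_radius(geom, scale):
    import dataclasses
    try:
        r1 = tk.derive_sheared_regime(geom)
        r2 = tk.derive_sheared_regime(
            dataclasses.replace(geom, shear_rate=geom.shear_rate * scale))
        r3 = tk.derive_sheared_regime(
            dataclasses.replace(geom, reactive_radius=geom.reactive_radius * scale))
    except RegimeValidityError:
        return
    assert r2.k_o == pytest.approx(scale * r1.k_o, rel=1e-9)
    assert r3.k_o == pytest.approx(scale * r1.k_o, rel=1e-9)


@settings(max_examples=100, derandomize=True)
@given(b_over_a=st.floats(1.01, 100.0), shear=st.floats(0.0, 1e5))
def test_unsheared_on_rate_independent_of_shear(b_over_a, shear):
    a = 5e-6
    g = tk.EncounterGeometry(diffusivity=1e-9, reactive_radius=a,
                             half_spacing=a * b_over_a, shear_rate=shear,
                             center_distance=1e-3, intrinsic_rate=1e9)
    g0 = tk.EncounterGeometry(diffusivity=1e-9, reactive_radius=a,
                              half_spacing=a * b_over_a, shear_rate=0.0,
                              intrinsic_rate=1e9)
    assert tk.derive_unsheared_regime(g).k_o == tk.derive_unsheared_regime(g0).k_o
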