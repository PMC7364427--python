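"""Geometry of the two localizers: forward models, inverse formulas, limits."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from stereoloc import (
    BETA_MAX_SP_DEG,
    UPSILON_DEG,
    DegenerateGeometryError,
    NLocalizerSpec,
    SectionPose,
    SturmPastyrSpec,
    euclidean_distance,
    n_forward_fiducials,
    n_localizer_z,
    sp_forward_distances,
    sp_forward_fiducials,
    sturm_pastyr_z,
)

SQRT5 = math.sqrt(5.0)


class TestEuclideanDistance:
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            ((0, 0), (3, 4), 5.0),
            ((2, 7), (2, 7), 0.0),
            ((0, 0), (140, 0), 140.0),  # rod A to rod C at beta = 0
        ],
    )
    def test_known_distances(self, p, q, expected):
        assert euclidean_distance(p, q) == pytest.approx(expected)
        assert euclidean_distance(q, p) == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            euclidean_distance((0.0, math.nan), (1.0, 1.0))


class TestNLocalizerZ:
    @pytest.mark.parametrize(
        "d_bc, d_ac, expected",
        [
            (70.0, 140.0, 70.0),  # diagonal fiducial at midpoint
            (0.0, 140.0, 0.0),  # fiducial B on top of C -> frame base
        ],
    )
    def test_linear_interpolation(self, d_bc, d_ac, expected):
        assert n_localizer_z(d_bc, d_ac) == pytest.approx(expected)

    def test_tilt_cancels_in_ratio(self):
        # distances measured in a 5-degree tilted section are both stretched
        # by 1/cos(beta); the ratio, and hence z, is unchanged
        trip = n_forward_fiducials(SectionPose(z=20.0, beta=5.0))
        d = trip.distances()
        assert d.d_bc == pytest.approx(20.0 / math.cos(math.radians(5.0)))
        assert n_localizer_z(d.d_bc, d.d_ac) == pytest.approx(20.0, rel=1e-12)

    def test_coincident_outer_fiducials_is_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            n_localizer_z(10.0, 0.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            n_localizer_z(-1.0, 140.0)

    @given(
        d_bc=st.floats(0.0, 140.0),
        k=st.floats(1e-3, 1e3),
    )
    @settings(derandomize=True, max_examples=100)
    def test_scale_invariance(self, d_bc, k):
        """Scaling both distances by k leaves z unchanged (pixel-size free)."""
        z0 = n_localizer_z(d_bc, 140.0)
        zk = n_localizer_z(d_bc * k, 140.0 * k)
        assert zk == pytest.approx(z0, rel=1e-9, abs=1e-9)

    def test_custom_frame_constants(self):
        spec = NLocalizerSpec(z_top=120.0, z_bottom=-60.0, rod_spacing=190.0)
        assert n_localizer_z(0.0, 100.0, spec) == -60.0
        assert n_localizer_z(50.0, 100.0, spec) == pytest.approx(30.0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            NLocalizerSpec(z_top=0.0, z_bottom=0.0)
        with pytest.raises(ValueError):
            NLocalizerSpec(rod_spacing=-1.0)


class TestSturmPastyrZ:
    @pytest.mark.parametrize("d", [1.0, 10.0, 70.0])
    def test_parallel_section_reduces_to_sum(self, d):
        """Equal distances (parallel section): z = d_AB + d_BC = 2d."""
        assert sturm_pastyr_z(d, d) == pytest.approx(2.0 * d, rel=1e-15)

    def test_apex_convention(self):
        assert sturm_pastyr_z(0.0, 0.0) == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            sturm_pastyr_z(-0.1, 1.0)

    @given(
        d_ab=st.floats(1e-6, 1e3),
        d_bc=st.floats(1e-6, 1e3),
        k=st.floats(1e-3, 1e3),
    )
    @settings(derandomize=True, max_examples=100)
    def test_scale_covariance(self, d_ab, d_bc, k):
        """Scaling both distances by k scales z by k (pixel size matters)."""
        z0 = sturm_pastyr_z(d_ab, d_bc)
        zk = sturm_pastyr_z(k * d_ab, k * d_bc)
        assert zk == pytest.approx(k * z0, rel=1e-9)


class TestForwardModels:
    def test_n_forward_flat_section(self):
        trip = n_forward_fiducials(SectionPose(z=20.0, beta=0.0))
        assert trip.c == (0.0, 0.0)
        assert trip.b == pytest.approx((20.0, 0.0))
        assert trip.a == pytest.approx((140.0, 0.0))

    def test_n_forward_60_degree_tilt_doubles_u(self):
        trip = n_forward_fiducials(SectionPose(z=20.0, beta=60.0))
        assert trip.b[0] == pytest.approx(40.0)
        assert trip.a[0] == pytest.approx(280.0)

    def test_n_forward_base_section_collapses_b_onto_c(self):
        trip = n_forward_fiducials(SectionPose(z=0.0, beta=5.0))
        assert trip.b == pytest.approx((0.0, 0.0))

    def test_n_forward_rejects_extreme_tilt(self):
        with pytest.raises(ValueError):
            n_forward_fiducials(SectionPose(z=20.0, beta=89.0))

    def test_sp_distances_flat_section(self):
        d = sp_forward_distances(SectionPose(z=20.0, beta=0.0))
        assert d.d_ab == pytest.approx(10.0)
        assert d.d_bc == pytest.approx(10.0)

    def test_sp_distances_at_beta_equal_upsilon(self):
        # sin(upsilon) = 1/sqrt(5); at beta = upsilon the AB triangle is
        # right-angled so d_ab = z sin(upsilon), and d_bc = z sin(u)/cos(2u)
        d = sp_forward_distances(SectionPose(z=20.0, beta=UPSILON_DEG))
        assert d.d_ab == pytest.approx(20.0 / SQRT5, rel=1e-12)
        assert d.d_bc == pytest.approx(20.0 / (SQRT5 * 0.6), rel=1e-12)

    def test_sp_fiducial_placement(self):
        trip = sp_forward_fiducials(SectionPose(z=20.0, beta=UPSILON_DEG))
        assert trip.a == pytest.approx((-20.0 / SQRT5, 0.0))
        assert trip.b == (0.0, 0.0)
        assert trip.c == pytest.approx((20.0 / (SQRT5 * 0.6), 0.0))

    def test_sp_apex(self):
        trip = sp_forward_fiducials(SectionPose(z=0.0, beta=10.0))
        assert trip.a == trip.b == trip.c == (0.0, 0.0)

    def test_sp_rejects_near_singular_tilt(self):
        # d_BC diverges at 90 - upsilon = 63.435 deg; limit is at 60 deg
        with pytest.raises(ValueError):
            sp_forward_distances(SectionPose(z=20.0, beta=63.0))

    def test_sp_singularity_angle(self):
        assert SturmPastyrSpec().beta_singularity == pytest.approx(63.434948822922)


class TestRoundTrips:
    @given(
        z=st.floats(1e-6, 140.0),
        beta=st.floats(0.0, BETA_MAX_SP_DEG),
    )
    @settings(derandomize=True, max_examples=200)
    def test_sturm_pastyr_round_trip(self, z, beta):
        """Forward distances then inverse formula recover z exactly."""
        d = sp_forward_distances(SectionPose(z=z, beta=beta))
        assert sturm_pastyr_z(d.d_ab, d.d_bc) == pytest.approx(z, rel=1e-9)

    @given(
        z=st.floats(0.0, 140.0),
        beta=st.floats(0.0, 85.0),
    )
    @settings(derandomize=True, max_examples=200)
    def test_n_localizer_round_trip(self, z, beta):
        """Forward fiducials then linear interpolation recover z exactly."""
        d = n_forward_fiducials(SectionPose(z=z, beta=beta)).distances()
        assert n_localizer_z(d.d_bc, d.d_ac) == pytest.approx(z, rel=1e-9, abs=1e-9)


class TestGeometricTrends:
    def test_d_ab_minimized_at_beta_equal_upsilon(self):
        """d_AB over tilt is smallest where the section is normal to rod A."""
        betas = [i * 0.5 for i in range(0, 121)]  # 0..60 deg
        d_abs = [sp_forward_distances(SectionPose(z=20.0, beta=b)).d_ab for b in betas]
        argmin = betas[d_abs.index(min(d_abs))]
        assert argmin == pytest.approx(UPSILON_DEG, abs=0.5)

    def test_d_bc_strictly_increasing_in_beta(self):
        betas = [i * 1.0 for i in range(0, 61)]
        d_bcs = [sp_forward_distances(SectionPose(z=20.0, beta=b)).d_bc for b in betas]
        assert all(b2 > b1 for b1, b2 in zip(d_bcs, d_bcs[1:]))
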