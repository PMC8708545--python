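"""Surface geometry, intersection and refraction kernel."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from keratoptics.optics_core import (ALIVE, MISSED, TIR, VIGNETTED,
                                     ApertureError, Ray, SagDomainError,
                                     SurfaceSpec, TotalInternalReflection,
                                     intersect, intersect_bundle, refract,
                                     refract_bundle, sag, sag_bundle,
                                     sag_gradient_bundle, surface_normal)


def sphere(R, sa=5.0):
    return SurfaceSpec("spherical", Ry=R, Rx=R, semi_aperture=sa)


class TestSag:
    def test_vertex_is_zero(self):
        for s in (sphere(7.428),
                  SurfaceSpec("aspheric", Ry=7.526, Rx=7.526, ky=-0.213,
                              kx=-0.213),
                  SurfaceSpec("biconic", Ry=6.287, Rx=6.704, ky=-0.005,
                              kx=-0.303),
                  SurfaceSpec("plane")):
            assert sag(s, 0.0, 0.0) == 0.0

    def test_sphere_closed_form(self):
        # z = R - sqrt(R^2 - r^2) at r = 1 mm
        R = 7.428
        expect = R - np.sqrt(R * R - 1.0)
        assert sag(sphere(R), 1.0, 0.0) == pytest.approx(expect, abs=1e-12)
        assert sag(sphere(R), 1.0, 0.0) == pytest.approx(0.067620, abs=1e-6)

    def test_biconic_reduces_to_aspheric(self, rng):
        bic = SurfaceSpec("biconic", Ry=7.526, Rx=7.526, ky=-0.213,
                          kx=-0.213)
        asp = SurfaceSpec("aspheric", Ry=7.526, Rx=7.526, ky=-0.213,
                          kx=-0.213)
        pts = rng.uniform(-3, 3, size=(50, 2))
        for x, y in pts:
            assert sag(bic, x, y) == pytest.approx(sag(asp, x, y),
                                                   abs=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(R=st.floats(6.0, 20.0), k=st.floats(-3.0, 0.5),
           x=st.floats(-2.0, 2.0), y=st.floats(-2.0, 2.0))
    def test_reduction_chain(self, R, k, x, y):
        """biconic -> aspheric -> sphere identities for random draws."""
        asp = SurfaceSpec("aspheric", Ry=R, Rx=R, ky=k, kx=k)
        bic = SurfaceSpec("biconic", Ry=R, Rx=R, ky=k, kx=k)
        assert sag(bic, x, y) == pytest.approx(sag(asp, x, y), abs=1e-12)
        sph = sphere(R)
        exact = R - np.sign(R) * np.sqrt(R * R - x * x - y * y)
        assert sag(sph, x, y) == pytest.approx(exact, abs=1e-12)

    def test_domain_error(self):
        # strongly curved oblate case runs out of definition
        s = SurfaceSpec("aspheric", Ry=2.0, Rx=2.0, ky=0.0, kx=0.0,
                        semi_aperture=3.0)
        with pytest.raises(SagDomainError):
            sag(s, 2.5, 0.0)
        _, ok = sag_bundle(s, np.array([0.5, 2.5]), np.array([0.0, 0.0]))
        assert ok.tolist() == [True, False]


class TestNormal:
    def test_vertex_normal_is_axis(self):
        for s in (sphere(7.48), SurfaceSpec("plane"),
                  SurfaceSpec("biconic", Ry=6.3, Rx=6.7, ky=-0.1, kx=-0.3)):
            assert np.allclose(surface_normal(s, 0, 0), [0, 0, 1])

    def test_sphere_normal_through_center(self):
        R = 7.48
        s = sphere(R)
        x, y = 1.2, -0.7
        z = sag(s, x, y)
        n = surface_normal(s, x, y)
        radial = np.array([x, y, z]) - np.array([0, 0, R])
        radial /= np.linalg.norm(radial)
        assert np.allclose(np.abs(n @ radial), 1.0, atol=1e-12)

    def test_matches_finite_difference(self, rng):
        s = SurfaceSpec("biconic", Ry=7.48, Rx=7.517, ky=-0.13, kx=-0.136)
        h = 1e-6
        for x, y in rng.uniform(-2.5, 2.5, size=(20, 2)):
            fx = (sag(s, x + h, y) - sag(s, x - h, y)) / (2 * h)
            fy = (sag(s, x, y + h) - sag(s, x, y - h)) / (2 * h)
            num = np.array([-fx, -fy, 1.0])
            num /= np.linalg.norm(num)
            assert np.allclose(surface_normal(s, x, y), num, atol=1e-7)

    def test_orthogonal_to_tangent(self):
        s = SurfaceSpec("aspheric", Ry=9.533, Rx=9.533, ky=-3.203, kx=-3.203)
        x, y, h = 1.5, 0.8, 1e-6
        n = surface_normal(s, x, y)
        tx = np.array([2 * h, 0, sag(s, x + h, y) - sag(s, x - h, y)])
        ty = np.array([0, 2 * h, sag(s, x, y + h) - sag(s, x, y - h)])
        assert abs(n @ tx / np.linalg.norm(tx)) < 1e-9
        assert abs(n @ ty / np.linalg.norm(ty)) < 1e-9

    def test_outside_aperture(self):
        with pytest.raises(ApertureError):
            surface_normal(sphere(7.48, sa=2.0), 2.5, 0.0)


class TestIntersect:
    def test_axial_ray_hits_vertex(self):
        ray = Ray([0, 0, -10], [0, 0, 1])
        s = sphere(7.428).with_vertex(3.0)
        pt, new = intersect(ray, s)
        assert np.allclose(pt, [0, 0, 3.0], atol=1e-12)
        assert new.opl == pytest.approx(13.0)

    def test_parallel_ray_sphere_closed_form(self):
        ray = Ray([0, 1.0, -5], [0, 0, 1])
        pt, new = intersect(ray, sphere(7.428))
        assert pt[2] == pytest.approx(0.067620, abs=1e-6)
        # point satisfies the implicit surface equation
        assert pt[2] == pytest.approx(sag(sphere(7.428), pt[0], pt[1]),
                                      abs=1e-10)

    def test_vignetted_outside_aperture(self):
        ray = Ray([0, 4.5, -5], [0, 0, 1])
        _, new = intersect(ray, sphere(7.428, sa=3.0))
        assert new.status == VIGNETTED

    def test_missed_surface(self):
        ray = Ray([0, 3.5, -5], [0, 0, 1])
        s = SurfaceSpec("spherical", Ry=3.0, Rx=3.0, semi_aperture=5.0)
        _, new = intersect(ray, s)
        assert new.status == MISSED

    def test_oblique_rays_satisfy_surface_equation(self, rng):
        s = SurfaceSpec("biconic", Ry=7.48, Rx=7.517, ky=-0.13, kx=-0.136)
        n = 100
        P = np.column_stack([rng.uniform(-2, 2, n), rng.uniform(-2, 2, n),
                             np.full(n, -10.0)])
        D = np.column_stack([rng.uniform(-0.1, 0.1, n),
                             rng.uniform(-0.1, 0.1, n), np.ones(n)])
        D /= np.linalg.norm(D, axis=1)[:, None]
        pts, t, status = intersect_bundle(P, D, s)
        ok = status == ALIVE
        assert ok.sum() > 80
        zs, _ = sag_bundle(s, pts[ok, 0], pts[ok, 1])
        assert np.max(np.abs(pts[ok, 2] - zs)) < 1e-10


class TestRefract:
    def test_same_index_unchanged(self):
        d = np.array([0.3, 0.1, 0.9])
        d /= np.linalg.norm(d)
        assert np.allclose(refract(d, [0, 0, 1], 1.33, 1.33), d, atol=1e-15)

    def test_snell_45_degrees(self):
        th1 = np.radians(45.0)
        d = np.array([0.0, np.sin(th1), np.cos(th1)])
        t = refract(d, [0, 0, 1], 1.0, 1.5)
        th2 = np.degrees(np.arcsin(np.hypot(t[0], t[1])))
        assert th2 == pytest.approx(28.1255, abs=1e-4)

    def test_total_internal_reflection(self):
        th1 = np.radians(80.0)
        d = np.array([0.0, np.sin(th1), np.cos(th1)])
        with pytest.raises(TotalInternalReflection):
            refract(d, [0, 0, 1], 1.5, 1.0)

    def test_snell_invariant_and_coplanarity(self, rng):
        n1, n2 = 1.0, 1.376
        for _ in range(20):
            d = rng.normal(size=3)
            d[2] = abs(d[2]) + 1.0
            d /= np.linalg.norm(d)
            nrm = np.array([0.1, -0.05, 1.0])
            nrm /= np.linalg.norm(nrm)
            t = refract(d, nrm, n1, n2)
            s1 = np.linalg.norm(np.cross(d, nrm))
            s2 = np.linalg.norm(np.cross(t, nrm))
            assert n1 * s1 == pytest.approx(n2 * s2, abs=1e-12)
            assert abs(np.dot(np.cross(d, nrm), t)) < 1e-12

    def test_reversibility(self, rng):
        """Refracting n1->n2 then reversing recovers the direction."""
        for _ in range(50):
            d = rng.normal(size=3)
            d[2] = abs(d[2]) + 0.7
            d /= np.linalg.norm(d)
            nrm = rng.normal(size=3) * 0.2 + [0, 0, 1]
            nrm /= np.linalg.norm(nrm)
            n1 = 1.0 + rng.random()
            n2 = n1 + rng.random()  # denser exit medium: no TIR forward
            t = refract(d, nrm, n1, n2)
            back = refract(-t, nrm, n2, n1)
            assert np.allclose(back, -d, atol=1e-10)

    def test_bundle_statuses(self):
        th = np.radians([10.0, 80.0])
        D = np.column_stack([np.zeros(2), np.sin(th), np.cos(th)])
        N = np.tile([0.0, 0.0, 1.0], (2, 1))
        out, status = refract_bundle(D, N, 1.5, 1.0)
        assert status.tolist() == [ALIVE, TIR]


class TestSurfaceSpecValidation:
    def test_spherical_constraints(self):
        with pytest.raises(ValueError):
            SurfaceSpec("spherical", Ry=7.0, Rx=7.1)
        with pytest.raises(ValueError):
            SurfaceSpec("spherical", Ry=7.0, Rx=7.0, ky=-0.1, kx=-0.1)

    def test_aspheric_constraints(self):
        with pytest.raises(ValueError):
            SurfaceSpec("aspheric", Ry=7.0, Rx=7.0, ky=-0.1, kx=-0.2)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            SurfaceSpec("spherical", Ry=0.0, Rx=0.0)
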