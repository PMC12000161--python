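"""Affine-invariant SPD geometry: distances, geodesics, means, eigenstructure."""

import numpy as np
import pytest
from scipy import linalg

from chelamorph import (
    NotPositiveDefiniteError,
    frechet_mean,
    geodesic,
    geodesic_point,
    point_to_geodesic,
    relative_eigenvectors,
    spd_distance,
)
from chelamorph.spd import spd_exp, spd_log, spd_power

from conftest import random_spd


class TestDistance:
    def test_identity_of_indiscernibles(self, rng):
        a = random_spd(rng, 6)
        assert spd_distance(a, a) == pytest.approx(0.0, abs=1e-10)

    def test_commuting_closed_form(self):
        d = spd_distance(np.eye(2), np.diag([np.e**2, np.e**2]))
        assert d == pytest.approx(2 * np.sqrt(2), rel=1e-12)

    def test_affine_invariance(self, rng):
        a, b = random_spd(rng, 5), random_spd(rng, 5)
        m = rng.standard_normal((5, 5)) + 5 * np.eye(5)
        assert spd_distance(m @ a @ m.T, m @ b @ m.T) == pytest.approx(
            spd_distance(a, b), rel=1e-8
        )

    def test_matches_generalized_eigenvalue_formulation(self, rng):
        # independent oracle: sqrt(sum log^2 lambda) over eigvals of (B, A)
        for dim in (2, 5, 11, 17):
            a, b = random_spd(rng, dim), random_spd(rng, dim)
            lam = linalg.eigh(b, a, eigvals_only=True)
            oracle = np.sqrt(np.sum(np.log(lam) ** 2))
            assert spd_distance(a, b) == pytest.approx(oracle, abs=1e-8)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(20):
            a, b, c = (random_spd(rng, 4) for _ in range(3))
            dab, dba = spd_distance(a, b), spd_distance(b, a)
            assert dab == pytest.approx(dba, abs=1e-8)
            assert dab >= 0
            assert spd_distance(a, c) <= dab + spd_distance(b, c) + 1e-8

    def test_non_pd_input_rejected_with_eigenvalue_named(self):
        bad = np.diag([1.0, -2.0, 3.0])
        with pytest.raises(NotPositiveDefiniteError, match="eigenvalue"):
            spd_distance(bad, np.eye(3))


class TestGeodesic:
    def test_endpoints(self, rng):
        a, b = random_spd(rng, 5), random_spd(rng, 5)
        assert np.allclose(geodesic_point(a, b, 0.0), a, atol=1e-10)
        assert np.allclose(geodesic_point(a, b, 1.0), b, atol=1e-8)

    def test_scalar_midpoint_closed_form(self):
        # 1-D SPD: midpoint of 1 and e^4 is e^2 (geometric mean)
        g = geodesic_point(np.array([[1.0]]), np.array([[np.e**4]]), 0.5)
        assert g[0, 0] == pytest.approx(np.e**2, rel=1e-10)

    @pytest.mark.parametrize("t", [0.1, 0.25, 0.5, 0.8])
    def test_constant_speed_parametrization(self, rng, t):
        a, b = random_spd(rng, 6), random_spd(rng, 6)
        d_ab = spd_distance(a, b)
        assert spd_distance(a, geodesic_point(a, b, t)) == pytest.approx(t * d_ab, abs=1e-6)

    def test_no_extrapolation(self, rng):
        a, b = random_spd(rng, 3), random_spd(rng, 3)
        with pytest.raises(ValueError):
            geodesic_point(a, b, 1.2)

    def test_discretized_path_length_additive(self, rng):
        a, b = random_spd(rng, 4), random_spd(rng, 4)
        path = geodesic(a, b, m=51)
        steps = sum(
            spd_distance(path.samples[i], path.samples[i + 1]) for i in range(50)
        )
        assert steps == pytest.approx(path.length, rel=1e-6)
        assert np.allclose(path.samples[0], a, atol=1e-10)
        assert np.allclose(path.samples[-1], b, atol=1e-8)


class TestPointToGeodesic:
    def test_endpoint_and_on_path_points(self, rng):
        a, b = random_spd(rng, 5), random_spd(rng, 5)
        path = geodesic(a, b)
        d, t = point_to_geodesic(a, path)
        assert d == pytest.approx(0.0, abs=1e-6) and t == pytest.approx(0.0, abs=1e-3)
        d, t = point_to_geodesic(geodesic_point(a, b, 0.5), path)
        assert d == pytest.approx(0.0, abs=1e-6) and t == pytest.approx(0.5, abs=1e-3)

    def test_planted_orthogonal_perturbation_recovered(self, rng):
        # perturb g(0.3) along a tangent direction orthogonal to the path;
        # the minimum distance should equal the planted norm within 2%
        a, b = random_spd(rng, 5), random_spd(rng, 5)
        path = geodesic(a, b)
        t0, h = 0.3, 1e-5
        g = geodesic_point(a, b, t0)
        vel = (geodesic_point(a, b, t0 + h) - geodesic_point(a, b, t0 - h)) / (2 * h)
        g_isqrt = spd_power(g, -0.5)
        g_sqrt = spd_power(g, 0.5)
        u = g_isqrt @ vel @ g_isqrt
        u = (u + u.T) / 2
        v = rng.standard_normal((5, 5))
        v = (v + v.T) / 2
        v -= (np.sum(v * u) / np.sum(u * u)) * u  # Frobenius-orthogonal to velocity
        eps = 0.05
        v *= eps / np.linalg.norm(v)
        p = g_sqrt @ spd_exp(v) @ g_sqrt
        d, t_star = point_to_geodesic(p, path)
        assert d == pytest.approx(eps, rel=0.02)
        assert t_star == pytest.approx(t0, abs=0.02)

    def test_survives_extreme_condition_numbers(self):
        # condition number 1e8 stress fixture: no exceptions, finite output
        a = np.diag(np.logspace(0, -8, 17))
        q, _ = np.linalg.qr(np.random.default_rng(7).standard_normal((17, 17)))
        b = q @ np.diag(np.logspace(0.2, -7.8, 17)) @ q.T
        b = (b + b.T) / 2
        path = geodesic(a, b, m=21)
        d, t = point_to_geodesic(geodesic_point(a, b, 0.4), path)
        assert np.isfinite(path.length) and np.isfinite(d)


class TestFrechetMean:
    def test_single_and_repeated_inputs(self, rng):
        a = random_spd(rng, 4)
        for mats in ([a], [a, a, a]):
            mean, info = frechet_mean(mats)
            assert info["converged"]
            assert np.allclose(mean, a, atol=1e-8)

    def test_commuting_diagonals_give_elementwise_geometric_mean(self):
        mats = [np.diag([1.0, 4.0]), np.diag([9.0, 16.0]), np.diag([3.0, 2.0])]
        mean, info = frechet_mean(mats)
        expected = np.diag([np.exp(np.mean(np.log([1, 9, 3]))), np.exp(np.mean(np.log([4, 16, 2])))])
        assert info["converged"]
        assert np.allclose(mean, expected, atol=1e-8)

    def test_weights_respected(self, rng):
        a, b = random_spd(rng, 3), random_spd(rng, 3)
        mean, _ = frechet_mean([a, b], weights=np.array([1.0, 0.0]))
        assert np.allclose(mean, a, atol=1e-8)
        mid, _ = frechet_mean([a, b])
        assert np.allclose(mid, geodesic_point(a, b, 0.5), atol=1e-7)


class TestRelativeEigenvectors:
    def test_degenerate_pair_flagged(self, rng):
        a = random_spd(rng, 4)
        w, _, degenerate = relative_eigenvectors(a, a)
        assert degenerate
        assert np.allclose(w, 1.0, atol=1e-9)

    def test_rank_one_inflation_direction_recovered(self, rng):
        a = random_spd(rng, 6)
        v = rng.standard_normal(6)
        b = a + 3.0 * np.outer(v, v)
        w, vecs, degenerate = relative_eigenvectors(a, b)
        assert not degenerate
        assert w[0] > 1.0 and np.allclose(w[1:], 1.0, atol=1e-8)
        lead = vecs[:, 0]
        cos = abs(lead @ v) / (np.linalg.norm(lead) * np.linalg.norm(v))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_reciprocal_duality(self, rng):
        a, b = random_spd(rng, 5), random_spd(rng, 5)
        w_ab, _, _ = relative_eigenvectors(a, b)
        w_ba, _, _ = relative_eigenvectors(b, a)
        assert np.allclose(np.sort(w_ab), np.sort(1.0 / w_ba), rtol=1e-8)


class TestMatrixFunctions:
    def test_log_exp_roundtrip(self, rng):
        a = random_spd(rng, 5)
        assert np.allclose(spd_exp(spd_log(a)), a, rtol=1e-9)

    def test_power_consistency(self, rng):
        a = random_spd(rng, 4)
        assert np.allclose(spd_power(a, 0.5) @ spd_power(a, 0.5), a, rtol=1e-9)
        assert np.allclose(spd_power(a, -1.0), np.linalg.inv(a), rtol=1e-8)
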