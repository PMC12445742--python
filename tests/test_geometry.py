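"""Core manifold-geometry estimation and pairwise quantities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from manifoldgeom import (
    DegenerateManifoldError,
    InputError,
    SignalDirectionError,
    estimate_manifold,
    gaussian_tail_error,
    geometry_grid,
    pair_geometry,
    project_2d,
)
from manifoldgeom.dataset import ActivityDataset
from manifoldgeom.geometry import summary_from_spectrum

from conftest import make_gaussian_dataset


def random_summary(rng, V=12, k=5):
    """Random manifold summary with orthonormal directions."""
    Q, _ = np.linalg.qr(rng.standard_normal((V, k)))
    lam = rng.uniform(0.2, 2.0, size=k)
    return summary_from_spectrum(rng.standard_normal(V), lam, Q)


class TestEstimateManifold:
    def test_isotropic_square_configuration(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        summ = estimate_manifold(X)
        assert np.allclose(summ.centroid, [0.0, 0.0])
        assert np.allclose(summ.radii[0], summ.radii[1])
        assert summ.dimensionality == pytest.approx(2.0)

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_equal_variance_coordinates_give_d_equals_k(self, rng, k):
        # k iid coordinates, the rest constant: k equal eigenvalues
        P, V = 4000, k + 5
        X = np.full((P, V), 3.14)
        X[:, :k] = rng.standard_normal((P, k))
        summ = estimate_manifold(X)
        assert summ.dimensionality == pytest.approx(k, rel=0.02)

    def test_matches_bruteforce_eigendecomposition(self, rng):
        X = rng.standard_normal((20, 8))
        summ = estimate_manifold(X)
        # independent oracle: eigendecomposition of the centered covariance
        Xc = X - X.mean(axis=0)
        C = Xc.T @ Xc / X.shape[0]
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        assert np.allclose(summ.centroid, X.mean(axis=0), atol=1e-8)
        assert np.allclose(summ.radii**2, evals[: summ.radii.size], atol=1e-8)
        assert summ.total_radius_sq == pytest.approx(np.trace(C), abs=1e-8)

    def test_summary_invariants(self, rng):
        summ = estimate_manifold(rng.standard_normal((30, 10)))
        gram = summ.directions.T @ summ.directions
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        assert np.all(np.diff(summ.radii) <= 1e-12)
        assert np.all(summ.radii >= 0)
        assert summ.total_radius_sq == pytest.approx(np.sum(summ.radii**2))
        n_nonzero = int(np.sum(summ.radii > 1e-12))
        assert 1.0 <= summ.dimensionality <= n_nonzero + 1e-9

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateManifoldError):
            estimate_manifold(np.ones((5, 3)))
        with pytest.raises(InputError):
            estimate_manifold(np.ones((1, 3)))


class TestParticipationRatioClosedForms:
    def test_two_component_spectrum(self):
        # spectrum (lambda, lambda/2): D = (1.5)^2 / 1.25 = 1.8 exactly
        summ = summary_from_spectrum(
            np.zeros(2), np.array([1.0, 0.5]), np.eye(2)
        )
        assert summ.dimensionality == pytest.approx(1.8, abs=1e-12)

    @pytest.mark.parametrize("k", [1, 2, 10, 50])
    def test_equal_spectrum(self, k):
        summ = summary_from_spectrum(
            np.zeros(k), np.full(k, 0.7), np.eye(k)
        )
        assert summ.dimensionality == pytest.approx(k, abs=1e-10)


class TestGaussianTail:
    def test_fixed_points_and_limits(self):
        assert gaussian_tail_error(0.0) == pytest.approx(0.5)
        assert gaussian_tail_error(50.0) == pytest.approx(0.0, abs=1e-12)
        assert gaussian_tail_error(-50.0) == pytest.approx(1.0, abs=1e-12)

    def test_against_quadrature_oracle(self):
        density = lambda t: np.exp(-t * t / 2) / np.sqrt(2 * np.pi)
        expected, _ = integrate.quad(density, 1.0, np.inf)
        assert gaussian_tail_error(1.0) == pytest.approx(expected, abs=1e-10)

    def test_monotone_and_symmetric(self):
        z = np.linspace(-4, 4, 101)
        h = gaussian_tail_error(z)
        assert np.all(np.diff(h) < 0)
        assert np.allclose(h + h[::-1], 1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(InputError):
            gaussian_tail_error(np.nan)


class TestPairGeometry:
    def test_self_pair_identity(self, rng):
        summ = random_summary(rng)
        pg = pair_geometry(summ, summ, m=5)
        assert pg.signal == pytest.approx(0.0, abs=1e-12)
        assert pg.bias == pytest.approx(0.0, abs=1e-12)
        assert pg.overlap_ab == pytest.approx(1.0 / summ.dimensionality, abs=1e-10)
        assert pg.snr == pytest.approx(0.0, abs=1e-12)
        assert pg.predicted_error == pytest.approx(0.5)

    def test_disjoint_blocks_closed_form(self):
        # manifolds on disjoint coordinate blocks, offset along a third block
        V = 9
        lam_a, lam_b = np.array([0.5, 0.25]), np.array([0.4, 0.1, 0.1])
        Ba = np.zeros((V, 2)); Ba[0, 0] = Ba[1, 1] = 1.0
        Bb = np.zeros((V, 3)); Bb[2, 0] = Bb[3, 1] = Bb[4, 2] = 1.0
        ca, cb = np.zeros(V), np.zeros(V)
        cb[8] = 1.3
        A = summary_from_spectrum(ca, lam_a, Ba)
        B = summary_from_spectrum(cb, lam_b, Bb)
        m = 4
        pg = pair_geometry(A, B, m)
        assert pg.overlap_a == pytest.approx(0.0, abs=1e-12)
        assert pg.overlap_b == pytest.approx(0.0, abs=1e-12)
        assert pg.overlap_ab == pytest.approx(0.0, abs=1e-12)
        expected = 0.5 * (pg.signal + pg.bias / m) * np.sqrt(A.dimensionality * m)
        assert pg.snr == pytest.approx(expected, rel=1e-12)

    def test_spherical_closed_form(self, rng):
        # V equal radii each: S = Delta^2/R_a^2, N^a = S/V, N^ab = 1/V
        V, sigma, delta = 7, 0.6, 1.9
        lam = np.full(V, sigma**2)
        Qa, _ = np.linalg.qr(rng.standard_normal((V, V)))
        Qb, _ = np.linalg.qr(rng.standard_normal((V, V)))
        ca = np.zeros(V)
        cb = np.zeros(V); cb[0] = delta
        A = summary_from_spectrum(ca, lam, Qa)
        B = summary_from_spectrum(cb, lam, Qb)
        pg = pair_geometry(A, B, m=5)
        Ra2 = V * sigma**2
        assert pg.signal == pytest.approx(delta**2 / Ra2, rel=1e-10)
        assert pg.overlap_a == pytest.approx(pg.signal / V, rel=1e-10)
        assert pg.overlap_b == pytest.approx(pg.signal / V, rel=1e-10)
        assert pg.overlap_ab == pytest.approx(1.0 / V, rel=1e-10)

    def test_ordered_pair_asymmetry(self, rng):
        A = random_summary(rng, V=15, k=4)
        B = random_summary(rng, V=15, k=7)
        ab, ba = pair_geometry(A, B, 5), pair_geometry(B, A, 5)
        assert ab.snr != pytest.approx(ba.snr)
        assert ab.bias == pytest.approx(
            (1.0 / (1.0 + ba.bias)) - 1.0, rel=1e-9
        )

    def test_combined_overlap_definition_and_m_dependence(self, rng):
        A = random_summary(rng)
        B = random_summary(rng)
        values = []
        for m in (1, 5, 20):
            pg = pair_geometry(A, B, m)
            assert pg.combined_overlap == pytest.approx(
                (pg.overlap_b + pg.overlap_ab) / m + pg.overlap_a, rel=1e-12
            )
            assert pg.predicted_error == pytest.approx(
                gaussian_tail_error(pg.snr), abs=1e-15
            )
            values.append(pg.combined_overlap)
        assert values[0] > values[1] > values[2]

    def test_errors(self, rng):
        A = random_summary(rng, V=10)
        B = random_summary(rng, V=11)
        with pytest.raises(InputError):
            pair_geometry(A, B, 5)


class TestInvariances:
    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 10_000), c=st.floats(0.01, 100.0))
    def test_scale_invariance(self, seed, c):
        """Multiplying all patterns by c > 0 leaves every pair quantity fixed."""
        r = np.random.default_rng(seed)
        Xa, Xb = r.standard_normal((25, 9)), 0.5 + r.standard_normal((25, 9))
        pg = pair_geometry(estimate_manifold(Xa), estimate_manifold(Xb), 5)
        pg_c = pair_geometry(
            estimate_manifold(c * Xa), estimate_manifold(c * Xb), 5
        )
        for attr in ("signal", "bias", "overlap_a", "overlap_b", "overlap_ab",
                     "combined_overlap", "snr", "predicted_error"):
            assert getattr(pg_c, attr) == pytest.approx(
                getattr(pg, attr), rel=1e-8, abs=1e-10
            )

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rotation_invariance(self, seed):
        r = np.random.default_rng(seed)
        Xa, Xb = r.standard_normal((25, 9)), 0.5 + r.standard_normal((25, 9))
        Q, _ = np.linalg.qr(r.standard_normal((9, 9)))
        pg = pair_geometry(estimate_manifold(Xa), estimate_manifold(Xb), 5)
        pg_q = pair_geometry(
            estimate_manifold(Xa @ Q), estimate_manifold(Xb @ Q), 5
        )
        for attr in ("signal", "bias", "overlap_a", "overlap_b", "overlap_ab",
                     "combined_overlap", "snr", "predicted_error"):
            assert getattr(pg_q, attr) == pytest.approx(
                getattr(pg, attr), rel=1e-7, abs=1e-9
            )


class TestGeometryGrid:
    def test_three_concepts_give_six_ordered_pairs(self, rng):
        ds = make_gaussian_dataset(rng, n_concepts=3)
        grid = geometry_grid(ds, m=5)
        assert len(grid.pairs) == 6
        assert len(grid.concepts) == 3
        assert set(grid.pairs.columns) >= {
            "concept_a", "concept_b", "m", "signal", "bias", "overlap_a",
            "overlap_b", "overlap_ab", "combined_overlap", "snr",
            "predicted_error",
        }

    def test_identical_clouds_have_zero_signal(self, rng):
        X = rng.standard_normal((40, 6))
        ds = ActivityDataset(
            np.vstack([X, X]),
            np.concatenate([np.repeat("a", 40), np.repeat("b", 40)]),
        )
        grid = geometry_grid(ds, m=5)
        assert grid.pairs["signal"].abs().max() < 1e-20

    def test_degenerate_concept_excluded_with_warning(self, rng, caplog):
        X = rng.standard_normal((30, 5))
        Y = 1.0 + rng.standard_normal((30, 5))
        Z = np.ones((30, 5))  # zero variance
        ds = ActivityDataset(
            np.vstack([X, Y, Z]),
            np.concatenate([np.repeat(c, 30) for c in ("a", "b", "z")]),
        )
        with caplog.at_level("WARNING"):
            grid = geometry_grid(ds, m=5)
        assert len(grid.pairs) == 2
        assert "z" in caplog.text


class TestProject2D:
    def test_separated_isotropic_clouds(self, rng):
        ds = make_gaussian_dataset(rng, separation=5.0, n_exemplars=400)
        proj = project_2d(ds, "c1", "c0")
        dx = proj.centroids["c1"][0] - proj.centroids["c0"][0]
        centers_dist = np.linalg.norm(
            ds.concept_patterns("c1").mean(0) - ds.concept_patterns("c0").mean(0)
        )
        assert dx == pytest.approx(centers_dist, rel=1e-10)
        assert abs(proj.centroids["c0"][1]) < 1e-8
        assert abs(proj.centroids["c1"][1]) < 1e-8

    def test_axes_orthonormal(self, rng):
        ds = make_gaussian_dataset(rng)
        proj = project_2d(ds, "c0", "c1")
        assert np.allclose(proj.axes.T @ proj.axes, np.eye(2), atol=1e-10)

    def test_y_axis_maximizes_residual_variance(self, rng):
        ds = make_gaussian_dataset(rng, ambient_dim=8, n_exemplars=100)
        proj = project_2d(ds, "c0", "c1")
        pooled = np.vstack(
            [ds.concept_patterns("c0"), ds.concept_patterns("c1")]
        )
        pooled = pooled - pooled.mean(axis=0)
        x = proj.axes[:, 0]
        var_y = np.var(pooled @ proj.axes[:, 1])
        # oracle: no random direction orthogonal to x beats the y-axis
        for _ in range(300):
            v = rng.standard_normal(8)
            v -= (v @ x) * x
            v /= np.linalg.norm(v)
            assert np.var(pooled @ v) <= var_y * (1 + 1e-9)

    def test_coincident_centroids_error(self, rng):
        X = rng.standard_normal((30, 4))
        ds = ActivityDataset(
            np.vstack([X, X]),
            np.concatenate([np.repeat("a", 30), np.repeat("b", 30)]),
        )
        with pytest.raises(SignalDirectionError):
            project_2d(ds, "a", "b")
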