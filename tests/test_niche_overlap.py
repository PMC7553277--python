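"""PCA-env density grids, Schoener's D, permutation tests, dynamics."""

import numpy as np
import pytest

from nichedyn.niche_overlap import (E_SUPPORT_FRAC, TRUNC, DensityGrid,
                                    density_grid, dynamics_category,
                                    equivalence_test, niche_dynamics,
                                    pooled_bounds, schoener_d,
                                    silverman_bandwidth, similarity_test)


# ----------------------------------------------------------------------
# independent brute-force oracles

def kde_oracle(points, x, y, hx, hy):
    """Direct double-loop truncated product-Gaussian density at (x, y)."""
    total = 0.0
    for px, py in points:
        dx, dy = (x - px) / hx, (y - py) / hy
        if abs(dx) <= TRUNC and abs(dy) <= TRUNC:
            total += (np.exp(-0.5 * dx * dx) / (hx * np.sqrt(2 * np.pi))
                      * np.exp(-0.5 * dy * dy) / (hy * np.sqrt(2 * np.pi)))
    return total / len(points)


def occupancy_oracle(o, e):
    support = e > E_SUPPORT_FRAC * e.max()
    z = np.zeros_like(o)
    for i in range(o.shape[0]):
        for j in range(o.shape[1]):
            if support[i, j]:
                z[i, j] = o[i, j] / e[i, j]
    return z / z.sum()


def schoener_oracle(z1, z2):
    return 1.0 - 0.5 * sum(abs(a - b)
                           for a, b in zip(z1.ravel(), z2.ravel()))


def dynamics_oracle(g1, g2):
    analog = (g1.e > 0) & (g2.e > 0)
    s_num = e_den = u_num = u_den = 0.0
    for i in range(g1.R):
        for j in range(g1.R):
            if not analog[i, j]:
                continue
            e_den += g2.z[i, j]
            u_den += g1.z[i, j]
            if g1.z[i, j] > 0:
                s_num += g2.z[i, j]
            if g2.z[i, j] == 0:
                u_num += g1.z[i, j]
    S = s_num / e_den
    return 1 - S, S, u_num / u_den


def manual_grid(z, e=None, R=None, bounds=(0.0, 1.0, 0.0, 1.0)):
    z = np.asarray(z, dtype=float)
    R = R or z.shape[0]
    if e is None:
        e = np.ones_like(z)
    return DensityGrid(R=R, bounds=bounds, o=z.copy(), e=np.asarray(e, float),
                       z=z / z.sum(), bandwidths=(0.1, 0.1, 0.1, 0.1))


def cluster(center, n, sd=0.15, seed=0):
    rng = np.random.default_rng(seed)
    return rng.normal(center, sd, size=(n, 2))


# ----------------------------------------------------------------------

class TestDensityGrid:
    def test_matches_bruteforce_kernel_sum(self):
        rng = np.random.default_rng(0)
        occ = rng.normal(0, 1, size=(15, 2))
        bg = rng.normal(0, 1.5, size=(60, 2))
        g = density_grid(occ, bg, R=10)
        xs, ys = g.cell_centers()
        hx, hy = g.bandwidths[0], g.bandwidths[1]
        idx = rng.integers(0, 10, size=(25, 2))
        for i, j in idx:
            assert g.o[i, j] == pytest.approx(
                kde_oracle(occ, xs[i], ys[j], hx, hy), abs=1e-9)
        assert np.allclose(g.z, occupancy_oracle(g.o, g.e), atol=1e-9)

    def test_tight_cluster_peaks_at_centroid_cell(self):
        occ = cluster((0.3, -0.2), 30, sd=0.02, seed=1)
        bg = np.random.default_rng(2).uniform(-1, 1, size=(500, 2))
        g = density_grid(occ, bg, R=50)
        xs, ys = g.cell_centers()
        i, j = np.unravel_index(np.argmax(g.z), g.z.shape)
        cx, cy = occ.mean(axis=0)
        assert abs(xs[i] - cx) <= (g.bounds[1] - g.bounds[0]) / 50
        assert abs(ys[j] - cy) <= (g.bounds[3] - g.bounds[2]) / 50

    def test_occurrences_like_background_give_flat_occupancy(self):
        rng = np.random.default_rng(3)
        bg = rng.uniform(0, 1, size=(5000, 2))
        occ = rng.uniform(0, 1, size=(5000, 2))
        g = density_grid(occ, bg, R=25)
        # occupancy over the well-sampled interior is near-uniform
        interior = g.e > 0.5 * np.median(g.e[g.e > 0])
        vals = g.z[interior & (g.z > 0)]
        assert vals.max() / vals.min() < 3.0

    def test_z_normalized_and_nonnegative(self):
        g = density_grid(cluster((0, 0), 20, seed=4),
                         cluster((0, 0), 200, sd=1.0, seed=5), R=30)
        assert g.z.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(g.o >= 0) and np.all(g.e >= 0) and np.all(g.z >= 0)

    def test_occurrence_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            density_grid(np.array([[5.0, 5.0]] * 5),
                         cluster((0, 0), 50, seed=6), R=10,
                         bounds=(-1, 1, -1, 1))

    def test_constant_coordinates_rejected(self):
        occ = np.zeros((6, 2))
        with pytest.raises(ValueError, match="bandwidth"):
            density_grid(occ, cluster((0, 0), 50, seed=7), R=10)

    def test_minimum_occurrences_enforced(self):
        with pytest.raises(ValueError):
            density_grid(cluster((0, 0), 4, seed=8),
                         cluster((0, 0), 50, seed=9), R=10)

    def test_silverman_bandwidth_formula(self):
        x = np.random.default_rng(10).normal(0, 2.0, size=200)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        expected = 0.9 * min(x.std(ddof=1), iqr / 1.349) * 200 ** -0.2
        assert silverman_bandwidth(x) == pytest.approx(expected)


class TestSchoenerD:
    def test_identical_grids_give_one(self):
        g = density_grid(cluster((0, 0), 30, seed=11),
                         cluster((0, 0), 200, sd=1.0, seed=12), R=40)
        assert schoener_d(g, g) == 1.0

    def test_disjoint_supports_give_zero(self):
        bounds = (-2, 30, -2, 30)
        bg = np.vstack([cluster((0, 0), 300, sd=0.5, seed=13),
                        cluster((25, 25), 300, sd=0.5, seed=14)])
        g1 = density_grid(cluster((0, 0), 40, sd=0.2, seed=15), bg, 60, bounds)
        g2 = density_grid(cluster((25, 25), 40, sd=0.2, seed=16), bg, 60, bounds)
        assert schoener_d(g1, g2) == 0.0

    def test_hand_computed_half_overlap(self):
        g1 = manual_grid(np.array([[0.5, 0.5], [0.0, 0.0]]))
        g2 = manual_grid(np.array([[0.25, 0.25], [0.25, 0.25]]))
        assert schoener_d(g1, g2) == pytest.approx(0.5)

    def test_symmetry_and_permutation_invariance(self):
        rng = np.random.default_rng(17)
        z1, z2 = rng.random((2, 5, 5))
        g1, g2 = manual_grid(z1), manual_grid(z2)
        assert schoener_d(g1, g2) == pytest.approx(schoener_d(g2, g1), abs=1e-12)
        perm = rng.permutation(25)
        p1 = manual_grid(z1.ravel()[perm].reshape(5, 5))
        p2 = manual_grid(z2.ravel()[perm].reshape(5, 5))
        assert schoener_d(p1, p2) == pytest.approx(schoener_d(g1, g2), abs=1e-12)

    def test_mismatched_grids_rejected(self):
        g1 = manual_grid(np.ones((4, 4)))
        g2 = manual_grid(np.ones((5, 5)))
        with pytest.raises(ValueError):
            schoener_d(g1, g2)


class TestEquivalence:
    def test_identical_sets_cannot_reject(self):
        occ = cluster((0, 0), 25, seed=18)
        bg = cluster((0, 0), 150, sd=1.0, seed=19)
        p = equivalence_test(occ, occ, bg, bg, nrep=49, seed=0, R=25)
        assert p == 1.0

    def test_disjoint_clusters_reject_at_floor(self):
        # backgrounds span both clusters, so mixed null splits always
        # produce overlapping occupancies (D_null > 0) while D_obs = 0
        rng = np.random.default_rng(20)
        bg1 = rng.uniform(-2, 27, size=(600, 2))
        bg2 = rng.uniform(-2, 27, size=(600, 2))
        occ1 = cluster((0, 0), 100, sd=0.2, seed=22)
        occ2 = cluster((25, 25), 100, sd=0.2, seed=23)
        p = equivalence_test(occ1, occ2, bg1, bg2, nrep=99, seed=1, R=40)
        assert p == pytest.approx(0.01)

    def test_p_in_valid_range_and_deterministic(self):
        occ1 = cluster((0, 0), 20, seed=24)
        occ2 = cluster((0.2, 0), 20, seed=25)
        bg = cluster((0, 0), 100, sd=1.0, seed=26)
        p1 = equivalence_test(occ1, occ2, bg, bg, nrep=19, seed=2, R=20)
        p2 = equivalence_test(occ1, occ2, bg, bg, nrep=19, seed=2, R=20)
        assert p1 == p2
        assert 1 / 20 <= p1 <= 1.0

    def test_nrep_validated(self):
        occ = cluster((0, 0), 10, seed=27)
        with pytest.raises(ValueError):
            equivalence_test(occ, occ, occ, occ, nrep=0, seed=0)


class TestSimilarity:
    def test_concentrated_matching_niche_is_significant(self):
        # a niche sitting on the same spot as the reference, within a wide
        # background: random recentring almost never reproduces the overlap
        bg = np.random.default_rng(28).uniform(-5, 5, size=(2000, 2))
        occ = cluster((0, 0), 60, sd=0.3, seed=29)
        bounds = pooled_bounds(bg)
        g_ref = density_grid(occ, bg, 40, bounds)
        p = similarity_test(g_ref, occ, bg, nrep=99, seed=3)
        assert p <= 0.05

    def test_zero_overlap_never_significant(self):
        bounds = (-2, 30, -2, 30)
        bg = np.vstack([cluster((0, 0), 400, sd=0.8, seed=30),
                        cluster((25, 25), 400, sd=0.8, seed=31)])
        g1 = density_grid(cluster((0, 0), 40, sd=0.2, seed=32), bg, 50, bounds)
        occ2 = cluster((25, 25), 40, sd=0.2, seed=33)
        p = similarity_test(g1, occ2, bg, nrep=49, seed=4)
        assert p == 1.0  # every null D >= D_obs = 0

    def test_p_range_and_determinism(self):
        bg = np.random.default_rng(34).uniform(-3, 3, size=(500, 2))
        occ1 = cluster((0.5, 0.5), 30, sd=0.4, seed=35)
        occ2 = cluster((-0.5, -0.5), 30, sd=0.4, seed=36)
        bounds = pooled_bounds(bg)
        g1 = density_grid(occ1, bg, 30, bounds)
        p1 = similarity_test(g1, occ2, bg, nrep=49, seed=5)
        p2 = similarity_test(g1, occ2, bg, nrep=49, seed=5)
        assert p1 == p2
        assert 1 / 50 <= p1 <= 1.0


class TestNicheDynamics:
    def test_identical_occupancies(self):
        g = density_grid(cluster((0, 0), 30, seed=37),
                         cluster((0, 0), 200, sd=1.0, seed=38), R=30)
        E, S, U = niche_dynamics(g, g)
        assert E == pytest.approx(0.0, abs=1e-12)
        assert S == pytest.approx(1.0, abs=1e-12)
        assert U == 0.0

    def test_disjoint_niches_in_shared_environment(self):
        # both backgrounds span both clusters: fully analogous environment,
        # occupancies disjoint
        rng = np.random.default_rng(39)
        bg1 = rng.uniform(-2, 27, size=(2000, 2))
        bg2 = rng.uniform(-2, 27, size=(2000, 2))
        bounds = pooled_bounds(bg1, bg2)
        g1 = density_grid(cluster((0, 0), 40, sd=0.2, seed=40), bg1, 50, bounds)
        g2 = density_grid(cluster((25, 25), 40, sd=0.2, seed=41), bg2, 50, bounds)
        E, S, U = niche_dynamics(g1, g2)
        assert (E, S, U) == (1.0, 0.0, 1.0)

    def test_expansion_stability_sum_to_one(self):
        rng = np.random.default_rng(42)
        for seed in range(3):
            bg = rng.uniform(-3, 3, size=(600, 2))
            bounds = pooled_bounds(bg)
            g1 = density_grid(cluster((0.5, 0), 25, sd=0.5, seed=seed), bg,
                              30, bounds)
            g2 = density_grid(cluster((-0.5, 0.3), 25, sd=0.5, seed=seed + 50),
                              bg, 30, bounds)
            E, S, U = niche_dynamics(g1, g2)
            assert E + S == pytest.approx(1.0, abs=1e-9)
            assert 0 <= E <= 1 and 0 <= U <= 1

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(43)
        bg = rng.uniform(-3, 3, size=(300, 2))
        bounds = pooled_bounds(bg)
        g1 = density_grid(cluster((0.4, 0), 15, sd=0.5, seed=44), bg, 10, bounds)
        g2 = density_grid(cluster((-0.4, 0.2), 15, sd=0.5, seed=45), bg, 10,
                          bounds)
        assert np.allclose(niche_dynamics(g1, g2), dynamics_oracle(g1, g2),
                           atol=1e-9)

    def test_empty_analogous_environment_rejected(self):
        z = np.ones((4, 4))
        g1 = manual_grid(z, e=np.kron([[1, 0], [0, 0]], np.ones((2, 2))))
        g2 = manual_grid(z, e=np.kron([[0, 0], [0, 1]], np.ones((2, 2))))
        with pytest.raises(ValueError, match="analogous"):
            niche_dynamics(g1, g2)


class TestDynamicsCategory:
    @pytest.mark.parametrize("value,label", [
        (0.81, "high"), (0.39, "low"), (0.5, "partial"), (0.7, "partial"),
        (0.71, "high"), (0.0, "low"), (1.0, "high"),
    ])
    def test_thresholds(self, value, label):
        assert dynamics_category(value) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            dynamics_category(1.1)
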