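import heapq

import numpy as np
import pytest

from unbindkit.feature_select import FeatureMatrix
from unbindkit.landscape import (
    assign_states,
    fit_gmm_fes,
    frame_weights_from_bias,
    kramers_rate_from_hessians,
    kramers_rate_network,
    mfpt_matrix,
    neb_mep,
    select_n_clusters,
    weighted_pca,
)
from unbindkit.toy_dynamics import MixtureSurface


def grid_minimax_saddle_energy(surface, a, b, lo, hi, n=400):
    """Brute-force saddle energy: minimax path cost on a dense grid."""
    xs = np.linspace(lo[0], hi[0], n)
    ys = np.linspace(lo[1], hi[1], n)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    e = surface.energy(np.column_stack([xx.ravel(), yy.ravel()])).reshape(n, n)
    ia = (np.abs(xs - a[0]).argmin(), np.abs(ys - a[1]).argmin())
    ib = (np.abs(xs - b[0]).argmin(), np.abs(ys - b[1]).argmin())
    dist = np.full(e.shape, np.inf)
    dist[ia] = e[ia]
    h = [(e[ia], ia)]
    while h:
        d, (i, j) = heapq.heappop(h)
        if d > dist[i, j]:
            continue
        if (i, j) == ib:
            return d
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < n and 0 <= nj < n:
                nd = max(d, e[ni, nj])
                if nd < dist[ni, nj]:
                    dist[ni, nj] = nd
                    heapq.heappush(h, (nd, (ni, nj)))
    return dist[ib]


class TestFrameWeights:
    def test_zero_bias_uniform(self):
        w = frame_weights_from_bias(np.zeros(5), beta=1.0)
        assert np.allclose(w, 0.2)

    def test_hand_normalized_exponentials(self):
        w = frame_weights_from_bias(np.array([0.0, np.log(3.0)]), beta=1.0)
        assert np.allclose(w, [0.25, 0.75])

    def test_sum_to_one_even_for_huge_bias(self, rng):
        w = frame_weights_from_bias(rng.uniform(0, 2000, 100), beta=1.0)
        assert np.isfinite(w).all() and w.sum() == pytest.approx(1.0)


class TestWeightedPCA:
    def test_uniform_weights_reduce_to_standard_pca(self, rng):
        x = rng.standard_normal((200, 5)) @ rng.standard_normal((5, 5))
        p = weighted_pca(FeatureMatrix(x, [f"f{i}" for i in range(5)]))
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc / len(x))
        order = np.argsort(evals)[::-1]
        ref = evecs[:, order]
        assert np.allclose(np.abs(p.loadings), np.abs(ref), atol=1e-8)
        assert np.all(np.diff(p.explained_variance) <= 1e-12)

    def test_rank_one_data_single_component(self, rng):
        u = rng.standard_normal(100)
        x = np.outer(u, [1.0, 2.0, -1.0])
        with pytest.warns(UserWarning, match="zero-variance"):
            p = weighted_pca(FeatureMatrix(x, list("abc")))
        assert p.explained_variance[0] == pytest.approx(1.0)

    def test_integer_weights_equal_frame_replication(self, rng):
        x = rng.standard_normal((30, 4))
        w = np.array([1.0, 2.0, 3.0] * 10)
        pw = weighted_pca(FeatureMatrix(x, list("abcd"), frame_weights=w))
        xrep = np.repeat(x, w.astype(int), axis=0)
        pr = weighted_pca(FeatureMatrix(xrep, list("abcd")))
        assert np.allclose(np.abs(pw.loadings), np.abs(pr.loadings))
        assert np.allclose(pw.explained_variance, pr.explained_variance)


class TestClusterCount:
    def test_three_planted_blobs(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        pts = np.vstack([c + 0.5 * rng.standard_normal((80, 2)) for c in centers])
        assert select_n_clusters(pts, range(2, 8), seed=0) == 3

    def test_deterministic_for_seed(self, rng):
        pts = rng.standard_normal((200, 2))
        k1 = select_n_clusters(pts, range(2, 6), seed=4)
        k2 = select_n_clusters(pts, range(2, 6), seed=4)
        assert k1 == k2

    def test_k_range_validated(self, rng):
        with pytest.raises(ValueError):
            select_n_clusters(rng.standard_normal((10, 2)), [15], seed=0)


class TestGMMFES:
    def sample_mixture(self, surface, n, rng):
        comp = rng.choice(len(surface.weights), n, p=surface.weights)
        return np.array(
            [
                rng.multivariate_normal(surface.means[c], surface.covariances[c])
                for c in comp
            ]
        )

    def test_parameter_recovery(self, rng):
        truth = MixtureSurface(
            [(0.5, [-2.0, 0.0], np.eye(2) * 0.3), (0.5, [2.0, 0.5], np.eye(2) * 0.4)]
        )
        x = self.sample_mixture(truth, 3000, rng)
        fes = fit_gmm_fes(x, None, k=2, beta=1.0, seed=0, assign_dims=2)
        order = np.argsort(fes.means[:, 0])
        se = np.sqrt(0.4 / 1500)
        for got, want in zip(fes.means[order], truth.means):
            assert np.all(np.abs(got - want) < 3 * 3 * se)
        assert np.allclose(np.sort(fes.weights), [0.5, 0.5], atol=0.05)

    def test_energy_at_well_separated_mode(self, rng):
        truth = MixtureSurface(
            [(0.7, [-5.0, 0.0], np.eye(2) * 0.2), (0.3, [5.0, 0.0], np.eye(2) * 0.2)]
        )
        # closed form at the mode: cross-term negligible at 10 sigma apart
        for i in (0, 1):
            w, mu, cov = truth.weights[i], truth.means[i], truth.covariances[i]
            expected = -np.log(w / (2 * np.pi * np.sqrt(np.linalg.det(cov))))
            assert truth.energy(mu) == pytest.approx(expected, abs=1e-8)

    def test_bias_reweighting_recovers_unbiased_weights(self, rng):
        """A sample tilted by a known bias, reweighted by exp(beta V),
        recovers the unbiased mixture weights."""
        truth = MixtureSurface(
            [(0.7, [-2.0, 0.0], np.eye(2) * 0.2), (0.3, [2.0, 0.0], np.eye(2) * 0.2)]
        )
        # biased sampling: draw with flipped weights, V(x) chosen to undo it
        biased = MixtureSurface(
            [(0.3, [-2.0, 0.0], np.eye(2) * 0.2), (0.7, [2.0, 0.0], np.eye(2) * 0.2)]
        )
        x = self.sample_mixture(biased, 6000, rng)
        v = truth.energy(x) - biased.energy(x)  # beta V = log(p_b/p_u)... sign below
        w = frame_weights_from_bias(-v, beta=1.0)
        fes = fit_gmm_fes(x, w, k=2, beta=1.0, seed=0, assign_dims=2)
        order = np.argsort(fes.means[:, 0])
        assert np.allclose(fes.weights[order], [0.7, 0.3], atol=0.05)

    def test_assign_states_and_tie_break(self):
        surf = MixtureSurface(
            [(0.5, [-1.0], [[0.1]]), (0.5, [1.0], [[0.1]])]
        )
        labels = assign_states(np.array([[-1.0], [1.0], [0.0]]), surf)
        assert labels[0] == 0 and labels[1] == 1
        assert labels[2] == 0  # exact tie resolves to the lowest index

    def test_assignment_consistent_with_weights_on_self_sample(self, rng):
        truth = MixtureSurface(
            [(0.6, [-2.0], [[0.2]]), (0.4, [2.0], [[0.2]])]
        )
        comp = rng.choice(2, 5000, p=truth.weights)
        x = truth.means[comp] + rng.standard_normal((5000, 1)) * np.sqrt(0.2)
        labels = assign_states(x, truth)
        frac = np.bincount(labels, minlength=2) / 5000
        assert np.allclose(frac, truth.weights, atol=0.03)


class TestNEB:
    def test_symmetric_saddle_at_midpoint(self):
        s = MixtureSurface(
            [(0.5, [-1.0, 0.0], np.eye(2) * 0.2), (0.5, [1.0, 0.0], np.eye(2) * 0.2)]
        )
        m1 = s.refine_minimum([-1, 0])
        m2 = s.refine_minimum([1, 0])
        p = neb_mep(s, m1, m2, n_images=32)
        assert p.converged
        assert np.allclose(p.saddle, [0.0, 0.0], atol=1e-3)
        assert p.barrier_forward == pytest.approx(p.barrier_backward, rel=1e-6)

    def test_asymmetric_saddle_matches_grid_oracle(self, asym_2d_surface):
        s = asym_2d_surface
        a = s.refine_minimum([-1.0, -0.3])
        b = s.refine_minimum([1.1, 0.4])
        p = neb_mep(s, a, b, n_images=32)
        assert p.converged
        e_oracle = grid_minimax_saddle_energy(s, a, b, [-2.5, -2.0], [2.5, 2.0])
        e_neb = s.energy(p.saddle)
        assert abs(e_neb - e_oracle) < 0.01 * p.barrier_forward
        # energy maximum sits at the reported saddle image
        assert p.saddle_index == int(np.argmax(p.energies))

    def test_degenerate_start_equals_end(self, asym_2d_surface):
        a = asym_2d_surface.refine_minimum([-1.0, -0.3])
        p = neb_mep(asym_2d_surface, a, a)
        assert p.barrier_forward == 0.0 and len(p.images) == 1

    def test_non_minimum_endpoint_rejected(self, asym_2d_surface):
        with pytest.raises(ValueError, match="minimum"):
            neb_mep(asym_2d_surface, [0.0, 0.0], [1.1, 0.4])


class TestRates:
    def test_arrhenius_factor_exact(self):
        lmin = np.array([2.0, 3.0])
        lsad = np.array([-1.0, 4.0])
        k1 = kramers_rate_from_hessians(lmin, lsad, 5.0, beta=1.0)
        k2 = kramers_rate_from_hessians(lmin, lsad, 5.0 + 0.7, beta=1.0)
        assert k2 / k1 == pytest.approx(np.exp(-0.7), rel=1e-12)

    def test_saddle_must_have_one_negative_mode(self):
        with pytest.raises(ValueError, match="negative"):
            kramers_rate_from_hessians([1.0], [2.0], 1.0, 1.0)
        with pytest.raises(ValueError, match="negative"):
            kramers_rate_from_hessians([1.0, 1.0], [-1.0, -2.0], 1.0, 1.0)

    def test_three_state_chain_matches_linear_solve_oracle(self):
        rates = np.array([[0.0, 2.0, 0.0], [1.0, 0.0, 0.5], [0.0, 0.25, 0.0]])
        m = mfpt_matrix(rates)
        q = np.array([[-2.0, 2.0], [1.0, -1.5]])
        sol = np.linalg.solve(q, [-1.0, -1.0])
        assert m[0, 2] == pytest.approx(sol[0], rel=1e-12)
        assert m[1, 2] == pytest.approx(sol[1], rel=1e-12)
        assert np.all(m[np.isfinite(m)] >= 0)

    def test_symmetric_double_well_equal_forward_backward(self):
        s = MixtureSurface(
            [(0.5, [-1.0, 0.0], np.eye(2) * 0.15), (0.5, [1.0, 0.0], np.eye(2) * 0.15)]
        )
        minima = np.array([s.refine_minimum([-1, 0]), s.refine_minimum([1, 0])])
        paths = {(0, 1): neb_mep(s, minima[0], minima[1])}
        net = kramers_rate_network(s, minima, paths)
        assert net.rates[0, 1] == pytest.approx(net.rates[1, 0], rel=1e-3)
        assert net.mfpt[0, 1] == pytest.approx(net.mfpt[1, 0], rel=1e-3)

    def test_rate_limiting_edge_invariant_under_uniform_rescaling(self):
        rates = np.array([[0.0, 2.0, 0.0], [1.0, 0.0, 0.5], [0.0, 0.25, 0.0]])
        m1 = mfpt_matrix(rates)
        m2 = mfpt_matrix(10.0 * rates)
        assert np.unravel_index(np.nanargmax(m1), m1.shape) == np.unravel_index(
            np.nanargmax(m2), m2.shape
        )

    def test_morphine_topology_final_step_rate_limiting(self):
        """OS <-> VRS <-> DS with barrier ordering OS->VRS < VRS->DS and
        VRS->OS << VRS->DS: the final dissociation edge is rate-limiting."""
        s = MixtureSurface(
            [
                (0.60, [0.0, 0.0], np.eye(2) * 0.08),    # OS (ground)
                (0.32, [1.4, 0.6], np.eye(2) * 0.10),    # VRS (vestibule)
                (0.08, [3.4, 0.0], np.eye(2) * 0.30),    # DS (dissociated)
            ],
            beta=1.0,
        )
        minima = np.array([s.refine_minimum(m) for m in s.means])
        e = s.energy(minima)
        paths = {
            (0, 1): neb_mep(s, minima[0], minima[1]),
            (1, 2): neb_mep(s, minima[1], minima[2]),
            (0, 2): neb_mep(s, minima[0], minima[2]),
        }
        b_os_vrs = s.energy(paths[(0, 1)].saddle) - e[0]
        b_vrs_os = s.energy(paths[(0, 1)].saddle) - e[1]
        b_vrs_ds = s.energy(paths[(1, 2)].saddle) - e[1]
        assert b_vrs_os < b_os_vrs < b_vrs_ds          # the planted ordering
        net = kramers_rate_network(s, minima, paths)
        # OS--DS is only reachable through VRS, so the direct path is not
        # an edge; the rate-limiting step is the final dissociation VRS->DS
        assert not net.adjacency[0, 2]
        assert net.rate_limiting_edge == (1, 2)
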