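import numpy as np
import pytest

from unbindkit.toy_dynamics import (
    Box,
    LinearCV,
    MetadParams,
    MixtureSurface,
    UnbindingCriterion,
    estimate_committor,
    run_langevin,
    run_metadynamics,
    run_unbinding,
)


@pytest.fixture(scope="module")
def harmonic():
    # single Gaussian: E(x) = x^2/2 at beta=2, so Boltzmann variance 1/2
    return MixtureSurface([(1.0, [0.0], [[0.5]])], beta=2.0)


class TestMixtureSurface:
    def test_energy_matches_log_density(self, asym_2d_surface):
        x = np.array([0.2, -0.1])
        e = asym_2d_surface.energy(x)
        assert np.isclose(e, -asym_2d_surface.log_density(x) / asym_2d_surface.beta)

    def test_gradient_and_hessian_match_finite_differences(self, asym_2d_surface):
        x0 = np.array([0.3, -0.2])
        eps = 1e-6
        g_num = np.array(
            [
                (
                    asym_2d_surface.energy(x0 + eps * e)
                    - asym_2d_surface.energy(x0 - eps * e)
                )
                / (2 * eps)
                for e in np.eye(2)
            ]
        )
        assert np.allclose(asym_2d_surface.gradient(x0), g_num, atol=1e-6)
        h_num = np.array(
            [
                (
                    asym_2d_surface.gradient(x0 + 1e-5 * e)
                    - asym_2d_surface.gradient(x0 - 1e-5 * e)
                )
                / 2e-5
                for e in np.eye(2)
            ]
        )
        assert np.allclose(asym_2d_surface.hessian(x0), h_num, atol=1e-6)

    def test_invalid_components_rejected(self):
        with pytest.raises(ValueError):
            MixtureSurface([(0.5, [0.0], [[1.0]])])  # weights must sum to 1
        with pytest.raises(np.linalg.LinAlgError):
            MixtureSurface([(1.0, [0.0, 0.0], [[1.0, 2.0], [2.0, 1.0]])])


class TestLangevin:
    def test_boltzmann_variance_in_harmonic_well(self, harmonic):
        traj = run_langevin(harmonic, step=0.005, n_steps=400_000, seed=1)
        x = traj.positions()[5000:, 0]
        # target variance 1/(beta*kappa) = 0.5; autocorrelation-aware SE
        tau_corr = 1.0 / (1.0 * 0.005)  # relaxation steps ~ gamma/(kappa dt)
        n_eff = x.size / (2 * tau_corr)
        se = 0.5 * np.sqrt(2.0 / n_eff)
        assert abs(x.var() - 0.5) < 3 * se

    def test_same_seed_bit_identical(self, harmonic):
        a = run_langevin(harmonic, 0.01, 2000, seed=42)
        b = run_langevin(harmonic, 0.01, 2000, seed=42)
        assert np.array_equal(a.positions(), b.positions())
        assert np.all(a.bias_at_frame == 0)

    def test_friction_rescales_dynamics_not_measure(self, harmonic):
        bins = np.linspace(-2.5, 2.5, 21)
        h = []
        for gamma, steps in ((1.0, 400_000), (10.0, 4_000_000)):
            traj = run_langevin(
                harmonic, step=0.005 * gamma, n_steps=int(steps / gamma),
                friction=gamma, seed=3, stride=4,
            )
            x = traj.positions()[1000:, 0]
            h.append(np.histogram(x, bins=bins, density=True)[0])
        assert np.abs(h[0] - h[1]).max() < 0.08

    def test_nonfinite_start_rejected(self, harmonic):
        with pytest.raises(ValueError):
            run_langevin(harmonic, 0.01, 10, x0=[np.nan])


class TestMetadynamics:
    def test_zero_hill_height_identical_to_langevin(self, harmonic):
        cv = LinearCV.coordinate(1)
        params = MetadParams(
            hill_height=0.0, hill_width=0.1, deposition_interval=0.1,
            grid_min=(-3.0,), grid_max=(3.0,),
        )
        a = run_metadynamics(harmonic, cv, params, 0.01, 3000, seed=9)
        b = run_langevin(harmonic, 0.01, 3000, seed=9)
        assert np.array_equal(a.positions(), b.positions())

    def test_interval_must_be_multiple_of_step(self, harmonic):
        cv = LinearCV.coordinate(1)
        params = MetadParams(
            hill_width=0.1, deposition_interval=0.25, grid_min=(-3.0,),
            grid_max=(3.0,),
        )
        with pytest.raises(ValueError, match="multiple"):
            run_metadynamics(harmonic, cv, params, 0.01 * 1.5, 100, seed=0)

    def test_well_tempered_height_schedule(self, double_well):
        """Recorded hill heights follow h*exp(-V/((gamma-1)kT)) with V the
        accumulated bias at the new hill's centre (replayed independently)."""
        cv = LinearCV.coordinate(1)
        params = MetadParams(
            hill_height=0.5, hill_width=0.1, bias_factor=5.0,
            deposition_interval=0.5, grid_min=(-3.0,), grid_max=(3.0,),
        )
        traj = run_metadynamics(
            double_well, cv, params, 0.005, 200_000, seed=4, x0=[-1.0], stride=10
        )
        log = traj.hill_log
        assert len(log) == 2000
        t, centers, heights = log[:, 0], log[:, 1], log[:, 2]
        wt_denom = (params.bias_factor - 1.0) * (1.0 / double_well.beta)
        # independent replay of the bias sum from exact Gaussians
        for i in (1, 10, 100, 500, 1999):
            v = (
                heights[:i]
                * np.exp(-0.5 * ((centers[i] - centers[:i]) / 0.1) ** 2)
            ).sum()
            expected = 0.5 * np.exp(-v / wt_denom)
            assert heights[i] == pytest.approx(expected, rel=0.03)
        # heights decay overall as the well fills
        assert heights[:20].mean() > 3 * heights[-200:].mean()

    def test_bias_enables_barrier_crossing(self, double_well):
        cv = LinearCV.coordinate(1)
        params = MetadParams(
            hill_height=0.5, hill_width=0.12, bias_factor=10.0,
            deposition_interval=0.25, grid_min=(-2.5,), grid_max=(2.5,),
        )
        n = 50_000
        biased = run_metadynamics(
            double_well, cv, params, 0.005, n, seed=8, x0=[-1.0]
        )
        unbiased = run_langevin(double_well, 0.005, n, seed=8, x0=[-1.0])

        def first_crossing(traj):
            above = traj.positions()[:, 0] > 0.5
            return int(np.argmax(above)) if above.any() else n + 1

        # the ~8 kT barrier is crossed, and far earlier than without bias
        assert first_crossing(biased) <= n
        assert 5 * first_crossing(biased) < first_crossing(unbiased)
        assert biased.positions().min() < -0.5 and biased.positions().max() > 0.5

    def test_reweighted_histogram_recovers_boltzmann(self, double_well):
        """Final-bias reweighting of a WT run restores the unbiased density."""
        cv = LinearCV.coordinate(1)
        params = MetadParams(
            hill_height=0.4, hill_width=0.12, bias_factor=8.0,
            deposition_interval=0.25, grid_min=(-2.5,), grid_max=(2.5,),
        )
        traj = run_metadynamics(
            double_well, cv, params, 0.005, 600_000, seed=5, x0=[-1.0], stride=5
        )
        x = traj.positions()[:, 0]
        v_final = traj.final_bias_at(x[:, None])
        w = np.exp(double_well.beta * (v_final - v_final.max()))
        bins = np.linspace(-1.8, 1.8, 13)
        hist, edges = np.histogram(x, bins=bins, weights=w, density=True)
        centers = 0.5 * (edges[1:] + edges[:-1])
        p_ref = np.exp(double_well.log_density(centers[:, None]))
        p_ref /= p_ref.sum() * np.diff(edges)[0]
        mask = p_ref > 0.05
        assert np.all(np.abs(hist[mask] / p_ref[mask] - 1.0) < 0.5)


class TestUnbinding:
    cv = LinearCV.coordinate(1)

    def params(self):
        return MetadParams(
            hill_height=0.4, hill_width=0.12, bias_factor=12.0,
            deposition_interval=0.5, grid_min=(-2.5,), grid_max=(2.5,),
        )

    def test_start_inside_absorbing_region_stops_immediately(self, double_well):
        stop = UnbindingCriterion(threshold=1.0)
        res = run_unbinding(
            double_well, self.cv, self.params(), stop, 1000, seed=0,
            step=0.005, x0=[1.5],
        )
        assert res.stop_time == 0.0 and not res.censored

    def test_max_steps_reached_is_censored_not_dropped(self, double_well):
        stop = UnbindingCriterion(threshold=1.0)
        res = run_unbinding(
            double_well, self.cv, self.params(), stop, 1, seed=0,
            step=0.005, x0=[-1.0],
        )
        assert res.censored and res.stop_time is None

    def test_fifteen_replicas_all_dissociate(self, double_well):
        stop = UnbindingCriterion(threshold=1.0)
        stops = []
        for r in range(15):
            res = run_unbinding(
                double_well, self.cv, self.params(), stop, 2_000_000,
                seed=100 + r, step=0.002, x0=[-1.0], stride=5,
            )
            assert not res.censored
            stops.append(res.stop_time)
        assert len(stops) == 15 and all(t > 0 for t in stops)


class TestCommittor:
    def test_half_at_symmetric_saddle(self, double_well):
        res = estimate_committor(
            double_well, [0.0], Box([-1.3], [-0.7]), Box([0.7], [1.3]),
            n_shots=200, step=0.005, seed=5, max_steps=200_000,
        )
        assert res.n_unresolved == 0
        assert abs(res.probability - 0.5) < 2 * res.stderr + 1e-12

    def test_deep_in_basin_a_commits_to_a(self, double_well):
        res = estimate_committor(
            double_well, [-1.0], Box([-1.3], [-0.7]), Box([0.7], [1.3]),
            n_shots=50, step=0.005, seed=6, max_steps=200_000,
        )
        assert res.probability < 0.05

    def test_monotone_along_reaction_coordinate(self, double_well):
        probs = []
        for x in (-0.5, -0.2, 0.0, 0.2, 0.5):
            res = estimate_committor(
                double_well, [x], Box([-1.3], [-0.7]), Box([0.7], [1.3]),
                n_shots=150, step=0.005, seed=7, max_steps=200_000,
            )
            probs.append(res.probability)
        # non-decreasing within binomial noise
        assert all(b >= a - 0.12 for a, b in zip(probs, probs[1:]))
        assert probs[0] < 0.25 and probs[-1] > 0.75

    def test_overlapping_basins_rejected(self, double_well):
        with pytest.raises(ValueError, match="disjoint"):
            estimate_committor(
                double_well, [0.0], Box([-1.0], [0.1]), Box([0.0], [1.0]),
                n_shots=10, step=0.005,
            )

    def test_budget_overflow_counted_unresolved(self, double_well):
        res = estimate_committor(
            double_well, [0.0], Box([-1.3], [-1.2]), Box([1.2], [1.3]),
            n_shots=20, step=0.005, seed=8, max_steps=10,
        )
        assert res.n_unresolved == 20
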