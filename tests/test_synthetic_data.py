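"""Ground-truth generators: chain sampling, analytic MFPT, toy Langevin,
structure fixtures and dose-response curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from bindkin import synthetic_data as syn
from bindkin.structgeom import measure_chi

R_KCAL = 1.98720e-3


def two_state(p01, p10, lag_time=1.0):
    return syn.GroundTruthChain(
        np.array([[1 - p01, p01], [p10, 1 - p10]]), ("a", "b"), lag_time
    )


class TestChainSampling:
    def test_absorbing_identity_gives_constant_sequence(self):
        chain = syn.GroundTruthChain(np.eye(2), ("a", "b"))
        (traj,) = syn.sample_discrete_trajectories(
            chain, 1, 50, start_distribution=[1, 0], seed=0
        )
        assert (traj == 0).all()

    def test_deterministic_period_two_alternation(self):
        chain = two_state(1.0, 1.0)
        (traj,) = syn.sample_discrete_trajectories(
            chain, 1, 20, start_distribution=[1, 0], seed=0
        )
        assert np.array_equal(traj, np.tile([0, 1], 10))

    def test_transition_frequency_matches_probability(self):
        # law of large numbers: frequency count is the independent oracle
        chain = two_state(0.3, 0.3)
        (traj,) = syn.sample_discrete_trajectories(
            chain, 1, 10**6, start_distribution=[1, 0], seed=1
        )
        from0 = traj[:-1] == 0
        freq = (traj[1:][from0] == 1).mean()
        assert freq == pytest.approx(0.3, abs=0.002)

    def test_empirical_matrix_within_three_binomial_se(self):
        chain = syn.default_chain()
        (traj,) = syn.sample_discrete_trajectories(
            chain, 1, 10**6,
            start_distribution=chain.stationary_distribution(), seed=2,
        )
        t = chain.transition_matrix
        for i in range(5):
            rows = traj[:-1] == i
            n = rows.sum()
            for j in range(5):
                p_hat = (traj[1:][rows] == j).mean()
                se = np.sqrt(max(t[i, j] * (1 - t[i, j]), 1e-12) / n)
                assert abs(p_hat - t[i, j]) <= 3 * se + 1e-9

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError):
            syn.GroundTruthChain(np.array([[0.5, 0.6], [0.5, 0.5]]), ("a", "b"))

    def test_substreams_stable_when_adding_trajectories(self):
        chain = syn.default_chain()
        few = syn.sample_discrete_trajectories(chain, 2, 100, seed=5)
        more = syn.sample_discrete_trajectories(chain, 4, 100, seed=5)
        for a, b in zip(few, more):
            assert np.array_equal(a, b)


class TestAnalyticMfpt:
    def test_certain_transition_is_one_step(self):
        assert syn.analytic_mfpt(two_state(1.0, 1.0), 0, 1).steps == pytest.approx(1.0)

    def test_geometric_waiting_time(self):
        res = syn.analytic_mfpt(two_state(0.1, 0.5, lag_time=0.5), 0, 1)
        assert res.steps == pytest.approx(10.0)
        assert res.time == pytest.approx(5.0)

    def test_three_state_linear_chain_by_hand(self):
        # m1 = 1 + 0.5 m1 -> 2; m0 = 1 + 0.5 m0 + 0.5 m1 -> 4
        t = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.0, 0.0, 1.0]])
        chain = syn.GroundTruthChain(t, ("a", "b", "c"))
        assert syn.analytic_mfpt(chain, 0, 2).steps == pytest.approx(4.0)

    def test_source_equals_target_is_zero(self):
        assert syn.analytic_mfpt(syn.default_chain(), "bulk", "bulk").steps == 0.0

    def test_unreachable_target_raises(self):
        chain = syn.GroundTruthChain(np.eye(2), ("a", "b"))
        with pytest.raises(ValueError):
            syn.analytic_mfpt(chain, 1, 0)

    def test_agrees_with_simulated_first_passage(self):
        t = np.array([[0.6, 0.4, 0.0], [0.2, 0.5, 0.3], [0.1, 0.0, 0.9]])
        chain = syn.GroundTruthChain(t, ("a", "b", "c"))
        truth = syn.analytic_mfpt(chain, 0, 2).steps
        trajs = syn.sample_discrete_trajectories(
            chain, 10_000, 200, start_distribution=[1, 0, 0], seed=3
        )
        fpts = []
        for traj in trajs:
            hits = np.flatnonzero(traj == 2)
            if len(hits):
                fpts.append(hits[0])
        fpts = np.asarray(fpts, dtype=float)
        assert len(fpts) > 9_900  # essentially every run reaches the target
        se = fpts.std(ddof=1) / np.sqrt(len(fpts))
        assert abs(fpts.mean() - truth) <= 3 * se


class TestToyBinding:
    def test_zero_temperature_stays_at_minimum(self):
        params = syn.ToyBindingParams(
            well_centers=[[0.0, 0.0, 0.0]], well_depths=[3.0],
            temperature=0.0, n_steps=100, seed=0,
        )
        traj = syn.simulate_toy_binding(params, receptor_sites=[[0.0, 0.0, 0.0]])
        lig = traj.coordinates[:, -1, :]
        assert np.allclose(lig, 0.0, atol=1e-12)

    def test_flat_bottom_restraint_confines(self):
        params = syn.ToyBindingParams(
            well_centers=[[0.0, 0.0, 0.0]], well_depths=[0.0],
            diffusion_coefficient=0.05, flat_bottom_k=5.0,
            n_steps=100_000, seed=7,
        )
        traj = syn.simulate_toy_binding(params, receptor_sites=[[0.0, 0.0, 0.0]])
        lig = traj.coordinates[:, -1, :]
        b = np.asarray(params.flat_bottom_bounds)
        lo, hi = b[0::2] - 2.0, b[1::2] + 2.0
        inside = ((lig >= lo) & (lig <= hi)).all(axis=1)
        assert inside.mean() >= 0.999

    def test_double_well_matches_boltzmann_weights(self):
        # histogram vs closed-form Boltzmann weight, independent quadrature oracle
        depths, centers, width = [1.5, 0.9], [[0.0], [6.0]], 1.5
        temperature = 298.0
        params = syn.ToyBindingParams(
            well_centers=centers, well_depths=depths, temperature=temperature,
            diffusion_coefficient=0.1, flat_bottom_bounds=(-6.0, 12.0),
            flat_bottom_k=5.0, well_width=width, n_steps=200_000, seed=11,
        )
        traj = syn.simulate_toy_binding(params, receptor_sites=[[0.0]])
        x = traj.coordinates[:, -1, 0]

        kt = R_KCAL * temperature

        def boltz(z):
            u = -sum(d * np.exp(-((z - c[0]) ** 2) / (2 * width**2))
                     for d, c in zip(depths, centers))
            return np.exp(-u / kt)

        window = 1.5
        z1 = quad(boltz, -window, window)[0]
        z2 = quad(boltz, 6 - window, 6 + window)[0]
        expected = z1 / z2

        n_blocks = 20
        blocks = np.array_split(x, n_blocks)
        ratios = []
        for b in blocks:
            n1 = (np.abs(b - 0.0) < window).sum()
            n2 = (np.abs(b - 6.0) < window).sum()
            if n2 > 0:
                ratios.append(n1 / n2)
        ratios = np.asarray(ratios)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - expected) <= 3 * se

    def test_zero_diffusion_rejected(self):
        params = syn.ToyBindingParams(
            well_centers=[[0.0, 0.0, 0.0]], well_depths=[1.0],
            diffusion_coefficient=0.0, n_steps=10,
        )
        with pytest.raises(ValueError):
            syn.simulate_toy_binding(params, receptor_sites=[[0.0, 0.0, 0.0]])

    def test_identical_seed_bitwise_reproducible(self):
        params = syn.ToyBindingParams(
            well_centers=[[0.0, 0.0, 0.0]], well_depths=[2.0],
            n_steps=500, seed=13,
        )
        a = syn.simulate_toy_binding(params, receptor_sites=[[1.0, 0.0, 0.0]])
        b = syn.simulate_toy_binding(params, receptor_sites=[[1.0, 0.0, 0.0]])
        assert np.array_equal(a.coordinates, b.coordinates)


class TestPheFixture:
    def test_chi1_zero_is_cis_coplanar(self):
        s = syn.make_phe_fixture(0.0, 120.0)
        n, ca, cb, cg = s.coords[:4]
        # coplanar: CG lies in the N-CA-CB plane, cis side
        normal = np.cross(ca - n, cb - ca)
        assert abs(np.dot(cg - cb, normal / np.linalg.norm(normal))) < 1e-9

    @settings(max_examples=50, deadline=None)
    @given(
        chi1=st.floats(min_value=-179.999, max_value=180.0),
        chi2=st.floats(min_value=-179.999, max_value=180.0),
    )
    def test_roundtrip_identity_on_angle_domain(self, chi1, chi2):
        obs = measure_chi(syn.make_phe_fixture(chi1, chi2), 1)
        assert obs.chi1 == pytest.approx(chi1, abs=1e-6)
        assert obs.chi2 == pytest.approx(chi2, abs=1e-6)

    def test_out_of_range_angle_rejected(self):
        with pytest.raises(ValueError):
            syn.make_phe_fixture(-180.0, 0.0)


class TestDoseResponse:
    def test_midpoint_and_low_dose_asymptote(self):
        truth = syn.AssayTruth(ic50=5e-9)
        df = syn.generate_dose_response(truth, [5e-9, 1e-15])
        assert df.inhibition_pct.iloc[0] == pytest.approx(50.0)
        assert df.inhibition_pct.iloc[1] == pytest.approx(0.0, abs=1e-3)

    def test_noise_free_curve_recovers_ic50(self):
        from bindkin.affinity import fit_ic50

        truth = syn.AssayTruth(ic50=5e-9)
        conc = np.logspace(-10, -6, 8)
        df = syn.generate_dose_response(truth, conc)
        fit = fit_ic50(df.concentration_M, df.inhibition_pct)
        assert not fit.flagged
        assert fit.ic50 == pytest.approx(5e-9, rel=1e-6)

    def test_noise_is_seeded(self):
        truth = syn.AssayTruth(ic50=5e-9, noise_sd=3.0, seed=4)
        a = syn.generate_dose_response(truth, [1e-9, 1e-8])
        b = syn.generate_dose_response(truth, [1e-9, 1e-8])
        assert np.array_equal(a.inhibition_pct, b.inhibition_pct)
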