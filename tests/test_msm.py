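"""Discretization, reversible estimation, PCCA lumping, bulk split, cores."""

import numpy as np
import pytest

from bindkin import msm, synthetic_data as syn
from bindkin.msm import MacrostateMap


class TestCluster:
    def test_separated_points_each_own_cluster(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
        data = np.repeat(pts, 50, axis=0)
        model, (dtraj,) = msm.cluster([data], k=4, seed=0)
        # zero within-cluster distance: every point sits on its center
        assigned = model.centers[dtraj]
        assert np.linalg.norm(assigned - data, axis=1).max() < 1e-10

    def test_two_blobs_fully_separated(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 0.1, size=(500, 2))
        b = rng.normal(20.0, 0.1, size=(500, 2))
        data = np.concatenate([a, b])
        _, (dtraj,) = msm.cluster([data], k=2, seed=0)
        assert len(np.unique(dtraj[:500])) == 1
        assert len(np.unique(dtraj[500:])) == 1
        assert dtraj[0] != dtraj[-1]

    def test_same_seed_identical_centers(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((2000, 3))
        m1, _ = msm.cluster([data], k=10, seed=42)
        m2, _ = msm.cluster([data], k=10, seed=42)
        assert np.array_equal(m1.centers, m2.centers)

    def test_k_exceeding_frames_raises(self):
        with pytest.raises(ValueError):
            msm.cluster([np.zeros((5, 2))], k=10, seed=0)


class TestCountMatrix:
    def test_lag_one_enumeration(self):
        c = msm.count_matrix([[0, 0, 1, 1]], lag=1)
        assert c.tolist() == [[1.0, 1.0], [0.0, 1.0]]

    def test_lag_two_enumeration(self):
        c = msm.count_matrix([[0, 1, 0, 1]], lag=2)
        assert c.tolist() == [[1.0, 0.0], [0.0, 1.0]]

    def test_duplicated_trajectory_doubles_counts(self):
        d = [0, 1, 2, 1, 0, 2]
        assert np.array_equal(
            msm.count_matrix([d, d], lag=1), 2 * msm.count_matrix([d], lag=1)
        )

    def test_lag_not_shorter_than_any_trajectory_raises(self):
        with pytest.raises(ValueError):
            msm.count_matrix([[0, 1]], lag=5)


class TestTrimErgodic:
    def test_fully_connected_retained(self):
        c = np.ones((3, 3))
        active, _ = msm.trim_ergodic(c)
        assert active.tolist() == [0, 1, 2]

    def test_sink_state_removed(self):
        c = np.array([[5.0, 1.0, 1.0], [1.0, 5.0, 0.0], [0.0, 0.0, 0.0]])
        active, _ = msm.trim_ergodic(c)
        assert active.tolist() == [0, 1]

    def test_largest_of_two_blocks_kept(self):
        c = np.zeros((5, 5))
        for i, j in [(0, 1), (1, 2), (2, 0), (3, 4), (4, 3)]:
            c[i, j] = 1.0
        active, sub = msm.trim_ergodic(c)
        assert active.tolist() == [0, 1, 2]
        assert sub.shape == (3, 3)


class TestReversibleEstimation:
    def test_symmetric_counts_closed_form(self):
        model = msm.estimate_reversible(np.array([[90.0, 10.0], [10.0, 90.0]]))
        assert model.transition_matrix == pytest.approx(
            np.array([[0.9, 0.1], [0.1, 0.9]]), abs=1e-9
        )
        assert model.stationary_distribution == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_single_state_chain(self):
        model = msm.estimate_reversible(np.array([[7.0]]))
        assert model.transition_matrix.tolist() == [[1.0]]
        assert model.stationary_distribution.tolist() == [1.0]

    def test_recovers_known_reversible_chain(self):
        chain = syn.default_chain()
        (traj,) = syn.sample_discrete_trajectories(
            chain, 1, 300_000,
            start_distribution=chain.stationary_distribution(), seed=0,
        )
        c = msm.count_matrix([traj], lag=1)
        active, c_act = msm.trim_ergodic(c)
        model = msm.estimate_reversible(c_act)
        t_true = chain.transition_matrix[np.ix_(active, active)]
        n_i = c_act.sum(axis=1)
        se = np.sqrt(np.maximum(t_true * (1 - t_true), 1e-12) / n_i[:, None])
        assert (np.abs(model.transition_matrix - t_true) <= 3 * se + 1e-6).all()

    def test_detailed_balance_holds(self):
        rng = np.random.default_rng(3)
        c = rng.integers(1, 50, size=(6, 6)).astype(float)  # asymmetric counts
        model = msm.estimate_reversible(c)
        flux = model.stationary_distribution[:, None] * model.transition_matrix
        assert np.allclose(flux, flux.T, rtol=1e-8, atol=1e-14)


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        # T = [[0.75,0.25],[0.25,0.75]] has lambda2 = 0.5
        rng = np.random.default_rng(4)
        model = msm.estimate_reversible(np.array([[75.0, 25.0], [25.0, 75.0]]))
        ts = model.implied_timescales(1)
        assert ts[0] == pytest.approx(1.0 / np.log(2.0), rel=1e-10)

    def test_markovian_data_plateaus(self):
        chain = syn.default_chain()
        trajs = syn.sample_discrete_trajectories(
            chain, 20, 20_000,
            start_distribution=chain.stationary_distribution(), seed=5,
        )
        table = msm.implied_timescales(trajs, lags=[1, 2, 5, 10], n_timescales=2)
        t2 = table["t2"].to_numpy()
        assert (np.abs(t2 - t2[0]) / t2[0] < 0.2).all()

    def test_negative_eigenvalue_gives_nan_with_warning(self):
        model = msm.estimate_reversible(np.array([[0.0, 50.0], [50.0, 0.0]]))
        with pytest.warns(UserWarning):
            ts = model.implied_timescales(1)
        assert np.isnan(ts[0])


def block_chain():
    """Two metastable 2-state blocks with weak inter-block exchange."""
    t = np.array([
        [0.50, 0.45, 0.05, 0.00],
        [0.45, 0.50, 0.00, 0.05],
        [0.05, 0.00, 0.50, 0.45],
        [0.00, 0.05, 0.45, 0.50],
    ])
    c = 10_000 * t  # symmetric, so already reversible counts
    return msm.estimate_reversible(c)


class TestPcca:
    def test_block_structure_recovered(self):
        model = block_chain()
        mmap = msm.pcca_lump(model, 2)
        assert mmap.labels[0] == mmap.labels[1]
        assert mmap.labels[2] == mmap.labels[3]
        assert mmap.labels[0] != mmap.labels[2]

    def test_n_macro_equals_n_states_is_identity_partition(self):
        model = block_chain()
        mmap = msm.pcca_lump(model, 4)
        assert len(np.unique(mmap.labels)) == 4

    def test_memberships_row_normalized(self):
        model = block_chain()
        for n_macro in (2, 3, 4):
            mmap = msm.pcca_lump(model, n_macro)
            assert mmap.memberships.sum(axis=1) == pytest.approx(1.0, abs=1e-10)
            assert (mmap.memberships >= -1e-12).all()

    def test_too_many_macrostates_raises(self):
        with pytest.raises(ValueError):
            msm.pcca_lump(block_chain(), 5)


class TestSplitBulk:
    def make_map(self, n_clusters=3, n_macro=2):
        chi = np.tile([1.0, 0.0], (n_clusters, 1))
        return MacrostateMap(
            n_macro=n_macro, active_set=np.arange(n_clusters),
            labels=np.zeros(n_clusters, dtype=np.int64), memberships=chi,
        )

    def test_pure_bulk_cluster_moved(self):
        mmap = self.make_map()
        dtrajs = [np.array([0, 0, 1, 1, 2, 2])]
        flags = [np.array([0, 0, 1, 1, 1, 0])]
        out = msm.split_bulk(mmap, dtrajs, flags)
        assert out.n_macro == 3 and out.bulk_id == 2
        assert out.labels[0] == 2       # 100% flag=0 -> bulk
        assert out.labels[1] == 0       # 0% flag=0 -> stays
        assert out.labels[2] == 2       # 50% tie -> bulk

    def test_minor_bulk_fraction_stays(self):
        mmap = self.make_map(n_clusters=1)
        dtrajs = [np.zeros(10, dtype=int)]
        flags = [np.array([0] + [1] * 9)]
        out = msm.split_bulk(mmap, dtrajs, flags)
        assert out.labels[0] == 0

    def test_no_bulk_frames_warns_and_keeps_map(self):
        mmap = self.make_map()
        dtrajs = [np.array([0, 1, 2])]
        flags = [np.ones(3, dtype=int)]
        with pytest.warns(UserWarning):
            out = msm.split_bulk(mmap, dtrajs, flags)
        assert out is mmap

    def test_generated_bulk_emissions_recovered(self):
        # state 0 emits flag 0 with p=0.95; its clusters must all go to bulk
        rng = np.random.default_rng(6)
        states = rng.integers(0, 3, size=5000)
        clusters = states.copy()  # one cluster per true state
        flags = np.where(
            states == 0, rng.random(5000) > 0.95, rng.random(5000) > 0.05
        ).astype(int)
        mmap = self.make_map(n_clusters=3)
        out = msm.split_bulk(mmap, [clusters], [flags])
        assert out.labels[0] == out.bulk_id
        assert out.labels[1] != out.bulk_id and out.labels[2] != out.bulk_id


class TestCoreAssignment:
    def make_map(self):
        # 4 clusters, 2 macrostates; clusters 0,1 in macro 0 / 2,3 in macro 1
        chi = np.array([[1.0, 0.0], [0.8, 0.2], [0.15, 0.85], [0.0, 1.0]])
        return MacrostateMap(
            n_macro=2, active_set=np.arange(4),
            labels=np.array([0, 0, 1, 1]), memberships=chi,
        )

    def test_all_above_threshold_matches_crisp(self):
        mmap = self.make_map()
        dtrajs = [np.array([0, 3, 0, 3])]
        core_dtrajs, core_clusters, core_macros = msm.core_assign(
            mmap, dtrajs, membership_threshold=0.9
        )
        assert core_clusters.tolist() == [0, 3]
        assert core_macros[core_dtrajs[0]].tolist() == [0, 1, 0, 1]

    def test_milestoning_fills_excursions(self):
        mmap = self.make_map()
        # core-A, non-core, non-core, core-B -> A A A B
        dtrajs = [np.array([0, 1, 2, 3])]
        core_dtrajs, _, core_macros = msm.core_assign(mmap, dtrajs, 0.9)
        assert core_macros[core_dtrajs[0]].tolist() == [0, 0, 0, 1]

    def test_leading_non_core_frames_dropped(self):
        mmap = self.make_map()
        dtrajs = [np.array([1, 2, 3, 0])]
        core_dtrajs, _, core_macros = msm.core_assign(mmap, dtrajs, 0.9)
        assert len(core_dtrajs[0]) == 2
        assert core_macros[core_dtrajs[0]].tolist() == [1, 0]

    def test_empty_core_falls_back_with_warning(self):
        chi = np.array([[0.7, 0.3], [0.6, 0.4], [0.1, 0.9]])
        mmap = MacrostateMap(
            n_macro=2, active_set=np.arange(3),
            labels=np.array([0, 0, 1]), memberships=chi,
        )
        with pytest.warns(UserWarning, match="empty core"):
            _, core_clusters, _ = msm.core_assign(mmap, [np.array([0, 1, 2])], 0.9)
        assert 0 in core_clusters  # max-membership cluster of macro 0

    def test_flag_consistency_suppresses_single_frame_teleports(self):
        chi = np.array([[1.0, 0.0], [0.0, 1.0]])
        mmap = MacrostateMap(
            n_macro=2, active_set=np.arange(2),
            labels=np.array([0, 1]), memberships=chi, bulk_id=1,
        )
        # cluster 1 is bulk; frame 2 claims bulk but its flag says in-contact
        dtrajs = [np.array([0, 0, 1, 0, 0])]
        flags = [np.array([1, 1, 1, 1, 1])]
        core_dtrajs, _, core_macros = msm.core_assign(
            mmap, dtrajs, 0.9, bulk_flags=flags
        )
        assert core_macros[core_dtrajs[0]].tolist() == [0, 0, 0, 0, 0]

    def test_core_reestimation_never_adds_macrostates(self):
        chain = syn.default_chain()
        trajs = syn.sample_discrete_trajectories(chain, 10, 3000, seed=7)
        c = msm.count_matrix(trajs, lag=1)
        active, c_act = msm.trim_ergodic(c)
        model = msm.estimate_reversible(c_act)
        mmap = msm.pcca_lump(model, 3)
        core_model, _, core_macros = msm.core_msm(mmap, trajs, lag=1)
        assert len(np.unique(core_macros)) <= 3


class TestRespawnSelection:
    def test_weights_inverse_to_counts(self):
        counts = np.array([100.0, 10.0, 1.0])
        w = 1.0 / (1.0 + counts)
        w /= w.sum()
        draws = msm.select_respawn_states(counts, 10_000, seed=0)
        freq = np.bincount(draws, minlength=3) / 10_000
        se = np.sqrt(w * (1 - w) / 10_000)
        assert (np.abs(freq - w) <= 3 * se).all()

    def test_single_cluster_always_selected(self):
        assert (msm.select_respawn_states(np.array([5.0]), 20, seed=1) == 0).all()

    def test_all_zero_counts_uniform(self):
        draws = msm.select_respawn_states(np.zeros(4), 20_000, seed=2)
        freq = np.bincount(draws, minlength=4) / 20_000
        se = np.sqrt(0.25 * 0.75 / 20_000)
        assert (np.abs(freq - 0.25) <= 3 * se).all()
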