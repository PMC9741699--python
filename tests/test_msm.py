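import numpy as np
import pytest

from metadiss import msm as M
from metadiss.errors import InvalidParameterError, TopologyError


def sample_chain(T, n, seed=0, start=0):
    rng = np.random.default_rng(seed)
    cdf = T.cumsum(axis=1)
    states = np.empty(n, dtype=int)
    states[0] = start
    u = rng.random(n)
    for t in range(1, n):
        states[t] = np.searchsorted(cdf[states[t - 1]], u[t])
    return states


@pytest.fixture(scope="module")
def chain3():
    T = np.array([[0.95, 0.04, 0.01], [0.03, 0.94, 0.03], [0.02, 0.05, 0.93]])
    return T, sample_chain(T, 100_000, seed=0)


class TestFeaturize:
    def test_constant_pair_constant_inverse(self, diss_traj_1000, dimer):
        fm = M.featurize_inverse_ca_distances(
            diss_traj_1000, dimer.interface_pairs
        )
        assert fm.X.shape == (1000, len(dimer.interface_pairs))
        assert np.all(fm.X > 0)

    def test_inverse_of_known_distance(self):
        from metadiss.descriptors import Trajectory
        from conftest import make_frame
        import biotite.structure as struc

        frame = make_frame([
            ("a", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)),
            ("b", 1, "GLY", "CA", "C", (10.0, 0.0, 0.0)),
        ])
        traj = Trajectory(stack=struc.stack([frame] * 3))
        fm = M.featurize_inverse_ca_distances(traj, [(1, 1)])
        np.testing.assert_allclose(fm.X, 0.1)

    def test_missing_ca_names_residue(self, diss_traj_1000):
        with pytest.raises(TopologyError, match="999"):
            M.featurize_inverse_ca_distances(diss_traj_1000, [(999, 1)])

    def test_separation_decreases_inverse_distances(self, diss_traj_1000, dimer):
        fm = M.featurize_inverse_ca_distances(diss_traj_1000, dimer.interface_pairs)
        assert np.all(fm.X[:500].mean(axis=0) > fm.X[800:].mean(axis=0))


class TestTica:
    def test_two_state_jump_process_separated(self):
        rng = np.random.default_rng(0)
        s = (rng.random(5000) < 0.005).cumsum() % 2
        X = np.column_stack(
            [s * 2.0 - 1.0 + rng.normal(0, 0.3, 5000)]
            + [rng.normal(0, 1, 5000) for _ in range(4)]
        )
        model = M.tica(X, lag=10, n_components=2)
        y = model.transform(X)[:, 0]
        pooled = np.sqrt((y[s == 0].var() + y[s == 1].var()) / 2)
        assert abs(y[s == 0].mean() - y[s == 1].mean()) > 3 * pooled

    def test_white_noise_eigenvalues_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4000, 5))
        model = M.tica(X, lag=5, n_components=5)
        assert np.all(np.abs(model.eigenvalues) < 3 / np.sqrt(4000))

    def test_eigenvalues_bounded_and_sorted(self, chain3):
        _, states = chain3
        X = np.column_stack([states == i for i in range(3)]).astype(float)
        X += np.random.default_rng(2).normal(0, 0.01, X.shape)
        model = M.tica(X, lag=1, n_components=2)
        assert np.all(model.eigenvalues <= 1 + 1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_zero_lag_rejected(self):
        with pytest.raises(InvalidParameterError):
            M.tica(np.random.default_rng(0).normal(size=(100, 2)), lag=0)

    def test_zero_variance_column_removed(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.normal(size=500), np.full(500, 7.0)])
        model = M.tica(X, lag=2, n_components=1)
        assert list(model.removed_columns) == [1]
        assert model.transform(X).shape == (500, 1)


class TestKmeans:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        blobs = np.concatenate(
            [rng.normal(c, 0.05, (50, 2)) for c in ((0, 0), (5, 5), (-5, 5))]
        )
        labels = M.kmeans_microstates(blobs, 3, seed=1)
        truth = np.repeat([0, 1, 2], 50)
        # same partition up to label permutation
        for t in range(3):
            assert len(set(labels[truth == t])) == 1
        assert len(set(labels)) == 3

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(200, 2))
        a = M.kmeans_microstates(y, 10, seed=5)
        b = M.kmeans_microstates(y, 10, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_k_exceeding_distinct_points(self):
        y = np.zeros((50, 1))
        with pytest.raises(InvalidParameterError):
            M.kmeans_microstates(y, 90)


class TestEstimateMsm:
    def test_recovers_generator_matrix(self, chain3):
        T, states = chain3
        model = M.estimate_msm(states, lag=1)
        assert np.abs(model.transition_matrix - T).max() < 0.02

    def test_second_timescale_close_to_truth(self, chain3):
        T, states = chain3
        model = M.estimate_msm(states, lag=1)
        lam2 = np.sort(np.linalg.eigvals(T).real)[-2]
        assert model.implied_timescales[0] == pytest.approx(
            -1 / np.log(lam2), rel=0.05
        )

    def test_rows_stochastic_and_detailed_balance(self, chain3):
        _, states = chain3
        model = M.estimate_msm(states, lag=1)
        np.testing.assert_allclose(model.transition_matrix.sum(axis=1), 1.0, atol=1e-10)
        flux = model.stationary_distribution[:, None] * model.transition_matrix
        np.testing.assert_allclose(flux, flux.T, atol=1e-8)

    def test_absorbing_state_excluded(self, chain3):
        _, states = chain3
        appended = np.r_[states, [3] * 50]  # entered once, never left
        model = M.estimate_msm(appended, lag=1)
        assert 3 not in model.active_set

    def test_no_cross_trajectory_transitions(self):
        # two trajectories pinned in different states never mix
        model = M.estimate_msm([np.zeros(100, int), np.ones(100, int)], lag=1)
        assert model.n_states == 1  # largest connected set is a single state

    def test_estimation_error_scales_inverse_sqrt(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        errors = []
        for n in (2000, 8000, 32000):
            reps = [
                np.abs(
                    M.estimate_msm(sample_chain(T, n, seed=s), lag=1).transition_matrix
                    - T
                ).max()
                for s in range(8)
            ]
            errors.append(np.mean(reps))
        assert errors[2] < errors[1] < errors[0]
        assert errors[2] < errors[0] / 2.0  # ~1/sqrt(16) ideally


class TestTimescaleScan:
    def test_markovian_chain_flat_timescales(self, chain3):
        _, states = chain3
        table = M.implied_timescales_scan(states, [1, 2, 4, 8], n_timescales=1)
        t2 = table["t2"].to_numpy()
        assert np.all(np.abs(t2 / t2[0] - 1.0) < 0.25)

    def test_output_sorted_by_lag(self, chain3):
        _, states = chain3
        table = M.implied_timescales_scan(states, [8, 1, 4], n_timescales=1)
        assert list(table["lag"]) == [1, 4, 8]

    def test_timescales_positive(self, chain3):
        _, states = chain3
        table = M.implied_timescales_scan(states, [1, 2], n_timescales=2)
        vals = table[["t2", "t3"]].to_numpy()
        assert np.all(vals[np.isfinite(vals)] > 0)


def block_msm():
    """Three 2-state blocks with detailed-balance-consistent weak coupling.

    Macrostate weights are designed as 0.97 / 0.02 / 0.01 (the dominant
    bound basin of a dissociating dimer plus two rare states)."""
    eps = 1e-3
    blocks = [
        np.array([[0.98, 0.02], [0.02, 0.98]]),
        np.array([[0.95, 0.05], [0.05, 0.95]]),
        np.array([[0.90, 0.10], [0.10, 0.90]]),
    ]
    pi = np.array([0.485, 0.485, 0.01, 0.01, 0.005, 0.005])
    T = np.zeros((6, 6))
    for i, b in enumerate(blocks):
        T[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] = b
    block_of = np.repeat(np.arange(3), 2)
    for i in range(6):
        for j in range(6):
            if block_of[i] != block_of[j]:
                T[i, j] = eps * pi[j]  # flux pi_i * eps * pi_j is symmetric
    T /= T.sum(axis=1, keepdims=True)
    return M.MSMModel(
        lag=1, transition_matrix=T, stationary_distribution=pi,
        active_set=np.arange(6), counts=T, implied_timescales=np.array([]),
    )


class TestPcca:
    def test_blocks_recovered_exactly(self):
        model = block_msm()
        chi, crisp = M.pcca(model, 3)
        groups = [set(np.flatnonzero(crisp == m)) for m in range(3)]
        assert sorted(map(sorted, groups)) == [[0, 1], [2, 3], [4, 5]]

    def test_memberships_row_stochastic(self):
        chi, _ = M.pcca(block_msm(), 3)
        np.testing.assert_allclose(chi.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(chi >= 0)

    def test_macrostate_populations_recovered(self):
        model = block_msm()
        chi, crisp = M.pcca(model, 3)
        pops, _ = M.macrostate_kinetics(model, chi)
        assert pops.sum() == pytest.approx(1.0)
        assert np.abs(np.sort(pops)[::-1] - np.array([0.97, 0.02, 0.01])).max() < 0.01


class TestKinetics:
    def test_two_state_closed_form(self):
        p, q, lag = 0.2, 0.05, 3
        T = np.array([[1 - p, p], [q, 1 - q]])
        pi = np.array([q / (p + q), p / (p + q)])
        model = M.MSMModel(lag=lag, transition_matrix=T, stationary_distribution=pi,
                           active_set=np.arange(2), counts=T,
                           implied_timescales=np.array([]))
        pops, mfpt = M.macrostate_kinetics(model, np.eye(2))
        assert mfpt[0, 1] == pytest.approx(lag / p)
        assert mfpt[1, 0] == pytest.approx(lag / q)
        assert pops.sum() == pytest.approx(1.0)

    def test_mfpt_ordering_matches_rates(self):
        model = block_msm()
        chi, _ = M.pcca(model, 3)
        pops, mfpt = M.macrostate_kinetics(model, chi)
        # leaving the heavy macrostate takes longer than returning to it
        heavy = int(np.argmax(pops))
        others = [m for m in range(3) if m != heavy]
        for o in others:
            assert mfpt[heavy, o] > mfpt[o, heavy]


class TestCkTest:
    def test_markovian_within_bands(self, chain3):
        _, states = chain3
        model = M.estimate_msm(states, lag=1)
        ck = M.ck_test(states, model, factors=[1, 2, 3, 5], n_macrostates=2)
        assert ck.within_bands().all()
        assert np.allclose(ck.predicted[0], ck.estimated[0], atol=0.02)  # k=1

    def test_non_markovian_cycle_flagged(self):
        labels = np.tile(np.r_[np.zeros(20, int), np.ones(20, int)], 200)
        model = M.estimate_msm(labels, lag=1)
        ck = M.ck_test(labels, model, factors=[1, 3, 5, 8], n_macrostates=2)
        assert not ck.within_bands().all()


class TestRmsdClustering:
    def test_duplicated_frames_pair_up(self, diss_traj_1000):
        from metadiss.descriptors import Trajectory

        sub = diss_traj_1000.stack[[0, 0, 300, 300]]
        labels, reps = M.hierarchical_cluster_rmsd(
            Trajectory(stack=sub), cutoff=0.1
        )
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_two_distant_conformations_two_clusters(self, diss_traj_1000):
        from metadiss.descriptors import Trajectory

        sub = diss_traj_1000.stack[[0, 1, 2, 900, 901, 902]]
        labels, reps = M.hierarchical_cluster_rmsd(Trajectory(stack=sub), cutoff=5.0)
        assert len(set(labels[:3])) >= 1
        assert set(labels[:3]).isdisjoint(set(labels[3:]))

    def test_single_frame_trivial_cluster(self, diss_traj_1000):
        from metadiss.descriptors import Trajectory

        labels, reps = M.hierarchical_cluster_rmsd(
            Trajectory(stack=diss_traj_1000.stack[0:1]), cutoff=0.1
        )
        assert list(labels) == [0] and reps == [0]

    def test_average_linkage_matches_brute_force_oracle(self, diss_traj_1000):
        """Cut labels equal an O(n^3) naive average-linkage implementation."""
        from metadiss.descriptors import Trajectory

        idx = list(range(0, 1000, 50))[:20]
        traj = Trajectory(stack=diss_traj_1000.stack[idx])
        cutoff = 2.0
        labels, _ = M.hierarchical_cluster_rmsd(traj, cutoff=cutoff)

        # oracle: naive agglomeration on the same aligned RMSD matrix
        coords = np.asarray(traj.stack.coord, dtype=float).copy()
        align = traj.stack.chain_id == "a"
        from metadiss.orientation import _kabsch

        ref = coords[0]
        for i in range(len(idx)):
            shift = coords[i][align].mean(axis=0)
            r = _kabsch(ref[align] - ref[align].mean(0), coords[i][align] - shift)
            coords[i] = (coords[i] - shift) @ r + ref[align].mean(0)
        n = len(idx)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = np.sqrt(
                    ((coords[i] - coords[j]) ** 2).sum(1).mean()
                )
        clusters = [{i} for i in range(n)]
        while len(clusters) > 1:
            best = None
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    link = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                    if best is None or link < best[0]:
                        best = (link, a, b)
            if best[0] > cutoff:
                break
            _, a, b = best
            clusters[a] |= clusters[b]
            del clusters[b]
        oracle = np.empty(n, dtype=int)
        for c, members in enumerate(clusters):
            for i in members:
                oracle[i] = c
        # same partition up to relabeling
        pairs_impl = {(i, j) for i in range(n) for j in range(n) if labels[i] == labels[j]}
        pairs_oracle = {(i, j) for i in range(n) for j in range(n) if oracle[i] == oracle[j]}
        assert pairs_impl == pairs_oracle


class TestEndToEnd:
    def test_macrostates_match_generator_labels(self, dimer, diss_schedule_1000, dimer_native):
        """featurize -> tICA -> k-means -> MSM -> PCCA(3) recovers the
        programmed bound/encounter/unbound labels for >= 90% of frames."""
        from metadiss.synthetic import generate_dissociation_trajectory

        from metadiss.descriptors import Trajectory

        trajs, labels_true = [], []
        for seed in (21, 22, 23):
            schedule = type(diss_schedule_1000)(
                n_frames=300, t_encounter=150, t_unbound=240, seed=seed,
                encounter_separation=2.0,
            )
            forward = generate_dissociation_trajectory(dimer, schedule)
            trajs.append(forward)
            labels_true.append(schedule.labels())
            # microscopic reversibility: the batch also holds rebinding
            # events, as unbiased simulations of a reversible system do
            trajs.append(Trajectory(stack=forward.stack[::-1]))
            labels_true.append(schedule.labels()[::-1])
        fms = [M.featurize_inverse_ca_distances(t, dimer.interface_pairs) for t in trajs]
        X = np.vstack([fm.X for fm in fms])
        model_t = M.tica(X, lag=5, n_components=1)
        ys = [model_t.transform(fm.X) for fm in fms]
        micro = M.kmeans_microstates(np.vstack(ys), 12, seed=0)
        split = np.split(micro, len(trajs))
        msm = M.estimate_msm(list(split), lag=5)
        chi, crisp_micro = M.pcca(msm, 3)
        index = -np.ones(12, dtype=int)
        index[msm.active_set] = np.arange(msm.n_states)
        macro = np.concatenate([
            np.where(index[s] >= 0, crisp_micro[index[s]], -1) for s in split
        ])
        truth = np.concatenate(labels_true)
        agreement = 0
        # best macro->label mapping
        from itertools import permutations

        names = np.array(["bound", "encounter", "unbound"])
        best = 0
        for perm in permutations(range(3)):
            mapped = np.where(macro >= 0, names[np.array(perm)[np.clip(macro, 0, 2)]], "?")
            best = max(best, (mapped == truth).mean())
        assert best >= 0.9
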