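import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster
from scipy.linalg import sqrtm

from allohub.mi import block_mi_matrix
from allohub.substates import (
    cluster_substates,
    covariance_overlap,
    segment_substates,
    split_blocks,
)
from allohub.synthetic import Coupling, Regime, SimSpec, simulate_alignment


def random_psd(rng, n=4):
    a = rng.normal(size=(n, n))
    return a @ a.T


def omega_sqrtm_oracle(a, b):
    """Independent oracle via scipy's dense matrix square root."""
    ra = np.real(sqrtm(a))
    rb = np.real(sqrtm(b))
    d = np.sqrt(max(np.trace(a) + np.trace(b) - 2 * np.trace(ra @ rb), 0.0))
    return 1.0 - d / np.sqrt(np.trace(a) + np.trace(b))


class TestSplitBlocks:
    def test_paper_block_scheme(self):
        ranges = split_blocks(400, 20)
        assert len(ranges) == 20
        assert all(len(r) == 20 for r in ranges)
        assert ranges[0].start == 0 and ranges[-1].stop == 400

    def test_remainder_goes_to_first_blocks(self):
        ranges = split_blocks(10, 3)
        assert [len(r) for r in ranges] == [4, 3, 3]
        assert [r.start for r in ranges] == [0, 4, 7]

    def test_too_many_blocks_rejected(self):
        with pytest.raises(ValueError):
            split_blocks(5, 6)
        with pytest.raises(ValueError):
            split_blocks(5, 0)


class TestCovarianceOverlap:
    def test_identical_matrices_give_one(self):
        rng = np.random.default_rng(0)
        a = random_psd(rng)
        assert covariance_overlap(a, a).omega == 1.0

    def test_orthogonal_diagonals_give_zero(self):
        r = covariance_overlap(np.diag([1.0, 0.0]), np.diag([0.0, 1.0]))
        assert r.omega == 0.0
        assert r.d == pytest.approx(np.sqrt(2))

    def test_scalar_multiple_closed_form(self):
        """Omega(A, 2A) = 1 - sqrt((3 - 2 sqrt 2)/3) for any PSD A."""
        rng = np.random.default_rng(1)
        closed = 1.0 - np.sqrt((3.0 - 2.0 * np.sqrt(2.0)) / 3.0)
        for _ in range(5):
            a = random_psd(rng, n=5)
            assert covariance_overlap(a, 2 * a).omega == pytest.approx(closed, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_matrix_sqrt_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_psd(rng), random_psd(rng)
        assert covariance_overlap(a, b).omega == pytest.approx(
            omega_sqrtm_oracle(a, b), abs=1e-10
        )

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = random_psd(rng), random_psd(rng)
        assert covariance_overlap(a, b).omega == pytest.approx(
            covariance_overlap(b, a).omega, abs=1e-10
        )

    def test_negative_eigenvalues_clipped_and_recorded(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])  # eigvals +-1
        with pytest.warns(UserWarning, match="clipped"):
            r = covariance_overlap(a, a.copy() * 1.0 + 0.0)
        # a == b path short-circuits; compare against a different matrix
        with pytest.warns(UserWarning, match="clipped"):
            r = covariance_overlap(a, np.diag([1.0, 0.0]))
        assert r.psd_adjustment == pytest.approx(1.0)

    def test_null_matrices_are_identical(self):
        assert covariance_overlap(np.zeros((3, 3)), np.zeros((3, 3))).omega == 1.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            covariance_overlap(np.eye(2), np.eye(3))


def regime_switch_matrices(seed, n_blocks=20, frames_per_block=400):
    """Block MI matrices with a planted regime switch at the mid block."""
    n_frames = n_blocks * frames_per_block
    pairs1 = [(0, 5), (2, 8), (4, 11), (6, 13)]
    pairs2 = [(1, 6), (3, 9), (5, 12), (7, 14)]
    regimes = [
        Regime(0, n_frames // 2, tuple(Coupling(i, j, 1.0) for i, j in pairs1)),
        Regime(n_frames // 2, n_frames, tuple(Coupling(i, j, 1.0) for i, j in pairs2)),
    ]
    spec = SimSpec(n_chains=1, n_res_per_chain=20, n_frames=n_frames,
                   regimes=regimes, seed=seed)
    aln, truth = simulate_alignment(spec)
    mats = [block_mi_matrix(aln, r) for r in split_blocks(aln, n_blocks)]
    return mats, n_blocks // 2


class TestSegmentSubstates:
    def test_identical_blocks_one_substate(self):
        m = np.diag([1.0, 2.0])
        ss = segment_substates([m] * 6)
        assert ss.n_substates == 1
        assert ss.probabilities[0] == 1.0
        assert ss.substates[0].member_blocks == list(range(6))

    def test_planted_regime_switch_recovered(self):
        mats, true_boundary = regime_switch_matrices(seed=0)
        ss = segment_substates(mats, omega_threshold=0.85, min_run=2)
        assert ss.n_substates == 2
        assert abs(ss.boundaries()[0] - true_boundary) <= 1
        np.testing.assert_allclose(ss.probabilities, [0.5, 0.5], atol=0.06)

    def test_construction_satisfies_overlap_separation(self):
        """The planted-regime generator must give within-regime overlap >=
        0.95 between adjacent blocks and across-regime overlap < 0.5."""
        mats, b = regime_switch_matrices(seed=1)
        within = [
            covariance_overlap(mats[t], mats[t + 1], warn_clip_frac=None).omega
            for t in range(b - 1)
        ]
        across = [
            covariance_overlap(mats[t], mats[t + b], warn_clip_frac=None).omega
            for t in range(b)
        ]
        assert min(within) >= 0.95
        assert max(across) < 0.5

    def test_threshold_one_isolates_every_block(self):
        rng = np.random.default_rng(3)
        mats = [random_psd(rng) for _ in range(5)]
        ss = segment_substates(mats, omega_threshold=1.0, min_run=1)
        assert ss.n_substates == 5

    def test_probabilities_partition_blocks(self):
        mats, _ = regime_switch_matrices(seed=2, n_blocks=10, frames_per_block=200)
        ss = segment_substates(mats, omega_threshold=0.8, min_run=1)
        assert ss.probabilities.sum() == pytest.approx(1.0)
        all_blocks = sorted(b for s in ss.substates for b in s.member_blocks)
        assert all_blocks == list(range(10))
        for s in ss.substates:  # contiguity
            assert s.member_blocks == list(
                range(s.member_blocks[0], s.member_blocks[-1] + 1)
            )

    def test_deterministic(self):
        mats, _ = regime_switch_matrices(seed=4, n_blocks=8, frames_per_block=100)
        a = segment_substates(mats)
        b = segment_substates(mats)
        assert [s.member_blocks for s in a.substates] == [
            s.member_blocks for s in b.substates
        ]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            segment_substates([])


def brute_force_complete_linkage(dist):
    """Naive agglomeration: repeatedly merge the pair of clusters with the
    smallest complete-linkage (max pairwise) distance."""
    clusters = [[i] for i in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


class TestClusterSubstates:
    def test_two_groups_perfectly_separated(self):
        a = np.diag([1.0, 0.0, 0.0])
        b = np.diag([0.0, 0.0, 1.0])
        z, flat, order = cluster_substates([a, a, b, b], cut_height=0.5)
        assert flat[0] == flat[1]
        assert flat[2] == flat[3]
        assert flat[0] != flat[2]

    @pytest.mark.parametrize("seed", range(3))
    def test_merge_heights_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mats = [random_psd(rng, n=3) for _ in range(6)]
        z, _, _ = cluster_substates(mats)
        dist = np.zeros((6, 6))
        for i in range(6):
            for j in range(i + 1, 6):
                dist[i, j] = dist[j, i] = (
                    1 - covariance_overlap(mats[i], mats[j], warn_clip_frac=None).omega
                )
        oracle_heights = brute_force_complete_linkage(dist)
        np.testing.assert_allclose(sorted(z[:, 2]), sorted(oracle_heights), atol=1e-10)

    def test_three_regime_structure_apo_holo_shared(self):
        """Apo-like, holo-like and shared-intermediate matrix ensembles
        separate into 3 clusters with the shared cluster drawing members
        from both states."""
        rng = np.random.default_rng(7)
        apo_m = np.diag([1.0, 0, 0, 0])
        holo_m = np.diag([0, 0, 0, 1.0])
        mid_m = np.diag([0, 1.0, 1.0, 0])
        mats, origin = [], []
        for state, base in (("apo", apo_m), ("holo", holo_m)):
            for _ in range(4):
                mats.append(base + 0.01 * np.abs(rng.normal(size=4)) * np.eye(4))
                origin.append(state)
            for _ in range(2):  # shared intermediate sampled by both states
                mats.append(mid_m + 0.01 * np.abs(rng.normal(size=4)) * np.eye(4))
                origin.append(state)
        z, flat, _ = cluster_substates(mats, n_clusters=3)
        assert len(set(flat)) == 3
        # the cluster containing the intermediates is mixed
        mid_label = flat[4]
        members = [origin[i] for i in range(len(mats)) if flat[i] == mid_label]
        assert {"apo", "holo"} <= set(members)

    def test_single_matrix_rejected(self):
        with pytest.raises(ValueError):
            cluster_substates([np.eye(2)])
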