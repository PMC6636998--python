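import itertools
import math

import numpy as np
import pytest

from allohub.hubnet import (
    _ranksum_p,
    call_hubs,
    coupling_Q,
    difference_network,
    ensemble_average,
    suggest_substitutions,
)
from allohub.mi import block_mi_matrix
from allohub.substates import Substate, SubstateSet, segment_substates
from allohub.synthetic import Coupling, SimSpec, simulate_alignment


def substate_set(matrices, probs=None, labels=None):
    n = len(matrices)
    probs = probs or [1.0 / n] * n
    subs = [
        Substate(member_blocks=[i], representative=np.asarray(m, float), probability=p)
        for i, (m, p) in enumerate(zip(matrices, probs))
    ]
    return SubstateSet(substates=subs, omega_threshold=0.85, min_run=1, labels=labels)


class TestEnsembleAverage:
    def test_single_substate_is_identity(self):
        m = np.array([[0.0, 0.4], [0.4, 0.0]])
        ens = ensemble_average([substate_set([m])], "apo")
        np.testing.assert_allclose(ens.matrix, m)

    def test_equal_probability_mean(self):
        a = np.full((2, 2), 0.2)
        b = np.full((2, 2), 0.4)
        ens = ensemble_average([substate_set([a, b])])
        assert ens.matrix[0, 1] == pytest.approx(0.3)

    def test_weighted_mean(self):
        a = np.full((2, 2), 0.4)
        b = np.zeros((2, 2))
        ens = ensemble_average([substate_set([a, b], probs=[0.75, 0.25])])
        assert ens.matrix[0, 1] == pytest.approx(0.3)

    def test_weights_sum_to_one_across_replicas(self):
        m = np.zeros((2, 2))
        ens = ensemble_average([substate_set([m, m]), substate_set([m])])
        assert ens.weights.sum() == pytest.approx(1.0)
        assert len(ens.stack) == 3

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([substate_set([np.zeros((2, 2)), np.zeros((3, 3))])])


class TestDifferenceNetwork:
    def _ens(self, value, labels=("A:1", "A:5")):
        m = np.array([[0.0, value], [value, 0.0]])
        ens = ensemble_average([substate_set([m])], "s")
        ens.labels = list(labels)
        return ens

    def test_identical_ensembles_zero_lfc(self):
        a = self._ens(0.3)
        t, diff = difference_network(a, a)
        assert np.all(t["log2fc"] == 0.0)
        assert np.all(diff == 0.0)

    def test_fourfold_change_without_pseudocount(self):
        t, _ = difference_network(self._ens(0.1), self._ens(0.4), pseudocount=0.0)
        assert t["log2fc"].iloc[0] == pytest.approx(2.0)

    def test_pseudocount_regularizes_zero_pairs(self):
        t, _ = difference_network(self._ens(0.0), self._ens(0.0), pseudocount=1e-3)
        assert t["log2fc"].iloc[0] == 0.0

    def test_antisymmetric_at_zero_pseudocount(self):
        a, h = self._ens(0.1), self._ens(0.4)
        t1, _ = difference_network(a, h, pseudocount=0.0)
        t2, _ = difference_network(h, a, pseudocount=0.0)
        np.testing.assert_allclose(t1["log2fc"], -t2["log2fc"])

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            difference_network(self._ens(0.1), self._ens(0.1, labels=("B:1", "B:5")))


def ranksum_enumeration_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating all assignments of the
    pooled tie-free sample to the two groups."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for a in x for b in y if a > b)
    mean = n1 * len(y) / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(comb)] = True
        xs, ys = pooled[mask], pooled[~mask]
        u = sum(1 for a in xs for b in ys if a > b)
        count += abs(u - mean) >= abs(u_obs - mean) - 1e-12
        total += 1
    return count / total


class TestRankSum:
    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, size=5)
        y = rng.normal(0.8, 1, size=5)
        assert _ranksum_p(x, y) == pytest.approx(
            ranksum_enumeration_oracle(x, y), abs=1e-10
        )

    def test_all_identical_gives_p_one(self):
        assert _ranksum_p(np.zeros(5), np.zeros(5)) == 1.0


def planted_states(trial, rho_apo=0.5, rho_holo=0.99, n_rep=5, n_frames=2400):
    def one_state(rho, seeds):
        sets = []
        for s in seeds:
            spec = SimSpec(n_chains=1, n_res_per_chain=20, n_frames=n_frames,
                           couplings=[Coupling(2, 9, rho)], seed=s)
            aln, _ = simulate_alignment(spec)
            sets.append(segment_substates([block_mi_matrix(aln)], min_run=1))
        return sets

    apo = ensemble_average(one_state(rho_apo, [1000 * trial + k for k in range(n_rep)]), "apo")
    holo = ensemble_average(
        one_state(rho_holo, [1000 * trial + 500 + k for k in range(n_rep)]), "holo"
    )
    return apo, holo


class TestCallHubs:
    def test_identical_stacks_no_hubs(self):
        m = np.array([[0.0, 0.0, 0.3], [0.0, 0.0, 0.1], [0.3, 0.1, 0.0]])
        ens = ensemble_average([substate_set([m, m, m])], "x")
        table, _ = difference_network(ens, ens)
        ht = call_hubs(table, ens, ens, lfc_min=2, p_max=0.01)
        assert len(ht.hubs) == 0

    def test_planted_pair_recovered_as_top_hubs(self):
        apo, holo = planted_states(trial=0)
        table, _ = difference_network(apo, holo)
        ht = call_hubs(table, apo, holo, lfc_min=2.0, p_max=0.01)
        sig = ht.pairs[ht.pairs["significant"]]
        assert {(r["i"], r["j"]) for _, r in sig.iterrows()} >= {(2, 9)}
        assert set(ht.hubs["index"].head(2)) == {2, 9}

    def test_planted_effect_cv_within_study_conditions(self):
        """Within-state coefficient of variation of the planted coupling
        stays below 0.1 across the replica samples."""
        apo, holo = planted_states(trial=1)
        for ens in (apo, holo):
            vals = np.array([m[2, 9] for m in ens.stack])
            assert np.std(vals) / np.mean(vals) <= 0.1

    def test_top_k_export(self):
        apo, holo = planted_states(trial=2)
        table, _ = difference_network(apo, holo)
        ht = call_hubs(table, apo, holo, lfc_min=0.0, p_max=0.999)
        top = ht.top(10)
        assert len(top) == min(10, len(ht.hubs))
        assert list(top["rank"]) == sorted(top["rank"])

    def test_bh_q_monotone_in_p(self):
        apo, holo = planted_states(trial=3)
        table, _ = difference_network(apo, holo)
        ht = call_hubs(table, apo, holo, lfc_min=2.0, q_max=0.05)
        ordered = ht.pairs.sort_values("p")
        q = ordered["q"].to_numpy()
        assert np.all(np.diff(q) >= -1e-12)

    def test_too_few_samples_rejected(self):
        m = np.zeros((2, 2))
        ens1 = ensemble_average([substate_set([m])], "a")
        ens2 = ensemble_average([substate_set([m, m])], "b")
        table, _ = difference_network(ens1, ens2)
        with pytest.raises(ValueError, match="replicas|substate"):
            call_hubs(table, ens1, ens2)


class TestSuggestSubstitutions:
    def _msa(self, tmp_path, records):
        p = tmp_path / "msa.fasta"
        p.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in records))
        return str(p)

    def test_column_frequency_arithmetic(self, tmp_path):
        msa = self._msa(tmp_path, [
            ("target", "MA"), ("s1", "MA"), ("s2", "MA"), ("s3", "MS"),
        ])
        out = suggest_substitutions(msa, "target", [2], min_freq=0.2)
        assert out == {2: {"S": 0.25}}

    def test_min_freq_filters_everything(self, tmp_path):
        msa = self._msa(tmp_path, [
            ("target", "MA"), ("s1", "MA"), ("s2", "MA"), ("s3", "MS"),
        ])
        assert suggest_substitutions(msa, "target", [2], min_freq=0.5) == {2: {}}

    def test_leading_gap_position_mapping(self, tmp_path):
        # target has a leading gap: its position 1 is alignment column 2
        # (0-based 1); hand-computed mapping
        msa = self._msa(tmp_path, [
            ("target", "-MKL"), ("s1", "AMKL"), ("s2", "AQKL"), ("s3", "AQRL"),
        ])
        out = suggest_substitutions(msa, "target", [1], min_freq=0.1)
        assert out == {1: {"Q": 0.5}}  # column {M,M,Q,Q}, wild type M

    def test_unknown_target_rejected(self, tmp_path):
        msa = self._msa(tmp_path, [("a", "MK"), ("b", "MK")])
        with pytest.raises(KeyError):
            suggest_substitutions(msa, "nope", [1])


class TestCouplingQ:
    def test_no_effect_gives_unity(self):
        res = coupling_Q(1.0, 1.0)
        assert res["Q"] == 1.0
        assert res["log10Q"] == 0.0

    def test_activator_arithmetic(self):
        # K_M^PEP 1.22 mM alone vs 0.23 mM with the activator bound
        res = coupling_Q(1.22, 0.23)
        assert res["Q"] == pytest.approx(5.304, abs=0.01)
        assert res["log10Q"] == pytest.approx(math.log10(1.22 / 0.23), abs=1e-12)
        assert res["Q"] > 1  # activation

    def test_inhibitor_arithmetic(self):
        res = coupling_Q(1.22, 7.08)
        assert res["Q"] == pytest.approx(0.1723, abs=0.001)
        assert res["Q"] < 1  # inhibition

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            coupling_Q(0.0, 1.0)
        with pytest.raises(ValueError):
            coupling_Q(1.0, -2.0)
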