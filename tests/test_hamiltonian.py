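"""Energy model assembly: constraint sets, masks, term builders, exact energies."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import spearmanr

import tetrafold as tf
from tetrafold.hamiltonian import (
    ALLOWED_PAIRS,
    FORBIDDEN_BACKTRACK_PAIRS,
    build_chirality,
    build_geometric,
    build_interaction,
    build_steric,
    chirality_forbidden_triples,
)
from tetrafold.pauli import PauliZOperator, QubitLayout
from tetrafold.solvers import energy_of_measured
from tetrafold.structure import turns_to_bitstring


def encode(turns, layout):
    return turns_to_bitstring(turns, layout)


class TestConstraintSets:
    def test_allowed_and_backtrack_partition_all_pairs(self):
        assert ALLOWED_PAIRS | FORBIDDEN_BACKTRACK_PAIRS == {
            (d, e) for d in range(4) for e in range(4)
        }
        assert not ALLOWED_PAIRS & FORBIDDEN_BACKTRACK_PAIRS

    def test_chirality_sets_are_all_distinct_triples(self):
        for parity in (0, 1):
            forbidden = chirality_forbidden_triples(parity)
            assert len(forbidden) == 12  # half of the 24 distinct triples
            for d, e, f in forbidden:
                assert len({d, e, f}) == 3

    def test_mirror_swap_flips_forbidden_status(self):
        """Swapping two directions inverts the triple product sign."""
        for parity in (0, 1):
            forbidden = chirality_forbidden_triples(parity)
            for d, e, f in itertools.permutations(range(4), 3):
                assert ((d, e, f) in forbidden) != ((e, d, f) in forbidden)

    def test_parity_flip_swaps_the_sets(self):
        even = chirality_forbidden_triples(0)
        odd = chirality_forbidden_triples(1)
        all_distinct = set(itertools.permutations(range(4), 3))
        assert even | odd == all_distinct and not even & odd


class TestMasks:
    def test_adjacent_turn_backtrack(self):
        for d in range(4):
            for e in range(4):
                expected = 1.0 if d == e else 0.0
                assert tf.steric_mask(1, 0, d, e) == expected

    def test_no_three_step_revisit(self):
        """No backtrack-free 3-bond sub-path revisits a site on this lattice."""
        for parity in (0, 1):
            for d in range(4):
                for e in range(4):
                    assert tf.steric_mask(2, parity, d, e) == 0.0

    def test_six_cycles_make_separation_five_collisions(self):
        vals = [
            tf.steric_mask(5, p, d, e, w_steric=5)
            for p in (0, 1)
            for d in range(4)
            for e in range(4)
        ]
        assert max(vals) > 0.0

    def test_contact_mask_zero_below_separation_five(self):
        for sep in (2, 3):
            for p in (0, 1):
                for d in range(4):
                    for e in range(4):
                        assert tf.contact_mask(sep, p, d, e) == 0.0

    def test_contact_mask_zero_for_even_residue_separation(self):
        # residue separation sep+1 even <=> sep odd
        for sep in (3, 5, 7):
            for p in (0, 1):
                for d in range(4):
                    for e in range(4):
                        assert tf.contact_mask(sep, p, d, e) == 0.0

    def test_contact_possible_at_residue_separation_five(self):
        vals = [
            tf.contact_mask(4, p, d, e)
            for p in (0, 1)
            for d in range(4)
            for e in range(4)
        ]
        assert max(vals) > 0.0

    def test_masks_bounded_and_deterministic(self):
        for sep in range(1, 6):
            for p in (0, 1):
                for d in range(4):
                    for e in range(4):
                        c1 = tf.steric_mask(sep, p, d, e, w_steric=5)
                        c2 = tf.steric_mask(sep, p, d, e, w_steric=5)
                        assert 0.0 <= c1 <= 1.0 and c1 == c2
                        m1 = tf.contact_mask(sep, p, d, e)
                        assert 0.0 <= m1 <= 1.0
                        assert m1 == tf.contact_mask(sep, p, d, e)

    def test_beyond_window_returns_zero(self):
        assert tf.steric_mask(5, 0, 0, 1, w_steric=4) == 0.0
        assert tf.contact_mask(8, 0, 0, 1, w_contact=7) == 0.0


class TestGeometricTerm:
    def test_one_hot_penalty_is_the_zero_operator(self, default_weights):
        """Under the dense encoding the one-hot component cancels exactly, so
        the geometric term is independent of mu_oh."""
        lay = QubitLayout(5)
        small = build_geometric(lay, tf.PenaltyWeights(mu_oh=1e-6))
        huge = build_geometric(lay, tf.PenaltyWeights(mu_oh=1e6))
        assert small == huge

    def test_zero_on_backtrack_free_encodings(self, default_weights):
        lay = QubitLayout(4)
        hg = build_geometric(lay, default_weights)
        for turns in tf.enumerate_conformations(4, backtrack_free=True):
            assert energy_of_measured(hg, encode(turns, lay)) == pytest.approx(0.0)

    def test_single_backtrack_costs_mu_ang(self, default_weights):
        lay = QubitLayout(3)
        hg = build_geometric(lay, default_weights)
        e = energy_of_measured(hg, encode((2, 2), lay))
        assert e == pytest.approx(default_weights.mu_ang)


class TestChiralityTerm:
    def test_backtrack_pair_costs_at_least_kappa_bt(self, default_weights):
        lay = QubitLayout(3)
        hc = build_chirality(lay, default_weights)
        for d in range(4):
            e = energy_of_measured(hc, encode((d, d), lay))
            assert e >= default_weights.kappa_bt - 1e-9

    def test_allowed_triples_cost_nothing(self, default_weights):
        lay = QubitLayout(4)
        hc = build_chirality(lay, default_weights)
        allowed = [
            t
            for t in itertools.permutations(range(4), 3)
            if t not in chirality_forbidden_triples(1)
        ]
        for turns in allowed:
            assert energy_of_measured(hc, encode(turns, lay)) == pytest.approx(0.0)

    def test_forbidden_triples_cost_kappa_chi(self, default_weights):
        lay = QubitLayout(4)
        hc = build_chirality(lay, default_weights)
        for turns in chirality_forbidden_triples(1):
            e = energy_of_measured(hc, encode(turns, lay))
            assert e == pytest.approx(default_weights.kappa_chi)


class TestStericTerm:
    def test_l3_reduces_to_backtrack_support(self, default_weights):
        """At L=3 only separation-1 masks are nonzero, so Hd charges exactly
        the backtracking pairs."""
        lay = QubitLayout(3)
        hd = build_steric(lay, default_weights)
        for d in range(4):
            for e in range(4):
                val = energy_of_measured(hd, encode((d, e), lay))
                expected = default_weights.eta if d == e else 0.0
                assert val == pytest.approx(expected)

    def test_linearity_in_eta(self, default_weights):
        lay = QubitLayout(5)
        h1 = build_steric(lay, default_weights)
        h2 = build_steric(
            lay, tf.PenaltyWeights(eta=2 * default_weights.eta)
        )
        np.testing.assert_allclose(
            h2.to_dense_diagonal(), 2 * h1.to_dense_diagonal(), atol=1e-9
        )


class TestInteractionTerm:
    def test_zero_matrix_gives_zero_operator(self):
        lay = QubitLayout(6)
        mj0 = tf.MJMatrix(np.zeros((20, 20)))
        assert build_interaction(lay, "YAGYSW", mj0).is_zero()

    def test_homopolymer_invariant_under_sequence_reversal(self, mj):
        lay = QubitLayout(6)
        assert build_interaction(lay, "AAAAAA", mj) == build_interaction(
            lay, "AAAAAA"[::-1], mj
        )

    def test_unknown_residue_reported_with_position(self, mj):
        lay = QubitLayout(4)
        with pytest.raises(ValueError, match="position 2"):
            build_interaction(lay, "AAXA", mj)

    def test_contact_conformations_rewarded_on_average(self, mj):
        """The mask is a marginal propensity over intermediate turns, so
        contact-forming conformations score at least as low as contact-free
        ones at the minimum and strictly lower on average (L=6 exhaustive)."""
        lay = QubitLayout(6)
        seq = "CCCCCC"  # strongest MJ self-interaction
        hi = build_interaction(lay, seq, mj)
        with_contact, without = [], []
        for turns in tf.enumerate_conformations(6, backtrack_free=True):
            conf = tf.turns_to_coordinates(turns)
            if not tf.is_self_avoiding(conf):
                continue
            e = energy_of_measured(hi, encode(turns, lay))
            (with_contact if tf.find_contacts(conf) else without).append(e)
        assert with_contact and without
        assert min(with_contact) <= min(without)
        assert np.mean(with_contact) < np.mean(without)
        assert min(with_contact) < 0  # a real reward is collected


class TestTotalAssembly:
    def test_homopolymer_qubit_count(self):
        prob = tf.build_total("AAAAA")
        assert prob.n_qubits == 8  # 2(L-1), no fixed turns

    def test_total_is_sum_of_weighted_parts(self, problem_l5):
        w = problem_l5.weights
        recomposed = (
            w.lambda_c * problem_l5.h_chirality
            + w.lambda_g * problem_l5.h_geometric
            + w.lambda_d * problem_l5.h_steric
            + w.lambda_i * problem_l5.h_interaction
        )
        assert recomposed == problem_l5.operator

    def test_doubling_lambdas_doubles_the_diagonal(self):
        base = tf.build_total("YAGY")
        doubled = tf.build_total(
            "YAGY",
            weights=tf.PenaltyWeights(
                lambda_c=2, lambda_g=2, lambda_d=2, lambda_i=2
            ),
        )
        np.testing.assert_allclose(
            doubled.operator.to_dense_diagonal(),
            2 * base.operator.to_dense_diagonal(),
            atol=1e-9,
        )

    def test_size_guard(self):
        with pytest.raises(ValueError, match="sliding-window"):
            tf.build_total("A" * 20)

    def test_penalty_dominance_at_l5(self, problem_l5, ground_l5, default_weights):
        """Every encoding containing a backtrack pair sits at least kappa_bt
        above the valid minimum (exhaustive)."""
        lay = problem_l5.layout
        floor = ground_l5.best_energy + default_weights.kappa_bt * 1.0
        for turns in tf.enumerate_conformations(5):
            if turns.is_backtrack_free():
                continue
            e = energy_of_measured(problem_l5.operator, encode(turns, lay))
            assert e >= floor - 1e-9

    def test_energy_correlates_with_exact_contact_energy(self, mj, default_weights):
        """Spearman link between the mask approximation and exact contacts."""
        seq = "CMFILV"
        prob = tf.build_total(seq)
        ham_e, exact_e = [], []
        for turns in tf.enumerate_conformations(6, backtrack_free=True):
            conf = tf.turns_to_coordinates(turns)
            if not tf.is_self_avoiding(conf):
                continue
            exact = tf.exact_conformation_energy(seq, turns, mj, default_weights)
            ham_e.append(energy_of_measured(prob.operator, encode(turns, prob.layout)))
            exact_e.append(exact)
        rho = spearmanr(ham_e, exact_e).statistic
        assert rho > 0


class TestExactConformationEnergy:
    def test_backtracking_is_infinite(self):
        assert math.isinf(tf.exact_conformation_energy("YAG", (0, 0)))

    def test_clean_open_chain_is_zero(self):
        assert tf.exact_conformation_energy("YAGY", (0, 1, 0)) == 0.0

    def test_single_contact_scores_its_mj_energy(self, mj, default_weights):
        """Exact energy = contact MJ term + kappa_chi per forbidden triple,
        checked against an independent count on a single-contact walk."""
        found = chi = None
        for turns in tf.enumerate_conformations(6, backtrack_free=True):
            conf = tf.turns_to_coordinates(turns)
            if not tf.is_self_avoiding(conf):
                continue
            if len(tf.find_contacts(conf)) == 1:
                found = turns
                chi = sum(
                    (turns[t - 1], turns[t], turns[t + 1])
                    in chirality_forbidden_triples(t % 2)
                    for t in range(1, len(turns) - 1)
                )
                break
        assert found is not None
        e = tf.exact_conformation_energy("CCCCCC", found, mj, default_weights)
        assert e == pytest.approx(
            mj.energy("C", "C") + chi * default_weights.kappa_chi
        )


class TestMJMatrix:
    def test_symmetric_with_full_alphabet(self, mj):
        assert set(mj.alphabet) == set("ACDEFGHIKLMNPQRSTVWY")
        np.testing.assert_allclose(mj.matrix, mj.matrix.T)

    def test_hydrophobic_pairs_bind_tighter_than_charged(self, mj):
        assert mj.energy("F", "F") < mj.energy("K", "K")

    def test_file_round_trip(self, mj, tmp_path):
        path = tmp_path / "mj.txt"
        mj.to_file(path)
        again = tf.MJMatrix.from_file(path)
        assert again.alphabet == mj.alphabet
        np.testing.assert_allclose(again.matrix, mj.matrix, atol=0.005)


class TestSequenceParsing:
    def test_plain_and_fasta(self):
        assert tf.parse_sequence("yagys") == "YAGYS"
        assert tf.parse_sequence(">frag|test\nYAG\nYS\n") == "YAGYS"

    def test_multi_record_fasta_rejected(self):
        with pytest.raises(ValueError):
            tf.parse_sequence(">a\nYAG\n>b\nGAV\n")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tf.parse_sequence("  \n ")
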