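import itertools
import math

import numpy as np
import pytest

from infolattice import (
    JointDistribution,
    conditional_entropy,
    conditional_interaction_information,
    entropy,
    enumerate_faces,
    eta,
    eta_from_entropies,
    interaction_information,
    interaction_information_batch,
    joint_entropy,
    total_correlation,
)
from infolattice.synthetic import (
    dirichlet_joint,
    extremal_triple,
    independent_law,
    markov_chain_law,
)

from conftest import merge_variables


def identical_pair(h=1.0):
    """Two perfectly coupled bits (possibly biased to set H)."""
    if h == 1.0:
        p = 0.5
    else:  # solve h(p) = h by bisection
        lo, hi = 1e-9, 0.5
        while hi - lo > 1e-14:
            mid = (lo + hi) / 2
            val = -mid * math.log2(mid) - (1 - mid) * math.log2(1 - mid)
            lo, hi = (mid, hi) if val < h else (lo, mid)
        p = lo
    return JointDistribution((0, 1), (2, 2), {(0, 0): p, (1, 1): 1 - p})


class TestEntropy:
    def test_fair_coin_is_one_bit(self):
        j = JointDistribution((0,), (2,), {(0,): 0.5, (1,): 0.5})
        assert entropy(j) == pytest.approx(1.0)

    def test_degenerate_is_zero(self):
        j = JointDistribution((0,), (2,), {(0,): 1.0})
        assert entropy(j) == 0.0

    def test_uniform_reaches_capacity(self):
        j = JointDistribution((0,), (9,), {(s,): 1 / 9 for s in range(9)})
        assert entropy(j) == pytest.approx(math.log2(9), abs=1e-12)


class TestJointEntropy:
    def test_parity_triple_is_two_bits(self):
        assert joint_entropy(extremal_triple("parity-even")) == pytest.approx(2.0)

    def test_deterministic_copy_adds_nothing(self):
        assert joint_entropy(identical_pair()) == pytest.approx(1.0)

    def test_independent_bits_additive(self):
        assert joint_entropy(independent_law(2, 2)) == pytest.approx(2.0)

    def test_monotone_under_inclusion(self, triple_joints):
        for j in triple_joints:
            for face in [(0,), (1,), (0, 1), (1, 2)]:
                grown = tuple(sorted(set(face) | {2 if 2 not in face else 0}))
                assert joint_entropy(j, grown) >= joint_entropy(j, face) - 1e-12


class TestConditionalEntropy:
    def test_conditioning_on_independent_variable_unchanged(self):
        j = independent_law(2, 3)
        assert conditional_entropy(j, (0,), (1,)) == pytest.approx(
            joint_entropy(j, (0,)), abs=1e-12
        )

    def test_copy_conditioning_zeroes_entropy(self):
        assert conditional_entropy(identical_pair(), (0,), (1,)) == pytest.approx(0.0, abs=1e-12)

    def test_overlapping_subsets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            conditional_entropy(identical_pair(), (0,), (0,))

    def test_definition_matches_entropy_difference(self, triple_joints):
        for j in triple_joints:
            direct = conditional_entropy(j, (2,), (0, 1))
            diff = joint_entropy(j) - joint_entropy(j, (0, 1))
            assert direct == pytest.approx(diff, abs=1e-10)

    def test_repeated_conditioning_associates(self, triple_joints):
        # H(X2 | X0, X1) computed in one shot equals conditioning in stages
        for j in triple_joints:
            one_shot = conditional_entropy(j, (2,), (0, 1))
            h_given_0 = joint_entropy(j, (0, 1, 2)) - joint_entropy(j, (0,))
            staged = h_given_0 - (joint_entropy(j, (0, 1)) - joint_entropy(j, (0,)))
            assert one_shot == pytest.approx(staged, abs=1e-10)


class TestInteractionInformation:
    def test_three_identical_bits(self):
        assert interaction_information(extremal_triple("identical")) == pytest.approx(1.0)

    @pytest.mark.parametrize("kind", ["parity-even", "parity-odd"])
    def test_parity_triples_attain_minus_one(self, kind):
        assert interaction_information(extremal_triple(kind)) == pytest.approx(-1.0)

    def test_product_law_pairs_vanish(self):
        j = independent_law(2, 3)
        assert interaction_information(j, (0, 1)) == pytest.approx(0.0, abs=1e-12)

    def test_self_information_is_entropy(self):
        j = identical_pair(h=0.7219280948873623)
        assert interaction_information(j) == pytest.approx(joint_entropy(j, (0,)), abs=1e-9)

    def test_symmetric_under_permutation(self, triple_joints):
        j = triple_joints[0]
        vals = {
            interaction_information(j.permuted(p))
            for p in itertools.permutations((0, 1, 2))
        }
        assert max(vals) - min(vals) < 1e-10


class TestConditionalInteractionInformation:
    def test_independent_triple_vanishes(self):
        j = independent_law(3, 2)
        assert conditional_interaction_information(j, (0, 1), (2,)) == pytest.approx(0.0, abs=1e-12)

    def test_parity_conditioning_creates_dependence(self):
        """I(X1;X2|X3) = 1 on the parity law although I(X1;X2) = 0."""
        xor = extremal_triple("parity-even")
        assert conditional_interaction_information(xor, (0, 1), (2,)) == pytest.approx(1.0)
        assert interaction_information(xor, (0, 1)) == pytest.approx(0.0, abs=1e-12)
        # consistency: I3 = I2 - I2|cond
        assert interaction_information(xor) == pytest.approx(0.0 - 1.0)

    def test_recursion_identity(self, triple_joints, quad_joints):
        """I_{k+1}(v, S) = I_k(S) - I_k(S | v) on random joints."""
        for j in triple_joints:
            lhs = interaction_information(j, (0, 1, 2))
            rhs = interaction_information(j, (1, 2)) - conditional_interaction_information(
                j, (1, 2), (0,)
            )
            assert lhs == pytest.approx(rhs, abs=1e-10)
        for j in quad_joints:
            lhs = interaction_information(j, (0, 1, 2, 3))
            rhs = interaction_information(j, (1, 2, 3)) - conditional_interaction_information(
                j, (1, 2, 3), (0,)
            )
            assert lhs == pytest.approx(rhs, abs=1e-10)


class TestTotalCorrelation:
    def test_independent_product_vanishes(self):
        assert total_correlation(independent_law(3, 3)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_pairwise_mutual_information(self, triple_joints):
        for j in triple_joints:
            assert total_correlation(j, (0, 2)) == pytest.approx(
                interaction_information(j, (0, 2)), abs=1e-10
            )

    def test_k_identical_bits(self):
        k = 4
        probs = {(0,) * k: 0.5, (1,) * k: 0.5}
        j = JointDistribution(tuple(range(k)), (2,) * k, probs)
        assert total_correlation(j) == pytest.approx(k - 1)

    def test_nonnegative(self, quad_joints):
        for j in quad_joints:
            assert total_correlation(j) >= -1e-12


class TestEta:
    def test_single_variable_is_entropy(self):
        j = dirichlet_joint((4,), rng=0)
        assert eta(j, (0,)) == pytest.approx(entropy(j), abs=1e-12)

    def test_full_set_is_interaction_information(self):
        xor = extremal_triple("parity-even")
        assert eta(xor, (0, 1, 2)) == pytest.approx(-1.0)

    def test_etas_sum_to_joint_entropy(self, triple_joints):
        for j in triple_joints:
            total = sum(eta(j, J) for J in enumerate_faces(3, 3))
            assert total == pytest.approx(joint_entropy(j), abs=1e-10)

    def test_superset_sums_reconstruct_interaction_information(self, triple_joints):
        """I_k(X_I) = sum of eta_J over faces J containing I."""
        for j in triple_joints:
            etas = {J: eta(j, J) for J in enumerate_faces(3, 3)}
            for face in enumerate_faces(3, 3):
                recon = sum(v for J, v in etas.items() if set(face) <= set(J))
                assert recon == pytest.approx(
                    interaction_information(j, face), abs=1e-10
                )

    def test_meeting_sums_reconstruct_entropies(self, triple_joints):
        """H_k(X_I) = sum of eta_J over faces J meeting I."""
        for j in triple_joints:
            etas = {J: eta(j, J) for J in enumerate_faces(3, 3)}
            for face in enumerate_faces(3, 3):
                recon = sum(v for J, v in etas.items() if set(face) & set(J))
                assert recon == pytest.approx(joint_entropy(j, face), abs=1e-10)

    def test_moebius_inversion_matches_conditioning(self, triple_joints, quad_joints):
        for j, n in [(triple_joints[0], 3), (triple_joints[5], 3), (quad_joints[0], 4)]:
            h_table = {f: joint_entropy(j, f) for f in enumerate_faces(n, n)}
            for J in enumerate_faces(n, n):
                assert eta_from_entropies(h_table, J, tuple(range(n))) == pytest.approx(
                    eta(j, J), abs=1e-10
                )

    def test_two_variable_closed_form(self):
        j = dirichlet_joint((2, 3), rng=1)
        h_table = {f: joint_entropy(j, f) for f in enumerate_faces(2, 2)}
        expect = h_table[(0,)] + h_table[(1,)] - h_table[(0, 1)]
        assert eta_from_entropies(h_table, (0, 1), (0, 1)) == pytest.approx(expect, abs=1e-12)

    def test_missing_face_raises(self):
        with pytest.raises(KeyError):
            eta_from_entropies({(0,): 1.0}, (0,), (0, 1))


class TestAlgebraicIdentities:
    def test_entropy_chain_rule(self, triple_joints):
        """H_{k+1} = H_k + conditional entropy of the added variable."""
        for j in triple_joints:
            lhs = joint_entropy(j, (0, 1, 2))
            rhs = joint_entropy(j, (1, 2)) + conditional_entropy(j, (0,), (1, 2))
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_joint_variable_chain_rule(self, triple_joints):
        """I_k((X0,X1); S) = I_k(X0; S) + I_k(X1; S | X0)."""
        for j in triple_joints:
            merged = merge_variables(j, (0, 1), new_var=9)
            lhs = interaction_information(merged, (9, 2))
            rhs = interaction_information(j, (0, 2)) + conditional_interaction_information(
                j, (1, 2), (0,)
            )
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_cocycle_identity(self, triple_joints):
        """I2(X;(Y,Z)) + I2(Y;Z) = I2((X,Y);Z) + I2(X;Y)."""
        for j in triple_joints:
            x_yz = merge_variables(j, (1, 2), new_var=9)
            xy_z = merge_variables(j, (0, 1), new_var=9)
            lhs = interaction_information(x_yz, (0, 9)) + interaction_information(j, (1, 2))
            rhs = interaction_information(xy_z, (9, 2)) + interaction_information(j, (0, 1))
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_naive_distributivity_fails_on_parity(self):
        """I2(X;(Y,Z)) != I2(X;Y) + I2(X;Z) in general: parity is a witness."""
        xor = extremal_triple("parity-even")
        merged = merge_variables(xor, (1, 2), new_var=9)
        lhs = interaction_information(merged, (0, 9))
        rhs = interaction_information(xor, (0, 1)) + interaction_information(xor, (0, 2))
        assert lhs == pytest.approx(1.0)
        assert rhs == pytest.approx(0.0, abs=1e-12)

    def test_alternating_inversion_roundtrip(self, quad_joints):
        """Recover every H_k from the I table by the dual alternating sum."""
        for j in quad_joints:
            i_table = {
                f: interaction_information(j, f) for f in enumerate_faces(4, 4)
            }
            for face in enumerate_faces(4, 4):
                recon = 0.0
                for r in range(1, len(face) + 1):
                    sign = 1 if r % 2 == 1 else -1
                    for t in itertools.combinations(face, r):
                        recon += sign * i_table[t]
                assert recon == pytest.approx(joint_entropy(j, face), abs=1e-10)

    def test_locality(self, quad_joints):
        """Measures on a subset agree whether computed on full law or marginal."""
        for j in quad_joints:
            sub = j.marginal((0, 2, 3))
            for face in [(0, 2), (0, 2, 3)]:
                assert interaction_information(j, face) == pytest.approx(
                    interaction_information(sub, face), abs=1e-12
                )


class TestBounds:
    def test_pairwise_information_bounds(self, triple_joints):
        for j in triple_joints:
            i2 = interaction_information(j, (0, 1))
            cap = min(joint_entropy(j, (0,)), joint_entropy(j, (1,)))
            assert -1e-12 <= i2 <= cap + 1e-12

    def test_triple_information_bounds(self, triple_joints):
        for j in triple_joints:
            i3 = interaction_information(j)
            cap = min(joint_entropy(j, (v,)) for v in (0, 1, 2))
            assert abs(i3) <= cap + 1e-12


class TestMarkovCriterion:
    def test_chain_satisfies_i3_equals_endpoint_i2(self):
        kernel = np.array([[0.9, 0.1], [0.1, 0.9]])
        chain = markov_chain_law(3, kernel)
        assert interaction_information(chain) == pytest.approx(
            interaction_information(chain, (0, 2)), abs=1e-10
        )

    def test_parity_violates_markov(self):
        xor = extremal_triple("parity-even")
        assert interaction_information(xor) != pytest.approx(
            interaction_information(xor, (0, 2)), abs=0.5
        )


def test_batch_interaction_matches_sparse(triple_joints):
    laws = np.stack([j.to_array() for j in triple_joints if j.alphabet_sizes == (2, 2, 2)])
    batch = interaction_information_batch(laws)
    sparse = [
        interaction_information(j) for j in triple_joints if j.alphabet_sizes == (2, 2, 2)
    ]
    np.testing.assert_allclose(batch, sparse, atol=1e-10)
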