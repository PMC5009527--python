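import numpy as np
import pytest

from oracles import enumerate_pair_posterior
from pnpalign.errors import InputError
from pnpalign.hmm import global_model, local_models, select_hmm
from pnpalign.posterior import (
    PosteriorSet,
    combine_models,
    compute_posteriors,
    consistency_transform,
    forward_backward,
)
from pnpalign.seqio import Family, Sequence


def seq(residues, sid="s"):
    return Sequence(sid, residues)


class TestSelectHmm:
    def test_high_identity_selects_global_model(self):
        models = select_hmm(0.60)
        assert [m.name for m in models] == ["global3"]

    def test_low_identity_selects_local_set(self):
        models = select_hmm(0.10)
        assert all(m.local for m in models)
        assert len(models) >= 1

    def test_threshold_boundary_takes_global_branch(self):
        assert select_hmm(0.40)[0].name == "global3"
        assert select_hmm(0.399999)[0].local

    def test_invalid_fraction_rejected(self):
        with pytest.raises(InputError):
            select_hmm(1.5)


class TestForwardBackward:
    def test_single_residue_pair_matches_hand_enumeration(self, global_hmm):
        """For x = y = 'A' the three alignments (match, two double-inserts)
        can be enumerated by hand; the posterior is the match share."""
        m = global_hmm
        e_match = m.pair_emission(m.encode("A"), m.encode("A"))[0, 0]
        e_single = m.single_emission(m.encode("A"))[0]
        p_match = m.init[0] * e_match * m.end[0]
        p_xy = (
            m.init[1] * e_single * m.trans[1, 2] * e_single * m.end[2]
        )
        p_yx = (
            m.init[2] * e_single * m.trans[2, 1] * e_single * m.end[1]
        )
        expected = p_match / (p_match + p_xy + p_yx)
        got = forward_backward(seq("A"), seq("A"), m, cutoff=0.0)
        assert got[0, 0] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("model_index", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, model_index):
        models = [global_model()] + local_models()
        model = models[model_index]
        rng = np.random.default_rng(11 + model_index)
        for _ in range(10):
            lx, ly = rng.integers(1, 5, size=2)
            x = "".join(rng.choice(list("ACDE"), lx))
            y = "".join(rng.choice(list("ACDE"), ly))
            ours = forward_backward(seq(x), seq(y), model, cutoff=0.0)
            oracle = enumerate_pair_posterior(x, y, model)
            assert np.abs(ours - oracle).max() < 1e-8

    def test_transpose_symmetry(self, global_hmm):
        x, y = seq("MKTAYIA"), seq("MKTAYV")
        pxy = forward_backward(x, y, global_hmm, cutoff=0.0)
        pyx = forward_backward(y, x, global_hmm, cutoff=0.0)
        assert np.allclose(pxy, pyx.T, atol=1e-12)

    def test_row_and_column_sums_bounded(self, local_hmm):
        p = forward_backward(seq("MKT"), seq("MKTA"), local_hmm, cutoff=0.0)
        assert p.sum(axis=1).max() <= 1 + 1e-6
        assert p.sum(axis=0).max() <= 1 + 1e-6

    def test_long_sequences_stay_finite(self, global_hmm):
        x = seq("ACDEFGHIKLMNPQRSTVWY" * 15)
        p = forward_backward(x, x, global_hmm)
        assert np.isfinite(p).all()
        assert p.max() > 0.5  # identical sequences: confident diagonal

    def test_sparsity_cutoff_zeroes_small_entries(self, global_hmm):
        x, y = seq("ACDEFG"), seq("GHIKLM")
        p = forward_backward(x, y, global_hmm, cutoff=0.05)
        assert ((p == 0) | (p >= 0.05)).all()


class TestCombineModels:
    def test_single_matrix_identity(self):
        m = np.array([[0.5, 0.1], [0.2, 0.7]])
        assert np.array_equal(combine_models([m], [1.0]), m)

    def test_equal_matrices_unchanged(self):
        m = np.array([[0.5, 0.1], [0.2, 0.7]])
        assert np.allclose(combine_models([m, m.copy()]), m)

    def test_hand_computed_convex_combination(self):
        a = np.array([[1.0, 0.0], [0.0, 1.0]])
        b = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = combine_models([a, b], [0.3, 0.7])
        assert np.allclose(out, np.array([[0.3, 0.7], [0.7, 0.3]]))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InputError, match="dimension"):
            combine_models([np.zeros((2, 2)), np.zeros((2, 3))])


class TestConsistencyTransform:
    def test_zero_rounds_is_identity(self, toy_posteriors):
        out = consistency_transform(toy_posteriors, rounds=0)
        for i, j in toy_posteriors.pairs():
            assert np.array_equal(out.get(i, j), toy_posteriors.get(i, j))

    def test_two_sequences_unchanged(self, global_hmm):
        fam = Family((seq("ACDE", "a"), seq("ACDF", "b")))
        ps = compute_posteriors(fam, [global_hmm], cutoff=0.0)
        out = consistency_transform(ps, rounds=1, cutoff=0.0)
        assert np.allclose(out.get(0, 1), ps.get(0, 1), atol=1e-12)

    def test_three_sequences_match_dense_oracle(self):
        """One round equals (2 P_xy + P_xz P_zy) / 3, hand-multiplied."""
        rng = np.random.default_rng(3)
        mats = {
            (0, 1): rng.random((3, 3)) * 0.3,
            (0, 2): rng.random((3, 2)) * 0.3,
            (1, 2): rng.random((3, 2)) * 0.3,
        }
        ps = PosteriorSet(3, {k: v.copy() for k, v in mats.items()})
        out = consistency_transform(ps, rounds=1, cutoff=0.0)
        expect_01 = (2 * mats[(0, 1)] + mats[(0, 2)] @ mats[(1, 2)].T) / 3
        expect_02 = (2 * mats[(0, 2)] + mats[(0, 1)] @ mats[(1, 2)]) / 3
        expect_12 = (2 * mats[(1, 2)] + mats[(0, 1)].T @ mats[(0, 2)]) / 3
        assert np.allclose(out.get(0, 1), expect_01, atol=1e-12)
        assert np.allclose(out.get(0, 2), expect_02, atol=1e-12)
        assert np.allclose(out.get(1, 2), expect_12, atol=1e-12)

    def test_permutation_equivariance(self, global_hmm):
        seqs = [seq("MKTAY", "a"), seq("MKTCY", "b"), seq("MRTAY", "c")]
        fam = Family(tuple(seqs))
        perm_fam = Family((seqs[2], seqs[0], seqs[1]))
        out = consistency_transform(
            compute_posteriors(fam, [global_hmm], cutoff=0.0), 1, cutoff=0.0
        )
        perm_out = consistency_transform(
            compute_posteriors(perm_fam, [global_hmm], cutoff=0.0), 1, cutoff=0.0
        )
        # pair (a, b) is (0, 1) originally and (1, 2) after the relabeling
        assert np.allclose(out.get(0, 1), perm_out.get(1, 2), atol=1e-12)

    def test_invariants_hold_after_rounds(self, toy_posteriors):
        out = consistency_transform(toy_posteriors, rounds=2)
        for i, j in out.pairs():
            m = out.get(i, j)
            assert m.sum(axis=1).max() <= 1 + 1e-6
            assert m.sum(axis=0).max() <= 1 + 1e-6
            assert (m >= 0).all()


class TestPosteriorSet:
    def test_reverse_order_is_transpose(self, toy_posteriors):
        assert np.array_equal(toy_posteriors.get(1, 0), toy_posteriors.get(0, 1).T)

    def test_incomplete_set_rejected(self):
        with pytest.raises(InputError, match="every pair"):
            PosteriorSet(3, {(0, 1): np.zeros((2, 2))})

    def test_self_pair_rejected(self, toy_posteriors):
        with pytest.raises(InputError):
            toy_posteriors.get(1, 1)
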