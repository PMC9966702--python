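"""Potts inference: reweighting, plmDCA, scoring, APC, inter-protein block."""

import numpy as np
import pytest

import spdca
from spdca.alignment import PairedAlignment
from spdca.coevolution import (
    PottsModel,
    apc_correct,
    coupling_scores,
    fit_mean_field,
    fit_plm,
    inter_protein_block,
    pseudolikelihood,
    sequence_weights,
    synthetic_alphabet,
    top_pairs,
    zero_sum_gauge,
)
from conftest import make_paired


class TestSequenceWeights:
    def test_identical_rows_share_weight(self):
        pa = make_paired(["ACDE"] * 5, len_a=2)
        w = sequence_weights(pa, theta=0.8)
        assert np.allclose(w.weights, 0.2)
        assert w.m_eff == pytest.approx(1.0)

    def test_distinct_rows_have_unit_weight(self):
        pa = make_paired(["ACDE", "FGHI", "KLMN"], len_a=2)
        w = sequence_weights(pa, theta=0.8)
        assert np.allclose(w.weights, 1.0)

    def test_mixed_cluster_weights(self):
        # two identical rows and one unrelated: brute-force expectation
        pa = make_paired(["ACDEF", "ACDEF", "KLMNP"], len_a=2)
        w = sequence_weights(pa, theta=0.8)
        assert np.allclose(w.weights, [0.5, 0.5, 1.0])

    def test_raising_theta_never_decreases_weights(self, rng):
        rows = rng.choice(list("ACDE"), size=(12, 8))
        pa = PairedAlignment(rows, [f"s{i}" for i in range(12)], len_a=4, len_b=4)
        prev = sequence_weights(pa, theta=0.3).weights
        for theta in (0.5, 0.75, 0.9, 1.0):
            cur = sequence_weights(pa, theta=theta).weights
            assert (cur >= prev - 1e-12).all()
            prev = cur


class TestFitPlm:
    def test_planted_copy_is_top_coupling(self):
        # column pair with copied states must dominate all couplings
        model, _ = spdca.make_planted_model(4, 4, q=4, n_pairs=0, seed=7)
        pa = spdca.sample_msa(model, 500, seed=7)
        rows = pa.rows.copy()
        rows[:, 6] = rows[:, 1]  # plant a perfect copy
        pa2 = PairedAlignment(rows, pa.species_ids, len_a=4, len_b=4)
        fit = fit_plm(pa2, sequence_weights(pa2), alphabet=synthetic_alphabet(4))
        S = coupling_scores(fit, apply_apc=False).scores
        np.fill_diagonal(S, 0.0)
        assert np.unravel_index(S.argmax(), S.shape) in {(1, 6), (6, 1)}

    def test_iid_columns_below_permutation_null(self, rng):
        # with no real couplings, fitted scores look like column-shuffled noise
        model, _ = spdca.make_planted_model(5, 5, q=4, n_pairs=0, seed=11)
        pa = spdca.sample_msa(model, 2000, seed=11)
        w = sequence_weights(pa)
        fit = fit_plm(pa, w, alphabet=synthetic_alphabet(4))
        S = coupling_scores(fit, apply_apc=False).scores
        iu = np.triu_indices(pa.length, k=1)
        observed = S[iu]
        null_vals = []
        for _ in range(5):
            perm_rows = np.column_stack(
                [rng.permutation(pa.rows[:, j]) for j in range(pa.length)]
            )
            ppa = PairedAlignment(perm_rows, pa.species_ids, len_a=5, len_b=5)
            pf = fit_plm(ppa, w, alphabet=synthetic_alphabet(4))
            null_vals.append(coupling_scores(pf, apply_apc=False).scores[iu])
        q99 = np.quantile(np.concatenate(null_vals), 0.99)
        # i.i.d. data is its own shuffle: at most ~1% of pairs may exceed
        # the null 99th percentile (allow 2 of 45 for sampling noise)
        assert (observed > q99).sum() <= 2

    def test_strong_regularization_kills_couplings(self):
        pa = make_paired(["ACDE", "CDEA", "DEAC", "EACD"], len_a=2)
        fit = fit_plm(pa, sequence_weights(pa), reg_couplings=1e3,
                      alphabet=synthetic_alphabet(5))
        S = coupling_scores(fit, apply_apc=False).scores
        assert S.max() < 1e-3

    def test_deterministic(self):
        model, _ = spdca.make_planted_model(3, 3, q=3, n_pairs=1, seed=2)
        pa = spdca.sample_msa(model, 100, seed=2)
        w = sequence_weights(pa)
        f1 = fit_plm(pa, w, alphabet=synthetic_alphabet(3))
        f2 = fit_plm(pa, w, alphabet=synthetic_alphabet(3))
        assert np.array_equal(f1.couplings, f2.couplings)

    def test_empty_alignment_rejected(self):
        pa = PairedAlignment(np.empty((0, 4), dtype="U1"), [], len_a=2, len_b=2)
        with pytest.raises(ValueError, match="empty"):
            fit_plm(pa, spdca.SequenceWeights(np.ones(0), 0.8))

    def test_fit_beats_random_parameters_at_tiny_scale(self):
        # exhaustible scale: L=3, q=2, 8 rows with col0 == col2 structure
        rows = np.array(
            [list(s) for s in
             ["AAA", "CAC", "AAA", "CCC", "ACA", "CAC", "AAA", "CCC"]]
        )
        pa = PairedAlignment(rows, [f"sp{i}" for i in range(8)], len_a=2, len_b=1)
        w = spdca.SequenceWeights(np.ones(8), 0.8)
        fit = fit_plm(pa, w, alphabet=synthetic_alphabet(2))
        pl_fit = pseudolikelihood(fit, pa)
        rng = np.random.default_rng(42)
        for _ in range(100):
            J = rng.normal(0, 1, (3, 3, 2, 2))
            J = 0.5 * (J + J.transpose(1, 0, 3, 2))
            for i in range(3):
                J[i, i] = 0.0
            rand = PottsModel(q=2, fields=rng.normal(0, 1, (3, 2)), couplings=J,
                              alphabet=synthetic_alphabet(2))
            assert pseudolikelihood(rand, pa) <= pl_fit


class TestCouplingScores:
    def _toy_model(self, J, q=3):
        L = J.shape[0]
        return PottsModel(q=q, fields=np.zeros((L, q)), couplings=J,
                          alphabet=synthetic_alphabet(q))

    def test_gauge_invariance_of_scores(self, rng):
        L, q = 4, 3
        J = rng.normal(size=(L, L, q, q))
        J = 0.5 * (J + J.transpose(1, 0, 3, 2))
        for i in range(L):
            J[i, i] = 0.0
        base = coupling_scores(self._toy_model(J), apply_apc=False).scores
        # add a per-row constant phi(s) to every J_ij(s, ·): a pure gauge shift
        shifted = J + rng.normal(size=(L, L, q))[:, :, :, None]
        shifted = 0.5 * (shifted + shifted.transpose(1, 0, 3, 2))
        for i in range(L):
            shifted[i, i] = 0.0
        out = coupling_scores(self._toy_model(shifted), apply_apc=False).scores
        assert np.allclose(out, base, atol=1e-8)

    def test_gap_state_excluded_from_norm(self):
        q = 3
        J = np.zeros((2, 2, q, q))
        J[0, 1, q - 1, q - 1] = 5.0  # coupling purely in the gap state
        J[1, 0] = J[0, 1].T
        model = PottsModel(q=q, fields=np.zeros((2, q)), couplings=J, alphabet="AC-")
        gapless = coupling_scores(model, apply_apc=False).scores
        full = coupling_scores(
            PottsModel(q=q, fields=np.zeros((2, q)), couplings=J, alphabet="ACD"),
            apply_apc=False,
        ).scores
        assert gapless[0, 1] < full[0, 1]

    def test_raw_scores_without_apc(self, rng):
        L, q = 5, 3
        J = rng.normal(size=(L, L, q, q))
        J = 0.5 * (J + J.transpose(1, 0, 3, 2))
        for i in range(L):
            J[i, i] = 0.0
        model = zero_sum_gauge(self._toy_model(J))
        cm = coupling_scores(model, apply_apc=False)
        expected = np.sqrt((model.couplings ** 2).sum(axis=(2, 3)))
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(cm.scores, expected, atol=1e-10)


class TestApc:
    def test_constant_matrix_annihilated(self):
        S = np.full((6, 6), 3.7)
        np.fill_diagonal(S, 0.0)
        assert np.allclose(apc_correct(S), 0.0, atol=1e-12)

    def test_matches_brute_force_formula(self, rng):
        S = rng.random((6, 6))
        S = 0.5 * (S + S.T)
        np.fill_diagonal(S, 0.0)
        out = apc_correct(S, clip=False)
        L = 6
        off = ~np.eye(L, dtype=bool)
        mean_all = S[off].mean()
        for i in range(L):
            for j in range(L):
                if i == j:
                    continue
                mi = S[i][np.arange(L) != i].mean()
                mj = S[j][np.arange(L) != j].mean()
                assert out[i, j] == pytest.approx(S[i, j] - mi * mj / mean_all)

    def test_clipping_removes_negatives(self, rng):
        S = rng.random((5, 5))
        S = 0.5 * (S + S.T)
        np.fill_diagonal(S, 0.0)
        assert apc_correct(S, clip=True).min() >= 0.0


class TestInterBlock:
    def test_slicing_contract(self, rng):
        S = rng.random((10, 10))
        S = 0.5 * (S + S.T)
        cm = spdca.CouplingMatrix(scores=S, apc_applied=False)
        block = inter_protein_block(cm, 4, 6)
        assert block.shape == (4, 6)
        assert np.array_equal(block, S[:4, 4:])

    def test_symmetry_mirrored_block(self, rng):
        S = rng.random((8, 8))
        S = 0.5 * (S + S.T)
        cm = spdca.CouplingMatrix(scores=S, apc_applied=False)
        assert np.array_equal(
            inter_protein_block(cm, 4, 4), S[4:, :4].T
        )

    def test_dimension_mismatch_errors(self):
        cm = spdca.CouplingMatrix(scores=np.zeros((6, 6)), apc_applied=False)
        with pytest.raises(ValueError, match="does not match"):
            inter_protein_block(cm, 4, 4)

    def test_planted_pair_is_block_argmax(self):
        model, truth = spdca.make_planted_model(6, 6, q=4, n_pairs=1,
                                                strength=2.5, seed=13)
        pa = spdca.sample_msa(model, 800, seed=13)
        fit = fit_plm(pa, sequence_weights(pa), alphabet=synthetic_alphabet(4))
        block = inter_protein_block(coupling_scores(fit), 6, 6)
        assert top_pairs(block)[0] == truth.pairs[0]


def test_mean_field_agrees_with_plm_on_strong_couplings():
    """Two independent inference routes must rank the same planted pairs first."""
    model, truth = spdca.make_planted_model(6, 6, q=4, n_pairs=2, strength=2.5, seed=3)
    pa = spdca.sample_msa(model, 1000, seed=3)
    w = sequence_weights(pa)
    top_plm = top_pairs(inter_protein_block(
        coupling_scores(fit_plm(pa, w, alphabet=synthetic_alphabet(4))), 6, 6))[:2]
    top_mf = top_pairs(inter_protein_block(
        coupling_scores(fit_mean_field(pa, w, alphabet=synthetic_alphabet(4))), 6, 6))[:2]
    assert set(top_plm) == set(truth.pairs)
    assert set(top_mf) == set(truth.pairs)
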