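"""Native maps, contact-evaluation statistics, MSA features, and text I/O."""

import math

import numpy as np
import pytest
from scipy import stats

from memcontact.contacts import (
    classification_metrics,
    map_pcc,
    msa_mutual_information,
    msa_pairwise_potential,
    native_contact_map,
    read_rr,
    read_score_matrix,
    relative_improvement,
    topk_precision,
    write_rr,
    write_score_matrix,
)
from memcontact.potentials import default_contact_potential
from memcontact.synthetic import make_msa, make_toy_structure
from memcontact.types import (
    AMINO_ACIDS,
    BANDS,
    ContactMap,
    LONG_RANGE,
    MSA,
    MemcontactError,
    RangeBand,
    StructureCoords,
    UNDEFINED,
)

ALL_SEP = RangeBand("all", 1, 10 ** 9)


def random_maps(L, rng, density=0.15):
    pred = rng.random((L, L))
    pred = (pred + pred.T) / 2
    np.fill_diagonal(pred, 0)
    nat = (rng.random((L, L)) < density).astype(float)
    nat = np.triu(nat, 1)
    nat = nat + nat.T
    return ContactMap(pred), ContactMap(nat, kind="native")


class TestNativeMap:
    def test_distance_boundary(self):
        for d, expect in [(7.9, 1.0), (8.1, 0.0)]:
            st = StructureCoords(ca=np.array([[0, 0, 0], [d, 0, 0]], float),
                                 cb=np.array([[0, 0, 0], [d, 0, 0]], float))
            assert native_contact_map(st).values[0, 1] == expect

    def test_symmetric_zero_diagonal(self, toy_structure):
        cm = native_contact_map(toy_structure)
        assert np.array_equal(cm.values, cm.values.T)
        assert np.all(np.diagonal(cm.values) == 0)

    def test_matches_all_pairs_oracle(self, rng):
        st = make_toy_structure(25, seed=9)
        cm = native_contact_map(st)
        pts = st.contact_atoms()
        for i in range(25):
            for j in range(25):
                expected = 0.0 if i == j else float(
                    math.dist(pts[i], pts[j]) <= 8.0)
                assert cm.values[i, j] == expected

    def test_glycine_falls_back_to_ca(self):
        cb = np.array([[0, 0, 0], [np.nan, np.nan, np.nan]], float)
        ca = np.array([[0, 0, 0], [5, 0, 0]], float)
        st = StructureCoords(ca=ca, cb=cb)
        assert native_contact_map(st).values[0, 1] == 1.0

    def test_missing_both_atoms_raises(self):
        ca = np.array([[0, 0, 0], [np.nan, 0, 0], [1, 1, 1]], float)
        st = StructureCoords(ca=ca, cb=np.full((3, 3), np.nan))
        with pytest.raises(MemcontactError, match="residue 1"):
            native_contact_map(st)


def brute_topk(pred, native, k, band):
    L = pred.shape[0]
    pairs = [(i, j) for i in range(L) for j in range(i + 1, L)
             if band.lo <= j - i <= band.hi]
    if not pairs or L // k < 1:
        return None
    pairs.sort(key=lambda ij: (-pred[ij], ij[0], ij[1]))
    taken = pairs[: L // k]
    return sum(native[ij] for ij in taken) / len(taken)


class TestTopkPrecision:
    def test_perfect_ranking(self, rng):
        pred, nat = random_maps(60, rng, density=0.3)
        # rank all native contacts first
        perfect = ContactMap(np.where(nat.values > 0, 0.9, 0.1) *
                             (1 - np.eye(60)))
        for band in BANDS.values():
            iu, ju = np.triu_indices(60, 1)
            n_nat = int(nat.values[iu, ju][(band.contains(ju - iu))].sum())
            if n_nat >= 60 // 5:
                assert topk_precision(perfect, nat, 5, band) == 1.0

    def test_no_natives_in_band(self, rng):
        pred, _ = random_maps(40, rng)
        empty = ContactMap(np.zeros((40, 40)), kind="native")
        assert topk_precision(pred, empty, 5, LONG_RANGE) == 0.0

    def test_band_without_pairs_undefined(self, rng):
        pred, nat = random_maps(10, rng)
        assert topk_precision(pred, nat, 1, LONG_RANGE) is UNDEFINED

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            L = int(rng.integers(12, 45))
            pred, nat = random_maps(L, rng)
            for band in list(BANDS.values()) + [ALL_SEP]:
                for k in (10, 5, 2, 1):
                    expected = brute_topk(pred.values, nat.values, k, band)
                    got = topk_precision(pred, nat, k, band)
                    assert got == expected


class TestMapPcc:
    def test_identical_maps(self, rng):
        pred, nat = random_maps(30, rng)
        assert map_pcc(nat, nat) == pytest.approx(1.0)

    def test_inverted_binary(self, rng):
        _, nat = random_maps(30, rng, density=0.4)
        inv = 1 - nat.values
        np.fill_diagonal(inv, 0)
        assert map_pcc(ContactMap(inv), nat) == pytest.approx(-1.0)

    def test_matches_pearsonr(self, rng):
        pred, nat = random_maps(35, rng)
        iu, ju = np.triu_indices(35, k=6)
        expected = stats.pearsonr(pred.values[iu, ju], nat.values[iu, ju])[0]
        assert map_pcc(pred, nat) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_undefined(self, rng):
        pred, _ = random_maps(20, rng)
        empty = ContactMap(np.zeros((20, 20)), kind="native")
        assert map_pcc(pred, empty) is UNDEFINED


class TestRelativeImprovement:
    def test_whole_map_pcc_improvement(self):
        # 0.29 → 0.37 is a ~28% relative gain
        assert round(relative_improvement(0.29, 0.37)) == 28

    def test_membrane_subset_improvement(self):
        # 0.132 → 0.222 is a ~68% relative gain
        assert round(relative_improvement(0.132, 0.222)) == 68

    def test_no_change(self):
        assert relative_improvement(0.5, 0.5) == 0.0

    def test_zero_base(self):
        with pytest.raises(MemcontactError):
            relative_improvement(0.0, 0.1)


def mann_whitney_auc(scores, truth):
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = 0.0
    for p in pos:
        wins += (p > neg).sum() + 0.5 * (p == neg).sum()
    return wins / (len(pos) * len(neg))


class TestClassificationMetrics:
    def test_perfect_predictions(self, rng):
        _, nat = random_maps(30, rng, density=0.3)
        out = classification_metrics(nat, nat)
        assert out["accuracy"] == 1.0
        assert out["auc"] == 1.0
        assert np.allclose(out["confusion"], np.eye(2))

    def test_sub_threshold_constant_all_negative(self, rng):
        _, nat = random_maps(20, rng, density=0.3)
        const = ContactMap(np.full((20, 20), 0.49) * (1 - np.eye(20)))
        out = classification_metrics(const, nat)
        assert out["confusion"][0, 1] == 0.0
        assert out["confusion"][1, 1] == 0.0

    def test_auc_matches_rank_sum_oracle(self, rng):
        pred, nat = random_maps(30, rng)
        out = classification_metrics(pred, nat)
        iu, ju = np.triu_indices(30, 1)
        expected = mann_whitney_auc(pred.values[iu, ju],
                                    nat.values[iu, ju].astype(int))
        assert out["auc"] == pytest.approx(expected, abs=1e-9)

    def test_single_class_auc_undefined(self, rng):
        pred, _ = random_maps(15, rng)
        empty = ContactMap(np.zeros((15, 15)), kind="native")
        assert classification_metrics(pred, empty)["auc"] is UNDEFINED


class TestMutualInformation:
    def test_two_column_toy_matches_enumeration(self):
        msa = MSA(["AC", "AC", "GT", "GT"])
        mi = msa_mutual_information(msa)
        # hand enumeration with add-one pseudocount over 21 symbols
        joint = np.ones((21, 21))
        pairs = [("A", "C"), ("A", "C"), ("G", "T"), ("G", "T")]
        for a, b in pairs:
            joint[AMINO_ACIDS.index(a), AMINO_ACIDS.index(b)] += 1
        f = joint / joint.sum()
        fa = f.sum(1, keepdims=True)
        fb = f.sum(0, keepdims=True)
        expected = float((f * np.log(f / (fa * fb))).sum())
        assert mi[0, 1] == pytest.approx(expected, abs=1e-12)
        assert mi[0, 0] == 0.0
        assert mi[0, 1] == mi[1, 0]

    def test_copied_column_is_argmax(self):
        msa = make_msa(8, 200, covarying_pairs=[(2, 6)], seed=5, coupling=1.0)
        mi = msa_mutual_information(msa)
        assert mi[2].argmax() == 6

    def test_independent_columns_stay_at_pseudocount_noise(self):
        # independent deep columns carry only smoothing bias, far below a
        # strongly coupled pair's signal
        indep = make_msa(6, 500, seed=7)
        mi_indep = msa_mutual_information(indep)
        off = mi_indep[~np.eye(6, dtype=bool)]
        planted = make_msa(6, 500, covarying_pairs=[(0, 5)], seed=7, coupling=0.9)
        mi_planted = msa_mutual_information(planted)[0, 5]
        assert off.max() < 0.2
        assert mi_planted > 3 * off.max()

    def test_depth_one_all_zero(self):
        assert np.all(msa_mutual_information(MSA(["ACDEF"])) == 0)

    def test_apc_keeps_planted_signal_on_top(self):
        msa = make_msa(10, 300, covarying_pairs=[(1, 8)], seed=3, coupling=0.9)
        mi = msa_mutual_information(msa, apc=True)
        iu, ju = np.triu_indices(10, 1)
        best = np.argmax(mi[iu, ju])
        assert (iu[best], ju[best]) == (1, 8)


class TestPairwisePotential:
    def test_single_sequence_exact_lookup(self):
        pot = default_contact_potential()
        seq = "ACDEF"
        out = msa_pairwise_potential(MSA([seq]), pot)
        for i, a in enumerate(seq):
            for j, b in enumerate(seq):
                assert out[i, j] == pot[AMINO_ACIDS.index(a), AMINO_ACIDS.index(b)]

    def test_uniform_table(self):
        msa = make_msa(5, 10, seed=1)
        out = msa_pairwise_potential(msa, np.full((20, 20), 3.5))
        assert np.allclose(out, 3.5)

    def test_matches_double_loop_oracle(self):
        msa = make_msa(6, 15, seed=2, gap_fraction=0.15)
        pot = default_contact_potential()
        out = msa_pairwise_potential(msa, pot)
        idx = msa.to_indices()
        for i in range(6):
            for j in range(6):
                vals = [pot[idx[r, i], idx[r, j]] for r in range(15)
                        if idx[r, i] < 20 and idx[r, j] < 20]
                if vals:
                    assert out[i, j] == pytest.approx(np.mean(vals), abs=1e-12)
                else:
                    assert np.isnan(out[i, j])

    def test_all_gap_pair_is_nan(self):
        msa = MSA(["A-", "A-"])
        out = msa_pairwise_potential(msa, default_contact_potential())
        assert np.isnan(out[0, 1]) and np.isnan(out[1, 1])


class TestTextIO:
    def test_identity_matrix(self):
        mat = read_score_matrix("1 0 0\n0 1 0\n0 0 1\n")
        assert np.array_equal(mat, np.eye(3))

    def test_ragged_raises(self):
        with pytest.raises(MemcontactError):
            read_score_matrix("1 2\n3\n")

    def test_non_square_raises(self):
        with pytest.raises(MemcontactError):
            read_score_matrix("1 2 3\n4 5 6\n")

    def test_asymmetric_averaged(self, caplog):
        mat = read_score_matrix("0 2\n0 0\n")
        assert mat[0, 1] == mat[1, 0] == 1.0

    def test_matrix_round_trip(self, rng):
        mat = rng.random((6, 6))
        mat = (mat + mat.T) / 2
        back = read_score_matrix(write_score_matrix(mat))
        assert np.allclose(back, mat, atol=1e-6)

    def test_rr_round_trip(self, rng):
        pred = rng.random((15, 15))
        pred = (pred + pred.T) / 2
        np.fill_diagonal(pred, 0)
        cm = ContactMap(pred)
        seq = "".join(rng.choice(list(AMINO_ACIDS), 15))
        back = read_rr(write_rr(cm, sequence=seq))
        assert back.size == 15
        assert np.allclose(back.values, cm.values, atol=1e-6)
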