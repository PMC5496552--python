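import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from commdrivers.containers import OccurrenceMatrix
from commdrivers.cooccurrence import (
    bayes_m_filter,
    c_score_matrix,
    c_score_pair,
    classify_pairs,
    ff_swap_null,
    matrix_level_test,
    pairwise_test,
)
from commdrivers.exceptions import (
    BinningError,
    ProvenanceError,
    TooFewSpeciesError,
)
from commdrivers.synthetic import generate_binary_cooccurrence


def pair_loop_oracle(M):
    """Exhaustive double loop over species pairs."""
    R = M.shape[0]
    scores = []
    for i, j in itertools.combinations(range(R), 2):
        s = int(np.sum(M[i] * M[j]))
        scores.append((int(M[i].sum()) - s) * (int(M[j].sum()) - s))
    return float(np.mean(scores))


def occ_from_array(M, groups=None):
    species = [f"sp{i}" for i in range(M.shape[0])]
    prov = None
    if groups is not None:
        prov = pd.DataFrame({"trophic_group": groups, "guild": "none"},
                            index=species)
    return OccurrenceMatrix(
        pd.DataFrame(M, index=species,
                     columns=[f"s{j}" for j in range(M.shape[1])]),
        provenance=prov)


class TestCScore:
    def test_pair_arithmetic(self):
        assert c_score_pair([1, 1, 1, 0, 0], [1, 1, 0, 1, 1]) == 2
        assert c_score_pair([1, 0, 1], [1, 0, 1]) == 0
        assert c_score_pair([1, 1, 0, 0], [0, 0, 1, 1]) == 4
        with pytest.raises(ValueError):
            c_score_pair([1, 0], [1, 0, 1])

    def test_matrix_level_closed_forms(self):
        assert c_score_matrix(np.array([[1, 0], [0, 1]])) == 1.0
        assert c_score_matrix(np.ones((4, 5), dtype=int)) == 0.0
        with pytest.raises(TooFewSpeciesError):
            c_score_matrix(np.ones((1, 5), dtype=int))

    def test_matches_pair_loop_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            M = (rng.random((10, 12)) < 0.4).astype(np.uint8)
            assert c_score_matrix(M) == pytest.approx(pair_loop_oracle(M),
                                                      abs=1e-12)


class TestFixedFixedNull:
    def test_two_by_two_checkerboard_swaps(self):
        M = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        ens = ff_swap_null(M, n_null=50, burn_in=1, thin=1, seed=0)
        states = {tuple(x.ravel()) for x in ens.matrices}
        assert states <= {(1, 0, 0, 1), (0, 1, 1, 0)}
        assert len(states) == 2  # the chain moves between both states

    def test_nested_matrix_is_degenerate(self):
        M = np.array([[1, 1], [1, 0]], dtype=np.uint8)
        with pytest.warns(UserWarning, match="singleton"):
            ens = ff_swap_null(M, n_null=10, burn_in=100, thin=10, seed=1)
        assert ens.degenerate
        assert all(np.array_equal(x, M) for x in ens.matrices)

    def test_margins_always_preserved(self):
        M = generate_binary_cooccurrence(10, 10, fill=0.45, seed=4)
        ens = ff_swap_null(M, n_null=100, burn_in=10_000, thin=900, seed=5)
        # 10_000 + 100*900 = 100_000 swap attempts in total
        for x in ens.matrices:
            np.testing.assert_array_equal(x.sum(axis=1), M.sum(axis=1))
            np.testing.assert_array_equal(x.sum(axis=0), M.sum(axis=0))
        assert ens.n_swaps > 0

    def test_chain_samples_ff_class_uniformly(self):
        # enumerate the full fixed-fixed class of a small matrix and compare
        # the chain's sampled C-score distribution with enumeration
        M = np.array(
            [[1, 1, 0, 0],
             [1, 0, 1, 0],
             [0, 1, 0, 1],
             [0, 0, 1, 1]], dtype=np.uint8)
        rt, ct = M.sum(1), M.sum(0)
        members = []
        for bits in itertools.product([0, 1], repeat=16):
            A = np.array(bits, dtype=np.uint8).reshape(4, 4)
            if np.array_equal(A.sum(1), rt) and np.array_equal(A.sum(0), ct):
                members.append(A)
        scores = np.array([c_score_matrix(A) for A in members])
        values, counts = np.unique(scores, return_counts=True)
        expected_freq = counts / counts.sum()
        ens = ff_swap_null(M, n_null=100_000, burn_in=500, thin=5, seed=9)
        sampled = np.array([c_score_matrix(x) for x in ens.matrices])
        obs = np.array([(np.isclose(sampled, v)).sum() for v in values])
        assert obs.sum() == len(sampled)  # no unexpected score values
        stat = chisquare(obs, expected_freq * len(sampled))
        assert stat.pvalue > 0.01


class TestMatrixLevelTest:
    def test_degenerate_class_flagged(self):
        M = np.array([[1, 1], [1, 0]], dtype=np.uint8)
        with pytest.warns(UserWarning):
            ens = ff_swap_null(M, n_null=20, burn_in=10, thin=1, seed=0)
        r = matrix_level_test(M, ens)
        assert r.degenerate and r.p_upper == 1.0 and np.isnan(r.ses)

    def test_provenance_mismatch_rejected(self):
        M = generate_binary_cooccurrence(8, 10, fill=0.4, seed=1)
        ens = ff_swap_null(M, n_null=10, burn_in=100, thin=10, seed=2)
        other = generate_binary_cooccurrence(8, 10, fill=0.4, seed=3)
        with pytest.raises(ProvenanceError):
            matrix_level_test(other, ens)

    def test_planted_segregation_detected(self):
        pairs = [(2 * k, 2 * k + 1, "segregated") for k in range(5)]
        M = generate_binary_cooccurrence(10, 60, planted_pairs=pairs,
                                         fill=0.5, seed=6)
        ens = ff_swap_null(M, n_null=999, burn_in=30_000, thin=100, seed=7)
        r = matrix_level_test(M, ens)
        assert r.p_upper <= 0.01
        assert r.ses > 0


class TestPairwise:
    def _fixture(self, seed):
        planted = [(0, 1, "segregated"), (2, 3, "aggregated")]
        M = generate_binary_cooccurrence(12, 68, planted_pairs=planted,
                                         fill=0.3, seed=seed)
        ens = ff_swap_null(M, n_null=500, burn_in=30_000, thin=300,
                           seed=seed + 1)
        return M, ens

    def test_planted_pairs_recovered(self):
        M, ens = self._fixture(11)
        pairs = {(p.species_a, p.species_b): p
                 for p in pairwise_test(occ_from_array(M), ens)}
        assert pairs[("sp0", "sp1")].classification == "segregated"
        assert pairs[("sp0", "sp1")].cl_flag
        assert pairs[("sp2", "sp3")].classification == "aggregated"
        assert pairs[("sp2", "sp3")].c_obs == 0

    def test_type_i_rate_near_nominal(self):
        # fully random matrices: ~5% of pairs CL-flagged at level 0.95
        rng = np.random.default_rng(13)
        rates = []
        for rep in range(60):
            M = (rng.random((15, 20)) < 0.3).astype(np.uint8)
            if not M.sum(axis=1).all():
                M[M.sum(axis=1) == 0, 0] = 1
            ens = ff_swap_null(M, n_null=300, burn_in=20_000, thin=500,
                               seed=int(rng.integers(2**31 - 1)))
            pairs = pairwise_test(occ_from_array(M), ens)
            rates.append(np.mean([p.cl_flag for p in pairs]))
        assert np.mean(rates) == pytest.approx(0.05, abs=0.03)

    def test_invariants_hold_per_pair(self):
        M, ens = self._fixture(17)
        for p in pairwise_test(occ_from_array(M), ens):
            assert p.c_obs >= 0
            assert p.shared <= min(p.r_a, p.r_b)
            if p.classification == "segregated":
                assert p.cl_flag and p.c_obs > p.null_mean
            if p.classification == "aggregated":
                assert p.cl_flag and p.c_obs < p.null_mean


class TestBayesM:
    def test_empty_cl_set_stays_empty(self):
        M = generate_binary_cooccurrence(6, 12, fill=0.5, seed=3)
        ens = ff_swap_null(M, n_null=200, burn_in=5000, thin=100, seed=4)
        pairs = pairwise_test(occ_from_array(M), ens, level=0.9999)
        assert not any(p.cl_flag for p in pairs)
        bayes_m_filter(pairs, ens)
        assert not any(p.bayesm_flag for p in pairs)

    def test_subset_of_cl_and_more_restrictive(self):
        rng = np.random.default_rng(21)
        n_cl = n_bm = 0
        for rep in range(25):
            M = (rng.random((14, 25)) < 0.35).astype(np.uint8)
            M[M.sum(axis=1) == 0, 0] = 1
            ens = ff_swap_null(M, n_null=300, burn_in=20_000, thin=300,
                               seed=int(rng.integers(2**31 - 1)))
            pairs = pairwise_test(occ_from_array(M), ens)
            bayes_m_filter(pairs, ens)
            for p in pairs:
                assert not (p.bayesm_flag and not p.cl_flag)
            n_cl += sum(p.cl_flag for p in pairs)
            n_bm += sum(p.bayesm_flag for p in pairs)
        assert 0 < n_bm < n_cl

    def test_bin_count_validated(self):
        M = generate_binary_cooccurrence(5, 10, fill=0.4, seed=1)
        ens = ff_swap_null(M, n_null=20, burn_in=100, thin=10, seed=2)
        pairs = pairwise_test(occ_from_array(M), ens)
        with pytest.raises(BinningError):
            bayes_m_filter(pairs, ens, n_bins=1)


class TestClassification:
    def test_toy_cross_tabulation(self):
        groups = ["plant"] * 3 + ["leafhopper"] * 3
        M = generate_binary_cooccurrence(6, 40, fill=0.4, seed=5,
                                         planted_pairs=[(0, 1, "segregated"),
                                                        (3, 4, "aggregated")])
        ens = ff_swap_null(M, n_null=500, burn_in=20_000, thin=200, seed=6)
        pairs = pairwise_test(occ_from_array(M, groups), ens)
        table = classify_pairs(pairs)
        assert table.loc["p-p", "segregated"] >= 1
        assert table.loc["l-l", "aggregated"] >= 1
        assert table.to_numpy().sum() == sum(p.cl_flag for p in pairs)

    def test_unknown_species_rejected(self):
        M = generate_binary_cooccurrence(4, 15, fill=0.4, seed=8)
        ens = ff_swap_null(M, n_null=50, burn_in=1000, thin=50, seed=9)
        pairs = pairwise_test(occ_from_array(M), ens)
        with pytest.raises(KeyError):
            classify_pairs(pairs, meta={"sp0": "plant"})

    def test_specialist_host_fixture_all_aggregated(self):
        # stacked specialist-host style fixture: every planted pair aggregated
        planted = [(0, 4, "aggregated"), (1, 5, "aggregated"),
                   (2, 6, "aggregated")]
        M = generate_binary_cooccurrence(8, 68, fill=0.25, seed=10,
                                         planted_pairs=planted)
        groups = ["leafhopper"] * 4 + ["plant"] * 4
        ens = ff_swap_null(M, n_null=800, burn_in=30_000, thin=300, seed=11)
        pairs = pairwise_test(occ_from_array(M, groups), ens)
        planted_results = [p for p in pairs
                           if (p.species_a, p.species_b) in
                           {("sp0", "sp4"), ("sp1", "sp5"), ("sp2", "sp6")}]
        assert all(p.classification == "aggregated" for p in planted_results)
        flagged = [p for p in pairs if p.cl_flag]
        assert {p.classification for p in planted_results} == {"aggregated"}
        assert len(flagged) >= 3
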