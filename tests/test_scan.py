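import numpy as np
import pandas as pd
import pytest

from tripla import (
    SyntheticConfig,
    conditioned_correlations,
    generate_null_dataset,
    generate_switching_dataset,
    scan_triplets,
    transform_matrix,
    triplet_network,
)
from tripla.scan import ScanResult, brute_force_enumerate, default_strata


def _planted_keys(truth):
    return {(t.x3_id, *sorted((t.x1_id, t.x2_id))) for t in truth.planted_triplets}


class TestScanTriplets:
    def test_enumeration_matches_brute_force(self):
        matrix = generate_null_dataset(12, 6, seed=0)
        tr = transform_matrix(matrix)
        ids = tr.gene_ids
        result = scan_triplets(tr, ids[:2], n_bins=2, seed=0)
        expected = set(brute_force_enumerate(ids[:2], ids))
        got = set(zip(result.triplets.x3, result.triplets.x1, result.triplets.x2))
        assert got == expected
        assert len(got) == 2 * (5 * 4 // 2)

    def test_single_candidate_counts(self):
        matrix = generate_null_dataset(12, 5, seed=1)
        tr = transform_matrix(matrix)
        result = scan_triplets(tr, [tr.gene_ids[0]], n_bins=2, seed=0)
        assert len(result.triplets) == 6  # C(4, 2)

    def test_invariant_to_gene_row_order(self):
        matrix = generate_null_dataset(15, 8, seed=2)
        tr = transform_matrix(matrix)
        shuffled = tr.data.sample(frac=1.0, random_state=4)
        from tripla import ExpressionMatrix

        tr2 = ExpressionMatrix(shuffled)
        r1 = scan_triplets(tr, [tr.gene_ids[0]], n_bins=3, seed=0)
        r2 = scan_triplets(tr2, [tr.gene_ids[0]], n_bins=3, seed=0)
        k1 = {(a, b, c): round(m, 10) for a, b, c, m in zip(r1.triplets.x3, r1.triplets.x1, r1.triplets.x2, r1.triplets.mla)}
        k2 = {(a, b, c): round(m, 10) for a, b, c, m in zip(r2.triplets.x3, r2.triplets.x1, r2.triplets.x2, r2.triplets.mla)}
        assert k1 == k2

    def test_deterministic_given_seed(self):
        matrix = generate_null_dataset(15, 10, seed=3)
        tr = transform_matrix(matrix)
        r1 = scan_triplets(tr, tr.gene_ids[:2], seed=5, method="normal_approx", n_pilot=50)
        r2 = scan_triplets(tr, tr.gene_ids[:2], seed=5, method="normal_approx", n_pilot=50)
        pd.testing.assert_frame_equal(r1.triplets, r2.triplets)

    def test_recovers_planted_triplets(self, planted_transformed):
        """Strong planted triplets dominate the scan ranking and pass FDR."""
        tr, truth = planted_transformed
        candidates = sorted({t.x3_id for t in truth.planted_triplets})
        result = scan_triplets(tr, candidates, n_bins=3, seed=0)
        planted = _planted_keys(truth)
        top = set(
            zip(result.triplets.x3[:20], result.triplets.x1[:20], result.triplets.x2[:20])
        )
        assert len(planted & top) >= 2  # strongest planted triplets lead the ranking
        sig = set(zip(result.significant.x3, result.significant.x1, result.significant.x2))
        assert len(planted & sig) >= 4

    def test_no_triplet_repeats_a_gene(self, planted_transformed):
        tr, truth = planted_transformed
        result = scan_triplets(tr, [truth.planted_triplets[0].x3_id], seed=0)
        t = result.triplets
        assert ((t.x1 != t.x2) & (t.x1 != t.x3) & (t.x2 != t.x3)).all()
        assert (t.x1 < t.x2).all()  # canonical pair order

    def test_empty_candidates_rejected(self, planted_transformed):
        tr, _ = planted_transformed
        with pytest.raises(ValueError):
            scan_triplets(tr, [])


class TestTripletNetwork:
    @staticmethod
    def _fake_scan(rows):
        frame = pd.DataFrame(rows, columns=["x3", "x1", "x2"])
        frame["mla"] = 0.5
        frame["p_value"] = 1e-6
        frame["q_value"] = 1e-4
        frame["significant"] = True
        return ScanResult(frame, {}, {})

    def test_single_triplet_counts(self):
        _, counts = triplet_network(self._fake_scan([("S1", "a", "b")]))
        assert counts.set_index("x3").loc["S1", "n_triplets"] == 1

    def test_shared_x3_counted_per_triplet(self):
        scan = self._fake_scan([("S1", "a", "b"), ("S1", "c", "d"), ("S2", "e", "f")])
        graph, counts = triplet_network(scan)
        table = counts.set_index("x3")["n_triplets"]
        assert table["S1"] == 2 and table["S2"] == 1
        assert graph.has_edge("a", "b")
        assert graph.edges["a", "b"]["kind"] == "switched_pair"

    def test_recovered_truth_bookkeeping(self):
        """X3 planted in 4 triplets, all recovered, shows 4 connections."""
        _, truth = generate_switching_dataset(
            SyntheticConfig(n_genes=40, n_planted_triplets=4, n_de_genes=4, shared_x3=True, seed=6)
        )
        rows = [(t.x3_id, *sorted((t.x1_id, t.x2_id))) for t in truth.planted_triplets]
        _, counts = triplet_network(self._fake_scan(rows))
        assert counts.set_index("x3").loc[truth.planted_triplets[0].x3_id, "n_triplets"] == 4

    def test_requires_a_significant_triplet(self):
        scan = self._fake_scan([("S1", "a", "b")])
        scan.triplets["significant"] = False
        with pytest.raises(ValueError):
            triplet_network(scan)


class TestConditionedCorrelations:
    def test_boundaries_match_tertile_quantiles_at_n30(self):
        """Tie-free n = 30: middle stratum spans [-0.37, 0.37], extremes +-1.85."""
        from tripla import normal_quantile_transform

        x3 = normal_quantile_transform(np.random.default_rng(0).normal(size=30))
        rng = np.random.default_rng(1)
        cc = conditioned_correlations(rng.normal(size=30), rng.normal(size=30), x3)
        assert (cc.n_low, cc.n_mid, cc.n_high) == (10, 10, 10)
        assert round(cc.boundaries[1], 2) == 0.37
        assert round(cc.boundaries[0], 2) == -0.37
        assert round(cc.extremes[1], 2) == 1.85
        assert int(cc.extremes[1] * 100) / 100 == 1.84  # truncation, as captions print
        assert round(cc.extremes[0], 2) == -1.85

    def test_default_strata_remainders(self):
        assert default_strata(30) == (10, 10, 10)
        assert default_strata(31) == (10, 11, 10)
        assert default_strata(32) == (11, 10, 11)

    def test_planted_triplet_shows_sign_flip(self):
        """The modulation law rho(z) = 0.9 tanh(5z) shows up as a tertile sign flip.

        With a symmetric (unshifted) X3 the flip corr_high > 0 > corr_low
        holds in >= 90% of replicates; the middle stratum straddles z = 0,
        so its correlation is smallest in magnitude in most (simulation
        oracle: ~87%) replicates at strata of 10 samples.
        """
        ordered_hits = 0
        both_hits = 0
        n_reps = 200
        for seed in range(n_reps):
            config = SyntheticConfig(
                n_genes=15, n_planted_triplets=1, n_de_genes=1, de_shift=0.0, seed=seed
            )
            matrix, truth = generate_switching_dataset(config)
            tr = transform_matrix(matrix)
            t = truth.planted_triplets[0]
            cc = conditioned_correlations(tr.row(t.x1_id), tr.row(t.x2_id), tr.row(t.x3_id))
            ordered = cc.corr_high > 0 > cc.corr_low
            mid_smallest = abs(cc.corr_mid) <= min(abs(cc.corr_low), abs(cc.corr_high))
            ordered_hits += ordered
            both_hits += ordered and mid_smallest
        assert ordered_hits >= 0.9 * n_reps
        assert both_hits >= 0.8 * n_reps

    def test_unmodulated_pair_shows_no_systematic_ordering(self):
        rng = np.random.default_rng(2)
        higher = 0
        for _ in range(100):
            x1, x2, x3 = rng.normal(size=(3, 30))
            cc = conditioned_correlations(x1, x2, x3)
            higher += cc.corr_high > cc.corr_low
        assert 30 <= higher <= 70

    def test_zero_variance_stratum_reported_missing(self):
        x3 = np.arange(9, dtype=float)
        x1 = np.r_[np.ones(3), np.random.default_rng(3).normal(size=6)]
        x2 = np.random.default_rng(4).normal(size=9)
        cc = conditioned_correlations(x1, x2, x3, 3, 3, 3)
        assert np.isnan(cc.corr_low)
        assert not np.isnan(cc.corr_high)

    def test_stratum_size_validation(self):
        x = np.random.default_rng(5).normal(size=12)
        with pytest.raises(ValueError):
            conditioned_correlations(x, x, x, 6, 4, 3)
        with pytest.raises(ValueError):
            conditioned_correlations(x, x, x, 8, 2, 2)
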