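"""Contact binning, derivative remapping, neo-TAD scoring and display.

Oracles: direct tallies, exhaustive per-base coordinate dictionaries,
brute-force window sums and sort-based percentile counts.
"""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from neotadkit.hic import (
    BinTable,
    ContactMatrix,
    bin_pairs,
    ectopic_contact_score,
    empty_pairs,
    fusion_domain_enrichment,
    insulation_profile,
    ipf_balance,
    read_pairs,
    remap_pairs_to_derivative,
    rotate_45,
    truncate_for_display,
    write_pairs,
)
from neotadkit.sv_genome import CoordinateError, GenomeModel, InsertionalDuplication, build_derivative


def make_pairs(rows):
    df = pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2"])
    df.insert(0, "read_id", [f"r{i}" for i in range(len(df))])
    df["strand1"] = "+"
    df["strand2"] = "-"
    return df


def matrix_from_dense(dense, resolution=1, chrom="c1"):
    dense = np.asarray(dense, dtype=float)
    bt = BinTable(resolution, {chrom: dense.shape[0] * resolution})
    return ContactMatrix(bt, sp.csr_matrix(dense))


class TestBinPairs:
    def test_single_diagonal_pair(self):
        cm = bin_pairs(make_pairs([("c1", 5, "c1", 5)]), BinTable(10, {"c1": 100}))
        assert cm.counts[0, 0] == 1
        assert cm.total_pairs() == 1

    def test_total_count_equals_direct_tally(self):
        rng = np.random.default_rng(3)
        n = 500
        sizes = {"c1": 1000, "c2": 700}
        rows = []
        for _ in range(n):
            c1, c2 = rng.choice(["c1", "c2"], size=2)
            rows.append((c1, rng.integers(sizes[c1]), c2, rng.integers(sizes[c2])))
        cm = bin_pairs(make_pairs(rows), BinTable(50, sizes))
        assert cm.total_pairs() == n
        assert cm.is_symmetric()

    def test_position_beyond_chrom_rejected_with_record(self):
        with pytest.raises(CoordinateError, match="r0"):
            bin_pairs(make_pairs([("c1", 100, "c1", 5)]), BinTable(10, {"c1": 100}))

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(CoordinateError, match="cX"):
            bin_pairs(make_pairs([("cX", 1, "cX", 2)]), BinTable(10, {"c1": 100}))


class TestRemap:
    @pytest.fixture()
    def setup(self):
        genome = GenomeModel.from_lengths({"acc": 1000, "don": 800, "bg": 500})
        sv = InsertionalDuplication("don", 200, 350, "acc", 600)
        _, seg_map = build_derivative(genome, sv)
        return genome, sv, seg_map

    def test_donor_end_moves_into_insert(self, setup):
        _, sv, seg_map = setup
        pairs = make_pairs([("don", 210, "acc", 100)])
        out = remap_pairs_to_derivative(pairs, seg_map)
        assert out.loc[0, "chrom1"] == "deracc"
        assert out.loc[0, "pos1"] == 600 + 10
        assert out.loc[0, "chrom2"] == "deracc"
        assert out.loc[0, "pos2"] == 100

    def test_untouched_chrom_passes_through(self, setup):
        _, _, seg_map = setup
        pairs = make_pairs([("bg", 10, "bg", 400)])
        out = remap_pairs_to_derivative(pairs, seg_map)
        pd.testing.assert_frame_equal(out, pairs)

    def test_record_count_conserved(self, setup):
        _, _, seg_map = setup
        rng = np.random.default_rng(0)
        pairs = make_pairs(
            [("don", rng.integers(800), "acc", rng.integers(1000)) for _ in range(200)]
        )
        assert len(remap_pairs_to_derivative(pairs, seg_map)) == 200

    def test_unmasked_map_rejected(self, setup):
        from dataclasses import replace

        _, _, seg_map = setup
        with pytest.raises(ValueError, match="masked"):
            remap_pairs_to_derivative(make_pairs([]), replace(seg_map, mask_mode="unmasked"))

    def test_remap_then_bin_equals_per_base_oracle(self):
        """remap∘bin against an exhaustive coordinate dictionary on a 1 kb toy."""
        genome = GenomeModel.from_lengths({"acc": 400, "don": 300})
        sv = InsertionalDuplication("don", 50, 120, "acc", 250)
        der, seg_map = build_derivative(genome, sv)
        oracle = {}
        for p in range(400):
            oracle[("acc", p)] = ("deracc", p if p < 250 else p + 70)
        for p in range(300):
            if 50 <= p < 120:
                oracle[("don", p)] = ("deracc", 250 + (p - 50))
            else:
                oracle[("don", p)] = ("don", p)
        rng = np.random.default_rng(11)
        rows = []
        for _ in range(300):
            c1 = rng.choice(["acc", "don"])
            c2 = rng.choice(["acc", "don"])
            rows.append((c1, rng.integers(genome.length(c1)), c2, rng.integers(genome.length(c2))))
        pairs = make_pairs(rows)
        bt = BinTable(25, {"don": 300, "deracc": der.length})
        got = bin_pairs(remap_pairs_to_derivative(pairs, seg_map), bt)
        oracle_rows = [
            (oracle[(r.chrom1, r.pos1)][0], oracle[(r.chrom1, r.pos1)][1],
             oracle[(r.chrom2, r.pos2)][0], oracle[(r.chrom2, r.pos2)][1])
            for r in pairs.itertuples(index=False)
        ]
        expected = bin_pairs(make_pairs(oracle_rows), bt)
        assert (got.counts != expected.counts).nnz == 0


class TestEctopicScore:
    def test_uniform_trans_scores_one(self):
        bt = BinTable(10, {"a": 100, "b": 100})
        dense = np.zeros((20, 20))
        dense[:10, 10:] = 2.0
        dense[10:, :10] = 2.0
        cm = ContactMatrix(bt, sp.csr_matrix(dense))
        s = ectopic_contact_score(cm, ("a", 20, 50), ("b", 10, 40), n_permutations=50, seed=0)
        assert s.score == pytest.approx(1.0)
        assert 0 < s.empirical_p <= 1

    def test_zero_background_raises(self):
        bt = BinTable(10, {"a": 100, "b": 100})
        cm = ContactMatrix(bt, sp.csr_matrix((20, 20)))
        with pytest.raises(ValueError, match="background"):
            ectopic_contact_score(cm, ("a", 0, 50), ("b", 0, 50), n_permutations=10, seed=0)

    def test_same_chromosome_rejected(self):
        bt = BinTable(10, {"a": 100, "b": 100})
        cm = ContactMatrix(bt, sp.csr_matrix(np.ones((20, 20))))
        with pytest.raises(ValueError, match="different chromosomes"):
            ectopic_contact_score(cm, ("a", 0, 50), ("a", 50, 100))

    def test_enriched_block_detected(self):
        rng = np.random.default_rng(5)
        bt = BinTable(10, {"a": 500, "b": 500})
        dense = np.zeros((100, 100))
        trans = rng.poisson(1.0, size=(50, 50)).astype(float)
        trans[10:20, 10:20] += 10
        dense[:50, 50:] = trans
        dense[50:, :50] = trans.T
        cm = ContactMatrix(bt, sp.csr_matrix(dense))
        s = ectopic_contact_score(cm, ("a", 100, 200), ("b", 100, 200),
                                  n_permutations=200, seed=1)
        assert s.score > 3
        assert s.empirical_p < 0.01


class TestFusionEnrichment:
    def test_uniform_matrix_gives_unity_both_sides(self):
        cm = matrix_from_dense(np.ones((40, 40)))
        out = fusion_domain_enrichment(cm, "c1", {"left": 10, "right": 30}, window=3)
        assert out["left"] == pytest.approx(1.0)
        assert out["right"] == pytest.approx(1.0)

    def test_doubling_quadrant_doubles_ratio(self):
        base = np.ones((40, 40))
        cm = matrix_from_dense(base)
        r1 = fusion_domain_enrichment(cm, "c1", {"left": 10}, window=3)["left"]
        boosted = base.copy()
        boosted[7:10, 10:13] *= 2
        boosted[10:13, 7:10] *= 2
        r2 = fusion_domain_enrichment(matrix_from_dense(boosted), "c1", {"left": 10}, window=3)["left"]
        assert r2 == pytest.approx(2 * r1)

    def test_window_exceeding_extent_raises(self):
        cm = matrix_from_dense(np.ones((10, 10)))
        with pytest.raises(ValueError, match="extent"):
            fusion_domain_enrichment(cm, "c1", {"left": 1}, window=3)

    def test_window_below_two_bins_raises(self):
        cm = matrix_from_dense(np.ones((10, 10)))
        with pytest.raises(ValueError, match="window"):
            fusion_domain_enrichment(cm, "c1", {"left": 5}, window=1)


class TestInsulation:
    def test_uniform_matrix_constant_profile_no_boundaries(self):
        cm = matrix_from_dense(np.ones((20, 20)))
        profile, boundaries = insulation_profile(cm, "c1", 3)
        interior = profile[np.isfinite(profile)]
        assert np.allclose(interior, 1.0)
        assert len(boundaries) == 0

    def test_two_block_matrix_minimum_at_junction(self):
        n, k = 30, 15
        dense = np.zeros((n, n))
        dense[:k, :k] = 5.0
        dense[k:, k:] = 5.0
        cm = matrix_from_dense(dense)
        profile, boundaries = insulation_profile(cm, "c1", 4)
        assert np.nanargmin(profile) == k
        assert k in boundaries

    def test_matches_brute_force_window_sums(self):
        rng = np.random.default_rng(2)
        dense = rng.poisson(3.0, size=(25, 25)).astype(float)
        dense = (dense + dense.T) / 2
        cm = matrix_from_dense(dense)
        w = 3
        profile, _ = insulation_profile(cm, "c1", w)
        for i in range(25):
            if i < w or i > 25 - w:
                assert np.isnan(profile[i])
            else:
                expected = np.mean([dense[a, b] for a in range(i - w, i)
                                    for b in range(i, i + w)])
                assert profile[i] == pytest.approx(expected)

    def test_oversized_window_raises(self):
        cm = matrix_from_dense(np.ones((10, 10)))
        with pytest.raises(ValueError, match="window"):
            insulation_profile(cm, "c1", 6)


class TestDisplay:
    def test_all_equal_values_unchanged(self):
        mat = np.full((5, 5), 7.0)
        out = truncate_for_display(mat, rotate=False)
        assert np.array_equal(out, mat)

    def test_exactly_eight_of_thousand_distinct_values_altered(self):
        rng = np.random.default_rng(9)
        vals = rng.permutation(np.arange(1, 1001, dtype=float))
        mat = vals.reshape(25, 40)
        out = truncate_for_display(mat, percentile=99.2, rotate=False)
        threshold = np.percentile(vals, 99.2)
        expected_altered = int((np.sort(vals) > threshold).sum())
        assert expected_altered == 8
        assert int((out != mat).sum()) == 8
        assert out.max() == pytest.approx(threshold)

    def test_percentile_100_unchanged(self):
        rng = np.random.default_rng(1)
        mat = rng.poisson(4, size=(10, 10)).astype(float)
        assert np.array_equal(truncate_for_display(mat, percentile=100, rotate=False), mat)

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError, match="empty"):
            truncate_for_display(np.empty((0, 0)))

    def test_invalid_percentile_raises(self):
        with pytest.raises(ValueError, match="percentile"):
            truncate_for_display(np.ones((2, 2)), percentile=0)

    def test_rotation_places_diagonals_in_rows(self):
        mat = np.arange(16, dtype=float).reshape(4, 4)
        rot = rotate_45(mat)
        assert rot.shape == (4, 7)
        assert rot[0, 0] == mat[0, 0]
        assert rot[1, 1] == mat[0, 1]
        assert rot[3, 3] == mat[0, 3]
        assert np.isnan(rot[3, 0])


class TestRoundTripsAndBalance:
    def test_pairs_io_round_trip(self, tmp_path):
        pairs = make_pairs([("c1", 5, "c2", 9), ("c2", 3, "c1", 1)])
        path = tmp_path / "test.pairs"
        write_pairs(pairs, path, chromsizes={"c1": 100, "c2": 100})
        back = read_pairs(path)
        pd.testing.assert_frame_equal(back, pairs)

    def test_empty_pairs_file_round_trip(self, tmp_path):
        path = tmp_path / "empty.pairs"
        write_pairs(empty_pairs(), path)
        assert len(read_pairs(path)) == 0

    def test_mtx_round_trip(self, tmp_path):
        cm = bin_pairs(make_pairs([("c1", 5, "c1", 95), ("c1", 15, "c1", 15)]),
                       BinTable(10, {"c1": 100}))
        cm.to_mtx(tmp_path / "m.mtx", tmp_path / "m.bins.bed")
        back = ContactMatrix.from_mtx(tmp_path / "m.mtx", tmp_path / "m.bins.bed")
        assert (back.counts != cm.counts).nnz == 0
        assert back.bin_table.resolution == 10

    def test_ipf_balancing_equalises_row_sums(self):
        rng = np.random.default_rng(4)
        dense = rng.poisson(5.0, size=(15, 15)).astype(float) + 1
        dense = (dense + dense.T) / 2
        cm = matrix_from_dense(dense)
        balanced = ipf_balance(cm)
        rows = np.asarray(balanced.counts.todense()).sum(axis=1)
        assert rows.std() / rows.mean() < 1e-4
        assert balanced.balanced
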