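"""Derivative construction, masking, liftover and overlap classification.

The independent oracle throughout is explicit string surgery / exhaustive
per-base maps built from toy sequences.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neotadkit.datasets import load_dup_gene_fixture
from neotadkit.sv_genome import (
    Chromosome,
    CoordinateError,
    GeneInterval,
    GenomeModel,
    InsertionalDuplication,
    build_custom_genome,
    build_derivative,
    classify_gene_overlap,
    lift_coordinate,
    mask_donor,
    reverse_complement,
)


def surgery(acc: str, don: str, sv: InsertionalDuplication) -> str:
    """Direct string-editing oracle for the derivative sequence."""
    insert = don[sv.donor_start : sv.donor_end]
    if sv.orientation == "reverse":
        insert = reverse_complement(insert)
    return acc[: sv.insertion_pos] + insert + acc[sv.insertion_pos :]


class TestBuildDerivative:
    def test_three_segments_and_length_conservation(self):
        genome = GenomeModel.from_lengths({"acc": 100_000, "don": 50_000})
        sv = InsertionalDuplication("don", 20_000, 28_200, "acc", 60_000)
        der, _ = build_derivative(genome, sv)
        assert der.length == 108_200
        assert [s.der_offset for s in der.segments] == [0, 60_000, 68_200]

    def test_empty_donor_interval_gives_identity(self):
        genome = GenomeModel.from_lengths({"acc": 100, "don": 50})
        der, _ = build_derivative(genome, InsertionalDuplication("don", 5, 5, "acc", 30))
        assert der.length == 100
        assert len(der.segments) == 1

    def test_insertion_at_chrom_ends_gives_two_segments(self):
        genome = GenomeModel.from_lengths({"acc": 100, "don": 50})
        for pos in (0, 100):
            der, _ = build_derivative(genome, InsertionalDuplication("don", 10, 20, "acc", pos))
            assert len(der.segments) == 2
            assert der.length == 110

    def test_reverse_orientation_matches_string_surgery(self, tiny_genome):
        sv = InsertionalDuplication("don", 10, 30, "acc", 25, orientation="reverse")
        der, _ = build_derivative(tiny_genome, sv)
        acc = tiny_genome["acc"].sequence
        don = tiny_genome["don"].sequence
        assert der.sequence(tiny_genome) == surgery(acc, don, sv)

    def test_out_of_bounds_interval_names_chrom(self):
        genome = GenomeModel.from_lengths({"acc": 100, "don": 50})
        with pytest.raises(CoordinateError, match="don"):
            build_derivative(genome, InsertionalDuplication("don", 10, 60, "acc", 30))
        with pytest.raises(CoordinateError, match="acc"):
            build_derivative(genome, InsertionalDuplication("don", 10, 20, "acc", 101))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_random_svs_match_surgery_oracle(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**20)))
        la = data.draw(st.integers(10, 2000))
        ld = data.draw(st.integers(10, 2000))
        acc = "".join(rng.choice(list("ACGT"), size=la))
        don = "".join(rng.choice(list("ACGT"), size=ld))
        start = data.draw(st.integers(0, ld))
        end = data.draw(st.integers(start, ld))
        ins = data.draw(st.integers(0, la))
        orient = data.draw(st.sampled_from(["forward", "reverse"]))
        genome = GenomeModel.from_sequences({"acc": acc, "don": don})
        sv = InsertionalDuplication("don", start, end, "acc", ins, orientation=orient)
        der, _ = build_derivative(genome, sv)
        assert der.length == la + (end - start)
        assert der.sequence(genome) == surgery(acc, don, sv)


class TestMaskDonor:
    def test_lengths_unchanged_and_interval_is_n(self, tiny_genome, tiny_sv):
        masked = mask_donor(tiny_genome, tiny_sv)
        assert masked.lengths() == tiny_genome.lengths()
        seq = masked["don"].sequence
        assert set(seq[20:35]) == {"N"}
        assert "N" not in seq[:20] + seq[35:]

    def test_empty_interval_leaves_sequence_unchanged(self, tiny_genome):
        sv = InsertionalDuplication("don", 5, 5, "acc", 10)
        assert mask_donor(tiny_genome, sv)["don"].sequence == tiny_genome["don"].sequence

    def test_gc_fraction_outside_interval_preserved(self, tiny_genome, tiny_sv):
        masked = mask_donor(tiny_genome, tiny_sv)["don"].sequence
        out = masked.replace("N", "")
        original = tiny_genome["don"].sequence
        outside = original[:20] + original[35:]
        gc = lambda s: sum(c in "GC" for c in s) / len(s)
        assert gc(out) == pytest.approx(gc(outside))

    def test_no_sequence_is_unsupported(self):
        genome = GenomeModel.from_lengths({"acc": 100, "don": 50})
        with pytest.raises(ValueError, match="no sequence"):
            mask_donor(genome, InsertionalDuplication("don", 10, 20, "acc", 30))


def exhaustive_map(genome, sv, mask_mode):
    """Per-base oracle: for each reference base find its derivative image(s)
    by matching sequence content of the explicitly built custom genome."""
    der, seg_map = build_derivative(genome, sv)
    fwd = {}
    # acceptor bases
    la = genome.length(sv.acceptor_chrom)
    for p in range(la):
        fwd[(sv.acceptor_chrom, p)] = [
            (der.name, p if p < sv.insertion_pos else p + sv.length)
        ]
    # donor bases
    for p in range(genome.length(sv.donor_chrom)):
        if sv.donor_start <= p < sv.donor_end:
            if sv.orientation == "forward":
                q = sv.insertion_pos + (p - sv.donor_start)
            else:
                q = sv.insertion_pos + (sv.donor_end - 1 - p)
            images = [(der.name, q)]
            if mask_mode == "unmasked":
                images = [(sv.donor_chrom, p)] + images
            fwd[(sv.donor_chrom, p)] = images
        else:
            fwd[(sv.donor_chrom, p)] = [(sv.donor_chrom, p)]
    return fwd


class TestLiftCoordinate:
    def test_acceptor_left_of_insertion_is_identity(self, tiny_genome, tiny_sv):
        _, seg_map = build_derivative(tiny_genome, tiny_sv)
        assert seg_map.ref_to_der("acc", 10) == [("deracc", 10)]

    @pytest.mark.parametrize("mask_mode,n_images", [("masked", 1), ("unmasked", 2)])
    def test_matches_exhaustive_per_base_oracle(self, tiny_genome, tiny_sv, mask_mode, n_images):
        from dataclasses import replace

        _, seg_map = build_derivative(tiny_genome, tiny_sv)
        seg_map = replace(seg_map, mask_mode=mask_mode)
        oracle = exhaustive_map(tiny_genome, tiny_sv, mask_mode)
        for (chrom, pos), expected in oracle.items():
            got = lift_coordinate(seg_map, chrom, pos, "ref_to_der")
            assert got == expected, (chrom, pos)
            if chrom == tiny_sv.donor_chrom and tiny_sv.donor_start <= pos < tiny_sv.donor_end:
                assert len(got) == n_images

    def test_der_to_ref_round_trip_masked(self, tiny_genome, tiny_sv):
        der, seg_map = build_derivative(tiny_genome, tiny_sv)
        for pos in range(der.length):
            chrom, ref = seg_map.der_to_ref(pos)
            back = [q for _, q in seg_map.ref_to_der(chrom, ref)]
            assert pos in back

    def test_reverse_orientation_reflects_within_insert(self, tiny_genome):
        sv = InsertionalDuplication("don", 20, 35, "acc", 60, orientation="reverse")
        _, seg_map = build_derivative(tiny_genome, sv)
        assert seg_map.ref_to_der("don", 20) == [("deracc", 60 + 14)]
        assert seg_map.ref_to_der("don", 34) == [("deracc", 60)]

    def test_out_of_bounds_raises(self, tiny_genome, tiny_sv):
        _, seg_map = build_derivative(tiny_genome, tiny_sv)
        with pytest.raises(CoordinateError):
            seg_map.ref_to_der("acc", 100)
        with pytest.raises(CoordinateError):
            seg_map.der_to_ref(10**6)

    def test_custom_genome_sequence_agrees_with_liftover(self, tiny_genome, tiny_sv):
        custom, seg_map = build_custom_genome(tiny_genome, tiny_sv)
        der_seq = custom[seg_map.der_name].sequence
        for pos in range(len(der_seq)):
            chrom, ref = seg_map.der_to_ref(pos)
            assert der_seq[pos] == tiny_genome[chrom].sequence[ref]


class TestClassifyGeneOverlap:
    def test_published_topology_fixture_counts(self):
        genes, sv = load_dup_gene_fixture()
        labels, counts = classify_gene_overlap(genes, sv)
        assert len(genes) == 8
        assert counts["complete"] == 6
        assert counts["partial"] == 2
        assert {g for g, lab in labels.items() if lab == "partial"} == {"ANTXR1", "MXD1"}

    def test_disjoint_gene_is_none_and_counts_sum(self):
        sv = InsertionalDuplication("c1", 100, 200, "c2", 50)
        genes = [
            GeneInterval("far", "c1", 300, 400),
            GeneInterval("other_chrom", "c2", 120, 180),
            GeneInterval("inside", "c1", 120, 180),
        ]
        labels, counts = classify_gene_overlap(genes, sv)
        assert labels == {"far": "none", "other_chrom": "none", "inside": "complete"}
        assert sum(counts.values()) == len(genes)

    def test_gene_equal_to_interval_is_complete(self):
        sv = InsertionalDuplication("c1", 100, 200, "c2", 50)
        labels, _ = classify_gene_overlap([GeneInterval("g", "c1", 100, 200)], sv)
        assert labels["g"] == "complete"

    def test_breakpoint_touching_gene_is_partial(self):
        sv = InsertionalDuplication("c1", 100, 200, "c2", 50)
        labels, _ = classify_gene_overlap(
            [GeneInterval("left", "c1", 50, 150), GeneInterval("right", "c1", 150, 250)], sv
        )
        assert labels == {"left": "partial", "right": "partial"}


def test_chromosome_invariants():
    with pytest.raises(ValueError):
        Chromosome("c", 0)
    with pytest.raises(ValueError):
        Chromosome("c", 5, "ACGT")
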