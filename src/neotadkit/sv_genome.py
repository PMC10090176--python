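"""Derivative-chromosome modelling for insertional duplications.

An insertional duplication copies a *donor* interval (e.g. an ~820 kb block
on chr2) and inserts it at a distant *acceptor* locus (e.g. Xq26.1),
producing a derivative chromosome such as der(X)ins(X;2)(q26.1;p13.3).
This module builds the derivative chromosome and the "custom reference"
used for Hi-C remapping — the acceptor chromosome is replaced by the
derivative and the original donor copy is masked with N so that short
reads from the duplicated sequence map onto the chimeric junctions — and
provides bidirectional coordinate liftover plus ORF-duplication
classification of genes against the duplicated interval.

All coordinates are 0-based, half-open ``[start, end)``, matching BED.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CoordinateError",
    "Chromosome",
    "GenomeModel",
    "InsertionalDuplication",
    "Segment",
    "DerivativeGenome",
    "SegmentMap",
    "GeneInterval",
    "build_derivative",
    "build_custom_genome",
    "mask_donor",
    "lift_coordinate",
    "classify_gene_overlap",
    "read_bed_genes",
    "write_bed_genes",
    "read_sv_json",
    "write_sv_json",
    "write_segment_map_tsv",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CoordinateError(ValueError):
    """A position or interval falls outside its chromosome."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r}: length must be > 0, got {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"chromosome {self.name!r}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass
class GenomeModel:
    """Ordered mapping of chromosome name -> :class:`Chromosome`."""

    chromosomes: dict[str, Chromosome]

    def __post_init__(self) -> None:
        for name, chrom in self.chromosomes.items():
            if name != chrom.name:
                raise ValueError(f"key {name!r} does not match chromosome name {chrom.name!r}")

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __getitem__(self, name: str) -> Chromosome:
        return self.chromosomes[name]

    def length(self, name: str) -> int:
        return self.chromosomes[name].length

    def lengths(self) -> dict[str, int]:
        return {name: c.length for name, c in self.chromosomes.items()}

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "GenomeModel":
        return cls({n: Chromosome(n, len(s), s) for n, s in sequences.items()})

    @classmethod
    def from_lengths(cls, lengths: Mapping[str, int]) -> "GenomeModel":
        return cls({n: Chromosome(n, length) for n, length in lengths.items()})

    @classmethod
    def from_fasta(cls, path) -> "GenomeModel":
        chroms: dict[str, Chromosome] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            chroms[rec.id] = Chromosome(rec.id, len(seq), seq)
        if not chroms:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(chroms)

    def to_fasta(self, path) -> None:
        records = []
        for name, chrom in self.chromosomes.items():
            if chrom.sequence is None:
                raise ValueError(f"chromosome {name!r} has no sequence to write")
            records.append(SeqRecord(Seq(chrom.sequence), id=name, description=""))
        SeqIO.write(records, str(path), "fasta")


Orientation = Literal["forward", "reverse"]


@dataclass(frozen=True)
class InsertionalDuplication:
    """A donor interval copied (or moved) into an acceptor chromosome.

    ``donor_copy_retained=True`` is the duplication case: the donor locus
    keeps its original copy, so the rearranged genome carries the sequence
    twice. ``False`` models a cut-and-paste insertion.
    """

    donor_chrom: str
    donor_start: int
    donor_end: int
    acceptor_chrom: str
    insertion_pos: int
    orientation: Orientation = "forward"
    donor_copy_retained: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.donor_start <= self.donor_end:
            raise CoordinateError(
                f"donor interval [{self.donor_start}, {self.donor_end}) is not a valid "
                f"half-open interval on {self.donor_chrom!r}"
            )
        if self.insertion_pos < 0:
            raise CoordinateError(f"insertion_pos {self.insertion_pos} < 0")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be 'forward' or 'reverse', got {self.orientation!r}")

    @property
    def donor_interval(self) -> tuple[int, int]:
        return (self.donor_start, self.donor_end)

    @property
    def length(self) -> int:
        return self.donor_end - self.donor_start

    @property
    def intra_chromosomal(self) -> bool:
        return self.donor_chrom == self.acceptor_chrom

    def validate_against(self, genome: GenomeModel) -> None:
        for chrom in (self.donor_chrom, self.acceptor_chrom):
            if chrom not in genome:
                raise CoordinateError(f"chromosome {chrom!r} not in genome")
        donor_len = genome.length(self.donor_chrom)
        if self.donor_end > donor_len:
            raise CoordinateError(
                f"donor interval end {self.donor_end} exceeds {self.donor_chrom!r} "
                f"length {donor_len}"
            )
        acc_len = genome.length(self.acceptor_chrom)
        if self.insertion_pos > acc_len:
            raise CoordinateError(
                f"insertion_pos {self.insertion_pos} exceeds {self.acceptor_chrom!r} "
                f"length {acc_len}"
            )


@dataclass(frozen=True)
class Segment:
    """A source interval placed at ``der_offset`` on the derivative."""

    source_chrom: str
    source_start: int
    source_end: int
    strand: Literal["+", "-"]
    der_offset: int

    @property
    def length(self) -> int:
        return self.source_end - self.source_start

    @property
    def der_end(self) -> int:
        return self.der_offset + self.length


@dataclass(frozen=True)
class DerivativeGenome:
    name: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        offset = 0
        for seg in self.segments:
            if seg.length <= 0:
                raise ValueError("zero-length segments must be dropped before construction")
            if seg.der_offset != offset:
                raise ValueError(
                    f"segment offsets not contiguous: expected {offset}, got {seg.der_offset}"
                )
            offset = seg.der_end

    @property
    def length(self) -> int:
        return self.segments[-1].der_end if self.segments else 0

    def sequence(self, genome: GenomeModel) -> str:
        parts = []
        for seg in self.segments:
            src = genome[seg.source_chrom].sequence
            if src is None:
                raise ValueError(f"chromosome {seg.source_chrom!r} has no sequence")
            piece = src[seg.source_start : seg.source_end]
            parts.append(piece if seg.strand == "+" else reverse_complement(piece))
        return "".join(parts)


@dataclass(frozen=True)
class SegmentMap:
    """Bidirectional coordinate map between a reference and a derivative.

    ``mask_mode='masked'`` mirrors the custom-reference construction in
    which the donor copy is N-masked: reads from the duplicated sequence
    can only map to the derivative insert, so the forward map is
    single-valued everywhere. In ``'unmasked'`` mode a donor-interval
    position has two images — its original location and the insert copy.
    """

    derivative: DerivativeGenome
    sv: InsertionalDuplication
    acceptor_length: int
    mask_mode: Literal["masked", "unmasked"] = "masked"

    @property
    def der_name(self) -> str:
        return self.derivative.name

    def ref_to_der(self, chrom: str, pos: int) -> list[tuple[str, int]]:
        sv = self.sv
        if chrom == sv.acceptor_chrom:
            if not 0 <= pos < self.acceptor_length:
                raise CoordinateError(
                    f"{chrom}:{pos} outside [0, {self.acceptor_length})"
                )
            if pos < sv.insertion_pos:
                return [(self.der_name, pos)]
            return [(self.der_name, pos + sv.length)]
        if chrom == sv.donor_chrom:
            if pos < 0:
                raise CoordinateError(f"{chrom}:{pos} is negative")
            if sv.donor_start <= pos < sv.donor_end:
                if sv.orientation == "forward":
                    der_pos = sv.insertion_pos + (pos - sv.donor_start)
                else:
                    der_pos = sv.insertion_pos + (sv.donor_end - 1 - pos)
                images = [(self.der_name, der_pos)]
                if self.mask_mode == "unmasked":
                    images.insert(0, (chrom, pos))
                return images
            return [(chrom, pos)]
        raise CoordinateError(f"chromosome {chrom!r} is not covered by this segment map")

    def der_to_ref(self, pos: int) -> tuple[str, int]:
        if not 0 <= pos < self.derivative.length:
            raise CoordinateError(f"{self.der_name}:{pos} outside [0, {self.derivative.length})")
        for seg in self.derivative.segments:
            if seg.der_offset <= pos < seg.der_end:
                delta = pos - seg.der_offset
                if seg.strand == "+":
                    return (seg.source_chrom, seg.source_start + delta)
                return (seg.source_chrom, seg.source_end - 1 - delta)
        raise CoordinateError(f"no segment contains derivative position {pos}")  # pragma: no cover

    def to_tsv(self, path) -> None:
        rows = [
            (s.source_chrom, s.source_start, s.source_end, s.strand, s.der_offset)
            for s in self.derivative.segments
        ]
        pd.DataFrame(
            rows, columns=["source_chrom", "source_start", "source_end", "strand", "der_offset"]
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: Literal["+", "-"] = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise CoordinateError(
                f"gene {self.gene_id!r}: interval [{self.start}, {self.end}) is empty or invalid"
            )


def build_derivative(
    genome: GenomeModel, sv: InsertionalDuplication, name: str | None = None
) -> tuple[DerivativeGenome, SegmentMap]:
    """Compose the derivative chromosome from the acceptor and the donor insert.

    Returns the three-segment derivative (acceptor-left, donor insert,
    acceptor-right; degenerate segments dropped) and its coordinate map in
    masked mode. Total length always equals acceptor length + donor
    interval length.
    """
    sv.validate_against(genome)
    if name is None:
        name = f"der{genome[sv.acceptor_chrom].name}"
    acc_len = genome.length(sv.acceptor_chrom)
    ins = sv.insertion_pos
    strand = "+" if sv.orientation == "forward" else "-"
    raw = [
        Segment(sv.acceptor_chrom, 0, ins, "+", 0),
        Segment(sv.donor_chrom, sv.donor_start, sv.donor_end, strand, ins),
        Segment(sv.acceptor_chrom, ins, acc_len, "+", ins + sv.length),
    ]
    segments: list[Segment] = []
    offset = 0
    for seg in raw:
        if seg.length == 0:
            continue
        prev = segments[-1] if segments else None
        if (
            prev is not None
            and prev.strand == seg.strand == "+"
            and prev.source_chrom == seg.source_chrom
            and prev.source_end == seg.source_start
        ):
            segments[-1] = replace(prev, source_end=seg.source_end)
        else:
            segments.append(replace(seg, der_offset=offset))
        offset += seg.length
    derivative = DerivativeGenome(name, tuple(segments))
    assert derivative.length == acc_len + sv.length
    seg_map = SegmentMap(derivative, sv, acc_len, mask_mode="masked")
    return derivative, seg_map


def mask_donor(genome: GenomeModel, sv: InsertionalDuplication) -> GenomeModel:
    """Replace the donor interval with N, preserving all chromosome lengths.

    This mirrors the custom-reference trick of masking the original copy of
    the duplicated region so that reads from it map uniquely to the
    derivative insert. Length-preserving masking keeps every reference bin
    table valid.
    """
    chrom = genome.chromosomes.get(sv.donor_chrom)
    if chrom is None:
        raise CoordinateError(f"chromosome {sv.donor_chrom!r} not in genome")
    if chrom.sequence is None:
        raise ValueError(f"cannot mask {sv.donor_chrom!r}: no sequence available")
    if sv.donor_end > chrom.length:
        raise CoordinateError(
            f"donor interval end {sv.donor_end} exceeds {sv.donor_chrom!r} length {chrom.length}"
        )
    seq = chrom.sequence
    masked = seq[: sv.donor_start] + "N" * sv.length + seq[sv.donor_end :]
    chroms = dict(genome.chromosomes)
    chroms[sv.donor_chrom] = Chromosome(chrom.name, chrom.length, masked)
    return GenomeModel(chroms)


def build_custom_genome(
    genome: GenomeModel, sv: InsertionalDuplication, name: str | None = None
) -> tuple[GenomeModel, SegmentMap]:
    """Build the full custom reference: acceptor replaced by the derivative,
    donor copy masked. Requires sequences on donor and acceptor."""
    derivative, seg_map = build_derivative(genome, sv, name=name)
    masked = mask_donor(genome, sv)
    chroms: dict[str, Chromosome] = {}
    for cname, chrom in masked.chromosomes.items():
        if cname == sv.acceptor_chrom:
            der_seq = derivative.sequence(genome)
            chroms[derivative.name] = Chromosome(derivative.name, derivative.length, der_seq)
        else:
            chroms[cname] = chrom
    return GenomeModel(chroms), seg_map


def lift_coordinate(
    seg_map: SegmentMap,
    chrom: str,
    pos: int,
    direction: Literal["ref_to_der", "der_to_ref"],
) -> list[tuple[str, int]]:
    """Lift a single position across the segment map.

    ``ref_to_der`` returns one image (two in unmasked mode inside the donor
    interval); ``der_to_ref`` always returns exactly one. Reverse-orientation
    inserts reflect positions within the insert.
    """
    if direction == "ref_to_der":
        return seg_map.ref_to_der(chrom, pos)
    if direction == "der_to_ref":
        if chrom != seg_map.der_name:
            raise CoordinateError(
                f"der_to_ref expects chromosome {seg_map.der_name!r}, got {chrom!r}"
            )
        return [seg_map.der_to_ref(pos)]
    raise ValueError(f"unknown direction {direction!r}")


def classify_gene_overlap(
    genes: Iterable[GeneInterval], sv: InsertionalDuplication
) -> tuple[dict[str, str], Counter]:
    """Label each gene's overlap with the duplicated interval.

    ``complete`` — the whole gene body (hence its ORF) lies inside the
    donor interval; ``partial`` — the interval truncates the gene, as for
    the breakpoint-straddling genes; ``none`` otherwise. Only donor-chrom
    genes can overlap.
    """
    labels: dict[str, str] = {}
    counts: Counter = Counter(complete=0, partial=0, none=0)
    for gene in genes:
        if gene.chrom != sv.donor_chrom:
            label = "none"
        elif sv.donor_start <= gene.start and gene.end <= sv.donor_end:
            label = "complete"
        elif gene.start < sv.donor_end and gene.end > sv.donor_start:
            label = "partial"
        else:
            label = "none"
        labels[gene.gene_id] = label
        counts[label] += 1
    return labels, counts


# ---------------------------------------------------------------------------
# I/O helpers

def read_sv_json(path) -> InsertionalDuplication:
    with open(path) as fh:
        d = json.load(fh)
    return InsertionalDuplication(
        donor_chrom=d["donor_chrom"],
        donor_start=int(d["donor_start"]),
        donor_end=int(d["donor_end"]),
        acceptor_chrom=d["acceptor_chrom"],
        insertion_pos=int(d["insertion_pos"]),
        orientation=d.get("orientation", "forward"),
        donor_copy_retained=bool(d.get("donor_copy_retained", True)),
    )


def write_sv_json(sv: InsertionalDuplication, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "donor_chrom": sv.donor_chrom,
                "donor_start": sv.donor_start,
                "donor_end": sv.donor_end,
                "acceptor_chrom": sv.acceptor_chrom,
                "insertion_pos": sv.insertion_pos,
                "orientation": sv.orientation,
                "donor_copy_retained": sv.donor_copy_retained,
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def read_bed_genes(path) -> list[GeneInterval]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
    if df.shape[1] < 4:
        raise ValueError(f"BED file {path} needs at least 4 columns (chrom, start, end, name)")
    genes = []
    for row in df.itertuples(index=False):
        strand = row[5] if df.shape[1] >= 6 and row[5] in ("+", "-") else "+"
        genes.append(GeneInterval(str(row[3]), str(row[0]), int(row[1]), int(row[2]), strand))
    return genes


def write_bed_genes(genes: Iterable[GeneInterval], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_segment_map_tsv(seg_map: SegmentMap, path) -> None:
    seg_map.to_tsv(path)
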