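"""Synthetic toy cases emulating an inter-chromosomal insertional duplication.

Real patient sequencing data for this class of case is typically under
restricted access, so every pipeline stage here is exercised on generated
data with known truth. The default case mirrors the structure of a
der(X)-type event: a donor block on a chr2-like chromosome containing
eight genes (the outermost two straddling the breakpoints) is inserted
between the two genes of an acceptor TAD on a chrX-like chromosome.
Generators produce:

* the two-chromosome genome, SV description, gene/enhancer/TAD BED
  annotations and the derivative chromosome, with a truth sidecar;
* Hi-C contact pairs with power-law distance decay, within-TAD
  enrichment, uniform trans background, and — for the rearranged
  haplotype — a neo-TAD across the left breakpoint only;
* trio genotypes and per-read allele observations with the 2:1
  allele/coverage imbalance the duplication produces on the carrier
  haplotype;
* haplotype-resolved expression counts for X-inactivation assessment and
  a DE table in which the hijacked acceptor gene is the top upregulated
  gene, plus pathway gene sets enriched for the perturbed genes.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hic import PAIRS_COLUMNS, empty_pairs, write_pairs
from .sv_genome import (
    DerivativeGenome,
    GeneInterval,
    GenomeModel,
    InsertionalDuplication,
    SegmentMap,
    build_derivative,
    write_bed_genes,
    write_sv_json,
)

__all__ = [
    "SyntheticCase",
    "make_toy_case",
    "simulate_pairs",
    "simulate_case_pairs",
    "lift_der_pairs_to_reference",
    "simulate_trio_reads",
    "simulate_ase_counts",
    "simulate_de_table",
    "make_pathways",
    "simulate_coexpression_matrix",
]

DONOR = "chr2"
ACCEPTOR = "chrX"
DER = "derX"

# default pathway composition: (n genes in pathway, n of them perturbed);
# with the default DE table all perturbed genes pass the DEG filter, giving
# in-pathway DEG rates of ~20.5%, ~10.8% and ~15.9%
PATHWAY_DESIGN = {"HH": (88, 18), "BMP_TGFB": (102, 11), "WNT": (88, 14)}


@dataclass
class SyntheticCase:
    """A bundled toy case with truth labels for every pipeline stage."""

    genome: GenomeModel
    sv: InsertionalDuplication
    genes: list[GeneInterval]
    enhancers: list[tuple[str, int, int]]
    tads_reference: dict[str, list[tuple[int, int]]]
    tads_derivative: dict[str, list[tuple[int, int]]]
    derivative: DerivativeGenome
    seg_map: SegmentMap
    truth: dict
    seed: int
    scale: int

    @property
    def reference_chromsizes(self) -> dict[str, int]:
        return self.genome.lengths()

    @property
    def derivative_chromsizes(self) -> dict[str, int]:
        """Chromosome sizes of the custom-reference view (acceptor replaced)."""
        sizes = {}
        for name, length in self.genome.lengths().items():
            if name == self.sv.acceptor_chrom:
                sizes[self.derivative.name] = self.derivative.length
            else:
                sizes[name] = length
        return sizes

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genome.to_fasta(outdir / "genome.fa")
        write_sv_json(self.sv, outdir / "sv.json")
        write_bed_genes(self.genes, outdir / "genes.bed")
        with open(outdir / "enhancers.bed", "w") as fh:
            for i, (chrom, s, e) in enumerate(self.enhancers):
                fh.write(f"{chrom}\t{s}\t{e}\tenh{i + 1}\n")
        with open(outdir / "tads.bed", "w") as fh:
            for chrom, tads in self.tads_reference.items():
                for s, e in tads:
                    fh.write(f"{chrom}\t{s}\t{e}\n")
        self.seg_map.to_tsv(outdir / "segment_map.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=str)
            fh.write("\n")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length).tobytes().decode()


def make_toy_case(
    seed: int = 0,
    scale: int = 1_000_000,
    carrier_parent: str = "maternal",
    xci_rho: float = 0.5,
) -> SyntheticCase:
    """Build the default toy case at ``scale`` bp per chromosome.

    The layout is fixed in chromosome-relative fractions; only sequences
    vary with the seed. The donor interval spans 30% of the chromosome,
    eight donor genes sit across it with the first and last straddling
    the breakpoints, and the insertion lands mid-way between the two
    acceptor-TAD genes. Deterministic per seed.
    """
    if scale < 100_000:
        raise ValueError(f"scale must be >= 100000 bp to fit the annotations, got {scale}")
    if carrier_parent not in ("maternal", "paternal"):
        raise ValueError(f"carrier_parent must be maternal/paternal, got {carrier_parent!r}")
    rng = np.random.default_rng(seed)
    L = int(scale)

    def f(x: float) -> int:
        return int(round(x * L))

    genome = GenomeModel.from_sequences(
        {DONOR: _random_sequence(rng, L), ACCEPTOR: _random_sequence(rng, L)}
    )
    sv = InsertionalDuplication(DONOR, f(0.30), f(0.60), ACCEPTOR, f(0.50))
    donor_gene_bounds = [
        (0.27, 0.34),  # straddles the left breakpoint (enhancer host)
        (0.36, 0.38), (0.39, 0.41), (0.42, 0.45),
        (0.46, 0.48), (0.50, 0.52), (0.53, 0.55),
        (0.58, 0.63),  # straddles the right breakpoint
    ]
    genes = [
        GeneInterval(f"D{i + 1}", DONOR, f(s), f(e), "+" if i % 2 == 0 else "-")
        for i, (s, e) in enumerate(donor_gene_bounds)
    ]
    genes += [
        GeneInterval("ACC1", ACCEPTOR, f(0.40), f(0.43), "+"),  # hijacked
        GeneInterval("ACC2", ACCEPTOR, f(0.56), f(0.60), "-"),
    ]
    enhancers = [(DONOR, f(a), f(b)) for a, b in ((0.305, 0.308), (0.315, 0.318), (0.325, 0.328))]
    tads_reference = {
        DONOR: [(f(0.00), f(0.20)), (f(0.26), f(0.46)), (f(0.46), f(0.64)), (f(0.70), f(0.90))],
        ACCEPTOR: [(f(0.05), f(0.25)), (f(0.35), f(0.65)), (f(0.70), f(0.90))],
    }
    derivative, seg_map = build_derivative(genome, sv, name=DER)
    # the acceptor TAD fuses with the left part of the insert (neo-TAD across
    # the LEFT breakpoint only); right-breakpoint domains abut without fusing
    tads_derivative = {
        DONOR: tads_reference[DONOR],
        DER: [
            (f(0.05), f(0.25)),
            (f(0.40), f(0.66)),   # neo-TAD: hijacked gene + enhancer-bearing insert part
            (f(0.66), f(0.80)),   # ends exactly at the right breakpoint
            (f(0.80), f(0.95)),
            (f(1.00), f(1.20)),
        ],
    }
    truth = {
        "carrier_parent": carrier_parent,
        "hijacked_gene_id": "ACC1",
        "neo_tad_side": "left",
        "xci_rho": xci_rho,
        "left_breakpoint_der": sv.insertion_pos,
        "right_breakpoint_der": sv.insertion_pos + sv.length,
        # where the ectopic trans signal concentrates on the reference map:
        # the donor segment fused into the neo-TAD x the acceptor side of it
        "ectopic_region_donor": [DONOR, sv.donor_start, sv.donor_start + f(0.16)],
        "ectopic_region_acceptor": [ACCEPTOR, f(0.35), f(0.50)],
        "gene_overlap_counts": {"complete": 6, "partial": 2},
    }
    return SyntheticCase(
        genome, sv, genes, enhancers, tads_reference, tads_derivative,
        derivative, seg_map, truth, seed, L,
    )


# ---------------------------------------------------------------------------
# Hi-C pair simulation


def _sample_distances(
    rng: np.random.Generator, n: int, lmax: int, alpha: float, s0: float
) -> np.ndarray:
    """Inverse-CDF sampling from density ~ (s + s0)^-alpha on [1, lmax]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        s = s0 * ((lmax + s0) / s0) ** u - s0
    else:
        a, b = s0 ** (1 - alpha), (lmax + s0) ** (1 - alpha)
        s = (a + u * (b - a)) ** (1.0 / (1 - alpha)) - s0
    return np.clip(np.rint(s).astype(np.int64), 1, lmax)


def _tad_index(pos: np.ndarray, tads: Sequence[tuple[int, int]]) -> np.ndarray:
    """Index of the TAD containing each position, or -1."""
    if not tads:
        return np.full(len(pos), -1, dtype=np.int64)
    starts = np.array([t[0] for t in tads])
    ends = np.array([t[1] for t in tads])
    idx = np.searchsorted(starts, pos, side="right") - 1
    inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
    return np.where(inside, idx, -1)


def simulate_pairs(
    chromsizes: Mapping[str, int],
    tads: Mapping[str, Sequence[tuple[int, int]]],
    n_pairs: int,
    seed: int,
    alpha: float = 1.0,
    s0: float = 1000.0,
    tad_boost: float = 3.0,
    trans_rate: float = 0.1,
    read_prefix: str = "p",
) -> pd.DataFrame:
    """Simulate Hi-C contact pairs over a genome.

    Cis contact distance is drawn with density proportional to
    ``(s + s0)^-alpha`` (the mammalian distance-decay regime at
    ``alpha=1``); pairs whose two ends share a TAD are enriched
    ``tad_boost``-fold at matched distance (via thinning of cross-TAD
    candidates); trans pairs are uniform at rate ``trans_rate``.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if tad_boost < 1:
        raise ValueError(f"tad_boost must be >= 1, got {tad_boost}")
    if not 0 <= trans_rate <= 1:
        raise ValueError(f"trans_rate must be in [0, 1], got {trans_rate}")
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    if n_pairs == 0:
        return empty_pairs()
    rng = np.random.default_rng(seed)
    chroms = list(chromsizes)
    lengths = np.array([chromsizes[c] for c in chroms], dtype=float)

    n_trans = rng.binomial(n_pairs, trans_rate) if len(chroms) > 1 else 0
    n_cis = n_pairs - n_trans

    records: list[tuple] = []
    # trans: chromosome pair with probability proportional to length product
    if n_trans:
        pair_idx = [(i, j) for i in range(len(chroms)) for j in range(i + 1, len(chroms))]
        weights = np.array([lengths[i] * lengths[j] for i, j in pair_idx])
        choice = rng.choice(len(pair_idx), size=n_trans, p=weights / weights.sum())
        for idx, (i, j) in enumerate(pair_idx):
            m = int((choice == idx).sum())
            if not m:
                continue
            p1 = rng.integers(0, int(lengths[i]), size=m)
            p2 = rng.integers(0, int(lengths[j]), size=m)
            records.extend(zip([chroms[i]] * m, p1, [chroms[j]] * m, p2))
    # cis: batch rejection to apply the within-TAD boost as thinning
    if n_cis:
        cis_weights = lengths / lengths.sum()
        kept = 0
        while kept < n_cis:
            batch = max(2 * (n_cis - kept), 1000)
            ci = rng.choice(len(chroms), size=batch, p=cis_weights)
            for k, chrom in enumerate(chroms):
                sel = ci == k
                m = int(sel.sum())
                if not m:
                    continue
                lmax = int(lengths[k]) - 1
                s = _sample_distances(rng, m, lmax, alpha, s0)
                p1 = (rng.random(m) * (lengths[k] - s)).astype(np.int64)
                p2 = p1 + s
                t = list(tads.get(chrom, []))
                i1, i2 = _tad_index(p1, t), _tad_index(p2, t)
                same_tad = (i1 >= 0) & (i1 == i2)
                accept = same_tad | (rng.random(m) < 1.0 / tad_boost)
                for a, b in zip(p1[accept], p2[accept]):
                    if kept < n_cis:
                        records.append((chrom, int(a), chrom, int(b)))
                        kept += 1
    df = pd.DataFrame(records, columns=["chrom1", "pos1", "chrom2", "pos2"])
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    df.insert(0, "read_id", [f"{read_prefix}{i}" for i in range(len(df))])
    df["strand1"] = "+"
    df["strand2"] = "-"
    return df[PAIRS_COLUMNS]


def lift_der_pairs_to_reference(pairs: pd.DataFrame, seg_map: SegmentMap) -> pd.DataFrame:
    """Map derivative-coordinate pair ends back to reference coordinates.

    The derivative-to-reference map is total and single-valued, so this is
    exact: insert positions return to the donor interval (emulating how
    reads from the rearranged haplotype align on the reference genome).
    """
    out = pairs.copy()
    for end in ("1", "2"):
        chrom = out[f"chrom{end}"].to_numpy(dtype=object)
        pos = out[f"pos{end}"].to_numpy().astype(np.int64)
        on_der = chrom == seg_map.der_name
        if on_der.any():
            p = pos[on_der]
            new_chrom = np.empty(len(p), dtype=object)
            new_pos = np.empty(len(p), dtype=np.int64)
            done = np.zeros(len(p), dtype=bool)
            for seg in seg_map.derivative.segments:
                m = (p >= seg.der_offset) & (p < seg.der_end) & ~done
                if not m.any():
                    continue
                delta = p[m] - seg.der_offset
                new_chrom[m] = seg.source_chrom
                if seg.strand == "+":
                    new_pos[m] = seg.source_start + delta
                else:
                    new_pos[m] = seg.source_end - 1 - delta
                done |= m
            if not done.all():
                raise ValueError("derivative position outside all segments")
            chrom[on_der] = new_chrom
            pos[on_der] = new_pos
        out[f"chrom{end}"] = chrom
        out[f"pos{end}"] = pos
    return out


def simulate_case_pairs(
    case: SyntheticCase,
    n_pairs: int = 100_000,
    seed: int = 0,
    proband: bool = True,
    het_fraction: float = 0.5,
    **sim_kwargs,
) -> pd.DataFrame:
    """Reference-coordinate Hi-C pairs for the proband or a control.

    The proband is heterozygous for the derivative, so half the pairs
    (``het_fraction``) are simulated on the custom-reference view — where
    the neo-TAD across the left breakpoint generates fused-domain
    contacts — and lifted back to reference coordinates, producing the
    ectopic donor x acceptor trans signal; the rest, and all control
    pairs, come from the intact reference.
    """
    if not proband:
        return simulate_pairs(
            case.reference_chromsizes, case.tads_reference, n_pairs, seed,
            read_prefix="c", **sim_kwargs,
        )
    n_der = int(round(n_pairs * het_fraction))
    der_pairs = simulate_pairs(
        case.derivative_chromsizes, case.tads_derivative, n_der, seed,
        read_prefix="d", **sim_kwargs,
    )
    ref_pairs = simulate_pairs(
        case.reference_chromsizes, case.tads_reference, n_pairs - n_der, seed + 1,
        read_prefix="r", **sim_kwargs,
    )
    lifted = lift_der_pairs_to_reference(der_pairs, case.seg_map)
    return pd.concat([lifted, ref_pairs], ignore_index=True)


# ---------------------------------------------------------------------------
# trio reads


def simulate_trio_reads(
    case: SyntheticCase,
    carrier_parent: str | None = None,
    depth: int = 30,
    n_sites: int = 50,
    error_rate: float = 0.01,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trio genotypes and per-read allele observations over the duplication.

    60% of the informative sites fall inside the donor interval, the rest
    in the flanks. ``depth`` is the diploid flank coverage: each haplotype
    contributes Poisson(depth/2) reads per site in the flanks, while
    inside the duplication the carrier haplotype carries two copies and
    contributes Poisson(depth), giving the 2:1 coverage (and ~2/3 allele
    fraction) signature. Observed alleles flip with ``error_rate``.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not 0 <= error_rate < 0.5:
        raise ValueError(f"error_rate must be in [0, 0.5), got {error_rate}")
    if carrier_parent is None:
        carrier_parent = case.truth["carrier_parent"]
    rng = np.random.default_rng(seed)
    sv = case.sv
    flank = sv.length // 2
    n_in = int(round(n_sites * 0.6))
    pos_in = np.sort(rng.integers(sv.donor_start, sv.donor_end, size=n_in))
    n_out = n_sites - n_in
    left = rng.integers(max(0, sv.donor_start - flank), sv.donor_start, size=n_out // 2)
    right = rng.integers(
        sv.donor_end, min(case.scale, sv.donor_end + flank), size=n_out - n_out // 2
    )
    positions = np.concatenate([left, pos_in, right])
    in_dup = np.concatenate(
        [np.zeros(len(left), bool), np.ones(n_in, bool), np.zeros(len(right), bool)]
    )

    site_rows, read_rows = [], []
    for i, (pos, inside) in enumerate(zip(positions, in_dup)):
        origin = "maternal" if i % 2 == 0 else "paternal"  # alternate informative parent
        homozygous_parent = rng.random() < 0.5
        if origin == "maternal":
            mother = "1/1" if homozygous_parent else "0/1"
            father = "0/0"
        else:
            father = "1/1" if homozygous_parent else "0/1"
            mother = "0/0"
        site_id = f"s{i:04d}"
        site_rows.append((site_id, sv.donor_chrom, int(pos), "0/1", mother, father))
        # the alt allele sits on the proband haplotype inherited from `origin`
        for hap in ("maternal", "paternal"):
            lam = depth if (inside and hap == carrier_parent) else depth / 2
            n_reads = rng.poisson(lam)
            true_allele = "alt" if hap == origin else "ref"
            flips = rng.random(n_reads) < error_rate
            for r in range(n_reads):
                allele = ("ref" if true_allele == "alt" else "alt") if flips[r] else true_allele
                read_rows.append((f"{site_id}_{hap[0]}{r}", site_id, allele,
                                  sv.donor_chrom, int(pos)))
    sites = pd.DataFrame(
        site_rows, columns=["site_id", "chrom", "pos", "proband_gt", "mother_gt", "father_gt"]
    )
    reads = pd.DataFrame(read_rows, columns=["read_id", "site_id", "allele", "chrom", "pos"])
    return sites, reads


# ---------------------------------------------------------------------------
# expression


def simulate_ase_counts(
    n_genes: int = 20,
    depth: int = 50,
    rho: float = 0.5,
    n_cells: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Haplotype-resolved X-linked expression counts under XCI skew ``rho``.

    Each of ``n_cells`` cells silences haplotype B with probability
    ``rho``; per-gene read counts are then binomial in the resulting
    cell-population fraction, so genes share the tissue-level skew.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must be in [0, 1]")
    rng = np.random.default_rng(seed)
    frac_a = rng.binomial(n_cells, rho) / n_cells
    totals = rng.poisson(depth, size=n_genes)
    hap_a = rng.binomial(totals, frac_a)
    return pd.DataFrame(
        {"gene_id": [f"X{i + 1}" for i in range(n_genes)], "hapA": hap_a, "hapB": totals - hap_a}
    )


def simulate_de_table(
    n_genes: int = 5000,
    n_effect_genes: int = 155,
    hijacked_lfc: float = 6.0,
    seed: int = 0,
    hijacked_gene_id: str = "ACC1",
) -> pd.DataFrame:
    """Per-gene DE table in which the hijacked gene is the top upregulated gene.

    Null genes draw p ~ Uniform(0,1) and log2FC ~ Normal(0, 0.25); effect
    genes (3.1% by default) get very small p and |log2FC| > 2; the
    hijacked gene takes the largest fold change of all. Column
    ``is_effect`` carries the truth flag.
    """
    if not 0 < n_effect_genes < n_genes:
        raise ValueError("need 0 < n_effect_genes < n_genes")
    rng = np.random.default_rng(seed)
    gene_ids = [hijacked_gene_id] + [f"G{i + 1:05d}" for i in range(n_genes - 1)]
    lfc = rng.normal(0.0, 0.25, size=n_genes)
    p = rng.uniform(0.0, 1.0, size=n_genes)
    is_effect = np.zeros(n_genes, dtype=bool)
    is_effect[:n_effect_genes] = True
    n_eff = n_effect_genes
    signs = rng.choice([-1.0, 1.0], size=n_eff)
    magnitudes = np.minimum(2.05 + rng.exponential(1.0, size=n_eff), hijacked_lfc - 0.5)
    lfc[:n_eff] = signs * magnitudes
    p[:n_eff] = 10.0 ** (-rng.uniform(6.0, 15.0, size=n_eff))
    lfc[0] = hijacked_lfc
    p[0] = 1e-20
    return pd.DataFrame(
        {"gene_id": gene_ids, "log2_fold_change": lfc, "p_value": p, "is_effect": is_effect}
    )


def make_pathways(
    de_table: pd.DataFrame,
    seed: int = 0,
    design: Mapping[str, tuple[int, int]] = None,
) -> dict[str, list[str]]:
    """Pathway gene sets with a chosen number of perturbed members each.

    The default design assigns disjoint perturbed genes so that the
    in-pathway DEG percentages land near the hedgehog / BMP-TGFb / WNT
    enrichment levels the toy case emulates.
    """
    if design is None:
        design = PATHWAY_DESIGN
    rng = np.random.default_rng(seed)
    effect = list(de_table.loc[de_table["is_effect"], "gene_id"])
    null = list(de_table.loc[~de_table["is_effect"], "gene_id"])
    need = sum(k for _, k in design.values())
    if need > len(effect):
        raise ValueError(f"design needs {need} perturbed genes, table has {len(effect)}")
    eff_pool = list(rng.permutation(effect))
    null_pool = list(rng.permutation(null))
    pathways = {}
    for name, (size, n_eff) in design.items():
        members = [eff_pool.pop() for _ in range(n_eff)]
        members += [null_pool.pop() for _ in range(size - n_eff)]
        pathways[name] = sorted(members)
    return pathways


def simulate_coexpression_matrix(
    n_genes: int = 200,
    n_samples: int = 8,
    k: int = 10,
    separation: float = 4.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Expression matrix with ``k`` well-separated co-expression programs.

    Cluster sizes are distinct so that size-ordered labels are
    unambiguous. Returns the genes x samples matrix and truth labels.
    """
    if k > n_genes:
        raise ValueError("k cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    base = (n_genes - k * (k - 1) // 2) // k
    if base < 1:
        raise ValueError("n_genes too small for k distinct cluster sizes")
    sizes = [base + (k - 1 - i) for i in range(k)]
    sizes[0] += n_genes - sum(sizes)
    centers = rng.normal(0.0, separation, size=(k, n_samples))
    rows, labels = [], []
    g = 0
    for ci, size in enumerate(sizes):
        for _ in range(size):
            rows.append(centers[ci] + rng.normal(0.0, 1.0, size=n_samples))
            labels.append(ci)
            g += 1
    idx = [f"gene{i + 1}" for i in range(n_genes)]
    mat = pd.DataFrame(rows, index=idx, columns=[f"s{j + 1}" for j in range(n_samples)])
    return mat, pd.Series(labels, index=idx, name="truth")
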