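"""Trio-based parent-of-origin inference and allele-specific expression.

For a de novo duplication in a trio, reads over the duplicated region can
be assigned to a parental haplotype wherever they carry an allele whose
transmission is unambiguous from the trio genotypes. Reads cluster into a
maternal and a paternal group; on the haplotype carrying the duplication
the cluster covers two copies instead of one, so its depth inside the
region is ~2x the other cluster's while the flanks stay 1:1. The
parent-of-origin call compares Poisson likelihoods of the observed
cluster depths under the two carrier hypotheses (2:1 vs 1:2 inside the
region, 1:1 outside).

The same phased-variant machinery supports allele-specific expression:
X-inactivation skew is summarised as the median haplotype-A fraction over
sufficiently covered X-linked genes, with per-gene exact binomial tests
against 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrioSite",
    "ReadObservation",
    "OriginCall",
    "ASERecord",
    "XCISummary",
    "classify_informative_sites",
    "cluster_reads_by_origin",
    "call_parent_of_origin",
    "assess_xci_skew",
    "read_trio_tsv",
    "read_trio_vcf",
    "read_observations_tsv",
    "read_ase_tsv",
]

Genotype = tuple[int, int]
Origin = Literal["maternal", "paternal", "ambiguous", "uninformative", "inconsistent"]


@dataclass(frozen=True)
class TrioSite:
    site_id: str
    chrom: str
    pos: int
    proband_gt: Genotype
    mother_gt: Genotype
    father_gt: Genotype
    origin_of_alt: Origin


@dataclass(frozen=True)
class ReadObservation:
    read_id: str
    site_id: str
    allele: Literal["ref", "alt"]


@dataclass(frozen=True)
class OriginCall:
    call: Literal["maternal", "paternal", "no_call"]
    log_likelihood_ratio: float
    maternal_depth_in: int
    paternal_depth_in: int
    maternal_depth_out: int
    paternal_depth_out: int

    def to_dict(self) -> dict:
        return {
            "call": self.call,
            "log_likelihood_ratio": self.log_likelihood_ratio,
            "maternal_depth_in": self.maternal_depth_in,
            "paternal_depth_in": self.paternal_depth_in,
            "maternal_depth_out": self.maternal_depth_out,
            "paternal_depth_out": self.paternal_depth_out,
        }


@dataclass(frozen=True)
class ASERecord:
    gene_id: str
    hapA_count: int
    hapB_count: int
    allele_fraction: float
    binomial_p: float
    classification: Literal["balanced", "skewed", "low_coverage"]


@dataclass(frozen=True)
class XCISummary:
    skew: float
    classification: Literal["random", "skewed"]
    n_genes_used: int
    records: tuple[ASERecord, ...]


def _parse_gt(gt) -> Genotype | None:
    """'0/1', '1|0', (0, 1) -> sorted biallelic tuple; None if not biallelic 0/1."""
    if isinstance(gt, str):
        sep = "|" if "|" in gt else "/"
        parts = gt.split(sep)
        if len(parts) != 2:
            return None
        try:
            alleles = tuple(int(p) for p in parts)
        except ValueError:
            return None
    else:
        alleles = tuple(int(a) for a in gt)
    if any(a not in (0, 1) for a in alleles) or len(alleles) != 2:
        return None
    return tuple(sorted(alleles))  # type: ignore[return-value]


def _origin_of_alt(proband: Genotype, mother: Genotype, father: Genotype) -> Origin:
    """Transmission truth table for a biallelic site.

    The proband inherits one allele from each parent; the assignment is
    informative when the proband is heterozygous and only one of the two
    (maternal-allele, paternal-allele) decompositions is possible.
    """
    decomps = {
        (m, f) for m in mother for f in father if tuple(sorted((m, f))) == proband
    }
    if not decomps:
        return "inconsistent"
    if proband != (0, 1):
        return "uninformative"
    origins = {"maternal" if m == 1 else "paternal" for m, f in decomps}
    return origins.pop() if len(origins) == 1 else "ambiguous"


def classify_informative_sites(sites: pd.DataFrame) -> tuple[list[TrioSite], int]:
    """Classify trio genotype rows into informative/ambiguous/inconsistent sites.

    ``sites`` needs columns site_id, chrom, pos, proband_gt, mother_gt,
    father_gt (genotypes as '0/1'-style strings or allele tuples).
    Mendelian-inconsistent sites are flagged ``inconsistent`` (excluded
    from all downstream voting); non-biallelic rows are skipped and
    counted. Returns (sites, n_skipped).
    """
    out: list[TrioSite] = []
    skipped = 0
    for row in sites.itertuples(index=False):
        gts = [_parse_gt(g) for g in (row.proband_gt, row.mother_gt, row.father_gt)]
        if any(g is None for g in gts):
            skipped += 1
            continue
        p, m, f = gts
        out.append(TrioSite(str(row.site_id), str(row.chrom), int(row.pos), p, m, f,
                            _origin_of_alt(p, m, f)))
    return out, skipped


def cluster_reads_by_origin(
    observations: Iterable[ReadObservation] | pd.DataFrame,
    sites: Sequence[TrioSite],
) -> dict[str, str]:
    """Label each read maternal/paternal/ambiguous by majority vote.

    At a site whose alt allele is of known parental origin, a read carrying
    alt votes for that parent and a read carrying ref votes for the other;
    ties or reads with no informative observation are ambiguous.
    """
    site_origin = {s.site_id: s.origin_of_alt for s in sites}
    if isinstance(observations, pd.DataFrame):
        observations = [
            ReadObservation(str(r.read_id), str(r.site_id), str(r.allele))
            for r in observations.itertuples(index=False)
        ]
    votes: dict[str, list[int]] = {}
    for obs in observations:
        if obs.site_id not in site_origin:
            raise KeyError(f"observation at unknown site {obs.site_id!r}")
        origin = site_origin[obs.site_id]
        votes.setdefault(obs.read_id, [0, 0])
        if origin not in ("maternal", "paternal"):
            continue
        if obs.allele not in ("ref", "alt"):
            raise ValueError(f"allele must be 'ref' or 'alt', got {obs.allele!r}")
        alt_parent_is_maternal = origin == "maternal"
        votes_maternal = alt_parent_is_maternal == (obs.allele == "alt")
        votes[obs.read_id][0 if votes_maternal else 1] += 1
    labels = {}
    for read_id, (m, p) in votes.items():
        if m > p:
            labels[read_id] = "maternal"
        elif p > m:
            labels[read_id] = "paternal"
        else:
            labels[read_id] = "ambiguous"
    return labels


def call_parent_of_origin(
    read_labels: Mapping[str, str],
    read_positions: Mapping[str, tuple[str, int]],
    dup_region: tuple[str, int, int],
    flank_region: tuple[str, int, int] | Sequence[tuple[str, int, int]],
    llr_threshold: float = 3.0,
) -> OriginCall:
    """Poisson log-likelihood-ratio test for the duplication carrier parent.

    Under the maternal-carrier model the maternal:paternal cluster depth
    ratio is 2:1 inside the duplicated region and 1:1 in the flanks; the
    paternal-carrier model is the mirror image. Per-region rates are
    profiled out (maximum likelihood given total depth), so the flank
    contributes equally to both models and the LLR reduces to the region
    depth imbalance. A call is made only when |LLR| >= ``llr_threshold``
    (nats).
    """
    if isinstance(flank_region[0], str):
        flank_regions = [flank_region]  # type: ignore[list-item]
    else:
        flank_regions = list(flank_region)  # type: ignore[arg-type]

    def _in(region, chrom, pos):
        c, s, e = region
        return chrom == c and s <= pos < e

    n = {("maternal", True): 0, ("maternal", False): 0,
         ("paternal", True): 0, ("paternal", False): 0}
    for read_id, label in read_labels.items():
        if label not in ("maternal", "paternal"):
            continue
        chrom, pos = read_positions[read_id]
        if _in(dup_region, chrom, pos):
            n[(label, True)] += 1
        elif any(_in(fr, chrom, pos) for fr in flank_regions):
            n[(label, False)] += 1
    m_in, p_in = n[("maternal", True)], n[("paternal", True)]
    m_out, p_out = n[("maternal", False)], n[("paternal", False)]
    if m_out == 0 or p_out == 0:
        raise ValueError(
            f"zero flank depth (maternal {m_out}, paternal {p_out}): cannot calibrate baseline"
        )
    if m_in + p_in == 0:
        return OriginCall("no_call", 0.0, m_in, p_in, m_out, p_out)

    def loglik(k_m: int, k_p: int, lam_m: float, lam_p: float) -> float:
        ll = 0.0
        for k, lam in ((k_m, lam_m), (k_p, lam_p)):
            if lam <= 0:
                if k > 0:
                    return -math.inf
                continue
            ll += k * math.log(lam) - lam - math.lgamma(k + 1)
        return ll

    total_in = m_in + p_in
    lam = total_in / 3.0  # per-haplotype-copy rate under either carrier model
    llr = loglik(m_in, p_in, 2 * lam, lam) - loglik(m_in, p_in, lam, 2 * lam)
    if llr >= llr_threshold:
        call = "maternal"
    elif llr <= -llr_threshold:
        call = "paternal"
    else:
        call = "no_call"
    return OriginCall(call, float(llr), m_in, p_in, m_out, p_out)


def assess_xci_skew(
    ase: Sequence[ASERecord] | pd.DataFrame,
    min_depth: int = 10,
    skew_threshold: float = 0.80,
) -> XCISummary:
    """Global X-inactivation skew from haplotype-resolved expression counts.

    The global skew is the median haplotype-A fraction over genes with
    total depth >= ``min_depth``; classified "skewed" when the median is
    >= ``skew_threshold`` or <= 1 - ``skew_threshold`` (0.80 by common
    clinical convention). Per-gene two-sided exact binomial p-values
    against 0.5 are attached to the records.
    """
    if isinstance(ase, pd.DataFrame):
        raw = [(str(r.gene_id), int(r.hapA), int(r.hapB)) for r in ase.itertuples(index=False)]
    else:
        raw = [(r.gene_id, r.hapA_count, r.hapB_count) for r in ase]
    records = []
    fractions = []
    for gene_id, a, b in raw:
        total = a + b
        if total < min_depth:
            records.append(ASERecord(gene_id, a, b, float("nan"), float("nan"), "low_coverage"))
            continue
        frac = a / total
        p = stats.binomtest(a, total, 0.5).pvalue
        cls = "skewed" if p < 0.05 else "balanced"
        records.append(ASERecord(gene_id, a, b, frac, float(p), cls))
        fractions.append(frac)
    if not fractions:
        raise ValueError(f"no genes with depth >= {min_depth}")
    skew = float(np.median(fractions))
    classification = "skewed" if skew >= skew_threshold or skew <= 1 - skew_threshold else "random"
    return XCISummary(skew, classification, len(fractions), tuple(records))


# ---------------------------------------------------------------------------
# I/O

def read_trio_tsv(path) -> pd.DataFrame:
    """TSV with columns site_id, chrom, pos, proband_gt, mother_gt, father_gt."""
    return pd.read_csv(path, sep="\t", dtype={"site_id": str, "chrom": str})


def read_trio_vcf(path, proband: str, mother: str, father: str) -> pd.DataFrame:
    """Extract trio GT fields from a VCF into the trio-genotype frame."""
    from pysam import VariantFile

    rows = []
    with VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            gts = {}
            for name in (proband, mother, father):
                gt = rec.samples[name]["GT"]
                if gt is None or any(a is None for a in gt):
                    gts = None
                    break
                gts[name] = "/".join(str(a) for a in gt)
            if gts is None:
                continue
            rows.append(
                (rec.id or f"{rec.chrom}:{rec.pos}", rec.chrom, rec.pos - 1,
                 gts[proband], gts[mother], gts[father])
            )
    return pd.DataFrame(
        rows, columns=["site_id", "chrom", "pos", "proband_gt", "mother_gt", "father_gt"]
    )


def read_observations_tsv(path) -> pd.DataFrame:
    """TSV with columns read_id, site_id, allele."""
    return pd.read_csv(path, sep="\t", dtype=str)


def read_ase_tsv(path) -> pd.DataFrame:
    """TSV with columns gene_id, hapA, hapB."""
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})
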