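"""End-to-end orchestration: one config, one machine-readable report.

Runs the stages in the order the analysis follows: derivative-genome
construction and ORF-duplication classification, Hi-C simulation/loading,
binning and remapping, ectopic trans scoring and per-breakpoint fusion
enrichment, insulation, trio parent-of-origin inference, X-inactivation
assessment, and the DE/pathway statistics. All randomness derives from a
single root seed split deterministically per stage.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import expression, hic, phasing, synthetic
from .sv_genome import build_derivative, classify_gene_overlap

logger = logging.getLogger("neotadkit")

_THRESHOLD_DEFAULTS = {
    "padj": 0.001,
    "lfc": 2.0,
    "llr": 3.0,
    "xci_skew": 0.80,
    "ase_min_depth": 10,
}
_SYNTHETIC_DEFAULTS = {
    "scale": 1_000_000,
    "carrier_parent": "maternal",
    "xci_rho": 0.5,
    "depth": 30,
    "n_sites": 50,
    "error_rate": 0.01,
    "n_genes": 5000,
    "n_effect_genes": 155,
    "hijacked_lfc": 6.0,
}
_TOP_KEYS = {
    "seed", "resolution", "percentile", "n_permutations", "n_pairs",
    "flank_exclusion", "fusion_window", "thresholds", "synthetic", "outdir",
}
_REQUIRED = ("resolution",)


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def validate_config(cfg: Mapping[str, Any]) -> dict:
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    for key in _REQUIRED:
        if key not in cfg:
            raise ConfigError(f"missing required config key: {key!r}")
    out = dict(cfg)
    out.setdefault("seed", 0)
    out.setdefault("percentile", 99.2)
    out.setdefault("n_permutations", 500)
    out.setdefault("n_pairs", 100_000)
    res = int(out["resolution"])
    if res <= 0:
        raise ConfigError("resolution must be a positive integer")
    # None -> auto: twice the width of the larger tested region
    out.setdefault("flank_exclusion", None)
    out.setdefault("fusion_window", 6 * res)
    thresholds = dict(_THRESHOLD_DEFAULTS)
    extra = set(cfg.get("thresholds", {})) - set(_THRESHOLD_DEFAULTS)
    if extra:
        raise ConfigError(f"unknown threshold key(s): {sorted(extra)}")
    thresholds.update(cfg.get("thresholds", {}))
    if not 0 < thresholds["padj"] <= 1:
        raise ConfigError("thresholds.padj must be in (0, 1]")
    if not 0.5 <= thresholds["xci_skew"] <= 1:
        raise ConfigError("thresholds.xci_skew must be in [0.5, 1]")
    out["thresholds"] = thresholds
    synth = dict(_SYNTHETIC_DEFAULTS)
    extra = set(cfg.get("synthetic", {})) - set(_SYNTHETIC_DEFAULTS)
    if extra:
        raise ConfigError(f"unknown synthetic key(s): {sorted(extra)}")
    synth.update(cfg.get("synthetic", {}))
    out["synthetic"] = synth
    return out


def _stage_seeds(root_seed: int, names: list[str]) -> dict[str, int]:
    state = np.random.SeedSequence(root_seed).generate_state(len(names))
    return {name: int(s % (2**31)) for name, s in zip(names, state)}


def run_pipeline(config: Mapping[str, Any]) -> dict:
    """Execute every stage on a synthetic case; returns the JSON-able report.

    Stage failures are recorded in the report without aborting later
    stages.
    """
    cfg = validate_config(config)
    seeds = _stage_seeds(cfg["seed"], ["case", "pairs", "score", "trio", "ase", "de", "cluster"])
    report: dict[str, Any] = {
        "neotadkit_version": _pkg_version("neotadkit"),
        "seed": cfg["seed"],
        "stage_seeds": seeds,
        "config": {k: v for k, v in cfg.items() if k != "outdir"},
        "failures": [],
    }

    def stage(name):
        def deco(fn):
            logger.info("stage %s (seed %s)", name, seeds.get(name, "-"))
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - partial report by contract
                logger.exception("stage %s failed", name)
                report["failures"].append({"stage": name, "error": f"{type(exc).__name__}: {exc}"})
        return deco

    th = cfg["thresholds"]
    sy = cfg["synthetic"]
    case = synthetic.make_toy_case(
        seed=seeds["case"], scale=int(sy["scale"]),
        carrier_parent=sy["carrier_parent"], xci_rho=sy["xci_rho"],
    )
    truth = case.truth
    state: dict[str, Any] = {}

    @stage("sv_genome")
    def _sv():
        derivative, _ = build_derivative(case.genome, case.sv, name=case.derivative.name)
        labels, counts = classify_gene_overlap(case.genes, case.sv)
        report["derivative"] = {
            "name": derivative.name,
            "length": derivative.length,
            "n_segments": len(derivative.segments),
            "left_breakpoint": truth["left_breakpoint_der"],
            "right_breakpoint": truth["right_breakpoint_der"],
        }
        report["gene_overlap"] = {
            "labels": labels,
            "counts": {k: counts[k] for k in ("complete", "partial", "none")},
        }

    @stage("hic")
    def _hic():
        res = int(cfg["resolution"])
        proband = synthetic.simulate_case_pairs(case, cfg["n_pairs"], seeds["pairs"], proband=True)
        bt_ref = hic.BinTable(res, case.reference_chromsizes)
        cm_ref = hic.bin_pairs(proband, bt_ref)
        ra = tuple(truth["ectopic_region_donor"])
        rb = tuple(truth["ectopic_region_acceptor"])
        flank = cfg["flank_exclusion"]
        if flank is None:
            flank = 2 * max(int(ra[2]) - int(ra[1]), int(rb[2]) - int(rb[1]))
        score = hic.ectopic_contact_score(
            cm_ref, (ra[0], int(ra[1]), int(ra[2])), (rb[0], int(rb[1]), int(rb[2])),
            flank_exclusion=flank,
            n_permutations=cfg["n_permutations"], seed=seeds["score"],
        )
        report["ectopic"] = {
            "score": score.score, "empirical_p": score.empirical_p,
            "observed_mean": score.observed_mean, "background_mean": score.background_mean,
            "n_permutations": score.n_permutations,
        }
        der_pairs = hic.remap_pairs_to_derivative(proband, case.seg_map)
        bt_der = hic.BinTable(res, case.derivative_chromsizes)
        cm_der = hic.bin_pairs(der_pairs, bt_der)
        enrich = hic.fusion_domain_enrichment(
            cm_der, case.derivative.name,
            {"left": truth["left_breakpoint_der"], "right": truth["right_breakpoint_der"]},
            window=cfg["fusion_window"],
        )
        profile, boundaries = hic.insulation_profile(cm_der, case.derivative.name, window_bins=3)
        report["fusion_enrichment"] = enrich
        report["insulation"] = {
            "n_bins": int(len(profile)),
            "boundaries": [int(b) for b in boundaries],
        }
        state["cm_der"] = cm_der

    @stage("display")
    def _display():
        disp = hic.truncate_for_display(
            state["cm_der"].cis(case.derivative.name), percentile=cfg["percentile"], rotate=True
        )
        report["display"] = {
            "percentile": cfg["percentile"],
            "shape": list(disp.shape),
            "max_value": float(np.nanmax(disp)),
        }

    @stage("trio")
    def _trio():
        sites_df, reads_df = synthetic.simulate_trio_reads(
            case, depth=int(sy["depth"]), n_sites=int(sy["n_sites"]),
            error_rate=float(sy["error_rate"]), seed=seeds["trio"],
        )
        sites, skipped = phasing.classify_informative_sites(sites_df)
        labels = phasing.cluster_reads_by_origin(
            reads_df[["read_id", "site_id", "allele"]], sites
        )
        positions = {r.read_id: (r.chrom, int(r.pos)) for r in reads_df.itertuples(index=False)}
        sv = case.sv
        flank = sv.length // 2
        call = phasing.call_parent_of_origin(
            labels, positions,
            dup_region=(sv.donor_chrom, sv.donor_start, sv.donor_end),
            flank_region=[
                (sv.donor_chrom, max(0, sv.donor_start - flank), sv.donor_start),
                (sv.donor_chrom, sv.donor_end, sv.donor_end + flank),
            ],
            llr_threshold=float(th["llr"]),
        )
        report["origin_call"] = call.to_dict() | {"n_sites_skipped": skipped}

    @stage("xci")
    def _xci():
        ase = synthetic.simulate_ase_counts(rho=float(sy["xci_rho"]), seed=seeds["ase"])
        summary = phasing.assess_xci_skew(
            ase, min_depth=int(th["ase_min_depth"]), skew_threshold=float(th["xci_skew"])
        )
        report["xci"] = {
            "skew": summary.skew,
            "classification": summary.classification,
            "n_genes_used": summary.n_genes_used,
        }

    @stage("expression")
    def _expr():
        de = synthetic.simulate_de_table(
            n_genes=int(sy["n_genes"]), n_effect_genes=int(sy["n_effect_genes"]),
            hijacked_lfc=float(sy["hijacked_lfc"]), seed=seeds["de"],
            hijacked_gene_id=truth["hijacked_gene_id"],
        )
        de["adjusted_p"] = expression.bh_adjust(de["p_value"])
        degs = expression.filter_degs(de, th["padj"], th["lfc"])
        pathways = synthetic.make_pathways(de, seed=seeds["de"])
        enrichments = {
            name: expression.pathway_enrichment(
                degs["gene_id"], de["gene_id"], genes, pathway_name=name
            )
            for name, genes in pathways.items()
        }
        top = de.sort_values("log2_fold_change", ascending=False).iloc[0]
        mat, _ = synthetic.simulate_coexpression_matrix(seed=seeds["cluster"])
        clusters, excluded = expression.cluster_coexpression(mat, k=10, seed=seeds["cluster"])
        report["expression"] = {
            "n_genes": int(len(de)),
            "n_degs": int(len(degs)),
            "deg_percent": 100.0 * len(degs) / len(de),
            "top_gene_by_lfc": str(top["gene_id"]),
            "hijacked_is_deg": bool(truth["hijacked_gene_id"] in set(degs["gene_id"])),
            "pathways": {
                name: {
                    "percent_deg_in_pathway": e.percent_deg_in_pathway,
                    "chi_square": e.chi_square,
                    "p_value": e.p_value,
                }
                for name, e in enrichments.items()
            },
            "n_coexpression_clusters": int(clusters.nunique()),
            "n_constant_genes_excluded": len(excluded),
        }

    # truth-recovery summary
    recovery = {}
    if "gene_overlap" in report:
        recovery["gene_overlap_counts"] = all(
            report["gene_overlap"]["counts"][k] == v
            for k, v in truth["gene_overlap_counts"].items()
        )
    if "ectopic" in report:
        recovery["ectopic_signal"] = (
            report["ectopic"]["score"] > 3 and report["ectopic"]["empirical_p"] < 0.01
        )
    if "fusion_enrichment" in report:
        fe = report["fusion_enrichment"]
        recovery["neo_tad_left_only"] = fe["left"] > fe["right"]
    if "origin_call" in report:
        recovery["carrier_parent"] = report["origin_call"]["call"] == truth["carrier_parent"]
    if "xci" in report:
        expected = "random" if 0.2 < truth["xci_rho"] < 0.8 else "skewed"
        recovery["xci_classification"] = report["xci"]["classification"] == expected
    if "expression" in report:
        recovery["hijacked_gene_top_deg"] = (
            report["expression"]["hijacked_is_deg"]
            and report["expression"]["top_gene_by_lfc"] == truth["hijacked_gene_id"]
        )
    report["truth_recovery"] = recovery
    report["truth_recovery_all_pass"] = bool(recovery) and all(recovery.values())

    outdir = cfg.get("outdir")
    if outdir:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
            fh.write("\n")
    return report
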