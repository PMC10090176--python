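"""Downstream expression statistics.

Operates on a per-gene differential-expression table (gene_id, log2
fold change, p-value) produced upstream — the DE model fit itself is
consumed, not reimplemented. Provides Benjamini-Hochberg adjustment, DEG
filtering (adjusted p < 0.001 and |log2FC| > 2 by default), 2x2
chi-square pathway enrichment with in-pathway DEG percentages, seeded
co-expression clustering into size-ordered clusters K1..Kk, ddCt
(2^-ddCt) relative quantification, and control-normalised fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "CtMeasurement",
    "bh_adjust",
    "filter_degs",
    "pathway_enrichment",
    "cluster_coexpression",
    "ddct_fold_change",
    "normalize_to_control",
    "read_de_table",
    "read_gmt",
]

DE_COLUMNS = ("gene_id", "log2_fold_change", "p_value")


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_name: str
    deg_in_pathway: int
    deg_out_pathway: int
    nondeg_in_pathway: int
    nondeg_out_pathway: int
    percent_deg_in_pathway: float
    chi_square: float
    p_value: float

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [[self.deg_in_pathway, self.deg_out_pathway],
             [self.nondeg_in_pathway, self.nondeg_out_pathway]]
        )


@dataclass(frozen=True)
class CtMeasurement:
    sample: str
    target_ct: float
    reference_ct: float

    def __post_init__(self) -> None:
        for name, ct in (("target_ct", self.target_ct), ("reference_ct", self.reference_ct)):
            if not np.isfinite(ct) or ct <= 0:
                raise ValueError(f"{name} must be a positive cycle number, got {ct}")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_degs(
    table: pd.DataFrame,
    padj_threshold: float = 0.001,
    lfc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Differentially expressed genes: adjusted p strictly below the
    threshold AND |log2FC| strictly above the fold-change threshold."""
    if "adjusted_p" not in table.columns or table["adjusted_p"].isna().any():
        raise ValueError("adjusted_p missing; run bh_adjust first")
    keep = (table["adjusted_p"] < padj_threshold) & (
        table["log2_fold_change"].abs() > lfc_threshold
    )
    return table[keep]


def pathway_enrichment(
    degs: Iterable[str],
    universe: Iterable[str],
    pathway_genes: Iterable[str],
    pathway_name: str = "",
    yates: bool = False,
) -> EnrichmentResult:
    """2x2 chi-square test of DEG membership vs pathway membership.

    The universe is the full set of tested genes; the in-pathway DEG
    percentage is reported relative to the pathway genes present in the
    universe. Yates continuity correction is off by default.
    """
    universe = set(universe)
    degs = set(degs) & universe
    pathway = set(pathway_genes) & universe
    if not pathway:
        raise ValueError(f"pathway {pathway_name!r} has no genes in the universe")
    if not degs <= universe:
        raise ValueError("DEGs must be a subset of the universe")
    a = len(degs & pathway)
    b = len(degs - pathway)
    c = len(pathway - degs)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    percent = 100.0 * a / len(pathway)
    return EnrichmentResult(pathway_name, a, b, c, d, percent, float(chi2), float(p))


def cluster_coexpression(
    expression: pd.DataFrame,
    k: int = 10,
    seed: int | None = 0,
) -> tuple[pd.Series, list[str]]:
    """Partition genes into k co-expression clusters labelled K1..Kk.

    Rows are genes, columns samples. Each gene is z-scored across samples,
    then genes are partitioned with seeded k-means; labels are ordered by
    cluster size (K1 largest). Constant rows cannot be z-scored and are
    excluded (returned separately).
    """
    mat = expression.to_numpy(dtype=float)
    if not np.all(np.isfinite(mat)):
        raise ValueError("expression matrix contains non-finite values")
    sd = mat.std(axis=1)
    constant = sd == 0
    excluded = list(expression.index[constant])
    usable = expression.index[~constant]
    if k > len(usable):
        raise ValueError(f"k={k} exceeds the {len(usable)} non-constant genes")
    z = (mat[~constant] - mat[~constant].mean(axis=1, keepdims=True)) / sd[~constant, None]
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(z)
    order = pd.Series(raw).value_counts().index.tolist()  # by size, ties by first seen
    rename = {old: f"K{rank + 1}" for rank, old in enumerate(order)}
    labels = pd.Series([rename[r] for r in raw], index=usable, name="cluster")
    return labels, excluded


def ddct_fold_change(sample: CtMeasurement, calibrator: CtMeasurement) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (target - reference)_sample - (target - reference)_calibrator;
    ddCt = 1 means the sample expresses the target at 50% of the
    calibrator level.
    """
    ddct = sample.delta_ct - calibrator.delta_ct
    return float(2.0 ** (-ddct))


def normalize_to_control(
    values: pd.DataFrame,
    control_group: str,
    group_col: str = "group",
    time_col: str = "timepoint",
    value_col: str = "value",
) -> pd.DataFrame:
    """Express each measurement as fold change over the same-timepoint control mean.

    The control mean maps to exactly 1.0 at every timepoint (the
    convention for plotting treated samples against controls set to 1).
    """
    out = values.copy()
    means = (
        values[values[group_col] == control_group]
        .groupby(time_col)[value_col]
        .mean()
    )
    if (means == 0).any() or means.isna().any():
        raise ValueError("control group mean is zero or undefined at some timepoint")
    missing = set(out[time_col]) - set(means.index)
    if missing:
        raise ValueError(f"no control measurements at timepoint(s) {sorted(missing)}")
    out["fold_change"] = out[value_col] / out[time_col].map(means)
    return out


# ---------------------------------------------------------------------------
# I/O

def read_de_table(path) -> pd.DataFrame:
    """TSV with columns gene_id, log2_fold_change (or log2FC), p_value (or pvalue)."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"log2FC": "log2_fold_change", "pvalue": "p_value", "padj": "adjusted_p"})
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns {sorted(missing)}")
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene-set file: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
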