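"""Hi-C contact binning, derivative remapping and neo-TAD scoring.

The central idea: after an inter-chromosomal insertion, contacts between
the donor block and its new neighbourhood appear as *ectopic trans signal*
on the reference map (donor-chrom x acceptor-chrom), and as a fused
chromatin domain (a "Shuffled-TAD" or neo-TAD) across the breakpoint on
the derivative (custom-reference) cis map. This module bins 4DN-style
pairs into symmetric contact matrices, remaps pairs onto a derivative
genome through a :class:`~neotadkit.sv_genome.SegmentMap`, and scores

* ectopic trans-contact enrichment between two regions, with an empirical
  permutation p-value against distance-free trans background;
* fusion-domain (cross-breakpoint) enrichment per breakpoint side against
  a distance-matched cis background;
* insulation profiles with boundary calls;

plus the percentile-truncated, optionally 45-degree-rotated display matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .sv_genome import CoordinateError, SegmentMap

__all__ = [
    "BinTable",
    "ContactMatrix",
    "EctopicScore",
    "read_pairs",
    "write_pairs",
    "bin_pairs",
    "remap_pairs_to_derivative",
    "ectopic_contact_score",
    "fusion_domain_enrichment",
    "insulation_profile",
    "truncate_for_display",
    "rotate_45",
    "ipf_balance",
]

PAIRS_COLUMNS = ["read_id", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]


@dataclass(frozen=True)
class BinTable:
    """Fixed-resolution genomic bins tiling each chromosome without gaps."""

    resolution: int
    chromsizes: dict[str, int]
    _offsets: dict[str, int] = field(init=False, repr=False)
    _nbins: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution}")
        offsets, nbins, cursor = {}, {}, 0
        for chrom, size in self.chromsizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")
            n = -(-size // self.resolution)  # ceil; last bin may be short
            offsets[chrom] = cursor
            nbins[chrom] = n
            cursor += n
        object.__setattr__(self, "_offsets", offsets)
        object.__setattr__(self, "_nbins", nbins)

    @property
    def n_bins(self) -> int:
        return sum(self._nbins.values())

    def chrom_bins(self, chrom: str) -> tuple[int, int]:
        """Half-open global bin index range [lo, hi) of ``chrom``."""
        off = self._offsets[chrom]
        return off, off + self._nbins[chrom]

    def bin_index(self, chrom: str, pos) -> np.ndarray:
        """Global bin index of position(s) on ``chrom`` (vectorised)."""
        pos = np.asarray(pos)
        size = self.chromsizes[chrom]
        if np.any((pos < 0) | (pos >= size)):
            bad = pos[(pos < 0) | (pos >= size)]
            raise CoordinateError(f"position(s) {bad[:3].tolist()} outside {chrom!r} [0, {size})")
        return self._offsets[chrom] + pos // self.resolution

    def region_bins(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of all bins overlapping [start, end)."""
        lo, hi = self.chrom_bins(chrom)
        first = lo + max(start, 0) // self.resolution
        last = lo + (min(end, self.chromsizes[chrom]) - 1) // self.resolution
        return np.arange(first, min(last, hi - 1) + 1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, size in self.chromsizes.items():
            for i in range(self._nbins[chrom]):
                rows.append((chrom, i * self.resolution, min((i + 1) * self.resolution, size)))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["index"] = np.arange(len(df))
        return df

    def to_bed(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path) -> "BinTable":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "index"])
        res = int((df["end"] - df["start"]).max())
        sizes = df.groupby("chrom", sort=False)["end"].max().to_dict()
        return cls(res, {str(k): int(v) for k, v in sizes.items()})


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts; each pair counted once, stored twice."""

    bin_table: BinTable
    counts: sp.csr_matrix
    balanced: bool = False

    def __post_init__(self) -> None:
        n = self.bin_table.n_bins
        if self.counts.shape != (n, n):
            raise ValueError(f"counts shape {self.counts.shape} != ({n}, {n})")

    def is_symmetric(self, tol: float = 0.0) -> bool:
        diff = self.counts - self.counts.T
        return bool(abs(diff).max() <= tol) if diff.nnz else True

    def total_pairs(self) -> float:
        """Sum over the upper triangle + diagonal (= number of binned pairs)."""
        return float(sp.triu(self.counts, k=1).sum() + self.counts.diagonal().sum())

    def submatrix(self, chrom_row: str, chrom_col: str) -> np.ndarray:
        r0, r1 = self.bin_table.chrom_bins(chrom_row)
        c0, c1 = self.bin_table.chrom_bins(chrom_col)
        return np.asarray(self.counts[r0:r1, c0:c1].todense())

    def cis(self, chrom: str) -> np.ndarray:
        return self.submatrix(chrom, chrom)

    def to_mtx(self, path, bins_path=None) -> None:
        scipy.io.mmwrite(str(path), sp.coo_matrix(self.counts))
        if bins_path is not None:
            self.bin_table.to_bed(bins_path)

    @classmethod
    def from_mtx(cls, path, bins_path) -> "ContactMatrix":
        counts = sp.csr_matrix(scipy.io.mmread(str(path)))
        return cls(BinTable.from_bed(bins_path), counts)


@dataclass(frozen=True)
class EctopicScore:
    observed_mean: float
    background_mean: float
    score: float
    empirical_p: float
    n_permutations: int


# ---------------------------------------------------------------------------
# pairs I/O (4DN .pairs text)

def write_pairs(pairs: pd.DataFrame, path, chromsizes: Mapping[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        if chromsizes:
            for chrom, size in chromsizes.items():
                fh.write(f"#chromsize: {chrom} {size}\n")
        fh.write("#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2\n")
        df = pairs.reindex(columns=PAIRS_COLUMNS)
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=PAIRS_COLUMNS,
        dtype={"chrom1": str, "chrom2": str},
    )
    return df


def empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": pd.Series(dtype=str),
            "chrom1": pd.Series(dtype=str),
            "pos1": pd.Series(dtype=np.int64),
            "chrom2": pd.Series(dtype=str),
            "pos2": pd.Series(dtype=np.int64),
            "strand1": pd.Series(dtype=str),
            "strand2": pd.Series(dtype=str),
        }
    )


# ---------------------------------------------------------------------------
# binning and remapping

def bin_pairs(pairs: pd.DataFrame, bin_table: BinTable) -> ContactMatrix:
    """Aggregate contact pairs into a symmetric binned matrix.

    Each input pair contributes exactly one count to the (unordered) bin
    pair; storage is symmetric, so the upper-triangle-plus-diagonal sum
    equals the number of input pairs.
    """
    n = bin_table.n_bins
    if len(pairs) == 0:
        return ContactMatrix(bin_table, sp.csr_matrix((n, n)))
    for col in ("chrom1", "chrom2"):
        unknown = set(pairs[col].unique()) - set(bin_table.chromsizes)
        if unknown:
            raise CoordinateError(f"pairs reference chromosomes not in bin table: {sorted(unknown)}")
    i = np.empty(len(pairs), dtype=np.int64)
    j = np.empty(len(pairs), dtype=np.int64)
    for col, out in (("1", i), ("2", j)):
        for chrom, idx in pairs.groupby(f"chrom{col}", sort=False).groups.items():
            pos = pairs.loc[idx, f"pos{col}"].to_numpy()
            size = bin_table.chromsizes[chrom]
            if np.any((pos < 0) | (pos >= size)):
                bad = pairs.loc[idx][(pos < 0) | (pos >= size)].iloc[0]
                raise CoordinateError(
                    f"pair {bad['read_id']!r} position {chrom}:"
                    f"{int(bad[f'pos{col}'])} outside [0, {size})"
                )
            out[pairs.index.get_indexer(idx)] = bin_table.bin_index(chrom, pos)
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    upper = sp.coo_matrix((np.ones(len(pairs)), (lo, hi)), shape=(n, n)).tocsr()
    strict = sp.triu(upper, k=1)
    counts = upper + strict.T
    return ContactMatrix(bin_table, counts.tocsr())


def remap_pairs_to_derivative(pairs: pd.DataFrame, seg_map: SegmentMap) -> pd.DataFrame:
    """Relocate pair ends onto the derivative genome.

    Requires a masked-mode map (single-valued forward map); donor-interval
    positions move into the derivative insert, acceptor positions shift
    around it, untouched chromosomes pass through. Record count conserved.
    """
    if seg_map.mask_mode != "masked":
        raise ValueError("remapping requires a masked-mode segment map (unambiguous forward map)")
    sv = seg_map.sv
    out = pairs.copy()
    for end in ("1", "2"):
        chrom = out[f"chrom{end}"].to_numpy(dtype=object)
        pos = out[f"pos{end}"].to_numpy().astype(np.int64)
        acc = chrom == sv.acceptor_chrom
        if acc.any():
            p = pos[acc]
            if np.any((p < 0) | (p >= seg_map.acceptor_length)):
                raise CoordinateError(
                    f"acceptor position outside [0, {seg_map.acceptor_length}) in pairs"
                )
            pos[acc] = np.where(p < sv.insertion_pos, p, p + sv.length)
            chrom[acc] = seg_map.der_name
        don = (chrom == sv.donor_chrom) & (pos >= sv.donor_start) & (pos < sv.donor_end)
        if don.any():
            p = pos[don]
            if sv.orientation == "forward":
                pos[don] = sv.insertion_pos + (p - sv.donor_start)
            else:
                pos[don] = sv.insertion_pos + (sv.donor_end - 1 - p)
            chrom[don] = seg_map.der_name
        out[f"chrom{end}"] = chrom
        out[f"pos{end}"] = pos
    return out


# ---------------------------------------------------------------------------
# scoring

def ectopic_contact_score(
    cm: ContactMatrix,
    region_a: tuple[str, int, int],
    region_b: tuple[str, int, int],
    flank_exclusion: int = 0,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> EctopicScore:
    """Enrichment of trans contacts between two regions over trans background.

    Background = all trans bin pairs between the two chromosomes excluding
    the tested regions extended by ``flank_exclusion`` bp on each side.
    The empirical p-value resamples background bin-pair sets of matching
    size without replacement; reported with a +1 pseudo-count.
    """
    chrom_a, start_a, end_a = region_a
    chrom_b, start_b, end_b = region_b
    if chrom_a == chrom_b:
        raise ValueError("ectopic score is defined between regions on different chromosomes")
    trans = cm.submatrix(chrom_a, chrom_b)
    lo_a, _ = cm.bin_table.chrom_bins(chrom_a)
    lo_b, _ = cm.bin_table.chrom_bins(chrom_b)
    rows = cm.bin_table.region_bins(chrom_a, start_a, end_a) - lo_a
    cols = cm.bin_table.region_bins(chrom_b, start_b, end_b) - lo_b
    obs = trans[np.ix_(rows, cols)].ravel()

    ex_rows = cm.bin_table.region_bins(chrom_a, start_a - flank_exclusion, end_a + flank_exclusion) - lo_a
    ex_cols = cm.bin_table.region_bins(chrom_b, start_b - flank_exclusion, end_b + flank_exclusion) - lo_b
    mask = np.ones(trans.shape, dtype=bool)
    mask[ex_rows, :] = False
    mask[:, ex_cols] = False
    background = trans[mask]
    if background.size == 0 or background.sum() == 0:
        raise ValueError("all-zero trans background: ectopic score undefined")

    observed_mean = float(obs.mean())
    background_mean = float(background.mean())
    score = observed_mean / background_mean
    rng = np.random.default_rng(seed)
    k = min(obs.size, background.size)
    hits = 0
    for _ in range(n_permutations):
        sample = rng.choice(background, size=k, replace=False)
        if sample.mean() >= observed_mean:
            hits += 1
    empirical_p = (hits + 1) / (n_permutations + 1)
    return EctopicScore(observed_mean, background_mean, score, empirical_p, n_permutations)


def fusion_domain_enrichment(
    cm: ContactMatrix,
    chrom: str,
    breakpoints: Mapping[str, int],
    window: int,
) -> dict[str, float]:
    """Cross-breakpoint contact enrichment per breakpoint side.

    For each breakpoint, the observed signal is the mean count in the
    window x window quadrant spanning the breakpoint; the expectation is a
    distance-matched mean over cis bin pairs away from every breakpoint
    (a neo-TAD shows up as a ratio > 1 specifically at the fused side).
    """
    mat = cm.cis(chrom)
    n = mat.shape[0]
    res = cm.bin_table.resolution
    w = window // res
    if w < 2:
        raise ValueError(f"window {window} bp is < 2 bins at {res} bp resolution")
    bp_bins = {side: int(pos // res) for side, pos in breakpoints.items()}
    for side, b in bp_bins.items():
        if b - w < 0 or b + w > n:
            raise ValueError(f"window around {side!r} breakpoint exceeds matrix extent")

    # distance-matched background: per-diagonal mean over pairs not crossing
    # (nor near) any breakpoint window
    ii, jj = np.triu_indices(n, k=1)
    d = jj - ii
    near = np.zeros(len(ii), dtype=bool)
    for b in bp_bins.values():
        near |= (ii < b + w) & (jj >= b - w)  # anything touching the quadrant zone
    vals = mat[ii, jj]
    bg_mean_by_d = {}
    for dist in range(1, 2 * w):
        sel = (d == dist) & ~near
        if sel.sum() == 0:
            raise ValueError("no distance-matched background away from breakpoints; matrix too small")
        bg_mean_by_d[dist] = vals[sel].mean()

    out = {}
    for side, b in bp_bins.items():
        obs_i, obs_j = np.meshgrid(np.arange(b - w, b), np.arange(b, b + w), indexing="ij")
        obs_vals = mat[obs_i.ravel(), obs_j.ravel()]
        dists = (obs_j - obs_i).ravel()
        expected = np.array([bg_mean_by_d[int(t)] for t in dists])
        if expected.mean() == 0:
            raise ValueError("zero background mean; enrichment undefined")
        out[side] = float(obs_vals.mean() / expected.mean())
    return out


def insulation_profile(
    cm: ContactMatrix,
    chrom: str,
    window_bins: int,
    boundary_delta: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-square insulation values and boundary calls.

    The value at interior bin *i* is the mean count in the
    ``window_bins x window_bins`` square straddling the bin (rows
    ``[i-w, i)``, columns ``[i, i+w)``); edge bins are NaN. Boundaries are
    local minima more than ``boundary_delta`` (default: one population
    standard deviation of the profile) below the profile mean.
    """
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    mat = cm.cis(chrom)
    n = mat.shape[0]
    if window_bins > n // 2:
        raise ValueError(f"window_bins {window_bins} exceeds half the matrix size {n}")
    w = window_bins
    profile = np.full(n, np.nan)
    for i in range(w, n - w + 1):
        profile[i] = mat[i - w : i, i : i + w].mean()
    finite = profile[np.isfinite(profile)]
    if boundary_delta is None:
        boundary_delta = float(finite.std())
    threshold = finite.mean() - boundary_delta
    boundaries = []
    for i in range(1, n - 1):
        if not np.isfinite(profile[i]):
            continue
        left = profile[i - 1] if np.isfinite(profile[i - 1]) else np.inf
        right = profile[i + 1] if np.isfinite(profile[i + 1]) else np.inf
        if profile[i] < threshold and profile[i] <= left and profile[i] <= right:
            boundaries.append(i)
    return profile, np.asarray(boundaries, dtype=int)


# ---------------------------------------------------------------------------
# display

def truncate_for_display(
    matrix: np.ndarray | ContactMatrix,
    percentile: float = 99.2,
    rotate: bool = True,
) -> np.ndarray:
    """Clamp values above the given percentile of nonzero entries.

    Truncating the brightest ~0.8% of counts improves the visibility of
    the smaller values; optionally returns the 45-degree-rotated
    triangular display array (NaN-padded).
    """
    if not 0 < percentile <= 100:
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    if isinstance(matrix, ContactMatrix):
        matrix = np.asarray(matrix.counts.todense(), dtype=float)
    mat = np.asarray(matrix, dtype=float)
    if mat.size == 0:
        raise ValueError("empty matrix")
    nz = mat[mat != 0]
    if nz.size:
        threshold = np.percentile(nz, percentile)  # linear interpolation
        mat = np.minimum(mat, threshold)
    return rotate_45(mat) if rotate else mat


def rotate_45(mat: np.ndarray) -> np.ndarray:
    """Rotate a square matrix for triangular heatmap display.

    Output[d, i+j] = mat[i, j] for j >= i; unused cells are NaN. Row d is
    the bin-distance diagonal, the x-axis is the genomic midpoint.
    """
    n = mat.shape[0]
    if mat.shape != (n, n):
        raise ValueError("rotation expects a square matrix")
    out = np.full((n, 2 * n - 1), np.nan)
    ii, jj = np.triu_indices(n)
    out[jj - ii, ii + jj] = mat[ii, jj]
    return out


def ipf_balance(cm: ContactMatrix, tol: float = 1e-5, max_iter: int = 200) -> ContactMatrix:
    """Iterative proportional fitting to equalise row sums. Default off in
    all scoring (ratio scores are balance-invariant under uniform coverage)."""
    mat = np.asarray(cm.counts.todense(), dtype=float)
    bias = np.ones(mat.shape[0])
    nz = mat.sum(axis=1) > 0
    for _ in range(max_iter):
        rows = (bias[:, None] * mat * bias[None, :]).sum(axis=1)
        target = rows[nz].mean()
        update = np.ones_like(bias)
        update[nz] = np.sqrt(rows[nz] / target)
        bias /= update
        if np.abs(update - 1).max() < tol:
            break
    balanced = bias[:, None] * mat * bias[None, :]
    return ContactMatrix(cm.bin_table, sp.csr_matrix(balanced), balanced=True)
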