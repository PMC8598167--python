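"""Nucleosome-resolution contact analytics.

Implements the local-contact statistics used to compare chromatin fiber
folding between cell states from proximity-ligation pair data:

* strand-orientation classification ("in", "out", "tandem(same)") and
  filtering of in-facing pairs (likely undigested di-nucleosome
  contamination), plus interval masking;
* multi-resolution binning of pairs into per-chromosome symmetric sparse
  count matrices (canonical bin sizes 10, 200 and 5000 bp);
* contact-probability decay curves: per 10 bp distance stratum, the
  diagonal sum divided by the number of elements in the diagonal, then
  normalized to unit total over all genomic distances;
* the long/short contact-probability odds ratio: cumulative probability in
  [500, 1000) bp over cumulative probability in [50, 500) bp;
* anchor-centred aggregate pileups (element-wise median or mean over
  window submatrices, intra- or inter-anchor) and pileup differences;
* the stratum-adjusted correlation coefficient (SCC, HiCRep-style):
  distance-stratified Pearson correlations combined with weights
  ``N_d * sqrt(var_d(x) * var_d(y))``, reported per chromosome with the
  median across chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csr_matrix

__all__ = [
    "BinnedMatrix",
    "DecayCurve",
    "OddsRatioResult",
    "Pileup",
    "SCCParams",
    "SCCResult",
    "classify_and_filter_pairs",
    "bin_pairs",
    "decay_curve",
    "decay_curves_by_orientation",
    "odds_ratio",
    "pileup",
    "pileup_difference",
    "hicrep_scc",
]

ORIENTATION_LABELS = {"in": "in", "out": "out", "tandem": "tandem(same)"}


def canonicalize_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Order each record so that (chrom1, pos1) <= (chrom2, pos2), swapping
    strand labels along with coordinates."""
    df = pairs.copy()
    flip = (df["chrom1"].to_numpy() > df["chrom2"].to_numpy()) | (
        (df["chrom1"].to_numpy() == df["chrom2"].to_numpy())
        & (df["pos1"].to_numpy() > df["pos2"].to_numpy())
    )
    for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
        va, vb = df[a].to_numpy().copy(), df[b].to_numpy().copy()
        df.loc[flip, a] = vb[flip]
        df.loc[flip, b] = va[flip]
    return df


def classify_and_filter_pairs(
    pairs: pd.DataFrame,
    drop_infacing: bool = True,
    exclude_regions: list | None = None,
) -> pd.DataFrame:
    """Assign strand-orientation classes and apply the standard filters.

    After canonical ordering, ``+/-`` is "in" (reads pointing toward each
    other), ``-/+`` is "out", and ``++``/``--`` is "tandem(same)".
    In-facing pairs are removed when ``drop_infacing``; pairs with either
    end inside an excluded interval (chrom, start, end; 0-based half-open)
    are removed.
    """
    for col in ("strand1", "strand2"):
        if col not in pairs.columns:
            raise ValueError(f"pairs table missing required column {col!r}")
        bad = ~pairs[col].isin(["+", "-"])
        if bad.any():
            first = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"invalid strand value in {col!r} at record {first}")
    df = canonicalize_pairs(pairs)
    s1 = df["strand1"].to_numpy()
    s2 = df["strand2"].to_numpy()
    orientation = np.where(
        (s1 == "+") & (s2 == "-"),
        ORIENTATION_LABELS["in"],
        np.where((s1 == "-") & (s2 == "+"), ORIENTATION_LABELS["out"],
                 ORIENTATION_LABELS["tandem"]),
    )
    df = df.assign(orientation=orientation)
    if drop_infacing:
        df = df[df["orientation"] != ORIENTATION_LABELS["in"]]
    if exclude_regions:
        keep = np.ones(len(df), dtype=bool)
        for chrom, start, end in exclude_regions:
            for cc, pc in (("chrom1", "pos1"), ("chrom2", "pos2")):
                hit = (
                    (df[cc].to_numpy() == chrom)
                    & (df[pc].to_numpy() - 1 >= start)
                    & (df[pc].to_numpy() - 1 < end)
                )
                keep &= ~hit
        df = df[keep]
    return df.reset_index(drop=True)


@dataclass
class BinnedMatrix:
    """Per-chromosome symmetric sparse contact-count matrix."""

    chrom: str
    bin_size: int
    counts: csr_matrix

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> float:
        """Total pair count (each pair counted once: upper triangle plus
        half of the symmetrized off-diagonal mass)."""
        full = self.counts.sum()
        diag = self.counts.diagonal().sum()
        return float((full - diag) / 2 + diag)


def bin_pairs(
    pairs: pd.DataFrame, chrom_sizes: dict, bin_size: int
) -> dict[str, BinnedMatrix]:
    """Bin canonical pairs into per-chromosome symmetric count matrices.

    Each pair increments cell ``((pos1-1)//bin, (pos2-1)//bin)`` and its
    transpose image (diagonal cells are incremented once).  Positions are
    1-based; inter-chromosomal records are rejected.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if (pairs["chrom1"].to_numpy() != pairs["chrom2"].to_numpy()).any():
        raise ValueError("inter-chromosomal pairs cannot be binned per-chromosome")
    out: dict[str, BinnedMatrix] = {}
    for chrom, size in chrom_sizes.items():
        sub = pairs[pairs["chrom1"] == chrom]
        n_bins = int(np.ceil(size / bin_size))
        p1 = sub["pos1"].to_numpy(np.int64)
        p2 = sub["pos2"].to_numpy(np.int64)
        if len(sub) and (
            (p1 < 1).any() or (p2 < 1).any() or (p1 > size).any() or (p2 > size).any()
        ):
            raise ValueError(f"positions outside chromosome bounds on {chrom}")
        b1 = (p1 - 1) // bin_size
        b2 = (p2 - 1) // bin_size
        m = coo_matrix(
            (np.ones(len(sub)), (b1, b2)), shape=(n_bins, n_bins)
        ).tocsr()
        upper = m + m.T
        upper.setdiag(upper.diagonal() / 2)
        out[chrom] = BinnedMatrix(chrom, bin_size, upper.tocsr())
    return out


@dataclass
class DecayCurve:
    """Normalized contact probability by genomic-distance stratum."""

    bin_size: int
    probability: np.ndarray   # index d covers genomic distance d * bin_size

    @property
    def distances_bp(self) -> np.ndarray:
        return np.arange(len(self.probability)) * self.bin_size

    def cumulative(self, lo_bp: float, hi_bp: float) -> float:
        """Cumulative probability over distances in the half-open band
        [lo_bp, hi_bp)."""
        d = self.distances_bp
        return float(self.probability[(d >= lo_bp) & (d < hi_bp)].sum())


def _diag_sums(matrix: BinnedMatrix) -> np.ndarray:
    coo = matrix.counts.tocoo()
    keep = coo.col >= coo.row
    d = coo.col[keep] - coo.row[keep]
    return np.bincount(d, weights=coo.data[keep], minlength=matrix.n_bins)


def decay_curve(matrices: dict[str, BinnedMatrix] | BinnedMatrix) -> DecayCurve:
    """Pooled contact-probability decay over all chromosomes.

    For each distance stratum d, diagonal sums and diagonal element counts
    are pooled across chromosomes; the per-element rate is then normalized
    so the curve sums to one across all genomic distances.
    """
    if isinstance(matrices, BinnedMatrix):
        matrices = {matrices.chrom: matrices}
    if not matrices:
        raise ValueError("no matrices given")
    bin_size = next(iter(matrices.values())).bin_size
    max_bins = max(m.n_bins for m in matrices.values())
    num = np.zeros(max_bins)
    den = np.zeros(max_bins)
    for m in matrices.values():
        if m.bin_size != bin_size:
            raise ValueError("mixed bin sizes")
        s = _diag_sums(m)
        num[: len(s)] += s
        den[: m.n_bins] += m.n_bins - np.arange(m.n_bins)
    if num.sum() == 0:
        raise ValueError("empty contact matrix")
    rate = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    return DecayCurve(bin_size, rate / rate.sum())


def decay_curves_by_orientation(
    pairs: pd.DataFrame, chrom_sizes: dict, bin_size: int = 10
) -> dict[str, DecayCurve]:
    """Classify pairs and compute one pooled decay curve per orientation
    class (in-facing pairs retained here so all classes are present)."""
    df = classify_and_filter_pairs(pairs, drop_infacing=False)
    out = {}
    for label, sub in df.groupby("orientation"):
        out[label] = decay_curve(bin_pairs(sub, chrom_sizes, bin_size))
    return out


@dataclass(frozen=True)
class OddsRatioResult:
    """Long/short contact-probability ratio with degenerate-input flag."""

    value: float
    defined: bool
    short_range: float
    long_range: float


def odds_ratio(
    curve: DecayCurve,
    short_band: tuple[float, float] = (50.0, 500.0),
    long_band: tuple[float, float] = (500.0, 1000.0),
) -> OddsRatioResult:
    """Cumulative probability in the long band over the short band
    (half-open intervals).  Zero short-range mass yields an explicitly
    undefined result rather than infinity."""
    short = curve.cumulative(*short_band)
    long = curve.cumulative(*long_band)
    if short == 0.0:
        return OddsRatioResult(float("nan"), False, short, long)
    return OddsRatioResult(long / short, True, short, long)


@dataclass
class Pileup:
    """Anchor-centred aggregate contact matrix."""

    matrix: np.ndarray
    bin_size: int
    half_width: int
    statistic: str            # "median" | "mean"
    mode: str                 # "intra" | "inter"
    n_submatrices: int
    n_anchors_dropped: int = 0


def _anchor_windows(matrix: BinnedMatrix, anchors: pd.DataFrame, half_bins: int):
    windows = []
    dropped = 0
    sub = anchors[anchors["chrom"] == matrix.chrom]
    for pos in sub["start"].to_numpy():
        c = int(pos) // matrix.bin_size
        lo, hi = c - half_bins, c + half_bins
        if lo < 0 or hi > matrix.n_bins:
            dropped += 1
            continue
        windows.append((lo, hi))
    return windows, dropped


def pileup(
    matrices: dict[str, BinnedMatrix] | BinnedMatrix,
    anchors: pd.DataFrame,
    half_width: int = 10_000,
    statistic: str = "median",
    mode: str = "intra",
    include_trans: bool = False,
) -> Pileup:
    """Element-wise aggregate over anchor-window submatrices.

    intra: each window against itself; inter: all ordered same-chromosome
    window pairs (i < j).  Anchors whose window runs off the matrix edge
    are dropped and counted.  ``include_trans`` has no effect on
    per-chromosome matrices (inter-chromosomal counts are not recorded
    in this container) and is rejected to avoid silently empty blocks.
    """
    if include_trans:
        raise NotImplementedError(
            "inter-chromosomal pileups require a trans contact container; "
            "per-chromosome matrices hold cis counts only")
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    if mode not in ("intra", "inter"):
        raise ValueError("mode must be 'intra' or 'inter'")
    if isinstance(matrices, BinnedMatrix):
        matrices = {matrices.chrom: matrices}
    bin_size = next(iter(matrices.values())).bin_size
    half_bins = int(half_width // bin_size)
    blocks = []
    dropped = 0
    for m in matrices.values():
        windows, d = _anchor_windows(m, anchors, half_bins)
        dropped += d
        dense = None
        if windows:
            dense = m.counts.toarray()
        if mode == "intra":
            for lo, hi in windows:
                blocks.append(dense[lo:hi, lo:hi])
        else:
            for i in range(len(windows)):
                for j in range(i + 1, len(windows)):
                    li, hi_ = windows[i]
                    lj, hj = windows[j]
                    blocks.append(dense[li:hi_, lj:hj])
    if not blocks:
        raise ValueError("no contributing submatrices")
    stack = np.stack(blocks)
    agg = np.median(stack, axis=0) if statistic == "median" else stack.mean(axis=0)
    return Pileup(agg, bin_size, half_width, statistic, mode, len(blocks), dropped)


def pileup_difference(a: Pileup, b: Pileup) -> np.ndarray:
    """Element-wise a - b (shapes, bin size and statistic must match)."""
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("pileup shapes differ")
    if a.bin_size != b.bin_size or a.statistic != b.statistic:
        raise ValueError("pileup bin size / statistic differ")
    return a.matrix - b.matrix


@dataclass(frozen=True)
class SCCParams:
    bin_size: int = 5000
    max_distance: int = 100_000
    smoothing_half_width: int = 1

    def __post_init__(self):
        if self.max_distance % self.bin_size:
            raise ValueError("max_distance must be a multiple of bin_size")


@dataclass
class SCCResult:
    per_chromosome: dict
    median: float


def _box_mean(dense: np.ndarray, h: int) -> np.ndarray:
    """2-D mean filter with window 2h+1, truncated at the matrix edges."""
    if h <= 0:
        return dense
    n = dense.shape[0]
    pad = np.zeros((n + 1, n + 1))
    pad[1:, 1:] = np.cumsum(np.cumsum(dense, axis=0), axis=1)
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    s = pad[np.ix_(hi, hi)] - pad[np.ix_(lo, hi)] - pad[np.ix_(hi, lo)] + pad[
        np.ix_(lo, lo)
    ]
    cnt = np.outer(hi - lo, hi - lo)
    return s / cnt


def _scc_single(x: np.ndarray, y: np.ndarray, n_strata: int) -> float:
    num = 0.0
    den = 0.0
    n = x.shape[0]
    for d in range(min(n_strata + 1, n)):
        xd = np.diagonal(x, offset=d)
        yd = np.diagonal(y, offset=d)
        vx = xd.var()
        vy = yd.var()
        if vx == 0.0 or vy == 0.0 or len(xd) < 2:
            continue
        r = np.corrcoef(xd, yd)[0, 1]
        w = len(xd) * np.sqrt(vx * vy)
        num += w * r
        den += w
    if den == 0.0:
        return float("nan")
    return num / den


def hicrep_scc(
    m1: dict[str, BinnedMatrix],
    m2: dict[str, BinnedMatrix],
    params: SCCParams = SCCParams(),
) -> SCCResult:
    """Stratum-adjusted correlation between two sets of contact matrices.

    Each matrix is normalized by its total contact sum, optionally
    smoothed with a 2-D mean filter, then distance strata up to
    ``max_distance`` are Pearson-correlated and combined with weights
    ``N_d * sqrt(var_d(x) * var_d(y))``.  Zero-variance strata carry zero
    weight.  Per-chromosome SCCs and their median are returned; an
    all-zero matrix yields NaN for that chromosome.
    """
    if set(m1) != set(m2):
        raise ValueError("chromosome sets differ")
    n_strata = params.max_distance // params.bin_size
    per = {}
    for chrom in m1:
        a, b = m1[chrom], m2[chrom]
        if a.bin_size != params.bin_size or b.bin_size != params.bin_size:
            raise ValueError("matrix bin size does not match SCC params")
        if a.n_bins != b.n_bins:
            raise ValueError(f"matrix shapes differ on {chrom}")
        ta, tb = a.counts.sum(), b.counts.sum()
        if ta == 0 or tb == 0:
            per[chrom] = float("nan")
            continue
        x = _box_mean(a.counts.toarray() / ta, params.smoothing_half_width)
        y = _box_mean(b.counts.toarray() / tb, params.smoothing_half_width)
        per[chrom] = _scc_single(x, y, n_strata)
    vals = [v for v in per.values() if not np.isnan(v)]
    med = float(np.median(vals)) if vals else float("nan")
    return SCCResult(per, med)
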