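"""Synthetic inputs for the chromatin-folding pipelines.

Every downstream stage of the package (fiber simulation, Micro-C style
contact analytics, erosion diameter estimation) consumes data that in the
laboratory comes from sequencing or tomography.  This module generates
statistically controlled stand-ins for each of those inputs:

* nucleosome tracks -- dyad positions with per-nucleosome acetylation and
  linker-histone (LH) occupancy flags, emulating MNase-seq nucleosome calls
  combined with ChIP-seq flag calls;
* contact-pair files -- 4DN-pairs-style records whose genomic-distance
  distribution is an explicit mixture of nucleosome-neighbour peaks, a
  long-range band, uniform background, and optional anchor-driven loop and
  stripe components;
* anchor sets -- sorted non-overlapping point anchors (condensin-peak /
  domain-boundary stand-ins) for pileup analysis;
* binary tube volumes -- solid cylinders on a voxel grid standing in for
  segmented chromatin-fiber tomograms.

All generators are pure functions of their spec and seed: rerunning with the
same arguments is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticFiberSpec",
    "SyntheticContactSpec",
    "generate_nucleosome_track",
    "generate_contact_pairs",
    "generate_anchors",
    "generate_tube_volume",
]

#: minimum distance between neighbouring dyads (one nucleosome footprint)
MIN_DYAD_SPACING = 147


@dataclass(frozen=True)
class SyntheticFiberSpec:
    """Parameters of a synthetic nucleosome track.

    Defaults mirror the quiescent-cell fiber of the study system: ~165 bp
    nucleosome repeat length and an LH density of 0.29 LH/nucleosome with
    almost no acetylation.
    """

    n_nucleosomes: int = 228
    mean_repeat_length: float = 165.0
    repeat_jitter_sd: float = 0.0
    nfr_positions: tuple[tuple[int, int], ...] = ()
    acetylation_density: float = 3 / 228
    lh_density: float = 0.29
    seed: int = 0

    def validate(self) -> None:
        if self.n_nucleosomes < 1:
            raise ValueError("n_nucleosomes must be >= 1")
        for name in ("acetylation_density", "lh_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_repeat_length < MIN_DYAD_SPACING:
            raise ValueError(
                f"mean_repeat_length must be >= {MIN_DYAD_SPACING} bp so dyads "
                "cannot overlap"
            )
        if self.repeat_jitter_sd < 0:
            raise ValueError("repeat_jitter_sd must be >= 0")
        for start, length in self.nfr_positions:
            if length < 0 or start < 0:
                raise ValueError("NFR positions must have start, length >= 0")


@dataclass(frozen=True)
class NucleosomeTrack:
    """Dyad positions (bp, 0-based) plus per-nucleosome boolean flags."""

    chrom: str
    dyads: np.ndarray          # int64, strictly increasing
    acetylated: np.ndarray     # bool
    lh_bound: np.ndarray       # bool

    def __post_init__(self):
        if not (len(self.dyads) == len(self.acetylated) == len(self.lh_bound)):
            raise ValueError("track arrays must have equal length")
        if len(self.dyads) > 1 and np.any(np.diff(self.dyads) < MIN_DYAD_SPACING):
            raise ValueError(f"dyads closer than {MIN_DYAD_SPACING} bp")

    @property
    def n_nucleosomes(self) -> int:
        return len(self.dyads)

    @property
    def linker_lengths(self) -> np.ndarray:
        """Linker DNA lengths (bp) between consecutive nucleosomes."""
        return np.diff(self.dyads) - MIN_DYAD_SPACING

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "dyad": self.dyads,
                "acetyl_flag": self.acetylated.astype(int),
                "lh_flag": self.lh_bound.astype(int),
            }
        )


def generate_nucleosome_track(
    spec: SyntheticFiberSpec, chrom: str = "chrS", start: int = 1000
) -> NucleosomeTrack:
    """Draw a nucleosome track from `spec`.

    Dyads are laid down sequentially with inter-dyad spacing
    ``max(147, N(mean_repeat_length, jitter_sd))``; a dyad that would fall
    inside a nucleosome-free region (NFR) is pushed past it, so NFRs are
    realized as dyad-free gaps.  Acetylation and LH flags are independent
    Bernoulli draws at the configured densities.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nfrs = sorted((int(s), int(s) + int(l)) for s, l in spec.nfr_positions)

    dyads = np.empty(spec.n_nucleosomes, dtype=np.int64)
    pos = float(start)
    for i in range(spec.n_nucleosomes):
        if i > 0:
            step = spec.mean_repeat_length
            if spec.repeat_jitter_sd > 0:
                step += rng.normal(0.0, spec.repeat_jitter_sd)
            pos += max(MIN_DYAD_SPACING, step)
        # nucleosome footprint is dyad +/- 73 bp; skip past any NFR it hits
        for lo, hi in nfrs:
            if pos + 74 > lo and pos - 73 < hi:
                pos = hi + 74.0
        dyads[i] = int(round(pos))
        pos = float(dyads[i])

    acetylated = rng.random(spec.n_nucleosomes) < spec.acetylation_density
    lh_bound = rng.random(spec.n_nucleosomes) < spec.lh_density
    return NucleosomeTrack(chrom, dyads, acetylated, lh_bound)


# ---------------------------------------------------------------------------
# contact pairs
# ---------------------------------------------------------------------------

STRAND_CLASSES = ("in", "out", "tandem_pp", "tandem_mm")


@dataclass(frozen=True)
class SyntheticContactSpec:
    """Mixture model for synthetic intra-chromosomal contact pairs.

    The genomic-distance distribution of non-background pairs is a mixture
    of nucleosome-neighbour components (separation k converted to bp as
    ``k * repeat_length`` with Gaussian jitter), a uniform long-range band,
    and optional anchor-loop / stripe components.  The remaining mass is
    uniform background.  ``infacing_fraction`` of pairs carry in-facing
    strand orientation (+/- after canonical ordering); the rest are split
    evenly among out-facing and the two tandem orientations.
    """

    chrom_sizes: dict = field(default_factory=lambda: {"chrS": 1_000_000})
    n_pairs: int = 100_000
    neighbor_weights: dict = field(default_factory=lambda: {1: 0.5, 2: 0.2, 3: 0.1})
    repeat_length: float = 165.0
    distance_jitter_sd: float = 15.0
    long_range_weight: float = 0.1
    long_range_band: tuple[float, float] = (500.0, 1000.0)
    background_weight: float = 0.05
    anchor_loop_fraction: float = 0.0
    stripe_fraction: float = 0.0
    anchors: tuple[int, ...] = ()
    anchor_jitter_sd: float = 200.0
    domain_size: int = 20_000
    infacing_fraction: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be > 0")
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must be non-empty")
        fracs = {
            "long_range_weight": self.long_range_weight,
            "background_weight": self.background_weight,
            "anchor_loop_fraction": self.anchor_loop_fraction,
            "stripe_fraction": self.stripe_fraction,
            "infacing_fraction": self.infacing_fraction,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(w < 0 for w in self.neighbor_weights.values()):
            raise ValueError("neighbor_weights must be >= 0")
        if (self.anchor_loop_fraction > 0 or self.stripe_fraction > 0) and len(
            self.anchors
        ) < 2:
            raise ValueError("anchor components require >= 2 anchors")

    def component_probabilities(self) -> tuple[np.ndarray, list]:
        """Normalized mixture over labelled components.

        Returns (probabilities, labels) where labels are
        ('neighbor', k), ('long',), ('background',), ('loop',), ('stripe',).
        """
        labels: list = [("loop",), ("stripe",)]
        raw = [self.anchor_loop_fraction, self.stripe_fraction]
        rest = 1.0 - self.anchor_loop_fraction - self.stripe_fraction
        if rest < 0:
            raise ValueError("anchor_loop_fraction + stripe_fraction > 1")
        nw_total = sum(self.neighbor_weights.values())
        dist_total = nw_total + self.long_range_weight + self.background_weight
        if dist_total <= 0:
            raise ValueError("distance mixture has zero total mass")
        for k in sorted(self.neighbor_weights):
            labels.append(("neighbor", k))
            raw.append(rest * self.neighbor_weights[k] / dist_total)
        labels.append(("long",))
        raw.append(rest * self.long_range_weight / dist_total)
        labels.append(("background",))
        raw.append(rest * self.background_weight / dist_total)
        p = np.asarray(raw, dtype=float)
        return p / p.sum(), labels


def generate_contact_pairs(spec: SyntheticContactSpec) -> pd.DataFrame:
    """Emit exactly ``spec.n_pairs`` canonical pair records.

    Columns: readID, chrom1, pos1, chrom2, pos2, strand1, strand2.
    Positions are 1-based and canonically ordered (pos1 <= pos2 within a
    chromosome).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pairs

    chroms = list(spec.chrom_sizes)
    sizes = np.array([spec.chrom_sizes[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    size_of = sizes[chrom_idx]

    probs, labels = spec.component_probabilities()
    comp = rng.choice(len(labels), size=n, p=probs)

    pos1 = np.empty(n, dtype=np.int64)
    pos2 = np.empty(n, dtype=np.int64)
    anchors = np.asarray(spec.anchors, dtype=np.int64)

    for ci, label in enumerate(labels):
        m = comp == ci
        cnt = int(m.sum())
        if cnt == 0:
            continue
        sz = size_of[m]
        if label[0] == "background":
            a = rng.integers(1, sz.astype(np.int64) + 1)
            b = rng.integers(1, sz.astype(np.int64) + 1)
            pos1[m], pos2[m] = np.minimum(a, b), np.maximum(a, b)
            continue
        if label[0] == "loop":
            pick = np.array(
                [rng.choice(len(anchors), size=2, replace=False) for _ in range(cnt)]
            )
            a = anchors[pick[:, 0]] + rng.normal(0, spec.anchor_jitter_sd, cnt)
            b = anchors[pick[:, 1]] + rng.normal(0, spec.anchor_jitter_sd, cnt)
            a = np.clip(np.rint(a), 1, sz).astype(np.int64)
            b = np.clip(np.rint(b), 1, sz).astype(np.int64)
            pos1[m], pos2[m] = np.minimum(a, b), np.maximum(a, b)
            continue
        if label[0] == "stripe":
            ai = rng.choice(len(anchors), size=cnt)
            a = anchors[ai] + rng.normal(0, spec.anchor_jitter_sd, cnt)
            off = rng.integers(0, spec.domain_size, size=cnt)
            b = anchors[ai] + off
            a = np.clip(np.rint(a), 1, sz).astype(np.int64)
            b = np.clip(np.rint(b), 1, sz).astype(np.int64)
            pos1[m], pos2[m] = np.minimum(a, b), np.maximum(a, b)
            continue
        # distance-driven components: draw a genomic distance, then a start
        if label[0] == "neighbor":
            d = label[1] * spec.repeat_length + rng.normal(
                0, spec.distance_jitter_sd, cnt
            )
        else:  # long-range band
            d = rng.uniform(*spec.long_range_band, size=cnt)
        d = np.maximum(np.rint(d), 1).astype(np.int64)
        hi = np.maximum(sz.astype(np.int64) - d, 1)
        a = rng.integers(1, hi + 1)
        pos1[m], pos2[m] = a, a + d

    # strand orientation after canonical ordering
    u = rng.random(n)
    strand1 = np.empty(n, dtype="U1")
    strand2 = np.empty(n, dtype="U1")
    f_in = spec.infacing_fraction
    rest = (1.0 - f_in) / 3.0
    edges = np.array([f_in, f_in + rest, f_in + 2 * rest])
    cls = np.searchsorted(edges, u, side="right")  # 0=in,1=out,2=++,3=--
    strand1[cls == 0], strand2[cls == 0] = "+", "-"
    strand1[cls == 1], strand2[cls == 1] = "-", "+"
    strand1[cls == 2], strand2[cls == 2] = "+", "+"
    strand1[cls == 3], strand2[cls == 3] = "-", "-"

    return pd.DataFrame(
        {
            "readID": [f"r{i}" for i in range(n)],
            "chrom1": np.array(chroms, dtype=object)[chrom_idx],
            "pos1": pos1,
            "chrom2": np.array(chroms, dtype=object)[chrom_idx],
            "pos2": pos2,
            "strand1": strand1,
            "strand2": strand2,
        }
    )


def generate_anchors(
    chrom_sizes: dict, n_anchors: int, min_spacing: int, seed: int = 0
) -> pd.DataFrame:
    """Sorted, non-overlapping single-point anchors (BED6-style frame).

    Anchors are placed on one chromosome at a time proportionally to length;
    within a chromosome, positions are drawn uniformly subject to the
    pairwise ``min_spacing`` constraint via the standard gap construction
    (draw from the shrunk interval, then re-expand).
    """
    if n_anchors < 0:
        raise ValueError("n_anchors must be >= 0")
    if min_spacing < 0:
        raise ValueError("min_spacing must be >= 0")
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    if n_anchors > 0 and n_anchors * min_spacing > sizes.sum():
        raise ValueError(
            f"cannot place {n_anchors} anchors with spacing {min_spacing} in "
            f"a genome of {int(sizes.sum())} bp"
        )
    counts = np.zeros(len(chroms), dtype=int)
    if n_anchors > 0:
        counts = rng.multinomial(n_anchors, sizes / sizes.sum())
        # rebalance chromosomes that cannot fit their allocation
        for i in np.argsort(-sizes):
            cap = int(sizes[i] // max(min_spacing, 1)) if min_spacing else n_anchors
            if counts[i] > cap:
                excess = counts[i] - cap
                counts[i] = cap
                for j in np.argsort(-sizes):
                    if j == i:
                        continue
                    cap_j = (
                        int(sizes[j] // max(min_spacing, 1))
                        if min_spacing
                        else n_anchors
                    )
                    room = cap_j - counts[j]
                    take = min(room, excess)
                    counts[j] += take
                    excess -= take
                if excess > 0:
                    raise ValueError("infeasible anchor packing")
    rows = []
    for ci, chrom in enumerate(chroms):
        k = int(counts[ci])
        if k == 0:
            continue
        size = int(sizes[ci])
        shrunk = size - (k - 1) * min_spacing
        if shrunk < k:
            raise ValueError("infeasible anchor packing on " + chrom)
        base = np.sort(rng.choice(shrunk, size=k, replace=False))
        pos = base + np.arange(k) * min_spacing
        for p in pos:
            rows.append((chrom, int(p), int(p) + 1, f"anchor_{chrom}_{int(p)}", 0, "."))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    return df.sort_values(["chrom", "start"], ignore_index=True)


@dataclass(frozen=True)
class BinaryVolume:
    """A 3-D binary segmentation mask with isotropic voxel size in nm."""

    mask: np.ndarray          # bool, shape (z, y, x)
    voxel_size: float         # nm per voxel edge

    def __post_init__(self):
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")


def generate_tube_volume(
    diameter: float,
    length: float,
    voxel_size: float,
    noise_fraction: float = 0.0,
    pad: int = 4,
    seed: int = 0,
) -> BinaryVolume:
    """Solid cylinder (axis along z, spanning the full z extent) on a
    voxel grid, optionally with salt-and-pepper noise flipping
    ``noise_fraction`` of all voxels."""
    if diameter <= 0 or length <= 0:
        raise ValueError("diameter and length must be > 0")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    if voxel_size >= diameter:
        raise ValueError("voxel_size must be smaller than the diameter")
    if not 0.0 <= noise_fraction <= 1.0:
        raise ValueError("noise_fraction must be in [0, 1]")
    r_vox = diameter / 2.0 / voxel_size
    nz = int(round(length / voxel_size))
    nxy = int(np.ceil(2 * r_vox)) + 2 * pad
    cz = nxy / 2.0 - 0.5
    yy, xx = np.meshgrid(np.arange(nxy), np.arange(nxy), indexing="ij")
    disk = (yy - cz) ** 2 + (xx - cz) ** 2 <= r_vox**2
    # the cylinder spans the full z extent, like a fiber crossing a
    # sub-tomogram; padding applies only laterally
    mask = np.broadcast_to(disk, (nz, nxy, nxy)).copy()
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(mask.shape) < noise_fraction
        mask = mask ^ flip
    return BinaryVolume(mask, float(voxel_size))
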