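"""Text I/O for the standard inputs and outputs.

Pairs files use the 4DN-style tab-separated dialect with a
``#columns:`` header; anchors are 6-column BED; nucleosome tracks are
4-column TSV (chrom, dyad, acetyl_flag, lh_flag); binary volumes go to
HDF5 with the voxel size as an attribute.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic_data import BinaryVolume, NucleosomeTrack

PAIRS_COLUMNS = ["readID", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]


def write_pairs(pairs: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: " + " ".join(PAIRS_COLUMNS) + "\n")
        pairs[PAIRS_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=PAIRS_COLUMNS,
        dtype={"pos1": np.int64, "pos2": np.int64},
    )
    for col, line_hint in (("strand1", 6), ("strand2", 7)):
        bad = ~df[col].isin(["+", "-"])
        if bad.any():
            first = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"missing/invalid strand in column {line_hint} at record {first}"
            )
    return df


def write_bed(anchors: pd.DataFrame, path) -> None:
    anchors[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )


def write_track(track: NucleosomeTrack, path) -> None:
    track.to_frame().to_csv(path, sep="\t", header=True, index=False)


def read_track(path) -> NucleosomeTrack:
    df = pd.read_csv(path, sep="\t")
    return NucleosomeTrack(
        chrom=str(df["chrom"].iloc[0]),
        dyads=df["dyad"].to_numpy(np.int64),
        acetylated=df["acetyl_flag"].to_numpy(bool),
        lh_bound=df["lh_flag"].to_numpy(bool),
    )


def write_volume(volume: BinaryVolume, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("mask", data=volume.mask.astype(np.uint8))
        ds.attrs["voxel_size_nm"] = volume.voxel_size


def read_volume(path) -> BinaryVolume:
    import h5py

    with h5py.File(path, "r") as fh:
        mask = fh["mask"][...].astype(bool)
        voxel = float(fh["mask"].attrs["voxel_size_nm"])
    return BinaryVolume(mask, voxel)


def write_sparse_matrix(matrix, path) -> None:
    """Bin-sparse TSV: bin1, bin2, count (upper triangle including diagonal)."""
    from scipy.sparse import coo_matrix

    coo = coo_matrix(matrix.counts)
    keep = coo.row <= coo.col
    pd.DataFrame(
        {"bin1": coo.row[keep], "bin2": coo.col[keep], "count": coo.data[keep]}
    ).to_csv(path, sep="\t", index=False)


def write_force_field(ff, path) -> None:
    """Force-field constants as a YAML mapping (every constant exposed)."""
    import dataclasses

    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(ff), fh, sort_keys=True)


def read_force_field(path):
    import yaml

    from .fiber_model import ForceFieldParams

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ForceFieldParams(**data)


def write_trajectory(traj, path) -> None:
    """Trajectory container: per-save groups (positions, twist, folded)
    plus scalar-series datasets and acceptance counters as attributes."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["n_saved"] = traj.n_saved
        if traj.schedule is not None:
            fh.attrs["seed"] = traj.schedule.seed
            fh.attrs["total_steps"] = traj.schedule.total_steps
        fh.create_dataset("steps", data=np.asarray(traj.steps))
        series = fh.create_group("series")
        for name, values in traj.series.items():
            series.create_dataset(name, data=np.asarray(values))
        snaps = fh.create_group("snapshots")
        for i, s in enumerate(traj.snapshots):
            g = snaps.create_group(f"{i:06d}")
            g.create_dataset("positions", data=s["positions"])
            g.create_dataset("twist", data=s["twist"])
            g.create_dataset("folded", data=s["folded"].astype(np.uint8))
        acc = fh.create_group("acceptance")
        for m in traj.proposals:
            acc.attrs[f"{m}_proposals"] = traj.proposals[m]
            acc.attrs[f"{m}_accepts"] = traj.accepts[m]


def read_trajectory(path, config):
    """Reload a trajectory; ``config`` supplies the topology the
    snapshots refer to."""
    import h5py

    from .mc_engine import Trajectory

    traj = Trajectory(config=config)
    with h5py.File(path, "r") as fh:
        traj.steps = list(fh["steps"][...])
        for name in fh["series"]:
            traj.series[name] = list(fh["series"][name][...])
        for key in sorted(fh["snapshots"]):
            g = fh["snapshots"][key]
            traj.snapshots.append(
                {
                    "positions": g["positions"][...],
                    "twist": g["twist"][...],
                    "folded": g["folded"][...].astype(bool),
                }
            )
        acc = fh["acceptance"]
        for m in list(traj.proposals):
            traj.proposals[m] = int(acc.attrs[f"{m}_proposals"])
            traj.accepts[m] = int(acc.attrs[f"{m}_accepts"])
    return traj
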