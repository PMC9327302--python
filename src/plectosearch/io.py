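"""Readers and writers: extended-XYZ chain trajectories, PDB snapshots,
TSV protein walks, and the validated run configuration.

The chain trajectory format is extended XYZ: per frame a line with the
atom count, a comment line of ``key=value`` pairs (frame number, rise,
helical repeat, linking number, seed), then one line per bp with the
element symbol P, the three coordinates and the junction twist increment
as a fifth column -- enough to round-trip a ChainTrajectory exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chain import ChainConfiguration, ChainTrajectory, SimParams
from .walker import ProteinDNATrajectory


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file (message carries the offending line)."""


# ---------------------------------------------------------------- XYZ I/O

def write_xyz(traj: ChainTrajectory, path) -> None:
    """Write a ChainTrajectory as extended XYZ with a twist column."""
    path = Path(path)
    with path.open("w") as fh:
        for k, frame in enumerate(traj.frames):
            lk = frame.total_twist()  # Tw only; Wr implicit in geometry
            fh.write(f"{frame.n_bp}\n")
            fh.write(
                f"frame={k} rise={frame.rise} "
                f"helical_repeat={frame.helical_repeat} tw={lk:.6f} "
                f"seed={traj.params.seed} "
                f"frame_interval={traj.frame_interval}\n")
            for i in range(frame.n_bp):
                x, y, z = frame.centers[i]
                fh.write(f"P {x:.6f} {y:.6f} {z:.6f} "
                         f"{frame.twist_increments[i]:.9f}\n")


def read_xyz(path, params: SimParams | None = None) -> ChainTrajectory:
    """Read an extended-XYZ chain trajectory written by :func:`write_xyz`.

    Malformed content raises TrajectoryFormatError naming the line; a file
    truncated mid-frame raises an error naming the last complete frame.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[ChainConfiguration] = []
    meta: dict = {}
    ln = 0
    n_bp_ref: int | None = None
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n_bp = int(lines[ln].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"{path}:{ln + 1}: expected atom count, got "
                f"{lines[ln]!r}") from exc
        if n_bp_ref is None:
            n_bp_ref = n_bp
        elif n_bp != n_bp_ref:
            raise TrajectoryFormatError(
                f"{path}:{ln + 1}: inconsistent n_bp {n_bp} != {n_bp_ref}")
        if ln + 1 + n_bp >= len(lines) + 1 and len(lines) - ln - 2 < n_bp:
            raise TrajectoryFormatError(
                f"{path}:{ln + 1}: truncated frame; last complete frame is "
                f"{len(frames) - 1}")
        comment = lines[ln + 1]
        meta = dict(kv.split("=", 1) for kv in comment.split() if "=" in kv)
        centers = np.empty((n_bp, 3))
        twists = np.empty(n_bp)
        for i in range(n_bp):
            lineno = ln + 2 + i
            if lineno >= len(lines):
                raise TrajectoryFormatError(
                    f"{path}: truncated at line {lineno + 1}; last complete "
                    f"frame is {len(frames) - 1}")
            parts = lines[lineno].split()
            if len(parts) != 5:
                raise TrajectoryFormatError(
                    f"{path}:{lineno + 1}: expected 'P x y z twist', got "
                    f"{lines[lineno]!r}")
            try:
                vals = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise TrajectoryFormatError(
                    f"{path}:{lineno + 1}: non-numeric field") from exc
            if not all(np.isfinite(vals)):
                raise TrajectoryFormatError(
                    f"{path}:{lineno + 1}: non-finite coordinate in frame "
                    f"{len(frames)}, atom {i}")
            centers[i] = vals[:3]
            twists[i] = vals[3]
        frames.append(ChainConfiguration(
            centers, twists,
            helical_repeat=float(meta.get("helical_repeat", 10.5)),
            rise=float(meta.get("rise", 3.34))))
        ln += 2 + n_bp
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames")
    if params is None:
        params = SimParams(seed=int(float(meta.get("seed", 0))))
    return ChainTrajectory(frames, int(float(meta.get("frame_interval", 1))),
                           params)


# ---------------------------------------------------------------- PDB out

def write_pdb(config: ChainConfiguration, path) -> None:
    """Write a single frame as a PDB chain of P atoms (one per bp center)
    for visualization."""
    from Bio.PDB import PDBIO, StructureBuilder

    sb = StructureBuilder.StructureBuilder()
    sb.init_structure("mcir")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    for i in range(config.n_bp):
        sb.init_residue("DN", " ", i + 1, " ")
        sb.init_atom("P", config.centers[i].astype(float), 0.0, 1.0, " ",
                     " P  ", i + 1, "P")
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))


# ------------------------------------------------------------- walk TSV

WALK_COLUMNS = ["frame", "R", "bp_index", "z", "theta", "x", "y", "z3d",
                "truth_label"]


def write_walk(traj: ProteinDNATrajectory, path) -> None:
    """Write a protein walk as TSV plus a JSON sidecar of metadata."""
    path = Path(path)
    df = pd.DataFrame({
        "frame": np.arange(len(traj)),
        "R": traj.R,
        "bp_index": traj.bp_index,
        "z": traj.z,
        "theta": traj.theta,
        "x": traj.xyz[:, 0],
        "y": traj.xyz[:, 1],
        "z3d": traj.xyz[:, 2],
        "truth_label": (traj.truth_labels if traj.truth_labels is not None
                        else [""] * len(traj)),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "n_bp": traj.n_bp, "seed": traj.seed, "rise": traj.rise,
        "helical_repeat": traj.helical_repeat,
        "frame_interval": traj.frame_interval,
    }, indent=2))


def read_walk(path) -> ProteinDNATrajectory:
    """Read a TSV walk written by :func:`write_walk`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in WALK_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing columns {missing}")
    if not df["frame"].is_monotonic_increasing:
        raise TrajectoryFormatError(f"{path}: non-monotone frame indices")
    bad = df[["R", "z", "theta", "x", "y", "z3d"]].isna().any(axis=1)
    if bad.any():
        raise TrajectoryFormatError(
            f"{path}: NaN field at frame {int(df['frame'][bad].iloc[0])}")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    labels = None
    if "truth_label" in df.columns and df["truth_label"].notna().any():
        lab = df["truth_label"].fillna("").astype(str).to_numpy(dtype=object)
        if (lab != "").any():
            labels = lab
    return ProteinDNATrajectory(
        R=df["R"].to_numpy(float),
        bp_index=df["bp_index"].to_numpy(np.int64),
        z=df["z"].to_numpy(float),
        theta=df["theta"].to_numpy(float),
        xyz=df[["x", "y", "z3d"]].to_numpy(float),
        n_bp=int(meta.get("n_bp", int(df["bp_index"].max()))),
        frame_interval=int(meta.get("frame_interval", 1)),
        seed=int(meta.get("seed", 0)),
        rise=float(meta.get("rise", 3.34)),
        helical_repeat=float(meta.get("helical_repeat", 10.5)),
        truth_labels=labels)
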