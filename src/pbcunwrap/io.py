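"""Plain-text trajectory I/O.

The native dialect is a TSV file with one row per (frame, particle):
a metadata comment line, then a header naming the columns

    frame  time  particle  x [y z]  Lx [Ly Lz]  [nx ny nz]

Floats are written with the shortest representation that round-trips to
the same double, so write -> read is bit-exact — storing far-from-origin
unwrapped coordinates at reduced precision silently corrupts
displacement statistics, so full fidelity is a correctness issue here,
not cosmetics.

The metadata line records whether the data are wrapped or unwrapped,
the scheme tag, the cell convention and the frame spacing, e.g.::

    # pbcunwrap kind=wrapped alpha=1 dt=1.0

Adapter readers for engine-specific binary formats are deliberately out
of this module; anything that can produce this TSV can feed the
pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BoxSeries, UnwrappedTrajectory, WrapConvention, WrappedTrajectory
from .molecule import MoleculeTopology

__all__ = ["read_trajectory", "write_trajectory", "read_topology"]

_AXES = ("x", "y", "z")


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; the message carries the offending detail."""


def write_trajectory(path, traj: WrappedTrajectory | UnwrappedTrajectory) -> None:
    """Write a trajectory in the native TSV dialect (bit-exact floats)."""
    path = Path(path)
    n_axes = traj.n_axes
    axes = _AXES[:n_axes]
    if isinstance(traj, WrappedTrajectory):
        meta = f"# pbcunwrap kind=wrapped alpha={traj.convention.alpha} dt={traj.box.dt!r}"
    else:
        meta = f"# pbcunwrap kind=unwrapped scheme={traj.scheme_tag} dt={traj.box.dt!r}"
    cols = ["frame", "time", "particle", *axes, *[f"L{a}" for a in axes]]
    images = getattr(traj, "images", None)
    if images is not None:
        cols += [f"n{a}" for a in axes]
    with path.open("w") as fh:
        fh.write(meta + "\n")
        fh.write("\t".join(cols) + "\n")
        dt = traj.box.dt
        for f in range(traj.n_frames):
            for p in range(traj.n_particles):
                row = [str(f), repr(float(f * dt)), str(p)]
                row += [repr(float(v)) for v in traj.positions[f, p]]
                row += [repr(float(v)) for v in traj.box.lengths[f]]
                if images is not None:
                    row += [str(int(v)) for v in images[f, p]]
                fh.write("\t".join(row) + "\n")


def _parse_meta(line: str) -> dict:
    meta: dict[str, str] = {}
    if not line.startswith("# pbcunwrap"):
        return meta
    for token in line.removeprefix("# pbcunwrap").split():
        if "=" in token:
            key, val = token.split("=", 1)
            meta[key] = val
    return meta


def read_trajectory(path, kind: str | None = None) -> WrappedTrajectory | UnwrappedTrajectory:
    """Read a native-dialect TSV trajectory.

    ``kind`` (``"wrapped"`` / ``"unwrapped"``) overrides the file's
    metadata line; files with image-number columns always come back as
    :class:`UnwrappedTrajectory` with ``images`` populated.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    meta = _parse_meta(first)
    skip = 1 if first.startswith("#") else 0
    try:
        df = pd.read_csv(path, sep="\t", skiprows=skip, float_precision="round_trip")
    except Exception as exc:  # ragged rows, bad floats ...
        raise TrajectoryParseError(f"{path}: {exc}") from exc

    for col in ("frame", "particle"):
        if col not in df.columns:
            raise TrajectoryParseError(f"{path}: missing required column '{col}'")
    axes = [a for a in _AXES if a in df.columns]
    if not axes:
        raise TrajectoryParseError(f"{path}: no coordinate column (x[, y, z]) found")
    for a in axes:
        if f"L{a}" not in df.columns:
            raise TrajectoryParseError(f"{path}: missing box column 'L{a}'")
    image_cols = [f"n{a}" for a in axes]
    has_images = all(c in df.columns for c in image_cols)

    frames = np.sort(df["frame"].unique())
    particles = np.sort(df["particle"].unique())
    n_f, n_p, n_a = len(frames), len(particles), len(axes)
    if len(df) != n_f * n_p:
        raise TrajectoryParseError(
            f"{path}: expected {n_f * n_p} rows for {n_f} frames x {n_p} particles, got {len(df)}"
        )
    df = df.sort_values(["frame", "particle"], kind="stable")
    positions = df[axes].to_numpy(dtype=float).reshape(n_f, n_p, n_a)
    lengths = df[[f"L{a}" for a in axes]].to_numpy(dtype=float).reshape(n_f, n_p, n_a)[:, 0, :]
    if np.any(lengths <= 0):
        bad = int(np.nonzero(lengths <= 0)[0][0])
        raise TrajectoryParseError(f"{path}: nonpositive box length at frame {bad}")

    dt = float(meta.get("dt", "nan"))
    if not np.isfinite(dt):
        times = df["time"].to_numpy(dtype=float) if "time" in df.columns else None
        dt = float(times[n_p] - times[0]) if times is not None and n_f > 1 else 1.0
    box = BoxSeries(lengths, dt=dt)

    kind = kind or meta.get("kind", "unwrapped" if has_images else "wrapped")
    if kind == "wrapped":
        alpha = int(meta.get("alpha", "1"))
        return WrappedTrajectory(positions, box, convention=WrapConvention(alpha))
    if kind != "unwrapped":
        raise TrajectoryParseError(f"{path}: unknown trajectory kind {kind!r}")
    images = None
    if has_images:
        images = df[image_cols].to_numpy(dtype=np.int64).reshape(n_f, n_p, n_a)
    return UnwrappedTrajectory(
        positions, box, scheme_tag=meta.get("scheme", "native"), images=images
    )


def read_topology(path) -> MoleculeTopology:
    """Read a JSON topology sidecar: masses, bond index pairs, reference atom."""
    with Path(path).open() as fh:
        data = json.load(fh)
    return MoleculeTopology.from_dict(data)
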