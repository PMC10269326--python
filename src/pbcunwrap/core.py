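"""Shared data model for wrapped/unwrapped trajectories in fluctuating boxes.

Positions are stored as double-precision arrays of shape
``(n_frames, n_particles, n_axes)``; per-frame orthorhombic box edge
lengths as ``(n_frames, n_axes)``.  All schemes in this package act on
each Cartesian axis independently, so the fundamental unit of work is a
1D series of coordinates paired with a 1D series of box lengths —
:func:`per_axis_view` exposes that decomposition.

Two conventions for the central cell coexist in MD software: the cell
``[0, L)`` anchored at the origin corner (GROMACS-style, ``alpha=0``) and
the cell ``[-L/2, L/2)`` centred on the origin (LAMMPS/NAMD-style,
``alpha=1``).  Boundary ownership is half-open so that wrapping is
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

__all__ = [
    "BoxSeries",
    "WrapConvention",
    "WrappedTrajectory",
    "UnwrappedTrajectory",
    "Violation",
    "validate_wrapped",
    "per_axis_view",
    "assemble_axis_views",
]


@dataclass(frozen=True)
class WrapConvention:
    """Central-cell convention: ``alpha=1`` -> [-L/2, L/2), ``alpha=0`` -> [0, L)."""

    alpha: int = 1

    def __post_init__(self) -> None:
        if self.alpha not in (0, 1):
            raise ValueError(f"alpha must be 0 or 1, got {self.alpha}")

    def bounds(self, L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Lower (closed) and upper (open) cell bounds for box lengths ``L``."""
        L = np.asarray(L, dtype=float)
        if self.alpha == 1:
            return -L / 2.0, L / 2.0
        return np.zeros_like(L), L


def _as_box_lengths(lengths) -> np.ndarray:
    arr = np.asarray(lengths, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("box lengths must be (n_frames,) or (n_frames, n_axes)")
    return arr


@dataclass
class BoxSeries:
    """Per-frame orthorhombic box edge lengths with a fixed sampling interval.

    Parameters
    ----------
    lengths:
        Edge lengths, shape ``(n_frames, n_axes)`` (a 1D array is treated
        as a single axis).  Strictly positive.
    dt:
        Time between consecutive frames (same unit throughout the
        analysis; the diffusion module reports D in length**2 / time).
    """

    lengths: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.lengths = _as_box_lengths(self.lengths)
        if not np.all(np.isfinite(self.lengths)):
            raise ValueError("box lengths must be finite")
        if np.any(self.lengths <= 0):
            raise ValueError("box lengths must be strictly positive")
        if self.n_axes not in (1, 2, 3):
            raise ValueError(f"n_axes must be 1, 2 or 3, got {self.n_axes}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.lengths.shape[0]

    @property
    def n_axes(self) -> int:
        return self.lengths.shape[1]

    @property
    def volumes(self) -> np.ndarray:
        """Per-frame cell volume (product of edge lengths)."""
        return np.prod(self.lengths, axis=1)

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.n_frames)


def _check_positions(positions, box: BoxSeries) -> np.ndarray:
    arr = np.asarray(positions, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None, None]
    elif arr.ndim == 2:
        # (n_frames, n_axes) single particle
        arr = arr[:, None, :]
    if arr.ndim != 3:
        raise ValueError("positions must have shape (n_frames, n_particles, n_axes)")
    if arr.shape[0] != box.n_frames:
        raise ValueError(
            f"positions have {arr.shape[0]} frames but box has {box.n_frames}"
        )
    if arr.shape[2] != box.n_axes:
        raise ValueError(
            f"positions have {arr.shape[2]} axes but box has {box.n_axes}"
        )
    return arr


@dataclass
class WrappedTrajectory:
    """In-box particle coordinates with their box series and cell convention."""

    positions: np.ndarray
    box: BoxSeries
    convention: WrapConvention = field(default_factory=WrapConvention)

    def __post_init__(self) -> None:
        self.positions = _check_positions(self.positions, self.box)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def n_axes(self) -> int:
        return self.positions.shape[2]


@dataclass
class UnwrappedTrajectory:
    """Off-box (unbounded) coordinates, optionally with integer image numbers.

    ``scheme_tag`` records provenance: ``"tor"``, ``"lat"``, ``"hlat"``,
    ``"kv"`` for scheme output or ``"native"`` for data that arrived
    unwrapped.  When ``images`` is present (lattice-view data) the lattice
    identity ``u_i = w_i + n_i * L_i`` holds against the paired wrapped
    trajectory.
    """

    positions: np.ndarray
    box: BoxSeries
    scheme_tag: str = "native"
    images: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = _check_positions(self.positions, self.box)
        if self.images is not None:
            self.images = np.asarray(self.images)
            if self.images.shape != self.positions.shape:
                raise ValueError("images must have the same shape as positions")
            if not np.issubdtype(self.images.dtype, np.integer):
                rounded = np.rint(self.images)
                if not np.array_equal(rounded, self.images):
                    raise ValueError("image numbers must be integers")
                self.images = rounded.astype(np.int64)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def n_axes(self) -> int:
        return self.positions.shape[2]


class Violation(NamedTuple):
    """A coordinate outside its frame's central cell."""

    frame: int
    particle: int
    axis: int
    value: float
    lower: float
    upper: float


def validate_wrapped(traj: WrappedTrajectory) -> list[Violation]:
    """Check every coordinate against the convention's central cell.

    Returns an empty list iff all coordinates satisfy
    ``lower <= w < upper`` for their frame's box.  Diagnostic only: never
    raises.
    """
    lower, upper = traj.convention.bounds(traj.box.lengths)  # (n_frames, n_axes)
    lo = lower[:, None, :]
    hi = upper[:, None, :]
    bad = (traj.positions < lo) | (traj.positions >= hi)
    out: list[Violation] = []
    for f, p, a in zip(*np.nonzero(bad)):
        out.append(
            Violation(
                int(f), int(p), int(a),
                float(traj.positions[f, p, a]),
                float(lo[f, 0, a]), float(hi[f, 0, a]),
            )
        )
    return out


class AxisSeries(NamedTuple):
    """One independent 1D unwrapping problem: a particle/axis coordinate series."""

    particle: int
    axis: int
    values: np.ndarray  # (n_frames,)
    lengths: np.ndarray  # (n_frames,)


def per_axis_view(traj: WrappedTrajectory | UnwrappedTrajectory) -> Iterator[AxisSeries]:
    """Decompose an ND trajectory into independent 1D (w, L) series.

    Orthorhombic boxes make every particle/axis pair an independent 1D
    problem.  Yields ``n_particles * n_axes`` series in (particle-major,
    axis-minor) order; :func:`assemble_axis_views` inverts the
    decomposition bit-for-bit.
    """
    for p in range(traj.n_particles):
        for a in range(traj.n_axes):
            yield AxisSeries(p, a, traj.positions[:, p, a], traj.box.lengths[:, a])


def assemble_axis_views(views: list[AxisSeries]) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild ``(positions, box_lengths)`` arrays from axis views.

    Inverse of :func:`per_axis_view`; reconstruction is exact.
    """
    if not views:
        raise ValueError("no axis views to assemble")
    n_particles = max(v.particle for v in views) + 1
    n_axes = max(v.axis for v in views) + 1
    n_frames = len(views[0].values)
    positions = np.empty((n_frames, n_particles, n_axes))
    lengths = np.empty((n_frames, n_axes))
    for v in views:
        positions[:, v.particle, v.axis] = v.values
        lengths[:, v.axis] = v.lengths
    return positions, lengths
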