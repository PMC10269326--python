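"""Unwrapping molecular trajectories without bond-stretching artifacts.

Toroidal-view unwrapping applied naively to every atom of a molecule
whose bonds straddle a periodic boundary displaces the atoms relative
to each other, stretching bonds by whole box lengths.  The remedy is an
order of operations:

1. make the molecule "whole" in every frame (each bond at its minimal
   periodic image),
2. compute the centre of mass of the whole molecule and wrap it into
   the cell,
3. unwrap the centre-of-mass trajectory with the toroidal scheme,
4. if atomic detail is needed, rebuild atoms around the unwrapped
   centre of mass from their whole-frame offsets.

Reconstruction preserves every intramolecular distance of the whole
frames exactly.  A single chosen reference atom can stand in for the
centre of mass throughout.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .core import BoxSeries, UnwrappedTrajectory, WrapConvention, WrappedTrajectory
from .unwrap import tor_unwrap
from .wrap import lattice_wrap

__all__ = ["MoleculeTopology", "make_whole", "com_series", "unwrap_molecule"]


class AmbiguousBondError(ValueError):
    """A bond's minimal-image length reaches L/2, so its image is ambiguous."""


@dataclass(frozen=True)
class MoleculeTopology:
    """Minimal topology: masses, bond list and a reference atom.

    The bond graph must be connected; traversal during
    :func:`make_whole` is breadth-first from ``reference`` with
    neighbours visited in ascending index order, so outputs are
    bit-reproducible.
    """

    masses: tuple[float, ...]
    bonds: tuple[tuple[int, int], ...]
    reference: int = 0

    def __post_init__(self) -> None:
        n = len(self.masses)
        if n == 0:
            raise ValueError("molecule needs at least one atom")
        if any(m <= 0 for m in self.masses):
            raise ValueError("masses must be positive")
        if not 0 <= self.reference < n:
            raise ValueError(f"reference atom {self.reference} out of range")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i}, {j})")
        if len(self._bfs_order()) != n - 1:  # BFS tree edges reach every atom
            raise ValueError("bond graph is disconnected")

    @property
    def n_atoms(self) -> int:
        return len(self.masses)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return [sorted(set(nbrs)) for nbrs in adj]

    def _bfs_order(self) -> list[tuple[int, int]]:
        """(parent, child) edges in deterministic BFS order from the reference."""
        adj = self.adjacency()
        seen = {self.reference}
        order: list[tuple[int, int]] = []
        queue = deque([self.reference])
        while queue:
            node = queue.popleft()
            for nbr in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    order.append((node, nbr))
                    queue.append(nbr)
        return order

    @classmethod
    def from_dict(cls, d: dict) -> "MoleculeTopology":
        return cls(
            masses=tuple(float(m) for m in d["masses"]),
            bonds=tuple((int(i), int(j)) for i, j in d.get("bonds", [])),
            reference=int(d.get("reference", 0)),
        )


def make_whole(positions: np.ndarray, box_lengths: np.ndarray, topology: MoleculeTopology) -> np.ndarray:
    """Reassemble a molecule across periodic boundaries in one frame.

    Starting from the reference atom, each neighbour is placed at its
    minimal-image position relative to its already-placed parent.
    Idempotent: a whole molecule is returned unchanged.

    Raises
    ------
    AmbiguousBondError
        If a minimal-image bond component reaches ``L/2``: the correct
        image is then undecidable from a single frame.
    """
    pos = np.array(positions, dtype=float)
    L = np.asarray(box_lengths, dtype=float)
    if pos.shape != (topology.n_atoms, L.shape[0]):
        raise ValueError(
            f"positions must be ({topology.n_atoms}, {L.shape[0]}), got {pos.shape}"
        )
    for parent, child in topology._bfs_order():
        delta = pos[child] - pos[parent]
        delta_min = delta - L * np.floor(delta / L + 0.5)
        if np.any(np.abs(delta_min) >= L / 2.0):
            raise AmbiguousBondError(
                f"bond ({parent}, {child}) has a minimal-image component >= L/2"
            )
        pos[child] = pos[parent] + delta_min
    return pos


def com_series(
    whole_positions: np.ndarray,
    topology: MoleculeTopology,
    box: BoxSeries,
    alpha: int = 1,
) -> WrappedTrajectory:
    """Wrapped centre-of-mass trajectory of per-frame whole molecules.

    ``whole_positions`` has shape ``(n_frames, n_atoms, n_axes)`` with
    every frame already whole.  The mass-weighted mean is wrapped into
    the alpha-cell of each frame's box.
    """
    pos = np.asarray(whole_positions, dtype=float)
    masses = np.asarray(topology.masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = np.einsum("fam,a->fm", pos, masses) / total  # (F, A)
    wrapped = lattice_wrap(com, box.lengths, alpha)
    return WrappedTrajectory(wrapped[:, None, :], box, convention=WrapConvention(alpha))


def unwrap_molecule(
    frames: np.ndarray,
    topology: MoleculeTopology,
    box: BoxSeries,
    alpha: int = 1,
    reference_mode: str = "com",
    reconstruct: bool = True,
) -> tuple[UnwrappedTrajectory, np.ndarray | None]:
    """Whole -> (COM or reference-atom) wrap -> toroidal unwrap -> rebuild.

    Parameters
    ----------
    frames:
        Raw (possibly broken) atom positions, ``(n_frames, n_atoms, n_axes)``.
    reference_mode:
        ``"com"`` tracks the mass-weighted centre; ``"atom"`` tracks the
        topology's reference atom instead (equivalent for diffusion
        estimates, cheaper).
    reconstruct:
        Also return atoms placed at ``unwrapped centre + whole-frame
        offset``; intramolecular distances of the whole frames are then
        preserved exactly.

    Returns the unwrapped single-particle trajectory of the tracked
    point and (optionally) the reconstructed atomic coordinates.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[1] != topology.n_atoms:
        raise ValueError("frames must be (n_frames, n_atoms, n_axes)")
    whole = np.empty_like(frames)
    for f in range(frames.shape[0]):
        whole[f] = make_whole(frames[f], box.lengths[f], topology)

    masses = np.asarray(topology.masses, dtype=float)
    if reference_mode == "com":
        centre = np.einsum("fam,a->fm", whole, masses) / masses.sum()
    elif reference_mode == "atom":
        centre = whole[:, topology.reference, :]
    else:
        raise ValueError("reference_mode must be 'com' or 'atom'")
    centre_wrapped = lattice_wrap(centre, box.lengths, alpha)
    u_centre = tor_unwrap(centre_wrapped, box.lengths)
    traj = UnwrappedTrajectory(u_centre[:, None, :], box, scheme_tag="tor")

    atoms = None
    if reconstruct:
        atoms = u_centre[:, None, :] + (whole - centre[:, None, :])
    return traj, atoms
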