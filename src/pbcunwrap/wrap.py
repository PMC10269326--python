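"""Rewrapping schemes matched to the lattice and toroidal unwrapping views.

A lattice-view unwrapped trajectory is an integer number of box lengths
away from its wrapped partner at every frame, so the stateless lattice
wrap recovers it exactly.  A toroidal-view unwrapped trajectory is not
"on lattice" once a boundary crossing has happened under box
fluctuations; it must be rewrapped by backtracing its displacements.
Pairing a trajectory with the wrong rewrapping scheme does not
reproduce the original wrapped data.
"""

from __future__ import annotations

import numpy as np

from .core import UnwrappedTrajectory, WrapConvention, WrappedTrajectory
from .unwrap import _check_inputs

__all__ = ["lattice_wrap", "tor_rewrap", "rewrap"]


def _check_alpha(alpha: int) -> int:
    if alpha not in (0, 1):
        raise ValueError(f"alpha must be 0 or 1, got {alpha!r}")
    return alpha


def _fold_into_cell(w: np.ndarray, L: np.ndarray, alpha: int) -> np.ndarray:
    """Fold round-off stragglers back into the half-open cell.

    ``u - L*floor(u/L + alpha/2)`` can land exactly on the open upper
    boundary (or a hair below the lower one) for large ``|u|/L``; one
    corrective shift restores the cell invariant without moving any
    interior point.
    """
    lo = -L / 2.0 if alpha == 1 else np.zeros_like(L)
    hi = lo + L
    w = np.where(w >= hi, w - L, w)
    w = np.where(w < lo, w + L, w)
    return w


def lattice_wrap(u, L, alpha: int = 1) -> np.ndarray:
    """Stateless lattice wrap: ``w_i = u_i - L_i * floor(u_i/L_i + alpha/2)``.

    Maps each frame independently into the central cell ``[-L/2, L/2)``
    (``alpha=1``) or ``[0, L)`` (``alpha=0``).  Idempotent, and the exact
    inverse of :func:`pbcunwrap.unwrap.lat_unwrap` output.
    """
    _check_alpha(alpha)
    u, L = _check_inputs(u, L)
    if not np.all(np.isfinite(u)):
        raise ValueError("coordinates must be finite")
    return _fold_into_cell(u - L * np.floor(u / L + alpha / 2.0), L, alpha)


def tor_rewrap(u, L, alpha: int = 1) -> np.ndarray:
    """Backtrace displacements of a toroidal-view unwrapped trajectory.

    ``w_{i+1} = (w_i + du_i) - L_{i+1} * floor((w_i + du_i)/L_{i+1} + alpha/2)``
    with ``du_i = u_{i+1} - u_i`` and ``w_0 = u_0``.

    The first frame must already lie inside the alpha-cell of ``L_0``;
    anything else signals that the data were not toroidally unwrapped
    from this convention.  Only displacements of ``u`` are consumed —
    image numbers are never inspected.
    """
    _check_alpha(alpha)
    u, L = _check_inputs(u, L)
    lo = -L[0] / 2.0 if alpha == 1 else np.zeros_like(L[0])
    hi = lo + L[0]
    if np.any(u[0] < lo) or np.any(u[0] >= hi):
        raise ValueError(
            "first frame lies outside the initial central cell; "
            "tor_rewrap requires toroidal-view input starting in-box"
        )
    w = np.empty_like(u)
    w[0] = u[0]
    du = np.diff(u, axis=0)
    for i in range(u.shape[0] - 1):
        x = w[i] + du[i]
        w[i + 1] = _fold_into_cell(
            x - L[i + 1] * np.floor(x / L[i + 1] + alpha / 2.0), L[i + 1], alpha
        )
    return w


def rewrap(traj: UnwrappedTrajectory, scheme: str = "tor", alpha: int = 1) -> WrappedTrajectory:
    """Rewrap an unwrapped trajectory with the scheme-matched wrap.

    ``scheme="lat"`` applies the stateless lattice wrap, ``scheme="tor"``
    the displacement backtrace.
    """
    scheme = scheme.lower()
    u = traj.positions
    L = traj.box.lengths[:, None, :]
    if scheme == "lat":
        w = lattice_wrap(u, L, alpha)
    elif scheme == "tor":
        w = tor_rewrap(u, L, alpha)
    else:
        raise ValueError(f"unknown rewrap scheme {scheme!r}; choose 'tor' or 'lat'")
    return WrappedTrajectory(w, traj.box, convention=WrapConvention(alpha))
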