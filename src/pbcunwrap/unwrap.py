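"""Trajectory unwrapping schemes for constant-pressure simulations.

Under a barostat the box edge lengths ``L_i`` fluctuate frame to frame,
and the familiar constant-volume unwrapping recipes stop agreeing with
one another.  Three schemes are implemented, all acting per axis:

``hlat``
    Heuristic lattice scheme: place frame ``i+1`` in the periodic image
    that minimises the apparent displacement from the previous unwrapped
    position.  Known to mis-assign images under box fluctuations.
``tor``
    Toroidal-view scheme: accumulate minimal in-box displacement
    vectors.  Preserves the statistics of the wrapped trajectory; the
    output is generally *not* an integer number of box lengths away from
    the wrapped coordinate.
``lat``
    Lattice-view scheme: track integer image numbers ``n_i`` (from jump
    detection in the wrapped coordinates) and set ``u_i = w_i + n_i L_i``
    exactly.  Preserves interparticle distances but injects unbounded
    multiplicative noise as the particle leaves the central cell.
``kv``
    The corrected-toroidal recursion (toroidal displacement plus a
    ``(L_{i+1}/L_i - 1)(u_i - w_i)`` lattice-rescaling term).  Provably
    equivalent to ``lat``; kept as an independent code path so the
    equivalence can be asserted numerically.

All recursions start from ``u_0 = w_0`` (and ``n_0 = 0``); ``floor`` is
the mathematical floor.  The 1D functions broadcast: ``w`` may have
trailing dimensions (particles, axes) as long as ``L`` broadcasts
against each frame slice.
"""

from __future__ import annotations

import numpy as np

from .core import BoxSeries, UnwrappedTrajectory, WrappedTrajectory

__all__ = ["hlat_unwrap", "tor_unwrap", "lat_unwrap", "kv_unwrap", "unwrap", "SCHEMES"]


def _check_inputs(w, L) -> tuple[np.ndarray, np.ndarray]:
    w = np.asarray(w, dtype=float)
    L = np.asarray(L, dtype=float)
    if w.shape[0] == 0:
        raise ValueError("empty trajectory")
    if L.shape[0] != w.shape[0]:
        raise ValueError(f"w has {w.shape[0]} frames but L has {L.shape[0]}")
    if np.any(L <= 0):
        raise ValueError("box lengths must be strictly positive")
    # broadcast L against per-frame slices of w
    L = np.broadcast_to(L.reshape(L.shape + (1,) * (w.ndim - L.ndim)), w.shape).astype(float)
    return w, L


def hlat_unwrap(w, L) -> np.ndarray:
    """Heuristic lattice unwrapping (minimal-step image choice).

    ``u_{i+1} = w_{i+1} - L_{i+1} * floor((w_{i+1} - u_i)/L_{i+1} + 1/2)``
    """
    w, L = _check_inputs(w, L)
    u = np.empty_like(w)
    u[0] = w[0]
    for i in range(w.shape[0] - 1):
        u[i + 1] = w[i + 1] - L[i + 1] * np.floor((w[i + 1] - u[i]) / L[i + 1] + 0.5)
    return u


def tor_unwrap(w, L) -> np.ndarray:
    """Toroidal-view unwrapping: sum of minimal in-box displacements.

    ``u_{i+1} = u_i + (w_{i+1} - w_i) - L_{i+1} * floor((w_{i+1} - w_i)/L_{i+1} + 1/2)``

    The recursion telescopes, so it is evaluated as a cumulative sum of
    minimal-image displacements (no per-frame Python loop).
    """
    w, L = _check_inputs(w, L)
    dw = np.diff(w, axis=0)
    dmin = dw - L[1:] * np.floor(dw / L[1:] + 0.5)
    u = np.empty_like(w)
    u[0] = w[0]
    np.cumsum(dmin, axis=0, out=u[1:])
    u[1:] += w[0]
    return u


def lat_unwrap(w, L) -> tuple[np.ndarray, np.ndarray]:
    """Lattice-view unwrapping via integer image numbers.

    Image increments are detected as large jumps in the wrapped
    coordinates, ``jump_i = -floor((w_{i+1} - w_i)/L_{i+1} + 1/2)``, and
    ``u_i = w_i + n_i * L_i`` holds exactly at every frame.

    Returns ``(u, n)`` with ``n`` an integer array.
    """
    w, L = _check_inputs(w, L)
    dw = np.diff(w, axis=0)
    jumps = -np.floor(dw / L[1:] + 0.5).astype(np.int64)
    n = np.zeros(w.shape, dtype=np.int64)
    np.cumsum(jumps, axis=0, out=n[1:])
    u = w + n * L
    return u, n


def kv_unwrap(w, L) -> np.ndarray:
    """Corrected-toroidal recursion (lattice-rescaling term added to ``tor``).

    ``u_{i+1} = u_i + dw - L_{i+1}*floor(dw/L_{i+1} + 1/2)
    + (L_{i+1}/L_i - 1)*(u_i - w_i)`` with ``dw = w_{i+1} - w_i``.
    Equivalent to :func:`lat_unwrap` (which evaluates the same lattice
    image in closed form); this literal recursion accumulates round-off
    instead and is retained for cross-validation.
    """
    w, L = _check_inputs(w, L)
    u = np.empty_like(w)
    u[0] = w[0]
    for i in range(w.shape[0] - 1):
        dw = w[i + 1] - w[i]
        u[i + 1] = (
            u[i]
            + dw
            - L[i + 1] * np.floor(dw / L[i + 1] + 0.5)
            + (L[i + 1] / L[i] - 1.0) * (u[i] - w[i])
        )
    return u


def image_unwrap(w, L, n) -> np.ndarray:
    """Lattice unwrap from explicitly book-kept image numbers: ``u = w + n L``.

    Alternative input path for engines that track image flips themselves
    instead of relying on jump detection.
    """
    w, L = _check_inputs(w, L)
    n = np.asarray(n)
    if n.shape != w.shape:
        raise ValueError("image numbers must match the coordinate shape")
    return w + n * L


SCHEMES = ("tor", "lat", "hlat", "kv")


def unwrap(traj: WrappedTrajectory, scheme: str = "tor") -> UnwrappedTrajectory:
    """Unwrap every particle/axis of a wrapped trajectory with one scheme.

    Records the scheme in ``scheme_tag``; the ``lat`` scheme additionally
    stores the integer image numbers.
    """
    scheme = scheme.lower()
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    w = traj.positions  # (F, P, A)
    L = traj.box.lengths[:, None, :]  # broadcast over particles
    images = None
    if traj.n_particles == 0:
        u = w.copy()
    elif scheme == "tor":
        u = tor_unwrap(w, L)
    elif scheme == "lat":
        u, images = lat_unwrap(w, L)
    elif scheme == "hlat":
        u = hlat_unwrap(w, L)
    else:
        u = kv_unwrap(w, L)
    return UnwrappedTrajectory(u, traj.box, scheme_tag=scheme, images=images)
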