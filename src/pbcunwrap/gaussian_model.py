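"""Exactly solvable Gaussian model of diffusion in a fluctuating periodic box.

The model is a discrete-time Wiener process confined between periodic
boundaries at ``±L_i/2``, where the box edge ``L_i = L + sigma_L * R'_i``
is itself Gaussian white noise.  Each step first rescales the in-box
coordinate with the box (mimicking barostat position rescaling), then
adds a diffusive displacement, then wraps:

    ``w_{i+1} = wrap_{alpha=1, L_{i+1}}( (L_{i+1}/L_i) w_i + sigma_w R_{i+1} )``

Driven by the *same* noise draws, two unwrapped partner processes are
propagated jointly:

*   the true off-lattice partner, whose multiplicative noise couples to
    the bounded wrapped coordinate and therefore stays bounded,

        ``u_{i+1} = u_i + (L_{i+1}/L_i - 1) w_i + sigma_w R_{i+1}``

*   the lattice-view partner, whose multiplicative noise couples to the
    unbounded coordinate itself and grows without bound,

        ``u*_{i+1} = (L_{i+1}/L_i) u*_i + sigma_w R_{i+1}``

These closed-form partners are the package's oracles: toroidal
unwrapping of ``w`` must reproduce ``u`` and lattice unwrapping must
reproduce ``u*`` frame by frame (up to round-off), which pins down every
sign and floor in the scheme implementations.

The generator emulates the barostat-coupled rescaling of coordinates and
white-noise box fluctuations; it has no inertia, no interparticle
forces and no box-volume autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BoxSeries, UnwrappedTrajectory, WrapConvention, WrappedTrajectory
from .wrap import _fold_into_cell

__all__ = ["GaussianModelParams", "ModelRealization", "simulate", "ensemble"]

#: Default parameters reproduce the reference study conditions:
#: box fluctuations of 10% and diffusive steps of 5% of the mean edge.
_DEFAULT_L = 1.0
_DEFAULT_SIGMA_L = 0.1
_DEFAULT_SIGMA_W = 0.05


@dataclass(frozen=True)
class GaussianModelParams:
    """Parameters of the fluctuating-box Gaussian model.

    Attributes
    ----------
    L:
        Mean box edge length (length unit; default 1 sets the scale).
    sigma_L:
        Box-noise amplitude.  Must stay below ``L/2`` so that sampled
        edges are positive with overwhelming probability; any sampled
        ``L_i <= 0`` is rejected at run time.
    sigma_w:
        Diffusive step amplitude, so the underlying free walk has
        ``D = sigma_w**2 / (2 dt)`` per axis.
    n_steps:
        Number of propagation steps; the realization has
        ``n_steps + 1`` frames.
    n_dims, n_particles:
        Independent axes (each with its own box series) and particles
        (sharing the box, as in a single simulation cell).
    dt:
        Frame spacing carried into the box series for downstream
        diffusion analysis.
    seed:
        Master seed; realizations are fully reproducible.
    """

    L: float = _DEFAULT_L
    sigma_L: float = _DEFAULT_SIGMA_L
    sigma_w: float = _DEFAULT_SIGMA_W
    n_steps: int = 1000
    n_dims: int = 1
    n_particles: int = 1
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.sigma_L < 0 or self.sigma_w < 0:
            raise ValueError("noise amplitudes must be nonnegative")
        if self.sigma_L >= self.L / 2:
            raise ValueError("sigma_L must be below L/2 to keep boxes positive")
        if self.n_steps < 1 or self.n_dims < 1 or self.n_particles < 1:
            raise ValueError("n_steps, n_dims and n_particles must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class ModelRealization:
    """One realization: wrapped trajectory plus its two unwrapped partners.

    All three share the identical box series and noise draws and the
    identical first frame.
    """

    params: GaussianModelParams
    w: WrappedTrajectory
    u_true: UnwrappedTrajectory
    u_star: UnwrappedTrajectory
    box: BoxSeries
    noise_particle: np.ndarray  # R_i, shape (n_frames, n_particles, n_dims)
    noise_box: np.ndarray  # R'_i, shape (n_frames, n_dims)


class BoxCollapseError(RuntimeError):
    """A sampled box edge came out nonpositive (sigma_L too close to L/2)."""


def _simulate_batch(params: GaussianModelParams, n_reps: int, rng: np.random.Generator):
    """Propagate ``n_reps`` independent realizations in lock step.

    Returns arrays with a leading replicate axis:
    ``L (n_reps, F, D)``, ``w/u/us (n_reps, F, P, D)`` and the noises.
    The per-step loop is vectorised over replicates, particles and axes.
    """
    F = params.n_steps + 1
    P, D = params.n_particles, params.n_dims
    Rp = rng.standard_normal((n_reps, F, D))  # box noise R'_i
    L = params.L + params.sigma_L * Rp
    if np.any(L <= 0):
        r, i, a = [int(x[0]) for x in np.nonzero(L <= 0)]
        raise BoxCollapseError(
            f"sampled box edge L={L[r, i, a]:.3g} <= 0 at replicate {r}, "
            f"frame {i}, axis {a}; reduce sigma_L or reseed"
        )
    R = np.empty((n_reps, F, P, D))
    R[:, 0] = 0.0  # no diffusive noise enters frame 0
    R[:, 1:] = rng.standard_normal((n_reps, F - 1, P, D))
    # initial position uniform in the frame-0 central cell, alpha = 1
    w0 = L[:, 0, None, :] * (rng.random((n_reps, P, D)) - 0.5)

    w = np.empty((n_reps, F, P, D))
    u = np.empty_like(w)
    us = np.empty_like(w)
    w[:, 0] = u[:, 0] = us[:, 0] = w0
    for i in range(params.n_steps):
        g = (L[:, i + 1] / L[:, i])[:, None, :]  # rescale factor, broadcast over P
        step = params.sigma_w * R[:, i + 1]
        x = g * w[:, i] + step
        Li1 = L[:, i + 1][:, None, :]
        w[:, i + 1] = _fold_into_cell(x - Li1 * np.floor(x / Li1 + 0.5), Li1, 1)
        u[:, i + 1] = u[:, i] + (g - 1.0) * w[:, i] + step
        us[:, i + 1] = g * us[:, i] + step
    return L, w, u, us, R, Rp


def _to_realization(params, L, w, u, us, R, Rp) -> ModelRealization:
    box = BoxSeries(L, dt=params.dt)
    return ModelRealization(
        params=params,
        w=WrappedTrajectory(w, box, convention=WrapConvention(1)),
        u_true=UnwrappedTrajectory(u, box, scheme_tag="native"),
        u_star=UnwrappedTrajectory(us, box, scheme_tag="native"),
        box=box,
        noise_particle=R,
        noise_box=Rp,
    )


def simulate(params: GaussianModelParams) -> ModelRealization:
    """Generate one seeded realization of the fluctuating-box model."""
    rng = np.random.default_rng(params.seed)
    L, w, u, us, R, Rp = _simulate_batch(params, 1, rng)
    return _to_realization(params, L[0], w[0], u[0], us[0], R[0], Rp[0])


def ensemble(params: GaussianModelParams, n_replicates: int) -> list[ModelRealization]:
    """Generate independent replicates with seeds derived from the master seed.

    Replicate streams come from ``SeedSequence(seed).spawn``, so the
    ensemble is reproducible and each replicate differs.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    out = []
    for child in np.random.SeedSequence(params.seed).spawn(n_replicates):
        rng = np.random.default_rng(child)
        L, w, u, us, R, Rp = _simulate_batch(params, 1, rng)
        out.append(_to_realization(params, L[0], w[0], u[0], us[0], R[0], Rp[0]))
    return out


def ensemble_arrays(params: GaussianModelParams, n_replicates: int):
    """Batch form of :func:`ensemble` for large ensembles.

    Returns ``(box_lengths, w, u_true, u_star)`` with a leading replicate
    axis, propagated in lock step (one vectorised pass instead of
    ``n_replicates`` Python loops).  The replicate streams differ from
    :func:`ensemble`'s, but are equally reproducible from the seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    L, w, u, us, _, _ = _simulate_batch(params, n_replicates, rng)
    return L, w, u, us
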