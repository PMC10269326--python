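"""Diffusion estimation and block-wise drift diagnostics.

The mean squared displacement of a d-dimensional diffusive process with
static localization noise is modelled as ``MSD(tau) = 2 d D tau + a**2``
(no motion-blur term: saved MD frames are instantaneous configurations).
Two estimators are provided:

*   an ordinary least-squares straight-line fit over a lag window
    ``[m_init, m_end]`` of the time-averaged single-trajectory MSD, and
*   the covariance-based estimator (CVE), a closed form in the increment
    variance and the lag-1 increment covariance that is unbiased in the
    presence of static noise.

Lattice-view unwrapping of constant-pressure data injects multiplicative
noise that grows with distance from the origin, so estimates drawn from
late trajectory segments drift upward.  :func:`block_analysis` segments
a trajectory into equal blocks, fits each independently and tests the
block-index trend of D with a rank correlation and a permutation
p-value — flat for toroidal-view data, positive for lattice-view data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import BoxSeries, UnwrappedTrajectory
from .sampling_bounds import KB

__all__ = [
    "MSDCurve",
    "DiffusionFit",
    "BlockSeries",
    "PairDiffusionResult",
    "msd",
    "msd_array",
    "ols_fit",
    "cve_fit",
    "cve_fit_array",
    "block_analysis",
    "pair_diffusion",
    "compressibility",
]

logger = logging.getLogger(__name__)


@dataclass
class MSDCurve:
    """Time-averaged MSD estimates at lag times ``tau = m * dt``."""

    lags: np.ndarray  #: lag times, starting at 0
    values: np.ndarray  #: MSD estimates (length**2)
    n_pairs: np.ndarray  #: number of averaged frame pairs N - m per lag
    dimension: int


@dataclass
class DiffusionFit:
    """A diffusion-coefficient estimate with its noise intercept.

    ``a2`` is the MSD vertical intercept (length**2); negative values
    are reported as-is.  ``stderr`` is the standard error on ``D``.
    """

    D: float
    a2: float
    dimension: int
    window: tuple[int, int] | None = None
    stderr: float = float("nan")
    B: float = 0.0  # motion blur excluded by construction


@dataclass
class BlockSeries:
    """Per-block diffusion fits and the block-index trend of D.

    ``trend`` is the Spearman rank correlation of ``D_i`` against the
    block index; ``p_value`` its two-sided permutation p-value.
    """

    block_length: float
    fits: list[DiffusionFit]
    trend: float
    p_value: float
    n_dropped_frames: int = 0

    @property
    def D_values(self) -> np.ndarray:
        return np.array([f.D for f in self.fits])


@dataclass
class PairDiffusionResult:
    """Single and relative diffusion coefficients of a particle pair."""

    D_x: float
    D_y: float
    D_pair: float
    gap: float  #: D_pair - (D_x + D_y); zero in expectation for independent pairs
    gap_stderr: float


def _require_unwrapped(u: UnwrappedTrajectory) -> None:
    if u.scheme_tag == "native-wrapped":
        raise ValueError("MSD/diffusion analysis requires an unwrapped trajectory")


def msd_array(u: np.ndarray, dt: float, max_lag_index: int, dimension: int | None = None) -> MSDCurve:
    """Time-averaged MSD of positions shaped ``(n_frames, n_particles, n_axes)``.

    ``MSD_m = (1/(N - m)) sum_i |u_{i+m} - u_i|**2`` per particle,
    averaged over particles; the squared norm runs over axes.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim == 1:
        u = u[:, None, None]
    n = u.shape[0]
    if not 0 < max_lag_index < n:
        raise ValueError(f"max_lag_index must be in [1, {n - 1}]")
    d = dimension if dimension is not None else u.shape[2]
    values = np.zeros(max_lag_index + 1)
    n_pairs = np.empty(max_lag_index + 1, dtype=np.int64)
    n_pairs[0] = n
    for m in range(1, max_lag_index + 1):
        disp = u[m:] - u[:-m]  # (N - m, P, A)
        sq = np.einsum("ipa,ipa->ip", disp, disp)
        values[m] = sq.mean()  # mean over pairs and particles
        n_pairs[m] = n - m
    return MSDCurve(
        lags=dt * np.arange(max_lag_index + 1),
        values=values,
        n_pairs=n_pairs,
        dimension=d,
    )


def msd(u: UnwrappedTrajectory, max_lag_index: int) -> MSDCurve:
    """Time-averaged MSD of an unwrapped trajectory (all axes pooled)."""
    _require_unwrapped(u)
    return msd_array(u.positions, u.box.dt, max_lag_index, dimension=u.n_axes)


def ols_fit(curve: MSDCurve, m_init: int, m_end: int) -> DiffusionFit:
    """Straight-line fit ``MSD = 2 d D tau + a**2`` over lags ``[m_init, m_end]``.

    Ordinary least squares on the stored MSD values; the slope standard
    error from the regression residuals propagates to ``D``.  The
    intercept may come out negative and is not clipped.
    """
    n_lags = len(curve.lags) - 1
    if not (0 <= m_init <= m_end <= n_lags):
        raise ValueError(f"window [{m_init}, {m_end}] outside curve lags [0, {n_lags}]")
    if m_end == m_init:
        raise ValueError("fit window must contain at least two lag values")
    tau = curve.lags[m_init : m_end + 1]
    y = curve.values[m_init : m_end + 1]
    res = stats.linregress(tau, y)
    denom = 2.0 * curve.dimension
    return DiffusionFit(
        D=res.slope / denom,
        a2=float(res.intercept),
        dimension=curve.dimension,
        window=(m_init, m_end),
        stderr=res.stderr / denom if np.isfinite(res.stderr) else float("nan"),
    )


def cve_fit_array(u: np.ndarray, dt: float, dimension: int | None = None) -> DiffusionFit:
    """Covariance-based estimator on raw positions ``(n_frames, n_particles, n_axes)``.

    Per particle and axis, with increments ``dx_i = x_{i+1} - x_i``:

        ``D_hat = <dx**2>/(2 dt) + <dx_i dx_{i+1}>/dt``
        ``sigma_loc**2 = -<dx_i dx_{i+1}>``

    The lag-1 covariance removes the static-noise contamination of the
    increment variance.  D is averaged over axes and particles; the
    reported intercept is the MSD form ``a**2 = 2 d sigma_loc**2``.  The
    standard error on D is the spread across particles (particles
    assumed independent); for a single particle it falls back to the
    large-N theoretical variance of the estimator.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim == 1:
        u = u[:, None, None]
    n, P, A = u.shape
    if n < 3:
        raise ValueError("CVE needs at least 3 frames")
    d = dimension if dimension is not None else A
    dx = np.diff(u, axis=0)  # (n-1, P, A)
    var = np.mean(dx**2, axis=0)  # (P, A)
    cov = np.mean(dx[:-1] * dx[1:], axis=0)
    D_pa = var / (2.0 * dt) + cov / dt  # (P, A)
    D_per_particle = D_pa.mean(axis=1)
    D = float(D_per_particle.mean())
    sigma2 = float(np.mean(-cov))
    if P > 1:
        stderr = float(D_per_particle.std(ddof=1) / np.sqrt(P))
    else:
        # single-trajectory CVE variance for a pure diffusive walk is
        # ~ 6 D^2 / n_increments per axis; axis average divides by A
        stderr = float(abs(D) * np.sqrt(6.0 / (dx.shape[0] * A)))
    return DiffusionFit(D=D, a2=2.0 * d * sigma2, dimension=d, stderr=stderr)


def cve_fit(u: UnwrappedTrajectory) -> DiffusionFit:
    """Covariance-based D estimate of an unwrapped trajectory."""
    _require_unwrapped(u)
    return cve_fit_array(u.positions, u.box.dt, dimension=u.n_axes)


def _fit_block(block: np.ndarray, dt: float, estimator: str, window, dimension: int) -> DiffusionFit:
    if estimator == "cve":
        return cve_fit_array(block, dt, dimension=dimension)
    if estimator == "ols":
        m_init, m_end = window
        curve = msd_array(block, dt, max_lag_index=m_end, dimension=dimension)
        return ols_fit(curve, m_init, m_end)
    raise ValueError(f"unknown estimator {estimator!r}; choose 'cve' or 'ols'")


def block_analysis(
    u: UnwrappedTrajectory,
    block_duration: float,
    estimator: str = "cve",
    window: tuple[int, int] = (1, 20),
    n_permutations: int = 10_000,
    seed: int = 0,
) -> BlockSeries:
    """Segment a trajectory into equal blocks and test for drift in D.

    Each block of duration ``block_duration`` is fitted independently
    (the trailing partial block is dropped with a logged notice).  The
    trend statistic is the Spearman rank correlation of ``D_i`` against
    the block index ``i`` with a seeded two-sided permutation p-value —
    robust to the nonlinear growth shape the lattice-view artifact
    produces.
    """
    _require_unwrapped(u)
    dt = u.box.dt
    frames_per_block = int(round(block_duration / dt))
    if frames_per_block < 3:
        raise ValueError("block_duration must span at least 3 frames")
    n_blocks = u.n_frames // frames_per_block
    if n_blocks < 2:
        raise ValueError("need at least 2 whole blocks")
    dropped = u.n_frames - n_blocks * frames_per_block
    if dropped:
        logger.info("block_analysis: dropping trailing partial block of %d frames", dropped)
    fits = []
    for b in range(n_blocks):
        block = u.positions[b * frames_per_block : (b + 1) * frames_per_block]
        fits.append(_fit_block(block, dt, estimator, window, u.n_axes))
    D = np.array([f.D for f in fits])
    trend, p_value = _permutation_trend(D, n_permutations, seed)
    return BlockSeries(
        block_length=frames_per_block * dt,
        fits=fits,
        trend=trend,
        p_value=p_value,
        n_dropped_frames=dropped,
    )


def _permutation_trend(D: np.ndarray, n_permutations: int, seed: int) -> tuple[float, float]:
    """Spearman correlation of D against block index, permutation p-value."""
    idx = np.arange(len(D))
    if np.allclose(D, D[0]):
        return 0.0, 1.0
    rho = float(stats.spearmanr(idx, D).statistic)
    rng = np.random.default_rng(seed)
    ranks = stats.rankdata(D)
    rank_idx = stats.rankdata(idx)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        null[k] = np.corrcoef(rank_idx, rng.permutation(ranks))[0, 1]
    p = (1 + np.sum(np.abs(null) >= abs(rho) - 1e-12)) / (n_permutations + 1)
    return rho, float(p)


def pair_diffusion(
    u_x: UnwrappedTrajectory,
    u_y: UnwrappedTrajectory,
    estimator: str = "cve",
    window: tuple[int, int] = (1, 20),
) -> PairDiffusionResult:
    """Diffusion of two particles and of their distance vector.

    For independent diffusive processes the relative coordinate
    ``X - Y`` is itself diffusive with ``D_pair = D_x + D_y``; the
    reported ``gap`` is the departure from that additivity, with a
    standard error combined from the three fits.
    """
    if u_x.n_frames != u_y.n_frames or u_x.box.dt != u_y.box.dt:
        raise ValueError("pair trajectories must share frame count and dt")
    dt = u_x.box.dt
    d = u_x.n_axes
    rel = u_x.positions - u_y.positions
    def _fit(arr):
        return _fit_block(arr, dt, estimator, window, d)
    fx, fy, fp = _fit(u_x.positions), _fit(u_y.positions), _fit(rel)
    gap = fp.D - (fx.D + fy.D)
    gap_se = float(np.sqrt(fx.stderr**2 + fy.stderr**2 + fp.stderr**2))
    return PairDiffusionResult(D_x=fx.D, D_y=fy.D, D_pair=fp.D, gap=gap, gap_stderr=gap_se)


def compressibility(volumes: np.ndarray, temperature: float) -> float:
    """Isothermal compressibility from equilibrium volume fluctuations.

    ``chi_T = Var(V) / (k_B T <V>)`` with the unbiased (n-1) variance.
    For volumes in nm^3 and temperature in K the result is in
    nm^3 mol / kJ (multiply by 1e-3/6.02214e23 m^3/J = 1.6606e-27 for Pa^-1).
    """
    v = np.asarray(volumes, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 volume samples")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    beta = 1.0 / (KB * temperature)
    return float(beta * v.var(ddof=1) / v.mean())
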