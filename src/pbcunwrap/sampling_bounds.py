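"""Safe trajectory-output intervals from boundary-crossing probabilities.

Unwrapping schemes silently fail when a particle moves more than half a
box length between saved frames, because the minimal-image displacement
then points the wrong way.  For ``N`` particles saved every ``dt`` over
a total time ``t_total``, the probability that at least one of the
``3 N t_total/dt`` sampled 1D displacements exceeds ``L/2`` is

    ``P = 1 - (1 - p)**(3 N t_total / dt)``,
    ``p = Pr(X > L/2) = erfc( L / (2 sqrt(2) sigma) )``

where the displacement scale ``sigma`` depends on the dominant dynamics
over one interval: ``sigma**2 = dt**2 / (beta m)`` when ballistic
(thermal velocity), ``sigma**2 = 2 D dt`` when diffusive.  Setting
``P = epsilon`` and solving for ``dt`` gives the largest safe output
interval.  The numeric root of the full relation is authoritative;
closed forms obtained from the asymptotic ``erfc`` expansion (a pure
logarithm in the ballistic limit, the lower Lambert-W branch in the
diffusive limit) serve as cross-checks.

Units are fixed internally to nm, ps, K and g/mol, for which the
Boltzmann constant is ``0.00831446... nm^2 g mol^-1 ps^-2 K^-1``
(equivalently kJ/mol/K).  Diffusion coefficients are therefore carried
in nm^2/ps here; the CLI accepts the conventional nm^2/ns and converts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import erfc, lambertw

__all__ = [
    "KB",
    "BoundSpec",
    "CrossingResult",
    "NoSafeIntervalError",
    "crossing_probability",
    "max_sampling_interval",
    "lambert_w_lower",
    "lambert_w_lower_series",
]

#: Boltzmann constant in nm^2 g mol^-1 ps^-2 K^-1 (= kJ mol^-1 K^-1).
KB = 0.00831446261815324

#: Below this value of p_single * n_frames * 3N the union bound
#: P ~ 3 N p t_total/dt is used verbatim; the truncation error is then
#: below 0.05% of the computed probability.
_SMALL_P_PRODUCT = 1e-3


class NoSafeIntervalError(ValueError):
    """No output interval in (0, t_total] keeps the failure probability at epsilon."""


@dataclass(frozen=True)
class BoundSpec:
    """Inputs of the safe-interval calculation.

    Exactly one of ``n_particles`` / ``density`` must be given (density
    in particles per nm^3, multiplied by ``L**3``), and exactly the
    mode-appropriate one of ``mass`` (g/mol, ballistic) / ``diffusion``
    (nm^2/ps, diffusive).
    """

    epsilon: float
    L: float
    t_total: float
    temperature: float
    mode: str  # "ballistic" | "diffusive"
    n_particles: float | None = None
    density: float | None = None
    mass: float | None = None
    diffusion: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must lie in (0, 1)")
        for name in ("L", "t_total", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mode not in ("ballistic", "diffusive"):
            raise ValueError("mode must be 'ballistic' or 'diffusive'")
        if (self.n_particles is None) == (self.density is None):
            raise ValueError("give exactly one of n_particles or density")
        if self.mode == "ballistic":
            if self.mass is None or self.diffusion is not None:
                raise ValueError("ballistic mode requires mass (and no diffusion)")
            if self.mass <= 0:
                raise ValueError("mass must be positive")
        else:
            if self.diffusion is None or self.mass is not None:
                raise ValueError("diffusive mode requires diffusion (and no mass)")
            if self.diffusion <= 0:
                raise ValueError("diffusion must be positive")
        n = self.n_particles if self.n_particles is not None else self.density * self.L**3
        if n <= 0:
            raise ValueError("particle count must be positive")

    @property
    def n(self) -> float:
        """Particle count N (from density if not given directly)."""
        if self.n_particles is not None:
            return float(self.n_particles)
        return float(self.density * self.L**3)

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)


@dataclass(frozen=True)
class CrossingResult:
    """Crossing probabilities at one sampling interval."""

    p_single: float  #: Pr(X > L/2) for one particle, one axis, one interval
    p_total: float  #: probability of >= 1 mis-unwrapping event in the whole run
    sigma: float  #: 1D displacement scale over the interval (nm)


def _sigma(spec: BoundSpec, dt: float) -> float:
    if spec.mode == "ballistic":
        return dt / np.sqrt(spec.beta * spec.mass)
    return np.sqrt(2.0 * spec.diffusion * dt)


def crossing_probability(spec: BoundSpec, dt: float) -> CrossingResult:
    """Probability of any mis-unwrapping event at output interval ``dt``.

    Uses the union-bound reduction ``P ~ M p`` (with
    ``M = 3 N t_total/dt`` sampled 1D displacements) whenever
    ``M p < 1e-3``; otherwise the exact complement
    ``1 - (1 - p)**M`` evaluated in log space.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    sigma = _sigma(spec, dt)
    p = float(erfc(spec.L / (2.0 * np.sqrt(2.0) * sigma)))
    m = 3.0 * spec.n * spec.t_total / dt
    if p * m < _SMALL_P_PRODUCT:
        p_total = p * m
    elif p >= 1.0:
        p_total = 1.0
    else:
        p_total = float(-np.expm1(m * np.log1p(-p)))
    return CrossingResult(p_single=p, p_total=p_total, sigma=float(sigma))


def lambert_w_lower(z: float) -> float:
    """Lower branch ``W_{-1}`` of the Lambert W function on [-1/e, 0)."""
    if not (-1.0 / np.e <= z < 0.0):
        raise ValueError(f"z={z} outside the W_-1 domain [-1/e, 0)")
    if z == -1.0 / np.e:  # scipy returns nan exactly at the branch point
        return -1.0
    return float(lambertw(z, k=-1).real)


def lambert_w_lower_series(z: float) -> float:
    """Three-term small-argument expansion of ``W_{-1}``.

    ``W_{-1}(z -> 0^-) ~ -ln(-1/z) - ln(ln(-1/z)) - ln(ln(-1/z))/ln(-1/z)``
    """
    if not (-1.0 / np.e <= z < 0.0):
        raise ValueError(f"z={z} outside the W_-1 domain [-1/e, 0)")
    eta = np.log(-1.0 / z)
    return float(-eta - np.log(eta) - np.log(eta) / eta)


def _dt_closed_form(spec: BoundSpec) -> float:
    """Safe interval from the asymptotic-erfc closed form.

    Replacing ``erfc(x)`` by ``exp(-x**2)/(x sqrt(pi))`` in the
    union-bound relation ``epsilon = 3 N (t_total/dt) p`` and solving:

    *   ballistic (``x = L sqrt(beta m) / (2 sqrt(2) dt)``): the ``1/dt``
        prefactor cancels against ``1/x``, leaving
        ``dt = sqrt(c / ln(A/epsilon))`` with ``c = L**2 beta m / 8`` and
        ``A = 3 N t_total * 2 sqrt(2) / (L sqrt(beta m pi))`` — a pure
        logarithm;
    *   diffusive (``x**2 = c'/dt``, ``c' = L**2/(16 D)``): the relation
        ``sqrt(y) exp(-y) = s`` in ``y = c'/dt`` is solved by the lower
        Lambert-W branch, ``y = -W_{-1}(-2 s**2)/2``, ``dt = c'/y``.
    """
    n3t = 3.0 * spec.n * spec.t_total
    if spec.mode == "ballistic":
        bm = spec.beta * spec.mass
        c = spec.L**2 * bm / 8.0
        a = n3t * 2.0 * np.sqrt(2.0) / (spec.L * np.sqrt(bm * np.pi))
        return float(np.sqrt(c / np.log(a / spec.epsilon)))
    c = spec.L**2 / (16.0 * spec.diffusion)
    # epsilon = (n3t / sqrt(pi c)) dt^{-1/2} exp(-c/dt); in y = c/dt this
    # reads sqrt(y) exp(-y) = s, i.e. y exp(-2y) = s^2
    s = spec.epsilon * c * np.sqrt(np.pi) / n3t
    y = -0.5 * lambert_w_lower(-2.0 * s * s)
    return float(c / y)


def max_sampling_interval(spec: BoundSpec, method: str = "root") -> float:
    """Largest output interval with total crossing probability ``epsilon``.

    ``method="root"`` (default) solves the full probability relation
    numerically with Brent's method; ``method="lambert"`` evaluates the
    asymptotic closed form.  The two agree to well within the asymptotic
    expansion error for all physically sensible inputs.

    Raises
    ------
    NoSafeIntervalError
        If no interval in ``(0, t_total]`` meets the tolerance.
    """
    if method == "lambert":
        return _dt_closed_form(spec)
    if method != "root":
        raise ValueError("method must be 'root' or 'lambert'")

    def f(dt: float) -> float:
        return crossing_probability(spec, dt).p_total - spec.epsilon

    lo, hi = 1e-9, spec.t_total
    if f(hi) <= 0:
        # even a single output frame stays within tolerance
        return float(hi)
    if f(lo) >= 0:
        raise NoSafeIntervalError(
            f"crossing probability exceeds epsilon={spec.epsilon} even at dt={lo}"
        )
    return float(brentq(f, lo, hi, xtol=1e-14, rtol=1e-12))
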