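# pbcunwrap

Unwrapping and diffusion analysis of particle trajectories from
constant-pressure (NPT) molecular-dynamics simulations with fluctuating
periodic boxes.

## The problem

MD engines store particle positions wrapped into the central simulation
cell. Computing a translational diffusion coefficient from the mean
squared displacement (MSD) requires *unwrapped* coordinates — the
boundary crossings have to be undone. At constant volume this is
unambiguous. Under a barostat, however, the box edge `L_i` changes every
frame and particle positions are rescaled along with it, and the two
natural views of periodic boundary conditions stop agreeing:

- **Toroidal view (TOR)** — accumulate minimal in-box displacements:

      u_{i+1} = u_i + (w_{i+1} − w_i) − L_{i+1} · floor((w_{i+1} − w_i)/L_{i+1} + 1/2)

  This preserves the statistics of the wrapped trajectory (a diffusive
  process stays diffusive) but the output is not an integer number of
  box lengths away from `w`, so interparticle distances are not
  preserved.

- **Lattice view (LAT)** — track integer image numbers `n_i` and set
  `u_i = w_i + n_i · L_i` exactly. This preserves distances, but the
  barostat rescaling acts on the full unwrapped coordinate: the
  trajectory picks up multiplicative noise `(L_{i+1}/L_i − 1) u_i` that
  grows without bound as the particle diffuses away from the origin.
  "Unwrapped" NPT trajectories written by common MD engines are of this
  kind, and block-wise diffusion estimates from them drift upward with
  simulation time.

`pbcunwrap` implements both schemes (plus the older heuristic `hlat` and
the corrected-toroidal `kv` recursion, which is provably identical to
`lat`), the rewrapping scheme consistent with each view, and diagnostics
that expose the lattice-view artifact. Users are people analysing NPT
trajectories who need trustworthy diffusion coefficients — the
recommended pipeline is: wrap on-lattice if needed, make molecules
whole, track the centre of mass, unwrap with TOR, then fit.

Everything operates per Cartesian axis on orthorhombic boxes, with the
central cell either `[−L/2, L/2)` (`alpha = 1`, LAMMPS/NAMD convention)
or `[0, L)` (`alpha = 0`, GROMACS convention).

## Validation model

A seeded fluctuating-box Brownian model serves as the package's oracle:
box edges `L_i = L + σ_L R'_i` are Gaussian white noise, and the same
noise draws jointly generate the wrapped trajectory `w`, its true
off-lattice partner `u` (noise coupled to the bounded wrapped
coordinate) and the lattice partner `u*` (noise coupled to the unbounded
coordinate). By construction `tor(w) ≡ u` and `lat(w) ≡ u*` frame by
frame, which pins down every sign and floor in the implementations.
Defaults are `σ_L = 0.1 L`, `σ_w = 0.05 L`.

## Safe output intervals

An unwrapping scheme silently fails when a particle moves more than
`L/2` between saved frames. For `N` particles over a total time
`t_total`, the package solves

    ε = 1 − (1 − erfc(L / (2·√2·σ)))^(3 N t_total/Δt)

for the largest safe output interval `Δt`, with `σ² = Δt²/(βm)`
(ballistic) or `σ² = 2 D Δt` (diffusive); an asymptotic closed form via
the lower Lambert-W branch cross-checks the numeric root.

## Worked example

```python
import numpy as np
from pbcunwrap import GaussianModelParams, simulate, unwrap, block_analysis

real = simulate(GaussianModelParams(L=1.0, sigma_L=0.1, sigma_w=0.05,
                                    n_steps=10_000, seed=42))
u_tor = unwrap(real.w, "tor")
u_lat = unwrap(real.w, "lat")
print(np.abs(u_tor.positions - real.u_true.positions).max())  # 1.62e-14
print(np.abs(u_lat.positions - real.u_star.positions).max())  # 1.78e-14

for tag, u in (("TOR", u_tor), ("LAT", u_lat)):
    b = block_analysis(u, 1000.0, estimator="ols", window=(0, 20), seed=1)
    print(tag, np.round(b.D_values, 4), f"trend={b.trend:+.2f} p={b.p_value:.3g}")
```

prints

```
TOR [0.0011 0.0018 0.0015 0.0014 0.0016 0.001  0.0014 0.0011 0.0016 0.0013] trend=-0.16 p=0.667
LAT [0.001  0.0018 0.0017 0.002  0.0019 0.0011 0.0015 0.0028 0.0046 0.0095] trend=+0.68 p=0.0324
```

Both unwraps agree with their closed-form partners to round-off. The
per-block diffusion coefficient of the TOR-unwrapped trajectory scatters
around the true `σ_w²/(2Δt) = 0.00125`; the LAT-unwrapped one grows by
nearly an order of magnitude toward late blocks — the lattice-view
artifact. (A single realization gives `p ≈ 0.03`; on a 200-realization
ensemble the LAT trend reaches `p < 1e-3` while TOR stays flat, as the
test suite asserts.)

The same analyses are available on trajectory files from the shell:

```sh
pbcunwrap simulate --seed 7 --n-steps 1000 --out w.tsv
pbcunwrap unwrap w.tsv u.tsv --scheme tor
pbcunwrap blocks u.tsv --block-duration 100 --estimator cve
pbcunwrap bounds --mode diffusive --epsilon 0.01 --box 2.5 \
    --density 33.3 --temperature 300 --diffusion 6 --t-total 1e6
# dt_max = 2.88617 ps
# P(dt_max) = 0.01
```

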