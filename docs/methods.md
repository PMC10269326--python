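# Methods

This note documents the models, conventions, numerical choices and
known limitations behind `pbcunwrap`, in the order a user meets them.

## Conventions and data model

All formulas are one-dimensional and applied independently per
Cartesian axis of an orthorhombic box; triclinic cells are out of scope.
Positions are double precision throughout — far-from-origin unwrapped
coordinates lose absolute precision linearly in `|u|/L`, which is why
trajectory files store shortest round-trip decimal representations and
the test suite checks bit-exact file round trips.

The central cell is half-open: `[−L/2, L/2)` for `alpha = 1`,
`[0, L)` for `alpha = 0`. The half-open choice makes wrapping
idempotent and gives every boundary point a unique owner; which edge
owns a particle exactly on it is not observable in practice but has to
be fixed for the wrap → validate closure to hold. After the wrap
formula `u − L·floor(u/L + α/2)` a single corrective fold handles the
floating-point stragglers that land exactly on the open upper edge.

## Unwrapping schemes

Four per-axis recursions, all started from `u_0 = w_0` (and image
numbers `n_0 = 0`), with `floor` the mathematical floor (ties resolve
downward) and the new box length `L_{i+1}` used wherever a box length
appears in a step — no averaging of consecutive boxes:

- `tor`: adds minimal in-box displacements; evaluated as a cumulative
  sum, so it is exactly associative with block splitting.
- `lat`: image numbers from jump detection,
  `n_{i+1} = n_i − floor((w_{i+1} − w_i)/L_{i+1} + 1/2)`, then
  `u_i = w_i + n_i L_i` exactly. Explicitly book-kept image numbers
  (engine `remap`-style output) are accepted through `image_unwrap` and
  the image-number columns of the file format.
- `hlat`: the heuristic minimal-step image choice; retained because
  legacy tools implement it, with its known NPT mis-assignments.
- `kv`: the corrected-toroidal recursion — the `tor` update plus a
  `(L_{i+1}/L_i − 1)(u_i − w_i)` lattice-rescaling term. Algebraically
  identical to `lat`; it is kept as a literal recursion (accumulating
  round-off) and the equivalence `kv ≡ lat` is asserted to 1e−9·|u| on
  100 seeded realizations, which validates the transcription of both.

Rewrapping is scheme-matched: the stateless lattice wrap inverts `lat`
exactly, while `tor` output must be rewrapped by backtracing its
displacements frame by frame (`tor_rewrap`), which consumes only
displacements and never image numbers. Cross-pairing the schemes does
not reproduce the wrapped data once any crossing has occurred — this is
asserted, not just documented.

## The fluctuating-box Gaussian model

The validation model draws box edges `L_i = L + σ_L R'_i` as white
noise (one independent series per axis, shared by all particles of a
realization) and propagates, from the same standard-normal draws
`R_{i+1}`,

    w_{i+1}  = wrap_{α=1, L_{i+1}}( (L_{i+1}/L_i) w_i + σ_w R_{i+1} )
    u_{i+1}  = u_i + (L_{i+1}/L_i − 1) w_i + σ_w R_{i+1}
    u*_{i+1} = (L_{i+1}/L_i) u*_i + σ_w R_{i+1}

The rescale-then-step order mimics barostat position rescaling. The
defining property — and the structural check on the transcription — is
that `tor(w)` reproduces `u` and `lat(w)` reproduces `u*` frame by
frame to round-off, *provided* every true step satisfies
`|Δu| < L_{i+1}/2`. At the default noise levels (`σ_L = 0.1 L`,
`σ_w = 0.05 L`, chosen to make the scheme divergence visible at desk
scale while keeping boxes positive) a violating step is a ≈5σ event,
roughly one per 10⁶ steps; the acceptance tests verify the condition
explicitly and require it to hold for ≥95 of 100 realizations rather
than assuming it.

The initial position is uniform in the frame-0 cell,
`w_0 = L_0 (R' − 1/2)`, so the wrapped trajectory never leaves its cell
at any frame, including the first.

What the model does *not* emulate: inertia, interparticle forces,
box-noise autocorrelation (a real barostat has a relaxation time — see
the estimator note below), and anisotropic or correlated-axis box
fluctuations. Passing tests on this model demonstrate the algebra and
statistics of the schemes, not the physics of any particular water
model.

## Safe output intervals

With `M = 3 N t_total/Δt` sampled 1D displacements, the probability of
at least one step beyond `L/2` is `P = 1 − (1 − p)^M` with
`p = erfc(L/(2√2 σ))`; `σ² = Δt²/(βm)` ballistic, `2DΔt` diffusive.
Internally the unit system is nm/ps/K/(g/mol) with
`k_B = 0.00831446… kJ mol⁻¹ K⁻¹`; the CLI converts D from nm²/ns.
`P` is evaluated in log space, with the union bound `P ≈ M p`
substituted when `M p < 10⁻³` (truncation error below 0.05% of the
result). The solver brackets the root of `P(Δt) = ε` in
`(10⁻⁹, t_total]` with Brent's method at 1e−12 relative tolerance; if
`P(t_total) ≤ ε` every admissible interval is safe and `t_total` is
returned, and if no interval satisfies the tolerance a
`NoSafeIntervalError` is raised.

Replacing `erfc(x)` by `e^{−x²}/(x√π)` gives closed forms used as
cross-checks. In the diffusive regime (`x² = c/Δt`, `c = L²/(16D)`) the
relation `√y e^{−y} = ε c √π / (3 N t_total)` in `y = c/Δt` is solved by
the lower Lambert-W branch, `y = −W_{−1}(−2s²)/2`. In the ballistic
regime the `1/Δt` frame-count prefactor cancels against the `1/x` of
the erfc expansion and the closed form collapses to a pure logarithm,
`Δt = sqrt(c / ln(A/ε))` with `c = L²βm/8` — no Lambert W survives the
cancellation. Both closed forms agree with the numeric root to well
under 1% at water-like conditions; the root is authoritative.

## Diffusion estimation

The MSD model is `MSD(τ) = 2dDτ + a²`: static noise only, no
motion-blur term, because saved MD frames are instantaneous
configurations. Estimators:

- **OLS**: straight-line fit over a lag window `[m_init, m_end]` of the
  time-averaged MSD; slope `2dD`, intercept `a²` (negative intercepts
  are reported unclipped), D uncertainty from the residual slope error.
- **CVE**: per axis, `D̂ = ⟨Δx²⟩/(2Δt) + ⟨Δx_i Δx_{i+1}⟩/Δt` with
  localization variance `σ̂² = −⟨Δx_i Δx_{i+1}⟩`, reported as the MSD
  intercept `a² = 2dσ̂²`. Averaged over axes and particles; the D
  standard error is the spread across particles (assumed independent),
  falling back to the single-trajectory value `D√(6/n)` for one
  particle. Both estimators are validated purely by parameter-recovery
  simulations (known D, known injected noise, 3-SE agreement), not
  against any published MD number.

**Block drift diagnostic.** `block_analysis` splits a trajectory into
equal non-overlapping blocks (trailing partial block dropped with a
notice), fits each independently, and tests the block-index trend of D
with a Spearman rank correlation and a seeded 10⁴-permutation two-sided
p-value — rank-based because the lattice-view growth is nonlinear.

Estimator choice matters here, and the white box noise of the Gaussian
model makes it sharper than in MD: the lattice-view artifact enters the
increments exactly like static localization noise with a slowly growing
amplitude, and the CVE's lag-1 covariance term cancels it out of D̂ by
construction (the growth shows up in its `a²` instead). An estimator
that does not model the intercept converts the growing `a²` into
apparent D growth — so the drift diagnostic in the acceptance tests
uses OLS with an origin-anchored window `(0, 20)`, where the known
exact point MSD(0) = 0 makes the fit sensitive to the intercept. On
real barostat data the box noise is correlated in time, the
cancellation is imperfect, and likelihood-type estimators drift as
well; the diagnostic's logic (per-block fits + rank trend) is
estimator-agnostic.

Pair diffusion estimates D on `X`, `Y` and the relative coordinate
`X − Y` and reports the additivity gap `D_pair − (D_X + D_Y)` with a
combined standard error; for independent processes the gap is zero in
expectation.

The compressibility utility is the equilibrium volume-fluctuation
relation `χ_T = Var(V)/(k_B T ⟨V⟩)` with the unbiased variance; for
nm³ volumes the result is in nm³·mol/kJ.

## Molecular trajectories

Applying the toroidal scheme atom by atom displaces bonded atoms
relative to each other whenever a bond straddles the boundary under box
rescaling. The supported order of operations is: make the molecule
whole in every frame (deterministic BFS from the reference atom in
ascending index order, each neighbour placed at its minimal image
relative to its placed parent), wrap the whole-molecule centre of mass,
toroidally unwrap that single trajectory, and optionally rebuild atoms
from their whole-frame offsets — which preserves all intramolecular
distances of the whole frames exactly. A bond whose minimal-image
component reaches `L/2` is ambiguous and raises; fixtures and users
must keep bonds below half the smallest box edge. Tracking a reference
atom instead of the COM is supported and statistically equivalent for
diffusion. Polymer end-to-end analyses need only the per-frame
make-whole step.

## Problem sizes in the test suite

The acceptance checks run 100–200 realizations of 10⁴ steps (oracle
equivalence, round trips, block drift), 200 walks of 3000 steps
(estimator recovery, pair additivity) and an 8000-step rigid dimer with
several hundred boundary crossings — sizes chosen so every quantitative
claim resolves at 3-standard-error precision while the whole suite
completes in well under a minute of simulation time per check.

## Known limitations

Triclinic boxes, velocities, finite-size corrections to D, Green–Kubo
estimation, likelihood-based (MLE/GLS) estimators and motion blur are
out of scope. No attempt is made to "sanitise" the bounded barostat
noise out of wrapped trajectories; at constant pressure the wrapped
dynamics is taken as the reference dynamics, and constant-volume
simulation is the recommendation when that noise is unacceptable.
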