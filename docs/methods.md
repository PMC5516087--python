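# Methods

`chiralring` simulates an annular epithelial monolayer — the ring of cells
that surrounds the *Drosophila* male genitalia during its 360° clockwise
rotation — as a two-dimensional vertex model with chirally biased junction
tension, and measures how junctional remodeling (T1 transitions)
self-organizes into collective rotation and traveling waves.

## Model

Cells are polygons; the degrees of freedom are the polygon vertices
`r_i`. Vertex motion is overdamped force balance,

    eta_i dr_i/dt = -dE/dr_i ,

with per-vertex friction `eta_i` (1 in the bulk, 100 on the outer wall, 10
on the inner wall). The energy has three parts:

* **Pressure**: `E_p = (K_a/2) sum_alpha (A_alpha/A_0 - 1)^2`, with
  preferred area `A_0 = pi (R_out^2 - R_in^2)/N ~ 0.0052` for the default
  `N = 450` cells between walls of radius `R_in = 0.5` and `R_out = 1`.
* **Tension**: `E_t = (K_p/(2 L_0)) sum_alpha (L_alpha - L_0)^2
  + sum_<kl> gamma_kl(t) l_kl`, with preferred perimeter
  `L_0 = 2 sqrt(pi A_0) ~ 0.26` and per-junction line tension `gamma_kl`.
* **Confinement**: radial springs `E_b = (k_out/2) sum_O (r_i - R_out)^2 +
  (k_in/2) sum_J (r_i - R_in)^2` on wall-tagged vertices
  (`k_out = k_in = 100`).

Lengths are in units of the outer radius and tensions in units of the
maximum chiral tension (`R_out = 1`, `gamma_c = 1`).

The chiral junction tension is

    gamma_kl = gamma_c cos^2(theta_kl - theta_0),

where `theta_kl` is the junction's axial angle measured **clockwise from
the local outward radius at the junction midpoint**, and `theta_0 = +45°`
by default. Measuring the angle in the local (co-rotating) frame is
essential: a chirality axis fixed in the laboratory frame leaves the model
exactly invariant under reflection about that axis, which maps clockwise
motion to counterclockwise motion, so the mean rotation would vanish
identically. With the local reference the same oblique bias acts at every
azimuthal position and drives a definite rotation sense; `theta_0 = 0°` or
`90°` (junctions biased exactly radially or tangentially) restores mirror
symmetry and rotation disappears. The package also exposes the
laboratory-frame axial angle (`bond_angle`) as a plain geometric query.

With temporal tension fluctuation enabled, each junction is additionally
modulated by `cos^2(pi f_kl t + delta_kl)` with quenched random
`f_kl ~ U[0,1]`, `delta_kl ~ U[0, 2 pi]` drawn once per junction. The
`pi` (rather than `2 pi`) in the phase makes `f_kl` the actual oscillation
frequency of the squared cosine — the factor `cos^2(2 pi f t)` would
oscillate at `2 f` — so a junction's contraction cycle has period
`1/f_kl`.

The tension is cell-autonomous (actomyosin contractility), so the force is
the energy gradient **at frozen `gamma_kl`** — the angle dependence of
`gamma` is not differentiated. This breaks energy conservation and is the
motor of the dynamics: the tissue can never relax to a quiescent state.

### A note on the perimeter normalization and the time step

Two published parameter combinations for this model do not close
numerically, and the package deviates deliberately:

1. With a perimeter term of the form `(K_p/2)(L/L_0 - 1)^2` and
   `K_p = 2.5 .. 20`, the junction-scale stiffness `2 K_p / L_0^2`
   (~120–940) overwhelms `gamma_c = 1`: a typical junction
   (length ~0.045) can contract by at most `gamma_c L_0^2 / (2 K_p)`
   ~ 0.004 and never reaches the T1 threshold `epsilon = 0.005`. The
   tissue is frozen at every `K_p` — no intercalation, no rotation. The
   singly normalized form `(K_p/(2 L_0))(L - L_0)^2` used here (junction
   modulus `K_p/L_0`) restores the balance of tension against elasticity
   at which the documented phenomenology appears with `K_p` keeping its
   conventional numeric range: maximum rotation speed `|v| ~ 0.05` at
   `K_p = 5`, `v ~ +0.04` at `K_p = 7.5`, complete loss of rotation at
   `K_p = 15`, sustained T1 flux and positive bond chirality, and
   `v ~ +0.025` at `K_p = 7.5` under fluctuating tension.
2. The explicit-Euler stability limit is set by the area term: the
   friction-scaled Hessian of the default tissue has largest eigenvalue
   ~6.7e3 (measured by power iteration on the analytic forces), so the
   integrator requires `dt < ~3e-4`. The package default is `dt = 2e-4`
   (stability margin ~1.4). All cadences and reported times are in model
   time units and unaffected by the internal step.

## T1 transitions

When a junction falls strictly below `epsilon = 0.005` it is checked for
eligibility and flipped: the bond rotates 90° (counter-clockwise) about
its midpoint and the five bonds at its two degree-3 endpoints reconnect,
so the two cells that shared it separate and the two cells that met only
at its endpoints become adjacent. Eligibility guards:

* **refractory** — a flipped bond may not flip again for
  `t1_refractory = 50` integrator steps (0.01 time units), preventing
  flip-flop cycling at the threshold;
* **triangle guard** — neither cell sharing the bond may be a triangle
  (the flip would create a 2-gon);
* **wall guard** — both endpoints pinned to the same wall is forbidden
  (the flip would rotate a wall-parallel junction into the wall);
* endpoints must have degree 3 and belong to exactly three cells each, and
  the two gaining cells must be distinct and not already adjacent.

Junction length is preserved by the rotation when it is at least
`epsilon`; a shorter (degenerate) junction is restored to `epsilon` about
its unchanged midpoint, which keeps refractory-protected junctions from
contracting through zero length. A flip whose rewired polygons would
self-intersect is rolled back and the bond marked refractory. Multiple
short bonds in one step are processed in ascending length order, each
re-validated against the updated topology. T1 moves conserve the vertex,
bond and cell counts and the total vertex degree.

## Initial configuration and burn-in

The initial tiling is generated from `N` uniform random points in the
annulus, regularized by 20 Lloyd iterations of a Voronoi diagram in which
points near a wall are accompanied by their radial mirror image across it,
so boundary cells close with chords tangent to the walls and every vertex
— including wall vertices — has degree 3 (`V = 2N`, `B = 3N`). Degenerate
degree-2 chord corners are spliced out at extraction. Vertices on
point–mirror ridges carry the wall tag and wall friction. Mean cell area
matches `A_0` to well under 1% at production resolution.

A fresh tiling carries elastic misfit far beyond what the production time
step can absorb, so the run protocol is: (i) quasi-static relaxation with
the chiral tension off (L-BFGS on the true potential, alternating with T1
passes); (ii) an Euler burn-in of 1 time unit, still with `gamma_c = 0`,
using a local trust-region displacement cap (at most 20% of the shortest
incident junction and `0.05 sqrt(A_0)` per step); (iii) at `t = 0` the
chiral tension switches on and plain Euler stepping begins. Recorded time
axes start at `t = 0`; the relaxation log is discarded.

## Observables

* **Angular velocity** `v_alpha = d psi_alpha / dt`: `psi` is the
  clockwise-positive angular position of the cell's area centroid,
  unwrapped along time and differentiated centrally on the recording
  cadence (0.1 time units). The global `v` is the unweighted mean over
  cells; clockwise rotation gives `v > 0`.
* **Shape anisotropy** `s_alpha`: half the eigenvalue difference of the
  area-normalized second-moment tensor of the polygon about its centroid
  (for an `a x b` rectangle, `(a^2 - b^2)/24`); zero for any shape with an
  isotropic tensor.
* **T1 rate** `n_T1`: events per unit time in a centered sliding window of
  1 time unit.
* **Bond chirality** `c = N_cl/N_ccl - N_ccl/N_cl`, counting junctions
  tilted clockwise (local angle strictly inside (0°, 90°)) versus
  counterclockwise (strictly inside (90°, 180°)); exact boundary angles
  count in neither.
* **Local fields** `v(theta, t)`, `n_T1(theta, t)`: cells and T1 events
  binned into 60 equal angular sectors (≈7–8 cells per sector at
  `N = 450`) by clockwise angular position; empty sectors are missing
  values, not zeros.

## Correlation analysis

Deviations are taken from the window mean (no further detrending, matching
the convention `delta x = x - <x>`). The 1D temporal estimator uses the
biased `1/n` normalization so the normalized autocorrelation is exactly 1
at zero lag; `C_xy(dt) = C_yx(-dt)` holds to machine precision. The 2D
estimator wraps the angular shift around the ring (clockwise-positive
`dtheta`) and averages each lag over its valid pairs (missing sectors are
pairwise-deleted). Wave speed is extracted by following the correlation
ridge outward from the origin — at each time lag the peak is searched only
near the peak of the previous lag, with parabolic sub-bin refinement —
and fitting `dtheta_peak = v_wave dt` through the origin; flat columns
(no angular contrast) are skipped and fewer than three usable lags raises
a no-ridge error instead of reporting a spurious slope. Oscillation
periods are read from the first positive-lag local maximum of the
temporal autocorrelation (prominence 5% of the maximum, lags beyond 0.3).

Stationary windows: desk-scale runs use `t in [20, t_end]` for
time-averaged quantities and correlations, for both the static and the
fluctuating tension regimes.

Ensemble profiles (e.g. the integrated T1–T1 correlation over seeds) are
aggregated pointwise with a normal-approximation 95% confidence band
(`mean ± 1.96 SE`).

## Parameter sweeps

`independent` mode restarts from a fresh tissue per parameter value;
`hysteresis` mode runs sorted values in increasing then decreasing order,
warm-starting each run from the previous final state, which exposes the
subcritical coexistence of rotating and jammed branches.

## What the generator does and does not emulate

The synthetic tissue reproduces the geometry (annulus between rigid
circular walls), the disorder (random polygonal tiling with near-uniform
cell areas), and the quenched randomness of the fluctuating-tension model.
It does not emulate cell divisions or extrusions (cell number is strictly
conserved), curved junctions, apico-basal structure, signalling gradients,
or measurement noise of segmented microscopy data — passing tests
demonstrate properties of the model, not of experimental tissue.

## Numerical choices and degenerate inputs

* Euler steps are computed by a compiled kernel identical in arithmetic to
  the pure-numpy reference step (asserted in the tests); the kernel
  returns to Python whenever a junction crosses the T1 threshold.
* Zero-length junctions and sub-3-gon loops raise geometry errors; a
  constant series cannot be z-scored; zero-variance inputs cannot be
  correlated; a zero-mean series has no CV.
* Bond angles exactly on a chirality-count boundary (0° or 90°) are
  excluded from both counts (measure-zero, documented for determinism).
* Ties in T1 processing order are broken by ascending length then bond id;
  all randomness flows from one master seed through `numpy.random.
  SeedSequence`, so runs are bit-reproducible.

## Problem sizes

Desk-scale analyses use the full `N = 450` tissue with `t_end = 40–60`
time units per run (0.2–0.3 M integrator steps), three seeds per reported
quantity, and a 16-seed ensemble at `t_end = 40` for the integrated
T1-correlation asymmetry. These sizes resolve the oscillation and
propagation structures while keeping a full analysis run in minutes on one
CPU.

## Known limitations

* The oscillation of the global velocity selects an angular mode set by
  the ring geometry and the tissue state; its period is sensitive to the
  elastic parameter reading discussed above.
* In this reconstruction the velocity oscillation is ring-synchronized (a
  standing mode): the spatiotemporal autocorrelation of the local velocity
  decays around `dtheta = 0` without a drifting ridge, so the wave-speed
  estimator reports no propagation under static tension, and the
  local-to-global velocity variance ratio (~3–4) is smaller than it would
  be if the oscillation phase were spread around the ring by a traveling
  wave. The estimators themselves recover synthetic traveling waves to
  within a few percent; the absence of propagation is a property of the
  reconstructed dynamics, not of the analysis.
* The wall model (radial springs on tagged vertices with high tangential
  friction) permits slow wall slip; very long runs accumulate boundary
  rearrangements that a hard-constraint wall would forbid.
* The T1 refractory and the `epsilon` restoration are regularizations at
  the spatial resolution limit; T1 counts at very soft parameters
  (`K_p <~ 2`) include threshold-cycling events and should be read as an
  activity measure, not a biological intercalation count.
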