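# chiralring

A chiral vertex-model simulator of an annular epithelial monolayer — the
ring of cells that surrounds the *Drosophila* male genitalia during its
360° clockwise rotation — together with the observable and correlation
machinery needed to measure how junctional remodeling (T1 transitions)
self-organizes into collective rotation and propagating activity waves.

It is written for quantitative biologists and biophysicists who want a
reproducible, scriptable implementation of chiral tissue mechanics:
every run is deterministic under a single seed, every output is a plain
CSV/JSON table, and the analysis layer (autocorrelations, spatiotemporal
correlation surfaces, wave-speed ridge fits, coefficient-of-variation and
ensemble statistics) operates on those tables.

## Model

Cells are polygons in a planar annulus between rigid circular walls
(radii `R_in = 0.5`, `R_out = 1`); the degrees of freedom are the polygon
vertices `r_i`, which follow overdamped force balance

```
eta_i dr_i/dt = - dE/dr_i |_(gamma frozen)
```

with energy

```
E = K_a/2 Σ_α (A_α/A_0 − 1)²                     (pressure)
  + K_p/(2 L_0) Σ_α (L_α − L_0)² + Σ_<kl> γ_kl ℓ_kl   (tension)
  + k_out/2 Σ_{i∈O} (r_i − R_out)² + k_in/2 Σ_{i∈J} (r_i − R_in)²
```

and chiral junction tension

```
γ_kl(t) = γ_c cos²(θ_kl − θ_0)            (static)
γ_kl(t) = γ_c cos²(π f_kl t + δ_kl) cos²(θ_kl − θ_0)    (fluctuating)
```

where `θ_kl` is the junction angle measured clockwise from the local
outward radius and `θ_0 = +45°`. Because `γ` is treated as independent of
the vertex positions when the force is derived, the system never relaxes
to equilibrium: junctions tilted 45° clockwise keep contracting, T1
neighbour exchanges keep firing, and the ring rotates clockwise. When a
junction shrinks below `ε = 0.005` it is rotated 90° about its midpoint
and the surrounding cells reconnect (a T1 transition); cell number is
conserved exactly. See `docs/methods.md` for conventions, guards, and the
deliberate deviations from the published parameterization.

## Worked example

```python
import numpy as np
from chiralring import ModelParameters, run_simulation
from chiralring.correlation import temporal_crosscorr, first_positive_peak

params = ModelParameters(K_p=7.5)          # static chiral tension
res = run_simulation(params, t_end=40.0, seed=1)
w = res.observables.window(20.0, 40.0)     # stationary window

print(f"mean angular velocity  v = {w.v_global.mean():+.4f} rad/time")
print(f"T1 transitions per time   = {w.n_t1.mean():.1f}")
print(f"bond chirality        c = {np.nanmean(w.c_chirality):+.2f}")
auto = temporal_crosscorr(w.v_global, w.v_global, 8.0, 0.1)
lag, _ = first_positive_peak(auto.dt_lags, auto.values)
print(f"oscillation period        = {lag:.2f}")
```

prints (exactly, for this seed):

```
mean angular velocity  v = +0.0402 rad/time
T1 transitions per time   = 43.9
bond chirality        c = +1.22
oscillation period        = 1.55
```

`v > 0` is clockwise rotation of the ring at about 4% of a radian per
model time unit; roughly 45 junction exchanges occur per time unit;
`c > 0` says clockwise-tilted junctions outnumber counterclockwise ones;
and the global velocity oscillates with a period of one to two time units
as elastic distortion accumulates and is released by bursts of T1s.

The same machinery is available from the shell:

```
chiralring run   --seed 1 --t-end 40 --out out/run1
chiralring analyze out/run1
chiralring sweep --parameter K_p --values 2.5,5,7.5,10,15 --t-end 40 --out out/kp
```

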