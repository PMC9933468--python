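# chargedrods

Ground states and metastable phases of charged linear rods — a coarse-grained
simulation package for suspensions of stiff, highly charged colloidal rods
(cellulose nanocrystals, fd-virus-like particles) in the regime where
screened electrostatic repulsion, not excluded volume, dominates the
structure.

## The model

Each rod of length *a* carries *Z* effective elementary charges and is
discretized into *M* collinear segments of charge *Z/M* and length *a/M*.
Two segments *i*, *j* at separation *r<sub>ij</sub>* interact through the
far-field Debye–Hückel potential of two uniformly charged line segments,

> βu<sub>ij</sub> = (Z/M)² λ · e<sup>−κ r<sub>ij</sub></sup>/r<sub>ij</sub> · σ(x<sub>i</sub>) σ(x<sub>j</sub>),  σ(x) = sinh(x)/x,  x<sub>k</sub> = (κa/2M)(**v̂**<sub>k</sub>·**r̂**<sub>ij</sub>),

where **v̂**<sub>k</sub> are the rod orientation unit vectors, κ⁻¹ the Debye
screening length and λ the Bjerrum length l<sub>B</sub> for energies in
k<sub>B</sub>T. Rod–rod energies are the M×M double sum over segments; the
rods are volumeless and purely repulsive. Everything is reduced by the rod
length: density ρ\* = ρa³, screening κ\* = κa, energies reported as
βu·a/(Z²l<sub>B</sub>).

On top of this potential the package provides

* **lattice** — AAA / ABA / ABC stacked hexagonal crystals (and square-based
  variants) with heliconical orientation fields: tilt ϕ, twist-per-layer Θ₁,
  start angle Θ₂ (azimuth ψ<sub>k</sub> = Θ₂ + kΘ₁);
* **optimize** — energy-per-particle evaluation with intra/interplane and
  neighbor-shell decompositions, scans over the in-plane spacing
  l<sub>xy</sub>\* (the layer spacing follows from the fixed density,
  l<sub>z</sub>\* = 2/(√3 ρ\* l<sub>xy</sub>\*²)) and over the tilt angle,
  and a candidate-set ground-state search;
* **mc** — zero-temperature (greedy) and finite-temperature Metropolis Monte
  Carlo with single-rod translation/rotation/combined moves, isochoric
  box-shape moves and acceptance-rate-adaptive step sizes;
* **observables** — Q-tensor order parameters S and B, pair correlation
  g(r), mean tilt and a heliconical-twist fit;
* **cnc** — mapping onto cellulose-nanocrystal suspensions: counterion-only
  evaporation curves κ\*(ρ\*), pH, line-valency estimates and effective
  aspect ratios (a + 2κ⁻¹)/(d + 2κ⁻¹);
* **cli_io / cli** — JSON run configs, extended-XYZ configurations and the
  `chargedrods` command-line tool.

## Worked example

The central qualitative result: the optimized in-plane cholesteric crystal
is unstable even at zero temperature and decays to a heliconical phase.

```python
from chargedrods.protocols import heliconical_relaxation

out = heliconical_relaxation(kappa_star=20.0, rho_star=10.0, n_steps=1500, seed=1)
print(f"tilt  = {out['tilt_deg']:.2f} deg")
print(f"twist = {out['twist_deg']:.0f} deg per layer")
print(f"u/rod = {out['trace'].u_per_rod[0]:.4e} -> {out['trace'].u_per_rod[-1]:.4e}")
```

prints (288 rods, M = 7, κ\* = 20, ρ\* = 10):

```
tilt  = 75.04 deg
twist = 120 deg per layer
u/rod = 6.3365e-03 -> 5.4491e-03
```

The AAA crystal started with rods lying in the hexagonal layers (tilt 90°)
and a 60° cholesteric twist; greedy descent tilts the rods to ≈75° and
doubles the twist to 120° — a heliconical smectic-C helix with a three-layer
pitch — while lowering the energy per rod by ≈14%. The same scans give the
lattice ground state itself: a unidirectional (ϕ = 0) close-packed ABC/ABA
crystal, with the ABC secondary minimum ≈15% and the heliconical AAA minimum
≈145% above it at κ\* = 50.

From the shell, the same pieces are available as e.g.

```
chargedrods optimize-lattice --kappa-star 50 --rho-star 10 --stacking ABC
chargedrods evaporation-curve --xi 2 --a-nm 150 --rho-star-max 30
```

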