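# Methods

## Interaction model

Rods are rigid, volumeless lines of length *a* carrying *Z* effective
elementary charges, represented as *M* collinear point-like segments of
charge *Z/M* spaced *a/M* apart (segment centers at ((k − (M+1)/2)/M)·a
along the axis, k = 1..M, i.e. half a segment inside each rod end). Two
segments interact through the far-field linearized Poisson–Boltzmann
(Debye–Hückel) potential of two uniformly charged line segments,

    beta u_ij = (Z/M)^2 * lambda * exp(-kappa r_ij)/r_ij * sigma(x_i) sigma(x_j),
    sigma(x) = sinh(x)/x,   x_k = (kappa a / 2M) (v_k . r_hat_ij),

obtained by expanding |r − s v| ≈ r − s(v·r̂) in the exponent of the
point-Yukawa kernel and integrating over each segment. The form is exact in
the limit r ≫ max(κ⁻¹, a/M); its leading relative error is ~κ(a/M)²/(8r),
a few percent at r ≈ 5 segment lengths and decaying as 1/r. The unit-tested
oracle for this transcription is a direct Gauss–Legendre double integral of
the uniform line-charge densities, which shares no code with the closed
form. Because σ is even, all energies respect rod head–tail symmetry, and
every energy carries a Z² prefactor exactly.

Validity note: the factorized far-field form diverges if nearly collinear
segments approach within a segment length (the "end-to-end distance" in the
exponent goes negative). Optimized structures never enter that regime —
their closest contacts stay at several segment lengths (see the
closest-end-separation observable, l_xy√3/4 ≈ 0.15a at ρ\* = 10 against a
segment length of a/15) — but pathological inputs (rods threaded through
each other with κa/M ≳ 1) produce huge finite energies rather than errors.
This is intended: in Monte Carlo such configurations are simply rejected.

Units: lengths are reduced by *a* (κ\* = κa, ρ\* = ρa³); energies are
reported as βu·a/(Z²l_B), so Z and λ never need numerical values during
lattice work. With defaults Z = 1, λ/a = 1 the code returns that reduced
number directly.

## Truncation

Segment pairs beyond r_c = n_trunc/κ\* + 1.5(ρ\*)^(−1/3) are dropped, and
rod pairs whose centers are farther than 1 + r_c apart cannot contain any
interacting segment pair and are skipped wholesale. The first term keeps
the truncation error ~e^(−n_trunc) relative at long screening lengths, the
second guarantees enough neighbor shells at high density. Adding segment
pairs is monotone (all terms positive), which the tests exploit. The
default n_trunc = 10 gives relative truncation errors below 10⁻⁴ over the
whole parameter span; desk-scale Monte Carlo runs use n_trunc = 6–8.

## Crystals and orientation fields

Hexagonal layers are stacked along z with registry sequences AAA, ABA
(hcp-like) or ABC (fcc-like); the two close-packing interstitial shifts are
reg·(√3/6, 1/2)·l_xy. The fixed reduced density ties the layer spacing to
the in-plane spacing, l_z\* = 2/(√3 ρ\* l_xy\*²) (1/(ρ\* l_xy\*²) for the
optional square-based variants). Orientations are uniform within a layer:
polar tilt ϕ shared by all layers, azimuth ψ_k = Θ₂ + k·Θ₁ for layer k
(k starts at 0, so Θ₂ is the azimuth of the first layer; the choice of
starting index only relabels Θ₂).

Azimuth origin. The triangular lattice is oriented with nearest-neighbor
bonds at 30°/90°/150° from the x-axis, so that ψ = 0 points along a
next-nearest-neighbor direction. This is forced by the physics of tilted
phases: an in-plane rod (ϕ → 90°) pointing along a nearest-neighbor bond at
l_xy\* < 1 would thread through its first neighbors, and the tilted-AAA
energy landscape then has its minimum at the wrong spacing with energies
two orders of magnitude too high. With the convention used here the closest
contacts of in-plane rods are end-segments of second neighbors straight
ahead and behind — the configuration the scans and the stability of the
Θ₁ ∈ {0°, 60°, 120°, 180°} twist set rely on. All angle parameters are
degrees in public interfaces, radians internally.

## Energy per particle and scans

The bulk energy per particle of a candidate crystal is the full interaction
energy of one central rod with every rod inside the rod cutoff (a spherical
cluster built ad hoc, ~300 rods at κ\* = 50 up to ~10⁴ at κ\* = 5 for
ρ\* = 10), averaged over one central rod per distinct layer environment
(the lcm of stacking and twist periods, capped at 6; a hexagonal AAA stack
with Θ₁ a multiple of 60° has a screw symmetry and needs one environment).
No ½ double-counting factor is applied; since structures are only compared
at equal density the convention cancels everywhere, and the periodic-cell
energies used in Monte Carlo are exactly half this value per rod (verified
in tests).

l_xy scans use ≥ 60 grid points over a bracket scaled as ρ\*^(−1/3)
(0.35–3.3 in those units, wide enough that both flanks rise), followed by
bounded scalar minimization around each interior grid minimum to a relative
tolerance of 10⁻⁴. Curves can carry two competing minima separated by a
barrier, so a purely local search would be wrong. Far up the flanks the
curves ripple (commensurability of shells crossing the cutoff); ripples
more than 100× above the lowest grid energy are not reported as competing
minima. Minima are classified by energy rank (primary, secondary, ...);
the barrier between two adjacent minima is the grid maximum between them
minus the shallower minimum. Tilt scans re-optimize l_xy\* at every ϕ
(default grid 2.5°) and refine grid minima parabolically; ϕ = 0 and 90°
endpoint minima are reported as such. Θ₂ is 0 throughout (it is 60°-periodic
on the lattice, which is tested).

A near-degeneracy is worth recording: at the strongest coupling studied
(ρ\* = 20, κ\* = 5) the optimized close-packed crystal at ϕ = 10°,
Θ₁ = 180° and the unidirectional ϕ = 0 crystal differ by only ~1×10⁻⁴ in
relative energy — with the sign depending on resolution (at M ≥ 11,
n_trunc ≥ 10 and fine grids the tilted one ends marginally lower). The
ground-state identity there is effectively degenerate; everywhere else in
the span ϕ = 0 close-packed wins by clear margins.

## Monte Carlo

NVT Metropolis in a periodic cuboid. One MC step is N single-rod trials
(translation by a uniform vector in [−δ_t, δ_t]³, rotation about a uniform
random axis by an angle uniform in (0, δ_r], or both applied jointly and
accepted jointly — all symmetric proposals) or 9 isochoric box trials: one
box length scaled by a uniform factor within ±0.5%, a second, randomly
chosen from the remaining two, scaled by the inverse (volume conserved to
machine precision), the third untouched, rod centers rescaled affinely.
Box steps are interleaved one per 10 particle steps by default (the
interleaving ratio is a free choice and is logged with the run config).

At T = 0 only strictly energy-lowering moves are accepted; the energy trace
is non-increasing by construction. δ_t and δ_r are adapted toward a 20–50%
acceptance rate during the first 300 steps of each 1000-step block
(multiplicative ×1.25 / ×0.8 every 10th step, per move kind) and frozen for
the rest of the block.

Local energy changes use a Verlet neighbor list over rod centers with a
0.3a skin, storing explicit periodic image shifts — exact for boxes smaller
than twice the cutoff, where minimum image fails; a rod also interacts with
its own periodic images (relevant at box heights below the cutoff), and
those image terms follow the trial state rigidly. Positions are wrapped
only at list rebuilds so a trial never sees its list invalidated by a
box-length jump. The local Δu equals a from-scratch total-energy difference
to 10⁻⁹ relative (tested, and optionally asserted at runtime every k-th
accepted move). Box trials recompute the total energy.

Stationarity and seeding. A mathematically perfect crystal is a stationary
point of every single-rod move (gradients vanish by inversion symmetry), so
greedy descent started from an exact lattice accepts nothing even when the
structure is collectively unstable. Stability tests therefore start from
the optimized crystal plus an infinitesimal Gaussian jitter (σ_pos =
0.005a, σ_angle = 2°) that seeds the instability the way thermal noise
would. With it, the optimized in-plane cholesteric AAA crystal (ϕ = 90°,
Θ₁ = 60°) at ρ\* = 10, κ\* = 20 relaxes under pure descent to the
heliconical phase: mean tilt ≈ 75°, twist 120° per layer, box distorted
self-consistently (l_z grows ~27%) — while a crystal sitting at a true
minimum stays put (tested).

The desk-scale stability run uses 288 rods (6 layers of 4×6 two-rod cells,
commensurate with both the 60° start and the 120° end twist), M = 7,
n_trunc = 6 and ~1.5×10³ MC steps with an energy-plateau early stop;
the tilt is converged to well within a degree of its value by then. Because
the box height (≈1.7a) is below the interaction cutoff (≈2a), the explicit
image sums — rather than a larger box — keep the periodic energetics exact
at this size.

## Observables

Q = (3⟨v⊗v⟩ − I)/2 (Maier–Saupe normalization, fixed by S = 1 for perfect
alignment); S is the largest eigenvalue, the biaxiality B the difference of
the two subsequent ones. g(r) is the standard center-of-mass radial
distribution with minimum-image distances, bin width 0.02a, normalized by
ideal-gas shell counts. The mean tilt folds head–tail symmetry onto
[0°, 90°]. The per-layer twist is measured by fitting ideal heliconical
axis fields over (Θ₁, ψ₀) to the per-layer directors (principal Q axes of
z-slabs, with the slab origin placed at the widest periodic gap): azimuth
steps alone cannot distinguish a 60° cholesteric from a 120° heliconical
twist, whose orientation vectors alternate the sign of v_z between layers;
the 3-D axis fit can. Mirror chiralities are folded together (the rods are
achiral, both handednesses are degenerate and occur depending on the seed).

## Suspension mapping

Under the assumption that only the rods' own dissociated monovalent
counterions screen, κ² = 4π l_B c with counterion density c = ξρ\*/a²
(ξ = Z/a the line valency density), giving the evaporation curve
κ\* = √(4π l_B ξ ρ\*); with proton counterions pH = −log₁₀ of the molarity
(nm⁻³ → mol/L via Avogadro's number and 10⁻²⁴ L/nm³). The worked reference
point ξ = 2 nm⁻¹, a = 150 nm, ρ\* = 17 gives 2.5 mM and pH 2.6. Effective
aspect ratios use a′ = a + 2κ⁻¹, d′ = d + 2κ⁻¹. Line valencies from
material data are computed by the direct arithmetic (charges per lateral
surface area × area, or mol per gram × rod mass), assuming full ionization
— charge regulation and Manning condensation are outside the model's scope.
The coupling parameter Λ = Z²l_B/ℓ is reported for all three natural length
choices ℓ ∈ {κ⁻¹, mean spacing aρ\*^(−1/3), a} side by side; all scale as
ξ²a at fixed (ρ\*, κ\*). Barrier heights from the tilt scans convert to the
line charge at which the barrier equals k_BT via Z²(l_B/a)Δũ = 1.

## What the synthetic conditions do and do not show

All inputs are generated internally (ideal lattices, heliconical fields,
seeded MC); there is no external data. The model omits excluded volume,
polydispersity, charge regulation and hydrodynamics, so passing tests
establish the behavior of the idealized electrostatic model — ground-state
identities, metastability of the heliconical phase, evaporation arithmetic
— not quantitative predictions for any real suspension. Finite-temperature
melting and the nematic-onset scans along evaporation curves are supported
by the same machinery but are only exercised at reduced size and duration
in the tests (a 36-rod melt/quench showing energy rise, orientational
disorder and glassy arrest); full-size versions are a matter of runtime,
not code.

## Numerical choices

* sinh(x)/x evaluated by series below |x| = 10⁻⁴.
* Energy kernels are numba-compiled; the brute-force oracles in the tests
  are plain numpy/Python and share no code with them.
* Scan problem sizes in the tests and the acceptance script (κ\* = 50/20
  for lattice scans, M = 7 with coarse grids for the 16-point ground-state
  sweep, the 288-rod relaxation) are chosen so the whole suite completes in
  minutes on one CPU; all are overridable.
* Reproducibility: a single integer seed determines every random draw
  (numpy PCG64); identical seed and config give bit-identical traces.
* Degenerate inputs: zero separations, non-unit orientations, incommensurate
  supercells, non-positive physical parameters and malformed config files
  raise immediately with explicit messages rather than propagating NaNs.
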