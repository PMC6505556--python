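# Methods

## Physical model

The haltere is idealised as a slender elastic cantilever stalk of length
x_d = 5000 μm carrying a rigid end bulb, clamped to a base plate that is
flapped and yawed. The stalk is uniform with cuticle-like properties
(E = 1.5 GPa, ρ = 1200 kg m⁻³, ν = 0.33, G = E/2(1+ν)). Two cross-section
designs are built in:

- **CS** — hollow circular tube, outer radius 150 μm, inner 50 μm.
  I = π(r_o⁴−r_i⁴)/4 ≈ 3.93×10⁸ μm⁴, J = 2I (closed circular section).
- **PS** — plus-shaped open section of two orthogonal 481 × 40.8 μm
  rectangles (aspect ratio ≈ 12). I = (t h³ + h t³ − t⁴)/12 ≈ 3.81×10⁸ μm⁴
  (the central t×t overlap counted once), and the Saint-Venant torsion
  constant from the thin-open-section result per rectangle,
  J = 2 k(h/t) h t³ with k(ar) = (1/3)(1 − 0.63/ar + 0.052/ar⁵)
  ≈ 2.06×10⁷ μm⁴.

The two designs have bending stiffness within 3% of each other but a
torsion-constant ratio J_CS/J_PS ≈ 38.1. A converged Prandtl
stress-function (membrane-analogy) solve of the full cruciform gives
J ≈ 2.16×10⁷ μm⁴: the design formula underestimates by ≈5% because it
neglects the stiffening of the central junction. The formula is kept as
the implementation — it is the standard open-section design result and the
basis of the ≈38 stiffness contrast — and the stress-function solution
serves as the independent oracle in the tests, with the junction neglect
bounded there. `match_second_moment` exposes the inverse design problem
(find h at fixed aspect ratio for a target I); matching I of the tube
exactly gives h ≈ 487 μm rather than the nominal 481 μm, and all
simulations use the nominal 481 × 40.8 dimensions.

Bulbs are solid ellipsoids of density ρ with the centre of mass x_d from
the base: a 500 μm sphere, and prolate spheroids of equal volume with
semi-major axis 1000 μm and semi-minor axes √(500³/1000) ≈ 353.6 μm,
oriented with the major axis either in the stroke plane ("vertical") or
lateral ("horizontal"). "major axis length 1000 μm" is read as the
semi-axis, the only reading that conserves the sphere's volume together
with the ≈353 μm minor axes. Asymmetric variants offset the bulb COM by
150 μm along y′ or z′. The bulb is rigid: it enters the model as a 6×6
rigid-body mass at the distal node, with the exact translation–rotation
coupling produced by the COM offset (no penalty springs).

## Kinematics and inertial loading

The stroke angle about the plate's Y axis is φ(t) = A_f sin(2π f_φ t) with
A_f = π/2 rad and f_φ = 40 Hz; the body yaws about global Z at θ̇ = Ω
(0 or 10 rad s⁻¹). Both motions are ramped from rest by a C² quintic
smoothstep over 2 flapping periods (a sigmoidal ramp of unspecified
duration is part of the nominal protocol; two periods is this package's
choice). In the haltere-fixed frame (x′ spanwise,
y′ lateral, z′ dorsal) the frame angular velocity is
ω = (−θ̇ sin φ, φ̇, θ̇ cos φ), and a material point fixed at r carries the
inertial load −m(ω̇×r + ω×(ω×r)). The decomposition is the classical one:

- Euler term ω̇×r at f_φ drives the large in-plane bending;
- the θ̇–φ̇ cross terms (the Coriolis-type load, 2Ωφ̇ sinφ·x in y′) act
  out of plane at 2f_φ, linear and odd in Ω;
- the φ̇² centrifugal term tensions the stalk (DC + 2f_φ), and for offset
  bulb COMs produces bending moments independent of Ω.

Deflections are small (≤0.01 rad), so loads are evaluated on the
undeformed configuration; the Coriolis coupling of *elastic* velocities
with the frame rotation, spin softening and stress stiffening are
second-order here (each ≲1% of the linear response) and neglected.
Gravity and aerodynamic forces are not modelled.

## Finite-element discretisation and time integration

The stalk is meshed with 31 (by default) two-node 3D Euler–Bernoulli beam
elements — 12 DOF each: linear axial EA and torsion GJ, cubic Hermite
bending EI in both planes — with consistent mass (the 420-coefficient
matrices; distributed bending rotary inertia is neglected, torsional
rotary inertia ρI_p is kept). Euler–Bernoulli rather than Timoshenko is
justified by slenderness (L/d ≈ 17; shear correction < 1%). Distributed
inertial loads, linear in x within each element, are integrated with the
shape functions (consistent nodal loads). The base node is clamped;
damping is Rayleigh, C = α_k K + α_m M with α_k = 1×10⁻⁵ s, α_m = 0.

Time integration is average-acceleration Newmark (γ = ½, β = ¼),
unconditionally stable and free of algorithmic damping, with dt = 10⁻⁵ s
(250 steps per flapping period) so that millisecond-scale spike-timing
shifts are resolved; sub-sample spike times come from local quadratic
interpolation. Runs last 10.5 flapping periods (0.2625 s, 26 251 steps);
amplitudes, spectra and spikes are measured over the last five *full*
periods, [0.125, 0.25] s, leaving half a period of margin at the end of
the run so that probability peaks at the window edge remain detectable.
The first in-plane bending mode of the CS model is ≈704 Hz (tube) —
an order of magnitude above the 80 Hz Coriolis line, so the response is
quasi-static-dominated.

Deformation angles follow the bulb: Δφ = arctan(δ_z/x_d) (in-plane),
Δθ = arctan(δ_y/x_d) (out-of-plane) from the bulb-COM deflection, and the
twist Δγ = arctan(Δδ_z/y_d) from two rigid-bulb points at ± the bulb y′
semi-axis (arctan of a deflection ratio, identical to the ratio itself at
these amplitudes). Spanwise surface
strain at circumferential angle α (0 = dorsal, π/2 = lateral) is recovered
from the element shape functions as ε_xx = u′ − c cos α·w″ − c sin α·v″ at
x_s = 300 μm from the base, the location of the campaniform fields.

## Neural encoding

Each sensillum is a linear–nonlinear cascade: the strain history is
correlated with a unit-norm spike-triggered average (STA), the projection
is mapped by a sigmoidal nonlinear decision function (NLD)
P = P_max/(1 + exp(−(ξ−ξ₀)/k)) with ξ₀ = 0.5, k = 0.08, P_max = 1, and a
spike is placed at each local maximum of P exceeding 0.9.

The measured cranefly filters exist only as normalised curves, so the
package generates stand-ins: a Gabor STA
g(τ) = exp(−(τ−τ₀)²/2σ²)·sin(2π f_STA (τ−τ₀) + π/2) on a 50 ms window
with τ₀ = 10 ms, σ = 4 ms, f_STA = f_φ = 40 Hz. Two properties of this
stand-in are deliberate:

- **Bandwidth.** σ = 4 ms keeps the filter broad enough to pass both f_φ
  and 2f_φ; the 2f_φ line is the entire rotation signature.
- **Linear phase.** The cosine carrier (phase π/2 at the envelope peak)
  makes the filter's transfer phase a pure delay. A sine carrier adds a
  constant −π/2 phase that rotates the 2f component into quadrature at the
  f-peak and nulls the rotation-induced timing shift — contradicting the
  measured encoder, whose defining demonstrated property is exactly that
  it exposes those shifts.

The projection is referenced to a fixed strain scale σ₀ rather than
re-normalised per recording: ξ(t) = tanh(STA·w(t)/(√n σ₀)) with the
steady-state mean removed from the window w(t) and σ₀ = 5×10⁻⁶ strain.
σ₀ stands in for the absolute displacement-to-strain calibration of the
electrophysiology and is set between the centrifugal tension-pulsation
scale (≈3×10⁻⁶ at the 300 μm site) and the Coriolis bending scale
(≈2×10⁻⁵): pure tension stays subthreshold while Coriolis-scale strains
can fire. The tanh keeps ξ ∈ (−1, 1), reproduces the matched-filter limits
(window ∝ STA → 1, orthogonal → 0, sign-flipped → −1), and, being
monotone, leaves spike *times* invariant under any rescaling of the strain
— amplitude only gates whether a peak crosses threshold, which is the
mechanism that silences the lateral sites in the absence of rotation.
A per-window cosine normalisation cannot produce that behaviour: the
lateral waveforms with and without rotation are both nearly pure 2f_φ
sinusoids and differ only in amplitude.

Where the strain is far above σ₀, tanh saturates to 1.0 in double
precision and the probability peak becomes a flat run; spikes are then
located at the maximum of the raw (pre-saturation) projection inside the
run — the exact-arithmetic peak position — with plateau midpoints as the
fallback when no raw trace accompanies the probability. Timing statistics
pair each rotation-condition spike with the nearest flapping-condition
spike within half a period and report the mean signed difference
(positive = rotation lags); sites silent without rotation are flagged
rotation-only. The pairing rule is this package's construction.

## Synthetic strain generator

The generator emulates the structure of the simulated base strain:
s(t) = offset + A sin(2πf_φt) + r·A_ref sin(4πf_φt + ψ) + seeded Gaussian
noise, with defaults A = 4.5×10⁻⁴ (the dorsal-fibre strain amplitude of
the base simulation at the 300 μm site), r = 1/25 (mirroring the
in-plane/out-of-plane ratio), zero noise. It reproduces the features the
encoding stage depends on — tone ratios, the 2f phase, the tensile offset,
overall scale — but none of the transients, mesh-level spatial structure
or measurement noise of real strain data, so tests built on it validate
the encoding cascade, not the structural model; the structural model is
tested against closed-form and oracle solutions instead. All stochastic
generation routes through one seeded RNG and is bit-reproducible.

## Numerical and design choices

- Quantities are μm in configuration, SI internally (conditioning).
- Static solves use a symmetric dense factorisation after clamping;
  assembly fails fast if the constrained stiffness is singular.
- The Newmark loop reports the first non-finite step as a divergence
  error.
- FFT-based dominant frequencies are computed on the mean-removed window;
  with a 5-period window the 40 and 80 Hz lines fall on bins.
- Scenario runs are deterministic; re-running byte-reproduces summaries.
- Mesh convergence: first bending frequency and p2p in-plane amplitude
  change by <1% and <2% from 31 to 62 elements.

## Known limitations

- The stalk spans the full base-to-bulb-COM distance; the bulb is
  attached at the distal node without an axial rigid link, so the stalk
  is ~10% longer than a stalk ending at the bulb surface would be.
- Warping/restrained-warping stiffness of the open section is neglected
  (Saint-Venant torsion only), as are the groove of real stalks, damping-
  induced instability phenomena, geometric nonlinearity, and rotations
  about more than one body axis.
- The in-plane p2p (flapping) to out-of-plane p2p (10 rad s⁻¹) ratio
  computes to ≈19.2. For any linear quasi-static model of these kinematics
  both responses share the same spatial load shape, so the ratio reduces
  to the load-amplitude ratio 2πf_φ/(2Ω·max_u[cos u · sin(A_f sin u)])
  ≈ 19.3 — a closed-form consequence of the prescribed motion itself.
- STA/NLD parameters are stand-ins; downstream timing predictions are
  therefore validated as ranges (0.2–1 ms), not point values.
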