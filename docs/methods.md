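# Methods

## Model

A conical cavity (half-opening angle ε measured from the axis, mouth radius
s_c, depth s_c/tan ε) is overlain by a liquid of surface tension σ, density
ρ and pressure p_l, with contact angle θ on the solid, and holds a trapped
amount of ideal gas characterised by the isothermal invariant nRT (J).

Because p_l and p_g are uniform, the gas/liquid interface has constant mean
curvature and, with the rotational symmetry of the cone, is a spherical
cap. The contact line is assumed to sit on the cone wall (0 < s ≤ s_c);
rim-pinned states are outside the model. With Δ = θ − ε:

- curvature `H = cos Δ / s` (convex H > 0, concave H < 0, flat at Δ = 90°),
- volume `V = (π/3) s³ (cot ε + (1 − sin Δ)²(2 + sin Δ)/cos³ Δ) = C(θ,ε) s³`,
- areas `A_lg = 2π s²/(1 + sin Δ)`, `A_sg = π s²/sin ε`.

**Equilibrium.** Substituting into `p_g V = nRT` with
`p_g = p_l + 2σH` gives the cubic
`p_l C s³ + 2σ cosΔ C s² − nRT = 0`. Its coefficient signs allow exactly
one positive root when p_l > 0 (Descartes), and zero, one or two under
tension. Roots come from companion-matrix eigenvalues (`numpy.roots`) —
robust near the flat-interface degeneracy where the quadratic coefficient
vanishes — and are polished by Newton steps; roots with
|Im| > 1e-9·|root| are discarded as complex. Every returned pocket must
satisfy `p_g V = nRT` to 1e-9 relative and the Young–Laplace balance to
1e-6 relative, or the solver raises. Roots with s > s_c are reported as
overfilled, never clamped; under positive liquid pressure the physical
pick among tension roots is deferred to the stability classification.

**Stability.** `Ψ = p_g/V + 2σ dH/dV` at the equilibrium; Ψ > 0 restoring.
In the cone both H and V are single-variable functions of s, so
`dH/dV = (dH/ds)/(dV/ds) = −cosΔ/(3C s⁴)` by the chain rule; a central
finite difference with relative step 1e-6 in s cross-checks it to 1e-4
relative inside `stability_psi` itself. Gravity is handled only through
the capillary bound `s_c ≤ l_c = sqrt(σ/(ρg))`; the mouth radius, the
largest in-plane dimension of the cap, is the compared length.

**Energetics.** `ΔE = σ(−2HV + A_lg + A_sg cos θ)` is the energy of the
pocket state relative to the fully wetted cavity (volume-displacement,
liquid/gas-interface and solid-wall terms). σ s² factors out, so the sign —
and hence the verdict — is independent of s; it reduces algebraically to
`θ > ε + 90°`. The reported flag uses that closed form rather than the
floating-point sign of ΔE, because on the boundary line ΔE is a ~1e-16
rounding residual of arbitrary sign; off the line the two agree and the
tests assert it.

**Energy landscape (independent oracle).** The total energy
`E(s) = σA_lg + σ cosθ A_sg + p_l V − nRT ln(V/V_ref)` assembles the
surface terms, the displacement work against the liquid, and the
isothermal free energy of the gas; V_ref (the bare cone volume) only fixes
an additive gauge constant. Its stationary points coincide with the
cubic's roots and its minima with Ψ > 0; the test-suite verifies both by
grid search, which provides a route to the equilibrium entirely
independent of the root-finder.

## Parameters and defaults

| quantity | default | note |
|---|---|---|
| σ (liquid iron) | 1.6 N/m | material preset |
| ρ (liquid iron) | 7000 kg/m³ | material preset |
| θ iron/copper | 37° | preset `iron-copper` |
| θ iron/corundum | 130° | preset `iron-corundum` |
| g | 9.81 m/s² | overridable |
| σ, ρ (water) | 0.0728 N/m, 998 kg/m³ | xylem-side constants at 20 °C (293.15 K); handbook values, not tuyère constants. The water/pit-wall contact angle is a required user input. |
| gas content | nRT directly, or fill spec | `nRT = p_fill · fraction · V_cone`: a recess charging with ambient air before immersion |

Internally everything is SI with radians; the CLI takes degrees and length
suffixes (mm, µm, …). ε is restricted to [1e-6, π/2 − 1e-6] rad so cot ε
and 1/sin ε stay finite. The removable 0/0 of the volume's cap term at
|Δ| = 90° is evaluated by its analytic limit (the term vanishes linearly in
the offset) whenever |cos Δ| < 1e-8.

## Design scans

`design_scan` maps admissibility, ΔE and Ψ over a (θ, ε) grid. ΔE needs
only a reference radius (the sign is s-independent; asserted in tests).
The Ψ map needs a gas content per cell: the package charges the reference
cone with ambient-pressure gas (p_fill = p_l) over 80 % of its volume — a
full charge under a concave equilibrium cap would expand just past the
mouth and be reported overfilled, leaving the interesting cells blank.
Cells without an in-cavity equilibrium carry Ψ = NaN and `exists = False`.

## Scenario generator

`fixture_suite(seed)` drives the property-based tests. It emulates the two
study conditions: liquid iron at 0.2–2 bar over millimetre cones
(σ = 1.6 N/m, ρ = 7000 kg/m³, θ spanning both sides of the θ = ε + 90°
line), and water under xylem-range tension (p_l from −2 MPa to −10 kPa)
over micrometre pit-chamber cones. Three fixed anchors guarantee one
scenario in each interface state: cavity flooded (no root), interface
present but energetically unfavourable, and favourable. What it does not
emulate: contact-angle hysteresis, gas dissolution into the liquid,
non-isothermal behaviour, interface dynamics, and non-conical cavity
shapes — passing tests say nothing about those effects in real systems.

## Problem sizes

The model is closed-form, so the suite runs in seconds at full size: the
criterion-line scan uses a 200×200 (θ, ε) grid; uniqueness and stability
are checked on 1000 random positive-pressure systems each; the energy
landscape is cross-checked on 50 systems (40 positive-pressure with
4000-point grids, 10 tension systems with 8000-point grids); the volume
formula is compared with scipy quadrature on a 100-triple (s, θ, ε) grid
at 1e-6 relative tolerance.

## Known limitations

- Only wall-attached spherical caps in perfect cones; pinned contact
  lines, re-entrant or non-axisymmetric profiles are out of scope.
- The gas is conserved and isothermal: no dissolution, diffusion through
  pit membranes, or thermal expansion, although the tuyère application is
  strongly non-isothermal in reality.
- The pit→cone mapping discards the pit channel; whether the channel
  volume contributes trapped gas during refilling is left open, so the
  channel radius only enters validation, not the physics.
- Gravity enters solely through the capillary-length bound; the cap shape
  itself is computed gravity-free.
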