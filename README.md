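# conepocket

Analytic modelling of gas pockets trapped in cone-shaped surface cavities.

A rotationally symmetric recess — an "ice-cream cone" milled into a flat
plate, the idealised shape of a xylem pit chamber — can hold a persistent
air pocket when a liquid flows over it. Whether it does depends on three
questions this package answers in closed form:

1. **Existence.** The gas/liquid interface is a spherical cap obeying the
   Young–Laplace balance `p_g = p_l + 2σH`, with the trapped gas isothermal
   and ideal (`p_g V = nRT`). In a cone of half-angle ε (measured from the
   axis) both the mean curvature `H = cos(θ−ε)/s` and the gas volume
   `V = C(θ,ε)·s³` are functions of the contact-circle radius `s` alone, so
   the two conditions combine into a cubic

   `p_l·C·s³ + 2σ·cos(θ−ε)·C·s² − nRT = 0`,

   which has exactly one positive root for `p_l > 0` and zero to two under
   tension (`p_l < 0`, the xylem regime).
2. **Stability.** An equilibrium is mechanically stable iff
   `Ψ = p_g/V + 2σ·dH/dV > 0` there. For cone cavities under positive
   liquid pressure Ψ is positive for every equilibrium, whatever the sign
   of `H`; under tension, stable and unstable branches coexist.
3. **Energetics.** Keeping the pocket rather than flooding the cavity costs
   `ΔE = σ(−2HV + A_lg + A_sg·cosθ)`, which is negative — air pocket
   favourable — exactly when `θ > ε + 90°`. For a given contact angle θ the
   admissible cone half-angles are `0 < ε < θ − 90°`. A capillary-length
   bound `s_c ≤ l_c = sqrt(σ/ρg)` keeps gravity from distorting the cap.

Two application scenarios are built in: **ferrophobic tuyère surfaces**
(liquid iron, σ = 1.6 N/m, ρ = 7000 kg/m³; θ ≈ 37° on bare copper,
θ ≈ 130° on a corundum coating — so cones with ε < 40° retain their air
pockets and insulate the pipe) and **xylem pit chambers** (water under
tension, where a stable air pocket can isolate a refilling conduit from its
embolised neighbour).

## Worked example

The tested prototype geometry — cone mouth radius 2.5 mm, ε = 30°, on a
corundum coating (θ = 130°):

```sh
conepocket energy --theta 130 --epsilon 30 --preset iron-corundum
```

```json
{
  "admissible_epsilon_max_deg": 40.00000000000001,
  "contact_radius_m": 0.001,
  "criterion_theta_gt_epsilon_plus_90deg": true,
  "delta_E_J": -4.65661026466192e-07,
  "delta_E_V_J": 9.313220529323846e-07,
  "delta_E_lg_J": 5.065022784312705e-06,
  "delta_E_sg_J": -6.462005863711282e-06,
  "ferrophobic": true
}
```

`delta_E_J < 0`: displacing the iron and keeping the air pocket is the
energetically favourable state (`ferrophobic: true`), and 30° lies inside
the admissible interval (0°, 40°). Charging that cone with ambient air over
60 % of its volume and immersing it at 1 bar:

```sh
conepocket stability --preset iron-corundum --epsilon 30 --sc 2.5mm \
    --pl 1e5 --fill-pressure 1e5 --fill-fraction 0.6
```

```json
{
  "equilibria": [
    {
      "capillary_length_m": 0.004826990761706644,
      "contact_radius_m": 0.0021666995350320896,
      "curvature_per_m": -80.14409698221435,
      "gas_pressure_Pa": 99743.53888965692,
      "psi_Pa_per_m3": 5855730551698.476,
      "stable": true,
      "within_capillary_bound": true,
      "...": "..."
    }
  ],
  "exists": true
}
```

The interface settles at s ≈ 2.17 mm with a slightly concave cap
(H ≈ −80 m⁻¹, so the gas sits just below ambient pressure), is
mechanically stable (Ψ > 0), and the 2.5 mm mouth radius stays within the
4.83 mm capillary length of liquid iron.

Other subcommands: `equilibrium` (root of the cubic), `scan`
(CSV map of ΔE, Ψ and admissibility over a θ×ε grid), `prototype` (the
three design checks on a concrete cone), `pit` (xylem-pit scenario, also
under negative pressure). The same model is available as a library:

```python
import math, conepocket as cp
iron = cp.MATERIALS["iron-corundum"].system(p_l=1e5)
print(cp.capillary_length(iron))            # 0.004826990761706644
print(cp.admissible_cone_angles(iron.theta))  # (0, 40°) in radians
```

## Layout

- `src/conepocket/geometry.py` — spherical-cap geometry in a cone; pit→cone mapping
- `src/conepocket/equilibrium.py` — the cubic, its roots, Young–Laplace contracts
- `src/conepocket/stability.py` — Ψ criterion, capillary length, formation energy, energy landscape
- `src/conepocket/scenarios.py` — material presets, design scans, prototype and xylem reports
- `src/conepocket/cli.py` — the `conepocket` command
- `docs/methods.md` — model assumptions, parameter choices, numerics, limitations
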