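# Methods

This note records the model assumptions, the parameter choices that
matter, the numerical decisions, and what the packaged presets do and
do not establish.

## Physical model

A projectile impacts the liquid column at the inlet of a rectangular
channel. The loading chain is:

1. **Impedance-matched source.** The impact interface obeys 1D
   pressure–velocity matching: Δp = Z_f Z_p/(Z_f+Z_p)·u_p with
   Z = ρc. The buffer plate customarily placed between projectile and
   liquid is assumed impedance-matched to the projectile and is not
   modelled. As the projectile decelerates (Newton's law with the
   linearized isentropic slope (∂p/∂c)_s of the liquid evaluated at
   normal conditions), the interface pressure decays exponentially:
   p(t) = p(0)e^(−λt), λ = ((γ−1)/2)(A_p/m_p)(∂p/∂c)_s. Amplitude is
   controlled by impact velocity, duration by projectile length — the
   two knobs are independent.
2. **Weak compression front.** The pulse (a few MPa) is ~10⁻³ of the
   bulk modulus, so the front is a *weak* shock: heating is negligible
   and the jump is treated as isentropic. Rankine–Hugoniot front speed
   and particle velocity follow from the isentrope; at 3 MPa the
   front-speed excess over c₀ is ~0.4%.
3. **Conduit propagation.** Rigid-wall 1D water-hammer equations at
   the conduit celerity c_f, solved by the method of characteristics
   (MOC). Wall compliance enters only through c_f (equivalently the
   corrected bulk modulus K_mod = ρ₀c_f²).
4. **Wall stresses.** Cells on the wall feel the total pressure of the
   passing front (compression) plus the axial shear of the boundary
   layer that grows behind it, estimated by the impulsively-started
   laminar (Stokes/Mirels-type) wall gradient driven by the local core
   velocity. Transverse shear is identically zero in a 1D model, in
   line with its observed negligibility in this geometry.

## Constants and internal consistency

Water: ρ₀ = 999.8 kg/m³, c₀ = 1439 m/s, μ = 1.0×10⁻³ Pa·s,
p₀ = 101325 Pa, Tait B = 3.35×10⁸ Pa, γ = 7.15. These handbook
constants are mutually inconsistent at the ~7% level: √(γB/ρ₀) ≈
1548 m/s ≠ c₀. The package treats (ρ₀, c₀, γ, B) as independent givens:

* the literal-B Tait curve serves the direct p↔ρ conversions;
* everything governing wave dynamics (local sound speed, jump
  conditions, particle velocity, celerity) uses a c₀-anchored isentrope
  ρ₀(1 + γp/K)^(1/γ) with K = ρ₀c₀², so acoustic limits are exact;
* the pulse decay slope (∂p/∂c)_s = (2γ/(γ−1))(p₀+B)/c₀ ≈
  5.415×10⁵ Pa·s/m keeps the literal B. This slope is ~16% above ρ₀c₀;
  the amplitude (impedance match at ρ₀c_f) and the decay (Tait slope)
  are therefore closed with slightly different stiffnesses, which is
  the standard formulation of this source model and changes the pulse
  shape only through λ.

Pressure datum: equation-of-state operations use the Tait datum (p = 0
at ρ₀); the solver carries the ambient offset p₀ explicitly and all
reported fields are *total* pressure.

## Tunable parameters

| parameter | default | why |
|---|---|---|
| channel a×b×l | 3×3×60 mm | representative chip; Kn = 10⁻⁷ ≪ 10⁻³ keeps the continuum description valid |
| wall material, thickness | borosilicate glass, 3 mm | a stiff chip wall: c_f within ~3% of c₀ and β ≈ 0.03 ≪ 1, justifying the rigid-wall solver |
| projectile | PMMA, 1 cm, bore-matched | gives λ ≈ 1.41×10⁵ s⁻¹ (7 µs pulse) |
| impact velocity u_p | 3.0 m/s | produces the ~3 MPa design amplitude; explicit and overridable |
| grid | Δz = 0.1 mm, Courant target 1 | interpolation-free MOC; Δt = Δz/c_f ≈ 72 ns, 585 steps over the 42 µs window |
| friction | quasi-steady laminar | Poiseuille number 56.91 for the square duct; attenuation ~0.002%/15 mm, far under the ~1%/15 mm design envelope |
| t_reg | one solver step | regularizes the t^(−1/2) shear divergence at front arrival; the quoted shear peak depends on it, so the full τ_z(t) trace is the primary output and t_reg is always reported |
| mean free path | 3×10⁻¹⁰ m | molecular scale of liquid water, for the Knudsen check |
| rigidity threshold | β < 0.1 | quantifies "β ≪ 1"; the raw β is always reported so the flag is auditable |

The shot-62 validation preset (0.67 kg steel projectile, 18.5 m/s,
38.1 mm bore, 12.74 mm wall, closed end) reflects a published
instrumented experiment. Its tube material and length are not
published: the preset assumes a near-rigid wall (celerity correction
off) and a 0.9 m tube, states both assumptions in its report, and
compares only the impacted-end peak, which is insensitive to length.
The square-section model of the round bore affects only the friction
closure and the (disabled) celerity correction.

## Numerical choices

* **MOC on a fixed grid.** At Courant 1 the scheme propagates the
  d'Alembert solution exactly (verified to machine precision); at
  Courant < 1 characteristic feet are linearly interpolated, which is
  slightly diffusive — production runs use a Courant-1 grid. Courant
  > 1 is refused, not clipped.
* **Inlet corner.** The fluid starts quiescent; the single corner
  sample (z=0, t=0) takes the boundary-consistent velocity
  p(0)/(ρc_f), because the impact sets the interface velocity
  instantaneously. Without this the launched front carries a one-step
  startup error.
* **Boundary conditions.** Inlet pressure prescribed by the pulse;
  outlet either reservoir (p = p₀, reflection −1) or dead end (u = 0,
  reflection +1, pressure doubling) — both verified against the
  characteristic algebra.
* **Celerity held constant.** The weak-shock front-speed correction
  (~0.4% at 3 MPa) is computed and reported but not fed back into
  propagation; it is below the discretization error at these scales.
* **Unsteady friction.** A Zielke-type convolution closure is
  available behind a flag; at these pulse durations and viscosities it
  adds little over the quasi-steady term and is not the default.
* **Rectangular-duct compliance factor.** The thick-walled
  rectangular-duct distensibility is derived from closed-frame
  mechanics (wall bending with the classic corner moment
  w(a³+b³)/(12(a+b)), Timoshenko shear with κ = 5/6, membrane
  stretch), grouped as Φ(a,b)/(abEe³). It is validated by its limits —
  rigid walls recover c₀ exactly, celerity increases monotonically
  with E and e, and Φ is symmetric in a↔b — rather than against any
  single published coefficient set, of which several circulate.

## What the presets do and do not show

The representative preset exercises the full chain under clean
conditions: a single impact, Newtonian water, hydraulically smooth
walls, no cavitation, no temperature effects. Passing tests establish
internal consistency of the model chain and agreement with the analytic
limits, plus one external check (the shot-62 peak, predicted within
~3% of the published computation). They do **not** establish:

* the true shear on a wall carpeted with cells — cells are below model
  resolution and are treated as wall roughness at most;
* turbulent boundary-layer shear: the laminar Stokes estimate brackets
  (0.1–10 kPa here) but does not reproduce a turbulence-closure
  computation; its peak depends on the regularization time;
* transverse (cross-channel) shear structure and edge stress
  concentration — genuinely 3D effects outside a 1D model, set to zero
  here consistent with their observed smallness away from the edges;
* repeated impacts, cavitation or column separation (rarefactions are
  rejected by the jump module on purpose).

## Degenerate inputs and error behaviour

Non-positive densities/pressures outside the EOS domain, rarefaction
fronts, a ≥ b violations, zero projectile mass, Courant > 1 and
non-positive regularization times raise `ValueError` rather than
returning garbage. Design-criteria failures make `run_simulation`
refuse unless forced; every report echoes its full configuration so
each number can be re-derived.
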