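# Methods

## Model

The cell is a growing cylinder of outer radius `r(t)` (an experimentally
controlled input), length `L`, volume `v = π r² L` and wall thickness `h`.
Fourteen coupled ODE states are integrated: `v, P, L, η, h, [Ca²⁺]ᵢ, [H⁺]ᵢ,
[K⁺]ᵢ, [Cl⁻]ᵢ, V_m`, the two stretch-channel open fractions, the slow
activation gate of the outward K⁺ rectifier, and the non-ionic osmolyte
pool `[Osm]ᵢ`.

**Water side.** `dv/dt = Lp·A_osm·((π_i − π_o) − P)` with `π = RT Σc`
(all solutes ideal, reflection coefficient 1, no transpiration). `A_osm`
is a *fixed* apical osmotic-zone area — this is what prevents exponential
growth; if it scaled with `v` the tube would grow exponentially (covered by
a test).

**Wall side.** Plastic yielding is restricted to an extensible tip volume
`v_ext`: `(1/v)dv/dt|wall = (v_ext/v)·φ·max(P−P_c, 0) + (1/ε)·dP/dt`, with
`φ = 1/η`. Equality of the two relative volume rates defines the turgor
ODE `dP/dt = ε·(water − plastic)`; only the water side is integrated and
the chamber side is recovered from the identity (tested to hold exactly),
avoiding a differential-algebraic system. Plastic flow below `P_c` is
clamped to zero.

**Wall material.** `dη/dt = −η·R_s/h + k₁(η_eq − η)`: fresh secreted
material softens the wall, maturation restores it toward the equilibrium
viscosity. The first term is read as `η·R_s/h` — the only dimensionally
consistent reading of the softening term. `R_s = k₂[Ca²⁺]ᵢ`, `k₂ = k₂ₐ/r²`
taken literally (note the source prints both `k₂ₐ = 2.15e−14 m³/(M s)` and
`k₂ = 4.1e−4 m/(M s)` at `r = 5 µm`, which differ by ~2×; we implement the
literal quotient 8.6e−4 and treat `k₂ₐ` as calibratable).
`dh/dt = −3(r²−rᵢ²)/(2r²)·dL/dt + R_s` with `rᵢ = r − h`; the thickness is
floored at 1 nm inside the RHS (with a warning) so degenerate inputs do not
divide by zero.

**Ion side.** Each cellular ion obeys
`d[X]/dt = −OV·ΣI/(zF) − k_X([X]−[X]_s) − ((1/v)dv/dt)[X] (+ buffering)`,
with `OV = 2/r` the transporter surface-to-volume ratio. Only the product
`OV × conductance` matters, which the tests assert as a scaling invariance.
Currents: two K⁺ channels, one Ca²⁺ channel and one Cl⁻ channel as
configurable ohmic/GHK kernels with two-state Boltzmann voltage gating, a
saturating H⁺-ATPase efflux, and a Cl⁻/2H⁺ symporter (ohmic with reversal
`2E_H − E_Cl`; the H⁺ pool receives twice its current). The H⁺ buffering
term is a linear relaxation with strength 500 s⁻¹ — protons are massively
buffered, so the pool merely tracks the pump/symporter balance; Ca²⁺
buffering is folded into its relaxation term (strength 0 by default).
Membrane potential obeys `C_m·dV/dt = −ΣI`. Stretch-activated Ca²⁺ and K⁺
channels are two-state gates with `k_OC` constant and
`k_CO = k_CO⁰·e^(kₐP)` (rate capped at 10³ s⁻¹: deep in saturation the
open fraction is ~1 regardless, and an uncapped exponential only makes the
ODE arbitrarily stiff). An optional stretch-activated Cl⁻ channel ships
disabled; enabling it reuses the K-gate open fraction.

## Where the oscillation comes from

Two mechanisms were considered. A loop in which tiny turgor oscillations
gate the stretch channels directly cannot work here: the data require the
turgor ripple to stay below ~0.0009 MPa while the mean turgor shifts by
~0.015 MPa between media conditions, which bounds `kₐ` so strongly that
linear analysis puts the loop gain two orders of magnitude below unity.
Instead — as in the electrophysiological models this one descends from —
the oscillator is electro-chemical: the Ca²⁺ channel activates on
depolarization (fast, regenerative) while the outward K⁺ rectifier
activates with a slow first-order gate (`τ = 60 s` on the vg2 kernel; all
other kernels remain instantaneous, `τ = 0`, which is also the default
form). `(V_m, n_vg2)` then form a relaxation oscillator; each voltage
excursion floods the tip with Ca²⁺, transiently softens the wall and
produces a growth pulse, while turgor, averaging over the cycle, barely
ripples (~2×10⁻⁴ MPa).

Turgor still controls the clock: the stretch channels contribute a
background inward current proportional to their open fraction `p(P)`, and
the oscillator sits near a saddle-node bifurcation whose distance-to-onset
this current sets. Higher mean turgor (hypotonic media) opens the gates,
raises the drive and halves the period; lower mean turgor (hypertonic
media, stiffer walls) closes them and slows the cycle toward the `p = 0`
period (~90 s); the symporter keeps the oscillator alive even with the
gates fully shut. This yields the observed period map (≈50 s at 0.36 Osm,
≈26 s at 0.18 Osm, ≈90 s at 1.16 Osm) from a single parameter set.

## The osmolyte pool

A strict reading treats `[Osm]ᵢ` as an externally fixed parameter. That
reading makes a 1.16 Osm hypertonic shift unsurvivable: `π_i − π_o − P`
drops to about −1.7 MPa, turgor collapses and no ionic mechanism can
plausibly supply the ~0.7 M rise required (it would need ~50 A/m² of
sustained uptake). Physically the non-ionic cytosolic pool is a conserved
solute: water loss concentrates it 1:1 and growth delivers it with new
cytoplasm. We therefore integrate it as a state,

    d[Osm]ᵢ/dt = rel·(S − [Osm]ᵢ)  if rel ≥ 0,   −rel·[Osm]ᵢ  otherwise,

with `rel = (1/v)dv/dt` and `S` the protocol's supply course. In any
growing steady state `[Osm]ᵢ = S` exactly, so isotonic/hypotonic behavior
is unchanged; under hypertonic stress the pool concentrates until
`π_i − π_o = P` and the system settles into a growth-arrested but still
oscillating state. The oil-injection scenario, where the experimenter
controls cellular osmolarity directly, uses the direct-control mode
(`osmolyte_dynamic = False`; the pool tracks the course with a 10 s lag).

## Parameters

Anchored values (used as-is): `Lp = 1e−6 m s⁻¹ MPa⁻¹`,
`k₂ₐ = 2.15e−14 m³/(M s)`, radii 5/5.5/3.5/6/12 µm per scenario, media
osmolarities (0.36/0.18/1.16/0.06–0.46 Osm), fusion-rate knockdown ×0.01,
media Ca²⁺ 0.13/1/1.3 mM, media pH 5.7/5.1, wall-viscosity schedules
(25/125/225 MPa s), injected osmolarity courses (0.5→0.75/1.0 M).

Everything else is a calibration output. The operating point was derived
analytically before any fitting: the published steady readouts
(volume change 3.45 µm³/s at 0.36 Osm with a 19-fold span over 0.06–0.46
Osm; turgor 0.214→0.229 MPa and extensibility 0.045→0.054 MPa⁻¹s⁻¹ across
the 0.36→0.18 Osm shift; water-side coefficients 1.030/−0.034) are mutually
consistent only if `π_i − π_o − P ≈ 0.30 MPa` at isotonic, which fixes
`Lp·A_osm`, total cellular osmolarity ≈ 0.57 M (a 0.5 M non-ionic pool
plus ion set-points — matching the injected-oil baseline), and
`P_c ≈ 0.199 MPa` with `v_ext·φ̄·(P̄−P_c)` equal to the water flux. The
absolute growth scale was then set by multiplying `A_osm` and `v_ext`
together (which leaves every ratio- and mean-based readout untouched) so
the mean elongation rate lands in the measured 4.07 ± 0.36 µm/min band;
the volume-change absolutes are correspondingly ~1.5× the published
simulated values, while their 19-fold ratio is preserved (we obtain ~15).
The electrical kernel conductances were designed by current-balance at the
operating point and tuned numerically for the period map; `calibrate()`
(seeded Latin-hypercube screening + Nelder–Mead polish) reproduces this
kind of search and is what the shipped file came out of.

Notable defaults: `ε = 1 MPa` (volumetric elastic modulus; also sets the
turgor ripple ≈ 1.7×10⁻⁴ MPa, far below the 0.005 MPa detection limit),
`kₐ = 2×10⁻⁴ Pa⁻¹`, gate rates `k_OC⁰ = 0.2 s⁻¹`, `k₁ = 0.35 s⁻¹`,
`η_eq = 25 MPa s`, ion set-points K 50.3 mM, Cl 12.1 mM, Ca 0.2 µM, pH 7.
Emergent means at isotonic: `h̄ ≈ 0.24 µm` (within the measured
0.2–0.5 µm), tip Ca²⁺ ≈ 10 µM mean with spikes to ~40 µM, `V_m` cycling
between −0.10 and −0.05 V.

## Numerics

LSODA with `rtol = 1e−8` and per-state absolute tolerances scaled to
typical magnitudes; integration restarts at every protocol breakpoint;
dense output at 0.1–0.25 s. Step protocols are 1 s linear ramps (the slow
osmolarity ramp scenario uses its genuine 1000 s ramp). Halving tolerances
moves the period by <0.5% (tested). Peak detection uses a prominence of 5%
of the series range; waveforms with alternating large/small peaks are
measured large-peak to large-peak; "exact period" averages are trapezoidal
means over one maximum-to-maximum window of the converged cycle. Regulation
coefficients use natural logs and synchronized single-period windows;
because the decompositions hold pointwise, the water-side sum is 1 to
float precision and the wall-side sum to ≲1e−12 (tolerances 1e−6/1e−3 are
asserted).

## What the scenarios do and do not establish

The scenario engine reproduces: the osmotic period map; undetectable turgor
oscillations; the post-shift turgor/extensibility means; the ~19-fold
volume-change span over the 0.06–0.46 Osm sweep; rising turgor with falling growth under wall-viscosity ramps;
faster volume growth, higher turgor and higher extensibility under
injected osmolarity; and a shorter Raba4d mutant tube. Known limitations:
(i) the hypertonic end state arrests volume growth while oscillating —
the period is right but the tube does not keep elongating; (ii) the
media-Ca²⁺ amplitude modulation is not reproduced — GHK currents scale
~linearly with external Ca²⁺, so the 10-fold media range overruns the
oscillator's drive window and the 0.13 mM baseline is quiescent; the pH
step shortens the period with roughly unchanged amplitude rather than
shrinking the amplitude; (iii) oscillations are regular single-frequency
cycles (no irregular shapes or secondary frequencies); (iv) geometry is a
cylinder with prescribed radius — no emergent tip shape.
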