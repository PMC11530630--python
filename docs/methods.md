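# Methods

## Scope and abstraction

chipflow simulates pressure-driven microfluidic channel networks at the 1D
(lumped-element) level. The abstraction is valid for laminar, fully developed,
viscous, incompressible flow, where each rectangular channel reduces to a
hydraulic resistor and the network to a linear circuit. Everything outside
that regime — inertia, compliance, elastic walls, non-rectangular
cross-sections, non-Newtonian rheology — is out of scope.

All internal quantities are SI (m, s, Pa, m³/s, Pa·s, m²/s, m³, mol/m³);
input files may declare units and the reader converts on load. The resistance,
droplet, and membrane laws are dimensionally consistent only in one system,
so a single internal system avoids silent unit drift.

## Circuit solve

The instantaneous hydraulic state is computed by Modified Nodal Analysis:
unknowns are the pressures of all non-reference nodes plus one flow per
pressure pump; equations are mass conservation per node plus one pressure
constraint per pressure pump; flow-rate pumps are fixed injections. The
ground node **and all open sinks** sit at the 0 Pa reference — sinks are open
outlets at atmospheric pressure, which is the natural reference of the
circuit analogy. Exactly one ground node is required; if only sinks are
marked, the first sink (by id) is promoted with a logged warning.

The solve is a direct dense `numpy.linalg.solve`; the networks this tool
targets are far below 10³ nodes, where robustness beats sparse machinery.
Components without a reference node make the system singular and are reported
with the offending node ids. Channel resistances are floored at 1e-30 SI to
exclude singular zero-resistance edges. The flow convention is: positive flow
runs from `node_a` to `node_b` of a channel, and from `node_from` to
`node_to` of a pump.

Channels entered with h > w are silently reoriented (w ↔ h swap) because the
rectangular-duct law is written for the wide-flat orientation and the physical
cross-section is unchanged. The law degrades near square sections; h/w is
restricted to < 1 strictly and a warning is logged above 0.9.

## Event-driven transport

Between events the flow field is constant and transport is exact plug-flow
advection: positions are kept as fractions of channel length in [0, 1]
(0 at `node_a`), so advancing by Δt is a pure shift of |Q|Δt/V. The engine's
step is the earliest of:

* a slug interface reaching a channel end (in the base module without
  composition tracking this reduces to the classic shortest-transit step
  t = V/Q),
* a droplet head reaching a channel end,
* a scheduled injection starting or stopping,
* an optional fixed output step,
* the horizon `max_time`.

Because no interface ever crosses a channel end inside a step, every
channel's outflow composition is constant within a step and node mixing is
exact — the steady state of a feed-forward network is reached *exactly* after
the transient flushes, not asymptotically.

Simultaneous events (within 1e-12 s) are processed in a deterministic order:
injections, then droplet boundary crossings by droplet id, then transit
events. The circuit is re-solved after every event; solves are memoised on
the resistance pattern so events that change no resistance cost nothing.
Flows below q_eps = 1e-18 m³/s are treated as quiescent (this is orders of
magnitude below any physical microfluidic flow and only serves to exclude
dead-end roundoff noise). A configurable event cap (default 5·10⁵) guards
against runaway schedules. Output cadence is decoupled from event clustering
via `ResultSet.sample`, which linearly interpolates pressures/flows (piecewise
constant for compositions) at arbitrary output times.

Droplet-only runs terminate early once every droplet has exited.

## Mixing

Channel contents are ordered slugs — intervals occupied by one homogeneous
mixture. Mixing at a node is instantaneous and complete: per species,
C₀ = Σ CᵢQᵢ / Σ Qᵢ over all inflows (channels and pump boundaries), and every
outflow channel receives the same mixed composition. Species are passive
scalars: they do not react, do not diffuse laterally, and do not alter the
carrier viscosity or channel resistance. The carrier viscosity comes from the
single fluid marked `continuous_phase`.

Adjacent slugs whose concentrations agree within 1e-12 relative per species
are merged, bounding slug counts over long runs. A node may not be both a
pump-fed boundary inlet and a junction of incoming channels; validation
rejects that case because the mixing rule would be ambiguous there.

## Droplets

A droplet is an atomic plug: its head position is tracked as a channel
fraction, it moves at Q/(w·h) (so a full channel crossing takes exactly V/Q),
and its resistance increment

    R_droplet = b · a(w, h) · μ_c · l_d / (w h³)

is booked to the one channel holding it. The geometric factor *a* is taken to
be the duct-law prefactor 12·[1 − (192h/π⁵w)·tanh(πw/2h)]⁻¹, so that *b*
expresses the droplet as a multiple of an equal-length continuous-phase plug;
with b = 1 and l_d = l the increment equals the channel's own resistance.
The default b is 3, the midpoint of the commonly quoted 2–5 range, overridable
per droplet. At a junction the droplet enters the outflow channel with the
highest instantaneous flow (ties break by channel id); it exits the network at
sink/ground nodes. Droplet formation, breakup, coalescence, interfacial
tension, and slip between droplet speed and mean flow are not modelled. A
droplet spanning a junction contributes its resistance to a single channel
(the one holding it); distributing it across both channels would be the main
alternative and is noted as such.

Timed injection schedules can be derived from spacing distances in the
injection channel: t_i = t_{i−1} + d_i·w·h/Q_in.

## Membranes and tanks

A membrane couples a channel to a well-stirred-like tank. Fick's first law is
not discretised spatially; it is lumped into a per-species resistance
(pore-discovery model):

    R_d  = 1/(4 r D_F)      R_th = th/(A_m D_F)
    N_p  = (A_m / πr²) · porosity
    R_M  = R_d/N_p + R_th      [s/m³],   flux J = ΔC / R_M

Zero porosity yields an explicit "impermeable" result (R_M = ∞, zero flux).
The effective thickness `th` is a user input; no tortuosity correction is
applied. Alternative permeability models are deliberately not implemented;
the `model` field is an enum with a single value so that additional models
can be added behind the same interface.

Tank contents mirror the channel's slug layout one-to-one. After each
advection step the tank material is rotated by the same fraction; material
that would leave at the downstream end re-enters at the front ("recycling"),
so tank moles are conserved exactly — this prevents species from effectively
jumping ahead in the channel through an ideally mixed tank. After rotation
the tank is regrouped at the channel's slug boundaries by volume-weighted
averaging (rotation, splitting and averaging each conserve moles exactly).

Each aligned slug pair exchanges through its share of membrane area
(proportional to its length fraction φ: R_M/φ, V_t·φ, V_c·φ — φ cancels from
the rates, so a uniform channel reproduces the lumped tank balance exactly).
The coupled linear pair

    V_t dC_t/dt = ΔC/R_M,    V_c dC_c/dt = −ΔC/R_M

is integrated with classic RK4 within each engine step. RK4 is used rather
than a single previous-difference (Euler-like) flux update because it is
strictly more accurate at identical cost scale and preserves the pair's mole
invariant exactly (the right-hand side is antisymmetric in the stored moles).
Sub-steps are capped at 1/10 of the fastest time constant
min(V_c R_M, V_t R_M), which keeps the integration deep in its asymptotic
regime and excludes overshoot of the linear flux law. Channel slugs on
membrane channels are merged only when the aligned tank slugs also match, so
alignment is never broken.

## Fixtures (synthetic study conditions)

The generators in `chipflow.fixtures` emulate the canonical applications at
desk scale with typical PDMS-chip values — widths/heights of tens to hundreds
of µm, lengths of mm, water-like carrier (1 mPa·s), nL/s-scale flows:

* `make_y_junction` — two equal inlets (tracer 1 and 0) merging; the steady
  outlet is the flow-weighted blend (0.5 for equal flows).
* `make_gradient_tree(n, seed)` — a diamond splitter/combiner tree with two
  inlets and n outlets; `seed` randomises stage channel lengths in
  [0.5, 2] mm. Returns the closed-form mixing-cascade prediction and a
  settle-time bound (longest cumulative transit). Draws that produce a
  locally reversed channel (where no cascade exists) are re-drawn
  deterministically.
* `make_ring_network` — injection channel, ring with a short bypass and a
  ~3× longer module branch, outlet. The free solve prefers the bypass; a
  header droplet parked there flips the payload onto the module branch.
* `make_membrane_channel` — one channel with a constant-concentration inlet
  and a membrane-backed tank. The defaults (Q·R_M ≈ 8·10⁴, tank 1 nL,
  channel 100 nL, τ = V_t·R_M ≈ 80 s) put the run in the
  constant-channel-concentration regime where the tank follows
  C_t(t) = C_in(1 − e^{−t/τ}); the residual depletion of the channel between
  flushes is ~1/(2·Q·R_M) ≈ 6·10⁻⁶ relative, below the 10⁻⁵ comparison level
  used in the tests.

What the fixtures do **not** reproduce: fabrication tolerances, entrance
effects, Taylor dispersion, droplet formation physics, or the exact
geometries of published devices — passing tests demonstrate internal
consistency of the 1D model and agreement with its closed forms, not
agreement with any particular fabricated chip. Validation against published
gradient-generator, ring-network, and organ-on-chip measurements requires
those external geometry/measurement files and is therefore out of the
self-contained test scope.

## Numerical choices and degenerate inputs

* Positions snap to channel ends within 1e-12 of a fraction; zero-length
  slugs are absorbed by their neighbour.
* A step that would advect more than one channel volume is accepted only for
  compositionally steady channels (where it is a no-op); anywhere else it is
  an internal error, since event scheduling must bound the step.
* Mass-conservation residuals are checked at every solve (against the global
  flow scale, so quiescent dead ends do not divide by roundoff noise);
  violations beyond 1e-6 abort the run.
* Equal-time events are merged with a 1e-12 s tolerance and ordered
  deterministically; reruns of identical inputs are byte-identical.
* `run_simulation` problem sizes in the shipped tests (trees to 8 outlets,
  rings with ≤ 3 droplets, membrane runs of a few thousand events) were
  chosen as representative desk-scale devices; the engine itself has no
  size-specific logic.

## Known limitations

* Mixing assumes perfect instantaneous node mixing; short junctions at high
  Péclet numbers in real devices mix only partially.
* Droplet resistance is booked to one channel at a time; junction-spanning
  droplets are approximated atomically.
* The tank is advection-free and quasi-well-mixed per mirrored cell; strong
  in-tank gradients are outside the model.
* Flow fields with recirculation loops have no closed-form mixing cascade;
  the engine still simulates them, but `steady_state_concentrations` refuses
  them.
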