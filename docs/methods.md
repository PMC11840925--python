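# Methods

This note records the models implemented in `glutx`, the defaults and why
they were chosen, the numerical choices that matter, and what the synthetic
data can and cannot show. Units throughout: Å, ns, kT = 1, concentrations mM.

## Four-state carrier model

States `C_out, CG_out, CG_in, C_in`; transitions with rates
`a·G_out` (external binding, per mM per ns), `b` (external release),
`c`/`d` (loaded translocation out→in / in→out), `e` (internal release),
`f·G_in` (internal binding), `g`/`h` (empty-carrier reorientation in / out).
The stationary distribution solves the master-equation balance as a
least-squares null-space problem with the normalisation row appended;
irreducibility of the embedded chain is checked first and reducible networks
are rejected with the disconnected states named.

**Unidirectional (tracer) fluxes.** Label an infinitesimal fraction of the
cis solution. The labelled bound states form a linear stationary subsystem
driven by `a·G_out·P(C_out)`; eliminating them yields

```
influx = a·G_out·P(C_out) · c·e / (b·d + b·e + c·e)
efflux = f·G_in ·P(C_in)  · d·b / (b·d + b·e + c·e)
```

The identity `influx − efflux = c·P(CG_out) − d·P(CG_in)` (the net cycle
flux) holds algebraically; the suite checks it to 1e−10 and checks the
fluxes against a Gillespie single-carrier simulation that tags each bound
ligand with its side of origin.

**V_max and K_m.** For each saturable protocol the concentration→∞ limit is
taken analytically by collapsing the instantaneously rebinding states out of
the network (e.g. zero-trans influx reduces to the three-state loop with
`V_oi = c·e·h / (h(c+d+e) + c·e)`; both-sides saturation gives
`V_ee = b·c·d·e / ((c+d)(b·d+b·e+c·e))`). A rectangular-hyperbola fit over a
10⁴-fold concentration ladder centred on the bisected half-saturation point
provides K_m and cross-checks V_max; disagreement beyond 0.1 % warns of
non-Michaelis behaviour (which genuinely occurs for strongly asymmetric rate
sets under exchange protocols — the warning is informative, not an error).

**Flux-ratio law.** In the fast binding/release regime (`b, e` and the
pseudo-first-order binding rates ≥ 10³ × the largest translocation rate,
the default factor is 10⁴) with `c = d` and `g = h` these limits reduce to
`V_ee = c/2` and `V_oi = c·h/(c+h)`, hence `V_ee/V_oi = (1 + c/h)/2`. The
closed form is kept as an independent cross-check of the solver; at
c/h = 10 both give 5.5, at c/h ≤ 1 the ratio never exceeds 1, and as
c/h → 0 it tends to 1/2. Time-rescaling invariance (all rates ×λ scales
fluxes by λ, ratios unchanged) and the Haldane V/K symmetry under detailed
balance are property-tested.

**Counterflow.** Two well-stirred compartments exchange glucose through the
carrier at quasi-steady state; labelled and unlabelled species are
kinetically identical, so each unidirectional flux carries label in
proportion to the cis specific activity. The resulting 4-ODE closed system
is integrated with LSODA (rtol 1e−9, atol 1e−12); total label and total
glucose are conserved by construction and verified to 1e−8 relative. The
overshoot assertion is qualitative (presence, not magnitude), as the
magnitude depends on volumes and carrier density.

## Synthetic gated channel

The generator emulates the *statistical structure* of a saturated-flooded
transporter system, not its atomistic detail.

**Geometry.** Pore region Z = −25…+20 Å; piecewise-constant radius:
vestibules 12 Å, central cavity 9 Å, bottleneck apertures 4.5 Å in 2 Å
bands at the gate planes Z = ±15 Å; impermeable membrane slab |Z| < 18 Å
outside the channel wall; box 116 × 116 × 120 Å, periodic in X/Y,
reflecting in Z. With ligand radius 4 Å, two ligands can pass abreast where
the radius is ≥ 8 Å (vestibules, central cavity) but the apertures are
strictly single-file — the geometric origin of "exchanges only where there
is room".

**Wells.** Gaussian axial wells at Z = 0 and +15 Å, depth 6 kT, width 3 Å,
standing in for the central and external binding sites. Depth was set so the
Kramers escape time (w²/D)·e^depth ≈ 0.5 μs at the fluid diffusivity,
placing well dwells in the few-hundred-ns range characteristic of bound
glucose, while unbound ligands clear the pore within ≤ 1 μs.

**Phases.** Fluid: gates open fraction 0.5, mean dwell 10 ns per state,
D = 8 Å²/ns. Gel: open fraction 0.02, mean closed dwell 200 ns, D = 4 Å²/ns.
The diffusivity was chosen so a free ligand traverses the 40 Å pore in
~0.1 μs (L²/2D ≈ 100 ns), which makes 1000-frame (1 μs) runs informative:
docked ligands escape within the run, fluid-phase systems show pore entries
and occasional complete transits, and the gel contrast is measurable. It is
deliberately below the bulk aqueous diffusivity of glucose (~67 Å²/ns),
representing crowded, surface-interacting motion in and near the pore; a
single D for pore and bulk is a simplification.

**Dynamics.** Euler–Maruyama overdamped steps, 10 substeps per 1 ns frame:
Gaussian displacement of variance 2·D·dt per axis plus drift −D·dt·∇U from
wells and a purely repulsive soft-sphere pair potential
U = (k/2)(2R − r)² for r < 2R (k = 2 kT/Å², minimum image in X/Y). The
deterministic drift displacement is capped at 2 Å per substep so that deep
transient overlaps relax over a few substeps rather than ballistically
ejecting a ligand through a wall discontinuity. Hard constraints are applied
after each step: box-face reflection in Z, channel-wall/slab enforcement
(axial move rejection at radius steps, lateral reflection at the wall, slab
face reflection for solution ligands), and closed-gate plane reflection using
the *pre-step* lateral position to decide whether the crossing happened
inside the aperture. One seeded generator drives gate chains and ligand
noise in fixed order, so trajectories are bit-reproducible given the seed
and replicas are distinct seeds.

**Initial state.** 12 docked ligands evenly spread over Z = −20…+15 Å with
small alternating lateral offsets where the channel admits them; 44 solution
ligands placed uniformly outside the slab with overlap rejection. The evenly
spread axial spacing (3.2 Å) is below the 8 Å soft-sphere rest distance, so
mild initial compression is accepted (it relaxes within the first substeps);
only interpenetration beyond half a ligand radius is rejected as an invalid
placement.

**What the generator does not emulate.** Protein flexibility and
conformational gating coupled to ligand occupancy; hydrogen-bonded "rolling"
of real glucose pairs; anomers/rotamers; hydrodynamic interactions; distinct
pore vs bulk diffusivities; lipid dynamics. Consequently, tests passing on
synthetic data validate the *analysis machinery* and the qualitative
phase phenomenology (accretion behind closed bottlenecks, exchange
persistence, transit collapse), not atomistic realism.

## Exchange detection

For each unordered ligand pair, let n(z) map the pore span (default
−25…+20 Å) linearly to [0, 1] and s_t = n(z_A) − n(z_B) the normalised
ordering gap. A frame pair (i, j), i < j, is a candidate when s_i·s_j < 0
(the ordering reverses — strict, so touching without reordering never
counts) and |s_j − s_i| > 0.4, and the event mean Z (mean of the four
bounding CoM Z values) lies in −15…+12 Å. Candidates are accepted greedily
by ascending window length (ties: earlier start, then lexicographic pair),
rejecting windows that share a frame with an accepted window of the same
pair; windows of different pairs are independent. The "0.4 normalised"
criterion admits two readings — a change in the ordering gap or an absolute
normalised position of the displaced ligand — and the gap-change reading is
the default because it is unit-free, translation-invariant and symmetric in
the partners; the alternative is available as `mode="abs_position"` for
sensitivity analysis. The implementation is vectorised over frame pairs
with cheap pair prefilters (must reorder; mean Z must be able to reach the
region) and is verified event-for-event against an O(pairs × frames²)
brute-force oracle on ~100 random instances.

**Classification.** `close` if the partners' minimum approach over the
window is ≤ 3.5 Å (inclusive), else `bypass`; the minimum is over heavy-atom
pair distances when atomic coordinates exist and over CoM distances
otherwise. Note that for CoM-only synthetic point ligands of radius 4 Å the
3.5 Å contact cutoff is effectively unreachable (two touching ligands have
CoM separation ≈ 8 Å), so synthetic events classify as bypass/surface; the
close/bypass split is physically meaningful only for atomistic input, where
3.5 Å is an atom–atom contact distance. `surface` overrides either label
when exactly one partner began the window inside a binding-well Z-band with
≥ 10 frames of prior residency while the other entered from solution; the
residency minimum is configurable and was fixed once at 10 frames (10 ns at
default sampling, comfortably longer than a drive-by).

**H-bond descriptor.** A supporting geometric criterion for atomistic input
only: donor–acceptor ≤ 3.5 Å with donor–H–acceptor angle ≥ 120°, donors/
acceptors being O/N atoms, hydrogens assigned by a 1.2 Å covalent cutoff.
CoM-only trajectories are rejected explicitly.

## Zones and flux statistics

Ordered half-open intervals covering the Z axis: IC solution (−∞, −25),
IC vestibule [−25, −15), central [−15, +5), EC vestibule [+5, +20),
EC solution [+20, ∞). The boundaries interpolate the stated landmarks
(external vestibule 5–15 Å, docked span −20…+15 Å, exchange region
−15…+12 Å) and are fully configurable. Half-open intervals make zone
assignment a total function and prevent double counting at boundaries.

A *complete transit* is first passage from one solution zone to the other,
with any return to the source solution zone resetting the attempt — robust
to vestibule re-crossings. Dwell segments partition each ligand's frames
exactly, so per-ligand dwell totals conserve time by construction. The
exchange-to-net ratio is events/transits (the common duration cancels);
zero transits with nonzero events is reported as +inf with a flag, and the
acceptance script reports the finite lower bound events/1 in that case so
its output remains strict JSON.

## Problem sizes

Default experiments use 1000 frames × 1 ns × 56 ligands and 3–5 replicas
per phase, which the package processes in seconds per replica (simulation
~2 s, detection ~2–5 s); the brute-force detector oracle runs on ≤ 5
ligands × ≤ 120 frames; the Monte-Carlo carrier oracle uses 3 × 10⁵ jumps
with a ±3-standard-error acceptance band. These sizes were chosen as the
smallest at which every law being tested is statistically sharp.

## Known limitations

* The carrier solver treats binding as pseudo-first-order; explicit
  substrate depletion appears only in the counterflow ODE system.
* The generator's single diffusion coefficient and rigid geometry mean
  absolute rates (entries/μs, transit counts) are order-of-magnitude
  emulations, not predictions; only paired-phase comparisons are meaningful.
* Gate kinetics are presets, not fits: no quantitative gating data exists
  to fit against, so the fluid/gel presets encode the qualitative regime
  (balanced vs rarely-open) at fixed, documented values.
* The exchange detector sees only Z-ordering; genuinely three-dimensional
  exchange geometry (rotation about a shared axis) is not resolved, by
  design.
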