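# Methods

## The physical model

A multicellular tumor spheroid (diameter D = 200–500 µm) sits in a
U-shaped PDMS trap inside a perfused microchannel (1000 × 1000 µm cross
section, 2000 µm long periodic unit). Culture medium (water at 37 °C,
ρ = 993.3 kg/m³, µ = 0.692 mPa·s) enters with flow rate Q = 5–20 µL/min; at
these rates the channel Reynolds number is ≈ 0.12, so the steady
incompressible Navier–Stokes equations are deep in the creeping-flow
regime. The two lateral faces are symmetry planes (the trap repeats in a
row), making the fully developed inlet profile plane Poiseuille in the
vertical coordinate, u_z(x) = 6U·(x/H)(1 − x/H), U = Q/(W·H).

Each dissolved species (oxygen, glucose) obeys a single balance across the
device,

    ∂c/∂t + u·∇c = ∇·(K ∇c) − R,        R = Vmax·c/(c + Km),

with convection only in the medium, Michaelis–Menten consumption only in
the spheroid, and pure diffusion in the PDMS lid and barrier (oxygen only —
PDMS is glucose-impermeable). At material interfaces the native
concentration jumps by the solubility (partition) ratio S relative to water
(S_O2: tissue 4.81, PDMS 6.8; glucose tissue 1) while the flux is
continuous. Oxygen enters both with the medium and by diffusion through the
1 mm PDMS lid, whose outer surface is held at ambient equilibrium; the
glass floor is impermeable. Tissue with oxygen below pO₂ = 10 mmHg
(0.01322 mM at the 37 °C Henry solubility 1.322×10⁻³ mM/mmHg) or glucose
below 0.5 mM is quiescent/hypoxic; below pO₂ ≈ 0 or 0.2 mM glucose it is
necrotic. Where a concentration falls below the necrosis level the dead
tissue stops consuming; the model holds the concentration there at the
threshold (`clamp_mode="pin"`, the default — matching the usual statement
that sub-necrotic values are kept constant), with pure consumption
deactivation (`"deactivate"`) available as the alternative reading. The
dead-cell mask only grows (necrosis does not revert) and is iterated with
the nonlinear solve to a fixed point.

## Discretization

**Transformed variable.** The species problem is solved in the
medium-equivalent concentration w = c/S_domain, which is continuous across
interfaces; using the effective diffusivity K·S per domain reproduces both
the native jump and native flux continuity without interface constraints.
In w-form the tissue sink is R = Vmax·S_t·w/(S_t·w + Km).

**Meshes.** The solid model is implicit (exact point classifiers for the
channel, the barrier variants and the sphere). Meshes are graded structured
tensor grids snapped to every planar feature, split into six Kuhn
tetrahedra per hex (conforming), with cells classified by centroid.
Named resolutions (general/trap/PDMS/sphere-band spacings in µm):
`test` (130/420/650/110, ≈6k cells), `coarse` (62/190/300/28, ≈62k),
`fine` (46/145/230/21, ≈112k), `paper` (33/100/160/15, ≈268k, the full
study-scale element count). Extra refinement bands straddle the
spheroid surface where the narrow gaps to the floor and arms carry the
convective supply. Curved interfaces are stair-stepped at the local
spacing; the spheroid volume is captured to ≪1% at `coarse`. The sphere is
embedded 2 µm (configurable) into the floor and the downstream barrier wall
so the contacts are meshable patches, not tangency points.

**Flow.** Equal-order P1/P1 velocity–pressure elements with
Brezzi–Pitkäranta pressure stabilization (α = 0.05·h²/µ); Dirichlet no
slip on floor, lid underside, barrier and spheroid; the nodal inlet
parabola is rescaled so its discrete facet integral equals Q exactly;
natural zero-traction outlet pins the pressure level. The convective term
is Picard-iterated (`mode="picard"`, relaxation 0.7, relative tolerance
1e−6); at Re ≈ 0.1 the pure Stokes mode differs by <0.1% in maximum shear
and is exactly linear in Q, which the sweep and acceptance drivers exploit
(one solve per geometry covers all flow rates). Direct sparse LU solves the
saddle system; discrete in/out flux balance holds to machine precision.

**Shear extraction.** The viscous traction is not evaluated on the
stair-step facets: velocity gradients are sampled at analytic points on the
true sphere (Fibonacci lattice), offset half a local cell outward, and
projected onto the tangent plane of the exact surface. The offset sequence
(0.5–2.4 h) walks outward until a medium cell is found; the estimate is
stable between offsets 0.5h and 1h and between mesh levels to a few
percent.

**Transport.** P1 elements with streamline-diffusion (SUPG) stabilization
of convection (coth-form τ). The Michaelis–Menten sink is
Newton-linearized about the previous iterate with the clipped-rate
derivative (flat where tissue is empty) and adaptive damping; because the
rate is nearly flat wherever c ≫ Km, three to six iterations reach a 1e−6
relative increment. The necrosis mask is an outer loop (max 20 passes).
Small streamline-diffusion overshoots (1–2% of c0 at the inflow floor
corner, growing mildly with the Péclet number) are the only violations of
the discrete maximum principle and shrink under refinement.

**Transient.** For the no-flow depletion scenario the system is closed
(velocity zero, all boundaries no-flux), and implicit Euler (default
dt = 60 s; tests use 120–180 s) advances the lumped-mass form, with the
Michaelis–Menten factor lagged one step. Summing the discrete equations
shows total native mass changes exactly by the integrated consumption; the
audit trail in `TransientResult` reproduces this to solver precision.

**Zone areas.** Mid-plane (y = W/2) area fractions are computed by
interpolating the field onto a dense polar quadrature grid over the
spheroid disc (160 radial × 360 angular points) and labelling each point,
so percentages are not quantized by mesh cells. Necrotic labelling uses
the pinned/deactivated cell mask plus an ε = 10⁻⁶ mM band above the
necrotic threshold (an exact zero is unreachable under Michaelis–Menten
kinetics). With that band the steady oxygen field never reaches the
necrotic level on desk-scale meshes (minimum ≈ 9×10⁻⁴ mM at c0 = 0.1 mM),
so oxygen-deficient tissue is reported as quiescent and the *combined*
quiescent + necrotic area — the quantity all sensitivity figures use — is
unaffected.

**Flux audit.** The steady balance check integrates the total transport
flux over a control sphere 1.5 local cells outside the stair-step
interface (truncated at the no-flux floor), where P1 gradients are
accurate; the convective term uses w − c0, exploiting zero net volumetric
flux to avoid catastrophic cancellation (the raw convective throughput for
glucose is two orders of magnitude above the consumption). Both species
balance to within 2% on the coarse mesh.

## Reported metrics

Two printed-figure conventions needed fixing against the published numbers
rather than their loose wording:

* the "maximum concentration mismatch" along the spheroid centre line is
  the spread relative to the profile *minimum*, 100·(max − min)/min
  (`mismatch_percent(..., reference="min")`); the max-referenced variant
  is the library default and both are exposed;
* the "enhancement of concentration" for a flow-rate change is evaluated
  at the depleted extreme of the centre line, 100·(min_Q′ − min_Q)/min_Q.

With these definitions one coarse-mesh run reproduces the published
anchors simultaneously (oxygen spread ≈55% vs ~52 at D = 500 and ≈3.2% vs
~3 at D = 200; glucose ≈7.9% vs ~8; flow-gain 37% vs 38 for oxygen and
1.1% vs 1 for glucose), whereas max-referenced readings are wrong by
30–60% systematically.

The glucose zone-sensitivity reference inlet concentration (not printed) is
taken as 1.0 mM — the value the study pairs with the oxygen reference
0.1 mM as the onset of deficiency zones; its ±20% sensitivity then matches
the printed +28.7% under the pin clamp.

## Study cases and the synthetic-data role

`spherotrap.fixtures` encodes every study scenario (diameter, flow-rate and
inlet-concentration sweeps, the zone-sensitivity pairs, the three-trap
comparison at equal 400 µm trap height, the no-flow transients) as named
configs with the standard device defaults; all inputs are generated by code. The
microwell trap is modelled as a cavity with the U-trap's inner footprint,
recessed 400 µm into the impermeable substrate (glass-walled, no-flux):
only that reading reproduces the strong oxygen and glucose starvation the
trap-type comparison reports, since a PDMS-walled well would keep feeding
the submerged spheroid with oxygen. What
these emulate is the *idealized* device: perfectly spherical aggregate,
rigid and impermeable to flow, uniform kinetics, constant-temperature
water-like medium. Passing tests therefore validate the transport model
and its numerics, not biological variability: real spheroids are
non-spherical, porous at their rim, heterogeneous in Vmax, and grow — all
explicitly out of scope.

## Known limitations

* Stair-step interfaces limit surface-quantity convergence to O(h): the
  grid-refinement change in spheroid-average oxygen between the coarse and
  fine meshes is ≈2.4% (and ≈4.5% in max shear), above the 1% a body-fitted grid achieves at
  study-scale resolution; a study-scale direct Stokes factorization
  exceeds the memory available to this package's solver, so refinement
  beyond `fine` is not exercised routinely.
* The micropost barrier's two 2°-wide gaps (~12 µm of arc) are below the
  voxel resolution of every named mesh level, so the micropost variant is
  transport-equivalent to the integrated barrier here; claims that
  distinguish them (slightly higher shear, slightly better glucose) are
  not resolvable at desk scale.
* The computed shear envelope's low end (≈0.34 mPa at D = 200, Q = 5) sits
  below the published ~0.5 mPa; the value is stable under mesh refinement,
  sampling offset and both shear definitions (tangential traction and
  µ√(2D:D)), so we report it as a genuine model/geometry difference.
* Oxygen–glucose metabolic coupling, lactate/pH, porous-medium flow inside
  the aggregate and growth are not modelled.
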