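# Methods

`aneucoil` simulates the endovascular coiling of a cerebral aneurysm with a
dimension-reduced elastic-rod model and grades the resulting placement with
an in silico Raymond–Roy-type occlusion classifier. This note records the
model, its numerical treatment, the defaults and why they were chosen, and
what the synthetic test problems do and do not demonstrate.

## Rod model

A coil is a Kirchhoff rod discretized as `N` material points joined by
edges. Each edge carries an adapted orthonormal frame; the only rotational
degree of freedom is the angle `phi^j` of the material frame about the
tangent, measured against the twist-free Bishop frame obtained by parallel
transport along the current centerline. The discrete strain energy is

    E = sum_j  alpha_abs/2 (|e^j|/|ē^j| - 1)^2 |ē^j|          (axial penalty)
      + sum_i  b/(2 l̄_i) |kappa_i - kappa̅_i|^2                (bending)
      + sum_j  beta/(2 l̄_j) (tau^j)^2                          (twist)

with integrated nodal curvatures `kappa_i` built from the discrete
curvature binormal `(kb)_i = 2 t^{i-1} x t^i / (1 + t^{i-1}·t^i)`, Voronoi
lengths `l̄_i`, and twist `tau^j = phi^j - phi^{j-1}` (the natural shape is
Bishop-framed, so its natural twist vanishes). The axial sum runs over all
edges, bending over interior nodes and twist over interior edges. The rod
is treated as inextensible in substance — real coils carry a
stretch-resistant filament — and the axial term is a penalty, not a
physical stiffness.

Bending/twisting stiffnesses come from the wound microstructure of the
device: a stock wire of diameter `D1` wound at pitch `p = 1.1` into a rod
of diameter `D2` behaves like a torsion spring with

    b    = E_w D1^4 p_c / (32 (2 + mu_w) D2),
    beta = E_w D1^4 p_c / (64 D2),        p_c = p D1,

so `beta/b = (2 + mu_w)/2` exactly. Defaults are platinum: `E_w = 168 GPa`,
`mu_w = 0.38`, density 21 450 kg/m^3 (node masses lump the wound wire
volume per segment). Internal units are mm, s, kg, giving forces in mN and
energies in uJ.

### Gradients

The vertex gradient of the energy is analytic. Three pieces enter: the
axial term; the bending term with frames varying by adapted parallel
transport (the "tilde" curvature gradients); and a holonomy term — moving
a vertex rotates every downstream parallel-transported frame about its
tangent by an increment whose edge gradients are `-(kb)_i / (2|e|)` on the
two incident edges, coupling through the suffix sums of the frame-angle
gradient. In this parametrization the twist energy depends on the angles
only, so it contributes to the `Phi`-gradient but not to the holonomy
coupling. Because published derivations differ in sign and frame
conventions, the implementation treats the central finite-difference
oracle as the contract: the analytic gradient is certified against it to
a relative 1e-5 on random rods in the test suite, and every sign above was
fixed by that oracle.

Consecutive antiparallel tangents (a 180-degree kink) make the curvature
binormal and the transport rotation singular; they raise an error rather
than being regularized, since such kinks violate the model's assumptions.
Twist increments are wrapped to (-pi, pi] to avoid spurious multi-turn
twist on coarse discretizations.

## Dynamics

Newton's second law with lumped masses, diagonal damping, and zero
rotational inertia (the rotational moment scales with `m D2^2` and is
negligible) is integrated by the symplectic (semi-implicit) Euler scheme:
velocities first, positions with the new velocities, and first-order
damped dynamics for the frame angles, `phi_dot = -grad_phi E / eta_phi`,
which relaxes the rotational DOFs quasistatically. After each step the
Bishop frames are re-propagated from the first edge, whose reference
director is transported in time so no artificial twist enters.

Numerical choices:

* **Time step.** The largest power-of-two fraction of a second below
  `0.5 sqrt(m l̄ / k_stiff)` where `k_stiff` is the stiffest explicit mode
  (axial penalty, segment-scale bending, contact springs). Power-of-two
  steps make runs bit-reproducible across step-count changes.
* **Damping.** `eta_X` defaults to critical damping of segment-scale
  bending (deployments are driven, quasi-static processes); free-space
  validation scenarios that must settle into a global equilibrium use
  near-critical damping of the slowest beam mode instead. `eta_Phi` is a
  small multiple of the explicit twist stability limit.
* **Axial penalty scale.** The dimensionless penalty `alpha` multiplies a
  reference stiffness of 1.5 N (1500 mN per unit strain). The scale was
  calibrated once on the reference dome deployment so that `alpha = 0.1`
  holds the mean relative segment stretch well below 1% while the softest
  tabulated value (`alpha = 0.025`) sits near the 1.5% regime, and is
  frozen; the trend of decreasing stretch with increasing `alpha` is a
  tested property.

## Insertion protocol

The micro-catheter is a rigid lidless tube (radius 0.25 mm) along a
3-point quadratic spline. The coil starts straight behind the inlet with
a twist-free frame. Nodes still inside the catheter are fully kinematic:
position prescribed on the spline at their arc coordinate, velocity
`v_push` along the local tangent; the step at which a node passes the tip
is recorded as its release step, after which it integrates freely. The
rotational DOFs are never constrained (the coil can rotate freely inside
the lubricated catheter). Membership is tracked by pushed arc length, not
geometric containment, so escaped nodes are never recaptured.

The conveyor is force-limited: whenever the compressive axial force in
the feed edge (the edge bridging the catheter tip) exceeds 6 mN — a
proxy for the interventionist's bounded push force — the feed pauses for
that step and resumes once the jam relaxes. Insertion ends when the
released coil length reaches the packing-density target (coil volume
`pi (D2/2)^2 L` against the dome volume); a short settling phase follows,
and for the final 10% of the steps the neck-cut dome is replaced by the
full vessel geometry so the coil may relax toward the parent lumen.
Multiple coils are inserted sequentially as one chain whose virtual
connecting edges carry no elasticity and no contact.

The default insertion speed (250 mm/s) and problem sizes (about 300
nodes, 15% packing density in a 2.5 mm dome) are the package's
desk-scale reference conditions; the near-critical damping makes the
process quasi-static, so the speed acts as a throughput parameter rather
than a physical loading rate.

## Contact

Detection is two-phase. Coil-coil: an octree over edge centers (leaf
capacity 8, depth cap 12) yields candidates by the center-distance
condition `|c_j - c_i| <= sqrt((l̄/2)^2 + D2^2)`; exact segment-segment
minimum distances (Lumelsky-style clamped closest points) then keep pairs
with `d_min <= D2`, overlap `eps = D2 - d_min`. Coil-wall: nodes against
surface triangles, broad phase `|c - c_T| <= D2/2 + r_ST` with
per-triangle enclosing-sphere radii, narrow phase the exact closest point
on the triangle with penetration `eps = D2/2 - dist`. A literal mode that
accepts only in-plane projections interior to a triangle is available
behind a flag; the closest-feature default prevents nodes from tunneling
through mesh creases. Only the closest triangle per node contributes, so
mesh creases are not double counted.

Forces: penalty normal forces with velocity dissipation; the wall
reaction additionally cancels the wall-pressing component of the node's
elastic + coil-coil force. Friction is Coulomb: slip-only between coil
segments (zero at vanishing relative tangential velocity), stick-slip
against walls with `mu_stick = 0.6 >= mu_slip = 0.4` and a stick
threshold `v_eps = 1e-3 mm/s`. The coefficients are deliberately high:
the walls are rigid here, and a compliant wall would otherwise provide
extra tangential resistance. Contact springs default to a multiple of
`b/l̄^3` so penetrations stay a small fraction of `D2`. Two explicit
regularizations keep the scheme stable: slip-friction magnitudes are
capped so a single step cannot reverse the sliding velocity, and pair
forces are distributed to the four incident nodes by the contact-point
barycentric weights (which keeps coil-coil interactions exactly
antisymmetric; the Coulomb cap and the antisymmetry are asserted inline
during every deployment run).

For execution speed the broad phase is cached: candidate sets are built
with an extra margin of `D2/2` and reused while no node has moved more
than half that margin (and the wall set and release set are unchanged);
the exact center-distance condition and the exact narrow phase are
re-applied every step, so the detected contact sets equal those of a
per-step rebuild.

## Geometry

The synthetic aneurysm is a revolved profile: a spherical dome of radius
`R` cut by a circular neck of radius `r_n` (plane at `z = -sqrt(R^2 -
r_n^2)`), closed flat for the insertion phase; the full vessel variant
extends the neck into a short cylindrical stem standing in for the
parent-lumen space a migrating coil could enter. Defaults (R = 2.5 mm,
r_n = 1 mm) sit in the clinically most frequent "very small" class.
Optional seeded radial bumps provide ensemble variety. User meshes
(STL/OBJ/PLY) are accepted and cut at a given neck plane; the cut is
capped by fanning each boundary loop from its centroid (loops are assumed
star-shaped, which neck cross sections are). Meshes must be watertight
with outward normals (positive divergence-theorem volume).

Natural shapes: `straight`; `helix` with imprint diameter `D3` and loop
spacing `1.2 D2`; and `complex3d`, a frozen parametric spline tracing
loops of varying orientation on a sphere of diameter `D3` — the reference
stand-in for proprietary 3D framing-coil shapes (fidelity to any
particular product is a non-goal). All programs are resampled to exactly
constant edge length; natural curvatures are extracted with the same
discrete operators used on the deformed rod, and the natural twist is
identically zero by the Bishop parametrization.

## Occlusion analysis

The deployed centerline is voxelized on the dome's bounding cube (70
voxels per axis by default): a voxel counts as coil when its center lies
within `D2/2` of the centerline (the union of segment capsules equals the
swept-circle volume of the coil). The aneurysm interior is split into a
core and a boundary region of equal volume by bisecting on a level set of
the signed distance function to the wall; the SDF backend computes exact
point-triangle distances through a BVH and takes the sign from the parity
of vertical-ray crossings, which is robust on watertight meshes. A neck
sphere (by default centered at the neck-opening centroid with the neck
radius — the choice is configurable and recorded in output metadata)
probes the inflow zone; only its intersection with the aneurysm counts
toward its reference volume.

Volume fractions are reported both referenced to the aneurysm volume
(`psi_BA + psi_CA = psi_AA`) and as region-local packing densities. The
classifier operates on the region-local densities with inclusive
thresholds: core 20%, boundary 18%, sphere 18%. Full core and boundary
give class I (sphere full) or II (sphere empty); empty core with full
boundary IIIa (either sphere state); full core with empty boundary IIIb;
both empty is Fail, read as migration into the parent vessel. Ensemble
statistics use the population (1/N) convention pointwise and for
region-integrated deviations; sweep confidence bands are normal
approximations, mean ± 1.96 SE per bin. The sweep protocol samples a coil
parameter uniformly on an interval, partitions the interval into 5 equal
bins and requires at least 30 samples per bin (underfilled bins are
flagged, not dropped), with scaled-down sample counts supported.

## What the synthetic tests show — and what they do not

The synthetic dome exercises every mechanism of the pipeline — imprinted
curvature, catheter release, wall and self contact with stick-slip
friction, the two-phase geometry swap, voxelization and classification —
under fully controlled conditions with analytic references (capsule
volumes, equal-volume ball partition, Euler-Bernoulli deflection limits).
It does not reproduce patient anatomy: real aneurysms are non-spherical,
necks are not circular, parent vessels curve, and walls comply. Passing
the suite therefore certifies the discretization, the contact handling
and the classifier logic, not clinical predictive accuracy. Hemodynamics,
clotting, wall deformation and catheter-coil friction are outside the
model.

## Known limitations

* The axial penalty admits a residual stretch of order `F/alpha_abs`;
  the reported stretch statistics quantify it per run.
* Explicit integration bounds the time step by the stiffest penalty;
  very soft penalties insert slowly because the force-limited feed
  pauses frequently.
* The neck-cap fan triangulation assumes star-shaped cut loops.
* The classifier thresholds are geometric surrogates calibrated to grade
  higher packing densities better; they are not validated against
  angiographic readings.
* Contact is node/segment-based; features smaller than an edge length
  (about one coil diameter at the default discretization) are not
  resolved.
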