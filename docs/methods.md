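# Methods

## Model overview

The pipeline couples two static models of the right lower limb at five
instants of the stance phase of normal gait (beginning and end of stance
plus the three extrema of the knee joint force, at roughly 2, 15, 30, 50
and 62 % of the gait cycle):

* a **rigid-body linkage** — thigh and leg+foot segments, spherical hip,
  revolute knee (single axis, medio-lateral), rigid ankle — used to resolve
  the muscle redundancy and extract joint reactions, and
* a **linear-elastic FE model** of femur, soft interface layer, tibia,
  fibula and patella, loaded with the recruited muscle forces and the GRF,
  used to recover displacements, strains, spring forces and reactions.

Units are mm, N, MPa (1 MPa = 1 N/mm²), kg and m/s² throughout; `y` is
vertical (up), `z` postero-anterior (anterior positive), `x` medio-lateral.
Coordinates follow the frontal/sagittal conventions used when reporting
gait forces: the frontal plane is x–y, the knee flexion axis is x.

Assumptions carried by both stages: quasi-static loading (inertial forces
are computed as m·a, verified ≲ 10 % of the GRF over the loaded positions,
then dropped), no gravity (the limb is grounded at the femoral head; adding
weight would only shift the reaction the validation compares anyway),
straight muscle lines of action (no wrapping), and all joint soft tissue
reduced to a bonded, isotropic linear-elastic layer.

## Muscle recruitment

The static equilibrium of the linkage is assembled as 10 rows: force
balance of each segment (6), moment balance of the whole limb about the hip
centre (3; the hip force and the internal knee reactions drop out, and
collinear action–reaction muscle pairs cancel exactly), and the moment of
the leg+foot about the knee flexion axis (1; the revolute knee transmits no
moment about its own axis). Reaction slots are the knee force (3) and hip
force (3).

The redundancy is resolved by min/max recruitment,

    min β   s.t.  f_i ≤ β N_i,  f_i ≥ 0,  C f + R r = d ,

solved as a linear program (HiGHS, feasibility tolerances 1e-10). Among
β-optimal solutions the returned one also minimises Σf_i — a fixed
tie-break that makes results reproducible across solvers. Muscle strengths
N_i are not part of any published table; all elements default to equal
strength (2500 N), which is the canonical form of the criterion, and the
validation quantities do not depend on the value. The implementation is
cross-checked against an independent oracle (bisection on β with
feasibility by vertex enumeration) on randomly generated small systems.

## FE formulation and boundary machinery

* **Element**: 4-node constant-strain tetrahedron (symmetric PSD element
  matrices with exactly six rigid modes; patch-test exact). 10-node
  elements are out of scope.
* **Bonded contact**: conforming interfaces merged node-to-node (tolerance
  1e-6 mm). The synthetic femur / soft layer / tibia column is generated
  with coincident interface rings so this applies exactly. Non-conforming
  ties are *not* implemented; the fibula and patella are instead attached
  with isotropic spring-ties (see below).
* **Remote points**: default *distributing* coupling — loads at the remote
  point are spread over the coupled patch statically equivalently (total
  force and moment about the point preserved), and springs attached at the
  remote point act on the average patch displacement. This avoids the
  artificial surface stiffening of rigid coupling; rigid coupling (six
  extra degrees of freedom tied to the patch by penalty) is available by
  flag. The COP and the calcaneus (insertion of gastrocnemius/plantaris)
  are remote points on the distal tibia.
* **Grounding**: three springs of 10⁹ N/mm (x, y, z) at the femoral-head
  remote point. Acting on the averaged patch displacement, they pin the
  translation (reaction ~2 kN ⇒ displacement ~1e-6 mm) while leaving
  rotations about the head free — a spherical joint.
* **Stabilisation**: three springs of 1 N/mm attached at three separated
  points of the distal tibia rim, one per space direction. Separating the
  anchor points ensures no rigid-body mode escapes all three springs (a
  single-point triple leaves rotation about the hip–anchor axis
  unresisted and the system singular).
* **Patellar tendon**: three parallel axial springs, k = E·A/L with
  E = 900 MPa, A = 160 mm², L = 50 mm ⇒ 2880 N/mm total, 960 N/mm each.
  L is configurable; 50 mm is the value consistent with the published
  stiffness.
* **Solver**: direct sparse LU with two steps of iterative refinement,
  which holds the relative residual near machine precision despite the
  10⁹…1 stiffness spread; singular systems are reported before/at
  factorisation. Strains are recovered per element; both the maximum
  absolute principal strain and the maximum component are exposed, since
  "maximal strain" is otherwise ambiguous.

Spring-ties (fibula–tibia, patella–femur) are isotropic node-pair springs
of 1e4 N/mm. Two deliberate choices here: a point tie between separated
nodes transmits transverse force without a balancing moment, so very stiff
ties would spuriously resist the rigid rotation mode that the stabilisation
springs are meant to govern; 1e4 N/mm carries the ~2.5 kN patellar load
path with < 0.1 mm relative motion while contributing ≪ the stabilisation
springs' rotational stiffness. This is a documented surrogate for bonded
contact of non-conforming parts, not a contact model.

## Synthetic anatomy

Bones are capped hollow tubes/frusta (cortical shell only) meshed by a
conforming hex-to-6-tet decomposition: femur 220 mm and tibia 200 mm at
outer/inner radius 40/28 mm, a 30 mm bonded soft layer (E = 120 MPa)
between them, a 170 mm fibula and a small patella, with landmarks
(femoral-head centre, epicondyles, malleolus, tuberosity, COP and calcaneus
anchors) and named attachment patches. Knee flexion poses the leg parts by
rigid rotation about the knee axis; the soft layer interpolates between the
femur's horizontal distal ring and the posed tibial ring so the bonded
interfaces stay conforming at every analysed flexion (5–38°).

The proportions are deliberately stubby. The published deformation pattern
is dominated by rigid rotation about the grounded femoral head; a
slender anatomical column at desk-scale mesh density would add elastic
bending that buries that signal. Shortening and thickening the column keeps
the elastic share of the distal-tibia displacement below ~5 % at every
position while leaving every load path intact.

The muscle table carries the 29 hip/knee-crossing muscles as 122 elements
in 33 recombination groups (three subdivisions each for adductor magnus and
adductor brevis, one per muscle otherwise). Attachment sites are laid out
anatomically by octant (adductors medial, glutei lateral/posterior,
quadriceps anterior via the patella, hamstrings posterior to tibia/fibula,
triceps surae to the calcaneus remote point). Within a group, element
attachment points are spread ±8 mm around the patch's uniform-traction load
point; for muscles with off-model (pelvic) origins the spread carries a
coherent horizontal bias along the muscle's own line, signed so the
resulting moment imbalance accumulates about the flexion axis and the
per-element vertical-axis moment error vanishes identically. This emulates
the fact that a distributed attachment area is never loaded exactly at a
single equivalent point, and it is what rocks the FE model about the
femoral head: the imbalance is carried by the weak springs
(≈ 0.4–3.7 % of the GRF, the same regime as the reference model's worst
case of ≈ 5 %), producing millimetre-to-centimetre rigid rotations on a
sub-millimetre elastic background.

The gait table defaults: GRF magnitudes (253, 592, 483, 644, 15) N —
first peak of the order of body weight (62 kg subject), near zero at the
end of stance; knee flexion (5, 15, 10, 14, 38)°, the last two fixed by the
reference trial and the first three free configuration values; segment
accelerations scaled from reference inertial-force components so m·a stays
of the order of tens of newtons (thigh 6.22 kg, leg+foot 3.8 kg).

What the generator does **not** emulate: real bone geometry and curvature,
menisci/cartilage as separate parts, contact and ligament mechanics, muscle
wrapping, trabecular bone, and the commercial musculoskeletal model's
subject-specific strengths and activation patterns. Passing tests therefore
show that the *workflow* — recruitment, mapping, boundary machinery,
validation logic — is implemented correctly and self-consistent, not that
it reproduces subject-specific strains; the published headline strains and
joint-force curves depend on unavailable geometry and are only re-derived
where they are internally computable (table norms and ratios).

## Validation criteria

1. **Distal-tibia displacement "nearly zero"** is implemented as: the
   *elastic* remainder of the distal-tibia displacement — total minus the
   least-squares rigid rotation about the femoral-head centre — is ≤ 5 % of
   the total. The raw displacement itself is centimetres even in the
   reference model (up to 50 mm), attributed there to rigid rotation; the
   rotation-removed reading reconciles the criterion with those numbers.
2. **Springs negligible**: stabilisation-spring resultant ≤ 5 % of the GRF
   magnitude (configurable; the reference model's own worst case is
   ≈ 5.3 %).
3. **Reaction match**: relative difference between the FE femoral-head
   reaction magnitude and the rigid-body hip reaction ≤ 16 %, the bound the
   reference results satisfy. On the synthetic model, where both stages
   share one geometry, the observed difference is ≤ 0.2 % and decreases
   monotonically as the stabilisation stiffness is swept 1 → 0.01 N/mm,
   because the springs are the only discrepancy source.

A global equilibrium audit (applied loads + ground-spring forces +
support reactions = 0 to 1e-6 relative) runs on every solve.

## Numerical choices and problem sizes

Node merge tolerance 1e-6 mm; LP feasibility 1e-10 with a 1e-9 slack on the
tie-break bound; linear solves refined to ~1e-12 relative residual; the
rigid/elastic split solved by unweighted least squares over all mesh nodes.
The default assembly is ≈ 2 500 nodes / 7 000 tets per position, chosen so
the five-position pipeline plus the stiffness sweep completes in well under
a minute on one core; the cantilever verification uses a 300 mm tube at
three densities (up to ~11 000 elements), reaching the Euler–Bernoulli tip
deflection within 9 % at the default density with monotone convergence.

## Known limitations

* Bonded-by-merge only; no tie constraints for non-conforming interfaces
  (spring-tie surrogate instead), no contact, no nonlinearity.
* Constant-strain tetrahedra are stiff in bending at coarse density; the
  convergence study quantifies this on the tube fixture.
* The recruitment stage derives its own active-muscle sets; they are not
  expected to equal any published per-position activation table.
* Published table rows with internally inconsistent roundings (a handful of
  resultants differ by 1 N from their own components) are reproduced as
  computed and shown side by side rather than asserted.
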