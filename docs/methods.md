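# Methods

## Model

`cortivox` generates cortical bone microstructure as a three-stage
pipeline: a *vector skeleton* (osteon axes, interconnection points,
Volkmann segments), a *labelled voxel volume* (constructive solid
geometry by label painting), and *derived products* (porosity report,
iso-surface meshes).

### Vector skeleton

Osteons are modelled as straight circular cylinders cast from the base
plane (z = 0) of the generation volume.  The count is deterministic,
`N = round(OnDn · A)` with `A` the base cross-section area in mm², so
osteon density is honoured exactly rather than in expectation.  Centres
are uniform over the base cross-section (rejection sampling against the
annular region for the tubular variant); no minimum-distance constraint
is applied, and overlapping osteons are retained and unioned — merged
osteons occur in remodelling bone and are a deliberate feature, not a
defect.  Each axis direction is
`(sin θ cos φ, sin θ sin φ, cos θ)` with tilt θ drawn from the osteon
inclination range and azimuth φ uniform on [0°, 360°); the axis is
clipped at its first exit through the top **or a lateral wall**, so
inclined osteons near the boundary never leave the volume.  For the
tubular variant the lateral exit is found by marching 256 samples along
the ray and bisecting the first crossing (40 iterations, i.e. to
machine-level accuracy relative to the model size).

A Haversian canal must fit inside its osteon.  A drawn canal diameter
at or above 0.9 × the osteon diameter is redrawn (up to 100 times, on a
per-osteon substream so neighbouring osteons keep their aligned draws)
and finally clamped to 0.9 × the osteon diameter with a warning.  The
0.9 guard and the redraw-then-clamp policy are our choice; nothing in
the underlying anatomy dictates how a non-fitting draw is resolved.

Interconnection points (IPs) — the candidate attachment sites of
Volkmann canals — are laid along each axis at arc lengths s, 2s, 3s …
strictly inside the axis length, with one spacing s drawn per osteon
from the `DBVC` range ("equally distanced" points argue for one draw per
osteon rather than per gap).

### Volkmann connectivity

Where Volkmann canals attach is the one genuinely open design choice:
anatomically they are short transverse channels connecting nearby
Haversian canals, but no closed-form rule for *which* canals is
available.  We link each IP to the nearest IP (3D distance) on each of
its osteon's `neighbor_k` nearest neighbouring osteons (k-nearest base
centres), de-duplicate unordered pairs, and discard candidates inclined
more than `θVC` from the transverse plane.  An earlier variant
restricted neighbours to the first Delaunay ring of the base centres;
that caps connectivity at the mean Delaunay degree (≈ 6) and tops out
near 2.7 % Volkmann porosity for a dense healthy model — below the
physiological 6 ± 3 % band — so the ring restriction was dropped in
favour of the plain k-nearest rule.

`neighbor_k` is the connectivity-density dial.  Its default, **9**, was
calibrated once so that the dense healthy validation model (Model I,
22 osteons/mm²) lands its Volkmann porosity inside the physiological
6 ± 3 % band (measured 5.7 ± 0.7 %); k = 8 gives 4.4 %, k = 10 gives
6.4 %.  The count-based (rather than radius-based) neighbourhood is
intentional: in sparse, osteoporotic tissue the canal network still
connects each canal to a similar number of neighbours over longer
distances, which is what keeps the osteoporotic validation model above
the 20 % overall-porosity threshold.  A fixed-radius rule was evaluated
and rejected because it starves sparse models of connectivity.

### Randomness

All draws derive from one integer master seed.  Each class of choice
(osteon position, diameter, tilt, azimuth, cement thickness, Haversian
diameter, Haversian redraw, Volkmann spacing, Volkmann diameter) owns a
named substream — a `numpy` generator seeded by
`SeedSequence(master_seed, spawn_key=(crc32(name), subkey))` — and the
i-th variate of a substream is a pure function of (master seed, name,
i).  Every range draw uses inverse-transform sampling,
`lo + u · (hi − lo)`: widening a range under the same seed maps all
draws monotonically, which makes monotonicity properties (e.g. larger
Haversian bounds never shrink canal volume) exactly testable.  The
distribution within each range is uniform; nothing in the admissible
data argues for another shape, and uniform maximises spread across the
physiological interval.

## Voxel CSG

The skeleton is rendered on an isotropic voxel grid covering the
bounding box of the macro shape.  Each voxel centre is classified by
point membership in the primitives, painted in ascending precedence

    OUTSIDE < MATRIX < CEMENT < VOLKMANN < HAVERSIAN

so later paints win.  Consequences: a canal-junction voxel counts once,
as Haversian, making overall = Haversian + Volkmann an exact identity;
cement annuli pierced by a canal yield to the canal; nothing ever
paints over OUTSIDE, which clips every primitive at the macro-shape
boundary (boundary-intersecting canals contribute only their inside
portion, as a volume *fraction* requires).  Painting order within one
label is immaterial, so the labelling is independent of primitive
order.  The cement annulus sits **outside** the osteon radius
(thickness added outward), matching the anatomical picture of a cement
line surrounding its osteon; cement is mineralised tissue and counts in
the solid denominator, never as porosity (at 0–5 µm thickness its
inclusion moves porosity by < 0.5 points).

Membership is voxel-centre only; no partial-volume weighting.  The
resulting bias is O(h) in the voxel size h and unbiased in expectation
for randomly placed features; a single 100 µm canal reproduces
π r² L / V within 2 % at h = 5 µm.  Default h = 5 µm resolves the
smallest healthy feature (40 µm Volkmann canals → 8 voxels across)
while keeping the 3 × 1.5 × 0.75 mm validation prism at 27 M voxels;
a warning fires when h exceeds a quarter of the smallest canal
diameter, and a hard cap (2 × 10⁸ voxels, configurable) guards
against accidental memory blow-ups.

Surfaces are extracted per export level (full printable solid = matrix
plus cement with canal voids; osteons; cement; canals-as-solids) by
marching cubes on the one-voxel-padded binary mask, which yields a
closed, consistently wound triangle mesh; meshes are exported as binary
(or ASCII) STL in mm.  No smoothing or decimation is applied beyond
what watertightness requires.

Isotropic scaling multiplies every coordinate, radius and length-like
parameter by the factor (density by its inverse square); porosity is a
volume ratio and is invariant when the voxel size is scaled
identically — the 5× scaled healthy model agrees with the 1× model to
well under 0.5 porosity points.

## Porosity check and classification

Porosity fractions are voxel counts over the non-OUTSIDE voxel count.
The healthy verdict keys on the overall band 14 ± 6 % (edges
inclusive); the per-canal bands (Haversian 8 ± 3 %, Volkmann 6 ± 3 %)
are reported as advisory pass/fail because published tabulations
disagree on which canal system carries which share — we follow the
assignment consistent with healthy-model outcomes (Haversian the larger
share) and always report both.  Overall porosity above 20 % adds an
osteoporosis-suggestive note.

An analytic oracle cross-checks the simulation: in the dilute,
fully-interior limit the expected Haversian fraction is

    E[φ_H] = OnDn · (π/4) · E[d²] · E[sec θ],   E[d²] = (lo² + lo·hi + hi²)/3

with d uniform on the Haversian diameter range and E[sec θ] by
quadrature over the inclination range.  Wall clipping and canal merging
make the simulated mean run ~2–8 % below this bound (most visibly for
the osteoporotic model, whose 95–150 µm canals merge often); the
seed-averaged simulation agrees with the oracle within 10 % relative
for all three validation models.

## What the validation models do and do not show

The three bundled configurations span a dense healthy, a moderate
healthy, and a sparse osteoporotic microstructure on a
3 × 1.5 × 0.75 mm prism.  Replication runs use 20 seeds per model
(standard error of the mean Haversian porosity ≈ 0.06 points, far
inside the comparison tolerances) at 10 µm voxels in the test suite and
5 µm in the acceptance script; the single-canal and convergence checks
establish that the 10 µm coarsening moves porosity by well under half a
point.  Passing these checks shows the generator reproduces the
*statistics* the parameters encode — exact osteon counts, canal
fractions, band classifications, scale invariance — for straight-axis,
uniform-draw microstructure.  It does not show fidelity to any real
specimen: real osteons curve and branch, canal diameters are not
uniform within their ranges, lacunae and canaliculi (below this model's
scale) are absent, and published single-model porosity values carry
seed-to-seed scatter of roughly ±1–2 points that averaged replication
deliberately smooths away.

## Known limitations

- Osteon axes are straight; no branching, drift or curvature.
- The Volkmann linking rule is a modelling choice; its `neighbor_k`
  default is calibrated against the healthy Volkmann band, and
  connectivity statistics for deliberately abnormal inputs inherit that
  choice rather than being independently validated.
- Voxel-centre membership slightly under-resolves cement lines thinner
  than one voxel (they are solid tissue, so porosity is unaffected).
- Tube cross-sections are simple polygons; free-form CAD curves must be
  approximated polygonally before input.
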