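# Methods

## Problem and measurement model

An array of radiopaque suture-knot markers is tied to soft tissue
(eight tendon markers T1–T8 in the validation layout; the four
lateral-row markers T1, T3, T5, T7 in the clinical layout) and three
bone markers H1–H3 are fixed in the humerus. Each CT scan yields one
world-millimetre point per marker; all science downstream is geometry
on those points. Three modelling commitments define the method:

* **Markers are points.** A knot is reduced to the volumetric centroid
  of its supra-threshold voxels. The centroid of a compact symmetric
  blob is robust to the exact segmentation boundary and attains
  sub-voxel accuracy through partial-volume averaging.
* **Bone is rigid.** The scapula defines the common world frame over
  time (follow-up scans are rigidly registered to the reference scan
  through scapular landmarks), and the humerus carries the virtual
  markers: software-only points placed once, in the reference scan,
  along the lateral edge of the rotator cuff footprint, and mapped
  into each follow-up by the least-squares rigid transform between the
  H1–H3 positions in the two scans.
* **Soft tissue is not rigid** — that is the signal. Tendon retraction
  is read out as growth of the medio-lateral lengths between footprint
  virtual markers and their tendon partners (V1T1, V2T3, V3T5, V4T7).

## Coordinate conventions

Volumes are handled in the LPS world frame native to DICOM-derived CT
(NIfTI RAS headers are converted on load by SimpleITK). Voxel index
(0,0,0) addresses the **center** of the corner voxel; indices are
0-based and fractional indices are meaningful. Landmarks and marker
seeds are supplied in world mm of their own scan, never as voxel
indices, decoupling annotation from storage layout.

Anatomical frames are right-handed orthonormal triads
(lateral, anterior, superior):

* scapula — lateral = unit(TS→AA); superior = component of AI→AA
  orthogonal to lateral; anterior = superior × lateral; origin AA;
* humerus — superior = unit(elbow midpoint→HH); lateral = component
  of ME→LE orthogonal to superior; anterior = superior × lateral;
  origin HH. HH may be given directly or as the algebraic
  least-squares sphere center of ≥5 head-surface points.

Because AA/AI and LE are lateral or superior on either shoulder, the
lateral and superior axes are anatomically true for both sides; the
anterior axis is the forced third right-handed axis and points
dorsally on left shoulders. Since scapular and humeral frames flip
together, the relative orientation angles are side-agnostic; the study
`side` flag only selects direction words for signed angles. A
mirrored left-side landmark set therefore yields exactly the mirrored
lateral axis, which is the property that matters for retraction
(medial = −lateral) being measured away from the midline on either
side.

Gram–Schmidt order is fixed as written above so results are bit
reproducible. Landmark triangles with area < 1 mm² are rejected as
collinear.

## Localization parameters

* `threshold_hu` (default **800 HU**): above cancellous bone and soft
  tissue, below the barium knot's plateau (~2000 HU in the phantom;
  the true knot HU is scanner- and batch-dependent, so this is a
  config knob, not a constant).
* 26-connectivity; component size gate **3–500 voxels** (~0.1–75 mm³
  at 0.5×0.5×0.6 mm). The lower gate removes noise specks, the upper
  gate removes cortical bone and metal hardware, which also exceed
  the threshold but are orders of magnitude larger than a ~1.5 mm
  knot.
* Centroid weighting: **uniform** by default (the volumetric
  centroid); intensity weighting is available but shifts the estimate
  toward the blob core, which adds nothing for symmetric knots.
* Seed assignment: greedy nearest seed-to-centroid matching, distance
  cap **10 mm** (knots are ~1 mm; 10 mm tolerates sloppy clicks while
  preventing cross-marker capture), ties broken lexicographically by
  label. A seed whose only in-cap component was claimed by a nearer
  seed is an ambiguity error; a seed with no in-cap component is a
  warning, and measurements touching it are reported missing rather
  than failing the scan.

## Rigid fitting

The Kabsch closed form (SVD of the cross-covariance of centered point
sets, smallest-singular-vector sign flip) returns the best *proper*
rotation; reflections are rejected at the type level. Exactly-three
point fits are accepted — rotation is fully determined for a
non-collinear triad — with collinearity gated at a smallest triangle
altitude of 0.5 mm. The fit RMS is reported alongside every transform
(registration quality over scapular landmarks; imputation quality over
bone markers) and surfaced in pipeline reports.

Registration is landmark-based, not intensity-based, by design: every
reported measurement is inter-marker or frame-relative, so a
deterministic, millisecond-scale landmark fit suffices; an
intensity-based backend would change no downstream contract and is a
declared extension point.

## Areas and angles

Quadrilateral vertex order follows the measurement name as printed in
study tables (`V1V2T3T1` ⇒ perimeter V1→V2→T3→T1). The area is the
mean of the two diagonal triangulations; for planar quads they agree
(the shoelace value), for warped quads the swap-average is a symmetric
compromise and is invariant under cyclic relabeling.

Orientation angles are projected angles: both axes are projected onto
the plane and the angle between the projections taken. Reported
values are unsigned magnitudes in [0°, 180°] — the tabulated
convention, where direction words live in the row label — with a
signed variant (oriented by the plane normal, (−180°, 180°])
available. When a projection retains less than 1e-6 of its vector's
norm the configuration is gimbal-like and an error is raised rather
than returning noise.

## Statistics

Precision of a measurement class is the unweighted mean of the
per-measurement sample SDs (n−1 denominator) over repeat scans.
Longitudinal change is final − baseline per measurement, summarized as
mean ± sample SD of the changes; the n−1 choice is self-consistent
with the bundled patient table, whose four medio-lateral changes
(18.4, 23.3, 17.6, 17.0 mm) give 19 ± 3 mm only under n−1 (n would
round the SD to 2). Display rounding (lengths/areas one decimal,
angles to the degree, summaries to the nearest unit) is applied only
at the reporting boundary; all internal values are unrounded.

## Phantom: what it emulates, and what it does not

The phantom renders markers as spheres of equivalent volume
(r = 0.75 mm, 2000 HU) rather than knot shapes: the centroid contract
is shape-robust and a knot geometry would add untestable detail. A
humeral-head bone sphere (r = 10 mm, 1200 HU) exercises the size
gate. Voxel coverage is computed on a 3×3×3 supersample so
partial-volume fractions — the mechanism behind sub-voxel centroids —
are represented rather than quantized; a Gaussian blur (default
0.8 mm FWHM) stands in for the reconstruction kernel, and i.i.d.
Gaussian noise (σ = 20 HU for stochastic studies) for quantum noise.
Default grid: 128×128×80 voxels at 0.5×0.5×0.6 mm, sized so all
markers plus retracted positions stay in-volume while a three-scan
study renders in ~1 s.

Motion scripts pose each timepoint relative to baseline: per-marker
medial retraction, optional humeral rotation about a scapular axis
through the humeral head, and whole-scan rigid repositioning on the
fixed scanner grid. The repeat-scan script repositions by a 0.3 mm
translation plus a 0.3° rotation (a pure translation would leave the
resampling pattern too correlated between repeats). The default
patient script uses the bundled patient table's medio-lateral
trajectories (final-visit mean retraction 19.075 mm) with humeral
pose held fixed, so scripted retraction maps one-to-one onto length
changes; humeral rotation is available but deliberately not in the
default, because footprint virtual markers ride with the humerus and
rotation adds a real (not artifactual) confound to V–T lengths that
deserves its own experiment.

What passing phantom tests do **not** show about real data: analyst
variability in landmark and seed placement (landmarks are exact in
the phantom, so phantom angle precision is ~0), tissue deformation
between scans, beam hardening and metal artifacts, and knot-shape
asymmetry. Phantom precisions (~0.06 mm pooled lengths) are therefore
a floor, roughly an order of magnitude below realistic repeat-scan
precision (~0.66 mm); agreement in order of magnitude and the <1 mm
bound are the meaningful checks.

## Numerical choices and degenerate inputs

* Frame/transform orthonormality validated at 1e-9; fit_rigid
  re-orthonormalizes its rotation by polar decomposition before
  validation.
* Affine round-trips are exact to <1e-9 voxel; file round-trips are
  lossless in intensity and ≤1e-6 elementwise in the affine (NIfTI
  stores float32 spacing).
* Degenerate quads return area 0; empty components, collinear triads,
  missing landmarks and sub-floor projections raise typed errors
  (`DegenerateGeometryError`, `IllConditionedProjectionError`, ...)
  rather than returning numbers.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); no global state. Identical configs
  byte-reproduce `measurements.csv` and `summary.json`; the manifest
  additionally records a wall-clock timestamp and is excluded from
  byte-identity.

## Known limitations

Marker identification is automated (threshold + components + seeds)
where a human analyst may click voxels interactively; the automation
is reproducible but its threshold default is a calibrated choice, not
a measured property of the marker material. Registration assumes the
scapular landmarks are re-identified consistently across scans; their
annotation error propagates directly into the longitudinal frame.
Only rigid registration is offered — scapulothoracic motion or growth
would violate it. Statistics are per-specimen descriptive summaries;
cohort-level inference is out of scope.
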