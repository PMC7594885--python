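# Methods

This note records the models, conventions and numerical choices behind
`isodrr`, and what the synthetic validation does and does not demonstrate.

## Patient frame and isocentric geometry

All modules share one right-handed patient frame: +X toward the patient's
left, +Y anterior, +Z superior, origin at the isocentre — the confluence of
the median-sagittal plane, the auricular (coronal) plane through both
external auditory meatus centres, and the anthropological (axial) plane
through their superior borders.

A projection is parameterized by two angles and two displacements:

- `cr(α, β) = R_M(β) · R_L(α) · (+Y)`, with `R_L` a right-handed rotation
  about +X (transverse axis) and `R_M` a right-handed rotation about +Y
  (anteroposterior axis).  The prose description of the angle convention
  ("angles increase clockwise") is ambiguous in 3-D; the signs here are
  *defined* by two anchor configurations that the test suite asserts:
  α = β = 0 puts the CR along +Y (posterior entry), and α = β = 90 puts it
  along +X (entering at the right EAM, travelling right → left).  With
  this order, β alone leaves the base CR fixed (the M axis *is* the base
  CR), and a β sweep at α = 90 traces a circle in the coronal plane.
- Displacements move the isocentre: raise/lower along the AP axis (the
  table vertical for a supine subject; raise(+) → −Y) and cranial/caudal
  along the longitudinal axis with cranial negative (long = −40 mm
  displaces the isocentre 40 mm superiorly).  Whether these displacements
  are best read in a room frame or the patient frame is not decidable from
  the parameterization itself; the mapping is our convention, isolated in
  `geometry.displaced_isocentre`.  All three packaged study projections
  use raise = 0, so only the cranial/caudal sign is exercised.
- `source = iso − (SID − OID)·cr`, `det_centre = iso + OID·cr`; the
  receptor is always perpendicular to the CR (oblique receptors are out of
  scope).  Defaults SID = 1000 mm, OID = 250 mm, detector 1024 × 1024
  pixels at 0.3 mm pitch (≈ a 24 × 30 cm film).  In-plane detector axes:
  `u_hat` is the normalized projection of +X onto the detector plane,
  falling back to +Z when the CR is transverse (lateral projections, where
  the fallback is logged); `v_hat = cr × u_hat`.  Pixel (0,0) is centred at
  `det_centre − ((n_u−1)/2)·pitch·u_hat − ((n_v−1)/2)·pitch·v_hat`.

## Renderer

One ray per pixel from the single focal spot through the pixel centre — a
divergent beam, which is what produces the `SID/(SID−OID)` magnification
and the depth-dependent distortion that parallel-ray shortcuts cannot.

The transport model is geometric, not radiometric: intensity codes map
linearly to attenuation (`mu_per_code`, default 7 × 10⁻⁴ per code per mm,
chosen so a soft-tissue code of 30 gives a water-like μ ≈ 0.02 mm⁻¹), and
each ray accumulates `∫ μ ds` between the entry and exit points of the
volume's physical bounding box (slab intersection; rays that miss
contribute exactly zero).  Sampling is composite midpoint with trilinear
interpolation; the requested step (default half the smallest voxel
spacing) is rounded down so an integer number of sub-steps tiles each
chord exactly, which makes the homogeneous-box integral exact up to
interpolation effects and gives monotone convergence as the step halves.
Points inside the bounding box but beyond the outermost voxel *centres*
take the nearest voxel's value, so a homogeneous box integrates to its
full physical chord.

Display grey is `255·clip((x − (level − w/2))/w, 0, 1)` of the raw
integral, rounded half away from zero — grey increases with attenuation
("bone bright").  Window/level default to the 1st/99th percentiles of the
integral map.  Applying the display map to the raw integral rather than to
the Beer–Lambert transmission `exp(−∫μ)` is a deliberate choice: both are
monotone in the line integral, so landmark positions and distances — the
quantities validated here — are unaffected, and the raw integral keeps the
marker blobs linear.  `render.transmission` exposes the physical quantity
for anyone who needs it.  Scatter, beam hardening, focal-spot blur, noise
and dose are out of scope.

## Volumes and packing

Volumes are unsigned-integer attenuation codes with per-axis spacing, an
origin at the centre of voxel (0,0,0) (MetaImage convention) and an axes
string mapping array axes to anatomical directions.  `pack_to_cube`
emulates the simulator-style preprocessing of CT data: trilinear resample
onto a 256³ grid whose per-axis spacing is `extent/256` (physical extent
preserved to within one voxel), then a global min–max rescale to [0, 255].
The rescale rule and interpolation kernel of the commercial packer are not
public; min–max plus trilinear is our documented choice.  A constant
volume has no dynamic range and packs to zeros.  I/O is uncompressed
MetaImage (`.mhd` + `.raw`) through SimpleITK, with header pre-validation
so malformed headers, truncated payloads and unsupported element types
produce distinct errors.

## Synthetic head phantom

The phantom emulates an anthropomorphic skull at the level needed for
*geometric* validation: an outer soft-tissue ellipsoid (code 30), an
ellipsoidal bone shell 6 mm thick (code 160), and 2 mm-radius marker
spheres (additive code, saturating at 255) at 15 named cephalometric
landmark positions, voxelized at voxel centres onto a 256³, 1 mm grid
centred on the isocentre.  Midline landmarks sit exactly on the
median-sagittal plane and left/right pairs are exact mirror images.
Landmark coordinates are anatomically plausible for an adult skull but
were chosen, once, so that the projected marker blobs of each measured
triplet stay well separated (≥ ~10 mm) on the study projections; the
"Porion" marker is displaced 10 mm posteriorly from the EAM rim for the
same reason.  The catalogue of exact marker centres is returned alongside
the volume and is the ground truth for the analytic oracle.  A seed
controls only optional soft-tissue texture noise (off by default);
geometry is deterministic.  What the phantom does *not* emulate: real
bone texture, an extended petrous ridge (a single representative midline
point stands in), overlapping fine anatomy, and film/screen physics — so
passing the synthetic validation demonstrates correctness of projection
geometry, not realism of image appearance or of human landmark
identification on real anatomy.

## Measurement pipeline

The analytic oracle projects exact landmark coordinates through the focal
point onto the detector plane.  The image route detects each rendered
marker inside a square region of interest (± 5 mm by default) centred on
the analytically predicted position — the in-silico analogue of an
observer who knows roughly where a landmark lies: a least-squares
background plane fitted to the ROI border is subtracted, the residual is
thresholded (Otsu, floored at 3 grey levels so that featureless ROIs
report "landmark not found" rather than fitting noise), exactly one
connected component is required, and the intensity-weighted centroid gives
the sub-pixel centre.  Distances are Euclidean in detector millimetres;
observer emulation optionally rounds to whole millimetres (half away from
zero), matching ruler readings.

The six packaged measurement definitions follow the validated design: two
distances per anatomical plane, each read on the projection whose receptor
is approximately perpendicular to that plane (sagittal pair on the
occipito-frontal 15° view; coronal and axial pairs on the left lateral).

## Agreement statistics

`icc_a_k` implements McGraw–Wong ICC(A,k) from the two-way ANOVA mean
squares, `(MS_R − MS_E)/(MS_R + (MS_C − MS_E)/n)`; the 95% interval is the
F-based single-measure interval (Satterthwaite degrees of freedom) stepped
up with the Spearman–Brown relation, the convention SPSS uses for
average-measures absolute agreement.  Degenerate inputs: zero total
variance is reported as perfect agreement (1.0) with a logged note, and a
point estimate ≥ 1 short-circuits the interval to [1, 1].  The test suite
cross-checks the point estimates against an independent implementation
(pingouin) to 10⁻¹⁰.

`bland_altman` uses differences `a − b`, sample SD (n − 1) and fixed
± 1.96 limits (not a t quantile), all computed from unrounded
intermediates; rounding (1 decimal for summary tables, 3 for the ICC,
whole mm for simulated observers) happens only at report time, and always
half away from zero.  Bland–Altman operates on the six per-measurement
means, not on the 24 raw readings.

The observer simulator adds independent `N(0, σ²)` noise per cell
(default σ = 1.5 mm, inside the 1–6 mm spread real observer panels show)
and optional whole-mm rounding.  Note that rounding adds ≈ 1/12 mm² of
quantization variance, so the ANOVA error-mean-square recovery of σ² is
checked with rounding off.

## Pipeline and problem sizes

`run_validation` chains phantom → three DRRs → image measurement →
analytic oracle → simulated panel → ICC + Bland–Altman, writing images,
CSVs, a report, a Bland–Altman plot and a JSON manifest; identical
configuration and seed give byte-identical CSV outputs.  The library and
CLI default to the full 1024² / 0.3 mm detector; the test suite and the
worked examples use 256² at 1.2 mm pitch (same 30.7 cm field of view),
which keeps a full validation run under a minute on one core while still
resolving marker centroids to a fraction of a millimetre.

## Known limitations

- Fixed-step trilinear sampling, not exact radiological path lengths
  (Siddon); accuracy is controlled by `step_mm` and bounded by the
  analytic-box oracle in the tests.
- The phantom's marker-sphere centroids, not anatomy, are what the image
  route localizes; human landmark-identification error on real
  radiographs is represented only through the observer noise model.
- Lateral isocentre displacement and non-perpendicular receptors are
  intentionally unsupported.
- The agreement between the analytic oracle and the image route validates
  this renderer's geometry; it says nothing about radiometric fidelity
  (grey-scale response, dose), which would need a step-wedge style study.
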