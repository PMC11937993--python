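# Methods

`nanoruler` analyses 3D DNA-PAINT localization data of the T4
bacteriophage used as a biological nanoscale ruler. Because no raw
acquisitions are distributed with the package, a synthetic-data generator
reproduces the statistical structure of such acquisitions from the known
virus geometry, and every measurement is validated by parameter recovery:
simulate at stated conditions, measure, compare with the known truth.

## Virus geometry

The capsid is modelled at two coupled levels.

* **Frame.** A 12-vertex prolate icosahedral frame: two poles and two
  pentagonal rings of five vertices, the rings mutually rotated by a skew
  angle α. The end caps are fixed exactly by the equilateral edge length
  *e* (ring radius R = e / 2 sin 36°, pole height h = √(e² − R²)); α is
  solved by least squares so the two families of inter-ring chords best
  match the target scalene edge lengths. For the default parameters
  (width 86 nm, length 120 nm, edges 50/70/73 nm) the solve gives
  α ≈ 30.6° and realises cross edges of 71.05/73.84 nm (residual 1.35 nm
  — the published 50/70/73 and 86 nm values are independent roundings and
  cannot all be met exactly; the edge lengths take priority, and the
  width is enforced only as a target with a 1 nm tolerance,
  2R = 85.06 nm). The frame carries the 20 faces (ten equilateral end-cap
  triangles, ten scalene mid-section triangles), the gp24 pentamer sites
  at the 11 non-tail vertices, and the idealised Hoc/Soc per-face
  triangular lattices (14 nm spacing).
* **Envelope.** A rounded surface of revolution with exactly the target
  width and length: a cylinder spanning the inter-ring section, closed by
  ellipsoidal caps reaching the poles. Whole-virus (polyclonal) labelling
  and registration reference clouds sample this envelope — the real
  capsid has rounded edges, and sampling the faceted frame instead
  biases noise-free wall measurements inward by 2–3 nm. The faceted
  surface remains available (`envelope="faceted"`) and is what the
  registration recovery tests use, because the rounded envelope is
  axisymmetric and azimuth about the virus axis is unidentifiable from
  it.

The tail is a coaxial tube (24 nm diameter, 140 nm long including the
neck) with a basal plate (50 nm diameter over the lowest 15% of the tail,
i.e. 21 nm). The basal plate exposes its side wall and its top rim
annulus; the substrate-contact face is not labelable (it is pressed
against the coverslip for a standing particle), and the hub of the plate
is occupied by the tube exit. Convention: virus axis = +z, substrate
z = 0, tail on [0, 140], capsid centre at 200 nm. All lengths in nm.

## Synthetic data generator

The generator emulates immunolabelled DNA-PAINT acquisitions:

* **Sites.** Whole-virus labelling places candidate epitopes uniformly on
  the surface at 0.01 /nm² by default (one per ~10×10 nm patch, dense
  polyclonal serum labelling; at much sparser densities per-particle
  profiles degenerate into single-strand clumps). A separate tail density
  is exposed because the published tail measurements come from particles
  with visibly dense tail labelling (we use 0.03 /nm² for those
  ensembles).
* **Labelling.** Each site carries a docking strand with probability
  `ele` (default 0.5) and is displaced by the antibody/nanobody linkage
  error: magnitude N(7, 7/3) nm clipped at zero, direction uniform on the
  outward hemisphere around the local surface normal (an isotropic mode
  exists; the outward default is what inflates measured widths above the
  model truth, as observed experimentally). gp24 site normals are taken
  from the rounded envelope, which is what keeps the 70/73 nm cross edges
  nearly uninflected (cylindrical push at the rings) while the 50 nm
  end-cap edges inflate into the mid-50s.
* **Localizations.** Each strand yields Poisson(20) binding events
  (≈100 000 frames at 50 Hz) at uniform random frames; each event adds
  Gaussian noise of 3 nm laterally and 6 nm axially and draws a
  log-normal photon count with mean 53 000 over 300 background photons
  per pixel. These two SDs are the fixed per-event precision; the
  astigmatism module supplies photon-derived values when the frame-level
  path is used.
* **Fields.** Particles are deposited without overlap at ≈1.25/µm²
  (≈500 per 400 µm²): 65% standing (tail down, Gaussian tilt of SD 5°)
  and 35% lying (axis in-plane, resting at one capsid radius). Overlay
  flags: 26% of particles aggregate as touching dimers (pairs share
  orientation, offset one capsid diameter perpendicular to the axis) and
  6% are blurred (15 nm isotropic jitter on all their localizations,
  emulating particles unstable during acquisition). Optional per-frame
  drift is added last. Ground truth (poses, classes, per-localization
  particle/site ids) is recorded.

What the generator does **not** emulate: imager-strand kinetics (on/off
rates and multi-blink temporal correlation), gold fiducials, detector
pixelation of the localization path, sample-dependent background
structure, partial tails or broken particles. Passing recovery tests
therefore validate the measurement chain under the stated noise model,
not robustness to every artefact of real acquisitions.

## Measurement chain

* **Profiles.** A measurement selects a slab (projection depth) and a
  stripe through the structure and histograms the localizations along the
  measurement axis at 6 nm bins (the standard render bin). Defaults
  follow published practice: 100 nm slab for x,y capsid widths with a
  17 nm cross-section stripe through the centre, a 70 nm central slab for
  x,z widths, 17 nm slice + 17 nm stripe for averaged structures. Two
  Gaussians plus a constant baseline are fitted by bounded L-BFGS-B least
  squares with an analytic gradient; initialisation uses local moments of
  the two dominant well-separated peaks with multiple starts. Fits that
  fail to converge, collide (< 2 bins apart) or pin a centre at the
  histogram boundary are flagged artifacts and excluded. Ensembles are
  filtered with the modified Z-score (0.6745·(x−median)/MAD, threshold
  3.5, Iglewicz–Hoban convention; MAD = 0 keeps all values with a
  warning) and reported as mean ± SD with n.
* **Measurement frames.** Standing capsids are measured in the lab frame.
  Tail measurements first align the particle by its principal axis
  (fat-end-up) — a 17 nm stripe walked along a 140 nm tail is spoiled by
  even the 5° standing tilt. The capsid centre estimate uses the mean z
  of large-radius (wall) localizations inside a symmetric window, which
  is immune to the outward-linkage smear of the top pole and to the tail.
* **Tail length.** The tail-region z-profile is a top-hat (the tube
  plateau dominates, the ends are edges), which a two-Gaussian model with
  a constant baseline cannot represent; the endpoint Gaussians are
  therefore fitted to the absolute derivative of the smoothed profile —
  each edge becomes a peak at the edge centre — with one centre
  constrained to the basal (substrate) window and one to the
  capsid-junction window. The radial gate follows the tail's own envelope
  (wide at the baseplate, narrow at the tube) plus a small margin.
* **gp24 triangles.** gp24 localizations are clustered (DBSCAN, 20 nm,
  ≥ 5 points), cluster centres of mass are matched to the nearest frame
  vertex under the particle's pose, and 3D distances are reported per
  edge family (equilateral end-cap edges vs long scalene cross edges).
* **Particle analysis.** Fields are segmented by DBSCAN (30 nm, 10
  neighbours) — our reading of the published "custom algorithm" plus
  manual selection. Candidates are scored for the toroidal capsid
  signature: ring-peak vs central annulus density in the capsid slab,
  with a size gate of ±30% around the model radius. Standing vs lying is
  decided by the capsid-region centroid height (threshold 150 nm = ¾ of
  the nominal 200 nm, tolerant to tilt). Dimers are flagged when the
  robust extent perpendicular to the particle axis exceeds 1.5× the
  capsid width; their ring features are re-measured on the dominant lobe
  (centre anchored one ring radius inside the outer projection edge —
  clustering centres are biased inward for touching rings). Blur is
  flagged when the robust (MAD) radial ring spread exceeds 11 nm: clean
  rings sit near 6 nm and 15 nm jitter takes them to ≈16 nm, so the
  threshold sits in the empty valley between the two populations.
* **Drift.** The acquisition is split into 20 windows; all window pairs
  are cross-correlated on the xy and xz projections of the 6 nm render
  (the marginals of the 3D correlation — standard SMLM practice, far
  cheaper than the 3D volume), with log-parabola sub-pixel interpolation;
  per-window offsets are solved by weighted least squares over the
  redundant pair set, anchored at window 1, and interpolated linearly.
  Low-count windows are down-weighted. A fiducial mode (smoothed mean
  path of marked clusters) is included. The published correlation method
  itself is unpublished; redundant cross-correlation is the closest
  established reading. Accuracy statements remove the arbitrary constant
  offset (the trajectory zero point).
* **Registration and fusion.** Global registration is RANSAC over
  descriptor correspondences on 8 nm voxel-downsampled clouds
  (rotation-invariant shape-context descriptors: each point's histogram
  of distances to all others; 3-point hypotheses screened by pairwise
  length consistency, scored by inlier fraction). Local refinement is
  point-to-point ICP (k-d tree + Kabsch; RMS non-increasing). Because a
  quasi-ellipsoidal particle offers many high-fitness but wrong consensi,
  the pipeline runs several independent RANSAC starts, refines each, and
  keeps the lowest terminal RMS (the correct basin is ~3 nm better).
  Fusion aligns every cloud to an evolving average (template-free) or to
  the geometric model cloud (model-guided), pools the localizations, and
  measures the average with the 17 nm slice/stripe procedure. The guided
  gp24 average augments the particle set by 10% synthetic model particles
  that are removed again before pooling. Transform-recovery statistics
  are quoted modulo the C5 symmetry of the virus (72° rotations about the
  axis are physically equivalent); with the axisymmetric rounded
  reference, azimuth is additionally free, which is harmless for
  width/length measurements but means guided gp24 averages preserve the
  vertex rings rather than individual vertex azimuths.
* **Astigmatism.** The defocus model is w(z) = w0·√(1 + u² + Au³ + Bu⁴),
  u = (z−c)/d, per axis; defaults w0 = 150 nm, d = 400 nm, A = B = 0,
  with the two axes focusing at ∓250 nm (typical cylindrical-lens optics;
  the experimental calibration behind the published ≈3/≈6 nm precision
  figures is not available, so precision targets are property-based, not
  numeric). z is looked up by minimising the distance in √width space
  over the calibrated range (standard for astigmatic SMLM; boundary
  minima are flagged). The Monte-Carlo precision estimate renders
  pixel-integrated spots from a cubic-spline width model (100 nm pixels,
  15 px patches), adds Poisson noise (EM excess noise ≈ doubled variance,
  toggleable), fits elliptical Gaussians, and reports SDs of x, y and the
  width-lookup z. At 53 000 photons / 300 background the defaults give
  σx,y ≈ 1–1.5 nm and σz ≈ 4–5.5 nm with σz > σx,y at focus and 1/√N
  photon scaling (shot-noise-limited, i.e. without background).

## Numerical choices and degenerate inputs

Histograms pad three empty bins per side so boundary peaks remain
fittable. Noise-free-limit checks sample profiles at 2 nm bins with
σ-scale stripes and margins (6 nm bins cannot resolve σ → 0 walls).
Empty profile regions raise with the region named; empty site sets,
empty fields and zero-event tables return empty objects rather than
raising. Unsolvable geometries (edge/width contradictions, ring
collisions, basal plate narrower than the tube) raise construction
errors naming the violated constraint. All randomness flows through
explicit seeds; identical seeds give byte-identical tables.

## Problem sizes

Default test and acceptance runs use 200-particle capsid ensembles,
60-particle dense-tail ensembles, 126-particle fusion, 430-particle
classification fields (at 6 binding events per strand), 100 registration
trials, and 20 000-frame drift fields — sizes chosen so the full chain
exercises every stage at comfortable statistical power.

## Known limitations

* The basal plate and neck are simplified cylinders/annuli; wedge
  structure, short tail fibers and the fibritin whiskers are not
  modelled (fibritin anchors exist as a site set only).
* Hoc/Soc lattices are idealised per-face triangular lattices, not the
  true quasi-equivalent T=13 lattice; only the 14 nm spacing is used.
* Measured tail-length and basal-width values carry 1–3 nm method bias
  (edge-centre vs structure-edge, annulus fill), comparable to the
  spread of the corresponding published values.
* The guided gp24 average constrains vertex rings, not vertex azimuths,
  when the rounded reference is used (see above).
* Drift recovery assumes structures persist across windows; it was not
  designed for fields sparser than a handful of particles.
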