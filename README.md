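# nanoruler

Analysis of the T4 bacteriophage as a three-dimensional biological
nanoscale ruler for single-molecule localization microscopy (SMLM).

T4 is a remarkably convenient reference structure for 3D DNA-PAINT: its
prolate icosahedral capsid (86 nm wide, 120 nm long by cryo-EM) and its
140 × 24 nm tail with a 50 nm basal plate offer calibrated distances from
~140 nm down to the tens of nanometres, and its vertex protein gp24 forms
pentamers at eleven of the twelve capsid vertices, spanning triangles
with 50/70/≈73 nm sides. This package provides, for whoever wants to use
(or simulate using) such a ruler:

* a **parametric T4 geometry** — the 12-vertex icosahedral frame (ten
  equilateral end-cap triangles, ten scalene mid-section triangles),
  a rounded capsid envelope, the tail with basal plate, and labelled
  protein site sets (gp24, Hoc/Soc lattices, fibritin anchors,
  whole-virus surface labelling);
* a **synthetic DNA-PAINT generator** — labelling efficiency, ≈7 nm
  antibody linkage error (outward-hemisphere by default), 3/3/6 nm
  localization noise, photon statistics, particle poses (65% standing /
  35% lying, 26% dimers, 6% blurred) and optional drift, with full
  ground truth;
* the **measurement chain** — drift correction by redundant window
  cross-correlation, DBSCAN segmentation with a toroid (hollow-capsid)
  gate, orientation/aggregation classification, cross-section profiles
  with two-Gaussian (L-BFGS-B) peak fitting and modified Z-score
  filtering, gp24 centre-of-mass triangle distances, astigmatic 3D
  calibration and Monte-Carlo precision estimation, and RANSAC+ICP
  model-guided particle fusion.

The core measurement is simple and explicit: a cross-section profile
N(x) of a slab∩stripe region is fitted with

    N(x) = b + A₁ exp(−(x−c₁)²/2w₁²) + A₂ exp(−(x−c₂)²/2w₂²),

and the structure size is the peak-to-peak distance c₂ − c₁; ensembles
are cleaned with the modified Z-score Mᵢ = 0.6745 (xᵢ − x̃)/MAD at
threshold 3.5 and reported as mean ± SD (n).

## Worked example

Simulate a small field at the default study conditions, classify it, and
recover the generator's composition:

```bash
python analysis/01_simulate_field.py
python analysis/02_classify_field.py
```

```
simulated 200 particles (296785 localizations) -> results/field
{
  "recovered": {
    "n_total": 198,
    "pct_standing": 67.7,
    "pct_lying": 32.3,
    "pct_dimer": 29.3,
    "pct_blurred": 2.0,
    "n_rejected": 2
  },
  "ground_truth": {
    "n_total": 200,
    "pct_standing": 67.0,
    "pct_dimer": 29.0,
    "pct_blurred": 3.5
  }
}
```

The recovered orientation and aggregation percentages match the
generated field within binomial sampling error. Morphometry on standing
particles (`python analysis/03_capsid_tail_measurements.py`):

```
capsid_width_xy     90.77 ±  1.72 nm  (n=194)
capsid_width_xz     92.29 ±  1.81 nm  (n=199)
capsid_length_xz   130.07 ±  5.04 nm  (n=168)
tail_width          28.18 ±  1.37 nm  (n=60)
basal_width         52.69 ±  4.06 nm  (n=58)
tail_length        143.75 ±  4.13 nm  (n=60)
```

The ≈7 nm outward linkage error inflates every measured dimension above
the model truth (86/120/24/50/140 nm) by roughly twice its mean radial
component — exactly the behaviour expected for antibody-labelled
structures. `analysis/04_gp24_triangles.py` measures the gp24 vertex
triangles (≈55.6 nm for the 50 nm end-cap sides, ≈72.1 nm for the
70/73 nm cross sides), `analysis/05_fuse_average.py` builds the
126-particle model-guided average (92.6 × 126.1 nm by the 17 nm
slice/stripe fit), and `analysis/06_drift_and_precision.py` reports the
drift-correction residual (≈0.6 nm RMS for a 50 nm injected drift) and
the Monte-Carlo 3D localization precision.

A thin CLI wraps the same library for shell use:

```bash
nanoruler simulate --out-dir run1
nanoruler detect  --table run1/localizations.csv --out-dir run1
nanoruler measure --table run1/localizations.csv --out-dir run1
nanoruler report  --out-dir run2
```

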