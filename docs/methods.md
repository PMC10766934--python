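# Methods

`volumetrix` is a digital re-creation of a phantom-and-cohort study of
threshold-based thyroid volumetry on quantitative SPECT/CT in Graves'
hyperthyroidism (GH). It answers, in simulation, the questions the physical
experiment answers on a scanner: how does the volume of an iso-contour VOI
("all voxels ≥ f × maximum uptake") depend on the threshold fraction f and on
the target-to-background ratio (T/B), which f best recovers the true volume,
and how do planar (Allen-formula) and tomographic volumetry compare with
ultrasound in a patient cohort.

## The digital phantom

Each thyroid lobe of the physical phantom is a 45° pipe elbow with a 25 mm
bore and a lumen volume of 26.5 mL (53 mL bilateral), placed inside a
NEMA IEC body-phantom tank of 10,122 mL. The elbow lumen is modelled as a
torus sector. The bend radius R is not printed anywhere, so it is calibrated
from Pappus' centroid theorem,

    V = π r² · R · θ   →   R = V / (π r² θ) = 68.74 mm,

which makes the analytic lumen volume exact by construction. The sector chord
(≈ 52.6 mm) is oriented craniocaudally and matches the printed 50 mm part
height well; the full silhouette extent is ≈ 62 mm, consistent with the
planar lobe length of ≈ 6.0 cm the physical study measured. The two lobes are
mirror images across the mid-sagittal plane with a 5 mm gap (the printed pose
is only qualitative); the 3.5 mm wall is metadata and is treated as cold
background. The tank's D-shaped cross-section is replaced by an equal-volume
elliptical cylinder (semi-axes 150 × 115 mm); because the background is
spatially uniform, its shape cannot influence the volumetry.

Voxelization is by voxel centre (no partial-volume supersampling). The
discretization error is O(voxel size): at 0.5 mm the bilateral volume is
53.03 mL (+0.05%), at 1.0 mm 53.13 mL (+0.25%). Geometry tests run at
0.5 mm; imaging experiments at 1.0 mm.

Activity is assigned as two uniform compartments: lobes at 142,857 Bq/mL and
tank at 142,857 / (T/B). The printed preparation narrative (148 MBq in
~103 mL) is internally inconsistent with its own printed concentration by a
factor of ten; the printed pair (142,857; 714 Bq/mL) is self-consistent with
both the dilution arithmetic (142,857 × 50.6 / 10,122 ≈ 714) and T/B 200, so
the printed concentrations are taken as ground truth.

## The imaging emulator

No projector or OSEM reconstruction is implemented. All downstream results
depend only on the effective resolution, the noise level and the T/B of the
*corrected reconstructed* image, so that image is modelled directly:

* **Tomographic**: truth ⊛ isotropic Gaussian PSF (FWHM 10.59 mm, the
  system's printed no-resolution-recovery figure; configurable down to ~7 mm
  to emulate resolution recovery), then per-voxel Poisson counts with
  expectation conc × voxel volume × sensitivity (73.4 cps/MBq) × acquisition
  time (60 frames × 12/15/18 s) × calibration factor (1.0, giving ≈10⁶ total
  counts for the default phantom — the regime the count knobs span).
* **Planar**: anterior line integral with optional Beer–Lambert weighting
  (μ = 0.15 cm⁻¹ at 140 keV; lobes sit 2 cm below the anterior tank surface),
  blurred with an 8 mm planar PSF, scaled to the 300/500/800-kilocount
  acquisition target, then Poisson.

The three count/time settings are treated as the n = 3 replicate structure
behind every "mean ± SD" of the phantom tables. Emulated planar T/B comes out
at ≈ 30/90/150 for tomographic T/B 200/600/1000 — strongly reduced from the
tomographic ratio, as observed (the physical study reports 6/16/24), but no
exact match is claimed: the residual gap is scatter and septal penetration,
which the emulator only exposes as an (off-by-default) additive background
knob.

Known emulator limitations: Poisson noise is applied after the blur, so the
noise is white rather than OSEM-correlated; this makes the noisy maximum a
more biased order statistic than a real reconstruction's. The `raw`
single-voxel maximum is the default reference (mirroring the vendor tool as
understood); a `hottest-n` mean is available to tame the bias.

## Threshold volumetry

`segment_voi` takes all voxels ≥ f × max within a search region (a box around
the lobes dilated by 2 × FWHM), keeps the 26-connected components carrying
the two most intense peaks (the bilateral lobes), and reports whole-voxel
volume. Superlevel sets are nested, so volume is non-increasing in f for any
fixed image — asserted across every sweep. Volume error is
100·|measured − true|/true.

The mechanism behind a low optimal threshold is reproduced, not asserted
numerically: noiseless, the maximum of the blurred 25 mm-bore lobes reaches
≈ 0.93–0.98 of the plateau and the volume-matching fraction sits near 0.4–0.5
(for objects much wider than the PSF the half-max contour recovers volume
within ~3%); with counting noise the reference max is biased upward by the
order statistic, the effective contour level rises, and the volume-matching
fraction drops into the 0.20–0.30 band — the regime in which the physical
study found 25% optimal. Noiseless volumes at a fixed fraction agree across
T/B 200/600/1000 to < 1% (bound asserted: 2%), reproducing the study's
negative finding deterministically.

## Planar volumetry

The vendor's proprietary boundary tool is approximated by a 20% iso-contour,
per the study's own statement of similarity. Two design choices are ours:
delineation runs on a lightly smoothed copy of the image (σ = 1 px) — a
human-drawn boundary on a displayed image is not destabilized by single-pixel
Poisson excursions, whereas a raw-pixel threshold fragments the ROI — and the
fixed background rectangle sits inferior to the gland on the midline, inside
the body outline. If the 20% contour merges the lobes across the gap, the
blob is split at the count-profile valley (the isthmus), as an operator
would. S is the total ROI area (cm²), L the mean row-extent (craniocaudal) of
the two lobes (cm), and V = S·L·K with K = 0.32 (configurable; the
literature range is 0.23–0.32). On the default phantom this yields
S ≈ 32 cm², L ≈ 6.0–6.15 cm and V ≈ 62–64 mL — always above the true 53 mL,
reproducing the overestimation direction (the physical study: 63.0–67.5 mL,
mean error 22.8%).

## Synthetic cohort

True volumes for 40 GH patients are log-normal with moments matched to the
published summary (31.68 ± 15.04 mL); log-normal keeps volumes positive at a
coefficient of variation near 0.5. Measurement channels are multiplicative:
ultrasound = true × (1 + ε_us), planar = true × 1.25 × (1 + ε_p),
SPECT-25% = true × 1.033 × (1 + ε_s), with independent zero-mean Gaussian
relative errors. Lobe dimensions use jittered 5:2:1.7 (L:W:T) shape ratios
rescaled so the two-lobe ellipsoid formula V = π/6·(L1·W1·T1 + L2·W2·T2)
equals the ultrasound volume exactly.

The noise magnitudes are calibration knobs, not measured quantities. They
were fixed once from the closed-form correlation of two multiplicatively
noisy channels sharing a log-normal truth,
r = σ_T² / √((σ_T² + m²(1+cv²)s_a²)(σ_T² + m²(1+cv²)s_b²)): relative SD 0.09
for the ultrasound and SPECT channels gives r(spect, us) ≈ 0.956 and 0.58 for
the planar channel gives r(planar, us) ≈ 0.59, the published correlation
structure. Tests assert only the ordering r(spect, us) > r(planar, us) and
the recovery of the +25% planar bias at large n; no claim of clinical realism
is made beyond the matched moments. What passing cohort tests show is that
the statistics pipeline recovers the parameters the generator put in — not
that real ultrasound or planar measurements behave this way.

A slow image-domain path (`full_chain_patient`) voxelizes each patient's
two-ellipsoid thyroid and runs the full planar and tomographic chains; it is
used for qualitative end-to-end validation (both channels overestimate a
noiseless thyroid; the 25% iso-contour is closer to truth than the Allen
product). A noiseless 25%-of-max contour necessarily overshoots the true
volume (it lies well outside the half-max boundary), so the parametric
channel model — not the image chain — generates the default cohort.

## Statistics

One-way fixed-effects ANOVA with the classical between/within decomposition;
Fisher LSD post-hoc pairwise t-tests on the pooled within-group MSE and df;
Pearson r and the OLS slope b of method-on-reference (ultrasound is the
reference/x variable); Bland–Altman limits of agreement mean ± 1.96 SD
(SD with n−1). Patient method comparisons use paired t-tests (within-subject
design); phantom tables use ANOVA + LSD. Two-sided tests, α = 0.05, no
multiple-testing correction beyond LSD's convention. Calibration is verified
by simulation: null type-I error 0.05 ± 0.02 at 2000 replicates, LoA coverage
≈ 95% at n = 10⁴.

## Numerical choices and degenerate inputs

* FWHM ↔ σ via FWHM = 2√(2 ln 2)·σ; convolution with zero-padding (mass
  preserved to 1e-6 given ≥3σ clearance).
* Thresholding is inclusive (≥); volumes are whole-voxel counts (no
  marching-cubes surface), matching the count × voxel-volume convention.
* A non-positive reference max yields an empty VOI with a warning, never an
  exception; ties in optimal-threshold selection break toward the smaller
  fraction.
* Self-intersecting tori (R ≤ r), lobes outside the tank, overlapping lobes,
  non-positive dimensions/ratios, empty ROIs and zero-variance regressors all
  raise typed errors.
* All stochastic stages consume explicit seeds (`numpy.random.Generator`);
  noiseless pipelines are bit-reproducible, noisy ones seed-reproducible.

## Problem sizes

Default experiments run on the 1 mm grid (≈300 × 230 × 187 voxels), three
T/B levels × three replicates, six threshold fractions; geometry validation
at 0.5 mm; cohort checks at n = 40 (default), 4000 (bias recovery) and 10⁵
(moment matching). A full noisy-plus-noiseless phantom study completes in a
few minutes on one CPU.
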