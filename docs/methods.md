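# Methods

`pamvasc` quantifies corticosteroid-induced vasoconstriction from volumetric
optical-resolution photoacoustic microscopy (OR-PAM) of skin. This note
records the models, the parameters that matter, and the design choices made
where the procedure was genuinely open.

## The measurement pipeline

An OR-PAM skin volume is a 3-D amplitude grid `(x, y, z)` with `z`
increasing into the tissue. The analysis of one subject's 7-volume series
(0–60 min, 10-min spacing) proceeds:

1. **Surface detection.** Per A-line, the skin profile is the shallowest
   depth where the amplitude reaches `frac` (default 0.5) of that A-line's
   maximum. A-lines below the noise floor (default 10% of the volume
   maximum) carry no surface information. Because first crossings can only
   err *deep* (there is nothing above the skin to cross on), the raw
   crossing field is cleaned one-sidedly: a wide minimum filter (81 pixels,
   wider than any hypodermal vessel stripe) seeds a reference surface; five
   iterations accept crossings within 90 µm of the reference and re-estimate
   it as a 41×41 local mean; coverage holes take the converged reference
   (a nearest-neighbour fill can copy a deep-vessel graze across a hole);
   an 11×11 median filter finishes. In unpigmented skin the first strong
   absorber is the superficial capillary plexus, so the detected profile
   runs a near-constant ~40–50 µm below the anatomical surface; this offset
   cancels in every relative and displacement statistic and stays well
   inside the ±2-axial-resolution tolerance used for peak recovery.
   The profile is detected on the t = 0 volume and reused for the whole
   series (`surface.fix_to_t0`, default on): the series is acquired at one
   location, and re-detecting per timepoint lets the vasoconstriction itself
   degrade the geometry reference — under strong capillary loss up to ~10%
   of A-lines otherwise lock onto hypodermal vessels at t = 60 min.

2. **Flattening.** Each A-line is shifted by linear interpolation so its
   surface lands at depth index 0. Linear interpolation is adequate because
   the 3-µm axial sampling is an order of magnitude finer than the 30-µm
   axial resolution.

3. **Layer segmentation.** The depth histogram counts voxels above a global
   Otsu threshold per depth index of the flattened volume, smoothed by a
   moving average over one axial resolution width (30 µm). Its two most
   prominent local maxima separated by ≥ 100 µm are the papillary-dermis
   (PD) and hypodermis (HD) plexus peaks. Slab boundaries follow the
   `valleys` rule by default: each boundary sits at the centre of the
   near-minimal count plateau between a peak and the inter-peak midpoint
   (tolerance 5% of the valley-to-peak range — the plateau centre is stable
   where an argmin would wander over a flat noise floor). The alternative
   `peaks` rule uses the peak depths themselves as boundaries; it is the
   more literal reading of peak-based segmentation but puts half of each
   plexus' voxel mass into the reticular-dermis (RD) slab, which swamps the
   small mid-dermis signal — hence not the default. Boundaries are computed
   once at t = 0 and reused (`layers.fix_to_t0`), since constriction itself
   shifts the histogram.

4. **Density quantification.** Per layer, the maximum-amplitude projection
   (MAP) over the slab is binarized with the averaged-Otsu scheme: each of
   the seven per-timepoint MAPs gets its own 256-bin Otsu threshold (bin
   edge maximizing between-class variance, ties toward the lower edge), the
   seven thresholds are averaged, and density is the count of pixels
   strictly greater than the average. Relative density normalizes by t = 0;
   the constriction percentage is `100·(1 − relative density at 60 min)`.
   All thresholds derive from each image's own histogram, so every statistic
   is invariant to global amplitude rescaling.

5. **Centroid tracking.** The depth centroid of the suprathreshold voxel
   set of the flattened volume (threshold fixed from t = 0; binary
   weighting by default, amplitude weighting behind a flag). Superficial
   capillary loss moves the centroid deeper; mid-dermis loss barely moves
   it — the discriminating contrast between topical and injected delivery.

6. **Group statistics.** Mean ± SEM (n−1 sample SD over √n) of relative
   density per group × layer, and two-tailed paired t-tests on final
   constriction percentages, pairing subjects by index between groups,
   the convention of the blanching-assay protocol (an unpaired Welch test is available via
   `study.test_kind = "welch"`; no multiple-testing correction by default,
   Bonferroni behind a flag).

## The synthetic phantom

No public dataset exists for this protocol, so validation rests on a
phantom whose scenes carry exact ground truth.

**Geometry.** Default grid 200×200×300 voxels at (5, 10, 3) µm — a
1.0×2.0×0.9 mm field standing in for the acquisition-scale 4×6×3 mm volume
(available as `PhantomSpec.full_size()`). The skin surface is a smooth
random field (mean depth 60 µm, amplitude 30 µm, lateral correlation length
400 µm, Gaussian-filtered white noise scaled to the amplitude bound).
Vessels are capsules (distance-to-polyline ≤ radius), max-composited:

* **PD**: 70 wandering horizontal capillaries at 60 ± 8 µm below the
  surface, radius 10–16 µm, giving ~48% projected coverage (~35 visible
  capillaries/mm²).
* **RD**: 20 near-vertical connectors rising from the deep plexus to join
  the superficial plexus (tops at the PD band depth, as ascending dermal
  vessels do), radius 9–15 µm, lateral drift 10–30% of their depth run.
* **HD**: 2 arteriole–venule pairs at 500 ± 15 µm, radius 35–55 µm, running
  the length of the field with gentle sinuosity.

Radii are *apparent* OR-PAM calibres — no tube thinner than the 30-µm axial
resolution — because sub-resolution tubes render PSF-limited and their
binarized width cannot track radius. Rendering adds the local surface depth
to each centerline point (vessels ride the undulating surface), convolves
with the anisotropic Gaussian PSF (5 µm lateral / 30 µm axial FWHM — the
imaging system's resolutions), and adds Gaussian noise (σ = 0.02 of unit
vessel intensity) clipped at zero. Everything is deterministic given the
seed; per-subject seeds derive from (master seed, group index, subject
index).

**Constriction.** A saturating-exponential schedule
`factor(t) = 1 − c_max·(1 − exp(−t/τ))` with τ = 20 min (curves flatten
near 60 min; a linear ramp is configurable). The schedule acts per layer in
one of two modes:

* `radius` — tube radii scale by `factor(t)`. Used for the thick HD tubes,
  whose binarized width tracks radius faithfully (recovery error ~2 pp).
* `dropout` — whole vessels disappear; the scheduled fraction of the
  layer's vessels is removed in a random but persistent order (shuffled
  evenly-spaced ranks, so the realized fraction equals the schedule).
  Used for the capillary layers: radius scaling drives PD/RD tubes through
  the sub-resolution regime, where the blurred peak dims as
  `erf(r/(√2·σ_axial))` and a fixed threshold over-reports the density loss
  by 7–16 pp relative to geometry — no faithful measurement can then track
  the radius. Physiologically, capillary constriction derecruits vessels:
  their hemoglobin signal vanishes rather than thins.

**Presets** mirror the four experimental arms. `c_max` is chosen so the
schedule reproduces characteristic in vivo layer-wise density losses at
60 min:
injection → RD only, c_max 0.521; topical → PD 0.670, RD 0.475 (dropout)
and HD 0.250 (radius); nonsteroid and control → no schedule. The PD value
accounts for projection overlap: with union coverage `1 − e^(−λ)` (λ ≈ 0.65
at the default grid), a dropout fraction `d` yields a density loss of
`1 − (1 − e^(−λ(1−d)))/(1 − e^(−λ))`, and inverting this at the
56.4% papillary target gives 0.670. Sparse layers have negligible overlap and
keep the linear inversion.

**Ground truth.** Each scene carries its vessel set per timepoint and an
analytic projected-area oracle: the lateral projection of a 3-D capsule is
exactly the 2-D buffer of its projected centerline, so layer-wise projected
area fractions are computed geometrically (shapely union, clipped to the
field) with no rendering, thresholds, or shared code with the measurement
path. Ground-truth band centres are the *realized* area-weighted mean
depths of the placed vessels.

**What the phantom does not emulate** — and hence what passing tests do not
show about real data: limited-view suppression of vertical vessels,
wavelength-dependent fluence and depth attenuation, speckle and systematic
reconstruction artifacts, epidermal melanin signal, inter-scan motion
beyond the optional per-B-scan jitter, and real biological variability in
vessel topology. The phantom validates the *measurement chain*, not the
biology.

## Validation summary (computed by the test suite and acceptance script)

* Otsu equals an exhaustive between-class-variance scan on random images
  (exact bin-edge match; ties toward the lower edge).
* Depth-histogram peaks land within ±60 µm (two axial resolution widths) of
  the realized plexus depths over 20 seeds, noiseless and noisy; the
  residual error is dominated by the first-absorber surface offset
  (~45 µm), with ~2 µm seed-to-seed spread.
* Per-layer mean constriction over 6 subjects per preset recovers the
  geometric oracle within ±5 pp (measured ≤ 1.7 pp); untreated arms stay
  within ±10 pp of zero (measured ≤ 0.3 pp).
* The qualitative structure — RD-only response to injection, PD > RD > HD
  under topical application, whole-skin ordering, and the centroid
  contrast — reproduces in ≥ 19 of 20 master seeds at a reduced
  96×96×240-voxel field with 2 subjects per arm (grid sizes chosen to keep
  the multi-seed sweeps desk-scale; the single-run recovery checks use the
  full default grid).
* Amplitude rescaling leaves every density trace bit-identical; a 40-µm
  surface tilt changes layer densities by ≤ 1.3% after flattening; the
  pixelwise max of the PD/RD/HD maps equals the whole-skin map exactly.
* The paired t-test matches the closed form (differences [1,2,3] →
  t = 3.4641, p = 0.0742) and scipy to 1e-9. A Monte-Carlo check of
  between-group discrimination at in-vivo-scale effect sizes (means
  ≈50% vs ≈2%, SEMs ≈9/1.5 pp, n = 6) reaches p < 0.005 in ~67 of 100
  replicates — in exact agreement with the analytic noncentral-t power of
  0.667 at those moments, and reported as such.

## Numerical notes and degenerate inputs

* Otsu on a constant image raises a degenerate-image error (propagated with
  the series index from the averaged scheme); a zero t = 0 density raises
  an undefined-baseline error; fewer than two histogram peaks, or an empty
  RD slab, raise segmentation errors naming the problem and (for slabs) the
  alternative rule.
* Volumes are float32 throughout; TIFF export quantizes to 16 bits with the
  scale factor recorded in metadata; HDF5 is lossless. Quantification never
  reads display exports.
* Subjects with incomplete series, mixed grids, or segmentation failures
  are excluded from group statistics and listed in the run manifest with
  the failure reason.
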