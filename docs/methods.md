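# Methods

## Measurement model

A reflective radiochromic film (XR-QA2 class) darkens with absorbed dose.
Scanned in RGB at 150 DPI and 16 bits per channel, the red channel carries
the strongest response; the working quantity is the *net pixel value*

    net = max(baseline − raw_red, 0),

where `baseline` is the raw red value of unexposed film.  This convention
anchors net = 0 at zero dose (the dose-response table's zero row) and makes
net increase monotonically with dose.  The original scanner scale of
published pixel-value tables is not always stated; baseline subtraction is
the only convention under which a response can start at exactly 0, and it
is what this package uses throughout.  The baseline is best supplied as a
region of interest over unexposed film (its median is robust to dust); the
fallback is the 99.5th percentile of the whole image.  8-bit scans are
rescaled by 257 to the 16-bit range so one calibration scale applies.

## Calibration

Net value versus dose x (mGy) is modelled as a saturating sum of two
decaying exponentials

    y(x) = y0 + A1·exp(−B1·x) + A2·exp(−B2·x),

with y0 the saturation asymptote, A1, A2 ≤ 0 and B1, B2 > 0.  The fit is
unweighted nonlinear least squares.  Two-exponential models are notoriously
sensitive to the starting point, so initialisation is deterministic: a
20×20 log-spaced grid over (B1, B2) ∈ [10⁻³, 0.5] mGy⁻¹ with a linear
least-squares solve for (y0, A1, A2) at each node, followed by
Levenberg–Marquardt refinement of all five coefficients (SSE tolerance
10⁻¹⁰).  The label-swap symmetry of the two terms is resolved by the
canonical ordering B1 < B2.  Standard errors come from the linearised
covariance at the optimum.

Fitted curves must be strictly increasing on their dose range (checked on a
1-mGy grid) and pass within 5% of y0 at zero dose; violation raises rather
than silently producing an uninvertible map.  For the packaged 14-point
table (doses 0–200 mGy) the fit gives y0 ≈ 29525, A1 ≈ −15404,
B1 ≈ 0.01617 mGy⁻¹, A2 ≈ −14172, B2 ≈ 0.08537 mGy⁻¹ with an RMS residual
of ≈ 148 counts (0.5% of y0); these numbers are recomputed, not stored, by
`scripts/acceptance.py` and the test suite.

Inversion is monotone bisection on the dose range to |Δdose| < 0.001 mGy,
vectorised over whole images.  Net values below the zero-dose response
clamp to 0 and values above the top-of-range response clamp to the maximum
dose; both are flagged in a per-pixel mask (`FLAG_BELOW_RANGE`,
`FLAG_SATURATED`).  Note that when the fitted curve has y(0) < 0 (the
reference fit gives y(0) ≈ −51 counts), a net value of exactly 0 legally
inverts to a small positive dose (~0.04 mGy); this is a property of the
fit, not an artifact of the inversion.

A calibration table can also be extracted from a segmented exposure strip:
each segment's net value is the mean over the central 50% of its ROI area
(margins trimmed against segment-edge gradients).

## Profiles

Short-axis profiles are taken at labelled long-axis positions
(A peripheral, B scattered, C adjusted/penumbra, D exposure centre),
cropped symmetrically about the phantom axis to the phantom diameter —
`round(diameter · dpi / 25.4) + 1` samples — because the film is cut wider
than the phantom and the margins carry artifacts.  By default the profile
row is averaged with its two neighbours to suppress single-row scanner
noise.  The summary statistic is the centre-to-periphery ratio:
mean of the central 5% of samples over the mean of the outer 10% per side.
The window fractions have no canonical values and are exposed as
parameters.

## Rotational reconstruction

With the phantom centred on the scanner's rotation axis the dose deposit is
rotationally symmetric, so the half-profile of each film row determines the
whole axial plane.  The radius profile defaults to the mean of the left and
right halves (halving noise and cancelling first-order film-tilt bias;
single-side modes are kept for fidelity checks).  Each output grid point
takes the profile value at its Euclidean distance from the centre, linearly
interpolated (nearest-neighbour available); points beyond the profile
extent hold NaN — "no measurement", deliberately distinct from zero dose.
The centre pixel is assigned the r = 0 value exactly.  Reconstruction is
performed by default after block-averaging the dose map to 50 DPI
(0.508 mm pixels), which suppresses scanner noise before it is rotated into
the volume; one slice per film row gives 0.508 mm inter-slice spacing.

The axis column defaults to the midpoint of the crop; an optional
refinement maximises the left–right correlation of the exposure row within
±10 px.  The method is only valid for a centred phantom — an off-centre or
elliptical phantom breaks the symmetry, and the package makes no attempt to
correct for it.

Pseudo-colour display maps a dose window (lo, hi) linearly onto a 256-entry
LUT (jet by default; any 256×3 table is accepted — published figures of
this kind rarely name their LUT), with NaN rendered as a background colour.

## Synthetic study conditions

The generator renders film scans of an analytic dose field so the whole
chain can be validated against exact ground truth.  The field is the
separable two-term model

    D(r, z) = A(z)·P(r) + S(z)·Q(r)

* `A(z)`: top-hat of the 20 mm beam width convolved with a 3 mm-σ Gaussian
  penumbra, normalised to 1 at the beam centre;
* `P(r) = surface_dose · exp(−μ·(R − r))`: primary beam attenuated from the
  surface toward the centre;
* `S(z) = scatter_peak · (1 − A(z)) · exp(−max(0, |z−z0| − w/2)/L)`:
  scatter tails (L = 40 mm) that vanish at the beam centre;
* `Q(r) = 1 − (r/R)²`: centre-peaked scatter, zero at the surface.

At the beam plane and phantom surface the field equals `surface_dose`
exactly.  The model is intentionally simple — no published dose equations
exist for this geometry, only qualitative behaviour — and its job is to
exhibit that behaviour (flat-to-centre-depressed exposure profiles, centre-
elevated scatter) with known ground truth.

Two presets fix the study conditions: **infant** (100 mm diameter, film
110 × 250 mm, surface dose 30 mGy, μ = 0.0006 mm⁻¹ → exposure-plane
centre/periphery ratio ≈ 0.98) and **adult** (160 mm, film 170 × 250 mm,
surface dose 25 mGy, μ = 0.004 mm⁻¹ → ratio ≈ 0.76).  Surface doses are
typical of a single 120 kVp axial body scan; the scatter peak is 8 mGy for
both.  Phantoms are 300 mm long; the beam centre sits at 125 mm of the
250 mm film; scans are rendered at 150 DPI against a baseline of 58000
counts.

Rendering maps dose through a forward calibration curve (by default the
same double-exponential family with y0 = 30000, A1 = −16000, B1 = 0.016,
A2 = −14000, B2 = 0.09, chosen so y(0) = 0 exactly), writes
`baseline − net` to the red channel (green/blue stay at baseline), adds
independent Gaussian scanner noise per pixel and channel (seeded;
default σ = 0), and rounds to 16-bit TIFF with DPI metadata.  Rounding
limits noiseless round-trip accuracy to ±0.5 count, i.e. ≲ 0.002 mGy at
preset dose levels.

What the generator does **not** emulate: Monte-Carlo transport, scanner
MTF and lateral-response artifacts, film-batch variation, Moiré patterns,
energy dependence.  Passing the closed-loop tests therefore demonstrates
the correctness of the analysis chain, not the physical fidelity of any
real film measurement.

## Numerical choices and verification

* Downsampling is block averaging (not decimation), edge blocks averaged
  over available pixels; integer DPI ratios only.
* The noiseless closed loop (generate → render → read → calibrate →
  reconstruct) recovers the generating field with RMSE ≈ 0.4% of the
  maximum dose for both presets (bound: 2%).
* Under σ = 100 counts of scanner noise, per-pixel dose errors pooled over
  10 seeded replicates match the first-order propagation
  σ_dose ≈ σ / y′(D) to ≈ 1% in spread (bound: 20%), restricted to
  5–28 mGy where neither clipping nor saturation interferes.
* Rotational symmetry of reconstructed slices is verified by sampling 360
  angles per radius with bilinear interpolation: the angular standard
  deviation stays below 1% of the slice maximum.  Two measurement caveats:
  the outermost two rings are excluded (bilinear samples there blend the
  NaN fill outside the disk, which is not signal), and slices whose maximum
  dose sits at the scanner-quantization floor (< 0.05 mGy) are held to an
  absolute 0.01 mGy spread instead, since a ratio to a near-zero maximum is
  ill-conditioned.
* DICOM export stores dose as `stored = round(d/slope) + 1` with
  `RescaleIntercept = −slope`, reserving stored 0 for outside-phantom
  points; the round trip is exact up to the 0.01 mGy default quantization
  step, including the NaN mask.  UIDs are derived deterministically from
  content so identical runs produce identical series.

## Known limitations

* Valid only for a full 360° rotation of a centred, circular phantom;
  under-/over-scan and off-centre geometries are out of scope.
* Calibration assumes a single film batch and scanner; no energy or
  lateral-response corrections.
* The dose model behind the presets is phenomenological; quantitative
  agreement with a real scanner/film/CT combination requires a measured
  calibration strip and real scans.
* Helical acquisitions are not supported.
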