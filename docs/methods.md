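# Methods

`colhier` quantifies how mineralization changes the hierarchical organization
of type I collagen in the turkey leg tendon model, combining two modalities:
small-angle fiber diffraction (structural metrics per scan position) and
polarization-resolved second harmonic generation microscopy (organization
maps per acquisition).  Because the real beamline/microscope data are not
bundled, a synthetic-data module generates both kinds of raw data from known
ground truth; every downstream stage is validated as a round trip through
that generator.

## Fiber-diffraction model and reduction

### Geometry

A flat detector at distance L behind the sample maps a pixel at in-plane
radius r to the scattering wavevector

    Q = (4*pi / lambda) * sin( arctan(r / L) / 2 ),

with the convention Q = 2*pi/d throughout (so the collagen intermolecular
feature at d ~ 2.3 nm sits near Q = 2.7 nm^-1, and the third meridional
order of a ~67 nm D-period near Q = 0.28 nm^-1).  Defaults: L = 700 mm,
lambda = 0.0979 nm, 75 um pixels on a 2162 x 2068 raster (an Eiger2 4M-class
detector).  The synthetic study uses a smaller raster (1100 x 1100 at
100 um) with the same distance and wavelength: it keeps full azimuthal
coverage to Q > 5 nm^-1 on-axis while making a 400-pattern scan simulable in
about a minute.  All geometry parameters are configurable; nothing
load-bearing depends on the defaults.

### Polar resampling

Profiles are computed by resampling each pattern onto a regular
(azimuth x Q) grid — 720 segments of 0.5 degrees by 0.004 nm^-1 bins —
with bilinear interpolation, not by histogramming pixels: at the D-period
annulus (r ~ 30 px) a 0.5-degree x one-bin cell contains far less than one
pixel, so histogram segments would be mostly empty.  Two numerical details:

* The image is multiplied by Q^4 before interpolation and the samples
  divided by Q^4 afterwards.  The dominant Porod background is strongly
  convex across pixels at small radii and plain bilinear sampling inflates
  it systematically; the flattened field is nearly constant, cancelling the
  bias.  Without this the recovered D-period is biased by roughly
  -0.08 nm; with it the noiseless bias is below 0.03 nm.
* Masked pixels (beamstop; sentinel -1) become NaN and poison any polar
  cell whose interpolation stencil touches them, so masked regions are
  excluded rather than diluted.

### Background subtraction

Around each diffraction feature a Porod-shaped background (I ~ Q^-4) is
removed by fitting a straight line to (ln Q, ln I) over two flank windows
outside the peak window, subtracting the fit from ln I, exponentiating the
residual, and scaling back to intensity units — algebraically I - exp(fit).
Flanks default to 20% of the peak-window width immediately outside each
edge.  A `background_mode` switch ("log" / "linear") selects between the
log-residual sequence and direct linear subtraction; the scaled-back results
are numerically identical, the switch documents the two readings of the
procedure.  Bins with non-positive intensity are flagged unusable; a flank
with fewer than three usable bins aborts that profile with a named error.

### The five metrics

* **D-period** (nm): the third meridional order is isolated in the window
  0.24-0.32 nm^-1 on the radial profile about the preferred orientation
  (azimuthal half-width +-20 degrees, both Friedel lobes).  The peak center
  is the intensity-weighted centroid of the background-subtracted signal
  (the mean of the peak, not the mode: the feature is blunted by beam
  divergence near the beamstop), and d = 3 * 2*pi / Q_centroid.
* **Intermolecular spacing** (nm): Gaussian fit to the background-subtracted
  equatorial profile in 1.9-3.5 nm^-1, taken orthogonal to the preferred
  orientation; d = 2*pi / Q_center.
* **Fibril dispersion** (deg): the per-segment background subtraction is
  repeated in each of the 720 azimuthal segments for the D-period window;
  the net peak signal per segment forms the azimuthal profile, folded to a
  180-degree period (Friedel symmetry), and its full width at half maximum
  is the dispersion.  The preferred fibril orientation is the lobe apex
  (parabolically refined below the 0.5-degree pitch).
* **Molecular dispersion** (deg): same procedure on the intermolecular
  window.
* **Relative supramolecular twist** (dimensionless): the molecular
  azimuthal spread convolves the fibril orientation spread with the
  intrafibrillar molecular (twist) spread.  A quadrature deconvolution
  surrogate is used: sigma_twist = sqrt(sigma_mol^2 - sigma_fib^2) with
  sigma = FWHM / (2 sqrt(2 ln 2)), clamped at zero (flagged) if the
  molecular width comes out narrower.  Raw twist is normalized by the mean
  raw twist of the non-mineralizing (NM) region, so the NM mean is 1 by
  construction.  This surrogate tracks relative trends between regions;
  it is not a full scattering model of the twist and absolute twist angles
  should not be read from it.

FWHM measurement details: half maximum is located by linear interpolation
between 0.5-degree bins, walking outward from the apex; ties at exactly the
half level resolve at the tied bin (toward the wider width); a lobe wider
than the half period reports 180 degrees with a flag.  Two robustness
choices matter on noisy segments.  First, the folded profile is smoothed
with a circular Gaussian (sigma 2 degrees by default, far below the
15-40 degree lobes of interest) and the kernel width removed from the
measured width in quadrature — exact for Gaussian lobes; without this,
noise triggers the outward walk early and biases widths low by 1-3 degrees.
Second, the half level is measured above a local lobe baseline estimated
from angular flanks just outside the lobe (3.5 sigma to 3.5 sigma + 10
degrees on each side) — the azimuthal analogue of the radial Porod flanks.
The per-segment power-law fit leaves a small smooth residual under the lobe
(from diffuse isotropic scatter, and from the mineral feature whose rising
low-Q tail a power law cannot follow); measuring from zero instead of this
baseline biases widths by about 2%.

### Per-pattern reduction and maps

`reduce_pattern` chains: minimum-signal gate (default 1e4 total counts;
failing patterns are skipped with a log entry) -> D-period azimuthal profile
-> preferred orientation + fibril dispersion -> meridional radial profile ->
D-period -> equatorial radial profile -> intermolecular spacing ->
intermolecular azimuthal profile -> molecular dispersion -> raw twist.  Any
sub-metric failure propagates as a NaN field with a flag string; a map
reduction never aborts on one bad pattern.  Horizontal binning sums
consecutive groups of patterns along the scan x direction (trailing
remainders dropped, positions replaced by group centres), reproducing the
acquisition-side bookkeeping of dense snake scans.

## pSHG model and fitting

Each acquisition is a 512 x 512 x 12 stack of SHG images at linear
polarization angles 0, 15, ..., 165 degrees.  Per pixel the intensity is
modelled as a sum of circular harmonics,

    I(alpha) = a0 + A2 cos 2(alpha - phi2) + A4 cos 4(alpha - phi4),

fitted by ordinary least squares on the basis {1, cos 2a, sin 2a, cos 4a,
sin 4a} — linear in its coefficients, so 12 angles spanning 180 degrees
determine the five parameters uniquely and noiseless model data are
recovered exactly.  The organization parameter reported is I2 = A2 / a0
(dimensionless, intensity-scale invariant; larger I2 means tighter
organization around the dominant direction phi2); the raw amplitude is also
stored.  I4/phi4 are computed and stored but excluded from summaries.
Amplitudes are non-negative by construction (quadrature pairs), phi2 lives
in [0, 180) and phi4 in [0, 90).  Least squares is unweighted; no noise
model is assumed.  Pixels with a0 <= 0 are masked; an intensity threshold
masks pixels whose mean intensity over angles falls below 10% of the
99th-percentile mean intensity (configurable, or an absolute level).

Region summaries are two-level: the mean I2 over valid pixels is taken per
acquisition, then the mean and sample standard deviation (n - 1) across
acquisitions per region.  A single-acquisition region reports std 0 with a
flag.

## Region statistics

One-way ANOVA (classical between/within mean squares, p from the F
distribution) followed by Tukey-Kramer pairwise comparisons:
q = |mean_i - mean_j| / sqrt(MSW/2 (1/n_i + 1/n_j)), adjusted p from the
studentized-range distribution with k groups and N - k error degrees of
freedom (valid for unequal group sizes).  Tail probabilities come from
scipy's studentized_range; tests cross-check q and p against scipy's
independent Tukey HSD implementation to 1e-6.  XRD metrics are compared per
scan pattern; pSHG per acquisition mean — the two sampling granularities
are deliberately not unified.  Scan positions are treated as independent
observations; spatial autocorrelation along the scan is ignored, a known
limitation inherited from the study design.  Significance stars follow the
0.05 / 0.01 / 0.001 / 0.0001 tiers.

## Synthetic data: what it emulates, what it does not

A scatter pattern is the sum of: a Porod term c Q^-4 (default amplitude 2);
a weak flat background (default 10 counts) standing for diffuse incoherent
scatter, which also keeps Poisson counts positive in the high-Q flanks so
per-segment log-space fits stay usable; meridional D-period orders 1-3 as
Gaussian arcs at Q = 2 pi n / d (radial sigma 0.01 nm^-1, amplitudes
600/300/200 counts) with a wrapped-Gaussian azimuthal envelope of width
fibril_sigma about the preferred orientation; an equatorial intermolecular
arc at Q = 2 pi / spacing (radial sigma 0.25 nm^-1, amplitude 40) with
azimuthal width sqrt(fibril_sigma^2 + twist_sigma^2); and a broad mineral
lobe (Gaussian in Q, center 0.6 nm^-1, sigma 0.3; azimuthal sigma 35
degrees, centred perpendicular to the fibril axis, amplitude 30 x
mineral_fraction).  A circular beamstop masks the centre (sentinel -1),
occluding the first meridional order.  Poisson noise is optional; all
randomness flows from one explicit seed per scene or per map (per-cell
substreams spawned from the map seed), never from global state.  Arc widths
were chosen so each feature fits inside its analysis window, and the
mineral lobe is a declared stand-in — no functional form for it is
established, only its azimuthal placement perpendicular to the fibril
orientation and its overlap in Q with the D-period feature.

Zero azimuthal spread degenerates to an indicator confined to the canonical
0.5-degree analysis bin containing the axis, so the delta-dispersion limit
is well-defined on a discrete detector.

pSHG stacks are generated directly from per-pixel (a0, i2, phi2, i4, phi4)
fields through the harmonic model above, clipped at zero (with a warning
when i2 + i4 > 1 makes that possible), then Poisson-sampled when shot noise
is on.  Ground truth is thus defined in the estimator's native
parameterization — the generator exercises estimation, masking, aggregation
and statistics, not the mapping from harmonophore physics to harmonic
amplitudes.

Not emulated, hence not validated by these tests: detector point-spread,
flat-field and dark structure, beam divergence (the real D-period peak is
blunted by it; the centroid estimator is the response to that, but the
simulated peak is symmetric), polarization/Lorentz corrections, waveplate
imperfections and residual birefringence, tissue heterogeneity within a
region, and spatial correlation between scan positions.  Passing the
round-trip suite shows the estimators are correct for data obeying the
stated models at realistic count levels, not that the models capture every
property of beamline or microscope data.

## Study conditions of the synthetic campaign

Region ground truth (NM / EM / LM): D-period 66.92 / 67.46 / 67.21 nm;
intermolecular spacing 2.37 / 2.16 / 2.13 nm; fibril dispersion FWHM
31.19 / 15.31 / 19.88 degrees; molecular dispersion FWHM 37.43 / 24.55 /
24.96 degrees (twist_sigma derived by quadrature: 8.79 / 8.15 / 6.41
degrees); mineral fraction 0 / 0.6 / 1; pSHG I2 0.21 / 0.29 / 0.33 at
a0 = 500 counts.  The diffraction campaign is a 20 x 20 snake scan split
into three vertical region bands (~133 patterns per region); the pSHG
campaign is 4 samples x (6 NM + 4 EM + 4 LM) = 56 acquisitions.  These
sizes keep the whole pipeline within minutes on one CPU while leaving
region-mean Monte-Carlo error well below the recovery tolerances
(D-period 0.2 nm, spacing 0.02 nm, dispersions 1 degree, twist 5%).

## Known limitations

* The twist estimate is a relative quantity by design; between-region
  ratios are meaningful, absolute angles are not.
* The per-segment background fit assumes the background is locally
  power-law-like between the flanks; strongly structured diffuse scatter
  inside a peak window would bias segment signals (the local azimuthal
  baseline absorbs the smooth part of such errors).
* At very low counts the Gaussian fit of the intermolecular peak and the
  FWHM crossing search degrade before the centroid does; failures surface
  as flagged missing metrics rather than wrong values where detectable.
* The statistics module treats observations as exchangeable within a
  region; no mixed-effects structure for per-sample variability is fitted.
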