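# Methods

## The measurement being emulated

FTIR imaging of a thin (~10 μm) unfixed cryosection yields, at every pixel
of a 2.56 × 2.56 μm grid, a mid-infrared absorbance spectrum over
4000–800 cm⁻¹.  Biological absorbance in this range decomposes into broad,
approximately Gaussian bands assignable to macromolecular classes: CH₂/CH₃
stretching of lipid acyl chains near 2925/2852 cm⁻¹, ester C=O of fatty
acids near 1740, amide I/II of proteins near 1655/1545, CH₂ bending near
1455, C–OH stretching of glycosylated compounds near 1160 and C–O of
cortisol near 1060.  The analysis asks two questions of a wild-type vs
mutant comparison: where is each class located (chemical images), and has
its relative abundance changed (band-area ratios, PCA).

## Synthetic sections

The simulator is the package's test and acceptance substrate; its defaults
are the study conditions and are not tuned per test.

**Geometry.**  Class III oocytes are rendered as a disc of radius 0.45·min
grid dimension in a 328 × 328 μm map (128 × 128 px at 2.56 μm); class IV as
an ellipse in a 164 × 492 μm map (64 × 192 px) surrounded by a zona radiata
(ZR) ring, default thickness 7.68 μm (3 px).  A ring thinner than one pixel
is a configuration error.  Pixel counts are floor(extent/pixel).

**Spectra.**  Each compartment carries a band list (center, Gaussian sigma,
peak absorbance) plus a linear baseline.  A pixel's spectrum is
`thickness × (Σ bands + baseline) + vapor_amplitude · vapor(ν) + ε`,
with per-pixel log-normal `thickness` (mean 1, CV 0.10 — section-thickness
variation), a fixed vapor line comb (23 Gaussian lines, σ = 1.6 cm⁻¹,
restricted to 1900–1300 cm⁻¹, unit peak; amplitude 0.03 AU — moderate
atmospheric contamination that is *not* thickness-scaled), and white noise
ε with SD 0.002 AU (typical focal-plane-array pixel noise).  Band shape is
Gaussian because its area has the closed form `amplitude·σ·√(2π)`, giving
every downstream stage an analytic oracle; Voigt/Lorentzian realism is
deliberately out of scope, as are diffraction, scattering and instrument
line-shape effects.

**Composition defaults** put the cytoplasm in the yolk-protein-dominated
regime of vitellogenic follicles (amide I peak 0.60–0.70 AU, LIP/CYT ≈ 0.08)
and make the ZR glycoprotein-rich (COH/ZR ≈ 0.20).  The mutant-like
contrast multiplies the lipid-family bands (2925, 2852, 1740, 1455) and the
cortisol band by one factor each (default 1.3).  Class III cytoplasm may
contain droplet-like inclusions (default ten, radius 5–10 μm) whose
lipid-family amplitudes are boosted 4×, a plausibility feature for oil
droplets rather than a fit to data.  There is **no between-oocyte
compositional variability**: maps of one group differ only through
thickness, droplet placement and noise realizations.  Consequences: (i) the
per-spectrum pooled t-test is exactly calibrated under the null (spectra are
iid), which the null study verifies; (ii) passing tests say nothing about
real data's biological between-oocyte variance, for which the per-oocyte
aggregation option (`aggregate_by="map_id"`) is the appropriate unit.

**Axis.**  Default 800–4000 cm⁻¹ at 4 cm⁻¹ point spacing, stored ascending.
The accuracy test of single-Gaussian band areas samples its pixels at
2 cm⁻¹, the conventional digitization spacing of 4 cm⁻¹-resolution
interferograms; the map-level default stays at 4 cm⁻¹ for economy.

**Seeding.**  One master seed per cohort; map *k* uses `master + k`, so any
subset of a cohort is reproducible in isolation.

## Preprocessing

**Vapor compensation** subtracts `α · reference` with α fitted per spectrum
by least squares *on second differences* within 1900–1300 cm⁻¹, clamped at
α ≥ 0.  High-pass matching is what makes a single-scale fit workable on
tissue: the broad amide bands overlapping the window carry ~10⁻⁴ of the
reference's second-difference energy, so they leave α essentially unbiased
(residual bias ≈ 0.1% of the default contamination), whereas a raw-domain
fit would be dominated by them.  The fitted α is recorded in the map's
provenance steps.

**Vector normalization** divides by the Euclidean norm over the working
range; at map level, pixels whose norm falls below 5% of the median pixel
norm are treated as background and zeroed instead of being amplified to
unit norm (the threshold is relative, so globally rescaled maps normalize
identically).  A spectrum that is exactly zero in the window raises a
degenerate-input error.

**Analysis chain** (before ratios and PCA): linear interpolation onto a
uniform 900–3050 cm⁻¹ axis at 2 cm⁻¹; subtraction of the straight line
through the two endpoint absorbances (anchors fixed at the range ends,
making the step annihilate any affine-in-wavenumber term exactly and leave
the endpoints at zero); vector normalization over the cropped range.  The
chain is idempotent.  An input that was itself affine degenerates to
numerical dust after the baseline step and is rejected explicitly.

## Band integration and imaging

Band areas are plain trapezoids over closed intervals `[lo, hi]`, with
edges falling between axis points handled by linear interpolation folded
into a per-axis weight vector — integration is therefore exactly linear in
the spectrum and exactly additive across adjacent bands, and a whole map
integrates as one matrix product.  No per-band local baseline is applied by
default (one global two-point baseline has already been applied); a switch
subtracts the chord between band endpoints when set.  Negative absorbances
integrate with sign.  False-color rendering maps `[scale.lo, scale.hi]`
linearly from blue to white with clamping; the four imaging windows use the
fixed display scales 0–6 (lipids), 0–15 (proteins), 0–1 (glyco), 0–8
(cortisol) in absorbance·cm⁻¹ of the normalized spectra.

## Ratios and statistics

CYT and ZR denominators are both the summed areas over 3002–2820 and
1763–900 cm⁻¹ — a total-biomass proxy.  Ratios are computed per extracted
spectrum (40 per cytoplasm, 10 per class IV ZR, drawn uniformly without
replacement from non-degenerate mask pixels with a recorded seed; the draw
depends only on the seed and the eligible coordinate set in row-major
order).  Groups are compared per ratio with the classical pooled-variance
two-sample t-test at p < 0.05, letters differing exactly when significant;
Welch, Holm adjustment and per-oocyte aggregation exist behind flags, all
off by default to mirror the conventional reporting style of such tables.
FA/CYT is reported for class III as well.

**A structural caveat of ratio semi-quantification.**  Because the
denominator contains the marker windows, any change in one class moves
*every* ratio: raising lipid-family amplitudes by 30% lowers PRT/CYT by
`0.3·g_L/(1+0.3·g_L)` (g_L = lipid share of CYT; ≈5% at defaults) with no
change in protein content.  At the simulator's noise level this shift is
dozens of within-group standard errors, so the effect study rejects PRT/CYT
essentially always — the expected behaviour of the method on these
conditions, exposed honestly by `analysis/06_calibration_studies.py` and
the acceptance suite.  Directionality of the lipid ratios (fold changes
+18% to +23% after the same coupling and band-overlap dilution) is
recovered in 100/100 seeded runs.

## PCA

Spectra of both groups are pooled, wavenumber means subtracted, and the
matrix decomposed by SVD; no variance scaling (standard for spectra, which
share units).  Explained variance = squared singular values over their
total; loadings orthonormal; the sign convention (largest-magnitude loading
element positive) makes results bit-stable.  Scores carry the group labels,
so separation is summarized by the point-biserial correlation of PC1 score
with genotype.  On the demo, class IV separates at |r| ≈ 0.99 with PC1
loading energy concentrated in the lipid windows; class III separates
weakly (|r| ≈ 0.33) because random droplet placement puts large
*within*-group variance on the same lipid direction — an informative
negative control for droplet-bearing tissue.

## Numerical and design choices

* Files: ENVI-style header + band-sequential float32 rasters, or plain
  whitespace tables at ≥ 6 significant digits; both self-describe axis,
  shape and pixel size, round-trip losslessly at their precision, and are
  normalized to ascending wavenumber on read.  Masks are single-band label
  rasters.  Vendor acquisition formats are out of scope.
* All pipeline tables are written with a fixed float format, so identical
  (scenario, seed) runs are byte-identical.
* Repeated-seed studies (type-I, power) run on 32 × 32 px single-disc maps —
  ~700 cytoplasm pixels comfortably hold the 40-spectrum draw — with master
  seeds strided by 1000 so per-map seeds never collide; 100 repetitions run
  in ~25 s on one CPU.
* `n_components` above the data rank is reduced with a logged warning;
  rank-deficient explained-variance edge cases return exact 1.0/0.0
  fractions.

## Limitations

* Gaussian bands and a linear baseline cannot reproduce scattering
  artifacts (resonant Mie), derivative-shaped distortions, or water
  liquid-phase bands; no claim is made about preprocessing robustness to
  those.
* The vapor comb is a stylized stand-in for the true rotational-vibrational
  spectrum; only the compensation *algorithm* is exercised by it.
* Compartment masks come from simulation ground truth or user rasters;
  segmentation of real photomicrographs is out of scope.
* Reported p-values inherit the per-spectrum unit of analysis; with real
  clustered data use the per-oocyte aggregation flag.
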