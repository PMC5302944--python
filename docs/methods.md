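# Methods

This note documents the models implemented in `radioqc`, the estimator and
default choices that were genuinely open, and what the synthetic-data tests
do and do not demonstrate about real data.

## Survival curves and RBE

Surviving fractions are modelled as SF(D) = exp(−αD − βD²) (linear-quadratic,
LQ) or exp(−αD) (linear, L). Because ln SF is linear in (α, β), fitting is
bounded linear least squares on the log scale with α ≥ 0 and β ≥ 0 enforced;
a parameter pinned at zero is flagged as a boundary solution rather than
given a one-sided standard error. Weights are 1/SEM² (delta method on the
log scale) when per-observation SEMs are provided, otherwise unweighted.

**Normalisation intercept.** Surviving fractions are normalised to the 0 Gy
control wells. The control counting noise therefore shifts *every*
observation of a dataset coherently, which a no-intercept fit neither models
nor reflects in its standard errors: in simulation, the nominal 2-SE
interval covered the true α in only ~76% of replicates. The fit therefore
includes a free intercept on the log scale whenever the dataset contains
0 Gy observations — the log-linear equivalent of fitting raw colony counts
with the plating efficiency as a nuisance parameter, which is the
statistically standard treatment of clonogenic data. With it, empirical
coverage of α is 95–96%. For data without a 0 Gy condition the fractions are
taken as exactly normalised and no intercept is used. Noise-free data
round-trip to the generating parameters at numerical precision either way.

**Model selection.** L is retained unless adding β improves the fit by a
nested F-test at p < 0.05 (1 numerator degree of freedom). With data
simulated at β = 0, L is selected in ≈98% of replicates (the constrained
boundary absorbs half of the would-be false positives).

**Isosurvival dose and RBE.** D(S) is the positive root of
βD² + αD + ln S = 0, evaluated in the conjugate form 2L/(α + √(α² + 4βL))
with L = −ln S, which is numerically stable as β → 0 (the textbook form
loses all precision for β ≲ 1e−8). RBE(S) = D_ref(S)/D_test(S). Its
standard error combines both fits by first-order propagation using the
analytic gradients of D with respect to (α, β) and the full parameter
covariances; the two fits are treated as independent. The published
uncertainty recipe for RBE error bars is not stated anywhere we could find,
so the delta method is declared as this package's choice.

**Generator.** `generate_survival_table` draws Poisson colony counts around
cells·PE·SF(D) and normalises by the observed control plating efficiency;
zero-colony wells become half a colony (with a warning) to keep ln SF
finite. By default cells are seeded per dose so that every well expects
~150 colonies — the way the assay is actually run — which makes the
log-scale noise approximately homoscedastic. Triplicate wells mirror
standard practice.

## Intranuclear hit statistics

Expected traversals of a nucleus are λ = Φ·A·10⁻⁸ (Φ in particles/cm², A in
µm²; the unit conversion is applied exactly once). Over an area sample
{A_i} the hit count follows the equal-weight mixture
P(k) = n⁻¹ Σ_i Poisson(k; λ_i), i.e. an empirical-distribution bootstrap
over the measured nuclei. Identities used as tests: mean = Φ·E[A];
Var = Φ·E[A] + Φ²·Var(A) (law of total variance); the pmf is tabulated to
the smallest K whose tail mass under the largest λ_i is < 1e−9. The model
SEM is evaluated at the same nucleus count as the observed sample so that
"mean ± SEM" is reported like-for-like. Goodness of fit uses a chi-square
over bins pooled to expected counts ≥ 5, with the tail absorbed in the last
bin; calibrated on model-drawn data (p > 0.01 in ≥ 98% of replicates).

The nuclear-area law is log-normal parameterised by arithmetic mean and CV
(σ² = ln(1+cv²)); the published source shows only a histogram of n = 1239
areas, so the family is a declared choice. Defaults mean = 89.5 µm²,
cv = 0.3 were calibrated once so that Φ·E[A] ≈ 3.4 at Φ = 3.8×10⁶ cm⁻²,
matching the transport-calculation value for the carbon beam; they are user
parameters, not fitted quantities.

## FNTD track read-out

Spots are detected on the white top-hat of the raw plane (disc radius 3 px),
matched-filtered with a 1 px Gaussian, and thresholded at a robust
background mean + 4 SD (median / 1.4826·MAD; for noise-free images, where
the MAD degenerates to zero, 5% of the dynamic range is used). Individual
tracks inside a thresholded component are separated at the maxima of a
Laplacian-of-Gaussian response at scale 2 px — slightly below the 2.5 px
spot width, which sharpens the response and deblends partially overlapping
tracks at clinical fluences (~0.04 spots/µm², where ~4% of spots have a
neighbour within the plain local-maximum resolution limit). Detections
closer than the declared minimum separation are merged toward the brighter
peak. Two significance gates suppress noise: components smaller than 5 px,
and filtered peaks below 6 SD of the background (over megapixel fields the
extreme-value tail of the filtered noise passes 5 SD). Centroids are
intensity-weighted with the background level subtracted from the weights.

Peak photon counts are taken from the *raw* image over the spot region and
divided by the dwell time (7.2 µs ⇒ counts/µs = MHz). Note the raw peak
includes the background offset and a small max-of-noise bias, so read-out
rates are biased high by ~1 MHz at the default noise level; classification
thresholds operate on the same scale, and the histogram-threshold operation
is applied to measured rates, so the bias cancels to first order.

Classification is a count-rate cut: ≥ threshold ⇒ primary ion (including
heavy projectile-like fragments indistinguishable from the beam), otherwise
light fragment. The clinical thresholds 5.3 MHz (carbon) and 4.4 MHz
(oxygen) are retained as citable defaults. `histogram_threshold` recovers a
threshold from data as the between-class-variance-maximising (Otsu) split of
the count-rate sample, returning the *centre* of the flat variance plateau
across an empty inter-class gap (the edge would bias toward one
population); a kernel-density bimodality check precedes it, and unimodal
samples yield a warning plus a boundary value the caller must confirm. The
generator's class-conditional rate Gaussians (carbon: 7.2 ± 0.7 MHz primary,
3.4 ± 0.7 MHz fragment; oxygen: 6.0 ± 0.6 / 2.8 ± 0.6 MHz; 8% fragments)
were calibrated once so that this split lands at the clinical thresholds.

## Nuclei and γ-H2AX foci

Nucleus segmentation: per-plane rolling-ball background subtraction →
maximum intensity projection → median filter (disc, 2 px) → Otsu threshold
→ hole filling → distance-transform watershed with markers at distance
maxima ≥ 4 µm apart → area filter (≥ 20 µm²). For rolling-ball radii above
16 px the image is downscaled before the ball and the background is
rescaled back (the classical large-radius speed-up); exact for small radii.
Border-touching nuclei are flagged (kept for hit assignment, excluded from
statistics by the QC filter). On synthetic discs and ellipses the measured
area is within 5% (typically < 1%) of truth for radii ≥ 5 px.

Focus detection runs per nucleus on the background-subtracted, projected and
lightly smoothed (1 px) damage channel. The threshold is the nucleus's
robust background (median) + 3 robust SD (1.4826·MAD) — robust rather than
moment-based so the foci themselves cannot inflate it — and, being relative,
makes counts invariant under uniform intensity scaling. Candidates are split
at h-maxima whose prominence exceeds both twice the noise scale and 30% of
the component's height above threshold, so flat-topped foci with noise on
the plateau are not oversplit while genuine double foci are. Focus *size* is
the area at half maximum, which is independent of the detection threshold
level; doubling the generated focus radius quadruples the measured area
(ratio 4.3 measured, segmentation bias included). The published macro's
parameters are unpublished; all values here are declared defaults exposed in
the configuration.

QC exclusions: a nucleus is `pan_stained` when more than 40% of its area
exceeds a global Otsu threshold of the in-nucleus damage signal, `apoptotic`
when its area is < 25 µm² or solidity < 0.7. These quantitative proxies
stand in for the visual criteria of the original protocol.

Statistics subtract the unirradiated-control background rate
(default 0.16 foci/nucleus), flooring at zero with a flag. Repair kinetics
report residual(t) = corrected mean(t) / corrected mean(0.5 h); the
generator's time course is initial·(r + (1−r)·2^(−t/T½)) per-nucleus Poisson
with default T½ = 6 h (γ-H2AX resolution half-lives of a few hours are
typical) and residual fractions r of 0.023 (photon-like), 0.153
(carbon-like) and 0.176 (oxygen-like). Because the 0.5 h baseline has
already decayed slightly, the ratio estimator carries a small (+0.01) upward
bias at these settings — well inside the ±0.03 recovery tolerance verified
over 50 replicates at 150 nuclei per timepoint. The metric–survival stage
is ordinary least squares of surviving fraction on the focus metric with
Pearson R² and its two-sided p.

## Registration and pairing

A single rigid translation per field is assumed (no rotation or scaling,
matching the observation that all track–focus displacement vectors share one
slope); per-nucleus translations are out of scope. Estimation: (1) coarse —
the mode of the 2-D histogram (0.5 µm bins) of all pairwise spot→focus
displacements within the search radius; every true pair votes for the same
bin while unrelated pairs spread smoothly, so this stays robust when most
tracks produce no focus (dense detector plane, sparse foci); (2) refinement
— component-wise median of nearest-neighbour displacements within a 1.5 µm
window, iterated twice with re-matching, then a trimmed mean over inliers
(residual ≤ 3× the median absolute residual), which is statistically more
efficient than the median once outliers are excluded. Noise-free shifts are
recovered exactly; under 0.3 µm jitter with 20% outliers the mean per-axis
error over 50 replicates is < 0.05 µm. Estimates are flagged unreliable
when fewer than half the matched spots are inliers or the residual spread
approaches the search radius.

Pairing is greedy one-to-one nearest-neighbour assignment in ascending
separation after translation, with a 5 µm default gate (~3 µm nuclear
movement plus focus-position uncertainty). Optimal bipartite matching would
be a drop-in refinement but is not implemented.

## Synthetic data: what it does and does not show

The generators emulate: LQ/linear survival with Poisson counting noise and
realistic per-dose seeding; log-normal nuclear areas; Poisson-placed
Gaussian track spots with bimodal count rates at clinical fluences over the
212.55 µm / 1800 px detector geometry; elliptical non-overlapping nuclei
(eccentricity ≤ 0.6) on the 322 nm widefield grid; disc-like foci placed at
track positions shifted by a global translation, plus Poisson background
foci; and repair time courses with residual plateaus. They do **not**
emulate: biological overdispersion between experiments, chromatin texture
or intensity inhomogeneity inside nuclei, 3-D focus structure, overlapping
or touching nuclei in confluent monolayers, detector-specific artefacts
(colour-centre saturation, read-out striping), or secondary-electron halos
around tracks. Passing tests therefore demonstrate the correctness and
calibration of the estimators under the stated noise models, not
segmentation robustness on difficult real microscopy.

Problem sizes used by the test suite were chosen to keep the default run
fast while leaving the statistical criteria well-powered: 300–500 fit
replicates for coverage, 10⁵ nuclei for sampler/total-variation checks, one
full 1800² detector plane (~1700 spots) for detection quality, 50 replicates
× 150 nuclei for repair-kinetics recovery, and 50 replicates for
registration robustness.

## Numerical and degenerate-input conventions

Positions use the pixel-centre convention (pixel (0,0) centre at 0 µm, x
right, y down); physical units are µm, µm², Gy, MHz, particles/cm²
throughout. SF = 0 wells are replaced by half a colony with a warning.
SF ≡ 1 datasets fit to α = β = 0. Blank images yield empty results with
warnings, not errors. All randomness flows through numpy Generators seeded
explicitly; every generator is bit-reproducible for a fixed seed and has a
noise-free mode emitting exact expected values. CLI artifacts (CSV, YAML,
JSON manifests without timestamps) are byte-identical across re-runs with
the same seed.
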