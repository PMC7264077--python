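# Methods

This note documents the models, estimators and numerical choices behind
`megpls`, and what the synthetic test bench does and does not show.

## Spectral pipeline

**Motion rejection.** A sample is retained iff every head-localization
fiducial's Euclidean displacement from its per-recording median position
is ≤ 5 mm (configurable). Masking requires a head-position trace; its
absence is an error rather than a silent skip.

**Epoching.** Contiguous retained runs are cut into non-overlapping 4-s
windows aligned to the start of each run; partial windows are dropped.
Non-overlap is deliberate: a 120-s recording yields at most 30 trials,
consistent with typical retained-trial counts after artifact rejection.

**Band power.** Canonical bands are delta 1–4, theta 4–8, alpha 8–12,
beta 12–25, gamma 25–55 Hz, half-open `[lo, hi)` so shared edges are
not double-counted. Band power is the variance of the band-pass
filtered signal, averaged over epochs — matching the per-band
beamformer design, where source series are already band-limited. The
filter is an order-4 Butterworth band-pass applied forward and backward
(`sosfiltfilt`), giving zero phase and a net |H|⁴ power response: pure
out-of-band tones are attenuated to well below 1%, and band additivity
for mixtures of band-confined signals holds within the package's 2%
leakage bound. A zero-phase FIR filter was considered and rejected: at
1200 Hz a FIR sharp enough for the 1–4 Hz band needs more taps than a
4-s epoch supports under zero-phase padding.

Two edge-handling details matter for short epochs. Padding is *even*
(mirror) reflection over three periods of the band's low edge: the
default odd padding inflates delta-band variance of a 4-s window
severalfold, while even padding is unbiased to ~1% across all bands.
A 60 Hz zero-phase notch (±2 Hz) is available for line-contaminated
data and is inert on synthetic inputs.

**Relative power.** Each band's power is divided by the summed power
over the five analysed bands. The composition is non-negative, sums to
one, and is exactly invariant to any global rescaling of a channel —
which is what removes source-depth bias after beamforming. An all-zero
power vector has no defined composition and raises an error.

## Forward model and beamformer

**Spherical head model.** Sensor fields are computed from the
closed-form solution for a current dipole in a homogeneous conducting
sphere. This toy model replaces anatomy-dependent realistic head models
(out of scope) while preserving the property the tests rely on:
radially oriented dipoles produce no external magnetic field, so source
moments effectively live in the tangential plane. Sensors are radial
magnetometers on a helmet-like shell at 1.2× the sphere radius; sources
sit on a regular grid strictly inside the conductor (the grid
convention mirrors the 8-mm spacing of the full-scale analysis, scaled
to desk-sized problems).

**LCMV.** The sensor covariance is pooled over epochs after per-epoch
mean removal and diagonally loaded with `reg × mean eigenvalue`
(default 5%, the conventional magnitude where no value is dictated by
the data; configurable). Per source, the lead field is reduced to its
two strongest field topographies (discarding the numerically silent
radial direction), the orientation maximizing output power — the
minimum eigenvector of `Lᵀ C⁻¹ L` — is selected, and the scalar
unit-gain weights are `w = C⁻¹l / (lᵀC⁻¹l)`. Weights are computed per
frequency band from band-filtered epochs, so each band's filter is
adapted to the covariance at those frequencies. No weight
normalization is applied; relative power already removes the
depth-dependent gain.

Two numerical properties are enforced and tested: unit gain at every
source (to 1e-8), and the regularization path — the output variance of
a filter at an off-target location is non-*decreasing* in the loading,
because loading trades interference suppression for weight-norm
control (the constrained minimum of `wᵀCw + reg·‖w‖²` moves away from
the unregularized variance minimum monotonically).

## PLS

**Mean-centered PLS** decomposes the features × groups matrix of group
means after removing each feature's grand mean across groups. The grand
mean is *unweighted* by group size (default), so contrasts are not
dominated by the largest group; the size-weighted variant is available
(`weighted_centering=True`). Centering makes each feature row sum to
zero, so exactly `n_groups − 1` structural LVs exist and the
singular-value energy equals the squared Frobenius norm of the centered
matrix.

**Behavioral PLS** decomposes the features × variables Pearson
correlation matrix pooled over all included subjects (the variant that
stacks per-group correlation blocks is available behind
`within_group_correlation=True`). Constant features or variables make
the correlation undefined and raise an error naming the offender.
Missing behavioral data are handled by listwise deletion per analysis
before entry (`from_band_power` does this), matching the differing
per-analysis Ns that arise when only subsets of a cohort have MRI or
neonatal data.

**Permutation test.** Group labels (mean-centered) or behavioral rows
(behavioral) are permuted; the full decomposition is recomputed each
time; `p(LV k) = (#{s_perm(k) ≥ s_obs(k)} + 1)/(n_perm + 1)`. The +1
smoothing avoids p = 0 and is the standard Monte-Carlo convention. The
per-index comparison makes LV1's p-value exact under exchangeability;
p-values of later LVs are reported but conservative interpretation is
advised when LV1 is strong.

**Bootstrap.** Subjects are resampled with replacement within group
(whole-sample if no groups); draws collapsing a group onto a single
unique subject are redrawn (at most 100 times, then an error). Each
resampled solution is sign-aligned to the original per LV (flip when
the salience dot product is negative); full Procrustes rotation across
LVs is available (`procrustes=True`) but off by default, since axis
reflection is the dominant instability when only LV1 is interpreted.
Bootstrap ratio = original salience / SE of aligned bootstrap
saliences; an SE below 1e-12 marks a degenerate feature (no sampling
variability, e.g. an identically-zero feature) and yields a ratio of 0
by convention. Contrast CIs are 2.5/97.5 percentiles of the aligned
bootstrap contrasts. Defaults are 500 permutations and 500 bootstraps,
both configurable.

**Sign convention.** Point-estimate LVs are oriented so the
largest-magnitude contrast element is positive. Orientations are
fundamentally arbitrary, so cross-analysis map comparisons report
magnitude or are interpreted up to sign.

**Brain scores** are the raw dot product `X·u`. For noise-free data the
centered group-mean scores reproduce `contrast × singular value`
exactly; this identity is tested.

## Structural measures and post-hoc analyses

The TV-CGV ratio is thalamic volume (hemispheric mean) divided by
cortical gray matter volume — dimensionless, scale-invariant, strictly
increasing in TV and decreasing in CGV. Structural inputs are consumed
as FreeSurfer-style tabular exports; no image processing is performed.

Z-map correlations pool all source × band bootstrap ratios of two
analyses into one Pearson correlation; maps must share the feature
grid. Tail-power associations select, per band, the
`ceil(fraction × n_sources)` locations (default 2.5%) from the skewed
tail of the band's z-scores — the side follows the sign of the
bias-corrected Fisher–Pearson sample skewness, with ties at the cutoff
broken by ascending source index and zero skew treated as positive —
then correlate each subject's tail-averaged relative power with a
covariate, per group and pooled. Pearson correlation is used
throughout, with two-sided t-based p-values.

The neonatal regression is OLS (via statsmodels) of a structural
outcome on GA, sex, infection, SNAP, log-morphine, log-pain and the
sex × GA interaction, with intercept, on complete cases; with 37
complete cases the F statistic carries (7, 29) degrees of freedom.
Perfect collinearity raises an explicit rank-deficiency error. No
multiple-testing correction is applied across post-hoc correlations.

## The synthetic cohort generator

The generator is the package's study-conditions bench: it emulates a
three-group cohort (default 23/36/39 subjects; MRI subset 13/24/13,
which yields 37 preterm complete cases for the neonatal regression) on
a 50-source grid with the five canonical bands.

**Brain block.** Per subject, source and band, an unconstrained logit
is drawn as `base + group shift + noise` and mapped through a softmax
per source, so relative power is compositional by construction. The
baseline composition is delta .25, theta .20, alpha .30, beta .15,
gamma .10. The ELGA-like group's logits are shifted by
`contrast_effect` (default 1.0, in logit units) along a unit-norm
"slowing" salience — delta/theta positive, alpha/beta negative, gamma
neutral, spatially smooth, and with zero band-sum per source so the
shift is a pure redistribution of power (this also makes log-power
projections on the salience equal logit projections, which the
recovery oracles use). `noise_sd` (default 0.15 logit units) is the
*independent per-feature residual* SD: it deliberately excludes the
global amplitude factors (removed by the compositional normalization)
and the shared spatial variance carried by the latent factor, which
dominate total between-subject variability in real recordings. Passing
tests at these conditions shows the estimators recover structure at
realistic residual-noise levels; it does not certify performance under
strongly spatially correlated residuals, which real data have.

**Latent factor.** Each subject's latent score is the projection of
their logit field on the planted salience, z-scored. The 11
neurocognitive outcomes (four WISC index scores, two CBCL, two BRIEF,
three BEERY — full-scale IQ is omitted as a composite of the index
scores) are `mean + SD × (ρ·latent + √(1−ρ²)·noise)` on their
published scales, with default loadings negative for cognitive/motor
scores and positive for behavior-problem scales.

**Structure.** Volumes and intensities are drawn from group-specific
normal distributions with means/SDs taken from published cohort
descriptives of the three groups. Subject-level deviations are coupled
to the *within-group* latent deviation (defaults: TV −0.4, CGV −0.1,
TI −0.4, CGI +0.3, CWI +0.2, ICV 0): the group-level component of the
latent is already expressed through the planted group means and the
neonatal model, and coupling the full latent would double-count group
separation and confound the neonatal predictors.

**Neonatal model.** GA, sex, infection, SNAP, morphine (log1p mg/kg)
and pain (log1p procedure count) are drawn per group from published
descriptives; term-born controls have no neonatal chart data. Preterm
TI is generated as `intercept + Xβ + residual` with the β vector
defaulting to published regression coefficients, and the residual
variance scaled so the generating model explains ρ² = 0.22 of the
preterm TI variance — the optimism-corrected value for which an
in-sample 7-predictor OLS on ~37 cases shows R² near the published
0.37 (`E[R²] ≈ ρ² + (1−ρ²)·p/(n−1)`).

**Sensor level.** For exercising the beamformer chain, sources emit
sums of band-limited Gaussian noise with requested per-band RMS
amplitudes through the spherical lead field, with optional white sensor
noise and a synthetic head-position trace into which a motion excursion
can be planted. The generator makes no attempt at 1/f spectral realism
or physiological artifacts; those are out of scope.

**Determinism.** Identical config and seed reproduce all outputs
bit-identically. The pipeline derives per-stage seeds from one master
seed via `SeedSequence` in a fixed order, so full-study reruns are
byte-identical at the CSV level.

## Problem sizes and tolerances

The shipped tests run the calibration and recovery studies at
desk-scale sizes chosen as the package's own benchmark conditions: null
calibration on 200 cohorts of 60 subjects × 50 features with 500
permutations; contrast recovery on 50 replicates of 60 subjects × 250
features with 500 permutations and bootstraps; behavioral recovery on
50 replicates of the default 98-subject cohort. Dense-algebra oracle
agreement is asserted at 1e-10 (SVD), 1e-8 (OLS) and 1e-12 (dot
products); compositional and unit-gain contracts at 1e-10 and 1e-8;
white-noise relative power matches bandwidth fractions within 0.02
absolute.

## Known limitations

- The spherical forward model and radial magnetometers are a toy
  geometry; cross-talk and depth-bias magnitudes do not transfer to
  realistic sensor arrays.
- Residual noise in the generator is independent across features;
  spatially correlated residuals in real data reduce the effective
  degrees of freedom of the permutation null less than independent
  noise does, and recovery at a given effect size will be harder.
- Only one latent factor links brain, outcomes and structure;
  multi-factor generation is deferred.
- Behavioral PLS p-values for LVs beyond the first inherit the usual
  conservativeness of per-index permutation comparisons.
- ICA-based artifact removal, realistic head models, vendor MEG formats
  and image processing are explicitly out of scope; the package
  consumes tabular structural exports.
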