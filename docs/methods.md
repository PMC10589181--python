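# Methods

## The experiment being modelled

A two-year laboratory incubation: 16 g of a loamy agricultural topsoil
(initial SOC 11.2 g C kg⁻¹, total N 0.88 g kg⁻¹) mixed with 0.4 g of
milled C4-grass root litter in gas-tight jars, six treatments × five
replicates. The litter batches span C:N ratios of 50, 65, 85 and 124
(C and N concentrations 44.17/0.89, 43.64/0.67, 44.39/0.52 and
43.43/0.35 %), plus an unamended control and a variant of the C:N 124
litter with ammonium nitrate added to bring the amendment C:N down to 50.
Jars are destructively sampled at 6, 12 and 24 months; each sample is
size-fractionated at 20 µm into a coarse (POC) and fine (MAOC) fraction,
and organic C and δ¹³C are measured on both fractions and on the bulk
soil. The added C roughly doubles the jar's carbon, so the litter-derived
share of initial C is ≈ 50%.

## Isotope accounting

Litter-derived carbon in any sample is estimated with the linear
two-source mixing equation, f_C4 = (δ_sample − δ_ref)/(δ_litter − δ_ref).
The reference signatures are the control means at time zero, taken per
fraction: litter δ¹³C −14.2‰, native MAOC −26.2‰, native POC 0.5‰ more
negative (−26.7‰). Linear mixing in δ is an approximation to mixing in
atom fraction; at natural-abundance differences of ~12‰ the error is far
below measurement noise, and it makes f_C4 exactly unbiased under
additive δ noise.

Fraction C contents are converted to g C per kg dry mineral soil using
**constant mass proportions**: per treatment, the coarse-mass share
coarse/(coarse + fine) is fixed at its earliest-occasion replicate mean
and applied at every occasion. Normalising by coarse + fine (not by the
pre-fractionation input) cancels the fractionation mass-recovery factor,
which hits both fractions alike; this removes fractionation-yield noise
from the pool time series. Mixing ratios outside [0, 1] (possible under
noise) are clipped and counted; the clip rate is reported on the
partition table.

Diagnostics: mass recovery = 100·(coarse + fine)/input mass; C recovery =
100·(sum of the four pools)/bulk SOC, where bulk SOC is measured on an
independent aliquot — so C recovery scatters around 100% once noise is on.

Relative changes follow the reporting convention of the summary table:
litter-derived pools are expressed against the C added with the litter;
native pools and total SOC against the initial amount in the control's
corresponding fraction (bulk plus added litter for total SOC). The
summary's Average row is the unweighted mean of treatment means; its SD
is taken over all replicate values (the convention that reproduces the
published Average row).

## Mass-balance fluxes

The jars are vented, not gas-monitored, so respiration is the residual
100 − %POC_new − %MAOC_new of the added litter C; small negative
residuals under noise are clamped to zero with a warning. Mineralised
litter N is (litter-derived C loss)/(litter C:N). Priming is the relative
difference between a treatment's old-C loss and the control's mean old-C
loss, per replicate, reported as mean ± SD; the control can be a single
jar or a replicate series.

## The synthetic generator

True pools per jar follow the linear system

    POC_s' = −k_s · POC_s
    MAOC_s' = −m_s · MAOC_s + h · k_s · POC_s        (s ∈ {new, old})

solved **exactly** on each inter-sampling interval (matrix exponential in
closed form, including the k = m degenerate case), never by Euler
stepping. The transfer fraction h routes decomposed POC to MAOC of the
same isotopic source; the rest is respired. Native-pool rates carry a
priming multiplier 1 + α·(CN − CN_ref)/CN_ref, clamped at zero, with the
control pinned at 1; the N-amended treatment uses the C:N 124 multiplier
plus a small positive offset (default +0.15), reflecting that mineral N
did not alleviate — and slightly strengthened — the priming. CN_ref
defaults to 25, the classic net-N-mineralisation threshold for microbial
substrate use.

Default rates (per month) were calibrated once, analytically, to the
observed two-year pattern: k_poc_new 0.0677 (~80% of added litter C lost
from POC), k_maoc_new 0.005 and h 0.125 (~9% of added C as MAOC_new at 24
months), k_poc_old 0.019 (~33% native POC loss), k_maoc_old 0.0088 with
α_MAOC = 0.066 (native MAOC losses rising from ~18% to ~22% across the
C:N gradient, positive priming against the control). α_POC defaults to
−0.05: the priming comparison showed *less* native-POC loss in amended
soils than in the control (negative priming, not significant). A single
linear multiplier anchored at the control cannot simultaneously produce
that and the (equally non-significant) increase of POC_old loss with C:N
seen in the treatment table; the generator follows the priming
comparison, and consequently its simulated POC_old losses decrease
slightly with C:N.

The initial native POC:MAOC split is not fixed by relative-change data;
it defaults to 30:70 of native SOC (configurable). Coarse mineral mass
share defaults to 0.775 (sand plus coarse silt of a sandy loam).

The measurement layer computes fraction δ¹³C by C-weighted mixing of the
source signatures, then applies noise: multiplicative concentration noise
(CV 3%), additive δ noise (SD 0.2‰), and a drawn mass-recovery factor
(98.2 ± 0.7%) applied to both fraction masses. Bulk C and δ are observed
independently of the fractions. Concentrations are reported per kg dry
mineral soil, so control and amended jars share one basis. One master
seed drives per-jar substreams keyed by a stable hash of (treatment,
replicate), making output independent of iteration order and
byte-identical across runs.

With noise off, observations invert exactly: the partition recovers the
simulator's true pools to < 1e−9 relative and C recovery is exactly 100%.
What passing tests on these data do *not* show: the generator has no
within-treatment biological variability (replicates differ only through
measurement noise), no temporal drift in reference signatures, no
microbial pools, N dynamics or moisture/temperature response — so field
data will scatter more and can violate the constant-reference assumption.

### Litter spectra

Synthetic DRIFT spectra live on the instrument grid (4000→400 cm⁻¹, 4
cm⁻¹ steps): Gaussian peaks centred inside each diagnostic band window
(aliphatic 2990–2915, aromatic 1660–1600, amide I 1658–1652, amide II
1548–1540, lignin 1512–1504, amide III 1320–1230, polysaccharides
1180–1140 cm⁻¹), a gentle sloping baseline, cosmetic peaks outside every
window, and additive absorbance noise (SD 0.002). Peak amplitudes are
affine in litter C:N, calibrated numerically (minimax per band, baseline
and band-overlap included) against the observed compound ratios. The
affine form reproduces the C:N 50 and C:N 124 batches within ~4% on all
five ratios; it cannot bend enough for the convex progression of the
amide ratios at the two intermediate batches (aliphatic:amide II is up to
~16% off there) — a documented limitation of the affine amplitude model,
not of the ratio computation.

Band ratios use the maximum absorbance over grid points inside the
window, ends inclusive, ties broken toward the lower wavenumber. The
amide I window lies inside the aromatic window; both are evaluated
independently (no de-overlapping). No baseline correction is applied
before ratio computation (a subtract-minimum hook exists, default off).
Ratios are invariant under positive scaling, hence identical on raw and
max-normalised spectra. Replicate handling defaults to per-replicate
ratios then averaging; averaging spectra first is also offered.

## Statistics

Regressions are ordinary least squares on individual jars (n = 5 per
treatment), one per pool × occasion, against the treatment-level quality
indicator; the N-amended treatment is excluded (its amendment C:N does
not describe the litter), as is the control (no indicator defined). The
slope test is a two-sided t with n − 2 df; significance at 0.05; no
multiple-testing correction is applied across the pool × occasion grid.
Degenerate inputs are resolved explicitly: constant y → slope 0, R² = 0,
p = 1; perfect fit → R² = 1, p = 0.

Treatment differences use one-way ANOVA plus Tukey HSD, with pairwise
adjusted p-values from the studentized-range distribution (numerical
quantiles, not table lookup). The compact letter display uses the
insert-and-absorb algorithm with groups processed in descending mean
order and absorbed letter sets minimised, which makes the letters
deterministic; two groups share a letter iff their adjusted p ≥ α.
Residual normality is reported as an advisory note (skewness, excess
kurtosis, QQ data export) and never gates results.

## Problem sizes and determinism

The default experiment is 6 treatments × 5 replicates × (t0 + 3
occasions) = 120 observations; the test suite and the acceptance script
use this size throughout, plus 1000–2000-replicate Monte-Carlo checks for
noise calibration, estimator unbiasedness and the null rejection rate of
the slope test — sizes at which those binomial/SE intervals are tight
enough to be informative while the whole suite stays fast. All
randomness flows from explicit seeds; reruns are bit-reproducible.

## Known limitations

- The generator's treatment effects enter only through the priming
  multiplier and litter amount; litter-decay rates themselves do not vary
  with C:N, so per-treatment POC_new differences are muted relative to
  real data.
- Bulk-based new/old partition uses the control's bulk reference; because
  native POC and MAOC decay at different rates, the old-pool mixture δ
  drifts slightly over time, biasing the bulk split by a few tenths of a
  percent (the per-fraction pools are unaffected).
- The JCAMP-DX reader covers uncompressed (X++(Y..Y)) AFFN data only.
- Real-data correlation magnitudes (e.g. quality-indicator R² against
  final pools) are reproducible only qualitatively from synthetic data.
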