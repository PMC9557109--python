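# Methods

## Problem and scope

Two summer maize hybrids of different maturity class, grown side by side for
several years, usually yield differently. The package implements the
physiological accounting that attributes that difference: how much thermal
time each hybrid consumes before and after silking, how long its canopy stays
photosynthetically effective after silking, how much vegetative dry matter is
remobilized into grain (and how a ¹³C pulse label corrects that estimate),
and whether the resulting metric differences are statistically supported in a
replicated trial. It is an analysis pipeline, not a crop growth simulator:
no soil, water or nitrogen processes, no light-response curves, no
grain-filling kinetics.

## Thermal time

Daily growing degree days are `max(0, (Tmax+Tmin)/2 − Tbase)` with
`Tbase = 10 °C` (the conventional maize base temperature; configurable).
Negative daily values are clipped to zero — standard agronomic practice and
irrelevant for summer data — and no upper temperature cap is applied.
Accumulation windows are start-exclusive and end-inclusive, so the
sowing→R1 and R1→R6 intervals tile the season exactly; day counts are plain
calendar-date differences. Published stage tables do not always follow one
endpoint convention internally, so reconciliation with printed day counts is
exact only where the source used the same convention.

Because the stated "yield per GDD" denominator is ambiguous in practice
(printed values reproduce with neither the total nor the post-silking
accumulated temperature alone), `yield_per_gdd` takes an explicit GDD
argument and the report layer emits both variants side by side
(`yield_per_gdd_total`, `yield_per_gdd_post`).

## Canopy dynamics

Post-silking LAI is modelled as `LAI(t) = A·exp(−(t−B)²/(2C²))` on the
days-after-silking axis (A = maximum LAI, B = its day, C = curve width in
days). The fit initializes from the closed-form log-quadratic solution
(log LAI is quadratic in t for exact Gaussian data) and refines by
Levenberg–Marquardt (`scipy.optimize.curve_fit`, xtol 1e-10); at least four
positive observations spanning the peak are required, flat series are
rejected. `R²` is reported as `1 − SS_res/SS_tot`. The duration of higher
LAI is `DLAI = C·√(2 ln 2)` — the time for the fitted curve to fall to half
its maximum, so `LAI(B ± DLAI) = A/2` identically.

Ear-leaf net photosynthesis after full expansion is fitted by OLS as
`Pn = a − b·t` using post-silking observations only. `Pi` is the *measured*
Pn at the earliest post-silking time point (not the fitted intercept), and
`APD = Pi/(2b)` is the time for the decline to lose half of Pi. This closed
form reproduces published APD values to within printed-coefficient rounding
for most rows; residual deviations of a day or two trace to the source's use
of unrounded coefficients and are not forced.

## Dry-matter partitioning and the ¹³C correction

With total aboveground dry mass per plant at R1 (silking) and R6 (maturity):
`PrSDMAR = 100·R1/R6`, `PoSDMA = R6 − R1`, `PoSDMAR = 100·PoSDMA/R6` (the
two shares sum to 100 by construction). Organ remobilization is
`DMR = m(R1) − m(R6)` and `DMRE = 100·DMR/m(R1)`; a negative DMR (the organ
gained mass) is retained and flagged, but floored at zero when converted to
a grain contribution, since remobilized-to-grain mass cannot be negative.

The ¹³C pulse label distributes over organs; per organ the tracer proxy is
`(mean labeled atom-% − mean reference atom-%)/100 × organ dry mass`,
assuming a constant carbon fraction across organs (no isotope-specific
fractionation model). Negative excesses are floored at zero before
normalization; a cohort with no positive excess is a labeling failure.
The year×hybrid mean grain fraction is applied to replicate-level DMR
(replicate-level fractions are not identifiable from a 3+3-plant cohort).
Then `DMR to grain = (DMR_leaf⁺ + DMR_stalk⁺)·f_grain` and
`DMRC = 100·(DMR to grain)/grain(R6)`; the complement `100 − DMRC` is the
contribution of post-silking assimilation.

Harvest index is grain over total dry mass at R6. Sink capacity is ears m⁻²
× grains per ear × single-kernel mass (1000-grain weight / 1000); the
grain/leaf ratio divides it by leaf area at R1 (per-plant masses scale to
area through the planting density, default 75,000 plants ha⁻¹). Yields are
standardized to 14% kernel moisture. Bract + cob ("other") is always a
separate pool, never merged into stalk.

## Statistics

The two-way ANOVA assumes the balanced fixed-effects factorial the design
prescribes (year fixed, equal replicates per cell); it is computed through
statsmodels OLS + `anova_lm` (type I, which coincides with the classical
balanced decomposition) and refuses unbalanced data or single-replicate
cells. Noise-free data with real effects would give an infinite F; that case
is flagged (`zero_error`) rather than reported as a number.

LSD mean separation uses `LSD = t(1−α/2, df_err)·√(2·MSE/n)` with the pooled
within-year one-way error (treatments = hybrids), α = 0.05 by default.
Letters are the maximal runs of consecutive descending means whose extremes
differ by at most the LSD; this makes "share a letter" exactly equivalent to
"not significantly different" under the pairwise LSD test, which the tests
verify by exhaustive pairwise comparison. Ties are broken by label order.

Pearson correlation and OLS regression wrap scipy. Percent and paired
difference ranges report raw per-year values; only their min/max are rounded
half-up to one decimal, matching how trial reports quote ranges. The
correlation report regresses replicate-level yield on DMA and on HI within
each year×hybrid (n = 3 points per regression — these r values are fragile
by construction, as in the source tables).

## Synthetic trials and what passing tests show

The generator emulates the published trial's structure at its reported
magnitudes: two hybrids (early: GDD to silking 800 °C d, total 1690;
mid-late: 900/1790), Gaussian LAI truths (A 4.55/5.13, C 42.3/49.6 d), Pn
declines (Pi 47.3/48.5, b 0.54/0.43), organ trajectories giving HI ≈
0.574/0.552 and DMRC ≈ 10.0/7.5%, grain ¹³C fractions 0.64/0.605, and yield
components near 12.0/13.0 t ha⁻¹. Weather is a seasonal sinusoid (mean
21.5 °C, amplitude 5.5, peak late July, 10 °C diurnal range) with AR(1)
noise; phenology dates are the first days accumulated GDD crosses each
hybrid's thresholds (V6 and V12 at 45% and 75% of the silking threshold,
R5 fixed at 45 days after silking). Printed "±" dispersions are read as
standard errors of n = 3 plots, so plot noise is drawn with sd = SE·√3.

Every generated quantity has a closed-form ground truth, which buys two
strong tests: at zero noise the full pipeline is the identity on the truth
(to 1e-6), and under realistic noise DLAI and HI estimates are unbiased to
within 2% over 100 seeds (run on a 2-year subset to keep the suite fast;
the per-seed problem is 4 Gaussian fits and 4 HI means, sizes chosen as the
smallest that still average over stage placement and weather draws). What
this does **not** show: real canopies are not exactly Gaussian (the
generator draws pre-silking LAI from the same curve, which real sigmoid
growth violates), real plot errors are correlated across traits, and real
phenology responds to photoperiod and stress — so passing tests certify the
estimators and bookkeeping, not the biological model.

## Numerical choices and degenerate inputs

- Gaussian fit: log-quadratic initialization falls back to
  (max, argmax, half-span) when the log-domain curvature is non-negative;
  the fitted width's sign is normalized to positive.
- Zero-variance inputs (flat LAI, constant regressor, equal-time Pn
  observations) raise typed errors rather than returning NaN.
- LSD letter ties use a tolerance of 1e-12 relative to the LSD.
- Report tables round at publication precision (yield integer, HI 3
  decimals, fit parameters 2); full precision is preserved in `machine/`.
- Dataset validation reports violations instead of raising; loading raises
  only when error-severity violations are present, and replicate imbalance
  is a warning (the ANOVA itself enforces balance).

## Known limitations

- DLAI recomputed from 2-decimal printed widths deviates from published
  columns by up to ~0.2 d (the source used unrounded fit parameters).
- APD's closed form cannot reproduce every published value exactly for the
  same reason; deviations up to ~2.4 d remain in some years.
- The ¹³C bookkeeping is a mass-proxy model; it does not model isotope
  discrimination or respiration losses.
- The generator's noise is independent across traits and plots; it cannot
  emulate spatially correlated field error.
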