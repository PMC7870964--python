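# Methods

## The model

`emberfire` predicts the monthly burned-area fraction BA ∈ [0, 1] of
coarse (≈1°) grid cells from socio-environmental drivers with a
*discretized* regression: BA is binned into 25 ordered classes — a zero
class [0, 10⁻⁶) plus 24 intervals dividing [10⁻⁶, 1] equally on a log
scale — and a dense network with a single hidden layer of 12 ELU units and
a 25-way softmax head is trained by categorical cross-entropy to predict
the class probabilities p_i. Continuous burned area is reconstructed as

    BA = Σ_i p_i B_i,

where B_i is the geometric mean of class i's bounds (B_1 = 0 for the zero
class, so an unburned prediction contributes nothing). The log binning is
the model's whole treatment of the extreme right-skew of burned area — the
majority of cell-months burn essentially nothing while a few savanna cells
burn tens of percent — and no class reweighting is applied on top of it.

Bins are left-closed/right-open with the top bin closed at 1. The literal
geometric mean of the zero class's bounds (0, 10⁻⁶) is 0, which we adopt;
it is the behaviour one wants when the model is confident a cell does not
burn.

### Training

Inputs are z-scored per feature (fitted on training rows only; the
population standard deviation). Vegetation-type fractions enter unscaled
in [0, 1]. Targets are one-hot class indices. Training uses minibatch
Adam (rate 10⁻³, batch 1024, optional per-epoch decay), inverted dropout
0.05 on the hidden layer, and early stopping on validation cross-entropy
(patience 20 epochs, minimum improvement 10⁻⁴); the parameters with the
best validation loss are returned. Everything is bit-reproducible from the
seed. The data split designates all rows from years 4–6 of the series as
the held-out test window (mirroring a 2005–2007 window in a 2002–2015
record); the remaining rows are split 70/30 into training and validation
at random.

Monitoring cross-entropy rather than accuracy is a deliberate choice:
class accuracy is a step function that barely moves for the dominant zero
class, while the cross-entropy tracks the probabilistic fit the
reconstruction actually uses.

## Feature engineering

Drivers are monthly gridded fields: temperature `ts` (°C), precipitation
`pr` (mm/month), cloud cover `cld`, vapour pressure `vp` (hPa), gross
primary productivity `gpp` (gC/m²/month), population density `pop`
(persons/km²), road density `rdtot`, and a lightning climatology `ltn`.
`pr`, `pop` and `rdtot` are transformed as log10(1 + x). Two fuel proxies
are derived from GPP:

- `gppl1` — cumulative GPP over the 12 months up to (and excluding) the
  current month: a proxy for standing grass/canopy biomass. The first 12
  months of a series are unusable and those samples are dropped.
- `gppm1`/`gppm1s` — GPP of the previous growing year, a litter proxy:
  for northern-hemisphere cells the previous calendar year (Jan–Dec); for
  southern cells the calendar year is shifted by six months, so any month
  of calendar year y uses the Jul(y−1)–Jun(y) window. The hemisphere is
  resolved per cell by the sign of the cell-centre latitude (equator cells
  count as northern). Both proxies are constant within a calendar year.

Vegetation-type fractions (the 12 classes: non-vegetated, needleleaved/
broadleaved evergreen/deciduous, mixed forests, open/closed shrublands,
woody savannas, savannas, grasslands, croplands) are appended to every
model's inputs and are never candidates in the driver search. Only cells
with at least 30% non-agricultural vegetation cover
(1 − cropland − non-vegetated ≥ 0.30) are modelled.

## Skill metrics and the aggregate score

For a model on a region, five metrics compare predicted and observed
burned area: Pearson correlations of spatially aggregated monthly series
(r_T), of yearly series (r_IA), of pooled per-cell yearly anomalies
(r_An; each cell-year total minus that cell's multi-year mean), of
per-cell time means across cells (r_S), and a fractional-deviation score
r_BA = 1 − |1 − BA_pred/BA_obs| on mean yearly totals. The pooled
cell-month correlation r_I is reported but never scored: it is known to be
a poor discriminator between models that differ in aggregate behaviour.
Spatial aggregates are area-weighted (spherical cell areas, totals in
Mha/yr) by default, with a flat-weighting option for synthetic tests. The
long-term trend is the OLS slope of yearly totals against year.

The metrics combine into

    P = 100 · sqrt( Σ w_i r_i² / Σ w_i ),   w_IA = 4, other w_i = 1,

which is 0 for a skill-free model and exactly 100 for an ideal one. The
interannual weight privileges interannual predictability, which would
otherwise be swamped by the far larger spatial extent of the data. A
variant normalization dividing by 4 Σ w_i (capping P at 50) is available
behind a flag for comparability with the alternative printed form of the
score; the default is the normalization consistent with a 0–100 range.

The anomaly correlation is defined per cell: a correlation of
region-total anomalies would be identical to r_IA by translation
invariance of the Pearson correlation and carry no extra information.

## Driver selection

Per region, a deterministic greedy backward elimination replaces manual
trial-and-error: starting from the full candidate set, each single-driver
removal is retrained and scored, the removal with the highest P is kept,
and the procedure iterates down to one driver, logging every evaluated
spec in a catalog. Each spec's training seed derives from (seed, region,
spec) via CRC-32, so reruns reproduce the catalog exactly. Ties break
toward fewer drivers, then lexicographic spec order. The *minimal model*
is the fewest-driver spec with P within 3.0 points of the best; ties at
equal size go to the higher score. Global predictions mosaic the minimal
regional models onto their (disjoint) region masks.

## Sensitivity analysis

Climate sensitivity perturbs one driver in raw units with everything else
fixed: temperature additively (default ΔT = 1 °C), vapour pressure
multiplicatively (default ×1.01), re-standardizes, and re-predicts.
S = ΔBA/ΔT is kept per month internally and reported as per-cell annual
means; S% = 100·S/BA is undefined where the baseline prediction is zero.
Vegetation fractions are held fixed (the perturbation is assumed too small
to move the vegetation distribution). If a region's selected model dropped
the perturbed variable, the best-scoring evaluated model that retains it
is used instead. Per-vegetation-type tables label each cell by its
dominant type (largest fraction, requiring ≥ 0.5; otherwise "mixed
vegetation") and report cell counts, total baseline burned area, and the
baseline-BA-weighted mean S%, plus a global-total row. The dominance
threshold is an interpretation: any single-type labelling of mixed cells
is a modelling choice, and the 0.5 cut guarantees the label is a majority.

## The synthetic world

Because the package is exercised without external data, a seeded generator
produces a world with known structure. Burned area follows

    BA = z · r₀ · F(fuel) · H(T) · exp(−λP) · (1+pop)^(−κ_r) · f_nat,

with F(fuel) = (fuel/f₀)·exp(1 − fuel/f₀) a hump with optimum f₀,
H(T) = σ((T−15)/2)·σ((30−T)/3) a thermal window (fire largely above
15 °C, declining beyond 30 °C), λ the instantaneous precipitation
suppression, κ_r a region-specific human-suppression exponent, f_nat the
non-agricultural fraction, and z ~ Bernoulli(1 − z₀) a zero-inflation
term; multiplicative lognormal noise (sd 0.3 by default) and clipping to
[0, 1] follow. Fuel is the trailing 12-month sum of realized GPP — biomass
accumulates — generated with a one-year spin-up so the first output month
already has a full history; on usable samples it coincides exactly with
the `gppl1` feature, making the generative driver set {ts, pr, gppl1}
(plus pop where κ_r ≠ 0).

Driver fields emulate the statistical structure of real data without any
geography: temperature has a meridional gradient (28 − 0.45·|lat| °C),
a seasonal cycle whose phase flips by six months across the equator and
whose amplitude grows poleward, smooth spatial anomalies, and yearly
anomalies; precipitation is seasonal, non-negative, and spatially smooth
with drought/wet years; GPP is hump-shaped in temperature and saturating
in precipitation times an unobserved smooth "fertility" field (so GPP
carries information no other driver has) with 15% noise; cloud cover and
vapour pressure are noisy monotone proxies of precipitation and
temperature (deliberate realistic collinearity); population density is
static and log-uniform-ish up to 10³ persons/km²; road density correlates
with population; lightning is a 12-month climatology. Vegetation fractions
draw 4 active natural types per cell from a Dirichlet plus a west-to-east
cropland gradient, so the burnable-cell filter has bite. The default world
is 20×20 cells at 3°/cell over 14 years with two regions: a weak-
suppression "NHAF"-like half (κ = 0.15) and a strong-suppression
"SA"-like half (κ = 1.2), mirroring the starkly different population
responses of African and South American fire regimes.

With noise and zero-inflation set to zero ("oracle mode") burned area is
an exact deterministic function of the drivers, and the generator's
analytic temperature derivative (central difference of the response, step
10⁻⁴ °C, all other drivers fixed — the same protocol as the model-based
perturbation) serves as ground truth for the sensitivity stage.

### What the generator does not emulate

No coastlines or real region geometries; no spatial contagion of fire
between cells; no fire–vegetation feedback; no autocorrelated weather
beyond the seasonal + yearly anomaly structure; no trends in population or
land use. Passing tests on this world therefore demonstrate that the
pipeline recovers known relationships of the stated form under realistic
skew, collinearity, and noise — not that the same skill transfers to any
particular observational record.

## Numerical choices and degenerate inputs

Pearson correlation of a constant series is undefined and returned as NaN
with a warning; a zero observed total makes r_BA undefined. Zero-variance
feature columns standardize with scale 1 (warning). Incomplete final years
are excluded from yearly series. Cell-months missing in either field are
excluded from every metric. The training-row guard (≥ 50 rows per hidden
unit by default) rejects degenerate fits. The test suite and worked
examples use problem sizes (20×20 cells, 14 years; search worlds with 8
candidate drivers and ~100-epoch fits) chosen to keep a full run on a
single CPU in the minutes range while leaving all recovery margins wide.

## Known limitations

- The discretization bounds reconstructed burned area above by
  B_25 ≈ 0.75; cells burning more than that in a month are under-predicted
  by construction.
- Perturbation sensitivities inherit the usual caveat of correlated
  inputs: the model's attribution to one driver is only trustworthy where
  the driver set gives the network a chance to separate effects (the
  fuel-accumulation timescale does exactly this for temperature).
- The greedy backward search is deterministic but not exhaustive; with
  strongly collinear candidates different seeds can retain different
  proxy subsets (the catalog records every evaluated spec, so this is
  auditable).
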