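"""Synthetic gridded fire world with a known burned-area response surface.

The generator emulates the statistical structure of the real driver
datasets — hemisphere-shifted seasonal cycles, spatially smooth fields,
hump-shaped fuel–climate coupling, a highly right-skewed zero-inflated
burned-area distribution, and region-specific human suppression — while the
underlying response function stays available in closed form, so that every
downstream stage (feature engineering, training, driver selection,
sensitivity analysis) can be tested against ground truth.

Monthly burned-area fraction is generated as

    BA = z * base_rate * F(fuel) * H(T) * exp(-lambda * P)
         * 10^(-kappa_r * log10(1 + pop)) * (1 - cropland - non_veg)

with F(fuel) = (fuel/f0) * exp(1 - fuel/f0)   (hump, maximum 1 at f0),
     H(T)    = sigmoid((T - T_lo)/2) * sigmoid((T_hi - T)/3),
     z ~ Bernoulli(1 - zero_inflation),
followed by multiplicative lognormal noise and clipping to [0, 1]. Fuel is
the trailing 12-month sum of realized GPP (biomass accumulates; the
generator runs a one-year spin-up so the first output month already has a
full fuel history), which on usable samples coincides with the ``gppl1``
feature. With ``noise_sd = 0`` and ``zero_inflation = 0`` burned area is an
exact deterministic function of the drivers (oracle mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .grid import (GridSpec, MonthlyField, RegionPartition, VegetationFractions,
                   VEG_TYPES, month_range)

#: Driver variable codes produced by the generator.
DRIVER_CODES = ["ts", "pr", "cld", "vp", "gpp", "pop", "rdtot", "ltn"]


class WorldConfigError(ValueError):
    """Raised when a world configuration is internally inconsistent."""


@dataclass(frozen=True)
class NicheParams:
    """Parameters of the generative fire-response surface.

    ``f0`` is the fuel optimum in gC/m^2 of GPP accumulated over the
    trailing 12 months; the temperature window
    [t_lo, t_hi] brackets where fire is thermally permitted; ``lam`` is the
    instantaneous precipitation suppression rate per mm/month; ``kappa``
    maps region code -> human-suppression exponent (burned area scales as
    (1 + pop)^-kappa); ``base_rate`` is the monthly burned fraction at the
    niche optimum with no suppression.
    """

    f0: float = 1800.0
    t_lo: float = 15.0
    t_hi: float = 30.0
    lam: float = 0.008
    kappa: dict = field(default_factory=lambda: {"NHAF": 0.15, "SA": 1.2})
    base_rate: float = 0.30

    def fuel_hump(self, fuel):
        r = np.asarray(fuel, dtype=float) / self.f0
        return r * np.exp(1.0 - r)

    def thermal_window(self, t):
        t = np.asarray(t, dtype=float)
        return expit((t - self.t_lo) / 2.0) * expit((self.t_hi - t) / 3.0)

    def suppression(self, pop, kappa_r):
        return 10.0 ** (-kappa_r * np.log10(1.0 + np.asarray(pop, dtype=float)))

    def response(self, fuel, t, pr, pop, kappa_r, natural_fraction):
        """Deterministic burned-area response (the z = 1, no-noise branch)."""
        ba = (self.base_rate * self.fuel_hump(fuel) * self.thermal_window(t)
              * np.exp(-self.lam * np.asarray(pr, dtype=float))
              * self.suppression(pop, kappa_r) * natural_fraction)
        return np.clip(ba, 0.0, 1.0)


@dataclass(frozen=True)
class WorldConfig:
    """Layout, span, and stochastic settings of a synthetic world.

    Defaults give a 20x20-cell world at 3 degrees/cell (so both hemispheres
    are represented), 14 years of monthly data, and two rectangular regions:
    a weak-suppression "NHAF"-like east half and a strong-suppression
    "SA"-like west half.
    """

    n_lat: int = 20
    n_lon: int = 20
    resolution: float = 3.0
    years: int = 14
    start_year: int = 2002
    regions: tuple = (("SA", (0, 20), (0, 10)), ("NHAF", (0, 20), (10, 20)))
    seed: int = 0
    noise_sd: float = 0.3
    zero_inflation: float = 0.3
    spatial_smoothness: int = 3
    interannual_anomalies: bool = True

    def __post_init__(self):
        if self.years < 3:
            raise WorldConfigError("years must be >= 3 (test-year window needs 3 years)")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise WorldConfigError("zero_inflation must lie in [0, 1)")
        if self.noise_sd < 0:
            raise WorldConfigError("noise_sd must be non-negative")
        if self.spatial_smoothness < 1:
            raise WorldConfigError("spatial_smoothness must be >= 1")

    def grid(self) -> GridSpec:
        return GridSpec.regular(self.n_lat, self.n_lon, self.resolution)

    def partition(self) -> RegionPartition:
        return RegionPartition.from_blocks(self.grid(), list(self.regions))

    def oracle_mode(self) -> "WorldConfig":
        """Noise-free variant: burned area is deterministic in the drivers."""
        return replace(self, noise_sd=0.0, zero_inflation=0.0)


@dataclass
class World:
    """A generated world: driver fields, vegetation, regions, burned area."""

    config: WorldConfig
    niche: NicheParams
    drivers: dict
    veg: VegetationFractions
    regions: RegionPartition
    ba: MonthlyField
    #: the generative fuel load (trailing 12-month GPP sum), kept for oracles
    fuel: MonthlyField = None

    @property
    def grid(self) -> GridSpec:
        return self.drivers["ts"].grid


def _smooth_field(rng, shape, width) -> np.ndarray:
    """Standardized spatially smooth Gaussian field on (lat, lon).

    Separable moving-average smoothing of white noise (kernel width =
    spatial correlation length in cells), then re-standardized.
    """
    from scipy.ndimage import uniform_filter

    raw = rng.standard_normal(shape)
    sm = uniform_filter(raw, size=max(1, int(width)), mode="reflect") if width > 1 else raw
    return (sm - sm.mean()) / (sm.std() + 1e-12)


def generate_world(config: WorldConfig, niche: NicheParams | None = None) -> World:
    """Generate drivers, vegetation fractions, regions, and burned area.

    The seed fully determines the output; the same config yields
    bit-identical worlds.
    """
    niche = niche or NicheParams()
    grid = config.grid()
    regions = config.partition()
    for code in regions.region_codes():
        if code not in niche.kappa:
            raise WorldConfigError(f"no suppression exponent kappa for region {code!r}")
    rng = np.random.default_rng(config.seed)
    nt = config.years * 12
    years, months = month_range(config.start_year, 1, nt)
    # one spin-up year so the first output month has a full 12-month fuel
    # history; all dynamic fields are generated internally for nt + 12
    # months and the spin-up year is discarded from the outputs
    nt_int = nt + 12
    years_int, months_int = month_range(config.start_year - 1, 1, nt_int)
    lat = grid.lat_centers[:, None] * np.ones((1, grid.n_lon))
    shape = (grid.n_lat, grid.n_lon)
    w = config.spatial_smoothness

    # --- temperature: meridional gradient + hemisphere-phased seasonal cycle
    t_base = 28.0 - 0.45 * np.abs(lat) + 1.5 * _smooth_field(rng, shape, w)
    amp = 4.0 + 0.30 * np.abs(lat)
    peak_month = np.where(lat >= 0, 7.0, 1.0)  # July north, January south
    phase = 2.0 * np.pi * (months_int[:, None, None] - peak_month[None]) / 12.0
    yr_index = (years_int - (config.start_year - 1))[:, None, None]
    n_years_int = config.years + 1
    if config.interannual_anomalies:
        t_anom = rng.normal(0.0, 0.8, size=n_years_int)
        p_anom = 1.0 + np.clip(rng.normal(0.0, 0.25, size=n_years_int), -0.6, 0.6)
    else:
        t_anom = np.zeros(n_years_int)
        p_anom = np.ones(n_years_int)
    ts = (t_base[None] + amp[None] * np.cos(phase)
          + t_anom[yr_index[:, 0, 0]][:, None, None]
          + 0.3 * rng.standard_normal((nt_int,) + shape))

    # --- precipitation: non-negative, seasonal (wet season in local summer)
    p_base = 100.0 * np.exp(0.5 * _smooth_field(rng, shape, w))
    pr = (p_base[None] * (1.0 + 0.9 * np.cos(phase))
          * p_anom[yr_index[:, 0, 0]][:, None, None]
          + 8.0 * rng.standard_normal((nt_int,) + shape))
    pr = np.clip(pr, 0.0, None)

    # --- GPP: hump-shaped in temperature and precipitation, times an
    # unobserved smooth "fertility" field, with multiplicative noise. The
    # fertility term makes GPP carry information no other driver has.
    fert = np.exp(0.4 * _smooth_field(rng, shape, w))
    gpp = (200.0 * fert[None] * np.exp(-((ts - 23.0) ** 2) / 128.0)
           * (pr / (pr + 60.0)))
    gpp = np.clip(gpp * (1.0 + 0.15 * rng.standard_normal(gpp.shape)), 0.0, None)

    # --- fuel load: trailing 12-month GPP sum (biomass accumulates); on
    # usable samples this coincides with the gppl1 feature
    csum = np.cumsum(gpp, axis=0)
    fuel = csum[11:-1].copy()
    fuel[1:] -= csum[:-13]  # fuel[t_out] = sum gpp over the 12 months before t_out

    # --- cloud cover and vapour pressure: noisy monotone proxies
    cld = np.clip(pr / (pr + 80.0) + 0.07 * rng.standard_normal(pr.shape), 0.0, 1.0)
    svp = 6.112 * np.exp(17.67 * ts / (ts + 243.5))  # hPa, saturation
    rh = np.clip(0.45 + 0.4 * pr / (pr + 80.0) + 0.08 * rng.standard_normal(pr.shape),
                 0.05, 1.0)
    vp = svp * rh * (1.0 + 0.05 * rng.standard_normal(ts.shape))

    # --- static human fields: right-skewed population, correlated roads
    log_pop = np.clip(1.5 + 1.2 * _smooth_field(rng, shape, max(1, w - 1)), 0.0, 3.0)
    pop = 10.0 ** log_pop - 1.0
    rdtot = np.clip(0.8 * log_pop + 0.5 * np.abs(rng.standard_normal(shape)), 0.0, None)

    # --- lightning: 12-month climatology tied to convective precip + noise
    clim = np.empty((12,) + shape)
    for m in range(12):
        sel = months_int[:12] == m + 1
        clim[m] = pr[:12][sel].mean(axis=0)
    clim = clim / (clim.mean() + 1e-12)
    ltn = np.clip(clim + 0.3 * rng.standard_normal(clim.shape), 0.0, None)
    ltn_full = ltn[(months - 1)]

    # drop the spin-up year from all dynamic fields
    ts, pr, gpp, cld, vp = (a[12:] for a in (ts, pr, gpp, cld, vp))

    # --- vegetation fractions: 4 active types per cell (Dirichlet) plus a
    # west-to-east cropland gradient so the burnable-area filter has bite
    n_type = len(VEG_TYPES)
    crop_idx = VEG_TYPES.index("croplands")
    nonveg_idx = VEG_TYPES.index("non_vegetated")
    fractions = np.zeros((n_type,) + shape)
    lon_frac = (np.arange(grid.n_lon) + 0.5) / grid.n_lon
    crop = np.clip(0.9 * lon_frac[None, :] ** 3 + 0.05 * rng.standard_normal(shape), 0.0, 0.85)
    nonveg = np.clip(0.05 + 0.03 * rng.standard_normal(shape), 0.0, 0.2)
    natural_types = [i for i in range(n_type) if i not in (crop_idx, nonveg_idx)]
    for i in range(grid.n_lat):
        for j in range(grid.n_lon):
            active = rng.choice(natural_types, size=4, replace=False)
            weights = rng.dirichlet(np.ones(4))
            remaining = 1.0 - crop[i, j] - nonveg[i, j]
            fractions[active, i, j] = weights * remaining
    fractions[crop_idx] = crop
    fractions[nonveg_idx] = nonveg
    veg = VegetationFractions(grid, fractions)

    # --- burned area from the generative response
    kappa_map = np.zeros(shape)
    for code in regions.region_codes():
        kappa_map[regions.mask(code)] = niche.kappa[code]
    natural = 1.0 - crop - nonveg
    ba = niche.response(fuel, ts, pr, pop[None], kappa_map[None], natural[None])
    if config.zero_inflation > 0:
        z = rng.random(ba.shape) >= config.zero_inflation
        ba = ba * z
    if config.noise_sd > 0:
        ba = ba * np.exp(config.noise_sd * rng.standard_normal(ba.shape))
    ba = np.clip(ba, 0.0, 1.0)

    def mf(name, arr, units=""):
        if arr.ndim == 2:
            arr = np.repeat(arr[None], nt, axis=0)
        return MonthlyField(grid, arr, years, months, name, units)

    drivers = {
        "ts": mf("ts", ts, "degC"),
        "pr": mf("pr", pr, "mm/month"),
        "cld": mf("cld", cld, "fraction"),
        "vp": mf("vp", vp, "hPa"),
        "gpp": mf("gpp", gpp, "gC/m2/month"),
        "pop": mf("pop", pop, "persons/km2"),
        "rdtot": mf("rdtot", rdtot, "km/km2"),
        "ltn": mf("ltn", ltn_full, "relative"),
    }
    return World(config, niche, drivers, veg, regions,
                 mf("ba", ba, "fraction"),
                 fuel=mf("fuel", fuel, "gC/m2/12mo"))


def analytic_sensitivity(world: World, delta: float = 1e-4) -> np.ndarray:
    """Ground-truth dBA/dT of the generative response, per (time, lat, lon).

    Central finite difference of the deterministic response with all drivers
    other than temperature held fixed — the same protocol as the model-based
    perturbation analysis. Intended for oracle-mode worlds; stochastic terms
    (zero inflation, noise) are excluded, so on a noisy world this is the
    sensitivity of the noise-free response.
    """
    niche = world.niche
    grid = world.grid
    ts = world.drivers["ts"].values
    pr = world.drivers["pr"].values
    fuel = world.fuel.values
    pop = world.drivers["pop"].values
    kappa_map = np.zeros((grid.n_lat, grid.n_lon))
    for code in world.regions.region_codes():
        kappa_map[world.regions.mask(code)] = niche.kappa[code]
    natural = (1.0 - world.veg.fraction_of("croplands")
               - world.veg.fraction_of("non_vegetated"))
    hi = niche.response(fuel, ts + delta, pr, pop, kappa_map[None], natural[None])
    lo = niche.response(fuel, ts - delta, pr, pop, kappa_map[None], natural[None])
    return (hi - lo) / (2.0 * delta)
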