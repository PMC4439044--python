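"""Synthetic study worlds with known ground truth.

Forward model of the whole observation chain, so that every pipeline stage
can be exercised without field data:

* a juvenile cohort whose daily passage follows flow pulses and whose size
  distribution drifts upward through the Jan 1 – Jun 30 season (fry early,
  smolt late);
* a rotary screw trap with logistic efficiency in log-flow and phenotype,
  beta-binomial (quasibinomial-dispersed) catches, periodic mark-release
  efficiency trials, and <=50 measured fish per day;
* otolith ⁸⁷Sr/⁸⁶Sr spot profiles with natal → downstream → ocean plateaus
  joined by logistic ramps (emulating the ~12-day growth each laser spot
  integrates), plus a linear OR–FL calibration with Gaussian residuals;
* adult returns with hatchery strays, an age split across return years and
  per-phenotype survival applied to the true outmigrant numbers.

All generators are deterministic for a fixed seed, and daily passage
integerization conserves the requested totals exactly. Site mean ratios for
the Stanislaus, San Joaquin and ocean follow measured values; the hatchery
stray sources are synthetic stand-ins with realistic spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .phenotype import FRY_MAX_MM, PARR_MAX_MM, PHENOTYPES
from .natal import IsotopeSpot, OtolithProfile
from .trap import DailyCatchRecord, EfficiencyTrial, _betabinom_rvs

#: minimum credible outmigrant fork length, mm (size floor of the trap catch)
FL_FLOOR_MM = 25.0
FL_CEIL_MM = 115.0
OCEAN_RATIO = 0.70918

#: true OR–FL line used by the generators (mm = slope*um + intercept)
TRUE_OR_FL_SLOPE = 0.171
TRUE_OR_FL_INTERCEPT = -12.76


@dataclass
class IsoscapeTruth:
    """Ground-truth ⁸⁷Sr/⁸⁶Sr signature of one natal source."""

    site_code: str
    mean_ratio: float
    sd_ratio: float
    n_reference: int = 40

    def __post_init__(self):
        if not 0.703 < self.mean_ratio < 0.7095:
            raise ValueError("mean ratio outside the freshwater range")
        if self.sd_ratio <= 0:
            raise ValueError("sd_ratio must be positive")


def default_isoscape() -> list[IsoscapeTruth]:
    """Five-source isoscape: measured focal/downstream means plus synthetic
    hatchery stray sources."""
    return [
        IsoscapeTruth("feather_hatchery", 0.70435, 0.00012, 40),
        IsoscapeTruth("mokelumne_hatchery", 0.70585, 0.00010, 40),
        IsoscapeTruth("stanislaus", 0.70660, 0.00008, 50),
        IsoscapeTruth("san_joaquin", 0.70716, 0.00013, 50),
        IsoscapeTruth("merced_hatchery", 0.70790, 0.00011, 40),
    ]


@dataclass
class CohortTruth:
    """Ground truth for one outmigration cohort (Jan 1 – Jun 30)."""

    year: int
    passage: pd.DataFrame            # date x (fry, parr, smolt), integer fish
    size_mean: pd.Series             # mm per day
    size_sd: pd.Series               # mm per day
    true_survival: dict[str, float]  # outmigrant -> spawner probability
    flow: pd.Series                  # m3/s
    temp: pd.Series                  # deg C (daily max)
    turbidity: pd.Series             # NTU

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.passage.index

    @property
    def totals(self) -> dict[str, int]:
        t = {p: int(self.passage[p].sum()) for p in PHENOTYPES}
        t["total"] = sum(t.values())
        return t


@dataclass
class TrapData:
    records: list[DailyCatchRecord]
    trials: list[EfficiencyTrial]
    true_catch: pd.DataFrame         # date x phenotype, what the trap caught
    efficiency: pd.DataFrame         # date x phenotype, true capture probability


@dataclass
class AdultWorld:
    """Adult returns from a cohort: escapement bookkeeping plus otolith sample."""

    adults: pd.DataFrame             # one row per sampled adult
    spawners_true: dict[str, int]    # E_i per phenotype (natal fish)
    E_n_true: float
    beta_true: dict[str, float]
    escapement_by_year: dict[int, float]
    age_distribution: dict[int, float]
    adclip_stray_rate: float
    stray_fraction: float


# ---------------------------------------------------------------------------


def _integerize(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` over ``weights`` (exact)."""
    w = np.asarray(weights, dtype=float)
    if total == 0 or w.sum() == 0:
        return np.zeros(len(w), dtype=np.int64)
    quota = total * w / w.sum()
    base = np.floor(quota).astype(np.int64)
    short = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def _season_index(year: int) -> pd.DatetimeIndex:
    return pd.date_range(f"{year}-01-01", f"{year}-06-30", freq="D")


def _bin_probs(mean: float, sd: float) -> np.ndarray:
    """Fry/parr/smolt probabilities of a 25-mm-floored Gaussian size mixture."""
    lo = (FL_FLOOR_MM - mean) / sd
    dist = truncnorm(lo, np.inf, loc=mean, scale=sd)
    p_fry = dist.cdf(FRY_MAX_MM)
    p_parr = dist.cdf(PARR_MAX_MM) - p_fry
    return np.array([p_fry, p_parr, max(1.0 - p_fry - p_parr, 0.0)])


def _truncnorm_bin(phen: str, mean: float, sd: float, size, rng) -> np.ndarray:
    """Sample fork lengths within a phenotype bin from the day's size mixture."""
    lo = {"fry": FL_FLOOR_MM, "parr": FRY_MAX_MM, "smolt": PARR_MAX_MM}[phen]
    hi = {"fry": FRY_MAX_MM, "parr": PARR_MAX_MM, "smolt": FL_CEIL_MM}[phen]
    a, b = (lo - mean) / sd, (hi - mean) / sd
    if a >= b:
        return np.full(size, (lo + hi) / 2.0)
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    pulses: list[tuple[str, int]] | None = None,
    baseline_total: int = 200_000,
    year: int = 2000,
    pulse_width: int = 7,
    size_start_mm: float = 30.0,
    size_end_mm: float = 95.0,
    size_sd_mm: float = 5.0,
    true_survival: dict[str, float] | None = None,
    base_flow: float = 8.0,
    peak_flow: float = 120.0,
    seed: int | np.random.Generator | None = None,
) -> CohortTruth:
    """Generate a cohort whose passage pulses ride on flow pulses.

    ``pulses`` is a list of (date, magnitude) pairs; each pulse distributes
    its magnitude over a triangular window of ``pulse_width`` days and adds
    a proportional flow bump, so outmigration pulses coincide with flow
    increases. The daily size mixture is a single Gaussian (floored at
    25 mm) whose mean drifts linearly from ``size_start_mm`` to
    ``size_end_mm``, producing fry-dominated early and smolt-dominated late
    passage. Column sums equal ``baseline_total + Σ magnitudes`` exactly.
    Defaults emulate the wetter-year study conditions (~2.15 M outmigrants,
    survival of order 0.1–2%).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dates = _season_index(year)
    if len(dates) == 0:
        raise ValueError("empty outmigration season")
    D = len(dates)
    if pulses is None:
        pulses = [(f"{year}-02-14", 1_650_000),
                  (f"{year}-04-01", 160_000),
                  (f"{year}-05-09", 140_000)]
    if true_survival is None:
        true_survival = {"fry": 0.0007, "parr": 0.0178, "smolt": 0.0077}

    daily_total = _integerize(np.ones(D), baseline_total)
    flow = np.full(D, base_flow, dtype=float)
    max_mag = max((m for _, m in pulses), default=1) or 1
    for when, mag in pulses:
        center = (pd.Timestamp(when) - dates[0]).days
        if not 0 <= center < D:
            raise ValueError(f"pulse date {when} outside the season")
        offs = np.arange(D) - center
        kern = np.clip(1.0 - np.abs(offs) / (pulse_width + 1.0), 0.0, None)
        daily_total += _integerize(kern, int(mag))
        flow += (peak_flow - base_flow) * (mag / max_mag) * kern

    t = np.arange(D) / max(D - 1, 1)
    size_mean = size_start_mm + (size_end_mm - size_start_mm) * t
    size_sd = np.full(D, size_sd_mm)

    passage = np.zeros((D, 3), dtype=np.int64)
    for i in range(D):
        if daily_total[i] > 0:
            passage[i] = rng.multinomial(daily_total[i],
                                         _bin_probs(size_mean[i], size_sd[i]))

    flow *= np.exp(rng.normal(0.0, 0.03, D))  # mild gauge noise
    temp = 8.0 + 11.0 * t + rng.normal(0.0, 0.6, D)
    turbidity = 2.0 + 0.25 * flow + rng.normal(0.0, 1.0, D).clip(-1.5)

    return CohortTruth(
        year=year,
        passage=pd.DataFrame(passage, index=dates, columns=list(PHENOTYPES)),
        size_mean=pd.Series(size_mean, index=dates),
        size_sd=pd.Series(size_sd, index=dates),
        true_survival=dict(true_survival),
        flow=pd.Series(flow, index=dates),
        temp=pd.Series(temp, index=dates),
        turbidity=pd.Series(turbidity, index=dates),
    )


def simulate_trap(
    cohort: CohortTruth,
    eff_coefs: dict[str, float] | None = None,
    overdispersion: float = 1.8,
    missing_days=(),
    trial_every: int = 7,
    trial_release: int = 300,
    max_measured: int = 50,
    seed: int | np.random.Generator | None = None,
) -> TrapData:
    """Run the screw trap over a cohort: catches, measurements, trials.

    Daily capture probability is logistic in log-flow with additive
    phenotype offsets (``eff_coefs`` keys: intercept, log_flow, parr,
    smolt). Catches are beta-binomial with quasibinomial dispersion
    ``overdispersion`` (phi >= 1; phi = 1 is binomial). Up to
    ``max_measured`` caught fish per day are measured, allocated across
    phenotypes without replacement; mark-release trials of every phenotype
    run every ``trial_every`` days at the day's flow. Records for
    ``missing_days`` are omitted entirely.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if overdispersion < 1.0:
        raise ValueError("overdispersion phi must be >= 1")
    if eff_coefs is None:
        eff_coefs = {"intercept": -2.2, "log_flow": -0.35,
                     "parr": -0.15, "smolt": -0.30}
    missing = {pd.Timestamp(d) for d in missing_days}

    dates = cohort.dates
    logflow = np.log(cohort.flow.to_numpy())
    offsets = {"fry": 0.0, "parr": eff_coefs.get("parr", 0.0),
               "smolt": eff_coefs.get("smolt", 0.0)}
    eff = {p: expit(eff_coefs["intercept"] + eff_coefs.get("log_flow", 0.0)
                    * logflow + offsets[p]) for p in PHENOTYPES}
    eff_df = pd.DataFrame(eff, index=dates)

    catch = {p: _betabinom_rvs(cohort.passage[p].to_numpy(), eff[p],
                               overdispersion, rng) for p in PHENOTYPES}
    catch_df = pd.DataFrame(catch, index=dates)

    records: list[DailyCatchRecord] = []
    for i, d in enumerate(dates):
        if d in missing:
            continue
        cvec = np.array([catch[p][i] for p in PHENOTYPES], dtype=np.int64)
        raw = int(cvec.sum())
        n_meas = min(max_measured, raw)
        fls: list[float] = []
        if n_meas > 0:
            alloc = rng.multivariate_hypergeometric(cvec, n_meas)
            for k, p in enumerate(PHENOTYPES):
                if alloc[k] > 0:
                    fls.extend(_truncnorm_bin(
                        p, cohort.size_mean.iloc[i], cohort.size_sd.iloc[i],
                        alloc[k], rng).tolist())
        records.append(DailyCatchRecord(d, raw, fls, True))

    trials: list[EfficiencyTrial] = []
    for i in range(0, len(dates), trial_every):
        d = dates[i]
        for p in PHENOTYPES:
            rec = int(_betabinom_rvs(np.array([trial_release]),
                                     np.array([eff[p][i]]),
                                     overdispersion, rng)[0])
            trials.append(EfficiencyTrial(d, trial_release, rec, p,
                                          float(cohort.flow.iloc[i])))

    return TrapData(records, trials, catch_df, eff_df)


# ---------------------------------------------------------------------------
# otolith world


def make_isoscape_references(
    isoscape: list[IsoscapeTruth] | None = None,
    seed: int | np.random.Generator | None = None,
    year: int = 2000,
) -> pd.DataFrame:
    """Known-origin reference table (site, ratio, year, sample_type)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    isoscape = isoscape or default_isoscape()
    rows = []
    for s in isoscape:
        vals = rng.normal(s.mean_ratio, s.sd_ratio, s.n_reference)
        for k, v in enumerate(vals):
            rows.append({"site": s.site_code, "ratio": float(v), "year": year,
                         "sample_type": "otolith" if k % 2 == 0 else "water"})
    return pd.DataFrame(rows)


def generate_profiles(
    adults: pd.DataFrame,
    isoscape: list[IsoscapeTruth] | None = None,
    downstream_site: str = "san_joaquin",
    spot_spacing_um: float = 10.0,
    start_radius_um: float = 100.0,
    noise_sd: float = 3e-5,
    spot_se: float = 5e-5,
    ramp_width_um: float = 8.0,
    downstream_span_um: float = 150.0,
    ocean_span_um: float = 250.0,
    seed: int | np.random.Generator | None = None,
) -> list[OtolithProfile]:
    """Three-plateau ⁸⁷Sr/⁸⁶Sr profiles for a table of adults.

    ``adults`` needs columns ``fish_id``, ``natal_site`` and
    ``exit_radius_um`` (NaN = fish never left the natal signature: pure
    natal profile). Spots sit every ``spot_spacing_um`` from
    ``start_radius_um``; the mean curve holds the natal plateau to the exit
    radius, ramps logistically (half-width ``ramp_width_um``, emulating the
    ~12 days of growth a spot integrates) to the downstream plateau, and
    after ``downstream_span_um`` ramps again to the ocean value. Gaussian
    noise ``noise_sd`` is added per spot.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    isoscape = isoscape or default_isoscape()
    means = {s.site_code: s.mean_ratio for s in isoscape}
    down = means[downstream_site]
    profiles = []
    for row in adults.itertuples(index=False):
        natal = means[row.natal_site]
        exit_r = getattr(row, "exit_radius_um", np.nan)
        if np.isnan(exit_r):
            radius = start_radius_um + 12 * spot_spacing_um
            d = np.arange(start_radius_um, radius + 1e-9, spot_spacing_um)
            mu = np.full(len(d), natal)
        else:
            if exit_r <= start_radius_um:
                raise ValueError("exit radius inside the core region")
            radius = exit_r + downstream_span_um + ocean_span_um
            d = np.arange(start_radius_um, radius + 1e-9, spot_spacing_um)
            w = max(ramp_width_um, 1e-6)
            mu = (natal
                  + (down - natal) * expit((d - exit_r - spot_spacing_um / 2) / w)
                  + (OCEAN_RATIO - down) * expit(
                      (d - exit_r - downstream_span_um) / w))
        ratios = mu + rng.normal(0.0, noise_sd, len(d)) if noise_sd > 0 else mu
        spots = [IsotopeSpot(float(di), float(ri), spot_se, k)
                 for k, (di, ri) in enumerate(zip(d, ratios))]
        profiles.append(OtolithProfile(str(row.fish_id), spots, float(d[-1])))
    return profiles


def generate_calibration(
    n: int = 224,
    slope: float = TRUE_OR_FL_SLOPE,
    intercept: float = TRUE_OR_FL_INTERCEPT,
    fl_range: tuple[float, float] = (28.0, 95.0),
    resid_sd_mm: float = 3.5,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """OR–FL calibration pairs from a linear relation plus Gaussian residuals.

    ``resid_sd_mm = 0`` makes a refit recover the line exactly; the 3.5 mm
    default reproduces a strong (r² ≈ 0.9) calibration over the juvenile
    size range.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fl_grid = rng.uniform(*fl_range, n)
    or_um = (fl_grid - intercept) / slope
    fl_obs = slope * or_um + intercept + (
        rng.normal(0.0, resid_sd_mm, n) if resid_sd_mm > 0 else 0.0)
    return pd.DataFrame({
        "fish_id": [f"cal{i:04d}" for i in range(n)],
        "or_um": or_um, "fl_mm": fl_obs, "source_site": "synthetic"})


def generate_escapement(
    cohort: CohortTruth,
    stray_fraction: float = 0.20,
    age_split: dict[int, float] | None = None,
    adclip_stray_rate: float = 0.15,
    n_sample: int | None = 90,
    focal_site: str = "stanislaus",
    isoscape: list[IsoscapeTruth] | None = None,
    or_fl_slope: float = TRUE_OR_FL_SLOPE,
    or_fl_intercept: float = TRUE_OR_FL_INTERCEPT,
    noise_free: bool = False,
    seed: int | np.random.Generator | None = None,
) -> AdultWorld:
    """Apply per-phenotype survival to a cohort and build the adult world.

    Natal spawners per phenotype are binomial draws J_i·S_i (deterministic
    rounding when ``noise_free``). Annual run sizes are assumed stationary,
    so every return year's total escapement equals
    E_n/((1−adclip)(1−stray)) and the age-distribution bookkeeping inverts
    exactly. The otolith sample holds ``n_sample`` adults (``None`` =
    sample every natal spawner) mixing natal fish and hatchery strays in
    the stated fraction; each natal adult carries a true exit fork length
    drawn from its phenotype's outmigrant size distribution (bin midpoint
    when ``noise_free``) converted to an exit radius through the true OR–FL
    line.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not 0 <= stray_fraction < 1:
        raise ValueError("stray_fraction must lie in [0, 1)")
    age_split = age_split or {2: 0.07, 3: 0.87, 4: 0.06, 5: 0.00}
    if abs(sum(age_split.values()) - 1.0) > 1e-9:
        raise ValueError("age_split must sum to 1")
    isoscape = isoscape or default_isoscape()
    J = cohort.totals

    spawners = {}
    for p in PHENOTYPES:
        s = cohort.true_survival[p]
        spawners[p] = (int(round(J[p] * s)) if noise_free
                       else int(rng.binomial(J[p], s)))
    E_n = float(sum(spawners.values()))
    beta_true = {p: spawners[p] / E_n if E_n else 0.0 for p in PHENOTYPES}

    denom = (1.0 - adclip_stray_rate) * (1.0 - stray_fraction)
    escapement_by_year = {cohort.year + a: E_n / denom
                          for a, f in age_split.items() if f > 0}

    if n_sample is None:
        natal_counts = np.array([spawners[p] for p in PHENOTYPES], dtype=np.int64)
        n_natal = int(natal_counts.sum())
        n_stray = int(round(n_natal * stray_fraction / (1.0 - stray_fraction)))
    else:
        n_natal = int(round(n_sample * (1.0 - stray_fraction)))
        n_stray = n_sample - n_natal
        probs = np.array([beta_true[p] for p in PHENOTYPES])
        natal_counts = (_integerize(probs, n_natal) if noise_free
                        else rng.multinomial(n_natal, probs))

    midpoints = {"fry": 42.0, "parr": 65.0, "smolt": 85.0}
    rows = []
    fid = 0
    ages = list(age_split)
    age_p = np.array([age_split[a] for a in ages])
    for k, p in enumerate(PHENOTYPES):
        daily = cohort.passage[p].to_numpy(dtype=float)
        for _ in range(int(natal_counts[k])):
            if noise_free or daily.sum() == 0:
                fl = midpoints[p]
            else:
                day = rng.choice(len(daily), p=daily / daily.sum())
                fl = float(_truncnorm_bin(p, cohort.size_mean.iloc[day],
                                          cohort.size_sd.iloc[day], 1, rng)[0])
            rows.append({"fish_id": f"ad{fid:04d}", "natal_site": focal_site,
                         "true_phenotype": p, "exit_fl_mm": fl,
                         "exit_radius_um": (fl - or_fl_intercept) / or_fl_slope,
                         "age": int(ages[int(np.argmax(age_p))] if noise_free
                                    else rng.choice(ages, p=age_p))})
            fid += 1
    stray_sites = [s.site_code for s in isoscape
                   if s.site_code not in (focal_site, "san_joaquin")]
    for _ in range(n_stray):
        fl = float(rng.uniform(60.0, 90.0))
        rows.append({"fish_id": f"ad{fid:04d}",
                     "natal_site": str(rng.choice(stray_sites)),
                     "true_phenotype": "stray", "exit_fl_mm": fl,
                     "exit_radius_um": (fl - or_fl_intercept) / or_fl_slope,
                     "age": int(rng.choice(ages, p=age_p))})
        fid += 1

    return AdultWorld(
        adults=pd.DataFrame(rows),
        spawners_true=spawners, E_n_true=E_n, beta_true=beta_true,
        escapement_by_year=escapement_by_year,
        age_distribution={a: f for a, f in age_split.items() if f > 0},
        adclip_stray_rate=adclip_stray_rate,
        stray_fraction=stray_fraction)
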