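"""Rotary-screw-trap (RST) catch expansion.

Raw daily trap catches undercount outmigrants because the trap samples only
a fraction of the river. A mark-release efficiency model (binomial GLM with
quasibinomial dispersion, logit link, log-flow and phenotype covariates)
estimates that fraction, and a Monte-Carlo procedure propagates both the
efficiency-model estimation error and the beta-binomial sampling error of
the catch into seasonal passage estimates per migratory phenotype, with
percentile confidence intervals. Phenology (range, IQR, median passage
date) is summarized from the expanded daily series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy.special import expit

from .phenotype import PHENOTYPES, phenotype_counts

#: lower clamp on simulated efficiency before dividing catch by it
EFFICIENCY_FLOOR = 1e-4


@dataclass
class DailyCatchRecord:
    """One trap-day: total count plus the measured-fish subsample (<=50)."""

    date: pd.Timestamp
    raw_count: int
    measured_fl: list[float] = field(default_factory=list)
    operational: bool = True

    def __post_init__(self):
        self.date = pd.Timestamp(self.date)
        if self.operational and self.raw_count < len(self.measured_fl):
            raise ValueError("raw_count smaller than number of measured fish")


@dataclass
class EfficiencyTrial:
    """One mark-release batch."""

    date: pd.Timestamp
    released: int
    recaptured: int
    phenotype: str
    flow: float

    def __post_init__(self):
        if self.released <= 0:
            raise ValueError("released must be positive")
        if not 0 <= self.recaptured <= self.released:
            raise ValueError("recaptured outside [0, released]")


@dataclass
class EfficiencyModel:
    """Fitted logit-link efficiency model with quasibinomial dispersion."""

    coefficients: np.ndarray
    covariance: np.ndarray
    dispersion: float
    design_info: object
    param_names: list[str]

    def design_matrix(self, flow, phenotype) -> np.ndarray:
        flow = np.asarray(flow, dtype=float)
        phen = np.broadcast_to(np.asarray(phenotype, dtype=object), flow.shape)
        new = pd.DataFrame({"flow": flow.ravel(), "phenotype": phen.ravel()})
        (X,) = build_design_matrices([self.design_info], new)
        return np.asarray(X)

    def efficiency(self, flow, phenotype, coefficients=None) -> np.ndarray:
        """Capture probability at given flow(s) for one phenotype (or array)."""
        beta = self.coefficients if coefficients is None else coefficients
        X = self.design_matrix(flow, phenotype)
        return expit(X @ beta)


@dataclass
class PassageEstimate:
    """Seasonal outmigrant abundance J_i for one phenotype with MC draws."""

    phenotype: str
    point: float
    lo95: float
    hi95: float
    draws: np.ndarray

    @property
    def se_log(self) -> float:
        """SE of log J implied by the percentile CI width ((log hi - log lo)/3.92)."""
        if self.lo95 <= 0:
            return float(np.std(np.log(np.clip(self.draws, 1e-9, None))))
        return float((np.log(self.hi95) - np.log(self.lo95)) / (2 * 1.96))


@dataclass
class PhenologySummary:
    """Passage-timing summary: range, interquartile range, median date."""

    phenotype: str
    first_date: pd.Timestamp
    last_date: pd.Timestamp
    iqr_start: pd.Timestamp
    iqr_end: pd.Timestamp
    median_date: pd.Timestamp


# ---------------------------------------------------------------------------
# daily bookkeeping


def apportion_unmeasured(record: DailyCatchRecord) -> dict[str, float]:
    """Split a day's raw count across phenotypes by measured-fish proportions.

    Counts are allocated proportionally, so they sum to ``raw_count`` exactly.
    A day with catch but no measured fish cannot be apportioned on its own;
    see :func:`apportion_series`, which borrows the nearest measured day.
    """
    if not record.operational:
        raise ValueError("cannot apportion a non-operational day")
    if record.raw_count == 0:
        return {p: 0.0 for p in PHENOTYPES}
    counts = phenotype_counts(record.measured_fl)
    n_meas = sum(counts.values())
    if n_meas == 0:
        raise ValueError(
            f"day {record.date.date()} has catch but no measured fish; "
            "use apportion_series to borrow neighbouring proportions"
        )
    return {p: record.raw_count * counts[p] / n_meas for p in PHENOTYPES}


def apportion_series(records: list[DailyCatchRecord]) -> pd.DataFrame:
    """Apportion every operational day; borrow nearest measured day if needed.

    Returns a date-indexed frame with one column per phenotype. Days with
    catch but no measured fish take the measured proportions of the nearest
    (by date) day that has measured fish.
    """
    records = sorted((r for r in records if r.operational), key=lambda r: r.date)
    measured = [r for r in records if len(r.measured_fl) > 0]
    rows = {}
    for rec in records:
        try:
            rows[rec.date] = apportion_unmeasured(rec)
        except ValueError:
            if not measured:
                raise ValueError("no measured fish on any day") from None
            donor = min(measured, key=lambda m: abs(m.date - rec.date))
            counts = phenotype_counts(donor.measured_fl)
            n = sum(counts.values())
            rows[rec.date] = {p: rec.raw_count * counts[p] / n for p in PHENOTYPES}
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return out[list(PHENOTYPES)]


def interpolate_missing(series: pd.Series, window: int = 3) -> pd.Series:
    """Fill missing (NaN) days with a triangular weighted mean of neighbours.

    Observed neighbours within ``±window`` days get weight
    ``1 - |offset|/(window+1)``; observed days pass through unchanged. A day
    with no observed neighbour in the window is set to 0 with a warning.
    """
    s = series.sort_index().astype(float)
    vals = s.to_numpy()
    out = vals.copy()
    idx = s.index
    for i in np.flatnonzero(np.isnan(vals)):
        wsum = vsum = 0.0
        for off in range(-window, window + 1):
            j = i + off
            if off == 0 or j < 0 or j >= len(vals) or np.isnan(vals[j]):
                continue
            # guard against irregular date gaps
            day_off = (idx[j] - idx[i]).days if hasattr(idx, "freq") or isinstance(
                idx, pd.DatetimeIndex) else off
            if abs(day_off) > window:
                continue
            w = 1.0 - abs(day_off) / (window + 1)
            wsum += w
            vsum += w * vals[j]
        if wsum == 0.0:
            warnings.warn(
                f"no observed neighbours within ±{window} days of "
                f"{idx[i]}; filling with 0", stacklevel=2)
            out[i] = 0.0
        else:
            out[i] = vsum / wsum
    return pd.Series(out, index=idx)


# ---------------------------------------------------------------------------
# efficiency model


def fit_efficiency(trials: list[EfficiencyTrial] | pd.DataFrame) -> EfficiencyModel:
    """Fit the trap-efficiency GLM (binomial, logit link, Pearson dispersion).

    Covariates are log(flow) and a phenotype factor; either term is dropped
    automatically when the covariate is constant across trials (e.g. the
    intercept-only case of a single-phenotype, single-flow design). The
    coefficient covariance is scaled by the Pearson chi-square dispersion
    (quasibinomial), which is also stored for beta-binomial catch simulation.
    """
    if isinstance(trials, pd.DataFrame):
        df = trials.copy()
    else:
        df = pd.DataFrame(
            {"date": [t.date for t in trials],
             "released": [t.released for t in trials],
             "recaptured": [t.recaptured for t in trials],
             "phenotype": [t.phenotype for t in trials],
             "flow": [t.flow for t in trials]})
    if (df["released"] <= 0).any():
        raise ValueError("released must be positive in every trial")
    if ((df["recaptured"] < 0) | (df["recaptured"] > df["released"])).any():
        raise ValueError("recaptured outside [0, released]")
    df = df.assign(failures=df["released"] - df["recaptured"])

    terms = []
    if df["flow"].nunique() > 1:
        terms.append("np.log(flow)")
    phen_present = sorted(df["phenotype"].unique(), key=PHENOTYPES.index)
    if len(phen_present) > 1:
        levels = [p for p in PHENOTYPES if p in phen_present]
        terms.append(f"C(phenotype, levels={levels!r})")
    rhs = " + ".join(terms) if terms else "1"

    model = smf.glm(f"recaptured + failures ~ {rhs}", data=df,
                    family=sm.families.Binomial())
    res = model.fit()

    X = np.asarray(model.exog)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("efficiency design matrix is rank deficient")
    if np.any(np.abs(res.params) > 30):
        warnings.warn("possible separation in efficiency trials: "
                      "extreme logit-scale coefficients", stacklevel=2)

    # quasibinomial: phi = Pearson chi-square / residual df, covariance
    # scaled by phi (statsmodels' scale='X2' normalizes by trial weights,
    # so compute the dispersion explicitly)
    phi = (float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else 1.0)
    return EfficiencyModel(
        coefficients=np.asarray(res.params),
        covariance=np.asarray(res.cov_params()) * phi,
        dispersion=phi,
        design_info=model.data.design_info,
        param_names=list(res.params.index),
    )


def constant_efficiency_model(p: float, dispersion: float = 1.0) -> EfficiencyModel:
    """Degenerate intercept-only efficiency model with known capture
    probability and zero coefficient covariance (identity-limit checks and
    noise-free worlds)."""
    from patsy import dmatrix
    di = dmatrix("1", pd.DataFrame({"flow": [1.0], "phenotype": ["fry"]})).design_info
    if 0.0 < p < 1.0:
        logit = float(np.log(p / (1.0 - p)))
    else:
        logit = 40.0 if p >= 1.0 else -40.0
    return EfficiencyModel(np.array([logit]), np.zeros((1, 1)), dispersion,
                           di, ["Intercept"])


# ---------------------------------------------------------------------------
# Monte-Carlo expansion


def _betabinom_rvs(n, p, phi, rng):
    """Compound beta-binomial draw with quasibinomial dispersion ``phi``.

    Parameterized by mean probability p and intra-class correlation
    rho = (phi - 1)/(n - 1) per trial size n, so the variance matches the
    quasibinomial n p (1-p) phi. rho <= 0 (phi <= 1 or n <= 1) degenerates
    to the plain binomial; p at the numeric endpoints is deterministic.
    """
    n = np.asarray(n, dtype=np.int64)
    p = np.asarray(p, dtype=float)
    out = np.zeros(np.broadcast(n, p).shape, dtype=np.int64)
    n, p = np.broadcast_arrays(n, p)

    deterministic = (p >= 1.0) | (p <= 0.0) | (n == 0)
    out[deterministic] = (n * p).astype(np.int64)[deterministic]

    live = ~deterministic
    if not np.any(live):
        return out
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(n > 1, (phi - 1.0) / np.maximum(n - 1.0, 1.0), 0.0)
    rho = np.clip(rho, 0.0, 1.0 - 1e-12)

    over = live & (rho > 0)
    plain = live & (rho <= 0)
    if np.any(plain):
        out[plain] = rng.binomial(n[plain], p[plain])
    if np.any(over):
        a = p[over] * (1.0 - rho[over]) / rho[over]
        b = (1.0 - p[over]) * (1.0 - rho[over]) / rho[over]
        g = rng.beta(a, b)
        out[over] = rng.binomial(n[over], g)
    return out


def simulate_passage(
    catch: pd.DataFrame,
    model: EfficiencyModel,
    flow: pd.Series,
    n_draws: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> dict[str, PassageEstimate]:
    """Expand daily catches into seasonal passage estimates per phenotype.

    Per Monte-Carlo draw: (1) sample a coefficient vector from
    MVN(coefficients, covariance); (2) compute daily efficiency from flow and
    phenotype; (3) provisional passage = catch/efficiency (rounded to an
    integer >= catch); (4) re-simulate the catch from a beta-binomial with
    that passage, efficiency and the model dispersion; (5) final daily
    passage = simulated catch / efficiency. Seasonal totals are the daily
    sums; the point estimate is the median of draws and the CI the 2.5/97.5
    percentiles. A ``"total"`` entry sums phenotypes within each draw.

    ``catch`` is a date-indexed frame with one column per phenotype (zeros
    and interpolated values allowed); ``flow`` must cover every catch date.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    catch = catch.sort_index()
    phens = [p for p in PHENOTYPES if p in catch.columns]
    missing_flow = catch.index.difference(flow.index)
    if len(missing_flow):
        raise ValueError(f"flow missing for catch dates, e.g. {missing_flow[0]}")
    fl = flow.loc[catch.index].to_numpy(dtype=float)

    # design matrix stacked (day x phenotype)
    X = np.vstack([model.design_matrix(fl, p) for p in phens])  # (P*D, k)
    c = np.concatenate([catch[p].to_numpy(dtype=float) for p in phens])
    D = len(catch.index)

    if np.allclose(model.covariance, 0.0):
        coef_draws = np.tile(model.coefficients, (n_draws, 1))
    else:
        coef_draws = rng.multivariate_normal(
            model.coefficients, model.covariance, size=n_draws, method="svd")

    p_mat = expit(coef_draws @ X.T)                      # (n_draws, P*D)
    p_mat = np.clip(p_mat, EFFICIENCY_FLOOR, 1.0)
    n_prov = np.maximum(np.rint(c / p_mat), np.ceil(c)).astype(np.int64)
    sim_catch = _betabinom_rvs(n_prov, p_mat, max(model.dispersion, 1.0), rng)
    passage = sim_catch / p_mat                          # (n_draws, P*D)
    passage[:, c == 0] = 0.0

    out: dict[str, PassageEstimate] = {}
    totals = np.zeros(n_draws)
    for k, p in enumerate(phens):
        seas = passage[:, k * D:(k + 1) * D].sum(axis=1)
        totals += seas
        lo, mid, hi = np.percentile(seas, [2.5, 50.0, 97.5])
        out[p] = PassageEstimate(p, float(mid), float(lo), float(hi), seas)
    lo, mid, hi = np.percentile(totals, [2.5, 50.0, 97.5])
    out["total"] = PassageEstimate("total", float(mid), float(lo), float(hi), totals)
    return out


def phenology(daily_passage: pd.Series, phenotype: str = "") -> PhenologySummary:
    """Range, IQR and median passage date from a daily passage series.

    Quartile dates are where cumulative passage first reaches 25/50/75% of
    the seasonal total; the range spans the first and last nonzero days.
    """
    s = daily_passage.sort_index().astype(float)
    total = s.sum()
    if total <= 0:
        raise ValueError("phenology undefined for zero seasonal passage")
    nz = s[s > 0]
    cum = s.cumsum().to_numpy() / total
    q25, q75 = (s.index[int(np.searchsorted(cum, q))] for q in (0.25, 0.75))
    # weighted median: midpoint of lower and upper median positions, so a
    # symmetric series peaks at its centre even when cum hits 0.5 exactly
    i_lo = int(np.searchsorted(cum, 0.5, side="left"))
    i_hi = int(np.searchsorted(cum, 0.5, side="right"))
    median = s.index[min((i_lo + i_hi) // 2, len(s) - 1)]
    return PhenologySummary(
        phenotype=phenotype,
        first_date=nz.index[0], last_date=nz.index[-1],
        iqr_start=q25, median_date=median, iqr_end=q75,
    )
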