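"""Otolith-radius → fork-length back-calculation and phenotype proportions.

Otolith radius (OR, um) scales linearly with fork length (FL, mm) within an
Evolutionarily Significant Unit, so an OLS calibration FL = a·OR + b fitted
on known juveniles lets the radius at natal exit be converted into the size
at which an adult left the river. Resampling the calibration residuals onto
each fish's predicted FL and reclassifying yields 95% CIs on the fry/parr/
smolt proportions β_i of the escapement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .phenotype import PHENOTYPES, assign_phenotype


@dataclass
class BackCalcModel:
    """Fitted OR–FL calibration line."""

    slope: float          # mm per um
    intercept: float      # mm
    slope_se: float
    intercept_se: float
    residuals: np.ndarray  # mm
    r2: float
    n: int


@dataclass
class PhenotypeProportions:
    """β_i (phenotype shares of the escapement) with resampled 95% CIs."""

    beta: dict[str, float]
    lo95: dict[str, float]
    hi95: dict[str, float]
    se: dict[str, float]
    n_resample: int
    n_fish: int


def fit_or_fl(or_um, fl_mm) -> BackCalcModel:
    """Ordinary least squares fit of FL (mm) on OR (um)."""
    x = np.asarray(or_um, dtype=float)
    y = np.asarray(fl_mm, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 calibration pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: all OR values identical")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return BackCalcModel(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        slope_se=float(res.bse[1]), intercept_se=float(res.bse[0]),
        residuals=np.asarray(res.resid), r2=float(res.rsquared), n=len(x))


def backcalculate_fl(exit_radius_um, model: BackCalcModel):
    """Predict fork length at exit from the otolith radius at exit.

    Flags (warns on) non-positive predictions, which indicate a radius
    outside the calibrated range.
    """
    r = np.asarray(exit_radius_um, dtype=float)
    if np.any(r <= 0):
        raise ValueError("exit radius must be positive")
    fl = model.slope * r + model.intercept
    if np.any(fl <= 0):
        warnings.warn("back-calculated FL <= 0: radius outside calibration range",
                      stacklevel=2)
    if np.ndim(exit_radius_um) == 0:
        return float(fl)
    return fl


def proportions_with_ci(
    exit_radii_um,
    model: BackCalcModel,
    n_resample: int = 5000,
    seed: int | np.random.Generator | None = None,
    resample_fish: bool = False,
) -> PhenotypeProportions:
    """Phenotype proportions of the adult sample with calibration-error CIs.

    β_i is the share of fish whose predicted exit FL falls in bin i (zero
    perturbation). Each replicate adds a calibration residual, sampled with
    replacement, to every fish's predicted FL and reclassifies; the CI is
    the 2.5/97.5 percentile of the replicate proportions. With
    ``resample_fish=True`` each replicate also bootstraps fish, adding the
    finite-sample sampling error of the adult sample itself.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = np.asarray(exit_radii_um, dtype=float)
    if r.size == 0:
        raise ValueError("no fish to classify")
    fl0 = model.slope * r + model.intercept
    n = len(fl0)

    def shares(fl):
        lab = assign_phenotype(np.clip(fl, 1e-6, None))
        return np.array([np.mean(lab == p) for p in PHENOTYPES])

    beta = shares(fl0)
    resid = np.asarray(model.residuals, dtype=float)
    reps = np.empty((n_resample, len(PHENOTYPES)))
    for b in range(n_resample):
        fl = fl0[rng.integers(0, n, n)] if resample_fish else fl0
        reps[b] = shares(fl + resid[rng.integers(0, len(resid), n)])
    lo = np.percentile(reps, 2.5, axis=0)
    hi = np.percentile(reps, 97.5, axis=0)
    se = reps.std(axis=0, ddof=1)
    return PhenotypeProportions(
        beta=dict(zip(PHENOTYPES, map(float, beta))),
        lo95=dict(zip(PHENOTYPES, map(float, lo))),
        hi95=dict(zip(PHENOTYPES, map(float, hi))),
        se=dict(zip(PHENOTYPES, map(float, se))),
        n_resample=n_resample, n_fish=n)
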