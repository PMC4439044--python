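"""Outmigrant-to-spawner survival with delta-method confidence intervals.

Natural escapement E_n is the adult return with hatchery (adclipped) and
unmarked strays removed and cohorts separated by age; spawners of phenotype
i are E_i = E_n·β_i, and survival is the ratio S_i = E_i / J_i against the
trap-expanded outmigrant abundance J_i. Assuming β_i and J_i independent,
the first-order (delta-method) variance of log S_i is

    SE(log S_i)² ≅ (SE(J_i)/J_i)² + (SE(β_i)/β_i)²

and the 95% CI is exp(log S_i ± 1.96·SE(log S_i)). Escapement uncertainty
is deliberately excluded (trap expansion dominates the error budget).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal


@dataclass
class EscapementInput:
    """Escapement configuration for one focal river."""

    total_escapement_by_year: dict[int, float]
    age_distribution: dict[int, float]        # age -> fraction, sums to 1
    adclip_stray_rate: float | dict[int, float]
    unmarked_stray_fraction: float

    def __post_init__(self):
        fr = list(self.age_distribution.values())
        if any(not 0 <= f <= 1 for f in fr) or abs(sum(fr) - 1.0) > 1e-6:
            raise ValueError("age fractions must lie in [0,1] and sum to 1")
        rates = (self.adclip_stray_rate.values()
                 if isinstance(self.adclip_stray_rate, dict)
                 else [self.adclip_stray_rate])
        if any(not 0 <= r <= 1 for r in rates) or not (
                0 <= self.unmarked_stray_fraction <= 1):
            raise ValueError("stray fractions must lie in [0,1]")


@dataclass
class SurvivalEstimate:
    phenotype: str
    E_n: float
    E_i: float
    J_i: float
    S_i: float
    se_logS: float
    lo95: float
    hi95: float

    @property
    def percent(self) -> float:
        """Survival in percent, rounded half-up to 2 decimals."""
        return round_half_up(100.0 * self.S_i, 2)


def round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits,
                                           rounding=ROUND_HALF_UP))


def natural_escapement(config: EscapementInput, cohort_year: int) -> float:
    """Natural escapement E_n attributable to one outmigration cohort.

    Sums, over return ages a, the total escapement of year cohort+a scaled
    by (1 − adclip stray rate) and the age-a fraction of that return, then
    removes unmarked strays:

        E_n = Σ_a esc(cohort+a)·(1 − adclip)·age_frac(a) · (1 − unmarked stray)
    """
    total = 0.0
    for age, frac in config.age_distribution.items():
        if frac == 0:
            continue
        year = cohort_year + age
        if year not in config.total_escapement_by_year:
            raise KeyError(f"no escapement estimate for return year {year}")
        adclip = (config.adclip_stray_rate.get(year, 0.0)
                  if isinstance(config.adclip_stray_rate, dict)
                  else config.adclip_stray_rate)
        total += config.total_escapement_by_year[year] * (1.0 - adclip) * frac
    return total * (1.0 - config.unmarked_stray_fraction)


def spawners_by_phenotype(E_n: float, beta: dict[str, float]) -> dict[str, float]:
    """E_i = E_n·β_i; shares must sum to 1 so that Σ E_i = E_n."""
    if abs(sum(beta.values()) - 1.0) > 1e-9:
        raise ValueError("phenotype proportions must sum to 1")
    return {p: E_n * b for p, b in beta.items()}


def survival(E_i: float, J_i: float, se_J: float = 0.0, se_beta: float = 0.0,
             beta: float | None = None, phenotype: str = "",
             E_n: float | None = None) -> SurvivalEstimate:
    """Survival S_i = E_i/J_i with a log-scale delta-method 95% CI.

    ``se_J`` and ``se_beta`` are absolute standard errors of J_i and β_i;
    ``beta`` is required whenever ``se_beta`` > 0.
    """
    if J_i <= 0:
        raise ValueError("J_i must be positive")
    if se_beta > 0 and (beta is None or beta <= 0):
        raise ValueError("beta must be positive when se_beta > 0")
    S = E_i / J_i
    var_log = (se_J / J_i) ** 2
    if se_beta > 0:
        var_log += (se_beta / beta) ** 2
    se_log = math.sqrt(var_log)
    if S > 0:
        lo = math.exp(math.log(S) - 1.96 * se_log)
        hi = math.exp(math.log(S) + 1.96 * se_log)
    else:
        lo = hi = 0.0
    return SurvivalEstimate(
        phenotype=phenotype, E_n=float(E_n if E_n is not None else E_i),
        E_i=float(E_i), J_i=float(J_i), S_i=float(S),
        se_logS=float(se_log), lo95=float(lo), hi95=float(hi))


def se_from_ci(lo: float, hi: float, point: float, log_scale: bool = True) -> float:
    """Map a 95% percentile CI to an absolute SE.

    On the log scale (default) SE(X) ≈ X·(log hi − log lo)/(2·1.96), matching
    the multiplicative spread of Monte-Carlo draws; set ``log_scale=False``
    for the plain (hi − lo)/(2·1.96).
    """
    if log_scale:
        if lo <= 0 or hi <= 0:
            raise ValueError("log-scale SE needs positive CI endpoints")
        return point * (math.log(hi) - math.log(lo)) / (2 * 1.96)
    return (hi - lo) / (2 * 1.96)
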