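"""Simulation experiments on synthetic worlds.

Thin drivers that generate complete worlds with the :mod:`otoscape.synthetic`
forward model, run the inference chain on them, and score the estimates
against the stored ground truth: per-world survival recovery (coverage and
bias) and passage-CI coverage over replicate seasons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthetic as syn
from . import trap
from .phenotype import PHENOTYPES
from .pipeline import analyze
from .survival import EscapementInput


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_world(
    seed: int,
    n_draws: int = 800,
    n_resample: int = 1500,
    n_sample: int | None = 90,
    noise_free: bool = False,
    cohort_kwargs: dict | None = None,
    trap_kwargs: dict | None = None,
    escapement_kwargs: dict | None = None,
) -> dict:
    """Generate one synthetic world, run the full pipeline, score it.

    Returns a dict with the true and estimated per-phenotype survivals, CI
    coverage flags, and the intermediate truth quantities. In
    ``noise_free`` mode every stochastic layer is switched off (perfect
    trap efficiency with a known degenerate efficiency model, every fish
    measured, exact isotope plateaus, zero calibration residuals, no
    strays) so the pipeline must reproduce the truth to rounding.
    """
    rng_cohort, rng_trap, rng_refs, rng_esc, rng_prof, rng_cal = _rngs(seed, 6)
    cohort_kwargs = dict(cohort_kwargs or {})
    trap_kwargs = dict(trap_kwargs or {})
    escapement_kwargs = dict(escapement_kwargs or {})
    efficiency_model = None

    if noise_free:
        trap_kwargs.setdefault("eff_coefs", {"intercept": 40.0, "log_flow": 0.0,
                                             "parr": 0.0, "smolt": 0.0})
        trap_kwargs.setdefault("overdispersion", 1.0)
        trap_kwargs.setdefault("max_measured", 10 ** 9)
        escapement_kwargs.setdefault("stray_fraction", 0.0)
        escapement_kwargs.setdefault("noise_free", True)
        n_sample = None
        efficiency_model = trap.constant_efficiency_model(1.0, dispersion=1.0)

    cohort = syn.generate_cohort(seed=rng_cohort, **cohort_kwargs)
    trapdata = syn.simulate_trap(cohort, seed=rng_trap, **trap_kwargs)
    references = syn.make_isoscape_references(seed=rng_refs)
    world = syn.generate_escapement(cohort, n_sample=n_sample, seed=rng_esc,
                                    **escapement_kwargs)
    profiles = syn.generate_profiles(
        world.adults, seed=rng_prof,
        noise_sd=0.0 if noise_free else 3e-5)
    calibration = syn.generate_calibration(
        seed=rng_cal, resid_sd_mm=0.0 if noise_free else 3.5)
    environment = pd.DataFrame({"flow_m3s": cohort.flow,
                                "temp_max_c": cohort.temp,
                                "turbidity_ntu": cohort.turbidity})
    escapement = EscapementInput(
        total_escapement_by_year=world.escapement_by_year,
        age_distribution=world.age_distribution,
        adclip_stray_rate=world.adclip_stray_rate,
        unmarked_stray_fraction=world.stray_fraction)

    res = analyze(trapdata.records, trapdata.trials, environment, profiles,
                  references, calibration, escapement, cohort.year,
                  n_draws=n_draws, n_resample=n_resample, seed=seed,
                  efficiency_model=efficiency_model)

    out = {"seed": seed, "E_n_true": world.E_n_true, "E_n_hat": res.E_n,
           "stray_true": world.stray_fraction,
           "stray_hat": res.stray_fraction, "result": res}
    J = cohort.totals
    for p in PHENOTYPES:
        S_true = world.spawners_true[p] / J[p] if J[p] else np.nan
        out[f"S_true_{p}"] = S_true
        est = res.survival.get(p)
        out[f"S_hat_{p}"] = est.S_i if est else np.nan
        out[f"J_true_{p}"] = J[p]
        out[f"J_hat_{p}"] = res.passage[p].point
        out[f"beta_true_{p}"] = world.beta_true[p]
        out[f"beta_hat_{p}"] = res.proportions.beta[p]
        out[f"covered_{p}"] = (bool(est and est.lo95 <= S_true <= est.hi95)
                               if np.isfinite(S_true) else np.nan)
    return out


def recovery_experiment(n_worlds: int = 100, seed: int = 0, **world_kwargs):
    """Survival recovery over replicate worlds.

    Returns ``(table, summary)``: one row per world, and a summary with
    pooled and per-phenotype 95%-CI coverage of the true survival plus the
    relative bias of the mean estimate.
    """
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(seed).spawn(n_worlds)]
    rows = [run_world(s, **world_kwargs) for s in seeds]
    table = pd.DataFrame([{k: v for k, v in r.items() if k != "result"}
                          for r in rows])
    summary = {"n_worlds": n_worlds}
    cov_all = []
    for p in PHENOTYPES:
        cov = table[f"covered_{p}"].astype(float)
        cov_all.append(cov)
        summary[f"coverage_{p}"] = float(cov.mean())
        truth = table[f"S_true_{p}"].mean()
        summary[f"rel_bias_{p}"] = float(
            (table[f"S_hat_{p}"].mean() - truth) / truth)
    summary["coverage_pooled"] = float(pd.concat(cov_all).mean())
    summary["max_abs_rel_bias"] = float(max(abs(summary[f"rel_bias_{p}"])
                                            for p in PHENOTYPES))
    return table, summary


def passage_coverage(
    n_seasons: int = 200,
    seed: int = 0,
    n_draws: int = 400,
    cohort_kwargs: dict | None = None,
    trap_kwargs: dict | None = None,
) -> dict:
    """95%-CI coverage of the true seasonal passage over replicate seasons.

    Each season: generate a cohort, run the trap, fit the efficiency GLM
    from that season's mark-release trials, Monte-Carlo-expand the catches,
    and check whether the total-passage CI covers the true total. Default
    cohorts are scaled-down seasons (~50k outmigrants) so many replicates
    stay cheap.
    """
    cohort_kwargs = cohort_kwargs or {
        "pulses": [("2000-02-15", 30_000), ("2000-04-10", 15_000)],
        "baseline_total": 5_000}
    trap_kwargs = trap_kwargs or {}
    covered, rel_err = [], []
    rngs = _rngs(seed, 3 * n_seasons)
    for k in range(n_seasons):
        rng_c, rng_t, rng_p = rngs[3 * k:3 * k + 3]
        cohort = syn.generate_cohort(seed=rng_c, **cohort_kwargs)
        td = syn.simulate_trap(cohort, seed=rng_t, **trap_kwargs)
        catch = pd.DataFrame({p: [r for r in td.true_catch[p]] for p in PHENOTYPES},
                             index=cohort.dates)
        model = trap.fit_efficiency(td.trials)
        passage = trap.simulate_passage(catch, model, cohort.flow,
                                        n_draws=n_draws, seed=rng_p)
        truth = cohort.totals["total"]
        est = passage["total"]
        covered.append(est.lo95 <= truth <= est.hi95)
        rel_err.append(est.point / truth - 1.0)
    return {"n_seasons": n_seasons,
            "coverage": float(np.mean(covered)),
            "mean_rel_err": float(np.mean(rel_err))}
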