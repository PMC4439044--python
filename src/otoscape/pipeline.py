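"""End-to-end orchestration: expand → assign → back-calculate → survive.

:func:`analyze` runs the full inference chain on in-memory inputs and is
what the CLI, the file-based :func:`run_all` and the simulation experiments
all share. Every stage draws its randomness from an explicit seed, so a
fixed configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import backcalc as bc
from . import io as oio
from . import natal as nat
from .survival import (EscapementInput, SurvivalEstimate,
                       natural_escapement, round_half_up,
                       spawners_by_phenotype)
from .survival import survival as estimate_survival
from . import trap
from .phenotype import PHENOTYPES

log = logging.getLogger("otoscape")


@dataclass
class RunConfig:
    """Single configuration for a full run (defaults mirror the study design:
    2000 Monte-Carlo draws, 5000 residual resamples, Jan 1 – Jun 30 season,
    55/75 mm bins)."""

    catch_csv: str
    lengths_csv: str
    trials_csv: str
    environment_csv: str
    spots_csv: str
    isoscape_csv: str
    calibration_csv: str
    escapement_yaml: str
    out_dir: str
    cohort_year: int
    focal_site: str = "stanislaus"
    n_draws: int = 2000
    n_resample: int = 5000
    seed: int = 1
    interp_window: int = 3
    natal_window: int = 3
    core_radius_um: float = 120.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ResultBundle:
    passage: dict[str, trap.PassageEstimate]
    phenology: dict[str, trap.PhenologySummary]
    catch_by_phenotype: pd.DataFrame
    assignments: pd.DataFrame
    exits: pd.DataFrame
    stray_fraction: float
    proportions: bc.PhenotypeProportions
    backcalc_model: bc.BackCalcModel
    survival: dict[str, SurvivalEstimate] = field(default_factory=dict)
    E_n: float = float("nan")


def expand_catches(records, trials, flow, season, n_draws=2000, seed=None,
                   interp_window=3, efficiency_model=None):
    """Apportion, interpolate and Monte-Carlo-expand the trap catches.

    ``efficiency_model`` overrides the GLM fit with a prespecified
    :class:`~otoscape.trap.EfficiencyModel` (e.g. a known constant-efficiency
    model in simulation studies)."""
    catch = trap.apportion_series(records)
    catch = catch.reindex(season)  # trap-out days become NaN
    catch = catch.apply(lambda s: trap.interpolate_missing(s, interp_window))
    model = efficiency_model if efficiency_model is not None \
        else trap.fit_efficiency(trials)
    passage = trap.simulate_passage(catch, model, flow, n_draws=n_draws, seed=seed)

    phenology = {}
    for p in PHENOTYPES:
        p_hat = model.efficiency(flow.loc[season].to_numpy(), p)
        daily = catch[p] / np.clip(p_hat, trap.EFFICIENCY_FLOOR, 1.0)
        if daily.sum() > 0:
            phenology[p] = trap.phenology(daily, p)
    return catch, model, passage, phenology


def assign_adults(profiles, references, focal_site, natal_window=3,
                  core_radius_um=120.0):
    """Train the isoscape, assign every profile, and locate natal exits."""
    clf = nat.train_isoscape(references)
    assigns, exits = [], []
    for pr in profiles:
        a = nat.assign_natal(pr, clf, focal_site, natal_window, core_radius_um)
        assigns.append({"fish_id": a.fish_id, "predicted_site": a.predicted_site,
                        "natal_value": a.natal_value, "is_stray": a.is_stray,
                        "p_focal": a.posterior.get(focal_site, 0.0)})
        if not a.is_stray:
            e = nat.detect_exit(pr, clf, focal_site)
            exits.append({"fish_id": e.fish_id, "exit_index": e.exit_index,
                          "exit_radius_um": e.exit_radius, "defined": e.defined,
                          "method": e.method})
    assignments = pd.DataFrame(assigns)
    exits = pd.DataFrame(exits)
    stray_fraction = float(assignments["is_stray"].mean()) if len(assignments) else 0.0
    return clf, assignments, exits, stray_fraction


def analyze(records, trials, environment, profiles, references, calibration,
            escapement, cohort_year, focal_site="stanislaus", n_draws=2000,
            n_resample=5000, seed=1, interp_window=3, natal_window=3,
            core_radius_um=120.0, efficiency_model=None) -> ResultBundle:
    """Full inference chain on in-memory inputs.

    ``escapement`` is an :class:`~otoscape.survival.EscapementInput`; its
    ``unmarked_stray_fraction`` is replaced by the otolith-derived stray
    fraction computed here. SE(J_i) comes from the log-scale width of the
    passage CI; SE(β_i) combines the calibration-resampling SD with the
    adult-sample multinomial component √(β(1−β)/n) in quadrature.
    """
    ss = np.random.SeedSequence(seed)
    seed_passage, seed_props = (int(s.generate_state(1)[0] % (2 ** 31))
                                for s in ss.spawn(2))
    season = pd.date_range(f"{cohort_year}-01-01", f"{cohort_year}-06-30", freq="D")
    flow = environment["flow_m3s"]

    catch, eff_model, passage, phenology = expand_catches(
        records, trials, flow, season, n_draws, seed_passage, interp_window,
        efficiency_model)
    log.info("expanded %d trap days, dispersion=%.2f",
             len(catch), eff_model.dispersion)

    clf, assignments, exits, stray_fraction = assign_adults(
        profiles, references, focal_site, natal_window, core_radius_um)
    log.info("assigned %d adults, stray fraction %.2f",
             len(assignments), stray_fraction)

    model = bc.fit_or_fl(calibration["or_um"], calibration["fl_mm"])
    usable = exits[exits["defined"]]
    props = bc.proportions_with_ci(usable["exit_radius_um"].to_numpy(), model,
                                   n_resample=n_resample, seed=seed_props)

    esc = EscapementInput(
        total_escapement_by_year=escapement.total_escapement_by_year,
        age_distribution=escapement.age_distribution,
        adclip_stray_rate=escapement.adclip_stray_rate,
        unmarked_stray_fraction=stray_fraction)
    E_n = natural_escapement(esc, cohort_year)
    E_i = spawners_by_phenotype(E_n, props.beta)

    survival = {}
    for p in PHENOTYPES:
        beta = props.beta[p]
        J = passage[p].point
        if J <= 0 or beta <= 0:
            continue
        se_J = passage[p].se_log * J
        se_beta = float(np.hypot(props.se[p],
                                 np.sqrt(beta * (1 - beta) / props.n_fish)))
        survival[p] = estimate_survival(E_i[p], J, se_J, se_beta, beta,
                                    phenotype=p, E_n=E_n)

    return ResultBundle(passage=passage, phenology=phenology,
                        catch_by_phenotype=catch, assignments=assignments,
                        exits=exits, stray_fraction=stray_fraction,
                        proportions=props, backcalc_model=model,
                        survival=survival, E_n=E_n)


def run_all(config: RunConfig) -> ResultBundle:
    """File-based run: read every input table, analyze, write every output."""
    records = oio.read_catch(config.catch_csv, config.lengths_csv)
    trials = oio.read_trials(config.trials_csv)
    environment = oio.read_environment(config.environment_csv)
    profiles = oio.read_spots(config.spots_csv)
    references = oio.read_isoscape(config.isoscape_csv)
    calibration = oio.read_calibration(config.calibration_csv)
    escapement = oio.read_escapement(config.escapement_yaml)

    res = analyze(records, trials, environment, profiles, references,
                  calibration, escapement, config.cohort_year,
                  config.focal_site, config.n_draws, config.n_resample,
                  config.seed, config.interp_window, config.natal_window,
                  config.core_radius_um)
    write_results(res, config.out_dir)
    return res


def write_results(res: ResultBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [{"phenotype": p, "J": est.point, "lo95": est.lo95, "hi95": est.hi95}
         for p, est in res.passage.items()]
    ).to_csv(out / "passage.csv", index=False)

    pd.DataFrame(
        [{"phenotype": p, "first": ph.first_date.date(),
          "last": ph.last_date.date(), "iqr_start": ph.iqr_start.date(),
          "iqr_end": ph.iqr_end.date(), "median": ph.median_date.date()}
         for p, ph in res.phenology.items()]
    ).to_csv(out / "phenology.csv", index=False)

    res.catch_by_phenotype.rename_axis("date").to_csv(out / "daily_catch.csv")
    res.assignments.to_csv(out / "assignments.csv", index=False)
    res.exits.to_csv(out / "exits.csv", index=False)

    pd.DataFrame(
        [{"phenotype": p, "beta": res.proportions.beta[p],
          "lo95": res.proportions.lo95[p], "hi95": res.proportions.hi95[p]}
         for p in PHENOTYPES]
    ).to_csv(out / "proportions.csv", index=False)

    pd.DataFrame(
        [{"phenotype": p, "contribution_pct": 100 * res.proportions.beta[p],
          "spawners": s.E_i, "J": s.J_i, "survival_pct": s.percent,
          "lo95_pct": round_half_up(100 * s.lo95, 2),
          "hi95_pct": round_half_up(100 * s.hi95, 2)}
         for p, s in res.survival.items()]
    ).to_csv(out / "survival.csv", index=False)
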