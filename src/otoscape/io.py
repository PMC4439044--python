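"""CSV/YAML schemas shared by the generators and the pipeline.

All tables are plain CSV with documented headers; the escapement
configuration is YAML. Readers validate required columns and raise with
the offending column named.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .natal import IsotopeSpot, OtolithProfile
from .survival import EscapementInput
from .trap import DailyCatchRecord, EfficiencyTrial

CATCH_COLUMNS = ["date", "raw_count", "operational"]
LENGTH_COLUMNS = ["date", "fl_mm"]
TRIAL_COLUMNS = ["date", "released", "recaptured", "phenotype", "flow"]
ENV_COLUMNS = ["date", "flow_m3s", "temp_max_c", "turbidity_ntu"]
SPOT_COLUMNS = ["fish_id", "index", "distance_um", "ratio", "se", "otolith_radius_um"]
ISOSCAPE_COLUMNS = ["site", "ratio", "year", "sample_type"]
CALIBRATION_COLUMNS = ["fish_id", "or_um", "fl_mm", "source_site"]


def _read(path, columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path)
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def write_catch(records: list[DailyCatchRecord], catch_csv, lengths_csv) -> None:
    pd.DataFrame(
        {"date": [r.date.date() for r in records],
         "raw_count": [r.raw_count for r in records],
         "operational": [r.operational for r in records]}
    ).to_csv(catch_csv, index=False)
    rows = [(r.date.date(), fl) for r in records for fl in r.measured_fl]
    pd.DataFrame(rows, columns=LENGTH_COLUMNS).to_csv(lengths_csv, index=False)


def read_catch(catch_csv, lengths_csv) -> list[DailyCatchRecord]:
    catch = _read(catch_csv, CATCH_COLUMNS)
    lengths = _read(lengths_csv, LENGTH_COLUMNS)
    lengths["date"] = pd.to_datetime(lengths["date"])
    by_day = lengths.groupby("date")["fl_mm"].apply(list)
    out = []
    for row in catch.itertuples(index=False):
        d = pd.Timestamp(row.date)
        out.append(DailyCatchRecord(d, int(row.raw_count),
                                    list(by_day.get(d, [])), bool(row.operational)))
    return out


def write_trials(trials: list[EfficiencyTrial], path) -> None:
    pd.DataFrame(
        {"date": [t.date.date() for t in trials],
         "released": [t.released for t in trials],
         "recaptured": [t.recaptured for t in trials],
         "phenotype": [t.phenotype for t in trials],
         "flow": [t.flow for t in trials]}).to_csv(path, index=False)


def read_trials(path) -> list[EfficiencyTrial]:
    df = _read(path, TRIAL_COLUMNS)
    return [EfficiencyTrial(pd.Timestamp(r.date), int(r.released),
                            int(r.recaptured), str(r.phenotype), float(r.flow))
            for r in df.itertuples(index=False)]


def write_environment(flow: pd.Series, temp: pd.Series, turbidity: pd.Series,
                      path) -> None:
    pd.DataFrame({"date": [d.date() for d in flow.index],
                  "flow_m3s": flow.to_numpy(),
                  "temp_max_c": temp.reindex(flow.index).to_numpy(),
                  "turbidity_ntu": turbidity.reindex(flow.index).to_numpy()}
                 ).to_csv(path, index=False)


def read_environment(path) -> pd.DataFrame:
    df = _read(path, ENV_COLUMNS)
    df["date"] = pd.to_datetime(df["date"])
    return df.set_index("date").sort_index()


def write_spots(profiles: list[OtolithProfile], path) -> None:
    rows = []
    for pr in profiles:
        for s in pr.spots:
            rows.append((pr.fish_id, s.index, s.distance_from_core, s.ratio,
                         s.se, pr.otolith_radius))
    pd.DataFrame(rows, columns=SPOT_COLUMNS).to_csv(path, index=False)


def read_spots(path) -> list[OtolithProfile]:
    df = _read(path, SPOT_COLUMNS)
    out = []
    for fid, grp in df.groupby("fish_id", sort=False):
        grp = grp.sort_values("index")
        spots = [IsotopeSpot(float(r.distance_um), float(r.ratio), float(r.se),
                             int(r.index)) for r in grp.itertuples(index=False)]
        out.append(OtolithProfile(str(fid), spots,
                                  float(grp["otolith_radius_um"].iloc[0])))
    return out


def write_isoscape(references: pd.DataFrame, path) -> None:
    references[ISOSCAPE_COLUMNS].to_csv(path, index=False)


def read_isoscape(path) -> pd.DataFrame:
    return _read(path, ISOSCAPE_COLUMNS)


def write_calibration(calibration: pd.DataFrame, path) -> None:
    calibration[CALIBRATION_COLUMNS].to_csv(path, index=False)


def read_calibration(path) -> pd.DataFrame:
    return _read(path, CALIBRATION_COLUMNS)


def write_escapement(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def read_escapement(path) -> EscapementInput:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("total_escapement_by_year", "age_distribution",
                "adclip_stray_rate", "unmarked_stray_fraction"):
        if key not in cfg:
            raise ValueError(f"{path}: missing escapement key {key!r}")
    return EscapementInput(
        total_escapement_by_year={int(k): float(v) for k, v in
                                  cfg["total_escapement_by_year"].items()},
        age_distribution={int(k): float(v) for k, v in
                          cfg["age_distribution"].items()},
        adclip_stray_rate=(
            {int(k): float(v) for k, v in cfg["adclip_stray_rate"].items()}
            if isinstance(cfg["adclip_stray_rate"], dict)
            else float(cfg["adclip_stray_rate"])),
        unmarked_stray_fraction=float(cfg["unmarked_stray_fraction"]),
    )
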