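"""One-config orchestration: simulate -> aggregate -> fit -> effects.

``run_pipeline`` drives the full analysis from a single :class:`RunConfig`
(loaded from YAML), writing patient/event CSVs (when simulating), the
aggregated series, the coefficient table, the per-subgroup effect table, a
disclosure-controlled descriptive table and a JSON manifest with the config
hash and library versions, so a run is reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cohort, io
from .calendar import StudyCalendar
from .effects import fit_subgroup_models
from .model import coefficient_table, fit_itsa
from .simulate import SimulationTruth, generate_population, generate_prescriptions

__all__ = ["RunConfig", "run_pipeline", "descriptive_table", "PipelineError"]

log = logging.getLogger("rxits")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    Exactly one of ``truth`` (simulate the cohort) or ``events_path`` +
    ``patients_path`` (load a user-supplied cohort in the documented CSV
    schema) must be set.
    """

    calendar: StudyCalendar
    out_dir: Path
    seed: int = 0
    truth: SimulationTruth | None = None
    events_path: Path | None = None
    patients_path: Path | None = None
    subgroups: list[str] = field(default_factory=lambda: ["all"])
    outcomes: list[str] = field(default_factory=lambda: ["prevalent", "new"])
    disclosure: bool = True
    naive_denominator: bool = True
    lag: int = 2
    fourier_pairs: int = 1
    window: tuple[int, int] | None = None  # default: interruption_1 .. end
    descriptive_month: str | None = None  # ISO month for the Table-1 summary

    def __post_init__(self) -> None:
        simulated = self.truth is not None
        supplied = self.events_path is not None or self.patients_path is not None
        if simulated == supplied:
            raise PipelineError(
                "config must set exactly one of truth settings or input paths"
            )
        if supplied and (self.events_path is None or self.patients_path is None):
            raise PipelineError("both events_path and patients_path are required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        base = base or Path(".")
        cal = (
            StudyCalendar.from_dict(raw["calendar"])
            if "calendar" in raw
            else StudyCalendar.covid_study()
        )
        seed = int(raw.get("seed", 0))
        truth = None
        if "truth" in raw:
            t = dict(raw["truth"])
            preset = t.pop("preset", None)
            if preset is not None:
                base_truth = getattr(SimulationTruth, preset)(
                    scale=t.pop("scale", 1.0), seed=seed
                ).to_dict()
                base_truth.update(t)
                t = base_truth
            t.setdefault("seed", seed)
            truth = SimulationTruth.from_dict(t)
        window = raw.get("window")
        if window is not None:
            window = (cal.t_index(str(window[0])), cal.t_index(str(window[1])))
        return cls(
            calendar=cal,
            out_dir=Path(raw.get("out_dir", "rxits-run")),
            seed=seed,
            truth=truth,
            events_path=(base / raw["events"]) if "events" in raw else None,
            patients_path=(base / raw["patients"]) if "patients" in raw else None,
            subgroups=list(raw.get("subgroups", ["all"])),
            outcomes=list(raw.get("outcomes", ["prevalent", "new"])),
            disclosure=bool(raw.get("disclosure", True)),
            naive_denominator=bool(raw.get("naive_denominator", True)),
            lag=int(raw.get("lag", 2)),
            fourier_pairs=int(raw.get("fourier_pairs", 1)),
            window=window,
            descriptive_month=raw.get("descriptive_month"),
        )

    def to_dict(self) -> dict:
        d = {
            "calendar": self.calendar.to_dict(),
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "subgroups": self.subgroups,
            "outcomes": self.outcomes,
            "disclosure": self.disclosure,
            "naive_denominator": self.naive_denominator,
            "lag": self.lag,
            "fourier_pairs": self.fourier_pairs,
            "window": list(self.window) if self.window else None,
            "descriptive_month": self.descriptive_month,
        }
        if self.truth is not None:
            d["truth"] = self.truth.to_dict()
        else:
            d["events"] = str(self.events_path)
            d["patients"] = str(self.patients_path)
        return d


def descriptive_table(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    calendar: StudyCalendar,
    month: str | int,
    subgroups: list[str],
    disclosure: bool = True,
) -> pd.DataFrame:
    """Point-in-time population summary with disclosure control.

    Per subgroup: prescribed and registered patient counts (redacted /
    rounded to the nearest 10), the rate per 1000 computed *from the rounded
    counts* (so group rows need not sum to the total), and the drug-class
    breakdown of prescribed patients.
    """
    t = month if isinstance(month, int) else calendar.t_index(month)
    rows = []
    classes = ("ssri", "tricyclic", "other", "multiple")
    for sg in subgroups:
        mask = cohort._subgroup_mask(patients, sg)
        pats = patients.loc[mask]
        registered = pats[
            (pats["reg_start"] <= t) & (t < pats["reg_end"])
        ]["patient_id"]
        ev = events[(events["month"] == t) & events["patient_id"].isin(registered)]
        prescribed = ev["patient_id"].nunique()
        by_class = (
            ev.groupby("patient_id")["drug_class"]
            .apply(cohort.assign_drug_class)
            .value_counts()
        )
        row: dict = {"subgroup": sg}
        if disclosure:
            p = cohort.disclosure_round(prescribed)
            r = cohort.disclosure_round(len(registered))
            row["prescribed"] = p
            row["registered"] = r
            row["rate_per_1000"] = (
                cohort.rate_per_1000(p, r) if p is not None and r else None
            )
            for c in classes:
                row[f"n_{c}"] = cohort.disclosure_round(int(by_class.get(c, 0)))
        else:
            row["prescribed"] = prescribed
            row["registered"] = len(registered)
            row["rate_per_1000"] = (
                cohort.rate_per_1000(prescribed, len(registered))
                if len(registered)
                else None
            )
            for c in classes:
                row[f"n_{c}"] = int(by_class.get(c, 0))
        rows.append(row)
    return pd.DataFrame(rows)


def _config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write all artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cal = config.calendar
    paths: dict[str, Path] = {}

    # --- stage 1: cohort data ------------------------------------------
    try:
        if config.truth is not None:
            patients = generate_population(config.truth, cal)
            events = generate_prescriptions(patients, config.truth, cal)
            io.write_patients(patients, out / "patients.csv", cal)
            io.write_events(events, out / "events.csv", cal)
            paths["patients"] = out / "patients.csv"
            paths["events"] = out / "events.csv"
        else:
            patients = io.read_patients(config.patients_path, cal)
            events = io.read_events(config.events_path, cal)
    except Exception as exc:
        raise PipelineError(f"simulate/load stage failed: {exc}") from exc
    log.info("cohort: %d patients, %d events", len(patients), len(events))

    # --- stage 2: aggregation ------------------------------------------
    try:
        pieces = []
        for sg in config.subgroups:
            if "prevalent" in config.outcomes:
                pieces.append(cohort.monthly_prevalent_counts(events, patients, cal, sg))
            if "new" in config.outcomes:
                pieces.append(
                    cohort.monthly_new_counts(
                        events, patients, cal, sg,
                        naive_denominator=config.naive_denominator,
                    )
                )
        series = pd.concat(pieces, ignore_index=True)
        io.write_series(series, out / "series.csv", cal)
        paths["series"] = out / "series.csv"
        if config.disclosure:
            published = cohort.apply_disclosure_control(series)
            io.write_series(published, out / "series_published.csv", cal)
            paths["series_published"] = out / "series_published.csv"
    except Exception as exc:
        raise PipelineError(f"aggregate stage failed: {exc}") from exc
    log.info("aggregated %d series rows", len(series))

    # --- stage 3 + 4: model and effects per subgroup/outcome -----------
    coef_tables, effect_rows = [], []
    for outcome in config.outcomes:
        subset = {
            sg: series[(series["subgroup"] == sg) & (series["outcome"] == outcome)]
            for sg in config.subgroups
        }
        results, errors = fit_subgroup_models(
            subset, cal, lag=config.lag, window=config.window,
            fourier_pairs=config.fourier_pairs,
        )
        for sg, exc in errors.items():
            log.warning("fit failed for %s/%s: %s", sg, outcome, exc)
        for sg, res in results.items():
            tab = coefficient_table(res.fitted)
            tab.insert(0, "outcome", outcome)
            tab.insert(0, "subgroup", sg)
            coef_tables.append(tab)
            a, alo, ahi = res.effects.average_rr
            d, dlo, dhi = res.effects.rate_difference_last
            effect_rows.append(
                {
                    "subgroup": sg,
                    "outcome": outcome,
                    "average_rr": round(a, 2),
                    "average_rr_ci_low": round(alo, 2),
                    "average_rr_ci_high": round(ahi, 2),
                    "rate_diff_last_month": round(d, 1),
                    "rate_diff_ci_low": round(dlo, 1),
                    "rate_diff_ci_high": round(dhi, 1),
                }
            )
    if not coef_tables:
        raise PipelineError("fit stage failed: no subgroup model converged")
    pd.concat(coef_tables, ignore_index=True).to_csv(
        out / "coefficients.csv", index=False
    )
    pd.DataFrame(effect_rows).to_csv(out / "effects.csv", index=False)
    paths["coefficients"] = out / "coefficients.csv"
    paths["effects"] = out / "effects.csv"

    # --- stage 5: descriptive table ------------------------------------
    desc_month = config.descriptive_month or cal.month_of(cal.n_months - 3)
    try:
        desc = descriptive_table(
            events, patients, cal, desc_month, config.subgroups,
            disclosure=config.disclosure,
        )
        desc.to_csv(out / "descriptive.csv", index=False)
        paths["descriptive"] = out / "descriptive.csv"
    except Exception as exc:
        raise PipelineError(f"descriptive stage failed: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "rxits": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    paths["manifest"] = out / "manifest.json"
    return paths
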