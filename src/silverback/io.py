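"""CSV schemata, run configuration, and the end-to-end pipeline runner.

All tables are UTF-8 CSV with a header row; dates are ISO-8601; ages are
decimal years.  Partner sets and orphan-id lists are semicolon-joined
within a cell.  ``full_run`` chains generator -> networks -> permutation
tests -> dyadic models -> survival models -> GLMs into one report
directory; with an identical configuration and seed the report is
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import OrphanEffectConfig
from .simulate import PopulationConfig, simulate_dispersal, simulate_incident_dataset
from .survival import SilerParams

__all__ = [
    "RunConfig",
    "read_demography",
    "write_demography",
    "read_scans",
    "write_scans",
    "read_incidents",
    "write_incidents",
    "write_report",
    "full_run",
]


# ---------------------------------------------------------------------------
# Demography
# ---------------------------------------------------------------------------

_TENURE_SEP, _ITEM_SEP = ":", ";"


def _tenures_to_str(tenures) -> str:
    return _ITEM_SEP.join(f"{s:.4f}{_TENURE_SEP}{e:.4f}" for s, e in (tenures or ()))


def _tenures_from_str(text) -> tuple:
    if not isinstance(text, str) or not text:
        return ()
    out = []
    for item in text.split(_ITEM_SEP):
        s, e = item.split(_TENURE_SEP)
        out.append((float(s), float(e)))
    return tuple(out)


def write_demography(roster: pd.DataFrame, path) -> None:
    out = roster.copy()
    out["birth_date"] = pd.to_datetime(out.birth_date).dt.strftime("%Y-%m-%d")
    out["dominance_tenures"] = [_tenures_to_str(t) for t in out.dominance_tenures]
    out["father_id"] = out.father_id.fillna("")
    out.to_csv(path, index=False)


def read_demography(path) -> pd.DataFrame:
    """Read a demographic roster CSV, validating the schema.

    Required columns: id, group, sex, birth_date, mother_id; optional:
    father_id, dominant, loss_age, orphan_class, death_age, censor_age,
    birth_date_uncertain, dominance_tenures.
    """
    roster = pd.read_csv(path)
    required = {"id", "group", "sex", "birth_date", "mother_id"}
    missing = required - set(roster.columns)
    if missing:
        raise ValueError(f"demography file {path}: missing columns {sorted(missing)}")
    if roster.id.duplicated().any():
        dupes = roster.id[roster.id.duplicated()].tolist()
        raise ValueError(f"demography file {path}: duplicate ids {dupes}")
    try:
        roster["birth_date"] = pd.to_datetime(roster.birth_date, format="%Y-%m-%d")
    except ValueError as err:
        raise ValueError(f"demography file {path}: malformed birth_date ({err})") from None
    known = set(roster.id) | {"unknown"}
    bad = roster.loc[~roster.mother_id.isin(known), ["id", "mother_id"]]
    if len(bad):
        raise ValueError(
            f"demography file {path}: unknown mother ids "
            f"{bad.mother_id.tolist()} (rows {bad.index.tolist()})"
        )
    if "father_id" in roster:
        roster["father_id"] = roster.father_id.replace({"": None, np.nan: None})
    if "dominance_tenures" in roster:
        roster["dominance_tenures"] = [
            _tenures_from_str(t) for t in roster.dominance_tenures
        ]
    if "dominant" in roster:
        roster["dominant"] = roster.dominant.astype(bool)
    return roster


# ---------------------------------------------------------------------------
# Focal scans and incidents
# ---------------------------------------------------------------------------


def _join_ids(ids) -> str:
    return _ITEM_SEP.join(ids)


def _split_ids(text) -> tuple:
    if not isinstance(text, str) or not text:
        return ()
    return tuple(text.split(_ITEM_SEP))


def write_scans(scans: pd.DataFrame, path) -> None:
    out = scans.copy()
    out["date"] = pd.to_datetime(out.date).dt.strftime("%Y-%m-%d")
    out["proximity_partners"] = [_join_ids(p) for p in out.proximity_partners]
    out["contact_partners"] = [_join_ids(p) for p in out.contact_partners]
    out.to_csv(path, index=False)


def read_scans(path, roster: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a focal-scan CSV, enforcing the scan invariants row by row.

    Rejects malformed dates, focal ids appearing in their own partner set,
    contact partners outside the 2-m set, and (when a roster is supplied)
    ids absent from the roster — each error names the offending row.
    """
    scans = pd.read_csv(path)
    required = {"date", "group", "focal", "proximity_partners", "contact_partners"}
    missing = required - set(scans.columns)
    if missing:
        raise ValueError(f"scan file {path}: missing columns {sorted(missing)}")
    try:
        scans["date"] = pd.to_datetime(scans.date, format="%Y-%m-%d")
    except ValueError as err:
        raise ValueError(f"scan file {path}: malformed date ({err})") from None
    scans["proximity_partners"] = [_split_ids(t) for t in scans.proximity_partners]
    scans["contact_partners"] = [_split_ids(t) for t in scans.contact_partners]
    known = set(roster.id) if roster is not None else None
    for k, row in enumerate(scans.itertuples(index=False)):
        prox, cont = set(row.proximity_partners), set(row.contact_partners)
        if row.focal in prox | cont:
            raise ValueError(f"scan file {path} row {k}: focal {row.focal} in own "
                             "partner set")
        if not cont <= prox:
            raise ValueError(
                f"scan file {path} row {k}: contact partners {sorted(cont - prox)} "
                "not within the 2-m proximity set"
            )
        if known is not None:
            unknown = ({row.focal} | prox) - known
            if unknown:
                raise ValueError(f"scan file {path} row {k}: unknown ids "
                                 f"{sorted(unknown)}")
    return scans


def write_incidents(incidents: pd.DataFrame, path) -> None:
    out = incidents.copy()
    out["date"] = pd.to_datetime(out.date).dt.strftime("%Y-%m-%d")
    out["orphan_ids"] = [_join_ids(o) for o in out.orphan_ids]
    out.to_csv(path, index=False)


def read_incidents(path) -> pd.DataFrame:
    incidents = pd.read_csv(path)
    required = {"incident", "group", "date", "mother_id", "orphan_ids"}
    missing = required - set(incidents.columns)
    if missing:
        raise ValueError(f"incident file {path}: missing columns {sorted(missing)}")
    incidents["date"] = pd.to_datetime(incidents.date, format="%Y-%m-%d")
    incidents["orphan_ids"] = [_split_ids(o) for o in incidents.orphan_ids]
    return incidents


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Settings for a full pipeline run; every default is overridable.

    The configuration (including the embedded population settings) is
    serialized into the report for provenance.
    """

    seed: int = 0
    population: PopulationConfig = field(default_factory=PopulationConfig)
    window_days: int = 183
    min_scans: int = 12
    n_sets: int = 10000
    thin: int = 200
    mcmc_walkers: int = 24
    mcmc_steps: int = 1500
    orphan_bins: tuple = (2.0, 4.0, 6.0, 8.0)

    def __post_init__(self):
        self.population = dataclasses.replace(self.population, seed=self.seed,
                                              window_days=self.window_days)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["population"]["siler_params"] = dataclasses.asdict(
            self.population.siler_params
        )
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict(), default=list)), fh,
                           sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        pop = d.pop("population", {})
        effects = pop.pop("orphan_effects", None)
        siler = pop.pop("siler_params", None)
        if siler is not None:
            pop["siler_params"] = SilerParams(**siler)
        if effects is not None:
            pop["orphan_effects"] = OrphanEffectConfig(**effects)
        if "group_size_range" in pop:
            pop["group_size_range"] = tuple(pop["group_size_range"])
        d["population"] = PopulationConfig(**pop)
        d.pop("orphan_bins", None)
        return cls(**d)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def write_report(results: dict, out_dir) -> Path:
    """Write the result tables and the JSON report of a pipeline run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.csv")
    summary = {k: v for k, v in results.items() if not isinstance(v, pd.DataFrame)}
    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return report_path


def full_run(config: RunConfig, out_dir, write_scan_table: bool = False) -> dict:
    """Run the complete analysis chain on a freshly simulated study.

    Generator -> SRI networks -> permutation tests (three metrics, two
    association types) -> dyadic models -> Cox and Bayesian Siler survival
    -> dispersal GLM, writing all result tables plus ``report.json`` under
    ``out_dir`` and returning the results dictionary.
    """
    from . import dyadic, glms, permutation, survival

    results: dict = {"config": config.to_dict()}
    study = simulate_incident_dataset(config.population)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_demography(study.roster, out / "roster.csv")
    write_incidents(study.incidents, out / "incidents.csv")
    if write_scan_table:
        write_scans(study.scans, out / "scans.csv")

    perm_reports = {}
    for assoc in ("proximity", "contact"):
        records = permutation.build_change_records(
            study.scans, study.roster, study.incidents, assoc_type=assoc,
            window_days=config.window_days, min_scans=config.min_scans,
        )
        results[f"change_records_{assoc}"] = records.set_index(["incident", "node"])
        for metric in ("binary_degree_norm", "weighted_degree_norm", "eigenvector"):
            res = permutation.run_permutation_test(
                records, metric=metric, assoc_type=assoc,
                n_sets=config.n_sets, thin=config.thin, seed=config.seed,
            )
            perm_reports[f"{assoc}_{metric}"] = res.report()
    results["permutation_tests"] = perm_reports

    for assoc in ("proximity", "contact"):
        dyads = dyadic.build_dyad_table(
            study.scans, study.roster, study.incidents, assoc_type=assoc,
            window_days=config.window_days, min_scans=config.min_scans,
        )
        results[f"dyads_{assoc}"] = dyads.set_index(["incident", "immature", "partner"])
        results[f"dyadic_all_immature_{assoc}"] = dyadic.fit_all_immature_model(dyads).coef_table
        results[f"dyadic_orphan_only_{assoc}"] = dyadic.fit_orphan_only_model(dyads).coef_table
        try:
            results[f"dyadic_adult_male_{assoc}"] = dyadic.fit_adult_male_model(dyads).coef_table
        except ValueError as err:
            results[f"adult_male_model_{assoc}_skipped"] = str(err)

    records = survival.build_survival_records(study.roster, merged=True)
    results["survival_records"] = records.set_index("id")
    results["cox_merged"] = survival.fit_cox_ph(records, class_coding="merged")
    fits = {
        v: survival.fit_siler_bayes(
            records, variant=v, n_walkers=config.mcmc_walkers,
            n_steps=config.mcmc_steps, seed=config.seed,
        )
        for v in ("null", "prop_hazards")
    }
    results["dic_comparison"] = survival.compare_dic(fits)
    results["siler_posterior_null"] = fits["null"].credible_interval()

    outcomes = simulate_dispersal(study.roster, config.population.dispersal_logit,
                                  config.seed)
    eligible = outcomes[outcomes.orphan_class.isin(
        ["non_orphan", "infant", "juv_subadult"])].copy()
    eligible["stayed"] = 1 - eligible.dispersed
    results["dispersal_glm_simulated"] = glms.fit_binomial_glm(
        eligible, "dispersed ~ C(orphan_class, Treatment('non_orphan'))"
    ).table()
    results["dispersal_glm_female_observed"] = glms.fit_female_dispersal().table()
    results["dispersal_glm_male_observed"] = glms.fit_male_dispersal().table()

    write_report(results, out)
    return results
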