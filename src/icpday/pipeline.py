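"""End-to-end orchestration: simulate/ingest -> preprocess -> cluster ->
cut-point -> IPTW effects -> cohort statistics, with a reproducibility
manifest.

Every stage is a pure function of (inputs, config, seed); the manifest
records the config hash, the seed and subject counts in/out of each stage so
identical runs are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import causal, cohort_stats, cluster, cutpoint, preprocess
from .simulate import SimConfig, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

COHORT_COLUMNS = (
    "subject_id", "age", "gender", "gcs_min", "apsiii", "oasis", "sofa",
    "fluid_balance_ml", "icu_death", "time_hours", "icu_intime",
)
CHARTEVENT_COLUMNS = ("subject_id", "charttime", "icp_mmHg")


@dataclass
class RunConfig:
    """Pipeline settings; see docs/methods.md for the rationale of defaults."""

    simulate: bool = True
    chartevents_path: str | None = None
    cohort_path: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    normalization: str = "zscore"       # or "minmax"
    k_min: int = 2
    k_max: int = 7
    min_group_frac: float = 0.05
    cut_rounding: int = 0
    estimands: tuple[str, ...] = ("ATT", "ATU", "ATE")
    n_boot: int = 1000
    fdr_q: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Fan a single run seed out to per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def validate_inputs(chartevents_path: str, cohort_path: str) -> list[dict]:
    """Schema checks on the two CSV inputs; returns itemized violations."""
    violations: list[dict] = []

    ce = pd.read_csv(chartevents_path)
    for col in CHARTEVENT_COLUMNS:
        if col not in ce.columns:
            violations.append({"file": "chartevents", "check": "column", "detail": f"missing column {col!r}"})
    if "charttime" in ce.columns:
        parsed = pd.to_datetime(ce["charttime"], errors="coerce", format="ISO8601")
        for row in np.flatnonzero(parsed.isna().to_numpy())[:20]:
            violations.append(
                {"file": "chartevents", "check": "timestamp", "row": int(row),
                 "detail": f"unparseable ISO-8601 timestamp at row {int(row)}"}
            )
    if "icp_mmHg" in ce.columns:
        vals = pd.to_numeric(ce["icp_mmHg"], errors="coerce")
        bad = int((~np.isfinite(vals)).sum())
        if bad:
            violations.append({"file": "chartevents", "check": "value", "detail": f"{bad} non-finite ICP values"})

    co = pd.read_csv(cohort_path)
    for col in COHORT_COLUMNS:
        if col not in co.columns:
            violations.append({"file": "cohort", "check": "column", "detail": f"missing column {col!r}"})
    if "subject_id" in co.columns and co["subject_id"].duplicated().any():
        dups = co.loc[co["subject_id"].duplicated(), "subject_id"].tolist()[:10]
        violations.append({"file": "cohort", "check": "duplicates", "detail": f"duplicate subject ids {dups}"})
    return violations


def _load_inputs(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    if config.simulate:
        sim_cfg = config.sim
        if sim_cfg.seed != config.seed:
            sim_cfg = SimConfig(**{**sim_cfg.to_dict(), "seed": config.seed})
        tables = simulate_cohort(sim_cfg)
        return tables["chartevents"], tables["cohort"], tables["truth"]
    issues = validate_inputs(config.chartevents_path, config.cohort_path)
    fatal = [v for v in issues if v["check"] in ("column", "duplicates")]
    if fatal:
        raise ValueError(f"input validation failed: {fatal}")
    ce = pd.read_csv(config.chartevents_path, parse_dates=["charttime"])
    co = pd.read_csv(config.cohort_path, parse_dates=["icu_intime"])
    return ce, co, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of output tables plus the manifest
    (and writes CSVs/JSON when ``config.out_dir`` is set)."""
    seeds = _stage_seeds(config.seed)
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}
    outputs: dict = {}

    chartevents, cohort, truth = _load_inputs(config)
    manifest["stages"]["input"] = {"n_subjects": int(len(cohort)), "n_events": int(len(chartevents))}

    # --- preprocessing -----------------------------------------------------
    day_starts = pd.Series(
        pd.to_datetime(cohort["icu_intime"]).to_numpy(), index=cohort["subject_id"]
    )
    series = preprocess.build_series_table(chartevents, day_starts)
    n_excluded = int(series["excluded"].sum())
    manifest["stages"]["preprocess"] = {
        "n_in": int(len(series)),
        "n_excluded": n_excluded,
        "n_out": int(len(series)) - n_excluded,
        "exclusion_reasons": series.loc[series["excluded"], "exclusion_reason"]
        .value_counts().to_dict(),
    }
    outputs["series"] = series
    analysis = cohort.merge(
        series.loc[~series["excluded"], ["subject_id", "icp_mean", "icp_variance"]],
        on="subject_id",
    ).reset_index(drop=True)
    if analysis.empty:
        raise RuntimeError("preprocess: no subjects remain after gap exclusion")

    # --- clustering --------------------------------------------------------
    matrix, kept_ids = preprocess.series_matrix(series)
    normalized, _ = preprocess.normalize_matrix(matrix, method=config.normalization)
    solution = cluster.select_k(
        normalized, range(config.k_min, config.k_max + 1), seed=seeds[0]
    )
    romans = cluster.size_ordered_labels(solution.labels)
    outputs["clusters"] = pd.DataFrame({"subject_id": kept_ids, "cluster": romans})
    outputs["db_by_k"] = pd.DataFrame(
        {"k": list(solution.per_k_db), "davies_bouldin": list(solution.per_k_db.values())}
    )
    manifest["stages"]["cluster"] = {"selected_k": solution.k, "db_index": solution.db_index}

    # --- cut-point survival ------------------------------------------------
    scans = []
    results: dict[str, cutpoint.CutpointResult] = {}
    for name in ("icp_mean", "icp_variance"):
        res = cutpoint.scan_cutpoints(
            analysis[name], analysis["time_hours"], analysis["icu_death"].astype(bool),
            min_group_frac=config.min_group_frac, rounding=config.cut_rounding,
        )
        results[name] = res
        t = res.scan_table.copy()
        t.insert(0, "marker", name)
        scans.append(t)
    outputs["cutpoint_scan"] = pd.concat(scans, ignore_index=True)
    manifest["stages"]["cutpoint"] = {
        name: {"best_cut": res.best_cut, "p_value": res.p_value, "corrected_p": res.corrected_p}
        for name, res in results.items()
    }
    mean_res = results["icp_mean"]
    if not mean_res.found:
        raise RuntimeError("cutpoint: no admissible ICP_mean cut-point")
    high = cutpoint.dichotomize(analysis["icp_mean"], mean_res.best_cut)

    km_rows = []
    for label, sel in (("high", high), ("low", ~high)):
        if sel.sum() == 0:
            continue
        kmf = cutpoint.km_estimate(
            analysis.loc[sel, "time_hours"], analysis.loc[sel, "icu_death"].astype(bool)
        )
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time_hours", "survival"]
        sf.insert(0, "group", f"icp_mean_{label}")
        km_rows.append(sf)
    outputs["km_groups"] = pd.concat(km_rows, ignore_index=True)

    # --- causal weighting --------------------------------------------------
    spec = causal.PSModelSpec()
    cov_names = [c for c in spec.candidate_covariates if c in analysis.columns]
    covs = analysis[cov_names]
    selected, screen_log = causal.screen_confounders(
        covs, high.astype(int), analysis["icu_death"], spec
    )
    effects, weight_cols = [], {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, estimand in enumerate(config.estimands):
            est = causal.estimate_effect(
                analysis["icu_death"], high.astype(int), covariates=covs[selected] if selected else None,
                spec=causal.PSModelSpec(candidate_covariates=tuple(selected), smoother=spec.smoother),
                estimand=estimand, n_boot=config.n_boot, seed=seeds[1 + i],
            )
            effects.append(
                {"estimand": estimand, "odds_ratio": est.estimate, "ci_low": est.ci_low,
                 "ci_high": est.ci_high, "p_value": est.p_value}
            )
            weight_cols[f"w_{estimand.lower()}"] = est.weights
            if estimand == "ATE":
                outputs["balance"] = est.balance_table.reset_index(names="covariate")
    outputs["effects"] = pd.DataFrame(effects)
    outputs["weights"] = pd.DataFrame({"subject_id": analysis["subject_id"], **weight_cols})
    outputs["confounder_screen"] = screen_log
    manifest["stages"]["causal"] = {
        "treatment_cut": mean_res.best_cut,
        "n_treated": int(high.sum()),
        "n_control": int((~high).sum()),
        "selected_confounders": selected,
    }

    # --- cohort statistics -------------------------------------------------
    table = analysis.copy()
    table["icp_group"] = np.where(high, f"> {mean_res.best_cut:g} mmHg", f"<= {mean_res.best_cut:g} mmHg")
    stat_vars = [c for c in ("age", "gender", "gcs_min", "apsiii", "oasis", "sofa",
                             "fluid_balance_ml", "icu_death", "icp_mean", "icp_variance")
                 if c in table.columns]
    outputs["table1"] = cohort_stats.compare_groups(
        table, "icp_group", variables=stat_vars,
        categorical=["gender", "icu_death"], alpha_fdr=config.fdr_q,
    )
    logit_covs = table[[c for c in ("age", "gcs_min", "apsiii", "oasis", "sofa") if c in table]].copy()
    logit_covs["icp_high"] = high.astype(float)
    outputs["logistic"] = cohort_stats.multivariate_logistic(
        table["icu_death"], logit_covs, always_keep=("age", "icp_high")
    )
    outputs["correlation"] = cohort_stats.fluid_icp_correlation(
        table["fluid_balance_ml"], table["icp_mean"],
        np.where(table["icu_death"] == 1, "icu_death", "survived"),
    )
    manifest["stages"]["stats"] = {
        "n_table1_rows": int(len(outputs["table1"])),
        "n_fdr_significant": int(outputs["table1"]["fdr_significant"].sum()),
    }

    if truth is not None:
        outputs["truth"] = truth
    outputs["chartevents"] = chartevents
    outputs["cohort"] = cohort
    outputs["manifest"] = manifest

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("series", "clusters", "db_by_k", "cutpoint_scan", "km_groups",
                     "effects", "weights", "balance", "table1", "logistic",
                     "correlation", "chartevents", "cohort", "truth"):
            if name in outputs:
                outputs[name].to_csv(out / f"{name}.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outputs
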