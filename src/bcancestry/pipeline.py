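"""End-to-end orchestration: simulate/ingest -> ancestry -> TMB ->
clinical battery -> somatic differentials -> germline -> screening
windows -> power, with a run manifest.

Each stage writes its outputs before the next starts, and the manifest
records per-stage row counts in the style of an exclusion-flow
diagram, so a failed run names the stage that broke.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from typing import Any, Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from bcancestry import __version__, ancestry as anc_mod, clinical as clin_mod
from bcancestry import germline as germ_mod, io as bcio, somatic as som_mod, tmb as tmb_mod
from bcancestry.config import CohortConfig, ConfigError
from bcancestry.power import PowerDesign, detectable_or
from bcancestry.synthetic import SyntheticBundle, generate_cohort, write_fixtures


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and exit category."""

    def __init__(self, stage: str, message: str, exit_code: int = 3):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = exit_code


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    started: float
    stages: List[Dict[str, Any]] = field(default_factory=list)
    finished: Optional[float] = None

    def record(self, name: str, outputs: Dict[str, str], rows: Dict[str, int], seconds: float) -> None:
        self.stages.append({
            "stage": name,
            "outputs": outputs,
            "rows": rows,
            "seconds": round(seconds, 3),
        })

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)


def _config_hash(config: Mapping[str, Any]) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_pipeline_config(config: "str | Mapping[str, Any]") -> Dict[str, Any]:
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    out = dict(config)
    out.setdefault("mode", "synthetic")
    out.setdefault("cohort", {})
    out.setdefault("power", {})
    out.setdefault("feature_kind", "gene")
    return out


def _ingest(conf: Dict[str, Any]) -> SyntheticBundle:
    inputs = conf.get("inputs") or {}
    for key in ("clinical", "somatic", "germline", "panel"):
        path = inputs.get(key)
        if not path:
            raise StageError("ingest", f"config missing inputs.{key} (path to the {key} table)", exit_code=2)
        if not os.path.exists(path):
            raise StageError("ingest", f"inputs.{key} not found: {path}", exit_code=2)
    clinical = bcio.read_clinical(inputs["clinical"])
    somatic = (
        bcio.read_somatic_vcf(inputs["somatic"])
        if inputs["somatic"].endswith(".vcf")
        else bcio.read_somatic_tsv(inputs["somatic"])
    )
    germline = bcio.read_germline(inputs["germline"])
    panel = bcio.read_panel(inputs["panel"])
    return SyntheticBundle(clinical=clinical, somatic=somatic, germline=germline,
                           panel=panel, truth={})


def run_pipeline(config: "str | Mapping[str, Any]", outdir: str) -> RunManifest:
    """Run every stage from one config; returns the manifest.

    ``config`` is a path to a YAML file or an equivalent mapping with
    keys ``mode`` (synthetic | ingest), ``cohort`` (synthetic-cohort
    parameters), ``inputs`` (paths, ingest mode), ``feature_kind`` and
    ``power``.
    """
    conf = _load_pipeline_config(config)
    os.makedirs(outdir, exist_ok=True)
    cohort_cfg = CohortConfig.from_dict(conf["cohort"]) if conf["mode"] == "synthetic" else None
    manifest = RunManifest(
        config_hash=_config_hash(conf),
        seed=int(cohort_cfg.seed) if cohort_cfg else -1,
        version=__version__,
        started=time.time(),
    )

    def stage(name):
        t0 = time.time()
        return t0

    # ---- stage: data ------------------------------------------------------
    t0 = time.time()
    if conf["mode"] == "synthetic":
        bundle = generate_cohort(cohort_cfg)
        data_dir = os.path.join(outdir, "data")
        paths = write_fixtures(bundle, data_dir)
    elif conf["mode"] == "ingest":
        bundle = _ingest(conf)
        paths = dict(conf.get("inputs") or {})
    else:
        raise StageError("config", f"unknown mode {conf['mode']!r}", exit_code=2)
    clinical = bundle.clinical
    if not len(clinical):
        raise StageError("data", "clinical table is empty", exit_code=3)
    manifest.record("data", {k: str(v) for k, v in paths.items()},
                    {"participants": len(clinical), "somatic_calls": len(bundle.somatic),
                     "germline_calls": len(bundle.germline)}, time.time() - t0)

    # ---- stage: ancestry --------------------------------------------------
    t0 = time.time()
    prop_cols = [c for c in clinical.columns if c.startswith("prop_")]
    if prop_cols:
        labels = anc_mod.assign_labels(clinical)
        clinical = clinical.copy()
        clinical["gAncestry"] = labels.to_numpy()
    elif "gAncestry" not in clinical.columns:
        raise StageError("ancestry", "no ancestry proportions or labels in the clinical table", exit_code=2)
    anc_out = os.path.join(outdir, "ancestry.tsv")
    clinical[["participant_id", "gAncestry"]].to_csv(anc_out, sep="\t", index=False)
    conc_out = os.path.join(outdir, "concordance.json")
    rows = {"participants": len(clinical)}
    if "sre" in clinical.columns:
        frac, table = anc_mod.concordance(clinical["gAncestry"], clinical["sre"])
        with open(conc_out, "w") as fh:
            json.dump({"concordance": frac, "table": table.to_dict()}, fh, indent=1)
        rows["concordant_fraction_pct"] = round(100 * frac, 1)
    manifest.record("ancestry", {"labels": anc_out, "concordance": conc_out}, rows, time.time() - t0)

    # ---- stage: tmb -------------------------------------------------------
    t0 = time.time()
    anc_by_sample = dict(zip(clinical["participant_id"], clinical["gAncestry"]))
    analysable = {s: a for s, a in anc_by_sample.items() if a in tmb_mod.POPULATION_BY_ANCESTRY}
    som = bundle.somatic[bundle.somatic["sample_id"].isin(analysable)]
    classified = tmb_mod.classify_table(som, analysable)
    tmb_df = tmb_mod.tmb_per_sample(classified, analysable, samples=sorted(analysable))
    fate_out = os.path.join(outdir, "somatic_fates.tsv")
    bcio.write_somatic_tsv(classified, fate_out)
    tmb_out = os.path.join(outdir, "tmb.tsv")
    tmb_df.to_csv(tmb_out, sep="\t", index=False)
    clinical = clinical.merge(
        tmb_df.rename(columns={"sample_id": "participant_id"})[["participant_id", "retained_count", "tmb"]],
        on="participant_id", how="left",
    )
    er = clinical.set_index("participant_id").loc[tmb_df["sample_id"], "ER"] if "ER" in clinical.columns else None
    tmb_er_out = os.path.join(outdir, "tmb_by_er.tsv")
    if er is not None and er.notna().any():
        by_er = tmb_mod.tmb_by_group(tmb_df["tmb"].to_numpy(), er.to_numpy())
        by_er.to_csv(tmb_er_out, sep="\t", index=False)
    manifest.record("tmb", {"fates": fate_out, "tmb": tmb_out, "tmb_by_er": tmb_er_out},
                    {"variants_in": len(som), "retained": int(classified["retained"].sum()),
                     "samples": len(tmb_df)}, time.time() - t0)

    # ---- stage: clinical battery -----------------------------------------
    t0 = time.time()
    records = []
    try:
        records += clin_mod.fit_age_model(clinical, "age_at_diagnosis")
        if clinical.get("age_at_death") is not None and clinical["age_at_death"].notna().sum() >= 10:
            records += clin_mod.fit_age_model(clinical, "age_at_death")
        for outcome in ("ER", "PR", "HER2", "grade", "stage", "lymph_node", "IMD_quintile"):
            if outcome in clinical.columns:
                records += clin_mod.fit_categorical_model(clinical, outcome)
        if clinical["retained_count"].notna().any():
            records += clin_mod.fit_tmb_model(clinical.dropna(subset=["retained_count"]))
    except clin_mod.SingleGroupError as exc:
        raise StageError("clinical", str(exc), exit_code=3) from exc
    forest = pd.DataFrame([r.to_dict() for r in records])
    forest_out = os.path.join(outdir, "forest.tsv")
    forest.to_csv(forest_out, sep="\t", index=False)
    lrt = clin_mod.lrt_imd(clinical, "age_at_diagnosis")
    imd_tests = clin_mod.imd_association_tests(clinical[clinical["gAncestry"] == "EUR"].drop(columns=["gAncestry"]))
    imd_out = os.path.join(outdir, "imd_tests.json")
    with open(imd_out, "w") as fh:
        json.dump({"lrt_age_at_diagnosis": lrt.to_dict(),
                   "within_EUR": imd_tests.to_dict(orient="records")}, fh, indent=1, default=str)
    manifest.record("clinical", {"forest": forest_out, "imd": imd_out},
                    {"terms": len(forest)}, time.time() - t0)

    # ---- stage: somatic differential -------------------------------------
    t0 = time.time()
    analytic = clinical[clinical["gAncestry"].isin(som_mod.ANALYTIC_GROUPS)]
    idx = analytic["participant_id"]
    matrix = som_mod.build_mutation_matrix(classified, idx, feature_kind=conf["feature_kind"])
    anc_series = analytic.set_index("participant_id")["gAncestry"]
    age_series = analytic.set_index("participant_id")["age_at_diagnosis"]
    logi = som_mod.per_feature_logistic(matrix, anc_series, age_series)
    thr = som_mod.threshold_classifier(matrix, anc_series)
    inter = som_mod.intersection_sets(thr)
    diff_out = os.path.join(outdir, "somatic_diff.tsv")
    logi.to_csv(diff_out, sep="\t", index=False)
    thr_out = os.path.join(outdir, "somatic_threshold.tsv")
    thr.to_csv(thr_out, sep="\t", index=False)
    inter_out = os.path.join(outdir, "intersections.json")
    with open(inter_out, "w") as fh:
        json.dump(inter, fh, indent=1)
    # per-patient variant-class counts (substitutions only: the synthetic
    # generator emits single-base substitutions)
    sub_counts = (
        bundle.somatic[bundle.somatic["sample_id"].isin(idx)]
        .groupby("sample_id").size().reindex(idx, fill_value=0)
        .rename("substitutions").to_frame()
    )
    rates = som_mod.variant_class_rates(sub_counts, anc_series, classes=("substitutions",))
    rates_out = os.path.join(outdir, "variant_class_rates.tsv")
    rates.to_csv(rates_out, sep="\t", index=False)
    manifest.record("somatic_diff",
                    {"logistic": diff_out, "threshold": thr_out, "intersections": inter_out,
                     "class_rates": rates_out},
                    {"features": matrix.shape[1],
                     "logistic_converged": int(logi["converged"].sum()),
                     "threshold_present": int(thr["intersection"].notna().sum())},
                    time.time() - t0)

    # ---- stage: germline --------------------------------------------------
    t0 = time.time()
    gclassified = germ_mod.classify_calls(bundle.germline, panel=set(bundle.panel))
    group_by_pid = dict(zip(analytic["participant_id"], analytic["gAncestry"]))
    burden = germ_mod.burden_summary(gclassified[gclassified["participant_id"].isin(group_by_pid)], group_by_pid)
    carriers = germ_mod.carrier_matrix(gclassified, list(analytic["participant_id"]))
    # enrichment restricted to genes with any carriers, to keep output tidy
    seen = carriers.columns[carriers.sum() > 0]
    enrich = germ_mod.gene_enrichment(carriers[seen], anc_series)
    burden_out = os.path.join(outdir, "germline_burden.tsv")
    burden.to_csv(burden_out, sep="\t", index=False)
    enrich_out = os.path.join(outdir, "germline_enrichment.tsv")
    enrich.to_csv(enrich_out, sep="\t", index=False)
    fisher_out = os.path.join(outdir, "brca_by_er.json")
    fisher_res = {}
    if "ER" in clinical.columns and "germline_brca" in clinical.columns:
        sub = clinical.dropna(subset=["ER"])
        a = int(((sub["ER"] == "negative") & (sub["germline_brca"] == 1)).sum())
        b = int(((sub["ER"] == "negative") & (sub["germline_brca"] == 0)).sum())
        c = int(((sub["ER"] == "positive") & (sub["germline_brca"] == 1)).sum())
        d = int(((sub["ER"] == "positive") & (sub["germline_brca"] == 0)).sum())
        try:
            p, orr = germ_mod.fisher_2x2(a, b, c, d)
            fisher_res = {"table": [[a, b], [c, d]], "p": p, "odds_ratio": orr}
        except ValueError as exc:
            fisher_res = {"table": [[a, b], [c, d]], "error": str(exc)}
        with open(fisher_out, "w") as fh:
            json.dump(fisher_res, fh, indent=1)
    manifest.record("germline", {"burden": burden_out, "enrichment": enrich_out,
                                 "brca_by_er": fisher_out},
                    {"calls": len(gclassified),
                     "pathogenic": int((gclassified["fate"] == germ_mod.PATHOGENIC).sum())},
                    time.time() - t0)

    # ---- stage: screening windows ----------------------------------------
    t0 = time.time()
    windows = []
    for g in som_mod.ANALYTIC_GROUPS:
        ages = clinical.loc[clinical["gAncestry"] == g, "age_at_diagnosis"].dropna()
        if len(ages) >= 10:
            w = clin_mod.derive_screening_window(ages, ancestry=g)
            d = w.to_dict()
            std_cov = clin_mod.window_coverage(ages, (50, 70))
            d["standard_50_70_pct"] = std_cov[2]
            windows.append(d)
    win_out = os.path.join(outdir, "screening_windows.tsv")
    pd.DataFrame(windows).to_csv(win_out, sep="\t", index=False)
    manifest.record("windows", {"windows": win_out}, {"groups": len(windows)}, time.time() - t0)

    # ---- stage: power -----------------------------------------------------
    t0 = time.time()
    sizes = clinical["gAncestry"].value_counts()
    n_ref = int(sizes.get("EUR", 0))
    power_conf = conf["power"]
    results = {}
    if n_ref >= 2 and power_conf.get("enabled", True):
        for g in ("AFR", "SAS"):
            n_min = int(sizes.get(g, 0))
            if n_min < 2:
                continue
            for freq in power_conf.get("frequencies", (0.05, 0.25)):
                design = PowerDesign(
                    n_ref=n_ref, n_min=n_min, freq_min=float(freq),
                    alpha=float(power_conf.get("alpha", 0.1)),
                    target_power=float(power_conf.get("target_power", 0.9)),
                    n_sims=int(power_conf.get("n_sims", 20000)),
                    seed=int(power_conf.get("seed", manifest.seed if manifest.seed >= 0 else 0)),
                )
                try:
                    results[f"{g}_freq{freq}"] = detectable_or(design)
                except ValueError as exc:
                    # small cohorts can make the target power unreachable
                    results[f"{g}_freq{freq}"] = {"error": str(exc)}
    power_out = os.path.join(outdir, "power.json")
    with open(power_out, "w") as fh:
        json.dump(results, fh, indent=1)
    manifest.record("power", {"power": power_out}, {"designs": len(results)}, time.time() - t0)

    manifest.finished = time.time()
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1)
    return manifest
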