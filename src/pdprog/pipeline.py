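"""End-to-end pipeline: simulate -> impute -> models -> evaluation -> survival.

A PipelineConfig (usually read from YAML) names the stages to run and
their parameter blocks.  All randomness derives from one root seed via
named substreams, so each stage is independently reproducible; every
artifact is written as CSV with a JSON metadata sidecar recording the
seed and configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import cohort as ch
from . import io as cio
from .evaluate import CVScheme, MixedStatusModel, TGLStatusModel, run_nested_cv
from .impute import RBMConfig, impute
from .mixed import fit_ordinal_mixed, genotype_test_associations
from .survival import (
    build_survival_records,
    fit_cox_frailty,
    kaplan_meier,
    logrank_test,
    survival_curves_by_subgroup,
)
from .tgl import Hyperparams, component_magnitudes, fit_ordinal_tgl

log = logging.getLogger("pdprog")

STAGES = ["simulate", "impute", "fit-mixed", "fit-tgl", "evaluate", "survival"]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _write_with_sidecar(df: pd.DataFrame, path: Path, meta: dict) -> None:
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = dict(meta)
    meta["rows"] = len(df)
    meta["written_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    sidecar.write_text(json.dumps(meta, indent=2, default=str))


def validate_config(config: dict) -> dict:
    if "seed" not in config:
        raise ValueError("config must set a global 'seed'")
    if "out_dir" not in config:
        raise ValueError("config must set 'out_dir'")
    stages = config.get("stages", STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    config = dict(config)
    config["stages"] = stages
    return config


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages in order; returns artifact paths."""
    config = validate_config(config)
    seed = int(config["seed"])
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    exclude_under_50 = bool(config.get("exclude_under_50", False))
    confhash = hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]
    meta = {"seed": seed, "config_hash": confhash}
    artifacts: dict[str, str] = {}

    table = None
    try:
        if "simulate" in stages:
            log.info("stage simulate")
            params = dict(config.get("simulate", {}))
            params["seed"] = stage_seed(seed, "simulate")
            gc = ch.GeneratorConfig(**params)
            table = ch.generate_cohort(gc)
            path = out / "cohort.csv"
            cio.write_cohort(table, path)
            ch.write_truth(gc, out / "cohort.truth.json")
            (path.with_suffix(".csv.meta.json")).write_text(
                json.dumps({**meta, "stage": "simulate", "rows": len(table)}, indent=2)
            )
            artifacts["cohort"] = str(path)
        elif "cohort" in config:
            table = cio.read_cohort(config["cohort"])

        if table is None:
            raise ValueError("no cohort: configure the simulate stage or a 'cohort' path")
        if exclude_under_50:
            table = table[table["age_years"] >= 50].reset_index(drop=True)

        if "impute" in stages:
            log.info("stage impute")
            blk = dict(config.get("impute", {}))
            method = blk.pop("imputer", "median")
            rbm = RBMConfig(**blk, seed=stage_seed(seed, "impute")) if method == "rbm" else None
            table = impute(table, method=method, config=rbm)
            path = out / "imputed.csv"
            _write_with_sidecar(table, path, {**meta, "stage": "impute", "imputer": method})
            artifacts["imputed"] = str(path)

        if "fit-mixed" in stages:
            log.info("stage fit-mixed")
            blk = config.get("mixed", {})
            fit = fit_ordinal_mixed(table, blk.get("covariates"))
            _write_with_sidecar(fit.or_table(), out / "status_associations.csv",
                                {**meta, "stage": "fit-mixed", "sigma_b": fit.sigma_b})
            perf = genotype_test_associations(table)
            _write_with_sidecar(perf, out / "test_associations.csv",
                                {**meta, "stage": "fit-mixed"})
            artifacts["status_associations"] = str(out / "status_associations.csv")
            artifacts["test_associations"] = str(out / "test_associations.csv")

        if "fit-tgl" in stages:
            log.info("stage fit-tgl")
            blk = config.get("tgl", {})
            theta = Hyperparams(**blk.get("theta", {"theta1": 0.1, "theta2": 0.1, "theta3": 0.5}))
            m_nci, m_pdd = fit_ordinal_tgl(table, blk.get("features"), theta,
                                           max_iter=int(blk.get("max_iter", 1000)))
            frames = []
            for name, m in (("NCI", m_nci), ("PDD", m_pdd)):
                cm = component_magnitudes(m).reset_index(names="feature").melt(
                    id_vars="feature", var_name="horizon", value_name="weight")
                cm["model"] = name
                frames.append(cm)
            _write_with_sidecar(pd.concat(frames, ignore_index=True), out / "tgl_weights.csv",
                                {**meta, "stage": "fit-tgl", "theta": vars(theta)})
            artifacts["tgl_weights"] = str(out / "tgl_weights.csv")

        if "evaluate" in stages:
            log.info("stage evaluate")
            blk = config.get("evaluate", {})
            scheme = CVScheme(
                n_outer=int(blk.get("n_outer", 100)),
                holdout_fraction=float(blk.get("holdout", 0.25)),
                inner_folds=int(blk.get("inner_folds", 5)),
                seed=stage_seed(seed, "evaluate"),
            )
            reports = []
            which = blk.get("models", ["mixed-bio", "mixed-cog", "tgl"])
            for name in which:
                model = _evaluation_model(name, blk)
                rep, _ = run_nested_cv(table, model, scheme)
                rep["model"] = name
                reports.append(rep)
            _write_with_sidecar(pd.concat(reports, ignore_index=True), out / "auc.csv",
                                {**meta, "stage": "evaluate", "scheme": vars(scheme)})
            artifacts["auc"] = str(out / "auc.csv")

        if "survival" in stages:
            log.info("stage survival")
            blk = config.get("survival", {})
            scale = blk.get("scale", "onset")
            recs = build_survival_records(table, scale)
            covs = blk.get("cox", ["sex", "gba", "apoe4", "onset_age_years"])
            fit = fit_cox_frailty(recs, covs, frailty_var=blk.get("frailty_var"))
            hr = pd.DataFrame({
                "covariate": fit.covariates,
                "coef": fit.params.to_numpy(),
                "hr": fit.hazard_ratios.to_numpy(),
                "se": fit.se.to_numpy(),
                "p": fit.pvalues.to_numpy(),
            })
            _write_with_sidecar(hr, out / "cox.csv",
                                {**meta, "stage": "survival", "scale": scale,
                                 "frailty_var": fit.frailty_var,
                                 "delayed_entry": scale != "months",
                                 "n_excluded_baseline_pdd": recs.attrs["n_excluded_baseline_pdd"]})
            curves = []
            for gcol in blk.get("groups", ["gba", "sex"]):
                for val, sub in recs.groupby(gcol):
                    km = kaplan_meier(sub)
                    km["group"] = f"{gcol}={val}"
                    curves.append(km)
                stat, p = logrank_test(recs, gcol)
                log.info("log-rank %s: chi2=%.3f p=%.4g", gcol, stat, p)
            _write_with_sidecar(pd.concat(curves, ignore_index=True), out / "km_curves.csv",
                                {**meta, "stage": "survival", "scale": scale})
            subgroups = pd.DataFrame([
                {"label": f"sex={s},gba={g}", "sex": s, "gba": g,
                 **{c: recs[c].mean() for c in covs if c not in ("sex", "gba")}}
                for s in (0, 1) for g in (0, 1)
            ])
            cox_curves = survival_curves_by_subgroup(fit, subgroups)
            _write_with_sidecar(cox_curves, out / "cox_curves.csv",
                                {**meta, "stage": "survival", "scale": scale})
            artifacts["cox"] = str(out / "cox.csv")
            artifacts["km_curves"] = str(out / "km_curves.csv")
            artifacts["cox_curves"] = str(out / "cox_curves.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    summary = out / "summary.txt"
    summary.write_text(
        "pdprog pipeline run\n"
        + f"seed: {seed}\nconfig hash: {confhash}\n"
        + "\n".join(f"{k}: {v}" for k, v in artifacts.items())
        + "\n"
    )
    artifacts["summary"] = str(summary)
    return artifacts


def _evaluation_model(name: str, blk: dict):
    bio = ["age_years", "disease_duration_years", "sex", "apoe4", "gba", "mapt_h1",
           "ledd_mg", "gds15", "education_years", "site"]
    from .cohort import TEST_COLUMNS

    if name == "mixed-bio":
        return MixedStatusModel(covariates=bio)
    if name == "mixed-cog":
        return MixedStatusModel(covariates=list(TEST_COLUMNS))
    if name == "tgl":
        theta = blk.get("theta")
        grid = [Hyperparams(**theta)] if theta else None
        return TGLStatusModel(theta_grid=grid, max_iter=int(blk.get("max_iter", 300)))
    raise ValueError(f"unknown evaluation model {name!r}")
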