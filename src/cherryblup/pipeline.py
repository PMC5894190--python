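"""One-command orchestration of the full synthetic study.

simulate (or load) -> curate -> kernels -> fit the full ADI model ->
reduced-model ladder -> heritability table -> breeding/midparent report
-> cross-validation report, with every artifact written as delimited
text and a machine-readable run log carrying the seed.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .genotypes import GenotypeCurator, KernelSet
from .model import ALL_TERMS, KernelGBLUP
from .selection import heritability, ladder_table, model_ladder, variance_table
from .simulate import SimulationScenario, simulate_dataset
from .validation import (
    genetic_summaries, kfold_cv, leave_family_out_cv, leave_year_out_cv,
    midparent_value,
)

__all__ = ["run_pipeline", "default_config"]


def default_config(seed: int = 0, output_dir: str = "cherryblup_run") -> dict:
    return {
        "seed": seed,
        "output_dir": output_dir,
        "scenario": {},          # overrides for SimulationScenario
        "trait": None,
        "model": {"terms": list(ALL_TERMS), "residual": "correlated"},
        "ladder": True,
        "cv": {"k": 5, "repeats": 2, "schemes": ["kfold", "family", "year"]},
    }


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as err:  # halt with stage name and cause
        raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err


def run_pipeline(config: dict) -> dict:
    """Execute the pipeline; returns a dict of artifact paths."""
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    artifacts: dict = {}

    # ---- inputs: simulate or load -------------------------------------
    pedigree = None
    if config.get("genotypes"):
        genotypes = _stage("load_genotypes", cio.read_dosage_csv, config["genotypes"])
        curator = GenotypeCurator()
        genotypes = _stage("curate", curator.fit_transform, genotypes)
        kernels = _stage("kernels", KernelSet.from_genotypes, genotypes)
        artifacts["kernels"] = {
            k: str(v) for k, v in cio.write_kernels(kernels, out / "kernels").items()
        }
        if not config.get("phenotypes"):
            raise RuntimeError(
                "pipeline stage 'assemble' failed: no phenotype path configured"
            )
        phenotypes = _stage("load_phenotypes", cio.read_phenotypes, config["phenotypes"])
        family_map = (
            _stage("load_families", cio.read_family_map, config["family_map"])
            if config.get("family_map") else {}
        )
        scenario = None
    else:
        scenario = SimulationScenario(**{**config.get("scenario", {}), "seed": seed})
        data = _stage("simulate", simulate_dataset, scenario)
        genotypes, kernels = data.genotypes, data.kernels
        phenotypes, family_map, pedigree = data.phenotypes, data.family_map, data.pedigree
        cio.write_dosage_csv(genotypes, out / "genotypes.csv")
        cio.write_phenotypes(phenotypes, out / "phenotypes.csv")
        cio.write_family_map(family_map, out / "family_map.csv")
        cio.write_truth(data.truth, out / "truth.json")
        artifacts["kernels"] = {
            k: str(v) for k, v in cio.write_kernels(kernels, out / "kernels").items()
        }

    trait = config.get("trait") or sorted(phenotypes["trait"].unique())[0]
    model_cfg = dict(config.get("model", {}))
    model_cfg.setdefault("terms", list(ALL_TERMS))
    proto = KernelGBLUP(**{**model_cfg, "terms": tuple(model_cfg["terms"]), "trait": trait})

    # ---- full fit ------------------------------------------------------
    full_fit = _stage("fit_full", KernelGBLUP(**proto.get_params()).fit, phenotypes, kernels)
    vt = variance_table({trait: full_fit})
    vt.to_csv(out / "variance_components.csv", index=False)
    artifacts["variance_components"] = str(out / "variance_components.csv")

    # ---- ladder --------------------------------------------------------
    if config.get("ladder", True) and set(proto.terms) == set(ALL_TERMS):
        reduced_fits = []
        for spec, _df in model_ladder(full_fit.spec_):
            params = {**proto.get_params(), "terms": spec.terms}
            reduced_fits.append(
                _stage(f"fit_{spec.label()}", KernelGBLUP(**params).fit, phenotypes, kernels)
            )
        lt = _stage("ladder_table", ladder_table, full_fit, reduced_fits)
        lt.to_csv(out / "model_ladder.csv", index=False)
        artifacts["model_ladder"] = str(out / "model_ladder.csv")

    # ---- heritability --------------------------------------------------
    h = heritability(full_fit)
    hrows = [{"trait": trait, "h2": h.h2, "H2": h.H2,
              **{f"pct_{k}": v for k, v in h.percentages.items()}}]
    pd.DataFrame(hrows).to_csv(out / "heritability.csv", index=False)
    artifacts["heritability"] = str(out / "heritability.csv")

    # ---- genetic values and midparent report ---------------------------
    summary = _stage("genetic_values", genetic_summaries, full_fit)
    summary.values.to_csv(out / "genetic_values.csv", index=False)
    artifacts["genetic_values"] = str(out / "genetic_values.csv")
    bv = summary.values.set_index("individual")["breeding_value"]
    mp_rows = []
    if pedigree is not None:
        seen = set()
        for rec in pedigree:
            if rec.is_founder or rec.family_id in seen:
                continue
            seen.add(rec.family_id)
            mp_rows.append(
                {
                    "family": rec.family_id,
                    "parent1": rec.sire_id,
                    "parent2": rec.dam_id,
                    "bv_parent1": bv.get(rec.sire_id, np.nan),
                    "bv_parent2": bv.get(rec.dam_id, np.nan),
                    "midparent_value": midparent_value(
                        bv.get(rec.sire_id, np.nan), bv.get(rec.dam_id, np.nan)
                    ),
                }
            )
    pd.DataFrame(
        mp_rows, columns=["family", "parent1", "parent2",
                          "bv_parent1", "bv_parent2", "midparent_value"]
    ).to_csv(out / "midparent_values.csv", index=False)
    artifacts["midparent_values"] = str(out / "midparent_values.csv")

    # ---- cross-validation ----------------------------------------------
    cv_cfg = config.get("cv") or {}
    schemes = cv_cfg.get("schemes", ["kfold"])
    cv_rows = []
    if "kfold" in schemes:
        res = _stage(
            "cv_kfold", kfold_cv, phenotypes, kernels, proto,
            cv_cfg.get("k", 5), cv_cfg.get("repeats", 2), seed, trait,
        )
        cv_rows.append({"scheme": res.scheme, "mean_accuracy": res.mean_accuracy,
                        "sd_accuracy": float(np.std(res.accuracies))})
    if "family" in schemes and family_map:
        res = _stage("cv_family", leave_family_out_cv, phenotypes, kernels,
                     family_map, proto, trait)
        cv_rows.append({"scheme": res.scheme, "mean_accuracy": res.mean_accuracy,
                        "sd_accuracy": float(np.nanstd(res.fold_accuracies[0]))})
    if "year" in schemes and phenotypes["year"].nunique() > 1:
        res = _stage("cv_year", leave_year_out_cv, phenotypes, kernels, proto, trait)
        cv_rows.append({"scheme": res.scheme, "mean_accuracy": res.mean_accuracy,
                        "sd_accuracy": float(np.nanstd(res.fold_accuracies[0]))})
    pd.DataFrame(cv_rows, columns=["scheme", "mean_accuracy", "sd_accuracy"]).to_csv(
        out / "cv_report.csv", index=False
    )
    artifacts["cv_report"] = str(out / "cv_report.csv")

    # ---- run log -------------------------------------------------------
    log = {
        "seed": seed,
        "trait": trait,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scenario": dataclasses.asdict(scenario) if scenario is not None else None,
        "model": {**model_cfg, "terms": list(proto.terms)},
        "converged": bool(full_fit.converged_),
        "loglik": full_fit.loglik_,
        "artifacts": {k: v for k, v in artifacts.items()},
    }

    def _jsonable(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=_jsonable))
    artifacts["run_log"] = str(out / "run_log.json")
    return artifacts
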