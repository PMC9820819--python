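"""End-to-end orchestration: simulate/load a cohort, run the correlation
screen, the factor models, and the redescription miner, and render the
outputs as plain delimited text + JSON with a run manifest.

Rounding conventions in rendered tables: correlation coefficients to 3
decimals, Jaccard indices to 5, percentages to 1.  Every number in a
rendered table is re-derivable from the stage outputs — rendering only
formats, it never computes.  The manifest records the master seed, the
per-stage derived seeds, parameters, package version and row counts, and
contains no timestamps, so identical configs produce byte-identical
bundles.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import views as V
from .cohort import (CohortConfig, CohortDataset, config_from_yaml,
                     generate_cohort, read_cohort, write_cohort)
from .factors import fit_factors, regress_on_factors, regressions_to_frame
from .mining import MinerParams, count_cooccurrence, default_params, mine
from .screen import DEFAULT_COVARIATES, adjust, records_to_frame, screen


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "out"
    seed: int = 0
    cohort_path: str | None = None       # load instead of simulating
    cohort: CohortConfig = field(default_factory=CohortConfig)
    gate: float = 0.001
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    n_factors: int = 6
    loading_threshold: float = 0.4
    mining_views: tuple[tuple[str, ...], ...] = (
        ("csf_biomarkers", "csf_elements"),
        ("csf_biomarkers", "plasma_elements"),
        ("csf_biomarkers", "csf_elements", "plasma_elements"),
    )
    miner_overrides: dict = field(default_factory=dict)
    run_screen: bool = True
    run_factors: bool = True
    run_mining: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        if "mining_views" in d:
            d["mining_views"] = tuple(tuple(v) for v in d["mining_views"])
        if "covariates" in d:
            d["covariates"] = tuple(d["covariates"])
        return cls(**d)


def _json_dump(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _derive_seed(master: int, stage: str) -> int:
    # stable per-stage stream below 2**31
    h = np.random.SeedSequence(
        [master, sum(ord(c) for c in stage), len(stage)])
    return int(h.generate_state(1)[0] % (2 ** 31))


def _mining_tag(views: tuple[str, ...]) -> str:
    if len(views) == 3:
        return "tripple"
    return "pair1" if "csf_elements" in views else "pair2"


def summary_table(redescriptions, views) -> pd.DataFrame:
    """Rendered summary mirroring the reported redescription tables:
    label, per-diagnosis percentages, one rule column per view, JS, p."""
    rows = []
    for rd in redescriptions:
        row = {
            "label": rd.specificity_label,
            "HC_pct": round(rd.per_diagnosis_pct.get("HC", 0.0), 1),
            "MCI_pct": round(rd.per_diagnosis_pct.get("MCI", 0.0), 1),
            "AD_pct": round(rd.per_diagnosis_pct.get("AD", 0.0), 1),
        }
        for i, q in enumerate(rd.queries, start=1):
            row[f"W{i}R"] = q.text()
        row["JS"] = round(rd.jaccard, 5)
        row["p_value"] = float(f"{rd.p_value:.4g}")
        rows.append(row)
    cols = (["label", "HC_pct", "MCI_pct", "AD_pct"]
            + [f"W{i}R" for i in range(1, len(views) + 1)] + ["JS", "p_value"])
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dict (also written
    to ``out_dir/manifest.json``)."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": {},
        "outputs": [],
        "skipped": [],
        "row_counts": {},
        "parameters": {
            "gate": config.gate,
            "n_factors": config.n_factors,
            "loading_threshold": config.loading_threshold,
            "covariates": list(config.covariates),
            "miner_overrides": dict(config.miner_overrides),
        },
    }

    def emit(name):
        manifest["outputs"].append(name)
        return os.path.join(config.out_dir, name)

    # --- cohort ---------------------------------------------------------
    try:
        if config.cohort_path:
            dataset = read_cohort(config.cohort_path)
        else:
            cohort_cfg = dataclasses.replace(
                config.cohort, seed=_derive_seed(config.seed, "cohort"))
            manifest["stage_seeds"]["cohort"] = cohort_cfg.seed
            dataset = generate_cohort(cohort_cfg)
            write_cohort(dataset, emit("cohort.csv"))
            manifest["outputs"].append("cohort.csv.views.yaml")
    except Exception as err:
        raise PipelineError("cohort", err) from err
    manifest["row_counts"]["cohort"] = dataset.n
    manifest["row_counts"]["diagnosis"] = {
        dx: int((dataset.data["diagnosis"] == dx).sum())
        for dx in dataset.categorical_levels["diagnosis"]}

    # --- correlation screen ---------------------------------------------
    if config.run_screen:
        try:
            records = screen(dataset, gate=config.gate)
            for rec in records:
                if rec.passes_gate:
                    adjust(rec, dataset, config.covariates, gate=config.gate)
            frame = records_to_frame(records)
            for col in ("r", "r_pearson", "r_partial"):
                frame[col] = frame[col].round(3)
            frame.to_csv(emit("correlations.csv"), index=False)
            manifest["row_counts"]["correlations"] = len(records)
            manifest["row_counts"]["gate_passing"] = int(
                sum(r.passes_gate for r in records))
        except Exception as err:
            raise PipelineError("screen", err) from err
    else:
        manifest["skipped"].append("screen")

    # --- factor models ---------------------------------------------------
    if config.run_factors:
        try:
            regs = []
            for view, tag in (("csf_elements", "csf"),
                              ("plasma_elements", "plasma")):
                sol = fit_factors(dataset, view, n_factors=config.n_factors,
                                  threshold=config.loading_threshold)
                _json_dump(sol.to_dict(), emit(f"factors_{tag}.json"))
                manifest["row_counts"][f"factor_scores_{tag}"] = len(sol.scores)
                for bm in dataset.view_columns["csf_biomarkers"]:
                    try:
                        regs.extend(regress_on_factors(dataset, sol, bm))
                    except ValueError:
                        continue
            rframe = regressions_to_frame(regs)
            rframe.to_csv(emit("factor_regressions.csv"), index=False)
            manifest["row_counts"]["factor_regressions"] = len(rframe)
        except Exception as err:
            raise PipelineError("factors", err) from err
    else:
        manifest["skipped"].append("factors")

    # --- redescription mining -------------------------------------------
    if config.run_mining:
        try:
            all_rds = []
            for views in config.mining_views:
                tag = _mining_tag(views)
                params = default_params(
                    views, seed=_derive_seed(config.seed, f"mine:{tag}"))
                for k, v in config.miner_overrides.items():
                    setattr(params, k, v)
                manifest["stage_seeds"][f"mine:{tag}"] = params.seed
                rds = mine(dataset, views, params)
                all_rds.extend(rds)
                _json_dump([rd.to_dict() for rd in rds],
                           emit(f"redescriptions_{tag}.json"))
                summary_table(rds, views).to_csv(
                    emit(f"redescriptions_{tag}.tsv"), sep="\t", index=False)
                manifest["row_counts"][f"redescriptions_{tag}"] = len(rds)
            co_rows = []
            bios = dataset.view_columns["csf_biomarkers"]
            elements = (dataset.view_columns["csf_elements"]
                        + dataset.view_columns["plasma_elements"])
            for bm in bios:
                for el in elements:
                    c = count_cooccurrence(all_rds, bm, el)
                    if c:
                        co_rows.append({"biomarker": bm, "element": el,
                                        "count": c})
            pd.DataFrame(co_rows, columns=["biomarker", "element", "count"]
                         ).to_csv(emit("cooccurrence_counts.csv"), index=False)
        except Exception as err:
            raise PipelineError("mining", err) from err
    else:
        manifest["skipped"].append("mining")

    _json_dump(manifest, os.path.join(config.out_dir, "manifest.json"))
    return manifest
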