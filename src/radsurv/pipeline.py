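"""End-to-end pipeline orchestration.

Stages: simulate (or ingest) -> extract -> cluster -> select -> fit ->
evaluate. Each stage persists its outputs under the run directory so any
stage can be re-run from its predecessor's files, and a manifest records
the configuration hash and derived seeds: re-running the same
configuration reproduces every numeric output bit-identically (for that
reason the run directory is named by config hash, not by timestamp).

Per run, one model is fitted per endpoint and per feature source (tumor
vs. node features): 8 models for the four default endpoints.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .clustering import (apply_preparation, apply_reduction, fit_preparation,
                         iterative_reduce, max_offdiag_abs_spearman,
                         plot_correlation_heatmap, spearman_matrix)
from .errors import ConfigurationError
from .evaluation import evaluate_endpoint
from .modeling import DEFAULT_GRID, fit_rsf, predict_risk, tune_rsf
from .selection import bootstrap_select, take_top
from .synthetic import (ENDPOINTS, CohortSpec, cohort_feature_table,
                        cohort_outcomes, generate_cohort, split_cohort,
                        write_cohort)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("radsurv")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the study defaults."""

    mode: str = "synthetic"  # "synthetic" | "files"
    data_dir: str | None = None  # cohort directory in files mode
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides in synthetic mode
    n_levels: int = 64
    cluster_threshold: float = 0.90
    n_boot: int = 100
    top_k: int = 10
    train_fraction: float = 2.0 / 3.0
    endpoints: tuple[str, ...] = ENDPOINTS
    horizon_months: float = 36.0
    rsf_n_estimators: int = 1000
    rsf_grid: dict | None = None
    cv_folds: int = 5
    penalties: tuple[str, ...] = ("ridge", "lasso", "elastic_net")
    seed: int = 0
    out_dir: str = "runs"
    save_figures: bool = False
    write_images: bool = False  # persist NIfTI volumes of a synthetic cohort

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigurationError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        if not 0.0 < self.cluster_threshold < 1.0:
            raise ConfigurationError(
                f"cluster_threshold must be in (0, 1), got {self.cluster_threshold}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.n_levels < 2 or self.n_boot < 1 or self.top_k < 1:
            raise ConfigurationError("n_levels, n_boot and top_k must be positive")
        if self.horizon_months <= 0:
            raise ConfigurationError("horizon_months must be positive")
        if self.mode == "files" and not self.data_dir:
            raise ConfigurationError("files mode requires data_dir")
        unknown = set(self.endpoints) - set(ENDPOINTS)
        if unknown:
            raise ConfigurationError(f"unknown endpoints: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "endpoints" in raw:
            raw["endpoints"] = tuple(raw["endpoints"])
        if "penalties" in raw:
            raw["penalties"] = tuple(raw["penalties"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _derived_seeds(master: int) -> dict[str, int]:
    """Named child seeds for each stage, all below 2**31."""
    state = np.random.SeedSequence(master).generate_state(4)
    names = ("cohort", "split", "selection", "model")
    return {n: int(s % (2**31 - 1)) for n, s in zip(names, state)}


def _load_file_cohort(data_dir: Path):
    outcomes = rio.read_outcomes(data_dir / "outcomes.csv")
    ids = sorted(outcomes["patient_id"].unique())
    patients = []
    for pid in ids:
        volumes = {}
        for seq in rio.SEQUENCES:
            p = data_dir / f"{pid}_{seq}.nii.gz"
            if p.exists():
                volumes[seq] = rio.read_volume(p, seq)
        masks = {}
        for structure in rio.STRUCTURES:
            p = data_dir / f"{pid}_{structure}_mask.nii.gz"
            if p.exists():
                masks[structure] = rio.read_mask(p, structure)
        if not volumes or not masks:
            raise ConfigurationError(f"no volumes/masks found for patient {pid} in {data_dir}")
        for vol in volumes.values():
            for name, mask in masks.items():
                rio.check_geometry(vol, mask, volume_name=f"{pid} volume",
                                   mask_name=f"{pid} {name} mask")
        patients.append((pid, volumes, masks))
    return patients, outcomes


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the evaluation reports and run paths."""
    seeds = _derived_seeds(config.seed)
    run_dir = Path(config.out_dir) / f"run_{config.config_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)
    t0 = _time.time()
    stage = "simulate"
    try:
        # --- stage 1: cohort -------------------------------------------------
        if config.mode == "synthetic":
            spec = CohortSpec(**{"seed": seeds["cohort"], **config.cohort})
            patients = generate_cohort(spec)
            outcomes = cohort_outcomes(patients)
            if config.write_images:
                write_cohort(patients, run_dir / "cohort")
            else:
                rio.write_outcomes(outcomes, run_dir / "outcomes.csv")
            log.info("simulate: %d patients", len(patients))
            stage = "extract"
            table = cohort_feature_table(patients, config.n_levels)
        else:
            loaded, outcomes = _load_file_cohort(Path(config.data_dir))
            stage = "extract"
            from .features import extract_all
            rows = {}
            for pid, volumes, masks in loaded:
                per_structure = extract_all(volumes, masks, config.n_levels)
                rows[pid] = {f"{s}_{k}": v for s in sorted(per_structure)
                             for k, v in per_structure[s].items()}
            table = pd.DataFrame.from_dict(rows, orient="index")
            table.index.name = "patient_id"

        rio.write_feature_table(table, run_dir / "features.csv")
        with open(run_dir / "extraction_manifest.json", "w") as fh:
            json.dump({"n_levels": config.n_levels, "ngldm_epsilon": 1e-6,
                       "n_features": table.shape[1], "catalogue": "v1"}, fh, indent=1)
        log.info("extract: %d x %d feature table", *table.shape)

        # --- stage 2: split --------------------------------------------------
        stage = "split"
        ids = list(table.index)
        train_ids, val_ids = split_cohort(ids, config.train_fraction, seeds["split"])
        json.dump({"train": train_ids, "validation": val_ids},
                  open(run_dir / "split.json", "w"), indent=1)

        structures = sorted({c.split("_", 1)[0] for c in table.columns})
        reports: dict[str, dict] = {}
        reduced_tables: dict[str, dict[str, pd.DataFrame]] = {}

        # --- stage 3: cluster (fit on training only) -------------------------
        stage = "cluster"
        for structure in structures:
            cols = [c for c in table.columns if c.startswith(f"{structure}_")]
            train_tab = table.loc[train_ids, cols]
            prep = fit_preparation(train_tab)
            train_clean = apply_preparation(train_tab, prep)
            val_clean = apply_preparation(table.loc[val_ids, cols], prep)
            corr = spearman_matrix(train_clean)
            corr.to_csv(run_dir / f"spearman_{structure}.csv")
            red_train, cmaps = iterative_reduce(train_clean, config.cluster_threshold)
            json.dump({"passes": [c.to_dict() for c in cmaps]},
                      open(run_dir / f"clusters_{structure}.json", "w"), indent=1)
            red_val = apply_reduction(val_clean, cmaps)
            reduced_tables[structure] = {"train": red_train, "val": red_val}
            red_train.to_csv(run_dir / f"reduced_{structure}_train.csv")
            red_val.to_csv(run_dir / f"reduced_{structure}_validation.csv")
            if config.save_figures:
                plot_correlation_heatmap(corr, run_dir / f"spearman_{structure}.png")
                plot_correlation_heatmap(spearman_matrix(red_train),
                                         run_dir / f"spearman_{structure}_reduced.png")
            audit = max_offdiag_abs_spearman(red_train)
            log.info("cluster[%s]: %d -> %d features (max |SC| %.3f)",
                     structure, len(cols), red_train.shape[1], audit)

        # --- stages 4-6: select, fit, evaluate per (structure, endpoint) -----
        risk_rows = []
        for structure in structures:
            red_train = reduced_tables[structure]["train"]
            red_val = reduced_tables[structure]["val"]
            for endpoint in config.endpoints:
                stage = f"select[{structure}/{endpoint}]"
                out_ep = outcomes[outcomes["endpoint"] == endpoint]
                train_out = out_ep[out_ep["patient_id"].isin(train_ids)]
                val_out = out_ep[out_ep["patient_id"].isin(val_ids)]
                ranked = bootstrap_select(
                    red_train, train_out, n_boot=config.n_boot,
                    top_k=min(config.top_k, red_train.shape[1]),
                    seed=seeds["selection"], penalties=config.penalties,
                    cv_folds=config.cv_folds)
                selected = take_top(ranked, min(config.top_k, len(ranked.features)))
                json.dump({"selected": selected, "scores": ranked.scores,
                           "frequencies": ranked.frequencies,
                           "provenance": ranked.provenance},
                          open(run_dir / f"selection_{structure}_{endpoint}.json", "w"),
                          indent=1)

                stage = f"fit[{structure}/{endpoint}]"
                grid = config.rsf_grid if config.rsf_grid is not None else DEFAULT_GRID
                best, score_tab = tune_rsf(
                    red_train[selected], train_out, grid=grid,
                    n_folds=config.cv_folds, seed=seeds["model"],
                    n_estimators=config.rsf_n_estimators)
                score_tab.to_csv(run_dir / f"tuning_{structure}_{endpoint}.csv", index=False)
                model = fit_rsf(red_train[selected], train_out, best,
                                seed=seeds["model"], endpoint=endpoint,
                                n_estimators=config.rsf_n_estimators)
                json.dump(model.manifest(),
                          open(run_dir / f"model_{structure}_{endpoint}.json", "w"),
                          indent=1)
                risk_train = predict_risk(model, red_train)
                risk_val = predict_risk(model, red_val)
                for split_name, series in (("train", risk_train), ("validation", risk_val)):
                    for pid, val in series.items():
                        risk_rows.append({"patient_id": pid, "endpoint": endpoint,
                                          "structure": structure, "split": split_name,
                                          "risk": float(val)})

                stage = f"evaluate[{structure}/{endpoint}]"
                tr = train_out.set_index("patient_id").loc[list(red_train.index)]
                va = val_out.set_index("patient_id").loc[list(red_val.index)]
                report = evaluate_endpoint(
                    risk_train.values, tr["time_months"].values, tr["event"].values,
                    risk_val.values, va["time_months"].values, va["event"].values,
                    horizon=config.horizon_months)
                report["selected_features"] = selected
                report["hyperparameters"] = {k: v for k, v in best.items()}
                reports[f"{structure}_{endpoint}"] = report
                log.info("evaluate[%s/%s]: validation C-index %.3f",
                         structure, endpoint, report["cindex_validation"])

        pd.DataFrame(risk_rows).to_csv(run_dir / "predicted_risks.csv", index=False)
        with open(run_dir / "reports.json", "w") as fh:
            json.dump(reports, fh, indent=1, default=float)

        manifest = {
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "derived_seeds": seeds,
            "n_patients": len(ids),
            "n_train": len(train_ids),
            "n_validation": len(val_ids),
            "models": sorted(reports),
            "version": "0.1.0",
        }
        with open(run_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    except ConfigurationError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    log.info("pipeline finished in %.1f s", _time.time() - t0)
    return {"run_dir": str(run_dir), "reports": reports, "manifest": manifest}
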