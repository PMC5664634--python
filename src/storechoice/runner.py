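"""End-to-end pipeline driver.

``run_pipeline`` executes simulate (or load) -> distances -> clusters ->
choice sets -> long-trip filter -> design -> fit -> evaluate, writing every
intermediate table plus a manifest with per-stage row counts, so that the
sample accounting of a run (generated -> screened -> estimated) is explicit
and any stage can be re-run from its persisted inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .clogit import ModelSpec, build_design, fit_clogit
from .errors import ConfigurationError, StoreChoiceError
from .evaluation import success_rates
from .io import read_shoppers, read_stores, write_table
from .pipeline import build_choice_sets, build_clusters, compute_distances, filter_long_trips
from .synthetic import SimConfig, TrueParams, generate_shoppers, generate_stores, simulate_choices

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("storechoice")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for a full pipeline run.

    Either ``shoppers_path``/``stores_path`` point at existing tables (with
    chosen stores filled in), or a ``sim`` block describes a synthetic run;
    ``true_params`` applies only when simulating.
    """

    out_dir: str = "storechoice_run"
    shoppers_path: str | None = None
    stores_path: str | None = None
    sim: SimConfig | None = None
    true_params: TrueParams | None = None
    screen_miles: float = 10.0
    ratio: float = 2.0
    single_pass: bool = False
    rebuild_choice_sets: bool = True
    max_separation_miles: float | None = None
    circuity_factor: float = 1.3
    spec: ModelSpec = field(default_factory=ModelSpec)
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        have_paths = self.shoppers_path is not None and self.stores_path is not None
        if not have_paths and self.sim is None:
            raise ConfigurationError("either shoppers_path/stores_path or a sim block is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {k: v for k, v in raw.items() if k not in ("sim", "spec", "true_params")}
        if "sim" in raw and raw["sim"] is not None:
            kwargs["sim"] = SimConfig.from_dict(raw["sim"])
        if "spec" in raw and raw["spec"] is not None:
            spec_raw = dict(raw["spec"])
            for key in ("store_attrs", "dist_attrs", "indiv_attrs"):
                if key in spec_raw:
                    spec_raw[key] = tuple(spec_raw[key])
            kwargs["spec"] = ModelSpec(**spec_raw)
        if "true_params" in raw and raw["true_params"] is not None:
            tp = raw["true_params"]
            kwargs["true_params"] = TrueParams(
                beta_main=dict(tp.get("beta_main", {})),
                theta_main=float(tp.get("theta_main", 0.0)),
                beta_inter={tuple(k.split(":")): v for k, v in tp.get("beta_inter", {}).items()},
                theta_inter=dict(tp.get("theta_inter", {})),
            )
        return cls(**kwargs)


def _config_echo(config: PipelineConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Mapping):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return clean(config)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full pipeline; returns the artifact directory.

    On a stage failure a ``FAILED`` marker naming the stage is written next
    to whatever partial outputs exist, and the error is re-raised.
    """
    logging.basicConfig(level=config.log_level, format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_echo(config),
        "versions": {
            "storechoice": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "stages": {},
    }
    stage = "init"
    try:
        stage = "input"
        if config.sim is not None:
            sim = config.sim if config.seed is None else dataclasses.replace(config.sim, seed=config.seed)
            manifest["seed"] = sim.seed
            stores = generate_stores(sim)
            shoppers = generate_shoppers(sim)
            params = config.true_params or TrueParams.reference()
            shoppers = simulate_choices(shoppers, stores, params, sim)
            circuity = sim.circuity_factor
        else:
            shoppers = read_shoppers(config.shoppers_path)
            stores = read_stores(config.stores_path)
            circuity = config.circuity_factor
            manifest["seed"] = config.seed
        log.info("input: %d shoppers, %d stores", len(shoppers), len(stores))
        manifest["stages"]["input"] = {"n_shoppers": len(shoppers), "n_stores": len(stores)}
        write_table(shoppers, out / "shoppers.csv")
        write_table(stores, out / "stores.csv")

        stage = "distances"
        distances = compute_distances(shoppers, stores, circuity)
        trips = distances.trip_distances(shoppers)
        write_table(
            pd.DataFrame({"shopper_id": trips.index, "trip_miles": trips.to_numpy()}),
            out / "trips.csv",
        )
        manifest["stages"]["distances"] = {"median_trip_miles": float(trips.median())}
        log.info("distances: median trip %.2f miles", trips.median())

        stage = "clusters"
        clusters = build_clusters(shoppers, config.max_separation_miles)
        manifest["stages"]["clusters"] = {"n_clusters": clusters.n_clusters}
        log.info("clusters: %d shopping clusters", clusters.n_clusters)

        stage = "choice_sets"
        sets = build_choice_sets(clusters, shoppers)
        manifest["stages"]["choice_sets"] = {"n_records": len(sets.frame)}
        log.info("choice sets: %d stacked records", len(sets.frame))

        stage = "filter"
        survivors, removals = filter_long_trips(
            shoppers, clusters, distances, config.screen_miles, config.ratio, config.single_pass
        )
        n_removed = int((removals["action"] == "removed").sum()) if len(removals) else 0
        write_table(removals, out / "removals.csv")
        manifest["stages"]["filter"] = {"n_removed": n_removed, "n_survivors": len(survivors)}
        log.info("filter: %d -> %d shoppers (%d removed)", len(shoppers), len(survivors), n_removed)

        stage = "rebuild"
        if config.rebuild_choice_sets:
            clusters = build_clusters(survivors, config.max_separation_miles)
            sets = build_choice_sets(clusters, survivors)
        else:
            keep = sets.frame["shopper_id"].isin(survivors["shopper_id"])
            sets = type(sets)(frame=sets.frame.loc[keep].reset_index(drop=True))
        write_table(clusters.frame, out / "clusters.csv")
        write_table(sets.frame, out / "choice_sets.csv")
        write_table(clusters.summaries(survivors), out / "cluster_summaries.csv")
        manifest["stages"]["rebuild"] = {
            "n_clusters": clusters.n_clusters,
            "n_records": len(sets.frame),
        }

        stage = "fit"
        data = build_design(survivors, stores, sets, distances, config.spec)
        fit = fit_clogit(data, config.spec)
        write_table(fit.summary(), out / "fit.csv")
        manifest["stages"]["fit"] = {
            "loglik": fit.loglik,
            "loglik_null": fit.loglik_null,
            "converged": fit.converged,
            "n_iter": fit.n_iter,
            "n_shoppers": fit.n_shoppers,
            "n_params": fit.n_params,
        }
        log.info("fit: loglik %.2f (null %.2f), converged=%s", fit.loglik, fit.loglik_null, fit.converged)

        stage = "evaluate"
        report = success_rates(fit, data)
        write_table(report.to_frame(), out / "success.csv")
        manifest["stages"]["evaluate"] = {
            "success_rate": report.success_rate,
            "model_success_rate": report.model_success_rate,
            "random_success_rate": report.random_success_rate,
        }
        log.info(
            "evaluate: success %.2f%% / model %.2f%% / random %.2f%%",
            100 * report.success_rate,
            100 * report.model_success_rate,
            100 * report.random_success_rate,
        )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n", encoding="utf-8")
        if isinstance(exc, StoreChoiceError):
            raise type(exc)(f"[stage {stage}] {exc}") from exc
        raise

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
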