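"""End-to-end pipeline: simulate -> EQI -> fit -> evaluate -> report.

Every stage writes plain CSV/JSON artifacts stamped with the run seed, the
config hash, and the package version, so a report bundle is reproducible
from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .eqi import EQI_DOMAINS, compute_eqi, write_eqi_table
from .evaluation import (effect_curve, effect_curve_frame, partition_of,
                         rank_models, waic_of)
from .inference import McmcConfig, PosteriorDraws, convergence_report, fit
from .models import MODEL_NAMES, PriorSpec, get_model_spec
from .pedigree import Cohort, prevalence, read_cohort, write_cohort
from .simulate import TruthConfig, simulate_cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    models: tuple = ("LM0", "LM1", "IM1", "LM2", "IM2")
    cohort_path: str | None = None     # None -> simulate
    eqi_path: str | None = None
    case_rule: str = "at_least_2"
    truth: TruthConfig | None = None
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self):
        unknown = [m for m in self.models if m not in MODEL_NAMES]
        if unknown:
            raise ValueError(f"unknown model name(s) {unknown}; choose from {MODEL_NAMES}")

    def config_hash(self) -> str:
        payload = yaml.safe_dump(_as_plain(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """One-row-per-quantity cohort summary (counts, prevalence per role,
    children-per-family histogram)."""
    df = cohort.df
    rows = [
        ("n_families", cohort.n_families),
        ("n_individuals", cohort.n_individuals),
        ("n_cases", cohort.n_cases),
        ("prevalence_pct", prevalence(cohort.n_individuals, cohort.n_cases)),
    ]
    for role in ("father", "mother", "child"):
        sub = df[df["role"] == role]
        rows.append((f"prevalence_pct_{role}",
                     prevalence(len(sub), int(sub["case"].sum())) if len(sub) else 0.0))
    kids = df[df["role"] == "child"].groupby("family_id").size()
    for k, cnt in kids.value_counts().sort_index().items():
        rows.append((f"families_with_{k}_children", int(cnt)))
    return pd.DataFrame(rows, columns=["quantity", "value"]).set_index("quantity")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns the manifest dictionary.

    A stage failure raises after earlier stages' outputs are already on
    disk, and the manifest names the completed stages.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": _as_plain(config),
        "stages_completed": [],
        "waic_likelihood": "conditional (shared latents in, individual noise out)",
    }

    def checkpoint():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    stage = "simulate/load"
    try:
        if config.cohort_path is None:
            truth = config.truth or TruthConfig(seed=config.seed)
            if truth.seed != config.seed:
                truth = dataclasses.replace(truth, seed=config.seed)
            cohort, eqi_table, meta = simulate_cohort(truth)
            write_cohort(cohort, out / "cohort.csv")
            write_eqi_table(eqi_table, out / "eqi.csv")
            manifest["simulation"] = meta
        else:
            cohort = read_cohort(config.cohort_path, case_rule=config.case_rule)
            from .eqi import read_eqi_table
            eqi_table = read_eqi_table(config.eqi_path)
        summarize_cohort(cohort).to_csv(out / "cohort_summary.csv")
        manifest["stages_completed"].append(stage)
        checkpoint()

        stage = "fit"
        fits: dict[str, PosteriorDraws] = {}
        for name in config.models:
            spec = get_model_spec(name)
            cfg = dataclasses.replace(config.mcmc, seed=config.seed)
            draws = fit(cohort, eqi_table, spec, config.priors, cfg)
            fits[name] = draws
            partition_of(draws).to_csv(out / f"variance_partition_{name}.csv")
            convergence_report(draws).table.to_csv(out / f"convergence_{name}.csv")
        manifest["stages_completed"].append(stage)
        checkpoint()

        stage = "evaluate"
        results = {name: waic_of(d) for name, d in fits.items()}
        order = rank_models(results) if len(results) > 1 else list(results)
        comparison = pd.DataFrame(
            [(nm, results[nm].waic, results[nm].lppd, results[nm].p_waic,
              order.index(nm) + 1) for nm in config.models],
            columns=["model", "waic", "lppd", "p_waic", "rank"],
        ).set_index("model")
        comparison.to_csv(out / "model_comparison.csv")
        manifest["waic_ranking"] = order
        for name, draws in fits.items():
            if draws.spline is not None:
                for dom in EQI_DOMAINS:
                    frame = effect_curve_frame(effect_curve(draws, dom))
                    frame.to_csv(out / f"effect_curve_{name}_{dom}.csv", index=False)
        manifest["stages_completed"].append(stage)
        checkpoint()
    except Exception:
        manifest["failed_stage"] = stage
        checkpoint()
        log.exception("pipeline failed at stage %r", stage)
        raise

    checkpoint()
    return manifest
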