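"""Pipeline assembly: run every stage on a dataset and write the report bundle.

``run_pipeline`` produces six plot-ready CSV tables plus a JSON run manifest:

* ``summary_ml.csv``       — per-cell n/mean/sd/median with the maximum limit
  and the Wilcoxon exceedance flag (survey-table style);
* ``factors.csv``          — BCF and BSAF profiles per sector and element;
* ``correlations.csv``     — Spearman rho/p long table across matrix-element
  pairs;
* ``hazard.csv``           — THQ per element and HI per sector;
* ``cancer_risk.csv``      — EDI, EWI, CR per carcinogen, TCR and its
  classification, under both cancer-risk scale modes;
* ``mc_exceedance.csv``    — Monte Carlo threshold sweep per sector and mode.

Numeric CSVs are written at full precision; the manifest records the config
snapshot, input digest, seeds and package version so a bundle can be
regenerated exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .bioaccumulation import factor_profile, factors_summary_frame
from .data import (
    Matrix,
    lookup_guideline,
    read_concentrations,
    summarize,
)
from .errors import TroutRiskError
from .montecarlo import DistributionSpec, MCConfig, simulate_tcr, threshold_sweep
from .risk import CR_MODES, ExposureParams, ToxicityParams, assess_sector, risk_table
from .stats import spearman_matrix, wilcoxon_vs_limit
from .synthetic import GeneratorConfig, generate

__all__ = ["PipelineError", "run_pipeline", "build_params"]

log = logging.getLogger("troutrisk")

DEFAULT_THRESHOLDS = (1e-6, 1e-5, 1e-4)


class PipelineError(TroutRiskError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


def build_params(
    config: Mapping[str, Any] | None,
) -> tuple[ExposureParams, ToxicityParams, dict[str, Any], dict[str, Any]]:
    """Materialise parameter registries from a nested config mapping.

    Recognised sections: ``exposure`` (ExposureParams fields), ``toxicity``
    (``rfd``/``csf`` per-element overrides), ``mc`` (n_draws, threshold,
    thresholds, confidence, family, cr_mode), ``generator`` (family,
    n_replicates).
    """
    config = dict(config or {})
    exposure = ExposureParams(**config.get("exposure", {}))
    tox_cfg = config.get("toxicity", {})
    toxicity = ToxicityParams()
    toxicity.rfd.update(tox_cfg.get("rfd", {}))
    toxicity.csf.update(tox_cfg.get("csf", {}))
    mc_cfg = {
        "n_draws": 10_000,
        "threshold": 1e-4,
        "confidence": 0.95,
        "family": "lognormal",
        "cr_mode": "as_printed",
        "thresholds": list(DEFAULT_THRESHOLDS),
        **config.get("mc", {}),
    }
    gen_cfg = {"family": "lognormal", "n_replicates": 12, **config.get("generator", {})}
    return exposure, toxicity, mc_cfg, gen_cfg


def _summary_with_limits(dataset: pd.DataFrame) -> pd.DataFrame:
    summary = summarize(dataset)
    rows = []
    for _, row in summary.iterrows():
        matrix = Matrix(row["matrix"])
        g = lookup_guideline(matrix, row["element"])
        cell = dataset[
            (dataset["sector"] == row["sector"])
            & (dataset["matrix"] == row["matrix"])
            & (dataset["element"] == row["element"])
        ]["concentration"]
        try:
            test = wilcoxon_vs_limit(cell.to_numpy(), g.value, alternative="greater")
            p, flag = test.p_value, test.significant
        except TroutRiskError:  # all values exactly at the limit
            p, flag = float("nan"), False
        rows.append(
            {
                **row,
                "units": matrix.units,
                "ml": g.value,
                "ml_source": g.source,
                "wilcoxon_p_greater": p,
                "exceeds_ml": flag,
            }
        )
    return pd.DataFrame(rows)


def _risk_tables(
    dataset: pd.DataFrame, exposure: ExposureParams, toxicity: ToxicityParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    muscle = dataset[dataset["matrix"] == Matrix.MUSCLE.value]
    means = (
        muscle.groupby(["sector", "element"], observed=True)["concentration"].mean().unstack()
    )
    hazard_rows, cancer_rows = [], []
    for sector in means.index:
        mc_by_element = means.loc[sector].to_dict()
        for mode in CR_MODES:
            res = assess_sector(sector, mc_by_element, exposure, toxicity, cr_mode=mode)
            if mode == CR_MODES[0]:
                hazard_rows.append(res)
            row: dict[str, Any] = {"sector": sector, "cr_mode": mode}
            for e in sorted(res.cr):
                row[f"EDI-{e}"] = res.edi[e]
                row[f"EWI-{e}"] = res.ewi[e]
                row[f"CR-{e}"] = res.cr[e]
            row["TCR"] = res.tcr
            row["TCR_class"] = res.tcr_class
            cancer_rows.append(row)
            log.info("sector %s, cancer-risk mode %s: TCR = %.6g (%s)",
                     sector, mode, res.tcr, res.tcr_class)
    tbl = risk_table(hazard_rows)
    hazard = tbl.drop(
        columns=[c for c in tbl.columns if c.startswith("CR-")] + ["TCR", "TCR_class", "cr_mode"]
    )
    return hazard, pd.DataFrame(cancer_rows)


def _mc_table(
    dataset: pd.DataFrame,
    exposure: ExposureParams,
    toxicity: ToxicityParams,
    mc_cfg: Mapping[str, Any],
    seed: int,
) -> pd.DataFrame:
    muscle = dataset[dataset["matrix"] == Matrix.MUSCLE.value]
    stats_ = (
        muscle.groupby(["sector", "element"], observed=True)["concentration"]
        .agg(["mean", "std"])
        .reset_index()
    )
    frames = []
    for si, (sector, sub) in enumerate(stats_.groupby("sector", sort=True)):
        specs = {
            r["element"]: DistributionSpec(
                element=r["element"],
                family=mc_cfg["family"],
                mean=float(r["mean"]),
                sd=float(r["std"]),
            )
            for _, r in sub.iterrows()
            if r["element"] in toxicity.csf
        }
        for mode in CR_MODES:
            cfg = MCConfig(
                n_draws=int(mc_cfg["n_draws"]),
                seed=seed + si,  # distinct stream per sector, shared across modes
                threshold=float(mc_cfg["threshold"]),
                confidence=float(mc_cfg["confidence"]),
            )
            result = simulate_tcr(specs, exposure, toxicity, cfg, cr_mode=mode, sector=str(sector))
            sweep = threshold_sweep(result, sorted(mc_cfg["thresholds"]))
            lo, mid, hi = sorted(result.percentiles)
            sweep["p_lo"] = result.percentiles[lo]
            sweep["p50"] = result.percentiles[mid]
            sweep["p_hi"] = result.percentiles[hi]
            frames.append(sweep)
            log.info(
                "MC sector %s mode %s: P(TCR > %g) = %.4f",
                sector, mode, cfg.threshold, result.exceedance_probability,
            )
    return pd.concat(frames, ignore_index=True)


def run_pipeline(
    input_source: str | Path,
    out_dir: str | Path,
    config: Mapping[str, Any] | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Run every stage and write the six-table bundle plus manifest.

    ``input_source`` is a concentration CSV path or the literal string
    ``"synthetic"`` to generate a dataset with the survey-calibrated
    generator.  Returns the mapping of output names to paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exposure, toxicity, mc_cfg, gen_cfg = build_params(config)

    input_digest = None
    try:
        if str(input_source) == "synthetic":
            dataset = generate(GeneratorConfig(seed=seed, **gen_cfg))
        else:
            dataset = read_concentrations(input_source)
            input_digest = hashlib.sha256(Path(input_source).read_bytes()).hexdigest()
    except Exception as exc:
        raise PipelineError("ingest", exc) from exc

    outputs: dict[str, pd.DataFrame] = {}
    stages = {
        "summarize": lambda: _summary_with_limits(dataset),
        "factors": lambda: pd.concat(
            [
                factors_summary_frame(factor_profile(dataset, "BCF")),
                factors_summary_frame(factor_profile(dataset, "BSAF")),
            ],
            ignore_index=True,
        ),
        "correlations": lambda: spearman_matrix(dataset).to_long(),
    }
    for stage, fn in stages.items():
        try:
            outputs[stage] = fn()
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
    try:
        outputs["hazard"], outputs["cancer_risk"] = _risk_tables(dataset, exposure, toxicity)
    except Exception as exc:
        raise PipelineError("risk", exc) from exc
    try:
        outputs["mc_exceedance"] = _mc_table(dataset, exposure, toxicity, mc_cfg, seed)
    except Exception as exc:
        raise PipelineError("monte_carlo", exc) from exc

    names = {
        "summarize": "summary_ml.csv",
        "factors": "factors.csv",
        "correlations": "correlations.csv",
        "hazard": "hazard.csv",
        "cancer_risk": "cancer_risk.csv",
        "mc_exceedance": "mc_exceedance.csv",
    }
    paths: dict[str, Path] = {}
    for stage, frame in outputs.items():
        path = out_dir / names[stage]
        frame.to_csv(path, index=False)
        paths[stage] = path

    manifest = {
        "subcommand": "run_pipeline",
        "input": str(input_source),
        "input_sha256": input_digest,
        "seed": seed,
        "config": {
            "exposure": asdict(exposure),
            "toxicity": {"rfd": toxicity.rfd, "csf": toxicity.csf},
            "mc": dict(mc_cfg),
            "generator": dict(gen_cfg),
        },
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": {k: p.name for k, p in paths.items()},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
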