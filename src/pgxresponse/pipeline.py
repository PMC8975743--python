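"""End-to-end pipeline: simulate -> call metaboliser -> associate -> power.

Ties the stages into one reproducible run driven by a flat YAML config
and a single top-level seed.  The seed is expanded into per-stage
sub-seeds by a fixed rule (``default_rng([seed, stage_index])`` with
stage indices simulate=0, call=1, associate=2, power=3), so any stage
can be re-run independently with an identical stream.  Every run writes
a manifest recording the config hash, seeds, outputs and exclusion
accounting (participants lost to missing genotypes, indeterminate
diplotypes or missing outcomes), mirroring the attrition reporting of
the study design this pipeline emulates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import models as models_mod
from . import power as power_mod
from .translation import call_cohort

logger = logging.getLogger(__name__)

STAGE_INDEX = {"simulate": 0, "call": 1, "associate": 2, "power": 3}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    rng = np.random.default_rng([seed, STAGE_INDEX[stage]])
    return int(rng.integers(0, 2**31 - 1))


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical JSON form of the config."""
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run (written as run_manifest.json)."""

    config_hash: str
    seed: int
    stage_seeds: dict[str, int]
    outputs: dict[str, str] = field(default_factory=dict)
    exclusions: dict[str, int] = field(default_factory=dict)
    n_retained: dict[str, int] = field(default_factory=dict)
    timestamps: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
        return path


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline config."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def run_all(
    config: dict,
    out_dir: str | Path,
    seed: int = 0,
    stages: tuple[str, ...] = ("simulate", "call", "associate", "power"),
) -> RunManifest:
    """Run the pipeline end to end.

    ``config`` keys (all optional):

    * ``cohort`` — :class:`~pgxresponse.cohort.CohortConfig` overrides
      for the simulation stage;
    * ``inputs`` — ``{vcf: ..., phenotypes: ...}`` to analyse existing
      files instead of simulating (``simulate`` must then be omitted
      from ``stages``);
    * ``call`` — ``{dosage_tolerance: ..., prefer_dosage: ...}``;
    * ``associate`` — ``{include_side_effect_scan: ..., n_nodes: ...}``;
    * ``power`` — ``{replicates: ..., statuses: [...], effects: [...]}``
      plus any :class:`~pgxresponse.power.PowerConfig` field.

    Any stage failure aborts with the stage name in the raised error.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_seeds = {s: stage_seed(seed, s) for s in STAGE_INDEX}
    manifest = RunManifest(
        config_hash=config_hash(config), seed=seed, stage_seeds=stage_seeds
    )

    def stamp(stage):
        manifest.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    vcf_path: Path | None = None
    pheno_path: Path | None = None

    try:
        if "simulate" in stages:
            stamp("simulate")
            cfg = cohort_mod.config_from_dict(config.get("cohort", {}))
            cohort = cohort_mod.generate_cohort(cfg, seed=stage_seeds["simulate"])
            paths = cohort_mod.write_cohort(cohort, out_dir)
            vcf_path, pheno_path = paths["vcf"], paths["phenotypes"]
            manifest.outputs.update({k: str(v) for k, v in paths.items()})
            manifest.n_retained["simulate"] = len(cohort.participants)
            logger.info(
                "stage=simulate n_participants=%d n_records=%d",
                len(cohort.participants),
                len(cohort.records),
            )
        else:
            inputs = config.get("inputs", {})
            if "vcf" not in inputs or "phenotypes" not in inputs:
                raise ValueError(
                    "config must provide inputs.vcf and inputs.phenotypes "
                    "when the simulate stage is disabled"
                )
            vcf_path = Path(inputs["vcf"])
            pheno_path = Path(inputs["phenotypes"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'simulate' failed: {exc}") from exc

    statuses_df: pd.DataFrame | None = None
    try:
        if "call" in stages:
            stamp("call")
            call_cfg = config.get("call", {})
            result = call_cohort(
                str(vcf_path),
                dosage_tolerance=call_cfg.get("dosage_tolerance", 0.1),
                prefer_dosage=call_cfg.get("prefer_dosage", False),
            )
            statuses_df = result.calls
            status_path = out_dir / "metabolizer_status.tsv"
            statuses_df.to_csv(status_path, sep="\t", index=False)
            manifest.outputs["statuses"] = str(status_path)
            n_missing = int(
                result.excluded["reason"].str.startswith("missing").sum()
            )
            manifest.exclusions["missing_genotype"] = n_missing
            manifest.exclusions["indeterminate_diplotype"] = (
                result.n_excluded - n_missing
            )
            manifest.n_retained["call"] = result.n_called
            logger.info(
                "stage=call n_called=%d n_excluded=%d",
                result.n_called,
                result.n_excluded,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'call' failed: {exc}") from exc

    try:
        if "associate" in stages:
            stamp("associate")
            records = cohort_mod.read_phenotypes(pheno_path)
            if statuses_df is not None:
                records = records.drop(columns=["status"], errors="ignore").merge(
                    statuses_df[["sample_id", "status"]].rename(
                        columns={"sample_id": "participant_id"}
                    ),
                    on="participant_id",
                    how="inner",
                )
            n_before = cohort_mod.read_phenotypes(pheno_path)[
                "participant_id"
            ].nunique()
            n_after = records["participant_id"].nunique()
            manifest.exclusions["missing_outcomes_or_status"] = n_before - n_after
            manifest.n_retained["associate"] = n_after
            assoc_cfg = config.get("associate", {})
            results = models_mod.run_primary_analysis(
                records,
                include_side_effect_scan=assoc_cfg.get(
                    "include_side_effect_scan", True
                ),
                include_pooled=assoc_cfg.get("include_pooled", True),
                n_nodes=assoc_cfg.get("n_nodes", 15),
            )
            results_path = out_dir / "association_results.tsv"
            results.to_csv(results_path, sep="\t", index=False, float_format="%.6g")
            manifest.outputs["association_results"] = str(results_path)
            report_path = out_dir / "report.md"
            report_path.write_text(report(results))
            manifest.outputs["report"] = str(report_path)
            logger.info("stage=associate n_rows=%d", len(results))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'associate' failed: {exc}") from exc

    try:
        if "power" in stages:
            stamp("power")
            pw_cfg_dict = dict(config.get("power", {}))
            statuses = tuple(pw_cfg_dict.pop("statuses", power_mod.NON_REFERENCE))
            effects = pw_cfg_dict.pop("effects", None)
            replicates = pw_cfg_dict.pop("replicates", None)
            pw_cfg = power_mod.PowerConfig(**pw_cfg_dict)
            if replicates is not None:
                pw_cfg.n_replicates = int(replicates)
            pw_cfg.seed = stage_seeds["power"]
            grid = power_mod.estimate_power(
                pw_cfg,
                statuses=statuses,
                effects=tuple(effects) if effects else None,
            )
            power_path = out_dir / "power_grid.tsv"
            grid.to_csv(power_path, sep="\t", index=False, float_format="%.6g")
            manifest.outputs["power_grid"] = str(power_path)
            logger.info("stage=power n_cells=%d", len(grid))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'power' failed: {exc}") from exc

    manifest.write(out_dir / "run_manifest.json")
    manifest.outputs["manifest"] = str(out_dir / "run_manifest.json")
    return manifest


def report(results: pd.DataFrame) -> str:
    """Render association results as a forest-plot-style markdown table.

    Groups rows by family (efficacy / tolerability / any side effect)
    and scope (per drug, then pooled), printing OR [95% CI] with ``*``
    for nominal significance (p < 0.05) and ``**`` for significance at
    the family's Bonferroni threshold.
    """
    required = {"family", "outcome", "scope", "contrast", "odds_ratio", "p"}
    if not required.issubset(results.columns):
        raise ValueError(
            f"results table lacks columns: {sorted(required - set(results.columns))}"
        )
    main = results[
        results["outcome"].isin(["efficacy", "discontinued", "any_side_effect"])
    ]
    lines = ["# Association summary", ""]
    titles = {
        "efficacy": "Efficacy (3-level, cumulative logit)",
        "discontinued": "Discontinuation due to side effects (inverse tolerability)",
        "any_side_effect": "Any side effect",
    }
    scope_order = list(models_mod.DRUGS) + ["pooled"]
    for outcome in ["efficacy", "discontinued", "any_side_effect"]:
        block = main[main["outcome"] == outcome]
        if block.empty:
            continue
        lines.append(f"## {titles[outcome]}")
        lines.append("")
        lines.append("| scope | contrast | OR [95% CI] | p | sig |")
        lines.append("|---|---|---|---|---|")
        for scope in scope_order:
            sub = block[block["scope"] == scope]
            for _, row in sub.iterrows():
                if np.isfinite(row["p"]):
                    flag = (
                        "**"
                        if row.get("sig_corrected", False)
                        else ("*" if row.get("sig_nominal", False) else "")
                    )
                    or_str = (
                        f"{row['odds_ratio']:.2f} "
                        f"[{row['ci_low']:.2f}-{row['ci_high']:.2f}]"
                    )
                    p_str = f"{row['p']:.3g}"
                else:
                    flag, or_str, p_str = "", "NA", "NA"
                lines.append(
                    f"| {scope} | {row['contrast']} vs normal | {or_str} | {p_str} | {flag} |"
                )
        lines.append("")
    lines.append("`*` p < 0.05 (nominal); `**` significant after Bonferroni correction.")
    lines.append("")
    return "\n".join(lines)
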