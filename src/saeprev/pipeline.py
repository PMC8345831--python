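"""End-to-end orchestration: simulate -> direct -> FH -> unit-level -> compare.

Stage seeds are derived from a single master seed by stable hashing of the
stage name, so adding or rerunning a stage never perturbs the random streams
of the others, and identical configs yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import align_estimates, comparison_report, plot_comparison
from .direct import direct_estimates
from .fh import fit_fh, select_model_aic
from .synthetic import (
    COVARIATES,
    PopulationConfig,
    compute_anc_covariate,
    draw_two_stage_sample,
    generate_population,
)
from .unit import ebp_estimates, fit_logistic_mixed, make_district_frames

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "stage_seed"]

STAGES = ("simulate", "sample", "anc", "direct", "fh", "unit", "bootstrap")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    population: PopulationConfig = field(default_factory=PopulationConfig)
    units_per_cluster: int = 25
    sampled_clusters: int | str = "auto"  # "auto": ~N_i/1000, clipped to [2, C]
    fh_candidates: list[list[str]] = field(default_factory=lambda: [["anc_logit"]])
    unit_covariates: list[str] = field(default_factory=lambda: list(COVARIATES))
    bootstrap_B: int = 200
    master_seed: int = 0
    out_dir: str = "saeprev_out"
    make_plots: bool = False

    def validate(self) -> None:
        self.population.validate()
        if self.bootstrap_B < 2:
            raise ValueError("bootstrap_B must be >= 2")
        if self.units_per_cluster < 1:
            raise ValueError("units_per_cluster must be >= 1")
        if not self.fh_candidates:
            raise ValueError("need at least one FH candidate covariate set")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        if d["population"]["district_sizes"] is not None:
            d["population"]["district_sizes"] = [
                int(x) for x in d["population"]["district_sizes"]
            ]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        pop = PopulationConfig(**d.pop("population", {}))
        if isinstance(pop.size_range, list):
            pop.size_range = tuple(pop.size_range)
        return cls(population=pop, **d)

    def config_hash(self) -> str:
        d = asdict(self)
        if d["population"]["district_sizes"] is not None:
            d["population"]["district_sizes"] = [
                int(x) for x in d["population"]["district_sizes"]
            ]
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _auto_clusters(pop) -> dict[int, int]:
    sizes = pop.district_sizes
    c_pop = pop.config.clusters_per_district
    return {
        int(d): int(np.clip(round(n / 1000.0), 2, c_pop))
        for d, n in sizes.items()
    }


def validate_inputs(tables: dict[str, pd.DataFrame]) -> list[dict]:
    """Schema and cross-reference checks; returns a machine-readable issue list.

    Recognized table names: "sample" (survey records), "anc" (district
    covariates), "frame" (unit-level auxiliary frame).
    """
    issues: list[dict] = []

    def issue(table, kind, detail):
        issues.append({"table": table, "kind": kind, "detail": detail})

    sample = tables.get("sample")
    if sample is not None:
        for col in ("district_id", "cluster_id", "weight", "y"):
            if col not in sample.columns:
                issue("sample", "missing_column", col)
        if "weight" in sample.columns:
            bad = sample.index[sample["weight"] <= 0].tolist()
            for row in bad:
                issue("sample", "nonpositive_weight", f"row {row}")
        if "y" in sample.columns and not sample["y"].isin([0, 1]).all():
            issue("sample", "nonbinary_outcome", "y has values outside {0,1}")
    anc = tables.get("anc")
    if anc is not None:
        for col in ("district_id",):
            if col not in anc.columns:
                issue("anc", "missing_column", col)
        if sample is not None and {"district_id"} <= set(anc.columns) and \
                "district_id" in sample.columns:
            missing = set(sample["district_id"]) - set(anc["district_id"])
            for d in sorted(missing):
                issue("anc", "district_missing", f"district {d} in sample, not in anc")
    frame = tables.get("frame")
    if frame is not None and sample is not None and \
            "district_id" in frame.columns and "district_id" in sample.columns:
        missing = set(sample["district_id"]) - set(frame["district_id"])
        for d in sorted(missing):
            issue("frame", "district_missing", f"district {d} in sample, not in frame")
    return issues


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, write output CSVs + manifest; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(config.master_seed, s) for s in STAGES}
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "stage_seeds": seeds,
        "counts": {},
        "outputs": {},
    }
    config.to_yaml(out / "config.yaml")

    logger.info("stage simulate: generating population")
    pop_cfg = PopulationConfig(**{**asdict(config.population), "seed": seeds["simulate"]})
    pop = generate_population(pop_cfg)
    manifest["counts"]["population_units"] = int(len(pop.units))

    logger.info("stage sample: drawing two-stage sample")
    clusters = (
        _auto_clusters(pop)
        if config.sampled_clusters == "auto"
        else int(config.sampled_clusters)
    )
    sample = draw_two_stage_sample(
        pop, clusters, config.units_per_cluster, seed=seeds["sample"]
    )
    sample.to_csv(out / "sample.csv")
    manifest["counts"]["sample_records"] = int(len(sample.records))
    manifest["outputs"]["sample"] = "sample.csv"

    anc = compute_anc_covariate(pop, seed=seeds["anc"])
    anc.to_csv(out / "anc_covariate.csv", index=False)
    manifest["outputs"]["anc"] = "anc_covariate.csv"

    issues = validate_inputs({"sample": sample.records, "anc": anc})
    if issues:
        raise ValueError(f"input validation failed: {issues}")

    logger.info("stage direct: design-weighted estimates")
    direct = direct_estimates(sample.records)
    direct.to_csv(out / "direct_estimates.csv", index=False)
    manifest["counts"]["districts"] = int(len(direct))
    manifest["outputs"]["direct"] = "direct_estimates.csv"

    logger.info("stage fh: area-level model")
    fh_inputs = direct.merge(anc, on="district_id")
    aic_table, best = select_model_aic(fh_inputs, config.fh_candidates)
    fh_fit = fit_fh(fh_inputs, best, method="REML")
    fh_df = fh_fit.to_frame()
    fh_df.to_csv(out / "fh_estimates.csv", index=False)
    fh_summary = fh_fit.summary()
    fh_summary["aic_table"] = [
        {**row, "covariates": list(row["covariates"])}
        for row in aic_table.to_dict("records")
    ]
    (out / "fh_model.json").write_text(json.dumps(fh_summary, indent=2, default=float))
    manifest["outputs"]["fh"] = "fh_estimates.csv"

    logger.info("stage unit: logistic mixed model + EBP + bootstrap (B=%d)",
                config.bootstrap_B)
    unit_fit = fit_logistic_mixed(sample.records, config.unit_covariates)
    frames = make_district_frames(pop, sample)
    unit_df = ebp_estimates(
        unit_fit, frames, B=config.bootstrap_B, seed=seeds["bootstrap"]
    )
    unit_df.to_csv(out / "unit_estimates.csv", index=False)
    (out / "unit_model.json").write_text(
        json.dumps(unit_fit.summary(), indent=2, default=float)
    )
    manifest["outputs"]["unit"] = "unit_estimates.csv"

    logger.info("stage compare: diagnostics")
    aligned = align_estimates(direct, fh_df, unit_df)
    aligned.to_csv(out / "comparison.csv", index=False)
    report = comparison_report(aligned)
    serializable = {
        k: (v.to_dict() if isinstance(v, pd.DataFrame) else v)
        for k, v in report.items()
    }
    (out / "comparison_report.json").write_text(
        json.dumps(serializable, indent=2, default=float)
    )
    manifest["outputs"]["comparison"] = "comparison.csv"
    if config.make_plots:
        plot_comparison(aligned, out / "comparison.png")
        manifest["outputs"]["plot"] = "comparison.png"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
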