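"""Configuration, orchestration and table IO for reproducible runs.

A run is: simulate a cohort -> synthesize per-parcel spectra -> estimate
PAF per spectrum -> aggregate to macro-regions -> fit the statistical
battery.  Everything is plain CSV/JSON under one output directory, with
a manifest recording the configuration and per-stage row counts so any
run is reconstructible from (config, seed).
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
from .paf import (
    DEFAULT_ALPHA_BAND,
    DEFAULT_FIT_RANGE,
    DEFAULT_HUBER_M,
    DEFAULT_PEAK_THRESHOLD,
    estimate_paf,
)
from .regions import aggregate_macro, load_region_map, validity_proportion
from .spectral import SpectralConfig
from .stats import (
    bonferroni_gate,
    change_score_regression,
    fit_reactivity_lmm,
    fit_subgroup_lmm,
    srs_association,
)
from .synthetic import Cohort, CohortDesign, default_frequency_grid, generate_cohort, synth_psd, SpectralParams

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "read_paf_table",
    "write_paf_table",
    "REQUIRED_PAF_COLUMNS",
]

log = logging.getLogger("pafreact")

REQUIRED_PAF_COLUMNS = (
    "subject",
    "diagnosis",
    "condition",
    "region",
    "paf_hz",
    "age_months",
    "sex",
    "srs_total",
)

ALL_STAGES = ("simulate", "estimate", "aggregate", "analyze")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; defaults reproduce the reference settings
    (5-s epochs, 80% overlap, Hamming, 1-55 Hz fit range, 7-13 Hz band,
    Huber M = 1.35, minimum 10 epochs, Bonferroni over 5 regions / 2
    subgroups)."""

    seed: int = 0
    out_dir: str = "results/run"
    stages: tuple = ALL_STAGES
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE
    band: tuple[float, float] = DEFAULT_ALPHA_BAND
    huber_m: float = DEFAULT_HUBER_M
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD
    region_map_path: str | None = None
    design: CohortDesign = field(default_factory=CohortDesign)
    n_region_comparisons: int = 5
    n_subgroup_comparisons: int = 2
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.spectral.overlap_fraction > 0.95:
            raise ValueError(
                "overlap_fraction above 0.95 leaves no independent data per epoch"
            )
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not self.fit_range[0] < self.fit_range[1]:
            raise ValueError("fit_range must be increasing")
        if not self.band[0] < self.band[1]:
            raise ValueError("band must be increasing")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "spectral" in raw and isinstance(raw["spectral"], dict):
            raw["spectral"] = SpectralConfig(**raw["spectral"])
        if "design" in raw and isinstance(raw["design"], dict):
            raw["design"] = CohortDesign(**raw["design"])
        for key in ("fit_range", "band"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "stages" in raw and isinstance(raw["stages"], list):
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"]["region_effects"] = {
            r: dataclasses.asdict(e) if dataclasses.is_dataclass(e) else e
            for r, e in self.design.region_effects.items()
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_paf_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format PAF table as CSV (round-trips with read)."""
    missing = [c for c in REQUIRED_PAF_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"PAF table missing required columns: {missing}")
    _check_duplicate_keys(table)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_paf_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format PAF table, validating columns and key uniqueness.

    Extra columns are preserved and passed through.
    """
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_PAF_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"PAF table missing required columns: {missing}")
    _check_duplicate_keys(table)
    return table


def _check_duplicate_keys(table: pd.DataFrame) -> None:
    dup = table.duplicated(["subject", "region", "condition"], keep=False)
    if dup.any():
        key = table.loc[dup, ["subject", "region", "condition"]].iloc[0].tolist()
        raise ValueError(f"duplicate subject x region x condition key: {key}")


def _estimate_micro_paf(cohort: Cohort, cfg: PipelineConfig) -> pd.DataFrame:
    """Synthesize each parcel spectrum and run the PAF estimator on it."""
    rng = np.random.default_rng(cfg.seed + 1)
    freqs = default_frequency_grid(spacing=1.0 / cfg.spectral.epoch_seconds)
    rows = []
    for rec in cohort.micro_params.itertuples(index=False):
        params = SpectralParams(
            offset=rec.offset,
            exponent=rec.exponent,
            peak_center=rec.peak_center,
            peak_amplitude=rec.peak_amplitude,
            peak_width=rec.peak_width,
            noise_sd=rec.noise_sd,
        )
        psd = synth_psd(params, freqs, seed=rng)
        fit = estimate_paf(
            psd,
            fit_range=cfg.fit_range,
            band=cfg.band,
            huber_m=cfg.huber_m,
            peak_threshold=cfg.peak_threshold,
        )
        rows.append(
            {
                "subject": rec.subject,
                "diagnosis": rec.diagnosis,
                "condition": rec.condition,
                "micro_region": rec.micro_region,
                "hemisphere": rec.hemisphere,
                "status": fit.status,
                "paf_hz": fit.center if fit.present else np.nan,
                "amplitude": fit.amplitude if fit.present else np.nan,
                "width_hz": fit.width if fit.present else np.nan,
                "slope": fit.aperiodic.slope if fit.aperiodic else np.nan,
                "intercept": fit.aperiodic.intercept if fit.aperiodic else np.nan,
                "r2": fit.r2,
            }
        )
    return pd.DataFrame(rows)


def _analyze(table: pd.DataFrame, cfg: PipelineConfig, out: Path) -> dict:
    regions = sorted(table["region"].unique())
    lmm_rows, change_rows, sub_rows, srs_rows = [], [], [], []
    interaction_p = {}
    for region in regions:
        res = fit_reactivity_lmm(table, region)
        interaction_p[region] = res.p("diagnosis_x_condition")
        lmm_rows.append(res.table.assign(region=region, converged=res.converged))
        cres = change_score_regression(table, region)
        change_rows.append(cres.table.assign(region=region))
    gates = bonferroni_gate(
        [interaction_p[r] for r in regions], cfg.n_region_comparisons
    )
    significant = [r for r, g in zip(regions, gates) if g]
    for region in significant:
        for diagnosis in ("TD", "ASD"):
            sres = fit_subgroup_lmm(table, region, diagnosis)
            sub_rows.append(sres.table.assign(region=region, subgroup=diagnosis))
        sr = srs_association(table, region)
        srs_rows.append(sr.table.assign(region=region))

    out.mkdir(parents=True, exist_ok=True)
    pd.concat(lmm_rows, ignore_index=True).to_csv(out / "reactivity_lmm.csv", index=False)
    pd.concat(change_rows, ignore_index=True).to_csv(out / "change_score.csv", index=False)
    if sub_rows:
        pd.concat(sub_rows, ignore_index=True).to_csv(out / "subgroup_lmm.csv", index=False)
    if srs_rows:
        pd.concat(srs_rows, ignore_index=True).to_csv(out / "srs_association.csv", index=False)
    summary = {
        "interaction_p": {r: float(interaction_p[r]) for r in regions},
        "bonferroni_alpha": 0.05 / cfg.n_region_comparisons,
        "significant_interaction_regions": significant,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Deterministic in (config, seed): reruns produce byte-identical
    tables.  Later stages read the artifacts of earlier ones, so a subset
    of stages can be rerun against an existing directory.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    region_map = load_region_map(cfg.region_map_path)
    counts: dict[str, int] = {}

    if "simulate" in cfg.stages:
        log.info("simulate: generating cohort (seed=%d)", cfg.seed)
        cohort = generate_cohort(cfg.design, seed=cfg.seed, region_map=region_map)
        cohort.covariates.to_csv(out / "covariates.csv", index=False)
        cohort.micro_params.to_csv(out / "micro_params.csv", index=False)
        cohort.macro_truth.to_csv(out / "macro_truth.csv", index=False)
        (out / "truth.json").write_text(json.dumps(cohort.truth, indent=2, sort_keys=True))
        counts["simulate"] = len(cohort.micro_params)

    if "estimate" in cfg.stages:
        cohort = _load_cohort(out, cfg, region_map)
        log.info("estimate: fitting %d parcel spectra", len(cohort.micro_params))
        micro = _estimate_micro_paf(cohort, cfg)
        micro.to_csv(out / "micro_paf.csv", index=False)
        counts["estimate"] = len(micro)

    if "aggregate" in cfg.stages:
        micro = pd.read_csv(out / "micro_paf.csv")
        covs = pd.read_csv(out / "covariates.csv")
        macro = aggregate_macro(micro, region_map)
        macro = macro.merge(covs, on=["subject"] + (["diagnosis"] if "diagnosis" in macro else []), how="left")
        table = macro.rename(columns={})[
            ["subject", "diagnosis", "condition", "region", "paf_hz",
             "n_valid_micro", "n_total_micro", "age_months", "sex", "srs_total"]
        ].sort_values(["subject", "region", "condition"]).reset_index(drop=True)
        write_paf_table(table, out / "paf_table.csv")
        micro_lab = micro if "diagnosis" in micro.columns else micro.merge(
            covs[["subject", "diagnosis"]], on="subject", how="left"
        )
        validity = validity_proportion(micro_lab, region_map)
        validity.to_csv(out / "validity.csv", index=False)
        counts["aggregate"] = len(table)

    if "analyze" in cfg.stages:
        table = read_paf_table(out / "paf_table.csv")
        log.info("analyze: fitting statistical battery")
        _analyze(table, cfg, out / "analyze")
        counts["analyze"] = int(table["paf_hz"].notna().sum())

    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_rows": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return out


def _load_cohort(out: Path, cfg: PipelineConfig, region_map) -> Cohort:
    """Rebuild the cohort object for stages running after `simulate`."""
    micro = pd.read_csv(out / "micro_params.csv")
    covs = pd.read_csv(out / "covariates.csv")
    macro = pd.read_csv(out / "macro_truth.csv")
    truth = json.loads((out / "truth.json").read_text())
    return Cohort(
        design=cfg.design,
        seed=cfg.seed,
        covariates=covs,
        macro_truth=macro,
        micro_params=micro,
        truth=truth,
    )
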