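"""Replicate-cohort simulation studies of estimator and model recovery.

Each study regenerates many synthetic cohorts at the design's sample
size, fits the corresponding model to each, and summarizes how well the
injected coefficient is recovered (or, under a null design, how often
the test rejects).  Cohort tables come from the generative truth (parcel
centers with simulated detection failures, aggregated to macro-regions),
so replicate studies measure the statistical machinery, not spectral
fitting noise.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .regions import load_region_map
from .stats import change_score_regression, fit_reactivity_lmm, srs_association
from .synthetic import CohortDesign, RegionEffects, generate_cohort

__all__ = [
    "single_region_design",
    "null_design",
    "coefficient_recovery",
    "null_rejection_rate",
]


def single_region_design(
    base: CohortDesign | None = None, region: str = "temporal_right"
) -> CohortDesign:
    """Restrict a design to one macro-region (replicate fits get cheap)."""
    base = base or CohortDesign()
    return dataclasses.replace(
        base,
        region_effects={region: base.region_effects[region]},
        srs_region=region,
    )


def null_design(region: str = "temporal_right") -> CohortDesign:
    """Single-region design with every injected effect and coupling zeroed."""
    return dataclasses.replace(
        single_region_design(),
        region_effects={region: RegionEffects()},
        baseline_coupling=0.0,
        srs_coupling=0.0,
    )


def coefficient_recovery(
    n_reps: int = 200,
    seed: int = 0,
    region: str = "temporal_right",
    design: CohortDesign | None = None,
) -> dict:
    """Recover the interaction, baseline-dependence and SRS coefficients
    over replicate cohorts.

    Returns per-coefficient mean estimates, the injected truths, and the
    biases (mean estimate minus truth).
    """
    design = design or single_region_design(region=region)
    region_map = load_region_map()
    interactions, baselines, srs_slopes = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_reps):
            cohort = generate_cohort(design, seed=seed + rep, region_map=region_map)
            table = cohort.paf_table()
            interactions.append(
                fit_reactivity_lmm(table, region).coef("diagnosis_x_condition")
            )
            baselines.append(
                change_score_regression(table, region).coef("baseline_paf")
            )
            srs_slopes.append(srs_association(table, region).coef("delta_paf"))
    truth_int = design.region_effects[region].interaction
    out = {
        "n_reps": n_reps,
        "region": region,
        "interaction_mean": float(np.mean(interactions)),
        "interaction_truth": truth_int,
        "interaction_bias": float(np.mean(interactions) - truth_int),
        "baseline_slope_mean": float(np.mean(baselines)),
        "baseline_slope_truth": design.baseline_coupling,
        "baseline_slope_bias": float(np.mean(baselines) - design.baseline_coupling),
        "srs_slope_mean": float(np.mean(srs_slopes)),
        "srs_slope_truth": design.srs_coupling,
        "srs_slope_bias": float(np.mean(srs_slopes) - design.srs_coupling),
    }
    return out


def null_rejection_rate(
    n_reps: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    region: str = "temporal_right",
) -> dict:
    """Type-I error of the interaction Wald test under a zero-effect design."""
    design = null_design(region)
    region_map = load_region_map()
    rejections = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_reps):
            cohort = generate_cohort(design, seed=seed + rep, region_map=region_map)
            res = fit_reactivity_lmm(cohort.paf_table(), region)
            rejections += res.p("diagnosis_x_condition") < alpha
    rate = rejections / n_reps
    mc_se = float(np.sqrt(alpha * (1 - alpha) / n_reps))
    return {
        "n_reps": n_reps,
        "alpha": alpha,
        "rejection_rate": rate,
        "monte_carlo_se": mc_se,
    }
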