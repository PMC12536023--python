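"""Synthetic M/EEG cohort generation.

Simulates the study conditions the reactivity analysis assumes: two
diagnostic groups (29 typically developing / TD, 22 autism spectrum
disorder / ASD children aged 60-95 months), two recording conditions
(dark-room rest DR, eyes-open video viewing EO), and per-parcel power
spectra made of a power-law aperiodic background plus an alpha-band
Gaussian peak whose true center carries the injected effect structure:

    log10 P(f) = b - chi * log10 f + a * exp(-(f - mu)^2 / (2 sigma^2)) + noise

Effects enter the true peak center mu additively per macro-region:
diagnosis, condition, their interaction, age and sex, plus a shared
subject-level random intercept.  The EO - DR change is coupled to the
(centered) DR baseline, social responsiveness (SRS) scores are generated
on the log scale from the true temporal reactivity, and alpha-peak
detection failures are simulated by zeroing the peak amplitude of random
parcel cells at a group-specific rate.  Every draw is governed by a
single seed; identical (design, seed) pairs give bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .spectral import PowerSpectrum, Recording
from .regions import load_region_map, RegionMap

__all__ = [
    "SpectralParams",
    "RegionEffects",
    "CohortDesign",
    "Cohort",
    "synth_psd",
    "synth_timeseries",
    "generate_cohort",
    "default_frequency_grid",
]


@dataclass(frozen=True)
class SpectralParams:
    """Generative parameters for one region/condition/subject spectrum.

    ``offset``/``exponent`` shape the aperiodic power law (log10-power
    intercept b and slope magnitude chi); the alpha peak is a Gaussian in
    log10-power with center ``peak_center`` (Hz), height
    ``peak_amplitude`` (log10-power units, 0 = no peak) and width
    ``peak_width`` (Hz).  ``noise_sd`` is i.i.d. Gaussian noise added in
    log10-power space.
    """

    offset: float = 1.0
    exponent: float = 1.5
    peak_center: float = 10.0
    peak_amplitude: float = 0.4
    peak_width: float = 1.2
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be >= 0")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def log10_power(self, freqs: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs, dtype=float)
        out = self.offset - self.exponent * np.log10(f)
        if self.peak_amplitude > 0:
            out = out + self.peak_amplitude * np.exp(
                -((f - self.peak_center) ** 2) / (2.0 * self.peak_width**2)
            )
        return out


def default_frequency_grid(
    spacing: float = 0.2, f_max: float = 60.0
) -> np.ndarray:
    """0.2 Hz grid mirroring 5-s Welch epochs, from `spacing` to `f_max`."""
    return np.arange(1, int(round(f_max / spacing)) + 1) * spacing


def synth_psd(
    params: SpectralParams,
    freqs: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> PowerSpectrum:
    """Evaluate the generative spectral model on a frequency grid."""
    freqs = default_frequency_grid() if freqs is None else np.asarray(freqs, float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be strictly positive")
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    logp = params.log10_power(freqs)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        logp = logp + rng.normal(0.0, params.noise_sd, size=freqs.size)
    return PowerSpectrum(freqs=freqs, power=10.0**logp)


def synth_timeseries(
    params: SpectralParams,
    fs: float = 500.0,
    duration: float = 120.0,
    seed: int | np.random.Generator | None = None,
    epoch_seconds: float = 5.0,
) -> Recording:
    """Synthesize a time series whose expected PSD is the model spectrum.

    Spectral shaping of white noise: the target one-sided density is
    evaluated on the full-length FFT grid, converted to Fourier amplitudes
    and given independent uniform random phases, then inverse transformed.
    The realization's Welch PSD fluctuates around the target with ordinary
    periodogram variability.
    """
    if duration < epoch_seconds:
        raise ValueError(
            f"duration {duration} s is shorter than one {epoch_seconds}-s epoch"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(fs * duration))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    target = np.zeros_like(freqs)
    pos = freqs > 0
    logp = params.log10_power(freqs[pos])
    if params.noise_sd > 0:
        logp = logp + rng.normal(0.0, params.noise_sd, size=logp.size)
    target[pos] = 10.0**logp
    # one-sided density -> complex amplitude; interior bins carry half the
    # (doubled) one-sided power each
    amp = np.sqrt(target * fs * n / 2.0)
    if n % 2 == 0:
        amp[-1] = np.sqrt(target[-1] * fs * n)  # Nyquist bin is not doubled
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = np.abs(spec[-1])
    samples = np.fft.irfft(spec, n=n)
    return Recording(samples=samples, fs=fs)


@dataclass(frozen=True)
class RegionEffects:
    """Additive fixed effects (Hz) on the true peak center in one region."""

    diagnosis: float = 0.0  # ASD relative to TD
    condition: float = 0.0  # EO relative to DR, in the TD group
    interaction: float = 0.0  # extra EO effect in the ASD group
    age: float = 0.0  # per month, centered at 75 months
    sex: float = 0.0  # male relative to female


def _default_region_effects() -> dict[str, RegionEffects]:
    # condition/diagnosis/interaction/age/sex profile per macro-region,
    # strongest reactivity in occipital cortex and a TD-only EO>DR effect
    # in temporal cortex (negative interaction)
    return {
        "cingulate_left": RegionEffects(0.088, 0.104, -0.330, 0.037, 0.265),
        "frontal_left": RegionEffects(-0.037, 0.009, -0.031, 0.031, 0.222),
        "occipital_left": RegionEffects(-0.036, 0.668, -0.331, 0.044, 0.386),
        "parietal_left": RegionEffects(-0.100, 0.101, -0.094, 0.041, 0.363),
        "temporal_left": RegionEffects(0.030, 0.309, -0.522, 0.043, 0.345),
        "cingulate_right": RegionEffects(0.079, 0.147, -0.252, 0.038, 0.214),
        "frontal_right": RegionEffects(0.053, 0.109, -0.178, 0.031, 0.182),
        "occipital_right": RegionEffects(-0.068, 0.608, -0.355, 0.042, 0.584),
        "parietal_right": RegionEffects(-0.062, 0.063, -0.074, 0.037, 0.421),
        "temporal_right": RegionEffects(0.471, 0.387, -0.662, 0.034, 0.167),
    }


@dataclass(frozen=True)
class CohortDesign:
    """Full parameterization of the synthetic cohort.

    Counts, covariate distributions and effect sizes default to the study
    conditions: 29 TD / 22 ASD children, ages 60-95 months, roughly 55%
    and 64% male; per-region fixed effects on the true peak center; an
    EO-DR change coupled to the centered DR baseline; log-SRS driven by
    the true temporal reactivity; and group-specific alpha-detection
    failure rates.  The seed passed to :func:`generate_cohort` fully
    determines every draw.
    """

    n_td: int = 29
    n_asd: int = 22
    age_range_months: tuple[int, int] = (60, 95)
    p_male: dict = field(default_factory=lambda: {"TD": 16 / 29, "ASD": 14 / 22})
    base_center_hz: float = 9.0
    age_center_months: float = 75.0
    region_effects: dict = field(default_factory=_default_region_effects)
    subject_sd: float = 0.3  # shared subject-level random intercept, Hz
    region_noise_sd: float = 0.25  # subject x region baseline scatter, Hz
    change_noise_sd: float = 0.35  # residual of the EO-DR change, Hz
    baseline_coupling: float = -0.6  # slope of EO-DR change on centered DR
    micro_jitter_sd: float = 0.1  # parcel-level scatter around macro truth, Hz
    srs_region: str = "temporal_right"
    srs_coupling: float = -0.324  # log-SRS per Hz of true reactivity
    srs_age: float = 0.017  # log-SRS per month
    srs_sex: float = 0.205  # log-SRS, male vs female
    srs_intercept: float = 3.95  # log-SRS at reference covariates
    srs_noise_sd: float = 0.4
    failure_prob: dict = field(default_factory=lambda: {"TD": 0.15, "ASD": 0.45})
    # generative spectral background
    offset_mean: float = 1.0
    offset_sd: float = 0.3
    exponent_mean: float = 1.5
    exponent_sd: float = 0.15
    peak_amplitude: float = 0.4
    peak_width_hz: float = 1.2
    spectrum_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_td <= 0 or self.n_asd <= 0:
            raise ValueError("group sizes must be positive")
        if self.age_range_months[0] >= self.age_range_months[1]:
            raise ValueError("age range must be a nonempty interval")
        for g, p in self.failure_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"failure probability for {g} must be in [0, 1]")
        for g, p in self.p_male.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"male proportion for {g} must be in [0, 1]")


@dataclass(frozen=True)
class Cohort:
    """A generated cohort: covariates, truth record, and parcel-level
    spectral parameters ready for spectrum synthesis."""

    design: CohortDesign
    seed: int
    covariates: pd.DataFrame  # subject, diagnosis, age_months, sex, srs_total
    macro_truth: pd.DataFrame  # subject, condition, region, true_center_hz
    micro_params: pd.DataFrame  # one row per subject x parcel x condition
    truth: dict  # injected coefficients for recovery tests

    def paf_table(self) -> pd.DataFrame:
        """Macro-region PAF table computed directly from the generative truth.

        Averages the true parcel centers over parcels whose peak survived
        the detection-failure draw (missing if none) — the idealized
        output of a perfectly accurate spectral estimator, used for fast
        replicate-level statistical simulations.
        """
        mp = self.micro_params
        present = mp[mp.peak_amplitude > 0]
        agg = (
            present.groupby(["subject", "condition", "region"], sort=True)["peak_center"]
            .agg(paf_hz="mean", n_valid_micro="count")
            .reset_index()
        )
        full = (
            mp.groupby(["subject", "condition", "region"], sort=True)
            .size()
            .rename("n_total_micro")
            .reset_index()
        )
        out = full.merge(agg, on=["subject", "condition", "region"], how="left")
        out["n_valid_micro"] = out["n_valid_micro"].fillna(0).astype(int)
        out = out.merge(self.covariates, on="subject", how="left")
        cols = [
            "subject", "diagnosis", "condition", "region", "paf_hz",
            "n_valid_micro", "n_total_micro", "age_months", "sex", "srs_total",
        ]
        return out[cols].sort_values(["subject", "region", "condition"]).reset_index(drop=True)


def generate_cohort(
    design: CohortDesign | None = None,
    seed: int = 0,
    region_map: RegionMap | None = None,
) -> Cohort:
    """Draw a full synthetic cohort from the design. Deterministic in seed."""
    design = design or CohortDesign()
    region_map = region_map or load_region_map()
    rng = np.random.default_rng(seed)

    groups = ["TD"] * design.n_td + ["ASD"] * design.n_asd
    n = len(groups)
    subjects = [f"S{i + 1:03d}" for i in range(n)]
    lo, hi = design.age_range_months
    ages = rng.integers(lo, hi + 1, size=n).astype(float)
    sex = np.array([rng.random() < design.p_male[g] for g in groups], dtype=int)
    asd = np.array([g == "ASD" for g in groups], dtype=float)
    u = rng.normal(0.0, design.subject_sd, size=n)  # shared subject intercept

    regions = sorted(design.region_effects)
    age_c = ages - design.age_center_months

    macro_rows = []
    delta_by_region: dict[str, np.ndarray] = {}
    center_tensor = np.empty((n, 2, len(regions)))  # (subject, DR/EO, region)
    for ri, region in enumerate(regions):
        eff = design.region_effects[region]
        dr_systematic = (
            design.base_center_hz
            + eff.diagnosis * asd
            + eff.age * age_c
            + eff.sex * sex
        )
        dr = dr_systematic + u + rng.normal(0.0, design.region_noise_sd, size=n)
        # couple the change to the idiosyncratic part of the baseline
        # (observed DR minus its covariate prediction) so that the injected
        # condition/interaction coefficients are exactly the fixed-effect
        # contrasts a mixed model estimates
        delta = (
            eff.condition
            + eff.interaction * asd
            + design.baseline_coupling * (dr - dr_systematic)
            + rng.normal(0.0, design.change_noise_sd, size=n)
        )
        eo = dr + delta
        delta_by_region[region] = delta
        center_tensor[:, 0, ri] = dr
        center_tensor[:, 1, ri] = eo
        for cond, vals in (("DR", dr), ("EO", eo)):
            macro_rows.append(
                pd.DataFrame(
                    {
                        "subject": subjects,
                        "condition": cond,
                        "region": region,
                        "true_center_hz": vals,
                    }
                )
            )
    macro_truth = pd.concat(macro_rows, ignore_index=True)

    ref_delta = delta_by_region.get(design.srs_region)
    if ref_delta is None:
        raise ValueError(f"srs_region {design.srs_region!r} not in region_effects")
    log_srs = (
        design.srs_intercept
        + design.srs_coupling * ref_delta
        + design.srs_age * age_c
        + design.srs_sex * sex
        + rng.normal(0.0, design.srs_noise_sd, size=n)
    )
    srs = np.round(np.exp(log_srs), 1)

    covariates = pd.DataFrame(
        {
            "subject": subjects,
            "diagnosis": groups,
            "age_months": ages,
            "sex": sex,
            "srs_total": srs,
        }
    )

    # parcel-level spectral parameters
    offsets = rng.normal(design.offset_mean, design.offset_sd, size=n)
    exponents = np.clip(
        rng.normal(design.exponent_mean, design.exponent_sd, size=n), 0.5, None
    )
    rmap = region_map.table.copy()
    rmap["region"] = rmap["macro_region"] + "_" + rmap["hemisphere"]
    region_idx = {r: i for i, r in enumerate(regions)}
    # designs may restrict to a subset of macro-regions; drop other parcels
    rmap = rmap[rmap["region"].isin(region_idx)].reset_index(drop=True)
    n_micro = len(rmap)
    parcel_region = rmap["region"].map(region_idx).to_numpy()
    total = n * 2 * n_micro
    subj_idx = np.repeat(np.arange(n), 2 * n_micro)
    cond_idx = np.tile(np.repeat([0, 1], n_micro), n)
    parcel_idx = np.tile(np.arange(n_micro), 2 * n)
    true_centers = center_tensor[subj_idx, cond_idx, parcel_region[parcel_idx]]
    p_fail = np.array([design.failure_prob[g] for g in groups])[subj_idx]
    failed = rng.random(total) < p_fail
    jitter = rng.normal(0.0, design.micro_jitter_sd, size=total)
    micro_params = pd.DataFrame(
        {
            "micro_region": rmap["micro_region"].to_numpy()[parcel_idx],
            "hemisphere": rmap["hemisphere"].to_numpy()[parcel_idx],
            "macro_region": rmap["macro_region"].to_numpy()[parcel_idx],
            "region": rmap["region"].to_numpy()[parcel_idx],
            "subject": np.array(subjects)[subj_idx],
            "diagnosis": np.array(groups)[subj_idx],
            "condition": np.array(["DR", "EO"])[cond_idx],
            "offset": offsets[subj_idx],
            "exponent": exponents[subj_idx],
            "peak_center": true_centers + jitter,
            "peak_amplitude": np.where(failed, 0.0, design.peak_amplitude),
            "peak_width": design.peak_width_hz,
            "noise_sd": design.spectrum_noise_sd,
        }
    )

    truth = {
        "seed": int(seed),
        "n_td": design.n_td,
        "n_asd": design.n_asd,
        "base_center_hz": design.base_center_hz,
        "region_effects": {r: asdict(e) for r, e in design.region_effects.items()},
        "baseline_coupling": design.baseline_coupling,
        "srs_coupling": design.srs_coupling,
        "srs_region": design.srs_region,
        "failure_prob": dict(design.failure_prob),
        "subject_sd": design.subject_sd,
    }
    return Cohort(
        design=design,
        seed=int(seed),
        covariates=covariates,
        macro_truth=macro_truth,
        micro_params=micro_params,
        truth=truth,
    )
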