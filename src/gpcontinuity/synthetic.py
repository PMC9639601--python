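"""Synthetic GP-record generator with a known provider-concentration truth.

The generator emulates the structure of UK primary-care consultation
data: patients nested in practices, several GPs per practice, and a
per-patient stream of GP contacts whose concentration on particular GPs
is controlled by covariates. It exists so every downstream stage of the
pipeline (cohort construction, continuity indices, multilevel models)
can be exercised and validated against known generative parameters
without access to any real records.

Generative model
----------------
For patient *i* in a practice with *G* GPs:

* a concentration parameter ``α_i`` with
  ``log α_i = β₀ + β_ethnicity + β_deprivation·(q_i − 1) + β_age + β_sex + u_practice``,
  where ``u_practice ~ N(0, σ_practice²)``;
* provider preference weights ``p_i ~ Dirichlet(α_i, …, α_i)`` over the
  practice's G GPs;
* a total visit count ``N_i ~ NegBin(mean μ_i, dispersion k)``, with
  ``μ_i`` scaled by the patient's at-risk fraction of the window and
  shifted by age and condition count (so consultation volume confounds
  continuity, as it does in real data);
* each visit assigned a GP iid from ``p_i`` and a date uniform over the
  patient's at-risk interval.

Small ``α_i`` concentrates the weights on one GP (UPC, COC → 1); large
``α_i`` approaches uniform allocation, for which
``E[COC] = 1/G`` exactly. More generally the Dirichlet-multinomial
structure gives the closed form ``E[COC] = (α + 1)/(Gα + 1)`` for every
visit total N ≥ 2, which the test-suite uses as an analytic oracle.

All randomness flows from the single config seed through named
``numpy.random.SeedSequence`` child streams (population = 0,
consultations = 1, practice intercepts = 2), so each stage is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "PopulationTables",
    "ConfigurationError",
    "IntegrityError",
    "generate_population",
    "generate_consultations",
    "expected_coc_uniform",
    "expected_coc_dirichlet",
    "simulate_mean_upc",
    "calibrate_offset_for_upc_gap",
]

AGE_BANDS = ("18-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+")

# Abstract long-term-condition vocabulary: labels with a physical/mental
# class stand in for real code lists, which are out of scope.
_PHYSICAL_CONDITIONS = (
    "asthma", "diabetes", "hypertension", "coronary_heart_disease", "copd",
    "arthritis", "cancer", "chronic_kidney_disease", "epilepsy", "stroke",
    "heart_failure", "atrial_fibrillation",
)
_MENTAL_CONDITIONS = (
    "depression", "anxiety", "severe_mental_illness", "dementia",
    "substance_misuse",
)

# Default ethnicity mix follows the analytic-sample proportions reported
# for English general practice (2011 Census main categories, White
# groups combined).
_DEFAULT_ETHNICITY_LEVELS = {
    "White": 0.856,
    "Indian": 0.027,
    "Black African": 0.021,
    "Pakistani": 0.018,
    "Any other Asian background": 0.017,
    "Black Caribbean": 0.014,
    "Mixed": 0.014,
    "All other ethnic groups": 0.014,
    "Bangladeshi": 0.008,
    "Any other Black background": 0.006,
    "Chinese": 0.005,
}

# Offsets on log α (positive ⇒ more diffuse care ⇒ lower continuity),
# oriented and sized to reproduce the qualitative group ordering seen in
# English primary care: lower continuity for Bangladeshi, Pakistani and
# Black groups, slightly higher for Indian and Chinese groups.
_DEFAULT_ETHNICITY_EFFECTS = {
    "White": 0.0,
    "Bangladeshi": 0.26,
    "Pakistani": 0.10,
    "Indian": -0.06,
    "Any other Asian background": -0.04,
    "Black African": 0.16,
    "Black Caribbean": 0.13,
    "Any other Black background": 0.15,
    "Chinese": -0.15,
    "Mixed": 0.04,
    "All other ethnic groups": 0.05,
}

_DEFAULT_AGE_EFFECTS = {
    "18-29": 0.0, "30-39": 0.0, "40-49": -0.07, "50-59": -0.12,
    "60-69": -0.18, "70-79": -0.22, "80+": -0.22,
}

_DEFAULT_AGE_BAND_PROBS = {
    "18-29": 0.154, "30-39": 0.169, "40-49": 0.164, "50-59": 0.174,
    "60-69": 0.141, "70-79": 0.116, "80+": 0.082,
}

# Consultation volume rises with age; log-scale offsets on the mean.
_DEFAULT_CONSULT_AGE_EFFECTS = {
    "18-29": -0.25, "30-39": -0.15, "40-49": -0.05, "50-59": 0.05,
    "60-69": 0.15, "70-79": 0.25, "80+": 0.30,
}

_DEFAULT_LTC_RATE_BY_AGE = {
    "18-29": 0.3, "30-39": 0.5, "40-49": 0.8, "50-59": 1.2,
    "60-69": 1.7, "70-79": 2.3, "80+": 2.8,
}

_DEFAULT_MODE_PROBS = {
    "face_to_face": 0.72, "telephone": 0.23, "online": 0.03, "home_visit": 0.02,
}


class ConfigurationError(ValueError):
    """An invalid generator configuration, naming the offending field."""


class IntegrityError(ValueError):
    """Referential-integrity failure between generated tables."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic population and its consultation process.

    Defaults describe a mid-sized study: 25 practices of 8 GPs and 200
    adult patients each, followed over the 4-year window 2016–2019, a
    mean of 12 GP consultations per patient over the full window with
    negative-binomial dispersion 1.4, and a baseline Dirichlet
    concentration of 0.75 (so baseline E[COC] = (0.75+1)/(8·0.75+1) = 0.25,
    the order of magnitude observed in English general practice).
    """

    n_practices: int = 25
    gps_per_practice: int = 8
    patients_per_practice: int = 200
    window_start: str = "2016-01-01"
    window_end: str = "2019-12-31"  # inclusive calendar date
    ethnicity_levels: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ETHNICITY_LEVELS))
    ethnicity_concentration_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ETHNICITY_EFFECTS))
    deprivation_effect: float = 0.05  # per quintile step above Q1, on log α
    age_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AGE_EFFECTS))
    sex_effects: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.0, "female": 0.15})
    base_log_concentration: float = float(np.log(0.75))
    practice_intercept_sd: float = 0.25
    mean_consultations: float = 12.0  # over the full window, before shifts
    consultation_dispersion: float = 1.4
    consultation_age_rate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONSULT_AGE_EFFECTS))
    consultation_rate_per_ltc: float = 0.08
    ltc_rate_by_age: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LTC_RATE_BY_AGE))
    mental_condition_fraction: float = 0.25
    exit_fraction: float = 0.10
    age_band_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AGE_BAND_PROBS))
    female_fraction: float = 0.55
    mode_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MODE_PROBS))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_practices", "gps_per_practice", "patients_per_practice"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if pd.Timestamp(self.window_start) >= pd.Timestamp(self.window_end):
            raise ConfigurationError("window_start must precede window_end")
        for name in ("practice_intercept_sd",):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("mean_consultations", "consultation_dispersion"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("mental_condition_fraction", "exit_fraction", "female_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be a probability in [0, 1]")
        for name in ("ethnicity_levels", "age_band_probs", "mode_probs"):
            probs = dict(getattr(self, name))
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError(f"{name} has a negative proportion")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} proportions must sum to 1")
        if any(r < 0 for r in dict(self.ltc_rate_by_age).values()):
            raise ConfigurationError("ltc_rate_by_age rates must be >= 0")
        missing = set(self.ethnicity_levels) - set(self.ethnicity_concentration_effects)
        if missing:
            raise ConfigurationError(
                "ethnicity_concentration_effects missing levels: "
                + ", ".join(sorted(missing))
            )

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)

    @property
    def window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        """Half-open analysis window [start, end_exclusive)."""
        return (
            pd.Timestamp(self.window_start),
            pd.Timestamp(self.window_end) + pd.Timedelta(days=1),
        )


@dataclass(frozen=True)
class PopulationTables:
    """Generated registry tables: practices, GPs, patients and conditions."""

    practices: pd.DataFrame
    gps: pd.DataFrame
    patients: pd.DataFrame
    conditions: pd.DataFrame


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # Named child streams off the root seed keep the stages independently
    # reproducible: 0 = population, 1 = consultations, 2 = practice intercepts.
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def generate_population(config: SyntheticConfig) -> PopulationTables:
    """Draw practices, GPs and patients with covariates and conditions.

    Covariates (age band, sex, ethnicity, deprivation quintile) are
    sampled independently from the configured marginals. A configurable
    fraction of patients receives an exit date uniform over the window,
    exercising follow-up truncation downstream. Condition counts are
    Poisson with an age-dependent rate; each condition is mental with
    the configured probability and has an onset date before baseline.
    """
    rng = _rng(config, 0)
    n_prac, g, per = config.n_practices, config.gps_per_practice, config.patients_per_practice
    n_pat = n_prac * per

    practices = pd.DataFrame({"practice_id": [f"prac{p:04d}" for p in range(n_prac)]})
    gps = pd.DataFrame(
        {
            "gp_id": [f"gp{p:04d}_{j:02d}" for p in range(n_prac) for j in range(g)],
            "practice_id": np.repeat(practices["practice_id"].to_numpy(), g),
        }
    )

    eth_levels = list(config.ethnicity_levels)
    eth_probs = np.array([config.ethnicity_levels[k] for k in eth_levels], dtype=float)
    bands = list(config.age_band_probs)
    band_probs = np.array([config.age_band_probs[b] for b in bands], dtype=float)

    patients = pd.DataFrame(
        {
            "patient_id": [f"pat{i:06d}" for i in range(n_pat)],
            "practice_id": np.repeat(practices["practice_id"].to_numpy(), per),
            "age_band": rng.choice(bands, size=n_pat, p=band_probs / band_probs.sum()),
            "sex": np.where(rng.random(n_pat) < config.female_fraction, "female", "male"),
            "ethnicity": rng.choice(eth_levels, size=n_pat, p=eth_probs / eth_probs.sum()),
            "imd_quintile": rng.choice(
                ["Q1", "Q2", "Q3", "Q4", "Q5"], size=n_pat
            ),
        }
    )

    start, end = config.window
    window_days = int((end - start).days)
    has_exit = rng.random(n_pat) < config.exit_fraction
    exit_offsets = rng.integers(1, window_days + 1, size=n_pat)
    exit_dates = start + pd.to_timedelta(exit_offsets, unit="D")
    patients["exit_date"] = pd.Series(exit_dates).where(has_exit, pd.NaT)

    # Long-term conditions at baseline: distinct labels per patient.
    rates = patients["age_band"].map(dict(config.ltc_rate_by_age)).to_numpy(dtype=float)
    n_cond = np.minimum(
        rng.poisson(rates), len(_PHYSICAL_CONDITIONS) + len(_MENTAL_CONDITIONS)
    )
    rows: list[tuple] = []
    baseline = start
    for pid, k in zip(patients["patient_id"], n_cond):
        if k == 0:
            continue
        n_mental = min(rng.binomial(k, config.mental_condition_fraction),
                       len(_MENTAL_CONDITIONS))
        n_phys = min(k - n_mental, len(_PHYSICAL_CONDITIONS))
        chosen = list(rng.choice(_MENTAL_CONDITIONS, size=n_mental, replace=False)) + \
            list(rng.choice(_PHYSICAL_CONDITIONS, size=n_phys, replace=False))
        for label in chosen:
            onset = baseline - pd.Timedelta(days=int(rng.integers(1, 3653)))
            rows.append(
                (pid, label,
                 "mental" if label in _MENTAL_CONDITIONS else "physical", onset)
            )
    conditions = pd.DataFrame(
        rows, columns=["patient_id", "condition", "condition_class", "onset_date"]
    )
    return PopulationTables(practices=practices, gps=gps, patients=patients,
                            conditions=conditions)


def _patient_log_alpha(pop: PopulationTables, config: SyntheticConfig) -> np.ndarray:
    """Per-patient log concentration from covariates plus practice intercepts."""
    pat = pop.patients
    rng_u = _rng(config, 2)
    practice_u = rng_u.normal(0.0, config.practice_intercept_sd, size=len(pop.practices))
    u_by_practice = dict(zip(pop.practices["practice_id"], practice_u))
    quintile = pat["imd_quintile"].str.slice(1).astype(int).to_numpy()
    log_alpha = (
        config.base_log_concentration
        + pat["ethnicity"].map(dict(config.ethnicity_concentration_effects)).to_numpy(dtype=float)
        + config.deprivation_effect * (quintile - 1)
        + pat["age_band"].map(dict(config.age_effects)).to_numpy(dtype=float)
        + pat["sex"].map(dict(config.sex_effects)).to_numpy(dtype=float)
        + pat["practice_id"].map(u_by_practice).to_numpy(dtype=float)
    )
    return log_alpha


def _dirichlet_weights(alpha: np.ndarray, n_gps: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Row-wise symmetric Dirichlet(α_i) weights over n_gps providers.

    In the α → 0 limit gamma draws underflow to exact zeros; a row that
    sums to zero is replaced by the limiting one-hot allocation on a
    uniformly chosen provider.
    """
    raw = rng.gamma(np.repeat(alpha[:, None], n_gps, axis=1))
    totals = raw.sum(axis=1)
    degenerate = totals <= 0
    if degenerate.any():
        idx = rng.integers(0, n_gps, size=int(degenerate.sum()))
        raw[degenerate] = 0.0
        raw[np.flatnonzero(degenerate), idx] = 1.0
        totals = raw.sum(axis=1)
    return raw / totals[:, None]


def generate_consultations(pop: PopulationTables,
                           config: SyntheticConfig) -> pd.DataFrame:
    """Draw the consultation event stream for a generated population.

    Returns a table with columns ``patient_id``, ``practice_id``,
    ``gp_id``, ``date`` and ``mode``, sorted by patient then date. Every
    event falls inside ``[window_start, patient exit)`` and references a
    GP of the patient's own practice.
    """
    pat = pop.patients
    known = set(pop.practices["practice_id"])
    unknown = set(pat["practice_id"]) - known
    if unknown:
        raise IntegrityError(
            f"patients reference unknown practices: {sorted(unknown)[:5]}"
        )
    rng = _rng(config, 1)
    n_pat = len(pat)
    g = config.gps_per_practice
    start, end = config.window
    window_days = int((end - start).days)

    exit_d = pd.to_datetime(pat["exit_date"])
    at_risk_days = np.where(
        exit_d.notna(), (exit_d - start).dt.days.to_numpy(), window_days
    ).astype(int)
    at_risk_days = np.clip(at_risk_days, 0, window_days)

    ltc_counts = (
        pop.conditions.groupby("patient_id").size()
        .reindex(pat["patient_id"], fill_value=0).to_numpy()
        if len(pop.conditions) else np.zeros(n_pat, dtype=int)
    )
    log_mu = (
        np.log(config.mean_consultations)
        + pat["age_band"].map(dict(config.consultation_age_rate_effects)).to_numpy(dtype=float)
        + config.consultation_rate_per_ltc * ltc_counts
        + np.log(np.maximum(at_risk_days, 1) / window_days)
    )
    mu = np.where(at_risk_days > 0, np.exp(log_mu), 0.0)
    k = config.consultation_dispersion
    n_visits = np.where(
        mu > 0, rng.negative_binomial(k, k / (k + np.maximum(mu, 1e-12))), 0
    ).astype(int)

    alpha = np.clip(np.exp(_patient_log_alpha(pop, config)), 1e-12, 1e12)
    weights = _dirichlet_weights(alpha, g, rng)

    total_events = int(n_visits.sum())
    pat_idx = np.repeat(np.arange(n_pat), n_visits)
    # Provider per visit: invert the per-patient weight CDF.
    cdf = np.cumsum(weights, axis=1)
    u = rng.random(total_events)
    gp_local = (u[:, None] > cdf[pat_idx]).sum(axis=1)
    practice_codes = pd.Categorical(
        pat["practice_id"], categories=pop.practices["practice_id"]
    ).codes
    gp_ids = pop.gps["gp_id"].to_numpy().reshape(len(pop.practices), g)
    gp_col = gp_ids[practice_codes[pat_idx], gp_local]

    offsets = np.floor(rng.random(total_events) * at_risk_days[pat_idx]).astype(int)
    dates = start + pd.to_timedelta(offsets, unit="D")

    modes = list(config.mode_probs)
    mode_p = np.array([config.mode_probs[m] for m in modes], dtype=float)
    mode_col = rng.choice(modes, size=total_events, p=mode_p / mode_p.sum())

    events = pd.DataFrame(
        {
            "patient_id": pat["patient_id"].to_numpy()[pat_idx],
            "practice_id": pat["practice_id"].to_numpy()[pat_idx],
            "gp_id": gp_col,
            "date": dates,
            "mode": mode_col,
        }
    )
    return events.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)


def expected_coc_uniform(n_gps: int) -> float:
    """Expected COC under uniform multinomial allocation over ``n_gps`` GPs.

    With N visits allocated multinomial(N, 1/G): E[Σ n_i²] = N + N(N−1)/G,
    so E[COC] = 1/G exactly, independent of N.
    """
    if n_gps < 1:
        raise ValueError("n_gps must be >= 1")
    return 1.0 / n_gps


def expected_coc_dirichlet(alpha: float, n_gps: int) -> float:
    """Expected COC under the Dirichlet-multinomial provider model.

    Conditional on weights p, E[COC | p, N] = Σ p_i²; averaging over
    p ~ Dirichlet(α, …, α) gives (α + 1)/(Gα + 1) for every N ≥ 2.
    Recovers 1 as α → 0 and 1/G as α → ∞.
    """
    if n_gps < 1:
        raise ValueError("n_gps must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return (alpha + 1.0) / (n_gps * alpha + 1.0)


def simulate_mean_upc(
    log_alpha: float,
    n_gps: int,
    mean_consultations: float,
    dispersion: float,
    n_patients: int,
    rng: np.random.Generator,
    min_consultations: int = 3,
) -> float:
    """Monte-Carlo mean UPC at a single concentration value.

    Simulates ``n_patients`` independent patients from the generator's
    visit-allocation law (negative-binomial totals, symmetric-Dirichlet
    weights, iid provider draws), keeps those meeting the visit minimum
    and returns their mean UPC. This is the calibration oracle mapping
    log-concentration offsets to mean-UPC differences; mean UPC has no
    convenient closed form, unlike mean COC.
    """
    k = dispersion
    mu = mean_consultations
    n = rng.negative_binomial(k, k / (k + mu), size=n_patients)
    keep = n >= min_consultations
    n = n[keep]
    alpha = float(np.clip(np.exp(log_alpha), 1e-12, 1e12))
    weights = _dirichlet_weights(np.full(n.size, alpha), n_gps, rng)
    cdf = np.cumsum(weights, axis=1)
    pat_idx = np.repeat(np.arange(n.size), n)
    u = rng.random(int(n.sum()))
    gp = (u[:, None] > cdf[pat_idx]).sum(axis=1)
    flat = pat_idx * n_gps + gp
    counts = np.bincount(flat, minlength=n.size * n_gps).reshape(n.size, n_gps)
    return float(np.mean(counts.max(axis=1) / n))


def calibrate_offset_for_upc_gap(
    target_gap: float,
    base_log_concentration: float = float(np.log(0.75)),
    n_gps: int = 8,
    mean_consultations: float = 12.0,
    dispersion: float = 1.4,
    n_patients: int = 40000,
    seed: int = 20160101,
    bracket: tuple[float, float] = (0.0, 2.0),
    tol: float = 1e-3,
) -> float:
    """Find the log-α offset producing a target mean-UPC gap vs baseline.

    Solves ``mean_upc(base + δ) − mean_upc(base) = target_gap`` (gap < 0
    for lower continuity) by bisection on δ, using common random numbers
    across evaluations so the simulated objective is monotone and smooth
    in δ. The returned offset is deterministic given the seed.
    """
    if target_gap >= 0:
        raise ValueError("target_gap must be negative (lower continuity)")

    def mean_at(delta: float) -> float:
        rng = np.random.default_rng(seed)
        return simulate_mean_upc(
            base_log_concentration + delta, n_gps, mean_consultations,
            dispersion, n_patients, rng,
        )

    base = mean_at(0.0)
    lo, hi = bracket
    f_hi = mean_at(hi) - base - target_gap
    if f_hi > 0:
        raise ValueError("bracket upper bound too small for the requested gap")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mean_at(mid) - base - target_gap > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
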