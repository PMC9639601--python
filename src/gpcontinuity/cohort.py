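"""Analysis-ready cohort construction from raw GP record tables.

Applies the study eligibility rules (registered at baseline, adult,
minimum consultation count with a GP in an allowed mode), computes
follow-up time truncated by deregistration, harmonizes ethnicity coded
in two sources (primary care taking precedence over hospital records),
and counts long-term conditions at baseline with the four-way
physical/mental combination category.

All window-membership tests use the half-open convention
``[baseline_date, end + 1 day)`` where ``window_end`` is an inclusive
calendar date, so the default 2016-01-01 – 2019-12-31 study window spans
exactly 4.0 years of 365.25 days.
"""

from __future__ import annotations

from collections import Counter, OrderedDict
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import DEFAULT_MODES, compute_continuity_table

__all__ = [
    "CohortSpec",
    "SchemaError",
    "CodingError",
    "ETHNICITY_MAIN_11",
    "ETHNICITY_DISAGGREGATED",
    "LTC_CATEGORIES",
    "EXCLUSION_ORDER",
    "harmonize_ethnicity",
    "count_ltc",
    "compute_follow_up",
    "filter_eligible_patients",
    "build_cohort",
]

DAYS_PER_YEAR = 365.25


class SchemaError(ValueError):
    """An input table is missing required columns."""


class CodingError(ValueError):
    """An unrecognised category value in a coded field."""


#: Main analysis scheme: 2011 Census categories with the White groups
#: combined to limit loss to missing detailed coding.
ETHNICITY_MAIN_11 = (
    "White", "Mixed", "Indian", "Pakistani", "Bangladeshi", "Chinese",
    "Any other Asian background", "Black African", "Black Caribbean",
    "Any other Black background", "All other ethnic groups",
)

#: Sensitivity scheme: White and mixed groups disaggregated.
ETHNICITY_DISAGGREGATED = (
    "White British", "Irish", "Other White",
    "White and Asian", "White and Black African", "White and Black Caribbean",
    "Other mixed",
    "Indian", "Pakistani", "Bangladeshi", "Chinese",
    "Any other Asian background", "Black African", "Black Caribbean",
    "Any other Black background", "All other ethnic groups",
)

#: Collapse map from the disaggregated scheme onto the main scheme.
_TO_MAIN_11 = {
    "White British": "White", "Irish": "White", "Other White": "White",
    "White and Asian": "Mixed", "White and Black African": "Mixed",
    "White and Black Caribbean": "Mixed", "Other mixed": "Mixed",
}

LTC_CATEGORIES = ("0-1", "2+ physical", "2+ mental", "physical+mental")

#: Fixed order in which exclusion reasons are applied and tallied.
EXCLUSION_ORDER = (
    "not_registered_at_baseline",
    "below_minimum_age",
    "failed_quality_or_linkage",
    "fewer_than_minimum_consultations",
    "missing_covariates",
)


@dataclass(frozen=True)
class CohortSpec:
    """Eligibility and window rules defining the analytic cohort.

    ``window_end`` is an inclusive calendar date. Defaults reproduce the
    study design: baseline 1 January 2016, follow-up to 31 December
    2019, adults only, at least three GP consultations in person, by
    telephone or online.
    """

    baseline_date: str = "2016-01-01"
    window_end: str = "2019-12-31"
    min_age_years: int = 18
    min_consultations: int = 3
    allowed_modes: frozenset = field(default_factory=lambda: DEFAULT_MODES)

    def __post_init__(self) -> None:
        if pd.Timestamp(self.baseline_date) >= pd.Timestamp(self.window_end):
            raise ValueError("baseline_date must precede window_end")
        if self.min_consultations < 1:
            raise ValueError("min_consultations must be >= 1")
        if not self.allowed_modes:
            raise ValueError("allowed_modes must be nonempty")

    def replace(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)

    @property
    def window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        """Half-open analysis window [baseline, end + 1 day)."""
        return (
            pd.Timestamp(self.baseline_date),
            pd.Timestamp(self.window_end) + pd.Timedelta(days=1),
        )


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing columns: {missing}")


def harmonize_ethnicity(primary_care_codes, hospital_codes,
                        scheme: str = "main-11"):
    """Resolve a patient's ethnicity from two coded sources.

    Each source is a list of ``(date, category)`` observations. The
    primary-care source takes precedence whenever it has any
    observation; hospital records are a fallback only. Within a source
    the modal category wins; ties are broken by the most recent
    observation, then by the scheme's fixed category order. Returns
    ``None`` when both sources are empty.

    In the ``main-11`` scheme detailed White and mixed categories are
    collapsed ("White British", "Irish" and "Other White" to "White";
    mixed subgroups to "Mixed").
    """
    if scheme not in ("main-11", "disaggregated"):
        raise ValueError(f"unknown scheme {scheme!r}")
    valid = set(ETHNICITY_DISAGGREGATED) | set(ETHNICITY_MAIN_11)
    obs = list(primary_care_codes) if primary_care_codes else []
    if not obs:
        obs = list(hospital_codes) if hospital_codes else []
    if not obs:
        return None
    for _, cat in obs:
        if cat not in valid:
            raise CodingError(f"unknown ethnicity category {cat!r}")
    if scheme == "main-11":
        obs = [(d, _TO_MAIN_11.get(c, c)) for d, c in obs]
        order = ETHNICITY_MAIN_11
    else:
        order = ETHNICITY_DISAGGREGATED
    tally = Counter(c for _, c in obs)
    top = max(tally.values())
    candidates = {c for c, n in tally.items() if n == top}
    if len(candidates) == 1:
        return candidates.pop()
    latest: dict[str, pd.Timestamp] = {}
    for d, c in obs:
        if c in candidates:
            d = pd.Timestamp(d)
            if c not in latest or d > latest[c]:
                latest[c] = d
    newest = max(latest.values())
    candidates = {c for c, d in latest.items() if d == newest}
    for c in order:
        if c in candidates:
            return c
    return sorted(candidates)[0]  # unreachable for known categories


def count_ltc(conditions, baseline_date) -> tuple[int, str]:
    """Count distinct long-term conditions present at baseline and classify.

    ``conditions`` is an iterable of ``(label, condition_class, onset_date)``
    (or a DataFrame with those columns); only conditions with onset on or
    before the baseline date count. The four-way category applies the
    precedence: 0–1 conditions → ``"0-1"``; at least one physical and one
    mental → ``"physical+mental"`` (this takes priority, so a patient
    with ≥2 of each is "physical+mental"); otherwise ``"2+ physical"`` or
    ``"2+ mental"``.
    """
    baseline = pd.Timestamp(baseline_date)
    if isinstance(conditions, pd.DataFrame):
        _require_columns(
            conditions, ("condition", "condition_class", "onset_date"), "conditions")
        items = conditions[["condition", "condition_class", "onset_date"]].itertuples(
            index=False)
    else:
        items = conditions
    seen: dict[str, str] = {}
    for label, clazz, onset in items:
        if clazz not in ("physical", "mental"):
            raise SchemaError(
                f"condition {label!r} has invalid class {clazz!r} "
                "(expected 'physical' or 'mental')"
            )
        if pd.Timestamp(onset) <= baseline:
            seen[label] = clazz
    count = len(seen)
    classes = set(seen.values())
    if count <= 1:
        category = "0-1"
    elif classes == {"physical", "mental"}:
        category = "physical+mental"
    elif classes == {"physical"}:
        category = "2+ physical"
    else:
        category = "2+ mental"
    return count, category


def compute_follow_up(exit_date, spec: CohortSpec,
                      practice_end_date=None) -> float:
    """Follow-up years from baseline to exit, practice closure or window end.

    ``(min(exit, practice_end, window_end + 1 day) − baseline)`` in
    365.25-day years. An exit on the baseline date yields 0; an exit
    before baseline is a contract violation (such patients are excluded
    upstream as not registered at baseline).
    """
    baseline, end = spec.window
    stop = end
    for candidate in (exit_date, practice_end_date):
        if candidate is not None and not pd.isna(candidate):
            stop = min(stop, pd.Timestamp(candidate))
    if stop < baseline:
        raise ValueError(
            f"exit date {stop.date()} precedes baseline {baseline.date()}; "
            "patient should have been excluded upstream"
        )
    return float((stop - baseline).days) / DAYS_PER_YEAR


_AGE_BAND_LOWER = {
    "<18": 0,  # pre-adult band, only ever seen on excluded patients
    "18-29": 18, "30-39": 30, "40-49": 40, "50-59": 50,
    "60-69": 60, "70-79": 70, "80+": 80,
}


def _age_at_baseline(patients: pd.DataFrame, baseline: pd.Timestamp) -> pd.Series:
    """Age in whole years at baseline, from age band or birth year."""
    if "age_band" in patients.columns:
        known = patients["age_band"].map(_AGE_BAND_LOWER)
        if known.isna().any() and patients["age_band"].notna().any():
            bad = patients.loc[
                known.isna() & patients["age_band"].notna(), "age_band"
            ].unique()
            if len(bad):
                raise CodingError(f"unknown age bands: {list(bad)[:5]}")
        return known
    if "birth_year" in patients.columns:
        return baseline.year - patients["birth_year"]
    raise SchemaError("patients table needs an 'age_band' or 'birth_year' column")


def filter_eligible_patients(
    patients: pd.DataFrame,
    consultations: pd.DataFrame,
    spec: CohortSpec,
) -> tuple[pd.DataFrame, "OrderedDict[str, int]"]:
    """Apply the eligibility rules; return survivors and exclusion tallies.

    Rules, applied in a fixed order so each patient is tallied under the
    first reason that excludes them:

    1. registered at baseline (registration on/before baseline if a
       ``registration_date`` column exists; exit after baseline);
    2. age ≥ the minimum at baseline;
    3. an acceptable ``quality_flag``, when that column is supplied;
    4. at least ``min_consultations`` events with a GP, in an allowed
       mode, inside ``[baseline, min(exit, window end))``;
    5. no missing analysis covariates (sex, ethnicity when present,
       deprivation quintile when present).

    Tallies plus survivors always sum to the input patient count.
    """
    _require_columns(patients, ("patient_id", "practice_id"), "patients")
    _require_columns(
        consultations, ("patient_id", "gp_id", "date", "mode"), "consultations")
    baseline, end = spec.window

    pat = patients.drop_duplicates("patient_id").copy()
    excluded = pd.Series("", index=pat.index, dtype=object)

    exit_d = (
        pd.to_datetime(pat["exit_date"]) if "exit_date" in pat.columns
        else pd.Series(pd.NaT, index=pat.index)
    )
    registered = exit_d.isna() | (exit_d > baseline)
    if "registration_date" in pat.columns:
        reg_d = pd.to_datetime(pat["registration_date"])
        registered &= reg_d.notna() & (reg_d <= baseline)
    excluded[~registered] = "not_registered_at_baseline"

    age = _age_at_baseline(pat, baseline)
    ok_age = age.notna() & (age >= spec.min_age_years)
    excluded[(excluded == "") & ~ok_age] = "below_minimum_age"

    if "quality_flag" in pat.columns:
        ok_quality = pat["quality_flag"].fillna(False).astype(bool)
        excluded[(excluded == "") & ~ok_quality] = "failed_quality_or_linkage"

    # Qualifying consultations per patient within the patient's own window.
    ev = consultations.copy()
    ev_dates = pd.to_datetime(ev["date"])
    ev = ev[ev["mode"].isin(spec.allowed_modes) & (ev_dates >= baseline)
            & (ev_dates < end)]
    exit_by_pid = dict(zip(pat["patient_id"], exit_d))
    if exit_d.notna().any():
        ev_exit = ev["patient_id"].map(exit_by_pid)
        ev = ev[ev_exit.isna() | (pd.to_datetime(ev["date"]) < ev_exit)]
    n_by_pid = ev.groupby("patient_id").size()
    n_cons = pat["patient_id"].map(n_by_pid).fillna(0).astype(int)
    n_cons.index = pat.index
    excluded[(excluded == "") & (n_cons < spec.min_consultations)] = (
        "fewer_than_minimum_consultations")

    covariate_cols = [c for c in ("sex", "ethnicity", "imd_quintile") if c in pat.columns]
    if covariate_cols:
        missing_cov = pat[covariate_cols].isna().any(axis=1)
        excluded[(excluded == "") & missing_cov] = "missing_covariates"

    tallies: "OrderedDict[str, int]" = OrderedDict(
        (reason, int((excluded == reason).sum())) for reason in EXCLUSION_ORDER
    )
    survivors = pat[excluded == ""].copy()
    tallies["eligible"] = len(survivors)
    return survivors, tallies


def build_cohort(
    patients: pd.DataFrame,
    consultations: pd.DataFrame,
    conditions: pd.DataFrame | None = None,
    spec: CohortSpec | None = None,
    scheme: str = "main-11",
) -> tuple[pd.DataFrame, "OrderedDict[str, int]"]:
    """Assemble the analysis-ready cohort table and the exclusion flow.

    One row per eligible patient with demographics, deprivation
    quintile, follow-up years, consultation total, continuity indices
    (UPC, COC) over the study window, and the baseline long-term
    condition count and category. Patients whose ethnicity arrives as
    raw two-source observations (columns ``ethnicity_obs_primary`` /
    ``ethnicity_obs_hospital`` holding lists of ``(date, category)``)
    are harmonized here; a pre-resolved ``ethnicity`` column is used
    as-is, mapped onto the requested scheme.

    Returns ``(cohort, flow)`` where ``flow`` is the ordered
    exclusion-reason tally ending with the eligible count.
    """
    spec = spec or CohortSpec()
    pat = patients.copy()

    if "ethnicity_obs_primary" in pat.columns or "ethnicity_obs_hospital" in pat.columns:
        prim = pat.get("ethnicity_obs_primary", pd.Series([None] * len(pat)))
        hosp = pat.get("ethnicity_obs_hospital", pd.Series([None] * len(pat)))
        pat["ethnicity"] = [
            harmonize_ethnicity(p, h, scheme) for p, h in zip(prim, hosp)
        ]
    elif "ethnicity" in pat.columns and scheme == "main-11":
        pat["ethnicity"] = pat["ethnicity"].map(
            lambda c: _TO_MAIN_11.get(c, c) if pd.notna(c) else c)

    eligible, flow = filter_eligible_patients(pat, consultations, spec)

    baseline, end = spec.window
    exit_d = (
        pd.to_datetime(eligible["exit_date"]) if "exit_date" in eligible.columns
        else pd.Series(pd.NaT, index=eligible.index)
    )
    follow_up = [
        compute_follow_up(x if pd.notna(x) else None, spec) for x in exit_d
    ]

    # Indices are computed over the fixed calendar window intersected with
    # each patient's registration period, matching the eligibility count.
    ev = consultations
    if "exit_date" in pat.columns:
        exit_by_pid = dict(
            zip(pat["patient_id"], pd.to_datetime(pat["exit_date"]))
        )
        ev_exit = ev["patient_id"].map(exit_by_pid)
        ev = ev[ev_exit.isna() | (pd.to_datetime(ev["date"]) < ev_exit)]
    continuity = compute_continuity_table(
        ev, (baseline, end),
        min_consultations=spec.min_consultations,
        allowed_modes=spec.allowed_modes,
    ).set_index("patient_id")

    if conditions is not None and len(conditions):
        _require_columns(
            conditions, ("patient_id", "condition", "condition_class", "onset_date"),
            "conditions")
        ltc = {
            pid: count_ltc(grp[["condition", "condition_class", "onset_date"]],
                           spec.baseline_date)
            for pid, grp in conditions.groupby("patient_id")
        }
    else:
        ltc = {}

    rows = eligible.reset_index(drop=True)
    pids = rows["patient_id"]
    cont = continuity.reindex(pids)
    ltc_pairs = [ltc.get(p, (0, "0-1")) for p in pids]
    cohort = pd.DataFrame(
        {
            "patient_id": pids.to_numpy(),
            "practice_id": rows["practice_id"].to_numpy(),
            "age_band": rows["age_band"].to_numpy() if "age_band" in rows else None,
            "sex": rows["sex"].to_numpy() if "sex" in rows else None,
            "ethnicity": rows["ethnicity"].to_numpy() if "ethnicity" in rows else None,
            "imd_quintile": (
                rows["imd_quintile"].to_numpy() if "imd_quintile" in rows else None),
            "follow_up_years": np.asarray(follow_up, dtype=float),
            "n_consultations": cont["n_consultations"].to_numpy(),
            "ltc_count": [c for c, _ in ltc_pairs],
            "ltc_category": [cat for _, cat in ltc_pairs],
            "upc": cont["upc"].to_numpy(),
            "coc": cont["coc"].to_numpy(),
        }
    )
    # The eligibility filter counts exactly the same qualifying events as
    # the continuity table, so every eligible patient has a profile row.
    assert not cohort["n_consultations"].isna().any()
    cohort["n_consultations"] = cohort["n_consultations"].astype(int)
    cohort = cohort.sort_values("patient_id", kind="stable").reset_index(drop=True)
    return cohort, flow
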