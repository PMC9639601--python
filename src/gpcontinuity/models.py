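"""Multilevel linear regression of continuity indices on patient covariates.

The outcome (UPC or COC) is modelled untransformed on its [0, 1] scale
with a linear mixed model: patient-level residual plus a GP-practice
random intercept to absorb the clustering of patients within practices.
Fits use restricted maximum likelihood by default. Every model includes
follow-up time (years) and total consultation count as continuous
nuisance terms, because both mechanically depress the indices.

The model sequence mirrors the standard sequential-adjustment design
for describing group differences:

* **Model 1** — each covariate separately (plus the two nuisance terms);
* **Model 2** — age + sex + deprivation + long-term-condition count +
  ethnicity, jointly;
* **Model 3** — as model 2 with the four-way condition *category*
  replacing the count;
* **Model 4** — model-2 covariates without condition terms, restricted
  to the subgroup with ≥2 long-term conditions.

95% confidence intervals are Wald intervals, estimate ± 1.96·SE.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import norm

from .cohort import SchemaError

__all__ = [
    "ModelSpec",
    "FitResult",
    "DegenerateDesignError",
    "REFERENCE_LEVELS",
    "make_model_spec",
    "fit_mixed_model",
    "run_model_suite",
]

log = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

#: Declared reference levels for the categorical covariates.
REFERENCE_LEVELS = {
    "age_band": "18-29",
    "sex": "male",
    "imd_quintile": "Q1",
    "ethnicity": "White",
    "ltc_category": "0-1",
}

#: Nuisance terms included in every fit.
ALWAYS_INCLUDED = ("follow_up_years", "n_consultations")

_CONTINUOUS = {"follow_up_years", "n_consultations", "ltc_count"}


class DegenerateDesignError(ValueError):
    """Design cannot support a practice random intercept."""


@dataclass(frozen=True)
class ModelSpec:
    """One regression: outcome, covariates, optional subgroup restriction."""

    outcome: str
    covariates: tuple[str, ...]
    model_id: str
    subgroup_query: str | None = None
    reference_levels: dict = field(default_factory=lambda: dict(REFERENCE_LEVELS))

    def __post_init__(self) -> None:
        if self.outcome not in ("upc", "coc"):
            raise ValueError(f"outcome must be 'upc' or 'coc', got {self.outcome!r}")
        if "ltc_count" in self.covariates and "ltc_category" in self.covariates:
            raise ValueError(
                "a model uses the condition count or the category, not both")


@dataclass
class FitResult:
    """Fixed effects with Wald CIs plus variance components for one fit."""

    model_id: str
    outcome: str
    terms: pd.DataFrame  # covariate, level, estimate, se, ci_low, ci_high, pvalue
    practice_variance: float
    residual_variance: float
    n_patients: int
    n_practices: int
    converged: bool
    n_dropped_missing: int = 0


_ADJUSTED_COVARIATES = (
    "age_band", "sex", "imd_quintile", "ltc_count", "ethnicity")


def make_model_spec(model_id: str, outcome: str = "upc") -> list[ModelSpec]:
    """Expand a model id into concrete :class:`ModelSpec` objects.

    Model 1 expands to one spec per covariate; the others are single
    fits. ``sensitivity-12m`` and ``sensitivity-disaggregated`` share
    the fully adjusted (model 2) design and differ only in the cohort
    they are given (12-month window; disaggregated ethnicity scheme,
    where the reference level becomes "White British").
    """
    if model_id == "1":
        return [
            ModelSpec(outcome=outcome, covariates=(cov,), model_id=f"1:{cov}")
            for cov in _ADJUSTED_COVARIATES
        ]
    if model_id in ("2", "sensitivity-12m"):
        return [ModelSpec(outcome=outcome, covariates=_ADJUSTED_COVARIATES,
                          model_id=model_id)]
    if model_id == "sensitivity-disaggregated":
        refs = dict(REFERENCE_LEVELS, ethnicity="White British")
        return [ModelSpec(outcome=outcome, covariates=_ADJUSTED_COVARIATES,
                          model_id=model_id, reference_levels=refs)]
    if model_id == "3":
        covs = tuple(c if c != "ltc_count" else "ltc_category"
                     for c in _ADJUSTED_COVARIATES)
        return [ModelSpec(outcome=outcome, covariates=covs, model_id="3")]
    if model_id == "4":
        covs = tuple(c for c in _ADJUSTED_COVARIATES if c != "ltc_count")
        return [ModelSpec(outcome=outcome, covariates=covs, model_id="4",
                          subgroup_query="ltc_count >= 2")]
    raise ValueError(f"unknown model id {model_id!r}")


def _term_snippet(cov: str, refs: dict) -> str:
    if cov in _CONTINUOUS:
        return cov
    ref = refs.get(cov)
    if ref is None:
        return f"C({cov})"
    return f"C({cov}, Treatment('{ref}'))"


_TERM_RE = re.compile(r"C\((\w+), Treatment\('(.*?)'\)\)\[T\.(.*)\]")


def _parse_term(name: str) -> tuple[str, str]:
    m = _TERM_RE.match(name)
    if m:
        return m.group(1), m.group(3)
    if name == "Intercept":
        return "intercept", ""
    return name, ""


def build_formula(spec: ModelSpec) -> str:
    terms = [*ALWAYS_INCLUDED,
             *(_term_snippet(c, spec.reference_levels) for c in spec.covariates)]
    return f"{spec.outcome} ~ " + " + ".join(terms)


def fit_mixed_model(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    reml: bool = True,
    group_col: str = "practice_id",
) -> FitResult:
    """Fit one practice-random-intercept model on the cohort table.

    Rows with missing values in the modelled columns are dropped
    (complete-case analysis) with the count recorded on the result.
    Non-convergence is reported on the ``converged`` flag rather than
    raised, so a model suite completes with diagnostics. A single
    practice cannot identify the random intercept and raises
    :class:`DegenerateDesignError` advising an ordinary least-squares fit.
    """
    needed = [spec.outcome, *ALWAYS_INCLUDED, *spec.covariates, group_col]
    missing_cols = [c for c in needed if c not in cohort.columns]
    if missing_cols:
        raise SchemaError(
            f"model {spec.model_id}: cohort is missing columns {missing_cols}")

    data = cohort
    if spec.subgroup_query:
        data = data.query(spec.subgroup_query)
    n_before = len(data)
    data = data.dropna(subset=needed)
    n_dropped = n_before - len(data)
    if n_dropped:
        log.info("model %s: dropped %d rows with missing values",
                 spec.model_id, n_dropped)
    if data.empty:
        raise ValueError(f"model {spec.model_id}: no rows after filtering")
    n_practices = data[group_col].nunique()
    if n_practices < 2:
        raise DegenerateDesignError(
            f"model {spec.model_id}: only {n_practices} practice(s); a "
            "practice random intercept is not identifiable — fit ordinary "
            "least squares instead"
        )

    for cov in (*ALWAYS_INCLUDED, *spec.covariates):
        if data[cov].nunique(dropna=True) < 2:
            raise DegenerateDesignError(
                f"model {spec.model_id}: covariate {cov!r} is constant in "
                "the modelled rows and cannot be estimated"
            )

    formula = build_formula(spec)
    md = smf.mixedlm(formula, data, groups=data[group_col])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = md.fit(reml=reml)
    converged = bool(getattr(res, "converged", False))
    if not converged:
        log.warning("model %s did not converge; estimates are flagged",
                    spec.model_id)

    fe = res.fe_params
    se = res.bse_fe
    rows = []
    for name in fe.index:
        cov, level = _parse_term(name)
        est, s = float(fe[name]), float(se[name])
        z = est / s if s > 0 else np.nan
        rows.append(
            {
                "covariate": cov,
                "level": level,
                "estimate": est,
                "se": s,
                "ci_low": est - Z_95 * s,
                "ci_high": est + Z_95 * s,
                "pvalue": float(2 * norm.sf(abs(z))) if np.isfinite(z) else np.nan,
            }
        )
    terms = pd.DataFrame(rows)
    return FitResult(
        model_id=spec.model_id,
        outcome=spec.outcome,
        terms=terms,
        practice_variance=float(np.asarray(res.cov_re)[0, 0]),
        residual_variance=float(res.scale),
        n_patients=len(data),
        n_practices=int(n_practices),
        converged=converged,
        n_dropped_missing=int(n_dropped),
    )


def ols_fixed_effects(cohort: pd.DataFrame, spec: ModelSpec) -> pd.Series:
    """Fixed effects of the same design under zero practice variance.

    Evaluates the mixed model's generalized-least-squares solve with the
    random-intercept variance pinned at zero, which reduces exactly to
    ordinary least squares on the same design matrix. Useful as a
    degenerate-case cross-check and for single-practice data.
    """
    data = cohort.dropna(
        subset=[spec.outcome, *ALWAYS_INCLUDED, *spec.covariates])
    if spec.subgroup_query:
        data = data.query(spec.subgroup_query)
    md = smf.mixedlm(build_formula(spec), data, groups=data["practice_id"])
    # Evaluate the GLS solve in the tau^2 -> 0 limit: a practice variance
    # twelve orders below the outcome scale is numerically indistinguishable
    # from zero while keeping the solver on its non-singular path.
    params, _singular = md.get_fe_params(
        np.array([[1e-12]]), np.zeros(0), tol=1e-14)
    return pd.Series(np.asarray(params).ravel(), index=md.exog_names)


def run_model_suite(
    cohort: pd.DataFrame,
    outcome: str = "upc",
    model_ids: tuple[str, ...] = ("1", "2", "3", "4"),
    reml: bool = True,
) -> dict[str, FitResult]:
    """Fit the configured model sequence; returns results keyed by model id.

    Model 1 contributes one entry per covariate (keys ``1:age_band``,
    ``1:ethnicity``, …). A subgroup model whose restriction leaves no
    rows is skipped with a logged warning rather than failing the suite.
    """
    results: dict[str, FitResult] = {}
    for model_id in model_ids:
        for spec in make_model_spec(model_id, outcome):
            if spec.subgroup_query is not None:
                if cohort.query(spec.subgroup_query).empty:
                    log.warning(
                        "model %s skipped: subgroup %r selects no rows",
                        spec.model_id, spec.subgroup_query)
                    continue
            results[spec.model_id] = fit_mixed_model(cohort, spec, reml=reml)
    return results
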