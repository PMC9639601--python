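"""Descriptive tables, interpretation arithmetic and coefficient exports.

Produces the two standard presentation artifacts of a continuity
analysis — a descriptive table of cohort composition with mean (SD)
continuity by stratum, and a long-format coefficient table suitable for
a forest plot — plus the small arithmetic that converts a UPC
difference between two groups into "one additional consultation with
the usual GP per so-many visits".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import FitResult

__all__ = [
    "table_one",
    "format_table_one",
    "visits_per_extra_same_gp_consultation",
    "coefficient_report",
    "forest_plot",
]

_BLOCKS = (
    ("age_band", None),
    ("sex", None),
    ("imd_quintile", None),
    ("ethnicity", None),
    ("ltc_group", None),
    ("ltc_category", "ltc_count >= 2"),
)


def table_one(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort description: n (%) and mean (SD) of UPC and COC per stratum.

    One block per stratifier — age band, sex, deprivation quintile,
    ethnicity, condition burden (0–1 vs ≥2), and the condition-type
    category within the ≥2 subgroup. Percentages are relative to the
    block's denominator and sum to 100 within each block. Values are
    returned at full precision; see :func:`format_table_one` for the
    printed form.
    """
    if cohort.empty:
        raise ValueError("cannot describe an empty cohort")
    df = cohort.copy()
    df["ltc_group"] = np.where(df["ltc_count"] >= 2, "2+", "0-1")
    out = []
    for block, query in _BLOCKS:
        sub = df.query(query) if query else df
        if block not in sub.columns or sub[block].isna().all():
            continue
        denom = len(sub)
        for level, grp in sub.groupby(block, observed=True, sort=True):
            out.append(
                {
                    "block": block,
                    "level": level,
                    "n": len(grp),
                    "pct": 100.0 * len(grp) / denom,
                    "upc_mean": float(grp["upc"].mean()),
                    "upc_sd": float(grp["upc"].std(ddof=1)) if len(grp) > 1 else 0.0,
                    "coc_mean": float(grp["coc"].mean()),
                    "coc_sd": float(grp["coc"].std(ddof=1)) if len(grp) > 1 else 0.0,
                }
            )
    return pd.DataFrame(out)


def format_table_one(table: pd.DataFrame) -> pd.DataFrame:
    """Render the descriptive table at presentation precision.

    Percentages to 1 decimal place and indices to 2, the customary
    precision for these tables; stored values keep full precision.
    """
    t = table.copy()
    t["n (%)"] = [f"{n} ({p:.1f})" for n, p in zip(t["n"], t["pct"])]
    t["UPC, mean (SD)"] = [
        f"{m:.2f} ({s:.2f})" for m, s in zip(t["upc_mean"], t["upc_sd"])]
    t["COC, mean (SD)"] = [
        f"{m:.2f} ({s:.2f})" for m, s in zip(t["coc_mean"], t["coc_sd"])]
    return t[["block", "level", "n (%)", "UPC, mean (SD)", "COC, mean (SD)"]]


def visits_per_extra_same_gp_consultation(mean_upc_a: float,
                                          mean_upc_b: float) -> float:
    """Visits over which group *a* accrues one extra usual-GP consultation.

    A UPC gap of Δ between two groups means that per visit, group *a*
    sees its most frequent GP Δ more often, i.e. one additional
    consultation with that GP every ``1/Δ`` visits. For example, mean
    UPCs of 0.45 and 0.41 give 1/0.04 = 25 visits.
    """
    for name, v in (("mean_upc_a", mean_upc_a), ("mean_upc_b", mean_upc_b)):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1], got {v}")
    gap = mean_upc_a - mean_upc_b
    if gap <= 0:
        raise ValueError(
            "mean_upc_a must exceed mean_upc_b; equal means give no "
            "additional-consultation interpretation"
        )
    return 1.0 / gap


def coefficient_report(fits: dict[str, FitResult],
                       alpha: float = 0.05) -> pd.DataFrame:
    """Long-format coefficient table across fitted models.

    One row per non-intercept fixed-effect term and model, with
    estimate, SE, Wald 95% CI, p-value and a significance marker
    (two-sided Wald p < 0.05, no multiple-testing correction — matching
    the usual presentation convention for these analyses). Reference
    levels are absorbed into the intercept and therefore absent. The
    export carries everything needed to draw a forest plot.
    """
    rows = []
    for model_id, fit in fits.items():
        t = fit.terms
        t = t[t["covariate"] != "intercept"]
        for _, r in t.iterrows():
            rows.append(
                {
                    "model_id": model_id,
                    "outcome": fit.outcome,
                    "covariate": r["covariate"],
                    "level": r["level"],
                    "estimate": r["estimate"],
                    "se": r["se"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "pvalue": r["pvalue"],
                    "significant": bool(r["pvalue"] < alpha),
                    "n_patients": fit.n_patients,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


def forest_plot(report: pd.DataFrame, covariate: str = "ethnicity",
                model_id: str = "2", path=None):
    """Draw a forest plot of one covariate's coefficients from the report.

    Point estimates with 95% CI whiskers against a zero reference line;
    the covariate's reference level is the implicit zero. Saves to
    ``path`` when given, otherwise returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = report[(report["covariate"] == covariate)
                 & (report["model_id"] == model_id)]
    if sub.empty:
        raise ValueError(f"no rows for covariate {covariate!r} in model {model_id!r}")
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(sub) + 1.5))
    y = np.arange(len(sub))[::-1]
    ax.errorbar(
        sub["estimate"], y,
        xerr=[sub["estimate"] - sub["ci_low"], sub["ci_high"] - sub["estimate"]],
        fmt="o", color="black", capsize=3,
    )
    ax.axvline(0.0, color="grey", lw=1, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(sub["level"])
    ax.set_xlabel(f"difference in {sub['outcome'].iloc[0].upper()} (95% CI)")
    ax.set_title(f"{covariate}, model {model_id}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
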