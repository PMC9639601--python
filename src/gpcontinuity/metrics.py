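"""Relational continuity-of-care indices computed from consultation records.

Two patient-level indices are provided, both functions of the *visit
profile* — the vector of a patient's visit counts per GP within an
analysis window:

* **UPC** (Usual Provider of Care): the share of visits made to the most
  frequently seen GP, ``max(n_i) / N``. Range (0, 1]; 1 means a single
  provider.
* **COC** (Bice–Boxerman Continuity of Care): the pairwise-concordance
  concentration of visits across all GPs seen,
  ``(Σ n_i² − N) / (N (N − 1))``. Range [0, 1]; 0 means every visit was
  with a different GP, 1 a single provider. Undefined (NaN) for N < 2
  because the denominator vanishes.

Both are invariant to provider relabelling and to event order, and
``COC ≤ UPC`` for every profile (the concordant-pair share can never
exceed the modal share).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MODES",
    "VisitProfile",
    "upc_from_counts",
    "coc_from_counts",
    "upc",
    "coc",
    "visit_profile",
    "compute_continuity_table",
]

#: Consultation modes counted by default: in-person, telephone and online
#: GP contacts. Other contact types (e.g. home visits) are excluded.
DEFAULT_MODES = frozenset({"face_to_face", "telephone", "online"})


@dataclass(frozen=True)
class VisitProfile:
    """Per-patient visit counts by provider over an analysis window.

    ``counts`` maps provider id -> number of visits; providers with zero
    visits are absent. The profile is the sufficient statistic for both
    continuity indices.
    """

    patient_id: object
    window: tuple[pd.Timestamp, pd.Timestamp]
    counts: Mapping[object, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for provider, n in self.counts.items():
            if n < 1 or int(n) != n:
                raise ValueError(
                    f"visit count for provider {provider!r} must be a "
                    f"positive integer, got {n!r}"
                )

    @property
    def n_visits(self) -> int:
        """Total visits N = Σ n_i."""
        return int(sum(self.counts.values()))

    @property
    def max_count(self) -> int:
        """Largest per-provider count m = max n_i (0 for an empty profile)."""
        return int(max(self.counts.values(), default=0))

    @property
    def n_providers(self) -> int:
        return len(self.counts)


def upc_from_counts(counts: Iterable[int]) -> float:
    """UPC index from raw per-provider visit counts: ``max / total``.

    Raises ``ValueError`` on an empty profile (N = 0) — the index is
    undefined with no visits.
    """
    c = np.asarray(list(counts), dtype=float)
    n = c.sum()
    if c.size == 0 or n <= 0:
        raise ValueError("UPC is undefined for a profile with no visits")
    return float(c.max() / n)


def coc_from_counts(counts: Iterable[int]) -> float:
    """Bice–Boxerman COC index from per-provider counts.

    Computed as ``(Σ n_i² − N) / (N (N − 1))`` — the proportion of
    ordered visit pairs made to the same provider. Returns NaN for
    N ≤ 1, where the index is undefined, so bulk computation over a
    cohort can proceed without exceptions.
    """
    c = np.asarray(list(counts), dtype=float)
    n = c.sum()
    if n < 2:
        return float("nan")
    return float((np.sum(c**2) - n) / (n * (n - 1.0)))


def upc(profile: VisitProfile) -> float:
    """UPC of a :class:`VisitProfile`."""
    return upc_from_counts(profile.counts.values())


def coc(profile: VisitProfile) -> float:
    """COC of a :class:`VisitProfile` (NaN when N < 2)."""
    return coc_from_counts(profile.counts.values())


def _check_window(window) -> tuple[pd.Timestamp, pd.Timestamp]:
    start, end = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    if start >= end:
        raise ValueError(f"window start {start.date()} must precede end {end.date()}")
    return start, end


def visit_profile(
    consultations: pd.DataFrame,
    patient_id: object,
    window,
    allowed_modes: frozenset[str] = DEFAULT_MODES,
) -> VisitProfile:
    """Build one patient's visit profile from a consultation event table.

    Only events with the given patient, an allowed mode and a date in
    the half-open interval ``[start, end)`` are counted. ``window`` is a
    ``(start, end)`` pair; ``end`` is exclusive.
    """
    start, end = _check_window(window)
    ev = consultations
    mask = (
        (ev["patient_id"] == patient_id)
        & ev["mode"].isin(allowed_modes)
        & (pd.to_datetime(ev["date"]) >= start)
        & (pd.to_datetime(ev["date"]) < end)
    )
    counts = ev.loc[mask, "gp_id"].value_counts().to_dict()
    return VisitProfile(patient_id=patient_id, window=(start, end), counts=counts)


def compute_continuity_table(
    consultations: pd.DataFrame,
    window,
    min_consultations: int = 3,
    allowed_modes: frozenset[str] = DEFAULT_MODES,
) -> pd.DataFrame:
    """Per-patient continuity indices for all patients meeting the visit minimum.

    Parameters
    ----------
    consultations
        Event table with columns ``patient_id``, ``gp_id``, ``date``, ``mode``.
    window
        ``(start, end)`` analysis window, ``end`` exclusive. The 4-year
        main window and the 12-month sensitivity window differ only here.
    min_consultations
        Patients with fewer qualifying visits than this are omitted
        (study default 3).

    Returns
    -------
    DataFrame with one row per retained patient: ``patient_id``, ``upc``,
    ``coc``, ``n_consultations``, ``n_providers``. ``coc`` is NaN when a
    patient has fewer than two visits (only reachable with
    ``min_consultations < 2``).
    """
    start, end = _check_window(window)
    if min_consultations < 1:
        raise ValueError("min_consultations must be >= 1")
    dates = pd.to_datetime(consultations["date"])
    ev = consultations.loc[
        consultations["mode"].isin(allowed_modes) & (dates >= start) & (dates < end)
    ]
    if ev.empty:
        return pd.DataFrame(
            columns=["patient_id", "upc", "coc", "n_consultations", "n_providers"]
        )
    counts = (
        ev.groupby(["patient_id", "gp_id"], sort=False, observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    g = counts.groupby("patient_id", sort=False, observed=True)["n"]
    per_patient = pd.DataFrame(
        {
            "n_consultations": g.sum(),
            "max_count": g.max(),
            "sum_sq": g.apply(lambda s: int(np.sum(np.asarray(s) ** 2))),
            "n_providers": g.size(),
        }
    )
    per_patient = per_patient[per_patient["n_consultations"] >= min_consultations]
    n = per_patient["n_consultations"].to_numpy(dtype=float)
    upc_vals = per_patient["max_count"].to_numpy(dtype=float) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        coc_vals = np.where(
            n >= 2, (per_patient["sum_sq"].to_numpy(dtype=float) - n) / (n * (n - 1.0)), np.nan
        )
    out = pd.DataFrame(
        {
            "patient_id": per_patient.index,
            "upc": upc_vals,
            "coc": coc_vals,
            "n_consultations": per_patient["n_consultations"].to_numpy(),
            "n_providers": per_patient["n_providers"].to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def _round_index(x: float) -> float:
    """Round an index to the 2-decimal presentation precision."""
    return float(f"{x:.2f}") if math.isfinite(x) else x
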