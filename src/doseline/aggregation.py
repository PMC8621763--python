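"""Multi-route and multi-chemical risk aggregation.

Because the sigmoid model depends only on the dose-to-ED50 ratio, exposures
through different routes (and from different chemicals) are combined by
summing their ED50 fractions — effectively setting ED50 = 1 for the summed
exposure — and evaluating the model once on the total.  The same linearity
of exposure in emission underlies the incremental-emission workflow: an
extra emission scales the background relative exposure by the emission
ratio, and the total is read off the piecewise-linear table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.stats import rankdata

from .dose_response import (
    DoseResponseCurve,
    log10_prhe_nonlinear,
    prhe_nonlinear,
)
from .errors import DataError, DomainError
from .segmentation import SegmentTable, evaluate_piecewise

__all__ = [
    "ChemicalRecord",
    "ExposureProfile",
    "RiskResult",
    "relative_exposure",
    "chemical_prhe",
    "total_relative_exposure",
    "total_prhe",
    "incremental_risk",
    "rank_emission_vs_risk",
    "RankingResult",
    "screen",
]


@dataclass(frozen=True)
class ChemicalRecord:
    """One chemical: identity, background emission, route-specific toxicity."""

    casrn: str
    name: str
    emission_rate: float = 0.0  # kg/yr
    ed50_ingestion: float | None = None  # mg/kg/d
    ed50_inhalation: float | None = None  # mg/kg/d

    def __post_init__(self) -> None:
        if self.ed50_ingestion is None and self.ed50_inhalation is None:
            raise DataError(f"{self.casrn}: at least one route ED50 is required")
        for route in ("ed50_ingestion", "ed50_inhalation"):
            value = getattr(self, route)
            if value is not None and not value > 0:
                raise DataError(f"{self.casrn}: {route} must be > 0, got {value!r}")
        if not self.emission_rate >= 0:
            raise DataError(
                f"{self.casrn}: emission_rate must be >= 0, got {self.emission_rate!r}"
            )


@dataclass(frozen=True)
class ExposureProfile:
    """Average daily doses per route for one age-group scenario (mg/kg/d)."""

    age_group: str
    dose_ingestion: float
    dose_inhalation: float

    def __post_init__(self) -> None:
        if self.dose_ingestion < 0 or self.dose_inhalation < 0:
            raise DataError(f"age {self.age_group}: doses must be >= 0")


@dataclass(frozen=True)
class RiskResult:
    """Relative exposure (fraction of ED50) with the risk it implies."""

    relative_exposure: float
    prhe: float
    log10_prhe: float
    method: str = "nonlinear"
    interval_label: str | None = None


def _route_ed50s(chem: ChemicalRecord) -> tuple[float, float]:
    """Resolve (ingestion, inhalation) ED50s, borrowing across routes when a
    route-specific value is missing (the usual practice when only one route
    has been characterized)."""
    ing, inh = chem.ed50_ingestion, chem.ed50_inhalation
    if ing is None:
        warnings.warn(
            f"{chem.casrn}: no ingestion ED50; using the inhalation value",
            stacklevel=3,
        )
        ing = inh
    if inh is None:
        warnings.warn(
            f"{chem.casrn}: no inhalation ED50; using the ingestion value",
            stacklevel=3,
        )
        inh = ing
    assert ing is not None and inh is not None
    return ing, inh


def relative_exposure(profile: ExposureProfile, chem: ChemicalRecord) -> float:
    """Combined relative exposure X_inh/ED50_inh + X_ing/ED50_ing."""
    ed50_ing, ed50_inh = _route_ed50s(chem)
    return profile.dose_ingestion / ed50_ing + profile.dose_inhalation / ed50_inh


def chemical_prhe(
    rel: float, curve: DoseResponseCurve | None = None
) -> RiskResult:
    """Risk for one chemical's combined relative exposure."""
    curve = curve or DoseResponseCurve()
    if not rel >= 0:
        raise DomainError(f"relative exposure must be >= 0, got {rel!r}")
    return RiskResult(
        relative_exposure=float(rel),
        prhe=prhe_nonlinear(rel, curve),
        log10_prhe=log10_prhe_nonlinear(rel, curve),
        method="nonlinear",
    )


def total_relative_exposure(rels: Iterable[float]) -> float:
    """Sum of per-chemical ED50 fractions (dose-additive combination)."""
    total = 0.0
    for r in rels:
        if not r >= 0:
            raise DomainError(f"relative exposures must be >= 0, got {r!r}")
        total += float(r)
    return total


def total_prhe(
    total_rel: float, curve: DoseResponseCurve | None = None
) -> RiskResult:
    """Aggregate risk of the summed relative exposure."""
    return chemical_prhe(total_rel, curve)


def incremental_risk(
    background_rel: float,
    background_emission: float,
    incremental_emission: float,
    table: SegmentTable,
) -> RiskResult:
    """Risk of background plus an incremental emission, via the linear table.

    The incremental relative exposure is the background relative exposure
    scaled by the emission ratio (average daily dose scales linearly with
    emission rate); the total is evaluated on the piecewise-linear table.
    """
    if background_emission < 0 or incremental_emission < 0:
        raise DataError("emissions must be >= 0")
    if incremental_emission > 0 and background_emission == 0:
        raise DataError(
            "background emission is zero: the emission-ratio scaling has no "
            "reference; supply the incremental dose fraction directly instead"
        )
    if not background_rel >= 0:
        raise DomainError(f"background_rel must be >= 0, got {background_rel!r}")

    incremental_rel = (
        background_rel * (incremental_emission / background_emission)
        if incremental_emission > 0
        else 0.0
    )
    x_total = background_rel + incremental_rel
    prhe = evaluate_piecewise(x_total, table)
    if 0.0 < x_total <= table.x_max:
        label = table.segment_for(x_total).label
        method = "piecewise"
    else:
        label = None
        method = "nonlinear" if x_total > table.x_max else "piecewise"
    return RiskResult(
        relative_exposure=x_total,
        prhe=prhe,
        log10_prhe=math.log10(prhe) if prhe > 0 else -math.inf,
        method=method,
        interval_label=label,
    )


class RankingResult(NamedTuple):
    emission_ranks: np.ndarray
    risk_ranks: np.ndarray
    correlation: float


def rank_emission_vs_risk(
    records: Sequence[tuple[float, float]]
) -> RankingResult:
    """Rank chemicals by emission and by risk and correlate the rankings.

    Rank 1 is the largest value; ties receive average ranks.  The returned
    correlation is the product-moment correlation of the two rank vectors
    (i.e. a Spearman-type rank correlation).
    """
    if len(records) < 3:
        raise DataError(f"need at least 3 records to rank, got {len(records)}")
    emissions = np.asarray([r[0] for r in records], dtype=float)
    risks = np.asarray([r[1] for r in records], dtype=float)
    e_ranks = rankdata(-emissions, method="average")
    r_ranks = rankdata(-risks, method="average")
    corr = float(np.corrcoef(e_ranks, r_ranks)[0, 1])
    return RankingResult(e_ranks, r_ranks, corr)


def screen(
    chemicals: Sequence[ChemicalRecord],
    exposures: dict[str, Sequence[ExposureProfile]],
    curve: DoseResponseCurve | None = None,
):
    """Per-chemical, per-age risk screen with aggregate rows.

    ``exposures`` maps CASRN to that chemical's age-group profiles.
    Chemicals without exposure data (and exposure keys without a chemical)
    are reported and skipped, not silently dropped.  Returns a pandas
    DataFrame in the results schema (one row per chemical x age plus one
    ``TOTAL`` row per age group).
    """
    import pandas as pd

    curve = curve or DoseResponseCurve()
    known = {c.casrn for c in chemicals}
    orphans = sorted(set(exposures) - known)
    if orphans:
        warnings.warn(f"exposure rows without inventory chemical: {orphans}")

    rows = []
    per_age_totals: dict[str, float] = {}
    for chem in chemicals:
        profiles = exposures.get(chem.casrn)
        if not profiles:
            warnings.warn(f"{chem.casrn}: no exposure data; skipped")
            continue
        ed50_ing, ed50_inh = _route_ed50s(chem)
        for prof in profiles:
            rel_ing = prof.dose_ingestion / ed50_ing
            rel_inh = prof.dose_inhalation / ed50_inh
            result = chemical_prhe(rel_ing + rel_inh, curve)
            per_age_totals[prof.age_group] = (
                per_age_totals.get(prof.age_group, 0.0) + result.relative_exposure
            )
            rows.append(
                {
                    "casrn": chem.casrn,
                    "name": chem.name,
                    "age_group": prof.age_group,
                    "rel_ingestion": rel_ing,
                    "rel_inhalation": rel_inh,
                    "rel_combined": result.relative_exposure,
                    "prhe": result.prhe,
                    "log10_prhe": result.log10_prhe,
                    "method": result.method,
                    "interval_label": "",
                }
            )
    for age, total in per_age_totals.items():
        result = total_prhe(total, curve)
        rows.append(
            {
                "casrn": "TOTAL",
                "name": "all chemicals combined",
                "age_group": age,
                "rel_ingestion": float("nan"),
                "rel_inhalation": float("nan"),
                "rel_combined": result.relative_exposure,
                "prhe": result.prhe,
                "log10_prhe": result.log10_prhe,
                "method": result.method,
                "interval_label": "",
            }
        )
    return pd.DataFrame(rows)
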