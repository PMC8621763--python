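"""Reading, validating and writing inventory, toxicity and exposure tables.

All tables are plain UTF-8 CSV with a mandatory header row, comma delimiter
and '.' decimal separator.  Lines starting with '#' are provenance comments
and are ignored on read.  CASRN strings are treated as opaque keys: hyphens
and leading zeros are preserved exactly.

Schemas
-------
inventory : casrn,name,emission_kg_per_year
toxicity  : casrn,route,ed50_value,ed50_unit      (route in {ingestion,
            inhalation}; ed50_unit in {kg_per_lifetime, mg_per_kg_per_day})
exposure  : casrn,age_group,dose_ingestion_mg_kg_d,dose_inhalation_mg_kg_d
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .aggregation import ChemicalRecord, ExposureProfile
from .errors import DataError, FormatError
from .segmentation import SegmentTable

__all__ = [
    "ToxicityRecordRaw",
    "BodyModel",
    "convert_ed50",
    "read_inventory",
    "read_toxicity",
    "read_exposure",
    "load_chemicals",
    "write_results",
    "write_segment_table",
    "read_segment_table",
]

ROUTES = ("ingestion", "inhalation")
UNITS = ("kg_per_lifetime", "mg_per_kg_per_day")


@dataclass(frozen=True)
class ToxicityRecordRaw:
    """One route-specific ED50 as reported, before unit conversion."""

    casrn: str
    ed50_route: str
    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.ed50_route not in ROUTES:
            raise FormatError(
                f"{self.casrn}: unknown route {self.ed50_route!r}; expected one of {ROUTES}"
            )
        if self.unit not in UNITS:
            raise FormatError(
                f"{self.casrn}: unknown ED50 unit {self.unit!r}; expected one of {UNITS}"
            )
        if not self.value > 0:
            raise DataError(f"{self.casrn}: ED50 must be > 0, got {self.value!r}")


@dataclass(frozen=True)
class BodyModel:
    """Standard body: 70 kg body weight over a 70-year (25,550-day) lifetime."""

    body_weight: float = 70.0  # kg
    lifetime_days: float = 25_550.0

    def __post_init__(self) -> None:
        if not (self.body_weight > 0 and self.lifetime_days > 0):
            raise DataError("body_weight and lifetime_days must be > 0")


def convert_ed50(raw: ToxicityRecordRaw, body: BodyModel | None = None) -> float:
    """ED50 in mg/kg bodyweight/d.

    Lifetime cumulative intakes (kg chemical per lifetime) are spread over
    the standard body and lifetime: value * 1e6 / (body_weight * lifetime_days).
    Values already in mg/kg/d pass through unchanged.
    """
    body = body or BodyModel()
    if raw.unit == "kg_per_lifetime":
        return raw.value * 1e6 / (body.body_weight * body.lifetime_days)
    return raw.value


# ---------------------------------------------------------------------------
# readers


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    df = pd.read_csv(path, comment="#", dtype={"casrn": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _check_unique_casrn(df: pd.DataFrame, path, subset=("casrn",)) -> None:
    dupes = df[df.duplicated(subset=list(subset), keep=False)]
    if not dupes.empty:
        rows = [i + 2 for i in dupes.index.tolist()]  # 1-based incl. header
        raise FormatError(f"{path}: duplicate casrn at row(s) {rows}")


def read_inventory(path: str | Path) -> pd.DataFrame:
    """Inventory table: casrn, name, emission_kg_per_year."""
    df = _read_csv(path, ["casrn", "name", "emission_kg_per_year"])
    _check_unique_casrn(df, path)
    bad = df[~(df["emission_kg_per_year"] >= 0)]
    if not bad.empty:
        rows = [i + 2 for i in bad.index.tolist()]
        raise DataError(f"{path}: negative or non-numeric emission at row(s) {rows}")
    return df


def read_toxicity(
    path: str | Path, body: BodyModel | None = None
) -> dict[str, dict[str, float]]:
    """Toxicity table -> {casrn: {route: ED50 in mg/kg/d}}."""
    df = _read_csv(path, ["casrn", "route", "ed50_value", "ed50_unit"])
    _check_unique_casrn(df, path, subset=("casrn", "route"))
    out: dict[str, dict[str, float]] = {}
    for i, row in df.iterrows():
        try:
            raw = ToxicityRecordRaw(
                casrn=row["casrn"],
                ed50_route=row["route"],
                value=float(row["ed50_value"]),
                unit=row["ed50_unit"],
            )
        except (DataError, ValueError) as exc:
            raise FormatError(f"{path}: row {i + 2}: {exc}") from exc
        out.setdefault(raw.casrn, {})[raw.ed50_route] = convert_ed50(raw, body)
    return out


def read_exposure(path: str | Path) -> dict[str, list[ExposureProfile]]:
    """Exposure table -> {casrn: [ExposureProfile per age group]}."""
    df = _read_csv(
        path,
        ["casrn", "age_group", "dose_ingestion_mg_kg_d", "dose_inhalation_mg_kg_d"],
    )
    _check_unique_casrn(df, path, subset=("casrn", "age_group"))
    out: dict[str, list[ExposureProfile]] = {}
    for i, row in df.iterrows():
        try:
            profile = ExposureProfile(
                age_group=str(row["age_group"]),
                dose_ingestion=float(row["dose_ingestion_mg_kg_d"]),
                dose_inhalation=float(row["dose_inhalation_mg_kg_d"]),
            )
        except (DataError, ValueError) as exc:
            raise DataError(f"{path}: row {i + 2}: {exc}") from exc
        out.setdefault(row["casrn"], []).append(profile)
    return out


def load_chemicals(
    inventory_path: str | Path,
    toxicity_path: str | Path,
    body: BodyModel | None = None,
) -> list[ChemicalRecord]:
    """Join inventory and toxicity tables on CASRN into ChemicalRecords.

    Chemicals present in only one of the two tables are reported (via the
    raised error's message for empty joins, a warning otherwise) and skipped.
    """
    import warnings

    inventory = read_inventory(inventory_path)
    toxicity = read_toxicity(toxicity_path, body)
    records = []
    missing_tox = []
    for _, row in inventory.iterrows():
        routes = toxicity.get(row["casrn"])
        if not routes:
            missing_tox.append(row["casrn"])
            continue
        records.append(
            ChemicalRecord(
                casrn=row["casrn"],
                name=row["name"],
                emission_rate=float(row["emission_kg_per_year"]),
                ed50_ingestion=routes.get("ingestion"),
                ed50_inhalation=routes.get("inhalation"),
            )
        )
    orphan_tox = sorted(set(toxicity) - set(inventory["casrn"]))
    if missing_tox:
        warnings.warn(f"no toxicity data, skipped: {missing_tox}")
    if orphan_tox:
        warnings.warn(f"toxicity rows without inventory chemical: {orphan_tox}")
    if not records:
        raise DataError("no chemical has both inventory and toxicity data")
    return records


# ---------------------------------------------------------------------------
# writers


def _write_with_header(df: pd.DataFrame, path: str | Path, provenance: dict | None):
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, index=False)


def write_results(
    results: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> None:
    """Write a results DataFrame (schema of :func:`doseline.aggregation.screen`)."""
    _write_with_header(results, path, provenance)


def write_segment_table(
    table: SegmentTable, path: str | Path, provenance: dict | None = None
) -> None:
    """Write a segment table as CSV (or JSON when the path ends in .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(table.to_json(), encoding="utf-8")
        return
    df = pd.DataFrame(table.to_records())
    _write_with_header(df, path, provenance)


def read_segment_table(path: str | Path) -> SegmentTable:
    """Read a segment table previously written as JSON."""
    return SegmentTable.from_json(Path(path).read_text(encoding="utf-8"))
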