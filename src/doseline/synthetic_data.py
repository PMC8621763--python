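"""Seeded synthetic inventories plus the packaged reference dataset.

The generator emulates the statistical structure of a national-scale
emission screen: per-chemical doses spanning ~13 orders of magnitude,
route-specific ED50s, ingestion-dominant route splits for ~90% of
chemicals, young children receiving ~3x the adult dose, and all combined
exposures below 1% of ED50.  Doses derive from emissions through fixed
per-chemical dose factors, so dose scales exactly linearly with emission —
the same linearity the incremental-emission workflow assumes.

The reference fixture bundles the published ten highest-risk chemicals of
the 2017 U.S. national inventory screen (combined dose-to-ED50 fractions
and risks at ages 3, 14, 25), the per-age totals over all 95 chemicals,
and the published four-interval linear table, so every downstream stage is
testable without external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .segmentation import LinearSegment, SegmentTable, SegmentationConfig

__all__ = [
    "GeneratorConfig",
    "SyntheticTables",
    "generate",
    "derive_exposure",
    "save_tables",
    "ReferenceFixture",
    "reference_fixture",
    "reference_segment_table",
    "ACROLEIN_BACKGROUND_EMISSION_KG",
]

#: National background emission of acrolein used in the worked examples (kg/yr).
ACROLEIN_BACKGROUND_EMISSION_KG = 10.1e6

#: Age multipliers relative to the adult (25-year-old) dose; teenagers sit
#: slightly above adults, mirroring the reference dataset's ~1.2x ratio.
AGE_GROUPS = ("3", "14", "25")
_TEEN_MULTIPLIER = 1.15

#: Calibration ceiling for the largest combined age-3 fraction of ED50;
#: mirrors the top observed fraction (acrolein, ~0.55%) and keeps every
#: synthetic exposure below 1% of ED50.
_MAX_COMBINED_FRACTION = 5.5e-3

_EMISSION_SPAN_ORDERS = 7.0  # kg/yr from 1e0 to 1e7, NEI-like


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic-data generator."""

    n_chemicals: int = 95
    seed: int = 0
    dose_span_orders: float = 13.0
    age_multiplier_child: float = 3.0
    ingestion_dominance: float = 0.9

    def __post_init__(self) -> None:
        if self.n_chemicals < 1:
            raise ConfigurationError("n_chemicals must be >= 1")
        if not self.dose_span_orders > 0:
            raise ConfigurationError("dose_span_orders must be > 0")
        if not self.age_multiplier_child >= 1:
            raise ConfigurationError("age_multiplier_child must be >= 1")
        if not (0.0 <= self.ingestion_dominance <= 1.0):
            raise ConfigurationError("ingestion_dominance must be in [0, 1]")


class SyntheticTables(NamedTuple):
    """Generated tables in the CSV schemas of :mod:`doseline.inventory_io`,
    plus the fixed per-chemical dose factors the exposures derive from."""

    inventory: pd.DataFrame
    toxicity: pd.DataFrame
    exposure: pd.DataFrame
    dose_factors: pd.DataFrame


def _age_multipliers(child: float) -> dict[str, float]:
    return {"3": child, "14": _TEEN_MULTIPLIER, "25": 1.0}


def derive_exposure(
    inventory: pd.DataFrame,
    dose_factors: pd.DataFrame,
    age_multiplier_child: float = 3.0,
) -> pd.DataFrame:
    """Exposure table implied by emissions and fixed dose factors.

    Dose (mg/kg/d) = emission (kg/yr) x per-route dose factor x age
    multiplier; exactly linear in the emission rate.
    """
    merged = inventory.merge(dose_factors, on="casrn")
    rows = []
    for age, mult in _age_multipliers(age_multiplier_child).items():
        for _, row in merged.iterrows():
            e = row["emission_kg_per_year"]
            rows.append(
                {
                    "casrn": row["casrn"],
                    "age_group": age,
                    "dose_ingestion_mg_kg_d": e * row["factor_ingestion"] * mult,
                    "dose_inhalation_mg_kg_d": e * row["factor_inhalation"] * mult,
                }
            )
    return pd.DataFrame(rows)


def generate(config: GeneratorConfig | None = None) -> SyntheticTables:
    """Draw a seeded synthetic inventory/toxicity/exposure triple.

    Emissions and ED50s are log-uniform (order-of-magnitude spans are the
    only structure imposed); dose factors are log-uniform over the span
    that, combined with the emission span, covers ``dose_span_orders``
    orders of magnitude in dose.  A final deterministic rescale of all
    dose factors pins the largest combined age-3 fraction of ED50 at
    ~0.55%, so every chemical stays below 1% of its ED50.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_chemicals

    casrn = [f"{600000 + i}-{i % 100:02d}-{i % 10}" for i in range(n)]
    names = [f"synthetic-chem-{i:03d}" for i in range(n)]

    log_emission = rng.uniform(0.0, _EMISSION_SPAN_ORDERS, n)
    emission = 10.0**log_emission

    # ED50s over a USEtox-like range, with an independent route offset.
    ed50_ing = 10.0 ** rng.uniform(-2.0, 3.0, n)
    ed50_inh = ed50_ing * 10.0 ** rng.uniform(-1.0, 1.0, n)

    factor_span = max(config.dose_span_orders - _EMISSION_SPAN_ORDERS, 1.0)
    log_factor = rng.uniform(-factor_span, 0.0, n)

    dominant = rng.random(n) < config.ingestion_dominance
    # Log10 of ingestion/inhalation dose ratio: up to ~2e7-fold in favour of
    # ingestion for dominant chemicals, mildly reversed otherwise.
    log_ratio = np.where(
        dominant, rng.uniform(0.1, 7.3, n), rng.uniform(-2.0, -0.1, n)
    )
    total_factor = 10.0**log_factor
    factor_ing = total_factor / (1.0 + 10.0**-log_ratio)
    factor_inh = total_factor - factor_ing

    # Deterministic calibration: the most-exposed chemical's combined age-3
    # fraction is pinned at the ceiling.
    child = config.age_multiplier_child
    frac3 = emission * child * (factor_ing / ed50_ing + factor_inh / ed50_inh)
    scale = _MAX_COMBINED_FRACTION / frac3.max()
    factor_ing = factor_ing * scale
    factor_inh = factor_inh * scale

    inventory = pd.DataFrame(
        {"casrn": casrn, "name": names, "emission_kg_per_year": emission}
    )
    # Inhalation rows exercise the lifetime-intake unit; 70 kg x 25,550 d.
    tox_rows = []
    for i in range(n):
        tox_rows.append(
            {
                "casrn": casrn[i],
                "route": "ingestion",
                "ed50_value": ed50_ing[i],
                "ed50_unit": "mg_per_kg_per_day",
            }
        )
        tox_rows.append(
            {
                "casrn": casrn[i],
                "route": "inhalation",
                "ed50_value": ed50_inh[i] * 70.0 * 25_550.0 / 1e6,
                "ed50_unit": "kg_per_lifetime",
            }
        )
    toxicity = pd.DataFrame(tox_rows)
    dose_factors = pd.DataFrame(
        {
            "casrn": casrn,
            "factor_ingestion": factor_ing,
            "factor_inhalation": factor_inh,
        }
    )
    exposure = derive_exposure(inventory, dose_factors, child)
    return SyntheticTables(inventory, toxicity, exposure, dose_factors)


def save_tables(tables: SyntheticTables, out_dir) -> dict[str, str]:
    """Write the generated tables as CSV files; returns {table: path}."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("inventory", "toxicity", "exposure", "dose_factors"):
        path = out / f"{name}.csv"
        getattr(tables, name).to_csv(path, index=False)
        paths[name] = str(path)
    return paths


# ---------------------------------------------------------------------------
# packaged reference dataset

# Ten highest-risk chemicals of the national screen: combined dose-to-ED50
# fraction and risk at ages 3 / 14 / 25.
_REFERENCE_ROWS = [
    # casrn, name, f3, f14, f25, p3, p14, p25
    ("107-02-8", "Acrolein", 5.47e-3, 1.86e-3, 1.55e-3, 1.64e-18, 4.08e-26, 1.56e-27),
    ("127-18-4", "Tetrachloroethylene", 5.96e-4, 2.07e-4, 1.90e-4, 1.25e-35, 7.08e-46, 9.20e-47),
    ("108-88-3", "Toluene", 5.45e-4, 1.89e-4, 1.74e-4, 1.91e-36, 8.34e-47, 1.05e-47),
    ("542-75-6", "1,3-Dichloropropene", 3.89e-4, 1.35e-4, 1.24e-4, 1.33e-39, 2.16e-50, 2.43e-51),
    ("71-43-2", "Benzene", 3.67e-4, 1.27e-4, 1.17e-4, 3.61e-40, 4.93e-51, 5.52e-52),
    ("50-00-0", "Formaldehyde", 1.72e-4, 5.89e-5, 5.11e-5, 7.75e-48, 8.03e-60, 1.66e-61),
    ("77-47-4", "Hexachlorocyclopentadiene", 1.38e-4, 4.79e-5, 4.39e-5, 3.47e-50, 2.69e-62, 2.47e-63),
    ("91-20-3", "Naphthalene", 9.45e-5, 3.28e-5, 3.01e-5, 2.40e-54, 6.07e-67, 5.10e-68),
    ("56-23-5", "Carbon Tetrachloride", 8.69e-5, 3.02e-5, 2.77e-5, 2.74e-55, 5.49e-68, 4.48e-69),
    ("75-07-0", "Acetaldehyde", 8.40e-5, 2.84e-5, 2.33e-5, 1.12e-55, 8.97e-69, 2.65e-71),
]

#: Per-age total relative exposure over all 95 screened chemicals.
_REFERENCE_TOTALS = {"3": 0.00823, "14": 0.00282, "25": 0.00242}


class ReferenceFixture(NamedTuple):
    """Packaged reference dataset.

    ``chemicals`` is long-format (casrn, name, age_group, fraction, prhe)
    for the ten top-risk chemicals, plus one synthetic remainder row per
    age — the published total minus the top-10 sum — so that summing the
    ``fraction`` column per age reproduces the published 95-chemical
    totals.  Remainder rows have no per-chemical risk (prhe = NaN).
    """

    chemicals: pd.DataFrame
    totals: dict[str, float]
    acrolein_background_emission_kg: float


def reference_fixture() -> ReferenceFixture:
    """The packaged reference dataset (see :class:`ReferenceFixture`)."""
    rows = []
    for casrn, name, f3, f14, f25, p3, p14, p25 in _REFERENCE_ROWS:
        for age, frac, prhe in (("3", f3, p3), ("14", f14, p14), ("25", f25, p25)):
            rows.append(
                {
                    "casrn": casrn,
                    "name": name,
                    "age_group": age,
                    "fraction": frac,
                    "prhe": prhe,
                }
            )
    df = pd.DataFrame(rows)
    for age, total in _REFERENCE_TOTALS.items():
        top10 = df.loc[df["age_group"] == age, "fraction"].sum()
        rows.append(
            {
                "casrn": "REST-85",
                "name": "remaining 85 chemicals (synthetic balance term)",
                "age_group": age,
                "fraction": total - top10,
                "prhe": float("nan"),
            }
        )
    return ReferenceFixture(
        chemicals=pd.DataFrame(rows),
        totals=dict(_REFERENCE_TOTALS),
        acrolein_background_emission_kg=ACROLEIN_BACKGROUND_EMISSION_KG,
    )


def reference_segment_table() -> SegmentTable:
    """The published four-interval linear table, at its printed precision.

    This is the rounded table the incremental-emission workflow looks risks
    up in (base dose X0, slope S, base risk R0 per interval); the package
    can also recompute the table at full precision with
    :func:`doseline.segmentation.build_segment_table`, which differs from
    the printed values only through the publication's rounding.
    """
    segments = (
        LinearSegment(0.0, 0.090, 0.00031, 0.0, label="I"),
        LinearSegment(0.090, 0.153, 0.013, 0.000028, label="II"),
        LinearSegment(0.153, 0.334, 0.18, 0.00085, label="III"),
        LinearSegment(0.334, 0.464, 0.51, 0.034, label="IV"),
    )
    return SegmentTable(segments=segments, config=SegmentationConfig())
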