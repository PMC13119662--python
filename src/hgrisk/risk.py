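"""Deterministic dietary mercury risk: EDI, THQ, HI, SWI, advisories.

The chain is: estimated daily intake EDI = C * IR_daily / BW (mg THg per kg
body weight per day, with IR converted from g/week), target hazard quotient
THQ = EDI / RfD (dimensionless; < 1 read as no significant non-carcinogenic
risk), hazard index HI = sum of THQs over a multi-species diet basket, and
safe weekly intake SWI = TWI * BW / C * 1000 (grams of fish per week at
which the weekly dose equals the tolerable weekly intake).  SWI values map
onto traffic-light consumption advisories (red / yellow / green).

Total mercury is used as a 1:1 proxy for methylmercury by default; an
optional ``mehg_fraction`` in (0, 1] scales the effective concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defaults
from .survey import Survey

__all__ = [
    "ConsumerGroup",
    "ToxReference",
    "DietBasket",
    "DeterministicRisk",
    "DEFAULT_GROUPS",
    "compute_edi",
    "compute_thq",
    "compute_hi",
    "compute_swi",
    "swi_at_quantiles",
    "classify_traffic_light",
    "deterministic_risk_table",
]


@dataclass(frozen=True)
class ConsumerGroup:
    """A consumer group with its fixed body weight in kg."""

    name: str
    bw_kg: float

    def __post_init__(self) -> None:
        if self.bw_kg <= 0:
            raise ValueError("body weight must be positive")


DEFAULT_GROUPS: tuple[ConsumerGroup, ...] = tuple(
    ConsumerGroup(name, bw) for name, bw in defaults.BODY_WEIGHT_KG.items()
)


@dataclass(frozen=True)
class ToxReference:
    """Toxicological benchmarks: oral RfD (mg/kg/day) and TWI (mg/kg/week)."""

    rfd_mg_kg_day: float = defaults.RFD_MG_KG_DAY
    twi_mg_kg_week: float = defaults.TWI_MG_KG_WEEK

    def __post_init__(self) -> None:
        if self.rfd_mg_kg_day <= 0 or self.twi_mg_kg_week <= 0:
            raise ValueError("RfD and TWI must be positive")


@dataclass(frozen=True)
class DietBasket:
    """Per-species shares of a total weekly fish intake (shares sum to 1)."""

    shares: dict[str, float] = field(default_factory=dict)
    total_ir_g_week: float = defaults.BASELINE_IR_G_WEEK

    def __post_init__(self) -> None:
        if self.total_ir_g_week <= 0:
            raise ValueError("total intake must be positive")
        if any(v < 0 for v in self.shares.values()):
            raise ValueError("basket shares must be non-negative")
        total = sum(self.shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"basket shares sum to {total}, expected 1")


@dataclass(frozen=True)
class DeterministicRisk:
    """Point-estimate risk for one species x consumer group."""

    species: str
    group: ConsumerGroup
    c_mg_kg: float
    edi_mg_kg_day: float
    thq: float
    swi_g_week: float
    category: str


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")


def compute_edi(c_mg_kg: float, ir_g_week: float, bw_kg: float, *,
                mehg_fraction: float = defaults.MEHG_FRACTION) -> float:
    """Estimated daily intake, mg THg per kg body weight per day.

    ``ir_g_week`` is grams of fish per week; the weekly -> daily conversion
    divides by exactly 7 (so the 140 g/week baseline is 0.02 kg/day).
    """
    _require_positive(c_mg_kg=c_mg_kg, ir_g_week=ir_g_week, bw_kg=bw_kg,
                      mehg_fraction=mehg_fraction)
    ir_kg_day = ir_g_week / defaults.DAYS_PER_WEEK / 1000.0
    return c_mg_kg * mehg_fraction * ir_kg_day / bw_kg


def compute_thq(c_mg_kg: float, ir_g_week: float, bw_kg: float,
                rfd_mg_kg_day: float = defaults.RFD_MG_KG_DAY, *,
                mehg_fraction: float = defaults.MEHG_FRACTION) -> float:
    """Target hazard quotient EDI / RfD (dimensionless)."""
    _require_positive(rfd_mg_kg_day=rfd_mg_kg_day)
    return compute_edi(c_mg_kg, ir_g_week, bw_kg,
                       mehg_fraction=mehg_fraction) / rfd_mg_kg_day


def compute_hi(basket: DietBasket, concentrations: dict[str, float],
               group: ConsumerGroup,
               tox: ToxReference = ToxReference()) -> float:
    """Hazard index: sum of per-species THQs over a diet basket.

    Each species contributes THQ at its share of the basket's total weekly
    intake; a single-species basket therefore reduces to that species' THQ.
    """
    missing = [s for s in basket.shares if s not in concentrations]
    if missing:
        raise KeyError(f"no concentration for basket species: {missing}")
    hi = 0.0
    for species, share in basket.shares.items():
        if share == 0.0:
            continue
        hi += compute_thq(concentrations[species],
                          share * basket.total_ir_g_week,
                          group.bw_kg, tox.rfd_mg_kg_day)
    return hi


def compute_swi(c_mg_kg: float, bw_kg: float,
                twi_mg_kg_week: float = defaults.TWI_MG_KG_WEEK, *,
                rounded: bool = False) -> float:
    """Safe weekly intake in grams of fish per week.

    SWI = TWI * BW / C * 1000; the identity SWI * C = TWI * BW * 1000 holds
    to machine precision.  ``rounded=True`` reports the nearest integer
    gram (the advisory-table convention).
    """
    _require_positive(c_mg_kg=c_mg_kg, bw_kg=bw_kg,
                      twi_mg_kg_week=twi_mg_kg_week)
    swi = twi_mg_kg_week * bw_kg / c_mg_kg * 1000.0
    return float(round(swi)) if rounded else swi


def swi_at_quantiles(muscle_values, bw_kg: float,
                     twi_mg_kg_week: float = defaults.TWI_MG_KG_WEEK,
                     ) -> tuple[float, float]:
    """SWI evaluated at the sample median and at the 95th percentile.

    Quantiles use linear interpolation between order statistics.  The
    percentile-based allowance is never above the median-based one (SWI is
    decreasing in concentration).  Small samples (n < 20) give an unstable
    P95; a warning is the caller's concern, the arithmetic is exact either
    way.
    """
    x = np.asarray(muscle_values, dtype=float)
    if x.size == 0:
        raise ValueError("empty concentration sample")
    c_med = float(np.median(x))
    c_p95 = float(np.percentile(x, 95))
    return (compute_swi(c_med, bw_kg, twi_mg_kg_week),
            compute_swi(c_p95, bw_kg, twi_mg_kg_week))


def classify_traffic_light(swi_g_week: float) -> str:
    """Advisory category for a safe weekly intake (g/week).

    Red below 140 g/week, yellow in [140, 300), green at 300 and above.
    """
    if swi_g_week < 0:
        raise ValueError("SWI cannot be negative")
    if swi_g_week < defaults.RED_BELOW_G_WEEK:
        return "red"
    if swi_g_week < defaults.GREEN_FROM_G_WEEK:
        return "yellow"
    return "green"


def deterministic_risk_table(
    survey: Survey,
    groups: tuple[ConsumerGroup, ...] = DEFAULT_GROUPS,
    tox: ToxReference = ToxReference(),
    ir_g_week: float = defaults.BASELINE_IR_G_WEEK,
) -> pd.DataFrame:
    """Advisory-table risk summary, one row per species.

    For each species, THQ at the baseline weekly intake is computed from
    the muscle median concentration for every consumer group, alongside
    median- and P95-based SWI (nearest gram) and the traffic-light category
    of the median-based SWI.
    """
    rows = []
    for species in survey.species_list():
        muscle = survey.muscle_values(species)
        if muscle.size == 0:
            continue
        c_med = float(np.median(muscle))
        row: dict[str, object] = {"species": species, "c_median": c_med,
                                  "n": int(muscle.size)}
        for grp in groups:
            swi_med, swi_p95 = swi_at_quantiles(muscle, grp.bw_kg,
                                                tox.twi_mg_kg_week)
            row[f"thq_{grp.name}"] = round(
                compute_thq(c_med, ir_g_week, grp.bw_kg,
                            tox.rfd_mg_kg_day), 3)
            row[f"swi_med_{grp.name}"] = round(swi_med)
            row[f"swi_p95_{grp.name}"] = round(swi_p95)
            row[f"category_{grp.name}"] = classify_traffic_light(swi_med)
        rows.append(row)
    return pd.DataFrame(rows)
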