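"""Time-and-cost model: visual versus DNA-barcode identification.

Visual identification is strictly per-individual — a technician checks each
specimen's diagnostic characters under the microscope, taking a per-species
number of minutes.  Barcoding splits into a small per-individual step
(tissue sampling) plus per-batch steps (DNA extraction, PCR preparation)
amortised over up to 96 individuals per thermocycler run, so its
per-individual labour shrinks with sample size.  Costs combine labour
(minutes × hourly technician rate) with per-individual consumables.

The default hourly rate is derived, not asserted: the reference visual
workload (335 min over 30 individuals of five lanternfish species) is priced
at €60.50 of labour, giving €60.50 / (335/60 h) ≈ €10.84/h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import yaml

#: Reference visual workload: per-individual diagnosis minutes for the five
#: myctophid species scored both visually and by barcode.
REFERENCE_VISUAL_MINUTES: dict[str, float] = {
    "Diogenichthys atlanticus": 15.0,
    "Hygophum hygomii": 10.0,
    "Lampanyctus alatus": 15.0,
    "Lampanyctus pusillus": 15.0,
    "Myctophum asperum": 10.0,
}

#: Individuals of each of those species in the reference comparison (n = 30).
REFERENCE_COUNTS: dict[str, int] = {
    "Diogenichthys atlanticus": 3,
    "Hygophum hygomii": 22,
    "Lampanyctus alatus": 1,
    "Lampanyctus pusillus": 3,
    "Myctophum asperum": 1,
}

#: Labour cost (€) of the reference visual workload, anchoring the rate.
REFERENCE_VISUAL_LABOUR_EUR = 60.5


@dataclass
class CostSpec:
    """Labour times, rate and consumables for both identification methods."""

    visual_minutes: dict[str, float] = field(
        default_factory=lambda: dict(REFERENCE_VISUAL_MINUTES)
    )
    #: visual minutes assumed for species absent from ``visual_minutes``
    #: (None = such species are an error)
    default_visual_minutes: Optional[float] = None
    tissue_minutes: float = 2.0
    extraction_minutes_per_batch: float = 15.0
    pcr_minutes_per_batch: float = 30.0
    batch_capacity: int = 96
    hourly_rate: Optional[float] = None  # €/h; None = derived default
    visual_consumables: float = 1.0  # €/individual
    barcode_consumables: float = 5.0  # €/individual

    def __post_init__(self) -> None:
        numeric = [
            self.tissue_minutes,
            self.extraction_minutes_per_batch,
            self.pcr_minutes_per_batch,
            self.visual_consumables,
            self.barcode_consumables,
            *self.visual_minutes.values(),
        ]
        if any(v < 0 for v in numeric) or (
            self.hourly_rate is not None and self.hourly_rate < 0
        ):
            raise ValueError("cost parameters must be nonnegative")
        if self.batch_capacity < 1:
            raise ValueError("batch_capacity must be ≥ 1")

    @property
    def rate(self) -> float:
        return default_hourly_rate() if self.hourly_rate is None else self.hourly_rate

    @classmethod
    def from_yaml(cls, path) -> "CostSpec":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def default_hourly_rate() -> float:
    """Technician rate (€/h) derived from the reference visual workload."""
    minutes = visual_minutes(REFERENCE_COUNTS, CostSpec(hourly_rate=0.0))
    return REFERENCE_VISUAL_LABOUR_EUR / (minutes / 60.0)


def visual_minutes(counts: Mapping[str, int], spec: CostSpec) -> float:
    """Total visual diagnosis minutes: Σ count(s) × minutes(s)."""
    total = 0.0
    for species, n in counts.items():
        minutes = spec.visual_minutes.get(species, spec.default_visual_minutes)
        if minutes is None:
            raise ValueError(f"no visual diagnosis time for species {species!r}")
        total += n * minutes
    return total


def barcode_minutes(n_individuals: int, spec: CostSpec) -> float:
    """Total barcoding labour minutes: per-individual tissue sampling plus
    per-batch extraction and PCR preparation (⌈n/96⌉ batches)."""
    if n_individuals < 0:
        raise ValueError("n_individuals must be ≥ 0")
    if n_individuals == 0:
        return 0.0
    batches = math.ceil(n_individuals / spec.batch_capacity)
    return n_individuals * spec.tissue_minutes + batches * (
        spec.extraction_minutes_per_batch + spec.pcr_minutes_per_batch
    )


@dataclass(frozen=True)
class CostReport:
    method: str
    labour_minutes: float
    labour_cost: float
    consumable_cost: float
    total_cost: float


def total_cost(
    minutes: float, n_individuals: int, consumable_rate: float, spec: CostSpec,
    method: str = "",
) -> CostReport:
    """Labour (minutes × rate/60) plus consumables (n × rate per individual),
    rounded to 2 decimals at the end only."""
    if consumable_rate < 0:
        raise ValueError("consumable_rate must be ≥ 0")
    labour = minutes * spec.rate / 60.0
    consumables = n_individuals * consumable_rate
    return CostReport(
        method,
        labour_minutes=minutes,
        labour_cost=round(labour, 2),
        consumable_cost=round(consumables, 2),
        total_cost=round(labour + consumables, 2),
    )


def compare_methods(counts: Mapping[str, int], spec: Optional[CostSpec] = None) -> dict[str, CostReport]:
    """Full visual-vs-barcoding comparison for a species count table."""
    spec = spec or CostSpec()
    n = sum(counts.values())
    vis_min = visual_minutes(counts, spec)
    bar_min = barcode_minutes(n, spec)
    return {
        "visual": total_cost(vis_min, n, spec.visual_consumables, spec, "visual"),
        "barcoding": total_cost(bar_min, n, spec.barcode_consumables, spec, "barcoding"),
    }


def labour_crossover(spec: Optional[CostSpec] = None, visual_minutes_per_individual: Optional[float] = None) -> int:
    """Smallest sample size at which barcoding needs fewer labour minutes
    per individual than visual identification (within one batch)."""
    spec = spec or CostSpec()
    if visual_minutes_per_individual is None:
        ref = visual_minutes(REFERENCE_COUNTS, spec)
        visual_minutes_per_individual = ref / sum(REFERENCE_COUNTS.values())
    batch = spec.extraction_minutes_per_batch + spec.pcr_minutes_per_batch
    if spec.tissue_minutes >= visual_minutes_per_individual:
        raise ValueError("barcoding per-individual time never drops below visual")
    for n in range(1, spec.batch_capacity + 1):
        if spec.tissue_minutes + batch / n < visual_minutes_per_individual:
            return n
    return spec.batch_capacity
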