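"""Per-species representation targets.

Targets are counts of occurrences (occupied catchments) that must fall inside
the selected network, set from IUCN Red List status first and range
restriction second:

* CR — 100% of occurrences (imminent extinction risk),
* EN — 75% of occurrences,
* VU — 50% of occurrences,
* otherwise, if range-restricted (total occupied area under 20 000 km² for
  fish and molluscs — low dispersal — or under 50 000 km² for odonates and
  aquatic plants) — 25% of occurrences,
* otherwise — at least two occurrences (capped at the occurrence count).

Threatened status always takes precedence over range restriction because it
demands the larger share of occurrences.  Fractional targets are rounded by
CEILING, the conservative choice: a species is never under-represented by
rounding.  The minimum-representation floor min(2, n) also applies to the
range-restricted rule (25% of a handful of occurrences would otherwise fall
below it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .types import THREATENED_STATUSES, SpeciesRecord, WorldBundle, range_sizes

#: Range-restriction thresholds (km², strict "under").
RANGE_RESTRICTION_KM2 = {
    "fish": 20_000.0,
    "mollusc": 20_000.0,
    "odonate": 50_000.0,
    "plant": 50_000.0,
}

#: Fraction of occurrences targeted per basis.
TARGET_FRACTIONS = {"status_CR": 1.0, "status_EN": 0.75, "status_VU": 0.50,
                    "range_restricted": 0.25}

TARGET_BASES = ("status_CR", "status_EN", "status_VU", "range_restricted", "minimum")


@dataclass(frozen=True)
class TargetSpec:
    """Representation target for one species."""

    species_id: str
    target_occurrences: int
    basis: str
    penalty_factor: float

    def __post_init__(self) -> None:
        if self.target_occurrences < 0:
            raise ValueError("target_occurrences must be nonnegative")
        if self.basis not in TARGET_BASES:
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.penalty_factor <= 0:
            raise ValueError("penalty_factor must be positive")


def is_range_restricted(taxon_group: str, range_km2: float) -> bool:
    """True iff the species' range falls strictly under its taxon threshold."""
    if range_km2 <= 0:
        raise ValueError("range_km2 must be positive")
    try:
        return range_km2 < RANGE_RESTRICTION_KM2[taxon_group]
    except KeyError:
        raise ValueError(f"unknown taxon_group {taxon_group!r}") from None


def assign_target(
    species: SpeciesRecord,
    n_occurrences: int,
    range_km2: float,
    penalty_factor: float = 10.0,
) -> TargetSpec:
    """Apply the target decision table to one species."""
    if n_occurrences < 1:
        raise ValueError(f"species {species.id}: n_occurrences must be >= 1")
    status = species.redlist_status
    if status in THREATENED_STATUSES:
        basis = f"status_{status}"
        target = math.ceil(TARGET_FRACTIONS[basis] * n_occurrences)
    elif is_range_restricted(species.taxon_group, range_km2):
        basis = "range_restricted"
        target = max(
            math.ceil(TARGET_FRACTIONS[basis] * n_occurrences), min(2, n_occurrences)
        )
    else:
        basis = "minimum"
        target = min(2, n_occurrences)
    return TargetSpec(
        species_id=species.id,
        target_occurrences=int(target),
        basis=basis,
        penalty_factor=penalty_factor,
    )


def build_target_table(
    bundle: WorldBundle, spf_scale: float = 10.0, penalty_factor: float | None = None
) -> pd.DataFrame:
    """Targets for every species in the bundle.

    Returns a DataFrame indexed by species id with columns ``target``,
    ``basis``, ``penalty_factor``, ``n_occurrences`` and ``range_km2``.
    The species penalty factor (SPF) defaults to ``spf_scale`` (10) times the
    mean catchment area, making a full shortfall commensurable with the area
    cost of the catchments that would remedy it; pass ``penalty_factor`` to
    override with an explicit value.
    """
    if penalty_factor is None:
        penalty_factor = spf_scale * float(bundle.catchments["area_km2"].mean())
    counts = bundle.occurrence_counts()
    ranges = range_sizes(bundle.occurrences, bundle.catchments).reindex(
        bundle.species.index
    )
    rows = []
    for sid, row in bundle.species.sort_index().iterrows():
        spec = assign_target(
            SpeciesRecord(id=str(sid), taxon_group=row["taxon_group"],
                          redlist_status=row["redlist_status"]),
            int(counts.loc[sid]),
            float(ranges.loc[sid]),
            penalty_factor=penalty_factor,
        )
        rows.append(
            {
                "species_id": sid,
                "target": spec.target_occurrences,
                "basis": spec.basis,
                "penalty_factor": spec.penalty_factor,
                "n_occurrences": int(counts.loc[sid]),
                "range_km2": float(ranges.loc[sid]),
            }
        )
    table = pd.DataFrame(
        rows, columns=["species_id", "target", "basis", "penalty_factor",
                       "n_occurrences", "range_km2"]
    )
    return table.set_index("species_id")
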