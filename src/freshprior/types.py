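"""Domain types for catchment-based conservation planning.

The planning unit is a river or lake catchment with an area (the cost proxy),
a pointer to its immediate downstream catchment (``None`` for outlets draining
to the sea or an endorheic sink), a freshwater-ecoregion membership, and the
fraction of its area under protected-area designation.  Species carry a taxon
group and an IUCN Red List category; occurrences are a sparse species x
catchment presence relation.

A :class:`WorldBundle` holds the validated tables for one planning world.
Tables are pandas DataFrames indexed by id so downstream modules can use
vectorized operations; single-record dataclasses are provided for APIs that
naturally take one record (e.g. target assignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

TAXON_GROUPS = ("fish", "mollusc", "odonate", "plant")
REDLIST_STATUSES = ("CR", "EN", "VU", "NT", "LC", "DD")
THREATENED_STATUSES = ("CR", "EN", "VU")
LOCK_STATUSES = ("available", "locked_in", "locked_out")

#: Marxan pu.dat status codes.
PU_STATUS_CODES = {"available": 0, "locked_in": 2, "locked_out": 3}
PU_STATUS_FROM_CODE = {v: k for k, v in PU_STATUS_CODES.items()}


class SchemaError(ValueError):
    """A required column is missing or a value falls outside its enumeration."""


class IntegrityError(ValueError):
    """An identifier does not resolve, or a structural invariant is violated."""


class TopologyError(ValueError):
    """The downstream pointers contain a cycle."""


@dataclass(frozen=True)
class Catchment:
    """One planning unit."""

    id: str
    area_km2: float
    downstream_id: Optional[str] = None
    ecoregion_id: str = "E1"
    country_code: Optional[str] = None
    protected_fraction: float = 0.0
    lock_status: str = "available"

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise SchemaError(f"catchment {self.id}: area_km2 must be > 0")
        if not 0.0 <= self.protected_fraction <= 1.0:
            raise SchemaError(
                f"catchment {self.id}: protected_fraction must be in [0, 1]"
            )
        if self.lock_status not in LOCK_STATUSES:
            raise SchemaError(f"catchment {self.id}: bad lock_status {self.lock_status!r}")


@dataclass(frozen=True)
class SpeciesRecord:
    """One conservation feature (species) with taxon group and Red List status."""

    id: str
    taxon_group: str
    redlist_status: str

    def __post_init__(self) -> None:
        if self.taxon_group not in TAXON_GROUPS:
            raise SchemaError(f"species {self.id}: bad taxon_group {self.taxon_group!r}")
        if self.redlist_status not in REDLIST_STATUSES:
            raise SchemaError(
                f"species {self.id}: bad redlist_status {self.redlist_status!r}"
            )


@dataclass
class WorldBundle:
    """Validated tables describing one planning world.

    Attributes
    ----------
    catchments : DataFrame indexed by catchment id with columns
        ``area_km2, downstream_id, ecoregion_id, country_code,
        protected_fraction, lock_status``.
    species : DataFrame indexed by species id with columns
        ``taxon_group, redlist_status``.
    occurrences : DataFrame with columns ``species_id, catchment_id``
        (deduplicated, sorted).
    adjacency : DataFrame with columns ``id1, id2, weight`` — undirected
        terrestrial-neighbour pairs used by the boundary-length penalty.
        May be empty; ``river_adjacency()`` derives one from the network.
    """

    catchments: pd.DataFrame
    species: pd.DataFrame
    occurrences: pd.DataFrame
    adjacency: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id1", "id2", "weight"])
    )

    def __post_init__(self) -> None:
        validate_bundle(self)

    @property
    def n_catchments(self) -> int:
        return len(self.catchments)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def total_area_km2(self) -> float:
        return float(self.catchments["area_km2"].sum())

    def occurrence_counts(self) -> pd.Series:
        """Number of occupied catchments per species (index = species id)."""
        counts = self.occurrences.groupby("species_id").size()
        return counts.reindex(self.species.index, fill_value=0)

    def river_adjacency(self) -> pd.DataFrame:
        """Undirected neighbour pairs induced by the river network, weight 1."""
        conn = build_connectivity(self.catchments)
        pairs = pd.DataFrame(
            {
                "id1": np.minimum(conn["upstream_id"], conn["downstream_id"]),
                "id2": np.maximum(conn["upstream_id"], conn["downstream_id"]),
                "weight": 1.0,
            }
        )
        return pairs.sort_values(["id1", "id2"], ignore_index=True)


_CATCHMENT_COLUMNS = {
    "area_km2",
    "downstream_id",
    "ecoregion_id",
    "protected_fraction",
}
_SPECIES_COLUMNS = {"taxon_group", "redlist_status"}
_OCC_COLUMNS = {"species_id", "catchment_id"}


def _require_columns(df: pd.DataFrame, required: Iterable[str], table: str) -> None:
    missing = sorted(set(required) - set(df.columns))
    if missing:
        raise SchemaError(f"{table} table is missing column(s): {', '.join(missing)}")


def validate_bundle(bundle: WorldBundle) -> None:
    """Check all structural invariants; raise Schema/Integrity/TopologyError."""
    cat = bundle.catchments
    _require_columns(cat, _CATCHMENT_COLUMNS, "catchment")
    _require_columns(bundle.species, _SPECIES_COLUMNS, "species")
    _require_columns(bundle.occurrences, _OCC_COLUMNS, "occurrence")

    if cat.index.has_duplicates:
        dupes = cat.index[cat.index.duplicated()].unique().tolist()
        raise IntegrityError(f"duplicate catchment id(s): {dupes}")
    if bundle.species.index.has_duplicates:
        dupes = bundle.species.index[bundle.species.index.duplicated()].unique().tolist()
        raise IntegrityError(f"duplicate species id(s): {dupes}")

    if (cat["area_km2"] <= 0).any():
        bad = cat.index[cat["area_km2"] <= 0].tolist()
        raise SchemaError(f"non-positive area_km2 for catchment(s): {bad}")
    pf = cat["protected_fraction"]
    if ((pf < 0) | (pf > 1)).any():
        bad = cat.index[(pf < 0) | (pf > 1)].tolist()
        raise SchemaError(f"protected_fraction outside [0, 1] for: {bad}")
    if "lock_status" in cat.columns:
        bad_status = ~cat["lock_status"].isin(LOCK_STATUSES)
        if bad_status.any():
            raise SchemaError(
                f"bad lock_status for: {cat.index[bad_status].tolist()}"
            )
    bad_taxon = ~bundle.species["taxon_group"].isin(TAXON_GROUPS)
    if bad_taxon.any():
        raise SchemaError(
            f"bad taxon_group for species: {bundle.species.index[bad_taxon].tolist()}"
        )
    bad_rl = ~bundle.species["redlist_status"].isin(REDLIST_STATUSES)
    if bad_rl.any():
        raise SchemaError(
            f"bad redlist_status for species: {bundle.species.index[bad_rl].tolist()}"
        )

    # referential integrity
    down = cat["downstream_id"].dropna()
    dangling = down[~down.isin(cat.index)]
    if len(dangling):
        raise IntegrityError(
            "downstream_id does not resolve for catchment(s): "
            f"{sorted(dangling.index.tolist())} -> {sorted(dangling.unique().tolist())}"
        )
    self_loop = down[down == down.index]
    if len(self_loop):
        raise TopologyError(
            f"catchment(s) point downstream to themselves: {self_loop.index.tolist()}"
        )

    occ = bundle.occurrences
    bad_sp = occ.loc[~occ["species_id"].isin(bundle.species.index), "species_id"]
    if len(bad_sp):
        raise IntegrityError(
            f"occurrence references unknown species id(s): {sorted(bad_sp.unique())}"
        )
    bad_cat = occ.loc[~occ["catchment_id"].isin(cat.index), "catchment_id"]
    if len(bad_cat):
        raise IntegrityError(
            f"occurrence references unknown catchment id(s): {sorted(bad_cat.unique())}"
        )
    if occ.duplicated(["species_id", "catchment_id"]).any():
        dupes = occ[occ.duplicated(["species_id", "catchment_id"])]
        raise IntegrityError(
            f"duplicate occurrence pairs: {dupes.to_records(index=False).tolist()[:5]}"
        )
    missing_occ = set(bundle.species.index) - set(occ["species_id"])
    if missing_occ:
        raise IntegrityError(
            f"species without any occurrence: {sorted(missing_occ)}"
        )

    if len(bundle.adjacency):
        _require_columns(bundle.adjacency, {"id1", "id2", "weight"}, "adjacency")
        adj = bundle.adjacency
        if (adj["id1"] == adj["id2"]).any():
            raise IntegrityError("adjacency contains self-pairs")
        for col in ("id1", "id2"):
            bad = adj.loc[~adj[col].isin(cat.index), col]
            if len(bad):
                raise IntegrityError(
                    f"adjacency references unknown catchment id(s): {sorted(bad.unique())}"
                )
        if (adj["weight"] < 0).any():
            raise SchemaError("adjacency weights must be nonnegative")

    # acyclicity of downstream pointers
    g = nx.DiGraph()
    g.add_nodes_from(cat.index)
    g.add_edges_from(zip(down.index, down.values))
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise TopologyError(f"downstream pointers form a cycle: {cycle}")


def build_connectivity(catchments: pd.DataFrame) -> pd.DataFrame:
    """Directed river connections (upstream_id, downstream_id, weight).

    One connection per catchment with a downstream pointer; outlets contribute
    none.  Weight defaults to 1 per connection; the connectivity-penalty
    multiplier scales the total.
    """
    down = catchments["downstream_id"].dropna()
    conn = pd.DataFrame(
        {
            "upstream_id": down.index.astype(str),
            "downstream_id": down.values.astype(str),
            "weight": 1.0,
        }
    )
    return conn.sort_values(["upstream_id", "downstream_id"], ignore_index=True)


def range_size(
    species_id: str, occurrences: pd.DataFrame, catchments: pd.DataFrame
) -> float:
    """Total area (km²) of the catchments in which the species occurs."""
    occ = occurrences.loc[occurrences["species_id"] == species_id, "catchment_id"]
    if occ.empty:
        raise KeyError(f"unknown species id or no occurrences: {species_id!r}")
    return float(catchments.loc[occ, "area_km2"].sum())


def range_sizes(occurrences: pd.DataFrame, catchments: pd.DataFrame) -> pd.Series:
    """Vectorized ``range_size`` for every species (index = species id)."""
    areas = catchments["area_km2"]
    occ = occurrences.assign(area=areas.loc[occurrences["catchment_id"]].values)
    return occ.groupby("species_id")["area"].sum()
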