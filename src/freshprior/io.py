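"""Readers and writers: delimited world tables and the Marxan input dialect.

World tables are plain CSV (``catchments.csv``, ``species.csv``,
``occurrences.csv``, optional ``adjacency.csv``).  The Marxan dialect is the
de-facto whitespace-delimited convention used by the reserve-selection tool
this package interoperates with:

``pu.dat``
    ``id  cost  status`` — cost is catchment area in km²; status 0 available,
    2 locked in, 3 locked out.
``spec.dat``
    ``id  target  spf`` — representation target in occurrence counts and the
    species penalty factor.
``puvspr.dat``
    ``species  pu  amount`` — sparse presence matrix (amount 1), sorted by
    planning-unit id then species id.
``bound.dat``
    ``id1  id2  boundary`` — symmetric terrestrial adjacency in boundary mode;
    directed (upstream, downstream) river connections in river mode.

Writing then re-reading reproduces ids, costs, statuses, targets and
occurrence pairs exactly; re-writing what was read reproduces the files
byte-for-byte.  Rows are ordered ascending-lexicographically by id for
determinism.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .types import (
    PU_STATUS_CODES,
    PU_STATUS_FROM_CODE,
    IntegrityError,
    SchemaError,
    WorldBundle,
    build_connectivity,
)

PathLike = Union[str, os.PathLike]


def load_world(
    catchment_table: PathLike,
    species_table: PathLike,
    occurrence_table: PathLike,
    adjacency_table: Optional[PathLike] = None,
) -> WorldBundle:
    """Load and validate a planning world from delimited files.

    Raises :class:`SchemaError` for missing columns, :class:`IntegrityError`
    for dangling ids, :class:`TopologyError` for downstream-pointer cycles.
    """
    cat = pd.read_csv(catchment_table, dtype={"id": str, "downstream_id": str,
                                              "ecoregion_id": str,
                                              "country_code": str},
                      float_precision="round_trip")
    if "id" not in cat.columns:
        raise SchemaError("catchment table is missing column(s): id")
    cat = cat.set_index("id")
    if "country_code" not in cat.columns:
        cat["country_code"] = pd.NA
    if "lock_status" not in cat.columns:
        cat["lock_status"] = "available"
    if "downstream_id" in cat.columns:
        cat["downstream_id"] = cat["downstream_id"].where(
            cat["downstream_id"].notna() & (cat["downstream_id"] != ""), pd.NA
        )
    cat = cat.sort_index()

    spp = pd.read_csv(species_table, dtype=str)
    if "id" not in spp.columns:
        raise SchemaError("species table is missing column(s): id")
    spp = spp.set_index("id").sort_index()

    occ = pd.read_csv(occurrence_table, dtype=str)
    if len(occ):
        occ = occ.sort_values(list(occ.columns[:2]), ignore_index=True)

    if adjacency_table is not None and Path(adjacency_table).exists():
        adj = pd.read_csv(adjacency_table, dtype={"id1": str, "id2": str},
                          float_precision="round_trip")
    else:
        adj = pd.DataFrame(columns=["id1", "id2", "weight"])

    return WorldBundle(catchments=cat, species=spp, occurrences=occ, adjacency=adj)


def write_world(bundle: WorldBundle, out_dir: PathLike) -> dict:
    """Write the world as CSV tables; returns the mapping of table -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "catchments": out / "catchments.csv",
        "species": out / "species.csv",
        "occurrences": out / "occurrences.csv",
        "adjacency": out / "adjacency.csv",
    }
    bundle.catchments.sort_index().to_csv(paths["catchments"], index_label="id")
    bundle.species.sort_index().to_csv(paths["species"], index_label="id")
    bundle.occurrences.sort_values(["species_id", "catchment_id"]).to_csv(
        paths["occurrences"], index=False
    )
    bundle.adjacency.to_csv(paths["adjacency"], index=False)
    return {k: str(v) for k, v in paths.items()}


@dataclass
class MarxanData:
    """Parsed Marxan-dialect inputs (verbatim tables)."""

    pu: pd.DataFrame       # columns id, cost, status
    spec: pd.DataFrame     # columns id, target, spf
    puvspr: pd.DataFrame   # columns species, pu, amount
    bound: pd.DataFrame    # columns id1, id2, boundary


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_marxan_inputs(
    bundle: WorldBundle,
    targets: pd.DataFrame,
    out_dir: PathLike,
    connectivity_mode: str = "boundary",
) -> dict:
    """Write pu.dat / spec.dat / puvspr.dat / bound.dat.

    ``targets`` is the table from
    :func:`freshprior.targets.build_target_table` (indexed by species id, with
    ``target`` and ``penalty_factor`` columns).  Lock statuses are taken from
    ``bundle.catchments['lock_status']`` — resolve the scenario first.
    ``connectivity_mode`` selects what bound.dat carries: symmetric adjacency
    (``boundary``) or directed river connections (``river``).
    """
    if connectivity_mode not in ("boundary", "river"):
        raise ValueError(f"connectivity_mode must be boundary|river, got {connectivity_mode!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cat = bundle.catchments.sort_index()
    pu = pd.DataFrame(
        {
            "id": cat.index,
            "cost": cat["area_km2"].astype(float).values,
            "status": cat["lock_status"].map(PU_STATUS_CODES).astype(int).values,
        }
    )
    _write_tsv(pu, out / "pu.dat")

    tgt = targets.sort_index()
    spec = pd.DataFrame(
        {
            "id": tgt.index,
            "target": tgt["target"].astype(int).values,
            "spf": tgt["penalty_factor"].astype(float).values,
        }
    )
    _write_tsv(spec, out / "spec.dat")

    puvspr = pd.DataFrame(
        {
            "species": bundle.occurrences["species_id"].values,
            "pu": bundle.occurrences["catchment_id"].values,
            "amount": 1,
        }
    ).sort_values(["pu", "species"], ignore_index=True)
    _write_tsv(puvspr, out / "puvspr.dat")

    if connectivity_mode == "river":
        conn = build_connectivity(bundle.catchments)
        bound = pd.DataFrame(
            {
                "id1": conn["upstream_id"].values,
                "id2": conn["downstream_id"].values,
                "boundary": conn["weight"].astype(float).values,
            }
        )
    else:
        adj = bundle.adjacency
        if not len(adj):
            adj = bundle.river_adjacency()
        bound = pd.DataFrame(
            {
                "id1": adj["id1"].values,
                "id2": adj["id2"].values,
                "boundary": adj["weight"].astype(float).values,
            }
        ).sort_values(["id1", "id2"], ignore_index=True)
    _write_tsv(bound, out / "bound.dat")

    return {name: str(out / f"{name}.dat") for name in ("pu", "spec", "puvspr", "bound")}


def read_marxan_inputs(in_dir: PathLike) -> MarxanData:
    """Read pu.dat / spec.dat / puvspr.dat / bound.dat back into tables."""
    p = Path(in_dir)
    pu = pd.read_csv(p / "pu.dat", sep="\t", dtype={"id": str},
                     float_precision="round_trip")
    spec = pd.read_csv(p / "spec.dat", sep="\t", dtype={"id": str},
                       float_precision="round_trip")
    puvspr = pd.read_csv(p / "puvspr.dat", sep="\t",
                         dtype={"species": str, "pu": str},
                         float_precision="round_trip")
    bound = pd.read_csv(p / "bound.dat", sep="\t", dtype={"id1": str, "id2": str},
                        float_precision="round_trip")
    bad = set(pu["status"]) - set(PU_STATUS_FROM_CODE)
    if bad:
        raise IntegrityError(f"pu.dat contains unknown status code(s): {sorted(bad)}")
    return MarxanData(pu=pu, spec=spec, puvspr=puvspr, bound=bound)


def rewrite_marxan_inputs(data: MarxanData, out_dir: PathLike) -> None:
    """Write parsed Marxan tables back out (byte-identical to the originals)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(data.pu, out / "pu.dat")
    _write_tsv(data.spec, out / "spec.dat")
    _write_tsv(data.puvspr, out / "puvspr.dat")
    _write_tsv(data.bound, out / "bound.dat")
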