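"""Shared fixtures: hand-built micro-worlds and generated test worlds."""

from __future__ import annotations

import pandas as pd
import pytest

from freshprior import WorldBundle, WorldConfig, generate_world


def make_bundle(catchments, species, occurrences, adjacency=None) -> WorldBundle:
    """Build a validated bundle from plain records.

    ``catchments``: list of dicts with at least id/area_km2 (downstream_id,
    ecoregion_id, country_code, protected_fraction, lock_status optional);
    ``species``: list of (id, taxon_group, redlist_status);
    ``occurrences``: list of (species_id, catchment_id).
    """
    cat_rows = []
    for c in catchments:
        cat_rows.append(
            {
                "id": c["id"],
                "area_km2": c.get("area_km2", 1000.0),
                "downstream_id": c.get("downstream_id", pd.NA),
                "ecoregion_id": c.get("ecoregion_id", "E1"),
                "country_code": c.get("country_code", pd.NA),
                "protected_fraction": c.get("protected_fraction", 0.0),
                "lock_status": c.get("lock_status", "available"),
            }
        )
    cat = pd.DataFrame(cat_rows).set_index("id").sort_index()
    spp = pd.DataFrame(
        [{"id": s[0], "taxon_group": s[1], "redlist_status": s[2]} for s in species]
    )
    spp = spp.set_index("id").sort_index() if len(spp) else pd.DataFrame(
        columns=["taxon_group", "redlist_status"],
        index=pd.Index([], name="id"),
    )
    occ = pd.DataFrame(occurrences, columns=["species_id", "catchment_id"])
    adj = (
        pd.DataFrame(adjacency, columns=["id1", "id2", "weight"])
        if adjacency
        else pd.DataFrame(columns=["id1", "id2", "weight"])
    )
    return WorldBundle(catchments=cat, species=spp, occurrences=occ, adjacency=adj)


@pytest.fixture
def chain_bundle():
    """Three-catchment chain A→B→C with two species and four occurrences."""
    return make_bundle(
        catchments=[
            {"id": "A", "area_km2": 5000.0, "downstream_id": "B"},
            {"id": "B", "area_km2": 7000.0, "downstream_id": "C"},
            {"id": "C", "area_km2": 3000.0},
        ],
        species=[("s1", "fish", "LC"), ("s2", "mollusc", "CR")],
        occurrences=[("s1", "A"), ("s1", "B"), ("s2", "B"), ("s2", "C")],
    )


@pytest.fixture(scope="session")
def small_world():
    """A small generated world reused by read-only tests."""
    cfg = WorldConfig(
        n_catchments=40,
        n_outlets=5,
        n_ecoregions=5,
        n_species={"fish": 12, "mollusc": 12, "odonate": 6, "plant": 10},
        range_contiguity=0.7,
        seed=7,
    )
    bundle, truth = generate_world(cfg)
    return bundle, truth, cfg
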