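"""Synthetic catchment worlds with the structure the analysis assumes.

Real inputs to this kind of prioritization — basin-hierarchy catchments,
expert-mapped species ranges, protected-area overlays — are large downloads;
the generator emulates their statistical structure so every pipeline stage is
testable offline:

* **Topology** — a forest of dendritic trees (each outlet a root, each other
  catchment pointing downstream to its parent), acyclic by construction;
  with probability ``topology_elongation`` a new catchment extends the most
  recently added one, otherwise it branches off a uniformly chosen existing
  catchment, producing the long mainstem-plus-tributary chains of real river
  networks rather than shallow star-like trees; catchment areas i.i.d. lognormal, optionally rank-coupled
  negatively to species richness (``area_richness_bias``) because
  high-endemism hotspot catchments — mountainous, coastal, karstic — run
  smaller than the continental average; an undirected adjacency graph of the
  tree edges plus a configurable fraction of terrestrial cross-links.
* **Ecoregions** — whole trees, merged smallest-first when there are more
  trees than ecoregions, mirroring how freshwater ecoregion boundaries follow
  drainage divides.
* **Species** — each range grows from a seed catchment along the adjacency
  graph until it reaches a geometrically distributed target size (mean
  1/(1 − ``range_contiguity``), truncated by component boundaries), so
  ranges are connected subgraphs as in catchment-based range mapping and
  terrestrial cross-links let them span drainage divides, as real dispersal
  does.  The smallest-ranged ``hotspot_fraction`` of species seed at one of
  ``n_hotspots`` hotspot catchments — reproducing how range-restricted
  species cluster in refugium-like endemism hotspots — while widespread
  species seed uniformly.  Red List statuses are drawn i.i.d. from a mixture
  approximating the status frequencies of European freshwater taxa and, by
  default, rank-aligned so that the most threatened categories carry the
  smallest ranges (``threat_range_bias``), as in real Red List data.
* **Protection** — i.i.d. beta fractions, rank-aligned toward species-rich
  catchments (``protection_biodiversity_bias``; protected areas are in part
  designated for biodiversity, so protection and richness correlate
  positively in real data), then smoothed once along the adjacency graph for
  spatial autocorrelation.  The alignment is a pure permutation, so the
  marginal distribution stays exactly beta; with the defaults some
  catchments exceed the 70% well-protected threshold so protection
  scenarios bite.
* **Planted structures** — optionally, threatened (CR) fish species confined
  to well-protected catchments in two different ecoregions, giving worlds a
  known priority/protection conflict for scenario comparisons.

Ground truth (endemic species, endemism-qualifying catchments, planted
species, well-protected catchments) is computed with independent plain-Python
code and returned alongside the bundle for assertions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .io import write_world
from .types import REDLIST_STATUSES, WorldBundle

_DEFAULT_N_SPECIES = {"fish": 94, "mollusc": 121, "odonate": 23, "plant": 62}
_DEFAULT_STATUS_P = {"CR": 0.09, "EN": 0.09, "VU": 0.16, "NT": 0.08,
                     "LC": 0.52, "DD": 0.06}
_SEVERITY = {"CR": 0, "EN": 1, "VU": 2, "NT": 3, "LC": 4, "DD": 5}


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the world generator (defaults emulate the real-data setting,
    scaled to desk size: ~200 catchments standing in for ~19k, species counts
    in the observed taxon ratio, mean catchment area ~500 km²)."""

    n_catchments: int = 200
    n_outlets: int = 25
    topology_elongation: float = 0.6
    area_lognormal_params: Tuple[float, float] = (7.8, 0.8)
    n_species: Dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_N_SPECIES)
    )
    status_probabilities: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_STATUS_P)
    )
    range_contiguity: float = 0.95
    n_hotspots: int = 1
    hotspot_fraction: float = 0.4
    threat_range_bias: float = 1.0
    n_ecoregions: int = 25
    protection_beta_params: Tuple[float, float] = (0.25, 1.5)
    protection_autocorrelation: float = 0.25
    protection_biodiversity_bias: float = 0.65
    area_richness_bias: float = 0.5
    cross_link_fraction: float = 0.3
    well_protected_threshold: float = 0.70
    endemism_fraction: float = 0.05
    n_planted_protected_threatened: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_catchments < 1 or self.n_outlets < 1:
            raise ValueError("counts must be positive")
        if self.n_outlets > self.n_catchments:
            raise ValueError("n_outlets cannot exceed n_catchments")
        if not 0.0 <= self.topology_elongation <= 1.0:
            raise ValueError("topology_elongation must be in [0, 1]")
        total_p = sum(self.status_probabilities.values())
        if abs(total_p - 1.0) > 1e-9:
            raise ValueError(f"status probabilities sum to {total_p}, not 1")
        if set(self.status_probabilities) - set(REDLIST_STATUSES):
            raise ValueError("unknown Red List categories in status_probabilities")
        if not 0.0 <= self.range_contiguity <= 1.0:
            raise ValueError("range_contiguity must be in [0, 1]")
        if not 0.0 <= self.hotspot_fraction <= 1.0:
            raise ValueError("hotspot_fraction must be in [0, 1]")
        if self.n_hotspots < 0:
            raise ValueError("n_hotspots must be nonnegative")
        if not 0.0 <= self.protection_autocorrelation <= 1.0:
            raise ValueError("protection_autocorrelation must be in [0, 1]")
        if not 0.0 <= self.protection_biodiversity_bias <= 1.0:
            raise ValueError("protection_biodiversity_bias must be in [0, 1]")
        if not 0.0 <= self.area_richness_bias <= 1.0:
            raise ValueError("area_richness_bias must be in [0, 1]")
        if any(n < 0 for n in self.n_species.values()):
            raise ValueError("species counts must be nonnegative")

    def replace(self, **kw) -> "WorldConfig":
        return replace(self, **kw)


def _cat_id(i: int, width: int) -> str:
    return f"C{i:0{width}d}"


def _copula_align(
    values: np.ndarray, scores: np.ndarray, bias: float, rng: np.random.Generator
) -> np.ndarray:
    """Permute ``values`` so larger ones tend to sit where ``scores`` are high.

    Gaussian-copula rank coupling with latent correlation ``bias``; being a
    pure permutation it preserves the marginal distribution exactly.
    """
    n = len(values)
    if bias <= 0 or n < 2:
        return values
    rank = np.argsort(np.argsort(scores, kind="stable"), kind="stable")
    z_score = (rank - rank.mean()) / max(rank.std(), 1e-12)
    z = bias * z_score + math.sqrt(max(0.0, 1.0 - bias**2)) * rng.normal(size=n)
    aligned = np.empty(n)
    aligned[np.argsort(-z, kind="stable")] = np.sort(values)[::-1]
    return aligned


def generate_topology(
    config: WorldConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Dendritic catchment forest with areas, ecoregions and adjacency.

    Returns ``(catchments, adjacency)``: a catchment table (without
    protection, added separately) and the undirected adjacency pairs.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n, k = config.n_catchments, config.n_outlets
    width = max(4, len(str(n)))
    ids = [_cat_id(i, width) for i in range(n)]

    parent = [-1] * n  # roots are nodes 0..k-1
    root = list(range(n))
    tree_nodes = {r: [r] for r in range(k)}  # members per basin
    tip = {r: r for r in range(k)}           # most recently added member
    for i in range(k, n):
        # pick a basin (proportionally to size), then either extend its
        # current tip upstream (mainstem growth) or branch off a uniform
        # member (tributary)
        j = int(rng.integers(0, i))  # uniform over existing nodes = size-biased
        t = root[j]
        if rng.random() < config.topology_elongation:
            p = tip[t]
        else:
            members = tree_nodes[t]
            p = members[int(rng.integers(0, len(members)))]
        parent[i] = p
        root[i] = t
        tree_nodes[t].append(i)
        tip[t] = i

    # ecoregions: whole trees, merging the smallest groups down to n_ecoregions
    trees: Dict[int, list] = {r: [] for r in range(k)}
    for i in range(n):
        trees[root[i]].append(i)
    groups = [sorted(members) for members in trees.values()]
    groups.sort(key=len)
    while len(groups) > config.n_ecoregions:
        a = groups.pop(0)
        b = groups.pop(0)
        merged = sorted(a + b)
        groups.append(merged)
        groups.sort(key=len)
    eco = [""] * n
    for g_idx, members in enumerate(sorted(groups, key=lambda g: g[0])):
        for i in members:
            eco[i] = f"E{g_idx + 1}"

    mu, sigma = config.area_lognormal_params
    areas = rng.lognormal(mu, sigma, size=n)

    catchments = pd.DataFrame(
        {
            "area_km2": areas,
            "downstream_id": [
                ids[parent[i]] if parent[i] >= 0 else pd.NA for i in range(n)
            ],
            "ecoregion_id": eco,
            "country_code": pd.NA,
            "protected_fraction": 0.0,
            "lock_status": "available",
        },
        index=pd.Index(ids, name="id"),
    )

    edges = {(min(i, parent[i]), max(i, parent[i])) for i in range(n) if parent[i] >= 0}
    n_cross = int(round(config.cross_link_fraction * n))
    attempts = 0
    while n_cross > 0 and attempts < 50 * max(1, n_cross) and n > 1:
        a, b = int(rng.integers(0, n)), int(rng.integers(0, n))
        attempts += 1
        if a == b:
            continue
        e = (min(a, b), max(a, b))
        if e in edges:
            continue
        edges.add(e)
        n_cross -= 1
    adjacency = pd.DataFrame(
        sorted((ids[a], ids[b], 1.0) for a, b in edges),
        columns=["id1", "id2", "weight"],
    )
    return catchments, adjacency


def _river_neighbours(catchments: pd.DataFrame) -> Dict[int, list]:
    ids = list(catchments.index)
    idx = {cid: i for i, cid in enumerate(ids)}
    nbrs: Dict[int, list] = {i: [] for i in range(len(ids))}
    for cid, down in catchments["downstream_id"].items():
        if pd.notna(down):
            i, j = idx[cid], idx[down]
            nbrs[i].append(j)
            nbrs[j].append(i)
    return nbrs


def generate_species(
    catchments: pd.DataFrame,
    config: WorldConfig,
    rng: Optional[np.random.Generator] = None,
    adjacency: Optional[pd.DataFrame] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Species records and contiguous occurrence ranges.

    Ranges grow along the adjacency graph (river edges plus terrestrial
    cross-links; river edges only if no adjacency is given) to a geometric
    target size with continuation parameter ``range_contiguity`` (expected
    size 1/(1−p) catchments, truncated by component boundaries).  The
    smallest-ranged ``hotspot_fraction`` of species seed at one of
    ``n_hotspots`` hotspot catchments; the rest seed uniformly.  Statuses are
    drawn i.i.d. and, with ``threat_range_bias`` > 0, rank-aligned so threat
    tracks small range size.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ids = list(catchments.index)
    n = len(ids)
    nbrs = _river_neighbours(catchments)
    if adjacency is not None and len(adjacency):
        idx = {cid: i for i, cid in enumerate(ids)}
        nbrs = {i: [] for i in range(n)}
        for i1, i2 in adjacency[["id1", "id2"]].itertuples(index=False):
            a, b = idx[i1], idx[i2]
            nbrs[a].append(b)
            nbrs[b].append(a)
    p = config.range_contiguity

    taxa = [g for g, cnt in sorted(config.n_species.items()) for _ in range(cnt)]
    m = len(taxa)
    width = max(4, len(str(m)))
    sp_ids = [f"S{i:0{width}d}" for i in range(m)]

    # geometric target sizes (mean 1/(1-p)); p = 0 gives all singletons
    sizes = rng.geometric(1.0 - p, size=m) if p < 1.0 else np.full(m, n)
    hotspots = (
        rng.choice(n, size=min(config.n_hotspots, n), replace=False)
        if config.n_hotspots > 0
        else np.array([], dtype=int)
    )
    n_hot_species = int(round(config.hotspot_fraction * m)) if len(hotspots) else 0
    small_first = np.argsort(sizes, kind="stable")
    hot_set = set(small_first[:n_hot_species].tolist())

    ranges = []
    for s in range(m):
        if s in hot_set:
            start = int(hotspots[int(rng.integers(0, len(hotspots)))])
        else:
            start = int(rng.integers(0, n))
        in_range = {start}
        frontier = set(nbrs[start])
        target_size = int(sizes[s])
        while frontier and len(in_range) < target_size:
            # compact growth: prefer the frontier catchment most connected
            # to the range, as ranges are nested sub-basins rather than
            # random dendritic sprawl; ties broken at random
            cands = sorted(frontier)
            links = [sum(1 for k in nbrs[c] if k in in_range) for c in cands]
            best = max(links)
            top = [c for c, l in zip(cands, links) if l == best]
            pick = top[int(rng.integers(0, len(top)))]
            in_range.add(pick)
            frontier.discard(pick)
            frontier.update(k for k in nbrs[pick] if k not in in_range)
        ranges.append(sorted(in_range))

    cats = list(config.status_probabilities)
    probs = np.array([config.status_probabilities[c] for c in cats])
    statuses = list(rng.choice(cats, size=m, p=probs))
    if config.threat_range_bias > 0 and m > 1:
        # align threat with small ranges, then decay by random swaps
        order = np.argsort([len(r) for r in ranges], kind="stable")
        ranked = sorted(statuses, key=lambda s: _SEVERITY[s])
        aligned = [None] * m
        for pos, sp in enumerate(order):
            aligned[sp] = ranked[pos]
        n_swaps = int(round((1.0 - config.threat_range_bias) * m))
        for _ in range(n_swaps):
            a, b = int(rng.integers(0, m)), int(rng.integers(0, m))
            aligned[a], aligned[b] = aligned[b], aligned[a]
        statuses = aligned

    species = pd.DataFrame(
        {"taxon_group": taxa, "redlist_status": statuses},
        index=pd.Index(sp_ids, name="id"),
    )
    occ_rows = [
        (sp_ids[s], ids[c]) for s in range(m) for c in ranges[s]
    ]
    occurrences = pd.DataFrame(occ_rows, columns=["species_id", "catchment_id"])
    occurrences = occurrences.sort_values(
        ["species_id", "catchment_id"], ignore_index=True
    )
    return species, occurrences


def generate_protection(
    catchments: pd.DataFrame,
    adjacency: pd.DataFrame,
    config: WorldConfig,
    rng: Optional[np.random.Generator] = None,
    richness: Optional[pd.Series] = None,
) -> pd.Series:
    """Spatially structured protected fractions.

    Beta-distributed fractions; with ``protection_biodiversity_bias`` > 0
    and a per-catchment ``richness`` series, the draws are rank-aligned so
    higher protection tends to sit on species-rich catchments (a pure
    permutation — the marginal stays beta).  Values are then smoothed once
    toward the mean of each catchment's adjacency neighbours with weight
    ``protection_autocorrelation`` and clamped to [0, 1].
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ids = list(catchments.index)
    n = len(ids)
    idx = {cid: i for i, cid in enumerate(ids)}
    a, b = config.protection_beta_params
    x = rng.beta(a, b, size=n)
    bias = config.protection_biodiversity_bias
    if bias > 0 and richness is not None and n > 1:
        rich = richness.reindex(catchments.index).fillna(0).to_numpy(dtype=float)
        x = _copula_align(x, rich, bias, rng)
    w = config.protection_autocorrelation
    if w > 0 and len(adjacency):
        nbr_sum = np.zeros(len(ids))
        nbr_cnt = np.zeros(len(ids))
        for i1, i2 in adjacency[["id1", "id2"]].itertuples(index=False):
            a_i, b_i = idx[i1], idx[i2]
            nbr_sum[a_i] += x[b_i]
            nbr_sum[b_i] += x[a_i]
            nbr_cnt[a_i] += 1
            nbr_cnt[b_i] += 1
        has = nbr_cnt > 0
        smoothed = x.copy()
        smoothed[has] = (1 - w) * x[has] + w * nbr_sum[has] / nbr_cnt[has]
        x = smoothed
    return pd.Series(np.clip(x, 0.0, 1.0), index=catchments.index,
                     name="protected_fraction")


def _plant_protected_threatened(
    catchments: pd.DataFrame,
    species: pd.DataFrame,
    occurrences: pd.DataFrame,
    config: WorldConfig,
    rng: np.random.Generator,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list]:
    """Add CR fish confined to well-protected catchments.

    Each planted species occupies one catchment in each of two ecoregions
    (one, if the world has a single ecoregion).  Homes are naturally
    well-protected catchments where available (richest first — protected
    areas sit on biodiverse catchments); otherwise the richest catchment of
    another ecoregion has its protected fraction raised above the threshold.
    """
    cat = catchments.copy()
    richness = occurrences.groupby("catchment_id").size().reindex(
        cat.index, fill_value=0
    )
    planted_rows = []
    occ_rows = []
    planted_ids = []
    for k in range(config.n_planted_protected_threatened):
        wp = cat.index[cat["protected_fraction"] > config.well_protected_threshold]
        wp = sorted(wp, key=lambda c: (-richness[c], c))
        home, used_ecos = [], set()
        for cid in wp:  # richest naturally protected catchments, distinct ecoregions
            eco = cat.at[cid, "ecoregion_id"]
            if eco not in used_ecos:
                home.append(cid)
                used_ecos.add(eco)
            if len(home) == 2:
                break
        while len(home) < 2:
            remaining = sorted(set(cat["ecoregion_id"]) - used_ecos)
            if not remaining:
                break
            eco = remaining[int(rng.integers(0, len(remaining)))]
            members = cat.index[cat["ecoregion_id"] == eco]
            cid = max(members, key=lambda c: (richness[c], c))
            cat.at[cid, "protected_fraction"] = float(rng.uniform(0.75, 0.95))
            home.append(cid)
            used_ecos.add(eco)
        home = sorted(set(home))
        sid = f"P{k:04d}"
        planted_ids.append(sid)
        planted_rows.append({"id": sid, "taxon_group": "fish", "redlist_status": "CR"})
        occ_rows.extend({"species_id": sid, "catchment_id": cid} for cid in home)
    if planted_rows:
        species = pd.concat(
            [species, pd.DataFrame(planted_rows).set_index("id")]
        ).sort_index()
        occurrences = pd.concat(
            [occurrences, pd.DataFrame(occ_rows)], ignore_index=True
        ).sort_values(["species_id", "catchment_id"], ignore_index=True)
    return cat, species, occurrences, planted_ids


def _ground_truth(
    catchments: pd.DataFrame,
    species: pd.DataFrame,
    occurrences: pd.DataFrame,
    config: WorldConfig,
    planted_ids: list,
) -> dict:
    # independent plain-python recomputation, used as oracle in tests
    eco = catchments["ecoregion_id"].to_dict()
    prot = catchments["protected_fraction"].to_dict()
    occ_by_species: Dict[str, list] = {}
    occ_by_catchment: Dict[str, list] = {}
    for sp, cid in occurrences[["species_id", "catchment_id"]].itertuples(index=False):
        occ_by_species.setdefault(sp, []).append(cid)
        occ_by_catchment.setdefault(cid, []).append(sp)
    endemic = sorted(
        sp for sp, cids in occ_by_species.items()
        if len({eco[c] for c in cids}) == 1
    )
    endemic_set = set(endemic)
    fm = {
        sp for sp in species.index
        if species.at[sp, "taxon_group"] in ("fish", "mollusc")
    }
    endemism_locked = []
    for cid in catchments.index:
        present_fm = [sp for sp in occ_by_catchment.get(cid, []) if sp in fm]
        if not present_fm:
            continue
        n_endemic = sum(1 for sp in present_fm if sp in endemic_set)
        if n_endemic / len(present_fm) >= config.endemism_fraction:
            endemism_locked.append(cid)
    well = sorted(
        cid for cid in catchments.index
        if prot[cid] > config.well_protected_threshold
    )
    return {
        "endemic_species": endemic,
        "endemism_locked_catchments": sorted(endemism_locked),
        "well_protected_catchments": well,
        "planted_species": sorted(planted_ids),
    }


def generate_world(
    config: Optional[WorldConfig] = None,
    out_dir=None,
    seed: Optional[int] = None,
) -> Tuple[WorldBundle, dict]:
    """Generate a complete, validated world bundle plus ground-truth metadata.

    A ``seed`` argument overrides ``config.seed``.  When ``out_dir`` is given
    the delimited tables and ``truth.json`` are written there (loadable with
    :func:`freshprior.io.load_world`).
    """
    config = config if config is not None else WorldConfig()
    if seed is not None:
        config = config.replace(seed=seed)
    rng = np.random.default_rng(config.seed)
    catchments, adjacency = generate_topology(config, rng)
    species, occurrences = generate_species(catchments, config, rng,
                                            adjacency=adjacency)
    richness = occurrences.groupby("catchment_id").size()
    if config.area_richness_bias > 0:
        rich = richness.reindex(catchments.index, fill_value=0).to_numpy(dtype=float)
        catchments["area_km2"] = _copula_align(
            catchments["area_km2"].to_numpy(), -rich, config.area_richness_bias, rng
        )
    catchments["protected_fraction"] = generate_protection(
        catchments, adjacency, config, rng, richness=richness
    )
    planted_ids: list = []
    if config.n_planted_protected_threatened > 0:
        catchments, species, occurrences, planted_ids = _plant_protected_threatened(
            catchments, species, occurrences, config, rng
        )
    truth = _ground_truth(catchments, species, occurrences, config, planted_ids)
    bundle = WorldBundle(
        catchments=catchments,
        species=species,
        occurrences=occurrences,
        adjacency=adjacency,
    )
    if out_dir is not None:
        write_world(bundle, out_dir)
        (Path(out_dir) / "truth.json").write_text(json.dumps(truth, indent=1))
    return bundle, truth
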