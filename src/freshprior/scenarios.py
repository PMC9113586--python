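"""Scenario resolution: endemism lock-ins, protection locks, problem assembly.

Three protection scenarios are modelled:

1. catchment protection ignored;
2. well-protected catchments (protected fraction strictly above 70% by
   default) locked IN a priori — does considering existing protection improve
   efficiency?
3. well-protected catchments locked OUT — which priority catchments lie
   outside well-protected areas and need further intervention?

Independently of protection, catchments holding unique assemblages — where
ecoregion-restricted ("endemic") fish and mollusc species make up at least 5%
of the fish and mollusc species present — are locked in a priori in every
scenario.  A catchment that is both endemism-locked and well-protected under
Scenario 3 resolves to locked-in: the endemism rule is a biodiversity
statement and takes precedence over the protection exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Set

import pandas as pd
import yaml

from .types import WorldBundle, build_connectivity

_FISH_MOLLUSC = ("fish", "mollusc")


@dataclass(frozen=True)
class ScenarioConfig:
    """Solver-facing configuration of one prioritization scenario.

    Parameters mirror the standard reserve-selection setup: area is the cost,
    the solution's total area is (softly) capped at ``area_cap_fraction`` of
    the planning region (17%, the Aichi Target 11 level), spatial structure is
    penalized either through total exposed boundary (``boundary`` mode, weight
    ``blm``) or through broken upstream river connections (``river`` mode,
    weight ``cp``).
    """

    protection_rule: str = "ignore"  # ignore | lock_in_well_protected | lock_out_well_protected
    well_protected_threshold: float = 0.70
    endemism_lock_in: bool = True
    endemism_fraction: float = 0.05
    connectivity_mode: str = "boundary"  # boundary | river
    blm: float = 10.0
    cp: float = 10.0
    area_cap_fraction: float = 0.17
    n_runs: int = 1000
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.protection_rule not in (
            "ignore", "lock_in_well_protected", "lock_out_well_protected"
        ):
            raise ValueError(f"bad protection_rule {self.protection_rule!r}")
        if self.connectivity_mode not in ("boundary", "river"):
            raise ValueError(f"bad connectivity_mode {self.connectivity_mode!r}")
        for name in ("well_protected_threshold", "endemism_fraction",
                     "area_cap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.blm < 0 or self.cp < 0:
            raise ValueError("blm and cp must be nonnegative")

    @classmethod
    def preset(cls, scenario: int, **overrides) -> "ScenarioConfig":
        """Named presets: scenario 1, 2 or 3 (see module docstring)."""
        rules = {
            1: "ignore",
            2: "lock_in_well_protected",
            3: "lock_out_well_protected",
        }
        if scenario not in rules:
            raise ValueError(f"scenario must be 1, 2 or 3, got {scenario}")
        return cls(protection_rule=rules[scenario], **overrides)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "scenario" in raw:
            scenario = raw.pop("scenario")
            return cls.preset(int(scenario), **raw)
        return cls(**raw)

    def replace(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


def endemic_species(occ: pd.DataFrame, catchments: pd.DataFrame) -> Set[str]:
    """Species whose occupied catchments lie within a single ecoregion."""
    eco = catchments["ecoregion_id"]
    per_species = occ.assign(eco=eco.loc[occ["catchment_id"]].values)
    n_eco = per_species.groupby("species_id")["eco"].nunique()
    return set(n_eco.index[n_eco == 1].astype(str))


def endemism_locked_catchments(
    occ: pd.DataFrame,
    catchments: pd.DataFrame,
    species: pd.DataFrame,
    endemism_fraction: float = 0.05,
) -> Set[str]:
    """Catchments whose assemblages qualify as unique.

    A catchment qualifies when endemic fish+mollusc species present make up at
    least ``endemism_fraction`` of all fish+mollusc species present.
    Catchments holding no fish or mollusc species never qualify (the ratio is
    undefined, not zero).
    """
    endemics = endemic_species(occ, catchments)
    fm_species = set(
        species.index[species["taxon_group"].isin(_FISH_MOLLUSC)].astype(str)
    )
    fm_occ = occ[occ["species_id"].isin(fm_species)]
    if not len(fm_occ):
        return set()
    totals = fm_occ.groupby("catchment_id").size()
    endemic_counts = (
        fm_occ[fm_occ["species_id"].isin(endemics)].groupby("catchment_id").size()
    ).reindex(totals.index, fill_value=0)
    frac = endemic_counts / totals
    return set(frac.index[frac >= endemism_fraction].astype(str))


def resolve_locks(
    catchments: pd.DataFrame,
    config: ScenarioConfig,
    endemism_locked: Optional[Set[str]] = None,
) -> pd.Series:
    """Lock status per catchment under the scenario's rules.

    Well-protected means protected_fraction strictly above the threshold
    ("exceeded 70%").  The endemism lock-in wins any conflict with a
    Scenario-3 exclusion.
    """
    endemism_locked = endemism_locked or set()
    status = pd.Series("available", index=catchments.index, dtype=object)
    well = catchments["protected_fraction"] > config.well_protected_threshold
    if config.protection_rule == "lock_in_well_protected":
        status[well] = "locked_in"
    elif config.protection_rule == "lock_out_well_protected":
        status[well] = "locked_out"
    if config.endemism_lock_in and endemism_locked:
        status[status.index.isin(endemism_locked)] = "locked_in"
    return status


@dataclass
class Problem:
    """A fully resolved, solvable prioritization problem."""

    bundle: WorldBundle
    targets: pd.DataFrame
    lock_status: pd.Series
    config: ScenarioConfig
    area_cap_km2: float
    connectivity: pd.DataFrame    # directed river connections (river mode)
    adjacency: pd.DataFrame       # undirected boundary pairs (boundary mode)
    warnings: list = field(default_factory=list)

    @property
    def catchment_ids(self):
        return self.bundle.catchments.index

    def locked_in_ids(self) -> Set[str]:
        return set(self.lock_status.index[self.lock_status == "locked_in"].astype(str))

    def locked_out_ids(self) -> Set[str]:
        return set(self.lock_status.index[self.lock_status == "locked_out"].astype(str))


def build_problem(
    bundle: WorldBundle,
    targets: pd.DataFrame,
    config: ScenarioConfig,
) -> Problem:
    """Resolve locks and package everything the solver needs.

    The area cap is ``area_cap_fraction`` × total world area.  If the locked-in
    area alone already exceeds the cap a feasibility warning is recorded on the
    problem (and emitted) but assembly proceeds — the cap is a soft penalty.
    """
    endemism = (
        endemism_locked_catchments(
            bundle.occurrences, bundle.catchments, bundle.species,
            config.endemism_fraction,
        )
        if config.endemism_lock_in
        else set()
    )
    locks = resolve_locks(bundle.catchments, config, endemism)
    cap = config.area_cap_fraction * bundle.total_area_km2

    notes = []
    locked_in_area = float(
        bundle.catchments.loc[locks == "locked_in", "area_km2"].sum()
    )
    if locked_in_area > cap:
        msg = (
            f"locked-in area {locked_in_area:.1f} km² exceeds the area cap "
            f"{cap:.1f} km²; solutions will carry a cap penalty"
        )
        notes.append(msg)
        warnings.warn(msg, stacklevel=2)

    adjacency = bundle.adjacency
    if config.connectivity_mode == "boundary" and not len(adjacency):
        adjacency = bundle.river_adjacency()

    return Problem(
        bundle=bundle,
        targets=targets,
        lock_status=locks,
        config=config,
        area_cap_km2=cap,
        connectivity=build_connectivity(bundle.catchments),
        adjacency=adjacency,
        warnings=notes,
    )
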