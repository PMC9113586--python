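"""Minimum-set solver: objective, annealing, portfolios, coverage, sweeps."""

import itertools
import random

import numpy as np
import pandas as pd
import pytest

import freshprior as fp
from freshprior import ScenarioConfig, WorldConfig, build_problem, generate_world
from freshprior.solver import AnnealState, CompiledProblem, exhaustive_optimum

from conftest import make_bundle


def _chain_problem(targets_zero=False, cp=10.0, mode="river", **cfg_kw):
    bundle = make_bundle(
        catchments=[
            {"id": "A", "area_km2": 100.0, "downstream_id": "B"},
            {"id": "B", "area_km2": 100.0, "downstream_id": "C"},
            {"id": "C", "area_km2": 100.0},
        ],
        species=[("s1", "fish", "LC")],
        occurrences=[("s1", "B")],
        adjacency=[("A", "B", 1.0), ("B", "C", 1.0)],
    )
    targets = fp.build_target_table(bundle)
    if targets_zero:
        targets["target"] = 0
    cfg = ScenarioConfig.preset(1, connectivity_mode=mode, cp=cp,
                                endemism_lock_in=False, **cfg_kw)
    return bundle, build_problem(bundle, targets, cfg)


class TestObjective:
    def test_empty_selection_zero_targets_is_zero(self):
        _, prob = _chain_problem(targets_zero=True)
        sol = fp.objective(prob, [])
        assert sol.objective == 0.0

    def test_river_penalty_is_asymmetric(self):
        # select {B}: connection (A,B) has downstream selected, upstream not
        # -> penalized; (B,C) has only the upstream selected -> no penalty
        _, prob = _chain_problem(targets_zero=True, cp=10.0)
        sol = fp.objective(prob, ["B"])
        assert sol.structure_penalty == pytest.approx(10.0)
        sol2 = fp.objective(prob, ["A", "B"])
        assert sol2.structure_penalty == pytest.approx(0.0)

    def test_boundary_penalty_counts_exposed_edges(self):
        _, prob = _chain_problem(targets_zero=True, mode="boundary", blm=10.0)
        sol = fp.objective(prob, ["B"])  # both incident edges exposed
        assert sol.structure_penalty == pytest.approx(20.0)

    def test_cost_is_selected_area(self):
        _, prob = _chain_problem(targets_zero=True)
        assert fp.objective(prob, ["A", "C"]).cost == pytest.approx(200.0)

    def test_lock_violation_raises(self):
        bundle, _ = _chain_problem()
        bundle.catchments.loc["A", "lock_status"] = "locked_in"
        targets = fp.build_target_table(bundle)
        prob = build_problem(bundle, targets, ScenarioConfig.preset(1))
        prob.lock_status["A"] = "locked_in"
        with pytest.raises(ValueError, match="locked-in"):
            fp.objective(prob, ["B"])


def _small_instance(seed, n=8):
    cfg = WorldConfig(
        n_catchments=n, n_outlets=2, n_ecoregions=2, n_hotspots=1,
        hotspot_fraction=0.3, range_contiguity=0.5,
        n_species={"fish": 4, "mollusc": 3, "odonate": 2, "plant": 3},
        n_planted_protected_threatened=0, seed=seed,
    )
    bundle, _ = generate_world(cfg)
    targets = fp.build_target_table(bundle)
    scen = ScenarioConfig.preset(
        1, connectivity_mode="river" if seed % 2 else "boundary",
        endemism_lock_in=False,
    )
    return build_problem(bundle, targets, scen)


def _independent_objective(problem, selected):
    """Objective recomputed from first principles, straight off the tables."""
    chosen = set(selected)
    cat = problem.bundle.catchments
    cost = float(cat.loc[sorted(chosen), "area_km2"].sum())
    short = 0.0
    occ = problem.bundle.occurrences
    for sid, row in problem.targets.iterrows():
        t = int(row["target"])
        if t <= 0:
            continue
        captured = occ[(occ["species_id"] == sid)
                       & (occ["catchment_id"].isin(chosen))].shape[0]
        if captured < t:
            short += row["penalty_factor"] * (t - captured) / t
    cfg = problem.config
    struct = 0.0
    if cfg.connectivity_mode == "river":
        for _, r in problem.connectivity.iterrows():
            if r["downstream_id"] in chosen and r["upstream_id"] not in chosen:
                struct += cfg.cp * r["weight"]
    else:
        for _, r in problem.adjacency.iterrows():
            if (r["id1"] in chosen) != (r["id2"] in chosen):
                struct += cfg.blm * r["weight"]
    cap_pen = 1000.0 * max(0.0, cost - problem.area_cap_km2)
    return cost + short + struct + cap_pen


class TestAnneal:
    def test_dominant_catchment_selected(self):
        # one cheap catchment holds every occurrence and fits the cap
        bundle = make_bundle(
            catchments=[{"id": "HOT", "area_km2": 100.0},
                        {"id": "COLD", "area_km2": 5000.0}],
            species=[("s1", "fish", "CR"), ("s2", "plant", "CR")],
            occurrences=[("s1", "HOT"), ("s2", "HOT")],
        )
        targets = fp.build_target_table(bundle)
        prob = build_problem(bundle, targets, ScenarioConfig.preset(1))
        sol = fp.anneal(prob, seed=0, n_iterations=500)
        assert sol.selected == ("HOT",)
        assert sol.shortfall_penalty == 0.0

    def test_all_locked_in_returns_full_set(self):
        bundle, _ = _chain_problem()
        bundle.catchments["lock_status"] = "locked_in"
        targets = fp.build_target_table(bundle)
        prob = build_problem(bundle, targets, ScenarioConfig.preset(1))
        prob.lock_status[:] = "locked_in"
        sol = fp.anneal(prob, seed=1, n_iterations=100)
        assert set(sol.selected) == {"A", "B", "C"}
        assert sol.shortfall_penalty == 0.0

    def test_deterministic_for_fixed_seed(self):
        prob = _small_instance(3)
        s1 = fp.anneal(prob, seed=42, n_iterations=500)
        s2 = fp.anneal(prob, seed=42, n_iterations=500)
        assert s1 == s2

    def test_matches_itertools_brute_force(self):
        # fully independent enumeration, objective recomputed off the tables
        prob = _small_instance(0, n=7)
        ids = sorted(prob.bundle.catchments.index)
        best = min(
            (
                _independent_objective(prob, subset)
                for r in range(len(ids) + 1)
                for subset in itertools.combinations(ids, r)
            )
        )
        sol = min(
            (fp.anneal(prob, seed=s, n_iterations=400) for s in range(20)),
            key=lambda s: s.objective,
        )
        assert sol.objective == pytest.approx(best, rel=1e-9)
        # and the package's own enumeration agrees
        assert exhaustive_optimum(prob).objective == pytest.approx(best, rel=1e-9)


class TestIncrementalObjective:
    @pytest.mark.parametrize("mode", ["boundary", "river"])
    def test_thousand_move_audit(self, mode):
        cfg = WorldConfig(n_catchments=30, n_outlets=3, n_ecoregions=3,
                          n_species={"fish": 8, "mollusc": 8, "odonate": 4,
                                     "plant": 4},
                          range_contiguity=0.7, seed=11)
        bundle, _ = generate_world(cfg)
        targets = fp.build_target_table(bundle)
        prob = build_problem(bundle, targets,
                             ScenarioConfig.preset(1, connectivity_mode=mode))
        c = CompiledProblem(prob)
        state = AnnealState(c)
        rng = random.Random(5)
        for _ in range(1000):
            state.toggle(rng.randrange(c.n))
        audit = state.audit()  # from-scratch recomputation
        incremental = (
            state.cost + state.short + state.struct
            + c.cap_weight * max(0.0, state.cost - c.cap)
        )
        assert incremental == pytest.approx(audit.objective, rel=1e-9)
        assert state.objective() == pytest.approx(audit.objective, rel=1e-9)


class TestPortfolio:
    def _locked_problem(self):
        bundle = make_bundle(
            catchments=[
                {"id": "IN", "area_km2": 100.0, "protected_fraction": 0.9},
                {"id": "OUT", "area_km2": 100.0, "protected_fraction": 0.8},
                {"id": "FREE", "area_km2": 100.0},
            ],
            species=[("s1", "fish", "CR")],
            occurrences=[("s1", "FREE")],
        )
        targets = fp.build_target_table(bundle)
        prob = build_problem(bundle, targets, ScenarioConfig.preset(1))
        prob.lock_status["IN"] = "locked_in"
        prob.lock_status["OUT"] = "locked_out"
        return prob

    def test_lock_frequencies(self):
        prob = self._locked_problem()
        res = fp.run_portfolio(prob, n_runs=5, base_seed=0, n_iterations=200)
        assert res.selection_frequency["IN"] == 5
        assert res.selection_frequency["OUT"] == 0

    def test_single_run_frequencies_binary(self):
        prob = _small_instance(4)
        res = fp.run_portfolio(prob, n_runs=1, base_seed=0, n_iterations=300)
        assert res.selection_frequency.isin([0, 1]).all()

    def test_twin_catchments_split_runs_evenly(self):
        # identical twin catchments, either alone meets the target: selection
        # frequency should be ~binomial(n_runs, 1/2) for each twin
        bundle = make_bundle(
            catchments=[{"id": "T1", "area_km2": 100.0},
                        {"id": "T2", "area_km2": 100.0}],
            species=[("s1", "fish", "LC")],
            occurrences=[("s1", "T1"), ("s1", "T2")],
        )
        targets = fp.build_target_table(bundle)
        targets["target"] = 1
        prob = build_problem(
            bundle,
            targets,
            ScenarioConfig.preset(1, endemism_lock_in=False,
                                  area_cap_fraction=0.6),  # room for one twin
        )
        n_runs = 200
        res = fp.run_portfolio(prob, n_runs=n_runs, base_seed=0, n_iterations=60)
        f1 = res.selection_frequency["T1"]
        assert res.selection_frequency.sum() == n_runs  # exactly one selected
        sigma = (n_runs * 0.25) ** 0.5
        assert abs(f1 - n_runs / 2) < 3 * sigma

    def test_reproducible_tables(self):
        prob = _small_instance(5)
        r1 = fp.run_portfolio(prob, n_runs=4, base_seed=9, n_iterations=300)
        r2 = fp.run_portfolio(prob, n_runs=4, base_seed=9, n_iterations=300)
        assert r1.objective_log.equals(r2.objective_log)
        assert r1.selection_frequency.equals(r2.selection_frequency)
        assert r1.coverage.equals(r2.coverage)
        assert r1.best == r2.best


class TestCoverage:
    def test_partial_coverage_arithmetic(self):
        bundle = make_bundle(
            catchments=[{"id": f"C{i}", "area_km2": 1000.0} for i in range(4)],
            species=[("s1", "fish", "VU")],
            occurrences=[("s1", f"C{i}") for i in range(4)],
        )
        targets = fp.build_target_table(bundle)
        targets["target"] = 3
        prob = build_problem(
            bundle, targets, ScenarioConfig.preset(1, endemism_lock_in=False)
        )
        sol = fp.objective(prob, ["C0", "C1", "C2"])
        cov = fp.coverage_report(sol, prob)
        assert cov.loc["s1", "captured"] == 3
        assert bool(cov.loc["s1", "met"]) is True
        assert cov.loc["s1", "proportion"] == pytest.approx(0.75)

    def test_zero_target_is_vacuously_met(self):
        bundle, prob = _chain_problem(targets_zero=True)
        sol = fp.objective(prob, [])
        cov = fp.coverage_report(sol, prob)
        assert cov["met"].all()

    def test_full_set_meets_everything(self, small_world):
        bundle, _, _ = small_world
        targets = fp.build_target_table(bundle)
        prob = build_problem(bundle, targets, ScenarioConfig.preset(1))
        sol = fp.objective(prob, list(bundle.catchments.index))
        cov = fp.coverage_report(sol, prob)
        assert cov["met"].all()
        assert (cov["proportion"] == 1.0).all()

    def test_status_table_layout(self, small_world):
        bundle, _, _ = small_world
        targets = fp.build_target_table(bundle)
        prob = build_problem(bundle, targets, ScenarioConfig.preset(1))
        sol = fp.objective(prob, list(bundle.catchments.index))
        tab = fp.coverage_by_status(fp.coverage_report(sol, prob))
        assert list(tab.index) == ["CR", "EN", "VU", "NT", "LC", "DD", "Total"]
        assert tab.loc["Total", "met"] == bundle.n_species
        assert tab.loc["Total", "unmet"] == 0


class TestSweep:
    def _world_problem(self, mode="river"):
        cfg = WorldConfig(n_catchments=40, n_outlets=5, n_ecoregions=5,
                          n_species={"fish": 12, "mollusc": 10, "odonate": 4,
                                     "plant": 6},
                          range_contiguity=0.8, seed=21)
        bundle, _ = generate_world(cfg)
        targets = fp.build_target_table(bundle)
        return build_problem(
            bundle, targets, ScenarioConfig.preset(1, connectivity_mode=mode)
        )

    def test_zero_weight_contributes_nothing(self):
        prob = self._world_problem()
        table = fp.sweep_parameter(prob, "cp", [0.0], n_runs=2, n_iterations=300)
        assert table["mean_structure_penalty"].iloc[0] == 0.0

    def test_single_value_single_run_one_row(self):
        prob = self._world_problem()
        table = fp.sweep_parameter(prob, "cp", [10.0], n_runs=1,
                                   n_iterations=300)
        assert len(table) == 1

    def test_broken_connections_nonincreasing_in_cp(self):
        # the raw (unit-weight) connectivity measure of the solutions should
        # not increase as the connectivity penalty grows
        prob = self._world_problem()
        table = fp.sweep_parameter(prob, "cp", [0.0, 10.0, 1000.0], n_runs=10,
                                   n_iterations=2000, base_seed=3)
        raw = table["mean_structure_raw"].to_numpy()
        assert raw[0] >= raw[2] - 1e-9
        assert raw[1] >= raw[2] - 1e-9

    def test_rejects_bad_parameter(self):
        prob = self._world_problem()
        with pytest.raises(ValueError):
            fp.sweep_parameter(prob, "spf", [1.0])
        with pytest.raises(ValueError):
            fp.sweep_parameter(prob, "cp", [])


class TestMonotoneCap:
    def test_shortfall_plus_cap_penalty_monotone_in_cap(self):
        # on exact optima, tightening the cap never reduces the pressure term
        prob = _small_instance(6, n=9)
        prev = None
        for frac in (0.6, 0.4, 0.25, 0.15, 0.08):
            cfg = prob.config.replace(area_cap_fraction=frac)
            p = build_problem(prob.bundle, prob.targets, cfg)
            sol = exhaustive_optimum(p)
            pressure = sol.shortfall_penalty + sol.cap_penalty
            if prev is not None:
                assert pressure >= prev - 1e-9
            prev = pressure


class TestExhaustiveGuard:
    def test_refuses_large_instances(self):
        cfg = WorldConfig(n_catchments=30, n_outlets=3, n_ecoregions=3,
                          n_species={"fish": 4, "mollusc": 4, "odonate": 2,
                                     "plant": 2},
                          range_contiguity=0.5, seed=1)
        bundle, _ = generate_world(cfg)
        targets = fp.build_target_table(bundle)
        prob = build_problem(bundle, targets, ScenarioConfig.preset(1))
        with pytest.raises(ValueError, match="enumeration"):
            exhaustive_optimum(prob, max_free=20)
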