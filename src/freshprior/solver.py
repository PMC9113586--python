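"""Simulated-annealing minimum-set reserve selection.

The solver selects a set of catchments minimizing

    objective = cost + shortfall_penalty + structure_penalty + cap_penalty

where

* ``cost`` is the summed area (km²) of selected catchments (area is the cost
  proxy for protection);
* ``shortfall_penalty`` is Σ_species spf_s · max(0, target_s − captured_s) /
  target_s — the species penalty factor (SPF) times the relative shortfall,
  with SPF scaled to catchment-area units so penalties and costs are
  commensurable;
* ``structure_penalty`` is BLM × total exposed boundary (adjacency pairs with
  exactly one member selected) in ``boundary`` mode, or CP × total weight of
  broken river connections in ``river`` mode.  A river connection (u → d) is
  broken when the downstream catchment d is selected but its immediate
  upstream neighbour u is not: upstream catchments influence downstream ones
  far more than vice versa, so protecting a catchment without its upstream
  condition is what gets penalized.  ``symmetric=True`` switches to counting
  any split connection, for sensitivity analysis;
* ``cap_penalty`` is cap_weight × km² by which the selected area exceeds the
  area cap (17% of the planning region by default) — a soft constraint, so
  locked-in area may legally exceed the cap.

Annealing uses geometric cooling over two temperature decades with the
initial temperature set adaptively from the spread of objective deltas over
random probe moves, followed by greedy single-catchment improvement to a
local optimum (the classic "iterative improvement" finishing step).
Locked-in catchments are never removed, locked-out never added.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, replace as dc_replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .scenarios import Problem
from .types import THREATENED_STATUSES

CAP_WEIGHT_DEFAULT = 1000.0  # penalty per km² over the cap; dwarfs any area saving


@dataclass(frozen=True)
class Solution:
    """One candidate reserve network with its objective breakdown."""

    selected: Tuple[str, ...]
    cost: float
    shortfall_penalty: float
    structure_penalty: float
    cap_penalty: float
    objective: float
    feasible_targets: int

    def sort_key(self) -> tuple:
        """Deterministic 'best' ordering: objective, then cost, then ids."""
        return (self.objective, self.cost, self.selected)


@dataclass
class PrioritizationResult:
    """Portfolio output: best network, selection frequencies, coverage."""

    best: Solution
    selection_frequency: pd.Series
    coverage: pd.DataFrame
    objective_log: pd.DataFrame
    n_runs: int


class CompiledProblem:
    """Array/list form of a Problem for the annealing inner loop."""

    def __init__(self, problem: Problem, cap_weight: float = CAP_WEIGHT_DEFAULT,
                 symmetric_river: bool = False):
        self.problem = problem
        bundle = problem.bundle
        cfg = problem.config

        self.ids: List[str] = sorted(bundle.catchments.index.astype(str))
        self.idx = {cid: i for i, cid in enumerate(self.ids)}
        n = len(self.ids)
        self.n = n
        cat = bundle.catchments.loc[self.ids]
        self.area: List[float] = [float(a) for a in cat["area_km2"]]

        locks = problem.lock_status
        self.locked_in = [locks.get(cid) == "locked_in" for cid in self.ids]
        self.locked_out = [locks.get(cid) == "locked_out" for cid in self.ids]
        self.free: List[int] = [
            i for i in range(n) if not (self.locked_in[i] or self.locked_out[i])
        ]

        tgt = problem.targets.sort_index()
        self.species_ids: List[str] = [str(s) for s in tgt.index]
        self.sidx = {sid: k for k, sid in enumerate(self.species_ids)}
        self.target: List[int] = [int(t) for t in tgt["target"]]
        self.spf: List[float] = [float(f) for f in tgt["penalty_factor"]]
        self.n_occ: List[int] = [int(c) for c in tgt["n_occurrences"]]

        self.species_in: List[List[int]] = [[] for _ in range(n)]
        self.catchments_of: List[List[int]] = [[] for _ in range(len(self.species_ids))]
        for sid, cid in bundle.occurrences[["species_id", "catchment_id"]].itertuples(
            index=False
        ):
            j, k = self.idx[str(cid)], self.sidx[str(sid)]
            self.species_in[j].append(k)
            self.catchments_of[k].append(j)

        self.mode = cfg.connectivity_mode
        self.struct_weight = cfg.blm if self.mode == "boundary" else cfg.cp
        self.symmetric_river = symmetric_river
        # boundary mode: per-catchment (neighbour, weighted boundary) incidences
        self.neighbours: List[List[Tuple[int, float]]] = [[] for _ in range(n)]
        if self.mode == "boundary":
            for a, b, w in problem.adjacency[["id1", "id2", "weight"]].itertuples(
                index=False
            ):
                i, j, wf = self.idx[str(a)], self.idx[str(b)], float(w) * self.struct_weight
                self.neighbours[i].append((j, wf))
                self.neighbours[j].append((i, wf))
        # river mode: incidences of directed connections (upstream -> downstream)
        self.ups: List[List[Tuple[int, float]]] = [[] for _ in range(n)]
        self.downs: List[List[Tuple[int, float]]] = [[] for _ in range(n)]
        if self.mode == "river":
            for u, d, w in problem.connectivity[
                ["upstream_id", "downstream_id", "weight"]
            ].itertuples(index=False):
                ui, di, wf = self.idx[str(u)], self.idx[str(d)], float(w) * self.struct_weight
                self.ups[di].append((ui, wf))
                self.downs[ui].append((di, wf))

        self.cap = float(problem.area_cap_km2)
        self.cap_weight = float(cap_weight)

    def locked_mask(self) -> List[bool]:
        return list(self.locked_in)

    def solution_from_mask(self, sel: Sequence[bool]) -> Solution:
        """From-scratch objective breakdown for a selection mask."""
        cost = sum(a for a, s in zip(self.area, sel) if s)
        captured = [0] * len(self.target)
        for j, s in enumerate(sel):
            if s:
                for k in self.species_in[j]:
                    captured[k] += 1
        short = 0.0
        met = 0
        for k, t in enumerate(self.target):
            if captured[k] >= t:
                met += 1
            elif t > 0:
                short += self.spf[k] * (t - captured[k]) / t
        struct = 0.0
        if self.mode == "boundary":
            for j in range(self.n):
                for k, w in self.neighbours[j]:
                    if j < k and sel[j] != sel[k]:
                        struct += w
        else:
            for d in range(self.n):
                if sel[d]:
                    for u, w in self.ups[d]:
                        if not sel[u]:
                            struct += w
            if self.symmetric_river:
                for u in range(self.n):
                    if sel[u]:
                        for d, w in self.downs[u]:
                            if not sel[d]:
                                struct += w
        cap_pen = self.cap_weight * max(0.0, cost - self.cap)
        return Solution(
            selected=tuple(self.ids[j] for j in range(self.n) if sel[j]),
            cost=cost,
            shortfall_penalty=short,
            structure_penalty=struct,
            cap_penalty=cap_pen,
            objective=cost + short + struct + cap_pen,
            feasible_targets=met,
        )


class AnnealState:
    """Incrementally maintained objective over single-catchment toggles.

    ``toggle(j)`` flips catchment ``j`` and returns the objective delta; a
    second ``toggle(j)`` reverts it exactly, so propose/reject is two calls.
    ``components()`` returns the incrementally maintained breakdown;
    ``audit()`` recomputes it from scratch for integrity checks.
    """

    def __init__(self, compiled: CompiledProblem):
        self.c = compiled
        self.reset(compiled.locked_mask())

    def reset(self, sel: Sequence[bool]) -> None:
        c = self.c
        self.sel = list(sel)
        self.cost = sum(a for a, s in zip(c.area, self.sel) if s)
        self.captured = [0] * len(c.target)
        for j, s in enumerate(self.sel):
            if s:
                for k in c.species_in[j]:
                    self.captured[k] += 1
        self.pen = [0.0] * len(c.target)
        short = 0.0
        for k, t in enumerate(c.target):
            missing = t - self.captured[k]
            if t > 0 and missing > 0:
                p = c.spf[k] * missing / t
                self.pen[k] = p
                short += p
        self.short = short
        self.struct = c.solution_from_mask(self.sel).structure_penalty

    def objective(self) -> float:
        over = self.cost - self.c.cap
        cap_pen = self.c.cap_weight * over if over > 0.0 else 0.0
        return self.cost + self.short + self.struct + cap_pen

    def toggle(self, j: int) -> float:
        c = self.c
        sel = self.sel
        before = self.objective()
        s = sel[j]
        new = not s
        self.cost += c.area[j] if new else -c.area[j]
        step = 1 if new else -1
        captured, pen, target, spf = self.captured, self.pen, c.target, c.spf
        dshort = 0.0
        for k in c.species_in[j]:
            cap_k = captured[k] + step
            captured[k] = cap_k
            t = target[k]
            missing = t - cap_k
            newpen = spf[k] * missing / t if (t > 0 and missing > 0) else 0.0
            dshort += newpen - pen[k]
            pen[k] = newpen
        self.short += dshort
        dstruct = 0.0
        if c.mode == "boundary":
            for k, w in c.neighbours[j]:
                dstruct += -w if sel[k] == new else w
        else:
            for u, w in c.ups[j]:
                if not sel[u]:
                    dstruct += w if new else -w
            for d, w in c.downs[j]:
                if sel[d]:
                    dstruct += -w if new else w
            if c.symmetric_river:
                for d, w in c.downs[j]:
                    if not sel[d]:
                        dstruct += w if new else -w
                for u, w in c.ups[j]:
                    if sel[u]:
                        dstruct += -w if new else w
        self.struct += dstruct
        sel[j] = new
        return self.objective() - before

    def audit(self) -> Solution:
        return self.c.solution_from_mask(self.sel)


def _probe_count(n: int) -> int:
    # adaptive-T0 probe walk; capped so tiny instances don't overspend
    return min(1000, 100 + 10 * n)


def default_iterations(n: int) -> int:
    """Annealing move budget: 10 000 moves per 100 catchments (min 2000)."""
    return max(2000, 100 * n)


def anneal(
    problem: Problem,
    seed: int,
    n_iterations: Optional[int] = None,
    compiled: Optional[CompiledProblem] = None,
    init_prob: Optional[float] = None,
    swap_prob: float = 0.3,
    directed_prob: float = 0.25,
    improve_cycles: int = 5,
) -> Solution:
    """One annealing run; deterministic for a fixed seed.

    Locked statuses are never violated: proposals only toggle free
    catchments, and the initial state contains the locked-in set plus a
    random subset of the free catchments sized so the starting cost sits
    near the area cap.  Proposals mix three move kinds: single toggles,
    paired remove/add swaps (probability ``swap_prob``) that let the search
    exchange catchments without crossing the cap penalty in between, and
    coverage-directed swaps (probability ``directed_prob``) that add a
    catchment holding an occurrence of a currently-unmet species while
    dropping a random selected one — the standard unmet-feature heuristic
    for minimum-set search.  The initial temperature is a
    robust (median-absolute-deviation) scale of the objective deltas over a
    random probe walk, so occasional huge cap-penalty deltas do not overheat
    the geometric two-decade schedule.

    The best state visited during annealing is then finished by iterative
    improvement: up to ``improve_cycles`` rounds of exhaustive greedy
    single-toggle passes interleaved with ``n_iterations`` improving-only
    random toggle/swap moves, stopping early when a round no longer
    improves.  Returns the final (local-optimal) state.
    """
    c = compiled if compiled is not None else CompiledProblem(problem)
    rng = random.Random(seed)
    n_iter = n_iterations if n_iterations is not None else default_iterations(c.n)

    if init_prob is None:
        free_area = sum(c.area[j] for j in c.free)
        locked_area = sum(a for a, m in zip(c.area, c.locked_in) if m)
        spare = max(0.0, c.cap - locked_area)
        init_prob = min(1.0, spare / free_area) if free_area > 0 else 0.0
    init = c.locked_mask()
    for j in c.free:
        if rng.random() < init_prob:
            init[j] = True
    state = AnnealState(c)
    state.reset(init)

    free = c.free
    nf = len(free)
    if not nf:
        return state.audit()

    sel = state.sel
    exp = math.exp
    rnd = rng.random
    rrange = rng.randrange
    do_swaps = nf >= 2
    freeset = set(free)
    m = len(c.target)

    def propose():
        # returns (toggled indices, delta); caller reverts on rejection
        u = rnd()
        if m and u < directed_prob:
            k = rrange(m)
            if state.pen[k] > 0.0:
                cands = c.catchments_of[k]
                j1 = cands[rrange(len(cands))]
                if not sel[j1] and j1 in freeset:
                    sel_free = [j for j in free if sel[j]]
                    if sel_free:
                        j2 = sel_free[rrange(len(sel_free))]
                        return (j1, j2), state.toggle(j1) + state.toggle(j2)
                    return (j1,), state.toggle(j1)
            j1 = free[rrange(nf)]
            return (j1,), state.toggle(j1)
        if do_swaps and u < directed_prob + swap_prob:
            j1 = free[rrange(nf)]
            j2 = free[rrange(nf)]
            if j1 != j2 and sel[j1] != sel[j2]:
                return (j1, j2), state.toggle(j1) + state.toggle(j2)
            return (j1,), state.toggle(j1)
        j1 = free[rrange(nf)]
        return (j1,), state.toggle(j1)

    # probe walk to scale the initial temperature
    deltas = [state.toggle(free[rrange(nf)]) for _ in range(_probe_count(c.n))]
    med = float(np.median(deltas))
    scale = 1.4826 * float(np.median(np.abs(np.asarray(deltas) - med)))
    t0 = max(scale, 1e-10)
    factor = 0.01 ** (1.0 / max(1, n_iter))  # two temperature decades
    state.reset(init)
    sel = state.sel

    cur = state.objective()
    best_obj = cur
    best_mask = list(sel)
    temp = t0
    for _ in range(n_iter):
        js, d = propose()
        if d <= 0.0 or rnd() < exp(-d / temp):
            cur += d
            if cur < best_obj - 1e-12:
                best_obj = cur
                best_mask = list(sel)
        else:
            for j in js:
                state.toggle(j)
        temp *= factor

    # iterative improvement from the best visited state
    state.reset(best_mask)
    sel = state.sel

    def greedy_pass():
        improved = True
        while improved:
            improved = False
            for j in free:
                d = state.toggle(j)
                if d < -1e-12:
                    improved = True
                else:
                    state.toggle(j)

    prev = state.objective()
    for _ in range(max(1, improve_cycles)):
        greedy_pass()
        for _ in range(n_iter):
            js, d = propose()
            if d >= -1e-12:
                for j in js:
                    state.toggle(j)
        now = state.objective()
        if now >= prev - 1e-9:
            break
        prev = now
    greedy_pass()

    return state.audit()


def objective(problem: Problem, selected: Iterable[str],
              compiled: Optional[CompiledProblem] = None) -> Solution:
    """From-scratch objective breakdown for an explicit catchment set.

    Raises ``ValueError`` if the set violates the problem's lock statuses.
    """
    c = compiled if compiled is not None else CompiledProblem(problem)
    chosen = set(str(s) for s in selected)
    unknown = chosen - set(c.ids)
    if unknown:
        raise KeyError(f"unknown catchment id(s): {sorted(unknown)}")
    sel = [cid in chosen for cid in c.ids]
    for j in range(c.n):
        if c.locked_in[j] and not sel[j]:
            raise ValueError(f"locked-in catchment {c.ids[j]} not selected")
        if c.locked_out[j] and sel[j]:
            raise ValueError(f"locked-out catchment {c.ids[j]} selected")
    return c.solution_from_mask(sel)


def run_portfolio(
    problem: Problem,
    n_runs: Optional[int] = None,
    base_seed: Optional[int] = None,
    n_iterations: Optional[int] = None,
    cap_weight: float = CAP_WEIGHT_DEFAULT,
) -> PrioritizationResult:
    """Repeat annealing ``n_runs`` times (seeds base_seed + i).

    The best network is the run with the lowest objective (ties: lowest cost,
    then lexicographically smallest selected-id set).  Selection frequency
    counts how often each catchment appears across the per-run solutions — the
    irreplaceability proxy.
    """
    cfg = problem.config
    n_runs = n_runs if n_runs is not None else cfg.n_runs
    base_seed = base_seed if base_seed is not None else cfg.base_seed
    c = CompiledProblem(problem, cap_weight=cap_weight)

    counts = dict.fromkeys(c.ids, 0)
    best: Optional[Solution] = None
    log_rows = []
    for i in range(n_runs):
        sol = anneal(problem, seed=base_seed + i, n_iterations=n_iterations,
                     compiled=c)
        for cid in sol.selected:
            counts[cid] += 1
        if best is None or sol.sort_key() < best.sort_key():
            best = sol
        log_rows.append(
            {
                "run": i,
                "seed": base_seed + i,
                "objective": sol.objective,
                "cost": sol.cost,
                "shortfall_penalty": sol.shortfall_penalty,
                "structure_penalty": sol.structure_penalty,
                "cap_penalty": sol.cap_penalty,
                "feasible_targets": sol.feasible_targets,
                "n_selected": len(sol.selected),
            }
        )
    freq = pd.Series(counts, name="selection_frequency").sort_index()
    coverage = coverage_report(best, problem, compiled=c)
    return PrioritizationResult(
        best=best,
        selection_frequency=freq,
        coverage=coverage,
        objective_log=pd.DataFrame(log_rows),
        n_runs=n_runs,
    )


def coverage_report(
    solution: Solution, problem: Problem,
    compiled: Optional[CompiledProblem] = None,
) -> pd.DataFrame:
    """Per-species representation achieved by a solution.

    Columns: ``captured`` (occurrences inside the network), ``target``,
    ``met`` (captured ≥ target; a zero target is vacuously met),
    ``proportion`` (captured / occurrences — the proportion of the species'
    range covered, occurrence-count based), ``proportion_area`` (the
    area-weighted alternative) and ``redlist_status``.
    """
    c = compiled if compiled is not None else CompiledProblem(problem)
    chosen = set(solution.selected)
    sel = [cid in chosen for cid in c.ids]
    captured = [0] * len(c.species_ids)
    captured_area = [0.0] * len(c.species_ids)
    range_area = [0.0] * len(c.species_ids)
    for j in range(c.n):
        for k in c.species_in[j]:
            range_area[k] += c.area[j]
            if sel[j]:
                captured[k] += 1
                captured_area[k] += c.area[j]
    status = problem.bundle.species["redlist_status"]
    rows = []
    for k, sid in enumerate(c.species_ids):
        n_occ = c.n_occ[k]
        rows.append(
            {
                "species_id": sid,
                "captured": captured[k],
                "target": c.target[k],
                "met": captured[k] >= c.target[k],
                "proportion": captured[k] / n_occ if n_occ else float("nan"),
                "proportion_area": captured_area[k] / range_area[k]
                if range_area[k]
                else float("nan"),
                "redlist_status": status.get(sid, "DD"),
            }
        )
    return pd.DataFrame(rows).set_index("species_id")


def coverage_by_status(coverage: pd.DataFrame) -> pd.DataFrame:
    """Met/unmet species counts per Red List category, plus a Total row."""
    order = ["CR", "EN", "VU", "NT", "LC", "DD"]
    tab = (
        coverage.groupby("redlist_status")["met"]
        .agg(met="sum", total="count")
        .reindex(order, fill_value=0)
    )
    tab["met"] = tab["met"].astype(int)
    tab["unmet"] = tab["total"] - tab["met"]
    tab = tab[["met", "unmet"]]
    tab.loc["Total"] = tab.sum()
    return tab


def threatened_targets_met(coverage: pd.DataFrame) -> int:
    """Number of threatened (CR+EN+VU) species whose targets are met."""
    thr = coverage["redlist_status"].isin(THREATENED_STATUSES)
    return int(coverage.loc[thr, "met"].sum())


def sweep_parameter(
    problem: Problem,
    parameter: str,
    values: Sequence[float],
    n_runs: int = 10,
    base_seed: int = 0,
    n_iterations: Optional[int] = None,
) -> pd.DataFrame:
    """Cost-vs-structure trade-off table over BLM or CP values.

    Runs a reduced-replicate portfolio at each value and reports the mean
    cost, mean structure penalty (weighted), mean raw structure measure
    (exposed boundary or broken river connections at unit weight, comparable
    across penalty values) and mean number of targets met over the per-run
    solutions — the table behind the calibration plots used to choose the
    default penalty weights.
    """
    if parameter not in ("blm", "cp"):
        raise ValueError("parameter must be 'blm' or 'cp'")
    if not len(values):
        raise ValueError("values must be nonempty")
    unit_cfg = problem.config.replace(**{parameter: 1.0})
    unit_c = CompiledProblem(dc_replace(problem, config=unit_cfg))
    rows = []
    for v in values:
        cfg = problem.config.replace(**{parameter: float(v)})
        prob_v = dc_replace(problem, config=cfg)
        c = CompiledProblem(prob_v)
        sols = [
            anneal(prob_v, seed=base_seed + i, n_iterations=n_iterations, compiled=c)
            for i in range(n_runs)
        ]
        raw = [
            unit_c.solution_from_mask([cid in set(s.selected) for cid in unit_c.ids])
            .structure_penalty
            for s in sols
        ]
        rows.append(
            {
                parameter: float(v),
                "mean_cost": float(np.mean([s.cost for s in sols])),
                "mean_structure_penalty": float(
                    np.mean([s.structure_penalty for s in sols])
                ),
                "mean_structure_raw": float(np.mean(raw)),
                "mean_targets_met": float(
                    np.mean([s.feasible_targets for s in sols])
                ),
            }
        )
    return pd.DataFrame(rows)


def exhaustive_optimum(
    problem: Problem, cap_weight: float = CAP_WEIGHT_DEFAULT, max_free: int = 20
) -> Solution:
    """Exact optimum by vectorized enumeration over all 2^n_free subsets.

    Only feasible for desk-sized instances (``max_free`` free catchments);
    used as the independent oracle for the annealer.
    """
    c = CompiledProblem(problem, cap_weight=cap_weight)
    free = c.free
    nf = len(free)
    if nf > max_free:
        raise ValueError(f"{nf} free catchments exceed enumeration limit {max_free}")

    n_states = 1 << nf
    bits = (np.arange(n_states)[:, None] >> np.arange(nf)[None, :]) & 1
    sel = np.zeros((n_states, c.n), dtype=bool)
    sel[:, np.array(c.locked_in, dtype=bool)] = True
    if nf:
        sel[:, np.array(free)] = bits.astype(bool)

    area = np.array(c.area)
    cost = sel @ area

    m = len(c.target)
    occ = np.zeros((c.n, m))
    for j in range(c.n):
        for k in c.species_in[j]:
            occ[j, k] = 1.0
    captured = sel @ occ
    tgt = np.array(c.target, dtype=float)
    spf = np.array(c.spf)
    t_safe = np.where(tgt > 0, tgt, 1.0)
    short = (np.maximum(0.0, tgt - captured) / t_safe * spf).sum(axis=1)

    struct = np.zeros(n_states)
    if c.mode == "boundary":
        for j in range(c.n):
            for k, w in c.neighbours[j]:
                if j < k:
                    struct += w * (sel[:, j] != sel[:, k])
    else:
        for d in range(c.n):
            for u, w in c.ups[d]:
                struct += w * (sel[:, d] & ~sel[:, u])
                if c.symmetric_river:
                    struct += w * (sel[:, u] & ~sel[:, d])
    cap_pen = c.cap_weight * np.maximum(0.0, cost - c.cap)
    obj = cost + short + struct + cap_pen

    near = np.flatnonzero(obj <= obj.min() + 1e-9)
    best_row = min(
        near,
        key=lambda r: (
            obj[r],
            cost[r],
            tuple(c.ids[j] for j in range(c.n) if sel[r, j]),
        ),
    )
    return c.solution_from_mask([bool(x) for x in sel[best_row]])
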