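"""Automated sulcus recognition by energy minimization.

Labels are assigned to an unlabeled sulcal graph by Metropolis simulated
annealing over single-node relabel moves (any central-region label or
background), under the constraint that a non-background label is carried by
at most one node.  Reliability follows the best-of-k rule: k independent
annealings are run and the one with the lowest central-sulcus energy (group
analyses) or lowest central-region energy (individual analyses) is kept.

A brute-force exhaustive minimizer over tiny graphs serves as the test
oracle for the annealer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .energy import (
    ControlModel,
    EnergyMap,
    edge_potential,
    local_energy_decomposition,
    node_potential,
    relation_key,
    total_energy,
)
from .graph import SulcalGraph
from .nomenclature import BACKGROUND, CENTRAL_REGION_LABELS


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule for the Metropolis sampler."""

    t0: float = 5.0
    gamma: float = 0.95
    sweeps: int = 20     # full-graph sweeps per temperature level
    t_min: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not (self.t0 > self.t_min > 0):
            raise ValueError("need t0 > t_min > 0")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must be in (0, 1)")


class _EnergyWorkspace:
    """Cached potentials and incremental (delta) energy evaluation."""

    def __init__(self, graph: SulcalGraph, model: ControlModel):
        self.graph = graph
        self.model = model
        self.nodes = list(graph.nodes)
        self.n = len(self.nodes)
        self.cand = list(model.labels) + [BACKGROUND]
        self.bg = len(self.cand) - 1
        hemi = graph.hemisphere
        # node potential matrix, node x candidate label
        self.P = np.array(
            [
                [node_potential(nd, lab, model, hemi) for lab in self.cand]
                for nd in self.nodes
            ]
        )
        idx = {nd.node_id: i for i, nd in enumerate(self.nodes)}
        self.incident: list[list[int]] = [[] for _ in range(self.n)]
        self.edge_nodes: list[tuple[int, int]] = []
        for k, e in enumerate(graph.edges):
            a, b = idx[e.endpoints[0]], idx[e.endpoints[1]]
            self.edge_nodes.append((a, b))
            self.incident[a].append(k)
            self.incident[b].append(k)
        # realized relation types per unordered node pair
        self.types_between: dict[tuple[int, int], set[str]] = {}
        for k, e in enumerate(graph.edges):
            a, b = self.edge_nodes[k]
            pair = (a, b) if a < b else (b, a)
            self.types_between.setdefault(pair, set()).add(e.relation_type)
        self._edge_pot_cache: dict[tuple[int, int, int], float] = {}
        # model relation keys indexed by endpoint label
        self.rel_by_label: dict[int, list[tuple]] = {c: [] for c in range(len(self.cand))}
        self.label_index = {lab: c for c, lab in enumerate(self.cand)}
        for key in model.expected_relations():
            lo, hi, t = key
            item = (self.label_index[lo], self.label_index[hi], t)
            self.rel_by_label[item[0]].append(item)
            if item[1] != item[0]:
                self.rel_by_label[item[1]].append(item)

    def edge_pot(self, edge_idx: int, ca: int, cb: int) -> float:
        key = (edge_idx, ca, cb) if ca <= cb else (edge_idx, cb, ca)
        pot = self._edge_pot_cache.get(key)
        if pot is None:
            e = self.graph.edges[edge_idx]
            pot = edge_potential(
                e, self.cand[key[1]], self.cand[key[2]], self.model, self.graph.hemisphere
            )
            self._edge_pot_cache[key] = pot
        return pot

    def restricted_energy(self, v: int, state: np.ndarray, holder: np.ndarray,
                          involved: tuple[int, ...]) -> float:
        """Energy terms that can change when node ``v`` is relabeled.

        ``state[i]`` is the candidate index of node i; ``holder[c]`` the node
        carrying candidate c (or -1).  ``involved`` are the non-background
        candidate labels whose missing-relation terms must be re-examined.
        """
        acc = self.P[v, state[v]]
        for k in self.incident[v]:
            a, b = self.edge_nodes[k]
            acc += self.edge_pot(k, state[a], state[b])
        lam = self.model.lambda_missing
        seen = set()
        for c in involved:
            for item in self.rel_by_label[c]:
                if item in seen:
                    continue
                seen.add(item)
                clo, chi, t = item
                na, nb = holder[clo], holder[chi]
                if na < 0 and nb < 0:
                    continue
                if na < 0 or nb < 0:
                    acc += lam  # one endpoint unassigned: relation unrealisable
                    continue
                pair = (na, nb) if na < nb else (nb, na)
                if t not in self.types_between.get(pair, ()):
                    acc += lam
        return float(acc)

    def labeling_from_state(self, state: np.ndarray) -> dict[str, str]:
        return {nd.node_id: self.cand[state[i]] for i, nd in enumerate(self.nodes)}


def anneal_labeling(
    graph: SulcalGraph,
    model: ControlModel,
    schedule: Optional[AnnealSchedule] = None,
) -> tuple[dict[str, str], float]:
    """Metropolis annealing over single-node relabel moves.

    Starts from the all-background labeling, proposes (node, label) moves,
    rejects moves that would duplicate a non-background label, and returns
    the best labeling visited together with its exact total energy.
    Deterministic given the schedule seed.
    """
    schedule = schedule or AnnealSchedule()
    if not graph.nodes:
        return {}, 0.0
    ws = _EnergyWorkspace(graph, model)
    rng = np.random.default_rng(schedule.seed)
    n, bg = ws.n, ws.bg
    n_cand = len(ws.cand)

    state = np.full(n, bg, dtype=int)
    holder = np.full(n_cand, -1, dtype=int)  # holder[bg] unused
    current = total_energy(graph, ws.labeling_from_state(state), model)
    best_e = current
    best_state = state.copy()

    t = schedule.t0
    while t >= schedule.t_min:
        n_props = schedule.sweeps * n
        vs = rng.integers(n, size=n_props)
        cs = rng.integers(n_cand, size=n_props)
        us = rng.random(n_props)
        for v, c_new, u in zip(vs, cs, us):
            c_old = state[v]
            if c_new == c_old:
                continue
            if c_new != bg and holder[c_new] >= 0:
                continue  # label uniqueness: move rejected
            involved = tuple(c for c in (c_old, c_new) if c != bg)
            before = ws.restricted_energy(v, state, holder, involved)
            state[v] = c_new
            if c_old != bg:
                holder[c_old] = -1
            if c_new != bg:
                holder[c_new] = v
            after = ws.restricted_energy(v, state, holder, involved)
            delta = after - before
            if delta <= 0.0 or u < math.exp(-delta / t):
                current += delta
                if current < best_e - 1e-12:
                    best_e = current
                    best_state = state.copy()
            else:  # revert
                state[v] = c_old
                if c_new != bg:
                    holder[c_new] = -1
                if c_old != bg:
                    holder[c_old] = v
        t *= schedule.gamma

    labeling = ws.labeling_from_state(best_state)
    return labeling, total_energy(graph, labeling, model)


def brute_force_labeling(
    graph: SulcalGraph, model: ControlModel, max_nodes: int = 6
) -> tuple[dict[str, str], float]:
    """Exhaustive minimum-energy labeling (test oracle, tiny graphs only)."""
    if len(graph.nodes) > max_nodes:
        raise ValueError(f"brute force limited to {max_nodes} nodes, got {len(graph.nodes)}")
    if not graph.nodes:
        return {}, 0.0
    ws = _EnergyWorkspace(graph, model)
    n, bg = ws.n, ws.bg
    n_cand = len(ws.cand)
    # candidates sorted by node potential: tightens the branch-and-bound
    order = [np.argsort(ws.P[i]).tolist() for i in range(n)]
    lam = model.lambda_missing

    best = [math.inf, None]
    state = np.full(n, -1, dtype=int)
    holder = np.full(n_cand, -1, dtype=int)

    def leaf_missing() -> float:
        count = 0
        for key in model.expected_relations():
            lo, hi, t = key
            na = holder[ws.label_index[lo]]
            nb = holder[ws.label_index[hi]]
            if na < 0 and nb < 0:
                continue
            if na < 0 or nb < 0:
                count += 1  # unrealisable: one endpoint unassigned
                continue
            pair = (na, nb) if na < nb else (nb, na)
            if t not in ws.types_between.get(pair, ()):
                count += 1
        return lam * count

    def rec(i: int, acc: float) -> None:
        if acc >= best[0]:
            return  # all remaining terms are non-negative
        if i == n:
            tot = acc + leaf_missing()
            if tot < best[0]:
                best[0] = tot
                best[1] = state.copy()
            return
        for c in order[i]:
            if c != bg and holder[c] >= 0:
                continue
            acc2 = acc + ws.P[i, c]
            for k in ws.incident[i]:
                a, b = ws.edge_nodes[k]
                other = b if a == i else a
                if other < i or state[other] >= 0:
                    acc2 += ws.edge_pot(k, c, state[other])
            state[i] = c
            if c != bg:
                holder[c] = i
            rec(i + 1, acc2)
            state[i] = -1
            if c != bg:
                holder[c] = -1

    rec(0, 0.0)
    labeling = ws.labeling_from_state(best[1])
    return labeling, total_energy(graph, labeling, model)


SELECTION_SCOPES = ("central_sulcus", "central_region")


def run_k_recognitions(
    graph: SulcalGraph,
    model: ControlModel,
    k: int = 10,
    schedule: Optional[AnnealSchedule] = None,
    seed: int = 0,
) -> list[tuple[dict[str, str], EnergyMap]]:
    """k independent annealings with distinct derived seeds.

    The runs are shared between analyses: group and individual analyses
    select from the same k recognitions under different scopes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    base = schedule or AnnealSchedule()
    runs = []
    for r in range(k):
        run_seed = np.random.SeedSequence(entropy=seed, spawn_key=(r,)).generate_state(1)[0]
        run_seed = int(run_seed % (2**31))
        sched = AnnealSchedule(base.t0, base.gamma, base.sweeps, base.t_min, run_seed)
        labeling, _ = anneal_labeling(graph, model, sched)
        runs.append((labeling, local_energy_decomposition(graph, labeling, model)))
    return runs


def select_recognition(
    runs: Sequence[tuple[dict[str, str], EnergyMap]], scope: str
) -> tuple[dict[str, str], EnergyMap]:
    """Pick the run minimizing the scope energy.

    ``central_sulcus``: local energy of S.C. (group analyses);
    ``central_region``: summed central-region local energy (individual
    analyses).  Ties break by total energy, then run index.
    """
    if scope not in SELECTION_SCOPES:
        raise ValueError(f"scope must be one of {SELECTION_SCOPES}")
    scored = []
    for r, (labeling, emap) in enumerate(runs):
        if scope == "central_sulcus":
            score = emap.local.get("S.C.", math.inf)
        else:
            score = sum(emap.local.get(lab, 0.0) for lab in CENTRAL_REGION_LABELS)
        scored.append((score, emap.total, r))
    scored.sort()
    _, _, r_best = scored[0]
    return runs[r_best]


def best_of_k_recognitions(
    graph: SulcalGraph,
    model: ControlModel,
    k: int = 10,
    scope: str = "central_region",
    schedule: Optional[AnnealSchedule] = None,
    seed: int = 0,
) -> tuple[dict[str, str], EnergyMap]:
    """Run k annealings and keep the most reliable one under ``scope``."""
    runs = run_k_recognitions(graph, model, k=k, schedule=schedule, seed=seed)
    return select_recognition(runs, scope)


def labeling_accuracy(graph: SulcalGraph, labeling: dict[str, str]) -> float:
    """Fraction of true-labeled folds assigned their true label."""
    truth = [(n.node_id, n.true_label) for n in graph.nodes if n.true_label not in (None, BACKGROUND)]
    if not truth:
        return float("nan")
    hits = sum(1 for nid, lab in truth if labeling.get(nid) == lab)
    return hits / len(truth)
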