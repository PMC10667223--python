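"""Delineation of risk phenogroups on the Mapper network.

The network is first partitioned into "autogroups" by Louvain modularity
maximization (edge weight = number of shared patients).  Autogroups are then
sorted by the crude mortality of their member patients and greedily merged:
at each step the pair of *adjacent* groups (joined by at least one network
edge) with the most similar mortality rates is combined, subject to a size
balance cap, until exactly three phenogroups remain.  Finally each patient
receives a unique low / intermediate / high label from the groups of the
nodes containing them (majority; ties to the higher-mortality group), with
multi-membership recorded for patients whose nodes span several groups.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities

from .mapper import MapperGraph

logger = logging.getLogger(__name__)

PHENOGROUP_LABELS = ("low", "intermediate", "high")


@dataclass
class MergeStep:
    """One executed merge: the pair joined, their mortality gap, new size."""

    pair: tuple[int, int]
    mortality_difference: float
    resulting_size: int
    group_count_after: int


@dataclass
class PhenogroupPartition:
    """Final three-group partition of nodes and patients."""

    node_to_group: dict[int, str]            # node id -> low/intermediate/high
    patient_to_group: dict[int, str]         # unique patient label
    multi_membership: dict[int, list[str]]   # patients whose nodes span >1 group
    merge_trace: list[MergeStep]
    group_mortality: dict[str, float]
    group_sizes: dict[str, int]              # unique patients per group

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"patient_id": p, "phenogroup": g,
             "n_candidate_groups": len(self.multi_membership.get(p, [g]))}
            for p, g in sorted(self.patient_to_group.items())
        ]
        return pd.DataFrame(rows)

    def write_trace_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([
                {"pair": list(s.pair), "mortality_difference": s.mortality_difference,
                 "resulting_size": s.resulting_size,
                 "group_count_after": s.group_count_after}
                for s in self.merge_trace
            ], fh, indent=1)


def _weighted_node_graph(graph: MapperGraph) -> nx.Graph:
    G = nx.Graph()
    members = {node.id: node.members for node in graph.nodes}
    G.add_nodes_from(members)
    for u, v in graph.edges:
        G.add_edge(u, v, weight=len(members[u] & members[v]))
    return G


def louvain_autogroup(graph: MapperGraph, resolution_param: float = 1.0,
                      seed: int = 0, target_groups: int | None = None,
                      target_slack: int = 2) -> list[set[int]]:
    """Louvain communities of the node graph, optionally tuned to a count.

    Edge weights are shared-patient counts.  With ``target_groups`` set, the
    Louvain resolution parameter is tuned by bisection until the community
    count is within ``target_slack`` of the target (higher resolution gives
    more, smaller communities).  Deterministic given ``seed``.
    """
    G = _weighted_node_graph(graph)
    if G.number_of_nodes() < 2:
        warnings.warn("graph has < 2 nodes; returning a single-group partition")
        return [set(G.nodes)]

    def communities(res: float) -> list[set[int]]:
        return [set(c) for c in louvain_communities(G, weight="weight",
                                                    resolution=res, seed=seed)]

    if target_groups is None:
        return communities(resolution_param)

    lo, hi = 0.01, resolution_param
    parts = communities(hi)
    # Expand upward until the count brackets the target.
    while len(parts) < target_groups - target_slack and hi < 512:
        hi *= 2
        parts = communities(hi)
    if abs(len(parts) - target_groups) <= target_slack:
        return parts
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        parts = communities(mid)
        if abs(len(parts) - target_groups) <= target_slack:
            return parts
        if len(parts) < target_groups:
            lo = mid
        else:
            hi = mid
    warnings.warn(
        f"could not reach {target_groups} +/- {target_slack} communities; got {len(parts)}")
    return parts


def group_mortality(groups: list[set[int]], graph: MapperGraph,
                    events: np.ndarray) -> tuple[list[float], list[int]]:
    """Crude death proportion and unique patient count per node group.

    A patient in several nodes of one group counts once.
    """
    events = np.asarray(events, dtype=float)
    members = {node.id: node.members for node in graph.nodes}
    rates, counts = [], []
    for g, node_ids in enumerate(groups):
        patients: set[int] = set()
        for nid in node_ids:
            patients |= members[nid]
        if not patients:
            raise ValueError(f"group {g} has no member patients")
        idx = np.fromiter(patients, dtype=int)
        rates.append(float(events[idx].mean()))
        counts.append(int(idx.size))
    return rates, counts


def merge_to_three(groups: list[set[int]], graph: MapperGraph,
                   events: np.ndarray, balance_cap: float = 1.4,
                   cap_relax: float = 1.1) -> PhenogroupPartition:
    """Greedy mortality-similarity merging of adjacent groups down to three.

    At each step the adjacent pair with the smallest absolute mortality
    difference is merged (ties: smaller combined patient count, then lower
    group id).  A merge that would push a group above
    ``balance_cap * total/3`` patients is skipped; if no merge is
    permissible the cap is relaxed by ``cap_relax`` and the step retried.
    Stops at exactly three groups, then labels them low / intermediate /
    high by mortality.
    """
    events = np.asarray(events, dtype=float)
    members = {node.id: node.members for node in graph.nodes}
    node_group = {nid: g for g, node_ids in enumerate(groups) for nid in node_ids}
    current: dict[int, set[int]] = {g: set(node_ids) for g, node_ids in enumerate(groups)}

    def patients_of(g: int) -> set[int]:
        out: set[int] = set()
        for nid in current[g]:
            out |= members[nid]
        return out

    def mortality_of(pats: set[int]) -> float:
        idx = np.fromiter(pats, dtype=int)
        return float(events[idx].mean())

    pats = {g: patients_of(g) for g in current}
    mort = {g: mortality_of(p) for g, p in pats.items()}
    total = len(set().union(*pats.values()))
    trace: list[MergeStep] = []
    cap = balance_cap

    def adjacency() -> set[tuple[int, int]]:
        adj: set[tuple[int, int]] = set()
        for u, v in graph.edges:
            gu, gv = node_group[u], node_group[v]
            if gu != gv:
                adj.add((min(gu, gv), max(gu, gv)))
        return adj

    while len(current) > 3:
        adj = adjacency()
        candidates = sorted(
            adj,
            key=lambda p: (abs(mort[p[0]] - mort[p[1]]),
                           len(pats[p[0]] | pats[p[1]]), p[0], p[1]),
        )
        chosen = None
        for a, b in candidates:
            if len(pats[a] | pats[b]) <= cap * total / 3:
                chosen = (a, b)
                break
        if chosen is None:
            if not candidates:
                raise ValueError(
                    "group adjacency is disconnected; cannot reduce to 3 groups "
                    f"(trace so far: {[s.pair for s in trace]})")
            cap *= cap_relax
            logger.info("no permissible merge; balance cap relaxed to %.3f", cap)
            continue
        a, b = chosen
        diff = abs(mort[a] - mort[b])
        current[a] |= current.pop(b)
        for nid in current[a]:
            node_group[nid] = a
        pats[a] = pats[a] | pats.pop(b)
        mort[a] = mortality_of(pats[a])
        mort.pop(b, None)
        trace.append(MergeStep(pair=(a, b), mortality_difference=diff,
                               resulting_size=len(pats[a]),
                               group_count_after=len(current)))

    if len(current) < 3:
        raise ValueError(f"need >= 3 initial groups, got {len(current)}")

    # Label final groups by mortality: low <= intermediate <= high.
    order = sorted(current, key=lambda g: mort[g])
    label_of = {g: PHENOGROUP_LABELS[i] for i, g in enumerate(order)}
    node_to_group = {nid: label_of[g] for nid, g in node_group.items()}

    patient_to_group, multi = assign_patients(node_to_group, graph,
                                              {label_of[g]: mort[g] for g in current})
    return PhenogroupPartition(
        node_to_group=node_to_group,
        patient_to_group=patient_to_group,
        multi_membership=multi,
        merge_trace=trace,
        group_mortality={label_of[g]: mort[g] for g in current},
        group_sizes={label_of[g]: len(pats[g]) for g in current},
    )


def assign_patients(node_to_group: dict[int, str], graph: MapperGraph,
                    mortality_by_label: dict[str, float]
                    ) -> tuple[dict[int, str], dict[int, list[str]]]:
    """Unique patient labels from node memberships.

    A patient's candidate groups are the groups of the nodes containing
    them; the unique label is the majority group by node count, ties going
    to the higher-mortality group.  Patients spanning more than one group
    are listed in the multi-membership record.
    """
    candidates: dict[int, list[str]] = {}
    for node in graph.nodes:
        g = node_to_group[node.id]
        for p in node.members:
            candidates.setdefault(p, []).append(g)
    patient_to_group: dict[int, str] = {}
    multi: dict[int, list[str]] = {}
    for p, cand in candidates.items():
        uniq = sorted(set(cand))
        if len(uniq) > 1:
            multi[p] = sorted(uniq, key=lambda g: mortality_by_label[g])
        counts = {g: cand.count(g) for g in uniq}
        best = max(counts.values())
        tied = [g for g, c in counts.items() if c == best]
        patient_to_group[p] = max(tied, key=lambda g: mortality_by_label[g])
    return patient_to_group, multi


def phenogroup_pipeline(graph: MapperGraph, events: np.ndarray,
                        target_groups: int | None = 14, seed: int = 0,
                        balance_cap: float = 1.4) -> PhenogroupPartition:
    """Autogroup + merge + assign in one call (the published procedure)."""
    groups = louvain_autogroup(graph, seed=seed, target_groups=target_groups)
    if len(groups) < 3:
        raise ValueError(f"Louvain produced {len(groups)} group(s); need >= 3 to merge")
    return merge_to_three(groups, graph, events, balance_cap=balance_cap)
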