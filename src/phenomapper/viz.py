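"""Static plots: KM curves, subgroup forest, and the network layout."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .mapper import MapperGraph
from .survival import km_estimate

GROUP_COLORS = {"low": "#2a9d8f", "intermediate": "#e9c46a", "high": "#e76f51"}


def km_plot(time, event, group, path, title="Survival by phenogroup"):
    """Stepwise KM curves with log-log 95% CI bands, one per group."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for g in pd.unique(group):
        sel = np.asarray(group) == g
        curve = km_estimate(np.asarray(time)[sel], np.asarray(event)[sel])
        t = np.concatenate([[0], np.repeat(curve.times, 2)])
        s = np.concatenate([[1, 1], np.repeat(curve.survival, 2)[:-1]])
        color = GROUP_COLORS.get(str(g))
        ax.plot(t, s, label=f"{g} (n={sel.sum()})", color=color)
        ax.fill_between(curve.times, curve.ci_lower, curve.ci_upper,
                        step="post", alpha=0.15, color=color)
    ax.set_xlabel("years since upgrade")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def forest_plot(table: pd.DataFrame, path, title="Device effect by subgroup"):
    """Horizontal forest plot from a subgroup_forest table."""
    tbl = table.dropna(subset=["hr"]).reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(tbl) + 1.5))
    y = np.arange(len(tbl))[::-1]
    ax.errorbar(tbl["hr"], y,
                xerr=[tbl["hr"] - tbl["ci_lower"], tbl["ci_upper"] - tbl["hr"]],
                fmt="s", color="k", ecolor="gray", capsize=2, markersize=4)
    ax.axvline(1.0, color="crimson", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(tbl["stratum"] + "  (n=" + tbl["n"].astype(str) + ")")
    ax.set_xscale("log")
    ax.set_xlabel("hazard ratio (log scale)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def network_plot(graph: MapperGraph, path, node_to_group: dict | None = None,
                 title="Topological patient-similarity network"):
    """Spring-layout rendering, nodes sized by membership and colored by
    event rate (or phenogroup when a partition is given)."""
    G = graph.to_networkx()
    pos = nx.spring_layout(G, seed=7)
    sizes = [10 + 6 * G.nodes[n]["size"] for n in G]
    if node_to_group:
        colors = [GROUP_COLORS.get(node_to_group.get(n), "#888888") for n in G]
        cmap = None
    else:
        colors = [G.nodes[n].get("event_rate", 0.0) for n in G]
        cmap = plt.cm.viridis
    fig, ax = plt.subplots(figsize=(7, 6))
    nx.draw_networkx_edges(G, pos, ax=ax, alpha=0.2, width=0.5)
    nx.draw_networkx_nodes(G, pos, ax=ax, node_size=sizes, node_color=colors,
                           cmap=cmap, linewidths=0)
    ax.set_axis_off()
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
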