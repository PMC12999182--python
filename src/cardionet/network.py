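"""Causality-network containers and serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class CausalityNetwork:
    """Per-condition cohort of directed-link estimates for one estimator.

    ``links`` is a tidy frame with one row per subject and directed link
    (columns subject, condition, estimator, source, target, T, ...);
    ``significance`` and ``summaries`` optionally carry the per-subject
    surrogate results and the cohort significance degrees.
    """

    estimator: str
    condition: str
    nodes: tuple[str, ...]
    links: pd.DataFrame
    significance: pd.DataFrame | None = None
    summaries: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        m = len(self.nodes)
        pairs = self.links.groupby(["source", "target"]).size()
        if len(pairs) != m * (m - 1):
            raise ValueError(
                f"expected {m * (m - 1)} directed links, found {len(pairs)}"
            )
        if pairs.nunique() != 1:
            raise ValueError("subjects are not consistent across links")

    @property
    def subjects(self) -> list[str]:
        return sorted(self.links["subject"].unique())

    def link_values(self, source: str, target: str, stat: str = "T") -> pd.Series:
        """Per-subject values of one link, indexed by subject id."""
        sel = self.links[
            (self.links["source"] == source) & (self.links["target"] == target)
        ]
        return sel.set_index("subject")[stat].sort_index()

    def mean_matrix(self, stat: str = "T") -> pd.DataFrame:
        """Source-by-target matrix of cohort-mean link values."""
        out = pd.DataFrame(np.nan, index=list(self.nodes), columns=list(self.nodes))
        for (s, t), grp in self.links.groupby(["source", "target"]):
            out.loc[s, t] = grp[stat].mean()
        return out

    def to_json(self, path: str | Path) -> Path:
        """Adjacency-with-weights snapshot (cohort means + significance degrees)."""
        mean = self.mean_matrix()
        payload = {
            "estimator": self.estimator,
            "condition": self.condition,
            "nodes": list(self.nodes),
            "links": [
                {
                    "source": s,
                    "target": t,
                    "mean_T": float(mean.loc[s, t]),
                }
                for s in self.nodes
                for t in self.nodes
                if s != t
            ],
        }
        if self.summaries is not None:
            degree = {
                (r["source"], r["target"]): (r["s"], r["class"])
                for _, r in self.summaries.iterrows()
            }
            for link in payload["links"]:
                s_val, cls = degree.get((link["source"], link["target"]), (None, None))
                link["s"] = s_val
                link["class"] = cls
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path

    def to_graphml(self, path: str | Path, stat: str = "T") -> Path:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        mean = self.mean_matrix(stat)
        for s in self.nodes:
            for t in self.nodes:
                if s != t:
                    g.add_edge(s, t, weight=float(mean.loc[s, t]))
        path = Path(path)
        nx.write_graphml(g, path)
        return path


def plot_network(network: CausalityNetwork, ax=None, threshold: float = 0.0):
    """Minimal arrow plot of cohort-mean link strengths (optional extra)."""
    import matplotlib.pyplot as plt
    import networkx as nx

    if ax is None:
        _fig, ax = plt.subplots(figsize=(4, 4))
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    mean = network.mean_matrix()
    for s in network.nodes:
        for t in network.nodes:
            if s != t and mean.loc[s, t] > threshold:
                g.add_edge(s, t, weight=mean.loc[s, t])
    pos = nx.circular_layout(g)
    weights = [5 * g[u][v]["weight"] + 0.5 for u, v in g.edges]
    nx.draw_networkx(g, pos, ax=ax, width=weights, node_color="lightsteelblue")
    ax.set_title(f"{network.estimator.upper()} {network.condition}")
    ax.set_axis_off()
    return ax
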