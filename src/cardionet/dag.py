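"""Zero-lag (within-beat) effect conventions.

Beat-indexed cardiovascular series are sampled once per heartbeat, which is
coarser than the timescale of several physiological interactions (e.g. the
fast vagal arm of the baroreflex, or respiratory gating of the same beat).
Such interactions show up at lag 0.  A simultaneous system is identifiable
only if the zero-lag coefficients form a directed acyclic graph; here the
convention is a fixed causal ordering of the four nodes,

    RESP (R)  ->  RR (H)  ->  MAP (M)  ->  AC (C),

with every forward pair a permitted zero-lag edge.  The ordering also
encodes the collider rule: when predicting a target, only its DAG parents
may enter at lag 0 (a descendant measured within the same beat would be a
collider and induce spurious association).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

DEFAULT_NODE_ORDER: tuple[str, ...] = ("R", "H", "M", "C")

DEFAULT_ZERO_LAG_EDGES: frozenset[tuple[str, str]] = frozenset(
    {("R", "H"), ("R", "M"), ("R", "C"), ("H", "M"), ("H", "C"), ("M", "C")}
)


@dataclass(frozen=True)
class ZeroLagDag:
    """Topological node ordering plus the set of permitted zero-lag edges.

    Parameters
    ----------
    node_order
        Causal ordering of the nodes; every zero-lag edge must point
        forward in this ordering (which guarantees acyclicity).
    edges
        Ordered (source, target) pairs allowed to carry a lag-0
        coefficient.
    """

    node_order: tuple[str, ...] = DEFAULT_NODE_ORDER
    edges: frozenset[tuple[str, str]] = DEFAULT_ZERO_LAG_EDGES

    def __post_init__(self) -> None:
        order = tuple(self.node_order)
        object.__setattr__(self, "node_order", order)
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        if len(set(order)) != len(order):
            raise ValueError("node_order contains duplicate labels")
        pos = {n: i for i, n in enumerate(order)}
        for src, tgt in self.edges:
            if src not in pos or tgt not in pos:
                raise ValueError(f"zero-lag edge {src}->{tgt} uses unknown node")
            if pos[src] >= pos[tgt]:
                raise ValueError(
                    f"zero-lag edge {src}->{tgt} is not consistent with the "
                    f"node ordering {order}"
                )
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ValueError("zero-lag edges do not form a DAG")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_order)
        g.add_edges_from(self.edges)
        return g

    def allows(self, source: str, target: str) -> bool:
        """True if source->target may carry a zero-lag coefficient."""
        return (source, target) in self.edges

    def parents(self, node: str) -> tuple[str, ...]:
        """DAG parents of *node*, in node_order."""
        return tuple(n for n in self.node_order if (n, node) in self.edges)

    def topological_order(self) -> tuple[str, ...]:
        return self.node_order


DEFAULT_DAG = ZeroLagDag()
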