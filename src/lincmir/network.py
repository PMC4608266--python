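"""Typed miRNA-lincRNA-mRNA regulatory network.

Node identity is the molecule id; target/decoy is an edge role, and a
transcript's role set is the union of its edge roles, so a lincRNA can be the
target of one miRNA and the decoy of another while remaining a single node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .classify import InteractionCall, Verdict
from .seq_io import ValidationError


@dataclass
class NodeInfo:
    kind: str                 # miRNA | lincRNA | mRNA
    roles: set[str] = field(default_factory=set)  # subset of {target, decoy}


@dataclass
class RegulatoryNetwork:
    nodes: dict[str, NodeInfo] = field(default_factory=dict)
    edges: set[tuple[str, str, str]] = field(default_factory=set)

    def add_edge(self, mirna_id: str, partner_id: str, role: str, kind: str) -> None:
        if role not in ("target", "decoy"):
            raise ValidationError(f"edge role must be target/decoy, got {role!r}")
        self.nodes.setdefault(mirna_id, NodeInfo("miRNA"))
        info = self.nodes.setdefault(partner_id, NodeInfo(kind))
        info.roles.add(role)
        self.edges.add((mirna_id, partner_id, role))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def mirnas_with_decoy(self, lincrna_id: str) -> set[str]:
        return {m for m, p, r in self.edges if p == lincrna_id and r == "decoy"}

    def targets_of(self, mirna_id: str, kind: str | None = None) -> set[str]:
        out = {p for m, p, r in self.edges if m == mirna_id and r == "target"}
        if kind is not None:
            out = {p for p in out if self.nodes[p].kind == kind}
        return out


@dataclass(frozen=True)
class NetworkSummary:
    n_mirnas: int
    n_lincrna_targets: int
    n_lincrna_decoys: int
    n_mrna_targets: int
    n_mrna_decoys: int
    n_nodes: int
    n_edges: int
    per_mirna: dict[str, dict[str, int]]


def build_network(
    calls: Sequence[InteractionCall],
    biotypes: Mapping[str, str] | None = None,
) -> RegulatoryNetwork:
    """Assemble the network from target/decoy calls.

    ``biotypes`` maps transcript ids to lincRNA/mRNA; unmapped transcripts
    default to lincRNA.  Calls with verdict none are rejected.
    """
    net = RegulatoryNetwork()
    for call in calls:
        if call.verdict is Verdict.NONE:
            raise ValidationError(
                "build_network requires target/decoy calls only; "
                f"got verdict none for {call.alignment.mirna_id} / "
                f"{call.alignment.transcript_id}"
            )
        tx = call.alignment.transcript_id
        kind = biotypes.get(tx, "lincRNA") if biotypes else "lincRNA"
        net.add_edge(call.alignment.mirna_id, tx, call.verdict.value, kind)
    return net


def summarize_network(net: RegulatoryNetwork) -> NetworkSummary:
    """Role-resolved class counts; dual-role molecules count once per role."""
    counts = {"lincRNA_target": 0, "lincRNA_decoy": 0,
              "mRNA_target": 0, "mRNA_decoy": 0}
    n_mirnas = 0
    for info in net.nodes.values():
        if info.kind == "miRNA":
            n_mirnas += 1
            continue
        for role in info.roles:
            counts[f"{info.kind}_{role}"] += 1
    per_mirna: dict[str, dict[str, int]] = {}
    for mirna, partner, role in net.edges:
        kind = net.nodes[partner].kind
        bucket = per_mirna.setdefault(
            mirna,
            {"lincRNA_target": 0, "lincRNA_decoy": 0,
             "mRNA_target": 0, "mRNA_decoy": 0},
        )
        bucket[f"{kind}_{role}"] += 1
    return NetworkSummary(
        n_mirnas=n_mirnas,
        n_lincrna_targets=counts["lincRNA_target"],
        n_lincrna_decoys=counts["lincRNA_decoy"],
        n_mrna_targets=counts["mRNA_target"],
        n_mrna_decoys=counts["mRNA_decoy"],
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        per_mirna=per_mirna,
    )


def find_subnetworks(net: RegulatoryNetwork) -> list[set[str]]:
    """Connected components of the undirected edge set, largest first.

    Ties are broken by the lexicographically smallest member so the output is
    deterministic.
    """
    graph = nx.Graph()
    graph.add_nodes_from(net.nodes)
    graph.add_edges_from((m, p) for m, p, _r in net.edges)
    components = [set(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), min(c)))
    return components
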