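"""Interaction-module extraction from a locally supplied scored edge list.

Mirrors the STRING-style step of the workflow: given the enriched proteins
of a pathway analysis and an undirected edge list with confidence scores in
[0, 1], keep edges above a confidence threshold among the proteins of
interest and report the connected components (largest first, singletons
omitted).  No remote service is contacted; the edge list is a local
3-column TSV (``protein_a``, ``protein_b``, ``score``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)


@dataclass
class ScoredEdgeList:
    """Undirected scored edges keyed by the sorted symbol pair."""

    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.edges)

    def add(self, a: str, b: str, score: float) -> None:
        """Add an edge; self-loops are dropped, duplicates keep the max score."""
        a, b = a.strip().upper(), b.strip().upper()
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"confidence score must be in [0, 1], got {score}")
        if a == b:
            logger.warning("dropping self-loop %s-%s", a, b)
            return
        key = (a, b) if a < b else (b, a)
        if key in self.edges:
            self.edges[key] = max(self.edges[key], score)
        else:
            self.edges[key] = score

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float]]
    ) -> "ScoredEdgeList":
        out = cls()
        for a, b, score in records:
            out.add(a, b, float(score))
        return out


def read_edge_list(path: str | Path) -> ScoredEdgeList:
    """Read a 3-column TSV edge list (header optional)."""
    path = Path(path)
    out = ScoredEdgeList()
    with path.open(encoding="utf-8") as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}, line {line_number}: need 3 tab-separated fields"
                )
            try:
                score = float(fields[2])
            except ValueError:
                if line_number == 1:  # header row
                    continue
                raise ValueError(
                    f"{path}, line {line_number}: unparsable score {fields[2]!r}"
                ) from None
            out.add(fields[0], fields[1], score)
    return out


def write_edge_list(edges: ScoredEdgeList, path: str | Path) -> None:
    path = Path(path)
    lines = ["protein_a\tprotein_b\tscore"]
    for (a, b) in sorted(edges.edges):
        lines.append(f"{a}\t{b}\t{edges.edges[(a, b)]!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class InteractionModule:
    """A connected component of the thresholded induced subgraph."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]

    def __len__(self) -> int:
        return len(self.nodes)


def induced_modules(
    proteins: Iterable[str],
    edges: ScoredEdgeList,
    min_score: float = 0.4,
) -> list[InteractionModule]:
    """Connected interaction modules among a protein set.

    The subgraph induced on ``proteins`` keeps edges with confidence
    strictly above ``min_score``; components are returned largest first
    (ties broken by smallest node name) and singletons are omitted.
    """
    if not (0.0 <= min_score <= 1.0):
        raise ValueError(f"min_score must be in [0, 1], got {min_score}")
    wanted = {p.strip().upper() for p in proteins}
    graph = nx.Graph()
    for (a, b), score in edges.edges.items():
        if a in wanted and b in wanted and score > min_score:
            graph.add_edge(a, b, score=score)
    modules = []
    for component in nx.connected_components(graph):
        if len(component) < 2:
            continue
        nodes = tuple(sorted(component))
        kept = tuple(
            (a, b, edges.edges[(a, b)])
            for (a, b) in sorted(edges.edges)
            if a in component and b in component and edges.edges[(a, b)] > min_score
        )
        modules.append(InteractionModule(nodes=nodes, edges=kept))
    modules.sort(key=lambda m: (-len(m.nodes), m.nodes[0]))
    return modules
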