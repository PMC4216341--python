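"""Two-mode ailment-category x species network analysis.

The survey's citation structure is a weighted bipartite graph: one node set
holds the 16 ailment categories, the other the plant species; an edge weight
counts the use reports linking a category to a species. The analysis layer
offers the weighted incidence matrix, UCINET DL interchange (the format the
social-network tools UCINET/NetDraw consume), two-mode degree centrality, a
one-mode category projection by shared species, a seeded force-directed
layout, and modularity-based grouping of categories. Published group
structure in this literature comes from visual inspection of NetDraw
layouts; here group identity is made reproducible via explicit greedy
modularity maximisation on the category projection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .reports import UseReport

__all__ = [
    "build_incidence",
    "binary_view",
    "write_ucinet_dl",
    "read_ucinet_dl",
    "two_mode_degree",
    "project_categories",
    "bipartite_graph",
    "layout_spring",
    "GroupPartition",
    "detect_groups",
    "write_graphml",
    "write_edgelist_tsv",
    "plot_network",
]


def build_incidence(reports: Sequence[UseReport],
                    node_mode: str = "category") -> pd.DataFrame:
    """Weighted incidence matrix: ailment rows x species columns.

    ``node_mode="category"`` (default) uses the 16 ailment categories as the
    row mode; ``"ailment"`` uses raw ailment labels. Row sums equal the
    per-category use-report counts (nur) and column sums the per-species
    totals (n) — the same marginals the consensus indices count.
    """
    if node_mode not in ("category", "ailment"):
        raise DomainError(f"node_mode must be 'category' or 'ailment', "
                          f"got {node_mode!r}")
    if not reports:
        return pd.DataFrame(dtype=int)
    if node_mode == "category":
        missing = sorted({r.ailment for r in reports if r.category is None})
        if missing:
            raise ValidationError(
                f"categorised reports required; uncategorised: {missing}")
        row_of = lambda r: r.category
    else:
        row_of = lambda r: r.ailment
    rows = sorted({row_of(r) for r in reports})
    cols = sorted({r.species_id for r in reports})
    matrix = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for r in reports:
        matrix.loc[row_of(r), r.species_id] += 1
    matrix.index.name = "ailment"
    matrix.columns.name = "species"
    return matrix


def binary_view(matrix: pd.DataFrame) -> pd.DataFrame:
    """0/1 view of the incidence matrix (entry > 0 -> 1)."""
    return (matrix > 0).astype(int)


def write_ucinet_dl(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write the matrix in UCINET DL fullmatrix dialect (LF endings).

    Header ``dl nr=<R> nc=<C> format=fullmatrix``, quoted labels one per
    line, then rows of space-separated integers.
    """
    if matrix.empty:
        raise DomainError("refusing to write a degenerate (empty) DL matrix")
    lines = [f"dl nr={matrix.shape[0]} nc={matrix.shape[1]} format=fullmatrix"]
    lines.append("row labels:")
    lines.extend(f'"{label}"' for label in matrix.index)
    lines.append("col labels:")
    lines.extend(f'"{label}"' for label in matrix.columns)
    lines.append("data:")
    for _, row in matrix.iterrows():
        lines.append(" ".join(str(int(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_ucinet_dl(path: str | Path) -> pd.DataFrame:
    """Read a DL fullmatrix file written by :func:`write_ucinet_dl`."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header = lines[0].strip().lower()
    m = re.match(r"dl\s+nr=(\d+)\s+nc=(\d+)\s+format=fullmatrix", header)
    if not m:
        raise ValidationError(f"not a DL fullmatrix header: {lines[0]!r}")
    nr, nc = int(m.group(1)), int(m.group(2))
    sections: dict[str, list[str]] = {}
    current = None
    for line in lines[1:]:
        stripped = line.strip()
        if not stripped:
            continue
        lowered = stripped.lower()
        if lowered in ("row labels:", "col labels:", "data:"):
            current = lowered
            sections[current] = []
        elif current is not None:
            sections[current].append(stripped)
        else:
            raise ValidationError(f"unexpected DL content outside sections: "
                                  f"{stripped!r}")
    def unquote(label: str) -> str:
        return label[1:-1] if len(label) >= 2 and label[0] == label[-1] == '"' \
            else label
    rows = [unquote(s) for s in sections.get("row labels:", [])]
    cols = [unquote(s) for s in sections.get("col labels:", [])]
    data = [[int(v) for v in s.split()] for s in sections.get("data:", [])]
    if len(rows) != nr or len(cols) != nc or len(data) != nr:
        raise ValidationError("DL label/data block sizes disagree with header")
    matrix = pd.DataFrame(data, index=rows, columns=cols, dtype=int)
    matrix.index.name = "ailment"
    matrix.columns.name = "species"
    return matrix


def two_mode_degree(matrix: pd.DataFrame, weighted: bool = False,
                    normalized: bool = False) -> pd.DataFrame:
    """Degree centrality for both modes.

    Unweighted degree counts nonzero incident cells; weighted degree is the
    marginal sum. The normalised variant divides by the opposite-mode size.
    """
    nr, nc = matrix.shape if not matrix.empty else (0, 0)
    rows = []
    for label in matrix.index:
        row = matrix.loc[label]
        deg = float(row.sum()) if weighted else float((row > 0).sum())
        rows.append({"node": label, "mode": "ailment",
                     "degree": deg / nc if (normalized and nc) else deg})
    for label in matrix.columns:
        col = matrix[label]
        deg = float(col.sum()) if weighted else float((col > 0).sum())
        rows.append({"node": label, "mode": "species",
                     "degree": deg / nr if (normalized and nr) else deg})
    return pd.DataFrame(rows, columns=["node", "mode", "degree"])


def project_categories(matrix: pd.DataFrame) -> pd.DataFrame:
    """One-mode category projection by shared species.

    Entry (a, b) counts species cited in both categories (a set notion, on
    the binary view); the diagonal carries each category's taxa count nt.
    """
    if matrix.empty:
        return pd.DataFrame(dtype=int)
    binary = binary_view(matrix).to_numpy()
    proj = binary @ binary.T
    out = pd.DataFrame(proj, index=matrix.index, columns=matrix.index,
                       dtype=int)
    out.index.name = out.columns.name = "ailment"
    return out


def bipartite_graph(matrix: pd.DataFrame) -> nx.Graph:
    """Weighted bipartite graph over the two label sets."""
    overlap = set(matrix.index) & set(matrix.columns)
    if overlap:
        raise ValidationError(
            f"row and column labels must be disjoint; shared: {sorted(overlap)}")
    graph = nx.Graph()
    graph.add_nodes_from(matrix.index, bipartite=0, mode="ailment")
    graph.add_nodes_from(matrix.columns, bipartite=1, mode="species")
    for row_label in matrix.index:
        for col_label in matrix.columns:
            weight = int(matrix.loc[row_label, col_label])
            if weight > 0:
                graph.add_edge(row_label, col_label, weight=weight)
    return graph


def layout_spring(matrix: pd.DataFrame, seed: int,
                  iterations: int = 100) -> dict:
    """Seeded Fruchterman-Reingold embedding, scaled to the unit box."""
    if matrix.empty:
        raise DomainError("cannot lay out an empty graph")
    graph = bipartite_graph(matrix)
    pos = nx.spring_layout(graph, seed=seed, iterations=iterations,
                           weight="weight")
    coords = np.array(list(pos.values()))
    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo
    span[span == 0] = 1.0
    return {node: tuple((xy - lo) / span) for node, xy in pos.items()}


@dataclass(frozen=True)
class GroupPartition:
    """Category -> group-id mapping with the partition's modularity score."""

    groups: Mapping[str, int]
    modularity: float
    method: str = "greedy_modularity"

    @property
    def n_groups(self) -> int:
        return len(set(self.groups.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.groups.items())
        return pd.DataFrame(rows, columns=["category", "group_id"])


def detect_groups(projection: pd.DataFrame, seed: int = 0,
                  method: str = "greedy_modularity") -> GroupPartition:
    """Group ailment categories by modularity maximisation on the weighted
    shared-species projection.

    Greedy (CNM) modularity maximisation is deterministic; the seed is
    accepted for interface stability across methods. Group ids are
    contiguous from 1, ordered by group size (then smallest member label).
    Fewer than two categories yield a single-group partition.
    """
    if method != "greedy_modularity":
        raise DomainError(f"unknown grouping method {method!r}")
    categories = list(projection.index)
    if len(categories) < 2:
        return GroupPartition(groups={c: 1 for c in categories},
                              modularity=0.0, method=method)
    graph = nx.Graph()
    graph.add_nodes_from(categories)
    for i, a in enumerate(categories):
        for b in categories[i + 1:]:
            weight = int(projection.loc[a, b])
            if weight > 0:
                graph.add_edge(a, b, weight=weight)
    if graph.number_of_edges() == 0:
        communities = [{c} for c in categories]
    else:
        communities = [
            set(c) for c in
            nx.community.greedy_modularity_communities(graph, weight="weight")
        ]
        # isolated categories end up as singletons already
    communities.sort(key=lambda c: (-len(c), min(c)))
    groups = {cat: gid for gid, members in enumerate(communities, start=1)
              for cat in sorted(members)}
    score = (nx.community.modularity(graph, communities, weight="weight")
             if graph.number_of_edges() else 0.0)
    return GroupPartition(groups=groups, modularity=float(score),
                          method=method)


def write_graphml(matrix: pd.DataFrame, path: str | Path) -> None:
    nx.write_graphml(bipartite_graph(matrix), path)


def write_edgelist_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Weighted edge list, ``source<TAB>target<TAB>weight``, sorted."""
    lines = ["source\ttarget\tweight"]
    for row_label in matrix.index:
        for col_label in matrix.columns:
            weight = int(matrix.loc[row_label, col_label])
            if weight > 0:
                lines.append(f"{row_label}\t{col_label}\t{weight}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def plot_network(matrix: pd.DataFrame, layout: Mapping[str, tuple],
                 path: str | Path, partition: GroupPartition | None = None
                 ) -> None:
    """Static figure of the two-mode network at the given layout."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    graph = bipartite_graph(matrix)
    fig, ax = plt.subplots(figsize=(10, 8))
    ailments = list(matrix.index)
    species = list(matrix.columns)
    nx.draw_networkx_edges(graph, layout, ax=ax, alpha=0.2)
    if partition is not None:
        colors = [partition.groups.get(a, 0) for a in ailments]
    else:
        colors = "tab:red"
    nx.draw_networkx_nodes(graph, layout, nodelist=species, node_size=20,
                           node_color="lightgray", ax=ax)
    nx.draw_networkx_nodes(graph, layout, nodelist=ailments, node_size=120,
                           node_color=colors, cmap="tab10", ax=ax)
    nx.draw_networkx_labels(graph, layout,
                            labels={a: a for a in ailments}, font_size=6,
                            ax=ax)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
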