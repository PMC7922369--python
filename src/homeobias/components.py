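"""Homeolog component construction and classification.

In an allohexaploid (subgenomes A, B, D), family members that descend
from one ancestral locus form small homologous sets.  This module links
members into connected components of a thresholded homology graph and
classifies each component:

* ``group``   — exactly three members, one per subgenome, on homologous
  chromosomes (same chromosome number): a complete triad.
* ``cluster`` — >= 4 members covering all three subgenomes with at least
  one subgenome carrying two or more copies (tandem expansion).
* ``pair``    — members from exactly two subgenomes (one homeolog lost).
* ``orphan``  — a single member, or a component confined to one subgenome.
* ``unresolved`` — a three-member, three-subgenome component whose
  chromosome numbers do not match; the triad criterion explicitly
  requires homologous chromosomes, so these are surfaced, not silently
  grouped.

Unplaced genes (no chromosome assignment) can have their subgenome
inferred from their partners: if the placed members of a component cover
exactly two subgenomes, the unplaced gene is speculated to come from the
missing third.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

SUBGENOMES = ("A", "B", "D")
COMPONENT_CLASSES = ("group", "cluster", "pair", "orphan", "unresolved")


@dataclass(frozen=True)
class GeneModel:
    """One gene's location: chromosome like "3B", or "unplaced"."""

    id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: bad strand {self.strand!r}")

    @property
    def subgenome(self) -> str:
        if self.chromosome == "unplaced":
            return "unknown"
        return self.chromosome[-1]

    @property
    def chromosome_number(self) -> int | None:
        if self.chromosome == "unplaced":
            return None
        return int(self.chromosome[:-1])


@dataclass
class HomeologComponent:
    id: str
    members: list[str]
    component_class: str = "unresolved"
    chromosome_number: int | None = None
    inferred_subgenomes: dict[str, str] = field(default_factory=dict)


def build_homology_graph(
    genes: dict[str, GeneModel],
    edges: list[tuple[str, str, float]],
    link_threshold: float,
) -> list[HomeologComponent]:
    """Connected components of edges with distance <= threshold.

    ``edges`` are (gene_a, gene_b, distance) triples; any endpoint not in
    ``genes`` is a validation error.  Output is deterministic: members
    and components sorted by gene id.
    """
    g = nx.Graph()
    g.add_nodes_from(genes)
    for a, b, dist in edges:
        for x in (a, b):
            if x not in genes:
                raise ValueError(f"edge references unknown gene id: {x}")
        if a != b and dist <= link_threshold:
            g.add_edge(a, b)
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0]
    )
    return [
        HomeologComponent(id=f"comp{i + 1:04d}", members=m)
        for i, m in enumerate(comps)
    ]


def edges_from_distance_matrix(dm) -> list[tuple[str, str, float]]:
    """All pairwise edges of a :class:`~homeobias.phylo.DistanceMatrix`."""
    out = []
    for i, a in enumerate(dm.labels):
        for j in range(i + 1, len(dm.labels)):
            out.append((a, dm.labels[j], float(dm.d[i, j])))
    return out


def infer_subgenome(component: HomeologComponent, genes: dict[str, GeneModel],
                    gene_id: str) -> str:
    """Speculate an unplaced gene's subgenome from its partners.

    If the placed members of the component cover exactly two subgenomes,
    the unplaced gene is assigned the missing third; otherwise unknown.
    """
    if gene_id not in component.members:
        raise ValueError(f"{gene_id} is not a member of {component.id}")
    placed = {
        genes[m].subgenome
        for m in component.members
        if m != gene_id and genes[m].subgenome != "unknown"
    }
    if len(placed) == 2:
        (missing,) = set(SUBGENOMES) - placed
        return missing
    return "unknown"


def classify_component(
    component: HomeologComponent,
    genes: dict[str, GeneModel],
    cluster_min: int = 4,
) -> str:
    """Assign the component class; also fills in subgenome inferences.

    ``cluster_min`` is the minimum member count for a cluster (the
    expanded-component criterion is read as >= 4 by default).
    """
    if not component.members:
        raise ValueError("component has no members")
    inferred: dict[str, str] = {}
    subg: list[str] = []
    for m in component.members:
        s = genes[m].subgenome
        if s == "unknown":
            s = infer_subgenome(component, genes, m)
            inferred[m] = s
        if s != "unknown":
            subg.append(s)
    component.inferred_subgenomes = inferred

    numbers = {
        genes[m].chromosome_number
        for m in component.members
        if genes[m].chromosome_number is not None
    }
    component.chromosome_number = numbers.pop() if len(numbers) == 1 else None
    distinct = set(subg)
    n = len(component.members)

    if n == 1 or len(distinct) <= 1:
        cls = "orphan"
    elif len(distinct) == 2:
        cls = "pair"
    elif n == 3:
        # complete triad only on homologous chromosomes
        cls = "group" if component.chromosome_number is not None else "unresolved"
    elif n >= cluster_min:
        counts = {s: subg.count(s) for s in SUBGENOMES}
        cls = "cluster" if max(counts.values()) >= 2 else "unresolved"
    else:
        cls = "unresolved"
    component.component_class = cls
    return cls


def classify_components(
    components: list[HomeologComponent],
    genes: dict[str, GeneModel],
    cluster_min: int = 4,
) -> list[HomeologComponent]:
    for c in components:
        classify_component(c, genes, cluster_min)
    return components


def summarize_components(components: list[HomeologComponent]) -> pd.DataFrame:
    """Per-class component and gene counts (gene totals conserved)."""
    rows = []
    for cls in COMPONENT_CLASSES:
        of_class = [c for c in components if c.component_class == cls]
        rows.append(
            {
                "class": cls,
                "n_components": len(of_class),
                "n_genes": sum(len(c.members) for c in of_class),
            }
        )
    df = pd.DataFrame(rows)
    total = {
        "class": "total",
        "n_components": int(df["n_components"].sum()),
        "n_genes": int(df["n_genes"].sum()),
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def components_table(components: list[HomeologComponent]) -> pd.DataFrame:
    rows = []
    for c in components:
        rows.append(
            {
                "component_id": c.id,
                "class": c.component_class,
                "chromosome_number": "" if c.chromosome_number is None else c.chromosome_number,
                "members": ",".join(c.members),
                "inferred_subgenomes": ";".join(
                    f"{g}={s}" for g, s in sorted(c.inferred_subgenomes.items())
                ),
            }
        )
    return pd.DataFrame(rows)
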