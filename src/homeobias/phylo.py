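"""Distance-based phylogeny for family members.

Pairwise distances come from shared k-mer content (a deterministic,
alignment-free stand-in for alignment distances; any user-supplied
:class:`DistanceMatrix` can be dropped in instead).  Trees are built with
the classical Saitou-Nei neighbor-joining agglomeration, with explicit
tie-breaking and negative-branch handling rules so runs are reproducible.
Branch support is estimated by bootstrap-resampling k-mer columns.

Family members are assigned to the two major phylogenetic groups
(Group I / Group II) and, within Group I, to one of six subgroups
(SNAC, ANAC34, SND, NAC1, NAM/CUC3, TIP) by nearest reference anchor —
the same classify-by-known-anchors scheme used for plant NAC catalogues.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .features import ProteinRecord

GROUP_I_SUBGROUPS = ("SNAC", "ANAC34", "SND", "NAC1", "NAM/CUC3", "TIP")


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with ordered labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if np.any(np.abs(self.d - self.d.T) > 1e-12):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")

    def __len__(self) -> int:
        return len(self.labels)

    def loc(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


def kmer_counts(sequence: str, k: int) -> Counter:
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k={k}")
    return Counter(sequence[i : i + k] for i in range(len(sequence) - k + 1))


def kmer_distance(a: ProteinRecord, b: ProteinRecord, k: int = 3) -> float:
    """1 - (shared k-mers / min total k-mers); symmetric, in [0, 1]."""
    ca, cb = kmer_counts(a.sequence, k), kmer_counts(b.sequence, k)
    shared = sum(min(ca[m], cb[m]) for m in ca.keys() & cb.keys())
    denom = min(sum(ca.values()), sum(cb.values()))
    return 1.0 - shared / denom


def kmer_profile_matrix(
    records: list[ProteinRecord], k: int = 3
) -> tuple[list[str], list[str], np.ndarray]:
    """Counts matrix (records x union k-mers), for bootstrap resampling."""
    counters = [kmer_counts(r.sequence, k) for r in records]
    kmers = sorted(set().union(*[set(c) for c in counters]))
    kidx = {m: j for j, m in enumerate(kmers)}
    counts = np.zeros((len(records), len(kmers)), dtype=np.int64)
    for i, c in enumerate(counters):
        for m, v in c.items():
            counts[i, kidx[m]] = v
    return [r.id for r in records], kmers, counts


def _distances_from_counts(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=1)
    n = counts.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(counts[i], counts[i + 1 :]).sum(axis=1)
        denom = np.minimum(totals[i], totals[i + 1 :])
        with np.errstate(invalid="ignore", divide="ignore"):
            row = 1.0 - shared / denom
        row[denom == 0] = 1.0  # no k-mers left after resampling
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return d


def kmer_distance_matrix(records: list[ProteinRecord], k: int = 3) -> DistanceMatrix:
    labels, _, counts = kmer_profile_matrix(records, k)
    return DistanceMatrix(labels=labels, d=_distances_from_counts(counts))


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    The returned :class:`skbio.TreeNode` has a trifurcating root (the
    standard unrooted representation), ``2n - 3`` edges for n leaves.

    Determinism rules: input taxa are processed in sorted-label order;
    Q-matrix ties pick the smallest (i, j) index pair; a negative branch
    length estimate is clamped to 0 with the deficit shifted onto its
    sibling branch.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    order = sorted(range(n), key=lambda i: dm.labels[i])
    labels = [dm.labels[i] for i in order]
    d = dm.d[np.ix_(order, order)].astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) pair on ties: scan upper triangle row-major
        best = (np.inf, -1, -1)
        for i in range(m):
            j = int(np.argmin(q[i, i + 1 :])) + i + 1 if i + 1 < m else -1
            if j >= 0 and q[i, j] < best[0]:
                best = (q[i, j], i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = du[keep]
        d_new[:-1, -1] = du[keep]
        nodes = [nodes[x] for x in keep] + [parent]
        d = d_new

    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode(children=[a, b, c])
    a.length = max(la, 0.0)
    b.length = max(lb, 0.0)
    c.length = max(lc, 0.0)
    return root


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Internal-edge bipartitions as frozensets of {side, complement}."""
    all_tips = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            parts.add(frozenset({side, all_tips - side}))
    return parts


def path_length_matrix(tree: TreeNode, labels: list[str]) -> np.ndarray:
    """Patristic (path-length) distances between the given tips."""
    skdm = tree.tip_tip_distances()
    idx = [list(skdm.ids).index(lbl) for lbl in labels]
    return np.asarray(skdm.data)[np.ix_(idx, idx)]


def bootstrap_support(
    records: list[ProteinRecord],
    k: int = 3,
    n_reps: int = 1000,
    seed: int = 0,
    reference_tree: TreeNode | None = None,
) -> tuple[TreeNode, dict[frozenset, float]]:
    """Bootstrap branch support by resampling k-mer columns.

    Each replicate draws k-mer columns of the count matrix with
    replacement, recomputes the distance matrix and NJ tree, and scores
    every reference bipartition by the fraction of replicate trees that
    contain it.  Returns the reference tree (support written onto the
    internal node names, 0-1 scale) and the bipartition -> support map.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels, kmers, counts = kmer_profile_matrix(records, k)
    if reference_tree is None:
        reference_tree = nj_tree(
            DistanceMatrix(labels=labels, d=_distances_from_counts(counts))
        )
    ref_parts = tree_bipartitions(reference_tree)
    hits = {p: 0 for p in ref_parts}
    rng = np.random.default_rng(seed)
    ncol = counts.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_counts = counts[:, cols]
        rep_dm = DistanceMatrix(labels=labels, d=_distances_from_counts(rep_counts))
        rep_parts = tree_bipartitions(nj_tree(rep_dm))
        for p in ref_parts & rep_parts:
            hits[p] += 1
    support = {p: hits[p] / n_reps for p in ref_parts}
    for node in reference_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        all_tips = frozenset(t.name for t in reference_tree.tips())
        key = frozenset({side, all_tips - side})
        if key in support:
            node.name = f"{support[key]:.3f}"
    return reference_tree, support


# ---------------------------------------------------------------------------
# Group / subgroup assignment by nearest anchor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubgroupCall:
    gene: str
    phylo_group: str  # "I" or "II"
    subgroup: str     # one of GROUP_I_SUBGROUPS, or "none" for Group II
    nearest_anchor: str
    ambiguous: bool


def assign_subgroups(
    dm: DistanceMatrix, anchor_subgroups: dict[str, str]
) -> dict[str, SubgroupCall]:
    """Assign each non-anchor gene to its nearest anchor's subgroup.

    ``anchor_subgroups`` maps anchor id -> subgroup name; the value
    ``"none"`` marks a Group-II anchor.  Ties between equally distant
    anchors go to the lexicographically smallest anchor id and are
    flagged ambiguous.
    """
    missing = [a for a in anchor_subgroups if a not in dm.labels]
    if missing:
        raise ValueError(f"anchors missing from distance matrix: {sorted(missing)}")
    for sg in anchor_subgroups.values():
        if sg != "none" and sg not in GROUP_I_SUBGROUPS:
            raise ValueError(f"unknown subgroup: {sg}")
    anchors = sorted(anchor_subgroups)
    aidx = [dm.labels.index(a) for a in anchors]
    out: dict[str, SubgroupCall] = {}
    for gi, gene in enumerate(dm.labels):
        if gene in anchor_subgroups:
            continue
        dists = dm.d[gi, aidx]
        best = float(dists.min())
        winners = [anchors[x] for x in np.nonzero(dists == best)[0]]
        anchor = min(winners)
        sg = anchor_subgroups[anchor]
        out[gene] = SubgroupCall(
            gene=gene,
            phylo_group="II" if sg == "none" else "I",
            subgroup=sg,
            nearest_anchor=anchor,
            ambiguous=len(winners) > 1,
        )
    return out


def load_anchor_fixture() -> tuple[list[ProteinRecord], dict[str, str]]:
    """Bundled synthetic anchor proteins and their subgroup map.

    Thirteen anchors: two per Group-I subgroup plus one Group-II anchor.
    These are synthetic stand-ins built around the bundled domain
    consensus and subgroup signature peptides, not real Arabidopsis
    sequences; replace with your own anchor FASTA for real analyses.
    """
    from Bio import SeqIO

    base = resources.files("homeobias.data")
    records = [
        ProteinRecord(id=r.id, sequence=str(r.seq))
        for r in SeqIO.parse(str(base.joinpath("anchors_synthetic.faa")), "fasta")
    ]
    mapping: dict[str, str] = {}
    with open(str(base.joinpath("anchor_subgroups.tsv"))) as fh:
        header = True
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if header:
                header = False
                continue
            anchor, sg = line.split("\t")
            mapping[anchor] = sg
    return records, mapping
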