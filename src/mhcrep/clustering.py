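"""Functional clustering of alleles by binder-repertoire overlap.

For an allele pair (a, b) and virus v, similarity is the Jaccard index of
the two alleles' binder-peptide sets on that virus,

    J_ab,v = |a_v ∩ b_v| / |a_v ∪ b_v|,

and the functional distance averages over viruses and converts to a
distance,

    D_ab = 1 - (1/N) Σ_v J_ab,v.

Alleles are clustered with UPGMA (size-weighted average linkage, merge
height d/2, deterministic tie-breaking by name-sorted pair). Node
confidence comes from virus-subsampled bootstrap replicates (default 1000
replicates, 20% of the viruses drawn without replacement) summarized with
the extended majority-rule consensus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .repertoire import BinderRepertoire


# ---------------------------------------------------------------------------
# Jaccard and functional distances
# ---------------------------------------------------------------------------


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """Jaccard similarity |A∩B| / |A∪B|.

    Two empty sets are indistinguishable repertoires, so J(∅, ∅) = 1 by
    convention.
    """
    a, b = set(set_a), set(set_b)
    union = len(a | b)
    if union == 0:
        return 1.0
    return len(a & b) / union


def _resolve_subset(repertoire: BinderRepertoire, virus_subset) -> list[str]:
    if virus_subset is None:
        subset = list(repertoire.viruses)
    else:
        subset = list(virus_subset)
        unknown = [v for v in subset if v not in set(repertoire.viruses)]
        if unknown:
            raise ValueError(f"viruses not in repertoire: {unknown}")
    if not subset:
        raise ValueError("virus subset is empty")
    return subset


def functional_distance(
    repertoire: BinderRepertoire,
    allele_a: str,
    allele_b: str,
    virus_subset: Sequence[str] | None = None,
) -> float:
    """D_ab = 1 − mean per-virus Jaccard over the subset (default all viruses)."""
    subset = _resolve_subset(repertoire, virus_subset)
    js = [
        jaccard(repertoire.binder_set(allele_a, v), repertoire.binder_set(allele_b, v))
        for v in subset
    ]
    return 1.0 - float(np.mean(js))


@dataclass
class DistanceMatrix:
    names: list[str]
    matrix: np.ndarray
    n_viruses: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.names)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match allele count")
        if np.isnan(self.matrix).any():
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix is not symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.names.index(a), self.names.index(b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(len(self.names), k=1)
        return self.matrix[iu]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("allele\t" + "\t".join(self.names) + "\n")
            for i, name in enumerate(self.names):
                fh.write(name + "\t" + "\t".join(f"{x:.6f}" for x in self.matrix[i]) + "\n")

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.names)}\n")
            for i, name in enumerate(self.names):
                fh.write(name + "  " + " ".join(f"{x:.6f}" for x in self.matrix[i]) + "\n")


def jaccard_cube(repertoire: BinderRepertoire) -> np.ndarray:
    """Per-virus Jaccard similarities, shape (alleles, alleles, viruses).

    Precomputing this makes virus-subsampled bootstrap replicates cheap:
    a replicate's distance matrix is 1 − the mean over its virus columns.
    """
    alleles = repertoire.alleles
    viruses = repertoire.viruses
    cube = np.ones((len(alleles), len(alleles), len(viruses)))
    for vi, v in enumerate(viruses):
        sets = [repertoire.binder_set(a, v) for a in alleles]
        for i in range(len(alleles)):
            for j in range(i + 1, len(alleles)):
                jv = jaccard(sets[i], sets[j])
                cube[i, j, vi] = cube[j, i, vi] = jv
    return cube


def distance_matrix(
    repertoire: BinderRepertoire,
    virus_subset: Sequence[str] | None = None,
    cube: np.ndarray | None = None,
) -> DistanceMatrix:
    """Full symmetric matrix of functional distances over all allele pairs."""
    if len(repertoire.alleles) < 2:
        raise ValueError("need at least 2 alleles for a distance matrix")
    subset = _resolve_subset(repertoire, virus_subset)
    if cube is None:
        cube = jaccard_cube(repertoire)
    idx = [repertoire.viruses.index(v) for v in subset]
    mat = 1.0 - cube[:, :, idx].mean(axis=2)
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(names=list(repertoire.alleles), matrix=mat, n_viruses=len(subset))


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class Tree:
    """Rooted tree node; leaves carry names, internal nodes heights/supports."""

    name: str | None = None
    children: list["Tree"] = field(default_factory=list)
    height: float = 0.0
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaves())

    def walk(self) -> Iterable["Tree"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def clades(self, include_root: bool = False) -> set[frozenset[str]]:
        """Leaf sets of internal nodes (non-trivial clades)."""
        out: set[frozenset[str]] = set()
        for node in self.walk():
            if node.is_leaf:
                continue
            if node is self and not include_root:
                continue
            out.add(node.leaf_set())
        return out

    def find_clade(self, leaf_set: frozenset[str]) -> "Tree | None":
        for node in self.walk():
            if not node.is_leaf and node.leaf_set() == leaf_set:
                return node
        return None

    def cophenetic(self) -> tuple[list[str], np.ndarray]:
        """Ultrametric cophenetic distances: 2 x height of the LCA."""
        names = sorted(self.leaves())
        pos = {n: i for i, n in enumerate(names)}
        n = len(names)
        mat = np.zeros((n, n))

        def visit(node: Tree) -> list[str]:
            if node.is_leaf:
                return [node.name]  # type: ignore[list-item]
            groups = [visit(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            d = 2.0 * node.height
                            mat[pos[a], pos[b]] = mat[pos[b], pos[a]] = d
            return [x for g in groups for x in g]

        visit(self)
        return names, mat

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        """All leaves equidistant from the root and heights non-decreasing."""
        ok = True

        def visit(node: Tree) -> None:
            nonlocal ok
            for c in node.children:
                if c.height > node.height + tol:
                    ok = False
                visit(c)

        visit(self)
        depths = []

        def depth(node: Tree) -> None:
            if node.is_leaf:
                depths.append(self.height - node.height)
            for c in node.children:
                depth(c)

        depth(self)
        if depths and (max(depths) - min(depths)) > tol:
            ok = False
        return ok

    def cut(self, k: int) -> list[frozenset[str]]:
        """Cut the dendrogram into k clusters (undo the k−1 highest merges)."""
        clusters: list[Tree] = [self]
        while len(clusters) < k:
            internal = [c for c in clusters if not c.is_leaf]
            if not internal:
                break
            top = max(internal, key=lambda c: (c.height, sorted(c.leaves())))
            clusters.remove(top)
            clusters.extend(top.children)
        return [c.leaf_set() for c in clusters]


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


def upgma(dm: DistanceMatrix) -> Tree:
    """Size-weighted average-linkage agglomeration into an ultrametric tree.

    Repeatedly merges the pair of clusters at minimal average distance at
    height d/2; ties are broken toward the lexicographically smallest
    name-sorted pair, so the result is deterministic.
    """
    if len(dm.names) < 2:
        raise ValueError("UPGMA needs at least 2 leaves")

    # cluster key = sorted tuple of leaf names (stable tie-break identity)
    nodes: dict[tuple, Tree] = {}
    sizes: dict[tuple, int] = {}
    dist: dict[frozenset, float] = {}
    keys: list[tuple] = []
    for i, name in enumerate(dm.names):
        key = (name,)
        nodes[key] = Tree(name=name, height=0.0)
        sizes[key] = 1
        keys.append(key)
    for i in range(len(dm.names)):
        for j in range(i + 1, len(dm.names)):
            dist[frozenset((keys[i], keys[j]))] = float(dm.matrix[i, j])

    active = sorted(keys)
    while len(active) > 1:
        best_pair = None
        best_d = math.inf
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a, b = active[i], active[j]
                d = dist[frozenset((a, b))]
                pair = tuple(sorted((a, b)))
                if d < best_d - 1e-15 or (
                    abs(d - best_d) <= 1e-15 and (best_pair is None or pair < best_pair)
                ):
                    best_d = d
                    best_pair = pair
        a, b = best_pair  # type: ignore[misc]
        merged_key = tuple(sorted(a + b))
        node = Tree(children=[nodes[a], nodes[b]], height=best_d / 2.0)
        na, nb = sizes[a], sizes[b]
        for other in active:
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((merged_key, other))] = (na * da + nb * db) / (na + nb)
        dist.pop(frozenset((a, b)))
        nodes[merged_key] = node
        sizes[merged_key] = na + nb
        active = sorted(k for k in active if k not in (a, b)) + [merged_key]
        active.sort()
    return nodes[active[0]]


# ---------------------------------------------------------------------------
# Bootstrap and consensus
# ---------------------------------------------------------------------------


def clade_frequencies(trees: Sequence[Tree]) -> dict[frozenset[str], float]:
    """Fraction of trees containing each non-trivial clade."""
    if not trees:
        raise ValueError("no trees")
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for clade in t.clades(include_root=False):
            counts[clade] = counts.get(clade, 0) + 1
    return {c: n / len(trees) for c, n in counts.items()}


def bootstrap_supports(
    repertoire: BinderRepertoire,
    n_reps: int = 1000,
    fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[Tree], dict[frozenset[str], float]]:
    """Virus-subsampled bootstrap of the UPGMA clustering.

    Each replicate draws ceil(fraction x N) viruses without replacement,
    recomputes the functional distance matrix on that subset and re-runs
    UPGMA. Returns the replicate trees and the clade frequency table
    (supports in [0, 1]).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    n_virus = len(repertoire.viruses)
    m = math.ceil(fraction * n_virus)
    if m < 1:
        raise ValueError("bootstrap subset would be empty")
    cube = jaccard_cube(repertoire)
    rng = np.random.default_rng(seed)
    trees: list[Tree] = []
    for _ in range(n_reps):
        idx = rng.choice(n_virus, size=m, replace=False)
        mat = 1.0 - cube[:, :, idx].mean(axis=2)
        np.fill_diagonal(mat, 0.0)
        dm = DistanceMatrix(names=list(repertoire.alleles), matrix=mat, n_viruses=m)
        trees.append(upgma(dm))
    return trees, clade_frequencies(trees)


def annotate_supports(tree: Tree, freqs: dict[frozenset[str], float]) -> Tree:
    """Attach bootstrap clade frequencies as supports on a tree (in place)."""
    root_set = tree.leaf_set()
    for node in tree.walk():
        if node.is_leaf:
            continue
        ls = node.leaf_set()
        node.support = 1.0 if ls == root_set else freqs.get(ls, 0.0)
    return tree


def _compatible(clade: frozenset, others: Iterable[frozenset]) -> bool:
    for o in others:
        inter = clade & o
        if inter and not (clade <= o or o <= clade):
            return False
    return True


def extended_majority_consensus(trees: Sequence[Tree]) -> Tree:
    """Extended (greedy) majority-rule consensus with clade supports.

    Clades in more than half of the trees are always included; the
    remaining clades are added in decreasing frequency (ties broken toward
    smaller then lexicographically smaller leaf sets) whenever compatible
    with everything already included. Node support is the clade frequency;
    node heights average the clade's merge heights over the trees that
    contain it.
    """
    if not trees:
        raise ValueError("no trees")
    leaf_set = trees[0].leaf_set()
    for t in trees[1:]:
        if t.leaf_set() != leaf_set:
            raise ValueError("trees have mismatched leaf sets")
    freqs = clade_frequencies(trees)

    order = sorted(
        freqs.items(), key=lambda kv: (-kv[1], len(kv[0]), tuple(sorted(kv[0])))
    )
    included: list[frozenset[str]] = []
    for clade, f in order:
        if f > 0.5 or _compatible(clade, included):
            included.append(clade)

    # mean merge height per clade over trees containing it (root included)
    def mean_height(cl: frozenset[str]) -> float:
        hs = []
        for t in trees:
            node = t.find_clade(cl)
            if node is not None:
                hs.append(node.height)
        return float(np.mean(hs)) if hs else 0.0

    # assemble the tree: nest included clades under the root (full leaf set)
    all_clades = [leaf_set] + sorted(included, key=len, reverse=True)
    node_of: dict[frozenset[str], Tree] = {}
    for cl in all_clades:
        if cl in node_of:
            continue
        node_of[cl] = Tree(
            height=mean_height(cl),
            support=1.0 if cl == leaf_set else freqs[cl],
        )
    leaf_nodes = {name: Tree(name=name, height=0.0) for name in leaf_set}

    def parent_of(item: frozenset[str]) -> frozenset[str] | None:
        best = None
        for cl in all_clades:
            if item < cl and (best is None or len(cl) < len(best)):
                best = cl
        return best

    for cl in all_clades:
        if cl == leaf_set:
            continue
        p = parent_of(cl)
        node_of[p].children.append(node_of[cl])  # type: ignore[index]
    for name in sorted(leaf_set):
        p = parent_of(frozenset((name,)))
        node_of[p].children.append(leaf_nodes[name])  # type: ignore[index]
    return node_of[leaf_set]


# ---------------------------------------------------------------------------
# Newick I/O (via scikit-bio for parsing)
# ---------------------------------------------------------------------------


_NEWICK_SPECIAL = set("(),:;'[] \t\n")


def _quote_label(name: str) -> str:
    if any(c in _NEWICK_SPECIAL for c in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _to_newick(node: Tree, parent_height: float | None) -> str:
    if node.is_leaf:
        label = _quote_label(node.name or "")
    else:
        inner = ",".join(_to_newick(c, node.height) for c in node.children)
        sup = "" if node.support is None else format(node.support, "g")
        label = f"({inner}){sup}"
    if parent_height is None:
        return label
    return f"{label}:{parent_height - node.height:.10g}"


def write_newick(tree: Tree, path: str | Path) -> None:
    """Newick with branch lengths from ultrametric heights; supports as
    internal node labels."""
    with open(path, "w") as fh:
        fh.write(_to_newick(tree, None) + ";\n")


def newick_string(tree: Tree) -> str:
    return _to_newick(tree, None) + ";"


def read_newick(path: str | Path) -> Tree:
    """Parse Newick (scikit-bio) back into a :class:`Tree`.

    Heights are reconstructed from branch lengths (leaf height 0); numeric
    internal labels become supports.
    """
    import skbio

    try:
        sk = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises format-specific parse errors
        raise ValueError(f"malformed newick in {path}: {exc}") from exc

    def convert(node) -> Tree:
        if node.is_tip():
            return Tree(name=node.name, height=0.0)
        children = [convert(c) for c in node.children]
        height = max(
            c.height + (ch.length if ch.length is not None else 0.0)
            for c, ch in zip(children, node.children)
        )
        support = None
        if node.name is not None:
            try:
                support = float(node.name)
            except ValueError:
                support = None
        return Tree(children=children, height=height, support=support)

    return convert(sk)
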