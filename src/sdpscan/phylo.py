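"""Poisson-corrected distances, neighbor joining, bootstrap, monophyly.

Distances are amino-acid substitutions per site under the Poisson
correction d = -ln(1 - p), where p is the proportion of differing sites
over columns where both sequences carry residues. Trees are built with the
Saitou-Nei neighbor-joining algorithm and are unrooted (stored with a
trifurcating seed node); bootstrap supports are fractions in [0, 1]
attached to internal edges.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .seqio import AlignedFamily, GAP

logger = logging.getLogger(__name__)


class PhyloError(ValueError):
    pass


@dataclass(frozen=True)
class DeletionPolicy:
    """Alignment-column filtering before distance computation.

    complete: keep only gapless columns; partial: keep columns with residue
    coverage >= coverage_cutoff (residual in-pair gaps are then pairwise
    deleted in the distance); pairwise: defer all deletion to the distance.
    """

    mode: str = "partial"
    coverage_cutoff: float = 0.95

    def __post_init__(self) -> None:
        if self.mode not in ("complete", "partial", "pairwise"):
            raise PhyloError(f"unknown deletion mode {self.mode!r}")
        if not 0 < self.coverage_cutoff <= 1:
            raise PhyloError("coverage_cutoff must be in (0, 1]")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise PhyloError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise PhyloError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise PhyloError("distance matrix diagonal not zero")
        if not np.all(np.isfinite(self.d)):
            raise PhyloError("distance matrix contains non-finite entries")

    def to_phylip(self) -> str:
        out = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.d):
            out.append(lab + "  " + "  ".join(f"{v:.6f}" for v in row))
        return "\n".join(out) + "\n"


class PhyloTree:
    """Unrooted tree with branch lengths (subs/site) and edge supports.

    Thin wrapper over a dendropy tree; supports are stored as internal-node
    labels on newick output (MEGA convention).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def leaf_labels(self) -> set[str]:
        return {lf.taxon.label for lf in self._tree.leaf_node_iter()}

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".6g",
        )
        return s.strip() + "\n"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions, each canonicalized to the side not
        containing the alphabetically first leaf."""
        leaves = self.leaf_labels()
        anchor = min(leaves)
        out: set[frozenset[str]] = set()
        for node in self._tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            if anchor in side:
                side = frozenset(leaves - side)
            if 2 <= len(side) <= len(leaves) - 2:
                out.add(side)
        return out

    def path_distance(self, a: str, b: str) -> float:
        pdm = self._tree.phylogenetic_distance_matrix()
        ta = self._tree.taxon_namespace.get_taxon(a)
        tb = self._tree.taxon_namespace.get_taxon(b)
        return pdm.distance(ta, tb)

    def robinson_foulds(self, other: "PhyloTree") -> int:
        if self.leaf_labels() != other.leaf_labels():
            raise PhyloError("trees have different leaf sets")
        s1, s2 = self.splits(), other.splits()
        return len(s1 ^ s2)


# ------------------------------------------------------------------ filtering


def filter_columns(family: AlignedFamily, policy: DeletionPolicy) -> AlignedFamily:
    if policy.mode == "pairwise":
        return family
    n = len(family.records)
    keep: list[int] = []
    for col in range(1, family.ncols + 1):
        column = family.column(col)
        cov = sum(1 for ch in column if ch != GAP) / n
        if policy.mode == "complete":
            if cov == 1.0:
                keep.append(col)
        else:
            if cov >= policy.coverage_cutoff:
                keep.append(col)
    if not keep:
        raise PhyloError(f"{policy.mode} deletion removed every column")
    return family.with_columns(keep)


# ------------------------------------------------------------------ distances


def poisson_distance(
    a: str, b: str, cap_saturation: bool = False
) -> float:
    """Poisson-corrected distance -ln(1-p) over columns where both a and b
    carry residues."""
    if len(a) != len(b):
        raise PhyloError("aligned strings differ in length")
    compared = differing = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x != y:
            differing += 1
    if compared == 0:
        raise PhyloError("no comparable columns between sequences")
    p = differing / compared
    if p >= 1.0:
        if cap_saturation:
            d_max = -math.log(1.0 / compared)
            warnings.warn(
                f"saturated pair (p=1); capping distance at {d_max:.4f}",
                stacklevel=2,
            )
            return d_max
        raise PhyloError("saturated pair (p=1); Poisson correction undefined")
    return -math.log(1.0 - p)


def distance_matrix(
    family: AlignedFamily,
    policy: DeletionPolicy | None = None,
    cap_saturation: bool = False,
) -> DistanceMatrix:
    if len(family.records) < 3:
        raise PhyloError("need >= 3 sequences for a distance matrix")
    policy = policy or DeletionPolicy()
    fam = filter_columns(family, policy)
    labels = fam.ids
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = poisson_distance(
                    fam.records[i][1], fam.records[j][1], cap_saturation
                )
            except PhyloError as e:
                raise PhyloError(
                    f"pair ({labels[i]}, {labels[j]}): {e}"
                ) from e
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------- neighbor joining


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei NJ. Ties in the Q criterion are broken by the
    lexicographically smallest (label_i, label_j) pair; negative branch
    lengths are clamped to zero with the deficit moved to the sibling
    branch (path lengths preserved)."""
    n = len(D.labels)
    if n < 3:
        raise PhyloError("neighbor joining needs >= 3 taxa")

    tns = dendropy.TaxonNamespace(sorted(D.labels))
    nodes: list[dendropy.Node] = []
    for lab in D.labels:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(lab)
        nodes.append(nd)
    labels = list(D.labels)
    d = D.d.copy()

    def clamp_pair(vi: float, vj: float) -> tuple[float, float]:
        if vi < 0:
            logger.info("clamping negative branch %.4g to 0", vi)
            vj += vi
            vi = 0.0
        if vj < 0:
            logger.info("clamping negative branch %.4g to 0", vj)
            vi += vj
            vj = 0.0
        return max(vi, 0.0), max(vj, 0.0)

    while len(labels) > 3:
        m = len(labels)
        r = d.sum(axis=1)
        best = None
        best_q = math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((labels[i], labels[j])))
                if q < best_q or (q == best_q and key < best[2]):
                    best_q = q
                    best = (i, j, key)
        i, j, _ = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        vi, vj = clamp_pair(vi, vj)
        parent = dendropy.Node()
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node to the rest
        dnew = 0.5 * (d[:, i] + d[:, j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep]])
        lastcol = np.append(dnew[keep], 0.0)
        d = np.column_stack([d, lastcol])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [f"({labels[i]},{labels[j]})"]

    # resolve the final three around a trifurcating root:
    # v_i = (d_ij + d_ik - d_jk) / 2
    root = dendropy.Node()
    v0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    v1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    v2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for nd, v in zip(nodes, (v0, v1, v2)):
        if v < 0:
            logger.info("clamping negative terminal branch %.4g to 0", v)
            v = 0.0
        nd.edge.length = v
        root.add_child(nd)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return PhyloTree(tree)


# ----------------------------------------------------------------- bootstrap


def bootstrap_support(
    family: AlignedFamily,
    policy: DeletionPolicy | None = None,
    n_reps: int = 500,
    seed: int = 0,
) -> PhyloTree:
    """Point-estimate NJ tree with bootstrap supports on internal edges.

    Columns of the post-filter alignment are resampled with replacement;
    each replicate tree is built with identical settings. Support is the
    fraction of usable replicates containing the same leaf bipartition.
    Replicates with saturated distances are skipped (denominator adjusted);
    more than 20% skipped is an error.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    policy = policy or DeletionPolicy()
    fam = filter_columns(family, policy)
    point = neighbor_joining(
        distance_matrix(fam, DeletionPolicy(mode="pairwise"))
    )
    rng = np.random.default_rng(seed)
    ncols = fam.ncols
    split_counts: dict[frozenset[str], int] = {s: 0 for s in point.splits()}
    used = skipped = 0
    for _ in range(n_reps):
        cols = (rng.integers(0, ncols, size=ncols) + 1).tolist()
        rep_fam = fam.with_columns(cols)
        try:
            rep_tree = neighbor_joining(
                distance_matrix(rep_fam, DeletionPolicy(mode="pairwise"))
            )
        except PhyloError:
            warnings.warn("bootstrap replicate skipped (saturated distance)",
                          stacklevel=2)
            skipped += 1
            continue
        used += 1
        rep_splits = rep_tree.splits()
        for s in split_counts:
            if s in rep_splits:
                split_counts[s] += 1
    if skipped > 0.2 * n_reps:
        raise PhyloError(
            f"{skipped}/{n_reps} bootstrap replicates skipped; data too saturated"
        )
    if used == 0:
        raise PhyloError("no usable bootstrap replicates")

    leaves = point.leaf_labels()
    anchor = min(leaves)
    for node in point.dendropy_tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = frozenset(leaves - side)
        if side in split_counts:
            node.label = f"{split_counts[side] / used:.6g}"
    return point


def get_supports(tree: PhyloTree) -> dict[frozenset[str], float]:
    """Map each supported internal-edge bipartition to its support fraction."""
    leaves = tree.leaf_labels()
    anchor = min(leaves)
    out: dict[frozenset[str], float] = {}
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None or node.label is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = frozenset(leaves - side)
        out[side] = float(node.label)
    return out


# ----------------------------------------------------------------- monophyly


def is_monophyletic(tree: PhyloTree, id_set: set[str]) -> bool:
    """True iff some edge bipartition separates exactly id_set from the rest."""
    leaves = tree.leaf_labels()
    unknown = set(id_set) - leaves
    if unknown:
        raise PhyloError(f"unknown leaf ids: {sorted(unknown)}")
    ids = frozenset(id_set)
    if len(ids) in (0,):
        raise PhyloError("empty id set")
    if len(ids) == 1 or len(ids) == len(leaves):
        return True
    comp = frozenset(leaves - ids)
    anchor = min(leaves)
    canon = comp if anchor in ids else ids
    if len(ids) == len(leaves) - 1:
        return True  # complement is a single leaf: always an edge
    return canon in tree.splits()
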