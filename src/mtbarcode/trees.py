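"""Neighbor-joining trees, outgroup rooting, and monophyly-based statistics.

The species-recovery statistic counts a "barcode species" whenever all
conspecific sequences form a monophyletic cluster in the rooted NJ tree, and
a genus-level "cohesive group" whenever all congeneric sequences (from >=2
species) do.  Failures are classified as paraphyletic (the intruding leaves
themselves form a nested clade) or polyphyletic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "PhyloTree",
    "RecoveryReport",
    "neighbor_joining",
    "root_with_outgroup",
    "is_monophyletic",
    "recovery_summary",
]


class Node:
    """Tree node; ``length`` is the branch to the parent (substitutions/site)."""

    __slots__ = ("label", "length", "children", "parent", "height")

    def __init__(self, label=None, length=None, children=None):
        self.label = label
        self.length = length
        self.children = list(children) if children else []
        self.parent = None
        self.height = None  # used by the simulator's ultrametric scaffold
        for c in self.children:
            c.parent = self

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


class PhyloTree:
    """A phylogenetic tree with branch lengths and unique leaf labels."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        labels = [l.label for l in root.leaves()]
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")

    # -- traversal helpers -------------------------------------------------
    def leaves(self):
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        return [l.label for l in self.leaves()]

    def postorder(self):
        return self.root.postorder()

    def clade_leafsets(self) -> dict[Node, frozenset]:
        """Leaf-label set of every node, computed in one postorder pass."""
        sets: dict[Node, frozenset] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                sets[node] = frozenset([node.label])
            else:
                s = frozenset()
                for c in node.children:
                    s |= sets[c]
                sets[node] = s
        return sets

    def prune(self, keep: set[str]) -> "PhyloTree":
        """Tree restricted to ``keep`` leaves, degree-2 nodes spliced out."""
        tree = self.copy()
        changed = True
        while changed:
            changed = False
            for node in list(tree.root.postorder()):
                if node.is_leaf and node.label not in keep and node.parent:
                    node.parent.remove_child(node)
                    changed = True
                elif (
                    not node.is_leaf
                    and len(node.children) == 1
                    and node.parent is not None
                ):
                    _splice(node)
                    changed = True
            while len(tree.root.children) == 1:
                child = tree.root.children[0]
                child.parent = None
                child.length = None
                tree.root = child
        return tree

    def copy(self) -> "PhyloTree":
        def rec(n):
            m = Node(n.label, n.length)
            m.height = n.height
            for c in n.children:
                m.add_child(rec(c))
            return m

        return PhyloTree(rec(self.root), rooted=self.rooted)

    def leaf_distance_matrix(self) -> DistanceMatrix:
        """Path-length (patristic) distances between all leaves."""
        labels = self.leaf_labels()
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        vals = np.zeros((n, n))
        below: dict[Node, dict[str, float]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                below[node] = {node.label: 0.0}
                continue
            merged: dict[str, float] = {}
            for c in node.children:
                d = {l: v + (c.length or 0.0) for l, v in below[c].items()}
                for la, va in merged.items():
                    for lb, vb in d.items():
                        vals[idx[la], idx[lb]] = vals[idx[lb], idx[la]] = va + vb
                merged.update(d)
            below[node] = merged
        return DistanceMatrix(labels, vals, "patristic")

    # -- newick I/O --------------------------------------------------------
    def to_newick(self, clamp_negative: bool = False) -> str:
        def rec(n):
            if n.is_leaf:
                s = _quote(n.label)
            else:
                s = "(" + ",".join(rec(c) for c in n.children) + ")"
            if n.length is not None:
                bl = max(n.length, 0.0) if clamp_negative else n.length
                s += f":{bl:.10g}"
            return s

        return rec(self.root) + ";"

    def write_newick(self, path, **kw) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kw) + "\n")

    @classmethod
    def from_newick(cls, newick: str, rooted: bool = True) -> "PhyloTree":
        import dendropy

        dt = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )

        def rec(dn):
            label = dn.taxon.label if dn.taxon else dn.label
            n = Node(label, dn.edge.length)
            for dc in dn.child_nodes():
                n.add_child(rec(dc))
            return n

        return cls(rec(dt.seed_node), rooted=rooted)

    @classmethod
    def read_newick(cls, path, **kw) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read(), **kw)


def _splice(node: Node) -> None:
    """Remove a degree-2 internal node, merging branch lengths."""
    (child,) = node.children
    parent = node.parent
    child.length = (child.length or 0.0) + (node.length or 0.0)
    node.remove_child(child)
    parent.remove_child(node)
    parent.add_child(child)


def neighbor_joining(dm: DistanceMatrix, saturation_cap: float = 5.0) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Iteratively joins the pair minimising
    Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k); ties are broken by
    the lowest (row, column) index pair.  Undefined (nan) input entries are
    replaced by ``saturation_cap`` to keep the algorithm total.  Output is
    unrooted with a trifurcating placeholder root.
    """
    D = dm.capped(saturation_cap)
    n = D.shape[0]
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix must be non-negative")

    D = D.astype(float).copy()
    nodes = [Node(label) for label in dm.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, 1)
        flat = np.full((m, m), np.inf)
        flat[iu] = Q[iu]
        i, j = np.unravel_index(np.argmin(flat), flat.shape)  # row-major: lowest (i,j) on ties
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = D[i, j] - vi
        new = Node()
        nodes[i].length = vi
        nodes[j].length = vj
        new.add_child(nodes[i])
        new.add_child(nodes[j])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep][None, :]])
        last = np.append(dnew[keep], 0.0)
        D = np.hstack([D, last[:, None]])
        nodes = [nodes[k] for k in keep] + [new]

    # Final three: closed-form three-point branch lengths on a trifurcation.
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = 0.5 * (dab + dac - dbc)
    b.length = 0.5 * (dab + dbc - dac)
    c.length = 0.5 * (dac + dbc - dab)
    root = Node(children=[a, b, c])
    return PhyloTree(root, rooted=False)


def _reroot_at_edge(tree: PhyloTree, child: Node, fraction: float = 0.5) -> PhyloTree:
    """Root on the edge above ``child``, placing the root ``fraction`` of the
    branch length toward ``child``."""
    tree = tree.copy()
    # Re-locate the corresponding node in the copy by path from root.
    path = []
    node = child
    while node.parent is not None:
        path.append(node.parent.children.index(node))
        node = node.parent
    node = tree.root
    for i in reversed(path):
        node = node.children[i]
    child = node

    old_parent = child.parent
    length = child.length or 0.0
    old_parent.remove_child(child)
    new_root = Node()
    child.length = length * fraction
    new_root.add_child(child)

    # Reverse the edges on the path from old_parent up to the old root.
    chain = []
    node = old_parent
    while node is not None:
        chain.append(node)
        node = node.parent
    lengths = [n.length for n in chain]  # edge above chain[k] links it to chain[k+1]
    for k in range(len(chain) - 1):
        chain[k + 1].remove_child(chain[k])
    new_root.add_child(chain[0])
    chain[0].length = length * (1.0 - fraction)
    for k in range(1, len(chain)):
        chain[k - 1].add_child(chain[k])
        chain[k].length = lengths[k - 1]

    # The old root may be left with a single child: splice it out.
    for n in list(new_root.postorder()):
        if not n.is_leaf and len(n.children) == 1 and n.parent is not None:
            _splice(n)
    return PhyloTree(new_root, rooted=True)


def root_with_outgroup(tree: PhyloTree, outgroup: set[str]) -> PhyloTree:
    """Root the tree on the edge separating the outgroup from the ingroup.

    When the outgroup is not monophyletic in the unrooted tree, the edge
    maximising outgroup purity (leaves classified correctly by the split) is
    used instead and a warning is logged.
    """
    outgroup = set(outgroup)
    all_labels = set(tree.leaf_labels())
    if not outgroup <= all_labels:
        raise ValueError(f"outgroup labels missing from tree: {outgroup - all_labels}")
    if not outgroup:
        raise ValueError("empty outgroup")

    leafsets = tree.clade_leafsets()
    best, best_score = None, -1
    exact = None
    for node, ls in leafsets.items():
        if node.parent is None:
            continue
        if ls == outgroup or (all_labels - ls) == outgroup:
            exact = node
            break
        # Purity: fraction of leaves classified correctly taking the child
        # side as the outgroup side (or its complement, whichever is better).
        score = max(
            len(ls & outgroup) + len((all_labels - ls) - outgroup),
            len(ls - outgroup) + len((all_labels - ls) & outgroup),
        )
        if score > best_score:
            best, best_score = node, score
    if exact is None:
        logger.warning(
            "outgroup not monophyletic in unrooted tree; rooting on the "
            "edge with best purity %d/%d", best_score, len(all_labels)
        )
        exact = best
    return _reroot_at_edge(tree, exact)


def is_monophyletic(tree: PhyloTree, labels) -> str:
    """Classify a leaf-label set as monophyletic / paraphyletic / polyphyletic.

    The smallest clade containing all labels is located on the rooted tree;
    the set is monophyletic when that clade contains no other leaf,
    paraphyletic when the extra leaves themselves form a clade, and
    polyphyletic otherwise.
    """
    labels = frozenset(labels)
    if len(labels) < 2:
        raise ValueError("need at least two leaves to assess monophyly")
    leafsets = tree.clade_leafsets()
    all_leaves = leafsets[tree.root]
    if not labels <= all_leaves:
        raise ValueError(f"labels not in tree: {set(labels) - set(all_leaves)}")

    mrca_set = min(
        (ls for ls in leafsets.values() if labels <= ls), key=len
    )
    extra = mrca_set - labels
    if not extra:
        return "monophyletic"
    clades = set(leafsets.values())
    return "paraphyletic" if extra in clades else "polyphyletic"


@dataclass
class RecoveryReport:
    """Per-profile counts of recovered barcode species and cohesive groups."""

    profile: str
    species_evaluated: int
    barcode_species: int
    genera_evaluated: int
    cohesive_groups: int
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def recovery_rate(self) -> float:
        """Percent of evaluated species recovered as monophyletic."""
        if self.species_evaluated == 0:
            return float("nan")
        return 100.0 * self.barcode_species / self.species_evaluated

    @property
    def cohesive_rate(self) -> float:
        """Percent of evaluated genera forming cohesive groups."""
        if self.genera_evaluated == 0:
            return float("nan")
        return 100.0 * self.cohesive_groups / self.genera_evaluated


def recovery_summary(
    tree: PhyloTree,
    taxonomy: dict[str, tuple],
    outgroup: set[str] = frozenset(),
    profile_name: str = "",
    include_singletons: bool = False,
) -> RecoveryReport:
    """Barcode-species and cohesive-group counts on a rooted NJ tree.

    ``taxonomy`` maps accession -> (species, genus, superorder).  Species
    with >=2 sequences are evaluated as barcode-species candidates; genera
    whose sequences represent >=2 species are evaluated as cohesive-group
    candidates.  ``include_singletons=True`` adds single-sequence species to
    the species denominator (counted as trivially recovered).
    """
    if not tree.rooted:
        raise ValueError("recovery summary requires a rooted tree")
    ingroup = [l for l in tree.leaf_labels() if l not in outgroup]
    missing = [l for l in ingroup if l not in taxonomy]
    if missing:
        raise ValueError(f"taxonomy missing for leaves: {missing[:5]}")

    by_species: dict[str, list[str]] = {}
    by_genus: dict[str, list[str]] = {}
    genus_species: dict[str, set[str]] = {}
    for acc in ingroup:
        sp, gen = taxonomy[acc][0], taxonomy[acc][1]
        by_species.setdefault(sp, []).append(acc)
        by_genus.setdefault(gen, []).append(acc)
        genus_species.setdefault(gen, set()).add(sp)

    failures = []
    species_eval = barcode = 0
    for sp, accs in sorted(by_species.items()):
        if len(accs) < 2:
            if include_singletons:
                species_eval += 1
                barcode += 1
            continue
        species_eval += 1
        status = is_monophyletic(tree, accs)
        if status == "monophyletic":
            barcode += 1
        else:
            failures.append((sp, status))

    genera_eval = cohesive = 0
    for gen, accs in sorted(by_genus.items()):
        if len(genus_species[gen]) < 2:
            continue
        genera_eval += 1
        if len(accs) < 2:
            continue
        status = is_monophyletic(tree, accs)
        if status == "monophyletic":
            cohesive += 1
        else:
            failures.append((gen, status))

    return RecoveryReport(
        profile=profile_name,
        species_evaluated=species_eval,
        barcode_species=barcode,
        genera_evaluated=genera_eval,
        cohesive_groups=cohesive,
        failures=failures,
    )
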