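"""Time-calibrated trees with possibly non-contemporaneous (fossil) tips.

A :class:`Chronogram` wraps a rooted, strictly bifurcating ``dendropy.Tree``
whose branch lengths are in Ma.  Node ages are measured before present: the
root carries the oldest age (the maximum root-to-tip path length), extant tips
sit at age 0, and tips whose path falls short of the longest one are extinct
tips with positive age.  Newick I/O goes through dendropy; bracketed
annotations are rejected rather than silently dropped so that a chronogram
written by this package re-parses to the identical object.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "Chronogram",
    "LttCurve",
    "read_newick",
    "read_newick_list",
    "write_newick",
    "graft_fossil_tip",
    "prune_tip",
    "ltt",
]

#: ages within this tolerance of zero are treated as the present
AGE_TOL = 1e-9
#: zero-length terminal branches are permitted down to this tolerance
LENGTH_TOL = 1e-12


class NewickError(ValueError):
    """Malformed or unsupported Newick input."""


class Chronogram:
    """A rooted binary chronogram with derived node ages.

    Construction validates the topology (exactly two children per internal
    node), requires a branch length on every non-root edge, and derives ages
    from the root height.  Instances are treated as immutable: tree surgery
    (:func:`graft_fossil_tip`, :func:`prune_tip`) returns new objects.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._ids: dict[str, dendropy.Node] = {}
        self._ages: dict[dendropy.Node, float] = {}
        self._validate_and_index()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Chronogram":
        pos = newick.find("[")
        if pos != -1:
            raise NewickError(
                f"bracketed annotation at character {pos} is not supported; "
                "strip comments/annotations before loading"
            )
        if ";" not in newick:
            raise NewickError(
                f"missing ';' terminator at character {len(newick.rstrip())}"
            )
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                rooting="force-rooted",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several DataError subclasses
            col = getattr(exc, "column", None)
            where = f" near character {col}" if col is not None else ""
            raise NewickError(f"malformed Newick{where}: {exc}") from exc
        return cls(tree)

    def _validate_and_index(self) -> None:
        seen: set[str] = set()
        counter = 0
        for node in self._tree.preorder_node_iter():
            nch = len(node.child_nodes())
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise NewickError("every tip must carry a label")
                label = node.taxon.label
            else:
                if nch != 2:
                    raise NewickError(
                        f"internal node with {nch} children; only strictly "
                        "bifurcating trees are supported"
                    )
                label = node.label or f"N{counter}"
                counter += 1
            if label in seen:
                raise NewickError(f"duplicate node label {label!r}")
            seen.add(label)
            node._cg_id = label  # type: ignore[attr-defined]
            self._ids[label] = node

        root = self._tree.seed_node
        depth: dict[dendropy.Node, float] = {root: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise NewickError(
                    f"missing branch length on the edge above {node._cg_id!r}"
                )
            if node.edge.length < -LENGTH_TOL:
                raise NewickError(
                    f"negative branch length on the edge above {node._cg_id!r}"
                )
            depth[node] = depth[node.parent_node] + max(node.edge.length, 0.0)
        height = max(depth[leaf] for leaf in self._tree.leaf_node_iter())
        if height <= 0:
            raise NewickError("root age must be positive (all branch lengths zero?)")
        for node, d in depth.items():
            age = height - d
            self._ages[node] = 0.0 if abs(age) < AGE_TOL else age

    # -- accessors ----------------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def root_age(self) -> float:
        return self._ages[self.root]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(n._cg_id for n in self._tree.leaf_node_iter())

    def node_ids(self) -> tuple[str, ...]:
        return tuple(n._cg_id for n in self._tree.preorder_node_iter())

    def node(self, node_id: str) -> dendropy.Node:
        try:
            return self._ids[node_id]
        except KeyError:
            raise KeyError(f"no node with id {node_id!r}") from None

    def id_of(self, node: dendropy.Node) -> str:
        return node._cg_id

    def age(self, node) -> float:
        """Age in Ma of a node (given as node object or id string)."""
        if isinstance(node, str):
            node = self.node(node)
        return self._ages[node]

    def extinct_tips(self) -> tuple[str, ...]:
        return tuple(
            n._cg_id for n in self._tree.leaf_node_iter() if self._ages[n] > AGE_TOL
        )

    def postorder(self):
        return self._tree.postorder_node_iter()

    def preorder(self):
        return self._tree.preorder_node_iter()

    # -- output -------------------------------------------------------------

    def to_newick(self) -> str:
        out = io.StringIO()
        self._write_node(self.root, out)
        out.write(";")
        return out.getvalue()

    def _write_node(self, node: dendropy.Node, out: io.StringIO) -> None:
        # plain-label dialect: tips only, 17 significant digits on lengths
        if node.is_leaf():
            out.write(node._cg_id)
        else:
            out.write("(")
            for i, child in enumerate(node.child_nodes()):
                if i:
                    out.write(",")
                self._write_node(child, out)
            out.write(")")
        if node.parent_node is not None:
            out.write(f":{node.edge.length:.17g}")

    def copy(self) -> "Chronogram":
        return Chronogram.from_newick(self.to_newick())


def read_newick(path) -> Chronogram:
    """Read the first tree of a Newick file as a :class:`Chronogram`."""
    with open(path) as fh:
        text = fh.read()
    trees = _split_newick(text)
    if not trees:
        raise NewickError(f"no tree found in {path}")
    return Chronogram.from_newick(trees[0])


def read_newick_list(path) -> list[Chronogram]:
    """Read every tree of a (possibly multi-tree) Newick file."""
    with open(path) as fh:
        text = fh.read()
    trees = _split_newick(text)
    if not trees:
        raise NewickError(f"no tree found in {path}")
    return [Chronogram.from_newick(t) for t in trees]


def _split_newick(text: str) -> list[str]:
    chunks = [c.strip() for c in text.split(";")]
    return [c + ";" for c in chunks if c]


def write_newick(chrono: Chronogram | list[Chronogram], path) -> None:
    items = chrono if isinstance(chrono, list) else [chrono]
    with open(path, "w") as fh:
        for c in items:
            fh.write(c.to_newick() + "\n")


# -- tree surgery -----------------------------------------------------------


def graft_fossil_tip(
    chrono: Chronogram,
    attachment: str,
    tip_age: float,
    divergence_age: float,
    label: str,
) -> Chronogram:
    """Attach a dated tip (typically a fossil) onto an existing edge.

    ``attachment`` names the node *below* the attachment edge; naming the root
    attaches on the root stem, creating a new, older root.  The new internal
    node sits at ``divergence_age``, which must fall strictly inside the
    attachment edge's age interval, and the fossil tip at ``tip_age`` below it.
    All pre-existing node ages are preserved.
    """
    if label in chrono.node_ids():
        raise ValueError(f"duplicate tip label {label!r}")
    if not 0 <= tip_age < divergence_age:
        raise ValueError(
            f"need 0 <= tip_age < divergence_age, got tip_age={tip_age}, "
            f"divergence_age={divergence_age}"
        )
    node = chrono.node(attachment)  # validates the reference
    node_age = chrono.age(node)
    if node.parent_node is None:
        if divergence_age <= node_age:
            raise ValueError(
                f"root-stem attachment requires divergence_age > root age "
                f"({node_age:g} Ma), got {divergence_age:g}"
            )
    else:
        parent_age = chrono.age(node.parent_node)
        if not node_age < divergence_age < parent_age:
            raise ValueError(
                f"divergence_age {divergence_age:g} outside the attachment edge "
                f"interval ({node_age:g}, {parent_age:g}) Ma"
            )

    work = dendropy.Tree(chrono.tree)  # deep copy, same traversal order
    target = None
    for orig, copy_node in zip(chrono.preorder(), work.preorder_node_iter()):
        if orig is node:
            target = copy_node
            break
    assert target is not None

    ns = work.taxon_namespace
    fossil = dendropy.Node(edge_length=divergence_age - tip_age)
    fossil.taxon = ns.new_taxon(label=label)

    if target.parent_node is None:
        new_root = dendropy.Node()
        target.edge.length = divergence_age - node_age
        new_root.add_child(target)
        new_root.add_child(fossil)
        work.seed_node = new_root
    else:
        parent = target.parent_node
        parent_age = chrono.age(node.parent_node)
        idx = parent.child_nodes().index(target)
        siblings = parent.child_nodes()
        for ch in siblings:
            parent.remove_child(ch)
        joint = dendropy.Node(edge_length=parent_age - divergence_age)
        target.edge.length = divergence_age - node_age
        joint.add_child(target)
        joint.add_child(fossil)
        for i, ch in enumerate(siblings):
            parent.add_child(joint if i == idx else ch)
    return Chronogram(work)


def prune_tip(chrono: Chronogram, label: str) -> Chronogram:
    """Remove one tip and suppress the resulting unifurcation (inverse of grafting)."""
    node = chrono.node(label)
    if not node.is_leaf():
        raise ValueError(f"{label!r} is not a tip")
    if chrono.n_tips <= 2:
        raise ValueError("cannot prune below two tips")
    work = dendropy.Tree(chrono.tree)
    target = None
    for orig, copy_node in zip(chrono.preorder(), work.preorder_node_iter()):
        if orig is node:
            target = copy_node
            break
    parent = target.parent_node
    parent.remove_child(target)
    (sib,) = parent.child_nodes()
    grand = parent.parent_node
    if grand is None:
        sib.edge.length = None
        sib.parent_node = None
        work.seed_node = sib
    else:
        sib.edge.length = sib.edge.length + parent.edge.length
        idx = grand.child_nodes().index(parent)
        siblings = grand.child_nodes()
        for ch in siblings:
            grand.remove_child(ch)
        for i, ch in enumerate(siblings):
            grand.add_child(sib if i == idx else ch)
    return Chronogram(work)


# -- lineage-through-time ---------------------------------------------------


@dataclass(frozen=True)
class LttCurve:
    """Step function of reconstructed lineage counts against age.

    ``breakpoints`` descend from the root age to 0; ``counts[i]`` is the number
    of lineages in the age interval ``(breakpoints[i+1], breakpoints[i]]``.
    With extinct tips in the tree, counts may decrease toward the present.
    """

    breakpoints: np.ndarray
    counts: np.ndarray

    @property
    def final_count(self) -> int:
        return int(self.counts[-1])

    def count_at(self, age: float) -> int:
        """Lineage count in the interval containing ``age``."""
        bp = self.breakpoints
        if age > bp[0] or age < bp[-1]:
            raise ValueError(f"age {age} outside curve range ({bp[-1]}, {bp[0]}]")
        i = int(np.searchsorted(-bp, -age, side="right"))
        return int(self.counts[max(0, min(i - 1, len(self.counts) - 1))])

    def rows(self):
        """Yield (age_start, age_end, count) TSV rows, oldest first."""
        for i, c in enumerate(self.counts):
            yield float(self.breakpoints[i]), float(self.breakpoints[i + 1]), int(c)


def ltt(trees: Chronogram | list[Chronogram]):
    """Lineage-through-time curve(s) for one chronogram or a list of them."""
    if isinstance(trees, list):
        return [ltt(t) for t in trees]
    chrono = trees
    deltas: dict[float, int] = {}
    for node in chrono.preorder():
        age = chrono.age(node)
        if not node.is_leaf():
            # a bifurcation adds one lineage going toward the present
            deltas[age] = deltas.get(age, 0) + 1
        elif age > AGE_TOL:
            # an extinct tip removes one
            deltas[age] = deltas.get(age, 0) - 1
    ages = sorted(deltas, reverse=True)
    root_age = chrono.root_age
    breakpoints = [root_age]
    counts = []
    running = 1
    prev = 1
    for a in ages:
        running += deltas[a]
        if AGE_TOL < a < root_age:
            breakpoints.append(a)
            counts.append(prev)  # count in the interval just ended
        prev = running
    breakpoints.append(0.0)
    counts.append(running)
    return LttCurve(np.asarray(breakpoints, dtype=float), np.asarray(counts, dtype=int))
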