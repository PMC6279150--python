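"""Reading, writing, rooting, and decomposing support-annotated phylogenetic trees.

Trees are represented as :class:`dendropy.Tree` objects with one extra
convention: every internal node may carry an integer bootstrap support in
percent (0–100), stored on the node as the attribute ``support``.  Numeric
internal-node labels in Newick input are interpreted as supports; on output
supports are emitted back as internal-node labels (the convention of the
common ML programs).  Branch supports are conceptually properties of the
*unrooted bipartition* under an edge, so rerooting re-derives them from a
split→support map rather than trusting node labels to travel correctly.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "OutgroupError",
    "Split",
    "parse_newick",
    "write_newick",
    "read_newick",
    "read_nexus_trees",
    "leaf_labels",
    "get_support",
    "set_support",
    "is_rooted",
    "root_with_outgroup",
    "splits",
    "split_support_map",
    "canonical_side",
]


class NewickParseError(ValueError):
    """Malformed Newick/NEXUS input."""


class TreeValidationError(ValueError):
    """Tree violates an invariant (duplicate leaves, bad support, negative length)."""


class OutgroupError(ValueError):
    """Requested outgroup is absent or not a clade in any rooting."""


@dataclass(frozen=True)
class Split:
    """A bipartition of a taxon set, canonically oriented.

    ``side_a`` always contains the lexicographically smallest taxon, so two
    splits over the same taxon set compare equal iff they induce the same
    bipartition.  ``frequency`` (a fraction in (0, 1] or a support percent,
    depending on provenance) is carried along but excluded from equality.
    """

    side_a: frozenset
    side_b: frozenset
    frequency: float | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.side_a & self.side_b:
            raise TreeValidationError("split sides are not disjoint")
        if not self.side_a or not self.side_b:
            raise TreeValidationError("split sides must be nonempty")
        if min(self.side_b) < min(self.side_a):
            a, b = self.side_b, self.side_a
            object.__setattr__(self, "side_a", a)
            object.__setattr__(self, "side_b", b)

    @property
    def taxa(self) -> frozenset:
        return self.side_a | self.side_b

    def is_trivial(self) -> bool:
        return len(self.side_a) < 2 or len(self.side_b) < 2

    def with_frequency(self, freq: float) -> "Split":
        return Split(self.side_a, self.side_b, freq)

    def __repr__(self):  # pragma: no cover - cosmetic
        a = ",".join(sorted(self.side_a))
        b = ",".join(sorted(self.side_b))
        f = "" if self.frequency is None else f" [{self.frequency:g}]"
        return f"Split({a} | {b}{f})"


def canonical_side(side, all_taxa) -> frozenset:
    """Return the side of the bipartition that contains the smallest taxon."""
    side = frozenset(side)
    if min(all_taxa) in side:
        return side
    return frozenset(all_taxa) - side


# ---------------------------------------------------------------------------
# support handling


def get_support(node) -> int | None:
    """Bootstrap percent on the edge subtending ``node``, or None."""
    return getattr(node, "support", None)


def set_support(node, value) -> None:
    if value is not None:
        value = int(round(value))
        if not 0 <= value <= 100:
            raise TreeValidationError(f"support {value} outside [0, 100]")
    node.support = value


def _interpret_label_supports(tree: dendropy.Tree, support_scale: str) -> None:
    """Convert numeric internal-node labels to integer percent supports.

    ``support_scale``: "percent" (labels already 0–100), "fraction" (labels in
    [0,1], multiplied by 100), or "auto" (fraction dialect assumed iff every
    numeric label is ≤ 1 and at least one carries a decimal point).
    """
    numeric: list[tuple[dendropy.Node, float, str]] = []
    for nd in tree.preorder_node_iter():
        nd.support = None
        if nd.is_leaf() or nd.label is None:
            continue
        try:
            val = float(nd.label)
        except ValueError:
            continue
        numeric.append((nd, val, nd.label))
    if not numeric:
        return
    scale = support_scale
    if scale == "auto":
        if all(v <= 1.0 for _, v, _ in numeric) and any(
            "." in raw for _, _, raw in numeric
        ):
            scale = "fraction"
        else:
            scale = "percent"
    for nd, val, _ in numeric:
        if scale == "fraction":
            val *= 100.0
        if not 0 <= val <= 100:
            raise TreeValidationError(
                f"support value {val} outside [0, 100] (scale={support_scale})"
            )
        nd.support = int(round(val))
        nd.label = None


def _validate(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    seen = set()
    for lab in labels:
        if lab in seen:
            raise TreeValidationError(f"duplicate leaf label: {lab!r}")
        seen.add(lab)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeValidationError(f"negative branch length {edge.length}")
    return tree


# ---------------------------------------------------------------------------
# parse / write


def parse_newick(text: str, support_scale: str = "auto") -> dendropy.Tree:
    """Parse one Newick tree; numeric internal labels become supports."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"Newick parse failed: {exc}") from exc
    _interpret_label_supports(tree, support_scale)
    return _validate(tree)


def read_newick(path, support_scale: str = "auto") -> list:
    """Read all trees from a (possibly multi-tree) Newick file."""
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    trees = []
    buf = []
    depth = 0
    for ch in text:
        buf.append(ch)
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == ";" and depth == 0:
            chunk = "".join(buf).strip()
            if chunk and chunk != ";":
                trees.append(parse_newick(chunk, support_scale))
            buf = []
    return trees


def read_nexus_trees(path, support_scale: str = "auto") -> list:
    """Read the TREES block of a NEXUS file (translate table honored)."""
    try:
        tl = dendropy.TreeList.get(
            path=str(path),
            schema="nexus",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickParseError(f"NEXUS parse failed: {exc}") from exc
    out = []
    for tree in tl:
        _interpret_label_supports(tree, support_scale)
        out.append(_validate(tree))
    return out


def _fmt_length(length, precision: int) -> str:
    if length is None:
        return ""
    return f":{length:.{precision}f}"


def _write_node(node, precision: int, out: io.StringIO) -> None:
    if node.is_leaf():
        out.write(node.taxon.label)
    else:
        out.write("(")
        for i, ch in enumerate(node.child_nodes()):
            if i:
                out.write(",")
            _write_node(ch, precision, out)
        out.write(")")
        sup = get_support(node)
        if sup is not None:
            out.write(str(int(sup)))
        elif node.label:
            out.write(node.label)
    out.write(_fmt_length(node.edge.length, precision))


def write_newick(tree: dendropy.Tree, precision: int = 6) -> str:
    """Serialize with supports as internal-node labels."""
    out = io.StringIO()
    root = tree.seed_node
    out.write("(")
    for i, ch in enumerate(root.child_nodes()):
        if i:
            out.write(",")
        _write_node(ch, precision, out)
    out.write(")")
    sup = get_support(root)
    if sup is not None:
        out.write(str(int(sup)))
    out.write(";")
    return out.getvalue()


# ---------------------------------------------------------------------------
# queries


def leaf_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def is_rooted(tree: dendropy.Tree) -> bool:
    """Rooted iff the base node is a bifurcation."""
    return len(tree.seed_node.child_nodes()) == 2


def _node_leafsets(tree: dendropy.Tree) -> dict:
    """Map node -> frozenset of leaf labels below it (postorder)."""
    sets: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            sets[nd] = frozenset([nd.taxon.label])
        else:
            acc = frozenset()
            for ch in nd.child_nodes():
                acc |= sets[ch]
            sets[nd] = acc
    return sets


def split_support_map(tree: dendropy.Tree) -> dict:
    """Map canonical bipartition side -> support (None if unlabeled).

    Keys are the canonical sides (containing the smallest taxon) of every
    nontrivial bipartition induced by an edge of the tree.  Where a rooted
    tree's two root edges induce the same bipartition the larger support wins.
    """
    all_taxa = leaf_labels(tree)
    sets = _node_leafsets(tree)
    out: dict = {}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        below = sets[nd]
        if len(below) < 2 or len(all_taxa - below) < 2:
            continue
        key = canonical_side(below, all_taxa)
        sup = get_support(nd)
        if key in out:
            prev = out[key]
            if prev is None or (sup is not None and sup > prev):
                out[key] = sup
        else:
            out[key] = sup
    return out


def splits(
    tree: dendropy.Tree,
    min_support: int = 0,
    include_unsupported: bool | None = None,
) -> set:
    """Nontrivial bipartitions of ``tree`` with support ≥ ``min_support``.

    Edges without a support value are included when ``min_support`` is 0 and
    excluded otherwise; pass ``include_unsupported`` to override.  Attached
    frequencies are the support percents (None where absent).
    """
    if len(leaf_labels(tree)) < 4:
        raise TreeValidationError("splits() needs a tree with >= 4 taxa")
    if include_unsupported is None:
        include_unsupported = min_support == 0
    all_taxa = leaf_labels(tree)
    out = set()
    for side, sup in split_support_map(tree).items():
        if sup is None:
            if not include_unsupported:
                continue
        elif sup < min_support:
            continue
        out.add(Split(side, all_taxa - side, None if sup is None else float(sup)))
    return out


# ---------------------------------------------------------------------------
# rooting


def root_with_outgroup(
    tree: dendropy.Tree,
    outgroup,
    fallback_to_single: bool = False,
) -> dendropy.Tree:
    """Root a copy of ``tree`` on the branch separating ``outgroup`` from the rest.

    The outgroup must form a clade in the unrooted sense (its bipartition must
    exist in the tree); otherwise :class:`OutgroupError` is raised, unless
    ``fallback_to_single`` is set, in which case the tree is rooted on the
    terminal branch of the first (sorted) outgroup taxon.  Supports are
    re-derived from the unrooted bipartitions, so the rooted tree's supports
    are attached to the correct branches regardless of the input rooting.
    """
    outgroup = frozenset(outgroup)
    if not outgroup:
        raise OutgroupError("empty outgroup")
    all_taxa = leaf_labels(tree)
    missing = outgroup - all_taxa
    if missing:
        raise OutgroupError(f"outgroup taxa absent from tree: {sorted(missing)}")
    ingroup = all_taxa - outgroup
    if not ingroup:
        raise OutgroupError("outgroup covers every taxon")

    supports = split_support_map(tree)
    work = parse_newick(write_newick(tree, precision=17))  # private full-precision copy

    sets = _node_leafsets(work)
    target_edge = None
    for nd in work.preorder_node_iter():
        if nd is work.seed_node:
            continue
        if sets[nd] == outgroup or sets[nd] == ingroup:
            target_edge = nd.edge
            break
    if target_edge is None:
        if len(outgroup) == 1:
            (only,) = outgroup
            leaf = next(
                lf for lf in work.leaf_node_iter() if lf.taxon.label == only
            )
            target_edge = leaf.edge
        elif fallback_to_single:
            first = sorted(outgroup)[0]
            leaf = next(
                lf for lf in work.leaf_node_iter() if lf.taxon.label == first
            )
            target_edge = leaf.edge
        else:
            raise OutgroupError(
                f"outgroup {sorted(outgroup)} is not a clade in any rooting"
            )

    length = target_edge.length
    if length is None:
        work.reroot_at_edge(target_edge, update_bipartitions=False)
    else:
        work.reroot_at_edge(
            target_edge,
            length1=length / 2.0,
            length2=length / 2.0,
            update_bipartitions=False,
        )
    work.is_rooted = True
    work.suppress_unifurcations()

    # reassign supports from the (rerooting-invariant) bipartition map
    sets = _node_leafsets(work)
    for nd in work.preorder_node_iter():
        if nd.is_leaf():
            continue
        if nd is work.seed_node:
            nd.support = None
            continue
        below = sets[nd]
        if len(below) < 2 or len(all_taxa - below) < 2:
            nd.support = None
            continue
        nd.support = supports.get(canonical_side(below, all_taxa))
    return work
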