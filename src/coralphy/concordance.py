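"""Gene-tree concordance analysis.

The core of the pipeline: classify each gene tree into one of three
early-divergence scenarios for the coralline ingroup (Sporolithales first,
Sporolithales+Rhodogorgonales first, Rhodogorgonales first), count clade
support across gene sets, summarize conflict proportions, and merge trees
into consensus split networks.

Two classification rules are provided.  The *early-divergence* rule inspects
only the first ingroup bifurcation after outgroup rooting and requires
bootstrap support on that first branch (the branch subtending the larger
ingroup side) to reach a threshold, ignoring all deeper relationships.  The
*full-topology* rule additionally requires every internal branch to reach the
threshold, each multi-taxon group to be monophyletic, and the between-group
topology to match the scenario's reference tree exactly.  The full rule is
strictly stronger: whenever it resolves, the early rule returns the same
label.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from . import treeio
from .treeio import Split, canonical_side

__all__ = [
    "OUTGROUP",
    "SPORO",
    "RHODO",
    "HAPA",
    "CORA",
    "Scenario",
    "GroupMap",
    "NodePatternCount",
    "SplitSystem",
    "MissingTaxonError",
    "is_monophyletic",
    "classify_early_divergence",
    "classify_full_topology",
    "count_node_support",
    "conflict_proportion",
    "consensus_network",
    "write_splits_nexus",
]

OUTGROUP = "OUTGROUP"
SPORO = "SPORO"
RHODO = "RHODO"
HAPA = "HAPA"
CORA = "CORA"

DEFAULT_MIN_SUPPORT = 50  # the "BS >= 50%" convention used throughout


class Scenario(str, Enum):
    SPORO_FIRST = "SPORO_FIRST"
    SPORO_RHODO_FIRST = "SPORO_RHODO_FIRST"
    RHODO_FIRST = "RHODO_FIRST"
    UNRESOLVED = "UNRESOLVED"


class MissingTaxonError(KeyError):
    """A queried taxon is absent from the tree."""


@dataclass(frozen=True)
class GroupMap:
    """Assignment of each taxon to exactly one named group."""

    mapping: dict
    group_order: tuple = (OUTGROUP, SPORO, RHODO, HAPA, CORA)

    def __post_init__(self):
        for t, g in self.mapping.items():
            if g not in self.group_order:
                raise ValueError(f"taxon {t!r} mapped to unknown group {g!r}")

    def taxa_in(self, group: str) -> frozenset:
        return frozenset(t for t, g in self.mapping.items() if g == group)

    @property
    def outgroup(self) -> frozenset:
        return self.taxa_in(OUTGROUP)

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.mapping)

    @classmethod
    def from_tsv(cls, path) -> "GroupMap":
        """Two-column TSV: taxon <tab> group."""
        mapping = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            taxon, group = line.split("\t")[:2]
            if taxon in mapping:
                raise ValueError(f"taxon {taxon!r} mapped twice")
            mapping[taxon] = group
        return cls(mapping)

    def to_tsv(self, path) -> None:
        lines = [f"{t}\t{g}" for t, g in sorted(self.mapping.items())]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class NodePatternCount:
    """How many gene trees show a queried clade with support above threshold."""

    query: frozenset
    n_supporting: int
    n_total: int
    supports: list

    def __post_init__(self):
        if not 0 <= self.n_supporting <= self.n_total:
            raise ValueError("0 <= n_supporting <= n_total violated")


@dataclass
class SplitSystem:
    """Splits with their frequencies among a set of input trees."""

    taxa: frozenset
    splits: list
    cutoff: float


def _support_or_default(node, unsupported: int = 0) -> int:
    sup = treeio.get_support(node)
    return unsupported if sup is None else sup


def is_monophyletic(tree, taxa, min_support: int = DEFAULT_MIN_SUPPORT) -> bool:
    """True iff ``taxa`` form a clade of the rooted ``tree`` at the support threshold.

    Singletons are always monophyletic.  Branches without a support value are
    treated as support 0 (conservative).
    """
    taxa = frozenset(taxa)
    if not taxa:
        raise ValueError("empty taxon query")
    leaves = treeio.leaf_labels(tree)
    missing = taxa - leaves
    if missing:
        raise MissingTaxonError(sorted(missing))
    if len(taxa) == 1:
        return True
    sets = treeio._node_leafsets(tree)
    for nd, below in sets.items():
        if below == taxa:
            if nd is tree.seed_node:
                return True  # whole-tree clade has no subtending branch
            return _support_or_default(nd) >= min_support
    return False


def _rooted_for_groups(tree, groups: GroupMap):
    present_out = groups.outgroup & treeio.leaf_labels(tree)
    if not present_out:
        raise treeio.OutgroupError("no outgroup taxon present in tree")
    try:
        return treeio.root_with_outgroup(tree, present_out)
    except treeio.OutgroupError:
        # outgroup para/polyphyletic in this gene tree: root on one taxon
        return treeio.root_with_outgroup(tree, {sorted(present_out)[0]})


def _ingroup_node(rooted, groups: GroupMap):
    """The child of the root whose leaves are all ingroup taxa (or None)."""
    out = groups.outgroup
    sets = treeio._node_leafsets(rooted)
    for ch in rooted.seed_node.child_nodes():
        if not (sets[ch] & out):
            return ch, sets
    return None, sets


def classify_early_divergence(
    tree,
    groups: GroupMap,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> Scenario:
    """Scenario label from the first ingroup bifurcation only."""
    label, _ = classify_early_divergence_detail(tree, groups, min_support)
    return label


def classify_early_divergence_detail(
    tree,
    groups: GroupMap,
    min_support: int = DEFAULT_MIN_SUPPORT,
):
    """As :func:`classify_early_divergence`, also returning the first-branch support.

    The "first branch" whose support is thresholded is the *diagnostic*
    branch of the matched scenario — the one whose bipartition distinguishes
    the three scenarios: the Rhodogorgonales+Hapalidiales+Corallinales clade
    for Sporo-first, the Sporolithales+Rhodogorgonales clade for
    Sporo-Rhodo-first, and the Sporolithales+Hapalidiales+Corallinales clade
    for Rhodo-first.  (The sibling clade at the same bifurcation — e.g.
    Hapalidiales+Corallinales under Sporo-Rhodo-first — occurs in all three
    scenarios and therefore certifies nothing about the early divergence.)
    When no scenario matches, the better-supported side is reported.
    """
    leaves = treeio.leaf_labels(tree)
    sporo = groups.taxa_in(SPORO) & leaves
    rhodo = groups.taxa_in(RHODO) & leaves
    if not (groups.outgroup & leaves) or not sporo or not rhodo:
        return Scenario.UNRESOLVED, None

    rooted = _rooted_for_groups(tree, groups)
    ingroup_node, sets = _ingroup_node(rooted, groups)
    if ingroup_node is None or ingroup_node.is_leaf():
        return Scenario.UNRESOLVED, None
    children = ingroup_node.child_nodes()
    if len(children) != 2:
        return Scenario.UNRESOLVED, None  # polytomy at the first divergence

    sides = [sets[ch] for ch in children]
    sups = [_support_or_default(ch) for ch in children]

    label = Scenario.UNRESOLVED
    first_branch_support = max(sups)
    for side, other_sup, own_sup in (
        (sides[0], sups[1], sups[0]),
        (sides[1], sups[0], sups[1]),
    ):
        if side == sporo:
            label = Scenario.SPORO_FIRST
            first_branch_support = other_sup  # the (R,H,C) clade branch
        elif side == sporo | rhodo:
            label = Scenario.SPORO_RHODO_FIRST
            first_branch_support = own_sup  # the (S,R) clade branch
        elif side == rhodo:
            label = Scenario.RHODO_FIRST
            first_branch_support = other_sup  # the (S,H,C) clade branch
    if label is not Scenario.UNRESOLVED and first_branch_support < min_support:
        label = Scenario.UNRESOLVED
    return label, first_branch_support


def classify_full_topology(
    tree,
    groups: GroupMap,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> Scenario:
    """Scenario label requiring full support, group monophyly, and exact topology.

    Resolves only when every internal branch of the rooted tree has support at
    or above the threshold, each multi-taxon group is monophyletic, and the
    between-group rooted topology equals the scenario's reference tree:
    Sporo-first (S,(R,(H,C))), Sporo-Rhodo-first ((S,R),(H,C)), Rhodo-first
    (R,(S,(H,C))).  Genes missing some taxa are classified on the reduced
    taxon set as long as all four ingroup groups stay represented.
    """
    leaves = treeio.leaf_labels(tree)
    present = {g: groups.taxa_in(g) & leaves for g in (SPORO, RHODO, HAPA, CORA)}
    if not (groups.outgroup & leaves) or any(not s for s in present.values()):
        return Scenario.UNRESOLVED

    rooted = _rooted_for_groups(tree, groups)
    sets = treeio._node_leafsets(rooted)
    all_taxa = treeio.leaf_labels(rooted)

    for nd in rooted.preorder_internal_node_iter():
        if nd is rooted.seed_node:
            continue
        below = sets[nd]
        if len(below) < 2 or len(all_taxa - below) < 2:
            continue  # trivial bipartition: no meaningful support
        if _support_or_default(nd) < min_support:
            return Scenario.UNRESOLVED

    clades = set(sets.values())
    for g, taxa in present.items():
        if len(taxa) > 1 and taxa not in clades:
            return Scenario.UNRESOLVED

    s, r, h, c = (present[g] for g in (SPORO, RHODO, HAPA, CORA))
    if (h | c) not in clades:
        return Scenario.UNRESOLVED
    if (r | h | c) in clades:
        return Scenario.SPORO_FIRST
    if (s | r) in clades:
        return Scenario.SPORO_RHODO_FIRST
    if (s | h | c) in clades:
        return Scenario.RHODO_FIRST
    return Scenario.UNRESOLVED


def count_node_support(
    trees,
    queries,
    groups: GroupMap,
    min_support: int = DEFAULT_MIN_SUPPORT,
):
    """Per clade query, count gene trees containing/supporting it.

    A tree enters ``n_total`` for a query when it contains every queried taxon
    and at least one outgroup taxon (for rooting); it enters ``n_supporting``
    when the clade is present with support at or above the threshold.  The
    observed support of every tree in which the clade is present (at any
    support) is recorded for support-distribution summaries.
    """
    if not trees:
        raise ValueError("no trees given")
    results = []
    for query in queries:
        query = frozenset(query)
        n_total = 0
        n_sup = 0
        observed = []
        for tree in trees:
            leaves = treeio.leaf_labels(tree)
            if not query <= leaves or not (groups.outgroup & leaves):
                continue
            n_total += 1
            rooted = _rooted_for_groups(tree, groups)
            sets = treeio._node_leafsets(rooted)
            node = next((nd for nd, below in sets.items() if below == query), None)
            if node is None:
                continue
            sup = 100 if len(query) == 1 else _support_or_default(node)
            observed.append(sup)
            if is_monophyletic(rooted, query, min_support):
                n_sup += 1
        results.append(NodePatternCount(query, n_sup, n_total, observed))
    return results


def conflict_proportion(
    n_reject_mt: int, n_total_mt: int, n_reject_pt: int, n_total_pt: int
) -> float:
    """Percent of genes (both organelles pooled) rejecting a reference topology.

    Reported to one decimal place, truncated rather than rounded: the
    convention under which 19 rejections out of 217 genes (8.7557...%) is
    reported as 8.7.
    """
    if n_total_mt < 0 or n_total_pt < 0 or n_total_mt + n_total_pt == 0:
        raise ValueError("totals must be positive")
    if not (0 <= n_reject_mt <= n_total_mt and 0 <= n_reject_pt <= n_total_pt):
        raise ValueError("rejections must lie within totals")
    pct = 100.0 * (n_reject_mt + n_reject_pt) / (n_total_mt + n_total_pt)
    return math.floor(pct * 10.0) / 10.0


def consensus_network(trees, cutoff: float = 0.2) -> SplitSystem:
    """All nontrivial splits occurring in at least ``cutoff`` of the input trees.

    With cutoff > 0.5 the result is a compatible (tree-like) split set; lower
    cutoffs admit conflicting splits, which a network viewer renders as
    reticulations.  Ties at the cutoff are retained.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    if not trees:
        raise ValueError("no trees given")
    taxa = treeio.leaf_labels(trees[0])
    for i, t in enumerate(trees[1:], start=2):
        other = treeio.leaf_labels(t)
        if other != taxa:
            diff = sorted(taxa ^ other)
            raise ValueError(f"tree {i} taxon set differs; symmetric difference {diff}")

    counts: Counter = Counter()
    for t in trees:
        sides = set()
        sets = treeio._node_leafsets(t)
        for nd in t.preorder_node_iter():
            if nd is t.seed_node:
                continue
            below = sets[nd]
            if len(below) < 2 or len(taxa - below) < 2:
                continue
            sides.add(canonical_side(below, taxa))
        counts.update(sides)

    n = len(trees)
    out = []
    for side, c in counts.items():
        freq = c / n
        if freq >= cutoff:
            out.append(Split(side, taxa - side, freq))
    out.sort(key=lambda s: (-s.frequency, sorted(s.side_a), sorted(s.side_b)))
    return SplitSystem(taxa, out, cutoff)


def write_splits_nexus(system: SplitSystem, path) -> None:
    """Serialize a split system to a NEXUS SPLITS block (SplitsTree-compatible)."""
    taxa = sorted(system.taxa)
    index = {t: i + 1 for i, t in enumerate(taxa)}
    lines = [
        "#NEXUS",
        "",
        "BEGIN TAXA;",
        f"    DIMENSIONS NTAX={len(taxa)};",
        "    TAXLABELS",
    ]
    lines += [f"        {t}" for t in taxa]
    lines += [
        "    ;",
        "END;",
        "",
        "BEGIN SPLITS;",
        f"    DIMENSIONS NTAX={len(taxa)} NSPLITS={len(system.splits)};",
        "    FORMAT LABELS=NO WEIGHTS=YES;",
        "    MATRIX",
    ]
    for sp in system.splits:
        ids = " ".join(str(index[t]) for t in sorted(sp.side_a, key=index.get))
        lines.append(f"        {sp.frequency:.6f}  {ids},")
    lines += ["    ;", "END;", ""]
    Path(path).write_text("\n".join(lines), encoding="utf-8")
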