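"""Multispecies-coalescent synthetic data for the coralline study design.

Gene trees are simulated under the multispecies coalescent (MSC) within a
rooted species tree whose branch lengths are in coalescent units (time over
2N generations): inside each species branch the k resident lineages coalesce
with exponential waiting times at rate k(k-1)/2, survivors pass to the
parent branch, and everything left coalesces in the (unbounded) root branch.
Sequences then evolve along each gene tree under Jukes–Cantor, with
``mutation_scale`` converting coalescent units to expected substitutions per
site.

The default nine-taxon fixture ``coralline9`` mirrors the coralline study
design: two outgroup taxa plus seven ingroup taxa in four ordinal groups of
sizes 1/2/2/2 (Sporolithales, Rhodogorgonales, Hapalidiales, Corallinales).
Its key free parameter is the *stem* — the internal branch between the first
and second ingroup divergences — which controls the amount of incomplete
lineage sorting at the contested early divergence.  One haplotype is sampled
per species (one organelle genome per taxon); there is no migration or
hybridization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import dendropy

from . import treeio
from .concordance import CORA, HAPA, OUTGROUP, RHODO, SPORO, GroupMap, Scenario
from .mlcore import Alignment

__all__ = [
    "SpeciesTreeModel",
    "Gene",
    "GeneSet",
    "coralline9",
    "coralline9_groups",
    "simulate_gene_tree",
    "simulate_alignment",
    "simulate_gene_set",
    "scenario_mixture_expectation",
    "gene_seed",
]

NT = "ACGT"


@dataclass
class SpeciesTreeModel:
    """Rooted species tree (coalescent-unit branch lengths) plus sequence model."""

    tree: dendropy.Tree
    groups: GroupMap
    mutation_scale: float = 0.05
    n_sites: int = 1000

    def __post_init__(self):
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative species-tree branch length")
        self._compiled = None

    @property
    def taxa(self) -> frozenset:
        return treeio.leaf_labels(self.tree)

    def _compile(self):
        """Flatten the species tree into postorder records for fast simulation.

        Each record is (node_depth, parent_depth, child_record_ids, taxon).
        Depth is distance from the root (so time decreases rootward); the
        root's parent depth is -inf, i.e. an unbounded terminal branch.
        """
        if self._compiled is not None:
            return self._compiled
        depth = {self.tree.seed_node: 0.0}
        for nd in self.tree.preorder_node_iter():
            if nd is self.tree.seed_node:
                continue
            length = nd.edge.length if nd.edge.length is not None else 0.0
            depth[nd] = depth[nd.parent_node] + length
        records = []
        index = {}
        for nd in self.tree.postorder_node_iter():
            parent_depth = (
                -np.inf if nd is self.tree.seed_node else depth[nd.parent_node]
            )
            records.append(
                (
                    depth[nd],
                    parent_depth,
                    [index[ch] for ch in nd.child_nodes()],
                    nd.taxon.label if nd.is_leaf() else None,
                )
            )
            index[nd] = len(records) - 1
        self._compiled = records
        return records


@dataclass
class Gene:
    gene_id: str
    tree: dendropy.Tree
    alignment: Alignment
    seed: int


@dataclass
class GeneSet:
    genes: list
    model: SpeciesTreeModel

    def __len__(self):
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def coralline9_groups() -> GroupMap:
    return GroupMap(
        {
            "O1": OUTGROUP,
            "O2": OUTGROUP,
            "S1": SPORO,
            "R1": RHODO,
            "R2": RHODO,
            "H1": HAPA,
            "H2": HAPA,
            "C1": CORA,
            "C2": CORA,
        }
    )


def coralline9(
    stem: float = 0.1,
    scenario: Scenario = Scenario.SPORO_FIRST,
    mutation_scale: float = 0.05,
    n_sites: int = 1000,
) -> SpeciesTreeModel:
    """The nine-taxon coralline-like fixture under a chosen generating scenario.

    All non-focal branches are several coalescent units long, so discordance
    is concentrated on the ``stem`` branch between the first and second
    ingroup divergences.  Node times (coalescent units before the tips):
    within-pair splits at 1, Hapalidiales/Corallinales split at 5, the second
    ingroup divergence at 9, the first at 9 + stem, and the root at 13 + stem.
    """
    T = float(stem)
    if T < 0:
        raise ValueError("stem must be >= 0")
    r_anc = "(R1:1,R2:1):8"  # Rhodogorgonales ancestor, t=1 .. t=9
    hc = "((H1:1,H2:1):4,(C1:1,C2:1):4):4"  # Hapalidiales+Corallinales, t=5 .. t=9
    if scenario is Scenario.SPORO_FIRST:
        ingroup = f"(S1:{9 + T:.6g},({r_anc},{hc}):{T:.6g})"
    elif scenario is Scenario.RHODO_FIRST:
        ingroup = f"((R1:1,R2:1):{8 + T:.6g},(S1:9,{hc}):{T:.6g})"
    elif scenario is Scenario.SPORO_RHODO_FIRST:
        hc_long = f"((H1:1,H2:1):4,(C1:1,C2:1):4):{4 + T:.6g}"
        ingroup = f"((S1:9,{r_anc}):{T:.6g},{hc_long})"
    else:
        raise ValueError(f"no generating tree for scenario {scenario}")
    newick = f"((O1:1,O2:1):{12 + T:.6g},{ingroup}:4);"
    return SpeciesTreeModel(
        tree=treeio.parse_newick(newick),
        groups=coralline9_groups(),
        mutation_scale=mutation_scale,
        n_sites=n_sites,
    )


# ---------------------------------------------------------------------------
# gene-tree simulation


def simulate_gene_tree(model: SpeciesTreeModel, seed) -> dendropy.Tree:
    """One MSC gene tree; leaves = species taxa, lengths in coalescent units."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = model._compile()

    # lineage = (node_payload, depth); payload is (taxon,) for a leaf or
    # (left_payload, right_payload, left_len, right_len) for an internal node
    surviving: list = [None] * len(records)
    for rid, (node_depth, parent_depth, child_ids, taxon) in enumerate(records):
        if taxon is not None:
            lineages = [((taxon,), node_depth)]
        else:
            lineages = []
            for cid in child_ids:
                lineages.extend(surviving[cid])
        t = node_depth
        while len(lineages) > 1:
            k = len(lineages)
            wait = rng.exponential(2.0 / (k * (k - 1)))
            t_new = t - wait
            if t_new <= parent_depth:
                break
            i, j = rng.choice(k, size=2, replace=False)
            (pa, da), (pb, db) = lineages[i], lineages[j]
            merged = ((pa, pb, da - t_new, db - t_new), t_new)
            lineages = [
                lin for idx, lin in enumerate(lineages) if idx not in (i, j)
            ] + [merged]
            t = t_new
        surviving[rid] = lineages

    (payload, _depth) = surviving[-1][0]

    taxa_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa_ns)

    def build(p, parent):
        node = dendropy.Node()
        parent.add_child(node)
        if len(p) == 1:
            node.taxon = taxa_ns.require_taxon(label=p[0])
        else:
            a, b, la, lb = p
            build(a, node).edge.length = la
            build(b, node).edge.length = lb
        return node

    if len(payload) == 1:
        tree.seed_node.taxon = taxa_ns.require_taxon(label=payload[0])
    else:
        a, b, la, lb = payload
        build(a, tree.seed_node).edge.length = la
        build(b, tree.seed_node).edge.length = lb
    tree.is_rooted = True
    return tree


def simulate_alignment(
    gene_tree: dendropy.Tree, n_sites: int, mutation_scale: float, seed
) -> Alignment:
    """Jukes–Cantor sequences evolved down the gene tree; root states uniform."""
    if n_sites < 1:
        raise ValueError("n_sites >= 1 required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states: dict = {gene_tree.seed_node: rng.integers(0, 4, size=n_sites)}
    labels, seqs = [], []
    for nd in gene_tree.preorder_node_iter():
        if nd is not gene_tree.seed_node:
            t = (nd.edge.length or 0.0) * mutation_scale
            p_same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
            parent = states[nd.parent_node]
            change = rng.random(n_sites) >= p_same
            shift = rng.integers(1, 4, size=n_sites)
            states[nd] = np.where(change, (parent + shift) % 4, parent)
        if nd.is_leaf():
            labels.append(nd.taxon.label)
            arr = states[nd]
            seqs.append("".join(NT[i] for i in arr))
    return Alignment(labels, seqs, NT)


def gene_seed(master_seed: int, gene_index: int) -> np.random.Generator:
    """Deterministic per-gene generator: SeedSequence(master).spawn-style keying."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(gene_index,))
    return np.random.default_rng(ss)


def simulate_gene_set(
    model: SpeciesTreeModel,
    n_genes: int,
    seed: int,
    n_sites: int | None = None,
) -> GeneSet:
    """Independent gene trees + alignments; gene i is reproducible in isolation."""
    if n_genes < 1:
        raise ValueError("n_genes >= 1 required")
    n_sites = model.n_sites if n_sites is None else n_sites
    genes = []
    for i in range(n_genes):
        rng = gene_seed(seed, i)
        gt = simulate_gene_tree(model, rng)
        aln = simulate_alignment(gt, n_sites, model.mutation_scale, rng)
        genes.append(Gene(f"g{i:04d}", gt, aln, i))
    return GeneSet(genes, model)


def mt_like(stem: float = 0.1, **kw) -> SpeciesTreeModel:
    """Mitochondrial-like preset: 22 loci of longer genes (1,500 nt)."""
    kw.setdefault("n_sites", 1500)
    return coralline9(stem=stem, **kw)


def pt_like(stem: float = 0.1, **kw) -> SpeciesTreeModel:
    """Plastid-like preset: 195 loci of shorter genes (900 nt)."""
    kw.setdefault("n_sites", 900)
    return coralline9(stem=stem, **kw)


MT_LIKE_N_GENES = 22
PT_LIKE_N_GENES = 195


# ---------------------------------------------------------------------------
# analytic MSC expectation


def scenario_mixture_expectation(model: SpeciesTreeModel) -> dict:
    """Expected scenario-label probabilities from the reduced three-lineage MSC.

    The ingroup must reduce to three stem lineages (Sporolithales,
    Rhodogorgonales, rest); with internal branch length T between the first
    and second ingroup divergences the generating scenario has probability
    1 - (2/3) e^(-T) and each minority scenario (1/3) e^(-T).
    """
    groups = model.groups
    rooted = treeio.root_with_outgroup(model.tree, groups.outgroup)
    sets = treeio._node_leafsets(rooted)
    ingroup_children = [
        ch
        for ch in rooted.seed_node.child_nodes()
        if not (sets[ch] & groups.outgroup)
    ]
    if len(ingroup_children) != 1:
        raise ValueError("model is not outgroup-rooted over a single ingroup clade")
    node = ingroup_children[0]
    if len(node.child_nodes()) != 2:
        raise ValueError("ingroup root is not a bifurcation")

    sporo = groups.taxa_in(SPORO)
    rhodo = groups.taxa_in(RHODO)
    rest = groups.taxa_in(HAPA) | groups.taxa_in(CORA)
    sides = {frozenset(sets[ch]): ch for ch in node.child_nodes()}

    def match(side_set):
        return sides.get(frozenset(side_set))

    if match(sporo) is not None:
        generating = Scenario.SPORO_FIRST
        inner = next(ch for ch in node.child_nodes() if sets[ch] != sporo)
    elif match(rhodo) is not None:
        generating = Scenario.RHODO_FIRST
        inner = next(ch for ch in node.child_nodes() if sets[ch] != rhodo)
    elif match(sporo | rhodo) is not None:
        generating = Scenario.SPORO_RHODO_FIRST
        inner = match(sporo | rhodo)
    else:
        raise ValueError("model does not reduce to an (S, R, rest) triple")

    T = inner.edge.length or 0.0
    minority = (1.0 / 3.0) * float(np.exp(-T))
    majority = 1.0 - 2.0 * minority
    out = {
        Scenario.SPORO_FIRST: minority,
        Scenario.SPORO_RHODO_FIRST: minority,
        Scenario.RHODO_FIRST: minority,
    }
    out[generating] = majority
    return out
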