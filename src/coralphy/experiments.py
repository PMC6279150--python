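"""Study-level experiments composing the pipeline stages.

Each function here is one complete computational experiment of the analysis:
simulate gene sets under the coralline multispecies-coalescent fixture,
estimate per-gene trees with bootstrap supports, classify topology
scenarios, run RELL/AU topology tests against the candidate evolutionary
scenarios, and measure TIGER subsampling behavior.  The numbered analysis
scripts and the acceptance machinery are thin wrappers over these.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import coalsim, concordance, mlcore, treeio
from .concordance import Scenario

__all__ = [
    "classify_gene_set",
    "scenario_recovery",
    "msc_triple_concordance",
    "kh_calibration",
    "gene_topology_tests",
    "subsampling_trend",
    "SHALLOW8_NEWICK",
    "SHALLOW8_FOCAL",
]


def classify_gene_set(
    gene_set,
    n_boot: int = 200,
    min_support: int = 50,
) -> pd.DataFrame:
    """Bootstrap NJ tree per gene, then early- and full-rule classification.

    Returns one row per gene: gene id, early-rule label, first-branch
    support, full-rule label.
    """
    groups = gene_set.model.groups
    rows = []
    for gene in gene_set:
        bt = mlcore.bootstrap_supports(gene.alignment, n_boot, seed=gene.seed)
        early, sup = concordance.classify_early_divergence_detail(
            bt, groups, min_support
        )
        full = concordance.classify_full_topology(bt, groups, min_support)
        rows.append(
            {
                "gene": gene.gene_id,
                "early_label": early.value,
                "first_branch_support": sup,
                "full_label": full.value,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RecoveryResult:
    counts: dict               # Scenario -> observed count (early rule)
    n_resolved: int
    n_genes: int
    frequencies: dict          # Scenario -> frequency among resolved genes
    expected: dict             # Scenario -> analytic MSC probability
    table: pd.DataFrame


def scenario_recovery(
    stem: float,
    n_genes: int,
    n_sites: int,
    n_boot: int,
    seed: int,
    scenario: Scenario = Scenario.SPORO_FIRST,
) -> RecoveryResult:
    """Simulate a gene set, classify every gene, compare with MSC expectation."""
    model = coalsim.coralline9(stem=stem, scenario=scenario, n_sites=n_sites)
    gs = coalsim.simulate_gene_set(model, n_genes, seed=seed)
    table = classify_gene_set(gs, n_boot=n_boot)
    counts = Counter(Scenario(v) for v in table["early_label"])
    resolved = [s for s in Scenario if s is not Scenario.UNRESOLVED]
    n_resolved = sum(counts[s] for s in resolved)
    freqs = {
        s: (counts[s] / n_resolved if n_resolved else float("nan"))
        for s in resolved
    }
    return RecoveryResult(
        counts=dict(counts),
        n_resolved=n_resolved,
        n_genes=n_genes,
        frequencies=freqs,
        expected=coalsim.scenario_mixture_expectation(model),
        table=table,
    )


def msc_triple_concordance(T: float, n_reps: int, seed: int) -> dict:
    """Observed vs analytic concordant-triple frequency on a rooted triple."""
    model = coalsim.SpeciesTreeModel(
        tree=treeio.parse_newick(f"((A:1,B:1):{T},C:{1 + T});"),
        groups=concordance.GroupMap(
            {"A": "SPORO", "B": "RHODO", "C": "HAPA"},
            ("SPORO", "RHODO", "HAPA"),
        ),
    )
    rng = np.random.default_rng(seed)
    pair = frozenset({"A", "B"})
    hits = 0
    for _ in range(n_reps):
        gt = coalsim.simulate_gene_tree(model, rng)
        if pair in set(treeio._node_leafsets(gt).values()):
            hits += 1
    expected = 1.0 - (2.0 / 3.0) * float(np.exp(-T))
    return {
        "observed": hits / n_reps,
        "expected": expected,
        "n": n_reps,
        "sigma": float(np.sqrt(expected * (1 - expected) / n_reps)),
    }


def kh_calibration(
    n_trials: int = 500,
    n_sites: int = 150,
    n_reps: int = 200,
    seed: int = 0,
) -> dict:
    """Calibration of the pairwise KH p-value under exchangeable rows.

    Each trial draws two topologies' site log-likelihoods i.i.d. from the
    same distribution (no true signal) and records the one-sided KH p-value
    for a pre-specified comparison direction; under the null these p-values
    are approximately uniform.
    """
    rng = np.random.default_rng(seed)
    ps = []
    for trial in range(n_trials):
        M = mlcore.SiteLikelihoodMatrix(
            ["t1", "t2"], rng.normal(size=(2, n_sites))
        )
        ps.append(
            mlcore.kh_test_pair(M, 0, 1, n_reps=n_reps, seed=seed + trial + 1)
        )
    ks = stats.kstest(ps, "uniform")
    return {"p_values": ps, "ks_statistic": float(ks.statistic),
            "ks_pvalue": float(ks.pvalue)}


def _scenario_reference_trees():
    return {
        s: coalsim.coralline9(stem=0.5, scenario=s).tree
        for s in (
            Scenario.SPORO_FIRST,
            Scenario.SPORO_RHODO_FIRST,
            Scenario.RHODO_FIRST,
        )
    }


def gene_topology_tests(
    gene_set,
    n_reps: int = 1000,
    tolerance: float = 1e-2,
    max_sweeps: int = 8,
) -> pd.DataFrame:
    """Per-gene AU/KH/SH tests of the three scenario topologies.

    For each gene, branch lengths of each candidate scenario topology are
    re-optimized on that gene's alignment under JC, per-site log-likelihoods
    collected, and the RELL tests run.  Returns one row per gene x topology.
    """
    refs = _scenario_reference_trees()
    rows = []
    for gene in gene_set:
        sitelks = []
        names = []
        for scen, ref in refs.items():
            opt = mlcore.optimize_branch_lengths(
                ref, gene.alignment, tolerance=tolerance, max_sweeps=max_sweeps
            )
            sitelks.append(mlcore.felsenstein_loglik(opt, gene.alignment))
            names.append(scen.value)
        M = mlcore.SiteLikelihoodMatrix(names, np.vstack(sitelks))
        res = mlcore.rell_topology_test(M, n_reps=n_reps, seed=gene.seed)
        df = res.to_dataframe()
        df.insert(0, "gene", gene.gene_id)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


# a shallow eight-taxon tree with a single short internal branch (0.01
# substitutions/site against 0.1 elsewhere), used for the subsampling
# direction experiment
SHALLOW8_NEWICK = (
    "(((A:0.25,B:0.25):0.1,(C:0.25,D:0.25):0.1):0.1,"
    "((E:0.25,F:0.25):0.1,(G:0.25,H:0.25):0.1):0.01);"
)
SHALLOW8_FOCAL = frozenset("EFGH")


def subsampling_trend(
    newick: str = SHALLOW8_NEWICK,
    focal=SHALLOW8_FOCAL,
    n_sites: int = 5000,
    mutation_scale: float = 1.0,
    keeps=(1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4),
    n_seeds: int = 5,
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """TIGER-ranked subsampling series: focal-split support and topology stability.

    For each seed: simulate one alignment down the fixed tree, rank sites by
    TIGER agreement, and for each keep proportion rebuild the NJ tree with
    bootstrap supports.  Records the focal split's support (-1 when the split
    is absent from the point tree) and whether the point topology matches the
    full-data point topology.
    """
    tree = treeio.parse_newick(newick)
    focal = frozenset(focal)
    rows = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        aln = coalsim.simulate_alignment(tree, n_sites, mutation_scale, rng)
        profile = mlcore.tiger_site_rates(aln)
        base_topology = None
        for keep in keeps:
            sub = mlcore.subsample_by_rate(aln, profile, keep)
            bt = mlcore.bootstrap_supports(sub, n_boot, seed=seed + s)
            taxa = treeio.leaf_labels(bt)
            support = -1
            for sp in treeio.splits(bt, 0):
                if sp.side_a in (focal, taxa - focal):
                    support = -1 if sp.frequency is None else int(sp.frequency)
            topo = frozenset(
                mlcore._nj_splits(mlcore.distance_matrix(sub, saturation="cap"))
            )
            if base_topology is None:
                base_topology = topo
            rows.append(
                {
                    "seed": s,
                    "keep": keep,
                    "focal_support": support,
                    "topology_stable": topo == base_topology,
                }
            )
    return pd.DataFrame(rows)
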