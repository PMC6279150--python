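"""TIGER site-rate subsampling series: what survives when fast sites go.

Two series are run.  First, a controlled shallow eight-taxon tree with one
short internal branch, where the qualitative expectation holds cleanly:
lowering the keep proportion never changes the NJ point topology and the
short branch's median support does not increase.  Second, the coralline
concatenated mitochondrial-like alignment, reported as observed — on this
deep tree with near-saturated outgroup distances, distance-based NJ after
aggressive subsampling is *not* guaranteed stable, and the trajectory is
printed without any monotonicity claim.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from coralphy import coalsim, experiments, mlcore, treeio

MASTER_SEED = 42
STEM = 0.1
RESULTS = Path(__file__).resolve().parent.parent / "results"
KEEPS = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4)


def concatenated_series():
    model = coalsim.mt_like(stem=STEM)
    gs = coalsim.simulate_gene_set(model, coalsim.MT_LIKE_N_GENES, seed=MASTER_SEED)
    seqs = {lab: [] for lab in gs.genes[0].alignment.labels}
    for g in gs:
        for lab, seq in zip(g.alignment.labels, g.alignment.sequences):
            seqs[lab].append(seq)
    labels = sorted(seqs)
    concat = mlcore.Alignment(labels, ["".join(seqs[l]) for l in labels])
    profile = mlcore.tiger_site_rates(concat)
    focal = frozenset({"R1", "R2", "H1", "H2", "C1", "C2"})
    rows = []
    for keep in KEEPS:
        sub = mlcore.subsample_by_rate(concat, profile, keep)
        bt = mlcore.bootstrap_supports(sub, 100, seed=MASTER_SEED)
        taxa = treeio.leaf_labels(bt)
        support = None
        for sp in treeio.splits(bt, 0):
            if sp.side_a in (focal, taxa - focal):
                support = sp.frequency
        rows.append(
            {
                "keep": keep,
                "n_sites": sub.n_sites,
                "stem_split_support": -1 if support is None else int(support),
            }
        )
    return concat.n_sites, pd.DataFrame(rows)


def main():
    RESULTS.mkdir(parents=True, exist_ok=True)

    trend = experiments.subsampling_trend(n_seeds=5, n_boot=100, seed=MASTER_SEED)
    trend.to_csv(RESULTS / "subsampling_shallow8.tsv", sep="\t", index=False)
    medians = trend.groupby("keep")["focal_support"].median().sort_index(
        ascending=False
    )
    print("shallow 8-taxon control (short internal branch 0.01 subs/site):")
    print(f"  topology stable in every seed/keep: {trend['topology_stable'].all()}")
    print("  median focal-branch support by keep:")
    for keep, med in medians.items():
        print(f"    keep {keep:.1f}: {med:.0f}")
    assert np.all(np.diff(medians.to_numpy()) <= 0)

    n_sites, series = concatenated_series()
    series.to_csv(RESULTS / "subsampling_concat_mt.tsv", sep="\t", index=False)
    print(
        f"\ncoralline concatenated mt-like series ({n_sites} sites), "
        "stem-split support as observed (-1 = split absent from NJ tree):"
    )
    for _, row in series.iterrows():
        print(
            f"  keep {row['keep']:.1f} ({int(row['n_sites'])} sites): "
            f"support {int(row['stem_split_support'])}"
        )
    print(f"wrote {RESULTS / 'subsampling_shallow8.tsv'} and "
          f"{RESULTS / 'subsampling_concat_mt.tsv'}")


if __name__ == "__main__":
    main()
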