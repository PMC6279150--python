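# Methods

## The problem

Coralline red algae (subclass Corallinophycidae) comprise four orders —
Sporolithales, Rhodogorgonales, Hapalidiales, Corallinales — whose earliest
divergences are contested: concatenated mitochondrial and plastid genomes
support different branching orders for Sporolithales and Rhodogorgonales
relative to the rest.  The leading explanation is incomplete lineage
sorting (ILS) during a rapid ancient radiation: individual organelle genes
carry different genealogies because ancestral polymorphism persisted across
closely spaced speciation events.

`coralphy` implements the full concordance analysis used to interrogate
this conflict — per-gene topology classification under bootstrap-support
thresholds, clade-support censuses, RELL-based topology tests, site-rate
subsampling, consensus split networks, counting dN/dS, and genome feature
summaries — driven by a multispecies-coalescent (MSC) generator so the whole
analysis runs on synthetic data with known truth.  The published per-gene
trees and alignments are not redistributed, so no attempt is made to
reproduce published per-gene counts; the pipeline's correctness is
established on simulation instead.

## The generative model

### Multispecies coalescent

Gene trees are drawn from the MSC: within each species-tree branch of
duration `T` (coalescent units, time/2N generations), the `k` resident
lineages coalesce after exponential waiting times at rate `k(k-1)/2`;
survivors pass rootward, and the root branch is unbounded.  One haplotype
is sampled per species, matching one organelle genome per taxon.  There is
no migration, hybridization, or gene flow: ILS is the only source of
discordance, which is the hypothesis under study.

For a rooted triple with internal branch `T`, the probability that a gene
tree matches the species tree is `1 − (2/3)e^(−T)`, and each discordant
resolution has probability `(1/3)e^(−T)`.  `scenario_mixture_expectation`
applies this to the reduced three-lineage problem (Sporolithales,
Rhodogorgonales, rest) and is the analytic oracle for the simulator and for
end-to-end parameter recovery.

### The coralline9 fixture

Nine taxa: two outgroup species (O1, O2) and seven ingroup species in
groups of 1/2/2/2 (S1; R1, R2; H1, H2; C1, C2), mirroring the study design.
Node times in coalescent units before the tips: within-pair splits at 1,
the Hapalidiales/Corallinales split at 5, the second ingroup divergence at
9, the first ingroup divergence at `9 + stem`, the root at `13 + stem`.
All non-focal internal branches are ≥ 4 coalescent units, so lineages
almost surely coalesce before reaching the focal **stem** branch
(`P(failure) ≤ e^(−4) ≈ 0.018`) and discordance is concentrated at the
contested early divergence, keeping the reduced-triple expectation accurate
to within ~2%.  Any of the three scenarios can be chosen as the generating
tree.

Sequences evolve by Jukes–Cantor with a single global
`mutation_scale = 0.05` substitutions/site per coalescent unit (default).
This puts outgroup–ingroup distances near 1.3 substitutions/site — deep but
below the JC saturation bound — and a 0.1-unit stem at 0.005
substitutions/site, i.e. ~10 expected substitutions in a 2 kb gene: exactly
the marginal-signal regime in which single-gene trees resolve the early
divergence only sometimes, as in the real data.  Presets: `mt_like` (22
loci of 1,500 nt) and `pt_like` (195 loci of 900 nt), the gene counts of
the two organelle data sets with organelle-typical gene lengths.  Per-gene
seeds derive from the master seed via `SeedSequence(master, spawn_key=(i,))`
so every gene is reproducible in isolation.

## Classification rules

Gene trees are rooted on the outgroup (falling back to a single designated
outgroup taxon when the outgroup is not a clade in the gene tree, as can
happen under deep ILS or estimation error).  Supports are attached to
unrooted bipartitions and re-derived after rerooting, so no support ever
migrates to the wrong branch.

**Early-divergence rule.**  Inspect the first ingroup bifurcation only.  If
one side is exactly the Sporolithales (resp. Sporolithales+Rhodogorgonales,
Rhodogorgonales) taxa present, the gene is Sporo-first (resp.
Sporo-Rhodo-first, Rhodo-first), provided the *diagnostic branch* has
bootstrap support ≥ 50: the (R,H,C) clade branch for Sporo-first, the (S,R)
branch for Sporo-Rhodo-first, the (S,H,C) branch for Rhodo-first.  The
diagnostic branch is the one whose bipartition distinguishes the three
scenarios; its sibling at the same bifurcation (e.g. the
Hapalidiales+Corallinales clade under Sporo-Rhodo-first) occurs in all
three scenarios and certifies nothing.  An earlier draft thresholded on the
branch subtending the larger ingroup side; on simulation this certified
Sporo-Rhodo-first calls with the non-diagnostic H+C clade at BS 100 while
the actual S+R grouping had BS 42, and was replaced.

**Full-topology rule.**  Strictly stronger: every internal branch must have
support ≥ 50, every multi-taxon group must be monophyletic, and the
between-group rooted topology must equal the scenario's reference exactly.
Whenever it resolves, the early rule returns the same label (a tested
invariant).  Genes missing taxa are classified on the reduced taxon set as
long as all four ingroup groups remain represented; unlabeled branches
count as support 0 (conservative, switchable).

## Inference core

Deliberately minimal, because the object of study is downstream of tree
inference: NJ on JC distances (Poisson-corrected for amino acids), plain
nonparametric bootstrap (sites resampled with replacement, supports =
percent of replicate NJ trees containing each point-tree split; saturated
replicate distances are capped at 5 substitutions/site rather than
discarded), and pruning likelihood under equal-frequency JC/Poisson models
with gaps as missing data.  Branch lengths are fit by coordinate-wise
bounded Brent; the likelihood is non-decreasing across sweeps and invariant
under rerooting (pulley principle, verified to < 1e-8 relative).

**Topology tests.**  RELL resampling of per-site log-likelihoods (no
re-optimization).  KH: centered bootstrap null for the difference to the
best topology.  SH: one-sided null from the max-centered statistic,
conservative relative to KH by construction (`p_SH ≥ p_KH`, tested).  AU:
multiscale bootstrap at relative sample sizes 0.5–1.4 (step 0.1, 1,000
replicates each); bootstrap proportions are fit on the probit scale to
`z(r) = d√r + c/√r` by weighted least squares with binomial-variance
weights, giving `p_AU = 1 − Φ(d − c)`.  Exact argmax ties share the win
equally; a topology winning (losing) at every scale receives `p_AU` 1 (0,
with a degenerate-fit warning).  Calibration of the pairwise KH p-value
under exchangeable rows is uniform (KS-tested in the acceptance suite).

**TIGER site rates.**  Each site induces a partition of the taxa by
character state (gaps excluded by default, or treated as a state); the
agreement of site *i* with site *j* is the fraction of *j*'s sets nested
within some set of *i*'s partition, and a site's rate is its mean agreement
with all other sites.  Identical patterns are deduplicated before the
quadratic pass, which makes 30 kb concatenations cheap.  Subsampling keeps
the `ceil(keep·S)` highest-rate (most conserved) sites in original order;
the published tool's exact `-b 50` bin semantics are not reproduced — a
keep-proportion grid stands in.

## dN/dS and rank-sum comparison

The published analysis used codeml's ML pairwise mode; here the pairwise
rates are estimated by Nei–Gojobori (1986) counting, which is fully
specifiable and desk-verifiable: synonymous site counts are per-codon
averages of the synonymous fraction at each position (averaged over both
sequences), observed differences are averaged over all minimal substitution
pathways excluding those through stop codons (readmitted only if every
pathway is blocked), and `pN`, `pS` receive the `d = −(3/4)ln(1 − 4p/3)`
correction, reported as NaN beyond the `p ≥ 3/4` domain.  Codon tables 4
(mitochondrial, TGA=Trp) and 11 (plastid) via Biopython.  Codons with gaps,
ambiguity, or stops in either sequence are skipped pairwise.  Lineage
comparisons use the two-sided Wilcoxon rank-sum test: exact enumeration for
tie-free combined samples ≤ 12, else the normal approximation with tie and
continuity corrections (scipy's `mannwhitneyu` under the hood).

## Genome feature summaries

GenBank records (Biopython) with GenBank 1-based inclusive coordinates at
the file boundary and 0-based half-open internally.  GC excludes ambiguity
codes from the denominator.  "Noncoding" = positions covered by no CDS,
tRNA, or rRNA feature (configurable); coverage is a union, so
coding + noncoding = total even with overlapping features.  Origin-spanning
features on circular records are handled through compound locations.
Intron lengths come from pre-annotated intron features and are reported
separately from the coding/noncoding partition, so both conventions for
"does intron interior count as noncoding" are recoverable.  The conflict
percentage is truncated (not rounded) to one decimal, the convention under
which 19/217 = 8.7557…% is reported as 8.7.

## Problem sizes and numerical choices

Simulation-backed checks use sizes that keep the full suite within a few
minutes on one core: 100,000 replicates for the triple oracle (3σ band
±0.004), 200 genes × 2 kb × 200 bootstrap replicates for end-to-end
recovery (3σ binomial bands on frequencies among resolved genes), 500
trials × 200 RELL replicates for KH calibration, and 5 seeds × 7 keep
levels for the subsampling series.  NJ branch lengths are clipped at zero;
bootstrap replicates never abort on saturation; branch-length optimization
stops when a sweep improves the total log-likelihood by < 1e-2 (analysis
defaults) with a warning if the sweep budget is exhausted.

## Known limitations

- The generator has no among-site rate variation, no per-branch rate
  variation, and no hybridization/introgression; passing tests show the
  pipeline recovers MSC truth under these conditions, not that real
  organelle data meet them.
- Distance-based NJ is noisy for deep, short branches near JC saturation.
  On the deep coralline fixture, TIGER-ranked subsampling is *not*
  guaranteed to preserve the NJ point topology: the clean signal sites of a
  deep balanced split share one agreement band, so support can collapse
  abruptly (and reappear) along the keep gradient instead of declining
  smoothly as in the published (ML, amino-acid) analysis.  The subsampling
  direction check therefore runs on a shallow eight-taxon control tree with
  one short internal branch, where topology stability and non-increasing
  support hold robustly; the deep-tree trajectory is reported descriptively
  by `analysis/05`.
- The AU fit uses a fixed scale grid and WLS on the probit scale; extreme
  bootstrap proportions are clipped at 1/(2B), which flattens p-values for
  overwhelmingly won/lost comparisons (handled by the special cases above).
- `classify_early_divergence` treats a polytomy at the first ingroup
  bifurcation as unresolved rather than testing each resolution.
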