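"""Minimal phylogenetic inference machinery.

Distances with Jukes–Cantor-type corrections, neighbor joining, pruning
(Felsenstein) likelihood under equal-frequency models, nonparametric
bootstrap supports, RELL-based topology tests (KH / SH / AU with multiscale
bootstrap), and TIGER-style site-agreement rates with rate-ranked
subsampling.

Deliberately small model set: JC for nucleotides, a Poisson model (uniform
exchangeabilities, frequencies 1/20) for amino acids.  The equal-frequency
k-state transition probability has only two distinct entries,

    P(same)  = 1/k + (1 - 1/k) * exp(-k t / (k-1))
    P(other) = (1 - P(same)) / (k - 1)

which keeps the pruning recursion a pair of axpy operations per edge.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

import dendropy

from . import treeio

__all__ = [
    "Alignment",
    "SiteLikelihoodMatrix",
    "TopologyTestResult",
    "SiteRateProfile",
    "SaturationError",
    "read_fasta",
    "write_fasta",
    "p_distance",
    "jc_distance",
    "poisson_distance",
    "distance_matrix",
    "neighbor_joining",
    "felsenstein_loglik",
    "optimize_branch_lengths",
    "bootstrap_supports",
    "rell_topology_test",
    "kh_test_pair",
    "tiger_site_rates",
    "subsample_by_rate",
]

NT_ALPHABET = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = set("-?.NnXx*")


class SaturationError(ValueError):
    """Observed divergence exceeds the correction's domain (p >= (k-1)/k)."""


# ---------------------------------------------------------------------------
# alignment container and FASTA IO


@dataclass
class Alignment:
    """A multiple sequence alignment: unique labels, equal-length rows."""

    labels: list
    sequences: list
    alphabet: str = NT_ALPHABET

    def __post_init__(self):
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in number")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")
        lens = {len(s) for s in self.sequences}
        if len(lens) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lens)}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def state_matrix(self) -> np.ndarray:
        """(n_taxa, n_sites) int8 matrix; -1 marks gap/ambiguity."""
        lut = np.full(256, -1, dtype=np.int8)
        for i, ch in enumerate(self.alphabet):
            lut[ord(ch)] = i
        raw = np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_taxa, self.n_sites)
        return lut[raw]

    def take_sites(self, idx) -> "Alignment":
        idx = list(idx)
        return Alignment(
            list(self.labels),
            ["".join(s[i] for i in idx) for s in self.sequences],
            self.alphabet,
        )

    def subset(self, labels) -> "Alignment":
        keep = [i for i, l in enumerate(self.labels) if l in set(labels)]
        return Alignment(
            [self.labels[i] for i in keep],
            [self.sequences[i] for i in keep],
            self.alphabet,
        )


def read_fasta(path, alphabet: str = NT_ALPHABET) -> Alignment:
    from Bio import SeqIO

    labels, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(rec.id)
        seqs.append(str(rec.seq))
    if not labels:
        raise ValueError(f"no sequences in {path}")
    return Alignment(labels, seqs, alphabet)


def write_fasta(aln: Alignment, path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for label, seq in zip(aln.labels, aln.sequences):
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# distances


def _comparable_mask(sa: np.ndarray, sb: np.ndarray) -> np.ndarray:
    return (sa >= 0) & (sb >= 0)


def p_distance(a: str, b: str, alphabet: str = NT_ALPHABET) -> float:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    aln = Alignment(["a", "b"], [a, b], alphabet)
    s = aln.state_matrix()
    mask = _comparable_mask(s[0], s[1])
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no comparable (non-gap) site pairs")
    return float((s[0][mask] != s[1][mask]).sum() / n)


def _correct(p: float, k: int) -> float:
    limit = (k - 1) / k
    if p >= limit:
        raise SaturationError(f"p = {p:.4f} >= {limit:.4f}: distance undefined")
    return -limit * math.log(1.0 - p / limit)


def jc_distance(a: str, b: str) -> float:
    """Jukes–Cantor distance d = -(3/4) ln(1 - (4/3) p) for nucleotides."""
    return _correct(p_distance(a, b, NT_ALPHABET), 4)


def poisson_distance(a: str, b: str) -> float:
    """Poisson-corrected distance d = -(19/20) ln(1 - (20/19) p) for amino acids."""
    return _correct(p_distance(a, b, AA_ALPHABET), 20)


def distance_matrix(
    aln: Alignment, saturation: str = "error", cap: float = 5.0
) -> np.ndarray:
    """Pairwise corrected distances.  ``saturation``: "error" or "cap".

    "cap" replaces an undefined (saturated) distance by ``cap``; bootstrap
    replicates use this so a resample that saturates one pair does not abort
    the replicate.
    """
    k = len(aln.alphabet)
    s = aln.state_matrix()
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = _comparable_mask(s[i], s[j])
            m = int(mask.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {aln.labels[i]} and {aln.labels[j]}"
                )
            p = float((s[i][mask] != s[j][mask]).sum() / m)
            try:
                d[i, j] = d[j, i] = _correct(p, k)
            except SaturationError:
                if saturation == "cap":
                    d[i, j] = d[j, i] = cap
                else:
                    raise
    return d


# ---------------------------------------------------------------------------
# neighbor joining


def _nj_topology(d: np.ndarray):
    """Run NJ, returning (children, lengths, leafsets) over node ids.

    Node ids 0..n-1 are leaves; internal nodes are appended.  The final node
    is the unrooted base (trifurcation for n >= 3).  Branch lengths are
    clipped at zero (standard practice for slightly non-additive input).
    """
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix not symmetric")
    D = d.astype(float).copy()
    active = list(range(n))
    children: dict = {}
    lengths: dict = {}
    next_id = n
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = divmod(int(np.argmin(q)), m)
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = next_id
        next_id += 1
        children[new] = [i, j]
        lengths[i], lengths[j] = li, lj
        row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[new, :-1] = row
        D[:-1, new] = row
        D[new, new] = 0.0
        active = [a for a in active if a not in (i, j)] + [new]
    i, j, k = active
    root = next_id
    children[root] = [i, j, k]
    lengths[i] = max(0.5 * (D[i, j] + D[i, k] - D[j, k]), 0.0)
    lengths[j] = max(0.5 * (D[i, j] + D[j, k] - D[i, k]), 0.0)
    lengths[k] = max(0.5 * (D[i, k] + D[j, k] - D[i, j]), 0.0)

    leafsets: dict = {i: frozenset([i]) for i in range(n)}
    order = sorted(children)  # creation order = valid postorder
    for node in order:
        leafsets[node] = frozenset().union(*(leafsets[c] for c in children[node]))
    return children, lengths, leafsets, root


def _nj_splits(d: np.ndarray) -> set:
    """Nontrivial splits (frozensets of leaf indices, canonical: containing 0)."""
    n = d.shape[0]
    children, _, leafsets, root = _nj_topology(d)
    full = frozenset(range(n))
    out = set()
    for node, ls in leafsets.items():
        if node < n or node == root:
            continue
        if len(ls) < 2 or len(full - ls) < 2:
            continue
        out.add(ls if 0 in ls else full - ls)
    return out


def neighbor_joining(d: np.ndarray, labels) -> dendropy.Tree:
    """Unrooted NJ tree; exact on additive matrices."""
    labels = list(labels)
    children, lengths, _, root = _nj_topology(np.asarray(d, dtype=float))

    def build(node):
        if node < len(labels):
            return f"{labels[node]}:{lengths.get(node, 0.0):.10f}"
        inner = ",".join(build(c) for c in children[node])
        if node == root:
            return f"({inner});"
        return f"({inner}):{lengths.get(node, 0.0):.10f}"

    return treeio.parse_newick(build(root))


# ---------------------------------------------------------------------------
# pruning likelihood


def _transition_pair(t: float, k: int):
    if t < 0:
        raise ValueError(f"negative branch length {t}")
    e = math.exp(-k * t / (k - 1))
    p_same = 1.0 / k + (1.0 - 1.0 / k) * e
    p_diff = (1.0 - p_same) / (k - 1)
    return p_same, p_diff


def felsenstein_loglik(
    tree: dendropy.Tree, aln: Alignment, model: str = "jc"
) -> np.ndarray:
    """Per-site log-likelihoods by the pruning algorithm.

    ``model``: "jc" (nucleotide, k=4) or "poisson" (amino acid, k=20), both
    with uniform stationary frequencies.  Gaps and ambiguity codes are missing
    data (partial likelihood 1 in every state).  Missing branch lengths are an
    error; the likelihood is invariant under the position of the root (pulley
    principle), which the tests verify numerically.
    """
    k = 4 if model == "jc" else len(AA_ALPHABET)
    if model == "poisson" and aln.alphabet != AA_ALPHABET:
        aln = Alignment(aln.labels, aln.sequences, AA_ALPHABET)
    states = aln.state_matrix()
    row = {lab: i for i, lab in enumerate(aln.labels)}
    S = aln.n_sites

    eye = np.eye(k)
    log_scale = np.zeros(S)

    def partial(node) -> np.ndarray:
        if node.is_leaf():
            lab = node.taxon.label
            if lab not in row:
                raise ValueError(f"taxon {lab!r} missing from alignment")
            st = states[row[lab]]
            L = np.ones((k, S))
            known = st >= 0
            L[:, known] = eye[:, st[known]]
            return L
        L = np.ones((k, S))
        for ch in node.child_nodes():
            t = ch.edge.length
            if t is None:
                raise ValueError("branch length missing")
            p_same, p_diff = _transition_pair(float(t), k)
            Lc = partial(ch)
            # (P @ Lc) with the two-valued JC-type matrix
            tot = Lc.sum(axis=0)
            L *= p_diff * tot[None, :] + (p_same - p_diff) * Lc
        mx = L.max(axis=0)
        mx[mx == 0] = 1.0
        log_scale[:] += np.log(mx)
        return L / mx

    Lroot = partial(tree.seed_node)
    site = Lroot.mean(axis=0)  # uniform frequencies 1/k
    return np.log(site) + log_scale.copy()


def optimize_branch_lengths(
    tree: dendropy.Tree,
    aln: Alignment,
    model: str = "jc",
    tolerance: float = 1e-4,
    max_sweeps: int = 20,
    max_length: float = 10.0,
) -> dendropy.Tree:
    """Coordinate-wise branch-length optimization (bounded Brent per edge).

    Sweeps over edges until the total log-likelihood improves by less than
    ``tolerance``; the likelihood is non-decreasing across sweeps.  Returns a
    new tree (the input is not modified).
    """
    work = treeio.parse_newick(treeio.write_newick(tree, precision=17))
    edges = [
        nd for nd in work.preorder_node_iter() if nd is not work.seed_node
    ]
    for nd in edges:
        if nd.edge.length is None:
            nd.edge.length = 0.1

    def total() -> float:
        return float(felsenstein_loglik(work, aln, model).sum())

    best = total()
    for _ in range(max_sweeps):
        before = best
        for nd in edges:
            old = nd.edge.length

            def neg(t, _nd=nd):
                _nd.edge.length = float(t)
                return -float(felsenstein_loglik(work, aln, model).sum())

            res = optimize.minimize_scalar(
                neg, bounds=(0.0, max_length), method="bounded",
                options={"xatol": max(tolerance * 1e-2, 1e-8)},
            )
            cand = -res.fun
            if cand >= best:
                nd.edge.length = float(res.x)
                best = cand
            else:  # keep previous length
                nd.edge.length = old
        if best - before < tolerance:
            break
    else:
        warnings.warn("branch-length optimization did not converge", RuntimeWarning)
    return work


# ---------------------------------------------------------------------------
# bootstrap supports


def bootstrap_supports(
    aln: Alignment, n_reps: int, seed, model: str = "jc"
) -> dendropy.Tree:
    """NJ point tree with internal edges annotated by bootstrap percents.

    Nonparametric bootstrap: sites resampled with replacement, the tree
    rebuilt by NJ on corrected distances, and each internal edge of the point
    tree scored by the percent of replicates whose tree contains its split.
    Saturated replicate distances are capped rather than discarded so every
    replicate counts.  Bit-reproducible for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps >= 1 required")
    rng = np.random.default_rng(seed)
    k = len(aln.alphabet)
    limit = (k - 1) / k
    s = aln.state_matrix()
    n, S = s.shape

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    diff = np.empty((len(pairs), S))
    valid = np.empty((len(pairs), S))
    for idx, (i, j) in enumerate(pairs):
        mask = _comparable_mask(s[i], s[j])
        valid[idx] = mask
        diff[idx] = mask & (s[i] != s[j])

    def dist_from_weights(w: np.ndarray) -> np.ndarray:
        num = diff @ w
        den = valid @ w
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(den > 0, num / np.maximum(den, 1e-300), limit)
        d = np.empty(len(pairs))
        for idx, p_ij in enumerate(p):
            if p_ij >= limit:
                d[idx] = 5.0
            else:
                d[idx] = -limit * math.log(1.0 - p_ij / limit)
        D = np.zeros((n, n))
        for idx, (i, j) in enumerate(pairs):
            D[i, j] = D[j, i] = d[idx]
        return D

    point_D = distance_matrix(aln, saturation="cap")
    point_tree = neighbor_joining(point_D, aln.labels)
    point_splits = _nj_splits(point_D)

    counts = {sp: 0 for sp in point_splits}
    for _ in range(n_reps):
        w = rng.multinomial(S, np.full(S, 1.0 / S)).astype(float)
        rep_splits = _nj_splits(dist_from_weights(w))
        for sp in counts:
            if sp in rep_splits:
                counts[sp] += 1

    # attach percents to the point tree's internal nodes
    all_taxa = treeio.leaf_labels(point_tree)
    label_index = {lab: i for i, lab in enumerate(aln.labels)}
    sets = treeio._node_leafsets(point_tree)
    for nd in point_tree.preorder_node_iter():
        if nd.is_leaf() or nd is point_tree.seed_node:
            continue
        below = sets[nd]
        if len(below) < 2 or len(all_taxa - below) < 2:
            continue
        idx = frozenset(label_index[l] for l in below)
        if 0 not in idx:
            idx = frozenset(range(n)) - idx
        if idx in counts:
            treeio.set_support(nd, round(100.0 * counts[idx] / n_reps))
    return point_tree


# ---------------------------------------------------------------------------
# RELL topology tests


@dataclass
class SiteLikelihoodMatrix:
    """Per-site log-likelihoods for a set of candidate topologies."""

    names: list
    loglik: np.ndarray  # (n_topologies, n_sites)

    def __post_init__(self):
        self.loglik = np.asarray(self.loglik, dtype=float)
        if self.loglik.ndim != 2:
            raise ValueError("loglik must be 2-D (topology x site)")
        if len(self.names) != self.loglik.shape[0]:
            raise ValueError("one name per topology required")
        if not np.all(np.isfinite(self.loglik)):
            raise ValueError("non-finite site log-likelihoods")

    @property
    def n_sites(self) -> int:
        return self.loglik.shape[1]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.loglik, index=self.names).to_csv(
            path, sep="\t", header=False
        )

    @classmethod
    def from_tsv(cls, path) -> "SiteLikelihoodMatrix":
        df = pd.read_csv(path, sep="\t", header=None, index_col=0)
        return cls([str(i) for i in df.index], df.to_numpy(dtype=float))


@dataclass
class TopologyTestResult:
    names: list
    loglik: np.ndarray       # total per topology
    delta: np.ndarray        # best minus own
    p_kh: np.ndarray
    p_sh: np.ndarray
    p_au: np.ndarray
    n_reps: int
    seed: object

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "topology": self.names,
                "loglik": self.loglik,
                "delta": self.delta,
                "p_KH": self.p_kh,
                "p_SH": self.p_sh,
                "p_AU": self.p_au,
            }
        )


DEFAULT_AU_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2))


def _rell_sums(M: np.ndarray, n_reps: int, rng, n_draw: int | None = None):
    """(n_reps, n_topologies) resampled total log-likelihoods."""
    T, S = M.shape
    n_draw = S if n_draw is None else n_draw
    counts = rng.multinomial(n_draw, np.full(S, 1.0 / S), size=n_reps)
    return counts.astype(float) @ M.T


def kh_test_pair(
    M: SiteLikelihoodMatrix, i: int, j: int, n_reps: int = 1000, seed=0
) -> float:
    """One-sided KH p-value for topology ``j`` against topology ``i``.

    Tests H0 E[l_i - l_j] = 0 against the alternative that ``i`` is better,
    with the null distribution of the statistic obtained by centering the
    RELL bootstrap distribution of the log-likelihood difference.  For a
    pre-specified pair (no best-tree selection) this p-value is calibrated.
    """
    rng = np.random.default_rng(seed)
    delta_obs = float(M.loglik[i].sum() - M.loglik[j].sum())
    sums = _rell_sums(M.loglik[[i, j], :], n_reps, rng)
    d = sums[:, 0] - sums[:, 1]
    centered = d - d.mean()
    return float(np.mean(centered >= delta_obs))


def rell_topology_test(
    M: SiteLikelihoodMatrix,
    n_reps: int = 1000,
    seed=0,
    scales=DEFAULT_AU_SCALES,
) -> TopologyTestResult:
    """KH, SH, and AU tests for every topology via RELL resampling.

    KH and SH p-values use centered bootstrap nulls against the ML (best)
    topology; the AU p-value comes from the multiscale bootstrap: bootstrap
    proportions BP(r) at relative sample sizes r are fit on the probit scale
    to z(r) = d*sqrt(r) + c/sqrt(r) by weighted least squares (binomial
    weights), giving p_AU = 1 - Phi(d - c).
    """
    if M.loglik.shape[0] < 2:
        raise ValueError("need >= 2 topologies")
    if n_reps < 100:
        raise ValueError("n_reps >= 100 required")
    rng = np.random.default_rng(seed)
    L = M.loglik
    T, S = L.shape
    totals = L.sum(axis=1)
    best = int(np.argmax(totals))
    delta = totals[best] - totals

    sums = _rell_sums(L, n_reps, rng)  # (B, T)
    centered = sums - sums.mean(axis=0, keepdims=True)

    p_kh = np.empty(T)
    p_sh = np.empty(T)
    max_centered = centered.max(axis=1)
    for t in range(T):
        d_bt = centered[:, best] - centered[:, t]
        p_kh[t] = np.mean(d_bt >= delta[t])
        p_sh[t] = np.mean(max_centered - centered[:, t] >= delta[t])

    # multiscale bootstrap for AU; exact ties share the win equally
    scales = np.asarray(list(scales), dtype=float)
    bp = np.zeros((len(scales), T))
    for si, r in enumerate(scales):
        n_draw = max(1, int(round(r * S)))
        sums_r = _rell_sums(L, n_reps, rng, n_draw)
        is_max = sums_r == sums_r.max(axis=1, keepdims=True)
        share = is_max / is_max.sum(axis=1, keepdims=True)
        bp[si] = share.sum(axis=0) / n_reps

    p_au = np.empty(T)
    eps = 1.0 / (2.0 * n_reps)
    for t in range(T):
        bp_t = bp[:, t]
        if np.all(bp_t <= 0):
            warnings.warn(
                f"topology {M.names[t]!r}: BP zero at every scale; degenerate AU fit",
                RuntimeWarning,
            )
            p_au[t] = 0.0
            continue
        if np.all(bp_t >= 1.0):
            p_au[t] = 1.0  # wins every replicate at every scale
            continue
        b = np.clip(bp_t, eps, 1.0 - eps)
        z = stats.norm.ppf(1.0 - b)  # z(r) = d sqrt(r) + c / sqrt(r)
        sr = np.sqrt(scales)
        X = np.column_stack([sr, 1.0 / sr])
        w = n_reps * stats.norm.pdf(z) ** 2 / (b * (1.0 - b))
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * W[:, None], z * W, rcond=None)
        d_hat, c_hat = coef
        p_au[t] = float(np.clip(1.0 - stats.norm.cdf(d_hat - c_hat), 0.0, 1.0))

    return TopologyTestResult(
        list(M.names), totals, delta, p_kh, p_sh, p_au, n_reps, seed
    )


# ---------------------------------------------------------------------------
# TIGER site rates


@dataclass
class SiteRateProfile:
    """Per-site agreement scores in [0, 1]; 1 = perfectly concordant site."""

    rates: np.ndarray

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)

    @property
    def ranking(self) -> np.ndarray:
        """Site indices from most to least conserved (stable in ties)."""
        return np.argsort(-self.rates, kind="stable")


def _site_partition(column: np.ndarray, gaps: str) -> tuple:
    """Partition of taxon indices by character state, as sorted bitmasks.

    ``gaps``: "exclude" drops gap/ambiguous taxa from the partition;
    "state" treats the gap symbol as one more character state.
    """
    groups: dict = {}
    for taxon, state in enumerate(column):
        if state < 0 and gaps == "exclude":
            continue
        groups.setdefault(int(state), 0)
        groups[int(state)] |= 1 << taxon
    return tuple(sorted(groups.values()))


def _pa(part_i: tuple, part_j: tuple) -> float:
    """Proportion of sets in partition j nested within some set of partition i."""
    if not part_j:
        return 1.0
    hits = 0
    for b in part_j:
        for a in part_i:
            if b & a == b:
                hits += 1
                break
    return hits / len(part_j)


def tiger_site_rates(aln: Alignment, gaps: str = "exclude") -> SiteRateProfile:
    """TIGER-style per-site agreement rates.

    Each site induces a partition of the taxa by character state; the
    agreement of site i with site j is the proportion of j's sets nested
    within some set of i's partition, and a site's rate is its mean agreement
    with all other sites.  Constant sites score 1; low scores mark fast,
    pattern-discordant sites.  Identical site patterns are deduplicated
    before the quadratic pass, which makes the computation cheap on long
    alignments with few taxa.
    """
    if aln.n_sites < 2:
        raise ValueError("need >= 2 sites")
    if aln.n_taxa < 3:
        raise ValueError("need >= 3 taxa")
    s = aln.state_matrix()
    S = aln.n_sites
    parts = [_site_partition(s[:, j], gaps) for j in range(S)]

    uniq: dict = {}
    site_of: np.ndarray = np.empty(S, dtype=int)
    for j, p in enumerate(parts):
        site_of[j] = uniq.setdefault(p, len(uniq))
    uparts = list(uniq)
    U = len(uparts)
    counts = np.bincount(site_of, minlength=U).astype(float)

    pa = np.empty((U, U))
    for i in range(U):
        for j in range(U):
            pa[i, j] = _pa(uparts[i], uparts[j])

    # rate(i) = mean over all sites j != i of pa(i, j), via unique-class sums
    totals = pa @ counts  # includes j == i (pa = 1 for identical patterns)
    rates = np.empty(S)
    for j in range(S):
        u = site_of[j]
        rates[j] = (totals[u] - 1.0) / (S - 1)
    return SiteRateProfile(rates)


def subsample_by_rate(
    aln: Alignment, profile: SiteRateProfile, keep_proportion: float
) -> Alignment:
    """Keep the ceil(keep * S) most conserved sites, preserving site order."""
    if not 0 < keep_proportion <= 1:
        raise ValueError("keep_proportion in (0, 1] required")
    S = aln.n_sites
    if len(profile.rates) != S:
        raise ValueError("profile length does not match alignment")
    n_keep = math.ceil(keep_proportion * S)
    chosen = sorted(profile.ranking[:n_keep].tolist())
    return aln.take_sites(chosen)
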