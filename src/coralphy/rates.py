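"""Pairwise dN/dS by codon counting and rank-sum comparison of rate distributions.

Nonsynonymous and synonymous substitution rates are estimated by the
Nei–Gojobori (1986) counting method with a Jukes–Cantor-type multiple-hit
correction: synonymous site counts are per-codon averages of the synonymous
fraction of the three possible changes at each position, differences between
codons are averaged over all minimal substitution pathways (pathways through
stop codons excluded), and the raw proportions pN = Nd/N, pS = Sd/S are
corrected by d = -(3/4) ln(1 - (4/3) p).  Organelle genes use NCBI codon
table 4 (mold/protozoan mitochondrial, TGA = Trp) or table 11 (plastid /
bacterial).

Lineage-level comparisons of dN distributions use the two-sided Wilcoxon
rank-sum (Mann–Whitney) test: exact enumeration for small tie-free samples,
normal approximation with tie and continuity corrections otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from scipy import stats

from Bio.Data import CodonTable

__all__ = [
    "RateEstimate",
    "RankSumResult",
    "translate",
    "nei_gojobori_dnds",
    "wilcoxon_rank_sum",
]

_BASES = "TCAG"
_SKIP_CHARS = set("-?NnXx")


@dataclass
class RateEstimate:
    pair: tuple
    n_sites: float        # nonsynonymous sites N
    s_sites: float        # synonymous sites S
    nd: float             # observed nonsynonymous differences
    sd: float             # observed synonymous differences
    pn: float
    ps: float
    dn: float             # nan when saturated (p >= 3/4)
    ds: float
    codon_table: int
    n_codons: int         # codons actually compared (gap/ambiguous skipped)


@dataclass
class RankSumResult:
    statistic: float
    p_value: float
    n_x: int
    n_y: int
    method: str

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def _table(table_id: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[int(table_id)]


def translate(cds: str, table: int) -> str:
    """Translate a CDS; internal stops appear as '*' rather than raising."""
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    tab = _table(table)
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in tab.stop_codons:
            out.append("*")
        else:
            out.append(tab.forward_table.get(codon, "X"))
    return "".join(out)


def _aa(codon: str, tab) -> str | None:
    """Amino acid for a codon, or None for a stop codon."""
    if codon in tab.stop_codons:
        return None
    return tab.forward_table[codon]


def _codon_site_counts(codon: str, tab) -> float:
    """Synonymous site count of one codon: sum of synonymous change fractions."""
    aa = _aa(codon, tab)
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _aa(alt, tab) is not None and _aa(alt, tab) == aa:
                syn += 1
        s += syn / 3.0
    return s


def _pathway_counts(a: str, b: str, tab) -> tuple:
    """(syn, nonsyn) differences between codons, averaged over minimal pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked (possible for triple changes through dense stop neighborhoods),
    stop-traversing pathways are readmitted so the difference is still
    counted.
    """
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order, allow_stops):
        syn = nonsyn = 0.0
        cur = a
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if _aa(nxt, tab) is None and not allow_stops:
                return None
            if _aa(nxt, tab) is not None and _aa(cur, tab) is not None and \
                    _aa(nxt, tab) == _aa(cur, tab):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        return syn, nonsyn

    for allow_stops in (False, True):
        results = [
            r
            for order in itertools.permutations(diff_pos)
            if (r := walk(order, allow_stops)) is not None
        ]
        if results:
            syn = sum(r[0] for r in results) / len(results)
            nonsyn = sum(r[1] for r in results) / len(results)
            return syn, nonsyn
    raise AssertionError("unreachable")


def _jc_correct(p: float) -> float:
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori_dnds(
    a: str, b: str, table: int = 4, pair=("a", "b")
) -> RateEstimate:
    """Nei–Gojobori counting estimate of dN and dS between two aligned CDSs.

    Codons containing gaps or ambiguity in either sequence are skipped
    pairwise; codons that are stop codons in either sequence are likewise
    skipped.  Saturated rates (raw proportion >= 3/4) come back as NaN.
    """
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3:
        raise ValueError(f"length {len(a)} not divisible by 3")
    tab = _table(table)

    S = N = sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if any(ch in _SKIP_CHARS for ch in ca + cb):
            continue
        if any(ch not in "ACGT" for ch in ca + cb):
            continue
        if _aa(ca, tab) is None or _aa(cb, tab) is None:
            continue
        n_codons += 1
        S += 0.5 * (_codon_site_counts(ca, tab) + _codon_site_counts(cb, tab))
        s_d, n_d = _pathway_counts(ca, cb, tab)
        sd += s_d
        nd += n_d
    if n_codons == 0:
        raise ValueError("no comparable codons (all gapped/ambiguous/stop)")
    N = 3.0 * n_codons - S

    pn = nd / N if N > 0 else 0.0
    ps = sd / S if S > 0 else 0.0
    return RateEstimate(
        pair=tuple(pair),
        n_sites=N,
        s_sites=S,
        nd=nd,
        sd=sd,
        pn=pn,
        ps=ps,
        dn=_jc_correct(pn),
        ds=_jc_correct(ps),
        codon_table=int(table),
        n_codons=n_codons,
    )


def wilcoxon_rank_sum(xs, ys) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact enumeration when the combined sample size is at most 12 and there
    are no ties; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    xs, ys = list(xs), list(ys)
    if not xs or not ys:
        raise ValueError("both samples must be nonempty")
    pooled = xs + ys
    has_ties = len(set(pooled)) < len(pooled)
    if not has_ties and len(pooled) <= 12:
        method = "exact"
        res = stats.mannwhitneyu(xs, ys, alternative="two-sided", method="exact")
    else:
        method = "normal"
        res = stats.mannwhitneyu(
            xs, ys, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
    return RankSumResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_x=len(xs),
        n_y=len(ys),
        method=method,
    )
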