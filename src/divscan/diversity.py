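"""Per-gene diversity and divergence estimators.

theta_pi is the unbiased average pairwise difference (sum over the
n(n-1)/2 sequence pairs, divided by the number of pairs and by the number of
retained sites); theta_w is Watterson's S/(a1*L).  Divergence D_xy averages,
over ingroup rows, the per-row proportion of differences to the outgroup
consensus, renormalizing by the sites where the consensus is resolved.
K_a/K_s counts consensus-vs-consensus coding differences with Nei-Gojobori
pathway averaging and fractional site denominators.

All per-site quantities are NaN when their denominator is empty; genes with
no variation legitimately report 0 (not NaN) when sites exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .alignment import FilteredAlignment, consensus_at
from .annotation import (
    CAT_NONCODING,
    CAT_NONSYN,
    CAT_SYN,
    CodingInterval,
    SiteAnnotation,
    codon_map,
    syn_fraction,
    translate_codon,
)

_BASES = "ACGT"


def harmonic(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i."""
    return sum(1.0 / i for i in range(1, n))


def harmonic2(n: int) -> float:
    """a2 = sum_{i=1}^{n-1} 1/i^2."""
    return sum(1.0 / i**2 for i in range(1, n))


def segregating_sites(f: FilteredAlignment) -> int:
    """Number of retained columns with exactly two ingroup alleles."""
    return int(f.variant_mask().sum())


def pairwise_diff_sums(f: FilteredAlignment) -> np.ndarray:
    """Per retained column, the number of sequence pairs that differ there:
    (n^2 - sum_a c_a^2)/2."""
    counts = f.allele_counts().astype(np.int64)
    n = f.n
    return (n * n - (counts**2).sum(axis=0)) / 2.0


def theta_pi_locus(f: FilteredAlignment) -> float:
    """Average pairwise differences per *locus* (not per site)."""
    n = f.n
    npairs = n * (n - 1) / 2.0
    return float(pairwise_diff_sums(f).sum() / npairs)


def theta_pi(f: FilteredAlignment) -> float:
    """Nucleotide diversity per site; NaN when no sites were retained."""
    if f.L == 0:
        return math.nan
    return theta_pi_locus(f) / f.L


def theta_w(f: FilteredAlignment) -> float:
    """Watterson's estimator per site: S / (a1 * L)."""
    if f.L == 0:
        return math.nan
    return segregating_sites(f) / (harmonic(f.n) * f.L)


def dxy(f: FilteredAlignment, consensus: np.ndarray) -> float:
    """Mean over ingroup rows of (differences to the outgroup consensus /
    usable sites); columns where the consensus is unresolved (N) are
    excluded from both numerator and denominator."""
    cons = consensus_at(np.asarray(consensus, dtype="S1"), f)
    valid = np.isin(cons, np.frombuffer(b"ACGT", dtype="S1"))
    usable = int(valid.sum())
    if usable == 0:
        return math.nan
    diffs = (f.matrix[:, valid] != cons[valid][None, :]).sum(axis=1)
    return float(diffs.mean() / usable)


def category_diversity(
    f: FilteredAlignment, ann: SiteAnnotation
) -> tuple[dict[str, float], dict[str, float]]:
    """theta_pi and theta_w restricted to each site category.

    Denominators are the category's fractional site counts; ``silent`` pools
    noncoding and synonymous sites.  Categories with zero sites report NaN.
    """
    n = f.n
    npairs = n * (n - 1) / 2.0
    a1 = harmonic(n)
    per_col = pairwise_diff_sums(f)
    variant = f.variant_mask()
    cats = ann.site_category

    num = {c: 0.0 for c in (CAT_NONCODING, CAT_SYN, CAT_NONSYN)}
    s_count = {c: 0 for c in num}
    for c in num:
        sel = cats == c
        num[c] = float(per_col[sel].sum()) / npairs
        s_count[c] = int((sel & variant).sum())

    sites = {
        CAT_NONCODING: float(ann.noncoding_sites),
        CAT_SYN: ann.syn_sites,
        CAT_NONSYN: ann.nonsyn_sites,
    }
    pi = {}
    tw = {}
    for c in num:
        if sites[c] > 0:
            pi[c] = num[c] / sites[c]
            tw[c] = s_count[c] / (a1 * sites[c])
        else:
            pi[c] = math.nan
            tw[c] = math.nan
    silent_sites = ann.silent_sites
    if silent_sites > 0:
        pi["silent"] = (num[CAT_NONCODING] + num[CAT_SYN]) / silent_sites
        tw["silent"] = (s_count[CAT_NONCODING] + s_count[CAT_SYN]) / (a1 * silent_sites)
    else:
        pi["silent"] = math.nan
        tw["silent"] = math.nan
    return pi, tw


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: float
    nonsyn_diffs: float
    syn_diffs: float
    nonsyn_sites: float
    syn_sites: float


def _pathway_counts(src: str, dst: str, diff_offsets: list[int]) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) step counts over mutational
    pathways from codon ``src`` to ``dst`` through the given offsets,
    excluding pathways that pass through a stop codon.  Falls back to
    independent single-substitution classification when every pathway is
    blocked."""
    paths = []
    for order in permutations(diff_offsets):
        cur = src
        steps = []
        ok = True
        for off in order:
            nxt = cur[:off] + dst[off] + cur[off + 1 :]
            if translate_codon(nxt) == "*" and nxt != dst:
                ok = False
                break
            steps.append((cur, nxt))
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:
        # all pathways hit an intermediate stop: classify changes one by one
        syn = nonsyn = 0.0
        for off in diff_offsets:
            alt = src[:off] + dst[off] + src[off + 1 :]
            if translate_codon(alt) == translate_codon(src) != "*" and translate_codon(alt) != "*":
                syn += 1
            else:
                nonsyn += 1
        return syn, nonsyn
    syn_tot = nonsyn_tot = 0.0
    for steps in paths:
        for cur, nxt in steps:
            a, b = translate_codon(cur), translate_codon(nxt)
            if a == b and a != "*":
                syn_tot += 1
            else:
                nonsyn_tot += 1
    k = len(paths)
    return syn_tot / k, nonsyn_tot / k


def ka_ks(
    f: FilteredAlignment,
    ann: SiteAnnotation | list[CodingInterval],
    outgroup_cons: np.ndarray,
) -> KaKsResult:
    """Nonsynonymous / synonymous divergence between the ingroup consensus
    and the outgroup consensus.

    Only retained coding positions contribute, and only codons where both
    consensus codons are fully resolved sense codons are usable; site
    denominators (Nei-Gojobori fractions on the ingroup-consensus codon) are
    accumulated over the same usable positions so numerator and denominator
    stay matched.  ``ratio`` is NaN when K_s = 0.
    """
    intervals = ann.coding_intervals if isinstance(ann, SiteAnnotation) else ann
    og = np.asarray(outgroup_cons, dtype="S1")
    if og.shape[0] != f.n_original_columns:
        raise ValueError("ka_ks needs a full-length outgroup consensus")
    pos_map, _ = codon_map(intervals, f.n_original_columns)
    retained = set(int(c) for c in f.retained_columns)
    codons = sorted({trip for trip, _ in pos_map.values()})
    syn_sites = nonsyn_sites = 0.0
    syn_diffs = nonsyn_diffs = 0.0
    for trip in codons:
        ing_codon = b"".join(f.consensus_all[list(trip)]).decode("ascii")
        og_codon = b"".join(og[list(trip)]).decode("ascii")
        if any(c not in _BASES for c in ing_codon + og_codon):
            continue
        if translate_codon(ing_codon) == "*" or translate_codon(og_codon) == "*":
            continue
        offs_retained = [off for off, p in enumerate(trip) if p in retained]
        if not offs_retained:
            continue
        for off in offs_retained:
            fsyn = syn_fraction(ing_codon, off)
            syn_sites += fsyn
            nonsyn_sites += 1.0 - fsyn
        diffs = [off for off in offs_retained if ing_codon[off] != og_codon[off]]
        if not diffs:
            continue
        # pathway target: outgroup bases at retained differing offsets only
        dst = list(ing_codon)
        for off in diffs:
            dst[off] = og_codon[off]
        s, ns = _pathway_counts(ing_codon, "".join(dst), diffs)
        syn_diffs += s
        nonsyn_diffs += ns
    ka = nonsyn_diffs / nonsyn_sites if nonsyn_sites > 0 else math.nan
    ks = syn_diffs / syn_sites if syn_sites > 0 else math.nan
    ratio = ka / ks if (ks and not math.isnan(ks) and ks > 0 and not math.isnan(ka)) else math.nan
    return KaKsResult(ka, ks, ratio, nonsyn_diffs, syn_diffs, nonsyn_sites, syn_sites)


@dataclass
class GeneDiversity:
    """Diversity/divergence record for one gene (NaN marks undefined)."""

    gene_id: str
    n: int
    L: int
    S: int
    theta_pi: float
    theta_w: float
    dxy: float
    pi_by_category: dict[str, float] = field(default_factory=dict)
    thetaw_by_category: dict[str, float] = field(default_factory=dict)
    ka: float = math.nan
    ks: float = math.nan
    ratio_pia_pis: float = math.nan
    ratio_ka_ks: float = math.nan
    kaks_raw: KaKsResult | None = None


def compute_gene_diversity(
    f: FilteredAlignment,
    ann: SiteAnnotation | None = None,
    outgroup_cons: np.ndarray | None = None,
) -> GeneDiversity:
    """Assemble the full per-gene diversity record, tolerating missing
    annotation (category stats NaN) and missing outgroup (divergence NaN)."""
    gd = GeneDiversity(
        gene_id=f.gene_id,
        n=f.n,
        L=f.L,
        S=segregating_sites(f) if f.L else 0,
        theta_pi=theta_pi(f),
        theta_w=theta_w(f),
        dxy=dxy(f, outgroup_cons) if (outgroup_cons is not None and f.L) else math.nan,
    )
    if ann is not None and f.L:
        gd.pi_by_category, gd.thetaw_by_category = category_diversity(f, ann)
        pia = gd.pi_by_category.get(CAT_NONSYN, math.nan)
        pis = gd.pi_by_category.get(CAT_SYN, math.nan)
        gd.ratio_pia_pis = pia / pis if (pis and pis > 0) else math.nan
        if outgroup_cons is not None:
            kk = ka_ks(f, ann, outgroup_cons)
            gd.ka, gd.ks, gd.ratio_ka_ks, gd.kaks_raw = kk.ka, kk.ks, kk.ratio, kk
    else:
        gd.pi_by_category = {c: math.nan for c in (CAT_NONCODING, CAT_SYN, CAT_NONSYN, "silent")}
        gd.thetaw_by_category = dict(gd.pi_by_category)
    return gd
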