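"""The four per-gene neutrality statistics and outgroup polarization.

* Tajima's D — normalized difference between pairwise diversity and the
  Watterson estimator (Tajima 1989 constants).
* Fay & Wu's normalized H — contrast between pairwise diversity and the
  high-frequency-weighted estimator theta_L, normalized by the Zeng et al.
  (2006) variance estimator; needs derived states from the outgroup.
* Ewens-Watterson F — haplotype homozygosity sum(p_k^2) over distinct rows
  of the filtered matrix (complete data, so no missing-haplotype policy).
* Kelly's Z_nS — mean pairwise r^2 over segregating sites; label-invariant.

P-value conventions live in :mod:`divscan.coalescent`; here only the
observed statistics are computed.  All four are NaN when undefined (S = 0,
no polarizable sites, or S < 2 for Z_nS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment import FilteredAlignment, consensus_at
from .diversity import harmonic, harmonic2, theta_pi_locus


@dataclass
class PolarizedSpectrum:
    """Unfolded site-frequency spectrum for polarizable segregating sites.

    ``counts[k]`` is the derived-allele count (1..n-1) at the k-th
    polarizable site; ``unpolarized`` counts segregating sites where the
    outgroup consensus is missing or matches neither ingroup allele.
    """

    n: int
    counts: np.ndarray
    unpolarized: int = 0

    @property
    def n_polarized(self) -> int:
        return len(self.counts)


def polarize(f: FilteredAlignment, consensus: np.ndarray) -> PolarizedSpectrum:
    """Infer derived-allele counts using the outgroup consensus as the
    ancestral state; third-allele or unresolved-consensus sites are tallied
    as unpolarized."""
    cons = consensus_at(np.asarray(consensus, dtype="S1"), f)
    counts4 = f.allele_counts()
    variant_cols = np.flatnonzero(f.variant_mask())
    derived = []
    unpolarized = 0
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for j in variant_cols:
        present = np.flatnonzero(counts4[:, j])
        a, b = bases[present[0]], bases[present[1]]
        anc = cons[j]
        if anc == a:
            derived.append(int(counts4[present[1], j]))
        elif anc == b:
            derived.append(int(counts4[present[0], j]))
        else:
            unpolarized += 1
    return PolarizedSpectrum(
        n=f.n, counts=np.asarray(derived, dtype=np.int64), unpolarized=unpolarized
    )


def tajima_d(S: int, pi_locus: float, n: int) -> float:
    """Tajima's D from the segregating-site count and per-locus pairwise
    diversity; NaN for S = 0 or n < 2."""
    if S == 0 or n < 2:
        return math.nan
    a1 = harmonic(n)
    a2 = harmonic2(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    denom = math.sqrt(e1 * S + e2 * S * (S - 1))
    if denom == 0:
        return math.nan
    return (pi_locus - S / a1) / denom


def theta_l(counts: np.ndarray, n: int) -> float:
    """Zeng et al.'s theta_L = sum(i * S_i) / (n - 1) over polarizable
    sites."""
    return float(np.sum(counts)) / (n - 1)


def _pi_from_counts(counts: np.ndarray, n: int) -> float:
    i = np.asarray(counts, dtype=float)
    return float((2.0 * i * (n - i)).sum() / (n * (n - 1)))


def fay_wu_h_var(n: int, S: int) -> float:
    """Variance of (theta_pi - theta_L) under neutrality, Zeng et al. (2006),
    with theta estimated by S/a1 and theta^2 by S(S-1)/(a1^2 + a2)."""
    an = harmonic(n)
    bn = harmonic2(n)
    bn1 = bn + 1.0 / n**2  # sum_{i=1}^{n} 1/i^2
    theta_w = S / an
    theta_sq = S * (S - 1) / (an**2 + bn)
    term1 = (n - 2) / (6.0 * (n - 1)) * theta_w
    term2 = (
        (18.0 * n**2 * (3 * n + 2) * bn1 - (88.0 * n**3 + 9 * n**2 - 13 * n + 6))
        / (9.0 * n * (n - 1) ** 2)
    ) * theta_sq
    return term1 + term2


def fay_wu_h(
    spectrum: PolarizedSpectrum,
    pi_locus: float | None = None,
    normalized: bool = True,
) -> float:
    """Fay & Wu's H from the polarized spectrum.

    With ``pi_locus`` omitted, pairwise diversity is computed from the
    polarizable sites themselves (so dropping unpolarized sites affects both
    terms consistently).  ``normalized=False`` returns the raw numerator
    theta_pi - theta_L for debugging."""
    n = spectrum.n
    S = spectrum.n_polarized
    if S == 0:
        return math.nan
    pi = _pi_from_counts(spectrum.counts, n) if pi_locus is None else pi_locus
    num = pi - theta_l(spectrum.counts, n)
    if not normalized:
        return num
    var = fay_wu_h_var(n, S)
    if var <= 0:
        return math.nan
    return num / math.sqrt(var)


def _row_matrix(x) -> np.ndarray:
    if isinstance(x, FilteredAlignment):
        return x.matrix
    return np.asarray(x)


def ewens_watterson_f(x) -> float:
    """Haplotype homozygosity sum(p_k^2) over distinct full rows.

    Accepts a :class:`FilteredAlignment` or any 2-D row matrix.  A matrix
    with zero columns has a single haplotype, F = 1."""
    mat = _row_matrix(x)
    n = mat.shape[0]
    if mat.shape[1] == 0:
        return 1.0
    _, counts = np.unique(mat, axis=0, return_counts=True)
    p = counts / n
    return float((p**2).sum())


def kelly_zns(x) -> float:
    """Mean r^2 over all pairs of segregating sites; NaN for S < 2."""
    if isinstance(x, FilteredAlignment):
        mat = x.binary_matrix().astype(float)
    else:
        mat = np.asarray(x, dtype=float)
        seg = (mat.var(axis=0) > 0)
        mat = mat[:, seg]
    S = mat.shape[1]
    if S < 2:
        return math.nan
    r = np.corrcoef(mat, rowvar=False)
    iu = np.triu_indices(S, k=1)
    return float((r[iu] ** 2).mean())


@dataclass
class NeutralityResult:
    """Observed statistics plus lower-tail simulation P-values for one gene.

    All four P-values use the lower tail P(stat_sim <= stat_obs); excess
    haplotype homozygosity therefore shows up as P_EW near 1."""

    gene_id: str
    S: int
    D: float = math.nan
    H: float = math.nan
    F: float = math.nan
    Zns: float = math.nan
    P_D: float = math.nan
    P_H: float = math.nan
    P_EW: float = math.nan
    P_Zns: float = math.nan
    unpolarized: int = 0


def gene_neutrality(
    f: FilteredAlignment, outgroup_cons: np.ndarray | None = None
) -> NeutralityResult:
    """Compute the four observed statistics for one filtered gene (P-values
    are filled in later against simulated nulls)."""
    from .diversity import segregating_sites  # local to avoid cycle noise

    S = segregating_sites(f) if f.L else 0
    res = NeutralityResult(gene_id=f.gene_id, S=S)
    if f.L == 0:
        return res
    pi_loc = theta_pi_locus(f)
    res.D = tajima_d(S, pi_loc, f.n)
    res.F = ewens_watterson_f(f)
    res.Zns = kelly_zns(f)
    if outgroup_cons is not None and S > 0:
        spec = polarize(f, outgroup_cons)
        res.unpolarized = spec.unpolarized
        res.H = fay_wu_h(spec)
    return res
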