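"""Standard-neutral-model coalescent simulator and empirical null
distributions.

The simulator is the classic Hudson construction: with k lineages the
waiting time to the next coalescence is exponential with rate k(k-1)/2 in
units of 2N generations, a uniformly random pair merges, and mutations fall
on branches as a Poisson process with rate theta_locus/2 per unit branch
length under the infinite-sites model (each mutation opens a new biallelic
column).  With theta_locus = 4*N*mu*L this parameterization gives
E[S] = theta_locus * a1 exactly, matching the ms convention (ms measures
time in 4N units with rate theta per unit; the products are identical).

Simulated replicates carry their true ancestral state, so null
distributions for Fay & Wu's H use perfect polarization.  Nulls here use no
recombination, which is conservative for Z_nS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .neutrality import (
    ewens_watterson_f,
    fay_wu_h,
    kelly_zns,
    tajima_d,
    PolarizedSpectrum,
)

_STATS = ("D", "H", "F", "Zns")


@dataclass
class CoalescentReplicate:
    """One simulated genealogy + mutations.

    ``branch_masks[b]`` is a bitmask over samples subtended by branch ``b``;
    lengths are in units of 2N generations.  ``matrix`` is the (n, S) 0/1
    haplotype matrix with 1 = derived."""

    n: int
    branch_masks: list[int]
    branch_lengths: np.ndarray
    total_branch_length: float
    matrix: np.ndarray

    @property
    def derived_counts(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    @property
    def S(self) -> int:
        return self.matrix.shape[1]


def _drop_mutations(
    n: int,
    bmasks: list[int],
    blens: np.ndarray,
    theta_locus: float,
    rng: np.random.Generator,
) -> np.ndarray:
    total = float(blens.sum())
    S = rng.poisson(theta_locus * total / 2.0) if total > 0 else 0
    if S == 0:
        return np.zeros((n, 0), dtype=np.uint8)
    which = rng.choice(len(bmasks), size=S, p=blens / total)
    masks = np.array([bmasks[w] for w in which], dtype=np.uint64)
    bits = (masks[:, None] >> np.arange(n, dtype=np.uint64)) & np.uint64(1)
    return bits.astype(np.uint8).T


def simulate_replicate(
    n: int, theta_locus: float, rng: np.random.Generator
) -> CoalescentReplicate:
    """Draw one neutral replicate: genealogy, branch lengths, mutations."""
    if n < 2:
        raise ValueError("need n >= 2")
    masks = [1 << i for i in range(n)]
    lens = [0.0] * n
    bmasks: list[int] = []
    blens: list[float] = []
    k = n
    while k > 1:
        dt = rng.exponential(2.0 / (k * (k - 1)))
        for t in range(k):
            lens[t] += dt
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        bmasks.extend((masks[i], masks[j]))
        blens.extend((lens[i], lens[j]))
        masks[i] |= masks[j]
        lens[i] = 0.0
        masks[j] = masks[k - 1]
        lens[j] = lens[k - 1]
        masks.pop()
        lens.pop()
        k -= 1
    blens_arr = np.asarray(blens)
    matrix = _drop_mutations(n, bmasks, blens_arr, theta_locus, rng)
    return CoalescentReplicate(
        n=n,
        branch_masks=bmasks,
        branch_lengths=blens_arr,
        total_branch_length=float(blens_arr.sum()),
        matrix=matrix,
    )


def fixed_s_simulator(S: int):
    """Alternative conditioning for null simulations: exactly ``S``
    mutations are placed on each genealogy (branch chosen proportionally
    to length) instead of a Poisson number driven by theta.  Returns a
    callable with the same signature as :func:`simulate_replicate`; the
    theta argument is ignored."""

    def simulate(n: int, theta_locus: float, rng: np.random.Generator) -> CoalescentReplicate:
        rep = simulate_replicate(n, 0.0, rng)
        blens = rep.branch_lengths
        total = rep.total_branch_length
        if S > 0 and total > 0:
            which = rng.choice(len(blens), size=S, p=blens / total)
            masks = np.array([rep.branch_masks[w] for w in which], dtype=np.uint64)
            bits = (masks[:, None] >> np.arange(n, dtype=np.uint64)) & np.uint64(1)
            rep.matrix = bits.astype(np.uint8).T
        return rep

    simulate.__name__ = f"fixed_s_{S}"
    return simulate


def star_sweep_replicate(
    n: int,
    theta_locus: float,
    rng: np.random.Generator,
    tip_length: float = 0.1,
    depth: float = 2.0,
) -> CoalescentReplicate:
    """Sweep-caricature genealogy for power checks: n-1 tips hang off a star
    at shallow depth ``tip_length`` (the swept haplotype) while one escaped
    lineage diverges at ``depth``; the long stem above the swept clade
    produces derived alleles at frequency n-1, the signature the compound
    test is sensitive to."""
    if n < 3:
        raise ValueError("sweep caricature needs n >= 3")
    bmasks = [1 << i for i in range(n - 1)]  # swept tips
    blens = [tip_length] * (n - 1)
    bmasks.append(1 << (n - 1))  # escaped lineage
    blens.append(depth)
    swept = (1 << (n - 1)) - 1
    bmasks.append(swept)  # stem of the swept clade
    blens.append(depth - tip_length)
    blens_arr = np.asarray(blens)
    matrix = _drop_mutations(n, bmasks, blens_arr, theta_locus, rng)
    return CoalescentReplicate(
        n=n,
        branch_masks=bmasks,
        branch_lengths=blens_arr,
        total_branch_length=float(blens_arr.sum()),
        matrix=matrix,
    )


def replicate_stats(rep: CoalescentReplicate) -> dict[str, float]:
    """All four neutrality statistics (plus S and per-locus pi) for one
    replicate, using the simulator's true ancestral states."""
    n = rep.n
    i = rep.derived_counts.astype(float)
    S = rep.S
    pi_locus = float((2.0 * i * (n - i)).sum() / (n * (n - 1)))
    out = {
        "S": float(S),
        "pi_locus": pi_locus,
        "D": tajima_d(S, pi_locus, n),
        "F": ewens_watterson_f(rep.matrix),
        "Zns": kelly_zns(rep.matrix) if S >= 2 else math.nan,
    }
    if S > 0:
        spec = PolarizedSpectrum(n=n, counts=rep.derived_counts.astype(np.int64))
        out["H"] = fay_wu_h(spec, pi_locus=pi_locus)
    else:
        out["H"] = math.nan
    return out


def null_statistics(
    n: int,
    theta_locus: float,
    reps: int,
    rng: np.random.Generator,
    simulator=simulate_replicate,
) -> dict[str, np.ndarray]:
    """Arrays (length ``reps``) of S, D, H, F, Zns over fresh replicates."""
    keys = ("S", "D", "H", "F", "Zns")
    out = {k: np.empty(reps) for k in keys}
    for r in range(reps):
        st = replicate_stats(simulator(n, theta_locus, rng))
        for k in keys:
            out[k][r] = st[k]
    return out


@dataclass
class NullDistribution:
    """Sorted simulated values of one statistic under the neutral null."""

    statistic_name: str
    n: int
    theta_locus: float
    reps: int
    values: np.ndarray  # sorted, NaN-free
    na_count: int
    seed: int | None = None


def null_distribution(
    stat,
    n: int,
    theta_locus: float,
    reps: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    simulator=simulate_replicate,
) -> NullDistribution:
    """Simulate the null distribution of ``stat`` (a name among
    D/H/F/Zns/S, or a callable on a replicate).  Replicates where the
    statistic is undefined are recorded as NA and excluded."""
    if rng is None:
        rng = np.random.default_rng(seed)
    name = stat if isinstance(stat, str) else getattr(stat, "__name__", "stat")
    vals = np.empty(reps)
    for r in range(reps):
        rep = simulator(n, theta_locus, rng)
        vals[r] = replicate_stats(rep)[stat] if isinstance(stat, str) else stat(rep)
    finite = vals[~np.isnan(vals)]
    return NullDistribution(
        statistic_name=name,
        n=n,
        theta_locus=theta_locus,
        reps=reps,
        values=np.sort(finite),
        na_count=int(reps - finite.size),
        seed=seed,
    )


def _sorted_values(null) -> np.ndarray:
    vals = null.values if isinstance(null, NullDistribution) else np.asarray(null)
    vals = vals[~np.isnan(vals)]
    return np.sort(vals)


def empirical_pvalue(observed: float, null, tail: str = "lower") -> float:
    """(+1)/(+1) empirical P-value against a simulated null.

    lower: (#{v <= obs} + 1)/(m + 1); upper: (#{v >= obs} + 1)/(m + 1).
    NaN observations give NaN; NA replicates were already excluded."""
    if observed is None or (isinstance(observed, float) and math.isnan(observed)):
        return math.nan
    vals = _sorted_values(null)
    m = vals.size
    if m == 0:
        return math.nan
    if tail == "lower":
        k = int(np.searchsorted(vals, observed, side="right"))
    elif tail == "upper":
        k = m - int(np.searchsorted(vals, observed, side="left"))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (k + 1) / (m + 1)


def ms_lines(rep: CoalescentReplicate, rng_positions=None) -> list[str]:
    """Render one replicate in ms-like text form (segsites / positions /
    haplotype rows) for cross-validation against external simulators."""
    S = rep.S
    lines = [f"segsites: {S}"]
    if S:
        if rng_positions is None:
            pos = np.linspace(0, 1, S, endpoint=False)
        else:
            pos = np.sort(rng_positions.uniform(size=S))
        lines.append("positions: " + " ".join(f"{p:.5f}" for p in pos))
        for row in rep.matrix:
            lines.append("".join(str(int(b)) for b in row))
    return lines
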