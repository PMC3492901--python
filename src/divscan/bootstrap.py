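"""Across-locus bootstrap of species-level means and CI-overlap comparisons.

Species means of per-gene statistics are compared through percentile
bootstrap confidence intervals obtained by resampling loci with
replacement; two species differ "significantly" only when their closed
intervals do not overlap (touching endpoints count as overlap, the
conservative reading).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

SIGNIFICANT = "significant"
NOT_SIGNIFICANT = "not_significant"


@dataclass
class BootstrapSummary:
    """Point estimate and percentile CI of an across-locus mean."""

    species: str
    statistic_name: str
    mean: float
    ci_low: float
    ci_high: float
    reps: int
    level: float = 0.95
    seed: int | None = None
    n_used: int = 0
    n_dropped: int = 0


def bootstrap_mean_ci(
    values,
    reps: int = 10000,
    level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    species: str = "",
    statistic_name: str = "",
) -> BootstrapSummary:
    """Percentile bootstrap CI for the mean of per-locus values.

    NaN values are dropped (count logged); an all-NaN input yields a NaN
    summary.  Deterministic for a fixed seed/rng."""
    vals = np.asarray(values, dtype=float)
    finite = vals[~np.isnan(vals)]
    dropped = int(vals.size - finite.size)
    if finite.size == 0:
        return BootstrapSummary(
            species, statistic_name, math.nan, math.nan, math.nan,
            reps, level, seed, 0, dropped,
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    m = finite.size
    idx = rng.integers(0, m, size=(reps, m))
    means = finite[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return BootstrapSummary(
        species=species,
        statistic_name=statistic_name,
        mean=float(finite.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        reps=reps,
        level=level,
        seed=seed,
        n_used=m,
        n_dropped=dropped,
    )


def compare_species(a: BootstrapSummary, b: BootstrapSummary) -> str:
    """CI-overlap comparison of two bootstrap summaries of the same
    statistic; non-overlap (strict) is significant."""
    if a.statistic_name != b.statistic_name:
        raise ValueError(
            f"cannot compare {a.statistic_name!r} with {b.statistic_name!r}"
        )
    for s in (a, b):
        if math.isnan(s.ci_low) or math.isnan(s.ci_high):
            raise ValueError("cannot compare an NA interval")
    disjoint = a.ci_high < b.ci_low or b.ci_high < a.ci_low
    return SIGNIFICANT if disjoint else NOT_SIGNIFICANT
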