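"""Compound DHEW neutrality test: calibration and the joint decision.

The DHEW test (Zeng et al. 2007) rejects neutrality only when Tajima's D,
Fay & Wu's normalized H, and the Ewens-Watterson test are *jointly*
significant at an adjusted per-component level P*.  P* is calibrated by
simulation so that, under the standard neutral model conditional on the
gene's sample size and observed diversity, the probability that all three
one-sided component P-values fall at or below P* equals the target
multidimensional level ``a``.

Component directions: D lower tail, H lower tail, and the *upper* tail of
Ewens-Watterson homozygosity F (the sweep-sensitive direction).  Genes with
at most one segregating site are excluded outright, mirroring the removal
of one-SNP genes from outlier calling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .coalescent import null_statistics, simulate_replicate


@dataclass
class PstarCalibration:
    """Result of a P* calibration run at one (n, theta_locus)."""

    p_star: float
    a: float
    reps: int
    n: int
    theta_locus: float
    n_calibration_used: int


def _lower_p(obs: np.ndarray, ref_sorted: np.ndarray) -> np.ndarray:
    m = ref_sorted.size
    return (np.searchsorted(ref_sorted, obs, side="right") + 1) / (m + 1)


def _upper_p(obs: np.ndarray, ref_sorted: np.ndarray) -> np.ndarray:
    m = ref_sorted.size
    return (m - np.searchsorted(ref_sorted, obs, side="left") + 1) / (m + 1)


def _clean_sort(x: np.ndarray) -> np.ndarray:
    return np.sort(x[~np.isnan(x)])


def calibrate_pstar(
    n: int,
    theta_locus: float,
    a: float = 0.0001,
    reps: int = 50000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    simulator=simulate_replicate,
) -> PstarCalibration:
    """Estimate the adjusted per-component level P* by simulation.

    Two independent replicate sets of size ``reps`` are drawn at
    (n, theta_locus): a reference set providing the component null
    distributions, and a calibration set on which the three component
    P-values are evaluated.  P* is the largest threshold p' such that the
    fraction of calibration replicates with all three component P-values
    <= p' stays <= a, floored at max(a, 1/(reps+1)).

    Calibration replicates with S <= 1 are dropped, mirroring the
    exclusion applied to observed genes.
    """
    if not 0 < a <= 1:
        raise ValueError("a must lie in (0, 1]")
    if a < 1.0 / reps:
        warnings.warn(
            f"a={a} is below the resolution of {reps} replicates; "
            "P* is floored at 1/(reps+1)",
            stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    ref = null_statistics(n, theta_locus, reps, rng, simulator=simulator)
    cal = null_statistics(n, theta_locus, reps, rng, simulator=simulator)
    keep = cal["S"] >= 2
    ref_d = _clean_sort(ref["D"])
    ref_h = _clean_sort(ref["H"])
    ref_f = _clean_sort(ref["F"])
    p_d = _lower_p(cal["D"][keep], ref_d)
    p_h = _lower_p(cal["H"][keep], ref_h)
    p_ew = _upper_p(cal["F"][keep], ref_f)
    m_stat = np.sort(np.maximum(np.maximum(p_d, p_h), p_ew))
    m = m_stat.size
    k = int(math.floor(a * m))
    while k > 0 and np.searchsorted(m_stat, m_stat[k - 1], side="right") > a * m:
        k -= 1
    p_star = float(m_stat[k - 1]) if k > 0 else 0.0
    p_star = min(1.0, max(p_star, a, 1.0 / (reps + 1)))
    return PstarCalibration(
        p_star=p_star,
        a=a,
        reps=reps,
        n=n,
        theta_locus=theta_locus,
        n_calibration_used=m,
    )


@dataclass
class DHEWResult:
    """Joint outlier decision for one gene."""

    gene_id: str
    a: float
    p_star: float
    component_p: tuple[float, float, float]  # (P_D, P_H, P_EW lower-tail)
    outlier: bool | None
    excluded: bool
    reason: str = ""


def dhew_test(
    gene_id: str,
    S: int,
    p_d: float,
    p_h: float,
    p_ew: float,
    p_star: float | PstarCalibration,
    a: float = 0.0001,
    p_ew_upper: float | None = None,
) -> DHEWResult:
    """Apply the joint all-components rule.

    ``p_ew`` is the reported lower-tail Ewens-Watterson P-value; the
    homozygosity-excess direction enters as 1 - p_ew unless a directly
    computed upper-tail value ``p_ew_upper`` is supplied.  Genes with
    S <= 1 or any undefined component are excluded (outlier undefined).
    """
    if isinstance(p_star, PstarCalibration):
        a = p_star.a
        p_star = p_star.p_star
    comp = (p_d, p_h, p_ew)
    if S <= 1:
        return DHEWResult(gene_id, a, p_star, comp, None, True, "S<=1")
    if any(x is None or math.isnan(x) for x in comp):
        return DHEWResult(gene_id, a, p_star, comp, None, True, "component NA")
    ew_dir = (1.0 - p_ew) if p_ew_upper is None else p_ew_upper
    outlier = p_d <= p_star and p_h <= p_star and ew_dir <= p_star
    return DHEWResult(gene_id, a, p_star, comp, bool(outlier), False)
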