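"""Site-category annotation: noncoding / synonymous / nonsynonymous.

Coding intervals (with a frame offset) are supplied per gene; no homology
search is performed here.  Within codons, a polymorphic site is synonymous
when every segregating allele, substituted into the ingroup-consensus codon
context, leaves the amino acid unchanged.  Monomorphic coding positions are
apportioned fractionally in the Nei-Gojobori style: a position contributes
f_syn = (#synonymous single-nucleotide changes)/3 to the synonymous site
count and 1 - f_syn to the nonsynonymous count, evaluated on the
ingroup-consensus codon (changes to stop codons count as nonsynonymous).

Codons whose consensus context is untranslatable (an N, or an internal stop)
are flagged ``mixed_excluded`` and drop out of all category totals, as do
partial codons at interval edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .alignment import FilteredAlignment, NUCLEOTIDES

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard nuclear code
_BASES = "ACGT"

CAT_NONCODING = "noncoding"
CAT_SYN = "synonymous"
CAT_NONSYN = "nonsynonymous"
CAT_MIXED = "mixed_excluded"


class AnnotationError(ValueError):
    """Inconsistent coding intervals / frame declarations."""


def translate_codon(codon: str) -> str:
    """One-letter amino acid, '*' for stop."""
    if codon in _TABLE.stop_codons:
        return "*"
    return _TABLE.forward_table[codon]


@lru_cache(maxsize=None)
def syn_fraction(codon: str, offset: int) -> float:
    """Fraction of the 3 possible single-nucleotide changes at ``offset``
    that are synonymous.  Changes producing a stop codon are nonsynonymous.
    Raises KeyError for stop codons (callers exclude them)."""
    aa = translate_codon(codon)
    if aa == "*":
        raise ValueError("stop codon has no site fraction")
    syn = 0
    for b in _BASES:
        if b == codon[offset]:
            continue
        alt = codon[:offset] + b + codon[offset + 1 :]
        if translate_codon(alt) == aa:
            syn += 1
    return syn / 3.0


@dataclass(frozen=True)
class CodingInterval:
    """Half-open column interval ``[start, end)`` with frame offset: the
    first complete codon begins at ``start + frame``."""

    start: int
    end: int
    frame: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frame <= 2):
            raise AnnotationError(f"frame must be 0/1/2, got {self.frame}")
        if self.end <= self.start:
            raise AnnotationError(f"empty interval [{self.start},{self.end})")


@dataclass
class SiteAnnotation:
    """Per-retained-site categories and fractional site counts for one gene."""

    gene_id: str
    coding_intervals: list[CodingInterval]
    site_category: np.ndarray  # object array over retained sites
    syn_sites: float
    nonsyn_sites: float
    noncoding_sites: int
    mixed_excluded: int = 0

    @property
    def silent_sites(self) -> float:
        return self.noncoding_sites + self.syn_sites


def _validate_intervals(intervals: list[CodingInterval], L: int) -> list[CodingInterval]:
    ivs = sorted(intervals, key=lambda iv: iv.start)
    prev_end = -1
    for iv in ivs:
        if iv.start < 0 or iv.end > L:
            raise AnnotationError(f"interval [{iv.start},{iv.end}) outside alignment of length {L}")
        if iv.start < prev_end:
            raise AnnotationError("overlapping coding intervals")
        prev_end = iv.end
    return ivs


def codon_map(
    intervals: list[CodingInterval], L: int
) -> tuple[dict[int, tuple[tuple[int, int, int], int]], np.ndarray]:
    """Map original column -> (codon position triple, offset in codon).

    Returns the map plus a boolean mask of all columns inside coding
    intervals (codon members or partial-codon tails)."""
    ivs = _validate_intervals(intervals, L)
    in_coding = np.zeros(L, dtype=bool)
    pos_map: dict[int, tuple[tuple[int, int, int], int]] = {}
    for iv in ivs:
        in_coding[iv.start : iv.end] = True
        for cs in range(iv.start + iv.frame, iv.end - 2, 3):
            triple = (cs, cs + 1, cs + 2)
            for off, p in enumerate(triple):
                pos_map[p] = (triple, off)
    return pos_map, in_coding


def classify_sites(
    f: FilteredAlignment, coding: list[CodingInterval]
) -> SiteAnnotation:
    """Assign a category to each retained site and accumulate fractional
    Nei-Gojobori site counts."""
    pos_map, in_coding = codon_map(coding, f.n_original_columns)
    cons = f.consensus_all
    cats = np.empty(f.L, dtype=object)
    syn_sites = 0.0
    nonsyn_sites = 0.0
    noncoding_sites = 0
    mixed = 0
    counts = f.allele_counts()
    for idx, col in enumerate(f.retained_columns):
        col = int(col)
        if col not in pos_map:
            if in_coding[col]:
                cats[idx] = CAT_MIXED  # partial codon at an interval edge
                mixed += 1
            else:
                cats[idx] = CAT_NONCODING
                noncoding_sites += 1
            continue
        triple, off = pos_map[col]
        codon = b"".join(cons[list(triple)]).decode("ascii")
        if any(c not in _BASES for c in codon) or translate_codon(codon) == "*":
            cats[idx] = CAT_MIXED
            mixed += 1
            continue
        fsyn = syn_fraction(codon, off)
        syn_sites += fsyn
        nonsyn_sites += 1.0 - fsyn
        alleles = [
            NUCLEOTIDES[a].decode("ascii")
            for a in range(4)
            if counts[a, idx] > 0
        ]
        if len(alleles) == 2:
            aas = {
                translate_codon(codon[:off] + b + codon[off + 1 :])
                for b in alleles
            }
            cats[idx] = CAT_SYN if len(aas) == 1 and "*" not in aas else CAT_NONSYN
        else:
            # monomorphic coding position: label by dominant degeneracy;
            # the label is cosmetic, the fractional counts drive statistics
            cats[idx] = CAT_SYN if fsyn >= 0.5 else CAT_NONSYN
    return SiteAnnotation(
        gene_id=f.gene_id,
        coding_intervals=list(coding),
        site_category=cats,
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        noncoding_sites=noncoding_sites,
        mixed_excluded=mixed,
    )


def count_sites(
    f: FilteredAlignment, ann: SiteAnnotation | list[CodingInterval]
) -> tuple[float, float, int]:
    """(synonymous, nonsynonymous, noncoding) fractional site counts.

    Accepts a finished :class:`SiteAnnotation` or raw coding intervals (in
    which case the classification is rerun)."""
    if isinstance(ann, SiteAnnotation):
        return ann.syn_sites, ann.nonsyn_sites, ann.noncoding_sites
    fresh = classify_sites(f, ann)
    return fresh.syn_sites, fresh.nonsyn_sites, fresh.noncoding_sites


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """100*numerator/denominator rounded half-up to ``decimals``; NaN when
    the denominator is zero."""
    if denominator == 0:
        return math.nan
    q = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def read_annotation_tsv(path: str | Path) -> dict[str, list[CodingInterval]]:
    """Read per-gene coding intervals: gene_id, start, end, frame."""
    out: dict[str, list[CodingInterval]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            gid, start, end, frame = line.split("\t")[:4]
            out.setdefault(gid, []).append(
                CodingInterval(int(start), int(end), int(frame))
            )
    return out


def write_annotation_tsv(
    annotations: dict[str, list[CodingInterval]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tstart\tend\tframe\n")
        for gid in sorted(annotations):
            for iv in annotations[gid]:
                fh.write(f"{gid}\t{iv.start}\t{iv.end}\t{iv.frame}\n")
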