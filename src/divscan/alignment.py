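"""Per-gene alignment I/O, primer masking and site filtering.

Every downstream statistic operates on a *complete*, at-most-biallelic site
matrix: columns carrying missing bases, alignment gaps, or more than two
distinct ingroup nucleotides are removed before any estimator sees the data.
Outgroup rows ride along on the same columns but never trigger removal; they
matter only for polarization and divergence.

Coordinates are 0-based, half-open throughout. The missing character is ``N``,
the gap character is ``-``; any other IUPAC ambiguity code in an ingroup row
is demoted to ``N`` on read (haploid megagametophyte data should not contain
heterozygous calls, so ambiguity is treated as a read failure, not an error).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = (b"A", b"C", b"G", b"T")
GAP = b"-"
MISSING = b"N"

#: removal_log reason codes
REMOVAL_PRIMER = "primer_masked"
REMOVAL_INDEL = "indel"
REMOVAL_MISSING = "missing"
REMOVAL_MULTIALLELIC = "infinite_sites_violation"


class AlignmentFormatError(ValueError):
    """Ragged or otherwise malformed alignment input."""


class MissingOutgroupError(ValueError):
    """No record in the FASTA matches the outgroup header tag."""


class PrimerConfigError(ValueError):
    """Primer intervals are overlapping, unordered, or out of bounds."""


def _to_matrix(seqs: list[str]) -> np.ndarray:
    rows = [np.frombuffer(s.upper().encode("ascii"), dtype="S1") for s in seqs]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise AlignmentFormatError(
            f"ragged alignment: row lengths {sorted(lengths)}"
        )
    return np.vstack(rows) if rows else np.empty((0, 0), dtype="S1")


def _normalize(mat: np.ndarray) -> np.ndarray:
    """Map every character outside {A,C,G,T,-} to the missing character N."""
    allowed = np.array([b"A", b"C", b"G", b"T", b"-"], dtype="S1")
    out = mat.copy()
    out[~np.isin(out, allowed)] = MISSING
    return out


@dataclass
class GeneAlignment:
    """A per-gene haploid sequence matrix with aligned outgroup row(s).

    ``ingroup`` and ``outgroup`` are ``(rows, columns)`` byte matrices
    (dtype ``S1``) over the alphabet ``A C G T - N``, sharing columns.
    """

    gene_id: str
    ingroup: np.ndarray
    outgroup: np.ndarray
    ingroup_ids: list[str] = field(default_factory=list)
    outgroup_ids: list[str] = field(default_factory=list)
    species: str = ""
    category: str = "control"
    primer_intervals: tuple[tuple[int, int], tuple[int, int]] | None = None
    masked_columns: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.ingroup.ndim != 2:
            raise AlignmentFormatError("ingroup must be a 2-D matrix")
        if self.ingroup.shape[0] < 2:
            raise AlignmentFormatError(
                f"{self.gene_id}: need >= 2 ingroup sequences, "
                f"got {self.ingroup.shape[0]}"
            )
        if self.outgroup.size and self.outgroup.shape[1] != self.ingroup.shape[1]:
            raise AlignmentFormatError(
                f"{self.gene_id}: outgroup columns do not match ingroup"
            )

    @property
    def n(self) -> int:
        """Ingroup sample size."""
        return self.ingroup.shape[0]

    @property
    def n_columns(self) -> int:
        return self.ingroup.shape[1]

    @property
    def has_outgroup(self) -> bool:
        return self.outgroup.shape[0] > 0 if self.outgroup.ndim == 2 else False


@dataclass
class FilteredAlignment:
    """Complete, at-most-biallelic ingroup matrix over retained columns.

    ``consensus_all`` is the ingroup plurality consensus over *all original*
    columns (ties and all-missing columns give ``N``); it provides codon
    context for positions that were filtered out.
    """

    gene_id: str
    matrix: np.ndarray
    retained_columns: np.ndarray
    removal_log: dict[int, str]
    consensus_all: np.ndarray
    n_original_columns: int

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    def allele_counts(self) -> np.ndarray:
        """(4, L) counts of A,C,G,T per retained column."""
        return np.stack(
            [(self.matrix == b).sum(axis=0) for b in NUCLEOTIDES]
        )

    def variant_mask(self) -> np.ndarray:
        """Boolean mask over retained columns with exactly two alleles."""
        return (self.allele_counts() > 0).sum(axis=0) == 2

    def binary_matrix(self) -> np.ndarray:
        """(n, S) 0/1 matrix over variant columns; 1 marks the minority
        allele (ties broken by ACGT order). Labels are arbitrary for the
        label-invariant statistics that consume this."""
        cols = np.flatnonzero(self.variant_mask())
        counts = self.allele_counts()[:, cols]
        # minority allele index per column; argmin over present alleles
        masked = np.where(counts > 0, counts, np.iinfo(np.int64).max)
        minor = masked.argmin(axis=0)
        minor_char = np.array(NUCLEOTIDES)[minor]
        return (self.matrix[:, cols] == minor_char[None, :]).astype(np.uint8)


def read_gene_fasta(
    path: str | Path,
    outgroup_tag: str,
    *,
    gene_id: str | None = None,
    species: str = "",
    category: str = "control",
    require_outgroup: bool = True,
) -> GeneAlignment:
    """Read one aligned per-gene FASTA, splitting ingroup from outgroup rows
    by substring match of ``outgroup_tag`` against the record description."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"{path}: empty FASTA")
    in_ids, in_seqs, out_ids, out_seqs = [], [], [], []
    for rec in records:
        if outgroup_tag and outgroup_tag in rec.description:
            out_ids.append(rec.description)
            out_seqs.append(str(rec.seq))
        else:
            in_ids.append(rec.description)
            in_seqs.append(str(rec.seq))
    if len(set(in_ids)) != len(in_ids):
        warnings.warn(f"{path}: duplicate ingroup headers", stacklevel=2)
    if not out_seqs and require_outgroup:
        raise MissingOutgroupError(
            f"{path}: no record matching outgroup tag {outgroup_tag!r}"
        )
    mat = _normalize(_to_matrix(in_seqs + out_seqs))
    k = len(in_seqs)
    return GeneAlignment(
        gene_id=gene_id or path.stem,
        ingroup=mat[:k],
        outgroup=mat[k:],
        ingroup_ids=in_ids,
        outgroup_ids=out_ids,
        species=species,
        category=category,
    )


def write_gene_fasta(aln: GeneAlignment, path: str | Path) -> None:
    """Write ingroup then outgroup rows as aligned FASTA."""
    recs = []
    for ids, mat in ((aln.ingroup_ids, aln.ingroup), (aln.outgroup_ids, aln.outgroup)):
        for name, row in zip(ids, mat):
            recs.append(
                SeqRecord(Seq(row.tobytes().decode("ascii")), id=name, description="")
            )
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta-2line")


def mask_primers(aln: GeneAlignment) -> GeneAlignment:
    """Replace every column outside the region spanned *between* the two
    primer intervals (and the primer columns themselves) with ``N``.

    Identity when no primer intervals are attached.  The retained interior is
    ``[fwd_end, rev_start)``.
    """
    if aln.primer_intervals is None:
        return aln
    (fs, fe), (rs, re) = aln.primer_intervals
    L = aln.n_columns
    if not (0 <= fs < fe <= rs < re <= L):
        raise PrimerConfigError(
            f"{aln.gene_id}: bad primer intervals {aln.primer_intervals} for L={L}"
        )
    masked = list(range(0, fe)) + list(range(rs, L))
    ing = aln.ingroup.copy()
    out = aln.outgroup.copy()
    ing[:, masked] = MISSING
    if out.size:
        out[:, masked] = MISSING
    return replace(
        aln,
        ingroup=ing,
        outgroup=out,
        masked_columns=frozenset(masked) | aln.masked_columns,
    )


def filter_sites(aln: GeneAlignment) -> FilteredAlignment:
    """Drop columns with primer masking, gaps, missing data, or more than two
    distinct ingroup alleles (infinite-sites violations).

    Only the *ingroup* triggers removal; outgroup gaps or ambiguity merely
    make a site unusable for polarization/divergence later.  Reason codes are
    assigned with precedence primer > indel > missing > infinite-sites.
    """
    ing = aln.ingroup
    L = aln.n_columns
    counts = np.stack([(ing == b).sum(axis=0) for b in NUCLEOTIDES])
    has_gap = (ing == GAP).any(axis=0)
    has_missing = (ing == MISSING).any(axis=0)
    n_alleles = (counts > 0).sum(axis=0)
    masked = np.zeros(L, dtype=bool)
    if aln.masked_columns:
        masked[list(aln.masked_columns)] = True

    removal_log: dict[int, str] = {}
    keep: list[int] = []
    for j in range(L):
        if masked[j]:
            removal_log[j] = REMOVAL_PRIMER
        elif has_gap[j]:
            removal_log[j] = REMOVAL_INDEL
        elif has_missing[j]:
            removal_log[j] = REMOVAL_MISSING
        elif n_alleles[j] > 2:
            removal_log[j] = REMOVAL_MULTIALLELIC
        else:
            keep.append(j)

    best = counts.argmax(axis=0)
    bestc = counts.max(axis=0)
    tie = (counts == bestc[None, :]).sum(axis=0) > 1
    consensus = np.array(NUCLEOTIDES)[best]
    consensus[tie | (bestc == 0)] = MISSING

    kept = np.asarray(keep, dtype=np.int64)
    return FilteredAlignment(
        gene_id=aln.gene_id,
        matrix=ing[:, kept] if kept.size else ing[:, :0],
        retained_columns=kept,
        removal_log=removal_log,
        consensus_all=consensus,
        n_original_columns=L,
    )


def outgroup_consensus(aln: GeneAlignment) -> np.ndarray:
    """Strict-majority consensus of the outgroup rows, full alignment length.

    Per column, the nucleotide carried by more than half of the non-gap,
    non-N outgroup characters; ties and all-missing columns give ``N``.
    """
    if not aln.has_outgroup:
        raise MissingOutgroupError(f"{aln.gene_id}: no outgroup rows")
    og = aln.outgroup
    counts = np.stack([(og == b).sum(axis=0) for b in NUCLEOTIDES])
    valid_total = counts.sum(axis=0)
    best = counts.argmax(axis=0)
    bestc = counts.max(axis=0)
    cons = np.array(NUCLEOTIDES)[best]
    cons[(valid_total == 0) | (2 * bestc <= valid_total)] = MISSING
    return cons


def consensus_at(consensus: np.ndarray, filtered: FilteredAlignment) -> np.ndarray:
    """Slice a full-length consensus down to the retained columns; a
    retained-length consensus passes through unchanged."""
    if consensus.shape[0] == filtered.n_original_columns:
        return consensus[filtered.retained_columns]
    if consensus.shape[0] == filtered.L:
        return consensus
    raise ValueError(
        f"consensus length {consensus.shape[0]} matches neither original "
        f"({filtered.n_original_columns}) nor retained ({filtered.L}) columns"
    )


def read_primer_tsv(path: str | Path) -> dict[str, tuple[tuple[int, int], tuple[int, int]]]:
    """Read per-gene primer intervals: gene_id, fwd_start, fwd_end,
    rev_start, rev_end (0-based, half-open)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            gid, fs, fe, rs, re = line.split("\t")[:5]
            out[gid] = ((int(fs), int(fe)), (int(rs), int(re)))
    return out
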