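"""Synthetic study-shaped data: per-gene FASTA alignments with an outgroup,
coding-interval annotations, and truth records.

Each gene is a neutral coalescent replicate mapped onto a random base
sequence under the infinite-sites model (uniform base composition,
Jukes-Cantor-style uniform target bases).  The outgroup descends from the
ingroup ancestral sequence with a Poisson number of substitutions chosen so
that the *expected tip-to-outgroup divergence* equals the configured
``outgroup_divergence`` (the ingroup lineages contribute
theta_site*(1-1/n) of divergence on average, which is subtracted from the
outgroup-branch rate).  Outgroup substitutions may hit polymorphic sites,
deliberately exercising the unpolarizable-site path downstream.

Defect injection (missing bases, indel columns, triallelic columns) and a
star-tree sweep caricature are available to exercise filters and the
compound test's power.  Default study parameters mirror a four-species
alpine-conifer resequencing design: 3-12 haploid megagametophyte sequences
per gene, ~300-450 bp amplicons, per-site theta around 0.001-0.01 and
outgroup divergence 0.01-0.09.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from zlib import crc32

import numpy as np
import pandas as pd
import yaml

from .alignment import GeneAlignment, write_gene_fasta
from .annotation import CodingInterval, write_annotation_tsv
from .coalescent import simulate_replicate, star_sweep_replicate

_ACGT = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SyntheticGeneSpec:
    """Parameters for one synthetic gene."""

    gene_id: str
    species: str = "synthetic"
    category: str = "candidate"
    n: int = 8
    L: int = 400
    theta_site: float = 0.005
    outgroup_divergence: float = 0.05
    coding_fraction: float = 0.8
    frame: int = 0
    defect_rates: dict[str, float] = field(
        default_factory=lambda: {"missing_col": 0.0, "indel_col": 0.0, "triallelic_col": 0.0}
    )
    scenario: str = "neutral"  # or "star_sweep"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n >= 2 required")
        for k, v in self.defect_rates.items():
            if not 0 <= v <= 1:
                raise ValueError(f"defect rate {k}={v} outside [0,1]")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside each synthetic gene."""

    gene_id: str
    theta_site: float
    scenario: str
    s_pre_defect: int
    variant_positions: np.ndarray
    derived_base: np.ndarray
    derived_counts: np.ndarray
    defect_columns: dict[str, list[int]]


def _random_other_base(rng: np.random.Generator, exclude: set[bytes]) -> bytes:
    choices = [b.tobytes() for b in _ACGT if b.tobytes() not in exclude]
    return choices[rng.integers(len(choices))]


def _inject_defects(
    ingroup: np.ndarray,
    rates: dict[str, float],
    variant_cols: set[int],
    rng: np.random.Generator,
) -> dict[str, list[int]]:
    n, L = ingroup.shape
    order = rng.permutation(L)
    counts = {
        k: int(rng.binomial(L, rates.get(k, 0.0)))
        for k in ("triallelic_col", "indel_col", "missing_col")
    }
    taken: set[int] = set()
    out: dict[str, list[int]] = {"triallelic_col": [], "indel_col": [], "missing_col": []}
    it = iter(int(c) for c in order)

    def next_free() -> int | None:
        for c in it:
            if c not in taken:
                return c
        return None

    for _ in range(counts["triallelic_col"]):
        col = next_free()
        if col is None:
            break
        alleles = set(ingroup[:, col].tobytes()[i : i + 1] for i in range(n))
        if len(alleles) == 2:
            # overwrite a row of an allele with count >= 2 so three alleles remain
            vals = ingroup[:, col]
            uniq, cnt = np.unique(vals, return_counts=True)
            major = uniq[cnt.argmax()]
            if cnt.max() < 2:
                continue
            row = int(np.flatnonzero(vals == major)[0])
            ingroup[row, col] = _random_other_base(rng, alleles)
        else:
            if n < 3:
                continue
            rows = rng.choice(n, size=2, replace=False)
            b1 = _random_other_base(rng, alleles)
            b2 = _random_other_base(rng, alleles | {b1})
            ingroup[rows[0], col] = b1
            ingroup[rows[1], col] = b2
        taken.add(col)
        out["triallelic_col"].append(col)
    for kind, char in (("indel_col", b"-"), ("missing_col", b"N")):
        for _ in range(counts[kind]):
            col = next_free()
            if col is None:
                break
            row = int(rng.integers(n))
            ingroup[row, col] = char
            taken.add(col)
            out[kind].append(col)
    for v in out.values():
        v.sort()
    return out


def generate_gene(
    spec: SyntheticGeneSpec, outgroup_tag: str = "Ptaeda"
) -> tuple[GeneAlignment, list[CodingInterval], TruthRecord]:
    """Emit one synthetic gene: alignment (+1 outgroup row), coding
    intervals, and the ground-truth record."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, crc32(spec.gene_id.encode())]))
    n, L = spec.n, spec.L
    anc = _ACGT[rng.integers(4, size=L)].copy()
    theta_locus = spec.theta_site * L
    if spec.scenario == "star_sweep":
        rep = star_sweep_replicate(n, theta_locus, rng)
    elif spec.scenario == "neutral":
        rep = simulate_replicate(n, theta_locus, rng)
    else:
        raise ValueError(f"unknown scenario {spec.scenario!r}")
    S = min(rep.S, L)
    positions = np.sort(rng.choice(L, size=S, replace=False))
    matrix = rep.matrix[:, :S]
    derived = np.empty(S, dtype="S1")
    ingroup = np.tile(anc, (n, 1))
    for j in range(S):
        p = int(positions[j])
        derived[j] = _random_other_base(rng, {anc[p].tobytes()})
        ingroup[matrix[:, j] == 1, p] = derived[j]

    # outgroup: substitutions from the ingroup ancestral sequence, at a rate
    # discounted by the mean ingroup-lineage depth so that measured D_xy
    # matches the configured divergence
    d_branch = max(spec.outgroup_divergence - spec.theta_site * (1.0 - 1.0 / n), 0.0)
    k_out = int(min(rng.poisson(d_branch * L), L))
    outgroup = anc.copy()
    if k_out:
        pos_o = rng.choice(L, size=k_out, replace=False)
        for p in pos_o:
            outgroup[p] = _random_other_base(rng, {anc[p].tobytes()})

    defect_cols = _inject_defects(
        ingroup, spec.defect_rates, set(int(p) for p in positions), rng
    )

    intervals: list[CodingInterval] = []
    if spec.coding_fraction > 0:
        clen = int(spec.coding_fraction * L) // 3 * 3
        if clen >= 3:
            start = (L - clen) // 2
            intervals = [CodingInterval(start, start + clen, spec.frame)]

    aln = GeneAlignment(
        gene_id=spec.gene_id,
        ingroup=ingroup,
        outgroup=outgroup[None, :],
        ingroup_ids=[f"{spec.species}_{i}|{spec.gene_id}" for i in range(n)],
        outgroup_ids=[f"{outgroup_tag}|{spec.gene_id}"],
        species=spec.species,
        category=spec.category,
    )
    truth = TruthRecord(
        gene_id=spec.gene_id,
        theta_site=spec.theta_site,
        scenario=spec.scenario,
        s_pre_defect=S,
        variant_positions=positions,
        derived_base=derived,
        derived_counts=matrix.sum(axis=0),
        defect_columns=defect_cols,
    )
    return aln, intervals, truth


@dataclass
class SpeciesProfile:
    """Per-species generation parameters (study-shaped defaults below)."""

    name: str
    theta_site: float
    divergence: float
    mean_n: float
    candidate_genes: int
    control_genes: int


#: Four-species design mirroring an alpine-conifer candidate-gene study:
#: per-site theta 0.0025-0.0082, outgroup divergence 0.016-0.087, mean
#: sample sizes 3-6, candidate/control gene counts as published.
DEFAULT_SPECIES = [
    SpeciesProfile("Abies_alba", 0.0059, 0.0873, 5, 70, 32),
    SpeciesProfile("Larix_decidua", 0.0077, 0.0829, 3, 61, 35),
    SpeciesProfile("Pinus_cembra", 0.0025, 0.0378, 6, 171, 109),
    SpeciesProfile("Pinus_mugo", 0.0082, 0.0157, 4, 190, 120),
]


@dataclass
class StudyConfig:
    """Whole-study generation configuration."""

    species: list[SpeciesProfile] = field(default_factory=lambda: list(DEFAULT_SPECIES))
    seed: int = 0
    mean_length: float = 385.0
    sd_length: float = 40.0
    length_range: tuple[int, int] = (300, 450)
    n_range: tuple[int, int] = (3, 12)
    coding_fraction: float = 0.8
    annotate_fraction: dict[str, float] = field(
        default_factory=lambda: {"candidate": 0.8, "control": 0.5}
    )
    defect_rates: dict[str, float] = field(
        default_factory=lambda: {"missing_col": 0.02, "indel_col": 0.01, "triallelic_col": 0.005}
    )
    scenario: str = "neutral"
    outgroup_tag: str = "Ptaeda"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        species = raw.pop("species", None)
        cfg = cls(**raw)
        if species is not None:
            cfg.species = [SpeciesProfile(**s) for s in species]
        return cfg


def generate_study(config: StudyConfig, outdir: str | Path) -> pd.DataFrame:
    """Write a reproducible directory of per-gene FASTA + annotations +
    manifest + truth table; returns the manifest."""
    outdir = Path(outdir)
    (outdir / "genes").mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(master)
    rows = []
    truth_rows = []
    annotations: dict[str, list[CodingInterval]] = {}
    lo_n, hi_n = config.n_range
    lo_l, hi_l = config.length_range
    for prof in config.species:
        for category, count in (
            ("candidate", prof.candidate_genes),
            ("control", prof.control_genes),
        ):
            for g in range(count):
                gene_id = f"{prof.name}_{category[:4]}_{g:04d}"
                n = int(np.clip(round(rng.normal(prof.mean_n, 1.5)), lo_n, hi_n))
                L = int(np.clip(round(rng.normal(config.mean_length, config.sd_length)), lo_l, hi_l))
                annotated = rng.random() < config.annotate_fraction.get(category, 0.0)
                seed_g = int(rng.integers(0, 2**31 - 1))
                spec = SyntheticGeneSpec(
                    gene_id=gene_id,
                    species=prof.name,
                    category=category,
                    n=n,
                    L=L,
                    theta_site=prof.theta_site,
                    outgroup_divergence=prof.divergence,
                    coding_fraction=config.coding_fraction if annotated else 0.0,
                    defect_rates=dict(config.defect_rates),
                    scenario=config.scenario,
                    seed=seed_g,
                )
                aln, intervals, truth = generate_gene(spec, config.outgroup_tag)
                rel = f"genes/{gene_id}.fasta"
                write_gene_fasta(aln, outdir / rel)
                if intervals:
                    annotations[gene_id] = intervals
                rows.append(
                    dict(
                        gene_id=gene_id,
                        species=prof.name,
                        category=category,
                        path=rel,
                        seed=seed_g,
                        n=n,
                        L=L,
                        theta_site=prof.theta_site,
                        outgroup_divergence=prof.divergence,
                        annotated=int(annotated),
                    )
                )
                truth_rows.append(
                    dict(
                        gene_id=gene_id,
                        theta_site=truth.theta_site,
                        scenario=truth.scenario,
                        s_pre_defect=truth.s_pre_defect,
                        n_triallelic=len(truth.defect_columns["triallelic_col"]),
                        n_indel=len(truth.defect_columns["indel_col"]),
                        n_missing=len(truth.defect_columns["missing_col"]),
                    )
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    write_annotation_tsv(annotations, outdir / "annotations.tsv")
    return manifest
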