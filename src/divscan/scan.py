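"""Whole-study orchestration: the :class:`NeutralityScan` model and its
:class:`ScanResults`.

``NeutralityScan`` is built from per-gene alignments (plus optional coding
annotations and primer intervals) and a :class:`RunConfig`; ``fit`` runs the
full analysis — mask, filter, annotate, diversity/divergence, the four
neutrality statistics with coalescent-simulated P-values, the compound DHEW
outlier decision, and across-locus bootstrap species summaries — and
returns a results object carrying tidy per-gene and per-species tables.

Null simulations for each gene condition on the standard neutral model and
that gene's observed diversity (theta_locus = theta_pi * L) and sample
size.  All randomness derives from a single run seed: each gene gets a
deterministic substream keyed by (seed, crc32(gene_id)), so any gene is
replayable in isolation and a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from zlib import crc32

import numpy as np
import pandas as pd
import yaml

from .alignment import (
    GeneAlignment,
    filter_sites,
    mask_primers,
    outgroup_consensus,
    read_gene_fasta,
    read_primer_tsv,
)
from .annotation import CodingInterval, classify_sites, percent, read_annotation_tsv
from .bootstrap import bootstrap_mean_ci
from .coalescent import empirical_pvalue, null_statistics
from .dhew import calibrate_pstar, dhew_test
from .diversity import compute_gene_diversity
from .neutrality import gene_neutrality

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Run-wide settings; defaults are the full study-scale values
    (10,000 single-test replicates, 50,000 DHEW calibration replicates at
    a = 0.0001, 10,000 bootstrap replicates)."""

    outgroup_tag: str = "Ptaeda"
    seed: int = 0
    reps_single: int = 10000
    reps_dhew: int = 50000
    a: float = 0.0001
    bootstrap_reps: int = 10000
    ci_level: float = 0.95
    monomorphic_as_zero: bool = True
    run_dhew: bool = True
    run_neutrality: bool = True
    fixed_s: bool = False  # condition nulls on observed S instead of theta_pi

    def __post_init__(self) -> None:
        if not 0 < self.a <= 1:
            raise ValueError("a must lie in (0, 1]")
        if self.reps_single < 1 or self.reps_dhew < 1 or self.bootstrap_reps < 1:
            raise ValueError("replicate counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


class NeutralityScan:
    """Diversity / neutrality-outlier scan over a collection of genes.

    Parameters
    ----------
    alignments:
        Per-gene :class:`GeneAlignment` objects (each may carry primer
        intervals).
    annotations:
        Optional per-gene coding intervals; genes without annotation get
        NaN category statistics, mirroring partially annotated studies.
    config:
        :class:`RunConfig`; replicate counts there control runtime.
    """

    def __init__(
        self,
        alignments: list[GeneAlignment],
        annotations: dict[str, list[CodingInterval]] | None = None,
        config: RunConfig | None = None,
    ) -> None:
        self.alignments = list(alignments)
        self.annotations = annotations or {}
        self.config = config or RunConfig()

    @classmethod
    def from_manifest(
        cls, manifest_path: str | Path, config: RunConfig | None = None
    ) -> "NeutralityScan":
        """Build a scan from a study directory: ``manifest.tsv`` with
        columns gene_id, species, category, path (FASTA relative to the
        manifest), plus optional ``annotations.tsv`` and ``primers.tsv``."""
        config = config or RunConfig()
        manifest_path = Path(manifest_path)
        base = manifest_path.parent
        manifest = pd.read_csv(manifest_path, sep="\t")
        ann_path = base / "annotations.tsv"
        annotations = read_annotation_tsv(ann_path) if ann_path.exists() else {}
        primer_path = base / "primers.tsv"
        primers = read_primer_tsv(primer_path) if primer_path.exists() else {}
        alignments = []
        for row in manifest.itertuples():
            aln = read_gene_fasta(
                base / row.path,
                config.outgroup_tag,
                gene_id=row.gene_id,
                species=getattr(row, "species", ""),
                category=getattr(row, "category", "control"),
                require_outgroup=False,
            )
            if row.gene_id in primers:
                aln = replace(aln, primer_intervals=primers[row.gene_id])
            alignments.append(aln)
        return cls(alignments, annotations, config)

    # ------------------------------------------------------------------

    def fit(self, seed: int | None = None) -> "ScanResults":
        """Run the full analysis; deterministic for a fixed seed."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        div_rows, neut_rows, out_rows, log_rows = [], [], [], []
        for aln in self.alignments:
            sub = np.random.SeedSequence([seed, crc32(aln.gene_id.encode())])
            rng = np.random.default_rng(sub)
            try:
                row_d, row_n, row_o, log = self._fit_gene(aln, rng, cfg)
            except Exception as exc:  # per-gene failure never aborts the run
                log_rows.append(
                    dict(gene_id=aln.gene_id, status="failed", detail=repr(exc)[:200],
                         n=aln.n, L=0, S=0)
                )
                continue
            div_rows.append(row_d)
            if row_n is not None:
                neut_rows.append(row_n)
            if row_o is not None:
                out_rows.append(row_o)
            log_rows.append(log)
        diversity = pd.DataFrame(div_rows)
        neutrality = pd.DataFrame(neut_rows)
        outliers = pd.DataFrame(out_rows)
        summary = self._species_summary(diversity, seed, cfg)
        log = pd.DataFrame(log_rows)
        return ScanResults(
            diversity=diversity,
            neutrality=neutrality,
            outliers=outliers,
            species_summary=summary,
            log=log,
            config=cfg,
            seed=seed,
        )

    def _fit_gene(self, aln: GeneAlignment, rng, cfg: RunConfig):
        masked = mask_primers(aln)
        f = filter_sites(masked)
        cons = outgroup_consensus(masked) if masked.has_outgroup else None
        intervals = self.annotations.get(aln.gene_id)
        ann = classify_sites(f, intervals) if (intervals and f.L) else None
        gd = compute_gene_diversity(f, ann, cons)
        row_d = dict(
            gene_id=aln.gene_id,
            species=aln.species,
            category=aln.category,
            n=gd.n,
            L=gd.L,
            S=gd.S,
            theta_pi=gd.theta_pi,
            theta_w=gd.theta_w,
            dxy=gd.dxy,
            pi_noncoding=gd.pi_by_category.get("noncoding", math.nan),
            pi_nonsyn=gd.pi_by_category.get("nonsynonymous", math.nan),
            pi_syn=gd.pi_by_category.get("synonymous", math.nan),
            pi_silent=gd.pi_by_category.get("silent", math.nan),
            thetaw_noncoding=gd.thetaw_by_category.get("noncoding", math.nan),
            thetaw_nonsyn=gd.thetaw_by_category.get("nonsynonymous", math.nan),
            thetaw_syn=gd.thetaw_by_category.get("synonymous", math.nan),
            Ka=gd.ka,
            Ks=gd.ks,
            ratio_pia_pis=gd.ratio_pia_pis,
            ratio_ka_ks=gd.ratio_ka_ks,
        )
        row_n = None
        row_o = None
        if cfg.run_neutrality and f.L > 0 and gd.S >= 1:
            res = gene_neutrality(f, cons)
            theta_locus = gd.theta_pi * f.L
            if cfg.fixed_s:
                from .coalescent import fixed_s_simulator

                simulator = fixed_s_simulator(gd.S)
            else:
                from .coalescent import simulate_replicate as simulator
            nulls = null_statistics(
                f.n, theta_locus, cfg.reps_single, rng, simulator=simulator
            )
            res.P_D = empirical_pvalue(res.D, nulls["D"], "lower")
            res.P_H = empirical_pvalue(res.H, nulls["H"], "lower")
            res.P_EW = empirical_pvalue(res.F, nulls["F"], "lower")
            res.P_Zns = empirical_pvalue(res.Zns, nulls["Zns"], "lower")
            p_ew_upper = empirical_pvalue(res.F, nulls["F"], "upper")
            row_n = dict(
                gene_id=aln.gene_id,
                species=aln.species,
                category=aln.category,
                S=res.S,
                D=res.D,
                H=res.H,
                F=res.F,
                Zns=res.Zns,
                P_D=res.P_D,
                P_H=res.P_H,
                P_EW=res.P_EW,
                P_Zns=res.P_Zns,
                unpolarized=res.unpolarized,
            )
            if cfg.run_dhew:
                if res.S >= 2 and not any(
                    math.isnan(x) for x in (res.P_D, res.P_H, res.P_EW)
                ):
                    cal = calibrate_pstar(
                        f.n, theta_locus, cfg.a, cfg.reps_dhew, rng=rng,
                        simulator=simulator,
                    )
                    dres = dhew_test(
                        aln.gene_id, res.S, res.P_D, res.P_H, res.P_EW,
                        cal, p_ew_upper=p_ew_upper,
                    )
                else:
                    dres = dhew_test(
                        aln.gene_id, res.S, res.P_D, res.P_H, res.P_EW,
                        math.nan, a=cfg.a,
                    )
                row_o = dict(
                    gene_id=aln.gene_id,
                    species=aln.species,
                    category=aln.category,
                    S=res.S,
                    P_D=res.P_D,
                    P_H=res.P_H,
                    P_EW=res.P_EW,
                    P_Zns=res.P_Zns,
                    P_star=dres.p_star,
                    outlier=(int(dres.outlier) if dres.outlier is not None else pd.NA),
                    excluded=int(dres.excluded),
                    reason=dres.reason,
                )
        log = dict(
            gene_id=aln.gene_id, status="ok", detail="",
            n=f.n, L=f.L, S=gd.S,
        )
        return row_d, row_n, row_o, log

    def _species_summary(self, diversity: pd.DataFrame, seed: int, cfg: RunConfig):
        if diversity.empty:
            return pd.DataFrame()
        rows = []
        stats = ("S", "theta_pi", "theta_w", "dxy")
        for (species, category), grp in diversity.groupby(
            ["species", "category"], sort=True
        ):
            sub = grp
            if not cfg.monomorphic_as_zero:
                sub = grp[grp["S"] > 0]
            row = dict(
                species=species,
                category=category,
                n_genes=len(grp),
                n_polymorphic=int((grp["S"] > 0).sum()),
                percent_polymorphic=percent(int((grp["S"] > 0).sum()), len(grp), 2),
            )
            boot_rng = np.random.default_rng(
                np.random.SeedSequence(
                    [seed, crc32(f"boot|{species}|{category}".encode())]
                )
            )
            for stat in stats:
                vals = sub[stat].to_numpy(dtype=float)
                bs = bootstrap_mean_ci(
                    vals,
                    reps=cfg.bootstrap_reps,
                    level=cfg.ci_level,
                    rng=boot_rng,
                    species=str(species),
                    statistic_name=stat,
                )
                row[f"{stat}_mean"] = bs.mean
                row[f"{stat}_sd"] = (
                    float(np.nanstd(vals, ddof=1)) if bs.n_used > 1 else math.nan
                )
                row[f"{stat}_ci_low"] = bs.ci_low
                row[f"{stat}_ci_high"] = bs.ci_high
            rows.append(row)
        return pd.DataFrame(rows)


def summarize_outliers(
    outliers: pd.DataFrame, totals: pd.Series | dict, decimals: int = 2
) -> pd.DataFrame:
    """Percent of outlier genes per (species, category).

    ``totals`` maps (species, category) to the total gene count for that
    cell (the denominator includes genes excluded from the compound test).
    """
    if isinstance(totals, dict):
        totals = pd.Series(totals)
    rows = []
    for key, total in totals.items():
        species, category = key
        if outliers.empty:
            k = 0
        else:
            sel = (outliers["species"] == species) & (outliers["category"] == category)
            k = int((outliers.loc[sel, "outlier"] == 1).sum())
        rows.append(
            dict(
                species=species,
                category=category,
                n_outliers=k,
                n_genes=int(total),
                percent_outliers=percent(k, int(total), decimals),
            )
        )
    return pd.DataFrame(rows)


@dataclass
class ScanResults:
    """Fitted scan: tidy per-gene and per-species tables.

    ``diversity`` mirrors the per-gene diversity/divergence table,
    ``neutrality`` the statistic/P-value table, ``outliers`` the compound
    DHEW table, and ``species_summary`` the species-by-category means with
    bootstrap CIs.  NaN renders as "NA" in the TSV exports.
    """

    diversity: pd.DataFrame
    neutrality: pd.DataFrame
    outliers: pd.DataFrame
    species_summary: pd.DataFrame
    log: pd.DataFrame
    config: RunConfig
    seed: int = 0

    def outlier_proportions(self, decimals: int = 2) -> pd.DataFrame:
        totals = self.diversity.groupby(["species", "category"]).size()
        return summarize_outliers(self.outliers, totals, decimals)

    def summary(self) -> str:
        """Human-readable run summary."""
        lines = [
            "Nucleotide diversity / neutrality-outlier scan",
            f"  genes analysed: {len(self.diversity)}   seed: {self.seed}",
            f"  null reps/gene: {self.config.reps_single}   "
            f"DHEW reps: {self.config.reps_dhew} at a={self.config.a:g}",
            "",
        ]
        if not self.species_summary.empty:
            cols = [
                "species", "category", "n_genes", "percent_polymorphic",
                "theta_pi_mean", "theta_pi_ci_low", "theta_pi_ci_high",
                "theta_w_mean", "dxy_mean",
            ]
            present = [c for c in cols if c in self.species_summary.columns]
            lines.append(self.species_summary[present].to_string(
                index=False, float_format=lambda v: f"{v:.4g}"))
            lines.append("")
        if not self.outliers.empty:
            props = self.outlier_proportions()
            lines.append("Compound DHEW outliers (% of genes per cell):")
            lines.append(props.to_string(index=False))
        return "\n".join(lines)

    def to_tsv(self, outdir: str | Path) -> None:
        """Write the five output tables; byte-identical across reruns with
        the same seed and config."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "diversity.tsv": self.diversity,
            "neutrality.tsv": self.neutrality,
            "outliers.tsv": self.outliers,
            "species_summary.tsv": self.species_summary,
            "run_log.tsv": self.log,
        }
        for name, df in tables.items():
            df.to_csv(
                outdir / name,
                sep="\t",
                index=False,
                na_rep="NA",
                float_format=_FLOAT_FMT,
                lineterminator="\n",
            )

    def plot_species_ci(self, statistic: str = "theta_pi", ax=None):
        """Errorbar plot of species means with bootstrap CIs (per
        category), in the style of across-species diversity comparisons."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        df = self.species_summary
        for off, (category, grp) in enumerate(df.groupby("category")):
            x = np.arange(len(grp)) + 0.15 * off
            mean = grp[f"{statistic}_mean"]
            lo = mean - grp[f"{statistic}_ci_low"]
            hi = grp[f"{statistic}_ci_high"] - mean
            ax.errorbar(x, mean, yerr=[lo, hi], fmt="o", capsize=3, label=category)
            ax.set_xticks(np.arange(len(grp)))
            ax.set_xticklabels(grp["species"], rotation=30, ha="right")
        ax.set_ylabel(statistic)
        ax.legend()
        return ax


def run_study(
    manifest_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> ScanResults:
    """Convenience wrapper: build a scan from a manifest, fit, write the
    output tables, and return the results."""
    scan = NeutralityScan.from_manifest(manifest_path, config)
    results = scan.fit(seed=seed)
    results.to_tsv(out_dir)
    return results
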