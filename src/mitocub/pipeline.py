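"""End-to-end analysis pipeline: screen -> metrics -> diagnostics -> optimal
codons -> clustering, with TSV/Newick/JSON outputs.

The default configuration reproduces the analysis conditions of the
comparative Medicago mitogenome study design this package implements:
>300 bp ATG..stop screening, standard genetic code, 10% ENC-ranked
expression pools, ΔRSCU >= 0.08, GC3s as the ENC-plot axis, strict
(fourfold-site) PR2, average linkage on 1 - Pearson r for RSCU clustering.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bias_diagnostics as diag
from . import codon_metrics as cm
from . import genome_io as gio
from . import optimal_codons as oc
from .genetic_code import get_code, to_rna

logger = logging.getLogger(__name__)

# output precision: RSCU/ΔRSCU 4 decimals, indices 3, percentages 2
_RSCU_FMT = "%.4f"


@dataclass
class RunConfig:
    """Configuration surface of one pipeline run."""

    inputs: list[tuple[str, str]]  # (species label, path to GenBank/FASTA)
    outdir: str = "mitocub_out"
    genetic_code: int = 1
    min_length_bp: int = 300  # strict >
    pool_fraction: float = 0.10
    delta_threshold: float = 0.08
    reference: str = "self"  # reference set for CAI/CBI/Fop
    enc_x: str = "gc3s"  # or "gc3"
    pr2_fourfold: bool = True
    linkage: str = "average"
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [s for s, _ in self.inputs]
        if len(set(labels)) != len(labels):
            raise ValueError("species labels must be unique")
        if self.min_length_bp <= 0 or not 0 < self.pool_fraction <= 0.5:
            raise ValueError("thresholds must be positive (pool fraction <= 0.5)")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a JSON config file; keyword arguments override file values."""
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        data["inputs"] = [tuple(p) for p in data["inputs"]]
        return cls(**data)


@dataclass
class RunReport:
    """Manifest of produced files, per-stage summaries, and warnings."""

    files: list[str] = field(default_factory=list)
    summaries: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add(self, path: Path) -> None:
        self.files.append(str(path))

    def to_json(self) -> str:
        return json.dumps(
            {
                "files": self.files,
                "summaries": self.summaries,
                "warnings": self.warnings,
            },
            indent=2,
            default=str,
        )


def _round(df: pd.DataFrame, spec: dict[str, int]) -> pd.DataFrame:
    out = df.copy()
    for col, nd in spec.items():
        if col in out.columns:
            out[col] = out[col].astype(float).round(nd)
    return out


def _read_input(path: str, species: str) -> gio.GenomeRecord:
    p = Path(path)
    if p.suffix.lower() in (".gb", ".gbk", ".gbff", ".genbank"):
        return gio.read_genbank(p, species=species)
    return gio.read_fasta_cds(p, species=species)


def _profile_table_tsv(profiles: pd.DataFrame, path: Path) -> None:
    rounded = _round(
        profiles,
        {
            "cai": 3, "cbi": 3, "fop": 3, "enc": 3,
            "gc1": 2, "gc2": 2, "gc3": 2, "gc_all": 2, "gc12": 2, "gc3s": 2,
            "a3s": 4, "t3s": 4, "c3s": 4, "g3s": 4,
        },
    )
    rounded.to_csv(path, sep="\t", index=False)


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline and return the run report.

    Produces, per species: screened-CDS FASTA, screening manifest,
    per-gene index TSV, genome and pool RSCU/optimal-codon TSVs, neutrality,
    ENC-deviation and PR2 TSVs, and a correlation matrix.  Across species:
    shared-CDS manifest, shared-optimal-codon summary, and an RSCU
    dendrogram in Newick format.  With a single input the cross-species
    stages are skipped with a warning.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    code = get_code(config.genetic_code)

    screened: dict[str, list[gio.CodingSequence]] = {}
    optimal_sets: dict[str, frozenset[str]] = {}
    genome_rscu_rows: dict[str, pd.Series] = {}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for species, path in config.inputs:
            sdir = outdir / species.replace(" ", "_")
            sdir.mkdir(exist_ok=True)
            record = _read_input(path, species)
            manifest: list[dict] = []
            cds_list = gio.screen_cds(
                record,
                min_length_bp=config.min_length_bp,
                genetic_code=config.genetic_code,
                manifest=manifest,
            )
            screened[species] = cds_list
            gio.write_manifest(manifest, sdir / "screening_manifest.tsv")
            report.add(sdir / "screening_manifest.tsv")
            if not cds_list:
                report.warnings.append(f"{species}: no CDS passed screening")
                continue
            gio.write_fasta(cds_list, sdir / "screened_cds.fasta")
            report.add(sdir / "screened_cds.fasta")

            profiles = cm.profile_genes(
                cds_list,
                genetic_code=config.genetic_code,
                reference=config.reference,
                pool_fraction=config.pool_fraction,
            )
            _profile_table_tsv(profiles, sdir / "gene_indices.tsv")
            report.add(sdir / "gene_indices.tsv")

            counts = [
                cm.count_codons(c, genetic_code=config.genetic_code)
                for c in cds_list
            ]
            genome_pool = cm.pool_counts(counts, source=species)
            genome_rscu = cm.rscu(genome_pool, code)
            rscu_df = pd.DataFrame(
                {
                    "amino_acid": [code.codon_to_aa[c] for c in sorted(genome_rscu)],
                    "codon": [to_rna(c) for c in sorted(genome_rscu)],
                    "rscu": [genome_rscu[c] for c in sorted(genome_rscu)],
                }
            ).sort_values(["amino_acid", "codon"])
            _round(rscu_df, {"rscu": 4}).to_csv(
                sdir / "genome_rscu.tsv", sep="\t", index=False
            )
            report.add(sdir / "genome_rscu.tsv")
            genome_rscu_rows[species] = cm.rscu_vector(genome_pool, code).rename(species)

            # diagnostics
            neut = diag.neutrality_regression(profiles)
            pd.DataFrame(
                [
                    {
                        "slope": round(neut.slope, 4),
                        "intercept": round(neut.intercept, 4),
                        "pearson_r": round(neut.pearson_r, 4),
                        "p_value": round(neut.p_value, 4),
                        "interpretation": neut.interpretation,
                    }
                ]
            ).to_csv(sdir / "neutrality.tsv", sep="\t", index=False)
            report.add(sdir / "neutrality.tsv")

            encres = diag.enc_plot(profiles, x=config.enc_x)
            pd.DataFrame(
                {
                    "gene": encres.genes,
                    config.enc_x: [round(100 * p[0], 2) for p in encres.points],
                    "enc": [round(p[1], 3) for p in encres.points],
                    "enc_expected": [
                        round(p[1] - d, 3)
                        for p, d in zip(encres.points, encres.deviations)
                    ],
                    "deviation": [round(d, 3) for d in encres.deviations],
                }
            ).to_csv(sdir / "enc_plot.tsv", sep="\t", index=False)
            report.add(sdir / "enc_plot.tsv")

            pr2_df = diag.pr2_table(
                counts, code, fourfold_only=config.pr2_fourfold
            )
            _round(pr2_df, {"x_g3_over_g3c3": 4, "y_a3_over_a3t3": 4}).to_csv(
                sdir / "pr2.tsv", sep="\t", index=False
            )
            report.add(sdir / "pr2.tsv")

            corr = diag.correlation_matrix(profiles)
            starred = corr.r.round(2).astype(str) + corr.stars
            starred.to_csv(sdir / "correlation_matrix.tsv", sep="\t")
            report.add(sdir / "correlation_matrix.tsv")

            # optimal codons
            finder = oc.OptimalCodonFinder(
                pool_fraction=config.pool_fraction,
                delta_threshold=config.delta_threshold,
                genetic_code=config.genetic_code,
            ).fit(cds_list)
            tab = finder.report_.table.copy()
            tab["codon"] = tab["codon"].map(to_rna)
            _round(tab, {"rscu_high": 4, "rscu_low": 4, "delta_rscu": 4}).to_csv(
                sdir / "optimal_codons.tsv", sep="\t", index=False
            )
            report.add(sdir / "optimal_codons.tsv")
            optimal_sets[species] = frozenset(
                to_rna(c) for c in finder.optimal_codons_
            )

            report.summaries[species] = {
                "n_cds_in": len(record.cds_features),
                "n_cds_screened": len(cds_list),
                "mean_enc": round(float(profiles["enc"].mean()), 2),
                "neutrality_slope": round(neut.slope, 4),
                "high_pool": finder.pools_.high_pool,
                "low_pool": finder.pools_.low_pool,
                "n_optimal": finder.report_.n_optimal,
                "enc_below_curve": encres.n_below,
            }

            if config.make_plots:
                _make_plots(sdir, profiles, neut, encres, pr2_df, report)

        # cross-species stages
        if len(screened) >= 2:
            shared = gio.shared_cds(list(screened.values()))
            rows = [
                {
                    "gene": gene,
                    **{
                        cds.species: cds.length_bp
                        for cds in cds_per_species
                    },
                }
                for gene, cds_per_species in shared.items()
            ]
            pd.DataFrame(rows).to_csv(
                outdir / "shared_cds_manifest.tsv", sep="\t", index=False
            )
            report.add(outdir / "shared_cds_manifest.tsv")
            if not shared:
                raise ValueError("no CDS shared across the input species")
            report.summaries["shared_genes"] = sorted(shared)

            summary = oc.shared_optimal(list(optimal_sets.values()))
            pd.DataFrame(
                [
                    {
                        "n_shared": summary["n_shared"],
                        "shared_codons": ",".join(sorted(summary["shared"])),
                        "n_au_ending": summary["n_au_ending"],
                        "n_gc_ending": summary["n_gc_ending"],
                    }
                ]
            ).to_csv(outdir / "shared_optimal_codons.tsv", sep="\t", index=False)
            report.add(outdir / "shared_optimal_codons.tsv")
            report.summaries["shared_optimal"] = sorted(summary["shared"])

            rscu_matrix = pd.DataFrame(genome_rscu_rows).T
            dend = diag.rscu_cluster(rscu_matrix, linkage=config.linkage)
            (outdir / "rscu_dendrogram.nwk").write_text(dend.newick + "\n")
            report.add(outdir / "rscu_dendrogram.nwk")
        else:
            msg = "single species input: cross-species stages skipped"
            report.warnings.append(msg)
            logger.warning(msg)

        report.warnings.extend(str(w.message) for w in caught)

    (outdir / "run_report.json").write_text(report.to_json())
    report.add(outdir / "run_report.json")
    return report


def _make_plots(sdir: Path, profiles, neut, encres, pr2_df, report: RunReport) -> None:
    """Basic neutrality / ENC / PR2 scatter plots (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    # neutrality
    fig, ax = plt.subplots(figsize=(5, 4))
    xs = [p[0] for p in neut.points]
    ys = [p[1] for p in neut.points]
    ax.scatter(xs, ys, s=18)
    grid = np.linspace(min(xs), max(xs), 50)
    ax.plot(grid, neut.slope * grid + neut.intercept, "r-",
            label=f"slope={neut.slope:.3f}")
    ax.set_xlabel("GC3 (%)")
    ax.set_ylabel("GC12 (%)")
    ax.legend()
    fig.savefig(sdir / "neutrality.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    report.add(sdir / "neutrality.png")

    # ENC plot
    fig, ax = plt.subplots(figsize=(5, 4))
    gx = np.linspace(0.01, 0.99, 99)
    ax.plot(gx * 100, diag.enc_expected(gx), "k--", label="expected")
    ax.scatter([100 * p[0] for p in encres.points], [p[1] for p in encres.points], s=18)
    ax.set_xlabel(f"{encres.x_variable.upper()} (%)")
    ax.set_ylabel("ENC")
    ax.legend()
    fig.savefig(sdir / "enc_plot.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    report.add(sdir / "enc_plot.png")

    # PR2
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(pr2_df["x_g3_over_g3c3"], pr2_df["y_a3_over_a3t3"], s=18)
    ax.axhline(0.5, color="grey", lw=0.8)
    ax.axvline(0.5, color="grey", lw=0.8)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("G3/(G3+C3)")
    ax.set_ylabel("A3/(A3+T3)")
    fig.savefig(sdir / "pr2.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    report.add(sdir / "pr2.png")
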