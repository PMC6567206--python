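"""End-to-end orchestration: filter -> classify -> profile -> blocks
(-> annotate), with a consolidated plain-text report.

All non-log outputs are deterministic: re-running an identical configuration
reproduces them byte for byte, and every number in the rendered summary can
be re-derived from the per-site table written alongside it.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pysam

from . import __version__
from .blocks import (
    GenotypeBlock,
    WindowDensity,
    blocks_to_bed,
    call_blocks,
    window_density,
    windows_to_tsv,
)
from .effects import (
    EffectAnnotation,
    Variant,
    annotate_variant,
    crossref_trait_genes,
    load_gene_models,
    load_genome,
    load_trait_table,
    summarize_effects,
)
from .profile import (
    ClassifiedSite,
    ProfileSummary,
    classified_to_tsv,
    classify_sites,
    per_chromosome_recovery,
    profile_summary,
    round_percent,
)
from .variants import (
    ConfigurationError,
    FilterConfig,
    FilterTally,
    apply_site_filters,
    read_multisample_variants,
    select_informative_sites,
)

logger = logging.getLogger("mabc")


@dataclass
class PipelineConfig:
    vcf: str
    donor: str
    recurrent: str
    progeny: str
    outdir: str
    filter: FilterConfig = field(default_factory=FilterConfig)
    window_size: int = 10_000
    window_step: Optional[int] = None
    min_markers: int = 3
    max_gap: int = 1_000_000
    chrom_sizes: Optional[str] = None  # TSV chrom<TAB>length; else VCF header
    genome_fasta: Optional[str] = None
    gff3: Optional[str] = None
    trait_table: Optional[str] = None
    plot: bool = False

    @property
    def role_map(self) -> Dict[str, str]:
        return {self.donor: "donor", self.recurrent: "recurrent", self.progeny: "progeny"}

    def validate(self) -> None:
        if not Path(self.vcf).exists():
            raise ConfigurationError(f"input VCF not found: {self.vcf}")
        annotate = [self.genome_fasta, self.gff3]
        if any(annotate) and not all(annotate):
            raise ConfigurationError(
                "annotation requires both --fasta and --gff (one is missing)"
            )
        for label, path in (
            ("chrom sizes", self.chrom_sizes),
            ("genome FASTA", self.genome_fasta),
            ("GFF3", self.gff3),
            ("trait table", self.trait_table),
        ):
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"{label} file not found: {path}")


@dataclass
class PipelineResult:
    tally: FilterTally
    n_informative: int
    n_parental_identical: int
    profile: ProfileSummary
    per_chrom_recovery: Dict[str, float]
    classified: List[ClassifiedSite]
    blocks: List[GenotypeBlock]
    windows: List[WindowDensity]
    effects: Optional[object] = None  # pandas tally DataFrame
    trait_report: Optional[object] = None


def _chrom_lengths(cfg: PipelineConfig, classified: List[ClassifiedSite]) -> Dict[str, int]:
    if cfg.chrom_sizes:
        out = {}
        for line in Path(cfg.chrom_sizes).read_text().strip().splitlines():
            chrom, length = line.split("\t")[:2]
            out[chrom] = int(length)
        return out
    with pysam.VariantFile(cfg.vcf) as vf:
        contigs = {
            name: c.length for name, c in vf.header.contigs.items() if c.length
        }
    if contigs:
        return contigs
    logger.warning("no contig lengths available; using max marker position per chromosome")
    out: Dict[str, int] = {}
    for site in classified:
        out[site.chrom] = max(out.get(site.chrom, 0), site.pos)
    return out


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full characterization pipeline and write the report bundle."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "filter"
    try:
        sites = list(read_multisample_variants(cfg.vcf, cfg.role_map))
        passing, tally = apply_site_filters(sites, cfg.filter)
        informative, dropped = select_informative_sites(passing)

        stage = "classify"
        classified = classify_sites(informative)
        profile = profile_summary(classified)
        per_chrom = per_chromosome_recovery(classified)

        stage = "blocks"
        chrom_lengths = _chrom_lengths(cfg, classified)
        windows = window_density(
            classified, chrom_lengths, cfg.window_size, cfg.window_step
        )
        blocks = call_blocks(classified, cfg.min_markers, cfg.max_gap)

        effects_tally = trait_report = None
        informative_by_key = {(s.chrom, s.pos): s for s in informative}
        if cfg.genome_fasta and cfg.gff3:
            stage = "annotate"
            genome = load_genome(cfg.genome_fasta)
            models = load_gene_models(cfg.gff3)
            annotations = [
                annotate_variant(
                    Variant(s.chrom, s.pos, s.ref, s.alts[0]), models, genome
                )
                for s in informative
            ]
            effects_tally = summarize_effects(annotations, classified)
            if cfg.trait_table:
                trait_report = crossref_trait_genes(
                    annotations, classified, load_trait_table(cfg.trait_table)
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    result = PipelineResult(
        tally=tally,
        n_informative=len(informative),
        n_parental_identical=dropped,
        profile=profile,
        per_chrom_recovery=per_chrom,
        classified=classified,
        blocks=blocks,
        windows=windows,
        effects=effects_tally,
        trait_report=trait_report,
    )

    (outdir / "filter_tally.tsv").write_text(tally.to_tsv())
    (outdir / "sites.tsv").write_text(classified_to_tsv(classified))
    (outdir / "summary.tsv").write_text(profile.to_tsv())
    (outdir / "blocks.bed").write_text(blocks_to_bed(blocks))
    (outdir / "windows.tsv").write_text(windows_to_tsv(windows))
    if effects_tally is not None:
        effects_tally.to_csv(outdir / "effects.tsv", sep="\t", index=False)
    if trait_report is not None:
        trait_report.to_csv(outdir / "trait_report.tsv", sep="\t", index=False)
    (outdir / "report.txt").write_text(render_summary(result))
    (outdir / "run.log").write_text(_run_log(cfg, result))
    if cfg.plot:
        from .blocks import plot_genotype_map

        plot_genotype_map(result.blocks, chrom_lengths, str(outdir / "genotype_map.png"))
    return result


def render_summary(result: PipelineResult) -> str:
    """Deterministic human-readable report (counts table, recovery rates,
    block and effect summaries)."""
    p = result.profile
    lines = [
        "# marker-assisted backcross genome characterization",
        "",
        "## site filtering",
        f"input sites:            {result.tally.input_count}",
    ]
    for name, count in sorted(result.tally.removed.items()):
        lines.append(f"removed ({name}): {count}")
    lines += [
        f"passing sites:          {result.tally.passing}",
        f"parental-identical:     {result.n_parental_identical}",
        f"informative markers:    {result.n_informative}",
        "",
        "## genotype profile (counts: SNPs / indels / total / genome %)",
    ]
    pct = p.percentages() if p.classified_total else {}
    from .profile import GenotypeClass

    labels = [
        ("recurrent-parent hom", GenotypeClass.RECURRENT_HOM),
        ("donor-parent hom    ", GenotypeClass.DONOR_HOM),
        ("heterozygous        ", GenotypeClass.HET),
    ]
    if p.classified_total:
        for label, g in labels:
            s = p.counts.get((g, "SNP"), 0)
            i = p.counts.get((g, "INDEL"), 0)
            lines.append(f"{label}  {s} / {i} / {s + i} / {pct[g]:.1f}")
        lines.append(
            f"total                 {p.classified_total} / 100.0"
        )
        lines.append(f"non-parental sites:   {p.non_parental}")
        lines.append(
            f"genome recovery rate: {round_percent(p.recovery_rate):.1f}%"
        )
        lines.append("")
        lines.append("## per-chromosome recovery (%)")
        for chrom in sorted(result.per_chrom_recovery):
            lines.append(
                f"{chrom}\t{round_percent(result.per_chrom_recovery[chrom]):.1f}"
            )
    else:
        lines.append("no classified sites")
    lines.append("")
    lines.append("## genotype blocks")
    real = [b for b in result.blocks if not b.flagged]
    micro = [b for b in result.blocks if b.flagged]
    if result.blocks:
        lines.append(f"blocks: {len(real)} (+{len(micro)} flagged micro-blocks)")
    else:
        lines.append("no blocks")
    if result.effects is not None:
        lines.append("")
        lines.append("## effect annotation")
        if len(result.effects):
            from .effects import protein_altering_counts

            lines.append(f"annotated terms: {int(result.effects['n'].sum())}")
            for gclass, n in sorted(protein_altering_counts(result.effects).items()):
                lines.append(f"protein-altering ({gclass}): {n}")
        else:
            lines.append("no annotations")
    if result.trait_report is not None:
        lines.append(f"trait-gene report rows: {len(result.trait_report)}")
    return "\n".join(lines) + "\n"


def _run_log(cfg: PipelineConfig, result: PipelineResult) -> str:
    lines = [
        f"mabc version: {__version__}",
        f"python: {sys.version.split()[0]}",
        f"input vcf: {cfg.vcf}",
        f"roles: donor={cfg.donor} recurrent={cfg.recurrent} progeny={cfg.progeny}",
        f"filter config: {cfg.filter}",
        f"window: size={cfg.window_size} step={cfg.window_step or cfg.window_size}",
        f"blocks: min_markers={cfg.min_markers} max_gap={cfg.max_gap}",
        f"warnings: {dict(result.tally.warnings)}",
    ]
    return "\n".join(lines) + "\n"
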