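"""Minimal codon-level variant-effect classifier.

Assigns one Sequence Ontology consequence term per variant (the most severe
across overlapping transcripts) by rebuilding and translating the mutant
coding sequence, in the spirit of SnpEff but restricted to the term set
needed for tallying protein-altering variants in a breeding line:

stop_gained, stop_lost, start_lost, frameshift_variant,
splice_donor_variant, splice_acceptor_variant, missense_variant,
inframe_insertion, inframe_deletion, synonymous_variant, UTR_variant,
intron_variant, intergenic_variant.

Impact tiers follow the usual fixed map (HIGH for stop/start/frameshift/
splice, MODERATE for missense/in-frame indels, LOW for synonymous, MODIFIER
for non-coding). Splice sites are the canonical 2 nt at each intron end.
Gene models use GFF3 conventions: 1-based inclusive intervals, CDS phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import pandas as pd
from Bio.Seq import Seq

#: Fixed severity order (most severe first); total over all emitted terms.
SEVERITY_ORDER = (
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift_variant",
    "splice_donor_variant",
    "splice_acceptor_variant",
    "missense_variant",
    "inframe_insertion",
    "inframe_deletion",
    "synonymous_variant",
    "UTR_variant",
    "intron_variant",
    "intergenic_variant",
)
_RANK = {t: i for i, t in enumerate(SEVERITY_ORDER)}

IMPACT = {
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "frameshift_variant": "HIGH",
    "splice_donor_variant": "HIGH",
    "splice_acceptor_variant": "HIGH",
    "missense_variant": "MODERATE",
    "inframe_insertion": "MODERATE",
    "inframe_deletion": "MODERATE",
    "synonymous_variant": "LOW",
    "UTR_variant": "MODIFIER",
    "intron_variant": "MODIFIER",
    "intergenic_variant": "MODIFIER",
}

SPLICE_SITE_WIDTH = 2  # canonical donor/acceptor dinucleotides


class Variant(NamedTuple):
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    @property
    def end(self) -> int:  # last reference base touched (1-based inclusive)
        return self.pos + len(self.ref) - 1

    @property
    def variant_class(self) -> str:
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"


class ReferenceMismatchError(ValueError):
    """Variant REF allele disagrees with the genome sequence."""


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # "+" | "-"
    exons: Tuple[Tuple[int, int], ...]  # 1-based inclusive, sorted by start
    cds: Tuple[Tuple[int, int], ...]  # subset of exon space

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: Tuple[Transcript, ...]


@dataclass(frozen=True)
class EffectAnnotation:
    variant: Variant
    so_term: str
    impact: str
    gene_id: Optional[str] = None
    transcript_id: Optional[str] = None
    protein_change: Optional[str] = None


def load_genome(fasta_path: str) -> Dict[str, str]:
    """Genome FASTA into an uppercase in-memory chrom->sequence map."""
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")
    }


def load_gene_models(gff_source: str, from_string: bool = False) -> List[GeneModel]:
    """Parse GFF3 gene models (gene -> mRNA/transcript -> exon/CDS) via an
    in-memory gffutils database."""
    import gffutils

    db = gffutils.create_db(
        gff_source,
        dbfn=":memory:",
        from_string=from_string,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: List[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = []
        for tr in db.children(gene, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = tuple(
                sorted((f.start, f.end) for f in db.children(tr, featuretype="exon"))
            )
            cds = tuple(
                sorted((f.start, f.end) for f in db.children(tr, featuretype="CDS"))
            )
            if not exons and cds:
                exons = cds
            transcripts.append(
                Transcript(
                    transcript_id=tr.id,
                    gene_id=gene.id,
                    chrom=gene.seqid,
                    strand=gene.strand,
                    exons=exons,
                    cds=cds,
                )
            )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                transcripts=tuple(t for t in transcripts if t.exons),
            )
        )
    return genes


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def _splice_windows(tr: Transcript) -> List[Tuple[int, int, str]]:
    """(start, end, donor|acceptor) windows: first/last 2 nt of each intron,
    oriented by strand."""
    out = []
    for s, e in tr.introns:
        if e - s + 1 < 2 * SPLICE_SITE_WIDTH:
            # tiny intron: whole intron is splice-critical; call it donor-side
            out.append((s, e, "donor" if tr.strand == "+" else "acceptor"))
            continue
        left = (s, s + SPLICE_SITE_WIDTH - 1)
        right = (e - SPLICE_SITE_WIDTH + 1, e)
        if tr.strand == "+":
            out.append((*left, "donor"))
            out.append((*right, "acceptor"))
        else:
            out.append((*right, "donor"))
            out.append((*left, "acceptor"))
    return out


def locate_variant(
    variant: Variant, gene_models: Sequence[GeneModel]
) -> List[Tuple[Transcript, str]]:
    """Region context per overlapping transcript.

    Region is one of ``CDS``, ``splice_donor``, ``splice_acceptor``, ``UTR``,
    ``intron``; an empty list means intergenic. A variant spanning several
    region kinds takes the most severe one (splice > CDS > UTR > intron).
    """
    hits: List[Tuple[Transcript, str]] = []
    for gene in gene_models:
        if gene.chrom != variant.chrom:
            continue
        for tr in gene.transcripts:
            s, e = tr.span
            if not _overlaps(variant.pos, variant.end, s, e):
                continue
            region = _region_for(variant, tr)
            hits.append((tr, region))
    return hits


def _region_for(variant: Variant, tr: Transcript) -> str:
    vs, ve = variant.pos, variant.end
    splice = None
    for s, e, kind in _splice_windows(tr):
        if _overlaps(vs, ve, s, e):
            splice = f"splice_{kind}"
            break
    if splice:
        return splice
    if any(_overlaps(vs, ve, s, e) for s, e in tr.cds):
        return "CDS"
    if any(_overlaps(vs, ve, s, e) for s, e in tr.exons):
        return "UTR"
    return "intron"


def _check_reference(variant: Variant, genome: Mapping[str, str]) -> None:
    seq = genome.get(variant.chrom)
    if seq is None:
        raise ReferenceMismatchError(f"chromosome {variant.chrom} not in genome")
    observed = seq[variant.pos - 1 : variant.pos - 1 + len(variant.ref)]
    if observed.upper() != variant.ref.upper():
        raise ReferenceMismatchError(
            f"REF {variant.ref!r} != genome {observed!r} at "
            f"{variant.chrom}:{variant.pos}"
        )


def _cds_offset(tr: Transcript, pos: int) -> Optional[int]:
    """Offset of genomic ``pos`` within the plus-strand CDS concatenation, or
    None when ``pos`` is outside every CDS interval."""
    off = 0
    for s, e in tr.cds:
        if s <= pos <= e:
            return off + (pos - s)
        off += e - s + 1
    return None


def _spliced_cds(tr: Transcript, genome: Mapping[str, str]) -> str:
    seq = genome[tr.chrom]
    return "".join(seq[s - 1 : e] for s, e in tr.cds)


def _translate(cds_plus: str, strand: str) -> str:
    seq = Seq(cds_plus)
    if strand == "-":
        seq = seq.reverse_complement()
    usable = len(seq) - len(seq) % 3
    return str(seq[:usable].translate())


def coding_consequence(
    variant: Variant, tr: Transcript, genome: Mapping[str, str]
) -> Optional[EffectAnnotation]:
    """Consequence of a variant lying fully inside one CDS interval.

    Builds the mutant CDS, translates reference and mutant (minus-strand
    transcripts by reverse complement) and classifies: indels by length
    change mod 3 (frameshift vs in-frame), SNPs by the amino-acid change
    (stop gained/lost, start lost, missense, synonymous). Annotating the
    reference allele against itself is a no-op and returns ``None``.
    """
    _check_reference(variant, genome)
    if variant.alt == variant.ref:
        return None

    off = _cds_offset(tr, variant.pos)
    if off is None or _cds_offset(tr, variant.end) is None:
        raise ValueError(
            f"variant {variant.chrom}:{variant.pos} not fully within CDS of "
            f"{tr.transcript_id}"
        )
    ref_cds = _spliced_cds(tr, genome)
    mut_cds = ref_cds[:off] + variant.alt + ref_cds[off + len(variant.ref) :]

    delta = len(variant.alt) - len(variant.ref)
    if delta != 0:
        if delta % 3 != 0:
            term = "frameshift_variant"
            change = f"frameshift at CDS position {_oriented_offset(tr, off, len(ref_cds)) + 1}"
        else:
            term = "inframe_insertion" if delta > 0 else "inframe_deletion"
            change = f"in-frame {'insertion' if delta > 0 else 'deletion'} of {abs(delta) // 3} aa"
        return EffectAnnotation(
            variant=variant,
            so_term=term,
            impact=IMPACT[term],
            gene_id=tr.gene_id,
            transcript_id=tr.transcript_id,
            protein_change=change,
        )

    ref_prot = _translate(ref_cds, tr.strand)
    mut_prot = _translate(mut_cds, tr.strand)
    cds_pos = _oriented_offset(tr, off, len(ref_cds))  # 0-based, translation orientation
    codon_idx = cds_pos // 3
    ref_aa = ref_prot[codon_idx] if codon_idx < len(ref_prot) else ""
    mut_aa = mut_prot[codon_idx] if codon_idx < len(mut_prot) else ""
    if codon_idx == 0 and ref_prot[:1] == "M" and mut_aa != "M":
        term = "start_lost"
    elif mut_aa == "*" and ref_aa != "*":
        term = "stop_gained"
    elif ref_aa == "*" and mut_aa != "*":
        term = "stop_lost"
    elif ref_aa == mut_aa:
        term = "synonymous_variant"
    else:
        term = "missense_variant"
    return EffectAnnotation(
        variant=variant,
        so_term=term,
        impact=IMPACT[term],
        gene_id=tr.gene_id,
        transcript_id=tr.transcript_id,
        protein_change=f"p.{ref_aa}{codon_idx + 1}{mut_aa}",
    )


def _oriented_offset(tr: Transcript, plus_offset: int, cds_len: int) -> int:
    """Plus-strand CDS offset -> offset in translation orientation."""
    return plus_offset if tr.strand == "+" else cds_len - 1 - plus_offset


def annotate_variant(
    variant: Variant,
    gene_models: Sequence[GeneModel],
    genome: Optional[Mapping[str, str]] = None,
) -> EffectAnnotation:
    """One most-severe annotation per variant across all transcripts."""
    hits = locate_variant(variant, gene_models)
    candidates: List[EffectAnnotation] = []
    for tr, region in hits:
        if region == "CDS" and genome is not None:
            within_one = any(
                s <= variant.pos and variant.end <= e for s, e in tr.cds
            )
            if within_one:
                ann = coding_consequence(variant, tr, genome)
                if ann is not None:
                    candidates.append(ann)
                continue
            # spans a CDS/intron or CDS/UTR boundary without touching a
            # splice dinucleotide: fall back to a length-based call
            delta = len(variant.alt) - len(variant.ref)
            term = "frameshift_variant" if delta % 3 != 0 else (
                "inframe_insertion" if delta > 0 else "inframe_deletion"
            )
            candidates.append(
                EffectAnnotation(
                    variant=variant,
                    so_term=term,
                    impact=IMPACT[term],
                    gene_id=tr.gene_id,
                    transcript_id=tr.transcript_id,
                )
            )
        else:
            term = {
                "CDS": "missense_variant",  # unreachable without genome
                "splice_donor": "splice_donor_variant",
                "splice_acceptor": "splice_acceptor_variant",
                "UTR": "UTR_variant",
                "intron": "intron_variant",
            }[region]
            candidates.append(
                EffectAnnotation(
                    variant=variant,
                    so_term=term,
                    impact=IMPACT[term],
                    gene_id=tr.gene_id,
                    transcript_id=tr.transcript_id,
                )
            )
    if not candidates:
        return EffectAnnotation(
            variant=variant, so_term="intergenic_variant", impact="MODIFIER"
        )
    return min(candidates, key=lambda a: _RANK[a.so_term])


def is_protein_altering(annotation: EffectAnnotation) -> bool:
    return annotation.impact in ("HIGH", "MODERATE")


def summarize_effects(
    annotations: Iterable[EffectAnnotation],
    classified: Iterable,
) -> pd.DataFrame:
    """Tally annotations by genotype class x SO term x SNP/indel.

    ``classified`` is an iterable of :class:`~mabc.profile.ClassifiedSite`;
    the join key is ``(chrom, pos)``. Each variant is counted once, at its
    most severe term (annotations are already one-per-variant).
    """
    class_by_site = {(c.chrom, c.pos): c.genotype_class.value for c in classified}
    rows = []
    for ann in annotations:
        key = (ann.variant.chrom, ann.variant.pos)
        rows.append(
            {
                "genotype_class": class_by_site.get(key, "unclassified"),
                "so_term": ann.so_term,
                "impact": ann.impact,
                "variant_class": ann.variant.variant_class,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["genotype_class", "so_term", "impact", "variant_class", "n"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["genotype_class", "so_term", "impact", "variant_class"])
        .size()
        .reset_index(name="n")
        .sort_values(["genotype_class", "so_term", "variant_class"])
        .reset_index(drop=True)
    )
    return out


def protein_altering_counts(tally: pd.DataFrame) -> Dict[str, int]:
    """Per-genotype-class count of HIGH/MODERATE-impact variants."""
    if tally.empty:
        return {}
    sub = tally[tally["impact"].isin(["HIGH", "MODERATE"])]
    return sub.groupby("genotype_class")["n"].sum().to_dict()


def load_trait_table(path: str) -> pd.DataFrame:
    """TSV with columns ``gene_id``, ``trait``, ``dataset``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "trait", "dataset"}
    if not required <= set(df.columns):
        raise ValueError(f"trait table needs columns {sorted(required)}")
    return df


def crossref_trait_genes(
    annotations: Iterable[EffectAnnotation],
    classified: Iterable,
    trait_table: pd.DataFrame,
) -> pd.DataFrame:
    """HIGH/MODERATE variants in trait-associated genes, one report row each
    (chrom, pos, ref, alt, genotype class, SO term, gene, trait, dataset)."""
    class_by_site = {(c.chrom, c.pos): c.genotype_class.value for c in classified}
    traits = trait_table.set_index("gene_id")
    rows = []
    for ann in annotations:
        if not is_protein_altering(ann) or ann.gene_id not in traits.index:
            continue
        hit = traits.loc[[ann.gene_id]]
        for _, t in hit.iterrows():
            rows.append(
                {
                    "chrom": ann.variant.chrom,
                    "pos": ann.variant.pos,
                    "ref": ann.variant.ref,
                    "alt": ann.variant.alt,
                    "genotype_class": class_by_site.get(
                        (ann.variant.chrom, ann.variant.pos), "unclassified"
                    ),
                    "alteration": ann.so_term,
                    "gene_id": ann.gene_id,
                    "trait": t["trait"],
                    "dataset": t["dataset"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "genotype_class",
            "alteration",
            "gene_id",
            "trait",
            "dataset",
        ],
    )
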