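"""Parental-origin classification of progeny genotypes and recovery rates.

At an informative marker (parents homozygous for different alleles) a progeny
call falls into exactly one of four classes: homozygous for the recurrent
parent's allele, homozygous for the donor's allele, heterozygous, or carrying
an allele matching neither parent. The recurrent-parent genome recovery rate
is the recurrent-allele frequency among classified markers,

    recovery = (YY + YK/2) / (YY + YK + KK)

with YY / YK / KK the recurrent-homozygous / heterozygous / donor-homozygous
marker counts. The no-selection expectation after n backcrosses is
1 - 2^-(n+1), unchanged by selfing; the expected heterozygous marker fraction
halves with every backcross and every selfing, 2^-(n_backcross + n_self).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Dict, Iterable, List, NamedTuple, Tuple

from .variants import VariantSite


class GenotypeClass(Enum):
    RECURRENT_HOM = "recurrent_hom"
    DONOR_HOM = "donor_hom"
    HET = "het"
    NON_PARENTAL = "non_parental"


class NonInformativeSiteError(ValueError):
    """Raised when a site does not have opposite-homozygous parents."""


class ClassifiedSite(NamedTuple):
    chrom: str
    pos: int
    genotype_class: GenotypeClass
    variant_class: str  # "SNP" | "INDEL"


def classify_site(site: VariantSite) -> GenotypeClass:
    """Classify a progeny call by parental origin at an informative site."""
    donor = site.calls["donor"]
    recurrent = site.calls["recurrent"]
    if not (donor.is_hom and recurrent.is_hom):
        raise NonInformativeSiteError(
            f"parents not both homozygous at {site.chrom}:{site.pos}"
        )
    d_allele, r_allele = donor.genotype[0], recurrent.genotype[0]
    if d_allele == r_allele:
        raise NonInformativeSiteError(
            f"parents share allele {d_allele} at {site.chrom}:{site.pos}"
        )
    progeny = site.calls["progeny"]
    if progeny.genotype is None:
        raise NonInformativeSiteError(
            f"missing progeny call at {site.chrom}:{site.pos}"
        )
    alleles = set(progeny.genotype)
    if not alleles <= {d_allele, r_allele}:
        return GenotypeClass.NON_PARENTAL
    if alleles == {r_allele}:
        return GenotypeClass.RECURRENT_HOM
    if alleles == {d_allele}:
        return GenotypeClass.DONOR_HOM
    return GenotypeClass.HET


def classify_sites(sites: Iterable[VariantSite]) -> List[ClassifiedSite]:
    return [
        ClassifiedSite(s.chrom, s.pos, classify_site(s), s.variant_class)
        for s in sites
    ]


def recovery_rate(yy: int, yk: int, kk: int) -> float:
    """Recurrent-allele frequency (YY + YK/2) / (YY + YK + KK)."""
    total = yy + yk + kk
    if total <= 0:
        raise ValueError("recovery rate undefined for all-zero counts")
    if min(yy, yk, kk) < 0:
        raise ValueError("negative genotype-class counts")
    return (yy + yk / 2) / total


def round_percent(fraction: float, decimals: int = 1) -> float:
    """Half-up percentage rounding, matching printed summary tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(fraction) * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ProfileSummary:
    """Genotype-class counts cross-tabulated by SNP/indel, with percentages
    on the classified (parental-allele) total and the recovery rate."""

    counts: Dict[Tuple[GenotypeClass, str], int] = field(default_factory=dict)
    non_parental: int = 0

    @classmethod
    def from_counts(
        cls,
        recurrent_snp: int,
        recurrent_indel: int,
        donor_snp: int,
        donor_indel: int,
        het_snp: int,
        het_indel: int,
        non_parental: int = 0,
    ) -> "ProfileSummary":
        return cls(
            counts={
                (GenotypeClass.RECURRENT_HOM, "SNP"): recurrent_snp,
                (GenotypeClass.RECURRENT_HOM, "INDEL"): recurrent_indel,
                (GenotypeClass.DONOR_HOM, "SNP"): donor_snp,
                (GenotypeClass.DONOR_HOM, "INDEL"): donor_indel,
                (GenotypeClass.HET, "SNP"): het_snp,
                (GenotypeClass.HET, "INDEL"): het_indel,
            },
            non_parental=non_parental,
        )

    def class_total(self, gclass: GenotypeClass) -> int:
        return self.counts.get((gclass, "SNP"), 0) + self.counts.get(
            (gclass, "INDEL"), 0
        )

    @property
    def yy(self) -> int:
        return self.class_total(GenotypeClass.RECURRENT_HOM)

    @property
    def yk(self) -> int:
        return self.class_total(GenotypeClass.HET)

    @property
    def kk(self) -> int:
        return self.class_total(GenotypeClass.DONOR_HOM)

    @property
    def classified_total(self) -> int:
        return self.yy + self.yk + self.kk

    @property
    def recovery_rate(self) -> float:
        return recovery_rate(self.yy, self.yk, self.kk)

    def percentages(self, decimals: int = 1) -> Dict[GenotypeClass, float]:
        total = self.classified_total
        return {
            g: round_percent(self.class_total(g) / total, decimals)
            for g in (
                GenotypeClass.RECURRENT_HOM,
                GenotypeClass.DONOR_HOM,
                GenotypeClass.HET,
            )
        }

    def to_tsv(self) -> str:
        """Four-row summary table (SNPs, Indels, Total, Genome %)."""
        pct = self.percentages()
        rows = [
            ("recurrent_hom", GenotypeClass.RECURRENT_HOM),
            ("donor_hom", GenotypeClass.DONOR_HOM),
            ("het", GenotypeClass.HET),
        ]
        lines = ["genotype\tsnps\tindels\ttotal\tgenome_pct"]
        snp_sum = indel_sum = 0
        for label, g in rows:
            s = self.counts.get((g, "SNP"), 0)
            i = self.counts.get((g, "INDEL"), 0)
            snp_sum += s
            indel_sum += i
            lines.append(f"{label}\t{s}\t{i}\t{s + i}\t{pct[g]:.1f}")
        lines.append(
            f"total\t{snp_sum}\t{indel_sum}\t{self.classified_total}\t100.0"
        )
        lines.append(f"non_parental\t\t\t{self.non_parental}\t")
        lines.append(f"recovery_rate_pct\t\t\t\t{round_percent(self.recovery_rate):.1f}")
        return "\n".join(lines) + "\n"


def profile_summary(classified: Iterable[ClassifiedSite]) -> ProfileSummary:
    """Cross-tabulate classified sites by genotype class and SNP/indel."""
    summary = ProfileSummary()
    for site in classified:
        if site.genotype_class is GenotypeClass.NON_PARENTAL:
            summary.non_parental += 1
            continue
        key = (site.genotype_class, site.variant_class)
        summary.counts[key] = summary.counts.get(key, 0) + 1
    return summary


def per_chromosome_recovery(
    classified: Iterable[ClassifiedSite],
) -> Dict[str, float]:
    """Recovery rate computed per chromosome (non-parental sites excluded)."""
    counts: Dict[str, List[int]] = {}
    for site in classified:
        if site.genotype_class is GenotypeClass.NON_PARENTAL:
            continue
        c = counts.setdefault(site.chrom, [0, 0, 0])
        if site.genotype_class is GenotypeClass.RECURRENT_HOM:
            c[0] += 1
        elif site.genotype_class is GenotypeClass.HET:
            c[1] += 1
        else:
            c[2] += 1
    return {chrom: recovery_rate(*c) for chrom, c in counts.items()}


def expected_recovery(n_backcross: int, n_self: int) -> Tuple[float, float]:
    """No-selection expectations after ``n_backcross`` backcrosses to the
    recurrent parent and ``n_self`` self-fertilizations.

    Returns ``(recurrent_allele_fraction, het_marker_fraction)``:
    ``1 - 2^-(n_backcross+1)`` (selfing leaves allele frequency unchanged)
    and ``2^-(n_backcross + n_self)`` (heterozygosity halves per backcross
    and per selfing; the F1 is heterozygous at every marker).
    """
    if n_backcross < 0 or n_self < 0:
        raise ValueError("generation counts must be non-negative")
    allele_fraction = 1.0 - 2.0 ** -(n_backcross + 1)
    het_fraction = 2.0 ** -(n_backcross + n_self)
    return allele_fraction, het_fraction


def classified_to_tsv(classified: Iterable[ClassifiedSite]) -> str:
    lines = ["chrom\tpos\tgenotype_class\tvariant_class"]
    for s in classified:
        lines.append(f"{s.chrom}\t{s.pos}\t{s.genotype_class.value}\t{s.variant_class}")
    return "\n".join(lines) + "\n"


def classified_from_tsv(text: str) -> List[ClassifiedSite]:
    lines = text.strip().splitlines()
    out = []
    for line in lines[1:]:
        chrom, pos, gclass, vclass = line.split("\t")
        out.append(ClassifiedSite(chrom, int(pos), GenotypeClass(gclass), vclass))
    return out
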