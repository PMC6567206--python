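"""Multi-sample VCF reading and site filtering for backcross progeny analysis.

A three-sample VCF (donor parent, recurrent parent, one progeny) is reduced to
the set of *informative markers*: biallelic sites where the two parents are
homozygous for different alleles, every call is present and well supported,
and heterozygous progeny calls show a balanced read ratio. The filter cascade
mirrors the quality rules commonly applied to GATK multi-sample calls in
backcross genome characterization:

missing data -> multi-allelic sites -> parental heterozygotes -> low depth
(DP < 6, per sample) -> low quality (QUAL < 20) -> progeny heterozygotes with
alternate-allele fraction outside the closed 40-60% band.

Coordinates are VCF convention (1-based, inclusive) throughout this module.
"""

from __future__ import annotations

import warnings as _warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Tuple

import pysam

ROLES = ("donor", "recurrent", "progeny")

#: Fixed filter order; tallies attribute each removed site to the first
#: failing filter in this order, which makes tallies reproducible.
FILTER_ORDER = (
    "missing",
    "multiallelic",
    "parental_het",
    "low_depth",
    "low_quality",
    "allele_balance",
)


class ConfigurationError(ValueError):
    """Raised when sample roles cannot be resolved against the VCF header."""


class RecordError(ValueError):
    """Raised for a malformed VCF record, carrying its ordinal position."""


@dataclass(frozen=True)
class SampleCall:
    """One sample's call at a site.

    genotype
        Unordered pair of allele indices into ``(ref,) + alts``; ``None``
        when the call is missing.
    allele_depths
        Per-allele supporting read counts (AD); ``None`` when absent.
    depth
        Total read depth (DP); ``None`` when absent.
    """

    genotype: Optional[Tuple[int, ...]]
    allele_depths: Optional[Tuple[int, ...]] = None
    depth: Optional[int] = None

    @property
    def is_missing(self) -> bool:
        return self.genotype is None

    @property
    def is_het(self) -> bool:
        return self.genotype is not None and len(set(self.genotype)) > 1

    @property
    def is_hom(self) -> bool:
        return self.genotype is not None and len(set(self.genotype)) == 1

    def effective_depth(self) -> Optional[int]:
        """DP, falling back to the AD sum when DP is absent."""
        if self.depth is not None:
            return self.depth
        if self.allele_depths is not None:
            return int(sum(self.allele_depths))
        return None


@dataclass
class VariantSite:
    """A single VCF record with the three role-mapped sample calls."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: Tuple[str, ...]
    qual: Optional[float]
    calls: Mapping[str, SampleCall]  # keyed by role

    @property
    def variant_class(self) -> str:
        """``"SNP"`` iff ref and every alt are single bases, else ``"INDEL"``."""
        if len(self.ref) == 1 and all(len(a) == 1 for a in self.alts):
            return "SNP"
        return "INDEL"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the site-filter cascade (defaults follow DP>=6, QUAL>=20,
    40-60% heterozygote allele-fraction band)."""

    min_depth: int = 6
    min_quality: float = 20.0
    het_af_band: Tuple[float, float] = (0.40, 0.60)
    drop_missing: bool = True
    drop_multiallelic: bool = True
    drop_parental_het: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.het_af_band
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"invalid allele-fraction band {self.het_af_band}")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


@dataclass
class FilterTally:
    """Removal accounting: input = passing + sum(removed) by construction."""

    input_count: int = 0
    passing: int = 0
    removed: Counter = field(default_factory=Counter)
    warnings: Counter = field(default_factory=Counter)

    def removed_total(self) -> int:
        return sum(self.removed.values())

    def to_tsv(self) -> str:
        lines = ["category\tcount", f"input\t{self.input_count}"]
        for name in FILTER_ORDER:
            lines.append(f"removed_{name}\t{self.removed.get(name, 0)}")
        lines.append(f"passing\t{self.passing}")
        for key in sorted(self.warnings):
            lines.append(f"warning_{key}\t{self.warnings[key]}")
        return "\n".join(lines) + "\n"


def _call_from_record(rec_sample) -> SampleCall:
    gt = rec_sample.get("GT")
    if gt is None or any(a is None for a in gt):
        gt = None
    else:
        gt = tuple(int(a) for a in gt)
    ad = rec_sample.get("AD")
    if ad is not None:
        if any(a is None for a in ad):
            ad = None
        else:
            ad = tuple(int(a) for a in ad)
    dp = rec_sample.get("DP")
    dp = int(dp) if dp is not None else None
    return SampleCall(genotype=gt, allele_depths=ad, depth=dp)


def resolve_roles(sample_names: Sequence[str], role_map: Mapping[str, str]) -> Mapping[str, str]:
    """Invert a sample-name->role map into role->sample-name, validating both
    that every role is covered and that every named sample exists."""
    role_to_sample = {}
    for sample, role in role_map.items():
        if role not in ROLES:
            raise ConfigurationError(f"unknown role {role!r}; expected one of {ROLES}")
        if sample not in sample_names:
            raise ConfigurationError(
                f"sample {sample!r} not in VCF header (has {list(sample_names)})"
            )
        role_to_sample[role] = sample
    missing = [r for r in ROLES if r not in role_to_sample]
    if missing:
        raise ConfigurationError(f"roles not assigned to any sample: {missing}")
    return role_to_sample


def read_multisample_variants(
    vcf_path: str, role_map: Mapping[str, str]
) -> Iterator[VariantSite]:
    """Stream ``VariantSite`` objects from a VCF.

    ``role_map`` maps sample names in the header to the roles
    ``donor`` / ``recurrent`` / ``progeny``. Records are passed through
    unfiltered (unknown contigs included); filtering is a downstream step.
    """
    with pysam.VariantFile(vcf_path) as vf:
        role_to_sample = resolve_roles(list(vf.header.samples), role_map)
        for i, rec in enumerate(vf, start=1):
            try:
                calls = {
                    role: _call_from_record(rec.samples[sample])
                    for role, sample in role_to_sample.items()
                }
                yield VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts) if rec.alts else (),
                    qual=rec.qual,
                    calls=calls,
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise RecordError(f"malformed VCF record #{i} at {rec.chrom}:{rec.pos}: {exc}") from exc


def allele_balance(call: SampleCall) -> Optional[float]:
    """Alternate-allele read fraction, alt/(ref+alt), from allele depths.

    Returns ``None`` (UNDEFINED) when allele depths are absent or sum to zero.
    """
    if call.allele_depths is None or len(call.allele_depths) < 2:
        return None
    ref_reads = call.allele_depths[0]
    alt_reads = sum(call.allele_depths[1:])
    denom = ref_reads + alt_reads
    if denom == 0:
        return None
    return alt_reads / denom


def site_filter_verdict(
    site: VariantSite, config: FilterConfig
) -> Tuple[Optional[str], Tuple[str, ...]]:
    """Return ``(first_failing_filter_or_None, warnings)`` for one site."""
    notes = []
    if config.drop_missing and any(site.calls[r].is_missing for r in ROLES):
        return "missing", ()
    if config.drop_multiallelic and len(site.alts) != 1:
        return "multiallelic", ()
    if config.drop_parental_het and (
        site.calls["donor"].is_het or site.calls["recurrent"].is_het
    ):
        return "parental_het", ()
    for role in ROLES:
        dp = site.calls[role].effective_depth()
        if dp is None:
            notes.append("depth_unavailable")
        elif dp < config.min_depth:
            return "low_depth", tuple(notes)
    if site.qual is None:
        notes.append("qual_unavailable")
    elif site.qual < config.min_quality:
        return "low_quality", tuple(notes)
    progeny = site.calls["progeny"]
    if progeny.is_het:
        ab = allele_balance(progeny)
        if ab is None:
            notes.append("allele_depths_unavailable")
        else:
            lo, hi = config.het_af_band
            if not (lo <= ab <= hi):
                return "allele_balance", tuple(notes)
    return None, tuple(notes)


def apply_site_filters(
    sites: Iterable[VariantSite], config: FilterConfig | None = None
) -> Tuple[list[VariantSite], FilterTally]:
    """Apply the filter cascade; returns passing sites and a removal tally."""
    config = config or FilterConfig()
    tally = FilterTally()
    passing: list[VariantSite] = []
    for site in sites:
        tally.input_count += 1
        verdict, notes = site_filter_verdict(site, config)
        for note in notes:
            tally.warnings[note] += 1
        if verdict is None:
            passing.append(site)
            tally.passing += 1
        else:
            tally.removed[verdict] += 1
    return passing, tally


def select_informative_sites(
    sites: Iterable[VariantSite],
) -> Tuple[list[VariantSite], int]:
    """Keep sites whose parents are homozygous for *different* alleles.

    Returns ``(informative_sites, n_parental_identical_dropped)``. Sites with
    a non-homozygous parent do not belong here (filter first) and raise.
    """
    informative: list[VariantSite] = []
    dropped = 0
    for site in sites:
        donor = site.calls["donor"]
        recurrent = site.calls["recurrent"]
        if not (donor.is_hom and recurrent.is_hom):
            raise ValueError(
                f"non-homozygous parental call at {site.chrom}:{site.pos}; "
                "apply_site_filters before selecting informative sites"
            )
        if donor.genotype[0] == recurrent.genotype[0]:
            dropped += 1
        else:
            informative.append(site)
    return informative, dropped


def filter_vcf_file(
    in_path: str,
    out_path: str,
    role_map: Mapping[str, str],
    config: FilterConfig | None = None,
) -> FilterTally:
    """Write passing records of ``in_path`` to ``out_path`` (same dialect,
    header copied verbatim) and return the removal tally."""
    config = config or FilterConfig()
    tally = FilterTally()
    with pysam.VariantFile(in_path) as vf, open(out_path, "w") as out:
        role_to_sample = resolve_roles(list(vf.header.samples), role_map)
        out.write(str(vf.header))
        for rec in vf:
            calls = {
                role: _call_from_record(rec.samples[sample])
                for role, sample in role_to_sample.items()
            }
            site = VariantSite(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alts=tuple(rec.alts) if rec.alts else (),
                qual=rec.qual,
                calls=calls,
            )
            tally.input_count += 1
            verdict, notes = site_filter_verdict(site, config)
            for note in notes:
                tally.warnings[note] += 1
            if verdict is None:
                tally.passing += 1
                out.write(str(rec))
            else:
                tally.removed[verdict] += 1
    return tally
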