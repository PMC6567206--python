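"""Forward-time backcross-breeding simulator with noisy VCF emission.

Simulates a diploid 12-chromosome genome (rice-like physical lengths, a
uniform genetic map of 1 cM per 400 kb by default), two fully homozygous
parents that differ at every marker, Haldane (no-interference) meiosis with
Poisson crossover counts, and a BCnFm breeding scheme with foreground
selection at a single target SNP: heterozygote selection at the target in
each backcross generation, donor-homozygote selection at the first selfing
product. The recurrent parent carries the REF allele at every marker and the
donor the ALT allele (a convenient convention for synthetic data; real
pipelines call against an external reference).

The simulator retains the true parent-of-origin mosaic of every individual,
so downstream estimates can be checked against exact truth, and emits
three-sample VCF text with configurable noise (missing calls, low depth, low
quality, skewed heterozygous allele balance, spurious multi-allelic records,
genotype errors) to exercise every filter of the analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .profile import recovery_rate

RECURRENT, DONOR = 0, 1

#: Rice-like chromosome physical lengths (bp), 12 chromosomes.
RICE_CHROM_LENGTHS: Dict[str, int] = {
    "chr01": 43_300_000,
    "chr02": 35_900_000,
    "chr03": 36_400_000,
    "chr04": 35_500_000,
    "chr05": 29_900_000,
    "chr06": 31_200_000,
    "chr07": 29_700_000,
    "chr08": 28_400_000,
    "chr09": 23_000_000,
    "chr10": 23_200_000,
    "chr11": 29_000_000,
    "chr12": 27_500_000,
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeConfig:
    """Physical and genetic layout of the simulated genome.

    ``kb_per_cm`` sets a uniform cM/Mb genetic map (default 400 kb/cM, i.e.
    ~932 cM over the 373-Mb default genome).
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(RICE_CHROM_LENGTHS)
    )
    kb_per_cm: float = 400.0

    def genetic_length_cm(self, chrom: str) -> float:
        return self.chrom_lengths[chrom] / (self.kb_per_cm * 1000.0)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass(frozen=True)
class SchemeSpec:
    """A BCnFm breeding scheme with single-locus foreground selection.

    BCnFm means n backcrosses to the recurrent parent followed by m-1
    self-fertilizations; BC3F2 is ``n_backcross=3, n_self=1``. The target
    locus defaults to a marker on chromosome 6, mimicking a salinity-
    tolerance SNP introgression; its exact position is a free parameter.
    """

    n_backcross: int = 3
    n_self: int = 1
    target_chrom: str = "chr06"
    target_pos: int = 4_300_000
    select: bool = True
    max_attempts: int = 10_000


@dataclass(frozen=True)
class NoiseModel:
    """Per-site noise rates for VCF emission (all rates in [0, 1]).

    The zero-noise default emits constant depth, exact 50:50 heterozygous
    allele depths and QUAL 99, so that emission is classification-lossless.
    Missingness and low-depth injection act on the progeny sample (the
    sample the allele-balance filter targets); ``ab_skew_value`` is the
    alternate-allele fraction forced at skewed heterozygous sites.
    """

    mean_depth: int = 30
    missing_rate: float = 0.0
    low_depth_rate: float = 0.0
    low_quality_rate: float = 0.0
    ab_skew_rate: float = 0.0
    ab_skew_value: float = 0.30
    multiallelic_rate: float = 0.0
    genotype_error_rate: float = 0.0
    binomial_allele_depths: bool = False

    def __post_init__(self) -> None:
        for name in (
            "missing_rate",
            "low_depth_rate",
            "low_quality_rate",
            "ab_skew_rate",
            "multiallelic_rate",
            "genotype_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def default_noisy(cls) -> "NoiseModel":
        """A realistic noise preset for pipeline stress-testing."""
        return cls(
            missing_rate=0.05,
            low_depth_rate=0.03,
            low_quality_rate=0.02,
            ab_skew_rate=0.02,
            multiallelic_rate=0.01,
        )


@dataclass(frozen=True)
class Haplotype:
    """Parent-of-origin mosaic of one chromosome copy: ``breaks[i]`` is the
    half-open 0-based end of segment i, ``origins[i]`` its origin
    (0 recurrent, 1 donor); the final break equals the chromosome length."""

    breaks: np.ndarray
    origins: np.ndarray

    def origin_at(self, pos0: np.ndarray | int) -> np.ndarray | np.integer:
        idx = np.searchsorted(self.breaks, pos0, side="right")
        return self.origins[idx]


def constant_haplotype(length: int, origin: int) -> Haplotype:
    return Haplotype(
        breaks=np.array([length], dtype=np.int64),
        origins=np.array([origin], dtype=np.int8),
    )


@dataclass
class SimulatedIndividual:
    """Diploid of parent-of-origin haplotype mosaics with pedigree log."""

    haplotypes: Dict[str, Tuple[Haplotype, Haplotype]]
    pedigree: List[str] = field(default_factory=list)


@dataclass
class MarkerMap:
    """Ordered parental-divergent markers per chromosome.

    The recurrent parent carries ``ref`` and the donor ``alt`` at every
    marker; ``is_indel`` flags length-polymorphic markers.
    """

    chrom_order: List[str]
    positions: Dict[str, np.ndarray]  # 1-based, strictly increasing
    ref: Dict[str, List[str]]
    alt: Dict[str, List[str]]
    is_indel: Dict[str, np.ndarray]

    @property
    def n_markers(self) -> int:
        return sum(len(self.positions[c]) for c in self.chrom_order)


class SelectionError(RuntimeError):
    """Foreground-selection rule unsatisfiable within the attempt bound."""


def _sample_positions(length: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """n distinct sorted 1-based positions on [1, length]."""
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.1) + 16))
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    if len(pos) > n:
        pos = np.sort(rng.choice(pos, size=n, replace=False))
    return pos.astype(np.int64)


def make_parental_genomes(
    config: GenomeConfig,
    rng: np.random.Generator,
    n_markers: Optional[int] = None,
    density: float = 1 / 3000,
    indel_fraction: float = 0.2,
) -> Tuple[MarkerMap, SimulatedIndividual, SimulatedIndividual]:
    """Marker map plus the two fully homozygous, fully divergent parents.

    Marker counts are allocated to chromosomes proportionally to physical
    length, either from a total ``n_markers`` or from ``density``
    (markers/bp; the default 1/3 kb yields ~1.2x10^5 markers on the default
    genome, the divergence scale of a typical japonica x japonica cross).
    """
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    if n_markers is None:
        per_chrom = np.round(lengths * density).astype(int)
    else:
        per_chrom = np.floor(n_markers * lengths / lengths.sum()).astype(int)
        # distribute the rounding remainder to the largest chromosomes
        for i in np.argsort(-lengths)[: n_markers - per_chrom.sum()]:
            per_chrom[i] += 1

    positions, refs, alts, indels = {}, {}, {}, {}
    for chrom, n in zip(chroms, per_chrom):
        length = config.chrom_lengths[chrom]
        pos = _sample_positions(length, int(n), rng)
        if len(pos) == 0:
            import warnings

            warnings.warn(f"no markers simulated on {chrom}", stacklevel=2)
        ref_idx = rng.integers(0, 4, size=len(pos))
        alt_idx = (ref_idx + rng.integers(1, 4, size=len(pos))) % 4
        ref = list(_BASES[ref_idx])
        alt = list(_BASES[alt_idx])
        is_indel = rng.random(len(pos)) < indel_fraction
        ins = rng.random(len(pos)) < 0.5  # insertion vs deletion style
        for i in np.flatnonzero(is_indel):
            tail = "".join(rng.choice(_BASES, size=rng.integers(1, 4)))
            if ins[i]:
                alt[i] = ref[i] + tail
            else:
                ref[i] = ref[i] + tail
                alt[i] = ref[i][0]
        positions[chrom] = pos
        refs[chrom], alts[chrom] = ref, alt
        indels[chrom] = is_indel

    marker_map = MarkerMap(
        chrom_order=chroms, positions=positions, ref=refs, alt=alts, is_indel=indels
    )
    donor = SimulatedIndividual(
        haplotypes={
            c: (
                constant_haplotype(config.chrom_lengths[c], DONOR),
                constant_haplotype(config.chrom_lengths[c], DONOR),
            )
            for c in chroms
        },
        pedigree=["donor parent"],
    )
    recurrent = SimulatedIndividual(
        haplotypes={
            c: (
                constant_haplotype(config.chrom_lengths[c], RECURRENT),
                constant_haplotype(config.chrom_lengths[c], RECURRENT),
            )
            for c in chroms
        },
        pedigree=["recurrent parent"],
    )
    return marker_map, donor, recurrent


def meiosis_chromosome(
    hap_a: Haplotype,
    hap_b: Haplotype,
    length: int,
    genetic_length_cm: float,
    rng: np.random.Generator,
) -> Haplotype:
    """One gamete chromosome under the Haldane model: crossover count
    ~ Poisson(genetic length in Morgans), positions uniform on the physical
    map, starting haplotype chosen with probability 1/2."""
    n_xo = rng.poisson(genetic_length_cm / 100.0)
    xo = (
        np.sort(rng.integers(1, length, size=n_xo)).astype(np.int64)
        if n_xo
        else np.empty(0, dtype=np.int64)
    )
    start = int(rng.integers(0, 2))
    pts = np.unique(
        np.concatenate([hap_a.breaks, hap_b.breaks, xo, [np.int64(length)]])
    )
    pts = pts[(pts > 0) & (pts <= length)]
    seg_starts = np.concatenate([[0], pts[:-1]])
    n_xo_before = np.searchsorted(xo, seg_starts, side="right")
    chooser = (start + n_xo_before) % 2
    origins = np.where(
        chooser == 0, hap_a.origin_at(seg_starts), hap_b.origin_at(seg_starts)
    ).astype(np.int8)
    keep = np.concatenate([origins[1:] != origins[:-1], [True]])
    return Haplotype(breaks=pts[keep], origins=origins[keep])


def meiosis(
    individual: SimulatedIndividual,
    config: GenomeConfig,
    rng: np.random.Generator,
) -> Dict[str, Haplotype]:
    """One full gamete (one recombinant haplotype per chromosome)."""
    return {
        chrom: meiosis_chromosome(
            *individual.haplotypes[chrom],
            config.chrom_lengths[chrom],
            config.genetic_length_cm(chrom),
            rng,
        )
        for chrom in individual.haplotypes
    }


def _gamete_carries_donor(gamete: Mapping[str, Haplotype], scheme: SchemeSpec) -> bool:
    hap = gamete[scheme.target_chrom]
    return int(hap.origin_at(scheme.target_pos - 1)) == DONOR


def run_scheme(
    scheme: SchemeSpec,
    config: GenomeConfig,
    rng: np.random.Generator,
) -> SimulatedIndividual:
    """Advance F1 -> BCnF1 -> selfings under the scheme's selection rules.

    With ``select=True``, every backcross generation keeps a progeny
    heterozygous at the target (i.e. the transmitted gamete carries the
    donor allele), and the first selfing product must be donor-homozygous at
    the target; gametes are redrawn until the rule is met, up to
    ``max_attempts``. The returned individual retains its true
    parent-of-origin mosaic and a pedigree log.
    """
    if scheme.target_chrom not in config.chrom_lengths:
        raise ValueError(f"target chromosome {scheme.target_chrom} not simulated")
    chroms = list(config.chrom_lengths)
    donor_hap = {c: constant_haplotype(config.chrom_lengths[c], DONOR) for c in chroms}
    rec_hap = {
        c: constant_haplotype(config.chrom_lengths[c], RECURRENT) for c in chroms
    }
    current = SimulatedIndividual(
        haplotypes={c: (donor_hap[c], rec_hap[c]) for c in chroms},
        pedigree=["F1 (donor x recurrent)"],
    )
    for k in range(1, scheme.n_backcross + 1):
        for attempt in range(scheme.max_attempts):
            gamete = meiosis(current, config, rng)
            if not scheme.select or _gamete_carries_donor(gamete, scheme):
                break
        else:
            raise SelectionError(
                f"no heterozygous-target gamete in {scheme.max_attempts} attempts "
                f"at backcross {k}"
            )
        current = SimulatedIndividual(
            haplotypes={c: (gamete[c], rec_hap[c]) for c in chroms},
            pedigree=current.pedigree + [f"BC{k}F1 (het at target)" if scheme.select else f"BC{k}F1"],
        )
    for s in range(1, scheme.n_self + 1):
        require_hom = scheme.select and s == 1
        for attempt in range(scheme.max_attempts):
            g1 = meiosis(current, config, rng)
            g2 = meiosis(current, config, rng)
            if not require_hom or (
                _gamete_carries_donor(g1, scheme) and _gamete_carries_donor(g2, scheme)
            ):
                break
        else:
            raise SelectionError(
                f"no donor-homozygous-target progeny in {scheme.max_attempts} "
                f"attempts at selfing {s}"
            )
        gen = f"BC{scheme.n_backcross}F{1 + s}"
        current = SimulatedIndividual(
            haplotypes={c: (g1[c], g2[c]) for c in chroms},
            pedigree=current.pedigree
            + [f"{gen} (donor-hom at target)" if require_hom else gen],
        )
    return current


def progeny_dosage(
    individual: SimulatedIndividual, marker_map: MarkerMap
) -> Dict[str, np.ndarray]:
    """Donor-allele dosage (0/1/2) at every marker."""
    out = {}
    for chrom in marker_map.chrom_order:
        pos0 = marker_map.positions[chrom] - 1
        h1, h2 = individual.haplotypes[chrom]
        out[chrom] = (h1.origin_at(pos0) + h2.origin_at(pos0)).astype(np.int8)
    return out


def dosage_class_counts(dosage: Mapping[str, np.ndarray]) -> Tuple[int, int, int]:
    """(recurrent-hom, het, donor-hom) marker counts from dosage arrays."""
    yy = yk = kk = 0
    for d in dosage.values():
        yy += int((d == 0).sum())
        yk += int((d == 1).sum())
        kk += int((d == 2).sum())
    return yy, yk, kk


def true_recovery(
    individual: SimulatedIndividual,
    marker_map: MarkerMap,
    exclude_chroms: Sequence[str] = (),
) -> float:
    """Recurrent-allele dosage averaged over markers (the noiseless truth
    the pipeline estimator must reproduce); identical arithmetic to
    :func:`mabc.profile.recovery_rate` so the oracle equality is exact."""
    dosage = progeny_dosage(individual, marker_map)
    if exclude_chroms:
        dosage = {c: d for c, d in dosage.items() if c not in exclude_chroms}
    yy, yk, kk = dosage_class_counts(dosage)
    return recovery_rate(yy, yk, kk)


def true_donor_segments(
    individual: SimulatedIndividual,
) -> List[Tuple[str, int, int]]:
    """0-based half-open intervals where *both* haplotypes are donor."""
    out: List[Tuple[str, int, int]] = []
    for chrom, (h1, h2) in individual.haplotypes.items():
        pts = np.unique(np.concatenate([h1.breaks, h2.breaks]))
        starts = np.concatenate([[0], pts[:-1]])
        both = (h1.origin_at(starts) == DONOR) & (h2.origin_at(starts) == DONOR)
        seg_start = None
        for s, e, b in zip(starts, pts, both):
            if b and seg_start is None:
                seg_start = int(s)
            elif not b and seg_start is not None:
                out.append((chrom, seg_start, int(s)))
                seg_start = None
        if seg_start is not None:
            out.append((chrom, seg_start, int(pts[-1])))
    return out


@dataclass
class Emission:
    """Emitted VCF text plus the per-marker noise bookkeeping (arrays are in
    marker-map order, concatenated over chromosomes)."""

    text: str
    chrom: np.ndarray
    pos: np.ndarray
    truth_dosage: np.ndarray
    missing: np.ndarray
    low_depth: np.ndarray
    low_quality: np.ndarray
    ab_skewed_het: np.ndarray
    multiallelic: np.ndarray
    genotype_error: np.ndarray

    @property
    def n_markers(self) -> int:
        return len(self.pos)


SAMPLE_NAMES = ("donor_parent", "recurrent_parent", "progeny")


def _other_base(*exclude: str) -> str:
    for b in "ACGT":
        if b not in exclude:
            return b
    return "N"


def emit_vcf(
    individual: SimulatedIndividual,
    marker_map: MarkerMap,
    config: GenomeConfig,
    noise: Optional[NoiseModel] = None,
    rng: Optional[np.random.Generator] = None,
    metadata: Optional[Mapping[str, object]] = None,
) -> Emission:
    """Serialize donor/recurrent/progeny calls to three-sample VCF text.

    One record per marker with GT:AD:DP per sample and a site QUAL; noise is
    injected at the configured per-site rates and recorded in the returned
    :class:`Emission` so tests can check filter behaviour against the known
    injection. Deterministic given the RNG state.
    """
    noise = noise or NoiseModel()
    rng = rng or np.random.default_rng(0)
    dosage = progeny_dosage(individual, marker_map)
    n = marker_map.n_markers

    miss = rng.random(n) < noise.missing_rate
    lowdp = rng.random(n) < noise.low_depth_rate
    lowq = rng.random(n) < noise.low_quality_rate
    skew = rng.random(n) < noise.ab_skew_rate
    multi = rng.random(n) < noise.multiallelic_rate
    gterr = rng.random(n) < noise.genotype_error_rate

    lines = [
        "##fileformat=VCFv4.2",
        "##source=mabc.simulate",
    ]
    for key in sorted(metadata or {}):
        lines.append(f"##mabc_{key}={metadata[key]}")
    for chrom in marker_map.chrom_order:
        lines.append(f"##contig=<ID={chrom},length={config.chrom_lengths[chrom]}>")
    lines += [
        '##FILTER=<ID=PASS,Description="All filters passed">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(SAMPLE_NAMES),
    ]

    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    depth = noise.mean_depth
    i = 0
    truth_all = []
    chrom_all = []
    pos_all = []
    for chrom in marker_map.chrom_order:
        pos_arr = marker_map.positions[chrom]
        d_arr = dosage[chrom]
        for j in range(len(pos_arr)):
            pos = int(pos_arr[j])
            ref = marker_map.ref[chrom][j]
            alt = marker_map.alt[chrom][j]
            d = int(d_arr[j])
            truth_all.append(d)
            chrom_all.append(chrom)
            pos_all.append(pos)

            emitted_d = d
            if gterr[i]:
                emitted_d = int((d + rng.integers(1, 3)) % 3)
            n_alleles = 2
            if multi[i]:
                alt = alt + "," + _other_base(ref[0], alt[0])
                n_alleles = 3

            qual = f"{rng.uniform(0.0, 19.9):.1f}" if lowq[i] else "99"

            def fmt(dosage_value: int, dp: int) -> str:
                if noise.binomial_allele_depths and dosage_value == 1:
                    alt_reads = int(rng.binomial(dp, 0.5))
                elif dosage_value == 1:
                    if skew[i]:
                        alt_reads = int(round(noise.ab_skew_value * dp))
                    else:
                        alt_reads = dp // 2
                elif dosage_value == 2:
                    alt_reads = dp
                else:
                    alt_reads = 0
                ad = [dp - alt_reads, alt_reads] + [0] * (n_alleles - 2)
                return f"{gt_strings[dosage_value]}:{','.join(map(str, ad))}:{dp}"

            donor_field = fmt(2, depth)
            recurrent_field = fmt(0, depth)
            if miss[i]:
                progeny_field = "./.:.:."
            else:
                dp = int(rng.integers(0, 6)) if lowdp[i] else depth
                progeny_field = fmt(emitted_d, dp)
            lines.append(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t.\tGT:AD:DP\t"
                f"{donor_field}\t{recurrent_field}\t{progeny_field}"
            )
            i += 1

    return Emission(
        text="\n".join(lines) + "\n",
        chrom=np.array(chrom_all),
        pos=np.array(pos_all, dtype=np.int64),
        truth_dosage=np.array(truth_all, dtype=np.int8),
        missing=miss,
        low_depth=lowdp,
        low_quality=lowq,
        ab_skewed_het=skew & (np.array(truth_all) == 1),
        multiallelic=multi,
        genotype_error=gterr,
    )


def chrom_sizes_text(config: GenomeConfig) -> str:
    return "".join(f"{c}\t{l}\n" for c, l in config.chrom_lengths.items())


def write_truth_segments(individual: SimulatedIndividual) -> str:
    """Per-haplotype parent-of-origin segments as TSV (0-based half-open)."""
    lines = ["chrom\thaplotype\tstart\tend\torigin"]
    for chrom, haps in individual.haplotypes.items():
        for h_idx, hap in enumerate(haps):
            start = 0
            for end, origin in zip(hap.breaks, hap.origins):
                label = "donor" if origin == DONOR else "recurrent"
                lines.append(f"{chrom}\t{h_idx}\t{start}\t{int(end)}\t{label}")
                start = int(end)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# toy annotation (synthetic genome + gene models for the effect module)
# ---------------------------------------------------------------------------

_SAFE_CODONS = [
    c
    for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in ("TAA", "TAG", "TGA", "ATG")
]


def _orf(n_codons: int, rng: np.random.Generator) -> str:
    body = "".join(
        _SAFE_CODONS[int(rng.integers(0, len(_SAFE_CODONS)))]
        for _ in range(n_codons - 2)
    )
    return "ATG" + body + "TAA"


def make_toy_annotation(seed: int = 0) -> Tuple[str, str, dict]:
    """Small synthetic genome FASTA + GFF3 for exercising the annotator.

    One ~9-kb contig ``toy1`` with a two-exon plus-strand gene (UTRs, one
    intron) and a single-exon minus-strand gene. Returns
    ``(fasta_text, gff3_text, info)`` where ``info`` records the exact CDS
    coordinates so tests can construct variants with known consequences.
    """
    rng = np.random.default_rng(seed)
    length = 9000
    seq = list("".join(_BASES[rng.integers(0, 4, size=length)]))

    # gene A, '+': exons 1001-1400 and 2001-2600; CDS 1101-1400 + 2001-2501
    cds_a = [(1101, 1400), (2001, 2501)]
    orf_a = _orf(sum(e - s + 1 for s, e in cds_a) // 3, rng)
    k = 0
    for s, e in cds_a:
        seq[s - 1 : e] = orf_a[k : k + (e - s + 1)]
        k += e - s + 1
    # canonical splice dinucleotides for the intron 1401..2000
    seq[1400:1402] = "GT"
    seq[1998:2000] = "AG"

    # gene B, '-': single CDS 5101-5700; genome holds the revcomp of its ORF
    cds_b = (5101, 5700)
    orf_b = _orf((cds_b[1] - cds_b[0] + 1) // 3, rng)
    from Bio.Seq import Seq as _Seq

    seq[cds_b[0] - 1 : cds_b[1]] = str(_Seq(orf_b).reverse_complement())

    fasta = ">toy1\n" + "".join(seq) + "\n"
    gff = "\n".join(
        [
            "##gff-version 3",
            "toy1\tmabc\tgene\t1001\t2600\t.\t+\t.\tID=geneA",
            "toy1\tmabc\tmRNA\t1001\t2600\t.\t+\t.\tID=geneA.1;Parent=geneA",
            "toy1\tmabc\texon\t1001\t1400\t.\t+\t.\tParent=geneA.1",
            "toy1\tmabc\texon\t2001\t2600\t.\t+\t.\tParent=geneA.1",
            "toy1\tmabc\tCDS\t1101\t1400\t.\t+\t0\tParent=geneA.1",
            "toy1\tmabc\tCDS\t2001\t2501\t.\t+\t0\tParent=geneA.1",
            "toy1\tmabc\tgene\t5001\t5800\t.\t-\t.\tID=geneB",
            "toy1\tmabc\tmRNA\t5001\t5800\t.\t-\t.\tID=geneB.1;Parent=geneB",
            "toy1\tmabc\texon\t5001\t5800\t.\t-\t.\tParent=geneB.1",
            "toy1\tmabc\tCDS\t5101\t5700\t.\t-\t0\tParent=geneB.1",
        ]
    ) + "\n"
    info = {
        "contig": "toy1",
        "length": length,
        "geneA_cds": cds_a,
        "geneA_intron": (1401, 2000),
        "geneB_cds": cds_b,
        "sequence": "".join(seq),
    }
    return fasta, gff, info
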