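"""Shared fixtures: in-memory variant sites, small VCF texts, toy annotation."""

from __future__ import annotations

from typing import Optional, Tuple

import pytest

from mabc.simulate import make_toy_annotation
from mabc.variants import SampleCall, VariantSite

ROLE_MAP = {"K": "donor", "Y": "recurrent", "P": "progeny"}

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tK\tY\tP\n"
)


def hom_call(allele: int, depth: int = 30) -> SampleCall:
    ad = (depth, 0) if allele == 0 else (0, depth)
    return SampleCall(genotype=(allele, allele), allele_depths=ad, depth=depth)


def het_call(alt_reads: int = 15, ref_reads: int = 15) -> SampleCall:
    return SampleCall(
        genotype=(0, 1),
        allele_depths=(ref_reads, alt_reads),
        depth=ref_reads + alt_reads,
    )


def make_site(
    chrom: str = "chr01",
    pos: int = 1000,
    ref: str = "G",
    alts: Tuple[str, ...] = ("A",),
    qual: Optional[float] = 99.0,
    donor: Optional[SampleCall] = None,
    recurrent: Optional[SampleCall] = None,
    progeny: Optional[SampleCall] = None,
) -> VariantSite:
    """A passing informative site (donor hom-alt, recurrent hom-ref,
    progeny balanced het) unless overridden."""
    return VariantSite(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=alts,
        qual=qual,
        calls={
            "donor": donor if donor is not None else hom_call(1),
            "recurrent": recurrent if recurrent is not None else hom_call(0),
            "progeny": progeny if progeny is not None else het_call(),
        },
    )


def write_vcf(tmp_path, body_lines, name="test.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + "".join(line + "\n" for line in body_lines))
    return str(path)


@pytest.fixture(scope="session")
def toy_annotation():
    """(fasta_text, gff3_text, info) for the synthetic two-gene contig."""
    return make_toy_annotation(seed=0)


@pytest.fixture(scope="session")
def toy_genome(toy_annotation):
    _, _, info = toy_annotation
    return {info["contig"]: info["sequence"]}


@pytest.fixture(scope="session")
def toy_models(toy_annotation):
    from mabc.effects import load_gene_models

    _, gff, _ = toy_annotation
    return load_gene_models(gff, from_string=True)
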