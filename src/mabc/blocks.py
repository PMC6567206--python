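"""Window densities and genotype-block segmentation along chromosomes.

Classified markers are summarized two ways, mirroring graphical-genotype
displays of introgression lines: per-window marker densities by genotype
class (default 10,000-nt non-overlapping windows), and maximal runs of
consecutive same-class markers ("genotype blocks"). Runs shorter than
``min_markers`` are kept but flagged as candidate micro-blocks — short
stretches embedded in longer blocks of another class, as produced by closely
spaced recombination events — rather than being merged away.

Internally marker positions are 1-based (VCF convention); window and block
coordinates are 0-based half-open (BED convention), converted at this
module's boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .profile import ClassifiedSite, GenotypeClass


@dataclass(frozen=True)
class WindowDensity:
    chrom: str
    start: int  # 0-based half-open
    end: int
    counts: Tuple[Tuple[GenotypeClass, int], ...]
    dominant: Optional[GenotypeClass]  # None on tie or empty window

    def count(self, gclass: GenotypeClass) -> int:
        return dict(self.counts).get(gclass, 0)


@dataclass(frozen=True)
class GenotypeBlock:
    chrom: str
    start: int  # 0-based half-open
    end: int
    genotype_class: GenotypeClass
    n_markers: int
    first_marker: int  # 1-based positions of supporting markers
    last_marker: int
    flagged: bool = False  # candidate micro-block (< min_markers support)


def window_density(
    classified: Sequence[ClassifiedSite],
    chrom_lengths: Dict[str, int],
    window_size: int = 10_000,
    step: Optional[int] = None,
) -> List[WindowDensity]:
    """Per-window genotype-class marker counts.

    Windows tile ``[0, chrom_length)`` with the given ``step`` (default:
    ``window_size``, i.e. non-overlapping); the terminal window is truncated
    at the chromosome end. The dominant class is the unique count maximum;
    ties and empty windows yield ``None``.
    """
    step = step or window_size
    if window_size <= 0 or step <= 0:
        raise ValueError("window_size and step must be positive")
    by_chrom: Dict[str, List[ClassifiedSite]] = {}
    for site in classified:
        length = chrom_lengths.get(site.chrom)
        if length is None:
            raise ValueError(f"no chromosome length for {site.chrom}")
        if site.pos > length:
            raise ValueError(
                f"marker {site.chrom}:{site.pos} beyond chromosome length {length}"
            )
        by_chrom.setdefault(site.chrom, []).append(site)

    classes = list(GenotypeClass)
    out: List[WindowDensity] = []
    for chrom in chrom_lengths:
        sites = sorted(by_chrom.get(chrom, []), key=lambda s: s.pos)
        pos0 = {
            g: np.array([s.pos - 1 for s in sites if s.genotype_class is g])
            for g in classes
        }
        length = chrom_lengths[chrom]
        for start in range(0, length, step):
            end = min(start + window_size, length)
            counts = {
                g: int(
                    np.searchsorted(pos0[g], end, side="left")
                    - np.searchsorted(pos0[g], start, side="left")
                )
                for g in classes
            }
            best = max(counts.values())
            if best == 0:
                dominant = None
            else:
                winners = [g for g, c in counts.items() if c == best]
                dominant = winners[0] if len(winners) == 1 else None
            out.append(
                WindowDensity(
                    chrom=chrom,
                    start=start,
                    end=end,
                    counts=tuple(counts.items()),
                    dominant=dominant,
                )
            )
    return out


def windows_to_tsv(windows: Iterable[WindowDensity]) -> str:
    classes = list(GenotypeClass)
    header = "chrom\tstart\tend\t" + "\t".join(g.value for g in classes) + "\tdominant"
    lines = [header]
    for w in windows:
        counts = dict(w.counts)
        dom = w.dominant.value if w.dominant else "NONE"
        lines.append(
            f"{w.chrom}\t{w.start}\t{w.end}\t"
            + "\t".join(str(counts.get(g, 0)) for g in classes)
            + f"\t{dom}"
        )
    return "\n".join(lines) + "\n"


def call_blocks(
    classified: Sequence[ClassifiedSite],
    min_markers: int = 3,
    max_gap: int = 1_000_000,
) -> List[GenotypeBlock]:
    """Maximal same-class marker runs, broken at class changes and at
    inter-marker gaps exceeding ``max_gap`` nt.

    Block extent is first-to-last supporting marker (not window edges). Runs
    with fewer than ``min_markers`` markers are flagged, not dropped: every
    classified marker belongs to exactly one returned block.
    """
    by_chrom: Dict[str, List[ClassifiedSite]] = {}
    for site in classified:
        by_chrom.setdefault(site.chrom, []).append(site)

    blocks: List[GenotypeBlock] = []
    for chrom in by_chrom:
        sites = sorted(by_chrom[chrom], key=lambda s: s.pos)
        run: List[ClassifiedSite] = []
        for site in sites:
            if run and (
                site.genotype_class is not run[-1].genotype_class
                or site.pos - run[-1].pos > max_gap
            ):
                blocks.append(_close_run(chrom, run, min_markers))
                run = []
            run.append(site)
        if run:
            blocks.append(_close_run(chrom, run, min_markers))
    blocks.sort(key=lambda b: (b.chrom, b.start))
    return blocks


def _close_run(
    chrom: str, run: Sequence[ClassifiedSite], min_markers: int
) -> GenotypeBlock:
    first, last = run[0].pos, run[-1].pos
    return GenotypeBlock(
        chrom=chrom,
        start=first - 1,
        end=last,
        genotype_class=run[0].genotype_class,
        n_markers=len(run),
        first_marker=first,
        last_marker=last,
        flagged=len(run) < min_markers,
    )


def blocks_to_bed(blocks: Iterable[GenotypeBlock]) -> str:
    """BED6 serialization; name = genotype class (``;flagged`` suffix for
    micro-blocks), score = supporting marker count."""
    lines = []
    for b in blocks:
        name = b.genotype_class.value + (";flagged" if b.flagged else "")
        lines.append(f"{b.chrom}\t{b.start}\t{b.end}\t{name}\t{b.n_markers}\t.")
    return "\n".join(lines) + ("\n" if lines else "")


def bed_to_blocks(text: str) -> List[GenotypeBlock]:
    blocks = []
    for line in text.strip().splitlines():
        if not line:
            continue
        chrom, start, end, name, score, _strand = line.split("\t")
        flagged = name.endswith(";flagged")
        gclass = GenotypeClass(name.split(";")[0])
        start, end = int(start), int(end)
        blocks.append(
            GenotypeBlock(
                chrom=chrom,
                start=start,
                end=end,
                genotype_class=gclass,
                n_markers=int(score),
                first_marker=start + 1,
                last_marker=end,
                flagged=flagged,
            )
        )
    return blocks


def _merged(intervals: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def interval_jaccard(
    a: Sequence[Tuple[str, int, int]], b: Sequence[Tuple[str, int, int]]
) -> float:
    """Jaccard index (bp intersection / bp union) of two interval sets given
    as ``(chrom, start, end)`` 0-based half-open triples."""
    chroms = {c for c, _, _ in a} | {c for c, _, _ in b}
    inter = union = 0
    for chrom in chroms:
        ia = _merged([(s, e) for c, s, e in a if c == chrom])
        ib = _merged([(s, e) for c, s, e in b if c == chrom])
        la = sum(e - s for s, e in ia)
        lb = sum(e - s for s, e in ib)
        # two-pointer sweep for intersection
        i = j = ov = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i][0], ib[j][0])
            e = min(ia[i][1], ib[j][1])
            if e > s:
                ov += e - s
            if ia[i][1] <= ib[j][1]:
                i += 1
            else:
                j += 1
        inter += ov
        union += la + lb - ov
    return inter / union if union else 1.0


def donor_block_intervals(
    blocks: Iterable[GenotypeBlock], include_flagged: bool = False
) -> List[Tuple[str, int, int]]:
    return [
        (b.chrom, b.start, b.end)
        for b in blocks
        if b.genotype_class is GenotypeClass.DONOR_HOM
        and (include_flagged or not b.flagged)
    ]


def plot_genotype_map(
    blocks: Sequence[GenotypeBlock],
    chrom_lengths: Dict[str, int],
    path: str,
) -> None:
    """Static chromosome-ideogram plot: colored bars per genotype block
    (black recurrent-homozygous, red donor-homozygous, blue heterozygous)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        GenotypeClass.RECURRENT_HOM: "black",
        GenotypeClass.DONOR_HOM: "red",
        GenotypeClass.HET: "blue",
        GenotypeClass.NON_PARENTAL: "grey",
    }
    chroms = list(chrom_lengths)
    fig, ax = plt.subplots(figsize=(10, 0.45 * len(chroms) + 1.5))
    for i, chrom in enumerate(chroms):
        y = len(chroms) - i
        ax.broken_barh([(0, chrom_lengths[chrom])], (y - 0.15, 0.3), color="#b8e0b8")
        for b in blocks:
            if b.chrom == chrom:
                ax.broken_barh(
                    [(b.start, max(b.end - b.start, chrom_lengths[chrom] / 800))],
                    (y - 0.15, 0.3),
                    color=colors[b.genotype_class],
                )
    ax.set_yticks([len(chroms) - i for i in range(len(chroms))])
    ax.set_yticklabels(chroms)
    ax.set_xlabel("position (bp)")
    ax.set_title("genotype blocks")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
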