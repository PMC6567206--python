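# Methods

## Problem setting

Marker-assisted backcrossing transfers a single donor allele (here, the
motivating case is a salinity-tolerance SNP moved between japonica rice
cultivars) into an elite recurrent-parent background: repeated crosses to
the recurrent parent with selection for heterozygotes at the target locus,
followed by selfing and selection for target homozygotes. Whole-genome
sequencing of parents and progeny then measures how much of the recurrent
genome has been recovered and where donor chromatin remains. `mabc`
implements that characterization — from a called multi-sample VCF to
recovery rates, genotype blocks and effect annotation — plus a simulator
that generates the same kind of data with known truth.

## Site filtering

A site enters the informative-marker set only if it survives a fixed
cascade, each removal attributed to the *first* failing rule so that
tallies are reproducible and order-independent:

1. **missing** — any of the three calls lacks a genotype;
2. **multiallelic** — the record does not have exactly one ALT allele
   (multi-allelic records are dropped whole, never decomposed);
3. **parental_het** — either parent call is heterozygous;
4. **low_depth** — any sample's depth is below `min_depth` (default 6).
   Depth is per sample, the stricter of the two readings of a site-level
   rule, and falls back to the AD sum when DP is absent; if neither is
   present the check is skipped for that sample and a warning counted;
5. **low_quality** — site QUAL below `min_quality` (default 20);
6. **allele_balance** — a heterozygous *progeny* call whose
   alternate-allele read fraction, computed from AD as alt/(ref+alt), lies
   outside the closed band [0.40, 0.60]. The band is inclusive ("40–60 %"
   read as a closed interval); a ratio exactly equal to a band edge (e.g.
   8/20) compares exactly in IEEE arithmetic because division is correctly
   rounded. When AD is absent the filter is skipped and a warning counted
   rather than silently dropping the site.

Downstream, sites where the parents are homozygous for the *same* allele
are uninformative for parental origin and are dropped with their own count.
Invariants tested: input = passing + Σremoved, permutation invariance,
idempotence, inclusive band edges.

## Genotype classification and recovery

At an informative site the progeny call maps to
recurrent-homozygous / donor-homozygous / heterozygous / non-parental.
Non-parental calls (an allele matching neither parent — caller artifacts or
mutations) are excluded from the recovery denominator and reported
separately; with biallelic sites and opposite-homozygous parents they
cannot occur after filtering, but the classifier is total.

The recovery rate (YY + YK/2)/(YY + YK + KK) is the recurrent-allele
frequency among classified markers and equals the mean per-site
recurrent-allele dosage/2 (a brute-force oracle asserted in tests).
Percentages in the summary table are rounded half-up to one decimal, the
convention of printed count tables. Per-chromosome recovery is reported to
localize unfixed or donor regions.

The theoretical expectation without selection is 1 − 2^−(n+1) after n
backcrosses — the fixed point iteration r ← (r+1)/2 from the F1 value 0.5
— and is unchanged by selfing. The expected heterozygous marker fraction is
2^−(n_backcross + n_self): 1 at F1, halving with every backcross and every
selfing. (The widely quoted "93.7 %" for three backcrosses plus one selfing
is the truncation of the exact 93.75 %.)

## Blocks and window densities

Marker densities are tallied in tiling windows (default 10,000 nt; a step
smaller than the window gives sliding windows). The dominant class of a
window is its unique count maximum; ties and empty windows are `NONE`,
never an arbitrary class order. Genotype blocks are maximal runs of
consecutive same-class markers, broken at class changes and at inter-marker
gaps above `max_gap` (default 1 Mb, respecting marker deserts). Block
extent is first-to-last supporting marker, not window edges. Runs shorter
than `min_markers` (default 3, suppressing single-marker noise) are
*flagged* as candidate micro-blocks — short stretches inside longer blocks
of another class, as produced by closely spaced recombination — rather
than merged away, so every marker belongs to exactly one block. BED6
output is 0-based half-open; the 1-based VCF convention is converted only
at the writer boundary.

## Effect annotation

The annotator is a deliberately minimal codon-level classifier in the
spirit of SnpEff, restricted to the term set needed for protein-alteration
tallies. Regions are resolved per transcript (splice > CDS > UTR > intron
for spanning variants; splice sites are the canonical 2-nt dinucleotides,
strand-aware). For a variant fully inside one CDS interval the mutant
spliced CDS is rebuilt and both alleles translated (minus strands via
reverse complement): indels are frameshift iff the length change is not a
multiple of three, otherwise in-frame; SNPs are classified by the
amino-acid change (stop gained/lost, start lost, missense, synonymous).
Impact follows the fixed SO-term map (HIGH: stop/start/frameshift/splice;
MODERATE: missense/in-frame; LOW: synonymous; MODIFIER: non-coding), and
"protein-altering" means HIGH ∪ MODERATE. Each variant receives exactly one
annotation — the most severe across transcripts under a fixed total
severity order — so tallies count variants once. Reference-allele
"variants" are a no-op; a REF disagreeing with the genome raises. Not
implemented (out of scope): regulatory features, NMD/LOF flags, phase
repair of partial gene models.

## Simulator

The simulator is the package's synthetic-data generator and ground-truth
oracle. Design choices:

- **Genome**: 12 chromosomes with rice-like physical lengths (373 Mb
  total) and a uniform genetic map of 1 cM / 400 kb (~932 cM); both are
  configuration, not hard-coded.
- **Markers**: parents fully homozygous for opposite alleles at every
  marker; positions uniform; ~20 % short indels. The default density of
  1 marker / 3 kb emulates the ~10⁵-marker divergence of a typical
  characterized cross; tests and the acceptance run use 2–5 × 10⁴ markers
  to keep runtimes in seconds. The recurrent parent carries REF
  everywhere — a convention, since real pipelines call against an external
  reference; nothing downstream depends on it.
- **Meiosis**: Haldane (no interference) — crossover counts
  Poisson(genetic length in Morgans), positions uniform on the physical
  map, starting haplotype fair; no obligate crossover. Chosen as the
  standard minimal model; interference would slightly narrow segment-length
  spread but leaves all expectations used here unchanged.
- **Scheme**: BCnFm with foreground selection (heterozygote at the target
  through the backcrosses, donor homozygote at the first selfing),
  implemented by redrawing gametes until the rule is met, with an explicit
  failure after a bounded number of attempts. The target defaults to
  chromosome 6 at 4.3 Mb, mimicking the chromosome of the motivating
  salinity-tolerance locus; its exact position is a free parameter.
- **Emission**: one VCF record per marker with GT:AD:DP and site QUAL.
  The zero-noise default is deterministic and classification-lossless
  (constant depth 30, exact 50:50 heterozygous AD, QUAL 99), so pipeline
  estimates equal truth exactly. Noise rates inject missing progeny calls,
  progeny depth < 6, QUAL < 20, heterozygous allele balance forced to a
  configured fraction (default 0.30), spurious multi-allelic records and
  genotype errors; every injection is recorded so tests can compare filter
  behaviour against the known truth. Missingness and depth noise act on
  the progeny sample — the sample the allele-balance rule targets; real
  data also loses parental calls, which the missing filter handles
  identically.
- **Determinism**: one seeded `numpy` generator threaded through every
  stochastic step; identical seeds give byte-identical VCF text.

What the simulator does *not* emulate: reference bias and mapping
artifacts, depth heterogeneity along the genome, linked marker ascertainment,
mutation during breeding, segregation distortion, polygenic phenotypes.
Passing tests therefore demonstrate correctness of the estimators and
filters under their stated models, not robustness to every real-data
pathology.

## Linkage drag and the two recovery summaries

Selecting the target homozygous conditions all four transmitted gametes on
carrying the donor allele there, which inflates donor content on the
target chromosome (classical linkage drag): the expected excess is
∫[(1−r(d))⁴ − 1/16] dd ≈ 0.3 Morgans per haplotype under Haldane, i.e.
≈ 3 percentage points on a 932-cM genome. Simulation confirms this: with
default settings the genome-wide mean recovery of BC3F2 individuals is
≈ 90.5 % while the mean over markers unlinked to the target sits at the
closed-form 93.75 %. The acceptance script therefore reports the off-target
mean as the estimate of the theoretical recovery (the quantity the closed
form predicts) and the genome-wide mean alongside under a descriptive key.
Per-chromosome recovery in the report makes the same distinction visible
on single individuals.

## Problem sizes and numerical notes

Simulation-based checks use 2,000 replicates at 24,000 markers (recovery
calibration; Monte-Carlo SE ≈ 0.1 pp) and single individuals at 5 × 10⁴
markers (oracle equality, block recovery at ≥ 1 marker / 10 kb). The
recovery estimator and the simulator's truth use the same arithmetic
((YY + YK/2)/total), so their equality on noiseless data is exact, not
approximate. Percentage rounding is half-up via `decimal`. All marker
coordinates are 1-based internally (VCF convention) and converted to
0-based half-open only when writing BED/window output.
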