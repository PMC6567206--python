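# mabc — genome characterization for marker-assisted backcross breeding

`mabc` is a Python library and command-line tool for breeders and
geneticists who characterize **marker-assisted backcross (MABC)
introgression lines** by whole-genome sequencing. Given a multi-sample VCF
containing the donor parent, the recurrent parent, and one progeny, it

1. **filters** variant sites (missing data, multi-allelic records, parental
   heterozygotes, depth `DP < 6` per sample, quality `QUAL < 20`, and
   heterozygous progeny calls whose alternate-allele fraction falls outside
   the closed 40–60 % band),
2. **classifies** every informative marker — a site where the two parents
   are homozygous for different alleles — as recurrent-homozygous (YY),
   donor-homozygous (KK), heterozygous (YK), or non-parental,
3. computes the **recurrent-parent genome recovery rate**

   recovery = (YY + YK/2) / (YY + YK + KK),

   together with its no-selection theoretical expectation
   1 − 2^−(n+1) after *n* backcrosses (unchanged by selfing; the expected
   heterozygous fraction is 2^−(n_backcross + n_self)),
4. segments chromosomes into **genotype blocks** and 10-kb window
   densities (the graphical genotype of the line), and
5. **annotates** protein-altering variants (frameshift, in-frame indel,
   missense, stop/start changes, splice donor/acceptor) against gene models
   and a trait-gene table.

A forward-time **breeding simulator** (Haldane meiosis, BCnFm schemes with
foreground selection at a single target SNP, configurable per-site noise)
generates fully synthetic three-sample VCFs with known truth, so the entire
pipeline is testable without any external data.

## Worked example

Simulate a BC3F2 individual (three backcrosses, one selfing, selection for
the donor allele at a chromosome-6 target) at 3,000 markers with realistic
noise, then run the full pipeline:

```bash
mabc all --scheme BC3F2 --seed 3 --markers 3000 --noise default -o demo/
```

The consolidated report (`demo/analysis/report.txt`) begins:

```
## site filtering
input sites:            3000
removed (allele_balance): 5
removed (low_depth): 83
removed (low_quality): 68
removed (missing): 151
removed (multiallelic): 29
passing sites:          2664
informative markers:    2664

## genotype profile (counts: SNPs / indels / total / genome %)
recurrent-parent hom  1798 / 448 / 2246 / 84.3
donor-parent hom      192 / 40 / 232 / 8.7
heterozygous          147 / 39 / 186 / 7.0
total                 2664 / 100.0
genome recovery rate: 87.8%
```

Reading this: 336 of 3,000 noisy sites were removed by the filter cascade
(each site attributed to the first rule it fails); of the 2,664 informative
markers, 84.3 % are fixed for the recurrent parent, 8.7 % for the donor and
7.0 % are still heterozygous, giving a recovery rate of 87.8 % for this
(deliberately small, single-individual) example. The per-chromosome table
shows the forced donor-homozygous target dragging chromosome 6 down to
45.7 % while five chromosomes are fully recovered. `blocks.bed` holds the
genotype blocks (BED6; name = class, score = supporting markers):

```
chr01	49726	6863956	recurrent_hom	51	.
chr01	7315888	11016168	het	27	.
```

Library use mirrors the CLI: `read_multisample_variants` →
`apply_site_filters` → `select_informative_sites` → `classify_sites` →
`profile_summary` / `call_blocks` / `annotate_variant`, and
`mabc.simulate.run_scheme` / `emit_vcf` for synthetic data. On noiseless
simulated data the pipeline estimate equals the simulator's true
marker-dosage recovery exactly, and called donor blocks recover the true
donor segments with Jaccard ≥ 0.9 at ≥ 1 marker / 10 kb — both are asserted
in the test suite.

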