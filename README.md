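# tumorsim

Data-driven simulation of tumor and matched-control capture-based NGS
reads (whole-exome or targeted panels), with phased germline SNPs and
clonality-aware allele-specific somatic events.

Benchmarking somatic variant callers, copy-number tools and purity
estimators needs sequencing data where the truth is known exactly — which
cells carry which event, on which haplotype, at what fraction. `tumorsim`
produces such data in two stages:

1. **Model building** — learn three reference models from control (non-cancer)
   alignments over a capture panel:
   * a *read-depth model* (RDM): per-captured-position fragment-start
     weights (for paired data only the mate at the lower coordinate
     counts, so each fragment is counted once), plus insert-size mean/sd;
   * a *quality model* (QM): the empirical distribution of Phred base
     qualities at each read cycle, in original sequencing orientation;
   * a *position-based error model* (PBE): for each captured position not
     masked as a common SNP, the rate and base profile of systematic
     errors supported by high-quality reads and bases.
2. **Generation** — combine the models with a genome profile (phased
   heterozygous SNPs, allele-specific copy-number alterations given as
   (copies of haplotype A, copies of haplotype B) per clone, and point
   mutations with an affected allele and multiplicity) plus a tumor
   content *t*, and emit FASTQ reads.

## The dosage model

Clones partition the tumor cells: a clone with clonality *c* holds a
fraction *t·c* of all cells, normal cells hold *1−t*, and remaining tumor
cells are diploid. On each segment the effective per-allele copy numbers
are the population averages

    e_A = Σ_pop f_pop · n_A(pop),     e_B analogous,

and generation makes the standard quantities exact by construction:

| quantity | expectation |
|---|---|
| read from haplotype A | e_A / (e_A + e_B) |
| coverage log2 ratio (tumor/control) | log2((e_A + e_B) / 2) |
| alt fraction of a het SNP phased to h | e_h / (e_A + e_B) |
| VAF of a point mutation (clonality c, multiplicity m) | t·c·m / (e_A + e_B) |

Each read draws its cell population proportionally to fraction × local
total copies, then a uniform copy of one haplotype — so SNP alleles,
mutation carriage and coverage modulation all follow from one sampling
scheme. Overlapping CNAs of one clone may be nested (the inner event
replaces the outer one on its span); distinct clones are disjoint
populations.

## Worked example

All inputs can be fabricated; no downloads are needed. Build a toy panel
and reference models, then generate an 80%-purity tumor carrying a clonal
hemizygous deletion and a subclonal point mutation:

```
$ tumorsim fixtures --spec fixture.yaml --out panel
$ tumorsim model-build --bams panel/control.bam --targets panel/targets.bed \
      --reference panel/reference.fa --min-depth 30 --out panel/built.zip
INFO tumorsim.model_builder: RDM panel/control.bam: 3200 fragments used, 0 records skipped

$ tumorsim generate --models panel/built.zip --reference panel/reference.fa \
      --snps snps.tsv --cnas cnas.tsv --pms pms.tsv \
      --tumor-content 0.8 --coverage 500 --seed 11 --kind tumor --out tumor
INFO tumorsim: tumor: 7094 fragments, realized on-target coverage 502.0x
```

`tumorsim expect` prints the closed-form expectations for the same
profile, e.g. for the deleted segment and the first SNPs:

```
event         chromosome  position_or_span  expected
segment_log2  chr1        3961-4460         -0.7370
snp_baf       chr1        4271              0.1667
```

and the generation report (`tumor.report.json`) shows the observed values
landing on them:

```
chr1 4271 phase B  obs 0.183  exp 0.167  depth 448
chr1 4283 phase A  obs 0.817  exp 0.833  depth 447
PM   8221          obs 0.207  exp 0.200  depth 818
```

Here the deletion (1,0) at t = 0.8 leaves e_A = 1 and e_B = 0.2, hence an
alt fraction of 0.2/1.2 ≈ 0.167 for B-phased SNPs and log2(0.6) ≈ −0.737
for the segment; the subclonal mutation (clonality 0.5, allele A, diploid
locus) has VAF 0.8·0.5/2 = 0.2. A matched control (`--kind
matched_control`) shares the SNPs but ignores every somatic event.

Multi-sample designs — tumor-content dilution series, longitudinal
subclone regression/emergence — run from one YAML via `tumorsim
scenario`, which also emits a matched control and a combined
expected-vs-observed event table.

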