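# Methods

## Reference models

All three models are cumulative pileup summaries over one or more control
BAM files restricted to a merged capture-target BED. Secondary,
supplementary, duplicate-flagged and unmapped records are always skipped;
this filter set is a deliberate choice (standard pileup hygiene) rather
than something the models require.

**Read-depth model (RDM).** The weight at captured position *p* is the
number of fragments, pooled over all input files, whose leftmost aligned
coordinate is *p*. For paired data only the mate at the lower coordinate
contributes (ties broken toward read 1), so a fragment is never counted
twice; single-end primary alignments all contribute. Weights are stored as
one dense array per target region — capture targets are small enough that
sparse storage buys nothing. Insert statistics are the sample mean and
(ddof = 1) standard deviation of absolute template lengths of proper pairs
whose leftmost mate starts on target; values ≤ 0 or above 2000 bp are
discarded as chimeric.

**Quality model (QM).** One histogram over Phred values 0–93 per read
cycle, where cycle means position in original sequencing orientation:
reverse-strand alignments are un-reversed before tallying. The model pools
strands and mates into a single per-cycle distribution; conditioning on
mate (read 1 vs read 2) or strand is a deliberate simplification — if the
two mates have materially different quality profiles on a platform, the
pooled model averages them.

**Position-based error model (PBE).** For each on-target position not in
the user-supplied common-SNP mask, bases with quality ≥ 20 from reads with
mapping quality ≥ 20 are pooled across files (thresholds are parameters).
A position is stored when high-quality depth reaches `min_depth` (default
50) and the non-reference fraction reaches `min_error_rate` (default
0.005); the stored profile is the relative frequency of the non-reference
bases seen there. The defaults are explicit, CLI-overridable parameters:
"high quality" is not a universal constant, and panels differ. The mask
may be any BED or VCF of positions; when none is supplied, passing the
same phased-SNP list used for generation is the recommended minimum.

Counting behind the PBE uses `pysam.AlignmentFile.count_coverage` (per-base
A/C/G/T counts with base-quality threshold and a read callback); the RDM
and QM walk records directly via `fetch`.

**Bundle format.** A zip archive holding `header.json` (format version,
builder parameters, target list and checksum) plus one `.npy` array per
payload. Round-trips are bit-exact; loading checks the version string and
fails explicitly on unknown versions or truncated archives.

## Genome profiles and dosage segments

A profile holds phased heterozygous SNPs (the alt allele assigned to
haplotype A or B; in VCF input, `a|b` maps the allele left of the bar to
haplotype A, so `0|1` puts the alt on B), allele-specific CNAs
((copies_A, copies_B) ≠ (1,1), half-open intervals) and point mutations
(affected allele, multiplicity = number of copies of that allele carrying
the variant). Every event carries a clone label and a clonality.

Clone semantics, chosen where several readings were defensible:

* clonality is the fraction of *tumor* cells in the clone; all events of
  one clone must declare the same clonality (validated), since a clone is
  one cell population;
* distinct clones are disjoint populations; tumor cells in no declared
  clone form a diploid background population. Lineage-nested clones
  (a subclone inside its parent's cells) are intentionally not modeled;
* within a clone, two CNAs may overlap only by strict nesting, and on the
  nested span the inner event's copies *replace* the outer ones — no
  composition algebra is attempted;
* summed clonality of clones whose CNAs cover a common segment may not
  exceed 1;
* events are clipped to target space: only captured positions can ever be
  sampled, and a point mutation outside the targets is dropped with a
  warning.

`resolve_segments` cuts the target space at every CNA breakpoint and
attaches to each segment its population mixture — normal cells at 1−t,
each covering clone at t·clonality with its local copies, background at
the remainder — and the effective copy numbers e_A, e_B (population
averages). Segments tile the targets exactly; this is property-tested
against an explicit per-cell enumeration oracle.

## Read generation

Per fragment: (1) sample a captured position with probability proportional
to RDM weight × the segment's coverage factor (e_A+e_B)/2; (2) draw the
cell population proportionally to fraction × local total copies, then a
uniform copy index over that population's copies — the copy index decides
the haplotype and, for multiplicity-m mutations, carriage (copies 0..m−1
carry it); (3) take the reference sequence (paired-end: two reads at the
ends of an insert drawn from Normal(mean, sd) truncated to ≥ read length
by resampling, up to 100 tries); (4) substitute SNP alleles phased to the
drawn haplotype; (5) draw a quality per cycle from the QM and inject
errors — at PBE-annotated genomic positions with the stored rate and base
profile, elsewhere with probability 10^(−Q/10) uniformly over the three
other bases; (6) for tumor samples apply carried point mutations; (7) pick
the fragment strand, forward with probability `strand_bias` (default 0.5).

Choices worth recording:

* **Coverage semantics.** CNAs modulate the RDM multiplicatively and the
  distribution is renormalized, so a requested read count is met exactly
  while relative coverage follows dosage. A requested *mean on-target
  coverage* is converted to a fragment budget by dividing by the expected
  on-target yield per fragment, computed from the modulated distribution
  and the discretized insert pmf. Reads may overhang target edges into
  flanking reference (as real capture reads do), and those bases do not
  count toward on-target depth — dividing by read length alone would
  undershoot small panels by 20–30%.
* **Mutation-vs-error order.** Point mutations are applied after
  sequencing errors, so a mutation overwrites an error at its own
  position; `pm_before_errors` flips the order. The difference is
  O(error rate) at mutated positions only.
* **Carriage of mutations whose clone has no local CNA.** Such clones live
  inside the diploid background population; a background read on the right
  haplotype carries the variant with probability t·clonality/f_background,
  which reproduces the closed-form VAF exactly. For a read whose fragment
  starts in one segment but spans a breakpoint, the population drawn at
  the start position is used throughout — an approximation confined to
  breakpoint-spanning reads.
* **Determinism.** Fragments are processed in fixed chunks of 512 serials;
  each chunk derives its RNG stream from (seed, chunk index) via NumPy's
  `SeedSequence`. Chunk boundaries never depend on the worker count, so
  output is byte-identical for any `--threads` value. Reads are emitted in
  serial order under the name scheme
  `<sample>:<serial>:<chrom>:<fragment start>:<insert>:<strand>`, which
  makes truth (origin, span, strand) recoverable from the FASTQ alone.
* **Qualities** are encoded Phred+33. Reads that would be > 50% N (e.g. at
  a chromosome edge) are redrawn, up to 10 attempts.
* If the requested read length exceeds the QM's observed cycles, the last
  cycle's distribution is repeated.

The report written next to each FASTQ contains per-segment fragment counts
and mean depths plus, per SNP and per mutation, the observed allelic
fraction next to the closed-form expectation from the dosage arithmetic —
the expectations are computed by `tumorsim.allele`, never re-derived ad
hoc.

## Synthetic data generator

`tumorsim.fixtures` fabricates every pipeline input deterministically from
a seed: i.i.d. uniform A/C/G/T references, evenly spaced targets kept
clear of chromosome ends, paired-end truth BAMs (uniform or centrally
peaked fragment starts, constant or linearly ramped qualities, fixed
insert length, optional injected systematic errors at stated rates) with a
sidecar recording exact per-position start counts, and analytically
constructed models that bypass BAM building entirely.

What the fixtures emulate — capture-shaped coverage, per-cycle quality
structure, recurrent position-specific errors, insert-size spread — is
sufficient to exercise every code path and every closed-form prediction.
What they do not emulate: GC-dependent coverage waves, indels and soft
clipping, duplicate reads, fragment-length/position correlation, platform
quality-by-base interactions. Tests passing on fixtures therefore validate
the arithmetic and the mechanics, not platform realism; realism on a real
panel comes from building models on real control BAMs.

## Test and verification sizes

Statistical checks run at sizes where the relevant binomial intervals are
decisive: coverage fidelity on 20 × 500 bp (request 100×) and 5 × 500 bp
(request 1000×) panels, accepted within 2%; strand balance on 10⁵ reads
against the 99% binomial interval; tumor-content recovery from 24 phased
SNPs at ≥ 500× inside a clonal (1,0) deletion at 80% purity, accepted
within 2 percentage points (t̂ = 2 − 1/AF_major, exact for this design
since AF_major = 1/(2−t)); dosage arithmetic against 10⁶-cell enumerations
over 24 random multi-clone/nested configurations to 10⁻³; and a grid of
tumor content {0.1,…,1.0} × CNA {(1,0),(2,0),(2,1),(3,1),(2,2)} ×
clonality {0.3, 1.0} at 250×, where each SNP/mutation/segment is compared
to its 99% interval and the family-wise fraction inside must be ≥ 95%
(with ≈ 400 individual 99% checks, demanding all of them inside would
fail a correctly calibrated simulator more often than not). Grid runs use
a near-noiseless quality model (Q93) so allele arithmetic is isolated
from sequencing error.

## Known limitations

* No indels, structural variants beyond CNAs, CRAM input, or BAM output.
* No GC-bias or duplicate modeling beyond what the RDM captures
  empirically; no base-quality recalibration.
* Insert sizes are truncated-normal by resampling; the realized
  distribution deviates from a true normal only when the mean is within a
  few standard deviations of the read length.
* Whole-chromosome-scale events are supported but dosage applies only to
  captured segments, since nothing else is ever sequenced.
* Threaded generation exists for API symmetry and determinism testing;
  pure-Python per-fragment assembly means wall-clock scaling with threads
  is modest.
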