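"""Genome profiles: phased germline SNPs, clone-resolved somatic events.

A profile describes the individual being simulated (heterozygous phased
SNPs on haplotypes A and B) and the tumor's somatic architecture:
allele-specific copy number alterations (CNAs) given as (copies_A,
copies_B) pairs and point mutations (PMs) with an affected allele and a
multiplicity, each tagged with a clone label and a clonality -- the
fraction of tumor cells belonging to that clone.

Clone semantics
---------------
Distinct clone labels are disjoint tumor-cell populations; every event of a
clone shares the clone's clonality. Within one clone two CNAs may overlap
only by strict nesting, and on the nested span the inner event's copy
numbers replace the outer ones. The sample is the mixture: normal cells at
fraction 1-t, each clone at t*clonality, and remaining tumor cells (diploid
at every locus) making up the rest, where t is the tumor content.

``resolve_segments`` partitions the capture-target space at every CNA
breakpoint into :class:`SegmentDosage` records carrying that mixture and
the resulting effective per-allele copy numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam

from tumorsim.errors import InputError, ValidationError
from tumorsim.regions import TargetRegions

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: Population labels reserved for non-clone cell populations.
NORMAL = "normal"
BACKGROUND = "background_tumor"


@dataclass(frozen=True)
class PhasedSNP:
    """Heterozygous germline SNV whose alt allele sits on one haplotype."""

    chromosome: str
    position: int  # 0-based
    ref_base: str
    alt_base: str
    phase: str  # haplotype carrying the alt: "A" or "B"

    def __post_init__(self) -> None:
        if self.ref_base not in VALID_BASES or self.alt_base not in VALID_BASES:
            raise ValidationError(
                f"SNP {self.chromosome}:{self.position + 1}: bases must be A/C/G/T"
            )
        if self.ref_base == self.alt_base:
            raise ValidationError(
                f"SNP {self.chromosome}:{self.position + 1}: ref equals alt"
            )
        if self.phase not in ("A", "B"):
            raise ValidationError(
                f"SNP {self.chromosome}:{self.position + 1}: phase must be A or B"
            )


@dataclass(frozen=True)
class SomaticCNA:
    """Allele-specific copy number alteration carried by one clone."""

    chromosome: str
    start: int  # 0-based half-open
    end: int
    copies_A: int
    copies_B: int
    clone_id: str
    clonality: float

    def __post_init__(self) -> None:
        loc = f"CNA {self.chromosome}:{self.start + 1}-{self.end}"
        if self.start >= self.end:
            raise ValidationError(f"{loc}: start must precede end")
        if self.copies_A < 0 or self.copies_B < 0:
            raise ValidationError(f"{loc}: negative copy number")
        if (self.copies_A, self.copies_B) == (1, 1):
            raise ValidationError(f"{loc}: (1,1) is not an alteration")
        if not (0.0 < self.clonality <= 1.0):
            raise ValidationError(f"{loc}: clonality must be in (0,1]")


@dataclass(frozen=True)
class SomaticPM:
    """Somatic point mutation on a given allele of one clone.

    ``multiplicity`` is how many copies of that allele carry the mutation
    in the clone's cells (relevant under amplification).
    """

    chromosome: str
    position: int  # 0-based
    ref_base: str
    alt_base: str
    allele: str  # "A" or "B"
    multiplicity: int
    clone_id: str
    clonality: float

    def __post_init__(self) -> None:
        loc = f"PM {self.chromosome}:{self.position + 1}"
        if self.ref_base not in VALID_BASES or self.alt_base not in VALID_BASES:
            raise ValidationError(f"{loc}: bases must be A/C/G/T")
        if self.ref_base == self.alt_base:
            raise ValidationError(f"{loc}: ref equals alt")
        if self.allele not in ("A", "B"):
            raise ValidationError(f"{loc}: allele must be A or B")
        if self.multiplicity < 1:
            raise ValidationError(f"{loc}: multiplicity must be >= 1")
        if not (0.0 < self.clonality <= 1.0):
            raise ValidationError(f"{loc}: clonality must be in (0,1]")


@dataclass(frozen=True)
class SamplePlan:
    """Per-sample generation parameters."""

    sample_name: str = "sample"
    sample_kind: str = "tumor"  # "tumor" | "matched_control"
    tumor_content: float = 0.0
    target_mean_coverage: float | None = None
    n_reads: int | None = None
    read_length: int = 100
    paired: bool = True
    strand_bias: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_kind not in ("tumor", "matched_control"):
            raise ValidationError("sample_kind must be tumor or matched_control")
        if not (0.0 <= self.tumor_content <= 1.0):
            raise ValidationError("tumor_content must be in [0,1]")
        if (self.target_mean_coverage is None) == (self.n_reads is None):
            raise ValidationError(
                "exactly one of target_mean_coverage / n_reads must be set"
            )
        if not (0.0 <= self.strand_bias <= 1.0):
            raise ValidationError("strand_bias must be in [0,1]")
        if self.read_length < 1:
            raise ValidationError("read_length must be positive")


@dataclass(frozen=True)
class Population:
    """One cell population of a segment's mixture."""

    label: str  # NORMAL, a clone_id, or BACKGROUND
    fraction: float
    copies_A: int
    copies_B: int

    @property
    def total_copies(self) -> int:
        return self.copies_A + self.copies_B


@dataclass(frozen=True)
class SegmentDosage:
    """Disjoint target interval with its cell-population mixture.

    ``effective_A``/``effective_B`` are the population-averaged per-allele
    copy numbers; their sum over 2 is the coverage modulation factor.
    """

    chromosome: str
    start: int
    end: int
    populations: tuple[Population, ...]
    effective_A: float = field(init=False)
    effective_B: float = field(init=False)

    def __post_init__(self) -> None:
        total = sum(p.fraction for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"segment {self.chromosome}:{self.start}-{self.end}: "
                f"population fractions sum to {total}, not 1"
            )
        object.__setattr__(
            self,
            "effective_A",
            sum(p.fraction * p.copies_A for p in self.populations),
        )
        object.__setattr__(
            self,
            "effective_B",
            sum(p.fraction * p.copies_B for p in self.populations),
        )

    @property
    def coverage_factor(self) -> float:
        return (self.effective_A + self.effective_B) / 2.0

    def population(self, label: str) -> Population | None:
        for p in self.populations:
            if p.label == label:
                return p
        return None


@dataclass
class GenomeProfile:
    """Full germline + somatic specification of the simulated individual."""

    snps: list[PhasedSNP] = field(default_factory=list)
    cnas: list[SomaticCNA] = field(default_factory=list)
    pms: list[SomaticPM] = field(default_factory=list)

    def germline_only(self) -> "GenomeProfile":
        """The matched-control view: germline SNPs, no somatic events."""
        return GenomeProfile(snps=list(self.snps), cnas=[], pms=[])


# ---------------------------------------------------------------------------
# parsing


def parse_snps(path: str) -> list[PhasedSNP]:
    """Read phased heterozygous SNVs from a VCF or a 5-column TSV.

    VCF genotypes must be phased (``a|b``); the allele left of the bar goes
    to haplotype A, so ``0|1`` puts the alt on haplotype B. Multiallelic or
    non-SNV records are skipped with a warning; an unphased heterozygous
    genotype is an error. The TSV form has a header and columns
    chrom, pos (1-based), ref, alt, phase (A or B).
    """
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _parse_snps_vcf(path)
    return _parse_snps_tsv(path)


def _parse_snps_vcf(path: str) -> list[PhasedSNP]:
    snps: list[PhasedSNP] = []
    skipped = 0
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot open VCF {path!r}: {exc}") from exc
    with vcf:
        if len(vcf.header.samples) < 1:
            raise InputError(f"{path}: VCF has no sample column")
        sample = vcf.header.samples[0]
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in VALID_BASES or alt not in VALID_BASES:
                skipped += 1
                continue
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or len(gt) != 2 or None in gt:
                skipped += 1
                continue
            if gt[0] == gt[1]:  # homozygous: not usable as a phased het
                skipped += 1
                continue
            if not call.phased:
                raise ValidationError(
                    f"{path}: unphased heterozygous genotype at "
                    f"{rec.chrom}:{rec.pos}"
                )
            phase = "A" if gt[0] == 1 else "B"
            snps.append(PhasedSNP(rec.chrom, rec.pos - 1, ref, alt, phase))
    if skipped:
        log.info("parse_snps %s: skipped %d non-het/non-SNV records", path, skipped)
    return snps


def _parse_snps_tsv(path: str) -> list[PhasedSNP]:
    snps: list[PhasedSNP] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith(("chrom", "#chrom", "chr")):
            raise InputError(f"{path}: SNP TSV requires a header row")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise InputError(f"{path}: line {lineno}: expected 5 columns")
            chrom, pos, ref, alt, phase = fields[:5]
            try:
                position = int(pos) - 1
            except ValueError as exc:
                raise InputError(f"{path}: line {lineno}: bad position") from exc
            snps.append(PhasedSNP(chrom, position, ref.upper(), alt.upper(), phase.upper()))
    return snps


def parse_cnas(path: str) -> list[SomaticCNA]:
    """Read CNAs from a TSV: chrom, start, end (1-based inclusive),
    copies_A, copies_B, clone_id, clonality. Header row required."""
    cnas: list[SomaticCNA] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith(("chrom", "#chrom", "chr")):
            raise InputError(f"{path}: CNA TSV requires a header row")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 7:
                raise InputError(f"{path}: line {lineno}: expected 7 columns")
            try:
                cnas.append(
                    SomaticCNA(
                        chromosome=f[0],
                        start=int(f[1]) - 1,
                        end=int(f[2]),
                        copies_A=int(f[3]),
                        copies_B=int(f[4]),
                        clone_id=f[5],
                        clonality=float(f[6]),
                    )
                )
            except ValueError as exc:
                raise InputError(f"{path}: line {lineno}: {exc}") from exc
    return cnas


def parse_pms(path: str) -> list[SomaticPM]:
    """Read PMs from a TSV: chrom, pos (1-based), ref, alt, allele,
    multiplicity, clone_id, clonality. Header row required."""
    pms: list[SomaticPM] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith(("chrom", "#chrom", "chr")):
            raise InputError(f"{path}: PM TSV requires a header row")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise InputError(f"{path}: line {lineno}: expected 8 columns")
            try:
                pms.append(
                    SomaticPM(
                        chromosome=f[0],
                        position=int(f[1]) - 1,
                        ref_base=f[2].upper(),
                        alt_base=f[3].upper(),
                        allele=f[4].upper(),
                        multiplicity=int(f[5]),
                        clone_id=f[6],
                        clonality=float(f[7]),
                    )
                )
            except ValueError as exc:
                raise InputError(f"{path}: line {lineno}: {exc}") from exc
    return pms


# ---------------------------------------------------------------------------
# segment resolution


def _strictly_nested(a: SomaticCNA, b: SomaticCNA) -> bool:
    """True if one interval strictly contains the other."""
    return (a.start <= b.start and b.end <= a.end and (a.start, a.end) != (b.start, b.end)) or (
        b.start <= a.start and a.end <= b.end and (a.start, a.end) != (b.start, b.end)
    )


def _overlap(a: SomaticCNA, b: SomaticCNA) -> bool:
    return a.chromosome == b.chromosome and a.start < b.end and b.start < a.end


def _clone_clonalities(cnas: list[SomaticCNA], pms: list[SomaticPM] | None = None
                       ) -> dict[str, float]:
    """Each clone's single clonality; inconsistent values are an error."""
    clon: dict[str, float] = {}
    events = [(c.clone_id, c.clonality) for c in cnas]
    if pms:
        events += [(p.clone_id, p.clonality) for p in pms]
    for clone_id, value in events:
        if clone_id in clon and abs(clon[clone_id] - value) > 1e-9:
            raise ValidationError(
                f"clone {clone_id!r} has inconsistent clonality values "
                f"({clon[clone_id]} vs {value}); events of one clone must agree"
            )
        clon.setdefault(clone_id, value)
    return clon


def resolve_segments(
    cnas: list[SomaticCNA],
    targets: TargetRegions,
    tumor_content: float,
) -> list[SegmentDosage]:
    """Partition target space at CNA breakpoints and mix cell populations.

    Within each resulting segment the populations are: normal cells at
    fraction 1-t (diploid); for every clone with a CNA covering the
    segment, t*clonality cells with the copies of that clone's innermost
    covering event; and background tumor cells (diploid) making up the
    rest. Same-clone partial overlaps, and overlapping distinct clones
    whose clonalities exceed 1, are validation errors.
    """
    if not (0.0 <= tumor_content <= 1.0):
        raise ValidationError("tumor_content must be in [0,1]")
    by_clone: dict[str, list[SomaticCNA]] = {}
    for cna in cnas:
        by_clone.setdefault(cna.clone_id, []).append(cna)
    clonality = _clone_clonalities(cnas)
    for clone_id, events in by_clone.items():
        for i in range(len(events)):
            for j in range(i + 1, len(events)):
                a, b = events[i], events[j]
                if _overlap(a, b) and not _strictly_nested(a, b):
                    raise ValidationError(
                        f"clone {clone_id!r}: partially overlapping CNAs "
                        f"{a.chromosome}:{a.start + 1}-{a.end} and "
                        f"{b.chromosome}:{b.start + 1}-{b.end} "
                        "(only strict nesting is allowed within a clone)"
                    )

    t = tumor_content
    segments: list[SegmentDosage] = []
    for chrom, rstart, rend in targets:
        cuts = {rstart, rend}
        for cna in cnas:
            if cna.chromosome != chrom:
                continue
            if cna.start > rstart and cna.start < rend:
                cuts.add(cna.start)
            if cna.end > rstart and cna.end < rend:
                cuts.add(cna.end)
        bounds = sorted(cuts)
        for seg_start, seg_end in zip(bounds, bounds[1:]):
            covering: dict[str, SomaticCNA] = {}
            for cna in cnas:
                if cna.chromosome != chrom:
                    continue
                if cna.start <= seg_start and seg_end <= cna.end:
                    prev = covering.get(cna.clone_id)
                    if prev is None or (cna.end - cna.start) < (prev.end - prev.start):
                        covering[cna.clone_id] = cna  # innermost wins
            total_clon = sum(clonality[c] for c in covering)
            if total_clon > 1.0 + 1e-9:
                raise ValidationError(
                    f"segment {chrom}:{seg_start + 1}-{seg_end}: summed clonality "
                    f"of overlapping clones {sorted(covering)} is {total_clon:.3f} > 1"
                )
            pops: list[Population] = []
            if t < 1.0:
                pops.append(Population(NORMAL, 1.0 - t, 1, 1))
            if t > 0.0:
                for clone_id, cna in sorted(covering.items()):
                    pops.append(
                        Population(
                            clone_id,
                            t * clonality[clone_id],
                            cna.copies_A,
                            cna.copies_B,
                        )
                    )
                rest = t * (1.0 - total_clon)
                if rest > 1e-12 or not covering:
                    pops.append(Population(BACKGROUND, max(rest, 0.0), 1, 1))
            segments.append(SegmentDosage(chrom, seg_start, seg_end, tuple(pops)))
    return segments


def segment_at(
    segments: list[SegmentDosage], chrom: str, pos: int
) -> SegmentDosage | None:
    for seg in segments:
        if seg.chromosome == chrom and seg.start <= pos < seg.end:
            return seg
    return None


def clone_copies_at(
    cnas: list[SomaticCNA], clone_id: str, chrom: str, pos: int
) -> tuple[int, int]:
    """Copies (A, B) of ``clone_id`` at a position: innermost covering CNA
    of that clone, or diploid (1,1) when none covers it."""
    best: SomaticCNA | None = None
    for cna in cnas:
        if cna.clone_id != clone_id or cna.chromosome != chrom:
            continue
        if cna.start <= pos < cna.end:
            if best is None or (cna.end - cna.start) < (best.end - best.start):
                best = cna
    if best is None:
        return (1, 1)
    return (best.copies_A, best.copies_B)


def validate_pms(
    pms: list[SomaticPM],
    segments: list[SegmentDosage],
    cnas: list[SomaticCNA],
    reference: pysam.FastaFile | None = None,
) -> list[SomaticPM]:
    """Check PM multiplicities against their own clone's local dosage.

    A PM is carried only by its clone's cells; its multiplicity may not
    exceed that clone's copies of the affected allele at the locus
    (diploid (1,1) when the clone has no CNA there). PMs falling outside
    the resolved target space are dropped with a warning, since no read
    can ever sample them. Clonality values must be consistent per clone
    across CNAs and PMs.
    """
    _clone_clonalities(cnas, pms)
    checked: list[SomaticPM] = []
    for pm in pms:
        seg = segment_at(segments, pm.chromosome, pm.position)
        if seg is None:
            log.warning(
                "PM %s:%d is off-target and will never be sampled; dropped",
                pm.chromosome,
                pm.position + 1,
            )
            continue
        copies = clone_copies_at(cnas, pm.clone_id, pm.chromosome, pm.position)
        allele_copies = copies[0] if pm.allele == "A" else copies[1]
        if pm.multiplicity > allele_copies:
            raise ValidationError(
                f"PM {pm.chromosome}:{pm.position + 1}: multiplicity "
                f"{pm.multiplicity} exceeds clone {pm.clone_id!r}'s "
                f"{allele_copies} copies of allele {pm.allele}"
            )
        if reference is not None:
            ref_base = reference.fetch(
                pm.chromosome, pm.position, pm.position + 1
            ).upper()
            if ref_base != pm.ref_base:
                raise ValidationError(
                    f"PM {pm.chromosome}:{pm.position + 1}: stated ref "
                    f"{pm.ref_base} does not match reference {ref_base}"
                )
        checked.append(pm)
    return checked


def check_snp_references(
    snps: list[PhasedSNP], reference: pysam.FastaFile
) -> None:
    """Raise if any SNP's stated ref base disagrees with the genome."""
    for snp in snps:
        ref_base = reference.fetch(
            snp.chromosome, snp.position, snp.position + 1
        ).upper()
        if ref_base != snp.ref_base:
            raise ValidationError(
                f"SNP {snp.chromosome}:{snp.position + 1}: stated ref "
                f"{snp.ref_base} does not match reference {ref_base}"
            )
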