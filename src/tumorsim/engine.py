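"""Read generation: from reference models + genome profile to FASTQ.

Each synthetic fragment is produced by the same per-fragment recipe:

1. sample a captured position from the read-depth model, with per-segment
   weights modulated by the segment's coverage factor (so copy-number
   dosage shapes relative coverage);
2. draw the originating cell population proportionally to cell fraction
   times total local copy number, then a uniform copy of the two
   haplotypes -- this makes the closed-form allelic-fraction expectations
   of :mod:`tumorsim.allele` exact by construction;
3. materialize the read sequence(s) from the reference, substituting
   phased SNP alleles carried by the drawn haplotype (paired-end fragments
   draw an insert size from the model's normal distribution, truncated to
   at least one read length by resampling);
4. inject base qualities and sequencing errors, first from the
   position-based error model at annotated genomic positions and then
   from the per-cycle quality model everywhere else;
5. for tumor samples, apply point mutations carried by the drawn
   population/copy (by default after the error step, so a mutation
   overwrites an error at its own position; ``pm_before_errors`` flips
   the order);
6. choose the fragment strand with probability ``strand_bias`` of being
   forward.

Determinism is worker-independent: fragments are processed in fixed-size
chunks and every chunk derives its own RNG stream from (seed, chunk
index), so the byte output depends only on inputs and seed.
"""

from __future__ import annotations

import bisect
import gzip
import json
import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pysam
from scipy.stats import norm

from tumorsim.allele import locus_expectation
from tumorsim.errors import GenerationError, ValidationError
from tumorsim.models import PositionErrorModel, QualityModel, ReadDepthModel
from tumorsim.profiles import (
    BACKGROUND,
    GenomeProfile,
    PhasedSNP,
    SamplePlan,
    SegmentDosage,
    SomaticPM,
    clone_copies_at,
    resolve_segments,
    validate_pms,
)

log = logging.getLogger(__name__)

#: Fragments are generated in fixed chunks of this many serials; chunk
#: boundaries never depend on the worker count, which is what makes the
#: output byte-identical across thread counts.
CHUNK_SIZE = 512

#: Bounded retries for degenerate draws (reads that are mostly N).
MAX_FRAGMENT_RETRIES = 10
MAX_INSERT_RETRIES = 100

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_PHRED_ERR = 10.0 ** (-np.arange(94) / 10.0)
_OTHER_BASES = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
_OTHER_BASES["N"] = list("ACGT")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FragmentDraw:
    """One sampled fragment: where it starts and which cells/copy it reads."""

    chromosome: str
    start: int
    insert_length: int  # == read_length for single-end
    population: str  # NORMAL, clone_id, or BACKGROUND
    haplotype: str  # "A" | "B"
    copy_index: int  # which copy of the haplotype (for PM multiplicity)
    strand: str  # "+" | "-"
    region_index: int
    segment_index: int


class FragmentSampler:
    """Precomputed sampling tables over the dosage-modulated RDM."""

    def __init__(
        self,
        rdm: ReadDepthModel,
        segments: list[SegmentDosage],
        plan: SamplePlan,
    ) -> None:
        self.rdm = rdm
        self.targets = rdm.targets
        self.segments = segments
        self.plan = plan
        flat_w = []
        flat_pos = []
        flat_region = []
        flat_seg = []
        seg_by_chrom: dict[str, list[tuple[int, SegmentDosage]]] = {}
        for i, seg in enumerate(segments):
            seg_by_chrom.setdefault(seg.chromosome, []).append((i, seg))
        for ri, (chrom, start, end) in enumerate(self.targets):
            w = np.asarray(rdm.weights[ri], dtype=float).copy()
            pos = np.arange(start, end, dtype=np.int64)
            seg_idx = np.full(end - start, -1, dtype=np.int64)
            factor = np.zeros(end - start, dtype=float)
            for si, seg in seg_by_chrom.get(chrom, []):
                lo, hi = max(seg.start, start), min(seg.end, end)
                if lo < hi:
                    seg_idx[lo - start : hi - start] = si
                    factor[lo - start : hi - start] = seg.coverage_factor
            if np.any(seg_idx < 0):
                raise GenerationError(
                    f"segments do not tile target {chrom}:{start}-{end}"
                )
            flat_w.append(w * factor)
            flat_pos.append(pos)
            flat_region.append(np.full(end - start, ri, dtype=np.int64))
            flat_seg.append(seg_idx)
        self.weights = np.concatenate(flat_w)
        self.positions = np.concatenate(flat_pos)
        self.region_idx = np.concatenate(flat_region)
        self.seg_idx = np.concatenate(flat_seg)
        total = self.weights.sum()
        if total <= 0:
            raise GenerationError(
                "all dosage-modulated sampling weights are zero"
            )
        self.probs = self.weights / total
        self.cum = np.cumsum(self.probs)
        self.cum[-1] = 1.0
        # per-segment population tables: P(pop) propto fraction * copies
        self._pop_cum: list[np.ndarray] = []
        self._pops: list[list] = []
        for seg in segments:
            raw = np.array(
                [p.fraction * p.total_copies for p in seg.populations], dtype=float
            )
            total_pop = raw.sum()
            if total_pop > 0:
                self._pop_cum.append(np.cumsum(raw / total_pop))
            else:
                self._pop_cum.append(raw)
            self._pops.append(list(seg.populations))

    def sample(self, rng: np.random.Generator) -> FragmentDraw:
        """Draw one fragment (position, population, haplotype copy, insert,
        strand) using ``rng``."""
        i = int(np.searchsorted(self.cum, rng.random(), side="right"))
        i = min(i, len(self.positions) - 1)
        seg_i = int(self.seg_idx[i])
        pops = self._pops[seg_i]
        cum = self._pop_cum[seg_i]
        if len(cum) == 0 or cum[-1] <= 0:
            raise GenerationError("sampled a segment with zero total copies")
        pi = int(np.searchsorted(cum, rng.random(), side="right"))
        pi = min(pi, len(pops) - 1)
        pop = pops[pi]
        k = int(rng.integers(pop.total_copies))
        if k < pop.copies_A:
            hap, copy_index = "A", k
        else:
            hap, copy_index = "B", k - pop.copies_A
        plan = self.plan
        if plan.paired:
            insert = self._draw_insert(rng)
        else:
            insert = plan.read_length
        strand = "+" if rng.random() < plan.strand_bias else "-"
        chrom = self.targets.regions[int(self.region_idx[i])][0]
        return FragmentDraw(
            chromosome=chrom,
            start=int(self.positions[i]),
            insert_length=insert,
            population=pop.label,
            haplotype=hap,
            copy_index=copy_index,
            strand=strand,
            region_index=int(self.region_idx[i]),
            segment_index=seg_i,
        )

    def _draw_insert(self, rng: np.random.Generator) -> int:
        mean, sd = self.rdm.insert_mean, self.rdm.insert_sd
        rl = self.plan.read_length
        if sd <= 0:
            return max(rl, int(round(mean)))
        for _ in range(MAX_INSERT_RETRIES):
            x = rng.normal(mean, sd)
            if x >= rl:
                return int(round(x))
        return rl  # pathological model (mean far below read length)


def sample_fragment(
    rdm: ReadDepthModel,
    segments: list[SegmentDosage],
    rng: np.random.Generator,
    plan: SamplePlan,
) -> FragmentDraw:
    """Convenience single draw; generation uses :class:`FragmentSampler`."""
    return FragmentSampler(rdm, segments, plan).sample(rng)


def insert_pmf(
    insert_mean: float, insert_sd: float, read_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Integer insert-length pmf implied by resampling-truncated rounding."""
    if insert_sd <= 0:
        return (np.array([max(read_length, int(round(insert_mean)))]), np.array([1.0]))
    lo = max(read_length, int(math.floor(insert_mean - 8 * insert_sd)))
    hi = int(math.ceil(insert_mean + 8 * insert_sd))
    vals = np.arange(lo, hi + 1)
    upper = norm.cdf(vals + 0.5, insert_mean, insert_sd)
    lower = norm.cdf(np.maximum(vals - 0.5, read_length), insert_mean, insert_sd)
    pmf = np.clip(upper - lower, 0.0, None)
    total = pmf.sum()
    if total <= 0:
        return (np.array([read_length]), np.array([1.0]))
    return vals, pmf / total


def expected_ontarget_bases(
    sampler: FragmentSampler, plan: SamplePlan
) -> float:
    """Expected on-target bases contributed by one fragment.

    Reads may overhang target boundaries into flanking sequence; those
    bases do not count toward on-target depth, so the read budget implied
    by a requested mean on-target coverage must divide by this expectation
    rather than by the raw read length.
    """
    targets = sampler.targets
    rl = plan.read_length
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in targets:
        by_chrom.setdefault(chrom, []).append((s, e))

    def ontarget(chrom: str, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        out = np.zeros_like(a, dtype=float)
        for s, e in by_chrom[chrom]:
            out += np.clip(np.minimum(b, e) - np.maximum(a, s), 0, None)
        return out

    expected = 0.0
    if plan.paired:
        ivals, ipmf = insert_pmf(sampler.rdm.insert_mean, sampler.rdm.insert_sd, rl)
    for ri, (chrom, s, e) in enumerate(targets):
        mask = sampler.region_idx == ri
        p = sampler.positions[mask]
        prob = sampler.probs[mask]
        if prob.sum() == 0:
            continue
        contrib = ontarget(chrom, p, p + rl)  # leftmost read
        if plan.paired:
            right = np.zeros_like(contrib)
            for ival, w in zip(ivals, ipmf):
                right += w * ontarget(chrom, p + ival - rl, p + ival)
            contrib = contrib + right
        expected += float((prob * contrib).sum())
    return expected


def reads_for_coverage(
    sampler: FragmentSampler, plan: SamplePlan
) -> int:
    """Fragment budget meeting a requested mean on-target coverage."""
    per_fragment = expected_ontarget_bases(sampler, plan)
    if per_fragment <= 0:
        raise GenerationError("expected on-target yield per fragment is zero")
    n = int(round(plan.target_mean_coverage * sampler.targets.total_length / per_fragment))
    return max(n, 1)


# ---------------------------------------------------------------------------
# per-chromosome lookup indexes


class _SiteIndex:
    """Sorted per-chromosome position index for SNPs / PMs / PBE sites."""

    def __init__(self, items: list[tuple[str, int, object]]) -> None:
        self._pos: dict[str, list[int]] = {}
        self._val: dict[str, list[object]] = {}
        for chrom, pos, val in sorted(items, key=lambda x: (x[0], x[1])):
            self._pos.setdefault(chrom, []).append(pos)
            self._val.setdefault(chrom, []).append(val)

    def in_span(self, chrom: str, start: int, end: int) -> list[tuple[int, object]]:
        pos = self._pos.get(chrom)
        if not pos:
            return []
        lo = bisect.bisect_left(pos, start)
        hi = bisect.bisect_left(pos, end)
        vals = self._val[chrom]
        return [(pos[i], vals[i]) for i in range(lo, hi)]


@dataclass
class _RefWindows:
    """In-memory reference slices covering each target region plus flanks."""

    windows: dict[int, tuple[int, str]]  # region index -> (window start, seq)
    chrom_lengths: dict[str, int]

    @classmethod
    def load(
        cls, fasta_path: str, sampler: FragmentSampler, plan: SamplePlan
    ) -> "_RefWindows":
        rdm = sampler.rdm
        flank = plan.read_length + 10
        if plan.paired:
            flank = max(
                flank,
                int(math.ceil(rdm.insert_mean + 10 * rdm.insert_sd)) + 10,
            )
        windows: dict[int, tuple[int, str]] = {}
        lengths: dict[str, int] = {}
        with pysam.FastaFile(fasta_path) as fasta:
            for name, length in zip(fasta.references, fasta.lengths):
                lengths[name] = length
            for ri, (chrom, s, e) in enumerate(sampler.targets):
                lo = max(0, s - 5)
                hi = min(lengths[chrom], e + flank)
                windows[ri] = (lo, fasta.fetch(chrom, lo, hi).upper())
        return cls(windows=windows, chrom_lengths=lengths)

    def fetch(self, region_index: int, chrom: str, start: int, end: int) -> str:
        wstart, seq = self.windows[region_index]
        lo, hi = start - wstart, end - wstart
        chunk = seq[max(lo, 0) : max(hi, 0)]
        # pad with N when a span escapes the loaded window / chromosome
        left_pad = max(0, -lo)
        right_pad = (end - start) - left_pad - len(chunk)
        return "N" * left_pad + chunk + "N" * max(0, right_pad)


# ---------------------------------------------------------------------------
# per-fragment assembly


@dataclass
class _ChunkStats:
    on_target_bases: float = 0.0
    forward_fragments: int = 0
    fragments: int = 0
    redraws: int = 0
    insert_sum: float = 0.0
    insert_sumsq: float = 0.0
    seg_fragments: np.ndarray | None = None
    seg_bases: np.ndarray | None = None
    snp_alt: dict = field(default_factory=dict)
    snp_depth: dict = field(default_factory=dict)
    pm_alt: dict = field(default_factory=dict)
    pm_depth: dict = field(default_factory=dict)

    def merge(self, other: "_ChunkStats") -> None:
        self.on_target_bases += other.on_target_bases
        self.forward_fragments += other.forward_fragments
        self.fragments += other.fragments
        self.redraws += other.redraws
        self.insert_sum += other.insert_sum
        self.insert_sumsq += other.insert_sumsq
        if other.seg_fragments is not None:
            if self.seg_fragments is None:
                self.seg_fragments = other.seg_fragments.copy()
                self.seg_bases = other.seg_bases.copy()
            else:
                self.seg_fragments += other.seg_fragments
                self.seg_bases += other.seg_bases
        for src, dst in (
            (other.snp_alt, self.snp_alt),
            (other.snp_depth, self.snp_depth),
            (other.pm_alt, self.pm_alt),
            (other.pm_depth, self.pm_depth),
        ):
            for key, val in src.items():
                dst[key] = dst.get(key, 0) + val


class _Generator:
    """Holds everything shared across chunks for one sample run."""

    def __init__(
        self,
        rdm: ReadDepthModel,
        qm: QualityModel,
        pbe: PositionErrorModel,
        profile: GenomeProfile,
        plan: SamplePlan,
        segments: list[SegmentDosage],
        reference_path: str,
        pm_before_errors: bool = False,
    ) -> None:
        self.plan = plan
        self.qm_cdf = qm.cdf()
        if plan.read_length > qm.max_read_length:
            # extend by repeating the last informative cycle
            extra = plan.read_length - qm.max_read_length
            last = self.qm_cdf[-1:]
            self.qm_cdf = np.vstack([self.qm_cdf, np.repeat(last, extra, axis=0)])
        self.qm_cdf = self.qm_cdf[: plan.read_length]
        self.sampler = FragmentSampler(rdm, segments, plan)
        self.segments = segments
        self.refs = _RefWindows.load(reference_path, self.sampler, plan)
        self.pm_before_errors = pm_before_errors
        self.tumor = plan.sample_kind == "tumor" and plan.tumor_content > 0
        self.snps = _SiteIndex([(s.chromosome, s.position, s) for s in profile.snps])
        pms = profile.pms if plan.sample_kind == "tumor" else []
        self.pms = _SiteIndex([(p.chromosome, p.position, p) for p in pms])
        self.pbe = _SiteIndex(
            [
                (chrom, pos, (rate, list(prof.keys()), np.array(list(prof.values()))))
                for (chrom, pos), (rate, prof) in pbe.sites.items()
            ]
        )
        self.targets = rdm.targets
        self.seg_bounds: dict[str, list[tuple[int, int, int]]] = {}
        for i, seg in enumerate(segments):
            self.seg_bounds.setdefault(seg.chromosome, []).append(
                (seg.start, seg.end, i)
            )

    # -- fragment-level carriage ------------------------------------------

    def _pm_carried(
        self,
        pm: SomaticPM,
        draw: FragmentDraw,
        rng: np.random.Generator,
    ) -> bool:
        if not self.tumor or draw.haplotype != pm.allele:
            return False
        seg = self.segments[draw.segment_index]
        listed = seg.population(pm.clone_id) is not None
        if listed:
            return draw.population == pm.clone_id and draw.copy_index < pm.multiplicity
        # clone has no CNA here: its cells live inside the diploid background
        if draw.population != BACKGROUND or draw.copy_index >= pm.multiplicity:
            return False
        bg = seg.population(BACKGROUND)
        if bg is None or bg.fraction <= 0:
            return False
        p = self.plan.tumor_content * pm.clonality / bg.fraction
        return rng.random() < min(p, 1.0)

    # -- one read end ------------------------------------------------------

    def _make_end(
        self,
        draw: FragmentDraw,
        span: tuple[int, int],
        is_reverse: bool,
        carried_pms: dict[int, SomaticPM],
        rng: np.random.Generator,
        stats: _ChunkStats,
    ) -> tuple[str, str] | None:
        start, end = span
        chrom = draw.chromosome
        rl = self.plan.read_length
        refseq = self.refs.fetch(draw.region_index, chrom, start, end)
        if refseq.count("N") * 2 > rl:
            return None
        bases = list(refseq)
        # (iv) phased germline SNPs on the drawn haplotype
        snp_hits = self.snps.in_span(chrom, start, end)
        for pos, snp in snp_hits:
            if snp.phase == draw.haplotype:
                bases[pos - start] = snp.alt_base

        def apply_pms() -> None:
            for pos, pm in carried_pms.items():
                if start <= pos < end:
                    bases[pos - start] = pm.alt_base

        if self.pm_before_errors:
            apply_pms()
        # (v) qualities and errors: PBE first, QM elsewhere
        quals = _sample_qualities(self.qm_cdf, rng)
        pbe_cycles: set[int] = set()
        for pos, (rate, alt_bases, alt_probs) in self.pbe.in_span(chrom, start, end):
            cycle = (pos - start) if not is_reverse else (end - 1 - pos)
            pbe_cycles.add(cycle)
            if rng.random() < rate:
                j = int(np.searchsorted(np.cumsum(alt_probs), rng.random()))
                bases[pos - start] = alt_bases[min(j, len(alt_bases) - 1)]
        err_p = _PHRED_ERR[quals]
        err_mask = rng.random(rl) < err_p
        for cycle in np.nonzero(err_mask)[0]:
            if int(cycle) in pbe_cycles:
                continue
            gi = (int(cycle)) if not is_reverse else (end - start - 1 - int(cycle))
            cur = bases[gi]
            others = _OTHER_BASES.get(cur, _OTHER_BASES["N"])
            bases[gi] = others[int(rng.integers(len(others)))]
        # (vi) somatic point mutations (default: after errors)
        if not self.pm_before_errors:
            apply_pms()
        # observed-event tallies, in genomic space, after everything
        for pos, snp in snp_hits:
            key = (chrom, pos)
            stats.snp_depth[key] = stats.snp_depth.get(key, 0) + 1
            if bases[pos - start] == snp.alt_base:
                stats.snp_alt[key] = stats.snp_alt.get(key, 0) + 1
        for pos, pm in self.pms.in_span(chrom, start, end):
            key = (chrom, pos)
            stats.pm_depth[key] = stats.pm_depth.get(key, 0) + 1
            if bases[pos - start] == pm.alt_base:
                stats.pm_alt[key] = stats.pm_alt.get(key, 0) + 1
        # coverage accounting
        for lo, hi in self.targets.intersect(chrom, start, end):
            stats.on_target_bases += hi - lo
        for seg_start, seg_end, si in self.seg_bounds.get(chrom, []):
            ov = min(end, seg_end) - max(start, seg_start)
            if ov > 0:
                stats.seg_bases[si] += ov
        seq = "".join(bases)
        qual = "".join(chr(q + 33) for q in quals)
        if is_reverse:
            seq = _revcomp(seq)
        return seq, qual

    # -- one fragment ------------------------------------------------------

    def make_fragment(
        self, serial: int, rng: np.random.Generator, stats: _ChunkStats
    ) -> tuple[str, str | None]:
        plan = self.plan
        rl = plan.read_length
        for attempt in range(MAX_FRAGMENT_RETRIES):
            draw = self.sampler.sample(rng)
            chrom, p, insert = draw.chromosome, draw.start, draw.insert_length
            left = (p, p + rl)
            right = (p + insert - rl, p + insert) if plan.paired else None
            carried: dict[int, SomaticPM] = {}
            span_end = right[1] if right else left[1]
            for pos, pm in self.pms.in_span(chrom, left[0], span_end):
                if self._pm_carried(pm, draw, rng):
                    carried[pos] = pm
            # tallies go to a scratch accumulator, committed only if the
            # whole fragment succeeds (a redraw must not double-count)
            local = _ChunkStats(
                seg_fragments=np.zeros(len(self.segments), dtype=np.int64),
                seg_bases=np.zeros(len(self.segments), dtype=np.float64),
            )
            end1 = self._make_end(draw, left, False, carried, rng, local)
            end2 = (
                self._make_end(draw, right, True, carried, rng, local)
                if plan.paired
                else None
            )
            if end1 is None or (plan.paired and end2 is None):
                stats.redraws += 1
                continue
            break
        else:
            raise GenerationError(
                f"fragment {serial}: no usable sequence after "
                f"{MAX_FRAGMENT_RETRIES} redraws"
            )
        stats.merge(local)
        stats.fragments += 1
        stats.seg_fragments[draw.segment_index] += 1
        if draw.strand == "+":
            stats.forward_fragments += 1
        if plan.paired:
            stats.insert_sum += insert
            stats.insert_sumsq += insert * insert
        name = f"{plan.sample_name}:{serial}:{chrom}:{p}:{insert}:{draw.strand}"
        if not plan.paired:
            seq, qual = end1
            if draw.strand == "-":
                seq, qual = _revcomp(seq), qual[::-1]
            return f"@{name}\n{seq}\n+\n{qual}\n", None
        # mate roles swap with strand; orientations stay (left fwd, right rev)
        (seq_l, qual_l), (seq_r, qual_r) = end1, end2
        if draw.strand == "+":
            r1 = f"@{name}/1\n{seq_l}\n+\n{qual_l}\n"
            r2 = f"@{name}/2\n{seq_r}\n+\n{qual_r}\n"
        else:
            r1 = f"@{name}/1\n{seq_r}\n+\n{qual_r}\n"
            r2 = f"@{name}/2\n{seq_l}\n+\n{qual_l}\n"
        return r1, r2

    def run_chunk(
        self, chunk_index: int, lo: int, hi: int
    ) -> tuple[str, str, _ChunkStats]:
        rng = np.random.default_rng([self.plan.seed, chunk_index])
        stats = _ChunkStats(
            seg_fragments=np.zeros(len(self.segments), dtype=np.int64),
            seg_bases=np.zeros(len(self.segments), dtype=np.float64),
        )
        r1_parts: list[str] = []
        r2_parts: list[str] = []
        for serial in range(lo, hi):
            r1, r2 = self.make_fragment(serial, rng, stats)
            r1_parts.append(r1)
            if r2 is not None:
                r2_parts.append(r2)
        return "".join(r1_parts), "".join(r2_parts), stats


def _sample_qualities(qm_cdf: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(qm_cdf.shape[0])
    return (u[:, None] > qm_cdf).sum(axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# top-level generation


def _open_out(path: str):
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def generate_sample(
    models: tuple[ReadDepthModel, QualityModel, PositionErrorModel],
    profile: GenomeProfile,
    plan: SamplePlan,
    reference: str,
    out_prefix: str,
    workers: int = 1,
    pm_before_errors: bool = False,
    gzip_output: bool = False,
) -> dict:
    """Generate one FASTQ sample (tumor or matched control); return a report.

    Matched controls ignore all somatic events and run at tumor content 0.
    Output goes to ``<prefix>.fastq`` (single-end) or ``<prefix>_R1.fastq``
    / ``<prefix>_R2.fastq`` (paired), with ``.gz`` appended when
    ``gzip_output`` is set. The report includes per-segment fragment
    counts and mean depths plus per-event observed and expected allelic
    fractions.
    """
    rdm, qm, pbe = models
    if plan.sample_kind == "matched_control":
        profile = profile.germline_only()
        plan_t = 0.0
    else:
        plan_t = plan.tumor_content
    eff_plan = SamplePlan(
        sample_name=plan.sample_name,
        sample_kind=plan.sample_kind,
        tumor_content=plan_t,
        target_mean_coverage=plan.target_mean_coverage,
        n_reads=plan.n_reads,
        read_length=plan.read_length,
        paired=plan.paired,
        strand_bias=plan.strand_bias,
        seed=plan.seed,
    )
    if eff_plan.paired and rdm.insert_mean <= 0:
        raise ValidationError(
            "paired-end generation requires insert statistics in the RDM"
        )
    segments = resolve_segments(profile.cnas, rdm.targets, plan_t)
    with pysam.FastaFile(reference) as fasta:
        pms = validate_pms(profile.pms, segments, profile.cnas, reference=fasta)
    profile = GenomeProfile(snps=profile.snps, cnas=profile.cnas, pms=pms)
    gen = _Generator(
        rdm, qm, pbe, profile, eff_plan, segments, reference, pm_before_errors
    )
    if eff_plan.n_reads is not None:
        n_fragments = eff_plan.n_reads
    else:
        n_fragments = reads_for_coverage(gen.sampler, eff_plan)
    n_chunks = (n_fragments + CHUNK_SIZE - 1) // CHUNK_SIZE
    chunks = [
        (ci, ci * CHUNK_SIZE, min((ci + 1) * CHUNK_SIZE, n_fragments))
        for ci in range(n_chunks)
    ]
    if workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(lambda c: gen.run_chunk(*c), chunks))
    else:
        results = [gen.run_chunk(*c) for c in chunks]
    stats = _ChunkStats(
        seg_fragments=np.zeros(len(segments), dtype=np.int64),
        seg_bases=np.zeros(len(segments), dtype=np.float64),
    )
    suffix = ".gz" if gzip_output else ""
    if eff_plan.paired:
        paths = [f"{out_prefix}_R1.fastq{suffix}", f"{out_prefix}_R2.fastq{suffix}"]
        with _open_out(paths[0]) as f1, _open_out(paths[1]) as f2:
            for r1_text, r2_text, chunk_stats in results:
                f1.write(r1_text)
                f2.write(r2_text)
                stats.merge(chunk_stats)
    else:
        paths = [f"{out_prefix}.fastq{suffix}"]
        with _open_out(paths[0]) as f1:
            for r1_text, _, chunk_stats in results:
                f1.write(r1_text)
                stats.merge(chunk_stats)
    report = _build_report(gen, profile, eff_plan, segments, stats, n_fragments, paths)
    with open(f"{out_prefix}.report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def _build_report(
    gen: _Generator,
    profile: GenomeProfile,
    plan: SamplePlan,
    segments: list[SegmentDosage],
    stats: _ChunkStats,
    n_fragments: int,
    paths: list[str],
) -> dict:
    total_len = gen.targets.total_length
    realized_cov = stats.on_target_bases / total_len if total_len else 0.0
    n = stats.fragments
    insert_mean = stats.insert_sum / n if (plan.paired and n) else None
    insert_sd = None
    if plan.paired and n > 1:
        var = (stats.insert_sumsq - stats.insert_sum**2 / n) / (n - 1)
        insert_sd = math.sqrt(max(var, 0.0))
    seg_rows = []
    for i, seg in enumerate(segments):
        seg_rows.append(
            {
                "chromosome": seg.chromosome,
                "start": seg.start,
                "end": seg.end,
                "coverage_factor": seg.coverage_factor,
                "expected_log2": (
                    math.log2(seg.coverage_factor) if seg.coverage_factor > 0 else None
                ),
                "n_fragments": int(stats.seg_fragments[i]),
                "mean_depth": float(stats.seg_bases[i]) / (seg.end - seg.start),
            }
        )
    snp_rows = []
    for snp in profile.snps:
        key = (snp.chromosome, snp.position)
        depth = stats.snp_depth.get(key, 0)
        alt = stats.snp_alt.get(key, 0)
        seg = _find_segment(segments, snp.chromosome, snp.position)
        expected = None
        if seg is not None and seg.effective_A + seg.effective_B > 0:
            expected = locus_expectation(seg, snp=snp).expected_baf_alt
        snp_rows.append(
            {
                "chromosome": snp.chromosome,
                "position": snp.position + 1,
                "phase": snp.phase,
                "depth": depth,
                "alt_count": alt,
                "observed_baf_alt": alt / depth if depth else None,
                "expected_baf_alt": expected,
            }
        )
    pm_rows = []
    for pm in profile.pms:
        key = (pm.chromosome, pm.position)
        depth = stats.pm_depth.get(key, 0)
        alt = stats.pm_alt.get(key, 0)
        seg = _find_segment(segments, pm.chromosome, pm.position)
        expected = None
        if plan.sample_kind == "tumor" and seg is not None:
            expected = locus_expectation(
                seg, pm=pm, tumor_content=plan.tumor_content
            ).expected_vaf
        pm_rows.append(
            {
                "chromosome": pm.chromosome,
                "position": pm.position + 1,
                "clone_id": pm.clone_id,
                "depth": depth,
                "alt_count": alt,
                "observed_vaf": alt / depth if depth else None,
                "expected_vaf": expected,
            }
        )
    return {
        "sample": plan.sample_name,
        "sample_kind": plan.sample_kind,
        "tumor_content": plan.tumor_content,
        "seed": plan.seed,
        "n_fragments": n_fragments,
        "read_length": plan.read_length,
        "paired": plan.paired,
        "requested_coverage": plan.target_mean_coverage,
        "realized_on_target_coverage": realized_cov,
        "forward_fraction": stats.forward_fragments / n if n else None,
        "insert_mean_realized": insert_mean,
        "insert_sd_realized": insert_sd,
        "redraws": stats.redraws,
        "outputs": paths,
        "segments": seg_rows,
        "snps": snp_rows,
        "pms": pm_rows,
    }


def _find_segment(
    segments: list[SegmentDosage], chrom: str, pos: int
) -> SegmentDosage | None:
    for seg in segments:
        if seg.chromosome == chrom and seg.start <= pos < seg.end:
            return seg
    return None
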