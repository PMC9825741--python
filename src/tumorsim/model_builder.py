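"""Build reference models from control alignments over a capture panel.

All three builders share the same pileup hygiene: secondary, supplementary,
duplicate-flagged and unmapped records are skipped. Counting is cumulative
across input files, so models built from several control samples pool their
evidence position by position.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pysam

from tumorsim.errors import InputError, ModelError
from tumorsim.models import (
    BASES,
    MAX_PHRED,
    PositionErrorModel,
    QualityModel,
    ReadDepthModel,
)
from tumorsim.regions import TargetRegions

log = logging.getLogger(__name__)

#: Proper-pair template lengths above this are treated as chimeric and dropped.
MAX_TEMPLATE_LENGTH = 2000


def _usable(read: pysam.AlignedSegment) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
    )


def _open_bam(path: str) -> pysam.AlignmentFile:
    try:
        bam = pysam.AlignmentFile(path, "rb")
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot open alignment file {path!r}: {exc}") from exc
    if not bam.has_index():
        bam.close()
        raise InputError(f"alignment file {path!r} is not indexed (missing .bai)")
    return bam


def _fragment_leftmost(read: pysam.AlignedSegment) -> bool:
    """True if this record represents its fragment's leftmost coordinate.

    For paired data only the mate aligning at the lower coordinate counts,
    so each fragment contributes exactly once; ties broken by read1.
    Single-end reads and reads with an unmapped mate always count.
    """
    if not read.is_paired or read.mate_is_unmapped:
        return True
    if read.reference_id != read.next_reference_id:
        return read.reference_start <= read.next_reference_start
    if read.reference_start != read.next_reference_start:
        return read.reference_start < read.next_reference_start
    return read.is_read1


def build_rdm(
    bams: list[str], targets: TargetRegions, paired: bool = True
) -> ReadDepthModel:
    """Count fragment leftmost starts per captured position across all files.

    The weight at position p is the total number of fragments whose leftmost
    aligned coordinate is p; only starts inside target regions accumulate.
    Insert statistics are the sample mean/sd of absolute template lengths of
    proper pairs whose leftmost mate starts on target.
    """
    if not bams:
        raise InputError("at least one alignment file is required")
    weights = [np.zeros(e - s, dtype=float) for _, s, e in targets]
    inserts: list[int] = []
    read_length_observed = 0
    for path in bams:
        used = skipped = 0
        with _open_bam(path) as bam:
            for i, (chrom, start, end) in enumerate(targets):
                for read in bam.fetch(chrom, start, end):
                    if not _usable(read):
                        skipped += 1
                        continue
                    pos = read.reference_start
                    if not (start <= pos < end):
                        continue  # overlaps region but starts elsewhere
                    if not _fragment_leftmost(read):
                        continue
                    weights[i][pos - start] += 1
                    used += 1
                    if read.query_length:
                        read_length_observed = max(
                            read_length_observed, read.query_length
                        )
                    if paired and read.is_proper_pair:
                        tlen = abs(read.template_length)
                        if 0 < tlen <= MAX_TEMPLATE_LENGTH:
                            inserts.append(tlen)
        log.info("RDM %s: %d fragments used, %d records skipped", path, used, skipped)
    total = sum(float(w.sum()) for w in weights)
    if total == 0:
        raise ModelError("empty RDM: no on-target fragment starts in any input")
    insert_mean = float(np.mean(inserts)) if inserts else 0.0
    insert_sd = float(np.std(inserts, ddof=1)) if len(inserts) > 1 else 0.0
    return ReadDepthModel(
        targets=targets,
        weights=weights,
        insert_mean=insert_mean if paired else 0.0,
        insert_sd=insert_sd if paired else 0.0,
        paired=paired,
        read_length_observed=read_length_observed,
        n_source_samples=len(bams),
    )


def build_qm(bams: list[str], targets: TargetRegions) -> QualityModel:
    """Per-cycle base-quality histograms over all on-target alignments.

    Cycle means position within the read in original sequencing orientation:
    reverse-strand alignments are un-reversed before tallying, so cycle 0
    always holds the first sequenced base.
    """
    if not bams:
        raise InputError("at least one alignment file is required")
    counts = np.zeros((0, MAX_PHRED + 1), dtype=float)
    for path in bams:
        with _open_bam(path) as bam:
            for chrom, start, end in targets:
                for read in bam.fetch(chrom, start, end):
                    if not _usable(read) or read.query_qualities is None:
                        continue
                    quals = np.asarray(read.query_qualities, dtype=np.int64)
                    if read.is_reverse:
                        quals = quals[::-1]
                    if len(quals) > counts.shape[0]:
                        grown = np.zeros((len(quals), MAX_PHRED + 1), dtype=float)
                        grown[: counts.shape[0]] = counts
                        counts = grown
                    np.add.at(counts, (np.arange(len(quals)), quals), 1.0)
    if counts.shape[0] == 0:
        raise ModelError("empty QM: no on-target reads with base qualities")
    sums = counts.sum(axis=1, keepdims=True)
    hist = np.divide(counts, sums, out=np.zeros_like(counts), where=sums > 0)
    return QualityModel(cycle_hist=hist)


def build_pbe(
    bams: list[str],
    targets: TargetRegions,
    reference: str,
    snp_mask: set[tuple[str, int]] | None = None,
    hq_base_quality_min: int = 20,
    hq_mapping_quality_min: int = 20,
    min_depth: int = 50,
    min_error_rate: float = 0.005,
) -> PositionErrorModel:
    """Detect per-position systematic errors supported by high-quality evidence.

    For each on-target position not in ``snp_mask``, bases with quality >=
    ``hq_base_quality_min`` from reads with mapping quality >=
    ``hq_mapping_quality_min`` are pooled across all files; the position is
    stored when high-quality depth reaches ``min_depth`` and the
    non-reference fraction reaches ``min_error_rate``.
    """
    if not bams:
        raise InputError("at least one alignment file is required")
    snp_mask = snp_mask or set()
    fasta = pysam.FastaFile(reference)
    ref_names = set(fasta.references)
    missing = [c for c in targets.chromosomes if c not in ref_names]
    if missing:
        fasta.close()
        raise InputError(f"reference lacks target chromosomes: {missing}")

    def keep(read: pysam.AlignedSegment) -> bool:
        return _usable(read) and read.mapping_quality >= hq_mapping_quality_min

    sites: dict[tuple[str, int], tuple[float, dict[str, float]]] = {}
    try:
        for chrom, start, end in targets:
            refseq = fasta.fetch(chrom, start, end).upper()
            acgt = np.zeros((4, end - start), dtype=np.int64)
            for path in bams:
                with _open_bam(path) as bam:
                    cov = bam.count_coverage(
                        chrom,
                        start,
                        end,
                        quality_threshold=hq_base_quality_min,
                        read_callback=keep,
                    )
                    acgt += np.asarray(cov, dtype=np.int64)
            depth = acgt.sum(axis=0)
            for off in np.nonzero(depth >= min_depth)[0]:
                pos = start + int(off)
                if (chrom, pos) in snp_mask:
                    continue
                ref_base = refseq[off]
                if ref_base not in BASES:
                    continue
                column = acgt[:, off]
                ref_i = BASES.index(ref_base)
                nonref = int(depth[off] - column[ref_i])
                if nonref == 0:
                    continue
                rate = nonref / int(depth[off])
                if rate < min_error_rate:
                    continue
                profile = {
                    BASES[i]: int(column[i]) / nonref
                    for i in range(4)
                    if i != ref_i and column[i] > 0
                }
                sites[(chrom, pos)] = (rate, profile)
    finally:
        fasta.close()
    return PositionErrorModel(
        sites=sites,
        hq_base_quality_min=hq_base_quality_min,
        hq_mapping_quality_min=hq_mapping_quality_min,
        min_depth=min_depth,
    )
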