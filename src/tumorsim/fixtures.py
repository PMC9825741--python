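"""Synthetic input fabrication: toy genomes, panels, truth BAMs, models.

Everything the pipeline consumes can be generated here deterministically
from a small :class:`FixtureSpec`, with sidecar truth (exact per-position
fragment-start counts, injected error rates) kept alongside so model
builders can be checked against known answers. Fixture BAMs are written
with minimal valid headers and proper-pair flags so standard toolchains
(samtools, pysam) accept them unmodified.
"""

from __future__ import annotations

import json
import textwrap
from dataclasses import dataclass, field

import numpy as np
import pysam

from tumorsim.errors import ValidationError
from tumorsim.models import (
    MAX_PHRED,
    PositionErrorModel,
    QualityModel,
    ReadDepthModel,
)
from tumorsim.regions import TargetRegions


@dataclass
class FixtureSpec:
    """Parameters of a fabricated dataset.

    ``error_positions`` lists injected systematic errors as
    ``(chromosome, position, rate, alt_base)`` with 0-based positions.
    """

    n_chromosomes: int = 1
    chromosome_length: int = 20_000
    n_targets: int = 4
    target_length: int = 500
    depth_profile: str = "uniform"  # "uniform" | "peaked"
    quality_profile: str = "constant"  # "constant" | "ramp"
    constant_quality: int = 30
    ramp_start: int = 38
    ramp_end: int = 20
    error_positions: list[tuple[str, int, float, str]] = field(default_factory=list)
    insert_mean: float = 300.0
    insert_sd: float = 0.0
    read_length: int = 100
    fragments_per_target: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_profile not in ("uniform", "peaked"):
            raise ValidationError("depth_profile must be uniform or peaked")
        if self.quality_profile not in ("constant", "ramp"):
            raise ValidationError("quality_profile must be constant or ramp")
        for chrom, pos, rate, alt in self.error_positions:
            if not (0.0 < rate <= 1.0):
                raise ValidationError(f"error rate at {chrom}:{pos} not in (0,1]")
            if alt not in "ACGT":
                raise ValidationError(f"alt base at {chrom}:{pos} must be A/C/G/T")
        span = self.n_targets_per_chromosome * (self.target_length + 1)
        flank = int(self.insert_mean + 10 * self.insert_sd) + self.read_length
        if span + 2 * flank > self.chromosome_length:
            raise ValidationError("targets plus flanks do not fit the chromosome")

    @property
    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def n_targets_per_chromosome(self) -> int:
        return -(-self.n_targets // self.n_chromosomes)  # ceil


def make_reference(spec: FixtureSpec, fasta_path: str) -> str:
    """Write a deterministic pseudo-random reference FASTA (+ .fai index)."""
    rng = np.random.default_rng([spec.seed, 1])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    with open(fasta_path, "w") as fh:
        for name in spec.chromosome_names:
            seq = rng.choice(bases, size=spec.chromosome_length).tobytes().decode()
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, 60)))
            fh.write("\n")
    pysam.faidx(fasta_path)
    return fasta_path


def make_targets(spec: FixtureSpec) -> TargetRegions:
    """Evenly spaced capture targets, kept clear of chromosome ends."""
    flank = int(spec.insert_mean + 10 * spec.insert_sd) + spec.read_length
    per_chrom = spec.n_targets_per_chromosome
    regions = []
    placed = 0
    for name in spec.chromosome_names:
        usable = spec.chromosome_length - 2 * flank
        gap = (usable - per_chrom * spec.target_length) // (per_chrom + 1)
        pos = flank + gap
        for _ in range(per_chrom):
            if placed >= spec.n_targets:
                break
            regions.append((name, pos, pos + spec.target_length))
            pos += spec.target_length + gap
            placed += 1
    return TargetRegions(tuple(regions))


def _start_weights(spec: FixtureSpec, length: int) -> np.ndarray:
    if spec.depth_profile == "uniform":
        return np.ones(length, dtype=float)
    # symmetric triangular peak over the target
    x = np.arange(length, dtype=float)
    return 1.0 + 4.0 * (1.0 - np.abs(x - (length - 1) / 2) / ((length - 1) / 2))


def _cycle_qualities(spec: FixtureSpec) -> np.ndarray:
    if spec.quality_profile == "constant":
        return np.full(spec.read_length, spec.constant_quality, dtype=np.int64)
    return np.round(
        np.linspace(spec.ramp_start, spec.ramp_end, spec.read_length)
    ).astype(np.int64)


@dataclass
class TruthBundle:
    """Exact ground truth recorded while writing a fixture BAM."""

    start_counts: list[np.ndarray]  # per target region
    inserts: list[int]
    cycle_qualities: np.ndarray
    error_positions: list[tuple[str, int, float, str]]

    def save(self, path: str) -> None:
        payload = {
            "start_counts": [c.tolist() for c in self.start_counts],
            "inserts": self.inserts,
            "cycle_qualities": self.cycle_qualities.tolist(),
            "error_positions": [list(e) for e in self.error_positions],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def make_truth_bam(
    spec: FixtureSpec,
    fasta_path: str,
    targets: TargetRegions,
    bam_path: str,
) -> TruthBundle:
    """Write a coordinate-sorted, indexed paired-end BAM with known truth.

    Fragment leftmost starts are drawn from the spec's depth profile and
    recorded exactly; base qualities follow the spec's cycle profile;
    sequences match the reference except at injected error positions,
    where the alternate base appears at the stated rate.
    """
    rng = np.random.default_rng([spec.seed, 2])
    fasta = pysam.FastaFile(fasta_path)
    read_len = spec.read_length
    insert = max(int(round(spec.insert_mean)), read_len)
    quals = _cycle_qualities(spec)
    err_by_chrom: dict[str, list[tuple[int, float, str]]] = {}
    for chrom, pos, rate, alt in spec.error_positions:
        err_by_chrom.setdefault(chrom, []).append((pos, rate, alt))

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": fasta.get_reference_length(name)}
            for name in fasta.references
        ],
    }
    tid = {name: i for i, name in enumerate(fasta.references)}

    start_counts = []
    inserts: list[int] = []
    records = []
    serial = 0
    for ri, (chrom, rstart, rend) in enumerate(targets):
        length = rend - rstart
        w = _start_weights(spec, length)
        starts = rng.choice(length, size=spec.fragments_per_target, p=w / w.sum())
        counts = np.bincount(starts, minlength=length).astype(np.int64)
        start_counts.append(counts)
        chrom_errs = err_by_chrom.get(chrom, [])
        for off in np.sort(starts):
            p = rstart + int(off)
            seqs = []
            for s in (p, p + insert - read_len):
                base_list = list(fasta.fetch(chrom, s, s + read_len).upper())
                for epos, rate, alt in chrom_errs:
                    if s <= epos < s + read_len and rng.random() < rate:
                        base_list[epos - s] = alt
                seqs.append("".join(base_list))
            inserts.append(insert)
            for mate, (s, flag) in enumerate([(p, 99), (p + insert - read_len, 147)]):
                a = pysam.AlignedSegment()
                a.query_name = f"frag{serial}"
                a.query_sequence = seqs[mate]
                a.flag = flag
                a.reference_id = tid[chrom]
                a.reference_start = s
                a.mapping_quality = 60
                a.cigarstring = f"{read_len}M"
                a.next_reference_id = tid[chrom]
                a.next_reference_start = (p + insert - read_len) if mate == 0 else p
                a.template_length = insert if mate == 0 else -insert
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(int(q) + 33) for q in (quals if mate == 0 else quals[::-1]))
                )
                records.append(a)
            serial += 1
    fasta.close()
    unsorted = bam_path + ".unsorted.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for a in records:
            bam.write(a)
    pysam.sort("-o", bam_path, unsorted)
    pysam.index(bam_path)
    import os

    os.remove(unsorted)
    return TruthBundle(
        start_counts=start_counts,
        inserts=inserts,
        cycle_qualities=quals,
        error_positions=list(spec.error_positions),
    )


def make_models_direct(
    spec: FixtureSpec, targets: TargetRegions
) -> tuple[ReadDepthModel, QualityModel, PositionErrorModel]:
    """Construct the three reference models analytically from the spec.

    Bypasses BAM construction entirely; used to exercise the read engine
    in isolation and as the closure check against models built from
    :func:`make_truth_bam` output.
    """
    weights = [
        _start_weights(spec, e - s) for _, s, e in targets
    ]
    rdm = ReadDepthModel(
        targets=targets,
        weights=weights,
        insert_mean=max(float(round(spec.insert_mean)), float(spec.read_length)),
        insert_sd=float(spec.insert_sd),
        paired=True,
        read_length_observed=spec.read_length,
        n_source_samples=1,
    )
    hist = np.zeros((spec.read_length, MAX_PHRED + 1), dtype=float)
    for cycle, q in enumerate(_cycle_qualities(spec)):
        hist[cycle, int(q)] = 1.0
    qm = QualityModel(cycle_hist=hist)
    sites = {
        (chrom, pos): (rate, {alt: 1.0})
        for chrom, pos, rate, alt in spec.error_positions
    }
    pbe = PositionErrorModel(sites=sites)
    return rdm, qm, pbe
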