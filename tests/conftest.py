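"""Shared fixtures: a small fabricated panel with reference, BAM and models."""

import os

import pysam
import pytest

from tumorsim.fixtures import (
    FixtureSpec,
    make_models_direct,
    make_reference,
    make_targets,
    make_truth_bam,
)

_FLIP = {"A": "C", "C": "G", "G": "T", "T": "A"}


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(
        n_chromosomes=2,
        chromosome_length=20_000,
        n_targets=4,
        target_length=500,
        depth_profile="uniform",
        quality_profile="constant",
        constant_quality=30,
        insert_mean=300.0,
        insert_sd=20.0,
        read_length=100,
        fragments_per_target=400,
        error_positions=[],
        seed=12,
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("panel")


@pytest.fixture(scope="session")
def reference(fixture_spec, fixture_dir):
    return make_reference(fixture_spec, str(fixture_dir / "reference.fa"))


@pytest.fixture(scope="session")
def targets(fixture_spec, reference):
    return make_targets(fixture_spec)


@pytest.fixture(scope="session")
def truth_and_bam(fixture_spec, reference, targets, fixture_dir):
    bam = str(fixture_dir / "control.bam")
    truth = make_truth_bam(fixture_spec, reference, targets, bam)
    return truth, bam


@pytest.fixture(scope="session")
def direct_models(fixture_spec, targets):
    return make_models_direct(fixture_spec, targets)


@pytest.fixture()
def fasta(reference):
    fa = pysam.FastaFile(reference)
    yield fa
    fa.close()


def flip_base(base: str) -> str:
    """A deterministic alternate base different from ``base``."""
    return _FLIP[base]


def write_tiny_bam(path, header_lengths, records):
    """Write and index a coordinate-sorted BAM from (already sorted) records.

    ``records`` are dicts with keys name, flag, chrom, pos, mapq, cigar,
    seq, qual (list of ints), and optional mate fields.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in header_lengths],
    }
    tid = {name: i for i, (name, _) in enumerate(header_lengths)}
    unsorted = path + ".unsorted.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for rec in records:
            a = pysam.AlignedSegment()
            a.query_name = rec["name"]
            a.flag = rec["flag"]
            a.reference_id = tid[rec["chrom"]]
            a.reference_start = rec["pos"]
            a.mapping_quality = rec.get("mapq", 60)
            a.query_sequence = rec["seq"]
            a.cigarstring = rec.get("cigar", f"{len(rec['seq'])}M")
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in rec["qual"])
            )
            if "mate_pos" in rec:
                a.next_reference_id = tid[rec.get("mate_chrom", rec["chrom"])]
                a.next_reference_start = rec["mate_pos"]
                a.template_length = rec.get("tlen", 0)
            bam.write(a)
    pysam.sort("-o", path, unsorted)
    pysam.index(path)
    os.remove(unsorted)
    return path
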