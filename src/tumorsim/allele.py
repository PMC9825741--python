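"""Closed-form dosage arithmetic: allele sampling probabilities, coverage
modulation, expected B-allele fractions, VAFs and log2 ratios.

For a segment with effective per-allele copy numbers e_A and e_B
(population-averaged over normal cells, clones and background tumor):

* a read drawn at the segment comes from haplotype A with probability
  e_A / (e_A + e_B);
* the segment's coverage is modulated by (e_A + e_B) / 2 relative to the
  diploid baseline, so expected log2(tumor/control) = log2((e_A + e_B)/2);
* a phased het SNP whose alt sits on haplotype h has expected alt
  fraction e_h / (e_A + e_B);
* a point mutation of clonality c and multiplicity m in a tumor of
  content t has expected VAF t*c*m / (e_A + e_B).

These are exact expectations under the generation scheme (population drawn
proportionally to fraction x total copies, then a uniform allele copy), and
the same formulas back the package's acceptance checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from tumorsim.errors import ValidationError
from tumorsim.profiles import PhasedSNP, SegmentDosage, SomaticPM


class DegenerateLocusError(ValidationError):
    """Total effective copy number is zero: no read can cover the locus."""


@dataclass(frozen=True)
class LocusExpectation:
    """Expected sampling behavior at one locus of a dosage segment."""

    p_allele_A: float
    coverage_factor: float
    expected_log2: float
    expected_baf_alt: float | None = None
    expected_vaf: float | None = None


def locus_expectation(
    segment: SegmentDosage,
    snp: PhasedSNP | None = None,
    pm: SomaticPM | None = None,
    tumor_content: float = 0.0,
) -> LocusExpectation:
    """Closed-form expectations for a locus inside ``segment``.

    When ``snp`` is given, the expected alt-allele fraction of that phased
    SNP is included; when ``pm`` is given, its expected variant allele
    fraction (using the PM's own clonality and multiplicity). Raises
    :class:`DegenerateLocusError` when the total effective dosage is zero
    (homozygous deletion across every population).
    """
    e_a, e_b = segment.effective_A, segment.effective_B
    total = e_a + e_b
    if total <= 0.0:
        raise DegenerateLocusError(
            f"segment {segment.chromosome}:{segment.start}-{segment.end}: "
            "total effective copy number is zero"
        )
    expectation = {
        "p_allele_A": e_a / total,
        "coverage_factor": total / 2.0,
        "expected_log2": math.log2(total / 2.0),
    }
    if snp is not None:
        e_alt = e_a if snp.phase == "A" else e_b
        expectation["expected_baf_alt"] = e_alt / total
    if pm is not None:
        expectation["expected_vaf"] = (
            tumor_content * pm.clonality * pm.multiplicity / total
        )
    return LocusExpectation(**expectation)
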