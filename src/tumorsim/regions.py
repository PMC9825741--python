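"""Capture-target intervals: BED parsing, merging, coordinate lookups.

All coordinates are 0-based half-open internally, matching BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tumorsim.errors import InputError, ValidationError


@dataclass(frozen=True)
class TargetRegions:
    """Sorted, merged capture-target intervals.

    ``regions`` is a list of ``(chrom, start, end)`` with 0-based half-open
    coordinates, sorted by (chrom, start) and non-overlapping.
    """

    regions: tuple[tuple[str, int, int], ...]
    total_length: int = field(init=False)

    def __post_init__(self) -> None:
        prev: tuple[str, int] | None = None
        for chrom, start, end in self.regions:
            if start >= end:
                raise ValidationError(f"empty/inverted region {chrom}:{start}-{end}")
            if prev is not None and prev[0] == chrom and start < prev[1]:
                raise ValidationError(f"regions overlap or are unsorted at {chrom}:{start}")
            prev = (chrom, end)
        object.__setattr__(
            self, "total_length", sum(e - s for _, s, e in self.regions)
        )

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for chrom, _, _ in self.regions:
            seen.setdefault(chrom)
        return list(seen)

    def contains(self, chrom: str, pos: int) -> bool:
        """True if ``pos`` (0-based) lies inside a target region."""
        for c, s, e in self.regions:
            if c == chrom and s <= pos < e:
                return True
        return False

    def region_index(self, chrom: str, pos: int) -> int | None:
        """Index of the region containing ``pos``, or None."""
        for i, (c, s, e) in enumerate(self.regions):
            if c == chrom and s <= pos < e:
                return i
        return None

    def intersect(self, chrom: str, start: int, end: int) -> list[tuple[int, int]]:
        """Intersections of [start, end) with target space on ``chrom``."""
        out = []
        for c, s, e in self.regions:
            if c != chrom:
                continue
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                out.append((lo, hi))
        return out


def merge_intervals(
    intervals: list[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Sort and merge overlapping or book-ended intervals."""
    merged: list[list] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    return [tuple(iv) for iv in merged]


def read_targets(path: str) -> TargetRegions:
    """Read a BED file (>=3 tab-separated columns) into merged TargetRegions.

    Raises :class:`InputError` on malformed lines (naming the line number)
    and :class:`ValidationError` on inverted intervals.
    """
    intervals: list[tuple[str, int, int]] = []
    try:
        fh = open(path)
    except OSError as exc:
        raise InputError(f"cannot open BED file {path!r}: {exc}") from exc
    with fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(
                    f"{path}: line {lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise InputError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise ValidationError(
                    f"{path}: line {lineno}: end {end} <= start {start}"
                )
            intervals.append((fields[0], start, end))
    if not intervals:
        raise InputError(f"{path}: no intervals found")
    return TargetRegions(tuple(merge_intervals(intervals)))


def write_targets(targets: TargetRegions, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in targets:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def position_arrays(targets: TargetRegions) -> tuple[np.ndarray, np.ndarray]:
    """Flattened (region_index, offset) helper arrays, one entry per captured base."""
    idx = np.concatenate(
        [np.full(e - s, i, dtype=np.int64) for i, (_, s, e) in enumerate(targets)]
    )
    off = np.concatenate(
        [np.arange(e - s, dtype=np.int64) for _, s, e in targets]
    )
    return idx, off
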