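"""Binned coverage tracks with RPKM normalisation and control subtraction.

A track stores one value per fixed-width bin per chromosome; bins tile
each chromosome exactly (the final bin may be truncated).  RPKM for a
bin is::

    count_overlapping_bin / (bin_length_kb * total_mapped_units / 1e6)

where the counting unit is a read (RNA mode) or a sequenced fragment
(Cut&Run mode).  The IgG (or wt-background) control is removed by
binwise subtraction floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import AlignmentRecord, fragment_interval
from .errors import ConfigurationError, DataError
from .tagging import AlleleTag, TaggedAlignment


@dataclass(slots=True)
class CoverageTrack:
    bin_size: int
    values: dict  # chrom -> np.ndarray
    chrom_lengths: dict
    normalization: str = "raw"
    total_units: int = 0

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def same_binning(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chrom_lengths == other.chrom_lengths
            and set(self.values) == set(other.values)
        )


def _intervals_from(items, unit: str):
    """Yield (chrom, start, end) spans from alignment records, pairs, or tuples."""
    for item in items:
        if isinstance(item, TaggedAlignment):
            recs = item.records
            item = recs if len(recs) > 1 else recs[0]
        if isinstance(item, AlignmentRecord):
            yield item.chrom, item.start, item.end
        elif isinstance(item, tuple) and len(item) == 3 and isinstance(item[0], str):
            yield item
        else:  # read pair
            if unit == "fragment":
                yield fragment_interval(item)
            else:
                for rec in item:
                    yield rec.chrom, rec.start, rec.end


def bin_counts(
    items, chrom_lengths: dict[str, int], bin_size: int, unit: str = "read"
) -> tuple[dict, int]:
    """Count units overlapping each bin; returns (per-chrom arrays, n units)."""
    if bin_size <= 0:
        raise ConfigurationError("bin_size must be positive")
    counts = {
        chrom: np.zeros(-(-length // bin_size)) for chrom, length in chrom_lengths.items()
    }
    n = 0
    for chrom, start, end in _intervals_from(items, unit):
        n += 1
        arr = counts.get(chrom)
        if arr is None:
            raise DataError(f"interval on unknown chromosome {chrom!r}")
        lo = start // bin_size
        hi = min((end - 1) // bin_size, len(arr) - 1)
        arr[lo : hi + 1] += 1
    return counts, n


def rpkm_track(
    items,
    chrom_lengths: dict[str, int],
    bin_size: int,
    unit: str = "read",
    total_units: int | None = None,
) -> CoverageTrack:
    """Build an RPKM-normalized coverage track.

    ``total_units`` defaults to the number of items supplied; pass the
    library's total mapped count explicitly when building a track from a
    subset (e.g. one allele) that should share the library normalisation.
    """
    counts, n = bin_counts(items, chrom_lengths, bin_size, unit)
    total = n if total_units is None else total_units
    if total == 0:
        values = counts  # all-zero track
    else:
        # count * 1e6 / (bin_kb * total); ordered so the single-bin
        # identity N / (1kb * N/1e6) = 1e6 is exact in floating point
        factor = 1e6 / (bin_size / 1000.0)
        values = {c: a * factor / total for c, a in counts.items()}
    return CoverageTrack(
        bin_size=bin_size,
        values=values,
        chrom_lengths=dict(chrom_lengths),
        normalization="RPKM",
        total_units=total,
    )


def subtract_control(treatment: CoverageTrack, control: CoverageTrack) -> CoverageTrack:
    """Binwise treatment - control, floored at zero."""
    if not treatment.same_binning(control):
        raise DataError("treatment and control tracks have different binning")
    values = {
        chrom: np.maximum(treatment.values[chrom] - control.values[chrom], 0.0)
        for chrom in treatment.values
    }
    return CoverageTrack(
        bin_size=treatment.bin_size,
        values=values,
        chrom_lengths=dict(treatment.chrom_lengths),
        normalization=f"{treatment.normalization}-control_subtracted",
        total_units=treatment.total_units,
    )


def allelic_tracks(
    tagged: list[TaggedAlignment],
    chrom_lengths: dict[str, int],
    bin_size: int,
    unit: str = "read",
) -> tuple[CoverageTrack, CoverageTrack]:
    """RPKM tracks from G1-only and G2-only reads (each self-normalized)."""
    g1 = [ta for ta in tagged if ta.tag is AlleleTag.G1]
    g2 = [ta for ta in tagged if ta.tag is AlleleTag.G2]
    return (
        rpkm_track(g1, chrom_lengths, bin_size, unit),
        rpkm_track(g2, chrom_lengths, bin_size, unit),
    )


def merge_raw_counts(count_sets: list[tuple[dict, int]], bin_size: int, chrom_lengths, as_rpkm=True):
    """Sum raw bin counts across replicates, then normalize once.

    Mirrors merging replicate libraries before peak calling.
    """
    merged = {c: np.zeros(-(-l // bin_size)) for c, l in chrom_lengths.items()}
    total = 0
    for counts, n in count_sets:
        total += n
        for c, arr in counts.items():
            merged[c] += arr
    if as_rpkm and total > 0:
        scale = (bin_size / 1000.0) * (total / 1e6)
        merged = {c: a / scale for c, a in merged.items()}
    return CoverageTrack(
        bin_size=bin_size,
        values=merged,
        chrom_lengths=dict(chrom_lengths),
        normalization="RPKM" if as_rpkm else "raw",
        total_units=total,
    )
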