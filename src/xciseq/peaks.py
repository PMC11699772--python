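"""Threshold peak calling, TSS windows, gene-level overlaps, Xi gains.

The caller is a documented substitute for SEACR's "norm" mode, which
operates on normalized bedGraph signal: bins whose signal exceeds a
data-derived threshold are merged into peaks (single sub-threshold bins
are bridged), and a peak's reported signal is the sum of its bin values.
Without a control track the threshold is a quantile of the track's own
nonzero bin values; with a control (IgG, or the wt sample when calling
knockout-specific Xi peaks) the threshold is the same quantile of the
control's nonzero bins, and a bin must additionally exceed the control's
corresponding bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import GeneModel
from .errors import ConfigurationError, DataError
from .tracks import CoverageTrack


@dataclass(frozen=True, slots=True)
class Peak:
    chrom: str
    start: int
    end: int
    total_signal: float
    max_signal: float
    source: str = ""

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class TSSRegion:
    gene_id: str
    chrom: str
    start: int
    end: int


@dataclass(slots=True)
class PeakGainReport:
    gained: list
    chrom: str
    chrom_length: int
    covered_fraction: float
    context_counts: dict = field(default_factory=dict)


def call_peaks(
    track: CoverageTrack,
    control: CoverageTrack | None = None,
    threshold_quantile: float = 0.99,
    min_width: int = 0,
    bridge_gap_bins: int = 1,
    source: str = "",
) -> list[Peak]:
    """Call enrichment peaks from a normalized coverage track.

    Contiguous runs of supra-threshold bins are merged into peaks; runs
    separated by at most ``bridge_gap_bins`` sub-threshold bins are
    joined.  Peaks narrower than ``min_width`` bp are dropped.  An
    all-zero track yields an empty list.
    """
    if not 0 < threshold_quantile < 1:
        raise ConfigurationError("threshold_quantile must be in (0, 1)")
    if control is not None and not track.same_binning(control):
        raise DataError("control track binning does not match")
    if control is not None:
        ref_values = np.concatenate([v[v > 0] for v in control.values.values()] or [np.empty(0)])
    else:
        ref_values = np.concatenate([v[v > 0] for v in track.values.values()] or [np.empty(0)])
    if ref_values.size == 0:
        if control is None:
            return []
        threshold = 0.0
    else:
        threshold = float(np.quantile(ref_values, threshold_quantile))
    peaks: list[Peak] = []
    bs = track.bin_size
    for chrom, values in track.values.items():
        above = values > threshold
        if control is not None:
            above &= values > control.values[chrom]
        idx = np.flatnonzero(above)
        if idx.size == 0:
            continue
        # split where the gap between supra-threshold bins exceeds the bridge
        breaks = np.flatnonzero(np.diff(idx) > bridge_gap_bins + 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        chrom_len = track.chrom_lengths[chrom]
        for s_i, e_i in zip(starts, ends):
            lo_bin, hi_bin = idx[s_i], idx[e_i]
            start = int(lo_bin) * bs
            end = min((int(hi_bin) + 1) * bs, chrom_len)
            if end - start < min_width:
                continue
            segment = values[lo_bin : hi_bin + 1]
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    total_signal=float(segment.sum()),
                    max_signal=float(segment.max()),
                    source=source,
                )
            )
    return peaks


def filter_peaks_by_signal(peaks: list[Peak], min_total_signal: float) -> list[Peak]:
    """Retain peaks with total signal >= threshold (order-preserving)."""
    if min_total_signal < 0:
        raise ConfigurationError("min_total_signal must be non-negative")
    return [p for p in peaks if p.total_signal >= min_total_signal]


def tss_regions(
    genes: list[GeneModel],
    chrom_lengths: dict[str, int],
    flank: int = 5000,
) -> list[TSSRegion]:
    """Strand-aware +/- ``flank`` bp windows around each TSS, clamped."""
    regions = []
    for g in genes:
        if g.chrom not in chrom_lengths:
            raise DataError(f"gene {g.gene_id} on unknown chromosome {g.chrom!r}")
        length = chrom_lengths[g.chrom]
        tss = g.tss
        regions.append(
            TSSRegion(
                gene_id=g.gene_id,
                chrom=g.chrom,
                start=max(0, tss - flank),
                end=min(length, tss + flank),
            )
        )
    return regions


def peaks_at_tss(peaks: list[Peak], regions: list[TSSRegion]) -> set[str]:
    """Genes with at least one peak overlapping a TSS window (>= 1 bp)."""
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    hit: set[str] = set()
    for region in regions:
        if region.gene_id in hit:
            continue
        for p in by_chrom.get(region.chrom, ()):
            if p.start < region.end and region.start < p.end:
                hit.add(region.gene_id)
                break
    return hit


def venn_counts(gene_sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive-region counts of the 2- or 3-set Venn partition.

    Keys are sorted tuples of the sample names whose exclusive
    intersection region the count belongs to.
    """
    names = list(gene_sets)
    if not 2 <= len(names) <= 3:
        raise ConfigurationError("venn_counts supports 2 or 3 sets")
    universe = set().union(*gene_sets.values())
    out: dict[tuple[str, ...], int] = {}
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(universe)
            for n in combo:
                inside &= gene_sets[n]
            for n in names:
                if n not in combo:
                    inside -= gene_sets[n]
            out[tuple(sorted(combo))] = len(inside)
    return out


def _overlaps_any(peak: Peak, others: list[Peak]) -> bool:
    return any(
        p.chrom == peak.chrom and p.start < peak.end and peak.start < p.end for p in others
    )


def xi_specific_gains(
    test_peaks: list[Peak],
    background_peaks: list[Peak],
    chrom: str,
    chrom_length: int,
    genes: list[GeneModel] | None = None,
    tss_flank: int = 5000,
) -> PeakGainReport:
    """Peaks present in the test (KO, Xi allele) but absent in background.

    A test peak is "gained" if it overlaps no background peak by >= 1 bp.
    The report includes the fraction of the target chromosome covered by
    gained peaks and, when an annotation is supplied, counts by genomic
    context (TSS window / gene body / intergenic, classified by peak
    midpoint with TSS windows taking priority).
    """
    for p in list(test_peaks) + list(background_peaks):
        if p.chrom != chrom:
            raise DataError(f"peak on {p.chrom!r}, expected {chrom!r}")
    gained = [p for p in test_peaks if not _overlaps_any(p, background_peaks)]
    covered = sum(p.width for p in gained)
    report = PeakGainReport(
        gained=gained,
        chrom=chrom,
        chrom_length=chrom_length,
        covered_fraction=covered / chrom_length,
    )
    if genes is not None:
        chrom_genes = [g for g in genes if g.chrom == chrom]
        windows = tss_regions(chrom_genes, {chrom: chrom_length}, flank=tss_flank)
        counts = {"tss": 0, "gene_body": 0, "intergenic": 0}
        for p in gained:
            mid = (p.start + p.end) // 2
            if any(w.start <= mid < w.end for w in windows):
                counts["tss"] += 1
            elif any(g.start <= mid < g.end for g in chrom_genes):
                counts["gene_body"] += 1
            else:
                counts["intergenic"] += 1
        report.context_counts = counts
    return report


def write_bed6(peaks: list[Peak], path: str) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.source or 'peak'}\t{p.total_signal:.6g}\t.\n"
            )
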