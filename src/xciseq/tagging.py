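"""Alignment filtering and SNP-based allele tagging.

Each retained read (RNA-seq) or read pair (Cut&Run) is classified by
the bases it shows at strain-diagnostic SNP sites:

* ``G1`` — matches haplotype-1 (129-analog) alleles only,
* ``G2`` — matches haplotype-2 (cast-analog) alleles only,
* ``CF`` — conflicting evidence (at least one match to each),
* ``UA`` — no valid SNP observation (no covered site, or every covered
  base matches neither allele and is treated as a sequencing error).

Filters reproduce the upstream alignment hygiene: reads must be mapped
with MAPQ >= 30; Cut&Run pairs must additionally have both mates on the
same chromosome with a fragment shorter than 1 kb (strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .alignment import AlignmentRecord, ReadPair
from .errors import DataError
from .pseudogenome import SNPTable

DEFAULT_MIN_MAPQ = 30
DEFAULT_MAX_FRAGMENT = 1000


class AlleleTag(str, Enum):
    G1 = "G1"
    G2 = "G2"
    CF = "CF"
    UA = "UA"


@dataclass(slots=True)
class TaggedAlignment:
    """An alignment (or pair) with its allele tag and SNP evidence."""

    records: tuple[AlignmentRecord, ...]
    tag: AlleleTag
    evidence: tuple[tuple[int, str, str | None], ...] = ()

    @property
    def read_id(self) -> str:
        return self.records[0].read_id

    @property
    def chrom(self) -> str:
        return self.records[0].chrom


@dataclass(slots=True)
class AllelicMappingSummary:
    """Per-library tagging tallies (mirrors an allelic mapping metrics table)."""

    library: str = ""
    total: int = 0
    passed: int = 0
    dropped: dict = field(default_factory=dict)
    tags: dict = field(default_factory=lambda: {t: 0 for t in AlleleTag})

    def check_partition(self) -> None:
        if sum(self.tags.values()) != self.passed:
            raise DataError("tag counts do not partition passed reads")

    def fractions(self) -> dict:
        denom = max(self.passed, 1)
        return {t.value: self.tags[t] / denom for t in AlleleTag}

    def three_category(self) -> dict:
        """RNA-style rollup: allele-uncertain pools CF with UA."""
        return {
            "g1_snp": self.tags[AlleleTag.G1],
            "g2_snp": self.tags[AlleleTag.G2],
            "allele_uncertain": self.tags[AlleleTag.CF] + self.tags[AlleleTag.UA],
        }

    def to_row(self) -> dict:
        row = {"library": self.library, "total": self.total, "passed": self.passed}
        row.update({t.value: self.tags[t] for t in AlleleTag})
        return row


def filter_alignment(
    record: AlignmentRecord, mapq_min: int = DEFAULT_MIN_MAPQ
) -> tuple[bool, str | None]:
    """Keep iff mapped with MAPQ >= ``mapq_min`` (boundary kept)."""
    if not record.mapped:
        return False, "unmapped"
    if record.mapq < mapq_min:
        return False, "low_mapq"
    return True, None


def filter_pair(
    r1: AlignmentRecord,
    r2: AlignmentRecord | None,
    max_fragment: int = DEFAULT_MAX_FRAGMENT,
) -> tuple[bool, str | None]:
    """Cut&Run pair filter: same chromosome, fragment strictly < 1 kb."""
    if r2 is None:
        return False, "orphan"
    if not (r1.mapped and r2.mapped):
        return False, "unmapped"
    if r1.chrom != r2.chrom:
        return False, "chimeric"
    frag = r1.fragment_length
    if frag is None:
        frag = max(r1.end, r2.end) - min(r1.start, r2.start)
    if frag >= max_fragment:
        return False, "fragment_length"
    return True, None


def classify_read(
    item: AlignmentRecord | ReadPair,
    snps: SNPTable,
    keep_evidence: bool = False,
) -> TaggedAlignment:
    """Tag a read (or pooled pair) from its bases at covered SNP sites.

    An observed base is a g1-match if it equals ``allele_g1`` at that
    site, a g2-match if it equals ``allele_g2``; a base matching neither
    is ignored as invalid (most likely a sequencing error).
    """
    records = item if isinstance(item, tuple) else (item,)
    n_g1 = 0
    n_g2 = 0
    evidence = [] if keep_evidence else None
    for rec in records:
        if not rec.mapped or rec.sequence is None:
            if rec.mapped and rec.sequence is None:
                raise DataError(f"read {rec.read_id} has no sequence; cannot tag")
            continue
        pos, a1, a2 = snps.in_span(rec.chrom, rec.start, rec.end)
        seq = rec.sequence
        start = rec.start
        for p, x, y in zip(pos, a1, a2):
            base = seq[p - start]
            if base == x:
                n_g1 += 1
                match = "g1"
            elif base == y:
                n_g2 += 1
                match = "g2"
            else:
                match = None
            if evidence is not None:
                evidence.append((int(p), base, match))
    if n_g1 and not n_g2:
        tag = AlleleTag.G1
    elif n_g2 and not n_g1:
        tag = AlleleTag.G2
    elif n_g1 and n_g2:
        tag = AlleleTag.CF
    else:
        tag = AlleleTag.UA
    return TaggedAlignment(records=records, tag=tag, evidence=tuple(evidence or ()))


def tag_library(
    alignments,
    snps: SNPTable,
    mode: str = "rna",
    library: str = "",
    min_mapq: int = DEFAULT_MIN_MAPQ,
    max_fragment: int = DEFAULT_MAX_FRAGMENT,
    keep_evidence: bool = False,
) -> tuple[list[TaggedAlignment], AllelicMappingSummary]:
    """Filter and tag a whole library.

    Parameters
    ----------
    alignments
        ``mode='rna'``: iterable of :class:`AlignmentRecord`.
        ``mode='cutrun'``: iterable of ``(read1, read2)`` pairs
        (``read2`` may be None for orphans).
    snps
        Retained diagnostic SNP table.
    mode
        ``'rna'`` applies the single-read MAPQ filter; ``'cutrun'``
        applies the pair filter first, then requires both mates to pass
        the MAPQ filter.
    """
    if mode not in ("rna", "cutrun"):
        raise ValueError(f"unknown mode {mode!r}")
    summary = AllelicMappingSummary(library=library)
    tagged: list[TaggedAlignment] = []
    known = set(snps.chroms)
    for item in alignments:
        summary.total += 1
        if mode == "rna":
            rec = item
            keep, reason = filter_alignment(rec, min_mapq)
            if keep and known and rec.chrom not in known:
                raise DataError(f"alignment chromosome {rec.chrom!r} not in SNP table")
            unit = rec
        else:
            r1, r2 = item
            keep, reason = filter_pair(r1, r2, max_fragment)
            if keep:
                for mate in (r1, r2):
                    ok, why = filter_alignment(mate, min_mapq)
                    if not ok:
                        keep, reason = False, why
                        break
            if keep and known and r1.chrom not in known:
                raise DataError(f"alignment chromosome {r1.chrom!r} not in SNP table")
            unit = (r1, r2)
        if not keep:
            summary.dropped[reason] = summary.dropped.get(reason, 0) + 1
            continue
        summary.passed += 1
        ta = classify_read(unit, snps, keep_evidence=keep_evidence)
        summary.tags[ta.tag] += 1
        tagged.append(ta)
    summary.check_partition()
    return tagged, summary


def split_by_tag(tagged: list[TaggedAlignment]) -> dict[AlleleTag, list[TaggedAlignment]]:
    """Separate tagged alignments by tag (e.g. to write G1/G2 files)."""
    out: dict[AlleleTag, list[TaggedAlignment]] = {t: [] for t in AlleleTag}
    for ta in tagged:
        out[ta.tag].append(ta)
    return out
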