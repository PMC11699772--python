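"""Strain-variant filtering and pseudo-diploid genome construction.

A hybrid cross (e.g. 129 x cast) is analysed against two
"pseudo-genomes": copies of the reference in which each retained
strain-diagnostic SNP allele has been substituted.  Both genomes share
reference coordinates because only single-base substitutions are
applied; indels and low-quality variant calls are filtered out first.

Haplotype 1 (``g1``) is the maternal / Xi-biased strain analog (129),
haplotype 2 (``g2``) the paternal analog (cast).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CoordinateError, DataError

_BASES = frozenset("ACGT")


@dataclass(frozen=True, slots=True)
class VariantCall:
    """A raw strain-variant record as parsed from a VCF.

    ``pos`` is the 1-based reference coordinate of the record;
    ``allele_g1``/``allele_g2`` are the alleles carried by the two
    strains (either may equal the reference allele).
    """

    chrom: str
    pos: int
    ref: str
    allele_g1: str
    allele_g2: str
    filter_status: str = "PASS"

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or len(self.allele_g1) != 1 or len(self.allele_g2) != 1

    @property
    def is_snv(self) -> bool:
        return not self.is_indel


@dataclass(frozen=True, slots=True)
class SNPRecord:
    """A retained strain-diagnostic SNP (1-based position)."""

    chrom: str
    pos: int
    allele_g1: str
    allele_g2: str


@dataclass(slots=True)
class FilterSummary:
    """Accounting of variant filtering: |input| = |retained| + sum(removed)."""

    n_input: int = 0
    n_retained: int = 0
    removed: dict = field(default_factory=dict)

    def check(self) -> None:
        if self.n_input != self.n_retained + sum(self.removed.values()):
            raise DataError("filter accounting does not balance")


class SNPTable:
    """Position-sorted per-chromosome table of diagnostic SNPs.

    Internally stores, per chromosome, parallel numpy arrays of 0-based
    positions and the two strain alleles, supporting fast span queries
    during read tagging.
    """

    def __init__(self, records: list[SNPRecord] | None = None):
        self._pos: dict[str, np.ndarray] = {}
        self._a1: dict[str, np.ndarray] = {}
        self._a2: dict[str, np.ndarray] = {}
        if records:
            self._build(records)

    def _build(self, records: list[SNPRecord]) -> None:
        by_chrom: dict[str, list[SNPRecord]] = {}
        for r in records:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: r.pos)
            pos = np.array([r.pos - 1 for r in recs], dtype=np.int64)
            if len(pos) > 1 and (np.diff(pos) == 0).any():
                raise DataError(f"duplicate SNP positions on {chrom}")
            self._pos[chrom] = pos
            self._a1[chrom] = np.array([r.allele_g1 for r in recs])
            self._a2[chrom] = np.array([r.allele_g2 for r in recs])

    @property
    def chroms(self) -> list[str]:
        return list(self._pos)

    def __len__(self) -> int:
        return sum(len(p) for p in self._pos.values())

    def n_on(self, chrom: str) -> int:
        return len(self._pos.get(chrom, ()))

    def positions(self, chrom: str) -> np.ndarray:
        """0-based SNP positions on ``chrom`` (empty array if none)."""
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    def alleles(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        empty = np.empty(0, dtype="<U1")
        return self._a1.get(chrom, empty), self._a2.get(chrom, empty)

    def lookup(self, chrom: str, pos: int) -> SNPRecord | None:
        """Look up a SNP by (chrom, 1-based pos)."""
        pos0 = pos - 1
        arr = self.positions(chrom)
        i = int(np.searchsorted(arr, pos0))
        if i < len(arr) and arr[i] == pos0:
            return SNPRecord(chrom, pos, str(self._a1[chrom][i]), str(self._a2[chrom][i]))
        return None

    def in_span(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """SNPs with 0-based position in [start, end).

        Returns (positions, alleles_g1, alleles_g2).
        """
        arr = self.positions(chrom)
        lo = int(np.searchsorted(arr, start, side="left"))
        hi = int(np.searchsorted(arr, end, side="left"))
        a1, a2 = self.alleles(chrom)
        return arr[lo:hi], a1[lo:hi], a2[lo:hi]

    def records(self) -> list[SNPRecord]:
        out = []
        for chrom in self._pos:
            a1, a2 = self._a1[chrom], self._a2[chrom]
            for p, x, y in zip(self._pos[chrom], a1, a2):
                out.append(SNPRecord(chrom, int(p) + 1, str(x), str(y)))
        return out

    def swapped(self) -> "SNPTable":
        """Return a copy with the two strain alleles exchanged."""
        t = SNPTable()
        t._pos = {c: p.copy() for c, p in self._pos.items()}
        t._a1 = {c: a.copy() for c, a in self._a2.items()}
        t._a2 = {c: a.copy() for c, a in self._a1.items()}
        return t


def filter_variants(
    calls: list[VariantCall], min_qual: float | None = None, quals: list[float] | None = None
) -> tuple[SNPTable, FilterSummary]:
    """Filter raw strain variants down to diagnostic SNPs.

    Retains biallelic single-nucleotide records with passing filter
    status and differing strain alleles.  Removal reasons are counted:
    ``indel``, ``lowqual``, ``same_allele`` (the strains agree, so the
    site cannot distinguish them), ``non_acgt``, ``duplicate``.

    Duplicate positions with conflicting alleles raise
    :class:`~xciseq.errors.DataError`; exact duplicates are dropped with
    a counted reason.
    """
    summary = FilterSummary(n_input=len(calls))
    removed = summary.removed
    for key in ("indel", "lowqual", "same_allele", "non_acgt", "duplicate"):
        removed[key] = 0
    kept: dict[tuple[str, int], SNPRecord] = {}
    for i, c in enumerate(calls):
        if c.is_indel:
            removed["indel"] += 1
            continue
        lowqual = c.filter_status not in ("PASS", ".")
        if min_qual is not None and quals is not None and quals[i] < min_qual:
            lowqual = True
        if lowqual:
            removed["lowqual"] += 1
            continue
        if c.allele_g1 not in _BASES or c.allele_g2 not in _BASES:
            removed["non_acgt"] += 1
            continue
        if c.allele_g1 == c.allele_g2:
            removed["same_allele"] += 1
            continue
        key = (c.chrom, c.pos)
        rec = SNPRecord(c.chrom, c.pos, c.allele_g1, c.allele_g2)
        if key in kept:
            if kept[key] != rec:
                raise DataError(f"conflicting alleles at {c.chrom}:{c.pos}")
            removed["duplicate"] += 1
            continue
        kept[key] = rec
    summary.n_retained = len(kept)
    summary.check()
    return SNPTable(list(kept.values())), summary


@dataclass(slots=True)
class PseudoGenomePair:
    """Two strain-substituted genomes on shared reference coordinates."""

    genome_g1: dict[str, str]
    genome_g2: dict[str, str]
    snps: SNPTable

    def hamming(self, chrom: str) -> int:
        """Base-by-base difference count between the two genomes."""
        a = np.frombuffer(self.genome_g1[chrom].encode(), dtype="S1")
        b = np.frombuffer(self.genome_g2[chrom].encode(), dtype="S1")
        return int((a != b).sum())


def build_pseudogenomes(reference: dict[str, str], snps: SNPTable) -> PseudoGenomePair:
    """Substitute the strain alleles into two copies of the reference.

    Returns a :class:`PseudoGenomePair` in which ``genome_g1`` carries
    ``allele_g1`` at every retained SNP, ``genome_g2`` carries
    ``allele_g2``, and all other bases equal the reference.  Chromosome
    lengths are preserved exactly (SNP-only substitution).
    """
    g1: dict[str, str] = {}
    g2: dict[str, str] = {}
    for chrom in snps.chroms:
        if chrom not in reference:
            raise DataError(f"SNP table chromosome {chrom!r} absent from reference")
        if snps.n_on(chrom) and snps.positions(chrom)[-1] >= len(reference[chrom]):
            raise CoordinateError(f"SNP beyond end of {chrom}")
    for chrom, seq in reference.items():
        pos = snps.positions(chrom)
        if len(pos) == 0:
            g1[chrom] = seq
            g2[chrom] = seq
            continue
        a1, a2 = snps.alleles(chrom)
        arr1 = np.frombuffer(seq.encode(), dtype="S1").copy()
        arr2 = arr1.copy()
        arr1[pos] = a1.astype("S1")
        arr2[pos] = a2.astype("S1")
        g1[chrom] = arr1.tobytes().decode()
        g2[chrom] = arr2.tobytes().decode()
    return PseudoGenomePair(g1, g2, snps)
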