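"""Gene models with exon structure, strand and TSS.

Coordinates are 0-based half-open throughout.  The transcription start
site (TSS) of a minus-strand gene is its rightmost transcribed base.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DataError

SILENCING_CLASSES = ("early", "intermediate", "late", "escape")


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A single-transcript gene model.

    Parameters
    ----------
    gene_id : str
        Unique identifier.
    chrom : str
        Chromosome name.
    strand : str
        ``'+'`` or ``'-'``.
    exons : tuple of (int, int)
        Sorted, non-overlapping exon intervals (0-based half-open).
    silencing_class : str, optional
        XCI silencing class for X-linked genes: one of
        ``early``, ``intermediate``, ``late``, ``escape``.
    is_xist : bool
        Whether this is the designated Xist-like locus.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    silencing_class: str | None = None
    is_xist: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise DataError(f"gene {self.gene_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise DataError(f"gene {self.gene_id}: empty exon ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise DataError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def transcript_length(self) -> int:
        """Summed exon length in bp (the effective length for TPM)."""
        return sum(e - s for s, e in self.exons)


def transcript_lengths(genes: list[GeneModel]) -> dict[str, int]:
    return {g.gene_id: g.transcript_length for g in genes}


def genes_by_chrom(genes: list[GeneModel]) -> dict[str, list[GeneModel]]:
    out: dict[str, list[GeneModel]] = {}
    for g in genes:
        out.setdefault(g.chrom, []).append(g)
    return out
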