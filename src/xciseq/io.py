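"""File-format boundaries: FASTA, VCF, SAM, BED12, bedGraph, tables.

Internal coordinates are 0-based half-open; VCF positions are converted
to/from 1-based at this boundary only.  Reading goes through pysam /
pyfaidx; writing emits plain conformant text so outputs are
deterministic byte-for-byte for a fixed input.
"""

from __future__ import annotations

import os
from collections import defaultdict

import pysam
from pyfaidx import Fasta

from .alignment import AlignmentRecord, ReadPair
from .annotation import GeneModel
from .errors import ParseError
from .pseudogenome import VariantCall

# ---------------------------------------------------------------- FASTA


def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    fa = Fasta(path, as_raw=True, sequence_always_upper=True)
    try:
        return {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()


# ------------------------------------------------------------------ VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FILTER=<ID=LowQual,Description="Low quality variant call">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(calls: list[VariantCall], contig_lengths: dict[str, int], path: str) -> None:
    """Write strain variants as a two-sample (G1, G2) haploid VCF."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tG1\tG2\n")
        for c in calls:
            alts = []
            for allele in (c.allele_g1, c.allele_g2):
                if allele != c.ref and allele not in alts:
                    alts.append(allele)
            alleles = [c.ref] + alts
            gt1 = alleles.index(c.allele_g1)
            gt2 = alleles.index(c.allele_g2)
            alt_field = ",".join(alts) if alts else "."
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{alt_field}\t.\t"
                f"{c.filter_status}\t.\tGT\t{gt1}\t{gt2}\n"
            )


def read_vcf(path: str) -> list[VariantCall]:
    calls = []
    with pysam.VariantFile(path) as vf:
        if not {"G1", "G2"} <= set(vf.header.samples):
            raise ParseError("VCF must contain samples G1 and G2")
        for rec in vf:
            try:
                a1 = rec.samples["G1"].alleles[0]
                a2 = rec.samples["G2"].alleles[0]
                if a1 is None or a2 is None:
                    raise ValueError("missing genotype")
                filt = list(rec.filter)
                status = filt[0] if filt else "PASS"
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        allele_g1=a1,
                        allele_g2=a2,
                        filter_status=status,
                    )
                )
            except (KeyError, ValueError, IndexError) as exc:
                raise ParseError(f"malformed VCF record at {rec.chrom}:{rec.pos}: {exc}") from exc
    return calls


# ------------------------------------------------------------------ SAM


def _sam_flag(rec: AlignmentRecord, mate: AlignmentRecord | None = None) -> int:
    flag = 0
    if rec.paired:
        flag |= 0x1
        flag |= 0x40 if rec.is_read1 else 0x80
        if rec.mapped and mate is not None and mate.mapped and rec.chrom == mate.chrom:
            flag |= 0x2
        if mate is not None and not mate.mapped:
            flag |= 0x8
    if not rec.mapped:
        flag |= 0x4
    if rec.strand == "-":
        flag |= 0x10
    return flag


def _sam_line(rec: AlignmentRecord, mate: AlignmentRecord | None = None) -> str:
    rname = rec.chrom if rec.mapped else "*"
    pos = rec.start + 1 if rec.mapped else 0
    cigar = f"{rec.length}M" if rec.mapped else "*"
    if mate is not None and mate.mapped:
        rnext = "=" if mate.chrom == rec.chrom else mate.chrom
        pnext = mate.start + 1
    else:
        rnext, pnext = "*", 0
    tlen = 0
    if rec.paired and rec.fragment_length is not None:
        tlen = rec.fragment_length if rec.is_read1 else -rec.fragment_length
    seq = rec.sequence if rec.sequence else "*"
    return (
        f"{rec.read_id}\t{_sam_flag(rec, mate)}\t{rname}\t{pos}\t{rec.mapq}\t"
        f"{cigar}\t{rnext}\t{pnext}\t{tlen}\t{seq}\t*"
    )


def write_sam(
    records: list[AlignmentRecord] | list[ReadPair],
    chrom_lengths: dict[str, int],
    path: str,
) -> None:
    """Write single-end records or read pairs to a SAM file."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for item in records:
            if isinstance(item, tuple):
                r1, r2 = item
                fh.write(_sam_line(r1, r2) + "\n")
                fh.write(_sam_line(r2, r1) + "\n")
            else:
                fh.write(_sam_line(item) + "\n")


def _from_pysam(a: "pysam.AlignedSegment") -> AlignmentRecord:
    seq = a.query_sequence
    return AlignmentRecord(
        read_id=a.query_name,
        chrom=a.reference_name if not a.is_unmapped else None,
        start=a.reference_start if not a.is_unmapped else 0,
        length=len(seq) if seq else (a.reference_length or 0),
        sequence=seq,
        mapq=a.mapping_quality,
        mapped=not a.is_unmapped,
        strand="-" if a.is_reverse else "+",
        mate_chrom=a.next_reference_name if a.is_paired and not a.mate_is_unmapped else None,
        fragment_length=abs(a.template_length) if a.is_paired else None,
        is_read1=not a.is_read2,
        paired=a.is_paired,
    )


def read_sam(path: str) -> list[AlignmentRecord]:
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        return [_from_pysam(a) for a in sam]


def read_sam_pairs(path: str) -> list[tuple[AlignmentRecord, AlignmentRecord | None]]:
    """Group a paired-end SAM by read name into (read1, read2) tuples.

    Orphans (a name seen once) are returned with ``None`` as the mate.
    """
    by_name: dict[str, list[AlignmentRecord]] = defaultdict(list)
    order: list[str] = []
    for rec in read_sam(path):
        if rec.read_id not in by_name:
            order.append(rec.read_id)
        by_name[rec.read_id].append(rec)
    pairs = []
    for name in order:
        recs = sorted(by_name[name], key=lambda r: not r.is_read1)
        if len(recs) == 2:
            pairs.append((recs[0], recs[1]))
        else:
            pairs.append((recs[0], None))
    return pairs


# ---------------------------------------------------------------- BED12


def write_bed12(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes},\t{starts},\n"
            )


def read_bed12(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED columns")
            try:
                chrom, start = f[0], int(f[1])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
                genes.append(GeneModel(gene_id=f[3], chrom=chrom, strand=f[5], exons=exons))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


# -------------------------------------------------------------- bedGraph


def write_bedgraph(track, path: str) -> None:
    """Write a CoverageTrack as 4-column bedGraph (nonzero bins only)."""
    with open(path, "w") as fh:
        for chrom, values in track.values.items():
            bs = track.bin_size
            length = track.chrom_lengths[chrom]
            for i, v in enumerate(values):
                if v != 0:
                    end = min((i + 1) * bs, length)
                    fh.write(f"{chrom}\t{i * bs}\t{end}\t{v:.6g}\n")


def read_bedgraph(path: str, bin_size: int, chrom_lengths: dict[str, int]):
    """Read a bedGraph written by :func:`write_bedgraph` back into a track."""
    import numpy as np

    from .tracks import CoverageTrack

    values = {
        chrom: np.zeros(-(-length // bin_size)) for chrom, length in chrom_lengths.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, value = f[0], int(f[1]), float(f[3])
            values[chrom][start // bin_size] = value
    return CoverageTrack(
        bin_size=bin_size, values=values, chrom_lengths=dict(chrom_lengths),
        normalization="raw", total_units=0,
    )
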