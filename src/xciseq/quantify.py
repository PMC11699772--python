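"""Gene-level total and allelic quantification.

Counts are gene x library matrices of total, haplotype-1 (G1) and
haplotype-2 (G2) read counts.  CF and UA reads contribute to the total
only, so ``g1 + g2 <= total`` always holds.  Normalisation follows the
standard definitions:

* CPM_g = count_g / sum_g(count) * 1e6
* TPM_g = (count_g / length_kb_g) / sum_g(count/length_kb) * 1e6

Differential expression is a documented substitute for DESeq2:
median-of-ratios size factors, per-gene two-sided Welch t-test on
log2(normalized count + 0.5), Benjamini-Hochberg correction, and the
FDR <= 0.1 / fold >= 2 decision rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneModel, transcript_lengths
from .errors import ConfigurationError, DataError
from .tagging import AlleleTag, TaggedAlignment

DE_FDR_THRESHOLD = 0.1
DE_FOLD_THRESHOLD = 2.0


@dataclass(slots=True)
class LibraryCounts:
    """Per-gene counts for one library plus counting accounting."""

    counts: pd.DataFrame  # index: gene; columns: total, g1, g2
    ambiguous: int = 0
    intergenic: int = 0

    @property
    def assigned(self) -> int:
        return int(self.counts["total"].sum())


@dataclass(slots=True)
class AllelicCountMatrix:
    """genes x libraries matrices of total / g1 / g2 counts."""

    total: pd.DataFrame
    g1: pd.DataFrame
    g2: pd.DataFrame
    ambiguous: dict = field(default_factory=dict)
    intergenic: dict = field(default_factory=dict)

    @classmethod
    def from_libraries(cls, libraries: dict[str, LibraryCounts]) -> "AllelicCountMatrix":
        total = pd.DataFrame({lib: lc.counts["total"] for lib, lc in libraries.items()})
        g1 = pd.DataFrame({lib: lc.counts["g1"] for lib, lc in libraries.items()})
        g2 = pd.DataFrame({lib: lc.counts["g2"] for lib, lc in libraries.items()})
        return cls(
            total=total.fillna(0).astype(int),
            g1=g1.fillna(0).astype(int),
            g2=g2.fillna(0).astype(int),
            ambiguous={lib: lc.ambiguous for lib, lc in libraries.items()},
            intergenic={lib: lc.intergenic for lib, lc in libraries.items()},
        )

    @property
    def libraries(self) -> list[str]:
        return list(self.total.columns)

    def validate(self) -> None:
        if (self.total < 0).any().any():
            raise DataError("negative counts")
        if ((self.g1 + self.g2) > self.total).any().any():
            raise DataError("allelic counts exceed totals")


@dataclass(slots=True)
class ExpressionTable:
    """TPM and CPM values (genes x libraries) with effective lengths."""

    tpm: pd.DataFrame
    cpm: pd.DataFrame
    lengths: pd.Series

    @property
    def libraries(self) -> list[str]:
        return list(self.tpm.columns)


def _exon_tree(genes: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.exons:
            tree.addi(s, e, g.gene_id)
    return trees


def count_reads(tagged, genes: list[GeneModel]) -> LibraryCounts:
    """Assign tagged reads to genes by exon overlap.

    Accepts :class:`TaggedAlignment` items or plain
    :class:`~xciseq.alignment.AlignmentRecord` (the latter contribute to
    totals only, as if untagged).

    A read increments a gene's total count if its aligned span overlaps
    any exon of that gene; reads overlapping exons of more than one gene
    are ambiguous and counted in neither.  G1/G2 tags increment the
    per-allele counts; CF and UA reads count toward totals only.
    """
    if not genes:
        raise DataError("empty annotation")
    trees = _exon_tree(genes)
    gene_ids = [g.gene_id for g in genes]
    idx = {gid: i for i, gid in enumerate(gene_ids)}
    total = np.zeros(len(gene_ids), dtype=np.int64)
    g1 = np.zeros_like(total)
    g2 = np.zeros_like(total)
    ambiguous = 0
    intergenic = 0
    for ta in tagged:
        records = ta.records if isinstance(ta, TaggedAlignment) else (ta,)
        tag = ta.tag if isinstance(ta, TaggedAlignment) else None
        hits: set[str] = set()
        for rec in records:
            tree = trees.get(rec.chrom)
            if tree is not None:
                for iv in tree.overlap(rec.start, rec.end):
                    hits.add(iv.data)
        if not hits:
            intergenic += 1
        elif len(hits) > 1:
            ambiguous += 1
        else:
            i = idx[hits.pop()]
            total[i] += 1
            if tag is AlleleTag.G1:
                g1[i] += 1
            elif tag is AlleleTag.G2:
                g2[i] += 1
    counts = pd.DataFrame({"total": total, "g1": g1, "g2": g2}, index=gene_ids)
    return LibraryCounts(counts=counts, ambiguous=ambiguous, intergenic=intergenic)


def tpm(matrix: AllelicCountMatrix, genes_or_lengths) -> ExpressionTable:
    """Compute TPM and CPM from total counts.

    ``genes_or_lengths`` is either a list of :class:`GeneModel` or a
    mapping / Series of per-gene effective lengths in bp (summed exon
    length).  A zero-total library yields an all-zero column with a
    warning.
    """
    if isinstance(genes_or_lengths, (dict, pd.Series)):
        lengths = pd.Series(genes_or_lengths, dtype=float)
    else:
        lengths = pd.Series(transcript_lengths(genes_or_lengths), dtype=float)
    lengths = lengths.reindex(matrix.total.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise DataError(f"missing lengths for genes: {missing[:5]}")
    if (lengths <= 0).any():
        raise ConfigurationError("effective lengths must be positive")
    counts = matrix.total.astype(float)
    rate = counts.div(lengths / 1000.0, axis=0)
    rate_sum = rate.sum(axis=0)
    count_sum = counts.sum(axis=0)
    zero_libs = count_sum[count_sum == 0].index.tolist()
    if zero_libs:
        warnings.warn(f"libraries with zero counts: {zero_libs}", stacklevel=2)
    tpm_df = rate.div(rate_sum.replace(0, np.nan), axis=1).fillna(0.0) * 1e6
    cpm_df = counts.div(count_sum.replace(0, np.nan), axis=1).fillna(0.0) * 1e6
    return ExpressionTable(tpm=tpm_df, cpm=cpm_df, lengths=lengths)


def expression_filter(
    expression: ExpressionTable | pd.DataFrame,
    min_cpm: float = 2.5,
    min_libraries: int = 2,
) -> pd.Index:
    """Genes with CPM >= ``min_cpm`` in at least ``min_libraries`` libraries."""
    cpm = expression.cpm if isinstance(expression, ExpressionTable) else expression
    if min_libraries > cpm.shape[1]:
        raise ConfigurationError(
            f"min_libraries={min_libraries} exceeds library count {cpm.shape[1]}"
        )
    ok = (cpm >= min_cpm).sum(axis=1) >= min_libraries
    return cpm.index[ok]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style normalisation)."""
    log_counts = np.log(counts.where(counts > 0))
    log_geomean = log_counts.mean(axis=1)
    usable = log_geomean.notna() & np.isfinite(log_geomean)
    if usable.sum() == 0:
        totals = counts.sum(axis=0).astype(float)
        return totals / totals.mean()
    ratios = log_counts.loc[usable].sub(log_geomean[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def differential_expression(
    matrix: AllelicCountMatrix | pd.DataFrame,
    groups: dict[str, str],
    reference: str = "wt",
    test_group: str = "ko",
    fdr_threshold: float = DE_FDR_THRESHOLD,
    fold_threshold: float = DE_FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Call differentially expressed genes between two groups.

    Returns a DataFrame indexed by gene with columns ``log2_fold``
    (test vs reference on size-factor-normalized counts), ``pvalue``,
    ``fdr`` and boolean ``de`` (FDR <= 0.1 and |fold| >= 2 by default).
    """
    counts = matrix.total if isinstance(matrix, AllelicCountMatrix) else matrix
    ref_libs = [l for l in counts.columns if groups.get(l) == reference]
    test_libs = [l for l in counts.columns if groups.get(l) == test_group]
    if not ref_libs or not test_libs:
        raise ConfigurationError("each group needs at least one library")
    sf = size_factors(counts[ref_libs + test_libs])
    norm = counts[ref_libs + test_libs].div(sf, axis=1)
    log_norm = np.log2(norm + 0.5)
    a = log_norm[test_libs].to_numpy()
    b = log_norm[ref_libs].to_numpy()
    log2_fold = np.log2((norm[test_libs].mean(axis=1) + 0.5) / (norm[ref_libs].mean(axis=1) + 0.5))
    if len(ref_libs) >= 2 and len(test_libs) >= 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
    else:
        # no replication: no inferential call, flag nothing
        pvals = np.ones(counts.shape[0])
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    result = pd.DataFrame(
        {
            "log2_fold": log2_fold,
            "pvalue": pvals,
            "fdr": fdr,
        },
        index=counts.index,
    )
    result["de"] = (result["fdr"] <= fdr_threshold) & (
        result["log2_fold"].abs() >= np.log2(fold_threshold)
    )
    return result
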