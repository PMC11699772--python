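"""XCI-facing results layer: allelic ratios, fold-change calls,
silencing-class summaries, escape calls and the Xist induction contrast.

The allelic ratio of a gene is the fraction of informative (G1 + G2)
reads carrying haplotype-1 (Xi-strain) alleles, ``g1 / (g1 + g2)``; the
raw odds ``g1 / g2`` are also emitted.  Allelic TPM for the Xi / Xa
scopes splits a gene's diploid TPM proportionally to its informative
read fractions.  Fold-change calls use the 1.25-fold threshold:
increased iff fold >= 1.25, decreased iff fold <= 1/1.25, else
unchanged; condition values average replicate libraries (clones)
before the fold is computed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .quantify import AllelicCountMatrix, ExpressionTable

FOLD_THRESHOLD = 1.25
ESCAPE_XI_THRESHOLD = 0.1


def allelic_ratios(
    matrix: AllelicCountMatrix,
    expression: ExpressionTable,
    min_tpm: float = 1.0,
) -> pd.DataFrame:
    """Per-gene, per-library Xi fractions for expressed genes.

    Genes below ``min_tpm`` or with zero informative reads in a library
    are omitted (their omission reason appears in the ``reason`` column
    of the attached ``.attrs['omitted']`` table).
    """
    rows = []
    omitted = []
    for lib in matrix.libraries:
        g1 = matrix.g1[lib]
        g2 = matrix.g2[lib]
        tpm = expression.tpm[lib]
        informative = g1 + g2
        for gene in matrix.total.index:
            if tpm[gene] <= min_tpm:
                omitted.append({"gene": gene, "library": lib, "reason": "low_tpm"})
                continue
            if informative[gene] == 0:
                omitted.append({"gene": gene, "library": lib, "reason": "no_informative_reads"})
                continue
            xi = g1[gene] / informative[gene]
            rows.append(
                {
                    "gene": gene,
                    "library": lib,
                    "xi_fraction": xi,
                    "xi_odds": np.inf if g2[gene] == 0 else g1[gene] / g2[gene],
                    "informative": int(informative[gene]),
                    "tpm": float(tpm[gene]),
                }
            )
    out = pd.DataFrame(rows, columns=["gene", "library", "xi_fraction", "xi_odds", "informative", "tpm"])
    out.attrs["omitted"] = pd.DataFrame(omitted, columns=["gene", "library", "reason"])
    return out


def allelic_tpm(
    expression: ExpressionTable, matrix: AllelicCountMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split diploid TPM into (Xi, Xa) components by informative-read fractions.

    Genes with no informative reads in a library get NaN in both.
    """
    informative = (matrix.g1 + matrix.g2).astype(float)
    frac_xi = matrix.g1 / informative.replace(0, np.nan)
    tpm = expression.tpm
    return tpm * frac_xi, tpm * (1.0 - frac_xi)


def escape_call(xi_fraction, threshold: float = ESCAPE_XI_THRESHOLD):
    """Escape iff the Xi fraction reaches the threshold (vectorized)."""
    return np.asarray(xi_fraction) >= threshold


def fold_change_calls(
    expr_wt: pd.DataFrame | ExpressionTable,
    expr_ko: pd.DataFrame | ExpressionTable,
    counts_wt: AllelicCountMatrix | None = None,
    counts_ko: AllelicCountMatrix | None = None,
    scope: str = "diploid",
    threshold: float = FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Classify per-gene KO/wt TPM fold changes at a given allele scope.

    ``scope`` is ``'diploid'`` (total TPM), ``'xi'`` or ``'xa'``
    (allelic TPM; requires the count matrices).  Replicate libraries are
    averaged per condition before the fold is taken.  Genes whose wt
    mean is zero with nonzero KO are reported as infinite fold,
    ``increased`` and flagged; genes undefined at the requested scope
    are dropped.  ``.attrs['summary']`` holds the increased/decreased
    fractions.
    """
    if scope not in ("diploid", "xi", "xa"):
        raise ConfigurationError(f"unknown scope {scope!r}")
    tpm_wt = expr_wt.tpm if isinstance(expr_wt, ExpressionTable) else expr_wt
    tpm_ko = expr_ko.tpm if isinstance(expr_ko, ExpressionTable) else expr_ko
    if scope != "diploid":
        if counts_wt is None or counts_ko is None:
            raise ConfigurationError("allelic scopes require count matrices")
        xi_wt, xa_wt = allelic_tpm(
            ExpressionTable(tpm=tpm_wt, cpm=tpm_wt, lengths=pd.Series(dtype=float)), counts_wt
        )
        xi_ko, xa_ko = allelic_tpm(
            ExpressionTable(tpm=tpm_ko, cpm=tpm_ko, lengths=pd.Series(dtype=float)), counts_ko
        )
        tpm_wt = xi_wt if scope == "xi" else xa_wt
        tpm_ko = xi_ko if scope == "xi" else xa_ko
    mean_wt = tpm_wt.mean(axis=1)
    mean_ko = tpm_ko.mean(axis=1)
    genes = mean_wt.index.intersection(mean_ko.index)
    rows = []
    for gene in genes:
        w, k = mean_wt[gene], mean_ko[gene]
        if np.isnan(w) or np.isnan(k):
            continue
        flagged = False
        if w == 0:
            if k == 0:
                continue
            fold, call, flagged = np.inf, "increased", True
        else:
            fold = k / w
            if fold >= threshold:
                call = "increased"
            elif fold <= 1.0 / threshold:
                call = "decreased"
            else:
                call = "unchanged"
        rows.append(
            {
                "gene": gene,
                "scope": scope,
                "fold": fold,
                "log2_fold": np.log2(fold) if fold > 0 else -np.inf,
                "call": call,
                "flagged": flagged,
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "scope", "fold", "log2_fold", "call", "flagged"])
    n = max(len(out), 1)
    out.attrs["summary"] = {
        "n": len(out),
        "n_increased": int((out["call"] == "increased").sum()) if len(out) else 0,
        "n_decreased": int((out["call"] == "decreased").sum()) if len(out) else 0,
        "pct_increased": 100.0 * (out["call"] == "increased").sum() / n,
        "pct_decreased": 100.0 * (out["call"] == "decreased").sum() / n,
    }
    return out


def silencing_class_summary(
    conditions: dict[str, tuple[ExpressionTable, AllelicCountMatrix]],
    classes: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median Xi / Xa expression per silencing class and condition.

    ``classes`` maps gene id -> class in {early, intermediate, late,
    escape}; unknown labels raise.  Returns (summary, escape_folds)
    where ``escape_folds`` is the per-gene Xi fold-change table of the
    escape class across conditions (first condition as reference).
    """
    valid = {"early", "intermediate", "late", "escape"}
    bad = set(classes.values()) - valid
    if bad:
        raise ConfigurationError(f"unknown silencing class labels: {sorted(bad)}")
    rows = []
    xi_medians_by_cond: dict[str, pd.Series] = {}
    for cond, (expr, matrix) in conditions.items():
        xi, xa = allelic_tpm(expr, matrix)
        xi_mean = xi.mean(axis=1)
        xa_mean = xa.mean(axis=1)
        xi_medians_by_cond[cond] = xi_mean
        for cls in ("early", "intermediate", "late", "escape"):
            members = [g for g, c in classes.items() if c == cls and g in xi_mean.index]
            members = [g for g in members if not np.isnan(xi_mean[g])]
            rows.append(
                {
                    "silencing_class": cls,
                    "condition": cond,
                    "median_xi": float(np.median([xi_mean[g] for g in members])) if members else np.nan,
                    "median_xa": float(np.median([xa_mean[g] for g in members])) if members else np.nan,
                    "n": len(members),
                }
            )
    summary = pd.DataFrame(rows)
    cond_names = list(conditions)
    escape_genes = [g for g, c in classes.items() if c == "escape"]
    fold_rows = []
    if len(cond_names) >= 2:
        ref = xi_medians_by_cond[cond_names[0]]
        for cond in cond_names[1:]:
            cur = xi_medians_by_cond[cond]
            for g in escape_genes:
                if g in ref.index and g in cur.index and ref[g] and not np.isnan(ref[g]):
                    fold_rows.append(
                        {"gene": g, "condition": cond, "xi_fold": float(cur[g] / ref[g])}
                    )
    escape_folds = pd.DataFrame(fold_rows, columns=["gene", "condition", "xi_fold"])
    return summary, escape_folds


def induction_contrast(
    expr_a: ExpressionTable | pd.DataFrame,
    expr_b: ExpressionTable | pd.DataFrame,
    gene: str,
) -> dict:
    """TPM fold change of one gene between two timepoints (B relative to A).

    Replicate libraries are averaged within each timepoint.  A zero
    baseline with nonzero later expression is reported as infinite fold
    and flagged.
    """
    tpm_a = expr_a.tpm if isinstance(expr_a, ExpressionTable) else expr_a
    tpm_b = expr_b.tpm if isinstance(expr_b, ExpressionTable) else expr_b
    a = float(tpm_a.loc[gene].mean())
    b = float(tpm_b.loc[gene].mean())
    if a == 0:
        return {"gene": gene, "fold": np.inf if b > 0 else np.nan,
                "log2_fold": np.inf if b > 0 else np.nan, "flagged": True}
    fold = b / a
    return {
        "gene": gene,
        "fold": fold,
        "log2_fold": float(np.log2(fold)) if fold > 0 else -np.inf,
        "flagged": False,
    }
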