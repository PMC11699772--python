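"""End-to-end study scenarios on synthetic hybrid-cross data.

Each function builds a generator configuration that mirrors one facet
of the study design (allelic-ratio recovery across silencing levels,
the Xi-specific response to knockout, Xist induction, planted Cut&Run
domains, differential-expression calibration), runs the full pipeline
on it, and returns the measured quantities next to the planted truth.
Problem sizes are desk-scale: tens of genes, a few hundred kilobases,
and 10^5-10^6 reads per scenario, which the methods note documents as
the package's reference conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .peaks import Peak, call_peaks, xi_specific_gains
from .pseudogenome import build_pseudogenomes, filter_variants
from .quantify import AllelicCountMatrix, count_reads, differential_expression, tpm
from .report import allelic_ratios, fold_change_calls, induction_contrast
from .simulate import (
    ChromosomeSpec,
    PlantedDomain,
    SimulationConfig,
    XCIProgram,
    simulate_annotation,
    simulate_count_matrix,
    simulate_cutrun,
    simulate_hybrid_reference,
    simulate_rnaseq,
)
from .tagging import AlleleTag, filter_alignment, filter_pair, tag_library
from .tracks import rpkm_track


def build_world(config: SimulationConfig, program: XCIProgram | None = None):
    """Reference, filtered SNPs, pseudo-genomes and annotation for a config."""
    reference, calls = simulate_hybrid_reference(config)
    snps, summary = filter_variants(calls)
    pair = build_pseudogenomes(reference, snps)
    genes = simulate_annotation(config, program)
    return reference, calls, snps, summary, pair, genes


def _resolved_table(genes: list[GeneModel], xi_fraction: dict[str, float]) -> pd.DataFrame:
    """A minimal per-gene program table with unit weights."""
    return pd.DataFrame(
        {
            "xi_fraction": [xi_fraction.get(g.gene_id, 0.5) for g in genes],
            "weight": 1.0,
        },
        index=[g.gene_id for g in genes],
    )


# ------------------------------------------------------- tagging fidelity


def tagging_world(seed: int, n_reads: int = 10_000, error_rate: float = 0.0):
    """Error-free single-library world for tagging-oracle checks.

    Returns (pair, snps, genes, records, truth, tagged, summary).
    """
    config = SimulationConfig(
        seed=seed,
        chromosomes=(ChromosomeSpec("chrX", 100_000, is_x=True),),
        genes_per_chromosome=16,
        sequencing_error_rate=error_rate,
    )
    _, _, snps, _, pair, genes = build_world(config)
    resolved = _resolved_table(genes, {g.gene_id: 0.3 for g in genes})
    records, truth = simulate_rnaseq(
        pair, genes, resolved, config, "lib0", stream=0, total_reads=n_reads
    )
    tagged, summary = tag_library(records, snps, mode="rna", library="lib0")
    return pair, snps, genes, records, truth, tagged, summary


def tagging_accuracy(seed: int, n_reads: int = 10_000) -> dict:
    """Fraction of informative error-free reads tagged with the true haplotype."""
    _, _, _, _, truth, tagged, summary = tagging_world(seed, n_reads, error_rate=0.0)
    truth_hap = dict(zip(truth["read_id"], truth["haplotype"]))
    n_informative = 0
    n_correct = 0
    for ta in tagged:
        if ta.tag in (AlleleTag.G1, AlleleTag.G2):
            n_informative += 1
            want = AlleleTag.G1 if truth_hap[ta.read_id] == 1 else AlleleTag.G2
            if ta.tag is want:
                n_correct += 1
    return {
        "n_passed": summary.passed,
        "n_informative": n_informative,
        "pct_correct": 100.0 * n_correct / max(n_informative, 1),
        "partition_ok": sum(summary.tags.values()) == summary.passed,
    }


# --------------------------------------------------- allelic-ratio recovery

RATIO_RECOVERY_FRACTIONS = (0.0, 0.02, 0.3, 0.5)


def ratio_recovery(seed: int, n_seeds: int = 20, reads_per_gene: int = 1500) -> pd.DataFrame:
    """Recover planted Xi fractions from the full tagging + counting path.

    Sixteen X-linked genes (four per planted fraction) per seed; one
    library per seed.  Returns a per-gene table of planted vs estimated
    Xi fraction with informative-read counts.
    """
    rows = []
    for k in range(n_seeds):
        config = SimulationConfig(
            seed=seed + k,
            chromosomes=(ChromosomeSpec("chrX", 100_000, is_x=True),),
            genes_per_chromosome=16,
            reads_per_gene=reads_per_gene,
        )
        _, _, snps, _, pair, genes = build_world(config)
        planted = {
            g.gene_id: RATIO_RECOVERY_FRACTIONS[i % len(RATIO_RECOVERY_FRACTIONS)]
            for i, g in enumerate(genes)
        }
        records, _ = simulate_rnaseq(
            pair, genes, _resolved_table(genes, planted), config, "lib0", stream=0
        )
        tagged, _ = tag_library(records, snps, mode="rna")
        lc = count_reads(tagged, genes)
        matrix = AllelicCountMatrix.from_libraries({"lib0": lc})
        expr = tpm(matrix, genes)
        ratios = allelic_ratios(matrix, expr, min_tpm=1.0)
        for _, r in ratios.iterrows():
            rows.append(
                {
                    "seed": seed + k,
                    "gene": r["gene"],
                    "true_xi": planted[r["gene"]],
                    "est_xi": r["xi_fraction"],
                    "informative": r["informative"],
                }
            )
    return pd.DataFrame(rows)


def ratio_recovery_metrics(table: pd.DataFrame, min_informative: int = 200) -> dict:
    sub = table[table["informative"] >= min_informative]
    err = (sub["est_xi"] - sub["true_xi"]).abs()
    return {
        "n_genes": int(len(sub)),
        "pct_within_0_05": 100.0 * float((err <= 0.05).mean()) if len(sub) else np.nan,
        "max_abs_error": float(err.max()) if len(sub) else np.nan,
        "mean_abs_error": float(err.mean()) if len(sub) else np.nan,
    }


# ------------------------------------------------------- Xi-scope asymmetry


def xi_asymmetry(seed: int, reads_per_gene: int = 4000) -> dict:
    """KO raising Xi output 1.5x in 80% of silenced X genes.

    Simulates three replicate libraries per condition (mirroring a
    two-wt-plus-CRISPR-control design) at the differentiated timepoint;
    silenced genes retain a 0.14 Xi fraction in wt.  Libraries are
    tagged and counted, and KO/wt folds are classified at the Xi and Xa
    scopes with the 1.25-fold rule.  Replicate number and depth are set
    so the Xi-scope fold estimate of a perturbed gene has a log2
    standard error of ~0.1, keeping the planted 1.5-fold shift (≈1.45
    in TPM space after compositional renormalisation) more than two
    standard errors above the 1.25 call threshold.
    """
    config = SimulationConfig(
        seed=seed,
        chromosomes=(
            ChromosomeSpec("chrX", 250_000, is_x=True),
            ChromosomeSpec("chr5", 250_000),
        ),
        genes_per_chromosome=40,
        reads_per_gene=reads_per_gene,
    )
    _, _, snps, _, pair, genes = build_world(config)
    x_genes = [g for g in genes if g.chrom == "chrX" and not g.is_xist]
    auto_genes = [g for g in genes if g.chrom == "chr5"][:10]
    genes = x_genes + auto_genes
    f_wt = 0.14
    k = 1.5
    n_pert = int(round(0.8 * len(x_genes)))
    perturbed = {g.gene_id for g in x_genes[:n_pert]}
    f_ko = k * f_wt / (1 - f_wt + k * f_wt)
    wt_xi = {g.gene_id: (f_wt if g in x_genes else 0.5) for g in genes}
    ko_xi = {
        g.gene_id: (f_ko if g.gene_id in perturbed else (f_wt if g in x_genes else 0.5))
        for g in genes
    }
    resolved_wt = _resolved_table(genes, wt_xi)
    resolved_ko = _resolved_table(genes, ko_xi)
    # perturbed genes emit more transcripts (Xi output adds to the total)
    resolved_ko.loc[list(perturbed), "weight"] = 1 - f_wt + k * f_wt
    libraries = {}
    for i, (cond, resolved) in enumerate(
        [("wt", resolved_wt)] * 3 + [("ko", resolved_ko)] * 3
    ):
        lib = f"{cond}{i % 3 + 1}"
        records, _ = simulate_rnaseq(pair, genes, resolved, config, lib, stream=i)
        tagged, _ = tag_library(records, snps, mode="rna")
        libraries[(cond, lib)] = count_reads(tagged, genes)
    wt_matrix = AllelicCountMatrix.from_libraries(
        {lib: lc for (cond, lib), lc in libraries.items() if cond == "wt"}
    )
    ko_matrix = AllelicCountMatrix.from_libraries(
        {lib: lc for (cond, lib), lc in libraries.items() if cond == "ko"}
    )
    expr_wt = tpm(wt_matrix, genes)
    expr_ko = tpm(ko_matrix, genes)
    out = {"perturbed": perturbed, "x_genes": [g.gene_id for g in x_genes]}
    for scope in ("xi", "xa"):
        calls = fold_change_calls(
            expr_wt, expr_ko, wt_matrix, ko_matrix, scope=scope
        )
        sub = calls[calls["gene"].isin(perturbed)]
        out[scope] = {
            "n_perturbed_called": int(len(sub)),
            "n_increased": int((sub["call"] == "increased").sum()),
            "n_decreased": int((sub["call"] == "decreased").sum()),
            "pct_increased": 100.0 * (sub["call"] == "increased").mean() if len(sub) else np.nan,
        }
    return out


# --------------------------------------------------------- Xist induction


def xist_induction(seed: int, n_seeds: int = 20, reads_per_library: int = 10_000) -> pd.DataFrame:
    """Estimate the planted Xist differentiation-induction factors.

    One library per condition x timepoint per seed, default program
    (wt 6.0-fold, KO 2.5-fold on the Xist-like locus's transcriptome
    share).  Reads are simulated without sequences (the contrast is
    diploid TPM; no tagging involved).
    """
    rows = []
    for kseed in range(n_seeds):
        config = SimulationConfig(
            seed=seed + kseed,
            chromosomes=(
                ChromosomeSpec("chr9", 120_000),
                ChromosomeSpec("chrX", 120_000, is_x=True),
            ),
            genes_per_chromosome=12,
        )
        program = XCIProgram()
        _, _, snps, _, pair, genes = build_world(config, program)
        table = program.realize(genes, config)
        xist_gene = next(g.gene_id for g in genes if g.is_xist)
        expr = {}
        for i, (cond, tp) in enumerate(
            [("wt", "D0"), ("wt", "D15"), ("ko", "D0"), ("ko", "D15")]
        ):
            resolved = program.resolve(table, cond, tp)
            records, _ = simulate_rnaseq(
                pair, genes, resolved, config, f"{cond}_{tp}", stream=i,
                total_reads=reads_per_library, with_sequences=False,
            )
            lc = count_reads(records, genes)
            matrix = AllelicCountMatrix.from_libraries({f"{cond}_{tp}": lc})
            expr[(cond, tp)] = tpm(matrix, genes)
        for cond in ("wt", "ko"):
            res = induction_contrast(expr[(cond, "D0")], expr[(cond, "D15")], xist_gene)
            rows.append(
                {
                    "seed": seed + kseed,
                    "condition": cond,
                    "fold": res["fold"],
                    "true_fold": program.xist_induction[cond],
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------- peak recovery


def _jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def match_peaks(
    peaks: list[Peak], domains: list[PlantedDomain], min_jaccard: float = 0.5
) -> tuple[int, int, int]:
    """(n_matched_domains, n_matched_peaks, n_peaks) at Jaccard matching."""
    matched_domains = 0
    matched_peaks = set()
    for d in domains:
        for i, p in enumerate(peaks):
            if p.chrom == d.chrom and _jaccard((p.start, p.end), (d.start, d.end)) >= min_jaccard:
                matched_domains += 1
                matched_peaks.add(i)
                break
    return matched_domains, len(matched_peaks), len(peaks)


def _filtered_fragments(pairs, min_mapq: int = 30, max_fragment: int = 1000):
    kept = []
    for r1, r2 in pairs:
        ok, _ = filter_pair(r1, r2, max_fragment)
        if ok and filter_alignment(r1, min_mapq)[0] and filter_alignment(r2, min_mapq)[0]:
            kept.append((r1, r2))
    return kept


def peak_recovery(
    seed: int,
    n_seeds: int = 20,
    n_fragments: int = 10_000,
    enrichment: float = 8.0,
    bin_size: int = 50,
) -> dict:
    """Recall/precision of planted Cut&Run domains over repeated simulations.

    Five 1-kb domains on a 500-kb chromosome (~20 kept fragments/kb
    genome-wide), called against an IgG background of equal depth.
    """
    chrom_len = 500_000
    domains = [
        PlantedDomain("chr7", s, s + 1000, enrichment) for s in range(50_000, 500_000, 100_000)
    ]
    n_dom_matched = n_peak_matched = n_peaks_total = 0
    for k in range(n_seeds):
        config = SimulationConfig(
            seed=seed + k,
            chromosomes=(ChromosomeSpec("chr7", chrom_len),),
            snp_density=0.0,
            cutrun_fragments=n_fragments,
        )
        reference, _ = simulate_hybrid_reference(config)
        pair = build_pseudogenomes(reference, filter_variants([])[0])
        treat, _ = simulate_cutrun(pair, config, domains, "h3k27me3", stream=0, with_sequences=False)
        igg, _ = simulate_cutrun(pair, config, [], "igg", stream=1, with_sequences=False)
        lengths = config.chrom_lengths
        t_track = rpkm_track(_filtered_fragments(treat), lengths, bin_size, unit="fragment")
        c_track = rpkm_track(_filtered_fragments(igg), lengths, bin_size, unit="fragment")
        peaks = call_peaks(t_track, control=c_track, threshold_quantile=0.99, min_width=400)
        md, mp, np_ = match_peaks(peaks, domains)
        n_dom_matched += md
        n_peak_matched += mp
        n_peaks_total += np_
    return {
        "n_domains": len(domains) * n_seeds,
        "recall": n_dom_matched / (len(domains) * n_seeds),
        "precision": n_peak_matched / max(n_peaks_total, 1),
        "n_peaks": n_peaks_total,
    }


# ------------------------------------------------------------- Xi gains


def xi_gain_calling(seed: int, n_fragments: int = 8000, bin_size: int = 200) -> dict:
    """KO-only planted Xi domains recovered by wt-as-background calling.

    Simulates allele-skewed (95% haplotype-1) domains present only in
    the KO Cut&Run library, builds G1-restricted RPKM tracks for both
    conditions, calls KO peaks using the wt track as the control, and
    reports the gains.
    """
    chrom, chrom_len = "chrX", 300_000
    domains = [
        PlantedDomain(chrom, s, s + 2000, 10.0, hap1_fraction=0.95)
        for s in (40_000, 110_000, 180_000, 250_000)
    ]
    config = SimulationConfig(
        seed=seed,
        chromosomes=(ChromosomeSpec(chrom, chrom_len, is_x=True),),
        cutrun_fragments=n_fragments,
    )
    reference, calls = simulate_hybrid_reference(config)
    snps, _ = filter_variants(calls)
    pair = build_pseudogenomes(reference, snps)
    ko_pairs, _ = simulate_cutrun(pair, config, domains, "ko", stream=0)
    wt_pairs, _ = simulate_cutrun(pair, config, [], "wt", stream=1)
    lengths = config.chrom_lengths
    tracks = {}
    for name, lib_pairs in (("ko", ko_pairs), ("wt", wt_pairs)):
        tagged, _ = tag_library(lib_pairs, snps, mode="cutrun", library=name)
        g1 = [ta for ta in tagged if ta.tag is AlleleTag.G1]
        tracks[name] = rpkm_track(g1, lengths, bin_size, unit="fragment")
    # allele-restricted coverage is patchy (SNP deserts give untaggable
    # stretches), so wider bins + bridging are used to ride over holes
    ko_peaks = call_peaks(
        tracks["ko"], control=tracks["wt"], threshold_quantile=0.99,
        min_width=400, bridge_gap_bins=2, source="ko",
    )
    wt_peaks = call_peaks(
        tracks["wt"], threshold_quantile=0.999, min_width=300, source="wt"
    )
    report = xi_specific_gains(ko_peaks, wt_peaks, chrom, chrom_len)
    md, mp, np_ = match_peaks(report.gained, domains)
    return {
        "n_planted": len(domains),
        "n_gained": len(report.gained),
        "n_matched": md,
        "covered_fraction": report.covered_fraction,
        "analytic_fraction": sum(p.width for p in report.gained) / chrom_len,
    }


# ---------------------------------------------------------- DE calibration


def de_calibration(seed: int, n_seeds: int = 20) -> dict:
    """Null FDR behaviour and power of the DE substitute.

    Null: 400 genes, 3 vs 3 libraries, no planted differences.  Power:
    10% of genes planted at 4-fold, measured against the truth flags.
    """
    null_fractions = []
    for k in range(n_seeds):
        counts, _, groups = simulate_count_matrix(seed + k, de_fraction=0.0)
        res = differential_expression(counts, groups, reference="ref", test_group="test")
        null_fractions.append(float((res["fdr"] <= 0.1).mean()))
    powers = []
    false_rates = []
    for k in range(n_seeds):
        counts, truth, groups = simulate_count_matrix(
            seed + 1000 + k, de_fraction=0.1, de_log2_fold=2.0
        )
        res = differential_expression(counts, groups, reference="ref", test_group="test")
        powers.append(float(res.loc[truth, "de"].mean()))
        false_rates.append(float(res.loc[~truth, "de"].mean()))
    return {
        "null_fdr_fraction_mean": float(np.mean(null_fractions)),
        "power_mean": float(np.mean(powers)),
        "false_flag_rate_mean": float(np.mean(false_rates)),
    }
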