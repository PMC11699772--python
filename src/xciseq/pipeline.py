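"""End-to-end orchestration: simulate -> pseudo-genome -> tag -> quantify
-> peaks -> XCI report, with all tables written to an output directory
and a checksummed run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import io
from .errors import XciseqError
from .peaks import call_peaks, write_bed6, xi_specific_gains
from .pseudogenome import build_pseudogenomes, filter_variants
from .quantify import AllelicCountMatrix, count_reads, differential_expression, tpm
from .report import allelic_ratios, fold_change_calls, induction_contrast, silencing_class_summary
from .simulate import (
    PlantedDomain,
    SimulationConfig,
    XCIProgram,
    simulate_annotation,
    simulate_cutrun,
    simulate_hybrid_reference,
    simulate_rnaseq,
)
from .tagging import AlleleTag, tag_library
from .tracks import rpkm_track


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(
    outdir: str,
    config: SimulationConfig | None = None,
    program: XCIProgram | None = None,
    replicates: int = 2,
    cutrun_fragments: int | None = None,
    write_alignments: bool = False,
) -> dict:
    """Run the full synthetic study end to end.

    Stages: hybrid reference + variants -> variant filtering ->
    pseudo-genomes -> annotation -> RNA-seq libraries (wt/ko x D0/D15 x
    replicates) -> tagging -> counting -> TPM -> allelic ratios,
    fold-change calls, silencing-class summary, Xist induction ->
    Cut&Run libraries -> G1 tracks -> wt-as-background Xi peak gains.
    All tables are written under ``outdir`` together with a manifest
    listing every output file with its SHA-256 checksum.

    Any stage failure is re-raised with the stage name; outputs written
    so far are retained.
    """
    config = config or SimulationConfig()
    program = program or XCIProgram()
    os.makedirs(outdir, exist_ok=True)
    outputs: list[str] = []
    stage = "init"

    def emit(name: str) -> str:
        path = os.path.join(outdir, name)
        outputs.append(path)
        return path

    try:
        stage = "simulate_reference"
        reference, calls = simulate_hybrid_reference(config)
        io.write_fasta(reference, emit("reference.fa"))
        io.write_vcf(calls, config.chrom_lengths, emit("variants.vcf"))

        stage = "pseudogenome"
        snps, filter_summary = filter_variants(calls)
        pair = build_pseudogenomes(reference, snps)
        io.write_fasta(pair.genome_g1, emit("pseudo_g1.fa"))
        io.write_fasta(pair.genome_g2, emit("pseudo_g2.fa"))
        _write_table(
            pd.DataFrame([dataclasses.asdict(r) for r in snps.records()]),
            emit("retained_snps.tsv"),
        )
        with open(emit("filter_summary.txt"), "w") as fh:
            fh.write(f"input\t{filter_summary.n_input}\n")
            fh.write(f"retained\t{filter_summary.n_retained}\n")
            for reason, n in filter_summary.removed.items():
                fh.write(f"removed_{reason}\t{n}\n")

        stage = "annotation"
        genes = simulate_annotation(config, program)
        io.write_bed12(genes, emit("genes.bed12"))
        table = program.realize(genes, config)
        _write_table(table.reset_index(), emit("gene_program_truth.tsv"))
        classes = {
            g: c
            for g, c in table["silencing_class"].items()
            if isinstance(c, str)
        }
        _write_table(
            pd.DataFrame(sorted(classes.items()), columns=["gene", "silencing_class"]),
            emit("silencing_classes.tsv"),
        )

        stage = "rnaseq"
        lib_specs = [
            (cond, tp, rep)
            for cond in ("wt", "ko")
            for tp in ("D0", "D15")
            for rep in range(1, replicates + 1)
        ]
        counts: dict[tuple[str, str], dict] = {}
        summaries = []
        for i, (cond, tp, rep) in enumerate(lib_specs):
            lib = f"{cond}_{tp}_r{rep}"
            resolved = program.resolve(table, cond, tp)
            records, truth = simulate_rnaseq(pair, genes, resolved, config, lib, stream=i)
            if write_alignments:
                io.write_sam(records, config.chrom_lengths, emit(f"{lib}.sam"))
            tagged, summary = tag_library(records, snps, mode="rna", library=lib)
            summaries.append(summary.to_row())
            counts.setdefault((cond, tp), {})[lib] = count_reads(tagged, genes)
        _write_table(pd.DataFrame(summaries), emit("allelic_mapping_summary.tsv"))

        stage = "quantify"
        matrices = {
            key: AllelicCountMatrix.from_libraries(libs) for key, libs in counts.items()
        }
        expr = {key: tpm(matrix, genes) for key, matrix in matrices.items()}
        for (cond, tp), matrix in matrices.items():
            _write_table(matrix.total, emit(f"counts_total_{cond}_{tp}.tsv"), index=True)
            _write_table(expr[(cond, tp)].tpm, emit(f"tpm_{cond}_{tp}.tsv"), index=True)
        d15 = pd.concat(
            [matrices[("wt", "D15")].total, matrices[("ko", "D15")].total], axis=1
        )
        groups = {lib: ("wt" if lib.startswith("wt") else "ko") for lib in d15.columns}
        deg = differential_expression(d15, groups)
        _write_table(deg.reset_index(names="gene"), emit("differential_expression_D15.tsv"))

        stage = "xci_report"
        ratios = allelic_ratios(matrices[("ko", "D15")], expr[("ko", "D15")])
        _write_table(ratios, emit("allelic_ratios_ko_D15.tsv"))
        for scope in ("diploid", "xi", "xa"):
            calls_df = fold_change_calls(
                expr[("wt", "D15")], expr[("ko", "D15")],
                matrices[("wt", "D15")], matrices[("ko", "D15")], scope=scope,
            )
            _write_table(calls_df, emit(f"fold_change_{scope}_D15.tsv"))
        summary_df, escape_folds = silencing_class_summary(
            {
                "wt": (expr[("wt", "D15")], matrices[("wt", "D15")]),
                "ko": (expr[("ko", "D15")], matrices[("ko", "D15")]),
            },
            classes,
        )
        _write_table(summary_df, emit("silencing_class_summary.tsv"))
        _write_table(escape_folds, emit("escape_gene_xi_folds.tsv"))
        xist = next((g.gene_id for g in genes if g.is_xist), None)
        if xist:
            rows = []
            for cond in ("wt", "ko"):
                res = induction_contrast(expr[(cond, "D0")], expr[(cond, "D15")], xist)
                res["condition"] = cond
                rows.append(res)
            _write_table(pd.DataFrame(rows), emit("xist_induction.tsv"))

        stage = "cutrun"
        x_chrom = next((c.name for c in config.chromosomes if c.is_x), None)
        if x_chrom is not None:
            length = config.chrom_lengths[x_chrom]
            step = length // 4
            domains = [
                PlantedDomain(x_chrom, s, s + 2000, 8.0, hap1_fraction=0.95)
                for s in range(step // 2, length - 2000, step)
            ]
            n_frag = cutrun_fragments or config.cutrun_fragments
            tracks = {}
            for i, (name, doms) in enumerate(
                [("ko", domains), ("wt", []), ("igg", [])]
            ):
                frag_pairs, _ = simulate_cutrun(
                    pair, config, doms, name, stream=100 + i, n_fragments=n_frag
                )
                tagged, _ = tag_library(frag_pairs, snps, mode="cutrun", library=name)
                g1 = [ta for ta in tagged if ta.tag is AlleleTag.G1]
                # allelic coverage is patchy at SNP deserts: 200-bp bins
                tracks[name] = rpkm_track(g1, config.chrom_lengths, 200, unit="fragment")
                io.write_bedgraph(tracks[name], emit(f"cutrun_{name}_g1.bedgraph"))
            ko_peaks = call_peaks(
                tracks["ko"], control=tracks["wt"], threshold_quantile=0.99,
                min_width=400, bridge_gap_bins=2, source="ko",
            )
            wt_peaks = call_peaks(
                tracks["wt"], threshold_quantile=0.999, min_width=300, source="wt"
            )
            write_bed6(ko_peaks, emit("peaks_ko_g1.bed"))
            write_bed6(wt_peaks, emit("peaks_wt_g1.bed"))
            gains = xi_specific_gains(
                [p for p in ko_peaks if p.chrom == x_chrom],
                [p for p in wt_peaks if p.chrom == x_chrom],
                x_chrom, length, genes,
            )
            with open(emit("xi_gain_report.tsv"), "w") as fh:
                fh.write("chrom\tstart\tend\ttotal_signal\n")
                for p in gains.gained:
                    fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.total_signal:.6g}\n")
                fh.write(f"# covered_fraction\t{gains.covered_fraction:.6g}\n")
                fh.write(f"# context_counts\t{json.dumps(gains.context_counts)}\n")
    except XciseqError as exc:
        raise XciseqError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "manifest"
    import xciseq

    manifest = {
        "created": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "versions": {
            "xciseq": xciseq.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
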