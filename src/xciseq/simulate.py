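"""Synthetic hybrid-cross data generator.

Emulates the data a 129 x cast hybrid ES-cell study produces, at desk
scale: a two-haplotype genome with configurable SNP density (plus
indels and low-quality records to exercise variant filtering), X-linked
genes with per-gene Xi-expression fractions by silencing class and
condition, RNA-seq reads sampled from known haplotypes, and Cut&Run
fragment pairs with planted enriched domains, length/chimera violations
and an IgG background.

Haplotype 1 is the maternal / Xi strain analog (the Tsix-stop design
forces the 129 X to become the Xi), haplotype 2 the cast analog.
Alignments are emitted directly with true placement coordinates; MAPQ
is assigned by the generator so the MAPQ >= 30 filter is exercised
deterministically.  All randomness flows from ``config.seed`` through
per-operation substreams, so identical configs produce byte-identical
outputs.

Expression programs are planted in transcriptome-share space (a gene's
fraction of the library), because share is what TPM measures: the
Xist-like locus's differentiation-induction factor multiplies its
share, with the remaining genes rescaled so total abundance is
conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AlignmentRecord, ReadPair
from .annotation import GeneModel
from .errors import ConfigurationError, DataError
from .pseudogenome import PseudoGenomePair, VariantCall

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# rng substream ids
_S_REFERENCE = 1
_S_ANNOTATION = 2
_S_RNA = 3
_S_CUTRUN = 4
_S_COUNTS = 5
_S_PROGRAM = 6


@dataclass(frozen=True, slots=True)
class ChromosomeSpec:
    name: str
    length: int
    is_x: bool = False


@dataclass(slots=True)
class SimulationConfig:
    """Study-condition knobs for the generator.

    Defaults emulate a 129 x cast cross at desk scale: the strain SNP
    density (~1 diagnostic SNP per 125 bp), 75 bp single-end RNA-seq
    reads, ~180 bp Cut&Run fragments with a small >1 kb heavy tail, and
    a low per-base sequencing error rate.
    """

    seed: int = 0
    chromosomes: tuple[ChromosomeSpec, ...] = (
        ChromosomeSpec("chr1", 200_000),
        ChromosomeSpec("chrX", 200_000, is_x=True),
    )
    snp_density: float = 0.008
    indel_fraction: float = 0.10
    lowqual_fraction: float = 0.10
    genes_per_chromosome: int = 20
    exons_per_gene: int = 3
    exon_length: int = 300
    intron_length: int = 200
    read_length: int = 75
    sequencing_error_rate: float = 0.002
    low_mapq_fraction: float = 0.05
    reads_per_gene: int = 600
    replicate_log_sd: float = 0.05
    fragment_mean: float = 180.0
    fragment_sd: float = 40.0
    heavy_tail_fraction: float = 0.02
    chimera_fraction: float = 0.01
    cutrun_fragments: int = 8000

    def __post_init__(self) -> None:
        for spec in self.chromosomes:
            if spec.length <= 0:
                raise ConfigurationError(f"chromosome {spec.name}: length must be > 0")
        for name in (
            "snp_density",
            "indel_fraction",
            "lowqual_fraction",
            "sequencing_error_rate",
            "low_mapq_fraction",
            "heavy_tail_fraction",
            "chimera_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} not in [0, 1]")
        if self.read_length <= 0 or self.exon_length <= self.read_length:
            raise ConfigurationError("exon_length must exceed read_length")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    def rng(self, stream: int, sub: int | None = None) -> np.random.Generator:
        key = [self.seed, stream] if sub is None else [self.seed, stream, sub]
        return np.random.default_rng(key)


@dataclass(frozen=True, slots=True)
class PlantedDomain:
    """A Cut&Run enrichment domain with optional allelic skew."""

    chrom: str
    start: int
    end: int
    enrichment: float
    hap1_fraction: float = 0.5


# --------------------------------------------------------------- genome


def simulate_hybrid_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[VariantCall]]:
    """Random reference sequences plus strain-variant records.

    Variant sites are placed by an independent Bernoulli(snp_density)
    per base.  ``indel_fraction`` of records are emitted as indels and
    ``lowqual_fraction`` of the SNPs carry a LowQual filter flag — both
    exist only to exercise the variant filter.  Either strain allele
    may equal the reference (as in a real strain VCF); retained records
    always have differing strain alleles.
    """
    rng = config.rng(_S_REFERENCE)
    reference: dict[str, str] = {}
    calls: list[VariantCall] = []
    for spec in config.chromosomes:
        codes = rng.integers(0, 4, spec.length)
        seq_arr = _BASES[codes]
        reference[spec.name] = seq_arr.tobytes().decode()
        positions = np.flatnonzero(rng.random(spec.length) < config.snp_density)
        for pos0 in positions:
            ref = seq_arr[pos0].decode()
            if rng.random() < config.indel_fraction:
                ins = ref + _BASES[rng.integers(0, 4)].decode()
                calls.append(
                    VariantCall(spec.name, int(pos0) + 1, ref, ref, ins, "PASS")
                )
                continue
            alt_choices = [b.decode() for b in _BASES if b.decode() != ref]
            alt = alt_choices[rng.integers(0, 3)]
            u = rng.random()
            if u < 0.45:
                a1, a2 = ref, alt
            elif u < 0.90:
                a1, a2 = alt, ref
            else:
                third = [b for b in alt_choices if b != alt]
                a1, a2 = alt, third[rng.integers(0, 2)]
            status = "LowQual" if rng.random() < config.lowqual_fraction else "PASS"
            calls.append(VariantCall(spec.name, int(pos0) + 1, ref, a1, a2, status))
    return reference, calls


# ----------------------------------------------------------- annotation


@dataclass(slots=True)
class XCIProgram:
    """Per-class Xi-expression program across conditions and timepoints.

    ``xi_fraction_differentiated`` gives the expected fraction of a
    gene's transcripts originating from the Xi haplotype in wt cells
    after differentiation; before differentiation every gene is
    biallelic (0.5).  In the knockout, a ``ko_perturbed_fraction`` of
    silenced-class genes have their Xi output multiplied by
    ``ko_xi_output_factor`` (escape genes by ``escape_ko_xi_factor``),
    and the Xist-like locus's differentiation induction is reduced from
    the wt factor to the KO factor.
    """

    class_fractions: dict = field(
        default_factory=lambda: {
            "early": 0.3, "intermediate": 0.3, "late": 0.2, "escape": 0.2,
        }
    )
    xi_fraction_differentiated: dict = field(
        default_factory=lambda: {
            "early": 0.01, "intermediate": 0.03, "late": 0.08, "escape": 0.30,
        }
    )
    xi_fraction_undifferentiated: float = 0.5
    ko_xi_output_factor: float = 1.5
    ko_perturbed_fraction: float = 0.8
    escape_ko_xi_factor: float = 1.15
    xist_xi_fraction: float = 0.95
    xist_induction: dict = field(default_factory=lambda: {"wt": 6.0, "ko": 2.5})
    xist_base_share: float = 0.02
    expression_log_sd: float = 0.8

    def __post_init__(self) -> None:
        for f in self.xi_fraction_differentiated.values():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError("Xi fractions must be in [0, 1]")
        if not 0.0 < self.xist_base_share < 0.5:
            raise ConfigurationError("xist_base_share must be in (0, 0.5)")

    def assign_class(self, rng: np.random.Generator) -> str:
        names = list(self.class_fractions)
        p = np.array([self.class_fractions[n] for n in names], dtype=float)
        return names[rng.choice(len(names), p=p / p.sum())]

    def realize(self, genes: list[GeneModel], config: SimulationConfig) -> pd.DataFrame:
        """Draw per-gene truth: base expression weights and KO perturbation flags."""
        rng = config.rng(_S_PROGRAM)
        is_x = {c.name: c.is_x for c in config.chromosomes}
        rows = []
        for g in genes:
            rows.append(
                {
                    "gene": g.gene_id,
                    "chrom": g.chrom,
                    "is_x": is_x.get(g.chrom, False),
                    "is_xist": g.is_xist,
                    "silencing_class": g.silencing_class,
                    "length": g.transcript_length,
                }
            )
        table = pd.DataFrame(rows).set_index("gene")
        weights = rng.lognormal(0.0, self.expression_log_sd, len(table))
        table["base_weight"] = weights
        others = ~table["is_xist"]
        if table["is_xist"].any():
            w_other = table.loc[others, "base_weight"].sum()
            table.loc[table["is_xist"], "base_weight"] = (
                self.xist_base_share / (1 - self.xist_base_share) * w_other
            )
        silenced = table["silencing_class"].isin(["early", "intermediate", "late"])
        table["perturbed"] = False
        table.loc[silenced, "perturbed"] = (
            rng.random(int(silenced.sum())) < self.ko_perturbed_fraction
        )
        return table

    def resolve(
        self, table: pd.DataFrame, condition: str, timepoint: str
    ) -> pd.DataFrame:
        """Per-gene (xi_fraction, weight) for one library's condition/timepoint."""
        if condition not in self.xist_induction:
            raise ConfigurationError(f"unknown condition {condition!r}")
        out = table.copy()
        differentiated = timepoint not in ("D0", "undifferentiated")
        if not differentiated:
            out["xi_fraction"] = np.where(out["is_x"], self.xi_fraction_undifferentiated, 0.5)
            out["weight"] = out["base_weight"]
            return out
        xi = np.full(len(out), 0.5)
        mult = np.ones(len(out))
        for i, (gene, row) in enumerate(out.iterrows()):
            if not row["is_x"]:
                continue
            if row["is_xist"]:
                xi[i] = self.xist_xi_fraction
                continue
            cls = row["silencing_class"]
            if cls is None or (isinstance(cls, float) and np.isnan(cls)):
                continue
            f = self.xi_fraction_differentiated[cls]
            k = 1.0
            if condition == "ko":
                if cls == "escape":
                    k = self.escape_ko_xi_factor
                elif row["perturbed"]:
                    k = self.ko_xi_output_factor
            xi[i] = k * f / (1 - f + k * f)
            mult[i] = 1 - f + k * f
        out["xi_fraction"] = xi
        out["weight"] = out["base_weight"] * mult
        if out["is_xist"].any():
            total = out["base_weight"].sum()
            w_x = float(out.loc[out["is_xist"], "base_weight"].iloc[0])
            factor = self.xist_induction[condition]
            new_wx = factor * w_x
            others = ~out["is_xist"]
            alpha = (total - new_wx) / out.loc[others, "weight"].sum()
            if alpha <= 0:
                raise ConfigurationError("Xist induction exceeds transcriptome budget")
            out.loc[others, "weight"] *= alpha
            out.loc[out["is_xist"], "weight"] = new_wx
        return out


def simulate_annotation(
    config: SimulationConfig, program: XCIProgram | None = None
) -> list[GeneModel]:
    """Place non-overlapping multi-exon gene models on each chromosome.

    X-linked genes receive silencing classes drawn from the program's
    class fractions; one X gene (the middle slot) is designated the
    Xist-like locus.
    """
    rng = config.rng(_S_ANNOTATION)
    genes: list[GeneModel] = []
    n = config.genes_per_chromosome
    if n == 0:
        return genes
    for spec in config.chromosomes:
        slot = spec.length // n
        min_exon = config.read_length + 10
        xist_slot = n // 2 if spec.is_x else -1
        for i in range(n):
            exon_lens = rng.integers(
                max(min_exon, int(0.7 * config.exon_length)),
                int(1.3 * config.exon_length) + 1,
                config.exons_per_gene,
            )
            introns = rng.integers(
                max(20, config.intron_length // 2),
                config.intron_length + 1,
                max(config.exons_per_gene - 1, 0),
            )
            span = int(exon_lens.sum() + introns.sum())
            if span >= slot:
                raise ConfigurationError(
                    f"{n} genes of span ~{span} bp do not fit on {spec.name}"
                )
            start = i * slot + int(rng.integers(0, slot - span))
            exons = []
            pos = start
            for j, el in enumerate(exon_lens):
                exons.append((pos, pos + int(el)))
                pos += int(el)
                if j < len(introns):
                    pos += int(introns[j])
            strand = "+" if rng.random() < 0.5 else "-"
            is_xist = i == xist_slot
            cls = None
            if spec.is_x and not is_xist and program is not None:
                cls = program.assign_class(rng)
            gene_id = f"{spec.name}_Xist" if is_xist else f"{spec.name}_g{i:03d}"
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=spec.name,
                    strand=strand,
                    exons=tuple(exons),
                    silencing_class=cls,
                    is_xist=is_xist,
                )
            )
    return genes


# -------------------------------------------------------------- RNA-seq


def _apply_errors(
    seq: str, n_err: int, rng: np.random.Generator
) -> str:
    arr = bytearray(seq.encode())
    positions = rng.integers(0, len(arr), n_err)
    for p in positions:
        current = arr[p]
        choices = [b for b in b"ACGT" if b != current]
        arr[p] = choices[rng.integers(0, len(choices))]
    return arr.decode()


def simulate_rnaseq(
    pair: PseudoGenomePair,
    genes: list[GeneModel],
    resolved: pd.DataFrame,
    config: SimulationConfig,
    library_id: str,
    stream: int = 0,
    total_reads: int | None = None,
    with_sequences: bool = True,
    error_rate: float | None = None,
) -> tuple[list[AlignmentRecord], pd.DataFrame]:
    """Sample single-end reads from known haplotypes.

    Each read of an X-linked gene originates from haplotype 1 (the Xi
    strain) with probability ``resolved['xi_fraction']`` and from
    haplotype 2 otherwise; reads fall within single exons (no splice
    structure).  Returns the alignment records (with true coordinates)
    and a per-read truth table.
    """
    rng = config.rng(_S_RNA, stream)
    err_rate = config.sequencing_error_rate if error_rate is None else error_rate
    rl = config.read_length
    for g in genes:
        if g.chrom not in pair.genome_g1:
            raise DataError(f"gene {g.gene_id} chromosome {g.chrom!r} missing from genomes")
        if g.gene_id not in resolved.index:
            raise DataError(f"gene {g.gene_id} missing from resolved program")
    weights = resolved.loc[[g.gene_id for g in genes], "weight"].to_numpy(float)
    share = weights / weights.sum()
    n_total = total_reads if total_reads is not None else config.reads_per_gene * len(genes)
    lam = n_total * share
    if config.replicate_log_sd > 0:
        lam = lam * rng.lognormal(0.0, config.replicate_log_sd, len(genes))
    n_reads = rng.poisson(lam)
    records: list[AlignmentRecord] = []
    t_read, t_gene, t_hap, t_mapq, t_err = [], [], [], [], []
    for g, n_g in zip(genes, n_reads):
        if n_g == 0:
            continue
        xi = float(resolved.at[g.gene_id, "xi_fraction"])
        exon_arr = [(s, e) for s, e in g.exons if e - s >= rl]
        ew = np.array([e - s - rl + 1 for s, e in exon_arr], dtype=float)
        ew /= ew.sum()
        exon_idx = rng.choice(len(exon_arr), n_g, p=ew)
        offsets = rng.random(n_g)
        hap1 = rng.random(n_g) < xi
        low = rng.random(n_g) < config.low_mapq_fraction
        mapqs = np.where(low, rng.integers(0, 30, n_g), 60)
        n_err = (
            rng.binomial(rl, err_rate, n_g) if err_rate > 0 else np.zeros(n_g, dtype=int)
        )
        seq_g1 = pair.genome_g1[g.chrom]
        seq_g2 = pair.genome_g2[g.chrom]
        for j in range(n_g):
            s, e = exon_arr[exon_idx[j]]
            start = s + int(offsets[j] * (e - s - rl + 1))
            rid = f"{library_id}|{g.gene_id}|{j}"
            seq = None
            if with_sequences:
                src = seq_g1 if hap1[j] else seq_g2
                seq = src[start : start + rl]
                if n_err[j]:
                    seq = _apply_errors(seq, int(n_err[j]), rng)
            records.append(
                AlignmentRecord(
                    read_id=rid,
                    chrom=g.chrom,
                    start=start,
                    length=rl,
                    sequence=seq,
                    mapq=int(mapqs[j]),
                )
            )
            t_read.append(rid)
            t_gene.append(g.gene_id)
            t_hap.append(1 if hap1[j] else 2)
            t_mapq.append(int(mapqs[j]))
            t_err.append(int(n_err[j]))
    truth = pd.DataFrame(
        {
            "read_id": t_read,
            "gene": t_gene,
            "haplotype": t_hap,
            "mapq": t_mapq,
            "n_errors": t_err,
        }
    )
    return records, truth


# -------------------------------------------------------------- Cut&Run


def simulate_cutrun(
    pair: PseudoGenomePair,
    config: SimulationConfig,
    domains: list[PlantedDomain],
    library_id: str,
    stream: int = 0,
    n_fragments: int | None = None,
    with_sequences: bool = True,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Sample paired-end fragments from a background + planted-domain mixture.

    Fragment midpoints are drawn from a mixture of a uniform genomic
    background and the planted domains, each domain weighted by
    ``(enrichment - 1) * width`` on top of the background it already
    receives.  A ``heavy_tail_fraction`` of fragments exceed 1 kb, a
    ``chimera_fraction`` have their second mate on a different
    chromosome, and fragment haplotypes follow the source domain's
    ``hap1_fraction`` (0.5 in background).  Pass ``domains=[]`` for an
    IgG-style background-only library.
    """
    rng = config.rng(_S_CUTRUN, stream)
    lengths = {c: len(s) for c, s in pair.genome_g1.items()}
    chroms = list(lengths)
    for d in domains:
        if d.enrichment < 1:
            raise ConfigurationError(f"domain enrichment {d.enrichment} < 1")
        if d.chrom not in lengths:
            raise DataError(f"domain chromosome {d.chrom!r} not in genome")
        if not 0 <= d.start < d.end <= lengths[d.chrom]:
            raise DataError(f"domain {d.chrom}:{d.start}-{d.end} outside chromosome")
    n = n_fragments if n_fragments is not None else config.cutrun_fragments
    # mixture components: one uniform background per chromosome, then domains
    comp_chrom = list(range(len(chroms))) + [chroms.index(d.chrom) for d in domains]
    comp_start = np.array([0] * len(chroms) + [d.start for d in domains])
    comp_width = np.array(
        [lengths[c] for c in chroms] + [d.end - d.start for d in domains], dtype=float
    )
    comp_hap = np.array([0.5] * len(chroms) + [d.hap1_fraction for d in domains])
    comp_weight = np.array(
        [float(lengths[c]) for c in chroms]
        + [(d.enrichment - 1.0) * (d.end - d.start) for d in domains]
    )
    comp = rng.choice(len(comp_weight), n, p=comp_weight / comp_weight.sum())
    mid = comp_start[comp] + (rng.random(n) * comp_width[comp]).astype(np.int64)
    chrom_idx = np.array(comp_chrom)[comp]
    dom_idx = np.where(comp >= len(chroms), comp - len(chroms), -1)
    hap1 = rng.random(n) < comp_hap[comp]
    rl = config.read_length
    heavy = rng.random(n) < config.heavy_tail_fraction
    frag_len = np.clip(
        rng.normal(config.fragment_mean, config.fragment_sd, n), rl, 999
    ).astype(np.int64)
    if heavy.any():
        frag_len[heavy] = rng.integers(1001, 3001, int(heavy.sum()))
    len_arr = np.array([lengths[c] for c in chroms])[chrom_idx]
    frag_len = np.minimum(frag_len, len_arr)
    start_arr = np.clip(mid - frag_len // 2, 0, len_arr - frag_len)
    chimeric = (rng.random(n) < config.chimera_fraction) & (len(chroms) > 1)
    mate_shift = rng.integers(1, max(len(chroms), 2), n)  # offset to a different chrom
    mate_u = rng.random(n)
    mapq1 = np.where(rng.random(n) < config.low_mapq_fraction, rng.integers(0, 30, n), 60)
    mapq2 = np.where(rng.random(n) < config.low_mapq_fraction, rng.integers(0, 30, n), 60)
    n_err1 = (
        rng.binomial(rl, config.sequencing_error_rate, n)
        if with_sequences and config.sequencing_error_rate > 0
        else np.zeros(n, dtype=int)
    )
    n_err2 = (
        rng.binomial(rl, config.sequencing_error_rate, n)
        if with_sequences and config.sequencing_error_rate > 0
        else np.zeros(n, dtype=int)
    )
    pairs: list[ReadPair] = []
    t_hap = np.where(hap1, 1, 2)
    overlong = frag_len >= 1000
    low_mapq = np.minimum(mapq1, mapq2) < 30
    for i in range(n):
        chrom = chroms[chrom_idx[i]]
        start = int(start_arr[i])
        L = int(frag_len[i])
        end = start + L
        genome = pair.genome_g1 if hap1[i] else pair.genome_g2
        rid = f"{library_id}|frag{i}"
        if chimeric[i]:
            chrom2 = chroms[(chrom_idx[i] + int(mate_shift[i])) % len(chroms)]
            start2 = int(mate_u[i] * (lengths[chrom2] - rl))
            frag = 0
        else:
            chrom2 = chrom
            start2 = end - rl
            frag = L
        seq1 = seq2 = None
        if with_sequences:
            seq1 = genome[chrom][start : start + rl]
            seq2 = genome[chrom2][start2 : start2 + rl]
            if n_err1[i]:
                seq1 = _apply_errors(seq1, int(n_err1[i]), rng)
            if n_err2[i]:
                seq2 = _apply_errors(seq2, int(n_err2[i]), rng)
        r1 = AlignmentRecord(
            read_id=rid, chrom=chrom, start=start, length=rl, sequence=seq1,
            mapq=int(mapq1[i]), mate_chrom=chrom2, fragment_length=frag,
            is_read1=True, paired=True,
        )
        r2 = AlignmentRecord(
            read_id=rid, chrom=chrom2, start=start2, length=rl, sequence=seq2,
            mapq=int(mapq2[i]), mate_chrom=chrom, fragment_length=frag,
            is_read1=False, paired=True, strand="-",
        )
        pairs.append((r1, r2))
    truth = pd.DataFrame(
        {
            "fragment_id": [f"{library_id}|frag{i}" for i in range(n)],
            "chrom": [chroms[j] for j in chrom_idx],
            "start": start_arr,
            "end": start_arr + frag_len,
            "domain": dom_idx,
            "haplotype": t_hap,
            "overlong": overlong,
            "chimeric": chimeric,
            "low_mapq": low_mapq,
        }
    )
    return pairs, truth


# -------------------------------------------------------- count sampling


def simulate_count_matrix(
    seed: int,
    n_genes: int = 400,
    n_ref: int = 3,
    n_test: int = 3,
    base_mean: float = 500.0,
    mean_log_sd: float = 0.8,
    biological_log2_sd: float = 0.25,
    de_fraction: float = 0.0,
    de_log2_fold: float = 2.0,
) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """Draw a Poisson-lognormal total-count matrix for DE testing.

    Returns (counts, truth DE flags, group labels).  A ``de_fraction``
    of genes have their mean multiplied by ``2**de_log2_fold`` in the
    test group (direction alternating), the rest are null.
    """
    rng = np.random.default_rng([seed, _S_COUNTS])
    genes = [f"g{i:04d}" for i in range(n_genes)]
    libs = [f"ref{j}" for j in range(n_ref)] + [f"test{j}" for j in range(n_test)]
    groups = {l: ("ref" if l.startswith("ref") else "test") for l in libs}
    means = base_mean * rng.lognormal(0.0, mean_log_sd, n_genes)
    de = rng.random(n_genes) < de_fraction
    sign = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    counts = np.empty((n_genes, len(libs)), dtype=np.int64)
    for j, lib in enumerate(libs):
        mu = means * 2 ** rng.normal(0.0, biological_log2_sd, n_genes)
        if groups[lib] == "test":
            mu = mu * np.where(de, 2.0 ** (sign * de_log2_fold), 1.0)
        counts[:, j] = rng.poisson(mu)
    return (
        pd.DataFrame(counts, index=genes, columns=libs),
        pd.Series(de, index=genes, name="de"),
        groups,
    )
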