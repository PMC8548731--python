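"""Synthetic genomes, annotations and MeRIP/RNA-seq count matrices.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale and with no external data:

* non-overlapping multi-exon gene loci (lncRNA biotypes and protein_coding)
  on both strands of random-sequence chromosomes;
* per-window IP/input counts with negative-binomial marginals.  IP and input
  libraries of a replicate share one realised per-window abundance (they are
  sequenced from the same RNA sample), so IP enrichment acts on the common
  rate and the conditional IP-vs-input comparison stays exactly calibrated
  under the null;
* planted exonic m6A peaks (enrichment fold > 1), optionally carrying a
  DRACH instance (GGACU) at the summit;
* per-gene RNA-seq counts with planted differential expression of magnitude
  ``de_log2fc_magnitude``, and a planted sign-coupling between methylation
  change and expression change tuned to ``meth_expr_correlation``;
* optional planted cis pairs: a coupled lncRNA whose nearest protein-coding
  neighbor is forced differentially expressed with the same (positive) or
  opposite (retrograde) sign.

Truth tables record every planted effect so each analysis stage can be
scored against ground truth.  A fixed seed reproduces byte-identical output
files.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_model import Gene, GenomeAnnotation, Transcript, write_gtf
from .expr_quant import GeneCountMatrix
from .merip_peaks import WindowCountMatrix, make_windows

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: DRACH instance planted at peak summits (RNA GGACU)
PLANT_MOTIF = "GGACT"
_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


class ConfigError(ValueError):
    pass


class PlacementError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 1_200_000
    n_lnc: int = 60
    n_coding: int = 120
    exon_count_range: tuple = (2, 6)
    exon_length_range: tuple = (250, 500)
    intron_length_range: tuple = (100, 400)
    intergenic_gap_range: tuple = (200, 2000)
    lnc_type_proportions: dict = field(default_factory=lambda: {
        "lincRNA": 0.5, "antisense": 0.3, "processed_transcript": 0.2})
    window_size: int = 100
    window_step: int = 50
    replicates_per_condition: int = 2
    nb_mean: float = 50.0
    nb_dispersion: float = 0.1
    expr_sigma: float = 0.5       # log-sd of per-gene expression level
    libsize_sigma: float = 0.2    # log-sd of library size factors
    peak_enrichment_fold: float = 8.0
    peak_length: int = 200
    frac_lnc_with_peak: float = 0.6
    frac_de: float = 0.3
    de_log2fc_magnitude: float = 2.0
    meth_log2fc_magnitude: float = 1.5
    meth_jitter_sd: float = 0.2
    meth_expr_correlation: float = 0.6
    motif_planting: bool = True
    plant_positive_pairs: int = 1
    plant_retro_pairs: int = 1

    def validate(self) -> None:
        if not -1.0 <= self.meth_expr_correlation <= 1.0:
            raise ConfigError("meth_expr_correlation must lie in [-1, 1]")
        for name in ("frac_lnc_with_peak", "frac_de"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.peak_enrichment_fold < 1.0:
            raise ConfigError("peak_enrichment_fold must be >= 1")
        if self.nb_mean <= 0 or self.nb_dispersion < 0:
            raise ConfigError("nb_mean must be positive, nb_dispersion >= 0")
        if not 0 < self.window_step <= self.window_size:
            raise ConfigError("require 0 < window_step <= window_size")
        lo, hi = self.exon_count_range
        if not 1 <= lo <= hi:
            raise ConfigError("bad exon_count_range")
        if self.exon_length_range[0] < self.peak_length + 6:
            raise ConfigError(
                "minimum exon length must exceed peak_length + 6 so planted "
                "peaks (and their summit motif) fit inside one exon")
        if self.replicates_per_condition < 1:
            raise ConfigError("need >= 1 replicate per condition")


# --------------------------------------------------------------------------
# Genome and annotation
# --------------------------------------------------------------------------

def generate_genome(config: SimulationConfig, with_sequence: bool = True
                    ) -> tuple[dict[str, np.ndarray], GenomeAnnotation]:
    """Random genome sequence plus a non-overlapping gene annotation.

    Gene loci are laid left to right with random intergenic gaps; lncRNA and
    protein-coding genes are interleaved in random order so every lncRNA has
    coding neighbors.  Each gene carries one transcript.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = {}
    if with_sequence:
        for c in chroms:
            genome[c] = BASES[rng.integers(0, 4, size=config.chrom_length)].copy()

    lnc_types = list(config.lnc_type_proportions)
    lnc_probs = np.array([config.lnc_type_proportions[t] for t in lnc_types])
    lnc_probs = lnc_probs / lnc_probs.sum()

    specs = []
    for i in range(config.n_lnc):
        gtype = lnc_types[int(rng.choice(len(lnc_types), p=lnc_probs))]
        specs.append((f"LNC{i + 1:05d}", gtype))
    for i in range(config.n_coding):
        specs.append((f"PCG{i + 1:05d}", "protein_coding"))

    order = rng.permutation(len(specs))
    cursors = {c: 0 for c in chroms}
    genes, transcripts = [], []
    for k, oi in enumerate(order):
        gene_id, gtype = specs[oi]
        chrom = chroms[k % len(chroms)]
        gap = int(rng.integers(*config.intergenic_gap_range))
        n_exons = int(rng.integers(config.exon_count_range[0],
                                   config.exon_count_range[1] + 1))
        exon_lens = rng.integers(config.exon_length_range[0],
                                 config.exon_length_range[1] + 1, size=n_exons)
        intron_lens = rng.integers(config.intron_length_range[0],
                                   config.intron_length_range[1] + 1,
                                   size=max(n_exons - 1, 0))
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursors[chrom] + gap
        exons, pos = [], start
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if j < len(intron_lens):
                pos += int(intron_lens[j])
        if pos > config.chrom_length:
            raise PlacementError(
                f"chromosome {chrom} too short to place gene {gene_id} "
                f"(needs up to {pos}, length {config.chrom_length})")
        cursors[chrom] = pos
        genes.append(Gene(gene_id, gene_id, gtype, chrom, strand, start, pos))
        transcripts.append(Transcript(f"{gene_id}.T1", gene_id, chrom, strand,
                                      tuple(exons)))
    return genome, GenomeAnnotation(genes, transcripts)


# --------------------------------------------------------------------------
# Effects and counts
# --------------------------------------------------------------------------

@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: dict[str, np.ndarray]
    annotation: GenomeAnnotation
    window_counts: WindowCountMatrix | None
    gene_counts: GeneCountMatrix
    truth_genes: pd.DataFrame
    truth_peaks: pd.DataFrame


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float
             ) -> np.ndarray:
    """NB(mean, variance mean + alpha mean^2) via gamma-Poisson mixing."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    rate = rng.gamma(1.0 / alpha, alpha * mean)
    return rng.poisson(rate)


def _sign_pair(rng: np.random.Generator, rho: float) -> tuple[int, int]:
    """Two +-1 signs with E[s1 s2] = rho."""
    s1 = 1 if rng.random() < 0.5 else -1
    s2 = s1 if rng.random() < (1.0 + rho) / 2.0 else -s1
    return s1, s2


def _nearest_coding(annotation: GenomeAnnotation, lnc: Gene) -> Gene | None:
    best, best_d = None, None
    for g in annotation.coding_genes():
        if g.chrom != lnc.chrom:
            continue
        d = max(lnc.start - g.end, g.start - lnc.end, 0)
        if best_d is None or (d, g.start) < (best_d, best.start):
            best, best_d = g, d
    return best


def generate_counts(config: SimulationConfig, annotation: GenomeAnnotation,
                    genome: dict[str, np.ndarray] | None = None,
                    with_windows: bool = True) -> SimulationResult:
    """Simulate count matrices and truth tables for an annotation.

    When ``genome`` is given and motif planting is on, each planted peak's
    summit sequence is overwritten (in place) with a DRACH instance on the
    transcript strand.  Peaks are planted only when peak_enrichment_fold > 1.
    """
    config.validate()
    if not annotation.transcripts:
        raise ConfigError("annotation has no transcripts/exons")
    rng = np.random.default_rng((config.seed, 1))

    lnc = sorted(g.gene_id for g in annotation.lnc_genes())
    coding = sorted(g.gene_id for g in annotation.coding_genes())
    all_genes = sorted(annotation.genes)

    # --- planted effect assignment (floor rounding, index order) ----------
    n_peak = math.floor(config.frac_lnc_with_peak * len(lnc))
    n_de_lnc = math.floor(config.frac_de * len(lnc))
    n_de_cod = math.floor(config.frac_de * len(coding))
    plant_peaks = config.peak_enrichment_fold > 1.0
    peaked = set(lnc[:n_peak]) if plant_peaks else set()
    de_flagged = set(lnc[:n_de_lnc])
    cod_flagged = list(coding[:n_de_cod])

    M, K = config.de_log2fc_magnitude, config.meth_log2fc_magnitude
    de_lfc: dict[str, float] = {}
    meth_lfc: dict[str, float] = {}
    coupled = [g for g in lnc if g in de_flagged and g in peaked]
    for g in sorted(de_flagged):
        if g in peaked:
            s_expr, s_meth = _sign_pair(rng, config.meth_expr_correlation)
            de_lfc[g] = s_expr * M
            meth_lfc[g] = s_meth * K + rng.normal(0.0, config.meth_jitter_sd)
        else:
            de_lfc[g] = (1 if rng.random() < 0.5 else -1) * M
    for g in cod_flagged:
        de_lfc[g] = (1 if rng.random() < 0.5 else -1) * M

    # --- planted cis neighbor pairs (marginals preserved by swapping) -----
    pair_kind: dict[str, str] = {}
    forced_coding: dict[str, float] = {}
    wanted = (["retrograde"] * config.plant_retro_pairs
              + ["positive"] * config.plant_positive_pairs)
    free = [g for g in cod_flagged]
    for kind, g in zip(wanted, coupled):
        neighbor = _nearest_coding(annotation, annotation.genes[g])
        if neighbor is None:
            continue
        s_lnc = -1 if kind == "retrograde" else 1
        de_lfc[g] = s_lnc * M
        meth_lfc[g] = s_lnc * K + rng.normal(0.0, config.meth_jitter_sd)
        # retrograde: coding moves opposite to the lncRNA; positive: same
        s_cod = -s_lnc if kind == "retrograde" else s_lnc
        forced_coding[neighbor.gene_id] = s_cod * M
        pair_kind[g] = kind
    for cid, lfc in forced_coding.items():
        if cid not in de_lfc:
            # keep the flagged-coding marginal exact: drop the last free one
            while free and (free[-1] in forced_coding):
                free.pop()
            if not free:
                raise ConfigError(
                    "cannot plant neighbor pairs: no flagged coding gene "
                    "available to swap (raise frac_de or n_coding)")
            dropped = free.pop()
            del de_lfc[dropped]
            cod_flagged.remove(dropped)
            cod_flagged.append(cid)
        de_lfc[cid] = lfc

    # --- expression levels -------------------------------------------------
    expr_level = {g: config.nb_mean * math.exp(rng.normal(0, config.expr_sigma))
                  for g in all_genes}

    def cond_mean(g: str, cond: str) -> float:
        lfc = de_lfc.get(g, 0.0)
        half = lfc / 2.0 if cond == "D4" else -lfc / 2.0
        return expr_level[g] * 2.0 ** half

    # --- planted peaks ------------------------------------------------------
    peak_rows = []
    for g in sorted(peaked):
        tx = annotation.canonical_transcript(g)
        eligible = [i for i, (s, e) in enumerate(tx.exons)
                    if e - s >= config.peak_length + 6]
        if not eligible:
            raise PlacementError(f"gene {g}: no exon can hold a planted peak")
        ei = eligible[int(rng.integers(len(eligible)))]
        s, e = tx.exons[ei]
        off = int(rng.integers(3, e - s - config.peak_length - 3 + 1))
        p0, p1 = s + off, s + off + config.peak_length
        offset = sum(b - a for a, b in tx.exons[:ei])
        sp0 = offset + (p0 - s)
        summit = (p0 + p1) // 2
        mlfc = meth_lfc.get(g)
        if mlfc is not None:
            fold_gm = max(config.peak_enrichment_fold * 2.0 ** (-mlfc / 2), 1.2)
            fold_d4 = max(config.peak_enrichment_fold * 2.0 ** (mlfc / 2), 1.2)
        else:
            fold_gm = fold_d4 = config.peak_enrichment_fold
        motif_start = -1
        if config.motif_planting and genome is not None:
            motif_start = summit - 2
            motif = PLANT_MOTIF.encode()
            if tx.strand == "-":
                motif = motif.translate(_COMPLEMENT)[::-1]
            genome[tx.chrom][motif_start:motif_start + 5] = \
                np.frombuffer(motif, dtype=np.uint8)
        peak_rows.append({
            "gene_id": g, "transcript_id": tx.transcript_id,
            "chrom": tx.chrom, "start": p0, "end": p1, "strand": tx.strand,
            "sp_start": sp0, "sp_end": sp0 + config.peak_length,
            "summit": summit,
            "fold_gm": fold_gm, "fold_d4": fold_d4,
            "true_diff_flag": mlfc is not None,
            "true_diff_meth_level": math.log2(fold_d4 / fold_gm)
            if mlfc is not None else 0.0,
            "motif_start": motif_start,
        })
    truth_peaks = pd.DataFrame(peak_rows, columns=[
        "gene_id", "transcript_id", "chrom", "start", "end", "strand",
        "sp_start", "sp_end", "summit", "fold_gm", "fold_d4",
        "true_diff_flag", "true_diff_meth_level", "motif_start"])

    # --- window-level MeRIP counts ------------------------------------------
    window_counts = None
    if with_windows:
        windows = make_windows(annotation, config.window_size, config.window_step)
        mu_gene = {c: np.array([cond_mean(g, c) for g in windows.gene_id])
                   for c in ("GM", "D4")}
        wlen_frac = ((windows.sp_end - windows.sp_start)
                     / config.window_size).to_numpy()
        fold = {c: np.ones(len(windows)) for c in ("GM", "D4")}
        for _, pk in truth_peaks.iterrows():
            in_tx = (windows.transcript_id == pk.transcript_id).to_numpy()
            ov = (np.minimum(windows.sp_end.to_numpy(), pk.sp_end)
                  - np.maximum(windows.sp_start.to_numpy(), pk.sp_start))
            frac = np.where(in_tx, np.clip(ov, 0, None), 0) \
                / (windows.sp_end - windows.sp_start).to_numpy()
            for c, f in (("GM", pk.fold_gm), ("D4", pk.fold_d4)):
                fold[c] = fold[c] * (1.0 + (f - 1.0) * frac)
        lib_rows, cols = [], {}
        alpha = config.nb_dispersion
        for cond in ("GM", "D4"):
            mu = mu_gene[cond] * wlen_frac
            for rep in range(1, config.replicates_per_condition + 1):
                s_ip = math.exp(rng.normal(0, config.libsize_sigma))
                s_in = math.exp(rng.normal(0, config.libsize_sigma))
                if alpha > 0:
                    rate = rng.gamma(1.0 / alpha, alpha * mu)
                else:
                    rate = mu
                ip_name, in_name = f"{cond}_IP_{rep}", f"{cond}_input_{rep}"
                cols[ip_name] = rng.poisson(rate * fold[cond] * s_ip)
                cols[in_name] = rng.poisson(rate * s_in)
                lib_rows.append({"library": ip_name, "condition": cond,
                                 "role": "IP", "replicate": rep})
                lib_rows.append({"library": in_name, "condition": cond,
                                 "role": "input", "replicate": rep})
        window_counts = WindowCountMatrix(
            windows,
            pd.DataFrame(cols, index=windows.index),
            pd.DataFrame(lib_rows).set_index("library"),
        )

    # --- gene-level RNA-seq counts ------------------------------------------
    length_scale = np.array(
        [annotation.exonic_length(g) / config.window_size for g in all_genes])
    gcols, conds = {}, {}
    for cond in ("GM", "D4"):
        mu = np.array([cond_mean(g, cond) for g in all_genes]) * length_scale
        for rep in range(1, config.replicates_per_condition + 1):
            s = math.exp(rng.normal(0, config.libsize_sigma))
            name = f"{cond}_{rep}"
            gcols[name] = _nb_draw(rng, mu * s, config.nb_dispersion)
            conds[name] = cond
    gene_counts = GeneCountMatrix(
        pd.DataFrame(gcols, index=pd.Index(all_genes, name="gene_id")),
        pd.Series(conds),
    )

    # --- gene truth table ----------------------------------------------------
    def group_of(g: str) -> str:
        if g not in coupled and g not in pair_kind:
            return ""
        m, x = meth_lfc.get(g, 0.0), de_lfc.get(g, 0.0)
        return ("Hyper-" if m > 0 else "Hypo-") + ("up" if x > 0 else "down")

    truth_genes = pd.DataFrame({
        "gene_id": all_genes,
        "gene_type": [annotation.genes[g].gene_type for g in all_genes],
        "expr_level": [expr_level[g] for g in all_genes],
        "true_de_flag": [g in de_lfc for g in all_genes],
        "true_de_log2fc": [de_lfc.get(g, 0.0) for g in all_genes],
        "has_peak": [g in peaked for g in all_genes],
        "true_diff_flag": [g in meth_lfc for g in all_genes],
        "true_diff_meth_level": [meth_lfc.get(g, float("nan"))
                                 for g in all_genes],
        "true_group": [group_of(g) for g in all_genes],
        "planted_pair": [pair_kind.get(g, "") for g in all_genes],
    })
    return SimulationResult(config, genome or {}, annotation, window_counts,
                            gene_counts, truth_genes, truth_peaks)


def simulate(config: SimulationConfig, with_windows: bool = True,
             with_sequence: bool = True) -> SimulationResult:
    """Full run: genome + annotation + counts + truth."""
    genome, annotation = generate_genome(config, with_sequence=with_sequence)
    return generate_counts(config, annotation,
                           genome=genome if with_sequence else None,
                           with_windows=with_windows)


# --------------------------------------------------------------------------
# Output files
# --------------------------------------------------------------------------

def write_fasta(genome: dict[str, np.ndarray], path: str) -> None:
    records = [SeqRecord(Seq(arr.tobytes().decode()), id=chrom, description="")
               for chrom, arr in genome.items()]
    SeqIO.write(records, path, "fasta")


def write_simulation(result: SimulationResult, outdir: str) -> dict[str, str]:
    """Write every artifact of a simulation; returns name -> path."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    if result.genome:
        write_fasta(result.genome, _p("genome.fa"))
    write_gtf(result.annotation, _p("annotation.gtf"))
    if result.window_counts is not None:
        wcm = result.window_counts
        pd.concat([wcm.windows, wcm.counts], axis=1).to_csv(
            _p("window_counts.tsv"), sep="\t", index=False)
        wcm.libraries.reset_index().to_csv(
            _p("merip_libraries.tsv"), sep="\t", index=False)
    gcm = result.gene_counts
    gcm.counts.to_csv(_p("gene_counts.tsv"), sep="\t")
    pd.DataFrame({"sample": gcm.conditions.index,
                  "condition": gcm.conditions.values}).to_csv(
        _p("rna_samples.tsv"), sep="\t", index=False)
    result.truth_genes.to_csv(_p("truth_genes.tsv"), sep="\t", index=False)
    result.truth_peaks.to_csv(_p("truth_peaks.tsv"), sep="\t", index=False)
    with open(_p("sim_config.tsv"), "w") as fh:
        for k, v in asdict(result.config).items():
            fh.write(f"{k}\t{v}\n")
    return paths


def read_window_counts(counts_path: str, libraries_path: str) -> WindowCountMatrix:
    """Load a window count matrix written by :func:`write_simulation`."""
    df = pd.read_csv(counts_path, sep="\t")
    libs = pd.read_csv(libraries_path, sep="\t").set_index("library")
    meta_cols = ["chrom", "start", "end", "strand", "gene_id",
                 "transcript_id", "sp_start", "sp_end"]
    windows = df[meta_cols]
    windows.index.name = "window_id"
    return WindowCountMatrix(windows, df[list(libs.index)], libs)


def read_gene_counts(counts_path: str, samples_path: str) -> GeneCountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    return GeneCountMatrix(counts,
                           pd.Series(samples.condition.values,
                                     index=samples["sample"].values))
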