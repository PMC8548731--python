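"""RPKM normalization, simplified NB differential expression, biotype split.

The differential-expression stage is a deliberately simple negative-binomial
Wald test on median-of-ratios normalized counts: per-gene fold change with a
0.5 pseudocount, method-of-moments dispersion (stabilized against collapse at
few replicates by flooring at the across-gene median), a delta-method
standard error, a two-sided normal p, and Benjamini-Hochberg adjustment.  It
trades the shrinkage machinery of dedicated DE packages for a transparent,
exactly-testable computation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import CODING_BIOTYPE, LNC_BIOTYPES, GenomeAnnotation
from .merip_peaks import bh_adjust

logger = logging.getLogger(__name__)

PADJ_THRESHOLD = 0.05
DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5
CONDITIONS = ("GM", "D4")


class CountMatrixError(ValueError):
    pass


@dataclass
class GeneCountMatrix:
    """Raw gene-level counts (genes x samples) with GM/D4 condition labels."""

    counts: pd.DataFrame
    conditions: pd.Series  # sample -> condition label
    library_size: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.conditions = pd.Series(self.conditions)
        if set(self.counts.columns) != set(self.conditions.index):
            raise CountMatrixError("condition labels must cover every sample")
        if (self.counts.to_numpy() < 0).any():
            raise CountMatrixError("negative counts")
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0)
        self.library_size = pd.Series(self.library_size)[self.counts.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def samples(self, condition: str | None = None) -> list[str]:
        if condition is None:
            return list(self.counts.columns)
        return [s for s in self.counts.columns if self.conditions[s] == condition]


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------

def rpkm(gcm: GeneCountMatrix, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, per gene and sample.

    Gene length is the spliced length of the canonical (longest) transcript.
    """
    missing = [g for g in gcm.gene_ids if g not in annotation.genes]
    if missing:
        raise CountMatrixError(
            f"genes absent from annotation: {', '.join(missing[:10])}"
            + ("..." if len(missing) > 10 else ""))
    lengths = pd.Series({g: annotation.exonic_length(g) for g in gcm.gene_ids})
    return gcm.counts.mul(1e9).div(gcm.library_size, axis=1).div(lengths, axis=0)


def mean_rpkm(gcm: GeneCountMatrix, annotation: GenomeAnnotation) -> pd.Series:
    """Arithmetic mean RPKM over all samples (the table's "meanfpkm")."""
    return rpkm(gcm, annotation).mean(axis=1)


def size_factors(gcm: GeneCountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over genes (with an all-positive row) of
    count_gj / geometric_mean_g.  Identical columns give factors of 1.
    """
    counts = gcm.counts.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise CountMatrixError(
            "no gene has positive counts in every sample; consider "
            "total-count normalization instead")
    logc = np.log(counts[positive])
    log_geomean = logc.mean(axis=1)
    ratios = np.exp(logc - log_geomean[:, None])
    return pd.Series(np.median(ratios, axis=0), index=gcm.counts.columns)


def expressed_mask(gcm: GeneCountMatrix, min_mean: float = 1.0) -> pd.Series:
    """"Expressed" = mean raw count >= min_mean in at least one condition."""
    keep = pd.Series(False, index=gcm.counts.index)
    for cond in gcm.conditions.unique():
        keep |= gcm.counts[gcm.samples(cond)].mean(axis=1) >= min_mean
    return keep


# --------------------------------------------------------------------------
# Differential expression
# --------------------------------------------------------------------------

def differential_expression(gcm: GeneCountMatrix,
                            annotation: GenomeAnnotation | None = None,
                            rpkm_floor: float = 0.0,
                            padj_threshold: float = PADJ_THRESHOLD) -> pd.DataFrame:
    """Simplified NB Wald test of D4 vs GM.

    Returns a frame with gene_id, baseMean, log2FoldChange, pvalue, padj,
    meanRPKM and direction (Up/Down/NS at padj <= threshold).  Genes below
    ``rpkm_floor`` mean RPKM are excluded before BH (requires annotation);
    the default floor of 0 keeps everything.
    """
    for cond in CONDITIONS:
        n = len(gcm.samples(cond))
        if n == 0:
            raise CountMatrixError(f"condition {cond} has no samples")
        if n < 2:
            raise CountMatrixError(
                f"condition {cond} has {n} sample(s); >=2 needed for "
                "dispersion estimation")
    sf = size_factors(gcm)
    norm = gcm.counts.div(sf, axis=1)
    gm, d4 = norm[gcm.samples("GM")], norm[gcm.samples("D4")]
    m_gm, m_d4 = gm.mean(axis=1), d4.mean(axis=1)
    n_gm, n_d4 = gm.shape[1], d4.shape[1]
    lfc = np.log2((m_d4 + PSEUDOCOUNT) / (m_gm + PSEUDOCOUNT))

    # method-of-moments dispersion, pooled across conditions; per-gene
    # estimates at few replicates collapse to zero too easily, so each gene
    # uses at least the across-gene median of the positive estimates
    s2 = (gm.var(axis=1, ddof=1) + d4.var(axis=1, ddof=1)) / 2
    mu = (m_gm + m_d4) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_gene = ((s2 - mu) / mu**2).to_numpy()
    alpha_gene = np.where(np.isfinite(alpha_gene), alpha_gene, 0.0)
    pos = alpha_gene[alpha_gene > 0]
    alpha_common = float(np.median(pos)) if pos.size else DISPERSION_FLOOR
    alpha = np.maximum(np.maximum(alpha_gene, alpha_common), DISPERSION_FLOOR)

    ln2sq = math.log(2) ** 2
    var_gm = (m_gm + alpha * m_gm**2) / n_gm
    var_d4 = (m_d4 + alpha * m_d4**2) / n_d4
    se2 = (var_gm / ((m_gm + PSEUDOCOUNT) ** 2)
           + var_d4 / ((m_d4 + PSEUDOCOUNT) ** 2)) / ln2sq
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    pvalue = 2 * stats.norm.sf(np.abs(z))

    res = pd.DataFrame({
        "gene_id": gcm.counts.index,
        "baseMean": norm.mean(axis=1).to_numpy(),
        "log2FoldChange": lfc.to_numpy(),
        "pvalue": pvalue,
    }).set_index("gene_id")

    if annotation is not None:
        res["meanRPKM"] = mean_rpkm(gcm, annotation)
        tested = res.index[res.meanRPKM >= rpkm_floor]
    else:
        res["meanRPKM"] = np.nan
        if rpkm_floor > 0:
            raise CountMatrixError("rpkm_floor > 0 requires an annotation")
        tested = res.index
    res["padj"] = np.nan
    res.loc[tested, "padj"] = bh_adjust(res.loc[tested, "pvalue"].to_numpy())
    res["direction"] = "NS"
    sig = res.padj <= padj_threshold
    res.loc[sig & (res.log2FoldChange > 0), "direction"] = "Up"
    res.loc[sig & (res.log2FoldChange < 0), "direction"] = "Down"
    logger.info("differential_expression: %d tested, %d Up, %d Down at padj<=%g",
                len(tested), (res.direction == "Up").sum(),
                (res.direction == "Down").sum(), padj_threshold)
    return res.reset_index()


def split_by_biotype(results: pd.DataFrame, annotation: GenomeAnnotation,
                     extra_lnc_types: tuple = ()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition DE results into (lncRNA, mRNA) by annotation gene_type.

    lncRNA = lincRNA / antisense / processed_transcript (plus extras);
    mRNA = protein_coding; anything else is dropped with a logged count.
    """
    lnc_types = LNC_BIOTYPES | set(extra_lnc_types)
    gtype = results.gene_id.map(
        lambda g: annotation.genes[g].gene_type if g in annotation.genes else "unknown")
    lnc = results[gtype.isin(lnc_types)]
    mrna = results[gtype == CODING_BIOTYPE]
    n_drop = len(results) - len(lnc) - len(mrna)
    if n_drop:
        logger.info("split_by_biotype: dropped %d genes of other/unknown type",
                    n_drop)
    return lnc.reset_index(drop=True), mrna.reset_index(drop=True)


DE_TABLE_COLUMNS = ["Ensembl_ID", "Gene_Name", "Expression", "log2FoldChange",
                    "meanfpkm", "padj"]


def de_results_to_table(results: pd.DataFrame,
                        annotation: GenomeAnnotation) -> pd.DataFrame:
    """DE results in the worked-example layout (Expression = Up/Down/NS)."""
    return pd.DataFrame({
        "Ensembl_ID": results.gene_id,
        "Gene_Name": results.gene_id.map(
            lambda g: annotation.genes[g].gene_name if g in annotation.genes else g),
        "Expression": results.direction,
        "log2FoldChange": results.log2FoldChange,
        "meanfpkm": results.meanRPKM,
        "padj": results.padj,
    }, columns=pd.Index(DE_TABLE_COLUMNS))
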