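"""Joint analysis of differential methylation and differential expression.

Genes significant on both axes (expression padj <= 0.05 and methylation
FDR <= 0.05) are placed in one of four quadrants by the signs of the two
changes (Hyper-up, Hyper-down, Hypo-up, Hypo-down); everything else is
Excluded with a reason.  The module also computes the Pearson correlation of
methylation change with expression change, compares expression-change
distributions of methylated vs unmethylated genes with a two-sample
Kolmogorov-Smirnov test, and replays two packaged worked-example tables
(a top differentially-expressed lncRNA table and a 15-row differential-peak
table) through the same classification rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .merip_peaks import DiffPeakRecord

PADJ_THRESHOLD = 0.05
METH_FDR_THRESHOLD = 0.05
GROUPS = ("Hyper-up", "Hyper-down", "Hypo-up", "Hypo-down")
EXCLUDED = "Excluded"

#: canonical record columns used across this module
RECORD_COLUMNS = ["gene_id", "rna_log2fc", "rna_padj", "meth_log2fc",
                  "meth_sig"]

TABLE1_COLUMNS = ["Ensembl_ID", "Gene_Name", "Expression", "log2FoldChange",
                  "meanfpkm", "padj"]
TABLE2_COLUMNS = ["Chr", "Peak_start", "Peak_end", "Strand", "Ensembl_ID",
                  "Gene_Name", "RNA-seq_log2FoldChange", "RNA-seq_padj",
                  "MeRIP-seq_diff.log2.fc", "MeRIP-seq_diff.lg.fdr",
                  "Gene_Type", "Group"]


class FixtureError(ValueError):
    pass


# --------------------------------------------------------------------------
# Quadrant classification
# --------------------------------------------------------------------------

def classify_quadrants(records: pd.DataFrame,
                       padj_threshold: float = PADJ_THRESHOLD,
                       meth_fdr_threshold: float = METH_FDR_THRESHOLD,
                       meth_sig_is_log10: bool = False
                       ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign each record to a methylation x expression quadrant.

    ``meth_sig`` is either a plain FDR or log10(FDR); the caller states which
    via ``meth_sig_is_log10`` (it is never guessed from the values).  Ties at
    a threshold count as significant (<=).  Records with a missing statistic
    or a zero effect on either axis are Excluded with a reason code.
    """
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise FixtureError(f"records lack columns: {missing}")
    out = records.copy()
    meth_cut = (math.log10(meth_fdr_threshold) if meth_sig_is_log10
                else meth_fdr_threshold)
    group, reason = [], []
    for row in out.itertuples(index=False):
        stats_ok = all(pd.notna(getattr(row, c))
                       for c in RECORD_COLUMNS[1:])
        if not stats_ok:
            group.append(EXCLUDED)
            reason.append("missing_statistic")
            continue
        if not (row.rna_padj <= padj_threshold
                and row.meth_sig <= meth_cut):
            group.append(EXCLUDED)
            reason.append("not_significant")
            continue
        if row.meth_log2fc == 0 or row.rna_log2fc == 0:
            group.append(EXCLUDED)
            reason.append("zero_effect")
            continue
        g = ("Hyper-" if row.meth_log2fc > 0 else "Hypo-") + \
            ("up" if row.rna_log2fc > 0 else "down")
        group.append(g)
        reason.append("")
    out["group"] = group
    out["reason"] = reason
    counts = {g: int((out.group == g).sum()) for g in GROUPS + (EXCLUDED,)}
    return out, counts


def records_from_results(de_results: pd.DataFrame,
                         diff_peaks: Sequence[DiffPeakRecord]) -> pd.DataFrame:
    """Build classification records from DE results and differential peaks.

    A gene with several differential peaks is represented by the peak with
    the smallest FDR (earliest coordinate on ties); meth_sig is that peak's
    plain FDR.  Genes without a DE row keep NaN expression statistics and
    end up Excluded.
    """
    best: dict[str, DiffPeakRecord] = {}
    for d in sorted(diff_peaks,
                    key=lambda d: (d.fdr, d.peak.interval.chrom,
                                   d.peak.interval.start)):
        best.setdefault(d.peak.gene_id, d)
    de = de_results.set_index("gene_id") if "gene_id" in de_results.columns \
        else de_results
    rows = []
    for gid in sorted(best):
        d = best[gid]
        rows.append({
            "gene_id": gid,
            "rna_log2fc": de.at[gid, "log2FoldChange"] if gid in de.index
            else np.nan,
            "rna_padj": de.at[gid, "padj"] if gid in de.index else np.nan,
            "meth_log2fc": d.diff_log2_fc,
            "meth_sig": d.fdr,
        })
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


# --------------------------------------------------------------------------
# Correlation and distribution comparison
# --------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def meth_expr_correlation(records: pd.DataFrame, subset: str = "significant",
                          padj_threshold: float = PADJ_THRESHOLD,
                          meth_fdr_threshold: float = METH_FDR_THRESHOLD,
                          meth_sig_is_log10: bool = False) -> CorrelationResult:
    """Pearson correlation of methylation change with expression change.

    ``subset`` picks records that pass ("significant") or fail
    ("nonsignificant") the same dual-significance rule the quadrants use;
    "all" uses every complete record.  p is two-sided from the t distribution
    with n - 2 df; with n < 3 it is undefined (NaN).
    """
    df = records.dropna(subset=RECORD_COLUMNS[1:])
    meth_cut = (math.log10(meth_fdr_threshold) if meth_sig_is_log10
                else meth_fdr_threshold)
    sig = (df.rna_padj <= padj_threshold) & (df.meth_sig <= meth_cut)
    if subset == "significant":
        df = df[sig]
    elif subset == "nonsignificant":
        df = df[~sig]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    n = len(df)
    if n < 2:
        return CorrelationResult(float("nan"), float("nan"), n)
    x, y = df.meth_log2fc.to_numpy(), df.rna_log2fc.to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n)
    if n < 3:
        r = float(np.corrcoef(x, y)[0, 1])
        return CorrelationResult(r, float("nan"), n)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n)


@dataclass
class KSResult:
    D: float
    p: float
    n1: int
    n2: int


def ks_by_methylation(log2fc: Sequence[float],
                      methylated: Sequence[bool]) -> KSResult:
    """Two-sample KS test of expression change, methylated vs not.

    D is the supremum ECDF distance; p is the asymptotic Kolmogorov
    approximation (documented as approximate below ~10 per group).
    """
    x = np.asarray(log2fc, dtype=float)
    m = np.asarray(methylated, dtype=bool)
    a, b = x[m], x[~m]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(float(res.statistic), float(res.pvalue), len(a), len(b))


# --------------------------------------------------------------------------
# Worked-example tables
# --------------------------------------------------------------------------

@dataclass
class WorkedExample:
    name: str              # "table1" or "table2"
    frame: pd.DataFrame    # original columns, typed
    records: pd.DataFrame | None  # canonical records (table2 only)


def fixture_path(name: str) -> str:
    return str(resources.files("lncm6a").joinpath(f"data/{name}.tsv"))


def load_worked_example(source: str) -> WorkedExample:
    """Load a packaged worked-example table ("table1"/"table2") or a TSV path.

    The header must match one of the two documented schemas exactly; for the
    differential-peak table the methylation significance column is log10(FDR)
    and is exposed as canonical records with ``meth_sig_is_log10=True``
    semantics.
    """
    path = fixture_path(source) if source in ("table1", "table2") else source
    df = pd.read_csv(path, sep="\t", dtype={"Chr": str})
    cols = list(df.columns)
    if cols == TABLE1_COLUMNS:
        return WorkedExample("table1", df, None)
    if cols == TABLE2_COLUMNS:
        records = pd.DataFrame({
            "gene_id": df["Ensembl_ID"],
            "rna_log2fc": df["RNA-seq_log2FoldChange"],
            "rna_padj": df["RNA-seq_padj"],
            "meth_log2fc": df["MeRIP-seq_diff.log2.fc"],
            "meth_sig": df["MeRIP-seq_diff.lg.fdr"],
        }, columns=pd.Index(RECORD_COLUMNS))
        return WorkedExample("table2", df, records)
    raise FixtureError(
        "unrecognized worked-example header.\n"
        f"found:    {cols}\n"
        f"expected: {TABLE1_COLUMNS}\n"
        f"      or: {TABLE2_COLUMNS}")
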