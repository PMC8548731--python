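"""Windowed MeRIP-seq peak detection and differential methylation.

The caller tiles each gene's spliced (exonic) transcript with fixed-width
sliding windows, tests IP enrichment over input per window with a conditional
binomial test, adjusts with Benjamini-Hochberg across windows, and merges
nearby significant windows into peaks.  Between-condition differences are
assessed per peak with Fisher's exact test on the pooled IP/input counts of
the two conditions.

Conventions: the methylation level of a span is
``log2(((x_ip + 1) / N_ip) / ((x_in + 1) / N_in))`` (pseudocount 1, library
totals N); differential significance is reported as log10 of the BH-adjusted
q ("lg.fdr"), so the 0.05 cutoff sits at log10(0.05) ~ -1.301.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_model import GenomeAnnotation, GenomicInterval, Transcript

logger = logging.getLogger(__name__)

WINDOW_WIDTH = 100  # nt, matches the ~100 nt RNA fragmentation of MeRIP
WINDOW_STEP = 50
PEAK_Q = 0.05
DIFF_Q = 0.05
LG_FDR_CUTOFF = math.log10(DIFF_Q)

CONDITIONS = ("GM", "D4")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (empty-safe)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# Window tiling
# --------------------------------------------------------------------------

def spliced_to_genomic_pieces(tx: Transcript, a: int, b: int) -> list[tuple[int, int]]:
    """Map the spliced interval [a, b) onto genomic exon pieces.

    Spliced coordinates here run in genomic (plus-strand) order along the
    concatenated exons, which keeps window bookkeeping strand-free; 5'/3'
    orientation is applied only where it matters (metagene, summits) via
    genome_model.
    """
    if not 0 <= a < b <= tx.spliced_length:
        raise ValueError(f"spliced interval [{a}, {b}) outside transcript")
    pieces = []
    offset = 0
    for s, e in tx.exons:
        length = e - s
        lo, hi = max(a, offset), min(b, offset + length)
        if lo < hi:
            pieces.append((s + (lo - offset), s + (hi - offset)))
        offset += length
    return pieces


def make_windows(annotation: GenomeAnnotation, width: int = WINDOW_WIDTH,
                 step: int = WINDOW_STEP,
                 gene_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Tile the canonical transcript of each gene with sliding windows.

    Returns one row per window with both its spliced span (sp_start/sp_end on
    the concatenated exons) and its genomic bounding interval.  A transcript
    shorter than ``width`` contributes a single full-length window; the
    trailing <step nt of a transcript are not re-covered by an extra stub.
    """
    if width <= 0 or step <= 0 or step > width:
        raise ValueError("require 0 < step <= width")
    rows = []
    ids = list(gene_ids) if gene_ids is not None else sorted(annotation.genes)
    for gene_id in ids:
        tx = annotation.canonical_transcript(gene_id)
        L = tx.spliced_length
        starts = range(0, L - width + 1, step) if L >= width else [0]
        for a in starts:
            b = min(a + width, L)
            pieces = spliced_to_genomic_pieces(tx, a, b)
            rows.append({
                "chrom": tx.chrom,
                "start": pieces[0][0],
                "end": pieces[-1][1],
                "strand": tx.strand,
                "gene_id": gene_id,
                "transcript_id": tx.transcript_id,
                "sp_start": a,
                "sp_end": b,
            })
    windows = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "gene_id",
                       "transcript_id", "sp_start", "sp_end"])
    windows.index.name = "window_id"
    return windows


@dataclass
class WindowCountMatrix:
    """Window coordinates plus per-library IP/input counts.

    ``libraries`` is indexed by library id with columns ``condition``
    (GM/D4), ``role`` (IP/input) and ``replicate``; IP and input libraries
    pair one-to-one within a condition by replicate number.
    """

    windows: pd.DataFrame
    counts: pd.DataFrame
    libraries: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.windows.index):
            raise ValueError("counts and windows must share an index")
        if set(self.counts.columns) != set(self.libraries.index):
            raise ValueError("counts columns must match library table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        for cond, grp in self.libraries.groupby("condition"):
            ip = set(grp.loc[grp.role == "IP", "replicate"])
            inp = set(grp.loc[grp.role == "input", "replicate"])
            if ip != inp:
                raise ValueError(
                    f"condition {cond}: IP and input replicates do not pair")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.libraries.condition.unique())

    def libs(self, condition: str, role: str) -> list[str]:
        m = (self.libraries.condition == condition) & (self.libraries.role == role)
        return sorted(self.libraries.index[m])

    def pooled(self, condition: str, role: str) -> pd.Series:
        """Replicate-summed counts per window for one condition/role."""
        return self.counts[self.libs(condition, role)].sum(axis=1)

    def total(self, condition: str, role: str) -> int:
        return int(self.pooled(condition, role).sum())

    def subset_conditions(self, conditions: Iterable[str]) -> "WindowCountMatrix":
        keep = self.libraries[self.libraries.condition.isin(set(conditions))]
        return WindowCountMatrix(self.windows, self.counts[list(keep.index)],
                                 keep)


# --------------------------------------------------------------------------
# Window-level enrichment test
# --------------------------------------------------------------------------

def window_test(x_ip, x_in, N_ip: int, N_in: int):
    """One-sided conditional binomial IP-enrichment p-value.

    Under the null of equal IP/input rates, conditionally on the window sum
    n = x_ip + x_in the IP count is Binomial(n, N_ip / (N_ip + N_in));
    returned is P(X >= x_ip), with p = 1 for empty windows.  Accepts scalars
    or arrays.
    """
    if N_ip <= 0 or N_in <= 0:
        raise ValueError("library totals must be positive")
    x_ip = np.asarray(x_ip, dtype=np.int64)
    x_in = np.asarray(x_in, dtype=np.int64)
    if (x_ip < 0).any() or (x_in < 0).any():
        raise ValueError("negative counts")
    n = x_ip + x_in
    p0 = N_ip / (N_ip + N_in)
    # P(X >= x) = sf(x - 1); sf(-1) = 1 covers x_ip = 0 and empty windows
    p = stats.binom.sf(x_ip - 1, n, p0)
    return p if p.shape else float(p)


def m6a_level(x_ip, x_in, N_ip: int, N_in: int):
    """log2 IP/input rate ratio with pseudocount 1."""
    x_ip = np.asarray(x_ip, dtype=float)
    x_in = np.asarray(x_in, dtype=float)
    out = np.log2(((x_ip + 1) / N_ip) / ((x_in + 1) / N_in))
    return out if out.shape else float(out)


# --------------------------------------------------------------------------
# Peak calling
# --------------------------------------------------------------------------

@dataclass
class PeakRecord:
    interval: GenomicInterval
    gene_id: str
    transcript_id: str
    sp_start: int
    sp_end: int
    summit: int          # genomic position of max-enrichment window midpoint
    summit_sp: int       # same position in spliced coordinates
    m6a_level: float
    pvalue: float
    fdr: float
    condition: str = ""
    window_ids: tuple = field(default_factory=tuple)


def _merge_runs(idx: list[int], windows: pd.DataFrame, step: int) -> list[list[int]]:
    """Group significant window ids (one transcript) into runs: gap <= step."""
    idx = sorted(idx, key=lambda i: windows.at[i, "sp_start"])
    runs: list[list[int]] = []
    for i in idx:
        if runs and windows.at[i, "sp_start"] - windows.at[runs[-1][-1], "sp_end"] <= step:
            runs[-1].append(i)
        else:
            runs.append([i])
    return runs


def call_peaks(wcm: WindowCountMatrix, condition: str,
               q_threshold: float = PEAK_Q,
               step: int = WINDOW_STEP) -> list[PeakRecord]:
    """Call m6A peaks for one condition.

    Replicates are pooled per window; BH runs across all windows of the
    condition; significant windows on the same transcript merge when their
    spliced gap is at most one window step.  A merged peak inherits the
    minimum window p (and q); its summit is the midpoint of its
    max-enrichment window.
    """
    if len(wcm.windows) == 0:
        return []
    x_ip = wcm.pooled(condition, "IP").to_numpy()
    x_in = wcm.pooled(condition, "input").to_numpy()
    N_ip, N_in = wcm.total(condition, "IP"), wcm.total(condition, "input")
    p = window_test(x_ip, x_in, N_ip, N_in)
    q = bh_adjust(p)
    sig = np.flatnonzero(q <= q_threshold)
    logger.info("call_peaks[%s]: %d/%d windows significant at q<=%g",
                condition, sig.size, len(p), q_threshold)
    enrich = ((x_ip + 1) / N_ip) / ((x_in + 1) / N_in)
    peaks: list[PeakRecord] = []
    windows = wcm.windows
    for tx_id, grp in windows.iloc[sig].groupby("transcript_id", sort=True):
        for run in _merge_runs(list(grp.index), windows, step):
            sub = windows.loc[run]
            a, b = int(sub.sp_start.min()), int(sub.sp_end.max())
            xi, xn = int(x_ip[run].sum()), int(x_in[run].sum())
            best = run[int(np.argmax(enrich[run]))]
            bw = windows.loc[best]
            summit = (int(bw.start) + int(bw.end)) // 2
            peaks.append(PeakRecord(
                interval=GenomicInterval(sub.chrom.iloc[0],
                                         int(sub.start.min()),
                                         int(sub.end.max()),
                                         sub.strand.iloc[0]),
                gene_id=sub.gene_id.iloc[0],
                transcript_id=tx_id,
                sp_start=a, sp_end=b,
                summit=summit,
                summit_sp=(int(bw.sp_start) + int(bw.sp_end)) // 2,
                m6a_level=m6a_level(xi, xn, N_ip, N_in),
                pvalue=float(p[run].min()),
                fdr=float(q[run].min()),
                condition=condition,
                window_ids=tuple(run),
            ))
    return peaks


def merge_peak_sets(*peak_sets: Sequence[PeakRecord]) -> list[PeakRecord]:
    """Union of peak sets: spliced intervals on the same transcript that
    overlap or touch are merged into one (coordinates only; statistics are
    recomputed downstream)."""
    by_tx: dict[str, list[PeakRecord]] = {}
    for peaks in peak_sets:
        for pk in peaks:
            by_tx.setdefault(pk.transcript_id, []).append(pk)
    merged: list[PeakRecord] = []
    for tx_id in sorted(by_tx):
        peaks = sorted(by_tx[tx_id], key=lambda p: p.sp_start)
        cur = peaks[0]
        cur_a, cur_b = cur.sp_start, cur.sp_end
        members = [cur]
        for pk in peaks[1:]:
            if pk.sp_start <= cur_b:
                cur_b = max(cur_b, pk.sp_end)
                members.append(pk)
            else:
                merged.append(_combine(members, cur_a, cur_b))
                cur_a, cur_b, members = pk.sp_start, pk.sp_end, [pk]
        merged.append(_combine(members, cur_a, cur_b))
    return merged


def _combine(members: list[PeakRecord], a: int, b: int) -> PeakRecord:
    first = members[0]
    best = min(members, key=lambda p: p.pvalue)
    return PeakRecord(
        interval=GenomicInterval(first.interval.chrom,
                                 min(p.interval.start for p in members),
                                 max(p.interval.end for p in members),
                                 first.interval.strand),
        gene_id=first.gene_id, transcript_id=first.transcript_id,
        sp_start=a, sp_end=b,
        summit=best.summit, summit_sp=best.summit_sp,
        m6a_level=best.m6a_level, pvalue=best.pvalue, fdr=best.fdr,
        condition="union",
        window_ids=tuple(sorted({w for p in members for w in p.window_ids})),
    )


# --------------------------------------------------------------------------
# Differential methylation
# --------------------------------------------------------------------------

def fisher_test(table) -> float:
    """Two-sided Fisher exact p ("sum of <=-probability tables")."""
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass
class DiffPeakRecord:
    peak: PeakRecord
    m6a_level_gm: float
    m6a_level_d4: float
    diff_log2_fc: float
    pvalue: float
    fdr: float
    diff_lg_fdr: float
    status: str  # hyper / hypo / ns


def differential_peaks(peaks_union: Sequence[PeakRecord],
                       wcm: WindowCountMatrix,
                       q_threshold: float = DIFF_Q) -> list[DiffPeakRecord]:
    """Fisher's exact test of IP/input balance between conditions per peak.

    For each peak the replicate-summed IP and input counts of its windows
    form a 2x2 table (condition x role), tested two-sided; BH runs across
    peaks and diff_lg_fdr is log10 of the adjusted q.  diff_log2_fc is the
    D4 - GM difference of peak methylation levels.

    The four cells are depth-normalized (rescaled to the geometric mean of
    the library totals and rounded) before the exact test, otherwise unequal
    sequencing depths alone shift the odds ratio away from 1.  Totals are
    taken over background windows (those not overlapping any peak of the
    union) so that the enrichment signal itself does not contaminate the
    depth estimate; peak methylation levels inside this function use the
    same background totals.
    """
    if not peaks_union:
        return []
    pooled = {(c, r): wcm.pooled(c, r) for c in CONDITIONS for r in ("IP", "input")}
    in_peak = pd.Series(False, index=wcm.windows.index)
    for pk in peaks_union:
        hit = ((wcm.windows.transcript_id == pk.transcript_id)
               & (wcm.windows.sp_start < pk.sp_end)
               & (wcm.windows.sp_end > pk.sp_start))
        in_peak |= hit
    bg = ~in_peak
    totals = {k: int(v[bg].sum()) for k, v in pooled.items()}
    if min(totals.values()) <= 0:  # degenerate: everything is peak
        totals = {k: int(v.sum()) for k, v in pooled.items()}
    ref = math.exp(np.mean([math.log(v) for v in totals.values()]))
    scale = {k: ref / v for k, v in totals.items()}
    tables, levels = [], []
    windows = wcm.windows
    for pk in peaks_union:
        in_tx = windows.transcript_id == pk.transcript_id
        hit = in_tx & (windows.sp_start < pk.sp_end) & (windows.sp_end > pk.sp_start)
        ids = windows.index[hit]
        if len(ids) == 0:
            raise ValueError(
                f"peak {pk.gene_id}:{pk.sp_start}-{pk.sp_end} overlaps no window")
        row, norm = {}, {}
        for c in CONDITIONS:
            xi = int(pooled[c, "IP"].loc[ids].sum())
            xn = int(pooled[c, "input"].loc[ids].sum())
            row[c] = (xi, xn)
            norm[c] = (int(round(xi * scale[c, "IP"])),
                       int(round(xn * scale[c, "input"])))
        tables.append(norm)
        levels.append({c: m6a_level(row[c][0], row[c][1],
                                    totals[c, "IP"], totals[c, "input"])
                       for c in CONDITIONS})
    pvals = np.array([
        fisher_test([[t["GM"][0], t["GM"][1]],
                     [t["D4"][0], t["D4"][1]]])
        for t in tables
    ])
    qvals = bh_adjust(pvals)
    out = []
    for pk, lv, p, q in zip(peaks_union, levels, pvals, qvals):
        dfc = lv["D4"] - lv["GM"]
        lg = math.log10(q) if q > 0 else -np.inf
        if q <= q_threshold and dfc > 0:
            status = "hyper"
        elif q <= q_threshold and dfc < 0:
            status = "hypo"
        else:
            status = "ns"
        out.append(DiffPeakRecord(pk, lv["GM"], lv["D4"], dfc,
                                  float(p), float(q), lg, status))
    n_sig = sum(d.status != "ns" for d in out)
    logger.info("differential_peaks: %d/%d peaks differential at q<=%g",
                n_sig, len(out), q_threshold)
    return out


# --------------------------------------------------------------------------
# Tabular output
# --------------------------------------------------------------------------

def peaks_to_dataframe(peaks: Sequence[PeakRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": p.interval.chrom, "start": p.interval.start,
        "end": p.interval.end, "strand": p.interval.strand,
        "gene_id": p.gene_id, "transcript_id": p.transcript_id,
        "sp_start": p.sp_start, "sp_end": p.sp_end, "summit": p.summit,
        "m6a_level": p.m6a_level, "pvalue": p.pvalue, "fdr": p.fdr,
        "condition": p.condition,
    } for p in peaks])


def write_peak_bed(peaks: Sequence[PeakRecord], path: str) -> None:
    """BED6+3: name=gene_id, extra columns gene_id, m6a_level, fdr."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.gene_id}\t0\t"
                     f"{iv.strand}\t{p.gene_id}\t{p.m6a_level:.4f}\t"
                     f"{p.fdr:.3e}\n")


DIFF_TABLE_COLUMNS = [
    "Chr", "Peak_start", "Peak_end", "Strand", "Ensembl_ID", "Gene_Name",
    "RNA-seq_log2FoldChange", "RNA-seq_padj", "MeRIP-seq_diff.log2.fc",
    "MeRIP-seq_diff.lg.fdr", "Gene_Type", "Group",
]


def diff_peaks_to_table(diffs: Sequence[DiffPeakRecord],
                        annotation: GenomeAnnotation,
                        de_results: pd.DataFrame | None = None,
                        groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Differential-peak table in the worked-example layout.

    RNA-seq columns are joined from a DE result table (indexed or keyed by
    gene_id) when given; the Group column from a gene_id -> group mapping.
    """
    de = None
    if de_results is not None:
        de = de_results.set_index("gene_id") if "gene_id" in de_results.columns \
            else de_results
    rows = []
    for d in diffs:
        g = annotation.genes[d.peak.gene_id]
        lfc = padj = np.nan
        if de is not None and g.gene_id in de.index:
            lfc = de.at[g.gene_id, "log2FoldChange"]
            padj = de.at[g.gene_id, "padj"]
        rows.append({
            "Chr": d.peak.interval.chrom,
            "Peak_start": d.peak.interval.start,
            "Peak_end": d.peak.interval.end,
            "Strand": d.peak.interval.strand,
            "Ensembl_ID": g.gene_id,
            "Gene_Name": g.gene_name,
            "RNA-seq_log2FoldChange": lfc,
            "RNA-seq_padj": padj,
            "MeRIP-seq_diff.log2.fc": d.diff_log2_fc,
            "MeRIP-seq_diff.lg.fdr": d.diff_lg_fdr,
            "Gene_Type": g.gene_type,
            "Group": (groups or {}).get(g.gene_id, ""),
        })
    return pd.DataFrame(rows, columns=DIFF_TABLE_COLUMNS)
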