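"""Peak placement over lncRNA architecture and motif enrichment.

Covers four descriptive summaries of a called peak set: which exon element
(first/internal/last, in transcript orientation) peaks fall in and how
enriched each element is relative to its share of exonic length; a metagene
density of peak summits along the transcript rescaled to [0, 1); the
peaks-per-gene distribution; and DRACH/k-mer motif over-representation in
peak sequences against a dinucleotide-preserving shuffled background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import (GenomeAnnotation, SINGLE_EXON, Transcript,
                           genomic_to_transcript)
from .merip_peaks import PeakRecord, bh_adjust, spliced_to_genomic_pieces

logger = logging.getLogger(__name__)

ELEMENTS = ("first_exon", "internal_exon", "last_exon")
DRACH = "DRACH"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


class SequenceError(ValueError):
    pass


# --------------------------------------------------------------------------
# Exon-element summary
# --------------------------------------------------------------------------

@dataclass
class ElementSummary:
    counts: dict[str, int]
    proportions: dict[str, float]
    length_share: dict[str, float]
    relative_enrichment: dict[str, float]
    n_single_exon: int
    n_unclassified: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "element": list(ELEMENTS),
            "n_peaks": [self.counts[e] for e in ELEMENTS],
            "proportion": [self.proportions[e] for e in ELEMENTS],
            "length_share": [self.length_share[e] for e in ELEMENTS],
            "relative_enrichment": [self.relative_enrichment[e]
                                    for e in ELEMENTS],
        })


def _element_lengths(tx: Transcript) -> dict[str, int]:
    lens = [e - s for s, e in tx.exons]
    if tx.strand == "-":
        lens = lens[::-1]
    return {"first_exon": lens[0], "internal_exon": sum(lens[1:-1]),
            "last_exon": lens[-1]}


def element_summary(peaks: Sequence[PeakRecord],
                    annotation: GenomeAnnotation) -> ElementSummary:
    """Tally peaks per exon element with length-normalized enrichment.

    Peaks on single-exon transcripts are counted separately (the three-way
    split is undefined for them); relative enrichment divides each element's
    share of peaks by its share of exonic length over the distinct multi-exon
    host transcripts of the classified peaks.
    """
    from .genome_model import exon_element  # local to avoid cycle confusion
    counts = {e: 0 for e in ELEMENTS}
    n_single = n_none = 0
    hosts: dict[str, Transcript] = {}
    for pk in peaks:
        tx = annotation.transcripts[pk.transcript_id]
        label = exon_element(tx, pk.interval)
        if label == SINGLE_EXON:
            n_single += 1
        elif label == "none":
            n_none += 1
        else:
            counts[label] += 1
            hosts[tx.transcript_id] = tx
    total = sum(counts.values())
    props = {e: counts[e] / total if total else float("nan") for e in ELEMENTS}
    elem_len = {e: 0 for e in ELEMENTS}
    for tx in hosts.values():
        for e, L in _element_lengths(tx).items():
            elem_len[e] += L
    len_total = sum(elem_len.values())
    share = {e: elem_len[e] / len_total if len_total else float("nan")
             for e in ELEMENTS}
    enrich = {e: props[e] / share[e] if share.get(e) else float("nan")
              for e in ELEMENTS}
    if n_none:
        logger.info("element_summary: %d peaks with midpoint outside exons",
                    n_none)
    return ElementSummary(counts, props, share, enrich, n_single, n_none)


# --------------------------------------------------------------------------
# Metagene profile
# --------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    n_bins: int
    density: np.ndarray
    n_peaks_used: int
    n_skipped: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": np.arange(self.n_bins),
                             "density": self.density})


def metagene(peaks: Sequence[PeakRecord], annotation: GenomeAnnotation,
             n_bins: int = 100) -> MetageneProfile:
    """Density of peak summits along the 5'->3' transcript, unit-rescaled.

    Each peak counts once at its summit; the bin is
    floor(n_bins * transcript_coord / L).  Summits that do not map onto an
    exon are skipped with a logged count; an empty peak list is an error.
    """
    if not peaks:
        raise ValueError("metagene: empty peak list")
    hist = np.zeros(n_bins)
    skipped = 0
    for pk in peaks:
        tx = annotation.transcripts[pk.transcript_id]
        coord = genomic_to_transcript(tx, pk.summit)
        if coord < 0:
            skipped += 1
            continue
        hist[int(n_bins * coord / tx.spliced_length)] += 1
    if skipped:
        logger.info("metagene: skipped %d peaks with non-exonic summit",
                    skipped)
    used = int(hist.sum())
    density = hist / used if used else hist
    return MetageneProfile(n_bins, density, used, skipped)


def peaks_per_gene(peaks: Sequence[PeakRecord],
                   gene_ids: Iterable[str] | None = None
                   ) -> tuple[pd.Series, float]:
    """Histogram and median of peak counts over methylated genes (>=1 peak)."""
    wanted = set(gene_ids) if gene_ids is not None else None
    per_gene: dict[str, int] = {}
    for pk in peaks:
        if wanted is None or pk.gene_id in wanted:
            per_gene[pk.gene_id] = per_gene.get(pk.gene_id, 0) + 1
    if not per_gene:
        return pd.Series(dtype=int), float("nan")
    counts = pd.Series(per_gene)
    return counts.value_counts().sort_index(), float(counts.median())


# --------------------------------------------------------------------------
# Sequences
# --------------------------------------------------------------------------

def _fetch(genome, chrom: str, start: int, end: int) -> str:
    seq = genome[chrom][start:end]
    if isinstance(seq, np.ndarray):
        return seq.tobytes().decode()
    return str(seq)  # pyfaidx and plain strings


def peak_sequence(pk: PeakRecord, annotation: GenomeAnnotation, genome) -> str:
    """Spliced, strand-oriented (5'->3') sequence under a peak."""
    tx = annotation.transcripts[pk.transcript_id]
    parts = [_fetch(genome, tx.chrom, s, e)
             for s, e in spliced_to_genomic_pieces(tx, pk.sp_start, pk.sp_end)]
    seq = "".join(parts).upper()
    if tx.strand == "-":
        seq = seq.encode().translate(_COMPLEMENT)[::-1].decode()
    return seq


def extract_peak_sequences(peaks: Sequence[PeakRecord],
                           annotation: GenomeAnnotation, genome) -> list[str]:
    return [peak_sequence(pk, annotation, genome) for pk in peaks]


def _normalize(seq: str, label: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise SequenceError(
            f"sequence {label}: invalid characters {sorted(bad)}")
    return s


# --------------------------------------------------------------------------
# Motif scanning and enrichment
# --------------------------------------------------------------------------

def scan_iupac(seq: str, pattern: str) -> list[int]:
    """Start positions where the IUPAC pattern matches, given strand only.

    Implemented as a direct per-position character-class check (the test
    suite compares it against a compiled-regex oracle).
    """
    s = _normalize(seq, "<query>")
    classes = [IUPAC[c] for c in pattern.upper()]
    k = len(classes)
    hits = []
    for i in range(len(s) - k + 1):
        for j, cls in enumerate(classes):
            if s[i + j] not in cls:
                break
        else:
            hits.append(i)
    return hits


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (Altschul-Erikson).

    Builds the dinucleotide multigraph, fixes a random last-exit edge per
    vertex forming a tree into the terminal nucleotide (rejection-sampled),
    permutes each vertex's remaining exits, and rebuilds the sequence as the
    resulting Eulerian walk.
    """
    s = _normalize(seq, "<shuffle>")
    if len(s) < 3:
        return s
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    vertices = list(edges)
    terminal = s[-1]
    while True:  # sample last-exit edges until they form a tree into terminal
        last = {v: edges[v][rng.integers(len(edges[v]))]
                for v in vertices if v != terminal}
        ok = True
        for v in vertices:
            if v == terminal:
                continue
            seen, cur = {v}, v
            while cur != terminal and cur in last:
                cur = last[cur]
                if cur in seen:
                    break
                seen.add(cur)
            if cur != terminal:
                ok = False
                break
        if ok:
            break
    pools = {}
    for v in vertices:
        pool = list(edges[v])
        if v != terminal:
            pool.remove(last[v])
        rng.shuffle(pool)
        if v != terminal:
            pool.append(last[v])
        pools[v] = pool
    out, cur = [s[0]], s[0]
    for _ in range(len(s) - 1):
        nxt = pools[cur].pop(0)
        out.append(nxt)
        cur = nxt
    return "".join(out)


@dataclass
class MotifResult:
    pattern: str
    fg_hits: int
    fg_sites: int
    bg_hits: int
    bg_sites: int
    fold: float
    pvalue: float
    qvalue: float = float("nan")


def _count_hits(seqs: Sequence[str], pattern: str) -> tuple[int, int]:
    k = len(pattern)
    hits = sites = 0
    for i, s in enumerate(seqs):
        s = _normalize(s, str(i))
        hits += len(scan_iupac(s, pattern))
        sites += max(len(s) - k + 1, 0)
    return hits, sites


def _binom_p(fg_hits, fg_sites, bg_hits, bg_sites):
    """One-sided binomial p of the foreground rate exceeding background."""
    rate = bg_hits / bg_sites if bg_sites else 0.0
    rate = min(max(rate, 0.5 / max(bg_sites, 1)), 1.0)
    return stats.binom.sf(np.asarray(fg_hits) - 1, np.asarray(fg_sites), rate)


def default_background(seqs: Sequence[str], rng: np.random.Generator,
                       n_shuffles: int = 10) -> list[str]:
    return [dinucleotide_shuffle(s, rng)
            for s in seqs for _ in range(n_shuffles)]


def motif_enrichment(fg_seqs: Sequence[str],
                     bg_seqs: Sequence[str] | None = None,
                     pattern: str = DRACH,
                     rng: np.random.Generator | None = None,
                     n_shuffles: int = 10) -> MotifResult:
    """Enrichment of one IUPAC pattern in foreground vs background.

    Background defaults to seeded dinucleotide-preserving shuffles of the
    foreground.  Matching is single-strand (sense/RNA) only.
    """
    if bg_seqs is None:
        if rng is None:
            rng = np.random.default_rng(0)
        bg_seqs = default_background(fg_seqs, rng, n_shuffles)
    fg_hits, fg_sites = _count_hits(fg_seqs, pattern)
    bg_hits, bg_sites = _count_hits(bg_seqs, pattern)
    fg_rate = fg_hits / fg_sites if fg_sites else float("nan")
    bg_rate = bg_hits / bg_sites if bg_sites else float("nan")
    fold = fg_rate / bg_rate if bg_rate else float("inf")
    p = float(_binom_p(fg_hits, fg_sites, bg_hits, bg_sites))
    return MotifResult(pattern, fg_hits, fg_sites, bg_hits, bg_sites,
                       fold, p, p)


def kmer_enrichment(fg_seqs: Sequence[str],
                    bg_seqs: Sequence[str] | None = None,
                    k_values: Sequence[int] = (5, 6, 7, 8),
                    rng: np.random.Generator | None = None,
                    n_shuffles: int = 10,
                    top: int | None = 20) -> pd.DataFrame:
    """De-novo mode: rank exact k-mers by one-sided binomial p, BH per k.

    k defaults to the 5-8 range used for short RNA motif discovery.
    """
    if bg_seqs is None:
        if rng is None:
            rng = np.random.default_rng(0)
        bg_seqs = default_background(fg_seqs, rng, n_shuffles)
    fg = [_normalize(s, str(i)) for i, s in enumerate(fg_seqs)]
    bg = [_normalize(s, str(i)) for i, s in enumerate(bg_seqs)]
    frames = []
    for k in k_values:
        fg_counts: dict[str, int] = {}
        bg_counts: dict[str, int] = {}
        fg_sites = bg_sites = 0
        for s in fg:
            fg_sites += max(len(s) - k + 1, 0)
            for i in range(len(s) - k + 1):
                w = s[i:i + k]
                fg_counts[w] = fg_counts.get(w, 0) + 1
        for s in bg:
            bg_sites += max(len(s) - k + 1, 0)
            for i in range(len(s) - k + 1):
                w = s[i:i + k]
                bg_counts[w] = bg_counts.get(w, 0) + 1
        kmers = sorted(fg_counts)
        fh = np.array([fg_counts[w] for w in kmers])
        bh = np.array([bg_counts.get(w, 0) for w in kmers])
        bg_rate = np.minimum(np.maximum(bh / bg_sites, 0.5 / bg_sites), 1.0)
        p = stats.binom.sf(fh - 1, fg_sites, bg_rate)
        with np.errstate(divide="ignore"):
            fold = (fh / fg_sites) / np.where(bh > 0, bh / bg_sites, np.nan)
        frames.append(pd.DataFrame({
            "kmer": kmers, "k": k, "fg_hits": fh, "fg_sites": fg_sites,
            "bg_hits": bh, "bg_sites": bg_sites, "fold": fold,
            "pvalue": p, "qvalue": bh_adjust(p),
        }))
    out = pd.concat(frames, ignore_index=True).sort_values(
        ["pvalue", "kmer"]).reset_index(drop=True)
    return out.head(top) if top else out
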