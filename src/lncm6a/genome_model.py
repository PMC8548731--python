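"""Annotation model and strand-aware coordinate arithmetic.

All coordinates are held internally as 0-based half-open intervals on the
genome; conversion to/from the 1-based inclusive GTF convention happens only
at file boundaries.  Every downstream stage (window tiling, peak placement,
metagene profiling, neighbor pairing) shares the containers defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import gffutils

logger = logging.getLogger(__name__)

#: sentinel returned when a genomic position does not map onto a transcript
INTRONIC = -1

LNC_BIOTYPES = frozenset({"lincRNA", "antisense", "processed_transcript"})
CODING_BIOTYPE = "protein_coding"


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Gene:
    gene_id: str
    gene_name: str
    gene_type: str
    chrom: str
    strand: str
    start: int
    end: int

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    #: exons as (start, end) tuples, disjoint, sorted by genomic start
    exons: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise AnnotationError(
                    f"{self.transcript_id}: bad exon [{s}, {e})"
                )
            if s < prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


class GenomeAnnotation:
    """Genes, transcripts and exons indexed for the analysis stages.

    ``load_summary`` records how many input records lacked a gene_type (they
    are kept with gene_type="unknown" and dropped later at the biotype split).
    """

    def __init__(self, genes: Iterable[Gene], transcripts: Iterable[Transcript],
                 load_summary: dict | None = None):
        self.genes: dict[str, Gene] = {g.gene_id: g for g in genes}
        self.transcripts: dict[str, Transcript] = {
            t.transcript_id: t for t in transcripts
        }
        self.load_summary = dict(load_summary or {})
        self._tx_by_gene: dict[str, list[str]] = {}
        for t in self.transcripts.values():
            if t.gene_id not in self.genes:
                raise AnnotationError(
                    f"transcript {t.transcript_id} references missing gene "
                    f"{t.gene_id}"
                )
            self._tx_by_gene.setdefault(t.gene_id, []).append(t.transcript_id)

    def __len__(self) -> int:
        return len(self.genes)

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [self.transcripts[t] for t in self._tx_by_gene.get(gene_id, [])]

    def canonical_transcript(self, gene_id: str) -> Transcript:
        """Longest transcript of the gene (by spliced length, id tie-break)."""
        txs = self.transcripts_of(gene_id)
        if not txs:
            raise AnnotationError(f"gene {gene_id} has no transcripts")
        return max(txs, key=lambda t: (t.spliced_length, t.transcript_id))

    def exonic_length(self, gene_id: str) -> int:
        return self.canonical_transcript(gene_id).spliced_length

    def genes_by_type(self, types: Iterable[str]) -> list[Gene]:
        wanted = set(types)
        return [g for g in self.genes.values() if g.gene_type in wanted]

    def lnc_genes(self, extra_types: Iterable[str] = ()) -> list[Gene]:
        return self.genes_by_type(LNC_BIOTYPES | set(extra_types))

    def coding_genes(self) -> list[Gene]:
        return self.genes_by_type({CODING_BIOTYPE})


# --------------------------------------------------------------------------
# GTF input / output
# --------------------------------------------------------------------------

def _prevalidate_gtf(path: str) -> int:
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            n_records += 1
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"found {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if end < start:
                raise AnnotationError(
                    f"{path}:{lineno}: end < start ({end} < {start})"
                )
    return n_records


def read_gtf(path: str, strip_chr_prefix: bool = False) -> GenomeAnnotation:
    """Load exon features from a GTF file.

    1-based inclusive GTF coordinates become 0-based half-open; records
    without a gene_type attribute are kept as ``unknown`` and counted in the
    returned annotation's ``load_summary``.
    """
    if _prevalidate_gtf(path) == 0:
        logger.warning("read_gtf: %s contains no feature records", path)
        return GenomeAnnotation([], [], load_summary={"n_exons": 0,
                                                      "n_missing_gene_type": 0})
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons_by_tx: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    gene_meta: dict[str, dict] = {}
    n_missing_type = 0
    n_exons = 0
    for feat in db.features_of_type("exon"):
        n_exons += 1
        gene_id = feat.attributes["gene_id"][0]
        tx_id = feat.attributes["transcript_id"][0]
        chrom = feat.seqid
        if strip_chr_prefix and chrom.startswith("chr"):
            chrom = chrom[3:]
        if "gene_type" in feat.attributes:
            gene_type = feat.attributes["gene_type"][0]
        else:
            gene_type = "unknown"
            n_missing_type += 1
        gene_name = feat.attributes.get("gene_name", [gene_id])[0]
        start, end = feat.start - 1, feat.end  # GTF -> half-open
        exons_by_tx.setdefault(tx_id, []).append((start, end))
        tx_meta[tx_id] = (gene_id, chrom, feat.strand)
        meta = gene_meta.setdefault(
            gene_id,
            {"name": gene_name, "type": gene_type, "chrom": chrom,
             "strand": feat.strand, "start": start, "end": end},
        )
        meta["start"] = min(meta["start"], start)
        meta["end"] = max(meta["end"], end)
        if meta["type"] == "unknown" and gene_type != "unknown":
            meta["type"] = gene_type

    if n_exons == 0:
        logger.warning("read_gtf: no exon features found in %s", path)
    if n_missing_type:
        logger.warning(
            "read_gtf: %d exon records lacked gene_type (set to 'unknown')",
            n_missing_type,
        )
    genes = [
        Gene(gid, m["name"], m["type"], m["chrom"], m["strand"],
             m["start"], m["end"])
        for gid, m in gene_meta.items()
    ]
    transcripts = [
        Transcript(tx, gid, chrom, strand, tuple(sorted(exons_by_tx[tx])))
        for tx, (gid, chrom, strand) in tx_meta.items()
    ]
    return GenomeAnnotation(
        genes, transcripts,
        load_summary={"n_exons": n_exons, "n_missing_gene_type": n_missing_type},
    )


def write_gtf(annotation: GenomeAnnotation, path: str) -> None:
    """Emit exon features, converting back to 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for tx in sorted(annotation.transcripts.values(),
                         key=lambda t: (t.chrom, t.start, t.transcript_id)):
            gene = annotation.genes[tx.gene_id]
            attrs = (
                f'gene_id "{gene.gene_id}"; '
                f'transcript_id "{tx.transcript_id}"; '
                f'gene_type "{gene.gene_type}"; '
                f'gene_name "{gene.gene_name}";'
            )
            for s, e in tx.exons:
                fh.write(
                    f"{tx.chrom}\tlncm6a\texon\t{s + 1}\t{e}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )


def write_bed6(intervals: Iterable[GenomicInterval], names: Iterable[str],
               path: str) -> None:
    with open(path, "w") as fh:
        for iv, name in zip(intervals, names):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# --------------------------------------------------------------------------
# Coordinate arithmetic
# --------------------------------------------------------------------------

def genomic_to_transcript(tx: Transcript, pos: int) -> int:
    """Map a genomic position to its spliced-transcript coordinate.

    Returns INTRONIC when ``pos`` lies in an intron or outside the transcript.
    On the + strand the coordinate counts exonic nucleotides preceding ``pos``;
    on the - strand it is ``L - 1`` minus that value, so coordinate 0 is the
    transcript's 5' end on either strand.
    """
    offset = 0
    plus_coord = None
    for s, e in tx.exons:
        if s <= pos < e:
            plus_coord = offset + (pos - s)
            break
        offset += e - s
    if plus_coord is None:
        return INTRONIC
    if tx.strand == "-":
        return tx.spliced_length - 1 - plus_coord
    return plus_coord


def transcript_to_genomic(tx: Transcript, coord: int) -> int:
    """Inverse of :func:`genomic_to_transcript` for coord in [0, L)."""
    L = tx.spliced_length
    if not 0 <= coord < L:
        raise ValueError(f"transcript coordinate {coord} outside [0, {L})")
    plus_coord = L - 1 - coord if tx.strand == "-" else coord
    offset = 0
    for s, e in tx.exons:
        if plus_coord < offset + (e - s):
            return s + (plus_coord - offset)
        offset += e - s
    raise AssertionError("unreachable: coord within [0, L)")


SINGLE_EXON = "single_exon"


def exon_element(tx: Transcript, interval: GenomicInterval) -> str:
    """Classify an interval as first_exon / internal_exon / last_exon / none.

    The interval midpoint decides; "first" and "last" follow transcript
    orientation, so the genomically last exon of a - strand transcript is its
    first exon.  Single-exon transcripts get their own label so callers can
    tally them separately.
    """
    if tx.n_exons == 1:
        s, e = tx.exons[0]
        return SINGLE_EXON if s <= interval.midpoint < e else "none"
    mid = interval.midpoint
    for i, (s, e) in enumerate(tx.exons):
        if s <= mid < e:
            genomic_idx = i
            break
    else:
        return "none"
    idx = genomic_idx if tx.strand != "-" else tx.n_exons - 1 - genomic_idx
    if idx == 0:
        return "first_exon"
    if idx == tx.n_exons - 1:
        return "last_exon"
    return "internal_exon"


def mirror_annotation(annotation: GenomeAnnotation,
                      chrom_lengths: dict[str, int]) -> GenomeAnnotation:
    """Reflect every coordinate through its chromosome end and flip strands.

    Used for strand-symmetry checks: position p becomes L - 1 - p, so the
    interval [s, e) becomes [L - e, L - s).
    """
    flip = {"+": "-", "-": "+", ".": "."}

    def _gene(g: Gene) -> Gene:
        L = chrom_lengths[g.chrom]
        return replace(g, start=L - g.end, end=L - g.start,
                       strand=flip[g.strand])

    def _tx(t: Transcript) -> Transcript:
        L = chrom_lengths[t.chrom]
        exons = tuple(sorted((L - e, L - s) for s, e in t.exons))
        return replace(t, strand=flip[t.strand], exons=exons)

    return GenomeAnnotation(
        [_gene(g) for g in annotation.genes.values()],
        [_tx(t) for t in annotation.transcripts.values()],
        load_summary=annotation.load_summary,
    )


def iter_exon_intervals(tx: Transcript) -> Iterator[GenomicInterval]:
    for s, e in tx.exons:
        yield GenomicInterval(tx.chrom, s, e, tx.strand)
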