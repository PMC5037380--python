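"""Transcriptome alignment ingestion and retention filtering.

A read is retained when it maps to the sense strand of transcripts of
exactly one gene with an alignment score of at least 85% of the clipped
fragment length.  Alignments come either from an external aligner via SAM
(``read_sam``; the production route, e.g. bwa-mem against a concatenated
human-mouse transcriptome) or from the built-in exact-seed ungapped aligner
(``KmerIndex``), which exists so the package is exercisable end-to-end
without an external aligner.

Strandedness convention: 3'-end libraries sequence the mRNA sense strand on
read 2, so "correct strandedness" means a forward-strand transcript
alignment (SAM reverse flag unset).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import pandas as pd
import pysam

from .readproc import TaggedRead
from .simdata import ToyTranscriptome

__all__ = [
    "AlignmentHit",
    "AlignedFragment",
    "TranscriptAnnotation",
    "KmerIndex",
    "resolve_gene",
    "filter_alignment",
    "assess_read",
    "align_tagged_reads",
    "read_sam",
    "DEFAULT_MIN_SCORE_FRAC",
]

DEFAULT_MIN_SCORE_FRAC = 0.85

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    transcript_id: str
    position: int          # 0-based leftmost reference position
    strand: str            # "sense" | "antisense"
    score: int             # matching bases (naive) or AS tag (SAM)


@dataclass(frozen=True)
class AlignedFragment:
    """One read's best transcriptome alignment and its retention decision."""

    read_id: str
    cell_barcode: str
    umi: str
    gene_id: str | None
    species: str | None
    strand: str | None
    alignment_score: int | None
    fragment_length: int
    status: str            # "kept" | "discarded"
    reason: str | None     # discard reason when status == "discarded"

    @property
    def kept(self) -> bool:
        return self.status == "kept"


class TranscriptAnnotation(Mapping):
    """Total mapping transcript_id -> (gene_id, species)."""

    def __init__(self, mapping: dict[str, tuple[str, str]]):
        self._map = dict(mapping)

    def __getitem__(self, transcript_id: str) -> tuple[str, str]:
        return self._map[transcript_id]

    def __iter__(self):
        return iter(self._map)

    def __len__(self):
        return len(self._map)

    def gene_species(self) -> dict[str, str]:
        return {gene: sp for gene, sp in self._map.values()}

    @classmethod
    def from_toy(cls, tx: ToyTranscriptome) -> "TranscriptAnnotation":
        return cls({g.transcript_id: (g.gene_id, g.species) for g in tx.genes})

    @classmethod
    def from_table(cls, path: str) -> "TranscriptAnnotation":
        """Load a TSV with columns transcript_id, gene_id, species."""
        df = pd.read_csv(path, sep="\t")
        required = {"transcript_id", "gene_id", "species"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation table needs columns {sorted(required)}")
        return cls(
            {row.transcript_id: (row.gene_id, row.species) for row in df.itertuples()}
        )


class KmerIndex:
    """Exact k-mer seeding with ungapped extension over a small transcriptome.

    Seeds are sampled every k bases along the query (both orientations);
    each seed hit proposes a diagonal, and the score of a diagonal is the
    number of matching bases between the query and the reference within the
    reference bounds.  K-mers occurring more than ``max_hits`` times in the
    index (poly(A) tails, low-complexity sequence) are masked out at build
    time.  All hits achieving the maximal score are reported.
    """

    def __init__(self, sequences: Mapping[str, str], k: int = 15, max_hits: int = 64):
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        self.k = k
        self.sequences = dict(sequences)
        index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        overflow: set[str] = set()
        for tid, seq in self.sequences.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if kmer in overflow:
                    continue
                bucket = index[kmer]
                bucket.append((tid, pos))
                if len(bucket) > max_hits:
                    overflow.add(kmer)
                    del index[kmer]
        self._index = dict(index)

    @classmethod
    def from_toy(cls, tx: ToyTranscriptome, k: int = 15, max_hits: int = 64) -> "KmerIndex":
        return cls(tx.sequences(), k=k, max_hits=max_hits)

    def _candidates(self, query: str) -> set[tuple[str, int]]:
        k = self.k
        n = len(query)
        if n < k:
            return set()
        positions = list(range(0, n - k + 1, k))
        if positions[-1] != n - k:
            positions.append(n - k)
        cands: set[tuple[str, int]] = set()
        for qpos in positions:
            for tid, tpos in self._index.get(query[qpos : qpos + k], ()):
                cands.add((tid, tpos - qpos))
        return cands

    def _score(self, query: str, tid: str, diag: int) -> tuple[int, int]:
        """(score, ref_start) of an ungapped alignment on one diagonal."""
        ref = self.sequences[tid]
        tstart = max(0, diag)
        qstart = tstart - diag
        tend = min(len(ref), diag + len(query))
        if tend <= tstart:
            return 0, tstart
        ref_sub = ref[tstart:tend]
        q_sub = query[qstart : qstart + (tend - tstart)]
        if ref_sub == q_sub:
            return len(ref_sub), tstart
        return sum(a == b for a, b in zip(ref_sub, q_sub)), tstart

    def align(self, fragment: str) -> list[AlignmentHit]:
        """All maximal-score ungapped hits for a fragment, both orientations."""
        best: list[AlignmentHit] = []
        best_score = 0
        for strand, query in (("sense", fragment), ("antisense", reverse_complement(fragment))):
            for tid, diag in self._candidates(query):
                score, tstart = self._score(query, tid, diag)
                if score == 0:
                    continue
                if score > best_score:
                    best = [AlignmentHit(tid, tstart, strand, score)]
                    best_score = score
                elif score == best_score:
                    hit = AlignmentHit(tid, tstart, strand, score)
                    if hit not in best:
                        best.append(hit)
        return best


def resolve_gene(
    hits: Iterable[AlignmentHit], ann: TranscriptAnnotation
) -> tuple[str | None, str | None, str | None]:
    """Reduce equal-best hits to a unique gene call.

    Returns ``(gene_id, strand, reason)``.  Hits to multiple transcripts of
    one gene resolve to that gene; hits spanning more than one gene are
    ambiguous (``reason="multigene"``); no hits -> ``reason="unaligned"``.
    A gene whose best hits are not all sense-strand is reported with
    ``strand="antisense"`` (ties across strands count as antisense: purity
    over yield).
    """
    hits = list(hits)
    if not hits:
        return None, None, "unaligned"
    genes = {ann[h.transcript_id][0] for h in hits}
    if len(genes) > 1:
        return None, None, "multigene"
    gene = genes.pop()
    strand = "sense" if all(h.strand == "sense" for h in hits) else "antisense"
    return gene, strand, None


def filter_alignment(
    fragment_length: int,
    score: int | None,
    strand: str | None,
    gene_id: str | None,
    reason: str | None,
    min_score_frac: float = DEFAULT_MIN_SCORE_FRAC,
) -> tuple[str, str | None]:
    """Apply the retention rule; returns (status, reason).

    Kept iff the read has a unique gene, sense strand, and
    ``score >= min_score_frac * fragment_length`` (real-valued, inclusive).
    """
    if reason is not None:
        return "discarded", reason
    if gene_id is None:
        return "discarded", "unaligned"
    if strand != "sense":
        return "discarded", "strand"
    if score is None:
        return "discarded", "no_score"
    if score < min_score_frac * fragment_length:
        return "discarded", "low_score"
    return "kept", None


def assess_read(
    read: TaggedRead,
    hits: Iterable[AlignmentHit],
    ann: TranscriptAnnotation,
    min_score_frac: float = DEFAULT_MIN_SCORE_FRAC,
) -> AlignedFragment:
    gene, strand, reason = resolve_gene(hits, ann)
    score = max((h.score for h in hits), default=None)
    status, why = filter_alignment(
        read.fragment_length, score, strand, gene, reason, min_score_frac
    )
    species = ann.gene_species().get(gene) if gene is not None else None
    return AlignedFragment(
        read_id=read.read_id,
        cell_barcode=read.cell_barcode,
        umi=read.umi,
        gene_id=gene if status == "kept" else gene,
        species=species,
        strand=strand,
        alignment_score=score,
        fragment_length=read.fragment_length,
        status=status,
        reason=why,
    )


def align_tagged_reads(
    reads: Iterable[TaggedRead],
    index: KmerIndex,
    ann: TranscriptAnnotation,
    min_score_frac: float = DEFAULT_MIN_SCORE_FRAC,
    counters: Counter | None = None,
) -> Iterator[AlignedFragment]:
    """Run the naive aligner + retention filter over a tagged-read stream."""
    gene_species = ann.gene_species()
    if counters is None:
        counters = Counter()
    for read in reads:
        hits = index.align(read.fragment)
        gene, strand, reason = resolve_gene(hits, ann)
        score = max((h.score for h in hits), default=None)
        status, why = filter_alignment(
            read.fragment_length, score, strand, gene, reason, min_score_frac
        )
        counters["kept" if status == "kept" else why] += 1
        yield AlignedFragment(
            read_id=read.read_id,
            cell_barcode=read.cell_barcode,
            umi=read.umi,
            gene_id=gene,
            species=gene_species.get(gene) if gene else None,
            strand=strand,
            alignment_score=score,
            fragment_length=read.fragment_length,
            status=status,
            reason=why,
        )


def _sam_hit(rec: pysam.AlignedSegment, fragment_length: int) -> AlignmentHit | None:
    if rec.is_unmapped:
        return None
    if rec.has_tag("AS"):
        score = int(rec.get_tag("AS"))
    elif rec.has_tag("NM"):
        score = fragment_length - int(rec.get_tag("NM"))
    else:
        return AlignmentHit(rec.reference_name, rec.reference_start,
                            "antisense" if rec.is_reverse else "sense", -1)
    return AlignmentHit(
        rec.reference_name,
        rec.reference_start,
        "antisense" if rec.is_reverse else "sense",
        score,
    )


def read_sam(
    path: str,
    ann: TranscriptAnnotation,
    tagged: Mapping[str, TaggedRead],
    min_score_frac: float = DEFAULT_MIN_SCORE_FRAC,
    counters: Counter | None = None,
) -> Iterator[AlignedFragment]:
    """Join external SAM alignments to tagged reads and apply the filters.

    Secondary/supplementary records are grouped with their primary by query
    name so gene uniqueness is evaluated over the whole hit set.  The AS tag
    is used as the alignment score when present, else fragment_length - NM;
    records with neither are discarded with reason ``"no_score"``.  Unknown
    reference names raise; SAM reads absent from ``tagged`` are counted as
    ``"orphan"`` and skipped.
    """
    if counters is None:
        counters = Counter()
    gene_species = ann.gene_species()
    by_read: dict[str, list[pysam.AlignedSegment]] = defaultdict(list)
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.reference_name is not None and rec.reference_name not in ann:
                raise KeyError(
                    f"SAM reference {rec.reference_name!r} absent from annotation"
                )
            by_read[rec.query_name].append(rec)
    for read_id, records in by_read.items():
        read = tagged.get(read_id)
        if read is None:
            counters["orphan"] += 1
            continue
        hits = [h for h in (_sam_hit(r, read.fragment_length) for r in records) if h]
        no_score = any(h.score < 0 for h in hits)
        if no_score:
            status, why = "discarded", "no_score"
            gene = strand = score = None
        else:
            best = max((h.score for h in hits), default=None)
            hits = [h for h in hits if h.score == best]
            gene, strand, reason = resolve_gene(hits, ann)
            score = best
            status, why = filter_alignment(
                read.fragment_length, score, strand, gene, reason, min_score_frac
            )
        counters["kept" if status == "kept" else why] += 1
        yield AlignedFragment(
            read_id=read_id,
            cell_barcode=read.cell_barcode,
            umi=read.umi,
            gene_id=gene,
            species=gene_species.get(gene) if gene else None,
            strand=strand,
            alignment_score=score,
            fragment_length=read.fragment_length,
            status=status,
            reason=why,
        )


def write_decision_log(fragments: Iterable[AlignedFragment], path: str) -> None:
    """Per-read decision log: read_id, status, reason, gene, score."""
    rows = [
        {
            "read_id": f.read_id,
            "status": f.status,
            "reason": f.reason or "",
            "gene_id": f.gene_id or "",
            "score": f.alignment_score if f.alignment_score is not None else "",
        }
        for f in fragments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
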