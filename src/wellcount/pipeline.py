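"""End-to-end pipeline: paired FASTQ -> UMI-collapsed cell x gene matrix."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from . import alignkit, molcount, readproc
from .alignkit import KmerIndex, TranscriptAnnotation
from .molcount import AddressTable, CountMatrix, KneeResult
from .simdata import ToyTranscriptome

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    matrix: CountMatrix
    raw_table: AddressTable        # after identical-address collapse
    collapsed_table: AddressTable  # after edit-distance-1 UMI collapse
    knee: KneeResult
    counters: Counter


def run_pipeline(
    r1_path: str,
    r2_path: str,
    tx: ToyTranscriptome | None = None,
    fasta: str | None = None,
    annotation: str | None = None,
    sam: str | None = None,
    layout: str = "12C8M",
    min_len: int = readproc.DEFAULT_MIN_FRAGMENT,
    min_score_frac: float = alignkit.DEFAULT_MIN_SCORE_FRAC,
    expected_cells: int | None = None,
    k: int = 15,
) -> PipelineResult:
    """Run extraction, alignment, filtering, UMI collapse and cell calling.

    Alignments come from the built-in naive aligner over ``tx`` (or a
    FASTA + annotation pair) unless an external ``sam`` file is supplied, in
    which case its records are joined to the tagged reads by read id.
    """
    if tx is None:
        if fasta is None or annotation is None:
            raise ValueError("provide either tx or fasta + annotation")
        tx = ToyTranscriptome.read(fasta, annotation)
    ann = TranscriptAnnotation.from_toy(tx)
    counters: Counter = Counter()

    tagged = readproc.tag_read_pairs(
        r1_path, r2_path, layout=layout, min_len=min_len, counters=counters
    )
    if sam is not None:
        tagged_map = {t.read_id: t for t in tagged}
        fragments = alignkit.read_sam(
            sam, ann, tagged_map, min_score_frac=min_score_frac, counters=counters
        )
    else:
        index = KmerIndex.from_toy(tx, k=k)
        fragments = alignkit.align_tagged_reads(
            tagged, index, ann, min_score_frac=min_score_frac, counters=counters
        )

    raw = AddressTable.from_fragments(fragments)
    collapsed = molcount.collapse_umis(raw)
    knee = molcount.call_cells(
        collapsed.molecules_per_barcode(), expected_cells=expected_cells
    )
    matrix = molcount.to_matrix(collapsed, knee.selected, ann.gene_species())
    return PipelineResult(
        matrix=matrix,
        raw_table=raw,
        collapsed_table=collapsed,
        knee=knee,
        counters=counters,
    )
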