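"""Read pre-processing: barcode/UMI extraction and poly(A) clipping.

Read 1 of each pair carries the bead (cell) barcode followed by the UMI;
read 2 carries the cDNA fragment.  This module parses read 1 according to a
compact layout spec (e.g. ``"12C8M"``: 12 barcode cycles then 8 UMI cycles),
clips the 3'-terminal poly(A) run off read 2, and drops fragments shorter
than 25 nt.  No barcode whitelisting or error correction is performed here:
bead barcodes are random split-pool sequences with no whitelist, and barcode
quality is a cell-calling concern downstream.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterator

import pysam

__all__ = [
    "ReadLayout",
    "TaggedRead",
    "ReadTooShortError",
    "extract_tags",
    "clip_polya",
    "length_filter",
    "tag_read_pairs",
]

DEFAULT_MIN_FRAGMENT = 25


class ReadTooShortError(ValueError):
    """Read 1 does not cover the barcode + UMI layout."""


@dataclass(frozen=True)
class ReadLayout:
    """Barcode and UMI spans on read 1 (0-based, half-open)."""

    barcode_span: tuple[int, int]
    umi_span: tuple[int, int]

    def __post_init__(self):
        (b0, b1), (u0, u1) = self.barcode_span, self.umi_span
        if not (0 <= b0 < b1 and 0 <= u0 < u1):
            raise ValueError("spans must be non-empty and non-negative")
        if max(b0, u0) < min(b1, u1):
            raise ValueError("barcode and UMI spans overlap")

    @property
    def min_read1_length(self) -> int:
        return max(self.barcode_span[1], self.umi_span[1])

    @property
    def barcode_length(self) -> int:
        return self.barcode_span[1] - self.barcode_span[0]

    @property
    def umi_length(self) -> int:
        return self.umi_span[1] - self.umi_span[0]

    @classmethod
    def parse(cls, spec: str) -> "ReadLayout":
        """Parse a compact layout string like ``"12C8M"``.

        Tokens are ``<n>C`` (cell barcode) and ``<n>M`` (molecular barcode /
        UMI), laid out left to right from the start of read 1.
        """
        tokens = re.findall(r"(\d+)([CM])", spec)
        if "".join(f"{n}{c}" for n, c in tokens) != spec:
            raise ValueError(f"malformed layout spec {spec!r}")
        pos = 0
        spans: dict[str, tuple[int, int]] = {}
        for n, code in tokens:
            n = int(n)
            if code in spans:
                raise ValueError(f"duplicate {code} token in layout {spec!r}")
            spans[code] = (pos, pos + n)
            pos += n
        if "C" not in spans or "M" not in spans:
            raise ValueError(f"layout {spec!r} must define both C and M spans")
        return cls(barcode_span=spans["C"], umi_span=spans["M"])


@dataclass(frozen=True)
class TaggedRead:
    """A read-2 fragment annotated with its cell barcode and UMI."""

    read_id: str
    cell_barcode: str
    umi: str
    fragment: str

    @property
    def fragment_length(self) -> int:
        return len(self.fragment)


def extract_tags(read1: str, layout: ReadLayout) -> tuple[str, str]:
    """Return the verbatim (cell_barcode, umi) subsequences of read 1.

    No error correction; ``N`` bases are passed through.  Raises
    :class:`ReadTooShortError` if read 1 does not cover the layout.
    """
    if len(read1) < layout.min_read1_length:
        raise ReadTooShortError(
            f"read 1 length {len(read1)} < layout end {layout.min_read1_length}"
        )
    b0, b1 = layout.barcode_span
    u0, u1 = layout.umi_span
    return read1[b0:b1], read1[u0:u1]


def clip_polya(fragment: str, min_run: int = 6, mismatch_per: int = 10) -> str:
    """Remove the maximal 3'-terminal poly(A) run from a fragment.

    A suffix of length L counts as a poly(A) run when it starts with an A,
    is at least ``min_run`` long, and contains at most ``L // mismatch_per``
    non-A bases (tolerating isolated sequencing errors inside the tail).
    The longest qualifying suffix is removed; the operation is idempotent.
    """
    n = len(fragment)
    best = 0
    non_a = 0
    for i in range(n - 1, -1, -1):
        if fragment[i] != "A":
            non_a += 1
        length = n - i
        if (
            fragment[i] == "A"
            and length >= min_run
            and non_a <= length // mismatch_per
        ):
            best = length
    return fragment[: n - best] if best else fragment


def length_filter(fragment: str, min_len: int = DEFAULT_MIN_FRAGMENT) -> bool:
    """Keep a fragment iff it is at least ``min_len`` nt (inclusive)."""
    return len(fragment) >= min_len


def tag_read_pairs(
    r1_path: str,
    r2_path: str,
    layout: ReadLayout | str = "12C8M",
    min_len: int = DEFAULT_MIN_FRAGMENT,
    clip: bool = True,
    counters: Counter | None = None,
) -> Iterator[TaggedRead]:
    """Stream (FASTQ read 1, FASTQ read 2) pairs into tagged fragments.

    Reads are dropped (and counted in ``counters``) with reason
    ``"short_read1"`` when read 1 does not cover the layout and
    ``"short_fragment"`` when the clipped fragment is below ``min_len``.
    Every input pair is accounted for exactly once:
    ``input == tagged + short_read1 + short_fragment``.

    Gzip-compressed FASTQ is handled transparently.
    """
    if isinstance(layout, str):
        layout = ReadLayout.parse(layout)
    if counters is None:
        counters = Counter()
    with pysam.FastxFile(r1_path) as f1, pysam.FastxFile(r2_path) as f2:
        for rec1, rec2 in zip(f1, f2):
            counters["input"] += 1
            if rec1.name != rec2.name:
                raise ValueError(
                    f"read name mismatch between mates: {rec1.name!r} vs {rec2.name!r}"
                )
            try:
                barcode, umi = extract_tags(rec1.sequence, layout)
            except ReadTooShortError:
                counters["short_read1"] += 1
                continue
            fragment = clip_polya(rec2.sequence) if clip else rec2.sequence
            if not length_filter(fragment, min_len):
                counters["short_fragment"] += 1
                continue
            counters["tagged"] += 1
            yield TaggedRead(rec1.name, barcode, umi, fragment)
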