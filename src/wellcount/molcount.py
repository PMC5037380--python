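"""Molecule counting: addresses, UMI collapse, cell calling, count matrix.

An *address* is the (gene, UMI, cell barcode) triple attached to each
retained read; in the absence of errors each distinct address is one
captured mRNA molecule.  Reads sharing an address are collapsed first, and
then, within each (barcode, gene) combination, an address is merged into a
higher-coverage address whose UMI lies within edit distance one.  The number
of surviving addresses per (cell, gene) is the molecule count.

Cell barcodes are called from the heavy-tailed per-barcode molecule-count
distribution by a knee point on the log-log rank plot (maximal distance to
the chord joining the curve's endpoints), with an explicit override for runs
where the expected cell count is known from imaging.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .alignkit import AlignedFragment

__all__ = [
    "AddressTable",
    "umi_distance",
    "collapse_group",
    "collapse_umis",
    "KneeResult",
    "call_cells",
    "knee_point",
    "CountMatrix",
    "to_matrix",
]

_BASES = "ACGT"


def umi_distance(u1: str, u2: str) -> int:
    """Hamming distance between two equal-length UMI sequences.

    UMI length is fixed by the read layout, so "edit distance" on UMIs is
    substitution-only; an indel would change the UMI length.
    """
    if len(u1) != len(u2):
        raise ValueError("UMIs must have equal length")
    return sum(a != b for a, b in zip(u1, u2))


@dataclass
class AddressTable:
    """Read counts per (cell barcode, gene, UMI), grouped by (barcode, gene)."""

    groups: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)

    def add(self, barcode: str, gene_id: str, umi: str, n: int = 1) -> None:
        if n < 1:
            raise ValueError("read count increment must be >= 1")
        group = self.groups.setdefault((barcode, gene_id), {})
        group[umi] = group.get(umi, 0) + n

    @classmethod
    def from_fragments(cls, fragments: Iterable[AlignedFragment]) -> "AddressTable":
        """Collapse retained reads with identical addresses, keeping multiplicity."""
        table = cls()
        for f in fragments:
            if f.kept:
                table.add(f.cell_barcode, f.gene_id, f.umi)
        return table

    @property
    def n_addresses(self) -> int:
        return sum(len(g) for g in self.groups.values())

    @property
    def total_reads(self) -> int:
        return sum(sum(g.values()) for g in self.groups.values())

    def molecules_per_barcode(self) -> dict[str, int]:
        out: Counter = Counter()
        for (barcode, _gene), group in self.groups.items():
            out[barcode] += len(group)
        return dict(out)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"barcode": bc, "gene_id": gene, "umi": umi, "read_count": n}
            for (bc, gene), group in sorted(self.groups.items())
            for umi, n in sorted(group.items())
        ]
        return pd.DataFrame(rows, columns=["barcode", "gene_id", "umi", "read_count"])


def _variants(umi: str) -> Iterable[str]:
    for i, c in enumerate(umi):
        for b in _BASES:
            if b != c:
                yield umi[:i] + b + umi[i + 1 :]


def collapse_group(counts: Mapping[str, int]) -> dict[str, int]:
    """Merge near-duplicate UMIs within one (barcode, gene) combination.

    Addresses are visited in ascending (read_count, UMI) order; each is
    merged into its highest-coverage Hamming-distance-1 neighbour provided
    that neighbour's *current* read count is strictly greater (a tie is not
    "a higher coverage address" and is left alone).  Merged read counts
    accumulate, so a survivor can absorb several error UMIs and then, having
    grown, absorb further neighbours visited later.  Ties among equal-count
    target neighbours break to the lexicographically smallest UMI.
    """
    current = dict(counts)
    order = sorted(current, key=lambda u: (current[u], u))
    for umi in order:
        mine = current.get(umi)
        if mine is None:
            continue  # already absorbed
        best_umi = None
        best_count = mine
        for v in _variants(umi):
            c = current.get(v)
            if c is None:
                continue
            if c > best_count or (c == best_count and best_umi is not None and v < best_umi):
                best_umi, best_count = v, c
        if best_umi is not None and best_count > mine:
            current[best_umi] = best_count + current.pop(umi)
    return current


def collapse_umis(table: AddressTable) -> AddressTable:
    """Apply :func:`collapse_group` to every (barcode, gene) combination.

    Total read counts are conserved; the number of addresses never grows.
    """
    out = AddressTable()
    for key, group in table.groups.items():
        out.groups[key] = collapse_group(group)
    return out


# ---------------------------------------------------------------------------
# cell calling
# ---------------------------------------------------------------------------

def knee_point(x: np.ndarray, y: np.ndarray, above: bool = True) -> int:
    """Index of the point farthest from the chord joining the endpoints.

    With ``above=True`` only points on the concave side of the chord (above
    it) are considered, which picks the corner where a high plateau breaks
    off; if no point is above the chord, all points compete.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points to find a knee")
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = float(np.hypot(dx, dy))
    if norm == 0:
        raise ValueError("degenerate curve: endpoints coincide")
    # signed perpendicular offset; positive = above the chord for dy < 0
    signed = (dx * (y - y[0]) - dy * (x - x[0])) / norm
    if above:
        mask = signed > 0
        if mask.any():
            candidates = np.where(mask, signed, -np.inf)
            return int(np.argmax(candidates))
    return int(np.argmax(np.abs(signed)))


@dataclass
class KneeResult:
    selected: list[str]
    threshold_count: int
    ranks: pd.DataFrame   # barcode, molecules, rank (descending order)
    knee_rank: int | None


def call_cells(
    totals: Mapping[str, int] | pd.Series,
    expected_cells: int | None = None,
    exclude_n_barcodes: bool = True,
) -> KneeResult:
    """Select cell barcodes from per-barcode molecule totals.

    Barcodes are ranked by descending molecule count; the threshold sits at
    the knee of the log10(count) vs log10(rank) curve (maximal distance from
    the chord joining its endpoints), and every barcode at or above the knee
    count is selected.  ``expected_cells`` overrides the knee and takes the
    top N, for runs where imaging gives the cell-bead pair count.  Barcodes
    containing N are excluded up front: they cannot be genuine bead
    sequences.
    """
    if isinstance(totals, pd.Series):
        totals = totals.to_dict()
    items = [
        (bc, int(n))
        for bc, n in totals.items()
        if n > 0 and not (exclude_n_barcodes and "N" in bc)
    ]
    if len(items) < 10:
        raise ValueError("need at least 10 barcodes with molecules to call cells")
    items.sort(key=lambda t: (-t[1], t[0]))
    barcodes = [bc for bc, _ in items]
    counts = np.array([n for _, n in items], dtype=np.int64)
    ranks = pd.DataFrame(
        {"barcode": barcodes, "molecules": counts, "rank": np.arange(1, len(items) + 1)}
    )

    if expected_cells is not None:
        if expected_cells < 1:
            raise ValueError("expected_cells must be >= 1")
        n_sel = min(expected_cells, len(items))
        return KneeResult(
            selected=barcodes[:n_sel],
            threshold_count=int(counts[n_sel - 1]),
            ranks=ranks,
            knee_rank=None,
        )

    if counts.min() == counts.max():
        raise ValueError(
            "degenerate molecule-count distribution (all barcodes equal); "
            "use the expected-cells override"
        )
    x = np.log10(np.arange(1, len(counts) + 1, dtype=float))
    y = np.log10(counts.astype(float))
    approx = knee_point(x, y, above=True)
    # the chord knee locates the scale of the break; refine to the largest
    # multiplicative drop between consecutive barcodes near it, which is the
    # actual cliff between the cell plateau and the ambient tail
    w0 = max(0, approx // 2)
    w1 = min(len(counts) - 2, max(4 * (approx + 1), approx + 10))
    gaps = y[w0 : w1 + 1] - y[w0 + 1 : w1 + 2]
    knee = w0 + int(np.argmax(gaps))
    threshold = int(counts[knee])
    selected = [bc for bc, n in items if n >= threshold]
    return KneeResult(
        selected=selected, threshold_count=threshold, ranks=ranks, knee_rank=knee + 1
    )


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sparse cells x genes molecule counts with per-gene species labels."""

    barcodes: list[str]
    genes: list[str]
    species: list[str]
    X: sp.csr_matrix

    def __post_init__(self):
        if self.X.shape != (len(self.barcodes), len(self.genes)):
            raise ValueError("matrix shape does not match barcode/gene labels")
        if len(self.species) != len(self.genes):
            raise ValueError("one species label per gene required")
        if (self.X.data < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_molecules(self) -> np.ndarray:
        """Molecules per cell (row sums)."""
        return np.asarray(self.X.sum(axis=1)).ravel().astype(np.int64)

    @property
    def n_genes_detected(self) -> np.ndarray:
        """Genes with at least one molecule, per cell."""
        return np.asarray((self.X > 0).sum(axis=1)).ravel().astype(np.int64)

    @classmethod
    def from_dense(
        cls,
        counts: np.ndarray | pd.DataFrame,
        barcodes: list[str] | None = None,
        genes: list[str] | None = None,
        species: list[str] | None = None,
    ) -> "CountMatrix":
        if isinstance(counts, pd.DataFrame):
            genes = list(counts.columns) if genes is None else genes
            barcodes = (
                [str(i) for i in counts.index] if barcodes is None else barcodes
            )
            counts = counts.to_numpy()
        n_cells, n_genes = counts.shape
        barcodes = barcodes or [f"cell{i}" for i in range(n_cells)]
        genes = genes or [f"gene{j}" for j in range(n_genes)]
        species = species or ["human"] * n_genes
        return cls(list(barcodes), list(genes), list(species), sp.csr_matrix(counts))

    def write(self, outdir: str | os.PathLike) -> None:
        """Matrix Market (genes x cells) + barcodes.tsv + genes.tsv sidecars."""
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        scipy.io.mmwrite(
            os.path.join(outdir, "matrix.mtx"), self.X.T.tocoo(), field="integer"
        )
        with open(os.path.join(outdir, "barcodes.tsv"), "w") as fh:
            fh.write("".join(f"{bc}\n" for bc in self.barcodes))
        with open(os.path.join(outdir, "genes.tsv"), "w") as fh:
            fh.write("".join(f"{g}\t{s}\n" for g, s in zip(self.genes, self.species)))

    @classmethod
    def read(cls, outdir: str | os.PathLike) -> "CountMatrix":
        outdir = str(outdir)
        X = sp.csr_matrix(scipy.io.mmread(os.path.join(outdir, "matrix.mtx")).T)
        with open(os.path.join(outdir, "barcodes.tsv")) as fh:
            barcodes = [line.strip() for line in fh if line.strip()]
        genes, species = [], []
        with open(os.path.join(outdir, "genes.tsv")) as fh:
            for line in fh:
                if line.strip():
                    g, s = line.rstrip("\n").split("\t")
                    genes.append(g)
                    species.append(s)
        return cls(barcodes, genes, species, X.astype(np.int64))


def to_matrix(
    table: AddressTable,
    cells: Iterable[str],
    gene_species: Mapping[str, str],
) -> CountMatrix:
    """Count surviving addresses per (cell, gene) into a sparse matrix.

    ``cells`` fixes the row order; ``gene_species`` fixes the column universe
    (all annotated genes, sorted), so matrices from different runs over the
    same annotation are column-compatible.
    """
    cells = list(cells)
    genes = sorted(gene_species)
    cell_index = {bc: i for i, bc in enumerate(cells)}
    gene_index = {g: j for j, g in enumerate(genes)}
    rows, cols, data = [], [], []
    for (barcode, gene), group in table.groups.items():
        i = cell_index.get(barcode)
        if i is None:
            continue
        j = gene_index.get(gene)
        if j is None:
            raise KeyError(f"gene {gene!r} missing from annotation")
        rows.append(i)
        cols.append(j)
        data.append(len(group))
    X = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(cells), len(genes)), dtype=np.int64
    )
    return CountMatrix(cells, genes, [gene_species[g] for g in genes], X)
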