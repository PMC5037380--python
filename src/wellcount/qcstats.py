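"""Mixed-species QC, per-cell summaries, and subsampling saturation curves.

In a barnyard (human/mouse mixture) experiment, each barcode's *purity* is
the fraction of its species-assignable molecules belonging to its majority
species.  Barcodes below 90% purity are classified as multiplets: wells
that captured cells of both species.  Same-species multiplets are invisible
to this statistic, so the observed cross-species multiplet fraction
understates the true multiplet rate by the factor ``2 * p_h * p_m`` (the
probability that a two-cell well is cross-species); the corrected estimate
divides by that factor.

Saturation curves subsample uniquely-aligned reads at a series of depths,
rebuild and re-collapse the address table at each depth, and report
molecules and genes detected — the library-complexity view of a run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .molcount import AddressTable, CountMatrix, collapse_group

__all__ = [
    "SpeciesCall",
    "species_call",
    "species_calls",
    "PurityReport",
    "purity_histogram",
    "SaturationCurve",
    "subsample_saturation",
    "per_cell_summary",
]

MULTIPLET_PURITY_THRESHOLD = 0.90


@dataclass(frozen=True)
class SpeciesCall:
    barcode: str
    n_human: int
    n_mouse: int
    human_fraction: float
    purity: float
    call: str  # "human" | "mouse" | "multiplet"


def species_call(
    barcode: str,
    n_human: int,
    n_mouse: int,
    threshold: float = MULTIPLET_PURITY_THRESHOLD,
) -> SpeciesCall:
    """Classify one barcode from its species-split molecule counts.

    ``purity = max(f, 1 - f)`` with ``f`` the human fraction; a barcode is a
    multiplet iff purity is strictly below the threshold (a barcode at
    exactly 90% purity is *not* a multiplet).
    """
    total = n_human + n_mouse
    if total < 1:
        raise ValueError("species call requires at least one molecule")
    f = n_human / total
    purity = max(f, 1.0 - f)
    if purity < threshold:
        call = "multiplet"
    else:
        call = "human" if f >= 0.5 else "mouse"
    return SpeciesCall(barcode, n_human, n_mouse, f, purity, call)


def species_calls(
    matrix: CountMatrix, threshold: float = MULTIPLET_PURITY_THRESHOLD
) -> pd.DataFrame:
    """Species calls for every cell of a count matrix.

    Only molecules of genes with an unambiguous species label ("human" or
    "mouse") enter the purity denominator.
    """
    sp_arr = np.asarray(matrix.species)
    human_cols = sp_arr == "human"
    mouse_cols = sp_arr == "mouse"
    n_h = np.asarray(matrix.X[:, human_cols].sum(axis=1)).ravel().astype(int)
    n_m = np.asarray(matrix.X[:, mouse_cols].sum(axis=1)).ravel().astype(int)
    rows = []
    for bc, h, m in zip(matrix.barcodes, n_h, n_m):
        if h + m == 0:
            continue
        c = species_call(bc, int(h), int(m), threshold)
        rows.append(c.__dict__)
    return pd.DataFrame(
        rows, columns=["barcode", "n_human", "n_mouse", "human_fraction", "purity", "call"]
    )


@dataclass
class PurityReport:
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    median_purity: float
    multiplet_fraction: float          # observed cross-species fraction
    corrected_multiplet_rate: float    # divided by 2 * p_h * p_m
    n_barcodes: int
    n_multiplets: int
    detectable_factor: float


def purity_histogram(calls: pd.DataFrame, n_bins: int = 50) -> PurityReport:
    """Binned human-fraction distribution plus purity/multiplet summary.

    The bimodal histogram (peaks near 0 and 1) is the classic barnyard
    picture.  The corrected multiplet rate rescales the observed
    cross-species fraction by ``2 * p_h * p_m`` estimated from the singlet
    species proportions, which is the chance a random two-cell well mixes
    species.
    """
    if len(calls) == 0:
        raise ValueError("no species calls to summarise")
    counts, edges = np.histogram(
        calls["human_fraction"].to_numpy(), bins=n_bins, range=(0.0, 1.0)
    )
    n = len(calls)
    n_multi = int((calls["call"] == "multiplet").sum())
    singlets = calls[calls["call"] != "multiplet"]
    if len(singlets):
        p_h = float((singlets["call"] == "human").mean())
    else:
        p_h = 0.5
    factor = 2.0 * p_h * (1.0 - p_h)
    observed = n_multi / n
    corrected = observed / factor if factor > 0 else float("nan")
    return PurityReport(
        bin_edges=edges,
        bin_counts=counts,
        median_purity=float(calls["purity"].median()),
        multiplet_fraction=observed,
        corrected_multiplet_rate=corrected,
        n_barcodes=n,
        n_multiplets=n_multi,
        detectable_factor=factor,
    )


@dataclass
class SaturationCurve:
    """Molecules/genes detected vs uniquely-aligned reads sampled."""

    table: pd.DataFrame  # depth_fraction, reads, molecules, genes, mean_* per cell
    seed: int
    nested: bool

    @property
    def depths(self) -> np.ndarray:
        return self.table["reads"].to_numpy()

    @property
    def molecules_detected(self) -> np.ndarray:
        return self.table["molecules"].to_numpy()

    @property
    def genes_detected(self) -> np.ndarray:
        return self.table["genes"].to_numpy()


def _rebuild_and_count(
    keys: list[tuple[str, str]],
    umis: list[str],
    sampled: np.ndarray,
) -> tuple[int, int, dict[str, int], dict[str, int]]:
    """Rebuild groups from sampled per-address read counts, collapse, count."""
    groups: dict[tuple[str, str], dict[str, int]] = {}
    for key, umi, n in zip(keys, umis, sampled):
        if n > 0:
            groups.setdefault(key, {})[umi] = int(n)
    molecules = 0
    genes: set[str] = set()
    per_cell_mol: dict[str, int] = {}
    per_cell_genes: dict[str, int] = {}
    for (barcode, gene), group in groups.items():
        m = len(collapse_group(group))
        molecules += m
        genes.add(gene)
        per_cell_mol[barcode] = per_cell_mol.get(barcode, 0) + m
        per_cell_genes[barcode] = per_cell_genes.get(barcode, 0) + 1
    return molecules, len(genes), per_cell_mol, per_cell_genes


def subsample_saturation(
    table: AddressTable,
    cells: Iterable[str] | None = None,
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    seed: int = 0,
    nested: bool = False,
) -> SaturationCurve:
    """Subsample reads without replacement and re-count molecules and genes.

    Reads are expanded from address read counts (the pre-collapse table) and
    sampled without replacement at each depth fraction; addresses are
    rebuilt and UMI-collapse re-applied on the sample.  With
    ``nested=False`` (default) each depth is an independent draw from a
    common seed; ``nested=True`` chains hypergeometric subsamples so the
    read sets are nested across depths.
    """
    fractions = sorted(fractions)
    if not fractions or not all(0.0 < f <= 1.0 for f in fractions):
        raise ValueError("depth fractions must lie in (0, 1]")
    cell_set = set(cells) if cells is not None else None
    keys: list[tuple[str, str]] = []
    umis: list[str] = []
    read_counts: list[int] = []
    for key, group in sorted(table.groups.items()):
        if cell_set is not None and key[0] not in cell_set:
            continue
        for umi, n in sorted(group.items()):
            keys.append(key)
            umis.append(umi)
            read_counts.append(n)
    if not read_counts:
        raise ValueError("address table is empty (after cell restriction)")
    colors = np.array(read_counts, dtype=np.int64)
    total = int(colors.sum())
    rng = np.random.default_rng(seed)

    rows = []
    if nested:
        # draw from deepest to shallowest, subsampling the previous sample
        samples: dict[float, np.ndarray] = {}
        prev = colors
        prev_n = total
        for f in reversed(fractions):
            n_sample = int(round(f * total))
            if n_sample == prev_n:
                samples[f] = prev
            else:
                samples[f] = rng.multivariate_hypergeometric(
                    prev, n_sample, method="marginals"
                )
            prev = samples[f]
            prev_n = n_sample
        draws = [(f, samples[f]) for f in fractions]
    else:
        draws = []
        for f in fractions:
            n_sample = int(round(f * total))
            if n_sample == total:
                draws.append((f, colors))
            else:
                draws.append(
                    (f, rng.multivariate_hypergeometric(colors, n_sample, method="marginals"))
                )

    for f, sampled in draws:
        molecules, genes, per_cell_mol, per_cell_genes = _rebuild_and_count(
            keys, umis, sampled
        )
        n_cells_obs = max(len(per_cell_mol), 1)
        rows.append(
            {
                "depth_fraction": f,
                "reads": int(sampled.sum()),
                "molecules": molecules,
                "genes": genes,
                "mean_molecules_per_cell": sum(per_cell_mol.values()) / n_cells_obs,
                "mean_genes_per_cell": sum(per_cell_genes.values()) / n_cells_obs,
            }
        )
    return SaturationCurve(table=pd.DataFrame(rows), seed=seed, nested=nested)


def per_cell_summary(matrix: CountMatrix) -> pd.DataFrame:
    """Per-cell molecule and detected-gene totals."""
    return pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "n_molecules": matrix.n_molecules,
            "n_genes": matrix.n_genes_detected,
        }
    )
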