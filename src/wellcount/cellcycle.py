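"""Cell-cycle phase scores, pattern classification, and within-class ordering.

Five phase gene sets (G1/S, S, G2, G2/M, M/G1) yield a phase-specific score
per cell: the mean log-normalized expression of the set's genes, z-scored
across cells per phase.  Each cell is assigned to one of ten binary on/off
score patterns — eight patterns along the cycle:

    only G1/S; G1/S+S; only S; S+G2; only G2; G2+G2/M; only G2/M; G2/M+M/G1

plus all-on and all-off — by maximal Pearson correlation of its 5-score
vector with the pattern vectors (on=+1, off=-1).  The all-on/all-off
patterns have zero variance so correlation is undefined; they are assigned
by rule before the cycle patterns: all-off when every z-score is negative,
all-on when every z-score is positive.  Within each cycle class, cells are
ordered by their relative correlation with the succeeding minus the
preceding pattern, which tracks progression through the class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .molcount import CountMatrix

__all__ = [
    "PHASES",
    "PatternLibrary",
    "load_phase_gene_sets",
    "write_phase_gene_sets",
    "phase_scores",
    "classify_pattern",
    "order_within_class",
    "classify_cells",
]

PHASES = ("G1/S", "S", "G2", "G2/M", "M/G1")

_CYCLE_NAMES = (
    "G1/S only",
    "G1/S+S",
    "S only",
    "S+G2",
    "G2 only",
    "G2+G2/M",
    "G2/M only",
    "G2/M+M/G1",
)


@dataclass(frozen=True)
class PatternLibrary:
    """The ten reference score patterns, encoded on=+1 / off=-1.

    Indices 1-8 are the cycle patterns in circular order; 9 is all-on and
    10 is all-off.  (Encoding on/off as 1/0 gives the same Pearson argmax;
    +/-1 is chosen for symmetry.)
    """

    vectors: np.ndarray  # 10 x 5
    names: tuple[str, ...]

    @classmethod
    def default(cls) -> "PatternLibrary":
        cycle = np.array(
            [
                [1, 0, 0, 0, 0],
                [1, 1, 0, 0, 0],
                [0, 1, 0, 0, 0],
                [0, 1, 1, 0, 0],
                [0, 0, 1, 0, 0],
                [0, 0, 1, 1, 0],
                [0, 0, 0, 1, 0],
                [0, 0, 0, 1, 1],
            ],
            dtype=float,
        )
        vectors = np.vstack([cycle, np.ones((1, 5)), np.zeros((1, 5))])
        vectors = 2.0 * vectors - 1.0
        return cls(vectors=vectors, names=_CYCLE_NAMES + ("all-on", "all-off"))

    @property
    def n_cycle(self) -> int:
        return 8

    def neighbors(self, pattern_index: int) -> tuple[int, int]:
        """(preceding, succeeding) 1-based indices on the circular cycle."""
        if not 1 <= pattern_index <= self.n_cycle:
            raise ValueError("circular neighbors are defined for cycle patterns 1-8")
        i = pattern_index - 1
        return ((i - 1) % 8) + 1, ((i + 1) % 8) + 1


def load_phase_gene_sets(path: str) -> dict[str, list[str]]:
    """Load ``phase<TAB>gene`` TSV into phase -> gene list.

    All five phases must be present with non-empty gene lists.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["phase", "gene"], comment="#")
    sets = {p: list(sub["gene"]) for p, sub in df.groupby("phase", sort=False)}
    missing = [p for p in PHASES if not sets.get(p)]
    if missing:
        raise ValueError(f"phase gene sets missing or empty for: {missing}")
    unknown = set(sets) - set(PHASES)
    if unknown:
        raise ValueError(f"unknown phase labels: {sorted(unknown)}")
    return {p: sets[p] for p in PHASES}


def write_phase_gene_sets(sets: dict[str, list[str]], path: str) -> None:
    with open(path, "w") as fh:
        for phase in PHASES:
            for gene in sets[phase]:
                fh.write(f"{phase}\t{gene}\n")


def phase_scores(
    matrix: CountMatrix, sets: dict[str, list[str]], scale: float = 1e4
) -> pd.DataFrame:
    """Phase-specific score per cell: mean log expression, z-scored per phase.

    Expression is the per-cell molecule fraction times ``scale``, log(1+x)
    transformed.  For each phase, the score is the mean over the set's genes
    that are present in the matrix; a phase with no genes present raises.
    Scores are z-scored across cells (population sd; a zero-sd column is
    defined as all-zero), so each column has mean 0 and sd 1.
    """
    if len(matrix.barcodes) < 2:
        raise ValueError("phase scores require at least 2 cells")
    totals = matrix.n_molecules.astype(float)
    if (totals == 0).any():
        raise ValueError("empty cell: cannot normalize zero-molecule cells")
    gene_index = {g: j for j, g in enumerate(matrix.genes)}
    X = matrix.X.toarray().astype(float)
    log_expr = np.log1p(scale * X / totals[:, None])

    cols = {}
    for phase in PHASES:
        genes = sets.get(phase, [])
        idx = [gene_index[g] for g in genes if g in gene_index]
        if not idx:
            raise ValueError(
                f"phase {phase!r}: none of its genes are present in the matrix "
                f"(missing: {genes})"
            )
        raw = log_expr[:, idx].mean(axis=1)
        sd = raw.std()
        cols[phase] = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    return pd.DataFrame(cols, index=matrix.barcodes)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def classify_pattern(
    scores: np.ndarray, lib: PatternLibrary | None = None
) -> tuple[int, float]:
    """Assign a 5-score vector to one of the ten patterns.

    Returns the 1-based pattern index and the Pearson correlation with the
    assigned pattern (``nan`` for the rule-assigned all-on/all-off classes).
    Ties in correlation break to the lower pattern index.
    """
    lib = lib or PatternLibrary.default()
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (5,):
        raise ValueError("expected a 5-vector of phase scores")
    if np.all(scores > 0):
        return 9, float("nan")
    if np.all(scores < 0):
        return 10, float("nan")
    corrs = [_pearson(scores, lib.vectors[i]) for i in range(lib.n_cycle)]
    best = int(np.argmax(corrs))
    return best + 1, corrs[best]


def order_within_class(
    scores: np.ndarray, pattern_index: int, lib: PatternLibrary | None = None
) -> np.ndarray:
    """Ordering keys for the cells of one cycle class.

    key = corr(scores, succeeding pattern) - corr(scores, preceding
    pattern); sorting ascending places cells still resembling the previous
    pattern first and cells drifting toward the next pattern last.
    """
    lib = lib or PatternLibrary.default()
    prev_i, next_i = lib.neighbors(pattern_index)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    prev_v = lib.vectors[prev_i - 1]
    next_v = lib.vectors[next_i - 1]
    return np.array([_pearson(s, next_v) - _pearson(s, prev_v) for s in scores])


def classify_cells(
    score_df: pd.DataFrame, lib: PatternLibrary | None = None
) -> pd.DataFrame:
    """Classify and order every cell; rows come back heatmap-ordered.

    Output columns: pattern (1-10), pattern_name, correlation, order_key.
    Rows are sorted by (pattern, order_key); all-on/all-off classes keep
    their input order (order_key 0).
    """
    lib = lib or PatternLibrary.default()
    if list(score_df.columns) != list(PHASES):
        raise ValueError(f"score columns must be {PHASES}")
    S = score_df.to_numpy(dtype=float)
    patterns = np.empty(len(S), dtype=int)
    corrs = np.empty(len(S))
    for i, row in enumerate(S):
        patterns[i], corrs[i] = classify_pattern(row, lib)
    keys = np.zeros(len(S))
    for p in range(1, lib.n_cycle + 1):
        mask = patterns == p
        if mask.any():
            keys[mask] = order_within_class(S[mask], p, lib)
    out = pd.DataFrame(
        {
            "pattern": patterns,
            "pattern_name": [lib.names[p - 1] for p in patterns],
            "correlation": corrs,
            "order_key": keys,
        },
        index=score_df.index,
    )
    return out.sort_values(["pattern", "order_key"], kind="stable")
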