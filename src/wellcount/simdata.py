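"""Synthetic data with ground truth for a microwell single-cell RNA-seq platform.

The simulator emulates the data structure of a bead-barcoded, 3'-end
single-cell RNA-seq experiment on a two-species (human/mouse) cell mixture:

* a toy transcriptome of random gene sequences, each ending in a poly(A) tail;
* per-barcode molecule tables with multiplet wells and ambient-RNA-only
  ("empty bead") barcodes;
* paired-end reads where read 1 carries the 12-nt cell barcode and the 8-nt
  UMI and read 2 carries a fragment sampled from the 3' end of a transcript,
  with optional per-base substitution errors;
* a full ground-truth record (`SimTruth`) linking every read to its source
  molecule and every molecule to its barcode, used as the oracle for the
  whole downstream pipeline.

Expression-level generators for the downstream analyses (cell-cycle phase
patterns, highly-variable genes, discrete subpopulations) live here too, so
that every simulated condition in the package is produced by one module.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CountDist",
    "Gene",
    "ToyTranscriptome",
    "SimConfig",
    "SimTruth",
    "build_toy_transcriptome",
    "simulate_experiment",
    "synthesize_reads",
    "simulate_umi_error_reads",
    "simulate_phase_cells",
    "simulate_populations",
    "simulate_hvg_matrix",
]

_BASES = "ACGT"
POLYA_TAIL_LENGTH = 25  # every toy transcript ends in this many A's (>= 20)


# ---------------------------------------------------------------------------
# count distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountDist:
    """Integer distribution spec for molecules/cell and reads/molecule.

    ``kind`` is one of:

    * ``"fixed"``     -- every draw equals ``mean`` (rounded);
    * ``"poisson"``   -- Poisson with the given mean;
    * ``"poisson1"``  -- 1 + Poisson(mean - 1), i.e. a shifted Poisson that is
      always >= 1 (used for reads per molecule so that no molecule is
      silently unobservable);
    * ``"nb"``        -- negative binomial parameterised by mean and
      ``dispersion`` (variance = mean + dispersion * mean**2).
    """

    mean: float
    kind: str = "poisson"
    dispersion: float = 0.0

    def __post_init__(self):
        if self.mean < 0:
            raise ValueError("mean must be non-negative")
        if self.kind not in ("fixed", "poisson", "poisson1", "nb"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "nb" and self.dispersion <= 0:
            raise ValueError("nb distribution requires dispersion > 0")
        if self.kind == "poisson1" and self.mean < 1:
            raise ValueError("poisson1 requires mean >= 1")

    @classmethod
    def fixed(cls, value: int) -> "CountDist":
        return cls(mean=float(value), kind="fixed")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(size, int(round(self.mean)), dtype=np.int64)
        if self.kind == "poisson":
            return rng.poisson(self.mean, size=size)
        if self.kind == "poisson1":
            return 1 + rng.poisson(self.mean - 1.0, size=size)
        # negative binomial: n = 1/dispersion, p = n / (n + mean)
        n = 1.0 / self.dispersion
        p = n / (n + self.mean)
        return rng.negative_binomial(n, p, size=size)


# ---------------------------------------------------------------------------
# toy transcriptome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    gene_id: str
    species: str          # "human" | "mouse"
    sequence: str         # core + poly(A) tail
    core_length: int      # length of the non-tail portion

    @property
    def transcript_id(self) -> str:
        return f"{self.gene_id}.t1"


@dataclass
class ToyTranscriptome:
    """A stand-in for a concatenated two-species reference transcriptome.

    One transcript per gene, named ``<gene_id>.t1``; every sequence ends in a
    poly(A) tail so that 3'-end fragments can run into the tail exactly as
    they do in real libraries.
    """

    genes: list[Gene]

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene_ids must be unique")
        for g in self.genes:
            if not g.sequence.endswith("A" * 20):
                raise ValueError(f"{g.gene_id}: sequence must end in >=20 A")

    def sequences(self) -> dict[str, str]:
        """transcript_id -> sequence (including tail)."""
        return {g.transcript_id: g.sequence for g in self.genes}

    def gene_species(self) -> dict[str, str]:
        return {g.gene_id: g.species for g in self.genes}

    def annotation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "species": [g.species for g in self.genes],
                "length": [len(g.sequence) for g in self.genes],
            }
        )

    def write(self, fasta_path: str | os.PathLike, annotation_path: str | os.PathLike) -> None:
        records = [
            SeqRecord(Seq(g.sequence), id=g.transcript_id, description=f"gene={g.gene_id} species={g.species}")
            for g in self.genes
        ]
        with open(fasta_path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
        self.annotation_frame().to_csv(annotation_path, sep="\t", index=False)

    @classmethod
    def read(cls, fasta_path: str | os.PathLike, annotation_path: str | os.PathLike) -> "ToyTranscriptome":
        ann = pd.read_csv(annotation_path, sep="\t")
        species = dict(zip(ann["gene_id"], ann["species"]))
        genes = []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            gid = rec.id.rsplit(".t", 1)[0]
            seq = str(rec.seq)
            core = len(seq.rstrip("A"))
            genes.append(Gene(gid, species[gid], seq, core))
        return cls(genes)


def _random_core(rng: np.random.Generator, length: int) -> str:
    """Random sequence with no A-run longer than 3.

    Keeping homopolymer A runs out of the gene body makes poly(A)-tail
    detection unambiguous: the only clippable run on a fragment is the tail.
    """
    out = []
    run = 0
    draws = rng.integers(0, 4, size=2 * length + 8)
    j = 0
    while len(out) < length:
        b = _BASES[draws[j] % 4] if run < 3 else _BASES[1 + draws[j] % 3]
        j += 1
        if j >= len(draws):
            draws = rng.integers(0, 4, size=2 * length)
            j = 0
        run = run + 1 if b == "A" else 0
        out.append(b)
    return "".join(out)


def build_toy_transcriptome(
    n_genes_per_species: int,
    length_range: tuple[int, int] = (200, 400),
    seed: int = 0,
) -> ToyTranscriptome:
    """Build a toy two-species transcriptome of random 3'-tailed transcripts.

    ``length_range`` bounds the core (non-tail) transcript length, inclusive.
    Deterministic given ``seed``.
    """
    if n_genes_per_species < 1:
        raise ValueError("n_genes_per_species must be >= 1")
    lo, hi = length_range
    if lo < 60:
        raise ValueError(
            "length_range lower bound must be >= 60 nt so that 3'-end "
            "fragments survive the 25-nt post-clip length filter"
        )
    if hi < lo:
        raise ValueError("length_range upper bound below lower bound")
    rng = np.random.default_rng(seed)
    tail = "A" * POLYA_TAIL_LENGTH
    genes = []
    for species, prefix in (("human", "HG"), ("mouse", "MM")):
        lengths = rng.integers(lo, hi + 1, size=n_genes_per_species)
        for i, core_len in enumerate(lengths):
            core = _random_core(rng, int(core_len))
            genes.append(
                Gene(
                    gene_id=f"{prefix}{i + 1:05d}",
                    species=species,
                    sequence=core + tail,
                    core_length=int(core_len),
                )
            )
    return ToyTranscriptome(genes)


# ---------------------------------------------------------------------------
# experiment configuration and truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated mixed-species experiment.

    Defaults emulate a modest microwell run: a 50/50 human/mouse mixture,
    a low multiplet rate, many empty-bead barcodes that capture only a few
    ambient molecules, ~500 captured molecules per cell and ~3 reads per
    molecule, sequenced 26 cycles on read 1 and 66 on read 2.
    """

    n_cells_human: int = 100
    n_cells_mouse: int = 100
    multiplet_rate: float = 0.01
    ambient_molecule_rate: float = 2.0
    n_empty_barcodes: int = 1000
    molecules_per_cell: CountDist = field(default_factory=lambda: CountDist(mean=500.0, kind="poisson"))
    reads_per_molecule: CountDist = field(default_factory=lambda: CountDist(mean=3.0, kind="poisson1"))
    per_base_error_rate: float = 0.0
    barcode_length: int = 12
    umi_length: int = 8
    read1_length: int = 26
    read2_length: int = 66
    seed: int = 0

    def __post_init__(self):
        for name in ("multiplet_rate", "per_base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ambient_molecule_rate < 0:
            raise ValueError("ambient_molecule_rate must be >= 0")
        if self.read1_length < self.barcode_length + self.umi_length:
            raise ValueError("read1_length must cover barcode + UMI")
        if min(self.n_cells_human, self.n_cells_mouse, self.n_empty_barcodes) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class SimTruth:
    """Ground truth: per-barcode identity, per-molecule origin, per-read errors.

    ``barcodes``:  barcode, kind (cell|multiplet|empty), composition
    ``molecules``: barcode, gene_id, umi, species (one row per molecule)
    ``reads``:     read_id, molecule (row index into ``molecules``),
                   r1_errors, r2_errors (comma-joined 0-based positions) --
                   filled by :func:`synthesize_reads`.
    """

    barcodes: pd.DataFrame
    molecules: pd.DataFrame
    reads: pd.DataFrame | None = None

    def molecule_counts(self) -> pd.DataFrame:
        """Distinct (barcode, gene_id, umi) triples per (barcode, gene).

        Two simulated molecules that collide on all three coordinates are
        indistinguishable in principle, so the countable truth is the number
        of distinct address triples.
        """
        distinct = self.molecules.drop_duplicates(["barcode", "gene_id", "umi"])
        out = distinct.groupby(["barcode", "gene_id"], sort=True).size()
        return out.rename("molecules").reset_index()

    def address_table(self):
        """The true (barcode, gene, UMI) address table with read counts.

        Two molecules colliding on all three coordinates contribute their
        reads to one address, exactly as sequencing would observe them.
        Requires :func:`synthesize_reads` to have filled ``reads``.
        """
        from .molcount import AddressTable

        if self.reads is None:
            raise ValueError("reads not synthesized yet")
        table = AddressTable()
        reads_per_mol = self.reads.groupby("molecule").size()
        barcodes = self.molecules["barcode"].to_numpy()
        genes = self.molecules["gene_id"].to_numpy()
        umis = self.molecules["umi"].to_numpy()
        for m, n in reads_per_mol.items():
            table.add(barcodes[int(m)], genes[int(m)], umis[int(m)], int(n))
        return table

    def molecules_per_barcode(self) -> pd.Series:
        distinct = self.molecules.drop_duplicates(["barcode", "gene_id", "umi"])
        return distinct.groupby("barcode").size()

    def cell_barcodes(self) -> list[str]:
        mask = self.barcodes["kind"].isin(["cell", "multiplet"])
        return list(self.barcodes.loc[mask, "barcode"])

    def write(self, outdir: str | os.PathLike, prefix: str = "truth") -> None:
        outdir = str(outdir)
        self.barcodes.to_csv(os.path.join(outdir, f"{prefix}_barcodes.tsv"), sep="\t", index=False)
        self.molecules.to_csv(os.path.join(outdir, f"{prefix}_molecules.tsv"), sep="\t", index=False)
        if self.reads is not None:
            self.reads.to_csv(os.path.join(outdir, f"{prefix}_reads.tsv"), sep="\t", index=False)


def _random_kmers(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """n distinct random DNA k-mers, drawn without replacement."""
    seen: dict[str, None] = {}
    while len(seen) < n:
        block = rng.integers(0, 4, size=(max(n - len(seen), 16), length))
        for row in block:
            kmer = "".join(_BASES[b] for b in row)
            if kmer not in seen:
                seen[kmer] = None
                if len(seen) == n:
                    break
    return list(seen)


def _draw_molecules(
    rng: np.random.Generator,
    n_molecules: int,
    gene_ids: np.ndarray,
    weights: np.ndarray,
    umi_length: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample gene assignments (multinomial) and random UMIs for one barcode."""
    if n_molecules == 0:
        return np.array([], dtype=object), np.array([], dtype=object)
    counts = rng.multinomial(n_molecules, weights)
    genes = np.repeat(gene_ids, counts)
    umi_mat = rng.integers(0, 4, size=(n_molecules, umi_length))
    umis = np.array(["".join(_BASES[b] for b in row) for row in umi_mat], dtype=object)
    return genes, umis


def simulate_experiment(tx: ToyTranscriptome, cfg: SimConfig) -> SimTruth:
    """Simulate the molecule content of every barcode in a mixed-species run.

    Each cell barcode hosts one cell; with probability ``multiplet_rate`` the
    well received a second cell whose species is drawn from the mixture
    proportions, so a multiplet is cross-species with probability
    ``2 * p_human * p_mouse``.  Empty-bead barcodes capture
    Poisson(``ambient_molecule_rate``) molecules from the pooled cellular
    expression profile.  UMIs are uniform random ``umi_length``-mers per
    molecule.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_cells = cfg.n_cells_human + cfg.n_cells_mouse
    n_barcodes = n_cells + cfg.n_empty_barcodes
    if n_barcodes > 4 ** cfg.barcode_length / 100:
        raise ValueError(
            "barcode space too small for the requested number of barcodes "
            "(collision-prone); increase barcode_length"
        )
    barcodes = _random_kmers(rng, n_barcodes, cfg.barcode_length)

    species_genes = {
        sp: np.array([g.gene_id for g in tx.genes if g.species == sp], dtype=object)
        for sp in ("human", "mouse")
    }
    for sp, ids in species_genes.items():
        if len(ids) == 0:
            raise ValueError(f"transcriptome has no {sp} genes")
    # per-species expression profile: lognormal gene weights, fixed per run
    species_weights = {}
    for sp, ids in species_genes.items():
        w = rng.lognormal(mean=0.0, sigma=1.0, size=len(ids))
        species_weights[sp] = w / w.sum()

    p_human = cfg.n_cells_human / n_cells if n_cells else 0.0
    pooled_genes = np.concatenate([species_genes["human"], species_genes["mouse"]])
    pooled_weights = np.concatenate(
        [p_human * species_weights["human"], (1.0 - p_human) * species_weights["mouse"]]
    )
    if pooled_weights.sum() > 0:
        pooled_weights = pooled_weights / pooled_weights.sum()

    cell_species = ["human"] * cfg.n_cells_human + ["mouse"] * cfg.n_cells_mouse

    bc_rows = []
    mol_barcode: list[str] = []
    mol_gene: list[np.ndarray] = []
    mol_umi: list[np.ndarray] = []
    mol_species: list[np.ndarray] = []

    def add_molecules(barcode: str, species: str, n: int):
        genes, umis = _draw_molecules(
            rng, n, species_genes[species], species_weights[species], cfg.umi_length
        )
        mol_barcode.extend([barcode] * n)
        mol_gene.append(genes)
        mol_umi.append(umis)
        mol_species.append(np.full(n, species, dtype=object))

    for i, sp in enumerate(cell_species):
        barcode = barcodes[i]
        is_multiplet = rng.random() < cfg.multiplet_rate
        members = [sp]
        if is_multiplet:
            second = "human" if rng.random() < p_human else "mouse"
            members.append(second)
        n_mols = cfg.molecules_per_cell.sample(rng, len(members))
        for member_sp, n in zip(members, n_mols):
            add_molecules(barcode, member_sp, int(n))
        bc_rows.append(
            {
                "barcode": barcode,
                "kind": "multiplet" if is_multiplet else "cell",
                "composition": "+".join(sorted(members)),
            }
        )

    for j in range(cfg.n_empty_barcodes):
        barcode = barcodes[n_cells + j]
        n = int(rng.poisson(cfg.ambient_molecule_rate))
        if n > 0:
            genes = np.repeat(pooled_genes, rng.multinomial(n, pooled_weights))
            umi_mat = rng.integers(0, 4, size=(n, cfg.umi_length))
            umis = np.array(["".join(_BASES[b] for b in row) for row in umi_mat], dtype=object)
            gene_sp = {g.gene_id: g.species for g in tx.genes}
            mol_barcode.extend([barcode] * n)
            mol_gene.append(genes)
            mol_umi.append(umis)
            mol_species.append(np.array([gene_sp[g] for g in genes], dtype=object))
        bc_rows.append({"barcode": barcode, "kind": "empty", "composition": "ambient"})

    molecules = pd.DataFrame(
        {
            "barcode": np.array(mol_barcode, dtype=object),
            "gene_id": np.concatenate(mol_gene) if mol_gene else np.array([], dtype=object),
            "umi": np.concatenate(mol_umi) if mol_umi else np.array([], dtype=object),
            "species": np.concatenate(mol_species) if mol_species else np.array([], dtype=object),
        }
    )
    return SimTruth(barcodes=pd.DataFrame(bc_rows), molecules=molecules)


# ---------------------------------------------------------------------------
# read synthesis
# ---------------------------------------------------------------------------

# fragments start uniformly within the final FRAGMENT_WINDOW nt of the gene
# body (3'-end chemistry), keeping enough non-tail overlap that an
# error-free fragment always survives the 25-nt post-clip filter
FRAGMENT_WINDOW = 150


def _min_core_overlap(read2_length: int, min_len: int = 25) -> int:
    """Smallest non-tail overlap that the poly(A) clipper provably respects.

    The clipper tolerates one non-A per 10 bases of run.  Toy cores carry no
    A-run longer than 3, so any d core bases contain at least floor(d/4)
    non-A.  For a clip to leave fewer than ``min_len`` core bases it would
    have to eat d >= overlap - (min_len - 1) core bases while satisfying
    floor(d/4) <= (read2_length - (min_len - 1)) // 10; choosing the overlap
    below makes that impossible.
    """
    allowed = (read2_length - (min_len - 1)) // 10
    return (min_len - 1) + 4 * (allowed + 1)


@dataclass(frozen=True)
class ReadFiles:
    r1: str
    r2: str
    sam: str


def _inject_errors(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, list[int]]:
    if rate <= 0.0:
        return seq, []
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq, []
    positions = sorted(rng.choice(len(seq), size=n_err, replace=False).tolist())
    chars = list(seq)
    for p in positions:
        alternatives = [b for b in _BASES if b != chars[p]]
        chars[p] = alternatives[rng.integers(0, 3)]
    return "".join(chars), positions


def synthesize_reads(
    truth: SimTruth,
    tx: ToyTranscriptome,
    cfg: SimConfig,
    outdir: str | os.PathLike,
    prefix: str = "sim",
) -> ReadFiles:
    """Emit paired FASTQ plus a ground-truth SAM for every simulated molecule.

    Read 1 is ``barcode + UMI`` padded to ``read1_length`` with A; read 2 is a
    ``read2_length`` window starting in the final 150 nt of the gene body,
    padded with A if it runs past the transcript (sequencing into the tail).
    Substitution errors are injected per base at ``per_base_error_rate`` and
    logged in ``truth.reads``.  The truth SAM holds one sense-strand record
    per read at the true transcript position.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = ReadFiles(
        r1=os.path.join(outdir, f"{prefix}_R1.fastq"),
        r2=os.path.join(outdir, f"{prefix}_R2.fastq"),
        sam=os.path.join(outdir, f"{prefix}_truth.sam"),
    )
    gene_info = {g.gene_id: g for g in tx.genes}
    seqs = tx.sequences()

    mols = truth.molecules
    n_mols = len(mols)
    n_reads_per_mol = cfg.reads_per_molecule.sample(rng, n_mols)
    pad1 = "A" * (cfg.read1_length - cfg.barcode_length - cfg.umi_length)
    min_core = _min_core_overlap(cfg.read2_length)
    too_short = [g.gene_id for g in tx.genes if g.core_length < min_core]
    if too_short:
        raise ValueError(
            f"transcript cores shorter than the minimum fragment overlap "
            f"({min_core} nt) for {cfg.read2_length}-cycle reads: {too_short[:5]}"
        )

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": g.transcript_id, "LN": len(g.sequence)} for g in tx.genes],
    }
    tid_index = {g.transcript_id: i for i, g in enumerate(tx.genes)}

    read_rows = []
    read_no = 0
    with open(paths.r1, "w") as f1, open(paths.r2, "w") as f2, pysam.AlignmentFile(
        paths.sam, "w", header=header
    ) as sam:
        barcodes = mols["barcode"].to_numpy()
        genes = mols["gene_id"].to_numpy()
        umis = mols["umi"].to_numpy()
        for m in range(n_mols):
            gene = gene_info[genes[m]]
            seq = seqs[gene.transcript_id]
            core_len = gene.core_length
            lo = max(0, core_len - FRAGMENT_WINDOW)
            hi = core_len - min_core
            for _ in range(int(n_reads_per_mol[m])):
                start = int(rng.integers(lo, hi + 1))
                frag = seq[start : start + cfg.read2_length]
                pad2 = cfg.read2_length - len(frag)
                r2_perfect = frag + "A" * pad2
                r1_perfect = barcodes[m] + umis[m] + pad1
                r1, err1 = _inject_errors(rng, r1_perfect, cfg.per_base_error_rate)
                r2, err2 = _inject_errors(rng, r2_perfect, cfg.per_base_error_rate)
                read_id = f"r{read_no:08d}"
                read_no += 1
                q1 = "I" * len(r1)
                q2 = "I" * len(r2)
                f1.write(f"@{read_id}\n{r1}\n+\n{q1}\n")
                f2.write(f"@{read_id}\n{r2}\n+\n{q2}\n")

                aln_len = len(frag)
                a = pysam.AlignedSegment(sam.header)
                a.query_name = read_id
                a.query_sequence = r2
                a.flag = 0
                a.reference_id = tid_index[gene.transcript_id]
                a.reference_start = start
                a.mapping_quality = 60
                a.cigar = [(0, aln_len)] + ([(4, pad2)] if pad2 else [])
                ref = seq[start : start + aln_len]
                score = sum(x == y for x, y in zip(ref, r2[:aln_len]))
                a.set_tag("AS", score)
                a.set_tag("NM", aln_len - score)
                sam.write(a)
                read_rows.append(
                    {
                        "read_id": read_id,
                        "molecule": m,
                        "r1_errors": ",".join(map(str, err1)),
                        "r2_errors": ",".join(map(str, err2)),
                    }
                )
    truth.reads = pd.DataFrame(read_rows, columns=["read_id", "molecule", "r1_errors", "r2_errors"])
    return paths


# ---------------------------------------------------------------------------
# focused generators for downstream analyses
# ---------------------------------------------------------------------------

def simulate_umi_error_reads(
    n_pairs: int = 300,
    mean_molecules: float = 10.0,
    reads_per_molecule: int = 6,
    umi_length: int = 8,
    error_rate: float = 0.01,
    seed: int = 0,
):
    """Reads whose UMIs carry per-base substitution errors, with truth counts.

    A controlled study of the UMI-collapse step in isolation: every
    (cell, gene) pair receives Poisson(``mean_molecules``) true molecules
    with random UMIs, each sequenced ``reads_per_molecule`` times, and each
    read's observed UMI picks up substitution errors at ``error_rate`` per
    base.  Barcode and gene are error-free so observed addresses group
    exactly like the truth.

    Returns ``(truth, observed)`` where ``truth`` maps
    (barcode, gene) -> number of distinct true UMIs and ``observed`` maps
    (barcode, gene) -> {observed_umi: read_count}.
    """
    rng = np.random.default_rng(seed)
    truth: dict[tuple[str, str], int] = {}
    observed: dict[tuple[str, str], dict[str, int]] = {}
    for i in range(n_pairs):
        key = (f"BC{i:06d}", "GENE")
        n_mol = int(rng.poisson(mean_molecules))
        umi_mat = rng.integers(0, 4, size=(n_mol, umi_length))
        umis = ["".join(_BASES[b] for b in row) for row in umi_mat]
        truth[key] = len(set(umis))
        group: dict[str, int] = {}
        for umi in umis:
            for _ in range(reads_per_molecule):
                obs, _err = _inject_errors(rng, umi, error_rate)
                group[obs] = group.get(obs, 0) + 1
        observed[key] = group
    return truth, observed


def _counts_from_rates(rng: np.random.Generator, rates: np.ndarray, depth: int) -> np.ndarray:
    """Per-cell multinomial counts from a (cells x genes) rate matrix."""
    probs = rates / rates.sum(axis=1, keepdims=True)
    return np.vstack([rng.multinomial(depth, p) for p in probs])


# the eight cell-cycle patterns (on=1) in circular order, matching
# wellcount.cellcycle.PatternLibrary
_CYCLE_ACTIVITY = np.array(
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


def simulate_phase_cells(
    n_cells: int = 500,
    genes_per_phase: int = 25,
    n_background: int = 875,
    depth: int = 10000,
    fold: float = 4.0,
    fold_sigma: float = 0.3,
    max_offset: float = 0.4,
    seed: int = 0,
):
    """Cells planted on an 8-pattern cell-cycle with known pseudotime.

    Each cell draws one of the eight cycle patterns plus a pseudotime offset
    u ~ Uniform(-``max_offset``, ``max_offset``); its phase activity vector
    interpolates linearly toward the preceding (u < 0) or succeeding (u > 0)
    pattern on the circle, so every cell has a well-defined planted pattern
    while within-class cells span a continuum of transitional states.
    Genes in an active phase set are elevated by a lognormal fold (median
    ``fold``).  Returns ``(counts, gene_sets, truth)`` where ``counts`` is a
    cells x genes integer DataFrame, ``gene_sets`` maps phase name -> gene
    list, and ``truth`` holds the planted pattern index (1-8) and the
    pseudotime offset.
    """
    from .cellcycle import PHASES

    rng = np.random.default_rng(seed)
    if not 0.0 <= max_offset < 0.5:
        raise ValueError("max_offset must lie in [0, 0.5) to keep patterns defined")
    n_phase_genes = 5 * genes_per_phase
    gene_names = [f"CC{p}_{j}" for p in range(5) for j in range(genes_per_phase)] + [
        f"BG_{j}" for j in range(n_background)
    ]
    gene_sets = {
        PHASES[p]: [f"CC{p}_{j}" for j in range(genes_per_phase)] for p in range(5)
    }
    base = rng.lognormal(0.0, 0.5, size=n_phase_genes + n_background)
    fold_g = rng.lognormal(np.log(fold), fold_sigma, size=n_phase_genes)

    planted = rng.integers(0, 8, size=n_cells)
    offset = rng.uniform(-max_offset, max_offset, size=n_cells)
    t = planted + offset
    j = np.floor(t).astype(int)
    f = t - j
    activity = (1 - f)[:, None] * _CYCLE_ACTIVITY[j % 8] + f[:, None] * _CYCLE_ACTIVITY[(j + 1) % 8]
    nearest = planted
    offset = np.asarray(offset)

    phase_of_gene = np.repeat(np.arange(5), genes_per_phase)
    rates = np.tile(base, (n_cells, 1))
    rates[:, :n_phase_genes] *= fold_g ** activity[:, phase_of_gene]
    counts = _counts_from_rates(rng, rates, depth)
    counts_df = pd.DataFrame(counts, columns=gene_names)
    truth = pd.DataFrame({"pattern": nearest + 1, "pseudotime": offset})
    return counts_df, gene_sets, truth


def simulate_populations(
    n_cells: tuple[int, int] = (200, 200),
    n_genes: int = 2000,
    module_size: int = 50,
    fold: float = 8.0,
    depth: int = 4000,
    seed: int = 0,
):
    """Two cell populations with disjoint elevated gene modules.

    Background gene rates span a wide lognormal dynamic range (as real
    transcriptomes do), so the module genes scatter across the mean-
    expression bins of the dispersion analysis instead of crowding one bin.
    Returns ``(counts_df, labels)``; ``labels`` is 0/1 per cell.
    """
    rng = np.random.default_rng(seed)
    total = sum(n_cells)
    gene_names = [f"G{j:05d}" for j in range(n_genes)]
    base = rng.lognormal(0.0, 1.5, size=n_genes)
    labels = np.repeat([0, 1], n_cells)
    rates = np.tile(base, (total, 1))
    rates[labels == 0, :module_size] *= fold
    rates[labels == 1, module_size : 2 * module_size] *= fold
    counts = _counts_from_rates(rng, rates, depth)
    return pd.DataFrame(counts, columns=gene_names), labels


def simulate_hvg_matrix(
    n_cells: int = 400,
    n_background: int = 2000,
    n_planted: int = 20,
    fold: float = 10.0,
    on_fraction: float = 0.3,
    depth: int = 6000,
    seed: int = 0,
):
    """Poisson-like background plus bimodal high-variance genes.

    Background genes have a fixed per-gene rate shared by all cells (a wide
    lognormal dynamic range), so their variation is sampling (technical)
    noise only.  Each planted gene is "on" (rate multiplied by ``fold``) in
    a random ``on_fraction`` of cells, which inflates its dispersion well
    above genes of the same mean.  Planted base rates are centred slightly
    below the background so that, after fold elevation, their means land in
    the well-populated middle of the mean-expression range where the binned
    dispersion baseline is stable — where real marker genes live.

    Returns ``(counts_df, planted_gene_names)``.
    """
    if on_fraction < 0.2:
        raise ValueError("planted genes should be on in >= 20% of cells")
    rng = np.random.default_rng(seed)
    gene_names = [f"HV_{j}" for j in range(n_planted)] + [f"BG_{j}" for j in range(n_background)]
    base = np.concatenate(
        [
            rng.lognormal(-0.5, 0.6, size=n_planted),
            rng.lognormal(0.0, 1.5, size=n_background),
        ]
    )
    rates = np.tile(base, (n_cells, 1))
    on = rng.random(size=(n_cells, n_planted)) < on_fraction
    rates[:, :n_planted] *= np.where(on, fold, 1.0)
    counts = _counts_from_rates(rng, rates, depth)
    return pd.DataFrame(counts, columns=gene_names), gene_names[:n_planted]
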