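# wellcount

Processing and QC for bead-barcoded, 3′-end single-cell RNA-seq — the data
produced by microwell (and droplet) platforms in which every mRNA capture
bead carries a cell barcode and each captured molecule a unique molecular
identifier (UMI). The package takes paired FASTQ (read 1 = 12-nt cell
barcode + 8-nt UMI; read 2 = cDNA fragment) to a UMI-collapsed cell × gene
molecule matrix, and implements the standard analyses used to validate and
exploit such data:

* **Read processing** — barcode/UMI extraction, mismatch-tolerant poly(A)
  clipping, 25-nt minimum fragment length.
* **Alignment filtering** — reads are retained when they map to the sense
  strand of transcripts of exactly one gene with alignment score
  ≥ 0.85 × fragment length, either from an external aligner's SAM (e.g.
  bwa-mem against a concatenated human–mouse transcriptome) or from a
  built-in exact-seed aligner for self-contained runs.
* **Molecule counting** — every retained read gets an *address*
  (gene, UMI, cell barcode); reads with identical addresses collapse to one,
  and an address merges into a higher-coverage address at UMI edit distance
  one within the same cell/gene. Distinct surviving addresses are molecules.
* **Cell calling** — a knee point on the log–log barcode rank/molecule-count
  curve separates cell-containing barcodes from ambient-RNA beads, with an
  `--expected-cells` override for runs where imaging gives the cell count.
* **Mixed-species (barnyard) QC** — per-barcode purity
  `max(f, 1−f)` of the human molecule fraction *f*; barcodes below 90%
  purity are multiplets, and a corrected multiplet rate accounts for
  same-species doublets being invisible.
* **Saturation** — reads subsampled without replacement at a ladder of
  depths, addresses rebuilt and re-collapsed, molecules/genes per depth.
* **Cell cycle** — five phase scores per cell (mean log-normalized
  expression of phase gene sets, z-scored), classification into ten on/off
  score patterns by maximal Pearson correlation, and ordering within each
  pattern by relative correlation with the neighbouring patterns.
* **Heterogeneity** — normalization to per-cell molecule fractions,
  highly-variable-gene selection by binned dispersion z-score (> 3, with
  ≥ 5 cells and ≥ 10% detection), a cell–cell Pearson correlation matrix fed
  to t-SNE, DBSCAN cluster assignment, per-cell marker-set scores
  `S = (n_subtype,i / N_subtype) / n_genes,i`, and hypergeometric tests for
  enrichment of above-median scores in a cluster.

A bundled simulator (`wellcount.simdata`) generates a toy two-species
transcriptome and barcoded reads with complete ground truth — multiplets,
ambient RNA, sequencing errors — so the entire pipeline is testable end to
end: with no injected errors the pipeline reproduces the simulated molecule
table exactly.

## Worked example

```python
import tempfile
from wellcount import simdata, pipeline, qcstats
from wellcount.simdata import SimConfig, CountDist

tx = simdata.build_toy_transcriptome(50, (200, 400), seed=1)
cfg = SimConfig(
    n_cells_human=40, n_cells_mouse=40, n_empty_barcodes=800,
    multiplet_rate=0.05, ambient_molecule_rate=2.0,
    molecules_per_cell=CountDist(mean=400.0),
    reads_per_molecule=CountDist(mean=3.0, kind="poisson1"),
    per_base_error_rate=0.005, seed=1,
)
truth = simdata.simulate_experiment(tx, cfg)
with tempfile.TemporaryDirectory() as d:
    paths = simdata.synthesize_reads(truth, tx, cfg, d)
    result = pipeline.run_pipeline(paths.r1, paths.r2, tx=tx)

calls = qcstats.species_calls(result.matrix)
report = qcstats.purity_histogram(calls)
```

prints, via the obvious summaries:

```
reads processed:    109747
reads kept:         109738 (100.0%)
cells called:       80 (knee at rank 80)
molecules counted:  35453
median purity:      1.0000
multiplet fraction: 0.0375 (corrected rate 0.0750)
mean molecules/cell: 443, mean genes/cell: 47.2
```

The knee recovered all 80 planted cells from among 880 barcodes. Three of
the seven simulated doublet wells mixed species; they are the 3/80 = 3.75%
of barcodes called multiplets (purity < 0.90), and dividing by the chance
that a doublet mixes species (2·p·(1−p) = 0.5 here) estimates the total
doublet rate at 7.5% — the same-species doublets are invisible to the purity
statistic. Median purity 1.0 reflects that ambient RNA attaches to empty
beads, not to cell-containing wells, in this simulation.

The same steps are available from a shell:

```bash
wellcount simulate --outdir run --seed 1
wellcount count --r1 run/sim_R1.fastq --r2 run/sim_R2.fastq \
    --fasta run/transcriptome.fasta --annotation run/genes.tsv --out run/matrix
wellcount qc-mix --matrix run/matrix --out run/calls.tsv
wellcount cluster --matrix run/matrix --out run/embedding.tsv
```

## Layout

```
src/wellcount/
  simdata.py    synthetic transcriptome, experiment and read simulators
  readproc.py   barcode/UMI extraction, poly(A) clipping, length filter
  alignkit.py   SAM ingestion, naive aligner, retention filters
  molcount.py   address table, UMI collapse, cell calling, count matrix
  qcstats.py    species purity/multiplets, saturation, per-cell summaries
  cellcycle.py  phase scores, ten-pattern classification, cycle ordering
  hetero.py     normalization, HVG selection, clustering, scores, enrichment
  pipeline.py   FASTQ -> matrix orchestration
  cli.py        `wellcount` command-line interface
docs/methods.md the model, parameter and design notes
```
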