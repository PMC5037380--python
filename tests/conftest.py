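import pytest

from wellcount import pipeline, simdata


@pytest.fixture(scope="session")
def toy_tx():
    return simdata.build_toy_transcriptome(20, (200, 300), seed=11)


@pytest.fixture(scope="session")
def small_run(toy_tx, tmp_path_factory):
    """An error-free small experiment run end to end, with its ground truth."""
    outdir = tmp_path_factory.mktemp("smallrun")
    cfg = simdata.SimConfig(
        n_cells_human=10,
        n_cells_mouse=10,
        n_empty_barcodes=50,
        molecules_per_cell=simdata.CountDist(mean=100.0),
        reads_per_molecule=simdata.CountDist.fixed(3),
        multiplet_rate=0.0,
        ambient_molecule_rate=1.0,
        per_base_error_rate=0.0,
        seed=3,
    )
    truth = simdata.simulate_experiment(toy_tx, cfg)
    paths = simdata.synthesize_reads(truth, toy_tx, cfg, outdir)
    result = pipeline.run_pipeline(paths.r1, paths.r2, tx=toy_tx, expected_cells=20)
    return {
        "tx": toy_tx,
        "cfg": cfg,
        "truth": truth,
        "paths": paths,
        "result": result,
    }
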