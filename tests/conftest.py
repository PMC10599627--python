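import pytest

from gbmcsf import qc, scoring, simulate


@pytest.fixture(scope="session")
def small_cfg():
    """Two-patient planted-effect dataset config used across modules."""
    return simulate.ScSimConfig(
        n_patients=2, n_cells_per_condition=150, outlier_fraction=0.0, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    adata, truth = simulate.simulate_sc_dataset(small_cfg)
    qc.annotate_qc_metrics(adata)
    scoring.log_normalize(adata)
    return adata, truth


@pytest.fixture(scope="session")
def null_dataset():
    """Zero planted effects: conditions are exchangeable."""
    cfg = simulate.ScSimConfig(
        n_patients=1,
        n_cells_per_condition=300,
        csf_effects={},
        planted_de=[],
        outlier_fraction=0.0,
        seed=5,
    )
    adata, _ = simulate.simulate_sc_dataset(cfg)
    scoring.log_normalize(adata)
    return adata


@pytest.fixture(scope="session")
def program_sets(small_cfg):
    return simulate.program_gene_sets(small_cfg)
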