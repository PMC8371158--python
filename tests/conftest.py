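import numpy as np
import pandas as pd
import pytest

from hruv.design import DesignConfig, generate_design
from hruv.preprocess import AssayBatch
from hruv.synthetic import SimConfig, simulate_experiment, standard_config


@pytest.fixture(scope="session")
def study_sheet():
    """Run sheet for the full 15-batch study geometry."""
    return generate_design(DesignConfig(n_batches=15, seed=0))


@pytest.fixture(scope="session")
def small_sheet():
    """A compact 2-batch, 4x5 design used by cheap unit tests."""
    return generate_design(
        DesignConfig(n_batches=2, rows_per_batch=4, row_size=5,
                     n_batch_replicates=2, n_conditioning_qc=2, seed=3)
    )


def tiny_sim_config(seed=0, n_batches=2, **overrides):
    """A fast small simulation: 2 batches of a 4x5 grid, 20 metabolites."""
    design = DesignConfig(n_batches=n_batches, rows_per_batch=4, row_size=5,
                          n_batch_replicates=2, n_conditioning_qc=2, seed=seed)
    kw = dict(n_metabolites=20, n_affected=2, seed=seed)
    kw.update(overrides)
    return SimConfig(design=design, **kw)


@pytest.fixture()
def tiny_batches():
    batches, truth = simulate_experiment(tiny_sim_config())
    return batches, truth


@pytest.fixture(scope="session")
def standard_run():
    """The 6-batch reference scenario (seed 0), shared across tests."""
    cfg = standard_config(seed=0, n_batches=6)
    batches, truth = simulate_experiment(cfg)
    return cfg, batches, truth


def concat_batches(batches) -> AssayBatch:
    return AssayBatch(
        values=pd.concat([b.values for b in batches], axis=1),
        annotation=pd.concat([b.annotation for b in batches], axis=0),
        scale=batches[0].scale,
        missing_mask=pd.concat([b.missing_mask for b in batches], axis=1),
    )


def toy_batch(values: np.ndarray, sample_types, groups=None, batch=1,
              metabolites=None, scale="log2") -> AssayBatch:
    """Assemble an AssayBatch from a plain array and per-measurement types."""
    values = np.asarray(values, dtype=float)
    n_met, n_meas = values.shape
    mets = metabolites or [f"M{i + 1}" for i in range(n_met)]
    meas = [f"b{batch}.m{j + 1}" for j in range(n_meas)]
    if groups is None:
        groups = [
            "QC" if t in ("pooledQC", "conditioningQC") else f"S{j}"
            for j, t in enumerate(sample_types)
        ]
    ann = pd.DataFrame(
        {
            "batch": batch,
            "run_index": np.arange(1, n_meas + 1),
            "row": 1,
            "column": np.arange(1, n_meas + 1),
            "sample_id": groups,
            "sample_type": list(sample_types),
            "replicate_group": groups,
        },
        index=pd.Index(meas, name="measurement"),
    )
    return AssayBatch(
        values=pd.DataFrame(values, index=mets, columns=meas),
        annotation=ann,
        scale=scale,
    )
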