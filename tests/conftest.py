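import numpy as np
import pandas as pd
import pytest

from grnpipe.io import ExpressionMatrix, SampleDesign
from grnpipe import synth


def design_grid(conditions=("control", "treatment"), timepoints=(6.0, 12.0, 24.0), replicates=3):
    return [
        SampleDesign(sample_id=f"{c}_{int(t)}h_r{r}", condition=c, timepoint=t, replicate=r)
        for c in conditions
        for t in timepoints
        for r in range(1, replicates + 1)
    ]


def matrix_from(values: np.ndarray, genes, design, scale="normalized") -> ExpressionMatrix:
    frame = pd.DataFrame(values, index=list(genes), columns=[d.sample_id for d in design])
    return ExpressionMatrix(values=frame, design=list(design), scale=scale)


@pytest.fixture
def toy_design():
    return design_grid(timepoints=(6.0,), replicates=2)


@pytest.fixture
def study_screen():
    """A small screen with the study design: 2 conditions x 3 timepoints x 3 reps."""
    grn = synth.make_grn(30, tf_fraction=0.5, density=0.05, seed=11)
    cfg = synth.SimulationConfig(seed=11)
    m, truth = synth.simulate_expression(grn, cfg)
    return grn, cfg, m, truth


@pytest.fixture
def synthetic_files(tmp_path):
    """On-disk synthetic dataset (counts/design/annotation/tf list/truth)."""
    grn = synth.make_grn(25, tf_fraction=0.4, density=0.06, seed=7)
    cfg = synth.SimulationConfig(seed=7)
    paths = synth.write_dataset(grn, cfg, tmp_path / "data")
    return grn, cfg, paths
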