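import numpy as np
import pandas as pd
import pytest

from mirchron.core_model import CtMatrix, ExpressionMatrix, TimeCourseDesign


@pytest.fixture
def design():
    return TimeCourseDesign.default(replicates=2)


@pytest.fixture
def samples(design):
    return sorted(design.replicate_map, key=lambda s: (
        design.rna_timepoints.index(design.timepoint_of(s)), s))


def make_matrix(values, design, layer="mRNA", orientation="expression", features=None):
    """Build an ExpressionMatrix from a (features × 14) array."""
    arr = np.asarray(values, dtype=float)
    samples = [f"{tp}_{i}" for tp in design.rna_timepoints for i in (1, 2)]
    idx = features or [f"f{i}" for i in range(arr.shape[0])]
    return ExpressionMatrix(
        layer=layer,
        values=pd.DataFrame(arr, index=idx, columns=samples),
        design=design,
        orientation=orientation,
    )


@pytest.fixture
def small_ct(design):
    """3 miRNAs + U6 over 14 samples, with a missing and an over-ceiling value."""
    samples = [f"{tp}_{i}" for tp in design.rna_timepoints for i in (1, 2)]
    rng = np.random.default_rng(11)
    vals = pd.DataFrame(
        rng.uniform(15, 30, size=(3, 14)),
        index=["miR-a", "miR-b", "miR-c"],
        columns=samples,
    )
    vals.iloc[0, 0] = np.nan  # undetected
    vals.iloc[1, 1] = 37.2  # above ceiling
    vals.loc["U6"] = 18.0
    return CtMatrix(values=vals, reference_assay="U6")
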