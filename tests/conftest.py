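import numpy as np
import pandas as pd
import pytest

from devindex import GroupDesign, OmicsMatrix, PipelineConfig, default_study_config


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def toy_design():
    """Two reference groups of 3 plus one treated group of 2."""
    group_of = {
        "b1": "base", "b2": "base", "b3": "base",
        "d1": "dis", "d2": "dis", "d3": "dis",
        "t1": "drugA", "t2": "drugA",
    }
    return GroupDesign(group_of=group_of, baseline_group="base", disease_group="dis")


@pytest.fixture
def toy_expression(rng, toy_design):
    """8 samples x 6 features; features 0-2 shifted in the disease group."""
    samples = list(toy_design.group_of)
    x = rng.normal(0.0, 1.0, (len(samples), 6))
    shift = np.array([3.0, 2.0, 1.5, 0.0, 0.0, 0.0])
    for i, s in enumerate(samples):
        if toy_design.group_of[s] == "dis":
            x[i] += shift
    df = pd.DataFrame(x, index=samples, columns=[f"g{j}" for j in range(6)])
    return OmicsMatrix(df, "expression")


def random_two_group(rng, n1=None, n2=None, p=1):
    n1 = n1 or int(rng.integers(2, 12))
    n2 = n2 or int(rng.integers(2, 12))
    return rng.normal(size=(n1, p)), rng.normal(size=(n2, p))


def scaled_study_config(seed):
    """Down-sized synthetic study for replicate-heavy tests: same group
    structure and couplings, fewer features and metabolites."""
    return default_study_config(seed=seed).replace(
        n_features=300,
        n_disease_features=60,
        n_metabolites=12,
        metabolite_missing=(),
    )


def scaled_pipeline_config(**kw):
    return PipelineConfig(n_top_features=60, **kw)
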