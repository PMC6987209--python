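import numpy as np
import pandas as pd
import pytest

from fibromark import EffectConfig, OmicsMatrix, SampleAnnotation, StudyDesign, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A small but structured study: 2 arms x 8 animals, 2 weeks, 2 batches."""
    design = StudyDesign(animals_per_group=8, weeks=(4, 12), batches=2, seed=42)
    effects = EffectConfig(
        n_features_rna=300,
        n_features_liver_protein=250,
        n_features_plasma=80,
        fraction_secreted_biomarker=0.02,
    )
    return generate_study(design, effects)


@pytest.fixture
def two_group_ann():
    """Annotation builder: n_a controls + n_b diseased, one week, one batch."""

    def make(n_a=8, n_b=8, fibrosis=None):
        ids = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
        tbl = pd.DataFrame(
            {
                "group": ["ctl"] * n_a + ["dis"] * n_b,
                "week": 12,
                "batch": 1,
                "fibrosis_score": fibrosis if fibrosis is not None else [0] * n_a + [3] * n_b,
            },
            index=pd.Index(ids, name="sample_id"),
        )
        return SampleAnnotation(tbl)

    return make


@pytest.fixture
def make_matrix():
    def make(values, samples=None, features=None, scale="log2", kind="test"):
        values = np.asarray(values, dtype=float)
        nf, ns = values.shape
        features = features or [f"F{i}" for i in range(nf)]
        samples = samples or [f"A{i}" for i in range(ns)]
        return OmicsMatrix(
            pd.DataFrame(values, index=features, columns=samples), scale=scale, kind=kind
        )

    return make
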