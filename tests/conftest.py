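import numpy as np
import pandas as pd
import pytest

from epipanel.simulate import CohortSimConfig, simulate_cohort


SMALL_SIM = CohortSimConfig(
    n_tumors_per_subtype=30, n_normals=12, n_genes=400,
    n_signature_genes=60, n_silenced_genes=6, seed=42,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared across read-only tests."""
    return simulate_cohort(SMALL_SIM)


@pytest.fixture(scope="session")
def default_cohort():
    """The default-condition cohort (300 tumors, 40 normals, 2,000 genes)."""
    return simulate_cohort(CohortSimConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def tiny_bundle():
    """A hand-sized, fully deterministic cohort for invariant tests."""
    genes = ["gA", "gB"]
    samples = ["S1", "S2", "S3", "N1"]
    expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]],
                        index=genes, columns=samples)
    meth = pd.DataFrame([[0.1, 0.2, 0.8, 0.1], [0.3, 0.4, 0.5, 0.2]],
                        index=["p1", "p2"], columns=samples)
    pm = pd.DataFrame({"probe_id": ["p1", "p2"], "gene_id": ["gA", "gB"],
                       "tss_distance": [-200, -50]})
    cnv = pd.DataFrame([[0.0, -1.0, 1.0, 0.0], [2.0, 0.0, -2.0, 0.0]],
                       index=genes, columns=samples)
    ann = pd.DataFrame(
        {"tissue": ["tumor", "tumor", "tumor", "normal"],
         "matched_pair_id": [None, None, None, "S1"],
         "subtype_label": ["1", "1", "unknown", "unknown"]},
        index=pd.Index(samples, name="sample_id"))
    from epipanel.cohort import CohortBundle
    return CohortBundle(expression=expr, methylation=meth, promoter_map=pm,
                        cnv=cnv, annotations=ann)
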