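import numpy as np
import pytest

import ibcsig as ib


@pytest.fixture(scope="session")
def default_cohort():
    """Default simulated discovery cohort (2000 genes, 20/20/5) + truth."""
    cfg = ib.SimulationConfig(seed=1)
    cohort, truth = ib.simulate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap 150-gene cohort for forest/pipeline unit tests."""
    cfg = ib.SimulationConfig(
        seed=7, n_genes=150, n_signal=10,
        n_per_class={"IBC": 12, "nonIBC": 12, "normal": 3},
    )
    cohort, truth = ib.simulate_cohort(cfg)
    return cfg, cohort, truth


def toy_cohort(values, labels, er=None, her2=None, gene_prefix="g"):
    """Hand-built cohort from a genes x samples array and label list."""
    values = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{i + 1}" for i in range(values.shape[0])]
    samples = [f"s{j + 1}" for j in range(values.shape[1])]
    ann = {}
    for j, sid in enumerate(samples):
        ann[sid] = ib.SampleAnnotation(
            sample_id=sid,
            class_label=labels[j],
            er_score=None if er is None else er[j],
            her2_score=None if her2 is None else her2[j],
        )
    return ib.ExpressionCohort(genes, samples, values, ann)
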