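import numpy as np
import pandas as pd
import pytest

from methylancestry.containers import IntensitySet, ProbeAnnotation, SampleMetadata
from methylancestry.simulate import SimConfig, scenario, simulate_cohort


@pytest.fixture(scope="session")
def clean_cohort():
    """Small randomized-design cohort with strong population structure."""
    return simulate_cohort(scenario("clean", seed=11))


@pytest.fixture(scope="session")
def confounded_cohort():
    """Cohort whose raw top variance axis is a batch effect."""
    return simulate_cohort(scenario("batch_confounded", seed=1))


@pytest.fixture()
def toy_annotation():
    table = pd.DataFrame(
        {
            "probe_type": ["II", "I_green", "II", "I_red", "II", "II"],
            "snp_distance": [0, 0, 5, 0, 0, 0],
            "maf": [0.10, 0.30, 0.20, 0.01, 0.05, 0.04],
            "source_flags": [frozenset({"a"})] * 6,
        },
        index=pd.Index([f"cg{i}" for i in range(6)], name="probe_id"),
    )
    return ProbeAnnotation(table=table, array="EPICv2")


def make_intensity_set(n_probes=4, n_samples=4, seed=0):
    rng = np.random.default_rng(seed)
    probes = [f"cg{i}" for i in range(n_probes)]
    samples = [f"s{i}" for i in range(n_samples)]
    shape = (n_probes, n_samples)
    return IntensitySet(
        meth=pd.DataFrame(rng.uniform(1000, 9000, shape), index=probes, columns=samples),
        unmeth=pd.DataFrame(rng.uniform(1000, 9000, shape), index=probes, columns=samples),
        detp=pd.DataFrame(np.full(shape, 1e-30), index=probes, columns=samples),
        beadcount=pd.DataFrame(np.full(shape, 12.0), index=probes, columns=samples),
        control=pd.DataFrame(
            rng.uniform(500, 5000, (3, n_samples)), index=["c0", "c1", "c2"], columns=samples
        ),
        rs_beta=pd.DataFrame(
            rng.uniform(0, 1, (2, n_samples)), index=["rs0", "rs1"], columns=samples
        ),
    )


@pytest.fixture()
def toy_iset():
    return make_intensity_set()
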