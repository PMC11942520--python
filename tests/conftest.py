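import numpy as np
import pytest

from adrnet.cohort import GenotypeMatrix
from adrnet.panel import filter_panel
from adrnet.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study bundle, generated once per session."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def bundle_dir(default_cohort, tmp_path_factory):
    """The default bundle written to disk (panel TSV, VCFs, clinical CSV, GMT)."""
    from adrnet.simulate import write_bundle

    out = tmp_path_factory.mktemp("bundle")
    write_bundle(default_cohort, out)
    return out


@pytest.fixture(scope="session")
def filtered_panel(default_cohort):
    filtered, _ = filter_panel(default_cohort.panel)
    return filtered


@pytest.fixture(scope="session")
def default_clustering(default_cohort):
    from adrnet.clustering import build_patient_graph, detect_communities

    graph = build_patient_graph(default_cohort.genotypes)
    return detect_communities(graph, seed=11)


def make_matrix(profiles, variant_ids=None, patient_ids=None):
    """Carrier matrix from a list of carrier index sets (one per patient)."""
    if variant_ids is None:
        n_var = max((max(p) for p in profiles if p), default=0) + 1
        variant_ids = [f"v{j}" for j in range(n_var)]
    if patient_ids is None:
        patient_ids = [f"P{i + 1:03d}" for i in range(len(profiles))]
    carrier = np.zeros((len(profiles), len(variant_ids)), dtype=np.int8)
    for i, p in enumerate(profiles):
        for j in p:
            carrier[i, j] = 1
    return GenotypeMatrix(
        patient_ids=patient_ids,
        variant_ids=variant_ids,
        carrier=carrier,
        missing_mask=np.zeros_like(carrier),
    )
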