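import numpy as np
import pytest

import morphnet as mn


@pytest.fixture(scope="session")
def full_scale_subject():
    """One subject at the full 210-ROI parcellation with toy vertex counts,
    shared by the structural-fidelity and construction-contract tests."""
    design = mn.CohortDesign(
        groups=(("HA", 2), ("MA", 2), ("HC", 2)),
        n_roi=210,
        vertices_per_roi=(30, 60),
        seed=42,
    )
    return mn.generate_cohort(design)[0]


@pytest.fixture(scope="session")
def full_scale_ensembles(full_scale_subject):
    """Default-config ensembles for all four feature networks of the
    full-scale subject."""
    cfg = mn.PipelineConfig()
    return {
        feature: mn.subject_ensemble(full_scale_subject, feature, cfg)
        for feature in mn.FEATURES
    }


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small three-group cohort with one planted regional effect, used by
    pipeline-level tests."""
    design = mn.CohortDesign(
        groups=(("HA", 8), ("MA", 8), ("HC", 8)),
        n_roi=10,
        vertices_per_roi=(25, 50),
        features=("CT", "SD"),
        effects=(mn.PlantedEffect(roi_id=3, feature="CT", groups=("HA",),
                                  magnitude=-2.5),),
        seed=11,
    )
    return mn.generate_cohort(design)


def random_connected_adjacency(rng, n, p=0.3):
    """Erdos-Renyi adjacency conditioned on connectivity (rejection)."""
    import scipy.sparse as sp
    import scipy.sparse.csgraph as csg

    while True:
        A = rng.random((n, n)) < p
        A = np.triu(A, 1)
        A = A | A.T
        if csg.connected_components(sp.csr_matrix(A))[0] == 1:
            return A
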