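import numpy as np
import pytest

from lsplace import BackboneTree, place_with_support
from lsplace.evaluation import label_placements
from lsplace.synthetic import SimulationScenario, simulate_scenario


@pytest.fixture(scope="session")
def quartet():
    return BackboneTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def e2e_study():
    """The end-to-end discrimination scenario: 300-leaf JC69 simulation,
    200 leaves pruned as queries leaving a 100-leaf backbone, L=2000,
    fast-bootstrap support with B=100; full-length and 200 bp fragmentary
    versions of the same queries."""
    scen = SimulationScenario(n_leaves=300, L=2000, n_queries=200, branch_scale=0.05, seed=1)
    study = simulate_scenario(scen)
    sps = place_with_support(
        study.queries, study.backbone_alignment, study.backbone_tree,
        method="fast_bs", B=100, seed=11,
    )
    labeled = label_placements(sps, study.truth)

    scen_f = SimulationScenario(
        n_leaves=300, L=2000, n_queries=200, branch_scale=0.05, seed=1, fragment_length=200
    )
    study_f = simulate_scenario(scen_f)
    sps_f = place_with_support(
        study_f.queries, study_f.backbone_alignment, study_f.backbone_tree,
        method="fast_bs", B=100, seed=11,
    )
    labeled_f = label_placements(sps_f, study_f.truth)
    return {
        "study": study,
        "supported": sps,
        "labeled": labeled,
        "supported_frag": sps_f,
        "labeled_frag": labeled_f,
    }
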