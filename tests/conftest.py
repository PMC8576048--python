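import numpy as np
import pytest

from hemiconn.atlas import Atlas, AtlasNode, make_synthetic_atlas, partition_edges
from hemiconn.connectome import build_feature_matrix, compute_fc
from hemiconn.simulate import SyntheticConfig, generate_cohort


def _node(node_id, hemi, partner, gyrus=1, lobe=1, cortical=True):
    return AtlasNode(
        node_id=node_id, name=f"n{node_id}", abbrev=f"n{node_id}",
        hemisphere=hemi, partner_id=partner, gyrus_id=gyrus, lobe_id=lobe,
        is_cortical=cortical,
    )


@pytest.fixture(scope="session")
def toy2_atlas():
    """Smallest valid atlas: one homotopic pair."""
    return Atlas((_node(1, "L", 2), _node(2, "R", 1)))


@pytest.fixture(scope="session")
def toy4_atlas():
    """Nodes 1L, 2L, 3R, 4R with partners 1-3 and 2-4."""
    return Atlas((
        _node(1, "L", 3, gyrus=1), _node(2, "L", 4, gyrus=2),
        _node(3, "R", 1, gyrus=1), _node(4, "R", 2, gyrus=2),
    ))


@pytest.fixture(scope="session")
def bundled_atlas():
    from hemiconn.atlas import load_bundled_atlas

    return load_bundled_atlas()


def disjoint_edges(partition, network, k):
    """First k node-disjoint edges of a network, for planting."""
    out, used = [], set()
    for e in partition.edges(network):
        if e[0] not in used and e[1] not in used:
            out.append(e)
            used.update(e)
        if len(out) == k:
            return out
    raise RuntimeError("not enough disjoint edges")


@pytest.fixture(scope="session")
def tiny_planted_study():
    """A 12-subject cohort on an 8-node atlas with 2 planted RH edges,
    plus its RH feature matrix — shared across prediction-level tests."""
    atlas = make_synthetic_atlas(4)
    partition = partition_edges(atlas)
    planted = disjoint_edges(partition, "RH", 2)
    config = SyntheticConfig(
        n_subjects=12, planted_edges=tuple((e, 0.625) for e in planted), seed=7
    )
    cohort = generate_cohort(config, atlas)
    fcs = [compute_fc(p) for p in cohort.panels]
    features = build_feature_matrix(fcs, partition, "RH")
    return {
        "atlas": atlas, "partition": partition, "planted": planted,
        "config": config, "cohort": cohort, "features": features,
    }
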