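import numpy as np
import pytest
from hypothesis import settings

from axonstat import synthetic
from axonstat.types import Skeleton, SkeletonNode, VoxelScale

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def scale():
    return VoxelScale(20.0, 20.0, 40.0)


@pytest.fixture
def unit_scale():
    return VoxelScale(1.0, 1.0, 1.0)


def make_chain(positions_nm, scale=VoxelScale(1.0, 1.0, 1.0), radii=None):
    """A path skeleton through the given nm positions (scale 1 => voxels=nm)."""
    radii = radii or [50.0] * len(positions_nm)
    sarr = scale.as_array()
    nodes = [
        SkeletonNode(i + 1, *(np.asarray(p, dtype=float) / sarr), radius=r)
        for i, (p, r) in enumerate(zip(positions_nm, radii))
    ]
    edges = [(i, i + 1) for i in range(1, len(nodes))]
    return Skeleton(nodes, edges, scale)


def random_tree(rng, n_nodes, scale=VoxelScale(1.0, 1.0, 1.0), span_nm=5000.0):
    """Random labelled tree with random positions and radii."""
    nodes = [
        SkeletonNode(
            i + 1,
            *(rng.uniform(0, span_nm, 3) / scale.as_array()),
            radius=float(rng.uniform(20, 200)),
        )
        for i in range(n_nodes)
    ]
    edges = [(int(rng.integers(1, i + 1)), i + 1) for i in range(1, n_nodes)]
    return Skeleton(nodes, edges, scale)


@pytest.fixture
def chain_factory():
    return make_chain


@pytest.fixture
def tree_factory():
    return random_tree


MINIMAL_NML = """
<things>
  <thing id="7">
    <nodes>
      <node id="1" x="0" y="0" z="0" radius="50"/>
      <node id="2" x="5" y="0" z="0" radius="50"/>
    </nodes>
    <edges><edge source="1" target="2"/></edges>
    <comments/>
  </thing>
</things>
"""


@pytest.fixture
def minimal_nml():
    return MINIMAL_NML


@pytest.fixture(scope="session")
def small_study():
    """A small two-group synthetic study shared across tests."""
    saline = synthetic.generate_group(
        6, "saline", synthetic.study_defaults("saline"), seed=11
    )
    cocaine = synthetic.generate_group(
        6, "cocaine", synthetic.study_defaults("cocaine"), seed=12, start_thing_id=7
    )
    return saline + cocaine
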