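import numpy as np
import pytest

from adsyn.morphometry import DendriteAnnotation
from adsyn.skeleton_io import DatasetMeta, SkeletonNode, SkeletonTree
from adsyn.synapse_quant import SynapseRecord
from adsyn.synthetic import GeneratorConfig, generate_dendrite_annotations


def make_chain(positions, name="chain", comments=None):
    """Straight skeleton chain (µm coordinates) from a list of positions."""
    tree = SkeletonTree(name=name)
    comments = comments or {}
    prev = None
    for i, pos in enumerate(positions, start=1):
        tree.nodes[i] = SkeletonNode(id=i, position=tuple(map(float, pos)),
                                     comment=comments.get(i))
        if prev is not None:
            tree.edges.add(frozenset((prev, i)))
        prev = i
    return tree


def chain_annotation(n_nodes=11, spacing=1.0, celltype="L2", **kwargs):
    """DendriteAnnotation of a straight vertical chain rooted at node 1."""
    positions = [(0.0, i * spacing, 0.0) for i in range(n_nodes)]
    tree = make_chain(positions)
    return DendriteAnnotation(tree=tree, celltype=celltype, soma_node=1, **kwargs)


def add_synapses(ad, spec):
    """spec: list of (node, onto) tuples; ids assigned sequentially."""
    for i, (node, onto) in enumerate(spec, start=1):
        ad.synapses.append(SynapseRecord(id=i, node=node, onto=onto))
    return ad


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def small_population(default_config):
    """A modest generated population shared by read-only tests."""
    ads, truth = generate_dendrite_annotations(
        default_config, {"L2": 10, "DL": 10, "L5tt": 4}, seed=123
    )
    return ads, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
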