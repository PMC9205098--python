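import numpy as np
import pytest

from hetppi.hetnet import HeteroNetwork, NodeRef, TypedEdge
from hetppi.line_embed import LineConfig
from hetppi.pipeline import cross_validate
from hetppi.synthetic import SyntheticConfig, default_acceptance_config, generate


def protein(i: int) -> NodeRef:
    return NodeRef(f"p{i}", "protein")


def ppi(i: int, j: int) -> TypedEdge:
    return TypedEdge(protein(i), protein(j), "protein-protein")


@pytest.fixture
def toy_network() -> HeteroNetwork:
    """p1-p2 (PP), p1-dr1 (drug-protein), p1-mi1 (miRNA-protein)."""
    p1, p2 = protein(1), protein(2)
    dr1 = NodeRef("dr1", "drug")
    mi1 = NodeRef("mi1", "miRNA")
    return HeteroNetwork(
        edges=[
            TypedEdge(p1, p2, "protein-protein"),
            TypedEdge(p1, dr1, "drug-protein"),
            TypedEdge(p1, mi1, "miRNA-protein"),
        ]
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """The fixed study conditions: 300 proteins, 6 communities, 400 other
    molecules, motif-tagged sequences."""
    return generate(default_acceptance_config())


@pytest.fixture(scope="session")
def small_dataset():
    """A lighter planted dataset for fast end-to-end runs."""
    cfg = SyntheticConfig(
        n_proteins=80, n_lncRNA=25, n_miRNA=25, n_disease=25, n_drug=25,
        n_communities=4, seed=42,
    )
    return generate(cfg)


SMALL_LINE = LineConfig(dim_per_order=16, total_samples=30_000)


@pytest.fixture(scope="session")
def cv_both(planted_dataset):
    net, records, _ = planted_dataset
    return cross_validate(net, records, features="both", seed=1)


@pytest.fixture(scope="session")
def cv_intra(planted_dataset):
    net, records, _ = planted_dataset
    return cross_validate(net, records, features="intra", seed=1)


@pytest.fixture(scope="session")
def cv_inter(planted_dataset):
    net, records, _ = planted_dataset
    return cross_validate(net, records, features="inter", seed=1)
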