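import numpy as np
import pytest

from exatlas.ontology import (
    AnatomyDAG,
    Condition,
    ConditionGraph,
    OntologyTerm,
    StageTree,
)

PANCREAS = "UBERON:0001264"
ENDOCRINE = "UBERON:0000016"
EXOCRINE = "UBERON:0001263"
FULLY_FORMED = "UBERON:0000066"
IMMATURE = "UBERON:0000112"


@pytest.fixture
def pancreas_dag() -> AnatomyDAG:
    """Toy anatomy: endocrine/exocrine pancreas part_of pancreas."""
    return AnatomyDAG(
        {
            PANCREAS: OntologyTerm(PANCREAS, "pancreas"),
            ENDOCRINE: OntologyTerm(ENDOCRINE, "endocrine pancreas", part_of_parents=(PANCREAS,)),
            EXOCRINE: OntologyTerm(EXOCRINE, "exocrine pancreas", part_of_parents=(PANCREAS,)),
        }
    )


@pytest.fixture
def pancreas_stages() -> StageTree:
    """Toy stages: sexually immature part_of fully formed."""
    return StageTree(
        {
            FULLY_FORMED: OntologyTerm(FULLY_FORMED, "fully formed stage"),
            IMMATURE: OntologyTerm(IMMATURE, "sexually immature stage", part_of_parents=(FULLY_FORMED,)),
        }
    )


@pytest.fixture
def pancreas_graph(pancreas_dag, pancreas_stages) -> ConditionGraph:
    return ConditionGraph(pancreas_dag, pancreas_stages)


def random_dag(rng: np.random.Generator, n_terms: int, extra_edge_p: float = 0.15) -> AnatomyDAG:
    """Random single-rooted DAG; all edges point to smaller indices, so
    acyclicity holds by construction."""
    ids = [f"T:{i:04d}" for i in range(n_terms)]
    terms = {ids[0]: OntologyTerm(ids[0], "root")}
    for i in range(1, n_terms):
        parent = ids[int(rng.integers(0, i))]
        part_of = ()
        if i >= 2 and rng.random() < extra_edge_p:
            j = int(rng.integers(0, i))
            if ids[j] != parent:
                part_of = (ids[j],)
        terms[ids[i]] = OntologyTerm(ids[i], f"term {i}", is_a_parents=(parent,), part_of_parents=part_of)
    return AnatomyDAG(terms)


def random_stage_tree(rng: np.random.Generator, n_terms: int, granular_p: float = 0.3) -> StageTree:
    ids = [f"S:{i:04d}" for i in range(n_terms)]
    terms = {ids[0]: OntologyTerm(ids[0], "stage root")}
    for i in range(1, n_terms):
        parent = ids[int(rng.integers(0, i))]
        granular = rng.random() < granular_p
        terms[ids[i]] = OntologyTerm(
            ids[i],
            f"stage {i}",
            part_of_parents=(parent,),
            subsets=frozenset({"granular_stage"}) if granular else frozenset(),
        )
    return StageTree(terms)
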