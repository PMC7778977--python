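"""Anatomy and developmental-stage ontologies and the condition partial order.

Expression is asserted at *conditions*: (anatomical entity, developmental
stage, sex, strain, species).  The anatomy is a DAG over ``is_a``/``part_of``
relations; stages form a tree (at most one ``part_of`` parent) ordered along
each sibling group by ``preceded_by``, and encoded as a nested set for fast
ancestry tests.  Sexes and strains each hang under a single root ("any",
"wild-type").  The partial order over conditions is the component-wise
product of these four orders and is computed lazily, never materialized.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

KNOWN_RELATIONSHIPS = {"part_of", "preceded_by", "immediately_preceded_by"}

GRANULAR_SUBSET = "granular_stage"

SEX_ROOT = "any"
SEXES = {"male", "female", "hermaphrodite"}
MISSING_VALUES = {"NA", "not_annotated", "confidential_restricted_data"}
STRAIN_ROOT = "wild-type"


class OntologyError(ValueError):
    """Malformed ontology input (parse failure, cycle, broken stage tree)."""


@dataclass(frozen=True)
class OntologyTerm:
    id: str
    name: str
    is_a_parents: tuple[str, ...] = ()
    part_of_parents: tuple[str, ...] = ()
    preceded_by: tuple[str, ...] = ()
    subsets: frozenset[str] = frozenset()


class AnatomyDAG:
    """Anatomical entities with typed child->parent edges (is_a, part_of)."""

    def __init__(self, terms: dict[str, OntologyTerm]):
        self.terms = terms
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        for t in terms.values():
            for p in itertools.chain(t.is_a_parents, t.part_of_parents):
                if p not in terms:
                    raise OntologyError(f"edge endpoint {p!r} (parent of {t.id!r}) not in ontology")
                g.add_edge(t.id, p)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise OntologyError(f"cycle in anatomy ontology involving term {cyc[0][0]!r}")
        self._graph = g

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable via is_a/part_of, excluding *term* itself."""
        if term not in self.terms:
            raise KeyError(term)
        return nx.descendants(self._graph, term)  # edges point child->parent

    def direct_children(self, term: str) -> set[str]:
        if term not in self.terms:
            raise KeyError(term)
        return set(self._graph.predecessors(term))

    def descendants(self, term: str) -> set[str]:
        if term not in self.terms:
            raise KeyError(term)
        return nx.ancestors(self._graph, term)

    def roots(self) -> set[str]:
        return {t for t in self.terms if self._graph.out_degree(t) == 0}

    def depths(self) -> dict[str, int]:
        """Longest path length from a root to each term (roots are depth 0)."""
        order = list(nx.topological_sort(self._graph))  # parents late
        depth: dict[str, int] = {}
        for node in reversed(order):
            parents = list(self._graph.successors(node))
            depth[node] = 0 if not parents else 1 + max(depth[p] for p in parents)
        return depth


class StageTree:
    """Developmental stages: a part_of tree with preceded_by sibling order.

    The tree is also encoded as a nested set model: each stage gets a
    (left, right) interval; a stage is an ancestor of another iff its
    interval strictly contains the other's.
    """

    def __init__(self, terms: dict[str, OntologyTerm]):
        self.terms = terms
        self.parent: dict[str, str | None] = {}
        for t in terms.values():
            parents = t.part_of_parents
            if len(parents) > 1:
                raise OntologyError(f"stage {t.id!r} has {len(parents)} part_of parents (max 1)")
            if parents and parents[0] not in terms:
                raise OntologyError(f"stage parent {parents[0]!r} of {t.id!r} not in ontology")
            self.parent[t.id] = parents[0] if parents else None
        # cycle check over the parent pointers
        g = nx.DiGraph((c, p) for c, p in self.parent.items() if p is not None)
        g.add_nodes_from(terms)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise OntologyError(f"cycle in stage ontology involving term {cyc[0][0]!r}")
        self.nested_set = self._build_nested_set()

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def _children_ordered(self, term: str | None) -> list[str]:
        sibs = sorted(t for t, p in self.parent.items() if p == term)
        # topological order within the sibling group from preceded_by
        # (b preceded_by a means a comes before b); ties broken by id.
        g = nx.DiGraph()
        g.add_nodes_from(sibs)
        for s in sibs:
            for pred in self.terms[s].preceded_by:
                if pred in g:
                    g.add_edge(pred, s)
        return list(nx.lexicographical_topological_sort(g))

    def _build_nested_set(self) -> dict[str, tuple[int, int]]:
        counter = itertools.count(1)
        intervals: dict[str, tuple[int, int]] = {}

        def visit(term: str) -> None:
            left = next(counter)
            for child in self._children_ordered(term):
                visit(child)
            intervals[term] = (left, next(counter))

        for root in self._children_ordered(None):
            visit(root)
        return intervals

    def ancestors(self, term: str) -> set[str]:
        if term not in self.terms:
            raise KeyError(term)
        out: set[str] = set()
        p = self.parent[term]
        while p is not None:
            out.add(p)
            p = self.parent[p]
        return out

    def is_ancestor(self, anc: str, term: str) -> bool:
        """Nested-set containment: anc's interval strictly contains term's."""
        al, ar = self.nested_set[anc]
        tl, tr = self.nested_set[term]
        return al < tl and tr < ar

    def generalize(self, stage_id: str) -> str:
        """Remap a stage tagged ``granular_stage`` to its nearest non-granular
        ancestor; non-granular stages are returned unchanged."""
        if stage_id not in self.terms:
            raise KeyError(stage_id)
        cur: str | None = stage_id
        while cur is not None:
            if GRANULAR_SUBSET not in self.terms[cur].subsets:
                return cur
            cur = self.parent[cur]
        raise OntologyError(f"granular stage {stage_id!r} has no non-granular ancestor")


@dataclass(frozen=True, order=True)
class Condition:
    anat_id: str
    stage_id: str
    sex: str = SEX_ROOT
    strain: str = STRAIN_ROOT
    species_id: int = 0


def _parse_relationship(value: str) -> tuple[str, str]:
    parts = value.split("!")[0].split()
    if len(parts) != 2:
        raise OntologyError(f"malformed relationship value {value!r}")
    return parts[0], parts[1]


def _validate_obo_lines(path: str) -> None:
    """Reject structurally broken lines with a line-numbered error; obonet
    itself is lenient and would silently drop them."""
    with open(path, encoding="utf-8") as fh:
        in_term = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("!")[0].strip()
            if not line:
                continue
            if line.startswith("["):
                if not line.endswith("]"):
                    raise OntologyError(f"{path}:{lineno}: malformed stanza header {raw.strip()!r}")
                in_term = line == "[Term]"
                continue
            if ":" not in line:
                raise OntologyError(f"{path}:{lineno}: expected 'tag: value', got {raw.strip()!r}")
            if in_term:
                tag, _, value = line.partition(":")
                if not value.strip():
                    raise OntologyError(f"{path}:{lineno}: empty value for tag {tag!r}")


def load_obo_subset(path: str, kind: str) -> AnatomyDAG | StageTree:
    """Parse a simplified OBO file into an :class:`AnatomyDAG` or
    :class:`StageTree`.

    Only ``[Term]`` stanzas with id/name/is_a/relationship/subset lines are
    honoured.  Unknown relationship types are ignored with a warning; cycles
    raise :class:`OntologyError`.
    """
    if kind not in ("anatomy", "stage"):
        raise ValueError(f"kind must be 'anatomy' or 'stage', got {kind!r}")
    _validate_obo_lines(path)
    graph = obonet.read_obo(path, ignore_obsolete=True)
    terms: dict[str, OntologyTerm] = {}
    for node, data in graph.nodes(data=True):
        part_of: list[str] = []
        preceded: list[str] = []
        for rel in data.get("relationship", ()):
            rtype, target = _parse_relationship(rel)
            if rtype == "part_of":
                part_of.append(target)
            elif rtype in ("preceded_by", "immediately_preceded_by"):
                preceded.append(target)
            else:
                logger.warning("ignoring unknown relationship %r on term %s", rtype, node)
        terms[node] = OntologyTerm(
            id=node,
            name=data.get("name", node),
            is_a_parents=tuple(data.get("is_a", ())),
            part_of_parents=tuple(part_of),
            preceded_by=tuple(preceded),
            subsets=frozenset(data.get("subset", ())),
        )
    return AnatomyDAG(terms) if kind == "anatomy" else StageTree(terms)


class ConditionGraph:
    """The partial order over conditions induced component-wise by the
    anatomy DAG, the stage tree and the flat sex/strain hierarchies.

    A condition c2 is an ancestor of c1 iff every component of c2 equals or
    is an ontology-ancestor of the corresponding component of c1, c2 != c1.
    Parent sets are computed on demand; the cross product is never built.
    """

    def __init__(self, anatomy: AnatomyDAG, stages: StageTree):
        self.anatomy = anatomy
        self.stages = stages

    def validate(self, c: Condition) -> None:
        if c.anat_id not in self.anatomy:
            raise KeyError(f"unknown anatomical entity {c.anat_id!r}")
        if c.stage_id not in self.stages:
            raise KeyError(f"unknown stage {c.stage_id!r}")

    @staticmethod
    def _sex_ancestors_or_self(sex: str) -> set[str]:
        # missing-value sexes never propagate into "any" and never match it
        if sex in SEXES:
            return {sex, SEX_ROOT}
        return {sex}

    @staticmethod
    def _strain_ancestors_or_self(strain: str) -> set[str]:
        if strain == STRAIN_ROOT or strain in MISSING_VALUES:
            return {strain}
        return {strain, STRAIN_ROOT}

    def ancestors(self, c: Condition) -> set[Condition]:
        """All strict ancestor conditions of *c* (aka condition_parents)."""
        self.validate(c)
        anats = self.anatomy.ancestors(c.anat_id) | {c.anat_id}
        stgs = self.stages.ancestors(c.stage_id) | {c.stage_id}
        sexes = self._sex_ancestors_or_self(c.sex)
        strains = self._strain_ancestors_or_self(c.strain)
        out = {
            Condition(a, s, x, st, c.species_id)
            for a in anats
            for s in stgs
            for x in sexes
            for st in strains
        }
        out.discard(c)
        return out

    def direct_anat_children(self, c: Condition) -> set[Condition]:
        """Conditions one anatomical level below *c*; stage, sex and strain
        are kept unchanged (the scope of absent-call propagation)."""
        self.validate(c)
        return {replace(c, anat_id=a) for a in self.anatomy.direct_children(c.anat_id)}


# aliases matching the operation vocabulary used in the docs
def anat_ancestors(dag: AnatomyDAG, term: str) -> set[str]:
    return dag.ancestors(term)


def anat_direct_children(dag: AnatomyDAG, term: str) -> set[str]:
    return dag.direct_children(term)


def generalize_stage(tree: StageTree, stage_id: str) -> str:
    return tree.generalize(stage_id)


def condition_parents(graph: ConditionGraph, c: Condition) -> set[Condition]:
    return graph.ancestors(c)


def condition_direct_anat_children(graph: ConditionGraph, c: Condition) -> set[Condition]:
    return graph.direct_anat_children(c)
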