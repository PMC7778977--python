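"""Call propagation along the condition graph and global-call integration.

Presence calls propagate to *all* ancestor conditions (a gene expressed in
the midbrain is expressed in the brain).  Absence calls propagate only to
direct anatomical child conditions, at the same stage/sex/strain — an assay
could miss expression confined to a small part of a large structure, so
absence is never pushed deeper.

Per gene-condition, presence always wins over absence, whatever the number
and quality of assays.  A global absent call requires absence support and no
conflicting presence in the condition or any sub-condition.  Confidence is
graded gold / silver / bronze from the number of distinct supporting
experiments and whether they contribute high-quality calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .calls import ABSENT, HIGH, PRESENT, AssayCall, DataType
from .ontology import Condition, ConditionGraph

GOLD = "gold"
SILVER = "silver"
BRONZE = "bronze"

CONFIDENCE_ORDER = {BRONZE: 0, SILVER: 1, GOLD: 2}


@dataclass(frozen=True)
class PropagatedCall:
    base: AssayCall
    target_condition: Condition
    origin: str  # observed | propagated

    def __post_init__(self):
        observed = self.target_condition == self.base.condition
        if (self.origin == "observed") != observed:
            raise ValueError("origin flag inconsistent with source/target conditions")


@dataclass(frozen=True)
class SupportCounts:
    """Distinct-experiment counts per data type, for each state."""

    presence: dict[DataType, int] = field(default_factory=dict)
    absence: dict[DataType, int] = field(default_factory=dict)

    def total_presence(self) -> int:
        return sum(self.presence.values())

    def total_absence(self) -> int:
        return sum(self.absence.values())


@dataclass(frozen=True)
class GlobalCall:
    gene: str
    condition: Condition
    state: str
    confidence: str
    support: SupportCounts
    observed: bool


def generalize_calls(calls: list[AssayCall], graph: ConditionGraph) -> list[AssayCall]:
    """Remap granular developmental stages to their nearest general ancestor
    before propagation."""
    out = []
    for c in calls:
        stage = graph.stages.generalize(c.condition.stage_id)
        if stage != c.condition.stage_id:
            c = replace(c, condition=replace(c.condition, stage_id=stage))
        out.append(c)
    return out


def propagate_presence(calls: list[AssayCall], graph: ConditionGraph) -> list[PropagatedCall]:
    out = []
    for call in calls:
        if call.state != PRESENT:
            raise ValueError("propagate_presence accepts present calls only")
        out.append(PropagatedCall(call, call.condition, "observed"))
        for target in sorted(graph.ancestors(call.condition)):
            out.append(PropagatedCall(call, target, "propagated"))
    return out


def propagate_absence(calls: list[AssayCall], graph: ConditionGraph) -> list[PropagatedCall]:
    out = []
    for call in calls:
        if call.state != ABSENT:
            raise ValueError("propagate_absence accepts absent calls only")
        out.append(PropagatedCall(call, call.condition, "observed"))
        for target in sorted(graph.direct_anat_children(call.condition)):
            out.append(PropagatedCall(call, target, "propagated"))
    return out


class CallIndex:
    """Propagated calls indexed by (gene, target condition)."""

    def __init__(self, propagated: list[PropagatedCall]):
        self._by_key: dict[tuple[str, Condition], list[PropagatedCall]] = {}
        for pc in propagated:
            self._by_key.setdefault((pc.base.gene, pc.target_condition), []).append(pc)

    def keys(self):
        return self._by_key.keys()

    def at(self, gene: str, condition: Condition) -> list[PropagatedCall]:
        return self._by_key.get((gene, condition), [])


def _experiment_support(records: list[PropagatedCall]) -> dict[str, bool]:
    """experiment_id -> contributes at least one high-quality call."""
    exp: dict[str, bool] = {}
    for r in records:
        exp[r.base.experiment_id] = exp.get(r.base.experiment_id, False) or r.base.quality == HIGH
    return exp


def assign_confidence(experiment_quality: dict[str, bool]) -> str:
    """gold: >=2 experiments with a high-quality call; silver: exactly one
    high-quality experiment, or >=2 experiments all low quality; bronze: a
    single low-quality experiment."""
    if not experiment_quality:
        raise ValueError("no supporting experiments")
    n_high = sum(experiment_quality.values())
    n_total = len(experiment_quality)
    if n_high >= 2:
        return GOLD
    if n_high == 1 or n_total >= 2:
        return SILVER
    return BRONZE


def _support_counts(records: list[PropagatedCall]) -> dict[DataType, int]:
    per_type: dict[DataType, set[str]] = {}
    for r in records:
        per_type.setdefault(r.base.data_type, set()).add(r.base.experiment_id)
    return {dt: len(exps) for dt, exps in sorted(per_type.items())}


def reconcile(gene: str, condition: Condition, index: CallIndex) -> GlobalCall | None:
    """One global call for a gene-condition, or None when no call reaches it.

    Because presence propagates to every ancestor condition, "a presence
    call exists in the condition or any sub-condition" is equivalent to "a
    presence record targets the condition"; similarly the absence records
    reaching a condition are exactly those observed there or in a direct
    anatomical parent.
    """
    records = index.at(gene, condition)
    if not records:
        return None
    presence = [r for r in records if r.base.state == PRESENT]
    absence = [r for r in records if r.base.state == ABSENT]
    winning = presence if presence else absence
    state = PRESENT if presence else ABSENT
    support = SupportCounts(presence=_support_counts(presence), absence=_support_counts(absence))
    confidence = assign_confidence(_experiment_support(winning))
    observed = any(r.origin == "observed" for r in winning)
    return GlobalCall(gene, condition, state, confidence, support, observed)


def integrate_calls(
    calls: list[AssayCall], graph: ConditionGraph, generalize_stages: bool = True
) -> list[GlobalCall]:
    """Full integration: stage generalization, propagation of both call
    states, and reconciliation at every condition reached by any call."""
    if generalize_stages:
        calls = generalize_calls(calls, graph)
    present = [c for c in calls if c.state == PRESENT]
    absent = [c for c in calls if c.state == ABSENT]
    propagated = propagate_presence(present, graph) + propagate_absence(absent, graph)
    index = CallIndex(propagated)
    out = []
    for gene, condition in sorted(index.keys()):
        gc = reconcile(gene, condition, index)
        if gc is not None:
            out.append(gc)
    return out
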