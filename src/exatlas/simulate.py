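"""Seeded synthetic data for every input the engine consumes.

The generator plants a known ground truth — gene sets expressed within
chosen anatomical subtrees at graded effect sizes — and emits the four assay
types around it:

* RNA-seq: intergenic-region TPMs drawn from an exponential background;
  expressed genes draw log-normal TPM centred ``effect`` doublings above the
  background's (1 - alpha) quantile, unexpressed genes two orders of
  magnitude below it.
* Affymetrix: log-scale probe signals; expressed probesets are shifted
  ``effect`` units above the background-probeset distribution, unexpressed
  ones sit below it.
* EST: per-library tag counts, Poisson with mean proportional to planted
  abundance (tier-middle genes average ``est_mean_expressed`` tags);
  unexpressed genes yield no tags — an EST is a sampled transcript.
* in situ hybridization: detected spots for a random subset of the truly
  expressed gene-conditions.

Each data type consumes its own pseudo-random stream derived from the master
seed by a fixed label, so adding one data type never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calls import AffymetrixChip, EstLibrary, InSituSpot, RnaSeqLibrary
from .ontology import (
    AnatomyDAG,
    Condition,
    ConditionGraph,
    GRANULAR_SUBSET,
    OntologyTerm,
    SEX_ROOT,
    STRAIN_ROOT,
    StageTree,
)

_STREAMS = {"ontology": 0, "patterns": 1, "rnaseq": 2, "affymetrix": 3, "est": 4, "insitu": 5}


@dataclass
class FixtureSpec:
    """Study conditions of the synthetic dataset. Defaults model a small
    multi-assay atlas: a 20-term anatomy, two planted expression programs of
    12 genes each at three effect tiers, two experiments per data type."""

    seed: int = 0
    n_genes: int = 40
    species_id: int = 9001
    # anatomy DAG
    anatomy_n_terms: int = 20
    anatomy_max_children: int = 3
    anatomy_multiparent_fraction: float = 0.1
    # stage tree
    stage_depth: int = 3
    stage_branching: int = 2
    granular_fraction: float = 0.4
    # planted expression programs
    n_patterns: int = 2
    genes_per_tier: int = 4
    pattern_effects: tuple[float, ...] = (4.0, 2.5, 1.0)  # log2-fold over background threshold
    # noise
    tpm_log_sigma: float = 0.5
    intergenic_rate: float = 1.0
    n_intergenic: int = 200
    rnaseq_alpha: float = 0.05
    affy_signal_mean: float = 6.0
    affy_signal_sd: float = 0.7
    affy_unexpressed_shift: float = -1.5
    probes_per_probeset: int = 8
    n_background_probesets: int = 10
    est_mean_expressed: float = 10.0
    est_background_rate: float = 0.0
    insitu_coverage: float = 0.3
    # assay design
    experiments_per_type: int = 2


@dataclass
class GroundTruth:
    """Planted truth: which gene is expressed where, at what effect size."""

    expressed_anats: dict[str, set[str]] = field(default_factory=dict)  # gene -> anat terms
    effect: dict[str, float] = field(default_factory=dict)  # gene -> log2 effect

    def expressed_conditions(
        self, gene: str, graph: ConditionGraph, stage_id: str, species_id: int
    ) -> set[Condition]:
        """Upward closure over the condition graph of the planted
        gene-condition pairs — what perfect call propagation would yield."""
        out: set[Condition] = set()
        for anat in self.expressed_anats.get(gene, ()):
            c = Condition(anat, stage_id, SEX_ROOT, STRAIN_ROOT, species_id)
            out.add(c)
            out |= graph.ancestors(c)
        return out


@dataclass
class SyntheticDataset:
    spec: FixtureSpec
    anatomy: AnatomyDAG
    stages: StageTree
    graph: ConditionGraph
    genes: list[str]
    data_stage: str  # stage at which assays are annotated (may be granular)
    truth_stage: str  # the generalized stage calls end up at
    conditions: list[Condition]
    truth: GroundTruth
    rnaseq: list[RnaSeqLibrary] = field(default_factory=list)
    affymetrix: list[AffymetrixChip] = field(default_factory=list)
    est: list[EstLibrary] = field(default_factory=list)
    insitu: list[InSituSpot] = field(default_factory=list)
    background_probesets: set[str] = field(default_factory=set)


def _rng(spec: FixtureSpec, label: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(_STREAMS[label],)))


def gen_anatomy(spec: FixtureSpec, rng: np.random.Generator) -> AnatomyDAG:
    """Random single-rooted DAG: term i attaches is_a to an earlier term with
    spare child capacity; a fraction of terms gain an extra part_of parent
    (earlier index, so acyclicity is free)."""
    n = spec.anatomy_n_terms
    ids = [f"ANAT:{i:07d}" for i in range(1, n + 1)]
    child_count = dict.fromkeys(range(n), 0)
    is_a: dict[int, list[int]] = {i: [] for i in range(n)}
    part_of: dict[int, list[int]] = {i: [] for i in range(n)}
    for i in range(1, n):
        open_parents = [j for j in range(i) if child_count[j] < spec.anatomy_max_children]
        if not open_parents:
            open_parents = list(range(i))
        j = int(rng.choice(open_parents))
        is_a[i].append(j)
        child_count[j] += 1
        if i >= 2 and rng.random() < spec.anatomy_multiparent_fraction:
            others = [k for k in range(i) if k != j]
            part_of[i].append(int(rng.choice(others)))
    terms = {
        ids[i]: OntologyTerm(
            id=ids[i],
            name=f"anatomical entity {i + 1}",
            is_a_parents=tuple(ids[j] for j in is_a[i]),
            part_of_parents=tuple(ids[j] for j in part_of[i]),
        )
        for i in range(n)
    }
    return AnatomyDAG(terms)


def gen_stages(spec: FixtureSpec, rng: np.random.Generator) -> StageTree:
    """Balanced part_of tree with preceded_by chains among siblings; leaves
    are tagged ``granular_stage`` with probability granular_fraction."""
    terms: dict[str, OntologyTerm] = {}
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"STG:{counter[0]:07d}"

    def build(parent: str | None, depth: int) -> None:
        prev = None
        for _ in range(spec.stage_branching if parent else 1):
            sid = new_id()
            is_leaf = depth == spec.stage_depth
            granular = is_leaf and rng.random() < spec.granular_fraction
            terms[sid] = OntologyTerm(
                id=sid,
                name=f"stage {counter[0]}",
                part_of_parents=(parent,) if parent else (),
                preceded_by=(prev,) if prev else (),
                subsets=frozenset({GRANULAR_SUBSET}) if granular else frozenset(),
            )
            prev = sid
            if not is_leaf:
                build(sid, depth + 1)

    build(None, 0)
    return StageTree(terms)


def _plant_patterns(
    spec: FixtureSpec, anatomy: AnatomyDAG, genes: list[str], rng: np.random.Generator
) -> GroundTruth:
    """Pick disjoint anatomical subtrees and assign gene tiers to each."""
    truth = GroundTruth()
    # candidate subtree roots: internal, non-root terms, smallest first so
    # patterns stay local; keep chosen subtrees disjoint
    depths = anatomy.depths()
    candidates = sorted(
        (t for t in anatomy.terms if 1 <= depths[t] and anatomy.direct_children(t)),
        key=lambda t: (len(anatomy.descendants(t)), t),
    )
    used: set[str] = set()
    roots: list[str] = []
    for t in candidates:
        if len(roots) == spec.n_patterns:
            break
        subtree = anatomy.descendants(t) | {t}
        if subtree & used:
            continue
        roots.append(t)
        used |= subtree
    gene_iter = iter(genes)
    for root in roots:
        subtree = anatomy.descendants(root) | {root}
        for effect in spec.pattern_effects:
            for _ in range(spec.genes_per_tier):
                try:
                    g = next(gene_iter)
                except StopIteration:
                    return truth
                truth.expressed_anats[g] = set(subtree)
                truth.effect[g] = effect
    return truth


def generate_dataset(spec: FixtureSpec) -> SyntheticDataset:
    anatomy = gen_anatomy(spec, _rng(spec, "ontology"))
    stages = gen_stages(spec, _rng(spec, "ontology"))
    graph = ConditionGraph(anatomy, stages)
    genes = [f"GENE:{i:05d}" for i in range(1, spec.n_genes + 1)]

    leaf_stages = sorted(s for s in stages.terms if not any(p == s for p in stages.parent.values()))
    granular_leaves = [s for s in leaf_stages if GRANULAR_SUBSET in stages.terms[s].subsets]
    data_stage = granular_leaves[0] if granular_leaves else leaf_stages[0]
    truth_stage = stages.generalize(data_stage)

    conditions = [
        Condition(a, data_stage, SEX_ROOT, STRAIN_ROOT, spec.species_id)
        for a in sorted(anatomy.terms)
    ]
    truth = _plant_patterns(spec, anatomy, genes, _rng(spec, "patterns"))
    ds = SyntheticDataset(
        spec, anatomy, stages, graph, genes, data_stage, truth_stage, conditions, truth
    )
    _gen_rnaseq(ds, _rng(spec, "rnaseq"))
    _gen_affymetrix(ds, _rng(spec, "affymetrix"))
    _gen_est(ds, _rng(spec, "est"))
    _gen_insitu(ds, _rng(spec, "insitu"))
    return ds


def _is_expressed(ds: SyntheticDataset, gene: str, anat: str) -> bool:
    return anat in ds.truth.expressed_anats.get(gene, ())


def _background_quantile(spec: FixtureSpec) -> float:
    """Theoretical (1 - alpha) quantile of the intergenic exponential."""
    return -np.log(spec.rnaseq_alpha) / spec.intergenic_rate


def _gen_rnaseq(ds: SyntheticDataset, rng: np.random.Generator) -> None:
    spec = ds.spec
    q = _background_quantile(spec)
    for cond in ds.conditions:
        for e in range(1, spec.experiments_per_type + 1):
            tpm = {}
            for g in ds.genes:
                if _is_expressed(ds, g, cond.anat_id):
                    centre = np.log(q) + ds.truth.effect[g] * np.log(2.0)
                else:
                    centre = np.log(q) - np.log(30.0)  # well below background
                tpm[g] = float(rng.lognormal(centre, spec.tpm_log_sigma))
            intergenic = rng.exponential(1.0 / spec.intergenic_rate, spec.n_intergenic)
            ds.rnaseq.append(
                RnaSeqLibrary(
                    library_id=f"rnaseq_lib_{cond.anat_id.split(':')[1]}_e{e}",
                    experiment_id=f"rnaseq_exp_{e}",
                    condition=cond,
                    gene_tpm=tpm,
                    intergenic_tpm=[float(x) for x in intergenic],
                )
            )


def _gen_affymetrix(ds: SyntheticDataset, rng: np.random.Generator) -> None:
    spec = ds.spec
    bg_ids = [f"AFFX:{i:04d}" for i in range(1, spec.n_background_probesets + 1)]
    ds.background_probesets = set(bg_ids)
    # two chip designs: type B covers only a prefix of genes, so the two
    # chip types reach different max ranks and exercise the rank
    # normalization between chip types
    designs = {"typeA": ds.genes, "typeB": ds.genes[: max(2, len(ds.genes) * 2 // 3)]}
    probeset_of = {g: f"PS:{g.split(':')[1]}" for g in ds.genes}
    gene_of = {ps: g for g, ps in probeset_of.items()}
    for cond in ds.conditions:
        for e in range(1, spec.experiments_per_type + 1):
            chip_type = "typeA" if e % 2 == 1 else "typeB"
            signal: dict[str, list[float]] = {}
            for g in designs[chip_type]:
                if _is_expressed(ds, g, cond.anat_id):
                    mu = spec.affy_signal_mean + ds.truth.effect[g]
                else:
                    mu = spec.affy_signal_mean + spec.affy_unexpressed_shift
                signal[probeset_of[g]] = [
                    float(x) for x in rng.normal(mu, spec.affy_signal_sd, spec.probes_per_probeset)
                ]
            for ps in bg_ids:
                signal[ps] = [
                    float(x)
                    for x in rng.normal(
                        spec.affy_signal_mean, spec.affy_signal_sd, spec.probes_per_probeset
                    )
                ]
            ds.affymetrix.append(
                AffymetrixChip(
                    chip_id=f"chip_{cond.anat_id.split(':')[1]}_e{e}",
                    experiment_id=f"affy_exp_{e}",
                    chip_type=chip_type,
                    condition=cond,
                    mode="cel_signal",
                    probeset_signal=signal,
                    probeset_to_gene=gene_of,
                )
            )


def _gen_est(ds: SyntheticDataset, rng: np.random.Generator) -> None:
    spec = ds.spec
    mid = float(np.median(spec.pattern_effects))
    for cond in ds.conditions:
        for e in range(1, spec.experiments_per_type + 1):
            counts: dict[str, int] = {}
            for g in ds.genes:
                if _is_expressed(ds, g, cond.anat_id):
                    mean = spec.est_mean_expressed * 2.0 ** (ds.truth.effect[g] - mid)
                elif spec.est_background_rate > 0:
                    mean = spec.est_background_rate
                else:
                    counts[g] = 0
                    continue
                counts[g] = int(rng.poisson(mean))
            ds.est.append(
                EstLibrary(
                    library_id=f"est_lib_{cond.anat_id.split(':')[1]}_e{e}",
                    condition=cond,
                    gene_est_count=counts,
                )
            )


def _gen_insitu(ds: SyntheticDataset, rng: np.random.Generator) -> None:
    spec = ds.spec
    n = 0
    for cond in ds.conditions:
        for g in ds.genes:
            if not _is_expressed(ds, g, cond.anat_id):
                continue
            if rng.random() >= spec.insitu_coverage:
                continue
            for e in range(1, spec.experiments_per_type + 1):
                n += 1
                ds.insitu.append(
                    InSituSpot(
                        evidence_id=f"spot_{n:06d}",
                        experiment_id=f"insitu_exp_{e}",
                        gene=g,
                        condition=cond,
                        detected=True,
                        quality="high" if rng.random() < 0.5 else "low",
                    )
                )
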