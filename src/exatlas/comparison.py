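"""Cross-species expression comparison over anatomical-similarity groups.

Anatomical entities of different species that derive from a common ancestral
structure (e.g. the tetrapod lung and the teleost swim bladder) are grouped
by curated similarity annotations.  Expression of a set of genes, one list
per species, is compared group by group: each queried gene is classified as
expressed / not expressed / no data from its global calls, and groups are
ordered by expression conservation then by the best expression rank.
Single-species comparisons use raw anatomical entities instead of groups.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from .integrate import ABSENT, GlobalCall, PRESENT
from .ranks import GlobalRank


@dataclass(frozen=True)
class SimilarityMember:
    species_ids: frozenset[int]
    entity_ids: frozenset[str]  # compound members may span several terms


@dataclass(frozen=True)
class SimilarityGroup:
    group_id: str
    members: tuple[SimilarityMember, ...]
    label: str = ""

    def entities(self) -> set[str]:
        return {e for m in self.members for e in m.entity_ids}

    def species(self) -> set[int]:
        return {s for m in self.members for s in m.species_ids}


def load_similarity_annotations(path: str) -> list[SimilarityGroup]:
    """Read a similarity-annotation TSV: group_id, taxon_id, species_ids
    (comma-separated), entity_ids (comma-separated), label. One row per
    group member; rows sharing a group_id form one group."""
    groups: dict[str, list[SimilarityMember]] = {}
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"group_id", "taxon_id", "species_ids", "entity_ids", "label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or ()))
            raise ValueError(f"{path}: missing column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                species = frozenset(int(s) for s in row["species_ids"].split(",") if s)
                entities = frozenset(e.strip() for e in row["entity_ids"].split(",") if e.strip())
                if not entities:
                    raise ValueError("no entity ids")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
            groups.setdefault(row["group_id"], []).append(SimilarityMember(species, entities))
            labels.setdefault(row["group_id"], row["label"])
    return [
        SimilarityGroup(gid, tuple(members), labels[gid]) for gid, members in sorted(groups.items())
    ]


def lookup_homology(
    groups: list[SimilarityGroup], entity: str, target_species: set[int]
) -> list[SimilarityGroup]:
    """Groups containing *entity* whose members cover every target species."""
    return [
        g
        for g in groups
        if entity in g.entities() and target_species <= g.species()
    ]


@dataclass(frozen=True)
class ComparisonRow:
    group_id: str
    label: str
    genes_present: frozenset[str]
    genes_absent: frozenset[str]
    genes_no_data: frozenset[str]
    conservation_score: float
    min_rank: float  # inf when no queried gene is present


def _classify(
    genes: set[str], entities: set[str], calls_by_gene: dict[str, list[GlobalCall]]
) -> tuple[set[str], set[str], set[str]]:
    present, absent, nodata = set(), set(), set()
    for gene in genes:
        states = {
            gc.state for gc in calls_by_gene.get(gene, []) if gc.condition.anat_id in entities
        }
        if PRESENT in states:
            present.add(gene)
        elif ABSENT in states:
            absent.add(gene)
        else:
            nodata.add(gene)
    return present, absent, nodata


def conservation_score(n_present: int, n_absent: int) -> float:
    """Majority fraction among genes with data; 0 when no gene has data."""
    n = n_present + n_absent
    return max(n_present, n_absent) / n if n else 0.0


def compare_expression(
    gene_lists: dict[int, set[str]],
    calls: list[GlobalCall],
    ranks: list[GlobalRank],
    groups: list[SimilarityGroup] | None = None,
) -> list[ComparisonRow]:
    """Partition the queried genes per anatomical entity (single species) or
    per similarity group (multiple species) into expressed / not expressed /
    no data; sort by conservation descending, then best (minimum) rank."""
    multi_species = len(gene_lists) > 1
    if multi_species and not groups:
        raise ValueError("multi-species comparison requires similarity groups")
    all_genes = {g for gs in gene_lists.values() for g in gs}
    calls_by_gene: dict[str, list[GlobalCall]] = {}
    for gc in calls:
        if gc.gene in all_genes:
            calls_by_gene.setdefault(gc.gene, []).append(gc)
    rank_by_gene_anat: dict[tuple[str, str], float] = {}
    for gr in ranks:
        key = (gr.gene, gr.condition.anat_id)
        if gr.gene in all_genes:
            cur = rank_by_gene_anat.get(key)
            if cur is None or gr.mean_norm_rank < cur:
                rank_by_gene_anat[key] = gr.mean_norm_rank

    if multi_species:
        units = [(g.group_id, g.label, g.entities()) for g in groups]
    else:
        anats = sorted(
            {gc.condition.anat_id for gene in all_genes for gc in calls_by_gene.get(gene, [])}
        )
        units = [(a, a, {a}) for a in anats]

    rows = []
    for unit_id, label, entities in units:
        present, absent, nodata = _classify(all_genes, entities, calls_by_gene)
        min_rank = min(
            (
                rank_by_gene_anat[(g, a)]
                for g in present
                for a in entities
                if (g, a) in rank_by_gene_anat
            ),
            default=float("inf"),
        )
        rows.append(
            ComparisonRow(
                group_id=unit_id,
                label=label,
                genes_present=frozenset(present),
                genes_absent=frozenset(absent),
                genes_no_data=frozenset(nodata),
                conservation_score=conservation_score(len(present), len(absent)),
                min_rank=min_rank,
            )
        )
    rows.sort(key=lambda r: (-r.conservation_score, r.min_rank, r.group_id))
    return rows
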