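"""Expression ranks and 0-100 expression scores.

Genes are ranked within each condition, per data type:

* RNA-seq: fractional ranks of TPM per library, combined across libraries
  by a weighted mean, the weight being each library's number of distinct
  rank values (libraries resolving more distinct ranks carry more weight).
* Affymetrix: fractional ranks of the per-gene max probeset signal per
  chip, normalized between chip types (a chip type's global max rank vs the
  max over the chip types present in the condition), then the same weighted
  mean.
* in situ hybridization: a per-gene evidence score (count of present spots,
  weighted by call quality), dense-ranked.
* EST: total tag count across the condition's libraries, dense-ranked.

Per-data-type ranks are then normalized against the species-wide max rank,
averaged with data-type-specific weights into one global weighted mean rank
per gene-condition, and mapped affinely onto a (0, 100] expression score
where the top-ranked gene scores 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .calls import AssayCall, DataType, EstLibrary, InSituSpot, PRESENT, HIGH
from .ontology import Condition

#: quality weights for in situ evidence scoring
INSITU_WEIGHTS = {"high": 1.0, "low": 0.5}


def fractional_rank(values: dict[str, float]) -> tuple[dict[str, float], int]:
    """Descending fractional ranks (top value -> rank 1; ties get the mean of
    the positions they span) and the number of distinct rank values."""
    if not values:
        raise ValueError("cannot rank an empty mapping")
    genes = sorted(values)
    arr = np.array([values[g] for g in genes], dtype=float)
    ranks = stats.rankdata(-arr, method="average")
    return dict(zip(genes, ranks.tolist())), len(np.unique(ranks))


def dense_rank(scores: dict[str, float]) -> dict[str, int]:
    """Descending dense ranks: ties share a rank, ranks are 1..k."""
    if not scores:
        raise ValueError("cannot rank an empty mapping")
    genes = sorted(scores)
    arr = np.array([scores[g] for g in genes], dtype=float)
    ranks = stats.rankdata(-arr, method="dense").astype(int)
    return dict(zip(genes, ranks.tolist()))


@dataclass
class LibraryRanking:
    assay_id: str
    condition: Condition
    frac_rank: dict[str, float]
    distinct_rank_count: int

    @classmethod
    def from_values(cls, assay_id: str, condition: Condition, values: dict[str, float]):
        ranks, distinct = fractional_rank(values)
        return cls(assay_id, condition, ranks, distinct)


@dataclass
class ChipRanking(LibraryRanking):
    chip_type: str = ""
    norm_frac_rank: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_signals(cls, assay_id, condition, chip_type, probeset_signal, probeset_to_gene):
        """Fractional rank on the highest probeset signal per gene."""
        gene_max: dict[str, float] = {}
        for ps, signals in probeset_signal.items():
            gene = probeset_to_gene.get(ps)
            if gene is None or not signals:
                continue
            m = max(signals)
            if gene not in gene_max or m > gene_max[gene]:
                gene_max[gene] = m
        ranks, distinct = fractional_rank(gene_max)
        return cls(assay_id, condition, ranks, distinct, chip_type=chip_type)


def weighted_mean_rank(ranks_and_weights: list[tuple[float, float]]) -> float:
    """Weighted mean of per-assay ranks, weighted by distinct rank counts."""
    if not ranks_and_weights:
        raise ValueError("no assays to combine")
    num = sum(w * r for r, w in ranks_and_weights)
    den = sum(w for _, w in ranks_and_weights)
    if den <= 0:
        raise ValueError("total weight is zero")
    return num / den


def rnaseq_condition_rank(rankings: list[LibraryRanking], gene: str) -> float | None:
    pairs = [
        (lr.frac_rank[gene], lr.distinct_rank_count) for lr in rankings if gene in lr.frac_rank
    ]
    return weighted_mean_rank(pairs) if pairs else None


def chip_type_global_max(chips: list[ChipRanking]) -> dict[str, float]:
    """Per chip type, the max fractional rank over all chips and conditions."""
    out: dict[str, float] = {}
    for ch in chips:
        m = max(ch.frac_rank.values())
        out[ch.chip_type] = max(out.get(ch.chip_type, 0.0), m)
    return out


def affy_normalize_chip_rank(chip: ChipRanking, type_max: dict[str, float], cond_max: float) -> None:
    """Scale a chip's ranks by (1 + condMax/typeMax)/2, where typeMax is the
    chip type's global max rank and condMax the max of the type maxima among
    chip types represented in the chip's condition. Fills norm_frac_rank."""
    tmax = type_max.get(chip.chip_type, 0.0)
    if tmax <= 0:
        raise ValueError(f"chip type {chip.chip_type!r} has no recorded max rank")
    factor = (1.0 + cond_max / tmax) / 2.0
    chip.norm_frac_rank = {g: r * factor for g, r in chip.frac_rank.items()}


def normalize_affy_chips(chips: list[ChipRanking]) -> None:
    type_max = chip_type_global_max(chips)
    by_cond: dict[Condition, list[ChipRanking]] = {}
    for ch in chips:
        by_cond.setdefault(ch.condition, []).append(ch)
    for cond_chips in by_cond.values():
        cond_max = max(type_max[ch.chip_type] for ch in cond_chips)
        for ch in cond_chips:
            affy_normalize_chip_rank(ch, type_max, cond_max)


def affy_condition_rank(chips: list[ChipRanking], gene: str) -> float | None:
    pairs = [
        (ch.norm_frac_rank[gene], ch.distinct_rank_count) for ch in chips if gene in ch.norm_frac_rank
    ]
    return weighted_mean_rank(pairs) if pairs else None


def insitu_condition_rank(
    calls: list[AssayCall], weights: dict[str, float] | None = None
) -> tuple[dict[str, int], int]:
    """Dense rank of per-gene evidence scores (sum of quality weights over
    present spots). Genes with only absent spots receive no rank."""
    weights = weights or INSITU_WEIGHTS
    scores: dict[str, float] = {}
    for c in calls:
        if c.state == PRESENT:
            scores[c.gene] = scores.get(c.gene, 0.0) + weights[c.quality]
    if not scores:
        return {}, 0
    ranks = dense_rank(scores)
    return ranks, max(ranks.values())


def est_condition_rank(libs: list[EstLibrary]) -> tuple[dict[str, int], int]:
    """Dense rank of total EST counts summed over the condition's libraries."""
    totals: dict[str, int] = {}
    for lib in libs:
        for gene, count in lib.gene_est_count.items():
            if count > 0:
                totals[gene] = totals.get(gene, 0) + count
    if not totals:
        return {}, 0
    ranks = dense_rank(totals)
    return ranks, max(ranks.values())


def normalize_datatype_rank(rank: float, datatype_condition_max: float, species_max: float) -> float:
    """rank * (1 + speciesMax/conditionDataTypeMax) / 2."""
    if datatype_condition_max <= 0:
        raise ValueError("data-type condition max rank must be positive")
    return rank * (1.0 + species_max / datatype_condition_max) / 2.0


@dataclass(frozen=True)
class GlobalRank:
    gene: str
    condition: Condition
    weight_rnaseq: float  # A: sum of distinct rank counts over libraries with g
    norm_rank_rnaseq: float  # B
    weight_affy: float  # C
    norm_rank_affy: float  # D
    weight_insitu: float  # E: max in situ dense rank in the condition
    norm_rank_insitu: float  # F
    weight_est: float  # G: max EST dense rank in the condition
    norm_rank_est: float  # H
    mean_norm_rank: float
    expression_score: float


def global_mean_rank(weights_and_ranks: list[tuple[float, float]]) -> float:
    """Weighted mean of normalized per-data-type ranks; zero-weight data
    types contribute nothing."""
    num = sum(w * r for w, r in weights_and_ranks)
    den = sum(w for w, _ in weights_and_ranks)
    if den <= 0:
        raise ValueError("no data type carries weight for this gene-condition")
    return num / den


def expression_score(rank: float, species_max: float) -> float:
    """(max + 1 - rank) * 100 / max: rank 1 scores 100, the worst rank
    scores 100/max."""
    if not 1.0 <= rank <= species_max + 1e-9:
        raise ValueError(f"rank {rank} outside [1, {species_max}]")
    return (species_max + 1.0 - rank) * 100.0 / species_max


@dataclass
class RankInputs:
    """Per-condition assay-level rankings for one species."""

    rnaseq: dict[Condition, list[LibraryRanking]] = field(default_factory=dict)
    affymetrix: dict[Condition, list[ChipRanking]] = field(default_factory=dict)
    insitu: dict[Condition, list[AssayCall]] = field(default_factory=dict)
    est: dict[Condition, list[EstLibrary]] = field(default_factory=dict)


def compute_global_ranks(inputs: RankInputs) -> list[GlobalRank]:
    """Full rank integration for one species.

    Per condition and data type, compute the (weighted-mean or dense) rank
    per gene; record each data type's per-condition max; take the species
    max over all of them; normalize; combine; score.
    """
    all_chips = [ch for chips in inputs.affymetrix.values() for ch in chips]
    if all_chips and not all(ch.norm_frac_rank for ch in all_chips):
        normalize_affy_chips(all_chips)

    # per (condition, data type): gene -> pre-normalization rank, plus max
    per_cond: dict[Condition, dict[DataType, tuple[dict[str, float], float]]] = {}

    def put(cond, dtype, gene_ranks):
        if gene_ranks:
            per_cond.setdefault(cond, {})[dtype] = (gene_ranks, max(gene_ranks.values()))

    for cond, libs in inputs.rnaseq.items():
        genes = {g for lr in libs for g in lr.frac_rank}
        put(cond, DataType.RNASEQ, {g: rnaseq_condition_rank(libs, g) for g in sorted(genes)})
    for cond, chips in inputs.affymetrix.items():
        genes = {g for ch in chips for g in ch.norm_frac_rank}
        put(cond, DataType.AFFYMETRIX, {g: affy_condition_rank(chips, g) for g in sorted(genes)})
    for cond, calls in inputs.insitu.items():
        ranks, _ = insitu_condition_rank(calls)
        put(cond, DataType.INSITU, {g: float(r) for g, r in ranks.items()})
    for cond, libs in inputs.est.items():
        ranks, _ = est_condition_rank(libs)
        put(cond, DataType.EST, {g: float(r) for g, r in ranks.items()})

    if not per_cond:
        return []
    species_max = max(m for dts in per_cond.values() for _, m in dts.values())

    # per data type, the weight of a gene-condition entry
    def weight(cond, dtype, gene) -> float:
        if dtype == DataType.RNASEQ:
            return float(
                sum(
                    lr.distinct_rank_count
                    for lr in inputs.rnaseq[cond]
                    if gene in lr.frac_rank
                )
            )
        if dtype == DataType.AFFYMETRIX:
            return float(
                sum(
                    ch.distinct_rank_count
                    for ch in inputs.affymetrix[cond]
                    if gene in ch.norm_frac_rank
                )
            )
        # in situ / EST: the condition's max dense rank
        return per_cond[cond][dtype][1]

    out: list[GlobalRank] = []
    for cond in sorted(per_cond, key=lambda c: (c.anat_id, c.stage_id, c.sex, c.strain)):
        dts = per_cond[cond]
        genes = sorted({g for gene_ranks, _ in dts.values() for g in gene_ranks})
        for gene in genes:
            wr: dict[DataType, tuple[float, float]] = {}
            for dtype, (gene_ranks, cond_max) in dts.items():
                if gene in gene_ranks:
                    norm = normalize_datatype_rank(gene_ranks[gene], cond_max, species_max)
                    wr[dtype] = (weight(cond, dtype, gene), norm)
            mean = global_mean_rank(list(wr.values()))
            out.append(
                GlobalRank(
                    gene=gene,
                    condition=cond,
                    weight_rnaseq=wr.get(DataType.RNASEQ, (0.0, 0.0))[0],
                    norm_rank_rnaseq=wr.get(DataType.RNASEQ, (0.0, 0.0))[1],
                    weight_affy=wr.get(DataType.AFFYMETRIX, (0.0, 0.0))[0],
                    norm_rank_affy=wr.get(DataType.AFFYMETRIX, (0.0, 0.0))[1],
                    weight_insitu=wr.get(DataType.INSITU, (0.0, 0.0))[0],
                    norm_rank_insitu=wr.get(DataType.INSITU, (0.0, 0.0))[1],
                    weight_est=wr.get(DataType.EST, (0.0, 0.0))[0],
                    norm_rank_est=wr.get(DataType.EST, (0.0, 0.0))[1],
                    mean_norm_rank=mean,
                    expression_score=expression_score(mean, species_max),
                )
            )
    return out
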