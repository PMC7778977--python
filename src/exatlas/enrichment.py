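"""Anatomical enrichment of a gene list over propagated presence calls.

Genes are associated to anatomical terms through their global present calls
(the association is upward-closed because presence propagates to ancestor
structures).  A gene list is tested per term with the hypergeometric upper
tail, exactly as Gene Ontology term enrichment — with an optional *elim*
decorrelation pass: terms are visited leaves-to-roots, and the foreground
genes of any term found significant are removed from its ancestors' gene
sets before those are tested, so broad top-level terms do not merely echo a
signal concentrated in one sub-structure.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .integrate import CONFIDENCE_ORDER, GlobalCall, PRESENT
from .ontology import AnatomyDAG


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    fg_count: int
    fg_size: int
    bg_count: int
    bg_size: int
    p_value: float
    fold_enrichment: float
    method: str  # classic | elim
    fdr: float = float("nan")


def build_gene2anat(
    global_calls: list[GlobalCall], min_confidence: str = "bronze"
) -> dict[str, set[str]]:
    """Anatomical term -> genes with a global present call of at least the
    given confidence in any condition with that term."""
    floor = CONFIDENCE_ORDER[min_confidence]
    out: dict[str, set[str]] = {}
    for gc in global_calls:
        if gc.state == PRESENT and CONFIDENCE_ORDER[gc.confidence] >= floor:
            out.setdefault(gc.condition.anat_id, set()).add(gc.gene)
    return out


def hypergeom_upper_tail(fg_count: int, fg_size: int, bg_count: int, bg_size: int) -> float:
    """P(X >= fg_count) for X ~ Hypergeom(bg_size, bg_count, fg_size)."""
    return float(stats.hypergeom.sf(fg_count - 1, bg_size, bg_count, fg_size))


def _check_sets(foreground: set[str], background: set[str]) -> None:
    if not foreground <= background:
        extra = sorted(foreground - background)[:5]
        raise ValueError(f"foreground genes not in background: {extra}")
    if not background:
        raise ValueError("background gene set is empty")


def _one_term(term, term_genes, foreground, background, method) -> EnrichmentResult:
    fg_size, bg_size = len(foreground), len(background)
    bg_count = len(term_genes & background)
    fg_count = len(term_genes & foreground)
    p = hypergeom_upper_tail(fg_count, fg_size, bg_count, bg_size)
    fold = (
        (fg_count / fg_size) / (bg_count / bg_size) if fg_count and bg_count else 0.0
    )
    return EnrichmentResult(term, fg_count, fg_size, bg_count, bg_size, p, fold, method)


def _with_fdr(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    if not results:
        return results
    _, fdr, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
    return [
        EnrichmentResult(
            r.term, r.fg_count, r.fg_size, r.bg_count, r.bg_size, r.p_value,
            r.fold_enrichment, r.method, fdr=float(q),
        )
        for r, q in zip(results, fdr)
    ]


def topanat_classic(
    foreground: set[str], background: set[str], gene2anat: dict[str, set[str]]
) -> list[EnrichmentResult]:
    """Independent per-term hypergeometric upper-tail test, BH-adjusted."""
    _check_sets(foreground, background)
    results = [
        _one_term(term, gene2anat[term], foreground, background, "classic")
        for term in sorted(gene2anat)
    ]
    return _with_fdr(results)


def topanat_elim(
    foreground: set[str],
    background: set[str],
    gene2anat: dict[str, set[str]],
    dag: AnatomyDAG,
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """elim decorrelation: process terms by level, deepest first; when a
    term's p-value falls below alpha, remove its foreground genes from all
    strict ancestors before they are tested. Ties in level are processed in
    term-id order for reproducibility."""
    _check_sets(foreground, background)
    depths = dag.depths()
    sets = {term: set(genes) for term, genes in gene2anat.items()}
    order = sorted(sets, key=lambda t: (-depths.get(t, 0), t))
    results = []
    for term in order:
        res = _one_term(term, sets[term], foreground, background, "elim")
        results.append(res)
        if res.p_value < alpha:
            eliminated = gene2anat[term] & foreground
            for anc in dag.ancestors(term):
                if anc in sets:
                    sets[anc] -= eliminated
    results.sort(key=lambda r: r.term)
    return _with_fdr(results)
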