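"""End-to-end orchestration: dataset directory -> calls -> global calls -> ranks.

Thin glue over the library modules, shared by the command-line interface and
by scripted analyses.  Each stage logs one structured line with its row
counts to standard error.
"""

from __future__ import annotations

import logging
import os
from dataclasses import replace

from . import io_tsv
from .calls import (
    AssayCall,
    affy_gene_calls,
    call_affy_cel,
    call_affy_mas5,
    call_est,
    call_insitu,
    call_rnaseq,
    filter_never_present,
)
from .integrate import GlobalCall, integrate_calls
from .ontology import ConditionGraph, load_obo_subset
from .ranks import (
    ChipRanking,
    GlobalRank,
    LibraryRanking,
    RankInputs,
    compute_global_ranks,
    normalize_affy_chips,
)
from .simulate import SyntheticDataset

logger = logging.getLogger("exatlas")


def write_dataset(ds: SyntheticDataset, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    io_tsv.write_obo(ds.anatomy, os.path.join(outdir, "anatomy.obo"))
    io_tsv.write_obo(ds.stages, os.path.join(outdir, "stages.obo"))
    io_tsv.write_rnaseq_tsv(ds.rnaseq, outdir)
    io_tsv.write_affymetrix_tsv(ds.affymetrix, outdir, ds.background_probesets)
    io_tsv.write_est_tsv(ds.est, outdir)
    io_tsv.write_insitu_tsv(ds.insitu, outdir)
    logger.info(
        "stage=simulate out=%s rnaseq_libs=%d chips=%d est_libs=%d insitu_spots=%d",
        outdir, len(ds.rnaseq), len(ds.affymetrix), len(ds.est), len(ds.insitu),
    )


def load_condition_graph(datadir: str) -> ConditionGraph:
    anatomy = load_obo_subset(os.path.join(datadir, "anatomy.obo"), "anatomy")
    stages = load_obo_subset(os.path.join(datadir, "stages.obo"), "stage")
    return ConditionGraph(anatomy, stages)


def run_calls(datadir: str, cfg: dict, data_types: list[str] | None = None) -> list[AssayCall]:
    """Produce per-assay calls for every data type with input tables in
    *datadir* (restricted to *data_types* when given)."""
    wanted = set(data_types or ["rnaseq", "affymetrix", "est", "insitu"])
    calls: list[AssayCall] = []
    if "rnaseq" in wanted and os.path.exists(os.path.join(datadir, "rnaseq_tpm.tsv")):
        libs = io_tsv.read_rnaseq_tsv(datadir)
        for lib in libs:
            calls.extend(call_rnaseq(lib, alpha=cfg["rnaseq_alpha"]))
        logger.info("stage=calls data_type=rnaseq libraries=%d calls=%d", len(libs), len(calls))
    if "affymetrix" in wanted and os.path.exists(os.path.join(datadir, "affy_conditions.tsv")):
        chips, background = io_tsv.read_affymetrix_tsv(datadir)
        probeset_calls = []
        for chip in chips:
            if chip.mode == "cel_signal":
                probeset_calls.extend(call_affy_cel(chip, background))
            else:
                probeset_calls.extend(call_affy_mas5(chip))
        excluded = filter_never_present(probeset_calls)
        gene_calls = affy_gene_calls(probeset_calls, excluded)
        calls.extend(gene_calls)
        logger.info(
            "stage=calls data_type=affymetrix chips=%d probeset_calls=%d excluded_probesets=%d calls=%d",
            len(chips), len(probeset_calls), len(excluded), len(gene_calls),
        )
    if "est" in wanted and os.path.exists(os.path.join(datadir, "est_counts.tsv")):
        libs = io_tsv.read_est_tsv(datadir)
        n0 = len(calls)
        for lib in libs:
            calls.extend(call_est(lib))
        logger.info("stage=calls data_type=est libraries=%d calls=%d", len(libs), len(calls) - n0)
    if "insitu" in wanted and os.path.exists(os.path.join(datadir, "insitu_spots.tsv")):
        spots = io_tsv.read_insitu_tsv(datadir)
        calls.extend(call_insitu(spots))
        logger.info("stage=calls data_type=insitu spots=%d", len(spots))
    return calls


def run_integrate(calls: list[AssayCall], graph: ConditionGraph) -> list[GlobalCall]:
    global_calls = integrate_calls(calls, graph)
    logger.info("stage=integrate assay_calls=%d global_calls=%d", len(calls), len(global_calls))
    return global_calls


def run_rank(datadir: str, cfg: dict, graph: ConditionGraph | None = None) -> list[GlobalRank]:
    """Rank genes per condition from the raw assay tables in *datadir*.

    Conditions are stage-generalized first so ranks land at the same
    conditions as the integrated calls.
    """
    if graph is None:
        graph = load_condition_graph(datadir)

    def gen(cond):
        stage = graph.stages.generalize(cond.stage_id)
        return cond if stage == cond.stage_id else replace(cond, stage_id=stage)

    inputs = RankInputs()
    if os.path.exists(os.path.join(datadir, "rnaseq_tpm.tsv")):
        for lib in io_tsv.read_rnaseq_tsv(datadir):
            lr = LibraryRanking.from_values(lib.library_id, gen(lib.condition), lib.gene_tpm)
            inputs.rnaseq.setdefault(lr.condition, []).append(lr)
    if os.path.exists(os.path.join(datadir, "affy_conditions.tsv")):
        chips, _ = io_tsv.read_affymetrix_tsv(datadir)
        chip_rankings = []
        for chip in chips:
            if chip.mode != "cel_signal":
                continue  # MAS5 files carry flags, not signals; no rank
            cr = ChipRanking.from_signals(
                chip.chip_id, gen(chip.condition), chip.chip_type,
                chip.probeset_signal, chip.probeset_to_gene,
            )
            chip_rankings.append(cr)
            inputs.affymetrix.setdefault(cr.condition, []).append(cr)
        if chip_rankings:
            normalize_affy_chips(chip_rankings)
    if os.path.exists(os.path.join(datadir, "insitu_spots.tsv")):
        for call in call_insitu(io_tsv.read_insitu_tsv(datadir)):
            cond = gen(call.condition)
            if call.condition != cond:
                call = replace(call, condition=cond)
            inputs.insitu.setdefault(cond, []).append(call)
    if os.path.exists(os.path.join(datadir, "est_counts.tsv")):
        for lib in io_tsv.read_est_tsv(datadir):
            inputs.est.setdefault(gen(lib.condition), []).append(lib)
    ranks = compute_global_ranks(inputs)
    logger.info("stage=rank gene_condition_rows=%d", len(ranks))
    return ranks
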