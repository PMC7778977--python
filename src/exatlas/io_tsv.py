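"""Readers and writers for the engine's tab-separated interchange formats.

Every table is UTF-8, tab-delimited, with a mandatory header row.  Readers
validate the schema and name any missing column.  Conditions are carried in
a conditions.tsv keyed by assay id; call and rank tables mirror the layout
of public expression-call download files.
"""

from __future__ import annotations

import os

import pandas as pd

from .calls import (
    AffymetrixChip,
    AssayCall,
    DataType,
    EstLibrary,
    InSituSpot,
    RnaSeqLibrary,
)
from .integrate import GlobalCall, SupportCounts
from .ontology import AnatomyDAG, Condition, OntologyTerm, StageTree
from .ranks import GlobalRank

QUALITIES = {"gold", "silver", "bronze"}


class SchemaError(ValueError):
    pass


def _read_tsv(path: str, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- ontologies


def write_obo(ontology: AnatomyDAG | StageTree, path: str) -> None:
    """Serialize to the simplified OBO dialect the loader reads back."""
    lines = ["format-version: 1.2", "ontology: exatlas-fixture", ""]
    for tid in sorted(ontology.terms):
        t: OntologyTerm = ontology.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {t.id}")
        lines.append(f"name: {t.name}")
        for p in t.is_a_parents:
            lines.append(f"is_a: {p}")
        for p in t.part_of_parents:
            lines.append(f"relationship: part_of {p}")
        for p in t.preceded_by:
            lines.append(f"relationship: preceded_by {p}")
        for s in sorted(t.subsets):
            lines.append(f"subset: {s}")
        lines.append("")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines))


# ---------------------------------------------------------------- conditions

_COND_COLS = ["assay_id", "anat_id", "anat_name", "stage_id", "stage_name", "sex", "strain", "species_id"]


def write_conditions_tsv(conditions: dict[str, Condition], path: str, names=None) -> None:
    names = names or {}
    rows = [
        {
            "assay_id": aid,
            "anat_id": c.anat_id,
            "anat_name": names.get(c.anat_id, c.anat_id),
            "stage_id": c.stage_id,
            "stage_name": names.get(c.stage_id, c.stage_id),
            "sex": c.sex,
            "strain": c.strain,
            "species_id": c.species_id,
        }
        for aid, c in sorted(conditions.items())
    ]
    _write_tsv(pd.DataFrame(rows, columns=_COND_COLS), path)


def read_conditions_tsv(path: str) -> dict[str, Condition]:
    df = _read_tsv(path, _COND_COLS)
    return {
        r.assay_id: Condition(r.anat_id, r.stage_id, r.sex, r.strain, int(r.species_id))
        for r in df.itertuples()
    }


# ------------------------------------------------------------- assay tables


def write_rnaseq_tsv(libs: list[RnaSeqLibrary], outdir: str) -> None:
    tpm_rows, bg_rows, conds = [], [], {}
    for lib in libs:
        conds[lib.library_id] = lib.condition
        for g, v in sorted(lib.gene_tpm.items()):
            tpm_rows.append(
                {"library_id": lib.library_id, "experiment_id": lib.experiment_id, "gene_id": g, "tpm": v}
            )
        for i, v in enumerate(lib.intergenic_tpm):
            bg_rows.append({"library_id": lib.library_id, "region_id": f"ig_{i:05d}", "tpm": v})
    _write_tsv(pd.DataFrame(tpm_rows), os.path.join(outdir, "rnaseq_tpm.tsv"))
    _write_tsv(pd.DataFrame(bg_rows), os.path.join(outdir, "rnaseq_intergenic.tsv"))
    write_conditions_tsv(conds, os.path.join(outdir, "rnaseq_conditions.tsv"))


def read_rnaseq_tsv(datadir: str) -> list[RnaSeqLibrary]:
    tpm = _read_tsv(os.path.join(datadir, "rnaseq_tpm.tsv"), ["library_id", "experiment_id", "gene_id", "tpm"])
    bg = _read_tsv(os.path.join(datadir, "rnaseq_intergenic.tsv"), ["library_id", "region_id", "tpm"])
    conds = read_conditions_tsv(os.path.join(datadir, "rnaseq_conditions.tsv"))
    libs = []
    bg_by_lib = {k: g["tpm"].astype(float).tolist() for k, g in bg.groupby("library_id")}
    for (lib_id, exp_id), g in tpm.groupby(["library_id", "experiment_id"], sort=True):
        libs.append(
            RnaSeqLibrary(
                library_id=lib_id,
                experiment_id=exp_id,
                condition=conds[lib_id],
                gene_tpm=dict(zip(g["gene_id"], g["tpm"].astype(float))),
                intergenic_tpm=bg_by_lib.get(lib_id, []),
            )
        )
    return libs


def write_affymetrix_tsv(chips: list[AffymetrixChip], outdir: str, background: set[str] = frozenset()) -> None:
    sig_rows, mas5_rows, map_rows, conds = [], [], [], {}
    probeset_map_seen = set()
    for chip in chips:
        conds[chip.chip_id] = chip.condition
        if chip.mode == "cel_signal":
            for ps, signals in sorted(chip.probeset_signal.items()):
                for i, s in enumerate(signals):
                    sig_rows.append(
                        {
                            "chip_id": chip.chip_id,
                            "experiment_id": chip.experiment_id,
                            "chip_type": chip.chip_type,
                            "probeset_id": ps,
                            "probe_index": i,
                            "signal": s,
                        }
                    )
        else:
            for ps, flag in sorted(chip.mas5_flag.items()):
                mas5_rows.append(
                    {
                        "chip_id": chip.chip_id,
                        "experiment_id": chip.experiment_id,
                        "chip_type": chip.chip_type,
                        "probeset_id": ps,
                        "flag": flag,
                    }
                )
        for ps, g in sorted((chip.probeset_to_gene or {}).items()):
            if ps not in probeset_map_seen:
                probeset_map_seen.add(ps)
                map_rows.append({"probeset_id": ps, "gene_id": g})
    _write_tsv(
        pd.DataFrame(sig_rows, columns=["chip_id", "experiment_id", "chip_type", "probeset_id", "probe_index", "signal"]),
        os.path.join(outdir, "affy_signal.tsv"),
    )
    _write_tsv(
        pd.DataFrame(mas5_rows, columns=["chip_id", "experiment_id", "chip_type", "probeset_id", "flag"]),
        os.path.join(outdir, "affy_mas5.tsv"),
    )
    _write_tsv(pd.DataFrame(map_rows, columns=["probeset_id", "gene_id"]), os.path.join(outdir, "probeset_map.tsv"))
    _write_tsv(
        pd.DataFrame({"probeset_id": sorted(background)}), os.path.join(outdir, "affy_background_probesets.tsv")
    )
    write_conditions_tsv(conds, os.path.join(outdir, "affy_conditions.tsv"))


def read_affymetrix_tsv(datadir: str) -> tuple[list[AffymetrixChip], set[str]]:
    conds = read_conditions_tsv(os.path.join(datadir, "affy_conditions.tsv"))
    pmap_df = _read_tsv(os.path.join(datadir, "probeset_map.tsv"), ["probeset_id", "gene_id"])
    pmap = dict(zip(pmap_df["probeset_id"], pmap_df["gene_id"]))
    chips = []
    sig_path = os.path.join(datadir, "affy_signal.tsv")
    if os.path.exists(sig_path):
        sig = _read_tsv(sig_path, ["chip_id", "experiment_id", "chip_type", "probeset_id", "probe_index", "signal"])
        for (chip_id, exp_id, chip_type), g in sig.groupby(["chip_id", "experiment_id", "chip_type"], sort=True):
            signal = {
                ps: grp.sort_values("probe_index", key=lambda s: s.astype(int))["signal"].astype(float).tolist()
                for ps, grp in g.groupby("probeset_id")
            }
            chips.append(
                AffymetrixChip(chip_id, exp_id, chip_type, conds[chip_id], "cel_signal",
                               probeset_signal=signal, probeset_to_gene=pmap)
            )
    mas5_path = os.path.join(datadir, "affy_mas5.tsv")
    if os.path.exists(mas5_path):
        mas5 = _read_tsv(mas5_path, ["chip_id", "experiment_id", "chip_type", "probeset_id", "flag"])
        for (chip_id, exp_id, chip_type), g in mas5.groupby(["chip_id", "experiment_id", "chip_type"], sort=True):
            chips.append(
                AffymetrixChip(chip_id, exp_id, chip_type, conds[chip_id], "mas5_flags",
                               mas5_flag=dict(zip(g["probeset_id"], g["flag"])), probeset_to_gene=pmap)
            )
    bg_path = os.path.join(datadir, "affy_background_probesets.tsv")
    background: set[str] = set()
    if os.path.exists(bg_path):
        background = set(_read_tsv(bg_path, ["probeset_id"])["probeset_id"])
    return chips, background


def write_est_tsv(libs: list[EstLibrary], outdir: str) -> None:
    rows, conds = [], {}
    for lib in libs:
        conds[lib.library_id] = lib.condition
        for g, c in sorted(lib.gene_est_count.items()):
            rows.append({"library_id": lib.library_id, "gene_id": g, "est_count": c})
    _write_tsv(pd.DataFrame(rows, columns=["library_id", "gene_id", "est_count"]), os.path.join(outdir, "est_counts.tsv"))
    write_conditions_tsv(conds, os.path.join(outdir, "est_conditions.tsv"))


def read_est_tsv(datadir: str) -> list[EstLibrary]:
    df = _read_tsv(os.path.join(datadir, "est_counts.tsv"), ["library_id", "gene_id", "est_count"])
    conds = read_conditions_tsv(os.path.join(datadir, "est_conditions.tsv"))
    return [
        EstLibrary(lib_id, conds[lib_id], dict(zip(g["gene_id"], g["est_count"].astype(int))))
        for lib_id, g in df.groupby("library_id", sort=True)
    ]


def write_insitu_tsv(spots: list[InSituSpot], outdir: str) -> None:
    rows, conds = [], {}
    for s in spots:
        conds[s.evidence_id] = s.condition
        rows.append(
            {
                "evidence_id": s.evidence_id,
                "experiment_id": s.experiment_id,
                "gene_id": s.gene,
                "detected": "yes" if s.detected else "no",
                "quality": s.quality,
            }
        )
    _write_tsv(
        pd.DataFrame(rows, columns=["evidence_id", "experiment_id", "gene_id", "detected", "quality"]),
        os.path.join(outdir, "insitu_spots.tsv"),
    )
    write_conditions_tsv(conds, os.path.join(outdir, "insitu_conditions.tsv"))


def read_insitu_tsv(datadir: str) -> list[InSituSpot]:
    df = _read_tsv(os.path.join(datadir, "insitu_spots.tsv"), ["evidence_id", "experiment_id", "gene_id", "detected", "quality"])
    conds = read_conditions_tsv(os.path.join(datadir, "insitu_conditions.tsv"))
    return [
        InSituSpot(r.evidence_id, r.experiment_id, r.gene_id, conds[r.evidence_id], r.detected == "yes", r.quality)
        for r in df.itertuples()
    ]


# -------------------------------------------------------------- assay calls

_ASSAY_CALL_COLS = [
    "gene_id", "anat_id", "stage_id", "sex", "strain", "species_id",
    "state", "quality", "data_type", "experiment_id", "assay_id",
]


def write_assay_calls_tsv(calls: list[AssayCall], path: str) -> None:
    rows = [
        {
            "gene_id": c.gene,
            "anat_id": c.condition.anat_id,
            "stage_id": c.condition.stage_id,
            "sex": c.condition.sex,
            "strain": c.condition.strain,
            "species_id": c.condition.species_id,
            "state": c.state,
            "quality": c.quality,
            "data_type": c.data_type.value,
            "experiment_id": c.experiment_id,
            "assay_id": c.assay_id,
        }
        for c in calls
    ]
    _write_tsv(pd.DataFrame(rows, columns=_ASSAY_CALL_COLS), path)


def read_assay_calls_tsv(path: str) -> list[AssayCall]:
    df = _read_tsv(path, _ASSAY_CALL_COLS)
    return [
        AssayCall(
            gene=r.gene_id,
            condition=Condition(r.anat_id, r.stage_id, r.sex, r.strain, int(r.species_id)),
            state=r.state,
            quality=r.quality,
            data_type=DataType(r.data_type),
            experiment_id=r.experiment_id,
            assay_id=r.assay_id,
        )
        for r in df.itertuples()
    ]


# ------------------------------------------------------------- global calls

_SUPPORT_COLS = [
    f"{dt.value}_{state}_exp_count" for dt in DataType for state in ("presence", "absence")
]
_GLOBAL_CALL_COLS = [
    "gene_id", "anat_id", "anat_name", "stage_id", "stage_name", "sex", "strain",
    "species_id", "expression", "call_quality", "observed", *_SUPPORT_COLS,
]


def write_call_tsv(calls: list[GlobalCall], path: str, names=None) -> None:
    names = names or {}
    rows = []
    for gc in calls:
        row = {
            "gene_id": gc.gene,
            "anat_id": gc.condition.anat_id,
            "anat_name": names.get(gc.condition.anat_id, gc.condition.anat_id),
            "stage_id": gc.condition.stage_id,
            "stage_name": names.get(gc.condition.stage_id, gc.condition.stage_id),
            "sex": gc.condition.sex,
            "strain": gc.condition.strain,
            "species_id": gc.condition.species_id,
            "expression": gc.state,
            "call_quality": gc.confidence,
            "observed": "yes" if gc.observed else "no",
        }
        for dt in DataType:
            row[f"{dt.value}_presence_exp_count"] = gc.support.presence.get(dt, 0)
            row[f"{dt.value}_absence_exp_count"] = gc.support.absence.get(dt, 0)
        rows.append(row)
    _write_tsv(pd.DataFrame(rows, columns=_GLOBAL_CALL_COLS), path)


def read_call_tsv(path: str) -> list[GlobalCall]:
    df = _read_tsv(path, _GLOBAL_CALL_COLS)
    out = []
    for r in df.itertuples():
        if r.call_quality not in QUALITIES:
            raise SchemaError(f"{path}: invalid call_quality {r.call_quality!r}")
        presence = {dt: int(getattr(r, f"{dt.value}_presence_exp_count")) for dt in DataType}
        absence = {dt: int(getattr(r, f"{dt.value}_absence_exp_count")) for dt in DataType}
        out.append(
            GlobalCall(
                gene=r.gene_id,
                condition=Condition(r.anat_id, r.stage_id, r.sex, r.strain, int(r.species_id)),
                state=r.expression,
                confidence=r.call_quality,
                support=SupportCounts(
                    presence={dt: n for dt, n in presence.items() if n},
                    absence={dt: n for dt, n in absence.items() if n},
                ),
                observed=r.observed == "yes",
            )
        )
    return out


# -------------------------------------------------------------------- ranks

_RANK_COLS = [
    "gene_id", "anat_id", "stage_id", "sex", "strain", "species_id", "rank", "expression_score",
    "rnaseq_weight", "rnaseq_norm_rank", "affymetrix_weight", "affymetrix_norm_rank",
    "insitu_weight", "insitu_norm_rank", "est_weight", "est_norm_rank",
]


def write_rank_tsv(ranks: list[GlobalRank], path: str) -> None:
    rows = [
        {
            "gene_id": g.gene,
            "anat_id": g.condition.anat_id,
            "stage_id": g.condition.stage_id,
            "sex": g.condition.sex,
            "strain": g.condition.strain,
            "species_id": g.condition.species_id,
            "rank": repr(g.mean_norm_rank),
            "expression_score": round(g.expression_score, 2),
            "rnaseq_weight": g.weight_rnaseq,
            "rnaseq_norm_rank": repr(g.norm_rank_rnaseq),
            "affymetrix_weight": g.weight_affy,
            "affymetrix_norm_rank": repr(g.norm_rank_affy),
            "insitu_weight": g.weight_insitu,
            "insitu_norm_rank": repr(g.norm_rank_insitu),
            "est_weight": g.weight_est,
            "est_norm_rank": repr(g.norm_rank_est),
        }
        for g in ranks
    ]
    _write_tsv(pd.DataFrame(rows, columns=_RANK_COLS), path)


def read_rank_tsv(path: str) -> list[GlobalRank]:
    df = _read_tsv(path, _RANK_COLS)
    out = []
    for r in df.itertuples():
        mean = float(r.rank)
        out.append(
            GlobalRank(
                gene=r.gene_id,
                condition=Condition(r.anat_id, r.stage_id, r.sex, r.strain, int(r.species_id)),
                weight_rnaseq=float(r.rnaseq_weight),
                norm_rank_rnaseq=float(r.rnaseq_norm_rank),
                weight_affy=float(r.affymetrix_weight),
                norm_rank_affy=float(r.affymetrix_norm_rank),
                weight_insitu=float(r.insitu_weight),
                norm_rank_insitu=float(r.insitu_norm_rank),
                weight_est=float(r.est_weight),
                norm_rank_est=float(r.est_norm_rank),
                mean_norm_rank=mean,
                expression_score=float(r.expression_score),
            )
        )
    return out
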