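"""Per-assay presence/absence expression calls.

Four data types produce calls:

* RNA-seq — a gene is present in a library when its TPM exceeds the
  empirical (1 - alpha) quantile of the library's intergenic-region TPMs
  (the background level of read mapping); all RNA-seq calls are high quality.
* Affymetrix — from MAS5 flags (always low quality) or, preferably, from
  normalized CEL signals via a one-sided Wilcoxon rank-sum test of each
  probeset against a pooled background probeset set; probesets never seen
  present (MAS5 'present' or CEL high-quality present) anywhere in the
  dataset are excluded, and surviving probesets are reconciled to one call
  per gene per chip by keeping the best call.
* EST — at least 7 tags mapped to a gene: present/high; 1-6: present/low;
  no absent calls (sampling too shallow).
* in situ hybridization — each annotated spot maps directly to one call.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .ontology import Condition

logger = logging.getLogger(__name__)

PRESENT = "present"
ABSENT = "absent"
HIGH = "high"
LOW = "low"

#: Wilcoxon p-value bounds for CEL-based Affymetrix detection.
AFFY_P_PRESENT_HIGH = 0.03
AFFY_P_PRESENT_LOW = 0.12

#: EST count giving a high-quality present call.
EST_HIGH_MIN = 7
#: Smallest EST count giving any (low-quality) present call.
EST_LOW_MIN = 1


class DataType(str, Enum):
    RNASEQ = "rnaseq"
    AFFYMETRIX = "affymetrix"
    EST = "est"
    INSITU = "insitu"


@dataclass(frozen=True)
class AssayCall:
    gene: str
    condition: Condition
    state: str  # present | absent
    quality: str  # high | low
    data_type: DataType
    experiment_id: str
    assay_id: str

    def __post_init__(self):
        if self.data_type == DataType.EST and self.state == ABSENT:
            raise ValueError("EST data never produce absent calls")


@dataclass(frozen=True)
class ProbesetCall:
    """Probeset-level Affymetrix call, before gene reconciliation."""

    probeset: str
    gene: str
    chip_id: str
    experiment_id: str
    condition: Condition
    state: str
    quality: str
    mas5_flag: str | None = None  # raw flag when the call came from MAS5


@dataclass
class RnaSeqLibrary:
    library_id: str
    experiment_id: str
    condition: Condition
    gene_tpm: dict[str, float]
    intergenic_tpm: list[float]


@dataclass
class AffymetrixChip:
    chip_id: str
    experiment_id: str
    chip_type: str
    condition: Condition
    mode: str  # cel_signal | mas5_flags
    probeset_signal: dict[str, list[float]] | None = None
    mas5_flag: dict[str, str] | None = None
    probeset_to_gene: dict[str, str] | None = None

    def __post_init__(self):
        if self.mode == "cel_signal" and (self.probeset_signal is None or self.mas5_flag):
            raise ValueError("cel_signal mode requires probeset_signal only")
        if self.mode == "mas5_flags" and (self.mas5_flag is None or self.probeset_signal):
            raise ValueError("mas5_flags mode requires mas5_flag only")


@dataclass
class EstLibrary:
    library_id: str
    condition: Condition
    gene_est_count: dict[str, int]


@dataclass(frozen=True)
class InSituSpot:
    evidence_id: str
    experiment_id: str
    gene: str
    condition: Condition
    detected: bool
    quality: str


def rnaseq_threshold(intergenic_tpm, alpha: float = 0.05) -> float:
    """Empirical (1 - alpha) quantile of the intergenic TPM distribution
    (linear interpolation), used as the per-library background level."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    arr = np.asarray(list(intergenic_tpm), dtype=float)
    if arr.size == 0:
        raise ValueError("intergenic TPM set is empty; cannot estimate background")
    return float(np.quantile(arr, 1.0 - alpha))


def call_rnaseq(lib: RnaSeqLibrary, alpha: float = 0.05) -> list[AssayCall]:
    """One call per gene: present iff TPM strictly exceeds the background
    threshold. All RNA-seq calls are high quality."""
    t = rnaseq_threshold(lib.intergenic_tpm, alpha)
    return [
        AssayCall(
            gene=g,
            condition=lib.condition,
            state=PRESENT if tpm > t else ABSENT,
            quality=HIGH,
            data_type=DataType.RNASEQ,
            experiment_id=lib.experiment_id,
            assay_id=lib.library_id,
        )
        for g, tpm in sorted(lib.gene_tpm.items())
    ]


_MAS5_MAP = {"present": (PRESENT, LOW), "marginal": (PRESENT, LOW), "absent": (ABSENT, LOW)}


def call_affy_mas5(chip: AffymetrixChip) -> list[ProbesetCall]:
    """MAS5 'present'/'marginal' -> present/low; 'absent' -> absent/low."""
    if chip.mode != "mas5_flags":
        raise ValueError("chip is not in mas5_flags mode")
    out = []
    for ps, flag in sorted(chip.mas5_flag.items()):
        if flag not in _MAS5_MAP:
            raise ValueError(f"unknown MAS5 flag {flag!r} on probeset {ps!r}")
        state, quality = _MAS5_MAP[flag]
        out.append(
            ProbesetCall(
                probeset=ps,
                gene=chip.probeset_to_gene.get(ps, ""),
                chip_id=chip.chip_id,
                experiment_id=chip.experiment_id,
                condition=chip.condition,
                state=state,
                quality=quality,
                mas5_flag=flag,
            )
        )
    return out


def wilcoxon_greater_p(sample, background) -> float:
    """One-sided rank-sum p-value for sample > background.

    Exact enumeration when both sides are small and tie-free; otherwise the
    normal approximation with continuity correction and midrank ties.
    """
    x = np.asarray(sample, dtype=float)
    y = np.asarray(background, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method, use_continuity=True)
    return float(res.pvalue)


def classify_affy_p(p: float) -> tuple[str, str]:
    if p < AFFY_P_PRESENT_HIGH:
        return PRESENT, HIGH
    if p <= AFFY_P_PRESENT_LOW:
        return PRESENT, LOW
    return ABSENT, HIGH


def call_affy_cel(
    chip: AffymetrixChip,
    background_probesets: set[str],
    p_value_fn=wilcoxon_greater_p,
) -> list[ProbesetCall]:
    """Wilcoxon test of each probeset's probe-level signals against the
    pooled background probesets' signals."""
    if chip.mode != "cel_signal":
        raise ValueError("chip is not in cel_signal mode")
    if not background_probesets:
        raise ValueError("background probeset set is empty")
    missing = background_probesets - set(chip.probeset_signal)
    if missing:
        raise ValueError(f"background probesets not on chip: {sorted(missing)[:5]}")
    background = [s for ps in sorted(background_probesets) for s in chip.probeset_signal[ps]]
    out = []
    for ps, signals in sorted(chip.probeset_signal.items()):
        if ps in background_probesets:
            continue
        if len(signals) < 1:
            warnings.warn(f"probeset {ps!r} has no probe signals; skipped", stacklevel=2)
            continue
        state, quality = classify_affy_p(p_value_fn(signals, background))
        out.append(
            ProbesetCall(
                probeset=ps,
                gene=chip.probeset_to_gene.get(ps, ""),
                chip_id=chip.chip_id,
                experiment_id=chip.experiment_id,
                condition=chip.condition,
                state=state,
                quality=quality,
            )
        )
    return out


def filter_never_present(all_probeset_calls) -> set[str]:
    """Probesets to exclude: never MAS5-flagged 'present' and never given a
    CEL high-quality present call anywhere in the dataset.

    A MAS5 'marginal' flag and a CEL low-quality present do not rescue a
    probeset.
    """
    seen: set[str] = set()
    reliable: set[str] = set()
    for call in all_probeset_calls:
        seen.add(call.probeset)
        if call.mas5_flag == "present":
            reliable.add(call.probeset)
        elif call.mas5_flag is None and call.state == PRESENT and call.quality == HIGH:
            reliable.add(call.probeset)
    return seen - reliable


#: best-first total order used for probeset -> gene reconciliation
_CALL_ORDER = {(PRESENT, HIGH): 0, (PRESENT, LOW): 1, (ABSENT, HIGH): 2, (ABSENT, LOW): 3}


def reconcile_probesets_to_gene(calls: list[ProbesetCall]) -> AssayCall | None:
    """Best surviving probeset call for one gene on one chip, ordered
    present/high > present/low > absent/high > absent/low."""
    if not calls:
        return None
    best = min(calls, key=lambda c: (_CALL_ORDER[(c.state, c.quality)], c.probeset))
    return AssayCall(
        gene=best.gene,
        condition=best.condition,
        state=best.state,
        quality=best.quality,
        data_type=DataType.AFFYMETRIX,
        experiment_id=best.experiment_id,
        assay_id=best.chip_id,
    )


def affy_gene_calls(probeset_calls: list[ProbesetCall], excluded: set[str]) -> list[AssayCall]:
    """Drop excluded probesets, then reconcile per (chip, gene). Genes whose
    probesets are all excluded yield no call at all (not an absent call)."""
    by_gene_chip: dict[tuple[str, str], list[ProbesetCall]] = {}
    for c in probeset_calls:
        if c.probeset in excluded:
            continue
        by_gene_chip.setdefault((c.chip_id, c.gene), []).append(c)
    out = []
    for key in sorted(by_gene_chip):
        call = reconcile_probesets_to_gene(by_gene_chip[key])
        if call is not None:
            out.append(call)
    return out


def call_est(lib: EstLibrary) -> list[AssayCall]:
    out = []
    for gene, count in sorted(lib.gene_est_count.items()):
        if count < 0:
            raise ValueError(f"negative EST count for gene {gene!r}")
        if count == 0:
            continue
        quality = HIGH if count >= EST_HIGH_MIN else LOW
        out.append(
            AssayCall(
                gene=gene,
                condition=lib.condition,
                state=PRESENT,
                quality=quality,
                data_type=DataType.EST,
                experiment_id=lib.library_id,
                assay_id=lib.library_id,
            )
        )
    return out


def call_insitu(spots: list[InSituSpot]) -> list[AssayCall]:
    return [
        AssayCall(
            gene=s.gene,
            condition=s.condition,
            state=PRESENT if s.detected else ABSENT,
            quality=s.quality,
            data_type=DataType.INSITU,
            experiment_id=s.experiment_id,
            assay_id=s.evidence_id,
        )
        for s in spots
    ]
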