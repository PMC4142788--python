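"""Phenotype derivation from raw behavioral records.

Two phenotypes drive the lesion-symptom analyses:

* **Apraxia of speech (AOS)** — from four binary abnormality flags on the
  Apraxia Battery for Adults subtests (Words of Increasing Length A and B,
  Repeated Trials, Inventory of Articulation). Three or four abnormal
  subtests classify a patient as AOS; zero or one as no-AOS; exactly two is
  indeterminate and excluded from AOS analyses.
* **Verbal short-term memory** — forward digit span, two trials per list
  length starting at two items, testing terminated at the first length with
  both trials failed. The span is the longest length with at least one
  correct trial; a span below 5 flags impairment.

A Western Aphasia Battery AQ below 93.8 additionally flags aphasia.

How "abnormal" is decided for each subtest (clinician consensus on speech
samples) is upstream of this package; the flags are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import pandas as pd

AOS_STATUS = Literal["AOS", "no_AOS", "indeterminate"]

#: WAB-R AQ below this value defines aphasia.
APHASIA_AQ_CUTOFF = 93.8

#: Forward digit span below this value defines impaired verbal STM.
SPAN_IMPAIRMENT_CUTOFF = 5

ABA_COLUMNS = ("aba_wil_a", "aba_wil_b", "aba_repeated", "aba_inventory")


@dataclass
class BehaviorRecord:
    """Raw per-patient behavioral data.

    ``span_trials`` is an ordered list of ``(list_length, trial1_correct,
    trial2_correct)`` with lengths starting at 2 and increasing by 1 without
    gaps. Trials recorded after the first length at which both trials failed
    are ignored (the protocol stops there). An empty list means the span
    task was not administered.
    """

    patient_id: str
    aba_flags: tuple[int, int, int, int]
    span_trials: list[tuple[int, int, int]] = field(default_factory=list)
    aphasia_aq: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.aba_flags) != 4:
            raise ValueError(
                f"patient {self.patient_id}: expected exactly 4 ABA flags, "
                f"got {len(self.aba_flags)}"
            )
        if any(f not in (0, 1) for f in self.aba_flags):
            raise ValueError(f"patient {self.patient_id}: ABA flags must be 0/1")
        _validate_trials(self.span_trials, self.patient_id)


def _validate_trials(trials: Sequence[tuple[int, int, int]], pid: str = "?") -> None:
    for i, (length, t1, t2) in enumerate(trials):
        if length != 2 + i:
            raise ValueError(
                f"patient {pid}: span list lengths must start at 2 and increase "
                f"by 1 without gaps; position {i} has length {length}"
            )
        if t1 not in (0, 1) or t2 not in (0, 1):
            raise ValueError(f"patient {pid}: trial outcomes must be 0/1")


@dataclass
class Phenotypes:
    """Derived per-patient phenotype assignments."""

    patient_id: str
    aos_status: AOS_STATUS
    digit_span: Optional[int]
    span_impaired: Optional[bool]
    aphasic: Optional[bool] = None

    @property
    def aos(self) -> Optional[bool]:
        """Binary AOS flag; ``None`` when indeterminate."""
        if self.aos_status == "indeterminate":
            return None
        return self.aos_status == "AOS"


def classify_aos(flags: Sequence[int]) -> AOS_STATUS:
    """Classify AOS status from the four subtest abnormality flags.

    The mapping depends only on the number of abnormal flags:
    0 or 1 -> ``no_AOS``; exactly 2 -> ``indeterminate``; 3 or 4 -> ``AOS``.
    """
    if len(flags) != 4:
        raise ValueError(f"expected exactly 4 flags, got {len(flags)}")
    if any(f not in (0, 1) for f in flags):
        raise ValueError("flags must be 0/1")
    n_abnormal = sum(flags)
    if n_abnormal >= 3:
        return "AOS"
    if n_abnormal == 2:
        return "indeterminate"
    return "no_AOS"


def score_digit_span(trials: Sequence[tuple[int, int, int]]) -> int:
    """Forward digit span from ordered two-trial records.

    The span is the maximum list length with at least one correct trial.
    Testing is considered terminated at the first length with both trials
    failed; any trials recorded beyond that point are ignored. Returns 0
    when no length was passed. Raises ``ValueError`` on an empty record
    (span undefined) or a gap in list lengths.
    """
    if len(trials) == 0:
        raise ValueError("no span trials recorded; span is undefined")
    _validate_trials(trials)
    span = 0
    for length, t1, t2 in trials:
        if t1 == 0 and t2 == 0:
            break
        span = length
    return span


def derive_phenotypes(
    records: Sequence[BehaviorRecord], aq_cutoff: float = APHASIA_AQ_CUTOFF
) -> list[Phenotypes]:
    """Derive AOS status, digit span, and impairment flags for a cohort.

    Patients without span trials get an undefined span (``None``) and are
    excluded from span analyses downstream rather than coerced to 0.
    Indeterminate-AOS patients are retained here; AOS analyses exclude them.
    Aphasia is ``aq < aq_cutoff`` (strict), ``None`` when AQ is missing.
    Derivation is deterministic and per-patient, so the output order simply
    follows the input order.
    """
    out: list[Phenotypes] = []
    for rec in records:
        status = classify_aos(rec.aba_flags)
        if rec.span_trials:
            span: Optional[int] = score_digit_span(rec.span_trials)
            impaired: Optional[bool] = span < SPAN_IMPAIRMENT_CUTOFF
        else:
            span = None
            impaired = None
        aphasic = None if rec.aphasia_aq is None else bool(rec.aphasia_aq < aq_cutoff)
        out.append(Phenotypes(rec.patient_id, status, span, impaired, aphasic))
    return out


# ---------------------------------------------------------------------------
# Tabular round trip (wide TSV: one row per patient, span_<L>_t1/t2 columns)
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[BehaviorRecord]) -> pd.DataFrame:
    """Serialize records to a wide table (one row per patient)."""
    max_len = max((len(r.span_trials) for r in records), default=0)
    rows = []
    for rec in records:
        row: dict = {"patient_id": rec.patient_id}
        for col, flag in zip(ABA_COLUMNS, rec.aba_flags):
            row[col] = flag
        row["wab_aq"] = rec.aphasia_aq
        for length, t1, t2 in rec.span_trials:
            row[f"span_{length}_t1"] = t1
            row[f"span_{length}_t2"] = t2
        rows.append(row)
    cols = ["patient_id", *ABA_COLUMNS, "wab_aq"]
    for i in range(max_len):
        cols += [f"span_{2 + i}_t1", f"span_{2 + i}_t2"]
    return pd.DataFrame(rows).reindex(columns=cols)


def frame_to_records(df: pd.DataFrame) -> list[BehaviorRecord]:
    """Parse a wide behavior table into records."""
    missing = [c for c in ("patient_id", *ABA_COLUMNS) if c not in df.columns]
    if missing:
        raise ValueError(f"behavior table missing columns: {missing}")
    span_lengths = sorted(
        int(c.split("_")[1]) for c in df.columns if c.startswith("span_") and c.endswith("_t1")
    )
    records = []
    for _, row in df.iterrows():
        trials = []
        for length in span_lengths:
            t1, t2 = row.get(f"span_{length}_t1"), row.get(f"span_{length}_t2")
            if pd.isna(t1) or pd.isna(t2):
                break
            trials.append((length, int(t1), int(t2)))
        aq = row.get("wab_aq")
        records.append(
            BehaviorRecord(
                patient_id=str(row["patient_id"]),
                aba_flags=tuple(int(row[c]) for c in ABA_COLUMNS),
                span_trials=trials,
                aphasia_aq=None if pd.isna(aq) else float(aq),
            )
        )
    return records


def read_behavior_table(path) -> list[BehaviorRecord]:
    """Read a tab-separated behavior table."""
    return frame_to_records(pd.read_csv(path, sep="\t"))


def write_behavior_table(records: Sequence[BehaviorRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def phenotypes_to_frame(phenotypes: Sequence[Phenotypes]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in phenotypes],
            "aos_status": [p.aos_status for p in phenotypes],
            "digit_span": [p.digit_span for p in phenotypes],
            "span_impaired": [p.span_impaired for p in phenotypes],
            "aphasic": [p.aphasic for p in phenotypes],
        }
    )
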