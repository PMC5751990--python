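"""Response labels and the 65-entry per-patient feature vector.

Patients are labeled complete responder (CR: no clinical tumor evidence and
no invasive residual on pathology), partial responder (PR: >= 50% size
decrease with significantly decreased cellularity) or non-responder (NR:
everything else).  For each on-treatment scan time the classifier input is
a fixed-order vector of 65 named features: 7 baseline mean QUS parameters,
24 baseline texture features (6 maps x CON/COR/ENE/HOM), their 7 + 24
week-minus-baseline changes, and the three binary molecular receptors
ER / PR / HER2 (+1 positive, 0 negative).

Naming convention: a trailing ``0`` marks a baseline (pre-treatment) value
(``MBF0``, ``AAC-ENE0``); a leading ``d`` marks a change from baseline
(``dMBF``, ``dAAC-ENE``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "ResponseLabel",
    "MolecularStatus",
    "PatientRecord",
    "QUS_PARAMS",
    "TEXTURE_PARAMS",
    "TEXTURES",
    "SCAN_TIMES",
    "FEATURE_NAMES",
    "MOLECULAR_NAMES",
    "scan_feature_names",
    "classify_response",
    "delta_features",
    "assemble_feature_vector",
    "cohort_feature_table",
]


class ResponseLabel(str, Enum):
    CR = "CR"
    PR = "PR"
    NR = "NR"


@dataclass(frozen=True)
class MolecularStatus:
    er: bool
    pr: bool
    her2: bool

    def encoded(self) -> dict[str, int]:
        return {"ER": int(self.er), "PR": int(self.pr), "HER2": int(self.her2)}


QUS_PARAMS = ("MBF", "SS", "SI", "ACE", "SAS", "ASD", "AAC")
# maps with texture features; ACE carries no textures
TEXTURE_PARAMS = ("MBF", "SS", "SI", "SAS", "ASD", "AAC")
TEXTURES = ("CON", "COR", "ENE", "HOM")
SCAN_TIMES = ("week0", "week1", "week4", "week8")
MOLECULAR_NAMES = ("ER", "PR", "HER2")


def scan_feature_names() -> list[str]:
    """The 31 per-scan features: 7 QUS means + 24 textures."""
    names = list(QUS_PARAMS)
    names += [f"{p}-{t}" for p in TEXTURE_PARAMS for t in TEXTURES]
    return names


def _baseline_names() -> list[str]:
    return [f"{n}0" for n in scan_feature_names()]


def _delta_names() -> list[str]:
    return [f"d{n}" for n in scan_feature_names()]


# fixed 65-entry order: 7 + 24 baseline, 7 + 24 delta, 3 molecular
FEATURE_NAMES: tuple[str, ...] = tuple(
    _baseline_names() + _delta_names() + list(MOLECULAR_NAMES))
assert len(FEATURE_NAMES) == 65


@dataclass
class PatientRecord:
    """One patient: sizes, pathology flags, molecular status, scans, outcome."""

    id: str
    pre_size: float                  # cm, longest axis before treatment
    post_size: float                 # cm, after treatment
    invasive_residual: bool
    cellularity_decreased: bool
    clinical_tumor_evidence: bool
    molecular: MolecularStatus
    scans: dict[str, dict[str, float]] = field(default_factory=dict)
    label: ResponseLabel | None = None
    recurrence_time: float = np.nan  # months
    event: bool = False              # recurrence observed (not censored)

    def __post_init__(self) -> None:
        if self.pre_size < 0 or self.post_size < 0:
            raise ValueError("tumor sizes must be >= 0")
        unknown = set(self.scans) - set(SCAN_TIMES) - {"preop"}
        if unknown:
            raise ValueError(f"unknown scan times: {sorted(unknown)}")


def classify_response(pre_size: float, post_size: float,
                      invasive_residual: bool, cellularity_decreased: bool,
                      clinical_tumor_evidence: bool) -> ResponseLabel:
    """Clinical-pathological response rule.

    CR: no clinical evidence of tumor and no invasive residual carcinoma.
    PR: tumor size decreased by at least half with significantly decreased
    cellularity.  NR: otherwise.
    """
    if pre_size <= 0:
        raise ValueError("pre-treatment size must be positive")
    if post_size < 0:
        raise ValueError("post-treatment size must be >= 0")
    if not clinical_tumor_evidence and not invasive_residual:
        return ResponseLabel.CR
    decrease = (pre_size - post_size) / pre_size
    if decrease >= 0.5 and cellularity_decreased:
        return ResponseLabel.PR
    return ResponseLabel.NR


def delta_features(baseline: dict[str, float], week: dict[str, float]
                   ) -> dict[str, float]:
    """Week-minus-baseline change of each of the 31 per-scan features."""
    names = scan_feature_names()
    for label, scan in (("baseline", baseline), ("week", week)):
        missing = [n for n in names if n not in scan]
        if missing:
            raise ValueError(f"{label} scan missing features: {missing}")
    return {f"d{n}": week[n] - baseline[n] for n in names}


def assemble_feature_vector(record: PatientRecord, scan_time: str
                            ) -> pd.Series:
    """The 65-entry named feature vector of one patient at one scan time.

    Raises with the full list of missing names when any component (baseline
    scan, on-treatment scan, molecular receptor) is absent.
    """
    if scan_time not in SCAN_TIMES or scan_time == "week0":
        raise ValueError(f"scan_time must be one of {SCAN_TIMES[1:]}")
    missing: list[str] = []
    baseline = record.scans.get("week0")
    week = record.scans.get(scan_time)
    if baseline is None:
        missing.append("week0 scan")
    if week is None:
        missing.append(f"{scan_time} scan")
    names = scan_feature_names()
    for label, scan in (("week0", baseline), (scan_time, week)):
        if scan is not None:
            missing += [f"{label}:{n}" for n in names if n not in scan
                        or not np.isfinite(scan[n])]
    if record.molecular is None:
        missing += list(MOLECULAR_NAMES)
    if missing:
        raise ValueError(
            f"patient {record.id} at {scan_time}: missing {missing}")
    values = {f"{n}0": baseline[n] for n in names}
    values.update(delta_features(baseline, week))
    values.update(record.molecular.encoded())
    vec = pd.Series([values[n] for n in FEATURE_NAMES],
                    index=list(FEATURE_NAMES), name=(record.id, scan_time))
    return vec


def cohort_feature_table(records: list[PatientRecord], scan_time: str
                         ) -> pd.DataFrame:
    """Stacked feature vectors with id / label / scan_time columns."""
    rows = []
    for rec in records:
        vec = assemble_feature_vector(rec, scan_time)
        row = vec.to_dict()
        row["id"] = rec.id
        row["label"] = rec.label.value if rec.label is not None else None
        row["scan_time"] = scan_time
        rows.append(row)
    df = pd.DataFrame(rows)
    return df[["id", "label", "scan_time"] + list(FEATURE_NAMES)]
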