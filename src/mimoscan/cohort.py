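"""Gluten-free-diet cohort analysis.

Encodes the published case series of psoriasis patients who adopted a
gluten-free diet (GfD): PASI-based response classification (PASI75 or
better within three months counts as response), gliadin-antibody serology
thresholding (titers >= 10 U/ml are elevated), and the serology-response
association via Fisher's exact test.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Gliadin IgG/IgA titers at or above this value (U/ml) count as elevated.
SEROLOGY_THRESHOLD_U_ML = 10.0

PasiClass = Literal["NI", "PASI75", "PASI90"]
Screen = Literal["pos", "neg", "ND"]

RESPONDER_CLASSES = {"PASI75", "PASI90"}


class CohortError(ValueError):
    """Raised for invalid patient records or cohort tables."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient of the GfD case series."""

    patient_id: str
    sex: str
    clinical_type: frozenset[str]  # subset of {PsO, PsA, PPPP}
    age_of_onset: float
    gliadin_screen: Screen
    igg_plus_iga: float | None
    iga: float | None
    age_at_gfd: float
    treatment: str
    pasi_baseline: float
    pasi_improvement_class: PasiClass | None
    psa_improvement: Literal["Yes", "NI", "not_applicable"]
    relapse_on_dietary_error: Literal["Yes", "NR"]

    def __post_init__(self) -> None:
        if self.pasi_baseline <= 0:
            raise CohortError(
                f"patient {self.patient_id}: PASI baseline must be > 0"
            )
        for name, titer in (("igg_plus_iga", self.igg_plus_iga), ("iga", self.iga)):
            if titer is not None and titer < 0:
                raise CohortError(
                    f"patient {self.patient_id}: {name} titer must be >= 0"
                )


@dataclass(frozen=True)
class ResponseSummary:
    n_total: int
    n_responders: int
    n_relapse_after_error: int
    n_psa_symptom_free: int
    serology_2x2: tuple[tuple[int, int], tuple[int, int]]
    fisher_p: float


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_response(record: PatientRecord) -> bool:
    """Responder iff the printed improvement class is PASI75 or PASI90."""
    if record.pasi_improvement_class is None:
        raise CohortError(
            f"patient {record.patient_id}: PASI improvement class missing"
        )
    return record.pasi_improvement_class in RESPONDER_CLASSES


def pasi_percent_improvement(baseline: float, follow_up: float) -> float:
    """Percent PASI improvement from baseline (negative if worsened)."""
    if baseline <= 0:
        raise CohortError("PASI baseline must be > 0")
    if follow_up < 0:
        raise CohortError("follow-up PASI must be >= 0")
    return 100.0 * (baseline - follow_up) / baseline


def classify_pasi_improvement(percent: float) -> PasiClass:
    """PASI90 iff >= 90% improvement, else PASI75 iff >= 75%, else NI."""
    if percent >= 90.0:
        return "PASI90"
    if percent >= 75.0:
        return "PASI75"
    return "NI"


def classify_serology(
    record: PatientRecord, threshold: float = SEROLOGY_THRESHOLD_U_ML
) -> bool | None:
    """Elevated gliadin serology: any available titer >= threshold.

    Falls back to the categorical screen result when no quantitative titer
    is available; returns None (not determined) when neither exists.
    """
    titers = [t for t in (record.igg_plus_iga, record.iga) if t is not None]
    if titers:
        return any(t >= threshold for t in titers)
    if record.gliadin_screen == "pos":
        return True
    if record.gliadin_screen == "neg":
        return False
    return None


# ---------------------------------------------------------------------------
# Association and summary
# ---------------------------------------------------------------------------

SerologyBasis = Literal["screen", "titer"]


def _serology_call(record: PatientRecord, basis: SerologyBasis) -> bool | None:
    if basis == "screen":
        if record.gliadin_screen == "pos":
            return True
        if record.gliadin_screen == "neg":
            return False
        return None
    return classify_serology(record)


def serology_2x2(
    records: Sequence[PatientRecord], basis: SerologyBasis = "screen"
) -> tuple[tuple[int, int], tuple[int, int]]:
    """2x2 counts: rows responder/non-responder, columns elevated/not.

    Patients without a serology call on the chosen basis are excluded.
    """
    table = [[0, 0], [0, 0]]
    for rec in records:
        elevated = _serology_call(rec, basis)
        if elevated is None:
            logger.info(
                "patient %s excluded from %s-based 2x2 (serology ND)",
                rec.patient_id, basis,
            )
            continue
        row = 0 if classify_response(rec) else 1
        col = 0 if elevated else 1
        table[row][col] += 1
    return (tuple(table[0]), tuple(table[1]))  # type: ignore[return-value]


@dataclass(frozen=True)
class AssociationResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    basis: SerologyBasis


def serology_response_association(
    records: Sequence[PatientRecord], basis: SerologyBasis = "screen"
) -> AssociationResult:
    """Two-sided Fisher exact test of serology status vs GfD response.

    A degenerate table (an empty row or column) yields p = 1 with a
    warning.
    """
    table = serology_2x2(records, basis=basis)
    arr = np.asarray(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn(
            "degenerate serology/response table (empty row or column); p = 1",
            stacklevel=2,
        )
        return AssociationResult(table=table, p_value=1.0, basis=basis)
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    return AssociationResult(table=table, p_value=float(min(p, 1.0)), basis=basis)


def summarize_cohort(
    records: Sequence[PatientRecord], serology_basis: SerologyBasis = "screen"
) -> ResponseSummary:
    """Cohort-level counts and the serology-response association."""
    ids = [r.patient_id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise CohortError(f"duplicate patient id(s): {dupes}")
    n_resp = sum(classify_response(r) for r in records)
    n_relapse = sum(r.relapse_on_dietary_error == "Yes" for r in records)
    n_psa_free = sum(r.psa_improvement == "Yes" for r in records)
    if records:
        assoc = serology_response_association(records, basis=serology_basis)
        table, fisher_p = assoc.table, assoc.p_value
    else:
        table, fisher_p = ((0, 0), (0, 0)), 1.0
    return ResponseSummary(
        n_total=len(records),
        n_responders=n_resp,
        n_relapse_after_error=n_relapse,
        n_psa_symptom_free=n_psa_free,
        serology_2x2=table,
        fisher_p=fisher_p,
    )


def summary_to_dict(records: Sequence[PatientRecord]) -> dict:
    """JSON-ready report including both serology bases (screen and titer)."""
    base = summarize_cohort(records)
    out = {
        "n_total": base.n_total,
        "n_responders": base.n_responders,
        "n_relapse_after_dietary_error": base.n_relapse_after_error,
        "n_psa_symptom_free": base.n_psa_symptom_free,
        "serology_association": {},
    }
    if records:
        for basis in ("screen", "titer"):
            assoc = serology_response_association(records, basis=basis)  # type: ignore[arg-type]
            out["serology_association"][basis] = {
                "table_rows_responder_nonresponder": [
                    list(assoc.table[0]), list(assoc.table[1])
                ],
                "fisher_two_sided_p": assoc.p_value,
            }
    return out


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

COHORT_COLUMNS = (
    "patient_id", "sex", "clinical_type", "age_of_onset_y", "gliadin_screen",
    "igg_plus_iga_u_ml", "iga_u_ml", "age_at_gfd_y", "treatment",
    "pasi_baseline", "pasi_improvement", "psa_improvement",
    "relapse_on_dietary_error",
)


def _parse_titer(raw: str) -> float | None:
    raw = raw.strip()
    if raw in ("", "ND", "neg"):
        return None
    return float(raw)


def read_cohort_table(path: str | Path) -> list[PatientRecord]:
    """Read a cohort TSV mirroring the published patient-table columns."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortError(f"cohort table missing column(s): {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        improvement = row["pasi_improvement"].strip()
        records.append(PatientRecord(
            patient_id=row["patient_id"].strip(),
            sex=row["sex"].strip(),
            clinical_type=frozenset(
                t.strip() for t in row["clinical_type"].split(",") if t.strip()
            ),
            age_of_onset=float(row["age_of_onset_y"]),
            gliadin_screen=row["gliadin_screen"].strip(),  # type: ignore[arg-type]
            igg_plus_iga=_parse_titer(row["igg_plus_iga_u_ml"]),
            iga=_parse_titer(row["iga_u_ml"]),
            age_at_gfd=float(row["age_at_gfd_y"]),
            treatment=row["treatment"].strip(),
            pasi_baseline=float(row["pasi_baseline"]),
            pasi_improvement_class=improvement if improvement else None,  # type: ignore[arg-type]
            psa_improvement=row["psa_improvement"].strip(),  # type: ignore[arg-type]
            relapse_on_dietary_error=row["relapse_on_dietary_error"].strip(),  # type: ignore[arg-type]
        ))
    return records


def write_cohort_table(
    records: Sequence[PatientRecord], path: str | Path
) -> None:
    with open(path, "w") as out:
        out.write("\t".join(COHORT_COLUMNS) + "\n")
        for r in records:
            out.write("\t".join([
                r.patient_id,
                r.sex,
                ",".join(sorted(r.clinical_type)),
                repr(r.age_of_onset),
                r.gliadin_screen,
                "" if r.igg_plus_iga is None else repr(r.igg_plus_iga),
                "" if r.iga is None else repr(r.iga),
                repr(r.age_at_gfd),
                r.treatment,
                repr(r.pasi_baseline),
                r.pasi_improvement_class or "",
                r.psa_improvement,
                r.relapse_on_dietary_error,
            ]) + "\n")


def reference_cohort_path() -> Path:
    """Path to the shipped GfD case-series table."""
    return Path(str(resources.files("mimoscan").joinpath("data/gfd_cohort.tsv")))


def load_reference_cohort() -> list[PatientRecord]:
    """The published 13-patient GfD case series."""
    return read_cohort_table(reference_cohort_path())


def summary_to_json(records: Sequence[PatientRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        json.dump(summary_to_dict(records), out, indent=2, sort_keys=True)
        out.write("\n")
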