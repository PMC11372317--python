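"""Domain types and I/O for structured Chinese-EMR exports.

A Chinese inpatient EMR decomposes into six top-level sub-datasets
(physician orders, the diagnosis sheet, laboratory reports, examination
results, surgical prescriptions, and narrative medical-record texts) plus
admission-record history fields that arrive pre-split by an upstream NLP
step.  The atomic unit everything downstream operates on is one *record*:
one field of one visit of one patient in one sub-dataset, carrying free
text and/or a structured lab result.

Two exchange formats are supported: JSONL (canonical — free text may
contain newlines) and CSV (RFC-4180 quoted, same columns).
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, replace
from datetime import date
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TopLevel",
    "MEDREC_PARTS",
    "ADMISSION_PARTS",
    "SubDatasetId",
    "LabResult",
    "EMRRecord",
    "RecordKey",
    "RowError",
    "Corpus",
    "read_corpus",
    "write_corpus",
    "filter_sample",
    "dedup_patients",
]


class TopLevel(str, Enum):
    """Top-level sub-dataset of a Chinese EMR."""

    ORDER = "order"
    DIAGNOSIS = "diagnosis"
    LAB = "lab"
    EXAM = "exam"
    SURGERY = "surgery"
    MEDREC = "medrec"
    ADMISSION = "admission"


#: The ten narrative medical-record text parts.
MEDREC_PARTS: tuple[str, ...] = (
    "course",
    "admission_text",
    "discharge",
    "referral",
    "consultation",
    "nursing",
    "death",
    "surgical_note",
    "informed_consent",
    "other",
)

#: The eight NLP-split admission-record history fields.
ADMISSION_PARTS: tuple[str, ...] = (
    "allergic",
    "chief_complaint",
    "disease",
    "tobacco_alcohol",
    "family",
    "marriage",
    "surgical",
    "toxic_exposure",
)


@dataclass(frozen=True, order=True)
class SubDatasetId:
    """Identifies a sub-dataset, optionally down to a named part.

    ``part`` is present iff ``top_level`` is ``medrec`` or ``admission``.
    """

    top_level: TopLevel
    part: Optional[str] = None

    def __post_init__(self) -> None:
        if self.top_level in (TopLevel.MEDREC, TopLevel.ADMISSION):
            allowed = MEDREC_PARTS if self.top_level is TopLevel.MEDREC else ADMISSION_PARTS
            if self.part is None:
                raise ValueError(f"{self.top_level.value} sub-dataset requires a part")
            if self.part not in allowed:
                raise ValueError(
                    f"unknown part {self.part!r} for {self.top_level.value}"
                )
        elif self.part is not None:
            raise ValueError(f"{self.top_level.value} sub-dataset takes no part")

    @property
    def label(self) -> str:
        """Stable string form, e.g. ``"diagnosis"`` or ``"medrec/nursing"``."""
        return self.top_level.value if self.part is None else f"{self.top_level.value}/{self.part}"

    @classmethod
    def parse(cls, label: str) -> "SubDatasetId":
        top, _, part = label.partition("/")
        return cls(TopLevel(top), part or None)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class LabResult:
    """One structured laboratory result.  ``value`` is None once redacted."""

    analyte: str
    value: Optional[float]
    unit: str

    def __post_init__(self) -> None:
        if self.value is not None and self.value < 0:
            raise ValueError("lab value must be non-negative")


@dataclass(frozen=True)
class EMRRecord:
    """One field of one visit of one patient in one sub-dataset."""

    patient_id: str
    visit_id: str
    hospital_id: str
    visit_date: date
    sex: str
    age_years: int
    subdataset: SubDatasetId
    text: str = ""
    lab: Optional[LabResult] = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.age_years < 0:
            raise ValueError("age_years must be non-negative")

    @property
    def matchable(self) -> bool:
        return bool(self.text) or self.lab is not None

    @property
    def year(self) -> int:
        return self.visit_date.year


#: (patient_id, visit_id, subdataset label, ordinal) — unique per record.
RecordKey = tuple[str, str, str, int]


@dataclass(frozen=True)
class RowError:
    """A malformed input row: collected, never silently dropped."""

    row_number: int
    message: str


class Corpus:
    """Ordered collection of EMR records with per-record keys.

    The ordinal component of a record key counts records sharing the same
    (patient, visit, sub-dataset) triple, in file order.
    """

    def __init__(
        self,
        records: Iterable[EMRRecord],
        provenance: str = "<memory>",
        errors: Sequence[RowError] = (),
    ) -> None:
        self.records: list[EMRRecord] = list(records)
        self.provenance = provenance
        self.errors: list[RowError] = list(errors)
        counts: dict[tuple[str, str, str], int] = {}
        self._keys: list[RecordKey] = []
        for rec in self.records:
            triple = (rec.patient_id, rec.visit_id, rec.subdataset.label)
            ordinal = counts.get(triple, 0)
            counts[triple] = ordinal + 1
            self._keys.append((*triple, ordinal))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EMRRecord]:
        return iter(self.records)

    def keys(self) -> list[RecordKey]:
        return list(self._keys)

    def items(self) -> Iterator[tuple[RecordKey, EMRRecord]]:
        return zip(self._keys, self.records)

    def patient_ids(self) -> list[str]:
        """Distinct patient ids in first-appearance order."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.patient_id, None)
        return list(seen)

    def last_visit_record(self, patient_id: Optional[str] = None) -> dict[str, EMRRecord]:
        """Map patient id -> the record of their latest visit date.

        Later file position wins ties, so the returned record reflects the
        most recently written metadata for that visit.
        """
        last: dict[str, EMRRecord] = {}
        for rec in self.records:
            prev = last.get(rec.patient_id)
            if prev is None or rec.visit_date >= prev.visit_date:
                last[rec.patient_id] = rec
        if patient_id is not None:
            return {patient_id: last[patient_id]}
        return last


# --- exchange formats -------------------------------------------------------

#: Canonical column order shared by JSONL and CSV.
FIELDS = (
    "patient_id",
    "visit_id",
    "hospital_id",
    "visit_date",
    "sex",
    "age_years",
    "subdataset",
    "part",
    "text",
    "lab_analyte",
    "lab_value",
    "lab_unit",
)


def _record_to_row(rec: EMRRecord) -> dict:
    return {
        "patient_id": rec.patient_id,
        "visit_id": rec.visit_id,
        "hospital_id": rec.hospital_id,
        "visit_date": rec.visit_date.isoformat(),
        "sex": rec.sex,
        "age_years": rec.age_years,
        "subdataset": rec.subdataset.top_level.value,
        "part": rec.subdataset.part,
        "text": rec.text,
        "lab_analyte": rec.lab.analyte if rec.lab else None,
        "lab_value": rec.lab.value if rec.lab else None,
        "lab_unit": rec.lab.unit if rec.lab else None,
    }


def _row_to_record(row: dict) -> EMRRecord:
    sds = SubDatasetId(TopLevel(str(row["subdataset"])), row.get("part") or None)
    lab = None
    if row.get("lab_analyte"):
        raw = row.get("lab_value")
        value = None if raw in (None, "") else float(raw)
        lab = LabResult(str(row["lab_analyte"]), value, str(row.get("lab_unit") or ""))
    return EMRRecord(
        patient_id=str(row["patient_id"]),
        visit_id=str(row["visit_id"]),
        hospital_id=str(row["hospital_id"]),
        visit_date=date.fromisoformat(str(row["visit_date"])),
        sex=str(row["sex"]),
        age_years=int(row["age_years"]),
        subdataset=sds,
        text=str(row.get("text") or ""),
        lab=lab,
    )


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    if suffix in (".csv", ".tsv"):
        return "csv"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_corpus(path: str | Path, format: Optional[str] = None) -> Corpus:
    """Read a corpus from JSONL or CSV.

    Malformed rows are collected into ``Corpus.errors`` with their 1-based
    row number; well-formed rows are kept in order.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    records: list[EMRRecord] = []
    errors: list[RowError] = []
    if fmt == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    records.append(_row_to_record(json.loads(line)))
                except (ValueError, KeyError, TypeError) as exc:
                    errors.append(RowError(lineno, str(exc)))
    elif fmt == "csv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                try:
                    records.append(_row_to_record(row))
                except (ValueError, KeyError, TypeError) as exc:
                    errors.append(RowError(lineno, str(exc)))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if errors:
        logger.warning("%s: %d malformed row(s) collected", path, len(errors))
    return Corpus(records, provenance=f"{path}:{fmt}", errors=errors)


def write_corpus(corpus: Corpus, path: str | Path, format: Optional[str] = None) -> Path:
    """Write a corpus losslessly in canonical field order (UTF-8)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in corpus:
                fh.write(json.dumps(_record_to_row(rec), ensure_ascii=False))
                fh.write("\n")
    elif fmt == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(FIELDS)
            for rec in corpus:
                row = _record_to_row(rec)
                writer.writerow(["" if row[k] is None else row[k] for k in FIELDS])
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def corpus_to_jsonl_str(corpus: Corpus) -> str:
    """Canonical JSONL serialization as a string (used by round-trip tests)."""
    buf = io.StringIO()
    for rec in corpus:
        buf.write(json.dumps(_record_to_row(rec), ensure_ascii=False))
        buf.write("\n")
    return buf.getvalue()


# --- sample construction ----------------------------------------------------

def _round_half_up(x: float | Decimal) -> int:
    return int(Decimal(str(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def filter_sample(
    corpus: Corpus,
    sex: str = "F",
    age_min: int = 14,
    age_max: int = 50,
    date_start: date = date(2010, 1, 1),
    date_end: date = date(2020, 12, 31),
    sample_fraction: float = 1.0,
    seed: int = 0,
) -> Corpus:
    """Patient-level inclusion filter followed by random patient sampling.

    Eligibility is assessed on each patient's *last* visit (sex, age at last
    visit, last visit date inside the study window); eligible patients are
    then sampled without replacement at ``sample_fraction`` (round-half-up
    count) with a deterministic seed.  All records of a sampled patient are
    retained in original order.
    """
    if not (0 < sample_fraction <= 1):
        raise ValueError("sample_fraction must be in (0, 1]")
    last = corpus.last_visit_record()
    eligible = sorted(
        pid
        for pid, rec in last.items()
        if rec.sex == sex
        and age_min <= rec.age_years <= age_max
        and date_start <= rec.visit_date <= date_end
    )
    if not eligible:
        logger.warning("filter_sample: no eligible patients")
        return Corpus([], provenance=corpus.provenance)
    k = _round_half_up(Decimal(str(sample_fraction)) * len(eligible))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(np.array(eligible, dtype=object), size=k, replace=False))
    return Corpus(
        [rec for rec in corpus if rec.patient_id in chosen],
        provenance=corpus.provenance,
    )


def dedup_patients(corpus: Corpus) -> Corpus:
    """Normalize to one logical patient per patient_id.

    Visits are retained; exact duplicate rows are dropped; conflicting
    sex/age metadata across a patient's records is harmonized to the
    last-visit values (with a warning).  Idempotent.
    """
    last = corpus.last_visit_record()
    seen: set[tuple] = set()
    out: list[EMRRecord] = []
    warned: set[str] = set()
    for rec in corpus:
        ref = last[rec.patient_id]
        if (rec.sex, rec.age_years) != (ref.sex, ref.age_years):
            if rec.patient_id not in warned:
                logger.warning(
                    "patient %s: conflicting metadata; last-visit values win",
                    rec.patient_id,
                )
                warned.add(rec.patient_id)
            rec = replace(rec, sex=ref.sex, age_years=ref.age_years)
        fp = (
            rec.patient_id,
            rec.visit_id,
            rec.subdataset.label,
            rec.text,
            rec.lab,
            rec.visit_date,
        )
        if fp in seen:
            continue
        seen.add(fp)
        out.append(rec)
    return Corpus(out, provenance=corpus.provenance)
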