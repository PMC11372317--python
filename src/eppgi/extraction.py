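"""The extraction pipeline: rule engine over a corpus, aggregated to flags.

Matches are aggregated bottom-up: a record carries sensitive reproductive
information (SRI) iff it has at least one active (non-suppressed) match; a
visit is flagged iff any of its records is; a patient is counted among
females with reproductive activities (FRA) iff any of her records is
flagged.  Frequency tables report, per sub-dataset, how often SRI is
identified at the patient level and at the record (per-visit) level —
the two granularities real-world-evidence studies consume.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Optional, Sequence

import pandas as pd

from .emr_model import (
    ADMISSION_PARTS,
    Corpus,
    MEDREC_PARTS,
    RecordKey,
    SubDatasetId,
    TopLevel,
)
from .rounding import percentage
from .rule_engine import CATEGORIES, Match, Rule, RuleSet, match_record

__all__ = [
    "ExtractionResult",
    "run_eppgi",
    "patient_table",
    "visit_table",
    "stratify",
    "restrict_ruleset",
    "diagnosis_marital_baseline",
]


@dataclass
class ExtractionResult:
    """Flags at record, visit and patient level, with match provenance."""

    matches: list[Match]
    record_flags: dict[RecordKey, bool]
    visit_flags: dict[tuple[str, str], bool]
    patient_flags: dict[str, bool]
    per_subdataset_patient_flags: dict[tuple[str, str], bool]
    run_meta: dict = field(default_factory=dict)

    def fra_patients(self) -> set[str]:
        return {pid for pid, flag in self.patient_flags.items() if flag}

    def n_fra(self) -> int:
        return len(self.fra_patients())


def run_eppgi(corpus: Corpus, ruleset: RuleSet) -> ExtractionResult:
    """Run the full extraction protocol over a corpus.

    Deterministic; every record is visited exactly once.  Warnings (e.g.
    unknown lab units) are tallied in ``run_meta``.
    """
    t0 = time.time()
    warnings: list[str] = []
    matches: list[Match] = []
    record_flags: dict[RecordKey, bool] = {}
    visit_flags: dict[tuple[str, str], bool] = {}
    patient_flags: dict[str, bool] = {}
    per_sds: dict[tuple[str, str], bool] = {}
    for key, rec in corpus.items():
        hits = match_record(rec, ruleset, ordinal=key[3], warnings=warnings)
        matches.extend(hits)
        active = any(h.active for h in hits)
        record_flags[key] = active
        vkey = (rec.patient_id, rec.visit_id)
        visit_flags[vkey] = visit_flags.get(vkey, False) or active
        patient_flags[rec.patient_id] = patient_flags.get(rec.patient_id, False) or active
        skey = (rec.patient_id, rec.subdataset.label)
        per_sds[skey] = per_sds.get(skey, False) or active
    return ExtractionResult(
        matches=matches,
        record_flags=record_flags,
        visit_flags=visit_flags,
        patient_flags=patient_flags,
        per_subdataset_patient_flags=per_sds,
        run_meta={
            "ruleset": ruleset.name,
            "ruleset_version": ruleset.version,
            "n_records": len(corpus),
            "n_warnings": len(warnings),
            "warnings": warnings[:100],
            "elapsed_s": round(time.time() - t0, 3),
        },
    )


def _canonical_subdataset_order() -> list[str]:
    order = [t.value for t in (TopLevel.ORDER, TopLevel.DIAGNOSIS, TopLevel.LAB, TopLevel.EXAM, TopLevel.SURGERY)]
    order.append(TopLevel.MEDREC.value)
    order.extend(f"medrec/{p}" for p in MEDREC_PARTS)
    order.append(TopLevel.ADMISSION.value)
    order.extend(f"admission/{p}" for p in ADMISSION_PARTS)
    return order


def patient_table(result: ExtractionResult, corpus: Corpus) -> pd.DataFrame:
    """Patient-level identification-frequency table.

    One row per sub-dataset present in the corpus: the number of distinct
    patients with at least one record there, the number flagged there, and
    the percentage (half-up, 2 decimals).  Aggregate rows are emitted for
    the medical-record texts and admission records as a whole.
    """
    denom: dict[str, set[str]] = {}
    numer: dict[str, set[str]] = {}
    for key, rec in corpus.items():
        labels = [rec.subdataset.label]
        if rec.subdataset.part is not None:
            labels.append(rec.subdataset.top_level.value)
        for label in labels:
            denom.setdefault(label, set()).add(rec.patient_id)
            if result.record_flags.get(key, False):
                numer.setdefault(label, set()).add(rec.patient_id)
    rows = []
    for label in _canonical_subdataset_order():
        if label not in denom:
            continue
        n, k = len(denom[label]), len(numer.get(label, set()))
        rows.append({
            "subdataset": label,
            "n_patients": n,
            "n_fra": k,
            "percent": percentage(k, n),
        })
    return pd.DataFrame(rows, columns=["subdataset", "n_patients", "n_fra", "percent"])


def visit_table(result: ExtractionResult, corpus: Corpus) -> pd.DataFrame:
    """Record-level (per-visit) identification-frequency table.

    Denominators count records, not patients, mirroring how EMRs are
    actually stored per visit.
    """
    denom: dict[str, int] = {}
    numer: dict[str, int] = {}
    for key, rec in corpus.items():
        labels = [rec.subdataset.label]
        if rec.subdataset.part is not None:
            labels.append(rec.subdataset.top_level.value)
        for label in labels:
            denom[label] = denom.get(label, 0) + 1
            if result.record_flags.get(key, False):
                numer[label] = numer.get(label, 0) + 1
    rows = []
    for label in _canonical_subdataset_order():
        if label not in denom:
            continue
        n, k = denom[label], numer.get(label, 0)
        rows.append({
            "subdataset": label,
            "n_records": n,
            "n_fra": k,
            "percent": percentage(k, n),
        })
    return pd.DataFrame(rows, columns=["subdataset", "n_records", "n_fra", "percent"])


def stratify(
    results: Mapping[str, ExtractionResult] | ExtractionResult,
    corpus: Corpus,
    by: str = "hospital",
) -> pd.DataFrame:
    """Per-hospital or per-year 0/1 patient counts for one or more methods.

    Each patient is assigned to the stratum of her last visit (missing
    stratum keys bucket under ``"unknown"``).  ``results`` may be a single
    extraction result or a mapping of method label -> result; the output
    has one row per (stratum, method) with flagged / unflagged counts.
    """
    if by not in ("hospital", "year"):
        raise ValueError("by must be 'hospital' or 'year'")
    if not isinstance(results, Mapping):
        results = {"eppgi": results}
    last = corpus.last_visit_record()
    strata: dict[str, str] = {}
    for pid, rec in last.items():
        if by == "hospital":
            strata[pid] = rec.hospital_id or "unknown"
        else:
            strata[pid] = str(rec.year) if rec.visit_date else "unknown"
    rows = []
    for method, res in results.items():
        counts: dict[str, list[int]] = {}
        for pid in last:
            stratum = strata.get(pid, "unknown")
            flagged = res.patient_flags.get(pid, False)
            counts.setdefault(stratum, [0, 0])[1 if flagged else 0] += 1
        for stratum in sorted(counts):
            zero, one = counts[stratum]
            rows.append({by: stratum, "method": method, "n_0": zero, "n_1": one})
    return pd.DataFrame(rows, columns=[by, "method", "n_0", "n_1"])


def restrict_ruleset(
    ruleset: RuleSet,
    categories: set[str] | Sequence[str],
    scope_overrides: Optional[Mapping[str, Sequence[str]]] = None,
) -> RuleSet:
    """Sub-ruleset keeping only include rules of the given categories.

    Exclusion rules are always retained (negation handling must not weaken
    when the positive vocabulary shrinks).  ``scope_overrides`` optionally
    narrows the scope of kept categories, e.g. confining diagnosis rules to
    the diagnosis sheet.
    """
    categories = set(categories)
    if not categories:
        raise ValueError("categories must be non-empty")
    unknown = categories - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    kept: list[Rule] = []
    for rule in ruleset.rules:
        if rule.polarity == "exclude":
            kept.append(rule)
            continue
        if rule.category not in categories:
            continue
        if scope_overrides and rule.category in scope_overrides:
            scope = tuple(SubDatasetId.parse(s) for s in scope_overrides[rule.category])
            rule = dc_replace(rule, scope=scope)
        kept.append(rule)
    return RuleSet(
        name=f"{ruleset.name}:restricted",
        version=ruleset.version,
        rules=tuple(kept),
        unit_registry=ruleset.unit_registry,
        analyte_aliases=ruleset.analyte_aliases,
    )


def diagnosis_marital_baseline(ruleset: RuleSet) -> RuleSet:
    """The traditional fixed-site baseline: diagnosis sheet + marriage history.

    Diagnosis-category rules run only against the diagnosis sheet and
    gestation-history rules only against the admission-record marriage
    field — the comparison arm against corpus-wide extraction.
    """
    return restrict_ruleset(
        ruleset,
        {"diagnosis", "gestation_history"},
        scope_overrides={
            "diagnosis": ["diagnosis"],
            "gestation_history": ["admission/marriage"],
        },
    )

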