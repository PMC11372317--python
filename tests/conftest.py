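"""Shared fixtures: rule sets, tiny corpora, and independent oracles."""

from __future__ import annotations

from datetime import date

import pytest

from eppgi import (
    Corpus,
    EMRRecord,
    LabResult,
    SubDatasetId,
    default_ruleset,
)


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


def make_record(
    pid="P1",
    vid=None,
    sds="diagnosis",
    text="",
    lab=None,
    sex="F",
    age=30,
    visit_date=date(2015, 6, 1),
    hospital="H01",
):
    return EMRRecord(
        patient_id=pid,
        visit_id=vid or f"{pid}-V0",
        hospital_id=hospital,
        visit_date=visit_date,
        sex=sex,
        age_years=age,
        subdataset=SubDatasetId.parse(sds),
        text=text,
        lab=lab,
    )


@pytest.fixture
def tiny_corpus():
    """3 records: one diagnosis, one lab, one nursing note."""
    return Corpus(
        [
            make_record("P1", sds="diagnosis", text="宫内孕"),
            make_record("P2", sds="lab", lab=LabResult("HCG", 1200.0, "IU/L")),
            make_record("P3", sds="medrec/nursing", text="护理记录：一般情况可。"),
        ]
    )


# --- independent oracles ----------------------------------------------------

def substring_scan_oracle(text: str, keywords_by_rule: dict[str, list[str]],
                          exclusion_keywords: list[str]) -> list[tuple[str, int, int, bool]]:
    """Exhaustive scan for literal keywords: every occurrence of every
    keyword, flagged suppressed when overlapping any exclusion occurrence.

    Independent of the engine: plain ``str.startswith`` at every offset.
    """
    ex_spans = []
    for kw in exclusion_keywords:
        for i in range(len(text)):
            if text.startswith(kw, i):
                ex_spans.append((i, i + len(kw)))
    hits = []
    for rule_id, kws in keywords_by_rule.items():
        for kw in kws:
            for i in range(len(text)):
                if text.startswith(kw, i):
                    span = (i, i + len(kw))
                    suppressed = any(span[0] < e and s < span[1] for s, e in ex_spans)
                    hits.append((rule_id, span[0], span[1], suppressed))
    hits.sort(key=lambda h: (h[1], h[2], h[0]))
    return hits


def boolean_mask_oracle(text: str, spans: list[tuple[int, int]], window: int,
                        mask_char: str = "*") -> tuple[str, int]:
    """Per-character boolean-marking oracle for window masking."""
    covered = [False] * len(text)
    for start, end in spans:
        for i in range(max(0, start - window), min(len(text), end + window)):
            covered[i] = True
    masked = "".join(mask_char if covered[i] else c for i, c in enumerate(text))
    return masked, sum(covered)
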