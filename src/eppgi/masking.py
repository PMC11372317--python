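"""Static desensitization of matched spans and residual-risk measurement.

Each matched keyword is widened by a symmetric context window (15 code
points on either side by default — a Chinese character counts as one) and
the widened, merged spans are overwritten with asterisks.  Widening the
mask beyond the keyword itself prevents the surrounding narrative from
giving the redacted content away ("…术后复查" next to a masked procedure
name still reads as a procedure).

Residual risk is quantified by re-running the extraction protocol as an
automated re-identification adversary on the masked corpus: the success
rate is the fraction of truly sensitive patients whose status can no
longer be recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Optional

from .emr_model import Corpus, EMRRecord, RecordKey
from .extraction import ExtractionResult, run_eppgi
from .rule_engine import Match, RuleSet

__all__ = [
    "MaskPolicy",
    "MaskedRecord",
    "mask_text",
    "mask_corpus",
    "ReidentificationReport",
    "reidentification_success_rate",
]


@dataclass(frozen=True)
class MaskPolicy:
    """How matched spans are concealed.

    window
        Code points of context masked before and after each keyword.
    mask_char
        Replacement character (must be printable, length 1).
    preserve_length
        Keep the masked text exactly as long as the original.
    merge_overlaps
        Merge expanded windows that touch or overlap into one span.
    mask_structured
        Also redact positive structured lab values (set value to null).
    """

    window: int = 15
    mask_char: str = "*"
    preserve_length: bool = True
    merge_overlaps: bool = True
    mask_structured: bool = True

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if len(self.mask_char) != 1 or not self.mask_char.isprintable():
            raise ValueError("mask_char must be a single printable character")


@dataclass(frozen=True)
class MaskedRecord:
    """Outcome of masking one text field."""

    masked_text: str
    masked_spans: tuple[tuple[int, int], ...]
    chars_masked: int


def _merge(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not spans:
        return []
    spans = sorted(spans)
    merged = [spans[0]]
    for start, end in spans[1:]:
        if start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def mask_text(text: str, matches: list[Match], policy: MaskPolicy = MaskPolicy()) -> MaskedRecord:
    """Mask the context window around every active match span.

    Spans are expanded by ``policy.window`` code points on each side,
    clipped to the text bounds, merged, and overwritten with the mask
    character.  Suppressed matches and empty lab spans are ignored; with no
    active spans the text passes through unchanged.
    """
    n = len(text)
    spans = []
    for m in matches:
        if m.suppressed or m.end <= m.start:
            continue
        if not (0 <= m.start < m.end <= n):
            raise ValueError(f"match span {m.span} outside text of length {n}")
        spans.append((max(0, m.start - policy.window), min(n, m.end + policy.window)))
    merged = _merge(spans) if policy.merge_overlaps else sorted(spans)
    covered = bytearray(n)
    for start, end in merged:
        for i in range(start, end):
            covered[i] = 1
    chars = [policy.mask_char if covered[i] else c for i, c in enumerate(text)]
    return MaskedRecord("".join(chars), tuple(merged), sum(covered))


def mask_corpus(
    corpus: Corpus,
    result: ExtractionResult,
    policy: MaskPolicy = MaskPolicy(),
) -> Corpus:
    """Apply static desensitization to every flagged record of a corpus.

    Text fields are masked around their active matches; flagged structured
    lab results are redacted by nulling the value (when
    ``policy.mask_structured``).  Records without sensitive information
    pass through unchanged, so masking is idempotent.
    """
    by_record: dict[RecordKey, list[Match]] = {}
    for m in result.matches:
        if m.subdataset is None:
            continue
        key = (m.patient_id, m.visit_id, m.subdataset.label, m.ordinal)
        by_record.setdefault(key, []).append(m)
    out: list[EMRRecord] = []
    for key, rec in corpus.items():
        hits = [m for m in by_record.get(key, []) if m.active]
        if not hits:
            out.append(rec)
            continue
        new = rec
        text_hits = [m for m in hits if m.end > m.start]
        if text_hits:
            masked = mask_text(rec.text, text_hits, policy)
            new = replace(new, text=masked.masked_text)
        if policy.mask_structured and rec.lab is not None and any(m.end == m.start for m in hits):
            new = replace(new, lab=replace(rec.lab, value=None))
        out.append(new)
    return Corpus(out, provenance=f"{corpus.provenance}|masked")


@dataclass(frozen=True)
class ReidentificationReport:
    """Residual-risk measurement on a masked corpus."""

    n_true_fra: int
    n_still_detected: int
    applicable: bool

    @property
    def success_rate(self) -> Optional[float]:
        if not self.applicable:
            return None
        return 1.0 - self.n_still_detected / self.n_true_fra


def reidentification_success_rate(
    masked: Corpus,
    truth: Mapping[str, bool],
    ruleset: RuleSet,
    adversary: Optional[Callable[[Corpus], set[str]]] = None,
) -> ReidentificationReport:
    """Success rate of masking against a re-identification adversary.

    The default adversary re-runs the extraction protocol on the masked
    corpus; ``adversary`` may substitute any callable mapping a corpus to
    the set of patient ids it believes are sensitive.  Success rate is
    1 − (true-positive patients still detected / true-positive patients);
    with zero true positives the rate is undefined (not-applicable).
    """
    true_fra = {pid for pid in masked.patient_ids() if truth.get(pid, False)}
    if not true_fra:
        return ReidentificationReport(0, 0, applicable=False)
    if adversary is None:
        adversary = lambda corpus: run_eppgi(corpus, ruleset).fra_patients()
    detected = adversary(masked) & true_fra
    return ReidentificationReport(len(true_fra), len(detected), applicable=True)
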