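"""Compile and execute extraction rule sets against EMR records.

Three kinds of rules cooperate:

* **keyword/regex rules** — Unicode-aware patterns for pregnancy- and
  gestation-related mentions (birth events, gravidity/parity shorthand,
  termination procedures, induction medications, fetus descriptions,
  pregnancy diagnoses and chief complaints);
* **lab-threshold rules** — positivity of an analyte (HCG) when its value,
  after unit conversion, strictly exceeds a threshold (10 ng/L or 25 IU/L
  by default — "exceeding" is read literally, so boundary values do not
  fire);
* **exclusion rules** — negation patterns (e.g. 否认…史 denial histories)
  whose spans suppress any overlapping keyword match in the same field.

Rule sets are plain YAML and fully user-replaceable; the shipped
``eppgi-default`` set reconstructs the published rule categories.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .emr_model import EMRRecord, LabResult, SubDatasetId

__all__ = [
    "CATEGORIES",
    "Rule",
    "RuleSet",
    "Match",
    "load_ruleset",
    "default_ruleset",
    "match_text",
    "match_lab",
    "match_record",
]

#: Rule categories; ``lab_threshold`` and ``exclusion`` are structural,
#: the rest classify keyword rules by what they describe.
CATEGORIES = (
    "diagnosis",
    "surgery",
    "chief_complaint",
    "gestation_history",
    "medication",
    "fetus_description",
    "lab_threshold",
    "exclusion",
)


@dataclass(frozen=True)
class Rule:
    """One typed matching rule, optionally scoped to sub-datasets."""

    rule_id: str
    category: str
    pattern: str = ""
    analyte: Optional[str] = None
    threshold: Optional[float] = None
    threshold_unit: Optional[str] = None
    scope: tuple[SubDatasetId, ...] = ()
    polarity: str = "include"
    case_insensitive: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown rule category {self.category!r}")
        if self.category == "lab_threshold":
            if self.pattern or self.analyte is None or self.threshold is None or self.threshold_unit is None:
                raise ValueError(
                    f"rule {self.rule_id}: lab_threshold rules need analyte/threshold/unit and no pattern"
                )
        elif not self.pattern:
            raise ValueError(f"rule {self.rule_id}: empty pattern")
        if self.category == "exclusion" and self.polarity != "exclude":
            raise ValueError(f"rule {self.rule_id}: exclusion rules must have polarity=exclude")
        if self.polarity not in ("include", "exclude"):
            raise ValueError(f"rule {self.rule_id}: bad polarity {self.polarity!r}")
        if self.pattern:
            try:
                object.__setattr__(self, "_compiled", re.compile(
                    self.pattern, re.IGNORECASE if self.case_insensitive else 0
                ))
            except re.error as exc:
                raise ValueError(f"rule {self.rule_id}: pattern does not compile: {exc}") from exc

    @property
    def compiled(self) -> re.Pattern:
        return self._compiled  # type: ignore[attr-defined]

    def in_scope(self, sds: SubDatasetId) -> bool:
        """Empty scope means corpus-wide; a top-level scope entry covers
        every part of that sub-dataset."""
        if not self.scope:
            return True
        for entry in self.scope:
            if entry == sds:
                return True
            if entry.part is None and entry.top_level == sds.top_level:
                return True
        return False


#: Aliases under which an analyte may be recorded, lower-cased.
DEFAULT_ANALYTE_ALIASES: dict[str, str] = {
    "hcg": "HCG",
    "β-hcg": "HCG",
    "b-hcg": "HCG",
    "beta-hcg": "HCG",
    "血hcg": "HCG",
    "绒毛膜促性腺激素": "HCG",
    "人绒毛膜促性腺激素": "HCG",
    "β-人绒毛膜促性腺激素": "HCG",
    "human chorionic gonadotropin": "HCG",
}

#: unit string -> (canonical unit, multiplicative factor to canonical).
#: Two incomparable families exist for HCG: mass concentration (ng/L)
#: and biological activity (IU/L; 1 mIU/mL == 1 IU/L).
DEFAULT_UNIT_REGISTRY: dict[str, tuple[str, float]] = {
    "ng/L": ("ng/L", 1.0),
    "ng/mL": ("ng/L", 1000.0),
    "ug/L": ("ng/L", 1000.0),
    "μg/L": ("ng/L", 1000.0),
    "IU/L": ("IU/L", 1.0),
    "U/L": ("IU/L", 1.0),
    "mIU/mL": ("IU/L", 1.0),
    "mIU/ml": ("IU/L", 1.0),
    "IU/mL": ("IU/L", 1000.0),
}


@dataclass(frozen=True)
class RuleSet:
    """An ordered, validated collection of rules plus unit/alias registries."""

    name: str
    version: str
    rules: tuple[Rule, ...]
    unit_registry: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_UNIT_REGISTRY)
    )
    analyte_aliases: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ANALYTE_ALIASES)
    )

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate rule_id(s): {sorted(dup)}")
        for r in self.rules:
            if r.category == "lab_threshold" and r.threshold_unit not in self.unit_registry:
                raise ValueError(
                    f"rule {r.rule_id}: threshold unit {r.threshold_unit!r} not in unit registry"
                )

    def categories(self) -> set[str]:
        return {r.category for r in self.rules}

    def include_rules(self) -> list[Rule]:
        return [r for r in self.rules if r.polarity == "include" and r.category != "lab_threshold"]

    def exclusion_rules(self) -> list[Rule]:
        return [r for r in self.rules if r.polarity == "exclude"]

    def lab_rules(self) -> list[Rule]:
        return [r for r in self.rules if r.category == "lab_threshold"]

    def canonical_analyte(self, analyte: str) -> str:
        return self.analyte_aliases.get(analyte.strip().lower(), analyte.strip().upper())

    def convert_unit(self, value: float, unit: str) -> Optional[tuple[str, float]]:
        """(canonical unit, converted value), or None for an unknown unit."""
        entry = self.unit_registry.get(unit)
        if entry is None:
            return None
        canonical, factor = entry
        return canonical, value * factor


@dataclass(frozen=True)
class Match:
    """A located sensitive-information hit.

    Spans are 0-based half-open code-point offsets into the record's text;
    lab-threshold hits carry span (0, 0) and empty matched text.  A match
    knocked out by an overlapping exclusion span has ``suppressed=True``.
    """

    rule_id: str
    start: int
    end: int
    matched_text: str
    suppressed: bool = False
    patient_id: str = ""
    visit_id: str = ""
    subdataset: Optional[SubDatasetId] = None
    ordinal: int = 0

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def active(self) -> bool:
        return not self.suppressed


# --- loading ----------------------------------------------------------------

def _rule_from_dict(d: Mapping) -> Rule:
    scope = tuple(SubDatasetId.parse(s) for s in d.get("scope", []) or [])
    return Rule(
        rule_id=str(d["rule_id"]),
        category=str(d["category"]),
        pattern=str(d.get("pattern", "") or ""),
        analyte=d.get("analyte"),
        threshold=None if d.get("threshold") is None else float(d["threshold"]),
        threshold_unit=d.get("threshold_unit"),
        scope=scope,
        polarity=str(d.get("polarity", "exclude" if d.get("category") == "exclusion" else "include")),
        case_insensitive=bool(d.get("case_insensitive", False)),
    )


def ruleset_from_dict(doc: Mapping) -> RuleSet:
    registry = dict(DEFAULT_UNIT_REGISTRY)
    registry.update({
        k: (v[0], float(v[1])) for k, v in (doc.get("unit_registry") or {}).items()
    })
    aliases = dict(DEFAULT_ANALYTE_ALIASES)
    aliases.update({k.lower(): v for k, v in (doc.get("analyte_aliases") or {}).items()})
    return RuleSet(
        name=str(doc.get("name", "unnamed")),
        version=str(doc.get("version", "0")),
        rules=tuple(_rule_from_dict(d) for d in doc.get("rules", [])),
        unit_registry=registry,
        analyte_aliases=aliases,
    )


def load_ruleset(path) -> RuleSet:
    """Load and compile a rule set from a YAML (or JSON) config file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    return ruleset_from_dict(doc)


def default_ruleset() -> RuleSet:
    """The shipped ``eppgi-default`` rule set."""
    ref = resources.files("eppgi").joinpath("rules/eppgi_default.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return ruleset_from_dict(yaml.safe_load(fh))


# --- matching ---------------------------------------------------------------

def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def match_text(text: str, ruleset: RuleSet, scope: SubDatasetId) -> list[Match]:
    """Run all in-scope keyword and exclusion rules over one text field.

    Returns every include-rule match in leftmost (start, end, rule_id)
    order; a match overlapping any exclusion-rule span in the same text is
    flagged ``suppressed``.  Suppressed matches are returned (for audit and
    provenance) but never count as sensitive-information hits downstream.
    """
    if not text:
        return []
    exclusion_spans: list[tuple[int, int]] = []
    for rule in ruleset.exclusion_rules():
        if not rule.in_scope(scope):
            continue
        for m in rule.compiled.finditer(text):
            if m.end() > m.start():
                exclusion_spans.append((m.start(), m.end()))
    hits: list[Match] = []
    for rule in ruleset.include_rules():
        if not rule.in_scope(scope):
            continue
        for m in rule.compiled.finditer(text):
            if m.end() == m.start():
                continue
            span = (m.start(), m.end())
            hits.append(
                Match(
                    rule_id=rule.rule_id,
                    start=span[0],
                    end=span[1],
                    matched_text=m.group(0),
                    suppressed=any(_overlaps(span, ex) for ex in exclusion_spans),
                )
            )
    hits.sort(key=lambda h: (h.start, h.end, h.rule_id))
    return hits


def match_lab(
    lab: LabResult,
    ruleset: RuleSet,
    warnings: Optional[list[str]] = None,
) -> list[Match]:
    """Fire lab-threshold rules against one structured result.

    A rule fires iff the analyte matches (alias-aware, case-insensitive),
    the result's unit converts into the rule's unit family, and the
    converted value **strictly exceeds** the threshold.  Redacted results
    (value None) and unknown units never fire; unknown units are reported
    through ``warnings``.
    """
    out: list[Match] = []
    if lab.value is None:
        return out
    for rule in ruleset.lab_rules():
        if ruleset.canonical_analyte(lab.analyte) != ruleset.canonical_analyte(rule.analyte or ""):
            continue
        converted = ruleset.convert_unit(lab.value, lab.unit)
        if converted is None:
            if warnings is not None:
                warnings.append(f"unknown lab unit {lab.unit!r}")
            continue
        canonical, value = converted
        rule_canonical, threshold = ruleset.convert_unit(float(rule.threshold), str(rule.threshold_unit))
        if canonical != rule_canonical:
            continue
        if value > threshold:
            out.append(Match(rule_id=rule.rule_id, start=0, end=0, matched_text=""))
    return out


def match_record(
    record: EMRRecord,
    ruleset: RuleSet,
    ordinal: int = 0,
    warnings: Optional[list[str]] = None,
) -> list[Match]:
    """All matches for one record: text matches (by span) then lab matches."""
    hits = match_text(record.text, ruleset, record.subdataset)
    if record.lab is not None:
        hits = hits + match_lab(record.lab, ruleset, warnings=warnings)
    return [
        replace(
            h,
            patient_id=record.patient_id,
            visit_id=record.visit_id,
            subdataset=record.subdataset,
            ordinal=ordinal,
        )
        for h in hits
    ]
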