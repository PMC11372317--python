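"""Seedable synthetic Chinese-EMR corpus generator with known ground truth.

Emulates the structure of a Chinese inpatient EMR export — six top-level
sub-datasets, ten medical-record text parts, eight NLP-split admission
history fields — so that extraction, masking and evaluation can be
exercised end-to-end without any real patient data.

Text is template-based (slot-filled clinical phrases), never free-form:
every planted sensitive phrase has an exact, recorded character span, and
every non-sensitive patient is built only from audited distractors
(negated histories such as 否认早产史, near-miss strings such as 早餐, and
sub-threshold HCG values), so ground truth is exact by construction.

The default parameters describe the study conditions the toolkit is
validated under: 62% patient-level prevalence of reproductive information,
per-sub-dataset signal probabilities ordered like the published frequency
profile (marriage history highest, then nursing records, down to
laboratory reports), visits per patient geometric with mean 2, eleven
admission years (2010–2020) across five hospitals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Optional, Union

import numpy as np

from .emr_model import (
    ADMISSION_PARTS,
    Corpus,
    EMRRecord,
    LabResult,
    MEDREC_PARTS,
    RecordKey,
    SubDatasetId,
)

__all__ = ["SynthConfig", "GroundTruth", "generate", "adversarial_fixture"]


# --- vocabularies -----------------------------------------------------------
# Positive phrases are chosen to be matchable by the default rule set; the
# audit test in the suite asserts this stays true if either side changes.

GESTATION_KEYWORDS = ("早产", "难产", "平产", "顺产", "死胎", "死产", "助产")
GP_SHORTHAND = ("孕2产1", "孕3产2", "G2P1", "G3P1", "孕1产1")
DIAGNOSIS_KEYWORDS = ("宫内孕", "宫外孕", "先兆流产", "早孕", "妊娠状态")
SURGERY_KEYWORDS = ("人工流产术", "剖宫产术", "清宫术", "引产术")
MEDICATION_KEYWORDS = ("米非司酮", "缩宫素", "米索前列醇", "催产素")
EXAM_KEYWORDS = ("胎心", "胎儿", "尿妊娠试验阳性", "宫内孕")
COMPLAINT_KEYWORDS = ("停经42天", "停经8周", "待产")

#: sub-dataset label -> positive keyword pool
KEYWORD_VOCAB: dict[str, tuple[str, ...]] = {
    "diagnosis": DIAGNOSIS_KEYWORDS,
    "order": MEDICATION_KEYWORDS,
    "surgery": SURGERY_KEYWORDS,
    "exam": EXAM_KEYWORDS,
    "admission/marriage": GP_SHORTHAND,
    "admission/chief_complaint": COMPLAINT_KEYWORDS,
    "admission/disease": DIAGNOSIS_KEYWORDS,
    "admission/surgical": SURGERY_KEYWORDS,
    **{f"medrec/{p}": GESTATION_KEYWORDS + GP_SHORTHAND for p in MEDREC_PARTS},
}

#: Distractors for negative patients: negated mentions (suppressed by the
#: exclusion rules) and near-miss strings that must not match anything.
DISTRACTORS = (
    "否认早产史",
    "否认流产史",
    "否认难产史",
    "否认妊娠史",
    "无死胎史",
    "早餐后出现腹痛",
    "子宫肌瘤待查",
    "未见胎心",
)

#: Neutral filler per sub-dataset family (never matches, never negates a
#: planted phrase).
NEUTRAL_TEXT: dict[str, tuple[str, ...]] = {
    "diagnosis": ("高血压病", "2型糖尿病", "上呼吸道感染", "缺铁性贫血", "慢性胃炎"),
    "order": ("口服阿莫西林0.5g", "静脉滴注生理盐水", "口服布洛芬0.3g"),
    "surgery": ("阑尾切除术", "胆囊切除术", "甲状腺结节切除术"),
    "exam": ("腹部B超未见明显异常", "胸片未见异常", "心电图大致正常"),
    "medrec": ("患者一般情况可，饮食睡眠正常。", "今日查房，生命体征平稳。", "病情稳定，继续目前治疗。"),
    "admission/allergic": ("否认药物及食物过敏史",),
    "admission/tobacco_alcohol": ("否认烟酒嗜好",),
    "admission/family": ("家族史无特殊",),
    "admission/toxic_exposure": ("否认毒物接触史",),
    "admission/disease": ("既往体健，否认高血压糖尿病史",),
    "admission/chief_complaint": ("腹痛3天", "头晕1周"),
    "admission/marriage": ("已婚", "未婚"),
    "admission/surgical": ("否认手术史", "阑尾切除术后"),
}

_PREFIXES: dict[str, tuple[str, ...]] = {
    "diagnosis": ("", "主要诊断："),
    "order": ("", "医嘱："),
    "surgery": ("", "拟行"),
    "exam": ("B超检查：", "检查所见："),
    "medrec": ("患者既往有", "记录：", "查房见"),
    "admission/marriage": ("已婚，", ""),
    "admission/chief_complaint": ("", "主诉："),
    "admission/disease": ("曾因", ""),
    "admission/surgical": ("曾行", ""),
}

_SUFFIXES: dict[str, tuple[str, ...]] = {
    "diagnosis": ("", "。"),
    "order": ("0.2mg口服", "静脉滴注"),
    "surgery": ("", "。"),
    "exam": ("，请结合临床。", "。"),
    "medrec": ("史。", "。", "，家属知情。"),
    "admission/marriage": ("。", ""),
    "admission/chief_complaint": ("。", ""),
    "admission/disease": ("就诊。", "。"),
    "admission/surgical": ("。", ""),
}

#: Probability that a given visit produces a record in each sub-dataset.
DEFAULT_PRESENCE: dict[str, float] = {
    "diagnosis": 0.95,
    "order": 0.90,
    "lab": 0.80,
    "exam": 0.75,
    "surgery": 0.30,
    "medrec/course": 0.60,
    "medrec/admission_text": 0.30,
    "medrec/discharge": 0.55,
    "medrec/referral": 0.02,
    "medrec/consultation": 0.10,
    "medrec/nursing": 0.50,
    "medrec/death": 0.005,
    "medrec/surgical_note": 0.25,
    "medrec/informed_consent": 0.35,
    "medrec/other": 0.50,
    "admission/allergic": 0.80,
    "admission/chief_complaint": 0.60,
    "admission/disease": 0.85,
    "admission/tobacco_alcohol": 0.70,
    "admission/family": 0.70,
    "admission/marriage": 0.85,
    "admission/surgical": 0.60,
    "admission/toxic_exposure": 0.60,
}

#: Probability that a sensitive patient's signal is planted in a
#: sub-dataset she has records in — ordered like the published profile:
#: marriage history highest, nursing next, laboratory lowest.
DEFAULT_HIT_PROBS: dict[str, float] = {
    "admission/marriage": 0.63,
    "medrec/nursing": 0.55,
    "medrec/course": 0.45,
    "medrec/informed_consent": 0.43,
    "medrec/discharge": 0.34,
    "medrec/other": 0.33,
    "medrec/consultation": 0.32,
    "medrec/surgical_note": 0.32,
    "medrec/admission_text": 0.30,
    "diagnosis": 0.29,
    "medrec/referral": 0.27,
    "admission/surgical": 0.23,
    "surgery": 0.20,
    "exam": 0.20,
    "order": 0.15,
    "medrec/death": 0.11,
    "lab": 0.10,
    "admission/disease": 0.03,
    "admission/chief_complaint": 0.01,
}

#: HCG sampling: (unit, low, high) triples, uniform within.  Positive
#: ranges all convert to well above 10 ng/L / 25 IU/L; negative ranges
#: stay strictly below both thresholds.
POSITIVE_HCG = (
    ("IU/L", 50.0, 200000.0),
    ("mIU/mL", 50.0, 200000.0),
    ("ng/L", 20.0, 50000.0),
    ("ng/mL", 0.05, 50.0),
)
NEGATIVE_HCG = (
    ("IU/L", 0.1, 4.9),
    ("mIU/mL", 0.1, 4.9),
    ("ng/L", 0.1, 8.0),
    ("ng/mL", 0.0001, 0.008),
)


@dataclass
class SynthConfig:
    """Generator parameters; defaults are the toolkit's study conditions."""

    n_patients: int = 200
    seed: int = 0
    fra_prevalence: Union[float, Mapping[int, float]] = 0.62
    per_subdataset_hit_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HIT_PROBS)
    )
    presence_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRESENCE)
    )
    mean_visits: float = 2.0
    max_visits: int = 6
    hospitals: tuple[tuple[str, float], ...] = (
        ("H01", 0.30),
        ("H02", 0.25),
        ("H03", 0.20),
        ("H04", 0.15),
        ("H05", 0.10),
    )
    year_range: tuple[int, int] = (2010, 2020)
    distractor_collision_rate: float = 0.0
    keyword_vocab: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(KEYWORD_VOCAB)
    )
    distractor_vocab: tuple[str, ...] = DISTRACTORS

    def __post_init__(self) -> None:
        probs = list(self.per_subdataset_hit_probs.values()) + list(self.presence_probs.values())
        if isinstance(self.fra_prevalence, Mapping):
            probs += list(self.fra_prevalence.values())
        else:
            probs.append(self.fra_prevalence)
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        prevalence_positive = (
            any(v > 0 for v in self.fra_prevalence.values())
            if isinstance(self.fra_prevalence, Mapping)
            else self.fra_prevalence > 0
        )
        if prevalence_positive and not any(self.keyword_vocab.values()):
            raise ValueError("positive prevalence requires a non-empty keyword vocabulary")

    def prevalence_for(self, year: int) -> float:
        if isinstance(self.fra_prevalence, Mapping):
            return float(self.fra_prevalence.get(year, 0.0))
        return float(self.fra_prevalence)


@dataclass
class GroundTruth:
    """Exact per-patient labels and planted-span provenance."""

    labels: dict[str, bool]
    spans: list[tuple[RecordKey, int, int, str]] = field(default_factory=list)

    def planted_phrases(self) -> set[str]:
        return {phrase for _, _, _, phrase in self.spans}


def _family(label: str) -> str:
    if label.startswith("medrec/"):
        return "medrec"
    return label


def _build_text(rng: np.random.Generator, label: str, phrase: str) -> tuple[str, int, int]:
    fam = _family(label)
    prefix = str(rng.choice(_PREFIXES.get(fam, ("",))))
    suffix = str(rng.choice(_SUFFIXES.get(fam, ("",))))
    return prefix + phrase + suffix, len(prefix), len(prefix) + len(phrase)


def _neutral_text(rng: np.random.Generator, label: str, distractors: tuple[str, ...]) -> str:
    pool = NEUTRAL_TEXT.get(label) or NEUTRAL_TEXT.get(_family(label)) or ("",)
    # medrec narrative occasionally carries a negated-history distractor
    if _family(label) == "medrec" and distractors and rng.random() < 0.3:
        return str(rng.choice(distractors)) + "，" + str(rng.choice(pool))
    return str(rng.choice(pool))


_ALL_LABELS: tuple[str, ...] = tuple(DEFAULT_PRESENCE)


def generate(config: SynthConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus plus exact ground truth, deterministically per seed.

    Every sensitive patient carries at least one planted signal (forced
    into the marriage-history field if no sub-dataset drew one); negative
    patients carry only distractors and sub-threshold lab values unless
    ``distractor_collision_rate`` > 0.
    """
    rng = np.random.default_rng(config.seed)
    hospital_ids = [h for h, _ in config.hospitals]
    weights = np.array([w for _, w in config.hospitals], dtype=float)
    weights = weights / weights.sum()
    y0, y1 = config.year_range
    records: list[EMRRecord] = []
    labels: dict[str, bool] = {}
    spans: list[tuple[RecordKey, int, int, str]] = []

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        hospital = str(rng.choice(hospital_ids, p=weights))
        age = int(rng.integers(16, 50))
        year = int(rng.integers(y0, y1 + 1))
        fra = bool(rng.random() < config.prevalence_for(year))
        collision = (not fra) and (rng.random() < config.distractor_collision_rate)
        labels[pid] = fra
        n_visits = min(int(rng.geometric(1.0 / config.mean_visits)), config.max_visits)
        # all visits stay inside the patient's enrollment year, so per-year
        # strata (keyed on last visit) are clean cohorts
        start = date(year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
        visit_dates = []
        d = start
        for _ in range(n_visits):
            visit_dates.append(min(d, date(year, 12, 31)))
            d = d + timedelta(days=int(rng.integers(5, 120)))

        # presence of each sub-dataset per visit, in fixed label order
        presence: dict[str, list[int]] = {}
        for v in range(n_visits):
            for label in _ALL_LABELS:
                if rng.random() < config.presence_probs.get(label, 0.0):
                    presence.setdefault(label, []).append(v)

        # which present sub-datasets carry the planted signal
        planted: dict[str, int] = {}
        if fra:
            for label in _ALL_LABELS:
                if label in presence and rng.random() < config.per_subdataset_hit_probs.get(label, 0.0):
                    planted[label] = presence[label][0]
            if not planted:
                presence.setdefault("admission/marriage", [0])
                planted["admission/marriage"] = presence["admission/marriage"][0]
        elif collision:
            candidates = [l for l in presence if l in config.keyword_vocab]
            if candidates:
                label = candidates[int(rng.integers(0, len(candidates)))]
                planted[label] = presence[label][0]

        for label in _ALL_LABELS:
            for v in presence.get(label, []):
                vid = f"{pid}-V{v}"
                sds = SubDatasetId.parse(label)
                common = dict(
                    patient_id=pid,
                    visit_id=vid,
                    hospital_id=hospital,
                    visit_date=visit_dates[v],
                    sex="F",
                    age_years=age,
                    subdataset=sds,
                )
                key: RecordKey = (pid, vid, label, 0)
                if label == "lab":
                    positive = planted.get(label) == v
                    pool = POSITIVE_HCG if positive else NEGATIVE_HCG
                    unit, lo, hi = pool[int(rng.integers(0, len(pool)))]
                    value = round(float(rng.uniform(lo, hi)), 4)
                    records.append(EMRRecord(**common, lab=LabResult("HCG", value, unit)))
                    if positive:
                        spans.append((key, 0, 0, f"HCG:{value}{unit}"))
                elif planted.get(label) == v:
                    vocab = config.keyword_vocab.get(label, ())
                    phrase = str(vocab[int(rng.integers(0, len(vocab)))])
                    text, s, e = _build_text(rng, label, phrase)
                    records.append(EMRRecord(**common, text=text))
                    spans.append((key, s, e, phrase))
                else:
                    records.append(
                        EMRRecord(**common, text=_neutral_text(rng, label, config.distractor_vocab))
                    )

    corpus = Corpus(records, provenance=f"synth:seed={config.seed}:n={config.n_patients}")
    return corpus, GroundTruth(labels=labels, spans=spans)


# --- hand-designed stress fixtures ------------------------------------------

def _rec(pid, vid, sds_label, text="", lab=None, year=2015, hospital="H01"):
    return EMRRecord(
        patient_id=pid,
        visit_id=vid,
        hospital_id=hospital,
        visit_date=date(year, 6, 1),
        sex="F",
        age_years=30,
        subdataset=SubDatasetId.parse(sds_label),
        text=text,
        lab=lab,
    )


def adversarial_fixture(kind: str) -> tuple[Corpus, GroundTruth]:
    """Small hand-designed corpora stressing specific failure modes.

    ``negation_heavy``
        Every mention is negated — truth all negative.
    ``boundary_hcg``
        HCG values exactly at, just above and just below the positivity
        thresholds, across unit synonyms — boundary values are negative
        under the strict comparison.
    ``overlap_windows``
        Two keywords close enough that their 15-character mask windows
        merge into one span.
    ``cross_subdataset_only``
        Sensitive information present only in nursing records — invisible
        to the diagnosis+marital-history baseline, found by corpus-wide
        extraction.
    """
    if kind == "negation_heavy":
        recs = [
            _rec("N1", "N1-V0", "medrec/course", "否认早产史，否认难产史。"),
            _rec("N2", "N2-V0", "admission/disease", "既往体健，否认妊娠史"),
            _rec("N3", "N3-V0", "medrec/nursing", "未见胎心，无死胎史。"),
        ]
        truth = GroundTruth(labels={"N1": False, "N2": False, "N3": False})
    elif kind == "boundary_hcg":
        recs = [
            _rec("B1", "B1-V0", "lab", lab=LabResult("HCG", 10.0, "ng/L")),
            _rec("B2", "B2-V0", "lab", lab=LabResult("HCG", 25.0, "IU/L")),
            _rec("B3", "B3-V0", "lab", lab=LabResult("HCG", 11.0, "ng/L")),
            _rec("B4", "B4-V0", "lab", lab=LabResult("HCG", 26.0, "IU/L")),
            _rec("B5", "B5-V0", "lab", lab=LabResult("HCG", 25.0, "mIU/mL")),
            _rec("B6", "B6-V0", "lab", lab=LabResult("HCG", 0.011, "ug/L")),
        ]
        truth = GroundTruth(
            labels={"B1": False, "B2": False, "B3": True, "B4": True, "B5": False, "B6": True}
        )
    elif kind == "overlap_windows":
        text = "患者既往有早产史，本次难产入院，过程记录如下，其余无特殊。"
        recs = [_rec("W1", "W1-V0", "medrec/course", text)]
        truth = GroundTruth(
            labels={"W1": True},
            spans=[
                (("W1", "W1-V0", "medrec/course", 0), text.index("早产"), text.index("早产") + 2, "早产"),
                (("W1", "W1-V0", "medrec/course", 0), text.index("难产"), text.index("难产") + 2, "难产"),
            ],
        )
    elif kind == "cross_subdataset_only":
        recs = []
        labels = {}
        for i in range(4):
            pid = f"X{i}"
            recs.append(_rec(pid, f"{pid}-V0", "diagnosis", "高血压病"))
            recs.append(_rec(pid, f"{pid}-V0", "admission/marriage", "已婚"))
            recs.append(_rec(pid, f"{pid}-V0", "medrec/nursing", "护理记录：产妇平产一女婴。"))
            labels[pid] = True
        truth = GroundTruth(labels=labels)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return Corpus(recs, provenance=f"adversarial:{kind}"), truth
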