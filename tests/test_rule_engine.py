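"""Rule compilation, keyword/lab matching, exclusion suppression."""

from __future__ import annotations

import numpy as np
import pytest

from eppgi import (
    LabResult,
    Rule,
    RuleSet,
    SubDatasetId,
    match_lab,
    match_record,
    match_text,
)
from eppgi.rule_engine import ruleset_from_dict

from conftest import make_record, substring_scan_oracle

DIAG = SubDatasetId.parse("diagnosis")
COURSE = SubDatasetId.parse("medrec/course")


class TestRuleSetLoading:
    def test_default_set_has_all_categories(self, ruleset):
        assert len(ruleset.categories()) >= 7
        assert {"gestation_history", "lab_threshold", "exclusion"} <= ruleset.categories()

    @pytest.mark.parametrize("kw", ["助产", "难产", "平产", "早产", "死产", "死胎"])
    def test_published_birth_event_keywords_match(self, ruleset, kw):
        hits = match_text(kw, ruleset, COURSE)
        assert any(m.matched_text == kw and m.active for m in hits)

    def test_empty_ruleset_matches_nothing(self):
        rs = RuleSet(name="empty", version="0", rules=())
        assert match_text("早产 G2P1 妊娠", rs, DIAG) == []

    def test_duplicate_rule_id_fatal(self):
        r = Rule(rule_id="a", category="diagnosis", pattern="妊娠")
        with pytest.raises(ValueError, match="duplicate"):
            RuleSet(name="x", version="0", rules=(r, r))

    def test_non_compiling_pattern_fatal_names_rule(self):
        with pytest.raises(ValueError, match="bad_rule"):
            Rule(rule_id="bad_rule", category="diagnosis", pattern="([")

    def test_lab_rule_requires_threshold_fields(self):
        with pytest.raises(ValueError):
            Rule(rule_id="x", category="lab_threshold")

    def test_unknown_threshold_unit_fatal(self):
        rule = Rule(rule_id="x", category="lab_threshold", analyte="HCG",
                    threshold=10, threshold_unit="furlong")
        with pytest.raises(ValueError, match="furlong"):
            RuleSet(name="x", version="0", rules=(rule,))

    def test_ruleset_from_dict_scope_parsing(self):
        rs = ruleset_from_dict({
            "name": "t", "version": "1",
            "rules": [{"rule_id": "r", "category": "diagnosis",
                       "pattern": "妊娠", "scope": ["diagnosis", "medrec/nursing"]}],
        })
        assert rs.rules[0].in_scope(DIAG)
        assert rs.rules[0].in_scope(SubDatasetId.parse("medrec/nursing"))
        assert not rs.rules[0].in_scope(COURSE)


class TestMatchText:
    def test_gestation_history_keyword_located(self, ruleset):
        hits = [m for m in match_text("患者有早产史", ruleset, COURSE) if m.active]
        assert len(hits) == 1
        assert hits[0].matched_text == "早产"
        assert hits[0].span == (3, 5)

    def test_empty_text(self, ruleset):
        assert match_text("", ruleset, DIAG) == []

    def test_denied_history_suppressed(self, ruleset):
        hits = match_text("否认早产史", ruleset, COURSE)
        assert hits, "the keyword itself must still be located"
        assert all(m.suppressed for m in hits)

    def test_suppression_matches_two_pass_oracle(self, ruleset):
        # independent two-pass scan: all include spans, all exclusion spans,
        # then the overlap rule
        text = "否认难产史，既往早产一次，无死胎史。"
        oracle = substring_scan_oracle(
            text,
            {"birth_events": ["难产", "早产", "死胎"]},
            ["否认难产史", "无死胎史"],
        )
        got = [
            (m.rule_id, m.start, m.end, m.suppressed)
            for m in match_text(text, ruleset, COURSE)
            if m.rule_id == "birth_events"
        ]
        assert got == oracle
        active = [m for m in match_text(text, ruleset, COURSE) if m.active]
        assert [m.matched_text for m in active] == ["早产"]

    def test_leftmost_ordering(self, ruleset):
        hits = match_text("难产后早产", ruleset, COURSE)
        assert [m.start for m in hits] == sorted(m.start for m in hits)

    def test_rule_insertion_order_irrelevant(self):
        r1 = Rule(rule_id="a", category="diagnosis", pattern="妊娠")
        r2 = Rule(rule_id="b", category="gestation_history", pattern="早产")
        text = "早产合并妊娠"
        fwd = match_text(text, RuleSet("x", "0", (r1, r2)), DIAG)
        rev = match_text(text, RuleSet("x", "0", (r2, r1)), DIAG)
        assert fwd == rev

    def test_scoped_rule_ignored_out_of_scope(self):
        rule = Rule(rule_id="r", category="diagnosis", pattern="妊娠",
                    scope=(DIAG,))
        rs = RuleSet("x", "0", (rule,))
        assert match_text("妊娠", rs, DIAG)
        assert not match_text("妊娠", rs, COURSE)

    def test_no_active_match_overlaps_exclusion_span(self, ruleset):
        texts = ["否认早产史无死胎史", "早产否认难产史", "未见胎心但胎动正常"]
        for text in texts:
            ex_spans = [
                (m.start(), m.end())
                for r in ruleset.exclusion_rules()
                for m in r.compiled.finditer(text)
            ]
            for m in match_text(text, ruleset, COURSE):
                if m.active:
                    assert not any(m.start < e and s < m.end for s, e in ex_spans)


class TestMatchLab:
    @pytest.mark.parametrize("value,unit,expect", [
        (26.0, "IU/L", True),    # strictly above 25 IU/L
        (25.0, "IU/L", False),   # boundary: "exceeding" is strict
        (11.0, "ng/L", True),    # strictly above 10 ng/L
        (10.0, "ng/L", False),
        (26.0, "mIU/mL", True),  # 1 mIU/mL == 1 IU/L
        (0.011, "ug/L", True),   # 0.011 ug/L == 11 ng/L
        (0.2, "IU/mL", True),    # 0.2 IU/mL == 200 IU/L
    ])
    def test_thresholds_and_units(self, ruleset, value, unit, expect):
        hits = match_lab(LabResult("HCG", value, unit), ruleset)
        assert bool(hits) is expect

    def test_unit_conversion_consistency(self, ruleset):
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = float(rng.uniform(0, 100))
            direct = bool(match_lab(LabResult("HCG", v, "mIU/mL"), ruleset))
            canonical = bool(match_lab(LabResult("HCG", v, "IU/L"), ruleset))
            assert direct == canonical

    @pytest.mark.parametrize("alias", ["hcg", "β-HCG", "绒毛膜促性腺激素",
                                       "Human Chorionic Gonadotropin"])
    def test_analyte_aliases(self, ruleset, alias):
        assert match_lab(LabResult(alias, 1000.0, "IU/L"), ruleset)

    def test_unknown_unit_warns_and_skips(self, ruleset):
        warnings: list[str] = []
        hits = match_lab(LabResult("HCG", 9999.0, "mol/L"), ruleset, warnings=warnings)
        assert hits == []
        assert warnings and "mol/L" in warnings[0]

    def test_other_analyte_never_fires(self, ruleset):
        assert match_lab(LabResult("TSH", 9999.0, "IU/L"), ruleset) == []

    def test_redacted_value_never_fires(self, ruleset):
        assert match_lab(LabResult("HCG", None, "IU/L"), ruleset) == []


class TestMatchRecord:
    def test_union_of_text_and_lab_channels(self, ruleset):
        rec = make_record("P1", sds="lab", text="宫内孕",
                          lab=LabResult("HCG", 500.0, "IU/L"))
        hits = match_record(rec, ruleset)
        rule_ids = {m.rule_id for m in hits}
        assert "pregnancy_diagnosis" in rule_ids
        assert "hcg_over_25_IUL" in rule_ids
        # text hits (by span) precede lab hits
        assert hits[-1].span == (0, 0)
        assert all(m.patient_id == "P1" for m in hits)

    def test_only_suppressed_matches_record(self, ruleset):
        rec = make_record("P1", sds="medrec/course", text="否认早产史")
        assert not any(m.active for m in match_record(rec, ruleset))

    def test_out_of_scope_record_yields_nothing(self):
        rule = Rule(rule_id="r", category="diagnosis", pattern="妊娠", scope=(DIAG,))
        rs = RuleSet("x", "0", (rule,))
        rec = make_record("P1", sds="medrec/course", text="妊娠")
        assert match_record(rec, rs) == []


class TestBruteForceEquivalence:
    """Engine output equals an exhaustive substring scan for literal rules."""

    KEYWORDS = {"kw_birth": ["早产", "死胎", "难产"], "kw_diag": ["妊娠", "宫内孕"]}
    EXCLUSIONS = ["否认早产史", "否认妊娠史", "无死胎史"]

    def _literal_ruleset(self):
        rules = [
            Rule(rule_id=rid, category="gestation_history", pattern="|".join(kws))
            for rid, kws in self.KEYWORDS.items()
        ]
        rules.append(Rule(rule_id="ex", category="exclusion", polarity="exclude",
                          pattern="|".join(self.EXCLUSIONS)))
        return RuleSet("literal", "0", tuple(rules))

    def test_random_texts_match_oracle(self):
        rs = self._literal_ruleset()
        rng = np.random.default_rng(2024)
        atoms = (["早", "产", "死", "胎", "难", "妊", "娠", "宫", "内", "孕", "否", "认",
                  "史", "无", "，", "。", "x"]
                 + sum(self.KEYWORDS.values(), []) + self.EXCLUSIONS)
        for _ in range(300):
            n = int(rng.integers(0, 12))
            text = "".join(str(atoms[i]) for i in rng.integers(0, len(atoms), size=n))
            got = [(m.rule_id, m.start, m.end, m.suppressed)
                   for m in match_text(text, rs, COURSE)]
            want = substring_scan_oracle(text, self.KEYWORDS, self.EXCLUSIONS)
            assert got == want, text
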