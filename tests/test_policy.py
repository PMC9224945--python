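"""Privacy-rule engine: evaluation semantics, combining algorithms and XML."""

import itertools
import random

import pytest

from genovault import policy as pol
from genovault.errors import PolicyXmlError, UnsupportedXacmlFeature
from genovault.policy import (
    AttributeValue,
    AuthzRequest,
    Combining,
    Condition,
    Effect,
    Outcome,
    Policy,
    PolicyRule,
    TargetMatch,
)

RULE_CAT = pol.CATEGORY_RULE


def attr(attr_id, value, category=RULE_CAT):
    return AttributeValue(category, attr_id, value)


class TestRuleEvaluation:
    def test_target_mismatch_is_not_applicable(self, worked_example):
        policy, bad_request = worked_example
        d = pol.evaluate_rule(policy.rules[0], bad_request)
        assert d.outcome is Outcome.NOT_APPLICABLE

    def test_fully_matching_request_is_permitted(self, worked_example):
        policy, _ = worked_example
        d = pol.evaluate_rule(policy.rules[0], pol.matching_worked_example_request())
        assert d.outcome is Outcome.PERMIT
        assert d.matched_rule_ids == (policy.rules[0].rule_id,)

    def test_false_condition_is_not_applicable(self, worked_example):
        policy, _ = worked_example
        req = pol.matching_worked_example_request(situation="Routine")
        assert pol.evaluate_rule(policy.rules[0], req).outcome is Outcome.NOT_APPLICABLE

    def test_missing_condition_attribute_is_indeterminate(self, worked_example):
        policy, _ = worked_example
        req = pol.matching_worked_example_request()
        req = AuthzRequest(
            tuple(a for a in req.attributes if a.attribute_id != "read_count")
        )
        assert pol.evaluate_rule(policy.rules[0], req).outcome is Outcome.INDETERMINATE

    def test_mistyped_condition_attribute_is_indeterminate(self, worked_example):
        policy, _ = worked_example
        req = pol.matching_worked_example_request(read_count="many")
        assert pol.evaluate_rule(policy.rules[0], req).outcome is Outcome.INDETERMINATE

    @pytest.mark.parametrize(
        "start,end,expected",
        # brute force over the interval boundary +-2 on each side
        [
            (40810027 + ds, 41216714 + de,
             Outcome.PERMIT if ds >= 0 and de <= 0 else Outcome.NOT_APPLICABLE)
            for ds in range(-2, 3)
            for de in range(-2, 3)
        ],
    )
    def test_region_containment_boundaries(self, worked_example, start, end, expected):
        policy, _ = worked_example
        req = pol.matching_worked_example_request(
            start_position=start, end_position=end
        )
        assert pol.evaluate_rule(policy.rules[0], req).outcome is expected


class TestWorkedExample:
    def test_non_practitioner_request_not_granted(self, worked_example):
        policy, request = worked_example
        d = pol.evaluate_policy(policy, request)
        assert d.outcome is not Outcome.PERMIT

    def test_matching_practitioner_request_granted(self, worked_example):
        policy, _ = worked_example
        d = pol.evaluate_policy(policy, pol.matching_worked_example_request())
        assert d.outcome is Outcome.PERMIT

    def test_fixture_survives_xml_round_trip(self, worked_example):
        policy, _ = worked_example
        assert pol.parse_policy_xml(pol.serialize_policy_xml(policy)) == policy

    def test_role_category_is_the_xacml_access_subject(self, worked_example):
        policy, _ = worked_example
        xml = pol.serialize_policy_xml(policy)
        assert b"urn:oasis:names:tc:xacml:1.0:subject-category:access-subject" in xml


class TestPolicyCombining:
    def test_empty_policy_not_applicable(self):
        d = pol.evaluate_policy(Policy("p"), AuthzRequest())
        assert d.outcome is Outcome.NOT_APPLICABLE

    def test_deny_overrides_beats_permit(self):
        rules = (
            PolicyRule("allow", Effect.PERMIT),
            PolicyRule("forbid", Effect.DENY),
        )
        d = pol.evaluate_policy(Policy("p", rules), AuthzRequest())
        assert d.outcome is Outcome.DENY
        assert d.matched_rule_ids == ("forbid",)

    def test_deny_overrides_is_order_independent(self):
        rules = [
            PolicyRule("r0", Effect.PERMIT),
            PolicyRule("r1", Effect.DENY),
            PolicyRule(
                "r2", Effect.PERMIT, target=(TargetMatch(RULE_CAT, "role", "x"),)
            ),
        ]
        req = AuthzRequest((attr("role", "x"),))
        for perm in itertools.permutations(rules):
            assert (
                pol.evaluate_policy(Policy("p", perm), req).outcome is Outcome.DENY
            )

    def test_first_applicable_returns_first_decisive_rule(self):
        rules = (
            PolicyRule("na", Effect.DENY, target=(TargetMatch(RULE_CAT, "role", "z"),)),
            PolicyRule("hit", Effect.PERMIT),
            PolicyRule("later", Effect.DENY),
        )
        d = pol.evaluate_policy(
            Policy("p", rules, Combining.FIRST_APPLICABLE),
            AuthzRequest((attr("role", "x"),)),
        )
        assert d.outcome is Outcome.PERMIT and d.matched_rule_ids == ("hit",)

    def test_repeated_evaluation_is_pure(self, worked_example):
        policy, request = worked_example
        first = pol.evaluate_policy(policy, request)
        assert all(
            pol.evaluate_policy(policy, request) == first for _ in range(5)
        )


def _oracle(policy: Policy, request: AuthzRequest) -> Outcome:
    """Combining-algorithm truth table, written independently of the engine:
    collect each rule's decision naively, then fold per algorithm."""
    per_rule = []
    for rule in policy.rules:
        if any(
            request.get(m.attribute_id) is None
            or request.get(m.attribute_id).value != m.value
            for m in rule.target
        ):
            per_rule.append(Outcome.NOT_APPLICABLE)
            continue
        results = []
        for cond in rule.conditions:
            a = request.get(cond.attribute_id)
            results.append(None if a is None else a.value == cond.value)
        if any(r is None for r in results):
            per_rule.append(Outcome.INDETERMINATE)
        elif not all(results):
            per_rule.append(Outcome.NOT_APPLICABLE)
        else:
            per_rule.append(Outcome(rule.effect.value))
    if policy.combining is Combining.FIRST_APPLICABLE:
        for o in per_rule:
            if o is not Outcome.NOT_APPLICABLE:
                return o
        return Outcome.NOT_APPLICABLE
    strong = (
        Outcome.DENY
        if policy.combining is Combining.DENY_OVERRIDES
        else Outcome.PERMIT
    )
    weak = Outcome.PERMIT if strong is Outcome.DENY else Outcome.DENY
    if strong in per_rule:
        return strong
    if Outcome.INDETERMINATE in per_rule:
        return Outcome.INDETERMINATE
    if weak in per_rule:
        return weak
    return Outcome.NOT_APPLICABLE


class TestOracleEquivalence:
    def test_randomized_policies_match_exhaustive_oracle(self):
        """Engine decision == independent truth-table oracle over randomized
        equality-condition policies and every request over 3 attributes."""
        rng = random.Random(20260925)
        attr_ids = ["a", "b", "c"]
        values = ["0", "1", "2", "3"]
        disagreements = 0
        for trial in range(120):
            rules = []
            for i in range(rng.randint(0, 4)):
                target = tuple(
                    TargetMatch(RULE_CAT, aid, rng.choice(values))
                    for aid in rng.sample(attr_ids, rng.randint(0, 2))
                )
                conds = tuple(
                    Condition(aid, "equals", value=rng.choice(values))
                    for aid in rng.sample(attr_ids, rng.randint(0, 2))
                )
                rules.append(
                    PolicyRule(
                        f"r{i}",
                        rng.choice([Effect.PERMIT, Effect.DENY]),
                        target,
                        conds,
                    )
                )
            policy = Policy(
                "p", tuple(rules), rng.choice(list(Combining))
            )
            # all requests over subsets of attributes and their values
            for present in itertools.product([None] + values, repeat=3):
                request = AuthzRequest(
                    tuple(
                        attr(aid, v)
                        for aid, v in zip(attr_ids, present)
                        if v is not None
                    )
                )
                if pol.evaluate_policy(policy, request).outcome is not _oracle(
                    policy, request
                ):
                    disagreements += 1
        assert disagreements == 0


class TestPolicyXml:
    def _round_trip(self, policy):
        assert pol.parse_policy_xml(pol.serialize_policy_xml(policy)) == policy

    def test_round_trip_across_operator_and_algorithm_mix(self):
        rng = random.Random(42)
        for combining in Combining:
            rules = []
            for i in range(3):
                conds = (
                    Condition("situation", "equals", value="Emergency"),
                    Condition("read_count", "integer-at-most", value=rng.randint(1, 9999)),
                    Condition("flag", "boolean-equals", value=bool(rng.random() < 0.5)),
                    Condition("ref", "equals", value=rng.randint(1, 40)),
                    Condition(
                        "start", "integer-range-within",
                        lo=rng.randint(0, 100), hi=rng.randint(200, 400),
                        attribute_id2="end",
                    ),
                )
                rules.append(
                    PolicyRule(
                        f"rule-{i}",
                        rng.choice([Effect.PERMIT, Effect.DENY]),
                        (TargetMatch(pol.CATEGORY_SUBJECT, "role", f"role{i}"),),
                        conds[: rng.randint(0, 5)],
                    )
                )
            self._round_trip(Policy(f"policy-{combining.value}", tuple(rules), combining))

    def test_obligations_are_an_unsupported_feature(self, worked_example):
        policy, _ = worked_example
        xml = pol.serialize_policy_xml(policy).decode()
        xml = xml.replace(
            "</Policy>",
            '<ObligationExpressions/></Policy>',
        )
        with pytest.raises(UnsupportedXacmlFeature, match="Obligation"):
            pol.parse_policy_xml(xml.encode())

    def test_policyset_root_rejected_by_name(self):
        xml = (
            '<PolicySet xmlns="urn:oasis:names:tc:xacml:3.0:core:schema:wd-17" '
            'PolicySetId="ps"/>'
        )
        with pytest.raises(UnsupportedXacmlFeature, match="PolicySet"):
            pol.parse_policy_xml(xml.encode())

    def test_malformed_xml_raises_parse_error(self):
        with pytest.raises(PolicyXmlError):
            pol.parse_policy_xml(b"<Policy")

    def test_multivalued_request_rejected(self):
        with pytest.raises(ValueError):
            AuthzRequest((attr("role", "a"), attr("role", "b")))
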