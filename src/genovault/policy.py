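"""Attribute-based access-control engine (XACML 3.0 subset).

Privacy rules for genomic containers are expressed in a small subset of
XACML: a ``Policy`` holds ordered ``Rule`` elements, each with a *target*
(required attribute matches, typically the subject ``role`` and the
``action-id``) and a list of *conditions* over request attributes such as
the situation, the requested read count, the presence of multiple
alignments, and the genomic region (reference id plus an inclusive
start/end position interval).  A request is a flat bag of typed attributes;
evaluation returns Permit, Deny, NotApplicable or Indeterminate and the
rules are combined with a named combining algorithm (deny-overrides by
default).

The resource is deliberately never matched in rules: a policy is stored in
the protection box of the hierarchy level it governs, so the resource is
implicit in *where* the policy lives.

:func:`build_worked_example` returns the package's reference fixture: a
Permit rule for the role ``practitioner`` executing ``GetDataBySimpleFilter``
on an Alzheimer-predisposition region of reference sequence 4, valid only
in an emergency, for at most 5000 reads, without multiple alignments, and
only for request intervals contained in 40,810,027..41,216,714 (both ends
included) — together with a request from a different role, which the policy
does not grant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Union

from lxml import etree

from genovault.errors import PolicyXmlError, UnsupportedXacmlFeature

__all__ = [
    "Effect",
    "Outcome",
    "Combining",
    "AttributeValue",
    "Condition",
    "PolicyRule",
    "Policy",
    "AuthzRequest",
    "Decision",
    "evaluate_rule",
    "evaluate_policy",
    "parse_policy_xml",
    "serialize_policy_xml",
    "build_worked_example",
    "CATEGORY_SUBJECT",
    "CATEGORY_ACTION",
    "CATEGORY_ENVIRONMENT",
    "CATEGORY_RULE",
]

# XACML category URIs: subject/action/environment are standard; attributes
# specific to genomic rules (read count, region...) use a package category.
CATEGORY_SUBJECT = "urn:oasis:names:tc:xacml:1.0:subject-category:access-subject"
CATEGORY_ACTION = "urn:oasis:names:tc:xacml:3.0:attribute-category:action"
CATEGORY_ENVIRONMENT = "urn:oasis:names:tc:xacml:3.0:attribute-category:environment"
CATEGORY_RULE = "urn:genovault:attribute-category:genomic"

_XACML_NS = "urn:oasis:names:tc:xacml:3.0:core:schema:wd-17"
_FN = "urn:oasis:names:tc:xacml:1.0:function:"
_ALG = "urn:oasis:names:tc:xacml:1.0:rule-combining-algorithm:"
_DT = {
    str: "http://www.w3.org/2001/XMLSchema#string",
    int: "http://www.w3.org/2001/XMLSchema#integer",
    bool: "http://www.w3.org/2001/XMLSchema#boolean",
}
_DT_INV = {uri: py for py, uri in _DT.items()}


class Effect(str, Enum):
    PERMIT = "Permit"
    DENY = "Deny"


class Outcome(str, Enum):
    PERMIT = "Permit"
    DENY = "Deny"
    NOT_APPLICABLE = "NotApplicable"
    INDETERMINATE = "Indeterminate"


class Combining(str, Enum):
    DENY_OVERRIDES = "deny-overrides"
    PERMIT_OVERRIDES = "permit-overrides"
    FIRST_APPLICABLE = "first-applicable"


AttrType = Union[str, int, bool]


@dataclass(frozen=True)
class AttributeValue:
    """One typed request attribute (category, id, value)."""

    category: str
    attribute_id: str
    value: AttrType

    def __post_init__(self):
        if type(self.value) not in (str, int, bool):
            raise TypeError(f"unsupported attribute datatype: {type(self.value)!r}")


@dataclass(frozen=True)
class Condition:
    """A single predicate over request attributes.

    Operators:

    * ``equals`` — attribute == value (string or integer)
    * ``boolean-equals`` — attribute == value (boolean)
    * ``integer-at-most`` — attribute <= value
    * ``integer-range-within`` — the request interval
      [``attribute_id``, ``attribute_id2``] must be contained in the
      inclusive bounds [``lo``, ``hi``]
    """

    attribute_id: str
    operator: str
    value: Optional[AttrType] = None
    lo: Optional[int] = None
    hi: Optional[int] = None
    attribute_id2: Optional[str] = None
    category: str = CATEGORY_RULE

    _OPERATORS = ("equals", "boolean-equals", "integer-at-most", "integer-range-within")

    def __post_init__(self):
        if self.operator not in self._OPERATORS:
            raise ValueError(f"unknown condition operator: {self.operator}")
        if self.operator == "integer-range-within":
            if self.lo is None or self.hi is None or self.attribute_id2 is None:
                raise ValueError("range condition needs lo, hi and attribute_id2")
        elif self.value is None:
            raise ValueError(f"{self.operator} condition needs a constant value")


@dataclass(frozen=True)
class TargetMatch:
    """Required equality match in a rule target (e.g. role, action-id)."""

    category: str
    attribute_id: str
    value: str


@dataclass(frozen=True)
class PolicyRule:
    rule_id: str
    effect: Effect
    target: tuple[TargetMatch, ...] = ()
    conditions: tuple[Condition, ...] = ()


@dataclass(frozen=True)
class Policy:
    policy_id: str
    rules: tuple[PolicyRule, ...] = ()
    combining: Combining = Combining.DENY_OVERRIDES


@dataclass(frozen=True)
class AuthzRequest:
    """A flat, single-valued bag of request attributes."""

    attributes: tuple[AttributeValue, ...] = ()

    def __post_init__(self):
        ids = [a.attribute_id for a in self.attributes]
        if len(ids) != len(set(ids)):
            raise ValueError("multi-valued attributes are not supported")

    def get(self, attribute_id: str) -> Optional[AttributeValue]:
        for a in self.attributes:
            if a.attribute_id == attribute_id:
                return a
        return None

    def with_attribute(self, attr: AttributeValue) -> "AuthzRequest":
        """Return a copy with ``attr`` set (replacing any same-id value)."""
        kept = tuple(a for a in self.attributes if a.attribute_id != attr.attribute_id)
        return AuthzRequest(kept + (attr,))


@dataclass(frozen=True)
class Decision:
    outcome: Outcome
    matched_rule_ids: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def _eval_condition(cond: Condition, request: AuthzRequest) -> Outcome | bool:
    """True/False, or INDETERMINATE for missing/mistyped attributes."""
    attr = request.get(cond.attribute_id)
    if attr is None:
        return Outcome.INDETERMINATE
    if cond.operator == "equals":
        if type(attr.value) is not type(cond.value):
            return Outcome.INDETERMINATE
        return attr.value == cond.value
    if cond.operator == "boolean-equals":
        if type(attr.value) is not bool or type(cond.value) is not bool:
            return Outcome.INDETERMINATE
        return attr.value == cond.value
    if cond.operator == "integer-at-most":
        if type(attr.value) is not int or type(attr.value) is bool:
            return Outcome.INDETERMINATE
        return attr.value <= cond.value
    # integer-range-within
    end = request.get(cond.attribute_id2)
    if end is None:
        return Outcome.INDETERMINATE
    if type(attr.value) is not int or type(end.value) is not int:
        return Outcome.INDETERMINATE
    return cond.lo <= attr.value and end.value <= cond.hi


def evaluate_rule(rule: PolicyRule, request: AuthzRequest) -> Decision:
    """Evaluate a single rule.

    Target mismatch -> NotApplicable.  Target match with every condition
    true -> the rule's effect.  A false condition -> NotApplicable.  A
    condition over a missing or mistyped attribute -> Indeterminate
    (Indeterminate dominates a false condition).
    """
    for match in rule.target:
        attr = request.get(match.attribute_id)
        if attr is None or attr.value != match.value:
            return Decision(Outcome.NOT_APPLICABLE)
    any_false = False
    for cond in rule.conditions:
        result = _eval_condition(cond, request)
        if result is Outcome.INDETERMINATE:
            return Decision(Outcome.INDETERMINATE)
        if result is False:
            any_false = True
    if any_false:
        return Decision(Outcome.NOT_APPLICABLE)
    return Decision(Outcome(rule.effect.value), (rule.rule_id,))


def evaluate_policy(policy: Policy, request: AuthzRequest) -> Decision:
    """Combine the policy's rule decisions with its combining algorithm.

    With no applicable rule the policy is NotApplicable; callers treat any
    non-Permit outcome as "not granted".
    """
    decisions = [(r.rule_id, evaluate_rule(r, request)) for r in policy.rules]
    if policy.combining is Combining.FIRST_APPLICABLE:
        for rid, d in decisions:
            if d.outcome in (Outcome.PERMIT, Outcome.DENY):
                return d
            if d.outcome is Outcome.INDETERMINATE:
                return Decision(Outcome.INDETERMINATE)
        return Decision(Outcome.NOT_APPLICABLE)

    if policy.combining is Combining.DENY_OVERRIDES:
        first, second = Outcome.DENY, Outcome.PERMIT
    else:  # permit-overrides
        first, second = Outcome.PERMIT, Outcome.DENY
    for wanted in (first,):
        hits = tuple(rid for rid, d in decisions if d.outcome is wanted)
        if hits:
            return Decision(wanted, hits)
    if any(d.outcome is Outcome.INDETERMINATE for _, d in decisions):
        return Decision(Outcome.INDETERMINATE)
    hits = tuple(rid for rid, d in decisions if d.outcome is second)
    if hits:
        return Decision(second, hits)
    return Decision(Outcome.NOT_APPLICABLE)


# ---------------------------------------------------------------------------
# XML serialisation (XACML 3.0 namespace, subset elements only)
# ---------------------------------------------------------------------------


def _q(tag: str) -> str:
    return f"{{{_XACML_NS}}}{tag}"


def _attr_value_el(parent, value: AttrType):
    el = etree.SubElement(parent, _q("AttributeValue"), DataType=_DT[type(value)])
    el.text = _to_text(value)
    return el


def _to_text(value: AttrType) -> str:
    if type(value) is bool:
        return "true" if value else "false"
    return str(value)


def _designator_el(parent, category: str, attribute_id: str, datatype: type):
    etree.SubElement(
        parent,
        _q("AttributeDesignator"),
        Category=category,
        AttributeId=attribute_id,
        DataType=_DT[datatype],
        MustBePresent="false",
    )


def _apply_for_condition(parent, cond: Condition):
    if cond.operator == "equals":
        fn = "string-equal" if type(cond.value) is str else "integer-equal"
        ap = etree.SubElement(parent, _q("Apply"), FunctionId=_FN + fn)
        _designator_el(ap, cond.category, cond.attribute_id, type(cond.value))
        _attr_value_el(ap, cond.value)
    elif cond.operator == "boolean-equals":
        ap = etree.SubElement(parent, _q("Apply"), FunctionId=_FN + "boolean-equal")
        _designator_el(ap, cond.category, cond.attribute_id, bool)
        _attr_value_el(ap, cond.value)
    elif cond.operator == "integer-at-most":
        ap = etree.SubElement(
            parent, _q("Apply"), FunctionId=_FN + "integer-less-than-or-equal"
        )
        _designator_el(ap, cond.category, cond.attribute_id, int)
        _attr_value_el(ap, cond.value)
    else:  # integer-range-within: and(start >= lo, end <= hi)
        outer = etree.SubElement(parent, _q("Apply"), FunctionId=_FN + "and")
        ge = etree.SubElement(
            outer, _q("Apply"), FunctionId=_FN + "integer-greater-than-or-equal"
        )
        _designator_el(ge, cond.category, cond.attribute_id, int)
        _attr_value_el(ge, cond.lo)
        le = etree.SubElement(
            outer, _q("Apply"), FunctionId=_FN + "integer-less-than-or-equal"
        )
        _designator_el(le, cond.category, cond.attribute_id2, int)
        _attr_value_el(le, cond.hi)


def serialize_policy_xml(policy: Policy) -> bytes:
    root = etree.Element(
        _q("Policy"),
        nsmap={None: _XACML_NS},
        PolicyId=policy.policy_id,
        RuleCombiningAlgId=_ALG + policy.combining.value,
        Version="1.0",
    )
    etree.SubElement(root, _q("Target"))
    for rule in policy.rules:
        rule_el = etree.SubElement(
            root, _q("Rule"), RuleId=rule.rule_id, Effect=rule.effect.value
        )
        target_el = etree.SubElement(rule_el, _q("Target"))
        if rule.target:
            allof = etree.SubElement(
                etree.SubElement(target_el, _q("AnyOf")), _q("AllOf")
            )
            for m in rule.target:
                match_el = etree.SubElement(
                    allof, _q("Match"), MatchId=_FN + "string-equal"
                )
                _attr_value_el(match_el, m.value)
                _designator_el(match_el, m.category, m.attribute_id, str)
        if rule.conditions:
            cond_el = etree.SubElement(rule_el, _q("Condition"))
            # Condition lists always wrap in an outer and-Apply, even with a
            # single member, so the parser can distinguish the member shapes.
            outer = etree.SubElement(cond_el, _q("Apply"), FunctionId=_FN + "and")
            for cond in rule.conditions:
                _apply_for_condition(outer, cond)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


_UNSUPPORTED = {
    "ObligationExpressions",
    "Obligations",
    "AdviceExpressions",
    "Advice",
    "PolicySet",
    "PolicySetIdReference",
    "PolicyIdReference",
    "CombinerParameters",
    "VariableDefinition",
    "VariableReference",
    "PolicyDefaults",
}


def _localname(el) -> str:
    return etree.QName(el).localname


def _parse_value(el) -> AttrType:
    dt = el.get("DataType")
    if dt not in _DT_INV:
        raise UnsupportedXacmlFeature(f"DataType {dt}")
    py = _DT_INV[dt]
    text = el.text or ""
    if py is bool:
        if text not in ("true", "false"):
            raise PolicyXmlError(f"bad boolean literal: {text!r}")
        return text == "true"
    if py is int:
        return int(text)
    return text


def _parse_designator(el) -> tuple[str, str, type]:
    dt = el.get("DataType")
    if dt not in _DT_INV:
        raise UnsupportedXacmlFeature(f"DataType {dt}")
    return el.get("Category"), el.get("AttributeId"), _DT_INV[dt]


def _parse_simple_apply(el) -> Condition:
    fn = el.get("FunctionId", "")
    children = [c for c in el if isinstance(c.tag, str)]
    if len(children) != 2:
        raise UnsupportedXacmlFeature(f"Apply arity {len(children)}")
    desig = next((c for c in children if _localname(c) == "AttributeDesignator"), None)
    value = next((c for c in children if _localname(c) == "AttributeValue"), None)
    if desig is None or value is None:
        raise UnsupportedXacmlFeature("Apply without designator/value pair")
    category, attribute_id, _ = _parse_designator(desig)
    const = _parse_value(value)
    short = fn.removeprefix(_FN)
    if short in ("string-equal", "integer-equal"):
        op = "equals"
    elif short == "boolean-equal":
        op = "boolean-equals"
    elif short == "integer-less-than-or-equal":
        op = "integer-at-most"
    elif short == "integer-greater-than-or-equal":
        op = "_at-least"  # only legal inside a range pair
    else:
        raise UnsupportedXacmlFeature(f"FunctionId {fn}")
    if op == "_at-least":
        return Condition(
            attribute_id, "integer-range-within",
            lo=const, hi=const, attribute_id2=attribute_id, category=category,
        )  # placeholder; replaced by the range folder
    return Condition(attribute_id, op, value=const, category=category)


def _parse_condition_member(el) -> Condition:
    if _localname(el) != "Apply":
        raise UnsupportedXacmlFeature(_localname(el))
    fn = el.get("FunctionId", "")
    if fn == _FN + "and":
        # nested and == inclusive range pair: and(start >= lo, end <= hi)
        parts = [c for c in el if isinstance(c.tag, str)]
        if len(parts) != 2:
            raise UnsupportedXacmlFeature("nested and with arity != 2")
        ge, le = parts
        if (
            ge.get("FunctionId") != _FN + "integer-greater-than-or-equal"
            or le.get("FunctionId") != _FN + "integer-less-than-or-equal"
        ):
            raise UnsupportedXacmlFeature("nested and that is not a range pair")
        g = _parse_simple_apply(ge)
        l = _parse_simple_apply(le)
        return Condition(
            g.attribute_id,
            "integer-range-within",
            lo=g.lo,
            hi=l.value,
            attribute_id2=l.attribute_id,
            category=g.category,
        )
    cond = _parse_simple_apply(el)
    if cond.operator == "integer-range-within":  # bare at-least placeholder
        raise UnsupportedXacmlFeature("integer-greater-than-or-equal outside a range pair")
    return cond


def _parse_rule(el) -> PolicyRule:
    effect = Effect(el.get("Effect"))
    target: list[TargetMatch] = []
    conditions: list[Condition] = []
    for child in el:
        if not isinstance(child.tag, str):
            continue
        name = _localname(child)
        if name == "Target":
            for match_el in child.iter(_q("Match")):
                value_el = match_el.find(_q("AttributeValue"))
                desig_el = match_el.find(_q("AttributeDesignator"))
                if value_el is None or desig_el is None:
                    raise UnsupportedXacmlFeature("Match without designator/value")
                category, attribute_id, _ = _parse_designator(desig_el)
                target.append(TargetMatch(category, attribute_id, str(_parse_value(value_el))))
        elif name == "Condition":
            members = [c for c in child if isinstance(c.tag, str)]
            if len(members) != 1:
                raise PolicyXmlError("Condition must contain exactly one Apply")
            top = members[0]
            if _localname(top) != "Apply":
                raise UnsupportedXacmlFeature(_localname(top))
            if top.get("FunctionId") != _FN + "and":
                raise UnsupportedXacmlFeature(
                    f"top-level condition FunctionId {top.get('FunctionId')}"
                )
            for member in top:
                if isinstance(member.tag, str):
                    conditions.append(_parse_condition_member(member))
        elif name in _UNSUPPORTED:
            raise UnsupportedXacmlFeature(name)
        else:
            raise UnsupportedXacmlFeature(name)
    return PolicyRule(el.get("RuleId"), effect, tuple(target), tuple(conditions))


def parse_policy_xml(data: bytes) -> Policy:
    """Parse a policy from the supported XACML 3.0 subset.

    Any element outside the subset (obligations, advice, policy sets,
    variable definitions...) raises :class:`UnsupportedXacmlFeature` naming
    the offending element.
    """
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise PolicyXmlError(f"malformed policy XML: {exc}") from exc
    if etree.QName(root).namespace != _XACML_NS:
        raise PolicyXmlError(f"unexpected namespace: {etree.QName(root).namespace}")
    if _localname(root) != "Policy":
        raise UnsupportedXacmlFeature(_localname(root))
    alg = root.get("RuleCombiningAlgId", "")
    if not alg.startswith(_ALG) or alg.removeprefix(_ALG) not in {
        c.value for c in Combining
    }:
        raise UnsupportedXacmlFeature(f"RuleCombiningAlgId {alg}")
    rules = []
    for child in root:
        if not isinstance(child.tag, str):
            continue
        name = _localname(child)
        if name == "Rule":
            rules.append(_parse_rule(child))
        elif name in ("Target", "Description"):
            continue
        else:
            raise UnsupportedXacmlFeature(name)
    return Policy(
        root.get("PolicyId"), tuple(rules), Combining(alg.removeprefix(_ALG))
    )


# ---------------------------------------------------------------------------
# Worked example fixture
# ---------------------------------------------------------------------------

WORKED_EXAMPLE = {
    "role": "practitioner",
    "action": "GetDataBySimpleFilter",
    "situation": "Emergency",
    "max_read_count": 5000,
    "multiple_alignments": False,
    "reference_id": 4,
    "range_lo": 40810027,
    "range_hi": 41216714,
}


def build_worked_example() -> tuple[Policy, AuthzRequest]:
    """The reference privacy rule and a non-matching request.

    The rule permits ``GetDataBySimpleFilter`` for the role ``practitioner``
    under an emergency, for at most 5000 reads, without multiple alignments,
    on reference sequence 4 within positions 40,810,027..41,216,714
    inclusive.  The returned request carries a different role (plus a date
    attribute no condition matches on), so the policy does not grant it.
    """
    w = WORKED_EXAMPLE
    rule = PolicyRule(
        rule_id="alzheimer-region-practitioner",
        effect=Effect.PERMIT,
        target=(
            TargetMatch(CATEGORY_SUBJECT, "role", w["role"]),
            TargetMatch(CATEGORY_ACTION, "action-id", w["action"]),
        ),
        conditions=(
            Condition("situation", "equals", value=w["situation"]),
            Condition("read_count", "integer-at-most", value=w["max_read_count"]),
            Condition(
                "presence_of_multiple_alignments",
                "boolean-equals",
                value=w["multiple_alignments"],
            ),
            Condition("reference_id", "equals", value=w["reference_id"]),
            Condition(
                "start_position",
                "integer-range-within",
                lo=w["range_lo"],
                hi=w["range_hi"],
                attribute_id2="end_position",
            ),
        ),
    )
    policy = Policy("alzheimer-region-policy", (rule,))
    request = AuthzRequest(
        (
            AttributeValue(CATEGORY_SUBJECT, "role", "researcher"),
            AttributeValue(CATEGORY_ACTION, "action-id", w["action"]),
            AttributeValue(CATEGORY_ENVIRONMENT, "date", "2022-05-31"),
        )
    )
    return policy, request


def matching_worked_example_request(**overrides: AttrType) -> AuthzRequest:
    """A request that satisfies every constraint of the worked-example rule.

    Keyword overrides replace individual attribute values, which is how the
    boundary-probing tests explore the rule's constants.
    """
    w = WORKED_EXAMPLE
    values: dict[str, tuple[str, AttrType]] = {
        "role": (CATEGORY_SUBJECT, w["role"]),
        "action-id": (CATEGORY_ACTION, w["action"]),
        "situation": (CATEGORY_RULE, w["situation"]),
        "read_count": (CATEGORY_RULE, w["max_read_count"]),
        "presence_of_multiple_alignments": (CATEGORY_RULE, w["multiple_alignments"]),
        "reference_id": (CATEGORY_RULE, w["reference_id"]),
        "start_position": (CATEGORY_RULE, w["range_lo"]),
        "end_position": (CATEGORY_RULE, w["range_hi"]),
    }
    for key, value in overrides.items():
        attr_id = key.replace("__", "-") if key == "action__id" else key
        if attr_id not in values:
            raise KeyError(attr_id)
        values[attr_id] = (values[attr_id][0], value)
    return AuthzRequest(
        tuple(AttributeValue(cat, attr_id, v) for attr_id, (cat, v) in values.items())
    )
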