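"""Hierarchical authorization over the dataset-group/dataset rule tree.

Policies live at two levels of the container: the dataset group (a study's
default rules) and the dataset (per-dataset specificities).  Two algorithms
combine them:

**Dataset access** (:func:`authorize_dataset`): the dataset's own rules are
checked first, and a dataset-level Permit is final — group-wide defaults
must not hide what a dataset explicitly allows.  If the dataset does not
grant (or has no policy at all), the *same* request is evaluated against
the group policy; a group-level Permit delegates access downward and the
returned request is annotated with a ``granted_by_dataset_group``
provenance attribute.  If neither level grants, the result is Deny.

**Dataset-group access** (:func:`authorize_dataset_group`): a request for
the whole group is granted only if the group policy permits, and then each
member dataset is reviewed one by one: a dataset with no policy of its own
inherits the group's grant, while a dataset whose policy exists but does
not permit the request is blocked and its data withheld.  The granted and
blocked dataset ids are both reported.

"Not granted" always means *any outcome other than Permit* — an explicit
Deny, a NotApplicable policy, or an Indeterminate evaluation all withhold
access.

:func:`authorize_operation` is the front door used by the command-line
layer: it injects the ``action-id`` attribute, applies the ownership check
for mutating operations, dispatches to the level-appropriate algorithm and
appends one audit record per call.  Creating a fresh container file is the
single operation that requires no authorization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from genovault import policy as pol
from genovault.audit import AuditLog
from genovault.container import GenomicContainer
from genovault.errors import AuthorizationError

__all__ = [
    "GRANTED_BY_GROUP_ATTR",
    "OPERATIONS",
    "MUTATING_OPERATIONS",
    "AuthzResult",
    "GroupAuthzResult",
    "authorize_dataset",
    "authorize_dataset_group",
    "authorize_operation",
]

GRANTED_BY_GROUP_ATTR = "granted_by_dataset_group"

OPERATIONS = frozenset(
    {
        "GetDataBySimpleFilter",
        "addDatasetGroup",
        "addDataset",
        "editAnyElement",
        "deleteAnyElement",
        "metadata-read",
        "metadata-write",
        "createFile",
    }
)
MUTATING_OPERATIONS = frozenset(
    {"addDatasetGroup", "addDataset", "editAnyElement", "deleteAnyElement",
     "metadata-write"}
)


@dataclass
class AuthzResult:
    outcome: pol.Outcome
    granted_by: Optional[str]  # "dataset" | "dataset_group" | None
    annotated_request: pol.AuthzRequest


@dataclass
class GroupAuthzResult:
    outcome: pol.Outcome
    granted_datasets: list[int]
    blocked_datasets: list[int]


def _policy_at(node) -> Optional[pol.Policy]:
    if node.protection is None:
        return None
    return node.protection.policy


def _granted(policy: Optional[pol.Policy], request: pol.AuthzRequest) -> bool:
    if policy is None:
        return False
    return pol.evaluate_policy(policy, request).outcome is pol.Outcome.PERMIT


def authorize_dataset(
    c: GenomicContainer, dg_id: int, dt_id: int, request: pol.AuthzRequest
) -> AuthzResult:
    """Dataset-first authorization with fallback to the enclosing group."""
    try:
        dg = c.group(dg_id)
        dt = dg.dataset(dt_id)
    except Exception as exc:
        raise AuthorizationError(str(exc)) from exc
    dt_policy = _policy_at(dt)
    if dt_policy is not None and _granted(dt_policy, request):
        return AuthzResult(pol.Outcome.PERMIT, "dataset", request)
    if _granted(_policy_at(dg), request):
        annotated = request.with_attribute(
            pol.AttributeValue(pol.CATEGORY_ENVIRONMENT, GRANTED_BY_GROUP_ATTR, True)
        )
        return AuthzResult(pol.Outcome.PERMIT, "dataset_group", annotated)
    return AuthzResult(pol.Outcome.DENY, None, request)


def authorize_dataset_group(
    c: GenomicContainer, dg_id: int, request: pol.AuthzRequest
) -> GroupAuthzResult:
    """Group-level authorization with a per-dataset compatibility review."""
    try:
        dg = c.group(dg_id)
    except Exception as exc:
        raise AuthorizationError(str(exc)) from exc
    if not _granted(_policy_at(dg), request):
        return GroupAuthzResult(pol.Outcome.DENY, [], [])
    granted, blocked = [], []
    for dt in dg.datasets:
        dt_policy = _policy_at(dt)
        if dt_policy is None or _granted(dt_policy, request):
            granted.append(dt.dt_id)  # no own policy -> inherits the group grant
        else:
            blocked.append(dt.dt_id)
    return GroupAuthzResult(pol.Outcome.PERMIT, granted, blocked)


def _ownership_ok(c: GenomicContainer, request: pol.AuthzRequest) -> bool:
    owner = c.file_header.owner
    if not owner:
        return True
    subject = request.get("subject-id")
    return subject is not None and subject.value == owner


def _subject_dict(request: pol.AuthzRequest) -> dict:
    return {a.attribute_id: a.value for a in request.attributes}


def authorize_operation(
    c: GenomicContainer,
    operation: str,
    target_path: tuple[int, ...],
    request: pol.AuthzRequest,
    audit: Optional[AuditLog] = None,
) -> AuthzResult:
    """Authorize an API operation before it is performed.

    ``target_path`` is ``()`` for file-level operations, ``(dg_id,)`` for a
    dataset group and ``(dg_id, dt_id)`` for a dataset.  Policy-governed
    hierarchy levels are evaluated with the two hierarchical algorithms;
    for *mutating* operations on a level with no policy anywhere above it,
    the file-ownership check alone decides.  Every call appends one audit
    record.
    """
    if operation not in OPERATIONS:
        raise AuthorizationError(f"unknown operation {operation!r}")
    request = request.with_attribute(
        pol.AttributeValue(pol.CATEGORY_ACTION, "action-id", operation)
    )

    result = _dispatch(c, operation, tuple(target_path), request)
    if audit is not None:
        audit.append(
            _subject_dict(request),
            operation,
            "/".join(str(i) for i in target_path) or "<file>",
            result.outcome.value,
        )
    return result


def _dispatch(c, operation, target_path, request) -> AuthzResult:
    if operation == "createFile":
        # Creating a new file is the one unauthorized operation.
        return AuthzResult(pol.Outcome.PERMIT, None, request)

    mutating = operation in MUTATING_OPERATIONS
    if mutating and not _ownership_ok(c, request):
        return AuthzResult(pol.Outcome.DENY, None, request)

    if len(target_path) == 0:
        # File level (e.g. addDatasetGroup): no policy level above groups
        # exists, so the ownership check above is the whole decision.
        return AuthzResult(pol.Outcome.PERMIT, None, request)

    if len(target_path) == 1:
        dg_id = target_path[0]
        try:
            dg = c.group(dg_id)
        except Exception as exc:
            raise AuthorizationError(str(exc)) from exc
        group_policy = _policy_at(dg)
        if group_policy is None and mutating:
            return AuthzResult(pol.Outcome.PERMIT, None, request)
        annotated = request.with_attribute(
            pol.AttributeValue(pol.CATEGORY_ENVIRONMENT, GRANTED_BY_GROUP_ATTR, True)
        )
        if operation == "GetDataBySimpleFilter":
            gres = authorize_dataset_group(c, dg_id, request)
            if gres.outcome is pol.Outcome.PERMIT:
                return AuthzResult(pol.Outcome.PERMIT, "dataset_group", annotated)
            return AuthzResult(pol.Outcome.DENY, None, request)
        if _granted(group_policy, request):
            return AuthzResult(pol.Outcome.PERMIT, "dataset_group", annotated)
        return AuthzResult(pol.Outcome.DENY, None, request)

    # dataset level (or deeper elements governed by their dataset)
    dg_id, dt_id = target_path[0], target_path[1]
    if mutating:
        dg = c.group(dg_id)
        dt = dg.dataset(dt_id)
        if _policy_at(dt) is None and _policy_at(dg) is None:
            return AuthzResult(pol.Outcome.PERMIT, None, request)
    return authorize_dataset(c, dg_id, dt_id, request)
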