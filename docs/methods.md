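# Methods

This note records the models, conventions and numerical choices behind
`genovault`, in the order a reader meets them: container, metadata,
policy engine, hierarchical authorization, selective protection,
encrypted envelope, search, and the synthetic-data generator the test
suite runs on.

## Container model and serialisation

The container is a strict hierarchy — File → Dataset Group → Dataset →
Access Unit → Block — in the access-unit organisation only; the
descriptor-stream organisation is rejected at parse time with a specific
error. Block payloads are opaque bytes: no descriptor semantics are
interpreted.

The *working representation* is a directory tree, one directory per box:
`dg_X`, `dt_X`, `au_X`; headers `flhd`/`dghd`/`dthd`/`auhd`; metadata
`flmd`/`dgmd`/`dtmd`; protection `dgpr`/`dtpr`/`aupr`; the dataset label
`labl`, access-unit info `auin`, block payloads `block_X`. This mirrors
how very large archives are manipulated in practice: piecewise on disk,
assembled into one file only for exchange. The dataset-level index has no
conventional file name at this layout's level of detail, so it is stored
as a `dtix` JSON file (`au_id → byte offset`), the same extrapolation that
gives access-unit protection its `aupr` name.

The *packed form* is `GIPAMS01` (8-byte tag; deliberately not a standard
magic, since no bit-exact format conformance is claimed) followed by
nested boxes: 4-byte ASCII type, 8-byte big-endian payload length,
payload. Container boxes `dgcn`/`dtcn`/`aucn` nest their children; the
top level is flat (`flhd`, optional `flmd`, then `dgcn` boxes), so an
empty container packs to the tag plus exactly one `flhd` box. Children
are emitted in ascending id order and headers are serialised as
sorted-key JSON, which makes packing a pure function of the tree: equal
trees give byte-identical files. Block ids are contiguous from 0 and
implied by order inside `aucn`, so they need no id field on the wire.

Identifiers are non-negative integers. Genomic coordinates in rules are
1-based inclusive on both ends, matching how the reference region in the
worked-example rule is stated ("both extremes included").

`validate()` returns the full list of invariant violations (unique ids
per level, contiguous block ids, index targets existing, encrypted flags
consistent with protection entries, magic intact) rather than failing on
the first, because the caller is often a person repairing a tree by hand.

## Metadata

A `MetadataRecord` carries the seven core study/sample fields (Title,
Type, Abstract, ProjectCentre, Description, Sample-TaxonId, Sample-Title)
plus ordered named extensions. EGA fields map one-to-one. NCBI metadata
has no Abstract, so that field is always left empty, and the NCBI
submission type is copied verbatim — no vocabulary translation table is
defined, and inventing one would be worse than none. The four extension
attributes exercised in tests (StudyDesign, BodySite, AnalyteType,
IsTumor) come from BioSample attributes.

The XML payload is `<Metadata>` with one element per core field and
`<Extension name="...">` entries, in fixed order so serialisation is
deterministic and diff-friendly. Unknown elements on parse are folded
into extensions instead of rejected — the format's extension mechanism is
the point, so strictness here would fight the design.

## Policy engine

The engine implements a deliberate XACML 3.0 subset: `Policy` with
ordered `Rule`s; rule targets as required equality matches (typically
`role` in the standard access-subject category and `action-id` in the
action category); conditions as typed predicates:

* `equals` (string or integer), `boolean-equals`,
* `integer-at-most` — "for a read count of 5000" is read as a cap, the
  only operationally sensible reading of a volume condition, and one
  under which the probe "largest permitted value" returns the same
  constant as under equality semantics;
* `integer-range-within` — the request's `[start_position,
  end_position]` must be *contained* in the rule's inclusive interval.
  Containment is the conservative reading for a rule protecting a
  region: a request straddling the boundary is not granted.

Rules never match a resource: a policy is stored in the protection box of
the level it governs, so the resource is implicit in placement.

Evaluation: target mismatch → NotApplicable; all conditions true → the
rule's effect; any condition false → NotApplicable; a condition over a
missing or mistyped attribute → Indeterminate, which dominates a false
condition. Condition failure maps to NotApplicable rather than Deny,
following XACML convention — the rule simply does not apply, and the
combining layer (or hierarchy) decides what non-application means.
Requests are single-valued per attribute id; multi-valued bags are
rejected up front rather than half-supported.

Combining algorithms: deny-overrides (default), permit-overrides,
first-applicable, each with the standard strength ordering (for
deny-overrides: Deny > Indeterminate > Permit > NotApplicable). A policy
with no applicable rule is NotApplicable, never Deny; every caller in
this package treats "not Permit" as "not granted", so the distinction is
observable but never unsafe.

XML round trips are lossless for the subset. The serializer always wraps
a rule's condition list in one `and`-Apply (even for a single condition)
and encodes `integer-range-within` as a nested `and` of
greater-than-or-equal / less-than-or-equal over the two position
attributes; the parser folds exactly that shape back, so parse∘serialize
is the identity without ambiguity. Anything outside the subset —
obligations, advice, policy sets, variable definitions, unknown
functions or datatypes — raises an error naming the offending element.

The packaged worked example is a Permit rule for role `practitioner`,
action `GetDataBySimpleFilter`, situation `Emergency`, read count ≤ 5000,
no multiple alignments, reference 4, positions within
40,810,027..41,216,714 inclusive, paired with a request from a different
role (carrying also a `date` attribute that no condition matches on, as
request attributes may legitimately outnumber rule conditions). The
policy does not grant that request; flipping the role and supplying
matching condition attributes yields Permit.

## Hierarchical authorization

Two algorithms operate over group- and dataset-level policies (access
units carry no rules of their own — there are no level-specific API
actions to govern there):

* **Dataset-first**: dataset rules are evaluated; Permit is final
  ("granted by dataset"). Otherwise the *same* request is evaluated
  against the group policy; Permit delegates downward and the request is
  annotated with boolean `granted_by_dataset_group` (the concept needs an
  attribute id; this name is the package's). Otherwise Deny. Delegation
  is immediately final — the annotated request is not re-evaluated
  against dataset rules, since the dataset already had its chance to
  speak first. "Not granted" uniformly means any outcome other than
  Permit.
* **Group-wide**: if the group policy does not permit, the whole request
  is denied with no per-dataset review. If it permits, each dataset is
  reviewed: a dataset with *no policy at all* inherits the group grant; a
  dataset whose policy exists but does not permit this request is
  blocked. A policy that is merely NotApplicable still blocks — an
  existing policy is a "different access rule", and silently inheriting
  around it would let a group default override dataset-specific intent.
  Granted and blocked id lists are both reported.

`authorize_operation` fronts both: it injects `action-id`, checks file
ownership (an `owner` field in the file header matched against the
request's `subject-id`) before policy evaluation for mutating operations,
dispatches by target level, and appends one audit record (timestamp,
subject attributes, operation, target, outcome) per call. Creating a new
container file is the single operation that requires no authorization.
For *mutating* operations on a level where no policy exists anywhere
above, the ownership check alone decides — otherwise a freshly created,
still policy-free file could never be populated; read operations keep the
strict rule that no applicable Permit means Deny.

## Selective protection

Payload encryption is ChaCha20-Poly1305 with a fresh random 12-byte nonce
per entry and the target path bound as associated data, so a ciphertext
moved to a different payload slot fails authentication. One AEAD suite is
used throughout (it is also the envelope cipher); the algorithm id is
recorded in each XML entry so alternatives can be added without schema
change. Entries live in the nearest enclosing level's box: block →
`aupr`, `dtmd` → `dtpr`, `dgmd` → `dgpr`. A block's `encrypted` flag is
*derived* from those entries on load, so flag and record cannot drift.
Double encryption of a target is refused.

Signatures are detached Ed25519 over the plaintext. The ordering is
sign-then-encrypt: integrity of the content is checkable after
decryption (`verify_payload`), and signing an already-encrypted target
is refused rather than silently binding a signature to ciphertext.

Key wrapping derives a key-encryption key from a passphrase with scrypt
(N=2^14, r=8, p=1 — interactive-use cost) and wraps the content key with
the same AEAD; a wrong passphrase is an authentication failure, never a
silently wrong key.

The protection box XML (`<Protection>` with an embedded policy element,
`<Encryption>`, `<Signature>`, `<WrappedKey>`; binary values base64) is a
functional schema of this package, not a claimed standard schema.

## Encrypted envelope

The envelope follows the public Crypt4GH design: magic `crypt4gh`,
version 1, per-reader header packets, then independently authenticated
data segments of 65,536 plaintext bytes (nonce + ciphertext + MAC; all
interior segments full-size). Readers trial-decrypt every packet,
ignoring failures — a failed MAC just means "not addressed to you" — and
collect every session key that verifies; each segment is then tried
against the collected keys until one authenticates. The two failure
modes are distinct exceptions: no packet verifies (wrong reader) versus
no key authenticates a segment (tampering or corruption). With an AEAD
the "compute tag, compare with stored MAC" step is internal to
decryption; an AEAD open failure *is* that comparison failing.

Key agreement is X25519; the packet key is
`blake2b-256(shared_secret ‖ reader_pk ‖ writer_pk)`. The published
format fixes the primitive families but this package's key-derivation
detail is its own, so byte-level interoperability with other
implementations is not claimed. Edit lists and recipient re-addition
are out of scope.

Range decryption takes 0-based half-open `[P, Q)` in the library (the
CLI accepts 1-based inclusive coordinates and converts) and decrypts
exactly the segments overlapping the range — `⌊(Q−1)/S⌋ − ⌊P/S⌋ + 1` of
them — which the test suite verifies by instrumentation, not just by
output equality.

## Search

The metadata index is a deterministic in-memory walk of the tree (one
entry per populated field, extensions included), standing in for the
relational database a deployed system would use; behaviour is identical
at desk scale. Matching is case-insensitive substring — the minimal
useful semantics. Every candidate hit is passed through metadata-read
authorization at its level (dataset hits through the dataset-first
algorithm, group hits through the group policy) and denied hits are
silently dropped, so absence of a result does not distinguish "no match"
from "no access".

## Synthetic data

All test inputs are generated, none downloaded. Two generators:

* `generate_fixture` builds regular containers (default 2 groups × 2
  datasets × 1 access unit × 1 block of 256 random bytes) with EGA-style
  human-study metadata (taxon 9606, GRCh38 sample titles) and a policy
  template at both levels: `all-permit`, `all-deny`, or the worked
  example. Defaults are sized for unit-test clarity, not archive realism.
* `generate_random_container` draws tree shape (≤3 groups × ≤3 datasets ×
  ≤3 access units × ≤4 blocks), block sizes (skewed small, 5% at the
  64 KiB maximum), optional labels, metadata, info payloads, indices and
  policy boxes from one seeded stream, for round-trip property tests: 100
  seeds cover empty trees, metadata-only nodes, policy-bearing nodes and
  maximum-size blocks.

Both are deterministic per seed down to packed bytes. What the fixtures
do *not* emulate: real compressed genomic payloads (blocks are random
bytes — nothing tests descriptor semantics because the container treats
payloads as opaque), archive-scale sizes, or concurrent access. Passing
tests therefore demonstrate the correctness of structure, policy
evaluation and cryptography, not performance at hundreds of gigabytes.

## Numerical and degenerate-input choices

* Empty payloads are legal everywhere: a 0-byte block, an empty
  plaintext envelope (zero segments), an empty metadata record.
* Probing problem sizes in `scripts/acceptance.py`: boundary windows of
  ±5 positions around each interval edge, reference candidates 1..10,
  read-count binary search over 1..10000 — small enough to run in
  seconds, wide enough that the recovered constants are measurements of
  the engine, not restatements.
* Random sources: tests use fixed seeds (hypothesis profiles included);
  library randomness (nonces, salts, session keys) comes from
  `os.urandom` unless the caller passes an `rng`, which the fixture and
  determinism paths do.
* The pure-Python/numpy crypto primitives favour clarity over side-channel
  hardening: they are not constant-time and are intended for this
  package's desk-scale use, with correctness pinned to RFC test vectors.

## Known limitations

No bit-exact conformance with any published container or envelope wire
format; no descriptor-stream mode; no obligations/advice or multi-valued
XACML requests; no OAuth/OpenID authentication stack (subject attributes
enter via the API or CLI flags and are trusted as given); the search
index is in-memory and rebuilt per process; deleting a non-terminal block
is refused to preserve contiguous block ids.
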