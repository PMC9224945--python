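"""Selective encryption and signing of container payloads.

Any identifiable payload of the container — an individual block or a
metadata file — can be protected independently: encrypted with an
authenticated cipher, signed with a detached public-key signature, or
both.  What was done to which payload is recorded as entries in the
*protection box* of the nearest enclosing hierarchy level (a block's
entries live in its access unit's ``aupr``, a ``dtmd``'s in the dataset's
``dtpr``, a ``dgmd``'s in the group's ``dgpr``).  The same protection box
also carries the level's privacy policy and passphrase-wrapped content
keys, so one XML record per level describes the complete protection state.

Algorithms: payload encryption uses ChaCha20-Poly1305 with a fresh 12-byte
nonce per entry and the target path bound in as associated data (moving a
ciphertext to another payload slot breaks authentication).  Signatures are
detached Ed25519 over the plaintext, so integrity is checked after
decryption (sign-then-encrypt).  Key wrapping derives a key-encryption key
from the passphrase with scrypt.  Algorithm identifiers are recorded in the
XML so alternatives can be added without a schema change.
"""

from __future__ import annotations

import base64
import os
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Optional

from lxml import etree

from genovault import _crypto
from genovault import policy as pol
from genovault.errors import IntegrityError, ProtectionError

if TYPE_CHECKING:  # avoid an import cycle; container imports this module
    from genovault.container import GenomicContainer

__all__ = [
    "AEAD_ALG",
    "SIG_ALG",
    "WRAP_METHOD",
    "EncryptionEntry",
    "SignatureEntry",
    "KeyWrapper",
    "ProtectionBox",
    "encrypt_target",
    "decrypt_target",
    "sign_target",
    "verify_target",
    "verify_payload",
    "wrap_key",
    "unwrap_key",
    "protection_to_xml",
    "protection_from_xml",
]

AEAD_ALG = "chacha20-poly1305"
SIG_ALG = "ed25519"
WRAP_METHOD = "scrypt-chacha20-poly1305"


@dataclass
class EncryptionEntry:
    target: str  # payload path relative to the container root
    nonce: bytes
    key_ref: str = "k0"
    algorithm: str = AEAD_ALG


@dataclass
class SignatureEntry:
    target: str
    public_key: bytes
    signature: bytes
    algorithm: str = SIG_ALG


@dataclass
class KeyWrapper:
    key_id: str
    salt: bytes
    nonce: bytes
    wrapped: bytes
    method: str = WRAP_METHOD


@dataclass
class ProtectionBox:
    """Per-level protection record: policy, encryption, signatures, keys."""

    policy: Optional[pol.Policy] = None
    encryption_entries: list[EncryptionEntry] = field(default_factory=list)
    signatures: list[SignatureEntry] = field(default_factory=list)
    wrapped_keys: list[KeyWrapper] = field(default_factory=list)

    def encryption_for(self, target: str) -> Optional[EncryptionEntry]:
        for e in self.encryption_entries:
            if e.target == target:
                return e
        return None

    def signature_for(self, target: str) -> Optional[SignatureEntry]:
        for s in self.signatures:
            if s.target == target:
                return s
        return None


# ---------------------------------------------------------------------------
# Target resolution
# ---------------------------------------------------------------------------


def _resolve(c: "GenomicContainer", target: str):
    """Map a target selector to (payload path, owning node, box file path).

    Selectors name the payload relative to the container root, e.g.
    ``dg_0/dt_1/au_0/block_2``, ``dg_0/dt_1/dtmd`` or ``dg_0/dgmd``.  The
    owning node is the hierarchy level whose protection box records the
    entry.
    """
    parts = target.split("/")
    payload_path = c.root_path.joinpath(*parts)
    leaf = parts[-1]
    try:
        if leaf.startswith("block_"):
            ids = [int(p.split("_", 1)[1]) for p in parts[:-1]]
            node = c.group(ids[0]).dataset(ids[1]).access_unit(ids[2])
            box_file = c.au_dir(*ids) / "aupr"
        elif leaf == "dtmd":
            ids = [int(p.split("_", 1)[1]) for p in parts[:-1]]
            node = c.group(ids[0]).dataset(ids[1])
            box_file = c.dataset_dir(*ids) / "dtpr"
        elif leaf == "dgmd":
            ids = [int(p.split("_", 1)[1]) for p in parts[:-1]]
            node = c.group(ids[0])
            box_file = c.group_dir(*ids) / "dgpr"
        else:
            raise ProtectionError(
                f"unsupported protection target {target!r} "
                "(expected a block, dtmd or dgmd payload)"
            )
    except (ValueError, IndexError):
        raise ProtectionError(f"malformed target selector {target!r}") from None
    if not payload_path.exists():
        raise ProtectionError(f"target payload does not exist: {target}")
    return payload_path, node, box_file


def _node_box(node) -> ProtectionBox:
    if node.protection is None:
        node.protection = ProtectionBox()
    return node.protection


def _write_box(node, box_file) -> None:
    box_file.write_bytes(protection_to_xml(node.protection))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def encrypt_target(
    c: "GenomicContainer",
    target: str,
    key: bytes,
    key_ref: str = "k0",
    rng: Optional[Callable[[int], bytes]] = None,
) -> EncryptionEntry:
    """Encrypt one payload in place and record the entry.

    Only the named payload's bytes change; everything else in the container
    is untouched except the enclosing level's protection box.
    """
    payload_path, node, box_file = _resolve(c, target)
    box = _node_box(node)
    if box.encryption_for(target) is not None:
        raise ProtectionError(f"target already encrypted: {target}")
    nonce = (rng or os.urandom)(12)
    plaintext = payload_path.read_bytes()
    ciphertext = _crypto.aead_encrypt(key, nonce, plaintext, target.encode())
    entry = EncryptionEntry(target=target, nonce=nonce, key_ref=key_ref)
    box.encryption_entries.append(entry)
    payload_path.write_bytes(ciphertext)
    _write_box(node, box_file)
    _sync_node_state(c, target, node, ciphertext)
    return entry


def _sync_node_state(c, target: str, node, ciphertext: Optional[bytes]) -> None:
    """Keep the in-memory tree consistent with the on-disk encrypted state."""
    leaf = target.rsplit("/", 1)[-1]
    if leaf.startswith("block_"):
        block = node.block(int(leaf.removeprefix("block_")))
        if ciphertext is not None:
            block.payload = ciphertext
            block.encrypted = True
    elif leaf in ("dtmd", "dgmd"):
        if ciphertext is not None:
            node.metadata_enc = ciphertext
            node.metadata = None


def decrypt_target(c: "GenomicContainer", target: str, key: bytes) -> bytes:
    """Authenticated decryption of one payload; returns the plaintext.

    The stored ciphertext is left in place.  A wrong key or a tampered
    ciphertext raises :class:`IntegrityError`; garbage is never returned.
    """
    payload_path, node, _ = _resolve(c, target)
    box = node.protection
    entry = box.encryption_for(target) if box is not None else None
    if entry is None:
        raise ProtectionError(f"no encryption entry for target: {target}")
    if entry.algorithm != AEAD_ALG:
        raise ProtectionError(f"unknown encryption algorithm {entry.algorithm!r}")
    return _crypto.aead_decrypt(
        key, entry.nonce, payload_path.read_bytes(), target.encode()
    )


def sign_target(
    c: "GenomicContainer", target: str, signing_key: bytes
) -> SignatureEntry:
    """Detached-sign a plaintext payload and record the entry.

    Signatures bind to the plaintext; to combine with encryption, sign
    first and encrypt afterwards, and verify with :func:`verify_payload`
    after decryption.
    """
    payload_path, node, box_file = _resolve(c, target)
    box = _node_box(node)
    if box.encryption_for(target) is not None:
        raise ProtectionError(
            f"target {target} is encrypted; signatures bind to the plaintext"
        )
    payload = payload_path.read_bytes()
    public = _crypto.ed25519_public_key(signing_key)
    entry = SignatureEntry(
        target=target,
        public_key=public,
        signature=_crypto.ed25519_sign(signing_key, payload),
    )
    box.signatures = [s for s in box.signatures if s.target != target]
    box.signatures.append(entry)
    _write_box(node, box_file)
    return entry


def verify_target(c: "GenomicContainer", target: str) -> bool:
    """Verify the recorded signature against the payload bytes on disk.

    True iff the payload is unchanged since signing.  For a payload that
    was encrypted after signing, decrypt first and use
    :func:`verify_payload` on the plaintext.
    """
    payload_path, node, _ = _resolve(c, target)
    return verify_payload(c, target, payload_path.read_bytes())


def verify_payload(c: "GenomicContainer", target: str, payload: bytes) -> bool:
    """Verify the recorded signature for ``target`` over caller-supplied bytes."""
    _, node, _ = _resolve(c, target)
    box = node.protection
    entry = box.signature_for(target) if box is not None else None
    if entry is None:
        raise ProtectionError(f"no signature entry for target: {target}")
    if entry.algorithm != SIG_ALG:
        raise ProtectionError(f"unknown signature algorithm {entry.algorithm!r}")
    return _crypto.ed25519_verify(entry.public_key, payload, entry.signature)


def wrap_key(
    key: bytes,
    passphrase: str,
    key_id: str = "k0",
    rng: Optional[Callable[[int], bytes]] = None,
) -> KeyWrapper:
    """Wrap a content key under a passphrase-derived key (scrypt + AEAD)."""
    salt, nonce, wrapped = _crypto.wrap_key_scrypt(key, passphrase, rng)
    return KeyWrapper(key_id=key_id, salt=salt, nonce=nonce, wrapped=wrapped)


def unwrap_key(wrapper: KeyWrapper, passphrase: str) -> bytes:
    """Recover the wrapped key; a wrong passphrase raises IntegrityError."""
    if wrapper.method != WRAP_METHOD:
        raise ProtectionError(f"unknown wrapping method {wrapper.method!r}")
    return _crypto.unwrap_key_scrypt(
        wrapper.salt, wrapper.nonce, wrapper.wrapped, passphrase
    )


# ---------------------------------------------------------------------------
# XML serialisation
# ---------------------------------------------------------------------------


def _b64(data: bytes) -> str:
    return base64.b64encode(data).decode("ascii")


def _unb64(text: Optional[str]) -> bytes:
    return base64.b64decode(text or "")


def protection_to_xml(box: ProtectionBox) -> bytes:
    root = etree.Element("Protection")
    if box.policy is not None:
        root.append(etree.fromstring(pol.serialize_policy_xml(box.policy)))
    for e in box.encryption_entries:
        etree.SubElement(
            root,
            "Encryption",
            target=e.target,
            alg=e.algorithm,
            nonce=_b64(e.nonce),
            keyRef=e.key_ref,
        )
    for s in box.signatures:
        etree.SubElement(
            root,
            "Signature",
            target=s.target,
            alg=s.algorithm,
            pubkey=_b64(s.public_key),
            value=_b64(s.signature),
        )
    for w in box.wrapped_keys:
        etree.SubElement(
            root,
            "WrappedKey",
            id=w.key_id,
            method=w.method,
            salt=_b64(w.salt),
            nonce=_b64(w.nonce),
            value=_b64(w.wrapped),
        )
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def protection_from_xml(data: bytes) -> ProtectionBox:
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ProtectionError(f"malformed protection XML: {exc}") from exc
    if root.tag != "Protection":
        raise ProtectionError(f"expected <Protection> root, got <{root.tag}>")
    box = ProtectionBox()
    for child in root:
        if not isinstance(child.tag, str):
            continue
        name = etree.QName(child).localname
        if name == "Policy":
            box.policy = pol.parse_policy_xml(etree.tostring(child))
        elif name == "Encryption":
            box.encryption_entries.append(
                EncryptionEntry(
                    target=child.get("target"),
                    nonce=_unb64(child.get("nonce")),
                    key_ref=child.get("keyRef", "k0"),
                    algorithm=child.get("alg", AEAD_ALG),
                )
            )
        elif name == "Signature":
            box.signatures.append(
                SignatureEntry(
                    target=child.get("target"),
                    public_key=_unb64(child.get("pubkey")),
                    signature=_unb64(child.get("value")),
                    algorithm=child.get("alg", SIG_ALG),
                )
            )
        elif name == "WrappedKey":
            box.wrapped_keys.append(
                KeyWrapper(
                    key_id=child.get("id"),
                    salt=_unb64(child.get("salt")),
                    nonce=_unb64(child.get("nonce")),
                    wrapped=_unb64(child.get("value")),
                    method=child.get("method", WRAP_METHOD),
                )
            )
        else:
            raise ProtectionError(f"unknown protection element <{name}>")
    return box
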