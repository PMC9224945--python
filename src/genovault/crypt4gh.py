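"""Crypt4GH-style encrypted-file envelope with range decryption.

An envelope is a header followed by data segments:

* **Header** — magic ``crypt4gh``, a version number, a packet count and one
  *header packet* per intended reader.  Each packet carries the writer's
  X25519 public key, a nonce and an AEAD-encrypted payload wrapping the
  symmetric *session key*; the AEAD key is derived from the X25519 shared
  secret of the writer's private and the reader's public key.  A reader
  attempts to decrypt every packet and ignores those that fail
  authentication — those were addressed to somebody else.  If none
  verifies, the file is unreadable for this key and an error is raised.
* **Data segments** — the plaintext split into fixed 65,536-byte chunks,
  each encrypted and authenticated independently (nonce + ciphertext +
  MAC) under the session key.  With several verified header packets, every
  collected key is tried until one authenticates the segment; a segment no
  key authenticates is an error distinct from the header failure.

Independent segments make *range* decryption possible: to serve bytes
``[P, Q)`` of the plaintext only the segments overlapping that interval
are read and decrypted.

Primitives are X25519 + ChaCha20-Poly1305.  The header-packet key is
``blake2b-256(shared_secret || reader_pk || writer_pk)``; byte-level
interoperability with other implementations of the public format is not
claimed.  Edit lists and recipient re-addition are not supported.
"""

from __future__ import annotations

import hashlib
import os
import struct
from dataclasses import dataclass
from typing import Optional, Sequence

from genovault import _crypto
from genovault.errors import (
    Crypt4ghFormatError,
    HeaderDecryptionError,
    IntegrityError,
    SegmentAuthenticationError,
)

__all__ = [
    "MAGIC",
    "VERSION",
    "SEGMENT_SIZE",
    "keygen",
    "encrypt",
    "decrypt",
    "decrypt_range",
    "Crypt4ghEnvelope",
    "parse_envelope",
]

MAGIC = b"crypt4gh"
VERSION = 1
SEGMENT_SIZE = 65536
_SEG_OVERHEAD = 12 + 16  # nonce + MAC per segment
_PACKET_METHOD_X25519 = 0
_DATA_METHOD_CHACHA20 = 0


def keygen(seed: Optional[int] = None) -> tuple[bytes, bytes]:
    """Generate an X25519 keypair; deterministic when ``seed`` is given."""
    if seed is None:
        private = os.urandom(32)
    else:
        private = hashlib.blake2b(
            seed.to_bytes(8, "little", signed=True),
            digest_size=32,
            person=b"gv-c4gh-keygen",
        ).digest()
    return private, _crypto.x25519_public_key(private)


def _packet_key(shared: bytes, reader_pk: bytes, writer_pk: bytes) -> bytes:
    return hashlib.blake2b(
        shared + reader_pk + writer_pk, digest_size=32
    ).digest()


@dataclass
class HeaderPacket:
    writer_public: bytes
    nonce: bytes
    encrypted_payload: bytes  # AEAD(method || session key)


@dataclass
class Crypt4ghEnvelope:
    version: int
    header_packets: list[HeaderPacket]
    segments: list[tuple[int, int]]  # (offset, length) of each segment record
    data: bytes  # the raw envelope bytes (segments reference into it)

    @property
    def plaintext_length(self) -> int:
        return sum(length - _SEG_OVERHEAD for _, length in self.segments)


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------


def encrypt(
    plaintext: bytes,
    writer_private: bytes,
    reader_publics: Sequence[bytes],
    rng=None,
) -> bytes:
    """Encrypt for one or more readers; all packets wrap one session key."""
    if not reader_publics:
        raise ValueError("at least one reader public key is required")
    rand = rng or os.urandom
    writer_pk = _crypto.x25519_public_key(writer_private)
    session_key = rand(32)

    out = bytearray()
    out += MAGIC
    out += struct.pack("<II", VERSION, len(reader_publics))
    packet_plain = struct.pack("<I", _DATA_METHOD_CHACHA20) + session_key
    for reader_pk in reader_publics:
        shared = _crypto.x25519(writer_private, reader_pk)
        key = _packet_key(shared, reader_pk, writer_pk)
        nonce = rand(12)
        enc = _crypto.aead_encrypt(key, nonce, packet_plain)
        body = struct.pack("<I", _PACKET_METHOD_X25519) + writer_pk + nonce + enc
        out += struct.pack("<I", 4 + len(body)) + body

    for i in range(0, len(plaintext), SEGMENT_SIZE):
        chunk = plaintext[i : i + SEGMENT_SIZE]
        nonce = rand(12)
        out += nonce + _crypto.aead_encrypt(session_key, nonce, chunk)
    return bytes(out)


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------


def parse_envelope(data: bytes) -> Crypt4ghEnvelope:
    """Split an envelope into header packets and segment extents."""
    if data[:8] != MAGIC:
        raise Crypt4ghFormatError("bad magic: not an encrypted envelope")
    if len(data) < 16:
        raise Crypt4ghFormatError("truncated header")
    version, n_packets = struct.unpack("<II", data[8:16])
    if version != VERSION:
        raise Crypt4ghFormatError(f"unsupported version {version}")
    if n_packets < 1:
        raise Crypt4ghFormatError("an envelope needs at least one header packet")
    offset = 16
    packets = []
    for _ in range(n_packets):
        if offset + 4 > len(data):
            raise Crypt4ghFormatError("truncated header packet")
        (packet_len,) = struct.unpack("<I", data[offset : offset + 4])
        end = offset + packet_len
        if packet_len < 4 + 4 + 32 + 12 + 16 or end > len(data):
            raise Crypt4ghFormatError("truncated header packet")
        (method,) = struct.unpack("<I", data[offset + 4 : offset + 8])
        if method != _PACKET_METHOD_X25519:
            raise Crypt4ghFormatError(f"unknown header packet method {method}")
        packets.append(
            HeaderPacket(
                writer_public=data[offset + 8 : offset + 40],
                nonce=data[offset + 40 : offset + 52],
                encrypted_payload=data[offset + 52 : end],
            )
        )
        offset = end
    segments = []
    while offset < len(data):
        remaining = len(data) - offset
        if remaining < _SEG_OVERHEAD:
            raise Crypt4ghFormatError("truncated data segment")
        length = min(SEGMENT_SIZE + _SEG_OVERHEAD, remaining)
        segments.append((offset, length))
        offset += length
    # all segments except possibly the last must be full-size
    for off, length in segments[:-1]:
        if length != SEGMENT_SIZE + _SEG_OVERHEAD:
            raise Crypt4ghFormatError("interior segment is not full-size")
    return Crypt4ghEnvelope(version, packets, segments, data)


def _session_keys(env: Crypt4ghEnvelope, reader_private: bytes) -> list[bytes]:
    """Trial-decrypt every header packet; collect all session keys."""
    reader_pk = _crypto.x25519_public_key(reader_private)
    keys = []
    for packet in env.header_packets:
        shared = _crypto.x25519(reader_private, packet.writer_public)
        key = _packet_key(shared, reader_pk, packet.writer_public)
        try:
            plain = _crypto.aead_decrypt(key, packet.nonce, packet.encrypted_payload)
        except IntegrityError:
            continue  # not intended for this reader
        (method,) = struct.unpack("<I", plain[:4])
        if method == _DATA_METHOD_CHACHA20 and len(plain) == 36:
            keys.append(plain[4:36])
    if not keys:
        raise HeaderDecryptionError(
            "no header packet could be verified: this file is not readable "
            "with the supplied key"
        )
    return keys


def _decrypt_segment(
    env: Crypt4ghEnvelope, extent: tuple[int, int], keys: list[bytes]
) -> bytes:
    offset, length = extent
    nonce = env.data[offset : offset + 12]
    blob = env.data[offset + 12 : offset + length]
    for key in keys:
        try:
            return _crypto.aead_decrypt(key, nonce, blob)
        except IntegrityError:
            continue
    raise SegmentAuthenticationError(
        "no decoded key authenticates this data segment"
    )


def decrypt(envelope: bytes, reader_private: bytes) -> bytes:
    """Decrypt the whole envelope."""
    env = parse_envelope(envelope)
    keys = _session_keys(env, reader_private)
    return b"".join(_decrypt_segment(env, ext, keys) for ext in env.segments)


def decrypt_range(
    envelope: bytes,
    reader_private: bytes,
    start: int,
    stop: int,
    stats: Optional[dict] = None,
) -> bytes:
    """Decrypt plaintext bytes ``[start, stop)`` touching only the segments
    that overlap the range.

    Equivalent to ``decrypt(envelope, key)[start:stop]``.  ``stats``, when
    given, receives ``segments_decrypted``.
    """
    env = parse_envelope(envelope)
    total = env.plaintext_length
    if start >= stop:
        raise ValueError(f"empty range: start {start} >= stop {stop}")
    if start < 0 or stop > total:
        raise ValueError(f"range [{start}, {stop}) outside plaintext of {total} bytes")
    keys = _session_keys(env, reader_private)
    first = start // SEGMENT_SIZE
    last = (stop - 1) // SEGMENT_SIZE  # segment containing position stop-1
    parts = [
        _decrypt_segment(env, env.segments[i], keys) for i in range(first, last + 1)
    ]
    if stats is not None:
        stats["segments_decrypted"] = last + 1 - first
    chunk = b"".join(parts)
    base = first * SEGMENT_SIZE
    return chunk[start - base : stop - base]
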