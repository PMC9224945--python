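"""Cryptographic primitives used by the protection and envelope codecs.

Self-contained implementations of the small set of modern primitives the
package needs:

* ChaCha20 stream cipher and the ChaCha20-Poly1305 AEAD construction
  (RFC 8439), with the keystream generated in parallel over 64-byte blocks
  via numpy uint32 arithmetic so that megabyte-scale payloads stay cheap.
* X25519 Diffie-Hellman over Curve25519 (RFC 7748).
* Ed25519 signatures (RFC 8032).
* scrypt-based key wrapping on top of :func:`hashlib.scrypt`.

All primitives are pinned to the published RFC test vectors in the test
suite.  They are *not* constant-time and are intended for desk-scale use
inside this package, not as a general-purpose crypto library.
"""

from __future__ import annotations

import hashlib
import hmac
import os

import numpy as np

__all__ = [
    "IntegrityError",
    "chacha20_block",
    "chacha20_xor",
    "poly1305_mac",
    "aead_encrypt",
    "aead_decrypt",
    "x25519",
    "x25519_public_key",
    "ed25519_public_key",
    "ed25519_sign",
    "ed25519_verify",
    "wrap_key_scrypt",
    "unwrap_key_scrypt",
]


class IntegrityError(Exception):
    """Authenticated decryption failed: wrong key, nonce or tampered data."""


# ---------------------------------------------------------------------------
# ChaCha20 (RFC 8439 section 2.3)
# ---------------------------------------------------------------------------

_SIGMA = np.frombuffer(b"expand 32-byte k", dtype="<u4").copy()


def _rotl(x: np.ndarray, n: int) -> np.ndarray:
    return (x << np.uint32(n)) | (x >> np.uint32(32 - n))


def _quarter(s: np.ndarray, a: int, b: int, c: int, d: int) -> None:
    s[a] += s[b]
    s[d] = _rotl(s[d] ^ s[a], 16)
    s[c] += s[d]
    s[b] = _rotl(s[b] ^ s[c], 12)
    s[a] += s[b]
    s[d] = _rotl(s[d] ^ s[a], 8)
    s[c] += s[d]
    s[b] = _rotl(s[b] ^ s[c], 7)


def _keystream(key: bytes, nonce: bytes, counter: int, nblocks: int) -> np.ndarray:
    """Keystream for ``nblocks`` consecutive 64-byte blocks, as a uint8 array."""
    if len(key) != 32 or len(nonce) != 12:
        raise ValueError("ChaCha20 needs a 32-byte key and a 12-byte nonce")
    state = np.empty((16, nblocks), dtype=np.uint32)
    state[0:4] = _SIGMA[:, None]
    state[4:12] = np.frombuffer(key, dtype="<u4")[:, None]
    # 32-bit block counter wraps; payloads here are far below 256 GiB.
    state[12] = (np.uint64(counter) + np.arange(nblocks, dtype=np.uint64)).astype(
        np.uint32
    )
    state[13:16] = np.frombuffer(nonce, dtype="<u4")[:, None]
    w = state.copy()
    with np.errstate(over="ignore"):
        for _ in range(10):
            _quarter(w, 0, 4, 8, 12)
            _quarter(w, 1, 5, 9, 13)
            _quarter(w, 2, 6, 10, 14)
            _quarter(w, 3, 7, 11, 15)
            _quarter(w, 0, 5, 10, 15)
            _quarter(w, 1, 6, 11, 12)
            _quarter(w, 2, 7, 8, 13)
            _quarter(w, 3, 4, 9, 14)
        w += state
    # Per block: 16 little-endian words in order -> transpose before flattening.
    return w.T.astype("<u4", order="C").view(np.uint8).reshape(-1)


def chacha20_block(key: bytes, nonce: bytes, counter: int) -> bytes:
    """One 64-byte ChaCha20 block (RFC 8439 section 2.3)."""
    return _keystream(key, nonce, counter, 1).tobytes()


def chacha20_xor(key: bytes, nonce: bytes, counter: int, data: bytes) -> bytes:
    """Encrypt/decrypt ``data`` with the ChaCha20 keystream."""
    if not data:
        return b""
    nblocks = (len(data) + 63) // 64
    ks = _keystream(key, nonce, counter, nblocks)[: len(data)]
    buf = np.frombuffer(data, dtype=np.uint8)
    return (buf ^ ks).tobytes()


# ---------------------------------------------------------------------------
# Poly1305 (RFC 8439 section 2.5)
# ---------------------------------------------------------------------------

_P1305 = (1 << 130) - 5


def poly1305_mac(key: bytes, msg: bytes) -> bytes:
    if len(key) != 32:
        raise ValueError("Poly1305 needs a 32-byte one-time key")
    r = int.from_bytes(key[:16], "little") & 0x0FFFFFFC0FFFFFFC0FFFFFFC0FFFFFFF
    s = int.from_bytes(key[16:], "little")
    acc = 0
    for i in range(0, len(msg), 16):
        block = msg[i : i + 16]
        n = int.from_bytes(block, "little") + (1 << (8 * len(block)))
        acc = ((acc + n) * r) % _P1305
    return ((acc + s) & ((1 << 128) - 1)).to_bytes(16, "little")


# ---------------------------------------------------------------------------
# ChaCha20-Poly1305 AEAD (RFC 8439 section 2.8)
# ---------------------------------------------------------------------------


def _pad16(n: int) -> bytes:
    return b"\x00" * (-n % 16)


def _aead_tag(otk: bytes, aad: bytes, ciphertext: bytes) -> bytes:
    mac_data = (
        aad
        + _pad16(len(aad))
        + ciphertext
        + _pad16(len(ciphertext))
        + len(aad).to_bytes(8, "little")
        + len(ciphertext).to_bytes(8, "little")
    )
    return poly1305_mac(otk, mac_data)


def aead_encrypt(key: bytes, nonce: bytes, plaintext: bytes, aad: bytes = b"") -> bytes:
    """AEAD-encrypt, returning ``ciphertext || 16-byte tag``."""
    otk = chacha20_block(key, nonce, 0)[:32]
    ct = chacha20_xor(key, nonce, 1, plaintext)
    return ct + _aead_tag(otk, aad, ct)


def aead_decrypt(key: bytes, nonce: bytes, data: bytes, aad: bytes = b"") -> bytes:
    """Verify and decrypt ``ciphertext || tag``; raise IntegrityError on failure."""
    if len(data) < 16:
        raise IntegrityError("ciphertext shorter than the authentication tag")
    ct, tag = data[:-16], data[-16:]
    otk = chacha20_block(key, nonce, 0)[:32]
    if not hmac.compare_digest(_aead_tag(otk, aad, ct), tag):
        raise IntegrityError("authentication tag mismatch")
    return chacha20_xor(key, nonce, 1, ct)


# ---------------------------------------------------------------------------
# X25519 (RFC 7748 section 5)
# ---------------------------------------------------------------------------

_P = 2**255 - 19
_A24 = 121665


def _clamp(k: bytes) -> int:
    e = bytearray(k)
    e[0] &= 248
    e[31] &= 127
    e[31] |= 64
    return int.from_bytes(e, "little")


def x25519(private_key: bytes, public_u: bytes) -> bytes:
    """Scalar multiplication on Curve25519's Montgomery u-line."""
    if len(private_key) != 32 or len(public_u) != 32:
        raise ValueError("X25519 keys are 32 bytes")
    k = _clamp(private_key)
    u = int.from_bytes(public_u, "little") & ((1 << 255) - 1)
    x1 = u
    x2, z2 = 1, 0
    x3, z3 = u, 1
    swap = 0
    for t in reversed(range(255)):
        k_t = (k >> t) & 1
        if swap ^ k_t:
            x2, x3 = x3, x2
            z2, z3 = z3, z2
        swap = k_t
        a = (x2 + z2) % _P
        aa = a * a % _P
        b = (x2 - z2) % _P
        bb = b * b % _P
        e = (aa - bb) % _P
        c = (x3 + z3) % _P
        d = (x3 - z3) % _P
        da = d * a % _P
        cb = c * b % _P
        x3 = (da + cb) % _P
        x3 = x3 * x3 % _P
        z3 = (da - cb) % _P
        z3 = x1 * z3 * z3 % _P
        x2 = aa * bb % _P
        z2 = e * (aa + _A24 * e) % _P
    if swap:
        x2, x3 = x3, x2
        z2, z3 = z3, z2
    return (x2 * pow(z2, _P - 2, _P) % _P).to_bytes(32, "little")


def x25519_public_key(private_key: bytes) -> bytes:
    return x25519(private_key, (9).to_bytes(32, "little"))


# ---------------------------------------------------------------------------
# Ed25519 (RFC 8032 section 5.1)
# ---------------------------------------------------------------------------

_L = 2**252 + 27742317777372353535851937790883648493
_D = (-121665 * pow(121666, _P - 2, _P)) % _P
_SQRT_M1 = pow(2, (_P - 1) // 4, _P)

_B_Y = 4 * pow(5, _P - 2, _P) % _P


def _recover_x(y: int, sign: int) -> int:
    if y >= _P:
        raise IntegrityError("invalid point encoding")
    x2 = (y * y - 1) * pow(_D * y * y + 1, _P - 2, _P) % _P
    if x2 == 0:
        if sign:
            raise IntegrityError("invalid point encoding")
        return 0
    x = pow(x2, (_P + 3) // 8, _P)
    if (x * x - x2) % _P != 0:
        x = x * _SQRT_M1 % _P
    if (x * x - x2) % _P != 0:
        raise IntegrityError("invalid point encoding")
    if x & 1 != sign:
        x = _P - x
    return x


_B = (_recover_x(_B_Y, 0), _B_Y, 1, _recover_x(_B_Y, 0) * _B_Y % _P)


def _pt_add(p, q):
    x1, y1, z1, t1 = p
    x2, y2, z2, t2 = q
    a = (y1 - x1) * (y2 - x2) % _P
    b = (y1 + x1) * (y2 + x2) % _P
    c = 2 * t1 * t2 * _D % _P
    d = 2 * z1 * z2 % _P
    e, f, g, h = b - a, d - c, d + c, b + a
    return (e * f % _P, g * h % _P, f * g % _P, e * h % _P)


def _pt_mul(s: int, p):
    q = (0, 1, 1, 0)
    while s > 0:
        if s & 1:
            q = _pt_add(q, p)
        p = _pt_add(p, p)
        s >>= 1
    return q


def _pt_equal(p, q) -> bool:
    # x1/z1 == x2/z2 and y1/z1 == y2/z2
    return (
        (p[0] * q[2] - q[0] * p[2]) % _P == 0
        and (p[1] * q[2] - q[1] * p[2]) % _P == 0
    )


def _pt_compress(p) -> bytes:
    zinv = pow(p[2], _P - 2, _P)
    x = p[0] * zinv % _P
    y = p[1] * zinv % _P
    return (y | ((x & 1) << 255)).to_bytes(32, "little")


def _pt_decompress(s: bytes):
    if len(s) != 32:
        raise IntegrityError("invalid point encoding")
    y = int.from_bytes(s, "little")
    sign = y >> 255
    y &= (1 << 255) - 1
    x = _recover_x(y, sign)
    return (x, y, 1, x * y % _P)


def _ed25519_secret_expand(secret: bytes):
    h = hashlib.sha512(secret).digest()
    a = _clamp(h[:32])
    return a, h[32:]


def ed25519_public_key(secret: bytes) -> bytes:
    if len(secret) != 32:
        raise ValueError("Ed25519 secret keys are 32 bytes")
    a, _ = _ed25519_secret_expand(secret)
    return _pt_compress(_pt_mul(a, _B))


def ed25519_sign(secret: bytes, msg: bytes) -> bytes:
    a, prefix = _ed25519_secret_expand(secret)
    pub = _pt_compress(_pt_mul(a, _B))
    r = int.from_bytes(hashlib.sha512(prefix + msg).digest(), "little") % _L
    r_enc = _pt_compress(_pt_mul(r, _B))
    h = int.from_bytes(hashlib.sha512(r_enc + pub + msg).digest(), "little") % _L
    s = (r + h * a) % _L
    return r_enc + s.to_bytes(32, "little")


def ed25519_verify(public: bytes, msg: bytes, signature: bytes) -> bool:
    if len(public) != 32 or len(signature) != 64:
        return False
    try:
        a_pt = _pt_decompress(public)
        r_pt = _pt_decompress(signature[:32])
    except IntegrityError:
        return False
    s = int.from_bytes(signature[32:], "little")
    if s >= _L:
        return False
    h = int.from_bytes(
        hashlib.sha512(signature[:32] + public + msg).digest(), "little"
    ) % _L
    return _pt_equal(_pt_mul(s, _B), _pt_add(r_pt, _pt_mul(h, a_pt)))


# ---------------------------------------------------------------------------
# Passphrase key wrapping (scrypt + AEAD)
# ---------------------------------------------------------------------------

_SCRYPT_N = 2**14
_SCRYPT_R = 8
_SCRYPT_P = 1


def _derive_wrapping_key(passphrase: str, salt: bytes) -> bytes:
    return hashlib.scrypt(
        passphrase.encode("utf-8"),
        salt=salt,
        n=_SCRYPT_N,
        r=_SCRYPT_R,
        p=_SCRYPT_P,
        dklen=32,
    )


def wrap_key_scrypt(
    key: bytes, passphrase: str, rng: "os.urandom.__class__ | None" = None
) -> tuple[bytes, bytes, bytes]:
    """Wrap ``key`` under a passphrase; returns (salt, nonce, wrapped)."""
    rand = rng if rng is not None else os.urandom
    salt = rand(16)
    nonce = rand(12)
    kek = _derive_wrapping_key(passphrase, salt)
    return salt, nonce, aead_encrypt(kek, nonce, key, b"genovault-key-wrap")


def unwrap_key_scrypt(salt: bytes, nonce: bytes, wrapped: bytes, passphrase: str) -> bytes:
    kek = _derive_wrapping_key(passphrase, salt)
    return aead_decrypt(kek, nonce, wrapped, b"genovault-key-wrap")
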