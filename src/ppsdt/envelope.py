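"""Asymmetric envelope for blinding nonces.

Each hospital blinds its frequency counts with a secret nonce ``z`` and ships
``z`` to the cloud sealed under the cloud's RSA public key, so the cloud — and
only the cloud — can remove the blinding homomorphically.  Sealing uses
randomized OAEP padding (SHA-1 hash and MGF1): textbook RSA on a small nonce
would be invertible by table lookup, which would defeat the blinding.  SHA-1
keeps the minimum modulus at 512 bits, small enough for fast test keys; the
padding needs only second-preimage-style randomness, not collision resistance.

One nonce is drawn per hospital per training session by default
(``NONCE_MIN`` ≤ z < ``NONCE_MAX``, a 32-bit range); session setup verifies
that ``max cell count + z`` stays below the Paillier modulus.
"""

from __future__ import annotations

import hashlib
import math
import secrets
from dataclasses import dataclass
from random import Random
from typing import Optional

from .paillier import KeyGenerationError, _random_prime

__all__ = [
    "EnvelopeError",
    "TamperError",
    "RsaKeyPair",
    "RsaPublicKey",
    "SealedNonce",
    "rsa_generate",
    "seal_nonce",
    "open_nonce",
    "random_nonce",
    "NONCE_MIN",
    "NONCE_MAX",
]

NONCE_MIN = 1
NONCE_MAX = 1 << 32  # exclusive

_HASH = hashlib.sha1
_HLEN = 20
_NONCE_BYTES = 8  # fixed-width big-endian encoding of z inside the padding


class EnvelopeError(Exception):
    """Base class for envelope failures."""


class TamperError(EnvelopeError):
    """Padding or integrity check failed on opening — ciphertext altered or wrong key."""


@dataclass(frozen=True)
class RsaPublicKey:
    modulus: int
    public_exponent: int

    @property
    def byte_length(self) -> int:
        return (self.modulus.bit_length() + 7) // 8


@dataclass(frozen=True)
class RsaKeyPair:
    modulus: int
    public_exponent: int
    private_exponent: int

    @property
    def public(self) -> RsaPublicKey:
        return RsaPublicKey(self.modulus, self.public_exponent)


@dataclass(frozen=True)
class SealedNonce:
    """OAEP-sealed nonce; opens only with the cloud's private key."""

    ciphertext: bytes
    hospital_id: str = ""


def rsa_generate(modulus_bits: int, seed: Optional[int] = None, public_exponent: int = 65537) -> RsaKeyPair:
    """Generate an RSA pair with ``e·d ≡ 1 (mod λ(n))``.

    ``modulus_bits`` ≥ 512; small keys are for tests (OAEP needs
    ``modulus ≥ 2·hLen + 2 + message`` bytes, satisfied from 512 bits up).
    """
    if modulus_bits < 512:
        raise ValueError("modulus_bits must be >= 512")
    rng = Random(seed) if seed is not None else None
    half = modulus_bits // 2
    for _ in range(1000):
        p = _random_prime(half, rng)
        q = _random_prime(modulus_bits - half, rng)
        if p == q:
            continue
        lam = math.lcm(p - 1, q - 1)
        if math.gcd(public_exponent, lam) != 1:
            continue
        d = pow(public_exponent, -1, lam)
        return RsaKeyPair(modulus=p * q, public_exponent=public_exponent, private_exponent=d)
    raise KeyGenerationError("could not assemble an RSA key pair")


def _mgf1(seed: bytes, length: int) -> bytes:
    out = b""
    for counter in range((length + _HLEN - 1) // _HLEN):
        out += _HASH(seed + counter.to_bytes(4, "big")).digest()
    return out[:length]


def _xor(a: bytes, b: bytes) -> bytes:
    return bytes(x ^ y for x, y in zip(a, b))


def seal_nonce(
    pk: RsaPublicKey, z: int, hospital_id: str = "", rng: Optional[Random] = None
) -> SealedNonce:
    """Seal a nonce under the cloud's public key with randomized OAEP padding."""
    if not NONCE_MIN <= z < NONCE_MAX:
        raise EnvelopeError(f"nonce {z} outside [{NONCE_MIN}, {NONCE_MAX})")
    k = pk.byte_length
    msg = z.to_bytes(_NONCE_BYTES, "big")
    if k < 2 * _HLEN + 2 + len(msg):
        raise EnvelopeError("RSA modulus too small for OAEP payload")
    lhash = _HASH(b"").digest()
    ps = b"\x00" * (k - len(msg) - 2 * _HLEN - 2)
    db = lhash + ps + b"\x01" + msg
    seed = (rng.randbytes(_HLEN) if rng is not None else secrets.token_bytes(_HLEN))
    masked_db = _xor(db, _mgf1(seed, k - _HLEN - 1))
    masked_seed = _xor(seed, _mgf1(masked_db, _HLEN))
    em = b"\x00" + masked_seed + masked_db
    c = pow(int.from_bytes(em, "big"), pk.public_exponent, pk.modulus)
    return SealedNonce(ciphertext=c.to_bytes(k, "big"), hospital_id=hospital_id)


def open_nonce(kp: RsaKeyPair, sealed: SealedNonce) -> int:
    """Open a sealed nonce; any padding inconsistency raises :class:`TamperError`."""
    k = (kp.modulus.bit_length() + 7) // 8
    c = int.from_bytes(sealed.ciphertext, "big")
    if len(sealed.ciphertext) != k or c >= kp.modulus:
        raise TamperError("ciphertext malformed for this key")
    em = pow(c, kp.private_exponent, kp.modulus).to_bytes(k, "big")
    if em[0] != 0:
        raise TamperError("OAEP decoding failed")
    masked_seed, masked_db = em[1 : 1 + _HLEN], em[1 + _HLEN :]
    seed = _xor(masked_seed, _mgf1(masked_db, _HLEN))
    db = _xor(masked_db, _mgf1(seed, k - _HLEN - 1))
    if db[:_HLEN] != _HASH(b"").digest():
        raise TamperError("OAEP decoding failed")
    rest = db[_HLEN:]
    sep = rest.find(b"\x01")
    if sep == -1 or any(rest[:sep]):
        raise TamperError("OAEP decoding failed")
    msg = rest[sep + 1 :]
    if len(msg) != _NONCE_BYTES:
        raise TamperError("OAEP decoding failed")
    z = int.from_bytes(msg, "big")
    if not NONCE_MIN <= z < NONCE_MAX:
        raise TamperError("recovered nonce outside the configured range")
    return z


def random_nonce(rng: Optional[Random] = None) -> int:
    """Draw a session nonce uniformly from [NONCE_MIN, NONCE_MAX)."""
    if rng is not None:
        return rng.randrange(NONCE_MIN, NONCE_MAX)
    return NONCE_MIN + secrets.randbelow(NONCE_MAX - NONCE_MIN)
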