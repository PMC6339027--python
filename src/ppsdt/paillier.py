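"""Paillier additive homomorphic cryptosystem.

The scheme works in the group :math:`\\mathbb{Z}^*_{n^2}` for an RSA-type
modulus ``n = p·q``.  A ciphertext of a plaintext ``m`` is

    c = g^m · r^n  mod n²

for a uniformly random ``r`` coprime to ``n``; decryption uses the Carmichael
value ``λ = lcm(p−1, q−1)`` and ``μ = (L(g^λ mod n²))⁻¹ mod n`` with
``L(x) = (x−1)/n``:

    m = L(c^λ mod n²) · μ  mod n

Multiplying two ciphertexts adds their plaintexts modulo ``n`` — the additive
homomorphism the secure frequency aggregation relies on.  Plaintexts here are
non-negative counts (or nonce-blinded counts); signed shifts enter only
through :func:`h_add_const`, which reduces the constant modulo ``n``.

Keys default to ``g = n + 1``, for which ``g^m mod n² = 1 + m·n`` — one
multiplication instead of a modular exponentiation.  Arbitrary generators
remain supported; the keygen check ``gcd(L(g^λ mod n²), n) = 1`` is always
performed.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
import secrets
from dataclasses import dataclass, field
from random import Random
from typing import Optional, Tuple

__all__ = [
    "PaillierError",
    "KeyGenerationError",
    "KeyMismatchError",
    "PaillierPublicKey",
    "PaillierPrivateKey",
    "PaillierCiphertext",
    "generate_keypair",
    "keypair_from_primes",
    "encrypt",
    "decrypt",
    "h_add",
    "h_add_const",
    "save_public_key",
    "save_private_key",
    "load_public_key",
    "load_private_key",
]


class PaillierError(Exception):
    """Base class for Paillier failures."""


class KeyGenerationError(PaillierError):
    """Prime search or key-consistency check failed."""


class KeyMismatchError(PaillierError):
    """A ciphertext was used with a key other than the one that produced it."""


# --------------------------------------------------------------------------
# primality — Miller–Rabin, 40 rounds (error probability ≤ 4^−40)

_MR_ROUNDS = 40
_SMALL_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47)


def is_probable_prime(n: int, rng: Optional[Random] = None, rounds: int = _MR_ROUNDS) -> bool:
    """Miller–Rabin probabilistic primality test."""
    if n < 2:
        return False
    for p in _SMALL_PRIMES:
        if n == p:
            return True
        if n % p == 0:
            return False
    d = n - 1
    s = 0
    while d % 2 == 0:
        d //= 2
        s += 1
    randbelow = rng.randrange if rng is not None else secrets.randbelow

    def _base() -> int:
        if rng is not None:
            return rng.randrange(2, n - 1)
        return 2 + secrets.randbelow(n - 3)

    for _ in range(rounds):
        a = _base()
        x = pow(a, d, n)
        if x in (1, n - 1):
            continue
        for _ in range(s - 1):
            x = (x * x) % n
            if x == n - 1:
                break
        else:
            return False
    return True


def _random_prime(bits: int, rng: Optional[Random], max_attempts: int = 100_000) -> int:
    """Uniform odd ``bits``-bit candidate with the top bit set, retried until prime."""
    for _ in range(max_attempts):
        if rng is not None:
            cand = rng.getrandbits(bits)
        else:
            cand = secrets.randbits(bits)
        cand |= (1 << (bits - 1)) | 1
        if is_probable_prime(cand, rng):
            return cand
    raise KeyGenerationError(f"no {bits}-bit prime found in {max_attempts} attempts")


# --------------------------------------------------------------------------
# key material


def _fingerprint(n: int, g: int) -> str:
    h = hashlib.sha256(f"{n:x}:{g:x}".encode()).hexdigest()
    return h[:16]


@dataclass(frozen=True)
class PaillierPublicKey:
    """Public half ``(n, g)`` of a Paillier pair; ``n²`` cached."""

    n: int
    g: int
    n_squared: int = field(init=False, repr=False)
    key_id: str = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_squared", self.n * self.n)
        object.__setattr__(self, "key_id", _fingerprint(self.n, self.g))


@dataclass(frozen=True)
class PaillierPrivateKey:
    """Private half ``(λ, μ)``; carries a copy of ``n`` for decryption."""

    lam: int
    mu: int
    n: int
    key_id: str

    @property
    def n_squared(self) -> int:
        return self.n * self.n


@dataclass(frozen=True)
class PaillierCiphertext:
    """An element of ``[1, n²)`` tagged with the fingerprint of its key."""

    value: int
    key_id: str


def _L(x: int, n: int) -> int:
    return (x - 1) // n


def keypair_from_primes(p: int, q: int, g: Optional[int] = None) -> Tuple[PaillierPublicKey, PaillierPrivateKey]:
    """Build a key pair from explicit primes (tiny keys for tests and teaching).

    ``g`` defaults to ``n + 1``.  Raises :class:`KeyGenerationError` if the
    generator lacks the required structure (``L(g^λ mod n²)`` not invertible
    modulo ``n``).
    """
    if p == q:
        raise KeyGenerationError("p and q must be distinct primes")
    n = p * q
    n2 = n * n
    lam = math.lcm(p - 1, q - 1)
    if g is None:
        g = n + 1
    if math.gcd(g, n2) != 1:
        raise KeyGenerationError("g is not a unit modulo n²")
    ell = _L(pow(g, lam, n2), n)
    if math.gcd(ell, n) != 1:
        raise KeyGenerationError("L(g^λ mod n²) is not invertible mod n; choose another g")
    mu = pow(ell, -1, n)
    pk = PaillierPublicKey(n=n, g=g)
    sk = PaillierPrivateKey(lam=lam, mu=mu, n=n, key_id=pk.key_id)
    return pk, sk


def generate_keypair(
    modulus_bits: int, seed: Optional[int] = None
) -> Tuple[PaillierPublicKey, PaillierPrivateKey]:
    """Generate a fresh pair with an ``modulus_bits``-bit modulus.

    Parameters
    ----------
    modulus_bits
        Target bit length of ``n``; at least 32.  Production use should stay
        at 2048 bits or above — small keys exist for fast tests only.
    seed
        Optional integer making generation deterministic.  Without it, primes
        come from the OS entropy source.
    """
    if modulus_bits < 32:
        raise ValueError("modulus_bits must be >= 32")
    rng = Random(seed) if seed is not None else None
    half = modulus_bits // 2
    for _ in range(1000):
        p = _random_prime(half, rng)
        q = _random_prime(modulus_bits - half, rng)
        if p == q:
            continue
        try:
            return keypair_from_primes(p, q)
        except KeyGenerationError:
            continue
    raise KeyGenerationError("could not assemble a consistent key pair")


# --------------------------------------------------------------------------
# core operations


def _check_key(obj_key_id: str, key_id: str) -> None:
    if obj_key_id != key_id:
        raise KeyMismatchError("ciphertext was produced under a different key")


def encrypt(
    pk: PaillierPublicKey,
    m: int,
    r: Optional[int] = None,
    rng: Optional[Random] = None,
) -> PaillierCiphertext:
    """Encrypt ``m ∈ [0, n)`` as ``g^m · r^n mod n²``.

    ``r`` may be fixed for reproducible vectors; otherwise it is drawn
    uniformly from the units of ``Z_n`` (rejection sampling on the gcd).
    """
    n, n2 = pk.n, pk.n_squared
    if not 0 <= m < n:
        raise ValueError(f"plaintext {m} outside [0, n)")
    if r is None:
        draw = rng.randrange if rng is not None else (lambda a, b: a + secrets.randbelow(b - a))
        while True:
            r = draw(1, n)
            if math.gcd(r, n) == 1:
                break
    elif not (1 <= r < n) or math.gcd(r, n) != 1:
        raise ValueError("randomness r must lie in [1, n) with gcd(r, n) = 1")
    if pk.g == n + 1:
        gm = (1 + m * n) % n2
    else:
        gm = pow(pk.g, m, n2)
    c = (gm * pow(r, n, n2)) % n2
    return PaillierCiphertext(value=c, key_id=pk.key_id)


def decrypt(sk: PaillierPrivateKey, c: PaillierCiphertext) -> int:
    """Recover the plaintext: ``L(c^λ mod n²) · μ mod n``."""
    _check_key(c.key_id, sk.key_id)
    n, n2 = sk.n, sk.n_squared
    return (_L(pow(c.value, sk.lam, n2), n) * sk.mu) % n


def h_add(pk: PaillierPublicKey, c1: PaillierCiphertext, c2: PaillierCiphertext) -> PaillierCiphertext:
    """Homomorphic addition: the product of ciphertexts decrypts to m1 + m2 mod n."""
    _check_key(c1.key_id, pk.key_id)
    _check_key(c2.key_id, pk.key_id)
    return PaillierCiphertext(value=(c1.value * c2.value) % pk.n_squared, key_id=pk.key_id)


def h_add_const(pk: PaillierPublicKey, c: PaillierCiphertext, k: int) -> PaillierCiphertext:
    """Homomorphic shift by a (possibly negative) constant: decrypts to m + k mod n.

    Multiplies by ``g^{k mod n}``; with ``k = −z`` this removes nonce
    blinding without any party decrypting.
    """
    _check_key(c.key_id, pk.key_id)
    n, n2 = pk.n, pk.n_squared
    k = k % n
    if pk.g == n + 1:
        gk = (1 + k * n) % n2
    else:
        gk = pow(pk.g, k, n2)
    return PaillierCiphertext(value=(c.value * gk) % n2, key_id=pk.key_id)


# --------------------------------------------------------------------------
# key files: JSON with lowercase hex fields, private material written 0600


def save_public_key(pk: PaillierPublicKey, path: str) -> None:
    with open(path, "w") as fh:
        json.dump({"n": f"{pk.n:x}", "g": f"{pk.g:x}"}, fh)


def save_private_key(sk: PaillierPrivateKey, path: str) -> None:
    fd = os.open(path, os.O_WRONLY | os.O_CREAT | os.O_TRUNC, 0o600)
    with os.fdopen(fd, "w") as fh:
        json.dump({"lambda": f"{sk.lam:x}", "mu": f"{sk.mu:x}", "n": f"{sk.n:x}"}, fh)


def load_public_key(path: str) -> PaillierPublicKey:
    with open(path) as fh:
        d = json.load(fh)
    return PaillierPublicKey(n=int(d["n"], 16), g=int(d["g"], 16))


def load_private_key(path: str) -> PaillierPrivateKey:
    with open(path) as fh:
        d = json.load(fh)
    n = int(d["n"], 16)
    g = n + 1  # key_id must match the public key's default-generator fingerprint
    return PaillierPrivateKey(
        lam=int(d["lambda"], 16), mu=int(d["mu"], 16), n=n, key_id=_fingerprint(n, g)
    )
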