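"""n-out-of-n additive secret sharing.

A secret x is split into n fragments that sum to x in the backend; each
computing party holds exactly one fragment.  Any n-1 fragments are (field
mode) uniformly distributed and reveal nothing.  Addition of two sharings
and multiplication by a public constant are local operations and cost no
communication; everything interactive lives in :mod:`mpclogit.protocols`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backends import same_backend
from .errors import ConfigurationError, DimensionError, ShareFormatError


@dataclass(frozen=True)
class Share:
    """One party's additive fragment of a scalar secret."""

    party_index: int  # 1-based
    value: object
    backend: object

    def __post_init__(self):
        if self.party_index < 1:
            raise ShareFormatError("party_index must be >= 1")


def split(x, n_parties: int, backend, rng) -> tuple[Share, ...]:
    """Split a secret scalar into ``n_parties`` additive shares.

    The first n-1 shares are drawn from the backend's masking distribution
    (uniform field elements / wide uniform reals); the last is the secret
    minus their sum, so the tuple reconstructs exactly.
    """
    if n_parties < 2:
        raise ConfigurationError("need at least 2 parties to share a secret")
    enc = backend.encode(np.asarray(x, dtype=float).reshape(()))
    masks = [backend.uniform((), rng) for _ in range(n_parties - 1)]
    last = enc
    for m in masks:
        last = backend.sub(last, m)
    values = masks + [last]
    return tuple(
        Share(party_index=i + 1, value=v[()] if hasattr(v, "shape") else v, backend=backend)
        for i, v in enumerate(values)
    )


def reconstruct(shares, decode: bool = True, expected_parties: int | None = None):
    """Sum a full tuple of shares back into the secret.

    Requires exactly one share per party index 1..n on a common backend;
    pass ``expected_parties`` to also catch a short (subset) tuple.
    """
    shares = tuple(shares)
    if not shares:
        raise ShareFormatError("empty share tuple")
    if expected_parties is not None and len(shares) != expected_parties:
        raise ShareFormatError(
            f"expected {expected_parties} shares, got {len(shares)}"
        )
    backend = shares[0].backend
    indices = sorted(s.party_index for s in shares)
    if indices != list(range(1, len(shares) + 1)):
        raise ShareFormatError(f"missing or duplicate party indices: {indices}")
    for s in shares[1:]:
        same_backend(backend, s.backend)
    total = np.asarray(shares[0].value)
    for s in shares[1:]:
        total = backend.add(total, np.asarray(s.value))
    if decode:
        return float(backend.decode(total))
    return total


class SharedMatrix:
    """A matrix secret held as per-party additive blocks.

    ``blocks[i]`` is party i+1's fragment; the elementwise backend-sum of
    all blocks equals the plaintext matrix (up to fixed-point rounding).
    """

    def __init__(self, blocks, backend):
        blocks = tuple(np.asarray(b) for b in blocks)
        if len(blocks) < 2:
            raise ConfigurationError("need at least 2 party blocks")
        shape = blocks[0].shape
        for b in blocks[1:]:
            if b.shape != shape:
                raise DimensionError("party blocks have inconsistent shapes")
        self.blocks = blocks
        self.backend = backend
        self.shape = shape

    @property
    def n_parties(self) -> int:
        return len(self.blocks)

    # -- construction ------------------------------------------------------
    @classmethod
    def share(cls, matrix, n_parties: int, backend, rng) -> "SharedMatrix":
        if n_parties < 2:
            raise ConfigurationError("need at least 2 parties")
        enc = backend.encode(np.asarray(matrix, dtype=float))
        masks = [backend.uniform(enc.shape, rng) for _ in range(n_parties - 1)]
        last = enc
        for m in masks:
            last = backend.sub(last, m)
        return cls(masks + [last], backend)

    @classmethod
    def from_public(cls, matrix, n_parties: int, backend) -> "SharedMatrix":
        """Trivial sharing of a public matrix: party 1 holds it, rest hold 0."""
        enc = backend.encode(np.asarray(matrix, dtype=float))
        zeros = [backend.zeros(enc.shape) for _ in range(n_parties - 1)]
        return cls([enc] + zeros, backend)

    # -- reconstruction ----------------------------------------------------
    def reconstruct(self, decode: bool = True):
        total = self.blocks[0]
        for b in self.blocks[1:]:
            total = self.backend.add(total, b)
        return self.backend.decode(total) if decode else total

    # -- local (communication-free) operations -----------------------------
    def _check_compat(self, other: "SharedMatrix"):
        same_backend(self.backend, other.backend)
        if self.shape != other.shape:
            raise DimensionError(f"shape mismatch: {self.shape} vs {other.shape}")
        if self.n_parties != other.n_parties:
            raise ConfigurationError("party counts differ")

    def __add__(self, other: "SharedMatrix") -> "SharedMatrix":
        self._check_compat(other)
        be = self.backend
        return SharedMatrix(
            [be.add(a, b) for a, b in zip(self.blocks, other.blocks)], be
        )

    def __sub__(self, other: "SharedMatrix") -> "SharedMatrix":
        self._check_compat(other)
        be = self.backend
        return SharedMatrix(
            [be.sub(a, b) for a, b in zip(self.blocks, other.blocks)], be
        )

    def __neg__(self) -> "SharedMatrix":
        be = self.backend
        return SharedMatrix([be.neg(b) for b in self.blocks], be)

    def scale_public_int(self, k: int) -> "SharedMatrix":
        """Multiply by a public integer (exact in both backends, local)."""
        be = self.backend
        if be.mode == "prime_field":
            kk = int(k) % be.modulus
            return SharedMatrix([be.mul(b, kk) for b in self.blocks], be)
        return SharedMatrix([b * float(k) for b in self.blocks], be)

    def add_public(self, matrix) -> "SharedMatrix":
        """Add a public matrix (applied to party 1's block only)."""
        be = self.backend
        enc = be.encode(np.broadcast_to(np.asarray(matrix, dtype=float), self.shape))
        blocks = list(self.blocks)
        blocks[0] = be.add(blocks[0], enc)
        return SharedMatrix(blocks, be)

    @property
    def T(self) -> "SharedMatrix":
        return SharedMatrix([b.T for b in self.blocks], self.backend)

    def reshape(self, *shape) -> "SharedMatrix":
        return SharedMatrix([b.reshape(*shape) for b in self.blocks], self.backend)

    def __getitem__(self, key) -> "SharedMatrix":
        return SharedMatrix([b[key] for b in self.blocks], self.backend)

    def __repr__(self):
        return f"SharedMatrix(shape={self.shape}, parties={self.n_parties}, backend={self.backend!r})"


def add_shares(x: SharedMatrix, y: SharedMatrix) -> SharedMatrix:
    """Local addition of two sharings; the ledger is never touched."""
    return x + y
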