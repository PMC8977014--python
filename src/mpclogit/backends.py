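"""Numeric backends for secret-shared arithmetic.

Two interchangeable value domains are provided:

``PrimeFieldBackend``
    Elements of Z_p for a large prime p, with reals embedded by fixed-point
    scaling (``frac_bits`` fractional bits; negatives map to the upper half
    of the field).  This is the textbook domain for additive secret sharing:
    shares are uniform field elements and hide the secret perfectly.

``RealBackend``
    Plain IEEE floats, with shares masked by uniform noise of configurable
    width.  Hiding is only statistical, but the domain supports operations a
    fixed-point ring cannot express — in particular exponentiating a share,
    which the exact secure-sigmoid path requires.

Field elements are stored in object-dtype numpy arrays of Python ints so
that 89-bit products never overflow; all backend arithmetic is elementwise.
"""

from __future__ import annotations

import numpy as np

from .errors import BackendMismatchError, EncodingRangeError

#: Mersenne prime 2^89 - 1.  Large enough that local fixed-point truncation
#: (error probability ~ 2^(magnitude_bits + 1 - 89) per operation) is safe
#: for desk-scale workloads at frac_bits = 20.
DEFAULT_MODULUS = (1 << 89) - 1


def _object_array(values, shape):
    out = np.empty(len(values), dtype=object)
    out[:] = values
    return out.reshape(shape)


class PrimeFieldBackend:
    """Fixed-point arithmetic over Z_p."""

    mode = "prime_field"

    def __init__(self, modulus: int = DEFAULT_MODULUS, frac_bits: int = 20):
        if modulus < 3 or modulus % 2 == 0:
            raise ValueError("modulus must be an odd prime >= 3")
        if frac_bits < 0:
            raise ValueError("frac_bits must be >= 0")
        self.modulus = int(modulus)
        self.frac_bits = int(frac_bits)
        self.scale = 1 << self.frac_bits
        self.half = self.modulus // 2
        # representable range: field half-range, and float64 exactness
        self.max_abs = min(self.modulus / (2.0 * self.scale), 2.0**52 / self.scale)

    # -- encoding ---------------------------------------------------------
    @property
    def tolerance(self) -> float:
        """Worst-case round-trip error of a single encode/decode."""
        return 2.0 ** (-self.frac_bits)

    def encode(self, x):
        arr = np.asarray(x, dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(np.abs(arr) >= self.max_abs):
            raise EncodingRangeError(
                f"value outside representable range (+-{self.max_abs:g})"
            )
        flat = np.rint(arr * self.scale).ravel()
        p = self.modulus
        vals = [int(v) % p for v in flat]
        return _object_array(vals, arr.shape)

    def decode(self, v):
        arr = np.asarray(v, dtype=object)
        p, half, scale = self.modulus, self.half, self.scale
        flat = [(int(e) - p if int(e) > half else int(e)) / scale for e in arr.ravel()]
        return np.asarray(flat, dtype=float).reshape(arr.shape)

    # -- elementwise ring ops ---------------------------------------------
    def zeros(self, shape):
        return _object_array([0] * int(np.prod(shape, dtype=int)), shape)

    def add(self, a, b):
        return (a + b) % self.modulus

    def sub(self, a, b):
        return (a - b) % self.modulus

    def neg(self, a):
        return (-a) % self.modulus

    def mul(self, a, b):
        return (a * b) % self.modulus

    def matmul(self, a, b):
        return np.dot(a, b) % self.modulus

    def uniform(self, shape, rng) -> np.ndarray:
        """Uniform field elements (the masking distribution for shares)."""
        n = int(np.prod(shape, dtype=int))
        words = (self.modulus.bit_length() + 63) // 64 + 1
        raw = rng.integers(0, 2**64, size=(n, words), dtype=np.uint64)
        p = self.modulus
        vals = []
        for row in raw:
            acc = 0
            for w in row:
                acc = (acc << 64) | int(w)
            vals.append(acc % p)
        return _object_array(vals, shape)

    # -- fixed-point truncation halves (used by the protocols) ------------
    def trunc_floor(self, a):
        """Party-1 half of local truncation: floor(share / 2^frac_bits)."""
        scale = self.scale
        flat = [int(e) // scale for e in np.asarray(a, dtype=object).ravel()]
        return _object_array(flat, np.asarray(a).shape)

    def trunc_complement(self, a):
        """Party-2 half: p - floor((p - share) / 2^frac_bits)."""
        p, scale = self.modulus, self.scale
        flat = [
            (p - (p - int(e)) // scale) % p
            for e in np.asarray(a, dtype=object).ravel()
        ]
        return _object_array(flat, np.asarray(a).shape)

    def __repr__(self):
        return f"PrimeFieldBackend(modulus~2^{self.modulus.bit_length()}, frac_bits={self.frac_bits})"


class RealBackend:
    """Floating-point shares masked by uniform noise of width ``mask_width``."""

    mode = "real"
    frac_bits = 0
    scale = 1

    def __init__(self, mask_width: float = 16.0):
        if mask_width <= 0:
            raise ValueError("mask_width must be positive")
        self.mask_width = float(mask_width)

    @property
    def tolerance(self) -> float:
        # float64 rounding amplified by the masking width
        return 1e-9

    def encode(self, x):
        arr = np.asarray(x, dtype=float)
        if np.any(~np.isfinite(arr)):
            raise EncodingRangeError("non-finite value")
        return arr.copy()

    def decode(self, v):
        return np.asarray(v, dtype=float)

    def zeros(self, shape):
        return np.zeros(shape, dtype=float)

    def add(self, a, b):
        return a + b

    def sub(self, a, b):
        return a - b

    def neg(self, a):
        return -a

    def mul(self, a, b):
        return a * b

    def matmul(self, a, b):
        return a @ b

    def uniform(self, shape, rng):
        return rng.uniform(-self.mask_width, self.mask_width, size=shape)

    def __repr__(self):
        return f"RealBackend(mask_width={self.mask_width})"


def same_backend(a, b):
    """Raise unless the two backends are compatible for joint arithmetic."""
    if a is b:
        return
    if type(a) is not type(b):
        raise BackendMismatchError(f"backend mismatch: {a!r} vs {b!r}")
    if isinstance(a, PrimeFieldBackend):
        if a.modulus != b.modulus or a.frac_bits != b.frac_bits:
            raise BackendMismatchError(f"field parameters differ: {a!r} vs {b!r}")


def make_backend(name: str, frac_bits: int = 20, mask_width: float = 16.0,
                 modulus: int = DEFAULT_MODULUS):
    """Build a backend from a CLI-style name: 'field' or 'real'."""
    if name in ("field", "prime_field"):
        return PrimeFieldBackend(modulus=modulus, frac_bits=frac_bits)
    if name == "real":
        return RealBackend(mask_width=mask_width)
    raise ValueError(f"unknown backend {name!r}")


# Module-level convenience wrappers (the spec-level encode/decode surface).
def encode(x, backend):
    return backend.encode(x)


def decode(v, backend):
    return backend.decode(v)
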