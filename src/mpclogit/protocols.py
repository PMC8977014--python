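"""Secure multiplication protocols over additive sharings.

Two interactive multiplication schemes are provided, matching the two
security settings:

* ``HonestMajority3`` — three computation parties, at most one corrupted.
  A product of two sharings is computed from the bilinear identity

      (x1+x2+x3)(y1+y2+y3) = sum_i  x_i*y_i + x_{p(i)}*y_i + x_i*y_{p(i)}

  where p(i) is the predecessor on the 3-cycle (p(1)=3, p(2)=1, p(3)=2).
  Each party needs its predecessor's input shares, so inputs are re-shared
  (fresh zero-sum masks), transferred one hop, combined locally, and the
  output is re-shared again.  Message accounting: 6 (input re-share, x and
  y masks bundled) + 3 (one bundled transfer per party) + 6 (output
  re-share) = 15 messages per scalar multiplication.

* ``DishonestMajority2`` — two computation parties, one corrupted, plus a
  trusted initializer that pre-distributes Beaver triples (a, b, c = a*b)
  during an offline phase.  Online, the parties open the masked differences
  d = x - a and e = y - b (2 messages each, 4 total) and combine locally:

      w_i = c_i + d*b_i + e*a_i      (+ d*e at party 1 only)

  Opening d and e is safe because a and b are uniform one-time masks.

On the fixed-point field backend every product carries a 2^frac_bits scale
surplus that is removed by local truncation (SecureML-style floor halves;
error at most 2 units in the last place).  Three-party truncation is not
purely local: party 3 first re-splits its share to the other two, the two-
party truncation runs, and a re-share restores three fresh shares; those 8
messages are ledgered under the separate ``truncation`` label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backends import PrimeFieldBackend, same_backend
from .errors import (
    ConfigurationError,
    DimensionError,
    ProtocolError,
    TripleReuseError,
)
from .ledger import CommLedger
from .shares import SharedMatrix

# 0-based predecessor map on the 3-cycle: p(1)=3, p(2)=1, p(3)=2.
PRED3 = (2, 0, 1)

HONEST_MESSAGES_PER_MULT = 15
DISHONEST_MESSAGES_PER_MULT = 4


@dataclass
class BeaverTriple:
    """A one-time multiplication triple: sharings of (a, b, a*b)."""

    a_blocks: tuple
    b_blocks: tuple
    c_blocks: tuple
    backend: object
    used: bool = field(default=False)

    @property
    def shape(self):
        return np.asarray(self.a_blocks[0]).shape

    def mark_used(self):
        if self.used:
            raise TripleReuseError("Beaver triple presented twice; triples are one-time")
        self.used = True

    def reconstruct(self):
        be = self.backend
        out = []
        for blocks in (self.a_blocks, self.b_blocks, self.c_blocks):
            total = blocks[0]
            for b in blocks[1:]:
                total = be.add(total, b)
            out.append(total)
        return tuple(out)


class TrustedInitializer:
    """Offline dealer of Beaver triples.

    Runs before any input-dependent message and never sees the parties'
    data; triple generation therefore costs zero online messages.
    """

    def __init__(self, backend, rng):
        self.backend = backend
        self.rng = rng
        self.triples_issued = 0

    def triple(self, shape=()) -> BeaverTriple:
        be, rng = self.backend, self.rng
        a = be.uniform(shape, rng)
        b = be.uniform(shape, rng)
        c = be.mul(a, b)

        def _split2(v):
            m = be.uniform(np.asarray(v).shape, rng)
            return (m, be.sub(v, m))

        self.triples_issued += 1
        return BeaverTriple(_split2(a), _split2(b), _split2(c), be)


def generate_triples(count: int, rng, backend=None) -> list[BeaverTriple]:
    """Generate ``count`` scalar Beaver triples (offline phase)."""
    if count < 1:
        raise ConfigurationError("count must be >= 1")
    if backend is None:
        backend = PrimeFieldBackend()
    dealer = TrustedInitializer(backend, rng)
    return [dealer.triple(()) for _ in range(count)]


# ---------------------------------------------------------------------------
# honest-majority 3-party protocol
# ---------------------------------------------------------------------------


class HonestMajority3:
    """Three-party semi-honest multiplication with re-sharing."""

    name = "honest3"
    n_parties = 3
    messages_per_mult = HONEST_MESSAGES_PER_MULT

    def __init__(self, backend, rng, ledger: CommLedger | None = None):
        self.backend = backend
        self.rng = rng
        self.ledger = ledger if ledger is not None else CommLedger()

    # -- helpers -----------------------------------------------------------
    def _check(self, x: SharedMatrix):
        if x.n_parties != 3:
            raise ProtocolError("honest-majority protocol requires exactly 3 parties")
        same_backend(self.backend, x.backend)

    def _fresh_blocks(self, blocks):
        """Re-randomize a 3-way sharing with 6 fresh masks (6 messages).

        Field mode uses the symmetric zero-sum pattern (party i sends one
        mask to each peer).  Real mode uses a collecting pattern instead:
        parties 2 and 3 send their masked shares to party 1, which cancels
        the accumulated magnitude of product shares — without this, float
        share magnitudes square at every chained multiplication and the
        reconstruction loses all precision.  Both patterns exchange 6
        messages and leave every new share randomized by peers' masks.
        """
        be, rng = self.backend, self.rng
        n = len(blocks)
        shape = np.asarray(blocks[0]).shape
        out = [np.asarray(b) for b in blocks]
        if be.mode == "real":
            r2, r3 = be.uniform(shape, rng), be.uniform(shape, rng)
            s2, s3 = be.uniform(shape, rng), be.uniform(shape, rng)
            t2, t3 = be.uniform(shape, rng), be.uniform(shape, rng)
            new1 = out[0] + (out[1] - r2) + (out[2] - r3) - s2 - s3
            new2 = r2 + s2 + t3 - t2
            new3 = r3 + s3 + t2 - t3
            return [new1, new2, new3]
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                r = be.uniform(shape, rng)
                out[i] = be.sub(out[i], r)
                out[j] = be.add(out[j], r)
        return out

    def reshare(self, x: SharedMatrix, label: str = "reshare") -> SharedMatrix:
        """Re-randomize a sharing; 6 messages per element (2 per party)."""
        self._check(x)
        k = int(np.prod(x.shape, dtype=int)) or 1
        self.ledger.record(label, 6 * k)
        return SharedMatrix(self._fresh_blocks(x.blocks), self.backend)

    def truncate(self, x: SharedMatrix, label: str = "truncation") -> SharedMatrix:
        """Remove one 2^frac_bits scale surplus after a fixed-point product."""
        be = self.backend
        if be.mode != "prime_field" or be.frac_bits == 0:
            return x
        k = int(np.prod(x.shape, dtype=int)) or 1
        # party 3 re-splits its share to parties 1 and 2 (2 messages/elt)
        u1 = be.uniform(x.shape, self.rng)
        u2 = be.sub(np.asarray(x.blocks[2]), u1)
        self.ledger.record(label, 2 * k)
        t1 = be.trunc_floor(be.add(np.asarray(x.blocks[0]), u1))
        t2 = be.trunc_complement(be.add(np.asarray(x.blocks[1]), u2))
        out = SharedMatrix([t1, t2, be.zeros(x.shape)], be)
        # restore three independent shares (6 messages/elt)
        self.ledger.record(label, 6 * k)
        return SharedMatrix(self._fresh_blocks(out.blocks), be)

    def rebalance(self, x: SharedMatrix, masks, label: str) -> SharedMatrix:
        """Re-share with caller-supplied masks: parties 2 and 3 send their
        masked shares to party 1 (2 messages/element); used to bound float
        share magnitudes before exponentiation."""
        self._check(x)
        k = int(np.prod(x.shape, dtype=int)) or 1
        self.ledger.record(label, 2 * k)
        be = self.backend
        r2, r3 = masks
        new1 = be.add(
            np.asarray(x.blocks[0]),
            be.add(be.sub(np.asarray(x.blocks[1]), r2),
                   be.sub(np.asarray(x.blocks[2]), r3)),
        )
        return SharedMatrix([new1, r2, r3], be)

    def refresh(self, x: SharedMatrix) -> SharedMatrix:
        """Bound float share magnitudes between iterations.

        Linear updates like 2B - BM double share magnitudes every step even
        though the value stays O(1); on the real backend the reconstruction
        error is the ulp of the share magnitude, so iterates are re-shared
        (6 messages/element, ledgered as a reshare) once per iteration.
        Field shares live mod p and need no refresh.
        """
        if self.backend.mode != "real":
            return x
        return self.reshare(x)

    def mult(self, x: SharedMatrix, y: SharedMatrix) -> SharedMatrix:
        """Elementwise secure product; 15 ledger messages per element."""
        self._check(x)
        self._check(y)
        if x.shape != y.shape:
            raise DimensionError(f"shape mismatch: {x.shape} vs {y.shape}")
        be = self.backend
        k = int(np.prod(x.shape, dtype=int)) or 1
        label = "mult_honest3"
        # input re-share: x and y masks bundled, 2 messages per party
        xb = self._fresh_blocks(x.blocks)
        yb = self._fresh_blocks(y.blocks)
        self.ledger.record(label, 6 * k)
        # each party sends its (re-shared) input pair one hop: 3 messages
        self.ledger.record(label, 3 * k)
        w = []
        for i in range(3):
            p = PRED3[i]
            term = be.mul(xb[i], yb[i])
            term = be.add(term, be.mul(xb[p], yb[i]))
            term = be.add(term, be.mul(xb[i], yb[p]))
            w.append(term)
        # output re-share: 6 messages
        w = self._fresh_blocks(w)
        self.ledger.record(label, 6 * k)
        return self.truncate(SharedMatrix(w, be))

    def mult_public(self, x: SharedMatrix, value: float) -> SharedMatrix:
        """Multiply by a public real; local except fixed-point truncation."""
        self._check(x)
        be = self.backend
        if be.mode == "real":
            return SharedMatrix([b * float(value) for b in x.blocks], be)
        enc = be.encode(np.asarray(value, dtype=float).reshape(()))
        out = SharedMatrix([be.mul(b, enc) for b in x.blocks], be)
        return self.truncate(out)

    def open(self, x: SharedMatrix, kind: str):
        """Reconstruct a shared value in the clear (all parties broadcast)."""
        self._check(x)
        k = int(np.prod(x.shape, dtype=int)) or 1
        self.ledger.record("open", 3 * 2 * k)
        self.ledger.note_opening(kind)
        return x.reconstruct()


# ---------------------------------------------------------------------------
# dishonest-majority 2-party protocol (Beaver triples)
# ---------------------------------------------------------------------------


class DishonestMajority2:
    """Two-party semi-honest multiplication via pre-distributed triples."""

    name = "dishonest2"
    n_parties = 2
    messages_per_mult = DISHONEST_MESSAGES_PER_MULT

    def __init__(self, backend, rng, ledger: CommLedger | None = None,
                 initializer: TrustedInitializer | None = None):
        self.backend = backend
        self.rng = rng
        self.ledger = ledger if ledger is not None else CommLedger()
        if initializer is None:
            initializer = TrustedInitializer(backend, rng)
        same_backend(backend, initializer.backend)
        self.initializer = initializer

    def _check(self, x: SharedMatrix):
        if x.n_parties != 2:
            raise ProtocolError("dishonest-majority protocol requires exactly 2 parties")
        same_backend(self.backend, x.backend)

    def truncate(self, x: SharedMatrix, label: str = "truncation") -> SharedMatrix:
        be = self.backend
        if be.mode != "prime_field" or be.frac_bits == 0:
            return x
        t1 = be.trunc_floor(np.asarray(x.blocks[0]))
        t2 = be.trunc_complement(np.asarray(x.blocks[1]))
        return SharedMatrix([t1, t2], be)  # fully local: 0 messages

    def mult(self, x: SharedMatrix, y: SharedMatrix,
             triple: BeaverTriple | None = None) -> SharedMatrix:
        """Elementwise Beaver product; 4 online messages per element."""
        self._check(x)
        self._check(y)
        if x.shape != y.shape:
            raise DimensionError(f"shape mismatch: {x.shape} vs {y.shape}")
        be = self.backend
        if triple is None:
            triple = self.initializer.triple(x.shape)
        else:
            same_backend(be, triple.backend)
            if triple.shape != x.shape:
                raise DimensionError("triple shape does not match operands")
        triple.mark_used()
        k = int(np.prod(x.shape, dtype=int)) or 1
        label = "mult_beaver2"
        # each party sends its (d_i, e_i) pair: 2 messages per party
        d_blocks = [be.sub(np.asarray(x.blocks[i]), triple.a_blocks[i]) for i in range(2)]
        e_blocks = [be.sub(np.asarray(y.blocks[i]), triple.b_blocks[i]) for i in range(2)]
        self.ledger.record(label, 4 * k)
        d = be.add(d_blocks[0], d_blocks[1])
        e = be.add(e_blocks[0], e_blocks[1])
        self.ledger.note_opening("beaver_d")
        self.ledger.note_opening("beaver_e")
        w = []
        for i in range(2):
            term = np.asarray(triple.c_blocks[i])
            term = be.add(term, be.mul(d, triple.b_blocks[i]))
            term = be.add(term, be.mul(e, triple.a_blocks[i]))
            if i == 0:  # the cross term enters the sum exactly once
                term = be.add(term, be.mul(d, e))
            w.append(term)
        return self.truncate(SharedMatrix(w, be))

    def mult_public(self, x: SharedMatrix, value: float) -> SharedMatrix:
        self._check(x)
        be = self.backend
        if be.mode == "real":
            return SharedMatrix([b * float(value) for b in x.blocks], be)
        enc = be.encode(np.asarray(value, dtype=float).reshape(()))
        out = SharedMatrix([be.mul(b, enc) for b in x.blocks], be)
        return self.truncate(out)

    def rebalance(self, x: SharedMatrix, masks, label: str) -> SharedMatrix:
        """Re-share with caller-supplied masks: party 2 sends its masked
        share to party 1 (1 message/element); used to bound float share
        magnitudes before exponentiation."""
        self._check(x)
        k = int(np.prod(x.shape, dtype=int)) or 1
        self.ledger.record(label, k)
        be = self.backend
        (r,) = masks
        return SharedMatrix(
            [be.add(np.asarray(x.blocks[0]), be.sub(np.asarray(x.blocks[1]), r)), r],
            be,
        )

    def refresh(self, x: SharedMatrix) -> SharedMatrix:
        """Bound float share magnitudes between iterations (see
        :meth:`HonestMajority3.refresh`); 1 message/element, ledgered as a
        reshare.  Field shares need no refresh."""
        if self.backend.mode != "real":
            return x
        return self.rebalance(
            x, [self.backend.uniform(x.shape, self.rng)], label="reshare"
        )

    def open(self, x: SharedMatrix, kind: str):
        self._check(x)
        k = int(np.prod(x.shape, dtype=int)) or 1
        self.ledger.record("open", 2 * k)
        self.ledger.note_opening(kind)
        return x.reconstruct()


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def reshare(x: SharedMatrix, rng, ledger: CommLedger) -> SharedMatrix:
    """Re-randomize a 3-party sharing (+6 ledger messages per element)."""
    return HonestMajority3(x.backend, rng, ledger).reshare(x)


def mult_honest3(x: SharedMatrix, y: SharedMatrix, rng,
                 ledger: CommLedger) -> SharedMatrix:
    """One honest-majority secure multiplication (15 messages/element)."""
    return HonestMajority3(x.backend, rng, ledger).mult(x, y)


def mult_beaver2(x: SharedMatrix, y: SharedMatrix, triple: BeaverTriple,
                 ledger: CommLedger, rng=None) -> SharedMatrix:
    """One Beaver-triple secure multiplication (4 online messages/element)."""
    if rng is None:
        rng = np.random.default_rng(0)  # unused when a triple is supplied
    proto = DishonestMajority2(x.backend, rng, ledger,
                               initializer=TrustedInitializer(x.backend, rng))
    return proto.mult(x, y, triple=triple)


def make_protocol(setting: str, backend, rng, ledger: CommLedger | None = None,
                  initializer_rng=None):
    """Build a protocol object for a security setting name."""
    if setting == "honest3":
        return HonestMajority3(backend, rng, ledger)
    if setting == "dishonest2":
        init_rng = initializer_rng if initializer_rng is not None else rng
        return DishonestMajority2(
            backend, rng, ledger,
            initializer=TrustedInitializer(backend, init_rng),
        )
    raise ConfigurationError(f"unknown security setting {setting!r}")


# ---------------------------------------------------------------------------
# triple serialization (offline phase run separately from training)
# ---------------------------------------------------------------------------


def save_triples(triples: list[BeaverTriple], path) -> None:
    """Write scalar triples to CSV (one row per triple, shares as columns)."""
    import csv

    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["a1", "a2", "b1", "b2", "c1", "c2"])
        for t in triples:
            row = []
            for blocks in (t.a_blocks, t.b_blocks, t.c_blocks):
                for b in blocks:
                    v = np.asarray(b).reshape(())[()]
                    row.append(repr(int(v)) if isinstance(v, int) else repr(float(v)))
            wr.writerow(row)


def load_triples(path, backend) -> list[BeaverTriple]:
    import csv

    conv = int if backend.mode == "prime_field" else float
    out = []
    with open(path, newline="") as fh:
        rd = csv.DictReader(fh)
        for row in rd:
            def as_arr(key):
                a = np.empty((), dtype=object if backend.mode == "prime_field" else float)
                a[()] = conv(row[key])
                return a

            out.append(BeaverTriple(
                (as_arr("a1"), as_arr("a2")),
                (as_arr("b1"), as_arr("b2")),
                (as_arr("c1"), as_arr("c2")),
                backend,
            ))
    return out
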