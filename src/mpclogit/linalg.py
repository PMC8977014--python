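"""Matrix operations on shared values, and Newton–Raphson matrix inversion.

Shared-by-shared matrix multiplication uses the naive cubic schedule: every
scalar product in C[i,k] = sum_j A[i,j]·B[j,k] is one secure multiplication,
so the ledger grows by rows·cols·inner times the per-multiplication cost.
The products themselves are evaluated in one vectorized elementwise call.

Matrix inversion follows the Nardi iteration, a Newton–Raphson scheme that
needs only additions and multiplications and therefore runs entirely under
MPC:

    B_{s+1} = 2 B_s - B_s M_s      B_0 = c^{-1} I
    M_{s+1} = 2 M_s - M_s^2        M_0 = c^{-1} X

It converges quadratically to X^{-1} whenever the spectral radius of
(I - c^{-1} X) is below 1; for symmetric positive-definite X the choice
c = trace(X) always satisfies this (trace >= largest eigenvalue).  The
trace is computed under MPC and revealed as a public scalar — an explicit,
documented leakage choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, NumericFailureError
from .shares import SharedMatrix


def _sum_axis(x: SharedMatrix, axis: int) -> SharedMatrix:
    """Local (communication-free) sum of a sharing along an axis."""
    be = x.backend
    blocks = []
    for b in x.blocks:
        s = b.sum(axis=axis)
        if be.mode == "prime_field":
            s = s % be.modulus
        blocks.append(s)
    return SharedMatrix(blocks, be)


def matmul_shared(a: SharedMatrix, b: SharedMatrix, protocol) -> SharedMatrix:
    """Secure matrix product reconstruct(a) @ reconstruct(b).

    Ledger cost: rows*inner*cols scalar multiplications at the protocol's
    per-multiplication message count.
    """
    if len(a.shape) != 2 or len(b.shape) != 2:
        raise DimensionError("matmul_shared expects 2-D sharings")
    r, q = a.shape
    q2, c = b.shape
    if q != q2:
        raise DimensionError(f"inner dimensions disagree: {a.shape} @ {b.shape}")
    be = a.backend
    ae = SharedMatrix(
        [np.broadcast_to(blk[:, :, None], (r, q, c)) for blk in a.blocks], be
    )
    bbe = SharedMatrix(
        [np.broadcast_to(blk[None, :, :], (r, q, c)) for blk in b.blocks], be
    )
    prod = protocol.mult(ae, bbe)
    return _sum_axis(prod, axis=1)


@dataclass
class NardiState:
    """Iteration state of the inversion: B_s -> X^{-1}, M_s = B_s X -> I."""

    B: SharedMatrix
    M: SharedMatrix
    s: int
    c: float


def nardi_init(x: SharedMatrix, c: float, protocol) -> NardiState:
    if len(x.shape) != 2 or x.shape[0] != x.shape[1]:
        raise DimensionError("can only invert square matrices")
    if c <= 0:
        raise NumericFailureError(f"scaling constant c must be positive, got {c}")
    m = x.shape[0]
    b0 = SharedMatrix.from_public(np.eye(m) / c, x.n_parties, x.backend)
    m0 = protocol.mult_public(x, 1.0 / c)
    return NardiState(B=b0, M=m0, s=0, c=float(c))


def nardi_step(state: NardiState, protocol) -> NardiState:
    """One update of both recurrences (two shared matrix multiplications)."""
    b2 = state.B.scale_public_int(2) - matmul_shared(state.B, state.M, protocol)
    m2 = state.M.scale_public_int(2) - matmul_shared(state.M, state.M, protocol)
    return NardiState(B=protocol.refresh(b2), M=protocol.refresh(m2),
                      s=state.s + 1, c=state.c)


def reveal_trace(x: SharedMatrix, protocol) -> float:
    """Sum the shared diagonal and open it as the public scaling constant."""
    be = x.backend
    diag_blocks = [np.diagonal(b).copy() for b in x.blocks]
    tr = _sum_axis(SharedMatrix(diag_blocks, be), axis=0)
    return float(np.asarray(protocol.open(tr.reshape(()), kind="trace")))


def invert_shared(x: SharedMatrix, protocol, n_steps: int = 30,
                  c: float | None = None, debug_plaintext: bool = False) -> SharedMatrix:
    """Approximate inverse of an SPD shared matrix via the Nardi iteration.

    ``c`` defaults to the revealed trace of X.  ``debug_plaintext``
    reconstructs the residual each step (plaintext-only diagnostics) and
    raises on divergence.
    """
    if c is None:
        c = reveal_trace(x, protocol)
    state = nardi_init(x, c, protocol)
    prev_residual = np.inf
    x_plain = x.reconstruct() if debug_plaintext else None
    for _ in range(n_steps):
        state = nardi_step(state, protocol)
        if debug_plaintext:
            residual = np.max(np.abs(state.B.reconstruct() @ x_plain - np.eye(x.shape[0])))
            if residual > 2.0 * prev_residual and residual > 1.0:
                raise NumericFailureError(
                    f"Nardi iteration diverging at step {state.s}: "
                    f"residual {residual:.3g} (bad conditioning or bad c={c:g})"
                )
            prev_residual = min(prev_residual, residual)
    return state.B
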