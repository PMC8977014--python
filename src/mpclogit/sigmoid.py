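"""Secure sigmoid evaluation on shared logits.

Two routes are provided, matching the two training algorithms:

Exact path (real backend only)
    sigma(z) = (1 + e^{-z})^{-1}.  Exponentiation uses the product trick:
    since z = z_1 + ... + z_n, each party exponentiates its own share
    locally, secret-shares the factor e^{z_i}, and the parties multiply the
    n shared factors under MPC, yielding a sharing of e^{z}.  The final
    reciprocal reuses the Nardi iteration specialized to 1x1 values.  The
    iteration with initial guess w/c converges only for w in (0, 2c); since
    w = 1 + e^{-z} is unbounded above, the sharing is first scaled by the
    public constant 2^{-k}, with k derived from a public, data-independent
    logit bound (default |z| <= 12), and the result rescaled afterwards.
    A larger bound widens the convergence basin but raises the error floor
    (each extra doubling of the prescale amplifies early rounding noise).
    The exponentials of shares are meaningless over a prime field, so the
    exact path rejects fixed-point backends.

Polynomial path (either backend)
    Degree 3/5/7 least-squares approximations of the sigmoid on [-8, 8],
    evaluated in u = z/8 with the odd-power ladder u^2, u^3 = u·u^2,
    u^5 = u^3·u^2, u^7 = u^5·u^2 (at most 4 secure multiplications per
    element).  Each polynomial is 0.5 plus an odd function, so
    g_d(z) + g_d(-z) = 1 identically.  Outside [-8, 8] the polynomials
    diverge from the sigmoid; no clipping is applied on shares because
    clipping a secret value would require a comparison protocol.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import ConfigurationError
from .shares import SharedMatrix

#: Least-squares coefficients on [-8, 8]; terms are (power, coefficient)
#: applied to u = z/8.  The 0.5 constant is handled separately.
POLY_TERMS = {
    "g3": ((1, 1.20096), (3, -0.81562)),
    "g5": ((1, 1.53048), (3, -2.3533056), (5, 1.3511295)),
    "g7": ((1, 1.73496), (3, -4.19407), (5, 5.43402), (7, -2.50739)),
}

SIGMOID_MODES = ("exact", "g3", "g5", "g7")


# ---------------------------------------------------------------------------
# plaintext references
# ---------------------------------------------------------------------------


def sigmoid(z):
    """Numerically stable plaintext logistic function."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid_poly_plaintext(z, mode: str, clip: bool = False):
    """Plaintext evaluation of the degree-3/5/7 approximation."""
    if mode not in POLY_TERMS:
        raise ConfigurationError(f"unknown polynomial sigmoid mode {mode!r}")
    z = np.asarray(z, dtype=float)
    if clip:
        z = np.clip(z, -8.0, 8.0)
    u = z / 8.0
    out = np.full_like(u, 0.5)
    for power, coeff in POLY_TERMS[mode]:
        out = out + coeff * u**power
    return out


def sigmoid_plaintext(z, mode: str = "exact", clip: bool = False):
    if mode == "exact":
        return sigmoid(z)
    return sigmoid_poly_plaintext(z, mode, clip=clip)


# ---------------------------------------------------------------------------
# secure paths
# ---------------------------------------------------------------------------


#: Mask width for exponent shares.  Exponentiation turns additive mask
#: width W into multiplicative spread e^W, and the MPC product then forms
#: intermediate terms of magnitude ~ e^(|z| + 3W) whose float rounding is
#: the dominant error (relative ~ eps * e^(3W)).  W = 4 keeps that below
#: 1e-10 while still masking logits statistically.
EXP_MASK_WIDTH = 4.0


def secure_exp(z: SharedMatrix, protocol,
               exp_mask_width: float = EXP_MASK_WIDTH) -> SharedMatrix:
    """Sharing of e^z from a sharing of z (real backend only).

    The sharing of z is first re-balanced so every share except party 1's
    is a narrow mask (see ``EXP_MASK_WIDTH``); each party then shares its
    local factor e^{z_i} (n·(n-1) messages per element) and the factors
    are multiplied under the protocol.
    """
    be = z.backend
    if be.mode != "real":
        raise ConfigurationError(
            "secure_exp needs the real backend: exponentiating prime-field "
            "shares is meaningless"
        )
    n = z.n_parties
    k = int(np.prod(z.shape, dtype=int)) or 1
    w = exp_mask_width
    masks = [protocol.rng.uniform(-w, w, size=z.shape) for _ in range(n - 1)]
    z = protocol.rebalance(z, masks, label="secure_exp_rebalance")
    factors = []
    for block in z.blocks:
        factors.append(SharedMatrix.share(np.exp(block), n, be, protocol.rng))
    protocol.ledger.record("secure_exp_share", n * (n - 1) * k)
    result = factors[0]
    for f in factors[1:]:
        result = protocol.mult(result, f)
    return result


def _reciprocal_shared(w: SharedMatrix, protocol, n_steps: int,
                       scale_pow2: int) -> SharedMatrix:
    """Elementwise 1/w via scalar Nardi with c = 2 after 2^-k prescaling."""
    inv_scale = 2.0 ** (-scale_pow2)
    ws = protocol.mult_public(w, inv_scale)  # w' in (0, 4) by construction
    c = 2.0
    b = SharedMatrix.from_public(np.full(w.shape, 1.0 / c), w.n_parties, w.backend)
    m = protocol.mult_public(ws, 1.0 / c)
    for _ in range(n_steps):
        b = protocol.refresh(b.scale_public_int(2) - protocol.mult(b, m))
        m = protocol.refresh(m.scale_public_int(2) - protocol.mult(m, m))
    return protocol.mult_public(b, inv_scale)


def sigmoid_exact(z: SharedMatrix, protocol, recip_steps: int = 40,
                  z_bound: float = 12.0) -> SharedMatrix:
    """Sharing of sigma(z) via distributed exponentiation and Nardi reciprocal.

    ``z_bound`` is the public magnitude bound on the logits that fixes the
    reciprocal prescaling; logits beyond it make the iteration diverge.
    """
    be = z.backend
    if be.mode != "real":
        raise ConfigurationError("exact sigmoid path requires the real backend")
    f = secure_exp(-z, protocol)          # e^{-z}
    w = f.add_public(np.ones(z.shape))    # 1 + e^{-z}, local
    # smallest k with (1 + e^{z_bound}) / 2^k < 2c = 4
    k = max(0, math.ceil(math.log2((1.0 + math.exp(z_bound)) / 4.0)))
    return _reciprocal_shared(w, protocol, n_steps=recip_steps, scale_pow2=k)


def sigmoid_poly(z: SharedMatrix, mode: str, protocol,
                 clip: bool = False) -> SharedMatrix:
    """Sharing of g_d(z) for d in {3, 5, 7} (either backend)."""
    if mode not in POLY_TERMS:
        raise ConfigurationError(f"unknown polynomial sigmoid mode {mode!r}")
    if clip:
        raise ConfigurationError(
            "clipping shared inputs requires a secure comparison protocol, "
            "which this package does not provide; clip is plaintext-only"
        )
    terms = dict(POLY_TERMS[mode])
    u = protocol.mult_public(z, 1.0 / 8.0)
    u2 = protocol.mult(u, u)
    powers = {1: u}
    prev = u
    for p in (3, 5, 7):
        if p > max(terms):
            break
        prev = protocol.mult(prev, u2)
        powers[p] = prev
    out = SharedMatrix.from_public(np.full(z.shape, 0.5), z.n_parties, z.backend)
    for power, coeff in terms.items():
        out = out + protocol.mult_public(powers[power], coeff)
    return out


def secure_sigmoid(z: SharedMatrix, mode: str, protocol, *,
                   recip_steps: int = 40, z_bound: float = 12.0) -> SharedMatrix:
    """Dispatch on the configured sigmoid mode."""
    if mode == "exact":
        return sigmoid_exact(z, protocol, recip_steps=recip_steps, z_bound=z_bound)
    return sigmoid_poly(z, mode, protocol)
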