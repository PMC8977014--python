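# Methods

## Problem and protocol model

Several input parties hold horizontal slices of one dataset (identical
schema, disjoint records) and want a jointly trained binary logistic
regression without revealing records. Each input party additively
secret-shares every cell to a set of computation parties; the computation
parties run the whole Newton–Raphson loop on shares; a result party sums
the final coefficient shares. All parties are semi-honest (they follow
the protocol but may inspect their view). Two settings are supported:
three computation parties with at most one corruption (honest majority),
and two computation parties plus a trusted initializer that only deals
Beaver multiplication triples offline (dishonest majority). Parties are
simulated in-process; a communication ledger at the single message choke
point counts every transfer at the granularity of one backend element,
reported as 32-bit messages.

## Estimation procedure

The log-likelihood is maximized by damped Newton steps with the constant
Böhning bound in place of the per-iteration Hessian:

    β ← β − H̃⁻¹ Xᵀ(y − π(Xβ)),   H̃ = −¼ XᵀX.

Because H̃ ⪯ H(β) for every β, the iteration converges monotonically
(linearly rather than quadratically), and H̃⁻¹ is computed once before
the loop. β starts at the zero vector, so the first iteration has
π ≡ ½. Exactly `n_iter` iterations are executed — no convergence test,
so the transcript length is data-independent. Default `n_iter = 10`,
which matches the communication accounting and is ample for the
well-conditioned designs the generator produces. An all-ones intercept
column is prepended by the data layer (default on). Labels are shared
like any other secret.

The matrix inverse is the Nardi/Newton iteration
B_{s+1} = 2B_s − B_sM_s, M_{s+1} = 2M_s − M_s² from B₀ = c⁻¹I,
M₀ = c⁻¹X, which converges quadratically when ρ(I − c⁻¹X) < 1. For SPD
X the trace dominates the largest eigenvalue, so c = trace(X) always
satisfies the condition; the trace is computed under MPC and revealed as
a public scalar — a deliberate, documented leakage (one scalar per
training run) that avoids a secure eigenvalue bound. Default 30 steps:
quadratic convergence makes that sufficient to machine precision for
condition numbers well beyond what a full-column-rank design produces.
Degenerate (rank-deficient) inputs surface as divergence, detectable
with the plaintext-debug flag of `invert_shared`.

## Numeric backends

**Prime field.** Fixed-point encoding with `frac_bits = 20` fractional
bits into Z_p, negatives in the upper half. The default modulus is the
Mersenne prime 2⁸⁹ − 1. The driver of that width is truncation: after
every fixed-point product, the 2²⁰ scale surplus is removed by local
floor-truncation halves (error ≤ 2 ulp), which fails with probability
about 2^(ℓ+1−κ) per operation, where ℓ bounds the product's magnitude
bits and κ is the modulus width. At κ = 89 that is ~2⁻³⁸ — negligible
over a full training run — whereas a 61-bit modulus would make failures
routine. Two-party truncation is purely local; with three parties the
third party first re-splits its share to the other two (2 messages),
the two-party truncation runs, and a re-share restores three fresh
shares (6 messages) — ledgered under a separate `truncation` label so
the multiplication itself retains its 15-message count.

**Real.** Shares are IEEE doubles masked by uniform noise of width
`mask_width` (default 16). Hiding is statistical only — this backend
exists because the exact-sigmoid path exponentiates shares, which a
fixed-point ring cannot express. Two numerical hazards are handled
explicitly:

* *Magnitude growth.* Sums and products of masked shares grow in
  magnitude even when the underlying value is O(1), and reconstruction
  error is the ulp of the share magnitude. The honest-majority re-share
  therefore uses a collecting pattern (parties 2 and 3 send masked
  shares to party 1, cancelling accumulated magnitude; 6 messages, same
  as the symmetric pattern), and iterative loops (Nardi, the sigmoid
  reciprocal, the β update) refresh their iterates once per step.
  Beaver multiplication is naturally self-bounding because the masked
  differences d, e are opened.
* *Exponent masking.* Before exponentiation, the logit sharing is
  re-balanced so all but one share is a narrow mask of width 4
  (`EXP_MASK_WIDTH`): mask width W costs a factor e^{3W} in relative
  float error through the product of exponentials, so W = 4 keeps that
  below 1e−10 while still masking the logits.

Per-algorithm defaults: real backend for the accurate algorithm, prime
field for the approximate one; both overridable.

## Sigmoid paths

*Exact.* Each party exponentiates its own share of −z, shares the
factor, and the factors are multiplied under MPC, giving shares of
e^{−z}; adding 1 is local. The reciprocal reuses the scalar Nardi
iteration with c = 2, which converges only for inputs in (0, 4); since
w = 1 + e^{−z} is unbounded, w is first scaled by a public constant
2^{−k} with k = ⌈log₂((1+e^{z_bound})/4)⌉ derived from a public logit
bound `z_bound` (default 12), and the result rescaled. The bound trades
coverage against accuracy: the iteration diverges for logits below
−(z_bound+0.4), while each extra doubling of the prescale amplifies the
early-iteration noise floor (measured ~2e−10 at z_bound 8, ~2e−8 at 12,
~1.5e−6 at 16 on a [−8, 8] grid). Default `recip_steps = 40` covers the
slow initial doubling phase at the default bound with margin.

*Polynomial.* The degree-3/5/7 least-squares coefficients on [−8, 8]
are hard constants; evaluation uses u = z/8 and the ladder u², u³=u·u²,
u⁵=u³·u², u⁷=u⁵·u² — 4 secure multiplications per element for degree 7.
Outside [−8, 8] the polynomials diverge from σ; no clipping is applied
on shares, because clipping a secret requires a secure comparison
protocol, which is out of scope. A clip option exists only on the
plaintext evaluator.

## Multiplication protocols and accounting

Honest majority: inputs are re-shared (x and y masks bundled; 6
messages), each party forwards its input-share pair one hop on the
3-cycle (3 messages), combines locally via the bilinear identity, and
the output is re-shared (6 messages): 15 messages per scalar
multiplication. Dishonest majority: with a pre-dealt triple
(a, b, c = ab), the parties open d = x − a and e = y − b (4 messages,
128 bits at 32-bit words) and combine as w = c + d·b + e·a + d·e, with
the d·e term added by party 1 only — adding it at every party would
double-count it in a 2-party sum. Triples are strictly one-time;
re-presenting one raises an error. Triple generation is offline (zero
ledger messages) and triples serialize to CSV so the offline phase can
run separately.

Matrix products use the naive cubic schedule (every scalar product is
one protocol multiplication, evaluated in one vectorized call), so
ledger counts are exactly rows·inner·cols times the per-multiplication
constant — predictable, at the cost of asymptotic cleverness.

The analytic communication report uses the conventional
per-multiplication constants of 420 bits (honest majority) and 128 bits
(dishonest online), an assumed 100–300 multiplications per iteration,
and 10 iterations; totals are printed in decimal Kb for the honest
setting and binary Kb for the dishonest one, the unit conventions under
which the 420 Kb and 125 Kb round figures arise. The measured ledger
reports messages and bits = messages × 32 (so a 15-message
multiplication measures 480 bits); both views are exposed side by side
and deliberately not reconciled.

## Synthetic data

The generator draws standard-normal features (optional scale), labels
from Bernoulli(σ(xᵀβ + b)) with a known coefficient vector, splits
records across a configurable number of input parties, and writes
per-party CSVs plus a truth sidecar. Draws where every label is
identical are regenerated with a warning (or rejected under a strict
flag). Default study conditions used throughout the tests: n = 500,
m = 4, β = (1, −0.5, 0.25, 0) for the MPC/plaintext agreement checks
and n = 2000, m = 5, β = (1, −0.5, 0.25, 0, 0.75), zero intercept, for
parameter recovery — sizes at which a full secure training run takes
well under a second, against the scale of real cohort studies rather
than the millions-of-records regime. What the generator does not
emulate: correlated or heavy-tailed features, separation, missing data,
covariate shift between input parties. Passing tests therefore
demonstrate protocol correctness and estimator agreement, not
robustness of logistic regression itself to messy data.

## Design choices where the design was open

* The Hessian bound is oriented as −¼XᵀX (m×m); the n×n orientation
  cannot precondition an m-vector update.
* The Beaver recombination uses the d·b/e·a pairing, the one that
  algebraically reduces to xy.
* The 15-message decomposition (6 + 3 + 6, with x and y bundled per
  message) is one defensible itemization of the known total; message
  counts, not the decomposition, are the tested contract.
* Record order after distribution is input-party index, then file row
  order; the likelihood is permutation-invariant, so this is pure
  bookkeeping.
* Every randomized operation takes an explicit generator; a single
  master seed derives separate sharing / protocol / initializer streams,
  making runs bit-reproducible in ledger counts and (real backend)
  coefficients.

## Known limitations

In-process simulation only: no sockets, serialization hardening, or
authentication. Semi-honest security; no collusion resistance beyond
the non-collusion assumption, no malicious-security machinery. Real-
backend hiding is statistical, not information-theoretic, and the
revealed inversion trace is a deliberate scalar leak. The exact sigmoid
path is undefined for logits beyond the configured public bound. No
regularization, no multi-class outcomes, no convergence-based stopping.
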