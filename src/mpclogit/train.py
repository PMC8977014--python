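"""Newton–Raphson logistic-regression training over shared data.

The estimation problem is the usual binary logistic model
P(y=1|x) = sigma(beta^T x); coefficients are found by Newton updates

    beta_new = beta_old - H^{-1} grad,   grad = X^T (y - pi)

with the Hessian replaced by the Böhning bound H~ = -1/4 X^T X, a constant
matrix that is computed and inverted (under MPC, via the Nardi iteration)
exactly once and reused in every iteration.  With that bound the update is
beta_new = beta_old + 4 (X^T X)^{-1} grad; convergence is guaranteed (though
linear rather than quadratic) because the bound dominates the true Hessian.

Two protocol variants are configured through :class:`TrainConfig`:

* ``accurate`` — exact secure sigmoid (distributed exponentiation plus a
  Nardi reciprocal); real backend.
* ``approx`` — degree 3/5/7 least-squares sigmoid polynomials; runs on the
  fixed-point field backend by default.

Training performs exactly ``n_iter`` updates with no convergence check, so
no data-dependent information leaks from an early stop; the only values
ever opened are the Beaver d/e masks, the inversion trace, and the final
coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .backends import make_backend
from .errors import ConfigurationError, DimensionError, NumericFailureError
from .ledger import CommLedger
from .linalg import invert_shared, matmul_shared
from .protocols import make_protocol
from .shares import SharedMatrix
from .sigmoid import SIGMOID_MODES, secure_sigmoid, sigmoid_plaintext

SETTINGS = ("honest3", "dishonest2")
ALGORITHMS = ("accurate", "approx")


@dataclass
class TrainConfig:
    """Everything that determines a training run.

    ``backend`` is 'real', 'field', or None for the per-algorithm default
    (real for the accurate algorithm, whose exact sigmoid needs share
    exponentials; field for the approximate algorithm).
    """

    setting: str = "honest3"
    algorithm: str = "accurate"
    sigmoid: str | None = None
    n_iter: int = 10
    nardi_steps: int = 30
    recip_steps: int = 40
    z_bound: float = 12.0
    seed: int = 0
    backend: str | None = None
    frac_bits: int = 20
    mask_width: float = 16.0
    add_intercept: bool = True

    def __post_init__(self):
        if self.setting not in SETTINGS:
            raise ConfigurationError(f"setting must be one of {SETTINGS}")
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(f"algorithm must be one of {ALGORITHMS}")
        if self.sigmoid is None:
            self.sigmoid = "exact" if self.algorithm == "accurate" else "g3"
        if self.sigmoid not in SIGMOID_MODES:
            raise ConfigurationError(f"sigmoid must be one of {SIGMOID_MODES}")
        if self.algorithm == "accurate" and self.sigmoid != "exact":
            raise ConfigurationError("the accurate algorithm uses the exact sigmoid")
        if self.algorithm == "approx" and self.sigmoid == "exact":
            raise ConfigurationError(
                "the approximate algorithm uses a polynomial sigmoid (g3/g5/g7)"
            )
        if self.n_iter < 1:
            raise ConfigurationError("n_iter must be >= 1")
        if self.backend is None:
            self.backend = "real" if self.algorithm == "accurate" else "field"

    @property
    def n_compute_parties(self) -> int:
        return 3 if self.setting == "honest3" else 2

    def resolve_backend(self):
        return make_backend(self.backend, frac_bits=self.frac_bits,
                            mask_width=self.mask_width)

    def rng_streams(self) -> dict:
        """Deterministic per-role random streams derived from the seed."""
        names = ("sharing", "protocol", "initializer", "data")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}

    def with_updates(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


@dataclass
class TrainingData:
    """Row-aligned sharings of the design matrix and the 0/1 labels."""

    X: SharedMatrix
    y: SharedMatrix

    def __post_init__(self):
        if len(self.X.shape) != 2 or len(self.y.shape) != 2 or self.y.shape[1] != 1:
            raise DimensionError("expected X of shape (n, m) and y of shape (n, 1)")
        if self.X.shape[0] != self.y.shape[0]:
            raise DimensionError("X and y disagree on the number of records")


@dataclass
class Model:
    """A trained coefficient vector plus run metadata."""

    beta: np.ndarray
    n_iter_used: int
    ledger: dict = field(default_factory=dict)
    config: TrainConfig | None = None
    feature_names: list | None = None

    def coefficients_frame(self):
        import pandas as pd

        names = self.feature_names
        if names is None:
            names = [f"x{i + 1}" for i in range(len(self.beta))]
        return pd.DataFrame({"feature": names, "coefficient": self.beta})

    def save(self, out_dir) -> None:
        """Write the coefficients CSV and a key-value run report."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.coefficients_frame().to_csv(out / "coefficients.csv", index=False)
        report = {"n_iter_used": self.n_iter_used, **self.ledger}
        if self.config is not None:
            report.update({f"config.{k}": v for k, v in vars(self.config).items()})
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# shared-training building blocks
# ---------------------------------------------------------------------------


def gradient_shared(X: SharedMatrix, y: SharedMatrix, beta: SharedMatrix,
                    sigmoid_mode: str, protocol, *, recip_steps: int = 40,
                    z_bound: float = 12.0) -> SharedMatrix:
    """Sharing of the log-likelihood gradient X^T (y - pi(X beta))."""
    z = matmul_shared(X, beta, protocol)
    pi = secure_sigmoid(z, sigmoid_mode, protocol,
                        recip_steps=recip_steps, z_bound=z_bound)
    return matmul_shared(X.T, y - pi, protocol)


def fixed_hessian_inverse(X: SharedMatrix, protocol,
                          nardi_steps: int = 30) -> SharedMatrix:
    """Sharing of (-1/4 X^T X)^{-1}, computed once before the loop."""
    s = matmul_shared(X.T, X, protocol)
    s_inv = invert_shared(s, protocol, n_steps=nardi_steps)
    return s_inv.scale_public_int(-4)


def newton_update(beta: SharedMatrix, h_inv: SharedMatrix,
                  grad: SharedMatrix, protocol) -> SharedMatrix:
    """beta - H~^{-1} grad, one shared matrix-vector product."""
    return beta - matmul_shared(h_inv, grad, protocol)


def _check_finite(shared: SharedMatrix, iteration: int) -> None:
    if shared.backend.mode != "real":
        return
    for b in shared.blocks:
        if not np.all(np.isfinite(b)):
            raise NumericFailureError(
                f"non-finite coefficient share at iteration {iteration}"
            )


def train(data: TrainingData, config: TrainConfig,
          ledger: CommLedger | None = None) -> Model:
    """Run the full privacy-preserving training loop and reveal beta.

    Executes exactly ``config.n_iter`` Newton updates (no convergence
    test), with the fixed-Hessian inverse computed once up front, starting
    from beta = 0.  Returns the reconstructed coefficients together with a
    ledger snapshot.
    """
    backend = config.resolve_backend()
    if data.X.n_parties != config.n_compute_parties:
        raise ConfigurationError(
            f"data is shared across {data.X.n_parties} parties but setting "
            f"{config.setting!r} expects {config.n_compute_parties}"
        )
    if ledger is None:
        ledger = CommLedger()
    rngs = config.rng_streams()
    protocol = make_protocol(config.setting, backend, rngs["protocol"],
                             ledger, initializer_rng=rngs["initializer"])
    m = data.X.shape[1]
    h_inv = fixed_hessian_inverse(data.X, protocol, nardi_steps=config.nardi_steps)
    beta = SharedMatrix.from_public(np.zeros((m, 1)), data.X.n_parties, backend)
    for it in range(1, config.n_iter + 1):
        grad = gradient_shared(data.X, data.y, beta, config.sigmoid, protocol,
                               recip_steps=config.recip_steps,
                               z_bound=config.z_bound)
        beta = protocol.refresh(newton_update(beta, h_inv, grad, protocol))
        _check_finite(beta, it)
    from .simulate import reveal_result  # local import: avoids module cycle

    revealed = reveal_result(beta, ledger)
    if not np.all(np.isfinite(revealed)):
        raise NumericFailureError("revealed coefficients are non-finite")
    return Model(beta=revealed, n_iter_used=config.n_iter,
                 ledger=ledger.snapshot(), config=config)


# ---------------------------------------------------------------------------
# plaintext oracle
# ---------------------------------------------------------------------------


def train_plaintext_baseline(X, y, variant: str = "fixed_hessian",
                             n_iter: int = 10, sigmoid_mode: str = "exact",
                             clip: bool = False) -> Model:
    """Ordinary (non-MPC) Newton training with the same update formulas.

    ``variant='full_newton'`` recomputes the true Hessian X^T W X each
    iteration; ``'fixed_hessian'`` uses the constant Böhning bound.  Serves
    as the agreement oracle for every shared-training test.
    """
    if variant not in ("full_newton", "fixed_hessian"):
        raise ConfigurationError("variant must be 'full_newton' or 'fixed_hessian'")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    n, m = X.shape
    beta = np.zeros(m)
    if variant == "fixed_hessian":
        h_inv_term = 4.0 * np.linalg.inv(X.T @ X)
    for it in range(n_iter):
        pi = sigmoid_plaintext(X @ beta, sigmoid_mode, clip=clip)
        grad = X.T @ (y - pi)
        if variant == "fixed_hessian":
            beta = beta + h_inv_term @ grad
        else:
            w = np.clip(pi * (1.0 - pi), 1e-12, None)
            beta = beta + np.linalg.solve(X.T @ (X * w[:, None]), grad)
        if not np.all(np.isfinite(beta)):
            raise NumericFailureError(
                f"plaintext training diverged at iteration {it + 1}"
            )
    return Model(beta=beta, n_iter_used=n_iter)
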