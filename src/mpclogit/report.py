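"""Communication-cost reporting: measured ledgers and analytic estimates.

The analytic mode reproduces the conventional cost accounting for a full
training run: a per-multiplication bit constant (420 bits in the honest-
majority setting, 128 bits online in the dishonest-majority setting),
multiplied by an assumed number of multiplications per iteration (between
100 and 300) and the iteration count (default 10).  Totals are reported in
Kb using the unit convention of the source accounting: decimal (1000-bit)
Kb for the honest-majority total, binary (1024-bit) Kb for the dishonest-
majority total.  Measured mode simply snapshots an actual run's ledger.
"""

from __future__ import annotations

from .errors import ConfigurationError
from .ledger import CommLedger
from .protocols import DISHONEST_MESSAGES_PER_MULT, HONEST_MESSAGES_PER_MULT

#: Conventional per-multiplication bit constants used by the analytic mode.
ANALYTIC_BITS_PER_MULT = {"honest3": 420, "dishonest2": 128}
#: Kb divisor convention per setting (see module docstring).
KB_DIVISOR = {"honest3": 1000, "dishonest2": 1024}

MULTS_PER_ITER_RANGE = (100, 300)


def message_ratio() -> float:
    """Honest-majority / dishonest-majority online messages per multiplication."""
    return HONEST_MESSAGES_PER_MULT / DISHONEST_MESSAGES_PER_MULT


def analytic_total_kb(setting: str, n_iter: int = 10,
                      mults_per_iter: int = 100) -> float:
    """Lower-bound data volume (Kb) for a whole training run."""
    if setting not in ANALYTIC_BITS_PER_MULT:
        raise ConfigurationError(f"unknown setting {setting!r}")
    lo, hi = MULTS_PER_ITER_RANGE
    if not lo <= mults_per_iter <= hi:
        raise ConfigurationError(
            f"mults_per_iter outside the analytic range {lo}-{hi}"
        )
    bits = ANALYTIC_BITS_PER_MULT[setting] * mults_per_iter * n_iter
    return bits / KB_DIVISOR[setting]


def comm_report(setting: str, n_iter: int = 10, mults_per_iter: int = 100,
                ledger: CommLedger | None = None) -> dict:
    """Analytic estimate plus, when a ledger is given, the measured counts."""
    report = {
        "setting": setting,
        "analytic.bits_per_mult": ANALYTIC_BITS_PER_MULT[setting],
        "analytic.messages_per_mult": (
            HONEST_MESSAGES_PER_MULT if setting == "honest3"
            else DISHONEST_MESSAGES_PER_MULT
        ),
        "analytic.n_iter": n_iter,
        "analytic.mults_per_iter": mults_per_iter,
        "analytic.total_kb": analytic_total_kb(setting, n_iter, mults_per_iter),
        "analytic.message_ratio": message_ratio(),
    }
    if ledger is not None:
        for key, value in ledger.snapshot().items():
            report[f"measured.{key}"] = value
    return report
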