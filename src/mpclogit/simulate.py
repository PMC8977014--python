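"""Party orchestration, partitioned-data I/O and synthetic data generation.

Roles: one or more *input parties* each hold a horizontal slice of the
records (identical schema); 2 or 3 *computation parties* receive additive
shares of every cell and never see plaintext data; a *trusted initializer*
(dishonest-majority setting only) deals Beaver triples offline; the
*result party* sums the coefficient shares at the end.  All parties are
simulated in-process; every transfer is counted on the communication
ledger, which is the single choke point for accounting.

The synthetic generator emulates the intended input: standard-normal
features, labels drawn from Bernoulli(sigma(x^T beta + intercept)) with a
known coefficient vector, records split across a configurable number of
input parties and written as per-party CSV files with a truth sidecar.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ProtocolError, SchemaMismatchError
from .ledger import CommLedger
from .shares import SharedMatrix
from .sigmoid import sigmoid
from .train import TrainingData

LABEL_COLUMN = "y"


@dataclass(frozen=True)
class PartyTopology:
    """Who participates: input parties, compute parties, optional dealer."""

    n_input_parties: int = 1
    n_compute_parties: int = 3
    has_trusted_initializer: bool = False

    def __post_init__(self):
        if self.n_input_parties < 1:
            raise ConfigurationError("need at least one input party")
        if self.n_compute_parties not in (2, 3):
            raise ConfigurationError("supported compute-party counts: 2 or 3")
        if self.n_compute_parties == 2 and not self.has_trusted_initializer:
            raise ConfigurationError(
                "the 2-party (dishonest-majority) setting requires a trusted "
                "initializer for Beaver triples"
            )
        if self.n_compute_parties == 3 and self.has_trusted_initializer:
            raise ConfigurationError(
                "the 3-party (honest-majority) setting uses no trusted initializer"
            )

    @classmethod
    def for_setting(cls, setting: str, n_input_parties: int = 1) -> "PartyTopology":
        if setting == "honest3":
            return cls(n_input_parties, 3, False)
        if setting == "dishonest2":
            return cls(n_input_parties, 2, True)
        raise ConfigurationError(f"unknown security setting {setting!r}")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic logistic population."""

    n_records: int = 2000
    m_features: int = 5
    true_beta: np.ndarray = field(default_factory=lambda: np.array([1.0, -0.5, 0.25, 0.0, 0.75]))
    intercept: float = 0.0
    feature_scale: float = 1.0
    partition: tuple | None = None  # records per input party; None = single party
    seed: int = 0
    strict: bool = False

    def __post_init__(self):
        self.true_beta = np.asarray(self.true_beta, dtype=float)
        if len(self.true_beta) != self.m_features:
            raise ConfigurationError("true_beta length must equal m_features")
        if self.partition is None:
            self.partition = (self.n_records,)
        self.partition = tuple(int(c) for c in self.partition)
        if sum(self.partition) != self.n_records or any(c < 1 for c in self.partition):
            raise ConfigurationError("partition must be positive counts summing to n_records")


def generate_logistic_data(spec: SyntheticSpec, rng=None):
    """Draw (X, y) from the Bernoulli-logistic model of the spec.

    Degenerate draws (all labels identical) are redrawn with a warning, or
    rejected outright when ``spec.strict`` is set.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    for attempt in range(10):
        X = rng.standard_normal((spec.n_records, spec.m_features)) * spec.feature_scale
        p = sigmoid(X @ spec.true_beta + spec.intercept)
        y = (rng.uniform(size=spec.n_records) < p).astype(int)
        if 0 < y.sum() < spec.n_records:
            if attempt > 0:
                warnings.warn(f"degenerate labels; regenerated ({attempt} retries)")
            return X, y
        if spec.strict:
            raise ConfigurationError(
                "degenerate synthetic labels (all one class) under strict mode"
            )
    raise ConfigurationError("could not generate non-degenerate labels in 10 attempts")


def generate_synthetic(spec: SyntheticSpec, out_dir) -> list[Path]:
    """Write horizontally partitioned per-party CSVs plus a truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X, y = generate_logistic_data(spec)
    columns = [f"x{j + 1}" for j in range(spec.m_features)]
    paths = []
    start = 0
    for i, count in enumerate(spec.partition, start=1):
        frame = pd.DataFrame(X[start:start + count], columns=columns)
        frame[LABEL_COLUMN] = y[start:start + count]
        path = out / f"party{i}.csv"
        frame.to_csv(path, index=False)
        paths.append(path)
        start += count
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "true_beta": list(spec.true_beta),
                "intercept": spec.intercept,
                "seed": spec.seed,
                "partition": list(spec.partition),
                "label_prevalence": float(np.mean(y)),
            },
            fh,
            indent=2,
        )
    return paths


def load_partitions(paths) -> pd.DataFrame:
    """Read per-party CSVs, check schemas, concatenate in canonical order.

    Canonical record order is input-party index ascending, then file row
    order.  All parties must present identical column sets including the
    label column 'y'.
    """
    frames = [pd.read_csv(p) for p in paths]
    if not frames:
        raise ConfigurationError("no input files")
    schema = list(frames[0].columns)
    if LABEL_COLUMN not in schema:
        raise SchemaMismatchError(f"label column {LABEL_COLUMN!r} missing")
    for p, f in zip(paths, frames):
        if list(f.columns) != schema:
            raise SchemaMismatchError(
                f"{p}: columns {list(f.columns)} differ from {schema}"
            )
    data = pd.concat(frames, ignore_index=True)
    labels = data[LABEL_COLUMN].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        raise SchemaMismatchError("labels must be 0/1")
    return data


def distribute_inputs(data, topology: PartyTopology, backend, rng,
                      add_intercept: bool = True) -> TrainingData:
    """Split every cell into one share per computation party.

    ``data`` is either a concatenated DataFrame (from ``load_partitions``)
    or a plain (X, y) pair.  An all-ones intercept column is prepended when
    requested.
    """
    if isinstance(data, tuple):
        X, y = data
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
    else:
        X = data.drop(columns=[LABEL_COLUMN]).to_numpy(dtype=float)
        y = data[LABEL_COLUMN].to_numpy(dtype=float).reshape(-1, 1)
    if add_intercept:
        X = np.hstack([np.ones((X.shape[0], 1)), X])
    n = topology.n_compute_parties
    return TrainingData(
        X=SharedMatrix.share(X, n, backend, rng),
        y=SharedMatrix.share(y, n, backend, rng),
    )


def reveal_result(beta_shared: SharedMatrix, ledger: CommLedger | None = None):
    """Result party: sum the coefficient shares and decode.

    Each computation party sends its full coefficient-share vector as one
    message; nothing else is ever reconstructed during training.
    """
    if beta_shared.n_parties < 2:
        raise ProtocolError("reveal needs one share vector per compute party")
    if ledger is not None:
        ledger.record("reveal", beta_shared.n_parties)
        ledger.note_opening("result")
    return np.asarray(beta_shared.reconstruct(), dtype=float).reshape(-1)


def load_config_file(path) -> dict:
    """Read a JSON config file mirroring the CLI flags."""
    with open(path) as fh:
        return json.load(fh)
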