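"""Relative importance of the four PET inputs via a small neural network.

A 4-9-2 feed-forward network (logistic activations, one hidden layer) maps
the station-hour weather state (T_a, T_mrt, v, RH) to the fatal and injury
outcome of that hour.  After training, Garson's connection-weight
decomposition attributes the network's input-output weight structure to the
four inputs:

    Q_i = sum_h sum_o ( |w_ih| / sum_k |w_kh| ) * |v_ho| ,   normalised so
    sum_i Q_i = 1.

Olden's signed variant (sum over paths of w_ih * v_ho, no normalisation by
hidden-unit totals) is available behind a flag for sensitivity checks.

Training is deliberately plain and fully seeded: min-max input (and target)
scaling to [0, 1], a 70/30 train/test split, full-batch gradient descent
with momentum on the mean squared error, and a pooled R^2 on the test split
as the fit diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import working_hour_mask

FEATURES = ("ta", "tmrt", "v", "rh")
TARGETS = ("fatal", "injury")


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkSpec:
    n_inputs: int = 4
    hidden_units: int = 9
    n_outputs: int = 2
    train_fraction: float = 0.70
    seed: int = 0
    learning_rate: float = 0.1
    momentum: float = 0.9
    max_epochs: int = 5000
    loss_tol: float = 1e-8        # early stop on |delta loss|
    target_encoding: str = "count"  # count | binary

    def __post_init__(self):
        if min(self.n_inputs, self.hidden_units, self.n_outputs) < 1:
            raise ValidationError("layer sizes must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must lie in (0, 1)")


@dataclass
class TrainedNetwork:
    spec: NetworkSpec
    w_hidden: np.ndarray   # (n_inputs + 1, hidden): last row is the bias
    w_output: np.ndarray   # (hidden + 1, n_outputs): last row is the bias
    feature_names: tuple[str, ...]
    r2: float
    epochs: int
    final_loss: float
    converged: bool
    x_min: np.ndarray
    x_range: np.ndarray

    @property
    def input_weights(self) -> np.ndarray:
        """(n_inputs, hidden) weight matrix, biases excluded."""
        return self.w_hidden[:-1, :]

    @property
    def output_weights(self) -> np.ndarray:
        """(hidden, n_outputs) weight matrix, biases excluded."""
        return self.w_output[:-1, :]


@dataclass(frozen=True)
class ImportanceResult:
    importances: dict[str, float]
    r2: float
    epochs: int
    final_loss: float
    method: str

    def __post_init__(self):
        total = sum(self.importances.values())
        if self.method == "garson":
            assert abs(total - 1.0) < 1e-9


def build_dataset(
    linked: pd.DataFrame,
    climate: pd.DataFrame,
    working_hours: tuple[int, int] = (7, 18),
    encoding: str = "count",
) -> pd.DataFrame:
    """One row per working station-hour: weather features and the fatal /
    injury outcome of that (city, district, hour).

    ``encoding='count'`` stores event counts; ``'binary'`` presence flags.
    Hours with no events keep zero targets — the feature rows are the
    exposure denominator, not just the accident hours.
    """
    if encoding not in ("count", "binary"):
        raise ValidationError(f"unknown target encoding {encoding!r}")
    for col in ("city", "district", "timestamp", *FEATURES):
        if col not in climate.columns:
            raise ValidationError(f"climate lacks column {col!r}")

    clim = climate.copy()
    clim["timestamp"] = pd.DatetimeIndex(clim["timestamp"])
    mask = working_hour_mask(pd.DatetimeIndex(clim["timestamp"]), working_hours)
    table = clim.loc[mask, ["city", "district", "timestamp", *FEATURES]]
    if len(table) == 0:
        raise ValidationError("no working station-hours in the climate frame")

    if len(linked):
        ev = linked.copy()
        ev["timestamp"] = pd.DatetimeIndex(ev["timestamp"]).floor("h")
        counts = (
            ev.groupby(["city", "district", "timestamp", "severity"])
            .size()
            .unstack("severity", fill_value=0)
            .reset_index()
        )
        table = table.merge(counts, on=["city", "district", "timestamp"],
                            how="left")
    for t in TARGETS:
        if t not in table.columns:
            table[t] = 0
    table[list(TARGETS)] = table[list(TARGETS)].fillna(0).astype(int)
    if encoding == "binary":
        table[list(TARGETS)] = (table[list(TARGETS)] > 0).astype(int)
    return table.reset_index(drop=True)


def _minmax(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lo = x.min(axis=0)
    rng = x.max(axis=0) - lo
    rng = np.where(rng == 0, 1.0, rng)
    return (x - lo) / rng, lo, rng


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def train_network(table: pd.DataFrame, spec: NetworkSpec = NetworkSpec()
                  ) -> TrainedNetwork:
    """Fit the 4-9-2 logistic network by full-batch gradient descent with
    momentum on the 70% split; R^2 is pooled over both outputs on the 30%
    test split (SST = 0 yields R^2 = 0 by convention)."""
    if len(table) < 100:
        raise ValidationError("at least 100 rows are required for training")
    x = table.loc[:, list(FEATURES)].to_numpy(float)
    y = table.loc[:, list(TARGETS)].to_numpy(float)
    if spec.target_encoding == "binary":
        y = (y > 0).astype(float)

    x, x_min, x_range = _minmax(x)
    y, _, _ = _minmax(y)

    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(x))
    n_train = int(round(spec.train_fraction * len(x)))
    tr, te = perm[:n_train], perm[n_train:]
    xtr, ytr, xte, yte = x[tr], y[tr], x[te], y[te]

    n_in, n_hid, n_out = spec.n_inputs, spec.hidden_units, spec.n_outputs
    if x.shape[1] != n_in or y.shape[1] != n_out:
        raise ValidationError("table shape does not match the network spec")
    w1 = rng.uniform(-0.5, 0.5, size=(n_in + 1, n_hid))
    w2 = rng.uniform(-0.5, 0.5, size=(n_hid + 1, n_out))
    v1 = np.zeros_like(w1)
    v2 = np.zeros_like(w2)

    ones_tr = np.ones((len(xtr), 1))
    prev_loss = np.inf
    loss = np.inf
    epoch = 0
    converged = False
    for epoch in range(1, spec.max_epochs + 1):
        a1 = np.hstack([xtr, ones_tr])
        h = _sigmoid(a1 @ w1)
        a2 = np.hstack([h, ones_tr])
        out = _sigmoid(a2 @ w2)

        err = out - ytr
        loss = float(np.mean(err**2))
        if abs(prev_loss - loss) < spec.loss_tol:
            converged = True
            break
        prev_loss = loss

        delta_out = 2.0 * err * out * (1.0 - out) / err.size
        grad2 = a2.T @ delta_out
        delta_hid = (delta_out @ w2[:-1].T) * h * (1.0 - h)
        grad1 = a1.T @ delta_hid

        v2 = spec.momentum * v2 - spec.learning_rate * grad2
        v1 = spec.momentum * v1 - spec.learning_rate * grad1
        w2 = w2 + v2
        w1 = w1 + v1

    def predict(xm):
        ones = np.ones((len(xm), 1))
        h = _sigmoid(np.hstack([xm, ones]) @ w1)
        return _sigmoid(np.hstack([h, ones]) @ w2)

    pred = predict(xte)
    sse = float(np.sum((yte - pred) ** 2))
    sst = float(np.sum((yte - yte.mean(axis=0)) ** 2))
    r2 = 0.0 if sst == 0.0 else 1.0 - sse / sst

    return TrainedNetwork(
        spec=spec, w_hidden=w1, w_output=w2, feature_names=FEATURES,
        r2=r2, epochs=epoch, final_loss=loss, converged=converged,
        x_min=x_min, x_range=x_range,
    )


def garson_importance(model: TrainedNetwork, method: str = "garson"
                      ) -> ImportanceResult:
    """Connection-weight importance of each input.

    ``garson``: per hidden unit, each input owns the share |w_ih| of the
    unit's total absolute input weight; shares are weighted by the unit's
    absolute output weights, summed over outputs, and normalised to 1.
    ``olden``: signed sums of w_ih * v_ho over hidden units and outputs
    (not normalised to 1; signs are informative).
    """
    w = model.input_weights      # (n_in, n_hid)
    v = model.output_weights     # (n_hid, n_out)
    if np.all(w == 0) or np.all(v == 0):
        raise ValidationError("all-zero weights: importance undefined")
    if method == "garson":
        share = np.abs(w) / np.abs(w).sum(axis=0, keepdims=True)
        contrib = share @ np.abs(v)          # (n_in, n_out)
        q = contrib.sum(axis=1)
        q = q / q.sum()
    elif method == "olden":
        q = (w @ v).sum(axis=1)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return ImportanceResult(
        importances=dict(zip(model.feature_names, (float(x) for x in q))),
        r2=model.r2, epochs=model.epochs, final_loss=model.final_loss,
        method=method,
    )
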