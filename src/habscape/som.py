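"""Kohonen self-organizing feature map for basin zoning.

A small neuron grid (2x2 by default, so each neuron is one zone) quantizes
the four standardized basin indicators (Q, NTL, POP, LUR).  Training is the
classic online rule: for each sample, the best-matching unit (BMU) by
Euclidean distance is found and every neuron's weight vector is pulled toward
the sample with a strength given by the learning rate times a Gaussian
neighbourhood function on the neuron grid; both the learning rate and the
neighbourhood radius decay exponentially over epochs.  The map preserves
topology — neighbouring neurons end up with more similar weights than distant
ones — which is what makes the zoning stable.

Zones are labelled A, B, C, D by *descending* mean member SUM (the sum of
the four standardized indicators), so A is always the highest joint
development level regardless of neuron indexing.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SOMSchedule", "SOMModel", "ZoneAssignment", "train_som", "assign_zones"]


@dataclass(frozen=True)
class SOMSchedule:
    """Exponentially decaying learning-rate / neighbourhood-radius schedule."""

    epochs: int = 500
    lr_initial: float = 0.5
    lr_final: float = 0.01
    radius_initial: float = 1.0
    radius_final: float = 0.1

    def __post_init__(self) -> None:
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        for a, b, name in (
            (self.lr_initial, self.lr_final, "learning rate"),
            (self.radius_initial, self.radius_final, "radius"),
        ):
            if a <= 0 or b <= 0 or b > a:
                raise ValueError(f"{name} schedule must be positive and non-increasing")

    def at(self, epoch: int) -> tuple[float, float]:
        """(learning rate, radius) at a 0-based epoch."""
        t = epoch / max(self.epochs - 1, 1)
        lr = self.lr_initial * (self.lr_final / self.lr_initial) ** t
        rad = self.radius_initial * (self.radius_final / self.radius_initial) ** t
        return lr, rad


@dataclass
class SOMModel:
    """Trained map: per-neuron weight vectors on a rows x cols neuron grid."""

    weights: np.ndarray  # (rows*cols, dim)
    grid_shape: tuple[int, int]
    schedule: SOMSchedule
    seed: int
    quantization_errors: np.ndarray = field(repr=False, default=None)

    @property
    def n_neurons(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    @property
    def neuron_positions(self) -> np.ndarray:
        rows, cols = self.grid_shape
        r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return np.column_stack([r.ravel(), c.ravel()]).astype(float)

    def bmu(self, data: np.ndarray) -> np.ndarray:
        """Index of the best-matching unit for each sample row."""
        data = np.atleast_2d(np.asarray(data, dtype=float))
        d2 = ((data[:, None, :] - self.weights[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def quantization_error(self, data: np.ndarray) -> float:
        data = np.atleast_2d(np.asarray(data, dtype=float))
        d = np.linalg.norm(data[:, None, :] - self.weights[None, :, :], axis=2)
        return float(d.min(axis=1).mean())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "grid_shape": list(self.grid_shape),
            "weights": self.weights.tolist(),
            "seed": self.seed,
            "schedule": {
                "epochs": self.schedule.epochs,
                "lr_initial": self.schedule.lr_initial,
                "lr_final": self.schedule.lr_final,
                "radius_initial": self.schedule.radius_initial,
                "radius_final": self.schedule.radius_final,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def train_som(
    data: np.ndarray,
    grid_shape: tuple[int, int] = (2, 2),
    schedule: SOMSchedule | None = None,
    seed: int = 0,
) -> SOMModel:
    """Train a SOM with classic online Kohonen updates.

    Weights are initialized from random data samples (seeded).  Per epoch the
    sample order is reshuffled; for each sample x the BMU b is found and every
    neuron j updated as ``w_j += lr * h(j, b) * (x - w_j)`` with the Gaussian
    neighbourhood ``h = exp(-d_grid(j, b)^2 / (2 radius^2))``.  Deterministic
    given seed.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValueError("empty training data")
    if not np.isfinite(data).all():
        raise ValueError("training data contains non-finite values")
    schedule = schedule or SOMSchedule()
    n, dim = data.shape
    n_neurons = grid_shape[0] * grid_shape[1]
    if n < n_neurons:
        raise ValueError(f"need at least {n_neurons} samples, got {n}")

    rng = np.random.default_rng(seed)
    init_idx = rng.choice(n, size=n_neurons, replace=False)
    weights = data[init_idx].copy()

    rows, cols = grid_shape
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    positions = np.column_stack([r.ravel(), c.ravel()]).astype(float)
    grid_d2 = ((positions[:, None, :] - positions[None, :, :]) ** 2).sum(axis=2)

    qe_history = np.empty(schedule.epochs)
    for epoch in range(schedule.epochs):
        lr, radius = schedule.at(epoch)
        order = rng.permutation(n)
        for idx in order:
            x = data[idx]
            b = int(((weights - x) ** 2).sum(axis=1).argmin())
            h = np.exp(-grid_d2[b] / (2.0 * radius**2))
            weights += (lr * h)[:, None] * (x - weights)
        d2 = ((data[:, None, :] - weights[None, :, :]) ** 2).sum(axis=2)
        qe_history[epoch] = float(np.sqrt(d2.min(axis=1)).mean())

    return SOMModel(
        weights=weights,
        grid_shape=grid_shape,
        schedule=schedule,
        seed=seed,
        quantization_errors=qe_history,
    )


@dataclass
class ZoneAssignment:
    """Zone label per basin plus per-zone indicator summaries."""

    labels: pd.Series  # basin_id -> zone letter
    summaries: pd.DataFrame  # per zone: n, mean standardized indicators, SUM
    neuron_of_zone: dict[str, int]
    degenerate: bool  # fewer non-empty neurons than zones requested


def assign_zones(
    som: SOMModel,
    table: pd.DataFrame,
    feature_cols: Sequence[str] = ("q_mean_std", "ntl_mean_std", "pop_mean_std", "lur_std"),
    sum_col: str = "SUM",
) -> ZoneAssignment:
    """Map each basin to its BMU and letter the zones by descending SUM.

    The zone ordering is data-driven (mean member SUM), so it is invariant to
    neuron index permutation.  If fewer neurons than the map size attract any
    member, the assignment is flagged degenerate.
    """
    feats = table[list(feature_cols)].to_numpy(dtype=float)
    bmus = som.bmu(feats)
    sums = table[sum_col].to_numpy(dtype=float)

    non_empty = np.unique(bmus)
    order = sorted(
        non_empty, key=lambda b: -float(np.mean(sums[bmus == b]))
    )
    letters = string.ascii_uppercase
    neuron_to_zone = {int(b): letters[i] for i, b in enumerate(order)}
    labels = pd.Series(
        [neuron_to_zone[int(b)] for b in bmus], index=table.index, name="zone"
    )

    rows = []
    for b in order:
        members = bmus == b
        row = {"zone": neuron_to_zone[int(b)], "n": int(members.sum())}
        for col in feature_cols:
            row[col] = float(table[col].to_numpy()[members].mean())
        row[sum_col] = float(sums[members].mean())
        rows.append(row)
    summaries = pd.DataFrame(rows).set_index("zone")
    return ZoneAssignment(
        labels=labels,
        summaries=summaries,
        neuron_of_zone={v: k for k, v in neuron_to_zone.items()},
        degenerate=len(non_empty) < som.n_neurons,
    )
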