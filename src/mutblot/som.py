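"""Self-organizing map with threshold-gated attraction/repulsion.

This is not a lattice SOM: the 200 competition units live directly in the
8-dimensional feature space and all distances (input-to-unit and
unit-to-winner) are Euclidean distances in that space.  For an input x
the winning unit w_min is the nearest unit; units whose distance to w_min
is within a rank-based threshold S (the distance of the unit at rank
ceil(q * n_units), winner = rank 1; the default q = 0.2 gives the
standard rank-40-of-200 setting) are
attracted toward x, all other units are repelled, with a Gaussian decay
D(w_j) = exp(-d_j(w_min)^2 / (2*pi*sigma^2)) in the unit-to-winner
distance.  Note the 2*pi*sigma^2 denominator: the decay is kept exactly
in this form.

The per-unit update magnitude is Delta(w_j) = +/- L * D(w_j) * (w_j - x);
units move by -Delta (gated units approach x, the rest recede), while the
input itself receives the opposite aggregate feedback
x(new) = x + sum_j Delta(w_j), which pulls similar inputs together and
dissimilar ones apart.  Unit movements are accumulated against the layer
state frozen at batch start and applied once per batch of 100 inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml


@dataclass
class SOMConfig:
    n_units: int = 200
    learning_rate: float = 0.005
    sigma: float = 1.0
    #: rank fraction for the attraction gate; 0.2 of 200 units = rank 40,
    #: the reference configuration
    threshold_quantile: float = 0.2
    batch_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold_quantile < 1:
            raise ValueError("threshold_quantile must be in (0, 1)")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SOMConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class CompetitionLayer:
    """The SOM's adjustable unit vectors: (n_units, feature_dim)."""

    units: np.ndarray

    def __post_init__(self) -> None:
        self.units = np.asarray(self.units, dtype=np.float64)
        if self.units.ndim != 2:
            raise ValueError("units must be a 2-D array")

    @property
    def n_units(self) -> int:
        return self.units.shape[0]

    def save(self, path: str | Path) -> None:
        np.savetxt(path, self.units)

    @classmethod
    def load(cls, path: str | Path) -> "CompetitionLayer":
        return cls(units=np.loadtxt(path, ndmin=2))


@dataclass
class BatchUpdateResult:
    updated_layer: CompetitionLayer
    updated_inputs: np.ndarray
    winners: np.ndarray
    thresholds: np.ndarray


def init_layer(
    first_batch: np.ndarray, n_units: int, rng: np.random.Generator
) -> CompetitionLayer:
    """Units drawn uniformly in the bounding box of the first batch."""
    first_batch = np.asarray(first_batch, dtype=np.float64)
    lo = first_batch.min(axis=0)
    hi = first_batch.max(axis=0)
    units = rng.uniform(lo, np.where(hi > lo, hi, lo + 1e-9), size=(n_units, lo.size))
    return CompetitionLayer(units=units)


def winner_and_distances(
    x: np.ndarray, layer: CompetitionLayer
) -> tuple[np.ndarray, int]:
    """Euclidean distances d_j(x) to every unit and the argmin winner.

    Ties are broken toward the lowest unit index.
    """
    if layer.n_units == 0:
        raise ValueError("competition layer is empty")
    x = np.asarray(x, dtype=np.float64)
    d = np.sqrt(((layer.units - x) ** 2).sum(axis=1))
    return d, int(np.argmin(d))


def threshold_rank(n_units: int, quantile: float) -> int:
    """1-based rank of the unit whose distance to the winner defines S.

    rank = ceil(quantile * n_units), with a small guard against binary
    floating-point excess (e.g. 0.2 * 200 -> 40, not 41).
    """
    return math.ceil(quantile * n_units - 1e-9)


def threshold_S(layer: CompetitionLayer, winner: int, quantile: float) -> float:
    """Distance of the rank-q unit to the winner (winner itself is rank 1)."""
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    d_to_winner = np.sqrt(((layer.units - layer.units[winner]) ** 2).sum(axis=1))
    rank = threshold_rank(layer.n_units, quantile)
    return float(np.sort(d_to_winner)[rank - 1])


def neighborhood_decay(d, sigma: float):
    """Gaussian decay exp(-d^2 / (2*pi*sigma^2)) in the winner distance."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    out = np.exp(-(d ** 2) / (2.0 * math.pi * sigma ** 2))
    return float(out) if out.ndim == 0 else out


def input_deltas(
    x: np.ndarray, layer: CompetitionLayer, config: SOMConfig
) -> tuple[np.ndarray, int, float]:
    """Per-unit update vectors Delta(w_j) for one input against a frozen layer.

    Delta(w_j) = L * D(w_j) * (w_j - x) for units with d_j(w_min) <= S,
    and the negative of that for the rest.  Returns (deltas, winner, S).
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input feature vector")
    _, winner = winner_and_distances(x, layer)
    d_to_winner = np.sqrt(((layer.units - layer.units[winner]) ** 2).sum(axis=1))
    S = threshold_S(layer, winner, config.threshold_quantile)
    decay = neighborhood_decay(d_to_winner, config.sigma)
    sign = np.where(d_to_winner <= S, 1.0, -1.0)
    deltas = (sign * config.learning_rate * decay)[:, None] * (layer.units - x)
    return deltas, winner, S


def batch_update(
    inputs: np.ndarray, layer: CompetitionLayer, config: SOMConfig
) -> BatchUpdateResult:
    """One frozen-layer batch step over up to ``batch_size`` inputs.

    Every input is scored against the layer state at batch start; unit
    movements (-Delta per input) are accumulated and applied once at batch
    end, and each input receives its own feedback x(new) = x + sum_j Delta.
    """
    inputs = np.asarray(inputs, dtype=np.float64)
    if inputs.ndim != 2:
        raise ValueError("inputs must be (batch, feature_dim)")
    if inputs.shape[0] > config.batch_size:
        raise ValueError(
            f"batch of {inputs.shape[0]} exceeds batch_size {config.batch_size}"
        )
    unit_motion = np.zeros_like(layer.units)
    updated_inputs = np.empty_like(inputs)
    winners = np.empty(inputs.shape[0], dtype=int)
    thresholds = np.empty(inputs.shape[0])
    for i, x in enumerate(inputs):
        deltas, winner, S = input_deltas(x, layer, config)
        unit_motion -= deltas
        updated_inputs[i] = x + deltas.sum(axis=0)
        winners[i] = winner
        thresholds[i] = S
    new_layer = CompetitionLayer(units=layer.units + unit_motion)
    return BatchUpdateResult(
        updated_layer=new_layer,
        updated_inputs=updated_inputs,
        winners=winners,
        thresholds=thresholds,
    )
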