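"""The perceptron nervous system.

Each organism is controlled by a classic feed-forward perceptron: a layer
of sensory units (one per colour intensity of the camera frame), one or
more associative layers, and three reacting units driving the motor
commands.  The network is fully described by its weight matrices A1..An
and bias vectors b1..bn — that description is the organism's genome, the
only thing inheritance and mutation touch.  Topology is static within a
lifetime.

The forward pass is ``result_k = sigma(A_k @ result_{k-1} + b_k)`` with a
logistic nonlinearity by default; the three reacting activations are
thresholded into turn-left / turn-right / speed commands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "Genome",
    "ActionCommand",
    "random_genome",
    "forward",
    "decode_action",
    "genome_to_json",
    "genome_from_json",
]

Turn = Literal["left", "none", "right"]
SpeedDelta = Literal["decrease", "none", "increase"]


@dataclass
class ActionCommand:
    """One motor decision: a turn direction and a speed change."""

    turn: Turn
    speed_delta: SpeedDelta


@dataclass
class Genome:
    """Weight matrices and bias vectors of one perceptron.

    ``weights[k]`` has shape ``(layer_sizes[k+1], layer_sizes[k])`` and
    ``biases[k]`` length ``layer_sizes[k+1]``.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        sizes = self.layer_sizes
        if len(self.weights) != len(sizes) - 1 or len(self.biases) != len(sizes) - 1:
            raise ValueError("genome needs one weight matrix and bias per layer gap")
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            expected = (sizes[k + 1], sizes[k])
            if w.shape != expected:
                raise ValueError(
                    f"weight matrix {k} has shape {w.shape}, expected {expected}")
            if b.shape != (sizes[k + 1],):
                raise ValueError(
                    f"bias vector {k} has length {b.shape}, expected {sizes[k + 1]}")
            if not (np.isfinite(w).all() and np.isfinite(b).all()):
                raise ValueError(f"non-finite entries in layer {k}")

    @property
    def n_units(self) -> int:
        """Total number of units (sensory + associative + reacting)."""
        return sum(self.layer_sizes)

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def copy(self) -> "Genome":
        return Genome(self.layer_sizes, [w.copy() for w in self.weights],
                      [b.copy() for b in self.biases], dict(self.metadata))


def random_genome(layer_sizes: Sequence[int], rng: np.random.Generator,
                  weight_init: float = 1.0) -> Genome:
    """Draw all weights and biases independently uniform in [-w0, w0]."""
    sizes = tuple(int(s) for s in layer_sizes)
    weights, biases = [], []
    for k in range(len(sizes) - 1):
        weights.append(rng.uniform(-weight_init, weight_init,
                                   size=(sizes[k + 1], sizes[k])))
        biases.append(rng.uniform(-weight_init, weight_init, size=sizes[k + 1]))
    return Genome(sizes, weights, biases)


def _step(z: np.ndarray) -> np.ndarray:
    return (z > 0).astype(float)


_ACTIVATIONS = {
    "logistic": expit,
    "tanh": np.tanh,
    "step": _step,
}


def forward(genome: Genome, input_vector: np.ndarray,
            activation: str = "logistic") -> np.ndarray:
    """Activations of the reacting layer for one input vector.

    Pure function: ``result_0`` is the sensory layer (the flattened frame),
    each subsequent layer is ``sigma(A_k @ result_{k-1} + b_k)``.
    """
    x = np.asarray(input_vector, dtype=float)
    if x.shape != (genome.layer_sizes[0],):
        raise ValueError(
            f"input length {x.shape} does not match sensory layer "
            f"size {genome.layer_sizes[0]}")
    act = _ACTIVATIONS[activation]
    for w, b in zip(genome.weights, genome.biases):
        x = act(w @ x + b)
    return x


def decode_action(r_activations: np.ndarray,
                  threshold: float = 0.5) -> ActionCommand:
    """Map the three reacting activations to a motor command.

    Unit 1 votes turn-left, unit 2 turn-right, unit 3 speed-up.  A unit
    fires when its activation strictly exceeds the threshold; if both or
    neither turn unit fires the organism goes straight, and a silent speed
    unit brakes toward rest.
    """
    r = np.asarray(r_activations, dtype=float)
    if r.shape != (3,):
        raise ValueError(f"expected 3 reacting activations, got shape {r.shape}")
    left, right, faster = (r > threshold)
    if left and not right:
        turn: Turn = "left"
    elif right and not left:
        turn = "right"
    else:
        turn = "none"
    return ActionCommand(turn=turn, speed_delta="increase" if faster else "decrease")


# ---------------------------------------------------------------------------
# serialization — loss-free JSON round-trip

def genome_to_json(genome: Genome) -> str:
    doc = {
        "layer_sizes": list(genome.layer_sizes),
        "weights": [w.tolist() for w in genome.weights],
        "biases": [b.tolist() for b in genome.biases],
        "metadata": genome.metadata,
    }
    return json.dumps(doc)


def genome_from_json(text: str) -> Genome:
    doc = json.loads(text)
    return Genome(
        tuple(doc["layer_sizes"]),
        [np.asarray(w, dtype=float) for w in doc["weights"]],
        [np.asarray(b, dtype=float) for b in doc["biases"]],
        doc.get("metadata", {}),
    )
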