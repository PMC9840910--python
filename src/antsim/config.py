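"""Run configuration: every knob of the simulator in one flat record.

A :class:`SimConfig` holds the arena geometry, the energy-budget constants
(maximum satiety 15, birth threshold fraction 0.7, initial satiety 8), the
camera parameters (30x30 pixels by default), the perceptron layer sizes
(default [2700, 297, 3], totalling 3000 units), the mutation bounds
``a <= b`` (probability) and ``c <= d`` (magnitude), motion limits, the
master seed and the run length.  Configurations round-trip through a flat
``key = value`` text file.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "ConfigError",
    "SimConfig",
    "default_config",
    "scaled_config",
    "load_config",
    "save_config",
    "config_digest",
]


class ConfigError(ValueError):
    """An invalid configuration value; the message names the field."""


@dataclass(frozen=True)
class SimConfig:
    # arena and clock
    arena_width: float = 100.0
    arena_height: float = 100.0
    dt: float = 0.1                  # seconds per tick
    duration: float = 600.0          # seconds of simulated time

    # energy budget (satiety units)
    hunger_period: float = 2.0       # seconds between unit satiety losses
    max_satiety: float = 15.0
    birth_fraction: float = 0.7      # birth threshold = max_satiety * birth_fraction
    initial_satiety: float = 8.0
    food_energy: float = 1.0         # satiety gained per particle

    # food and population
    food_count: int = 100
    eat_radius: float = 1.5
    initial_population: int = 30
    max_population: int = 0          # soft cap on births; 0 = unbounded

    # rendered geometry (billboard sizes, length units)
    food_radius: float = 0.4
    organism_radius: float = 0.5
    food_height: float = 0.8
    organism_height: float = 1.0

    # vision
    vision_width: int = 30
    vision_height: int = 30
    fov: float = math.pi / 2         # radians
    view_range: float = 0.0          # 0 -> arena diagonal

    # nervous system
    layer_sizes: tuple[int, ...] = (2700, 297, 3)
    activation: str = "logistic"     # logistic | tanh | step
    action_threshold: float = 0.5
    weight_init: float = 1.0         # initial weights uniform in [-w0, w0]

    # mutation bounds: epsilon ~ U[a,b] (probability), delta ~ U[c,d] (magnitude)
    mutation_a: float = 0.1
    mutation_b: float = 0.3
    mutation_c: float = 0.02
    mutation_d: float = 0.5

    # motion
    max_speed: float = 5.0           # length units / s
    turn_rate: float = 1.5           # rad / s
    speed_step: float = 10.0         # speed change per second of command
    initial_speed: float = 0.0       # speed at spawn (founders and newborns)

    # bookkeeping
    sample_interval: int = 100       # ticks between metric samples
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def birth_satiety(self) -> float:
        """Satiety threshold at which an organism produces a descendant."""
        return self.max_satiety * self.birth_fraction

    @property
    def resolved_view_range(self) -> float:
        if self.view_range > 0:
            return self.view_range
        return math.hypot(self.arena_width, self.arena_height)

    @property
    def n_ticks(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def input_size(self) -> int:
        return 3 * self.vision_width * self.vision_height

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        def bad(name: str, why: str) -> None:
            raise ConfigError(f"invalid config field {name!r}: {why}")

        for name in ("arena_width", "arena_height", "dt", "hunger_period",
                     "max_satiety", "food_energy", "eat_radius", "max_speed",
                     "weight_init"):
            if getattr(self, name) <= 0:
                bad(name, "must be > 0")
        for name in ("food_count", "initial_population", "max_population",
                     "vision_width", "vision_height", "sample_interval"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                bad(name, "must be a non-negative integer")
        if self.vision_width == 0 or self.vision_height == 0:
            bad("vision_width", "frame dimensions must be >= 1")
        if self.sample_interval == 0:
            bad("sample_interval", "must be >= 1")
        if self.duration < 0:
            bad("duration", "must be >= 0")
        if not 0 < self.birth_fraction <= 1:
            bad("birth_fraction", "must be in (0, 1]")
        if not 0 <= self.initial_satiety <= self.max_satiety:
            bad("initial_satiety", "must be within [0, max_satiety]")
        if not 0 <= self.mutation_a <= self.mutation_b <= 1:
            bad("mutation_a", "requires 0 <= a <= b <= 1")
        if self.mutation_c > self.mutation_d:
            bad("mutation_c", "requires c <= d")
        if not 0 < self.fov <= 2 * math.pi:
            bad("fov", "must be in (0, 2*pi]")
        if self.view_range < 0:
            bad("view_range", "must be >= 0 (0 means arena diagonal)")
        if self.turn_rate < 0 or self.speed_step < 0:
            bad("turn_rate", "motion rates must be >= 0")
        if not 0 <= self.initial_speed <= self.max_speed:
            bad("initial_speed", "must be within [0, max_speed]")
        sizes = tuple(self.layer_sizes)
        if len(sizes) < 2 or any((not isinstance(s, int)) or s < 1 for s in sizes):
            bad("layer_sizes", "needs >= 2 positive integer layer sizes")
        object.__setattr__(self, "layer_sizes", sizes)
        if sizes[0] != self.input_size:
            bad("layer_sizes",
                f"first layer must equal 3*vision_width*vision_height "
                f"= {self.input_size}, got {sizes[0]}")
        if sizes[-1] != 3:
            bad("layer_sizes", "last layer must have 3 reacting units")
        if self.activation not in ("logistic", "tanh", "step"):
            bad("activation", "must be one of logistic, tanh, step")
        if not isinstance(self.seed, int) or self.seed < 0:
            bad("seed", "must be a non-negative integer")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def default_config(**overrides) -> SimConfig:
    """The default parameterisation: 30x30 vision, [2700, 297, 3] network."""
    return SimConfig(**overrides)


def scaled_config(seed: int = 0, **overrides) -> SimConfig:
    """Desk-scale conditions for the lifetime-growth experiment.

    A 30x30 arena with 55 food particles, 20 founders, 10x10 vision feeding a
    [300, 24, 3] perceptron, a 3 s hunger period, and a population cap of 60.
    The food density gives an idealised straight full-speed mover roughly
    twice the break-even intake (2 * eat_radius * max_speed * food_density *
    hunger_period ~ 2.5 particles per hunger period), but wall clamping and
    path self-overlap cut the realised intake of blind trajectories to
    around break-even, so sustained persistence requires steering toward
    food — the trait selection acts on.
    """
    params = dict(
        arena_width=30.0,
        arena_height=30.0,
        food_count=55,
        hunger_period=3.0,
        eat_radius=1.5,
        initial_population=20,
        max_population=60,
        vision_width=10,
        vision_height=10,
        layer_sizes=(300, 24, 3),
        view_range=20.0,
        duration=2000.0,            # 20 000 ticks at dt = 0.1 s
        sample_interval=100,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


# ---------------------------------------------------------------------------
# flat key = value text format

_FIELD_TYPES = {f.name: f.type for f in fields(SimConfig)}


def _format_value(value) -> str:
    if isinstance(value, tuple):
        return ",".join(str(v) for v in value)
    return repr(value) if isinstance(value, float) else str(value)


def _parse_value(name: str, text: str):
    text = text.strip()
    if name == "layer_sizes":
        return tuple(int(p) for p in text.split(",") if p.strip())
    if name == "activation":
        return text
    if name in ("food_count", "initial_population", "max_population",
                "vision_width", "vision_height", "sample_interval", "seed"):
        return int(text)
    return float(text)


def save_config(config: SimConfig, path) -> None:
    lines = ["# antsim run configuration"]
    for f in fields(SimConfig):
        lines.append(f"{f.name} = {_format_value(getattr(config, f.name))}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_config(path) -> SimConfig:
    """Parse a flat ``key = value`` configuration file.

    Unknown keys and malformed lines raise :class:`ConfigError` naming the
    offending key; missing keys take their defaults.
    """
    values = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in _FIELD_TYPES:
                raise ConfigError(f"line {lineno}: unknown config field {key!r}")
            try:
                values[key] = _parse_value(key, val)
            except ValueError as exc:
                raise ConfigError(f"invalid config field {key!r}: {exc}") from exc
    return SimConfig(**values)


def config_digest(config: SimConfig) -> str:
    """Short stable hash of the full configuration, for logs."""
    text = "\n".join(
        f"{f.name}={_format_value(getattr(config, f.name))}" for f in fields(SimConfig)
    )
    return hashlib.sha256(text.encode()).hexdigest()[:12]
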