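"""The 2D arena and the per-tick simulation loop.

Organisms are coloured discs with a heading on a bounded plane scattered
with green food particles.  Each tick, every live organism — processed in
ascending id order so runs are exactly reproducible — renders its
first-person frame, feeds it through its perceptron, decodes the motor
command, moves, eats any food within reach, pays its hunger cost, and
reproduces if its satiety has reached the birth threshold.  Deaths are
removed and eaten food respawned (constant active count) at the end of
the tick.

Randomness is split into four named streams derived from the master seed
(placement, mutation, food, tiebreak) so that, e.g., extra mutation draws
never perturb where food respawns.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import brain as _brain
from . import vision as _vision
from .config import SimConfig
from .evolution import MutationParams, metabolism_tick, mutate, split_satiety

__all__ = [
    "Pose",
    "Organism",
    "FoodParticle",
    "WorldState",
    "init_world",
    "step",
    "check_eating",
    "respawn_food",
    "state_digest",
    "state_record",
]

RNG_STREAMS = ("placement", "mutation", "food", "tiebreak")


@dataclass
class Pose:
    x: float
    y: float
    heading: float          # radians in [0, 2*pi)
    speed: float = 0.0      # length units / s, in [0, max_speed]


@dataclass
class Organism:
    id: int
    pose: Pose
    satiety: float
    genome_id: int
    born_at: float                      # seconds
    parent_id: int | None = None
    generation: int = 0
    color: tuple[float, float, float] = (0.5, 0.35, 0.15)
    hunger_elapsed: float = 0.0         # seconds since last satiety decrement

    @property
    def x(self) -> float:
        return self.pose.x

    @property
    def y(self) -> float:
        return self.pose.y


@dataclass
class FoodParticle:
    id: int
    x: float
    y: float
    energy: float
    active: bool = True


@dataclass
class WorldState:
    """The single mutable simulation root."""

    time: float
    tick: int
    organisms: dict[int, Organism]
    food: list[FoodParticle]
    genomes: dict[int, _brain.Genome]
    rng: dict[str, np.random.Generator]
    births_total: int = 0
    deaths_total: int = 0
    food_eaten_total: int = 0
    next_id: int = 0
    events: list[dict] = field(default_factory=list)
    # numpy mirrors of the food table, kept in sync for the fast path
    _food_xy: np.ndarray | None = None
    _food_active: np.ndarray | None = None

    def iter_organisms(self):
        """Live organisms in ascending id order."""
        for oid in sorted(self.organisms):
            yield self.organisms[oid]

    @property
    def population(self) -> int:
        return len(self.organisms)

    @property
    def active_food_count(self) -> int:
        return int(self._food_active.sum()) if self._food_active is not None else 0

    def drain_events(self) -> list[dict]:
        out, self.events = self.events, []
        return out


def _sync_food_arrays(state: WorldState) -> None:
    n = len(state.food)
    state._food_xy = np.array([[p.x, p.y] for p in state.food],
                              dtype=float).reshape(n, 2)
    state._food_active = np.array([p.active for p in state.food], dtype=bool)


def _draw_color(rng: np.random.Generator) -> tuple[float, float, float]:
    # brown-toned lineage palette: warm red dominant, green subordinate, low blue
    r = rng.uniform(0.45, 0.7)
    g = rng.uniform(0.25, 0.45)
    b = rng.uniform(0.08, 0.2)
    return (r, g, b)


def init_world(config: SimConfig) -> WorldState:
    """Scatter the founding population and the food uniformly on the plane.

    Every founder gets satiety ``initial_satiety``, a uniform random pose,
    a lineage colour and an independently random genome.  Identical
    config (including seed) yields bit-identical state.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(len(RNG_STREAMS))
    rng = {name: np.random.default_rng(s) for name, s in zip(RNG_STREAMS, streams)}
    state = WorldState(time=0.0, tick=0, organisms={}, food=[], genomes={}, rng=rng)
    place = rng["placement"]
    for i in range(config.initial_population):
        x = place.uniform(0, config.arena_width)
        y = place.uniform(0, config.arena_height)
        heading = place.uniform(0, 2 * math.pi)
        color = _draw_color(place)
        genome = _brain.random_genome(config.layer_sizes, place, config.weight_init)
        org = Organism(id=i, pose=Pose(x, y, heading, config.initial_speed),
                       satiety=float(config.initial_satiety), genome_id=i,
                       born_at=0.0, parent_id=None, generation=0, color=color)
        state.organisms[i] = org
        state.genomes[i] = genome
    state.next_id = config.initial_population
    food_rng = rng["food"]
    for j in range(config.food_count):
        fx = food_rng.uniform(0, config.arena_width)
        fy = food_rng.uniform(0, config.arena_height)
        state.food.append(FoodParticle(id=j, x=fx, y=fy,
                                       energy=float(config.food_energy)))
    _sync_food_arrays(state)
    return state


def check_eating(state: WorldState, organism: Organism,
                 config: SimConfig) -> tuple[float, list[int]]:
    """Consume every active particle within ``eat_radius``, nearest first.

    Satiety rises by one ``food_energy`` per particle but never beyond
    ``max_satiety``; particles in reach are consumed (deactivated) even
    when the organism is already full.  Returns the satiety delta and the
    consumed particle ids.
    """
    if state._food_active is None or not len(state.food):
        return 0.0, []
    pos = np.array([organism.pose.x, organism.pose.y])
    d2 = ((state._food_xy - pos) ** 2).sum(axis=1)
    hits = state._food_active & (d2 <= config.eat_radius ** 2)
    if not hits.any():
        return 0.0, []
    idx = np.flatnonzero(hits)
    idx = idx[np.argsort(d2[idx], kind="stable")]   # nearest first; index tiebreak
    before = organism.satiety
    consumed: list[int] = []
    for j in idx:
        state._food_active[j] = False
        state.food[j].active = False
        organism.satiety = min(organism.satiety + config.food_energy,
                               config.max_satiety)
        consumed.append(int(j))
    state.food_eaten_total += len(consumed)
    return organism.satiety - before, consumed


def respawn_food(state: WorldState, config: SimConfig) -> WorldState:
    """Replace inactive particles at uniform random spots (constant count)."""
    inactive = np.flatnonzero(~state._food_active) if state._food_active is not None else []
    rng = state.rng["food"]
    for j in inactive:
        p = state.food[j]
        p.x = rng.uniform(0, config.arena_width)
        p.y = rng.uniform(0, config.arena_height)
        p.active = True
        state._food_xy[j, 0] = p.x
        state._food_xy[j, 1] = p.y
        state._food_active[j] = True
    return state


def _apply_motion(pose: Pose, cmd: _brain.ActionCommand, config: SimConfig) -> None:
    dt = config.dt
    if cmd.turn == "left":
        pose.heading += config.turn_rate * dt
    elif cmd.turn == "right":
        pose.heading -= config.turn_rate * dt
    pose.heading %= 2 * math.pi
    if cmd.speed_delta == "increase":
        pose.speed = min(pose.speed + config.speed_step * dt, config.max_speed)
    elif cmd.speed_delta == "decrease":
        pose.speed = max(pose.speed - config.speed_step * dt, 0.0)
    # boundary policy: clamp to the arena, heading unchanged
    pose.x = min(max(pose.x + math.cos(pose.heading) * pose.speed * dt, 0.0),
                 config.arena_width)
    pose.y = min(max(pose.y + math.sin(pose.heading) * pose.speed * dt, 0.0),
                 config.arena_height)


def step(state: WorldState, config: SimConfig) -> WorldState:
    """Advance the world by one tick (mutates and returns ``state``).

    Per live organism, in ascending id order: render -> flatten -> forward
    -> decode -> motion -> eating -> metabolism -> reproduction.  An
    organism moved earlier in the tick is seen at its new position by
    later ones; organisms that starve mid-tick stay visible until the end
    of the tick; newborns enter the world at the end of the tick.
    """
    dt = config.dt
    t_end = (state.tick + 1) * dt
    ids = sorted(state.organisms)
    n_org = len(ids)
    mparams = MutationParams.from_config(config)
    view_range = config.resolved_view_range
    W, H = config.vision_width, config.vision_height

    if n_org:
        # one combined object table per tick: food rows first, organisms after;
        # organism rows are updated in place as each one moves so later-id
        # observers see the new positions
        n_food = len(state.food)
        centers = np.empty((n_food + n_org, 2))
        centers[:n_food] = state._food_xy
        for i, oid in enumerate(ids):
            o = state.organisms[oid].pose
            centers[n_food + i, 0] = o.x
            centers[n_food + i, 1] = o.y
        radii = np.concatenate([np.full(n_food, config.food_radius),
                                np.full(n_org, config.organism_radius)])
        heights = np.concatenate([np.full(n_food, config.food_height),
                                  np.full(n_org, config.organism_height)])
        colors = np.concatenate([
            np.tile(np.array(_vision.FOOD_COLOR), (n_food, 1)),
            np.array([state.organisms[i].color for i in ids]).reshape(n_org, 3)])
        active = np.concatenate([state._food_active,
                                 np.ones(n_org, dtype=bool)])
        frame_buf = np.empty((H, W, 3))

    dead: list[Organism] = []
    born: list[tuple[Organism, _brain.Genome]] = []
    live_count = n_org

    for i, oid in enumerate(ids):
        org = state.organisms[oid]
        if org.satiety <= 0:    # defensive: removed organisms never reach here
            continue
        # vision: active food plus every other organism (self excluded)
        pixels = _vision.render_scene(org.pose.x, org.pose.y, org.pose.heading,
                                      centers, radii, heights, colors,
                                      W, H, config.fov, view_range,
                                      active=active, exclude=n_food + i,
                                      out=frame_buf)
        input_vector = pixels.transpose(2, 0, 1).reshape(-1)
        r = _brain.forward(state.genomes[org.genome_id], input_vector,
                           config.activation)
        cmd = _brain.decode_action(r, config.action_threshold)
        _apply_motion(org.pose, cmd, config)
        centers[n_food + i, 0] = org.pose.x
        centers[n_food + i, 1] = org.pose.y
        _, consumed = check_eating(state, org, config)
        for j in consumed:
            active[j] = False
        if metabolism_tick(org, config, dt):
            dead.append(org)
            live_count -= 1
            state.events.append({
                "type": "death", "tick": state.tick + 1, "time": t_end,
                "id": org.id, "born_at": org.born_at,
                "lifetime": t_end - org.born_at, "generation": org.generation,
            })
            continue
        if org.satiety >= config.birth_satiety and (
                config.max_population == 0 or live_count < config.max_population):
            parent_after, child_satiety = split_satiety(org.satiety)
            org.satiety = parent_after
            child_genome = mutate(state.genomes[org.genome_id], mparams,
                                  state.rng["mutation"])
            cid = state.next_id
            state.next_id += 1
            child = Organism(
                id=cid,
                pose=Pose(org.pose.x, org.pose.y,
                          (org.pose.heading + math.pi) % (2 * math.pi),
                          config.initial_speed),
                satiety=child_satiety, genome_id=cid, born_at=t_end,
                parent_id=org.id, generation=org.generation + 1, color=org.color)
            born.append((child, child_genome))
            live_count += 1
            state.events.append({
                "type": "birth", "tick": state.tick + 1, "time": t_end,
                "parent_id": org.id, "child_id": cid,
                "parent_satiety_after": parent_after,
                "child_satiety": child_satiety, "generation": child.generation,
            })

    for org in dead:
        del state.organisms[org.id]
        del state.genomes[org.genome_id]
        state.deaths_total += 1
    for child, genome in born:
        state.organisms[child.id] = child
        state.genomes[child.id] = genome
        state.births_total += 1
    respawn_food(state, config)
    state.tick += 1
    state.time = state.tick * dt
    return state


# ---------------------------------------------------------------------------
# state inspection

def state_record(state: WorldState) -> dict:
    """One JSON-lines state dump record."""
    return {
        "tick": state.tick,
        "organisms": [
            {"id": o.id, "x": o.pose.x, "y": o.pose.y, "heading": o.pose.heading,
             "satiety": o.satiety, "generation": o.generation}
            for o in state.iter_organisms()
        ],
        "food_active_count": state.active_food_count,
    }


def state_digest(state: WorldState) -> str:
    """SHA-256 digest of the full dynamical state (bit-exact floats)."""
    doc = {
        "tick": state.tick,
        "time": repr(state.time),
        "organisms": [
            [o.id, repr(o.pose.x), repr(o.pose.y), repr(o.pose.heading),
             repr(o.pose.speed), repr(o.satiety), repr(o.hunger_elapsed),
             o.generation, o.genome_id]
            for o in state.iter_organisms()
        ],
        "food": [[p.id, repr(p.x), repr(p.y), p.active] for p in state.food],
        "counters": [state.births_total, state.deaths_total,
                     state.food_eaten_total],
    }
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()
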