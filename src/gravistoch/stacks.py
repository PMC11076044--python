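"""Procedural generation of block stacks.

A stack is built in three steps: (1) designate a horizontal placement area,
(2) drop blocks one by one at uniform random horizontal positions -- each
rests on the ground, or on the topmost already-placed block beneath it --
and (3) fine-tune the horizontal overlap between every block and its support
to a value drawn from U(0.2, 0.8).  Small areas cluster blocks and therefore
build taller stacks; the overlap draw controls how precarious each contact
is, which is what makes roughly half the stacks collapse.

Blocks are 3:1:1 cuboids (1.2 x 0.4 x 0.4 arbitrary units, 0.2 kg); the long
axis of each block is chosen uniformly among x, y, z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

BLOCK_LONG = 1.2
BLOCK_SHORT = 0.4
BLOCK_MASS = 0.2

_HALF_EXTENTS = {
    "long-x": np.array([BLOCK_LONG / 2, BLOCK_SHORT / 2, BLOCK_SHORT / 2]),
    "long-y": np.array([BLOCK_SHORT / 2, BLOCK_LONG / 2, BLOCK_SHORT / 2]),
    "long-z": np.array([BLOCK_SHORT / 2, BLOCK_SHORT / 2, BLOCK_LONG / 2]),
}
BLOCK_TYPES = tuple(_HALF_EXTENTS)


class InvalidConfigError(ValueError):
    pass


class GenerationError(RuntimeError):
    """Raised when rejection sampling exhausts its attempt budget."""


@dataclass(frozen=True)
class Block:
    """One axis-aligned cuboid block in its initial pose."""

    block_type: str
    center: np.ndarray
    mass: float = BLOCK_MASS

    def __post_init__(self):
        if self.block_type not in _HALF_EXTENTS:
            raise InvalidConfigError(f"unknown block type {self.block_type!r}")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))

    @property
    def half_extents(self) -> np.ndarray:
        return _HALF_EXTENTS[self.block_type]

    @property
    def top(self) -> float:
        return float(self.center[2] + self.half_extents[2])

    @property
    def bottom(self) -> float:
        return float(self.center[2] - self.half_extents[2])


@dataclass(frozen=True)
class StackGenConfig:
    """Parameters of the block-stacking procedure.

    ``area_x``/``area_y`` are the horizontal placement half-ranges (centers
    are drawn from U(-area_x, +area_x) x U(-area_y, +area_y)); when None they
    are themselves drawn from U(*area_bounds*) per stack.
    """

    n_blocks: int = 10
    area_x: float | None = None
    area_y: float | None = None
    area_bounds: tuple[float, float] = (0.2, 2.0)
    overlap_range: tuple[float, float] = (0.2, 0.8)
    seed: int | None = None

    def __post_init__(self):
        if self.n_blocks < 2:
            raise InvalidConfigError("a stack needs at least 2 blocks")
        for v, name in ((self.area_x, "area_x"), (self.area_y, "area_y")):
            if v is not None and v <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        lo, hi = self.overlap_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise InvalidConfigError("overlap_range must lie within [0, 1]")
        if not (0 < self.area_bounds[0] <= self.area_bounds[1]):
            raise InvalidConfigError("area_bounds must be positive and ordered")


@dataclass
class Stack:
    """An ordered list of blocks plus generation metadata."""

    blocks: list[Block]
    gen_config: StackGenConfig
    area: tuple[float, float] = (0.0, 0.0)  # realized (area_x, area_y)
    supports: list[int | None] = field(default_factory=list)  # index of each block's support
    label_stable: bool | None = None

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def height(self) -> float:
        return max(b.top for b in self.blocks)

    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.blocks])

    def half_extents(self) -> np.ndarray:
        return np.array([b.half_extents for b in self.blocks])


# ----------------------------------------------------------------------
def _footprints_overlap(c1, h1, c2, h2) -> bool:
    return (
        abs(c1[0] - c2[0]) < h1[0] + h2[0] and abs(c1[1] - c2[1]) < h1[1] + h2[1]
    )


def overlap_fraction(upper: Block, lower: Block, axis: int) -> float:
    """Overlap length along ``axis`` as a fraction of the smaller footprint.

    Relative to the smaller of the two footprints so that any target in
    (0, 1] is geometrically reachable regardless of which block is longer.
    """
    hu, hl = upper.half_extents[axis], lower.half_extents[axis]
    lo = max(upper.center[axis] - hu, lower.center[axis] - hl)
    hi = min(upper.center[axis] + hu, lower.center[axis] + hl)
    return max(hi - lo, 0.0) / (2.0 * min(hu, hl))


def pair_overlap(upper: Block, lower: Block) -> float:
    """The stack-relevant overlap of a contacting pair: min over x and y."""
    return min(overlap_fraction(upper, lower, 0), overlap_fraction(upper, lower, 1))


def _adjusted_coord(
    u: float, lo_c: float, hu: float, hl: float, target: float, bound: float
) -> float:
    """Center coordinate of the upper block giving ``target`` overlap.

    Keeps the block on its current side of the support when possible and
    clamps into the designated area [-bound, +bound]; clamping moves the
    block toward the support center, so realized overlap only exceeds target.
    """
    d = hu + hl - 2.0 * target * min(hu, hl)
    side = 1.0 if u >= lo_c else -1.0
    cand = lo_c + side * d
    if abs(cand) > bound:
        other = lo_c - side * d
        if abs(other) <= bound:
            return other
        return float(np.clip(cand, -bound, bound))
    return cand


def generate_stack(config: StackGenConfig, rng: np.random.Generator | None = None) -> Stack:
    """Run the three-step block-stacking procedure; deterministic given seed."""
    rng = rng or np.random.default_rng(config.seed)
    ax = config.area_x if config.area_x is not None else float(rng.uniform(*config.area_bounds))
    ay = config.area_y if config.area_y is not None else float(rng.uniform(*config.area_bounds))

    blocks: list[Block] = []
    supports: list[int | None] = []
    for _ in range(config.n_blocks):
        btype = BLOCK_TYPES[int(rng.integers(3))]
        half = _HALF_EXTENTS[btype]
        cx = float(rng.uniform(-ax, ax))
        cy = float(rng.uniform(-ay, ay))
        below = [
            j
            for j, b in enumerate(blocks)
            if _footprints_overlap((cx, cy), half, b.center, b.half_extents)
        ]
        if below:
            # rest on the topmost block underneath (physical support)
            sup = max(below, key=lambda j: blocks[j].top)
            cz = blocks[sup].top + half[2]
        else:
            sup = None
            cz = float(half[2])
        blocks.append(Block(btype, np.array([cx, cy, cz])))
        supports.append(sup)

    # step 3: fine-tune each block's overlap with its support
    bounds = (ax, ay)
    for i, sup in enumerate(supports):
        if sup is None:
            continue
        upper, lower = blocks[i], blocks[sup]
        target = float(rng.uniform(*config.overlap_range))
        fx = overlap_fraction(upper, lower, 0)
        fy = overlap_fraction(upper, lower, 1)
        order = (0, 1) if fx <= fy else (1, 0)
        center = upper.center.copy()
        first = True
        for axis in order:
            frac = overlap_fraction(Block(upper.block_type, center), lower, axis)
            if first or frac < target:
                center[axis] = _adjusted_coord(
                    center[axis],
                    float(lower.center[axis]),
                    float(upper.half_extents[axis]),
                    float(lower.half_extents[axis]),
                    target,
                    bounds[axis],
                )
            first = False
        blocks[i] = Block(upper.block_type, center)

    return Stack(blocks=blocks, gen_config=config, area=(ax, ay), supports=supports)


def generate_labeled_set(
    n_stable: int,
    n_unstable: int,
    config: StackGenConfig,
    sim_config=None,
    max_attempts: int = 10_000,
    rng: np.random.Generator | None = None,
) -> list[Stack]:
    """Rejection-sample stacks until the requested stable/unstable counts.

    Labels come from a natural-gravity simulation (displacement < 0.01 on
    every block at every stage = stable).  Raises GenerationError naming the
    missing category if the per-category attempt budget runs out.
    """
    from .physics import SimConfig, quick_stable

    sim_config = sim_config or SimConfig()
    rng = rng or np.random.default_rng(config.seed)
    stable: list[Stack] = []
    unstable: list[Stack] = []
    attempts = {"stable": 0, "unstable": 0}
    while len(stable) < n_stable or len(unstable) < n_unstable:
        stack = generate_stack(replace(config, seed=int(rng.integers(2**31))))
        label = quick_stable(stack, config=sim_config)
        cat = "stable" if label else "unstable"
        want = n_stable if label else n_unstable
        bucket = stable if label else unstable
        if len(bucket) < want:
            stack.label_stable = label
            bucket.append(stack)
        else:
            # a full bucket means this draw counts against the other category
            other = "unstable" if label else "stable"
            attempts[other] += 1
            if attempts[other] >= max_attempts:
                raise GenerationError(
                    f"could not generate enough {other} stacks "
                    f"({max_attempts} attempts exhausted)"
                )
    return stable + unstable


# ----------------------------------------------------------------------
# JSON round-trip
def stack_to_dict(stack: Stack) -> dict:
    cfg = stack.gen_config
    return {
        "blocks": [
            {
                "type": b.block_type,
                "center": [float(x) for x in b.center],
                "half_extents": [float(x) for x in b.half_extents],
                "mass": b.mass,
            }
            for b in stack.blocks
        ],
        "gen_config": {
            "n_blocks": cfg.n_blocks,
            "area_x": cfg.area_x,
            "area_y": cfg.area_y,
            "area_bounds": list(cfg.area_bounds),
            "overlap_range": list(cfg.overlap_range),
            "seed": cfg.seed,
        },
        "area": list(stack.area),
        "supports": stack.supports,
        "label_stable": stack.label_stable,
    }


def stack_from_dict(d: dict) -> Stack:
    cfg = d["gen_config"]
    config = StackGenConfig(
        n_blocks=cfg["n_blocks"],
        area_x=cfg["area_x"],
        area_y=cfg["area_y"],
        area_bounds=tuple(cfg["area_bounds"]),
        overlap_range=tuple(cfg["overlap_range"]),
        seed=cfg["seed"],
    )
    blocks = [
        Block(b["type"], np.array(b["center"]), b.get("mass", BLOCK_MASS)) for b in d["blocks"]
    ]
    return Stack(
        blocks=blocks,
        gen_config=config,
        area=tuple(d.get("area", (0.0, 0.0))),
        supports=d.get("supports", []),
        label_stable=d.get("label_stable"),
    )


def save_stacks(stacks: list[Stack], path: str | Path) -> None:
    Path(path).write_text(json.dumps([stack_to_dict(s) for s in stacks], indent=1))


def load_stacks(path: str | Path) -> list[Stack]:
    return [stack_from_dict(d) for d in json.loads(Path(path).read_text())]
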