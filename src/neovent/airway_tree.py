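"""Morphometric conducting airway tree (generations 0-7).

The resolved model domain is a dichotomous bifurcating tree from the trachea
(generation 0) down to generation 7, whose terminal outlets are closed by
lumped tissue units (see :mod:`neovent.mechanics`).  The real airway tree of
an individual infant is irregular; here a regular self-similar dichotomy
with a controllable left/right asymmetry factor and optional log-normal
jitter stands in for it, and the single binding anatomical calibration is
the conducting-airway (anatomical) dead space: all linear dimensions are
rescaled by one global factor so the tree volume matches a prescribed dead
space per kilogram of body weight (2.2 ml/kg for the default patient).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AirwaySegment",
    "AirwayTree",
    "MorphometryParams",
    "generate_tree",
    "dead_space",
    "validate_tree",
    "read_tree",
    "write_tree",
]

LOBES = ("trachea/main", "RUL", "RML", "RLL", "LUL", "LLL")


@dataclass(frozen=True)
class AirwaySegment:
    """One cylindrical conducting airway."""

    id: str
    parent_id: str | None
    generation: int
    length: float    # mm
    diameter: float  # mm
    lobe: str = "trachea/main"
    is_terminal: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError(
                f"segment {self.id}: length and diameter must be positive"
            )
        if self.generation < 0:
            raise ValueError(f"segment {self.id}: negative generation")

    @property
    def volume_ml(self) -> float:
        """Cylinder volume pi (d/2)^2 L in ml."""
        return math.pi * (self.diameter / 2.0) ** 2 * self.length / 1000.0

    @property
    def area_mm2(self) -> float:
        return math.pi * (self.diameter / 2.0) ** 2


@dataclass
class AirwayTree:
    """The conducting tree: a mapping of segments plus the root id.

    Segments are stored in insertion order (root first, then a depth-first
    order for generated trees), which fixes the terminal ordering used by
    the compliance partition.
    """

    segments: dict[str, AirwaySegment]
    root_id: str

    def __post_init__(self) -> None:
        if self.root_id not in self.segments:
            raise ValueError(f"root id {self.root_id!r} not among segments")
        self._children: dict[str, list[str]] = {s: [] for s in self.segments}
        for seg in self.segments.values():
            if seg.parent_id is not None:
                if seg.parent_id not in self.segments:
                    raise ValueError(
                        f"segment {seg.id}: missing parent {seg.parent_id!r}"
                    )
                self._children[seg.parent_id].append(seg.id)

    def __len__(self) -> int:
        return len(self.segments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AirwayTree):
            return NotImplemented
        return self.root_id == other.root_id and self.segments == other.segments

    @property
    def root(self) -> AirwaySegment:
        return self.segments[self.root_id]

    def children(self, segment_id: str) -> list[AirwaySegment]:
        return [self.segments[c] for c in self._children[segment_id]]

    def terminals(self) -> list[AirwaySegment]:
        return [s for s in self.segments.values() if s.is_terminal]

    @property
    def max_generation(self) -> int:
        return max(s.generation for s in self.segments.values())

    def total_volume_ml(self) -> float:
        return sum(s.volume_ml for s in self.segments.values())

    def scaled(self, factor: float) -> "AirwayTree":
        """Return a copy with all lengths and diameters multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        segs = {
            k: replace(s, length=s.length * factor, diameter=s.diameter * factor)
            for k, s in self.segments.items()
        }
        return AirwayTree(segments=segs, root_id=self.root_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.id for s in self.segments.values()],
                "parent_id": [s.parent_id for s in self.segments.values()],
                "generation": [s.generation for s in self.segments.values()],
                "length_mm": [s.length for s in self.segments.values()],
                "diameter_mm": [s.diameter for s in self.segments.values()],
                "lobe": [s.lobe for s in self.segments.values()],
                "is_terminal": [s.is_terminal for s in self.segments.values()],
            }
        )


@dataclass(frozen=True)
class MorphometryParams:
    """Self-similar branching parameters.

    The homothety ratios default to the classic 2^(-1/3) ≈ 0.79 per
    generation; the trachea dimensions are pre-calibration placeholders for
    a ~0.76 kg preterm infant (the dead-space calibration rescales them).
    ``asymmetry_factor`` a splits each ratio into (1+a) / (1-a) between the
    two children, producing heterogeneous root-to-leaf path lengths.
    """

    trachea_length: float = 30.0    # mm
    trachea_diameter: float = 3.5   # mm
    diameter_ratio_per_generation: float = 0.79
    length_ratio_per_generation: float = 0.79
    asymmetry_factor: float = 0.1
    jitter_sd: float = 0.0          # log-scale sd of multiplicative jitter
    seed: int = 0
    max_generation: int = 7

    def __post_init__(self) -> None:
        for name in ("diameter_ratio_per_generation", "length_ratio_per_generation"):
            r = getattr(self, name)
            if not 0 < r < 1:
                raise ValueError(f"{name} must be in (0, 1), got {r}")
        if not 0 <= self.asymmetry_factor <= 0.5:
            raise ValueError("asymmetry_factor must be in [0, 0.5]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be nonnegative")
        if self.trachea_length <= 0 or self.trachea_diameter <= 0:
            raise ValueError("trachea dimensions must be positive")
        if self.max_generation < 1:
            raise ValueError("max_generation must be at least 1")


def _lobe_label(seg_id: str, generation: int) -> str:
    """Lobe bookkeeping: five lobes from the generation-2 subtrees.

    The four grandchildren of the trachea are mapped to RUL, (RML|RLL split
    at generation 3), LUL and LLL; the trachea and main bronchi are labelled
    'trachea/main'.  Purely for reporting.
    """
    if generation < 2:
        return "trachea/main"
    # seg ids are the root id followed by one 'L'/'R' letter per generation
    path = seg_id[1:]
    branch2 = path[:2]
    if branch2 == "LL":
        return "RUL"
    if branch2 == "LR":
        if generation == 2:
            return "RLL"
        return "RML" if path[2] == "L" else "RLL"
    if branch2 == "RL":
        return "LUL"
    return "LLL"


def generate_tree(
    params: MorphometryParams = MorphometryParams(),
    body_mass: float = 0.76,
    target_deadspace_per_kg: float | None = 2.2,
) -> AirwayTree:
    """Generate the dichotomous generations 0..max_generation tree.

    Children of a segment scale its length and diameter by the per-generation
    ratios, split asymmetrically by ``asymmetry_factor`` and perturbed by
    seeded log-normal jitter.  If ``target_deadspace_per_kg`` is given, every
    linear dimension is rescaled by the unique global factor making
    :func:`dead_space` equal the target (volume scales with the cube of a
    uniform linear factor).
    """
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    if target_deadspace_per_kg is not None and target_deadspace_per_kg <= 0:
        raise ValueError("target_deadspace_per_kg must be positive")
    rng = np.random.default_rng(params.seed)
    gmax = params.max_generation
    segments: dict[str, AirwaySegment] = {}
    root = AirwaySegment(
        id="T",
        parent_id=None,
        generation=0,
        length=params.trachea_length,
        diameter=params.trachea_diameter,
        lobe="trachea/main",
        is_terminal=(gmax == 0),
    )
    segments[root.id] = root

    def grow(parent: AirwaySegment) -> None:
        if parent.generation >= gmax:
            return
        a = params.asymmetry_factor
        for letter, factor in (("L", 1.0 + a), ("R", 1.0 - a)):
            jl = math.exp(rng.normal(0.0, params.jitter_sd)) if params.jitter_sd else 1.0
            jd = math.exp(rng.normal(0.0, params.jitter_sd)) if params.jitter_sd else 1.0
            gen = parent.generation + 1
            seg_id = parent.id + letter
            child = AirwaySegment(
                id=seg_id,
                parent_id=parent.id,
                generation=gen,
                length=parent.length * params.length_ratio_per_generation * factor * jl,
                diameter=parent.diameter
                * params.diameter_ratio_per_generation
                * factor
                * jd,
                lobe=_lobe_label(seg_id, gen),
                is_terminal=(gen == gmax),
            )
            segments[child.id] = child
            grow(child)

    grow(root)
    tree = AirwayTree(segments=segments, root_id=root.id)
    if target_deadspace_per_kg is not None:
        target_ml = target_deadspace_per_kg * body_mass
        factor = (target_ml / tree.total_volume_ml()) ** (1.0 / 3.0)
        tree = tree.scaled(factor)
    return tree


def dead_space(tree: AirwayTree, body_mass: float) -> float:
    """Anatomical dead space of the conducting tree, ml per kg body weight."""
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    return tree.total_volume_ml() / body_mass


def validate_tree(tree: AirwayTree) -> list[str]:
    """Check structural invariants; return a list of violations (empty = valid).

    Rules: a single generation-0 root; connectivity from the root;
    generation(child) = generation(parent) + 1; every non-terminal segment
    has exactly two children; the terminal flag marks exactly the
    deepest-generation segments.
    """
    violations: list[str] = []
    roots = [s for s in tree.segments.values() if s.parent_id is None]
    if len(roots) != 1:
        violations.append(
            f"root: expected exactly one parentless segment, found "
            f"{[s.id for s in roots]}"
        )
    if tree.root.generation != 0:
        violations.append(f"root {tree.root_id}: generation is {tree.root.generation}, not 0")

    # connectivity
    reachable: set[str] = set()
    stack = [tree.root_id]
    while stack:
        sid = stack.pop()
        if sid in reachable:
            violations.append(f"{sid}: cycle detected")
            continue
        reachable.add(sid)
        stack.extend(c.id for c in tree.children(sid))
    for sid in tree.segments:
        if sid not in reachable:
            violations.append(f"{sid}: disconnected from root")

    gmax = tree.max_generation
    for seg in tree.segments.values():
        if seg.parent_id is not None:
            pgen = tree.segments[seg.parent_id].generation
            if seg.generation != pgen + 1:
                violations.append(
                    f"{seg.id}: generation {seg.generation} is not parent+1 ({pgen + 1})"
                )
        nchild = len(tree.children(seg.id))
        if seg.is_terminal and nchild != 0:
            violations.append(f"{seg.id}: terminal segment has children")
        if not seg.is_terminal and nchild != 2:
            violations.append(
                f"{seg.id}: non-terminal segment has {nchild} children (expected 2)"
            )
        if seg.is_terminal != (seg.generation == gmax):
            violations.append(
                f"{seg.id}: terminal flag inconsistent with generation {seg.generation}"
            )
    return violations


_COLUMNS = ["id", "parent_id", "generation", "length_mm", "diameter_mm", "lobe", "is_terminal"]


def write_tree(tree: AirwayTree, path: str | Path) -> None:
    """Write the tree in the tabular dialect (CSV, header mandatory).

    One row per segment; the root's parent field is empty.  Floats are
    written with full round-trip precision.
    """
    df = tree.to_frame()
    df["parent_id"] = df["parent_id"].fillna("")
    df["length_mm"] = [repr(float(x)) for x in df["length_mm"]]
    df["diameter_mm"] = [repr(float(x)) for x in df["diameter_mm"]]
    df[_COLUMNS].to_csv(path, index=False)


def read_tree(path: str | Path) -> AirwayTree:
    """Read a tree written by :func:`write_tree`; inverse round-trip exact."""
    try:
        df = pd.read_csv(
            path,
            dtype={"id": str, "parent_id": str, "lobe": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no root (empty file)") from None
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    segments: dict[str, AirwaySegment] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        sid = row.id
        if not isinstance(sid, str) or sid == "":
            raise ValueError(f"{path}: line {i}: missing id")
        if sid in segments:
            raise ValueError(f"{path}: line {i}: duplicate id {sid!r}")
        parent = row.parent_id if isinstance(row.parent_id, str) and row.parent_id else None
        try:
            segments[sid] = AirwaySegment(
                id=sid,
                parent_id=parent,
                generation=int(row.generation),
                length=float(row.length_mm),
                diameter=float(row.diameter_mm),
                lobe=row.lobe,
                is_terminal=bool(row.is_terminal),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from None
    roots = [s for s in segments.values() if s.parent_id is None]
    if not roots:
        raise ValueError(f"{path}: no root")
    for seg in segments.values():
        if seg.parent_id is not None and seg.parent_id not in segments:
            raise ValueError(f"{path}: segment {seg.id}: missing parent {seg.parent_id!r}")
    return AirwayTree(segments=segments, root_id=roots[0].id)
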