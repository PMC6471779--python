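"""Grid colour sets, region/neighbourhood colour functions, and unfolding.

Space is encoded by colouring every place with the colour set
``Grid3D = CS x CS x CS`` where ``CS = {1..D_i}`` (1-based, closed, no
wraparound).  A bacterial colony is a *region*: the set of grid positions
within Chebyshev-like per-axis radius ``R`` of a centre ``(M1,M2,M3)``
whose per-axis offsets are exact multiples of the sparseness ``S_i``
(``S_i = 1`` dense, ``S_i = 2`` one empty position between bacteria, ...).
Diffusion is guarded by the 26-point Moore neighbourhood ``neighbour3D26``
which degenerates to 8 neighbours in 2D (``D3 = 1``) and 2 in 1D.

``unfold`` expands a :class:`ColouredNet` into a flat
:class:`~qsbiofilm.petri.PetriNet` with one transition instance per
guard-satisfying colour binding; unfolded node names are
``basename__x_y_z`` so traces can be aggregated per position.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .petri import (
    ARC_STANDARD,
    POST,
    PRE,
    Arc,
    PetriNet,
    Place,
    PetriNetError,
    Transition,
)

__all__ = [
    "GridSpec",
    "Colour",
    "RegionSpec",
    "ColouredNet",
    "neighbours",
    "region_member",
    "region_positions",
    "unfold",
    "unfold_size_formula",
    "instance_name",
    "split_instance_name",
]


class Colour(NamedTuple):
    """A grid position; coordinates are 1-based."""

    x: int
    y: int
    z: int = 1


@dataclass(frozen=True)
class GridSpec:
    """Axis lengths of the environment grid (1D: D2=D3=1; 2D: D3=1)."""

    D1: int
    D2: int = 1
    D3: int = 1

    def __post_init__(self):
        if min(self.D1, self.D2, self.D3) < 1:
            raise PetriNetError("grid axis lengths must be >= 1")

    @classmethod
    def square(cls, D: int, dims: int = 2) -> "GridSpec":
        """Uniform grid of side D in 1, 2 or 3 dimensions."""
        if dims == 1:
            return cls(D, 1, 1)
        if dims == 2:
            return cls(D, D, 1)
        return cls(D, D, D)

    @property
    def dims(self) -> int:
        return 3 if self.D3 > 1 else (2 if self.D2 > 1 else 1)

    def __contains__(self, c: Colour) -> bool:
        return 1 <= c[0] <= self.D1 and 1 <= c[1] <= self.D2 and 1 <= c[2] <= self.D3

    def positions(self) -> Iterable[Colour]:
        for x in range(1, self.D1 + 1):
            for y in range(1, self.D2 + 1):
                for z in range(1, self.D3 + 1):
                    yield Colour(x, y, z)


@dataclass(frozen=True)
class RegionSpec:
    """Colony region: centre (M1,M2,M3), radius R, sparseness (S1,S2,S3)."""

    M1: int
    M2: int = 1
    M3: int = 1
    R: int = 0
    S1: int = 1
    S2: int = 1
    S3: int = 1

    def __post_init__(self):
        if self.R < 0:
            raise PetriNetError("region radius must be non-negative")
        if min(self.S1, self.S2, self.S3) < 1:
            raise PetriNetError("sparseness values must be positive")

    @property
    def centre(self) -> Colour:
        return Colour(self.M1, self.M2, self.M3)


def neighbours(g: GridSpec, c: Colour) -> set[Colour]:
    """Moore neighbourhood of ``c``: in-bounds c' != c with max|delta| = 1."""
    c = Colour(*c)
    if c not in g:
        raise PetriNetError(f"colour {tuple(c)} outside grid")
    out = set()
    for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3):
        if dx == dy == dz == 0:
            continue
        n = Colour(c.x + dx, c.y + dy, c.z + dz)
        if n in g:
            out.add(n)
    return out


def region_member(r: RegionSpec, c: Colour) -> bool:
    """True iff per axis i: |c_i - M_i| <= R and S_i divides (c_i - M_i)."""
    c = Colour(*c)
    for ci, mi, si in ((c.x, r.M1, r.S1), (c.y, r.M2, r.S2), (c.z, r.M3, r.S3)):
        d = ci - mi
        if abs(d) > r.R or d % si != 0:
            return False
    return True


def region_positions(g: GridSpec, r: RegionSpec) -> list[Colour]:
    """All in-bounds region members in lexicographic (x, y, z) order.

    The paper's configurations never clip, so a region whose bounding box
    leaves the grid is a configuration error.
    """
    if r.centre not in g:
        raise PetriNetError("region centre outside grid")
    out = [c for c in g.positions() if region_member(r, c)]
    # the occupied bounding box must fit the grid on every extended axis
    # (degenerate axes, D_i == 1, carry no spatial extent by construction)
    for mi, si, di in ((r.M1, r.S1, g.D1), (r.M2, r.S2, g.D2), (r.M3, r.S3, g.D3)):
        reach = (r.R // si) * si
        if di > 1 and (mi - reach < 1 or mi + reach > di):
            raise PetriNetError("region exceeds grid bounds")
    return out


# ---------------------------------------------------------------------------
# coloured nets and unfolding
# ---------------------------------------------------------------------------

GUARD_REGION = "region"
GUARD_NEIGHBOUR = "neighbour3D26"
EXPR_SELF = "(x,y,z)"  # the binding's own position
EXPR_NEIGHBOUR = "(a,b,c)"  # the Moore-adjacent partner position


@dataclass
class ColouredNet:
    """A flat net annotated with the Grid3D colour set.

    ``guards`` maps every transition to ``"region"`` (instantiate once per
    colony position) or ``"neighbour3D26"`` (instantiate once per ordered
    pair of Moore-adjacent cells).  ``arc_expressions`` maps ``(place,
    transition, direction)`` to ``"(x,y,z)"`` or ``"(a,b,c)"``; unannotated
    arcs default to ``"(x,y,z)"``.  ``coloured_initial`` maps place ->
    {colour: multiplicity} and overrides the base initial marking.
    """

    base: PetriNet
    guards: dict[str, str] = field(default_factory=dict)
    arc_expressions: dict[tuple, str] = field(default_factory=dict)
    coloured_initial: dict[str, dict[Colour, float]] = field(default_factory=dict)

    def __post_init__(self):
        for t in self.base.transitions:
            g = self.guards.get(t.name)
            if g not in (GUARD_REGION, GUARD_NEIGHBOUR):
                raise PetriNetError(
                    f"transition {t.name!r} needs a guard in "
                    f"{{{GUARD_REGION!r}, {GUARD_NEIGHBOUR!r}}}"
                )

    def expression(self, arc: Arc) -> str:
        return self.arc_expressions.get(
            (arc.place, arc.transition, arc.direction), EXPR_SELF
        )


def instance_name(base: str, c: Colour) -> str:
    return f"{base}__{c.x}_{c.y}_{c.z}"


def split_instance_name(name: str) -> tuple[str, Colour]:
    base, coords = name.rsplit("__", 1)
    x, y, z = (int(v) for v in coords.split("_"))
    return base, Colour(x, y, z)


def unfold(cn: ColouredNet, g: GridSpec, r: RegionSpec) -> PetriNet:
    """Unfold a coloured net into a flat Petri net.

    Region-guarded transitions instantiate once per colony position with
    every arc bound to that position.  Neighbour-guarded transitions
    instantiate once per ordered pair of Moore-adjacent cells; arcs with
    the ``(a,b,c)`` expression bind to the partner cell.  Place instances
    are created for every colour that appears on an arc of a surviving
    transition instance plus every colour holding initial tokens; untouched
    colours are pruned.
    """
    colony = region_positions(g, r)
    places_seen: dict[str, dict[Colour, float]] = {}
    transitions: list[Transition] = []
    arcs: list[Arc] = []

    def touch(base_place: str, c: Colour):
        places_seen.setdefault(base_place, {}).setdefault(c, None)

    for t in cn.base.transitions:
        guard = cn.guards[t.name]
        pre = cn.base.pre_arcs(t.name)
        post = cn.base.post_arcs(t.name)
        if guard == GUARD_REGION:
            bindings = [(c, c) for c in colony]
        else:
            bindings = [
                (c, n) for c in g.positions() for n in sorted(neighbours(g, c))
            ]
        for own, partner in bindings:
            suffix = own if guard == GUARD_REGION else (own, partner)
            if guard == GUARD_REGION:
                tname = instance_name(t.name, own)
            else:
                tname = (
                    f"{t.name}__{own.x}_{own.y}_{own.z}"
                    f"__{partner.x}_{partner.y}_{partner.z}"
                )
            transitions.append(
                Transition(tname, t.regime, t.rate_constant, t.category)
            )
            for a in pre + post:
                c = partner if cn.expression(a) == EXPR_NEIGHBOUR else own
                if c not in g:
                    raise PetriNetError(
                        f"arc of {t.name!r} binds colour {tuple(c)} outside grid"
                    )
                touch(a.place, c)
                arcs.append(
                    Arc(instance_name(a.place, c), tname, a.direction, a.kind, a.weight)
                )

    # colours carrying initial tokens survive even with no adjacent transition
    for p in cn.base.places:
        init = cn.coloured_initial.get(p.name)
        if init:
            for c in init:
                touch(p.name, Colour(*c))

    places: list[Place] = []
    for p in cn.base.places:
        for c in sorted(places_seen.get(p.name, {})):
            init = cn.coloured_initial.get(p.name)
            value = float(init.get(c, 0.0)) if init is not None else p.initial
            places.append(Place(instance_name(p.name, c), p.regime, value))

    return PetriNet(
        places, transitions, arcs, dict(cn.base.constants), name=f"{cn.base.name}_unfolded"
    )


def unfold_size_formula(
    D: int,
    N: int,
    places_per_bacterium: int = 33,
    transitions_per_bacterium: int = 39,
) -> tuple[int, int]:
    """Closed-form unfolded size on a DxD 2D grid hosting N bacteria.

    places = P_b*N + D^2 (the shared environment species covers the whole
    grid, per-bacterium subnets only colony positions); transitions =
    T_b*N + 8D^2 - 12D + 4 (the second term counts ordered Moore-adjacent
    cell pairs of the DxD grid).  Defaults are the published per-bacterium
    subnet sizes.
    """
    return (
        places_per_bacterium * N + D * D,
        transitions_per_bacterium * N + 8 * D * D - 12 * D + 4,
    )
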