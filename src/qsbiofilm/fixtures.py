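"""Synthetic ground-truth fixtures: category traces, golden nets with
closed-form behaviour, and colony configurations.

``make_category_trace`` builds deterministic piecewise-linear traces that
satisfy exactly one behaviour-category formula at zero noise.  All clean
values sit mid-quantum (a global +0.005 offset) and all non-flat segments
use slopes of at least two truncation quanta per step, so adding noise
below 0.0045 never changes the truncated series and hence never changes
the classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ColouredNet, Colour, GridSpec, RegionSpec, region_positions
from .petri import (
    ARC_STANDARD,
    POST,
    PRE,
    Arc,
    PetriNet,
    PetriNetError,
    Place,
    Transition,
)
from .pltlc import CATEGORY_ORDER
from .simulate import Trace

__all__ = [
    "TraceRecipe",
    "make_category_trace",
    "make_golden_nets",
    "make_diffusion_model",
    "make_colony_configs",
]

_OFFSET = 0.005  # keeps every clean value mid-quantum
_SLOPE = 0.02  # two truncation quanta per unit step


@dataclass(frozen=True)
class TraceRecipe:
    """Recipe for a synthetic single-variable trace.

    ``category`` indexes the behaviour library (1-based, matching the
    order of :data:`qsbiofilm.pltlc.CATEGORY_ORDER`).
    """

    category: int
    amplitude: float = 10.0
    length: int = 400
    peak_frac: float = 0.35
    noise: float = 0.0
    seed: int = 0
    name: str = "X"

    def __post_init__(self):
        if not 1 <= self.category <= 6:
            raise PetriNetError("category must be in 1..6")
        if self.length < 20 or self.amplitude < 1.0 or not 0.1 <= self.peak_frac <= 0.8:
            raise PetriNetError("inconsistent trace recipe")
        if self.noise >= _OFFSET:
            raise PetriNetError("noise must stay below the truncation guard 0.005")


def _ramp(v0: float, v1: float, steps: int) -> np.ndarray:
    return np.linspace(v0, v1, steps, endpoint=False)


def make_category_trace(r: TraceRecipe) -> Trace:
    """Deterministic synthetic trace realising one behaviour category."""
    n, A = r.length, r.amplitude
    peak = max(int(n * r.peak_frac), 4)
    if r.category == 1:  # always steady state zero
        x = np.zeros(n)
    elif r.category == 2:  # always steady state above zero
        x = np.full(n, A)
    elif r.category == 3:  # decreasing weakly until steady state zero
        fall = min(n - 4, int(A / _SLOPE) + 1)
        x = np.concatenate([_ramp(A, 0.0, fall), np.zeros(n - fall)])
    elif r.category == 4:  # increasing weakly until steady state
        rise = min(n - 4, int(A / _SLOPE) + 1)
        x = np.concatenate([_ramp(0.0, A, rise), np.full(n - rise, A)])
    elif r.category == 5:  # peaks once, falls weakly to steady state zero
        fall = min(n - peak - 2, int(A / _SLOPE) + 1)
        x = np.concatenate([
            _ramp(0.0, A, peak), _ramp(A, 0.0, fall), np.zeros(n - peak - fall)])
    else:  # falls, rises to peak, falls weakly to steady state zero
        dip = max(peak // 2, 2)
        fall = min(n - peak - dip - 2, int(A / _SLOPE) + 1)
        x = np.concatenate([
            _ramp(A / 2, A / 4, dip), _ramp(A / 4, A, peak),
            _ramp(A, 0.0, fall), np.zeros(n - dip - peak - fall)])
    # slopes must clear two quanta per step; rescale time if they do not
    x = x + _OFFSET
    if r.noise > 0:
        rng = np.random.default_rng(r.seed)
        x = np.clip(x + rng.uniform(-r.noise, r.noise, size=n), 0.0, None)
    times = np.arange(n, dtype=float)
    return Trace(times, x[:, None], [r.name],
                 {"recipe_category": CATEGORY_ORDER[r.category - 1],
                  "seed": r.seed})


# ---------------------------------------------------------------------------
# golden nets
# ---------------------------------------------------------------------------

def make_golden_nets() -> dict[str, PetriNet]:
    """Small nets with closed-form or structurally known behaviour.

    * ``degradation`` -- A -> 0 with k=0.1, A(0)=100; mean 100 e^{-0.1 t}.
    * ``birth_death`` -- 0 -> A (5.0), A -> 0 (0.5); stationary mean 10.
    * ``cycle`` -- conservative A <-> B loop; one P-invariant {A, B}.
    * ``chain`` -- irreversible A -> B; no T-invariant cover.
    """
    nets = {}
    nets["degradation"] = PetriNet(
        [Place("A", "discrete", 100)],
        [Transition("deg", "stochastic", 0.1)],
        [Arc("A", "deg", PRE, ARC_STANDARD, 1)],
        name="degradation",
    )
    nets["birth_death"] = PetriNet(
        [Place("A", "discrete", 0)],
        [Transition("birth", "stochastic", 5.0),
         Transition("death", "stochastic", 0.5)],
        [Arc("A", "birth", POST, ARC_STANDARD, 1),
         Arc("A", "death", PRE, ARC_STANDARD, 1)],
        name="birth_death",
    )
    nets["cycle"] = PetriNet(
        [Place("A", "discrete", 5), Place("B", "discrete", 0)],
        [Transition("ab", "stochastic", 1.0), Transition("ba", "stochastic", 1.0)],
        [Arc("A", "ab", PRE, ARC_STANDARD, 1), Arc("B", "ab", POST, ARC_STANDARD, 1),
         Arc("B", "ba", PRE, ARC_STANDARD, 1), Arc("A", "ba", POST, ARC_STANDARD, 1)],
        name="cycle",
    )
    nets["chain"] = PetriNet(
        [Place("A", "discrete", 1), Place("B", "discrete", 0)],
        [Transition("ab", "stochastic", 1.0)],
        [Arc("A", "ab", PRE, ARC_STANDARD, 1), Arc("B", "ab", POST, ARC_STANDARD, 1)],
        name="chain",
    )
    return nets


def make_diffusion_model(tokens: int = 1000, k: float = 1.0):
    """The pure-diffusion coloured net: one place, one two-way transition
    guarded by the Moore neighbourhood, all tokens initially at the grid
    centre.  Returns a factory mapping a GridSpec to
    ``(ColouredNet, RegionSpec)``."""

    def build(g: GridSpec) -> tuple[ColouredNet, RegionSpec]:
        centre = Colour((g.D1 + 1) // 2, (g.D2 + 1) // 2, (g.D3 + 1) // 2)
        base = PetriNet(
            [Place("A", "discrete", tokens)],
            [Transition("Diffusion", "stochastic", k)],
            [Arc("A", "Diffusion", PRE, ARC_STANDARD, 1),
             Arc("A", "Diffusion", POST, ARC_STANDARD, 1)],
            name="diffusion",
        )
        cn = ColouredNet(
            base,
            {"Diffusion": "neighbour3D26"},
            {("A", "Diffusion", POST): "(a,b,c)"},
            {"A": {centre: tokens}},
        )
        return cn, RegionSpec(*centre, R=0)

    return build


# ---------------------------------------------------------------------------
# colony configurations
# ---------------------------------------------------------------------------

def named_colony_configs() -> list[tuple[str, GridSpec, RegionSpec]]:
    """The fixed experiment configurations: 21x21 with R in {0,2,5,7} and
    101x101 with R in {0,2,4,7,9,11}, sparseness chosen so every colony
    except the single bacterium holds 5x5 = 25 positions."""
    out = []
    for D, rs in ((21, [(0, 1), (2, 1), (5, 2), (7, 3)]),
                  (101, [(0, 1), (2, 1), (4, 2), (7, 3), (9, 4), (11, 5)])):
        m = (D + 1) // 2
        for R, S in rs:
            out.append((f"{D}x{D}_R{R}",
                        GridSpec.square(D, 2),
                        RegionSpec(m, m, 1, R, S, S, 1)))
    return out


def make_colony_configs(n: int, seed: int = 0) -> list[tuple[GridSpec, RegionSpec]]:
    """``n`` random valid (grid, region) pairs spanning 1D/2D/3D, with the
    named experiment configurations always included first."""
    if n < 1:
        raise PetriNetError("need n >= 1 configurations")
    out = [(g, r) for _, g, r in named_colony_configs()]
    target = max(n, len(out))
    rng = np.random.default_rng(seed)
    while len(out) < target:
        dims = int(rng.integers(1, 4))
        D = int(rng.integers(5, 16))
        g = GridSpec.square(D, dims)
        m = (D + 1) // 2
        R = int(rng.integers(0, (D - 1) // 2 + 1))
        S = int(rng.integers(1, max(R, 1) + 1))
        r = RegionSpec(m, m if dims >= 2 else 1, m if dims == 3 else 1,
                       R, S, S, S)
        try:
            region_positions(g, r)
        except PetriNetError:
            continue
        out.append((g, r))
    return out
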