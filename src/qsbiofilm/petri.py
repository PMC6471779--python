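"""Extended hybrid Petri nets with mass-action kinetics.

The data model covers the extended net class used throughout the package:
discrete and continuous places, stochastic and continuous transitions, and
three arc kinds -- ``standard`` (consuming/producing), ``read`` (enabling
test ``m(p) >= w``) and ``inhibitor`` (enabling test ``m(p) < w``).  Test
arcs never move tokens and contribute nothing to the incidence matrix.

All firing rates follow mass-action kinetics: for a transition with rate
constant ``k`` the propensity/rate is ``k`` times, for every standard or
read pre-arc, the combinatorial factor ``C(m(p), w)`` when the place is
discrete and ``m(p)**w`` when it is continuous.  Inhibitor arcs gate the
rate (it is zero when the transition is disabled) but never contribute a
magnitude factor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "Place",
    "Transition",
    "Arc",
    "PetriNet",
    "Marking",
    "is_enabled",
    "rate",
    "fire",
    "incidence_matrix",
    "load_net",
    "save_net",
    "import_sbml",
    "PetriNetError",
]


class PetriNetError(ValueError):
    """Raised for structural errors: unknown nodes, bad arcs, bad markings."""


DISCRETE = "discrete"
CONTINUOUS = "continuous"
STOCHASTIC = "stochastic"

ARC_STANDARD = "standard"
ARC_READ = "read"
ARC_INHIBITOR = "inhibitor"
PRE = "pre"
POST = "post"


@dataclass(frozen=True)
class Place:
    """A place (species/state variable) with a simulation regime.

    ``regime`` is ``"discrete"`` (integer token count) or ``"continuous"``
    (non-negative real concentration).
    """

    name: str
    regime: str = CONTINUOUS
    initial: float = 0.0

    def __post_init__(self):
        if self.regime not in (DISCRETE, CONTINUOUS):
            raise PetriNetError(f"unknown place regime {self.regime!r}")
        if self.initial < 0:
            raise PetriNetError(f"place {self.name}: negative initial marking")
        if self.regime == DISCRETE and self.initial != int(self.initial):
            raise PetriNetError(
                f"discrete place {self.name} requires integer initial marking"
            )


@dataclass(frozen=True)
class Transition:
    """A transition (reaction) with a mass-action rate constant.

    ``regime`` selects stochastic (exponential race) or continuous (ODE
    flux) interpretation; ``category`` optionally records the qualitative
    rate level (low/medium/high) of the biofilm component.
    """

    name: str
    regime: str = STOCHASTIC
    rate_constant: float = 1.0
    category: str | None = None

    def __post_init__(self):
        if self.regime not in (STOCHASTIC, CONTINUOUS):
            raise PetriNetError(f"unknown transition regime {self.regime!r}")
        if not self.rate_constant > 0:
            raise PetriNetError(
                f"transition {self.name}: rate constant must be positive"
            )
        if self.category not in (None, "low", "medium", "high"):
            raise PetriNetError(f"unknown rate category {self.category!r}")


@dataclass(frozen=True)
class Arc:
    """An arc between a place and a transition.

    ``weight`` may be a positive integer or the name of a net constant
    (e.g. ``"THR"``) resolved against ``PetriNet.constants``.
    """

    place: str
    transition: str
    direction: str = PRE
    kind: str = ARC_STANDARD
    weight: int | str = 1

    def __post_init__(self):
        if self.direction not in (PRE, POST):
            raise PetriNetError(f"bad arc direction {self.direction!r}")
        if self.kind not in (ARC_STANDARD, ARC_READ, ARC_INHIBITOR):
            raise PetriNetError(f"bad arc kind {self.kind!r}")
        if self.kind in (ARC_READ, ARC_INHIBITOR) and self.direction != PRE:
            raise PetriNetError("read/inhibitor arcs must have direction 'pre'")
        if isinstance(self.weight, bool) or (
            isinstance(self.weight, int) and self.weight < 1
        ):
            raise PetriNetError("arc weights must be positive integers")


@dataclass
class Marking:
    """A marking: mapping from place name to token count / concentration."""

    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, place: str) -> float:
        return self.values.get(place, 0.0)

    def __setitem__(self, place: str, value: float) -> None:
        self.values[place] = value

    def copy(self) -> "Marking":
        return Marking(dict(self.values))


@dataclass
class PetriNet:
    """A bipartite net; node names must be unique across places+transitions."""

    places: list[Place] = field(default_factory=list)
    transitions: list[Transition] = field(default_factory=list)
    arcs: list[Arc] = field(default_factory=list)
    constants: dict[str, int] = field(default_factory=dict)
    name: str = "net"

    def __post_init__(self):
        self.validate()

    # -- lookup helpers -------------------------------------------------
    def validate(self) -> None:
        pnames = [p.name for p in self.places]
        tnames = [t.name for t in self.transitions]
        if len(set(pnames)) != len(pnames) or len(set(tnames)) != len(tnames):
            raise PetriNetError("duplicate node names")
        if set(pnames) & set(tnames):
            raise PetriNetError("place and transition names overlap")
        pset, tset = set(pnames), set(tnames)
        for a in self.arcs:
            if a.place not in pset:
                raise PetriNetError(f"arc references unknown place {a.place!r}")
            if a.transition not in tset:
                raise PetriNetError(
                    f"arc references unknown transition {a.transition!r}"
                )
            self.resolve_weight(a)

    def place(self, name: str) -> Place:
        for p in self.places:
            if p.name == name:
                return p
        raise PetriNetError(f"unknown place {name!r}")

    def transition(self, name: str) -> Transition:
        for t in self.transitions:
            if t.name == name:
                return t
        raise PetriNetError(f"unknown transition {name!r}")

    @property
    def place_names(self) -> list[str]:
        return [p.name for p in self.places]

    @property
    def transition_names(self) -> list[str]:
        return [t.name for t in self.transitions]

    def resolve_weight(self, arc: Arc) -> int:
        w = arc.weight
        if isinstance(w, str):
            if w not in self.constants:
                raise PetriNetError(f"undefined arc-weight constant {w!r}")
            w = self.constants[w]
        if not isinstance(w, (int, np.integer)) or w < 1:
            raise PetriNetError(f"arc weight {arc.weight!r} must resolve to >= 1")
        return int(w)

    def pre_arcs(self, transition: str) -> list[Arc]:
        return [a for a in self.arcs if a.transition == transition and a.direction == PRE]

    def post_arcs(self, transition: str) -> list[Arc]:
        return [a for a in self.arcs if a.transition == transition and a.direction == POST]

    def initial_marking(self) -> Marking:
        return Marking({p.name: p.initial for p in self.places})

    def with_rate(self, transition: str, rate_constant: float) -> "PetriNet":
        """Return a copy of the net with one transition's rate replaced."""
        self.transition(transition)  # existence check
        trans = [
            replace(t, rate_constant=rate_constant) if t.name == transition else t
            for t in self.transitions
        ]
        return PetriNet(list(self.places), trans, list(self.arcs),
                        dict(self.constants), self.name)


# ---------------------------------------------------------------------------
# firing semantics
# ---------------------------------------------------------------------------

def is_enabled(net: PetriNet, t: str, m: Marking) -> bool:
    """True iff every standard/read pre-arc has ``m(p) >= w`` and every
    inhibitor pre-arc has ``m(p) < w``."""
    net.transition(t)
    for a in net.pre_arcs(t):
        w = net.resolve_weight(a)
        mv = m[a.place]
        if a.kind == ARC_INHIBITOR:
            if not mv < w:
                return False
        else:
            if not mv >= w:
                return False
    return True


def rate(net: PetriNet, t: str, m: Marking) -> float:
    """Mass-action rate of ``t`` at marking ``m`` (0 when disabled)."""
    for a in net.pre_arcs(t):
        if m[a.place] < 0:
            raise PetriNetError(f"negative marking on place {a.place!r}")
    if not is_enabled(net, t, m):
        return 0.0
    r = net.transition(t).rate_constant
    for a in net.pre_arcs(t):
        if a.kind == ARC_INHIBITOR:
            continue
        w = net.resolve_weight(a)
        mv = m[a.place]
        if net.place(a.place).regime == DISCRETE:
            r *= math.comb(int(mv), w)
        else:
            r *= mv**w
    return r


def fire(net: PetriNet, t: str, m: Marking) -> Marking:
    """Fire ``t`` once; read/inhibitor arcs leave tested places unchanged."""
    if not is_enabled(net, t, m):
        raise PetriNetError(f"transition {t!r} is not enabled")
    out = m.copy()
    for a in net.pre_arcs(t):
        if a.kind == ARC_STANDARD:
            out[a.place] = out[a.place] - net.resolve_weight(a)
    for a in net.post_arcs(t):
        out[a.place] = out[a.place] + net.resolve_weight(a)
    for p in net.places:
        v = out[p.name]
        if v < 0:
            raise PetriNetError(f"firing {t!r} made place {p.name!r} negative")
        if p.regime == DISCRETE and v != int(v):
            raise PetriNetError(f"discrete place {p.name!r} left non-integral")
    return out


def incidence_matrix(net: PetriNet) -> np.ndarray:
    """Integer incidence matrix C (places x transitions).

    Entry C[p, t] = post-weight - standard-pre-weight; read and inhibitor
    arcs contribute 0, so constant places tested only by read arcs get
    all-zero rows.
    """
    pidx = {p.name: i for i, p in enumerate(net.places)}
    tidx = {t.name: j for j, t in enumerate(net.transitions)}
    C = np.zeros((len(net.places), len(net.transitions)), dtype=np.int64)
    for a in net.arcs:
        if a.kind != ARC_STANDARD:
            continue
        w = net.resolve_weight(a)
        if a.direction == PRE:
            C[pidx[a.place], tidx[a.transition]] -= w
        else:
            C[pidx[a.place], tidx[a.transition]] += w
    return C


# ---------------------------------------------------------------------------
# native YAML/JSON net format
# ---------------------------------------------------------------------------

def net_to_dict(net: PetriNet) -> dict:
    return {
        "name": net.name,
        "constants": dict(net.constants),
        "places": [
            {"name": p.name, "regime": p.regime, "initial": p.initial}
            for p in net.places
        ],
        "transitions": [
            {
                "name": t.name,
                "regime": t.regime,
                "rate_constant": t.rate_constant,
                **({"category": t.category} if t.category else {}),
            }
            for t in net.transitions
        ],
        "arcs": [
            {
                "place": a.place,
                "transition": a.transition,
                "direction": a.direction,
                "kind": a.kind,
                "weight": a.weight,
            }
            for a in net.arcs
        ],
    }


def net_from_dict(d: dict) -> PetriNet:
    return PetriNet(
        places=[Place(**p) for p in d.get("places", [])],
        transitions=[Transition(**t) for t in d.get("transitions", [])],
        arcs=[Arc(**a) for a in d.get("arcs", [])],
        constants=dict(d.get("constants", {})),
        name=d.get("name", "net"),
    )


def save_net(net: PetriNet, path) -> None:
    path = str(path)
    d = net_to_dict(net)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(d, fh, indent=1)
        else:
            yaml.safe_dump(d, fh, sort_keys=False)


def load_net(path) -> PetriNet:
    path = str(path)
    with open(path) as fh:
        d = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    return net_from_dict(d)


# ---------------------------------------------------------------------------
# SBML level-2 import (mass-action subset)
# ---------------------------------------------------------------------------

def import_sbml(path_or_string, regime: str = CONTINUOUS) -> PetriNet:
    """Import an SBML level-2 model as a Petri net.

    Species become places (initialAmount/initialConcentration -> initial
    marking), reactions become transitions, reactant/product stoichiometry
    becomes standard arc weights and modifiers become read arcs.  The rate
    constant is taken from the first local kineticLaw parameter (or a
    matching global parameter) -- i.e. only mass-action models round-trip
    faithfully, which is all this package needs.
    """
    from lxml import etree

    text = path_or_string
    if isinstance(text, str) and text.lstrip().startswith("<"):
        root = etree.fromstring(text.encode())
    else:
        root = etree.parse(str(path_or_string)).getroot()

    def local(tag):
        return etree.QName(tag).localname

    model = next(el for el in root.iter() if local(el.tag) == "model")
    globals_: dict[str, float] = {}
    places, transitions, arcs = [], [], []
    for el in model.iter():
        if local(el.tag) == "parameter" and local(el.getparent().getparent().tag) == "model":
            globals_[el.get("id")] = float(el.get("value", "1"))
    for el in model.iter():
        if local(el.tag) == "species":
            init = el.get("initialAmount") or el.get("initialConcentration") or "0"
            places.append(Place(el.get("id"), regime=regime, initial=float(init)))
    for el in model.iter():
        if local(el.tag) != "reaction":
            continue
        rid = el.get("id")
        k = 1.0
        for sub in el.iter():
            tag = local(sub.tag)
            if tag == "parameter":  # first local kineticLaw parameter
                k = float(sub.get("value", "1"))
                break
            if tag == "ci" and sub.text and sub.text.strip() in globals_:
                k = globals_[sub.text.strip()]
        transitions.append(Transition(rid, regime=regime, rate_constant=k))
        for sub in el.iter():
            tag = local(sub.tag)
            if tag == "speciesReference":
                w = int(float(sub.get("stoichiometry", "1")))
                parent = local(sub.getparent().tag)
                direction = PRE if parent == "listOfReactants" else POST
                arcs.append(Arc(sub.get("species"), rid, direction, ARC_STANDARD, w))
            elif tag == "modifierSpeciesReference":
                arcs.append(Arc(sub.get("species"), rid, PRE, ARC_READ, 1))
    return PetriNet(places, transitions, arcs, {}, name=model.get("id") or "sbml")
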