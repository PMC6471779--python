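"""Builders for the four model variants of the AI-2 quorum-sensing model.

* :func:`build_phase2` -- AI-2 production during exponential growth
  (methionine cycle, SAM decarboxylation branch, LuxS/Pfs expression),
  21 places and 23 transitions, two finite source pools (Nutrients,
  Putrescine) and two constant gene places attached by read arcs.
* :func:`build_phase3` -- biofilm formation during stationary phase
  (lsr import/repression circuit), 11 places and 15 transitions plus the
  discrete threshold "go" mechanism (place ``go``, stochastic transitions
  ``open``/``close`` wired with read and inhibitor arcs).
* :func:`build_combined` -- the union of both, fused on the shared
  environment pool ``AI2_Out``, plus a ``Diffusion`` sink whose rate
  constant is the diffusion parameter multiplied by the Moore neighbour
  count of the intended dimensionality (2, 8 or 26).
* :func:`build_spatial` -- the combined model as a coloured net over a
  grid: every place coloured ``Grid3D``, every transition guarded by the
  colony ``region`` predicate except ``Diffusion``, which becomes a
  two-way transport between Moore-adjacent cells.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

from .grid import (
    EXPR_NEIGHBOUR,
    GUARD_NEIGHBOUR,
    GUARD_REGION,
    ColouredNet,
    GridSpec,
    RegionSpec,
    region_positions,
)
from .petri import (
    ARC_INHIBITOR,
    ARC_READ,
    ARC_STANDARD,
    POST,
    PRE,
    Arc,
    PetriNet,
    PetriNetError,
    Place,
    Transition,
)

__all__ = [
    "ModelVariant",
    "build_phase2",
    "build_phase3",
    "build_combined",
    "build_spatial",
    "load_phase2_params",
    "PHASE3_CATEGORY",
]

#: Rate-level ratios are fixed at 1 : 10 : 10^4 for the stand-alone
#: biofilm component and rescaled to 1e-4 : 1e-3 : 1 in the combined model.
PHASE3_LEVELS = {"low": 1.0, "medium": 10.0, "high": 1.0e4}
COMBINED_LEVELS = {"low": 1.0e-4, "medium": 1.0e-3, "high": 1.0}

NEIGHBOUR_COUNT = {1: 2, 2: 8, 3: 26}


@dataclass(frozen=True)
class ModelVariant:
    """Configuration shared by the builders.

    ``THR_open``/``THR_close`` are the open/close thresholds of the go
    mechanism (the close threshold defaults to 1; the combined and spatial
    experiments use the symmetric setting 40/40).  ``dims`` selects the
    dimensionality whose neighbour count scales the non-spatial Diffusion
    rate.  ``hybrid_partition`` lists the transitions kept stochastic in
    the hybrid reading.
    """

    name: str = "combined"
    THR_open: int = 40
    THR_close: int = 1
    rate_levels: tuple = tuple(sorted(COMBINED_LEVELS.items()))
    diffusion_k: float = 0.1
    dims: int = 2
    hybrid_partition: frozenset = frozenset({"open", "close"})

    def __post_init__(self):
        levels = dict(self.rate_levels)
        if not (self.THR_open >= self.THR_close >= 1):
            raise PetriNetError("configurations require THR_open >= THR_close >= 1")
        lo, me, hi = levels["low"], levels["medium"], levels["high"]
        if abs(me / lo - 10.0) > 1e-9 or abs(hi / lo - 1.0e4) > 1e-6 * 1e4:
            raise PetriNetError("rate levels must keep the ratio 1 : 10 : 10^4")

    @property
    def levels(self) -> dict[str, float]:
        return dict(self.rate_levels)

    @classmethod
    def phase3(cls, THR_open: int = 10, THR_close: int = 1) -> "ModelVariant":
        return cls("phase3", THR_open, THR_close,
                   tuple(sorted(PHASE3_LEVELS.items())))

    @classmethod
    def combined(cls, THR_open: int = 40, THR_close: int = 40,
                 diffusion_k: float = 0.1, dims: int = 2) -> "ModelVariant":
        return cls("combined", THR_open, THR_close,
                   tuple(sorted(COMBINED_LEVELS.items())), diffusion_k, dims)


# ---------------------------------------------------------------------------
# phase 2: AI-2 production
# ---------------------------------------------------------------------------

#: (transition, [standard pre], [read pre], [post]) -- all weights 1.
PHASE2_REACTIONS: list[tuple[str, list[str], list[str], list[str]]] = [
    ("bio_reac", ["Nutrients"], [], ["Met"]),
    ("AdoMet", ["Met"], [], ["SAM"]),
    ("MethyTrans", ["SAM"], [], ["SAH"]),
    ("SAH_Hydro", ["SAH"], ["Pfs_prot"], ["SRH", "Adenine"]),
    ("SRH_cleave", ["SRH"], ["LuxS_prot"], ["Homocys", "DPD"]),
    ("Met_recover", ["Homocys", "Adenine"], [], ["Met"]),
    ("AI2_syn", ["DPD"], [], ["AI2_In_Phase2"]),
    ("DPD_deg", ["DPD"], [], []),
    ("AI2_excret", ["AI2_In_Phase2"], [], ["AI2_Out"]),
    ("SAM_Decarb", ["SAM"], [], ["Decarb_SAM"]),
    ("SpeE_syn", ["Decarb_SAM", "Putrescine"], [], ["MTA", "Spermidine"]),
    ("MTR_syn", ["MTA"], ["Pfs_prot"], ["MTR", "Spermidine"]),
    ("MTR_excret", ["MTR"], [], []),
    ("Spermi_util", ["Spermidine"], [], []),
    ("Polyamin_util", ["Putrescine"], [], []),
    ("LuxS_transcription", [], ["luxS_gene"], ["LuxS_mRNA"]),
    ("LuxS_translation", [], ["LuxS_mRNA"], ["LuxS_prot"]),
    ("LuxS_mRNA_deg", ["LuxS_mRNA"], [], []),
    ("LuxS_prot_deg", ["LuxS_prot"], [], []),
    ("pfs_transcription", [], ["pfs_gene"], ["Pfs_mRNA"]),
    ("pfs_translation", [], ["Pfs_mRNA"], ["Pfs_prot"]),
    ("Pfs_mRNA_deg", ["Pfs_mRNA"], [], []),
    ("Pfs_prot_deg", ["Pfs_prot"], [], []),
]

PHASE2_PLACES = [
    "Adenine", "AI2_In_Phase2", "AI2_Out", "Decarb_SAM", "DPD", "Homocys",
    "luxS_gene", "LuxS_mRNA", "LuxS_prot", "Met", "MTA", "MTR", "Nutrients",
    "pfs_gene", "Pfs_mRNA", "Pfs_prot", "Putrescine", "SAH", "SAM",
    "Spermidine", "SRH",
]


def load_phase2_params(path=None) -> dict:
    """Load the packaged AI-2 production parameter set.

    The shipped file is a synthetic stand-in for the original experimental
    parameterisation (which is not printed in any source available to this
    package); it was calibrated so the continuous trace reproduces the
    published qualitative behaviour of every species.
    """
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    ref = importlib.resources.files("qsbiofilm").joinpath(
        "data/phase2_params_synthetic.yaml"
    )
    return yaml.safe_load(ref.read_text())


def build_phase2(params: dict | None = None) -> PetriNet:
    """AI-2 production model: 21 places, 23 transitions.

    ``params`` maps ``rate_constants`` (by transition) and
    ``initial_marking`` (by place); missing entries raise a build error
    naming the node.
    """
    if params is None or isinstance(params, (str, bytes)) or hasattr(params, "__fspath__"):
        params = load_phase2_params(params)
    rates = params["rate_constants"]
    init = params["initial_marking"]
    places, transitions, arcs = [], [], []
    for name in PHASE2_PLACES:
        if name not in init:
            raise PetriNetError(f"phase 2 build: missing initial marking for {name!r}")
        places.append(Place(name, "continuous", float(init[name])))
    for tname, pre, read, post in PHASE2_REACTIONS:
        if tname not in rates:
            raise PetriNetError(f"phase 2 build: missing rate constant for {tname!r}")
        transitions.append(Transition(tname, "continuous", float(rates[tname])))
        for p in pre:
            arcs.append(Arc(p, tname, PRE, ARC_STANDARD, 1))
        for p in read:
            arcs.append(Arc(p, tname, PRE, ARC_READ, 1))
        for p in post:
            arcs.append(Arc(p, tname, POST, ARC_STANDARD, 1))
    return PetriNet(places, transitions, arcs, {}, name="phase2")


# ---------------------------------------------------------------------------
# phase 3: biofilm formation
# ---------------------------------------------------------------------------

PHASE3_CATEGORY = {
    "BasalProduceLsrABCD": "low",
    "BasalProduceLsrK": "low",
    "BasalProduceLsrR": "low",
    "LsrABCD_deg": "low",
    "LsrK_deg": "low",
    "LsrR_deg": "low",
    "LsrR_AI2_P_deg": "low",
    "open": "high",
    "close": "high",
    # medium: all other transitions
    "inflow": "medium",
    "Transport_in": "medium",
    "Phosphorylation": "medium",
    "repress": "medium",
    "derepress": "medium",
    "TranscribeTranslate": "medium",
    "Biofilmformation_AI2": "medium",
    "Biofilmformation_LsrR": "medium",
}

#: (transition, [standard pre], [(read place, weight)], [(inhibitor place,
#: weight)], [post]) -- weights may name net constants.
PHASE3_REACTIONS = [
    ("inflow", [], [], [], ["AI2_Out"]),
    ("open", [], [("AI2_Out", "THR")], [("go", 1)], ["go"]),
    ("close", ["go"], [], [("AI2_Out", "THR_close")], []),
    ("Transport_in", ["AI2_Out"], [("LsrABCD", 1), ("go", 1)], [], ["AI2_In"]),
    ("Phosphorylation", ["AI2_In"], [("LsrK", 1)], [], ["AI2_P"]),
    ("repress", ["LsrR", "lsrGenes"], [], [], ["lsrGenes_LsrR"]),
    ("derepress", ["lsrGenes_LsrR", "AI2_P"], [], [], ["lsrGenes", "LsrR_AI2_P"]),
    ("TranscribeTranslate", [], [("lsrGenes", 1)], [], ["LsrABCD", "LsrK", "LsrR"]),
    ("BasalProduceLsrABCD", [], [], [], ["LsrABCD"]),
    ("BasalProduceLsrK", [], [], [], ["LsrK"]),
    ("BasalProduceLsrR", [], [], [], ["LsrR"]),
    ("LsrABCD_deg", ["LsrABCD"], [], [], []),
    ("LsrK_deg", ["LsrK"], [], [], []),
    ("LsrR_deg", ["LsrR"], [], [], []),
    ("LsrR_AI2_P_deg", ["LsrR_AI2_P"], [], [], []),
    ("Biofilmformation_AI2", ["AI2_In"], [("QSeBC", 1)], [], ["Biofilm"]),
    ("Biofilmformation_LsrR", ["LsrR"], [("AI2_In", 1)], [], ["Biofilm"]),
]

#: Table of initial token counts for the biofilm component.
PHASE3_INITIAL = {
    "QSeBC": 1,           # constant coupling sensor, never changes
    "lsrGenes_LsrR": 1,   # repressed state of the lsr genes
    "LsrABCD": 1, "LsrK": 1, "LsrR": 1,  # basal Lsr protein levels
    # all other places start empty
    "AI2_In": 0, "AI2_Out": 0, "AI2_P": 0, "Biofilm": 0, "go": 0,
    "lsrGenes": 0, "LsrR_AI2_P": 0,
}

PHASE3_GO_NODES = frozenset({"go", "open", "close"})


def build_phase3(variant: ModelVariant | None = None) -> PetriNet:
    """Biofilm formation model: 11 core places + go, 15 core transitions +
    open/close (12 places, 17 transitions in total)."""
    if variant is None:
        variant = ModelVariant.phase3()
    levels = variant.levels
    places = []
    for name, value in sorted(PHASE3_INITIAL.items()):
        regime = "discrete" if name == "go" else "continuous"
        places.append(Place(name, regime, value))
    transitions, arcs = [], []
    for tname, pre, read, inh, post in PHASE3_REACTIONS:
        cat = PHASE3_CATEGORY[tname]
        regime = "stochastic" if tname in variant.hybrid_partition | {"open", "close"} else "continuous"
        transitions.append(Transition(tname, regime, levels[cat], cat))
        for p in pre:
            arcs.append(Arc(p, tname, PRE, ARC_STANDARD, 1))
        for p, w in read:
            arcs.append(Arc(p, tname, PRE, ARC_READ, w))
        for p, w in inh:
            arcs.append(Arc(p, tname, PRE, ARC_INHIBITOR, w))
        for p in post:
            arcs.append(Arc(p, tname, POST, ARC_STANDARD, 1))
    constants = {"THR": variant.THR_open, "THR_close": variant.THR_close}
    return PetriNet(places, transitions, arcs, constants, name="phase3")


def phase3_core(net: PetriNet) -> PetriNet:
    """The biofilm net with the go mechanism removed (11 places, 15
    transitions) -- the object of the structural analyses, which do not
    cover inhibitor arcs."""
    places = [p for p in net.places if p.name != "go"]
    transitions = [t for t in net.transitions if t.name not in ("open", "close")]
    keep_t = {t.name for t in transitions}
    arcs = [a for a in net.arcs
            if a.place != "go" and a.transition in keep_t]
    return PetriNet(places, transitions, arcs, dict(net.constants),
                    name=f"{net.name}_core")


# ---------------------------------------------------------------------------
# combined and spatial
# ---------------------------------------------------------------------------

def build_combined(variant: ModelVariant | None = None,
                   phase2_params: dict | None = None) -> PetriNet:
    """Combined two-phase model: phase 2 and phase 3 fused on the logical
    place AI2_Out, plus a Diffusion sink draining AI2_Out with rate
    constant ``diffusion_k * neighbour count``.

    Phase-3 rate levels are re-scaled to 1e-4 / 1e-3 / 1 to concord with
    the production component; AI2_In of each component is renamed
    AI2_In_Phase2 / AI2_In_Phase3.
    """
    if variant is None:
        variant = ModelVariant.combined()
    p2 = build_phase2(phase2_params)
    p3 = build_phase3(variant)

    def rename(name: str) -> str:
        return "AI2_In_Phase3" if name == "AI2_In" else name

    places = list(p2.places)
    names2 = set(p2.place_names)
    for p in p3.places:
        nm = rename(p.name)
        if nm == "AI2_Out":
            continue  # the logical (shared) place, already present
        if nm in names2:
            raise PetriNetError(f"unintended place collision {nm!r}")
        places.append(Place(nm, p.regime, p.initial))
    collision = set(p2.transition_names) & set(p3.transition_names)
    if collision:
        raise PetriNetError(f"transition name collision {sorted(collision)}")
    transitions = list(p2.transitions) + list(p3.transitions)
    arcs = list(p2.arcs) + [
        Arc(rename(a.place), a.transition, a.direction, a.kind, a.weight)
        for a in p3.arcs
    ]
    transitions.append(
        Transition("Diffusion", "continuous",
                   variant.diffusion_k * NEIGHBOUR_COUNT[variant.dims])
    )
    arcs.append(Arc("AI2_Out", "Diffusion", PRE, ARC_STANDARD, 1))
    constants = {"THR": variant.THR_open, "THR_close": variant.THR_close}
    return PetriNet(places, transitions, arcs, constants, name="combined")


def build_spatial(variant: ModelVariant | None = None,
                  g: GridSpec | None = None,
                  r: RegionSpec | None = None,
                  phase2_params: dict | None = None) -> ColouredNet:
    """Spatial coloured model.

    The combined net is coloured with the Grid3D colour set; every
    transition gets the colony ``region`` guard except ``Diffusion``,
    which is made two-way between Moore-adjacent cells (pre arc bound to
    the cell, post arc carrying the ``(a,b,c)`` neighbour expression) so
    the broadcast AI-2 signal can travel over the whole grid.  The
    non-spatial ``inflow`` source of the biofilm component is dropped: in
    space, external AI-2 arrives by diffusion.  The initial marking is
    replicated onto every region position.
    """
    if variant is None:
        variant = ModelVariant.combined()
    if g is None:
        g = GridSpec.square(21, 2)
    if r is None:
        r = RegionSpec(M1=(g.D1 + 1) // 2, M2=(g.D2 + 1) // 2,
                       M3=(g.D3 + 1) // 2, R=2)
    combined = build_combined(variant, phase2_params)
    places = list(combined.places)
    transitions = []
    for t in combined.transitions:
        if t.name == "inflow":
            continue
        if t.name == "Diffusion":
            # per neighbour-pair instance: plain kd (the neighbour-count
            # factor of the non-spatial model is realised by unfolding)
            transitions.append(Transition(t.name, t.regime, variant.diffusion_k))
        else:
            transitions.append(t)
    keep = {t.name for t in transitions}
    arcs = [a for a in combined.arcs if a.transition in keep]
    arcs.append(Arc("AI2_Out", "Diffusion", POST, ARC_STANDARD, 1))
    base = PetriNet(places, transitions, arcs, dict(combined.constants),
                    name="spatial")
    guards = {t.name: (GUARD_NEIGHBOUR if t.name == "Diffusion" else GUARD_REGION)
              for t in transitions}
    arc_exprs = {("AI2_Out", "Diffusion", POST): EXPR_NEIGHBOUR}
    colony = region_positions(g, r)
    coloured_initial: dict[str, dict] = {}
    for p in places:
        if p.name == "AI2_Out":
            coloured_initial[p.name] = {}
        else:
            coloured_initial[p.name] = {c: p.initial for c in colony} if p.initial else {}
    return ColouredNet(base, guards, arc_exprs, coloured_initial)
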