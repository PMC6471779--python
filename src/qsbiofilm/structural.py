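"""Structural net analysis: invariants, T-cover, siphons/traps, ES class.

Everything here is integer-exact (Python ints; no floating point), so every
reported invariant can be re-verified against the incidence matrix.

Conventions used by the analyses:

* P/T-invariants are minimal semi-positive integer solutions of
  ``C' x = 0`` / ``C x = 0``, computed with the Farkas elimination
  algorithm.  Read and inhibitor arcs are excluded from ``C`` (a constant
  place tested only by read arcs has an all-zero row and hence forms a
  trivial 1-P-invariant).
* For siphons, traps and the ES class, read arcs are treated as self-loops
  (the tested place is both pre- and post-place of the transition), which
  is the standard treatment that makes a read-only constant place a
  marked trap.  Inhibitor arcs are outside classical structure theory and
  must be removed before calling these analyses (the model builders expose
  the nets with the go mechanism already separable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

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
    incidence_matrix,
)

__all__ = [
    "Invariant",
    "make_transition_bordered",
    "p_invariants",
    "t_invariants",
    "t_invariants_cover",
    "minimal_siphons",
    "minimal_traps",
    "siphon_trap_property",
    "is_extended_simple",
    "classify_net",
]

MAX_SIPHON_PLACES = 40


@dataclass(frozen=True)
class Invariant:
    """A minimal semi-positive P- or T-invariant."""

    kind: str  # "P" or "T"
    weights: tuple[tuple[str, int], ...]  # (node name, positive weight)

    @property
    def support(self) -> frozenset[str]:
        return frozenset(n for n, _ in self.weights)

    def weight(self, name: str) -> int:
        return dict(self.weights).get(name, 0)


# ---------------------------------------------------------------------------
# bordering
# ---------------------------------------------------------------------------

def make_transition_bordered(net: PetriNet) -> PetriNet:
    """Add a source transition for every source place and a sink transition
    for every sink place, modelling an environment with infinite in/out
    flow; the result has no source/sink places.

    Read/inhibitor arcs count as both pre and post when deciding whether a
    place is a boundary place (a read-only place is self-sufficient).
    """
    has_in = {p.name: False for p in net.places}
    has_out = {p.name: False for p in net.places}
    for a in net.arcs:
        if a.kind == ARC_STANDARD:
            if a.direction == PRE:
                has_out[a.place] = True
            else:
                has_in[a.place] = True
        else:  # test arcs: token is checked and returned
            has_in[a.place] = True
            has_out[a.place] = True
    places = list(net.places)
    transitions = list(net.transitions)
    arcs = list(net.arcs)
    changed = False
    for p in net.places:
        if not has_in[p.name]:
            transitions.append(Transition(f"src_{p.name}", p.regime if p.regime == "continuous" else "stochastic", 1.0))
            arcs.append(Arc(p.name, f"src_{p.name}", POST, ARC_STANDARD, 1))
            changed = True
        if not has_out[p.name]:
            transitions.append(Transition(f"snk_{p.name}", p.regime if p.regime == "continuous" else "stochastic", 1.0))
            arcs.append(Arc(p.name, f"snk_{p.name}", PRE, ARC_STANDARD, 1))
            changed = True
    if not changed:
        return net
    return PetriNet(places, transitions, arcs, dict(net.constants), f"{net.name}_bordered")


# ---------------------------------------------------------------------------
# invariants (Farkas elimination, integer exact)
# ---------------------------------------------------------------------------

def _farkas(matrix: list[list[int]], names: list[str], kind: str) -> list[Invariant]:
    """All minimal semi-positive integer solutions of ``matrix @ x = 0``
    where columns of ``matrix`` are indexed by ``names``."""
    n = len(names)
    # rows: (solution vector over names, residual row of remaining constraints)
    rows = [([1 if j == i else 0 for j in range(n)], [int(r[i]) for r in matrix])
            for i in range(n)]
    n_cons = len(matrix)
    for c in range(n_cons):
        pos = [r for r in rows if r[1][c] > 0]
        neg = [r for r in rows if r[1][c] < 0]
        zero = [r for r in rows if r[1][c] == 0]
        new_rows = list(zero)
        for xp, rp in pos:
            for xn, rn in neg:
                a, b = rp[c], -rn[c]
                sol = [b * u + a * v for u, v in zip(xp, xn)]
                g = np.gcd.reduce([s for s in sol if s] or [1])
                sol = [s // int(g) for s in sol]
                res = [b * u + a * v for u, v in zip(rp, rn)]
                res = [rr // int(g) for rr in res]
                new_rows.append((sol, res))
        # prune non-minimal supports to keep the row set small
        new_rows = _prune_supports(new_rows)
        rows = new_rows
    sols = _prune_supports(rows)
    out = []
    seen = set()
    for sol, _ in sols:
        w = tuple((names[i], sol[i]) for i in range(n) if sol[i] > 0)
        if w and w not in seen:
            seen.add(w)
            out.append(Invariant(kind, w))
    return sorted(out, key=lambda inv: sorted(inv.support))


def _prune_supports(rows):
    supports = [frozenset(i for i, v in enumerate(sol) if v) for sol, _ in rows]
    keep = []
    for i, (sol, res) in enumerate(rows):
        si = supports[i]
        if not si:
            continue
        minimal = True
        for j, sj in enumerate(supports):
            if i != j and sj and sj < si:
                minimal = False
                break
            if i > j and sj == si:
                minimal = False
                break
        if minimal:
            keep.append((sol, res))
    return keep


def p_invariants(net: PetriNet) -> list[Invariant]:
    """Minimal semi-positive solutions of C' x = 0 (conserved token sums)."""
    C = incidence_matrix(net)
    return _farkas(C.T.tolist(), net.place_names, "P")


def t_invariants(net: PetriNet) -> list[Invariant]:
    """Minimal semi-positive solutions of C x = 0 (cyclic firing vectors)."""
    C = incidence_matrix(net)
    return _farkas(C.tolist(), net.transition_names, "T")


def t_invariants_cover(net: PetriNet) -> tuple[list[Invariant], bool]:
    """Minimal T-invariants plus whether every transition occurs in some
    support (the "covered with T-invariants" criterion)."""
    invs = t_invariants(net)
    covered_set = set().union(*(inv.support for inv in invs)) if invs else set()
    return invs, covered_set == set(net.transition_names)


# ---------------------------------------------------------------------------
# siphons and traps
# ---------------------------------------------------------------------------

def _pre_post_sets(net: PetriNet):
    """(pre_t, post_t): for each transition, the places it takes from /
    puts into, with read arcs counted on both sides."""
    if any(a.kind == ARC_INHIBITOR for a in net.arcs):
        raise PetriNetError(
            "siphon/trap and ES analysis require a net without inhibitor arcs"
        )
    takes: dict[str, set[str]] = {t.name: set() for t in net.transitions}
    puts: dict[str, set[str]] = {t.name: set() for t in net.transitions}
    for a in net.arcs:
        if a.kind == ARC_READ:
            takes[a.transition].add(a.place)
            puts[a.transition].add(a.place)
        elif a.direction == PRE:
            takes[a.transition].add(a.place)
        else:
            puts[a.transition].add(a.place)
    return takes, puts


def minimal_siphons(net: PetriNet) -> list[frozenset[str]]:
    """All minimal siphons: non-empty S with pre(S) subseteq post(S), i.e.
    every transition feeding S also takes from S.

    Branch-and-bound: grow a candidate from each seed place, branching on
    which pre-place of an uncovered feeding transition to add; minimality
    is enforced by subset filtering.  Guarded by a size bound since the
    problem is exponential in general.
    """
    if len(net.places) > MAX_SIPHON_PLACES:
        raise PetriNetError(
            f"net too large for exhaustive siphon search (> {MAX_SIPHON_PLACES} places)"
        )
    takes, puts = _pre_post_sets(net)
    feeders: dict[str, list[str]] = {p.name: [] for p in net.places}
    for t in net.transitions:
        for p in puts[t.name]:
            feeders[p].append(t.name)
    found: list[frozenset[str]] = []

    def add_result(s: frozenset):
        for f in found:
            if f <= s:
                return
        found[:] = [f for f in found if not s <= f]
        found.append(s)

    def expand(s: set[str], forbidden: set[str]):
        if any(f <= s for f in found):
            return
        # find a violated feeding transition
        for p in sorted(s):
            for t in feeders[p]:
                if not (takes[t] & s):
                    choices = sorted(takes[t] - forbidden)
                    if not choices:
                        return
                    blocked = set(forbidden)
                    for q in choices:
                        expand(s | {q}, blocked)
                        blocked.add(q)
                    return
        add_result(frozenset(s))

    for seed in sorted(p.name for p in net.places):
        expand({seed}, set())
    return sorted(found, key=sorted)


def _reversed_net(net: PetriNet) -> PetriNet:
    arcs = [
        Arc(a.place, a.transition, POST if a.direction == PRE else PRE, a.kind, a.weight)
        if a.kind == ARC_STANDARD
        else a
        for a in net.arcs
    ]
    return PetriNet(list(net.places), list(net.transitions), arcs,
                    dict(net.constants), f"{net.name}_rev")


def minimal_traps(net: PetriNet) -> list[frozenset[str]]:
    """All minimal traps (siphons of the arc-reversed net)."""
    return minimal_siphons(_reversed_net(net))


def _max_trap_within(net: PetriNet, subset: frozenset[str]) -> frozenset[str]:
    """Largest trap contained in ``subset`` (standard erosion fixpoint)."""
    takes, puts = _pre_post_sets(net)
    trap = set(subset)
    changed = True
    while changed:
        changed = False
        for p in list(trap):
            # p stays only if every transition taking from p puts into trap
            for t in net.transitions:
                if p in takes[t.name] and not (puts[t.name] & trap):
                    trap.discard(p)
                    changed = True
                    break
    return frozenset(trap)


def siphon_trap_property(
    net: PetriNet, marking=None
) -> tuple[list[frozenset[str]], list[frozenset[str]], bool]:
    """(minimal siphons, minimal traps, STP).

    STP: every (minimal) siphon contains a trap that is marked under the
    net's initial marking.  Checking minimal siphons suffices: every siphon
    contains a minimal one, and the maximal contained trap grows with the
    siphon.
    """
    if marking is None:
        marking = net.initial_marking()
    siphons = minimal_siphons(net)
    traps = minimal_traps(net)
    stp = True
    for s in siphons:
        trap = _max_trap_within(net, s)
        if not trap or not any(marking[p] > 0 for p in trap):
            stp = False
            break
    return siphons, traps, stp


# ---------------------------------------------------------------------------
# net class + deductions
# ---------------------------------------------------------------------------

def is_extended_simple(net: PetriNet) -> bool:
    """Extended Simple (asymmetric choice): whenever two places share a
    post-transition, one post-set contains the other."""
    takes, _ = _pre_post_sets(net)
    post_of_place: dict[str, set[str]] = {p.name: set() for p in net.places}
    for t, ps in takes.items():
        for p in ps:
            post_of_place[p].add(t)
    names = sorted(post_of_place)
    for i, p in enumerate(names):
        for q in names[i + 1:]:
            sp, sq = post_of_place[p], post_of_place[q]
            if sp & sq and not (sp <= sq or sq <= sp):
                return False
    return True


def classify_net(net: PetriNet, marking=None) -> dict:
    """Structural report: ES membership, STP, and the standard deductions
    (STP & ES => live for any rates; STP alone => no dead states)."""
    siphons, traps, stp = siphon_trap_property(net, marking)
    es = is_extended_simple(net)
    deductions = []
    if stp and es:
        deductions.append(
            "STP holds and the net is Extended Simple: "
            "the net is live for any timing (time-independently live)."
        )
    elif stp:
        deductions.append(
            "STP holds but the net is beyond Extended Simple: "
            "structurally we can only deduce freedom of dead states."
        )
    else:
        deductions.append("STP does not hold: no structural liveness deduction.")
    return {
        "is_ES": es,
        "STP": stp,
        "minimal_siphons": [sorted(s) for s in siphons],
        "minimal_traps": [sorted(t) for t in traps],
        "deductions": deductions,
    }
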