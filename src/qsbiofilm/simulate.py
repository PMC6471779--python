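"""Simulation regimes: RK4 ODE, exact Gillespie SSA, delta-leaping, hybrid.

All four simulators consume a :class:`~qsbiofilm.petri.PetriNet` and a
:class:`SimConfig` and produce a :class:`Trace` on a fixed equidistant
recording grid.  Jump processes are recorded by previous-value hold; the
ODE solver steps through the grid points exactly.

The stochastic engines run on a flattened array encoding of the net
(:class:`CompiledNet`) with numba-jitted inner loops, so the unfolded
spatial nets (thousands of transitions) remain tractable.  Identical seed
and configuration reproduce bit-identical traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .petri import (
    ARC_INHIBITOR,
    ARC_READ,
    ARC_STANDARD,
    DISCRETE,
    PRE,
    PetriNet,
    PetriNetError,
)

__all__ = [
    "SimConfig",
    "Trace",
    "simulate_ode",
    "simulate_gillespie",
    "simulate_delta_leaping",
    "simulate_hybrid",
    "simulate_ensemble",
    "average_runs",
    "CompiledNet",
]


@dataclass
class SimConfig:
    """Simulation settings.

    t_end / n_record define the recording grid; n_runs > 1 makes the
    stochastic simulators return the ensemble mean.  ``h`` is the fixed
    ODE step (default: a quarter of the recording interval), ``eps`` the
    leap relative-change control, and ``fallback`` the population below
    which a transition is handled exactly rather than leaped.
    """

    t_end: float
    n_record: int = 1000
    n_runs: int = 1
    seed: int = 0
    method: str = "gillespie"
    h: float | None = None
    eps: float = 0.03
    fallback: int = 10
    delta: float | None = None  # max leap; default: the recording interval

    def __post_init__(self):
        if self.t_end <= 0 or self.n_record < 2 or self.n_runs < 1:
            raise PetriNetError("invalid simulation configuration")

    @property
    def record_times(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.n_record)

    @property
    def ode_step(self) -> float:
        return self.h if self.h is not None else self.t_end / (self.n_record - 1) / 4.0

    def run_seed(self, run: int) -> int:
        """Per-run RNG seed, reproducibly derived from (seed, run)."""
        return int(np.random.SeedSequence([self.seed, run]).generate_state(1)[0] % 2**31)


@dataclass
class Trace:
    """Time grid x variable matrix, the common currency of the pipeline."""

    times: np.ndarray
    values: np.ndarray  # shape (n_record, n_variables)
    names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.times), len(self.names)):
            raise PetriNetError("trace shape mismatch")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trace":
        df = pd.read_csv(path)
        return cls(
            times=df.iloc[:, 0].to_numpy(),
            values=df.iloc[:, 1:].to_numpy(),
            names=list(df.columns[1:]),
        )

    def select(self, names: list[str]) -> "Trace":
        idx = [self.names.index(n) for n in names]
        return Trace(self.times, self.values[:, idx], list(names), dict(self.meta))


def average_runs(traces: list[Trace]) -> Trace:
    """Pointwise arithmetic mean of runs on identical recording grids."""
    if not traces:
        raise PetriNetError("no traces to average")
    first = traces[0]
    for tr in traces[1:]:
        if tr.names != first.names or not np.array_equal(tr.times, first.times):
            raise PetriNetError("averaging requires identical grids and variables")
    values = np.mean([tr.values for tr in traces], axis=0)
    meta = dict(first.meta)
    meta["runs_averaged"] = len(traces)
    return Trace(first.times.copy(), values, list(first.names), meta)


# ---------------------------------------------------------------------------
# compiled net representation
# ---------------------------------------------------------------------------

KIND_STD, KIND_READ, KIND_INH = 0, 1, 2


class CompiledNet:
    """Flattened array encoding of a net for the jitted kernels.

    CSR-style layouts: per transition its pre-arcs (place index, weight,
    kind) and its stoichiometry (place index, signed delta), plus a
    dependency list (transitions whose propensity may change when this one
    fires) for incremental SSA updates.
    """

    def __init__(self, net: PetriNet):
        self.net = net
        self.place_names = net.place_names
        self.transition_names = net.transition_names
        pidx = {p: i for i, p in enumerate(self.place_names)}
        tidx = {t: j for j, t in enumerate(self.transition_names)}
        n_t = len(self.transition_names)

        pre: list[list[tuple[int, int, int]]] = [[] for _ in range(n_t)]
        sto: list[dict[int, int]] = [{} for _ in range(n_t)]
        for a in net.arcs:
            j = tidx[a.transition]
            p = pidx[a.place]
            w = net.resolve_weight(a)
            if a.direction == PRE:
                kind = {ARC_STANDARD: KIND_STD, ARC_READ: KIND_READ, ARC_INHIBITOR: KIND_INH}[a.kind]
                pre[j].append((p, w, kind))
                if a.kind == ARC_STANDARD:
                    sto[j][p] = sto[j].get(p, 0) - w
            else:
                sto[j][p] = sto[j].get(p, 0) + w
        sto = [{p: d for p, d in s.items() if d != 0} for s in sto]

        def csr(rows, fields):
            ptr = np.zeros(len(rows) + 1, dtype=np.int64)
            for i, r in enumerate(rows):
                ptr[i + 1] = ptr[i] + len(r)
            cols = [np.empty(int(ptr[-1]), dtype=np.int64) for _ in range(fields)]
            for i, r in enumerate(rows):
                for k, item in enumerate(r):
                    for f in range(fields):
                        cols[f][ptr[i] + k] = item[f]
            return ptr, cols

        self.pre_ptr, (self.pre_place, self.pre_w, self.pre_kind) = csr(pre, 3)
        self.st_ptr, (self.st_place, self.st_delta) = csr(
            [sorted(s.items()) for s in sto], 2
        )

        # dependency graph: firing j changes places in sto[j]; affected
        # transitions are those with any pre-arc on a changed place
        readers: dict[int, set[int]] = {}
        for j in range(n_t):
            for (p, _, _) in pre[j]:
                readers.setdefault(p, set()).add(j)
        dep = []
        for j in range(n_t):
            s: set[int] = set()
            for p in sto[j]:
                s |= readers.get(p, set())
            dep.append(sorted(s))
        self.dep_ptr, (self.dep_idx,) = csr([[(d,) for d in ds] for ds in dep], 1)

        self.k = np.array([t.rate_constant for t in net.transitions], dtype=np.float64)
        self.x0 = np.array([p.initial for p in net.places], dtype=np.float64)
        # transitions whose propensity is discontinuous in state (threshold
        # gates): inhibitor arcs or read arcs with weight > 1.  These are
        # simulated exactly inside the leaping scheme; plain weight-1 read
        # arcs (enzymes, side conditions) change only at such gate events
        # or smoothly, and stay leapable.
        self.gated = np.array(
            [
                any(kind == KIND_INH or (kind == KIND_READ and w > 1)
                    for (_, w, kind) in pre[j])
                for j in range(n_t)
            ],
            dtype=np.bool_,
        )


# ---------------------------------------------------------------------------
# jitted kernels
# ---------------------------------------------------------------------------

@njit(cache=False)
def _propensity(j, x, k, pre_ptr, pre_place, pre_w, pre_kind):
    a = k[j]
    for i in range(pre_ptr[j], pre_ptr[j + 1]):
        p = pre_place[i]
        w = pre_w[i]
        kind = pre_kind[i]
        m = x[p]
        if kind == KIND_INH:
            if m >= w:
                return 0.0
            continue
        if m < w:
            return 0.0
        # combinatorial mass action C(m, w); w is 1 in all shipped models
        f = 1.0
        for r in range(w):
            f *= (m - r) / (r + 1)
        a *= f
    return a


@njit(cache=False)
def _all_propensities(x, k, pre_ptr, pre_place, pre_w, pre_kind, out):
    for j in range(len(k)):
        out[j] = _propensity(j, x, k, pre_ptr, pre_place, pre_w, pre_kind)


@njit(cache=False)
def _ssa_kernel(
    x,
    k,
    pre_ptr,
    pre_place,
    pre_w,
    pre_kind,
    st_ptr,
    st_place,
    st_delta,
    dep_ptr,
    dep_idx,
    rec_times,
    rec,
    seed,
):
    np.random.seed(seed)
    n_t = len(k)
    n_rec = len(rec_times)
    a = np.empty(n_t)
    _all_propensities(x, k, pre_ptr, pre_place, pre_w, pre_kind, a)
    total = a.sum()
    t = 0.0
    rec_i = 0
    events = 0
    while True:
        if total <= 1e-300:
            break
        dt = np.random.exponential(1.0 / total)
        t_next = t + dt
        while rec_i < n_rec and rec_times[rec_i] < t_next:
            for p in range(len(x)):
                rec[rec_i, p] = x[p]
            rec_i += 1
        if rec_i >= n_rec:
            break
        t = t_next
        # categorical choice
        r = np.random.random() * total
        acc = 0.0
        j = n_t - 1
        for jj in range(n_t):
            acc += a[jj]
            if r < acc:
                j = jj
                break
        for i in range(st_ptr[j], st_ptr[j + 1]):
            x[st_place[i]] += st_delta[i]
        for i in range(dep_ptr[j], dep_ptr[j + 1]):
            jj = dep_idx[i]
            new = _propensity(jj, x, k, pre_ptr, pre_place, pre_w, pre_kind)
            total += new - a[jj]
            a[jj] = new
        events += 1
        if events % 4096 == 0:  # refresh accumulated float error
            total = a.sum()
    while rec_i < n_rec:
        for p in range(len(x)):
            rec[rec_i, p] = x[p]
        rec_i += 1
    return events


@njit(cache=False)
def _leap_kernel(
    x,
    k,
    pre_ptr,
    pre_place,
    pre_w,
    pre_kind,
    st_ptr,
    st_place,
    st_delta,
    gated,
    rec_times,
    rec,
    seed,
    eps,
    delta_max,
):
    """Delta-leaping: fixed maximum leap ``delta_max``, shortened where the
    expected drift would change any population by more than ``eps``
    relative; non-gated transitions fire Poisson counts per leap, gated
    (test-arc) transitions run in an exact exponential race so threshold
    mechanisms keep single-token semantics; negativity is handled by
    reject-and-halve."""
    np.random.seed(seed)
    n_t = len(k)
    n_p = len(x)
    n_rec = len(rec_times)
    t_end = rec_times[n_rec - 1]
    a = np.empty(n_t)
    mu = np.empty(n_p)
    fires = np.empty(n_t, dtype=np.int64)
    x_old = np.empty(n_p)
    x_mid = np.empty(n_p)
    t = 0.0
    rec_i = 0

    while t < t_end and rec_i < n_rec:
        _all_propensities(x, k, pre_ptr, pre_place, pre_w, pre_kind, a)
        total = 0.0
        a_crit = 0.0
        for j in range(n_t):
            total += a[j]
            if gated[j]:
                a_crit += a[j]
        if total <= 1e-300:
            break

        # drift cap: expected change of any population <= eps (relative)
        for p in range(n_p):
            mu[p] = 0.0
        for j in range(n_t):
            if a[j] <= 0.0 or gated[j]:
                continue
            for i in range(st_ptr[j], st_ptr[j + 1]):
                mu[st_place[i]] += a[j] * st_delta[i]
        tau = delta_max
        if t + tau > t_end:
            tau = t_end - t
        for p in range(n_p):
            if mu[p] != 0.0:
                # allow a drift of eps relative or a few tokens, whichever
                # is larger (small populations are guarded by rejection
                # and by the exact-SSA branch below)
                c = max(eps * x[p], 3.0) / abs(mu[p])
                if c < tau:
                    tau = c

        if tau * total < 5.0:
            # quiet system: an exact SSA step is both cheaper and unbiased
            dt = np.random.exponential(1.0 / total)
            t_next = t + dt
            while rec_i < n_rec and rec_times[rec_i] < t_next:
                for p in range(n_p):
                    rec[rec_i, p] = x[p]
                rec_i += 1
            t = t_next
            if rec_i >= n_rec:
                break
            r = np.random.random() * total
            acc = 0.0
            j = n_t - 1
            for jj in range(n_t):
                acc += a[jj]
                if r < acc:
                    j = jj
                    break
            for i in range(st_ptr[j], st_ptr[j + 1]):
                x[st_place[i]] += st_delta[i]
            continue

        # exact race for the gated transitions
        t_crit = np.inf
        if a_crit > 0.0:
            t_crit = np.random.exponential(1.0 / a_crit)
        step = min(tau, t_crit)
        fire_critical = t_crit <= tau

        record_pending = rec_i < n_rec and rec_times[rec_i] < t + step
        if record_pending:
            for p in range(n_p):
                x_old[p] = x[p]

        # midpoint predictor removes the O(step) propensity bias
        for p in range(n_p):
            x_mid[p] = max(x[p] + 0.5 * step * mu[p], 0.0)
        for j in range(n_t):
            if a[j] > 0.0 and not gated[j]:
                a[j] = _propensity(j, x_mid, k, pre_ptr, pre_place, pre_w, pre_kind)

        for attempt in range(60):
            neg = False
            for j in range(n_t):
                fires[j] = 0
                if a[j] <= 0.0 or gated[j]:
                    continue
                fires[j] = np.random.poisson(a[j] * step)
            for j in range(n_t):
                if fires[j] == 0:
                    continue
                for i in range(st_ptr[j], st_ptr[j + 1]):
                    x[st_place[i]] += st_delta[i] * fires[j]
            for p in range(n_p):
                if x[p] < 0.0:
                    neg = True
                    break
            if not neg:
                break
            for j in range(n_t):  # reject: undo, halve, redraw
                if fires[j] == 0:
                    continue
                for i in range(st_ptr[j], st_ptr[j + 1]):
                    x[st_place[i]] -= st_delta[i] * fires[j]
            step *= 0.5
            fire_critical = False
            if step * total < 1e-12:
                break

        t_next = t + step
        # a leap leaves the intra-leap path unresolved: record points inside
        # the leap window get the linear interpolant of its end states
        # (conserves every weighted token sum; gated transitions fire only
        # at leap boundaries, so discrete gate places stay integral)
        while rec_i < n_rec and rec_times[rec_i] < t_next:
            if record_pending and step > 0.0:
                frac = (rec_times[rec_i] - t) / step
                for p in range(n_p):
                    rec[rec_i, p] = x_old[p] + (x[p] - x_old[p]) * frac
            else:
                for p in range(n_p):
                    rec[rec_i, p] = x[p]
            rec_i += 1
        t = t_next
        if fire_critical and a_crit > 0.0:
            r = np.random.random() * a_crit
            acc = 0.0
            chosen = -1
            for j in range(n_t):
                if not gated[j] or a[j] <= 0.0:
                    continue
                acc += a[j]
                if r < acc:
                    chosen = j
                    break
            if chosen >= 0:
                # fire only if still enabled after the leap updates
                if _propensity(chosen, x, k, pre_ptr, pre_place, pre_w, pre_kind) > 0.0:
                    for i in range(st_ptr[chosen], st_ptr[chosen + 1]):
                        x[st_place[i]] += st_delta[i]

    while rec_i < n_rec:
        for p in range(n_p):
            rec[rec_i, p] = x[p]
        rec_i += 1


# ---------------------------------------------------------------------------
# public simulators
# ---------------------------------------------------------------------------

def _check_nonneg_int(net: PetriNet):
    for p in net.places:
        if p.initial < 0:
            raise PetriNetError(f"negative initial marking on {p.name}")


def _run_stochastic(net: PetriNet, cfg: SimConfig, kernel: str) -> Trace:
    comp = CompiledNet(net)
    rec_times = cfg.record_times
    runs = []
    for run in range(cfg.n_runs):
        x = comp.x0.copy()
        if not np.all(x == np.floor(x)):
            raise PetriNetError("stochastic simulation requires integer markings")
        rec = np.empty((cfg.n_record, len(x)))
        seed = cfg.run_seed(run)
        if kernel == "ssa":
            _ssa_kernel(
                x, comp.k, comp.pre_ptr, comp.pre_place, comp.pre_w, comp.pre_kind,
                comp.st_ptr, comp.st_place, comp.st_delta, comp.dep_ptr, comp.dep_idx,
                rec_times, rec, seed,
            )
        else:
            delta = cfg.delta if cfg.delta is not None else cfg.t_end / (cfg.n_record - 1)
            _leap_kernel(
                x, comp.k, comp.pre_ptr, comp.pre_place, comp.pre_w, comp.pre_kind,
                comp.st_ptr, comp.st_place, comp.st_delta, comp.gated,
                rec_times, rec, seed, cfg.eps, delta,
            )
        runs.append(
            Trace(rec_times.copy(), rec, list(comp.place_names),
                  {"method": kernel, "seed": seed, "run": run})
        )
    if cfg.n_runs == 1:
        tr = runs[0]
        tr.meta["base_seed"] = cfg.seed
        return tr
    out = average_runs(runs)
    out.meta.update({"method": kernel, "base_seed": cfg.seed})
    return out


def simulate_gillespie(net: PetriNet, cfg: SimConfig) -> Trace:
    """Exact SSA (direct method); n_runs > 1 returns the ensemble mean."""
    _check_nonneg_int(net)
    return _run_stochastic(net, cfg, "ssa")


def simulate_delta_leaping(net: PetriNet, cfg: SimConfig) -> Trace:
    """Approximative delta-leaping: Poisson firing counts over leaps of at
    most ``cfg.delta`` (default: the recording interval), shortened by the
    ``eps`` relative drift criterion; test-arc-gated transitions are
    simulated exactly; negative excursions are rejected."""
    _check_nonneg_int(net)
    return _run_stochastic(net, cfg, "leap")


def simulate_ensemble(net: PetriNet, cfg: SimConfig, method: str | None = None) -> list[Trace]:
    """Individual runs (list of traces) for the chosen stochastic method."""
    method = method or cfg.method
    out = []
    for run in range(cfg.n_runs):
        # per-run derived seed keeps every run individually replayable
        sub_seed_cfg = SimConfig(cfg.t_end, cfg.n_record, 1, cfg.run_seed(run), method,
                                 cfg.h, cfg.eps, cfg.fallback, cfg.delta)
        if method == "gillespie":
            out.append(simulate_gillespie(net, sub_seed_cfg))
        elif method == "delta_leaping":
            out.append(simulate_delta_leaping(net, sub_seed_cfg))
        elif method == "hybrid":
            out.append(simulate_hybrid(net, None, sub_seed_cfg))
        else:
            raise PetriNetError(f"unknown ensemble method {method!r}")
    return out


# -- ODE ---------------------------------------------------------------------

def _ode_rhs_factory(net: PetriNet):
    comp = CompiledNet(net)
    from scipy import sparse

    n_t = len(comp.k)
    rows, cols, vals = [], [], []
    for j in range(n_t):
        for i in range(comp.st_ptr[j], comp.st_ptr[j + 1]):
            rows.append(comp.st_place[i])
            cols.append(j)
            vals.append(comp.st_delta[i])
    C = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(comp.x0), n_t), dtype=float
    )

    pre_ptr, pre_place = comp.pre_ptr, comp.pre_place
    pre_w, pre_kind, k = comp.pre_w, comp.pre_kind, comp.k

    def rates(x):
        v = k.copy()
        for j in range(n_t):
            for i in range(pre_ptr[j], pre_ptr[j + 1]):
                m = x[pre_place[i]]
                w = pre_w[i]
                if pre_kind[i] == KIND_INH:
                    if m >= w:
                        v[j] = 0.0
                        break
                else:
                    v[j] *= max(m, 0.0) ** w
        return v

    def rhs(x):
        return C @ rates(x)

    return comp, rhs, rates, C


def simulate_ode(net: PetriNet, cfg: SimConfig) -> Trace:
    """Classic fixed-step RK4 on dm/dt = C v(m), recorded at the grid."""
    comp, rhs, _, _ = _ode_rhs_factory(net)
    h = cfg.ode_step
    rec_times = cfg.record_times
    x = comp.x0.astype(float).copy()
    rec = np.empty((cfg.n_record, len(x)))
    rec[0] = x
    t = 0.0
    scale = max(1.0, float(np.max(np.abs(x))) if len(x) else 1.0)
    for i in range(1, cfg.n_record):
        target = rec_times[i]
        while t < target - 1e-12:
            step = min(h, target - t)
            k1 = rhs(x)
            k2 = rhs(x + 0.5 * step * k1)
            k3 = rhs(x + 0.5 * step * k2)
            k4 = rhs(x + step * k3)
            x = x + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if np.any(x < -1e-6 * scale):
                raise PetriNetError(
                    "ODE state went negative beyond tolerance; "
                    "reduce the step size h"
                )
            np.clip(x, 0.0, None, out=x)
            t += step
        rec[i] = x
    return Trace(rec_times.copy(), rec, list(comp.place_names),
                 {"method": "ode_rk4", "h": h})


# -- hybrid ------------------------------------------------------------------

def simulate_hybrid(net: PetriNet, partition: set | None, cfg: SimConfig) -> Trace:
    """Hybrid simulation: the continuous subnet is integrated with RK4
    between stochastic events; event times come from integrated-hazard
    sampling of the (piecewise-constant per substep) stochastic
    propensities.  ``partition`` names the stochastic transitions (default:
    those whose regime is stochastic in the net definition).  Discrete
    places are updated instantaneously and seen by the continuous rates.
    """
    if partition is None:
        partition = {t.name for t in net.transitions if t.regime == "stochastic"}
    unknown = partition - set(net.transition_names)
    if unknown:
        raise PetriNetError(f"partition names unknown transitions: {sorted(unknown)}")
    comp, rhs_all, rates_all, C = _ode_rhs_factory(net)
    tidx = {t: j for j, t in enumerate(comp.transition_names)}
    pidx = {p: i for i, p in enumerate(comp.place_names)}
    stoch = np.zeros(len(comp.k), dtype=bool)
    for name in partition:
        stoch[tidx[name]] = True
    discrete = np.array([p.regime == DISCRETE for p in net.places])
    # a continuous transition must not move tokens on a discrete place
    for j, cont in enumerate(~stoch):
        if not cont:
            continue
        for i in range(comp.st_ptr[j], comp.st_ptr[j + 1]):
            if discrete[comp.st_place[i]]:
                raise PetriNetError(
                    f"continuous transition {comp.transition_names[j]!r} writes "
                    f"discrete place {comp.place_names[comp.st_place[i]]!r}; "
                    "fix the hybrid partition"
                )

    def cont_rhs(x):
        v = rates_all(x)
        v[stoch] = 0.0
        return C @ v

    def stoch_propensities(x):
        # discrete semantics (combinatorial factors) for stochastic part
        a = np.zeros(len(comp.k))
        for j in np.nonzero(stoch)[0]:
            aj = comp.k[j]
            for i in range(comp.pre_ptr[j], comp.pre_ptr[j + 1]):
                m = x[comp.pre_place[i]]
                w = comp.pre_w[i]
                if comp.pre_kind[i] == KIND_INH:
                    if m >= w:
                        aj = 0.0
                        break
                elif m < w:
                    aj = 0.0
                    break
                else:
                    f = 1.0
                    for r in range(w):
                        f *= (m - r) / (r + 1)
                    aj *= f
            a[j] = aj
        return a

    rng = np.random.default_rng(cfg.seed)
    rec_times = cfg.record_times
    x = comp.x0.astype(float).copy()
    rec = np.empty((cfg.n_record, len(x)))
    rec[0] = x
    t = 0.0
    h = cfg.ode_step
    budget = rng.exponential()  # integrated hazard until next event

    def rk4(x, step):
        k1 = cont_rhs(x)
        k2 = cont_rhs(x + 0.5 * step * k1)
        k3 = cont_rhs(x + 0.5 * step * k2)
        k4 = cont_rhs(x + step * k3)
        out = x + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        np.clip(out, 0.0, None, out=out)
        return out

    def stable_step(x, limit):
        # explicit-RK stability cap: the fastest per-place consumption
        # coefficient bounds the local Jacobian for mass-action nets
        v = rates_all(x)
        v[stoch] = 0.0
        lam = 1e-12
        for j in np.nonzero(v > 0)[0]:
            for ii in range(comp.pre_ptr[j], comp.pre_ptr[j + 1]):
                if comp.pre_kind[ii] == KIND_STD:
                    lam = max(lam, v[j] / max(x[comp.pre_place[ii]], 1e-9))
        return min(limit, 0.6 / lam)

    for i in range(1, cfg.n_record):
        target = rec_times[i]
        while t < target - 1e-12:
            step = min(stable_step(x, h), target - t)
            a = stoch_propensities(x)
            a_tot = float(a.sum())
            if a_tot * step >= budget:
                # event inside this substep (propensities held constant)
                frac = budget / (a_tot * step)
                sub = step * frac
                x = rk4(x, sub)
                t += sub
                # re-evaluate at event time for the categorical choice
                a_now = stoch_propensities(x)
                if a_now.sum() > 0:
                    j = rng.choice(len(a_now), p=a_now / a_now.sum())
                    for ii in range(comp.st_ptr[j], comp.st_ptr[j + 1]):
                        x[comp.st_place[ii]] += comp.st_delta[ii]
                    if np.any(x < 0):
                        raise PetriNetError("stochastic firing made marking negative")
                budget = rng.exponential()
            else:
                budget -= a_tot * step
                x = rk4(x, step)
                t += step
        rec[i] = x
    return Trace(rec_times.copy(), rec, list(comp.place_names),
                 {"method": "hybrid", "seed": cfg.seed})
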