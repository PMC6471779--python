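"""End-to-end validation scenarios: behaviour classification of the AI-2
production model, threshold dynamics of the biofilm component, and the
spatial colony-sparseness experiments, plus the trace-difference (AD)
analysis used to cross-validate the two stochastic simulators.

Every experiment is configured by an :class:`ExperimentConfig`, seeds all
randomness explicitly and writes plain CSV/JSON outputs, so re-running a
configuration reproduces identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridSpec, RegionSpec, region_positions, split_instance_name, unfold
from .models import ModelVariant, build_phase2, build_phase3, build_spatial
from .petri import PetriNet, Place, PetriNetError
from .pltlc import classify
from .simulate import (
    SimConfig,
    Trace,
    average_runs,
    simulate_delta_leaping,
    simulate_ensemble,
    simulate_ode,
)

__all__ = [
    "ExperimentConfig",
    "TotalsRow",
    "run_phase2_validation",
    "run_phase3_scenarios",
    "limited_supply_net",
    "run_spatial",
    "spatial_config_table",
    "ad_heatmap",
    "pooled_se",
    "grid_total",
    "position_matrix",
]


@dataclass
class ExperimentConfig:
    """One named scenario."""

    name: str = "scenario"
    variant: ModelVariant = field(default_factory=ModelVariant.combined)
    grid: GridSpec = field(default_factory=lambda: GridSpec.square(21, 2))
    region: RegionSpec = field(default_factory=lambda: RegionSpec(11, 11, 1, 2))
    sim: SimConfig = field(default_factory=lambda: SimConfig(
        t_end=20000, n_record=1000, n_runs=10, seed=0,
        method="delta_leaping", eps=0.15))
    outputs: str | None = None

    def validate(self):
        region_positions(self.grid, self.region)  # raises if unrealisable


@dataclass(frozen=True)
class TotalsRow:
    """Grid-summed end-of-horizon ensemble means for one configuration."""

    config: str
    n_bacteria: int
    total_AI2_Out: float
    total_Biofilm: float


# ---------------------------------------------------------------------------
# phase 2: RK4 trace + behaviour categories
# ---------------------------------------------------------------------------

def run_phase2_validation(params=None, t_end: float = 10000.0,
                          n_record: int = 10000, h: float = 0.1,
                          outputs: str | None = None):
    """Simulate the AI-2 production model with fixed-step RK4 and classify
    every species with the behaviour-category library.

    Returns ``(trace, {species: category})``.
    """
    net = build_phase2(params)
    cfg = SimConfig(t_end=t_end, n_record=n_record, method="ode_rk4", h=h)
    trace = simulate_ode(net, cfg)
    categories = classify(trace)
    if outputs:
        out = Path(outputs)
        out.mkdir(parents=True, exist_ok=True)
        trace.to_csv(out / "phase2_trace.csv")
        (out / "phase2_categories.json").write_text(
            json.dumps(categories, indent=1, sort_keys=True))
    return trace, categories


# ---------------------------------------------------------------------------
# phase 3: threshold scenarios
# ---------------------------------------------------------------------------

def limited_supply_net(net: PetriNet, stock: float = 100.0) -> PetriNet:
    """The biofilm model under a finite AI-2 budget: the environment inflow
    is removed and AI2_Out starts with ``stock`` tokens."""
    places = [Place("AI2_Out", p.regime, stock) if p.name == "AI2_Out" else p
              for p in net.places]
    transitions = [t for t in net.transitions if t.name != "inflow"]
    arcs = [a for a in net.arcs if a.transition != "inflow"]
    return PetriNet(places, transitions, arcs, dict(net.constants),
                    name=f"{net.name}_limited")


def run_phase3_scenarios(THR_values=(10, 30), t_end: float = 100.0,
                         n_record: int = 1000, n_runs: int = 10,
                         seed: int = 0, stock: float = 100.0,
                         outputs: str | None = None) -> dict[str, list[Trace]]:
    """Simulate the biofilm component under unlimited and limited AI-2
    supply, each both fully stochastically and in the hybrid reading.

    Returns a dict ``{"{supply}_{method}_THR{v}": [runs...]}``.
    """
    results: dict[str, list[Trace]] = {}
    for thr in THR_values:
        variant = ModelVariant.phase3(THR_open=thr)
        nets = {
            "unlimited": build_phase3(variant),
            "limited": limited_supply_net(build_phase3(variant), stock),
        }
        for supply, net in nets.items():
            cfg = SimConfig(t_end=t_end, n_record=n_record, n_runs=n_runs,
                            seed=seed)
            results[f"{supply}_stochastic_THR{thr}"] = simulate_ensemble(
                net, cfg, "gillespie")
            results[f"{supply}_hybrid_THR{thr}"] = simulate_ensemble(
                net, cfg, "hybrid")
    if outputs:
        out = Path(outputs)
        out.mkdir(parents=True, exist_ok=True)
        for key, runs in results.items():
            average_runs(runs).to_csv(out / f"phase3_{key}_mean.csv")
    return results


# ---------------------------------------------------------------------------
# spatial experiments
# ---------------------------------------------------------------------------

def spatial_config_table(D: int = 21) -> list[tuple[str, RegionSpec]]:
    """The named colony configurations on a DxD grid: a single bacterium
    and 25-bacterium colonies of increasing sparseness."""
    m = (D + 1) // 2
    if D >= 47:
        rows = [("R0", RegionSpec(m, m, 1, 0)),
                ("R2", RegionSpec(m, m, 1, 2, 1, 1, 1)),
                ("R4", RegionSpec(m, m, 1, 4, 2, 2, 1)),
                ("R7", RegionSpec(m, m, 1, 7, 3, 3, 1)),
                ("R9", RegionSpec(m, m, 1, 9, 4, 4, 1)),
                ("R11", RegionSpec(m, m, 1, 11, 5, 5, 1))]
    else:
        rows = [("R0", RegionSpec(m, m, 1, 0)),
                ("R2", RegionSpec(m, m, 1, 2, 1, 1, 1)),
                ("R5", RegionSpec(m, m, 1, 5, 2, 2, 1)),
                ("R7", RegionSpec(m, m, 1, 7, 3, 3, 1))]
    # on small grids keep only the configurations that fit
    def fits(r: RegionSpec) -> bool:
        reach = (r.R // r.S1) * r.S1
        return m - reach >= 1 and m + reach <= D
    return [(label, r) for label, r in rows if fits(r)]


def grid_total(trace: Trace, base: str, index: int = -1) -> float:
    """Grid-summed value of coloured place ``base`` at one record index."""
    return float(sum(trace[n][index] for n in trace.names
                     if n.startswith(base + "__")))


def position_matrix(trace: Trace, base: str, g: GridSpec, index: int = -1) -> np.ndarray:
    """(D1 x D2) matrix of a coloured place at one record index (2D grids)."""
    M = np.zeros((g.D1, g.D2))
    for n in trace.names:
        if n.startswith(base + "__"):
            _, c = split_instance_name(n)
            M[c.x - 1, c.y - 1] = trace[n][index]
    return M


def run_spatial(configs=None, variant: ModelVariant | None = None,
                grid: GridSpec | None = None, sim: SimConfig | None = None,
                heatmap_indices=None, outputs: str | None = None):
    """Run the colony-sparseness experiment set.

    For each configuration: unfold the coloured model, run the delta-leaping
    ensemble, and report grid-summed ensemble means of AI2_Out and Biofilm
    at the end of the horizon, plus per-position Biofilm matrices at the
    requested record indices.

    Returns ``(rows, heatmaps, means)`` where rows is a list of
    :class:`TotalsRow`, heatmaps maps config label -> {index: matrix} and
    means maps config label -> ensemble-mean Trace.
    """
    grid = grid or GridSpec.square(21, 2)
    variant = variant or ModelVariant.combined()
    sim = sim or SimConfig(t_end=20000, n_record=1000, n_runs=10, seed=0,
                           method="delta_leaping", eps=0.15)
    configs = configs if configs is not None else spatial_config_table(grid.D1)
    if heatmap_indices is None:
        heatmap_indices = (sim.n_record // 2, sim.n_record - 1)
    rows, heatmaps, means = [], {}, {}
    for label, region in configs:
        cn = build_spatial(variant, grid, region)
        net = unfold(cn, grid, region)
        mean = simulate_delta_leaping(net, sim)
        rows.append(TotalsRow(
            config=label,
            n_bacteria=len(region_positions(grid, region)),
            total_AI2_Out=grid_total(mean, "AI2_Out"),
            total_Biofilm=grid_total(mean, "Biofilm"),
        ))
        heatmaps[label] = {
            i: position_matrix(mean, "Biofilm", grid, i) for i in heatmap_indices
        }
        means[label] = mean
    if outputs:
        out = Path(outputs)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([asdict(r) for r in rows]).to_csv(
            out / "spatial_totals.csv", index=False)
        for label, by_index in heatmaps.items():
            for i, M in by_index.items():
                np.savetxt(out / f"biofilm_{label}_t{i}.csv", M, delimiter=",")
        from . import __version__

        manifest = {
            "qsbiofilm_version": __version__,
            "grid": asdict(grid), "sim": asdict(sim),
            "run_seeds": [sim.run_seed(i) for i in range(sim.n_runs)],
            "configs": [label for label, _ in configs],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return rows, heatmaps, means


# ---------------------------------------------------------------------------
# trace-difference analysis
# ---------------------------------------------------------------------------

def ad_heatmap(tr1: Trace, tr2: Trace) -> np.ndarray:
    """AD(t) = |DataSet1(t) - DataSet2(t)|, a (variables x time) matrix."""
    if tr1.names != tr2.names or not np.array_equal(tr1.times, tr2.times):
        raise PetriNetError("AD analysis requires identical grids and variables")
    return np.abs(tr1.values - tr2.values).T


def pooled_se(runs1: list[Trace], runs2: list[Trace]) -> np.ndarray:
    """Pooled standard error of the difference of two ensemble means,
    (variables x time), from the per-run sample variances."""
    v1 = np.var([tr.values for tr in runs1], axis=0, ddof=1) / len(runs1)
    v2 = np.var([tr.values for tr in runs2], axis=0, ddof=1) / len(runs2)
    return np.sqrt(v1 + v2).T
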