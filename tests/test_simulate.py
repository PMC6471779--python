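import numpy as np
import pytest

from qsbiofilm.experiments import limited_supply_net
from qsbiofilm.petri import Arc, PetriNet, PetriNetError, Place, Transition
from qsbiofilm.simulate import (
    SimConfig,
    Trace,
    average_runs,
    simulate_delta_leaping,
    simulate_ensemble,
    simulate_gillespie,
    simulate_hybrid,
    simulate_ode,
)


def continuous_decay(k=0.25, a0=50.0):
    return PetriNet(
        [Place("A", "continuous", a0)],
        [Transition("deg", "continuous", k)],
        [Arc("A", "deg", "pre", "standard", 1)],
    )


class TestODE:
    def test_exponential_decay_matches_closed_form(self):
        net = continuous_decay()
        tr = simulate_ode(net, SimConfig(t_end=10, n_record=101, h=0.01))
        expect = 50.0 * np.exp(-0.25 * tr.times)
        assert np.max(np.abs(tr["A"] - expect) / expect) < 1e-6

    def test_empty_marking_without_sources_stays_zero(self):
        net = PetriNet(
            [Place("A", "continuous", 0), Place("B", "continuous", 0)],
            [Transition("ab", "continuous", 1.0)],
            [Arc("A", "ab", "pre", "standard", 1),
             Arc("B", "ab", "post", "standard", 1)],
        )
        tr = simulate_ode(net, SimConfig(t_end=5, n_record=11))
        assert not tr.values.any()

    def test_conservative_net_conserves_token_sum(self, golden):
        cyc = golden["cycle"]
        net = PetriNet(
            [Place(p.name, "continuous", p.initial) for p in cyc.places],
            [Transition(t.name, "continuous", t.rate_constant)
             for t in cyc.transitions],
            list(cyc.arcs),
        )
        tr = simulate_ode(net, SimConfig(t_end=20, n_record=201, h=0.01))
        total = tr["A"] + tr["B"]
        assert np.max(np.abs(total - total[0]) / total[0]) < 1e-8


class TestGillespie:
    def test_degradation_mean_within_clt_band(self, golden):
        n_runs = 300
        tr = simulate_gillespie(
            golden["degradation"], SimConfig(t_end=30, n_record=31,
                                             n_runs=n_runs, seed=11))
        expect = 100 * np.exp(-0.1 * tr.times)
        se = np.sqrt(np.maximum(expect * (1 - np.exp(-0.1 * tr.times)), 1e-9) / n_runs)
        assert np.all(np.abs(tr["A"] - expect) <= 3 * se + 1e-9)

    def test_dead_net_constant_trace(self):
        net = PetriNet(
            [Place("A", "discrete", 3)],
            [Transition("t", "stochastic", 1.0)],
            [Arc("A", "t", "pre", "standard", 5)],  # never enabled
        )
        tr = simulate_gillespie(net, SimConfig(t_end=10, n_record=11, seed=0))
        assert np.all(tr["A"] == 3)

    def test_competing_transitions_split_by_rates(self):
        net = PetriNet(
            [Place("A", "discrete", 1), Place("B", "discrete", 0),
             Place("C", "discrete", 0)],
            [Transition("b", "stochastic", 3.0), Transition("c", "stochastic", 1.0)],
            [Arc("A", "b", "pre", "standard", 1), Arc("B", "b", "post", "standard", 1),
             Arc("A", "c", "pre", "standard", 1), Arc("C", "c", "post", "standard", 1)],
        )
        wins = 0
        n = 400
        for run in range(n):
            tr = simulate_gillespie(net, SimConfig(t_end=50, n_record=3, seed=run))
            wins += tr["B"][-1] == 1
        p = wins / n  # expect 3/4; binomial 99.7% band
        assert abs(p - 0.75) < 3 * np.sqrt(0.75 * 0.25 / n)

    def test_non_integer_marking_rejected(self):
        net = PetriNet([Place("A", "continuous", 1.5)],
                       [Transition("t", "stochastic", 1.0)],
                       [Arc("A", "t", "pre", "standard", 1)])
        with pytest.raises(PetriNetError):
            simulate_gillespie(net, SimConfig(t_end=1, n_record=2))


class TestDeltaLeaping:
    def test_dead_net_constant(self, golden):
        net = PetriNet([Place("A", "discrete", 0)],
                       [Transition("t", "stochastic", 2.0)],
                       [Arc("A", "t", "pre", "standard", 1)])
        tr = simulate_delta_leaping(net, SimConfig(t_end=5, n_record=6, seed=1))
        assert not tr["A"].any()

    def test_degradation_mean_within_clt_band(self, golden):
        n_runs = 300
        tr = simulate_delta_leaping(
            golden["degradation"], SimConfig(t_end=30, n_record=31,
                                             n_runs=n_runs, seed=12))
        expect = 100 * np.exp(-0.1 * tr.times)
        se = np.sqrt(np.maximum(expect * (1 - np.exp(-0.1 * tr.times)), 1e-9) / n_runs)
        assert np.all(np.abs(tr["A"] - expect) <= 3 * se + 1e-9)

    def test_agrees_with_gillespie_on_birth_death(self, golden):
        n = 300
        cfgG = SimConfig(t_end=40, n_record=41, n_runs=n, seed=21)
        cfgL = SimConfig(t_end=40, n_record=41, n_runs=n, seed=22)
        g = simulate_gillespie(golden["birth_death"], cfgG)
        l = simulate_delta_leaping(golden["birth_death"], cfgL)
        # stationary mean lambda/mu = 10, variance 10 (Poisson)
        se = np.sqrt(10.0 / n)
        tail = slice(20, None)
        assert abs(g["A"][tail].mean() - 10) < 3 * se
        assert abs(l["A"][tail].mean() - 10) < 3 * se
        assert np.all(np.abs(g["A"][tail] - l["A"][tail]) < 6 * se * np.sqrt(2))


class TestHybrid:
    def test_unlimited_supply_toggles_gate_repeatedly(self, phase3_net):
        tr = simulate_hybrid(phase3_net, None,
                             SimConfig(t_end=100, n_record=1000, seed=2))
        toggles = int(np.sum(np.abs(np.diff(tr["go"])) > 0))
        assert toggles > 2
        # biofilm accumulates stepwise: never decreases, grows overall
        assert np.all(np.diff(tr["Biofilm"]) >= -1e-9)
        assert tr["Biofilm"][-1] > 10

    def test_gate_closed_forever_blocks_import(self, phase3_net):
        closed = limited_supply_net(phase3_net, stock=5.0)  # below THR=10
        tr = simulate_hybrid(closed, None,
                             SimConfig(t_end=50, n_record=200, seed=3))
        assert not tr["go"].any()
        assert not tr["AI2_In"].any()

    def test_limited_supply_returns_to_repressed_state(self, phase3_net):
        tr = simulate_hybrid(limited_supply_net(phase3_net, 100.0), None,
                             SimConfig(t_end=200, n_record=1000, seed=4))
        assert tr["go"][-1] == 0
        assert tr["AI2_P"][-1] < 0.05
        assert tr["lsrGenes_LsrR"][-1] > 0.9
        cons = tr["lsrGenes"] + tr["lsrGenes_LsrR"]
        assert np.max(np.abs(cons - 1)) < 1e-6

    def test_bad_partition_rejected(self, phase3_net):
        with pytest.raises(PetriNetError):
            simulate_hybrid(phase3_net, {"nonexistent"},
                            SimConfig(t_end=1, n_record=2))
        # a continuous transition may not write a discrete place
        with pytest.raises(PetriNetError):
            simulate_hybrid(phase3_net, {"open"},  # close left continuous
                            SimConfig(t_end=1, n_record=2))


class TestInvariantsAlongTrajectories:
    def test_phase3_p_invariants_conserved_stochastically(self, phase3_net):
        tr = simulate_gillespie(phase3_net,
                                SimConfig(t_end=50, n_record=2000, seed=5))
        assert np.all(tr["lsrGenes"] + tr["lsrGenes_LsrR"] == 1)
        assert np.all(tr["QSeBC"] == 1)
        assert np.all(tr.values >= 0)
        assert np.all(tr["go"] <= 1)


class TestAveraging:
    def test_average_of_identical_traces_is_identity(self, golden):
        tr = simulate_gillespie(golden["degradation"],
                                SimConfig(t_end=5, n_record=6, seed=1))
        avg = average_runs([tr, tr, tr])
        assert np.array_equal(avg.values, tr.values)
        assert avg.meta["runs_averaged"] == 3

    def test_average_of_indicator_traces_in_unit_interval(self, phase3_net):
        runs = simulate_ensemble(
            phase3_net, SimConfig(t_end=30, n_record=100, n_runs=5, seed=6),
            "gillespie")
        avg = average_runs(runs)
        assert np.all((0 <= avg["go"]) & (avg["go"] <= 1))

    def test_mismatched_grids_rejected(self):
        a = Trace(np.arange(3.0), np.zeros((3, 1)), ["A"])
        b = Trace(np.arange(4.0), np.zeros((4, 1)), ["A"])
        with pytest.raises(PetriNetError):
            average_runs([a, b])


class TestDeterminism:
    @pytest.mark.parametrize("method", ["gillespie", "delta_leaping"])
    def test_stochastic_replay_bit_identical(self, golden, method):
        from qsbiofilm.simulate import simulate_delta_leaping, simulate_gillespie
        fn = {"gillespie": simulate_gillespie,
              "delta_leaping": simulate_delta_leaping}[method]
        cfg = SimConfig(t_end=20, n_record=21, n_runs=3, seed=9)
        a = fn(golden["birth_death"], cfg)
        b = fn(golden["birth_death"], cfg)
        assert np.array_equal(a.values, b.values)

    def test_hybrid_replay_bit_identical(self, phase3_net):
        cfg = SimConfig(t_end=30, n_record=100, seed=10)
        a = simulate_hybrid(phase3_net, None, cfg)
        b = simulate_hybrid(phase3_net, None, cfg)
        assert np.array_equal(a.values, b.values)

    def test_ode_deterministic(self):
        net = continuous_decay()
        cfg = SimConfig(t_end=5, n_record=11, h=0.1)
        assert np.array_equal(simulate_ode(net, cfg).values,
                              simulate_ode(net, cfg).values)


class TestTraceIO:
    def test_csv_roundtrip(self, tmp_path, golden):
        tr = simulate_gillespie(golden["degradation"],
                                SimConfig(t_end=5, n_record=6, seed=1))
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        back = Trace.from_csv(path)
        assert back.names == tr.names
        assert np.allclose(back.values, tr.values)
        assert np.allclose(back.times, tr.times)
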