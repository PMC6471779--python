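import numpy as np
import pytest

from qsbiofilm.grid import Colour, GridSpec, RegionSpec, split_instance_name, unfold
from qsbiofilm.models import (
    ModelVariant,
    PHASE3_CATEGORY,
    build_combined,
    build_phase2,
    build_phase3,
    build_spatial,
    load_phase2_params,
    phase3_core,
)
from qsbiofilm.petri import PetriNetError, incidence_matrix, net_to_dict
from qsbiofilm.simulate import SimConfig, simulate_ode


class TestPhase2:
    def test_published_node_counts(self, phase2_net):
        assert len(phase2_net.places) == 21
        assert len(phase2_net.transitions) == 23

    def test_source_places(self, phase2_net):
        # source places have only outgoing (consuming) arcs; read-tested
        # constant places count as self-sufficient, not as sources
        incoming = {a.place for a in phase2_net.arcs
                    if a.direction == "post" or a.kind != "standard"}
        sources = {p.name for p in phase2_net.places if p.name not in incoming}
        assert sources == {"Nutrients", "Putrescine"}

    def test_constant_genes_have_zero_incidence(self, phase2_net):
        C = incidence_matrix(phase2_net)
        for gene in ("luxS_gene", "pfs_gene"):
            assert not C[phase2_net.place_names.index(gene)].any()

    def test_missing_rate_constant_names_transition(self):
        params = load_phase2_params()
        del params["rate_constants"]["AdoMet"]
        with pytest.raises(PetriNetError, match="AdoMet"):
            build_phase2(params)

    def test_missing_initial_names_place(self):
        params = load_phase2_params()
        del params["initial_marking"]["SAM"]
        with pytest.raises(PetriNetError, match="SAM"):
            build_phase2(params)

    def test_vanishing_rates_give_constant_trace(self):
        params = load_phase2_params()
        params["rate_constants"] = {k: 1e-300 for k in params["rate_constants"]}
        net = build_phase2(params)
        tr = simulate_ode(net, SimConfig(t_end=10, n_record=20, h=0.5))
        assert np.allclose(tr.values, tr.values[0], atol=1e-12)


class TestPhase3:
    def test_published_node_counts(self, phase3_net):
        assert len(phase3_net.places) == 12  # 11 core + go
        assert len(phase3_net.transitions) == 17  # 15 core + open/close
        core = phase3_core(phase3_net)
        assert (len(core.places), len(core.transitions)) == (11, 15)

    def test_initial_marking_table(self, phase3_net):
        init = {p.name: p.initial for p in phase3_net.places}
        assert init["QSeBC"] == 1 and init["lsrGenes_LsrR"] == 1
        assert init["LsrABCD"] == init["LsrK"] == init["LsrR"] == 1
        assert init["Biofilm"] == 0 and init["go"] == 0

    def test_rate_categories(self, phase3_net):
        assert phase3_net.transition("open").category == "high"
        assert phase3_net.transition("close").category == "high"
        assert phase3_net.transition("BasalProduceLsrK").category == "low"
        assert phase3_net.transition("Transport_in").category == "medium"
        # stand-alone levels keep the ratio 1 : 10 : 10^4
        assert phase3_net.transition("open").rate_constant == pytest.approx(1e4)
        assert phase3_net.transition("Transport_in").rate_constant == pytest.approx(10)

    def test_thresholds_resolve_from_constants(self):
        net = build_phase3(ModelVariant.phase3(THR_open=30))
        arc = next(a for a in net.arcs if a.transition == "open" and a.kind == "read")
        assert net.resolve_weight(arc) == 30


class TestCombined:
    def test_single_fused_ai2_out(self, combined_net):
        assert combined_net.place_names.count("AI2_Out") == 1
        assert "AI2_In_Phase2" in combined_net.place_names
        assert "AI2_In_Phase3" in combined_net.place_names
        assert "AI2_In" not in combined_net.place_names

    def test_transition_count_is_union_plus_diffusion(self, combined_net):
        assert len(combined_net.transitions) == 23 + 17 + 1

    def test_diffusion_rate_scaled_by_neighbour_count(self, combined_net):
        # 2D: 8 Moore neighbours, kd = 0.1
        assert combined_net.transition("Diffusion").rate_constant == pytest.approx(0.8)
        net3d = build_combined(ModelVariant.combined(dims=3))
        assert net3d.transition("Diffusion").rate_constant == pytest.approx(2.6)

    def test_rate_level_rescaling_keeps_ratios(self, combined_net, phase3_net):
        for t3 in phase3_net.transitions:
            tc = combined_net.transition(t3.name)
            assert tc.rate_constant == pytest.approx(t3.rate_constant * 1e-4)

    def test_restriction_to_production_component(self, combined_net, phase2_net):
        for t in phase2_net.transitions:
            tc = combined_net.transition(t.name)
            assert tc.rate_constant == t.rate_constant
        arcs2 = {(a.place, a.transition, a.direction, a.kind)
                 for a in phase2_net.arcs}
        arcsc = {(a.place, a.transition, a.direction, a.kind)
                 for a in combined_net.arcs
                 if a.transition in set(phase2_net.transition_names)}
        assert arcs2 == arcsc

    def test_rebuild_is_deterministic(self):
        assert net_to_dict(build_combined()) == net_to_dict(build_combined())

    def test_threshold_defaults_symmetric(self, combined_net):
        assert combined_net.constants == {"THR": 40, "THR_close": 40}


class TestSpatial:
    def test_coloured_initial_puts_25_tokens_on_lsrk(self):
        g = GridSpec.square(21, 2)
        r = RegionSpec(11, 11, 1, 2, 1, 1, 1)
        cn = build_spatial(ModelVariant.combined(), g, r)
        lsrk = cn.coloured_initial["LsrK"]
        assert len(lsrk) == 25 and all(v == 1 for v in lsrk.values())

    def test_only_ai2_out_exists_outside_colony(self):
        g = GridSpec.square(7, 2)
        r = RegionSpec(4, 4, 1, 1, 1, 1, 1)
        u = unfold(build_spatial(ModelVariant.combined(), g, r), g, r)
        colony = {(x, y) for x in (3, 4, 5) for y in (3, 4, 5)}
        for p in u.places:
            base, c = split_instance_name(p.name)
            if (c.x, c.y) not in colony:
                assert base == "AI2_Out"

    def test_radius_zero_single_bacterium(self):
        g = GridSpec.square(5, 2)
        r = RegionSpec(3, 3, 1, 0)
        u = unfold(build_spatial(ModelVariant.combined(), g, r), g, r)
        bacterium = [p for p in u.places if not p.name.startswith("AI2_Out__")]
        assert len(bacterium) == 31
        assert len([p for p in u.places if p.name.startswith("AI2_Out__")]) == 25

    def test_inflow_replaced_by_twoway_diffusion(self):
        g = GridSpec.square(5, 2)
        cn = build_spatial(ModelVariant.combined(), g, RegionSpec(3, 3, 1, 0))
        assert "inflow" not in cn.base.transition_names
        diff_arcs = [a for a in cn.base.arcs if a.transition == "Diffusion"]
        assert {a.direction for a in diff_arcs} == {"pre", "post"}
        assert cn.expression(next(a for a in diff_arcs if a.direction == "post")) == "(a,b,c)"


class TestModelVariant:
    def test_rejects_broken_level_ratios(self):
        with pytest.raises(PetriNetError):
            ModelVariant(rate_levels=(("high", 1.0), ("low", 1e-4), ("medium", 1e-2)))

    def test_rejects_close_above_open(self):
        with pytest.raises(PetriNetError):
            ModelVariant(THR_open=10, THR_close=20)
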