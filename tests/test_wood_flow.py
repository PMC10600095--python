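"""Flow-network construction, mass balance, scaling and import deltas."""

import numpy as np
import pytest

from circwood.wood_flow import (
    HWP_CATEGORIES,
    FlowTable,
    FlowValidationError,
    build_scenario_flows,
    derive_import_deltas,
    node_balance,
    scale_to_harvest,
    uk_production,
)

BAU_SPEC = [
    ("forest_gate", "sawmill", 60.0),
    ("forest_gate", "panel_mill", 40.0),
    ("sawmill", "carcassing", 40.0),
    ("sawmill", "panel_mill", 20.0),
    ("panel_mill", "mdf", 55.0),
    ("panel_mill", "loss", 5.0),
]


class TestBuild:
    def test_forest_gate_outflow_sums_to_harvest(self):
        table = build_scenario_flows(BAU_SPEC)
        assert table.harvest_total == pytest.approx(100.0)
        assert table.outflow("forest_gate") == pytest.approx(100.0)

    def test_empty_spec_is_vacuously_balanced(self):
        table = build_scenario_flows([])
        assert table.flows == ()
        assert node_balance(table).empty

    def test_unknown_node_rejected_with_name(self):
        with pytest.raises(FlowValidationError) as exc:
            build_scenario_flows([("forest_gate", "sauna", 1.0)])
        assert exc.value.node == "sauna"

    def test_negative_quantity_rejected(self):
        with pytest.raises(FlowValidationError):
            build_scenario_flows([("forest_gate", "sawmill", -1.0)])

    def test_unbalanced_node_rejected_naming_node(self):
        spec = BAU_SPEC[:-1]  # drop the loss flow -> panel_mill unbalanced
        with pytest.raises(FlowValidationError) as exc:
            build_scenario_flows(spec)
        assert exc.value.node == "panel_mill"

    @pytest.mark.parametrize("seed", range(5))
    def test_random_balanced_spec_residuals_below_tolerance(self, seed):
        # brute-force conservation oracle: per-node inflow/outflow summation
        rng = np.random.default_rng(seed)
        saw, panel = rng.dirichlet([3.0, 2.0]) * 100.0
        to_panel = rng.uniform(0, saw * 0.4)
        spec = [
            ("forest_gate", "sawmill", saw),
            ("forest_gate", "panel_mill", panel),
            ("sawmill", "carcassing", saw - to_panel),
            ("sawmill", "panel_mill", to_panel),
            ("panel_mill", "mdf", panel + to_panel),
        ]
        table = build_scenario_flows(spec)
        for node in ("sawmill", "panel_mill"):
            inflow = sum(q for s, t, q in spec if t == node)
            outflow = sum(q for s, t, q in spec if s == node)
            assert abs(inflow - outflow) < 1e-6 * table.harvest_total
        assert not node_balance(table)["flagged"].any()


class TestNodeBalance:
    def test_balanced_fixture_all_residuals_zero(self, bundle):
        for table in bundle.flow_tables.values():
            report = node_balance(table)
            assert np.allclose(report["residual"], 0.0, atol=1e-9)

    def test_deleting_one_flow_flags_the_node(self):
        table = build_scenario_flows(BAU_SPEC)
        broken = FlowTable(
            scenario_id=table.scenario_id,
            flows=tuple(
                f for f in table.flows
                if not (f.source == "sawmill" and f.target == "panel_mill")
            ),
            harvest_total=table.harvest_total,
        )
        report = node_balance(broken)
        flagged = set(report[report["flagged"]]["node"])
        assert flagged == {"sawmill", "panel_mill"}


class TestScale:
    def test_scale_to_national_harvest(self):
        table = build_scenario_flows(BAU_SPEC)
        scaled = scale_to_harvest(table, 9.5e6)
        assert scaled.outflow("forest_gate") == pytest.approx(9.5e6)
        assert not node_balance(scaled)["flagged"].any()

    def test_scale_factor_one_is_identity(self):
        table = build_scenario_flows(BAU_SPEC)
        assert scale_to_harvest(table, 100.0) == table

    def test_per_flow_ratio_constant(self, bundle):
        # linearity oracle, flow by flow
        table = bundle.flow_tables["bau"]
        scaled = scale_to_harvest(table, 3.3e6)
        for before, after in zip(table.flows, scaled.flows):
            assert after.quantity == pytest.approx(before.quantity * 3.3e4)

    def test_non_positive_harvest_rejected(self):
        table = build_scenario_flows(BAU_SPEC)
        with pytest.raises(ValueError):
            scale_to_harvest(table, 0.0)


class TestImportDeltas:
    def test_self_comparison_all_zero(self, bundle):
        bau = bundle.flow_tables["bau"]
        assert all(d.delta_volume == 0.0 for d in derive_import_deltas(bau, bau))

    def test_production_rise_mirrored_by_import_fall(self, bundle):
        bau = bundle.flow_tables["bau"]
        casc = bundle.flow_tables["cascading"]
        deltas = {d.category: d.delta_volume for d in derive_import_deltas(casc, bau)}
        rise = casc.production("carcassing") - bau.production("carcassing")
        assert rise > 0
        assert deltas["carcassing"] == pytest.approx(-rise)

    @pytest.mark.parametrize("sid", ["cascading", "circular", "cascading_circular"])
    def test_total_supply_conserved_outside_woodfuel(self, bundle, sid):
        # brute-force conservation oracle over all non-woodfuel categories
        bau = bundle.flow_tables["bau"]
        scen = bundle.flow_tables[sid]
        deltas = {d.category: d.delta_volume for d in derive_import_deltas(scen, bau)}
        for cat in HWP_CATEGORIES:
            if cat == "woodfuel":
                continue
            assert scen.production(cat) + deltas[cat] == pytest.approx(
                bau.production(cat)
            )

    def test_woodfuel_net_consumption_falls_in_circular(self, bundle):
        bau = bundle.flow_tables["bau"]
        circ = bundle.flow_tables["circular"]
        replacement = 1.0  # normalised units
        deltas = {
            d.category: d.delta_volume
            for d in derive_import_deltas(circ, bau, replacement)
        }
        net_change = (
            circ.production("woodfuel") + deltas["woodfuel"]
            - bau.production("woodfuel")
        )
        assert net_change < 0

    def test_mismatched_harvest_rejected(self, bundle):
        bau = bundle.flow_tables["bau"]
        scaled = scale_to_harvest(bundle.flow_tables["circular"], 9.5e6)
        with pytest.raises(ValueError):
            derive_import_deltas(scaled, bau)


class TestScenarioStructure:
    """Structural invariants of the four shipped scenarios."""

    def test_all_flows_non_negative(self, bundle):
        for table in bundle.flow_tables.values():
            assert all(f.quantity >= 0 for f in table.flows)

    def test_bau_cascades_recovered_waste_wood(self, bundle):
        bau = bundle.flow_tables["bau"]
        targets = {f.target for f in bau.flows if f.source == "waste_wood"}
        assert {"panel_mill", "woodfuel_plant"} <= targets

    @pytest.mark.parametrize("sid", ["circular", "cascading_circular"])
    def test_circular_recycles_and_spares_virgin_wood(self, bundle, sid):
        bau = bundle.flow_tables["bau"]
        scen = bundle.flow_tables[sid]

        def gate_to_panel(t):
            return sum(
                f.quantity for f in t.flows
                if f.source == "forest_gate" and f.target == "panel_mill"
            )

        assert gate_to_panel(scen) < gate_to_panel(bau)
        assert scen.production("recycled_mdf") > 0

    def test_csv_and_sankey_round_trip(self, bundle, tmp_path):
        import json

        table = bundle.flow_tables["circular"]
        table.to_csv(tmp_path / "flows.csv")
        back = FlowTable.from_csv(tmp_path / "flows.csv", "circular")
        assert back == table
        sankey = json.loads(table.to_sankey_json())
        assert sum(l["value"] for l in sankey["links"]) == pytest.approx(
            sum(f.quantity for f in table.flows)
        )
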