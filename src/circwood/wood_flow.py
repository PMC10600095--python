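"""Scenario wood-flow networks: construction, validation, scaling, import deltas.

A wood-use scenario is a directed network of annual wood flows (green tonnes
per year) from the forest gate through processing stages (sawmill, panel mill,
woodfuel plant, MDF recycling) to harvested-wood-product (HWP) sinks. Four
scenarios are modelled: business-as-usual (``bau``), enhanced ``cascading``
(more sawnwood, fewer panels from virgin wood), ``circular`` (waste MDF
recycled into new MDF) and the combination ``cascading_circular``.

Mass balance is enforced at every intermediate node: inflow must equal
outflow, with losses declared as explicit flows. Because total national
consumption of each product is held constant across scenarios, changes in
domestic production are mirrored by opposite changes in imports; those import
deltas are derived here and priced downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "HWP_CATEGORIES",
    "SCENARIO_IDS",
    "SOURCE_NODES",
    "PRODUCT_NODES",
    "PROCESS_NODES",
    "Flow",
    "FlowTable",
    "ImportDelta",
    "FlowValidationError",
    "build_scenario_flows",
    "scale_to_harvest",
    "node_balance",
    "derive_import_deltas",
    "uk_production",
]

#: Product categories. Every flow terminating in a product node carries
#: exactly one of these.
HWP_CATEGORIES: tuple[str, ...] = (
    "carcassing",
    "fencing",
    "fence_poles",
    "packaging_pallets",
    "particleboard",
    "mdf",
    "recycled_mdf",
    "woodfuel",
    "other",
)

SCENARIO_IDS: tuple[str, ...] = ("bau", "cascading", "circular", "cascading_circular")

#: Nodes that inject material into the network (not balance-checked).
SOURCE_NODES: frozenset[str] = frozenset({"forest_gate", "waste_wood"})

#: Terminal product nodes, one per HWP category (not balance-checked).
PRODUCT_NODES: frozenset[str] = frozenset(HWP_CATEGORIES)

#: Intermediate processing nodes; inflow must equal outflow.
PROCESS_NODES: frozenset[str] = frozenset(
    {"sawmill", "panel_mill", "woodfuel_plant", "mdf_recycling"}
)

#: Explicit loss sink (bark, fines, drying loss declared by the spec).
LOSS_NODE = "loss"

KNOWN_NODES: frozenset[str] = (
    SOURCE_NODES | PRODUCT_NODES | PROCESS_NODES | {LOSS_NODE}
)


class FlowValidationError(ValueError):
    """A flow specification violates the network contract.

    Carries the offending node name (if any) in :attr:`node`.
    """

    def __init__(self, message: str, node: str | None = None):
        super().__init__(message)
        self.node = node


@dataclass(frozen=True)
class Flow:
    source: str
    target: str
    quantity: float  # green tonnes / yr


@dataclass(frozen=True)
class FlowTable:
    """One scenario's annual wood-flow network.

    ``harvest_total`` is the total outflow of the forest-gate node; all flow
    quantities are green tonnes per year at that harvest.
    """

    scenario_id: str
    flows: tuple[Flow, ...]
    harvest_total: float

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scenario_id: str) -> "FlowTable":
        rows = df[df["scenario_id"] == scenario_id]
        spec = [(r.source, r.target, float(r.quantity)) for r in rows.itertuples()]
        return build_scenario_flows(spec, scenario_id=scenario_id)

    @classmethod
    def from_csv(cls, path: str | Path, scenario_id: str) -> "FlowTable":
        return cls.from_frame(pd.read_csv(path), scenario_id)

    # -- accessors ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario_id": self.scenario_id,
                "source": [f.source for f in self.flows],
                "target": [f.target for f in self.flows],
                "quantity": [f.quantity for f in self.flows],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_sankey_json(self) -> str:
        """Export as a node/link JSON object for Sankey plotting."""
        nodes = sorted({f.source for f in self.flows} | {f.target for f in self.flows})
        index = {n: i for i, n in enumerate(nodes)}
        links = [
            {"source": index[f.source], "target": index[f.target], "value": f.quantity}
            for f in self.flows
        ]
        return json.dumps({"nodes": [{"name": n} for n in nodes], "links": links})

    def inflow(self, node: str) -> float:
        return sum(f.quantity for f in self.flows if f.target == node)

    def outflow(self, node: str) -> float:
        return sum(f.quantity for f in self.flows if f.source == node)

    def throughput(self, node: str) -> float:
        """Material processed by a node: inflow for process nodes, outflow
        for source nodes."""
        if node in SOURCE_NODES:
            return self.outflow(node)
        return self.inflow(node)

    def production(self, category: str) -> float:
        """Domestic production of one HWP category (inflow to its node)."""
        if category not in HWP_CATEGORIES:
            raise KeyError(f"unknown HWP category {category!r}")
        return self.inflow(category)


# ---------------------------------------------------------------------------


def build_scenario_flows(
    spec: Iterable[tuple[str, str, float]],
    scenario_id: str = "bau",
    tolerance: float = 1e-6,
) -> FlowTable:
    """Build and validate a :class:`FlowTable` from (source, target, quantity)
    triples.

    Every node name must be known, every quantity non-negative, and every
    intermediate (processing) node balanced to ``tolerance × harvest_total``
    (losses must appear as explicit flows to the loss node). An empty spec
    yields an empty, vacuously balanced table.
    """
    flows = []
    for source, target, quantity in spec:
        for node in (source, target):
            if node not in KNOWN_NODES:
                raise FlowValidationError(f"unknown node name {node!r}", node=node)
        if quantity < 0:
            raise FlowValidationError(
                f"negative quantity {quantity} on flow {source}->{target}",
                node=source,
            )
        flows.append(Flow(source, target, float(quantity)))

    table = FlowTable(
        scenario_id=scenario_id,
        flows=tuple(flows),
        harvest_total=sum(f.quantity for f in flows if f.source == "forest_gate"),
    )
    report = node_balance(table, tolerance=tolerance)
    bad = report[report["flagged"]]
    if not bad.empty:
        node = bad.iloc[0]["node"]
        resid = bad.iloc[0]["residual"]
        raise FlowValidationError(
            f"node {node!r} unbalanced: residual {resid:g} green t/yr", node=node
        )
    return table


def node_balance(table: FlowTable, tolerance: float = 1e-6) -> pd.DataFrame:
    """Per-node mass-balance report for the intermediate nodes.

    residual(n) = inflow(n) − outflow(n); a node is flagged when
    ``|residual| > tolerance × harvest_total``. Report-only: never raises.
    """
    nodes = sorted(
        {f.source for f in table.flows} | {f.target for f in table.flows}
    )
    rows = []
    abs_tol = tolerance * table.harvest_total if table.harvest_total else tolerance
    for n in nodes:
        if n not in PROCESS_NODES:
            continue
        resid = table.inflow(n) - table.outflow(n)
        rows.append({"node": n, "residual": resid, "flagged": abs(resid) > abs_tol})
    return pd.DataFrame(rows, columns=["node", "residual", "flagged"])


def scale_to_harvest(table: FlowTable, harvest: float) -> FlowTable:
    """Rescale every flow so total forest-gate outflow equals ``harvest``."""
    if harvest <= 0:
        raise ValueError(f"harvest must be positive, got {harvest}")
    if table.harvest_total <= 0:
        raise FlowValidationError("table has no forest-gate outflow to scale")
    factor = harvest / table.harvest_total
    return FlowTable(
        scenario_id=table.scenario_id,
        flows=tuple(replace(f, quantity=f.quantity * factor) for f in table.flows),
        harvest_total=harvest,
    )


def uk_production(table: FlowTable) -> dict[str, float]:
    """Domestic production per HWP category (green tonnes/yr)."""
    return {c: table.production(c) for c in HWP_CATEGORIES}


@dataclass(frozen=True)
class ImportDelta:
    """Change in imported volume of one HWP category relative to BAU.

    Positive = more imports. For every category except woodfuel, imports move
    opposite to domestic production so that total supply is constant. Woodfuel
    additionally carries a configured import volume replacing recycled waste-MDF
    fuel, which leaves a real net reduction in national woodfuel consumption
    in circular scenarios.
    """

    category: str
    delta_volume: float  # signed green-tonne-equivalent / yr vs BAU


def derive_import_deltas(
    scenario: FlowTable,
    bau: FlowTable,
    woodfuel_import_replacement: float = 0.0,
    tolerance: float = 1e-6,
) -> list[ImportDelta]:
    """Import-volume changes versus BAU under the constant-supply rule.

    For each category, delta = BAU production − scenario production, so that
    UK production + imports is invariant. For woodfuel the delta is instead
    the configured import replacement of diverted recycled-waste-MDF fuel;
    net woodfuel consumption is then free to fall in circular scenarios.
    """
    if abs(scenario.harvest_total - bau.harvest_total) > tolerance * max(
        bau.harvest_total, 1.0
    ):
        raise ValueError(
            "harvest totals differ: "
            f"{scenario.harvest_total:g} vs {bau.harvest_total:g}"
        )
    deltas = []
    for cat in HWP_CATEGORIES:
        if cat == "woodfuel":
            d = float(woodfuel_import_replacement)
            if scenario.scenario_id == bau.scenario_id:
                d = 0.0
        else:
            d = bau.production(cat) - scenario.production(cat)
        deltas.append(ImportDelta(category=cat, delta_volume=d))
    return deltas
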