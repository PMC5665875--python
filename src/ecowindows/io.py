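"""YAML/JSON serialization of network schemas and site configurations.

The on-disk network format is deliberately dense and explicit: every CPT row
lists its full parent-state combination, and sparse/default-row dialects are
rejected at validation so a config file means exactly one network.  A
JSON-Schema document describing the format ships with the package
(``data/network.schema.json``); the structural rules it states are enforced
by the loader and :func:`ecowindows.dbn.validate_schema`.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from ecowindows.dbn import (
    ConditionalTable,
    NetworkSchema,
    NodeSpec,
    RegimeRule,
    RegimeSelector,
    StateSpace,
)
from ecowindows.seagrass import SiteConfig


def network_json_schema() -> dict:
    """The shipped JSON-Schema document for the network file format."""
    text = resources.files("ecowindows").joinpath("data/network.schema.json").read_text()
    return json.loads(text)


# ---------------------------------------------------------------------------
# network schema
# ---------------------------------------------------------------------------

def schema_to_dict(schema: NetworkSchema) -> dict:
    return {
        "name": schema.name,
        "nodes": [
            {
                "name": n.name,
                "states": list(n.states.labels),
                **({"zero_state": n.states.zero_label} if n.states.zero_label else {}),
                "intra_parents": list(n.intra_parents),
                "inter_parents": list(n.inter_parents),
                "role": n.role,
            }
            for n in schema.nodes
        ],
        "tables": {
            tid: {
                "child": t.child,
                "parent_order": list(t.parent_order),
                "rows": [
                    {"parents": list(combo), "p": [float(x) for x in row]}
                    for combo, row in t.rows.items()
                ],
            }
            for tid, t in schema.tables.items()
        },
        "selectors": {
            node: {
                "rules": [
                    {
                        "table": r.table,
                        **({"months": sorted(r.months)} if r.months is not None else {}),
                        **({"slices": list(r.slices)} if r.slices is not None else {}),
                        **({"regime": r.regime} if r.regime is not None else {}),
                    }
                    for r in sel.rules
                ],
                **({"default": sel.default} if sel.default is not None else {}),
            }
            for node, sel in schema.selectors.items()
        },
    }


def schema_from_dict(data: dict) -> NetworkSchema:
    nodes = []
    for nd in data["nodes"]:
        nodes.append(NodeSpec(
            name=nd["name"],
            states=StateSpace(tuple(nd["states"]), nd.get("zero_state")),
            intra_parents=tuple(nd.get("intra_parents", ())),
            inter_parents=tuple(nd.get("inter_parents", ())),
            role=nd.get("role", "process"),
        ))
    tables = {}
    for tid, td in data.get("tables", {}).items():
        rows = {}
        for row in td["rows"]:
            rows[tuple(row["parents"])] = np.asarray(row["p"], dtype=float)
        tables[tid] = ConditionalTable(td["child"], tuple(td["parent_order"]), rows)
    selectors = {}
    for node, sd in data.get("selectors", {}).items():
        rules = tuple(
            RegimeRule(
                table=rd["table"],
                months=frozenset(rd["months"]) if "months" in rd else None,
                slices=tuple(rd["slices"]) if "slices" in rd else None,
                regime=rd.get("regime"),
            )
            for rd in sd.get("rules", ())
        )
        selectors[node] = RegimeSelector(rules=rules, default=sd.get("default"))
    return NetworkSchema(nodes=nodes, tables=tables, selectors=selectors,
                         name=data.get("name", "network"))


def save_network(schema: NetworkSchema, path: str | Path) -> None:
    path = Path(path)
    data = schema_to_dict(schema)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=1))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_network(path: str | Path) -> NetworkSchema:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return schema_from_dict(data)


# ---------------------------------------------------------------------------
# site configuration
# ---------------------------------------------------------------------------

def site_to_dict(site: SiteConfig) -> dict:
    return {
        "site_name": site.site_name,
        "latitude": site.latitude,
        "climate": site.climate,
        "tidal": site.tidal,
        "meadow_type": site.meadow_type,
        "life_history": site.life_history,
        "genus_label": site.genus_label,
        "light_p": [round(float(p), 6) for p in site.light_p],
        "reference_value": site.reference_value,
        "reference_units": site.reference_units,
    }


def site_from_dict(data: dict) -> SiteConfig:
    return SiteConfig(**data)


def save_site(site: SiteConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(site_to_dict(site), sort_keys=False))


def load_site(path: str | Path) -> SiteConfig:
    return site_from_dict(yaml.safe_load(Path(path).read_text()))
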