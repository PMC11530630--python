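"""Network JSON reading/writing and result serialisation.

The canonical input format is a JSON object with top-level keys ``nodes``,
``channels``, ``pumps``, ``fluids``, ``species``, ``injections``,
``droplets``, ``membranes`` and ``settings``. Every physical value is either
a plain number (SI) or ``{"value": x, "unit": "um"}``. The reader validates
structurally (unknown keys are rejected with their JSON pointer) and converts
units on load; a JSON Schema describing the format ships with the package at
``chipflow/schema/network.schema.json``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from . import __version__
from .engine import ResultSet, SimulationConfig
from .network import DropletSpec, Injection, MembraneSpec, Network

SCHEMA_PATH = Path(__file__).parent / "schema" / "network.schema.json"


class FormatError(ValueError):
    """Malformed network file; the message carries a JSON pointer."""


def _require_keys(obj: dict, allowed: set[str], required: set[str], where: str) -> None:
    unknown = set(obj) - allowed
    if unknown:
        raise FormatError(f"{where}: unknown key(s) {sorted(unknown)}")
    missing = required - set(obj)
    if missing:
        raise FormatError(f"{where}: missing required key(s) {sorted(missing)}")


def _qty(obj: dict, key: str, dimension: str, where: str,
         default: Any = ...) -> float:
    from .units import UnitError, to_si

    if key not in obj:
        if default is ...:
            raise FormatError(f"{where}: missing {key!r}")
        return default
    try:
        return to_si(obj[key], dimension, f"{where}/{key}")
    except UnitError as e:
        raise FormatError(str(e)) from e


def read_network(source: str | Path | dict) -> tuple[Network, SimulationConfig]:
    """Parse and validate a network description (path, JSON text, or dict)."""
    if isinstance(source, dict):
        doc = source
    else:
        p = Path(source)
        if p.exists():
            doc = json.loads(p.read_text())
        else:
            raise FormatError(f"no such file: {source}")
    if not isinstance(doc, dict):
        raise FormatError("/: top level must be an object")
    _require_keys(
        doc,
        {"nodes", "channels", "pumps", "fluids", "species", "injections",
         "droplets", "membranes", "settings"},
        {"nodes", "channels", "pumps", "fluids"},
        "/",
    )
    net = Network()
    for i, nd in enumerate(doc["nodes"]):
        w = f"/nodes/{i}"
        _require_keys(nd, {"id", "ground", "sink"}, {"id"}, w)
        net.add_node(str(nd["id"]), ground=bool(nd.get("ground", False)),
                     sink=bool(nd.get("sink", False)))
    for i, cd in enumerate(doc["channels"]):
        w = f"/channels/{i}"
        _require_keys(cd, {"id", "node_a", "node_b", "width", "height", "length"},
                      {"id", "node_a", "node_b", "width", "height", "length"}, w)
        net.add_channel(str(cd["id"]), str(cd["node_a"]), str(cd["node_b"]),
                        _qty(cd, "width", "length", w),
                        _qty(cd, "height", "length", w),
                        _qty(cd, "length", "length", w))
    for i, pdk in enumerate(doc["pumps"]):
        w = f"/pumps/{i}"
        _require_keys(pdk, {"id", "node_from", "node_to", "kind", "value"},
                      {"id", "node_from", "node_to", "kind", "value"}, w)
        kind = str(pdk["kind"])
        dim = "flow_rate" if kind == "flow_rate" else "pressure"
        net.add_pump(str(pdk["id"]), str(pdk["node_from"]), str(pdk["node_to"]),
                     kind, _qty(pdk, "value", dim, w))
    for i, fd in enumerate(doc["fluids"]):
        w = f"/fluids/{i}"
        _require_keys(fd, {"id", "viscosity", "continuous_phase"},
                      {"id", "viscosity"}, w)
        net.add_fluid(str(fd["id"]), _qty(fd, "viscosity", "viscosity", w),
                      continuous_phase=bool(fd.get("continuous_phase", False)))
    for i, sd in enumerate(doc.get("species", [])):
        w = f"/species/{i}"
        _require_keys(sd, {"id", "diffusion_coefficient"},
                      {"id", "diffusion_coefficient"}, w)
        net.add_species(str(sd["id"]),
                        _qty(sd, "diffusion_coefficient", "diffusivity", w))
    for i, jd in enumerate(doc.get("injections", [])):
        w = f"/injections/{i}"
        _require_keys(jd, {"node", "species_concentrations", "t_start", "t_end"},
                      {"node", "species_concentrations"}, w)
        conc = {
            str(sp): _qty(jd["species_concentrations"], sp, "concentration", w)
            for sp in jd["species_concentrations"]
        }
        t_end = jd.get("t_end")
        net.injections.append(Injection(
            str(jd["node"]), conc,
            t_start=_qty(jd, "t_start", "time", w, 0.0),
            t_end=None if t_end is None else _qty(jd, "t_end", "time", w),
        ))
    for i, dd in enumerate(doc.get("droplets", [])):
        w = f"/droplets/{i}"
        _require_keys(dd, {"id", "length", "b", "channel", "t_inject"},
                      {"id", "length", "channel"}, w)
        net.droplets.append(DropletSpec(
            str(dd["id"]),
            _qty(dd, "length", "length", w),
            float(dd.get("b", 3.0)),  # midpoint of the usual 2..5 range
            str(dd["channel"]),
            t_inject=_qty(dd, "t_inject", "time", w, 0.0),
        ))
    for i, md in enumerate(doc.get("membranes", [])):
        w = f"/membranes/{i}"
        _require_keys(md, {"id", "channel", "area", "pore_radius", "porosity",
                           "thickness", "tank_volume", "model"},
                      {"id", "channel", "area", "pore_radius", "porosity",
                       "thickness", "tank_volume"}, w)
        spec = MembraneSpec(
            str(md["id"]), str(md["channel"]),
            _qty(md, "area", "area", w),
            _qty(md, "pore_radius", "length", w),
            float(md["porosity"]),
            _qty(md, "thickness", "length", w),
            _qty(md, "tank_volume", "volume", w),
            model=str(md.get("model", "pore_discovery")),
        )
        net.membranes[spec.id] = spec

    st = doc.get("settings", {})
    w = "/settings"
    _require_keys(st, {"max_time", "fixed_step", "modules", "max_events",
                       "terminate_on_droplet_exit", "record"}, set(), w)
    config = SimulationConfig(
        max_time=_qty(st, "max_time", "time", w, 1.0),
        fixed_step=(None if st.get("fixed_step") is None
                    else _qty(st, "fixed_step", "time", w)),
        modules=set(st["modules"]) if "modules" in st else None,
        max_events=int(st.get("max_events", 500_000)),
        terminate_on_droplet_exit=bool(st.get("terminate_on_droplet_exit", True)),
        record=str(st.get("record", "events")),
    )
    return net, config


def network_to_dict(net: Network, config: Optional[SimulationConfig] = None) -> dict:
    """Serialise a network (SI values) back to the JSON structure."""
    doc: dict[str, Any] = {
        "nodes": [
            {"id": n.id, "ground": n.is_ground, "sink": n.is_sink}
            for n in net.nodes.values()
        ],
        "channels": [
            {"id": c.id, "node_a": c.node_a, "node_b": c.node_b,
             "width": c.width, "height": c.height, "length": c.length}
            for c in net.channels.values()
        ],
        "pumps": [
            {"id": p.id, "node_from": p.node_from, "node_to": p.node_to,
             "kind": p.kind, "value": p.value}
            for p in net.pumps.values()
        ],
        "fluids": [
            {"id": f.id, "viscosity": f.viscosity,
             "continuous_phase": f.continuous_phase}
            for f in net.fluids.values()
        ],
    }
    if net.species:
        doc["species"] = [
            {"id": s.id, "diffusion_coefficient": s.diffusion_coefficient}
            for s in net.species.values()
        ]
    if net.injections:
        doc["injections"] = [
            {"node": j.node, "species_concentrations": dict(j.species_concentrations),
             "t_start": j.t_start, **({"t_end": j.t_end} if j.t_end is not None else {})}
            for j in net.injections
        ]
    if net.droplets:
        doc["droplets"] = [
            {"id": d.id, "length": d.length, "b": d.b,
             "channel": d.channel, "t_inject": d.t_inject}
            for d in net.droplets
        ]
    if net.membranes:
        doc["membranes"] = [
            {"id": m.id, "channel": m.channel, "area": m.area,
             "pore_radius": m.pore_radius, "porosity": m.porosity,
             "thickness": m.thickness, "tank_volume": m.tank_volume,
             "model": m.model}
            for m in net.membranes.values()
        ]
    if config is not None:
        doc["settings"] = {
            "max_time": config.max_time,
            **({"fixed_step": config.fixed_step}
               if config.fixed_step is not None else {}),
            **({"modules": sorted(config.modules)}
               if config.modules is not None else {}),
        }
    return doc


def write_network(net: Network, path: str | Path,
                  config: Optional[SimulationConfig] = None) -> None:
    Path(path).write_text(json.dumps(network_to_dict(net, config), indent=2) + "\n")


# -- result writers ---------------------------------------------------------------

def results_frame(rs: ResultSet) -> pd.DataFrame:
    """Long-format time series: (time, entity_type, id, variable, value)."""
    rows: list[tuple] = []
    for rec in rs.records:
        t = rec.time
        for nid in sorted(rec.node_pressures):
            rows.append((t, "node", nid, "pressure_Pa", rec.node_pressures[nid]))
        for cid in sorted(rec.channel_flows):
            rows.append((t, "channel", cid, "flow_m3_per_s", rec.channel_flows[cid]))
        for nid in sorted(rec.node_mixtures):
            mix = rec.node_mixtures[nid]
            for sp, c in mix.concentrations:
                rows.append((t, "node", nid, f"concentration[{sp}]_mol_per_m3", c))
        for mid in sorted(rec.tank_concentrations):
            for sp in sorted(rec.tank_concentrations[mid]):
                rows.append((t, "tank", mid, f"concentration[{sp}]_mol_per_m3",
                             rec.tank_concentrations[mid][sp]))
        for did in sorted(rec.droplet_positions):
            ch, pos = rec.droplet_positions[did]
            if ch is not None:
                rows.append((t, "droplet", did, f"head_fraction[{ch}]", pos))
    return pd.DataFrame(rows, columns=["time", "entity_type", "id", "variable", "value"])


def write_results(rs: ResultSet, out_dir: str | Path,
                  wall_time: Optional[float] = None) -> list[Path]:
    """Write the CSV time series, JSON summary, droplet paths, and manifest.

    Deterministic column and row order; reruns of the same input produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    ts = out / "timeseries.csv"
    results_frame(rs).to_csv(ts, index=False, float_format="%.12g")
    written.append(ts)

    summary = {
        "final_time": rs.records[-1].time if rs.records else None,
        "event_count": rs.event_count,
        "node_pressures": rs.final_flow.node_pressures if rs.final_flow else {},
        "channel_flows": rs.final_flow.channel_flows if rs.final_flow else {},
        "tank_concentrations": (
            rs.records[-1].tank_concentrations if rs.records else {}
        ),
        "event_log": [
            {"time": e.time, "kind": e.kind, "payload": e.payload}
            for e in rs.event_log
        ],
    }
    sj = out / "summary.json"
    sj.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(sj)

    if rs.droplet_paths:
        dp = out / "droplet_paths.json"
        dp.write_text(json.dumps(rs.droplet_paths, indent=2, sort_keys=True) + "\n")
        written.append(dp)

    manifest = {
        "software": f"chipflow {__version__}",
        "config": {
            "max_time": rs.config.max_time,
            "fixed_step": rs.config.fixed_step,
            "modules": sorted(rs.config.resolve_modules(rs.network)),
        },
        "event_count": rs.event_count,
        "droplet_paths_written": bool(rs.droplet_paths),
        **({"wall_time_s": round(wall_time, 3)} if wall_time is not None else {}),
        "outputs": [p.name for p in written],
    }
    mf = out / "manifest.json"
    mf.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mf)
    return written
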