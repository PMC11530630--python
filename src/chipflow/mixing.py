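"""Mixture transport: slug-based plug flow with instantaneous node mixing.

Channel contents are represented as ordered slugs — contiguous intervals of
the channel occupied by one homogeneous mixture. Slugs advect with the flow
without changing composition (convection-dominated regime, lateral diffusion
neglected); at a junction all inflows mix instantaneously and completely,
flow-rate weighted:

    C_out = sum(C_i * Q_i) / sum(Q_i)

The model assumes non-reactive, fully miscible fluids on a fixed flow field:
mixtures are passive scalars and do not alter channel resistance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

#: relative concentration difference below which adjacent slugs merge
MERGE_RTOL = 1e-12
#: tolerance on slug interval bookkeeping (fractions of channel length)
POS_EPS = 1e-12


class MixingError(ValueError):
    pass


@dataclass(frozen=True)
class Mixture:
    """Immutable species -> concentration map [mol/m^3]; absent species = 0."""

    concentrations: tuple[tuple[str, float], ...] = ()

    @staticmethod
    def of(conc: dict[str, float] | "Mixture" | None = None, **kw: float) -> "Mixture":
        if isinstance(conc, Mixture):
            return conc
        d = dict(conc or {})
        d.update(kw)
        for sp, c in d.items():
            if c < 0 or not math.isfinite(c):
                raise MixingError(f"invalid concentration {c!r} for species {sp!r}")
        items = tuple(sorted((sp, float(c)) for sp, c in d.items() if c != 0.0))
        return Mixture(items)

    def as_dict(self) -> dict[str, float]:
        return dict(self.concentrations)

    def get(self, species: str) -> float:
        for sp, c in self.concentrations:
            if sp == species:
                return c
        return 0.0

    def species(self) -> set[str]:
        return {sp for sp, _ in self.concentrations}

    def close_to(self, other: "Mixture", rtol: float = MERGE_RTOL) -> bool:
        for sp in self.species() | other.species():
            a, b = self.get(sp), other.get(sp)
            if abs(a - b) > rtol * max(abs(a), abs(b), 1e-300):
                return False
        return True


@dataclass
class Slug:
    """One homogeneous mixture occupying [start, end) of a channel (fractions,
    0 at node_a)."""

    start: float
    end: float
    mixture: Mixture

    @property
    def length(self) -> float:
        return self.end - self.start


def full_channel(mixture: Mixture | None = None) -> list[Slug]:
    """A channel uniformly filled with one mixture."""
    return [Slug(0.0, 1.0, mixture or Mixture())]


def mix_at_node(inflows: Sequence[tuple[float, Mixture]]) -> Mixture:
    """Flow-rate-weighted instantaneous mixing of all inflow streams.

    ``inflows`` is a sequence of (volumetric flow rate, mixture). Per species
    the outflow concentration is sum(C_i Q_i) / sum(Q_i).
    """
    if not inflows:
        raise MixingError("node mixing needs at least one inflow")
    q_total = 0.0
    for q, _ in inflows:
        if q < 0:
            raise MixingError("inflow rates must be non-negative")
        q_total += q
    if q_total <= 0:
        raise MixingError("no outflow defined: total inflow rate is zero")
    species: set[str] = set()
    for _, m in inflows:
        species |= m.species()
    out = {
        sp: sum(q * m.get(sp) for q, m in inflows) / q_total
        for sp in species
    }
    return Mixture.of(out)


def merge_slugs(slugs: list[Slug]) -> list[Slug]:
    """Merge adjacent slugs with (near-)identical mixtures; drop empty ones."""
    out: list[Slug] = []
    for s in slugs:
        if s.length <= POS_EPS:
            if out:
                out[-1].end = s.end
            continue
        if out and out[-1].mixture.close_to(s.mixture):
            out[-1].end = s.end
        else:
            out.append(s)
    if out:
        out[0].start = 0.0 if out[0].start < POS_EPS else out[0].start
        out[-1].end = 1.0 if out[-1].end > 1.0 - POS_EPS else out[-1].end
    return out


def propagate_slugs(
    slugs: list[Slug],
    dfrac: float,
    inlet_mixture: Mixture,
) -> tuple[list[Slug], list[tuple[Mixture, float]]]:
    """Advect a channel's slugs by a signed fraction of the channel length.

    Positive ``dfrac`` moves material toward node_b; the inlet mixture fills
    the vacated interval at the upstream end. Returns the updated slug list
    and the ordered outflow record: (mixture, fraction-volume) pairs delivered
    to the downstream node, first-delivered first.

    Species amount is conserved exactly: inflow = outflow + change in storage,
    because intervals are only translated, clipped, and created.
    """
    if abs(dfrac) <= 0.0:
        return slugs, []
    if abs(dfrac) > 1.0 + POS_EPS:
        raise MixingError(
            f"advection step {dfrac:g} exceeds one channel volume; "
            "event scheduling must bound the step"
        )
    dfrac = max(-1.0, min(1.0, dfrac))
    out: list[tuple[Mixture, float]] = []
    kept: list[Slug] = []
    if dfrac > 0:
        for s in slugs:
            a, b = s.start + dfrac, s.end + dfrac
            if b > 1.0:
                out.append((s.mixture, b - max(a, 1.0)))
            if a < 1.0:
                kept.append(Slug(a, min(b, 1.0), s.mixture))
        kept.insert(0, Slug(0.0, dfrac, inlet_mixture))
        # outflow order: the slug nearest the outlet leaves first
        out = [(m, v) for m, v in reversed(out) if v > POS_EPS]
    else:
        d = -dfrac
        for s in slugs:
            a, b = s.start - d, s.end - d
            if a < 0.0:
                out.append((s.mixture, min(b, 0.0) - a))
            if b > 0.0:
                kept.append(Slug(max(a, 0.0), b, s.mixture))
        kept.append(Slug(1.0 - d, 1.0, inlet_mixture))
        out = [(m, v) for m, v in out if v > POS_EPS]
    return merge_slugs(kept), out


def slug_partition_ok(slugs: list[Slug], tol: float = 1e-9) -> bool:
    """Check that slugs partition [0, 1] without gaps or overlaps."""
    if not slugs:
        return False
    if abs(slugs[0].start) > tol or abs(slugs[-1].end - 1.0) > tol:
        return False
    for prev, nxt in zip(slugs, slugs[1:]):
        if abs(prev.end - nxt.start) > tol:
            return False
    return True


def steady_state_concentrations(
    net,
    flow_state,
    boundary_mixtures: dict[str, Mixture],
) -> dict[str, Mixture]:
    """Closed-form steady-state mixture at every node by cascading the node
    mixing rule through the flow-directed graph in topological order.

    ``boundary_mixtures`` maps inlet node ids to the mixture their pump
    delivers. Only valid when the flow directions form a DAG (no
    recirculation loops).
    """
    import networkx as nx

    q_eps = 1e-18
    dg = nx.DiGraph()
    dg.add_nodes_from(net.nodes)
    for cid, q in flow_state.channel_flows.items():
        c = net.channels[cid]
        if q > q_eps:
            dg.add_edge(c.node_a, c.node_b, channel=cid, q=q)
        elif q < -q_eps:
            dg.add_edge(c.node_b, c.node_a, channel=cid, q=-q)
    if not nx.is_directed_acyclic_graph(dg):
        raise MixingError("flow field contains a cycle; no closed-form cascade")
    result: dict[str, Mixture] = {}
    for node in nx.topological_sort(dg):
        inflows: list[tuple[float, Mixture]] = []
        for up, _, data in dg.in_edges(node, data=True):
            inflows.append((data["q"], result[up]))
        for p in net.pumps.values():
            qp = flow_state.pump_flows.get(p.id, 0.0)
            if (p.node_to == node and qp > q_eps) or (p.node_from == node and qp < -q_eps):
                inflows.append((abs(qp), boundary_mixtures.get(node, Mixture())))
        result[node] = mix_at_node(inflows) if inflows else boundary_mixtures.get(node, Mixture())
    return result


def outlet_concentration_profile(resultset, node: str):
    """Time series of the mixture arriving at a sink node, as a DataFrame
    with columns (time, node, species, concentration)."""
    import pandas as pd

    net = resultset.network
    if node not in net.nodes:
        raise MixingError(f"unknown node {node!r}")
    if not (net.nodes[node].is_sink or net.nodes[node].is_ground):
        raise MixingError(f"node {node!r} is not a sink")
    rows = []
    for rec in resultset.records:
        mix = rec.node_mixtures.get(node, Mixture())
        species = set(net.species) | mix.species()
        for sp in sorted(species):
            rows.append((rec.time, node, sp, mix.get(sp)))
    return pd.DataFrame(rows, columns=["time", "node", "species", "concentration"])
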