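"""Network data model for 1D microfluidic circuits.

A microfluidic chip is abstracted as a graph: channel junctions and ports are
nodes, rectangular channels are edges carrying a hydraulic resistance, and
pumps are the sources of the circuit analogy (flow-rate pump = current source,
pressure pump = voltage source). Pressure drop, volumetric flow rate and
hydraulic resistance obey Hagen-Poiseuille's law dP = Q * R, the hydraulic
analog of Ohm's law.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

log = logging.getLogger(__name__)

#: channels with resistance below this are rejected (singular circuits)
MIN_RESISTANCE = 1e-30


class NetworkError(ValueError):
    """Raised for physically or structurally invalid network definitions."""


def rectangular_prefactor(w: float, h: float) -> float:
    """Geometric prefactor of the rectangular-duct resistance law.

    ``12 * [1 - (192 h / (pi^5 w)) * tanh(pi w / (2 h))]^-1``, valid for the
    wide-flat orientation h/w < 1. Tends to 12 in the shallow-channel limit
    h/w -> 0.
    """
    if w <= 0 or h <= 0:
        raise NetworkError("channel cross-section dimensions must be positive")
    if h / w >= 1.0:
        raise NetworkError(
            f"rectangular-duct law requires h/w < 1 (got h/w = {h / w:.4g}); "
            "swap width and height for tall channels"
        )
    bracket = 1.0 - (192.0 * h / (math.pi**5 * w)) * math.tanh(math.pi * w / (2.0 * h))
    return 12.0 / bracket


def channel_resistance(w: float, h: float, l: float, mu_c: float) -> float:
    """Hydraulic resistance [Pa*s/m^3] of a rectangular channel.

    Parameters are width ``w``, height ``h`` and length ``l`` in metres
    (h/w < 1 required) and the dynamic viscosity ``mu_c`` of the continuous
    phase in Pa*s.
    """
    if l <= 0:
        raise NetworkError("channel length must be positive")
    if mu_c <= 0:
        raise NetworkError("viscosity must be positive")
    return rectangular_prefactor(w, h) * mu_c * l / (w * h**3)


def channel_volume(w: float, h: float, l: float) -> float:
    """Interior volume [m^3] of a rectangular channel."""
    if w <= 0 or h <= 0 or l <= 0:
        raise NetworkError("channel dimensions must be positive")
    return w * h * l


@dataclass(frozen=True)
class Node:
    id: str
    is_ground: bool = False  # pressure reference (0 Pa)
    is_sink: bool = False  # open outlet at reference pressure


@dataclass(frozen=True)
class Channel:
    """Rectangular channel between two nodes; orientation node_a -> node_b."""

    id: str
    node_a: str
    node_b: str
    width: float
    height: float
    length: float

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise NetworkError(f"channel {self.id!r}: node_a == node_b")
        if self.width <= 0 or self.height <= 0 or self.length <= 0:
            raise NetworkError(f"channel {self.id!r}: dimensions must be positive")
        if self.height > self.width:
            # the duct law is written for the wide-flat orientation; the
            # physical cross-section is unchanged by the swap
            w, h = self.height, self.width
            log.warning(
                "channel %s: h/w >= 1, swapping width and height to %gx%g",
                self.id, w, h,
            )
            object.__setattr__(self, "width", w)
            object.__setattr__(self, "height", h)
        if self.height / self.width > 0.9:
            log.warning(
                "channel %s: aspect ratio h/w = %.3f approaches 1; the "
                "rectangular-duct law loses accuracy near square sections",
                self.id, self.height / self.width,
            )

    @property
    def volume(self) -> float:
        return channel_volume(self.width, self.height, self.length)

    def resistance(self, mu_c: float) -> float:
        return channel_resistance(self.width, self.height, self.length, mu_c)


@dataclass(frozen=True)
class Fluid:
    id: str
    viscosity: float  # dynamic viscosity [Pa*s]
    continuous_phase: bool = False

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise NetworkError(f"fluid {self.id!r}: viscosity must be positive")


@dataclass(frozen=True)
class Species:
    id: str
    diffusion_coefficient: float  # [m^2/s]

    def __post_init__(self) -> None:
        if self.diffusion_coefficient <= 0:
            raise NetworkError(
                f"species {self.id!r}: diffusion coefficient must be positive"
            )


@dataclass(frozen=True)
class Pump:
    """Flow-rate pump (current source) or pressure pump (voltage source).

    Oriented node_from -> node_to: a flow-rate pump drives ``value`` m^3/s in
    that direction; a pressure pump holds P(node_to) - P(node_from) = value Pa.
    """

    id: str
    node_from: str
    node_to: str
    kind: str  # "flow_rate" | "pressure"
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("flow_rate", "pressure"):
            raise NetworkError(f"pump {self.id!r}: kind must be flow_rate|pressure")
        if not math.isfinite(self.value):
            raise NetworkError(f"pump {self.id!r}: value must be finite")
        if self.node_from == self.node_to:
            raise NetworkError(f"pump {self.id!r}: node_from == node_to")


@dataclass(frozen=True)
class Injection:
    """Inlet mixture schedule: node receives these concentrations on [t_start, t_end)."""

    node: str
    species_concentrations: dict[str, float]
    t_start: float = 0.0
    t_end: Optional[float] = None  # None = until simulation end

    def __post_init__(self) -> None:
        for sp, c in self.species_concentrations.items():
            if c < 0 or not math.isfinite(c):
                raise NetworkError(f"injection at {self.node!r}: C[{sp}] invalid")
        if self.t_end is not None and self.t_end <= self.t_start:
            raise NetworkError(f"injection at {self.node!r}: t_end <= t_start")

    def active(self, t: float) -> bool:
        return t >= self.t_start and (self.t_end is None or t < self.t_end)


@dataclass(frozen=True)
class DropletSpec:
    """Scheduled droplet: injected into `channel` at time `t_inject`."""

    id: str
    length: float  # [m]
    b: float  # resistance factor, usually 2..5
    channel: str
    t_inject: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise NetworkError(f"droplet {self.id!r}: length must be positive")
        if self.b <= 0:
            raise NetworkError(f"droplet {self.id!r}: b must be positive")
        if not (2.0 <= self.b <= 5.0):
            log.warning("droplet %s: b = %g outside the usual 2..5 range", self.id, self.b)


@dataclass(frozen=True)
class MembraneSpec:
    """Porous membrane attached alongside a channel, backed by a tank."""

    id: str
    channel: str
    area: float  # membrane surface A_m [m^2]
    pore_radius: float  # r [m]
    porosity: float  # fraction in (0, 1]
    thickness: float  # effective thickness th [m]
    tank_volume: float  # V_t [m^3]
    model: str = "pore_discovery"

    def __post_init__(self) -> None:
        if min(self.area, self.pore_radius, self.thickness, self.tank_volume) <= 0:
            raise NetworkError(f"membrane {self.id!r}: geometry must be positive")
        if not (0.0 <= self.porosity < 1.0):
            raise NetworkError(f"membrane {self.id!r}: porosity must be in [0, 1)")
        if self.model != "pore_discovery":
            raise NetworkError(
                f"membrane {self.id!r}: only the pore_discovery resistance "
                f"model is implemented (got {self.model!r})"
            )


@dataclass
class Network:
    """A full chip description: graph plus pumps, fluids, species, schedules."""

    nodes: dict[str, Node] = field(default_factory=dict)
    channels: dict[str, Channel] = field(default_factory=dict)
    pumps: dict[str, Pump] = field(default_factory=dict)
    fluids: dict[str, Fluid] = field(default_factory=dict)
    species: dict[str, Species] = field(default_factory=dict)
    injections: list[Injection] = field(default_factory=list)
    droplets: list[DropletSpec] = field(default_factory=list)
    membranes: dict[str, MembraneSpec] = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------
    def add_node(self, id: str, *, ground: bool = False, sink: bool = False) -> Node:
        if id in self.nodes:
            raise NetworkError(f"duplicate node id {id!r}")
        n = Node(id, is_ground=ground, is_sink=sink)
        self.nodes[id] = n
        return n

    def add_channel(self, id: str, node_a: str, node_b: str,
                    width: float, height: float, length: float) -> Channel:
        if id in self.channels:
            raise NetworkError(f"duplicate channel id {id!r}")
        c = Channel(id, node_a, node_b, width, height, length)
        self.channels[id] = c
        return c

    def add_pump(self, id: str, node_from: str, node_to: str,
                 kind: str, value: float) -> Pump:
        if id in self.pumps:
            raise NetworkError(f"duplicate pump id {id!r}")
        p = Pump(id, node_from, node_to, kind, value)
        self.pumps[id] = p
        return p

    def add_fluid(self, id: str, viscosity: float, *, continuous_phase: bool = False) -> Fluid:
        if id in self.fluids:
            raise NetworkError(f"duplicate fluid id {id!r}")
        f = Fluid(id, viscosity, continuous_phase)
        self.fluids[id] = f
        return f

    def add_species(self, id: str, diffusion_coefficient: float) -> Species:
        if id in self.species:
            raise NetworkError(f"duplicate species id {id!r}")
        s = Species(id, diffusion_coefficient)
        self.species[id] = s
        return s

    # -- derived quantities ---------------------------------------------------
    @property
    def continuous_viscosity(self) -> float:
        """Viscosity of the designated continuous-phase (carrier) fluid."""
        carriers = [f for f in self.fluids.values() if f.continuous_phase]
        if len(carriers) == 1:
            return carriers[0].viscosity
        if not carriers and len(self.fluids) == 1:
            return next(iter(self.fluids.values())).viscosity
        raise NetworkError(
            "exactly one fluid must be marked continuous_phase "
            f"(found {len(carriers)} of {len(self.fluids)})"
        )

    def base_resistances(self) -> dict[str, float]:
        """Droplet-free hydraulic resistance of every channel."""
        mu = self.continuous_viscosity
        out = {}
        for cid, c in self.channels.items():
            r = c.resistance(mu)
            if r < MIN_RESISTANCE:
                raise NetworkError(f"channel {cid!r}: resistance below minimum")
            out[cid] = r
        return out

    def graph(self, include_pumps: bool = True) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for c in self.channels.values():
            g.add_edge(c.node_a, c.node_b, key=c.id)
        if include_pumps:
            for p in self.pumps.values():
                g.add_edge(p.node_from, p.node_to, key=p.id)
        return g

    def ground_node(self) -> str:
        grounds = [n.id for n in self.nodes.values() if n.is_ground]
        if len(grounds) == 1:
            return grounds[0]
        if not grounds:
            sinks = [n.id for n in self.nodes.values() if n.is_sink]
            if sinks:
                gid = sorted(sinks)[0]
                log.warning("no ground node marked; defaulting to sink %r", gid)
                return gid
        raise NetworkError(f"need exactly one ground node (found {len(grounds)})")

    def reference_nodes(self) -> set[str]:
        """Nodes pinned at the 0 Pa reference: the ground plus all open sinks."""
        refs = {n.id for n in self.nodes.values() if n.is_sink}
        refs.add(self.ground_node())
        return refs


def validate_network(net: Network) -> list[str]:
    """Return a list of human-readable violations; empty iff the network is well formed."""
    problems: list[str] = []
    for c in net.channels.values():
        for end, label in ((c.node_a, "node_a"), (c.node_b, "node_b")):
            if end not in net.nodes:
                problems.append(f"channel {c.id!r}: unknown {label} {end!r}")
        if c.height / c.width >= 1.0:
            problems.append(f"channel {c.id!r}: h/w >= 1 outside duct-law domain")
    for p in net.pumps.values():
        for end in (p.node_from, p.node_to):
            if end not in net.nodes:
                problems.append(f"pump {p.id!r}: unknown node {end!r}")
    if not net.pumps:
        problems.append("no source: the network has no pump")
    grounds = [n.id for n in net.nodes.values() if n.is_ground]
    if len(grounds) != 1:
        sinks = [n.id for n in net.nodes.values() if n.is_sink]
        if not (len(grounds) == 0 and sinks):
            problems.append(
                f"need exactly one ground node (found {len(grounds)}, "
                f"{len(sinks)} sinks to default to)"
            )
    if net.nodes:
        g = net.graph()
        if not nx.is_connected(g):
            comps = [sorted(c) for c in nx.connected_components(g)]
            problems.append(f"graph not connected: components {comps}")
    # id resolution for schedules
    for inj in net.injections:
        if inj.node not in net.nodes:
            problems.append(f"injection: unknown node {inj.node!r}")
        for sp in inj.species_concentrations:
            if sp not in net.species:
                problems.append(f"injection at {inj.node!r}: unknown species {sp!r}")
        # a boundary-inflow node must not also be a junction of incoming channels
        incoming = [c.id for c in net.channels.values()
                    if inj.node in (c.node_a, c.node_b)]
        pumped = any(p.node_to == inj.node or p.node_from == inj.node
                     for p in net.pumps.values())
        if not pumped:
            problems.append(
                f"injection at {inj.node!r}: node has no pump attached "
                f"(boundary mixtures enter through pumps)"
            )
        del incoming
    for d in net.droplets:
        if d.channel not in net.channels:
            problems.append(f"droplet {d.id!r}: unknown channel {d.channel!r}")
        elif d.length >= net.channels[d.channel].length:
            problems.append(
                f"droplet {d.id!r}: length {d.length:g} m does not fit "
                f"channel {d.channel!r} ({net.channels[d.channel].length:g} m)"
            )
    for m in net.membranes.values():
        if m.channel not in net.channels:
            problems.append(f"membrane {m.id!r}: unknown channel {m.channel!r}")
    if net.fluids:
        try:
            net.continuous_viscosity
        except NetworkError as e:
            problems.append(str(e))
    elif net.channels:
        problems.append("no fluid defined: channel resistance needs a viscosity")
    return problems

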