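"""Droplet routing on top of the base engine.

A droplet is a dispersed-phase plug that raises the hydraulic resistance of
the channel it occupies; in turn the flow field determines its speed and the
branch it takes at a junction (the path of least resistance, i.e. the branch
with the highest instantaneous flow rate). Resistance and motion are coupled
through the flow field: droplet speed in a channel equals Q / (w h), so a
droplet crosses a channel in exactly V / |Q|.

The resistance increment of one droplet of length l_d is

    R_droplet = b * a * mu_c * l_d / (w h^3)

with ``a`` the geometric prefactor of the rectangular-duct law, so that b
expresses the droplet as a multiple of the equivalent continuous-phase plug
(b usually between 2 and 5). A channel holding n droplets has
R* = R + sum of their increments. Droplet formation is not modelled; droplets
enter the network through a timed injection schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .network import Channel, Network, rectangular_prefactor
from .solver import FlowState

Q_EPS = 1e-18  # flows below this count as quiescent


class DropletError(ValueError):
    pass


def droplet_resistance(l_droplet: float, b: float, w: float, h: float,
                       mu_c: float, channel_length: Optional[float] = None) -> float:
    """Resistance increment [Pa*s/m^3] of one droplet in a rectangular channel."""
    if l_droplet <= 0 or b <= 0:
        raise DropletError("droplet length and resistance factor must be positive")
    if channel_length is not None and l_droplet >= channel_length:
        raise DropletError(
            f"droplet length {l_droplet:g} m >= channel length "
            f"{channel_length:g} m; junction-spanning droplets are unsupported"
        )
    return b * rectangular_prefactor(w, h) * mu_c * l_droplet / (w * h**3)


@dataclass
class DropletState:
    """Runtime state of one droplet.

    ``pos`` is the head (leading interface) as a fraction of channel length
    measured from node_a; the tail trails by length/channel_length along the
    flow direction. Resistance is booked to the single channel holding the
    droplet (atomic transfer at junctions).
    """

    id: str
    length: float
    b: float
    status: str = "scheduled"  # scheduled | in_channel | exited
    channel: Optional[str] = None
    pos: float = 0.0
    t_inject: float = 0.0
    path: list[str] = field(default_factory=list)

    def tail(self, channel: Channel, flow_sign: float) -> float:
        return self.pos - flow_sign * self.length / channel.length


def effective_resistance(channel: Channel, base: float,
                         droplets: Sequence[DropletState], mu_c: float) -> float:
    """R* = R + sum of resident droplet increments."""
    r = base
    for d in droplets:
        if d.status == "in_channel" and d.channel == channel.id:
            r += droplet_resistance(d.length, d.b, channel.width, channel.height,
                                    mu_c, channel.length)
    return r


def effective_resistances(net: Network, droplets: Sequence[DropletState],
                          base: Optional[dict[str, float]] = None) -> dict[str, float]:
    """Per-channel R* for the whole network."""
    if base is None:
        base = net.base_resistances()
    mu = net.continuous_viscosity
    out = dict(base)
    for d in droplets:
        if d.status == "in_channel" and d.channel is not None:
            c = net.channels[d.channel]
            out[c.id] += droplet_resistance(d.length, d.b, c.width, c.height,
                                            mu, c.length)
    return out


def outflow_channels(net: Network, node: str, flow_state: FlowState,
                     exclude: Optional[str] = None) -> list[tuple[str, float]]:
    """Channels carrying flow away from ``node``: (channel id, |Q|) pairs."""
    out = []
    for cid, c in net.channels.items():
        if cid == exclude:
            continue
        q = flow_state.channel_flows[cid]
        if c.node_a == node and q > Q_EPS:
            out.append((cid, q))
        elif c.node_b == node and q < -Q_EPS:
            out.append((cid, -q))
    return out


def select_branch(net: Network, node: str, flow_state: FlowState,
                  arriving_from: Optional[str] = None) -> str:
    """Branch a droplet takes at a junction: the outflow channel with the
    highest instantaneous volumetric flow rate; ties break by channel id."""
    cand = outflow_channels(net, node, flow_state, exclude=arriving_from)
    if not cand:
        raise DropletError(f"droplet reached dead end at node {node!r}")
    cand.sort(key=lambda t: (-t[1], t[0]))
    return cand[0][0]


def time_to_boundary(d: DropletState, net: Network, flow_state: FlowState) -> float:
    """Time until the droplet head reaches the downstream channel end at the
    current speed Q/(w h); +inf in a quiescent channel."""
    if d.status != "in_channel" or d.channel is None:
        return float("inf")
    c = net.channels[d.channel]
    q = flow_state.channel_flows[d.channel]
    if abs(q) <= Q_EPS:
        return float("inf")
    v = c.volume
    if q > 0:
        return (1.0 - d.pos) * v / q
    return d.pos * v / (-q)


def droplet_events(droplets: Sequence[DropletState], net: Network,
                   flow_state: FlowState) -> list[tuple[float, str]]:
    """(time-until-boundary, droplet id) for every moving droplet, earliest first;
    ties break by droplet id."""
    ev = [
        (time_to_boundary(d, net, flow_state), d.id)
        for d in droplets
        if d.status == "in_channel"
    ]
    ev = [e for e in ev if e[0] != float("inf")]
    ev.sort()
    return ev


def advance_droplets(droplets: Sequence[DropletState], net: Network,
                     flow_state: FlowState, dt: float) -> None:
    """Move every in-channel droplet by Q*dt/V along its channel (in place)."""
    for d in droplets:
        if d.status != "in_channel" or d.channel is None:
            continue
        c = net.channels[d.channel]
        q = flow_state.channel_flows[d.channel]
        d.pos += q * dt / c.volume
        if d.pos > 1.0 + 1e-9 or d.pos < -1e-9:
            raise DropletError(
                f"droplet {d.id!r} overshot channel {d.channel!r} "
                f"(pos={d.pos:.6g}); event scheduling bug"
            )
        d.pos = min(max(d.pos, 0.0), 1.0)


def transfer_droplet(d: DropletState, net: Network, flow_state: FlowState) -> None:
    """Move a droplet whose head reached a channel end into the next branch
    (atomically), or retire it at an open outlet."""
    if d.channel is None:
        raise DropletError(f"droplet {d.id!r} is not in a channel")
    c = net.channels[d.channel]
    q = flow_state.channel_flows[d.channel]
    node = c.node_b if q >= 0 else c.node_a
    try:
        nxt = select_branch(net, node, flow_state, arriving_from=d.channel)
    except DropletError:
        n = net.nodes[node]
        if n.is_sink or n.is_ground:
            d.status = "exited"
            d.channel = None
            return
        raise
    nc = net.channels[nxt]
    if d.length >= nc.length:
        raise DropletError(
            f"droplet {d.id!r} does not fit channel {nxt!r}"
        )
    d.channel = nxt
    # enter at the junction end of the new channel
    d.pos = 0.0 if nc.node_a == node else 1.0
    d.path.append(nxt)


def extract_paths(resultset) -> dict[str, list[str]]:
    """Ordered, adjacent-duplicate-free channel sequence per droplet."""
    paths: dict[str, list[str]] = {}
    for did, raw in resultset.droplet_paths.items():
        clean: list[str] = []
        for cid in raw:
            if not clean or clean[-1] != cid:
                clean.append(cid)
        paths[did] = clean
    return paths


def injection_times_from_distances(distances: Sequence[float], q_in: float,
                                   width: float, height: float,
                                   t0: float = 0.0) -> list[float]:
    """Translate droplet spacing distances d_i in the injection channel into
    injection times: t_i = t_{i-1} + d_i * w * h / Q_in.

    The first droplet is injected at ``t0``; each of the ``len(distances)``
    following droplets trails the previous one by its spacing. Returns one
    time per droplet (``len(distances) + 1`` entries).
    """
    if q_in <= 0:
        raise DropletError("injection flow rate must be positive")
    times = [t0]
    for d in distances:
        if d < 0:
            raise DropletError("droplet spacing must be non-negative")
        times.append(times[-1] + d * width * height / q_in)
    return times
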