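"""Programmatic test-network generators.

Desk-scale analogs of the canonical microfluidic applications: concentration
gradient-generator trees (mixing), droplet ring networks with a bypass
(droplet routing), and a channel + membrane + tank geometry (organ-on-chip
style species exchange), plus elementary series/parallel circuits. Every
generator returns a network that passes validation, so all modules can be
exercised with no external data.

Default dimensions are typical PDMS-chip values: channel widths and heights
of tens to hundreds of micrometres, lengths of millimetres, water as the
carrier (1 mPa*s), flow rates of nanolitres to microlitres per second.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .membranes import membrane_resistance
from .mixing import Mixture, steady_state_concentrations
from .network import Injection, DropletSpec, MembraneSpec, Network
from .solver import solve_flow

WATER = 1e-3  # Pa*s


@dataclass
class FixtureSpec:
    """Parameters of a generated fixture (recorded for reproducibility)."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: Optional[int] = None


def make_series_chain(n: int = 3, *, width: float = 1e-4, height: float = 5e-5,
                      lengths: Optional[Sequence[float]] = None,
                      q_in: float = 1e-9) -> Network:
    """A single path of n channels driven by one flow-rate pump."""
    if n < 1:
        raise ValueError("need at least one channel")
    lengths = list(lengths) if lengths is not None else [1e-3] * n
    net = Network()
    net.add_fluid("water", WATER, continuous_phase=True)
    net.add_node("inlet")
    for i in range(1, n):
        net.add_node(f"n{i}")
    net.add_node("outlet", ground=True, sink=True)
    names = ["inlet"] + [f"n{i}" for i in range(1, n)] + ["outlet"]
    for i in range(n):
        net.add_channel(f"c{i + 1}", names[i], names[i + 1], width, height, lengths[i])
    net.add_pump("p1", "outlet", "inlet", "flow_rate", q_in)
    return net


def make_parallel_pair(*, width: float = 1e-4, height: float = 5e-5,
                       lengths: tuple[float, float] = (1e-3, 1e-3),
                       q_in: float = 1e-9) -> Network:
    """Two channels in parallel between an inlet and a grounded outlet."""
    net = Network()
    net.add_fluid("water", WATER, continuous_phase=True)
    net.add_node("inlet")
    net.add_node("outlet", ground=True, sink=True)
    net.add_channel("c1", "inlet", "outlet", width, height, lengths[0])
    net.add_channel("c2", "inlet", "outlet", width, height, lengths[1])
    net.add_pump("p1", "outlet", "inlet", "flow_rate", q_in)
    return net


def make_y_junction(*, q_a: float = 1e-9, q_b: float = 1e-9,
                    c_a: float = 1.0, c_b: float = 0.0,
                    species: str = "dye") -> Network:
    """Two inlet channels merging into one outlet channel.

    Inlet A carries concentration ``c_a`` and inlet B ``c_b`` of the tracer
    species; with equal pump rates the junction produces a 50/50 blend.
    """
    net = Network()
    net.add_fluid("water", WATER, continuous_phase=True)
    net.add_species(species, 1e-9)
    net.add_node("in_a")
    net.add_node("in_b")
    net.add_node("junction")
    net.add_node("outlet", ground=True, sink=True)
    net.add_channel("ca", "in_a", "junction", 1e-4, 5e-5, 1e-3)
    net.add_channel("cb", "in_b", "junction", 1e-4, 5e-5, 1e-3)
    net.add_channel("cout", "junction", "outlet", 1e-4, 5e-5, 2e-3)
    net.add_pump("pa", "outlet", "in_a", "flow_rate", q_a)
    net.add_pump("pb", "outlet", "in_b", "flow_rate", q_b)
    net.injections.append(Injection("in_a", {species: c_a}))
    net.injections.append(Injection("in_b", {species: c_b}))
    return net


def make_gradient_tree(
    n_outlets: int = 5,
    seed: Optional[int] = None,
    *,
    stage_length_range: tuple[float, float] = (0.5e-3, 2e-3),
    q_in: float = 1e-9,
    species: str = "dye",
) -> tuple[Network, dict[str, float], float]:
    """Splitter/combiner (diamond) gradient-generator tree with two inlets.

    Row k (k = 2 .. n_outlets) holds k nodes; node j of row k feeds nodes j
    and j+1 of row k+1 through two channels. Row 2 is the two inlets, fed
    with tracer concentrations 1 and 0; row n ends in one outlet channel per
    node. ``seed`` randomises the per-stage channel lengths (and thereby the
    stage resistances and mixing ratios) within ``stage_length_range``.

    Returns ``(network, predicted outlet concentration per sink node,
    settle_time)`` where the prediction is the closed-form flow-rate-weighted
    mixing cascade through the solved flow field and ``settle_time`` bounds
    the transient flush (the longest cumulative transit along any path).
    """
    if n_outlets < 2:
        raise ValueError("a gradient tree needs at least two outlets")
    rng = random.Random(seed)
    # randomized lengths can occasionally reverse a channel near the outlet
    # rows, where the closed-form cascade no longer applies; re-draw (bounded,
    # deterministic per seed) until the field is strictly feed-forward
    for _ in range(50):
        try:
            return _build_gradient_tree(n_outlets, rng if seed is not None else None,
                                        stage_length_range, q_in, species)
        except _NonFeedForward:
            if seed is None:
                raise RuntimeError("gradient tree: non-downstream flow")
    raise RuntimeError("gradient tree: could not draw a feed-forward variant")


class _NonFeedForward(Exception):
    pass


def _build_gradient_tree(
    n_outlets: int,
    rng: Optional[random.Random],
    stage_length_range: tuple[float, float],
    q_in: float,
    species: str,
) -> tuple[Network, dict[str, float], float]:
    def length() -> float:
        if rng is None:
            return 1e-3
        lo, hi = stage_length_range
        return rng.uniform(lo, hi)

    net = Network()
    net.add_fluid("water", WATER, continuous_phase=True)
    net.add_species(species, 1e-9)
    w, h = 1e-4, 5e-5
    for k in range(2, n_outlets + 1):
        for j in range(k):
            net.add_node(f"r{k}_{j}")
    for j in range(n_outlets):
        net.add_node(f"out{j}", ground=(j == 0), sink=True)
    for k in range(2, n_outlets):
        for j in range(k):
            net.add_channel(f"s{k}_{j}L", f"r{k}_{j}", f"r{k + 1}_{j}", w, h, length())
            net.add_channel(f"s{k}_{j}R", f"r{k}_{j}", f"r{k + 1}_{j + 1}", w, h, length())
    for j in range(n_outlets):
        net.add_channel(f"o{j}", f"r{n_outlets}_{j}", f"out{j}", w, h, length())
    net.add_pump("pa", "out0", "r2_0", "flow_rate", q_in)
    net.add_pump("pb", "out0", "r2_1", "flow_rate", q_in)
    net.injections.append(Injection("r2_0", {species: 1.0}))
    net.injections.append(Injection("r2_1", {species: 0.0}))

    flow = solve_flow(net)
    for cid, q in flow.channel_flows.items():
        if q <= 0:
            raise _NonFeedForward(cid)
    boundary = {"r2_0": Mixture.of({species: 1.0}), "r2_1": Mixture.of({species: 0.0})}
    cascade = steady_state_concentrations(net, flow, boundary)
    predictions = {f"out{j}": cascade[f"out{j}"].get(species) for j in range(n_outlets)}

    # longest cumulative transit from an inlet to any outlet
    settle: dict[str, float] = {"r2_0": 0.0, "r2_1": 0.0}
    for k in range(2, n_outlets + 1):
        for j in range(k):
            node = f"r{k}_{j}" if k < n_outlets else f"r{n_outlets}_{j}"
            settle.setdefault(node, 0.0)
    order = [f"r{k}_{j}" for k in range(2, n_outlets + 1) for j in range(k)]
    order += [f"out{j}" for j in range(n_outlets)]
    for node in order:
        best = settle.get(node, 0.0)
        for cid, c in net.channels.items():
            if c.node_b == node:
                up = settle.get(c.node_a, 0.0)
                best = max(best, up + c.volume / flow.channel_flows[cid])
        settle[node] = best
    settle_time = max(settle[f"out{j}"] for j in range(n_outlets))
    return net, predictions, settle_time


def make_ring_network(
    n_modules: int = 1,
    *,
    width: float = 1e-4,
    height: float = 5e-5,
    bypass_length: float = 1e-3,
    module_length: float = 3e-3,
    q_in: float = 1e-9,
    droplet_specs: Optional[Sequence[DropletSpec]] = None,
) -> Network:
    """Ring network(s) with a module branch and a shorter bypass branch.

    Each ring splits at a junction into a long "module" channel and a short
    bypass; a droplet-free solve sends more flow through the bypass, so a
    lone payload droplet takes it. A header droplet parked in the bypass
    raises its resistance enough to flip the payload onto the module branch
    (the module/bypass length ratio of 3 exceeds the usual droplet b range,
    so a single header with b >= 2.5 and a length of a few channel widths
    suffices).
    """
    if n_modules < 1:
        raise ValueError("need at least one ring")
    net = Network()
    net.add_fluid("oil", WATER, continuous_phase=True)
    net.add_node("inlet")
    for i in range(n_modules):
        net.add_node(f"j{i}")
        net.add_node(f"k{i}")
    net.add_node("outlet", ground=True, sink=True)
    net.add_channel("c_in", "inlet", "j0", width, height, 2e-3)
    for i in range(n_modules):
        net.add_channel(f"bypass{i}", f"j{i}", f"k{i}", width, height, bypass_length)
        net.add_channel(f"module{i}", f"j{i}", f"k{i}", width, height, module_length)
        nxt = f"j{i + 1}" if i + 1 < n_modules else "outlet"
        net.add_channel(f"link{i}", f"k{i}", nxt, width, height, 2e-3)
    net.add_pump("p_in", "outlet", "inlet", "flow_rate", q_in)
    if droplet_specs is not None:
        net.droplets.extend(droplet_specs)
    return net


def make_membrane_channel(
    *,
    width: float = 1e-4,
    height: float = 5e-5,
    length: float = 2e-2,
    area: float = 1e-8,
    pore_radius: float = 1e-7,
    porosity: float = 1e-4,
    thickness: float = 1e-5,
    tank_volume: float = 1e-12,
    q_in: float = 1e-9,
    c_in: float = 1.0,
    species: str = "drug",
    diffusion: float = 1e-9,
) -> tuple[Network, dict[str, float]]:
    """Single channel with a constant-concentration inlet and one membrane-backed
    tank.

    The defaults put the run in the constant-channel-concentration regime
    (the channel flushes much faster than it is depleted through the
    membrane: Q * R_M >> 1), so the tank concentration follows the analytic
    relaxation C_t(t) = C_in (1 - exp(-t / (V_t R_M))) from an empty start.

    Returns ``(network, info)`` with ``info`` holding the per-species
    membrane resistance ``R_M``, the tank time constant ``tau = V_t * R_M``
    and the channel transit time.
    """
    net = Network()
    net.add_fluid("medium", WATER, continuous_phase=True)
    net.add_species(species, diffusion)
    net.add_node("inlet")
    net.add_node("outlet", ground=True, sink=True)
    net.add_channel("c1", "inlet", "outlet", width, height, length)
    net.add_pump("p1", "outlet", "inlet", "flow_rate", q_in)
    net.injections.append(Injection("inlet", {species: c_in}))
    spec = MembraneSpec("m1", "c1", area, pore_radius, porosity,
                        thickness, tank_volume)
    net.membranes["m1"] = spec
    r_m = membrane_resistance(spec, diffusion)
    info = {
        "R_M": r_m,
        "tau": tank_volume * r_m,
        "transit": net.channels["c1"].volume / q_in,
        "c_in": c_in,
    }
    return net, info
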