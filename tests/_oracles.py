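"""Independent reference implementations used only by the test suite.

Everything here is deliberately written from first principles — full-graph
Laplacian least-style assembly, Kahn topological sort, a naive event
enumerator — so the package under test is checked against separately coded
physics rather than against itself.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np


# -- dense circuit solve -------------------------------------------------------

def oracle_solve(net, resistances):
    """Node pressures and channel flows by dense full-Laplacian assembly.

    Unknowns: every node pressure plus one flow per pressure pump; reference
    nodes (ground + sinks) are pinned with explicit P = 0 rows.
    """
    nodes = sorted(net.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    refs = sorted(net.reference_nodes())
    ppumps = sorted(p.id for p in net.pumps.values() if p.kind == "pressure")
    n, k = len(nodes), len(ppumps)
    A = np.zeros((n + k, n + k))
    b = np.zeros(n + k)
    # KCL rows for every node (reference rows overwritten below)
    for c in net.channels.values():
        g = 1.0 / resistances[c.id]
        ia, ib = idx[c.node_a], idx[c.node_b]
        A[ia, ia] += g
        A[ia, ib] -= g
        A[ib, ib] += g
        A[ib, ia] -= g
    for p in net.pumps.values():
        if p.kind == "flow_rate":
            b[idx[p.node_from]] -= p.value
            b[idx[p.node_to]] += p.value
        else:
            j = n + ppumps.index(p.id)
            A[idx[p.node_from], j] += 1.0
            A[idx[p.node_to], j] -= 1.0
            A[j, idx[p.node_to]] = 1.0
            A[j, idx[p.node_from]] = -1.0
            b[j] = p.value
    for r in refs:
        i = idx[r]
        A[i, :] = 0.0
        A[i, i] = 1.0
        b[i] = 0.0
    x = np.linalg.solve(A, b)
    pressures = {nid: float(x[idx[nid]]) for nid in nodes}
    flows = {
        c.id: (pressures[c.node_a] - pressures[c.node_b]) / resistances[c.id]
        for c in net.channels.values()
    }
    pump_flows = {}
    for p in net.pumps.values():
        pump_flows[p.id] = (p.value if p.kind == "flow_rate"
                            else float(x[n + ppumps.index(p.id)]))
    return pressures, flows, pump_flows


# -- steady-state mixing cascade ----------------------------------------------

def oracle_cascade(net, flows, pump_flows, boundary, q_eps=1e-18):
    """Steady node concentrations by Kahn topological order over the
    flow-directed graph; plain weighted means, no package code."""
    succ: dict[str, list[tuple[str, float]]] = {n: [] for n in net.nodes}
    indeg = {n: 0 for n in net.nodes}
    incoming: dict[str, list[tuple[str, float]]] = {n: [] for n in net.nodes}
    for c in net.channels.values():
        q = flows[c.id]
        if q > q_eps:
            up, dn = c.node_a, c.node_b
        elif q < -q_eps:
            up, dn = c.node_b, c.node_a
            q = -q
        else:
            continue
        succ[up].append((dn, q))
        incoming[dn].append((up, q))
        indeg[dn] += 1
    conc: dict[str, dict[str, float]] = {}
    ready = [n for n in sorted(net.nodes) if indeg[n] == 0]
    seen = 0
    while ready:
        node = ready.pop()
        seen += 1
        pairs = []
        for up, q in incoming[node]:
            pairs.append((q, conc[up]))
        for p in net.pumps.values():
            qp = pump_flows[p.id]
            if (p.node_to == node and qp > q_eps) or (p.node_from == node and qp < -q_eps):
                pairs.append((abs(qp), boundary.get(node, {})))
        if pairs:
            qt = sum(q for q, _ in pairs)
            species = set()
            for _, m in pairs:
                species |= set(m)
            conc[node] = {sp: sum(q * m.get(sp, 0.0) for q, m in pairs) / qt
                          for sp in species}
        else:
            conc[node] = dict(boundary.get(node, {}))
        for dn, _ in succ[node]:
            indeg[dn] -= 1
            if indeg[dn] == 0:
                ready.append(dn)
    assert seen == len(net.nodes), "flow graph has a cycle"
    return conc


# -- brute-force droplet event enumerator ---------------------------------------

def _duct_prefactor(w, h):
    return 12.0 / (1.0 - (192.0 * h / (math.pi**5 * w)) * math.tanh(math.pi * w / (2.0 * h)))


@dataclass
class _Drop:
    id: str
    length: float
    b: float
    channel: str | None = None
    pos: float = 0.0
    status: str = "scheduled"
    t_inject: float = 0.0
    path: list = field(default_factory=list)


def oracle_droplet_run(net, q_eps=1e-18, t_cap=1e6, max_events=10_000):
    """Exhaustively enumerate droplet events, re-solving the dense circuit
    after every single candidate event.

    Returns (event list [(kind, droplet id, time)], paths per droplet).
    Model semantics: droplet head moves at Q/(w h); at a junction it enters
    the outflow channel with the highest flow (ties by channel id); its
    resistance increment b * a * mu * l_d / (w h^3) is booked to the channel
    holding it; it exits the network at sink/ground nodes.
    """
    mu = net.continuous_viscosity
    base = {}
    for c in net.channels.values():
        base[c.id] = _duct_prefactor(c.width, c.height) * mu * c.length / (c.width * c.height**3)
    drops = [
        _Drop(s.id, s.length, s.b, t_inject=s.t_inject)
        for s in sorted(net.droplets, key=lambda s: (s.t_inject, s.id))
    ]
    spec_channel = {s.id: s.channel for s in net.droplets}
    events = []
    t = 0.0
    for _ in range(max_events):
        if all(d.status == "exited" for d in drops):
            break
        resist = dict(base)
        for d in drops:
            if d.status == "in_channel":
                c = net.channels[d.channel]
                resist[d.channel] += d.b * _duct_prefactor(c.width, c.height) * mu * d.length / (c.width * c.height**3)
        _, flows, _ = oracle_solve(net, resist)

        # due actions at the current instant, one at a time
        acted = False
        for d in drops:  # already ordered by (t_inject, id)
            if d.status == "scheduled" and d.t_inject <= t + 1e-12:
                cid = spec_channel[d.id]
                q = flows[cid]
                d.status, d.channel = "in_channel", cid
                d.pos = 0.0 if q >= 0 else 1.0
                d.path = [cid]
                events.append(("injection", d.id, t))
                acted = True
                break
        if acted:
            continue
        for d in sorted(drops, key=lambda d: d.id):
            if d.status != "in_channel":
                continue
            q = flows[d.channel]
            at_end = (q > q_eps and d.pos >= 1 - 1e-9) or (q < -q_eps and d.pos <= 1e-9)
            if not at_end:
                continue
            c = net.channels[d.channel]
            node = c.node_b if q >= 0 else c.node_a
            cand = []
            for c2 in net.channels.values():
                if c2.id == d.channel:
                    continue
                q2 = flows[c2.id]
                if c2.node_a == node and q2 > q_eps:
                    cand.append((-q2, c2.id))
                elif c2.node_b == node and q2 < -q_eps:
                    cand.append((q2, c2.id))
            if cand:
                cand.sort()
                nxt = cand[0][1]
                c2 = net.channels[nxt]
                d.channel = nxt
                d.pos = 0.0 if c2.node_a == node else 1.0
                d.path.append(nxt)
            else:
                d.status, d.channel = "exited", None
            events.append(("droplet_boundary", d.id, t))
            acted = True
            break
        if acted:
            continue

        # next candidate event time
        dt = math.inf
        for d in drops:
            if d.status == "scheduled":
                dt = min(dt, d.t_inject - t)
            elif d.status == "in_channel":
                c = net.channels[d.channel]
                q = flows[d.channel]
                if abs(q) > q_eps:
                    v = c.width * c.height * c.length
                    dt = min(dt, (1 - d.pos) * v / q if q > 0 else d.pos * v / (-q))
        if not math.isfinite(dt) or t + dt > t_cap:
            break
        for d in drops:
            if d.status == "in_channel":
                c = net.channels[d.channel]
                q = flows[d.channel]
                v = c.width * c.height * c.length
                d.pos = min(max(d.pos + q * dt / v, 0.0), 1.0)
        t += dt
    return events, {d.id: d.path for d in drops}


# -- random network generator ------------------------------------------------------

def random_network(rng: random.Random, max_nodes: int = 12):
    """Random connected resistor network with 1-2 flow pumps and possibly a
    pressure pump; node n0 is the grounded sink."""
    from chipflow import Network

    n = rng.randint(2, max_nodes)
    net = Network()
    net.add_fluid("water", 1e-3, continuous_phase=True)
    net.add_node("n0", ground=True, sink=True)
    for i in range(1, n):
        net.add_node(f"n{i}")
    cid = 0

    def add_channel(a, b):
        nonlocal cid
        w = rng.uniform(5e-5, 2e-4)
        h = w * rng.uniform(0.2, 0.8)
        l = rng.uniform(5e-4, 5e-3)
        net.add_channel(f"c{cid}", a, b, w, h, l)
        cid += 1

    for i in range(1, n):  # random spanning tree
        add_channel(f"n{rng.randint(0, i - 1)}", f"n{i}")
    for _ in range(rng.randint(0, n)):  # extra edges
        a, b = rng.sample(range(n), 2)
        add_channel(f"n{a}", f"n{b}")
    net.add_pump("p0", "n0", f"n{rng.randint(1, n - 1)}", "flow_rate",
                 rng.uniform(0.1, 5) * 1e-9)
    if n > 2 and rng.random() < 0.5:
        net.add_pump("p1", "n0", f"n{rng.randint(1, n - 1)}", "flow_rate",
                     rng.uniform(0.1, 5) * 1e-9)
    if n > 3 and rng.random() < 0.4:
        a, b = rng.sample(range(1, n), 2)
        net.add_pump("pp", f"n{a}", f"n{b}", "pressure", rng.uniform(1, 100))
    return net
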