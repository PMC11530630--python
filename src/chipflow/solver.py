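"""Instantaneous hydraulic circuit solve by Modified Nodal Analysis (MNA).

Unknowns are the pressures of all non-reference nodes plus one flow unknown
per pressure pump. Equations are mass conservation (Kirchhoff current law) at
every non-reference node plus the pressure constraint of each pressure pump.
Flow-rate pumps enter the right-hand side as fixed injections. The ground
node and all open sinks sit at the 0 Pa reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import networkx as nx
import numpy as np

from .network import MIN_RESISTANCE, Network, NetworkError


class SingularNetworkError(NetworkError):
    """The MNA system is singular, e.g. a subnetwork floats without a reference."""


@dataclass
class FlowState:
    """Solved snapshot of the hydraulic circuit at one instant."""

    time: float
    node_pressures: dict[str, float]
    channel_flows: dict[str, float]  # signed, positive node_a -> node_b
    pump_flows: dict[str, float]  # signed, positive node_from -> node_to
    effective_resistances: dict[str, float] = field(default_factory=dict)

    def conservation_residuals(self, net: Network) -> dict[str, float]:
        """Signed net inflow per node, normalised by the largest local flow."""
        inflow: dict[str, float] = {n: 0.0 for n in net.nodes}
        scale: dict[str, float] = {n: 0.0 for n in net.nodes}
        for cid, q in self.channel_flows.items():
            c = net.channels[cid]
            inflow[c.node_a] -= q
            inflow[c.node_b] += q
            scale[c.node_a] = max(scale[c.node_a], abs(q))
            scale[c.node_b] = max(scale[c.node_b], abs(q))
        for pid, q in self.pump_flows.items():
            p = net.pumps[pid]
            inflow[p.node_from] -= q
            inflow[p.node_to] += q
            scale[p.node_from] = max(scale[p.node_from], abs(q))
            scale[p.node_to] = max(scale[p.node_to], abs(q))
        refs = net.reference_nodes()
        # quiescent dead-end branches carry only roundoff-level flow; judge
        # them against the network-wide scale rather than their own noise
        global_scale = max(list(scale.values()) + [0.0])
        out = {}
        for n in net.nodes:
            if n in refs:
                continue
            denom = max(scale[n], global_scale)
            out[n] = inflow[n] / denom if denom > 0 else inflow[n]
        return out


@dataclass
class MNASystem:
    """Assembled linear system A x = b with labelled unknowns."""

    matrix: np.ndarray
    rhs: np.ndarray
    pressure_index: dict[str, int]  # node id -> column
    pump_index: dict[str, int]  # pressure pump id -> column
    reference: set[str]


def _check_referenced(net: Network) -> None:
    g = net.graph()
    refs = net.reference_nodes()
    for comp in nx.connected_components(g):
        if not comp & refs:
            raise SingularNetworkError(
                f"floating subnetwork without pressure reference: {sorted(comp)}"
            )


def assemble_system(
    net: Network,
    effective_resistances: Mapping[str, float],
) -> MNASystem:
    """Build the MNA matrix for the given per-channel effective resistances."""
    _check_referenced(net)
    refs = net.reference_nodes()
    free = sorted(n for n in net.nodes if n not in refs)
    p_idx = {n: i for i, n in enumerate(free)}
    ppumps = sorted(p.id for p in net.pumps.values() if p.kind == "pressure")
    q_idx = {pid: len(free) + i for i, pid in enumerate(ppumps)}
    n = len(free) + len(ppumps)
    A = np.zeros((n, n))
    b = np.zeros(n)

    for cid, c in net.channels.items():
        r = max(effective_resistances[cid], MIN_RESISTANCE)
        g = 1.0 / r
        ia = p_idx.get(c.node_a)
        ib = p_idx.get(c.node_b)
        if ia is not None:
            A[ia, ia] += g
            if ib is not None:
                A[ia, ib] -= g
        if ib is not None:
            A[ib, ib] += g
            if ia is not None:
                A[ib, ia] -= g

    for p in net.pumps.values():
        i_from = p_idx.get(p.node_from)
        i_to = p_idx.get(p.node_to)
        if p.kind == "flow_rate":
            if i_from is not None:
                b[i_from] -= p.value
            if i_to is not None:
                b[i_to] += p.value
        else:  # pressure pump: unknown flow + constraint P_to - P_from = value
            j = q_idx[p.id]
            if i_from is not None:
                A[i_from, j] += 1.0  # flow q leaves node_from
                A[j, i_from] -= 1.0
            if i_to is not None:
                A[i_to, j] -= 1.0  # flow q enters node_to
                A[j, i_to] += 1.0
            b[j] = p.value

    return MNASystem(A, b, p_idx, q_idx, refs)


def solve_flow(
    net: Network,
    effective_resistances: Optional[Mapping[str, float]] = None,
    time: float = 0.0,
) -> FlowState:
    """Solve node pressures and channel/pump flow rates.

    ``effective_resistances`` defaults to the droplet-free base resistances;
    the droplet module passes augmented values R* = R + sum(R_droplet).
    """
    if effective_resistances is None:
        effective_resistances = net.base_resistances()
    sys = assemble_system(net, effective_resistances)
    if sys.matrix.size:
        try:
            x = np.linalg.solve(sys.matrix, sys.rhs)
        except np.linalg.LinAlgError as e:
            raise SingularNetworkError(f"singular MNA system: {e}") from e
    else:
        x = np.empty(0)

    pressures = {n: 0.0 for n in net.nodes}
    for node, i in sys.pressure_index.items():
        pressures[node] = float(x[i])

    flows = {}
    for cid, c in net.channels.items():
        r = max(effective_resistances[cid], MIN_RESISTANCE)
        flows[cid] = (pressures[c.node_a] - pressures[c.node_b]) / r

    pump_flows = {}
    for p in net.pumps.values():
        if p.kind == "flow_rate":
            pump_flows[p.id] = p.value
        else:
            pump_flows[p.id] = float(x[sys.pump_index[p.id]])

    return FlowState(
        time=time,
        node_pressures=pressures,
        channel_flows=flows,
        pump_flows=pump_flows,
        effective_resistances=dict(effective_resistances),
    )


def equivalent_resistance(net: Network, port_a: str, port_b: str) -> float:
    """Two-terminal hydraulic resistance dP/Q seen between two nodes.

    Measured by driving a unit probe flow into ``port_a`` and out of
    ``port_b`` on a pump-free copy of the network with ``port_b`` as the
    only reference.
    """
    if port_a not in net.nodes or port_b not in net.nodes:
        raise NetworkError("unknown port node")
    probe = Network(
        nodes={
            n: type(net.nodes[n])(n, is_ground=(n == port_b), is_sink=False)
            for n in net.nodes
        },
        channels=dict(net.channels),
        fluids=dict(net.fluids),
        species=dict(net.species),
    )
    probe.add_pump("__probe__", port_b, port_a, "flow_rate", 1.0)
    if not nx.has_path(probe.graph(include_pumps=False), port_a, port_b):
        raise SingularNetworkError(f"ports {port_a!r} and {port_b!r} are disconnected")
    state = solve_flow(probe, net.base_resistances())
    return state.node_pressures[port_a] - state.node_pressures[port_b]
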