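"""Event-driven simulation engine.

The engine alternates instantaneous circuit solves with discrete events.
Between events the flow field is constant, so material transport is exact
plug-flow advection: every slug and droplet interface in a channel moves
downstream by the fraction |Q| dt / V of the channel length. Events are the
instants at which the piecewise description changes:

  * a slug interface or droplet head reaches a channel end,
  * a scheduled injection starts or stops,
  * a configured fixed time step elapses,
  * the simulation horizon is reached.

The step to the next event is the minimum of all pending candidates; in the
droplet-free base module the characteristic step is the shortest channel
transit time t = V_channel / Q_channel. After every event the circuit is
re-solved (solves are memoised on the resistance pattern, so events that do
not change any resistance are free).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import droplets as dropmod
from . import membranes as memmod
from .mixing import (
    Mixture,
    Slug,
    full_channel,
    mix_at_node,
    propagate_slugs,
    slug_partition_ok,
)
from .network import Network, NetworkError, validate_network
from .solver import FlowState, solve_flow

log = logging.getLogger(__name__)

#: flows with magnitude below this are treated as quiescent
Q_EPS = 1e-18
#: events closer than this in time are merged and processed together
T_MERGE = 1e-12


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Run settings.

    ``modules`` defaults to whatever the network description implies:
    mixing when injections or species are present, droplets when a droplet
    schedule exists, membranes when membranes are attached (membranes imply
    mixing).
    """

    max_time: float = 1.0
    fixed_step: Optional[float] = None
    modules: Optional[set[str]] = None
    max_events: int = 500_000
    q_eps: float = Q_EPS
    terminate_on_droplet_exit: bool = True
    record: str = "events"  # "events" | "final"

    def __post_init__(self) -> None:
        if self.max_time <= 0:
            raise ValueError("max_time must be positive")
        if self.fixed_step is not None and self.fixed_step <= 0:
            raise ValueError("fixed_step must be positive")
        if self.modules is not None:
            unknown = set(self.modules) - {"mixing", "droplets", "membranes"}
            if unknown:
                raise ValueError(f"unknown modules {sorted(unknown)}")

    def resolve_modules(self, net: Network) -> set[str]:
        if self.modules is not None:
            mods = set(self.modules)
        else:
            mods = set()
            if net.injections or net.species:
                mods.add("mixing")
            if net.droplets:
                mods.add("droplets")
            if net.membranes:
                mods.add("membranes")
        if "membranes" in mods:
            mods.add("mixing")  # membranes build on mixture transport
        return mods


@dataclass(frozen=True)
class Event:
    """A scheduled incident requiring special treatment."""

    time: float
    kind: str  # fixed_step | channel_transit | droplet_boundary | injection | termination
    payload: Optional[str] = None


@dataclass
class Record:
    """One conservation-checked snapshot of the simulation state."""

    time: float
    node_pressures: dict[str, float]
    channel_flows: dict[str, float]
    node_mixtures: dict[str, Mixture]
    tank_concentrations: dict[str, dict[str, float]]
    droplet_positions: dict[str, tuple[Optional[str], float]]


@dataclass
class ResultSet:
    """Everything a run produces: time series, final state, droplet paths."""

    network: Network
    config: SimulationConfig
    records: list[Record] = field(default_factory=list)
    event_log: list[Event] = field(default_factory=list)
    droplet_paths: dict[str, list[str]] = field(default_factory=dict)
    final_flow: Optional[FlowState] = None
    final_slugs: dict[str, list[Slug]] = field(default_factory=dict)
    final_tanks: dict[str, memmod.TankState] = field(default_factory=dict)
    event_count: int = 0

    @property
    def times(self) -> list[float]:
        return [r.time for r in self.records]

    def sample(self, times: Sequence[float]) -> list[Record]:
        """Linearly interpolated snapshots at arbitrary output times,
        decoupling the output cadence from the event clustering."""
        out = []
        recs = self.records
        if not recs:
            return out
        j = 0
        for t in times:
            while j + 1 < len(recs) and recs[j + 1].time <= t:
                j += 1
            if j + 1 >= len(recs) or recs[j].time >= t:
                src = recs[min(j, len(recs) - 1)]
                out.append(Record(t, dict(src.node_pressures), dict(src.channel_flows),
                                  dict(src.node_mixtures),
                                  {k: dict(v) for k, v in src.tank_concentrations.items()},
                                  dict(src.droplet_positions)))
                continue
            lo, hi = recs[j], recs[j + 1]
            w = (t - lo.time) / (hi.time - lo.time)

            def lerp(a: dict, b: dict) -> dict:
                return {k: (1 - w) * a[k] + w * b.get(k, a[k]) for k in a}

            out.append(Record(
                t,
                lerp(lo.node_pressures, hi.node_pressures),
                lerp(lo.channel_flows, hi.channel_flows),
                dict(lo.node_mixtures),  # compositions are piecewise constant
                {k: lerp(v, hi.tank_concentrations.get(k, v))
                 for k, v in lo.tank_concentrations.items()},
                dict(lo.droplet_positions),
            ))
        return out


def min_transit_time(flow_state: FlowState, net: Network,
                     q_eps: float = Q_EPS) -> float:
    """Shortest channel transit time t = V_channel / Q_channel over all
    channels carrying flow; +inf for a quiescent network."""
    best = math.inf
    for cid, c in net.channels.items():
        q = abs(flow_state.channel_flows[cid])
        if q > q_eps:
            best = min(best, c.volume / q)
    return best


class _Engine:
    def __init__(self, net: Network, config: SimulationConfig):
        problems = validate_network(net)
        if problems:
            raise NetworkError("invalid network: " + "; ".join(problems))
        self.net = net
        self.config = config
        self.modules = config.resolve_modules(net)
        self.t = 0.0
        self.base_r = net.base_resistances()
        self.slugs: dict[str, list[Slug]] = {
            cid: full_channel() for cid in net.channels
        }
        self.droplets: dict[str, dropmod.DropletState] = {}
        if "droplets" in self.modules:
            for spec in net.droplets:
                self.droplets[spec.id] = dropmod.DropletState(
                    id=spec.id, length=spec.length, b=spec.b,
                    t_inject=spec.t_inject,
                )
        self.membranes: dict[str, memmod.MembraneRuntime] = {}
        if "membranes" in self.modules:
            for mid, spec in net.membranes.items():
                self.membranes[mid] = memmod.MembraneRuntime.create(net, spec)
        self.result = ResultSet(network=net, config=config)
        self._next_fixed = config.fixed_step
        self._flow_cache: tuple[Optional[tuple], Optional[FlowState]] = (None, None)

    # -- flow ----------------------------------------------------------------
    def _solve(self) -> FlowState:
        resist = dropmod.effective_resistances(
            self.net, list(self.droplets.values()), self.base_r,
        ) if self.droplets else dict(self.base_r)
        key = tuple(sorted(resist.items()))
        cached_key, cached = self._flow_cache
        if cached_key == key and cached is not None:
            cached.time = self.t
            return cached
        state = solve_flow(self.net, resist, time=self.t)
        residuals = state.conservation_residuals(self.net)
        worst = max((abs(v) for v in residuals.values()), default=0.0)
        if worst > 1e-6:
            raise SimulationError(f"mass conservation violated: residual {worst:g}")
        self._flow_cache = (key, state)
        return state

    # -- boundary mixtures -----------------------------------------------------
    def _boundary_mixture(self, node: str) -> Mixture:
        active = [inj for inj in self.net.injections
                  if inj.node == node and inj.active(self.t)]
        if not active:
            return Mixture()
        latest = max(active, key=lambda i: i.t_start)
        return Mixture.of(latest.species_concentrations)

    def _node_mixtures(self, flow: FlowState) -> dict[str, Mixture]:
        """Instantaneously mixed outflow composition at every node."""
        inflows: dict[str, list[tuple[float, Mixture]]] = {n: [] for n in self.net.nodes}
        for cid, c in self.net.channels.items():
            q = flow.channel_flows[cid]
            if q > self.config.q_eps:
                inflows[c.node_b].append((q, self.slugs[cid][-1].mixture))
            elif q < -self.config.q_eps:
                inflows[c.node_a].append((-q, self.slugs[cid][0].mixture))
        for pid, p in self.net.pumps.items():
            q = flow.pump_flows[pid]
            if q > self.config.q_eps:
                inflows[p.node_to].append((q, self._boundary_mixture(p.node_to)))
            elif q < -self.config.q_eps:
                inflows[p.node_from].append((-q, self._boundary_mixture(p.node_from)))
        return {
            n: mix_at_node(fl) if fl else self._boundary_mixture(n)
            for n, fl in inflows.items()
        }

    # -- event scheduling --------------------------------------------------------
    def _interface_arrival(self, cid: str, flow: FlowState,
                           node_mix: dict[str, Mixture]) -> float:
        """Time until the slug interface nearest the outlet reaches the
        channel end; +inf if the channel is compositionally steady."""
        q = flow.channel_flows[cid]
        if abs(q) <= self.config.q_eps:
            return math.inf
        c = self.net.channels[cid]
        slugs = self.slugs[cid]
        if q > 0:
            inlet = node_mix[c.node_a]
            boundaries = [s.start for s in slugs[1:]]
            if not inlet.close_to(slugs[0].mixture):
                boundaries.append(0.0)
            if not boundaries:
                return math.inf
            return (1.0 - max(boundaries)) * c.volume / q
        inlet = node_mix[c.node_b]
        boundaries = [s.end for s in slugs[:-1]]
        if not inlet.close_to(slugs[-1].mixture):
            boundaries.append(1.0)
        if not boundaries:
            return math.inf
        return min(boundaries) * c.volume / (-q)

    def next_event(self, flow: FlowState, node_mix: dict[str, Mixture]) -> Event:
        """Earliest pending incident from the current time."""
        t = self.t
        cand: list[Event] = [Event(self.config.max_time, "termination")]
        if self.config.fixed_step is not None:
            cand.append(Event(self._next_fixed, "fixed_step"))
        # schedule boundaries of inlet mixtures
        for inj in self.net.injections:
            for tb in (inj.t_start, inj.t_end):
                if tb is not None and tb > t + T_MERGE:
                    cand.append(Event(tb, "injection", inj.node))
        # droplet injections and boundary crossings
        for d in self.droplets.values():
            if d.status == "scheduled" and d.t_inject > t + T_MERGE:
                cand.append(Event(d.t_inject, "injection", d.id))
            elif d.status == "in_channel":
                dt = dropmod.time_to_boundary(d, self.net, flow)
                if dt < math.inf:
                    cand.append(Event(t + dt, "droplet_boundary", d.id))
        # slug interface arrivals
        if "mixing" in self.modules:
            for cid in self.net.channels:
                dt = self._interface_arrival(cid, flow, node_mix)
                if dt < math.inf:
                    cand.append(Event(t + dt, "channel_transit", cid))
        order = {"injection": 0, "droplet_boundary": 1, "channel_transit": 2,
                 "fixed_step": 3, "termination": 4}
        cand.sort(key=lambda e: (e.time, order[e.kind], e.payload or ""))
        return cand[0]

    # -- state advance -------------------------------------------------------------
    def advance(self, flow: FlowState, node_mix: dict[str, Mixture], dt: float) -> None:
        """Move all material by dt of constant-flow plug advection, then apply
        the membrane hooks at the new time."""
        if dt < 0:
            raise SimulationError("negative time step")
        if dt == 0:
            return
        dfracs: dict[str, float] = {}
        for cid, c in self.net.channels.items():
            q = flow.channel_flows[cid]
            dfrac = q * dt / c.volume
            dfracs[cid] = dfrac
            if abs(dfrac) <= 0:
                continue
            inlet = node_mix[c.node_a] if dfrac > 0 else node_mix[c.node_b]
            if abs(dfrac) > 1.0 + 1e-9:
                slugs = self.slugs[cid]
                if len(slugs) == 1 and inlet.close_to(slugs[0].mixture):
                    # compositionally steady channel: a multi-volume flush is
                    # a no-op, so a long step (e.g. a jump to the horizon or a
                    # coarse fixed step) is exact here
                    dfracs[cid] = 0.0
                    continue
                raise SimulationError(
                    f"advection overshoot in channel {cid!r}: step crosses "
                    f"{abs(dfrac):.3f} channel volumes"
                )
            self.slugs[cid], _ = propagate_slugs(self.slugs[cid],
                                                 max(-1.0, min(1.0, dfrac)), inlet)
            if not slug_partition_ok(self.slugs[cid]):
                raise SimulationError(f"slug partition broken in channel {cid!r}")
        if self.droplets:
            dropmod.advance_droplets(list(self.droplets.values()), self.net, flow, dt)
        for rt in self.membranes.values():
            cid = rt.spec.channel
            memmod.mirror_and_recycle(self.slugs[cid], rt.tank, dfracs[cid])
            memmod.exchange_step(self.slugs[cid], rt.tank,
                                 self.net.channels[cid].volume, rt.r_m, dt)
            self._joint_merge(cid, rt.tank)
        self.t += dt

    def _joint_merge(self, cid: str, tank: memmod.TankState) -> None:
        """Merge adjacent slug pairs only when both channel and tank sides
        match, preserving the one-to-one alignment."""
        cs, ts = self.slugs[cid], tank.slugs
        new_c: list[Slug] = []
        new_t: list[Slug] = []
        for c_slug, t_slug in zip(cs, ts):
            if (new_c and new_c[-1].mixture.close_to(c_slug.mixture)
                    and new_t[-1].mixture.close_to(t_slug.mixture)):
                new_c[-1].end = c_slug.end
                new_t[-1].end = t_slug.end
            else:
                new_c.append(c_slug)
                new_t.append(t_slug)
        self.slugs[cid], tank.slugs = new_c, new_t

    # -- events --------------------------------------------------------------------
    def _process_due_actions(self, flow: FlowState) -> bool:
        """Apply at most one state-changing event due at the current instant.

        Simultaneous events are processed in deterministic order across loop
        iterations: droplet injections first (by time then id), then droplet
        boundary transfers (by id). Returns True if something changed.
        """
        for d in sorted(self.droplets.values(), key=lambda d: (d.t_inject, d.id)):
            if d.status == "scheduled" and d.t_inject <= self.t + T_MERGE:
                spec_channel = next(s.channel for s in self.net.droplets
                                    if s.id == d.id)
                c = self.net.channels[spec_channel]
                q = flow.channel_flows[spec_channel]
                d.status = "in_channel"
                d.channel = spec_channel
                d.pos = 0.0 if q >= 0 else 1.0
                d.path = [spec_channel]
                self.result.event_log.append(Event(self.t, "injection", d.id))
                return True
        for did in sorted(self.droplets):
            d = self.droplets[did]
            if d.status != "in_channel" or d.channel is None:
                continue
            q = flow.channel_flows[d.channel]
            at_end = (q > self.config.q_eps and d.pos >= 1.0 - 1e-9) or \
                     (q < -self.config.q_eps and d.pos <= 1e-9)
            if at_end:
                dropmod.transfer_droplet(d, self.net, flow)
                self.result.event_log.append(
                    Event(self.t, "droplet_boundary", d.id))
                return True
        return False

    # -- recording -------------------------------------------------------------------
    def _record(self, flow: FlowState, node_mix: dict[str, Mixture]) -> None:
        if self.config.record == "final" :
            self.result.records = self.result.records[-1:]
        tank_c = {
            mid: {sp: rt.tank.mean_concentration(sp)
                  for sp in sorted(set(self.net.species) | rt.tank.species())}
            for mid, rt in self.membranes.items()
        }
        drops = {d.id: (d.channel, d.pos) for d in self.droplets.values()}
        if self.result.records and abs(self.result.records[-1].time - self.t) < T_MERGE:
            self.result.records.pop()
        self.result.records.append(Record(
            self.t, dict(flow.node_pressures), dict(flow.channel_flows),
            node_mix, tank_c, drops,
        ))

    # -- main loop --------------------------------------------------------------------
    def run(self) -> ResultSet:
        cfg = self.config
        if cfg.fixed_step is not None:
            self._next_fixed = cfg.fixed_step
        while True:
            self.result.event_count += 1
            if self.result.event_count > cfg.max_events:
                raise SimulationError(
                    f"event cap exceeded ({cfg.max_events}); runaway schedule?"
                )
            flow = self._solve()
            if self._process_due_actions(flow):
                continue  # re-solve with the changed resistance pattern
            node_mix = self._node_mixtures(flow)
            self._record(flow, node_mix)

            if self.t >= cfg.max_time - T_MERGE:
                self.result.event_log.append(Event(self.t, "termination"))
                break
            if ("droplets" in self.modules and cfg.terminate_on_droplet_exit
                    and self.droplets
                    and all(d.status == "exited" for d in self.droplets.values())):
                self.result.event_log.append(Event(self.t, "termination"))
                break

            ev = self.next_event(flow, node_mix)
            if ev.kind == "termination" and ev.time >= cfg.max_time:
                # nothing pending before the horizon: jump there
                dt = cfg.max_time - self.t
                if not math.isfinite(dt):
                    break
                self.advance(flow, node_mix, dt)
                continue
            dt = max(ev.time - self.t, 0.0)
            self.advance(flow, node_mix, dt)
            if ev.kind == "fixed_step":
                self._next_fixed = ev.time + cfg.fixed_step  # type: ignore[operator]

        self.result.final_flow = self._solve()
        self.result.final_slugs = self.slugs
        self.result.final_tanks = {mid: rt.tank for mid, rt in self.membranes.items()}
        self.result.droplet_paths = {
            d.id: list(d.path) for d in self.droplets.values()
        }
        return self.result


def run_simulation(net: Network, config: Optional[SimulationConfig] = None) -> ResultSet:
    """Run a full event-driven simulation of a network.

    The loop is: solve flow -> apply due events -> schedule the next event ->
    advance material -> repeat, until the horizon is reached or (for droplet
    runs) all droplets have left the network.
    """
    return _Engine(net, config or SimulationConfig()).run()
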