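"""Membrane/tank species exchange for organ-on-chip style devices.

A porous membrane attached alongside a channel connects it to a well-stirred
tank (e.g. an organ chamber). Fick's first law is lumped into a single
species-dependent membrane resistance R_M via the pore-discovery model:

    R_d  = 1 / (4 r D_F)          resistance of discovering one pore
    N_p  = (A_m / (pi r^2)) * porosity    number of pores
    R_th = th / (A_m D_F)         resistance of crossing the effective thickness
    R_M  = R_d / N_p + R_th       [s/m^3]

so the molar flux from channel to tank is J = dC / R_M. The tank balance
V_t dC_t/dt = dC / R_M is integrated per engine step with the classic
fourth-order Runge-Kutta method, coupled to the matching channel-side
balance so that moles are conserved on both sides.

Tank contents mirror the channel's slug layout: every channel slug has an
aligned tank slug, each pair exchanging through its share of membrane area.
There is no advective flow in the tank; when the channel slugs advect, the
tank slugs are rotated alongside, and material that would leave at the
downstream end is recycled to the tank front, so tank moles are conserved
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .mixing import Mixture, Slug
from .network import MembraneSpec, Network

#: RK4 sub-steps are capped at this fraction of the fastest exchange time
#: constant min(V_c R_M, V_t R_M), keeping the integration well inside the
#: asymptotic accuracy regime and excluding overshoot of the linear flux law
SUBSTEP_FRACTION = 0.1


class MembraneError(ValueError):
    pass


def membrane_resistance(membrane: MembraneSpec, d_f: float) -> float:
    """Pore-discovery membrane resistance R_M [s/m^3] for one species.

    Returns ``math.inf`` for a zero-porosity (impermeable) membrane.
    """
    if d_f <= 0:
        raise MembraneError("diffusion coefficient must be positive")
    if membrane.porosity == 0.0:
        return math.inf
    r_d = 1.0 / (4.0 * membrane.pore_radius * d_f)
    a_p = math.pi * membrane.pore_radius**2
    n_p = membrane.area / a_p * membrane.porosity
    r_th = membrane.thickness / (membrane.area * d_f)
    return r_d / n_p + r_th


def membrane_flux(delta_c: float, r_m: float) -> float:
    """Molar flow [mol/s] across the membrane: J = dC / R_M.

    Positive when the channel side is richer (``delta_c = C_channel - C_tank``).
    """
    if r_m == math.inf:
        return 0.0
    if r_m <= 0:
        raise MembraneError("membrane resistance must be positive")
    return delta_c / r_m


def rk4_step(f: Callable[[float, np.ndarray], np.ndarray],
             y: np.ndarray, t: float, dt: float) -> np.ndarray:
    """One classic fourth-order Runge-Kutta step for y' = f(t, y)."""
    y = np.asarray(y, dtype=float)
    k1 = np.asarray(f(t, y), dtype=float)
    k2 = np.asarray(f(t + dt / 2.0, y + dt / 2.0 * k1), dtype=float)
    k3 = np.asarray(f(t + dt / 2.0, y + dt / 2.0 * k2), dtype=float)
    k4 = np.asarray(f(t + dt, y + dt * k3), dtype=float)
    y_next = y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if not np.all(np.isfinite(y_next)):
        raise MembraneError(
            f"non-finite RK4 stage at t={t:g}, dt={dt:g}: y={y!r}"
        )
    return y_next


@dataclass
class TankState:
    """Well-stirred-like tank with slugs mirroring the attached channel."""

    membrane_id: str
    volume: float
    slugs: list[Slug] = field(default_factory=list)

    def total_moles(self, species: str) -> float:
        return sum(s.length * self.volume * s.mixture.get(species) for s in self.slugs)

    def mean_concentration(self, species: str) -> float:
        return sum(s.length * s.mixture.get(species) for s in self.slugs)

    def species(self) -> set[str]:
        out: set[str] = set()
        for s in self.slugs:
            out |= s.mixture.species()
        return out


def _rotate(slugs: Sequence[Slug], dfrac: float) -> list[Slug]:
    """Cyclically shift slug material by a signed fraction; exiting material
    re-enters at the opposite end (recycling). Conserves content exactly."""
    if not slugs or dfrac == 0.0:
        return [Slug(s.start, s.end, s.mixture) for s in slugs]
    d = dfrac % 1.0
    pieces: list[Slug] = []
    for s in slugs:
        a, b = s.start + d, s.end + d
        if b <= 1.0 + 1e-15:
            pieces.append(Slug(a, min(b, 1.0), s.mixture))
        elif a >= 1.0:
            pieces.append(Slug(a - 1.0, b - 1.0, s.mixture))
        else:
            pieces.append(Slug(a, 1.0, s.mixture))
            pieces.append(Slug(0.0, b - 1.0, s.mixture))
    pieces.sort(key=lambda s: s.start)
    return pieces


def mirror_and_recycle(channel_slugs: Sequence[Slug], tank: TankState,
                       dfrac: float) -> None:
    """Re-align tank slugs to the channel's slug layout after an advection step.

    Tank material is rotated by the channel's advection fraction (material
    that would exit downstream is re-inserted at the front), then regrouped
    at the channel slug boundaries; sub-slugs falling inside one channel slug
    are volume-weighted averaged so the alignment stays one-to-one. Rotation,
    splitting and averaging all conserve tank moles exactly.
    """
    rotated = _rotate(tank.slugs, dfrac) if tank.slugs else [Slug(0.0, 1.0, Mixture())]
    aligned: list[Slug] = []
    for cs in channel_slugs:
        species: set[str] = set()
        for rs in rotated:
            species |= rs.mixture.species()
        totals: dict[str, float] = {sp: 0.0 for sp in species}
        vol = 0.0
        for rs in rotated:
            lo, hi = max(cs.start, rs.start), min(cs.end, rs.end)
            if hi <= lo:
                continue
            vol += hi - lo
            for sp in species:
                totals[sp] += (hi - lo) * rs.mixture.get(sp)
        if vol <= 0.0:
            aligned.append(Slug(cs.start, cs.end, Mixture()))
            continue
        aligned.append(
            Slug(cs.start, cs.end, Mixture.of({sp: totals[sp] / vol for sp in species}))
        )
    tank.slugs = aligned


def exchange_step(channel_slugs: list[Slug], tank: TankState,
                  channel_volume: float,
                  r_m: Mapping[str, float], dt: float) -> None:
    """Exchange species between each aligned channel/tank slug pair over dt.

    Per pair and species the coupled linear pair

        V_t,k dC_t/dt =  (C_c - C_t) / R_M,k
        V_c,k dC_c/dt = -(C_c - C_t) / R_M,k

    is integrated with RK4, where the pair's membrane share scales with its
    length fraction phi_k: R_M,k = R_M / phi_k, V_t,k = V_t phi_k and
    V_c,k = V_c phi_k. Total moles per species in each pair are conserved
    (the pair ODE preserves V_c C_c + V_t C_t; RK4 preserves it exactly for
    this antisymmetric right-hand side).
    """
    if len(channel_slugs) != len(tank.slugs):
        raise MembraneError(
            f"slug misalignment: {len(channel_slugs)} channel vs "
            f"{len(tank.slugs)} tank slugs"
        )
    for cs, ts in zip(channel_slugs, tank.slugs):
        if abs(cs.start - ts.start) > 1e-9 or abs(cs.end - ts.end) > 1e-9:
            raise MembraneError("slug misalignment: interval mismatch")
        species = cs.mixture.species() | ts.mixture.species()
        if not species:
            continue
        c_new: dict[str, float] = {}
        t_new: dict[str, float] = {}
        for sp in sorted(species):
            rm = r_m.get(sp, math.inf)
            cc, ct = cs.mixture.get(sp), ts.mixture.get(sp)
            if rm == math.inf or cc == ct:
                c_new[sp], t_new[sp] = cc, ct
                continue
            # phi cancels from both rates: the pair relaxes with the full
            # channel/tank time constants regardless of its length share
            tau_c = channel_volume * rm
            tau_t = tank.volume * rm

            def f(_t: float, y: np.ndarray) -> np.ndarray:
                dc = y[0] - y[1]
                return np.array([-dc / tau_c, dc / tau_t])

            n_sub = max(1, math.ceil(dt / (SUBSTEP_FRACTION * min(tau_c, tau_t))))
            h = dt / n_sub
            y = np.array([cc, ct])
            for _ in range(n_sub):
                y = rk4_step(f, y, 0.0, h)
            c_new[sp], t_new[sp] = float(y[0]), float(y[1])
        cs.mixture = Mixture.of(c_new)
        ts.mixture = Mixture.of(t_new)


@dataclass
class MembraneRuntime:
    """Engine-facing bundle: spec, per-species R_M, and the tank state."""

    spec: MembraneSpec
    r_m: dict[str, float]
    tank: TankState

    @staticmethod
    def create(net: Network, spec: MembraneSpec) -> "MembraneRuntime":
        r_m = {
            sid: membrane_resistance(spec, sp.diffusion_coefficient)
            for sid, sp in net.species.items()
        }
        tank = TankState(spec.id, spec.tank_volume, [Slug(0.0, 1.0, Mixture())])
        return MembraneRuntime(spec, r_m, tank)
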