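"""Quasi-steady laminar flow on the airway network over the breathing cycle.

Each instant of the slow sedentary cycle (0.25 Hz) is treated as an
independent steady problem: branch flows come from the linear Poiseuille
conductance network (Kirchhoff balance at every node), and node pressures are
accumulated from the mouth (0 Pa reference) down the tree.  Two dissipation
terms beyond fully developed Poiseuille flow are available and on by default,
since short, developing-flow airway segments dissipate more than the
Hagen-Poiseuille law predicts:

* a Pedley-type entrance-flow multiplier Z = max(1, (C/4) * sqrt(Re * d / L))
  on each branch's viscous drop, and
* minor losses K * rho * U^2 / 2 at the larynx (jet expansion) and at each
  bifurcation entry (secondary-flow/bend loss).

These corrections enter the reported pressures only; the flow split in
equal-pressure mode is computed from the linear conductance network, which
keeps it scale-invariant and exactly mass-conserving.

Units at the interface follow respiratory convention: flows in L/min,
geometry in cm, velocities in m/s, pressures in Pa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .morphometry import AirwayTree, UpperAirwaySection, LOBES

LPM_TO_M3S = 1.0 / 60000.0  # 1 L/min in m^3/s
CM = 1e-2
CM2 = 1e-4

#: canonical node names of the upper airway chain; the distal node of the
#: larynx is the tracheal inlet.
MOUTH_NODE = "mouth"
TRACHEA_INLET_NODE = "trachea_inlet"


class FlowDomainError(ValueError):
    """A flow argument is outside its physical domain."""


class FlowStructureError(ValueError):
    """The network is not solvable (disconnected / singular)."""


@dataclass
class GasProperties:
    density: float = 1.225  # kg/m^3
    viscosity: float = 1.7894e-5  # kg/(m s)

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise FlowDomainError("gas density and viscosity must be positive")


@dataclass
class BreathingCycle:
    """Sedentary sinusoidal breathing: Q(t) = Q_peak * sin(2*pi*t/T).

    Inhalation occupies [0, T/2]; the signed waveform integrates to zero over
    a period.  The peak flow of a half-sine with a given inspiratory mean is
    mean * pi / 2 (6 L/min mean -> 9.42 L/min peak).
    """

    period_T: float = 4.0  # s
    mean_inspiratory_flow: float = 6.0  # L/min

    def __post_init__(self) -> None:
        if self.period_T <= 0 or self.mean_inspiratory_flow < 0:
            raise FlowDomainError("period and mean flow must be positive")

    @property
    def peak_flow(self) -> float:
        return self.mean_inspiratory_flow * math.pi / 2.0


def waveform_flow(cycle: BreathingCycle, t: float) -> float:
    """Signed inlet flow at time t, L/min (positive = inspiratory)."""
    if t < 0:
        raise FlowDomainError("t must be non-negative")
    return cycle.peak_flow * math.sin(2.0 * math.pi * t / cycle.period_T)


def poiseuille_resistance(length: float, diameter: float, gas: GasProperties) -> float:
    """Hagen-Poiseuille resistance 128 mu L / (pi d^4), SI (Pa s / m^3)."""
    if diameter <= 0 or length <= 0:
        raise FlowDomainError("length and diameter must be positive")
    return 128.0 * gas.viscosity * length / (math.pi * diameter**4)


def elliptical_resistance(a: float, b: float, length: float, gas: GasProperties) -> float:
    """Exact laminar resistance of an elliptical tube, SI.

    dP = 4 mu L Q (a^2 + b^2) / (pi a^3 b^3); reduces to Hagen-Poiseuille for a = b.
    """
    if a <= 0 or b <= 0 or length <= 0:
        raise FlowDomainError("semi-axes and length must be positive")
    return 4.0 * gas.viscosity * length * (a**2 + b**2) / (math.pi * a**3 * b**3)


def reynolds(Q_lpm: float, csa_cm2: float, hydraulic_diameter_cm: float, gas: GasProperties) -> float:
    """Reynolds number rho * U * D_h / mu with U = Q / CSA (inputs in L/min, cm^2, cm)."""
    if csa_cm2 <= 0 or hydraulic_diameter_cm <= 0:
        raise FlowDomainError("csa and hydraulic diameter must be positive")
    U = abs(Q_lpm) * LPM_TO_M3S / (csa_cm2 * CM2)
    return gas.density * U * hydraulic_diameter_cm * CM / gas.viscosity


@dataclass
class LossModel:
    """Dissipation beyond fully developed Poiseuille flow.

    pedley_C : coefficient of the entrance-flow multiplier (1.85 classical);
        set ``pedley=False`` for pure Poiseuille pressures.
    junction_K : minor-loss coefficient applied on each non-root branch's
        velocity head at its entry (bend/secondary-flow loss).
    larynx_K : minor-loss coefficient on the laryngeal jet velocity head.
    ring_roughness : when True, the tracheal effective diameter used for its
        viscous drop is reduced by the ring depth (off by default; rings are
        geometric annotations only).
    """

    pedley: bool = True
    pedley_C: float = 1.85
    junction_K: float = 0.5
    larynx_K: float = 1.0
    ring_roughness: bool = False


@dataclass
class OutletBC:
    mode: str = "equal_pressure"  # or "lobar_fractions"
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("equal_pressure", "lobar_fractions"):
            raise FlowDomainError(f"unknown outlet BC mode {self.mode!r}")
        if self.mode == "lobar_fractions":
            total = sum(self.fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise FlowDomainError(f"lobar fractions must sum to 1, got {total}")


@dataclass
class FlowSolution:
    """One steady (or quasi-steady snapshot) network solution.

    ``branch_flow`` (L/min, signed, + = inspiratory), ``branch_velocity``
    (m/s, signed) and ``branch_reynolds`` are keyed by branch id and by
    upper-airway section name; ``node_pressure`` (Pa, mouth = 0) is keyed by
    node name: ``mouth``, each section name's distal node, ``trachea_inlet``
    and each branch id's distal node.
    """

    time: float
    branch_flow: dict[str, float]
    branch_velocity: dict[str, float]
    branch_reynolds: dict[str, float]
    node_pressure: dict[str, float]


def _branch_resistance(tree: AirwayTree, branch_id: str, gas: GasProperties, losses: LossModel) -> float:
    b = tree.branches[branch_id]
    d = b.diameter
    if branch_id == tree.root_id and losses.ring_roughness and tree.rings.enabled:
        d = d - 2.0 * tree.rings.depth_d / 10.0
    return poiseuille_resistance(b.length * CM, d * CM, gas)


def _subtree_conductance(tree: AirwayTree, gas: GasProperties, losses: LossModel) -> dict[str, float]:
    """Bottom-up series/parallel conductance of each branch subtree (SI)."""
    g: dict[str, float] = {}

    def rec(bid: str) -> float:
        b = tree.branches[bid]
        R = _branch_resistance(tree, bid, gas, losses)
        if b.is_terminal:
            g[bid] = 1.0 / R
        else:
            g_down = sum(rec(c) for c in b.child_ids)
            g[bid] = 1.0 / (R + 1.0 / g_down)
        return g[bid]

    rec(tree.root_id)
    return g


def _branch_velocity(tree: AirwayTree, branch_id: str, Q_lpm: float) -> float:
    """Mean axial velocity, m/s; the trachea uses its C-shape effective area."""
    b = tree.branches[branch_id]
    csa = tree.trachea.csa_effective if branch_id == tree.root_id else b.csa
    return Q_lpm * LPM_TO_M3S / (csa * CM2)


def solve_steady(
    tree: AirwayTree,
    Q_in: float,
    bc: OutletBC | None = None,
    gas: GasProperties | None = None,
    losses: LossModel | None = None,
    time: float = 0.0,
) -> FlowSolution:
    """Steady laminar network solve at inlet flow Q_in (L/min, >= 0).

    equal_pressure mode: terminal outlets share one pressure; flows split by
    inverse path resistance (series/parallel conductance recursion).
    lobar_fractions mode: each lobe's configured share of Q_in is distributed
    equally among its terminal branches.
    """
    if Q_in < 0:
        raise FlowDomainError("Q_in must be non-negative (exhalation is handled by solve_transient)")
    bc = bc or OutletBC()
    gas = gas or GasProperties()
    losses = losses or LossModel()

    flow: dict[str, float] = {}
    if bc.mode == "equal_pressure":
        g = _subtree_conductance(tree, gas, losses)
        flow[tree.root_id] = Q_in
        stack = [tree.root_id]
        while stack:
            bid = stack.pop()
            kids = tree.branches[bid].child_ids
            if kids:
                g_tot = sum(g[c] for c in kids)
                for c in kids:
                    flow[c] = flow[bid] * g[c] / g_tot
                stack.extend(kids)
    else:
        by_lobe: dict[str, list[str]] = {}
        for tid in tree.terminal_ids:
            by_lobe.setdefault(tree.branches[tid].lobe, []).append(tid)
        unknown = set(bc.fractions) - set(by_lobe)
        if unknown:
            raise FlowStructureError(f"lobar fractions reference absent lobes: {sorted(unknown)}")
        for tid in tree.terminal_ids:
            lobe = tree.branches[tid].lobe
            frac = bc.fractions.get(lobe, 0.0)
            flow[tid] = Q_in * frac / len(by_lobe[lobe])

        def up(bid: str) -> float:
            b = tree.branches[bid]
            if not b.is_terminal:
                flow[bid] = sum(up(c) for c in b.child_ids)
            return flow[bid]

        up(tree.root_id)

    velocity = {bid: _branch_velocity(tree, bid, q) for bid, q in flow.items()}
    re = {
        bid: reynolds(q, (tree.trachea.csa_effective if bid == tree.root_id else tree.branches[bid].csa), tree.branches[bid].diameter, gas)
        for bid, q in flow.items()
    }

    pressure: dict[str, float] = {MOUTH_NODE: 0.0}
    p = 0.0
    for sec in tree.upper_airway:
        Q_si = Q_in * LPM_TO_M3S
        U = Q_si / (sec.csa * CM2)
        flow[sec.name] = Q_in
        velocity[sec.name] = U
        re[sec.name] = reynolds(Q_in, sec.csa, sec.hydraulic_diameter, gas)
        drop = elliptical_resistance(sec.semi_axis_a * CM, sec.semi_axis_b * CM, sec.length * CM, gas) * Q_si
        if sec.name == "larynx":
            drop += losses.larynx_K * 0.5 * gas.density * U * U
        p -= drop
        pressure[sec.name] = p
    pressure[TRACHEA_INLET_NODE] = p

    stack = [(tree.root_id, TRACHEA_INLET_NODE)]
    while stack:
        bid, up_node = stack.pop()
        b = tree.branches[bid]
        Q_si = flow[bid] * LPM_TO_M3S
        drop = _branch_resistance(tree, bid, gas, losses) * Q_si
        if losses.pedley and re[bid] > 0:
            Z = (losses.pedley_C / 4.0) * math.sqrt(re[bid] * b.diameter / b.length)
            drop *= max(1.0, Z)
        if bid != tree.root_id:
            drop += losses.junction_K * 0.5 * gas.density * velocity[bid] ** 2
        pressure[bid] = pressure[up_node] - drop
        stack.extend((c, bid) for c in b.child_ids)

    return FlowSolution(time=time, branch_flow=flow, branch_velocity=velocity, branch_reynolds=re, node_pressure=pressure)


def _flip(sol: FlowSolution) -> FlowSolution:
    """Exhalation snapshot: reverse every flow, velocity and pressure drop."""
    return FlowSolution(
        time=sol.time,
        branch_flow={k: -v for k, v in sol.branch_flow.items()},
        branch_velocity={k: -v for k, v in sol.branch_velocity.items()},
        branch_reynolds=dict(sol.branch_reynolds),
        node_pressure={k: -v for k, v in sol.node_pressure.items()},
    )


def solve_transient(
    tree: AirwayTree,
    cycle: BreathingCycle | None = None,
    bc: OutletBC | None = None,
    gas: GasProperties | None = None,
    dt: float = 0.01,
    losses: LossModel | None = None,
) -> list[FlowSolution]:
    """Quasi-steady snapshots over one full breathing cycle [0, T], step dt.

    Each snapshot is ``solve_steady`` at |Q(t)|; during exhalation all branch
    flows (and pressure drops) are sign-reversed.  dt must divide T/2 evenly.
    """
    cycle = cycle or BreathingCycle()
    if dt <= 0:
        raise FlowDomainError("dt must be positive")
    n_half = cycle.period_T / 2.0 / dt
    if abs(n_half - round(n_half)) > 1e-9:
        raise FlowDomainError("dt must divide T/2 evenly")
    n = int(round(cycle.period_T / dt))
    out = []
    for i in range(n + 1):
        t = i * dt
        Q = waveform_flow(cycle, t)
        sol = solve_steady(tree, abs(Q), bc=bc, gas=gas, losses=losses, time=t)
        if Q < 0:
            sol = _flip(sol)
        out.append(sol)
    return out


def pressure_drop(sol: FlowSolution, node_a: str, node_b: str) -> float:
    """Static pressure difference p(a) - p(b), Pa."""
    for node in (node_a, node_b):
        if node not in sol.node_pressure:
            raise FlowStructureError(f"unknown node {node!r}")
    return sol.node_pressure[node_a] - sol.node_pressure[node_b]


def lobar_flow_fractions(tree: AirwayTree, sol: FlowSolution) -> dict[str, float]:
    """Fraction of total outlet flow leaving through each lobe's terminals."""
    totals = {lobe: 0.0 for lobe in LOBES}
    for tid in tree.terminal_ids:
        totals[tree.branches[tid].lobe] += sol.branch_flow[tid]
    grand = sum(totals.values())
    if grand == 0:
        return {lobe: float("nan") for lobe in totals}
    return {lobe: q / grand for lobe, q in totals.items()}


def mass_conservation_residual(tree: AirwayTree, sol: FlowSolution) -> float:
    """Worst relative Kirchhoff imbalance over interior nodes."""
    worst = 0.0
    for b in tree.branches.values():
        if b.child_ids:
            q_in = sol.branch_flow[b.id]
            q_out = sum(sol.branch_flow[c] for c in b.child_ids)
            scale = max(abs(q_in), 1e-30)
            worst = max(worst, abs(q_in - q_out) / scale)
    return worst


def glottis_reynolds(tree: AirwayTree, Q_lpm: float, gas: GasProperties | None = None) -> float:
    """Reynolds number at the minimum-CSA (laryngeal/glottis) section."""
    gas = gas or GasProperties()
    if not tree.upper_airway:
        raise FlowStructureError("tree has no upper airway sections")
    glottis = min(tree.upper_airway, key=lambda s: s.csa)
    return reynolds(Q_lpm, glottis.csa, glottis.hydraulic_diameter, gas)


def generation_outlet_pressure_drop(tree: AirwayTree, sol: FlowSolution) -> float:
    """Tracheal inlet to mean terminal-outlet static pressure drop, Pa."""
    terminals = tree.terminal_ids
    mean_p = sum(sol.node_pressure[t] for t in terminals) / len(terminals)
    return sol.node_pressure[TRACHEA_INLET_NODE] - mean_p
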