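"""Aerosol transport and deposition on the airway network.

The resolved 3D particle tracking of a CFD discrete-phase model is replaced
by a 1D Lagrangian bolus model closed with empirical deposition-efficiency
correlations — the same correlations such models are validated against:

* upper airway (oral cavity, pharynx, larynx): DE = 1 - exp(-a * IP) with
  the impaction parameter IP = rho_p * d_p^2 * Q (g um^2 L / (cm^3 min)),
* tracheobronchial regions: DE = 1 - exp(-a * St^b) with the Stokes number
  St = rho_p * d_p^2 * U * C_c / (36 * mu * R_0), evaluated with the mean
  velocity U and radius R_0 of the parent branch at region entry.

A bolus enters at the mouth at its injection time, advects along each
conduit at the local instantaneous mean velocity, splits at bifurcations in
proportion to the instantaneous daughter flows, and on every region change
loses the correlation's deposited fraction.  Reaching a terminal
(generation-6) outlet while flow is inspiratory counts as escape, credited
to that branch's lobe; at flow reversal suspended boluses advect backward
and may deposit again or leave through the mouth (recorded as exhaled and
folded into the suspended bucket of the conservation ledger).

Two modes: deterministic fractional-bolus accounting (default, zero
variance) and a seeded Monte-Carlo per-particle mode for position-fate maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .flow_network import (
    CM,
    CM2,
    LPM_TO_M3S,
    BreathingCycle,
    FlowSolution,
    GasProperties,
)
from .morphometry import AirwayTree, LOBES, REGIONS

UPPER_REGIONS = ("oral", "pharynx", "larynx")


class AerosolDomainError(ValueError):
    pass


class CorrelationError(ValueError):
    """A deposition correlation is missing or of the wrong form."""


@dataclass
class ParticleSpec:
    """Inert spherical aerosol particle (water-like density by default)."""

    diameter_dp: float = 7.0  # um
    density_rho_p: float = 998.2  # kg/m^3
    cunningham_Cc: float = 1.0

    def __post_init__(self) -> None:
        if self.diameter_dp < 0 or self.density_rho_p <= 0:
            raise AerosolDomainError("particle diameter must be >= 0 and density > 0")
        if self.cunningham_Cc < 1:
            raise AerosolDomainError("Cunningham slip factor must be >= 1")


@dataclass
class InjectionSet:
    """Timed bolus of particles on the oral inlet disk."""

    n_particles: int = 2720
    disk_diameter: float = 2.16  # cm
    t_inj: float = 0.0  # s
    positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles <= 0:
            raise AerosolDomainError("n_particles must be positive")
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.positions):
            r = np.hypot(self.positions[:, 0], self.positions[:, 1])
            if np.any(r > self.disk_diameter / 2.0 + 1e-12):
                raise AerosolDomainError("injection positions outside the oral disk")


@dataclass
class DECorrelation:
    region: str
    form: str  # "stokes_exp" or "ip_exp"
    a: float
    b: float = 1.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.form not in ("stokes_exp", "ip_exp"):
            raise CorrelationError(f"unknown correlation form {self.form!r}")
        if self.a < 0:
            raise CorrelationError("correlation constant a must be >= 0")
        if self.form == "stokes_exp" and self.b <= 0:
            raise CorrelationError("stokes_exp exponent b must be > 0")


@dataclass
class DepositionRecord:
    """Conserved ledger of the fate of an injected bolus (fractions of injected)."""

    deposited: dict[str, float] = field(default_factory=dict)
    escaped: dict[str, float] = field(default_factory=dict)
    suspended: float = 0.0
    exhaled: float = 0.0  # mouth exit during exhalation; counted inside `suspended`
    per_region_entering: dict[str, float] = field(default_factory=dict)

    @property
    def total_deposited(self) -> float:
        return sum(self.deposited.values())

    @property
    def total_escaped(self) -> float:
        return sum(self.escaped.values())

    def conservation_residual(self) -> float:
        return abs(self.total_deposited + self.total_escaped + self.suspended - 1.0)


def stokes_number(p: ParticleSpec, U: float, R_0: float, gas: GasProperties | None = None) -> float:
    """St = rho_p d_p^2 U C_c / (36 mu R_0), all SI (U m/s, R_0 m)."""
    gas = gas or GasProperties()
    if R_0 <= 0:
        raise AerosolDomainError("R_0 must be positive")
    if U < 0:
        raise AerosolDomainError("U must be non-negative")
    dp_m = p.diameter_dp * 1e-6
    return p.density_rho_p * dp_m**2 * U * p.cunningham_Cc / (36.0 * gas.viscosity * R_0)


def impaction_parameter(p: ParticleSpec, Q_lpm: float) -> float:
    """IP = rho (g/cm^3) * d_p^2 (um^2) * Q (L/min), the conventional aerosol unit."""
    if Q_lpm < 0:
        raise AerosolDomainError("Q must be non-negative")
    rho_gcc = p.density_rho_p / 1000.0
    return rho_gcc * p.diameter_dp**2 * Q_lpm


def de_stokes(St: float, corr: DECorrelation) -> float:
    """DE = 1 - exp(-a * St^b); in [0, 1), monotone non-decreasing in St."""
    if corr.form != "stokes_exp":
        raise CorrelationError(f"correlation for {corr.region!r} is not stokes_exp")
    if St < 0:
        raise AerosolDomainError("St must be non-negative")
    if St == 0:
        return 0.0
    return 1.0 - math.exp(-corr.a * St**corr.b)


def de_ip(IP: float, corr: DECorrelation) -> float:
    """DE = 1 - exp(-a * IP); in [0, 1), monotone non-decreasing in IP."""
    if corr.form != "ip_exp":
        raise CorrelationError(f"correlation for {corr.region!r} is not ip_exp")
    if IP < 0:
        raise AerosolDomainError("IP must be non-negative")
    return 1.0 - math.exp(-corr.a * IP)


# ---------------------------------------------------------------------------
# 1D bolus transport
# ---------------------------------------------------------------------------

@dataclass
class _Conduit:
    """Uniform 1D description of a transport conduit (section or branch)."""

    name: str
    length: float  # cm
    radius: float  # cm, hydraulic radius used for St
    region: str
    upstream: str | None  # conduit name toward the mouth
    downstream: list[str]  # conduit names away from the mouth ([] = terminal)
    lobe: str = "none"


def _build_conduits(tree: AirwayTree) -> dict[str, _Conduit]:
    conduits: dict[str, _Conduit] = {}
    prev = None
    for sec in tree.upper_airway:
        conduits[sec.name] = _Conduit(
            name=sec.name,
            length=sec.length,
            radius=sec.hydraulic_diameter / 2.0,
            region=sec.region,
            upstream=prev,
            downstream=[],
        )
        if prev is not None:
            conduits[prev].downstream = [sec.name]
        prev = sec.name
    for b in tree.branches.values():
        up = b.parent_id if b.parent_id is not None else prev
        conduits[b.id] = _Conduit(
            name=b.id,
            length=b.length,
            radius=b.radius,
            region=b.region,
            upstream=up,
            downstream=list(b.child_ids),
            lobe=b.lobe,
        )
    if prev is not None:
        conduits[prev].downstream = [tree.root_id]
    return conduits


def _check_correlations(conduits: dict[str, _Conduit], correlations: dict[str, DECorrelation]) -> None:
    for c in conduits.values():
        corr = correlations.get(c.region)
        if corr is None:
            raise CorrelationError(f"no deposition correlation configured for region {c.region!r}")
        expected = "ip_exp" if c.region in UPPER_REGIONS else "stokes_exp"
        if corr.form != expected:
            raise CorrelationError(f"region {c.region!r} requires form {expected!r}, got {corr.form!r}")


class _FlowSeries:
    """Uniform-dt snapshot lookup with signed velocities in cm/s."""

    def __init__(self, snapshots: list[FlowSolution]):
        if len(snapshots) < 2:
            raise AerosolDomainError("flow series needs at least two snapshots")
        self.snapshots = snapshots
        self.t0 = snapshots[0].time
        self.dt = snapshots[1].time - snapshots[0].time
        self.t_end = snapshots[-1].time

    def at(self, t: float) -> FlowSolution:
        i = int(round((t - self.t0) / self.dt))
        i = min(max(i, 0), len(self.snapshots) - 1)
        return self.snapshots[i]

    def velocity_cm_s(self, sol: FlowSolution, name: str) -> float:
        return sol.branch_velocity[name] / CM  # m/s -> cm/s


def _entry_probability(
    p: ParticleSpec,
    conduit: _Conduit,
    parent: _Conduit | None,
    sol: FlowSolution,
    correlations: dict[str, DECorrelation],
    gas: GasProperties,
    inlet_Q_lpm: float,
) -> float:
    corr = correlations[conduit.region]
    if corr.form == "ip_exp":
        return de_ip(impaction_parameter(p, abs(inlet_Q_lpm)), corr)
    ref = parent if parent is not None else conduit
    U = abs(sol.branch_velocity.get(ref.name, 0.0))
    St = stokes_number(p, U, ref.radius * CM, gas)
    return de_stokes(St, corr)


@dataclass
class _Bolus:
    conduit: str
    s: float  # cm from the conduit's mouth-side end
    frac: float
    region: str


def transport(
    tree: AirwayTree,
    flow_series: list[FlowSolution],
    injection: InjectionSet,
    p: ParticleSpec,
    correlations: dict[str, DECorrelation],
    mode: str = "deterministic",
    gas: GasProperties | None = None,
    rng_seed: int | None = None,
    min_fraction: float = 1e-12,
) -> DepositionRecord:
    """Transport one injected bolus through the flow series; returns the fate ledger.

    ``mode="deterministic"`` propagates fractional boluses (splitting at each
    bifurcation); ``mode="mc"`` tracks ``injection.n_particles`` individual
    particles with seeded Bernoulli deposition and routing, converging to the
    deterministic ledger as n grows.
    """
    gas = gas or GasProperties()
    conduits = _build_conduits(tree)
    _check_correlations(conduits, correlations)
    series = _FlowSeries(flow_series)
    if injection.t_inj < series.t0 or injection.t_inj >= series.t_end:
        raise AerosolDomainError("flow series does not cover the injection time")

    first = tree.upper_airway[0].name if tree.upper_airway else tree.root_id
    record = DepositionRecord(
        deposited={r: 0.0 for r in REGIONS},
        escaped={lobe: 0.0 for lobe in LOBES},
        per_region_entering={r: 0.0 for r in REGIONS},
    )

    if mode == "deterministic":
        _transport_deterministic(record, conduits, series, injection, p, correlations, gas, first, tree, min_fraction)
    elif mode == "mc":
        rng = np.random.default_rng(injection.seed if rng_seed is None else rng_seed)
        _transport_mc(record, conduits, series, injection, p, correlations, gas, first, tree, rng)
    else:
        raise AerosolDomainError(f"unknown transport mode {mode!r}")
    return record


def _inlet_Q(series: _FlowSeries, sol: FlowSolution, tree: AirwayTree) -> float:
    return sol.branch_flow[tree.root_id]


def _enter(
    record: DepositionRecord,
    bolus: _Bolus,
    conduit: _Conduit,
    parent: _Conduit | None,
    sol: FlowSolution,
    p: ParticleSpec,
    correlations: dict[str, DECorrelation],
    gas: GasProperties,
    inlet_Q: float,
) -> None:
    """Region-change bookkeeping for a fractional bolus (deterministic mode)."""
    record.per_region_entering[conduit.region] += bolus.frac
    prob = _entry_probability(p, conduit, parent, sol, correlations, gas, inlet_Q)
    record.deposited[conduit.region] += bolus.frac * prob
    bolus.frac *= 1.0 - prob
    bolus.region = conduit.region


def _transport_deterministic(record, conduits, series, injection, p, correlations, gas, first, tree, min_fraction):
    sol0 = series.at(injection.t_inj)
    bolus0 = _Bolus(conduit=first, s=0.0, frac=1.0, region="")
    _enter(record, bolus0, conduits[first], None, sol0, p, correlations, gas, _inlet_Q(series, sol0, tree))
    boluses = [bolus0]

    t = injection.t_inj
    dt = series.dt
    while t < series.t_end - 1e-12 and boluses:
        sol = series.at(t)
        inlet_Q = _inlet_Q(series, sol, tree)
        new_boluses: list[_Bolus] = []
        for b in boluses:
            remaining = dt
            alive = True
            while remaining > 1e-15 and alive:
                c = conduits[b.conduit]
                v = series.velocity_cm_s(sol, c.name)
                if v == 0.0:
                    break
                if v > 0:
                    dist = c.length - b.s
                    t_cross = dist / v
                    if t_cross > remaining:
                        b.s += v * remaining
                        remaining = 0.0
                        break
                    remaining -= t_cross
                    if not c.downstream:
                        record.escaped[c.lobe] += b.frac
                        alive = False
                        break
                    if len(c.downstream) == 1:
                        nxt = conduits[c.downstream[0]]
                        b.conduit, b.s = nxt.name, 0.0
                        if nxt.region != b.region:
                            _enter(record, b, nxt, c, sol, p, correlations, gas, inlet_Q)
                    else:
                        q = [abs(sol.branch_flow[d]) for d in c.downstream]
                        q_tot = sum(q)
                        if q_tot == 0:
                            b.s = c.length
                            remaining = 0.0
                            break
                        parts = []
                        for d, qi in zip(c.downstream, q):
                            nb = _Bolus(conduit=d, s=0.0, frac=b.frac * qi / q_tot, region=b.region)
                            nxt = conduits[d]
                            if nxt.region != nb.region:
                                _enter(record, nb, nxt, c, sol, p, correlations, gas, inlet_Q)
                            parts.append(nb)
                        # continue advecting the first daughter in-place, queue the rest
                        b = parts[0]
                        for extra in parts[1:]:
                            if extra.frac > min_fraction:
                                extra_remaining = remaining
                                _advect_single(extra, conduits, series, sol, record, p, correlations, gas, inlet_Q, extra_remaining, new_boluses)
                else:
                    t_cross = b.s / (-v)
                    if t_cross > remaining:
                        b.s += v * remaining
                        remaining = 0.0
                        break
                    remaining -= t_cross
                    if c.upstream is None:
                        record.exhaled += b.frac
                        alive = False
                        break
                    up = conduits[c.upstream]
                    b.conduit, b.s = up.name, up.length
                    if up.region != b.region:
                        _enter(record, b, up, c, sol, p, correlations, gas, inlet_Q)
            if alive and b.frac > min_fraction:
                new_boluses.append(b)
        boluses = new_boluses
        t += dt

    record.suspended = sum(b.frac for b in boluses) + record.exhaled
    _round_ledger(record)


def _advect_single(b, conduits, series, sol, record, p, correlations, gas, inlet_Q, remaining, out):
    """Finish the current step for a bolus spawned mid-step at a bifurcation."""
    alive = True
    while remaining > 1e-15 and alive:
        c = conduits[b.conduit]
        v = series.velocity_cm_s(sol, c.name)
        if v <= 0.0:
            break
        dist = c.length - b.s
        t_cross = dist / v
        if t_cross > remaining:
            b.s += v * remaining
            break
        remaining -= t_cross
        if not c.downstream:
            record.escaped[c.lobe] += b.frac
            alive = False
            break
        if len(c.downstream) == 1:
            nxt = conduits[c.downstream[0]]
            b.conduit, b.s = nxt.name, 0.0
            if nxt.region != b.region:
                _enter(record, b, nxt, c, sol, p, correlations, gas, inlet_Q)
        else:
            q = [abs(sol.branch_flow[d]) for d in c.downstream]
            q_tot = sum(q)
            if q_tot == 0:
                b.s = c.length
                break
            parts = []
            for d, qi in zip(c.downstream, q):
                nb = _Bolus(conduit=d, s=0.0, frac=b.frac * qi / q_tot, region=b.region)
                nxt = conduits[d]
                if nxt.region != nb.region:
                    _enter(record, nb, nxt, c, sol, p, correlations, gas, inlet_Q)
                parts.append(nb)
            b = parts[0]
            for extra in parts[1:]:
                _advect_single(extra, conduits, series, sol, record, p, correlations, gas, inlet_Q, remaining, out)
    if alive:
        out.append(b)


def _transport_mc(record, conduits, series, injection, p, correlations, gas, first, tree, rng):
    n = injection.n_particles
    w = 1.0 / n
    fates = []  # per-particle fate labels, aligned with injection.positions
    for i in range(n):
        conduit = first
        s = 0.0
        region = ""
        sol = series.at(injection.t_inj)
        inlet_Q = _inlet_Q(series, sol, tree)
        # entry into the first region
        record.per_region_entering[conduits[first].region] += w
        prob = _entry_probability(p, conduits[first], None, sol, correlations, gas, inlet_Q)
        fate = None
        if rng.uniform() < prob:
            record.deposited[conduits[first].region] += w
            fate = "deposited:" + conduits[first].region
        region = conduits[first].region
        t = injection.t_inj
        while fate is None and t < series.t_end - 1e-12:
            sol = series.at(t)
            inlet_Q = _inlet_Q(series, sol, tree)
            remaining = series.dt
            while remaining > 1e-15 and fate is None:
                c = conduits[conduit]
                v = series.velocity_cm_s(sol, c.name)
                if v == 0.0:
                    break
                if v > 0:
                    t_cross = (c.length - s) / v
                    if t_cross > remaining:
                        s += v * remaining
                        remaining = 0.0
                        break
                    remaining -= t_cross
                    if not c.downstream:
                        record.escaped[c.lobe] += w
                        fate = "escaped:" + c.lobe
                        break
                    if len(c.downstream) == 1:
                        nxt_name = c.downstream[0]
                    else:
                        q = np.array([abs(sol.branch_flow[d]) for d in c.downstream])
                        if q.sum() == 0:
                            s = c.length
                            break
                        nxt_name = c.downstream[int(rng.choice(len(q), p=q / q.sum()))]
                    nxt = conduits[nxt_name]
                    prev = c
                    conduit, s = nxt_name, 0.0
                    if nxt.region != region:
                        record.per_region_entering[nxt.region] += w
                        prob = _entry_probability(p, nxt, prev, sol, correlations, gas, inlet_Q)
                        region = nxt.region
                        if rng.uniform() < prob:
                            record.deposited[region] += w
                            fate = "deposited:" + region
                else:
                    t_cross = s / (-v)
                    if t_cross > remaining:
                        s += v * remaining
                        remaining = 0.0
                        break
                    remaining -= t_cross
                    if c.upstream is None:
                        record.exhaled += w
                        fate = "exhaled"
                        break
                    up = conduits[c.upstream]
                    prev = c
                    conduit, s = up.name, up.length
                    if up.region != region:
                        record.per_region_entering[up.region] += w
                        prob = _entry_probability(p, up, prev, sol, correlations, gas, inlet_Q)
                        region = up.region
                        if rng.uniform() < prob:
                            record.deposited[region] += w
                            fate = "deposited:" + region
            t += series.dt
        fates.append(fate or "suspended")
    n_susp = sum(1 for f in fates if f == "suspended")
    record.suspended = n_susp * w + record.exhaled
    record.fates = fates  # position-fate map support (aligned with injection.positions)
    _round_ledger(record)


def _round_ledger(record: DepositionRecord) -> None:
    # clamp tiny negative rounding residue
    for k, v in record.deposited.items():
        record.deposited[k] = max(0.0, v)
    for k, v in record.escaped.items():
        record.escaped[k] = max(0.0, v)
    record.suspended = max(0.0, record.suspended)


def regional_DE(record: DepositionRecord, region: str) -> float | None:
    """Deposited / entering for one region; None when the region was never entered."""
    entering = record.per_region_entering.get(region, 0.0)
    if entering <= 0.0:
        return None
    return record.deposited.get(region, 0.0) / entering


def total_DE(record: DepositionRecord) -> float:
    """Whole-model deposition efficiency: total deposited fraction of injected."""
    return record.total_deposited


def entry_transport_numbers(
    tree: AirwayTree,
    sol: FlowSolution,
    p: ParticleSpec,
    gas: GasProperties | None = None,
) -> dict[str, float]:
    """Per-region governing transport number at region entry for one snapshot:
    the impaction parameter (at the instantaneous inlet flow) for the upper
    airway, the Stokes number (parent-branch mean velocity and radius,
    averaged over the region's entry branches) downstream."""
    gas = gas or GasProperties()
    conduits = _build_conduits(tree)
    Q = abs(sol.branch_flow[tree.root_id])
    numbers: dict[str, list[float]] = {}
    for c in conduits.values():
        if c.upstream is None:
            parent = c
        else:
            parent = conduits[c.upstream]
        if parent.region == c.region and c.upstream is not None:
            continue  # not a region-entry conduit
        if c.region in UPPER_REGIONS:
            val = impaction_parameter(p, Q)
        else:
            U = abs(sol.branch_velocity.get(parent.name, 0.0))
            val = stokes_number(p, U, parent.radius * CM, gas)
        numbers.setdefault(c.region, []).append(val)
    return {region: float(np.mean(vals)) for region, vals in numbers.items()}


def default_injection_times(cycle: BreathingCycle | None = None, step: float = 0.2):
    cycle = cycle or BreathingCycle()
    n = int(round(cycle.period_T / 2.0 / step))
    return [round(i * step, 10) for i in range(n)]


def injection_sweep(
    tree: AirwayTree,
    cycle: BreathingCycle,
    p: ParticleSpec,
    correlations: dict[str, DECorrelation],
    times: list[float] | None = None,
    flow_series: list[FlowSolution] | None = None,
    injection: InjectionSet | None = None,
    mode: str = "deterministic",
    dt: float = 0.01,
) -> list[tuple[float, DepositionRecord]]:
    """One DepositionRecord per injection time on the default 0-1.8 s grid."""
    from .flow_network import solve_transient

    times = default_injection_times(cycle) if times is None else times
    bad = [t for t in times if not 0.0 <= t < cycle.period_T / 2.0]
    if bad:
        raise AerosolDomainError(f"injection times outside inhalation [0, T/2): {bad}")
    if flow_series is None:
        flow_series = solve_transient(tree, cycle, dt=dt)
    out = []
    for t_inj in times:
        inj = injection or InjectionSet(t_inj=t_inj)
        inj = InjectionSet(inj.n_particles, inj.disk_diameter, t_inj, inj.positions, inj.seed)
        out.append((t_inj, transport(tree, flow_series, inj, p, correlations, mode=mode)))
    return out


def steady_vs_transient(
    tree: AirwayTree,
    cycle: BreathingCycle,
    p: ParticleSpec,
    correlations: dict[str, DECorrelation],
    dt: float = 0.01,
    times: list[float] | None = None,
) -> dict:
    """Total/regional DE under constant mean flow vs the cycle-averaged transient.

    The steady case holds the mean inspiratory flow (default 6 L/min)
    constant for one inhalation's duration; the transient case averages the
    injection-time sweep over the breathing cycle.  Also reports the best
    single injection time.
    """
    from .flow_network import solve_steady, solve_transient

    n_steady = int(round(cycle.period_T / dt))
    steady_sol = solve_steady(tree, cycle.mean_inspiratory_flow)
    steady_series = [
        FlowSolution(i * dt, steady_sol.branch_flow, steady_sol.branch_velocity, steady_sol.branch_reynolds, steady_sol.node_pressure)
        for i in range(n_steady + 1)
    ]
    steady_rec = transport(tree, steady_series, InjectionSet(t_inj=0.0), p, correlations)

    sweep = injection_sweep(tree, cycle, p, correlations, times=times, dt=dt)
    mean_total = float(np.mean([total_DE(r) for _, r in sweep]))
    best_t, best_rec = max(sweep, key=lambda tr: total_DE(tr[1]))

    regions = list(REGIONS)
    return {
        "steady": {"total_DE": total_DE(steady_rec), "regional_DE": {r: regional_DE(steady_rec, r) for r in regions}, "record": steady_rec},
        "transient": {
            "total_DE_cycle_mean": mean_total,
            "best_t_inj": best_t,
            "total_DE_best": total_DE(best_rec),
            "regional_DE_best": {r: regional_DE(best_rec, r) for r in regions},
            "sweep": sweep,
        },
    }
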