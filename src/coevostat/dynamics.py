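"""Chemostat ecology: state containers, RK4 integration, and the full
eco-evolutionary simulation loop.

The ecological state is (R, {N_i}, {V_j}): resource concentration plus the
densities of every extant host and phage strain, each strain pinned to a
genotype bin.  Dynamics are deterministic ODEs integrated with classical RK4
at a fixed timestep; stochasticity enters only through mutation.  After each
step, mutants are injected (see :mod:`coevostat.evolution`) and any
population below 1 cell (virion) per ml is culled — the continuous densities
are an abstraction of discrete populations, and a density below one
individual per ml means the strain is lost.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _core
from .errors import ConsistencyError, InvalidParameterError, NumericalFailureError
from .evolution import MutationEvent, assign_mutant_events
from .infection import AdsorptionMatrix
from .landscapes import GrowthLandscape, bin_of
from .params import ModelParameters

CULL_THRESHOLD = 1.0  # cells (virions) per ml; strict inequality removes


@dataclass(frozen=True)
class SystemState:
    """Resource concentration plus the binned strain communities at a time."""

    t: float
    R: float
    host_bins: np.ndarray      # int64 genotype bin per host strain
    host_density: np.ndarray   # cells/ml
    phage_bins: np.ndarray
    phage_density: np.ndarray  # virions/ml
    rho: float = 0.01
    #: growth scaling per host strain; set by the simulator, else derive from a landscape
    delta: np.ndarray | None = None

    def __post_init__(self):
        if self.host_bins.size != self.host_density.size:
            raise ConsistencyError("host bins and densities differ in length")
        if self.phage_bins.size != self.phage_density.size:
            raise ConsistencyError("phage bins and densities differ in length")

    @classmethod
    def initial(cls, params: ModelParameters) -> "SystemState":
        """The standard initial condition: fresh medium (R = R0), one host
        strain at h_init, and one phage strain at v_init unless V_init = 0."""
        hb = np.array([bin_of(params.h_init, params.rho)], dtype=np.int64)
        if params.V_init > 0:
            vb = np.array([bin_of(params.v_init, params.rho)], dtype=np.int64)
            vd = np.array([params.V_init])
        else:
            vb = np.zeros(0, dtype=np.int64)
            vd = np.zeros(0)
        return cls(t=0.0, R=params.R0, host_bins=hb,
                   host_density=np.array([params.N_init]),
                   phage_bins=vb, phage_density=vd, rho=params.rho)

    @classmethod
    def from_communities(cls, hosts: dict[float, float], phages: dict[float, float],
                         R: float, rho: float = 0.01, t: float = 0.0) -> "SystemState":
        """Build a state from genotype -> density mappings."""
        hb = np.array([bin_of(h, rho) for h in hosts], dtype=np.int64)
        vb = np.array([bin_of(v, rho) for v in phages], dtype=np.int64)
        return cls(t=t, R=R, host_bins=hb,
                   host_density=np.array(list(hosts.values()), dtype=float),
                   phage_bins=vb,
                   phage_density=np.array(list(phages.values()), dtype=float),
                   rho=rho)

    @property
    def hosts(self) -> dict[float, float]:
        """Genotype -> density map for hosts."""
        return {float(b * self.rho): float(n)
                for b, n in zip(self.host_bins, self.host_density)}

    @property
    def phages(self) -> dict[float, float]:
        return {float(b * self.rho): float(v)
                for b, v in zip(self.phage_bins, self.phage_density)}

    @property
    def host_genotypes(self) -> np.ndarray:
        return self.host_bins * self.rho

    @property
    def phage_genotypes(self) -> np.ndarray:
        return self.phage_bins * self.rho

    @property
    def total_host_density(self) -> float:
        return float(self.host_density.sum())

    @property
    def total_phage_density(self) -> float:
        return float(self.phage_density.sum())

    def with_delta(self, landscape: GrowthLandscape) -> "SystemState":
        return replace(self, delta=landscape.delta_at_bins(self.host_bins, self.t))


def derivatives(state: SystemState, params: ModelParameters,
                theta: np.ndarray | AdsorptionMatrix,
                landscape: GrowthLandscape | None = None):
    """Time derivatives (dR/dt, dN/dt array, dV/dt array) of a state."""
    theta = theta.theta if isinstance(theta, AdsorptionMatrix) else np.asarray(theta, float)
    if theta.shape != (state.host_bins.size, state.phage_bins.size):
        raise ConsistencyError(
            f"theta shape {theta.shape} does not match roster "
            f"({state.host_bins.size} hosts, {state.phage_bins.size} phages)")
    delta = state.delta
    if delta is None:
        if landscape is None:
            raise ConsistencyError("state has no delta cache and no landscape was given")
        delta = landscape.delta_at_bins(state.host_bins, state.t)
    return _core.derivs(state.R, state.host_density, state.phage_density,
                        np.asarray(delta, float), theta,
                        params.omega, params.R0, params.epsilon, params.gamma,
                        params.K, params.beta)


_STATUS_VAR = {1: "R", 2: "N", 3: "V"}


def rk4_step(state: SystemState, params: ModelParameters,
             theta: np.ndarray | AdsorptionMatrix,
             landscape: GrowthLandscape | None = None,
             dt: float | None = None) -> SystemState:
    """One classical RK4 update of (R, all N_i, all V_j).

    The strain roster (and, for dynamic landscapes, the landscape itself) is
    held fixed within the step.
    """
    if dt is None:
        dt = params.dt
    if dt <= 0:
        raise InvalidParameterError(f"dt must be > 0, got {dt!r}")
    theta_arr = theta.theta if isinstance(theta, AdsorptionMatrix) else np.asarray(theta, float)
    delta = state.delta
    if delta is None:
        if landscape is None:
            raise ConsistencyError("state has no delta cache and no landscape was given")
        delta = landscape.delta_at_bins(state.host_bins, state.t)
    R2, N2, V2, status = _core.rk4_step(
        state.R, state.host_density, state.phage_density,
        np.asarray(delta, float), theta_arr,
        params.omega, params.R0, params.epsilon, params.gamma, params.K,
        params.beta, dt)
    if status:
        raise NumericalFailureError(_STATUS_VAR[status])
    return replace(state, t=state.t + dt, R=float(R2), host_density=N2,
                   phage_density=V2, delta=np.asarray(delta, float))


def cull_extinct(state: SystemState, threshold: float = CULL_THRESHOLD) -> SystemState:
    """Remove every population strictly below the extinction threshold."""
    mh = state.host_density >= threshold
    mv = state.phage_density >= threshold
    if mh.all() and mv.all():
        return state
    return replace(state,
                   host_bins=state.host_bins[mh], host_density=state.host_density[mh],
                   phage_bins=state.phage_bins[mv], phage_density=state.phage_density[mv],
                   delta=None if state.delta is None else state.delta[mh])


@dataclass
class Trajectory:
    """Sampled states of one simulation run plus run metadata.

    ``range_edge`` is True if any mutation reached (or overshot) the genotype
    range boundaries h = 0 or h = 1; the experiment layer discards such runs,
    as edge effects make them artefactual, but the trajectory is still
    returned for diagnosis.
    """

    params: ModelParameters
    seed: int | None
    scheme: str
    samples: list[SystemState] = field(default_factory=list)
    range_edge: bool = False
    landscape_kind: str = ""
    events: list = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.samples])

    @property
    def final(self) -> SystemState:
        return self.samples[-1]

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long format: (time, variable, genotype_bin, value)."""
        rows = []
        for s in self.samples:
            rows.append((s.t, "R", -1, s.R))
            for b, n in zip(s.host_bins, s.host_density):
                rows.append((s.t, "N", int(b), n))
            for b, v in zip(s.phage_bins, s.phage_density):
                rows.append((s.t, "V", int(b), v))
        return pd.DataFrame(rows, columns=["time", "variable", "genotype_bin", "value"])

    def to_csv(self, path) -> None:
        """Write the tidy trajectory with a run-metadata comment header."""
        buf = io.StringIO()
        for k, v in self.params.to_dict().items():
            buf.write(f"# {k}: {v!r}\n")
        buf.write(f"# seed: {self.seed}\n")
        buf.write(f"# scheme: {self.scheme}\n")
        buf.write(f"# landscape: {self.landscape_kind}\n")
        buf.write(f"# range_edge: {self.range_edge}\n")
        self.to_dataframe().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def simulate(params: ModelParameters, landscape: GrowthLandscape,
             seed: int | None = 0, scheme: str = "gaussian",
             output_stride: int = 1000,
             initial_state: SystemState | None = None,
             record_events: bool = False) -> Trajectory:
    """Run the full eco-evolutionary simulation.

    Per step: RK4 update of the ODEs -> stochastic mutant injection -> cull of
    sub-threshold populations.  States are recorded every ``output_stride``
    steps (plus the initial and final states).  Identical arguments and seed
    give bit-identical trajectories.

    Parameters
    ----------
    initial_state
        Override the standard single-strain initial condition, e.g. to seed a
        multi-strain community for equilibrium experiments.
    """
    if landscape.rho != params.rho:
        raise ConsistencyError("landscape and parameters disagree on rho")
    state0 = SystemState.initial(params) if initial_state is None else initial_state
    # two deterministic streams per run: numba's stream supplies the
    # per-step Poisson mutation totals inside the compiled loop, the
    # Generator supplies event details (strain assignment, genotype offsets)
    rng = np.random.default_rng(seed)
    _core.seed_stream(np.random.SeedSequence(seed).generate_state(1)[0])
    mutation_on = params.M_B > 0 or params.M_V > 0

    host_bins = state0.host_bins.astype(np.int64)
    N = state0.host_density.astype(float).copy()
    phage_bins = state0.phage_bins.astype(np.int64)
    V = state0.phage_density.astype(float).copy()
    R = float(state0.R)
    adsm = AdsorptionMatrix.build(host_bins, phage_bins, params.phi, params.s,
                                  scheme=scheme, rho=params.rho)
    table = landscape.table_at(0.0)
    delta = table[host_bins]
    schedule = [st for st in landscape.schedule_times() if st > 0.0]

    traj = Trajectory(params=params, seed=seed, scheme=scheme,
                      landscape_kind=landscape.kind)
    n_bins = params.n_bins

    def snapshot(t):
        traj.samples.append(SystemState(
            t=t, R=R, host_bins=host_bins.copy(), host_density=N.copy(),
            phage_bins=phage_bins.copy(), phage_density=V.copy(),
            rho=params.rho, delta=delta.copy()))

    snapshot(0.0)
    n_steps = params.n_steps
    omega, R0, eps, gamma, K, beta = (params.omega, params.R0, params.epsilon,
                                      params.gamma, params.K, params.beta)
    dt = params.dt
    MB_L = params.M_B * params.L
    MV_L = params.M_V * params.L

    ev_kind = np.zeros(_core.MAX_INLINE_EVENTS, dtype=np.int64)
    ev_parent = np.zeros(_core.MAX_INLINE_EVENTS, dtype=np.int64)
    ev_child = np.zeros(_core.MAX_INLINE_EVENTS, dtype=np.int64)

    step = 0
    while step < n_steps:
        t = step * dt
        if schedule and t >= schedule[0]:
            # second landscape peak stepped up: re-tabulate growth factors
            while schedule and t >= schedule[0]:
                schedule.pop(0)
            table = landscape.table_at(t)
            delta = table[host_bins]

        # next point where the compiled loop must hand control back
        next_stop = ((step // output_stride) + 1) * output_stride
        if schedule:
            next_stop = min(next_stop, int(schedule[0] // dt) + 1)
        next_stop = min(next_stop, n_steps)

        taken, R, N, V, n_eff, n_unassigned, status = _core.advance(
            R, N, V, delta, adsm.theta, omega, R0, eps, gamma, K, beta, dt,
            MB_L, MV_L, params.sigma_B, params.sigma_V, n_bins,
            next_stop - step, mutation_on, ev_kind, ev_parent, ev_child)
        step += taken
        if status:
            raise NumericalFailureError(_STATUS_VAR[status], step=step - 1)

        events = []
        if n_eff:
            for k in range(n_eff):
                if ev_kind[k] == 0:
                    parent = int(host_bins[ev_parent[k]])
                else:
                    parent = int(phage_bins[ev_parent[k]])
                child = parent + int(ev_child[k])
                events.append(MutationEvent(
                    kind="host" if ev_kind[k] == 0 else "phage",
                    parent_bin=parent, offspring_bin=child,
                    range_edge=child < 0 or child > n_bins - 1))
        elif n_unassigned:
            # a mutant burst larger than the inline buffer: assign in Python
            growth, phage_prod = _core.production_rates(R, N, V, delta,
                                                        adsm.theta, gamma, K, beta)
            events = assign_mutant_events(n_unassigned, host_bins, MB_L * growth,
                                          phage_bins, MV_L * phage_prod,
                                          params, rng)
        if events:
            for ev in events:
                if ev.range_edge:
                    traj.range_edge = True
                    continue
                if ev.offspring_bin in (0, n_bins - 1):
                    traj.range_edge = True
                amount = ev.count / params.L
                if ev.kind == "host":
                    i = int(np.nonzero(host_bins == ev.parent_bin)[0][0])
                    N[i] = max(N[i] - amount, 0.0)
                    j = np.nonzero(host_bins == ev.offspring_bin)[0]
                    if j.size:
                        N[j[0]] += amount
                    else:
                        host_bins = np.append(host_bins, ev.offspring_bin)
                        N = np.append(N, amount)
                        delta = np.append(delta, table[ev.offspring_bin])
                        adsm = adsm.with_host(ev.offspring_bin)
                else:
                    i = int(np.nonzero(phage_bins == ev.parent_bin)[0][0])
                    V[i] = max(V[i] - amount, 0.0)
                    j = np.nonzero(phage_bins == ev.offspring_bin)[0]
                    if j.size:
                        V[j[0]] += amount
                    else:
                        phage_bins = np.append(phage_bins, ev.offspring_bin)
                        V = np.append(V, amount)
                        adsm = adsm.with_phage(ev.offspring_bin)
            if record_events and events:
                traj.events.extend((step * dt, ev) for ev in events)

        if (N.size and N.min() < CULL_THRESHOLD) or \
           (V.size and V.min() < CULL_THRESHOLD):
            mh = N >= CULL_THRESHOLD
            mv = V >= CULL_THRESHOLD
            host_bins, N, delta = host_bins[mh], N[mh], delta[mh]
            phage_bins, V = phage_bins[mv], V[mv]
            adsm = adsm.select(mh, mv)

        if step % output_stride == 0 or step == n_steps:
            snapshot(step * dt)

    if traj.samples[-1].t != n_steps * dt:
        snapshot(n_steps * dt)
    return traj
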