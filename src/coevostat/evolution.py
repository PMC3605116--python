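"""Stochastic mutation engine.

Mutation couples to the ecology through production: the expected number of
mutants arising from a strain over a timestep is the mutation rate times the
number of new particles the strain produced in that interval (scaled by the
chemostat volume L).  Mutant counts are drawn Poisson; each mutant's genotype
is the parent's plus a normal deviate (sd sigma_B for hosts, sigma_V for
phage), binned at resolution rho.  Because sigma is comparable to rho, most
offsets round back to the parental bin; such zero-effect mutations are
dropped.  Mutant density is debited from the parent population, so mutation
is a reclassification of newly produced particles and conserves total
density (up to the floor-at-zero edge case for near-empty parents).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _core
from .errors import ConsistencyError
from .params import ModelParameters


@dataclass(frozen=True)
class MutationEvent:
    """One mutant lineage created in a single timestep.

    ``range_edge`` marks events whose offspring bin fell outside the genotype
    grid; such events are never applied, only flagged.
    """

    kind: str            # "host" or "phage"
    parent_bin: int
    offspring_bin: int
    count: int = 1
    range_edge: bool = False


def expected_mutant_rate(state, params: ModelParameters, theta: np.ndarray):
    """Per-strain expected mutant production rates (mutants per minute).

    Host strain i: M_B * L * gamma R N_i delta_i / (R + K).
    Phage strain j: M_V * L * sum_i beta theta_ij N_i V_j.

    ``state`` must carry a ``delta`` attribute (set by the simulator) or the
    rates can be computed directly via :func:`production_rates_from_arrays`.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (state.host_bins.size, state.phage_bins.size):
        raise ConsistencyError(
            f"theta shape {theta.shape} does not match roster "
            f"({state.host_bins.size} hosts, {state.phage_bins.size} phages)")
    growth, phage_prod = _core.production_rates(
        state.R, state.host_density, state.phage_density, state.delta, theta,
        params.gamma, params.K, params.beta)
    return params.M_B * params.L * growth, params.M_V * params.L * phage_prod


def draw_mutants(host_bins, host_rates, phage_bins, phage_rates,
                 params: ModelParameters, rng: np.random.Generator,
                 dt: float | None = None) -> list[MutationEvent]:
    """Draw the mutation events for one timestep.

    Counts are Poisson with mean rate*dt per strain; genotype offsets are
    normal.  The draw order is fixed for reproducibility: host strains in
    ascending bin order, then phage strains in ascending bin order.
    """
    if dt is None:
        dt = params.dt
    host_rates = np.asarray(host_rates, dtype=float)
    phage_rates = np.asarray(phage_rates, dtype=float)
    # superposition: one Poisson draw on the total rate, split multinomially
    # over strains only when mutants actually arise — jointly identical to
    # independent per-strain Poisson counts, and cheap on the common
    # zero-mutant step
    lam = (float(host_rates.sum()) + float(phage_rates.sum())) * dt
    if lam <= 0.0:
        return []
    total = rng.poisson(lam)
    return assign_mutant_events(total, host_bins, host_rates,
                                phage_bins, phage_rates, params, rng)


def assign_mutant_events(total: int, host_bins, host_rates,
                         phage_bins, phage_rates,
                         params: ModelParameters,
                         rng: np.random.Generator) -> list[MutationEvent]:
    """Distribute ``total`` mutants over strains and draw their genotypes.

    The total is split multinomially in proportion to the per-strain rates
    (jointly equivalent to independent per-strain Poisson counts), then each
    mutant's genotype offset is drawn normal and binned.
    """
    if total == 0:
        return []
    host_rates = np.asarray(host_rates, dtype=float)
    phage_rates = np.asarray(phage_rates, dtype=float)
    host_bins = np.asarray(host_bins)
    phage_bins = np.asarray(phage_bins)
    ho = np.argsort(host_bins, kind="stable")
    vo = np.argsort(phage_bins, kind="stable")
    rates = np.concatenate([host_rates[ho], phage_rates[vo]])
    counts = rng.multinomial(total, rates / rates.sum())
    n_hosts = host_bins.size
    n_bins = params.n_bins
    events: list[MutationEvent] = []
    for k, c in enumerate(counts):
        if c == 0:
            continue
        if k < n_hosts:
            kind, parent, sigma = "host", int(host_bins[ho[k]]), params.sigma_B
        else:
            kind, parent, sigma = "phage", int(phage_bins[vo[k - n_hosts]]), params.sigma_V
        for _ in range(c):
            offset = rng.normal(0.0, sigma)
            child = parent + int(round(offset / params.rho))
            if child == parent:
                continue  # zero-effect mutation
            edge = child < 0 or child > n_bins - 1
            events.append(MutationEvent(kind=kind, parent_bin=parent,
                                        offspring_bin=child, count=1,
                                        range_edge=edge))
    return events


def apply_mutations(state, events, params: ModelParameters):
    """Apply mutation events to a community state, returning the new state.

    Each applied event moves count/L density units from the parent bin to the
    offspring bin (creating the offspring population if absent); the parent
    is floored at zero.  Events flagged ``range_edge`` are skipped.  The
    result is independent of the order in which events are applied.
    """
    from .dynamics import SystemState  # local import to avoid a cycle

    host_bins = state.host_bins.copy()
    N = state.host_density.copy()
    phage_bins = state.phage_bins.copy()
    V = state.phage_density.copy()
    new_hosts: list[int] = []
    new_phages: list[int] = []
    for ev in events:
        if ev.range_edge:
            continue
        if ev.kind == "host":
            bins, dens, added = host_bins, N, new_hosts
        else:
            bins, dens, added = phage_bins, V, new_phages
        amount = ev.count / params.L
        where = np.nonzero(bins == ev.parent_bin)[0]
        if where.size == 0:
            raise ConsistencyError(f"mutation event references absent parent bin {ev.parent_bin}")
        dens[where[0]] = max(dens[where[0]] - amount, 0.0)
        child = np.nonzero(bins == ev.offspring_bin)[0]
        if child.size:
            dens[child[0]] += amount
        else:
            if ev.kind == "host":
                host_bins = np.append(host_bins, ev.offspring_bin)
                N = np.append(N, amount)
            else:
                phage_bins = np.append(phage_bins, ev.offspring_bin)
                V = np.append(V, amount)
            added.append(ev.offspring_bin)
    return SystemState(t=state.t, R=state.R,
                       host_bins=host_bins, host_density=N,
                       phage_bins=phage_bins, phage_density=V,
                       rho=state.rho)
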