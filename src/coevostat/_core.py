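"""Numba-compiled inner kernels for the chemostat ODE integration.

These operate on raw arrays; :mod:`coevostat.dynamics` provides the public,
object-level interface.  Keeping the per-step arithmetic compiled lets a full
2e6-step run finish in seconds while the surrounding Python loop handles the
(rare) stochastic mutation and extinction events.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def derivs(R, N, V, delta, theta, omega, R0, eps, gamma, K, beta):
    """Right-hand sides of the chemostat equations.

    dR/dt = -omega (R - R0) - sum_i eps gamma R N_i delta_i / (R + K)
    dN_i/dt = -omega N_i + gamma R N_i delta_i / (R + K) - sum_j theta_ij N_i V_j
    dV_j/dt = -omega V_j + sum_i beta theta_ij N_i V_j
    """
    monod = gamma * R / (R + K)
    growth = monod * delta * N
    dR = -omega * (R - R0) - eps * np.sum(growth)
    if V.size > 0:
        lys = theta @ V          # per-capita lysis rate per host strain
        dN = -omega * N + growth - N * lys
        dV = (-omega + beta * (theta.T @ N)) * V
    else:
        dN = -omega * N + growth
        dV = np.zeros(0)
    return dR, dN, dV


@njit(cache=True)
def rk4_step(R, N, V, delta, theta, omega, R0, eps, gamma, K, beta, dt):
    """One classical 4th-order Runge-Kutta step.

    Returns (R', N', V', status); status is 0 on success, or 1/2/3 if the
    updated R/N/V respectively contains a non-finite value.
    """
    k1R, k1N, k1V = derivs(R, N, V, delta, theta, omega, R0, eps, gamma, K, beta)
    k2R, k2N, k2V = derivs(R + 0.5 * dt * k1R, N + 0.5 * dt * k1N, V + 0.5 * dt * k1V,
                           delta, theta, omega, R0, eps, gamma, K, beta)
    k3R, k3N, k3V = derivs(R + 0.5 * dt * k2R, N + 0.5 * dt * k2N, V + 0.5 * dt * k2V,
                           delta, theta, omega, R0, eps, gamma, K, beta)
    k4R, k4N, k4V = derivs(R + dt * k3R, N + dt * k3N, V + dt * k3V,
                           delta, theta, omega, R0, eps, gamma, K, beta)
    R2 = R + dt / 6.0 * (k1R + 2.0 * k2R + 2.0 * k3R + k4R)
    N2 = N + dt / 6.0 * (k1N + 2.0 * k2N + 2.0 * k3N + k4N)
    V2 = V + dt / 6.0 * (k1V + 2.0 * k2V + 2.0 * k3V + k4V)
    status = 0
    if not np.isfinite(R2):
        status = 1
    for i in range(N2.size):
        if not np.isfinite(N2[i]):
            status = 2
    for j in range(V2.size):
        if not np.isfinite(V2[j]):
            status = 3
    return R2, N2, V2, status


@njit(cache=True)
def seed_stream(seed):
    """Seed numba's internal RNG stream (used for per-step mutation totals)."""
    np.random.seed(seed)


MAX_INLINE_EVENTS = 64


@njit(cache=True)
def advance(R, N, V, delta, theta, omega, R0, eps, gamma, K, beta, dt,
            MB_L, MV_L, sigma_B, sigma_V, n_bins, max_steps, mutation_on,
            ev_kind, ev_parent, ev_child):
    """Integrate up to ``max_steps`` RK4 steps, stopping early on events.

    After each step the total expected mutant count lam = (M_B L * host
    production + M_V L * phage production) * dt is evaluated and a Poisson
    total drawn from numba's RNG stream.  Each mutant is assigned to a
    parent strain in proportion to the per-strain production rates (hosts in
    roster order, then phage) and given a normal genotype offset; mutants
    whose offset rounds back to the parental bin are dropped in place.
    Effective mutations are written to the ``ev_*`` output buffers
    (kind 0 = host, 1 = phage; parent as roster index; child as bin, possibly
    outside [0, n_bins-1] for range-edge overshoots) and control returns to
    the caller.  The loop also exits when any population falls below the
    extinction threshold.

    Returns (steps_taken, R, N, V, n_eff, n_unassigned, status); if the
    per-step mutant total exceeds the event buffer, it is returned in
    ``n_unassigned`` for the caller to assign instead.  ``status`` as in
    rk4_step; 0 means no numerical failure.
    """
    steps = 0
    while steps < max_steps:
        R2, N2, V2, status = rk4_step(R, N, V, delta, theta, omega, R0, eps,
                                      gamma, K, beta, dt)
        steps += 1
        if status:
            return steps, R2, N2, V2, 0, 0, status
        R, N, V = R2, N2, V2
        needs_exit = False
        n_eff = 0
        if mutation_on:
            monod = gamma * R / (R + K)
            growth_sum = 0.0
            for i in range(N.size):
                growth_sum += monod * delta[i] * N[i]
            pp_sum = 0.0
            if V.size > 0:
                prod = theta.T @ N
                for j in range(V.size):
                    pp_sum += beta * prod[j] * V[j]
            host_tot = MB_L * growth_sum
            total_rate = host_tot + MV_L * pp_sum
            lam = total_rate * dt
            if lam > 0.0:
                n_mut = np.random.poisson(lam)
                if n_mut > MAX_INLINE_EVENTS:
                    return steps, R, N, V, 0, n_mut, 0
                for _ in range(n_mut):
                    u = np.random.random() * total_rate
                    kind = 0
                    parent_idx = -1
                    if u < host_tot:
                        acc = 0.0
                        for i in range(N.size):
                            acc += MB_L * monod * delta[i] * N[i]
                            if u <= acc:
                                parent_idx = i
                                break
                        if parent_idx < 0:
                            parent_idx = N.size - 1
                        parent_bin = 0  # placeholder; caller maps index->bin
                        sigma = sigma_B
                    else:
                        kind = 1
                        acc = host_tot
                        prod = theta.T @ N
                        for j in range(V.size):
                            acc += MV_L * beta * prod[j] * V[j]
                            if u <= acc:
                                parent_idx = j
                                break
                        if parent_idx < 0:
                            parent_idx = V.size - 1
                        sigma = sigma_V
                    offset = np.random.normal(0.0, sigma)
                    # offset is in genotype units; one bin spans rho = 1/(n_bins-1)
                    shift = int(round(offset * (n_bins - 1)))
                    if shift == 0:
                        continue  # zero-effect mutation
                    if n_eff < ev_kind.size:
                        ev_kind[n_eff] = kind
                        ev_parent[n_eff] = parent_idx
                        ev_child[n_eff] = shift  # relative; caller adds parent bin
                        n_eff += 1
                if n_eff > 0:
                    needs_exit = True
        for i in range(N.size):
            if N[i] < 1.0:
                needs_exit = True
        for j in range(V.size):
            if V[j] < 1.0:
                needs_exit = True
        if needs_exit:
            return steps, R, N, V, n_eff, 0, 0
    return steps, R, N, V, 0, 0, 0


@njit(cache=True)
def production_rates(R, N, V, delta, theta, gamma, K, beta):
    """Gross production (new particles per min per ml) for each strain.

    Host strain i produces gamma R N_i delta_i / (R + K) new cells;
    phage strain j produces sum_i beta theta_ij N_i V_j new virions.
    """
    growth = gamma * R / (R + K) * delta * N
    if V.size > 0:
        phage_prod = beta * (theta.T @ N) * V
    else:
        phage_prod = np.zeros(0)
    return growth, phage_prod
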