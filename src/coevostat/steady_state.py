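"""Closed-form equilibrium theory for the strict lock-and-key chemostat.

For a single host strain without phage the chemostat has the classical R*
equilibrium: growth balances washout at the limiting resource concentration

    Rbar(delta) = omega K / (gamma delta - omega),

with equilibrium density Nbar fixed by the resource balance.  With a
perfect-match phage the host is instead predator-limited at

    Nhat = omega / (beta phi),

independent of its growth rate, while the phage equilibrates at a density
that rises with host growth rate.  Because every phage-supported host sits at
the same density Nhat, a community of strains with distinct growth factors
draws resource down in a computable cascade: after the i fastest strains have
established, the resource settles at the positive root Rhat_i of a quadratic.
A new strain i+1 can invade while Rhat_i exceeds its own Rbar_{i+1}; the
first strain whose Rbar exceeds the prevailing Rhat becomes resource-limited
(too sparse to support phage) and closes the community.  The number of
coexisting strains x found this way is independent of introduction order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CannotEstablishError, InvalidParameterError, NoGrowthError
from .params import ModelParameters


def rbar(delta: float, params: ModelParameters) -> float:
    """Limiting resource concentration R* for a strain with growth factor delta."""
    g = params.gamma * delta - params.omega
    if g <= 0:
        raise NoGrowthError(
            f"gamma*delta = {params.gamma * delta:.3g} <= omega = {params.omega:.3g}: "
            "strain cannot persist at any resource concentration")
    return params.omega * params.K / g


def nbar(delta: float, params: ModelParameters) -> float:
    """Phage-free equilibrium host density at the strain's own R*.

    Algebraically equal to the resource balance
    omega (R0 - Rbar)(Rbar + K) / (epsilon gamma delta Rbar).
    """
    rb = rbar(delta, params)
    if rb > params.R0:
        raise CannotEstablishError(
            f"Rbar = {rb:.4g} > R0 = {params.R0:.4g}: strain washes out")
    return params.omega * (params.R0 - rb) * (rb + params.K) / (
        params.epsilon * params.gamma * delta * rb)


def phage_limited(params: ModelParameters, delta: float,
                  R: float | None = None) -> tuple[float, float]:
    """Equilibrium (Nhat, Vhat) for a host with its perfect-match phage.

    Nhat = omega/(beta phi) regardless of delta.  Vhat depends on the ambient
    resource level; by default the single-pair coexistence resource level is
    used (the root of the resource balance with N = Nhat).
    """
    nhat = params.omega / (params.beta * params.phi)
    if R is None:
        R = rhat(1, [delta], params)
    vhat = -params.omega / params.phi + (params.gamma / params.phi) * R * delta / (R + params.K)
    return nhat, vhat


def rhat(i: int, delta_pool, params: ModelParameters) -> float:
    """Equilibrium resource after the i fastest strains are phage-limited.

    Positive root of (R - R0)(R + K) + C R = 0 with
    C = epsilon gamma sum_{j<=i} delta_j / (beta phi), i.e.

        Rhat_i = [ (R0 - K - C) + sqrt((R0 - K - C)^2 + 4 R0 K) ] / 2.
    """
    delta_pool = np.asarray(delta_pool, dtype=float)
    if not 1 <= i <= delta_pool.size:
        raise InvalidParameterError(f"i must be in [1, {delta_pool.size}], got {i}")
    C = params.epsilon * params.gamma * delta_pool[:i].sum() / (params.beta * params.phi)
    b = params.R0 - params.K - C
    disc = b * b + 4.0 * params.R0 * params.K
    return (b + np.sqrt(disc)) / 2.0


@dataclass(frozen=True)
class SteadyStatePrediction:
    """Bundle of the analytic equilibrium quantities for a strain pool."""

    delta_pool: tuple[float, ...]
    rbar_seq: tuple[float, ...]     # limiting resource per strain
    rhat_seq: tuple[float, ...]     # phage-limited resource after i strains
    n_hat: float                    # phage-limited host density (delta-independent)
    r_star: float                   # min Rbar (fastest strain)
    n_star: float                   # resource-limited carrying capacity
    diversity: int                  # number of coexisting strains x
    all_phage_limited: bool         # True when every pool strain invades


def steady_state_diversity(delta_pool, params: ModelParameters,
                           full: bool = False):
    """Number of coexisting host strains under strict lock-and-key infection.

    Walks the sequential-introduction cascade: x is the smallest i with
    Rbar_i > Rhat_i (strain i is resource-limited and closes the community).
    If no strain in the pool is resource-limited, x equals the pool size and
    the prediction is flagged ``all_phage_limited``.

    With ``full=True`` returns the complete :class:`SteadyStatePrediction`.
    """
    delta_pool = np.asarray(delta_pool, dtype=float)
    if delta_pool.size == 0:
        raise InvalidParameterError("delta pool must be non-empty")
    if np.any(np.diff(delta_pool) >= 0):
        raise InvalidParameterError("delta pool must be strictly descending")
    rbars = [rbar(d, params) for d in delta_pool]
    rhats = [rhat(i, delta_pool, params) for i in range(1, delta_pool.size + 1)]
    x = None
    for i, (rb, rh) in enumerate(zip(rbars, rhats), start=1):
        if rb > rh:
            x = i
            break
    all_pl = x is None
    if all_pl:
        x = delta_pool.size
    if not full:
        return x
    return SteadyStatePrediction(
        delta_pool=tuple(delta_pool), rbar_seq=tuple(rbars), rhat_seq=tuple(rhats),
        n_hat=params.omega / (params.beta * params.phi),
        r_star=rbars[0], n_star=nbar(delta_pool[0], params),
        diversity=x, all_phage_limited=all_pl)


@dataclass(frozen=True)
class EqualGrowthPrediction:
    """Outcome predicted when all strains share one growth factor."""

    delta: float
    n_strains: int
    rbar: float
    n_hat: float
    coexistence_stable: bool   # always False: phage-supported coexistence collapses
    statement: str


def equal_growth_collapse_check(params: ModelParameters, delta: float,
                                n_strains: int) -> EqualGrowthPrediction:
    """Corollary: with equal growth rates, phage-supported coexistence fails.

    All strains share the same Rbar, so the first strain to establish without
    phage draws resource to that common Rbar, at which every phage-limited
    strain (held at Nhat with extra mortality from its phage) declines; host
    or phage extinctions follow until only phage-free strains remain.  Used
    as the oracle for the strict-scheme equal-delta simulation test.
    """
    rb = rbar(delta, params)
    return EqualGrowthPrediction(
        delta=delta, n_strains=n_strains, rbar=rb,
        n_hat=params.omega / (params.beta * params.phi),
        coexistence_stable=False,
        statement="at most the phage-free strains persist; all phage are lost",
    )


def diversity_scan(R0_values, delta_pool, params: ModelParameters):
    """Steady-state diversity as a function of resource supply.

    Returns a DataFrame with one row per R0: (R0, x, all_phage_limited,
    Rhat sequence as semicolon-joined string).
    """
    import pandas as pd

    rows = []
    for r0 in R0_values:
        p = params.replace(R0=float(r0))
        pred = steady_state_diversity(delta_pool, p, full=True)
        rows.append({
            "R0": float(r0), "x": pred.diversity,
            "all_phage_limited": pred.all_phage_limited,
            "rhat_seq": ";".join(f"{v:.6g}" for v in pred.rhat_seq),
        })
    return pd.DataFrame(rows)
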