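"""Derived quantities: fitness fields, growth-lysis correlation, genotype
range, strain richness, and maximum community growth rate.

The fitness field evaluates the hypothetical net per-capita rate of density
change for *every* genotype on the grid, given the current resource level and
the extant community — i.e. the time-dependent adaptive landscape the
populations actually experience, with the host field decomposed into its
growth (resource uptake) and lysis (phage predation) components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import UndefinedObservableError
from .infection import adsorption_gaussian, adsorption_strict
from .landscapes import GrowthLandscape, genotype_grid
from .params import ModelParameters


@dataclass(frozen=True)
class FitnessField:
    """Per-genotype hypothetical rates at one timepoint.

    ``dN_dt`` and ``dV_dt`` are per-capita net rates (1/min) for a rare
    invader of each genotype; ``growth`` and ``lysis`` are the host field's
    two components, so dN_dt = growth - lysis - omega.
    """

    t: float
    grid: np.ndarray
    dN_dt: np.ndarray
    growth: np.ndarray
    lysis: np.ndarray
    dV_dt: np.ndarray

    def to_dataframe(self):
        """Dense grid table (t, genotype, dN_dt, growth, lysis, dV_dt)."""
        import pandas as pd

        return pd.DataFrame({
            "t": self.t, "genotype": self.grid, "dN_dt": self.dN_dt,
            "growth": self.growth, "lysis": self.lysis, "dV_dt": self.dV_dt,
        })


def _theta_row(x_traits: np.ndarray, other_traits: np.ndarray,
               params: ModelParameters, scheme: str) -> np.ndarray:
    """Kernel between every grid genotype (rows) and the community (cols)."""
    if scheme == "strict":
        xb = np.rint(x_traits / params.rho).astype(np.int64)
        ob = np.rint(other_traits / params.rho).astype(np.int64)
        return adsorption_strict(xb[:, None], ob[None, :], params.phi)
    return adsorption_gaussian(x_traits[:, None], other_traits[None, :],
                               params.phi, params.s)


def fitness_field(state, params: ModelParameters, landscape: GrowthLandscape,
                  scheme: str = "gaussian") -> FitnessField:
    """Hypothetical per-capita rates for all grid genotypes at state time."""
    grid = genotype_grid(params.rho)
    table = landscape.table_at(state.t)
    monod = params.gamma * state.R / (state.R + params.K)
    growth = table * monod
    theta_hp = _theta_row(grid, state.phage_genotypes, params, scheme)
    lysis = theta_hp @ state.phage_density if state.phage_bins.size else np.zeros(grid.size)
    dN = growth - lysis - params.omega
    theta_ph = _theta_row(grid, state.host_genotypes, params, scheme)
    production = params.beta * (theta_ph @ state.host_density) if state.host_bins.size \
        else np.zeros(grid.size)
    dV = production - params.omega
    return FitnessField(t=state.t, grid=grid, dN_dt=dN, growth=growth,
                        lysis=lysis, dV_dt=dV)


def _qualifying(state, threshold: float, which: str = "host"):
    dens = state.host_density if which == "host" else state.phage_density
    bins = state.host_bins if which == "host" else state.phage_bins
    total = dens.sum()
    if total == 0:
        return bins[:0], dens[:0]
    mask = dens > threshold * total
    return bins[mask], dens[mask]


def growth_lysis_correlation(state, params: ModelParameters,
                             density_fraction_threshold: float = 0.01,
                             scheme: str = "gaussian",
                             landscape: GrowthLandscape | None = None):
    """Pearson correlation of per-capita growth vs lysis rates across strains.

    Only host strains forming more than ``density_fraction_threshold`` of
    total host density qualify.  Significance is the standard t-transform
    two-sided p-value.

    Raises
    ------
    UndefinedObservableError
        Fewer than 3 qualifying strains, or zero variance in either rate.
    """
    bins, dens = _qualifying(state, density_fraction_threshold, "host")
    if bins.size < 3:
        raise UndefinedObservableError(
            f"correlation needs >= 3 qualifying strains, have {bins.size}")
    if state.delta is not None and bins.size == state.host_bins.size:
        delta = state.delta
    else:
        if landscape is None:
            raise UndefinedObservableError("need a landscape (or cached delta) for growth rates")
        delta = landscape.table_at(state.t)[bins]
    monod = params.gamma * state.R / (state.R + params.K)
    growth = np.asarray(delta, float) * monod
    traits = bins * params.rho
    theta = _theta_row(np.asarray(traits, float), state.phage_genotypes, params, scheme)
    lysis = theta @ state.phage_density if state.phage_bins.size else np.zeros(bins.size)
    if np.ptp(growth) == 0 or np.ptp(lysis) == 0:
        raise UndefinedObservableError("zero variance in growth or lysis rates")
    r, p = stats.pearsonr(growth, lysis)
    return float(r), float(p)


def genotype_range(state, density_fraction_threshold: float = 0.01) -> float:
    """h_max - h_min over host strains above the density-fraction threshold."""
    bins, _ = _qualifying(state, density_fraction_threshold, "host")
    if bins.size == 0:
        raise UndefinedObservableError("no qualifying host strains")
    return float((bins.max() - bins.min()) * state.rho)


def strain_richness(state, which: str = "host", gap: int = 1) -> int:
    """Number of genotype clusters for one population class.

    A cluster is a maximal run of occupied bins in which consecutive occupied
    bins are separated by at most ``gap`` - 1 empty bins; with the default
    ``gap = 1``, adjacent occupied bins merge and any empty bin separates
    clusters.
    """
    bins = state.host_bins if which == "host" else state.phage_bins
    if bins.size == 0:
        return 0
    b = np.sort(np.unique(bins))
    return 1 + int(np.sum(np.diff(b) > gap))


def max_growth_rate(state, landscape: GrowthLandscape,
                    as_rate: bool = True, gamma: float | None = None) -> float:
    """Maximum growth scaling delta over extant host strains.

    With ``as_rate`` (default) the value is reported as delta * gamma, the
    scale used when plotting growth-rate landscapes; ``gamma`` defaults to
    the benchmark uptake rate if not given.
    """
    if state.host_bins.size == 0:
        raise UndefinedObservableError("empty host community")
    table = landscape.table_at(state.t)
    dmax = float(table[state.host_bins].max())
    if not as_rate:
        return dmax
    if gamma is None:
        from .params import DEFAULT_PARAMS

        gamma = DEFAULT_PARAMS.gamma
    return dmax * gamma


def correlation_windows(trajectory, params: ModelParameters,
                        landscape: GrowthLandscape,
                        fraction: float = 0.05, scheme: str = "gaussian"):
    """Growth-lysis correlations pooled over early/middle/late run windows.

    Each window is the first, middle, or last ``fraction`` of sampled
    timepoints; strains from all samples in a window are pooled before the
    correlation is computed.  Samples with fewer than 3 qualifying strains
    contribute their strains to the pool but windows that end up with fewer
    than 3 points in total are reported as None.
    """
    samples = trajectory.samples
    n = len(samples)
    k = max(1, int(round(fraction * n)))
    windows = {
        "early": samples[:k],
        "middle": samples[(n - k) // 2:(n - k) // 2 + k],
        "late": samples[-k:],
    }
    out = {}
    for name, group in windows.items():
        gs, ls = [], []
        for s in group:
            bins, _ = _qualifying(s, 0.01, "host")
            if bins.size == 0:
                continue
            delta = landscape.table_at(s.t)[bins]
            monod = params.gamma * s.R / (s.R + params.K)
            theta = _theta_row(bins * params.rho, s.phage_genotypes, params, scheme)
            lys = theta @ s.phage_density if s.phage_bins.size else np.zeros(bins.size)
            gs.append(delta * monod)
            ls.append(lys)
        if not gs:
            out[name] = None
            continue
        g = np.concatenate(gs)
        l = np.concatenate(ls)
        if g.size < 3 or np.ptp(g) == 0 or np.ptp(l) == 0:
            out[name] = None
        else:
            r, p = stats.pearsonr(g, l)
            out[name] = (float(r), float(p))
    return out
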