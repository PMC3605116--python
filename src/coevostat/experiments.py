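"""Pre-packaged experiment designs.

Each experiment reproduces one of the study designs on the model — the
single-run diversification case study, paired with/without-phage evolvability
comparisons, the genotype-range parameter grid, the rugged-landscape
ensembles, and the one-at-a-time parameter sensitivity scan — at a
configurable scale.  ``scale`` multiplies the run duration (default 0.1, a
ten-fold reduction of the full-length designs); replicate counts are
arguments.  Runs in which mutation reaches the edge of the genotype range
are flagged and excluded from ensemble statistics (their count is reported).

Everything is reproducible from the master seed: replicate seeds are spawned
deterministically with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import SystemState, Trajectory, simulate
from .errors import UndefinedObservableError
from .landscapes import (GrowthLandscape, make_dynamic_two_peak,
                         make_multi_peak, make_rugged_slope, make_single_peak)
from .observables import (correlation_windows, genotype_range, max_growth_rate,
                          strain_richness)
from .params import ModelParameters

#: ensemble mutation rates used by the evolvability and range experiments
ENSEMBLE_M = 1e-5


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2**31) from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


@dataclass
class EnsembleResult:
    """Replicate-level table plus metadata for one experiment.

    ``table`` has one row per run including discarded (range-edge) runs;
    statistics helpers operate on the kept rows only.
    """

    experiment: str
    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def kept(self) -> pd.DataFrame:
        if "discarded" in self.table:
            return self.table[~self.table["discarded"]]
        return self.table

    @property
    def n_discarded(self) -> int:
        if "discarded" in self.table:
            return int(self.table["discarded"].sum())
        return 0

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# experiment: {self.experiment}\n")
            for k, v in self.meta.items():
                fh.write(f"# {k}: {v!r}\n")
            self.table.to_csv(fh, index=False)


@dataclass
class CaseStudyResult:
    trajectory: Trajectory
    control: Trajectory
    correlations: dict
    host_richness: int
    phage_richness: int
    control_richness: int
    total_host_density: float
    n_hat: float


def run_case_study(seed: int = 0, params: ModelParameters | None = None,
                   scale: float = 0.1, output_stride: int = 2000) -> CaseStudyResult:
    """Single-peak diversification case study with a phage-free control.

    Both runs start from one host strain at h = 0.2 (the coevolutionary run
    adds a perfect-match phage) and share all other parameters.
    """
    if params is None:
        params = ModelParameters()
    params = params.replace(T=params.T * scale)
    landscape = make_single_peak(params.delta_min, params.delta_max, params.rho)
    traj = simulate(params, landscape, seed=seed, output_stride=output_stride)
    control = simulate(params.replace(V_init=0.0), landscape, seed=seed,
                       output_stride=output_stride)
    corr = correlation_windows(traj, params, landscape)
    return CaseStudyResult(
        trajectory=traj, control=control, correlations=corr,
        host_richness=strain_richness(traj.final, "host"),
        phage_richness=strain_richness(traj.final, "phage"),
        control_richness=strain_richness(control.final, "host"),
        total_host_density=traj.final.total_host_density,
        n_hat=params.omega / (params.beta * params.phi),
    )


def _hillclimb_peak(table: np.ndarray, start_bin: int) -> float:
    """Growth factor of the local maximum reached by strict hillclimbing."""
    i = start_bin
    while True:
        left = table[i - 1] if i > 0 else -np.inf
        right = table[i + 1] if i < table.size - 1 else -np.inf
        if left <= table[i] and right <= table[i]:
            return float(table[i])
        i = i - 1 if left > right else i + 1


def run_paired_evolvability(kind: str = "multi_peak", n_pairs: int = 10,
                            seed: int = 0, scale: float = 0.1,
                            params: ModelParameters | None = None,
                            n_blocks: int = 5, span: int = 5,
                            s: float | None = None,
                            output_stride: int = 20000) -> EnsembleResult:
    """Paired with/without-phage runs on a valley-bearing landscape.

    Pairs share the landscape and the replicate seed; the only difference is
    ``V_init = 0`` for the no-phage partner.  Mutation rates default to the
    ensemble setting (1e-5 for both classes) so the scaled-down duration
    carries a comparable mutational input to the full-length designs.
    """
    if params is None:
        params = ModelParameters(M_B=ENSEMBLE_M, M_V=ENSEMBLE_M)
    params = params.replace(T=params.T * scale)
    if s is None:
        # specialist phage drive valley crossing; the default specificity is
        # chosen per landscape family (see docs/methods.md)
        s = {"multi_peak": 400.0, "rugged_slope": 1000.0}.get(kind)
    if s is not None:
        params = params.replace(s=s)
    seeds = spawn_seeds(seed, n_pairs)
    rows = []
    for k, child in enumerate(seeds):
        if kind == "multi_peak":
            landscape = make_multi_peak(n_blocks, params.delta_min,
                                        params.delta_max, params.rho)
        elif kind == "rugged_slope":
            landscape = make_rugged_slope(span, seed=child,
                                          delta_min=params.delta_min,
                                          delta_max=params.delta_max, rho=params.rho)
        elif kind == "dynamic_two_peak":
            landscape = make_dynamic_two_peak(params.delta_min, params.delta_max,
                                              rho=params.rho, T=params.T)
        else:
            raise ValueError(f"unsupported landscape kind {kind!r}")
        with_phage = simulate(params, landscape, seed=child,
                              output_stride=output_stride)
        no_phage = simulate(params.replace(V_init=0.0), landscape, seed=child,
                            output_stride=output_stride)
        table0 = landscape.table_at(params.T)
        mg_w = max_growth_rate(with_phage.final, landscape, as_rate=False)
        mg_n = max_growth_rate(no_phage.final, landscape, as_rate=False)
        local_peak = _hillclimb_peak(landscape.table_at(0.0),
                                     int(round(params.h_init / params.rho)))
        row = {
            "pair": k, "seed": child,
            "max_delta_with_phage": mg_w, "max_delta_no_phage": mg_n,
            "improved": mg_w > mg_n,
            "local_peak_delta": local_peak,
            "global_max_delta": float(table0.max()),
            "no_phage_reached_global": mg_n >= float(table0.max()) - 1e-12,
            "discarded": with_phage.range_edge or no_phage.range_edge,
        }
        if kind == "multi_peak":
            b_w = landscape.meta["b_w"]
            adv = (int(no_phage.final.host_bins.max() * params.rho / b_w)
                   - int(params.h_init / b_w))
            row["no_phage_blocks_advanced"] = adv
        rows.append(row)
    return EnsembleResult(
        experiment=f"paired_evolvability_{kind}",
        table=pd.DataFrame(rows),
        meta={"kind": kind, "n_pairs": n_pairs, "seed": seed, "scale": scale,
              "T": params.T, "s": params.s, "M_B": params.M_B, "M_V": params.M_V,
              "n_blocks": n_blocks, "span": span},
    )


def run_range_sensitivity(R0_values=(1.7, 2.2, 2.7),
                          delta_min_values=(0.8, 0.9, 1.0),
                          s_values=(100, 400, 1000),
                          reps: int = 10, seed: int = 0, scale: float = 0.1,
                          params: ModelParameters | None = None,
                          output_stride: int = 50000) -> EnsembleResult:
    """Final-community genotype range over a (R0, delta_min, s) grid.

    Follows the standing-variation design: single-peak landscape, both
    strains started at the optimum h = v = 0.5, ensemble per grid cell.
    """
    if params is None:
        params = ModelParameters(M_B=ENSEMBLE_M, M_V=ENSEMBLE_M,
                                 h_init=0.5, v_init=0.5, T=5e6)
    params = params.replace(T=params.T * scale)
    cells = [(r0, dmin, s) for r0 in R0_values for dmin in delta_min_values
             for s in s_values]
    seeds = spawn_seeds(seed, len(cells) * reps)
    rows = []
    i = 0
    for r0, dmin, s in cells:
        cell_params = params.replace(R0=r0, delta_min=dmin, s=s)
        landscape = make_single_peak(dmin, cell_params.delta_max, cell_params.rho)
        for rep in range(reps):
            child = seeds[i]; i += 1
            traj = simulate(cell_params, landscape, seed=child,
                            output_stride=output_stride)
            try:
                rng = genotype_range(traj.final)
            except UndefinedObservableError:
                rng = np.nan
            rows.append({"R0": r0, "delta_min": dmin, "s": s, "rep": rep,
                         "seed": child, "genotype_range": rng,
                         "discarded": traj.range_edge})
    return EnsembleResult(
        experiment="range_sensitivity", table=pd.DataFrame(rows),
        meta={"reps": reps, "seed": seed, "scale": scale, "T": params.T,
              "M_B": params.M_B, "M_V": params.M_V},
    )


def run_rugged_ensemble(spans=(1, 3, 5, 7), s_values=(100, 500, 1000),
                        n_landscapes: int = 5, seed: int = 0, scale: float = 0.1,
                        params: ModelParameters | None = None,
                        output_stride: int = 50000) -> EnsembleResult:
    """Adaptation on rugged-slope landscapes: no-phage vs phage across s.

    For each smoothing span a fresh ensemble of landscapes is generated; on
    each landscape one no-phage run is followed by coevolutionary runs at
    each specificity value, all starting from h = v = 0.2.
    """
    if params is None:
        params = ModelParameters(M_B=ENSEMBLE_M, M_V=ENSEMBLE_M)
    params = params.replace(T=params.T * scale)
    seeds = spawn_seeds(seed, len(spans) * n_landscapes)
    rows = []
    i = 0
    for span in spans:
        for k in range(n_landscapes):
            child = seeds[i]; i += 1
            landscape = make_rugged_slope(span, seed=child,
                                          delta_min=params.delta_min,
                                          delta_max=params.delta_max,
                                          rho=params.rho)
            gmax = float(landscape.table.max())
            no_phage = simulate(params.replace(V_init=0.0), landscape,
                                seed=child, output_stride=output_stride)
            mg_n = max_growth_rate(no_phage.final, landscape, as_rate=False)
            rows.append({"span": span, "landscape": k, "s": np.nan,
                         "phage": False, "seed": child, "max_delta": mg_n,
                         "global_max_delta": gmax,
                         "reached_global": mg_n >= gmax - 1e-12,
                         "discarded": no_phage.range_edge})
            for s in s_values:
                traj = simulate(params.replace(s=s), landscape, seed=child,
                                output_stride=output_stride)
                mg = max_growth_rate(traj.final, landscape, as_rate=False)
                rows.append({"span": span, "landscape": k, "s": s,
                             "phage": True, "seed": child, "max_delta": mg,
                             "global_max_delta": gmax,
                             "reached_global": mg >= gmax - 1e-12,
                             "discarded": traj.range_edge})
    return EnsembleResult(
        experiment="rugged_ensemble", table=pd.DataFrame(rows),
        meta={"spans": tuple(spans), "s_values": tuple(s_values),
              "n_landscapes": n_landscapes, "seed": seed, "scale": scale,
              "T": params.T},
    )


SENSITIVITY_PARAMS = ("R0", "gamma", "K", "omega", "epsilon", "beta", "phi")


def run_parameter_sensitivity(factors=(0.5, 1.5), reps: int = 3, seed: int = 0,
                              scale: float = 0.1,
                              params: ModelParameters | None = None,
                              output_stride: int = 50000) -> EnsembleResult:
    """One-at-a-time parameter scan, final state normalised to benchmark.

    Each of R0, gamma, K, omega, epsilon, beta and phi is multiplied in turn
    by each factor; final resource, total densities and strain richness are
    reported relative to the benchmark ensemble mean.
    """
    if params is None:
        params = ModelParameters()
    params = params.replace(T=params.T * scale)
    cases = [("benchmark", 1.0)] + [(p_, f) for p_ in SENSITIVITY_PARAMS
                                    for f in factors]
    seeds = spawn_seeds(seed, len(cases) * reps)
    landscape = make_single_peak(params.delta_min, params.delta_max, params.rho)
    rows = []
    i = 0
    for name, factor in cases:
        run_params = params if name == "benchmark" else params.replace(
            **{name: getattr(params, name) * factor})
        for rep in range(reps):
            child = seeds[i]; i += 1
            traj = simulate(run_params, landscape, seed=child,
                            output_stride=output_stride)
            f = traj.final
            rows.append({"param": name, "factor": factor, "rep": rep,
                         "seed": child, "R": f.R,
                         "total_N": f.total_host_density,
                         "total_V": f.total_phage_density,
                         "host_richness": strain_richness(f, "host"),
                         "phage_richness": strain_richness(f, "phage"),
                         "discarded": traj.range_edge})
    table = pd.DataFrame(rows)
    bench = table[(table["param"] == "benchmark") & ~table["discarded"]]
    for col in ("R", "total_N", "total_V", "host_richness", "phage_richness"):
        table[f"{col}_rel"] = table[col] / bench[col].mean()
    return EnsembleResult(
        experiment="parameter_sensitivity", table=table,
        meta={"factors": tuple(factors), "reps": reps, "seed": seed,
              "scale": scale, "T": params.T},
    )


def run_mutation_asymmetry(n_seeds: int = 5, seed: int = 0, scale: float = 0.1,
                           M_B: float = 1e-5, M_V_low: float = 1e-7,
                           params: ModelParameters | None = None,
                           output_stride: int = 50000) -> EnsembleResult:
    """Phage persistence under symmetric vs strongly asymmetric mutation.

    With M_V << M_B the phage cannot track their diversifying hosts and are
    expected to go extinct in most runs; with M_V = M_B they persist.
    """
    if params is None:
        params = ModelParameters()
    params = params.replace(T=params.T * scale)
    landscape = make_single_peak(params.delta_min, params.delta_max, params.rho)
    seeds = spawn_seeds(seed, n_seeds)
    rows = []
    for k, child in enumerate(seeds):
        for label, mv in (("asymmetric", M_V_low), ("symmetric", M_B)):
            traj = simulate(params.replace(M_B=M_B, M_V=mv), landscape,
                            seed=child, output_stride=output_stride)
            rows.append({"case": label, "rep": k, "seed": child,
                         "M_B": M_B, "M_V": mv,
                         "phage_extinct": traj.final.phage_bins.size == 0,
                         "host_richness": strain_richness(traj.final, "host"),
                         "discarded": traj.range_edge})
    return EnsembleResult(
        experiment="mutation_asymmetry", table=pd.DataFrame(rows),
        meta={"n_seeds": n_seeds, "seed": seed, "scale": scale, "T": params.T},
    )
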