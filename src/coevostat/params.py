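"""Model parameters for the multi-strain chemostat.

Defaults reproduce the benchmark parameterisation of the model: an *E. coli*-like
host growing on a single limiting resource in a chemostat, predated by a lytic
phage whose adsorption rate depends on genetic match to the host.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

from .errors import InvalidParameterError


@dataclass(frozen=True)
class ModelParameters:
    """All constants governing chemostat ecology, infection and mutation.

    Units follow the chemostat literature: concentrations in ug/ml, densities
    in cells (virions) per ml, time in minutes.

    Parameters
    ----------
    omega : float
        Chemostat dilution rate (1/min).
    R0 : float
        Resource supply concentration (ug/ml).
    epsilon : float
        Resource conversion rate (ug per cell produced).
    gamma : float
        Maximum resource uptake rate (ug/min).
    K : float
        Half-saturation constant of Monod uptake (ug/ml).
    phi : float
        Maximum adsorption rate (ml per (min * cell)).
    beta : float
        Burst size: virions released per lysis event.
    s : float
        Phage specificity; larger values make infection decay faster with
        genetic distance.
    delta_min, delta_max : float
        Range of the genotype-dependent growth scaling factor.
    M_B, M_V : float
        Mutation rates per new cell / virion produced.
    sigma_B, sigma_V : float
        Standard deviations of the (normal) mutation step in genotype space.
    dt : float
        Integration timestep (min).
    T : float
        Simulation duration (min).
    rho : float
        Genotype binning resolution; genotypes live on the grid
        {0, rho, 2*rho, ..., 1}.
    L : float
        Chemostat volume (ml).
    N_init, V_init : float
        Initial host / phage densities.  ``V_init = 0`` gives a phage-free run.
    h_init, v_init : float
        Initial host / phage genotypes.
    """

    omega: float = 0.0033
    R0: float = 2.2
    epsilon: float = 2.6e-6
    gamma: float = 0.0123
    K: float = 4.0
    phi: float = 0.104e-8
    beta: float = 71.0
    s: float = 100.0
    delta_min: float = 0.8
    delta_max: float = 1.2
    M_B: float = 1e-6
    M_V: float = 1e-6
    sigma_B: float = 0.01
    sigma_V: float = 0.01
    dt: float = 10.0
    T: float = 20e6
    rho: float = 0.01
    L: float = 1.0
    N_init: float = 4.6e4
    V_init: float = 8.1e5
    h_init: float = 0.2
    v_init: float = 0.2

    def __post_init__(self) -> None:
        positive = (
            "omega R0 epsilon gamma K phi beta delta_min delta_max "
            "dt T rho L N_init"
        ).split()
        for name in positive:
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise InvalidParameterError(f"{name} must be finite and > 0, got {value!r}")
        nonneg = "s M_B M_V sigma_B sigma_V V_init".split()
        for name in nonneg:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {value!r}")
        if self.delta_max < self.delta_min:
            raise InvalidParameterError("delta_max must be >= delta_min")
        for name in ("h_init", "v_init"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {value!r}")
        n = 1.0 / self.rho
        if abs(n - round(n)) > 1e-9:
            raise InvalidParameterError("1/rho must be an integer so the genotype grid spans [0, 1]")

    @property
    def n_bins(self) -> int:
        """Number of genotype bins (grid points) on [0, 1]."""
        return int(round(1.0 / self.rho)) + 1

    @property
    def n_steps(self) -> int:
        """Number of integration steps implied by T and dt."""
        return int(round(self.T / self.dt))

    def replace(self, **changes: Any) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


#: the benchmark parameterisation used throughout the experiments
DEFAULT_PARAMS = ModelParameters()
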