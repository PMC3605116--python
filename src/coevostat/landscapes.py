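"""Genotype-to-growth-rate landscapes.

Host genotype ``h`` in [0, 1] determines two pleiotropically linked traits:
the resistance phenotype ``h_hat = h`` (which sets susceptibility to phage via
genetic distance) and the growth scaling factor ``delta = f(h)``.  The mapping
``f`` is an adaptive landscape; four families are provided:

``single_peak``
    Piecewise linear tent: (0, delta_min) -> (0.5, delta_max) -> (1, delta_min).
``dynamic_two_peak``
    Pointwise maximum of the static single peak and a second peak whose height
    grows over time according to a schedule, modelling a changing environment.
``multi_peak``
    ``n`` repeated up-down-up blocks forming a saw-toothed increasing gradient
    with ``n`` interior local maxima separated by fitness valleys.
``rugged_slope``
    A linear slope from (0, delta_min) to (1, delta_max) with added uniform
    noise, smoothed by a centred moving average of width ``span``; smaller
    ``span`` means a more rugged landscape.

Genotypes are binned at resolution ``rho`` (default 0.01), so every landscape
is tabulated on the 1/rho + 1 point grid and evaluation of a continuous
genotype returns the value of its bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import InvalidParameterError

DEFAULT_RHO = 0.01


def genotype_grid(rho: float = DEFAULT_RHO) -> np.ndarray:
    """The genotype bin centres {0, rho, ..., 1}."""
    n = int(round(1.0 / rho))
    return np.arange(n + 1) * rho


def bin_of(genotype: float, rho: float = DEFAULT_RHO) -> int:
    """Bin index of a genotype: ``round(h / rho)``.

    Raises
    ------
    InvalidParameterError
        If the genotype lies outside [0, 1].
    """
    if not 0.0 <= genotype <= 1.0:
        raise InvalidParameterError(f"genotype must lie in [0, 1], got {genotype!r}")
    return int(round(genotype / rho))


def _check_bounds(delta_min: float, delta_max: float) -> None:
    for name, v in (("delta_min", delta_min), ("delta_max", delta_max)):
        if not math.isfinite(v) or v <= 0:
            raise InvalidParameterError(f"{name} must be finite and > 0, got {v!r}")
    if delta_max < delta_min:
        raise InvalidParameterError("delta_max must be >= delta_min")


def _tent(h: np.ndarray | float, centre: float, height: float, delta_min: float) -> np.ndarray | float:
    """Piecewise linear peak joining (0, delta_min)-(centre, height)-(1, delta_min)."""
    h = np.asarray(h, dtype=float)
    left = delta_min + (height - delta_min) * h / centre
    right = delta_min + (height - delta_min) * (1.0 - h) / (1.0 - centre)
    return np.where(h <= centre, left, right)


@dataclass(frozen=True)
class GrowthLandscape:
    """A tabulated genotype -> growth-scaling mapping.

    Static kinds ignore the time argument of the evaluation methods; the
    ``dynamic_two_peak`` kind re-tabulates as the scheduled second-peak height
    changes.
    """

    kind: str
    rho: float
    table: np.ndarray                      # delta at each bin centre (at t=0)
    meta: dict = field(default_factory=dict)
    exact_fn: Callable[[float], float] | None = None
    #: sorted (time, second-peak height) pairs; dynamic kind only
    schedule: tuple[tuple[float, float], ...] = ()

    @property
    def n_bins(self) -> int:
        return self.table.size

    @property
    def is_dynamic(self) -> bool:
        return self.kind == "dynamic_two_peak"

    def second_peak_height(self, t: float) -> float:
        """Scheduled height of the second peak at time t (step function)."""
        height = -np.inf
        for st, sh in self.schedule:
            if st <= t:
                height = sh
            else:
                break
        return height

    def table_at(self, t: float = 0.0) -> np.ndarray:
        """The full delta table at time ``t``."""
        if not self.is_dynamic:
            return self.table
        height = self.second_peak_height(t)
        if not np.isfinite(height):
            return self.table
        grid = genotype_grid(self.rho)
        second = _tent(grid, self.meta["second_centre"], height, self.meta["delta_min"])
        return np.maximum(self.table, second)

    def delta(self, genotype: float, t: float = 0.0) -> float:
        """Growth scaling of a (binned) genotype at time t."""
        return float(self.table_at(t)[bin_of(genotype, self.rho)])

    def delta_at_bins(self, bins: np.ndarray, t: float = 0.0) -> np.ndarray:
        return self.table_at(t)[bins]

    def exact(self, genotype: float, t: float = 0.0) -> float:
        """Un-binned (continuous piecewise) evaluation where one exists.

        For the rugged kind the tabulated value is the definition, so this
        coincides with :meth:`delta`.
        """
        if self.is_dynamic:
            height = self.second_peak_height(t)
            first = self.exact_fn(genotype)  # type: ignore[misc]
            if not np.isfinite(height):
                return float(first)
            second = _tent(genotype, self.meta["second_centre"], height, self.meta["delta_min"])
            return float(max(first, second))
        if self.exact_fn is not None:
            return float(self.exact_fn(genotype))
        return self.delta(genotype, t)

    def schedule_times(self) -> list[float]:
        return [st for st, _ in self.schedule]

    def to_dataframe(self, t: float = 0.0):
        """Two-column table (h, delta); import deferred to keep pandas optional here."""
        import pandas as pd

        return pd.DataFrame({"h": genotype_grid(self.rho), "delta": self.table_at(t)})

    def export_text(self, path, t: float = 0.0) -> None:
        """Write the landscape as two-column tabular text (h, delta)."""
        grid = genotype_grid(self.rho)
        np.savetxt(path, np.column_stack([grid, self.table_at(t)]),
                   header="h delta", comments="# ")


def make_single_peak(delta_min: float = 0.8, delta_max: float = 1.2,
                     rho: float = DEFAULT_RHO) -> GrowthLandscape:
    """Smooth single-peak tent landscape with its maximum at h = 0.5."""
    _check_bounds(delta_min, delta_max)
    grid = genotype_grid(rho)
    exact = lambda h: float(_tent(float(h), 0.5, delta_max, delta_min))  # noqa: E731
    table = np.asarray(_tent(grid, 0.5, delta_max, delta_min), dtype=float)
    return GrowthLandscape(
        kind="single_peak", rho=rho, table=table, exact_fn=exact,
        meta={"delta_min": delta_min, "delta_max": delta_max},
    )


def make_dynamic_two_peak(
    delta_min: float = 0.8,
    delta_max: float = 1.2,
    schedule: Sequence[tuple[float, float]] | None = None,
    second_centre: float = 0.8,
    rho: float = DEFAULT_RHO,
    T: float = 20e6,
) -> GrowthLandscape:
    """Two-peak landscape whose second peak rises stepwise over time.

    At any time the landscape is the pointwise maximum of the static initial
    single peak (centre 0.5, height ``delta_max``) and a second tent centred at
    ``second_centre`` with the currently scheduled height.  The default
    schedule ramps the second peak from ``delta_min`` to
    ``delta_max + 0.1*(delta_max - delta_min)`` in 10 equal steps over ``T``.

    ``schedule`` must be non-decreasing in both time and height.
    """
    _check_bounds(delta_min, delta_max)
    if not 0.0 < second_centre < 1.0:
        raise InvalidParameterError("second_centre must lie strictly inside (0, 1)")
    if schedule is None:
        top = delta_max + 0.1 * (delta_max - delta_min)
        heights = np.linspace(delta_min, top, 10)
        times = np.linspace(0.0, T, 11)[:-1]
        schedule = list(zip(times, heights))
    schedule = [(float(t), float(h)) for t, h in schedule]
    times = [t for t, _ in schedule]
    heights = [h for _, h in schedule]
    if times != sorted(times) or heights != sorted(heights):
        raise InvalidParameterError(
            "schedule must be non-decreasing in both time and second-peak height"
        )
    base = make_single_peak(delta_min, delta_max, rho)
    return GrowthLandscape(
        kind="dynamic_two_peak", rho=rho, table=base.table, exact_fn=base.exact_fn,
        schedule=tuple(schedule),
        meta={"delta_min": delta_min, "delta_max": delta_max,
              "second_centre": second_centre},
    )


def make_multi_peak(n: int, delta_min: float = 0.8, delta_max: float = 1.2,
                    rho: float = DEFAULT_RHO) -> GrowthLandscape:
    """Saw-toothed increasing landscape of ``n`` up-down-up blocks.

    Each block of width ``b_w = 1/n`` rises from its baseline by the block
    height ``b_h = (delta_max - delta_min)/n`` along the anchor motif
    (0, 0) -> (b_w/3, b_h) -> (2 b_w/3, 0) -> (b_w, b_h); the last point of a
    block is the first of the next, so the profile climbs from ``delta_min``
    at h = 0 to ``delta_max`` at h = 1 with ``n`` interior local maxima.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise InvalidParameterError(f"block count n must be an integer >= 1, got {n!r}")
    _check_bounds(delta_min, delta_max)
    b_w = 1.0 / n
    b_h = (delta_max - delta_min) / n

    def exact(h: float) -> float:
        h = float(h)
        if not 0.0 <= h <= 1.0:
            raise InvalidParameterError(f"genotype must lie in [0, 1], got {h!r}")
        m = min(int(h // b_w), n - 1)
        u = h - m * b_w
        third = b_w / 3.0
        if u <= third:
            motif = b_h * u / third
        elif u <= 2.0 * third:
            motif = b_h * (1.0 - (u - third) / third)
        else:
            motif = b_h * (u - 2.0 * third) / third
        return delta_min + m * b_h + motif

    grid = genotype_grid(rho)
    table = np.array([exact(h) for h in grid])
    return GrowthLandscape(
        kind="multi_peak", rho=rho, table=table, exact_fn=exact,
        meta={"delta_min": delta_min, "delta_max": delta_max, "n": n,
              "b_w": b_w, "b_h": b_h},
    )


def make_rugged_slope(span: int, seed: int, amplitude: float = 0.2,
                      delta_min: float = 0.8, delta_max: float = 1.2,
                      rho: float = DEFAULT_RHO) -> GrowthLandscape:
    """Linear slope plus uniform noise, smoothed by a moving average.

    The base profile is the straight line from (0, delta_min) to
    (1, delta_max) tabulated on the rho-grid.  I.i.d. uniform noise with
    peak-to-peak amplitude ``amplitude`` (i.e. on [-amplitude/2, +amplitude/2],
    so the mean slope is unbiased) is added per grid point, then the result is
    smoothed with a centred moving average of width ``span`` grid points;
    windows are truncated at the domain edges.  ``span = 1`` leaves the raw
    noisy slope untouched.  Deterministic given ``seed``.
    """
    if not isinstance(span, (int, np.integer)) or span < 1 or span % 2 == 0:
        raise InvalidParameterError(f"span must be an odd positive integer, got {span!r}")
    if not math.isfinite(amplitude) or amplitude < 0:
        raise InvalidParameterError(f"amplitude must be >= 0, got {amplitude!r}")
    _check_bounds(delta_min, delta_max)
    grid = genotype_grid(rho)
    base = delta_min + (delta_max - delta_min) * grid
    rng = np.random.default_rng(seed)
    noise = rng.uniform(-amplitude / 2.0, amplitude / 2.0, size=grid.size)
    if span == 1:
        table = base + noise
    else:
        # smooth the noise component only: on the interior this equals
        # smoothing the sum (the slope is linear), while at the truncated
        # edge windows it avoids biasing the mean gradient
        kernel = np.ones(span)
        sums = np.convolve(noise, kernel, mode="same")
        counts = np.convolve(np.ones_like(noise), kernel, mode="same")
        table = base + sums / counts
    return GrowthLandscape(
        kind="rugged_slope", rho=rho, table=table,
        meta={"delta_min": delta_min, "delta_max": delta_max, "span": int(span),
              "amplitude": amplitude, "seed": int(seed)},
    )


def genotype_to_phenotype(genotype: float,
                          landscape: GrowthLandscape | None = None,
                          t: float = 0.0):
    """Map a genotype to its phenotype(s).

    Resistance and infection traits are the identity maps (h_hat = h,
    v_hat = v).  If a landscape is supplied the genotype is treated as a host
    and the pair ``(h_hat, delta)`` is returned; otherwise the bare trait.
    """
    if not 0.0 <= genotype <= 1.0:
        raise InvalidParameterError(f"genotype must lie in [0, 1], got {genotype!r}")
    if landscape is None:
        return float(genotype)
    return float(genotype), landscape.delta(genotype, t)
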