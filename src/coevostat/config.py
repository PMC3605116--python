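"""YAML run-configuration loading.

A configuration file has two blocks::

    parameters:        # any ModelParameters field; omitted fields keep defaults
      R0: 2.2
      s: 100
    landscape:
      kind: single_peak            # or dynamic_two_peak | multi_peak | rugged_slope
      # kind-specific settings, e.g. n, span, seed, amplitude, schedule

Landscape delta bounds and rho default to the parameter block's values.
"""

from __future__ import annotations

import yaml

from .errors import InvalidParameterError
from .landscapes import (GrowthLandscape, make_dynamic_two_peak,
                         make_multi_peak, make_rugged_slope, make_single_peak)
from .params import ModelParameters


def build_landscape(spec: dict, params: ModelParameters) -> GrowthLandscape:
    """Construct a landscape from its configuration block."""
    spec = dict(spec)
    kind = spec.pop("kind", "single_peak")
    common = dict(delta_min=spec.pop("delta_min", params.delta_min),
                  delta_max=spec.pop("delta_max", params.delta_max),
                  rho=spec.pop("rho", params.rho))
    if kind == "single_peak":
        return make_single_peak(**common, **spec)
    if kind == "dynamic_two_peak":
        schedule = spec.pop("schedule", None)
        if schedule is not None:
            schedule = [tuple(entry) for entry in schedule]
        return make_dynamic_two_peak(**common, schedule=schedule,
                                     T=spec.pop("T", params.T), **spec)
    if kind == "multi_peak":
        return make_multi_peak(n=int(spec.pop("n", 5)), **common, **spec)
    if kind == "rugged_slope":
        return make_rugged_slope(span=int(spec.pop("span", 5)),
                                 seed=int(spec.pop("seed", 0)), **common, **spec)
    raise InvalidParameterError(f"unknown landscape kind {kind!r}")


def load_config(path) -> tuple[ModelParameters, GrowthLandscape]:
    """Read a YAML config file into (parameters, landscape)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    params = ModelParameters.from_dict(raw.get("parameters", {}) or {})
    landscape = build_landscape(raw.get("landscape", {}) or {}, params)
    return params, landscape
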