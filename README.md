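# coevostat

Eco-evolutionary simulation of bacteria and lytic bacteriophage coevolving in
a resource-limited chemostat, together with the closed-form steady-state
theory of the model. The package is aimed at theoretical ecologists and
evolutionary microbiologists studying kill-the-winner dynamics,
phage-driven host diversification, and the effect of coevolving phage on
host evolvability across rugged adaptive landscapes.

## The model

A well-mixed chemostat with dilution rate ω supplies resource at
concentration R₀. Host strains *i* (density Nᵢ cells/ml) grow by Monod
kinetics scaled by a genotype-dependent factor δᵢ; phage strains *j*
(density Vⱼ virions/ml) adsorb to hosts and lyse them instantly, releasing β
virions per burst:

    dR/dt  = −ω(R − R₀) − Σᵢ εγR Nᵢ δᵢ/(R + K)
    dNᵢ/dt = −ωNᵢ + γR Nᵢ δᵢ/(R + K) − Σⱼ θᵢⱼ Nᵢ Vⱼ
    dVⱼ/dt = −ωVⱼ + Σᵢ β θᵢⱼ Nᵢ Vⱼ

Genotypes are points h, v ∈ [0, 1] binned at resolution ρ. Infection is a
relaxed lock-and-key kernel, θᵢⱼ = ϕ·exp(−s(ĥᵢ − v̂ⱼ)²), maximal on a perfect
genetic match and falling off with distance at a rate set by the phage
specificity *s*; a strict exact-match variant is used for equilibrium
analysis. Host genotype pleiotropically sets both resistance (ĥ = h) and
growth rate (δ = f(h), an adaptive landscape — single-peak, dynamic
two-peak, saw-toothed multi-peak, or noisy rugged slope). New strains enter
by stochastic mutation of new particles (Poisson counts, normal genotype
steps); strains below 1 cell/ml wash out. The analytic theory gives each
strain's limiting resource concentration R̄ = ωK/(γδ − ω), the phage-limited
host density N̂ = ω/(βϕ) (independent of δ), and a sequential-introduction
cascade predicting the number *x* of host strains that stably coexist under
strict lock-and-key infection.

## Worked example

```python
import numpy as np
from coevostat import (ModelParameters, make_single_peak, simulate,
                       steady_state_diversity, strain_richness)

params = ModelParameters()            # benchmark chemostat parameters

# analytic prediction: how many host strains coexist at steady state?
pool = np.round(np.linspace(1.2, 0.8, 11), 10)
x = steady_state_diversity(pool, params)
print(f"predicted steady-state diversity: {x} host strains")

# a coevolutionary run on the single-peak landscape (tenth-scale duration)
landscape = make_single_peak()
traj = simulate(params.replace(T=2e6), landscape, seed=0, output_stride=2000)
final = traj.final
print(f"final resource {final.R:.3f} ug/ml, "
      f"{final.host_bins.size} host strains in "
      f"{strain_richness(final, 'host')} clusters, "
      f"total hosts {final.total_host_density:.3g} cells/ml")
```

Output:

```
predicted steady-state diversity: 6 host strains
final resource 2.024 ug/ml, 6 host strains in 2 clusters, total hosts 4.52e+04 cells/ml
```

The cascade predicts six coexisting host strains for the benchmark
parameters. The tenth-scale simulation shows the early phase of
coevolution: the host community (seeded at genotype 0.2) has climbed toward
the growth optimum and begun splitting into clusters, with total host
density already above the single-strain phage-limited level
N̂ ≈ 4.47×10⁴ cells/ml; branching continues and diversity builds over the
full-length run as resources are drawn down toward limiting levels.

A CLI wraps the packaged experiments
(`coevostat simulate|steady-state|case-study|evolvability|range-scan|rugged-scan|param-scan`);
see `coevostat --help`.

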