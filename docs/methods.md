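# Methods

## The model

`coevostat` simulates a well-mixed chemostat containing one limiting
resource, a community of bacterial strains, and a community of lytic
bacteriophage strains. The ecological state is (R, {N_i}, {V_j}) — resource
concentration (ug/ml) and per-strain densities (cells or virions per ml) —
and evolves by

    dR/dt   = -omega (R - R0) - sum_i eps * gamma R N_i delta_i / (R + K)
    dN_i/dt = -omega N_i + gamma R N_i delta_i / (R + K) - sum_j theta_ij N_i V_j
    dV_j/dt = -omega V_j + sum_i beta theta_ij N_i V_j

Growth is Monod-limited with a genotype-dependent scaling factor delta_i;
every adsorption event causes instantaneous lysis releasing beta virions (no
latent period, no multiple infection). Both populations live on a
one-dimensional genotype space h, v in [0, 1], binned at resolution rho:
strains are bins, and a strain's phenotypes are its resistance trait
(h_hat = h), its growth factor (delta = f(h), the adaptive landscape), or the
phage infection trait (v_hat = v). Infection follows a relaxed lock-and-key
kernel, theta_ij = phi exp(-s (h_hat_i - v_hat_j)^2), so phage are
specialists on genetically similar hosts; the strict variant (theta = phi on
exact bin match, else 0) is the s -> infinity limit used by the equilibrium
theory. Because host genotype jointly sets resistance and growth rate, the
model couples kill-the-winner ecology to adaptation on the growth landscape.

Dynamics are deterministic ODEs integrated with classical fixed-step RK4;
stochasticity enters only through mutation. After each step, each strain
spawns Poisson(M * L * production_rate * dt) mutants, each mutant's genotype
is the parent's plus a Normal(0, sigma) deviate re-binned at rho (offsets
that round back to the parent are dropped), and the mutant density (count/L)
is debited from the parent — mutation reclassifies newly produced particles
rather than creating mass, which makes conservation testable. Populations
falling below 1 cell (virion) per ml are culled, closing the loop between
ecological invasion/extinction and evolution without separating timescales.

Per-step operation order is integrate -> mutate -> cull: mutant counts use
the production rates of the freshly integrated state, and culling last
prevents sub-unit remnants from seeding mutants. The initial resource is
R(0) = R0 (a fresh-medium assumption; the equilibrium results do not depend
on it).

## Parameters

Defaults (see `ModelParameters`) describe an E. coli-like host and a lytic
phage in a slow-turnover chemostat: omega = 0.0033 /min, R0 = 2.2 ug/ml,
eps = 2.6e-6 ug/cell, gamma = 0.0123 ug/min, K = 4 ug/ml, phi = 1.04e-9
ml/(min cell), beta = 71, s = 100, delta in [0.8, 1.2], M_B = M_V = 1e-6 per
new particle, sigma_B = sigma_V = 0.01, dt = 10 min, T = 2e7 min, rho = 0.01,
L = 1 ml. The derived scales worth keeping in mind: the phage-limited host
density Nhat = omega/(beta phi) ~ 4.47e4 cells/ml, the fastest strain's
limiting resource R* ~ 1.152 ug/ml, and the phage-free carrying capacity
N* ~ 4.03e5 cells/ml.

## Landscapes

Four genotype -> delta families: a single piecewise-linear peak at h = 0.5;
a dynamic two-peak variant whose second peak (default centre 0.8) rises
stepwise over the run — heights and times are configurable, defaulting to a
10-step linear ramp from delta_min to slightly above delta_max, since no
canonical schedule exists; a saw-toothed multi-peak landscape of n identical
up-down-up blocks (n interior local maxima separated by fitness valleys on a
rising gradient); and rugged slopes built from a linear gradient plus
uniform noise smoothed by a centred moving average of width `span`. Noise
"amplitude 0.2" is implemented as uniform on [-0.1, +0.1] (peak-to-peak 0.2)
so the mean gradient is unbiased. The moving average is applied to the noise
component only with truncated edge windows: on the interior this is
identical to smoothing the noisy profile (the base is linear), while at the
edges it avoids biasing the slope, and it keeps the zero-amplitude landscape
exactly linear for every span. Landscapes are tabulated on the rho-grid;
continuous evaluation returns the bin value, since genotypes only exist at
bin centres.

## Equilibrium theory

For one strain without phage the classical R* result holds:
Rbar = omega K / (gamma delta - omega), with density Nbar fixed by resource
balance. With a perfect-match phage the host is predator-limited at
Nhat = omega/(beta phi) independent of delta, while the phage density rises
with host growth rate. Under strict lock-and-key, a pool of strains with
distinct growth factors delta_1 > ... > delta_H admits a sequential
cascade: with the i fastest strains phage-limited at Nhat, the resource
settles at the positive root Rhat_i of
(R - R0)(R + K) + C_i R = 0, C_i = eps gamma sum_{j<=i} delta_j / (beta phi).
Strain i is the first resource-limited (community-closing) strain when
Rbar_i > Rhat_i; the count x of coexisting strains found this way is
independent of introduction order. With the default pool
{1.2, 1.16, ..., 0.8} and R0 = 2.2 the cascade gives x = 6; this is the
quantity `scripts/acceptance.py` recomputes. A corollary: with *equal*
growth factors all strains share one Rbar, so the first strain that
establishes without phage drags R to that common Rbar and every
phage-limited competitor declines — phage-supported coexistence requires
growth-rate variation. The simulation test of the corollary seeds equal-delta
strains with phage plus one phage-free invader, which instantiates the
resource-limited strain the argument turns on (a fully symmetric all-phage
community is a neutral equilibrium and does not collapse on its own).

Eq-form note: the textbook nested expression for Nbar is implemented in the
algebraically simplified form omega (R0 - Rbar)(Rbar + K)/(eps gamma delta
Rbar); the equivalence is unit-tested at random parameter points. The
boundary case Rbar = R0 returns Nbar = 0 rather than an error.

## Numerics

RK4 with dt = 10 min resolves the dynamics to well below 0.1% (halving dt
changes benchmark equilibria by < 0.1%; the integrator is exercised against
a closed-form washout solution and a fine-step Euler oracle). The inner step
is numba-compiled; a 2e5-step run takes a couple of seconds on one core.
Non-finite states abort with the offending variable named. The adsorption
matrix is extended/sliced incrementally as strains appear and die, and every
incremental update is bit-identical to a full rebuild (tested). One RNG
stream per run with a fixed draw order (hosts by ascending bin, then phage)
makes trajectories bit-reproducible given the seed; experiment replicate
seeds are spawned from the master seed via `SeedSequence`.

Mutants landing outside [0, 1] are skipped and flag the run (`range_edge`);
mutants landing exactly on the boundary bins are applied but also flag.
Flagged runs are returned for diagnosis but excluded from ensemble
statistics, since edge-truncated genotype distributions are artefactual.

## Scaled-down experiment designs

The packaged experiments default to `scale = 0.1` (a tenth of the
full design durations, e.g. T = 2e6 min for the 2e7-min designs) so a full
grid fits in CI-scale compute; `--full` restores the printed designs. Two
regimes deserve comment:

- Diversification timescale. At the benchmark mutation rates (1e-6) the
  case-study community needs roughly 2e6 min to climb from h = 0.2 to the
  growth optimum and begins branching only after that; three or more host
  clusters typically appear by ~4e6 min and five clusters by ~8e6 min.
  A tenth-scale case study therefore shows early-transient dynamics,
  not the diversified quasi-steady state.
- Mutation supply. The ensemble experiments (genotype range, evolvability,
  rugged-slope scans) use M_B = M_V = 1e-5, the rates the full-length
  ensemble designs themselves use, which also keeps the total mutational
  input T*M of a tenth-scale run comparable to a full-length run at 1e-6.
- Evolvability ensembles. Valley crossing on the multi-peak landscape is
  driven by the lysis-relief gradient; at generalist specificity (s = 100)
  the relief over one mutation step barely offsets the growth cost and
  crossings are rare events on the full 2e7-min timescale. The paired
  multi-peak ensemble therefore defaults to specialist phage (s = 400 at
  T = 1e6), where the same mechanism operates within reach of short runs;
  the rugged-slope ensemble uses s = 1000 at T = 2e6 for its specialist
  arm, matching the full design's finding that specialists confer the
  benefit. Durations are capped low because on these rising landscapes a
  fully successful run eventually drives genotypes to the h = 1 boundary
  and is discarded under the range-edge rule. The multi-peak landscape uses
  n = 5 blocks (no canonical value exists; 5 gives valleys a few mutation
  steps wide against sigma = 0.01).
- Standing-variation scan. The specificity direction (genotype range
  decreasing in s) is a steady-state property that inverts during the early
  transient: specialist phage branch hosts faster, generalists spread them
  wider eventually. The scan therefore runs at T = 2e6 (0.4 of the printed
  design duration), where all three directions (R0 up, delta_min up, s
  down) are stable.
- Mutation-rate asymmetry. With static phage (M_V = 0) the evolving host
  community escapes in genotype space and all phage wash out within a few
  million minutes. A small phage mutation supply restores tracking: at
  M_V = 1e-7 against M_B = 1e-5, roughly 2e2 effective phage mutations per
  1e6 min suffice for the phage community to persist through full-length
  runs. The persistence/extinction boundary thus sits between those two
  supplies under this package's Poisson(rate*dt) mutant-count convention.

What the synthetic regimes do not emulate: real phage latent periods,
multiplicity of infection, demographic noise in densities (densities are
continuous ODE variables; only mutation is stochastic), spatial structure,
and any genotype space beyond the binned line. Passing tests therefore
validate the model's internal logic and its agreement with its own
equilibrium theory — not quantitative transfer to laboratory systems.

## Known limitations

- The continuous-density abstraction with a 1/ml cull is a coarse stand-in
  for demographic stochasticity; absolute extinction times are not
  meaningful, only their parameter dependence.
- Equilibrium theory covers the strict lock-and-key limit; the relaxed
  kernel's steady states are only characterised numerically.
- No eigenvalue/stability analysis of the multi-strain equilibria is
  provided; stability is probed by simulation.
- On slope-type landscapes whose global optimum sits at h = 1, complete
  adaptation necessarily approaches the genotype range edge, so the most
  successful runs can end range-edge-flagged; ensemble summaries report how
  many runs were discarded for this reason.
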