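# Methods

`optews` studies whether a purely local, symbol-based statistic — the
ordinal-pattern transition (OPT) entropy of a single node's time series —
can warn of an approaching explosive synchronization transition in a
coupled dynamical network before the global order parameter moves. This
note records the models, the estimators, the numerical choices, and what
the simulations do and do not establish.

## Ordinal symbolization and entropies

A scalar series `x_1..x_T` is cut into blocks of `D` samples separated by a
lag `tau`; each block is mapped to the permutation that sorts it ascending,
labelled by its 1-based lexicographic rank among the `D!` permutations.
Ties are broken by temporal order (the earlier sample ranks lower), the
dominant convention in the ordinal-analysis literature. Two block
conventions are provided:

- **disjoint** (default): blocks advance by `tau*D` samples, giving
  `L = floor(T/(tau*D))` symbols. This is the convention implied by the
  block-count formula the entropies here are defined with.
- **overlapping**: stride-1 Bandt–Pompe blocks, `L = T-(D-1)*tau`, for
  comparison with most published permutation-entropy values. For long
  white-noise series both give the same pattern distribution (tested at
  `n = 1e5` within 0.01).

From the symbol stream we estimate

- the pattern distribution `p(pi_l)` and the normalized permutation
  entropy `H = -sum p ln p / ln D!` (natural logarithm, `0 ln 0 := 0`);
- the transition matrix `p_lm = #(pi_l, pi_m)/#(pi_l)` over consecutive
  symbol pairs, self-transitions included, rows of never-observed source
  patterns identically zero. The matrix is row-stochastic in this
  indexing (each observed row sums to 1);
- the local successor entropy of each pattern, normalized by `ln D!`, and
  the OPT entropy `HT`: the plain average of the `D!` local entropies.
  Unobserved patterns contribute zero, which deliberately deflates `HT`
  when the dynamics visits only part of the pattern alphabet.

All experiments use `D = 3`, `tau = 1` on the (already subsampled or
sectioned) observable, disjoint blocks, and target roughly 2000 observable
samples per node per coupling (about 650 blocks, comfortably above the
`L >> D! = 6` guard; a warning fires below `10*D!` blocks). `D <= 7` is
enforced; beyond that the alphabet outgrows any practical series.

A Poincaré-section helper reduces oscillatory signals to the amplitude
series of their strict local extrema (three-point comparison; plateaus
yield no extremum; an optional threshold keeps only spike maxima). This is
the entropy input for the two chaotic/spiking families below.

## The three dynamical families

All networks are undirected and unweighted; the coupling strength `d`
multiplies the sum of output differences over neighbors. `d` is interpreted
as the k_max-normalized strength (`d = sigma/k_max`) so different
topologies are comparable. Explosive transitions are induced by
degree-correlated heterogeneity: a node's intrinsic time scale grows with
its degree, dynamically isolating the hubs.

**Kuramoto star (N=31).** `dtheta_i/dt = omega_i + d sum_j a_ij
sin(theta_j - theta_i)`, hub frequency 1.3, leaves `1 + 0.005 eps` with
`eps ~ U(0,1)`. Fixed-step RK4, `dt = 0.01`; the entropy input is the
instantaneous frequency (the right-hand side evaluated at the state, not a
finite difference) recorded every 200 steps, i.e. every 2 time units.

**Chialvo star (N=31) and scale-free (N=100).** The two-dimensional neural
map `x' = x^2 exp(y - x) + I + d sum a_ij (x_j - x_i)`,
`y' = a y - b x + c` with `a=0.89, b=0.6, c=0.28`; the bias current `I`
sets the spiking rate. Star: hub `I = 0.050`, leaves `0.049 + 1e-4 eps`;
scale-free: `I = 0.049 + 3e-5 k`. The entropy input is the sequence of
spike maxima (`x > 0.5`); the phase for the order parameter advances by
2*pi per spike with linear interpolation between spikes.

**Rössler star (N=31) and scale-free (N=500, gamma=2.25, mean degree 4).**
The phase-coherent chaotic oscillator (`a=0.165, b=0.4, c=8.5`),
diffusively coupled in `y`, frequency parameter `w = 1.06 + 2.73e-4 k`.
Star leaves get an extra `U(0, 1e-4)` jitter so the backward route
actually desynchronizes; larger jitter (3e-3 and up) was checked to smear
the transition into a continuous one, so it is kept small. The entropy
input is the sequence of strict local minima of `y`, detected online
during integration; the phase is the unwrapped `arctan2(y, x)`.

The scale-free builder draws a truncated power-law degree sequence
(`p(k) ~ k^-gamma`, structural cutoff `sqrt(N<k>)`, lowest degree chosen so
the truncated mean is closest to the target), pairs it with the
configuration model, removes self-loops and parallel edges, and keeps the
largest component; a draw is accepted if the realized mean degree is
within 15% of the target.

## Sweep protocol and indicators

Forward sweeps increase `d` over a grid, starting from random initial
conditions and carrying each point's final state into the next; backward
sweeps start near synchrony at the largest coupling and descend. At each
grid point, after a discarded transient, the package records the time-
averaged order parameter `R`, per-node `H` and `HT`, the fluctuation
standard deviation `sigma_f` and the lag-1 autocorrelation `AC(1)` of the
same observable that feeds the entropies. `AC(1)` is the *uncentered*
normalized inner product, exactly as the comparator statistic is defined
here; a centered variant sits behind a flag. `sigma_f` is reported as a
standard deviation (the square root of the variance).

A transition is classified explosive when a single grid step carries `R`
across `jump_threshold = 0.4`; the hysteresis width is the difference of
forward and backward critical couplings, floored at zero. The early-
warning alarm watches `Delta(d) = <HT>_hub - <HT>_min-degree-class`: it
fires at the first coupling where `Delta` exceeds its low-coupling
baseline (first 3 grid points) by `n_sigma = 3` baseline standard
deviations for 2 consecutive points. Persistence suppresses single-point
noise alarms; both knobs are configurable. The degree-cutoff analysis
compares `<HT>_k` profiles at a low and a near-transition coupling and
returns the smallest degree above which every larger class exceeds the
low-coupling profile by a margin (default 0.05).

## Numerical choices

- Integrators: fixed-step RK4 for both flows, `dt = 0.01` (halving `dt`
  changes retained Kuramoto phases by < 1e-5); exact iteration for the
  map. Numba-compiled kernels; identical seeds give bit-identical runs.
- Transients: 500 time units (Kuramoto), 600 (Rössler), 10000 iterations
  (Chialvo) per grid point on top of state carryover.
- Degenerate inputs: monotone series give `H = HT = 0`; constant series
  symbolize to the all-ties pattern (rank 1); a node with fewer than two
  spikes has no phase and the network `R` for that window is undefined
  (NaN) rather than fabricated.
- Problem sizes in the shipped acceptance runs are reduced from the
  full-study sizes (600–2000 observable samples per node, 2–5
  realizations instead of 10–64) so a complete recomputation stays within
  desk scale; grids and sizes are the package's own defaults and are
  echoed into every output.

## What the simulations show — and an honest discrepancy

The Chialvo family reproduces the sentinel-hub picture cleanly: on the
star, the forward jump (`d_c ~ 4.5e-4`) is abrupt with a finite hysteresis
loop, and the hub-class OPT entropy rises by ~0.6 (from ~0.31 to ~0.93)
already at one-ninth of the critical coupling while the leaf class stays
near baseline; on the N=100 scale-free graph the largest-degree class
rises before the order parameter moves.

The Kuramoto star reproduces the explosive jump and hysteresis, and the
comparator statistics behave as expected (leaf `sigma_f` grows linearly
with `d`; the hub's `sigma_f` is not peaked at the forward transition).
However, under the equations and protocol implemented here, the
pre-transition incoherent state is a quasiperiodic drift whose hub OPT
entropy stays flat up to the jump: the hub-entropy precursor does not
appear. A coexisting chaotic "splay" state with suppressed mean field does
show the elevated-hub/flat-leaf pattern, but noiseless continuation does
not reliably reach it. The corresponding acceptance checks are left
failing rather than weakened.

The Rössler family shows a strong sentinel *departure* with the opposite
sign: the diffusive self-term `-d k_i y_i` lowers a hub's effective
parameter `a_eff = 0.165 - k_i d` into a periodic window of the isolated
oscillator (verified directly on single nodes: `HT` of the minima sequence
drops from 0.43 to 0 as `a` goes from 0.165 to 0.14), so high-degree
nodes' entropy falls sharply before the transition while low-degree
classes stay flat. The effect is monotone in degree and begins well before
the hysteresis window — structurally the same sentinel phenomenon, but as
an entropy drop. Checks that require a rise are likewise left failing, and
the acceptance script reports the signed change it actually measures.

## What passing tests do not show

The synthetic generators implement the idealized study conditions: exact
model equations, quenched parameter disorder as the only stochasticity, no
measurement noise, no drift in parameters. Real recordings (e.g. from
electronic-circuit networks) add component tolerance, environmental noise
and finite sampling; the circuit-dataset loader and the normalization of
entropy traces to their uncoupled value are exercised against a synthetic
stand-in generated by the package's own Rössler star, not against real
hardware data, so tests passing here say nothing about any particular
laboratory dataset. Pointwise entropy-vs-coupling curves depend on
integrator, grid and window choices and are not expected to be
reproducible across implementations; the invariants and qualitative
patterns above are.
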