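# optews

Ordinal-pattern transition entropy as a **local early-warning signal for
explosive synchronization** in networks of coupled dynamical systems.

Explosive synchronization (ES) is a first-order-like transition: as the
coupling `d` among oscillators grows, the phase order parameter

    R = (1/N) ⟨| Σ_j e^{iθ_j(t)} |⟩_t

stays near its incoherent floor and then jumps abruptly to R ≈ 1, typically
with hysteresis between the forward and backward continuations. Because R
barely moves before the jump, global observables give almost no warning.
This package implements a *local* alternative: symbolize a single node's
time series into ordinal patterns of length D (the permutation that sorts
each block of D lagged samples), build the pattern-transition matrix
`p_ℓm = #(π_ℓ, π_m)/#(π_ℓ)`, and measure the ordinal-pattern transition
(OPT) entropy

    H_πℓ = −(1/ln D!) Σ_m p_ℓm ln p_ℓm ,      HT = (1/D!) Σ_ℓ H_πℓ ,

alongside the normalized permutation entropy `H = −Σ p ln p / ln D!`. On
heterogeneous graphs whose node parameters are degree-correlated (the
standard recipe for inducing ES), the highest-degree nodes act as
*sentinels*: their OPT entropy departs from its weak-coupling baseline
while low-degree nodes stay flat, long before R moves.

The package is for researchers in nonlinear dynamics and network
physiology/neuroscience who want to (a) compute ordinal entropies with
explicit, tested conventions, (b) regenerate the networked study systems —
Kuramoto phase oscillators, Chialvo neural maps, Rössler chaotic
oscillators on star and scale-free graphs — and (c) evaluate hub-vs-leaf
early-warning statistics (OPT entropy, fluctuation standard deviation,
lag-1 autocorrelation) along forward/backward coupling sweeps.

## Worked example

Compute entropies of a deterministic periodic signal and of white noise:

```bash
$ optews fixtures --kind periodic --seed 0 --out demo
demo/periodic.csv
$ optews entropy --input demo/periodic.csv
L=800 H=0.773706 HT=0.000000
$ optews fixtures --kind white-noise --seed 0 --out demo
demo/white_noise.csv
$ optews entropy --input demo/white_noise.csv
L=20000 H=0.999878 HT=0.999393
```

The periodic signal visits three of the six D=3 patterns with unequal
frequency (H ≈ 0.77) but every pattern has a unique successor, so the
transition entropy is exactly zero; white noise visits all patterns and
all transitions uniformly, so both entropies approach 1. This separation —
`HT` collapsing for predictable dynamics while saturating for mixing
dynamics — is what makes `HT` a sharper probe than `H`.

A sweep over coupling for the N=31 Chialvo star, and the alarm report:

```bash
$ optews sweep --preset chialvo-star --direction both --out chialvo_star
forward: critical d=0.00045 (explosive in 7/10 realizations)
backward: critical d=0.0002 (explosive in 10/10 realizations)
$ optews ews --sweep-table chialvo_star/sweep_forward.csv --baseline-points 2
{
  "measure": "HT",
  "n_sigma": 3.0,
  "baseline_points": 2,
  "alarm_coupling": 0.0001,
  "hub_degree": 30,
  "reference_degree": 1
}
```

The forward jump sits at d ≈ 4.5e-4 with a hysteresis loop down to
d ≈ 2e-4, and the hub's OPT entropy leaves its baseline at d ≈ 1e-4 —
a factor ~4 before the transition — while the leaf class stays flat. (On
this system the hub entropy starts moving almost immediately, so the
alarm's baseline window is restricted to the two weakest couplings; the
default 3-point window would swallow the departure itself.)
`optews reproduce fig1|fig2|fig3 --out DIR` writes reduced-realization
tables for all three families.

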