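# Methods

## Model and assumptions

The receiver is a sphere of radius `Rr` whose `n` receptors are treated as
statistically exchangeable and virtually co-located: no receptor-position
effects, no heterogeneous rates. Each receptor is a single-server loss
queue — one bond at a time, exponential service (trafficking) at rate `mu`,
no waiting room — so an arrival finding the receptor busy is lost
(rejected). Molecule transport is pure diffusion from a point transmitter
in an unbounded medium; there is no advection, degradation, desorption or
ligand–ligand interaction, and a molecule is removed once absorbed.

Arrivals at a receptor are modelled as a non-homogeneous Poisson process.
Fresh arrivals have rate `lambda_o(t) = rabsorb(t)/n`, where `rabsorb` is
the absorbing-receptor rate obtained by superposing the per-pulse hitting
fraction `F(t)` (linearity of the diffusion problem). Rejected molecules
remain near the surface and re-attempt with the capture probability
`Pc = F(delta_t)` evaluated at the bounce distance
`d* = 3*sqrt(3)*sqrt(2*D*dt_particle) + Rr` (three standard deviations of
a one-axis Brownian step, scaled for 3-D). Two deliberate approximations
are inherited from the underlying theory: (i) the overflow (re-attempt)
stream is treated as Poisson although true overflow traffic is Pascal with
larger variance; (ii) the occupancy entering the rejection/absorption split
is the *quasi-static* steady M/M/1/1 busy probability `Ao(t)/(1+Ao(t))`
applied pointwise in time.

`Pc` is computed once per configuration — it depends on `n`, `D`, the
particle step and the pulse period, never on `t`.

## Parameters

| parameter | meaning | default (reference set) |
|---|---|---|
| `Rr` | receiver radius | 2.5 µm |
| `rs` | receptor radius | 4 nm |
| `n` | receptor count | 10 000 |
| `d` | TX–RX centre distance | 26.5 µm |
| `D` | diffusion coefficient | 1.18e-10 m²/s |
| `Q`, `delta_t` | pulse size / period | 50 (or 100) / 10 ms |
| `1/mu` | mean trafficking time | 4 s (or 2 s) |
| `dt_particle` | particle step entering `d*` | 100 ns |
| `grid_dt` | rate-evaluation spacing | 10 ms (= `delta_t`) |

The defaults are the reference operating conditions of the study this
model targets; `D` is taken directly from that parameter set (the
Stokes–Einstein helper `kB*T/(6*pi*eta*rm)` reproduces it to within 3% at
T = 310 K, eta = 1.1 mPa·s, rm = 1.75 nm, but the temperature/viscosity
pair is not itself part of the reference set, so `D` is primary).
All internal computation is SI; config keys carry explicit unit suffixes
(`Rr_um`, `rs_nm`, `delta_t_ms`, ...) because the hitting-fraction
exponentials mix metre and inverse-metre scales and unit mix-ups are the
dominant failure mode.

## Numerical choices

- **Hitting fraction.** `F(t)` contains `exp(A)*erfc(B)` with `A` up to
  ~1e5, far beyond float range. It is evaluated as `erfcx(B)*exp(A-B^2)`
  with the exact identity `A - B^2 = -(d-Rr)^2/(4Dt)`; the result is finite
  and monotone for all `t`. `t <= 0` is special-cased to 0 (the limit value)
  rather than evaluating 0/0.
- **Pulse superposition.** Rates are evaluated on a grid aligned to pulse
  times with spacing `grid_dt = delta_t` by default. The divisor
  `min(t - tk, delta_t)` of the most recent pulse approaches 0/0; any pulse
  younger than `grid_dt/2` is dropped — with the reference distance the
  first arrivals of a pulse take ~1 s against a 10 ms period, so the
  dropped mass is far below double precision. On the aligned grid the pulse
  sum telescopes exactly to `(Q/delta_t)*F(t)`, which is asserted in tests.
  The pulse count is capped at the emission horizon `t_end`.
- **Integration.** Cumulative counts use the trapezoid rule on the
  evaluation grid; halving `grid_dt` moves `N_r(10 s)` and `N_a(10 s)` by
  well under 0.5%.
- **Dosing inversion.** Minimal `pi_r` by bisection on the binomial upper
  tail (monotone in `pi_r`; tolerance 1e-6), keeping the feasible endpoint
  so the achieved success probability never undershoots the target. The
  recapture feedback is inverted numerically by bisection on
  `[0, lambda_o']` (tolerance 1e-12 relative) instead of the closed-form
  quadratic, keeping a single code path that also covers `Pc = 0`.
  `nmin = 0` returns the smallest positive float with a warning.
- **Occupancy law.** Exact binomial up to `n = 1000`, continuity-corrected
  normal approximation above (the threshold is a package choice; the
  approximation is standard "for large n" without a stated cutoff). The
  continuity correction matters: without it the CDF sup-norm error at
  `n*pi_r*(1-pi_r) = 250` is ~1.3e-2; with it the error is an order of
  magnitude smaller. Tail probabilities go through the scipy survival
  function, never naive summation.
- **Queue bank.** Aggregate arrivals are generated by Lewis–Shedler
  thinning against a per-cell constant majorant 1.05× the cell maximum of
  the piecewise-linear `Lambda_o'`; a rate above its majorant raises
  instead of clipping. Arrivals are generated aggregate-then-split
  (uniform receptor assignment), statistically identical to n independent
  streams by Poisson superposition/splitting but O(total arrivals). One
  child generator per replicate is derived from the master seed, so runs
  are bit-reproducible.
- **Brownian oracle.** Plain end-of-step absorption test with no
  Brownian-bridge correction, to keep the oracle trivially auditable. The
  scheme *underestimates* the true first-passage CDF with a bias shrinking
  like sqrt(dt); the step precondition (per-axis sigma <= Rr/5) plus a 10%
  discretization allowance in the comparison report budget for it, and a
  test asserts the monotone approach as dt is refined.

## Queue-simulator outcome rules (a genuinely open design point)

The simulator supports two per-arrival outcome rules. The default,
`outcome="blocking"`, draws each arrival's fate from the model's
instantaneous busy probability `Ao(t)/(1+Ao(t))` — a direct Monte-Carlo of
the closed-form rate system that matches `N_r`/`N_a` in expectation at
every `t` and is what "using the M/M/1/1 model to determine the outcome"
means operationally. `outcome="stateful"` tracks explicit busy servers
(idle → absorb and hold for exp(mu); busy → reject). The two differ during
transients: the stateful bank's occupancy obeys
`dp/dt = lambda(1-p) - mu*p` and lags the quasi-static value by roughly
`1/(lambda+mu)` ≈ 3.6 s under the reference parameters — comparable to the
10 s horizon — giving `N_r(10 s)` ≈ 79 against the closed-form 130. The
stateful rule is therefore only compared to the closed forms near steady
state (the constant-rate Erlang-blocking check, where it is exact), while
the blocking rule validates the thinning/splitting/counting machinery
end to end.

## Synthetic data

The package consumes no external data; the packaged fixtures are parameter
sets, and all stochastic inputs are generated internally (thinned Poisson
arrivals, Gaussian Brownian steps) under the physical assumptions above.
Passing tests therefore demonstrate internal consistency of model,
simulator and oracle under ideal diffusion — not agreement with wet-lab
receptor kinetics, where receptor clustering, reversible binding,
competition and flow all violate the assumptions.

## Known limitations and discrepancies

- The quasi-static occupancy approximation overestimates early-time
  rejections relative to a true transient server bank (see above); both
  numbers are available in the package.
- Reported reference behaviour for the cumulative rejection count at
  t = 10 s (~200 for Q = 50, just under 1000 for Q = 100, 1/mu = 4 s) is
  not reproduced by the published closed-form chain, which yields 129.8 and
  517.6. Replacing the n-receptor hitting fraction in the *arrival* rate
  with its absorbing-sphere limit — an approximation the model itself
  argues against and that would erase the n-dependence of the arrival
  rate — yields ≈190 and ≈740, suggesting the reference figures were
  produced with that variant. This package implements the published
  equations; the corresponding acceptance test is expected to fail and the
  discrepancy is reported, not calibrated away.
- Steady-state convergence of the absorption rate is slow
  (`F(t)/F(inf) ≈ 1 - 2(d-Rr)/sqrt(4*pi*D*t)`): at t = 500 s the rate is
  still ~6% below its limit; limit tests evaluate at t = 1e7 s.
- The capture probability treats every bounced molecule as restarting from
  `d*` independently; correlations between successive attempts are ignored.
- Problem sizes used in the shipped tests and acceptance computations
  (10 s horizons on 10 ms grids, 2000–6000 Monte-Carlo particles, 20
  queue-bank replicates) were chosen as the smallest sizes at which
  sampling error is clearly below the effects being checked.
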