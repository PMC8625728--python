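# receptorq

Receptor-saturation queuing model for diffusion-based molecular
communication receivers, with a targeted-drug-delivery dosing case study.

## The problem

A transmitter nanomachine (a drug reservoir, an engineered cell) releases
pulses of Q ligand molecules every Δt seconds into an unbounded 3-D medium.
The molecules diffuse (coefficient D) toward a spherical receiver of radius
R_r at centre distance d, whose surface carries n circular receptors of
radius r_s. Binding is not instantaneous: an occupied receptor internalises
its ligand over an exponential *trafficking time* of mean 1/μ, during which
further ligands bounce off — the receiver *saturates*. Particle-based
simulation of such systems tracks millions of molecules; this package
instead models each receptor as a single-server loss queue (M/M/1/1) fed by
the diffusive arrival stream, which reproduces the aggregate
absorption/rejection behaviour in milliseconds.

## The model

Fresh arrivals per receptor derive from the closed-form hitting fraction of
an n-receptor sphere,

    F(t) = (R_r/d) · (n·r_s/(n·r_s + π·R_r)) · [erfc(u) − erfcx(B)·e^(−u²)],

with u = (d−R_r)/√(4Dt), α = (n·r_s + π·R_r)/(π·R_r²), B = u + α√(Dt)
(the bracket is the overflow-safe rewrite of erfc(u) − e^A·erfc(B) using
A − B² = −u²). Pulsed emission gives the per-receptor fresh rate
λ_o(t) = (Q/Δt)·F(t)/n. A ligand bounced off a busy receptor re-attempts
with capture probability P_c = F(Δt) evaluated at the bounce distance
d* = 3√3·√(2·D·dt) + R_r, inflating the offered rate to

    λ_o′ = λ_o · (1 + P_c · λ_o/(μ + λ_o)),   A_o = λ_o′/μ,

from which the loss-queue split is λ_r = A_o²μ/(1+A_o) (rejections) and
λ_a = A_o·μ/(1+A_o) (absorptions), with λ_a + λ_r = λ_o′ exactly.
Aggregates are n× the per-receptor rates; cumulative counts N_r(t), N_a(t)
are trapezoid integrals. The busy-receptor count is Binomial(n, A_o/(1+A_o)),
which supports dose planning: invert P(n_busy ≥ n_min) ≥ target for the
smallest release rate Q/Δt.

Two seeded stochastic tools validate the closed forms: a thinned
non-homogeneous Poisson queue-bank simulator, and a Brownian Monte-Carlo
oracle for the n→∞ (absorbing-sphere) limit (R_r/d)·erfc(u).

## Worked example

The packaged fixture `table1_q50_mu4` is the reference configuration:
R_r = 2.5 µm, r_s = 4 nm, n = 10 000, d = 26.5 µm, D = 1.18e-10 m²/s,
Q = 50 per 10 ms (5000 molecules/s), 1/μ = 4 s.

```sh
receptorq model run --config table1_q50_mu4 --out series.csv --summary summary.json
```

`summary.json` (rounded):

```json
{"Pc": 0.6515, "rabsorb_steady": 394.2812, "emission_rate": 5000.0,
 "lambda_o_ss": 0.0394, "lambda_o_prime_ss": 0.0429, "Ao_ss": 0.1717,
 "Lambda_a_ss": 366.3674, "Lambda_r_ss": 62.9092, "E_busy_ss": 1465.4696}
```

A bounced ligand is recaptured with probability 0.65; of the 5000
molecules/s released, 394.3/s would be absorbed by ideal (instantaneous)
receptors, but trafficking congestion lowers the steady absorption rate to
366.4/s and keeps ~1465 of the 10 000 receptors busy. Selected rows of
`series.csv`:

```text
 t_s  lambda_o       Ao        N_r         N_a     E_busy
 1.0  0.004424 0.017894   0.163998   14.269775 175.798683
 5.0  0.018821 0.078719  31.609954  535.524833 729.748168
10.0  0.024262 0.102641 129.847163 1592.892247 930.864069
```

By 10 s the receiver has absorbed ~1593 molecules and rejected ~130; the
slow ramp reflects the ~5 s diffusion time (d−R_r)²/D.

Dose planning — smallest release rate keeping at least 2000 receptors
occupied with 95% probability:

```sh
receptorq dose --config table1_q50_mu4 --nmin 2000 --target 0.95 --out dose.json
# => pi_r_required 0.2066, release_rate 7353.1 molecules/s,
#    achieved_p_success 0.9500
```

The stochastic validators are `receptorq queue-sim --config table1_q50_mu4
--seed 42 --replicates 20 --out sim.csv` and `receptorq oracle --config
table1_q50_mu4 --seed 7 --out oracle.csv`; `receptorq fixtures list` shows
the packaged parameter sets. See `docs/methods.md` for assumptions,
numerics and limitations.

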