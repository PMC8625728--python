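"""Saturated-receiver rate system.

Each receptor is a single-server loss queue (M/M/1/1): a bound ligand
occupies the receptor for an exponential trafficking time of mean 1/mu,
during which further ligands bounce off.  A bounced ligand stays close to
the surface and re-attempts with the capture probability Pc, which feeds
back into the offered arrival rate:

    lambda_o'(t) = lambda_o(t) * (1 + Pc * lambda_o(t) / (mu + lambda_o(t)))
    Ao(t)        = lambda_o'(t) / mu                      (offered load)
    lambda_r(t)  = Ao^2 * mu / (1 + Ao)                   (rejections)
    lambda_a(t)  = Ao * mu / (1 + Ao)                     (absorptions)

``Ao/(1+Ao)`` is the single-server Erlang blocking (= busy) probability, so
``lambda_a + lambda_r = lambda_o'`` exactly.  Aggregates are n times the
per-receptor rates (receptors are treated as co-located and exchangeable),
and the cumulative absorption/rejection counts are trapezoid integrals of
the aggregate rates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .config import GeometryParams, ModelConfig
from .diffusion import fhit_cumulative, fhit_infinity, rabsorb_rate, rabsorb_steady

__all__ = [
    "RateSeries",
    "d_star",
    "capture_probability",
    "lambda_o_prime",
    "offered_load",
    "rejection_rate",
    "absorption_rate",
    "build_rate_series",
    "steady_state_absorption",
    "steady_state_summary",
]


@dataclass(frozen=True)
class RateSeries:
    """Per-receptor and aggregate rate trajectories on a time grid.

    Rates are 1/s; ``Ao`` is dimensionless; ``Nr``/``Na`` are cumulative
    rejection/absorption counts; ``E_busy`` is the expected number of busy
    receptors n*Ao/(1+Ao).
    """

    t: np.ndarray
    lambda_o: np.ndarray
    lambda_o_prime: np.ndarray
    lambda_r: np.ndarray
    lambda_a: np.ndarray
    Ao: np.ndarray
    Lambda_o_prime: np.ndarray
    Lambda_r: np.ndarray
    Lambda_a: np.ndarray
    Nr: np.ndarray
    Na: np.ndarray
    E_busy: np.ndarray
    n: int
    Pc: float

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the canonical column order."""
        return pd.DataFrame({
            "t_s": self.t,
            "lambda_o": self.lambda_o,
            "lambda_o_prime": self.lambda_o_prime,
            "Ao": self.Ao,
            "Lambda_r": self.Lambda_r,
            "Lambda_a": self.Lambda_a,
            "N_r": self.Nr,
            "N_a": self.Na,
            "E_busy": self.E_busy,
        })


def d_star(D: float, dt_particle: float, Rr: float) -> float:
    """Distance from the receiver centre after a bounce off a busy receptor:
    sqrt(3) * 3*sqrt(2*D*dt) + Rr, i.e. three standard deviations of a
    single-axis Brownian step in one particle time step, scaled by sqrt(3)
    for the three spatial dimensions, measured from the surface."""
    if not (D > 0 and dt_particle > 0 and Rr > 0):
        raise ValueError(f"D, dt_particle, Rr must be > 0, got {D}, {dt_particle}, {Rr}")
    return math.sqrt(3.0) * 3.0 * math.sqrt(2.0 * D * dt_particle) + Rr


def capture_probability(geom: GeometryParams, D: float, dt_particle: float,
                        delta_t: float) -> float:
    """Probability that a ligand bounced off a busy receptor reaches the
    receiver's receptors again within one emission period: the hitting
    fraction evaluated at ``delta_t`` with the TX-RX distance replaced by the
    bounce distance d*.  Constant in time for a given configuration."""
    if delta_t < 0:
        raise ValueError("delta_t must be >= 0")
    if delta_t == 0:
        return 0.0
    pc = float(fhit_cumulative(delta_t, geom, D,
                               d_override=d_star(D, dt_particle, geom.Rr)))
    return min(max(pc, 0.0), 1.0)


def lambda_o_prime(lambda_o_t, Pc: float, mu: float):
    """Total offered rate per receptor, fresh arrivals plus re-attempts:
    lambda_o * (1 + Pc * lambda_o/(mu + lambda_o)).  The second factor uses
    the probability lambda_o/(mu+lambda_o) of finding the receptor busy."""
    if mu <= 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    if not 0.0 <= Pc <= 1.0:
        raise ValueError(f"Pc must be in [0, 1], got {Pc}")
    lo = np.asarray(lambda_o_t, dtype=float)
    if np.any(lo < 0):
        raise ValueError("lambda_o must be >= 0")
    out = lo * (1.0 + Pc * lo / (mu + lo))
    return out if out.ndim else float(out)


def offered_load(lambda_o_prime_t, mu: float):
    """Per-receptor load Ao = lambda_o' / mu (dimensionless)."""
    if mu <= 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    out = np.asarray(lambda_o_prime_t, dtype=float) / mu
    return out if out.ndim else float(out)


def rejection_rate(Ao, mu: float):
    """Per-receptor rejection rate Ao^2 * mu / (1 + Ao): offered rate times
    the Erlang single-server blocking probability Ao/(1+Ao)."""
    A = np.asarray(Ao, dtype=float)
    out = A * A * mu / (1.0 + A)
    return out if out.ndim else float(out)


def absorption_rate(Ao, mu: float):
    """Per-receptor absorption rate Ao * mu / (1 + Ao); complements
    :func:`rejection_rate` so that lambda_a + lambda_r = lambda_o' exactly."""
    A = np.asarray(Ao, dtype=float)
    out = A * mu / (1.0 + A)
    return out if out.ndim else float(out)


def build_rate_series(config: ModelConfig) -> RateSeries:
    """Evaluate the full rate system on the configured grid.

    The grid spans [0, t_end] with spacing ``numerics.grid_dt`` (default one
    pulse period, aligned with the pulse times).  Cumulative counts use the
    trapezoid rule on that grid.
    """
    geom, med, em, kin, num = (config.geometry, config.medium, config.emission,
                               config.kinetics, config.numerics)
    n_steps = int(round(em.t_end / num.grid_dt))
    if n_steps < 1 or not math.isclose(n_steps * num.grid_dt, em.t_end, rel_tol=1e-9):
        raise ValueError(f"grid_dt={num.grid_dt} must divide t_end={em.t_end}")
    t = np.arange(n_steps + 1) * num.grid_dt

    lo = np.array([rabsorb_rate(ti, geom, med.D, em, num.grid_dt) for ti in t]) / geom.n
    Pc = capture_probability(geom, med.D, num.dt_particle, em.delta_t)
    lop = lambda_o_prime(lo, Pc, kin.mu)
    Ao = offered_load(lop, kin.mu)
    lr = rejection_rate(Ao, kin.mu)
    la = absorption_rate(Ao, kin.mu)
    n = geom.n
    Nr = cumulative_trapezoid(n * lr, t, initial=0.0)
    Na = cumulative_trapezoid(n * la, t, initial=0.0)
    return RateSeries(t=t, lambda_o=lo, lambda_o_prime=lop, lambda_r=lr,
                      lambda_a=la, Ao=Ao, Lambda_o_prime=n * lop,
                      Lambda_r=n * lr, Lambda_a=n * la, Nr=Nr, Na=Na,
                      E_busy=n * Ao / (1.0 + Ao), n=n, Pc=Pc)


def steady_state_absorption(config: ModelConfig) -> float:
    """Steady-state aggregate absorption rate Lambda_a = n*lambda_o'/(1+Ao),
    evaluated with the steady per-receptor fresh rate lambda_o =
    rabsorb_steady/n.  Recovers the absorbing-receptor rate as mu -> inf."""
    return steady_state_summary(config)["Lambda_a_ss"]


def steady_state_summary(config: ModelConfig) -> dict[str, float]:
    """Steady-state quantities of the configured system (all 1/s except the
    dimensionless Pc, Ao and busy-receptor count)."""
    geom, med, em, kin, num = (config.geometry, config.medium, config.emission,
                               config.kinetics, config.numerics)
    r_ss = rabsorb_steady(geom, med.D, em)
    lo = r_ss / geom.n
    Pc = capture_probability(geom, med.D, num.dt_particle, em.delta_t)
    lop = lambda_o_prime(lo, Pc, kin.mu)
    Ao = offered_load(lop, kin.mu)
    return {
        "Pc": Pc,
        "rabsorb_steady": r_ss,
        "emission_rate": em.rate,
        "fhit_infinity": fhit_infinity(geom),
        "lambda_o_ss": lo,
        "lambda_o_prime_ss": lop,
        "Ao_ss": Ao,
        "Lambda_a_ss": geom.n * lop / (1.0 + Ao),
        "Lambda_r_ss": geom.n * rejection_rate(Ao, kin.mu),
        "E_busy_ss": geom.n * Ao / (1.0 + Ao),
    }
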