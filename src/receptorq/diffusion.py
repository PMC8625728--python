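"""Diffusive hitting fraction of an n-receptor spherical receiver and the
pulsed-emission absorption-rate model built on it.

A point transmitter at centre distance ``d`` from a spherical receiver of
radius ``Rr`` releases molecules that diffuse with coefficient ``D``.  The
receiver carries ``n`` circular, perfectly absorbing receptors of radius
``rs``.  The expected fraction of a pulse absorbed by time ``t`` has the
closed form

    F(t) = (Rr/d) * (n*rs / (n*rs + pi*Rr))
           * [ erfc(u) - erfcx(B) * exp(-u^2) ]

with ``u = (d-Rr)/sqrt(4*D*t)``, ``alpha = (n*rs + pi*Rr)/(pi*Rr^2)`` and
``B = u + alpha*sqrt(D*t)``.  The bracket is the numerically stable rewrite
of ``erfc(u) - exp(A)*erfc(B)`` using the identity ``A - B^2 = -u^2`` with
``A = (d-Rr)*alpha + D*t*alpha^2``: the naive ``exp(A)`` overflows for any
realistic receptor density, while ``erfcx(B)*exp(-u^2)`` is stable for all
``t``.  As ``n -> inf`` the formula reduces to the classic absorbing-sphere
first-passage CDF ``(Rr/d)*erfc(u)``.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.special import erfc, erfcx

from .config import KB, EmissionSchedule, GeometryParams

__all__ = [
    "stokes_einstein_D",
    "fhit_cumulative",
    "fhit_infinity",
    "fhit_window",
    "absorbing_sphere_cdf",
    "rabsorb_rate",
    "lambda_o",
    "rabsorb_steady",
]


def stokes_einstein_D(T: float, eta: float, rm: float) -> float:
    """Diffusion coefficient of a sphere of radius ``rm`` (m) in a medium of
    viscosity ``eta`` (Pa*s) at temperature ``T`` (K): kB*T / (6*pi*eta*rm)."""
    if not (T > 0 and eta > 0 and rm > 0):
        raise ValueError(f"T, eta, rm must all be > 0, got T={T}, eta={eta}, rm={rm}")
    D = KB * T / (6.0 * math.pi * eta * rm)
    if not (D > 0 and math.isfinite(D)):
        raise ValueError(f"derived diffusion coefficient is not positive/finite: {D}")
    return D


def _effective_d(geom: GeometryParams, d_override: float | None) -> float:
    d = geom.d if d_override is None else float(d_override)
    if d <= geom.Rr:
        raise ValueError(f"distance {d} must exceed the receiver radius {geom.Rr}")
    return d


def fhit_infinity(geom: GeometryParams, d_override: float | None = None) -> float:
    """Analytic t->inf plateau (Rr/d) * n*rs/(n*rs + pi*Rr)."""
    d = _effective_d(geom, d_override)
    nrs = geom.n * geom.rs
    return (geom.Rr / d) * nrs / (nrs + math.pi * geom.Rr)


def fhit_cumulative(t, geom: GeometryParams, D: float,
                    d_override: float | None = None):
    """Expected fraction of a single pulse absorbed by the n receptors up to
    time ``t`` (s).  Vectorised over ``t``; ``t = 0`` returns 0 (continuity).

    ``d_override`` replaces the TX-RX distance, which is how the capture
    probability after a bounce off a busy receptor reuses this formula with
    the bounce distance d*.
    """
    d = _effective_d(geom, d_override)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    pref = fhit_infinity(geom, d)
    alpha = (geom.n * geom.rs + math.pi * geom.Rr) / (math.pi * geom.Rr**2)
    out = np.zeros_like(t)
    pos = t > 0
    if np.any(pos):
        tp = t[pos]
        u = (d - geom.Rr) / np.sqrt(4.0 * D * tp)
        B = u + alpha * np.sqrt(D * tp)
        out[pos] = pref * (erfc(u) - erfcx(B) * np.exp(-u * u))
    return out if out.ndim else float(out)


def absorbing_sphere_cdf(t, Rr: float, d: float, D: float):
    """First-passage CDF to a fully absorbing sphere, (Rr/d)*erfc((d-Rr)/sqrt(4Dt)).

    This is the n->inf limit of :func:`fhit_cumulative` and the analytic
    reference for the Brownian Monte-Carlo oracle.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = (Rr / d) * erfc((d - Rr) / np.sqrt(4.0 * D * t[pos]))
    return out if out.ndim else float(out)


def fhit_window(t1: float, t2: float, geom: GeometryParams, D: float,
                d_override: float | None = None) -> float:
    """Expected fraction absorbed in the interval (t1, t2]."""
    if t1 > t2:
        raise ValueError(f"window requires t1 <= t2, got ({t1}, {t2})")
    return float(fhit_cumulative(t2, geom, D, d_override)
                 - fhit_cumulative(t1, geom, D, d_override))


def rabsorb_rate(t: float, geom: GeometryParams, D: float,
                 emission: EmissionSchedule,
                 grid_dt: float | None = None) -> float:
    """Absorption rate (molecules/s) at time ``t`` of a receiver with
    absorbing receptors, for pulses of ``Q`` molecules every ``delta_t``:

        Q * sum_k  F(max(0, t-tk-delta_t), t-tk] / min(t-tk, delta_t)

    over pulses ``tk = k*delta_t`` with ``k <= floor(t/delta_t)`` (the pulse
    at exactly ``t`` contributes nothing), capped at the emission horizon.
    A pulse younger than half the evaluation-grid spacing is dropped: its
    divisor ``min(t-tk, delta_t)`` approaches 0/0 while the diffusion lag
    makes its true contribution negligible.

    On a grid aligned with the pulse times this sum telescopes exactly to
    ``(Q/delta_t) * F(t)``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    dt = emission.delta_t
    eps = 0.5 * (dt if grid_dt is None else float(grid_dt))
    n_pulses = min(math.floor(t / dt), math.floor(emission.t_end / dt))
    age = t - dt * np.arange(0, n_pulses + 1)  # age of each pulse at time t
    age = age[age >= eps]
    if age.size == 0:
        return 0.0
    win = (fhit_cumulative(age, geom, D)
           - fhit_cumulative(np.maximum(age - dt, 0.0), geom, D))
    return float(emission.Q * np.sum(win / np.minimum(age, dt)))


def lambda_o(t: float, geom: GeometryParams, D: float,
             emission: EmissionSchedule, grid_dt: float | None = None) -> float:
    """Fresh-molecule arrival rate per receptor (1/s): rabsorb_rate / n."""
    return rabsorb_rate(t, geom, D, emission, grid_dt) / geom.n


def rabsorb_steady(geom: GeometryParams, D: float,
                   emission: EmissionSchedule) -> float:
    """Steady-state absorption rate (molecules/s) of the absorbing-receptor
    receiver: (Q/delta_t) * (Rr/d) * n*rs/(n*rs + pi*Rr)."""
    return emission.rate * fhit_infinity(geom)
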