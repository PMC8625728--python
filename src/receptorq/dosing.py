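"""Receptor-occupancy statistics and release-rate planning.

With n exchangeable receptors each busy with probability
``pi_r = Ao/(1+Ao)`` (the single-server Erlang blocking probability), the
number of busy receptors is Binomial(n, pi_r), well approximated by a
normal law for large n.  For drugs that only need a minimum number of
occupied receptors (e.g. competitive antagonists), the success probability
is the binomial upper tail P(n_busy >= n_min); inverting it yields the
smallest release rate Q/delta_t that achieves a target success probability
at steady state.
"""
from __future__ import annotations

import math
import sys
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import ModelConfig
from .diffusion import fhit_infinity
from .saturation import capture_probability, lambda_o_prime, offered_load

__all__ = [
    "OccupancyDistribution",
    "DosingSolution",
    "occupancy_probability",
    "busy_distribution",
    "p_success",
    "invert_for_release_rate",
    "forward_p_success",
]

#: above this receptor count the normal approximation is used by default
NORMAL_APPROX_THRESHOLD = 1000


def occupancy_probability(Ao) -> float:
    """Per-receptor busy probability pi_r = Ao/(1+Ao) for offered load Ao
    (coincides with the rejection probability of the loss queue)."""
    A = np.asarray(Ao, dtype=float)
    if np.any(A < 0):
        raise ValueError("Ao must be >= 0")
    out = A / (1.0 + A)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class OccupancyDistribution:
    """Law of the number of busy receptors at a time point.

    ``law`` is ``"binomial"`` (exact) or ``"normal-approx"`` (continuity
    corrected); mean and variance are n*pi_r and n*pi_r*(1-pi_r) either way.
    """

    n: int
    pi_r: float
    law: str

    @property
    def mean(self) -> float:
        return self.n * self.pi_r

    @property
    def variance(self) -> float:
        return self.n * self.pi_r * (1.0 - self.pi_r)

    def _frozen(self):
        if self.law == "binomial":
            return stats.binom(self.n, self.pi_r)
        return stats.norm(loc=self.mean, scale=math.sqrt(max(self.variance, 0.0)))

    def pmf(self, k):
        """P(n_busy = k); for the normal law, the unit-interval mass around k."""
        if self.law == "binomial":
            return stats.binom.pmf(k, self.n, self.pi_r)
        fr = self._frozen()
        return fr.cdf(np.asarray(k) + 0.5) - fr.cdf(np.asarray(k) - 0.5)

    def cdf(self, k):
        """P(n_busy <= k) (continuity corrected under the normal law)."""
        if self.law == "binomial":
            return stats.binom.cdf(k, self.n, self.pi_r)
        return self._frozen().cdf(np.asarray(k, dtype=float) + 0.5)

    def tail(self, k):
        """Upper tail P(n_busy >= k)."""
        if self.law == "binomial":
            return stats.binom.sf(np.asarray(k) - 1, self.n, self.pi_r)
        return self._frozen().sf(np.asarray(k, dtype=float) - 0.5)


def busy_distribution(n: int, pi_r: float, *,
                      threshold: int = NORMAL_APPROX_THRESHOLD,
                      exact: bool | None = None) -> OccupancyDistribution:
    """Occupancy law for ``n`` receptors with busy probability ``pi_r``:
    exact binomial for n <= ``threshold``, normal approximation above.
    ``exact=True``/``False`` forces the law regardless of n."""
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"n must be a positive integer, got {n}")
    if not 0.0 <= pi_r <= 1.0:
        raise ValueError(f"pi_r must be in [0, 1], got {pi_r}")
    if exact is None:
        exact = n <= threshold
    return OccupancyDistribution(n=int(n), pi_r=float(pi_r),
                                 law="binomial" if exact else "normal-approx")


def p_success(nmin: int, n: int, pi_r: float) -> float:
    """Probability that at least ``nmin`` of ``n`` receptors are busy,
    P(n_busy >= nmin) under Binomial(n, pi_r), computed through the
    binomial survival function (numerically stable in both tails)."""
    if not 0 <= nmin <= n:
        raise ValueError(f"nmin must satisfy 0 <= nmin <= n, got nmin={nmin}, n={n}")
    if not 0.0 <= pi_r <= 1.0:
        raise ValueError(f"pi_r must be in [0, 1], got {pi_r}")
    return float(stats.binom.sf(nmin - 1, n, pi_r))


@dataclass(frozen=True)
class DosingSolution:
    """Release rate achieving a target minimum-occupancy probability."""

    pi_r_required: float
    Ao_required: float
    lambda_o_required: float
    release_rate: float
    achieved_p_success: float
    nmin: int
    target: float


def _invert_lambda_o(lop_target: float, Pc: float, mu: float,
                     rel_tol: float = 1e-12) -> float:
    """Invert lambda_o' = lambda_o*(1 + Pc*lambda_o/(mu+lambda_o)) for
    lambda_o by bisection on [0, lambda_o'] (the map is increasing and
    lambda_o' >= lambda_o).  A single numeric code path covers Pc = 0."""
    if lop_target <= 0.0:
        return 0.0
    lo_low, lo_high = 0.0, lop_target
    while lo_high - lo_low > rel_tol * lop_target:
        mid = 0.5 * (lo_low + lo_high)
        if lambda_o_prime(mid, Pc, mu) < lop_target:
            lo_low = mid
        else:
            lo_high = mid
    return 0.5 * (lo_low + lo_high)


def invert_for_release_rate(nmin: int, target: float, config: ModelConfig,
                            pi_tol: float = 1e-6) -> DosingSolution:
    """Smallest steady-state release rate Q/delta_t (molecules/s) whose
    induced receptor occupancy satisfies P(n_busy >= nmin) >= target.

    Chain: bisect for the minimal busy probability pi_r with
    p_success(nmin, n, pi_r) >= target; map pi_r -> Ao = pi_r/(1-pi_r) and
    Ao -> lambda_o' = Ao*mu; invert the recapture feedback numerically for
    lambda_o; scale to the release rate through the steady-state absorption
    law Q/delta_t = lambda_o * n / [(Rr/d) * n*rs/(n*rs + pi*Rr)].
    """
    geom, kin = config.geometry, config.kinetics
    n = geom.n
    if not 0.0 < target < 1.0:
        raise ValueError(f"target must be in (0, 1), got {target}")
    if not 0 <= nmin <= n:
        raise ValueError(f"nmin must satisfy 0 <= nmin <= n = {n}, got {nmin}")

    if nmin == 0:
        warnings.warn("nmin=0 is always satisfied; returning the smallest "
                      "representable positive release rate", UserWarning)
        return DosingSolution(pi_r_required=0.0, Ao_required=0.0,
                              lambda_o_required=0.0,
                              release_rate=sys.float_info.min,
                              achieved_p_success=1.0, nmin=nmin, target=target)

    # minimal pi_r with p_success >= target; p_success is continuous and
    # nondecreasing in pi_r with p_success(1) = 1, so the target is always
    # reachable for target < 1 -- the hi endpoint stays feasible throughout.
    lo, hi = 0.0, 1.0
    if p_success(nmin, n, hi) < target:  # defensive; cannot happen for target < 1
        raise ValueError(f"target {target} unreachable with pi_r < 1")
    while hi - lo > pi_tol:
        mid = 0.5 * (lo + hi)
        if p_success(nmin, n, mid) >= target:
            hi = mid
        else:
            lo = mid
    pi_r = hi  # feasible endpoint: achieved_p_success >= target by construction
    if pi_r >= 1.0:
        raise ValueError(f"target {target} with nmin={nmin} requires pi_r >= 1: infeasible")

    Ao = pi_r / (1.0 - pi_r)
    lop = Ao * kin.mu
    Pc = capture_probability(geom, config.medium.D, config.numerics.dt_particle,
                             config.emission.delta_t)
    lam_o = _invert_lambda_o(lop, Pc, kin.mu)
    release_rate = lam_o * n / fhit_infinity(geom)
    return DosingSolution(pi_r_required=pi_r, Ao_required=Ao,
                          lambda_o_required=lam_o, release_rate=release_rate,
                          achieved_p_success=p_success(nmin, n, pi_r),
                          nmin=nmin, target=target)


def forward_p_success(release_rate: float, nmin: int, config: ModelConfig) -> float:
    """Steady-state p_success produced by a given release rate Q/delta_t;
    the forward direction of :func:`invert_for_release_rate` (round-trip
    check and what-if evaluation)."""
    geom, kin = config.geometry, config.kinetics
    lam_o = release_rate * fhit_infinity(geom) / geom.n
    Pc = capture_probability(geom, config.medium.D, config.numerics.dt_particle,
                             config.emission.delta_t)
    Ao = offered_load(lambda_o_prime(lam_o, Pc, kin.mu), kin.mu)
    return p_success(nmin, geom.n, occupancy_probability(Ao))
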