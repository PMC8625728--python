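"""Stochastic receptor-bank simulator.

Aggregate molecule arrivals at the receiver form a non-homogeneous Poisson
process with rate Lambda_o'(t) = n * lambda_o'(t), generated by
Lewis-Shedler thinning against a piecewise-constant majorant.  Each arrival
is assigned to one of the n receptors uniformly at random (Poisson
splitting) and its outcome decided by one of two rules:

``outcome="blocking"`` (default)
    The arrival is rejected with the model's instantaneous busy probability
    Ao(t)/(1+Ao(t)); absorbed arrivals draw an exponential(mu) service used
    only for the busy-receptor trace.  This is a direct Monte-Carlo of the
    closed-form rate system and matches it in expectation at every t.

``outcome="stateful"``
    Each receptor carries explicit busy state: an arrival to an idle
    receptor starts an exponential(mu) service and is absorbed, an arrival
    to a busy receptor is rejected.  This is the physical loss-queue bank;
    during rate transients its occupancy lags the quasi-static closed forms
    by roughly the relaxation time 1/(lambda+mu) (see docs/methods.md), so
    only compare it to them near steady state.

Both rules are fully reproducible from the master seed (one child generator
per replicate).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .saturation import RateSeries, build_rate_series

__all__ = ["QueueSimResult", "ComparisonReport", "simulate_bank",
           "simulate_from_series", "constant_rate_series", "compare_to_model"]

#: safety factor of the thinning majorant over the per-cell maximum rate
MAJORANT_FACTOR = 1.05


@dataclass(frozen=True)
class QueueSimResult:
    """Cumulative counts per time bin for each replicate.

    ``arrivals``, ``absorptions``, ``rejections`` have shape
    (replicates, len(time_bins)) and satisfy
    arrivals = absorptions + rejections exactly; ``n_busy`` is the number of
    receptors in service at each bin edge.
    """

    seed: int
    time_bins: np.ndarray
    arrivals: np.ndarray
    absorptions: np.ndarray
    rejections: np.ndarray
    n_busy: np.ndarray
    n: int
    mu: float
    outcome: str

    @property
    def replicates(self) -> int:
        return self.arrivals.shape[0]


def _thinned_arrivals(rng: np.random.Generator, t: np.ndarray,
                      Lam: np.ndarray) -> np.ndarray:
    """Arrival times of a non-homogeneous Poisson process with piecewise-
    linear rate ``Lam`` on grid ``t``, by thinning against a per-cell
    constant majorant."""
    times: list[np.ndarray] = []
    for i in range(len(t) - 1):
        width = t[i + 1] - t[i]
        maj = MAJORANT_FACTOR * max(Lam[i], Lam[i + 1])
        if maj <= 0.0:
            continue
        k = rng.poisson(maj * width)
        if k == 0:
            continue
        cand = t[i] + width * rng.random(k)
        lam_c = np.interp(cand, t, Lam)
        if np.any(lam_c > maj):
            raise RuntimeError("thinning majorant violated; rate exceeds "
                               f"{maj} in cell [{t[i]}, {t[i+1]}]")
        times.append(cand[rng.random(k) * maj < lam_c])
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def simulate_from_series(series: RateSeries, mu: float, seed: int,
                         replicates: int = 1,
                         outcome: str = "blocking") -> QueueSimResult:
    """Run the receptor bank against a precomputed :class:`RateSeries`."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if outcome not in ("blocking", "stateful"):
        raise ValueError(f"outcome must be 'blocking' or 'stateful', got {outcome!r}")
    t = series.t
    n = series.n
    nb = len(t)
    shape = (replicates, nb)
    arr = np.zeros(shape, dtype=np.int64)
    absd = np.zeros(shape, dtype=np.int64)
    rej = np.zeros(shape, dtype=np.int64)
    busy = np.zeros(shape, dtype=np.int64)
    pi_busy = series.Ao / (1.0 + series.Ao)

    for r in range(replicates):
        rng = np.random.default_rng([int(seed), r])
        at = _thinned_arrivals(rng, t, series.Lambda_o_prime)
        starts: np.ndarray
        ends: np.ndarray
        if at.size == 0:
            rejected = np.empty(0, dtype=bool)
            starts = ends = np.empty(0)
        elif outcome == "blocking":
            p = np.interp(at, t, pi_busy)
            rejected = rng.random(at.size) < p
            starts = at[~rejected]
            ends = starts + rng.exponential(1.0 / mu, starts.size)
        else:  # stateful
            rid = rng.integers(0, n, at.size)
            service = rng.exponential(1.0 / mu, at.size)  # drawn per arrival: fixed stream layout
            busy_until = np.zeros(n)
            rejected = np.zeros(at.size, dtype=bool)
            s_list, e_list = [], []
            for j in range(at.size):
                if busy_until[rid[j]] > at[j]:
                    rejected[j] = True
                else:
                    busy_until[rid[j]] = at[j] + service[j]
                    s_list.append(at[j])
                    e_list.append(busy_until[rid[j]])
            starts = np.asarray(s_list)
            ends = np.asarray(e_list)
        arr[r] = np.searchsorted(at, t, side="right")
        rej[r] = np.searchsorted(np.sort(at[rejected]) if at.size else at, t, side="right")
        absd[r] = arr[r] - rej[r]
        busy[r] = (np.searchsorted(np.sort(starts), t, side="right")
                   - np.searchsorted(np.sort(ends), t, side="right"))
    return QueueSimResult(seed=int(seed), time_bins=t, arrivals=arr,
                          absorptions=absd, rejections=rej, n_busy=busy,
                          n=n, mu=mu, outcome=outcome)


def simulate_bank(config: ModelConfig, seed: int, replicates: int = 1,
                  outcome: str = "blocking") -> QueueSimResult:
    """Build the closed-form rate series for ``config`` and run the
    stochastic receptor bank against it."""
    series = build_rate_series(config)
    return simulate_from_series(series, config.kinetics.mu, seed, replicates, outcome)


def constant_rate_series(lam_per_receptor: float, n: int, mu: float,
                         t_end: float, grid_dt: float) -> RateSeries:
    """Synthetic series with a time-constant per-receptor offered rate;
    handy for steady-state checks (e.g. Erlang blocking at lambda = mu)."""
    t = np.arange(0.0, t_end + grid_dt / 2, grid_dt)
    lop = np.full_like(t, lam_per_receptor)
    Ao = lop / mu
    lr = Ao * Ao * mu / (1.0 + Ao)
    la = Ao * mu / (1.0 + Ao)
    from scipy.integrate import cumulative_trapezoid
    return RateSeries(t=t, lambda_o=lop.copy(), lambda_o_prime=lop, lambda_r=lr,
                      lambda_a=la, Ao=Ao, Lambda_o_prime=n * lop, Lambda_r=n * lr,
                      Lambda_a=n * la, Nr=cumulative_trapezoid(n * lr, t, initial=0.0),
                      Na=cumulative_trapezoid(n * la, t, initial=0.0),
                      E_busy=n * Ao / (1.0 + Ao), n=n, Pc=0.0)


@dataclass(frozen=True)
class ComparisonReport:
    """Per-bin z-scores of simulated cumulative counts against the model."""

    t: np.ndarray
    z_rejections: np.ndarray
    z_absorptions: np.ndarray
    max_abs_z: float


def _zscores(counts: np.ndarray, model: np.ndarray) -> np.ndarray:
    mean = counts.mean(axis=0)
    se = counts.std(axis=0, ddof=1) / np.sqrt(counts.shape[0])
    z = np.zeros_like(mean, dtype=float)
    ok = se > 0
    z[ok] = (mean[ok] - model[ok]) / se[ok]
    z[~ok] = np.where(np.abs(mean[~ok] - model[~ok]) < 1.0, 0.0, np.inf)
    return z


def compare_to_model(result: QueueSimResult, series: RateSeries) -> ComparisonReport:
    """z-scores of the replicate-mean cumulative rejection/absorption counts
    against the closed-form Nr/Na on the shared grid."""
    if result.arrivals.size == 0 or result.replicates < 2:
        raise ValueError("need a non-empty result with at least 2 replicates")
    if result.time_bins.shape != series.t.shape or not np.allclose(result.time_bins, series.t):
        raise ValueError("result and series are on different time grids")
    z_r = _zscores(result.rejections, series.Nr)
    z_a = _zscores(result.absorptions, series.Na)
    return ComparisonReport(t=series.t, z_rejections=z_r, z_absorptions=z_a,
                            max_abs_z=float(max(np.max(np.abs(z_r)), np.max(np.abs(z_a)))))
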