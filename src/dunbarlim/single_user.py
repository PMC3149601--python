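"""Mean-field reduction: one focal user among independent partners.

The focal user has ``k_i`` directed links — ``k_i/2`` partners reached
through outgoing links and the same partners sending through incoming ones.
Partner dynamics are ignored: each partner independently sends one message
per step with probability ``min(1, beta * k_i)``, the popularity effect that
makes inflow scale as ``<R> ~ k_i^2`` (``k_i/2`` sources, each sending at a
rate itself proportional to ``k_i``).  The focal user runs exactly the
network model's reply/enqueue mechanics with queue capacity ``q_cap`` (plus
optional Gaussian noise); partner priorities are drawn once per run from a
discrete power law.

Two regimes emerge in ``omega_out(T) = total replies / (k_i/2)``:

* sub-saturation (inflow well below capacity): every message is eventually
  answered, replies track inflow, ``omega ~ beta * k_i * T`` grows with k;
* saturation (inflow exceeds capacity): the queue pins at ``q_cap`` and the
  per-step reply count at ``~q_cap/2``, so ``omega ~ T * q_cap / k_i``
  decays as 1/k.

The crossover degree — the peak of the curve — scales with queue capacity;
its absolute position also depends on the send-rate normaliser ``beta``,
which has no canonical value, so only the regime structure is meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from .queue_abm import derive_seed

__all__ = [
    "SingleUserConfig",
    "SingleUserResult",
    "run_single_user",
    "sweep_single_user",
    "loglog_slope",
    "fit_regime_exponents",
    "sigma_robustness",
    "sample_partner_priorities",
]

PRIORITY_SUPPORT = (1, 10_000)  # discrete power-law support for partner priorities


@dataclass
class SingleUserConfig:
    k_i: int                    # total degree; k_out = k_in = k_i / 2
    q_cap: int = 50
    gamma_prio: float = -2.1
    T: int = 500
    beta: float = 5e-4          # per-partner send prob = min(1, beta * k_i)
    sigma: float = 0.0          # sd of Gaussian noise on the focal capacity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_i < 2 or self.k_i % 2 != 0:
            raise ValueError("k_i must be even and >= 2")
        if self.q_cap < 1 or self.T < 1 or self.beta < 0 or self.sigma < 0:
            raise ValueError("invalid configuration")

    @property
    def n_partners(self) -> int:
        return self.k_i // 2

    @property
    def send_prob(self) -> float:
        s = self.beta * self.k_i
        if s > 1.0:
            warnings.warn(
                f"beta*k_i = {s:.3g} > 1 clamped to 1; inflow no longer "
                "scales quadratically at this k"
            )
            return 1.0
        return s


@dataclass
class SingleUserResult:
    config: SingleUserConfig
    omega_T: float              # total replies / (k_i / 2)
    mean_inflow: float          # messages received per step, before discard
    replies_total: int
    partner_weights: np.ndarray
    capacity_used: int


def sample_partner_priorities(
    n: int, gamma: float, rng: np.random.Generator
) -> np.ndarray:
    """Static partner priorities from a discrete power law on [1, 1e4]."""
    lo, hi = PRIORITY_SUPPORT
    support = np.arange(lo, hi + 1, dtype=np.float64)
    pmf = support**gamma
    pmf /= pmf.sum()
    return rng.choice(np.arange(lo, hi + 1), size=n, p=pmf).astype(np.float64)


def run_single_user(config: SingleUserConfig) -> SingleUserResult:
    """Simulate the focal user for T steps."""
    rng = np.random.default_rng(config.seed)
    prios = sample_partner_priorities(config.n_partners, config.gamma_prio, rng)
    if config.sigma > 0:
        cap = max(int(round(rng.normal(config.q_cap, config.sigma))), 1)
    else:
        cap = config.q_cap
    w, replies, arrivals = _kernels.run_single_user_kernel(
        np.uint32(derive_seed(config.seed, 1)),
        prios,
        float(config.send_prob),
        int(cap),
        int(config.T),
    )
    return SingleUserResult(
        config=config,
        omega_T=float(replies / config.n_partners),
        mean_inflow=float(arrivals / config.T),
        replies_total=int(replies),
        partner_weights=w,
        capacity_used=cap,
    )


def sweep_single_user(
    k_grid: Sequence[int],
    replicas: int = 100,
    q_cap: int = 50,
    gamma_prio: float = -2.1,
    T: int = 500,
    beta: float = 5e-4,
    sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Median omega and mean inflow over replicas, per grid degree.

    Returns a frame with columns ``k, omega_median, omega_q25, omega_q75,
    inflow_mean, replies_median``.
    """
    rows = []
    for gi, k in enumerate(k_grid):
        omegas = np.empty(replicas)
        inflows = np.empty(replicas)
        repl = np.empty(replicas)
        for r in range(replicas):
            cfg = SingleUserConfig(
                k_i=int(k), q_cap=q_cap, gamma_prio=gamma_prio, T=T,
                beta=beta, sigma=sigma,
                seed=derive_seed(seed, gi * 100_003 + r),
            )
            res = run_single_user(cfg)
            omegas[r] = res.omega_T
            inflows[r] = res.mean_inflow
            repl[r] = res.replies_total
        rows.append(
            dict(
                k=int(k),
                omega_median=float(np.median(omegas)),
                omega_q25=float(np.percentile(omegas, 25)),
                omega_q75=float(np.percentile(omegas, 75)),
                inflow_mean=float(np.mean(inflows)),
                replies_median=float(np.median(repl)),
            )
        )
    return pd.DataFrame(rows)


def loglog_slope(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Least-squares slope (and stderr) of log y against log x."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    mask = (x > 0) & (y > 0)
    if mask.sum() < 2:
        raise ValueError("need at least two positive points")
    fit = stats.linregress(np.log(x[mask]), np.log(y[mask]))
    return float(fit.slope), float(fit.stderr)


def fit_regime_exponents(
    sweep: pd.DataFrame, min_points_per_side: int = 4
) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    """Scaling exponents on the two sides of the omega peak.

    Returns ``((alpha_low, se), (alpha_high, se))``: ``alpha_low`` is the
    log-log slope of mean inflow against k below the peak (expected ~2),
    ``alpha_high`` the slope of median omega against k above it
    (expected ~-1).
    """
    k = sweep["k"].to_numpy()
    peak_k = k[int(np.argmax(sweep["omega_median"].to_numpy()))]
    low = sweep[sweep["k"] < peak_k]
    high = sweep[sweep["k"] > peak_k]
    if len(low) < min_points_per_side or len(high) < min_points_per_side:
        raise ValueError(
            f"need >= {min_points_per_side} grid points on each side of the "
            f"peak at k={peak_k}"
        )
    alpha_low = loglog_slope(low["k"], low["inflow_mean"])
    alpha_high = loglog_slope(high["k"], high["omega_median"])
    return alpha_low, alpha_high


def sigma_robustness(
    k_grid: Sequence[int],
    sigmas: Sequence[float],
    replicas: int = 200,
    seed: int = 0,
    **kwargs,
) -> Tuple[pd.DataFrame, float]:
    """Overlay of median omega curves across capacity-noise levels.

    Returns the long-format frame (one row per sigma and k) and the maximum
    pairwise sup-distance between the median curves.
    """
    frames: List[pd.DataFrame] = []
    for si, s in enumerate(sigmas):
        df = sweep_single_user(
            k_grid, replicas=replicas, sigma=float(s),
            seed=derive_seed(seed, si), **kwargs,
        )
        df["sigma"] = float(s)
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    sup = 0.0
    for a in range(len(frames)):
        for b in range(a + 1, len(frames)):
            d = np.max(np.abs(frames[a]["omega_median"].to_numpy()
                              - frames[b]["omega_median"].to_numpy()))
            sup = max(sup, float(d))
    return long, sup
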