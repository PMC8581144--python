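"""Threshold-burden survival model.

Generative model for the observation that raising the irradiation dose above
the shoulder dose keeps lowering survival while the mutation burden of the
survivors saturates. Per-individual mutation burdens after a dose ``D`` are
drawn from a right-skewed distribution whose linear-scale mean grows linearly
with dose (``kappa * D`` mutations per genome) at a constant coefficient of
variation; an individual survives iff its burden falls below a fixed
threshold ``T``. Consequences:

* survival probability = CDF of the dose-``D`` burden distribution at ``T``,
  strictly decreasing in dose;
* the mean burden among survivors is the lower-truncated mean E[X | X < T],
  which is always below ``T`` and approaches it as dose grows.

The default family is lognormal (closed-form truncated mean); a gamma family
with the same (mean, cv) parameterisation is available behind
``family="gamma"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammainc, ndtri

from . import dose_response

__all__ = [
    "ThresholdModelConfig",
    "survival_probability",
    "survivor_mean_burden",
    "simulate_cohort",
    "dose_efficiency_curve",
    "calibrate",
    "calibrate_from_dq_ld50",
]


@dataclass(frozen=True)
class ThresholdModelConfig:
    """Parameters of the threshold-burden model.

    threshold
        Maximum mutation burden (mutations/genome) compatible with survival.
    kappa
        Mean burden per Gy; the linear-scale mean at dose D is ``kappa * D``.
    cv
        Coefficient of variation of the burden distribution, constant in dose.
    family
        "lognormal" (default) or "gamma".
    """

    threshold: float
    kappa: float
    cv: float = 0.5
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")
        if not self.cv > 0:
            raise ValueError("cv must be positive")
        if self.family not in ("lognormal", "gamma"):
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def sigma(self) -> float:
        """Lognormal shape: sigma^2 = ln(1 + cv^2)."""
        return float(np.sqrt(np.log1p(self.cv**2)))

    def mu(self, dose: float) -> float:
        """Lognormal location at dose D so the linear mean is exactly kappa*D."""
        return float(np.log(self.kappa * dose) - self.sigma**2 / 2)

    def _dist(self, dose: float):
        mean = self.kappa * dose
        if self.family == "lognormal":
            return stats.lognorm(s=self.sigma, scale=np.exp(self.mu(dose)))
        shape = 1.0 / self.cv**2
        return stats.gamma(a=shape, scale=mean / shape)


def survival_probability(config: ThresholdModelConfig, dose: float) -> float:
    """P(burden < threshold) at the given dose; 1.0 at dose 0 by convention."""
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if dose == 0:
        return 1.0
    return float(config._dist(dose).cdf(config.threshold))


def survivor_mean_burden(config: ThresholdModelConfig, dose: float) -> float:
    """Truncated mean E[X | X < T] of the dose-D burden distribution.

    Lognormal closed form: ``E[X] * Phi((lnT - mu - sigma^2)/sigma) /
    Phi((lnT - mu)/sigma)``; gamma uses the regularized incomplete-gamma
    ratio. Always strictly below the threshold.
    """
    p = survival_probability(config, dose)
    if p <= 0 or not np.isfinite(p):
        raise ValueError("no survivors at this dose (survival probability is 0)")
    mean = config.kappa * dose
    t = config.threshold
    if config.family == "lognormal":
        sigma = config.sigma
        mu = config.mu(dose)
        z = (np.log(t) - mu) / sigma
        return float(mean * stats.norm.cdf(z - sigma) / stats.norm.cdf(z))
    shape = 1.0 / config.cv**2
    scale = mean / shape
    return float(mean * gammainc(shape + 1, t / scale) / gammainc(shape, t / scale))


def simulate_cohort(
    config: ThresholdModelConfig, dose: float, n: int, seed: int
) -> pd.DataFrame:
    """Draw n individual burdens at the given dose; survived iff burden < T.

    Returns a DataFrame with columns ``burden`` and ``survived``;
    reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if dose == 0:
        burdens = np.zeros(n)
    else:
        burdens = config._dist(dose).rvs(size=n, random_state=rng)
    return pd.DataFrame({"burden": burdens, "survived": burdens < config.threshold})


def dose_efficiency_curve(
    config: ThresholdModelConfig, doses: list[float] | np.ndarray
) -> pd.DataFrame:
    """Tabulate the survival / survivor-burden trade-off over a dose ladder.

    For consecutive doses the incremental gain ratio
    ``(burden_{i+1} - burden_i) / (survival_i - survival_{i+1})`` measures
    mutations gained per unit of survival lost; it shrinks once the survivor
    mean approaches the threshold. A zero survival drop leaves the ratio NaN
    (flagged undefined).
    """
    doses = np.asarray(doses, dtype=float)
    if len(doses) < 3:
        raise ValueError("need at least 3 doses")
    if np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be strictly increasing")
    surv = np.array([survival_probability(config, d) for d in doses])
    burden = np.array([survivor_mean_burden(config, d) for d in doses])
    gain = np.full(len(doses), np.nan)
    for i in range(1, len(doses)):
        drop = surv[i - 1] - surv[i]
        if drop > 0:
            gain[i] = (burden[i] - burden[i - 1]) / drop
    return pd.DataFrame(
        {
            "dose_gy": doses,
            "survival": surv,
            "mean_burden_survivors": burden,
            "gain_ratio": gain,
        }
    )


def calibrate(
    dose_a: float,
    survival_a: float,
    dose_b: float,
    survival_b: float,
    kappa: float = 0.08,
) -> ThresholdModelConfig:
    """Solve (cv, T) of a lognormal config from two (dose, survival) anchors.

    Survival under the lognormal family depends only on the shape sigma and
    the ratio T/kappa, so two anchors determine both; kappa (the burden
    scale, mutations per genome per Gy) remains the free degree of freedom
    and defaults to 0.08, giving burdens of tens of mutations per genome in
    the 500-1000 Gy range.
    """
    if not (0 < survival_b < survival_a < 1):
        raise ValueError("require 0 < survival_b < survival_a < 1")
    if not (0 < dose_a < dose_b):
        raise ValueError("require 0 < dose_a < dose_b")
    za, zb = ndtri(survival_a), ndtri(survival_b)
    sigma = np.log(dose_b / dose_a) / (za - zb)
    # zb = (ln T - mu(dose_b)) / sigma with mu = ln(kappa D) - sigma^2/2
    ln_t = zb * sigma + np.log(kappa * dose_b) - sigma**2 / 2
    cv = float(np.sqrt(np.expm1(sigma**2)))
    return ThresholdModelConfig(threshold=float(np.exp(ln_t)), kappa=kappa, cv=cv)


def calibrate_from_dq_ld50(
    dq: float, ld50_gy: float, kappa: float = 0.08
) -> ThresholdModelConfig:
    """Calibrate against a fitted multitarget curve: anchor at the shoulder
    dose (multitarget survival there) and at LD50 (survival 0.5)."""
    d0, m = dose_response.solve_from_dq_ld50(dq, ld50_gy)
    s_dq = dose_response.survival_fraction(dq, d0, m)
    return calibrate(dq, s_dq, ld50_gy, 0.5, kappa=kappa)
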