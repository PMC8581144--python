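"""Single-hit multitarget dose-survival modelling.

The multitarget model describes seed/cell survival after acute irradiation as

    S(D) = 1 - (1 - exp(-D / D0))**m

where ``D`` is the absorbed dose (Gy), ``D0`` is the dose reducing survival to
1/e on the exponential limb, and ``m`` is the dimensionless extrapolation
number (the zero-dose intercept of the back-extrapolated exponential limb).
Two summary statistics are derived from a fit:

* the shoulder dose ``Dq = D0 * ln(m)``, where the survival curve turns from
  its flat shoulder into rapid decline, and
* ``LD50``, the dose at which half the individuals die, with the closed form
  ``LD50 = -D0 * ln(1 - 0.5**(1/m))``.

`solve_from_dq_ld50` inverts a printed (Dq, LD50) pair back to (D0, m), which
is useful when a study reports only the two summary doses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

__all__ = [
    "SurvivalDataset",
    "MultitargetFit",
    "survival_fraction",
    "shoulder_dose",
    "ld50",
    "solve_from_dq_ld50",
    "fit_multitarget",
    "read_survival_tsv",
]

M_MIN = 1.0
M_MAX = 1000.0


class FitError(RuntimeError):
    """Raised when a survival dataset does not support a well-posed fit."""


def _check_params(d0: float, m: float) -> None:
    if not d0 > 0:
        raise ValueError(f"D0 must be positive, got {d0}")
    if not m >= M_MIN:
        raise ValueError(f"extrapolation number m must be >= 1, got {m}")


def survival_fraction(dose, d0: float, m: float):
    """Multitarget survival fraction ``1 - (1 - exp(-D/D0))**m``.

    Accepts scalar or array dose; strictly decreasing in dose, equal to 1 at
    ``D = 0`` and tending to 0 as ``D -> inf``.
    """
    _check_params(d0, m)
    dose_arr = np.asarray(dose, dtype=float)
    if np.any(dose_arr < 0):
        raise ValueError("dose must be non-negative")
    out = 1.0 - np.power(-np.expm1(-dose_arr / d0), m)
    if np.isscalar(dose) or dose_arr.ndim == 0:
        return float(out)
    return out


def shoulder_dose(d0: float, m: float) -> float:
    """Shoulder dose ``Dq = D0 * ln(m)`` (Gy)."""
    _check_params(d0, m)
    return float(d0 * np.log(m))


def ld50(d0: float, m: float) -> float:
    """Dose giving 50% survival: ``-D0 * ln(1 - 0.5**(1/m))`` (Gy)."""
    _check_params(d0, m)
    return float(-d0 * np.log(-np.expm1(np.log(0.5) / m)))


def _dq_ld50_ratio(m: float) -> float:
    # LD50/Dq depends on m alone; decreasing from +inf (m -> 1) toward 1.
    return -np.log(-np.expm1(np.log(0.5) / m)) / np.log(m)


def solve_from_dq_ld50(dq: float, ld50_gy: float) -> tuple[float, float]:
    """Invert printed summary doses (Dq, LD50) to model parameters (D0, m).

    Solves ``LD50/Dq = -ln(1 - 0.5**(1/m)) / ln(m)`` for m by bracketed root
    finding on m in [1.0001, 1000], then ``D0 = Dq / ln(m)``.
    """
    if not (ld50_gy > dq > 0):
        raise ValueError("require LD50 > Dq > 0")
    target = ld50_gy / dq
    lo, hi = 1.0001, M_MAX
    f = lambda m: _dq_ld50_ratio(m) - target
    if f(lo) < 0 or f(hi) > 0:
        raise ValueError("inconsistent Dq/LD50 pair: no m in [1.0001, 1000]")
    m = brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    d0 = dq / np.log(m)
    return float(d0), float(m)


@dataclass(frozen=True)
class SurvivalDataset:
    """Dose-survival counts, one entry per dose x replicate.

    The reference assay scores survival 4 weeks after sowing, four replicates
    of 50 seeds per dose.
    """

    doses: tuple[float, ...]
    survived: tuple[int, ...]
    total: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.doses) == len(self.survived) == len(self.total)):
            raise ValueError("doses, survived and total must be parallel")
        for d, s, t in zip(self.doses, self.survived, self.total):
            if d < 0:
                raise ValueError("doses must be non-negative")
            if t <= 0:
                raise ValueError("total seeds per replicate must be positive")
            if not 0 <= s <= t:
                raise ValueError("require 0 <= survived <= total")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_gy": self.doses, "survived": self.survived, "total": self.total}
        )

    def pooled_fractions(self, weight_by_total: bool = False):
        """Collapse replicates to one survival fraction per distinct dose."""
        df = self.to_frame()
        if weight_by_total:
            g = df.groupby("dose_gy").sum()
            frac = g["survived"] / g["total"]
        else:
            df["frac"] = df["survived"] / df["total"]
            frac = df.groupby("dose_gy")["frac"].mean()
        doses = frac.index.to_numpy(dtype=float)
        order = np.argsort(doses)
        return doses[order], frac.to_numpy(dtype=float)[order]


@dataclass(frozen=True)
class MultitargetFit:
    """Fitted multitarget parameters and derived summary doses."""

    d0: float
    m: float
    dq: float
    ld50: float
    rss: float

    def predict(self, dose):
        return survival_fraction(dose, self.d0, self.m)

    def to_dict(self) -> dict:
        return {"d0": self.d0, "m": self.m, "dq": self.dq, "ld50": self.ld50, "rss": self.rss}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _make_fit(d0: float, m: float, rss: float) -> MultitargetFit:
    return MultitargetFit(
        d0=float(d0), m=float(m), dq=shoulder_dose(d0, m), ld50=ld50(d0, m), rss=float(rss)
    )


def _check_well_posed(doses: np.ndarray, fracs: np.ndarray) -> None:
    if len(doses) < 3:
        raise FitError("need at least 3 distinct doses")
    if np.all(fracs > 0.95) or np.all(fracs < 0.05):
        raise FitError(
            "degenerate survival data: all fractions near 1 or near 0 "
            f"(range {fracs.min():.3f}-{fracs.max():.3f})"
        )
    if fracs.max() <= 0.8:
        raise FitError("no dose with survival fraction > 0.8 (shoulder not sampled)")
    if fracs.min() >= 0.5:
        raise FitError("no dose with survival fraction < 0.5 (decline not sampled)")


def fit_multitarget(
    data: SurvivalDataset,
    method: str = "nls",
    weight_by_total: bool = False,
) -> MultitargetFit:
    """Least-squares fit of (D0, m) to survival fractions.

    ``method='nls'`` (default) minimises the residual sum of squares on the
    linear survival-fraction scale: a coarse grid over (D0, m) seeds a bounded
    Levenberg-Marquardt-style refinement, so the optimum is well-defined for
    any dose grid. ``method='semilog'`` is the classical radiobiology
    alternative: a straight-line fit of log-survival on the terminal limb
    (fractions < 0.5) whose slope gives D0 and back-extrapolated intercept
    gives m.
    """
    doses, fracs = data.pooled_fractions(weight_by_total=weight_by_total)
    _check_well_posed(doses, fracs)

    if method == "semilog":
        limb = fracs < 0.5
        if limb.sum() < 2:
            raise FitError("semilog method needs >= 2 doses on the terminal limb")
        y = np.log(np.clip(fracs[limb], 1e-12, None))
        slope, intercept = np.polyfit(doses[limb], y, 1)
        if slope >= 0:
            raise FitError("terminal limb slope is non-negative")
        d0 = -1.0 / slope
        m = max(M_MIN, min(M_MAX, float(np.exp(intercept))))
        rss = float(np.sum((fracs - survival_fraction(doses, d0, m)) ** 2))
        return _make_fit(d0, m, rss)
    if method != "nls":
        raise ValueError(f"unknown fitting method {method!r}")

    dmax = doses.max()
    d0_grid = np.linspace(dmax / 20, dmax, 50)
    m_grid = np.logspace(0, np.log10(M_MAX), 20)

    def rss_of(d0: float, m: float) -> float:
        return float(np.sum((fracs - survival_fraction(doses, d0, m)) ** 2))

    best = min(
        ((rss_of(d0, m), d0, m) for d0 in d0_grid for m in m_grid), key=lambda t: t[0]
    )
    _, d0_init, m_init = best

    def residuals(theta):
        return fracs - survival_fraction(doses, theta[0], theta[1])

    sol = least_squares(
        residuals,
        x0=[d0_init, max(m_init, M_MIN + 1e-9)],
        bounds=([1e-6, M_MIN], [20 * dmax, M_MAX]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    d0, m = sol.x
    return _make_fit(d0, m, rss_of(d0, m))


def read_survival_tsv(path: str | Path) -> SurvivalDataset:
    """Read a TSV with columns dose_gy, survived, total (one row per dose x replicate)."""
    df = pd.read_csv(path, sep="\t")
    required = {"dose_gy", "survived", "total"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival TSV missing columns: {sorted(missing)}")
    return SurvivalDataset(
        doses=tuple(float(x) for x in df["dose_gy"]),
        survived=tuple(int(x) for x in df["survived"]),
        total=tuple(int(x) for x in df["total"]),
    )
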