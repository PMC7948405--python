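"""Pre-steady-state (stopped-flow) binding analysis.

Under pseudo-first-order conditions (ligand >> sites) a one-step binding
reaction relaxes exponentially, S(t) = offset + amplitude * exp(-k_obs t),
with k_obs = k_on [L] + k_off.  Fitting exponentials at several ligand
concentrations and regressing k_obs on [L] yields k_on (slope) and k_off
(intercept); their ratio k_off/k_on is a kinetic K_d that should agree with
the equilibrium value if binding is single-step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .datasets import ProgressCurve, TransientSeries

__all__ = [
    "RateConstants",
    "ExponentialDecayFit",
    "fit_single_exponential",
    "KobsLineFit",
    "fit_kobs_line",
    "kd_from_rates",
    "fold_change_koff",
    "consistency_report",
]


@dataclass(frozen=True)
class RateConstants:
    """Association/dissociation rate constants and the kinetic K_d they imply."""

    k_on: float  # uM^-1 s^-1
    k_off: float  # s^-1
    k_on_sd: float | None = None
    k_off_sd: float | None = None
    k_d_equilibrium: float | None = None  # uM, optional comparator
    k_off_clamped: bool = False

    def __post_init__(self) -> None:
        if not self.k_on > 0:
            raise ValueError("k_on must be positive")
        if self.k_off < 0:
            raise ValueError("k_off must be nonnegative")

    @property
    def k_d_kinetic(self) -> float:
        """k_off/k_on, uM."""
        return self.k_off / self.k_on


class ExponentialDecayFit(BaseEstimator, RegressorMixin):
    """Single-exponential fit S(t) = offset + amplitude * exp(-k_obs t).

    A floating offset absorbs the arbitrary instrument baseline.  Attributes:
    ``k_obs_`` (s^-1), ``amplitude_``, ``offset_`` with ``*_sd_`` companions.
    """

    @staticmethod
    def _model(t, k_obs, amplitude, offset):
        return offset + amplitude * np.exp(-k_obs * t)

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        s = np.asarray(y, dtype=float).ravel()
        if t.size < 20:
            raise ValueError("need >= 20 points for a reliable exponential fit")
        span = s.max() - s.min()
        if span == 0 or span < 1e-12 * max(abs(s).max(), 1.0):
            raise ValueError("flat progress curve: amplitude ~ 0, k_obs undefined")
        amp0 = s[0] - s[-1]
        off0 = s[-1]
        # crude rate guess from the time to cover ~63% of the total change
        target = s[0] - 0.632 * amp0
        idx = int(np.argmin(np.abs(s - target)))
        k0 = 1.0 / max(t[idx] - t[0], (t[-1] - t[0]) / t.size)
        try:
            popt, pcov = curve_fit(
                self._model, t, s, p0=[k0, amp0, off0],
                bounds=([1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as exc:
            raise RuntimeError(f"exponential fit did not converge: {exc}") from exc
        self.k_obs_, self.amplitude_, self.offset_ = map(float, popt)
        sds = np.sqrt(np.diag(pcov))
        self.k_obs_sd_, self.amplitude_sd_, self.offset_sd_ = map(float, sds)
        if (t[-1] - t[0]) * self.k_obs_ < 1.0:
            warnings.warn(
                "time window shorter than 1/k_obs; rate poorly determined",
                stacklevel=2,
            )
        return self

    def predict(self, X):
        return self._model(np.asarray(X, dtype=float).ravel(),
                           self.k_obs_, self.amplitude_, self.offset_)


def fit_single_exponential(curve: ProgressCurve) -> tuple[float, float, float]:
    """Fit one progress curve; returns (k_obs, amplitude, offset)."""
    est = ExponentialDecayFit().fit(curve.times, curve.signals)
    return est.k_obs_, est.amplitude_, est.offset_


class KobsLineFit(BaseEstimator, RegressorMixin):
    """Line fit k_obs = k_on [L] + k_off, optionally weighted by 1/sd^2.

    Attributes: ``k_on_`` (slope, uM^-1 s^-1), ``k_off_`` (intercept, s^-1)
    with ``*_sd_`` companions.  A fitted negative intercept is reported
    clamped at zero with ``k_off_clamped_`` set, since a dissociation rate
    constant cannot be negative.
    """

    def __init__(self, weighted: bool = True):
        self.weighted = weighted

    def fit(self, X, y, sample_sd=None):
        x = np.asarray(X, dtype=float).ravel()
        k = np.asarray(y, dtype=float).ravel()
        if x.size < 2 or np.unique(x).size < 2:
            raise ValueError("need >= 2 distinct concentrations (rank-deficient design)")
        if self.weighted and sample_sd is not None:
            sd = np.asarray(sample_sd, dtype=float).ravel()
            if np.any(sd <= 0):
                raise ValueError("weights require strictly positive k_obs SDs")
            w = 1.0 / sd**2
        else:
            w = np.ones_like(x)
        # weighted normal equations with covariance from the weighted design
        sw = np.sqrt(w)
        A = np.column_stack([x * sw, sw])
        coef, *_ = np.linalg.lstsq(A, k * sw, rcond=None)
        slope, intercept = map(float, coef)
        resid = k - (slope * x + intercept)
        dof = max(x.size - 2, 1)
        if sample_sd is not None and self.weighted:
            cov = np.linalg.inv(A.T @ A)  # SDs known: no variance rescaling
        else:
            s2 = float(np.sum(w * resid**2) / dof)
            cov = s2 * np.linalg.inv(A.T @ A)
        self.k_on_ = slope
        self.k_on_sd_ = float(np.sqrt(cov[0, 0]))
        self.k_off_sd_ = float(np.sqrt(cov[1, 1]))
        self.k_off_clamped_ = intercept < 0
        if self.k_off_clamped_:
            warnings.warn(
                f"fitted intercept {intercept:.3g} s^-1 is negative; k_off reported "
                "as 0 (release too slow to resolve)", stacklevel=2,
            )
        self.k_off_ = max(intercept, 0.0)
        self.residuals_ = resid
        return self

    def predict(self, X):
        return self.k_on_ * np.asarray(X, dtype=float).ravel() + self.k_off_


def fit_kobs_line(series: TransientSeries, k_d_equilibrium: float | None = None,
                  weighted: bool = True) -> RateConstants:
    """Regress a k_obs series on ligand concentration; returns RateConstants."""
    if series.pseudo_first_order_flags is not None and not np.all(
        series.pseudo_first_order_flags
    ):
        warnings.warn(
            "some curves violate the pseudo-first-order guard (ligand < 10x sites)",
            stacklevel=2,
        )
    est = KobsLineFit(weighted=weighted).fit(
        series.ligand_concentrations, series.k_obs_values, sample_sd=series.k_obs_sds
    )
    return RateConstants(
        est.k_on_, est.k_off_, est.k_on_sd_, est.k_off_sd_,
        k_d_equilibrium=k_d_equilibrium, k_off_clamped=est.k_off_clamped_,
    )


def kd_from_rates(k_off: float, k_on: float) -> float:
    """Kinetic dissociation constant k_off/k_on (uM for uM^-1 s^-1 inputs)."""
    if not k_on > 0:
        raise ValueError("k_on must be positive")
    if k_off < 0:
        raise ValueError("k_off must be nonnegative")
    return k_off / k_on


def fold_change_koff(k_off_ref: float, k_off_test: float) -> float:
    """Fold slowdown of ligand release, reference over test."""
    if not (k_off_ref > 0 and k_off_test > 0):
        raise ValueError("rate constants must be positive")
    return k_off_ref / k_off_test


def consistency_report(rc: RateConstants, factor: float = 1.5) -> tuple[float, bool]:
    """Kinetic/equilibrium K_d ratio and pass flag (within ``factor`` either way)."""
    if rc.k_d_equilibrium is None or not rc.k_d_equilibrium > 0:
        raise ValueError("equilibrium K_d required for the consistency check")
    ratio = rc.k_d_kinetic / rc.k_d_equilibrium
    ok = (1.0 / factor) <= ratio <= factor
    return ratio, ok
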