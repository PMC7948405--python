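"""Cap-isomerization thermodynamics.

Cytosolic sulfotransferases carry a ~30-residue active-site cap that must
open for nucleotide (PAP) exchange.  With PAP release rate-limiting, turnover
is proportional to the fraction of enzyme with the cap open:

    k_cat = F_open * k_rel = k_rel / (1 + K_iso),    K_iso = [closed]/[open]

A ligand that stabilizes the closed cap by a free energy ``ddg`` (negative =
stabilizing) multiplies K_iso by ``K = exp(-ddg / (R T))`` and therefore
suppresses k_cat by nearly the same factor when K_iso >> 1.  This module
converts among K_iso, F_open, k_cat, free-energy differences and predicted
percent inhibition, and provides the calculated-vs-experimental free-energy
regression used to validate such predictions across a compound series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ThermoContext",
    "CapStabilization",
    "CorrelationPoint",
    "fraction_open",
    "fraction_closed",
    "kcat_from_iso",
    "ddg_from_kcat_ratio",
    "kfold_from_ddg",
    "percent_inhibition_paper_convention",
    "percent_inhibition_ratio_convention",
    "cap_stabilization_from_ddg",
    "FreeEnergyCorrelation",
    "free_energy_correlation",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.987e-3


@dataclass(frozen=True)
class ThermoContext:
    """Thermodynamic and kinetic constants of the cap open/closed equilibrium.

    Parameters
    ----------
    gas_constant : float
        Gas constant, kcal mol^-1 K^-1.
    temperature : float
        Absolute temperature, K.  Assays are run at 25 (+/- 2) C, so the
        default is 298.15 K.
    k_iso_baseline : float
        Cap-isomerization equilibrium constant [closed]/[open] of the
        uninhibited, nucleotide-bound enzyme (13 for SULT1A3).
    k_rel : float
        Rate constant for nucleotide release from the cap-open enzyme, s^-1.
    """

    gas_constant: float = GAS_CONSTANT_KCAL
    temperature: float = 298.15
    k_iso_baseline: float = 13.0
    k_rel: float = 2.5

    def __post_init__(self) -> None:
        for name in ("gas_constant", "temperature", "k_iso_baseline", "k_rel"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")

    @property
    def rt(self) -> float:
        """R*T in kcal mol^-1."""
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class CorrelationPoint:
    """One compound's calculated vs experimental cap-stabilization energy (kcal/mol)."""

    compound_id: str
    ddg_calc: float
    ddg_exp: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ddg_calc) and math.isfinite(self.ddg_exp)):
            raise ValueError(f"non-finite free energy for {self.compound_id}")


def fraction_open(k_iso: float) -> float:
    """Fraction of nucleotide-bound enzyme with the cap open, 1/(1 + K_iso)."""
    k_iso = np.asarray(k_iso, dtype=float)
    if np.any(k_iso < 0):
        raise ValueError("k_iso must be nonnegative")
    out = 1.0 / (1.0 + k_iso)
    return float(out) if out.ndim == 0 else out


def fraction_closed(k_iso: float) -> float:
    """Fraction of nucleotide-bound enzyme with the cap closed, K_iso/(1 + K_iso)."""
    k_iso = np.asarray(k_iso, dtype=float)
    if np.any(k_iso < 0):
        raise ValueError("k_iso must be nonnegative")
    out = k_iso / (1.0 + k_iso)
    return float(out) if out.ndim == 0 else out


def kcat_from_iso(ctx: ThermoContext, k_iso: float | None = None) -> float:
    """Turnover number k_cat = k_rel / (1 + K_iso), s^-1.

    Release from the cap-open conformation is rate-limiting, so k_cat is the
    release rate constant scaled by the open fraction.  For K_iso >> 1 this
    approaches k_rel / K_iso.
    """
    if k_iso is None:
        k_iso = ctx.k_iso_baseline
    return ctx.k_rel * fraction_open(k_iso)


def ddg_from_kcat_ratio(kcat_1: float, kcat_2: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Cap-stabilization free-energy difference from a turnover ratio.

    Returns -R*T*ln(kcat_1/kcat_2) in kcal mol^-1; antisymmetric under
    argument swap.  Valid in the K_iso >> 1 regime where the k_cat ratio
    equals the inverse K_iso ratio.
    """
    if not (kcat_1 > 0 and kcat_2 > 0):
        raise ValueError("turnover numbers must be positive")
    return -ctx.rt * math.log(kcat_1 / kcat_2)


def kfold_from_ddg(ddg: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Fold change in K_iso implied by a stabilization energy: exp(-ddg/(R T))."""
    if not math.isfinite(ddg):
        raise ValueError("ddg must be finite")
    return math.exp(-ddg / ctx.rt)


def percent_inhibition_paper_convention(
    ddg: float, ctx: ThermoContext = ThermoContext()
) -> float:
    """Predicted percent inhibition at saturating inhibitor, 100*K/(1+K).

    ``K = exp(-ddg/(R T))`` is the fold stabilization of the closed cap.
    This arithmetic treats K as if it were the inhibited enzyme's entire
    K_iso, i.e. the closed fraction of a two-state system whose equilibrium
    constant is K.  ddg = -1.17 and -1.41 kcal/mol give 88% and 92%.
    """
    if ddg > 0:
        warnings.warn(
            "positive ddg destabilizes the closed cap; predicted inhibition is "
            "below 50% and the model's premise (stabilization) does not hold",
            stacklevel=2,
        )
    k = kfold_from_ddg(ddg, ctx)
    return 100.0 * k / (1.0 + k)


def percent_inhibition_ratio_convention(
    ddg: float, ctx: ThermoContext = ThermoContext()
) -> float:
    """Predicted percent inhibition at saturation as 100*(1 - 1/K).

    Under the K_iso >> 1 approximation the k_cat ratio of inhibited to
    uninhibited enzyme is 1/K, so inhibition is 1 - 1/K.  This is the
    convention strictly implied by the turnover-ratio relation; it converges
    with the 100*K/(1+K) convention as ddg -> -inf.
    """
    if ddg > 0:
        warnings.warn(
            "positive ddg destabilizes the closed cap; formula yields negative inhibition",
            stacklevel=2,
        )
    k = kfold_from_ddg(ddg, ctx)
    return 100.0 * (1.0 - 1.0 / k)


@dataclass(frozen=True)
class CapStabilization:
    """Derived quantities for one compound's calculated cap stabilization."""

    compound_id: str
    delta_g_calc: float
    k_fold: float
    percent_inhibition_predicted: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_inhibition_predicted <= 100.0:
            raise ValueError("predicted percent inhibition must lie in [0, 100]")


def cap_stabilization_from_ddg(
    compound_id: str, delta_g_calc: float, ctx: ThermoContext = ThermoContext()
) -> CapStabilization:
    """Bundle K-fold and predicted saturation inhibition for a calculated ddg."""
    k = kfold_from_ddg(delta_g_calc, ctx)
    pct = percent_inhibition_paper_convention(delta_g_calc, ctx)
    return CapStabilization(compound_id, delta_g_calc, k, pct)


class FreeEnergyCorrelation(BaseEstimator, RegressorMixin):
    """Ordinary least-squares line of calculated on experimental ddG.

    A slope of 1 across a compound series means the full calculated
    cap-stabilizing potential is expressed as inhibition.  Unweighted OLS is
    used: uncertainty in the calculated (y) dimension is negligible compared
    with the spread of the experimental values.

    Attributes
    ----------
    slope_, intercept_ : float
        Fitted line ``ddg_calc = slope_ * ddg_exp + intercept_``.
    r_ : float
        Pearson correlation coefficient.
    slope_se_, intercept_se_ : float
        Standard errors of slope and intercept.
    """

    def fit(self, X, y=None):
        if y is None:  # allow a list of CorrelationPoint
            pts = list(X)
            x = np.array([p.ddg_exp for p in pts], dtype=float)
            y_ = np.array([p.ddg_calc for p in pts], dtype=float)
        else:
            x = np.asarray(X, dtype=float).ravel()
            y_ = np.asarray(y, dtype=float).ravel()
        if x.size < 3:
            raise ValueError("need at least 3 points for the free-energy correlation")
        if x.size != y_.size:
            raise ValueError("x and y lengths differ")
        if np.ptp(x) == 0:
            raise ValueError("zero variance in experimental ddG; line undefined")
        res = stats.linregress(x, y_)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_ = float(res.rvalue)
        self.slope_se_ = float(res.stderr)
        self.intercept_se_ = float(res.intercept_stderr)
        self.n_points_ = int(x.size)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).ravel()
        return self.slope_ * x + self.intercept_


def free_energy_correlation(points) -> tuple[float, float, float]:
    """Fit the ddG_calc-vs-ddG_exp line; returns (slope, intercept, Pearson R)."""
    fitted = FreeEnergyCorrelation().fit(points)
    return fitted.slope_, fitted.intercept_, fitted.r_
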