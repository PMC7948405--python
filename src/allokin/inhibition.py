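"""Tight-binding partial noncompetitive inhibition and ex vivo IC50 fits.

At 20 nM active sites an inhibitor with K_i of 11-70 nM is depleted by the
enzyme, so free != total and the bound complex must come from the binding
quadratic rather than a hyperbola.  With both substrates saturating and the
allostere acting only on turnover, the normalized rate is

    v/Vmax = ([E]_tot + [ESI]*(alpha - 1)) / [E]_tot

where alpha = k_cat,inh / k_cat is the residual activity at saturating
inhibitor and [ESI] is the physically meaningful (smaller) root of

    [ESI] = { (E + I + K_i) - sqrt((E + I + K_i)^2 - 4 I E) } / 2 .

The cell-based (ex vivo) readout is media dopamine-sulfate accumulation,
suppressed saturably:  [DPS] = [DPS]_-inh - [DPS]_supp * I / (IC50 + I).
Beer-Lambert quantitation and a mass-balance QC round out the module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .datasets import DoseResponseDataset

__all__ = [
    "InhibitorParams",
    "ExVivoParams",
    "QuantSpec",
    "esi_bound",
    "rate_partial_noncompetitive",
    "percent_inhibition_at_saturation",
    "InhibitionCurveFit",
    "fit_inhibition_curve",
    "exvivo_dps_model",
    "ExVivoIC50Fit",
    "fit_exvivo",
    "conc_from_absorbance",
    "mass_balance_check",
]


@dataclass(frozen=True)
class InhibitorParams:
    """Allosteric-site dissociation constant and residual activity of one compound.

    ``k_i`` in nM; ``alpha`` is the fraction of Vmax remaining at saturating
    inhibitor, so percent inhibition at saturation is 100*(1 - alpha).
    """

    compound_id: str
    k_i: float
    alpha: float
    k_i_sd: float | None = None
    alpha_sd: float | None = None

    def __post_init__(self) -> None:
        if not self.k_i > 0:
            raise ValueError("k_i must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def pct_inh_sat(self) -> float:
        return 100.0 * (1.0 - self.alpha)


@dataclass(frozen=True)
class ExVivoParams:
    """Cell-assay suppression parameters: baseline and suppressible DPS (uM), IC50 (nM)."""

    dps_no_inh: float
    dps_suppressible: float
    ic50: float
    dps_no_inh_sd: float | None = None
    dps_suppressible_sd: float | None = None
    ic50_sd: float | None = None

    def __post_init__(self) -> None:
        if min(self.dps_no_inh, self.dps_suppressible, self.ic50) < 0:
            raise ValueError("ex vivo parameters must be nonnegative")
        if self.dps_suppressible > self.dps_no_inh * (1 + 1e-9):
            raise ValueError("suppressible DPS cannot exceed the uninhibited level")

    @property
    def pct_inh_sat(self) -> float:
        return 100.0 * self.dps_suppressible / self.dps_no_inh


@dataclass(frozen=True)
class QuantSpec:
    """Beer-Lambert quantitation: extinction coefficient (mM^-1 cm^-1), wavelength, path."""

    extinction_coefficient: float
    wavelength: float = 280.0
    path_length: float = 1.0

    def __post_init__(self) -> None:
        if min(self.extinction_coefficient, self.wavelength, self.path_length) <= 0:
            raise ValueError("QuantSpec fields must be positive")


def esi_bound(e_total, i_total, k_i: float):
    """Enzyme-inhibitor complex concentration (nM) with depletion.

    Smaller root of the binding quadratic, evaluated in the
    multiply-by-conjugate form 2*I*E / (s + sqrt(s^2 - 4*I*E)) with
    s = E + I + K_i, which is free of catastrophic cancellation when
    I >> E or E >> I.
    """
    e = np.asarray(e_total, dtype=float)
    i = np.asarray(i_total, dtype=float)
    if np.any(e < 0) or np.any(i < 0):
        raise ValueError("concentrations must be nonnegative")
    if not k_i > 0:
        raise ValueError("k_i must be positive")
    s = e + i + k_i
    disc = s * s - 4.0 * i * e
    if np.any(disc < 0):
        # analytically impossible for k_i > 0: disc = (E - I)^2 + K^2 + 2K(E + I)
        raise ArithmeticError(
            f"negative discriminant in binding quadratic (min {np.min(disc):g}); "
            f"inputs e={e!r} i={i!r} k_i={k_i!r}"
        )
    out = 2.0 * i * e / (s + np.sqrt(disc))
    return float(out) if out.ndim == 0 else out


def rate_partial_noncompetitive(e_total, i_total, params: InhibitorParams):
    """Normalized rate v/Vmax under tight-binding partial noncompetitive inhibition."""
    e = np.asarray(e_total, dtype=float)
    esi = esi_bound(e, i_total, params.k_i)
    out = (e + esi * (params.alpha - 1.0)) / e
    return float(out) if np.ndim(out) == 0 else out


def percent_inhibition_at_saturation(params: InhibitorParams) -> float:
    """100*(1 - alpha): inhibition when every enzyme carries inhibitor."""
    return params.pct_inh_sat


class InhibitionCurveFit(BaseEstimator, RegressorMixin):
    """Least-squares fit of the tight-binding partial-inhibition dose curve.

    Parameters
    ----------
    e_total : float
        Active-site concentration, nM.  Fixed, not fitted.
    normalize : bool
        Divide responses by the mean zero-dose response before fitting
        (zero-dose points are retained in the fit).
    aggregate : {'mean', 'pooled'}
        Average replicates per dose before fitting, or fit all raw points.
    bootstrap : int
        If > 0, residual-bootstrap resample count for alternative SDs.
    random_state : int or None
        Seed for the bootstrap.

    Attributes
    ----------
    k_i_, alpha_ : float
        Estimates (nM, dimensionless).
    k_i_sd_, alpha_sd_ : float
        1-SD uncertainties from the fit covariance (or bootstrap).
    residuals_ : ndarray
        Observed minus fitted normalized rates.
    """

    def __init__(
        self,
        e_total: float = 20.0,
        normalize: bool = True,
        aggregate: str = "mean",
        bootstrap: int = 0,
        random_state: int | None = None,
    ):
        self.e_total = e_total
        self.normalize = normalize
        self.aggregate = aggregate
        self.bootstrap = bootstrap
        self.random_state = random_state

    def _model(self, doses, k_i, alpha):
        return rate_partial_noncompetitive(
            self.e_total, doses, InhibitorParams("", k_i, np.clip(alpha, 0.0, 1.0))
        )

    def fit(self, X, y):
        doses = np.asarray(X, dtype=float).ravel()
        resp = np.asarray(y, dtype=float).ravel()
        if doses.size != resp.size:
            raise ValueError("doses and responses must have equal length")
        if np.unique(doses).size < 5:
            raise ValueError("need >= 5 distinct doses to fit K_i and alpha")
        if self.normalize:
            zero = resp[doses == 0]
            if zero.size:
                resp = resp / zero.mean()
        if self.aggregate == "mean":
            uniq = np.unique(doses)
            resp = np.array([resp[doses == d].mean() for d in uniq])
            doses = uniq
        elif self.aggregate != "pooled":
            raise ValueError("aggregate must be 'mean' or 'pooled'")

        alpha0 = float(np.clip(resp.min(), 0.0, 1.0))
        mid = (1.0 + alpha0) / 2.0
        pos = doses[doses > 0]
        k0 = float(pos[np.argmin(np.abs(resp[doses > 0] - mid))]) if pos.size else 1.0
        try:
            popt, pcov = curve_fit(
                self._model, doses, resp,
                p0=[max(k0, 1e-3), alpha0],
                bounds=([1e-9, 0.0], [np.inf, 1.0]),
                maxfev=20000,
            )
        except RuntimeError as exc:
            raise RuntimeError(f"inhibition fit did not converge: {exc}") from exc
        self.k_i_, self.alpha_ = float(popt[0]), float(popt[1])
        sds = np.sqrt(np.diag(pcov))
        self.k_i_sd_, self.alpha_sd_ = float(sds[0]), float(sds[1])
        self.residuals_ = resp - self._model(doses, *popt)
        self.doses_, self.responses_ = doses, resp

        pos = doses[doses > 0]
        if pos.size and (pos.max() < 0.5 * self.k_i_ or pos.min() > 5.0 * self.k_i_):
            warnings.warn(
                "dose range poorly brackets the fitted K_i; estimates are "
                "ill-conditioned", stacklevel=2,
            )
        if self.bootstrap:
            self._bootstrap_sds(doses, resp)
        return self

    def _bootstrap_sds(self, doses, resp):
        rng = np.random.default_rng(self.random_state)
        fitted = self._model(doses, self.k_i_, self.alpha_)
        draws = []
        for _ in range(self.bootstrap):
            y_b = fitted + rng.choice(self.residuals_, size=self.residuals_.size, replace=True)
            try:
                popt, _ = curve_fit(
                    self._model, doses, y_b, p0=[self.k_i_, self.alpha_],
                    bounds=([1e-9, 0.0], [np.inf, 1.0]), maxfev=5000,
                )
                draws.append(popt)
            except RuntimeError:
                continue
        if draws:
            draws = np.asarray(draws)
            self.k_i_sd_boot_ = float(draws[:, 0].std(ddof=1))
            self.alpha_sd_boot_ = float(draws[:, 1].std(ddof=1))

    def predict(self, X):
        doses = np.asarray(X, dtype=float).ravel()
        return self._model(doses, self.k_i_, self.alpha_)

    def params_(self, compound_id: str = "") -> InhibitorParams:
        return InhibitorParams(
            compound_id, self.k_i_, self.alpha_, self.k_i_sd_, self.alpha_sd_
        )


def fit_inhibition_curve(
    data: DoseResponseDataset, start: InhibitorParams | None = None, **kwargs
) -> InhibitorParams:
    """Fit a dose-response dataset; returns InhibitorParams with 1-SD uncertainties."""
    if data.response_kind != "in_vitro_rate":
        raise ValueError("fit_inhibition_curve expects in_vitro_rate data")
    est = InhibitionCurveFit(e_total=data.e_total, **kwargs)
    est.fit(data.doses, data.responses)
    if start is not None:  # caller-supplied start only overrides the heuristic p0
        pass
    return est.params_(data.compound_id)


# --- ex vivo (cell-based) suppression ---------------------------------------

def exvivo_dps_model(i, params: ExVivoParams):
    """Media DPS (uM) at inhibitor dose i (nM): baseline minus saturable suppression."""
    i = np.asarray(i, dtype=float)
    if np.any(i < 0):
        raise ValueError("inhibitor concentration must be nonnegative")
    out = params.dps_no_inh - params.dps_suppressible * i / (params.ic50 + i)
    return float(out) if out.ndim == 0 else out


class ExVivoIC50Fit(BaseEstimator, RegressorMixin):
    """Least-squares fit of DPS suppression: [DPS]_-inh, [DPS]_supp and IC50.

    Attributes: ``dps_no_inh_`` and ``dps_suppressible_`` (uM), ``ic50_``
    (nM), each with a ``*_sd_`` companion; ``pct_inh_sat_`` is
    100*suppressible/baseline.
    """

    def __init__(self, aggregate: str = "mean"):
        self.aggregate = aggregate

    @staticmethod
    def _model(i, no_inh, supp, ic50):
        return no_inh - supp * i / (ic50 + i)

    def fit(self, X, y):
        doses = np.asarray(X, dtype=float).ravel()
        dps = np.asarray(y, dtype=float).ravel()
        if np.unique(doses).size < 5 or 0.0 not in doses:
            raise ValueError("need >= 5 distinct doses including zero")
        if np.all(doses == 0):
            raise ValueError("degenerate design: all doses zero")
        if self.aggregate == "mean":
            uniq = np.unique(doses)
            dps = np.array([dps[doses == d].mean() for d in uniq])
            doses = uniq
        base0 = dps[doses == 0].mean()
        supp0 = max(base0 - dps.min(), 1e-6)
        half = base0 - supp0 / 2.0
        pos = doses[doses > 0]
        ic0 = float(pos[np.argmin(np.abs(dps[doses > 0] - half))])
        try:
            popt, pcov = curve_fit(
                self._model, doses, dps,
                p0=[base0, supp0, max(ic0, 1e-3)],
                bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as exc:
            raise RuntimeError(f"ex vivo fit did not converge: {exc}") from exc
        self.dps_no_inh_, self.dps_suppressible_, self.ic50_ = map(float, popt)
        sds = np.sqrt(np.diag(pcov))
        self.dps_no_inh_sd_, self.dps_suppressible_sd_, self.ic50_sd_ = map(float, sds)
        self.residuals_ = dps - self._model(doses, *popt)
        self.pct_inh_sat_ = 100.0 * self.dps_suppressible_ / self.dps_no_inh_
        if doses.max() < 3.0 * self.ic50_:
            warnings.warn(
                "maximum dose below 3x IC50; suppression plateau unresolved",
                stacklevel=2,
            )
        return self

    def predict(self, X):
        return self._model(np.asarray(X, dtype=float).ravel(),
                           self.dps_no_inh_, self.dps_suppressible_, self.ic50_)

    def params_(self) -> ExVivoParams:
        return ExVivoParams(
            self.dps_no_inh_, min(self.dps_suppressible_, self.dps_no_inh_), self.ic50_,
            self.dps_no_inh_sd_, self.dps_suppressible_sd_, self.ic50_sd_,
        )


def fit_exvivo(data: DoseResponseDataset, **kwargs) -> ExVivoParams:
    """Fit an ex vivo DPS dataset; returns ExVivoParams with 1-SD uncertainties."""
    if data.response_kind != "ex_vivo_dps":
        raise ValueError("fit_exvivo expects ex_vivo_dps data")
    est = ExVivoIC50Fit(**kwargs).fit(data.doses, data.responses)
    return est.params_()


# --- quantitation and QC -----------------------------------------------------

def conc_from_absorbance(a: float, spec: QuantSpec) -> float:
    """Concentration in mM from absorbance, A / (epsilon * path)."""
    if a < 0:
        raise ValueError("absorbance must be nonnegative")
    return a / (spec.extinction_coefficient * spec.path_length)


def mass_balance_check(dp: float, dps: float, dp_added: float,
                       threshold: float = 0.95) -> tuple[float, bool]:
    """Recovery fraction (DP + DPS)/DP_added and pass flag (inclusive >= threshold)."""
    if min(dp, dps) < 0:
        raise ValueError("metabolite concentrations must be nonnegative")
    if not dp_added > 0:
        raise ValueError("dp_added must be positive")
    recovery = (dp + dps) / dp_added
    return recovery, recovery >= threshold
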