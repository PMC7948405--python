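"""Typed containers for the dataset shapes the fitters consume.

Concentrations are carried in nM internally except where a field name says
otherwise (stopped-flow ligand concentrations are in uM, matching how such
data are recorded).  Each container keeps a free-form ``metadata`` dict; the
synthetic generators embed their ground-truth parameters and seed there so
every fit is checkable by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "DoseResponseDataset",
    "TitrationDataset",
    "ProgressCurve",
    "TransientSeries",
]

ResponseKind = Literal["in_vitro_rate", "ex_vivo_dps"]


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class DoseResponseDataset:
    """Inhibitor dose vs normalized rate (or media metabolite concentration).

    ``doses`` are inhibitor totals in nM; ``responses`` are v/Vmax for
    ``response_kind='in_vitro_rate'`` or media DPS in uM for
    ``'ex_vivo_dps'``.  ``e_total`` is the active-site concentration in nM
    (dimer concentrations are entered x2, sites treated as independent).
    """

    doses: np.ndarray
    responses: np.ndarray
    response_kind: ResponseKind = "in_vitro_rate"
    e_total: float | None = None
    replicate_ids: np.ndarray | None = None
    compound_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doses = _as_float_array(self.doses, "doses")
        self.responses = _as_float_array(self.responses, "responses")
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must have equal length")
        if np.any(self.doses < 0):
            raise ValueError("doses must be nonnegative")
        if self.response_kind == "in_vitro_rate" and not (
            self.e_total is not None and self.e_total > 0
        ):
            raise ValueError("e_total (nM active sites) required for in_vitro_rate data")
        if self.replicate_ids is not None:
            self.replicate_ids = np.asarray(self.replicate_ids).ravel()
            if self.replicate_ids.shape != self.doses.shape:
                raise ValueError("replicate_ids length mismatch")

    def aggregated(self) -> tuple[np.ndarray, np.ndarray]:
        """Replicate-averaged (unique strictly increasing doses, mean responses)."""
        doses = np.unique(self.doses)
        means = np.array([self.responses[self.doses == d].mean() for d in doses])
        return doses, means

    @property
    def n_doses(self) -> int:
        return int(np.unique(self.doses).size)


@dataclass
class TitrationDataset:
    """Equilibrium fluorescence titration of a ligand into enzyme.

    ``site_concentration`` is binding sites in nM (dimer concentration x2,
    one site per monomer).  ``background`` labels the enzyme species being
    titrated (e.g. 'E', 'E.PAP', 'E.PAP.Tam'); ligands held saturating
    define the species rather than entering the fit as competitors.
    """

    ligand_totals: np.ndarray
    signals: np.ndarray
    site_concentration: float
    background: str = "E"
    replicate_ids: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ligand_totals = _as_float_array(self.ligand_totals, "ligand_totals")
        self.signals = _as_float_array(self.signals, "signals")
        if self.ligand_totals.shape != self.signals.shape:
            raise ValueError("ligand_totals and signals must have equal length")
        if np.any(self.ligand_totals < 0):
            raise ValueError("ligand_totals must be nonnegative")
        if not self.site_concentration > 0:
            raise ValueError("site_concentration must be positive")

    def aggregated(self) -> tuple[np.ndarray, np.ndarray]:
        doses = np.unique(self.ligand_totals)
        means = np.array([self.signals[self.ligand_totals == d].mean() for d in doses])
        return doses, means


@dataclass
class ProgressCurve:
    """One stopped-flow fluorescence progress curve at fixed ligand.

    Concentrations are after 1:1 mixing: ``ligand_um`` in uM,
    ``site_concentration_nm`` in nM (dimer x2).  The pseudo-first-order
    regime requires ligand >> sites; ``pseudo_first_order`` records whether
    ligand >= 10x sites.
    """

    times: np.ndarray
    signals: np.ndarray
    ligand_um: float
    site_concentration_nm: float
    n_averaged: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.signals = _as_float_array(self.signals, "signals")
        if self.times.shape != self.signals.shape:
            raise ValueError("times and signals must have equal length")
        if self.times[0] < 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing from >= 0")
        if not (self.ligand_um > 0 and self.site_concentration_nm > 0):
            raise ValueError("concentrations must be positive")

    @property
    def pseudo_first_order(self) -> bool:
        return self.ligand_um * 1e3 >= 10.0 * self.site_concentration_nm


@dataclass
class TransientSeries:
    """k_obs vs ligand concentration from a set of progress curves."""

    ligand_concentrations: np.ndarray  # uM, after mix
    k_obs_values: np.ndarray  # s^-1
    k_obs_sds: np.ndarray | None = None
    pseudo_first_order_flags: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ligand_concentrations = _as_float_array(
            self.ligand_concentrations, "ligand_concentrations"
        )
        self.k_obs_values = _as_float_array(self.k_obs_values, "k_obs_values")
        if self.ligand_concentrations.shape != self.k_obs_values.shape:
            raise ValueError("length mismatch between concentrations and k_obs")
        if self.ligand_concentrations.size < 2:
            raise ValueError("need at least 2 concentrations for the k_obs line")
        if self.k_obs_sds is not None:
            self.k_obs_sds = _as_float_array(self.k_obs_sds, "k_obs_sds")
            if self.k_obs_sds.shape != self.k_obs_values.shape:
                raise ValueError("k_obs_sds length mismatch")
            if np.any(self.k_obs_sds < 0):
                raise ValueError("k_obs_sds must be nonnegative")
        if self.pseudo_first_order_flags is not None:
            self.pseudo_first_order_flags = np.asarray(
                self.pseudo_first_order_flags, dtype=bool
            ).ravel()
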