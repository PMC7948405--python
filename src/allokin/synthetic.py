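"""Synthetic datasets with known ground truth for every fitter.

The scenario catalog carries the characterized parameter sets of the three
allosteric SULT1A3 inhibitors (CMP8/12/13): in vitro K_i and residual
activity alpha, ex vivo IC50 and suppressible fraction, equilibrium K_d of
CMP13 against the open/closed enzyme species, and PAP on/off rate constants
for the corresponding stopped-flow series.  Generators evaluate the exact
model of the matching fitter at the study's assay conditions (20 nM active
sites, doses 0.2-20 x K_i, 30 nM binding sites for titrations, PAP at
0.25-1.0 uM after 1:1 mix) and add seeded Gaussian noise, so every fitter
is testable by parameter recovery with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding import BindingFit, titration_signal
from .competition import CompetitionSystem, rate_two_inhibitors
from .datasets import DoseResponseDataset, ProgressCurve, TitrationDataset, TransientSeries
from .inhibition import ExVivoParams, InhibitorParams, exvivo_dps_model, rate_partial_noncompetitive

__all__ = [
    "NoiseSpec",
    "SCENARIOS",
    "gen_dose_response",
    "gen_titration",
    "gen_progress_curves",
    "gen_kobs_series",
    "gen_competition_curve",
    "gen_correlation_points",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Seeded Gaussian noise: multiplicative (fraction of signal) or additive (a.u.)."""

    kind: str = "multiplicative"
    sigma: float = 0.02
    seed: int = 0
    replicate_count: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative", "additive"):
            raise ValueError("kind must be 'multiplicative' or 'additive'")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")

    def apply(self, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        eps = rng.standard_normal(y.shape)
        if self.kind == "multiplicative":
            return y * (1.0 + self.sigma * eps)
        return y + self.sigma * eps


#: Characterized parameter sets used as generator ground truths.
SCENARIOS: dict = {
    "in_vitro": {
        "CMP8": InhibitorParams("CMP8", k_i=34.0, alpha=0.46),
        "CMP12": InhibitorParams("CMP12", k_i=70.0, alpha=0.17),
        "CMP13": InhibitorParams("CMP13", k_i=11.0, alpha=0.02),
    },
    # baseline media DPS at 100 uM dopamine / 24 h; the suppressible fraction
    # and IC50 are the characterized values
    "ex_vivo": {
        "CMP12": ExVivoParams(dps_no_inh=40.0, dps_suppressible=0.84 * 40.0, ic50=260.0),
        "CMP13": ExVivoParams(dps_no_inh=40.0, dps_suppressible=0.95 * 40.0, ic50=12.0),
    },
    # CMP13 binding to the open (E), closed (E.PAP) and held-open (E.PAP.Tam)
    # enzyme species; K_d in nM, sites = 15 nM dimer x 2
    "binding": {
        "E": {"k_d": 130.0, "sites": 30.0},
        "E.PAP": {"k_d": 11.0, "sites": 30.0},
        "E.PAP.Tam": {"k_d": 133.0, "sites": 30.0},
    },
    # PAP association with open/inhibited/held-open species: k_on uM^-1 s^-1,
    # k_off s^-1; sites after 1:1 mix (10 nM dimer -> 20 nM sites)
    "transient": {
        "E": {"k_on": 6.9, "k_off": 2.5, "sites_nm": 20.0},
        "E.CMP13": {"k_on": 6.6, "k_off": 0.18, "sites_nm": 20.0},
        "E.CMP13.Tam": {"k_on": 6.5, "k_off": 2.3, "sites_nm": 20.0},
    },
}

E_TOTAL_SITES_NM = 20.0  # active-site concentration of the initial-rate assay
DEAD_TIME_S = 1.5e-3  # stopped-flow mixing dead time


def _dose_grid(k_ref: float, n: int = 10, lo: float = 0.2, hi: float = 20.0,
               include_zero: bool = True) -> np.ndarray:
    """Log-spaced dose grid lo-hi x K_ref, optionally with a zero dose."""
    grid = np.geomspace(lo * k_ref, hi * k_ref, n)
    return np.concatenate([[0.0], grid]) if include_zero else grid


def gen_dose_response(
    scenario: str,
    doses: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(sigma=0.0),
    e_total: float = E_TOTAL_SITES_NM,
    kind: str = "in_vitro",
) -> DoseResponseDataset:
    """Dose-response data for one compound, in vitro rates or ex vivo DPS."""
    rng = np.random.default_rng(noise.seed)
    if kind == "in_vitro":
        truth = SCENARIOS["in_vitro"][scenario]
        if doses is None:
            doses = _dose_grid(truth.k_i)
        doses = np.asarray(doses, dtype=float)
        clean = rate_partial_noncompetitive(e_total, doses, truth)
        meta_truth = {"k_i": truth.k_i, "alpha": truth.alpha}
        response_kind = "in_vitro_rate"
    elif kind == "ex_vivo":
        truth = SCENARIOS["ex_vivo"][scenario]
        if doses is None:
            doses = _dose_grid(truth.ic50)
        doses = np.asarray(doses, dtype=float)
        clean = exvivo_dps_model(doses, truth)
        meta_truth = {
            "dps_no_inh": truth.dps_no_inh,
            "dps_suppressible": truth.dps_suppressible,
            "ic50": truth.ic50,
        }
        response_kind = "ex_vivo_dps"
        e_total = None
    else:
        raise ValueError("kind must be 'in_vitro' or 'ex_vivo'")

    reps = noise.replicate_count
    all_doses = np.repeat(doses, reps)
    all_resp = noise.apply(np.repeat(clean, reps), rng)
    return DoseResponseDataset(
        doses=all_doses,
        responses=all_resp,
        response_kind=response_kind,
        e_total=e_total,
        replicate_ids=np.tile(np.arange(reps), doses.size),
        compound_id=scenario,
        metadata={"ground_truth": meta_truth, "noise": vars(noise).copy(),
                  "seed": noise.seed},
    )


def gen_titration(
    scenario: str,
    ligand_totals: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(kind="multiplicative", sigma=0.0),
    signal_free: float = 1.0,
    signal_bound: float = 0.4,
) -> TitrationDataset:
    """Fluorescence titration of CMP13 into one enzyme species (quench on binding)."""
    spec = SCENARIOS["binding"][scenario]
    k_d, sites = spec["k_d"], spec["sites"]
    if ligand_totals is None:
        ligand_totals = np.concatenate([[0.0], np.geomspace(0.1 * k_d, 20.0 * k_d, 11)])
    ligand_totals = np.asarray(ligand_totals, dtype=float)
    fit = BindingFit(k_d=k_d, signal_free=signal_free, signal_bound=signal_bound)
    clean = titration_signal(ligand_totals, fit, sites)
    rng = np.random.default_rng(noise.seed)
    reps = noise.replicate_count
    all_l = np.repeat(ligand_totals, reps)
    all_s = noise.apply(np.repeat(clean, reps), rng)
    return TitrationDataset(
        ligand_totals=all_l,
        signals=all_s,
        site_concentration=sites,
        background=scenario,
        replicate_ids=np.tile(np.arange(reps), ligand_totals.size),
        metadata={
            "ground_truth": {"k_d": k_d, "signal_free": signal_free,
                             "signal_bound": signal_bound},
            "seed": noise.seed,
        },
    )


def gen_progress_curves(
    scenario: str,
    concentrations_um: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(kind="additive", sigma=0.0),
    n_points: int = 200,
    n_averaged: int = 5,
    amplitude: float = -0.2,
    offset: float = 1.0,
    dead_time: float = DEAD_TIME_S,
    allow_slow_ligand: bool = False,
) -> list[ProgressCurve]:
    """Stopped-flow exponentials at several ligand concentrations (after mix).

    k_obs = k_on [L] + k_off per the scenario's rate constants.  Each curve
    is the average of ``n_averaged`` shots (noise scaled by 1/sqrt(n)).
    Refuses ligand below 10x sites (pseudo-first-order guard) unless
    ``allow_slow_ligand``.
    """
    spec = SCENARIOS["transient"][scenario]
    k_on, k_off, sites_nm = spec["k_on"], spec["k_off"], spec["sites_nm"]
    if concentrations_um is None:
        concentrations_um = np.array([0.25, 0.5, 0.75, 1.0])
    concentrations_um = np.asarray(concentrations_um, dtype=float)
    guard = concentrations_um * 1e3 < 10.0 * sites_nm
    if np.any(guard) and not allow_slow_ligand:
        bad = concentrations_um[guard]
        raise ValueError(
            f"ligand {bad} uM below 10x sites ({sites_nm} nM): pseudo-first-order "
            "assumption invalid (pass allow_slow_ligand=True to override)"
        )
    rng = np.random.default_rng(noise.seed)
    curves = []
    for conc in concentrations_um:
        k_obs = k_on * conc + k_off
        t = np.linspace(dead_time, dead_time + 5.0 / k_obs, n_points)
        clean = offset + amplitude * np.exp(-k_obs * t)
        # averaged-shot noise: per-point sigma shrinks by sqrt(n_averaged)
        eff = NoiseSpec(noise.kind, noise.sigma / np.sqrt(n_averaged), noise.seed,
                        noise.replicate_count)
        sig = eff.apply(clean, rng)
        curves.append(
            ProgressCurve(
                times=t, signals=sig, ligand_um=float(conc),
                site_concentration_nm=sites_nm, n_averaged=n_averaged,
                metadata={
                    "ground_truth": {"k_obs": k_obs, "k_on": k_on, "k_off": k_off,
                                     "amplitude": amplitude, "offset": offset},
                    "seed": noise.seed,
                },
            )
        )
    return curves


def gen_kobs_series(
    scenario: str,
    concentrations_um: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(kind="multiplicative", sigma=0.0),
) -> TransientSeries:
    """k_obs vs [ligand] series directly from the scenario's rate line."""
    spec = SCENARIOS["transient"][scenario]
    if concentrations_um is None:
        concentrations_um = np.array([0.25, 0.5, 0.75, 1.0])
    concentrations_um = np.asarray(concentrations_um, dtype=float)
    clean = spec["k_on"] * concentrations_um + spec["k_off"]
    rng = np.random.default_rng(noise.seed)
    reps = noise.replicate_count
    draws = np.array([noise.apply(clean, rng) for _ in range(reps)])
    k_obs = draws.mean(axis=0)
    sds = draws.std(axis=0, ddof=1) if reps > 1 else None
    flags = concentrations_um * 1e3 >= 10.0 * spec["sites_nm"]
    return TransientSeries(
        ligand_concentrations=concentrations_um,
        k_obs_values=k_obs,
        k_obs_sds=sds,
        pseudo_first_order_flags=flags,
        metadata={"ground_truth": {"k_on": spec["k_on"], "k_off": spec["k_off"]},
                  "seed": noise.seed},
    )


def gen_competition_curve(
    sys: CompetitionSystem | None = None,
    b_fixed: float = 20.0 * 11.0,
    a_grid: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(sigma=0.0),
) -> DoseResponseDataset:
    """Displacement curve: CMP8 titrated against a fixed saturating partner.

    Defaults to CMP8 vs CMP13 held at 20 x K_i (180 nM after rounding the
    assay's 0.18 uM), CMP8 spanning 0-300 x K_i.
    """
    if sys is None:
        sys = CompetitionSystem(SCENARIOS["in_vitro"]["CMP8"],
                                SCENARIOS["in_vitro"]["CMP13"])
    if a_grid is None:
        a_grid = np.concatenate([[0.0], np.geomspace(0.5 * sys.inhibitor_a.k_i,
                                                     300.0 * sys.inhibitor_a.k_i, 12)])
    a_grid = np.asarray(a_grid, dtype=float)
    clean = rate_two_inhibitors(a_grid, b_fixed, sys)
    rng = np.random.default_rng(noise.seed)
    reps = noise.replicate_count
    all_a = np.repeat(a_grid, reps)
    all_v = noise.apply(np.repeat(clean, reps), rng)
    return DoseResponseDataset(
        doses=all_a,
        responses=all_v,
        response_kind="in_vitro_rate",
        e_total=E_TOTAL_SITES_NM,
        replicate_ids=np.tile(np.arange(reps), a_grid.size),
        compound_id=f"{sys.inhibitor_a.compound_id}-vs-{sys.inhibitor_b.compound_id}",
        metadata={
            "ground_truth": {
                "k_i_a": sys.inhibitor_a.k_i, "alpha_a": sys.inhibitor_a.alpha,
                "k_i_b": sys.inhibitor_b.k_i, "alpha_b": sys.inhibitor_b.alpha,
                "b_fixed": b_fixed,
            },
            "seed": noise.seed,
        },
    )


def gen_correlation_points(
    ddg_calc: np.ndarray | None = None,
    slope: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
):
    """Compound series for the free-energy correlation: ddg_exp = ddg_calc/slope + noise.

    Defaults emulate a six-compound series spanning -0.2 to -1.5 kcal/mol
    with 0.05 kcal/mol scatter in the experimental dimension.
    """
    from .thermo import CorrelationPoint

    if ddg_calc is None:
        ddg_calc = np.linspace(-0.2, -1.5, 6)
    ddg_calc = np.asarray(ddg_calc, dtype=float)
    rng = np.random.default_rng(seed)
    ddg_exp = ddg_calc / slope + noise_sd * rng.standard_normal(ddg_calc.shape)
    return [
        CorrelationPoint(f"cmp{i+1}", float(c), float(e))
        for i, (c, e) in enumerate(zip(ddg_calc, ddg_exp))
    ]
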