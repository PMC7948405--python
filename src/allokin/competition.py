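"""Two inhibitors competing for one allosteric site.

With both substrates saturating and inhibitors A and B binding mutually
exclusively at the allosteric site, the rapid-equilibrium rate is

    v/Vmax = (KiA*KiB + KiB*aA*[A] + KiA*aB*[B])
             / (KiA*KiB + [A]*KiB + [B]*KiA)

where aA, aB are the residual activity fractions at saturation.  Holding
one inhibitor fixed collapses this to a single-inhibitor hyperbola with
constants C1 = 1 + aA*[A]/KiA and C2 = 1 + [A]/KiA.  Titrating a weak
partial inhibitor (A) against a saturating strong one (B) raises the rate
toward A's own plateau alpha_A — the displacement signature that proves a
shared site.  The form neglects enzyme depletion; a mass-action numerical
solution is provided as a diagnostic for that approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .inhibition import InhibitorParams

__all__ = [
    "CompetitionSystem",
    "FixedInhibitorReduction",
    "rate_two_inhibitors",
    "reduce_fixed_b",
    "simulate_displacement",
    "rate_two_inhibitors_depleted",
]


@dataclass(frozen=True)
class CompetitionSystem:
    """Two inhibitors sharing the allosteric site; v_max scales the output."""

    inhibitor_a: InhibitorParams
    inhibitor_b: InhibitorParams
    v_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.v_max > 0:
            raise ValueError("v_max must be positive")


@dataclass(frozen=True)
class FixedInhibitorReduction:
    """Constants of the fixed-[A] simplification: v = Vmax (C1 KiB + aB b)/(C2 KiB + b)."""

    c1: float
    c2: float
    a_fixed: float

    def __post_init__(self) -> None:
        if self.c2 < 1.0 - 1e-12:
            raise ValueError("c2 must be >= 1")
        if self.c1 > self.c2 + 1e-12:
            raise ValueError("c1 cannot exceed c2 for alpha_A <= 1")


def rate_two_inhibitors(a, b, sys: CompetitionSystem):
    """v/Vmax with inhibitors A and B at totals a, b (nM), no enzyme depletion."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("inhibitor concentrations must be nonnegative")
    ka, aa = sys.inhibitor_a.k_i, sys.inhibitor_a.alpha
    kb, ab = sys.inhibitor_b.k_i, sys.inhibitor_b.alpha
    num = ka * kb + kb * aa * a + ka * ab * b
    den = ka * kb + a * kb + b * ka
    out = sys.v_max * num / den
    return float(out) if np.ndim(out) == 0 else out


def reduce_fixed_b(sys: CompetitionSystem, a_fixed: float) -> FixedInhibitorReduction:
    """Constants C1, C2 of the one-variable form obtained by fixing [A]."""
    if a_fixed < 0:
        raise ValueError("a_fixed must be nonnegative")
    ka, aa = sys.inhibitor_a.k_i, sys.inhibitor_a.alpha
    return FixedInhibitorReduction(
        c1=1.0 + a_fixed * aa / ka,
        c2=1.0 + a_fixed / ka,
        a_fixed=a_fixed,
    )


def rate_reduced(b, red: FixedInhibitorReduction, sys: CompetitionSystem):
    """v/Vmax from the reduced form; identical to rate_two_inhibitors at fixed [A]."""
    b = np.asarray(b, dtype=float)
    kb, ab = sys.inhibitor_b.k_i, sys.inhibitor_b.alpha
    out = sys.v_max * (red.c1 * kb + ab * b) / (red.c2 * kb + b)
    return float(out) if np.ndim(out) == 0 else out


def simulate_displacement(sys: CompetitionSystem, b_fixed: float, a_grid) -> np.ndarray:
    """Displacement curve: v/Vmax vs [A] at fixed saturating [B].

    Rises toward the plateau alpha_A (A's own residual activity) when
    alpha_A > alpha_B; plateau inhibition is 100*(1 - alpha_A) regardless of
    b_fixed or K_iB.
    """
    a_grid = np.asarray(a_grid, dtype=float)
    if b_fixed < 0 or np.any(a_grid < 0):
        raise ValueError("concentrations must be nonnegative")
    return rate_two_inhibitors(a_grid, b_fixed, sys)


def rate_two_inhibitors_depleted(
    e_total: float, a_total: float, b_total: float, sys: CompetitionSystem
) -> float:
    """Diagnostic: v/Vmax from the full mass-action system with enzyme depletion.

    Solves for free enzyme with A and B depleted by binding (mutually
    exclusive site), then forms v = (E_f + aA*EA + aB*EB)/E_tot.  Quantifies
    the error of the no-depletion rate law when K_i is comparable to the
    site concentration; not used for reproduction of the displacement curve.
    """
    if min(e_total, a_total, b_total) < 0 or e_total == 0:
        raise ValueError("need e_total > 0 and nonnegative inhibitor totals")
    ka, aa = sys.inhibitor_a.k_i, sys.inhibitor_a.alpha
    kb, ab = sys.inhibitor_b.k_i, sys.inhibitor_b.alpha

    def residual(e_free: float) -> float:
        a_free = a_total / (1.0 + e_free / ka)
        b_free = b_total / (1.0 + e_free / kb)
        return e_free * (1.0 + a_free / ka + b_free / kb) - e_total

    e_free = brentq(residual, 0.0, e_total, xtol=1e-14 * max(e_total, 1.0), rtol=1e-14)
    a_free = a_total / (1.0 + e_free / ka)
    b_free = b_total / (1.0 + e_free / kb)
    ea = e_free * a_free / ka
    eb = e_free * b_free / kb
    return sys.v_max * (e_free + aa * ea + ab * eb) / e_total
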