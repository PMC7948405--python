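# Methods

## The model chain

### Cap isomerization and turnover

The enzyme's nucleotide-bound state is treated as a two-state system, cap
open ⇌ cap closed, with equilibrium constant K_iso = [closed]/[open]
(13 ± 1.7 for the uninhibited SULT1A3·PAP complex). Nucleotide release —
the rate-limiting step of the forward catalytic cycle — occurs only from
the open state with rate constant k_rel, so

    k_cat = F_open · k_rel = k_rel / (1 + K_iso),

and for K_iso ≫ 1, k_cat ≈ k_rel/K_iso. If k_rel is unaffected by a
cap-stabilizing allostere (verified kinetically: the inhibitor changes the
PAP off-rate of the *closed-cap pathway* but not release from the open
form), the turnover ratio of two ligand states equals the inverse ratio of
their K_iso values, giving the free-energy relation

    ΔΔG = −RT ln(k_cat,1 / k_cat,2).

Defaults: R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹, T = 298.15 K (assays at
25 ± 2 °C), k_rel = 2.5 s⁻¹ (the PAP off-rate from the open enzyme). All
are overridable through `ThermoContext`.

### Percent-inhibition conventions

A calculated stabilization ΔG maps to a fold change K = exp(−ΔG/RT) in
K_iso. Two conventions convert K to "percent inhibition at saturating
inhibitor" and both are implemented, explicitly labelled:

- paper convention, 100·K/(1+K): treats K as the inhibited enzyme's entire
  isomerization constant. ΔG = −1.17 and −1.41 kcal/mol give 87.8% and
  91.5% (printed as 88%/92%).
- ratio convention, 100·(1−1/K): follows strictly from the turnover-ratio
  approximation. The same ΔG values give 86.1% and 90.7%.

The conventions converge as ΔG → −∞ (difference < 0.5 points for K > 200).
The paper convention is the one that reproduces the published predictions
and is used for reproduction; the choice is a documentation decision, not a
physical one, because the conversion formula is not stated alongside the
printed percentages. A related bookkeeping note: the printed companion
K_iso fold of 7.6 for ΔG = −1.17 kcal/mol is not exp(1.17/RT) at any
temperature consistent with the −1.41 → 11 conversion; the package computes
7.21 from the formula and reports that, rather than hard-coding the printed
value.

### Tight-binding partial noncompetitive inhibition

With both substrates saturating, an allosteric partial inhibitor scales
turnover of the inhibitor-bound enzyme by α = k_cat,inh/k_cat ∈ [0, 1]:

    v/V_max = ([E]_tot + [ESI](α − 1)) / [E]_tot,
    [ESI] = {(E+I+K_i) − √((E+I+K_i)² − 4·I·E)} / 2.

The smaller quadratic root is the physical branch; it is evaluated in the
multiply-by-conjugate form 2IE/(s + √(s²−4IE)), s = E+I+K_i, which avoids
catastrophic cancellation when I ≫ E (or E ≫ I). The discriminant is
analytically nonnegative for K_i > 0; a negative value raises a
computational error with the offending inputs.

Fitting: unweighted Levenberg–Marquardt least squares (scipy `curve_fit`)
with α bounded to [0, 1] and K_i > 0; 1-SD uncertainties from the fit
covariance, with a seeded residual-bootstrap alternative. Responses are
normalized to the mean zero-dose rate before fitting (zero-dose points are
retained); replicates are averaged per dose by default with pooled fitting
available. A warning is issued when the dose range fails to bracket the
fitted K_i.

### Two-inhibitor competition

Mutually exclusive binding of A and B at the allosteric site under rapid
equilibrium, substrates saturating:

    v/V_max = (K_iA·K_iB + K_iB·α_A[A] + K_iA·α_B[B])
              / (K_iA·K_iB + [A]·K_iB + [B]·K_iA).

At fixed [A] this collapses to a hyperbola in [B] with constants
C1 = 1 + α_A[A]/K_iA and C2 = 1 + [A]/K_iA (the reduction is verified to
machine precision against the full form). The saturating-[A] limit is
exactly α_A independent of [B] and K_iB — titrating the weak partial
inhibitor CMP8 (K_i 34 nM, α 0.46) against 20×K_i CMP13 (11 nM, 0.02)
therefore relieves inhibition to CMP8's own 54% plateau. Two deliberate
properties of this form:

- it neglects enzyme depletion (no [E]_tot term), matching how the
  displacement overlay is simulated rather than fitted. A mass-action
  numerical solution with depletion (`rate_two_inhibitors_depleted`,
  Brent root-finding on free enzyme) is provided as a diagnostic; at 20 nM
  sites vs K_iB = 11 nM the depletion correction is visible but does not
  move the plateau.
- at any finite dose the curve sits below the plateau: at 300×K_iA against
  180 nM fixed partner the rate is ≈0.44 vs the 0.46 limit (~4%), because
  the [B]·K_iA denominator term persists. The module exposes `simulate`,
  not `fit`, for two-inhibitor data.

### Equilibrium titrations

Binding is monitored by ligand-induced quench of intrinsic protein
fluorescence. One site per monomer; dimer concentrations are converted ×2
to sites, treated as independent (no cooperativity is modelled). At 30 nM
sites against K_d = 11 nM the free≈total approximation fails, so the
occupied fraction comes from the same depletion quadratic and the signal is

    S = S_free + (S_bound − S_free) · f_bound.

The depletion-aware quadratic is the default fit; the naive hyperbola is
available behind `depletion=False` and demonstrably overestimates K_d by
>50% in the tight regime. The occupancy error of the hyperbola scales as
~e_sites/(l + K_d): roughly 1% at sites = K_d/100 and 0.1% at K_d/1000.
Background ligands held saturating (PAP at 100×K_d, 4-hydroxy-tamoxifen at
200×K_d) define the enzyme species being titrated and do not enter the fit
as competing equilibria. Signal direction is a free sign — quench and
enhancement fit identically.

### Stopped-flow transients

Single-step binding under pseudo-first-order conditions (ligand ≥ 10×
sites; the generator refuses lower ratios unless overridden) relaxes as
S(t) = offset + amplitude·exp(−k_obs t) with k_obs = k_on[L] + k_off. The
exponential fit floats the offset (stopped-flow baselines are arbitrary);
curves start at a 1.5 ms instrument dead time (configurable). Ligand
concentrations are quoted after 1:1 mixing. k_obs SDs from replicate
determinations propagate as 1/σ² weights into the line fit (unweighted
option retained); a negative fitted intercept is reported clamped at zero
with a flag, since k_off ≥ 0. The kinetic K_d = k_off/k_on is compared to
the equilibrium K_d with a configurable agreement factor (default 1.5×).
For the inhibitor-bound complex the computed kinetic K_d is 0.18/6.6 =
0.027 µM; the tabulated 0.029 reflects rounding of the inputs and the
computed value is what the package reports.

### Ex vivo suppression and quantitation

In SULT1A3-expressing cells dosed with 100 µM dopamine, media
dopamine-sulfate (DPS) accumulates linearly in time and dose, so the
24-hour DPS level responds 1:1 to enzyme inhibition:

    [DPS]([I]) = [DPS]_−inh − [DPS]_supp · [I]/(IC50 + [I]).

Percent inhibition at saturation is 100·[DPS]_supp/[DPS]_−inh. Metabolites
are quantitated by Beer–Lambert (ε₂₈₀ = 3.2 mM⁻¹cm⁻¹ for dopamine, ε₂₈₄ =
2.8 for DPS) and a mass-balance QC requires (DP + DPS)/DP_added ≥ 0.95 —
the boundary is treated as inclusive.

## Synthetic data: what it emulates and what it does not

Generators evaluate the exact model of the matching fitter at the assay
designs and add seeded Gaussian noise:

| dataset | design | truth (defaults) | noise |
|---|---|---|---|
| dose–response | 20 nM sites, 0 + log-spaced 0.2–20×K_i (10 doses), triplicate | K_i/α: 34/0.46, 70/0.17, 11/0.02 | 2% multiplicative |
| ex vivo DPS | 0 + 0.2–20×IC50 | IC50 260/12 nM, suppressible 84%/95%, baseline 40 µM | 2% multiplicative |
| titration | 30 nM sites, 0 + 0.1–20×K_d (11 doses), triplicate | K_d 130/11/133 nM, quench 1.0→0.4 a.u. | 1% multiplicative |
| stopped flow | 20 nM sites, PAP 0.25/0.5/0.75/1.0 µM after mix, 200 pts over 5/k_obs, 5-shot average | k_on/k_off: 6.9/2.5, 6.6/0.18, 6.5/2.3 | 1% additive ÷ √5 |
| ddG series | 6 compounds, −0.2…−1.5 kcal/mol | slope 1 | σ = 0.05 kcal/mol on the experimental axis |

The baseline media DPS of 40 µM is a choice: the uninhibited 24-hour level
at 100 µM dopamine is not tabulated, and 40 µM is a realistic mid-linear-
regime value; only the IC50 and the suppressible *fraction* carry
information, so this scale does not affect recovery conclusions. Noise
magnitudes (2% rates, 1% fluorescence) were set so recovered SDs are
comparable to the parenthetical SDs of the characterized parameters — a
calibration of the generator, not a measured instrument property.

Not emulated: photon-level instrument noise, inner-filter and
photobleaching effects, HPLC peak shapes, multi-exponential or
conformational-selection binding schemes, substrate-side (competitive/
uncompetitive) inhibition, and cooperativity between monomers. Passing
recovery tests therefore show the estimators are correct and well
conditioned at the stated designs — not that real instrument artifacts are
handled.

One concentration bookkeeping choice: the stopped-flow enzyme feed is 20 nM
dimer pre-mix (10 nM dimer = 20 nM sites after mixing), which keeps the
lowest PAP concentration (0.25 µM) above the 10× pseudo-first-order guard.

## Numerical choices

- Binding quadratics in conjugate form (no cancellation); discriminant
  guard raises with diagnostics.
- Nonlinear fits: scipy `curve_fit` (trust-region reflective when bounded),
  data-driven starting values (minimum response for α, half-change dose for
  K_i/K_d/IC50, 63%-decay time for k_obs), maxfev 20000; non-convergence
  raises with the optimizer message.
- OLS for the free-energy correlation is unweighted: scatter in the
  calculated dimension is negligible, so errors-in-variables machinery is
  not warranted. Recovery of the generating slope is judged against the
  sampling SE implied by the generating noise, σ/√S_xx.
- Monte-Carlo recovery asserts medians within 2 Monte-Carlo standard errors
  (1.2533·σ/√n) of truth over 200 seeds per fitter — problem sizes chosen
  to make the recovery study sharp yet quick.
- Degenerate inputs: all-zero dose columns, flat progress curves,
  rank-deficient k_obs designs, and zero-variance correlation abscissae all
  raise `ValueError` rather than returning unidentified parameters.

## Known limitations

- The two-inhibitor fit surface is intentionally absent (simulation only);
  fitting displacement data would require the depletion-aware model plus
  error propagation from both single-inhibitor fits.
- k_obs uncertainties assume independent Gaussian errors; correlated
  drift across a shot average is not modelled.
- The ex vivo model assumes DPS export is fast relative to formation (so
  media DPS mirrors enzyme flux); no transport step is modelled.
- Percent-inhibition predictions from ΔG use the two-state cap model
  without the baseline K_iso correction; with K_iso = 13 explicitly the
  predicted values shift by ~1–2 points (both paths are available through
  `kcat_from_iso`).
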