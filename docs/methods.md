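# Methods and modeling notes

This document records the model structure, parameter provenance, and
numerical methods behind `crossfeed`, including the assumptions a user
should review before trusting the outputs in a new setting.

## 1. Medium chemistry and pH

Medium pH is treated as an *algebraic* function of culture history: at any
instant the composition (phosphate buffer, accumulated weak acids, protons
released by growth) determines pH through electroneutrality. The solver
finds the root of

```
h + c0 − Kw/h − L − q_P(pH)·P_tot − Σ_i f_i(pH)·A_i = 0
```

where `h = [H+]`, `c0` is a fixed cation offset chosen once so that the
*initial* medium composition reproduces the stated initial pH, `L` is the
cumulative proton load from growth (mol/L), `q_P` is the mean negative
charge per phosphate at that pH, and `f_i` is the dissociated fraction of
weak acid `i` (total `A_i`, mol/L). The residual is strictly decreasing in
pH, so bisection on pH ∈ (1, 13) with tolerance 1e−12 is globally
convergent. At the solution the charge residual is < 1e−10 M (measured:
~4e−16 M).

Assumptions and their limits:

- **Single-pKa2 phosphate (pKa 7.20) by default.** Around pH 4–8, H3PO4 and
  PO4³⁻ are negligible; a full triprotic model is available
  (`MediumSpec(triprotic=True)`) and agrees with the default to < 0.05 pH
  units over the simulated range.
- **Activity coefficients are ignored** (concentrations ≈ activities).
  Adequate at the ionic strengths of the minimal media modeled here; do not
  reuse for high-salt media without revisiting.
- **The fixed cation offset is a stand-in for everything not modeled
  explicitly** (counterions of the phosphate salts, trace ions). It is
  calibrated at t = 0 and held constant, which is exact for a closed batch.
- **Biomass-linked proton release**: growth itself releases protons
  (ammonium uptake, CO2) at `Y_H = 0.009 mol H+ per g cdw` for every guild.
  This single lumped yield is the dominant driver of acidification in
  non-producing cultures and pins the low-buffer biomass ceiling near
  (buffer capacity)/`Y_H`; conclusions near the arrest boundary are
  sensitive to it (see §6).

Weak-acid speciation uses the Henderson–Hasselbalch closed form; acetic
acid pKa 4.756, lactic acid pKa 3.86.

## 2. Growth-rate laws

Six inhibition forms are implemented (`kinetics.FORM_PARAMS`), evaluated in
closed form and clamped at zero:

| form id | expression (μ in h⁻¹) | inhibitor basis |
| --- | --- | --- |
| `monod_haldane_exp` | `mu_max · S/(ks+S) · exp(−S/ki)` | protonated acid S, mM |
| `monod_product_exp` | `mu_max · G/(kg+G) · exp(−k·P)` | protonated acid P, mM |
| `dual_substrate_exp` | `mu_max · G/(kg+G) · L/(kl+L) · exp(−alpha·L)` | protonated acid L, mM |
| `linear_pH` | `mu_max · (1 − H/h_star)` | free protons H, mol/L |
| `ghose_tyagi` | `mu_max · (1 − P/p_star)` | total acid P, mM |
| `combined_stress` | product of Monod, exponential-product, and pH terms | both |

Notes on provenance and units:

- The inhibitor in the exponential terms is the **protonated** (membrane-
  permeant) acid concentration in mM; the pH-threshold term uses free
  `[H+]` in mol/L with `h_star = 10^−4.4` (growth is impossible at or below
  pH 4.4). These two bases must not be mixed up when refitting.
- `alpha` (4.44 mM⁻¹) is the per-mM exponential sensitivity of the
  lactic+glucose form.
- The Haldane argmax has the closed form
  `S* = (−ks + sqrt(ks² + 4·ks·ki))/2`; the numeric optimizer is checked
  against it (agreement ≤ 1e−10 relative, see §5).
- Bundled wild-type parameterizations (`kinetics.wildtype_model`): acetic
  sole-carbon {mu_max 0.4, ks 0.0723, ki 0.760}; lactic sole-carbon
  {0.5, 0.0038, 0.317}; acetic+glucose {0.65, kg 0.005, k 1.35};
  lactic+glucose {0.65, kg 0.005, kl 0.0743, alpha 4.44}; pH threshold
  {0.665, h_star 10^−4.4}. Peak rates implied: 0.2258, 0.4040, and 0.7348
  h⁻¹ (lactic+glucose at 56 mM glucose).

## 3. Batch consortium model

State variables: biomass per guild `X_j` (g cdw/L), glucose `G` (mM), one
exchanged acid `A` (total, mM), cumulative proton load `L` (mol/L). pH is
solved algebraically inside the right-hand side at every evaluation.

- **Producer law**: Monod in glucose × linear total-acid inhibition
  (Ghose–Tyagi, ceiling `p_star`) × pH-arrest factor. Secretes acid at
  `Y_PX` g acid per g biomass.
- **Consumer law**: Monod–Haldane in protonated acid × pH-arrest factor.
  Consumes acid at `1/Y_XA`.
- **Generalist**: Monod in glucose × pH-arrest factor.
- **pH-arrest factor** `(1 − H/h_star)+` with `h_star = 10^−4.4` is applied
  to **every guild by default**; pass `h_star=None` in a guild override to
  disable it. This choice is consequential (§6).
- No diauxie: the consumer uses only the acid, the producer only glucose.
- Acid leak from the generalist is off by default (`leak=0`; 0.016 g/g is a
  plausible alternative).

Preset parameter families (`presets.guild`, `presets.scenario`):

| guild | family `ode` | family `measured` |
| --- | --- | --- |
| generalist (wt) | μmax 0.6, Y_XG 0.43 | μmax 0.65 |
| acetate producer | μmax 0.6, Y_XG 0.25, Y_PX 0.38 | μmax 0.54 |
| acetate consumer | μmax 0.3, Y_XA 0.24 | μmax 0.14 |
| lactate producer | μmax 0.3, Y_XG 0.05, Y_PX 15 | μmax 0.24 |
| lactate consumer | μmax 0.5, Y_XA 0.5 | μmax 0.41 |

All guilds share `Y_H = 0.009 mol H+/g`. Total-acid ceilings `p_star`:
1.44 mM protonated-equivalent (acetic), 0.45 (lactic). The `ode` family is
the self-consistent parameter set used for simulation; the `measured`
family carries independently measured exponential rates. The two disagree
for the producers (e.g. 0.6 vs 0.54 h⁻¹) — this discrepancy is surfaced
rather than reconciled, and the families are kept separate so a user can
choose either basis.

Media: minimal phosphate 6.3 mM vs conventional 64 mM; glucose 5000/180 ≈
27.8 mM; initial pH 7.0; inoculum 0.008 g cdw/L per guild (OD600 0.020 ×
0.4 g cdw per OD unit); working volume 0.1 L for per-culture mmol
quantities.

Integration: `scipy.integrate.solve_ivp` with LSODA, rel_tol 1e−6 / abs_tol
1e−9 by default, `max_step` 1.0 h, and non-terminal events for growth
arrest (pH reaching 4.4) and glucose exhaustion. Endpoint metrics shift by
< 0.1 % under tolerance tightening to 1e−9/1e−12 or step halving.

## 4. ATP accounting

Per mol substrate, using P/O ratios NADH → 2 and FADH2 → 1 (the unique
simple-integer assignment consistent with all five ledgers):

| mode | pathway | ATP/mol |
| --- | --- | --- |
| generalist | glycolysis + PDH + TCA + oxidative phosphorylation | 26 |
| acetate producer | glycolysis + pta-ackA branch | 4 |
| lactate producer | glycolysis + ldhA branch | 2 |
| acetate consumer | acs activation + TCA + respiration | 7 |
| lactate consumer | lactate dehydrogenase + PDH + TCA + respiration | 12 |

Opportunity costs (what a producer forgoes relative to complete oxidation):
acetate 22, lactate 24; producer yield + opportunity cost = 26 exactly.
Electron balances close exactly for every mode, and both acids have degree
of reduction `(4C + H − 2O)/C = 4` — the same electrons per carbon as
glucose, which is why stranding them is costly. Proteome investment
accounting (e.g. pyruvate dehydrogenase complex, 42 096 amino acids per
assembly) is available via `energetics.proteome_investment`.

## 5. Numerical methods

- **pH**: bisection, §1.
- **Peak growth**: bounded scalar minimization (xatol 1e−12) followed by a
  derivative polish — Brent root-finding on the central-difference
  derivative. Function-value-only search locates a quadratic optimum no
  better than √ε ≈ 1.5e−8 relative; the polish reaches ~ε^(2/3), measured
  ≤ 2.4e−11 against the Haldane closed form.
- **Refitting**: `lmfit` Levenberg–Marquardt with xtol/ftol 1e−12 and a
  deterministic multi-start grid (each non-`mu_max` parameter scaled by
  {0.2, 1, 5}; best χ² wins). Starting points are clipped strictly inside
  the bounds: a parameter that starts exactly on a bound or exactly at the
  bounds midpoint can stall in bounded Levenberg–Marquardt.
- **Identifiable refit design** (`workbench.refit_dataset`): dose grids are
  log-spaced with a zero-dose control (half-saturation constants down to
  0.0038 mM are invisible to uniform grids), and the glucose-coupled forms
  vary glucose over {0.01, 1, 56} mM because `kg` is structurally
  unidentifiable at a single saturating glucose level.
- **Growth-rate estimation**: slope of ln(biomass) over the largest
  contiguous window with log-linear R² ≥ 0.98 and ≥ 4 points (earlier
  window preferred on ties), via prefix sums. If no window qualifies the
  best window is returned flagged low-confidence.
- **Model selection**: candidates ranked by (−R² rounded to 12 decimals,
  number of parameters, form id) — deterministic and independent of
  candidate order.

## 6. Sensitivity: the pH-arrest factor on the consumer

Whether the acid **consumer** also carries the pH-arrest factor is the
single most consequential switch near the low-buffer boundary, and both
poles were measured:

- **Factor on (default)**: every culture in a weakly buffered medium
  arrests at pH 4.4 with residual acid present. The consortium then ends
  with slightly *more* dissociated acid in the medium than the generalist
  (the consumer is substrate-starved early, while the medium is near pH 7
  and almost all acid is deprotonated), so its final biomass lands ~0.5 %
  *below* the generalist's (0.2460 vs 0.2471 g/L) even though it converts
  64 % more glucose. Secretion-yield sweeps remain strictly monotone.
- **Factor off for consumers**: consumers keep scavenging below pH 4.4,
  every sweep member converges to the same proton-budget ceiling
  (0.2901 g/L, exact ties), and the secretion-yield sweep degenerates —
  the biomass ordering carries no information.

The default is the on-by-default factor for all guilds; disable per guild
with `h_star=None` only with this trade-off in mind.

## 7. Synthetic data: scope and limits

`synthdata` reproduces the measurement process, not new biology: lognormal
multiplicative OD noise (CV 3 %), HPLC left-censoring at 0.1 mM (values
below the limit are NaN with a censored flag), and drop-plate colony counts
(Poisson counts in the countable 3–30 per 10 µL drop range after automatic
decimal dilution, 2.5e12 CFU per g cdw, producer counts obtained by
difference and clamped at zero). Sampling follows a per-doubling cadence.
Conversions OD→cdw (0.4 g/L per OD600) and cdw→CFU are conventional
bridge values, not measured here; absolute CFU-based quantities inherit
their uncertainty. Noise-free round trips (trajectory → observations →
metrics) preserve performance metrics to ≤ 1e−9 relative (1e−3 for
proton-normalized biomass, which requires pH reconstruction), and the
growth-rate estimator recovers a generating rate of 0.65 h⁻¹ to within
0.5 % in the 100-seed mean.
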