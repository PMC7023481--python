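# Methods

This note documents the models implemented in `pbbm`, the assumptions they
make, the defaults they ship with and why, the numerical choices, and what
the synthetic data generator does and does not emulate.

## Solubility model

A single acidic pKa Henderson–Hasselbalch curve,
`S(pH) = S0·(1 + 10^(pH − pKa))`, describes the total aqueous solubility of
the un-ionized/ionized pair.  The intrinsic solubility S0 is recovered by
anchoring the curve to one measured point (for ibuprofen 1.99 mg/mL at
pH 6.2 with pKa 4.54, giving S0 ≈ 42.6 µg/mL).  An optional *solubility
factor* cap (the maximum/intrinsic ratio) truncates the exponential growth
at high pH, standing in for predicted solubility profiles that level off;
by default no cap is applied, because no defensible cap value is available
for ibuprofen in the physiological range.  Shake-flask solubilities
measured in aspirated human GI fluids are shipped as a fixture for
plotting overlays only: they embed media effects (bile salts, buffer
species, self-buffering) that a bulk-pH curve deliberately does not model.

## Six-state gut/plasma models

Both variants track amounts (µg): gastric solid, duodenal solid/dissolved,
jejunal solid/dissolved, plasma; two cumulative states (eliminated,
distally transited solid) close the mass balance identically.  Shared
assumptions: no gastric dissolution or absorption (gastric pH ≪ pKa for an
acid; tablet disintegrates but particles only empty), well-mixed lumen
compartments with fixed effective volumes V1/V2, dissolved drug absorbed
in place at a fast fixed Ka = 12 h⁻¹ (permeability is not rate limiting),
only solid particles transit distally, no luminal degradation, and
one-compartment disposition with Kel and V3 fixed externally (from NCA).

The basic variant empties the stomach first order (Kempt) throughout and
dissolves solids first order (`Kd_simple·M_solid`).  The extended variant
(a) keeps first-order emptying only until the first post-dose phase-III
contraction at t = TMMC, when the entire remaining gastric load transfers
to the duodenum as a bolus, and (b) makes dissolution pH-driven and
saturable: `K_Diss·M_solid·max(0, Cs(pH(t)) − C_lumen)`, with Cs evaluated
from the subject's luminal pH series (piecewise-linear in time, constant
beyond the endpoints).  The bilinear form is the only one that is
simultaneously proportional to the remaining solid, responsive to pH
through Cs, and dimensionally consistent with a dissolution coefficient in
mL/(µg·h).  The driving force is clamped at zero: a pH drop stalls
dissolution but does not precipitate drug, consistent with the absence of
any precipitation mechanism for an acid moving down the gut's pH gradient.

Numerics: LSODA with rtol 1e-8, atol 1e-10 µg (1e-5/1e-7 inside the
fitting loop, where speed matters and the objective tolerates it).  The
phase-III bolus is an event, never integrated across: the solver stops at
TMMC, the transfer is applied, and integration restarts; output times at
t ≥ TMMC report the post-event state.  Output amounts are clipped at zero
to remove integrator-scale undershoot.  Mass balance is asserted at 1e-6
relative in the test suite and holds at ~1e-14 in practice; a fixed-step
RK4 oracle at dt = 1e-3 h agrees to better than 0.1%.

## Estimation

Per subject, {Kempt, K_TD, K_TJ, K_Diss (or Kd_simple), V1, V2} are fitted
simultaneously to the duodenal, jejunal and plasma streams; Ka, Kel, V3
and TMMC stay fixed.  V1 and V2 are estimated, not pinned to imaging
values: the effective volume in contact with dissolving particles exceeds
resting fluid volumes.

Weighting.  Two residual schemes are provided.  The default,
`"proportional"`, divides each residual by the model prediction floored at
the quantification limit — the efficient choice when observation error is
multiplicative (as the cohort generator produces and as concentration
assays typically behave).  `"stream_max"` scales each stream's residuals
by its maximum observed concentration, which only equalizes stream scales;
it is retained because it makes no assumption about the error model.  A
Fisher-information comparison at the cohort-median parameters showed the
proportional scheme reduces estimator SD by roughly 2–4× for the transit
and volume parameters, which motivated the default.

Optimization: bounded least squares on log-parameters (trust-region
reflective), multi-start with the cohort-median vector as the first start
and log-uniform draws within bounds (observed fitted ranges widened by
×[0.1, 10]) for the rest; 16 starts by default, fewer in the test suite's
simulation studies.  The finite-difference step for the Jacobian is 1e-3
in log space — large enough to sit above the ODE solver's noise floor,
which otherwise silently destroys the search direction.

Identifiability.  At the cohort-median parameter values the jejunal exit
constant K_TJ is close to structurally unidentifiable from this study
design: jejunal solids dissolve (at `K_Diss·(Cs − C)` ≈ several h⁻¹ at
jejunal pH) far faster than they transit (0.081 h⁻¹), so K_TJ perturbs all
observables at about the 1% level.  With 10% observation noise the
information bound puts the relative SD of any K_TJ estimator near 200%,
and the package's recovery study reproduces exactly that: all parameters
except K_TJ are recovered with median relative error well under 15%, K_TJ
is not.  The very large between-subject CV of published K_TJ estimates
points the same way.  Users should treat fitted K_TJ values as weakly
informed by data of this design.

Deviation metrics: absolute percentage deviation of Cmax, Tmax (first time
achieving the maximum) and trapezoid AUC, per region, evaluated on the
observation grid.

## NCA, Wagner–Nelson and IV disposition

NCA uses the linear trapezoid throughout (appropriate for monotone-rise /
short-tail profiles at this sampling density) and picks the terminal slope
by the best adjusted R² over the last 3–6 quantifiable points
(configurable).  Trailing below-quantification zeros are kept in the AUC
but excluded from the slope, and contribute no extrapolated tail.

Wagner–Nelson assumes one-compartment disposition.  Ibuprofen's IV
disposition is two-compartmental, so the deconvolved absorption profile
carries a known bias during the distribution phase; the method is used
regardless because the elimination constant it needs is available
model-free from NCA.  Output is clamped to [0, 1.05] with clamping logged.

The 1/2/3-compartment IV models are micro-constant parameterized
(K10, K12, K21, K13, K31, Vc; CL = K10·Vc) with a zero-order infusion over
the stated duration (6 min for the reference IV study, not a bolus).  The
solution is evaluated analytically by eigendecomposition of the rate
matrix.  Fits minimize unweighted SSR in log-parameter space from a small
seeded multi-start; models are compared by AIC = n·ln(SSR/n) + 2p and R².
Model selection is exercised on data with a small multiplicative error,
since with exactly noise-free data the SSR of nested models degenerates to
the numerical floor and the comparison is meaningless.

## ACAT-style transit simulator

Nine compartments — stomach, duodenum, jejunum 1–2, ileum 1–3, caecum,
ascending colon — each a continuous stirred tank with volume, pH and
transit time from its schedule.  A single-entry schedule is static; a
multi-entry schedule is read by step-hold interpolation (15-min
granularity by default, the ".cat" analog).  Both solid and dissolved
drug transit at 1/transit_time; drug exiting the ascending colon is
unabsorbed loss.  The gastric transit time is the scan knob of the
sensitivity analysis (default card: 0.25 h; phase-III-informed setting:
2.04 h).

Dissolution is Nernst–Brunner for shrinking monodisperse spheres:
`dM/dt = 3·D·M_solid/(ρ·r(t)·h_eff)·(Cs(pH) − C)` with h_eff = min(r,
30 µm) and the particle radius shrinking with the cube root of the total
remaining solid fraction (a global, not per-compartment, radius — a
simplification over particle-population tracking).  Defaults: r0 = 62 µm,
D = 7.5e-6 cm²/s (typical for a ~206 g/mol solute), true density
1.2 g/mL.  Absorption from dissolved drug at `k_abs = 2·Peff/R` with
Peff = 4.1e-4 cm/s and effective lumen radii (cm) duodenum 1.53,
jejunum 1.45/1.29, ileum 1.15/1.02/0.90, caecum 3.39, colon 2.41; the
stomach does not absorb.  Absorbed drug enters the central compartment of
the two-compartment disposition model; there is no first-pass loss (none
is observed for ibuprofen), so portal and systemic amounts coincide.

Key simplification: volume changes re-equilibrate concentration but do not
transport drug; only transit flows move mass.  Deliberately out of scope:
absorption scale factors, paracellular and transporter pathways,
stochastic fluid pockets, polydisperse particle size distributions.

Numerics: LSODA (rtol 1e-8, atol 1e-9) integrated segment-wise between
schedule breakpoints so no discontinuity is stepped across; output on a
0.01 h grid.  Mass balance holds at ~1e-14.  Cross-checks: a
non-dissolving tracer's mean small-intestinal residence reproduces the sum
of the six SI transit times (3.24 h) to <1%; with instant emptying,
dissolution and absorption the plasma curve converges to the closed-form
two-compartment bolus; AUC·CL equals the absorbed amount to <2%.

The static-vs-dynamic fluid comparison holds pH identical in both arms (it
overwrites the dynamic schedules' pH with the static card's values) so
that any difference is attributable to fluid volumes alone.

## Manometry and phase-III detection

Phase III of the MMC appears as regular high-amplitude contractions
(≈2–3/min at ~75 mmHg antral, 11–12/min at ~33 mmHg duodenal).  Sliding
windows (2 min, 30 s hop — settings are the package's; only the method
family is prescribed by the physiology) are scored by: the fraction of
mean-removed Welch-periodogram energy (50% overlapped segments) in the
9–12 cycles/min band, the log mean rectified amplitude, and the
contraction rate from prominence-thresholded peak detection (prominence
measures peak-to-trough, so burst amplitude is recovered independent of
baseline).  An L2-penalized logistic regression over these features scores
each window; above-threshold windows merge into intervals that must last
≥2 min (antral) or ≥3 min (duodenal).  Intervals are reported at window
centers — the unbiased onset attribution for a window detector, since a
window fires when roughly half of it covers the burst.  TMMC is the onset
of the first retained interval after dosing.  On the default synthetic
traces the detector recovers embedded onsets within one hop in ≥90% of
100 seeded trials.

## Synthetic cohort generator

The generator emulates the fasted-state aspiration study design: 800 mg
with 250 mL water; duodenal/jejunal sampling at 0, 0.25, 0.5, 0.75, 1,
1.5, 2, 2.5, 3, 4, 5, 6, 7 h; plasma at 0, 0.167, 0.33, 0.5, 0.75, 1,
1.5, 2, 2.5, 3, 4, 5, 6, 7, 8, 12, 28 h; optional repeat visits that
reuse a subject's rate constants but redraw TMMC, pH and noise.

Truth distributions are lognormal around the published cohort medians
(Kempt 0.18 h⁻¹, K_TD 0.47 h⁻¹, K_TJ 0.081 h⁻¹, K_Diss 1.52e-3 mL/(µg·h),
V1 123.24 mL, V2 49.99 mL) — medians rather than means because the
published CVs (up to ~360%) indicate heavy right tails — with a default
30% CV.  TMMC is lognormal with median 2.04 h (the observed average time
to phase III) and GSD 1.4.  Disposition defaults Kel 0.5 h⁻¹ and V3
8.1 L make Kel·V3 match the published 4.05 L/h clearance.

Luminal pH is a mean-reverting (Ornstein–Uhlenbeck) walk on a 5-min grid,
duodenum mean 6.0 clipped to [4.0, 7.0], jejunum mean 6.6 clipped to
[4.5, 7.5], reversion 1.5 h⁻¹ and volatility 2.0 — parameters chosen to
produce the strongly fluctuating, low-buffer-capacity pH the in vivo
aspirates show, with excursions that repeatedly cross the solubility
cliff around pH 5.  Real aspirate traces are not public, so these are
configuration defaults, flagged as such in the cohort manifest, not
claims about any subject.

Observations are truth × lognormal error (default CV 10%); values below
the assay's quantification limit (0.32 µg/mL, the reported linearity
floor) are recorded as zero.  Everything is deterministic per
(seed, subject index, occasion).

What passing tests on this generator do *not* show: recovery of media
effects on solubility, surface-pH dissolution physics, fluid pockets,
food effects, or inter-occasion covariance beyond the repeat-visit
resampling — none of which the generator emulates.

Dynamic compartment schedules stamp volume/pH every 15 min over 0–7 h
(29 entries), volumes lognormal around compartment means (duodenum
45 mL), pH normal around compartment means; the gastric transit time is
the subject's TMMC.  The published dynamic runs used schedule values that
were never tabulated, so those simulation outputs are emulated in shape,
not reproduced in number.

## Problem sizes used by the test battery

Simulation studies in the tests use 20 replicate subjects for parameter
recovery, 4 subjects × 2 model variants for the model-comparison
direction, 100 traces for phase-III detection, 200 random draws for state
non-negativity, and a dt = 1e-3 h RK4 oracle over 8 h — sizes at which
every stochastic check is stable under the fixed seeds while the whole
suite stays lightweight on a single CPU.
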