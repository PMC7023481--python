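# pbbm — mechanistic physiologically-based biopharmaceutics modeling of oral ibuprofen

`pbbm` is a Python pipeline for explaining and predicting the luminal and
systemic behavior of an orally dosed, rapidly permeating weak acid
(ibuprofen, 800 mg immediate-release, fasted state) from gastrointestinal
physiology: luminal pH, fluid volumes, gastric emptying and the migrating
motor complex (MMC).  It is aimed at biopharmaceutics and pharmacometrics
scientists who want a transparent, testable alternative to black-box
absorption simulators.

## What it does

* **pH-driven solubility** (`pbbm.physchem`).  Henderson–Hasselbalch for a
  monoprotic acid, `S(pH) = S0·(1 + 10^(pH − pKa))`, optionally capped by a
  *solubility factor* (max/intrinsic ratio), anchored to a measured
  reference point (1.99 mg/mL at pH 6.2 for ibuprofen, pKa 4.54).
* **Six-state gut/plasma models** (`pbbm.gis`).  Amounts of solid drug in
  stomach, duodenum and jejunum and dissolved drug in duodenum, jejunum and
  plasma.  The basic variant uses first-order gastric emptying and
  first-order dissolution; the extended variant adds (i) pH-dependent
  dissolution `K_Diss·M_solid·max(0, Cs(pH(t)) − C)` with the luminal pH
  re-read at every time point and (ii) a phase-III "house-keeper wave" that
  empties all remaining gastric solid into the duodenum at t = TMMC.
  Dissolved drug is absorbed where it stands (Ka fixed at 12 h⁻¹); only
  solids transit distally.
* **Simultaneous estimation** (`pbbm.estimation`).  Per-subject fits of
  {Kempt, K_TD, K_TJ, K_Diss, V1, V2} to duodenal, jejunal and plasma
  streams at once (bounded multi-start least squares in log space), cohort
  summary tables (mean/SD/CV%/median) and Cmax/Tmax/AUC deviation metrics.
* **NCA, deconvolution and IV disposition** (`pbbm.nca`).
  Non-compartmental analysis (linear trapezoid, best-adjusted-R² terminal
  slope), Wagner–Nelson fraction absorbed
  `Fabs(t) = (C + kel·AUC0–t)/(kel·AUC0–∞)`, and 1/2/3-compartment IV
  infusion fits compared by `AIC = n·ln(SSR/n) + 2p`.
* **ACAT-style transit simulator** (`pbbm.acat`).  Nine well-stirred GI
  compartments (stomach → ascending colon) with per-compartment volume, pH
  and transit time (static or 15-min dynamic ".cat"-style schedules),
  Nernst–Brunner dissolution of shrinking monodisperse spheres, absorption
  at `k_abs = 2·Peff/R`, two-compartment disposition, and a gastric-transit
  sensitivity scan.
* **MMC phase-III detection** (`pbbm.mmc`).  Spectral band-energy fraction
  in 9–12 cycles/min, contraction features, an L2-penalized logistic
  classifier, and interval/TMMC calling with per-region duration rules.
* **Virtual cohorts** (`pbbm.cohort`).  Seeded generator reproducing the
  study design: GI sampling 0–7 h, plasma to 28 h, fluctuating
  low-buffer-capacity intestinal pH (mean-reverting process), lognormal
  parameter and TMMC variability, proportional observation noise with a
  quantification limit, labeled synthetic manometry, and dynamic
  volume/pH schedules.

## Worked example

```python
import numpy as np
from pbbm import datasets
from pbbm.gis import GISParameters, SubjectPhysiology, simulate_gis
from pbbm.nca import nca

sol = datasets.ibuprofen_solubility()           # anchored at 1.99 mg/mL, pH 6.2
phys = SubjectPhysiology(tmmc_h=2.04,
                         ph_duodenum=[[0.0, 6.0]], ph_jejunum=[[0.0, 6.6]],
                         v1_ml=123.24, v2_ml=49.99, kel_per_h=0.5, v3_ml=8100.0)
params = GISParameters(kempt_per_h=0.18, k_td_per_h=0.47, k_tj_per_h=0.081,
                       k_diss_ml_per_ug_h=1.52e-3)
t = np.linspace(0.0, 28.0, 281)
traj = simulate_gis(params, phys, 8e5, t, "gisplus", sol)
res = nca(t, traj.c_plasma)
print(f"plasma Cmax  {res.cmax_ug_per_ml:.1f} ug/mL at Tmax {res.tmax_h:.1f} h")
print(f"AUC(0-inf)   {res.auc_0_inf_ug_h_per_ml:.0f} ug*h/mL")
print(f"mass balance {traj.mass_balance_error():.2e}")
```

prints

```
plasma Cmax  56.6 ug/mL at Tmax 3.1 h
AUC(0-inf)   197 ug*h/mL
mass balance 3.49e-15
```

i.e. for a median subject the 800 mg dose produces a plasma peak of
~57 µg/mL three hours post-dose — the peak forms shortly after the
phase-III wave at 2.04 h dumps the ~70% of the dose still in the stomach
into the duodenum, where pH 6 solubility (≈1.3 mg/mL vs 0.04 mg/mL
un-ionized) lets it dissolve and absorb rapidly — and the integrator
conserves mass to machine precision.

The same models are available from the shell:

```bash
pbbm synth --seed 1 --n-subjects 5 --out cohort/
pbbm fit --data cohort/concentrations.csv \
         --phys-scalars cohort/physiology_scalars.csv \
         --phys-ph cohort/physiology_ph.csv --out fits/
pbbm acat --out acat_run/          # default static card, 24 h
pbbm psa  --grid 0.25,0.5,1,2.04,4 --out psa.csv
```

## Layout

```
src/pbbm/        physchem, gis, estimation, nca, acat, mmc, cohort,
                 io, cli, datasets, reporting (+ packaged CSV/JSON cards)
tests/           pytest suite incl. property tests and oracle cross-checks
docs/methods.md  model assumptions, parameter choices, numerical notes
scripts/         acceptance.py
```
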