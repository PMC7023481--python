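"""Independent reference implementations used only to cross-check the
package: a fixed-step RK4 integrator for the six-state GI model, the
Bateman one-compartment oral solution, and the two-compartment bolus
solution.  These share no code with the implementations they verify."""

import numpy as np


def rk4_gis(params, phys, dose_ug, t_end_h, dt_h, variant, solubility):
    """Fixed-step RK4 for the GI chain; the phase-III bolus is applied at
    the step boundary nearest TMMC (choose TMMC a multiple of dt)."""

    kempt, ktd, ktj = params.kempt_per_h, params.k_td_per_h, params.k_tj_per_h
    ka, kel = params.ka_per_h, phys.kel_per_h
    v1, v2 = phys.v1_ml, phys.v2_ml

    def cs(series, t):
        ph = np.interp(t, series[:, 0], series[:, 1])
        s = solubility.s0_ug_per_ml * (1 + 10 ** (ph - solubility.pka))
        if solubility.cap is not None:
            s = min(s, solubility.s0_ug_per_ml * solubility.cap)
        return s

    def deriv(t, y):
        ms, mds, mdd, mjs, mjd, mp, elim, dist = y
        if variant == "gisplus":
            kd = params.k_diss_ml_per_ug_h
            r_d = kd * mds * max(0.0, cs(phys.ph_duodenum, t) - mdd / v1)
            r_j = kd * mjs * max(0.0, cs(phys.ph_jejunum, t) - mjd / v2)
        else:
            r_d = params.kd_simple_per_h * mds
            r_j = params.kd_simple_per_h * mjs
        return np.array([
            -kempt * ms,
            kempt * ms - ktd * mds - r_d,
            r_d - ka * mdd,
            ktd * mds - ktj * mjs - r_j,
            r_j - ka * mjd,
            ka * (mdd + mjd) - kel * mp,
            kel * mp,
            ktj * mjs,
        ])

    n = int(round(t_end_h / dt_h))
    times = np.arange(n + 1) * dt_h
    ys = np.empty((n + 1, 8))
    y = np.zeros(8)
    y[0] = dose_ug
    ys[0] = y
    i_event = int(round(phys.tmmc_h / dt_h)) if variant == "gisplus" else -1
    for i in range(n):
        t = times[i]
        if i == i_event:
            y = y.copy()
            y[1] += y[0]
            y[0] = 0.0
        k1 = deriv(t, y)
        k2 = deriv(t + dt_h / 2, y + dt_h / 2 * k1)
        k3 = deriv(t + dt_h / 2, y + dt_h / 2 * k2)
        k4 = deriv(t + dt_h, y + dt_h * k3)
        y = y + dt_h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        ys[i + 1] = y
    # reported state at the event time is post-bolus, matching the solver
    if variant == "gisplus" and 0 <= i_event <= n:
        ys[i_event, 1] += ys[i_event, 0]
        ys[i_event, 0] = 0.0
    return times, ys


def bateman_conc(dose, ka, kel, v, t):
    """One-compartment oral first-order absorption concentration."""
    t = np.asarray(t, float)
    return dose * ka / (v * (ka - kel)) * (np.exp(-kel * t) - np.exp(-ka * t))


def two_compartment_bolus_conc(dose, k10, k12, k21, vc, t):
    """Closed-form bi-exponential central concentration after an IV bolus."""
    t = np.asarray(t, float)
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4 * k10 * k21)
    alpha, beta = (s + disc) / 2, (s - disc) / 2
    a = dose / vc * (alpha - k21) / (alpha - beta)
    b = dose / vc * (k21 - beta) / (alpha - beta)
    return a * np.exp(-alpha * t) + b * np.exp(-beta * t)
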