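"""Six-state gastrointestinal simulation (GIS) models for one subject.

Two variants of a stomach-duodenum-jejunum-plasma mass-transport model for
an orally dosed, rapidly permeating weak acid (ibuprofen):

* ``"gis"`` -- the basic model: first-order gastric emptying, first-order
  dissolution in duodenum and jejunum (rate ``Kd_simple * M_solid``),
  first-order transit of *solid* drug, instant in-place absorption of
  dissolved drug (Ka fixed high), one-compartment disposition (Kel, V3).
* ``"gisplus"`` -- the same chain, but (a) gastric emptying is first order
  only until the first post-dose phase-III contraction at t = TMMC, when
  all remaining gastric solid is transferred to the duodenum as a bolus
  (the migrating-motor-complex "house-keeper wave"), and (b) dissolution
  is pH-driven: ``K_Diss * M_solid * max(0, Cs(pH(t)) - C_lumen)`` with the
  saturation solubility Cs re-evaluated at each time point from the
  subject's measured luminal pH series.

States (amounts, ug): solid drug in stomach, duodenum, jejunum; dissolved
drug in duodenum, jejunum; drug in plasma.  Two cumulative bookkeeping
states (eliminated drug, solid drug transited past the jejunum) close the
mass balance exactly.

Assumptions: no gastric dissolution or absorption (gastric pH is well below
the pKa), well-mixed lumen compartments, only solid particles transit
distally (dissolved drug is absorbed where it stands), no luminal
degradation, no re-precipitation on a pH drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .physchem import AcidSolubilityProfile, solubility_at_ph

__all__ = [
    "SubjectPhysiology",
    "GISParameters",
    "GISTrajectory",
    "GISIntegrationError",
    "ph_at",
    "dissolution_rate",
    "simulate_gis",
    "gastric_fraction_remaining",
]

#: order of the amount states in a trajectory
STATE_NAMES = (
    "m_stomach_solid",
    "m_duodenum_solid",
    "m_duodenum_dissolved",
    "m_jejunum_solid",
    "m_jejunum_dissolved",
    "m_plasma",
)


class GISIntegrationError(RuntimeError):
    """ODE integrator failure; carries the last valid state reached."""

    def __init__(self, message: str, t_last: float, y_last: np.ndarray):
        super().__init__(message)
        self.t_last = t_last
        self.y_last = y_last


@dataclass
class SubjectPhysiology:
    """Fixed per-subject physiology feeding the GIS models.

    ``ph_duodenum``/``ph_jejunum`` are (n, 2) arrays of (time h, pH),
    time-sorted.  ``tmmc_h`` is the time from dosing to the first post-dose
    phase-III contraction front.  ``kel_per_h`` and ``v3_ml`` are the
    one-compartment disposition constants (fixed from non-compartmental
    analysis, never fitted).
    """

    tmmc_h: float
    ph_duodenum: np.ndarray
    ph_jejunum: np.ndarray
    v1_ml: float
    v2_ml: float
    kel_per_h: float
    v3_ml: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.ph_duodenum = np.atleast_2d(np.asarray(self.ph_duodenum, dtype=float))
        self.ph_jejunum = np.atleast_2d(np.asarray(self.ph_jejunum, dtype=float))
        if self.tmmc_h < 0:
            raise ValueError("TMMC must be >= 0")
        for name, v in (("V1", self.v1_ml), ("V2", self.v2_ml), ("V3", self.v3_ml), ("Kel", self.kel_per_h)):
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for label, series in (("duodenum", self.ph_duodenum), ("jejunum", self.ph_jejunum)):
            if series.size == 0:
                raise ValueError(f"{label} pH series is empty")
            if series.shape[1] != 2:
                raise ValueError(f"{label} pH series must have shape (n, 2)")
            if np.any(np.diff(series[:, 0]) < 0):
                raise ValueError(f"{label} pH series must be time-sorted")
            if np.any((series[:, 1] <= 0) | (series[:, 1] >= 14)):
                raise ValueError(f"{label} pH values must lie in (0, 14)")


@dataclass
class GISParameters:
    """Rate constants of the GIS/GISPlus models.

    Exactly one of ``k_diss`` (second-order pH-driven coefficient,
    mL/(ug*h); "gisplus") or ``kd_simple`` (first-order coefficient, 1/h;
    basic "gis") is used, selected by the simulation variant.  ``ka`` is
    fixed high (default 12 1/h) because permeability is not rate limiting
    for ibuprofen.
    """

    kempt_per_h: float
    k_td_per_h: float
    k_tj_per_h: float
    k_diss_ml_per_ug_h: float | None = None
    kd_simple_per_h: float | None = None
    ka_per_h: float = 12.0

    def __post_init__(self) -> None:
        for name, v in (
            ("Kempt", self.kempt_per_h),
            ("K_TD", self.k_td_per_h),
            ("K_TJ", self.k_tj_per_h),
            ("K_Diss", self.k_diss_ml_per_ug_h),
            ("Kd_simple", self.kd_simple_per_h),
            ("Ka", self.ka_per_h),
        ):
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def rate_for_variant(self, variant: str) -> float:
        if variant == "gisplus":
            if self.k_diss_ml_per_ug_h is None:
                raise ValueError("gisplus variant requires k_diss_ml_per_ug_h")
            return self.k_diss_ml_per_ug_h
        if variant == "gis":
            if self.kd_simple_per_h is None:
                raise ValueError("gis variant requires kd_simple_per_h")
            return self.kd_simple_per_h
        raise ValueError(f"unknown variant {variant!r}")


@dataclass
class GISTrajectory:
    """Simulated amount trajectories plus derived concentrations."""

    time_h: np.ndarray
    amounts_ug: dict[str, np.ndarray]
    cumulative_eliminated_ug: np.ndarray
    cumulative_distal_transit_ug: np.ndarray
    dose_ug: float
    physiology: SubjectPhysiology
    variant: str
    parameters: GISParameters = field(repr=False, default=None)

    @property
    def c_duodenum(self) -> np.ndarray:
        return self.amounts_ug["m_duodenum_dissolved"] / self.physiology.v1_ml

    @property
    def c_jejunum(self) -> np.ndarray:
        return self.amounts_ug["m_jejunum_dissolved"] / self.physiology.v2_ml

    @property
    def c_plasma(self) -> np.ndarray:
        return self.amounts_ug["m_plasma"] / self.physiology.v3_ml

    def concentration(self, region: str) -> np.ndarray:
        return {"duodenum": self.c_duodenum, "jejunum": self.c_jejunum, "plasma": self.c_plasma}[region]

    def mass_balance_error(self) -> float:
        """Max relative deviation of total accounted mass from the dose."""
        total = (
            sum(self.amounts_ug[name] for name in STATE_NAMES)
            + self.cumulative_eliminated_ug
            + self.cumulative_distal_transit_ug
        )
        return float(np.max(np.abs(total - self.dose_ug)) / self.dose_ug)


def ph_at(series: np.ndarray, t) -> float | np.ndarray:
    """Interpolate a time-stamped pH series at time(s) ``t`` (hours).

    Piecewise linear between knots; constant extrapolation beyond the
    first/last knot.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.size == 0:
        raise ValueError("pH series is empty")
    out = np.interp(t, series[:, 0], series[:, 1])
    return float(out) if np.ndim(t) == 0 else out


def dissolution_rate(
    m_solid_ug: float,
    c_lumen_ug_per_ml: float,
    ph: float,
    k_diss_ml_per_ug_h: float,
    solubility: AcidSolubilityProfile,
) -> float:
    """pH-driven lumenal dissolution rate, ug/h.

    Bilinear in the remaining solid amount and the solubility-gap driving
    force, clamped at zero (undersaturation only; no re-precipitation):
    ``K_Diss * M_solid * max(0, Cs(pH) - C_lumen)``.
    """
    if m_solid_ug < 0 or c_lumen_ug_per_ml < 0:
        raise ValueError("amount and concentration must be >= 0")
    cs = solubility_at_ph(solubility, ph)
    return k_diss_ml_per_ug_h * m_solid_ug * max(0.0, cs - c_lumen_ug_per_ml)


def _make_rhs(params: GISParameters, phys: SubjectPhysiology, variant: str,
              solubility: AcidSolubilityProfile | None):
    kempt = params.kempt_per_h
    ktd = params.k_td_per_h
    ktj = params.k_tj_per_h
    ka = params.ka_per_h
    kel = phys.kel_per_h
    v1, v2 = phys.v1_ml, phys.v2_ml
    kdiss = params.rate_for_variant(variant)

    if variant == "gisplus":
        if solubility is None:
            raise ValueError("gisplus variant requires a solubility profile")
        # hoist pH-knot arrays and the Henderson-Hasselbalch constants out
        # of the hot loop; Cs(pH(t)) stays exact
        td, ph_d = phys.ph_duodenum[:, 0], phys.ph_duodenum[:, 1]
        tj, ph_j = phys.ph_jejunum[:, 0], phys.ph_jejunum[:, 1]
        s0, pka = solubility.s0_ug_per_ml, solubility.pka
        cs_max = s0 * solubility.cap if solubility.cap is not None else np.inf

        def rhs(t, y):
            ms, mds, mdd, mjs, mjd, mp, _elim, _dist = y
            cs_d = min(s0 * (1.0 + 10.0 ** (np.interp(t, td, ph_d) - pka)), cs_max)
            cs_j = min(s0 * (1.0 + 10.0 ** (np.interp(t, tj, ph_j) - pka)), cs_max)
            r_duo = kdiss * max(mds, 0.0) * max(0.0, cs_d - max(mdd, 0.0) / v1)
            r_jej = kdiss * max(mjs, 0.0) * max(0.0, cs_j - max(mjd, 0.0) / v2)
            return (
                -kempt * ms,
                kempt * ms - ktd * mds - r_duo,
                r_duo - ka * mdd,
                ktd * mds - ktj * mjs - r_jej,
                r_jej - ka * mjd,
                ka * (mdd + mjd) - kel * mp,
                kel * mp,
                ktj * mjs,
            )
    else:

        def rhs(t, y):
            ms, mds, mdd, mjs, mjd, mp, _elim, _dist = y
            r_duo = kdiss * max(mds, 0.0)
            r_jej = kdiss * max(mjs, 0.0)
            return (
                -kempt * ms,
                kempt * ms - ktd * mds - r_duo,
                r_duo - ka * mdd,
                ktd * mds - ktj * mjs - r_jej,
                r_jej - ka * mjd,
                ka * (mdd + mjd) - kel * mp,
                kel * mp,
                ktj * mjs,
            )

    return rhs


def _integrate(rhs, t0, t1, y0, t_eval, rtol, atol):
    """Integrate on [t0, t1]; return states at t_eval and the state at t1."""
    if t1 == t0:
        n = len(t_eval)
        return np.asarray(t_eval), np.tile(np.asarray(y0)[:, None], (1, n)), np.asarray(y0)
    t_all = np.append(np.asarray(t_eval, dtype=float), t1)  # t1 last; solver needs sorted
    t_all_sorted = np.unique(t_all)
    sol = solve_ivp(
        rhs, (t0, t1), y0, method="LSODA", t_eval=t_all_sorted, rtol=rtol, atol=atol,
    )
    if not sol.success:
        t_last = sol.t[-1] if sol.t.size else t0
        y_last = sol.y[:, -1] if sol.t.size else np.asarray(y0)
        raise GISIntegrationError(f"integrator failed: {sol.message}", t_last, y_last)
    idx = np.searchsorted(sol.t, np.asarray(t_eval, dtype=float))
    return np.asarray(t_eval), sol.y[:, idx], sol.y[:, -1]


def simulate_gis(
    params: GISParameters,
    phys: SubjectPhysiology,
    dose_ug: float,
    t_grid: np.ndarray,
    variant: str = "gisplus",
    solubility: AcidSolubilityProfile | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> GISTrajectory:
    """Integrate the six-state model over ``t_grid`` (hours, sorted, from 0).

    Under ``"gisplus"`` the phase-III gastric bolus at t = TMMC is handled
    as an event: the integration stops at TMMC, the remaining gastric solid
    is moved to the duodenal solid pool, and integration restarts -- the
    discontinuity is never integrated across.  Output times at t >= TMMC
    report the post-event state.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if np.any(np.diff(t_grid) < 0) or t_grid[0] != 0.0:
        raise ValueError("t_grid must be sorted and start at 0")
    if not dose_ug > 0:
        raise ValueError("dose must be positive")
    if variant not in ("gis", "gisplus"):
        raise ValueError(f"unknown variant {variant!r}")

    rhs = _make_rhs(params, phys, variant, solubility)
    y0 = np.zeros(8)
    y0[0] = dose_ug
    t_end = t_grid[-1]
    tmmc = phys.tmmc_h

    out = np.empty((8, t_grid.size))
    if variant == "gisplus" and 0.0 < tmmc < t_end:
        pre_mask = t_grid < tmmc
        t_pre = t_grid[pre_mask]
        _, y_pre, y_at = _integrate(rhs, 0.0, tmmc, y0, t_pre, rtol, atol)
        out[:, pre_mask] = y_pre
        # phase-III bolus: all remaining gastric solid to the duodenum
        y_at = y_at.copy()
        y_at[1] += y_at[0]
        y_at[0] = 0.0
        t_post = t_grid[~pre_mask]
        _, y_post, _ = _integrate(rhs, tmmc, t_end, y_at, t_post, rtol, atol)
        out[:, ~pre_mask] = y_post
    elif variant == "gisplus" and tmmc == 0.0:
        y0[1] = y0[0]
        y0[0] = 0.0
        _, out[:], _ = _integrate(rhs, 0.0, t_end, y0, t_grid, rtol, atol)
    else:
        _, out[:], _ = _integrate(rhs, 0.0, t_end, y0, t_grid, rtol, atol)

    # guard against integrator-scale negative undershoot
    out[out < 0] = 0.0

    amounts = {name: out[i] for i, name in enumerate(STATE_NAMES)}
    return GISTrajectory(
        time_h=t_grid,
        amounts_ug=amounts,
        cumulative_eliminated_ug=out[6],
        cumulative_distal_transit_ug=out[7],
        dose_ug=dose_ug,
        physiology=phys,
        variant=variant,
        parameters=params,
    )


def gastric_fraction_remaining(
    params: GISParameters,
    phys: SubjectPhysiology,
    t_grid: np.ndarray,
    variant: str = "gisplus",
) -> np.ndarray:
    """Fraction of the dose still in the stomach at each grid time.

    The gastric pool is decoupled from the rest of the chain, so the
    closed form is used directly: ``exp(-Kempt*t)``, set to 0 from TMMC
    onward under the "gisplus" variant (the phase-III wave empties the
    stomach completely).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    frac = np.exp(-params.kempt_per_h * t_grid)
    if variant == "gisplus":
        frac = np.where(t_grid >= phys.tmmc_h, 0.0, frac)
    return frac
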