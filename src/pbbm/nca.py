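"""Non-compartmental analysis, Wagner-Nelson deconvolution, and
mammillary (1/2/3-compartment) IV pharmacokinetic fitting.

NCA uses the linear trapezoid throughout (profiles here rise monotonically
and have short tails at the study's sampling density) with the terminal
slope lambda_z chosen by the best adjusted log-linear fit over the last
3..6 positive samples.  Wagner-Nelson assumes one-compartment disposition:

    Fabs(t) = (C(t) + kel * AUC_0..t) / (kel * AUC_0..inf)

a deliberate, documented bias for a drug whose IV disposition is actually
two-compartmental.  Mammillary IV models are fitted to constant-rate
infusion data by least squares in log-parameter space, compared by
AIC = n*ln(SSR/n) + 2*p and R^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "NCAResult",
    "MammillaryPK",
    "nca",
    "auc_trapezoid",
    "wagner_nelson",
    "absorption_rate",
    "infusion_concentration",
    "fit_mammillary_iv",
]


@dataclass
class NCAResult:
    cmax_ug_per_ml: float
    tmax_h: float
    auc_0_t_ug_h_per_ml: float
    lambda_z_per_h: float | None
    auc_0_inf_ug_h_per_ml: float | None
    n_points_lambda_z: int
    lambda_z_r2adj: float | None = None


@dataclass
class MammillaryPK:
    """Micro-constant parameterization of a 1/2/3-compartment IV model.

    Central volume ``vc_ml`` converts amounts to concentration; clearance
    is the identity CL = K10 * Vc.
    """

    n_compartments: int
    k10_per_h: float
    vc_ml: float
    k12_per_h: float | None = None
    k21_per_h: float | None = None
    k13_per_h: float | None = None
    k31_per_h: float | None = None

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2, 3):
            raise ValueError("n_compartments must be 1, 2 or 3")
        if not (self.k10_per_h > 0 and self.vc_ml > 0):
            raise ValueError("K10 and Vc must be positive")
        if self.n_compartments >= 2 and not (self.k12_per_h > 0 and self.k21_per_h > 0):
            raise ValueError("2/3-compartment models need positive K12, K21")
        if self.n_compartments == 3 and not (self.k13_per_h > 0 and self.k31_per_h > 0):
            raise ValueError("3-compartment models need positive K13, K31")

    @property
    def cl_ml_per_h(self) -> float:
        return self.k10_per_h * self.vc_ml

    def rate_matrix(self) -> np.ndarray:
        """First-order rate matrix A with dA_amounts/dt = A @ amounts."""
        n = self.n_compartments
        a = np.zeros((n, n))
        a[0, 0] = -self.k10_per_h
        if n >= 2:
            a[0, 0] -= self.k12_per_h
            a[0, 1] = self.k21_per_h
            a[1, 0] = self.k12_per_h
            a[1, 1] = -self.k21_per_h
        if n == 3:
            a[0, 0] -= self.k13_per_h
            a[0, 2] = self.k31_per_h
            a[2, 0] = self.k13_per_h
            a[2, 2] = -self.k31_per_h
        return a


def auc_trapezoid(time_h: np.ndarray, conc: np.ndarray) -> float:
    """Linear-trapezoid area under the curve."""
    return float(np.trapezoid(np.asarray(conc, float), np.asarray(time_h, float)))


def _cumulative_auc(time_h: np.ndarray, conc: np.ndarray) -> np.ndarray:
    t = np.asarray(time_h, float)
    c = np.asarray(conc, float)
    seg = 0.5 * (c[1:] + c[:-1]) * np.diff(t)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _fit_lambda_z(time_h, conc, candidates=(3, 4, 5, 6)):
    """Log-linear terminal regression; best adjusted-R^2 over the last
    3..6 points with positive concentrations (the Tmax point excluded
    when possible)."""
    t = np.asarray(time_h, float)
    c = np.asarray(conc, float)
    pos = c > 0
    t_pos, c_pos = t[pos], c[pos]
    best = None
    for k in candidates:
        if k > t_pos.size:
            continue
        tt, cc = t_pos[-k:], np.log(c_pos[-k:])
        if np.ptp(tt) == 0:
            continue
        slope, intercept = np.polyfit(tt, cc, 1)
        if slope >= 0:
            continue
        resid = cc - (slope * tt + intercept)
        sst = np.sum((cc - cc.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 0.0
        r2adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        if best is None or r2adj > best[2]:
            best = (-slope, k, r2adj)
    return best  # (lambda_z, n_points, r2adj) or None


def nca(time_h, conc, dose_ug: float | None = None) -> NCAResult:
    """Non-compartmental analysis of a single concentration-time profile.

    Requires at least three samples.  If the terminal slope cannot be
    estimated (e.g. non-positive terminal concentrations), lambda_z and
    the extrapolated AUC are reported as ``None``.
    """
    t = np.asarray(time_h, float)
    c = np.asarray(conc, float)
    if t.size < 3:
        raise ValueError("NCA needs at least 3 samples")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted")
    i_max = int(np.argmax(c))  # first time achieving the max
    auc_t = auc_trapezoid(t, c)
    # lambda_z uses the positive (quantifiable) samples only; trailing
    # below-quantification zeros carry no extrapolatable tail
    fit = _fit_lambda_z(t, c)
    if fit is None:
        logger.warning("lambda_z unestimable; AUC extrapolation skipped")
        lam, npts, r2adj, auc_inf = None, 0, None, None
    else:
        lam, npts, r2adj = fit
        auc_inf = auc_t + c[-1] / lam
    return NCAResult(
        cmax_ug_per_ml=float(c[i_max]),
        tmax_h=float(t[i_max]),
        auc_0_t_ug_h_per_ml=auc_t,
        lambda_z_per_h=lam,
        auc_0_inf_ug_h_per_ml=auc_inf,
        n_points_lambda_z=npts,
        lambda_z_r2adj=r2adj,
    )


def wagner_nelson(time_h, conc, kel_per_h: float, auc_0_inf: float | None = None) -> np.ndarray:
    """Fraction-absorbed series by Wagner-Nelson deconvolution.

    ``kel_per_h`` is the subject's terminal elimination rate (typically the
    NCA lambda_z).  The output is clamped to [0, 1.05]; clamping is logged.
    """
    if not kel_per_h > 0:
        raise ValueError("kel must be positive")
    t = np.asarray(time_h, float)
    c = np.asarray(conc, float)
    auc_cum = _cumulative_auc(t, c)
    if auc_0_inf is None:
        res = nca(t, c)
        if res.auc_0_inf_ug_h_per_ml is None:
            raise ValueError("AUC_0_inf unestimable; pass auc_0_inf explicitly")
        auc_0_inf = res.auc_0_inf_ug_h_per_ml
    fabs = (c + kel_per_h * auc_cum) / (kel_per_h * auc_0_inf)
    if np.any(fabs < 0) or np.any(fabs > 1.05):
        logger.warning(
            "Wagner-Nelson output clamped to [0, 1.05] at %d point(s)",
            int(np.sum((fabs < 0) | (fabs > 1.05))),
        )
    return np.clip(fabs, 0.0, 1.05)


def absorption_rate(time_h, fabs, dose_ug: float) -> np.ndarray:
    """Absorption rate (ug/h) as the time derivative of dose * Fabs.

    Central finite differences in the interior; one-sided at endpoints.
    """
    t = np.asarray(time_h, float)
    return np.gradient(dose_ug * np.asarray(fabs, float), t)


def infusion_concentration(pk: MammillaryPK, dose_ug: float, infusion_h: float, time_h) -> np.ndarray:
    """Central-compartment concentration for a zero-order IV infusion.

    Analytic solution via eigendecomposition of the rate matrix: during
    the infusion A(t) = A_inv (e^{Kt} - I) b with b the infusion-rate
    vector; afterwards the homogeneous propagator e^{K(t-T)} applies.
    """
    if not infusion_h > 0:
        raise ValueError("infusion duration must be positive")
    t = np.atleast_1d(np.asarray(time_h, float))
    k = pk.rate_matrix()
    n = k.shape[0]
    rate = dose_ug / infusion_h
    b = np.zeros(n)
    b[0] = rate
    w, v = np.linalg.eig(k)
    v_inv = np.linalg.inv(v)
    kb = np.linalg.solve(k, b)  # K^{-1} b

    def state(tau_on: np.ndarray) -> np.ndarray:
        # amounts during infusion at times tau_on (>=0)
        e = np.exp(np.outer(w, tau_on))  # (n, m)
        return np.real(v @ (e * (v_inv @ kb)[:, None])) - kb[:, None]

    y_end = state(np.array([infusion_h]))[:, 0]
    out = np.empty((n, t.size))
    on = t <= infusion_h
    out[:, on] = state(np.clip(t[on], 0.0, None))
    if np.any(~on):
        tau = t[~on] - infusion_h
        e = np.exp(np.outer(w, tau))
        out[:, ~on] = np.real(v @ (e * (v_inv @ y_end)[:, None]))
    conc = out[0] / pk.vc_ml
    return conc if np.ndim(time_h) else float(conc[0])


_N_PARAMS = {1: 2, 2: 4, 3: 6}


def fit_mammillary_iv(
    time_h,
    conc,
    dose_ug: float,
    infusion_h: float,
    n_compartments: int,
    n_starts: int = 5,
    seed: int = 0,
) -> tuple[MammillaryPK, dict]:
    """Least-squares fit of the infusion solution to observed IV data.

    Returns the fitted model and ``{"aic", "r2", "ssr"}`` where
    AIC = n_obs * ln(SSR/n_obs) + 2 * n_params.
    """
    t = np.asarray(time_h, float)
    c = np.asarray(conc, float)
    p = _N_PARAMS[n_compartments]
    if t.size <= p:
        raise ValueError("need more observations than parameters")

    # heuristic starting point: terminal slope for k10, back-extrapolated C0 for vc
    fit0 = _fit_lambda_z(t, c)
    lam0 = fit0[0] if fit0 else 0.5
    vc0 = dose_ug / max(c.max(), 1e-12)

    def build(x):
        k = np.exp(x)
        kw = dict(n_compartments=n_compartments, k10_per_h=k[0], vc_ml=k[1])
        if n_compartments >= 2:
            kw.update(k12_per_h=k[2], k21_per_h=k[3])
        if n_compartments == 3:
            kw.update(k13_per_h=k[4], k31_per_h=k[5])
        return MammillaryPK(**kw)

    def resid(x):
        try:
            pred = infusion_concentration(build(x), dose_ug, infusion_h, t)
        except (np.linalg.LinAlgError, ValueError):
            return np.full(t.size, 1e6)
        return pred - c

    x0 = np.log(np.array([lam0, vc0, 1.0, 1.0, 0.5, 0.5][:p]))
    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + rng.uniform(-1.5, 1.5, p) for _ in range(n_starts - 1)]
    lo, hi = np.log(1e-4), np.log(1e9)
    best = None
    for s in starts:
        sol = least_squares(resid, np.clip(s, lo + 1, hi - 1), bounds=(lo, hi))
        ssr = float(2 * sol.cost)
        if best is None or ssr < best[1]:
            best = (sol.x, ssr)
    x_best, ssr = best
    n_obs = t.size
    aic = n_obs * math.log(max(ssr, 1e-300) / n_obs) + 2 * p
    sst = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
    return build(x_best), {"aic": aic, "r2": r2, "ssr": ssr}
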