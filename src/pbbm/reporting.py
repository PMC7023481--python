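"""Summary tables and figures for fitted cohorts and simulations.

Tables mirror the published layouts (per-subject parameter table with
Average/SD/CV%/Median rows; per-region deviation table; plasma PK summary);
figures cover concentration-time overlays, gastric-emptying kinetics,
solubility vs pH, fraction absorbed, and the gastric-transit sensitivity
curve.  Matplotlib is imported lazily so headless table-only use never
touches a display backend.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import summarize_parameters

PARAMETER_COLUMNS = ["kempt_per_h", "k_td_per_h", "k_tj_per_h",
                     "k_diss_ml_per_ug_h", "v1_ml", "v2_ml"]

__all__ = ["parameter_summary_table", "deviation_table", "plot_concentrations",
           "plot_solubility_curve", "plot_psa_curve"]


def parameter_summary_table(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Per-subject parameters with Average/SD/CV%/Median summary rows.

    Column order follows the published parameter table (Kempt, K_TD,
    K_TJ, K_Diss, V1, V2); subjects are sorted by id for deterministic
    output.  An empty input yields headers only.
    """
    cols = [c for c in PARAMETER_COLUMNS if c in per_subject.columns]
    if per_subject.empty:
        return pd.DataFrame(columns=cols)
    body = per_subject.set_index("subject")[cols].sort_index() \
        if "subject" in per_subject.columns else per_subject[cols]
    stats = summarize_parameters(body)
    head = pd.DataFrame(
        [stats.loc["mean"], stats.loc["sd"], stats.loc["cv_pct"]],
        index=["Average", "SD", "CV%"],
    )[cols]
    tail = pd.DataFrame([stats.loc["median"]], index=["Median"])[cols]
    return pd.concat([head, body, tail])


def deviation_table(per_subject_devs: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Average the per-subject deviation tables into one per-region,
    per-variant comparison (rows: region x metric, columns: variant)."""
    out = {}
    for variant, frames in per_subject_devs.items():
        acc = sum(frames) / len(frames) if isinstance(frames, list) else frames
        out[variant] = acc.stack()
    return pd.DataFrame(out)


def plot_concentrations(ax, time_h, observed, predicted=None, region: str = ""):
    ax.plot(time_h, observed, "ko", ms=4, label="observed")
    if predicted is not None:
        ax.plot(time_h, predicted, "r-", label="model")
    ax.set_xlabel("time (h)")
    ax.set_ylabel(f"{region} concentration (ug/mL)")
    ax.legend(frameon=False)
    return ax


def plot_solubility_curve(ax, profile, measured: pd.DataFrame | None = None,
                          ph_range=(1.0, 8.0)):
    from .physchem import solubility_at_ph

    ph = np.linspace(*ph_range, 200)
    ax.semilogy(ph, solubility_at_ph(profile, ph) / 1000.0, "g-", label="model")
    if measured is not None:
        ax.semilogy(measured["ph"], measured["solubility_mg_per_ml"], "bo",
                    label="measured fluids")
    ax.set_xlabel("pH")
    ax.set_ylabel("solubility (mg/mL)")
    ax.legend(frameon=False)
    return ax


def plot_psa_curve(ax, psa: pd.DataFrame):
    ax.plot(psa["gastric_transit_h"], psa["cmax_ug_per_ml"], "o-")
    ax.set_xlabel("gastric transit time (h)")
    ax.set_ylabel("plasma Cmax (ug/mL)")
    return ax
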