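"""Packaged reference datasets: published ibuprofen parameter tables.

Small text fixtures shipped with the package -- the fitted per-subject
GIS-Plus parameter table from the fasted-state aspiration study, the
default compartmental-absorption-and-transit (ACAT-style) volume/pH/transit
card, the ibuprofen drug card (physicochemical, biopharmaceutic and
two-compartment IV disposition constants), measured fluid solubilities, and
the observed plasma PK summary used for validation overlays.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .acat import ACATDrug, CompartmentSchedule
from .nca import MammillaryPK
from .physchem import AcidSolubilityProfile, anchor_intrinsic_solubility

__all__ = [
    "gisplus_subject_parameters",
    "ibuprofen_card",
    "ibuprofen_solubility",
    "ibuprofen_drug",
    "ibuprofen_iv_pk",
    "acat_default_schedules",
    "measured_fluid_solubility",
    "observed_plasma_pk",
]


def _data(name: str):
    return resources.files("pbbm.data").joinpath(name)


def gisplus_subject_parameters() -> pd.DataFrame:
    """Per-subject fitted GIS-Plus parameters (19 study occasions)."""
    with _data("gisplus_subject_parameters.csv").open() as fh:
        return pd.read_csv(fh)


def ibuprofen_card() -> dict:
    """Raw ibuprofen drug card as a dict."""
    with _data("ibuprofen.json").open() as fh:
        return json.load(fh)


def ibuprofen_solubility(cap: float | None = None) -> AcidSolubilityProfile:
    """Solubility profile anchored at the reference measurement
    (1.99 mg/mL at pH 6.2, acidic pKa 4.54)."""
    card = ibuprofen_card()
    return anchor_intrinsic_solubility(
        s_ref_ug_per_ml=card["reference_solubility_mg_per_ml"] * 1000.0,
        ph_ref=card["reference_ph"],
        pka=card["pka_acidic"],
        cap=cap,
    )


def ibuprofen_drug() -> ACATDrug:
    """ACAT drug card for an 800 mg ibuprofen immediate-release dose."""
    card = ibuprofen_card()
    return ACATDrug(
        dose_ug=card["dose_mg"] * 1000.0,
        peff_cm_per_s=card["peff_cm_per_s"],
        particle_radius_um=card["particle_radius_um"],
        density_g_per_ml=card["acat_defaults"]["true_density_g_per_ml"],
        diffusion_coeff_cm2_per_s=card["acat_defaults"]["diffusion_coeff_cm2_per_s"],
        solubility=ibuprofen_solubility(),
    )


def ibuprofen_iv_pk() -> MammillaryPK:
    """Two-compartment IV disposition constants (Vc = CL / K10)."""
    pk = ibuprofen_card()["two_compartment_pk"]
    vc_ml = pk["clearance_l_per_h"] * 1000.0 / pk["k10_per_h"]
    return MammillaryPK(
        n_compartments=2,
        k10_per_h=pk["k10_per_h"],
        k12_per_h=pk["k12_per_h"],
        k21_per_h=pk["k21_per_h"],
        vc_ml=vc_ml,
    )


def acat_default_schedules() -> dict[str, CompartmentSchedule]:
    """Static default volume/pH/transit card of the nine-compartment model."""
    with _data("acat_default_schedule.csv").open() as fh:
        df = pd.read_csv(fh)
    out = {}
    for name, grp in df.groupby("compartment", sort=False):
        out[name] = CompartmentSchedule(
            name=name,
            times_h=grp["time_h"].to_numpy(),
            volumes_ml=grp["volume_ml"].to_numpy(),
            phs=grp["ph"].to_numpy(),
            transit_time_h=float(grp["transit_time_h"].iloc[0]),
        )
    return out


def measured_fluid_solubility() -> pd.DataFrame:
    """Shake-flask ibuprofen solubility in aspirated human GI fluids.

    Real-fluid media effects make these deviate from the ideal
    Henderson-Hasselbalch curve; shipped for plotting/validation overlays,
    never forced onto the model curve.
    """
    with _data("measured_fluid_solubility.csv").open() as fh:
        return pd.read_csv(fh)


def observed_plasma_pk() -> pd.Series:
    """Observed plasma PK summary of the 800 mg fasted-state study
    (reference values for comparison; the raw profiles are not public)."""
    with _data("observed_plasma_pk.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("parameter")["observed"]
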