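"""pH-dependent solubility of a monoprotic weak acid.

For an ionizable acid the total aqueous solubility rises with pH as the
ionized fraction grows (Henderson-Hasselbalch):

    S(pH) = S0 * (1 + 10**(pH - pKa))

where ``S0`` is the intrinsic (un-ionized) solubility.  An optional
*solubility factor* cap -- the ratio of maximum to intrinsic solubility --
limits the curve at high pH, emulating predicted solubility profiles that
level off instead of growing without bound.

This profile is the thermodynamic driving force used by every dissolution
model in the package (lumen ODE models and the compartmental absorption
and transit simulator alike).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["AcidSolubilityProfile", "solubility_at_ph", "anchor_intrinsic_solubility"]


@dataclass(frozen=True)
class AcidSolubilityProfile:
    """Monoprotic-acid solubility curve.

    Parameters
    ----------
    s0_ug_per_ml
        Intrinsic (fully un-ionized) solubility, ug/mL.  Must be positive.
    pka
        Acidic pKa, in (0, 14).
    cap
        Optional solubility factor (max/intrinsic ratio, >= 1).  ``None``
        means the Henderson-Hasselbalch curve is uncapped.
    reference_ph, reference_solubility_ug_per_ml
        Optional provenance: the measured anchor point the profile was
        derived from (not used in evaluation).
    """

    s0_ug_per_ml: float
    pka: float
    cap: float | None = None
    reference_ph: float | None = None
    reference_solubility_ug_per_ml: float | None = None

    def __post_init__(self) -> None:
        if not (self.s0_ug_per_ml > 0 and math.isfinite(self.s0_ug_per_ml)):
            raise ValueError(f"intrinsic solubility must be positive, got {self.s0_ug_per_ml}")
        if not (0.0 < self.pka < 14.0):
            raise ValueError(f"pKa must lie in (0, 14), got {self.pka}")
        if self.cap is not None and not self.cap >= 1.0:
            raise ValueError(f"solubility factor cap must be >= 1, got {self.cap}")

    def solubility(self, ph):
        """Alias for :func:`solubility_at_ph` as a method."""
        return solubility_at_ph(self, ph)


def solubility_at_ph(profile: AcidSolubilityProfile, ph):
    """Total solubility (ug/mL) of the acid at the given bulk pH.

    Accepts a scalar or array pH; non-finite values are rejected.  The
    result is non-decreasing in pH and, when a cap is present, bounded by
    ``S0 * cap``.
    """
    ph_arr = np.asarray(ph, dtype=float)
    if not np.all(np.isfinite(ph_arr)):
        raise ValueError("pH must be finite")
    s = profile.s0_ug_per_ml * (1.0 + 10.0 ** (ph_arr - profile.pka))
    if profile.cap is not None:
        s = np.minimum(s, profile.s0_ug_per_ml * profile.cap)
    return float(s) if np.isscalar(ph) or ph_arr.ndim == 0 else s


def anchor_intrinsic_solubility(
    s_ref_ug_per_ml: float,
    ph_ref: float,
    pka: float,
    cap: float | None = None,
) -> AcidSolubilityProfile:
    """Recover the intrinsic solubility from one measured (pH, S) point.

    Inverts the Henderson-Hasselbalch relation,
    ``S0 = S_ref / (1 + 10**(pH_ref - pKa))``, so that evaluating the
    returned profile at ``ph_ref`` reproduces ``s_ref_ug_per_ml`` exactly
    (when the cap is not binding there).
    """
    if not (s_ref_ug_per_ml > 0 and math.isfinite(s_ref_ug_per_ml)):
        raise ValueError(f"reference solubility must be positive, got {s_ref_ug_per_ml}")
    if not math.isfinite(ph_ref):
        raise ValueError("reference pH must be finite")
    s0 = s_ref_ug_per_ml / (1.0 + 10.0 ** (ph_ref - pka))
    return AcidSolubilityProfile(
        s0_ug_per_ml=s0,
        pka=pka,
        cap=cap,
        reference_ph=ph_ref,
        reference_solubility_ug_per_ml=s_ref_ug_per_ml,
    )
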