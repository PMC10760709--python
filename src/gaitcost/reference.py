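"""Reference cost coefficients.

``STEADY_COEFFS`` holds the steady-rate coefficients (a0, a1, a2) per
population group, drawn from treadmill indirect-calorimetry literature
(W/kg with speed in m/s).  ``INVERSE_OPT_V1`` and ``INVERSE_OPT_V2`` hold
the changing-speed and turning coefficients estimated by inverse
optimization from preferred-speed data in unilateral Jaipur-foot prosthesis
users, plus the prior estimates for adults without amputation.  Version 1
keeps the literature a2 fixed; version 2 refits a2 together with a_change
and a_turn.

These tables serve as fixed inputs: defaults for the synthetic cohort
generator and fixed coefficients in the inverse optimization.  The
no-amputation row is a literature reference, never refit here.
"""

from __future__ import annotations

from .cost import CostCoefficients

__all__ = ["STEADY_COEFFS", "INVERSE_OPT_V1", "INVERSE_OPT_V2", "coefficients"]

#: steady-rate quadratic coefficients (a0, a1, a2) per group, W/kg units
STEADY_COEFFS: dict[str, tuple[float, float, float]] = {
    "above_knee": (4.97, -5.98, 5.62),
    "below_knee": (3.64, -2.19, 2.89),
    "none": (2.22, 0.0, 1.115),
}

#: inverse-optimization estimates, literature a2 held fixed: (a_change, a_turn)
INVERSE_OPT_V1: dict[str, tuple[float, float]] = {
    "above_knee": (2.67, 7.71),
    "below_knee": (2.65, 6.64),
    "none": (1.34, 1.11),
}

#: inverse-optimization estimates with a2 refit: (a2, a_change, a_turn)
INVERSE_OPT_V2: dict[str, tuple[float, float, float]] = {
    "above_knee": (6.12, 1.84, 6.53),
    "below_knee": (3.66, 1.41, 4.26),
    "none": (1.19, 1.30, 1.04),
}


def coefficients(group: str, version: int | None = 1) -> CostCoefficients:
    """Assemble a full :class:`CostCoefficients` for a group.

    Parameters
    ----------
    group :
        ``"above_knee"``, ``"below_knee"`` or ``"none"``.
    version :
        1 -> literature a2 with version-1 (a_change, a_turn);
        2 -> refit (a2, a_change, a_turn);
        None -> steady coefficients only (a_change = a_turn = 0).
    """
    a0, a1, a2 = STEADY_COEFFS[group]
    if version is None:
        return CostCoefficients(a0, a1, a2, 0.0, 0.0, group)
    if version == 1:
        a_change, a_turn = INVERSE_OPT_V1[group]
        return CostCoefficients(a0, a1, a2, a_change, a_turn, group)
    if version == 2:
        a2f, a_change, a_turn = INVERSE_OPT_V2[group]
        return CostCoefficients(a0, a1, a2f, a_change, a_turn, group)
    raise ValueError(f"version must be 1, 2 or None, got {version!r}")
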