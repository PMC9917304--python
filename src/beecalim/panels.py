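"""Stimulus panels.

The standard aliphatic panel crosses 4 functional groups (primary and
secondary alcohols, aldehydes, ketones) with 4 carbon chain lengths
(C6-C9), plus an unscented air control: 16 odorants, 120 unordered odor
pairs.

Vapor pressures (mmHg, ~25 C) are compiled from standard physico-chemical
reference tables; they are literature values, not measurements from any
single experiment, and can be overridden per stimulus when constructing a
custom panel.
"""

from __future__ import annotations

from .types import OdorPanel, OdorStimulus, ValidationError

# (name, functional_group, chain_length, vapor_pressure mmHg at ~25 C)
ALIPHATIC_ODORANTS = [
    ("1-hexanol", "primary_alcohol", 6, 0.95),
    ("1-heptanol", "primary_alcohol", 7, 0.22),
    ("1-octanol", "primary_alcohol", 8, 0.079),
    ("1-nonanol", "primary_alcohol", 9, 0.023),
    ("2-hexanol", "secondary_alcohol", 6, 3.2),
    ("2-heptanol", "secondary_alcohol", 7, 0.99),
    ("2-octanol", "secondary_alcohol", 8, 0.27),
    ("2-nonanol", "secondary_alcohol", 9, 0.092),
    ("hexanal", "aldehyde", 6, 11.3),
    ("heptanal", "aldehyde", 7, 3.5),
    ("octanal", "aldehyde", 8, 1.2),
    ("nonanal", "aldehyde", 9, 0.37),
    ("2-hexanone", "ketone", 6, 11.6),
    ("2-heptanone", "ketone", 7, 3.9),
    ("2-octanone", "ketone", 8, 1.4),
    ("2-nonanone", "ketone", 9, 0.62),
]

AIR_CONTROL = "air"


def aliphatic_panel(include_control: bool = True) -> OdorPanel:
    """The 16-odorant aliphatic panel (4 groups x C6-C9), plus air control."""
    stimuli = [
        OdorStimulus(name, group, chain, vp)
        for name, group, chain, vp in ALIPHATIC_ODORANTS
    ]
    if include_control:
        stimuli.append(OdorStimulus(AIR_CONTROL, "control", is_control=True))
    panel = OdorPanel(stimuli, panel_name="aliphatic")
    validate_aliphatic(panel)
    return panel


def validate_aliphatic(panel: OdorPanel) -> None:
    """Check the 4 x 4 group-by-chain structure of an aliphatic panel."""
    odorants = panel.odorants
    if len(odorants) != 16:
        raise ValidationError(
            f"aliphatic panel needs 16 odorants, got {len(odorants)}"
        )
    cells = {(s.functional_group, s.chain_length) for s in odorants}
    if len(cells) != 16:
        raise ValidationError("aliphatic panel must cover 4 groups x 4 chain lengths")
    if any(s.chain_length is None for s in odorants):
        raise ValidationError("every aliphatic odorant needs a chain length")


def mb_panel() -> OdorPanel:
    """Reduced high-activity panel used for mushroom-body recordings."""
    keep = {"1-hexanol", "2-hexanone", "2-heptanone", "heptanal", "octanal"}
    stimuli = [
        OdorStimulus(name, group, chain, vp)
        for name, group, chain, vp in ALIPHATIC_ODORANTS
        if name in keep
    ]
    stimuli.append(OdorStimulus(AIR_CONTROL, "control", is_control=True))
    return OdorPanel(stimuli, panel_name="mb_reduced")
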