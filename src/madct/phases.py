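"""Cardiac phase labels used throughout the annular-dynamics analysis.

Multiphase cardiac CT is reconstructed into 20 frames at 5% R-R increments;
the analysis works on six named phases annotated upstream:

* ``MD`` mid-diastole (onset of diastasis)
* ``LD`` late diastole (just before atrial contraction)
* ``ED`` end-diastole (after atrial contraction, before ventricular systole)
* ``MS`` mid-systole (first phase of aortic valve opening)
* ``LS`` late systole (between mid- and end-systole; the leaflet-to-annulus
  index is measured here)
* ``ES`` end-systole (minimal left-ventricular volume)

Within one analyzed cycle the ordering is MD < LD < ED < MS < LS < ES.
"""

from __future__ import annotations

from enum import Enum


class PhaseLabel(str, Enum):
    MD = "MD"
    LD = "LD"
    ED = "ED"
    MS = "MS"
    LS = "LS"
    ES = "ES"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


PHASE_ORDER: tuple[PhaseLabel, ...] = (
    PhaseLabel.MD,
    PhaseLabel.LD,
    PhaseLabel.ED,
    PhaseLabel.MS,
    PhaseLabel.LS,
    PhaseLabel.ES,
)

PHASE_INDEX: dict[PhaseLabel, int] = {p: i for i, p in enumerate(PHASE_ORDER)}


def as_phase(value: "PhaseLabel | str") -> PhaseLabel:
    """Coerce a string such as ``"ES"`` to a :class:`PhaseLabel`."""
    if isinstance(value, PhaseLabel):
        return value
    try:
        return PhaseLabel(value)
    except ValueError as exc:
        valid = ", ".join(p.value for p in PHASE_ORDER)
        raise ValueError(f"unknown cardiac phase {value!r}; expected one of {valid}") from exc
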