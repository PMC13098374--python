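"""Arterial elastance and aortic distensibility estimates.

Two non-invasive surrogates of systemic arterial load:

* **Ea** (arterial elastance, mmHg/mL/kg): mean oscillometric blood pressure
  divided by the weight-indexed forward stroke volume, where FSV is the
  echocardiographic aortic velocity-time integral times the aortic valve
  cross-sectional area (cm·cm² = mL).
* **ADI** (aortic distensibility index, mmHg⁻¹, conventionally reported
  ×10³): fractional cross-sectional area change of the ascending aorta over
  the cycle divided by the systemic pulse pressure (SAP − DAP).  The
  fractional change is taken against the minimal (diastolic) area, the
  baseline convention for distensibility indices.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "HemodynamicRecord",
    "forward_stroke_volume",
    "arterial_elastance",
    "aortic_distensibility_index",
]


def forward_stroke_volume(vti_cm: float, av_csa_cm2: float) -> float:
    """FSV (mL) = aortic VTI (cm) × aortic valve cross-sectional area (cm²)."""
    if vti_cm <= 0 or av_csa_cm2 <= 0:
        raise ValueError(f"VTI and AV CSA must be positive, got {vti_cm}, {av_csa_cm2}")
    return vti_cm * av_csa_cm2


def arterial_elastance(mbp_mmhg: float, fsv_ml: float, body_weight_kg: float) -> float:
    """Ea (mmHg/mL/kg) = MBP / (FSV / BW).

    MBP is the recorded oscillometric mean, not reconstructed from SAP/DAP.
    """
    if fsv_ml <= 0:
        raise ValueError(f"FSV must be positive, got {fsv_ml}")
    if body_weight_kg <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight_kg}")
    return mbp_mmhg / (fsv_ml / body_weight_kg)


def aortic_distensibility_index(
    area_max_mm2: float, area_min_mm2: float, sap_mmhg: float, dap_mmhg: float
) -> float:
    """ADI (mmHg⁻¹) = ((A_max − A_min)/A_min) / (SAP − DAP).

    Returned on the natural scale; multiply by 10³ for the conventional
    reporting unit.
    """
    if area_min_mm2 <= 0:
        raise ValueError(f"minimal aortic area must be positive, got {area_min_mm2}")
    if area_max_mm2 < area_min_mm2:
        raise ValueError("maximal aortic area must be >= minimal area")
    if sap_mmhg <= dap_mmhg:
        raise ValueError(f"require SAP > DAP, got SAP={sap_mmhg}, DAP={dap_mmhg}")
    return ((area_max_mm2 - area_min_mm2) / area_min_mm2) / (sap_mmhg - dap_mmhg)


@dataclass(frozen=True)
class HemodynamicRecord:
    """Pressures, aortic flow and aortic area measurements for one visit."""

    sap_mmhg: float
    dap_mmhg: float
    mbp_mmhg: float
    vti_cm: float
    av_csa_cm2: float
    ao_area_max_mm2: float
    ao_area_min_mm2: float

    def __post_init__(self) -> None:
        if not self.sap_mmhg > self.dap_mmhg > 0:
            raise ValueError(f"require SAP > DAP > 0, got SAP={self.sap_mmhg}, DAP={self.dap_mmhg}")
        if not self.ao_area_max_mm2 >= self.ao_area_min_mm2 > 0:
            raise ValueError("require aortic area_max >= area_min > 0")

    @property
    def pulse_pressure_mmhg(self) -> float:
        return self.sap_mmhg - self.dap_mmhg

    @property
    def fsv_ml(self) -> float:
        return forward_stroke_volume(self.vti_cm, self.av_csa_cm2)

    def ea(self, body_weight_kg: float) -> float:
        return arterial_elastance(self.mbp_mmhg, self.fsv_ml, body_weight_kg)

    @property
    def adi(self) -> float:
        return aortic_distensibility_index(
            self.ao_area_max_mm2, self.ao_area_min_mm2, self.sap_mmhg, self.dap_mmhg
        )
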