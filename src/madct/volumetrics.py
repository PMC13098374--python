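"""Chamber volumetrics, regurgitation quantification and allometric indexing.

Volumetric mitral-regurgitation quantification uses the biventricular
stroke-volume difference: with no relevant right-sided regurgitation the
right-ventricular total stroke volume is a surrogate for the left
ventricle's forward stroke volume, so

    RVol = LV TSV - RV TSV        RF = RVol / LV TSV

Measurements are indexed allometrically to remove body-size dependence:
linear measures by BW^(1/3) (mm/kg^1/3), areas by body surface area
(cm²/m²) and volumes by body weight (mL/kg).  BSA uses the standard canine
allometric form BSA = 0.101·BW^(2/3) (BW in kg, BSA in m²); the constant is
recorded here so a different convention rescales all area indices uniformly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "BSA_COEFFICIENT",
    "SubjectInfo",
    "VolumeRecord",
    "PhysiologicImplausibilityWarning",
    "canine_bsa",
    "stroke_volume_and_ef",
    "mitral_regurgitation",
    "index_measurement",
]

BSA_COEFFICIENT = 0.101


class PhysiologicImplausibilityWarning(UserWarning):
    """Computed quantity is physiologically implausible (e.g. negative RVol)."""


def canine_bsa(body_weight_kg: float) -> float:
    """Canine body surface area (m²) from body weight: 0.101·BW^(2/3)."""
    if body_weight_kg <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight_kg}")
    return BSA_COEFFICIENT * body_weight_kg ** (2.0 / 3.0)


@dataclass(frozen=True)
class SubjectInfo:
    """Subject demographics; BSA is derived from body weight."""

    subject_id: str
    body_weight_kg: float
    age_years: Optional[float] = None
    sex: Optional[str] = None
    breed: Optional[str] = None

    def __post_init__(self) -> None:
        if self.body_weight_kg <= 0:
            raise ValueError(f"body weight must be positive, got {self.body_weight_kg}")

    @property
    def bsa_m2(self) -> float:
        return canine_bsa(self.body_weight_kg)


def stroke_volume_and_ef(lvedv_ml: float, lvesv_ml: float) -> tuple[float, float]:
    """LV total stroke volume (mL) and ejection fraction.

    TSV = LVEDV − LVESV; EF = TSV/LVEDV.  EF = 1 (LVESV = 0) is allowed
    mathematically but flagged implausible.
    """
    if lvesv_ml < 0:
        raise ValueError(f"LVESV must be non-negative, got {lvesv_ml}")
    if lvesv_ml >= lvedv_ml:
        raise ValueError(f"LVESV ({lvesv_ml}) must be smaller than LVEDV ({lvedv_ml})")
    tsv = lvedv_ml - lvesv_ml
    ef = tsv / lvedv_ml
    if lvesv_ml == 0:
        warnings.warn("EF = 1 (LVESV = 0) is physiologically implausible", PhysiologicImplausibilityWarning)
    return tsv, ef


def mitral_regurgitation(lv_tsv_ml: float, rv_tsv_ml: float) -> tuple[float, float]:
    """Regurgitant volume (mL) and fraction from the biventricular TSV difference.

    Negative RVol (RV TSV exceeding LV TSV) is returned unchanged with a
    warning rather than clipped, keeping the estimator unbiased when it
    feeds paired statistics.
    """
    if lv_tsv_ml <= 0:
        raise ValueError(f"LV TSV must be positive, got {lv_tsv_ml}")
    rvol = lv_tsv_ml - rv_tsv_ml
    rf = rvol / lv_tsv_ml
    if rvol < 0:
        warnings.warn(
            f"negative regurgitant volume ({rvol:.3g} mL): RV TSV exceeds LV TSV",
            PhysiologicImplausibilityWarning,
        )
    return rvol, rf


def index_measurement(value: float, kind: str, subject: SubjectInfo) -> float:
    """Allometric indexing of a raw measurement.

    ``kind``:
      * ``"linear"`` — value in mm, divided by BW^(1/3) → mm/kg^1/3
      * ``"area"``   — value in mm², converted to cm² and divided by BSA → cm²/m²
      * ``"volume"`` — value in mL, divided by BW → mL/kg
    """
    bw = subject.body_weight_kg
    if kind == "linear":
        return value / bw ** (1.0 / 3.0)
    if kind == "area":
        return (value / 100.0) / subject.bsa_m2
    if kind == "volume":
        return value / bw
    raise ValueError(f"unknown indexing kind {kind!r}; expected 'linear', 'area' or 'volume'")


@dataclass(frozen=True)
class VolumeRecord:
    """Chamber volumes (mL) for one subject visit, with derived MR quantities.

    LA volumes follow the CT convention: LAEDV is the minimal (end-diastolic)
    and LAESV the maximal (end-systolic) left atrial volume, appendage and
    pulmonary veins excluded upstream.
    """

    lvedv_ml: float
    lvesv_ml: float
    laedv_ml: float
    laesv_ml: float
    rv_tsv_ml: float

    def __post_init__(self) -> None:
        if not self.lvedv_ml > self.lvesv_ml >= 0:
            raise ValueError(
                f"require LVEDV > LVESV >= 0, got LVEDV={self.lvedv_ml}, LVESV={self.lvesv_ml}"
            )
        if not self.laesv_ml >= self.laedv_ml >= 0:
            raise ValueError(
                f"require LAESV >= LAEDV >= 0, got LAESV={self.laesv_ml}, LAEDV={self.laedv_ml}"
            )
        if self.rv_tsv_ml <= 0:
            raise ValueError(f"RV TSV must be positive, got {self.rv_tsv_ml}")

    @property
    def lv_tsv_ml(self) -> float:
        return self.lvedv_ml - self.lvesv_ml

    @property
    def ef(self) -> float:
        return stroke_volume_and_ef(self.lvedv_ml, self.lvesv_ml)[1]

    @property
    def rvol_ml(self) -> float:
        return mitral_regurgitation(self.lv_tsv_ml, self.rv_tsv_ml)[0]

    @property
    def rf(self) -> float:
        return mitral_regurgitation(self.lv_tsv_ml, self.rv_tsv_ml)[1]
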