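"""Synthetic cohort generator with known ground truth.

No per-dog raw data accompany the study design this package implements, so
validation runs on simulated cohorts that reproduce the structure the
analysis assumes:

* Each subject's annulus at each phase is a saddle ellipse
  ``x = a·cosθ, y = b·sinθ, z = h·cos2θ`` — the simplest closed curve with
  two horns (θ = 0, π) and two commissural lows (θ = ±π/2).  Closed forms
  (projected area πab, APD 2a, ICD 2b) make it an exact oracle for the
  geometry pipeline.
* Semi-axes scale allometrically with BW^(1/3), so the *indexed* per-phase
  diameters are population constants (taken from the pre-treatment cohort
  tables) times a subject-level scale factor.  Default pre-treatment values
  program paradoxical systolic expansion (ES > ED).
* Volumes are built in indexed units obeying conservation exactly before
  noise: TSV = LVEDV − LVESV, RVol = RF_true·TSV, RV TSV = FSV = TSV − RVol.
* A treatment effect multiplies the systolic-phase semi-axes (annular
  contraction), shifts volumes additively and preserves the trigone chord;
  pressures are unchanged by default.
* Measurement noise is added last: isotropic Gaussian jitter on marker
  coordinates and multiplicative Gaussian noise on volumes/flow/pressures.
  Both visits share the subject-level random effects (paired structure).

All randomness flows through one :class:`numpy.random.Generator` passed
explicitly or derived from a seed; identical config + seed gives identical
output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .geometry import AnnulusLandmarkSet, LeafletMeasurement, N_MARKERS
from .hemodynamics import HemodynamicRecord
from .phases import PhaseLabel, as_phase
from .volumetrics import SubjectInfo, VolumeRecord, canine_bsa

__all__ = [
    "AnnulusPhaseParams",
    "TreatmentEffect",
    "CohortConfig",
    "SubjectTruth",
    "SyntheticTruth",
    "CohortDataset",
    "annulus_from_params",
    "apply_treatment_effect",
    "generate_cohort",
]

_DEFAULT_PHASES = ("MD", "LD", "ED", "MS", "LS", "ES")

# Indexed per-phase annular diameters (mm/kg^1/3) of the untreated cohort;
# LS values sit between MS and ES.
_APD_INDEX = {"MD": 10.68, "LD": 10.85, "ED": 9.75, "MS": 10.52, "LS": 10.70, "ES": 10.96}
_ICD_INDEX = {"MD": 12.10, "LD": 12.17, "ED": 11.18, "MS": 11.57, "LS": 11.45, "ES": 11.32}


@dataclass(frozen=True)
class AnnulusPhaseParams:
    """Saddle-ellipse parameters for one phase: semi-axes a, b, height h (mm)
    and the (symmetric) trigone angle ±θ_t flanking the aortic horn."""

    a: float
    b: float
    h: float
    trigone_angle: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.h) <= 0:
            raise ValueError("saddle parameters a, b, h must be positive")
        if not 0 < self.trigone_angle < np.pi / 2:
            raise ValueError("trigone angle must lie in (0, π/2)")

    @property
    def ttd(self) -> float:
        """Trigone chord 2·b·sin(θ_t), exact on the analytic curve."""
        return 2.0 * self.b * np.sin(self.trigone_angle)


@dataclass(frozen=True)
class TreatmentEffect:
    """Programmed post-treatment changes.

    ``apd_mult``/``icd_mult`` multiply the systolic-phase semi-axes a and b
    (keys are phase names); volumes shift additively on the indexed scale
    (mL/kg); ``d_rf`` shifts the true regurgitant fraction; ``d_mbp`` shifts
    pressures.  The trigone chord is preserved by re-solving the trigone
    angle after the b-multiplier.
    """

    apd_mult: dict[str, float] = field(default_factory=lambda: {"MS": 1.0, "LS": 0.95, "ES": 0.906})
    icd_mult: dict[str, float] = field(default_factory=lambda: {"MS": 0.976, "LS": 0.956, "ES": 0.934})
    d_lvedv: float = -0.52
    d_lvesv: float = -0.28
    d_rf: float = -0.0975
    d_laedv: float = -0.18
    d_laesv: float = -0.37
    d_mbp: float = 0.0

    def __post_init__(self) -> None:
        for mult in (*self.apd_mult.values(), *self.icd_mult.values()):
            if mult <= 0:
                raise ValueError("effect multipliers must be positive")

    @classmethod
    def null(cls) -> "TreatmentEffect":
        return cls(apd_mult={}, icd_mult={}, d_lvedv=0.0, d_lvesv=0.0, d_rf=0.0,
                   d_laedv=0.0, d_laesv=0.0, d_mbp=0.0)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the simulated cohort.

    Defaults emulate the untreated stage-B2 cohort the analysis targets:
    20 dogs, body weight uniform on 4.3–19.6 kg, indexed annular diameters
    per phase from the pre-treatment tables (systolic expansion built in),
    LVEDV 4.21 mL/kg with total EF 0.639 and RF 0.371, MBP 89.5 mmHg, ADI
    5.379×10⁻³ mmHg⁻¹, and the default treatment effect reproducing the
    observed post-treatment systolic contraction and volume reductions.
    """

    n_subjects: int = 20
    phases: tuple[str, ...] = _DEFAULT_PHASES
    bw_range: tuple[float, float] = (4.3, 19.6)
    apd_index: dict[str, float] = field(default_factory=lambda: dict(_APD_INDEX))
    icd_index: dict[str, float] = field(default_factory=lambda: dict(_ICD_INDEX))
    saddle_height_index: float = 0.9  # mm/kg^1/3, semi-amplitude of z = h·cos2θ
    trigone_angle: float = 3 * np.pi / 16  # gives indexed TTD ≈ 6.2
    marker_angle_offset: float = np.pi / 16  # markers straddle the horns
    lai_pre: float = 1.21
    # volumes / hemodynamics (indexed scale)
    lvedv_index: float = 4.21
    ef_total: float = 0.639
    rf_true: float = 0.371
    laedv_index: float = 0.96
    laesv_index: float = 1.94
    mbp: float = 89.5
    sap_frac: float = 1.25  # SAP = sap_frac·MBP, DAP = dap_frac·MBP
    dap_frac: float = 0.78
    adi_true: float = 5.379e-3  # mmHg^-1
    ao_area_per_bsa: float = 240.0  # mm²/m², minimal ascending-aortic area
    av_csa_per_bsa: float = 2.4  # cm²/m², aortic valve area
    # subject-level variability (shared by both visits)
    subject_scale_sd: float = 0.08  # annular size factor
    subject_volume_sd: float = 0.15  # volume factor
    subject_bp_sd: float = 15.0  # mmHg on subject MBP
    # measurement noise (per visit)
    marker_jitter_mm: float = 0.3
    volume_cv: float = 0.04
    pressure_sd: float = 6.0  # mmHg
    leaflet_sd_mm: float = 0.2
    effect: TreatmentEffect = field(default_factory=TreatmentEffect)
    include_landmarks: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("cohort needs at least 3 subjects")
        if not 0 < self.ef_total < 1:
            raise ValueError(f"total EF must be in (0, 1), got {self.ef_total}")
        if not 0 < self.rf_true < 1:
            raise ValueError(f"RF_true must be in (0, 1), got {self.rf_true}")
        if not 0 <= self.rf_true + self.effect.d_rf < 1:
            raise ValueError("post-treatment RF leaves [0, 1)")
        if min(self.marker_jitter_mm, self.volume_cv, self.pressure_sd, self.leaflet_sd_mm) < 0:
            raise ValueError("noise levels must be non-negative")
        object.__setattr__(self, "phases", tuple(str(as_phase(p)) for p in self.phases))

    def with_(self, **kwargs) -> "CohortConfig":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["effect"] = dataclasses.asdict(self.effect)
        payload["phases"] = list(self.phases)
        payload["bw_range"] = list(self.bw_range)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if "effect" in payload:
            payload["effect"] = TreatmentEffect(**payload["effect"])
        for key in ("phases", "bw_range"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class SubjectTruth:
    """Ground-truth parameters for one subject (both visits)."""

    subject_id: str
    bw_kg: float
    bsa_m2: float
    annulus_scale: float
    volume_scale: float
    mbp_true: float
    adi_true: float
    annulus: dict[str, dict[str, AnnulusPhaseParams]]  # visit -> phase -> params
    volumes_index: dict[str, dict[str, float]]  # visit -> {lvedv, lvesv, rvol, rf, ...}
    tll_mm: float


@dataclass
class SyntheticTruth:
    """Cohort-level ground truth: config, seed and per-subject parameters."""

    config: CohortConfig
    seed: Optional[int]
    subjects: list[SubjectTruth]

    def programmed_apd_difference(self, phase: PhaseLabel | str) -> float:
        """Population-mean pre−post difference in indexed APD at ``phase`` (mm/kg^1/3)."""
        key = str(as_phase(phase))
        mult = self.config.effect.apd_mult.get(key, 1.0)
        return self.config.apd_index[key] * (1.0 - mult)

    def programmed_rf_difference(self) -> float:
        return -self.config.effect.d_rf


@dataclass
class CohortDataset:
    """Complete paired cohort: every subject has pre and post records."""

    subjects: list[SubjectInfo]
    landmarks: dict[tuple[str, str, str], AnnulusLandmarkSet]  # (sid, visit, phase)
    leaflets: dict[tuple[str, str], LeafletMeasurement]  # (sid, visit)
    volumes: dict[tuple[str, str], VolumeRecord]
    hemodynamics: dict[tuple[str, str], HemodynamicRecord]

    @property
    def phases(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(k[2] for k in self.landmarks))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def annulus_from_params(
    params: AnnulusPhaseParams,
    n_markers: int = N_MARKERS,
    jitter_mm: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    theta_offset: float = 0.0,
    rigid: Optional[tuple[np.ndarray, np.ndarray]] = None,
    subject_id: str = "synthetic",
    visit: str = "pre",
    phase: PhaseLabel | str = PhaseLabel.ES,
) -> AnnulusLandmarkSet:
    """Sample marker landmarks from the analytic saddle ellipse.

    Markers sit at θ_k = θ_offset + 2πk/n on the curve, optionally jittered
    with isotropic Gaussian noise of SD ``jitter_mm`` and moved by a rigid
    transform ``(R, t)`` (pass ``rigid="random"`` for a seeded random
    rotation + translation).  Trigones are flagged at the two markers
    nearest ±trigone_angle.
    """
    if jitter_mm < 0:
        raise ValueError(f"jitter must be non-negative, got {jitter_mm}")
    theta = theta_offset + 2.0 * np.pi * np.arange(n_markers) / n_markers
    pts = np.column_stack([
        params.a * np.cos(theta),
        params.b * np.sin(theta),
        params.h * np.cos(2.0 * theta),
    ])

    def nearest(angle: float) -> int:
        d = np.angle(np.exp(1j * (theta - angle)))
        return int(np.argmin(np.abs(d)))

    trigones = (nearest(params.trigone_angle), nearest(-params.trigone_angle))
    if trigones[0] == trigones[1]:
        raise ValueError("trigone angles map to the same marker; use distinct angles")
    if jitter_mm > 0:
        if rng is None:
            raise ValueError("jitter requires an explicit rng")
        pts = pts + rng.normal(0.0, jitter_mm, size=pts.shape)
    if rigid == "random":
        if rng is None:
            raise ValueError("random rigid transform requires an explicit rng")
        rigid = (_random_rotation(rng), rng.uniform(-50.0, 50.0, size=3))
    if rigid is not None:
        rot, trans = rigid
        pts = pts @ np.asarray(rot).T + np.asarray(trans)
    return AnnulusLandmarkSet(
        subject_id=subject_id,
        visit=visit,
        phase=as_phase(phase),
        markers=pts,
        trigone_indices=trigones,
    )


def apply_treatment_effect(
    pre_params: dict[str, AnnulusPhaseParams], effect: TreatmentEffect
) -> dict[str, AnnulusPhaseParams]:
    """Post-treatment annulus truth from the pre-treatment phase parameters.

    Systolic-phase semi-axes are multiplied; diastolic phases are returned
    unchanged.  The trigone chord (TTD = 2b·sinθ_t) is preserved by
    re-solving the trigone angle, reflecting the fixed fibrous trigones.
    """
    post: dict[str, AnnulusPhaseParams] = {}
    for phase, p in pre_params.items():
        ma = effect.apd_mult.get(phase, 1.0)
        mb = effect.icd_mult.get(phase, 1.0)
        if ma == 1.0 and mb == 1.0:
            post[phase] = p
            continue
        sin_t = min(1.0 - 1e-9, np.sin(p.trigone_angle) / mb)
        post[phase] = AnnulusPhaseParams(
            a=p.a * ma, b=p.b * mb, h=p.h, trigone_angle=float(np.arcsin(sin_t))
        )
    return post


def _noisy(rng: np.random.Generator, value: float, cv: float) -> float:
    return value * (1.0 + rng.normal(0.0, cv)) if cv > 0 else value


def generate_cohort(
    config: Optional[CohortConfig] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[CohortDataset, SyntheticTruth]:
    """Simulate a paired pre/post cohort with known ground truth.

    Subject-level random effects (annular scale, volume scale, blood
    pressure) are drawn once and shared by both visits; the treatment
    effect modifies the post-visit truth; measurement noise is applied
    last, independently per visit.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cfg = config if config is not None else CohortConfig()
    eff = cfg.effect
    subjects: list[SubjectInfo] = []
    truths: list[SubjectTruth] = []
    landmarks: dict[tuple[str, str, str], AnnulusLandmarkSet] = {}
    leaflets: dict[tuple[str, str], LeafletMeasurement] = {}
    volumes: dict[tuple[str, str], VolumeRecord] = {}
    hemo: dict[tuple[str, str], HemodynamicRecord] = {}

    for i in range(cfg.n_subjects):
        sid = f"dog{i + 1:03d}"
        bw = float(rng.uniform(*cfg.bw_range))
        s = bw ** (1.0 / 3.0)
        bsa = canine_bsa(bw)
        g = float(1.0 + rng.normal(0.0, cfg.subject_scale_sd))
        v = float(max(0.4, 1.0 + rng.normal(0.0, cfg.subject_volume_sd)))
        mbp_true = float(cfg.mbp + rng.normal(0.0, cfg.subject_bp_sd))
        adi_true = float(cfg.adi_true * np.exp(rng.normal(0.0, 0.18)))
        subjects.append(SubjectInfo(subject_id=sid, body_weight_kg=bw))

        pre_annulus = {
            phase: AnnulusPhaseParams(
                a=cfg.apd_index[phase] * g * s / 2.0,
                b=cfg.icd_index[phase] * g * s / 2.0,
                h=cfg.saddle_height_index * s,
                trigone_angle=cfg.trigone_angle,
            )
            for phase in cfg.phases
        }
        post_annulus = apply_treatment_effect(pre_annulus, eff)
        annulus_truth = {"pre": pre_annulus, "post": post_annulus}

        # indexed volume truth (conservation exact before noise)
        lvedv_pre = cfg.lvedv_index * v
        tsv_pre = cfg.ef_total * lvedv_pre
        vol_truth = {
            "pre": {
                "lvedv": lvedv_pre,
                "lvesv": lvedv_pre - tsv_pre,
                "rf": cfg.rf_true,
                "rvol": cfg.rf_true * tsv_pre,
                "laedv": cfg.laedv_index * v,
                "laesv": cfg.laesv_index * v,
            }
        }
        lvedv_post = lvedv_pre + eff.d_lvedv * v
        lvesv_post = vol_truth["pre"]["lvesv"] + eff.d_lvesv * v
        tsv_post = lvedv_post - lvesv_post
        rf_post = cfg.rf_true + eff.d_rf
        vol_truth["post"] = {
            "lvedv": lvedv_post,
            "lvesv": lvesv_post,
            "rf": rf_post,
            "rvol": rf_post * tsv_post,
            "laedv": vol_truth["pre"]["laedv"] + eff.d_laedv * v,
            "laesv": vol_truth["pre"]["laesv"] + eff.d_laesv * v,
        }
        tll_mm = cfg.lai_pre * cfg.apd_index["LS"] * g * s if "LS" in cfg.phases else 0.0

        for visit in ("pre", "post"):
            if cfg.include_landmarks:
                for phase in cfg.phases:
                    landmarks[(sid, visit, phase)] = annulus_from_params(
                        annulus_truth[visit][phase],
                        jitter_mm=cfg.marker_jitter_mm,
                        rng=rng,
                        theta_offset=cfg.marker_angle_offset,
                        rigid="random",
                        subject_id=sid,
                        visit=visit,
                        phase=phase,
                    )
                if "LS" in cfg.phases:
                    aortic = 0.55 * tll_mm + float(rng.normal(0.0, cfg.leaflet_sd_mm))
                    parietal = 0.45 * tll_mm + float(rng.normal(0.0, cfg.leaflet_sd_mm))
                    leaflets[(sid, visit)] = LeafletMeasurement(
                        aortic_leaflet_length=aortic, parietal_leaflet_length=parietal
                    )

            vt = vol_truth[visit]
            tsv = vt["lvedv"] - vt["lvesv"]
            fsv = tsv - vt["rvol"]  # = RV TSV, conservation
            lvedv_ml = _noisy(rng, vt["lvedv"] * bw, cfg.volume_cv)
            lvesv_ml = min(_noisy(rng, vt["lvesv"] * bw, cfg.volume_cv), 0.95 * lvedv_ml)
            laedv_ml = _noisy(rng, vt["laedv"] * bw, cfg.volume_cv)
            laesv_ml = max(_noisy(rng, vt["laesv"] * bw, cfg.volume_cv), laedv_ml)
            volumes[(sid, visit)] = VolumeRecord(
                lvedv_ml=lvedv_ml,
                lvesv_ml=lvesv_ml,
                laedv_ml=laedv_ml,
                laesv_ml=laesv_ml,
                rv_tsv_ml=_noisy(rng, fsv * bw, cfg.volume_cv),
            )
            mbp_visit = mbp_true + (eff.d_mbp if visit == "post" else 0.0)
            mbp = mbp_visit + float(rng.normal(0.0, cfg.pressure_sd)) if cfg.pressure_sd > 0 else mbp_visit
            sap = cfg.sap_frac * mbp
            dap = cfg.dap_frac * mbp
            ao_min_true = cfg.ao_area_per_bsa * bsa
            ao_max_true = ao_min_true * (1.0 + adi_true * (sap - dap))
            ao_min = _noisy(rng, ao_min_true, cfg.volume_cv / 2)
            ao_max = max(_noisy(rng, ao_max_true, cfg.volume_cv / 2), ao_min)
            av_csa = cfg.av_csa_per_bsa * bsa
            vti = _noisy(rng, (fsv * bw) / av_csa, cfg.volume_cv)
            hemo[(sid, visit)] = HemodynamicRecord(
                sap_mmhg=sap, dap_mmhg=dap, mbp_mmhg=mbp,
                vti_cm=vti, av_csa_cm2=av_csa,
                ao_area_max_mm2=ao_max,
                ao_area_min_mm2=ao_min,
            )

        truths.append(
            SubjectTruth(
                subject_id=sid, bw_kg=bw, bsa_m2=bsa, annulus_scale=g, volume_scale=v,
                mbp_true=mbp_true, adi_true=adi_true, annulus=annulus_truth,
                volumes_index=vol_truth, tll_mm=tll_mm,
            )
        )

    dataset = CohortDataset(
        subjects=subjects, landmarks=landmarks, leaflets=leaflets,
        volumes=volumes, hemodynamics=hemo,
    )
    return dataset, SyntheticTruth(config=cfg, seed=seed, subjects=truths)
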