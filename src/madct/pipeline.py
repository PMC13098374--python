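"""End-to-end measurement pipeline: cohort data → indexed metric table → report.

``measure_cohort`` turns a :class:`~madct.simulate.CohortDataset` (or files
read through :mod:`madct.io`) into a long-format table with one row per
subject × visit × variable (× phase for annular metrics), all values on the
reporting scale:

* MAA in cm²/m² (area indexed to BSA)
* APD / ICD / TTD in mm/kg^1/3 (linear indexed to BW^1/3)
* SI, LAI dimensionless
* LVEDV/LVESV/LVSV/RVol/LAEDV/LAESV in mL/kg, LVEF and RF in %
* Ea in mmHg/mL/kg, ADI in mmHg⁻¹ × 10³, MBP in mmHg

``compare_cohort`` then runs the paired pre/post statistics on that table.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

from .dynamics import MADProfile, build_mad_profile
from .geometry import AnnulusLandmarkSet, LeafletMeasurement, annulus_metrics
from .hemodynamics import HemodynamicRecord
from .phases import PhaseLabel, as_phase
from .simulate import CohortDataset
from .stats import comparison_table
from .volumetrics import SubjectInfo, VolumeRecord, index_measurement, mitral_regurgitation, stroke_volume_and_ef

__all__ = ["measure_cohort", "compare_cohort", "mad_profiles", "plot_mad_curves", "ANNULAR_VARIABLES"]

ANNULAR_VARIABLES = ("MAA", "APD", "ICD", "TTD", "SI")
GLOBAL_VARIABLES = (
    "LAI", "LVEDV", "LVESV", "LVEF", "LVSV", "RVol", "RF",
    "LAESV", "LAEDV", "Ea", "ADI", "MBP",
)


def _annular_rows(subject: SubjectInfo, visit: str, phase: str, landmarks: AnnulusLandmarkSet,
                  leaflets: Optional[LeafletMeasurement], M: int) -> list[dict]:
    use_leaflets = leaflets if as_phase(phase) is PhaseLabel.LS else None
    m = annulus_metrics(landmarks, leaflets=use_leaflets, M=M, check_self_intersection=False)
    rows = [
        dict(variable="MAA", value=index_measurement(m.maa, "area", subject)),
        dict(variable="APD", value=index_measurement(m.apd, "linear", subject)),
        dict(variable="ICD", value=index_measurement(m.icd, "linear", subject)),
        dict(variable="TTD", value=index_measurement(m.ttd, "linear", subject)),
        dict(variable="SI", value=m.si),
    ]
    for row in rows:
        row.update(subject_id=subject.subject_id, visit=visit, phase=phase)
    if m.lai is not None:
        rows.append(dict(subject_id=subject.subject_id, visit=visit, phase="", variable="LAI", value=m.lai))
    return rows


def _volume_rows(subject: SubjectInfo, visit: str, vol: VolumeRecord,
                 hemo: Optional[HemodynamicRecord]) -> list[dict]:
    tsv, ef = stroke_volume_and_ef(vol.lvedv_ml, vol.lvesv_ml)
    rvol, rf = mitral_regurgitation(tsv, vol.rv_tsv_ml)
    values = {
        "LVEDV": index_measurement(vol.lvedv_ml, "volume", subject),
        "LVESV": index_measurement(vol.lvesv_ml, "volume", subject),
        "LVEF": 100.0 * ef,
        "LVSV": index_measurement(tsv, "volume", subject),
        "RVol": index_measurement(rvol, "volume", subject),
        "RF": 100.0 * rf,
        "LAESV": index_measurement(vol.laesv_ml, "volume", subject),
        "LAEDV": index_measurement(vol.laedv_ml, "volume", subject),
    }
    if hemo is not None:
        values["Ea"] = hemo.ea(subject.body_weight_kg)
        values["ADI"] = 1e3 * hemo.adi
        values["MBP"] = hemo.mbp_mmhg
    return [
        dict(subject_id=subject.subject_id, visit=visit, phase="", variable=k, value=v)
        for k, v in values.items()
    ]


def measure_cohort(dataset: CohortDataset, M: int = 512) -> pd.DataFrame:
    """Compute the full indexed metric table for a cohort.

    Returns a long-format DataFrame with columns
    ``subject_id, visit, phase, variable, value`` (phase empty for
    non-annular variables).  ``M`` is the ring resampling density.
    """
    rows: list[dict] = []
    for subject in dataset.subjects:
        sid = subject.subject_id
        for visit in ("pre", "post"):
            for (s, vis, phase), lm in dataset.landmarks.items():
                if s == sid and vis == visit:
                    rows.extend(
                        _annular_rows(subject, visit, phase, lm, dataset.leaflets.get((sid, visit)), M)
                    )
            if (sid, visit) in dataset.volumes:
                rows.extend(
                    _volume_rows(subject, visit, dataset.volumes[(sid, visit)],
                                 dataset.hemodynamics.get((sid, visit)))
                )
    return pd.DataFrame(rows, columns=["subject_id", "visit", "phase", "variable", "value"])


def compare_cohort(metrics: pd.DataFrame, alpha: float = 0.05,
                   variables: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Paired pre/post comparison table (one row per variable × phase)."""
    return comparison_table(metrics, variables=variables, alpha=alpha)


def mad_profiles(dataset: CohortDataset, M: int = 512) -> dict[tuple[str, str], MADProfile]:
    """Per-subject, per-visit annular-dynamics profiles (raw mm metrics)."""
    grouped: dict[tuple[str, str], dict] = {}
    for (sid, visit, phase), lm in dataset.landmarks.items():
        leaflets = dataset.leaflets.get((sid, visit)) if as_phase(phase) is PhaseLabel.LS else None
        grouped.setdefault((sid, visit), {})[as_phase(phase)] = annulus_metrics(
            lm, leaflets=leaflets, M=M, check_self_intersection=False
        )
    return {
        key: build_mad_profile(key[0], key[1], series)
        for key, series in grouped.items()
        if PhaseLabel.ED in series and PhaseLabel.ES in series
    }


def plot_mad_curves(metrics: pd.DataFrame, path, variable: str = "MAA") -> None:
    """Export a simple cohort-mean annular-dynamics curve (pre vs post) as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .phases import PHASE_ORDER

    sub = metrics[(metrics["variable"] == variable) & (metrics["phase"] != "")]
    order = [p.value for p in PHASE_ORDER if p.value in set(sub["phase"])]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for visit, marker in (("pre", "o"), ("post", "s")):
        means = sub[sub["visit"] == visit].groupby("phase")["value"].mean().reindex(order)
        ax.plot(order, means.to_numpy(), marker=marker, label=visit)
    ax.set_xlabel("cardiac phase")
    ax.set_ylabel(f"indexed {variable}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
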