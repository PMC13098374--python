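"""File formats: landmark files, measurement tables and the bundled
reference-table fixture.

Landmark files carry the 16 ordered annular markers for one subject /
visit / phase, in millimetres, device frame.  Two dialects:

* JSON: ``{"subject_id", "visit": "pre"|"post", "phase": "MD|LD|ED|MS|LS|ES",
  "units": "mm", "markers": [[x,y,z]×16], "trigone_indices": [i, j]}``
* CSV: one row per marker with columns
  ``subject_id, visit, phase, idx, x, y, z, is_trigone``.

The measurement table is a per-subject-visit CSV with chamber volumes,
pressures, aortic flow/area quantities and body weight; see
``MEASUREMENT_COLUMNS``.  Extra columns are ignored with a log entry.
Writers and readers round-trip losslessly (repr-precision floats).
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import AnnulusLandmarkSet, LeafletMeasurement, N_MARKERS
from .hemodynamics import HemodynamicRecord
from .phases import as_phase
from .simulate import CohortDataset
from .volumetrics import SubjectInfo, VolumeRecord

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_measurements",
    "write_measurements",
    "load_paper_fixture",
    "MEASUREMENT_COLUMNS",
]

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "subject_id", "visit", "BW_kg",
    "LVEDV_mL", "LVESV_mL", "LAEDV_mL", "LAESV_mL", "RV_TSV_mL",
    "SAP_mmHg", "DAP_mmHg", "MBP_mmHg",
    "AoArea_max_mm2", "AoArea_min_mm2", "VTI_cm", "AVCSA_cm2",
]
LEAFLET_COLUMNS = ["AorticLeaflet_mm", "ParietalLeaflet_mm"]

_FIXTURE_SHA256 = "7b436d6060f7df70f981c657943b944675bbc5c8e0252adb0062ba4892fabb4d"


def write_landmarks(landmarks: AnnulusLandmarkSet, path) -> None:
    """Write one landmark set as JSON (``.json``) or per-marker CSV (``.csv``)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "subject_id": landmarks.subject_id,
            "visit": landmarks.visit,
            "phase": landmarks.phase.value,
            "units": "mm",
            "markers": [[float(c) for c in row] for row in landmarks.markers],
            "trigone_indices": list(landmarks.trigone_indices),
        }
        path.write_text(json.dumps(payload, indent=1))
    elif path.suffix == ".csv":
        trig = set(landmarks.trigone_indices)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["subject_id", "visit", "phase", "idx", "x", "y", "z", "is_trigone"])
            for k, (x, y, z) in enumerate(landmarks.markers):
                writer.writerow([landmarks.subject_id, landmarks.visit, landmarks.phase.value,
                                 k, repr(float(x)), repr(float(y)), repr(float(z)), int(k in trig)])
    else:
        raise ValueError(f"unsupported landmark file extension {path.suffix!r} (use .json or .csv)")


def read_landmarks(path) -> AnnulusLandmarkSet:
    """Parse a landmark file (JSON or CSV dialect) into an :class:`AnnulusLandmarkSet`."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        for key in ("subject_id", "visit", "phase", "markers", "trigone_indices"):
            if key not in payload:
                raise ValueError(f"landmark file {path} is missing required field {key!r}")
        markers = np.asarray(payload["markers"], dtype=float)
        if markers.shape != (N_MARKERS, 3):
            raise ValueError(
                f"landmark file {path}: expected {N_MARKERS} markers of 3 coordinates, got shape {markers.shape}"
            )
        trig = payload["trigone_indices"]
        if len(trig) != 2:
            raise ValueError(f"landmark file {path}: trigone_indices must hold exactly 2 indices")
        return AnnulusLandmarkSet(
            subject_id=str(payload["subject_id"]),
            visit=payload["visit"],
            phase=as_phase(payload["phase"]),
            markers=markers,
            trigone_indices=(int(trig[0]), int(trig[1])),
        )
    if path.suffix == ".csv":
        rows = list(csv.DictReader(open(path, newline="")))
        if len(rows) != N_MARKERS:
            raise ValueError(f"landmark file {path}: expected {N_MARKERS} marker rows, got {len(rows)}")
        rows.sort(key=lambda r: int(r["idx"]))
        markers = np.array([[float(r["x"]), float(r["y"]), float(r["z"])] for r in rows])
        trig = [int(r["idx"]) for r in rows if int(r["is_trigone"])]
        if len(trig) != 2:
            raise ValueError(f"landmark file {path}: expected exactly 2 trigone markers, got {len(trig)}")
        first = rows[0]
        return AnnulusLandmarkSet(
            subject_id=first["subject_id"],
            visit=first["visit"],
            phase=as_phase(first["phase"]),
            markers=markers,
            trigone_indices=(trig[0], trig[1]),
        )
    raise ValueError(f"unsupported landmark file extension {path.suffix!r} (use .json or .csv)")


def write_measurements(dataset: CohortDataset, path) -> None:
    """Write the per-subject-visit measurement table (volumes, pressures, flow)."""
    rows = []
    bw = {s.subject_id: s.body_weight_kg for s in dataset.subjects}
    for (sid, visit), vol in dataset.volumes.items():
        row = {
            "subject_id": sid, "visit": visit, "BW_kg": bw[sid],
            "LVEDV_mL": vol.lvedv_ml, "LVESV_mL": vol.lvesv_ml,
            "LAEDV_mL": vol.laedv_ml, "LAESV_mL": vol.laesv_ml,
            "RV_TSV_mL": vol.rv_tsv_ml,
        }
        hemo = dataset.hemodynamics.get((sid, visit))
        if hemo is not None:
            row.update({
                "SAP_mmHg": hemo.sap_mmhg, "DAP_mmHg": hemo.dap_mmhg, "MBP_mmHg": hemo.mbp_mmhg,
                "AoArea_max_mm2": hemo.ao_area_max_mm2, "AoArea_min_mm2": hemo.ao_area_min_mm2,
                "VTI_cm": hemo.vti_cm, "AVCSA_cm2": hemo.av_csa_cm2,
            })
        leaf = dataset.leaflets.get((sid, visit))
        if leaf is not None:
            row.update({"AorticLeaflet_mm": leaf.aortic_leaflet_length,
                        "ParietalLeaflet_mm": leaf.parietal_leaflet_length})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_measurements(path) -> dict[tuple[str, str], dict]:
    """Read a measurement table into per-(subject, visit) record dicts.

    Each value holds ``subject`` (:class:`SubjectInfo`), ``volumes``
    (:class:`VolumeRecord`), and optionally ``hemodynamics`` and
    ``leaflets`` when their columns are present.
    """
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS[:8] if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table {path} is missing required column(s): {', '.join(missing)}")
    known = set(MEASUREMENT_COLUMNS) | set(LEAFLET_COLUMNS)
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.info("measurement table %s: ignoring extra column(s) %s", path, ", ".join(extra))
    has_hemo = all(c in df.columns for c in MEASUREMENT_COLUMNS[8:])
    has_leaf = all(c in df.columns for c in LEAFLET_COLUMNS)
    out: dict[tuple[str, str], dict] = {}
    for _, row in df.iterrows():
        key = (str(row["subject_id"]), str(row["visit"]))
        entry = {
            "subject": SubjectInfo(subject_id=key[0], body_weight_kg=float(row["BW_kg"])),
            "volumes": VolumeRecord(
                lvedv_ml=float(row["LVEDV_mL"]), lvesv_ml=float(row["LVESV_mL"]),
                laedv_ml=float(row["LAEDV_mL"]), laesv_ml=float(row["LAESV_mL"]),
                rv_tsv_ml=float(row["RV_TSV_mL"]),
            ),
        }
        if has_hemo and not row[MEASUREMENT_COLUMNS[8:]].isna().any():
            entry["hemodynamics"] = HemodynamicRecord(
                sap_mmhg=float(row["SAP_mmHg"]), dap_mmhg=float(row["DAP_mmHg"]),
                mbp_mmhg=float(row["MBP_mmHg"]), vti_cm=float(row["VTI_cm"]),
                av_csa_cm2=float(row["AVCSA_cm2"]),
                ao_area_max_mm2=float(row["AoArea_max_mm2"]),
                ao_area_min_mm2=float(row["AoArea_min_mm2"]),
            )
        if has_leaf and not row[LEAFLET_COLUMNS].isna().any():
            entry["leaflets"] = LeafletMeasurement(
                aortic_leaflet_length=float(row["AorticLeaflet_mm"]),
                parietal_leaflet_length=float(row["ParietalLeaflet_mm"]),
            )
        out[key] = entry
    return out


def dataset_from_files(landmark_paths, measurements_path) -> CohortDataset:
    """Assemble a :class:`CohortDataset` from landmark files + a measurement table."""
    records = read_measurements(measurements_path)
    landmarks = {}
    for p in landmark_paths:
        lm = read_landmarks(p)
        landmarks[(lm.subject_id, lm.visit, lm.phase.value)] = lm
    subjects = {}
    volumes, hemos, leafs = {}, {}, {}
    for (sid, visit), entry in records.items():
        subjects[sid] = entry["subject"]
        volumes[(sid, visit)] = entry["volumes"]
        if "hemodynamics" in entry:
            hemos[(sid, visit)] = entry["hemodynamics"]
        if "leaflets" in entry:
            leafs[(sid, visit)] = entry["leaflets"]
    return CohortDataset(
        subjects=list(subjects.values()), landmarks=landmarks,
        leaflets=leafs, volumes=volumes, hemodynamics=hemos,
    )


def load_paper_fixture() -> dict:
    """Load the bundled, read-only reference summary tables.

    The file stores the printed cohort summary statistics (means, SDs,
    medians, IQRs, mean differences, CIs, p-value strings) keyed by
    variable × phase × visit.  A checksum mismatch raises, guarding against
    accidental edits.
    """
    data = resources.files("madct.data").joinpath("reference_tables.json").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise ValueError(f"reference-table fixture checksum mismatch ({digest})")
    return json.loads(data)
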