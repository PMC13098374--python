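"""Saddle-annulus reconstruction and geometric metrics from 3D landmarks.

The mitral annulus is segmented upstream (manual marker placement on
multiplanar-reformatted cardiac CT) as 16 ordered 3D markers, two of which
are flagged as the left/lateral and right/medial fibrous trigones.  This
module reconstructs a smooth, closed, saddle-shaped ring through the markers
and computes the standard annular metric panel:

* **MAA** — mitral annular area: area of the ring projected onto its
  total-least-squares (best-fit) plane, mm².
* **APD** — aortoparietal distance: in-plane distance between the aortic and
  parietal horns (the elevated points of the saddle on either side of the
  annulus), mm.
* **ICD** — intercommissural distance: maximal caliper width of the
  projected ring along the in-plane direction orthogonal to the APD axis, mm.
* **TTD** — trigone-to-trigone distance: straight 3D chord between the two
  fibrous trigone markers, mm.
* **SI**  — sphericity index, APD/ICD (dimensionless).
* **LAI** — leaflet-to-annulus index, total leaflet length / APD, measured
  at late systole (a coaptation-reserve measure).

All coordinates are in millimetres.  Allometric indexing is applied at the
reporting stage (see :mod:`madct.volumetrics`), never here.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .phases import PhaseLabel, as_phase

__all__ = [
    "AnnulusLandmarkSet",
    "AnnulusRing",
    "AnnulusMetrics",
    "LeafletMeasurement",
    "DegenerateLandmarksError",
    "EmptyPortionError",
    "resample_ring",
    "annulus_area",
    "aortoparietal_distance",
    "intercommissural_distance",
    "trigone_distance",
    "sphericity_index",
    "leaflet_annulus_index",
    "annulus_metrics",
]

N_MARKERS = 16
#: Saddle height (max signed elevation, mm) below which the ring is treated
#: as flat and the horn axis falls back to the centroid–trigone-midpoint line.
FLAT_SADDLE_MM = 0.05
_COINCIDENT_TOL = 1e-6

WINDING_CCW = "ccw_from_atrium"
WINDING_CW = "cw_from_atrium"


class DegenerateLandmarksError(ValueError):
    """Raised for landmark sets that cannot define a ring (e.g. coincident markers)."""


class EmptyPortionError(ValueError):
    """Raised when the aortic or parietal portion of a ring contains no points."""


@dataclass(frozen=True)
class AnnulusLandmarkSet:
    """Ordered ring of 16 annular markers for one subject / visit / phase.

    Markers are ordered counter-clockwise when viewed from the left atrium
    (``winding="ccw_from_atrium"``, the default) or clockwise
    (``"cw_from_atrium"``); the tag fixes the sign of saddle elevation.
    """

    subject_id: str
    visit: str
    phase: PhaseLabel
    markers: np.ndarray  # (16, 3), mm
    trigone_indices: tuple[int, int]
    winding: str = WINDING_CCW

    def __post_init__(self) -> None:
        markers = np.asarray(self.markers, dtype=float)
        if markers.shape != (N_MARKERS, 3):
            raise ValueError(
                f"expected {N_MARKERS} markers with 3 coordinates, got array of shape {markers.shape}"
            )
        if not np.all(np.isfinite(markers)):
            raise ValueError("markers contain non-finite coordinates")
        object.__setattr__(self, "markers", markers)
        object.__setattr__(self, "phase", as_phase(self.phase))
        if self.visit not in ("pre", "post"):
            raise ValueError(f"visit must be 'pre' or 'post', got {self.visit!r}")
        i, j = self.trigone_indices
        if not (0 <= i < N_MARKERS and 0 <= j < N_MARKERS) or i == j:
            raise ValueError(f"trigone_indices must be two distinct indices in [0, 15], got {(i, j)}")
        object.__setattr__(self, "trigone_indices", (int(i), int(j)))
        if self.winding not in (WINDING_CCW, WINDING_CW):
            raise ValueError(f"unknown winding tag {self.winding!r}")
        closed = np.vstack([markers, markers[:1]])
        gaps = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        if np.any(gaps <= _COINCIDENT_TOL):
            k = int(np.argmin(gaps))
            raise DegenerateLandmarksError(
                f"consecutive markers {k} and {(k + 1) % N_MARKERS} coincide (distance <= {_COINCIDENT_TOL} mm)"
            )

    @property
    def trigone_points(self) -> np.ndarray:
        """(2, 3) coordinates of the trigone markers."""
        return self.markers[list(self.trigone_indices)]


@dataclass
class AnnulusRing:
    """Densely resampled closed annulus curve with its best-fit plane.

    ``curve`` holds M approximately arc-length-uniform points on the closed
    periodic cubic interpolating spline through the markers (the closing
    point is not repeated).  ``is_aortic`` partitions the curve into the
    aortic portion (the arc between the trigones spanning the aortomitral
    continuity — the shorter trigone-to-trigone arc) and the parietal
    portion (the rest).  ``plane_normal`` is unit length and oriented toward
    the left atrium.
    """

    curve: np.ndarray  # (M, 3)
    plane_origin: np.ndarray  # (3,)
    plane_normal: np.ndarray  # (3,)
    is_aortic: np.ndarray  # (M,) bool
    trigone_points: np.ndarray  # (2, 3)

    def __post_init__(self) -> None:
        if not self.is_aortic.any() or self.is_aortic.all():
            raise EmptyPortionError("both the aortic and parietal portions must be non-empty")

    @cached_property
    def _basis(self) -> tuple[np.ndarray, np.ndarray]:
        return _plane_basis(self.plane_normal)

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project 3D points into in-plane (u, v) coordinates."""
        e1, e2 = self._basis
        rel = np.atleast_2d(points) - self.plane_origin
        return np.column_stack([rel @ e1, rel @ e2])

    @cached_property
    def curve_uv(self) -> np.ndarray:
        return self.project(self.curve)

    @cached_property
    def elevation(self) -> np.ndarray:
        """Signed elevation of each curve point above the plane (+ toward atrium)."""
        return (self.curve - self.plane_origin) @ self.plane_normal

    @cached_property
    def self_intersecting(self) -> bool:
        """True when the plane-projected ring self-intersects.

        Degenerate manual landmarking should not crash a batch: metrics are
        still computed, with this flag attached as a warning.
        """
        from shapely import LinearRing

        return not LinearRing(self.curve_uv).is_simple


@dataclass(frozen=True)
class AnnulusMetrics:
    """Annular metric panel at one cardiac phase (raw mm / mm² units)."""

    maa: float
    apd: float
    icd: float
    ttd: float
    si: float
    aortic_horn: np.ndarray
    parietal_horn: np.ndarray
    phase: PhaseLabel
    lai: Optional[float] = None
    self_intersecting: bool = False

    def __post_init__(self) -> None:
        for name in ("maa", "apd", "icd", "ttd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name.upper()} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class LeafletMeasurement:
    """Aortic (anterior) and parietal (posterior) leaflet lengths at late systole."""

    aortic_leaflet_length: float  # mm, mid-A2
    parietal_leaflet_length: float  # mm, mid-P2
    phase: PhaseLabel = PhaseLabel.LS

    def __post_init__(self) -> None:
        if self.aortic_leaflet_length <= 0 or self.parietal_leaflet_length <= 0:
            raise ValueError("leaflet lengths must be positive")
        object.__setattr__(self, "phase", as_phase(self.phase))

    @property
    def tll(self) -> float:
        """Total leaflet length (mm), the sum of both leaflets."""
        return self.aortic_leaflet_length + self.parietal_leaflet_length


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(n)))] = 1.0
    e1 = seed - (seed @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def resample_ring(landmarks: AnnulusLandmarkSet, M: int = 512) -> AnnulusRing:
    """Reconstruct the closed saddle ring through the 16 markers.

    A closed periodic cubic interpolating spline under chord-length
    parametrization is fit through the markers and resampled at ``M``
    approximately arc-length-uniform points.  The best-fit plane is the
    total-least-squares plane of the resampled points, its normal oriented
    toward the atrium using the landmark winding tag.  Curve points are
    labelled aortic (shorter trigone-to-trigone arc) or parietal.
    """
    if M < 64:
        raise ValueError(f"M must be >= 64, got {M}")
    pts = landmarks.markers
    closed = np.vstack([pts, pts[:1]])
    chords = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    t_knots = np.concatenate([[0.0], np.cumsum(chords)])
    spline = CubicSpline(t_knots, closed, bc_type="periodic", axis=0)

    # invert the arc-length function on a dense grid for uniform spacing
    t_dense = np.linspace(0.0, t_knots[-1], 8 * M + 1)
    p_dense = spline(t_dense)
    seg = np.linalg.norm(np.diff(p_dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    s_targets = np.linspace(0.0, arc[-1], M, endpoint=False)
    t_uniform = np.interp(s_targets, arc, t_dense)
    curve = spline(t_uniform)

    origin = curve.mean(axis=0)
    centered = curve - origin
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[2]
    # Newell-style orientation: for CCW-from-atrium ordering the polygon
    # normal points toward the atrial viewer.
    rolled = np.roll(centered, -1, axis=0)
    newell = np.cross(centered, rolled).sum(axis=0)
    if landmarks.winding == WINDING_CW:
        newell = -newell
    if newell @ normal < 0:
        normal = -normal

    i1, i2 = sorted(landmarks.trigone_indices)
    t_a, t_b = t_knots[i1], t_knots[i2]
    inside = (t_uniform >= t_a) & (t_uniform <= t_b)
    if (t_b - t_a) <= t_knots[-1] - (t_b - t_a):
        is_aortic = inside
    else:
        is_aortic = ~inside

    return AnnulusRing(
        curve=curve,
        plane_origin=origin,
        plane_normal=normal,
        is_aortic=is_aortic,
        trigone_points=landmarks.trigone_points.copy(),
    )


def annulus_area(ring: AnnulusRing) -> float:
    """Projected mitral annular area (MAA, mm²).

    Shoelace area of the polygon obtained by projecting the dense curve onto
    the best-fit plane.  Always positive; if the projection self-intersects
    the area is still returned (``ring.self_intersecting`` carries the flag).
    """
    uv = ring.curve_uv
    x, y = uv[:, 0], uv[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def _horns_by_elevation(ring: AnnulusRing) -> tuple[np.ndarray, np.ndarray, float]:
    elev = ring.elevation
    idx_a = np.flatnonzero(ring.is_aortic)
    idx_p = np.flatnonzero(~ring.is_aortic)
    ia = idx_a[np.argmax(elev[idx_a])]
    ip = idx_p[np.argmax(elev[idx_p])]
    return ring.curve[ia], ring.curve[ip], float(max(elev[ia], elev[ip]))


def _horns_by_trigone_axis(ring: AnnulusRing) -> tuple[np.ndarray, np.ndarray]:
    """Flat-ring fallback: horns are the intersections of the projected curve
    with the line through the projected centroid and the trigone-chord midpoint."""
    uv = ring.curve_uv
    c = uv.mean(axis=0)
    mid = ring.project(ring.trigone_points.mean(axis=0))[0]
    d = mid - c
    nd = np.linalg.norm(d)
    if nd < 1e-12:
        raise EmptyPortionError("trigone midpoint coincides with the ring centroid; horn axis undefined")
    d /= nd
    rel = uv - c
    along = rel @ d
    perp = rel[:, 0] * (-d[1]) + rel[:, 1] * d[0]
    nxt = np.roll(np.arange(len(uv)), -1)
    cross_mask = (perp * perp[nxt] < 0) | (perp == 0)
    if cross_mask.sum() < 2:
        raise EmptyPortionError("projected ring does not cross the trigone axis twice")
    crossings_w = []
    crossings_3d = []
    for k in np.flatnonzero(cross_mask):
        k2 = nxt[k]
        denom = perp[k] - perp[k2]
        f = 0.0 if denom == 0 else perp[k] / denom
        crossings_w.append((1 - f) * along[k] + f * along[k2])
        crossings_3d.append((1 - f) * ring.curve[k] + f * ring.curve[k2])
    w = np.asarray(crossings_w)
    aortic = crossings_3d[int(np.argmax(w))]  # trigone-midpoint (aortic) side
    parietal = crossings_3d[int(np.argmin(w))]
    return aortic, parietal


def aortoparietal_distance(ring: AnnulusRing) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """APD (mm) and the 3D aortic/parietal horn points.

    Each horn is the point of its portion with maximal signed elevation
    above the best-fit plane; APD is the in-plane distance between the
    horns' projections.  Rings flatter than ``FLAT_SADDLE_MM`` use the
    centroid–trigone-midpoint axis fallback.
    """
    aortic, parietal, max_elev = _horns_by_elevation(ring)
    if max_elev < FLAT_SADDLE_MM:
        aortic, parietal = _horns_by_trigone_axis(ring)
    ua, up = ring.project(np.vstack([aortic, parietal]))
    return float(np.linalg.norm(ua - up)), (aortic, parietal)


def intercommissural_distance(ring: AnnulusRing, apd_axis: np.ndarray) -> float:
    """ICD (mm): maximal caliper width of the projected ring orthogonal to the APD axis.

    ``apd_axis`` is a 3D direction (its in-plane component is used); the ICD
    is max minus min of the scalar projections of the curve onto the
    in-plane direction orthogonal to it.
    """
    axis = np.asarray(apd_axis, dtype=float)
    n = ring.plane_normal
    in_plane = axis - (axis @ n) * n
    norm = np.linalg.norm(in_plane)
    if norm < 1e-12:
        raise ValueError("APD axis has no in-plane component (zero-length axis)")
    ortho = np.cross(n, in_plane / norm)
    proj = (ring.curve - ring.plane_origin) @ ortho
    return float(proj.max() - proj.min())


def trigone_distance(landmarks: AnnulusLandmarkSet) -> float:
    """TTD (mm): straight 3D distance between the two trigone markers."""
    a, b = landmarks.trigone_points
    return float(np.linalg.norm(a - b))


def sphericity_index(apd: float, icd: float) -> float:
    """Sphericity index SI = APD/ICD."""
    if icd <= 0:
        raise ValueError(f"ICD must be positive, got {icd}")
    return apd / icd


def leaflet_annulus_index(leaflets: LeafletMeasurement, apd_late_systole: float) -> float:
    """LAI = total leaflet length / APD, at late systole."""
    if leaflets.phase is not PhaseLabel.LS:
        raise ValueError(f"LAI requires late-systolic leaflet lengths, got phase {leaflets.phase}")
    if apd_late_systole <= 0:
        raise ValueError(f"APD must be positive, got {apd_late_systole}")
    return leaflets.tll / apd_late_systole


def annulus_metrics(
    landmarks: AnnulusLandmarkSet,
    leaflets: Optional[LeafletMeasurement] = None,
    M: int = 512,
    check_self_intersection: bool = True,
) -> AnnulusMetrics:
    """Compute the full annular metric panel for one landmark set.

    Facade chaining ring resampling, projected area, horn finding, caliper
    ICD, trigone chord, sphericity index and (when late-systolic leaflet
    lengths are supplied) the LAI.  Deterministic for fixed input and M.
    ``check_self_intersection=False`` skips the projected-simplicity test,
    which large simulation batches do not need.
    """
    ring = resample_ring(landmarks, M=M)
    maa = annulus_area(ring)
    apd, (aortic_horn, parietal_horn) = aortoparietal_distance(ring)
    icd = intercommissural_distance(ring, aortic_horn - parietal_horn)
    ttd = trigone_distance(landmarks)
    si = sphericity_index(apd, icd)
    lai = None
    if leaflets is not None:
        lai = leaflet_annulus_index(leaflets, apd)
    return AnnulusMetrics(
        maa=maa,
        apd=apd,
        icd=icd,
        ttd=ttd,
        si=si,
        aortic_horn=aortic_horn,
        parietal_horn=parietal_horn,
        phase=landmarks.phase,
        lai=lai,
        self_intersecting=ring.self_intersecting if check_self_intersection else False,
    )
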