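"""Per-phase annular-dynamics profiles and systolic behaviour classification.

A healthy mitral annulus contracts during ventricular systole; in
degenerative mitral valve disease it can instead expand (paradoxical
systolic expansion), enlarging the regurgitant orifice.  This module
assembles per-phase :class:`~madct.geometry.AnnulusMetrics` into a profile
and classifies the end-diastole → end-systole change of a chosen metric as
expansion, contraction or neither.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .geometry import AnnulusMetrics
from .phases import PHASE_INDEX, PhaseLabel, as_phase

__all__ = ["MADProfile", "SystolicBehavior", "build_mad_profile", "systolic_behavior", "phase_of_minimum"]

_METRIC_ATTR = {"MAA": "maa", "APD": "apd", "ICD": "icd", "TTD": "ttd", "SI": "si"}


@dataclass(frozen=True)
class MADProfile:
    """Ordered phase → metrics series for one subject visit.

    Missing phases are simply absent — never interpolated; the profile must
    contain at least end-diastole and end-systole.
    """

    subject_id: str
    visit: str
    series: dict[PhaseLabel, AnnulusMetrics]
    lai: Optional[float] = None

    def __post_init__(self) -> None:
        if PhaseLabel.ED not in self.series or PhaseLabel.ES not in self.series:
            raise ValueError("profile must contain at least the ED and ES phases")
        ordered = dict(sorted(self.series.items(), key=lambda kv: PHASE_INDEX[kv[0]]))
        object.__setattr__(self, "series", ordered)

    @property
    def phases(self) -> tuple[PhaseLabel, ...]:
        return tuple(self.series)

    def metric(self, phase: PhaseLabel | str, name: str) -> float:
        return getattr(self.series[as_phase(phase)], _METRIC_ATTR[name])


@dataclass(frozen=True)
class SystolicBehavior:
    classification: str  # "expansion" | "contraction" | "none"
    delta: float  # metric(ES) - metric(ED), metric units
    relative_change: float  # delta / metric(ED)


def build_mad_profile(
    subject_id: str,
    visit: str,
    metrics_by_phase: Iterable[AnnulusMetrics] | Mapping[PhaseLabel, AnnulusMetrics],
    lai: Optional[float] = None,
) -> MADProfile:
    """Assemble per-phase metrics into an ordered profile.

    Duplicate phase entries are an error; an LAI measured at late systole
    may be attached explicitly or is taken from the LS entry when present.
    """
    if isinstance(metrics_by_phase, Mapping):
        entries = [(as_phase(p), m) for p, m in metrics_by_phase.items()]
    else:
        entries = [(m.phase, m) for m in metrics_by_phase]
    series: dict[PhaseLabel, AnnulusMetrics] = {}
    for phase, metrics in entries:
        if phase in series:
            raise ValueError(f"duplicate metrics for phase {phase}")
        series[phase] = metrics
    if lai is None and PhaseLabel.LS in series:
        lai = series[PhaseLabel.LS].lai
    return MADProfile(subject_id=subject_id, visit=visit, series=series, lai=lai)


def systolic_behavior(profile: MADProfile, metric: str = "MAA", tolerance: float = 0.01) -> SystolicBehavior:
    """Classify the ED→ES change of a metric as expansion/contraction/none.

    The relative change (ES − ED)/ED is compared against a dead-band
    (default ±1%) so that per-subject noise does not flip the sign label.
    The classification is invariant to allometric indexing because the
    denominators cancel in the ratio.
    """
    if metric not in _METRIC_ATTR:
        raise ValueError(f"unknown metric {metric!r}; expected one of {sorted(_METRIC_ATTR)}")
    ed = profile.metric(PhaseLabel.ED, metric)
    es = profile.metric(PhaseLabel.ES, metric)
    delta = es - ed
    rel = delta / ed
    if rel > tolerance:
        label = "expansion"
    elif rel < -tolerance:
        label = "contraction"
    else:
        label = "none"
    return SystolicBehavior(classification=label, delta=delta, relative_change=rel)


def phase_of_minimum(profile: MADProfile, metric: str = "MAA") -> PhaseLabel:
    """Phase at which the metric is minimal; ties resolve to the earlier phase."""
    if metric not in _METRIC_ATTR:
        raise ValueError(f"unknown metric {metric!r}; expected one of {sorted(_METRIC_ATTR)}")
    best_phase = None
    best_value = None
    for phase in profile.phases:  # already in cycle order
        value = profile.metric(phase, metric)
        if best_value is None or value < best_value:
            best_phase, best_value = phase, value
    return best_phase
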