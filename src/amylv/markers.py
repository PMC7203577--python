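"""Model-based progression markers, recovery score, and status prediction.

Seven markers summarise each subject-scan: the wall-to-cavity volume ratio
V_wall/V_LV, mean end-diastolic circumferential and longitudinal strains
over the three short-axis layers, the diastolic filling work W, the mean
end-diastolic first principal stress over the three layers, the average
stress-stretch slope f-bar of the fitted material, and the shape-trajectory
direction relative to the healthy cohort.  Percent changes from baseline to
follow-up are mapped to better/worse calls; the recovery score is the
proportion of "better" calls and scores strictly above 0.5 predict a
stable-or-recovery clinical course.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from . import geometry
from .forward import ReducedOrderInflation
from .mechanics import (
    MaterialParameters,
    PressureVolumeCurve,
    average_slope,
    diastolic_work,
    principal_stress,
    uniaxial_fiber_response,
)

__all__ = [
    "MARKER_NAMES",
    "MarkerVector",
    "ProgressionRecord",
    "percent_change",
    "classify_marker",
    "recovery_score",
    "predict_status",
    "agreement",
    "compute_markers",
    "progression_record",
    "score_distribution",
]

MARKER_NAMES = ("v_ratio", "e_cc", "e_ll", "work", "sigma1", "f_slope", "shape")

# direction of improvement for the numeric markers: thinner wall, larger
# strains (more compliant), less work, less stress, shallower stiffness
_BETTER_IF_NEGATIVE = {"v_ratio", "work", "sigma1", "f_slope"}
_BETTER_IF_POSITIVE = {"e_cc", "e_ll"}


@dataclass
class MarkerVector:
    """The seven progression markers of one subject-scan."""

    v_ratio: float  # V_wall / V_LV, dimensionless
    e_cc: float  # mean end-diastolic circumferential strain
    e_ll: float  # mean end-diastolic longitudinal strain
    work: float  # diastolic filling work, mmHg mL
    sigma1: float  # mean end-diastolic first principal stress, kPa
    f_slope: float  # average stress-stretch slope, kPa
    shape: Optional[str] = None  # 'toward_healthy' / 'away_from_healthy'

    def numeric(self) -> dict:
        d = asdict(self)
        d.pop("shape")
        return d

    def __post_init__(self):
        for k, v in self.numeric().items():
            if not np.isfinite(v):
                raise ValueError(f"marker {k} is not finite")


@dataclass
class ProgressionRecord:
    baseline: MarkerVector
    followup: MarkerVector
    pct_change: dict
    calls: dict
    recovery_score: float
    predicted_status: str


def percent_change(baseline_value: float, followup_value: float) -> float:
    """(follow-up - baseline) / baseline x 100."""
    if baseline_value == 0:
        raise ValueError("baseline value must be nonzero for a percent change")
    return (followup_value - baseline_value) / baseline_value * 100.0


def classify_marker(marker_name: str, value) -> str:
    """'better' or 'worse' for one marker.

    ``value`` is the percent change for numeric markers, or the trajectory
    direction for the shape marker.  An exact zero change counts as worse
    (conservative: no improvement shown).
    """
    if marker_name == "shape":
        if value in ("toward_healthy", "down"):
            return "better"
        if value in ("away_from_healthy", "up"):
            return "worse"
        raise ValueError(f"unknown shape direction {value!r}")
    if marker_name in _BETTER_IF_NEGATIVE:
        return "better" if value < 0 else "worse"
    if marker_name in _BETTER_IF_POSITIVE:
        return "better" if value > 0 else "worse"
    raise ValueError(f"unknown marker {marker_name!r}")


def recovery_score(calls: Sequence[str]) -> float:
    """Proportion of 'better' calls among the seven markers."""
    if len(calls) != 7:
        raise ValueError("recovery score needs exactly 7 marker calls")
    bad = set(calls) - {"better", "worse"}
    if bad:
        raise ValueError(f"unknown call values {bad}")
    return sum(c == "better" for c in calls) / 7.0


def predict_status(score: float) -> str:
    """Scores strictly above 0.5 predict a stable-or-recovery course."""
    return "stable_or_recovery" if score > 0.5 else "worsening"


def agreement(predictions: Sequence[str], clinical: Sequence[str]) -> int:
    """Count of cases where the threshold prediction matches the clinical
    assessment (Recovery and Stable both count as stable_or_recovery)."""
    allowed = {"Recovery", "Stable", "Worsening"}
    bad = set(clinical) - allowed
    if bad:
        raise ValueError(f"unknown clinical labels {bad}")
    n = 0
    for pred, clin in zip(predictions, clinical, strict=True):
        n += (pred == "stable_or_recovery") == (clin in ("Recovery", "Stable"))
    return n


# ---------------------------------------------------------------------------


def compute_markers(
    template,
    series,
    curve: PressureVolumeCurve,
    params: MaterialParameters,
    shape_dir: Optional[str] = None,
    model: Optional[ReducedOrderInflation] = None,
    lambda_max: float = 1.15,
    n_layer: int = 3,
    n_reg: int = 20,
) -> MarkerVector:
    """Assemble the seven markers of one fitted, simulated subject-scan.

    ``series`` is the simulated mesh series at the fitted parameters;
    strain and stress markers are averaged over the three strain layers at
    end-diastole; the volume ratio uses the early-diastolic reference.
    """
    if len(series) < 2:
        raise ValueError("need a simulated series with at least two frames")
    v_ratio = geometry.wall_volume(template) / geometry.chamber_volume(template)
    field = geometry.regional_strains(series, template, n_layer=n_layer, n_reg=n_reg)
    e_cc = float(field.E_cc[:, :, -1].mean())
    e_ll = float(field.E_ll[:, :, -1].mean())
    work = diastolic_work(curve)

    model = model or ReducedOrderInflation()
    pts = series[-1].points if hasattr(series[-1], "points") else series[-1]
    sig = model.cauchy_stress_field(template, pts, params)
    rings = geometry.select_layer_rings(template, n_layer)
    mask = np.isin(template.elem_ring, rings)
    sigma1 = float(np.mean(principal_stress(sig[mask])))

    f_slope = average_slope(uniaxial_fiber_response(params, lambda_max))
    return MarkerVector(
        v_ratio=v_ratio, e_cc=e_cc, e_ll=e_ll, work=work,
        sigma1=sigma1, f_slope=f_slope, shape=shape_dir,
    )


def progression_record(
    baseline: MarkerVector, followup: MarkerVector
) -> ProgressionRecord:
    """Percent changes, calls, recovery score and predicted status."""
    if baseline.shape is None or followup.shape is None:
        raise ValueError("shape direction missing: run the shape stage first")
    pct = {
        k: percent_change(bv, fv)
        for (k, bv), fv in zip(baseline.numeric().items(), followup.numeric().values())
    }
    calls = {k: classify_marker(k, v) for k, v in pct.items()}
    calls["shape"] = classify_marker("shape", followup.shape)
    ordered = [calls[k] for k in MARKER_NAMES]
    score = recovery_score(ordered)
    return ProgressionRecord(
        baseline=baseline,
        followup=followup,
        pct_change=pct,
        calls=calls,
        recovery_score=score,
        predicted_status=predict_status(score),
    )


def score_distribution(call_samples: np.ndarray) -> dict:
    """Distribution of recovery scores over per-draw marker calls.

    ``call_samples`` is (n_draws, 7) of booleans (True = better).  Returns
    a mapping score -> probability.
    """
    calls = np.asarray(call_samples, dtype=bool)
    if calls.ndim != 2 or calls.shape[1] != 7:
        raise ValueError("call_samples must be (n_draws, 7)")
    scores = calls.sum(axis=1) / 7.0
    out = {}
    for s in np.unique(scores):
        out[float(s)] = float(np.mean(scores == s))
    return out
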