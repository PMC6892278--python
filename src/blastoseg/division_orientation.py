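"""Division-orientation statistics against the isotropic (sine) null.

The division angle is defined from two unit axes: e1, the mother cell's
shortest principal axis measured a fixed lead time before cytokinesis, and
e2, the axis connecting the two daughter centroids just after division.
With α = arccos|e1·e2| ∈ [0°, 90°] the reported statistic is θ = 90° − α, so
θ = 90° means the daughters separated along the shortest axis and θ = 0°
perpendicular to it.

If e2 is isotropic and independent of e1, α has density ∝ sin α on
[0°, 90°] and the CDF of θ is F(θ) = sin θ — the "sine null".  Observed
angle sets are compared to it with a one-sample Kolmogorov-Smirnov test,
and histograms use arcsine-spaced bin edges so each bin carries equal null
probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .shape_metrics import CellShapeRecord


@dataclass
class DivisionEvent:
    mother_id: int
    daughter_ids: tuple[int, int]
    t_div: int
    e1: np.ndarray
    e2: np.ndarray
    theta: float


def _check_unit(v: np.ndarray, name: str, tol: float = 1e-6) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if abs(n - 1.0) > tol:
        raise ValueError(f"{name} is not a unit vector (norm {n:.8f})")
    return v


def frame_at_lead(t_div: int, lead_minutes: float, frame_interval_minutes: float) -> int:
    """Frame index nearest to t_div − lead; ties round toward earlier frames."""
    if frame_interval_minutes <= 0:
        raise ValueError("frame interval must be positive")
    offset = lead_minutes / frame_interval_minutes
    # round half toward the earlier (larger offset) frame
    return t_div - int(np.floor(offset + 0.5))


def shortest_axis_at(
    track: dict[int, CellShapeRecord],
    t_div: int,
    lead: float = 50.0,
    frame_interval: float = 10.0,
) -> np.ndarray:
    """Mother shortest axis at the frame nearest to t_div − lead minutes.

    `track` maps frame index → shape record of the mother cell.
    """
    target = frame_at_lead(t_div, lead, frame_interval)
    for cand in (target, target - 1, target + 1):
        if cand in track:
            return np.asarray(track[cand].e_short, dtype=float)
    raise KeyError(
        f"no shape record within one frame of target {target} (t_div={t_div}, lead={lead} min)"
    )


def daughter_axis(c1, c2) -> np.ndarray:
    """Unit vector along the line connecting the daughter centroids."""
    d = np.asarray(c2, dtype=float) - np.asarray(c1, dtype=float)
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise ValueError("daughter centroids coincide; division axis undefined")
    return d / n


def division_angle(e1, e2) -> float:
    """θ = 90° − arccos|e1·e2| in degrees; sign of either axis is irrelevant."""
    e1 = _check_unit(e1, "e1")
    e2 = _check_unit(e2, "e2")
    c = min(abs(float(np.dot(e1, e2))), 1.0)
    return 90.0 - np.degrees(np.arccos(c))


def sine_null_cdf(theta) -> np.ndarray | float:
    """Null CDF F(θ) = sin θ for θ in degrees on [0, 90]."""
    t = np.asarray(theta, dtype=float)
    if np.any(t < 0) or np.any(t > 90):
        raise ValueError("theta must lie in [0, 90] degrees")
    out = np.sin(np.radians(t))
    return float(out) if np.isscalar(theta) else out


def sample_null(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw θ from the sine null by inverse CDF: θ = arcsin(U)."""
    return np.degrees(np.arcsin(rng.uniform(0.0, 1.0, size=n)))


def equal_probability_bins(n_bins: int) -> np.ndarray:
    """Bin edges θ_k = arcsin(k/n) in degrees: each bin has null mass 1/n."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    k = np.arange(n_bins + 1) / n_bins
    return np.degrees(np.arcsin(k))


def ks_test_vs_null(angles) -> tuple[float, float]:
    """One-sample KS test of observed θ against F(θ) = sin θ.

    Exact p-value for n ≤ 100, asymptotic beyond.
    """
    a = np.asarray(angles, dtype=float)
    if a.size < 5:
        raise ValueError(f"need at least 5 angles, got {a.size}")
    if np.any(a < 0) or np.any(a > 90):
        raise ValueError("angles must lie in [0, 90] degrees")
    method = "exact" if a.size <= 100 else "asymp"
    res = stats.kstest(a, sine_null_cdf, method=method)
    return float(res.statistic), float(res.pvalue)


def apicobasal_angle(
    track: dict[int, CellShapeRecord],
    t_div: int,
    embryo_com,
    lead: float = 60.0,
    frame_interval: float = 10.0,
) -> float:
    """Angle (degrees, [0, 90]) between the cell's longest axis and its
    apico-basal axis (embryo center of mass → cell centroid), both taken at
    t_div − lead minutes.  0° = radially elongated, 90° = tangential.
    """
    target = frame_at_lead(t_div, lead, frame_interval)
    rec = None
    for cand in (target, target - 1, target + 1):
        if cand in track:
            rec = track[cand]
            break
    if rec is None:
        raise KeyError(f"no shape record within one frame of target {target}")
    u = np.asarray(rec.centroid, dtype=float) - np.asarray(embryo_com, dtype=float)
    n = np.linalg.norm(u)
    if n < 1e-9:
        raise ValueError("cell centroid coincides with the embryo center of mass")
    u /= n
    e_long = _check_unit(rec.e_long, "e_long")
    c = min(abs(float(np.dot(e_long, u))), 1.0)
    return float(np.degrees(np.arccos(c)))
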