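"""Thresholding, suitability classes, risk overlay and area change statistics.

Continuous suitability is binarized at the maximum test sensitivity plus
specificity (MTSPS) threshold t, and the suitable range [t, 1] is split into
three equal-width bins giving the four classes unsuitable / low / medium /
high. 'Optimal' host area is the medium-or-high host class; inside it the
pest's class becomes the risk level. Per-class areas use latitude-aware
spherical cell areas by default (planar cell counts optional), and change
between time slices is reported as percent extension (+) or shortening (−)
relative to the earlier slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import ClimateGrid, row_areas_km2
from .maxent import SuitabilityGrid

#: integer codes for suitability classes
UNSUITABLE, LOW, MEDIUM, HIGH = 0, 1, 2, 3
SUIT_CLASS_NAMES = {UNSUITABLE: "unsuitable", LOW: "low", MEDIUM: "medium", HIGH: "high"}

#: integer codes for risk levels
OUTSIDE_OPTIMAL, NO_RISK, LOW_RISK, MEDIUM_RISK, HIGH_RISK = 0, 1, 2, 3, 4
RISK_CLASS_NAMES = {
    OUTSIDE_OPTIMAL: "outside_optimal", NO_RISK: "no_risk",
    LOW_RISK: "low_risk", MEDIUM_RISK: "medium_risk", HIGH_RISK: "high_risk",
}
RISK_LEVELS = ["no_risk", "low_risk", "medium_risk", "high_risk"]


@dataclass
class ClassGrid:
    """Four-class suitability map with the threshold and interior cut points."""

    grid: ClimateGrid  # integer class codes in values
    threshold_t: float
    class_bounds: tuple[float, float]

    @property
    def codes(self) -> np.ndarray:
        return self.grid.values.astype(int)

    @property
    def mask(self) -> np.ndarray:
        return self.grid.mask


@dataclass
class RiskMap:
    """Pest risk classes inside the optimal-host mask."""

    grid: ClimateGrid  # integer risk codes
    pest_slice: str
    host_slice: str

    @property
    def codes(self) -> np.ndarray:
        return self.grid.values.astype(int)

    @property
    def mask(self) -> np.ndarray:
        return self.grid.mask

    @property
    def optimal_mask(self) -> np.ndarray:
        return (~self.mask) & (self.codes != OUTSIDE_OPTIMAL)


def mtsps_threshold(test_presence_scores: np.ndarray,
                    background_scores: np.ndarray) -> float:
    """Maximum test sensitivity plus specificity threshold.

    Candidate thresholds are midpoints of adjacent distinct pooled scores;
    sensitivity counts presences >= t, specificity background < t; ties go to
    the smallest maximizing t.
    """
    p = np.asarray(test_presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("mtsps_threshold requires non-empty score vectors")
    pooled = np.unique(np.concatenate([p, b]))
    if pooled.size < 2:
        raise ValueError("all scores identical; MTSPS threshold is undefined")
    candidates = (pooled[:-1] + pooled[1:]) / 2.0
    best_t, best_val = None, -np.inf
    for t in candidates:
        val = (p >= t).mean() + (b < t).mean()
        if val > best_val + 1e-12:
            best_t, best_val = float(t), val
    assert best_t is not None
    return best_t


def classify_suitability(suit: SuitabilityGrid, t: float) -> ClassGrid:
    """Threshold a suitability map into unsuitable/low/medium/high.

    Values < t are unsuitable; [t, 1] is split into three equal-width bins
    (half-open below, closed at 1). A value exactly at t is low; 1.0 is high.
    """
    if not 0 < t < 1:
        raise ValueError(f"threshold must be in (0, 1), got {t}")
    b1 = t + (1.0 - t) / 3.0
    b2 = t + 2.0 * (1.0 - t) / 3.0
    v = suit.grid.values
    codes = np.full(v.shape, UNSUITABLE, dtype=float)
    codes[(v >= t) & (v < b1)] = LOW
    codes[(v >= b1) & (v < b2)] = MEDIUM
    codes[v >= b2] = HIGH
    codes[suit.mask] = 0.0
    grid = suit.grid.with_values(codes, name="suitability_class", units="class")
    return ClassGrid(grid=grid, threshold_t=t, class_bounds=(b1, b2))


def optimal_mask(host_classes: ClassGrid) -> np.ndarray:
    """True where the host class is medium or high ('optimal conditions')."""
    codes = host_classes.codes
    return (~host_classes.mask) & ((codes == MEDIUM) | (codes == HIGH))


def risk_overlay(pest_classes: ClassGrid, host_mask: np.ndarray,
                 pest_slice: str = "current", host_slice: str = "current") -> RiskMap:
    """Pest suitability class inside the optimal-host mask, cellwise.

    Outside the mask every cell is outside_optimal; inside, pest unsuitable /
    low / medium / high map to no / low / medium / high risk.
    """
    if host_mask.shape != pest_classes.grid.shape:
        raise ValueError("host mask is not aligned with the pest class grid")
    codes = pest_classes.codes
    risk = np.full(codes.shape, OUTSIDE_OPTIMAL, dtype=float)
    inside = host_mask & ~pest_classes.mask
    mapping = {UNSUITABLE: NO_RISK, LOW: LOW_RISK, MEDIUM: MEDIUM_RISK, HIGH: HIGH_RISK}
    for suit_code, risk_code in mapping.items():
        risk[inside & (codes == suit_code)] = risk_code
    grid = pest_classes.grid.with_values(risk, name="risk", units="class")
    return RiskMap(grid=grid, pest_slice=pest_slice, host_slice=host_slice)


def area_summary(risk: RiskMap, geodesic: bool = True) -> pd.DataFrame:
    """Per-risk-class area (km²) and percent of the optimal-host area.

    ``geodesic=True`` weights cells by their latitude-dependent spherical
    area; ``False`` counts cells as equal-area pixels.
    """
    opt = risk.optimal_mask
    if not opt.any():
        raise ValueError("risk map has no optimal cells")
    if geodesic:
        areas = np.broadcast_to(row_areas_km2(risk.grid)[:, None], risk.grid.shape)
    else:
        areas = np.ones(risk.grid.shape)
    total = areas[opt].sum()
    rows = []
    codes = risk.codes
    for code, name in ((NO_RISK, "no_risk"), (LOW_RISK, "low_risk"),
                       (MEDIUM_RISK, "medium_risk"), (HIGH_RISK, "high_risk")):
        a = areas[opt & (codes == code)].sum()
        rows.append({"class": name, "area_km2": float(a),
                     "percent_of_optimal": float(100.0 * a / total)})
    df = pd.DataFrame(rows)
    df.attrs["optimal_area_km2"] = float(total)
    return df


def change_stats(current: pd.DataFrame, future: pd.DataFrame) -> pd.DataFrame:
    """Percent change per class between two area summaries.

    change% = (future − current) / current × 100; positive values are
    extensions, negative shortenings. A class absent now (area 0) has no
    defined change and is flagged NaN.
    """
    cur = current.set_index("class")["area_km2"]
    fut = future.set_index("class")["area_km2"]
    if set(cur.index) != set(fut.index):
        raise ValueError("area summaries have different class sets")
    rows = []
    for cls in cur.index:
        if cur[cls] > 0:
            change = (fut[cls] - cur[cls]) / cur[cls] * 100.0
            defined = True
        else:
            change, defined = float("nan"), False
        rows.append({"class": cls, "area_current_km2": float(cur[cls]),
                     "area_future_km2": float(fut[cls]),
                     "change_percent": float(change), "defined": defined})
    return pd.DataFrame(rows)


def percent_change(current_km2: float, future_km2: float) -> float:
    """(future − current) / current × 100; the printed extension/shortening form."""
    if current_km2 <= 0:
        raise ValueError("percent change undefined for zero current area")
    return (future_km2 - current_km2) / current_km2 * 100.0
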