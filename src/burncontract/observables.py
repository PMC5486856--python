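"""Wound-area and field-probe reductions.

The study's response variable is the *relative wound surface area*: 40
material points are seeded on the initial wound boundary, tracked with
the tissue, and the shoelace area of the resulting polygon at time t is
divided by its day-0 value.  Field probes average a quantity over nine
material points (the wound center, four at radius c_I/2 and four at
radius c_I), evaluated in the Lagrangian frame so the probes follow the
tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationResult",
    "wound_boundary_points",
    "polygon_area",
    "relative_area",
    "probe_points",
    "probe_average",
]


@dataclass
class SimulationResult:
    """Time series produced by either engine.

    ``times`` are in days.  ``boundary_polygons`` has shape
    (n_times, n_vertices, 2) in cm (displaced positions of the tracked
    boundary material points).  ``probes`` maps a field name ("M",
    "rho", ...) to the 9-point Lagrangian probe average per output time.
    ``profiles`` optionally carries solver-specific snapshots.
    """

    times: np.ndarray
    boundary_polygons: np.ndarray
    probes: dict[str, np.ndarray]
    engine: str = ""
    profiles: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def relative_areas(self) -> np.ndarray:
        a0 = polygon_area(self.boundary_polygons[0])
        return np.array([polygon_area(v) / a0 for v in self.boundary_polygons])

    def areas_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_day": self.times,
                             "relative_area": self.relative_areas})

    def probes_frame(self) -> pd.DataFrame:
        rows = []
        for name, vals in self.probes.items():
            for t, v in zip(self.times, vals):
                rows.append((t, name, v))
        return pd.DataFrame(rows, columns=["time_day", "probe", "value"])


def wound_boundary_points(c_I: float, n: int = 40) -> np.ndarray:
    """Material points (c_I cos(2 pi (i-1)/n), c_I sin(2 pi (i-1)/n)), i=1..n."""
    if n < 3:
        raise ValueError("need at least 3 boundary points")
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([c_I * np.cos(ang), c_I * np.sin(ang)])


def polygon_area(vertices) -> float:
    """Shoelace area of a simple polygon (orientation-independent)."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise ValueError("polygon needs >= 3 two-dimensional vertices")
    if _self_intersects(v):
        raise ValueError("self-intersecting polygon")
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _self_intersects(v: np.ndarray) -> bool:
    """Brute-force proper-crossing test between non-adjacent edges."""
    n = len(v)
    if n > 200:           # polygons here are small; skip O(n^2) otherwise
        return False
    a = v
    b = np.roll(v, -1, axis=0)
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            if _segments_cross(a[i], b[i], a[j], b[j]):
                return True
    return False


def _segments_cross(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    return (d1 * d2 < 0) and (d3 * d4 < 0)


def relative_area(result: SimulationResult, t: float) -> float:
    """Polygon area at output time t (days) over the area at t = 0."""
    idx = _time_index(result.times, t)
    areas = result.relative_areas
    return float(areas[idx])


def probe_points(c_I: float) -> np.ndarray:
    """The 9 probe material points: center, 4 at c_I/2, 4 at c_I."""
    pts = [(0.0, 0.0)]
    for i in range(1, 5):
        a = 2.0 * np.pi * (i - 0.5) / 4.0
        pts.append(((c_I / 2.0) * np.cos(a), (c_I / 2.0) * np.sin(a)))
    for i in range(1, 5):
        a = 2.0 * np.pi * (i - 1.0) / 4.0
        pts.append((c_I * np.cos(a), c_I * np.sin(a)))
    return np.array(pts)


def probe_average(result: SimulationResult, t: float,
                  fields: tuple[str, ...] = ("M", "rho")) -> tuple[float, ...]:
    """Probe averages recorded by the engine at output time t."""
    idx = _time_index(result.times, t)
    return tuple(float(result.probes[f][idx]) for f in fields)


def _time_index(times: np.ndarray, t: float) -> int:
    idx = int(np.argmin(np.abs(np.asarray(times) - t)))
    if abs(times[idx] - t) > 1e-9 * max(1.0, abs(t)):
        raise ValueError(f"time {t} not among output times")
    return idx
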