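"""Closed-form physiology metrics.

Circumferential cyclic strain of a vessel wall from imaging time
series, and percentage contraction from impedance (cell-index) traces.

Strain uses Eθθ(t) = ½[(r(t)/r(0))² − 1] = [A(t)/A(0) − 1]/2 — the two
forms are algebraically identical for a circular cross-section
(A = πr²), and when both area and radius series are supplied their
agreement is reported.

Contraction normalizes the cell index to 1 at agonist addition and
returns (1 − CI_min) × 100, where CI_min is the minimum normalized CI
within a post-agonist window (default 30 minutes, half-open
(t₀, t₀+30]). Relaxation yields negative percentages, unclamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "circumferential_strain",
    "contraction_percent",
    "StrainSeries",
    "ContractionTrace",
    "StrainResult",
]


@dataclass(frozen=True)
class StrainResult:
    strain_area: np.ndarray | None
    strain_radius: np.ndarray | None
    max_abs_difference: float | None

    @property
    def strain(self) -> np.ndarray:
        s = self.strain_area if self.strain_area is not None else self.strain_radius
        assert s is not None
        return s


def circumferential_strain(areas=None, radii=None) -> StrainResult:
    """Circumferential cyclic strain per timepoint.

    The first element of each series is the reference (t = 0) value and
    must be positive. Supply areas, radii, or both; with both, the two
    strain series and their maximum absolute disagreement are returned.
    """
    if areas is None and radii is None:
        raise ValueError("supply areas and/or radii")
    s_a = s_r = None
    if areas is not None:
        A = np.asarray(areas, dtype=float)
        if A.size == 0 or A[0] <= 0:
            raise ValueError("reference area A(0) must be positive")
        if (A <= 0).any():
            raise ValueError("areas must be positive")
        s_a = (A / A[0] - 1.0) / 2.0
    if radii is not None:
        r = np.asarray(radii, dtype=float)
        if r.size == 0 or r[0] <= 0:
            raise ValueError("reference radius r(0) must be positive")
        if (r <= 0).any():
            raise ValueError("radii must be positive")
        s_r = ((r / r[0]) ** 2 - 1.0) / 2.0
    diff = None
    if s_a is not None and s_r is not None:
        if s_a.shape != s_r.shape:
            raise ValueError("area and radius series must have equal length")
        diff = float(np.max(np.abs(s_a - s_r)))
    return StrainResult(strain_area=s_a, strain_radius=s_r, max_abs_difference=diff)


def contraction_percent(times, ci, agonist_time: float, window: float = 30.0) -> float:
    """Percentage contraction from a cell-index trace.

    ``times`` and ``window`` share one unit (minutes by convention).
    CI is normalized to 1 at the last timepoint at or before
    ``agonist_time``; the minimum normalized CI over the half-open
    window (agonist_time, agonist_time + window] defines the result
    (1 − CI_min) × 100.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(ci, dtype=float)
    if t.size == 0 or t.shape != x.shape:
        raise ValueError("times and ci must be equal-length non-empty series")
    if agonist_time < t[0] or agonist_time > t[-1]:
        raise ValueError("agonist_time must lie within the trace")
    at_idx = np.flatnonzero(t <= agonist_time)[-1]
    ci0 = x[at_idx]
    if ci0 == 0:
        raise ValueError("cell index at agonist addition is zero; cannot normalize")
    norm = x / ci0
    in_window = (t > agonist_time) & (t <= agonist_time + window)
    if not in_window.any():
        raise ValueError("no timepoints inside the post-agonist window")
    ci_min = float(np.min(norm[in_window]))
    return (1.0 - ci_min) * 100.0


@dataclass
class StrainSeries:
    """Imaging time series of a vessel cross-section.

    ``times`` in ms with the reference frame first; at least one of
    ``areas``/``radii`` must be given (positive values).
    """

    times: np.ndarray
    areas: np.ndarray | None = None
    radii: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.areas is None and self.radii is None:
            raise ValueError("StrainSeries needs areas and/or radii")
        for name in ("areas", "radii"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.times.shape:
                    raise ValueError(f"{name} must match times in length")
                setattr(self, name, v)

    def strain(self) -> StrainResult:
        return circumferential_strain(areas=self.areas, radii=self.radii)


@dataclass
class ContractionTrace:
    """Cell-index trace with the agonist-addition time marked."""

    times: np.ndarray
    ci: np.ndarray
    agonist_time: float
    window: float = 30.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ci = np.asarray(self.ci, dtype=float)
        if self.times.size == 0:
            raise ValueError("trace is empty")
        if not (self.times[0] <= self.agonist_time <= self.times[-1]):
            raise ValueError("agonist_time outside trace")

    def contraction_percent(self) -> float:
        return contraction_percent(self.times, self.ci, self.agonist_time, self.window)
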