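"""Whole-vacuole analysis: steady-state currents, current density, J/V curves.

Whole-vacuole currents are normalised to membrane area so that vacuoles of
different size can be pooled: J = I / A in A m^-2.  The area comes either
from the optical diameter (sphere, A = pi d^2) or from the membrane
capacitance with a specific capacitance (default 10 mF m^-2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .gating import Trace

__all__ = [
    "VacuoleGeometry",
    "JVPoint",
    "JVCurve",
    "steady_state_current",
    "current_density",
    "aggregate_jv",
    "DEFAULT_SPECIFIC_CAPACITANCE_MF_M2",
    "DEFAULT_WINDOW_FRACTION",
]

DEFAULT_SPECIFIC_CAPACITANCE_MF_M2 = 10.0
DEFAULT_WINDOW_FRACTION = 0.1


@dataclass(frozen=True)
class VacuoleGeometry:
    """Vacuole sizing: exactly one of optical diameter or capacitance."""

    diameter_um: float | None = None
    capacitance_pF: float | None = None
    specific_capacitance_mF_m2: float = DEFAULT_SPECIFIC_CAPACITANCE_MF_M2

    def __post_init__(self):
        if (self.diameter_um is None) == (self.capacitance_pF is None):
            raise InvalidInputError(
                "set exactly one of diameter_um or capacitance_pF"
            )

    @classmethod
    def from_diameter(cls, diameter_um: float) -> "VacuoleGeometry":
        return cls(diameter_um=diameter_um)

    @classmethod
    def from_capacitance(cls, capacitance_pF: float,
                         specific_capacitance_mF_m2: float =
                         DEFAULT_SPECIFIC_CAPACITANCE_MF_M2) -> "VacuoleGeometry":
        return cls(capacitance_pF=capacitance_pF,
                   specific_capacitance_mF_m2=specific_capacitance_mF_m2)

    @property
    def area_m2(self) -> float:
        if self.diameter_um is not None:
            if self.diameter_um <= 0:
                raise InvalidInputError("diameter must be > 0")
            d = self.diameter_um * 1e-6
            return math.pi * d**2
        if self.capacitance_pF <= 0 or self.specific_capacitance_mF_m2 <= 0:
            raise InvalidInputError("capacitance and specific capacitance must be > 0")
        return (self.capacitance_pF * 1e-12) / (self.specific_capacitance_mF_m2 * 1e-3)


@dataclass(frozen=True)
class JVPoint:
    voltage_mV: float
    density_A_m2: float
    sem_A_m2: float | None = None
    n: int = 1


@dataclass(frozen=True)
class JVCurve:
    """Current density/voltage curve with per-point SEM and n."""

    points: tuple[JVPoint, ...]
    label: str = ""

    def __post_init__(self):
        if not self.points:
            raise InvalidInputError("empty J/V curve")
        if any(not math.isfinite(p.density_A_m2) for p in self.points):
            raise InvalidInputError("non-finite current density")
        object.__setattr__(self, "points",
                           tuple(sorted(self.points, key=lambda p: p.voltage_mV)))

    @property
    def voltages_mV(self) -> np.ndarray:
        return np.array([p.voltage_mV for p in self.points])

    @property
    def densities_A_m2(self) -> np.ndarray:
        return np.array([p.density_A_m2 for p in self.points])


def steady_state_current(sweep: Trace,
                         window_fraction: float = DEFAULT_WINDOW_FRACTION) -> float:
    """Mean current (pA) over the final fraction of the test-pulse segment.

    The channels activate slowly on a voltage step, so the plateau is read
    from the end of the 3 s test pulse; ``window_fraction`` is the trailing
    fraction averaged (default last 10%).
    """
    if not (0.0 < window_fraction <= 0.5):
        raise InvalidInputError("window_fraction must be in (0, 0.5]")
    if sweep.segments_s is not None:
        i0 = int(round(sweep.segments_s.get("holding", 0.0) * sweep.sampling_rate_hz))
        n_test = int(round(sweep.segments_s["test"] * sweep.sampling_rate_hz))
        seg = sweep.samples_pA[i0:i0 + n_test]
    else:
        seg = sweep.samples_pA
    if seg.size < 10:
        raise InvalidInputError("test segment shorter than 10 samples")
    n_win = max(1, int(round(window_fraction * seg.size)))
    return float(seg[-n_win:].mean())


def current_density(current_pA: float, geometry: VacuoleGeometry) -> float:
    """J = I / A in A m^-2 (current in pA)."""
    area = geometry.area_m2
    if area <= 0:
        raise InvalidInputError("membrane area must be > 0")
    return current_pA * 1e-12 / area


def aggregate_jv(curves) -> JVCurve:
    """Pointwise mean +- SEM over per-vacuole J/V curves.

    All curves must share the same voltage grid exactly (grids already
    include any junction-potential shift; no interpolation is done, so
    curves recorded on shifted grids cannot be pooled).  With n = 1 the SEM
    is reported as absent.
    """
    curves = list(curves)
    if not curves:
        raise InvalidInputError("at least one J/V curve required")
    grid = curves[0].voltages_mV
    for c in curves[1:]:
        if len(c.voltages_mV) != len(grid) or not np.allclose(
                c.voltages_mV, grid, rtol=0, atol=1e-9):
            raise InvalidInputError(
                "voltage grids differ; align sweeps before aggregation"
            )
    data = np.vstack([c.densities_A_m2 for c in curves])
    n = data.shape[0]
    mean = data.mean(axis=0)
    sem = data.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else None
    points = tuple(
        JVPoint(voltage_mV=float(v), density_A_m2=float(m),
                sem_A_m2=(float(s) if sem is not None else None), n=n)
        for v, m, s in zip(grid, mean, sem if sem is not None else np.zeros_like(mean))
    )
    return JVCurve(points, label=f"mean of {n} vacuoles")
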