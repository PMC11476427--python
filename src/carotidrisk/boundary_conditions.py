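"""Patient-specific inflow/outflow boundary conditions from ultrasound data.

Carotid duplex ultrasound reports, per artery, the peak systolic velocity
(PSV), the end-diastolic velocity (EDV), the pulse rate and the lumen area at
the measurement site.  This module reconstructs a periodic velocity waveform
over one cardiac cycle from those landmarks, converts it to a mass-flow
waveform (m_dot = rho * V * A), and builds the parabolic (Poiseuille-type)
boundary velocity profiles the flow solver imposes at the CCA inlet and ECA
outlet.

The waveform shape between the two printed landmarks is a modelling choice:
a half-sine systolic pulse of duration ``systolic_fraction * T`` riding on a
constant diastolic baseline — the simplest continuous periodic curve whose
minimum is EDV and whose maximum is PSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MMHG_TO_PA = 133.322


@dataclass(frozen=True)
class FluidProps:
    """Blood treated as an incompressible Newtonian fluid."""

    density: float = 1050.0  # kg/m^3
    viscosity: float = 0.0035  # Pa s (dynamic)

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be strictly positive")


@dataclass
class Waveform:
    """Sampled periodic waveform over one cardiac cycle [0, T].

    ``kind`` is 'velocity' (m/s) or 'massflow' (kg/s per unit out-of-plane
    depth in the planar model).
    """

    times: np.ndarray
    values: np.ndarray
    kind: str
    period: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("velocity", "massflow"):
            raise ValueError(f"unknown waveform kind {self.kind!r}")
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.times[0] != 0.0 or not np.isclose(self.times[-1], self.period):
            raise ValueError("waveform must span exactly [0, T]")
        if not np.isclose(self.values[0], self.values[-1], rtol=1e-9, atol=1e-12):
            raise ValueError("waveform must be periodic: value(0) == value(T)")
        if self.kind == "velocity" and np.any(self.values <= 0):
            raise ValueError("velocity waveform values must be positive")

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        """Periodic interpolation at arbitrary times."""
        tau = np.mod(t, self.period)
        return np.interp(tau, self.times, self.values)

    def resample(self, times: np.ndarray) -> "Waveform":
        times = np.asarray(times, dtype=float)
        return Waveform(times, self(times), self.kind, self.period)

    # -- serialization (two-column CSV + JSON sidecar) ----------------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(
            path,
            np.column_stack([self.times, self.values]),
            delimiter=",",
            header="t,value",
            comments="",
        )
        sidecar = {"kind": self.kind, "period": self.period,
                   "units": "m/s" if self.kind == "velocity" else "kg/s"}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Waveform":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(data[:, 0], data[:, 1], meta["kind"], meta["period"])


def cycle_duration(pulse_rate: float) -> float:
    """Cardiac-cycle duration T (s) from the pulse rate (beats/min)."""
    if not 30.0 <= pulse_rate <= 200.0:
        raise ValueError(f"pulse rate {pulse_rate} outside physiologic range [30, 200] bpm")
    return 60.0 / pulse_rate


def velocity_waveform(
    psv: float,
    edv: float,
    period: float,
    systolic_fraction: float = 0.3,
    n_samples: int = 201,
) -> Waveform:
    """Periodic velocity waveform with min EDV and max PSV.

    The cycle starts at end-diastole: value(0) = EDV.  A half-sine pulse
    occupies t in [0, systolic_fraction * T]; the remainder of the cycle sits
    at the diastolic baseline.
    """
    if not 0 < edv < psv:
        raise ValueError("require 0 < EDV < PSV")
    if not 0 < systolic_fraction < 1:
        raise ValueError("systolic_fraction must lie in (0, 1)")
    t = np.linspace(0.0, period, n_samples)
    t_peak = 0.5 * systolic_fraction * period
    # make sure the peak is an actual sample so max(values) == PSV exactly
    if not np.any(np.isclose(t, t_peak)):
        t = np.sort(np.append(t, t_peak))
    v = np.full_like(t, edv)
    sys_mask = t <= systolic_fraction * period
    u = t[sys_mask] / (systolic_fraction * period)
    v[sys_mask] = edv + (psv - edv) * np.sin(np.pi * u)
    # guard rounding at the pulse edges
    v = np.clip(v, edv, psv)
    return Waveform(t, v, "velocity", period)


def mass_flow_waveform(w: Waveform, area: float, props: FluidProps) -> Waveform:
    """Pointwise conversion m_dot(t) = rho * V(t) * A."""
    if w.kind != "velocity":
        raise ValueError("mass_flow_waveform expects a velocity waveform")
    if area <= 0:
        raise ValueError("area must be positive")
    return Waveform(w.times.copy(), props.density * w.values * area, "massflow", w.period)


@dataclass
class ParabolicProfile:
    """Parabolic (Poiseuille-type) velocity profile across a boundary of
    width ``width``: v(xi) = v_max * (1 - (2 xi / width)^2), xi in
    [-width/2, width/2], scaled so the integrated per-unit-depth mass flux
    rho * \\int v dxi equals ``target_massflow``.
    """

    target_massflow: float
    width: float
    density: float
    v_max: float = field(init=False)

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("boundary width must be positive")
        mean = self.target_massflow / (self.density * self.width)
        self.v_max = 1.5 * mean  # parabola: peak = 1.5 x mean

    def __call__(self, xi: np.ndarray) -> np.ndarray:
        """Velocity magnitude at transverse offset(s) xi from the centre."""
        xi = np.asarray(xi, dtype=float)
        return self.v_max * (1.0 - (2.0 * xi / self.width) ** 2)


def inflow_velocity_profile(
    target_massflow: float, boundary_width: float, props: FluidProps
) -> ParabolicProfile:
    """Boundary velocity profile carrying ``target_massflow`` (kg/s per unit
    depth) across a straight boundary segment of the given width."""
    return ParabolicProfile(target_massflow, boundary_width, props.density)
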