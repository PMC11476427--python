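"""Simulation-derived hemodynamic features.

Computes, from a wall shear record and boundary pressure traces over one
cardiac cycle, the feature set fed to the event-prediction model:

* TAWSS: time-averaged magnitude of the instantaneous wall shear stress,
  TAWSS = (1/T) \\int_0^T |tau_w| dt.  The magnitude convention is used so
  TAWSS is non-negative and the low-TAWSS threshold (0.4 Pa, the level below
  which atherogenesis is favoured) is meaningful.
* OSI: oscillatory shear index,
  OSI = 1/2 * (1 - |(1/T)\\int tau_w dt| / ((1/T)\\int |tau_w| dt)),
  ranging 0 (purely unidirectional shear) to 0.5 (zero-mean oscillation).
* Wall fractions: the fraction of wall length with TAWSS below 0.4 Pa and
  with OSI above a configurable cut (default 0.2).  In the planar model all
  "normalized areas" are boundary-length fractions.
* Pressure ratios P_ECA/P_CCA and P_ICA/P_CCA from cycle-mean absolute
  boundary pressures (gauge traces plus a diastolic reference offset,
  default 80 mmHg; without the offset the zero-pressure ICA outlet would
  force P_ICA/P_CCA to zero identically).

A high-TAWSS flag (>40 Pa, the endothelial-damage level) is logged as a
diagnostic but is not part of the model feature set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .boundary_conditions import MMHG_TO_PA

logger = logging.getLogger(__name__)

LOW_TAWSS_THRESHOLD = 0.4  # Pa
HIGH_TAWSS_THRESHOLD = 40.0  # Pa, diagnostic only
DEFAULT_OSI_THRESHOLD = 0.2
DEFAULT_PRESSURE_OFFSET = 80.0 * MMHG_TO_PA  # diastolic reference, Pa


@dataclass
class HemodynamicFeatures:
    """Per-case simulation feature row."""

    peak_tawss: float  # Pa
    vessel_avg_tawss: float  # Pa
    vessel_avg_osi: float
    frac_low_tawss: float
    frac_high_osi: float
    p_eca_over_cca: float
    p_ica_over_cca: float

    def validate(self) -> None:
        if not 0 <= self.vessel_avg_tawss <= self.peak_tawss:
            raise ValueError("require peak_tawss >= vessel_avg_tawss >= 0")
        if not 0 <= self.vessel_avg_osi <= 0.5:
            raise ValueError("vessel-average OSI outside [0, 0.5]")
        for f in (self.frac_low_tawss, self.frac_high_osi):
            if not 0 <= f <= 1:
                raise ValueError("wall fractions must lie in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {
            "peak_tawss": self.peak_tawss,
            "vessel_avg_tawss": self.vessel_avg_tawss,
            "vessel_avg_osi": self.vessel_avg_osi,
            "norm_area_low_tawss": self.frac_low_tawss,
            "norm_area_high_osi": self.frac_high_osi,
            "p_eca_over_cca": self.p_eca_over_cca,
            "p_ica_over_cca": self.p_ica_over_cca,
        }


def _check_cycle(times: np.ndarray, period: float) -> None:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 3:
        raise ValueError("need a 1-D time grid with at least 3 samples")
    if not np.isclose(times[0], 0.0, atol=1e-12) or not np.isclose(times[-1], period):
        raise ValueError("record must span exactly one cycle [0, T]")
    dt = np.diff(times)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-8):
        raise ValueError("cycle sampling must be uniform")


def tawss(record) -> np.ndarray:
    """Per-wall-point time-averaged |tau_w| (Pa) over one cycle.

    ``record`` needs attributes ``times`` (nt,), ``tau`` (n_points, nt) and
    ``period``.
    """
    _check_cycle(record.times, record.period)
    return np.trapezoid(np.abs(record.tau), record.times, axis=1) / record.period


def osi(record) -> np.ndarray:
    """Per-wall-point oscillatory shear index in [0, 0.5].

    Wall points with zero shear over the whole cycle (0/0 in the defining
    ratio) are assigned OSI 0: no shear means no directional oscillation.
    """
    _check_cycle(record.times, record.period)
    mean_signed = np.trapezoid(record.tau, record.times, axis=1) / record.period
    mean_abs = np.trapezoid(np.abs(record.tau), record.times, axis=1) / record.period
    out = np.zeros_like(mean_abs)
    nz = mean_abs > 0
    out[nz] = 0.5 * (1.0 - np.abs(mean_signed[nz]) / mean_abs[nz])
    return np.clip(out, 0.0, 0.5)


def _length_fraction(values: np.ndarray, arclengths: np.ndarray, mask_fn) -> float:
    """Fraction of wall length whose segments satisfy ``mask_fn`` of the
    segment-mean field value.  Segments are classified by the mean of their
    endpoint values."""
    seg_len = np.diff(arclengths)
    seg_val = 0.5 * (values[:-1] + values[1:])
    total = seg_len.sum()
    return float(seg_len[mask_fn(seg_val)].sum() / total)


def feature_summary(
    tawss_field: np.ndarray,
    osi_field: np.ndarray,
    wall_arclengths: np.ndarray,
    pressure_traces: dict[str, np.ndarray],
    times: np.ndarray,
    period: float,
    low_tawss_threshold: float = LOW_TAWSS_THRESHOLD,
    osi_threshold: float = DEFAULT_OSI_THRESHOLD,
    pressure_offset: float = DEFAULT_PRESSURE_OFFSET,
    pressure_statistic: str = "cycle_mean",
) -> HemodynamicFeatures:
    """Collapse wall fields and boundary pressures into the model features.

    ``pressure_traces`` maps 'inlet'/'outlet_ica'/'outlet_eca' to gauge
    pressure traces (Pa) on the cycle time grid.  ``pressure_statistic`` is
    'cycle_mean' (default) or 'systolic_peak'.
    """
    tawss_field = np.asarray(tawss_field, dtype=float)
    osi_field = np.asarray(osi_field, dtype=float)
    s = np.asarray(wall_arclengths, dtype=float)
    if not (tawss_field.shape == osi_field.shape == s.shape):
        raise ValueError("TAWSS, OSI and arc-length arrays must share one wall "
                         "discretization")
    if np.any(np.diff(s) <= 0):
        raise ValueError("wall arc-lengths must be strictly increasing")

    # arc-length (trapezoid) weighted wall statistics
    weights = np.gradient(s)
    weights[0] = 0.5 * (s[1] - s[0])
    weights[-1] = 0.5 * (s[-1] - s[-2])
    total = weights.sum()
    peak = float(tawss_field.max())
    avg_tawss = float((weights * tawss_field).sum() / total)
    avg_osi = float((weights * osi_field).sum() / total)
    frac_low = _length_fraction(tawss_field, s, lambda v: v < low_tawss_threshold)
    frac_high_osi = _length_fraction(osi_field, s, lambda v: v > osi_threshold)

    frac_high_tawss = _length_fraction(tawss_field, s, lambda v: v > HIGH_TAWSS_THRESHOLD)
    if frac_high_tawss > 0:
        logger.info("diagnostic: %.1f%% of wall length above %g Pa TAWSS",
                    100 * frac_high_tawss, HIGH_TAWSS_THRESHOLD)

    def stat(trace: np.ndarray) -> float:
        trace = np.asarray(trace, dtype=float)
        if pressure_statistic == "cycle_mean":
            g = np.trapezoid(trace, times) / period
        elif pressure_statistic == "systolic_peak":
            g = trace.max()
        else:
            raise ValueError(f"unknown pressure statistic {pressure_statistic!r}")
        return float(g + pressure_offset)

    p_cca = stat(pressure_traces["inlet"])
    feats = HemodynamicFeatures(
        peak_tawss=peak,
        vessel_avg_tawss=avg_tawss,
        vessel_avg_osi=avg_osi,
        frac_low_tawss=frac_low,
        frac_high_osi=frac_high_osi,
        p_eca_over_cca=stat(pressure_traces["outlet_eca"]) / p_cca,
        p_ica_over_cca=stat(pressure_traces["outlet_ica"]) / p_cca,
    )
    feats.validate()
    return feats
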