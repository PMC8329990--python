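"""Nanoflow cytometry quantification.

Sizing uses a standard curve anchored on silica bead knots: side-scatter
modes are located by 1-D k-means (quantile-initialized, deterministic),
paired with the known bead diameters, and interpolated piecewise-linearly on
log-log axes (scatter grows as a strong power of diameter for sub-wavelength
silica, so a power law is locally exact and the interpolant is monotone).
Concentration scales the known bead concentration by the event-rate ratio
and dilution.  Positivity gates are set at a high quantile of a negative
control; percentages use a strictly-above rule, and MFI is reported over the
total population (with the positives-only variant alongside).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from evcq._errors import CalibrationError, ConfigError, EvcqError

__all__ = [
    "SizeStandardCurve",
    "ConcentrationCalibration",
    "Gate",
    "fit_size_curve",
    "apply_size_curve",
    "calibrate_concentration",
    "sample_concentration",
    "subtract_blank",
    "set_gate",
    "quantify_positive",
    "purity",
]

_CHANNEL_COLUMNS = {"green": "fl_green_adu", "red": "fl_red_adu", "ssc": "ssc_adu"}


@dataclass(frozen=True)
class SizeStandardCurve:
    """Monotone SSC -> diameter mapping through bead knots.

    Knots are ``(ssc_adu, diameter_nm)`` pairs strictly increasing in both
    coordinates; between knots the curve is linear in (log SSC, log diameter),
    beyond them it extrapolates with the end-segment slope.  Evaluation at a
    knot's SSC returns that knot's diameter exactly.
    """

    knots_ssc_adu: np.ndarray
    knots_diameter_nm: np.ndarray
    interpolation: str = "log-log-linear"

    def __post_init__(self) -> None:
        s = np.asarray(self.knots_ssc_adu, dtype=float)
        d = np.asarray(self.knots_diameter_nm, dtype=float)
        if s.size != d.size or s.size < 2:
            raise ConfigError("need >= 2 (ssc, diameter) knots of equal length")
        if np.any(np.diff(s) <= 0) or np.any(np.diff(d) <= 0):
            raise CalibrationError(
                "degenerate bead data: knots must increase strictly in both axes"
            )
        if np.any(s <= 0) or np.any(d <= 0):
            raise ConfigError("knots must be positive")
        object.__setattr__(self, "knots_ssc_adu", s)
        object.__setattr__(self, "knots_diameter_nm", d)

    def __call__(self, ssc_adu) -> np.ndarray:
        ssc = np.atleast_1d(np.asarray(ssc_adu, dtype=float))
        ls = np.log(self.knots_ssc_adu)
        ld = np.log(self.knots_diameter_nm)
        with np.errstate(divide="ignore"):
            lx = np.log(ssc)
        out = np.interp(lx, ls, ld)
        # extrapolate with end slopes beyond the knot range
        lo = lx < ls[0]
        hi = lx > ls[-1]
        if lo.any():
            slope = (ld[1] - ld[0]) / (ls[1] - ls[0])
            out[lo] = ld[0] + slope * (lx[lo] - ls[0])
        if hi.any():
            slope = (ld[-1] - ld[-2]) / (ls[-1] - ls[-2])
            out[hi] = ld[-1] + slope * (lx[hi] - ls[-1])
        res = np.exp(out)
        # exact knot identity, untouched by log/exp round-trip error
        for s, d in zip(self.knots_ssc_adu, self.knots_diameter_nm):
            res[ssc == s] = d
        if np.isscalar(ssc_adu):
            return float(res[0])
        return res


@dataclass(frozen=True)
class ConcentrationCalibration:
    """Event-rate -> particles/ml scaling from the concentration bead standard."""

    bead_known_concentration_per_ml: float
    bead_event_rate_per_min: float

    def __post_init__(self) -> None:
        if self.bead_known_concentration_per_ml <= 0:
            raise ConfigError("bead concentration must be > 0")
        if self.bead_event_rate_per_min <= 0:
            raise CalibrationError("invalid standard: bead event rate must be > 0")

    @property
    def particles_per_ml_per_event_rate(self) -> float:
        return self.bead_known_concentration_per_ml / self.bead_event_rate_per_min


@dataclass(frozen=True)
class Gate:
    """Positivity threshold for one fluorescence channel, with provenance."""

    channel: str
    threshold_adu: float
    quantile: float
    control_id: str = ""

    def __post_init__(self) -> None:
        if self.channel not in ("green", "red"):
            raise ConfigError("gate channel must be 'green' or 'red'")
        if self.threshold_adu < 0:
            raise ConfigError("threshold must be >= 0")


def _channel_values(events: pd.DataFrame, channel: str) -> np.ndarray:
    col = _CHANNEL_COLUMNS.get(channel, channel)
    if col not in events.columns:
        raise ConfigError(f"events table lacks channel column {col!r}")
    return events[col].to_numpy(dtype=float)


def fit_size_curve(
    bead_events: pd.DataFrame,
    bead_diameters_nm: Sequence[float],
    random_state: int = 0,
) -> SizeStandardCurve:
    """Fit the size standard curve from a multimodal bead acquisition.

    SSC modes are found by 1-D k-means with k = number of diameters,
    initialized at evenly spaced SSC quantiles (deterministic); each mode's
    median SSC is paired with the corresponding diameter in ascending order.
    """
    diams = np.sort(np.asarray(bead_diameters_nm, dtype=float))
    if diams.size < 2:
        raise ConfigError("need at least two bead diameters")
    ssc = _channel_values(bead_events, "ssc")
    if ssc.size < diams.size:
        raise CalibrationError("degenerate bead data: fewer events than modes")
    k = diams.size
    init = np.quantile(ssc, (np.arange(k) + 0.5) / k).reshape(-1, 1)
    km = KMeans(n_clusters=k, init=init, n_init=1, random_state=random_state)
    labels = km.fit_predict(ssc.reshape(-1, 1))
    medians = np.sort(
        [float(np.median(ssc[labels == c])) for c in range(k)]
    )
    if np.any(np.diff(medians) <= 0):
        raise CalibrationError("degenerate bead data: SSC modes are not separated")
    return SizeStandardCurve(np.asarray(medians), diams)


def apply_size_curve(
    events: pd.DataFrame,
    curve: SizeStandardCurve,
    extrapolate: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Per-event diameters plus a summary (median, mean +- sd).

    With ``extrapolate=False`` events below the smallest knot are flagged
    ``below_calibration_range`` and their diameter set to NaN instead of
    being silently extrapolated.
    """
    out = events.copy()
    if len(events) == 0:
        out["diameter_nm"] = pd.Series(dtype=float)
        out["below_calibration_range"] = pd.Series(dtype=bool)
        return out, {"n": 0, "median_nm": None, "mean_nm": None, "sd_nm": None}
    ssc = _channel_values(events, "ssc")
    d = np.asarray(curve(ssc), dtype=float)
    below = ssc < curve.knots_ssc_adu[0]
    if not extrapolate:
        d = d.copy()
        d[below] = np.nan
    out["diameter_nm"] = d
    out["below_calibration_range"] = below
    valid = d[np.isfinite(d)]
    summary = {
        "n": int(valid.size),
        "median_nm": float(np.median(valid)) if valid.size else None,
        "mean_nm": float(valid.mean()) if valid.size else None,
        "sd_nm": float(valid.std(ddof=1)) if valid.size > 1 else None,
    }
    return out, summary


def calibrate_concentration(
    bead_event_rate_per_min: float,
    bead_known_concentration_per_ml: float,
) -> ConcentrationCalibration:
    return ConcentrationCalibration(
        bead_known_concentration_per_ml=bead_known_concentration_per_ml,
        bead_event_rate_per_min=bead_event_rate_per_min,
    )


def sample_concentration(
    sample_event_rate_per_min: float,
    calibration: ConcentrationCalibration,
    dilution_factor: float = 1.0,
) -> float:
    """known_concentration x (sample rate / bead rate) x dilution factor."""
    if sample_event_rate_per_min < 0 or dilution_factor <= 0:
        raise ConfigError("sample rate must be >= 0 and dilution > 0")
    return (
        calibration.particles_per_ml_per_event_rate
        * sample_event_rate_per_min
        * dilution_factor
    )


def subtract_blank(
    sample_counts: Sequence[float], blank_counts: Sequence[float]
) -> np.ndarray:
    """Element-wise blank (PBS) subtraction, clipped at zero."""
    s = np.asarray(sample_counts, dtype=float)
    b = np.asarray(blank_counts, dtype=float)
    if s.shape != b.shape:
        raise ConfigError(
            f"binning mismatch: sample {s.shape} vs blank {b.shape}"
        )
    return np.clip(s - b, 0.0, None)


def set_gate(
    control_events: pd.DataFrame,
    channel: str,
    quantile: float = 0.995,
    control_id: str = "",
    min_events: int = 200,
) -> Gate:
    """Gate at a high quantile of the negative-control channel distribution."""
    if not 0.0 < quantile < 1.0:
        raise ConfigError("quantile must be in (0, 1)")
    vals = _channel_values(control_events, channel)
    if vals.size < min_events:
        raise CalibrationError(
            f"control underpowered: {vals.size} events, need >= {min_events}"
        )
    return Gate(
        channel=channel,
        threshold_adu=float(np.quantile(vals, quantile)),
        quantile=quantile,
        control_id=control_id,
    )


def quantify_positive(events: pd.DataFrame, gate: Gate) -> dict:
    """Percent positive (strictly above threshold), MFI over all events,
    and MFI over positives.

    Events exactly at the threshold count as negative.  MFI over the total
    population is the primary enrichment readout; the positives-only MFI is
    reported alongside (NaN when there are no positives).
    """
    if len(events) == 0:
        raise EvcqError("empty event set")
    vals = _channel_values(events, gate.channel)
    pos = vals > gate.threshold_adu
    n_pos = int(pos.sum())
    return {
        "n_events": int(vals.size),
        "n_positive": n_pos,
        "percent_positive": 100.0 * n_pos / vals.size,
        "mfi_all": float(vals.mean()),
        "mfi_positive": float(vals[pos].mean()) if n_pos else float("nan"),
    }


def purity(events: pd.DataFrame, red_gate: Gate) -> float:
    """Percent of events above the membrane-dye (red) gate = vesicular fraction."""
    if red_gate.channel != "red":
        raise ConfigError("purity requires a red-channel gate")
    if len(events) == 0:
        return 0.0
    vals = _channel_values(events, "red")
    return 100.0 * float((vals > red_gate.threshold_adu).mean())
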