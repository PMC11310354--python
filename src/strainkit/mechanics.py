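"""Tendon mechanics: bulk strain, stress, apparent modulus, regressions.

Converts a predicted strain sequence plus a grip-force trace into the
bulk longitudinal strain (pooled median of exx over the tendon region
and the hold window), a stress-strain curve (tendon force over
cross-sectional area), and the apparent modulus — the slope of the most
linear contiguous stretch of the loading-phase curve.  "Apparent"
because the boundary conditions are physiological rather than
controlled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .inference import SequencePrediction
from .types import LoadProtocol, TendonGeometry

__all__ = [
    "ForceTrace",
    "StressStrainRecord",
    "bulk_longitudinal_strain",
    "tendon_force",
    "stress",
    "apparent_modulus",
    "effort_regression",
    "stress_strain_record",
]

#: Default grip-to-tendon force transmission coefficient.  A placeholder
#: scalar for the biomechanical grip-to-FDS-tendon relation; configure it
#: to a subject-specific value when one is available.
DEFAULT_TRANSMISSION = 0.25


@dataclass
class ForceTrace:
    """A time-stamped grip-force recording for one trial."""

    time: np.ndarray
    grip_force: np.ndarray
    effort_level: float = np.nan
    mvc: float = np.nan

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.grip_force = np.asarray(self.grip_force, dtype=float)
        if self.time.shape != self.grip_force.shape or self.time.ndim != 1:
            raise ValueError("time and grip_force must be equal-length 1-D")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.grip_force < 0):
            raise ValueError("forces must be >= 0")

    @classmethod
    def from_csv(cls, path, effort_level: float = np.nan,
                 mvc: float = np.nan) -> "ForceTrace":
        df = pd.read_csv(path)
        for col in ("time_s", "grip_force_N"):
            if col not in df.columns:
                raise ValueError(f"force CSV must have a {col!r} column")
        return cls(df["time_s"].to_numpy(), df["grip_force_N"].to_numpy(),
                   effort_level, mvc)


@dataclass
class StressStrainRecord:
    """Time-resolved stress/strain of one trial plus its fitted modulus."""

    time: np.ndarray
    tendon_force: np.ndarray
    stress: np.ndarray
    bulk_strain_series: np.ndarray
    csa: float
    apparent_modulus: float
    linear_region: tuple[int, int]
    bulk_strain_hold: float


def bulk_longitudinal_strain(
    prediction: SequencePrediction,
    geometry: TendonGeometry,
    hold_window: tuple[float, float],
    frame_times: np.ndarray,
) -> float:
    """Pooled median of exx over tendon pixels and hold-window frames.

    ``frame_times`` gives the acquisition time of each predicted field
    (frames 2..T of the sequence).
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if len(frame_times) != len(prediction.fields):
        raise ValueError("one time stamp per predicted field required")
    t0, t1 = hold_window
    sel = (frame_times >= t0) & (frame_times <= t1)
    if not sel.any():
        raise ValueError("hold window contains no frames")
    mask = geometry.tendon_mask
    if not mask.any():
        raise ValueError("tendon mask is empty")
    pooled = np.concatenate(
        [f.exx[mask] for f, s in zip(prediction.fields, sel) if s]
    )
    return float(np.median(pooled))


def tendon_force(
    grip_force, transmission: float = DEFAULT_TRANSMISSION
):
    """Map grip force (N) to tendon force (N) with a linear coefficient."""
    if transmission <= 0:
        raise ValueError("transmission coefficient must be positive")
    grip_force = np.asarray(grip_force, dtype=float)
    if np.any(grip_force < 0):
        raise ValueError("grip force must be >= 0")
    out = transmission * grip_force
    return float(out) if out.ndim == 0 else out


def stress(tendon_force_n, csa_mm2: float):
    """Engineering stress in MPa from force (N) and area (mm^2)."""
    if csa_mm2 <= 0:
        raise ValueError("cross-sectional area must be positive")
    out = np.asarray(tendon_force_n, dtype=float) / csa_mm2
    return float(out) if out.ndim == 0 else out


def apparent_modulus(
    stress_series: Sequence[float],
    strain_series: Sequence[float],
    window_fraction: float = 0.4,
) -> tuple[float, tuple[int, int]]:
    """Slope (MPa) of the most linear window of a stress-strain curve.

    Scans every contiguous window covering at least ``window_fraction``
    of the points and returns the OLS slope of the window with the
    highest coefficient of determination; ties prefer longer windows.
    """
    sig = np.asarray(stress_series, dtype=float)
    eps = np.asarray(strain_series, dtype=float)
    if sig.shape != eps.shape or sig.ndim != 1:
        raise ValueError("stress and strain must be equal-length 1-D")
    n = sig.size
    if n < 5:
        raise ValueError("need at least 5 loading-phase points")
    if np.ptp(eps) == 0:
        raise ValueError("strain is constant; modulus undefined")
    min_len = max(int(np.ceil(window_fraction * n)), 3)

    best = (-np.inf, 0, None, None)  # (r2, length, slope, window)
    for length in range(min_len, n + 1):
        for start in range(0, n - length + 1):
            e = eps[start: start + length]
            s = sig[start: start + length]
            if np.ptp(e) == 0:
                continue
            slope, intercept = np.polyfit(e, s, 1)
            resid = s - (slope * e + intercept)
            ss_tot = np.sum((s - s.mean()) ** 2)
            r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
            if (r2, length) > (best[0], best[1]):
                best = (r2, length, slope, (start, start + length))
    if best[2] is None:
        raise ValueError("no usable window found")
    return float(best[2]), best[3]


def effort_regression(
    effort_levels: Sequence[float],
    responses: Sequence[float],
    subjects: Sequence | None = None,
) -> tuple[float, float, float]:
    """Linear regression of a per-trial response on effort level.

    With more than one subject, subject enters as a fixed blocking term
    (repeated-measures style); otherwise plain OLS.  Returns
    (slope, r_squared, p_value) for the effort coefficient.
    """
    x = np.asarray(effort_levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 (effort, response) trials")
    df = pd.DataFrame({"effort": x, "response": y})
    formula = "response ~ effort"
    if subjects is not None:
        df["subject"] = list(subjects)
        if df["subject"].nunique() > 1:
            formula += " + C(subject)"
    fit = smf.ols(formula, data=df).fit()
    r2 = float(fit.rsquared)
    p = float(fit.pvalues["effort"])
    # degenerate (constant) responses: report no fit rather than NaN
    return (
        float(fit.params["effort"]),
        r2 if np.isfinite(r2) else 0.0,
        p if np.isfinite(p) else 1.0,
    )


def stress_strain_record(
    prediction: SequencePrediction,
    force: ForceTrace,
    geometry: TendonGeometry,
    csa_mm2: float,
    frame_times: np.ndarray,
    protocol: LoadProtocol = LoadProtocol(),
    transmission: float = DEFAULT_TRANSMISSION,
    window_fraction: float = 0.4,
) -> StressStrainRecord:
    """Assemble the full stress-strain analysis of one trial.

    Grip force is interpolated to the frame times; bulk strain per frame
    is the median exx over the tendon mask.  The modulus fit uses the
    loading ramp (the phase where stress actually increases); when the
    ramp holds fewer than 5 frames the fit extends through the hold so
    the regression stays determined.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    grip_at_frames = np.interp(frame_times, force.time, force.grip_force)
    tf = tendon_force(grip_at_frames, transmission)
    sig = stress(tf, csa_mm2)
    mask = geometry.tendon_mask
    eps = np.array([float(np.median(f.exx[mask])) for f in prediction.fields])

    loading = frame_times <= protocol.ramp_s
    if loading.sum() < 5:
        loading = frame_times <= protocol.ramp_s + protocol.hold_s
    modulus, region = apparent_modulus(
        sig[loading], eps[loading], window_fraction
    )
    hold = (protocol.ramp_s, protocol.ramp_s + protocol.hold_s)
    bulk = bulk_longitudinal_strain(prediction, geometry, hold, frame_times)
    return StressStrainRecord(
        time=frame_times,
        tendon_force=tf,
        stress=sig,
        bulk_strain_series=eps,
        csa=csa_mm2,
        apparent_modulus=modulus,
        linear_region=region,
        bulk_strain_hold=bulk,
    )
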