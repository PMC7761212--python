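"""Size-exclusion chromatography: peak metrics, calibration, apparent mass.

A gel-filtration column separates on hydrodynamic size, and over its useful
range log10(MW) is linear in elution volume.  Fitting that line on standard
proteins turns an elution volume into an apparent molecular mass.  The peak
metrics also yield the on-column dilution factor — peak width at half height
divided by the injected volume — needed to convert loaded to on-column
concentrations for equilibrium work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    HemequilWarning,
    InsufficientDataError,
    MultiPeakError,
    TruncatedPeakError,
)
from .io_spectra import Chromatogram

__all__ = [
    "PeakMetrics",
    "SecCalibration",
    "peak_metrics",
    "fit_sec_calibration",
    "apparent_mw",
]

#: Fraction of samples at each trace end used for the baseline estimate.
BASELINE_EDGE_FRACTION = 0.05

#: Minimum length (samples) of a disjoint above-half-max run that counts as a
#: second peak; shorter excursions are treated as noise.
_MIN_SECOND_PEAK_RUN = 3


@dataclass
class PeakMetrics:
    """Apex position/height, FWHM and the derived dilution factor."""

    apex_volume_ml: float
    apex_height: float
    fwhm_ml: float
    dilution_factor: float

    def __post_init__(self):
        if self.fwhm_ml <= 0:
            raise ValueError("fwhm_ml must be > 0")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")


@dataclass
class SecCalibration:
    """log10(MW/kDa) = intercept + slope * Ve, fitted on standards."""

    slope: float
    intercept: float
    r_squared: float
    standards: list = field(default_factory=list)

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        if len(self.standards) < 3:
            raise ValueError("calibration needs >= 3 standards")

    @property
    def ve_range_ml(self) -> tuple[float, float]:
        ves = [ve for *_, ve in self.standards]
        return min(ves), max(ves)


def peak_metrics(chrom: Chromatogram, smooth_window: int = 1) -> PeakMetrics:
    """Apex, height, FWHM and dilution factor of a single-peak chromatogram.

    A baseline (median of the first and last 5% of samples) is subtracted
    first.  The apex is refined by a parabola through the three samples
    around the maximum; the FWHM comes from linear interpolation of the two
    half-maximum crossings.  ``smooth_window`` > 1 applies adjacent-average
    smoothing before the metrics — recommended for noisy traces, at a small
    cost in width fidelity.

    Raises :class:`TruncatedPeakError` if the maximum sits at a trace end and
    :class:`MultiPeakError` if a second region rises above half-maximum.
    """
    from .io_spectra import smooth_adjacent_average

    v = chrom.volume_ml
    s = chrom.signal.astype(float)
    if smooth_window > 1:
        s = smooth_adjacent_average(s, smooth_window)

    n_edge = max(1, int(round(BASELINE_EDGE_FRACTION * s.size)))
    baseline = float(np.median(np.concatenate([s[:n_edge], s[-n_edge:]])))
    s = s - baseline

    i_max = int(np.argmax(s))
    ties = np.flatnonzero(s == s[i_max])
    if ties.size > 1:
        warnings.warn(
            "tied maxima in chromatogram; using the leftmost",
            HemequilWarning,
            stacklevel=2,
        )
    if i_max == 0 or i_max == s.size - 1:
        raise TruncatedPeakError("truncated peak: maximum at trace boundary")

    # 3-point parabolic refinement of the apex.
    y1, y2, y3 = s[i_max - 1 : i_max + 2]
    denom = y1 - 2 * y2 + y3
    if denom >= 0:  # flat or concave-up triplet: keep the sample apex
        apex_v = float(v[i_max])
        apex_h = float(y2)
    else:
        delta = 0.5 * (y1 - y3) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
        h = v[i_max + 1] - v[i_max] if delta >= 0 else v[i_max] - v[i_max - 1]
        apex_v = float(v[i_max] + delta * h)
        apex_h = float(y2 - 0.25 * (y1 - y3) * delta)

    half = apex_h / 2.0
    above = s >= half
    runs = _runs(above)
    main = next((r for r in runs if r[0] <= i_max < r[1]), None)
    if main is None:  # numerical corner: apex sample below interpolated half
        raise MultiPeakError("could not locate the half-maximum region")
    others = [r for r in runs if r is not main and r[1] - r[0] >= _MIN_SECOND_PEAK_RUN]
    if others:
        raise MultiPeakError(
            "multi-peak trace: more than one region above half-maximum"
        )

    lo, hi = main
    if lo == 0 or hi == s.size:
        raise TruncatedPeakError("truncated peak: half-maximum region hits boundary")
    left = _cross(v, s, lo - 1, lo, half)
    right = _cross(v, s, hi - 1, hi, half)
    fwhm = right - left
    return PeakMetrics(
        apex_volume_ml=apex_v,
        apex_height=apex_h,
        fwhm_ml=fwhm,
        dilution_factor=fwhm / chrom.load_volume_ml,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of consecutive True values."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return [(int(a), int(b)) for a, b in zip(idx[::2], idx[1::2])]


def _cross(v, s, i, j, level) -> float:
    """Volume where the segment (i, j) crosses ``level``, by linear interp."""
    if s[j] == s[i]:
        return float(v[i])
    frac = (level - s[i]) / (s[j] - s[i])
    return float(v[i] + frac * (v[j] - v[i]))


def fit_sec_calibration(standards) -> SecCalibration:
    """Least-squares line of log10(MW/kDa) on elution volume.

    ``standards`` is a sequence of ``(mw_kda, ve_ml)`` or
    ``(name, mw_kda, ve_ml)`` tuples.  A non-negative slope (larger proteins
    eluting later) is physically implausible and triggers a warning.
    """
    named = []
    for entry in standards:
        if len(entry) == 3:
            named.append((str(entry[0]), float(entry[1]), float(entry[2])))
        else:
            mw, ve = entry
            named.append((f"{float(mw):g}kDa", float(mw), float(ve)))
    if len(named) < 3:
        raise InsufficientDataError("calibration needs >= 3 standards")
    ve = np.array([e[2] for e in named])
    if np.unique(ve).size < len(named):
        raise ValueError("standards must have distinct elution volumes")
    log_mw = np.log10([e[1] for e in named])
    fit = stats.linregress(ve, log_mw)
    if fit.slope >= 0:
        warnings.warn(
            "non-physical calibration: slope >= 0 (larger proteins should "
            "elute earlier)",
            HemequilWarning,
            stacklevel=2,
        )
    return SecCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        standards=named,
    )


def apparent_mw(cal: SecCalibration, ve_ml: float) -> float:
    """Apparent molecular mass (kDa) at elution volume ``ve_ml``.

    Warns when ``ve_ml`` falls more than 10% of the calibrated span outside
    the standards' range (extrapolation).
    """
    lo, hi = cal.ve_range_ml
    pad = 0.1 * (hi - lo)
    if not (lo - pad <= ve_ml <= hi + pad):
        warnings.warn(
            f"elution volume {ve_ml:g} mL outside calibration range "
            f"[{lo:g}, {hi:g}] mL (+/-10%); extrapolating",
            HemequilWarning,
            stacklevel=2,
        )
    return float(10.0 ** (cal.intercept + cal.slope * ve_ml))
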