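"""Core data containers, CSV I/O, smoothing and the two-state melt fit.

The containers are thin, validated wrappers around numpy arrays:

* :class:`Spectrum` — an absorbance or ellipticity trace A(lambda),
* :class:`Chromatogram` — a detector trace S(V) with its injection metadata,
* :class:`MeltCurve` / :class:`MeltFit` — a CD-at-222-nm thermal unfolding
  trace and the parameters of its two-state fit.

All traces are stored with a strictly increasing abscissa; files with
shuffled rows are sorted on read (with a warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import lmfit
import numpy as np
import pandas as pd

from .errors import (
    HemequilWarning,
    InsufficientDataError,
    NoTransitionError,
    ParseError,
)

__all__ = [
    "Spectrum",
    "Chromatogram",
    "MeltCurve",
    "MeltFit",
    "read_xy_csv",
    "write_xy_csv",
    "smooth_adjacent_average",
    "fit_two_state_melt",
]


def _validated_xy(x, y, xname: str):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError(f"{xname} and values must be 1-D arrays of equal length")
    if x.size < 2:
        raise InsufficientDataError("insufficient data: need at least 2 points")
    if not np.all(np.diff(x) > 0):
        raise ValueError(f"{xname} must be strictly increasing")
    return x, y


@dataclass
class Spectrum:
    """A wavelength-resolved trace (absorbance in AU or ellipticity in mdeg).

    ``meta`` holds free-form acquisition metadata (species, redox_state,
    concentration_uM, pathlength_cm, ...).
    """

    wavelength_nm: np.ndarray
    value: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelength_nm, self.value = _validated_xy(
            self.wavelength_nm, self.value, "wavelength_nm"
        )
        if "pathlength_cm" in self.meta and float(self.meta["pathlength_cm"]) <= 0:
            raise ValueError("pathlength_cm must be > 0")

    def interp(self, wavelength_nm: float) -> float:
        """Linearly interpolated value at an arbitrary wavelength."""
        lo, hi = self.wavelength_nm[0], self.wavelength_nm[-1]
        if not (lo <= wavelength_nm <= hi):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside spectrum range [{lo}, {hi}] nm"
            )
        return float(np.interp(wavelength_nm, self.wavelength_nm, self.value))


@dataclass
class Chromatogram:
    """A size-exclusion elution trace plus its injection parameters.

    ``loaded_conc_uM`` is the injected total protein concentration in dimer
    equivalents ([D_tot] = [M]/2 + [D]); ``load_volume_ml`` the injected
    volume (0.1 mL for a standard 100 uL loop).
    """

    volume_ml: np.ndarray
    signal: np.ndarray
    load_volume_ml: float = 0.1
    loaded_conc_uM: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.volume_ml, self.signal = _validated_xy(
            self.volume_ml, self.signal, "volume_ml"
        )
        self.load_volume_ml = float(self.load_volume_ml)
        self.loaded_conc_uM = float(self.loaded_conc_uM)
        if self.load_volume_ml <= 0:
            raise ValueError("load_volume_ml must be > 0")
        if self.loaded_conc_uM < 0:
            raise ValueError("loaded_conc_uM must be >= 0")


@dataclass
class MeltCurve:
    """CD signal at 222 nm versus temperature."""

    temperature_c: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temperature_c, self.signal = _validated_xy(
            self.temperature_c, self.signal, "temperature_c"
        )
        if self.temperature_c.size < 8:
            raise InsufficientDataError("melt curve needs at least 8 points")


@dataclass
class MeltFit:
    """Two-state melt fit result.

    ``baselines`` is (intercept_folded, slope_folded, intercept_unfolded,
    slope_unfolded); ``transition_width`` is the sigmoid width in deg C
    (a van't Hoff-style steepness parameter, not a full transition span).
    """

    tm_c: float
    transition_width: float
    baselines: tuple[float, float, float, float]
    rss: float

    def __post_init__(self):
        if self.transition_width <= 0:
            raise ValueError("transition_width must be > 0")
        if self.rss < 0:
            raise ValueError("rss must be >= 0")


_KINDS = {
    "spectrum": (Spectrum, ("wavelength_nm", "value")),
    "chromatogram": (Chromatogram, ("volume_ml", "signal")),
    "melt": (MeltCurve, ("temperature_c", "signal")),
}

# Chromatogram metadata keys lifted from the header into constructor args.
_CHROM_META_ARGS = ("load_volume_ml", "loaded_conc_uM")


def read_xy_csv(
    path, kind: Literal["spectrum", "chromatogram", "melt"]
) -> Spectrum | Chromatogram | MeltCurve:
    """Read a two-column CSV into the container selected by ``kind``.

    The dialect is comma-separated with ``.`` decimals.  Leading lines of the
    form ``# key: value`` populate the container's metadata; one optional
    non-numeric column-name row is skipped.  Rows are sorted by the abscissa
    if needed (with a warning).
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown kind {kind!r}; expected one of {sorted(_KINDS)}")
    cls, _ = _KINDS[kind]
    path = Path(path)
    meta: dict = {}
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 2:
                raise ParseError(f"{path.name}, line {lineno}: expected two columns")
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError:
                if not xs:  # tolerate a single column-name header row
                    continue
                raise ParseError(
                    f"{path.name}, line {lineno}: non-numeric row {line!r}"
                ) from None
            xs.append(x)
            ys.append(y)
    if len(xs) < 2:
        raise InsufficientDataError(f"{path.name}: insufficient data (<2 rows)")
    x = np.array(xs)
    y = np.array(ys)
    if not np.all(np.diff(x) > 0):
        warnings.warn(
            f"{path.name}: rows were not sorted by the first column; sorting",
            HemequilWarning,
            stacklevel=2,
        )
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
    if kind == "chromatogram":
        kwargs = {k: float(meta.pop(k)) for k in _CHROM_META_ARGS if k in meta}
        return Chromatogram(x, y, meta=meta, **kwargs)
    return cls(x, y, meta=meta)


def write_xy_csv(path, obj: Spectrum | Chromatogram | MeltCurve) -> None:
    """Write a container back to the two-column CSV dialect of read_xy_csv."""
    for kind, (cls, cols) in _KINDS.items():
        if isinstance(obj, cls):
            xcol, ycol = cols
            break
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    meta = dict(obj.meta)
    if isinstance(obj, Chromatogram):
        meta = {
            "load_volume_ml": obj.load_volume_ml,
            "loaded_conc_uM": obj.loaded_conc_uM,
            **meta,
        }
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write(f"{xcol},{ycol}\n")
        x = getattr(obj, xcol)
        y = getattr(obj, ycol)
        for xi, yi in zip(x, y):
            fh.write(f"{xi:.10g},{yi:.10g}\n")


def smooth_adjacent_average(values, window: int):
    """Adjacent-averaging smoothing with a fixed output length.

    Odd windows are centered on each point; even windows are trailing (the
    mean of point *i* and the ``window - 1`` preceding points), matching the
    common instrument-software convention for "two-point" smoothing.  Edges
    use truncated windows, so the output length equals the input length and
    ``window == 1`` is the identity.
    """
    values = np.asarray(values, dtype=float)
    window = int(window)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > values.size:
        raise ValueError(f"window {window} exceeds sequence length {values.size}")
    ser = pd.Series(values)
    centered = window % 2 == 1
    out = ser.rolling(window, center=centered, min_periods=1).mean()
    return out.to_numpy()


def _two_state_signal(t, tm, width, b_n, m_n, b_u, m_u):
    folded = b_n + m_n * t
    unfolded = b_u + m_u * t
    frac_unfolded = 1.0 / (1.0 + np.exp((tm - t) / width))
    return folded + (unfolded - folded) * frac_unfolded


def fit_two_state_melt(curve: MeltCurve) -> MeltFit:
    """Fit a two-state unfolding sigmoid with sloped native/unfolded baselines.

    The model is ``S(T) = N(T) + (U(T) - N(T)) * f_u(T)`` with linear
    baselines ``N``, ``U`` and ``f_u(T) = 1 / (1 + exp((Tm - T)/w))``.
    Initialization: Tm at the steepest point of the (lightly smoothed)
    derivative, w = 2 degC, baselines from the first/last 10% of points.

    Raises :class:`NoTransitionError` when the fitted midpoint falls outside
    the scanned range, the transition amplitude is negligible against the
    overall signal excursion, or the width is so large the sigmoid degenerates
    into a baseline drift.
    """
    t = curve.temperature_c
    s = curve.signal
    span = t[-1] - t[0]
    n_edge = max(2, t.size // 10)

    smooth = smooth_adjacent_average(s, min(5, s.size))
    deriv = np.gradient(smooth, t)
    tm0 = float(t[np.argmax(np.abs(deriv))])
    tm0 = min(max(tm0, t[0] + 0.05 * span), t[-1] - 0.05 * span)

    pre_fit = np.polyfit(t[:n_edge], s[:n_edge], 1)
    post_fit = np.polyfit(t[-n_edge:], s[-n_edge:], 1)

    params = lmfit.Parameters()
    params.add("tm", value=tm0, min=t[0], max=t[-1])
    params.add("width", value=2.0, min=1e-3, max=span)
    params.add("b_n", value=pre_fit[1])
    params.add("m_n", value=pre_fit[0])
    params.add("b_u", value=post_fit[1])
    params.add("m_u", value=post_fit[0])

    def residual(p):
        return _two_state_signal(t, p["tm"], p["width"], p["b_n"], p["m_n"],
                                 p["b_u"], p["m_u"]) - s

    try:
        result = lmfit.minimize(residual, params, method="leastsq")
    except Exception as exc:  # pragma: no cover - lmfit failure paths vary
        raise NoTransitionError(f"no transition detected (fit failed: {exc})")
    if not result.success:
        raise NoTransitionError("no transition detected (fit did not converge)")

    p = result.params
    tm = float(p["tm"].value)
    width = float(p["width"].value)
    baselines = (float(p["b_n"].value), float(p["m_n"].value),
                 float(p["b_u"].value), float(p["m_u"].value))
    rss = float(np.sum(np.asarray(result.residual) ** 2))

    # Degeneracy guards: a straight line fits the model perfectly with an
    # arbitrary Tm, so require a genuine mid-range, sharp, sizable step.
    amplitude = abs((baselines[2] + baselines[3] * tm)
                    - (baselines[0] + baselines[1] * tm))
    excursion = float(np.ptp(s))
    margin = 0.02 * span
    if not (t[0] + margin < tm < t[-1] - margin):
        raise NoTransitionError("no transition detected (midpoint at scan edge)")
    if width > span / 2:
        raise NoTransitionError("no transition detected (transition too broad)")
    if excursion == 0 or amplitude < 0.1 * excursion:
        raise NoTransitionError("no transition detected (amplitude too small)")
    return MeltFit(tm_c=tm, transition_width=width, baselines=baselines, rss=rss)
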