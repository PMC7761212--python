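"""Pentacoordinate-fraction estimation from ferrous-deoxy visible spectra.

A hexacoordinate deoxy globin (distal histidine bound) shows resolved
alpha/beta Q-bands near 555/528 nm, while a pentacoordinate species (free
distal site, as in an E7L mutant) shows a single broad band around 555 nm.
A measured deoxy spectrum of a partly hexacoordinate protein is modelled as
a two-endmember mixture, and the pentacoordinate fraction *f* is estimated
either from the A555/A540 band ratio (inverted against the references'
absolute band values — the ratio of a mixture is a rational, not linear,
function of *f*) or by full-band non-negative least-squares unmixing, which
is invariant to overall scale (concentration/pathlength).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .errors import HemequilWarning, InsufficientDataError
from .io_spectra import Spectrum

__all__ = [
    "ReferencePair",
    "CoordinationEstimate",
    "SeriesEntry",
    "band_ratio",
    "penta_fraction_from_ratio",
    "penta_fraction_unmix",
    "coordination_series",
]

#: Wavelength window (nm) over which reference spectra must be defined and
#: are area-normalized.
REFERENCE_WINDOW_NM = (450.0, 650.0)


def _area(spec: Spectrum, lo: float, hi: float) -> float:
    mask = (spec.wavelength_nm >= lo) & (spec.wavelength_nm <= hi)
    return float(np.trapezoid(spec.value[mask], spec.wavelength_nm[mask]))


@dataclass
class ReferencePair:
    """Pure hexacoordinate and pentacoordinate deoxy reference spectra.

    ``normalization`` — ``"area"`` scales each reference to unit area over
    450-650 nm, ``"wavelength:<nm>"`` to unit value at a wavelength,
    ``"none"`` leaves them untouched.  Normalization is applied on
    construction.
    """

    hexa: Spectrum
    penta: Spectrum
    normalization: str = "area"

    def __post_init__(self):
        lo, hi = REFERENCE_WINDOW_NM
        for name, spec in (("hexa", self.hexa), ("penta", self.penta)):
            if spec.wavelength_nm[0] > lo or spec.wavelength_nm[-1] < hi:
                raise ValueError(f"{name} reference must cover [{lo}, {hi}] nm")
            band = spec.value[
                (spec.wavelength_nm >= 530) & (spec.wavelength_nm <= 570)
            ]
            if not np.all(band > 0):
                raise ValueError(f"{name} reference must be positive on 530-570 nm")
        if self.normalization == "none":
            return
        for spec in (self.hexa, self.penta):
            if self.normalization == "area":
                norm = _area(spec, lo, hi)
            elif self.normalization.startswith("wavelength:"):
                norm = spec.interp(float(self.normalization.split(":", 1)[1]))
            else:
                raise ValueError(f"unknown normalization {self.normalization!r}")
            if norm <= 0:
                raise ValueError("normalization constant must be positive")
            spec.value = spec.value / norm


@dataclass
class CoordinationEstimate:
    """Estimated pentacoordinate fraction of one deoxy spectrum."""

    f_penta: float
    method: Literal["ratio", "unmix"]
    residual: float = float("nan")
    ratio_observed: float = float("nan")

    def __post_init__(self):
        if not (0.0 <= self.f_penta <= 1.0):
            raise ValueError("f_penta must lie in [0, 1]")


@dataclass
class SeriesEntry:
    """One concentration point of a coordination series (error text when the
    per-spectrum estimate failed)."""

    conc_uM: float
    f_penta: float | None
    error: str | None = None


def band_ratio(spec: Spectrum, num_nm: float = 555.0, den_nm: float = 540.0) -> float:
    """A(num_nm)/A(den_nm) with linear interpolation between samples.

    The default A555/A540 ratio indexes the degree of heme hexacoordination:
    hexacoordinate deoxy spectra have a deep valley at 540 nm between the
    alpha and beta bands, pentacoordinate ones do not.
    """
    num = spec.interp(num_nm)
    den = spec.interp(den_nm)
    if den <= 0:
        raise ValueError(f"absorbance at {den_nm} nm must be > 0")
    return num / den


def penta_fraction_from_ratio(
    r_obs: float, refs: ReferencePair, num_nm: float = 555.0, den_nm: float = 540.0
) -> CoordinationEstimate:
    """Invert the band ratio of a two-endmember mixture for f_penta.

    For a mixture ``f*P + (1-f)*H`` the observed ratio is
    ``r = (f*P_num + (1-f)*H_num) / (f*P_den + (1-f)*H_den)``; solving for f
    uses the references' absolute band values after normalization.  Solutions
    outside [0, 1] are clipped with a warning.
    """
    h_num, h_den = refs.hexa.interp(num_nm), refs.hexa.interp(den_nm)
    p_num, p_den = refs.penta.interp(num_nm), refs.penta.interp(den_nm)
    if abs(h_num / h_den - p_num / p_den) < 1e-6:
        raise ValueError(
            "references indistinguishable: endmember band ratios are equal"
        )
    denom = (r_obs * p_den - p_num) - (r_obs * h_den - h_num)
    f = (h_num - r_obs * h_den) / denom
    if not (0.0 <= f <= 1.0):
        warnings.warn(
            f"ratio inversion gave f = {f:.4g} outside [0, 1]; clipping",
            HemequilWarning,
            stacklevel=2,
        )
        f = float(np.clip(f, 0.0, 1.0))
    return CoordinationEstimate(
        f_penta=float(f), method="ratio", ratio_observed=float(r_obs)
    )


def penta_fraction_unmix(
    spec: Spectrum,
    refs: ReferencePair,
    window_nm: tuple[float, float] = (500.0, 600.0),
    allow_offset: bool = False,
) -> CoordinationEstimate:
    """Full-band two-endmember unmixing by non-negative least squares.

    Solves ``spec ~ a*penta + b*hexa`` with a, b >= 0 on a common wavelength
    grid inside ``window_nm`` and reports ``f = a/(a+b)``; the free overall
    scale ``c = a+b`` absorbs concentration and pathlength, so the estimate
    is invariant to positive scaling of the input.  ``allow_offset`` adds an
    unconstrained constant baseline term.
    """
    lo, hi = window_nm
    if hi - lo < 20.0:
        raise ValueError("unmixing window must span at least 20 nm")
    for name, sp in (("spectrum", spec), ("hexa", refs.hexa), ("penta", refs.penta)):
        if sp.wavelength_nm[0] > lo or sp.wavelength_nm[-1] < hi:
            raise ValueError(f"{name} does not cover the window [{lo}, {hi}] nm")
    grid = spec.wavelength_nm[(spec.wavelength_nm >= lo) & (spec.wavelength_nm <= hi)]
    if grid.size < 10:
        raise InsufficientDataError("too few spectral samples in the window")
    obs = np.interp(grid, spec.wavelength_nm, spec.value)
    penta = np.interp(grid, refs.penta.wavelength_nm, refs.penta.value)
    hexa = np.interp(grid, refs.hexa.wavelength_nm, refs.hexa.value)

    if allow_offset:
        design = np.column_stack([penta, hexa, np.ones_like(grid)])
        sol = optimize.lsq_linear(
            design, obs, bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf])
        )
        a, b = sol.x[0], sol.x[1]
        residual = float(np.linalg.norm(design @ sol.x - obs))
    else:
        coeffs, residual = optimize.nnls(np.column_stack([penta, hexa]), obs)
        a, b = coeffs
    if a + b <= 0:
        raise ValueError("unmixing degenerate: zero total endmember weight")
    return CoordinationEstimate(
        f_penta=float(a / (a + b)), method="unmix", residual=float(residual)
    )


def coordination_series(
    spectra: Sequence[tuple[float, Spectrum]],
    refs: ReferencePair,
    method: Literal["ratio", "unmix"] = "unmix",
) -> list[SeriesEntry]:
    """Per-spectrum pentacoordinate fractions across a concentration series.

    Entries are returned sorted by concentration, unsmoothed; per-spectrum
    failures are recorded in the entry rather than aborting the series.
    """
    if len(spectra) < 2:
        raise InsufficientDataError("a series needs >= 2 concentrations")
    if method not in ("ratio", "unmix"):
        raise ValueError(f"unknown method {method!r}")
    out = []
    for conc, spec in sorted(spectra, key=lambda cs: cs[0]):
        try:
            if method == "ratio":
                est = penta_fraction_from_ratio(band_ratio(spec), refs)
            else:
                est = penta_fraction_unmix(spec, refs)
            out.append(SeriesEntry(conc_uM=float(conc), f_penta=est.f_penta))
        except Exception as exc:
            out.append(SeriesEntry(conc_uM=float(conc), f_penta=None, error=str(exc)))
    return out
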