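"""Monomer-dimer equilibrium analysis of fast-exchange SEC data.

A self-associating protein in rapid monomer/dimer exchange elutes from a
gel-filtration column as a single peak whose position is the
equilibrium-weighted average of the monomer (``Vm``) and dimer (``Vd``)
elution volumes.  Because log10(MW) is linear in elution volume, the percent
dimer follows directly from the peak apex::

    %D = 100 * (2**((Vm - Ve)/(Vm - Vd)) - 1)

With total concentration expressed in dimer equivalents,
``Dtot = [M]/2 + [D]``, mass action ``Kd = [M]^2/[D]`` gives

    Kd = Dtot * 0.04 * (100 - %D)**2 / %D

so that a plot of ``y = log10(%D / (0.04*(100-%D)**2))`` against
``log10 Dtot`` is a straight line of slope 1 crossing zero at
``Dtot = Kd`` (the Manning linearization).  Loaded concentrations must first
be divided by the on-column dilution factor (FWHM / injected volume).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    FitConvergenceError,
    HemequilWarning,
    InsufficientDataError,
    NoAssociationError,
)
from .io_spectra import Chromatogram
from .sec import peak_metrics

__all__ = [
    "ColumnModel",
    "EquilibriumPoint",
    "KdFit",
    "percent_dimer_from_elution",
    "elution_volume_from_percent_dimer",
    "effective_mw",
    "fraction_dimer",
    "manning_y",
    "fit_kd_manning",
    "fit_kd_hyperbolic",
    "equilibrium_points_from_chromatograms",
]

#: %D window retained for the log transform; points outside are excluded.
PERCENT_D_WINDOW = (1.0, 99.0)

#: |slope - 1| beyond which the unconstrained Manning slope draws a warning.
SLOPE_WARN_TOL = 0.15


@dataclass
class ColumnModel:
    """Column endpoints for one species: monomer/dimer elution volumes and
    the monomer molecular mass A (kDa)."""

    vm_ml: float
    vd_ml: float
    monomer_mw_kda: float

    def __post_init__(self):
        if not self.vd_ml < self.vm_ml:
            raise ValueError("dimer must elute earlier: vd_ml < vm_ml")
        if self.monomer_mw_kda <= 0:
            raise ValueError("monomer_mw_kda must be > 0")


@dataclass
class EquilibriumPoint:
    """One concentration point of an SEC dilution series."""

    dtot_loaded_uM: float
    dtot_corrected_uM: float
    percent_dimer: float
    ve_ml: float

    def __post_init__(self):
        if self.dtot_loaded_uM <= 0 or self.dtot_corrected_uM <= 0:
            raise ValueError("concentrations must be > 0")
        if self.dtot_corrected_uM > self.dtot_loaded_uM * (1 + 1e-9):
            raise ValueError("dtot_corrected_uM cannot exceed dtot_loaded_uM")
        if not (0.0 <= self.percent_dimer <= 100.0):
            raise ValueError("percent_dimer must lie in [0, 100]")


@dataclass
class KdFit:
    """Result of a Kd estimate (uM, dimer-equivalent concentration scale)."""

    kd_uM: float
    log_points: list = field(default_factory=list)
    slope_unconstrained: float = float("nan")
    stderr_log_kd: float = 0.0
    n_points_used: int = 0
    method: str = "manning"

    def __post_init__(self):
        if self.kd_uM <= 0:
            raise ValueError("kd_uM must be > 0")
        if self.n_points_used < 3:
            raise ValueError("a Kd fit needs >= 3 points")


def percent_dimer_from_elution(ve_ml: float, col: ColumnModel) -> float:
    """Percent dimer implied by a peak apex at ``ve_ml``.

    Values outside the [Vd, Vm] window (possible with noisy apexes) are
    clipped to [0, 100] with a warning.
    """
    span = col.vm_ml - col.vd_ml
    if span == 0:
        raise ValueError("vm_ml == vd_ml: column cannot separate the species")
    pd_raw = 100.0 * (2.0 ** ((col.vm_ml - ve_ml) / span) - 1.0)
    if not (0.0 <= pd_raw <= 100.0):
        warnings.warn(
            f"elution volume {ve_ml:g} mL outside [Vd, Vm]; clipping %D",
            HemequilWarning,
            stacklevel=2,
        )
        pd_raw = float(np.clip(pd_raw, 0.0, 100.0))
    return float(pd_raw)


def elution_volume_from_percent_dimer(percent_dimer: float, col: ColumnModel) -> float:
    """Exact inverse of :func:`percent_dimer_from_elution` on [0, 100]."""
    if not (0.0 <= percent_dimer <= 100.0):
        raise ValueError("percent_dimer must lie in [0, 100]")
    span = col.vm_ml - col.vd_ml
    return float(col.vm_ml - span * np.log2(1.0 + percent_dimer / 100.0))


def effective_mw(col: ColumnModel, percent_dimer: float) -> float:
    """Exchange-averaged effective mass ``A * (1 + %D/100)`` in kDa."""
    if not (0.0 <= percent_dimer <= 100.0):
        raise ValueError("percent_dimer must lie in [0, 100]")
    return float(col.monomer_mw_kda * (1.0 + percent_dimer / 100.0))


def fraction_dimer(dtot_uM: float, kd_uM: float) -> float:
    """Equilibrium percent dimer at total concentration ``dtot_uM``.

    Closed-form root in [0, 100] of ``Kd = Dtot*0.04*(100-%D)^2/%D``::

        %D = 100 * (S - sqrt(S^2 - 64*Dtot^2)) / (8*Dtot),  S = 8*Dtot + Kd

    ``kd_uM = 0`` is the infinitely tight dimer (returns 100).
    """
    if dtot_uM <= 0:
        raise ValueError("dtot_uM must be > 0")
    if kd_uM < 0:
        raise ValueError("kd_uM must be >= 0")
    if kd_uM == 0:
        return 100.0
    s = 8.0 * dtot_uM + kd_uM
    disc = s * s - 64.0 * dtot_uM * dtot_uM
    pd = 100.0 * (s - np.sqrt(disc)) / (8.0 * dtot_uM)
    return float(np.clip(pd, 0.0, 100.0))


def manning_y(percent_dimer: float) -> float:
    """The Manning transform ``log10(%D / (0.04*(100-%D)^2))``.

    Zero exactly when ``Dtot = Kd`` (i.e. %D ~ 60.96).  Undefined at the
    endpoints, which carry no equilibrium information.
    """
    if not (0.0 < percent_dimer < 100.0):
        raise ValueError("excluded point: %D must lie strictly in (0, 100)")
    return float(
        np.log10(percent_dimer / (0.04 * (100.0 - percent_dimer) ** 2))
    )


def _usable(points: Sequence[EquilibriumPoint]):
    lo, hi = PERCENT_D_WINDOW
    usable, excluded = [], []
    for p in points:
        (usable if lo <= p.percent_dimer <= hi else excluded).append(p)
    return usable, excluded


def fit_kd_manning(
    points: Sequence[EquilibriumPoint], fix_slope: bool = True
) -> KdFit:
    """Estimate Kd from the Manning line through (log10 Dtot, y).

    With ``fix_slope`` (default) the theoretical slope of 1 is imposed and
    ``log10 Kd`` is the mean of ``log10 Dtot - y`` over usable points; the
    unconstrained OLS slope is always reported as a diagnostic.  With
    ``fix_slope=False`` the OLS line itself is inverted at y = 0.

    Points with %D outside [1, 99] are excluded with a warning.  A series in
    which every point is essentially monomeric raises
    :class:`NoAssociationError` — the expected outcome for a species like
    AHb2 whose elution volume does not shift with concentration.
    """
    points = list(points)
    usable, excluded = _usable(points)
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} point(s) with %D outside "
            f"[{PERCENT_D_WINDOW[0]:g}, {PERCENT_D_WINDOW[1]:g}]",
            HemequilWarning,
            stacklevel=2,
        )
    if len(usable) < 3:
        if points and all(p.percent_dimer < PERCENT_D_WINDOW[0] for p in points):
            raise NoAssociationError(
                "no association detected: all points are essentially monomeric"
            )
        raise InsufficientDataError(
            f"only {len(usable)} usable point(s); need >= 3"
        )

    log_d = np.array([np.log10(p.dtot_corrected_uM) for p in usable])
    y = np.array([manning_y(p.percent_dimer) for p in usable])

    ols = stats.linregress(log_d, y)
    slope_diag = float(ols.slope)
    if abs(slope_diag - 1.0) > SLOPE_WARN_TOL:
        warnings.warn(
            f"unconstrained Manning slope {slope_diag:.3f} deviates from the "
            "theoretical slope of 1 by more than "
            f"{SLOPE_WARN_TOL:g}; the two-state monomer-dimer model may not hold",
            HemequilWarning,
            stacklevel=2,
        )

    if fix_slope:
        per_point = log_d - y
        log_kd = float(np.mean(per_point))
        stderr = float(np.std(per_point, ddof=1) / np.sqrt(len(per_point)))
    else:
        log_kd = float(-ols.intercept / ols.slope)
        # scatter-based uncertainty of the y=0 crossing, first order
        resid = y - (ols.intercept + ols.slope * log_d)
        stderr = float(
            np.sqrt(np.sum(resid**2) / max(len(usable) - 2, 1))
            / (abs(ols.slope) * np.sqrt(len(usable)))
        )
    return KdFit(
        kd_uM=float(10.0**log_kd),
        log_points=[(float(a), float(b)) for a, b in zip(log_d, y)],
        slope_unconstrained=slope_diag,
        stderr_log_kd=stderr,
        n_points_used=len(usable),
        method="manning" if fix_slope else "manning_free_slope",
    )


def fit_kd_hyperbolic(points: Sequence[EquilibriumPoint]) -> KdFit:
    """Direct nonlinear fit of %D = f(Dtot; Kd), optimizing log10 Kd.

    Initialized from the Manning estimate (or the median concentration when
    the Manning fit is unavailable).  On non-convergence raises
    :class:`FitConvergenceError` carrying the Manning fallback.
    """
    points = list(points)
    if len(points) < 4:
        raise InsufficientDataError("hyperbolic fit needs >= 4 points")
    dtot = np.array([p.dtot_corrected_uM for p in points])
    pd_obs = np.array([p.percent_dimer for p in points])

    fallback = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", HemequilWarning)
            fallback = fit_kd_manning(points)
        log_kd0 = np.log10(fallback.kd_uM)
    except (NoAssociationError, InsufficientDataError):
        log_kd0 = float(np.median(np.log10(dtot)))

    def resid(theta):
        kd = 10.0 ** theta[0]
        return np.array([fraction_dimer(d, kd) for d in dtot]) - pd_obs

    sol = optimize.least_squares(resid, x0=[log_kd0], method="lm")
    if not sol.success or not np.isfinite(sol.x[0]):
        raise FitConvergenceError(
            "hyperbolic Kd fit did not converge", fallback=fallback
        )
    log_kd = float(sol.x[0])
    resid_final = resid(sol.x)
    dof = max(len(points) - 1, 1)
    # Gauss-Newton standard error on log10 Kd
    jac = sol.jac.ravel()
    jtj = float(np.dot(jac, jac))
    stderr = float(np.sqrt(np.sum(resid_final**2) / dof / jtj)) if jtj > 0 else 0.0
    usable, _ = _usable(points)
    return KdFit(
        kd_uM=10.0**log_kd,
        log_points=[
            (float(np.log10(p.dtot_corrected_uM)), float(manning_y(p.percent_dimer)))
            for p in usable
            if 0 < p.percent_dimer < 100
        ],
        slope_unconstrained=(
            fallback.slope_unconstrained if fallback is not None else float("nan")
        ),
        stderr_log_kd=stderr,
        n_points_used=len(points),
        method="hyperbolic",
    )


def equilibrium_points_from_chromatograms(
    chroms: Sequence[Chromatogram],
    col: ColumnModel,
    smooth_window: int = 19,
    dilution_factor: float | None = None,
) -> list[EquilibriumPoint]:
    """Reduce raw chromatograms to (Dtot_corrected, %D) equilibrium points.

    Each trace contributes its apex (→ %D via the column model) and its own
    measured dilution factor (FWHM / load volume) unless a fixed
    ``dilution_factor`` override is given.  ``smooth_window`` is forwarded to
    :func:`hemequil.sec.peak_metrics`; the default (19 samples, centered) is
    about a quarter of the half-height width of the built-in synthetic peaks,
    which suppresses apex jitter while broadening the measured FWHM by <1%.
    """
    pts = []
    for chrom in chroms:
        if chrom.loaded_conc_uM <= 0:
            raise ValueError("each chromatogram needs loaded_conc_uM > 0")
        metrics = peak_metrics(chrom, smooth_window=smooth_window)
        df = dilution_factor if dilution_factor is not None else metrics.dilution_factor
        pts.append(
            EquilibriumPoint(
                dtot_loaded_uM=chrom.loaded_conc_uM,
                dtot_corrected_uM=chrom.loaded_conc_uM / df,
                percent_dimer=percent_dimer_from_elution(
                    metrics.apex_volume_ml, col
                ),
                ve_ml=metrics.apex_volume_ml,
            )
        )
    return pts
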