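"""Ferguson-plot analysis of native PAGE mobilities.

In native gel electrophoresis the log of a protein's relative mobility (Rf,
measured against the tracking dye) falls linearly with the gel concentration
%T.  The negative slope of ``100*log10(100*Rf)`` versus %T — the retardation
coefficient Kr — depends on molecular size but not charge, so a log-log line
of Kr against molecular mass for standards lets the mass of an unknown (here
an AHb2-like monomer) be read off from its own Kr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import HemequilWarning, InsufficientDataError
from collections import OrderedDict

__all__ = [
    "FergusonTable",
    "FergusonModel",
    "retardation_coefficient",
    "fit_ferguson_standard_curve",
    "estimate_mw_ferguson",
    "ferguson_mass_pipeline",
]


@dataclass
class FergusonTable:
    """Long-format gel mobilities: (protein_id, %T, Rf) entries."""

    entries: list  # of (protein_id: str, percent_t: float, rf: float)

    def __post_init__(self):
        clean = []
        for pid, pt, rf in self.entries:
            pt, rf = float(pt), float(rf)
            if not (0.0 < pt < 100.0):
                raise ValueError(f"{pid}: %T must lie in (0, 100), got {pt}")
            if not (0.0 < rf <= 1.0):
                raise ValueError(f"{pid}: Rf must lie in (0, 1], got {rf}")
            clean.append((str(pid), pt, rf))
        self.entries = clean
        for pid, group in self.by_protein().items():
            if len({pt for pt, _ in group}) < 3:
                raise ValueError(f"{pid}: needs >= 3 distinct %T values")

    def by_protein(self) -> "OrderedDict[str, list[tuple[float, float]]]":
        out: OrderedDict[str, list] = OrderedDict()
        for pid, pt, rf in self.entries:
            out.setdefault(pid, []).append((pt, rf))
        return out


@dataclass
class FergusonModel:
    """Per-protein retardation coefficients plus the standard curve
    log10(Kr) = intercept + slope * log10(MW/kDa)."""

    kr_by_protein: dict
    curve_slope: float
    curve_intercept: float
    r_squared: float
    standards_used: list = field(default_factory=list)


def retardation_coefficient(percent_t: Sequence[float], rf: Sequence[float]) -> float:
    """Kr = minus the OLS slope of ``100*log10(100*Rf)`` on %T.

    Kr <= 0 (mobility not decreasing with gel concentration) marks a
    non-sieving species and draws a warning rather than an error.
    """
    pt = np.asarray(percent_t, dtype=float)
    rf = np.asarray(rf, dtype=float)
    if pt.size != rf.size:
        raise ValueError("percent_t and rf must have equal length")
    if np.unique(pt).size < 3:
        raise InsufficientDataError("need >= 3 distinct %T values")
    if np.any(rf <= 0):
        raise ValueError("Rf values must be > 0")
    y = 100.0 * np.log10(100.0 * rf)
    fit = stats.linregress(pt, y)
    kr = -float(fit.slope)
    if kr <= 0:
        warnings.warn(
            f"non-sieving species: Kr = {kr:.4g} <= 0",
            HemequilWarning,
            stacklevel=2,
        )
    return kr


def fit_ferguson_standard_curve(standards: Sequence[tuple[float, float]]) -> FergusonModel:
    """OLS line of log10(Kr) on log10(MW) over standards ``(mw_kda, kr)``.

    Standards with Kr <= 0 are excluded with a warning; at least 3 usable
    standards are required.
    """
    usable, dropped = [], []
    for mw, kr in standards:
        (usable if kr > 0 else dropped).append((float(mw), float(kr)))
    if dropped:
        warnings.warn(
            f"excluded {len(dropped)} standard(s) with Kr <= 0",
            HemequilWarning,
            stacklevel=2,
        )
    if len(usable) < 3:
        raise InsufficientDataError(
            f"only {len(usable)} usable standard(s); need >= 3"
        )
    log_mw = np.log10([mw for mw, _ in usable])
    log_kr = np.log10([kr for _, kr in usable])
    fit = stats.linregress(log_mw, log_kr)
    return FergusonModel(
        kr_by_protein={},
        curve_slope=float(fit.slope),
        curve_intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        standards_used=usable,
    )


def estimate_mw_ferguson(curve: FergusonModel, kr: float) -> float:
    """Invert the standard curve: MW = 10**((log10 Kr - intercept)/slope)."""
    if kr <= 0:
        raise ValueError("kr must be > 0")
    if curve.curve_slope == 0:
        raise ValueError("degenerate standard curve (slope 0)")
    return float(10.0 ** ((np.log10(kr) - curve.curve_intercept) / curve.curve_slope))


def ferguson_mass_pipeline(
    table: FergusonTable,
    standards_mw_kda: Mapping[str, float],
    unknown_ids: Sequence[str],
) -> tuple[FergusonModel, dict]:
    """Full Ferguson workflow: Kr per protein, standard curve, unknown masses.

    ``standards_mw_kda`` maps standard protein ids in ``table`` to their known
    masses; every id in ``unknown_ids`` must also appear in the table.
    Returns the fitted model (with ``kr_by_protein`` populated) and a map of
    unknown id -> estimated mass (kDa).
    """
    groups = table.by_protein()
    missing = [pid for pid in list(standards_mw_kda) + list(unknown_ids)
               if pid not in groups]
    if missing:
        raise KeyError(f"proteins absent from gel table: {missing}")
    kr_by_protein = {
        pid: retardation_coefficient([pt for pt, _ in grp], [rf for _, rf in grp])
        for pid, grp in groups.items()
    }
    curve = fit_ferguson_standard_curve(
        [(standards_mw_kda[pid], kr_by_protein[pid]) for pid in standards_mw_kda]
    )
    curve.kr_by_protein = kr_by_protein
    masses = {
        pid: estimate_mw_ferguson(curve, kr_by_protein[pid]) for pid in unknown_ids
    }
    return curve, masses
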