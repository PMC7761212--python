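"""Ground-truth simulators for every analysis stage, with named presets.

The presets encode the study conditions for the four SEC species
(ferrous-oxy AHb1, ferric AHb1, the T45A interface mutant, and monomeric
AHb2) and the two deoxy-coordination series (wild-type AHb1 and T45A).  The
column geometry itself is not published, so the default is a plausible
Superdex-75-like line, log10 MW(kDa) = 3.0 - 0.2*Ve, placed so that the
AHb1 monomer (18.034 kDa) and dimer (36.068 kDa) elute at 8.719 and
7.214 mL; all of it is configurable.

Every generator is a pure function of its arguments including the seed:
identical calls are bit-identical, and a master seed deterministically
spawns independent per-item streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dimer import ColumnModel, elution_volume_from_percent_dimer, fraction_dimer
from .ferguson import FergusonTable
from .io_spectra import Chromatogram, MeltCurve, Spectrum
from .coordination import ReferencePair

__all__ = [
    "SecPreset",
    "CoordinationPreset",
    "SEC_PRESETS",
    "COORDINATION_PRESETS",
    "DEFAULT_COLUMN",
    "default_sec_standards",
    "make_reference_shapes",
    "simulate_chromatogram",
    "simulate_sec_series",
    "simulate_gel_runs",
    "simulate_deoxy_spectrum",
    "simulate_melt_curve",
    "preset_f_penta",
]

#: Gaussian FWHM / sigma conversion factor, 2*sqrt(2*ln 2).
FWHM_PER_SIGMA = 2.354820045030949

#: Default synthetic column: monomer at 8.719 mL, dimer at 7.214 mL on the
#: line log10 MW = 3.0 - 0.2*Ve, with the AHb1 monomer mass.
DEFAULT_COLUMN = ColumnModel(vm_ml=8.719, vd_ml=7.214, monomer_mw_kda=18.034)

#: Injection volume (mL) of a standard 100 uL loop.
DEFAULT_LOAD_ML = 0.1

#: Volume axis of simulated chromatograms (mL): covers the dimer and monomer
#: peaks with >3 sigma of margin at ~80 samples per peak FWHM.
CHROM_GRID_ML = (6.0, 10.0, 0.01)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


@dataclass(frozen=True)
class SecPreset:
    """One SEC dilution-series scenario (species + acquisition design)."""

    name: str
    kd_uM: float | None  # None = monomer-only species (no dimerization)
    column: ColumnModel = field(default_factory=lambda: DEFAULT_COLUMN)
    dilution_factor: float = 8.0
    conc_range_uM: tuple[float, float] = (0.07, 85.0)
    n_points: int = 12
    noise_frac: float = 0.01

    def __post_init__(self):
        lo, hi = self.conc_range_uM
        if not lo < hi:
            raise ValueError("conc_range_uM must be (low, high) with low < high")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        if self.kd_uM is not None and self.kd_uM < 0:
            raise ValueError("kd_uM must be >= 0 or None")

    @property
    def monomer_only(self) -> bool:
        return self.kd_uM is None


@dataclass(frozen=True)
class CoordinationPreset:
    """Anchors (conc_uM, f_penta) of a deoxy coordination series; f is
    interpolated linearly in log10 concentration between anchors."""

    name: str
    f_map: tuple  # of (conc_uM, f_penta)
    noise_frac: float = 0.005

    def __post_init__(self):
        concs = [c for c, _ in self.f_map]
        fs = [f for _, f in self.f_map]
        if any(c2 <= c1 for c1, c2 in zip(concs, concs[1:])):
            raise ValueError("f_map concentrations must be strictly increasing")
        if any(not (0.0 <= f <= 1.0) for f in fs):
            raise ValueError("f values must lie in [0, 1]")


#: SEC presets at the reported dissociation constants and ranges:
#: Kd 1.2 uM (ferrous-oxy AHb1, series 0.07-85 uM), 11 uM (ferric AHb1),
#: 876 uM (T45A), and the monomer-only AHb2 control over 0.1-60 uM.
#: Dilution factors 8/8/7/6 as measured for the four species.
SEC_PRESETS: dict[str, SecPreset] = {
    p.name: p
    for p in [
        SecPreset("AHb1_oxy", kd_uM=1.2, dilution_factor=8.0,
                  conc_range_uM=(0.07, 85.0)),
        SecPreset("AHb1_ferric", kd_uM=11.0, dilution_factor=8.0,
                  conc_range_uM=(0.1, 300.0)),
        SecPreset("AHb1_T45A", kd_uM=876.0, dilution_factor=7.0,
                  conc_range_uM=(1.0, 1000.0)),
        SecPreset(
            "AHb2",
            kd_uM=None,
            # AHb2 endpoints on the same column line at its own monomer mass
            column=ColumnModel(vm_ml=8.7392, vd_ml=7.2337, monomer_mw_kda=17.871),
            dilution_factor=6.0,
            conc_range_uM=(0.1, 60.0),
        ),
    ]
}

#: Coordination presets: wild-type pentacoordination rises ~13% -> ~65%
#: between 1 and 190 uM; the T45A mutant stays flat at ~26% over 0.7-350 uM.
COORDINATION_PRESETS: dict[str, CoordinationPreset] = {
    p.name: p
    for p in [
        CoordinationPreset("AHb1_wt", f_map=((1.0, 0.13), (190.0, 0.65))),
        CoordinationPreset("AHb1_T45A", f_map=((0.7, 0.26), (350.0, 0.26))),
    ]
}


def preset_f_penta(preset: CoordinationPreset, conc_uM: float) -> float:
    """Ground-truth pentacoordinate fraction at a concentration.

    Linear in log10(conc) between anchors, clamped at the end anchors.
    """
    if conc_uM <= 0:
        raise ValueError("conc_uM must be > 0")
    concs = np.log10([c for c, _ in preset.f_map])
    fs = [f for _, f in preset.f_map]
    return float(np.interp(np.log10(conc_uM), concs, fs))


def default_sec_standards() -> list[tuple[str, float, float]]:
    """Synthetic calibration standards (name, MW kDa, Ve mL).

    The five classical gel-filtration standards (BSA 66, ovalbumin 43,
    carbonic anhydrase 29, myoglobin 17.6, cytochrome c 12.4 kDa) placed
    exactly on the default column line log10 MW = 3.0 - 0.2*Ve.
    """
    masses = [
        ("BSA", 66.0),
        ("ovalbumin", 43.0),
        ("carbonic_anhydrase", 29.0),
        ("myoglobin", 17.6),
        ("cytochrome_c", 12.4),
    ]
    return [(name, mw, (3.0 - np.log10(mw)) / 0.2) for name, mw in masses]


def _gaussian(x, center, sigma):
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def make_reference_shapes() -> ReferencePair:
    """Deterministic pure hexa/penta deoxy reference spectra.

    Built from fixed Gaussian bands on a 450-650 nm grid (0.5 nm step):
    the hexacoordinate endmember has resolved alpha (555 nm) and beta
    (528 nm) bands with a valley at ~540 nm; the pentacoordinate endmember a
    single broad band near 558 nm.  Both sit on a weak broad background, are
    strictly positive, and are area-normalized; their A555/A540 ratios
    differ by ~1, comfortably above the 0.2 separability floor.
    """
    wl = np.arange(450.0, 650.0 + 0.25, 0.5)
    hexa = (
        1.00 * _gaussian(wl, 555.0, 6.0)
        + 0.90 * _gaussian(wl, 528.0, 9.0)
        + 0.12 * _gaussian(wl, 560.0, 60.0)
        + 0.02
    )
    penta = (
        0.85 * _gaussian(wl, 558.0, 20.0)
        + 0.12 * _gaussian(wl, 560.0, 60.0)
        + 0.02
    )
    return ReferencePair(
        hexa=Spectrum(wl, hexa, meta={"species": "deoxy-AHb2-like",
                                      "coordination": "hexa"}),
        penta=Spectrum(wl.copy(), penta, meta={"species": "AHb1-E7L-like",
                                               "coordination": "penta"}),
        normalization="area",
    )


def simulate_chromatogram(
    dtot_loaded_uM: float, preset: SecPreset, seed: int
) -> Chromatogram:
    """One fast-exchange SEC trace at a loaded concentration.

    The on-column concentration is the load divided by the preset's dilution
    factor; the equilibrium %D at that concentration sets the apex through
    the elution-volume relation; the peak is Gaussian with
    FWHM = dilution_factor * load volume and height proportional to the
    loaded concentration, plus seeded additive Gaussian noise of standard
    deviation ``noise_frac * height``.
    """
    if dtot_loaded_uM <= 0:
        raise ValueError("dtot_loaded_uM must be > 0")
    dtot_column = dtot_loaded_uM / preset.dilution_factor
    if preset.monomer_only:
        pd = 0.0
    else:
        pd = fraction_dimer(dtot_column, preset.kd_uM)
    apex = elution_volume_from_percent_dimer(pd, preset.column)
    fwhm = preset.dilution_factor * DEFAULT_LOAD_ML
    sigma = fwhm / FWHM_PER_SIGMA
    lo, hi, step = CHROM_GRID_ML
    volume = np.arange(lo, hi + step / 2, step)
    height = dtot_loaded_uM  # arbitrary detector units, linear in load
    signal = height * _gaussian(volume, apex, sigma)
    if preset.noise_frac > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, preset.noise_frac * height, volume.size)
    return Chromatogram(
        volume_ml=volume,
        signal=signal,
        load_volume_ml=DEFAULT_LOAD_ML,
        loaded_conc_uM=dtot_loaded_uM,
        meta={
            "preset": preset.name,
            "truth_percent_dimer": pd,
            "truth_apex_ml": apex,
        },
    )


def simulate_sec_series(preset: SecPreset, seed: int) -> list[Chromatogram]:
    """A full dilution series: log-spaced loads across the preset's range,
    one seeded chromatogram per load (noise streams derived from the master
    seed, noiseless structure independent of it)."""
    loads = np.geomspace(*preset.conc_range_uM, preset.n_points)
    seeds = _spawn_seeds(seed, preset.n_points)
    return [simulate_chromatogram(load, preset, s) for load, s in zip(loads, seeds)]


#: Ideal Ferguson-behavior constants: Kr = KR_COEF * MW**KR_EXP, Rf0 free
#: mobility at zero gel concentration.
KR_COEF = 0.5
KR_EXP = 0.7
RF0 = 0.9


def simulate_gel_runs(
    standards: Sequence[tuple[str, float]],
    unknown_mw_kda: float,
    percent_t_list: Sequence[float],
    noise_frac: float = 0.0,
    seed: int = 0,
    unknown_id: str = "unknown",
) -> FergusonTable:
    """Native-PAGE mobilities for standards plus one unknown.

    Ideal Ferguson behavior: ``Rf = Rf0 * 10**(-Kr * %T / 100)`` with
    ``Kr = 0.5 * MW**0.7``; multiplicative log-normal noise of sigma
    ``noise_frac`` on each Rf, clipped to (0, 1].
    """
    percent_t_list = [float(t) for t in percent_t_list]
    if len(set(percent_t_list)) < 3:
        raise ValueError("need >= 3 distinct %T values")
    proteins = [(str(pid), float(mw)) for pid, mw in standards]
    proteins.append((unknown_id, float(unknown_mw_kda)))
    rng = np.random.default_rng(seed)
    entries = []
    for pid, mw in proteins:
        kr = KR_COEF * mw**KR_EXP
        for pt in percent_t_list:
            rf = RF0 * 10.0 ** (-kr * pt / 100.0)
            if noise_frac > 0:
                rf *= np.exp(rng.normal(0.0, noise_frac))
            entries.append((pid, pt, float(np.clip(rf, 1e-6, 1.0))))
    return FergusonTable(entries)


def simulate_deoxy_spectrum(
    f_penta: float, scale: float = 1.0, noise_frac: float = 0.0, seed: int = 0
) -> Spectrum:
    """A deoxy visible spectrum as a two-endmember mixture.

    ``scale * (f * penta + (1 - f) * hexa)`` on the built-in reference
    shapes, plus seeded additive Gaussian noise with standard deviation
    ``noise_frac`` times the spectrum maximum.
    """
    if not (0.0 <= f_penta <= 1.0):
        raise ValueError("f_penta must lie in [0, 1]")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    refs = make_reference_shapes()
    value = scale * (f_penta * refs.penta.value + (1.0 - f_penta) * refs.hexa.value)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        value = value + rng.normal(0.0, noise_frac * value.max(), value.size)
    return Spectrum(
        refs.hexa.wavelength_nm.copy(),
        value,
        meta={"truth_f_penta": f_penta, "scale": scale},
    )


def simulate_melt_curve(
    tm_c: float,
    width_c: float = 2.0,
    baselines: tuple[float, float, float, float] = (-20.0, 0.0, -2.0, 0.0),
    noise_frac: float = 0.0,
    seed: int = 0,
) -> MeltCurve:
    """A two-state CD melt on a 20-100 degC grid (0.25 degC sampling).

    ``baselines`` is (intercept_folded, slope_folded, intercept_unfolded,
    slope_unfolded) in mdeg and mdeg/degC; noise is additive Gaussian with
    standard deviation ``noise_frac`` times the signal excursion.
    """
    if not (20.0 < tm_c < 100.0):
        raise ValueError("tm_c must lie strictly inside the 20-100 degC scan")
    if width_c <= 0:
        raise ValueError("width_c must be > 0")
    t = np.arange(20.0, 100.0 + 0.125, 0.25)
    b_n, m_n, b_u, m_u = baselines
    folded = b_n + m_n * t
    unfolded = b_u + m_u * t
    frac_u = 1.0 / (1.0 + np.exp((tm_c - t) / width_c))
    signal = folded + (unfolded - folded) * frac_u
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_frac * np.ptp(signal), t.size)
    return MeltCurve(t, signal, meta={"truth_tm_c": tm_c, "truth_width_c": width_c})
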