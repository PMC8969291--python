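"""Theoretical b/y fragment ions and the cross-correlation (XCorr) match score.

XCorr is the classic SEQUEST-style score: the experimental spectrum is
square-root transformed, binned, locally normalised, and correlated with a
unit-intensity theoretical fragment spectrum; the correlation at lag zero is
penalised by the mean correlation over lags within +-75 bins.  Computed here
directly from the peptide and the peak list, it serves as a universal match
score that does not depend on which search engine produced the PSM.

Monoisotopic masses throughout (residue masses from pyteomics); only the b
and y series are generated, at fragment charges 1..max(1, precursor_charge-1).
No neutral losses, no a-ions, no deisotoping and no precursor-peak removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pyteomics.mass import std_aa_mass

from .io import ModifiedPeptide, Spectrum

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "NEUTRON_MASS",
    "RESIDUE_MASS",
    "FragmentIon",
    "BinnedSpectrum",
    "neutral_peptide_mass",
    "theoretical_fragments",
    "preprocess_for_xcorr",
    "xcorr",
]

PROTON_MASS = 1.007276
WATER_MASS = 18.010565
NEUTRON_MASS = 1.00335  # 13C - 12C, for isotope-error correction

RESIDUE_MASS: dict[str, float] = {
    aa: std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

#: half-width, in bins, of the lag window whose mean correlation penalises XCorr
XCORR_OFFSET = 75
#: number of equal m/z windows used for local intensity normalisation
XCORR_WINDOWS = 10
#: value each window's maximum is scaled to
XCORR_WINDOW_MAX = 50.0
#: final scale applied to the correlation difference
XCORR_SCALE = 0.005


@dataclass(frozen=True)
class FragmentIon:
    series: str  # 'b' or 'y'
    ordinal: int  # 1..len-1
    fragment_charge: int
    mz: float


@dataclass(frozen=True)
class BinnedSpectrum:
    """Processed, binned intensities; length covers max m/z plus the lag flank."""

    bin_width: float
    values: np.ndarray


def neutral_peptide_mass(p: ModifiedPeptide) -> float:
    """Monoisotopic neutral mass: residues + water + modification deltas (Da)."""
    try:
        total = sum(RESIDUE_MASS[aa] for aa in p.stripped_sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    return total + WATER_MASS + sum(d for _, d in p.mods)


def _mod_by_position(p: ModifiedPeptide) -> np.ndarray:
    """Summed modification delta per position 0..len (0 = N-terminus)."""
    deltas = np.zeros(len(p) + 1)
    for pos, d in p.mods:
        deltas[pos] += d
    return deltas


def theoretical_fragments(
    p: ModifiedPeptide, precursor_charge: int
) -> list[FragmentIon]:
    """All b_i / y_i ions, i = 1..len-1, at charges 1..max(1, precursor_charge-1).

    A modification delta travels with the fragment containing the modified
    residue; N-terminal modifications belong to the b series.
    """
    n = len(p)
    if n < 2:
        return []
    residues = np.array([RESIDUE_MASS[aa] for aa in p.stripped_sequence])
    mods = _mod_by_position(p)
    # prefix[i] = neutral mass of residues 1..i incl. N-term and contained mods
    prefix = np.cumsum(residues + mods[1:]) + mods[0]
    total = prefix[-1]
    max_z = max(1, precursor_charge - 1)
    out: list[FragmentIon] = []
    for z in range(1, max_z + 1):
        for i in range(1, n):
            b_mass = prefix[i - 1]
            y_mass = total - prefix[i - 1] + WATER_MASS
            out.append(FragmentIon("b", i, z, (b_mass + z * PROTON_MASS) / z))
            out.append(FragmentIon("y", n - i, z, (y_mass + z * PROTON_MASS) / z))
    return out


def preprocess_for_xcorr(
    s: Spectrum, bin_width: float = 0.02, flank: int = XCORR_OFFSET
) -> BinnedSpectrum:
    """Square-root transform, bin, and window-normalise an experimental spectrum.

    The occupied m/z range is split into 10 equal windows and each window is
    scaled so its maximum becomes 50, which makes the score invariant to
    uniform intensity scaling.  The returned array carries ``flank`` trailing
    zeros so lagged correlations stay in range.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(s) == 0:
        return BinnedSpectrum(bin_width, np.zeros(flank + 1))
    bins = np.rint(s.mz / bin_width).astype(np.int64)
    nd = int(bins.max()) + 1
    raw = np.zeros(nd)
    np.maximum.at(raw, bins, np.sqrt(s.intensity))
    out = np.zeros(nd + flank)
    edges = np.linspace(0, nd, XCORR_WINDOWS + 1).astype(int)
    for a, b in zip(edges[:-1], edges[1:]):
        if b > a:
            m = raw[a:b].max()
            if m > 0:
                out[a:b] = raw[a:b] * (XCORR_WINDOW_MAX / m)
    return BinnedSpectrum(bin_width, out)


def _theoretical_bins(
    p: ModifiedPeptide, precursor_charge: int, bin_width: float
) -> np.ndarray:
    mzs = np.array([f.mz for f in theoretical_fragments(p, precursor_charge)])
    if mzs.size == 0:
        return np.zeros(0, dtype=np.int64)
    return np.unique(np.rint(mzs / bin_width).astype(np.int64))


def xcorr(
    s: Spectrum,
    p: ModifiedPeptide,
    precursor_charge: int,
    bin_width: float = 0.02,
    offset: int = XCORR_OFFSET,
) -> float:
    """Fast cross-correlation score between spectrum and peptide.

    Equivalent to correlating the unit theoretical spectrum with the processed
    experimental spectrum at lag 0 and subtracting the mean correlation over
    lags -offset..+offset (excluding 0), scaled by 0.005; implemented in one
    pass by pre-subtracting each bin's local lag-window mean.
    """
    binned = preprocess_for_xcorr(s, bin_width, flank=offset)
    y = binned.values
    if not y.any():
        return 0.0
    k = offset
    pad = np.zeros(y.size + 2 * k)
    pad[k : k + y.size] = y
    csum = np.concatenate(([0.0], np.cumsum(pad)))
    winsum = csum[2 * k + 1 :] - csum[: y.size]  # sum over each bin's +-k window
    yprime = y - (winsum - y) / (2 * k)
    tbins = _theoretical_bins(p, precursor_charge, bin_width)
    tbins = tbins[tbins < y.size]  # bins beyond the flank see only zeros
    if tbins.size == 0:
        return 0.0
    return float(XCORR_SCALE * yprime[tbins].sum())
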