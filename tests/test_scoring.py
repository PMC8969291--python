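from __future__ import annotations

import numpy as np
import pytest

from conftest import spectrum_from_peptide
from psmrescore.io import ModifiedPeptide, Spectrum, parse_peptide_string
from psmrescore.scoring import (
    PROTON_MASS,
    XCORR_OFFSET,
    XCORR_SCALE,
    neutral_peptide_mass,
    preprocess_for_xcorr,
    theoretical_fragments,
    xcorr,
)


def naive_xcorr(s: Spectrum, p: ModifiedPeptide, charge: int, bin_width: float = 0.02,
                offset: int = XCORR_OFFSET) -> float:
    """Independent oracle: enumerate every lag of the raw correlation sum."""
    binned = preprocess_for_xcorr(s, bin_width, flank=offset)
    y = binned.values
    frags = theoretical_fragments(p, charge)
    tbins = np.unique(np.rint(np.array([f.mz for f in frags]) / bin_width).astype(int))

    def corr(tau: int) -> float:
        total = 0.0
        for b in tbins:
            j = b + tau
            if 0 <= j < y.size:
                total += y[j]
        return total

    lags = [t for t in range(-offset, offset + 1) if t != 0]
    return XCORR_SCALE * (corr(0) - sum(corr(t) for t in lags) / len(lags))


def random_instance(rng, n_peaks=60, pep_len=(6, 12)):
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    seq = "".join(rng.choice(aas, size=int(rng.integers(*pep_len))))
    pep = ModifiedPeptide(seq)
    mz = np.sort(rng.uniform(100, 1500, n_peaks))
    inten = rng.lognormal(4, 1, n_peaks)
    return Spectrum(key=1, precursor_mz=800.0, precursor_charge=2, mz=mz, intensity=inten), pep


class TestNeutralMass:
    @pytest.mark.parametrize(
        "pep, expected",
        [("G", 75.03203), ("PEPTIDE", 799.35994)],
    )
    def test_hand_sums(self, pep, expected):
        assert neutral_peptide_mass(parse_peptide_string(pep)) == pytest.approx(
            expected, abs=1e-4
        )

    def test_modification_delta_is_additive(self):
        base = neutral_peptide_mass(parse_peptide_string("PEPTIDE"))
        modded = neutral_peptide_mass(parse_peptide_string("PEPTIDE+15.995"))
        assert modded == pytest.approx(base + 15.995, abs=1e-9)


class TestTheoreticalFragments:
    def test_pep_charge2_values(self):
        frags = {
            (f.series, f.ordinal): f.mz
            for f in theoretical_fragments(parse_peptide_string("PEP"), 2)
        }
        assert set(frags) == {("b", 1), ("b", 2), ("y", 1), ("y", 2)}
        assert frags[("b", 2)] == pytest.approx(227.10263, abs=1e-4)
        assert frags[("y", 1)] == pytest.approx(116.07060, abs=1e-4)

    def test_single_residue_has_no_fragments(self):
        assert theoretical_fragments(parse_peptide_string("K"), 2) == []

    def test_fragment_charges_up_to_precursor_minus_one(self):
        frags = theoretical_fragments(parse_peptide_string("PEPTIDE"), 3)
        assert {f.fragment_charge for f in frags} == {1, 2}
        frags1 = theoretical_fragments(parse_peptide_string("PEPTIDE"), 1)
        assert {f.fragment_charge for f in frags1} == {1}

    def test_modification_travels_with_containing_fragment(self):
        plain = {(f.series, f.ordinal, f.fragment_charge): f.mz
                 for f in theoretical_fragments(parse_peptide_string("CAK"), 2)}
        mod = {(f.series, f.ordinal, f.fragment_charge): f.mz
               for f in theoretical_fragments(parse_peptide_string("C+57.021AK"), 2)}
        # residue 1 modified: all b ions contain it; y1/y2 do not, y at full length n/a
        assert mod[("b", 1, 1)] == pytest.approx(plain[("b", 1, 1)] + 57.021, abs=1e-9)
        assert mod[("b", 2, 1)] == pytest.approx(plain[("b", 2, 1)] + 57.021, abs=1e-9)
        assert mod[("y", 1, 1)] == pytest.approx(plain[("y", 1, 1)], abs=1e-9)
        assert mod[("y", 2, 1)] == pytest.approx(plain[("y", 2, 1)], abs=1e-9)

    def test_b_y_complementarity(self):
        p = parse_peptide_string("PEPTM+15.995IDEK")
        frags = {(f.series, f.ordinal): f.mz for f in theoretical_fragments(p, 2)}
        total = neutral_peptide_mass(p)
        n = len(p)
        for i in range(1, n):
            b = (frags[("b", i)] - PROTON_MASS)
            y = (frags[("y", n - i)] - PROTON_MASS)
            assert b + y == pytest.approx(total, abs=1e-6)


class TestPreprocess:
    def test_empty_spectrum_all_zero(self):
        s = Spectrum(1, 0.0, 2, np.zeros(0), np.zeros(0))
        assert not preprocess_for_xcorr(s).values.any()

    def test_single_peak_scaled_to_50(self):
        s = Spectrum(1, 0.0, 2, np.array([500.0]), np.array([123.0]))
        vals = preprocess_for_xcorr(s).values
        assert np.count_nonzero(vals) == 1
        assert vals.max() == pytest.approx(50.0)

    def test_equal_peaks_share_window_max(self):
        s = Spectrum(1, 0.0, 2, np.array([500.0, 500.5]), np.array([80.0, 80.0]))
        vals = preprocess_for_xcorr(s).values
        assert np.isclose(vals, 50.0).sum() == 2


class TestXcorr:
    def test_empty_spectrum_scores_zero(self):
        s = Spectrum(1, 0.0, 2, np.zeros(0), np.zeros(0))
        assert xcorr(s, parse_peptide_string("PEPTIDEK"), 2) == 0.0

    def test_self_match_beats_reversed(self):
        p = parse_peptide_string("LGEHNIDVLEGNEQFINAAK")
        s = spectrum_from_peptide(p, 2)
        rev = ModifiedPeptide(p.stripped_sequence[::-1])
        assert xcorr(s, p, 2) > xcorr(s, rev, 2)

    def test_fast_equals_naive_oracle(self, rng):
        """Fast formulation == explicit lag enumeration, 100 random instances."""
        worst = 0.0
        for _ in range(100):
            s, p = random_instance(rng)
            worst = max(worst, abs(xcorr(s, p, 2) - naive_xcorr(s, p, 2)))
        assert worst < 1e-6

    def test_invariant_to_uniform_intensity_scaling(self, rng):
        for _ in range(10):
            s, p = random_instance(rng)
            scaled = Spectrum(1, s.precursor_mz, 2, s.mz, s.intensity * 1e3)
            assert xcorr(scaled, p, 2) == pytest.approx(xcorr(s, p, 2), abs=1e-9)

    def test_self_match_beats_shuffled_peptides(self, rng):
        """Noiseless self-match spectra outrank shuffled sequences >=99/100."""
        wins = 0
        for _ in range(100):
            _, p = random_instance(rng, pep_len=(8, 14))
            s = spectrum_from_peptide(p, 2)
            letters = list(p.stripped_sequence)
            rng.shuffle(letters)
            shuffled = ModifiedPeptide("".join(letters))
            if xcorr(s, p, 2) > xcorr(s, shuffled, 2):
                wins += 1
        assert wins >= 99
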