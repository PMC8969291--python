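from __future__ import annotations

import numpy as np
import pytest

from conftest import make_record, spectrum_from_peptide
from psmrescore.features import (
    FEATURE_NAMES,
    FeatureConfig,
    annotate_spectrum,
    charge_class,
    compute_feature_vector,
    expanded_feature_names,
    missed_cleavages,
    tryptic_state,
)
from psmrescore.io import Spectrum, parse_peptide_string
from psmrescore.scoring import theoretical_fragments

CFG = FeatureConfig()


class TestAnnotate:
    def test_empty_spectrum_matches_nothing(self):
        s = Spectrum(1, 0.0, 2, np.zeros(0), np.zeros(0))
        ann = annotate_spectrum(s, parse_peptide_string("PEPTIDE"), 2, 0.02)
        assert ann.matched == [] and ann.mass_errors.size == 0

    def test_exact_theoretical_spectrum_saturates(self):
        p = parse_peptide_string("PEPTIDE")
        s = spectrum_from_peptide(p, 2)
        ann = annotate_spectrum(s, p, 2, 0.02)
        assert len(ann.matched) == 12  # 2 series x 6 ordinals, singly charged
        assert ann.ordinals["b"] == ann.ordinals["y"] == {1, 2, 3, 4, 5, 6}
        assert np.allclose(ann.mass_errors, 0.0)

    def test_error_recorded_within_tolerance(self):
        p = parse_peptide_string("PEP")
        y1 = next(f.mz for f in theoretical_fragments(p, 2) if f.series == "y" and f.ordinal == 1)
        tol = 0.02
        s = Spectrum(1, 0.0, 2, np.array([y1 + 0.5 * tol]), np.array([10.0]))
        ann = annotate_spectrum(s, p, 2, tol)
        assert 1 in ann.ordinals["y"]
        err = [e for (ion, _, _, _), e in zip(ann.matched, ann.mass_errors) if ion.series == "y"]
        assert err[0] == pytest.approx(0.5 * tol, abs=1e-9)

    def test_each_ion_claims_at_most_one_peak(self):
        p = parse_peptide_string("PEPTIDE")
        s = spectrum_from_peptide(p, 2)
        ann = annotate_spectrum(s, p, 2, 0.02)
        per_ion = [(ion.series, ion.ordinal, ion.fragment_charge) for ion, _, _, _ in ann.matched]
        assert len(per_ion) == len(set(per_ion))


class TestTrypticState:
    @pytest.mark.parametrize(
        "pre, pep, post, expected",
        [
            ("K", "TIDDR", "A", 2),
            ("A", "TIDDR", "A", 0),
            ("K", "TIDDG", "A", 1),
            ("A", "TIDDG", "A", None),
            ("-", "TIDDR", "A", 2),  # protein N-terminus conforms
            ("K", "TIDDG", "-", 2),  # protein C-terminus conforms
            ("K", "PIDDR", "A", 0),  # proline after the cut blocks the N-term
            ("K", "TIDDK", "P", 1),  # proline following blocks the C-term
        ],
    )
    def test_states(self, pre, pep, post, expected):
        assert tryptic_state(pre, parse_peptide_string(pep), post, "trypsin") == expected

    def test_unknown_enzyme(self):
        with pytest.raises(ValueError, match="unknown enzyme"):
            tryptic_state("K", parse_peptide_string("TIDDR"), "A", "pepsinX")


class TestMissedCleavages:
    @pytest.mark.parametrize(
        "pep, expected",
        [("TIDDR", 0), ("TIDDKR", 1), ("TIDDKPR", 0), ("KRKR", 3)],
    )
    def test_counts(self, pep, expected):
        assert missed_cleavages(parse_peptide_string(pep), "trypsin") == expected

    def test_trypsin_p_ignores_proline_block(self):
        assert missed_cleavages(parse_peptide_string("TIDDKPR"), "trypsin/p") == 1


class TestChargeClass:
    @pytest.mark.parametrize("z, expected", [(1, 1), (3, 3), (6, 6), (8, 6)])
    def test_capping(self, z, expected):
        assert charge_class(z) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            charge_class(0)


class TestFeatureVector:
    def test_25_names_and_32_expanded(self):
        rec = make_record("PEPTIDE")
        fv = compute_feature_vector(rec, spectrum_from_peptide(rec.peptide, 2), CFG)
        assert len(FEATURE_NAMES) == 25
        assert set(fv.as_dict()) == set(FEATURE_NAMES)
        assert fv.expanded().shape == (32,)
        assert len(expanded_feature_names()) == 32

    def test_saturated_fixture(self):
        """Exact b/y spectrum: full coverage, zero errors, n-term tryptic only.

        The peptide must not start with proline, which would block the
        N-terminal tryptic site and change the enzymatic state.
        """
        rec = make_record("GASTIDE", pre="K", post="A")
        fv = compute_feature_vector(rec, spectrum_from_peptide(rec.peptide, 2), CFG)
        assert fv.seq_cover_y == 1.0 and fv.seq_cover_b == 1.0
        assert fv.num_consecutive_y == 6 and fv.num_consecutive_b == 6
        assert fv.mean_frag_mass_err == 0.0 and fv.sd_frag_mass_err == 0.0
        assert fv.tryptic == 1
        assert fv.pep_len == 7 and fv.charge == 2
        assert fv.n_anno_peaks == 12
        assert fv.abs_mass_diff == pytest.approx(0.0, abs=1e-6)
        assert fv.delta_xcorr == 0.0  # singleton group

    def test_fraction_of_matched_intensity(self):
        """TIC 100 with 40 units under matched y peaks gives frac_intensity_y 0.4."""
        p = parse_peptide_string("PEP")
        frags = {(f.series, f.ordinal): f.mz for f in theoretical_fragments(p, 2)}
        mz = np.array(sorted([frags[("y", 1)], frags[("y", 2)], 800.0, 900.0]))
        inten = {frags[("y", 1)]: 25.0, frags[("y", 2)]: 15.0, 800.0: 40.0, 900.0: 20.0}
        s = Spectrum(1, 0.0, 2, mz, np.array([inten[m] for m in mz]))
        rec = make_record("PEP")
        fv = compute_feature_vector(rec, s, CFG)
        assert fv.frac_intensity_y == pytest.approx(0.4)
        assert fv.sum_intensity_all == pytest.approx(np.log10(101.0))

    def test_mass_diff_isotope_correction(self):
        from psmrescore.scoring import NEUTRON_MASS, PROTON_MASS, neutral_peptide_mass

        p = parse_peptide_string("PEPTIDEK")
        m = neutral_peptide_mass(p)
        z = 2
        rec = make_record("PEPTIDEK", precursor_mz=(m + NEUTRON_MASS + z * PROTON_MASS) / z)
        fv = compute_feature_vector(rec, spectrum_from_peptide(p, z), CFG)
        assert abs(fv.mass_diff) < 1e-6  # one-neutron offset is snapped away
        raw_cfg = FeatureConfig(isotope_correction=False)
        fv_raw = compute_feature_vector(rec, spectrum_from_peptide(p, z), raw_cfg)
        assert fv_raw.mass_diff == pytest.approx(NEUTRON_MASS, abs=1e-6)

    def test_tryptic_none_expands_to_zero_onehot(self):
        rec = make_record("TIDDG", pre="A", post="A")
        fv = compute_feature_vector(rec, spectrum_from_peptide(rec.peptide, 2), CFG)
        assert fv.tryptic == -1
        v = fv.expanded()
        names = expanded_feature_names()
        tryptic_slice = [names.index(f"tryptic_{t}") for t in (0, 1, 2)]
        assert not v[tryptic_slice].any()

    def test_invariants_on_random_spectra(self, rng):
        """frac sums bounded, coverage bounds, consecutive <= matched <= len-1."""
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(30):
            seq = "".join(rng.choice(aas, size=int(rng.integers(6, 13))))
            rec = make_record(seq)
            mzv = np.sort(rng.uniform(100, 1400, 50))
            s = Spectrum(1, rec.precursor_mz, 2, mzv, rng.lognormal(4, 1, 50))
            fv = compute_feature_vector(rec, s, CFG)
            assert 0.0 <= fv.frac_intensity_y <= 1.0
            assert 0.0 <= fv.frac_intensity_b <= 1.0
            assert 0.0 <= fv.seq_cover_y <= 1.0 and 0.0 <= fv.seq_cover_b <= 1.0
            assert fv.num_consecutive_y <= len(seq) - 1
            assert fv.abs_mass_diff == pytest.approx(abs(fv.mass_diff))
            assert fv.n_anno_peaks <= 50


def test_target_xcorr_dominates_decoy_xcorr():
    """On generated data the target XCorr distribution sits above the decoys'."""
    from psmrescore.pipeline import extract_features
    from psmrescore.synthetic import SyntheticConfig, generate_psms

    cfg = SyntheticConfig(n_correct=150, n_incorrect=100, n_decoys=250, seed=11)
    records, spectra, _ = generate_psms(cfg)
    _, _, xcorrs = extract_features(records, {"synthetic.mgf": spectra}, CFG)
    decoy = np.array([r.is_decoy for r in records])
    t, d = np.sort(xcorrs[~decoy]), np.sort(xcorrs[decoy])
    # stochastic dominance at the quartiles and the median
    for q in (0.25, 0.5, 0.75):
        assert np.quantile(t, q) > np.quantile(d, q)
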