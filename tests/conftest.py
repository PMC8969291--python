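from __future__ import annotations

import numpy as np
import pytest

from psmrescore.io import ModifiedPeptide, PsmRecord, Spectrum
from psmrescore.scoring import theoretical_fragments


def spectrum_from_peptide(
    peptide: ModifiedPeptide,
    precursor_charge: int,
    intensity: float = 100.0,
    key: int = 1,
) -> Spectrum:
    """A noiseless spectrum containing exactly the peptide's theoretical peaks."""
    frags = theoretical_fragments(peptide, precursor_charge)
    mz = np.array(sorted(f.mz for f in frags))
    return Spectrum(
        key=key,
        precursor_mz=0.0 if not len(mz) else float(mz[-1]),
        precursor_charge=precursor_charge,
        mz=mz,
        intensity=np.full(mz.size, intensity),
    )


def make_record(
    peptide: str | ModifiedPeptide,
    charge: int = 2,
    scan: int = 1,
    precursor_mz: float | None = None,
    pre: str = "K",
    post: str = "A",
    is_decoy: bool = False,
    source_file: str = "run.mgf",
) -> PsmRecord:
    from psmrescore.io import parse_peptide_string
    from psmrescore.scoring import PROTON_MASS, neutral_peptide_mass

    pep = parse_peptide_string(peptide) if isinstance(peptide, str) else peptide
    if precursor_mz is None:
        precursor_mz = (neutral_peptide_mass(pep) + charge * PROTON_MASS) / charge
    acc = "XXX_sp|TEST" if is_decoy else "sp|TEST"
    return PsmRecord(
        source_file=source_file,
        scan=scan,
        charge=charge,
        precursor_mz=precursor_mz,
        peptide=pep,
        proteins=((acc, pre, post),),
        is_decoy=is_decoy,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
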