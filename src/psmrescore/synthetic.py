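"""Ground-truth-labelled synthetic PSM datasets in the TSV + MGF input contract.

The generator emulates the statistical structure of a real target-decoy
search at desk scale: a pool of tryptic peptides is digested from random
protein sequences; "correct" PSMs get spectra built from their own b/y ions
(partial fragment coverage, intensity variation, m/z jitter, noise peaks),
while "incorrect" target PSMs and decoy PSMs pair a genuine spectrum of one
peptide with a different, precursor-mass-matched peptide — so decoys behave
like real random hits and the decoy/incorrect-target exchangeability that
underpins decoy-based FDR estimation holds by construction.

With ``auxiliary_signal`` enabled, correct PSMs receive instrument-like tight
fragment m/z jitter while accidental matches keep tolerance-limited uniform
errors; the fragment mass-error features then carry class signal that XCorr
(insensitive below its bin width) does not exploit, which is exactly the
headroom a learned multi-feature score can convert into extra identifications.
Truth labels are returned separately and never written into the PSM table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pyteomics import mgf as _mgf

from .io import ModifiedPeptide, PsmRecord, Spectrum
from .scoring import PROTON_MASS, neutral_peptide_mass, theoretical_fragments

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_psms", "generate_dataset"]

_CARBAMIDOMETHYL = 57.021
_OXIDATION = 15.995


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults give 5,000 target PSMs of which 60% are correct, plus 5,000
    decoys — a desk-scale stand-in for a cell-line search result.  Coverage
    is drawn per PSM as uniform(center - spread, center + spread) clipped to
    [0.05, 1], so correct and incorrect XCorr distributions overlap the way
    target/decoy score distributions do in practice.
    """

    n_correct: int = 3000
    n_incorrect: int = 2000
    n_decoys: int = 5000
    pep_len_range: tuple[int, int] = (7, 14)
    fragment_coverage_correct: float = 0.35
    fragment_coverage_incorrect: float = 0.35
    coverage_spread: float = 0.30
    n_noise_peaks: int = 40
    intensity_noise: float = 0.7  # lognormal sigma of peak intensities
    mass_jitter_sd: float = 0.004  # Da, fragment m/z jitter
    aux_mass_jitter_sd: float = 0.0015  # Da, for correct PSMs when auxiliary_signal
    auxiliary_signal: bool = True
    decoy_prefix: str = "XXX_"
    n_proteins: int = 60
    protein_length: int = 360
    mass_match_window: float = 2.0  # Da, spectrum-vs-assigned mass matching
    precursor_ppm_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fragment_coverage_correct <= 1):
            raise ValueError("fragment_coverage_correct must be in [0, 1]")
        if not (0 <= self.fragment_coverage_incorrect <= 1):
            raise ValueError("fragment_coverage_incorrect must be in [0, 1]")
        if min(self.n_correct, self.n_incorrect, self.n_decoys) < 0:
            raise ValueError("PSM counts must be >= 0")


@dataclass
class SyntheticDataset:
    tsv_path: Path
    mgf_path: Path
    truth_path: Path
    labels: np.ndarray  # 1 = correct target, 0 = incorrect target or decoy


@dataclass(frozen=True)
class _PoolEntry:
    peptide: ModifiedPeptide
    mass: float
    accession: str
    pre: str
    post: str


_AA = "ACDEFGHIKLMNPQRSTVWY"
# rough residue frequencies so digests look protein-like (Leu/Ser rich, Trp rare)
_AA_P = np.array(
    [8.3, 1.4, 5.4, 6.8, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7, 2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.3, 6.9, 1.1, 2.9]
)
_AA_P = _AA_P / _AA_P.sum()


def _digest_tryptic(
    seq: str, min_len: int, max_len: int, max_missed: int = 1
) -> list[tuple[str, str, str]]:
    """(peptide, pre, post) for tryptic peptides with up to max_missed missed sites."""
    sites = [i + 1 for i in range(len(seq) - 1) if seq[i] in "KR" and seq[i + 1] != "P"]
    bounds = [0] + sites + [len(seq)]
    out = []
    for i in range(len(bounds) - 1):
        for m in range(max_missed + 1):
            j = i + 1 + m
            if j >= len(bounds):
                break
            pep = seq[bounds[i] : bounds[j]]
            if not min_len <= len(pep) <= max_len:
                continue
            pre = seq[bounds[i] - 1] if bounds[i] > 0 else "-"
            post = seq[bounds[j]] if bounds[j] < len(seq) else "-"
            out.append((pep, pre, post))
    return out


def _apply_mods(seq: str, rng: np.random.Generator) -> ModifiedPeptide:
    """Fixed carbamidomethyl on every Cys; oxidation on one Met 30% of the time."""
    mods = [(i + 1, _CARBAMIDOMETHYL) for i, aa in enumerate(seq) if aa == "C"]
    met = [i + 1 for i, aa in enumerate(seq) if aa == "M"]
    if met and rng.random() < 0.3:
        mods.append((int(rng.choice(met)), _OXIDATION))
    mods.sort()
    return ModifiedPeptide(seq, tuple(mods))


def _build_pool(cfg: SyntheticConfig, rng: np.random.Generator) -> list[_PoolEntry]:
    lo, hi = cfg.pep_len_range
    entries: list[_PoolEntry] = []
    seen: set[str] = set()
    for pi in range(cfg.n_proteins):
        seq = "".join(rng.choice(list(_AA), size=cfg.protein_length, p=_AA_P))
        acc = f"sp|SYNP{pi:04d}"
        for pep, pre, post in _digest_tryptic(seq, lo, hi):
            if pep in seen:
                continue
            seen.add(pep)
            peptide = _apply_mods(pep, rng)
            entries.append(
                _PoolEntry(peptide, neutral_peptide_mass(peptide), acc, pre, post)
            )
    if len(entries) < 10:
        raise ValueError("peptide pool too small; increase n_proteins")
    return entries


def _pseudo_reverse(entry: _PoolEntry, prefix: str) -> _PoolEntry:
    """Reverse all but the C-terminal residue, remapping modification positions."""
    seq = entry.peptide.stripped_sequence
    n = len(seq)
    rev = seq[: n - 1][::-1] + seq[-1]
    mods = tuple(
        sorted((pos if pos in (0, n) else n - pos, d) for pos, d in entry.peptide.mods)
    )
    peptide = ModifiedPeptide(rev, mods)
    return _PoolEntry(peptide, entry.mass, prefix + entry.accession, entry.pre, entry.post)


def _draw_coverage(center: float, spread: float, rng: np.random.Generator) -> float:
    return float(np.clip(center + rng.uniform(-spread, spread), 0.05, 1.0))


def _build_spectrum(
    entry: _PoolEntry,
    charge: int,
    coverage: float,
    jitter_sd: float,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    frags = theoretical_fragments(entry.peptide, charge)
    mzs = np.array([f.mz for f in frags])
    keep = rng.random(mzs.size) < coverage
    mz = mzs[keep] + rng.normal(0.0, jitter_sd, int(keep.sum())) if jitter_sd > 0 else mzs[keep]
    inten = rng.lognormal(mean=5.0, sigma=cfg.intensity_noise, size=mz.size)
    if cfg.n_noise_peaks > 0:
        top = max(float(mzs.max()) if mzs.size else 500.0, 500.0)
        nmz = rng.uniform(120.0, top * 1.05, cfg.n_noise_peaks)
        nint = rng.lognormal(mean=3.8, sigma=cfg.intensity_noise, size=cfg.n_noise_peaks)
        mz = np.concatenate([mz, nmz])
        inten = np.concatenate([inten, nint])
    order = np.argsort(mz, kind="stable")
    return mz[order], inten[order]


def _mass_matched_other(
    mass: float,
    own_seq: str,
    pool: list[_PoolEntry],
    sorted_masses: np.ndarray,
    sorted_idx: np.ndarray,
    window: float,
    rng: np.random.Generator,
) -> _PoolEntry:
    lo = int(np.searchsorted(sorted_masses, mass - window, side="left"))
    hi = int(np.searchsorted(sorted_masses, mass + window, side="right"))
    cands = [
        int(sorted_idx[k])
        for k in range(lo, hi)
        if pool[int(sorted_idx[k])].peptide.stripped_sequence != own_seq
    ]
    if cands:
        return pool[int(rng.choice(cands))]
    # no neighbour in window: fall back to the nearest-mass different peptide
    k = int(np.clip(np.searchsorted(sorted_masses, mass), 0, sorted_masses.size - 1))
    for step in range(sorted_masses.size):
        for kk in (k - step, k + step):
            if 0 <= kk < sorted_masses.size:
                cand = pool[int(sorted_idx[kk])]
                if cand.peptide.stripped_sequence != own_seq:
                    return cand
    raise RuntimeError("no mass-matched peptide available")


def generate_psms(
    cfg: SyntheticConfig = SyntheticConfig(),
    mgf_name: str = "synthetic.mgf",
) -> tuple[list[PsmRecord], dict[int, Spectrum], np.ndarray]:
    """In-memory dataset: PSM records, spectra keyed by scan, truth labels.

    Labels: 1 for a correct target PSM, 0 for incorrect targets and decoys.
    """
    rng = np.random.default_rng(cfg.seed)
    pool = _build_pool(cfg, rng)
    masses = np.array([e.mass for e in pool])
    sorted_idx = np.argsort(masses, kind="stable")
    sorted_masses = masses[sorted_idx]

    jitter_correct = cfg.aux_mass_jitter_sd if cfg.auxiliary_signal else cfg.mass_jitter_sd

    plan: list[str] = (
        ["correct"] * cfg.n_correct
        + ["incorrect"] * cfg.n_incorrect
        + ["decoy"] * cfg.n_decoys
    )
    rng.shuffle(plan)

    records: list[PsmRecord] = []
    spectra: dict[int, Spectrum] = {}
    labels = np.zeros(len(plan), dtype=np.int8)
    for scan0, kind in enumerate(plan):
        scan = scan0 + 1
        charge = int(rng.choice([2, 3], p=[0.7, 0.3]))
        assigned = pool[int(rng.integers(len(pool)))]
        if kind == "correct":
            spectrum_pep = assigned
            coverage = _draw_coverage(cfg.fragment_coverage_correct, cfg.coverage_spread, rng)
            jitter = jitter_correct
            labels[scan0] = 1
        else:
            spectrum_pep = _mass_matched_other(
                assigned.mass,
                assigned.peptide.stripped_sequence,
                pool,
                sorted_masses,
                sorted_idx,
                cfg.mass_match_window,
                rng,
            )
            coverage = _draw_coverage(
                cfg.fragment_coverage_incorrect, cfg.coverage_spread, rng
            )
            jitter = cfg.mass_jitter_sd
        if kind == "decoy":
            assigned = _pseudo_reverse(assigned, cfg.decoy_prefix)
        mz, inten = _build_spectrum(spectrum_pep, charge, coverage, jitter, cfg, rng)
        precursor_mz = (assigned.mass + charge * PROTON_MASS) / charge
        precursor_mz *= 1.0 + rng.normal(0.0, cfg.precursor_ppm_sd) * 1e-6
        spectra[scan] = Spectrum(
            key=scan,
            precursor_mz=precursor_mz,
            precursor_charge=charge,
            mz=mz,
            intensity=inten,
        )
        records.append(
            PsmRecord(
                source_file=mgf_name,
                scan=scan,
                charge=charge,
                precursor_mz=precursor_mz,
                peptide=assigned.peptide,
                proteins=((assigned.accession, assigned.pre, assigned.post),),
                is_decoy=kind == "decoy",
            )
        )
    return records, spectra, labels


def generate_dataset(
    cfg: SyntheticConfig = SyntheticConfig(),
    out_dir: Path | str = ".",
) -> SyntheticDataset:
    """Write the TSV + MGF pair (and a separate truth table) to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mgf_path = out_dir / "synthetic.mgf"
    tsv_path = out_dir / "synthetic_psms.tsv"
    truth_path = out_dir / "synthetic_truth.tsv"

    records, spectra, labels = generate_psms(cfg, mgf_name=mgf_path.name)

    blocks = [
        {
            "m/z array": spectra[r.scan].mz,
            "intensity array": spectra[r.scan].intensity,
            "params": {
                "title": f"synthetic scan {r.scan}",
                "scans": r.scan,
                "pepmass": spectra[r.scan].precursor_mz,
                "charge": r.charge,
            },
        }
        for r in records
    ]
    _mgf.write(blocks, output=str(mgf_path), file_mode="w")

    with open(tsv_path, "wt", encoding="utf-8") as fh:
        fh.write("File\tScan\tCharge\tPrecursorMZ\tPeptide\tProtein\n")
        for r in records:
            acc, pre, post = r.proteins[0]
            fh.write(
                f"{r.source_file}\t{r.scan}\t{r.charge}\t{r.precursor_mz!r}\t"
                f"{r.peptide.serialize()}\t{acc}(pre = '{pre}', post = '{post}')\n"
            )
    with open(truth_path, "wt", encoding="utf-8") as fh:
        fh.write("Scan\tIsCorrect\tIsDecoy\n")
        for r, lab in zip(records, labels):
            fh.write(f"{r.scan}\t{int(lab)}\t{int(r.is_decoy)}\n")
    return SyntheticDataset(tsv_path, mgf_path, truth_path, labels)
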