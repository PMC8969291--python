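"""Reading and writing the engine-agnostic PSM input contract.

Search results arrive as a tab-separated table whose six required columns
(spectrum file, scan, charge, precursor m/z, peptide, protein) are located by
user-supplied zero-based indices rather than by header names, so the output of
any database search tool can be consumed after a trivial export.  Peptides
carry modifications inline as signed mass deltas following the modified
residue (``"PEPTM+15.995IDE"``, with an annotation before the first residue
denoting an N-terminal modification).  Protein fields list parent accessions
separated by ``";"``, each optionally suffixed with the flanking residues as
``(pre = 'K', post = 'A')``; ``'-'`` marks a protein terminus.  Peak lists are
read from Mascot Generic Format (MGF) files, indexed by SCANS when present and
by TITLE otherwise.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from pyteomics import mgf as _mgf

__all__ = [
    "AMINO_ACIDS",
    "ColumnSpec",
    "ModifiedPeptide",
    "PsmRecord",
    "Spectrum",
    "PeptideParseError",
    "TableFormatError",
    "MgfFormatError",
    "parse_peptide_string",
    "parse_protein_field",
    "read_psm_table",
    "read_mgf",
    "write_rescored_table",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class PeptideParseError(ValueError):
    """A peptide string does not follow the inline-modification grammar."""


class TableFormatError(ValueError):
    """A PSM table row violates the input contract."""


class MgfFormatError(ValueError):
    """An MGF file cannot be indexed unambiguously."""


@dataclass(frozen=True)
class ModifiedPeptide:
    """A stripped peptide sequence plus positioned modification mass deltas.

    ``mods`` holds ``(position, delta_mass)`` pairs where position is the
    1-based residue index carrying the modification, or 0 for an N-terminal
    modification.  Deltas are in Da and may be negative.
    """

    stripped_sequence: str
    mods: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        # canonical order: by position, preserving insertion order within a position
        object.__setattr__(
            self,
            "mods",
            tuple(
                sorted(((int(p), float(d)) for p, d in self.mods), key=lambda t: t[0])
            ),
        )
        seq = self.stripped_sequence
        if not seq:
            raise PeptideParseError("empty peptide sequence")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise PeptideParseError(
                f"non-amino-acid character {sorted(bad)[0]!r} in peptide {seq!r}"
            )
        for pos, _ in self.mods:
            if not 0 <= pos <= len(seq):
                raise PeptideParseError(
                    f"modification position {pos} outside [0, {len(seq)}] for {seq!r}"
                )

    def __len__(self) -> int:
        return len(self.stripped_sequence)

    def serialize(self) -> str:
        """Inline-annotation string; ``parse_peptide_string`` round-trips it."""
        by_pos: dict[int, list[float]] = {}
        for pos, delta in self.mods:
            by_pos.setdefault(pos, []).append(delta)

        def _fmt(delta: float) -> str:
            # positional (never exponent) notation: 'E' would be ambiguous with Glu
            digits = np.format_float_positional(abs(delta), trim="-")
            return ("+" if delta >= 0 else "-") + digits

        parts = ["".join(_fmt(d) for d in by_pos.get(0, []))]
        for i, aa in enumerate(self.stripped_sequence, start=1):
            parts.append(aa)
            parts.append("".join(_fmt(d) for d in by_pos.get(i, [])))
        return "".join(parts)


_MOD_RE = re.compile(r"([+-])\s*(\d+(?:\.\d+)?)")


def parse_peptide_string(raw: str) -> ModifiedPeptide:
    """Parse a peptide with inline modification deltas, e.g. ``"M+15.995"``.

    Whitespace around the sign is tolerated (search tools print ``"M + 15.995"``).
    An annotation before the first residue is an N-terminal modification.
    """
    raw = raw.strip()
    seq: list[str] = []
    mods: list[tuple[int, float]] = []
    i = 0
    while i < len(raw):
        ch = raw[i]
        if ch.isalpha():
            if ch.upper() not in AMINO_ACIDS:
                raise PeptideParseError(
                    f"non-amino-acid character {ch!r} in peptide {raw!r}"
                )
            seq.append(ch.upper())
            i += 1
        elif ch in "+-" or ch.isspace():
            j = i
            while j < len(raw) and raw[j].isspace():
                j += 1
            m = _MOD_RE.match(raw, j)
            if m is None:
                raise PeptideParseError(f"malformed modification mass in {raw!r} at offset {i}")
            delta = float(m.group(2))
            if m.group(1) == "-":
                delta = -delta
            mods.append((len(seq), delta))
            i = m.end()
        else:
            raise PeptideParseError(f"unexpected character {ch!r} in peptide {raw!r}")
    if not seq:
        raise PeptideParseError(f"no amino acids in peptide string {raw!r}")
    return ModifiedPeptide("".join(seq), tuple(mods))


@dataclass(frozen=True)
class ColumnSpec:
    """Zero-based column indices locating the six required fields in the TSV."""

    file_col: int
    scan_col: int
    charge_col: int
    precursor_mz_col: int
    peptide_col: int
    protein_col: int
    extra_score_cols: tuple[int, ...] = ()
    has_header: Optional[bool] = None  # None: auto-detect from the first row

    def __post_init__(self) -> None:
        object.__setattr__(self, "extra_score_cols", tuple(self.extra_score_cols))
        req = self.required_cols
        if any(c < 0 for c in req + self.extra_score_cols):
            raise ValueError("column indices must be non-negative")
        if len(set(req)) != 6:
            raise ValueError("the six required column indices must be distinct")
        if set(self.extra_score_cols) & set(req):
            raise ValueError("extra_score_cols overlap the required columns")

    @property
    def required_cols(self) -> tuple[int, ...]:
        return (
            self.file_col,
            self.scan_col,
            self.charge_col,
            self.precursor_mz_col,
            self.peptide_col,
            self.protein_col,
        )

    @property
    def max_col(self) -> int:
        return max(self.required_cols + self.extra_score_cols)


@dataclass(frozen=True)
class PsmRecord:
    """One candidate peptide-spectrum match read from the search-result table."""

    source_file: str
    scan: int
    charge: int
    precursor_mz: float
    peptide: ModifiedPeptide
    proteins: tuple[tuple[str, str, str], ...]  # (accession, pre_aa, post_aa)
    is_decoy: bool
    extra_scores: tuple[float, ...] = ()
    rank: int = 1

    def __post_init__(self) -> None:
        if not self.proteins:
            raise TableFormatError("PSM has an empty protein list")
        if self.charge < 1:
            raise TableFormatError(f"charge must be >= 1, got {self.charge}")
        if not self.precursor_mz > 0:
            raise TableFormatError(f"precursor m/z must be positive, got {self.precursor_mz}")


@dataclass
class Spectrum:
    """An MS/MS peak list with precursor metadata; peaks kept sorted by m/z."""

    key: Union[int, str]
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return int(self.mz.size)


_FLANK_RE = re.compile(
    r"^(?P<acc>.*?)\s*\(\s*pre\s*=\s*['‘’](?P<pre>.)['‘’]\s*,"
    r"\s*post\s*=\s*['‘’](?P<post>.)['‘’]\s*\)\s*$"
)


def parse_protein_field(raw: str) -> tuple[tuple[str, str, str], ...]:
    """Split a ``";"``-separated protein list into (accession, pre, post) triples.

    Accessions lacking the ``(pre = 'X', post = 'Y')`` suffix get ``'-'`` for
    both flanks (treated as protein termini).
    """
    out = []
    for item in raw.split(";"):
        item = item.strip()
        if not item:
            continue
        m = _FLANK_RE.match(item)
        if m:
            out.append((m.group("acc").strip(), m.group("pre"), m.group("post")))
        else:
            out.append((item, "-", "-"))
    if not out:
        raise TableFormatError(f"empty protein field: {raw!r}")
    return tuple(out)


def _looks_like_header(fields: Sequence[str], spec: ColumnSpec) -> bool:
    for col in (spec.charge_col, spec.precursor_mz_col, spec.scan_col):
        try:
            float(fields[col])
        except (ValueError, IndexError):
            return True
    return False


def read_psm_table(
    path: Union[str, Path], spec: ColumnSpec, decoy_prefix: str = "XXX_"
) -> list[PsmRecord]:
    """Read a PSM table; one record per row, in file order.

    A PSM is flagged decoy only when *all* parent accessions carry
    ``decoy_prefix`` — a peptide shared with any target protein counts as a
    target, the standard target-decoy convention.
    """
    path = Path(path)
    records: list[PsmRecord] = []
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines:
        first = lines[0].split("\t")
        header = (
            spec.has_header
            if spec.has_header is not None
            else _looks_like_header(first, spec)
        )
        if header:
            start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) <= spec.max_col:
            raise TableFormatError(
                f"row {lineno}: {len(fields)} columns, need at least {spec.max_col + 1}"
            )
        try:
            scan = int(float(fields[spec.scan_col]))
            charge = int(float(fields[spec.charge_col]))
            precursor_mz = float(fields[spec.precursor_mz_col])
        except ValueError as exc:
            raise TableFormatError(f"row {lineno}: un-parseable numeric field ({exc})") from None
        if not math.isfinite(precursor_mz):
            raise TableFormatError(f"row {lineno}: non-finite precursor m/z")
        try:
            peptide = parse_peptide_string(fields[spec.peptide_col])
        except PeptideParseError as exc:
            raise TableFormatError(f"row {lineno}: {exc}") from None
        proteins = parse_protein_field(fields[spec.protein_col])
        is_decoy = all(acc.startswith(decoy_prefix) for acc, _, _ in proteins)
        extras = tuple(float(fields[c]) for c in spec.extra_score_cols)
        records.append(
            PsmRecord(
                source_file=fields[spec.file_col].strip(),
                scan=scan,
                charge=charge,
                precursor_mz=precursor_mz,
                peptide=peptide,
                proteins=proteins,
                is_decoy=is_decoy,
                extra_scores=extras,
            )
        )
    return records


def read_mgf(path: Union[str, Path]) -> dict[Union[int, str], Spectrum]:
    """Read an MGF file into a mapping keyed by SCANS (fallback: TITLE).

    Duplicate keys are an error — downstream lookup must be unambiguous.
    Out-of-order peak lists are sorted, not rejected.
    """
    spectra: dict[Union[int, str], Spectrum] = {}
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry.get("params", {})
            if "scans" in params:
                key: Union[int, str] = int(str(params["scans"]).split("-")[0])
            elif "title" in params:
                key = str(params["title"])
            else:
                raise MgfFormatError(
                    f"{path}: spectrum block missing both SCANS and TITLE"
                )
            if key in spectra:
                raise MgfFormatError(f"{path}: duplicate spectrum key {key!r}")
            pepmass = params.get("pepmass", (0.0,))
            precursor_mz = float(pepmass[0]) if pepmass and pepmass[0] else 0.0
            charge_list = params.get("charge")
            precursor_charge = int(charge_list[0]) if charge_list else 0
            spectra[key] = Spectrum(
                key=key,
                precursor_mz=precursor_mz,
                precursor_charge=precursor_charge,
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
            )
    return spectra


def _protein_field(rec: PsmRecord) -> str:
    return ";".join(
        f"{acc}(pre = '{pre}', post = '{post}')" for acc, pre, post in rec.proteins
    )


def write_rescored_table(records, features, results, path) -> None:
    """Write the rescored PSM table: input columns, the 25 named features,
    then ``svm_score`` and ``q_value``.

    ``features`` is a sequence of :class:`~psmrescore.features.FeatureVector`
    aligned with ``records``; ``results`` carries per-PSM scores/q-values in
    the same order.
    """
    import pandas as pd

    from .features import FEATURE_NAMES

    n = len(records)
    if len(features) != n or len(results.scores) != n or len(results.qvalues) != n:
        raise ValueError(
            f"records ({n}), features ({len(features)}) and results "
            f"({len(results.scores)}) must be aligned and equal length"
        )
    data: dict[str, list] = {
        "File": [r.source_file for r in records],
        "Scan": [r.scan for r in records],
        "Charge": [r.charge for r in records],
        "PrecursorMZ": [r.precursor_mz for r in records],
        "Peptide": [r.peptide.serialize() for r in records],
        "Protein": [_protein_field(r) for r in records],
    }
    n_extra = len(records[0].extra_scores) if n else 0
    for j in range(n_extra):
        data[f"ExtraScore{j}"] = [r.extra_scores[j] for r in records]
    for name in FEATURE_NAMES:
        data[name] = [getattr(fv, name) for fv in features]
    data["svm_score"] = list(np.asarray(results.scores, dtype=float))
    data["q_value"] = list(np.asarray(results.qvalues, dtype=float))
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
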