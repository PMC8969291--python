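"""End-to-end glue: table + spectra -> features -> iterative SVM -> output.

This is the library-level workflow the command line wraps.  It resolves each
PSM's spectrum, computes XCorr once per PSM (sharing it between the feature
vector and the rank-1/rank-2 margin within each (file, scan, charge) group),
assembles the expanded numeric matrix (appending any pass-through tool
scores), and runs the iterative rescoring loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .features import FeatureConfig, FeatureVector, compute_feature_vector
from .io import (
    ColumnSpec,
    PsmRecord,
    Spectrum,
    read_mgf,
    read_psm_table,
    write_rescored_table,
)
from .rescoring import RescoringResult, TrainingConfig, rescore_iteratively
from .scoring import xcorr as _xcorr

__all__ = [
    "SpectrumLookupError",
    "extract_features",
    "rescore_records",
    "rescore_file",
    "load_spectra_for",
]


class SpectrumLookupError(KeyError):
    pass


def _resolve_spectrum(
    rec: PsmRecord, spectra_by_file: Mapping[str, Mapping]
) -> Spectrum:
    try:
        per_file = spectra_by_file[rec.source_file]
    except KeyError:
        raise SpectrumLookupError(
            f"no spectra loaded for source file {rec.source_file!r}"
        ) from None
    try:
        return per_file[rec.scan]
    except KeyError:
        raise SpectrumLookupError(
            f"scan {rec.scan} not found in spectra of {rec.source_file!r}"
        ) from None


def extract_features(
    records: Sequence[PsmRecord],
    spectra_by_file: Mapping[str, Mapping],
    cfg: FeatureConfig = FeatureConfig(),
) -> tuple[list[FeatureVector], np.ndarray, np.ndarray]:
    """Feature vectors, expanded matrix (with extra tool scores appended) and
    per-PSM XCorr for every record, preserving input order.

    PSMs sharing (file, scan, charge) are treated as competing ranks of the
    same spectrum: each one's delta_xcorr is its XCorr minus the best XCorr
    among the others, and ranks are assigned by descending XCorr.
    """
    n = len(records)
    xcorrs = np.zeros(n)
    specs: list[Spectrum] = []
    groups: dict[tuple, list[int]] = {}
    for i, rec in enumerate(records):
        spec = _resolve_spectrum(rec, spectra_by_file)
        specs.append(spec)
        xcorrs[i] = _xcorr(spec, rec.peptide, rec.charge, cfg.bin_width, cfg.xcorr_offset)
        groups.setdefault((rec.source_file, rec.scan, rec.charge), []).append(i)

    rivals: list[Optional[float]] = [None] * n
    for idx in groups.values():
        if len(idx) < 2:
            continue
        for i in idx:
            rivals[i] = max(xcorrs[j] for j in idx if j != i)

    fvs = [
        compute_feature_vector(
            rec, spec, cfg, xcorr_score=float(xcorrs[i]), rival_xcorr=rivals[i]
        )
        for i, (rec, spec) in enumerate(zip(records, specs))
    ]
    X = np.array(
        [np.concatenate([fv.expanded(), rec.extra_scores]) for fv, rec in zip(fvs, records)]
    )
    return fvs, X, xcorrs


def rescore_records(
    records: Sequence[PsmRecord],
    spectra_by_file: Mapping[str, Mapping],
    feat_cfg: FeatureConfig = FeatureConfig(),
    train_cfg: TrainingConfig = TrainingConfig(),
) -> tuple[list[FeatureVector], np.ndarray, RescoringResult]:
    """Features plus the iterative-SVM result for a set of PSM records."""
    fvs, X, xcorrs = extract_features(records, spectra_by_file, feat_cfg)
    is_decoy = np.array([r.is_decoy for r in records], dtype=bool)
    result = rescore_iteratively(X, is_decoy, xcorrs, train_cfg)
    return fvs, xcorrs, result


def load_spectra_for(
    records: Sequence[PsmRecord], mgf_dir: Union[str, Path]
) -> dict[str, Mapping]:
    """Load one MGF per distinct source-file value, resolved inside mgf_dir.

    Tries the literal name, then ``<name>.mgf``, then ``<stem>.mgf``.
    """
    mgf_dir = Path(mgf_dir)
    out: dict[str, Mapping] = {}
    for name in sorted({r.source_file for r in records}):
        candidates = [
            mgf_dir / name,
            mgf_dir / f"{name}.mgf",
            mgf_dir / f"{Path(name).stem}.mgf",
        ]
        path = next((c for c in candidates if c.is_file()), None)
        if path is None:
            raise FileNotFoundError(
                f"MGF file for source {name!r} not found in {mgf_dir}"
            )
        out[name] = read_mgf(path)
    return out


@dataclass
class RescoreRunSummary:
    n_psms: int
    n_targets: int
    n_decoys: int
    result: RescoringResult
    output_path: Path


def rescore_file(
    psm_path: Union[str, Path],
    mgf_dir: Union[str, Path],
    colspec: ColumnSpec,
    decoy_prefix: str = "XXX_",
    feat_cfg: FeatureConfig = FeatureConfig(),
    train_cfg: TrainingConfig = TrainingConfig(),
    out_path: Optional[Union[str, Path]] = None,
) -> RescoreRunSummary:
    """Read a PSM table and its MGF(s), rescore, and write the output table.

    By default the output lands next to the input as ``<stem>.rescored.tsv``.
    """
    psm_path = Path(psm_path)
    records = read_psm_table(psm_path, colspec, decoy_prefix)
    if not records:
        raise ValueError(f"no PSMs parsed from {psm_path}")
    spectra = load_spectra_for(records, mgf_dir)
    fvs, _, result = rescore_records(records, spectra, feat_cfg, train_cfg)
    if out_path is None:
        out_path = psm_path.with_suffix(".rescored.tsv")
    out_path = Path(out_path)
    write_rescored_table(records, fvs, result, out_path)
    n_decoys = sum(r.is_decoy for r in records)
    return RescoreRunSummary(
        n_psms=len(records),
        n_targets=len(records) - n_decoys,
        n_decoys=n_decoys,
        result=result,
        output_path=out_path,
    )
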