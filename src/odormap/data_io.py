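"""Readers, writers and preprocessing for paired spectrum/sensory datasets.

Mass spectra arrive as peak lists (integer nominal-mass m/z, nonnegative
intensity) from NIST-style MSP files, JCAMP-DX peak tables, or a dense CSV
matrix.  Preprocessing mirrors the modeling pipeline's contract:

* windowing to an inclusive m/z range (default 51-262, i.e. 212 integer
  bins — fragments below m/z 51 are dominated by odorless air components,
  very heavy fragments by low-volatility species);
* normalization by the single global maximum of a dataset, mapping every
  entry into [0, 1] with maximum exactly 1;
* alignment of spectrum and sensory matrices on their common sample ids.

Sensory data are descriptor-applicability matrices: one row per odorant, one
column per verbal descriptor, values in [0, 1] after normalization.
"""

from __future__ import annotations

import csv
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RawSpectrum",
    "SpectrumMatrix",
    "SensoryMatrix",
    "read_spectra",
    "write_spectra",
    "window_mz",
    "normalize_max",
    "align_by_id",
    "read_sensory_csv",
    "write_sensory_csv",
    "normalize_cas",
    "MZ_LO",
    "MZ_HI",
]

MZ_LO = 51
MZ_HI = 262


@dataclass
class RawSpectrum:
    """One electron-ionization spectrum: a compound id and its peak list."""

    compound_id: str
    peaks: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mz, inten in self.peaks.items():
            if mz <= 0:
                raise ValueError(f"{self.compound_id}: m/z must be positive, got {mz}")
            if inten < 0:
                raise ValueError(
                    f"{self.compound_id}: negative intensity {inten} at m/z {mz}"
                )


@dataclass
class SpectrumMatrix:
    """Dense N x bins intensity matrix; column j holds m/z ``mz_range[0] + j``."""

    ids: list[str]
    mz_range: tuple[int, int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        lo, hi = self.mz_range
        if self.values.shape != (len(self.ids), hi - lo + 1):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.ids)} ids and m/z range {lo}-{hi}"
            )

    @property
    def mz_values(self) -> np.ndarray:
        return np.arange(self.mz_range[0], self.mz_range[1] + 1)


@dataclass
class SensoryMatrix:
    """N x descriptors applicability matrix with descriptor labels."""

    ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.descriptor_names)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.ids)} ids and {len(self.descriptor_names)} descriptors"
            )


def normalize_cas(cas: str) -> str:
    """Canonicalize a CAS registry number: strip whitespace, re-hyphenate.

    No checksum validation is performed; a string that cannot be hyphenated
    is returned stripped, with a warning.
    """
    s = re.sub(r"\s+", "", str(cas))
    digits = s.replace("-", "")
    if digits.isdigit() and len(digits) >= 5:
        return f"{digits[:-3]}-{digits[-3:-1]}-{digits[-1]}"
    if not re.fullmatch(r"\d{2,7}-\d{2}-\d", s):
        logger.warning("id %r does not look like a CAS number; using as-is", s)
    return s


# ---------------------------------------------------------------------------
# readers / writers


def _round_mz(mz: float, where: str) -> int:
    if float(mz) != int(mz):
        logger.warning("%s: fractional m/z %s rounded to nearest integer", where, mz)
    return int(round(float(mz)))


def _read_msp(path: Path) -> list[RawSpectrum]:
    # matchms handles the NIST MSP dialect; imported lazily (slow import).
    from matchms.importing import load_from_msp

    out: list[RawSpectrum] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for idx, spec in enumerate(load_from_msp(str(path), metadata_harmonization=False)):
            if spec is None:
                raise ValueError(f"{path}: malformed MSP record at index {idx}")
            meta = spec.metadata
            cid = meta.get("cas") or meta.get("casno") or meta.get("compound_name")
            if cid is None:
                cid = f"record_{idx}"
            peaks: dict[int, float] = {}
            for mz, inten in zip(spec.peaks.mz, spec.peaks.intensities):
                peaks[_round_mz(mz, f"{path}[{idx}]")] = float(inten)
            out.append(RawSpectrum(compound_id=str(cid), peaks=peaks))
    return out


_JCAMP_PAIR = re.compile(r"([\d.+-eE]+)\s*,\s*([\d.+-eE]+)")


def _read_jcamp(path: Path) -> list[RawSpectrum]:
    """Minimal JCAMP-DX reader for ##PEAK TABLE=(XY..XY) blocks."""
    out: list[RawSpectrum] = []
    title = None
    cas = None
    peaks: dict[int, float] | None = None
    idx = 0

    def flush() -> None:
        nonlocal title, cas, peaks, idx
        if peaks is not None:
            cid = cas or title or f"record_{idx}"
            out.append(RawSpectrum(compound_id=str(cid), peaks=peaks))
            idx += 1
        title = cas = None
        peaks = None

    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "TITLE":
                flush()
                title = value
            elif key in ("CASREGISTRYNO", "CASREGISTRYNUMBER"):
                cas = value
            elif key in ("PEAKTABLE", "XYDATA"):
                peaks = {}
            elif key == "END":
                flush()
        elif peaks is not None:
            for x, y in _JCAMP_PAIR.findall(line):
                mz = _round_mz(float(x), f"{path}[{idx}]")
                inten = float(y)
                if inten < 0:
                    raise ValueError(f"{path}: record {idx}: negative intensity {inten}")
                peaks[mz] = inten
    flush()
    return out


def _read_csv_spectra(path: Path) -> list[RawSpectrum]:
    df = pd.read_csv(path, index_col=0)
    mzs = [_round_mz(float(c), str(path)) for c in df.columns]
    out = []
    for cid, row in zip(df.index.astype(str), df.to_numpy(dtype=float)):
        peaks = {mz: float(v) for mz, v in zip(mzs, row) if v != 0.0}
        out.append(RawSpectrum(compound_id=cid, peaks=peaks))
    return out


def read_spectra(path: str | Path, format: str | None = None) -> list[RawSpectrum]:
    """Read spectra from an MSP, JCAMP-DX or CSV-matrix file.

    ``format`` is one of ``"msp"``, ``"jcamp"``, ``"csv"``; when omitted it is
    inferred from the file suffix.  An empty file yields an empty list with a
    logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".msp": "msp", ".jdx": "jcamp", ".dx": "jcamp", ".csv": "csv"}.get(
            path.suffix.lower(), ""
        )
    if format not in ("msp", "jcamp", "csv"):
        raise ValueError(f"unknown spectrum format {format!r} for {path}")
    if path.stat().st_size == 0:
        logger.warning("%s is empty", path)
        return []
    reader = {"msp": _read_msp, "jcamp": _read_jcamp, "csv": _read_csv_spectra}[format]
    return reader(path)


def write_spectra(
    spectra: list[RawSpectrum], path: str | Path, format: str = "msp"
) -> None:
    """Write peak lists as MSP, JCAMP-DX or a dense CSV matrix."""
    path = Path(path)
    if format == "msp":
        with path.open("w") as fh:
            for s in spectra:
                fh.write(f"NAME: {s.compound_id}\n")
                fh.write(f"Num Peaks: {len(s.peaks)}\n")
                for mz in sorted(s.peaks):
                    fh.write(f"{mz} {s.peaks[mz]}\n")
                fh.write("\n")
    elif format == "jcamp":
        with path.open("w") as fh:
            for s in spectra:
                fh.write(f"##TITLE={s.compound_id}\n##JCAMP-DX=4.24\n")
                fh.write("##DATA TYPE=MASS SPECTRUM\n")
                fh.write(f"##NPOINTS={len(s.peaks)}\n##PEAK TABLE=(XY..XY)\n")
                for mz in sorted(s.peaks):
                    fh.write(f"{mz},{s.peaks[mz]}\n")
                fh.write("##END=\n")
    elif format == "csv":
        all_mz = sorted({mz for s in spectra for mz in s.peaks})
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", *all_mz])
            for s in spectra:
                writer.writerow([s.compound_id, *[s.peaks.get(mz, 0.0) for mz in all_mz]])
    else:
        raise ValueError(f"unknown spectrum format {format!r}")


def read_sensory_csv(path: str | Path) -> SensoryMatrix:
    """Read a sensory matrix: first column sample id, header descriptor names."""
    df = pd.read_csv(path, index_col=0)
    return SensoryMatrix(
        ids=[str(i) for i in df.index],
        descriptor_names=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_sensory_csv(sens: SensoryMatrix, path: str | Path) -> None:
    pd.DataFrame(sens.values, index=sens.ids, columns=sens.descriptor_names).to_csv(
        path, index_label="id"
    )


def write_spectrum_matrix_csv(spec: SpectrumMatrix, path: str | Path) -> None:
    pd.DataFrame(spec.values, index=spec.ids, columns=spec.mz_values).to_csv(
        path, index_label="id"
    )


# ---------------------------------------------------------------------------
# preprocessing


def window_mz(
    spectra: list[RawSpectrum], lo: int = MZ_LO, hi: int = MZ_HI
) -> SpectrumMatrix:
    """Dense, unnormalized intensity matrix over the inclusive m/z window.

    A peak at m/z ``lo`` lands in column 0, one at ``hi`` in the last column;
    peaks outside the window are dropped and absent bins are zero.  The
    default window 51-262 yields 212 columns.
    """
    if lo > hi:
        raise ValueError(f"invalid m/z window: lo={lo} > hi={hi}")
    n_bins = hi - lo + 1
    values = np.zeros((len(spectra), n_bins))
    for i, s in enumerate(spectra):
        for mz, inten in s.peaks.items():
            if lo <= mz <= hi:
                values[i, mz - lo] = inten
    return SpectrumMatrix(
        ids=[s.compound_id for s in spectra], mz_range=(lo, hi), values=values
    )


def normalize_max(matrix, per_sample: bool = False):
    """Divide by the single global dataset maximum, mapping into [0, 1].

    Accepts a plain array, a :class:`SpectrumMatrix` or a
    :class:`SensoryMatrix` and returns the same kind.  ``per_sample=True``
    normalizes each row by its own maximum instead (off by default; the
    standard preprocessing uses one scalar per dataset).  Negative entries or
    an all-zero matrix (undefined normalization) are errors.
    """
    if isinstance(matrix, SpectrumMatrix):
        return SpectrumMatrix(
            ids=list(matrix.ids),
            mz_range=matrix.mz_range,
            values=normalize_max(matrix.values, per_sample=per_sample),
        )
    if isinstance(matrix, SensoryMatrix):
        return SensoryMatrix(
            ids=list(matrix.ids),
            descriptor_names=list(matrix.descriptor_names),
            values=normalize_max(matrix.values, per_sample=per_sample),
        )
    values = np.asarray(matrix, dtype=float)
    if np.any(values < 0):
        raise ValueError("negative entries: intensities and applicabilities are nonnegative")
    if per_sample:
        row_max = values.max(axis=1, keepdims=True)
        if np.any(row_max == 0):
            raise ValueError("a row is all zero; per-sample normalization undefined")
        return values / row_max
    m = values.max()
    if m == 0:
        raise ValueError("all-zero matrix; normalization undefined")
    return values / m


def align_by_id(
    spec: SpectrumMatrix, sens: SensoryMatrix
) -> tuple[SpectrumMatrix, SensoryMatrix]:
    """Restrict both matrices to their common sample ids, in matching order.

    Ids are CAS-normalized before comparison.  Duplicate ids within one
    matrix and an empty intersection are errors.
    """
    spec_ids = [normalize_cas(i) for i in spec.ids]
    sens_ids = [normalize_cas(i) for i in sens.ids]
    for name, ids in (("spectrum", spec_ids), ("sensory", sens_ids)):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise ValueError(f"duplicate id {i!r} in {name} matrix")
            seen.add(i)
    sens_pos = {i: k for k, i in enumerate(sens_ids)}
    common = [i for i in spec_ids if i in sens_pos]
    if not common:
        raise ValueError("no common sample ids between spectrum and sensory data")
    spec_rows = [k for k, i in enumerate(spec_ids) if i in sens_pos]
    sens_rows = [sens_pos[i] for i in common]
    return (
        SpectrumMatrix(
            ids=common, mz_range=spec.mz_range, values=spec.values[spec_rows]
        ),
        SensoryMatrix(
            ids=common,
            descriptor_names=list(sens.descriptor_names),
            values=sens.values[sens_rows],
        ),
    )
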