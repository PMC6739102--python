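"""Reading and writing of spectra, peak lists, metadata and result tables.

The on-disk formats are the plain-text exports typical of MALDI-TOF
workflows: a raw spectrum is a two-column text file (m/z, intensity) or a
one-intensity-per-line file paired with an external m/z grid; a peak list
is a two-column file (m/z, signal-to-noise ratio).  Every raw spectrum in a
dataset must sit on the identical m/z grid, because downstream validation
correlates index-aligned intensity windows between spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "RawSpectrum",
    "PeakList",
    "MetadataTable",
    "SpectrumDataset",
    "read_raw_spectrum",
    "read_peak_list",
    "load_dataset",
    "write_outputs",
    "read_usf_matrix_csv",
]

#: tolerance (Da) for declaring two m/z grids identical
GRID_ATOL = 1e-9


class FormatError(ValueError):
    """Raised when an input file violates the expected layout or invariants."""


@dataclass(frozen=True)
class RawSpectrum:
    """A one-dimensional spectrum: intensities on a strictly increasing m/z axis."""

    spectrum_id: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.ndim != 1 or inten.ndim != 1 or mz.size != inten.size:
            raise FormatError(
                f"{self.spectrum_id}: mz and intensity must be 1-D and equal length"
            )
        if mz.size < 2:
            raise FormatError(f"{self.spectrum_id}: a spectrum needs >= 2 samples")
        if not np.all(np.diff(mz) > 0):
            raise FormatError(f"{self.spectrum_id}: m/z axis must be strictly increasing")
        if not np.all(np.isfinite(inten)) or np.any(inten < 0):
            raise FormatError(f"{self.spectrum_id}: intensities must be finite and >= 0")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class PeakList:
    """Detected peak centroids (m/z, Da) with signal-to-noise ratios."""

    spectrum_id: str
    mz: np.ndarray
    snr: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        snr = np.asarray(self.snr, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "snr", snr)
        if mz.ndim != 1 or snr.ndim != 1 or mz.size != snr.size:
            raise FormatError(f"{self.spectrum_id}: peak mz/snr must be 1-D, equal length")
        if mz.size and not np.all(np.diff(mz) > 0):
            raise FormatError(f"{self.spectrum_id}: peak m/z must be strictly increasing")
        if mz.size and (not np.all(np.isfinite(snr)) or np.any(snr < 0)):
            raise FormatError(f"{self.spectrum_id}: S/N must be finite and >= 0")

    def __len__(self) -> int:
        return int(self.mz.size)


class MetadataTable:
    """Per-spectrum metadata keyed by spectrum id.

    Wraps a DataFrame indexed by ``spectrum_id`` with at least a
    ``strain_label`` column; any further columns are carried through to the
    output match table untouched.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate spectrum ids in metadata: {dupes}")
        self.frame = frame

    @classmethod
    def from_csv(cls, path: str | Path) -> "MetadataTable":
        frame = pd.read_csv(path, dtype=str)
        if "spectrum_id" not in frame.columns:
            raise FormatError(f"{path}: metadata needs a 'spectrum_id' column")
        return cls(frame.set_index("spectrum_id"))

    def strain_of(self, spectrum_id: str) -> str:
        try:
            return str(self.frame.loc[spectrum_id, "strain_label"])
        except KeyError as exc:
            raise KeyError(f"no metadata row for spectrum {spectrum_id!r}") from exc

    def __contains__(self, spectrum_id: str) -> bool:
        return spectrum_id in self.frame.index


@dataclass
class SpectrumDataset:
    """All inputs of one dereplication run: (raw, peaks) per spectrum id.

    Invariant: every spectrum has both files and all raw spectra share one
    m/z grid (checked at construction; drift must be fixed by regridding).
    """

    records: dict[str, tuple[RawSpectrum, PeakList]]
    metadata: MetadataTable | None = None
    reference_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("dataset contains no spectra")
        ids = sorted(self.records)
        grid = self.records[ids[0]][0].mz
        for sid in ids:
            raw, peaks = self.records[sid]
            if raw.spectrum_id != sid or peaks.spectrum_id != sid:
                raise FormatError(f"record key {sid!r} does not match spectrum ids")
            if raw.mz.size != grid.size or not np.allclose(
                raw.mz, grid, rtol=0.0, atol=GRID_ATOL
            ):
                raise FormatError(
                    f"spectrum {sid!r} is not on the shared m/z grid; regrid first"
                )
        missing = [r for r in self.reference_ids if r not in self.records]
        if missing:
            raise FormatError(f"reference ids not in dataset: {missing}")

    @property
    def ids(self) -> list[str]:
        return sorted(self.records)

    @property
    def grid(self) -> np.ndarray:
        return self.records[self.ids[0]][0].mz

    def raw(self, sid: str) -> RawSpectrum:
        return self.records[sid][0]

    def peaks(self, sid: str) -> PeakList:
        return self.records[sid][1]

    def __len__(self) -> int:
        return len(self.records)


def _parse_rows(path: Path, n_cols: int) -> list[tuple[float, ...]]:
    """Parse whitespace/comma-delimited numeric rows, skipping '#' comments
    and a single non-numeric header line."""
    rows: list[tuple[float, ...]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.replace(",", " ").split()
            try:
                values = tuple(float(p) for p in parts)
            except ValueError:
                if not rows and lineno <= 2:  # tolerate one header line
                    continue
                raise FormatError(f"{path}:{lineno}: malformed row {text!r}") from None
            if len(values) != n_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(values)}"
                )
            rows.append(values)
    return rows


def read_raw_spectrum(
    path: str | Path,
    dialect: str = "two_column",
    grid: np.ndarray | None = None,
    spectrum_id: str | None = None,
) -> RawSpectrum:
    """Read a raw spectrum text export.

    ``two_column`` expects "mz intensity" rows; ``intensity_only`` expects one
    intensity per line and requires ``grid`` (the shared m/z axis).
    """
    path = Path(path)
    sid = spectrum_id if spectrum_id is not None else path.stem
    if dialect == "two_column":
        rows = _parse_rows(path, 2)
        if not rows:
            raise FormatError(f"{path}: no data rows")
        arr = np.asarray(rows, dtype=float)
        return RawSpectrum(sid, arr[:, 0], arr[:, 1])
    if dialect == "intensity_only":
        if grid is None:
            raise ValueError("intensity_only dialect requires an m/z grid")
        rows = _parse_rows(path, 1)
        inten = np.asarray([r[0] for r in rows], dtype=float)
        if inten.size != np.asarray(grid).size:
            raise FormatError(
                f"{path}: {inten.size} intensities do not fit grid of {np.asarray(grid).size}"
            )
        return RawSpectrum(sid, np.asarray(grid, dtype=float), inten)
    raise ValueError(f"unknown raw-spectrum dialect {dialect!r}")


def read_peak_list(path: str | Path, spectrum_id: str | None = None) -> PeakList:
    """Read a peak-list file of "mz snr" rows; empty file is a valid empty list."""
    path = Path(path)
    sid = spectrum_id if spectrum_id is not None else path.stem
    rows = _parse_rows(path, 2)
    if not rows:
        return PeakList(sid, np.empty(0), np.empty(0))
    arr = np.asarray(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    if not np.array_equal(order, np.arange(arr.shape[0])):
        warnings.warn(f"{path}: peaks were not sorted by m/z; sorting", stacklevel=2)
        arr = arr[order]
    return PeakList(sid, arr[:, 0], arr[:, 1])


def load_dataset(
    raw_dir: str | Path,
    peak_dir: str | Path,
    metadata: str | Path | None = None,
    reference_ids: Sequence[str] | None = None,
    dialect: str = "two_column",
) -> SpectrumDataset:
    """Load matched raw/peak file pairs from two directories.

    Pairing is by file stem; a stem present on only one side is an error.
    """
    raw_dir, peak_dir = Path(raw_dir), Path(peak_dir)
    raw_files = {p.stem: p for p in sorted(raw_dir.iterdir()) if p.is_file()}
    peak_files = {p.stem: p for p in sorted(peak_dir.iterdir()) if p.is_file()}
    orphans = sorted(set(raw_files) ^ set(peak_files))
    if orphans:
        raise FormatError(f"unpaired raw/peak file stems: {orphans}")
    if not raw_files:
        raise FormatError(f"no spectra found under {raw_dir}")
    records = {}
    for stem in sorted(raw_files):
        raw = read_raw_spectrum(raw_files[stem], dialect=dialect)
        peaks = read_peak_list(peak_files[stem])
        records[stem] = (raw, peaks)
    meta = MetadataTable.from_csv(metadata) if metadata is not None else None
    return SpectrumDataset(
        records=records,
        metadata=meta,
        reference_ids=list(reference_ids) if reference_ids else [],
    )


def write_outputs(result, usf, out_dir: str | Path) -> dict[str, Path]:
    """Write the match table and USF matrix CSVs for a finished run.

    The match table has one row per spectrum (quality class, reference ids,
    OIU, metadata columns if present); the USF matrix is written with ids in
    reference-selection-then-id order so a round trip reproduces it exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for sid in sorted(result.quality):
        qc = result.quality[sid]
        if sid in result.assignments:
            refs = [result.assignments[sid]]
        else:
            refs = sorted(r for r, _ in result.low_quality_matches.get(sid, ()))
        oiu = result.assignments.get(sid, "")
        rows.append(
            {
                "spectrum_id": sid,
                "quality_class": qc.quality_class,
                "n_strong_peaks": qc.n_strong_peaks,
                "reference_id": ";".join(refs),
                "oiu_id": oiu,
                "is_reference": sid in result.references,
            }
        )
    match = pd.DataFrame(rows)
    if result.metadata is not None:
        match = match.join(result.metadata.frame, on="spectrum_id")
    match_path = out_dir / "match_table.csv"
    match.to_csv(match_path, index=False)

    ref_order = [r for r in result.references if r in usf.ids]
    rest = [i for i in usf.ids if i not in set(ref_order)]
    ordered = ref_order + rest
    usf_frame = usf.to_frame().loc[ordered, ordered]
    usf_path = out_dir / "usf_matrix.csv"
    usf_frame.to_csv(usf_path)
    return {"match_table": match_path, "usf_matrix": usf_path}


def read_usf_matrix_csv(path: str | Path):
    """Round-trip reader for the USF matrix CSV written by :func:`write_outputs`."""
    from .usf import USFMatrix

    frame = pd.read_csv(path, index_col=0)
    if list(frame.index) != list(frame.columns):
        raise FormatError(f"{path}: USF matrix rows/columns disagree")
    return USFMatrix(ids=list(frame.index), counts=frame.to_numpy(dtype=np.int64))
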