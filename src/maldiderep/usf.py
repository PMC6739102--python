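"""Unique spectral features (USFs) between pairs of spectra.

Two spectra are compared in two stages.  First their peak lists are matched
within a mass-accuracy window expressed in parts per million (ppm) of the
peak m/z.  Second, every peak is validated on the raw signal: the Pearson
product-moment correlation (PPMC) between the two intensity traces in a
local window around the peak centroid decides whether the feature is shared.
A peak whose local PPMC falls below the threshold is a unique spectral
feature (USF) of its spectrum relative to the other.  This one rule covers
all cases: an unmatched peak with high local correlation was merely missed
by the peak caller and is treated as shared, while a matched peak with low
correlation (e.g. an m/z shift inside the window) is still unique.

USF counts are directional, so the matrix of pairwise counts is asymmetric:
``counts[i][j]`` is the number of features of spectrum *i* absent from *j*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import PeakList, RawSpectrum, SpectrumDataset

__all__ = [
    "DereplicationParams",
    "PeakMatchResult",
    "USFMatrix",
    "ppm_difference",
    "match_peaks",
    "local_ppmc",
    "count_usf_pair",
    "build_usf_matrix",
]


@dataclass(frozen=True)
class DereplicationParams:
    """Tunable parameters of the dereplication pipeline.

    ppm_window
        Mass-accuracy window for peak matching, in ppm (default 700).
    local_ppmc_threshold
        Fraction in [0, 1]; a peak with local PPMC below it is a USF
        (default 0.50; 0.20 is the species-level preset).
    snr_threshold
        S/N cut-off defining a "strong" peak for quality control (30).
    min_good_peaks
        Strong peaks required for a spectrum to be good quality (5).
    dice_threshold
        Dice coefficient a low-quality spectrum must exceed to be matched
        to a reference (0.70).
    ppmc_halfwidth_factor
        Local-correlation window half-width, as a multiple of the ppm
        window at the peak's m/z (default 2).
    compare_to
        Reference-selection pool: "evaluated" compares a candidate to every
        spectrum already visited in sorted order; "references" only to the
        references selected so far.
    """

    ppm_window: float = 700.0
    local_ppmc_threshold: float = 0.50
    snr_threshold: float = 30.0
    min_good_peaks: int = 5
    dice_threshold: float = 0.70
    ppmc_halfwidth_factor: float = 2.0
    compare_to: str = "evaluated"

    def __post_init__(self) -> None:
        if self.ppm_window <= 0:
            raise ValueError("ppm_window must be positive")
        if not 0.0 <= self.dice_threshold <= 1.0:
            raise ValueError("dice_threshold must lie in [0, 1]")
        if self.min_good_peaks < 1:
            raise ValueError("min_good_peaks must be >= 1")
        if self.ppmc_halfwidth_factor <= 0:
            raise ValueError("ppmc_halfwidth_factor must be positive")
        if self.compare_to not in ("evaluated", "references"):
            raise ValueError("compare_to must be 'evaluated' or 'references'")

    @classmethod
    def species_level(cls, **overrides) -> "DereplicationParams":
        """Preset for clustering at the species level (PPMC threshold 20%)."""
        overrides.setdefault("local_ppmc_threshold", 0.20)
        return cls(**overrides)


@dataclass(frozen=True)
class PeakMatchResult:
    """One-to-one matching between two peak lists."""

    matched: tuple[tuple[int, int], ...]
    unmatched_a: tuple[int, ...]
    unmatched_b: tuple[int, ...]

    def swap(self) -> "PeakMatchResult":
        return PeakMatchResult(
            matched=tuple(sorted((j, i) for i, j in self.matched)),
            unmatched_a=self.unmatched_b,
            unmatched_b=self.unmatched_a,
        )


@dataclass
class USFMatrix:
    """Asymmetric matrix of pairwise USF counts; diagonal is zero."""

    ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.ids)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square and match ids")
        if np.any(self.counts < 0):
            raise ValueError("USF counts must be non-negative")
        if np.any(np.diagonal(self.counts) != 0):
            raise ValueError("USF matrix diagonal must be zero")
        self._index = {sid: k for k, sid in enumerate(self.ids)}

    def value(self, a: str, b: str) -> int:
        return int(self.counts[self._index[a], self._index[b]])

    def row_sum(self, a: str) -> int:
        return int(self.counts[self._index[a]].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.ids, columns=self.ids)


def ppm_difference(mz_a: float, mz_b: float) -> float:
    """Relative m/z difference in ppm, symmetric (mean-centroid denominator)."""
    if mz_a <= 0 or mz_b <= 0:
        raise ValueError("m/z values must be positive")
    return abs(mz_a - mz_b) / ((mz_a + mz_b) / 2.0) * 1e6


def match_peaks(
    peaks_a: PeakList, peaks_b: PeakList, ppm_window: float
) -> PeakMatchResult:
    """Greedy one-to-one matching of two sorted peak lists within a ppm window.

    Candidate pairs inside the window are taken in order of ascending ppm
    difference (ties toward the lower-m/z pair), skipping peaks already used,
    so the result is deterministic and symmetric under swapping the inputs.
    """
    mza, mzb = peaks_a.mz, peaks_b.mz
    cands: list[tuple[float, float, int, int]] = []
    for i, ma in enumerate(mza):
        # window in Da grows with m/z; only a local band of B can match
        half = ppm_window * 1e-6 * ma / (1 - ppm_window * 0.5e-6)
        lo = int(np.searchsorted(mzb, ma - 2 * half, "left"))
        hi = int(np.searchsorted(mzb, ma + 2 * half, "right"))
        for j in range(lo, hi):
            d = ppm_difference(float(ma), float(mzb[j]))
            if d <= ppm_window:
                cands.append((d, float(min(ma, mzb[j])), i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _, _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j))
    return PeakMatchResult(
        matched=tuple(sorted(matched)),
        unmatched_a=tuple(k for k in range(len(mza)) if k not in used_a),
        unmatched_b=tuple(k for k in range(len(mzb)) if k not in used_b),
    )


def _ppmc_window(
    mz_axis: np.ndarray, center_mz: float, params: DereplicationParams
) -> tuple[int, int]:
    if not mz_axis[0] <= center_mz <= mz_axis[-1]:
        raise ValueError(f"peak centroid {center_mz} outside the m/z grid")
    half = params.ppmc_halfwidth_factor * params.ppm_window * center_mz * 1e-6
    lo = int(np.searchsorted(mz_axis, center_mz - half, "left"))
    hi = int(np.searchsorted(mz_axis, center_mz + half, "right"))
    if hi - lo < 3:
        raise ValueError(
            f"local PPMC window around {center_mz} Da covers {hi - lo} grid "
            "points (< 3); the grid is too coarse for this ppm window"
        )
    return lo, hi


def local_ppmc(
    raw_a: RawSpectrum,
    raw_b: RawSpectrum,
    center_mz: float,
    params: DereplicationParams,
) -> float:
    """Pearson correlation of the two raw traces in a window around a peak.

    Identical windows give 1; a window with zero variance on either side
    gives 0 (a flat trace carries no evidence of a shared feature).
    """
    lo, hi = _ppmc_window(raw_a.mz, center_mz, params)
    a = raw_a.intensity[lo:hi]
    b = raw_b.intensity[lo:hi]
    if np.array_equal(a, b):
        return 1.0
    am = a - a.mean()
    bm = b - b.mean()
    ssa = float(am @ am)
    ssb = float(bm @ bm)
    if ssa == 0.0 or ssb == 0.0:
        return 0.0
    r = float(am @ bm) / np.sqrt(ssa * ssb)
    return float(np.clip(r, -1.0, 1.0))


def count_usf_pair(
    a: tuple[RawSpectrum, PeakList],
    b: tuple[RawSpectrum, PeakList],
    params: DereplicationParams | None = None,
) -> tuple[int, int]:
    """USF counts of A relative to B and of B relative to A.

    Each side's peaks are validated around their own centroids; a peak is a
    USF of its spectrum iff the local PPMC against the other raw trace is
    below ``params.local_ppmc_threshold``.
    """
    params = params or DereplicationParams()
    raw_a, peaks_a = a
    raw_b, peaks_b = b
    t = params.local_ppmc_threshold
    usf_a = sum(
        1 for m in peaks_a.mz if local_ppmc(raw_a, raw_b, float(m), params) < t
    )
    usf_b = sum(
        1 for m in peaks_b.mz if local_ppmc(raw_b, raw_a, float(m), params) < t
    )
    return usf_a, usf_b


def build_usf_matrix(
    dataset: SpectrumDataset,
    params: DereplicationParams | None = None,
    ids: Sequence[str] | None = None,
) -> USFMatrix:
    """Pairwise USF counts over ``ids`` (default: all spectra, sorted by id)."""
    params = params or DereplicationParams()
    ids = sorted(ids) if ids is not None else dataset.ids
    n = len(ids)
    counts = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            uij, uji = count_usf_pair(
                dataset.records[ids[i]], dataset.records[ids[j]], params
            )
            counts[i, j] = uij
            counts[j, i] = uji
    return USFMatrix(ids=list(ids), counts=counts)
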