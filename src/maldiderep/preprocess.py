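"""Spectrum preprocessing: regridding onto a fixed m/z axis and
continuous-wavelet-transform (CWT) peak detection.

Regridding resamples a raw spectrum onto a shared equally spaced m/z grid by
inverse-distance weighting of the two bracketing raw samples (linear
interpolation); grid points outside the measured range get intensity 0.

Peak calling follows the classic CWT ridge scheme: the spectrum is convolved
with a Ricker (Mexican-hat) wavelet over a dyadic ladder of scales, local
maxima of the coefficients are linked into ridge lines across scales, and a
ridge is a peak if it persists over enough scales and its coefficient rises
sufficiently above the local noise floor (a high quantile of the
smallest-scale coefficients in a sliding window).  This makes the caller
robust to baseline drift and slowly varying noise without explicit
smoothing.  Only the S/N cut-off (3) and the relative amplitude floor
(1e-4 of the maximum intensity) are fixed conventions of the pipeline;
scales and ridge rules are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import PeakList, RawSpectrum

__all__ = ["GridSpec", "CwtParams", "make_grid", "regrid", "call_peaks_cwt", "CwtPeakCaller"]


@dataclass(frozen=True)
class GridSpec:
    """An equally spaced m/z axis from mz_min to mz_max inclusive."""

    mz_min: float
    mz_max: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.mz_min < self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        if self.n_points < 2:
            raise ValueError("a grid needs at least 2 points")

    @property
    def step(self) -> float:
        return (self.mz_max - self.mz_min) / (self.n_points - 1)


def _default_scales() -> tuple[int, ...]:
    return (1, 2, 4, 8, 16, 32, 64)


@dataclass(frozen=True)
class CwtParams:
    """Parameters of the CWT peak caller.

    snr_min: minimum ridge S/N (default 3).
    rel_amplitude_min: minimum apex intensity as a fraction of the spectrum
        maximum (default 1e-4).
    scales: wavelet scales in grid points (default 1..64, doubling).
    min_ridge_length: scales a ridge must span to count as a peak (5).
    gap_tolerance: consecutive scales a ridge may skip before closing (3).
    noise_window: sliding-window width (grid points) for the noise floor.
    noise_quantile: quantile of |smallest-scale coefficients| used as noise.
    snr_scale_max: largest scale whose ridge coefficient may define the peak
        strength.  Genuine peaks reach their best coefficient at a scale
        comparable to their width, whereas smoothed noise only builds broad
        coherent bumps at the largest scales; capping the strength scale
        suppresses those while leaving real peaks untouched.
    """

    snr_min: float = 3.0
    rel_amplitude_min: float = 1e-4
    scales: tuple[int, ...] = field(default_factory=_default_scales)
    min_ridge_length: int = 5
    gap_tolerance: int = 3
    noise_window: int = 500
    noise_quantile: float = 0.95
    snr_scale_max: float = 16.0

    def __post_init__(self) -> None:
        if self.snr_min <= 0:
            raise ValueError("snr_min must be positive")
        if not 0.0 <= self.rel_amplitude_min < 1.0:
            raise ValueError("rel_amplitude_min must lie in [0, 1)")
        sc = tuple(self.scales)
        if not sc or any(s <= 0 for s in sc) or any(
            b <= a for a, b in zip(sc, sc[1:])
        ):
            raise ValueError("scales must be positive and increasing")
        object.__setattr__(self, "scales", sc)


def make_grid(spec: GridSpec) -> np.ndarray:
    """Materialize the m/z axis of a :class:`GridSpec`."""
    return np.linspace(spec.mz_min, spec.mz_max, spec.n_points)


def regrid(raw: RawSpectrum, grid: np.ndarray) -> RawSpectrum:
    """Resample ``raw`` onto ``grid`` by inverse-distance weighted averaging.

    Each grid point takes the weighted average of the two raw samples that
    bracket it (weights inversely proportional to distance, i.e. linear
    interpolation); outside the measured m/z range the intensity is 0.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be a strictly increasing 1-D axis")
    inten = np.interp(grid, raw.mz, raw.intensity, left=0.0, right=0.0)
    return RawSpectrum(raw.spectrum_id, grid, inten)


def _ricker(n_points: int, scale: float) -> np.ndarray:
    """Ricker (Mexican-hat) wavelet, L2-normalized, on ``n_points`` samples."""
    amp = 2.0 / (np.sqrt(3.0 * scale) * np.pi**0.25)
    x = np.arange(n_points) - (n_points - 1) / 2.0
    xsq = x**2 / scale**2
    return amp * (1.0 - xsq) * np.exp(-xsq / 2.0)


def _cwt(signal: np.ndarray, scales: Sequence[int]) -> np.ndarray:
    out = np.empty((len(scales), signal.size))
    for k, a in enumerate(scales):
        width = int(min(10 * a + 1, signal.size))
        if width % 2 == 0:  # odd kernel: symmetric signals keep a unique apex
            width -= 1
        out[k] = np.convolve(signal, _ricker(width, a), mode="same")
    return out


def _local_maxima(row: np.ndarray, order: int) -> np.ndarray:
    """Indices of strict local maxima of ``row`` within a +/- order window."""
    from scipy.signal import argrelmax

    (idx,) = argrelmax(row, order=max(1, order), mode="clip")
    return idx[row[idx] > 0]


@dataclass
class _Ridge:
    rows: list[int]
    cols: list[int]
    gap: int = 0


def _link_ridges(coefs: np.ndarray, scales: Sequence[int], gap_tolerance: int) -> list[_Ridge]:
    """Link per-scale maxima into ridge lines, largest scale downward."""
    n_scales = len(scales)
    active: list[_Ridge] = []
    finished: list[_Ridge] = []
    for row in range(n_scales - 1, -1, -1):
        scale = scales[row]
        max_dist = max(1, scale // 4 + 1)
        maxima = list(_local_maxima(coefs[row], order=max(1, scale // 2)))
        taken: set[int] = set()
        still_active: list[_Ridge] = []
        for ridge in active:
            prev = ridge.cols[-1]
            best = None
            for c in maxima:
                if c in taken or abs(c - prev) > max_dist:
                    continue
                if best is None or abs(c - prev) < abs(best - prev):
                    best = c
            if best is not None:
                taken.add(best)
                ridge.rows.append(row)
                ridge.cols.append(best)
                ridge.gap = 0
                still_active.append(ridge)
            else:
                ridge.gap += 1
                if ridge.gap > gap_tolerance:
                    finished.append(ridge)
                else:
                    still_active.append(ridge)
        for c in maxima:
            if c not in taken:
                still_active.append(_Ridge(rows=[row], cols=[c]))
        active = still_active
    finished.extend(active)
    return finished


def call_peaks_cwt(raw: RawSpectrum, params: CwtParams | None = None) -> PeakList:
    """Detect peaks in a uniformly gridded spectrum by CWT ridge analysis.

    Returns centroid m/z (ridge position at the smallest scale reached) and
    S/N (maximum ridge coefficient over the local noise floor), keeping only
    ridges that span >= ``min_ridge_length`` scales, pass ``snr_min`` and
    whose apex intensity reaches ``rel_amplitude_min`` of the spectrum max.
    """
    params = params or CwtParams()
    steps = np.diff(raw.mz)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=0.0):
        raise ValueError("spectrum must be on a uniform m/z grid; regrid first")

    coefs = _cwt(raw.intensity, params.scales)
    ridges = _link_ridges(coefs, params.scales, params.gap_tolerance)

    # sliding noise floor from the smallest-scale coefficients
    abs_small = np.abs(coefs[0])
    halfwin = max(1, params.noise_window // 2)
    n = raw.intensity.size
    max_inten = float(raw.intensity.max())
    eps = 1e-12

    found: dict[int, float] = {}  # apex column -> best snr
    for ridge in ridges:
        if len(ridge.rows) < params.min_ridge_length:
            continue
        apex = ridge.cols[-1]  # smallest scale reached: most accurate position
        small = [
            (r, c)
            for r, c in zip(ridge.rows, ridge.cols)
            if params.scales[r] <= params.snr_scale_max
        ] or [(ridge.rows[-1], apex)]
        signal = max(abs(float(coefs[r, c])) for r, c in small)
        lo, hi = max(0, apex - halfwin), min(n, apex + halfwin)
        noise = max(float(np.quantile(abs_small[lo:hi], params.noise_quantile)), eps)
        snr = signal / noise
        if snr < params.snr_min:
            continue
        if raw.intensity[apex] < params.rel_amplitude_min * max_inten:
            continue
        found[apex] = max(found.get(apex, 0.0), snr)

    cols = np.array(sorted(found), dtype=int)
    return PeakList(
        raw.spectrum_id,
        raw.mz[cols] if cols.size else np.empty(0),
        np.array([found[c] for c in cols]) if cols.size else np.empty(0),
    )


class CwtPeakCaller(TransformerMixin, BaseEstimator):
    """Estimator-style wrapper around :func:`call_peaks_cwt`.

    Stateless (``fit`` is a no-op); ``transform`` maps raw spectra to peak
    lists so the caller can sit in a pipeline next to :class:`Dereplicator`.
    """

    def __init__(
        self,
        snr_min: float = 3.0,
        rel_amplitude_min: float = 1e-4,
        scales: tuple[int, ...] = _default_scales(),
        min_ridge_length: int = 5,
        gap_tolerance: int = 3,
    ):
        self.snr_min = snr_min
        self.rel_amplitude_min = rel_amplitude_min
        self.scales = scales
        self.min_ridge_length = min_ridge_length
        self.gap_tolerance = gap_tolerance

    def _params(self) -> CwtParams:
        return CwtParams(
            snr_min=self.snr_min,
            rel_amplitude_min=self.rel_amplitude_min,
            scales=tuple(self.scales),
            min_ridge_length=self.min_ridge_length,
            gap_tolerance=self.gap_tolerance,
        )

    def fit(self, X, y=None) -> "CwtPeakCaller":
        return self

    def transform(self, X: Sequence[RawSpectrum]) -> list[PeakList]:
        params = self._params()
        return [call_peaks_cwt(raw, params) for raw in X]
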